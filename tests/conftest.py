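"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plastidfind import (
    AMINO_ACIDS,
    WINDOW_COLUMNS,
    ScoringMatrix,
    SyntheticSpec,
    build_matrix,
    generate_benchmark,
    generate_toy_genome,
    generate_training_alignment,
)


# ---------------------------------------------------------------------------
# independent brute-force scorers (kept deliberately naive; they never call
# the implementation they check)

def oracle_window_score(sequence, mature_start, values: pd.DataFrame, columns):
    """Per-position loop over the matrix DataFrame."""
    total = 0.0
    complete = True
    for j in columns:
        if j > 0:
            pos = mature_start + j - 1
        else:
            pos = mature_start + j
        if pos < 1 or pos > len(sequence):
            complete = False
            continue
        residue = sequence[pos - 1]
        if residue in values.index:
            total += float(values.at[residue, j])
    return total, complete


def oracle_relocate(sequence, mature_start, values: pd.DataFrame):
    """Exhaustive candidate scoring with the documented tie rules."""
    scores = {}
    selectable = {}
    for d in (-2, -1, 0, 1, 2):
        site = mature_start + d
        if site < 1:
            scores[d] = 0.0
            selectable[d] = False
            continue
        scores[d], _ = oracle_window_score(sequence, site, values, WINDOW_COLUMNS)
        cov = 0
        for j in WINDOW_COLUMNS:
            pos = site + j - (1 if j > 0 else 0)
            if 1 <= pos <= len(sequence):
                cov += 1
        selectable[d] = cov > 0
    cands = [d for d in scores if selectable[d]] or [0]
    best = max(scores[d] for d in cands)
    tied = [d for d in cands if scores[d] == best]
    if 0 in tied:
        offset = 0
    else:
        smallest = min(abs(d) for d in tied)
        tied = [d for d in tied if abs(d) == smallest]
        offset = min(tied)
    return mature_start + offset, offset, tuple(scores[d] for d in (-2, -1, 0, 1, 2))


def random_matrix(rng: np.random.Generator) -> ScoringMatrix:
    """A structurally valid matrix with random non-negative entries."""
    raw = rng.random((20, 25)) * rng.random(25)  # vary column scale
    # normalize columns so the per-column sum stays within the bits bound
    raw = raw / raw.sum(axis=0, keepdims=True) * rng.uniform(0, 4.3, size=25)
    df = pd.DataFrame(raw, index=list(AMINO_ACIDS), columns=list(WINDOW_COLUMNS))
    return ScoringMatrix(df)


def random_sequence(rng: np.random.Generator, n: int, x_prob: float = 0.05) -> str:
    letters = list(AMINO_ACIDS) + ["X"]
    probs = [(1 - x_prob) / 20] * 20 + [x_prob]
    return "".join(rng.choice(letters, size=n, p=probs))


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def spec() -> SyntheticSpec:
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def trained_matrix(spec):
    return build_matrix(generate_training_alignment(spec, 500))


@pytest.fixture(scope="session")
def benchmark(spec):
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def toy_genome(spec):
    return generate_toy_genome(spec)
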