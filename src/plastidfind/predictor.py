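"""Core prediction: cleavage-site relocation, transit-peptide score, classes.

Given a protein, a positive signal-peptide call with its predicted cleavage
site, and a scoring matrix, the predictor

1. scores the five candidate cleavage sites within +/-2 of the predicted
   one with the full 25-column matrix and relocates the site to the
   highest-scoring candidate;
2. computes a transit-peptide score over columns +1..+20 only (the
   cleavage site itself is not evaluated);
3. assigns one of four classes:

   - "plastid, high confidence": relocated site agrees with the predictor
     (offset 0) and transit score strictly above the cutoff (default 2);
   - "plastid, low confidence": the +1 residue is one of F/W/Y/L but the
     high-confidence conditions fail;
   - "not plastid, SignalP positive": a signal peptide without an
     acceptable +1 residue (candidates for retention in the ER or other
     secretory targeting);
   - "not plastid, SignalP negative": no signal peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .matrix import WINDOW_COLUMNS, ScoringMatrix
from .signalp import SignalPResult

#: Residues accepted at the first transit-peptide position.
DEFAULT_PLUS1 = frozenset("FWYL")
#: Transit-peptide score cutoff gating the high-confidence call (strict >).
DEFAULT_CUTOFF = 2.0
#: Sliding-window offsets around the predictor's cleavage site.
OFFSETS = (-2, -1, 0, 1, 2)
#: Columns used per candidate in the reduced "core" scoring mode.
CORE5_COLUMNS = (-2, -1, 1, 2, 3)


class PredictionClass(Enum):
    """The four output classes, serialized with their canonical labels."""

    PLASTID_HIGH = "plastid, high confidence"
    PLASTID_LOW = "plastid, low confidence"
    NOT_PLASTID_SP_POSITIVE = "not plastid, SignalP positive"
    NOT_PLASTID_SP_NEGATIVE = "not plastid, SignalP negative"

    def __str__(self) -> str:
        return self.value


@dataclass
class PredictionRecord:
    """Per-protein prediction output."""

    id: str
    prediction: PredictionClass
    signalp_mature_start: int | None = None
    asafind_mature_start: int | None = None
    offset: int | None = None
    candidate_scores: tuple[float, ...] | None = None  # offsets -2..+2
    cleavage_score: float | None = None
    plus1_residue: str | None = None
    transit_score: float | None = None
    truncated_window: bool = False


def window_score(
    sequence: str,
    mature_start: int,
    matrix: ScoringMatrix,
    columns: Sequence[int] | None = None,
) -> tuple[float, bool]:
    """Score a sequence window anchored on a candidate cleavage site.

    ``mature_start`` is 1-based; matrix column j < 0 addresses residue
    ``mature_start + j`` and column j > 0 addresses ``mature_start + j - 1``
    (no position 0).  Positions falling outside the sequence and
    non-canonical residues contribute 0; the returned flag is False iff any
    addressed position fell outside the sequence.
    """
    if mature_start < 2:
        raise ValueError("mature_start must be >= 2")
    return _window_score_unchecked(sequence, mature_start, matrix, columns)


def _window_score_unchecked(
    sequence: str,
    mature_start: int,
    matrix: ScoringMatrix,
    columns: Sequence[int] | None = None,
) -> tuple[float, bool]:
    if columns is None:
        columns = WINDOW_COLUMNS
    if not len(columns):
        raise ValueError("columns must be non-empty")
    total = 0.0
    complete = True
    n = len(sequence)
    for j in columns:
        pos = mature_start + j - (1 if j > 0 else 0)  # 1-based
        if pos < 1 or pos > n:
            complete = False
            continue
        total += matrix.score(j, sequence[pos - 1])
    return total, complete


def _coverage(sequence: str, mature_start: int, columns: Sequence[int]) -> int:
    n = len(sequence)
    cov = 0
    for j in columns:
        pos = mature_start + j - (1 if j > 0 else 0)
        if 1 <= pos <= n:
            cov += 1
    return cov


def predict_cleavage_site(
    sequence: str,
    signalp_mature_start: int,
    matrix: ScoringMatrix,
    window_mode: str = "full25",
) -> tuple[int, int, tuple[float, ...]]:
    """Relocate the cleavage site within +/-2 of the predictor's call.

    Each of the five candidates is scored over the full 25-column window
    ("full25", default) or over the five core columns -2..+3 ("core5").
    Returns (relocated mature start, offset, the five candidate scores in
    offset order -2..+2).  Ties prefer offset 0, then the smallest
    |offset|, then the upstream candidate.
    """
    if signalp_mature_start < 2:
        raise ValueError("signalp_mature_start must be >= 2")
    if window_mode == "full25":
        columns: Sequence[int] = WINDOW_COLUMNS
    elif window_mode == "core5":
        columns = CORE5_COLUMNS
    else:
        raise ValueError(f"unknown window mode '{window_mode}'")

    scores: list[float] = []
    selectable: list[bool] = []
    for d in OFFSETS:
        site = signalp_mature_start + d
        if site < 2:
            # impossible cleavage position: scored with zero-fill but only
            # selectable if its window still covers part of the sequence
            score, _ = _window_score_unchecked(sequence, site, matrix, columns) \
                if site >= 1 else (0.0, False)
            scores.append(score if site >= 1 else 0.0)
            selectable.append(site >= 1 and _coverage(sequence, site, columns) > 0)
        else:
            score, _ = _window_score_unchecked(sequence, site, matrix, columns)
            scores.append(score)
            selectable.append(_coverage(sequence, site, columns) > 0)

    candidates = [d for d, ok in zip(OFFSETS, selectable) if ok] or [0]
    best = max(scores[OFFSETS.index(d)] for d in candidates)
    tied = [d for d in candidates if scores[OFFSETS.index(d)] == best]
    offset = min(tied, key=lambda d: (abs(d), d > 0))
    return signalp_mature_start + offset, offset, tuple(scores)


def transit_peptide_score(
    sequence: str, asafind_mature_start: int, matrix: ScoringMatrix
) -> tuple[float, bool]:
    """Score the 20 residues downstream of the cleavage site (+1..+20).

    The cleavage-site columns -5..-1 are excluded: this score evaluates the
    transit peptide, not the ER cleavage site itself.
    """
    return window_score(
        sequence, asafind_mature_start, matrix, columns=tuple(range(1, 21))
    )


def _clean_sequence(sequence: str, seq_id: str) -> str:
    seq = sequence.upper()
    star = seq.find("*")
    if star != -1:
        warnings.warn(
            f"{seq_id}: stop character at position {star + 1}; "
            "it and everything after it are ignored",
            stacklevel=3,
        )
        seq = seq[:star]
    return seq


def classify(
    sequence: str,
    signalp: SignalPResult,
    matrix: ScoringMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    plus1_set: frozenset[str] | set[str] = DEFAULT_PLUS1,
    window_mode: str = "full25",
) -> PredictionRecord:
    """Run the full decision procedure for one protein."""
    if not sequence:
        raise ValueError(f"{signalp.id}: empty sequence")
    seq = _clean_sequence(sequence, signalp.id)

    if not signalp.positive:
        return PredictionRecord(
            id=signalp.id, prediction=PredictionClass.NOT_PLASTID_SP_NEGATIVE
        )

    ms = signalp.mature_start
    assert ms is not None
    site, offset, cand_scores = predict_cleavage_site(seq, ms, matrix, window_mode)
    cleavage_score = max(cand_scores)
    plus1 = seq[site - 1] if site <= len(seq) else None
    _, win_complete = _window_score_unchecked(seq, site, matrix, WINDOW_COLUMNS)
    t_score, t_complete = _window_score_unchecked(
        seq, site, matrix, tuple(range(1, 21))
    )
    truncated = not (win_complete and t_complete)

    base = dict(
        id=signalp.id,
        signalp_mature_start=ms,
        asafind_mature_start=site,
        offset=offset,
        candidate_scores=cand_scores,
        cleavage_score=cleavage_score,
        plus1_residue=plus1,
        transit_score=t_score,
        truncated_window=truncated,
    )
    if plus1 is None or plus1 not in plus1_set:
        return PredictionRecord(prediction=PredictionClass.NOT_PLASTID_SP_POSITIVE, **base)
    if offset == 0 and t_score > cutoff:
        return PredictionRecord(prediction=PredictionClass.PLASTID_HIGH, **base)
    return PredictionRecord(prediction=PredictionClass.PLASTID_LOW, **base)


def classify_all(
    sequences: Iterable[tuple[str, str]],
    signalp_results: Sequence[SignalPResult],
    matrix: ScoringMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    plus1_set: frozenset[str] | set[str] = DEFAULT_PLUS1,
    window_mode: str = "full25",
) -> list[PredictionRecord]:
    """Classify every (id, sequence) pair against its predictor record."""
    from .signalp import match_to_sequences

    seqs = list(sequences)
    matched = match_to_sequences(signalp_results, [sid for sid, _ in seqs])
    out = []
    for sid, seq in seqs:
        key = sid.split()[0]
        out.append(
            classify(seq, matched[key], matrix, cutoff, plus1_set, window_mode)
        )
    return out


PREDICTION_TSV_COLUMNS = (
    "id", "signalp_pos", "asafind_pos", "offset",
    "score_m2", "score_m1", "score_0", "score_p1", "score_p2",
    "cleavage_score", "plus1_aa", "transit_score", "truncated", "prediction",
)


def _fmt(value, number: bool = False) -> str:
    if value is None:
        return "."
    if number and isinstance(value, float):
        return "%.6f" % value
    return str(value)


def predictions_to_tsv_lines(records: Sequence[PredictionRecord]) -> list[str]:
    """Serialize predictions to the frozen TSV layout (absent values '.')."""
    lines = ["\t".join(PREDICTION_TSV_COLUMNS)]
    for r in records:
        cand = r.candidate_scores or (None,) * 5
        fields = [
            r.id,
            _fmt(r.signalp_mature_start),
            _fmt(r.asafind_mature_start),
            _fmt(r.offset),
            *[_fmt(c, number=True) for c in cand],
            _fmt(r.cleavage_score, number=True),
            _fmt(r.plus1_residue),
            _fmt(r.transit_score, number=True),
            "Y" if r.truncated_window else "N",
            r.prediction.value,
        ]
        lines.append("\t".join(fields))
    return lines


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    Path(path).write_text("\n".join(predictions_to_tsv_lines(records)) + "\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Read a predictions TSV back into records (for evaluation)."""
    labels = {c.value: c for c in PredictionClass}
    records = []
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines or lines[0].split("\t")[0] != "id":
        raise ValueError("predictions file missing header")
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(PREDICTION_TSV_COLUMNS):
            raise ValueError(f"bad predictions row: {ln!r}")

        def opt(x, conv):
            return None if x == "." else conv(x)

        cand = tuple(opt(x, float) for x in f[4:9])
        records.append(
            PredictionRecord(
                id=f[0],
                signalp_mature_start=opt(f[1], int),
                asafind_mature_start=opt(f[2], int),
                offset=opt(f[3], int),
                candidate_scores=None if cand[0] is None else cand,  # type: ignore[arg-type]
                cleavage_score=opt(f[9], float),
                plus1_residue=opt(f[10], str),
                transit_score=opt(f[11], float),
                truncated_window=f[12] == "Y",
                prediction=labels[f[13]],
            )
        )
    return records
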