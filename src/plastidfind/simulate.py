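"""Seeded synthetic data: benchmark proteins, training alignments, toy genomes.

Everything downstream of this module is testable without sequence downloads
or an external signal-peptide predictor.  The generator emulates the
structure of red-lineage bipartite plastid-targeting presequences:

* positives carry a hydrophobic signal peptide whose C-terminal five
  residues and the first twenty transit-peptide residues are drawn from a
  ground-truth probability matrix shaped like the ASAFAP cleavage motif
  (A-rich -3/-1, S at -2, a dominant phenylalanine at +1, A at +2, P
  enriched at +3, an S/T/R/K-rich and D/E-poor transit peptide);
* secretory negatives share the signal peptide (including a realistic
  A-X-A style c-region, which signal peptidase imposes on plastid and
  secretory proteins alike) but continue with background composition, with
  every candidate +1 position of the sliding window kept outside
  {F, W, Y, L} so the negative label is unambiguous;
* non-secretory negatives have no signal peptide at all.

Matched mock predictor output carries the true cleavage sites (optionally
perturbed by one position) so the prediction pipeline can run end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import AMINO_ACIDS, WINDOW_COLUMNS, CleavageWindow
from .signalp import SignalPResult
from .genecatalog import GeneModel, GenomeSequence

# ---------------------------------------------------------------------------
# residue compositions


def _composition(spec: Mapping[str, float]) -> pd.Series:
    """Full 20-residue probability vector; unspecified residues share the
    leftover mass equally."""
    probs = pd.Series(0.0, index=list(AMINO_ACIDS))
    for aa, p in spec.items():
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue '{aa}'")
        probs[aa] = p
    rest = 1.0 - sum(spec.values())
    if rest < -1e-9:
        raise ValueError("composition probabilities exceed 1")
    unspecified = [a for a in AMINO_ACIDS if a not in spec]
    if unspecified and rest > 0:
        probs[unspecified] = rest / len(unspecified)
    return probs / probs.sum()


#: Whole-proteome-like background (approximate Swiss-Prot frequencies).
BACKGROUND = _composition({
    "A": .083, "R": .055, "N": .040, "D": .054, "C": .014, "Q": .039,
    "E": .067, "G": .071, "H": .023, "I": .059, "L": .096, "K": .058,
    "M": .024, "F": .039, "P": .047, "S": .066, "T": .053, "W": .011,
    "Y": .029, "V": .069,
})

#: Hydrophobic signal-peptide core.
SIGNAL_CORE = _composition({
    "L": .28, "A": .18, "V": .12, "F": .09, "I": .09, "S": .06,
    "T": .05, "G": .05, "M": .03, "W": .02, "C": .02, "P": .01,
})

#: Signal-peptide c-region (last five residues): small-residue biased,
#: as required by signal peptidase for any ER-targeted protein.
SIGNAL_CREGION = _composition({
    "A": .45, "S": .15, "V": .08, "G": .08, "T": .06, "L": .06,
    "C": .04, "P": .03, "Q": .03, "F": .02,
})

#: Transit peptide beyond the scored window: hydroxylated (S/T) and
#: positive (R/K) residues enriched, acidic (D/E) residues depleted.
TRANSIT_COMPOSITION = _composition({
    "S": .20, "A": .13, "T": .10, "R": .08, "K": .07, "G": .05,
    "F": .04, "L": .04, "N": .04, "P": .04, "V": .04, "Q": .04,
    "I": .03, "M": .02, "H": .02, "Y": .02,
    "C": .01, "W": .01, "D": .01, "E": .01,
})


def default_ground_truth_pwm() -> pd.DataFrame:
    """Per-column residue probabilities of the synthetic cleavage motif.

    Qualitatively shaped like the diatom ASAFAP logo; the numeric values
    are fixture constants of this package, not the published training
    matrix.
    """
    transit = TRANSIT_COMPOSITION.to_dict()
    columns = {
        -5: {"A": .22, "S": .12, "L": .12, "V": .10, "T": .08, "F": .06,
             "G": .06, "I": .05, "C": .03, "M": .03},
        -4: {"A": .20, "S": .10, "L": .12, "V": .10, "F": .08, "T": .06,
             "I": .06, "G": .06},
        -3: {"A": .45, "S": .12, "V": .10, "G": .06, "T": .06, "C": .04,
             "L": .04},
        -2: {"S": .30, "A": .22, "T": .08, "N": .06, "G": .06, "L": .05,
             "Q": .04},
        -1: {"A": .55, "S": .12, "G": .08, "C": .05, "T": .05, "V": .03},
        1: {"F": .90, "L": .03, "Y": .03, "W": .01, "S": .01},
        2: {"A": .30, "S": .12, "V": .10, "P": .08, "T": .07, "G": .06,
            "N": .05, "L": .05},
        3: {"P": .28, "A": .14, "S": .12, "Q": .07, "N": .06, "T": .06,
            "G": .05},
    }
    data = {}
    for col in WINDOW_COLUMNS:
        data[col] = _composition(columns[col]) if col in columns else pd.Series(transit)
    return pd.DataFrame(data, index=list(AMINO_ACIDS))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark."""

    seed: int = 0
    n_positive: int = 200
    n_secretory_negative: int = 200
    n_nonsecretory: int = 200
    signal_length_range: tuple[int, int] = (14, 22)   # incl. initiator Met
    transit_length_range: tuple[int, int] = (25, 45)
    mature_length_range: tuple[int, int] = (80, 200)
    site_perturb_prob: float = 0.0
    ground_truth_pwm: pd.DataFrame = field(default_factory=default_ground_truth_pwm)
    transit_composition: pd.Series = field(
        default_factory=lambda: TRANSIT_COMPOSITION.copy()
    )

    def __post_init__(self) -> None:
        for lo, hi in (self.signal_length_range, self.transit_length_range,
                       self.mature_length_range):
            if lo > hi or lo < 1:
                raise ValueError("length ranges must be non-empty")
        if self.signal_length_range[0] < 7:
            raise ValueError("signal peptides must be at least 7 residues "
                             "(Met + core + 5-residue c-region)")
        if self.transit_length_range[0] < 20:
            raise ValueError("transit peptides must cover the 20 scored positions")
        if not 0.0 <= self.site_perturb_prob <= 1.0:
            raise ValueError("site_perturb_prob must be in [0, 1]")
        sums = self.ground_truth_pwm.sum(axis=0)
        if not np.allclose(sums.to_numpy(), 1.0, atol=1e-6):
            raise ValueError("ground-truth PWM columns must sum to 1")
        if not math.isclose(float(self.transit_composition.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("transit composition must sum to 1")


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one benchmark protein."""

    id: str
    category: str  # plastid | secretory | non_secretory
    true_plastid: bool
    true_mature_start: int | None


def _draw(rng: np.random.Generator, composition: pd.Series, n: int) -> str:
    return "".join(
        rng.choice(list(composition.index), size=n, p=composition.to_numpy())
    )


def _draw_window(rng: np.random.Generator, pwm: pd.DataFrame) -> str:
    return "".join(
        rng.choice(list(pwm.index), p=pwm[c].to_numpy()) for c in WINDOW_COLUMNS
    )


def _signal_peptide(rng: np.random.Generator, spec: SyntheticSpec,
                    cregion: str | None) -> str:
    """Met + hydrophobic core + 5-residue c-region (supplied or sampled)."""
    length = int(rng.integers(spec.signal_length_range[0],
                              spec.signal_length_range[1] + 1))
    core = _draw(rng, SIGNAL_CORE, length - 6)
    tail = cregion if cregion is not None else _draw(rng, SIGNAL_CREGION, 5)
    return "M" + core + tail


def _mock_positive(rng: np.random.Generator, spec: SyntheticSpec,
                   name: str, mature_start: int) -> SignalPResult:
    site = mature_start
    if spec.site_perturb_prob > 0 and rng.random() < spec.site_perturb_prob:
        site += int(rng.choice([-1, 1]))
        site = max(site, 2)
    scores = {"Cmax": 0.7, "Ymax": 0.75, "Smax": 0.92, "Smean": 0.85, "D": 0.8}
    return SignalPResult(name, True, site, scores)


def generate_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[tuple[str, str]], list[SignalPResult], list[TruthLabel]]:
    """Generate the three benchmark classes with matched predictor output.

    Returns (FASTA records as (id, sequence), mock predictor records,
    truth labels).  Fully deterministic per spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    nonset = [a for a in BACKGROUND.index if a not in "FWYL"]
    bg_nonset = BACKGROUND[nonset] / BACKGROUND[nonset].sum()
    if bg_nonset.isna().any() or not len(nonset):
        raise ValueError("background composition leaves no +1 residue outside FWYL")

    records: list[tuple[str, str]] = []
    signalp: list[SignalPResult] = []
    truths: list[TruthLabel] = []

    for i in range(spec.n_positive):
        name = f"pos_{i + 1:04d}"
        window = _draw_window(rng, spec.ground_truth_pwm)
        sp = _signal_peptide(rng, spec, cregion=window[:5])
        t_len = int(rng.integers(spec.transit_length_range[0],
                                 spec.transit_length_range[1] + 1))
        transit = window[5:] + _draw(rng, spec.transit_composition, t_len - 20)
        m_len = int(rng.integers(spec.mature_length_range[0],
                                 spec.mature_length_range[1] + 1))
        seq = sp + transit + _draw(rng, BACKGROUND, m_len)
        ms = len(sp) + 1
        records.append((name, seq))
        signalp.append(_mock_positive(rng, spec, name, ms))
        truths.append(TruthLabel(name, "plastid", True, ms))

    # for negatives, all five +1 candidates of the sliding window (the two
    # last c-region residues and the first three downstream residues) avoid
    # F/W/Y/L so that the negative class label is unambiguous
    creg_nonset = SIGNAL_CREGION[nonset] / SIGNAL_CREGION[nonset].sum()
    for i in range(spec.n_secretory_negative):
        name = f"sec_{i + 1:04d}"
        cregion = _draw(rng, SIGNAL_CREGION, 3) + _draw(rng, creg_nonset, 2)
        sp = _signal_peptide(rng, spec, cregion=cregion)
        downstream = _draw(rng, bg_nonset, 3) + _draw(rng, BACKGROUND, 17)
        m_len = int(rng.integers(spec.mature_length_range[0],
                                 spec.mature_length_range[1] + 1))
        seq = sp + downstream + _draw(rng, BACKGROUND, m_len)
        ms = len(sp) + 1
        records.append((name, seq))
        signalp.append(_mock_positive(rng, spec, name, ms))
        truths.append(TruthLabel(name, "secretory", False, ms))

    for i in range(spec.n_nonsecretory):
        name = f"neg_{i + 1:04d}"
        m_len = int(rng.integers(spec.mature_length_range[0],
                                 spec.mature_length_range[1] + 1))
        seq = "M" + _draw(rng, BACKGROUND, m_len + 40)
        records.append((name, seq))
        scores = {"Cmax": 0.1, "Ymax": 0.12, "Smax": 0.2, "Smean": 0.15, "D": 0.13}
        signalp.append(SignalPResult(name, False, None, scores))
        truths.append(TruthLabel(name, "non_secretory", False, None))

    return records, signalp, truths


def generate_training_alignment(spec: SyntheticSpec, n: int) -> list[CleavageWindow]:
    """Sample n 25-mer cleavage windows column-independently from the PWM."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return [
        CleavageWindow(_draw_window(rng, spec.ground_truth_pwm), f"train_{i + 1:05d}")
        for i in range(n)
    ]


def signalp_short_lines(results: Sequence[SignalPResult]) -> list[str]:
    """Render mock predictor records in the 14-column short text format."""
    lines = ["# SignalP-NN euk predictions (synthetic mock)"]
    for r in results:
        s = dict(r.raw_scores) or {"Cmax": 0.0, "Ymax": 0.0, "Smax": 0.0,
                                   "Smean": 0.0, "D": 0.0}
        flag = "Y" if r.positive else "N"
        pos = r.mature_start if r.positive else 1
        lines.append(
            f"{r.id} {s['Cmax']:.3f} {pos} {flag} {s['Ymax']:.3f} {pos} {flag} "
            f"{s['Smax']:.3f} {max(pos - 5, 1)} {flag} {s['Smean']:.3f} {flag} "
            f"{s['D']:.3f} {flag}"
        )
    return lines


# ---------------------------------------------------------------------------
# toy genome

_BODY_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "F": "TTC", "P": "CCG", "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAC",
    "V": "GTT",
}  # no Met codon: ORF bodies avoid internal in-frame ATG by construction


def _orf(rng: np.random.Generator, n_body: int) -> tuple[str, str]:
    """(nucleotides, protein) of ATG + n_body safe codons + TAA."""
    body_aas = "".join(rng.choice(list(_BODY_CODON), size=n_body))
    nt = "ATG" + "".join(_BODY_CODON[a] for a in body_aas) + "TAA"
    return nt, "M" + body_aas


def _background_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@dataclass
class ToyGenome:
    """Planted toy genome with models of known intended fate."""

    genome: GenomeSequence
    models: list[GeneModel]
    unmapped_proteins: list[tuple[str, str]]
    #: model/protein id -> expectation dict (action, and for extensions the
    #: full ORF coordinates and protein)
    truth: dict[str, dict[str, object]]


def generate_toy_genome(spec: SyntheticSpec) -> ToyGenome:
    """Build a genome with planted ORFs exercising every optimizer rule.

    Planted cases: a model truncated at both ends, a reverse-strand
    truncated model, nested overlapping models (longest wins), an
    identical-protein pair (curated model wins), a model without EST
    support, a >10 kb model, and unmapped paralogs at identity 1.0
    (excluded) and ~0.75 (rescued).
    """
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    offset = 0
    models: list[GeneModel] = []
    truth: dict[str, dict[str, object]] = {}

    def emit(dna: str) -> int:
        nonlocal offset
        parts.append(dna)
        start = offset + 1
        offset += len(dna)
        return start

    emit(_background_dna(rng, 100))

    # A: truncated at both ends; extension recovers the full ORF
    orf_a, prot_a = _orf(rng, 40)
    a0 = emit(orf_a)
    a_end = a0 + len(orf_a) - 1
    models.append(GeneModel("mA", "chr1", "+", a0 + 6, a_end - 9, est_support=True))
    truth["mA"] = {"action": "extended", "start": a0, "end": a_end, "protein": prot_a}
    emit(_background_dna(rng, 50))

    # B: nested ORFs, the longer model wins the locus
    inner_b, prot_b_inner = _orf(rng, 15)
    head_b = "".join(
        _BODY_CODON[a] for a in rng.choice(list(_BODY_CODON), size=20)
    )
    orf_b = "ATG" + head_b + inner_b[:-3] + "TAA"
    b0 = emit(orf_b)
    b_end = b0 + len(orf_b) - 1
    models.append(GeneModel("mB_long", "chr1", "+", b0, b_end, est_support=True))
    models.append(
        GeneModel("mB_short", "chr1", "+", b0 + 3 + len(head_b), b_end,
                  est_support=True, jgi_filtered=True)
    )
    truth["mB_long"] = {"action": "selected", "start": b0, "end": b_end}
    truth["mB_short"] = {"action": "dropped:locus_selection"}
    emit(_background_dna(rng, 50))

    # C: identical protein at two loci; the curated model is kept
    orf_c, prot_c = _orf(rng, 30)
    c1 = emit(orf_c)
    emit(_background_dna(rng, 40))
    c2 = emit(orf_c)
    models.append(GeneModel("mC1", "chr1", "+", c1, c1 + len(orf_c) - 1,
                            est_support=True, jgi_filtered=False))
    models.append(GeneModel("mC2", "chr1", "+", c2, c2 + len(orf_c) - 1,
                            est_support=True, jgi_filtered=True))
    truth["mC1"] = {"action": "dropped:duplicate_protein", "protein": prot_c}
    truth["mC2"] = {"action": "selected", "protein": prot_c}
    emit(_background_dna(rng, 50))

    # D: reverse strand, 5'-truncated model
    from Bio.Seq import Seq

    orf_d, prot_d = _orf(rng, 25)
    d0 = emit(str(Seq(orf_d).reverse_complement()))
    d_end = d0 + len(orf_d) - 1
    models.append(GeneModel("mD", "chr1", "-", d0 + 3, d_end - 6, est_support=True))
    truth["mD"] = {"action": "extended", "start": d0, "end": d_end, "protein": prot_d}
    emit(_background_dna(rng, 50))

    # E: valid ORF without EST support
    orf_e, _ = _orf(rng, 20)
    e0 = emit(orf_e)
    models.append(GeneModel("mE", "chr1", "+", e0, e0 + len(orf_e) - 1,
                            est_support=False))
    truth["mE"] = {"action": "dropped:invalid_est"}

    # F: over-long model spanning >10 kb of background
    long_start = emit(_background_dna(rng, 10_200))
    models.append(GeneModel("mLong", "chr1", "+", long_start + 30,
                            long_start + 30 + 10_049, est_support=True))
    truth["mLong"] = {"action": "dropped:over_10000nt"}
    emit(_background_dna(rng, 60))

    genome = GenomeSequence("chr1", "".join(parts))

    # unmapped paralogs
    mutated = list(prot_a)
    for i in range(1, len(mutated), 4):  # mutate every 4th residue -> ~75% identity
        mutated[i] = "G" if mutated[i] != "G" else "A"
    unmapped = [("u_dup_of_C", prot_c), ("u_paralog_of_A", "".join(mutated))]
    truth["u_dup_of_C"] = {"action": "dropped:redundant_unmapped"}
    truth["u_paralog_of_A"] = {"action": "rescued"}

    return ToyGenome(genome, models, unmapped, truth)


# ---------------------------------------------------------------------------
# FASTA helpers

def write_fasta(records: Sequence[tuple[str, str]], path, seed: int | None = None) -> None:
    """Write (id, sequence) pairs as FASTA; the seed is recorded per header."""
    from pathlib import Path

    lines = []
    tag = f" seed={seed}" if seed is not None else ""
    for name, seq in records:
        lines.append(f">{name}{tag}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs; '#' comment lines are tolerated."""
    from io import StringIO
    from pathlib import Path

    from Bio import SeqIO

    text = "\n".join(
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    )
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(StringIO(text), "fasta")]
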