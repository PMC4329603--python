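"""Information-weighted cleavage-site scoring matrix.

The scoring matrix covers a 25-residue window around the signal-peptide
cleavage site: five positions upstream (columns -5..-1, the C-terminal end
of the signal peptide) and twenty downstream (columns +1..+20, the start of
the transit peptide).  There is no column 0; the scissile bond lies between
-1 and +1, so the conserved phenylalanine of the ASAFAP motif sits at +1.

Each matrix cell is the empirical residue frequency in that column of the
training alignment multiplied by the column's information content in bits
(sequence-logo weighting): ``M(j, a) = f(j, a) * R(j)`` with
``R(j) = log2(20) - H(j) - e(n)`` where ``H`` is the Shannon entropy of the
column and ``e(n) = 19 / (2 ln2 n)`` the optional small-sample correction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Window columns in order: -5..-1 then +1..+20 (no column 0).
WINDOW_COLUMNS: tuple[int, ...] = tuple(range(-5, 0)) + tuple(range(1, 21))
WINDOW_LENGTH = len(WINDOW_COLUMNS)  # 25
MAX_BITS = math.log2(20)


class DegenerateColumnError(ValueError):
    """A window column holds no countable (canonical) residues."""


class MatrixFormatError(ValueError):
    """A scoring-matrix file violates the TSV dialect."""


@dataclass(frozen=True)
class CleavageWindow:
    """A 25-mer spanning a signal-peptide cleavage site (-5..+20).

    ``residues`` may contain 'X' for unknown positions; anything outside
    the 20-letter alphabet is treated as unknown when counting.
    """

    residues: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(
                f"cleavage window must be {WINDOW_LENGTH} residues, "
                f"got {len(self.residues)} ({self.source_id or 'unnamed'})"
            )


def small_sample_correction(n: int, alphabet_size: int = 20) -> float:
    """e(n) = (s - 1) / (2 ln2 n), the logo small-sample bias term."""
    if n <= 0:
        raise ValueError("n must be positive")
    return (alphabet_size - 1) / (2.0 * math.log(2) * n)


def column_information(
    residues: Iterable[str], apply_correction: bool = False
) -> float:
    """Information content of one alignment column, in bits.

    'X' and other non-canonical letters are excluded before counting.
    Returns ``log2(20) - H - e(n)`` clamped to >= 0.

    Raises
    ------
    DegenerateColumnError
        If no canonical residues remain after exclusion.
    """
    counts = Counter(r for r in residues if r in AMINO_ACIDS)
    n = sum(counts.values())
    if n == 0:
        raise DegenerateColumnError("column holds no canonical residues")
    freqs = np.array(list(counts.values()), dtype=float) / n
    entropy = float(-(freqs * np.log2(freqs)).sum())
    info = MAX_BITS - entropy
    if apply_correction:
        info -= small_sample_correction(n)
    return max(info, 0.0)


@dataclass
class ScoringMatrix:
    """25-column x 20-residue table of information-weighted frequencies.

    Values are non-negative and each column sums to that column's
    information content (at most log2(20) ~ 4.3219 bits).  Residues outside
    the canonical alphabet are looked up as 0 by scorers.
    """

    values: pd.DataFrame  # index: residues, columns: WINDOW_COLUMNS
    n_sequences: int = 0
    correction_applied: bool = False

    def __post_init__(self) -> None:
        df = self.values
        if tuple(df.columns) != WINDOW_COLUMNS:
            raise ValueError("matrix columns must be -5..-1, 1..20 in order")
        if sorted(df.index) != sorted(AMINO_ACIDS):
            raise ValueError("matrix rows must be the 20 canonical residues")
        if (df.to_numpy() < 0).any():
            raise ValueError("matrix values must be non-negative")
        # canonical row order for stable serialization
        self.values = df.loc[list(AMINO_ACIDS)]

    def score(self, column: int, residue: str) -> float:
        """Cell lookup; non-canonical residues score 0."""
        if residue not in AMINO_ACIDS:
            return 0.0
        return float(self.values.at[residue, column])

    def column_information(self, column: int) -> float:
        return float(self.values[column].sum())

    def column_frequencies(self, column: int) -> pd.Series:
        """Per-residue frequencies of one column (uniform if zero-info)."""
        col = self.values[column]
        total = col.sum()
        if total == 0:
            return pd.Series(1.0 / len(AMINO_ACIDS), index=col.index)
        return col / total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoringMatrix):
            return NotImplemented
        return bool(
            np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=1e-9)
        )


def build_matrix(
    windows: Sequence[CleavageWindow], apply_correction: bool = False
) -> ScoringMatrix:
    """Build the scoring matrix from an alignment of cleavage windows.

    For each window column ``j``: ``M(j, a) = f(j, a) * R(j)``, frequencies
    taken over the canonical residues observed in that column.

    Raises
    ------
    ValueError
        If ``windows`` is empty.
    DegenerateColumnError
        If some column consists entirely of unknown residues.
    """
    if not windows:
        raise ValueError("cannot build a matrix from an empty training set")
    data = np.zeros((len(AMINO_ACIDS), WINDOW_LENGTH))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for ci, col in enumerate(WINDOW_COLUMNS):
        letters = [w.residues[ci] for w in windows]
        try:
            info = column_information(letters, apply_correction)
        except DegenerateColumnError:
            raise DegenerateColumnError(
                f"column {col:+d} holds no canonical residues"
            ) from None
        counts = Counter(r for r in letters if r in AMINO_ACIDS)
        n = sum(counts.values())
        for residue, c in counts.items():
            data[aa_index[residue], ci] = (c / n) * info
    df = pd.DataFrame(data, index=list(AMINO_ACIDS), columns=list(WINDOW_COLUMNS))
    return ScoringMatrix(df, n_sequences=len(windows), correction_applied=apply_correction)


def matrix_from_probabilities(probabilities: pd.DataFrame) -> ScoringMatrix:
    """Exact matrix implied by a known per-column probability table.

    The infinite-sample limit of :func:`build_matrix`: frequencies are the
    given probabilities and the information content is computed from them
    analytically.  Used for the packaged stand-in matrix built from the
    synthetic ground-truth motif model.
    """
    probs = probabilities.loc[list(AMINO_ACIDS), list(WINDOW_COLUMNS)]
    data = np.zeros_like(probs.to_numpy(), dtype=float)
    for ci, col in enumerate(WINDOW_COLUMNS):
        p = probs[col].to_numpy(dtype=float)
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"column {col:+d} probabilities do not sum to 1")
        nz = p > 0
        entropy = float(-(p[nz] * np.log2(p[nz])).sum())
        data[:, ci] = p * max(MAX_BITS - entropy, 0.0)
    df = pd.DataFrame(data, index=list(AMINO_ACIDS), columns=list(WINDOW_COLUMNS))
    return ScoringMatrix(df, n_sequences=0, correction_applied=False)


_HEADER = ["residue"] + [str(c) for c in WINDOW_COLUMNS]


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: header 'residue', -5..-1, 1..20; 20 rows."""
    lines = ["\t".join(_HEADER)]
    for residue in AMINO_ACIDS:
        vals = ["%.10g" % matrix.values.at[residue, c] for c in WINDOW_COLUMNS]
        lines.append("\t".join([residue] + vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> ScoringMatrix:
    """Read a scoring matrix written by :func:`write_matrix`.

    Raises :class:`MatrixFormatError` on wrong dimensions, duplicate or
    unknown residue rows, or negative values, naming the offending
    row/column.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise MatrixFormatError("empty matrix file")
    header = lines[0].split("\t")
    if header != _HEADER:
        raise MatrixFormatError(
            f"bad header: expected 25 columns -5..-1,1..20, got {header[1:]}"
        )
    rows: dict[str, list[float]] = {}
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != WINDOW_LENGTH + 1:
            raise MatrixFormatError(
                f"line {i}: expected {WINDOW_LENGTH + 1} fields, got {len(fields)}"
            )
        residue = fields[0]
        if residue not in AMINO_ACIDS:
            raise MatrixFormatError(f"line {i}: unknown residue row '{residue}'")
        if residue in rows:
            raise MatrixFormatError(f"line {i}: duplicate residue row '{residue}'")
        vals = []
        for col, f in zip(WINDOW_COLUMNS, fields[1:]):
            try:
                v = float(f)
            except ValueError:
                raise MatrixFormatError(
                    f"line {i}, column {col:+d}: non-numeric value '{f}'"
                ) from None
            if v < 0:
                raise MatrixFormatError(
                    f"line {i}, column {col:+d}: negative value {f}"
                )
            vals.append(v)
        rows[residue] = vals
    if len(rows) != len(AMINO_ACIDS):
        missing = sorted(set(AMINO_ACIDS) - set(rows))
        raise MatrixFormatError(f"missing residue rows: {''.join(missing)}")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(WINDOW_COLUMNS))
    return ScoringMatrix(df)


def read_training_windows(path: str | Path) -> list[CleavageWindow]:
    """Read a training alignment of 25-mer windows.

    Accepts FASTA (records are the windows) or TSV with columns id, window.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    text = "\n".join(lines)
    windows: list[CleavageWindow] = []
    if text.startswith(">"):
        from Bio import SeqIO
        from io import StringIO

        for rec in SeqIO.parse(StringIO(text), "fasta"):
            windows.append(CleavageWindow(str(rec.seq).upper(), rec.id))
    else:
        if lines and lines[0].split("\t")[0] == "id":
            lines = lines[1:]
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 2:
                raise MatrixFormatError(f"training TSV needs columns id, window: {ln!r}")
            windows.append(CleavageWindow(fields[1].upper(), fields[0]))
    return windows


def logo_export(matrix: ScoringMatrix) -> pd.DataFrame:
    """Per-column frequencies and information for external logo tools."""
    records = []
    for col in WINDOW_COLUMNS:
        freqs = matrix.column_frequencies(col)
        row: dict[str, object] = {"column": col, "information": matrix.column_information(col)}
        row.update({a: float(freqs[a]) for a in AMINO_ACIDS})
        records.append(row)
    return pd.DataFrame.from_records(records)
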