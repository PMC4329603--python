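"""Parsers for external signal-peptide predictor output.

The predictor itself (SignalP) is never run here; the package consumes its
text output.  Two dialects are supported: the SignalP 3.0 NN "short" format
and a minimal generic TSV (id, positive, mature_start) into which output of
any predictor version can be converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SignalPParseError(ValueError):
    """Malformed predictor output; message carries the line number."""


@dataclass(frozen=True)
class SignalPResult:
    """One signal-peptide call.

    ``mature_start`` is the 1-based index of the first mature-protein
    residue (the +1 position); present iff the call is positive, and at
    least 2 because a signal peptide has at least one residue.
    """

    id: str
    positive: bool
    mature_start: int | None = None
    raw_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive:
            if self.mature_start is None:
                raise ValueError(f"{self.id}: positive record needs mature_start")
            if self.mature_start < 2:
                raise ValueError(
                    f"{self.id}: mature_start must be >= 2 "
                    "(a signal peptide has at least one residue)"
                )
        elif self.mature_start is not None:
            raise ValueError(f"{self.id}: negative record cannot carry mature_start")


# SignalP 3.0 NN short format columns after the sequence name
_SHORT3_COLS = (
    "Cmax", "Cpos", "Cflag",
    "Ymax", "Ypos", "Yflag",
    "Smax", "Spos", "Sflag",
    "Smean", "Smeanflag",
    "D", "Dflag",
)


def parse_signalp3_short(lines: Iterable[str]) -> list[SignalPResult]:
    """Parse SignalP 3.0 NN short-format output.

    A record is positive iff its D-score flag is 'Y' (the network's
    composite decision score); the cleavage site is taken from the Ymax
    position, which SignalP reports as the first mature residue.
    """
    results: list[SignalPResult] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 14:
            raise SignalPParseError(
                f"line {lineno}: expected 14 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        name = fields[0]
        vals = dict(zip(_SHORT3_COLS, fields[1:]))
        try:
            raw_scores = {
                k: float(vals[k]) for k in ("Cmax", "Ymax", "Smax", "Smean", "D")
            }
            ypos = int(vals["Ypos"])
        except ValueError as exc:
            raise SignalPParseError(f"line {lineno}: non-numeric score ({exc})") from None
        positive = vals["Dflag"] == "Y"
        if positive and ypos < 2:
            raise SignalPParseError(
                f"line {lineno}: positive record with cleavage position {ypos} "
                "(signal peptide would be empty)"
            )
        results.append(
            SignalPResult(
                id=name,
                positive=positive,
                mature_start=ypos if positive else None,
                raw_scores=raw_scores,
            )
        )
    return results


def parse_generic_tsv(lines: Iterable[str]) -> list[SignalPResult]:
    """Parse the generic dialect: TSV with header id, positive, mature_start."""
    results: list[SignalPResult] = []
    seen_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not seen_header:
            if [f.strip() for f in fields[:3]] != ["id", "positive", "mature_start"]:
                raise SignalPParseError(
                    f"line {lineno}: expected header 'id\\tpositive\\tmature_start'"
                )
            seen_header = True
            continue
        if len(fields) < 2:
            raise SignalPParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        name, flag = fields[0], fields[1].strip()
        pos_field = fields[2].strip() if len(fields) > 2 else ""
        if flag not in ("Y", "N"):
            raise SignalPParseError(f"line {lineno}: positive flag must be Y or N, got '{flag}'")
        if flag == "Y":
            try:
                ms = int(pos_field)
            except ValueError:
                raise SignalPParseError(
                    f"line {lineno}: non-numeric mature_start '{pos_field}'"
                ) from None
            if ms < 2:
                raise SignalPParseError(
                    f"line {lineno}: mature_start {ms} implies a zero-length signal peptide"
                )
            results.append(SignalPResult(name, True, ms))
        else:
            results.append(SignalPResult(name, False))
    if not seen_header:
        raise SignalPParseError("missing header line 'id\\tpositive\\tmature_start'")
    return results


def write_generic_tsv(results: Sequence[SignalPResult], path: str | Path) -> None:
    """Write records in the generic dialect (round-trips with the parser)."""
    lines = ["id\tpositive\tmature_start"]
    for r in results:
        lines.append(
            f"{r.id}\tY\t{r.mature_start}" if r.positive else f"{r.id}\tN\t"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_predictor_file(path: str | Path, dialect: str = "auto") -> list[SignalPResult]:
    """Read a predictor-output file in either dialect.

    ``dialect``: 'short3', 'tsv', or 'auto' (sniff: a generic file starts
    with the id/positive/mature_start header).
    """
    lines = Path(path).read_text().splitlines()
    if dialect == "auto":
        data = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        dialect = "tsv" if data and data[0].startswith("id\t") else "short3"
    if dialect == "short3":
        return parse_signalp3_short(lines)
    if dialect == "tsv":
        return parse_generic_tsv(lines)
    raise ValueError(f"unknown predictor dialect '{dialect}'")


def match_to_sequences(
    results: Sequence[SignalPResult], sequence_ids: Sequence[str]
) -> dict[str, SignalPResult]:
    """Pair predictor records with FASTA identifiers.

    Matching is on the first whitespace-delimited header token,
    case-sensitive.  Predictor records without a sequence raise a warning;
    sequences without a predictor record are an error.
    """
    by_id = {r.id: r for r in results}
    wanted = [sid.split()[0] for sid in sequence_ids]
    missing = [sid for sid in wanted if sid not in by_id]
    if missing:
        raise KeyError(
            "no predictor record for sequence(s): " + ", ".join(missing)
        )
    extra = set(by_id) - set(wanted)
    if extra:
        warnings.warn(
            f"{len(extra)} predictor record(s) without a matching sequence: "
            + ", ".join(sorted(extra)[:5]),
            stacklevel=2,
        )
    return {sid: by_id[sid] for sid in wanted}
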