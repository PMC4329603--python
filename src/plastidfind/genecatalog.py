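"""Toy-scale gene-catalog optimization.

Draft gene models from whole-genome annotation pipelines are frequently
truncated, especially at the 5' end.  The optimization implemented here
maximizes the fraction of full-length proteins in a catalog:

1. each model is extended in frame: upstream to the first ATG codon and
   downstream to the first stop codon;
2. models spanning more than 10 kb are assumed incorrect and dropped;
3. a model is valid iff it starts with ATG, has no internal stop codon,
   has EST support, and ends at a stop codon;
4. per locus (same chromosome and strand, overlapping spans, single
   linkage) the longest valid model is kept; among models encoding the
   identical protein the curated ("filtered") model wins, and exact
   duplicate proteins are removed;
5. proteins from models without a chromosome assignment are rescued iff
   they are less than 95% identical to every protein already selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_MAX_NT = 10_000
DEFAULT_IDENTITY = 0.95


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome/scaffold; DNA over A,C,G,T,N, uppercase-canonicalized."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty genome sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: invalid DNA letters {sorted(bad)}")


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS gene model on a genome (1-based inclusive coordinates)."""

    id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    est_support: bool = False
    jgi_filtered: bool = False
    unterminated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        if self.cds_start > self.cds_end or self.cds_start < 1:
            raise ValueError(f"{self.id}: bad CDS coordinates")

    @property
    def span(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class ValidationFlags:
    starts_with_atg: bool
    no_internal_stop: bool
    est_support: bool
    terminal_stop: bool

    @property
    def passes(self) -> bool:
        return (
            self.starts_with_atg
            and self.no_internal_stop
            and self.est_support
            and self.terminal_stop
        )


def cds_sequence(genome: GenomeSequence, model: GeneModel) -> str:
    """Coding-strand nucleotide sequence of the model."""
    if model.cds_end > len(genome.sequence):
        raise ValueError(f"{model.id}: model extends past end of {genome.id}")
    s = genome.sequence[model.cds_start - 1 : model.cds_end]
    return str(Seq(s).reverse_complement()) if model.strand == "-" else s


def protein_sequence(genome: GenomeSequence, model: GeneModel) -> str:
    """Translate the CDS; a trailing stop codon is not part of the protein."""
    nt = cds_sequence(genome, model)
    nt = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(nt).translate())
    return prot[:-1] if prot.endswith("*") else prot


def _extend_forward(seq: str, start: int, end: int) -> tuple[int, int, bool]:
    """Frame-preserving extension on + coordinates; returns (start, end, terminated)."""
    # upstream: stop if the model already begins with ATG; otherwise scan
    # codon-by-codon until an ATG, abandoning on an in-frame stop or the
    # sequence start
    if seq[start - 1 : start + 2] != "ATG":
        pos = start - 3
        while pos >= 1:
            codon = seq[pos - 1 : pos + 2]
            if codon == "ATG":
                start = pos
                break
            if codon in STOP_CODONS:
                break
            pos -= 3
    # downstream: scan in frame to the first stop codon, which becomes the end
    n_codons = (end - start + 1) // 3
    frame_end = start + 3 * n_codons - 1  # last in-frame complete codon
    last_codon = seq[frame_end - 3 : frame_end]
    terminated = last_codon in STOP_CODONS
    if not terminated:
        pos = frame_end + 1
        while pos + 2 <= len(seq):
            codon = seq[pos - 1 : pos + 2]
            end = pos + 2
            if codon in STOP_CODONS:
                terminated = True
                break
            pos += 3
    else:
        end = frame_end
    return start, end, terminated


def extend_model(genome: GenomeSequence, model: GeneModel) -> GeneModel:
    """Extend a model in frame to the first upstream ATG and downstream stop.

    The reading frame is preserved throughout; a model that already starts
    at an ATG and ends at a stop codon is a fixed point.  If no downstream
    stop exists before the sequence end, the returned model is flagged
    ``unterminated``.
    """
    L = len(genome.sequence)
    if model.cds_end > L:
        raise ValueError(f"{model.id}: model out of genome bounds")
    if model.strand == "+":
        start, end, terminated = _extend_forward(
            genome.sequence, model.cds_start, model.cds_end
        )
    else:
        rc = str(Seq(genome.sequence).reverse_complement())
        r_start, r_end = L - model.cds_end + 1, L - model.cds_start + 1
        r_start, r_end, terminated = _extend_forward(rc, r_start, r_end)
        start, end = L - r_end + 1, L - r_start + 1
    return replace(
        model, cds_start=start, cds_end=end, unterminated=not terminated
    )


def length_filter(model: GeneModel, max_nt: int = DEFAULT_MAX_NT) -> bool:
    """Keep iff the genomic span is at most ``max_nt`` (strictly over → drop)."""
    return model.span <= max_nt


def validate_model(genome: GenomeSequence, model: GeneModel) -> ValidationFlags:
    """The four validity checks applied after extension."""
    nt = cds_sequence(genome, model)
    codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
    internal = codons[:-1] if codons else []
    return ValidationFlags(
        starts_with_atg=bool(codons) and codons[0] == "ATG",
        no_internal_stop=not any(c in STOP_CODONS for c in internal),
        est_support=model.est_support,
        terminal_stop=bool(codons) and codons[-1] in STOP_CODONS,
    )


def _overlaps(a: GeneModel, b: GeneModel) -> bool:
    return (
        a.chrom == b.chrom
        and a.strand == b.strand
        and a.cds_start <= b.cds_end
        and b.cds_start <= a.cds_end
    )


def group_loci(models: Sequence[GeneModel]) -> list[list[GeneModel]]:
    """Single-linkage clusters of same-chromosome, same-strand overlapping spans."""
    loci: list[list[GeneModel]] = []
    for m in sorted(models, key=lambda m: (m.chrom, m.strand, m.cds_start, m.cds_end)):
        if loci:
            last = loci[-1]
            if any(_overlaps(m, o) for o in last):
                last.append(m)
                continue
        loci.append([m])
    return loci


def select_per_locus(
    genome_by_id: dict[str, GenomeSequence], models: Sequence[GeneModel]
) -> list[GeneModel]:
    """Pick one representative per locus and deduplicate identical proteins.

    The longest model per locus wins; length ties encoding the same protein
    resolve to the curated (jgi_filtered) model; exact duplicate proteins
    across loci are reduced to a single representative.
    """
    representatives: list[GeneModel] = []
    for locus in group_loci(models):
        # longest first; on ties prefer the curated model, then stable id order
        winner = sorted(
            locus, key=lambda m: (-m.span, not m.jgi_filtered, m.id)
        )[0]
        representatives.append(winner)
    # global removal of exact-duplicate proteins, curated models preferred
    seen: dict[str, GeneModel] = {}
    for m in sorted(representatives, key=lambda m: (not m.jgi_filtered, m.id)):
        prot = protein_sequence(genome_by_id[m.chrom], m)
        seen.setdefault(prot, m)
    kept = set(id(m) for m in seen.values())
    return [m for m in representatives if id(m) in kept]


_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Identity = matches / alignment length under global alignment
    (match 1, mismatch 0, unit gap cost)."""
    if not a or not b:
        return 0.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def rescue_unmapped(
    unmapped_proteins: Sequence[tuple[str, str]],
    selected_proteins: Sequence[str],
    threshold: float = DEFAULT_IDENTITY,
) -> list[tuple[str, str]]:
    """Add unmapped proteins that are < threshold identical to every
    chromosome-derived protein.  An empty selected set rescues everything."""
    additions = []
    for pid, prot in unmapped_proteins:
        best = max(
            (pairwise_identity(prot, s) for s in selected_proteins), default=0.0
        )
        if best < threshold:
            additions.append((pid, prot))
    return additions


@dataclass
class CatalogResult:
    """Outcome of the full optimization."""

    proteins: list[tuple[str, str]]  # (model id, protein sequence)
    provenance: list[tuple[str, str]]  # (model id, action)
    selected_models: list[GeneModel] = field(default_factory=list)
    rescued: list[tuple[str, str]] = field(default_factory=list)


def optimize_catalog(
    genomes: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
    unmapped_proteins: Sequence[tuple[str, str]] = (),
    max_nt: int = DEFAULT_MAX_NT,
    identity_threshold: float = DEFAULT_IDENTITY,
    extend: bool = True,
) -> CatalogResult:
    """Run the full optimization pipeline on a catalog."""
    genome_by_id = {g.id: g for g in genomes}
    provenance: list[tuple[str, str]] = []
    survivors: list[GeneModel] = []
    extension_tag: dict[str, str] = {}
    for m in models:
        if m.chrom not in genome_by_id:
            raise KeyError(f"{m.id}: unknown chromosome '{m.chrom}'")
        ext = extend_model(genome_by_id[m.chrom], m) if extend else m
        extension_tag[m.id] = (
            "extended" if (ext.cds_start, ext.cds_end) != (m.cds_start, m.cds_end)
            else "kept"
        )
        if not length_filter(ext, max_nt):
            provenance.append((m.id, f"dropped:over_{max_nt}nt"))
            continue
        flags = validate_model(genome_by_id[ext.chrom], ext)
        if not flags.passes:
            failed = [
                name for name, ok in (
                    ("atg", flags.starts_with_atg),
                    ("internal_stop", flags.no_internal_stop),
                    ("est", flags.est_support),
                    ("terminal_stop", flags.terminal_stop),
                ) if not ok
            ]
            provenance.append((m.id, "dropped:invalid_" + "+".join(failed)))
            continue
        survivors.append(ext)

    representatives: list[GeneModel] = []
    for locus in group_loci(survivors):
        winner = sorted(locus, key=lambda m: (-m.span, not m.jgi_filtered, m.id))[0]
        representatives.append(winner)
        for m in locus:
            if m is not winner:
                provenance.append((m.id, "dropped:locus_selection"))
    seen: dict[str, GeneModel] = {}
    for m in sorted(representatives, key=lambda m: (not m.jgi_filtered, m.id)):
        seen.setdefault(protein_sequence(genome_by_id[m.chrom], m), m)
    kept_ids = {id(m) for m in seen.values()}
    selected = []
    for m in representatives:
        if id(m) in kept_ids:
            selected.append(m)
            provenance.append((m.id, extension_tag[m.id]))
        else:
            provenance.append((m.id, "dropped:duplicate_protein"))

    proteins = [(m.id, protein_sequence(genome_by_id[m.chrom], m)) for m in selected]
    rescued = rescue_unmapped(
        unmapped_proteins, [p for _, p in proteins], identity_threshold
    )
    rescued_ids = {pid for pid, _ in rescued}
    for pid, _ in unmapped_proteins:
        provenance.append(
            (pid, "rescued" if pid in rescued_ids else "dropped:redundant_unmapped")
        )
    return CatalogResult(
        proteins=proteins + rescued,
        provenance=provenance,
        selected_models=selected,
        rescued=rescued,
    )


# ---------------------------------------------------------------------------
# GFF3-style model I/O (CDS features with est_support/jgi_filtered attributes)

def read_models_gff3(path: str | Path) -> list[GeneModel]:
    models = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) != 9:
            raise ValueError(f"line {lineno}: GFF3 needs 9 columns, got {len(f)}")
        if f[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        models.append(
            GeneModel(
                id=attrs.get("ID", f"model{lineno}"),
                chrom=f[0],
                strand=f[6],
                cds_start=int(f[3]),
                cds_end=int(f[4]),
                est_support=attrs.get("est_support", "false").lower() == "true",
                jgi_filtered=attrs.get("jgi_filtered", "false").lower() == "true",
            )
        )
    return models


def write_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = (
            f"ID={m.id};est_support={'true' if m.est_support else 'false'};"
            f"jgi_filtered={'true' if m.jgi_filtered else 'false'}"
        )
        lines.append(
            "\t".join(
                [m.chrom, "plastidfind", "CDS", str(m.cds_start), str(m.cds_end),
                 ".", m.strand, "0", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
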