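# Methods

## Model

`plastidfind` classifies proteins of red-lineage secondary-plastid
organisms into four localization classes from two inputs: the amino-acid
sequence and an external signal-peptide call (positive/negative plus the
1-based index of the first mature residue). The method assumes that
plastid-targeted proteins carry a bipartite presequence whose
signal-peptide cleavage site is spanned by a conserved motif with a
near-invariant phenylalanine at +1, and that the downstream transit peptide
has a recognizable composition (hydroxylated-residue rich, acidic-residue
poor, net positive). It makes no attempt to model membrane topology,
mitochondrial targeting, or sub-plastid compartments.

### Scoring matrix

The matrix covers columns −5..−1 and +1..+20 (no column 0; the scissile
bond sits between −1 and +1, so "ASA|FAP" has F at +1). For a training
alignment of 25-mer windows, column `j` gets

    R(j) = log2(20) − H(j) − e(n),   e(n) = 19 / (2·ln2·n),

the sequence-logo information content with the standard small-sample
correction, and each cell is `M(j,a) = f(j,a)·R(j)` with `f` the empirical
residue frequency. Consequences used throughout: per-column cell sums equal
`R(j)`; all cells are ≥ 0 and `R(j) ≤ log2 20 ≈ 4.3219` bits.

Numerical choices:

* the correction is exposed as a flag and **off by default**, which gives
  the clean analytic identity `R = log2 20 − H` used by the tests;
  corrected values are clamped at 0;
* `X` and other non-canonical letters (B, Z, J, U, O, `*`) are excluded
  from frequency counts and score 0 at lookup; a column consisting only of
  such letters is a hard error naming the column;
* window positions falling outside the sequence contribute 0 ("zero-fill")
  and mark the window incomplete; records with incomplete windows are still
  classified but flagged `truncated`.

### Cleavage-site relocation and classes

Candidate sites at offsets −2..+2 from the predictor's site are each scored
with the **full 25-column matrix** (a reduced mode scoring only columns
{−2, −1, +1, +2, +3} is available as `--window-mode core5`; the full-window
reading is the default because the candidate windows are 25-position
windows by construction). Score ties prefer offset 0, then the smaller
|offset|, then the upstream candidate — agreement with the predictor gates
the high-confidence class, so ties must not demote records spuriously. The
transit-peptide score is the window score restricted to columns +1..+20 at
the **relocated** site; both the +1-residue check and the transit score use
the relocated site, matching the order of the decision steps.

Classification: predictor-negative → *not plastid, SignalP negative*;
relocated +1 ∉ {F, W, Y, L} → *not plastid, SignalP positive*; offset 0 and
transit score strictly > 2 → *plastid, high confidence*; otherwise
*plastid, low confidence*. The cutoff comparison is strict, so a score of
exactly 2.0 is low confidence. Stop characters (`*`) truncate the sequence
with a warning.

Tunable parameters: cutoff (default 2.0, dimensionless bits-weighted
score), +1 residue set (default FWYL), window mode (default full25).

### Evaluation

Standard definitions: sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`,
`MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn))` with the common
convention MCC := 0 on a vanishing denominator; zero denominators are
errors for sensitivity/specificity. Predicted-positive is either the
high-confidence class alone (`high_only`) or either plastid class
(`high_or_low`); both "not plastid" classes count as predicted negative.
ROC points are (1 − specificity, sensitivity).

### Gene-catalog optimization

Single-CDS gene models on a genome are (1) extended in frame — upstream
codon-by-codon to the first ATG, abandoning the upstream extension if an
in-frame stop or the sequence start intervenes, and downstream to the first
stop codon, flagging `unterminated` when none exists; (2) dropped when the
genomic span exceeds 10 000 nt (strictly over); (3) kept only if they start
with ATG, contain no internal stop, have EST support (consumed as an input
flag), and end at a stop codon; (4) grouped into loci by single-linkage
clustering of same-chromosome, same-strand overlapping spans, keeping the
longest model per locus, resolving identical-protein ties toward the
curated ("filtered") model and removing exact duplicate proteins; and
(5) supplemented by unmapped-model proteins whose best global-alignment
identity (match 1, mismatch 0, unit gap cost; identity = matches /
alignment length) against every chromosome-derived protein is below 0.95.
Design choices made where the procedure was genuinely open: loci are
defined by span overlap only (exon structure is not modeled), the 10 kb
filter uses genomic span, the upstream stop-guard prevents biologically
impossible extensions, and extension applies to all inputs by default
(flag-controlled). The full optimization is idempotent on its own output.

## Synthetic data

The generator emulates the benchmark structure the method is meant for:

* **positives** — Met + hydrophobic core (signal peptide of 14–22 residues
  total) whose last five residues, and the first twenty transit-peptide
  residues, are drawn column-wise from a ground-truth probability matrix
  shaped like the published cleavage-site logos (A-rich −3/−1, S at −2,
  F at +1 with probability 0.90, A at +2, P enriched at +3, S/T/R/K-rich
  +4..+20); the transit peptide continues to 25–45 residues with a
  hydroxylated/positive composition (S+T ≈ 0.30, D+E ≈ 0.02), then a
  background-composition mature domain of 80–200 residues;
* **secretory negatives** — same signal-peptide architecture (including an
  A-X-A style c-region, which signal peptidase imposes on plastid and
  secretory proteins alike), followed by background composition;
* **non-secretory negatives** — background sequence with a negative mock
  predictor record.

Mock predictor records carry the true cleavage site, perturbed by ±1 with a
configurable probability (default 0). A single RNG stream per invocation
makes every output deterministic in the seed.

Two deliberate design decisions keep the class labels unambiguous:

1. the +1 column of the ground-truth matrix is strongly F-dominant (0.90),
   consistent with the near-invariance of the +1 phenylalanine in real
   presequence logos;
2. in secretory negatives, **all five candidate +1 positions** of the
   sliding window (the last two c-region residues and the first three
   downstream residues) avoid F/W/Y/L. Without this, the relocation step
   can legitimately find an aromatic +1 in a "negative" sequence, making
   the label, not the prediction, wrong.

What the generator does **not** emulate: real signal-peptide score
distributions (predictor output is mocked), genuine borderline secretory
sequences with aromatic residues near the cleavage site, homology structure
within the training set, intron-containing gene models, and sequencing
noise. Passing the synthetic benchmark therefore demonstrates internal
correctness and parameter recovery, **not** real-data accuracy; in
particular the near-perfect synthetic specificity is optimistic compared
with what mixed real secretomes can yield.

The toy genome plants one ORF per optimizer rule (truncated both ends,
reverse-strand truncated, nested overlap, identical-protein pair with one
curated model, missing EST support, >10 kb span) plus two unmapped
paralogs at identities 1.0 and ≈ 0.76, and records each intended fate.

The packaged `builtin-fixture` matrix is derived analytically from the
ground-truth probability table (the infinite-sample limit of training). It
is a loudly-labeled stand-in for a matrix trained on real presequences and
must not be used for biological inference; `predict` refuses to run unless
a matrix is named explicitly.

## Problem sizes

Default study conditions: 500 training windows, 200 proteins per benchmark
class, 5 000 windows for frequency-convergence checks, 1 000 random
(sequence, matrix) instances for oracle-equivalence checks, and a ~11 kb
toy genome with 8 models. These sizes give stable statistics (binomial
standard errors ≲ 2 % on the benchmark rates) while keeping any run to
seconds.

## Known limitations

* The decision procedure consumes external signal-peptide calls; its
  accuracy is bounded by theirs, and only the SignalP 3.0 NN short dialect
  plus a generic TSV are parsed.
* The scoring matrix assumes positional independence (no dinucleotide/
  pairwise terms) and ignores presequence length.
* Gene models are single-CDS; spliced genes must be provided as joined
  CDS coordinates or via the generic TSV/protein route.
* The unmapped-model rescue is O(n·m) pairwise global alignment — fine at
  catalog-curation scale, not for all-against-all proteome comparison.
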