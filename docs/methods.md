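# Methods

`riboscope` implements the computational stages of a bacterial ribosome
profiling + Rend-seq study as a reusable, tested pipeline, together with a
generative simulator that provides ground truth for every stage. This note
records the models, the parameters that matter, the numerical choices, and
what the simulator does and does not emulate.

## Coordinate conventions

All genomic coordinates inside the package are 0-based, half-open and
strand-explicit. "Upstream" always means 5' of a feature *on its own
strand*; the 3' end of a minus-strand read is its lower genomic coordinate.
GFF3's 1-based inclusive convention is converted only at the I/O boundary
(`riboscope.io`), the single place an off-by-one can enter. Strand handling
is exercised aggressively: the simulator places ~40% of genes on the minus
strand, and mirror tests (reverse-complement the genome, flip the tracks)
assert that phasing tables, metagenes and TSS candidates are invariant.

## Read preprocessing

Raw reads carry a fixed layout: 2 nt UMI + footprint + 5 nt UMI + 5 nt
sample barcode at the 3' end. The pipeline order is fixed and asserted by a
test: (1) demultiplex by exact match of the last 5 nt (no mismatch
tolerance — exactness is reproducible), (2) deduplicate on the *full*
sequence with the UMI still attached, so PCR duplicates collapse while
identical footprints with distinct UMIs survive, (3) strip the UMI and drop
footprints shorter than 5 nt. Reads overlapping a user-supplied
contaminant (rRNA/tRNA) interval by ≥1 nt are discarded. Quantitative
stages use only unambiguously mapped reads (read ids appearing on a single
alignment line).

## Phasing and metagenes

Frame is defined from the annotated start codon — frame *f* at gene-local
position *l* means *l* mod 3 = *f* — with no P-site offset correction.
Phasing is tabulated per read length from footprint 3' ends.

Metagene profiles include only coding genes that are (a) at least 50 nt
from any other coding region *on both flanks* (either strand), preventing
neighbour bleed-through, and (b) covered by strictly more than 10 mapped
reads. Each included gene's window vector is divided by its own mean over
the plotted window before the equal-weight average; this makes per-gene
depth cancel exactly (doubling one library's coverage of a gene changes
nothing) and makes a flat track average to exactly 1.0 — a fixed point the
tests pin.

## Ribosome silhouettes

A silhouette is the vector of per-position footprint 3'-end counts over a
gene body; it captures the *shape* of ribosome coverage independent of
depth (Spearman is rank-based, so uniform scaling is a no-op, also tested).
Because shallow coverage leaves shared empty positions that fake agreement,
each pair of silhouettes is first compressed: positions with zero counts in
*both* vectors are removed, positions where exactly one is zero are kept.
Similarity is Spearman's rank correlation with average ranks (count data is
tie-heavy; the tie rule must be fixed for reproducibility). Correlations
are undefined — propagated as `None`, never coerced to 0 — when fewer than
2 positions survive compression or either compressed vector is constant.

A gene qualifies for comparison only with ≥50 mapped reads across ≥10
distinct positions in every participating replicate. Between two states
with ≥2 replicates each, the statistic is `median_within` (all within-state
replicate pairs, pooled across both states by default; a flag restricts to
the first state) versus `median_between` (all cross-state pairs). Medians
are lower-median order statistics: identical to the usual median for odd
pair counts, and exact — not interpolated — in degenerate cases such as
state B being a copy of state A, where `median_within = median_between`
must hold exactly.

A gene is called "differential silhouette" when `median_within −
median_between > margin`. The margin default is 0 (the diagonal of a
within-vs-between scatter), but 0 is a *visualisation* threshold, not a
decision rule: under the no-change null the difference is exchangeable
noise, so ~50% of unperturbed genes sit below the diagonal (a property the
tests verify). Discrimination analyses therefore use a positive margin,
0.1 by default in this package, chosen from that exchangeability argument;
at the reference operating point (~1,000 reads/gene, 2+2 replicates,
8-fold rate perturbation over half the gene body) it separates perturbed
from unperturbed genes with ≥90% precision and recall.

## Rend-seq TSS calling

Two per-position scores are computed on a strand-oriented density track
RNA(n), with a 100 nt window each side, ε = 0.001:

    peak_density(n)  = RNA(n) / ( Σ_{m=−100..100} RNA(n+m) / 200 )
    delta_density(n) = ( Σ_{m=−100..0} RNA(n+m) + ε ) / ( Σ_{m=1..100} RNA(n+m) + ε )

Two definitional quirks are implemented exactly as written and pinned by
closed-form tests: the peak denominator divides a 201-term sum by 200 (a
uniform track scores 200/201, an isolated spike scores 200), and the delta
numerator includes m = 0, i.e. the peak itself. Note the tension between
this formula and its verbal description as an upstream-over-downstream
"increase": at a genuine 5' end the upstream window is empty and delta is
*small* (≈ E/100 for enrichment E on an otherwise clean track). This
package follows the formula and treats low delta as TSS-like; the default
threshold is `delta ≤ 0.5` together with `peak ≥ 10`, both exposed as
configuration.

Candidate positions must first pass a prefilter — ≥5 reads at n and mean
density ≥0.1 over the 201 nt window; positions whose window is truncated
by a contig edge are excluded. Runs of passing positions closer than 5 nt
collapse to the maximal-peak position (ties to the 5'-most), replacing the
original workflow's manual curation with a deterministic rule. Each
candidate is assigned to the nearest downstream start codon on its strand
within 500 nt; the distance is the 5' leader length. Leaders classify as
leaderless (<5 nt), leadered (≥15 nt) or anomalous (5–14 nt, the range
observed to be empty in the data this package models).

Which density feeds which score is configurable; the default runs both on
Rend-seq 5'-end counts, and `call_tss` accepts a separate `delta_track`
(e.g. RNA-seq coverage) when end-counts are too sparse for a stable
denominator.

## Pseudogene recoding

Every annotated gene is scanned for three anomalies in its annotated
frame: non-ATG first codon, missing terminal stop (UAG/UAA/UGA), internal
stop. Anomalous loci are ranked by total footprints (ties stable by
coordinate). ORF boundaries are then proposed by a deterministic score
replacing manual profile review: candidate ORFs are the ancestral start
plus every in-locus ATG (near-cognate starts are out of scope), each run
to its first in-frame stop; the score is the fraction of locus footprints
inside the ORF minus 0.1 × ORF length / locus length, with ties broken
ancestral-first, then longest, then 5'-most. The length penalty (λ = 0.1)
discourages vacuous full-locus ORFs; proposals require ≥20 footprints.

Readthrough/frameshift efficiency at a two-ORF locus is the ratio of mean
per-nt 3'-end density downstream of the shift site to that upstream, with
9 nt excluded at every ORF boundary to keep initiation and termination
peaks out of both means. The estimator is this package's definition (the
original description of the quantity does not fix a window protocol); it
is unbiased under Poisson placement, with recovery tested at efficiencies
0.05–0.5 and bias <0.01 at high depth. Slippery-site scanning reports
X_XXY_YYZ heptamers (two homotrinucleotides; X may equal Y, covering
homopolymeric sites such as T_TTT_TTT), homopolymeric A/T runs ≥8 nt, and
13 nt windows containing ≥12 A/T — the transcriptional-slippage-prone
signature.

## Quantification

Reads are counted for the single same-strand gene containing the assigned
end position; reads in no gene or at positions shared by overlapping
same-strand genes are tallied as uncounted (column sum + uncounted = input
reads, asserted). Size factors are the standard median-of-ratios: the
median over genes nonzero in every library of the count over the per-gene
geometric mean. The implementation is cross-checked in a test against
pydeseq2's normalization on the same matrix. Fold changes are
log2(mean_B + c) − log2(mean_A + c) on normalized counts with pseudocount
c = 0.5 (symmetric, standard); repression in B is negative. Dispersion
shrinkage and Wald testing are deliberately not reimplemented — this
package stops at normalized fold changes, and a library-exclusion flag in
the run config supports dropping anomalous libraries from comparisons.

## The simulator

The generator emulates the observable structure the analyses consume, not
sequencing chemistry:

* **Genome**: random background with ATG…stop genes packed with
  configurable spacing, ~40% minus-strand; a designated fraction (10%)
  made pseudogene-like by injecting exactly one anomaly; one reserved
  rRNA-like interval for contaminant-filter tests.
* **Leaders**: a mixture of 60% leaderless (0–3 nt) and 40% Normal(40, 8)
  truncated at ≥15 nt; lengths 4–14 nt are never emitted, reproducing the
  observed empty gap.
* **Footprints**: per-gene read counts are multinomial over genes with
  log-normal expression weights (σ = 0.5); within a gene, 3' ends step
  codon-wise with frame offsets drawn from the periodicity vector
  (default 0.8/0.1/0.1) and lengths from a distribution placing exactly
  80% of mass in 16–26 nt. Raw reads carry the UMI/barcode layout above so
  preprocessing is testable end to end.
* **Rend-seq**: uniform body coverage plus excess reads whose 5' end is
  exactly the TSS; the peak fraction is (E−1)/(L+E−1) for transcript
  length L, so the expected TSS-to-mean-body end-count ratio equals the
  enrichment parameter E exactly (default 30).
* **Perturbations**: condition-B fold changes per gene; silhouette
  perturbations multiply per-codon rates over the downstream half of
  designated genes by 8; frameshift loci attenuate rates past the shift
  codon by the efficiency.

Placement noise is Poisson/multinomial per position — the simplest model
consistent with count data, which keeps recovery tolerances computable.
Every read is attributed to its generating gene in an audit log whose
totals equal the library depth exactly, and identical configurations
produce byte-identical outputs.

**What the simulator does not emulate** — and hence what passing recovery
tests do not establish about real data: sequencing errors and quality
scores; alignment ambiguity beyond duplicated read ids; ribosomal pausing
structure beyond the frame preference; operonic co-transcription (each
gene gets its own transcript, so TSS recovery is measured under the
single-gene-per-transcript regime); UTR structure beyond a fixed 15 nt 3'
tail; and broad expression dynamic range. Defaults describe moderately
expressed, well-separated genes (intergenic spacing ≥150 nt, log-normal
σ = 0.5): the TSS caller's printed prefilter needs ≥5 reads at the peak
and the delta window needs 100 nt of clean upstream sequence, so genes
below that coverage or inside dense operons are not recoverable by
construction — on real data, recovery for weakly expressed or
operon-internal genes will be correspondingly lower.

## Reference operating points

The recovery analyses in `scripts/acceptance.py` and the acceptance tests
run at desk scale, sized to finish in seconds while leaving standard
errors well inside their tolerance bands: frameshift loci at 10⁴ reads
(estimate sd ≈ 0.4 pp at 18% efficiency), Rend-seq enrichment and TSS
recovery at 100 genes × 10⁵ reads, fold-change recovery at 10⁴ expected
focal counts (fold sd ≈ 4%), read-length calibration at 10⁵ reads, and
formula oracles on 1,000 random tracks at 10⁻⁹ relative error. The
Spearman implementation is checked against an explicit average-rank oracle
exhaustively for all integer vector pairs through length 4 (entries 0–3)
plus a dense seeded sample at length 5.

## Known limitations

* TSS calling reports no statistical confidence; thresholds are empirical
  and exposed, not derived from a noise model.
* The delta score's upstream window makes closely spaced same-strand
  genes (<~135 nt usable upstream) intrinsically hard; candidates there
  fail `max_delta` even at high coverage.
* Silhouette comparison requires ≥2 replicates per state and abstains
  (rather than guessing) on ineligible genes; the flag margin trades
  recall against the ~50% null rate at margin 0 and must be chosen for
  the replicate structure at hand.
* `propose_orf` considers ATG starts only, and the efficiency estimator
  assumes a single dominant shift site per locus.
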