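# Methods

## The design and its statistical problem

The pipeline targets tag-count expression profiling of the litchi
fruit-abscission-zone time course: seven libraries (CK0–CK3 untreated,
ETH1–ETH3 ethephon-treated, sampled 0–3 days after treatment), each a
single sequencing library built from pooled biological replicates.
Pooling leaves **no replicate-level variance estimate**, so differential
expression cannot use dispersion-estimating replicate models (DESeq2,
edgeR); instead each gene is tested between two libraries with the
Audic–Claverie exact conditional statistic, and the biological-noise
burden is shifted onto two design features: a stringent dual calling
gate and subtraction of control drift.

## The exact test

Conditional on observing count *x* in a library of size *N₁*, the count
*Y* in a library of size *N₂* under the null of equal relative abundance
(flat prior over abundance) follows

p(y|x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ).

This is algebraically a negative binomial with *x*+1 successes and
success probability *N₁/(N₁+N₂)* (write the pmf as C(x+y, y)·q^y·p^(x+1)
with p = N₁/(N₁+N₂)); the implementation therefore evaluates tails
through `scipy.stats.nbinom`'s log-space cdf/sf, which is stable for
counts up to 10⁶ and beyond. The two-sided p-value is
min(1, 2·min(P(Y≤y|x), P(Y≥y|x))) — doubled because a single test must
call both up- and down-regulation.

Two numerical/behavioural notes:

* **Role asymmetry.** The tail construction is *not* symmetric under
  exchanging the two libraries (the conditional tail sets differ), even
  though the conditional pmf is exchange-symmetric at equal library
  sizes. The tests assert the pmf symmetry and the rank-consistency of
  p-values under exchange, which are the properties that actually hold.
* **x = y = 0.** The two-sided p is 1 at equal library sizes but
  2·N₁/(N₁+N₂) in general; with the ~±15% library-size spread of this
  design that is ≥ 0.9 and never approaches significance.

**Dual gate.** A gene is a DEG iff FDR ≤ 0.001 *and* |log₂FC| ≥ 2, both
inclusive. FDR is Benjamini–Hochberg across all genes of one pair (the
design names only "FDR"; BH is the default reading, Storey's q is
available for the KEGG screen). Fold change is computed on
pseudo-counted library-size-normalized counts,
log₂(((y+1)/N₂)/((x+1)/N₁)), so on/off genes stay finite; with equal
gene length in both libraries this equals the RPKM ratio, so the choice
of scale is immaterial to the gate. The fold gate also makes calling
robust to mild count overdispersion, which inflates p-values but not
fold-change noise at high counts.

## Background subtraction and the responsive union

Untreated pedicels drift over three days, so a treatment call at day
*t* (CKt vs ETHt) is attributed to ethephon only if the gene is not a
CK0-vs-CKt DEG. Exclusion is **by gene id, not by direction**: a gene
drifting in the control is considered unreliable for treatment
attribution regardless of direction (a direction-aware mode exists
behind a flag). The three surviving sets ETHt/CKt union into the
ethephon-responsive set; a gene may carry opposite directions at
different days and both are retained in its direction vector.

## Enrichment screen and candidates

Responsive genes are screened against two flat vocabularies (GO-like,
KEGG-like) with the one-sided (over-representation) upper-tail
hypergeometric test; adjustment is BH within vocabulary (Storey's
single-λ q behind a flag, λ = 0.5), significance at adjusted ≤ 0.05 for
both. The background universe is all genes with ≥ 1 assigned read in
≥ 1 library — unexpressed genes cannot be responsive and would inflate
N. No GO-DAG ancestor propagation is done; terms are flat sets.
Candidates are responsive genes belonging to ≥ 1 significant term of
either vocabulary ("membership in significant terms" reading),
deduplicated.

## Temporal groups

From the sign profile s = (s₁, s₂, s₃) of a candidate (±1/0 per day
after subtraction), groups are assigned by a total, mutually exclusive
rule, checked exhaustively over all 26 nonzero profiles:

* **IV** (constant): s₁ ≠ 0, s₃ ≠ 0, same sign — day-2 status is
  deliberately unconstrained so a missed middle call does not demote a
  persistent gene;
* **I** (early/transient): s₁ ≠ 0 and not IV — this includes
  sign-reversing profiles (s₁ and s₃ nonzero with opposite signs),
  which the "transient change" reading covers;
* **II** (middle): s₁ = 0, s₂ ≠ 0;
* **III** (late): s₁ = s₂ = 0, s₃ ≠ 0.

The published 13 sub-clusters of the litchi study have no printed
membership rule, so exact reconstruction is not claimed. The default
sub-clustering partitions each group by exact sign pattern
(deterministic, labels lexicographic within group: 1A, 1B, …); a
fidelity mode runs average-linkage hierarchical clustering (Euclidean,
`scipy.cluster.hierarchy`) on the log₂FC profiles cut to a requested
cluster count, with cluster labels ordered by first appearance — both
modes are deterministic given inputs.

All summary percentages are 100·part/total rounded **half-up** to two
decimals (matching how the published tables print), computed in exact
decimal arithmetic.

## qPCR validation

2^−ΔΔCt with two reference genes: ΔCt = mean replicate target Ct minus
the arithmetic mean of the two per-reference mean Cts (equivalent to
the geometric mean of their linear expressions — the combination rule
is a package choice, as assay write-ups rarely state one), calibrated
to the 0 d sample, so RE(0 d) = 1 exactly. Concordance against the tag
data is, by default, agreement of the day-1 direction of change
(threshold 1.5-fold, below which a change counts as "no change") with
the ETH1-vs-CK0 RPKM ratio (floored at 10⁻⁶ RPKM to keep ratios
finite); a whole-profile Spearman mode is available. Efficiency
correction and primer-level modelling are out of scope — the
efficiency-free ΔΔCt form is used.

## The synthetic-data generator

The generator is a first-class module: it defines the conditions under
which the pipeline's statistical claims are made.

* **Counts**: negative binomial with mean μ and variance μ + d·μ²
  (gamma–Poisson mixture), one shared dispersion knob d; d = 0 is
  Poisson. Pooled unreplicated libraries leave dispersion
  unidentifiable, so a single knob is deliberate. The default d = 0.02
  adds mild technical-style overdispersion; the pooled design gives no
  basis for a larger biological value, and the dual gate makes calls
  robust to this level (the null false-call rate stays ≈ 0).
* **Baselines**: per-gene relative abundance log-uniform over three
  orders of magnitude (1–1000), normalized to a target depth of 10⁶
  assigned reads per library — so the panel always contains low-count
  genes that stress the exact test and high-count genes that stress the
  fold gate.
* **Planted effects**: pattern labels over {+, −, 0}³ give the sign of
  the ethephon effect per day; effect magnitude is a single log₂ value,
  default 3.0 (8-fold). The pipeline's gate is 4-fold; planting
  *exactly* at a threshold makes the fold gate a coin flip by symmetry
  of the sampling noise, so the default sits comfortably above the gate
  and recovery rates measure test power rather than boundary behaviour.
  The default planted fractions (16% of genes) cover all four temporal
  groups.
* **Control drift**: optionally, a configured gene fraction carries a
  persistent ±8-fold "time effect" in CK1–CK3 *and* ETH1–ETH3 (so it
  cancels in the treatment comparison and is visible only to CK0-vs-CKt)
  — this exercises the background-subtraction stage with non-empty
  control DEG sets. Default fraction 0.
* **Annotations**: term sizes uniform in a range; enriched terms draw
  each member from the planted (non-null) genes with probability equal
  to the enrichment strength (default 0.9), others uniformly.
* **Ct tables**: targets preferentially planted day-1 responders
  (mirroring validation panels focused on the early response), baseline
  Ct uniform in 22–30 cycles, planted log₂ effects subtracted
  cycle-for-cycle, Gaussian noise (default sd 0.2 cycles, 3
  replicates); references EF-1α/GAPDH-style constant in expectation.
* **Seeding**: one master seed; independent `numpy` SeedSequence
  streams per section and per library. Identical seeds give
  byte-identical outputs.

What the generator does **not** emulate: gene-correlated effects,
library-specific GC/length biases, multi-mapping ambiguity, annotation
incompleteness, or realistic biological co-regulation — so passing
recovery tests demonstrate correctness and calibration of the chain
under its stated sampling model, not performance on real tissue
libraries.

## Problem sizes used in the checks

Simulation-based checks run at 1000–2000 genes × 7 libraries at depth
10⁶ over 100 seeds (a few seconds per batch): large enough that the
planted structure dominates sampling noise at the chosen effect sizes,
small enough to iterate on freely. The brute-force oracle for the exact
test covers the full grid x, y ∈ [0, 200] at all nine pairings of
library sizes {10⁴, 10⁶, 10⁷}; agreement is ~10⁻¹³, far inside the
10⁻¹⁰ tolerance asserted.

## Known limitations

* The exact test assumes Poisson sampling around fixed relative
  abundances; with real biological replicate variance it is
  anti-conservative, and only the fold gate and background subtraction
  temper that. This mirrors the design being reimplemented rather than
  fixing it.
* The published genome-scale gene lists (6167 responsive, 2730
  candidates) cannot be recomputed — no raw reads or genome were
  deposited — so the published integers are used only to verify the
  bookkeeping and summary arithmetic.
* "Q-value" for the pathway screen defaults to BH; Storey's q (single
  λ) is provided but no pi0 smoothing is attempted.
* Hierarchical sub-clustering at small group sizes depends on linkage
  ties; determinism is guaranteed, equivalence to any published
  clustering is not claimed.
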