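# Methods

This note documents the models, parameter choices and numerical
behaviour of each pipeline stage, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Positional biotype classification

Geometry is evaluated on gene bodies (union of transcripts) in 0-based
half-open coordinates; exon structure never affects the label. For each
lncRNA a single partner coding gene is selected: maximal body overlap
first, then minimal body distance within the genic window, ties broken
by lexicographically smallest gene id. The rule table:

* opposite strands, lncRNA inside the coding body → **XI**; coding body
  inside the lncRNA → **XO**;
* opposite strands, partial overlap → **XH** if both 5′ ends lie in the
  overlap, **XT** if both 3′ ends do. For interval gene bodies on
  opposite strands these are the only possibilities (a mixed-end overlap
  implies containment); a flagged `ambiguous_ends` fallback exists for
  defensive completeness but is unreachable on valid input;
* opposite strands, no overlap, distance ≤ window → **XH** when the
  facing ends are the 5′ ends (divergent), **XT** when they are the 3′
  ends (convergent). The six-label nomenclature describes orientation,
  not overlap, so near-divergent and near-convergent pairs without
  overlap carry the same labels;
* same strand, no overlap, distance ≤ window → **SD** downstream of the
  coding 3′ end, **SU** upstream of its 5′ end;
* no coding gene within the window and no overlap → **IG**.

Same-strand *overlap* is outside the seven-label scheme and is reported
as an explicit `unclassified_sense_overlap` outcome, never silently
binned as IG.

Parameters: `genic_window` = 5000 bp. The "< 5 kb" convention is
ambiguous exactly at the boundary; distance ≤ 5000 counts as genic here
(inclusive reading, documented so the boundary case is predictable).
Distances are body-to-body, the conservative reading when no anchor
(TSS vs body) is specified.

## Expression preparation

RPKM matrices are filtered at ≥ 1 RPKM in ≥ 1 timepoint (both
configurable; no persistence requirement by default since none is
standard). "Associated genes" are the partner coding genes of genic
lncRNAs and the intergenic lncRNAs themselves; per-biotype expressed
fractions are computed over partner coding genes only, so IG reports
NA. Standardization is time-based: log₂(x+1), then per-gene z-scoring
with the population (n) denominator — the convention of the fuzzy
clustering literature — with constant rows mapped to zero vectors and a
logged warning. The log transform is a config switch; it changes
correlations only mildly for well-expressed genes but stabilizes the
heavy RPKM tail.

## Fuzzy c-means stage clustering

The textbook alternating updates are used: membership
µ_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)} with Euclidean d, centroid update
weighted by µ^m, iterated until the maximal centroid shift is below
`tol` = 1e-6 (max 1000 iterations). A gene coincident with centroids
splits membership equally among them. Defaults m = 1.25 and
min.acore = 0.5 are the study's stated settings. Initialization is
k-means++ from the config seed; because FCM converges to local optima,
`n_init` = 5 restarts (seeds derived from the config seed) are run and
the lowest-objective solution kept — this keeps the result
deterministic while removing the dominant failure mode (two centroids
landing in one tight cluster). Membership rows sum to 1 at every
iteration (tracked in `rowsum_dev`) and the objective history is
non-increasing.

The number of clusters c is a free parameter (the source analysis never
states its value); the default is 9, which for the synthetic bundle is
the number of planted profile groups plus slack for the background.

Stage assignment: per cluster, the mean membership of each stage's
markers; the best stage wins if its mean reaches min.acore, ties and
sub-threshold maxima leave the cluster unassigned. Legacy marker
symbols are normalized at load (POU5F/OCT4 → POU5F1, TDGF → TDGF1,
CTIP2 → BCL11B). A gene counts toward at most one stage — that of its
argmax cluster, if stage-assigned and the membership reaches min.acore —
grouped by association biotype.

## Co-expression modules

Unsigned adjacency a_ij = |r_ij|^β on the standardized matrix (signed
variant available). The default β = 10 follows the convention of using
higher soft powers for unsigned networks built from few samples; with
only 8 timepoints, sample correlations are inflated and β = 6 leaves
too much background adjacency. `select_soft_power` implements the
scale-free-fit criterion (smallest power with R² ≥ 0.8 on the log-log
degree fit, fallback to the best power with a warning) for data-driven
choice; it needs ≥ 20 genes to be meaningful.

TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit
diagonal, computed with the diagonal zeroed inside the formula. Modules
are average-linkage clusters of 1 − TOM under a static cut; clusters
below `min_module_size` = 10 become label 0, and modules are renumbered
by decreasing size so labelling is order-invariant.

Static-cut caveat: a cut at 0.99 keeps clusters separate only when
between-cluster TOM stays below 0.01. Low-connectivity genes violate
this easily — the denominator min(k_i,k_j)+1 is small for them, so a
noise gene with chance correlation to a module inflates its TOM toward
that module and can chain two distinct modules together under average
linkage. The function default stays at 0.99, but the pipeline's bundle
analysis cuts at 0.97, which separates planted modules (between-TOM
≲ 0.005 at β = 10) while still merging within-module dissimilarities
(≈ 0.05). Module counts per biotype are evaluated on biotype-stratified
runs: only a biotype's associated genes enter its network, and a module
counts for the biotype when ≥ `min_module_size` of its genes are of that
biotype.

## Mutual-information networks

MI is the plug-in histogram estimator over equal-frequency (rank) bins,
in bits; `bins="auto"` uses B = ⌊√n⌋. The estimator is exactly
symmetric, and MI(x,x) = log₂B when B divides n (the binned variable is
uniform by construction). Constant vectors give MI 0 with a warning.

Plug-in bias matters: for independent variables the expected MI is
≈ (B−1)²/(2n ln 2) bits, so √n binning at n = 300–1000 inflates *all*
MI values by 0.3–0.65 bits. This shared offset compresses the *ratios*
the DPI test depends on. The pipeline therefore fixes B = 10 for its
network analyses (bias ≈ 0.02–0.2 bits at the bundle's n = 300), and
bound-style checks on independent pairs use small B for the same
reason. The library-level function defaults (auto binning, alpha = 0.05,
200 permutations) are kept for general use.

Edge threshold: the (1−alpha) quantile of a pooled permutation null
(one random pair per draw, one member shuffled). Per-pair nulls would
cost n_perm per pair for no benefit at these sizes. `alpha ≥ 1` is the
degenerate keep-everything cutoff (threshold 0). The pipeline uses
alpha = 0.001 with 4000 permutations because the multiedge-partner
statistic is sensitive to single false edges (one false edge can raise
the count by 2).

DPI pruning: for every triangle, the strictly weakest edge is marked
for removal when its MI is below (1 − tolerance)·(second-smallest MI),
tolerance 0.15; equal-MI triangles are tie-protected. All marks are
computed on the input graph and applied at once, and an edge that is
the maximal-MI edge of any triangle is protected outright, so triangle
maxima always survive. This is deliberately more conservative than
flag-then-remove DPI, where a triangle's maximum can be deleted through
a different triangle; the conservative variant makes the pruning
monotone with respect to triangle maxima at the cost of occasionally
keeping an indirect edge that two strong triangles disagree about.

Hubs are ranked by degree, ties by summed edge MI, then gene id. The
"multiedge partner" count of a gene set is its number of members with
degree ≥ 2 — one documented reading of a statistic whose original
operational definition is not public; the network-change table reports
this count per biotype in both stage networks and their signed
difference.

## Coding potential

The Fickett TESTCODE statistic uses the eight published parameters: for
each base, the codon-position asymmetry max(c₀,c₁,c₂)/(min+1) and the
base fraction, each mapped through the lookup tables transcribed from
the original publication (Fickett, 1982) and combined with the
published weights. Ns are excluded before counting; the score is case-
and N-position-invariant and strand-specific. Sequences must be ≥ 200 nt
with ≤ 10% non-ACGTN characters.

ORF coverage scans the three forward frames for ATG…{TAA,TAG,TGA}
spans (stop included; first ATG after the previous stop opens the
reading). Unterminated ORFs are not counted by default (`open_ended`
flag available), nor are reverse-strand frames (`scan_reverse`), since
transcripts are stranded. Verdicts: coding iff Fickett ≥ 0.74 (the
classic TESTCODE coding bound) *and* coverage ≥ 0.5; noncoding iff both
are below; otherwise indeterminate. Both cutoffs are configurable since
no reference values are printed for this combination.

## Synthetic data: what it emulates, and what it does not

`simulate_bundle` fabricates the full study input set with planted
truth:

* **Annotation** — one synthetic chromosome, 252 lncRNA/coding pairs
  placed left-to-right with 10.5-kb spacers (no cross-pair proximity),
  realizing all seven biotypes over a range of overlaps and gaps in
  both orientations; the first XH pair realizes the 599-bp 5′-overlap
  divergent geometry of the pipeline's candidate-gene readout. For XI
  the lncRNA length equals the requested overlap (containment), for XO
  the coding length does.
* **Expression** — RPKM = 2^(profile + N(0, sd)) over 8 timepoints
  (log-normal: positive and heavy-tailed like RPKM). Planted groups:
  three marker-anchored stage clusters (pluripotency high at D0,
  commitment peaking at D7, later rising to D77) and per-biotype module
  groups whose profiles were chosen with pairwise |r| ≤ ~0.5 within
  each stratum so planted modules are separable; planted noise
  sd = 0.15 (log₂ scale), background flat rows at ~2 RPKM with sd 0.4,
  silenced genes at ~0.25 RPKM. Genic lncRNAs mirror their partner's
  profile with extra noise (sd 0.35) — divergent pairs co-express — but
  carry no association biotype, so they are never double-counted.
  Per-gene variance of real data is unknown; these noise levels are
  free parameters chosen once as plausible, not calibrated.
* **Networks** — separate replicate-rich matrices (n = 300 samples,
  dependency strength 0.95) rather than the 8 timepoints, because MI
  estimation needs replicates. Planted multiedge structure uses
  disjoint 3-gene Markov chains (each contributes exactly one
  degree-2 middle after DPI): XH 3→7 chains, IG 7→2, XI 6→2 across the
  two stages, giving the increase-for-XH / decrease-for-IG-and-XI
  pattern; the hub fixture is a 13-gene star on commitment XH genes.
  The strength 0.95 keeps the DPI ratio resolvable under estimator
  bias. Exact post-inference counts can deviate from the planted
  values by occasional retained skip-edges or false positives; the
  direction of change and the hub identity are the stable readouts.
* **Sequences** — coding transcripts carry an ATG…stop ORF spanning
  80% of 1200 nt with codons drawn from a fixed biased usage table
  (Fickett's statistic needs compositional asymmetry); noncoding
  transcripts are uniform random.

Not emulated: read-level data (FASTQ), splicing isoforms beyond one
transcript per gene, replicate structure within timepoints, batch
effects, GO term semantics (the target set is a plain gene-id list),
and the original study's data volumes. Passing tests therefore
demonstrate correctness of the algorithms and recoverability of planted
structure at desk scale — not that the original dataset would yield the
same numbers.

## Determinism and problem sizes

Every stochastic step takes a seed and derives sub-seeds additively;
identical config + seed gives byte-identical reports (no timestamps are
written). The default test and acceptance workloads use the bundle
(516-gene matrix, 21-gene network pools, 50 transcripts), 20-replicate
recovery checks for clustering/stage/network statistics, and a
~500-case geometry grid — sizes chosen so the full suite runs in well
under a minute while every planted structure is overdetermined.

## Known limitations

* The static tree cut makes module detection sensitive to
  low-connectivity bridge genes (see above); dynamic tree cutting is
  not implemented.
* The pooled permutation null assumes exchangeability across gene
  pairs; a per-pair null mode would be needed for strongly heteroskedastic
  data.
* The conservative DPI variant can retain an indirect edge that
  classic ARACNe would remove when triangles overlap.
* Enrichment uses a one-sided hypergeometric test without
  multiple-testing correction by default (raw percentages are the
  primary readout); BH correction is left to the caller.
* Multi-transcript genes collapse to the gene-body union; isoform-level
  biotypes are out of scope.
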