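# Methods

This note documents the models, conventions and numerical choices behind
`triomethyl`, in the order the pipeline applies them.

## Beta values and probe filtering

The methylated fraction at a CpG is `beta = M / (M + U + 100)` with `M`
and `U` the methylated/unmethylated fluorescence intensities.  The
offset 100 in the denominator is the standard Illumina convention: it
shrinks betas of low-intensity probes toward 0 and bounds the value
strictly below 1.  (The formula is sometimes printed without parentheses
as `M/M+U+100`; the literal reading is dimensionally meaningless and the
offset form is the only sensible interpretation.)

Standard filters remove probes with an `rs` identifier (SNP control
probes), probes on the X/Y chromosomes (sex confounds a mixed-sex
cohort), and unreliable measurements.  Reliability filtering is a
simplified greedy procedure over the detection-p matrix: iteratively
remove the probe or sample with the highest fraction of detection
p-values above 0.05 until every row and column has at most 5% unreliable
entries, with ties broken probe-before-sample, then lexicographically.
Full-featured array QC (as in dedicated preprocessing suites) uses a
statistic-guided variant of this idea; the greedy rule here keeps the
same behaviour on the clear-cut cases (a failed sample, a dead probe) and
is exactly reproducible.  Thresholds (`p_threshold = 0.05`,
`stop_fraction = 0.05`) are package defaults; both are exposed.

Out of scope by design: `.idat` parsing, background correction, SWAN or
any other normalization, batch-effect handling, bisulphite-conversion QC.
The pipeline starts from a beta matrix.

## Methylation states and the trio rule

States use the stringent two-sided cutoffs hypo = [0, 0.2] and
hyper = [0.8, 1.0], implemented as **closed** intervals (`beta <= 0.2`,
`beta >= 0.8`).  Closedness matters only on the exact boundary and makes
the minimal-score triples (0.8, 0.8, 0.2) / (0.2, 0.2, 0.8)
representable; both cutoffs are configurable.

A CpG qualifies for a trio when the affected child and affected parent
share one extreme state and the unaffected parent holds the opposite one.
A triple with a missing beta in any member cannot be evaluated and is
skipped for that trio; the count of skipped probes is recorded on the
result.

## TbSSch scoring

Qualifying triples are scored by their total distance from the 0.5
midline, normalized by 1.5:

    affected-hyper:  [(C - 0.5) + (PA - 0.5) + (0.5 - PU)] / 1.5
    affected-hypo:   [(0.5 - C) + (0.5 - PA) + (PU - 0.5)] / 1.5

Under the 0.2/0.8 cutoffs each term is at least 0.3, so the score lies in
[0.6, 1.0]; the two directions are mirror images
(`score_hypo(C, PA, PU) = score_hyper(1-C, 1-PA, 1-PU)`).  Numerically
the score is evaluated on a decimal-scaled axis (all operands multiplied
by 10) so betas given to two decimals — in particular the boundary
triples — score exactly; the scaled form agrees with the literal formula
to machine epsilon everywhere.

## Gene aggregation, scopes, family pool

Every probe–gene annotation link contributes the probe's score to that
gene (a multi-gene probe supports each of its genes, the 450K manifest
convention); a gene's score is the **maximum** over its supporting CpGs.
The promoter scope keeps only links whose region group is TSS200 or
TSS1500 (the two promoter blocks, 200 bp and 1500 bp upstream of the
transcription start site).  Gene lists are sorted by descending score
with ties broken by gene symbol, so serialized lists are byte-stable.

The family pool contains the genes that appear in **two or more** trio
lists ("more than one" read strictly), scored by the maximum over all
occurrences.  A gene may be supported by CpGs of opposite directions in
different trios or probes; both are retained and reported with their
directions.

## Gene p-values for enrichment

The subnetwork search consumes p-values, but no canonical p-value exists
for a bounded separation score.  The package uses the explicit convention
`p = clamp(1 - TbSSch, 1e-6, 1)`: strictly decreasing in the score,
confined to (0, 1].  It is an ordering device, not a calibrated tail
probability, and is documented as such on the API.

## Active subnetworks and pathway testing

Scored genes receive `z = Phi^-1(1 - p)`; network genes without a score
get p just below 1 (z about -6), so they join a subnetwork only when
topology demands it.  A subnetwork of k members is scored by
`z_A = (sum z_i) / sqrt(k)`.

The search is a deterministic greedy seed-and-extend: seeds are the
top 20 genes by z; from each seed the neighbor maximizing the new z_A is
added while z_A does not decrease and the subnetwork has at most 50
members; a candidate is accepted only if its overlap with every accepted
subnetwork is at most 50%, where overlap is the intersection as a
fraction of the **smaller** set; the search stops after 5 acceptances.
The classical active-modules literature uses simulated annealing with
Monte-Carlo calibration of z_A; the greedy variant trades claimed
optimality for exact reproducibility and desk-scale speed (a property
test logs the greedy-to-exhaustive z_A ratio on tiny graphs; greedy is
not claimed optimal).  All search parameters are exposed.

Each subnetwork is tested against every pathway with a two-sided
(enrichment/depletion) hypergeometric test.  The two-sided p is the
minimum-likelihood construction — the total probability of all outcomes
no more likely than the observed overlap — computed in exact integer
arithmetic (`math.comb` plus rational comparison), which removes any
floating-point ambiguity in deciding which outcomes belong to the sum; a
tail-doubling variant is available behind a flag.  The direction is
*enriched* when the overlap is at or above its expectation
`n*K/N` (ties count as enriched).  Bonferroni correction uses the number
of pathways tested per subnetwork as the multiplicity.  A pathway
significant in at least one subnetwork enters the final list once, via
its most significant occurrence (ties to the lower subnetwork id).  The
background universe is the pathway collection's universe file when given,
otherwise network nodes plus scored genes; pathway sets are intersected
with the background.

## Dual arm

All affected samples form one pool, the unaffected parents the other.
Per probe, a two-sample t-test compares the pools — Welch's
unequal-variance form by default, since pool sizes are unequal (2:1) and
variance homogeneity is not guaranteed — followed by Benjamini–Hochberg
step-up FDR across all tested probes.  Probes with fewer than two
non-missing values in either pool are skipped with a reason; probes that
are exactly constant in both pools get t = 0, p = 1 (equal means) or
p = 0 (different means) where the statistic is otherwise undefined.

Heatmap clustering takes the k = 1000 highest-variance probes (sample
variance across all samples, ties by probe id) and clusters probes and
samples agglomeratively with average linkage on Euclidean distances; the
distance/linkage choice is conventional for methylation heatmaps and only
the leaf orderings are exported.

Gene-level group means average beta over CpG-island probes only
(island probes are the densest, most promoter-relevant signal), each
multi-gene probe again contributing to all its genes.  Means are rescaled
onto [-1, 1] with the piecewise range map `y = C + (x - A)(D - C)/(B - A)`
applied as [0, 0.5] -> [-1, 0] and [0.5, 1] -> [0, 1]; both pieces reduce
to `y = 2x - 1`, which is asserted as a property.  A gene is flagged
*dual* when its two rescaled means differ by more than 0.05 (configurable)
— the tabular equivalent of a two-color gene box in a rendered pathway
diagram; diagram rendering itself is out of scope and the table is
written TSV for any external renderer.  The dual arm is annotation only:
it does not feed the trio arm (and in the null regime the FDR-adjusted
t-tests are expected to return no significant sites).

## Synthetic cohorts

The generator's defaults encode the reference study conditions: 13 trios
(39 samples), 20,000 probes over 2,000 genes — a deliberate ~24x
downsampling of a 485k-probe array that preserves probes-per-gene density
— with 0.2% of probes planted as trio-differential per trio, affected
pair in [0.85, 1] and unaffected parent in [0, 0.15] (or mirrored;
directions alternate).  Planted events therefore always satisfy the trio
rule and score at least 0.7.  Planting is restricted to autosomal `cg`
probes of the planted genes, which are chosen among genes with at least
one promoter-linked probe so the promoter-restricted arm sees the signal
too.

Background betas come from the two-component mixture Beta(0.5, 10) /
Beta(10, 0.5) with weight 0.5, reproducing the bimodal marginal
distribution of methylation arrays (no claim of matching any particular
cohort's moments).  The component correlation structure is the one
genuinely open modeling choice:

* ``component_mode="probe"`` (default) draws the component once per probe
  and shares it across all samples.  This matches real arrays — a CpG's
  methylation state is largely probe-intrinsic and consistent across
  individuals — and makes chance trio-rule qualifiers vanishingly rare
  (analytically ~1.9e-8 per probe and trio).
* ``component_mode="sample"`` draws every (probe, sample) value
  independently.  Individuals are then uncorrelated at each CpG and the
  rule fires by chance at the analytic rate
  `P(hyper)^2 P(hypo) + P(hypo)^2 P(hyper)` (~22% under the defaults) —
  far beyond anything biological.  The mode exists to validate the
  chance-qualifier accounting against that closed form, and the tests
  exercise it for exactly that purpose.

Consequently, what the passing recovery tests show is that the pipeline
faithfully recovers planted signal embedded in realistic probe-stable
background; they do not show robustness to confounders the generator does
not model (batch effects, cell-composition shifts, age trends, probe
cross-reactivity, intensity-level artifacts).

The PPI simulation is an Erdos–Renyi background (edge probability 0.005,
mean degree ~10 at 2,000 genes) plus a full clique on the planted genes;
the pathway collection holds the planted gene set plus 49 random decoy
pathways of 20–60 genes.  The truth ledger records every planted event
and, via a direct post-hoc scan, every chance qualifier; chance
qualifiers count as rule-level positives (the rule is deterministic) but
are excluded from pathway-recovery scoring.

## Determinism and problem sizes

Every stochastic component is a pure function of its parameters and seed;
repeated runs produce byte-identical output files (paths inside the run
log are stored relative to the output directory for this reason).  The
test suite and the acceptance script run the recovery study at the
default 13-trio / 20,000-probe scale across 20 seeds, the trio-rule
equivalence scan at 10,000 probes x 13 trios x 20 seeds, the
hypergeometric enumeration at backgrounds up to 30, and the null t-test
at 1,000 probes with 6 samples per pool; these sizes were chosen as the
smallest at which the targeted behaviour is unambiguous.

## Known limitations

* The score-to-p mapping is a convention; downstream p-value magnitudes
  inherit its arbitrariness (orderings do not).
* The greedy subnetwork search is not optimal and can miss high-z_A
  modules reachable only through low-z bridges.
* Reliability filtering is a stand-in for full array QC and sees only the
  detection-p matrix.
* The generator does not simulate intensity-level artifacts, probe-type
  chemistry, batch effects or covariates; real-cohort performance is not
  certified by the simulation results.
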