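# Methods

## Common deletion region discovery

A deletion cohort is a set of fragments — one contiguous somatically deleted
interval per record, several per sample allowed — over a fixed analysis
window. Coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read (`start + 1`, `end` unchanged), and the two
input dialects must be named explicitly because a silent off-by-one in
genomic coordinates is worse than a required flag.

Coverage is stabbing depth: `depth(x) = #{fragments f : f.start ≤ x ≤ f.end}`,
computed by a sweep line with +1 events at starts and −1 events at `end + 1`.
The CDR candidate is the maximal-depth run of this step function, merging
adjacent equal-depth segments; when several disjoint runs tie on depth the
longest is returned (ties broken by smaller start) and the rest are reported
as alternates. The reported support is the number of fragments that *fully
contain* the candidate — containment, not overlap, because a PCR amplicon
inside the region is only lost from alleles whose deletion spans all of it.
In degenerate cohorts a merged run can be stitched from different fragment
sets, making containment support lower than the coverage depth; the
containment count is what is reported because it is the operationally
meaningful number.

Whether the candidate is *called* a CDR is a rule, not a discovery:
`support_fraction ≥ min_fraction` (default 0.8) and `length ≥ min_length`
(default 1 kb). Genes whose deletions scatter without a shared core produce
shallow, fragmented maximal runs that fail this rule. Both thresholds are
exposed on the CLI. Fragments are counted per-fragment, not per-sample,
matching how containment percentages over deletion-fragment collections are
quoted; zygosity is carried on records and available as a filter but does
not weight coverage.

`interval_length_kb` rounds half-up to one decimal (5110 bp → 5.1 kb),
matching how region sizes are printed.

## qPCR copy-number quantification

The assay is a duplex reaction: a target amplicon inside the CDR and a
reference-gene amplicon (GAPDH) amplified in the same well, in triplicate.
Quantification is classic comparative-Ct with efficiency fixed at 2.0 —
the titration module exists precisely to verify that both amplicons run
near-perfect, closely matched efficiencies, which is the regime where the
uncorrected `2^-ΔΔCt` form is valid; `--efficiency` overrides it.

* **Informativeness gate.** A sample qualifies for calling only when its
  reference-gene mean Ct is ≤ 34.0 cycles (boundary inclusive): beyond that
  there is too little amplifiable DNA for a stable ΔCt.
* **Calling.** Per-replicate ΔCt values are converted to RCNs against the
  paired normal's mean ΔCt, and the tumor's replicate RCNs are compared to
  the normal's by a two-sided two-sample Student's t-test at α = 0.05:
  deletion if significantly lower, amplification if significantly higher.
  Testing on replicate RCNs rather than ΔCt is a presentation choice (the
  RCN is a monotone transform of ΔCt, so the orderings agree); a complete
  target dropout against an informative reference is called a deletion with
  RCN 0, p recorded as 0 and a dropout flag. Zero-variance replicate sets
  (which only arise in noise-free simulation) get the limiting p-value —
  0 when the means differ, 1 when they agree — with a warning. No
  multiple-testing correction is applied across samples: each tumor/normal
  pair is its own self-contained experiment.
* **Detection limit.** Spike-in mixtures of zero-copy DNA in a two-copy
  background are tested per fraction against the pure two-copy control; the
  limit is the smallest significant fraction *with all larger fractions
  also significant*. The monotone qualifier stabilizes the "lowest
  significant dilution" definition against isolated false positives at low
  fractions.
* **Controls.** A quantification run is expected to carry 100% two-copy,
  100% zero-copy and 20/80 mixture controls (sample ids `CTRL_2COPY`,
  `CTRL_0COPY`, `CTRL_MIX20`); their absence downgrades the run report to
  "uncontrolled" rather than erroring, since the statistics do not depend
  on them.

## Association statistics

Calls from two assays are merged by OR (deletion seen by either) or AND
(seen by both). Contingency tables orient rows by outcome and columns by
call, so `a/b` split the outcome-positive group. The odds ratio is the
cross-product `(ad)/(bc)` with a Wald log-scale 95% CI; zero cells flag the
estimate as degenerate, with the Haldane–Anscombe +0.5 correction behind a
flag. The two-sided Fisher p follows the point-probability convention (sum
of hypergeometric probabilities no larger than the observed table's); a
doubling-rule variant is provided. The Cochran–Armitage trend statistic
uses integer scores 0, 1, 2, … and the pooled-proportion variance, with a
normal-approximation p and no continuity correction. Samples with a missing
covariate level are dropped from that covariate's table and the dropped
count is reported.

## Synthetic data

The generators define the conditions the test suite runs under; they are
seeded and byte-reproducible.

**Deletion cohorts.** Each fragment contains the planted CDR with the
configured probability (default 0.9, 100 fragments, the 5.1 kb region in a
400 kb window). Containing fragments draw breakpoints uniformly in the
flanks; the first three are pinned to attain the planted boundaries (one
fragment equal to the CDR itself — the minimal observed deletion that
delimits a real base-resolution CDR — plus one start-attaining and one
end-attaining fragment). This keeps the depth plateau over the planted
region at least two above any flank position, so discovery recovers the
region base-exactly whenever at least three fragments contain it.
Non-containing fragments live wholly inside one flank with
truncated-exponential lengths (scale `breakpoint_spread`, default 50 kb,
never the full flank), which means they never partially erode the planted
plateau — an idealization: real non-CDR deletions can clip into the region.
Consequently an amplicon inside the planted CDR has containment
concentrated exactly at the planted fraction.

**qPCR plates.** `Ct = baseline − log2(effective copies / 2) + noise`, with
effective target copies `(1 − null_fraction) · true_copies`, reference fixed
at two copies, and baseline 28 cycles (only differences matter). Noise is
Gaussian on the cycle scale and split into a *well* component shared by the
two channels of a duplex reaction and a *channel* component:
`ct_noise_sd` (default 0.1 cycles, a typical replicate SD) is the total
per-Ct SD and `shared_noise_fraction` (default 0.8) the variance fraction
carried by the well effect. The shared component models pipetting and
template-load variation, which hits both channels of the same well equally
and cancels in ΔCt; the defaults give a replicate ΔCt SD of ≈ 0.063 cycles,
the precision at which triplicates detect a 20% zero-copy spike-in
essentially always while a 10% spike-in is borderline — the observed
operating regime of this assay class. A fully independent noise model at
the same per-Ct SD would give ΔCt SD 0.14 and only ~55% power at 20%,
which contradicts that regime; the split model is therefore the default
rather than an option. Zero effective copies produce the no-amplification
sentinel. DNA mass fractions are treated as copy fractions (equal genome
mass per cell across the mixed lines).

**Clinical tables.** Binary covariates are independent Bernoulli draws at
configured prevalences; the deletion call follows
`logit P = logit(base_rate) + Σ β_j x_j` with planted log-odds. Separately,
`table2_preset()` is deterministic: 139 samples grouped by call pattern
(19 positive by both assays, 32 CDR-only, 25 exon-1β-only, 63 neither; the
per-level pattern counts are derived from the published margins, which are
internally consistent — every level satisfies OR-merged = A + B − both),
with covariate levels laid out blockwise within each pattern class. All
covariate-by-call margins are exact; covariate–covariate structure is
arbitrary, so the preset supports marginal cross-tabulations only, not
joint or stratified analyses. Three samples carry a missing
differentiation level, consistent with that covariate's published totals.

## What the synthetic data does not show

Passing on these generators demonstrates the pipeline's correctness under
its own assumptions, not field performance: no tumor purity or subclonal
dilution, no reference-gene instability, no PCR inhibitors or efficiency
drift, no partial overlap of non-containing deletions with the CDR, and
covariates without realistic correlation structure. Cohort-level positive
rates in real tissue series depend on per-sample data and are outside what
synthetic margins can certify.

## Numerical choices and problem sizes

Least-squares fits use closed-form simple regression; t-tests are
equal-variance Student tests (the classic form for triplicate qPCR);
Fisher's exact p is validated against exhaustive hypergeometric enumeration
for all tables with n ≤ 30; the trend statistic was cross-checked against
an independent implementation once and its value on the stage counts is
frozen in the tests. Report rounding is half-up (odds ratios 2 dp,
percentages 1 dp, proportions 3 dp). Simulation sizes in the test and
acceptance runs — 200 random cohorts for the sweep-line/brute-force
equivalence, 2,000 simulated pairs for the type-I rate, 10 repeated
experiments for the detection limit, 1,000 replicates per planted odds
ratio for CI coverage — were chosen so each Monte-Carlo bound sits several
standard errors from its pass boundary while the whole suite stays
desk-scale.
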