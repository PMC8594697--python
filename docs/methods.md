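# Methods

## The window model

The unit of inference is a fixed 200-bp genomic window advanced in 100-bp
steps, analysed separately per cytosine context (CG, CHG, CHH).  Windows
start at 0, step, 2·step, … while the start lies inside the chromosome; the
final windows are truncated at the chromosome end, so every base is covered
and every interior base lies in exactly window/step = 2 windows.

A replicate's window level is the *unweighted mean of per-site ratios*
(n_meth/n_total over sites with coverage ≥ `min_site_coverage`), not the
pooled-count ratio.  The unweighted mean keeps a single deeply covered site
from dominating the window; the pooled-count alternative is available
through the Fisher test variant.  A window is *defined* for a replicate
only when it holds at least `min_sites_per_window` eligible sites — four,
the smallest count at which a standard deviation across sites or replicates
is meaningfully estimable — and a window enters testing only when it is
defined in **every** replicate of both groups.  Undefined is a represented
state (NaN), never coerced to zero: a window without data is not an
unmethylated window.

### The two-group test

The default statistic is the pooled-variance Student t-test on the
per-replicate window levels.  Two alternatives sit behind
`DmrCallParams.stat`: `welch` (unequal-variance) and `fisher` (Fisher's
exact test on read counts pooled over sites and replicates).  Student is
the default for two reasons: it is the test named throughout the original
analysis protocol, and at the realistic replication level of WGBS designs
(2–3 replicates per condition) it is the only one of the three that is
exactly calibrated under the null of equal group distributions — with
n = 3 per group the Welch–Satterthwaite degrees of freedom make the Welch
test conservative (empirical size ≈ 0.035 at nominal 0.05), which distorts
any downstream false-discovery reasoning.  With equal group sizes the
Student and Welch *statistics* coincide; only their reference distributions
differ.

Degenerate windows (zero variance in both groups) return p = 1 when the
means agree and p = 0 when they differ; a zero-variance group with the
Welch option falls back to scipy's behaviour.

### SDA filtering and DMR status

SDA ("standard deviation of averages") is the sample standard deviation
(ddof = 1) of a group's replicate window levels, in percentage points — a
direct measure of between-replicate reproducibility.  A window passes only
when *both* groups' SDA is at or below the per-context ceiling.  The
ceilings default to CG 10, CHG 10, CHH 5 pp and are plain configuration
values: in the original analysis they were fixed empirically by visual
inspection and never published, so these defaults claim only to be
reasonable relative to each context's baseline variability (CHH levels are
low, hence the tighter ceiling), and every interface exposes them.

A DMR is a single significant window: p ≤ `p_threshold` (default 0.01,
raw — no multiple-testing correction by default, mirroring the protocol;
a BH option exists), SDA pass, |δmC| ≥ `min_abs_delta` (default 0).
δmC is test-minus-reference, so hypo/hyper is the state of the test
condition (seedling/young graft) relative to the reference (donor tree).
Overlapping significant windows are *not* merged — the published counts are
consistent with window-level reporting — though `merge_dmrs` provides a
post-hoc merge of same-direction runs.  Printed-style summary percentages
round half-away-from-zero at the stated precision.

## Association and integration choices

Linking distance and promoter/terminator width share one `flank`
parameter (2000 bp): the analysis we mirror defined gene-proximal DMRs by
a 2000-bp neighbourhood and reported promoter/body/terminator splits
without stating a separate width.  Distance is measured between closest
interval edges (0 when overlapping).  A DMR touching several regions takes
the highest-priority class, promoter > body > terminator by default; the
priority is configurable because the source counts are disjoint without
stating the rule.  The classes are strand-aware; mirror-imaging the
chromosome swaps promoter and terminator, which the tests verify.  Each
feature keeps only its largest-|δmC| DMR (ties: smaller start, then
lexicographic context), and a DMR near several features contributes one
link per feature.

Integration defaults to CHH-context links and |log2 ratio| ≥ 1.5.  "Ratio"
is interpreted as a log2 ratio throughout.  The correlation is computed by
the regression route (R², then r = sign(slope)·√R², then the t-test with
n − 2 df), which the tests pin to Pearson's r within 1e−9.  For n < 50 an
F-ratio between the variances of the two plotted variables is reported
alongside, as in the source protocol; this pre-check is statistically
unusual (the two variables are on different scales), so it only annotates
the result and never gates the t-test.

Functional enrichment is a one-sided hypergeometric over-representation
test per BIN against the platform background with BH correction.  The
protocol named only "enrichment … with BH"; the count-based hypergeometric
is used because it is parameter-free and reproducible, where the classical
MapMan statistic (a Wilcoxon on expression values per class) tests a
different hypothesis.  Transcripts mapping to several BINs keep the
deepest (most specific) code; unassigned transcripts are excluded before
any percentage is formed.

qPCR quantification follows 2^−ΔΔCt with a multi-reference normalization
factor: per-gene quantity efficiency^(ΔCt against the calibrator), NF =
geometric mean of the reference-gene quantities, normalized expression =
target quantity / NF.  Amplification efficiency defaults to 2.0 (reactions
validated near 100%) and is overridable per primer pair.  A uniform shift
of all of a sample's Cts cancels exactly.

## The synthetic study

The generator emulates the moments of a plant WGBS comparison that the
caller actually consumes:

* cytosine positions per context with CHH-dominant densities (defaults
  CG 0.04, CHG 0.04, CHH 0.30 per bp counting both strands — a ~38%-GC
  genome in which roughly three quarters of cytosines are CHH);
* context baselines CG 60, CHG 40, CHH 10%, replicate-independent;
* coverage Poisson with mean 14 truncated at ≥ 1 (a site with zero reads
  would simply be absent from a call file), methylated counts binomial at
  the site level;
* injected regions shift the test condition's level by a signed delta,
  clipped to [0, 100], in their context only;
* expression: a gene's expected log2 ratio is −effect·(promoter CHH
  δ/100); replicate expression values carry Gaussian noise scaled so the
  realized ratio's own standard deviation equals `expression_noise_sd`,
  and p-values come from a pooled t-test on those replicates.  The default
  effect (30 log2-units per methylation fraction) and promoter-injection
  dose range (−9 to −4 pp) are chosen so that a typical coupled gene shows
  a ~5–7 pp promoter δmC and a ~1.5–2.7 log2 ratio — the magnitude regime
  the source study reports for its promoter-DMR genes — with replicate
  noise (0.35 log2 units) typical of two-colour microarray replicates.

Determinism: every draw derives from `SimSpec.seed` through fixed child
streams ordered by genomic coordinate, so identical specs produce
byte-identical files regardless of iteration strategy.

What the generator does **not** model — and what passing tests therefore do
not show about real data: read-level artefacts (bisulfite conversion
failure, mapping bias, PCR duplicates), spatial autocorrelation of
methylation outside the injected regions, between-replicate biological
variance beyond sampling noise (real SDA distributions are wider), genuine
TE sequence content, and any enrichment structure in the functional map
(class assignment is random, so the enrichment stage's expected finding on
synthetic data is *nothing*).

## Problem sizes and benchmark behaviour

The shipped study fixture is a 2-Mb, two-chromosome genome with three
replicates per condition — small enough that the full pipeline runs in
tens of seconds while every window sees realistic site counts.  The null
calibration check uses a 4.4-Mb no-signal genome and non-overlapping
windows (step = window size) so the ~64k tested p-values are independent
and the p ≤ 0.05 fraction can be compared to its binomial interval.  The
recovery benchmark injects 200 × 500-bp CHH regions at −30 pp into 2 Mb.

On that benchmark the caller recovers every injected region
(sensitivity 1.0), but its single-window precision plateaus near 0.86 and
cannot reach 0.9 under the default parameters.  This is a structural
ceiling, not a tuning artefact: ~18.7k null CHH windows at a calibrated
p ≤ 0.01 yield ~180 false single-window calls, while 200 injections can
contribute at most ~1,300 true overlapping windows, bounding precision at
roughly 0.88 even with perfect power.  The honest levers all change the
reported object rather than improving it: a conservative test (Welch)
trades the false calls for miscalibration, a |δmC| floor or BH correction
departs from the mirrored protocol, and merging windows makes precision
worse (false calls survive as singleton regions).  The per-window
false-discovery behaviour is exactly the nominal test level; users who
need region-level precision should raise `min_abs_delta` or enable the BH
option and accept the departure from the original protocol.

## Degenerate inputs and edge behaviour

Empty DMR sets summarise to zero counts with NaN (undefined) shares;
empty quadrant classes are reported as undefined, never 0/0; a
zero-variance variable makes the correlation undefined and flagged.  The
density track's hotspot flag marks bins at or above the 0.99 quantile of
that context's nonzero bin counts (linear-interpolation quantile).  A DMR
whose closest-edge distance equals the flank exactly (flush against the
neighbourhood boundary) is classified to the flank class of its side.
Chromosome lengths, when not supplied, are inferred from the largest
observed coordinate per chromosome.
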