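# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical edge-case policies. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential expression

**Fold change.** For transcript *t*, FC = max(m_T/m_N, m_N/m_T) where m_T
and m_N are arithmetic means of the *linear* normalized intensities, and
log2FC = log2(m_T/m_N) is signed tumor-over-normal. Arithmetic means of
linear intensities match the usual meaning of "fold change" on normalized
microarray intensity; a geometric-mean variant would be equivalent to
averaging on the log scale and is deliberately not the default.

**Test.** Two-sided two-sample Student's *t* with equal variances assumed
(`equal_var=False` gives Welch). The test runs on log2 intensities by
default — variance stabilization, the convention behind volcano P values
— with `on_log_scale=False` available for linear-scale testing. Expression
intensities on disk may be declared `linear` or `log2`; the loader
exponentiates declared-log2 data rather than guessing the scale.

**Calls.** UP ⇔ FC ≥ fc_min (inclusive, default 2.0) ∧ P < alpha (strict,
default 0.05) ∧ m_T > m_N; DOWN symmetric. Raw P drives the call; the
screen was designed around per-transcript filtering, so BH-adjusted
values are attached as a reporting column only. Degenerate inputs: zero
pooled variance with equal means gives P = 1; with unequal means, the
smallest positive double with a warning (perfect separation).

**Clustering.** Samples and transcripts are ordered by agglomerative
clustering with distance 1 − Pearson *r* and average linkage — the common
default for expression heatmaps. Rows are pre-sorted lexicographically by
identifier before linkage so equal-distance merges resolve identically
regardless of input order. A single-transcript subset yields a degenerate
result (no merges) because one profile cannot order samples.

## Co-expression network

Candidate lncRNA × mRNA pairs are scored by the sample Pearson
correlation across **all** samples pooled (tumor and normal together):
co-expression is a property of the joint profile, and with strong
differential expression the group separation itself is a legitimate and
dominant source of correlation. The P value is the exact *t*-transform
under the bivariate-normal null, *t* = r√((n−2)/(1−r²)) with n−2 df,
two-sided. This is the standard exact test for Pearson's *r*; at n = 10
it maps r = 0.9 to P ≈ 3.9×10⁻⁴, just inside a 5×10⁻⁴ cutoff, which is
why the default thresholds (|r| > 0.9, P < 0.0005, both strict) act as a
coherent pair at this sample size. Both thresholds are strict
inequalities.

Correlation is computed on linear intensities by default, matching the
screen's use of normalized intensity values; `on_log_scale=True` switches
to log2. Zero-variance transcripts make the correlation undefined: the
pair is skipped with a logged warning and counted, rather than aborting
the run. Degrees, per-class maximum-degree nodes (ties all reported),
negative edges and connected components (ordered by size then smallest
member id) summarize topology; components beyond the largest are the
"satellite" networks.

## Over-representation analysis

One-sided hypergeometric upper tail P(X ≥ k) with X ~
Hypergeom(N, K, n): universe size N, set size K, query size n, overlap k.
This is identical to one-sided Fisher's exact on the 2×2 table. The
universe defaults to the union of all set members unless the caller
supplies a measured-gene universe; query genes outside the universe are
dropped with a warning. Sets are ranked by raw ascending P (ties:
larger overlap, then name) because the display convention is a −log10 P
bar chart; the BH column is informational and does not drive the top-k
cut (default 20). The tail is evaluated by `scipy.stats.hypergeom.sf`,
which works in log space and is verified in the tests against exhaustive
combinatorial enumeration for every universe of size ≤ 12.

## 2^−ΔΔCt quantification

Livak aggregation: ΔCt per sample, then ΔΔCt as the difference of group
means of ΔCt, then ratio = 2^−ΔΔCt. Group-mean aggregation is the
standard choice when group sizes are unequal. Amplification efficiency
is fixed at 2 (the method's assumption); per-sample ratios are available
for inspection. Per-sample technical offsets cancel exactly because the
reference Ct is subtracted within each sample — this invariance is
property-tested. The loader accepts pre-averaged Ct values only (one row
per sample × gene).

## Synthetic-data generator

Log2 intensity of transcript *t* in sample *s*:

    log2 x[t,s] = baseline(t) + de_shift(t)·1{s tumor}
                  + loading(t)·factor(block(t), s) + ε,   ε ~ N(0, noise_sd)

with baselines uniform on log2 [4, 10], factors drawn i.i.d. N(0,
factor_sd) per sample, and the matrix emitted as 2^(log2 x) — linear
scale, as microarray normalized intensities are consumed here. Defaults
mirror the emulated study design: 5 tumor + 5 normal samples, 10 lncRNAs
+ 80 mRNAs, de_fraction 0.2 planted differentially expressed with linear
fold change uniform in [2, 8], noise_sd 0.1 (log2 cycles of roughly ±7%
multiplicative noise, a typical within-group CV for normalized arrays).
DE planting is stratified by transcript class so both classes are
represented at the same rate. The demo dataset raises the planted fold
changes to [8, 64], emulating a validated shortlist of strongly
differentially expressed lncRNAs. All randomness flows from one
`numpy.random.Generator` seeded by the design; outputs are byte-stable
across runs.

Ct tables are simulated so that 2^−ΔΔCt equals the planted fold change
exactly at zero Ct noise: the gene's tumor Ct is shifted by −log2(FC)
cycles relative to a zero-shift reference gene, plus per-sample offsets
that must (and do) cancel.

**Analysis scale for recovery experiments.** The latent-factor blocks
plant *linear* correlation on the log2 scale. After exponentiation, the
correlation of anti-correlated members is bounded well away from −1
(the lognormal attenuation effect; at factor_sd = 2 the attainable
linear-scale correlation of a +1/−1 loading pair is ≈ −0.15), so planted
negative edges are not recoverable from linear intensities at the
|r| > 0.9 threshold. The planted-network recovery and null-calibration
experiments therefore run the screen with its log-scale option — matching
the scale on which the structure is linear — while the default for real
intensity data remains linear. This is a matched-analysis choice, not a
tuning step: on the log scale the generator and the screen describe the
same linear model.

**What the generator does not emulate:** probe-level effects, batch or
hybridization artifacts, FFPE RNA degradation, heavy-tailed or
intensity-dependent noise, correlated gene sets beyond the planted
blocks, and annotation error. Passing recovery tests therefore
demonstrate correctness of the computations under the stated model, not
robustness to those real-data phenomena.

## Experiment sizes

The validation experiments use: 10,000 null transcripts for the type-I
check (3-binomial-SE band around 0.05); 20 seeded replicates for
planted-edge precision/recall (threshold 0.9 each); 50 null simulations
of 800 pairs for the false-edge expectation (800 × 0.0005 = 0.4, mean
required < 1); 10⁵ permutations for the correlation-test oracle
(agreement within 0.02, covering Monte-Carlo error plus the discreteness
of the n = 10 conditional permutation null); the exhaustive 252-split
label permutation for the 5v5 *t*-test oracle; and full enumeration for
all hypergeometric configurations with N ≤ 12.

## Known limitations

- The screen tests each transcript marginally; no moderated-variance
  (empirical-Bayes) shrinkage, which matters at n = 5 per group.
- The correlation P value assumes bivariate normality; for linear-scale
  intensities this is approximate (log-scale testing is the better-
  calibrated option and is exposed as a flag).
- ORA ignores gene-set overlap structure and any ontology topology;
  results depend strongly on the supplied universe.
- The network draws no direction or causality; an edge is symmetric
  evidence of co-expression only.
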