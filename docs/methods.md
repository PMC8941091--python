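# Methods

## Overview

`reactscape` infers the balance of mass effects versus species selection in
microbial community assembly from paired DNA/RNA 16S OTU tables. The
pipeline runs: (optional) simulation → phantom correction → stratum
singleton filter → CSS normalization → Bray–Curtis and Sørensen PCoA →
DNA–RNA pair distances and the ∆-distance → abundance-group thresholds →
origin and reactivity classification. This note documents the models,
the tunable parameters, the numerical choices, and what the synthetic data
do and do not establish.

## Preprocessing

**Phantom correction.** An OTU observed in an RNA sample but absent from
its paired DNA sample would imply activity without presence; such
observations get DNA = 1 (the smallest possible presence). The operation
only promotes exact zeros whose paired RNA is positive; it never decreases
a count.

**Stratum singleton filter.** Within each habitat × season × nucleic-acid
stratum, an OTU observation present in exactly one sample of the stratum
with fewer than `min_reads = 10` reads is considered unreliable and zeroed
(observation-level, not a global row drop — the same OTU may be perfectly
reliable in another stratum). The filter is idempotent. The boundary is
inclusive on the keep side: exactly 10 reads survive.

**CSS normalization.** For sample *j* with quantile *q*, the scaling factor
is s_j = Σ { x_ij : x_ij ≤ Q_j(q) }, where Q_j(q) is the q-th quantile of
the sample's *nonzero* counts (using all counts would give q_j = 0 on
sparse tables), ties included (≤). Values are x_ij / s_j × 1000. The scale
constant only moves absolute numbers ("CSS reads"), never relative
patterns, so thresholds quoted in CSS reads are specific to the constant.
The standalone function defaults to the fixed median (q = 0.5) for
determinism and testability; the *pipeline* default is the adaptive mode
(`quantile=None`), which scans a 0.05-grid from 0.5 and stops where the
median scaling factor across samples stabilises (relative change < 10 %).
The adaptive default matters when DNA and RNA libraries have very different
count distributions (e.g. RNA concentrated on few active taxa): a fixed low
quantile then scales the two members of a pair incommensurably and library
composition leaks into m_BC as a spurious abundance signal.

**Rarefaction** (sensitivity analysis only): samples below the target depth
are dropped and reported; the rest are subsampled without replacement
(multivariate hypergeometric), seeded.

## Ordination and pair distances

Bray–Curtis d = Σ|x−y| / Σ(x+y) is computed on normalized values; Sørensen
d = (b+c)/(2a+b+c) on presence/absence (> 0), which equals quantitative
Bray–Curtis applied to 0/1 data. PCoA is the classical Gower construction:
eigendecomposition of the double-centred −d²/2 matrix. Axes with negative
eigenvalues are dropped without Lingoes/Cailliez correction — matching
common practice — but their total magnitude is reported
(`negative_eigenvalue_mass`) so users can judge distortion.
`proportion_explained` is taken over the sum of *positive* eigenvalues (a
choice that shifts n₇₅% slightly; documented here because it is not the
only convention). Axis signs are fixed by making the largest-magnitude
loading of each axis positive; signs are otherwise arbitrary and distances
are sign-invariant.

n₇₅% is the smallest k whose cumulative explained variance reaches the
threshold (default 0.75, boundary inclusive); if the threshold is never
reached, k falls back to the number of positive axes. A two-sample
ordination of a zero dissimilarity has no positive axes; pair distances at
k = 0 are defined as 0.

Pair distances are Euclidean over the first k axes, with k chosen per
metric — the Sørensen and Bray–Curtis ordinations concentrate variance
differently. One *joint* ordination per metric covers all DNA and RNA
samples so pair coordinates are commensurable; unpaired samples shape the
ordination but produce no record. On positive semidefinite inputs the
full-axis pair distance equals the input dissimilarity (≤ 1), hence
∆ = m_BC − m_S ∈ [−1, 1]; under negative-eigenvalue distortion the bound is
not guaranteed and is asserted only on PSD fixtures.

## Abundance groups

The rank abundance curve of a stratum is the per-OTU mean CSS abundance,
zero-mean OTUs dropped, sorted descending. "Acceleration" is interpreted as
the negated second discrete difference of log₁₀ abundance **along rank**
after a centred moving-average smoothing (default window 5 ranks). On this
scale a geometric (log-linear) decay is exactly zero and a decay-rate break
produces a localized positive peak at the break rank, whereas a pure power
law (constant log-log slope) yields a monotone profile with no interior
maxima and is rejected. Differencing with respect to log-rank was
considered and rejected: for log-linear segments the second derivative with
respect to log rank grows in proportion to rank, so the profile is monotone
and planted breaks are not local maxima. Peaks are found with a minimum
separation of the smoothing window (merging smoothing ripple) after
rounding the profile to 12 decimals (so flat plateaus stay flat and peak
ranks are exactly invariant to rescaling the curve). The abundances at the
first and second peak rank become t_abundant and t_moderate; with a single
peak the result is flagged `single_threshold`. Group assignment is boundary
inclusive upward: mean ≥ t_abundant → abundant, [t_moderate, t_abundant) →
moderate, (0, t_moderate) → rare, 0 → absent.

## Origin and reactivity

**Origin** is an incidence concept: the earliest habitat, in the fixed
continuum order (soil, soilwater, stream, upriver, reservoirs, downriver,
estuary), in which the OTU has any DNA count, pooling seasons and years,
computed on filtered *counts* (not CSS values). OTUs detected only in
off-continuum habitats (tributaries, lakes, groundwater, …) are labelled
`other`; the order is configurable.

**Local contributions** are read fractions: 100 × (OTU reads in stratum) /
(stratum total), separately for DNA and RNA, on raw filtered counts.

**PRT.** The potential reactivity threshold is the median of all *nonzero*
%RNA contributions pooled across every stratum — one global value, applied
per stratum. Above the PRT an OTU's RNA tracks its DNA (reactive); at or
below it (boundary on the unreactive side, since reactive is "above the
median"), or with no RNA at all, the OTU is unreactive in that stratum. An
OTU may switch classes between strata. The PRT is always computed from the
data at hand, never hard-coded.

## The synthetic-data generators

**Mock experiment.** Four SAD families span an evenness gradient —
geometric series (ratio r; default 0.8), lognormal (parameterised by
1/σ; 0.8), broken stick blended toward uniform (weight 0.3), and
near-uniform symmetric Dirichlet (α = 50). Each family is parameterised so
that a larger `evenness_param` always raises Pielou J'. DNA assemblages are
multinomial draws (default depth 5000, richness 60, 5 sites); RNA is the
DNA vector with `n_remove` random nonzero OTUs zeroed — no re-sampling by
default, because removal-then-redraw changes the m_S/m_BC balance (a redraw
mode can be added at the call site by resampling from the truncated
composition). The default removal grid (0, 5, 10, 15) keeps the largest
level at roughly half the observed richness of the least even family;
removal cannot exceed *observed* richness, which for steep SADs is far
below nominal richness. Removing OTUs creates DNA-only taxa — the mock
dial for mass effects — and mean ∆ falls with the removal count, while the
less even families sit at higher ∆ (the selection end of the evenness
gradient). Depths are constant per scenario; real library sizes vary, but
the mock design isolates the removal and evenness axes.

**Watershed continuum.** Habitat h recruits `round(recruitment_rate ×
source_pool_size)` new OTUs (the source habitat recruits the full pool;
defaults 200 and 0.1) with lognormal(0, σ = 1.5) abundance scores; the two
terrestrial pools get a ×10 dominance factor, so soil/soilwater taxa
dominate reads everywhere downstream. Within a stratum, the unreactive
taxa are the bottom `carryover_unreactive_frac[season]` fraction of
carried-over OTUs (and `local_unreactive_frac = 0.5` of local ones) ranked
by DNA abundance with lognormal jitter (σ = 0.3): passive influx is
concentrated among numerically dilute taxa, while locally dominant taxa
are growing and hence reactive. The carry-over fraction ramps downstream
(from 0.4× at the source to 1× at the estuary) — transported taxa
accumulate along the flow path — giving each season a real spatial ∆
gradient. Defaults: spring 0.7, summer 0.3 (mass effects dominate spring);
depth 20 000 (a typical freshwater 16S library); 4 sample pairs per
stratum. Reactive taxa receive RNA proportional to DNA (×lognormal(0,
0.3) noise, so the reactive log-log %RNA–%DNA slope is ≈ 1); unreactive
taxa sit at a fixed relative RNA floor (default 2.5 × 10⁻⁵). Whether a
floor taxon registers as "below PRT" or "no RNA" is then purely a matter
of sequencing depth, as in real libraries.

Two parameterizations serve different validations. The *default* keeps the
floor faint, so most unreactive taxa are invisible in RNA and the seasonal
contrast is carried by incidence (m_S) — this is the configuration for the
spring/summer and CSS-vs-rarefaction checks. The *recovery* configuration
(depth 10⁵, floor 10⁻⁴, equal carry-over 0.5/0.5, no spatial ramp) makes
the floor reliably detectable and the floor/reactive clusters of nonzero
%RNA count-balanced around the pooled median, which is the regime in which
the PRT separates the two truth classes; origin and reactivity recovery
are ≥ 90 % there. At the default (low) depth the faint floor is mostly
censored to zero RNA, the nonzero pool is reactive-dominated, and the
median lands inside the reactive cluster — recovery degrades gracefully
rather than failing, but the recovery guarantee is a high-depth statement.

What the simulations do **not** emulate: sequencing error and chimeras,
taxonomy, variable library sizes, within-stratum environmental gradients,
OTUs recruited from unsampled habitats, and any coupling between abundance
groups and reactivity beyond the rank-biased draw. Passing tests therefore
show that the statistics recover the *designed* structure, not that the
specific field values of any real watershed are reproduced.

## Numerical choices and degenerate inputs

- Eigenvalues within `n · 1e-12 · max|λ|` of zero are treated as zero.
- Dissimilarity matrices are validated: symmetry to 1e-12, zero diagonal,
  entries in [0, 1], no NaN.
- All-zero samples are rejected by both dissimilarities and CSS; all-zero
  OTU rows are dropped by `classify` (origin is undefined without a single
  detection, and `classify_origin` raises on such rows).
- Equal acceleration maxima are broken toward the lowest rank.
- All generator randomness flows through `numpy.random.SeedSequence`
  spawned from one user seed; identical scenarios are bit-identical,
  including across pipeline reruns (manifest hashes verify this).
- Pipeline outputs are plain TSV/JSON; BIOM v2.1 I/O is available behind a
  lazy import.

## Problem sizes

The bundled validations use: mock grid 4 × 4 × 5 sites (160 samples, 20
seeds), continuum 112 samples × ~320 OTUs (20 seeds), 50 random PSD
ordination fixtures (≤ 10 samples), 50 random planted-break curves, and 3
recovery-configuration seeds — sizes at which every check runs in seconds
while leaving the asymptotic regime to the user's hardware.

## Known limitations

- The ∆ bounds (±1) are analytic only for PSD inputs; strongly
  non-Euclidean dissimilarities can distort truncated distances.
- The intra-pipeline cache is the stage-output directory itself; stages
  are re-runnable from written intermediates but there is no content-hash
  keyed memoization (the ordination sizes here do not warrant it).
- n₇₅% on data with thousands of samples may retain hundreds of axes;
  truncation is then mostly noise exclusion, and absolute ∆ values are not
  comparable across datasets — only relative patterns are.
- The PRT is a single global median; strata with systematically deeper RNA
  libraries shift it.
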