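# Methods

This note documents the models, conventions and numerical choices behind
`connrel`, in the order data flow through the package.

## Reliability model

Reliability is the consistency intraclass correlation from a two-way mixed
model with fixed session effects, ICC(3,1): subjects are random, the two
sessions are fixed levels, and a constant session offset is not counted
against reliability. With *BMS* the between-subject mean square and *EMS*
the residual mean square after removing subject and session effects,

    ICC = (BMS − EMS) / (BMS + (k − 1) EMS),   k = 2 sessions.

For k = 2 the implementation reduces the ANOVA to sums and differences:
with s_i = x_i1 + x_i2 and d_i = x_i1 − x_i2 over the n retained subjects,
BMS = Σ(s − s̄)² / (2(n−1)) and EMS = Σ(d − d̄)² / (2(n−1)). This form is
numerically direct (no subtraction of large sums of squares) and lets one
vectorized pass handle tens of thousands of edges, including per-edge
subject masks for the thresholded variant. The scalar path accepts general
k ≥ 2.

Confidence intervals are the F-based Shrout–Fleiss construction at a fixed
95 % level (α = 0.05): FL = (BMS/EMS)/F₁₋α/₂;n−1,(n−1)(k−1), FU =
(BMS/EMS)·F₁₋α/₂;(n−1)(k−1),n−1, bounds (FL−1)/(FL+k−1) and
(FU−1)/(FU+k−1). 95 % is the community default; no other level is implied
by the cited implementations. Negative ICC estimates are retained
unclamped — a linear-mixed-model estimator would clamp them at zero but is
otherwise equivalent, and all rank-based downstream statistics are
unaffected. Degenerate all-identical tables have undefined ICC and
propagate as missing. Bin labelings use half-open intervals closed on the
left (0.40 → "fair" in the 4-bin scheme, 0.80 → "perfect" in the 5-bin
scheme); interval notation like "0.40–0.60" is ambiguous at its endpoints,
so one convention is fixed and applied everywhere, including to
consistency-ratio bins.

Missing policy throughout: undefined correlations (zero-variance regions)
and under-populated estimates propagate as NaN and are excluded pairwise;
nothing is imputed.

## Preprocessing conventions

The per-run order is fixed: GSR (optional) → high-pass → scrub →
concatenate → correlate.

- **GSR** regresses each region on an intercept plus the unfiltered
  cross-region mean series, immediately after loading — i.e. the regressor
  is computed from the raw run, before filtering.
- **High-pass** is a 4th-order Butterworth at 0.008 Hz applied
  forward-backward (zero phase). The filter family and phase behavior are
  package choices — they are standard, preserve timing, and have a
  testable frequency response; order and cutoff are configurable.
  Residual column means (tiny after filtfilt) are subtracted so the output
  is exactly mean-free.
- **Scrubbing** deletes frames with framewise relative RMS displacement
  strictly greater than 0.30 mm; a subject is excluded when the flagged
  fraction strictly exceeds 15 % in any run. Both boundaries are strict by
  convention. Motion flags depend only on the RMS trace, so GSR+ and GSR−
  branches share identical scrubbing decisions by construction.
- **Concatenation** demeans each run's columns before stacking. Whether to
  demean is genuinely open; demeaning is chosen because between-run
  baseline offsets otherwise inflate pooled correlations with a spurious
  shared component.

Connectivity is plain Pearson correlation in r units; no Fisher transform
is applied anywhere, since thresholding and averaging operate on raw r.
Edge vectors use row-major upper-triangle order (i < j); network averages
use within-network edges only.

## Thresholding analysis

Absolute thresholding zeroes off-diagonal values below t, comparing signed
values — negative edges drop at any positive t. Proportional ("relative")
thresholding retains the ceil(p·E) largest edges *by signed value*; whether
proportional selection should rank by signed value or magnitude is
unstated in common toolboxes, so signed ranking is the documented default
(magnitude ranking would keep strong negative edges). Ties at the cut are
broken deterministically by canonical edge order. Retained counts use
ceiling rounding, making p = 1.0 exactly the identity.

The consistency ratio of an edge is (#subjects retained in both sessions)
/ (#subjects retained in at least one); edges never retained are excluded
from summaries. Reliability after thresholding is computed per edge only
over subjects retaining it in both sessions, with a floor of 10 such
subjects (ICC on fewer is too unstable to summarize; the floor is
configurable).

**Trend convention.** Sweep trends are Spearman correlations of the
per-threshold median statistic against threshold *stringency*: the r
cutoff itself in absolute mode, and the removed fraction 1 − p in relative
mode. Under this convention "consistency falls as thresholding tightens"
appears as a negative rho in both modes, which is how such trends are
conventionally reported. (Correlating against the retained proportion
instead would merely flip the sign in relative mode.)

## Synthetic cohorts

Two generators provide ground truth at different levels.

**Edge-level.** Each edge e has population mean μ_e, between-subject SD
σ_b,e and within-subject SD σ_w,e; observations are μ + b_i + ε_is with
independent normal components, so true ICC = σ_b²/(σ_b²+σ_w²) exactly.
This is the reference for estimator bias, CI coverage and recovery-slope
tests.

**Timeseries-level.** The generator emulates a two-day, four-run
resting-state protocol (2 runs × 1,200 frames per session, TR 0.72 s):

- A deterministic population correlation matrix from a fixed-seed
  five-factor loading model (Σ = BBᵀ + D rescaled to unit diagonal),
  giving a broad continuous spread of edge strengths rather than a few
  block values.
- Per subject, a latent matrix: population structure plus a seeded
  symmetric perturbation, projected back to a valid correlation matrix
  (iterated eigenvalue clipping with diagonal renormalization, smallest
  eigenvalue ≥ −1e−10, idempotent on valid input). The perturbation scale
  is heterogeneous per edge — drawn once per cohort and partly tracking
  population edge strength — which is what makes true reliability vary
  across edges and couples strength to reliability positively, as observed
  in large test-retest cohorts.
- Per session, a further session-specific perturbation of the subject's
  latent matrix. This is the within-subject variance source; without it
  the only session noise would be finite-length sampling error and every
  edge would be nearly perfectly reliable, unlike real data.
- A shared low-frequency global component (random walk low-passed below
  0.05 Hz, unit SD) added to all regions with a per-subject amplitude
  (truncated normal, mean 1.0, SD 0.5) that is *constant across sessions* —
  a stable between-subject "baseline" signal, which is why GSR removes
  reliable variance in this model.
- Motion spikes: Bernoulli frames (rate 0.02) corrupt all regions
  simultaneously (additive noise, SD 4 signal units) and set the RMS trace
  to 0.5 mm; clean frames draw RMS below 0.30 mm; the first frame is 0 by
  the relative-displacement convention.

All randomness flows from one cohort seed through per-subject substreams,
so subject i's data are identical in any cohort of any size with the same
seed.

Default noise scales (subject deviation 0.10, session deviation 0.10,
both before projection) were chosen once so that estimated edge
reliability spans the poor-to-excellent range with a median near 0.4–0.47
and the proportional-threshold consistency curve declines roughly linearly,
crossing 0.5 near mid-grid — the regime reported for large two-day
test-retest cohorts. The default synthetic parcellation is 40 regions, a
desk-scale stand-in for the 229–379-region atlases used in practice; all
operations are atlas-size-agnostic and record the region count in their
outputs.

**What the generator does not model:** hemodynamics, spatial structure
within regions, temporally autocorrelated regional noise beyond the global
component, distance-dependent artifacts, or family structure. Passing
recovery tests therefore demonstrates correctness of the estimators and
pipeline plumbing under a plausible covariance model, not robustness to
every property of real fMRI. One known divergence: in this model the
median ICC of consistently retained edges *falls* slightly with stricter
relative thresholds at study scale, whereas large real cohorts show a
slight rise; the real-data effect rides on a much stronger
strength-reliability coupling across tens of thousands of edges than the
synthetic model reproduces.

## Comparison tests and sample size

Kruskal–Wallis (tie-corrected, χ² p), Wilcoxon signed rank (normal
approximation with continuity correction, zeros dropped; the reported Z is
signed so that positive means the second sample exceeds the first) and
Spearman (average ranks, t-approximation p) wrap scipy.stats behind a
uniform TestOutcome record. P-values are reported as computed, never
floored.

The minimum-subjects utility is the Walter–Eliasziw–Donner approximation
with θ(ρ) = (1 + (k−1)ρ)/(1 − ρ), C₀ = θ(ρ₀)/θ(ρ₁):

    n = 1 + 2k (z₁₋α + z₁₋β)² / ((k−1) (ln C₀)²),

rounded up. α is one-sided — the alternative ICC > ρ₀ is directional —
which is the convention under which detecting ICC = 0.20 at 80 % power
with k = 2 requires 152 subjects. An empirical power check (simulated
panels at the returned n, one-sided F test of ICC = 0) confirms the
approximation lands within a few points of nominal power.

## Problem sizes used in the test and acceptance suites

Study-scale checks run on a simulated 100-subject cohort (40 regions,
4 × 1,200 frames); estimator calibration uses 200 subjects × 1,000 edges
(recovery) and 50 subjects × 2,000 replicate edges (CI coverage);
end-to-end determinism uses a 20-subject smoke cohort (12 regions, 200
frames per run). These sizes were chosen as the smallest at which the
targeted effects are stable, keeping the full suite fast enough to run
routinely.
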