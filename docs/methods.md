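# Methods

## Recoil model and fitting

An ablated junction is modelled as a Kelvin–Voigt element: a spring
(elasticity *E*) in parallel with a dashpot (viscosity *μ*). When the
tension borne by the interface is released, the distance between the two
tricellular vertices that flanked it relaxes as

ΔL(t) = D·(1 − e^(−t/τ)),  τ = μ/E,

with *D* the asymptotic recoil amplitude (µm) and τ the relaxation time
(s). The model's displacement is zero at t = 0 while the physical
vertex-to-vertex distance is the finite pre-ablation length L₀; the fit is
therefore performed on the **recoil increment** ΔL(t) = L(t) − L_ref over
the post-ablation frames, which preserves the functional form while
matching the observable. L_ref defaults to the length at the last
pre-ablation frame (`l_ref_mode="last_pre"`); averaging all pre-ablation
frames (`"mean_pre"`) is available when several pre frames exist.

Time conventions: t = 0 sits at the last pre-ablation frame, and the first
post-ablation frame sits at t = Δt (one frame interval), because the
ablation instant inside the inter-frame gap is unobserved. The fit uses
post-ablation frames only; a flag (`include_t0`) optionally adds the
anchor point (0, 0).

**Retraction velocity** is (L at the first post frame − L at the last pre
frame)/Δt — for a noiseless Kelvin–Voigt track this equals
D·(1 − e^(−Δt/τ))/Δt exactly, which the tests pin.

**Optimisation.** Unweighted nonlinear least squares (no per-frame
uncertainty model is available for manually tracked vertices), bounded to
D ≥ 0 and τ ∈ [Δt/10, 10·T_total]. Initialisation: D₀ = ΔL at the final
frame; τ₀ = the earliest time at which ΔL reaches (1 − 1/e)·D₀, found by
linear interpolation (including the implicit (0, 0) point). Two starts are
tried (the heuristic τ₀ and the geometric mid-point of the τ bounds) and
the lower-RSS solution kept; if the gradient-based solver fails outright,
a 200×200 grid search over the same bounds (D linear, τ log-spaced) takes
over and the result is flagged `method="grid_fallback"`. A track with no
net recoil (final ΔL ≤ 0) returns `converged=False` with diagnostics
rather than raising, and ensemble summaries report how many fits were
excluded. The same grid search doubles as a slow, assumption-free oracle
in the tests: the optimizer must never report a worse RSS than the best
grid node.

**What τ estimates look like in practice.** τ is well constrained only
when the recoil amplitude clearly exceeds the tracking noise. At the
default noise (0.05 µm per vertex coordinate) a control-scale junction
(D ≈ 1.2 µm) recovers τ with ~15% median error from 9 post frames, but a
weak-recoil junction (D ≈ 0.7 µm at a 0.05 µm/s velocity scale) yields
right-skewed τ estimates — the mean across junctions can exceed the
generating value noticeably while the median stays close. Summaries
therefore report both s.d. and s.e.m., and per-track tables keep the RSS
and convergence flags.

## Synthetic recoil data

`simulate_recoil_track` places two vertices on a line with a random
orientation and centre, separated by L₀ before ablation and by
L₀ + D·(1 − e^(−t/τ)) after, then adds isotropic Gaussian noise
(sd `noise_sd`, default 0.05 µm — a proxy for manual-tracking jitter;
no magnitude is established for the real protocol, so the value is a
package choice exposed in the generator) independently to every
coordinate at every frame. Acquisition defaults mirror the emulated
experiments: Δt = 4 s, one pre-ablation frame, nine post-ablation frames
covering 36 s.

`simulate_condition_ensemble` draws per-replicate (L₀, D, τ) from
lognormal distributions parameterised by arithmetic mean and CV —
lognormal keeps the parameters positive and the CV parameterisation is
directly interpretable; CV = 0 collapses to the mean exactly. Defaults
(CV 0.2 for D, 0.15 for τ and L₀) represent typical inter-embryo spread;
they are the study conditions, not tuning knobs. Per-replicate seeds are
derived as `default_rng(seed).integers(0, 2**31, n)`, so every track is
reproducible element-wise, and the ensemble carries its ground-truth
parameter list for recovery tests. The demonstration regime pairs 17
control junctions (τ 11 s, velocity scale 0.100 µm/s) against 12
knockdown junctions (τ 12 s, 0.051 µm/s — a 49% programmed decrease);
an overexpression pairing (τ 8 s vs 10 s, +43%) is used in the analysis
scripts. The velocity scale itself is a package choice; only the relative
effects and relaxation times are anchored to the emulated regime.

Limitations: each junction is generated independently — there is no
mechanical network coupling to neighbouring interfaces, no drift or
systematic tracking bias, and noise is uncorrelated across frames. Passing
recovery tests shows the estimator is correct under these assumptions, not
that real tissue obeys them.

## Synthetic epithelium and linescans

`synth_epithelium_image` builds a Voronoi lattice from uniformly random
cell centres (mirrored across the field edges so all interior ridges are
finite), draws each ridge as a band of half-width 0.15 µm, and assigns
junction pixels the intensity
`junction_intensity · (1 + punctateness · sin(2π·s/period))`, where *s* is
the pixel's arclength coordinate along its nearest ridge (period 1 µm by
default). `punctateness = 0` gives exactly uniform junctions, so a
linescan confined to a junction has heterogeneity 0; any positive
punctateness adds peaks and troughs along the junction. z-slices share
geometry with independent Gaussian background noise, and intensities are
clamped at zero. The generated object records the ridge segments, so
analyses can place linescans on ground-truth junctions.

Linescans sample the **maximum-intensity projection** (matching the stated
order of operations) by bilinear interpolation (`map_coordinates`,
order 1) at uniform arclength steps, default one pixel, endpoints
inclusive; line width is one sample (no perpendicular averaging; an
averaging option exists but is off, since only a plain line is specified
for the emulated protocol). Heterogeneity uses the sample (n−1) standard
deviation by default; the denominator is a convention, exposed as `ddof`,
and the default is pinned by tests. A constant profile short-circuits to
sd = 0 exactly, avoiding float-summation residue. Per-embryo summaries
average over however many lines an embryo contributes and record the
count.

The generator does not emulate point-spread blur, bleaching, junction
curvature within a ridge, or cytoplasmic signal; heterogeneity differences
between conditions are therefore cleaner than in real images.

## Clone morphometry

Within one unit (follicle or segment), the statistic is the **ratio of
group means**, clone over control — not the mean of per-cell ratios, since
cells are not paired across groups and group sizes differ. Per-unit ratios
are the observations fed to group statistics, matching how units are
counted as n. `widths_from_boundaries` converts an ordered apical-boundary
annotation into per-cell widths by consecutive differences. The synthetic
generator draws control widths lognormally (mean 3 µm, CV 0.15 by default)
and scales independent clone draws by a constriction factor; CV = 0 makes
the recovered ratio exact, and the cohort mean ratio recovers the factor
within Monte-Carlo error for CV ≤ 0.3.

## Group statistics

Mann–Whitney U uses midranks, with the exact null distribution (full
enumeration) when the combined n ≤ 14 and there are no ties — covering the
condition sizes of the emulated experiments — and the normal approximation
with tie and continuity corrections otherwise. Two-sided p doubles the
smaller one-sided tail, capped at 1. Degenerate inputs (all observations
identical) return p = 1 with a flag rather than an error. Student's t is
the pooled-variance two-sample test (df = n₁+n₂−2); one-way ANOVA is the
standard between/within decomposition; for two groups F = t² to numerical
precision, which a test asserts. Percent change is defined on group means,
100·(mean_treated − mean_control)/mean_control. No multiple-testing
correction is applied (none is part of the emulated protocol); report
metadata says so. Significance stars follow the */**/***/**** convention
at p ≤ 0.05/0.01/0.001/0.0001.

## Problem sizes and determinism

Everything is seeded through a single integer; generators and the pipeline
are bit-reproducible given (config, seed). The standard verification runs
use: a 3×3 (D, τ) grid for exact recovery; 50 tracks for the
optimizer-vs-grid oracle; 200 tracks per τ regime for recovery; 100
repetitions of the 17-vs-12 end-to-end comparison; 50–100 epithelium pairs
for the punctate/uniform separation; 2000 simulations for the
Mann–Whitney null calibration; and 500 cohorts for constriction recovery.
These sizes keep Monte-Carlo error comfortably below the assertion margins
while remaining desk-scale.
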