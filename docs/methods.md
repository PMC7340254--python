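# Methods

This note records the models, numerical choices and design decisions behind
vrscreen, and what the synthetic tests do and do not establish about real
beamline data.

## Curve comparison

**Ratio construction.** For titration-point curve I(q) and apo reference
J(q) on a common grid, the ratio R(q) = (I+c)/(J−c) is computed over points
where both intensities (and both constant-adjusted intensities) are
positive; dropped points are counted and reported. R is divided by its
geometric mean so proportional curves give R ≡ 1 — V_R is therefore exactly
scale-invariant, which is why a pure concentration error between samples
does not register. The constant c models flat buffer-scattering mismatch
(unbound ligand, counterions): splitting it symmetrically between numerator
and denominator makes c = −b/2 cancel an additive offset b on I exactly,
while exchanging I and J together with c → −c maps R to 1/R, so V_R (built
from a reciprocal-invariant channel distance, below) is symmetric in its
two arguments including under c-fitting.

**Shannon channels.** The usable window [q_min, q_max] is tiled from q_min
with channels of width Δq = π/D_max. D_max is a user input (no indirect
transform is performed); the default 7.2 nm is appropriate for ~26–32 kDa
two-lobed receptors. Per channel the geometric mean R_i of retained ratio
points is taken; an empty channel is an error (the caller may widen the
window), and at least two channels are required. The highest-q channel is
generally partial and carries weight w = N_q,channel/M_q, where M_q is the
mean point count of the complete channels (exact for uniform grids).

**Volatility ratio.** V_R = Σ w·|R_i − R_{i+1}| / ((R_i + R_{i+1})/2), the
weight of each difference being that of its more-partial channel (only the
last term is ever down-weighted). The relative difference is invariant
under R → 1/R, which carries the exchange symmetry. With c-fitting enabled,
V_R(c) is minimized by Powell's method started from c = 0, from the
buffer-matching estimate −b/(1+a) of a least-squares fit I ≈ aJ + b, and
from the best point of a coarse deterministic scan; |c| is bounded by 10×
the median |I| over the three highest-q channels so the adjustment can
never flip intensity signs or flatten genuine signal, and a candidate that
escapes the bound or fails to improve on c = 0 is discarded. The multiple
seeds matter because V_R(c) holds a narrow basin at the offset-cancelling
value which a single line search can step over.

**χ_lin.** Reduced χ (the square root of χ²/ν) of I against the best
weighted scale+offset transform of J; ν = n − 2. Its quoted σ comes from
the sampling variance 2/ν of χ²_ν. With missing or all-zero errors the fit
falls back to unit weights.

**Guinier fit.** Weighted linear regression of ln I on q², with the window
chosen automatically: the longest low-q window satisfying q·R_g ≤ 1.3
(configurable), with three guards — the window must start where I is at
least 25% of the curve maximum (at qR_g = 1.3 intensity has only fallen to
57% of I(0), so genuine Guinier windows can never start deep in the decay);
growth stops at the first q·R_g violation; and the window must be
left-maximal (prepending one lower-q point must break the fit, otherwise
that longer window is the candidate). Without the first and third guards
the search can lock onto shallow high-q ledges of oscillatory form factors.
Candidate windows whose residuals trend systematically (|correlation| ≥ 0.6
with point index) are trimmed. A strong low-q upturn (aggregation) either
forces the window past the upturn or, if nothing admissible remains, raises
a no-Guinier-region error. Prefix-sum accumulation makes each candidate
window O(1), so the search is linear-time per start index.

**Invariants.** V_c = I(0)/∫qI dq and V_P = 2π²I(0)/∫q²I dq, trapezoidal,
with the Guinier model I(0)·exp(−q²R_g²/3) filling [0, q_min). Both are
invariant to intensity rescaling. V_c's σ propagates per-point intensity
errors through the trapezoid weights plus the relative R_g error (the
correlated I(0) contribution); V_P carries no σ, matching the convention
that uncertainty estimation for V_P-like metrics goes through jackknife.

## Binding model

[RL] is the smaller root of x² − (R+L+K_D)x + RL = 0, evaluated in the
rationalized form 2RL/(b + √(b²−4RL)) to avoid cancellation when K_D
dominates; conservation then holds to rounding. The metric model is linear
in the bound fraction. The global fit per experiment set shares X_apo
across ligands, weights residuals by the metric's per-point σ when it
exists (χ_lin, R_g, V_c) and unweighted otherwise (V_R, V_P), and uses
Powell minimization with three deterministic starts — log₁₀K_D at the
receptor concentration and ±2 decades, X endpoints read from the curve
ends — keeping the best objective. The likelihood is flat far from [R], so
multiple starts guard against spurious interior optima. The ±4-decade box
on log₁₀K_D is enforced by clipping inside the objective; because affine
rescaling of the metric rescales the endpoints only, K_D estimates are
invariant under X → aX + b.

**Degenerate-affinity rule.** After the fit, each ligand's curve is
re-scored with its K_D pinned at the weak-side box bound and X_holo
re-solved in closed form. If that explains the curve within one noise
degree of freedom of the free fit (SSR ratio ≤ 1 + 1/ν, ν = n − 3), binding
is not resolvable and the bound is reported with an `at_bound` flag. In the
noise-free limit every beyond-box affinity therefore lands exactly at the
bound. Under noise, a truly signal-free curve is noise floor plus scatter,
and maximum likelihood will sometimes prefer an interior K_D that chases
that scatter; stricter thresholds were found to mis-clamp genuine
weak-binding ligands and are not used. This mirrors the behavior of
published weak-ligand fits, which report interior values with very large
error bars rather than piles at the bound.

**Uncertainties.** (1) Noise replicates: each replicate perturbs every
metric value by N(0, σ_point) and refits the whole set (default 1000
replicates, seeded); requires per-point σ. (2) Jackknife: one titration
point of one ligand removed per replicate, the whole set refit; a ligand's
σ is the spread over its own N removals. Replicate refits warm-start from
the full-data solution plus one cold start. In both estimators, replicates
whose fitted apo–holo difference deviates >3σ from the ensemble mean are
discarded in a single pass, per ligand, before σ(log₁₀K_D) is taken; losing
more than half the replicates raises an instability warning. The reported
K_D is always the full-data fit; replicates feed only σ.

## Mixture theory

Dilute-limit mixing is exactly linear in intensity:
I_mix = (1−f)I_A + fI_B. The Debye engine computes profiles from atomic
coordinates with constant per-element electron-count weights (vacuum: no
hydration layer, no excluded-volume term, no q-dependent form factors),
accelerated by an f_i·f_j-weighted pair-distance histogram with 0.01 nm
bins. These solvent simplifications shift absolute profiles but not the
*mixing-linearity* conclusions, which are properties of the linear
intensity combination. For unequal-size endpoint pairs
(oligomerization), both number-weighted (default) and equal-mass
weightings of the fraction are available, since the meaning of "fraction"
is ambiguous there. The sweep fits an ordinary least-squares line over the
fraction grid (101 points) and reports the maximum |residual| as a
percentage of the endpoint-to-endpoint metric change; identical endpoints
flag the sweep degenerate rather than dividing by zero.

## Synthetic titrations

The generator emulates a screening experiment on a compacting two-lobed
receptor:

- **Endpoint profiles:** analytic two-sphere dumbbell whose lobe
  separation sets R_g exactly: R_g² = (3/5)a² + (d/2)². Defaults give an
  apo R_g of 1.96 nm shrinking by 0.13 nm on closure (the compaction scale
  of a ~26 kDa histidine-binding receptor); a sphere-pair variant is also
  provided. The resulting saturation ΔV_R over the 0.2–2.0 nm⁻¹ window is
  ≈0.23. A variant with extra hinge density can reach the larger ΔV_R seen
  for real receptors (~0.4) but breaks the <3% mixing linearity that the
  linear metric model assumes, so it is not the default.
- **Ladder:** 0.0, 0.2, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5, 2.0, 4.0, 10.0
  at fixed receptor concentration (default 20 µM).
- **Apo replicates:** besides the ladder's ratio-0 well, `n_apo_replicates`
  (default 3) independent apo measurements feed the reference pool, as a
  screening plate provides. This matters: with a single apo well the
  reference *is* that well, its V_R is identically zero while every other
  point carries the positive noise floor, and the resulting artificial
  step mimics tight binding.
- **Ligand background:** flat in q, proportional to free-ligand
  concentration — the regime the fitted constant c is designed to remove.
- **Noise:** per-q-point Gaussian, either relative (σ = ε·I, default
  ε = 5%) or dose-scaled counting (σ = √(I/dose_per_point), so 4× dose
  halves σ). Noise applied per q-point partially averages out in the
  channel means: for the default pair, ε = 5% induces ≈8–10% random error
  on the V_R curves, and ε = 2.3% induces ≈4–5%. Sensitivity analyses that
  assume "5% random error" on the fitted observable therefore use
  ε = 2.3%; the acceptance script reports the induced metric-level error
  alongside the recovery surface.
- All randomness flows through explicit `numpy.random.default_rng` seeds;
  there is no hidden global state.

What the generator does **not** emulate: inter-particle structure factors,
radiation damage, capillary fouling, frame-level artifacts, non-flat buffer
mismatch, or the session-to-session grid differences of real beamlines.
Passing synthetic tests therefore demonstrates the correctness and
statistical behavior of the analysis chain under its stated assumptions,
not robustness to every beamline pathology.

## Problem sizes and tolerances

Unit tests run on ≤350-point grids with oracle agreement asserted at
1e-10 (V_R vs a loop-level brute-force evaluation; the two-state solver vs
200-iteration bisection over a 5×5×5 grid spanning 8 decades). The
recovery surface uses 100 seeds per affinity at five affinities spanning
±2 decades of [R]; medians inside ±1 decade fall near 0.05–0.25 decades
and are asserted ≤ 0.3, with monotone degradation outward — the ±2-decade
edges are the boundary of the design's sensitivity band, and the
weak-binding edge (100×[R], maximum bound fraction ≈0.09 on the ladder) is
reported but not bounded, since amplitude and affinity degenerate there.
Guinier recovery checks use a conservative q·R_g ≤ 0.8 window where
truncation bias is below 1% (at the 1.3 default the bias on the dumbbell
pair's ΔR_g is ≈6% — an estimator property, not a generator error). The
noise-replicate default of 1000 is reduced to 20–60 in unit tests for
speed; determinism and monotonicity, not absolute σ values, are asserted
there.

## Known limitations

- The Guinier auto-range is a documented longest-valid-window search, not
  a re-implementation of any specific published range-selection algorithm;
  window choices on marginal data will differ from other tools.
- V_R carries a positive noise-induced bias (it is a folded statistic);
  at signal levels near the noise floor this inflates apparent changes.
  Detectability in practice requires a metric change comfortably above
  the replicate floor.
- The weak-binding side of the recovery surface is intrinsically less
  identifiable than the tight side for a free-amplitude fit; reported σ
  values there are large and should be trusted over point estimates.
- c-fitting can trade against genuine signal when the flat background is
  a large fraction (≳30%) of the windowed intensity; at realistic
  small-molecule background levels (a few percent) the trade-off is
  negligible.
- χ_lin's definition (reduced χ against a scale+offset transform) is one
  of several in circulation; its absolute scale depends on the error
  model of the input σ column.
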