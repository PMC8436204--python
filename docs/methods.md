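# Methods

## Physical models

### Voigt thin film on a quartz sensor

The sensor is an AT-cut quartz crystal (fundamental f₀ = 5 MHz, acoustic
impedance z_q = 8.8×10⁶ kg m⁻² s⁻¹ by default; both configurable) loaded
with a single uniform viscoelastic film — here a supported vesicle layer
(SVL), i.e. intact vesicles adsorbed without rupture — under a Newtonian
bulk liquid (default: water/PBS-like, ρ_b = 1000 kg m⁻³, η_b = 1 mPa·s).
The film is a Kelvin–Voigt element with density ρ, thickness L, viscosity η
and shear modulus μ.  In the thin-film limit (L ≪ penetration depth δ) the
per-overtone shifts, referenced to the sensor already immersed in buffer so
all bulk-only terms cancel, are

    Δf_n = −(1 / 2π ρ_q h_q) [ Lρω − 2L (η_b/δ)² ηω² / (μ² + ω²η²) ]
    ΔD_n = (1 / π n f₀ ρ_q h_q) · 2L (η_b/δ)² μω / (μ² + ω²η²)

with ω = 2π n f₀, δ = √(2η_b/ρ_b ω) and ρ_q h_q = z_q/2f₀.  Assumptions:
no-slip coupling, lateral homogeneity, a single layer (no multilayer
stack), and shifts small relative to f₀.  The model reduces to the
Sauerbrey relation Δf = −n f₀ Lρ/ρ_q h_q in the rigid limit (μ→∞ or η→0
with μ large), which the test suite verifies to <0.5% with ΔD < 10⁻⁸.  A
warning (not an error) is raised when L > δ/2, where the truncation
degrades; enforcing the regime is the caller's responsibility because
plateau data near the boundary are still routinely inverted in practice.

Mass sensitivity: the Sauerbrey constant defaults to z_q/2f₀² ≈ 17.6
ng cm⁻² Hz⁻¹ and is cross-checked (warning at >5% deviation) when supplied
explicitly.  The `sqrt_n` Sauerbrey mode divides Δf by √n instead of n:
soft lossy layers show Δf closer to √n-scaling than n-scaling, and the √n
normalization partially compensates the rigid model's mass underestimation.
Because the uptake readout is a mass *ratio* (NP mass over SVL mass on the
same overtones), the overall √n inflation cancels and only the difference
in viscoelastic bias between the pre- and post-uptake states separates the
two mass routes.

### An exact identifiability degeneracy

In the truncated thin-film form, the observables are invariant under the
one-parameter family (ρ, L, η, μ) → (cρ, L/c, η/c, μ/c): only ρL, Lη and Lμ
are identifiable from any number of overtones.  This is the well-known ρ–L
ambiguity of QCM-D inversion in its sharpest form.  Consequences adopted
throughout:

* the fit always reports the areal mass ρ·L, which is invariant and
  recovered to machine precision on noiseless data;
* `identifiability_flag` is set from the Jacobian conditioning at the
  optimum (singular-value ratio < 10⁻⁷, which detects the exact degeneracy
  even when the residual is zero) or from the unscaled-curvature ratio of
  individual-parameter to product uncertainty (threshold 3×);
* recovering η and μ individually requires pinning ρ or L via the
  `fixed` argument, and the round-trip tests do exactly that.

## Numerical choices

**Inversion.**  Bounded least squares (scipy trust-region reflective) over
log₁₀-parameters, default box ρ ∈ [500, 1500] kg m⁻³, L ∈ [1, 100] nm,
η ∈ [0.5, 50] mPa·s, μ ∈ [10², 10⁷] Pa.  A deterministic multistart grid
(the 1/4 and 3/4 quantiles of each log-range, 2⁴ starts, plus the center)
replaces random restarts so fits are reproducible without seeds.  Δf
residuals are weighted by 1/n; ΔD residuals are multiplied by 10⁸.  The ΔD
weight deliberately exceeds "comparable magnitude" (~10⁷) by an order of
magnitude: dissipation pins the film's viscoelastic correction, leaving the
frequency residuals to fix the areal mass, and with comparable weights a
few percent of Δf noise can trade areal mass against the correction term
almost freely.  With the chosen weighting, 2% multiplicative noise on all
12 observables leaves the areal mass within 5% in ≥90% of seeded
replicates.  Confidence half-widths come from the local curvature (Gauss–
Newton covariance) at the optimum, propagated from log to linear scale.

**Plateau detection.**  A plateau is the longest terminal segment on which
the Theil–Sen slope of every overtone's Δf is within `slope_tol` (default
0.05 Hz/min) both over the whole segment and over its initial
`min_duration` (default 30 min) window — the initial window carries the
steepest residual drift of a saturating approach, so checking it prevents
declaring the plateau too early; segments are scanned at ~120 candidate
onsets and Theil–Sen uses ≤151 subsampled points.  The reported value is
the mean over the final `min_duration` window only: a whole-segment mean
is biased low by O(slope_tol × segment length) while the terminal window
sits closest to the asymptote (measured: <0.1% vs ~1–1.5% error on an
8-time-constant exponential).  The 0.05 Hz/min default was chosen so that
this residual bias stays well under 1% at the study's formation
timescales.  If no qualifying segment exists, the terminal-window mean is
returned flagged `achieved=False`.

**Segmented uptake trend.**  After normalizing to the 0 mol % reference
(exactly 100%), the continuous model y = a + b·min(x, c) is fitted by
linear least squares at every candidate breakpoint c on a 1 mol % grid
strictly inside the data range; smallest residual wins, ties to the
smaller c.  The fit falls back to a single line (breakpoint = None) unless
the segmented residual is below `fallback_factor` (default 0.5) times the
line residual — on exactly linear data the segmented model cannot reach
zero residual with an interior breakpoint, so the fallback triggers
correctly there.

**Waiting-time estimators.**  Under a single dominant barrier the first-
anchoring time is exponential; fixed-length runs right-censor it.  The MLE
is τ̂ = (Σ all waits, censored included)/(uncensored count d), with CI from
the pivot 2T/τ ~ χ²(2d) — exact without censoring, the standard gamma
approximation under Type-I censoring.  All-censored samples raise an error
carrying the one-sided lower bound.  The cumulative-curve fit uses Hazen
plotting positions (i−½)/N (censored trials in the denominator only)
against 1 − e^(−t/τ); its CI reuses the χ² pivot around the fitted τ
because least-squares curvature on an empirical CDF understates the
sampling variability by an order of magnitude (correlated residuals).  The
Kolmogorov–Smirnov distance to the fitted exponential is attached as a
goodness-of-fit measure.

**Arrhenius consistency.**  τ = τ₀·e^(ΔG/k_BT) with k_BT defaulting to
2.494 kJ/mol (300 K; the CG simulation temperature is not pinned by the
emulated study, so it is configurable).  τ₀ is never estimated jointly
with barriers from the same data (not identifiable); the pairwise check
compares ln(τᵢ/τⱼ) with (ΔGᵢ−ΔGⱼ)/k_BT so τ₀ cancels.  The pipeline's
pass tolerance is twice the pooled CI width in ln-τ units: a pairwise
discrepancy combines two estimates, so this admits ~3σ draws on both
sides while remaining far below the signal of mislabeled conditions.
Coarse-grained-to-laboratory time rescaling is exposed only as an optional
scalar multiplier on reported times (default 1).

## The synthetic scenario

The generator emulates a four-condition study (0/15/30/45 mol %
cholesterol in DOPC) with 12 anchoring trials per condition.  Defaults:

* **SVL truth**: ρ = 762 + 1.8·c kg m⁻³ (0.762 g cm⁻³ at 0% cholesterol,
  rising with packing), L = 15 nm constant, η = 6 + 0.05·c mPa·s,
  μ = 1.5 + 0.01·c MPa.  These give per-overtone responses with ΔD in the
  few-10⁻⁶ range and a ~9% viscoelastic Δf deficit relative to Sauerbrey —
  a soft but lossy film for which the two mass routes agree on uptake
  percentages within ~15%, as the emulated study type reports.
* **Trace shape**: baseline 30 min; vesicle deposition as a saturating
  exponential (timescale 30 min, span 8 timescales); rinse 30 min; NP
  incubation (timescale 90 min, span 8 timescales); final rinse.  Additive
  Gaussian noise σ_Δf = 0.3 Hz, σ_ΔD = 0.1×10⁻⁶ per point.  The post-uptake
  layer keeps (L, η, μ) and raises ρ by Δm/L, isolating the areal-mass
  change the analysis is meant to measure.
* **Uptake truth**: 18% mass gain at 0% cholesterol declining linearly to
  20% of that value at the 35 mol % breakpoint, flat beyond.
* **Anchoring truth**: ΔG(c) = 2.0 + (2/3)·c kJ/mol — the exact line
  through barriers of 12, 21 and 32 kJ/mol at 15, 30 and 45 mol % — with
  τ(c) = τ₀ e^(ΔG/k_BT).  τ₀ ≈ 5.35×10⁻³ ns is calibrated so that
  τ(45%) = 2× the 1 μs observation window, i.e. ~0.5 anchored ligands
  expected there.  Run length 5 μs (so a realistic minority of
  high-cholesterol runs are censored).  Note this calibration is a
  *scenario* choice: combined with the steep barrier line it makes
  low-cholesterol waits far shorter than any physical anchoring time.  The
  generator reproduces the study's relations (exponential growth of τ,
  linear barrier, sub-unity anchor counts at high cholesterol), not
  absolute coarse-grained timescales, which are anyway systematically
  underestimated in coarse-grained dynamics.
* **Anisotropy truth**: r(c) = 0.080 + 0.00267·c (≈0.08 for fluid DOPC,
  ≈0.20 at 45 mol %), realized by inverting the G-factor formula at fixed
  total intensity (G = 0.9) and adding σ = 2 a.u. Gaussian noise per
  channel, 3 replicates per condition.

Every generator is a pure function of (config, seed) via
`numpy.random.SeedSequence(seed, stream, condition)`; anchored-ligand
counts use the exact Poisson-process identity count = 1 + Poisson((T −
t₁)/τ) given a first arrival t₁ ≤ T.

What the generators do **not** emulate: vesicle rupture or exchange,
baseline drift and temperature artifacts in QCM-D, non-exponential
(multi-barrier or correlated) anchoring, photobleaching or scattering in
anisotropy, and any coupling between the three data streams beyond the
shared cholesterol axis.  Passing tests therefore demonstrate estimator
correctness and pipeline integrity under the stated noise models, not
robustness to instrument pathologies.

## Parameters that matter most

| parameter | unit | default | why |
|---|---|---|---|
| `slope_tol` | Hz/min | 0.05 | plateau flatness; sets asymptote bias |
| `min_duration` | s | 1800 | plateau evidence window and value window |
| `dd_scale` | — | 10⁸ | ΔD residual weight; conditions the inversion |
| `lipid_mass_fraction` | — | 1.0 | fraction of SVL mass that is lipid; QCM-D vesicle masses are water-dominated, so set deliberately for real data |
| `kbt` | kJ/mol | 2.494 | thermal scale linking τ to barriers |
| `tau0` | ns | 5.35×10⁻³ | attempt-time prefactor; config-supplied, never fitted |
| `run_length` | ns | 5000 | censoring horizon of anchoring trials |

## Known limitations

* The thin-film truncation omits the full Voinova bulk-film interaction
  terms; inversions of films approaching δ/2 inherit that bias.
* ρ and L are reported individually for continuity with common practice
  but are meaningful only jointly (see the degeneracy above); trust the
  areal mass and the flag.
* The lipid/NP conversion depends linearly on `lipid_mass_fraction` and on
  the NP molar mass; `estimate_np_molar_mass` is an order-of-magnitude
  helper (gold core + grafted thiol shell), not a characterization
  substitute.
* The segmented trend assumes an exactly flat post-breakpoint regime; a
  shallow decline beyond the breakpoint biases the breakpoint upward.
* Censored MLE CIs use the χ²(2d) approximation under Type-I censoring;
  for heavily censored small samples (d ≤ 3) the interval is rough.
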