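# npuptake

Quantitative analysis of **passive nanoparticle uptake into lipid membranes
with varying cholesterol content**, built around quartz crystal microbalance
with dissipation monitoring (QCM-D).

Small amphiphilic gold nanoparticles (2–5 nm core, mixed
charged/hydrophobic thiol ligands such as 70:30 MUS:OT) can spontaneously
and non-disruptively embed into fluid phosphocholine bilayers.  Membrane
cholesterol stiffens and packs the bilayer, raising the free-energy barrier
for the key "anchoring" step — the translocation of a charged ligand
terminal across the bilayer core — and thereby suppressing uptake.  This
package implements the full analysis chain such a study needs:

1. **QCM-D forward models** (`npuptake.qcm`): the Sauerbrey rigid-film
   relation and a single-layer Voigt (Voinova) viscoelastic model giving
   per-overtone frequency (Δf) and dissipation (ΔD) shifts of a film of
   density ρ, thickness L, viscosity η and shear modulus μ under bulk
   liquid,

   Δfₙ = −(1/2πρ_q h_q) [ Lρω − 2L(η_b/δ)² ηω²/(μ² + ω²η²) ],
   ΔDₙ = (1/πnf₀ρ_q h_q) · 2L(η_b/δ)² μω/(μ² + ω²η²),

   with ω = 2πnf₀ and δ the viscous penetration depth.
2. **Inversion** (`npuptake.inversion`): trace smoothing, robust terminal
   plateau detection, and bounded weighted least-squares fitting of the
   Voigt parameters to multi-overtone plateaus, reporting the areal mass
   ρ·L as the robustly identifiable quantity (the thin-film model is
   exactly invariant under (ρ, L, η, μ) → (cρ, L/c, η/c, μ/c), so ρ and L
   separately are flagged when ill-determined).
3. **Uptake quantification** (`npuptake.uptake`): percent mass change
   100·m_NP/m_SVL of the supported vesicle layer (SVL), lipid-per-NP count
   ratios, and a segmented linear-decline-then-flat trend with a
   grid-searched breakpoint in cholesterol mole percent.
4. **Anchoring kinetics** (`npuptake.kinetics`): right-censored exponential
   maximum likelihood and cumulative-distribution fits of first-anchoring
   waiting times τ, Poisson expected anchor counts per observation window,
   ordinary-least-squares barrier-vs-cholesterol trends, and an Arrhenius
   consistency check ln(τᵢ/τⱼ) ≈ (ΔGᵢ − ΔGⱼ)/k_BT linking simulation waiting
   times to metadynamics barriers.
5. **Membrane-order probes** (`npuptake.anisotropy`): G-factor-corrected
   DPH fluorescence anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) and its
   linear trend with cholesterol.
6. **Synthetic data** (`npuptake.synthetic`): generators for every input —
   full QCM-D experiment traces, anchoring-time tables, polarized-intensity
   quadruples — with known ground truth and bit-reproducible seeding, so
   the whole chain is testable without instruments or simulations.

## Worked example

Run the bundled synthetic study (cholesterol at 0/15/30/45 mol %, 12
anchoring trials per condition) from the command line:

```bash
npuptake --seed 1 --out demo run-study
```

This writes `demo/study_report.json`. Highlights from that report:

| chol (mol %) | m_SVL (ng/cm²) | uptake % (Voigt) | uptake % (√n-Sauerbrey) | normalized uptake % | τ_anchor (ns) | N_anchors (1 μs) |
|---:|---:|---:|---:|---:|---:|---:|
| 0  | 1142.6 | 18.02 | 20.33 | 100.0 | 0.01 | 83661 |
| 15 | 1183.0 | 11.83 | 13.18 | 65.6 | 0.51 | 1517 |
| 30 | 1224.2 | 5.65  | 6.25  | 31.3 | 31.2 | 27.9 |
| 45 | 1263.3 | 3.70  | 3.95  | 20.5 | 1366 | 0.67 |

Reading the numbers: the SVL areal mass (ρ·L from the Voigt inversion)
rises mildly with cholesterol, while the nanoparticle mass gain falls
steeply — the segmented trend fit places the breakpoint at 35 mol %, after
which uptake flattens near 20% of the cholesterol-free reference.  The two
mass models (viscoelastic inversion vs √n-normalized Sauerbrey) agree on
the uptake efficiencies to within ~13%.  Anchoring times grow exponentially
with cholesterol: the fitted ln τ-vs-cholesterol slope is 0.264 per mol %
against 0.267 = b/k_BT expected from the linear barrier ground truth
(slope b = 0.667 kJ/mol per mol %, the line through barriers of 12, 21 and
32 kJ/mol at 15, 30 and 45 mol %), and the pairwise Arrhenius consistency
check passes.  The expected anchor count in a 1 μs window drops to ~0.5 at
45 mol % (τ = 2× window by scenario calibration).  DPH anisotropy rises
linearly from r ≈ 0.079 with slope 2.7×10⁻³ per mol %.

The same analyses are available as subcommands on real exported data:
`simulate-qcm`, `simulate-anchoring`, `simulate-anisotropy`, `fit-svl`,
`quantify-uptake`, `fit-anchoring`, `anisotropy`, `run-study` (see
`npuptake --help`), or directly as library functions.

## Layout

```
src/npuptake/
  qcm.py         forward models (Voigt, Sauerbrey, overtone normalization)
  inversion.py   smoothing, plateau detection, Voigt layer fitting
  uptake.py      uptake percent, lipid/NP ratios, segmented trend
  kinetics.py    censored-exponential tau, barrier fits, Arrhenius checks
  anisotropy.py  polarized intensities, anisotropy, linear trends
  synthetic.py   ground-truth study generators
  io.py          delimited-table readers/writers, JSON serialization
  pipeline.py    end-to-end study driver with run manifest
  cli.py         click-based command line
docs/methods.md  model assumptions, parameter choices, limitations
```
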