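# Methods

## Signal model and the segmented fit

A voxel's normalized diffusion signal across b-values is modelled as the
two-compartment bi-exponential

    s(b) = f·e^(−D*·b) + (1−f)·e^(−D·b),

with the fast (pseudo-diffusion) compartment attributed to capillary blood.
The acquisition scheme is 10 b-values, 0–1000 s/mm² in steps of ~111, with
three orthogonal directions combined by geometric mean (arithmetic mean of
log-signal, the trace-weighted convention).  The geometric mean makes
combining before or after b=0 normalization equivalent for ideal signals,
which is why that convention was chosen over the arithmetic mean — the
acquisition itself does not dictate one.

The fit is segmented because D* ≫ D: above a boundary b (default
222 s/mm², read strictly, so the high subset is {333,…,1000}) the perfusion
term is nearly dead and ln s(b) is fit linearly for D (slope) and f
(intercept, ln(1−f)); below the boundary the mono-exponential prediction is
subtracted and f·e^(−D*·b) is fit to the residual by bounded one-parameter
least squares on the signal (not its log — residuals can be near zero or
negative under noise), with D* searched in [D, D*max].  The search uses a
64-point log-spaced grid to localize the global minimum followed by
golden-section refinement to machine precision; a multistart grid is needed
because the residual objective can be multimodal for noisy curves.

The one-pass segmented estimate carries a deterministic bias: at b = 333
the perfusion term of a slow compartment (D* ≈ 0.008 mm²/s) still retains
~7% of its amplitude, which leaks into the step-1 slope and intercept and
propagates into D* errors of up to ~15%.  The composed voxel/volume fit
therefore alternates the two steps (default 15 iterations): subtract the
current perfusion estimate from the high-b signal, refit (D, f), refit D*.
The truth is a fixed point of this alternation and convergence is linear;
at infinite SNR all phantom classes recover to ≤0.1%.  Setting
`n_iterations=0` restores the strict one-pass behavior, and the
segment-level functions are always one-pass.

Voxel hygiene: voxels with non-positive high-b signal are unfittable and
flagged; f ≤ 10⁻³ means no perfusion compartment (D* undefined, WTT and
qCBF are zero); fitted D* at/above 0.10 mm²/s marks a misfit and excludes
the voxel from all downstream quantification.  Clamps are f ∈ [0,1],
D ∈ [0, 0.01], D* ∈ [D, 0.10] mm²/s (all configurable); the D ceiling is
about 3× free-water diffusivity, the D* ceiling is the historical exclusion
threshold.  The sum of squared residuals is computed on the normalized
signal over all 10 b-values.

Whether step 2 should refit f jointly with D* is ambiguous in the two-step
tradition; both readings are supported (`refit_f`), defaulting to keeping
the step-1 intercept.

## Water transport time and qCBF

The fast compartment is modelled as an instantaneous impulse of water at
the voxel centre spreading by isotropic Gaussian diffusion with coefficient
D*.  The water transport time is the time at which half the water has left
a sphere of radius 0.5 mm.  Writing s = 4·D*·WTT, the mass inside radius R
of the normalized 3D Gaussian (density ∝ e^(−r²/s)) is

    F(R, s) = erf(R/√s) − (2R/√(πs))·e^(−R²/s),

implemented both in closed form and by adaptive radial quadrature (they
agree to 1e-9; each can serve as the other's cross-check).  Solving
F(0.5, s) = 0.5 by bracketed Brent iteration gives s = 0.21133…, and the
published chain rounds stagewise: s → 0.21, σ = √(s/2) → 0.32 mm.  The
check value F(0.5, 0.21) = 0.502810 is reproduced by the exact error
function.  Then

    WTT = σ²/(2·D*)   [s],
    qCBF = f·D* · 2·fw/(ρ·σ²)·100·60 = f·D* · 92,578.125 ≈ f·D* · 93,000,

with fw = 0.79 and ρ = 1.0 g/mL.  Two deliberate documentation points:

- The rounding chain matters.  Carrying the unrounded root through gives
  σ = 0.3251 mm and a constant of ≈89,718 — about 3% lower.  The module
  computes both chains (`appendix_chain(rounded=...)`) and defaults the
  maps to σ = 0.32 for comparability with the published ≈93,000 factor.
- ρ = 1.0 g/mL is what the ≈93,000 arithmetic uses; the tissue-density
  value 1.04 g/mL is available by configuration (constant ≈89,017) and the
  discrepancy is documented rather than silently resolved.

A quartic-denominator rational approximation of erf (coefficients 0.278393,
0.230389, 0.000972, 0.078108; max error ≤5e-4 on x ≥ 0) is retained as a
validated alternative for reproducing the derivation's printed digits; the
production root-solve uses the exact special function.  Voxels with
D* ≤ 1e-5 mm²/s would map to unphysically long transport times; they are
assigned WTT = 0, flagged, and excluded from statistics rather than being
imputed.

The capillary-geometry alternative uses the classical network model: mean
blood speed v = 6·D*/l with segment length l = 0.11 mm, transit L/v over
total path L = 2 mm, water fraction 0.65 and density 1.047 g/mL, giving a
conversion of ≈101,589 — a fixed 1.097× the WTT constant, since both are
proportional to f·D*.  The exact functional form used in published
capillary comparisons is not always printed; this reconstruction is the
standard one and the coefficient is fully exposed in configuration.

## CSF suppression simulation

Inversion-recovery spin echo with a perfect 180° pulse:
S = |1 − 2e^(−TI/T1) + e^(−TR/T1)|·e^(−TE/T2), normalized to equilibrium.
The CSF null is the closed form TI = T1·ln(2/(1+e^(−TR/T1))).  Residual
fractions are reported relative to a spin echo *without* inversion at the
same TR (longitudinal factor 1 − e^(−TR/T1)); the T1-only penalty and the
echo-time factor e^(−TE/T2) are reported separately and multiply exactly.
The reference deliberately excludes the echo-time decay so that "T1+T2
combined" is meaningful — a TE-matched reference would cancel the T2 term.

Default constants are representative 3 T literature values — CSF T1/T2 =
4500/2000 ms, blood T1/T2 = 1650/60 ms — giving a null TI of ≈1839 ms and a
combined blood residual of ≈22% at TR/TE = 5000/37 ms.  Published
suppression figures depend on the exact relaxation constants assumed, which
are often not printed; these defaults are therefore bracketing values
(tests assert the 0.10–0.30 residual band and the 1700–2000 ms null
window), not digit-exact targets, and all constants are overridable.

## Infarct volumetry

Plain thresholding: a voxel is infarct when its diffusion coefficient is
strictly below the cutoff — 5.15e-4 mm²/s on the IVIM D map, 5.7e-4 mm²/s
on mean diffusivity (per-direction ADC = −ln(S_b/S_0)/b averaged
arithmetically).  Strict inequality is a choice (boundary voxels excluded);
connected-component filtering exists but defaults off since the volumetry
is defined as plain thresholding.  Volume is voxel count × voxel volume.

## The digital phantom

Tissue classes with piecewise-constant (f, D, D*, T2, S0): white matter
(0.02, 7e-4, 0.008), gray matter (0.05, 8e-4, 0.012), CSF (f=0, D=3e-3,
T2=2000 ms), infarct core (0.01, 4.5e-4, 0.008) and a hyperperfused rim
(0.08, 8e-4, 0.03) in one hemisphere, laid out as nested boxes on a
32×32×8 grid of 2 mm voxels.  Signal is the S0-weighted mixture of class
bi-exponentials, identical across three directions before noise (isotropy);
noise is Rician — the magnitude of a complex Gaussian perturbation with
σ = S̄0/SNR, SNR defined at b=0 against the mean in-brain S0.  A
partial-volume band (default 1 voxel; class indicators box-filtered)
creates mixed voxels at class boundaries, reproducing the
multi-exponential contamination that CSF borders cause in real data.

What the phantom does not emulate: anatomy, T2-weighted signal formation
(T2 enters only as a truth map for masking), motion/eddy artifacts,
direction-dependent diffusion, spatially varying noise.  Passing tests
therefore demonstrate correctness of the estimation chain under the model's
own assumptions, not robustness to everything an MRI scanner produces.

Two scale choices made deliberately: exact-equality volumetry claims
(IVIM-D vs MD vs constructed core) are tested on sharp (band = 0) phantoms,
because with a mixing band the two thresholds cut the boundary voxels'
intermediate diffusivities at different fractions and exact equality is not
defined; and ROI agreement studies restrict to pure voxels plus a T2 < 300 ms
cutoff — the phantom analogue of the in-vivo protocol of avoiding brain
edges and ventricles — since a mixed voxel has no well-defined single-voxel
reference perfusion.

## Agreement statistics

Lin's concordance correlation coefficient uses population (1/n) moments —
the original definition — with a Fisher-z confidence interval using Lin's
asymptotic variance.  Bland–Altman limits are mean ± 1.96·sd of the paired
differences (sample sd); limits from n < 3 are flagged unstable.
Regression is ordinary least squares with R² the squared Pearson
correlation.  The leave-one-out T2 cutoff scans midpoints of adjacent
sorted samples, scores 0/1 classification accuracy (for a fixed candidate
cut, leave-one-out accuracy equals plain accuracy), breaks ties toward the
higher threshold (more conservative CSF removal), and flags the result
unreliable when no cut beats chance.  Mixed-effects models and signed-rank
tests on study tables are routine statistics best called directly from
scipy/statsmodels and are not re-implemented here.

## Problem sizes and determinism

Tests and examples run the 32×32×8 phantom (≈5400 brain voxels, ~1.5 s per
volume fit), SNR sweeps at {25, 50, 100, ∞}, six-state agreement studies at
SNR = 100, and a 10⁶-point erf-error grid; the whole suite completes in
well under a minute.  Every stochastic step takes an explicit seed
(`numpy.random.default_rng`), and a fixed seed reproduces phantom data
bit-exactly.

## Known limitations

- The two-step fit assumes the boundary cleanly separates regimes; tissues
  with D* ≲ 3·D converge slowly in the alternation and retain residual bias.
- qCBF inherits D* misfit error multiplicatively; the D* ≥ 0.10 exclusion
  and the WTT floor bound, but do not remove, this sensitivity.
- The WTT derivation assumes randomly oriented, isotropic capillary flow
  dominating the anisotropic signal; organs with strongly oriented
  microvasculature violate it.
- The capillary comparison model is a reconstruction from the classical
  constants, not a pinned published pipeline.
- Rician noise is simulated per-frame i.i.d.; parallel-imaging noise
  correlation is not modelled.
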