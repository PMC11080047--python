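# Methods

This note records the models, numerical choices and design decisions
behind `glasspharm`, and what the synthetic-data round trips do and do
not demonstrate.

## Dielectric forward models

The loss of one relaxation process is the imaginary part of the
Havriliak–Negami function, evaluated through the real closed form
(modulus/phase of 1 + (iωτ)^a) rather than complex arithmetic; the two
agree to machine precision and the closed form is cheaper inside
optimisation loops. Only the loss is modelled: ε∞ does not contribute to
ε″ and is carried as fit metadata. The DC term is σ_dc/(ε0·ω^s) with the
ohmic exponent s = 1 by default (overridable); conductivity exponents
are rarely resolvable on synthetic-quality data and the study conditions
do not constrain them.

The HN peak-time conversion τ_max(τ_HN, a, b) uses the standard
two-sine-factor formula; it is validated in the test suite against
brute-force peak location (dense log-grid search plus parabolic
refinement) to 0.5 % over (a, b) ∈ (0.3, 1]², and reduces exactly to
τ_HN at b = 1.

**KWW frequency-domain shape.** ε″(ω) = Δε·ω·∫₀^∞ φ(t) cos(ωt) dt with
φ(t) = exp[−(t/τ)^β] (the boundary terms of the partial integration
vanish). The integral is evaluated per frequency with QUADPACK's
cosine-weighted adaptive Clenshaw–Curtis quadrature on [0, t_cut],
t_cut = τ·(ln 1/ε_tail)^{1/β} with ε_tail = 10⁻¹⁸, relative tolerance
10⁻¹⁰. This was chosen over a fixed Filon-type log-grid scheme because
the adaptive routine keeps full relative accuracy in the far peak
flanks, where piecewise-linear interpolants lose precision to
oscillatory cancellation; a hand-written Filon transform is kept in the
test suite as the independent cross-check (agreement 10⁻⁴ near the
peak), and the β = 1 limit matches the Debye closed form to better than
10⁻⁶. Quadrature failure raises with diagnostics rather than returning
a value. During shape fits the transform is evaluated on a 10
points-per-decade grid and interpolated with a cubic spline in log f —
the loss is smooth on that axis and the interpolation error is far below
the fit residuals.

## Spectral deconvolution

Fits minimise uniform-weight least squares on log10 ε″ (points with
ε″ ≤ 0 are masked); Δε, τ and σ_dc are optimised in log10, the shape
exponents linearly in (0, 1]. Log-residuals weight the decades of a
loss spectrum evenly, which is what a practitioner's by-eye fit
effectively does. Starts are deterministic and data-driven: peak
positions of the smoothed log-spectrum assigned to the planned processes
slow-to-fast, τ₀ = 1/(2πf_peak), Δε₀ = 2 × peak height, a = b = 0.8.
The number and kind of processes is explicit user configuration (a
`FitPlan`); there is no automatic model selection, mirroring manual
practice. Non-convergence is flagged on the result, never silent.

In the orchestrated pipeline, glassy isotherms are fitted with two CC
processes. A fitted component whose peak lies more than half a decade
outside the frequency window, or whose strength is below 5 % of the
strongest component, is discarded as unconstrained; near-duplicate
components (peaks within two decades) are merged. Because at most one
secondary peak is usually in view at a time, surviving points are
assigned to the β/γ branches either by rank within isotherms that show
both peaks or by two-line clustering of log10 τ versus 1/T, with the
steeper branch labelled β. Above Tg the β/γ contributions are pinned to
their glassy-state Arrhenius extrapolations with only Δε free — they are
barely visible under the α-peak and would otherwise destabilise its
shape. An α component whose peak sits within half a decade of the
window edge is dropped as unresolvable.

Δε normalisation uses Δε_N(T) = Δε(T)/Δε(T_ref) with T_ref = 312 K,
interpolating linearly when T_ref is not a grid point. The
recrystallization-onset detector references the median of the
pre-drop points as the plateau and reports the linearly interpolated
first persistent crossing of (1 − threshold)·plateau, threshold 0.05 by
default (no quantitative criterion for the "drop" exists in the source
analyses; 5 % of plateau is comfortably above the synthetic noise and
far below the smallest drop of interest). With the generator's sigmoid
of width 1 K this construction crosses ≈ 0.6 K below the nominal onset
parameter — a property of any threshold detector on a smooth drop, left
uncorrected and documented.

## Masterplot and KWW fit

Superposition uses peak-maximum alignment: each spectrum's maximum is
located by a parabola through the five points around the discrete
maximum in log f, shifted onto the reference peak, and normalised to
unit peak height — deterministic, and exactly shape-preserving because
only horizontal shifts are applied. Spectra whose maximum sits at the
window edge are excluded with a warning. In the KWW fit the flank more
than two decades above the peak gets weight 0.25 (configurable): in
composite spectra that flank carries the β-process contribution, which
the one-process KWW shape should not chase. Fits to individual spectra
(`fit_kww_spectrum`) and to merged master curves (`fit_kww`) share the
same machinery.

## Relaxation map

The VFT law is parameterised τ = τ∞·exp(D/(T−T0)) with D in kelvin (not
the dimensionless strength D′ = D/T0); with the reference parameter
triple (log10 τ∞ = −15.73, T0 = 248.0 K, D = 2257 K) this
parameterisation reproduces the published Tg = 303 K at τ = 100 s, which
fixes the reading. The printed "log10 τ∞ = 15.73" is taken with a
negative sign: a pre-exponential of 10^15.73 s is unphysical and
inconsistent with that same Tg. VFT fitting grid-searches T0 (the
model is linear in the other two parameters at fixed T0) before bounded
least-squares refinement with T0 below the coldest data point;
asymptotic standard errors come from the Jacobian. Tg and m_p are
closed-form; the fragility expression is verified against a central
finite difference of log10 τ versus Tg/T in the tests.

Evaluating the closed form at the reference triple gives m_p ≈ 97.3.
The source analysis quotes m_p = 91 for the same parameters — a value
inconsistent with its own printed triple under any reading we found
(it may derive from unrounded fit values or the calorimetric Tg). The
package reports the closed-form value; 91 is not used as an oracle.

Coupling-model classification compares the secondary process's
Arrhenius extrapolation with τ_0(T) = t_c^n·τ_α^β over the α-point
temperatures above Tg (the liquid measurement grid by default),
declaring JG when the mean offset is within 1 decade. Both the grid and
the tolerance matter: the reference β-parameters sit ~1.3 decades from
the coupling prediction just above Tg and drift further by 342 K, so on
the full grid the default-scenario β comes out non-JG while visual
continuation near Tg would call it JG. The classification of
*constructed* agreement/disagreement cases is what the tests pin down;
the tolerance is configurable and the per-temperature offsets are
returned for inspection.

## DSC analysis

Heat flow is exothermic-positive internally; readers normalise via the
file's `exo_up` metadata. ΔCp = baseline separation at the midpoint
divided by the heating rate in K/s. Baselines are linear fits to the
leading/trailing 25 % of the analysis window; the midpoint temperature
is the root of a local linear fit through the central part of the step
(|deviation| ≤ 25 % of the separation), which is exact for a clean
sigmoid and unbiased under noise, unlike a first-crossing rule.
Derivative-based constructions (steepest tangent for Tg onset and
exotherm onset) smooth with a ~1 K Savitzky–Golay window first.
The melting multiplet is fitted as n Gaussians over a linear baseline;
amplitudes are constrained to the dominant sign of the
baseline-corrected window (melting components are all endothermic), and
missing initial centres are seeded by splitting the most prominent
extremum — overlapping components merge into a single discrete maximum,
and this deterministic seeding separates them reliably. Onsets of
overlapping peaks are computed per deconvolved component via the
Gaussian closed form center − 2σ, not on the raw curve. Collapse
(σ → 0) or non-convergence raises.

## Stability analyses

ΔCp values enter the MLC fit per total sample mass (the additivity
argument: immobilised molecules contribute nothing, so ΔCp scales with
the mobile amorphous mass fraction); the zero-crossing −intercept/slope
carries a standard error from full error propagation including the
slope–intercept covariance. Tc(w) is fitted as a continuous two-segment
line over a 0.1 wt % breakpoint grid; monotone data put the breakpoint
at a boundary and are flagged. Polymorph labels come from matching
component tangent onsets to reference windows (IV 406–409, III 410–414,
II 414–417, I 420–423 K, ±0.7 K tolerance, nearest-midpoint
tie-breaking); anything else is the undefined form "X".

## Synthetic data

The BDS generator composes the forward models under the study
conditions: VFT α (reference triple above), Arrhenius β
(−17.57, 80.4 kJ/mol) and γ (−12.39, 23.8 kJ/mol), temperature grids
153–308 K in 5 K and 310–342 K in 2 K steps, frequencies 10⁻¹–10⁶ Hz at
8 points/decade. β_KWW falls linearly from 0.55 (pure drug) to 0.40
(50 wt % silica); the α HN shape is derived from it through the
interconversion ab ≈ β_KWW^1.23 with b = 0.55 held, or the α-peak can be
generated directly from the KWW transform. Δε scales with the drug mass
fraction and is held flat in T below the recrystallization onset;
above the onset (333/327/325/337 K at 10/20/30/40 wt %, none at 0 or
50 wt %) it drops along a logistic of width δ = 1 K centred at
onset + 2δ to a residual amorphous fraction 0.2 + 0.01·(w − 10) that
grows with loading. DC conductivity is slaved to structural mobility,
σ(T) = 10⁻¹² S/m · τ_α(312 K)/τ_α(T). Noise is multiplicative
log-normal on ε″ (relative SD 0.02 by default).

The DSC generator uses Tg = 307 K (logistic step of width 2 K, ΔCp
falling linearly from 0.35 J g⁻¹ K⁻¹ to zero at the 65 wt % MLC), a
Gaussian exotherm of σ = 4 K whose tangent onset follows the V-shaped
Tc(w) (357 K pure, vertex at 27.3 wt %, slopes −1.1/+1.0 K per wt % —
the slopes are a generator choice; only the end points and vertex are
anchored), and four Gaussian melting endotherms whose tangent onsets
sit at 406, 410, 414, 421 K with widths 1.00/1.75/1.05/1.25 K taken
from the reference onset–peak pairs via σ = (peak − onset)/2. Melting
weights default to the III-dominant pattern (0.25/0.50/0.15/0.10).
Absolute Δε (4) and ΔCp (0.35 J g⁻¹ K⁻¹) anchor scales only; no test
depends on their absolute values. Heat-flow noise is additive Gaussian,
SD = 0.5 % of the exotherm amplitude. All generators take explicit
seeds (default 42) and are bit-reproducible.

**What the round trips show — and don't.** Passing recovery tests
demonstrate that the estimators are unbiased and precise when the data
actually follow the assumed model with well-separated processes and the
stated noise. Real spectra add electrode polarization,
Maxwell–Wagner–Sillars interfacial contributions in composites,
temperature-dependent Δε, non-Gaussian peak shapes in DSC and baseline
curvature — none of which the generators emulate, so real-data accuracy
will be limited by model mismatch rather than by the numerics tested
here.

## Problem sizes

Default runs deconvolve 49 isotherms per composition (32 glassy, 17
liquid) of 57 frequency points each, fit master curves of ~700 merged
points, and analyse DSC traces of ~1 500 points; the acceptance script
uses exactly these sizes and completes in well under a minute on one
core.

## Known limitations

* The pipeline's automatic β/γ branch assignment assumes the standard
  window geometry (γ visible cold, β visible warm); exotic windows need
  explicit fit plans.
* The KWW/HN shape interconversion is the usual approximate empirical
  relation; the masterplot fit of HN-generated spectra therefore
  recovers an *effective* β_KWW (≈ 0.52 for the 0.55-targeted default),
  not the exponent that parameterised the generator — only fits of
  KWW-generated peaks are expected to round-trip exactly.
* Fragility and Tg inherit the VFT extrapolation's assumptions; no
  alternative Tg conventions (e.g. τ = 1000 s) are provided.
* Tangent onsets are exact only for Gaussian components; strongly
  asymmetric melting peaks would need a different peak model.
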