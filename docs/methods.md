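# Methods

## Model and assumptions

Each XH bond is treated as an isolated one-dimensional Morse oscillator in
the bond-stretch coordinate z (ångström, positive = elongation).  The
model deliberately ignores interbond coupling, combination bands, and
Fermi/Darling–Dennison resonances: it predicts exactly one transition per
bond per Δν region.  This is the regime where CH-stretching overtones
(Δν = 3 especially) are well described by local modes; for fundamentals
and Δν = 2 the normal-mode picture can still contribute structure the
model cannot produce.

Energies follow the Birge–Sponer ladder ν̃(0→n) = nω₀ − n(n+1)χ, the
exact eigenvalue-difference law of the Morse well.  With χ > 0 the ladder
compresses; the well supports ⌊ω₀/2χ − ½⌋ + 1 bound levels (≈ 25 for CH),
and the package refuses transitions beyond the last bound state.

Intensities follow from per-atom response tensors contracted with
transition integrals of z-powers (electric, via the atomic polar tensor)
and of z-powers times the conjugate momentum p (magnetic, via the atomic
axial tensor), each Taylor-expanded to second order in z.  The 1/k!
factors of the expansion belong to the moment assembly; `TensorExpansion`
stores raw derivatives.  Atom displacements are t_α·z with
t_H − t_heavy = 1 and mass-weighted sum zero, which keeps the centre of
mass fixed during the stretch.

## Transition integrals: closed forms and oracle

The Morse eigenfunctions in y = 2λe^{−αz} (λ = ω₀/2χ) are
N_v y^{λ−v−½} e^{−y/2} L_v^{(2λ−2v−1)}(y).  Matrix elements of zᵏ reduce,
via z = (ln 2λ − ln y)/α and term-by-term Laguerre expansion, to moments
∫y^{β−1}e^{−y}(ln 2λ − ln y)ᵏ dy = Γ(β)·G_k(β), where G_k involves the
digamma/trigamma/tetragamma functions of β = 2λ − v − 1 + j.  Momentum
elements use dL_v^{(s)}/dy = −L_{v−1}^{(s+1)} and reduce to the same
moment family.  These are *exact* closed forms for all eighteen
⟨0|zᵏ|v⟩, ⟨0|zᵏp|v⟩ with k ≤ 3, v ≤ 3 — no perturbative truncation in
χ/ω₀ — and they tend to the textbook harmonic ladder-operator values as
χ/ω₀ → 0 (first order in χ/ω₀, verified per decade in the tests).

The independent arbiter is a sinc-DVR (Colbert–Miller) grid
diagonalization of the same well: kinetic matrix exact in the sinc basis,
Morse potential on the diagonal, matrix elements by grid quadrature, and
an analytic sinc first-derivative matrix for p.  Defaults: 1201 points on
z ∈ [−1, +3] Å, which covers the v ≤ 3 classical turning points of CH-like
wells with wide margin; a grid-doubling convergence check is available
(shift > 10⁻⁶ relative raises an error).  The test suite requires
closed-form/oracle agreement within 0.5% (absolute floor 10⁻⁶ dᵏ) over
χ/ω₀ ∈ [0.005, 0.025]; in practice agreement is ~10⁻¹⁰.

Numerical care: near the harmonic limit the closed-form sums cancel by
factors of order λ, so they are evaluated in extended precision with
Pochhammer products for Γ ratios and asymptotic (Bernoulli-series)
digamma/trigamma/tetragamma for β ≥ 30; below that threshold scipy's
float64 special functions are used directly (deep wells have no
cancellation problem).

Phase convention: real eigenfunctions with the outermost lobe (largest z)
positive, in both the analytic forms and the DVR (sign fixed on the
rightmost extremum).  Position integrals are then real, momentum
integrals purely imaginary; rotational strengths are computed as
R = Im(μ·m*) and are reproducible to machine precision.

## Units and constants

Internal units: cm⁻¹, Å, u, elementary charge e; momentum integrals carry
ħ/Å.  All cgs conversions live in `constants.py`.  The characteristic
length is d = √(ħ/(2 m_R c ω̃₀)) in electrostatic cgs (ω̃₀ in cm⁻¹),
≈ 0.192 Å for a CH oscillator at 3100 cm⁻¹ — the convention consistent
with "about 0.2 Å"; the plain harmonic length √(ħ/mω) would give 0.11 Å.
Dipole strengths convert via (e·Å)² → 10⁻⁴⁰ esu²cm²; the AAT is carried
as an opaque tagged unit (e·Å²/ħ at order zero) chosen so that A·⟨p⟩
lands in e·Å like the electric moment — only products of defined
combinations enter observables, and the scaling constant is exposed in
`constants.py` rather than buried in formulas.

Spectral synthesis uses the cgs integrated-absorption relation
∫(ε/ν̃)dν̃ = [8π³N_A/(3000 h c ln10)]·D ≈ 1.087×10³⁸·D, and the same
constant against 4R for Δε, so a band-level Δε/ε of an isolated line
equals its g = 4R/D.  Each line contributes an **HWHM**-parameterized
(not FWHM) area-normalized Lorentzian scaled by ν̃₀·D; region defaults
are 7 (mid-IR), 10 (fundamental), 15 (Δν=2), 40 (Δν=3) and
30 cm⁻¹ (stretch–bend combination region).  Area identities are exact on
a sufficiently wide grid; the default plotting grid (lines ± 10 HWHM,
step HWHM/10) captures ~94% of each Lorentzian's area, and a grid that
truncates a line emits a warning quoting the lost fraction.

## Fitting

*Morse wells* are fit to energy scans E(z) = E₀ + D(1−e^{−α(z−z₀)})² by
bounded nonlinear least squares, initialized from a parabola through the
three lowest points (α₀ = √(f/2D₀)).  A finite depth ceiling (5×10⁶ cm⁻¹)
keeps the optimizer out of the flat harmonic valley (D→∞, α→0 at fixed
curvature); hitting it — or a propagated χ standard error above 50%, or
χ < 0.5 cm⁻¹ — marks the anharmonicity as *ill-determined*, which is what
a narrow, effectively harmonic scan deserves rather than a spurious χ.
The fitted (D, α) convert to (ω₀, χ) exactly.

*Tensor profiles* are fit per component by ordinary polynomial least
squares (default order 2, matching the model's truncation), with
coefficients rescaled by k! so stored values are derivatives; residual
RMS is reported per column.  Rank-deficient designs (fewer distinct
displacements than order+1) raise immediately.

Default scan designs (also used by the synthetic generator): 11 energy
points on [−0.3, +0.6] Å — asymmetric to sample the anharmonic tail — and
9 tensor points on ±0.2 Å.  Noise propagation note: at 1% profile noise
this design determines tensor values and slopes to a few percent, but the
*curvature* standard error is ~7–10% of a CH-typical second derivative;
tests therefore bound order-2 recovery by the propagated 4σ error rather
than pretending the design is more informative than it is.

## Synthetic fixtures

The generator emulates the study inputs: Morse wells drawn uniformly from
the printed CH envelope (ω₀ ∈ [3060, 3185], χ ∈ [59, 63] cm⁻¹, masses
12 and 1 u), exact-quadratic tensor profiles with APT magnitudes (tenths
of e) giving CH-typical dipole strengths of order 10⁻³⁹ esu²cm², and AAT
magnitudes set so dissymmetry ratios land in the 10⁻⁴–10⁻³ range observed
for CH stretches.  Gaussian noise (relative to the local energy value for
scans, to the profile spread for tensors) is applied only after the truth
record is frozen; a single seeded `default_rng` threads all randomness,
and identical seeds reproduce identical tables bit for bit.

What the generator does **not** emulate: correlated electronic-structure
errors along a scan, basis-set or functional bias in tensor profiles,
combination-band leakage, resonance mixing, or solvent shifts.  Passing
parameter-recovery tests therefore demonstrates the estimators are
correct and well-conditioned under the stated noise model, not that the
physical tensors of a real molecule are recoverable to the same accuracy.

The printed two-molecule parameter sets ship with fixed placeholder
directions (tetrahedral-ish unit vectors) and, on request,
arbitrary-but-fixed placeholder tensors, because the published tensor
scans exist only as figures; wavenumber-level results never depend on
these placeholders, and intensity-level tests use synthetic bonds with
known truth instead.

## Design choices

* **Band grouping** uses single-linkage clustering on line positions with
  a 50 cm⁻¹ gap threshold.  With the printed parameter sets this yields
  two Δν = 3 clusters for methyloxirane and four for methylthiirane — the
  predicted band counts; any threshold in (41, 63.5) cm⁻¹ gives the same
  answer, while substantially smaller gaps would split bands that the
  40 cm⁻¹ Lorentzians merge.
* **χ sign convention**: χ > 0 compresses the ladder; the harmonic limit
  is χ → 0⁺ and χ/ω₀ ≥ ½ is rejected.
* **Operator ordering**: momentum acts on the right (⟨0|zᵏ p|v⟩); the
  convention is fixed jointly with the phase convention above.
* **Mirror images**: reflecting a bond reflects its direction and APT
  vectors as polar vectors and its AAT vectors as axial vectors (extra
  sign), which negates every R and Δε and preserves every D and ε — the
  enantiomer relation, tested to machine precision.
* **1-based atom indices** in user-facing labels (C5–H6 …), matching
  conventional structure numbering; XYZ files are read in file order.

## Limitations

States above v = 3 and non-Morse potentials are out of scope; so are
coupled-oscillator (HCAO) Hamiltonians, combination bands, resonance
treatments, rotational structure, Gaussian/Voigt profiles and solvent
modelling.  Per-line g = 4R/D equals a band-level Δε/ε only for isolated
lines; overlapping bands of opposite sign can show any apparent band g.
Absolute intensities inherit the placeholder status of any synthetic
tensors used — only wavenumbers, band counts, relative patterns, and
symmetry behaviour are meaningful in that case.
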