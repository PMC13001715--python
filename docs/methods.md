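# Methods

`cuepr` implements the computational chain used to argue for simultaneous
multi-site Cu²⁺ binding to serum albumin: geometric analysis of the metal
sites in a crystal structure, a forward model from site-occupancy
configurations to pulsed-dipolar distance distributions, CW EPR powder
simulation with spin counting, ESEEM/HYSCORE time-domain processing, and
RIDME trace simulation with regularized inversion. This note records the
models, the parameters that matter, and the numerical choices.

## Structure-derived site geometry

Coordinate files (PDB/mmCIF) are read with gemmi; only the first model is
kept, and for alternate locations the highest-occupancy conformer wins
(ties resolve to altloc `A`). Metal sites are defined as one site per metal
atom, with donors being non-hydrogen N/O/S atoms (protein or water) within
a **donor cutoff of 3.0 Å** — wide enough to cover Cu–N/Cu–O coordination
bonds (1.9–2.3 Å) with thermal scatter, and configurable. Sites are
ordered by their lowest donor residue number and mapped to the canonical
albumin site names (ATCUN = residues 1–3; site B = His9/Asp13; site A =
His67/His246/Asp248; His287/Glu152; His317/Asp211; His509/Glu564) whenever
the donor residues identify one.

Pairwise Cu–Cu distances are Euclidean metal–metal separations converted
to nm (×0.1 exactly). Disulfides are CYS SG–SG pairs within 2.5 Å under
greedy nearest-pair matching, which is exact for well-separated bridges
and deterministic otherwise. Crystallographic contacts use an embedded
operator table (P1, P6₁, P2₁2₁2₁) together with the standard
orthogonalisation convention (**a** along x, **b** in the x–y plane);
minimum image contacts scan all operators × lattice translations in a
±1-cell block, excluding the identity with zero shift. The operator table
is cross-checked against gemmi's space-group tables in the test suite.

## Occupancy configurations → distance distributions

A configuration is a subset (size ≥ 2) of the six sites assumed occupied
simultaneously. Its predicted distance distribution is a Gaussian mixture
with one component per unordered occupied pair, equal amplitudes,
σ = 0.1 nm, means taken from the distance table, renormalized on the
default grid 1–10 nm (step 0.02 nm). Configurations of sizes 2–6 are
enumerated (57 for six sites); both pair-only and larger subsets are
provided because the short-range evidence concerns pairs while the
simulated comparisons use triples.

Configurations are scored against an experimental distribution by the
**overlap coefficient** ∫ min(P₁, P₂) dr restricted to a detectability
window, both densities renormalized within the window; 1 means identical,
0 disjoint. The window defaults to **1.5–8.0 nm**: below ~1.5 nm the
dipolar oscillation is too fast to be sampled after the dead time, and
beyond ~8 nm it exceeds the observable trace length. The overlap score is
symmetric and unit-free; a Wasserstein-based alternative
(exp(−W₁)) is available behind a flag. The score reproduces qualitative
ranking statements only — no amplitude fitting or model selection is
attempted, and equal pair amplitudes are fixed by construction.

## CW EPR powder simulation

The spin system is an effective S = 1/2 coupled to a single I = 3/2 Cu
nucleus with axial g and A tensors (no ⁶³Cu/⁶⁵Cu isotope splitting — one
effective parameter set). Resonance fields use second-order perturbation
theory in the hyperfine coupling with orientation-effective
g(θ) = √(g∥²cos²θ + g⊥²sin²θ) and A(θ) likewise:

    B(m_I) = B₀ − a·m_I − a²[I(I+1) − m_I²]/(2B₀),

with B₀ = hν/(g(θ)μ_B) and a the coupling in field units. The second-order
shift is downward; the test suite checks the formula against exact
diagonalization of the 8×8 spin Hamiltonian (≤0.5 G over the published
ATCUN parameter regime, g∥ = 2.198, A∥ = 607 MHz). Physical constants are
CODATA 2018 values kept in one module.

Powder spectra integrate over orientations by Gauss–Legendre quadrature in
cos θ (axial symmetry ⇒ 1-D integral; default 301 nodes; 256→512 nodes
changes the spectrum by < 0.5% RMS). Stick intensities are shared linearly
between neighbouring field bins, convolved with a Gaussian of the system's
FWHM, and differentiated numerically. No 1/g intensity correction is
applied by default; this affects relative amplitudes only, not the
linearity analyses. A- and g-strain are out of scope.

**Double integration** is the spin-counting step: the derivative trace is
baseline-corrected by the mean of its first/last 2% of points, integrated
to the absorption profile, the absorption corrected by a straight line
anchored on the same edge regions (the signal vanishes there, so any
trend is integration drift — this keeps the double integral stable under
trace noise), then integrated again. Titration analysis is an ordinary
least-squares line of double integral vs. molar equivalents with R²
reported; if the integrals have zero variance R² is reported as 0.

The default acquisition grid mirrors the X-band experiment: ~9.5 GHz,
centre 3100 G, sweep 1600 G, 2667 points.

## ESEEM and HYSCORE processing

Three-pulse ESEEM traces are real-valued echo amplitudes vs. T (phase
correction is assumed upstream of this package). Background removal fits
b(T) = c·exp(−T/τ_d) and returns (data − b)/b, preserving fractional
modulation depths. To stop the decay fit tilting along the nuclear
modulation, the fit target is a centred moving average of the trace
(window = 1/8 of the trace by default) restricted to the interior where
the average is exact; the smoothing gain on an exponential is computed in
closed form and divided out of the fitted amplitude, so a pure exponential
still yields an identically zero output. If the fit fails a log-domain
linear fit is used with a warning.

Spectra are obtained by Hamming window → zero-fill (factor 2 × next power
of two) → FFT → magnitude; axes are MHz (8 ns dwell ⇒ 62.5 MHz Nyquist).
HYSCORE matrices get per-row then per-column 3rd-order polynomial baseline
subtraction, a separable 2-D Hamming window, zero-filled 2-D FFT,
magnitude, folding to the requested quadrant, and symmetrisation
S ← (S + Sᵀ)/2, which is idempotent and makes correlated frequencies
appear at both (ν_a, ν_b) and (ν_b, ν_a).

Blind spots: 3-pulse modulation at nuclear frequency ν is suppressed as
sin²(πντ); the k-th blind spot is τ = k/ν. The synthetic generator applies
the suppression factor per line (the processor itself is τ-agnostic), so
the blind-spot logic is testable end to end: a line generated at its blind
spot loses ≥10× peak amplitude relative to maximal visibility. The default
line list emulates remote imidazole ¹⁴N: quadrupole lines at 0.7/1.4/2.0
MHz plus a broader double-quantum line at 4.0 MHz, with depths of a few
percent on an exponential decay.

## RIDME simulation and inversion

The dipolar trace model is the standard pulsed-dipolar form factor:

    V(t) = [(1 − λ) + λ·(K P)(t)] · exp(−k t^d),

with powder kernel K(t, r) = ∫₀¹ cos(2π ν_dd(r)(1 − 3x²) t) dx and
ν_dd = 52.04 MHz·nm³ / r³ for a g ≈ 2 pair (configurable constant;
Cu²⁺ g-anisotropy is not modelled in the kernel because the experiment
itself averages orientation selection by summing field positions, which
`combine_field_positions` reproduces as a pointwise mean renormalized to
V(0) = 1). The kernel is computed by fixed-order Gauss–Legendre quadrature
(default 401 nodes, chosen so the fastest oscillation on the default grids
is fully resolved; agreement with the Fresnel-integral closed form is
~1e-14, and < 1e-6 against a 10⁵-point Riemann sum). The background is a
stretched exponential with free dimensionality d ∈ (1, 4), fitted jointly
with the signal in product form. Default grids: t up to 2.1 µs (τ₂ = 2.5
µs minus dead time, 8 ns steps), r = 1.5–8 nm at 0.02 nm.

**Inversion** minimises ‖model − V‖² + α²‖L₂P‖² subject to P ≥ 0, where L₂
is the second-difference operator **with Dirichlet boundaries** (P treated
as zero just outside the grid). The boundary choice matters: at the long-r
edge the kernel is nearly constant in t and degenerate with the
background, and an edge-penalising operator prevents probability mass
piling up there. The solver is:

1. initial background from a tail fit (A·exp(−k t^d) on t ≥ 0.4 t_max),
   λ₀ = 1 − A;
2. α selection at that background — GCV by default, brought to standard
   form with L₂⁻¹ so the criterion matches the seminorm actually penalised
   (an L-curve corner search and fixed α are alternatives);
3. refinement of (k, d, λ) by bounded nonlinear least squares with the
   non-negative Tikhonov solve nested inside (variable projection). The
   (k, d) valley is shallow, so three starts are used (tail-fit d plus low
   and high stretch dimensions) and the best converged fit kept. The
   stacked Tikhonov matrix is QR-compressed once per α so each inner NNLS
   solves an equivalent square problem.

The returned P is renormalized to unit integral. Confidence bands are
residual-resampling bootstrap percentiles (2.5/97.5) with refits
warm-started from the point estimate — warm starting is what makes the
band collapse for noiseless data instead of reporting optimizer scatter
from the flat background valley.

Relaxation fits: phase-memory decay as y₀·exp(−(t/Tm)^β) (a constant
trace is rejected as degenerate); inversion recovery as a biexponential
y∞ − a_f·e^(−t/T1f) − a_s·e^(−t/T1s) with single-exponential fallback, and
the recommended RIDME mixing time is 0.7 × the amplitude-weighted mean T1.

## Synthetic data: what it emulates, what it does not

All fixtures are pure functions of (spec, seed).

The **decoy structure** places six Cu ions with 2–4 donor atoms each
(canonical residue names/numbers, bond lengths 2.0–2.3 Å) at coordinates
that realise the anchored distance constraints: ATCUN–siteB 1.8 nm,
ATCUN–His287 3.5 nm, His317 pairs drawn within 4.0–4.9 nm, His509 pairs
within 4.5–7.6 nm; unconstrained pairs are left to the embedder (classical
MDS initialisation + least-squares refinement, constrained residuals
< 1e-6 nm or an error with a residual report). The file is written as P1
with a padded box; symmetry tests use separate hand-built fixtures. The
decoy has no protein backbone, no electron density, and no realistic
packing — it exists so site detection, labelling, distance tabulation and
the downstream dipolar pipeline can run with no downloads, not to imitate
a refined structure.

The **CW titration generator** superposes two axial species normalized to
unit double integral: an ATCUN-like species with the published g∥/A∥
(perpendicular components are representative placeholder values for
N/O-coordinated Cu²⁺, to be replaced by fitted numbers when available)
whose weight saturates at 1 equivalent, and a secondary species taking the
remainder, so the total double integral is proportional to added
equivalents by construction. Noise is Gaussian, scaled to the series
maximum. Passing titration tests therefore demonstrates the integration
and regression machinery, not any binding thermodynamics.

ESEEM/HYSCORE/RIDME generators use the physical signal forms above with
seeded Gaussian noise; the RIDME study condition is modulation depth 0.3,
background k = 0.05 µs⁻¹·⁵, d = 1.5, and noise σ = 0.02 (SNR 50 on the
normalized trace).

## Known limitations

- The modulation depth λ is overestimated by ~0.1 on noisy single-peak
  traces (spurious long-r mass trades against the background); mode
  positions are unaffected, which is what the distance analysis uses.
- GCV occasionally under-smooths two-component distributions; the doublet
  modes remain resolved but side structure can appear at ~20% of peak.
- The CW engine is axial-only, Gaussian-broadened, single-isotope; no
  fitting of g/A to data is provided.
- ESEEM processing assumes phase-corrected real traces; the ¹H region
  (~14 MHz) is generated but not analysed.
- Symmetry operations cover only the three space groups the package needs
  (P1, P6₁, P2₁2₁2₁); others raise an explicit error.
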