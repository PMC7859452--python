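# Methods

This note records the models implemented in `scrdimer`, the conventions
and defaults they depend on, and the boundaries of what the synthetic
data can and cannot demonstrate about real experiments.

## Physical conventions

All volumetric and hydrodynamic quantities derive from one record
(`Conventions`): partial specific volume v̄ = 0.73 cm³/g, hydration
δ = 0.30 g water per g protein, water at 20 °C (ρ = 0.99823 g/cm³,
η = 0.01002 poise), and a hydration-shell bead inflation of 0.31 nm. The
v̄/δ pair is the standard protein convention; it also reproduces, from
printed Guinier radii and sequence masses, the published elongation
ratios of the benchmark fragments (1.7, 2.4, 3.1, 2.2), which is how the
pair was validated before being frozen.

**Monomer-mass reference sphere.** The elongation ratio R_G/R_O always
computes R_O from the *monomer's* hydrated volume, including for dimer
species. Published dimer ratios are only mutually consistent under this
convention (e.g. an R_G of 6.0 nm over the 38 kDa monomer sphere gives
3.1); with the dimer-mass sphere they would be systematically smaller.

## Bead-chain fragments

Each SCR domain is three collinear touching beads of radius 0.6 nm
spanning the 3.6 nm per-domain solution length; inter-domain linkers are
0.4 nm surface-to-surface gaps, so an n-domain chain is
`3.6 n + 0.4 (n − 1)` nm long. Bead *radii* carry the packing geometry;
bead *volumes* carry the scattering mass (`Σ V_i = M v̄ / N_A`), so the
thin chain still scatters with the correct forward intensity. Decorations
emulate the expression constructs: one 1.1 nm bead per N-glycan
(2,200 g/mol each, a biantennary disialylated chain) placed at +z on the
middle bead of its domain with ±15° seeded azimuthal jitter, and three
0.5 nm beads (2,500 g/mol total, a 23-residue extended tag) continuing
the chain at the C-terminus. These masses are not experimental inputs;
they are nominal values for typical yeast-expressed constructs.

Dimers are built by duplicating the monomer: side-by-side modes offset
the copy perpendicular to the chain so the *contact domains* touch
(parallel keeps the chain direction, antiparallel reverses it; both
rotate the copy so glycans point away from the interface), and end-to-end
joins the chains head-to-tail. Side-by-side roughly doubles the
cross-section at constant length; end-to-end doubles the length — the
two signatures the analysis distinguishes via R_XS and P(r) length.
Beads may not overlap by more than 1% of the smaller radius; violations
raise immediately rather than producing silently unphysical models.

## SAXS analysis

**Guinier.** Weighted linear regression of ln I on Q², iterated until the
window satisfies `Q_max · R_G ≤ max_qrg` (default 1.5), starting at the
first positive-intensity point, ties broken toward the wider window.
Flat curves return R_G = 0 with a flag; rising curves raise. For strongly
elongated particles the 1.5 limit biases R_G low (the classic rod
artifact, several percent for a two-domain chain); analyses of elongated
fragments should pass `max_qrg` of 0.8–1.2, mirroring experimental
practice for these proteins.

**Cross-section.** `ln(I·Q)` vs Q² with `R_XS = sqrt(−2·slope)` — the
infinite-rod approximation. Without an explicit window the fit starts
above the Guinier region and iterates the limits to
`0.4 ≤ Q·R_XS ≤ 1.0`. Globular curves either fail with a positive slope
or are flagged `no_rod_plateau` by a residual-curvature test (quadratic
term halving the linear-fit residual at rms > 0.02).

**P(r).** Non-negative least squares on a trapezoid discretization of the
sine-kernel forward map, with a second-difference smoothness penalty and
implicit P(0) = P(dmax) = 0; non-negativity is imposed exactly (NNLS)
rather than as the soft penalty some IFT programs use. When α is not
given it is chosen by a discrete L-curve corner search over a 12-point
logarithmic grid scaled to the design matrix. Reported descriptors: the
real-space R_G `sqrt(∫r²P / 2∫P)`, the modal distance M (argmax with
parabolic refinement), and L as the end of the support (last r above 1%
of the peak) — the sphere oracle test recovers R_G to 0.1% and L to 2%.
The inversion requires `Q_max · dmax ≥ π`; below that the problem is
unresolvable and the call fails loudly.

## Debye curves and R-factor ranking

Theoretical curves are the exact O(N²) Debye double sum with
uniform-sphere amplitudes on the scattering radii `(3V_i/4π)^{1/3}`;
I(0) = (ΣV)² identically, so a dimer scatters 4× the monomer per
particle and 2× per unit mass. The R-factor scale c minimizes
`Σ|I_exp − c·I_model|` by golden-section search (the objective is convex;
a brute-force grid oracle confirms the minimizer in tests); disabling the
scale fit reproduces absolute-intensity comparison. The library filter
uses the volume-weighted second-moment R_G of each model (not a Guinier
fit of its curve) within ±rg_tolerance of the experimental Guinier R_G,
then ranks ascending by R-factor with deterministic id tie-breaks.

The mixture forward model in the generator divides each component's
Debye curve by its oligomer state, which makes mixing equal-mass-
concentration: noiseless mixture intensities are affine in the mass
fractions at every Q, and fitting a monomer model to mixtures of growing
dimer fraction degrades monotonically — the fingerprint used to read
poor fits as dimerization evidence.

## Hydrodynamics

Sedimentation coefficients come from the generalized Kirkwood–Riseman
double sum with bead radii inflated by the 0.31 nm shell,
`f = 6πη Σa_i / (1 + (Σa_i)^{-1} Σ_{i≠j} a_i a_j/d_ij)`, and
`s = M(1 − v̄ρ)/(N_A f)`. This is a deliberate simplification of shell
modelling: it is exact in the Stokes limit (single bead, verified to
1e-6), gives the classic 1.50 dimer/monomer ratio for touching equal
spheres, and preserves the qualitative shape dependence (extending a
chain at fixed volume lowers s), but it *underestimates the friction of
thin bead chains* — the coarse two-domain chain computes ≈1.9–2.0 S
against an observed ≈1.6 S and an atomistic shell-model value of 1.4 S.
Hydrodynamic conclusions from the bead chains are therefore qualitative;
tests assert a deliberately wide ±0.4 S band around the observed value.
f/f₀ uses the hydrated equal-volume sphere of the same mass; the
SEDFIT-style fitted frictional ratios quoted in experimental tables
differ from this convention by ~0.1 and no exact reconciliation is
attempted. `mass_from_s_f` inverts (s, f/f₀) → M by fixed point (M scales
as s^{3/2} at fixed shape) and is used to label distribution peaks as
monomer or dimer.

## Sedimentation velocity

The forward model solves the ideal (non-interacting, concentration-
independent) Lamm equation in sector geometry. The default solver is a
conservative finite-volume scheme on 200 radial cells with explicit Euler
stepping under a 0.4× CFL guard; advection is central-differenced when
the cell Péclet number is below 2 (the relevant regime here — first-order
upwinding adds enough numerical diffusion to bias downstream fraction
recovery) and upwinded otherwise. The Faxén closed form (erf boundary at
`r_m e^{sω²t}` with `e^{−2sω²t}` radial dilution) is the documented fast
path; both obey the boundary-midpoint law to better than 1%.

The species distribution is a simplified ls-g*(s)-style inversion, *not*
a full c(s) fit: scans are decomposed by NNLS against a dictionary of
single-species boundaries on an s grid with a second-difference penalty
(default α = 0.005, chosen by a sweep over the seeded fixture suite:
worst recovered-fraction error 0.021 and s error 0.032 S for the 60:40
two-species scenario, with no spurious peaks). Differences from c(s)
fitting: the frictional ratio of the dictionary is fixed (not floated),
meniscus and baseline come from run metadata (not floated), and 0.06 cm
at the meniscus plus 0.15 cm at the base are trimmed where the ideal
model ignores end effects. The dictionary uses the finite-difference
solver by default; the Faxén dictionary is faster but its boundary-shape
error biases recovered fractions by up to ~0.1 and is therefore opt-in.
Peak integration splits at valley minima between significant maxima
(≥2% of the global maximum; ties toward the lower-s valley) and
normalizes trapezoid areas, so fractions sum to 1 by construction.

## Mass action and site logic

Concentrations are converted to monomer-equivalent molarity
(`c_µM = 10⁶ · c_mg/ml / M`) and the working convention is
`K_D = c (1 − f_D)² / f_D`. The textbook `[M]²/[D]` convention is exactly
2× larger and available behind `convention="molar"`; the
monomer-equivalent form is the default because it reproduces the
published worked-example constants (90 µM from the 11%/30% pair, 5 µM
from 80% dimer) from their printed inputs. Series are summarized by the
per-point mean and half-range rather than a fitted isotherm — observed
fraction-vs-concentration behaviour (e.g. a 60:40 ratio flat in
concentration) can violate simple mass action, and the spread reports
that tension instead of hiding it. The inverse solve uses the stable
quadratic root `f = 2c/((2c+K) + sqrt(K(K+4c)))`; forward and inverse are
exact inverses to 1e-10 over the tested ranges.

`localize_site` classifies fragments at a strong/weak threshold of 10 µM
(separating the observed 3–6 µM cluster from 31 µM and above; exposed as
a parameter). The primary site is the intersection of the strong
fragments' domain sets — exhaustive tests over every contiguous planted
site on a five-domain panel recover the plant exactly. Contributing
domains are the intersection, outside the primary set, of the weak
fragments that are disjoint from or strict supersets of it; weak
fragments partially overlapping the primary site carry no independent
information and are excluded. Empty strong intersections are reported as
`ambiguous`, never silently resolved.

## Synthetic data: what it does and does not show

The generators reproduce the *statistical structure* the analysis
assumes: seeded Gaussian SAXS noise growing linearly in Q
(`σ = noise·I·(1 + Q/Q_max)`), additive AUC noise at 0.5% of the initial
plateau, mass-action fraction tables with optional beta-distributed
jitter, and mixtures that are exactly affine in mass fraction. Passing
tests therefore demonstrate correctness of the estimators under their
own model assumptions and their noise robustness at realistic levels.
They do not demonstrate robustness to what real data add: inter-particle
interference and concentration effects in SAXS, time-invariant/radially-
invariant noise and optical artifacts in AUC interference data,
reaction-boundary dynamics of fast-interconverting monomer–dimer systems
(species are simulated as non-interacting), glycan heterogeneity, or
calibration errors in concentration. The default panel (seven fragments,
0.2–3 mg/ml, K_D map spanning 3 µM to monomeric) mirrors the study
conditions of the C-terminal CFH deletion series.

## Problem sizes

Defaults were chosen so a full test run stays interactive on one CPU:
240-point SAXS curves, 201-point P(r) grids, 200 radial cells × 20 scans
per sedimentation run, 51-point s grids, and 20-seed replicate sets for
the stochastic recovery checks (500 replicates for the Guinier bias
check, which is the cheapest fit).

## Known limitations

* Kirkwood hydrodynamics on thin chains is qualitative (see above); no
  shell-model filling, rotational diffusion, or intrinsic viscosity.
* The ls-g*(s) stand-in does not float f/f₀, meniscus or baseline and has
  no reaction-boundary model; closely spaced species (< ~0.5 S at these
  diffusion levels) merge.
* The IFT picks α by L-curve corner, which can under-smooth very noisy
  curves; pass α explicitly for low-quality data.
* Bead models are rigid; inter-domain flexibility enters only through
  the conformer-library ranking interface, not the generator.
* `f/f₀` of coarse chain models can fall marginally below 1 (by < 3%)
  because the chain's hydrodynamic volume underruns the hydrated-sphere
  reference; values below 1 − 0.03 raise as convention mismatches.
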