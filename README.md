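# scrdimer

Monomer–dimer analysis of tandem SCR-domain protein fragments from
small-angle X-ray scattering (SAXS) and analytical-ultracentrifugation
(AUC) data, with set-logic localization of the dimerization site across a
nested fragment deletion panel.

## The problem

Complement Factor H (CFH), the major fluid-phase regulator of the
alternative complement pathway, is a chain of 20 short complement
regulator (SCR) domains that self-associates weakly in solution. Locating
a self-association site inside a multi-domain region is done by expressing
a nested panel of fragments (here the C-terminal five domains,
SCR-16…SCR-20, cut into one- to five-domain pieces), measuring the
monomer–dimer equilibrium of each fragment, and intersecting the domain
content of the strongly dimerizing fragments. `scrdimer` implements that
entire computational pipeline for solution-scattering and
sedimentation-velocity data, together with seeded synthetic-data
generators so every stage is testable without the (non-deposited)
experimental raw data.

## What it computes

**SAXS** (`scrdimer.saxs`)

* Guinier fit `ln I(Q) = ln I(0) − R_G²Q²/3` over a self-consistent low-Q
  window bounded by `Q·R_G ≤ 1.5`;
* rod cross-section fit `ln(I·Q) = const − R_XS²Q²/2`;
* regularized indirect Fourier transform to the distance distribution
  `P(r) = (1/2π²) ∫ I(Q) Q r sin(Qr) dQ`, with the maximum dimension *L*,
  the modal distance *M*, and the real-space R_G;
* the elongation ratio R_G/R_O, where R_O is the R_G of a sphere with the
  protein's hydrated volume `V_h = M(v̄ + δ)/N_A`
  (v̄ = 0.73 cm³/g, δ = 0.30 g/g).

**Model fitting** (`scrdimer.fitting`) — exact Debye-sum curves from bead
models and ranking of a model library against an experimental curve by
the R-factor `R = 100·Σ|I_exp − c·I_model| / Σ|I_exp|` after an R_G
pre-filter.

**Hydrodynamics** (`scrdimer.hydro`) — Kirkwood–Riseman sedimentation
coefficients of bead models (radii inflated by a 0.31 nm hydration
shell), s → s_20,w standardization, frictional ratios f/f₀, and molar
masses from (s, f/f₀).

**AUC** (`scrdimer.sedimentation`, `scrdimer.auc`) — finite-difference and
Faxén solutions of the ideal Lamm equation, and a non-negative
Tikhonov-regularized ls-g*(s)-style inversion of scan sets into species
distributions with peak integration into monomer/dimer fractions.

**Equilibrium** (`scrdimer.equilibrium`) — mass-action K_D from
(concentration, dimer-fraction) points using monomer-equivalent molar
units, `K_D = c(1 − f_D)²/f_D`, its inverse for simulation, aggregation
over concentration series, and the dimer-site inference: *primary* site =
intersection of the domain sets of all strongly dimerizing fragments
(K_D ≤ 10 µM by default), *contributing* domains from the weakly
dimerizing remainder.

**Synthetic data** (`scrdimer.fragments`, `scrdimer.synthetic`) — bead
chains (three beads per 3.6 nm SCR domain, 0.4 nm linkers, optional
glycan and tag beads), dimers in parallel / antiparallel / end-to-end
geometries, noisy mixture SAXS curves, sedimentation boundary sets, and
mass-action fragment panels at planted K_D values.

## Worked example

```python
import numpy as np
import scrdimer as sd

# a two-domain His-tagged, glycosylated fragment that is 80% dimer
spec = sd.FragmentSpec("SCR-17/18H", (17, 18), 22000.0, has_tag=True, glycan_count=2)
monomer = sd.build_fragment_model(spec, seed=0)
dimer = sd.build_dimer_model(monomer, "side_by_side_parallel")

q = np.linspace(0.05, 3.0, 240)
mix = sd.MixtureSpec(dimer_fraction=0.8, total_concentration=1.0,
                     noise_level=0.01, seed=0)
curve = sd.simulate_saxs_curve([(monomer, 0.2), (dimer, 0.8)], mix, q)

fit = sd.guinier_fit(curve)                       # rg=2.64 nm, window 0.05-0.57 1/nm
ratio = sd.rg_ro_ratio(fit.rg, spec.monomer_mass) # 1.64
pr = sd.ift_pr(curve, dmax=1.3 * dimer.length)    # L=13.5 nm, mode=2.0 nm

kd = sd.fractions_to_kd(0.80, 1.0, 10000.0)       # 5.0 uM

panel = sd.default_panel(seed=1)
ests = [(e.spec, sd.kd_from_series(e.points, e.spec.monomer_mass).kd)
        for e in panel.entries]
site = sd.localize_site(ests, strong_threshold=10.0)
print(sorted(site.primary_domains), sorted(site.contributing_domains))
# [17] [18]
```

The Guinier R_G of 2.64 nm and elongation ratio 1.64 say the 80%-dimer
sample is only slightly larger than the monomeric two-domain benchmark —
the side-by-side dimer geometry keeps the length — while the single-point
K_D of 5.0 µM marks strong dimerization. Across the whole seven-fragment
panel the strongly dimerizing set (K_D ≤ 10 µM) shares exactly domain 17,
and the weak self-dimerizers single out domain 18 as contributing.

The same stages are scriptable from the shell:

```sh
scrdimer simulate --seed 2 --out panel.tsv
scrdimer kd --panel panel.tsv
scrdimer localize --panel panel.tsv --threshold 10
scrdimer run-all --seed 3 --out report/
```

## Layout

```
src/scrdimer/     conventions, fragments, synthetic, saxs, fitting,
                  hydro, sedimentation, auc, equilibrium, io, pipeline, cli
tests/            pytest + hypothesis suite (analytic oracles throughout)
docs/methods.md   model assumptions, conventions, numerical choices
scripts/          acceptance.py
```
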