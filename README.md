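# nanodisc

Integrative small-angle scattering and ensemble analysis of lipid nanodiscs
— discoidal particles in which two membrane-scaffold proteins (MSPs)
encircle a small lipid bilayer patch. The package is for structural
biophysicists who want to (i) fit SAXS/SANS curves of nanodiscs with a
molecular-constrained analytical model, (ii) compute scattering and NOE
observables from conformational ensembles, (iii) refine ensembles against
experiments by Bayesian/Maximum-Entropy (BME) reweighting, and (iv) analyse
the resulting ensembles (shape, clustering, lipid structure) — with a
synthetic-data generator that exercises the whole pipeline against known
ground truth.

## The models

**Scattering model.** The disc is a stack of flat elliptical layers (tail
core of height `H_tails` between two headgroup layers of thickness
`D_head`) inside a hollow elliptical belt cylinder (height `H_belt`,
width `W_belt`). Geometry follows from molecular constraints:
`π R_major R_minor = (N_lipid/2) A_head` with `R_major = ε R_minor`,
`H_tails = 2 CV_lipid ν_tails / A_head`, and `W_belt` from the belt-volume
constraint. The intensity is an orientation average of coherent
elliptical-cylinder amplitudes on absolute scale, with interface roughness,
optional Gaussian-coil His-tag terms and lipid-number polydispersity; X-ray
and neutron contrasts are computed from chemical composition.

**BME reweighting.** Given per-frame observables `F_i(x_j)` and experimental
targets, BME minimizes `L(w) = (m/2) χ²_r(w) − θ S_rel(w)` where
`S_rel = −Σ_j w_j log(w_j/w⁰_j)`; it is solved through the convex dual over
Lagrange multipliers, with sign constraints for one-sided (NOE bound)
restraints. Diagnostics include `S_rel` and the effective ensemble fraction
`φ_eff = exp(S_rel)`, plus an L-curve θ scan with a suggested elbow.

**Forward models and analyses.** Debye-equation scattering from bead
ensembles (pair-distance histogram), NOE effective distances
`⟨R⁻³⟩^(−1/3)` with one-sided χ², self-avoiding-walk His-tag decoration,
gyration-tensor acylindricity `C = sqrt(λx² − λy²)` (and the fitted-axes
convention `sqrt(a² − b²)`), RMSD quality-threshold clustering, bilayer
thickness maps and `S_CH = ½(3cos²θ − 1)` order parameters with rim/core
zones.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Fit the analytical model to a noisy synthetic SAXS curve and recover the
planted axis ratio:

```python
import numpy as np
from nanodisc import (NanodiscParams, FreeParam, ScatteringCurve,
                      model_intensity, fit_sas, derive_dimensions)

truth = NanodiscParams(a_head=52.0, eps=1.3, n_lipid=102.0, scale_xray=1.1)
q = np.linspace(0.01, 0.25, 60)
ideal = model_intensity(q, truth, n_alpha=32, n_psi=16).intensity
sigma = 0.02 * ideal
rng = np.random.default_rng(7)
data = ScatteringCurve(q=q, intensity=ideal + rng.normal(scale=sigma),
                       sigma=sigma, contrast="xray")

free = [FreeParam("eps", 1.2, 1.0, 1.8),
        FreeParam("a_head", 55.0, 40.0, 70.0),
        FreeParam("scale_xray", 1.0, 0.5, 2.0)]
res = fit_sas([data], free, NanodiscParams(a_head=52.0, n_lipid=102.0), seed=1)
print({k: round(v, 4) for k, v in res.values.items()})
print("chi2_r =", round(res.chi2_global, 3))
print("eps 95% interval:", tuple(round(v, 3) for v in res.interval("eps")))
```

prints

```
{'eps': 1.2877, 'a_head': 52.0026, 'scale_xray': 1.0951}
chi2_r = 0.779
eps 95% interval: (1.272, 1.303)
```

The planted ε = 1.3 lies inside the reported 95% interval and the reduced
chi-square is of order one, as it should be for correctly stated noise. The
derived geometry for the gel-phase DMPC disc,

```python
d = derive_dimensions(NanodiscParams(a_head=52.0, eps=1.4, n_lipid=102.0))
print({k: round(v) for k, v in d.as_dict().items()})
# {'R_major': 34, 'R_minor': 25, 'H_lipid': 42, 'H_tails': 29, 'D_head': 6, 'W_belt': 9}
```

gives semi-axes of 34 × 25 Å and a 9 Å belt — a disc a bit over 8 nm across.

A command-line interface wraps the pipeline stages
(`nanodisc simulate | fit-sas | forward | reweight | analyze-shape |
analyze-lipids`); `nanodisc simulate --seed 1 --out demo/` writes a complete
synthetic benchmark (multi-model PDB ensemble, true weights, SAXS curve,
NOE table, observable matrices, truth report).

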