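# bapkin

Kinetic modelling of occupational benzo(a)pyrene (BaP) exposure through its
urinary biomarker 3-hydroxybenzo(a)pyrene (3-OHBaP).

Workers in aluminium, silicon, creosote or carbon plants are exposed to
polycyclic aromatic hydrocarbons by inhalation **and** skin contact, and air
monitoring alone cannot tell the routes apart. Biomonitoring of 3-OHBaP in
repeated urine voids can — provided a kinetic model links external dose to
the biomarker time course. `bapkin` provides two such models and the tooling
to use them for exposure reconstruction; it is aimed at occupational
hygienists and toxicokinetic modellers.

## Models

**PBPK model.** BaP and 3-OHBaP each occupy a blood pool plus lung, adipose,
skin, kidney, liver and rest-of-body compartments. Perfusion-limited tissues
follow `dA_i/dt = Q_i (C_bl − C_i/P_i)`; diffusion-limited tissues (BaP
lung; 3-OHBaP lung, adipose, kidney) replace `Q_i` with a permeability-area
product `PA_i`. Inhalation enters as `Q_alv·C_inh` with exhaled back-loss
`Q_alv·C_bl/P_B`; dermal contact as `k_P·A·P_DV·C_vehicle` into skin. BaP is
cleared hepatically at `(V_max/K_M)·C_liv/P_LV`, a fraction
`f_3OHBaP = 0.185` forming 3-OHBaP, which undergoes fast biliary transfer
(`K_b = 663.8 h⁻¹`), entero-hepatic recirculation (`K_gil`), renal transfer
to the bladder (`K_kb`) and bladder emptying to urine (`K_bu = 0.102 h⁻¹`).
All transfers are first-order, so the system is linear and is solved
*exactly* by segment-wise matrix exponentials (mass balance ≈ 1e−14).

**One-compartment TK model.** Route-specific first-order absorption
(`ka_inh = 48.35×10⁻³ h⁻¹`, `ka_der = 61.81×10⁻³ h⁻¹`) into a single body
compartment eliminating at `k_b = 198.26×10⁻³ h⁻¹`; urinary 3-OHBaP is
`α_route·k_b·B(t)` with `α_inh = 3.99×10⁻²`, `α_der = 1.64×10⁻²`. Bateman
closed forms and exact window convolution — no integration error.

Around them: rat-to-human scaling rules (`C_rat-human = 1020.03`, GFR ratio
125/1.31, bile-flow ratio 350/22.5, Morimoto skin factor ≈ 0.1105),
multi-day multi-route exposure scenarios including the 14 encoded worker
fixtures, creatinine-corrected urine void series, a 1000-run all-parameter
Monte Carlo stability analysis, a Monte Carlo Pearson-χ² dose search, and a
synthetic-data generator with known ground truth. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

Simulate a monitored worker's best-fit scenario, then recover dermal levels
from a synthetic noisy urine series:

```python
from dataclasses import replace
from bapkin import (PBPKModel, worker_fixture, SyntheticSpec,
                    generate_worker_dataset, fit_exposure)

fx = worker_fixture(1)                       # shooting-target factory, subject 1
traj = PBPKModel().simulate(fx.simulated, dt=0.5)
print(f"absorbed BaP:        {traj.absorbed()[-1]:.2f} nmol")
print(f"urinary 3-OHBaP:     {traj.urine_cumulative()[-1]:.3e} nmol")
print(f"mass balance error:  {traj.mass_balance().max():.1e}")

dermal = replace(fx.simulated, windows=fx.simulated.by_route("dermal"))
obs, truth = generate_worker_dataset(
    SyntheticSpec(scenario=dermal, model="tk", cv=0.15, seed=1))
fit = fit_exposure(obs, dermal, model="tk", n_iter=1000, seed=2)
for i, w in enumerate(dermal.windows):
    print(f"window {i}: true {w.level:6.1f}  fitted {fit.levels[i]:6.1f} fmol/mL")
```

prints

```
absorbed BaP:        103.71 nmol
urinary 3-OHBaP:     2.780e-05 nmol
mass balance error:  2.9e-14
window 0: true   19.8  fitted   20.0 fmol/mL
window 1: true   26.1  fitted   22.4 fmol/mL
```

The trajectory line says the two-day scenario delivers ~104 nmol of BaP, of
which a small fraction reaches urine as 3-OHBaP, with the absorbed amount
accounted for to machine precision. The fit lines show the χ² search
recovering the two generating dermal vehicle concentrations from a series
with 15 % multiplicative measurement noise — within ~1 % on day 1 and ~14 %
on day 2.

A CLI mirrors the library: `bapkin simulate`, `bapkin fit`,
`bapkin sensitivity`, `bapkin synth` (each writes a reproducibility
manifest; see `bapkin --help`).

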