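# blasthead

Desk-scale modelling of primary blast-induced traumatic brain injury
(bTBI): how the overpressure wave from a free-field TNT detonation
transmits through the layered tissues of the head, and what the
resulting intracranial pressures and shear stresses mean for injury
severity.

The package is aimed at injury-biomechanics researchers who want a
transparent, scriptable 1D counterpart to 3D finite-element head-blast
simulation: every stage — source, transmission, metrics, classification
— is an importable function with a thin CLI on top, and every physical
constant is in a plain-text configuration.

## What it computes

**Blast source.** A centrally ignited spherical TNT charge of mass
*m* (radius *a* = (3*m*/4πρ₀)^⅓) is burned at constant volume into
Jones–Wilkins–Lee (JWL) detonation products,

> P(V, E) = A (1 − ω/R₁V) e^(−R₁V) + B (1 − ω/R₂V) e^(−R₂V) + ωE/V,

surrounded by ideal-gas air (P = (γ−1)ρe, γ = 1.4), and integrated with
a 1D spherically symmetric Lagrangian finite-volume scheme
(von Neumann–Richtmyer artificial viscosity).  The side-on overpressure
history at a standoff gauge is recorded and can be fit with the modified
Friedlander waveform ΔP (1 − τ) e^(−bτ), τ = (t − t_a)/t_d.

**Tissue column.** The head's through-thickness path is a planar
uniaxial-strain column — scalp / skull / CSF / brain, loaded face first —
driven by the normally reflected surface load
2ΔP(7P₀ + 4ΔP)/(7P₀ + ΔP).  Volumetric response per material: linear
elastic (scalp, nasal cavity), Mie–Grüneisen shock EOS from the linear
Hugoniot U_s = C₀ + sU_p (skull, CSF), or linear bulk (brain).  The
brain's deviatoric response is the single-term shear relaxation

> G(t) = G∞ + (G₀ − G∞) e^(−βt),  G₀ = 41 kPa, G∞ = 7.8 kPa, β = 700 s⁻¹,

integrated with a recursive exponential integrator (exact for
piecewise-linear strain).  Virtual gauges record pressure and von Mises
stress (= 3/2 |s_axial| in uniaxial strain).

**Injury analysis.** Per gauge: peak positive/negative pressure, the
largest positive-to-negative excursion within a 1 ms window, and
severity labels from the Ward intracranial-pressure contusion index
(<173 kPa none/minor; 173–235 kPa minor contusion or cortex hemorrhage;
>235 kPa serious contusion) and the Zhang von Mises axonal thresholds
(6.0 / 7.8 / 10.0 kPa for 25 / 50 / 80 % mild-TBI probability).

**Scenarios.** The default study is five charge masses (250–450 g) at
1.0 m for three head orientations (anterior, right-lateral, posterior),
orientation entering through per-orientation skull thicknesses.

## Worked example

```python
from blasthead.scenario_pipeline import BlastScenario, run_scenario

report = run_scenario(BlastScenario(0.30, "anterior"))
print(report.impinging_bop_kpa)
print(report.to_dict()["gauges"]["proximal_cortex"])
```

prints (about 15 s on one core):

```
345.5335821125714
{'peak_positive_kpa': 2129.12..., 'peak_negative_kpa': -312.20...,
 'peak_to_peak_1ms_kpa': 2441.32..., 'time_of_peak_ms': 0.794,
 'peak_von_mises_kpa': 0.0790..., 'severity_peak': 'SERIOUS_CONTUSION',
 'severity_peak_to_peak': 'SERIOUS_CONTUSION', 'axonal_band': 'BELOW_25PCT'}
```

Reading: a 300 g charge at 1 m produces a free-field impinging blast
overpressure of ≈346 kPa.  Applied as a fully reflected load to a
blocked 1D column, the proximal-cortex gauge sees ≈2.1 MPa peak
pressure (far above what a finite 3D head experiences — the planar
column neither diffracts nor relieves the load, so in-brain magnitudes
are upper bounds, not predictions), while brain von Mises stress stays
below 0.1 kPa, two orders of magnitude under the 6 kPa axonal-injury
threshold — the same qualitative conclusion 3D studies reach: pressure,
not shear, is the plausible primary-blast injury driver.

The same stages from the shell:

```bash
blasthead detonate --mass-g 300 --standoff-m 1.0 --out trace.csv
blasthead sweep --masses 250,300,350,400,450 --orientations all --quick --out results/
```

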