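# Constitutive laws and material constants for the head constituents,
# the TNT detonation products and the ambient air.  Tissue constants are
# quoted in the units they are conventionally reported in and normalised
# to SI on load.
scalp:
  law: linear_elastic
  K: 34.7 MPa
  G: 5.88 MPa
  rho: 1.04 g/cm^3
nasal_cavity:
  law: linear_elastic
  K: 2.19 GPa
  G: 225.3 Pa
  rho: 1.04 g/cm^3
skull:
  law: shock_eos
  C0: 1850 m/s
  s: 0.94
  rho0: 1.412 g/cm^3
  G: 2.664 GPa
csf:
  law: shock_eos
  C0: 1647 m/s
  s: 1.921
  rho0: 0.998 g/cm^3
  G: 500 Pa
brain:
  law: viscoelastic
  K: 2.19 GPa
  rho: 1.04 g/cm^3
  G0: 41 kPa
  Ginf: 7.8 kPa
  beta: 700 1/s
# Standard-library TNT JWL parameter set (Lee-style product EOS).
tnt:
  law: jwl
  A: 371.2 GPa
  B: 3.231 GPa
  R1: 4.15
  R2: 0.95
  omega: 0.30
  rho0: 1630 kg/m^3
  e0: 4.29 MJ/kg
air:
  law: ideal_gas
  gamma: 1.4
  rho: 1.225 kg/m^3
  p0: 101.325 kPa
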