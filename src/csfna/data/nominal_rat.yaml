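# Nominal physiological parameter set for an adult rat.
# Concentrations are given in mM (1 mM = 1e-6 mol/cm^3); everything else in
# cm / s / g base units. P_vb and P_sb are deliberately enormous: the
# ependymal and pial contact surfaces impose no rate-limiting resistance, so
# ISF sodium at the tissue-CSF interfaces equilibrates instantaneously with
# the adjacent CSF compartment.
P_BCSFB: {value: 3.8e-5, unit: cm/s}      # BCSFB influx permeability, blood -> ventricular CSF
A_BCSFB: {value: 1.0, unit: cm^2}         # choroid plexus surface area
V_s: {value: 0.2, unit: cm^3}             # subarachnoid space volume
V_v: {value: 0.1, unit: cm^3}             # ventricular system volume
V_b: {value: 1.1, unit: cm^3}             # brain tissue volume
P_BBB: {value: 1.4e-7, unit: cm/s}        # BBB influx permeability, blood -> brain tissue
A_BBB: {value: 140.0, unit: cm^2/g}       # BBB surface area per gram of brain
f_d: {value: 0.34, unit: cm^3/g}          # sodium distribution factor (tissue mol/g -> ISF mol/cm^3)
D: {value: 1.15e-5, unit: cm^2/s}         # sodium diffusivity in brain ISF
Q_csf: {value: 3.6e-5, unit: cm^3/s}      # bulk CSF flow, ventricles -> subarachnoid -> blood
lam: {value: 0.2, unit: dimensionless}    # ISF volume fraction of brain tissue
rho: {value: 1.0, unit: g/cm^3}           # brain density
P_vb: {value: 1.0e6, unit: cm/s}          # ventricle-tissue contact surface permeability
P_sb: {value: 1.0e6, unit: cm/s}          # subarachnoid-tissue contact surface permeability
C_blood: {value: 140.0, unit: mM}         # blood sodium (held constant)
C_csf0: {value: 145.0, unit: mM}          # shared initial CSF sodium, C_v(0) = C_s(0)
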