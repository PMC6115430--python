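"""Unit conventions and conversion factors.

The internal unit system is kPa for pressure, ml for volume, s for time and
mm for lengths, so that resistances carry kPa·s/ml and compliances ml/kPa.
All conversions from external/clinical units (cmH2O, cm²/s, SI) happen at
the boundaries; no module converts units internally.
"""

#: 1 cmH2O in kPa (conventional water-column factor).
CMH2O_TO_KPA = 0.0980665

#: 1 cm²/s in mm²/s (diffusivities).
CM2_S_TO_MM2_S = 100.0

#: 1 Pa·s/m³ in kPa·s/ml.
PA_S_PER_M3_TO_KPA_S_PER_ML = 1e-9

#: 1 ml/s in mm³/s.
ML_S_TO_MM3_S = 1e3


def cmh2o_to_kpa(p: float) -> float:
    return p * CMH2O_TO_KPA


def kpa_to_cmh2o(p: float) -> float:
    return p / CMH2O_TO_KPA
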