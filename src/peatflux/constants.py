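"""Physical constants and the audited unit chain.

Every unit conversion used by the package lives here so the whole
emission calculation can be checked in one place.
"""

# Ideal gas
R_J_PER_MOL_K = 8.31446  # J mol-1 K-1
KELVIN_OFFSET = 273.15
MOLAR_MASS_C = 12.011  # g mol-1

# Default incubation conditions
DEFAULT_TEMPERATURE_C = 23.0
DEFAULT_PRESSURE_KPA = 101.325

# Carbonate system (freshwater, ~25 C reference values)
HENRY_KH_25C = 3.4e-2        # mol L-1 atm-1, CO2(aq) per unit partial pressure
HENRY_VANT_HOFF_K = 2400.0   # K, d(ln KH)/d(1/T)
PKA1_CARBONIC = 6.35         # first dissociation, CO2* -> HCO3- + H+

# Unit chain for upscaling
MG_PER_G_TO_FRACTION = 1e-3  # (mg C / g C) -> (g C / g C); also kt/Mt
HA_TO_M2 = 1e4
G_TO_MT = 1e-12
DAYS_PER_YEAR = 365
Z_95 = 1.96

# Spectroscopy
INDEX_BANDS_CM1 = (1420.0, 1510.0, 1630.0, 1720.0)
REFERENCE_BAND_CM1 = 1090.0
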