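"""Physical constants and unit-conversion factors used throughout the package."""

#: Boltzmann constant in electron volts per kelvin, as conventionally used in
#: metabolic-theory TPC work.
BOLTZMANN_EV: float = 8.62e-5

#: Celsius -> kelvin offset.
ABS_ZERO_C: float = 273.15

#: Oxycaloric equivalent: joules of metabolic energy per mg of O2 respired.
OXYGEN_TO_JOULES: float = 14.06

MINUTES_PER_HOUR: float = 60.0

#: Millilitres per litre; densities are recorded per mL, energy rates per L.
ML_PER_L: float = 1000.0

#: Default standardisation temperature (degC) for the Sharpe-Schoolfield rate
#: at reference temperature. The balance and mismatch results are invariant to
#: this choice; only r_tref rescales.
DEFAULT_TREF_C: float = 20.0
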