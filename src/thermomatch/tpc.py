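"""Sharpe-Schoolfield thermal performance curve: equation and closed forms.

The high-temperature-inactivation Sharpe-Schoolfield model describes a
unimodal biological rate as a Boltzmann-Arrhenius rise moderated by
reversible enzyme inactivation above a characteristic temperature::

    rate(T) = r_tref * exp(-Ea/k * (1/T_K - 1/Tref_K))
              / (1 + exp(Eh/k * (1/th - 1/T_K)))

with ``T_K = T + 273.15`` kelvin, ``Ea`` the activation energy (eV) setting
the slope of the rising limb, ``Eh`` the deactivation energy (eV) setting
the steepness of the post-optimum decline, ``th`` the kelvin temperature at
which inactivation half-suppresses the rate, and ``r_tref`` the rate at the
standardisation temperature ``Tref``.

All public interfaces take temperatures in degC; kelvin appears only inside
the equation. The optimum has a closed form, used both to derive Topt/MRP
from a fit and, inverted, to reconstruct ``th`` from a published Topt.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .constants import ABS_ZERO_C, BOLTZMANN_EV, DEFAULT_TREF_C
from .errors import DomainError

__all__ = [
    "TPCParams",
    "sharpe_schoolfield",
    "topt_of",
    "mrp_of",
    "th_from_topt",
]


class TPCParams(NamedTuple):
    """Full Sharpe-Schoolfield parameter set (temperatures: th in K, Tref in degC)."""

    r_tref: float
    ea: float
    eh: float
    th: float
    tref: float = DEFAULT_TREF_C

    def __call__(self, temp_c):
        return sharpe_schoolfield(temp_c, *self)


def _check_ea_eh(ea: float, eh: float) -> None:
    if not (eh > ea > 0.0):
        raise DomainError(f"require Eh > Ea > 0, got Ea={ea!r}, Eh={eh!r}")


def sharpe_schoolfield(temp_c, r_tref, ea, eh, th, tref=DEFAULT_TREF_C):
    """Evaluate the TPC at ``temp_c`` (degC, scalar or array).

    Positive and finite on any physiological range for valid parameters.
    """
    _check_ea_eh(ea, eh)
    if th <= 0.0:
        raise DomainError(f"th must be positive kelvin, got {th!r}")
    t_k = np.asarray(temp_c, dtype=float) + ABS_ZERO_C
    tref_k = tref + ABS_ZERO_C
    k = BOLTZMANN_EV
    rise = np.exp(-ea / k * (1.0 / t_k - 1.0 / tref_k))
    inact = 1.0 + np.exp(eh / k * (1.0 / th - 1.0 / t_k))
    out = r_tref * rise / inact
    return out if out.ndim else float(out)


def topt_of(ea: float, eh: float, th: float) -> float:
    """Optimum temperature (degC) via the closed form.

    Topt_K = Eh * th / (Eh + k * th * ln(Eh/Ea - 1)).
    """
    _check_ea_eh(ea, eh)
    k = BOLTZMANN_EV
    topt_k = eh * th / (eh + k * th * np.log(eh / ea - 1.0))
    return float(topt_k - ABS_ZERO_C)


def mrp_of(params: TPCParams) -> float:
    """Maximum rate of performance: the curve evaluated at its own Topt."""
    return float(sharpe_schoolfield(topt_of(params.ea, params.eh, params.th),
                                    *params))


def th_from_topt(ea: float, eh: float, topt_c: float) -> float:
    """Invert the Topt closed form for the half-inactivation temperature (K).

    th = Topt_K * Eh / (Eh - k * Topt_K * ln(Eh/Ea - 1)).

    In the limit Eh -> infinity this tends to Topt_K: inactivation becomes a
    step at th and the optimum sits directly on it.
    """
    _check_ea_eh(ea, eh)
    k = BOLTZMANN_EV
    topt_k = topt_c + ABS_ZERO_C
    denom = eh - k * topt_k * np.log(eh / ea - 1.0)
    if denom <= 0.0:
        raise DomainError(
            f"no positive th reproduces Topt={topt_c} degC with Ea={ea}, Eh={eh}"
        )
    return float(topt_k * eh / denom)
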