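"""Energetic balances, thermal-mismatch classification, and the CREB.

An organism's energetic balance is the ratio of its energy-gain rate to its
energy-loss rate evaluated on a fine temperature grid: net photosynthesis
over respiration for an alga, assimilated ingestion over respiration for
the consumer. Two temperatures summarise a balance curve: Tm, where the
ratio peaks, and Tc, the crossover where the ratio falls through 1 and
losses start exceeding gains.

Intraspecific thermal mismatch is the region where a species' own balance
declines with warming. Between an interacting pair, region 1 of the
interspecific mismatch is where the two balances trend in opposite
directions and region 2 where both decline. The consumer-resource
energetic balance (CREB) is the natural log of the consumer's balance over
the resource's; its trend with temperature (declining / increasing /
U-shaped / hump-shaped / flat) is the qualitative predictor of how
interaction strength responds to warming.

Derivatives on the 0.001 degC grid are centred finite differences after a
moving-average smoothing (default window 0.5 degC), so instrument-scale
wiggles cannot fragment the contiguous regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .models import PredictionGrid

__all__ = [
    "BalanceCurve",
    "MismatchReport",
    "InterTMReport",
    "CREBCurve",
    "energetic_balance",
    "find_Tm",
    "find_Tc",
    "intra_tm",
    "inter_tm",
    "creb",
    "classify_trend",
    "predict_is_trend",
]


@dataclass(frozen=True)
class BalanceCurve:
    """Gain, loss, and gain/loss ratio on a shared temperature grid.

    The ratio is NaN-masked wherever loss <= 0; ``masked_fraction`` reports
    how much of the grid that removed.
    """

    temperatures: np.ndarray
    gain: np.ndarray
    loss: np.ndarray
    ratio: np.ndarray
    species: str = ""
    gain_kind: str = ""
    loss_kind: str = ""
    masked_fraction: float = 0.0


@dataclass(frozen=True)
class MismatchReport:
    species: str
    tm_c: float
    tm_on_boundary: bool
    ratio_diverges_at_edge: bool
    tc_c: float | None
    always_deficit: bool
    intra_tm_intervals: tuple  # ((start, stop), ...) degC


@dataclass(frozen=True)
class InterTMReport:
    region1: tuple  # intervals where balance derivatives have opposite signs
    region2: tuple  # intervals where both balances decline
    onset_c: float | None


@dataclass(frozen=True)
class CREBCurve:
    temperatures: np.ndarray
    values: np.ndarray
    trend: str = ""
    flags: tuple = field(default_factory=tuple)


def energetic_balance(gain_grid: PredictionGrid, loss_grid: PredictionGrid,
                      species: str = "", gain_kind: str = "",
                      loss_kind: str = "") -> BalanceCurve:
    """Pointwise gain/loss ratio on identical grids, with loss<=0 masked."""
    if (gain_grid.temperatures.shape != loss_grid.temperatures.shape
            or not np.allclose(gain_grid.temperatures, loss_grid.temperatures)):
        raise InputError("gain and loss grids must share their temperatures")
    loss = loss_grid.values
    bad = loss <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, gain_grid.values / np.where(bad, 1.0, loss))
    return BalanceCurve(gain_grid.temperatures, gain_grid.values, loss, ratio,
                        species=species, gain_kind=gain_kind,
                        loss_kind=loss_kind,
                        masked_fraction=float(bad.mean()))


def _valid(curve: BalanceCurve):
    ok = np.isfinite(curve.ratio)
    if not ok.any():
        raise InputError("balance ratio is masked everywhere")
    return ok


def find_Tm(curve: BalanceCurve) -> tuple[float, bool, bool]:
    """Temperature of the balance maximum.

    Returns ``(tm_c, on_boundary, ratio_diverges_at_edge)``. Interior local
    maxima are preferred (lowest first on ties): when the loss curve
    collapses towards zero at a grid edge the raw ratio diverges there, and
    that edge blow-up is a division artefact, not a performance optimum. If
    no interior maximum exists the (flagged) grid argmax is returned — a
    monotonically declining balance correctly reports the grid minimum.
    """
    ok = _valid(curve)
    t, r = curve.temperatures[ok], curve.ratio[ok]
    interior = np.where((r[1:-1] >= r[:-2]) & (r[1:-1] > r[2:]))[0] + 1
    edge_max = float(max(r[0], r[-1]))
    if interior.size:
        best = interior[np.argmax(r[interior])]
        # several local maxima: keep the lowest-temperature one among ties
        ties = interior[np.isclose(r[interior], r[best], rtol=0, atol=0)]
        best = int(ties.min())
        return float(t[best]), False, bool(edge_max > r[best])
    i = int(np.argmax(r))
    return float(t[i]), i in (0, r.size - 1), False


def find_Tc(curve: BalanceCurve) -> tuple[float | None, bool]:
    """Crossover temperature: lowest downward crossing of ratio = 1.

    Located by sign change between adjacent grid points and refined by
    linear interpolation. Returns ``(tc_c or None, always_deficit)``;
    ``always_deficit`` marks a balance that never reaches 1 at all.
    """
    ok = _valid(curve)
    t, r = curve.temperatures[ok], curve.ratio[ok]
    down = np.where((r[:-1] >= 1.0) & (r[1:] < 1.0))[0]
    if down.size == 0:
        return None, bool(np.all(r < 1.0))
    i = int(down[0])
    if r[i] == 1.0:
        return float(t[i]), False
    frac = (r[i] - 1.0) / (r[i] - r[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i])), False


def _smoothed_derivative(t: np.ndarray, v: np.ndarray,
                         window_c: float = 0.5) -> np.ndarray:
    """Centred finite difference of a moving-average-smoothed signal."""
    step = float(np.median(np.diff(t)))
    w = max(1, int(round(window_c / step)))
    if w > 1:
        kernel = np.ones(w) / w
        pad = np.concatenate([np.full(w // 2, v[0]), v, np.full(w - 1 - w // 2, v[-1])])
        v = np.convolve(pad, kernel, mode="valid")
    return np.gradient(v, t)


def _intervals(t: np.ndarray, mask: np.ndarray) -> tuple:
    """Maximal runs of True as (start, stop) temperature pairs."""
    if not mask.any():
        return ()
    idx = np.where(mask)[0]
    breaks = np.where(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return tuple((float(t[a]), float(t[b])) for a, b in zip(starts, stops))


def intra_tm(curve: BalanceCurve, window_c: float = 0.5) -> tuple:
    """Interval(s) where the balance declines with warming.

    For a unimodal balance this is [Tm, grid max]; a strictly increasing
    balance yields no interval, a strictly decreasing one the full span.
    """
    ok = _valid(curve)
    t, r = curve.temperatures[ok], curve.ratio[ok]
    return _intervals(t, _smoothed_derivative(t, r, window_c) < 0)


def inter_tm(consumer_curve: BalanceCurve, resource_curve: BalanceCurve,
             window_c: float = 0.5) -> InterTMReport:
    """Interspecific mismatch regions on the curves' common grid.

    Region 1: the balances trend in opposite directions; region 2: both
    decline. Every grid point with at least one declining species falls in
    exactly one of the two.
    """
    tc, tr = consumer_curve.temperatures, resource_curve.temperatures
    lo, hi = max(tc[0], tr[0]), min(tc[-1], tr[-1])
    mc = (tc >= lo) & (tc <= hi)
    mr = (tr >= lo) & (tr <= hi)
    if mc.sum() != mr.sum() or not np.allclose(tc[mc], tr[mr]):
        raise InputError("balance curves do not share a common grid")
    t = tc[mc]
    dc = _smoothed_derivative(t, consumer_curve.ratio[mc], window_c)
    dr = _smoothed_derivative(t, resource_curve.ratio[mr], window_c)
    opposite = (dc * dr) < 0
    both_down = (dc < 0) & (dr < 0)
    r1, r2 = _intervals(t, opposite), _intervals(t, both_down)
    onset = min((iv[0] for iv in r1 + r2), default=None)
    return InterTMReport(region1=r1, region2=r2, onset_c=onset)


def creb(consumer_curve: BalanceCurve, resource_curve: BalanceCurve) -> CREBCurve:
    """ln(consumer balance) - ln(resource balance), pointwise.

    Defined only where both component ratios are positive; the reported
    domain is trimmed accordingly. Antisymmetric under swapping the two
    curves.
    """
    if (consumer_curve.temperatures.shape != resource_curve.temperatures.shape
            or not np.allclose(consumer_curve.temperatures,
                               resource_curve.temperatures)):
        raise InputError("CREB requires a common temperature grid")
    rc, rr = consumer_curve.ratio, resource_curve.ratio
    ok = np.isfinite(rc) & np.isfinite(rr) & (rc > 0) & (rr > 0)
    if not ok.any():
        raise InputError("no grid point with both balances positive")
    flags = () if ok.all() else ("domain_trimmed",)
    return CREBCurve(consumer_curve.temperatures[ok],
                     np.log(rc[ok]) - np.log(rr[ok]), flags=flags)


TREND_LABELS = ("declining", "increasing", "u_shaped", "hump_shaped", "flat")


def classify_trend(curve: CREBCurve, eps_fraction: float = 0.01,
                   window_c: float = 0.5) -> str:
    """Label the CREB's temperature trend from its smoothed derivative.

    The derivative is thresholded at ``eps = eps_fraction * range(CREB)``
    per degC: everywhere below -eps -> declining; above +eps -> increasing;
    negative-then-positive -> u_shaped; positive-then-negative ->
    hump_shaped; never outside +-eps -> flat. Multiple sign alternations
    fall back to the first/last significant sign.
    """
    t, v = curve.temperatures, curve.values
    if t.size < 3:
        raise InputError("need >= 3 points to classify a trend")
    d = _smoothed_derivative(t, v, window_c)
    eps = eps_fraction * float(np.ptp(v))
    sign = np.zeros_like(d, dtype=int)
    sign[d > eps] = 1
    sign[d < -eps] = -1
    nz = sign[sign != 0]
    if nz.size == 0:
        return "flat"
    pattern = nz[np.concatenate([[True], nz[1:] != nz[:-1]])]
    if pattern.size == 1:
        return "declining" if pattern[0] < 0 else "increasing"
    first, last = int(pattern[0]), int(pattern[-1])
    if (first, last) == (-1, 1):
        return "u_shaped"
    if (first, last) == (1, -1):
        return "hump_shaped"
    # alternation ending where it started; report the dominant direction
    return "declining" if np.trapezoid(d, t) < 0 else "increasing"


def predict_is_trend(trend: str) -> dict:
    """Map a CREB trend to the expected interaction-strength trend.

    A declining CREB predicts weakening top-down control, an increasing one
    strengthening; U-shaped and flat CREBs predict constant-or-increasing
    interaction strength (direction indeterminate without the curvature's
    sign changing the balance of the two species' constraints).
    """
    if trend not in TREND_LABELS:
        raise InputError(f"unknown trend label {trend!r}")
    mapping = {
        "declining": ("decreasing", False),
        "increasing": ("increasing", False),
        "u_shaped": ("constant_or_increasing", True),
        "flat": ("constant_or_increasing", True),
        "hump_shaped": ("constant_or_decreasing", True),
    }
    predicted, indeterminate = mapping[trend]
    return {"predicted_is_trend": predicted,
            "indeterminate_direction": indeterminate}
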