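"""Per-capita physiological rates from raw assay measurements.

Oxygen time series from respirometry vials are reduced to OLS slopes; the
block-matched control mean is subtracted and the difference scaled by the
organism denominator (cell density for algae, live daphnids for the
consumer). Grazing assays yield per-capita raw ingestion from start/end
cell densities corrected by the control density change. Energy conversions
use the oxycaloric equivalent (14.06 J per mg O2) and a unitless
assimilation efficiency.

Unit tags are carried on every estimate; cross-unit arithmetic without an
explicit conversion raises :class:`~thermomatch.errors.UnitsError`. Control
corrections only ever use controls from the replicate's own temporal block;
a missing block raises rather than silently pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ML_PER_L, MINUTES_PER_HOUR, OXYGEN_TO_JOULES
from .errors import BlockMatchingError, DomainError, InputError, UnitsError

__all__ = [
    "ReplicateOxygenSeries",
    "IngestionReplicate",
    "RateEstimate",
    "oxygen_slope",
    "respiration_rate",
    "net_photosynthesis_rate",
    "ingestion_raw",
    "respiration_to_energy",
    "energy_to_respiration",
    "ingestion_to_energy",
    "volume_corrected",
    "oxygen_rates",
    "ingestion_rates",
    "oxygen_series_from_frame",
    "ingestion_replicates_from_frame",
    "rates_to_frame",
]

# Canonical unit tags.
U_O2_CELL = "mg_O2_per_L_per_min_per_cell"
U_O2_DAPHNID = "mg_O2_per_L_per_min_per_daphnid"
U_CELLS_DAPHNID = "cells_per_mL_per_h_per_daphnid"
U_ENERGY_DAPHNID = "J_per_L_per_h_per_daphnid"


@dataclass(frozen=True)
class ReplicateOxygenSeries:
    """One vial's timed oxygen readings with block/role metadata.

    ``denominator`` is cells per mL for algal vials or the count of live
    individuals at the start for consumer vials; it is ignored (and may be
    zero) for controls.
    """

    replicate_id: str
    block: str
    role: str  # "organism" | "control"
    temperature_c: float
    times_min: np.ndarray
    oxygen_mg_per_l: np.ndarray
    denominator: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        o = np.asarray(self.oxygen_mg_per_l, dtype=float)
        if self.role not in ("organism", "control"):
            raise InputError(f"role must be organism|control, got {self.role!r}")
        if t.size < 3 or o.size != t.size:
            raise InputError("need >= 3 paired time/oxygen readings")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if self.role == "organism" and not self.denominator > 0:
            raise InputError("organism vials need a positive denominator")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "oxygen_mg_per_l", o)


@dataclass(frozen=True)
class IngestionReplicate:
    """Start/end algal densities for one grazing-assay vial."""

    replicate_id: str
    block: str
    temperature_c: float
    density_t0: float   # cells per mL at assay start
    density_t_end: float  # cells per mL at assay end
    n_consumers: int    # live daphnids at start (0 for controls)
    duration_min: float = 150.0
    role: str = "organism"

    def __post_init__(self):
        if self.density_t0 < 0 or self.density_t_end < 0:
            raise InputError("densities must be non-negative")
        if self.duration_min <= 0:
            raise InputError("assay duration must be positive")
        if self.role == "organism" and self.n_consumers < 1:
            raise InputError("treatment vials need >= 1 live consumer at start")


@dataclass(frozen=True)
class RateEstimate:
    """A per-capita physiological rate at one assay temperature."""

    temperature_c: float
    value: float
    units: str
    rate_kind: str
    block: str = ""
    replicate_id: str = ""
    flags: tuple = field(default_factory=tuple)


def oxygen_slope(series: ReplicateOxygenSeries) -> float:
    """OLS slope of oxygen (mg O2 L^-1) against time (min) for one vial."""
    t = series.times_min
    if np.ptp(t) == 0:
        raise InputError("degenerate time axis (zero variance)")
    return float(stats.linregress(t, series.oxygen_mg_per_l).slope)


def _control_mean(control_slopes: Sequence[float]) -> float:
    slopes = np.asarray(list(control_slopes), dtype=float)
    if slopes.size == 0:
        raise BlockMatchingError("no control slopes from the same temporal block")
    return float(slopes.mean())


def respiration_rate(m_t, control_slopes, d, *, units=U_O2_DAPHNID, **meta) -> RateEstimate:
    """Per-capita respiration: ``-1 * (m_t - mean(controls)) / d``.

    Positive when the organism vial loses oxygen faster than its
    block-matched controls. Negative corrected rates are retained (they occur
    for weakly-respiring algae when the control mean exceeds the vial slope);
    they are flagged, never dropped.
    """
    if not d > 0:
        raise InputError(f"denominator must be positive, got {d!r}")
    value = -1.0 * (m_t - _control_mean(control_slopes)) / d
    flags = ("negative_rate",) if value < 0 else ()
    return RateEstimate(meta.pop("temperature_c", np.nan), value, units,
                        "respiration", flags=flags, **meta)


def net_photosynthesis_rate(m_t, control_slopes, d, *, units=U_O2_CELL, **meta) -> RateEstimate:
    """Per-capita net photosynthesis: ``(m_t - mean(controls)) / d``.

    Same correction as respiration but without the sign flip, so the rate is
    positive under net oxygen production.
    """
    if not d > 0:
        raise InputError(f"denominator must be positive, got {d!r}")
    value = (m_t - _control_mean(control_slopes)) / d
    flags = ("negative_rate",) if value < 0 else ()
    return RateEstimate(meta.pop("temperature_c", np.nan), value, units,
                        "net_photosynthesis", flags=flags, **meta)


def ingestion_raw(rep: IngestionReplicate,
                  controls_t0: Sequence[float],
                  controls_t_end: Sequence[float]) -> RateEstimate:
    """Per-capita raw ingestion (cells mL^-1 h^-1 per consumer).

    rI = (D_T0 - D_Tend + (mean(C_Tend) - mean(C_T0))) / (y * t), with t in
    hours. The control term credits the consumer for resource growth (or
    debits settling) observed without consumers.
    """
    c0 = np.asarray(list(controls_t0), dtype=float)
    c1 = np.asarray(list(controls_t_end), dtype=float)
    if c0.size == 0 or c1.size == 0:
        raise BlockMatchingError("ingestion correction needs same-block controls")
    if rep.n_consumers < 1:
        raise InputError("per-capita rate undefined without live consumers")
    t_h = rep.duration_min / MINUTES_PER_HOUR
    value = (rep.density_t0 - rep.density_t_end + (c1.mean() - c0.mean())) / (
        rep.n_consumers * t_h)
    return RateEstimate(rep.temperature_c, value, U_CELLS_DAPHNID, "ingestion",
                        block=rep.block, replicate_id=rep.replicate_id)


def respiration_to_energy(rate: RateEstimate) -> RateEstimate:
    """mg O2 L^-1 min^-1 -> J L^-1 h^-1 via 14.06 J per mg O2 and 60 min/h."""
    if rate.units != U_O2_DAPHNID:
        raise UnitsError(f"expected {U_O2_DAPHNID}, got {rate.units}")
    return replace(rate, value=rate.value * OXYGEN_TO_JOULES * MINUTES_PER_HOUR,
                   units=U_ENERGY_DAPHNID)


def energy_to_respiration(rate: RateEstimate) -> RateEstimate:
    """Inverse of :func:`respiration_to_energy`."""
    if rate.units != U_ENERGY_DAPHNID:
        raise UnitsError(f"expected {U_ENERGY_DAPHNID}, got {rate.units}")
    return replace(rate, value=rate.value / (OXYGEN_TO_JOULES * MINUTES_PER_HOUR),
                   units=U_O2_DAPHNID)


def ingestion_to_energy(rate: RateEstimate, per_cell_energy_j: float,
                        assimilation: float) -> RateEstimate:
    """Assimilated ingestion in energy units.

    I^E = rI * per_cell_energy * assimilation, with a single mL -> L scaling
    (densities are per mL, energy rates per L) applied here and nowhere else.
    """
    if rate.units != U_CELLS_DAPHNID:
        raise UnitsError(f"expected {U_CELLS_DAPHNID}, got {rate.units}")
    if not 0.0 < assimilation <= 1.0:
        raise DomainError(f"assimilation efficiency must be in (0,1], got {assimilation!r}")
    value = rate.value * per_cell_energy_j * assimilation * ML_PER_L
    return replace(rate, value=value, units=U_ENERGY_DAPHNID)


def volume_corrected(rate: RateEstimate, volume_l: float) -> RateEstimate:
    """Convert a per-litre-of-assay-volume rate to an absolute per-individual
    rate by multiplying by the vial volume (litres). Units gain a
    ``volume_corrected.`` prefix so downstream unit checks stay strict."""
    if volume_l <= 0:
        raise DomainError("vial volume must be positive")
    return replace(rate, value=rate.value * volume_l,
                   units="volume_corrected." + rate.units)


# ---------------------------------------------------------------------------
# Collection-level reductions (block discipline enforced here)

def oxygen_rates(series: Iterable[ReplicateOxygenSeries], rate_kind: str,
                 *, units: str | None = None) -> list[RateEstimate]:
    """Reduce a collection of vials to block-corrected per-capita rates.

    Organism vials are grouped by (temperature, block); each is corrected by
    the mean control slope of its own group. Missing controls raise.
    """
    if rate_kind not in ("respiration", "net_photosynthesis"):
        raise DomainError(f"unknown rate_kind {rate_kind!r}")
    series = list(series)
    controls: dict[tuple, list[float]] = {}
    for s in series:
        if s.role == "control":
            controls.setdefault((s.temperature_c, s.block), []).append(oxygen_slope(s))
    out = []
    maker = respiration_rate if rate_kind == "respiration" else net_photosynthesis_rate
    if units is None:
        units = U_O2_DAPHNID if rate_kind == "respiration" else U_O2_CELL
    for s in series:
        if s.role != "organism":
            continue
        key = (s.temperature_c, s.block)
        if key not in controls:
            raise BlockMatchingError(
                f"no controls in block {s.block!r} at {s.temperature_c} degC")
        out.append(maker(oxygen_slope(s), controls[key], s.denominator,
                         units=units, temperature_c=s.temperature_c,
                         block=s.block, replicate_id=s.replicate_id))
    return out


def ingestion_rates(reps: Iterable[IngestionReplicate]) -> list[RateEstimate]:
    """Per-capita raw ingestion for every treatment vial, block-corrected."""
    reps = list(reps)
    ctrl0: dict[tuple, list[float]] = {}
    ctrl1: dict[tuple, list[float]] = {}
    for r in reps:
        if r.role == "control":
            key = (r.temperature_c, r.block)
            ctrl0.setdefault(key, []).append(r.density_t0)
            ctrl1.setdefault(key, []).append(r.density_t_end)
    out = []
    for r in reps:
        if r.role != "organism":
            continue
        key = (r.temperature_c, r.block)
        if key not in ctrl0:
            raise BlockMatchingError(
                f"no ingestion controls in block {r.block!r} at {r.temperature_c} degC")
        out.append(ingestion_raw(r, ctrl0[key], ctrl1[key]))
    return out


# ---------------------------------------------------------------------------
# Tabular round trips (schemas match the CSVs the generators write)

def oxygen_series_from_frame(df: pd.DataFrame) -> list[ReplicateOxygenSeries]:
    out = []
    cols = ["replicate_id", "block", "role", "temperature_C"]
    for key, g in df.groupby(cols, sort=False):
        g = g.sort_values("time_min")
        out.append(ReplicateOxygenSeries(
            replicate_id=str(key[0]), block=str(key[1]), role=str(key[2]),
            temperature_c=float(key[3]),
            times_min=g["time_min"].to_numpy(float),
            oxygen_mg_per_l=g["oxygen_mg_per_L"].to_numpy(float),
            denominator=float(g["n_organisms_or_density"].iloc[0])))
    return out


def ingestion_replicates_from_frame(df: pd.DataFrame) -> list[IngestionReplicate]:
    return [IngestionReplicate(
        replicate_id=str(r.replicate_id), block=str(r.block),
        temperature_c=float(r.temperature_C),
        density_t0=float(r.density_t0_cells_per_mL),
        density_t_end=float(r.density_t150_cells_per_mL),
        n_consumers=int(r.n_consumers), duration_min=float(r.duration_min),
        role=str(r.role)) for r in df.itertuples()]


def rates_to_frame(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rate_kind": e.rate_kind, "temperature_C": e.temperature_c,
        "block": e.block, "replicate_id": e.replicate_id,
        "value": e.value, "units": e.units,
        "flags": ";".join(e.flags),
    } for e in estimates])
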