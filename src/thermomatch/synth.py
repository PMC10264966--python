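"""Seeded synthetic-assay generators.

The generators emulate the *design* of the laboratory assays — blocked
replication (n = 3 per temporal block, two blocks), matched controls at
every temperature, 1-min oxygen readings over 30 min, 150-min grazing
assays — with rates drawn from published thermal-performance summaries, so
that every downstream stage of the pipeline can be exercised end to end
without any deposited data.

A scenario preset bundles the per-rate summaries (unimodal TPC summaries
as (Ea, Eh, Topt, MRP); linear ingestion as slope plus a crossover-
temperature anchor), the assay temperatures and replication, the energy
constants, and a noise model (additive Gaussian on oxygen slopes,
multiplicative log-normal on cell densities, a small common control drift
per block). With all noise terms zero the full rate -> fit pipeline
reproduces the generating parameters exactly; fixed seeds give
byte-identical tables.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_TREF_C, MINUTES_PER_HOUR, ML_PER_L, OXYGEN_TO_JOULES
from .errors import ConfigurationError, DomainError
from .rates import RateEstimate, U_ENERGY_DAPHNID
from .tpc import TPCParams, sharpe_schoolfield, th_from_topt

__all__ = [
    "TPCSummary",
    "LinearSummary",
    "ISLine",
    "NoiseModel",
    "ScenarioPreset",
    "LinearLine",
    "load_preset",
    "list_presets",
    "noise_free",
    "reconstruct_tpc_from_summary",
    "derive_linear_intercept",
    "resolve_linear_line",
    "generate_oxygen_experiment",
    "generate_ingestion_experiment",
    "generate_is_experiment",
    "generate_rate_samples",
]

OXY_T_MAX_MIN = 30.0   # oxygen assay duration, readings every minute
OXY_BASELINE = 8.0     # mg O2 L^-1 starting saturation in every vial


@dataclass(frozen=True)
class TPCSummary:
    """Published TPC point summary: slopes in eV, optimum and peak rate."""

    ea: float
    eh: float
    topt_c: float
    mrp: float
    units: str

    def __post_init__(self):
        if not (self.eh > self.ea > 0):
            raise DomainError(f"require Eh > Ea > 0 (Ea={self.ea}, Eh={self.eh})")
        if not self.mrp > 0:
            raise DomainError("MRP must be positive")
        if not 0.0 <= self.topt_c <= 60.0:
            raise DomainError(f"implausible Topt {self.topt_c} degC")


@dataclass(frozen=True)
class LinearSummary:
    """Linear (or flat) rate summary.

    The intercept may be given directly or pinned through a crossover
    temperature: the published figure for an ingestion line is where the
    gain/loss ratio crosses 1, which fixes the unprinted intercept as
    intercept = loss(Tc) - slope * Tc.
    """

    slope: float
    units: str
    intercept: float | None = None
    tc_anchor_c: float | None = None
    zero_slope: bool = False

    def __post_init__(self):
        if (self.intercept is None) == (self.tc_anchor_c is None):
            raise ConfigurationError(
                "provide exactly one of intercept / tc_anchor_c")
        if self.zero_slope and self.slope != 0.0:
            raise ConfigurationError("zero_slope set but slope != 0")


class ISLine(NamedTuple):
    """Interaction-strength line: IS(T) = anchor_is + slope * (T - anchor_t)."""

    slope_per_c: float
    anchor_t_c: float
    anchor_is: float
    noise_sd: float

    def __call__(self, temp_c):
        return self.anchor_is + self.slope_per_c * (np.asarray(temp_c, float)
                                                    - self.anchor_t_c)


@dataclass(frozen=True)
class NoiseModel:
    slope_noise_sd: float | None = None  # None -> 10% of signal at Topt
    density_cv: float = 0.05
    control_drift_sd: float = 0.0
    control_density_drift_per_h: float = 0.0  # signed fraction per hour

    def __post_init__(self):
        for name in ("slope_noise_sd", "density_cv", "control_drift_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    species_name: str
    kind: str  # "resource" | "pair"
    rate_presets: dict
    assay_temperatures_c: tuple
    replicates_per_block: int = 3
    n_blocks: int = 2
    noise: NoiseModel = field(default_factory=NoiseModel)
    oxygen_assay_density: float | None = None
    initial_density: float | None = None
    assimilation_efficiency: float | None = None
    per_cell_energy_j: float | None = None
    n_consumers_per_vial: int = 5
    dead_consumer_rate: float = 0.0
    ingestion_duration_min: float = 150.0
    is_line: ISLine | None = None
    resource_preset: str | None = None

    def __post_init__(self):
        temps = tuple(float(t) for t in self.assay_temperatures_c)
        if len(set(temps)) != len(temps):
            raise ConfigurationError("assay temperatures must be distinct")
        if self.replicates_per_block < 1 or self.n_blocks < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if self.assimilation_efficiency is not None and not (
                0.0 < self.assimilation_efficiency <= 1.0):
            raise ConfigurationError("assimilation efficiency must be in (0,1]")
        object.__setattr__(self, "assay_temperatures_c", temps)


def _summary_from_dict(d: dict):
    if d["model"] == "tpc":
        return TPCSummary(ea=float(d["Ea_eV"]), eh=float(d["Eh_eV"]),
                          topt_c=float(d["Topt_C"]), mrp=float(d["MRP"]),
                          units=str(d["units"]))
    if d["model"] == "linear":
        return LinearSummary(slope=float(d["slope"]),
                             tc_anchor_c=float(d["tc_anchor_C"]),
                             zero_slope=bool(d.get("zero_slope", False)),
                             units=str(d["units"]))
    raise ConfigurationError(f"unknown rate model {d['model']!r}")


def list_presets() -> list[str]:
    root = _resources.files("thermomatch") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioPreset:
    """Load a shipped scenario preset by name (see :func:`list_presets`)."""
    path = _resources.files("thermomatch") / "presets" / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError as exc:
        raise ConfigurationError(f"no preset named {name!r}") from exc
    noise = NoiseModel(**{
        "slope_noise_sd": raw["noise"].get("slope_noise_sd"),
        "density_cv": float(raw["noise"].get("density_cv", 0.05)),
        "control_drift_sd": float(raw["noise"].get("control_drift_sd", 0.0)),
        "control_density_drift_per_h": float(
            raw["noise"].get("control_density_drift_per_h", 0.0)),
    })
    is_line = None
    if "is_line" in raw:
        il = raw["is_line"]
        is_line = ISLine(float(il["slope_per_C"]), float(il["anchor_T_C"]),
                         float(il["anchor_IS"]), float(il["noise_sd"]))
    return ScenarioPreset(
        name=name,
        species_name=str(raw["species_name"]),
        kind=str(raw["kind"]),
        rate_presets={k: _summary_from_dict(v)
                      for k, v in raw["rate_presets"].items()},
        assay_temperatures_c=tuple(raw["assay_temperatures_C"]),
        replicates_per_block=int(raw["replicates_per_block"]),
        n_blocks=int(raw["n_blocks"]),
        noise=noise,
        oxygen_assay_density=_opt_float(raw.get("oxygen_assay_density_cells_per_mL")),
        initial_density=_opt_float(raw.get("initial_density_cells_per_mL")),
        assimilation_efficiency=_opt_float(raw.get("assimilation_efficiency")),
        per_cell_energy_j=_opt_float(raw.get("per_cell_energy_J")),
        n_consumers_per_vial=int(raw.get("n_consumers_per_vial", 5)),
        dead_consumer_rate=float(raw.get("dead_consumer_rate", 0.0)),
        ingestion_duration_min=float(raw.get("ingestion_duration_min", 150.0)),
        is_line=is_line,
        resource_preset=raw.get("resource_preset"),
    )


def _opt_float(v):
    return None if v is None else float(v)


def noise_free(preset: ScenarioPreset) -> ScenarioPreset:
    """Copy of a preset with every stochastic term zeroed (exact round trips)."""
    from dataclasses import replace
    il = preset.is_line
    return replace(
        preset,
        noise=NoiseModel(0.0, 0.0, 0.0, 0.0),
        dead_consumer_rate=0.0,
        is_line=None if il is None else il._replace(noise_sd=0.0))


# ---------------------------------------------------------------------------
# Summary -> curve reconstruction

def reconstruct_tpc_from_summary(summary: TPCSummary,
                                 tref: float = DEFAULT_TREF_C) -> TPCParams:
    """Full parameter set from an (Ea, Eh, Topt, MRP) summary.

    th is solved from the closed-form optimum relation, then r_tref is
    scaled so the curve attains exactly MRP at Topt.
    """
    th = th_from_topt(summary.ea, summary.eh, summary.topt_c)
    unit_peak = sharpe_schoolfield(summary.topt_c, 1.0, summary.ea,
                                   summary.eh, th, tref)
    return TPCParams(summary.mrp / unit_peak, summary.ea, summary.eh, th, tref)


class LinearLine(NamedTuple):
    slope: float
    intercept: float

    def __call__(self, temp_c):
        return self.intercept + self.slope * np.asarray(temp_c, dtype=float)


def derive_linear_intercept(linear: LinearSummary,
                            loss_curve: Callable[[float], float]) -> float:
    """Pin the line's intercept so gain/loss = 1 at the crossover anchor."""
    if linear.intercept is not None:
        return linear.intercept
    tc = linear.tc_anchor_c
    return float(loss_curve(tc)) - linear.slope * tc


def resolve_linear_line(linear: LinearSummary,
                        loss_curve: Callable | None = None) -> LinearLine:
    if linear.intercept is None and loss_curve is None:
        raise ConfigurationError(
            "anchored line needs the loss curve to derive its intercept")
    return LinearLine(linear.slope, derive_linear_intercept(linear, loss_curve))


def consumer_gain_loss(preset: ScenarioPreset,
                       tref: float = DEFAULT_TREF_C) -> tuple[LinearLine, TPCParams]:
    """(ingestion line, respiration TPC) for a pair preset, energy units."""
    if preset.kind != "pair":
        raise ConfigurationError("consumer curves require a pair preset")
    loss = reconstruct_tpc_from_summary(preset.rate_presets["respiration"], tref)
    gain = resolve_linear_line(preset.rate_presets["ingestion"], loss)
    return gain, loss


def resource_gain_loss(preset: ScenarioPreset,
                       tref: float = DEFAULT_TREF_C) -> tuple[TPCParams, TPCParams]:
    """(net photosynthesis, respiration) TPCs for a resource preset."""
    if preset.kind != "resource":
        raise ConfigurationError("resource curves require a resource preset")
    return (reconstruct_tpc_from_summary(preset.rate_presets["net_photosynthesis"], tref),
            reconstruct_tpc_from_summary(preset.rate_presets["respiration"], tref))


# ---------------------------------------------------------------------------
# Generators

def _rate_in_oxygen_units(summary: TPCSummary, tref: float):
    """Curve callable in mg O2 L^-1 min^-1 (converting from energy units if
    the summary is tabulated energetically, as consumer respiration is)."""
    params = reconstruct_tpc_from_summary(summary, tref)
    if summary.units == U_ENERGY_DAPHNID:
        factor = 1.0 / (OXYGEN_TO_JOULES * MINUTES_PER_HOUR)
    else:
        factor = 1.0
    return lambda t: params(t) * factor, params, factor


def _alive(rng, preset: ScenarioPreset) -> int:
    n = preset.n_consumers_per_vial
    if preset.dead_consumer_rate > 0:
        n -= int(rng.binomial(n - 1, preset.dead_consumer_rate))
    return n


def generate_oxygen_experiment(preset: ScenarioPreset, rate_kind: str,
                               seed=None, tref: float = DEFAULT_TREF_C) -> pd.DataFrame:
    """Blocked oxygen time series (organism + matched control vials).

    Each organism vial's oxygen trace is linear with slope
    ``sign * rate(T) * d + block drift + Gaussian noise`` (sign is negative
    for respiration, positive for net photosynthesis); controls carry the
    block drift and noise only. Readings every minute for 30 min.
    """
    if rate_kind not in preset.rate_presets:
        raise ConfigurationError(f"{preset.name} has no {rate_kind!r} preset")
    summary = preset.rate_presets[rate_kind]
    if not isinstance(summary, TPCSummary):
        raise ConfigurationError(f"{rate_kind!r} is not a unimodal (TPC) rate")
    rate_o2, params, _ = _rate_in_oxygen_units(summary, tref)
    sign = -1.0 if rate_kind == "respiration" else 1.0
    consumer = preset.kind == "pair"
    d_nominal = (preset.n_consumers_per_vial if consumer
                 else preset.oxygen_assay_density)
    if d_nominal is None:
        raise ConfigurationError("preset lacks an oxygen-assay denominator")
    sd = preset.noise.slope_noise_sd
    if sd is None:
        sd = 0.1 * abs(rate_o2(summary.topt_c)) * d_nominal

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, OXY_T_MAX_MIN + 0.5, 1.0)
    rows = []
    for b in range(1, preset.n_blocks + 1):
        block = f"B{b}"
        drift = rng.normal(0.0, preset.noise.control_drift_sd)
        for temp in preset.assay_temperatures_c:
            for i in range(1, preset.replicates_per_block + 1):
                d = _alive(rng, preset) if consumer else d_nominal
                m = sign * rate_o2(temp) * d + drift + rng.normal(0.0, sd)
                _append_series(rows, f"{block}-T{temp:g}-org{i}", block,
                               "organism", temp, times, m, d)
                mc = drift + rng.normal(0.0, sd)
                _append_series(rows, f"{block}-T{temp:g}-ctl{i}", block,
                               "control", temp, times, mc, 0.0)
    return pd.DataFrame(rows)


def _append_series(rows, rid, block, role, temp, times, slope, denom):
    oxy = OXY_BASELINE + slope * times
    for t, o in zip(times, oxy):
        rows.append({"replicate_id": rid, "block": block, "role": role,
                     "temperature_C": temp, "time_min": t,
                     "oxygen_mg_per_L": o, "n_organisms_or_density": denom})


def _measured(rng, true_value, cv):
    """Multiplicative log-normal measurement with unit mean and the given CV."""
    if cv == 0.0:
        return float(true_value)
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(true_value * rng.lognormal(-0.5 * sigma * sigma, sigma))


def generate_ingestion_experiment(preset: ScenarioPreset, seed=None,
                                  tref: float = DEFAULT_TREF_C) -> pd.DataFrame:
    """Grazing-assay start/end densities for treatment and control vials.

    Treatment vials lose ``rI * y * t`` cells on top of the shared control
    drift, where rI (cells mL^-1 h^-1 per consumer) is back-computed from
    the preset's anchored ingestion energy line so the published slope is
    recovered after the control correction and energy conversion.
    """
    if preset.kind != "pair":
        raise ConfigurationError("ingestion assays require a pair preset")
    gain_line, _ = consumer_gain_loss(preset, tref)
    to_cells = 1.0 / (preset.per_cell_energy_j
                      * preset.assimilation_efficiency * ML_PER_L)
    t_h = preset.ingestion_duration_min / MINUTES_PER_HOUR
    drift = preset.noise.control_density_drift_per_h
    cv = preset.noise.density_cv
    d0 = preset.initial_density

    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, preset.n_blocks + 1):
        block = f"B{b}"
        for temp in preset.assay_temperatures_c:
            delta_ctrl = d0 * drift * t_h
            for i in range(1, preset.replicates_per_block + 1):
                rows.append(_ing_row(f"{block}-T{temp:g}-ctl{i}", block, temp,
                                     "control", _measured(rng, d0, cv),
                                     _measured(rng, d0 + delta_ctrl, cv), 0,
                                     preset.ingestion_duration_min))
            for i in range(1, preset.replicates_per_block + 1):
                y = _alive(rng, preset)
                ri_cells = float(gain_line(temp)) * to_cells
                end = d0 + delta_ctrl - ri_cells * y * t_h
                rows.append(_ing_row(f"{block}-T{temp:g}-org{i}", block, temp,
                                     "organism", _measured(rng, d0, cv),
                                     _measured(rng, end, cv), y,
                                     preset.ingestion_duration_min))
    return pd.DataFrame(rows)


def _ing_row(rid, block, temp, role, dens0, dens1, y, dur):
    return {"replicate_id": rid, "block": block, "temperature_C": temp,
            "role": role, "density_t0_cells_per_mL": dens0,
            "density_t150_cells_per_mL": dens1, "n_consumers": y,
            "duration_min": dur}


def generate_is_experiment(preset: ScenarioPreset, seed=None) -> pd.DataFrame:
    """Grazing-assay densities whose log response ratio follows the preset's
    interaction-strength line.

    Per replicate an IS value is drawn as line(T) + Gaussian noise and the
    treatment end density set to ``N * exp(-IS * y * t)`` against the block's
    control mean N, so the Dynamic Index recovers the draw exactly. Kept
    separate from :func:`generate_ingestion_experiment`: the ingestion energy
    slope and the IS slope are different transforms of the same densities and
    cannot both be encoded exactly by a single generating process.
    """
    if preset.kind != "pair" or preset.is_line is None:
        raise ConfigurationError("IS generation requires a pair preset with is_line")
    line = preset.is_line
    t_h = preset.ingestion_duration_min / MINUTES_PER_HOUR
    cv = preset.noise.density_cv
    d0 = preset.initial_density
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, preset.n_blocks + 1):
        block = f"B{b}"
        for temp in preset.assay_temperatures_c:
            ctrl_end = [_measured(rng, d0, cv)
                        for _ in range(preset.replicates_per_block)]
            for i, c in enumerate(ctrl_end, start=1):
                rows.append(_ing_row(f"{block}-T{temp:g}-ctl{i}", block, temp,
                                     "control", _measured(rng, d0, cv), c, 0,
                                     preset.ingestion_duration_min))
            n_mean = float(np.mean(ctrl_end))
            for i in range(1, preset.replicates_per_block + 1):
                y = _alive(rng, preset)
                is_val = float(line(temp)) + rng.normal(0.0, line.noise_sd)
                d_end = n_mean * np.exp(-is_val * y * t_h)
                rows.append(_ing_row(f"{block}-T{temp:g}-org{i}", block, temp,
                                     "organism", _measured(rng, d0, cv),
                                     d_end, y, preset.ingestion_duration_min))
    return pd.DataFrame(rows)


def generate_rate_samples(preset: ScenarioPreset, rate_kind: str,
                          n_per_temp: int = 6, cv: float = 0.1, seed=None,
                          tref: float = DEFAULT_TREF_C) -> list[RateEstimate]:
    """Per-capita rate draws straight from the reconstructed curve.

    Multiplicative log-normal noise with unit mean and the given CV, at each
    assay temperature; the short route for parameter-recovery studies that
    bypasses the raw-assay emulation.
    """
    summary = preset.rate_presets.get(rate_kind)
    if not isinstance(summary, TPCSummary):
        raise ConfigurationError(f"{rate_kind!r} is not a unimodal (TPC) rate")
    params = reconstruct_tpc_from_summary(summary, tref)
    rng = np.random.default_rng(seed)
    out = []
    n_half = max(1, n_per_temp // preset.n_blocks)
    for temp in preset.assay_temperatures_c:
        for i in range(n_per_temp):
            block = f"B{i // n_half + 1}"
            out.append(RateEstimate(
                temperature_c=temp,
                value=_measured(rng, params(temp), cv),
                units=summary.units, rate_kind=rate_kind, block=block,
                replicate_id=f"{block}-T{temp:g}-r{i + 1}"))
    return out
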