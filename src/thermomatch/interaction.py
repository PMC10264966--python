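"""Per-capita interaction strength (Dynamic Index) and its thermal trend.

The Dynamic Index is the per-capita, per-hour log response ratio
``IS = ln(N/D) / (y t)`` with N the block-matched control-mean resource
density at assay end, D the density with consumers present, y the live
consumers and t the assay duration in hours. It needs no equilibrium
assumption, which suits 150-min grazing assays, and is positive when
consumers depress resource density.

IS records from both consumer-resource pairs enter one GLM with a
temperature x resource-species interaction (two-way ANOVA, Type II sums of
squares) plus per-pair regressions for the printed slopes; the fitted
trends are then checked for concordance against the CREB-based prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .constants import MINUTES_PER_HOUR
from .errors import BlockMatchingError, InputError
from .rates import IngestionReplicate

__all__ = [
    "ISRecord",
    "ISModel",
    "dynamic_index",
    "is_records_from_replicates",
    "is_regression",
    "concordance",
]


@dataclass(frozen=True)
class ISRecord:
    pair: str
    temperature_c: float
    block: str
    value: float  # h^-1 consumer^-1
    n_controls_used: int = 0
    replicate_id: str = ""


def dynamic_index(n: float, d: float, y: int, t_h: float) -> float:
    """``ln(N/D) / (y t)``; antisymmetric under swapping N and D."""
    if d <= 0:
        raise InputError("treatment density must be positive (log undefined)")
    if n <= 0:
        raise InputError("control-mean density must be positive")
    if y < 1 or t_h <= 0:
        raise InputError("need >= 1 consumer and a positive duration")
    return float(np.log(n / d) / (y * t_h))


def is_records_from_replicates(reps: Iterable[IngestionReplicate],
                               pair: str) -> list[ISRecord]:
    """Dynamic Index per treatment vial, against same-block control means."""
    reps = list(reps)
    ctrl: dict[tuple, list[float]] = {}
    for r in reps:
        if r.role == "control":
            ctrl.setdefault((r.temperature_c, r.block), []).append(r.density_t_end)
    out = []
    for r in reps:
        if r.role != "organism":
            continue
        key = (r.temperature_c, r.block)
        if key not in ctrl:
            raise BlockMatchingError(
                f"no IS controls in block {r.block!r} at {r.temperature_c} degC")
        n = float(np.mean(ctrl[key]))
        t_h = r.duration_min / MINUTES_PER_HOUR
        out.append(ISRecord(pair=pair, temperature_c=r.temperature_c,
                            block=r.block,
                            value=dynamic_index(n, r.density_t_end,
                                                r.n_consumers, t_h),
                            n_controls_used=len(ctrl[key]),
                            replicate_id=r.replicate_id))
    return out


@dataclass(frozen=True)
class ISModel:
    """Per-pair slopes plus the temperature x species interaction test."""

    slopes: dict  # pair -> {"beta", "se", "p_value", "intercept"}
    interaction_f: float
    interaction_df: tuple
    interaction_p: float
    residual_sd: float
    n_obs: int


def is_regression(records: Sequence[ISRecord]) -> ISModel:
    """Full GLM of IS on temperature, species, and their interaction.

    The interaction F (Type II ANOVA) tests whether the two pairs' thermal
    slopes differ; per-pair OLS fits supply the individual slopes and
    p-values. Centring temperature leaves the interaction F unchanged.
    """
    records = list(records)
    df = pd.DataFrame([{"pair": r.pair, "temperature": r.temperature_c,
                        "value": r.value} for r in records])
    if df.empty or df["pair"].nunique() < 1:
        raise InputError("no IS records")
    for pair, g in df.groupby("pair"):
        if g["temperature"].nunique() < 2:
            raise InputError(f"pair {pair!r} has < 2 assay temperatures")
    slopes = {}
    for pair, g in df.groupby("pair"):
        res = sm.OLS(g["value"].to_numpy(),
                     sm.add_constant(g["temperature"].to_numpy())).fit()
        slopes[pair] = {"intercept": float(res.params[0]),
                        "beta": float(res.params[1]),
                        "se": float(res.bse[1]),
                        "p_value": float(res.pvalues[1])}
    if df["pair"].nunique() >= 2:
        full = smf.ols("value ~ temperature * C(pair)", data=df).fit()
        an = anova_lm(full, typ=2)
        row = an.loc["temperature:C(pair)"]
        inter_f = float(row["F"])
        inter_p = float(row["PR(>F)"])
        inter_df = (int(row["df"]), int(an.loc["Residual", "df"]))
        resid_sd = float(np.sqrt(full.mse_resid))
    else:
        inter_f, inter_p, inter_df = np.nan, np.nan, (0, 0)
        resid_sd = float(df["value"].std())
    return ISModel(slopes=slopes, interaction_f=inter_f,
                   interaction_df=inter_df, interaction_p=inter_p,
                   residual_sd=resid_sd, n_obs=int(len(df)))


def concordance(predicted: dict | str, model: ISModel, pair: str,
                alpha: float = 0.05) -> str:
    """Compare the CREB-based prediction with the fitted IS slope.

    Returns ``agree`` / ``disagree`` / ``inconclusive``. A significant slope
    is compared by sign against a directional prediction; a non-significant
    slope agrees with a constant-or-* prediction and is inconclusive against
    a directional one.
    """
    trend = predicted["predicted_is_trend"] if isinstance(predicted, dict) else predicted
    info = model.slopes.get(pair)
    if info is None:
        raise InputError(f"model has no slope for pair {pair!r}")
    significant = info["p_value"] < alpha
    direction = "increasing" if info["beta"] > 0 else "decreasing"
    if trend in ("decreasing", "increasing"):
        if not significant:
            return "inconclusive"
        return "agree" if direction == trend else "disagree"
    if trend == "constant_or_increasing":
        if not significant:
            return "agree"
        return "agree" if direction == "increasing" else "disagree"
    if trend == "constant_or_decreasing":
        if not significant:
            return "agree"
        return "agree" if direction == "decreasing" else "disagree"
    raise InputError(f"unknown predicted trend {trend!r}")
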