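"""Reconstruction-based mismatch analysis straight from published summaries.

No raw data enters here: the TPCs are rebuilt from (Ea, Eh, Topt, MRP)
point summaries, ingestion lines are pinned at their published crossover
temperatures, and the balance/mismatch/CREB machinery runs on the
reconstructed curves. This is the desk-scale route to every deterministic
quantity: species Tm and Tc, intra- and inter-specific mismatch regions,
the CREB trend, and the predicted interaction-strength trend.
"""

from __future__ import annotations

from .constants import DEFAULT_TREF_C
from .mismatch import (BalanceCurve, classify_trend, creb, energetic_balance,
                       find_Tc, find_Tm, inter_tm, intra_tm, predict_is_trend)
from .models import predict_grid
from .synth import consumer_gain_loss, load_preset, resource_gain_loss

__all__ = ["resource_balance_curve", "consumer_balance_curve",
           "reconstruction_report"]


def resource_balance_curve(preset_name: str, t_min=None, t_max=None,
                           step: float = 0.001,
                           tref: float = DEFAULT_TREF_C) -> BalanceCurve:
    """P/R_r balance of a resource preset on its (or a given) assay range."""
    preset = load_preset(preset_name)
    gain, loss = resource_gain_loss(preset, tref)
    t_min = min(preset.assay_temperatures_c) if t_min is None else t_min
    t_max = max(preset.assay_temperatures_c) if t_max is None else t_max
    return energetic_balance(predict_grid(gain, t_min, t_max, step),
                             predict_grid(loss, t_min, t_max, step),
                             species=preset.species_name,
                             gain_kind="net_photosynthesis",
                             loss_kind="respiration")


def consumer_balance_curve(pair_name: str, t_min=None, t_max=None,
                           step: float = 0.001,
                           tref: float = DEFAULT_TREF_C) -> BalanceCurve:
    """I/R_c balance of a pair preset, ingestion pinned at its crossover."""
    preset = load_preset(pair_name)
    gain, loss = consumer_gain_loss(preset, tref)
    t_min = min(preset.assay_temperatures_c) if t_min is None else t_min
    t_max = max(preset.assay_temperatures_c) if t_max is None else t_max
    return energetic_balance(predict_grid(gain, t_min, t_max, step),
                             predict_grid(loss, t_min, t_max, step),
                             species=preset.species_name,
                             gain_kind="ingestion", loss_kind="respiration")


def _species_entry(bal: BalanceCurve, window_c: float) -> dict:
    tm, on_edge, diverges = find_Tm(bal)
    tc, deficit = find_Tc(bal)
    return {"Tm_C": tm, "Tm_on_boundary": on_edge,
            "ratio_diverges_at_edge": diverges, "Tc_C": tc,
            "always_deficit": deficit,
            "intra_TM_intervals_C": intra_tm(bal, window_c)}


def reconstruction_report(pair_name: str, step: float = 0.001,
                          window_c: float = 0.5,
                          eps_fraction: float = 0.01,
                          tref: float = DEFAULT_TREF_C) -> dict:
    """Full deterministic mismatch report for one consumer-resource pair."""
    pair = load_preset(pair_name)
    res_name = pair.resource_preset
    t_lo, t_hi = min(pair.assay_temperatures_c), max(pair.assay_temperatures_c)

    res_own = resource_balance_curve(res_name, step=step, tref=tref)
    res_common = resource_balance_curve(res_name, t_lo, t_hi, step, tref)
    con = consumer_balance_curve(pair_name, t_lo, t_hi, step, tref)

    regions = inter_tm(con, res_common, window_c)
    creb_curve = creb(con, res_common)
    trend = classify_trend(creb_curve, eps_fraction, window_c)
    return {
        "pair": pair_name,
        "resource": {res_name: _species_entry(res_own, window_c)},
        "consumer": _species_entry(con, window_c),
        "inter_TM": {"region1_C": regions.region1,
                     "region2_C": regions.region2,
                     "onset_C": regions.onset_c},
        "creb_trend": trend,
        **predict_is_trend(trend),
    }
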