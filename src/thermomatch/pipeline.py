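"""One-command pipeline: simulate -> rates -> fits -> mismatch -> interaction.

``run_all`` executes the whole analysis for both consumer-resource pairs on
synthetic assays, mirroring the study's order: generate (or load) raw
measurements, reduce them to per-capita rates, fit TPCs and ingestion
lines, build energetic balances and mismatch reports, compute CREBs and
their predicted interaction-strength trends, measure interaction strength,
and check concordance. Outputs are CSV tables plus a JSON summary and a
run manifest recording versions, seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_csv
from .constants import DEFAULT_TREF_C
from .errors import ConfigurationError
from .interaction import concordance, is_records_from_replicates, is_regression
from .mismatch import (classify_trend, creb, energetic_balance, find_Tc,
                       find_Tm, inter_tm, intra_tm, predict_is_trend)
from .models import bootstrap_cis, fit_linear_rate, fit_tpc, predict_grid
from .rates import (ingestion_rates, ingestion_replicates_from_frame,
                    ingestion_to_energy, oxygen_rates, oxygen_series_from_frame,
                    rates_to_frame, respiration_to_energy)
from .synth import (generate_ingestion_experiment, generate_is_experiment,
                    generate_oxygen_experiment, load_preset,
                    noise_free as _noise_free)

log = logging.getLogger("thermomatch")

PAIR_PRESETS = ("daphnia_on_chlamydomonas", "daphnia_on_desmodesmus")


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run depends on."""

    pairs: tuple = PAIR_PRESETS
    tref_c: float = DEFAULT_TREF_C
    grid_step_c: float = 0.001
    n_boot: int = 999
    ci_level: float = 0.95
    alpha: float = 0.05
    trend_eps_fraction: float = 0.01
    smoothing_window_c: float = 0.5
    multistart: int = 20
    seed: int = 0
    noise_free: bool = False
    exclusions: tuple = field(default_factory=tuple)  # replicate_ids to drop
    out_dir: str = "thermomatch_out"

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        cfg = cls(**raw)
        cfg.pairs = tuple(cfg.pairs)
        cfg.exclusions = tuple(cfg.exclusions)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    """Derived, recorded seed per stage (stable across runs)."""
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _fit_bundle(rates, cfg, seed):
    fit = fit_tpc(rates, tref=cfg.tref_c, multistart=cfg.multistart, seed=seed)
    ci = bootstrap_cis(fit, rates, n_boot=cfg.n_boot, level=cfg.ci_level,
                       seed=seed + 1)
    return fit, ci


def _drop_excluded(df, exclusions):
    if exclusions and "replicate_id" in df.columns:
        dropped = df[df["replicate_id"].isin(exclusions)]
        for rid in dropped["replicate_id"].unique():
            log.info("dropped replicate %s (reason=explicit_exclusion)", rid)
        df = df[~df["replicate_id"].isin(exclusions)]
    return df


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline for every configured pair; return summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"pairs": {}, "species": {}}
    seeds_used: dict = {}

    fits_cache: dict = {}
    for pair_name in config.pairs:
        pair = load_preset(pair_name)
        resource = load_preset(pair.resource_preset)
        if config.noise_free:
            pair, resource = _noise_free(pair), _noise_free(resource)

        # --- resource stage: oxygen assays -> rates -> TPC fits -----------
        if resource.name not in fits_cache:
            r_entry = {}
            all_rates = []
            for kind in ("net_photosynthesis", "respiration"):
                s = _stage_seed(config.seed, f"oxy:{resource.name}:{kind}")
                seeds_used[f"oxygen/{resource.name}/{kind}"] = s
                df = generate_oxygen_experiment(resource, kind, seed=s,
                                                tref=config.tref_c)
                df = _drop_excluded(df, config.exclusions)
                write_csv(df, out / f"oxygen_series_{resource.name}_{kind}.csv")
                rates = oxygen_rates(oxygen_series_from_frame(df), kind,
                                     units="mg_O2_per_L_per_min_per_cell")
                all_rates.extend(rates)
                fit, ci = _fit_bundle(rates, config,
                                      _stage_seed(config.seed, f"fit:{resource.name}:{kind}"))
                r_entry[kind] = (fit, ci)
            write_csv(rates_to_frame(all_rates), out / f"rates_{resource.name}.csv")
            fits_cache[resource.name] = r_entry
        r_entry = fits_cache[resource.name]

        # --- consumer stage: respiration TPC + ingestion line -------------
        s = _stage_seed(config.seed, f"oxy:{pair.name}:respiration")
        seeds_used[f"oxygen/{pair.name}/respiration"] = s
        df_resp = generate_oxygen_experiment(pair, "respiration", seed=s,
                                             tref=config.tref_c)
        df_resp = _drop_excluded(df_resp, config.exclusions)
        write_csv(df_resp, out / f"oxygen_series_{pair.name}_respiration.csv")
        resp_rates = [respiration_to_energy(r) for r in oxygen_rates(
            oxygen_series_from_frame(df_resp), "respiration")]
        rc_fit, rc_ci = _fit_bundle(resp_rates, config,
                                    _stage_seed(config.seed, f"fit:{pair.name}:respiration"))

        s = _stage_seed(config.seed, f"ingestion:{pair.name}")
        seeds_used[f"ingestion/{pair.name}"] = s
        df_ing = generate_ingestion_experiment(pair, seed=s, tref=config.tref_c)
        df_ing = _drop_excluded(df_ing, config.exclusions)
        write_csv(df_ing, out / f"ingestion_{pair.name}.csv")
        ing_energy = [ingestion_to_energy(r, pair.per_cell_energy_j,
                                          pair.assimilation_efficiency)
                      for r in ingestion_rates(
                          ingestion_replicates_from_frame(df_ing))]
        ing_fit = fit_linear_rate(ing_energy, alpha=config.alpha)
        write_csv(rates_to_frame(resp_rates + ing_energy), out / f"rates_{pair.name}.csv")

        # --- balances, mismatch, CREB --------------------------------------
        t_lo, t_hi = min(pair.assay_temperatures_c), max(pair.assay_temperatures_c)
        rt_lo, rt_hi = (min(resource.assay_temperatures_c),
                        max(resource.assay_temperatures_c))
        step = config.grid_step_c
        win = config.smoothing_window_c

        res_balance = energetic_balance(
            predict_grid(r_entry["net_photosynthesis"][0], rt_lo, rt_hi, step),
            predict_grid(r_entry["respiration"][0], rt_lo, rt_hi, step),
            species=resource.species_name, gain_kind="net_photosynthesis",
            loss_kind="respiration")
        con_balance = energetic_balance(
            predict_grid(ing_fit, t_lo, t_hi, step),
            predict_grid(rc_fit, t_lo, t_hi, step),
            species=pair.species_name, gain_kind="ingestion",
            loss_kind="respiration")
        res_on_pair = energetic_balance(
            predict_grid(r_entry["net_photosynthesis"][0], t_lo, t_hi, step),
            predict_grid(r_entry["respiration"][0], t_lo, t_hi, step),
            species=resource.species_name)

        species_reports = {}
        for label, bal in ((resource.name, res_balance), (pair.name, con_balance)):
            tm, on_edge, diverges = find_Tm(bal)
            tc, deficit = find_Tc(bal)
            species_reports[label] = {
                "Tm_C": tm, "Tm_on_boundary": on_edge,
                "ratio_diverges_at_edge": diverges, "Tc_C": tc,
                "always_deficit": deficit,
                "intra_TM_intervals_C": intra_tm(bal, win),
            }
        summary["species"].update(species_reports)

        regions = inter_tm(con_balance, res_on_pair, win)
        creb_curve = creb(con_balance, res_on_pair)
        trend = classify_trend(creb_curve, config.trend_eps_fraction, win)
        prediction = predict_is_trend(trend)
        write_csv(pd.DataFrame({"temperature_C": creb_curve.temperatures,
                                "creb_value": creb_curve.values}),
                  out / f"creb_{pair.name}.csv")

        summary["pairs"][pair.name] = {
            "consumer_fit": _fit_dict(rc_fit, rc_ci),
            "resource_fits": {k: _fit_dict(*v) for k, v in r_entry.items()},
            "ingestion_line": {
                "slope": ing_fit.slope_, "intercept": ing_fit.intercept_,
                "p_value": ing_fit.p_value_,
                "constrained_zero": ing_fit.constrained_zero_},
            "inter_TM": {"region1_C": regions.region1,
                         "region2_C": regions.region2,
                         "onset_C": regions.onset_c},
            "creb_trend": trend,
            **prediction,
        }

    # --- interaction strength across both pairs ----------------------------
    all_records = []
    for pair_name in config.pairs:
        pair = load_preset(pair_name)
        if config.noise_free:
            pair = _noise_free(pair)
        s = _stage_seed(config.seed, f"is:{pair.name}")
        seeds_used[f"is/{pair.name}"] = s
        df_is = generate_is_experiment(pair, seed=s)
        df_is = _drop_excluded(df_is, config.exclusions)
        write_csv(df_is, out / f"is_assay_{pair.name}.csv")
        all_records.extend(is_records_from_replicates(
            ingestion_replicates_from_frame(df_is), pair.name))
    write_csv(pd.DataFrame([{"pair": r.pair, "temperature_C": r.temperature_c,
                             "block": r.block,
                             "value_per_h_per_daphnid": r.value,
                             "n_controls_used": r.n_controls_used,
                             "replicate_id": r.replicate_id}
                            for r in all_records]), out / "is_records.csv")
    model = is_regression(all_records)
    summary["interaction_model"] = {
        "slopes": model.slopes, "interaction_F": model.interaction_f,
        "interaction_df": model.interaction_df,
        "interaction_p": model.interaction_p, "n_obs": model.n_obs,
    }
    for pair_name in config.pairs:
        entry = summary["pairs"][pair_name]
        entry["is_slope"] = model.slopes[pair_name]["beta"]
        entry["concordance"] = concordance(
            {"predicted_is_trend": entry["predicted_is_trend"]},
            model, pair_name, alpha=config.alpha)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds_used,
    }
    (out / "mismatch_report.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable))
    (out / "is_model.json").write_text(
        json.dumps(summary["interaction_model"], indent=2, default=_jsonable))
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable))
    return summary


def _fit_dict(fit, ci):
    return {"r_tref": fit.r_tref_, "Ea_eV": fit.ea_, "Eh_eV": fit.eh_,
            "th_K": fit.th_, "Topt_C": fit.topt_, "MRP": fit.mrp_,
            "sse": fit.sse_, "n_obs": fit.n_obs_,
            "ci": {k: list(v) for k, v in ci.items()}}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
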