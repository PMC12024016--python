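"""End-to-end assessment pipeline: config in, per-year report out.

The pipeline runs length-weight -> growth (ELEFAN) -> mortality (catch
curve + empirical M) -> LBB -> spatial, per year, and assembles an
:class:`AssessmentReport`. Configuration is a nested dict (typically loaded
from YAML):

.. code-block:: yaml

    seed: 1
    inputs:
      length_frequency: lf.csv       # year,bin_lower_mm,count
      length_weight: lw.csv          # length_mm,weight_g[,sex][,year]
      logbook: logbook.csv           # date,lat,lon,nets,catch_t
    mean_temp_c: 25.0                # scalar or {year: temp}
    elefan:
      linf_range: [30, 50]
      k_range: [0.2, 1.0]
      grid: [40, 40]
    lbb:
      mcmc: {chains: 3, iterations: 20000, burn_in: 5000}
      use_elefan_linf: false         # center the Linf prior on the ELEFAN fit
      priors: {}                     # optional per-year LBBPriors fields
    output_dir: out                  # optional; writes report.json + report.csv

Every stage logs its timing; any stage error aborts with the stage named.
The machine-readable JSON report keeps full precision; the CSV mirror is
rounded the way assessment tables are printed (optimum lengths to integer
cm, ratios to 2 decimals, B/Bmsy to 1 decimal).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, LBStockError
from .growth import ElefanModel, growth_performance
from .lbb import LBBModel, LBBPriors
from .length_weight import LengthWeightModel
from .mortality import estimate_mortality
from .spatial import center_of_gravity, cpue_correlations, grid_aggregate
from .tables import read_length_frequency, read_logbook

__all__ = ["AssessmentReport", "load_config", "run_pipeline", "read_length_weight"]

log = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "mean_temp_c": 25.0,
    "elefan": {"linf_range": [25.0, 50.0], "k_range": [0.2, 1.2],
               "grid": [40, 40], "ma_window": 5},
    "lbb": {"mcmc": {"chains": 3, "iterations": 20_000, "burn_in": 5_000},
            "use_elefan_linf": False, "priors": {}},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg


def read_length_weight(path) -> pd.DataFrame:
    """Length-weight CSV: ``length_mm,weight_g`` with optional ``sex`` and
    ``year`` columns."""
    df = pd.read_csv(path)
    for col in ("length_mm", "weight_g"):
        if col not in df.columns:
            raise FormatError(f"length-weight CSV needs column '{col}'")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric values in column '{col}'")
    if (df["length_mm"] <= 0).any() or (df["weight_g"] <= 0).any():
        raise FormatError("lengths and weights must be positive")
    return df


@dataclass
class AssessmentReport:
    """Per-year assessment blocks plus fleet-wide spatial statistics."""

    years: dict[int, dict] = field(default_factory=dict)
    correlations: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "meta": self.meta,
            "years": {str(y): self.years[y] for y in sorted(self.years)},
            "cpue_correlations": self.correlations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_csv(self, path) -> None:
        """Wide per-year table, display-rounded."""
        rows = {}
        for year in sorted(self.years):
            blk = self.years[year]
            row = {}
            lw = blk.get("length_weight")
            if lw:
                row.update({"a": f"{lw['a']:.3g}", "b": round(lw["b"], 2),
                            "lw_r2": round(lw["r_squared"], 4),
                            "growth_type": lw["growth_type"]})
            gr = blk.get("growth")
            if gr:
                row.update({"Linf_cm": round(gr["linf"], 2), "K": round(gr["k"], 2),
                            "t0": round(gr["t0"], 2),
                            "phi_prime": round(gr["phi_prime"], 2)})
            mo = blk.get("mortality")
            if mo:
                row.update({"Z": round(mo["z"], 2), "M": round(mo["m"], 2),
                            "F": round(mo["f"], 2), "E": round(mo["e"], 2)})
            lb = blk.get("lbb")
            if lb:
                row.update({
                    "LBB_Linf_cm": round(lb["linf"], 1),
                    "Lc_cm": round(lb["lc"], 1),
                    "M_K": round(lb["mk"], 2), "F_K": round(lb["fk"], 2),
                    "Z_K": round(lb["zk"], 2), "F_M": round(lb["fm"], 2),
                    "E_lbb": round(lb["e"], 2),
                    "Lopt_cm": int(round(lb["reference_points"]["l_opt"])),
                    "Lcopt_cm": int(round(lb["reference_points"]["lc_opt"])),
                    "B_B0": round(lb["reference_points"]["bb0"], 2),
                    "B_Bmsy": round(lb["reference_points"]["bbmsy"], 1),
                    "L95_Linf": round(lb["indicators"]["l95_over_linf"], 2),
                    "Lmean_Lcopt": round(lb["indicators"]["lmean_over_lcopt"], 2),
                    "Lc_Lcopt": round(lb["indicators"]["lc_over_lcopt"], 2),
                    "status": lb["status"],
                })
            sp = blk.get("spatial")
            if sp:
                row.update({"cog_lat": round(sp["cog_lat"], 2),
                            "cog_lon": round(sp["cog_lon"], 2),
                            "total_catch_t": round(sp["total_catch_t"], 1),
                            "mean_cpue": round(sp["mean_cpue"], 3)})
            rows[year] = row
        pd.DataFrame(rows).to_csv(path)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except LBStockError as exc:
                raise LBStockError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path) -> AssessmentReport:
    """Execute the full assessment described by ``config``.

    Deterministic: the same config and seed produce a byte-identical report.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge(_DEFAULTS, config)
    if "inputs" not in cfg or "length_frequency" not in cfg["inputs"]:
        raise FormatError("config must name inputs.length_frequency")
    seed = int(cfg["seed"])
    report = AssessmentReport(meta={"seed": seed, "package": "lbstock"})

    tables = _stage("read_lf")(read_length_frequency)(cfg["inputs"]["length_frequency"])
    years = sorted(tables)
    for y in years:
        report.years[y] = {}

    # ---- length-weight ---------------------------------------------------
    lw_path = cfg["inputs"].get("length_weight")
    if lw_path:
        lw_df = _stage("read_lw")(read_length_weight)(lw_path)

        @_stage("length_weight")
        def _fit_lw(df):
            out = {}
            groups = df.groupby("year") if "year" in df.columns else [(None, df)]
            for gyear, grp in groups:
                res = LengthWeightModel(grp["length_mm"], grp["weight_g"]).fit()
                out[gyear] = {
                    "a": res.a, "b": res.b, "r_squared": res.r_squared,
                    "n": res.n, "p_value_b_eq_3": res.p_value_b_eq_3,
                    "growth_type": res.growth_type(), "length_unit": res.length_unit,
                }
            return out

        lw_fits = _fit_lw(lw_df)
        for y in years:
            report.years[y]["length_weight"] = lw_fits.get(y, lw_fits.get(None))

    # ---- growth + mortality + LBB per year --------------------------------
    e_cfg = cfg["elefan"]
    temps = cfg["mean_temp_c"]
    lbb_cfg = cfg["lbb"]
    for i, y in enumerate(years):
        table = tables[y]

        @_stage(f"growth[{y}]")
        def _growth(table=table):
            model = ElefanModel(table, ma_window=int(e_cfg.get("ma_window", 5)))
            return model.fit(tuple(e_cfg["linf_range"]), tuple(e_cfg["k_range"]),
                             grid=tuple(e_cfg["grid"]))

        efit = _growth()
        report.years[y]["growth"] = {
            "linf": efit.linf, "k": efit.k, "t0": efit.params.t0,
            "phi_prime": growth_performance(efit.linf, efit.k),
            "rn_score": efit.rn_score,
        }

        temp = temps.get(y, temps.get(str(y))) if isinstance(temps, dict) else temps
        if temp is None:
            raise FormatError(f"no mean_temp_c entry for year {y}")

        @_stage(f"mortality[{y}]")
        def _mort(table=table, efit=efit, temp=temp):
            return estimate_mortality(table, efit.params, float(temp))

        mort, _cc = _mort()
        report.years[y]["mortality"] = {
            "z": mort.z, "m": mort.m, "f": mort.f, "e": mort.e,
            "mean_temp_c": mort.mean_temp,
        }

        @_stage(f"lbb[{y}]")
        def _lbb(table=table, efit=efit, i=i):
            pri_cfg = (lbb_cfg.get("priors") or {})
            pri_over = dict(pri_cfg.get(y) or pri_cfg.get(str(y)) or {})
            if lbb_cfg.get("use_elefan_linf") and "linf_prior" not in pri_over:
                pri_over["linf_prior"] = efit.linf
                pri_over.setdefault("linf_cv", 0.05)
            if pri_over:
                priors = LBBPriors.from_table(table, **pri_over)
            else:
                priors = None  # LBBModel derives and logs data-driven defaults
                log.info("lbb[%s]: no priors in config, using data-driven defaults", y)
            mcmc = lbb_cfg["mcmc"]
            return LBBModel(table, priors).fit(
                chains=int(mcmc["chains"]), iterations=int(mcmc["iterations"]),
                burn_in=int(mcmc["burn_in"]), seed=(seed * 1009 + i) % (2**31),
            )

        lfit = _lbb()
        rp = lfit.reference_points()
        ind = lfit.length_indicators(table)
        report.years[y]["lbb"] = {
            "linf": lfit.linf, "lc": lfit.lc, "alpha": lfit.alpha,
            "mk": lfit.mk, "fk": lfit.fk, "zk": lfit.zk, "fm": lfit.fm,
            "e": lfit.e, "converged": lfit.converged,
            "acceptance_rate": lfit.acceptance_rate,
            "ci": {k: list(v) for k, v in lfit.ci.items()},
            "reference_points": {
                "l_opt": rp.l_opt, "lc_opt": rp.lc_opt, "ypr": rp.ypr,
                "cpue_r": rp.cpue_r, "b0_r": rp.b0_r, "bb0": rp.bb0,
                "bmsy_b0": rp.bmsy_b0, "bbmsy": rp.bbmsy,
            },
            "indicators": {
                "l95th": ind.l95th, "l95_over_linf": ind.l95_over_linf,
                "lmean": ind.lmean, "lmean_over_lcopt": ind.lmean_over_lcopt,
                "lc_over_lcopt": ind.lc_over_lcopt,
            },
            "status": lfit.status(),
        }

    # ---- spatial -----------------------------------------------------------
    logbook_path = cfg["inputs"].get("logbook")
    if logbook_path:
        records = _stage("read_logbook")(read_logbook)(logbook_path)

        @_stage("spatial")
        def _spatial():
            cells = grid_aggregate(records)
            for y in years:
                sub = cells[cells["year"] == y]
                if sub.empty:
                    continue
                cog = center_of_gravity(records, y)
                report.years[y]["spatial"] = {
                    "cog_lat": cog.lat, "cog_lon": cog.lon,
                    "total_catch_t": float(sub["total_catch"].sum()),
                    "n_ops": int(sub["n_ops"].sum()),
                    "mean_cpue": float(sub["total_catch"].sum()
                                       / sub["total_nets"].sum()),
                    "n_cells": int(len(sub)),
                }
            report.correlations = cpue_correlations(records).to_dict("records")

        _spatial()

    out_dir = cfg.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_csv(out / "report.csv")
        log.info("report written to %s", out)
    return report
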