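"""Staged analysis pipeline: simulation/ingest through clinal modelling.

Stages run in a fixed order (each consumes the previous ones' in-memory
results and writes machine-readable tables plus a parameter log):

    simulate -> climate -> rings -> detrend -> dendroclim
             -> resilience -> quantgen -> cline

Given a seed, the whole chain is deterministic.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as clim
from . import dendroclim, detrend, io, quantgen, resilience, rings as rings_mod
from .cline import MarsRegression
from .config import RunConfig
from .datatypes import DesignTable, RingSeriesSet
from .lmm import fit_lmm, lrt_random
from .simulate import SimParams, simulate_dataset

STAGES = ("simulate", "climate", "rings", "detrend", "dendroclim",
          "resilience", "quantgen", "cline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, upto: str = "cline") -> dict:
    """Run the chain up to (and including) the requested stage.

    Returns the in-memory result bundle; every stage also writes CSV/JSON
    outputs under ``config.outdir`` together with a run log recording the
    seed and per-stage parameters.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.as_dict()}
    log: dict = {"seed": config.seed, "config": config.as_dict(),
                 "started": time.strftime("%Y-%m-%d %H:%M:%S"), "stages": {}}

    def stage_done(name, **params):
        log["stages"][name] = params
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    # -- simulate / ingest -------------------------------------------------
    try:
        if config.rings_path is None:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", config.seed)
            params = SimParams(**sim_kwargs)
            sim = simulate_dataset(params)
            design, rings = sim["design"], sim["rings"]
            daily, genotypes = sim["daily"], sim.get("genotypes")
            io.write_design(design, outdir / "design.csv")
            io.write_long_csv(rings, outdir / "rings.csv")
            io.write_rwl(rings, outdir / "rings.rwl")
            daily.to_csv(outdir / "daily_climate.csv", index=False,
                         float_format="%.4g")
            if genotypes is not None:
                io.write_genotypes(genotypes, outdir / "genotypes.csv")
            (outdir / "truth.json").write_text(
                json.dumps(sim["truth"].to_json(), indent=2)
            )
            bundle.update(design=design, rings=rings, daily=daily,
                          genotypes=genotypes, truth=sim["truth"])
            stage_done("simulate", params=sim["truth"].to_json()["params"])
        else:
            rings = (io.read_rwl(config.rings_path)
                     if str(config.rings_path).endswith(".rwl")
                     else io.read_long_csv(config.rings_path))
            design = io.read_design(config.design_path)
            design.check_trees(rings.trees)
            daily = io.read_daily_climate(config.climate_path)
            genotypes = None
            if config.genotypes_path:
                genotypes = io.read_genotypes(config.genotypes_path, design)
            bundle.update(design=design, rings=rings, daily=daily,
                          genotypes=genotypes)
            stage_done("simulate", source="files")
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc
    if last == 0:
        return bundle

    # -- climate -----------------------------------------------------------
    try:
        monthly = clim.aggregate_monthly(daily)
        smi = clim.compute_smi(monthly, config.w_max, config.w_crit)
        anomalies = clim.summer_anomaly(
            smi, "SMI", (config.first_year, config.last_year)
        )
        if config.drought_years == "auto":
            events = clim.detect_droughts(
                anomalies.loc[config.first_year:config.last_year],
                quantile=config.drought_quantile,
            )
        else:
            events = [int(y) for y in config.drought_years]
        _write(monthly, outdir, "monthly_climate.csv")
        _write(smi, outdir, "smi.csv")
        anomalies.rename("summer_smi_ratio").to_csv(outdir / "summer_anomaly.csv")
        bundle.update(monthly=monthly, smi=smi, anomalies=anomalies,
                      events=events)
        stage_done("climate", w_max=config.w_max, w_crit=config.w_crit,
                   events=events)
    except Exception as exc:
        raise PipelineError("climate", exc) from exc
    if last == 1:
        return bundle

    # -- rings: BAI, tracheid derivatives, dating screen --------------------
    try:
        bai = rings_mod.rw_to_bai(rings)
        traits = rings.data.copy()
        if {"TDr", "TDt", "CWT"} <= set(traits.columns):
            traits = rings_mod.derive_tracheid(traits)
        traits = traits.merge(bai, on=["tree", "year"])
        dating = rings_mod.crossdate_check(rings)
        _write(bai, outdir, "bai.csv")
        _write(dating, outdir, "crossdating.csv")
        bundle.update(bai=bai, traits=traits, dating=dating)
        stage_done("rings", n_flagged=int(dating["flagged"].sum()))
    except Exception as exc:
        raise PipelineError("rings", exc) from exc
    if last == 2:
        return bundle

    # -- detrend: additive trend removal + AR prewhitening ------------------
    try:
        df = traits.copy()
        first = df.groupby("tree")["year"].transform("min")
        df["age"] = df["year"] - first + 1
        df["size"] = df.groupby("tree")["BAI"].cumsum()
        mean_size = df.groupby("tree")["BAI"].mean()
        comp = detrend.competition_index(design, mean_size.reindex(
            design.data["tree"]).fillna(mean_size.mean()))
        df["comp"] = df["tree"].map(comp)
        df["logBAI"] = np.log(df["BAI"])
        fit = detrend.fit_trend(df, "logBAI", ("age", "size", "comp"),
                                seed=config.seed)
        df["residual1"] = fit.residuals
        pw = detrend.prewhiten(df[["tree", "year", "residual1"]])
        pw = pw[pw["year"] >= config.first_year]
        _write(pw, outdir, "residuals.csv")
        bundle.update(residuals=pw, trend_edf=fit.edf)
        stage_done("detrend", edf=fit.edf, alpha=list(map(float, fit.alpha)),
                   cut_year=config.first_year)
    except Exception as exc:
        raise PipelineError("detrend", exc) from exc
    if last == 3:
        return bundle

    # -- dendroclim ---------------------------------------------------------
    try:
        ok = pw.dropna(subset=["residual2"])
        grouping = design.data.set_index("tree")["provenance"]
        chron, chron_stats = rings_mod.build_chronology(
            ok.rename(columns={"residual2": "value"}), grouping
        )
        site_chron = ok.groupby("year")["residual2"].mean()
        corr = dendroclim.monthly_correlations(
            site_chron, smi.rename(columns={"SMI": "smi"}), "smi",
            (config.first_year, config.last_year),
            n_boot=config.n_boot, seed=config.seed,
        )
        chronologies = {
            g: grp.set_index("year")["mean"] for g, grp in chron.groupby("group")
        }
        sens = dendroclim.climate_sensitivity(
            chronologies, smi.rename(columns={"SMI": "smi"}), "smi",
            "curr-07", (config.first_year, config.last_year),
        )
        _write(chron, outdir, "chronologies.csv")
        _write(chron_stats, outdir, "chronology_stats.csv")
        corr.to_csv(outdir / "dendroclim_correlations.csv")
        sens.to_csv(outdir / "climate_sensitivity.csv")
        bundle.update(chronologies=chron, chronology_stats=chron_stats,
                      correlations=corr, sensitivity=sens)
        stage_done("dendroclim", n_boot=config.n_boot,
                   window=[config.first_year, config.last_year])
    except Exception as exc:
        raise PipelineError("dendroclim", exc) from exc
    if last == 4:
        return bundle

    # -- resilience ----------------------------------------------------------
    try:
        if not events:
            raise ValueError("no drought events detected or configured")
        recs = resilience.resilience_for_events(
            bai, events, config.pre_years, config.post_years
        )
        means = resilience.mean_indices(recs)
        prov_map = design.data.set_index("tree")["provenance"]
        summary = resilience.group_summary(recs, prov_map)
        _write(recs, outdir, "resilience.csv")
        _write(means, outdir, "resilience_means.csv")
        summary.to_csv(outdir / "resilience_by_provenance.csv")
        bundle.update(resilience=recs, resilience_means=means)
        stage_done("resilience", events=events, pre=config.pre_years,
                   post=config.post_years)
    except Exception as exc:
        raise PipelineError("resilience", exc) from exc
    if last == 5:
        return bundle

    # -- quantgen ------------------------------------------------------------
    try:
        main_event = events[len(events) // 2] if len(events) > 1 else events[0]
        ev = recs[recs["event"] == main_event].copy()
        size_to_event = (
            bai[bai["year"] <= main_event].groupby("tree")["BAI"].sum()
        )
        d = design.data.set_index("tree")
        ev["provenance"] = ev["tree"].map(d["provenance"])
        ev["family"] = ev["tree"].map(d["family"])
        ev["block"] = ev["tree"].map(d["block"])
        ev["tree_size"] = ev["tree"].map(size_to_event)
        spec = quantgen.drought_model_spec("Rl")
        res = fit_lmm(ev, spec)
        h2 = quantgen.heritability(
            res, config.relatedness_r, fam_term="family",
            pheno_terms=("family",), plot_term="family:block",
        )
        q = quantgen.qst(res, config.relatedness_r)
        lrt = lrt_random(ev, spec, "provenance")
        out = {
            "event": int(main_event),
            "varcomp": {k: float(v) for k, v in res.varcomp.items()},
            "loglik": res.loglik,
            "h2": {"estimate": h2.estimate, "se": h2.se, "ci": h2.ci},
            "qst": {"estimate": q.estimate, "se": q.se, "ci": q.ci},
            "lrt_provenance": lrt,
            "relatedness_r": config.relatedness_r,
        }
        if genotypes is not None:
            G = quantgen.gmatrix(genotypes)
            r_hat = quantgen.avg_within_family(G, genotypes.family)
            theta_snp, theta = quantgen.fst_weir_cockerham(genotypes)
            gst_snp, gst = quantgen.fst_nei(genotypes)
            pd.DataFrame({"theta_wc": theta_snp, "gst_nei": gst_snp}).to_csv(
                outdir / "fst_per_snp.csv"
            )
            out.update(r_hat=r_hat, fst_wc=theta, gst_nei=gst)
        (outdir / "quantgen.json").write_text(
            json.dumps(out, indent=2, default=float)
        )
        bundle.update(quantgen=out, lmm_results=res)
        stage_done("quantgen", event=int(main_event), r=config.relatedness_r)
    except Exception as exc:
        raise PipelineError("quantgen", exc) from exc
    if last == 6:
        return bundle

    # -- cline ----------------------------------------------------------------
    try:
        prov_map = design.data.set_index("tree")["provenance"]
        ev = recs[recs["event"] == bundle["quantgen"]["event"]].copy()
        ev["provenance"] = ev["tree"].map(prov_map)
        prov_means = ev.groupby("provenance")["Rl"].mean().rename("Rl")
        table = design.origin_climate().join(prov_means)
        mars = MarsRegression(table.reset_index(), "Rl").fit()
        surf = mars.response_surface("origin_MAT", "origin_summer_smi")
        (outdir / "cline_model.json").write_text(
            json.dumps(mars.summary(), indent=2)
        )
        _write(surf, outdir, "cline_surface.csv")
        _write(table.reset_index(), outdir, "provenance_means.csv")
        bundle.update(cline=mars, cline_table=table, surface=surf)
        stage_done("cline", r2=mars.r2, gcv=mars.gcv)
    except Exception as exc:
        raise PipelineError("cline", exc) from exc
    return bundle
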