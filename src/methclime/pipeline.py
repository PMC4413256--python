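"""End-to-end orchestration: simulate -> quant -> dmr -> gwas -> varcomp -> popgen.

A single config dict drives every stage; outputs are plain TSV tables in
a run directory plus a provenance manifest (seed, parameter hash,
package version).  Re-running with the same config and seed reproduces
all tables bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dmr, gwas, io, popgen, quant, varcomp
from .simulate import Architecture, SimConfig, simulate_all

DEFAULT_CONFIG = {
    "seed": 0,
    "n_accessions": 60,
    "n_snps": 2000,
    "genome_length": 2_000_000,
    "n_chromosomes": 5,
    "n_genes": 150,
    "n_tes": 150,
    "fst_target": 0.187,
    "depth_mean": 12.6,
    "conversion_error": 0.0041,
    "site_spacing": 60,
    # stage parameters (paper-scale defaults, all overridable)
    "window_size": 200,
    "window_step": 100,
    "dmr_window": 100,
    "dmr_fdr": 0.05,
    "dmr_min_diff": 0.3,
    "dmr_accessions": 6,
    "top_n_windows": 2000,
    "cis_window_gwas": 100_000,
    "cis_window_varcomp": 50_000,
    "varcomp_restarts": 2,
    "varcomp_phenotypes": 5,
    "n_permutations": 200,
    "stages": ["simulate", "quant", "dmr", "gwas", "varcomp", "popgen"],
}


def validate_config(cfg: dict) -> dict:
    full = dict(DEFAULT_CONFIG)
    unknown = set(cfg) - set(full)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    full.update(cfg)
    if not (0 < full["dmr_fdr"] <= 1):
        raise ValueError("dmr_fdr must be in (0, 1]")
    if full["window_size"] <= 0 or full["dmr_window"] <= 0:
        raise ValueError("window sizes must be positive")
    if full["window_size"] % full["window_step"] != 0:
        raise ValueError("window_size must be a multiple of window_step")
    if not (0 <= full["dmr_min_diff"] <= 1):
        raise ValueError("dmr_min_diff must be a fraction")
    if full["varcomp_restarts"] < 1 or full["n_permutations"] < 1:
        raise ValueError("restarts/permutations must be >= 1")
    SimConfig(
        n_accessions=full["n_accessions"], n_snps=full["n_snps"],
        genome_length=full["genome_length"],
        n_chromosomes=full["n_chromosomes"], seed=full["seed"],
    ).validate()
    return full


def _sim_config(cfg: dict) -> SimConfig:
    return SimConfig(
        n_accessions=cfg["n_accessions"], n_snps=cfg["n_snps"],
        genome_length=cfg["genome_length"],
        n_chromosomes=cfg["n_chromosomes"], fst_target=cfg["fst_target"],
        n_genes=cfg["n_genes"], n_tes=cfg["n_tes"],
        depth_mean=cfg["depth_mean"],
        conversion_error=cfg["conversion_error"],
        site_spacing=cfg["site_spacing"], seed=cfg["seed"],
        architecture=Architecture(),
    )


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict; tables land in ``outdir``.  A stage
    failure halts downstream stages but retains partial outputs, marked
    in the manifest.
    """
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg,
        "stages_completed": [],
        "stages_failed": [],
        "tables": [],
    }

    def save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        manifest["tables"].append(name)

    state: dict = {}
    stage_fns = {
        "simulate": _stage_simulate, "quant": _stage_quant,
        "dmr": _stage_dmr, "gwas": _stage_gwas,
        "varcomp": _stage_varcomp, "popgen": _stage_popgen,
    }
    order = [s for s in DEFAULT_CONFIG["stages"] if s in cfg["stages"]]
    failed = False
    for stage in order:
        if failed:
            break
        try:
            stage_fns[stage](cfg, state, save, outdir)
            manifest["stages_completed"].append(stage)
        except Exception as exc:  # halt downstream, keep partial output
            manifest["stages_failed"].append(
                {"stage": stage, "error": f"{type(exc).__name__}: {exc}"})
            failed = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg, state, save, outdir):
    sim = simulate_all(_sim_config(cfg))
    state.update(sim)
    io.write_fixtures(sim, outdir / "inputs")


def _stage_quant(cfg, state, save, outdir):
    counts = state["methylomes"]
    eff = quant.conversion_efficiency(counts)
    df = counts.samples.copy()
    df["conversion_efficiency"] = eff
    save(df, "conversion_efficiency.tsv")
    ctx = quant.context_averages(counts)
    save(ctx, "context_averages.tsv")
    state["context_averages"] = ctx
    wm = quant.sliding_windows(counts, size=cfg["window_size"],
                               step=cfg["window_step"], context="CHH")
    state["windows"] = wm
    sel = quant.select_variable_windows(
        wm, top_n=min(cfg["top_n_windows"], wm.n_windows), max_missing=0.5)
    state["variable_windows"] = sel
    save(wm.windows.iloc[sel].assign(index=sel), "variable_windows.tsv")


def _stage_dmr(cfg, state, save, outdir):
    counts = state["methylomes"]
    accs = state["genotypes"].accessions[: cfg["dmr_accessions"]]
    res = dmr.temperature_dmrs(
        counts, accessions=accs, window=cfg["dmr_window"],
        fdr=cfg["dmr_fdr"], min_diff=cfg["dmr_min_diff"])
    save(res["per_accession"], "temperature_dmr_counts.tsv")
    if not res["consensus"].empty:
        save(res["consensus"], "temperature_dmr_consensus.tsv")
    state["temperature_dmrs"] = res


def _stage_gwas(cfg, state, save, outdir):
    g = state["genotypes"]
    counts = state["methylomes"]
    # phenotype: average CHH methylation of large TEs at 10C
    fa = quant.feature_average(counts, state["annotations"], context="CHH",
                               kind="te", min_length=2000)
    cols = [i for i in range(counts.n_samples)
            if counts.samples.iloc[i]["environment"] == "10C"]
    y = fa.iloc[:, cols].mean(axis=0).to_numpy()
    K = gwas.kinship_ibs(g)
    res = gwas.lmm_scan(y, g, K)
    save(res.assoc, "gwas_te_chh.tsv")
    state["gwas_te_chh"] = res
    state["kinship"] = K


def _stage_varcomp(cfg, state, save, outdir):
    g = state["genotypes"]
    wm = state["windows"]
    sel = state["variable_windows"][: cfg["varcomp_phenotypes"]]
    snp_ids = g.snps["id"].to_numpy()
    cmt2_idx = np.flatnonzero(np.isin(snp_ids, ["CMT2a", "CMT2b"]))
    rows = []
    env10 = (wm.samples["environment"] == "10C").to_numpy()
    env16 = (wm.samples["environment"] == "16C").to_numpy()
    R_cmt2 = (varcomp.relatedness_from_snps(g, cmt2_idx)
              if len(cmt2_idx) else None)
    for w in sel:
        anchor_chrom = wm.windows.iloc[w]["chrom"]
        anchor_pos = int((wm.windows.iloc[w]["start"]
                          + wm.windows.iloc[w]["end"]) // 2)
        cis_idx, trans_idx = varcomp.cis_trans_selectors(
            g, anchor_chrom, anchor_pos, cfg["cis_window_varcomp"])
        try:
            R_cis = (varcomp.relatedness_from_snps(g, cis_idx)
                     if len(cis_idx) else None)
        except ValueError:
            R_cis = None
        R_trans = varcomp.relatedness_from_snps(g, trans_idx)
        Y = np.column_stack([wm.level[w][env10], wm.level[w][env16]])
        try:
            fit = varcomp.fit_varcomp(Y, R_cmt2, R_cis, R_trans,
                                      restarts=cfg["varcomp_restarts"],
                                      seed=cfg["seed"])
        except (ValueError, RuntimeError):
            continue
        if not fit.converged:
            continue
        row = {"window": int(w), "chrom": anchor_chrom,
               "anchor_pos": anchor_pos, "loglik": fit.loglik}
        row.update(fit.fractions)
        rows.append(row)
    if rows:
        save(pd.DataFrame(rows), "varcomp_fractions.tsv")


def _stage_popgen(cfg, state, save, outdir):
    g = state["genotypes"]
    fst = popgen.hudson_fst(g)
    ctx = state["context_averages"]
    cg10 = ctx[(ctx["context"] == "CG") & (ctx["environment"] == "10C")]
    lat = g.metadata["latitude"]
    env_tbl = pd.DataFrame({"latitude": lat})
    corr = popgen.env_correlations(ctx, env_tbl)
    save(corr, "env_correlations.tsv")
    y = cg10.set_index("accession")["level"].reindex(g.accessions).to_numpy()
    q = popgen.qst(y, g)
    summary = pd.DataFrame([{
        "hudson_fst": fst["fst"],
        "qst_global_cg": q.qst,
        "sigma2_between": q.sigma2_between,
        "sigma2_within": q.sigma2_within,
    }])
    save(summary, "qst_fst.tsv")
    state["qst_fst"] = summary
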