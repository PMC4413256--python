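"""Differential methylation between paired samples.

Per non-overlapping 100 bp window, counts are summed within each sample
and compared with Fisher's exact test on the 2x2 (methylated,
unmethylated) table; Benjamini-Hochberg control across tested windows;
calls require both q <= fdr and an absolute level difference of at
least ``min_diff`` (difference semantics; a ratio variant is available
by flag).  Also: per-accession temperature-DMR summaries, annotation
overlap, mutant-dependent DMR sets, and TE-family permutation
enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotationSet, MethylCounts


def _tile_counts(counts: MethylCounts, sample: int, window: int,
                 context: str | None) -> pd.DataFrame:
    sub = counts if context is None else counts.select_context(context)
    chrom = sub.sites["chrom"].to_numpy()
    pos = sub.sites["pos"].to_numpy()
    widx = (pos - 1) // window
    df = pd.DataFrame({
        "chrom": chrom, "widx": widx,
        "meth": sub.meth[:, sample], "total": sub.total[:, sample]})
    agg = df.groupby(["chrom", "widx"], sort=True).sum().reset_index()
    agg["start"] = agg["widx"] * window + 1
    agg["end"] = agg["start"] + window - 1
    return agg


def pairwise_dmr_test(
    countsA: MethylCounts,
    countsB: MethylCounts,
    sampleA: int = 0,
    sampleB: int = 0,
    window: int = 100,
    fdr: float = 0.05,
    min_diff: float = 0.3,
    context: str | None = "CHH",
    ratio_semantics: bool = False,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call DMRs between two samples on non-overlapping tiles.

    Returns a DataFrame of calls (chrom, start, end, levelA, levelB,
    difference, p, q, direction); ``direction`` is "gain" when B > A.
    Windows with zero coverage in either sample are untested and do not
    enter the FDR denominator.
    """
    if not (0 < fdr <= 1):
        raise ValueError("fdr must be in (0, 1]")
    a = _tile_counts(countsA, sampleA, window, context)
    b = _tile_counts(countsB, sampleB, window, context)
    merged = a.merge(b, on=["chrom", "widx", "start", "end"],
                     suffixes=("_a", "_b"))
    merged = merged[(merged["total_a"] > 0) & (merged["total_b"] > 0)]
    merged = merged.reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "levelA",
                                     "levelB", "difference", "p", "q",
                                     "direction"])
    ma = merged["meth_a"].to_numpy(np.int64)
    ta = merged["total_a"].to_numpy(np.int64)
    mb = merged["meth_b"].to_numpy(np.int64)
    tb = merged["total_b"].to_numpy(np.int64)
    pvals = np.empty(len(merged))
    for i in range(len(merged)):
        _, pvals[i] = fisher_exact(
            [[ma[i], ta[i] - ma[i]], [mb[i], tb[i] - mb[i]]])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    la = ma / ta
    lb = mb / tb
    if ratio_semantics:
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.abs(np.log2((lb + 1e-9) / (la + 1e-9)))
        big = change >= min_diff
    else:
        big = np.abs(lb - la) >= min_diff
    out = pd.DataFrame({
        "chrom": merged["chrom"], "start": merged["start"],
        "end": merged["end"], "levelA": la, "levelB": lb,
        "difference": lb - la, "p": pvals, "q": qvals,
        "direction": np.where(lb > la, "gain", "loss"),
    })
    if return_all:
        out["called"] = (qvals <= fdr) & big
        return out
    return out[(qvals <= fdr) & big].reset_index(drop=True)


def temperature_dmrs(
    counts: MethylCounts,
    env_a: str = "10C",
    env_b: str = "16C",
    accessions: list[str] | None = None,
    window: int = 100,
    fdr: float = 0.05,
    min_diff: float = 0.3,
    context: str = "CHH",
    consensus_k: int = 1,
) -> dict:
    """Per-accession gain/loss counts for env_b - env_a, plus a consensus set.

    The consensus set contains windows called (either direction) in at
    least ``consensus_k`` accessions.
    """
    if accessions is None:
        accessions = [a for a in pd.unique(counts.samples["accession"])
                      if {env_a, env_b} <= set(
                          counts.samples.loc[
                              counts.samples["accession"] == a,
                              "environment"])]
    if not accessions:
        raise ValueError("no accession measured in both environments")
    per_acc = []
    seen: dict[tuple, int] = {}
    for acc in accessions:
        sa = counts.sample_index(acc, env_a)
        sb = counts.sample_index(acc, env_b)
        calls = pairwise_dmr_test(counts, counts, sa, sb, window=window,
                                  fdr=fdr, min_diff=min_diff, context=context)
        gains = int((calls["direction"] == "gain").sum())
        losses = int((calls["direction"] == "loss").sum())
        per_acc.append((acc, gains, losses))
        for _, r in calls.iterrows():
            key = (r["chrom"], int(r["start"]), int(r["end"]))
            seen[key] = seen.get(key, 0) + 1
    consensus = pd.DataFrame(
        [k for k, v in seen.items() if v >= consensus_k],
        columns=["chrom", "start", "end"])
    return {
        "per_accession": pd.DataFrame(per_acc,
                                      columns=["accession", "gained", "lost"]),
        "consensus": consensus.sort_values(["chrom", "start"]).reset_index(
            drop=True) if not consensus.empty else consensus,
    }


def annotate_overlap(dmrs: pd.DataFrame, annot: AnnotationSet,
                     kind: str = "te", flank: int = 500) -> dict:
    """Fractions of DMRs directly overlapping / within ``flank`` bp of features.

    Intervals are 1-based closed; the distance between touching
    intervals is 0.
    """
    if dmrs.empty:
        raise ValueError("empty DMR set; overlap fractions undefined")
    feats = annot.features
    if kind is not None:
        feats = feats[feats["kind"] == kind]
    direct = np.zeros(len(dmrs), bool)
    near = np.zeros(len(dmrs), bool)
    for c, sub in feats.groupby("chrom"):
        m = (dmrs["chrom"] == c).to_numpy()
        if not m.any():
            continue
        qs = dmrs.loc[m, "start"].to_numpy()
        qe = dmrs.loc[m, "end"].to_numpy()
        fs = np.sort(sub["start"].to_numpy())
        fe = sub.sort_values("start")["end"].to_numpy()
        # distance to nearest feature for each query
        dist = np.full(len(qs), np.inf)
        for s, e in zip(fs, fe):
            d = np.maximum(0, np.maximum(s - qe, qs - e))
            dist = np.minimum(dist, d)
        rows = np.flatnonzero(m)
        direct[rows] = dist == 0
        near[rows] = dist <= flank
    return {
        "direct_fraction": float(direct.mean()),
        "within_flank_fraction": float(near.mean()),
        "direct": direct,
        "within_flank": near,
    }


def dependent_dmrs(
    mutant: MethylCounts,
    wildtype: MethylCounts,
    label: str,
    window: int = 100,
    fdr: float = 0.05,
    min_diff: float = 0.3,
    context: str | None = "CHH",
    loss_only: bool = True,
) -> pd.DataFrame:
    """Windows losing methylation in a mutant vs wild type.

    A window is ``label``-dependent when methylation is significantly
    lower in the mutant (direction filter on by default).
    """
    calls = pairwise_dmr_test(wildtype, mutant, window=window, fdr=fdr,
                              min_diff=min_diff, context=context)
    # orientation: A=wildtype, B=mutant, so loss-in-mutant is "loss"
    if loss_only:
        calls = calls[calls["direction"] == "loss"].reset_index(drop=True)
    calls = calls.copy()
    calls["dependent_on"] = label
    return calls


def overlap_enrichment(setA: set, setB: set, universe: set) -> dict:
    """2x2 overlap table, odds ratio, Fisher p, per-set overlap percentages."""
    if not universe:
        raise ValueError("empty universe")
    if not (setA <= universe and setB <= universe):
        raise ValueError("sets must be subsets of the universe")
    n11 = len(setA & setB)
    n10 = len(setA - setB)
    n01 = len(setB - setA)
    n00 = len(universe) - n11 - n10 - n01
    return overlap_enrichment_from_counts(n11, n10, n01, n00)


def overlap_enrichment_from_counts(n11: int, n10: int, n01: int, n00: int
                                   ) -> dict:
    """Same as :func:`overlap_enrichment` but on a printed 2x2 table."""
    table = np.array([[n11, n10], [n01, n00]])
    odds, p = fisher_exact(table)
    if np.isinf(odds):
        odds = np.finfo(float).max
    p = max(p, np.finfo(float).tiny)
    nA = n11 + n10
    nB = n11 + n01
    return {
        "table": table,
        "odds_ratio": float(odds),
        "p": float(p),
        "pct_A_overlapping": int(round(100 * n11 / nA)) if nA else np.nan,
        "pct_B_overlapping": int(round(100 * n11 / nB)) if nB else np.nan,
    }


def te_family_enrichment(
    variable_ids: set,
    tes: pd.DataFrame,
    by: str = "family",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs expected 'variable' TEs per family, with a permutation null.

    expected = |variable| * |family| / |all|; the null permutes the
    variable label over all TEs; a family is flagged over-represented
    when observed exceeds the 95th null quantile (and expected).
    Empirical p uses (r + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    fam = tes[by].to_numpy()
    ids = tes["id"].to_numpy()
    if not set(variable_ids) <= set(ids):
        raise ValueError("variable set must be a subset of the TE table")
    names, codes = np.unique(fam, return_inverse=True)
    n_fam = len(names)
    n_all = len(ids)
    n_var = len(variable_ids)
    is_var = np.isin(ids, list(variable_ids))
    observed = np.bincount(codes[is_var], minlength=n_fam)
    fam_sizes = np.bincount(codes, minlength=n_fam)
    expected = n_var * fam_sizes / n_all

    null = np.empty((n_perm, n_fam), dtype=np.int64)
    for r in range(n_perm):
        pick = rng.choice(n_all, size=n_var, replace=False)
        null[r] = np.bincount(codes[pick], minlength=n_fam)
    q95 = np.quantile(null, 0.95, axis=0)
    exceed = (null >= observed[None, :]).sum(axis=0)
    p_emp = (exceed + 1) / (n_perm + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(expected > 0, observed / expected, np.nan)
    out = pd.DataFrame({
        by: names, "n_total": fam_sizes, "expected": expected,
        "observed": observed, "enrichment": enr, "q95_null": q95,
        "p_empirical": p_emp,
        "over_represented": (observed > q95) & (observed > expected),
    })
    return out[out["n_total"] > 0].reset_index(drop=True)
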