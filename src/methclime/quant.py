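"""Per-cytosine counts -> methylation phenotypes.

Site levels, bisulfite conversion efficiency from the chloroplast
control, genome-wide context averages, feature averages, half-
overlapping sliding windows, most-variable window selection, gene-body
methylation (GBM) gene classification, and site-level group
comparisons.

Aggregation convention: a region's level is count-weighted,
``sum(meth) / sum(total)`` over its covered sites; genome-wide context
averages are unweighted means of site levels by default (a coverage-
weighted variant is available by flag).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CONTEXTS, AnnotationSet, MethylCounts, WindowMatrix


def site_levels(counts: MethylCounts, min_coverage: int = 1) -> np.ndarray:
    """Per-site methylation level ``meth/total``; NaN below min coverage."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if (counts.meth > counts.total).any():
        raise ValueError("record with meth > total")
    tot = counts.total.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lv = counts.meth / tot
    lv[counts.total < min_coverage] = np.nan
    return lv


def conversion_efficiency(counts: MethylCounts,
                          chloroplast: str = "ChrC") -> np.ndarray:
    """Per-sample efficiency = 1 - sum(meth)/sum(total) on the chloroplast."""
    m = (counts.sites["chrom"] == chloroplast).to_numpy()
    if not m.any():
        raise ValueError(f"no sites on chloroplast contig {chloroplast!r}")
    tot = counts.total[m].sum(axis=0).astype(float)
    if (tot == 0).any():
        raise ValueError("sample with no covered chloroplast cytosine")
    return 1.0 - counts.meth[m].sum(axis=0) / tot


def context_averages(
    counts: MethylCounts,
    contexts: tuple[str, ...] = CONTEXTS,
    min_coverage: int = 1,
    weighted: bool = False,
    exclude_chrom: str | None = "ChrC",
) -> pd.DataFrame:
    """Genome-wide mean methylation per sample and context.

    Returns a long DataFrame (accession, environment, context, level).
    Unweighted across covered sites by default.
    """
    sub = counts
    if exclude_chrom is not None:
        sub = counts.select_chrom(exclude_chrom, keep=False)
    lv = site_levels(sub, min_coverage)
    recs = []
    ctx_arr = sub.sites["context"].to_numpy()
    for ctx in contexts:
        m = ctx_arr == ctx
        if not m.any():
            warnings.warn(f"context {ctx} absent; reported as missing")
            vals = np.full(sub.n_samples, np.nan)
        elif weighted:
            tot = sub.total[m].astype(float)
            tot[sub.total[m] < min_coverage] = 0.0
            meth = np.where(tot > 0, sub.meth[m], 0)
            denom = tot.sum(axis=0)
            vals = np.where(denom > 0, meth.sum(axis=0) / denom, np.nan)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.nanmean(lv[m], axis=0)
        df = sub.samples.copy()
        df["context"] = ctx
        df["level"] = vals
        recs.append(df)
    return pd.concat(recs, ignore_index=True)


def feature_average(
    counts: MethylCounts,
    annot: AnnotationSet,
    context: str | None = None,
    kind: str | None = None,
    min_length: int = 0,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Count-weighted mean level per feature x sample.

    ``sum(meth)/sum(total)`` within the feature span; selector supports
    feature kind and a minimum length (e.g. transposons over 2 kb).
    Features outside genome bounds are rejected.
    """
    feats = annot.features
    if kind is not None:
        feats = feats[feats["kind"] == kind]
    if min_length:
        feats = feats[(feats["end"] - feats["start"] + 1) > min_length]
    if feats.empty:
        raise ValueError("no features selected")
    for _, r in feats.iterrows():
        size = annot.chrom_sizes.get(r["chrom"])
        if size is None or r["start"] < 1 or r["end"] > size:
            raise ValueError(f"feature {r['id']} outside genome bounds")

    sub = counts if context is None else counts.select_context(context)
    meth = sub.meth.astype(np.int64)
    tot = sub.total.astype(np.int64).copy()
    low = sub.total < min_coverage
    meth = np.where(low, 0, meth)
    tot[low] = 0

    out = np.full((len(feats), sub.n_samples), np.nan)
    chrom_arr = sub.sites["chrom"].to_numpy()
    pos_arr = sub.sites["pos"].to_numpy()
    for fi, (_, r) in enumerate(feats.iterrows()):
        m = (chrom_arr == r["chrom"]) & (pos_arr >= r["start"]) & \
            (pos_arr <= r["end"])
        if not m.any():
            continue
        d = tot[m].sum(axis=0).astype(float)
        n = meth[m].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[fi] = np.where(d > 0, n / d, np.nan)
    res = pd.DataFrame(out, index=feats["id"].to_numpy())
    res.columns = pd.MultiIndex.from_frame(sub.samples)
    return res


def _window_starts(length: int, size: int, step: int) -> np.ndarray:
    n_w = (length - size) // step + 1
    if n_w <= 0:
        return np.array([], dtype=np.int64)
    return 1 + step * np.arange(n_w, dtype=np.int64)


def sliding_windows(
    counts: MethylCounts,
    size: int = 200,
    step: int = 100,
    context: str = "CHH",
    min_coverage: int = 1,
    exclude_chrom: str | None = "ChrC",
) -> WindowMatrix:
    """Count-weighted levels in half-overlapping sliding windows."""
    if size <= 0:
        raise ValueError("window size must be positive")
    if size % step != 0:
        raise ValueError("window size must be a multiple of the step")
    sub = counts.select_context(context)
    if exclude_chrom is not None:
        sub = sub.select_chrom(exclude_chrom, keep=False)
    meth = sub.meth.astype(np.int64)
    tot = sub.total.astype(np.int64).copy()
    low = sub.total < min_coverage
    meth = np.where(low, 0, meth)
    tot[low] = 0

    win_rows, meth_rows, cov_rows = [], [], []
    chrom_arr = sub.sites["chrom"].to_numpy()
    pos_arr = sub.sites["pos"].to_numpy()
    # chromosome lengths: from the parent counts (all contexts)
    for chrom in pd.unique(counts.sites["chrom"]):
        if exclude_chrom is not None and chrom == exclude_chrom:
            continue
        length = int(counts.sites.loc[counts.sites["chrom"] == chrom,
                                      "pos"].max())
        starts = _window_starts(length, size, step)
        if len(starts) == 0:
            continue
        n_w = len(starts)
        msum = np.zeros((n_w, sub.n_samples), dtype=np.int64)
        csum = np.zeros((n_w, sub.n_samples), dtype=np.int64)
        m = chrom_arr == chrom
        p = pos_arr[m]
        sm, st = meth[m], tot[m]
        # site at pos p is in windows i with start in (p-size, p]
        i_max = np.minimum((p - 1) // step, n_w - 1)
        i_min = np.maximum(np.ceil((p - size) / step).astype(np.int64), 0)
        for off in range(size // step):
            i = i_min + off
            ok = i <= i_max
            np.add.at(msum, i[ok], sm[ok])
            np.add.at(csum, i[ok], st[ok])
        win_rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + size - 1}))
        meth_rows.append(msum)
        cov_rows.append(csum)
    windows = pd.concat(win_rows, ignore_index=True)
    msum = np.concatenate(meth_rows)
    csum = np.concatenate(cov_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(csum > 0, msum / csum.astype(float), np.nan)
    windows["context"] = context
    return WindowMatrix(windows=windows, level=level, coverage=csum,
                        samples=sub.samples, context=context)


def select_variable_windows(
    wm: WindowMatrix,
    top_n: int = 100_000,
    max_missing: float = 0.0,
    environment: str | None = None,
) -> np.ndarray:
    """Indices of the ``top_n`` most accession-variable windows.

    Windows whose missing fraction exceeds ``max_missing`` are dropped
    first (default: any missing cell disqualifies).  Ranking is by
    across-sample variance of the window level; ties break toward the
    earlier genomic coordinate.
    """
    lv = wm.level
    if environment is not None:
        cols = (wm.samples["environment"] == environment).to_numpy()
        lv = lv[:, cols]
    miss = np.isnan(lv).mean(axis=1)
    ok = miss <= max_missing
    idx = np.flatnonzero(ok)
    if len(idx) < top_n:
        warnings.warn(
            f"only {len(idx)} windows pass the missingness filter "
            f"(requested {top_n}); returning all")
        top_n = len(idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(lv[idx], axis=1)
    # stable sort on -variance keeps genomic order among ties
    order = np.argsort(-var, kind="stable")
    return np.sort(idx[order[:top_n]])


def classify_gbm_genes(
    gene_context_means: dict[str, pd.DataFrame],
    cg_min: float = 0.05,
    chg_max: float = 0.05,
    use_chh: bool = True,
) -> pd.Series:
    """Label genes {unmethylated, gbm, te_like, excluded}.

    Input: per-context gene x sample level matrices (as from
    :func:`feature_average`).  A gene is GBM iff its across-sample mean
    CG level is >= ``cg_min`` and its CHG (and, by default, CHH) mean is
    below ``chg_max``; high CG with high CHG/CHH is transposon-like and
    excluded; missing context data excludes the gene.
    """
    cg = gene_context_means["CG"].mean(axis=1)
    chg = gene_context_means["CHG"].mean(axis=1)
    chh = gene_context_means["CHH"].mean(axis=1) if use_chh else None
    labels = {}
    for gene in cg.index:
        vals = [cg.get(gene), chg.get(gene)]
        if use_chh:
            vals.append(chh.get(gene))
        if any(v is None or np.isnan(v) for v in vals):
            labels[gene] = "excluded"
            continue
        non_cg_high = chg[gene] >= chg_max or (use_chh and chh[gene] >= chg_max)
        if cg[gene] >= cg_min and not non_cg_high:
            labels[gene] = "gbm"
        elif cg[gene] >= cg_min:
            labels[gene] = "te_like"
        else:
            labels[gene] = "unmethylated"
    return pd.Series(labels, name="gbm_class")


def site_group_comparison(
    counts: MethylCounts,
    group_labels: pd.Series,
    detect_cutoff: float = 0.01,
    context: str = "CG",
    min_coverage: int = 1,
) -> dict:
    """Per-site group means, detected-site counts, and their difference.

    ``group_labels`` maps sample column index (or accession) to exactly
    two group names; the difference is first-group minus second-group.
    """
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    sub = counts.select_context(context)
    lv = site_levels(sub, min_coverage)
    means = {}
    for gname in groups:
        accs = set(group_labels.index[group_labels == gname])
        cols = sub.samples["accession"].isin(accs).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 accessions")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means[gname] = np.nanmean(lv[:, cols], axis=1)
    g1, g2 = groups
    detected = {g: int(np.nansum(means[g] >= detect_cutoff)) for g in groups}
    diff = means[g1] - means[g2]
    return {"group_means": means, "detected_sites": detected,
            "difference": diff, "groups": (g1, g2)}
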