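"""Population differentiation and environment-of-origin analyses.

Hudson Fst (ratio of averages across sites), Haseman-Elston regression
for additive variance, the Qst statistic
``sigmaB^2 / (sigmaB^2 + 2 sigmaW^2)``, climate-variable correlation
tables, allele-frequency geography of associated SNPs, SNP-set overlap
permutation enrichment, and expression contrasts between regions for
GBM / non-GBM gene classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, pearsonr, ranksums, spearmanr

from .datatypes import GenotypeTable
from .gwas import kinship_ibs


# --------------------------------------------------------------------------
# Hudson Fst

def hudson_fst_site(p1, p2, n1, n2):
    """Per-site Hudson numerator and denominator (sample-size corrected)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(g: GenotypeTable, region_col: str = "region") -> dict:
    """Hudson Fst between the north and south subpopulations.

    Returns per-site values plus the genome-wide ratio-of-averages
    estimate (and the average-of-ratios, for comparison; the genome
    value is the ratio of averages).  Sites monomorphic in both
    populations are excluded.
    """
    region = g.metadata[region_col].to_numpy()
    pops = pd.unique(region)
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    m1 = region == pops[0]
    m2 = region == pops[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 sampled accessions per population")
    geno = np.ma.masked_equal(g.genotypes, -1)
    p1 = np.asarray(geno[m1].mean(axis=0))
    p2 = np.asarray(geno[m2].mean(axis=0))
    num, den = hudson_fst_site(p1, p2, n1, n2)
    keep = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(keep, num / np.where(keep, den, 1.0), np.nan)
    fst = (float(num[keep].sum() / den[keep].sum()) if keep.any()
           else float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_of_ratios = float(np.nanmean(per_site[keep]))
    return {
        "fst": fst,
        "fst_mean_of_ratios": mean_of_ratios,
        "per_site": per_site,
        "numerator": num,
        "denominator": den,
        "populations": tuple(pops),
    }


# --------------------------------------------------------------------------
# Haseman-Elston / Qst

def he_additive_variance(y: np.ndarray, K: np.ndarray) -> float:
    """Additive variance by Haseman-Elston product regression.

    Regresses the off-diagonal phenotype cross-products ``y_i y_j``
    (i < j, phenotype centered) on the matching kinship entries, with an
    intercept; the slope, floored at 0, estimates sigma_A^2.
    """
    y = np.asarray(y, float)
    y = y - y.mean()
    iu = np.triu_indices(len(y), k=1)
    cp = (np.outer(y, y))[iu]
    kk = np.asarray(K)[iu]
    if np.ptp(kk) < 1e-12:
        raise ValueError("kinship off-diagonals are constant; slope undefined")
    X = np.column_stack([np.ones_like(kk), kk])
    coef, *_ = np.linalg.lstsq(X, cp, rcond=None)
    return float(max(coef[1], 0.0))


@dataclass
class QstResult:
    sigma2_overall: float
    sigma2_north: float
    sigma2_south: float
    sigma2_within: float
    sigma2_between: float
    qst: float
    degenerate: bool

    def summary(self) -> str:
        return (
            "Qst (Haseman-Elston additive variances)\n"
            f"  overall {self.sigma2_overall:.4f}  north "
            f"{self.sigma2_north:.4f}  south {self.sigma2_south:.4f}\n"
            f"  within (weighted) {self.sigma2_within:.4f}  between "
            f"{self.sigma2_between:.4f}\n"
            f"  Qst = {self.qst:.4f}" +
            ("  [degenerate variances]" if self.degenerate else "")
        )


def qst(y: np.ndarray, g: GenotypeTable, region_col: str = "region",
        north_label: str = "north") -> QstResult:
    """Quantitative-trait differentiation between north and south.

    sigmaW^2 is the (n_k - 1)-weighted average of the within-population
    additive variances, sigmaB^2 = overall - within floored at 0, and
    Qst = sigmaB^2 / (sigmaB^2 + 2 sigmaW^2).  Within-population kinship
    is recomputed on each subsample to keep the IBS normalization
    consistent.
    """
    region = g.metadata[region_col].to_numpy()
    mN = region == north_label
    mS = ~mN
    if min(mN.sum(), mS.sum()) < 4:
        raise ValueError("need >= 4 accessions per population")
    y = np.asarray(y, float)
    K_all = kinship_ibs(g)
    s2_all = he_additive_variance(y, K_all)
    out = {}
    for name, m in (("north", mN), ("south", mS)):
        sub = g.subset_accessions(np.flatnonzero(m))
        out[name] = he_additive_variance(y[m], kinship_ibs(sub))
    wN, wS = mN.sum() - 1, mS.sum() - 1
    s2_w = (wN * out["north"] + wS * out["south"]) / (wN + wS)
    s2_b = max(s2_all - s2_w, 0.0)
    denom = s2_b + 2 * s2_w
    degenerate = denom <= 0
    q = 0.0 if degenerate else s2_b / denom
    return QstResult(sigma2_overall=s2_all, sigma2_north=out["north"],
                     sigma2_south=out["south"], sigma2_within=s2_w,
                     sigma2_between=s2_b, qst=q, degenerate=degenerate)


# --------------------------------------------------------------------------
# environment-of-origin correlations

def env_correlations(methylation: pd.DataFrame, env: pd.DataFrame
                     ) -> pd.DataFrame:
    """Correlation table of methylation averages vs climate variables.

    ``methylation`` is long (accession, environment, context, level) as
    from :func:`methclime.quant.context_averages`; ``env`` is accession-
    indexed with one column per environment-of-origin variable.  For
    each (variable, growth environment, context): Pearson r, Spearman
    rho and its two-sided p, pairwise-complete.
    """
    rows = []
    for var in env.columns:
        for (genv, ctx), sub in methylation.groupby(
                ["environment", "context"], sort=False):
            x = sub.set_index("accession")["level"]
            joined = pd.concat([x, env[var]], axis=1, join="inner").dropna()
            if len(joined) < 3 or joined.iloc[:, 1].nunique() < 2 \
                    or joined.iloc[:, 0].nunique() < 2:
                rows.append((var, genv, ctx, np.nan, np.nan, np.nan,
                             len(joined)))
                continue
            r = pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
            rho, p = spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append((var, genv, ctx, r, rho, p, len(joined)))
    return pd.DataFrame(rows, columns=["variable", "growth_env", "context",
                                       "pearson_r", "spearman_rho",
                                       "rho_p", "n"])


# --------------------------------------------------------------------------
# allele geography / SNP-set enrichment

def allele_geography(g: GenotypeTable, snp_idx: np.ndarray,
                     n_background: int = 10_000, seed: int = 0) -> dict:
    """Regional frequencies, latitude correlations and spectrum shift.

    For each SNP in the set: non-reference allele frequency per region
    and the point-biserial (Pearson) correlation between the allele and
    latitude; the set's overall-frequency spectrum is compared to
    random background SNPs with a two-sample KS test.
    """
    snp_idx = np.asarray(snp_idx)
    if snp_idx.size == 0:
        raise ValueError("empty SNP set")
    rng = np.random.default_rng(seed)
    region = g.metadata["region"].to_numpy()
    lat = g.metadata["latitude"].to_numpy(float)
    geno = g.genotypes
    rows = []
    for j in snp_idx:
        col = geno[:, j].astype(float)
        freq_n = float(col[region == "north"].mean())
        freq_s = float(col[region == "south"].mean())
        if col.std() > 0 and np.std(lat) > 0:
            r = float(pearsonr(col, lat).statistic)
        else:
            r = np.nan
        rows.append((int(j), freq_n, freq_s, r))
    table = pd.DataFrame(rows, columns=["snp_index", "freq_north",
                                        "freq_south", "latitude_r"])
    bg = rng.choice(g.n_snps, size=min(n_background, g.n_snps), replace=False)
    set_freq = geno[:, snp_idx].mean(axis=0)
    bg_freq = geno[:, bg].mean(axis=0)
    ks = ks_2samp(set_freq, bg_freq)
    return {"table": table, "spectrum_ks_stat": float(ks.statistic),
            "spectrum_ks_p": float(ks.pvalue),
            "background_freqs": bg_freq, "set_freqs": set_freq}


def snp_overlap_permutation(
    g: GenotypeTable,
    snp_idx: np.ndarray,
    regions: pd.DataFrame | None = None,
    anchor_snps: np.ndarray | None = None,
    flank: int = 0,
    n_perm: int = 1000,
    seed: int = 0,
    freq_match: bool = True,
    maf_bin: float = 0.02,
) -> dict:
    """Fold enrichment of a SNP set in genomic regions, by permutation.

    ``regions`` is an interval table (chrom, start, end, 1-based
    closed), or ``anchor_snps`` plus ``flank`` defines regions around
    anchor positions.  Null sets are frequency-matched random SNP draws
    (MAF bins of ``maf_bin``); if a bin cannot be matched the draw falls
    back to uniform with a warning.  p = (#null >= obs + 1)/(n_perm + 1).
    """
    snp_idx = np.asarray(snp_idx)
    rng = np.random.default_rng(seed)
    chrom = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    inside = np.zeros(g.n_snps, bool)
    if regions is not None:
        for _, r in regions.iterrows():
            inside |= (chrom == r["chrom"]) & (pos >= r["start"] - flank) \
                & (pos <= r["end"] + flank)
    elif anchor_snps is not None:
        for j in np.asarray(anchor_snps):
            inside |= (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= flank)
    else:
        raise ValueError("provide regions or anchor_snps")

    observed = int(inside[snp_idx].sum())
    freqs = np.ma.masked_equal(g.genotypes, -1).mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    bins = np.floor(np.asarray(maf) / maf_bin).astype(int)
    k = len(snp_idx)
    null = np.empty(n_perm, dtype=np.int64)
    uniform_fallback = False
    pool_by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    set_bins = bins[snp_idx]
    for r in range(n_perm):
        draw = np.empty(k, dtype=np.int64)
        for i, b in enumerate(set_bins):
            pool = pool_by_bin.get(b)
            if freq_match and pool is not None and len(pool) > 0:
                draw[i] = rng.choice(pool)
            else:
                uniform_fallback = True
                draw[i] = rng.integers(g.n_snps)
        null[r] = inside[draw].sum()
    if uniform_fallback and freq_match:
        warnings.warn("frequency matching incomplete; uniform draws used "
                      "for some SNPs")
    mean_null = null.mean()
    fold = observed / mean_null if mean_null > 0 else np.inf
    p = (int((null >= observed).sum()) + 1) / (n_perm + 1)
    return {"observed": observed, "null_mean": float(mean_null),
            "fold": float(fold), "p": float(p), "null": null}


# --------------------------------------------------------------------------
# expression contrasts

def normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Median-of-genes effective library-size normalization per sample."""
    wide = expr.pivot_table(index="gene",
                            columns=["accession", "environment"],
                            values="expression")
    med = wide.median(axis=0)
    scale = med / med.mean()
    norm = wide / scale
    out = norm.stack(["accession", "environment"], future_stack=True) \
        .rename("expression").reset_index()
    return out


def expression_comparisons(
    expr: pd.DataFrame,
    gene_classes: pd.Series,
    metadata: pd.DataFrame,
    temps: tuple[str, str] = ("10C", "16C"),
    normalize: bool = True,
) -> dict:
    """Region contrasts of expression for GBM vs non-GBM gene classes.

    Per gene class and growth environment: Wilcoxon rank-sum of
    per-accession mean expression, north vs south; per-gene
    between-temperature variation |delta expression| compared north vs
    south; and the per-accession GBM-mean expression normalized by the
    non-GBM mean (a within-sample control for library size).
    """
    if normalize:
        expr = normalize_expression(expr)
    gbm_genes = set(gene_classes.index[gene_classes == "gbm"])
    known = set(gene_classes.index)
    cls = expr["gene"].map(
        lambda g: "gbm" if g in gbm_genes
        else ("non_gbm" if g in known else "unknown"))
    expr = expr.assign(gene_class=cls)
    expr = expr[expr["gene_class"] != "unknown"]
    region = metadata["region"]

    results: dict = {"north_vs_south": {}, "temp_variation": {},
                     "gbm_norm_by_nongbm": None}
    for genv in temps:
        sub = expr[expr["environment"] == genv]
        for gcls, s2 in sub.groupby("gene_class"):
            per_acc = s2.groupby("accession")["expression"].mean()
            if per_acc.index.nunique() < 2 or \
                    s2["gene"].nunique() < 2:
                continue
            north = per_acc[region.reindex(per_acc.index) == "north"]
            south = per_acc[region.reindex(per_acc.index) == "south"]
            stat, p = ranksums(north, south)
            results["north_vs_south"][(genv, gcls)] = {
                "north_mean": float(north.mean()),
                "south_mean": float(south.mean()),
                "stat": float(stat), "p": float(p),
            }
    # between-temperature variation per gene and accession
    wide = expr.pivot_table(index=["gene", "gene_class", "accession"],
                            columns="environment", values="expression")
    if set(temps) <= set(wide.columns):
        delta = (wide[temps[1]] - wide[temps[0]]).abs().rename("delta")
        d = delta.reset_index()
        d["region"] = region.reindex(d["accession"]).to_numpy()
        for gcls, s2 in d.groupby("gene_class"):
            per_acc = s2.groupby(["accession", "region"],
                                 observed=True)["delta"].mean().reset_index()
            north = per_acc.loc[per_acc["region"] == "north", "delta"]
            south = per_acc.loc[per_acc["region"] == "south", "delta"]
            if len(north) and len(south):
                stat, p = ranksums(north, south)
                results["temp_variation"][gcls] = {
                    "north_mean": float(north.mean()),
                    "south_mean": float(south.mean()),
                    "stat": float(stat), "p": float(p),
                }
    # GBM-mean normalized by non-GBM mean per accession
    per = expr.groupby(["accession", "gene_class"])["expression"].mean() \
        .unstack("gene_class")
    if {"gbm", "non_gbm"} <= set(per.columns):
        results["gbm_norm_by_nongbm"] = (per["gbm"] / per["non_gbm"])
    return results
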