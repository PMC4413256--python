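"""Kinship-corrected association mapping.

The workhorse is an EMMA-style linear mixed model
``y = X beta + u + e`` with ``u ~ N(0, sg^2 K)`` and ``e ~ N(0, se^2 I)``:
the variance ratio is estimated once by maximum likelihood on the null
model and reused for every SNP (the usual "population parameters
previously determined" approximation), each SNP then being tested by
generalized least squares with a Wald t test.  On top of that sit a
stepwise cofactor scan, cis/trans classification of associations,
effect-direction summaries, BLUP-based structure correction of
phenotypes, an F2 cross simulator, and a Haley-Knott interval-mapping
scan with permutation thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binomtest, chi2, t as t_dist

from .datatypes import GenotypeTable


# --------------------------------------------------------------------------
# kinship

def kinship_ibs(g: GenotypeTable | np.ndarray) -> np.ndarray:
    """Identity-by-state kinship: fraction of SNPs with identical alleles.

    Pairwise-complete over missing (-1) genotypes; the diagonal is 1.
    """
    geno = g.genotypes if isinstance(g, GenotypeTable) else np.asarray(g)
    n = geno.shape[0]
    if n < 2:
        raise ValueError("need at least 2 accessions for kinship")
    obs = (geno >= 0).astype(np.float64)
    g0 = ((geno == 0) & (geno >= 0)).astype(np.float64)
    g1 = (geno == 1).astype(np.float64)
    same = g0 @ g0.T + g1 @ g1.T
    denom = obs @ obs.T
    if (denom == 0).any():
        raise ValueError("accession pair with no jointly observed SNPs")
    K = same / denom
    np.fill_diagonal(K, 1.0)
    return K


def shrink_psd(K: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Add delta*I if K has negative eigenvalues; returns (K', delta)."""
    w = np.linalg.eigvalsh(K)
    lo = w.min()
    if lo >= -tol:
        return K, 0.0
    delta = -lo + tol
    warnings.warn(f"kinship not PSD; shrinking with delta={delta:.3g}")
    return K + delta * np.eye(len(K)), delta


# --------------------------------------------------------------------------
# EMMA-style mixed model

def _ml_delta(yr: np.ndarray, X0r: np.ndarray, S: np.ndarray,
              reml: bool = True) -> tuple[float, float, float]:
    """Estimate delta = se^2/sg^2 on the null model (REML by default).

    Returns (delta, sg2, loglik).  REML is the conventional choice for
    association scans: it removes the small-sample bias of the profiled
    variance and keeps the per-SNP Wald test calibrated.
    """
    n = len(yr)
    p = X0r.shape[1]

    def neg_loglik(logd: float) -> float:
        d = np.exp(logd)
        w = 1.0 / (S + d)
        Xw = X0r * w[:, None]
        A = X0r.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yr)
        r = yr - X0r @ beta
        rss = (r * r * w).sum()
        if reml:
            sg2 = rss / (n - p)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi * sg2)
                         + np.log(S + d).sum()
                         + np.linalg.slogdet(A)[1] + (n - p))
        else:
            sg2 = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * sg2)
                         + np.log(S + d).sum() + n)
        return -ll

    grid = np.linspace(-8, 8, 17)
    vals = [neg_loglik(x) for x in grid]
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(neg_loglik, bounds=(lo, hi), method="bounded")
    d = float(np.exp(res.x))
    w = 1.0 / (S + d)
    Xw = X0r * w[:, None]
    beta = np.linalg.solve(X0r.T @ Xw, Xw.T @ yr)
    r = yr - X0r @ beta
    sg2 = float((r * r * w).sum() / (n - p if reml else n))
    return d, sg2, -float(res.fun)


@dataclass
class LMMScanResults:
    """Single-marker mixed-model scan results (statsmodels-style)."""

    assoc: pd.DataFrame
    delta: float
    sigma_g2: float
    null_loglik: float
    bonferroni: float
    n_tested: int
    cofactors: list[int] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.assoc[self.assoc["significant"]]

    def top_hit(self) -> pd.Series:
        tested = self.assoc.dropna(subset=["p"])
        return tested.loc[tested["p"].idxmin()]

    def lambda_gc(self) -> float:
        p = self.assoc["p"].dropna().to_numpy()
        stat = chi2.isf(p, df=1)
        return float(np.median(stat) / chi2.isf(0.5, df=1))

    def summary(self) -> str:
        lines = [
            "Mixed-model association scan",
            f"  SNPs tested: {self.n_tested}  (Bonferroni "
            f"p<={self.bonferroni:.3g})",
            f"  delta (se^2/sg^2): {self.delta:.4g}   "
            f"null loglik: {self.null_loglik:.2f}",
            f"  significant hits: {int(self.assoc['significant'].sum())}",
        ]
        if self.cofactors:
            lines.append(f"  cofactor SNP indices: {self.cofactors}")
        return "\n".join(lines)


class MixedLMM:
    """EMMA-style LMM for one phenotype against a genotype panel.

    Parameters
    ----------
    y : phenotype vector aligned with the genotype rows.
    genotypes : GenotypeTable (or plain 0/1 matrix).
    K : kinship matrix; computed by IBS if omitted.
    maf_min : SNPs below this minor-allele frequency are not tested.
    """

    def __init__(self, y, genotypes, K: np.ndarray | None = None,
                 maf_min: float = 0.05):
        self.gt = genotypes if isinstance(genotypes, GenotypeTable) else None
        G = (genotypes.genotypes if self.gt is not None
             else np.asarray(genotypes)).astype(np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(y) != G.shape[0]:
            raise ValueError("phenotype not aligned with genotype rows")
        # mean-impute missing genotypes per SNP
        miss = G < 0
        if miss.any():
            colmean = np.where(
                miss.all(axis=0), 0.0,
                np.nanmean(np.where(miss, np.nan, G), axis=0))
            G = np.where(miss, colmean[None, :], G)
        self.y = y
        self.G = G
        self.n, self.m = G.shape
        if K is None:
            K = kinship_ibs(genotypes)
        K, _ = shrink_psd(K)
        S, U = np.linalg.eigh(K)
        self.S = np.clip(S, 0.0, None)
        self.U = U
        self.maf_min = maf_min

    def fit(self, cofactors: list[int] | None = None,
            alpha: float = 0.05) -> LMMScanResults:
        cof = list(cofactors or [])
        X0 = np.column_stack([np.ones(self.n)] +
                             [self.G[:, j] for j in cof])
        yr = self.U.T @ self.y
        X0r = self.U.T @ X0
        delta, sg2, ll0 = _ml_delta(yr, X0r, self.S)
        w = 1.0 / (self.S + delta)
        sw = np.sqrt(w)
        yt = yr * sw
        X0t = X0r * sw[:, None]
        Gt = (self.U.T @ self.G) * sw[:, None]
        # residualize against the null design
        Q0, _ = np.linalg.qr(X0t)
        yq = yt - Q0 @ (Q0.T @ yt)
        Gq = Gt - Q0 @ (Q0.T @ Gt)
        gg = (Gq * Gq).sum(axis=0)
        gy = Gq.T @ yq
        yy = float(yq @ yq)
        p0 = X0t.shape[1]
        dof = self.n - p0 - 1

        freqs = self.G.mean(axis=0)
        maf = np.minimum(freqs, 1 - freqs)
        testable = (maf >= self.maf_min) & (gg > 1e-10 * self.n)
        testable[cof] = False  # no self-testing of cofactors

        beta = np.full(self.m, np.nan)
        se = np.full(self.m, np.nan)
        pvals = np.full(self.m, np.nan)
        b = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = yy - b * gy
        s2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se_all = np.sqrt(s2 / gg)
            tstat = b / se_all
        beta[testable] = b[testable]
        se[testable] = se_all[testable]
        pvals[testable] = 2 * t_dist.sf(np.abs(tstat[testable]), dof)

        n_tested = int(testable.sum())
        thr = alpha / max(n_tested, 1)
        assoc = pd.DataFrame({
            "snp": (self.gt.snps["id"] if self.gt is not None
                    else pd.RangeIndex(self.m).astype(str)),
            "chrom": (self.gt.snps["chrom"] if self.gt is not None else ""),
            "pos": (self.gt.snps["pos"] if self.gt is not None else -1),
            "beta": beta, "se": se, "p": pvals, "maf": maf,
            "significant": np.where(np.isnan(pvals), False, pvals <= thr),
        })
        return LMMScanResults(assoc=assoc, delta=delta, sigma_g2=sg2,
                              null_loglik=ll0, bonferroni=thr,
                              n_tested=n_tested, cofactors=cof)


def lmm_scan(y, genotypes, K: np.ndarray | None = None,
             cofactors: list[int] | None = None,
             maf_min: float = 0.05, alpha: float = 0.05) -> LMMScanResults:
    """Functional wrapper around :class:`MixedLMM`."""
    return MixedLMM(y, genotypes, K, maf_min).fit(cofactors, alpha)


def stepwise_scan(y, genotypes, K: np.ndarray | None = None,
                  max_cofactors: int = 5, maf_min: float = 0.05,
                  alpha: float = 0.05) -> dict:
    """Multi-locus scan: iteratively condition on the strongest SNP.

    Stops when no SNP passes the per-scan Bonferroni threshold or
    ``max_cofactors`` is reached.  Returns the ordered cofactor list and
    the per-step scan results.
    """
    if max_cofactors < 1:
        raise ValueError("max_cofactors must be >= 1")
    model = MixedLMM(y, genotypes, K, maf_min)
    cof: list[int] = []
    steps = []
    for _ in range(max_cofactors + 1):
        res = model.fit(cofactors=cof, alpha=alpha)
        steps.append(res)
        tested = res.assoc.dropna(subset=["p"])
        if tested.empty:
            break
        j = int(tested["p"].idxmin())
        if tested.loc[j, "p"] > res.bonferroni or len(cof) >= max_cofactors:
            break
        cof.append(j)
    return {"cofactors": cof, "steps": steps}


# --------------------------------------------------------------------------
# cis / trans

def classify_cis_trans(assoc: pd.DataFrame, cis_window: int = 100_000) -> dict:
    """Label associations cis/trans relative to each phenotype's anchor.

    ``assoc`` needs columns phenotype, anchor_chrom, anchor_pos, chrom,
    pos, significant.  cis = same chromosome within ``cis_window`` bp.
    Returns the labeled frame plus summary fractions.
    """
    df = assoc.copy()
    has_anchor = df["anchor_chrom"].notna() & df["anchor_pos"].notna()
    df["cis"] = (
        has_anchor
        & (df["chrom"] == df["anchor_chrom"])
        & ((df["pos"] - df["anchor_pos"]).abs() <= cis_window)
    )
    sig = df[df["significant"] & has_anchor]
    phenos = sig.groupby("phenotype")["cis"].any()
    frac_cis_pheno = float(phenos.mean()) if len(phenos) else np.nan
    frac_trans_assoc = (float((~sig["cis"]).mean()) if len(sig) else np.nan)
    return {
        "assoc": df,
        "fraction_phenotypes_with_cis": frac_cis_pheno,
        "fraction_associations_trans": frac_trans_assoc,
        "n_phenotypes": int(len(phenos)),
    }


def effect_direction_summary(assoc: pd.DataFrame,
                             class_col: str = "cis") -> dict:
    """Direction-of-effect tally of non-reference alleles, per cis/trans.

    Genotypes are coded as non-reference allele counts, so ``beta``'s
    sign is the non-reference direction directly.  Reports up/down
    counts, both ratios, and the exact two-sided binomial p against 0.5.
    """
    out = {}
    sig = assoc[assoc["significant"]]
    for label, sub in sig.groupby(sig[class_col].map(
            {True: "cis", False: "trans"})):
        n_up = int((sub["beta"] > 0).sum())
        n_down = int((sub["beta"] < 0).sum())
        if n_up + n_down == 0:
            out[label] = {"n_up": 0, "n_down": 0, "ratio_up_down": np.nan,
                          "ratio_down_up": np.nan, "p": np.nan}
            continue
        p = binomtest(n_up, n_up + n_down, 0.5).pvalue
        out[label] = {
            "n_up": n_up, "n_down": n_down,
            "ratio_up_down": n_up / n_down if n_down else np.inf,
            "ratio_down_up": n_down / n_up if n_up else np.inf,
            "p": float(p),
        }
    return out


# --------------------------------------------------------------------------
# BLUP correction

def blup_correct(y, K: np.ndarray) -> np.ndarray:
    """Remove the BLUP of the kinship random effect from a phenotype.

    Fits ``y = mu + u + e`` with ``u ~ N(0, sg^2 K)`` by ML and returns
    ``y - u_hat``.  With sg^2 -> 0 the phenotype is returned unchanged.
    """
    y = np.asarray(y, dtype=np.float64)
    K, _ = shrink_psd(K)
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yr = U.T @ y
    X0r = U.T @ np.ones((len(y), 1))
    delta, sg2, _ = _ml_delta(yr, X0r, S)
    w = 1.0 / (S + delta)
    Xw = X0r * w[:, None]
    mu = float(np.linalg.solve(X0r.T @ Xw, Xw.T @ yr).ravel()[0])
    r = yr - X0r.ravel() * mu
    u_hat = U @ (S / (S + delta) * r)
    return y - u_hat


# --------------------------------------------------------------------------
# F2 cross simulation and Haley-Knott interval mapping

def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


def _f2_transition(r: float) -> np.ndarray:
    """3x3 genotype transition matrix between linked loci in an F2."""
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def simulate_f2(marker_map: pd.DataFrame, n_individuals: int,
                seed: int = 0) -> np.ndarray:
    """F2 genotypes {0,1,2} at mapped markers via two independent gametes.

    ``marker_map`` columns: chrom, cM (ascending within chromosome).
    """
    rng = np.random.default_rng(seed)
    marker_map = marker_map.reset_index(drop=True)
    geno = np.zeros((n_individuals, len(marker_map)), dtype=np.int8)
    for chrom in pd.unique(marker_map["chrom"]):
        idx = np.flatnonzero((marker_map["chrom"] == chrom).to_numpy())
        cm = marker_map.loc[idx, "cM"].to_numpy()
        if not np.all(np.diff(cm) >= 0):
            raise ValueError("markers unordered within chromosome")
        r = haldane_r(np.diff(cm))
        for gamete in range(2):
            al = np.zeros((n_individuals, len(idx)), dtype=np.int8)
            al[:, 0] = rng.random(n_individuals) < 0.5
            for k in range(1, len(idx)):
                flip = rng.random(n_individuals) < r[k - 1]
                al[:, k] = np.where(flip, 1 - al[:, k - 1], al[:, k - 1])
            geno[:, idx] += al
    return geno


@dataclass
class HKScanResults:
    """Haley-Knott scan: LOD curve, permutation threshold, peak support."""

    grid: pd.DataFrame       # chrom, cM, lod
    threshold: float
    n_perm: int
    peak: pd.Series
    support_interval: tuple[float, float]

    def summary(self) -> str:
        return (
            "Haley-Knott F2 scan\n"
            f"  peak: {self.peak['chrom']} @ {self.peak['cM']:.1f} cM, "
            f"LOD {self.peak['lod']:.2f}\n"
            f"  genome-wide 0.05 threshold ({self.n_perm} permutations): "
            f"{self.threshold:.2f}\n"
            f"  1.5-LOD support interval: "
            f"[{self.support_interval[0]:.1f}, "
            f"{self.support_interval[1]:.1f}] cM"
        )


def hk_scan(f2_genotypes: np.ndarray, phenotype: np.ndarray,
            marker_map: pd.DataFrame, step_cM: float = 4.0,
            n_perm: int = 1000, seed: int = 0,
            alpha: float = 0.05) -> HKScanResults:
    """Haley-Knott regression on an F2: additive + dominance dosages.

    At each grid position, genotype probabilities are obtained from the
    flanking markers under the Haldane map function; the phenotype is
    regressed on the expected additive (P(BB) - P(AA)) and dominance
    (P(AB)) dosages and LOD = (n/2) log10(RSS0/RSS1).  The genome-wide
    threshold is the (1 - alpha) quantile of the max LOD over phenotype
    permutations.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1) \
        if n_perm > 0 else np.empty((n, 0))
    Yall = np.column_stack([y, perms])
    Yc = Yall - Yall.mean(axis=0)
    rss0 = (Yc * Yc).sum(axis=0)

    rows = []
    lods = []
    marker_map = marker_map.reset_index(drop=True)
    for chrom in pd.unique(marker_map["chrom"]):
        idx = np.flatnonzero((marker_map["chrom"] == chrom).to_numpy())
        cm = marker_map.loc[idx, "cM"].to_numpy()
        if not np.all(np.diff(cm) > 0):
            raise ValueError("markers unordered within chromosome")
        G = f2_genotypes[:, idx]
        grid = np.arange(cm[0], cm[-1] + 1e-9, step_cM)
        if grid[-1] < cm[-1]:
            grid = np.append(grid, cm[-1])
        for pos in grid:
            jr = int(np.searchsorted(cm, pos, side="left"))
            jl = max(jr - 1, 0)
            jr = min(jr, len(cm) - 1)
            if np.isclose(pos, cm[jr]):
                probs = np.eye(3)[G[:, jr]]
            elif np.isclose(pos, cm[jl]):
                probs = np.eye(3)[G[:, jl]]
            else:
                Tl = _f2_transition(float(haldane_r(pos - cm[jl])))
                Tr = _f2_transition(float(haldane_r(cm[jr] - pos)))
                Tlr = _f2_transition(float(haldane_r(cm[jr] - cm[jl])))
                num = Tl[G[:, jl]] * Tr[:, G[:, jr]].T
                den = Tlr[G[:, jl], G[:, jr]]
                probs = num / den[:, None]
            a = probs[:, 2] - probs[:, 0]
            d = probs[:, 1]
            X = np.column_stack([np.ones(n), a, d])
            Q, _ = np.linalg.qr(X)
            proj = Q.T @ Yall
            rss1 = (Yall * Yall).sum(axis=0) - (proj * proj).sum(axis=0)
            rss1 = np.maximum(rss1, 1e-300)
            lod = (n / 2.0) * np.log10(rss0 / rss1)
            rows.append((chrom, float(pos)))
            lods.append(lod)
    lods = np.asarray(lods)  # (n_grid, 1 + n_perm)
    grid_df = pd.DataFrame(rows, columns=["chrom", "cM"])
    grid_df["lod"] = lods[:, 0]
    if n_perm > 0:
        max_perm = lods[:, 1:].max(axis=0)
        threshold = float(np.quantile(max_perm, 1 - alpha))
    else:
        threshold = np.nan
    pk = grid_df.loc[grid_df["lod"].idxmax()]
    on_chrom = grid_df[grid_df["chrom"] == pk["chrom"]]
    drop = on_chrom[on_chrom["lod"] >= pk["lod"] - 1.5]
    support = (float(drop["cM"].min()), float(drop["cM"].max()))
    return HKScanResults(grid=grid_df, threshold=threshold, n_perm=n_perm,
                         peak=pk, support_interval=support)
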