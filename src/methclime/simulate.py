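"""Synthetic data generator.

Emulates the data structure of a two-temperature methylome study of
naturally inbred *Arabidopsis* accessions from a latitudinally structured
population: Balding-Nichols two-subpopulation genotypes, a major trans
locus for TE CHH methylation represented by a repulsion-phase SNP pair
("CMT2a"/"CMT2b", whose non-reference alleles never co-occur), cis SNP
effects on individual transposons, temperature-sensitive CHH methylation
(higher at 16C than 10C), CG gene-body methylation driven by a set of
north-enriched trans SNPs so that it correlates with latitude of origin,
and bisulfite conversion error applied symmetrically at read level.

All distributional choices are generator conventions: effects act on the
logit of the per-site methylation probability and observed counts are
binomial draws at Poisson sequencing depth.  None of this is inferred
from real data; it exists so every downstream stage of the pipeline can
be tested against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datatypes import (
    ENVIRONMENTS,
    AnnotationSet,
    GenotypeTable,
    MethylCounts,
    TruthRecord,
)

# Default TE family table (family -> (superfamily, relative frequency)).
# Names follow the common Arabidopsis repeat nomenclature.
DEFAULT_TE_FAMILIES = {
    "HELITRONY3": ("RC/Helitron", 0.20),
    "ATREP3": ("RC/Helitron", 0.12),
    "ATREP2": ("RC/Helitron", 0.06),
    "VANDAL21": ("DNA/MuDR", 0.08),
    "VANDAL2": ("DNA/MuDR", 0.06),
    "ATMU1": ("DNA/MuDR", 0.06),
    "ATCOPIA78": ("LTR/Copia", 0.08),
    "META1": ("LTR/Gypsy", 0.10),
    "ATGP1": ("LTR/Gypsy", 0.08),
    "ATSINE4": ("SINE", 0.04),
    "RathE1_cons": ("SINE-like", 0.04),
    "ATLINE1_1": ("LINE/L1", 0.08),
}


@dataclass
class Architecture:
    """Effect sizes on the logit scale, and planted population signals."""

    cis_effect: float = 1.4          # per-TE cis SNP effect (random sign)
    cis_fraction: float = 0.45       # fraction of TEs given a cis SNP effect
    trans_poly_sd: float = 0.25      # polygenic trans effect on TE CHH
    major_effect_a: float = 0.9      # CMT2a non-ref raises TE CHH
    major_effect_b: float = 0.9      # CMT2b non-ref lowers TE CHH
    env_chh_ratio: float = 1.14      # genome-wide mean CHH at 16C / 10C
    # planted temperature DMRs are sized to be callable at the standard
    # 0.3 minimum-difference threshold (baseline ~0.12 -> ~0.5)
    temp_gain_shift: float = 2.0     # extra 16C logit shift in gain-DMR TEs
    temp_loss_shift: float = -2.5    # 16C logit shift in loss-DMR TEs
    n_gbm_trans_snps: int = 15       # north-enriched trans SNPs for GBM
    gbm_trans_effect: float = 0.12   # per-SNP liability effect
    gbm_poly_sd: float = 0.25        # polygenic GBM liability (within-pop sd)
    gbm_noise_sd: float = 0.53       # non-genetic GBM liability noise
    expression_coupling: float = 0.25


@dataclass
class SimConfig:
    n_accessions: int = 150
    n_snps: int = 10000
    genome_length: int = 2_000_000
    n_chromosomes: int = 5
    pop_split: float = 0.5           # fraction of accessions from the north
    fst_target: float = 0.187
    n_genes: int = 300
    n_tes: int = 300
    architecture: Architecture = field(default_factory=Architecture)
    conversion_error: float = 0.0041
    depth_mean: float = 12.6
    seed: int = 0
    # generator geometry
    site_spacing: int = 40           # bp between simulated cytosines
    context_probs: tuple = (0.25, 0.25, 0.50)   # CG, CHG, CHH
    chloroplast_length: int = 20_000
    lat_split: float = 60.0
    within_demes: int = 4            # nested demes per region
    within_fst: float = 0.05         # deme-level divergence within regions
    gbm_gene_fraction: float = 0.30
    telike_gene_fraction: float = 0.05
    variable_te_fraction: float = 0.027
    # sized so called loss windows run at about half the gained ones
    temp_loss_te_fraction: float = 0.02
    cmt2_dependent_te_fraction: float = 0.5
    major_freqs: dict = field(default_factory=lambda: {
        # non-reference allele frequencies by region (paper-scale)
        "a": {"south": 0.226, "north": 0.095},
        "b": {"south": 0.306, "north": 0.079},
    })
    te_families: dict = field(default_factory=lambda: dict(DEFAULT_TE_FAMILIES))
    include_cmt2_null: bool = False

    def validate(self) -> None:
        if min(self.n_accessions, self.n_snps, self.n_genes + self.n_tes,
               self.n_chromosomes) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.pop_split <= 1.0):
            raise ValueError("pop_split must be a fraction")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if not (0.0 <= self.conversion_error < 0.5):
            raise ValueError("conversion_error must be a small fraction")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


def _chrom_names(cfg: SimConfig) -> list[str]:
    return [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]


def _chrom_length(cfg: SimConfig) -> int:
    return cfg.genome_length // cfg.n_chromosomes


def simulate_genotypes(cfg: SimConfig) -> GenotypeTable:
    """Two-subpopulation inbred genotypes with planted focal loci.

    Allele-frequency divergence follows the Balding-Nichols model with
    divergence parameter equal to ``cfg.fst_target``, so the realized
    Hudson Fst tracks the target.  Two designated SNPs form the
    CMT2-like major-locus pair: their non-reference alleles are drawn in
    repulsion (never on the same accession), at region-specific
    frequencies.  A further block of north-enriched SNPs (ids
    ``GBMtrans*``) provides the trans architecture of gene-body
    methylation.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    n_north = int(round(cfg.pop_split * n))
    n_south = n - n_north
    if min(n_north, n_south) < 4:
        raise ValueError(
            "need at least 4 accessions per subpopulation for variance "
            f"estimates (got north={n_north}, south={n_south})"
        )
    region = np.array(["north"] * n_north + ["south"] * n_south)
    lat = np.where(
        region == "north",
        rng.uniform(62.8, 68.4, size=n),
        rng.uniform(55.4, 59.9, size=n),
    )

    # Balding-Nichols subpopulation frequencies, with nested demes inside
    # each region so that within-region kinship is not degenerate
    F = cfg.fst_target
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_north = rng.beta(a, b)
        p_south = rng.beta(a, b)
    else:
        p_north = p_anc
        p_south = p_anc

    def _deme_freqs(p_reg: np.ndarray) -> np.ndarray:
        Fw = cfg.within_fst
        if Fw <= 0 or cfg.within_demes <= 1:
            return np.tile(p_reg, (max(cfg.within_demes, 1), 1))
        pc = np.clip(p_reg, 1e-3, 1 - 1e-3)
        aw = pc * (1 - Fw) / Fw
        bw = (1 - pc) * (1 - Fw) / Fw
        return rng.beta(aw[None, :], bw[None, :],
                        size=(cfg.within_demes, cfg.n_snps))

    geno = np.empty((n, cfg.n_snps), dtype=np.int8)
    for reg, p_reg in (("north", p_north), ("south", p_south)):
        m = np.flatnonzero(region == reg)
        pd_demes = _deme_freqs(p_reg)
        deme = np.arange(len(m)) % max(cfg.within_demes, 1)
        geno[m] = (rng.random((len(m), cfg.n_snps))
                   < pd_demes[deme]).astype(np.int8)

    # SNP coordinates: uniform over nuclear chromosomes, sorted
    chroms = _chrom_names(cfg)
    L = _chrom_length(cfg)
    chrom_idx = np.sort(rng.integers(0, cfg.n_chromosomes, size=cfg.n_snps))
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    for c in range(cfg.n_chromosomes):
        m = chrom_idx == c
        pos[m] = np.sort(rng.choice(np.arange(1, L + 1), size=m.sum(),
                                    replace=False))
    ids = [f"snp_{chroms[c]}_{p}" for c, p in zip(chrom_idx, pos)]
    snps = pd.DataFrame({
        "chrom": [chroms[c] for c in chrom_idx],
        "pos": pos,
        "id": ids,
    })

    # CMT2-like major-locus pair in repulsion on the middle chromosome
    major_chrom = min(3, cfg.n_chromosomes - 1)  # Chr4 when 5 chromosomes
    cand = np.flatnonzero(chrom_idx == major_chrom)
    mid = L // 2
    order = np.argsort(np.abs(pos[cand] - mid))
    ia, ib = int(cand[order[0]]), int(cand[order[1]])
    if pos[ia] > pos[ib]:
        ia, ib = ib, ia
    for j, name in ((ia, "CMT2a"), (ib, "CMT2b")):
        snps.loc[j, "id"] = name
    fa, fb = cfg.major_freqs["a"], cfg.major_freqs["b"]
    for reg in ("north", "south"):
        m = region == reg
        pa, pb = fa[reg], fb[reg]
        cat = rng.choice(3, size=m.sum(), p=[pa, pb, 1 - pa - pb])
        geno[m, ia] = (cat == 0).astype(np.int8)
        geno[m, ib] = (cat == 1).astype(np.int8)

    # north-enriched trans SNPs for GBM (strong regional differentiation)
    arch = cfg.architecture
    k = arch.n_gbm_trans_snps
    forbidden = {ia, ib}
    pool = [j for j in range(cfg.n_snps) if j not in forbidden]
    trans_idx = rng.choice(pool, size=k, replace=False)
    for j in trans_idx:
        gn = (rng.random(n_north) < 0.85).astype(np.int8)
        gs = (rng.random(n_south) < 0.05).astype(np.int8)
        geno[region == "north", j] = gn
        geno[region == "south", j] = gs
        snps.loc[j, "id"] = f"GBMtrans_{snps.loc[j, 'chrom']}_{snps.loc[j, 'pos']}"

    accessions = [f"acc{i:04d}" for i in range(n)]
    metadata = pd.DataFrame(
        {"latitude": lat, "region": region,
         "cmt2_null": np.zeros(n, dtype=bool)},
        index=accessions,
    )
    if cfg.include_cmt2_null:
        # one rare northern accession with a non-functional CMT2
        null_i = int(np.flatnonzero(region == "north")[0])
        metadata.iloc[null_i, metadata.columns.get_loc("cmt2_null")] = True
    return GenotypeTable(geno, snps, accessions, metadata)


def simulate_annotations(cfg: SimConfig, rng: np.random.Generator | None = None
                         ) -> AnnotationSet:
    """Gene/TE intervals plus a chloroplast control contig.

    Features are laid out on a jittered grid (no pathological overlaps);
    TEs get families/superfamilies from a configurable frequency table
    and a configurable fraction is flagged ``variable`` (the planted
    hosts of temperature DMRs).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    chroms = _chrom_names(cfg)
    L = _chrom_length(cfg)
    n_feat = cfg.n_genes + cfg.n_tes
    if n_feat > 0 and cfg.genome_length < n_feat * 300:
        raise ValueError("genome_length too small for requested features")

    kinds = np.array(["gene"] * cfg.n_genes + ["te"] * cfg.n_tes)
    rng.shuffle(kinds)
    per_chrom = np.array_split(np.arange(n_feat), cfg.n_chromosomes)
    rows = []
    fam_names = list(cfg.te_families)
    fam_probs = np.array([cfg.te_families[f][1] for f in fam_names], float)
    fam_probs = fam_probs / fam_probs.sum()
    gi = ti = 0
    for c, idxs in enumerate(per_chrom):
        k = len(idxs)
        if k == 0:
            continue
        slot = L // k
        for s, j in enumerate(idxs):
            kind = kinds[j]
            start = s * slot + int(rng.integers(1, max(2, slot // 10)))
            if kind == "gene":
                length = int(np.clip(rng.lognormal(7.4, 0.5), 500, slot * 0.9))
                fid, fam, sfam = f"gene{gi:05d}", "", ""
                gi += 1
            else:
                length = int(np.clip(rng.lognormal(7.0, 1.0), 100, slot * 0.9))
                fam = str(rng.choice(fam_names, p=fam_probs))
                sfam = cfg.te_families[fam][0]
                fid = f"te{ti:05d}"
                ti += 1
            end = min(start + length - 1, L)
            rows.append((chroms[c], start, end, kind, fam, sfam, False, fid))
    feats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "kind", "family",
                       "superfamily", "variable", "id"])

    te_rows = np.flatnonzero((feats["kind"] == "te").to_numpy())
    n_var = int(round(cfg.variable_te_fraction * len(te_rows)))
    if n_var > 0:
        var_rows = rng.choice(te_rows, size=n_var, replace=False)
        feats.loc[var_rows, "variable"] = True

    # overlap sanity (construction avoids it; guard anyway)
    ov = 0
    for c in chroms:
        sub = feats[feats["chrom"] == c].sort_values("start")
        if len(sub) > 1:
            ov += int((sub["start"].to_numpy()[1:] <=
                       sub["end"].to_numpy()[:-1]).sum())
    if n_feat > 0 and ov / max(1, n_feat) > 0.5:
        warnings.warn("more than half of simulated features overlap")

    chrom_sizes = {c: L for c in chroms}
    chrom_sizes["ChrC"] = cfg.chloroplast_length
    return AnnotationSet(features=feats, chrom_sizes=chrom_sizes,
                         chloroplast="ChrC")


def _site_feature_index(sites: pd.DataFrame, feats: pd.DataFrame) -> np.ndarray:
    """Index of the feature covering each site (-1 = intergenic).

    Features are non-overlapping per chromosome by construction.
    """
    out = np.full(len(sites), -1, dtype=np.int64)
    for c, sub in feats.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        m = (sites["chrom"] == c).to_numpy()
        if not m.any():
            continue
        p = sites.loc[m, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p <= ends[np.clip(j, 0, None)])
        rows = np.flatnonzero(m)
        out[rows[ok]] = sub.index.to_numpy()[j[ok]]
    return out


def simulate_methylomes(
    genotypes: GenotypeTable,
    annot: AnnotationSet,
    cfg: SimConfig,
) -> tuple[MethylCounts, TruthRecord]:
    """Per-cytosine counts for every accession at both temperatures.

    The latent per-site methylation probability is
    ``expit(baseline + cis + polygenic trans + major locus + environment
    + GBM liability)`` with each term restricted to the context/feature
    combination it belongs to; observed methylated reads are
    ``Binomial(depth, p*(1-eps) + (1-p)*eps)`` with symmetric conversion
    error ``eps`` and Poisson depth.  The chloroplast contig is simulated
    fully unmethylated (p = 0) as the conversion-efficiency control.
    """
    cfg.validate()
    arch = cfg.architecture
    rng = np.random.default_rng(cfg.seed + 2)
    chroms = _chrom_names(cfg)
    L = _chrom_length(cfg)
    n_acc = genotypes.n_accessions

    # --- site grid ---------------------------------------------------------
    rows = []
    for c in chroms:
        p = np.arange(cfg.site_spacing // 2, L, cfg.site_spacing) + 1
        rows.append(pd.DataFrame({"chrom": c, "pos": p}))
    pC = np.arange(cfg.site_spacing // 2, cfg.chloroplast_length,
                   cfg.site_spacing) + 1
    rows.append(pd.DataFrame({"chrom": annot.chloroplast, "pos": pC}))
    sites = pd.concat(rows, ignore_index=True)
    ns = len(sites)
    ctx = rng.choice(["CG", "CHG", "CHH"], size=ns, p=cfg.context_probs)
    strand = rng.choice(["+", "-"], size=ns)
    sites["strand"] = strand
    sites["context"] = ctx

    nuclear = (sites["chrom"] != annot.chloroplast).to_numpy()
    feats = annot.features
    fidx = _site_feature_index(sites, feats)
    in_te = np.zeros(ns, bool)
    in_gene = np.zeros(ns, bool)
    hit = fidx >= 0
    kinds = feats["kind"].reindex(fidx[hit]).to_numpy()
    in_te[np.flatnonzero(hit)[kinds == "te"]] = True
    in_gene[np.flatnonzero(hit)[kinds == "gene"]] = True

    is_cg = ctx == "CG"
    is_chg = ctx == "CHG"
    is_chh = ctx == "CHH"

    # --- gene classes ------------------------------------------------------
    gene_ids = feats.loc[feats["kind"] == "gene", "id"].tolist()
    ng = len(gene_ids)
    gene_class = np.array(["unmethylated"] * ng, dtype=object)
    n_gbm = int(round(cfg.gbm_gene_fraction * ng))
    n_telike = int(round(cfg.telike_gene_fraction * ng))
    cls_idx = rng.permutation(ng)
    gene_class[cls_idx[:n_gbm]] = "gbm"
    gene_class[cls_idx[n_gbm:n_gbm + n_telike]] = "telike"
    gene_class_by_fid = dict(zip(
        feats.index[feats["kind"] == "gene"], gene_class))

    site_gene_class = np.array(["none"] * ns, dtype=object)
    gmask = in_gene
    site_gene_class[gmask] = [gene_class_by_fid[f] for f in fidx[gmask]]

    # --- baseline logits ---------------------------------------------------
    base = np.full(ns, logit(0.02), dtype=np.float64)
    base[is_cg & (site_gene_class == "gbm")] = logit(0.30)
    base[is_cg & (site_gene_class == "unmethylated")] = logit(0.01)
    base[is_cg & (site_gene_class == "telike")] = logit(0.60)
    base[is_cg & in_te] = logit(0.45)
    base[is_chg & in_te] = logit(0.30)
    base[is_chg & (site_gene_class == "telike")] = logit(0.40)
    base[is_chg & ~in_te & (site_gene_class != "telike")] = logit(0.015)
    base[is_chh & in_te] = logit(0.12)
    base[is_chh & (site_gene_class == "telike")] = logit(0.15)
    base[is_chh & ~in_te & (site_gene_class != "telike")] = logit(0.02)
    base += rng.normal(0.0, 0.3, size=ns)  # site-level heterogeneity

    # --- TE pathway assignments -------------------------------------------
    te_fids = feats.index[feats["kind"] == "te"].to_numpy()
    n_te = len(te_fids)
    var_te = feats.loc[te_fids, "variable"].to_numpy(bool)
    # DCL3/RdDM-dependent: the variable TEs; CMT2-dependent: a random subset
    dcl3_te = var_te.copy()
    cmt2_te = rng.random(n_te) < cfg.cmt2_dependent_te_fraction
    loss_te = (~var_te) & (rng.random(n_te) <
                           cfg.temp_loss_te_fraction)
    te_flag = {f: i for i, f in enumerate(te_fids)}
    site_te = np.full(ns, -1, dtype=np.int64)
    m = in_te
    site_te[m] = [te_flag[f] for f in fidx[m]]

    chh_te = is_chh & in_te
    site_cmt2 = chh_te & np.isin(site_te, np.flatnonzero(cmt2_te))
    site_dcl3 = chh_te & np.isin(site_te, np.flatnonzero(dcl3_te))
    site_gain = site_dcl3  # gain temperature DMRs live in variable TEs
    site_loss = chh_te & np.isin(site_te, np.flatnonzero(loss_te))
    # loss-DMR hosts start highly methylated at 10C so that the drop at
    # 16C is large enough to be a callable difference
    base[site_loss] += logit(0.5) - logit(0.12)

    # --- accession-level effects ------------------------------------------
    g = genotypes.genotypes.astype(np.float64)
    snp_ids = genotypes.snps["id"].to_numpy()
    ia = int(np.flatnonzero(snp_ids == "CMT2a")[0]) if "CMT2a" in snp_ids else -1
    ib = int(np.flatnonzero(snp_ids == "CMT2b")[0]) if "CMT2b" in snp_ids else -1
    major = np.zeros(n_acc)
    if ia >= 0 and ib >= 0:
        major = arch.major_effect_a * g[:, ia] - arch.major_effect_b * g[:, ib]

    # polygenic trans on TE CHH
    u = rng.normal(0.0, 1.0, size=genotypes.n_snps)
    gs = g - g.mean(axis=0)
    poly = gs @ u
    sd = poly.std()
    poly = poly / sd * arch.trans_poly_sd if sd > 0 else poly

    # cis effects: one SNP within 50 kb of a TE, for a fraction of TEs
    cis_rows = []
    cis_site_eff = np.zeros((ns, n_acc), dtype=np.float32)
    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    n_cis = int(round(arch.cis_fraction * n_te))
    cis_tes = rng.choice(n_te, size=n_cis, replace=False) if n_cis else []
    for t in cis_tes:
        f = te_fids[t]
        tc = feats.loc[f, "chrom"]
        mid = (feats.loc[f, "start"] + feats.loc[f, "end"]) // 2
        cand = np.flatnonzero((snp_chrom == tc) &
                              (np.abs(snp_pos - mid) <= 50_000))
        cand = cand[(cand != ia) & (cand != ib)]
        if len(cand) == 0:
            continue
        j = int(rng.choice(cand))
        eff = arch.cis_effect * (1 if rng.random() < 0.5 else -1)
        smask = chh_te & (site_te == t)
        if smask.any():
            cis_site_eff[smask] += np.float32(eff) * g[:, j].astype(np.float32)
            cis_rows.append((feats.loc[f, "id"], tc, feats.loc[f, "start"],
                             feats.loc[f, "end"], j, int(snp_pos[j]), eff))
    cis_effects = pd.DataFrame(
        cis_rows, columns=["te_id", "chrom", "start", "end",
                           "snp_index", "snp_pos", "effect"])

    # GBM liability: north-enriched trans SNPs + polygenic + noise,
    # applied to CG sites of GBM genes
    trans_mask = np.char.startswith(snp_ids.astype(str), "GBMtrans")
    u_cg = rng.normal(0.0, 1.0, size=genotypes.n_snps)
    poly_cg = gs @ u_cg
    # normalize to the pooled *within-region* sd so gbm_poly_sd is the
    # within-population additive scale (the quantity Qst is built from)
    reg_arr = genotypes.metadata["region"].to_numpy()
    sds = [poly_cg[reg_arr == r].std() for r in ("north", "south")
           if (reg_arr == r).any()]
    sd_cg = float(np.mean(sds)) if sds else 0.0
    poly_cg = (poly_cg / sd_cg * arch.gbm_poly_sd if sd_cg > 0
               else poly_cg * 0.0)
    liab = (g[:, trans_mask].sum(axis=1) * arch.gbm_trans_effect
            + poly_cg
            + rng.normal(0.0, arch.gbm_noise_sd, size=n_acc))
    liab = liab - liab.mean()
    site_gbm = is_cg & (site_gene_class == "gbm")

    # --- assemble latent logits (10C) --------------------------------------
    x10 = np.tile(base[:, None], (1, n_acc)).astype(np.float32)
    x10[site_cmt2] += major.astype(np.float32)[None, :]
    x10[chh_te] += poly.astype(np.float32)[None, :]
    x10 += cis_site_eff
    x10[site_gbm] += liab.astype(np.float32)[None, :]
    # knocked-out pathway in null accessions
    null_acc = genotypes.metadata["cmt2_null"].to_numpy(bool)
    if null_acc.any():
        x10[np.ix_(site_cmt2, null_acc)] -= 4.0

    # --- environment: calibrated so mean CHH is env_chh_ratio higher at 16C
    local = np.zeros(ns, dtype=np.float32)
    local[site_gain] = arch.temp_gain_shift
    local[site_loss] = arch.temp_loss_shift
    chh_n = is_chh & nuclear
    eps_cal = cfg.conversion_error

    def observed(p: np.ndarray) -> np.ndarray:
        # calibrate on the observed scale, where conversion error acts
        return p * (1 - 2 * eps_cal) + eps_cal

    p10_chh = expit(x10[chh_n].astype(np.float64))
    mean10 = observed(p10_chh).mean()
    xloc = x10[chh_n].astype(np.float64) + local[chh_n][:, None]

    def ratio_gap(delta: float) -> float:
        return observed(expit(xloc + delta)).mean() / mean10 \
            - arch.env_chh_ratio

    if arch.env_chh_ratio == 1.0 and not (site_gain.any() or site_loss.any()):
        delta = 0.0
    else:
        delta = brentq(ratio_gap, -4.0, 4.0, xtol=1e-6)
    x16 = x10.copy()
    x16[chh_n] += (local[chh_n][:, None] + np.float32(delta))

    # --- observation model -------------------------------------------------
    p = np.stack([expit(x10.astype(np.float64)),
                  expit(x16.astype(np.float64))], axis=2)
    p[~nuclear] = 0.0  # chloroplast control
    eps = cfg.conversion_error
    p_obs = p * (1 - eps) + (1 - p) * eps
    depth = rng.poisson(cfg.depth_mean, size=p_obs.shape).astype(np.int32)
    meth = rng.binomial(depth, p_obs).astype(np.int32)

    samples = pd.DataFrame(
        [(a, e) for e in ENVIRONMENTS for a in genotypes.accessions],
        columns=["accession", "environment"])
    meth2 = np.concatenate([meth[:, :, 0], meth[:, :, 1]], axis=1)
    tot2 = np.concatenate([depth[:, :, 0], depth[:, :, 1]], axis=1)
    counts = MethylCounts(sites=sites, meth=meth2, total=tot2, samples=samples)

    def _te_windows(mask: np.ndarray) -> pd.DataFrame:
        sel = feats.loc[te_fids[mask], ["chrom", "start", "end", "id"]]
        return sel.reset_index(drop=True)

    truth = TruthRecord(
        causal_snps=cis_effects[["snp_index", "snp_pos", "effect"]].assign(
            kind="cis") if len(cis_effects) else pd.DataFrame(),
        major_locus={"CMT2a": ia, "CMT2b": ib, "effect": major},
        temp_gain_windows=_te_windows(dcl3_te),
        temp_loss_windows=_te_windows(loss_te),
        cmt2_dependent_windows=_te_windows(cmt2_te),
        dcl3_dependent_windows=_te_windows(dcl3_te),
        gbm_liability=pd.DataFrame({"accession": genotypes.accessions,
                                    "liability": liab}),
        gbm_genes=[gene_ids[i] for i in range(ng) if gene_class[i] == "gbm"],
        cis_effects=cis_effects,
        env_logit_shift=float(delta),
    )
    return counts, truth


def simulate_mutant_pair(
    annot: AnnotationSet,
    cfg: SimConfig,
    truth: TruthRecord,
    pathway: str = "cmt2",
    depth_mean: float = 30.0,
    seed: int | None = None,
) -> tuple[MethylCounts, MethylCounts]:
    """A knockout/wild-type methylome pair sharing one reference genotype.

    Sites inside ``pathway``-dependent TEs lose their methylation in the
    mutant (logit shifted far down); everything else is shared.  Used to
    exercise mutant-dependent DMR calling against planted truth.
    """
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    chroms = _chrom_names(cfg)
    L = _chrom_length(cfg)
    rows = []
    for c in chroms:
        p = np.arange(cfg.site_spacing // 2, L, cfg.site_spacing) + 1
        rows.append(pd.DataFrame({"chrom": c, "pos": p}))
    sites = pd.concat(rows, ignore_index=True)
    ns = len(sites)
    sites["strand"] = rng.choice(["+", "-"], size=ns)
    sites["context"] = "CHH"

    wins = (truth.cmt2_dependent_windows if pathway == "cmt2"
            else truth.dcl3_dependent_windows)
    dep = np.zeros(ns, bool)
    for c, sub in wins.groupby("chrom"):
        m = (sites["chrom"] == c).to_numpy()
        p = sites.loc[m, "pos"].to_numpy()
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.set_index("start").loc[starts, "end"].to_numpy()
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p <= ends[np.clip(j, 0, None)])
        dep[np.flatnonzero(m)[ok]] = True

    in_te = dep | (rng.random(ns) < 0.3)
    base = np.where(in_te, logit(0.6), logit(0.03))
    base = base + rng.normal(0, 0.2, ns)
    x_wt = base
    x_mut = np.where(dep, base - 6.0, base)
    eps = cfg.conversion_error

    def _draw(x):
        p = expit(x)
        p_obs = p * (1 - eps) + (1 - p) * eps
        d = rng.poisson(depth_mean, size=ns).astype(np.int32)
        m = rng.binomial(d, p_obs).astype(np.int32)
        return m[:, None], d[:, None]

    m_wt, d_wt = _draw(x_wt)
    m_mut, d_mut = _draw(x_mut)
    wt = MethylCounts(sites=sites.copy(), meth=m_wt, total=d_wt,
                      samples=pd.DataFrame({"accession": ["WT"],
                                            "environment": ["10C"]}))
    mut = MethylCounts(sites=sites.copy(), meth=m_mut, total=d_mut,
                       samples=pd.DataFrame({"accession": [pathway.upper() + "ko"],
                                             "environment": ["10C"]}))
    return mut, wt


def simulate_expression(
    genotypes: GenotypeTable,
    annot: AnnotationSet,
    truth: TruthRecord,
    cfg: SimConfig,
    coupling: float | None = None,
    library_scale: np.ndarray | None = None,
) -> pd.DataFrame:
    """Log-normal gene expression with optional coupling to GBM liability.

    Returns a long DataFrame (gene, accession, environment, expression).
    GBM genes pick up ``coupling * liability`` on the log scale; other
    genes are uncoupled.  ``library_scale`` multiplies whole samples to
    emulate library-size confounding.
    """
    if coupling is None:
        coupling = cfg.architecture.expression_coupling
    rng = np.random.default_rng(cfg.seed + 3)
    genes = annot.features.loc[annot.features["kind"] == "gene", "id"].tolist()
    gbm = set(truth.gbm_genes)
    liab = truth.gbm_liability.set_index("accession")["liability"]
    n_acc = genotypes.n_accessions
    base = rng.normal(4.0, 1.0, size=len(genes))
    recs = []
    for e in ENVIRONMENTS:
        noise = rng.normal(0.0, 0.4, size=(len(genes), n_acc))
        for gi, gene in enumerate(genes):
            x = base[gi] + noise[gi]
            if gene in gbm and coupling != 0.0:
                x = x + coupling * liab.loc[genotypes.accessions].to_numpy()
            expr = np.exp(x)
            if library_scale is not None:
                expr = expr * library_scale
            recs.append(pd.DataFrame({
                "gene": gene, "accession": genotypes.accessions,
                "environment": e, "expression": expr}))
    return pd.concat(recs, ignore_index=True)


def simulate_all(cfg: SimConfig) -> dict:
    """Run the full generator; returns all tables plus truth."""
    g = simulate_genotypes(cfg)
    annot = simulate_annotations(cfg)
    counts, truth = simulate_methylomes(g, annot, cfg)
    expr = simulate_expression(g, annot, truth, cfg)
    return {"genotypes": g, "annotations": annot, "methylomes": counts,
            "truth": truth, "expression": expr}
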