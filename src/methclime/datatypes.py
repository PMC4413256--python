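"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; BED output
converts to 0-based half-open at the file boundary (see :mod:`methclime.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ENVIRONMENTS = ("10C", "16C")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class GenotypeTable:
    """Biallelic genotypes for naturally inbred accessions.

    genotypes : (n_accessions, n_snps) int8 matrix coded 0 (reference
        homozygote) / 1 (non-reference homozygote); -1 marks missing.
    snps : DataFrame with columns chrom, pos (1-based), id.
    metadata : per-accession DataFrame indexed like ``accessions`` with at
        least ``latitude`` (degrees N) and ``region`` ("north"/"south").
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    accessions: list[str]
    metadata: pd.DataFrame

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        g = np.ma.masked_equal(self.genotypes, -1)
        return np.asarray(g.mean(axis=0))

    def subset_accessions(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            genotypes=self.genotypes[idx],
            snps=self.snps,
            accessions=[self.accessions[i] for i in idx],
            metadata=self.metadata.iloc[idx],
        )

    def subset_snps(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            genotypes=self.genotypes[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            accessions=self.accessions,
            metadata=self.metadata,
        )


@dataclass
class AnnotationSet:
    """Genomic features (genes, transposons) plus the chloroplast control.

    features : DataFrame with columns chrom, start, end (1-based inclusive),
        kind ("gene"/"te"), family, superfamily, variable (bool; planted
        temperature-DMR hosts), id.
    """

    features: pd.DataFrame
    chrom_sizes: dict[str, int]
    chloroplast: str = "ChrC"

    def genes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "gene"]

    def tes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "te"]


@dataclass
class MethylCounts:
    """Stacked per-cytosine read counts for a panel of samples.

    sites : DataFrame with columns chrom, pos (1-based), strand, context.
    meth, total : (n_sites, n_samples) integer arrays of methylated and total
        read counts.  ``samples`` carries ``(accession, environment)`` labels.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame  # columns: accession, environment

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def sample_index(self, accession: str, environment: str) -> int:
        m = (self.samples["accession"] == accession) & (
            self.samples["environment"] == environment
        )
        idx = np.flatnonzero(m.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"sample ({accession}, {environment}) not unique")
        return int(idx[0])

    def select_context(self, context: str) -> "MethylCounts":
        m = (self.sites["context"] == context).to_numpy()
        return MethylCounts(
            sites=self.sites[m].reset_index(drop=True),
            meth=self.meth[m],
            total=self.total[m],
            samples=self.samples,
        )

    def select_chrom(self, chrom: str, keep: bool = True) -> "MethylCounts":
        m = (self.sites["chrom"] == chrom).to_numpy()
        if not keep:
            m = ~m
        return MethylCounts(
            sites=self.sites[m].reset_index(drop=True),
            meth=self.meth[m],
            total=self.total[m],
            samples=self.samples,
        )


@dataclass
class WindowMatrix:
    """Sliding-window methylation levels.

    windows : DataFrame chrom, start, end (1-based inclusive), context.
    level : (n_windows, n_samples) float array in [0,1], NaN where no
        covered site fell in the window.
    coverage : matching total-read-count array.
    """

    windows: pd.DataFrame
    level: np.ndarray
    coverage: np.ndarray
    samples: pd.DataFrame
    context: str

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class TruthRecord:
    """Ground truth planted by the simulator, for parameter-recovery tests."""

    causal_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    major_locus: dict = field(default_factory=dict)
    temp_gain_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    temp_loss_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    cmt2_dependent_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    dcl3_dependent_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    gbm_liability: pd.DataFrame = field(default_factory=pd.DataFrame)
    gbm_genes: list = field(default_factory=list)
    cis_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    env_logit_shift: float = 0.0
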