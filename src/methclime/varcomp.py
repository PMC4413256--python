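"""Two-environment variance decomposition of methylation phenotypes.

For an N x 2 phenotype matrix Y (accessions x environments) the model is

    Y = 1_N mu^T + U_CMT2 + U_cis + U_trans + Psi

with each U_k ~ MVN(0, C_k, R_k) matrix-normal (C_k a 2x2 environment
covariance, R_k an accession relatedness matrix built from the relevant
SNP set) and Psi ~ MVN(0, Sigma, I_N).  Vectorizing with the
environment index slow and the accession index fast, the covariance of
vec(Y) is  sum_k C_k (x) R_k + Sigma (x) I_N  ((x) = Kronecker).

Each 2x2 covariance is parameterized as a^2 * J + diag(b1^2, b2^2)
(shared plus environment-specific), which makes the shared /
environment-interaction split of every component directly identifiable.
Parameters are estimated by maximum likelihood with random restarts;
environment means are profiled out by GLS.  Fits are then partitioned
into E, CMT2, CMT2xE, cis, cisxE, trans, transxE and noise fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .datatypes import GenotypeTable

COMPONENTS = ("cmt2", "cis", "trans")
FRACTION_KEYS = ("E", "CMT2", "CMT2xE", "cis", "cisxE",
                 "trans", "transxE", "noise")


# --------------------------------------------------------------------------
# relatedness

def relatedness_from_snps(g: GenotypeTable, snp_idx: np.ndarray) -> np.ndarray:
    """Standardized-genotype relatedness from a SNP subset.

    G_std G_std^T / m, rescaled so the mean diagonal is 1; PSD by
    construction.
    """
    snp_idx = np.asarray(snp_idx)
    if snp_idx.size == 0:
        raise ValueError("no SNPs selected for relatedness")
    G = g.genotypes[:, snp_idx].astype(np.float64)
    p = G.mean(axis=0)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all selected SNPs are monomorphic")
    Gs = (G[:, keep] - p[keep]) / sd[keep]
    R = Gs @ Gs.T / keep.sum()
    scale = np.mean(np.diag(R))
    return R / scale


def cis_trans_selectors(g: GenotypeTable, anchor_chrom: str, anchor_pos: int,
                        cis_window: int = 50_000) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint cis (within window of the anchor) / trans SNP index sets."""
    chrom = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    cis = (chrom == anchor_chrom) & (np.abs(pos - anchor_pos) <= cis_window)
    return np.flatnonzero(cis), np.flatnonzero(~cis)


# --------------------------------------------------------------------------
# model

def _c_from_params(a: float, b1: float, b2: float) -> np.ndarray:
    return a * a * np.ones((2, 2)) + np.diag([b1 * b1, b2 * b2])


class VarianceComponentsResults:
    """Fitted environment means, 2x2 components, and variance fractions."""

    def __init__(self, mu, components, sigma, loglik, converged,
                 n_restarts_used, n_per_env):
        self.mu = mu
        self.components = components          # dict name -> 2x2 C
        self.sigma = sigma                    # 2x2 noise covariance
        self.loglik = loglik
        self.converged = converged
        self.n_restarts_used = n_restarts_used
        self.n_per_env = n_per_env
        self._fractions: dict | None = None

    @property
    def fractions(self) -> dict:
        if self._fractions is None:
            self._fractions = self._partition()
        return self._fractions

    def _partition(self) -> dict:
        if not self.converged:
            raise RuntimeError("refusing to partition a non-converged fit")
        n = np.asarray(self.n_per_env, dtype=float)
        grand = float(np.sum(n * self.mu) / n.sum())
        var_e = float(np.sum(n * (self.mu - grand) ** 2) / n.sum())
        raw = {"E": var_e}
        for name, C in self.components.items():
            shared = float(C[0, 1])           # a^2
            spec = float(np.mean(np.diag(C)) - shared)
            key = "CMT2" if name == "cmt2" else name
            raw[key] = shared
            raw[key + "xE"] = spec
        raw["noise"] = float(np.mean(np.diag(self.sigma)))
        total = sum(raw.values())
        if total <= 0:
            return {k: np.nan for k in FRACTION_KEYS}
        return {k: raw.get(k, 0.0) / total for k in FRACTION_KEYS}

    @property
    def total_explained(self) -> float:
        return 1.0 - self.fractions["noise"]

    def summary(self) -> str:
        lines = [
            "Two-environment variance-components fit (ML)",
            f"  loglik: {self.loglik:.3f}   converged: {self.converged}"
            f"   restarts used: {self.n_restarts_used}",
            f"  environment means: {np.round(self.mu, 4).tolist()}",
            "  variance fractions:",
        ]
        for k in FRACTION_KEYS:
            lines.append(f"    {k:8s} {self.fractions[k]:.4f}")
        return "\n".join(lines)


class TwoEnvVarianceModel:
    """ML fit of the Kronecker-structured two-environment mixed model.

    Parameters
    ----------
    Y : (N, 2) phenotype; NaN cells are treated as unobserved.
    R : dict mapping component name ("cmt2", "cis", "trans") to an N x N
        relatedness matrix.  Components may be omitted (e.g. when no cis
        SNPs exist for a phenotype).
    """

    def __init__(self, Y: np.ndarray, R: dict[str, np.ndarray]):
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be N x 2 (two environments)")
        self.N = Y.shape[0]
        obs = ~np.isnan(Y)
        if (obs.sum(axis=0) < 2).any():
            raise ValueError("need >= 2 observed accessions per environment")
        self.Y = Y
        self.obs_mask = obs.T.ravel()         # env slow, accession fast
        self.y_obs = Y.T.ravel()[self.obs_mask]
        self.names = [k for k in COMPONENTS if k in R]
        for k in self.names:
            Rk = R[k]
            if Rk.shape != (self.N, self.N):
                raise ValueError(f"R[{k!r}] has wrong shape")
            w = np.linalg.eigvalsh(Rk)
            if w.min() < -1e-6:
                raise ValueError(f"R[{k!r}] is not PSD")
        self.R = {k: np.asarray(R[k], float) for k in self.names}
        env_idx = np.repeat([0, 1], self.N)[self.obs_mask]
        self.X = np.column_stack([(env_idx == 0).astype(float),
                                  (env_idx == 1).astype(float)])
        self.n_per_env = [int(obs[:, 0].sum()), int(obs[:, 1].sum())]

    # -- likelihood machinery ------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> tuple[dict, np.ndarray]:
        comps = {}
        for i, k in enumerate(self.names):
            a, b1, b2 = theta[3 * i: 3 * i + 3]
            comps[k] = _c_from_params(a, b1, b2)
        a, b1, b2 = theta[-3:]
        sigma = _c_from_params(a, b1, b2)
        return comps, sigma

    def _omega(self, comps: dict, sigma: np.ndarray) -> np.ndarray:
        N = self.N
        O = np.kron(sigma, np.eye(N))
        for k, C in comps.items():
            O += np.kron(C, self.R[k])
        return O[np.ix_(self.obs_mask, self.obs_mask)]

    def loglik(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Profile log-likelihood (mu maximized out by GLS) and mu-hat."""
        comps, sigma = self._unpack(theta)
        O = self._omega(comps, sigma)
        O[np.diag_indices_from(O)] += 1e-9
        try:
            cf = cho_factor(O, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, np.full(2, np.nan)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Oi_X = cho_solve(cf, self.X)
        Oi_y = cho_solve(cf, self.y_obs)
        XtOiX = self.X.T @ Oi_X
        mu = np.linalg.solve(XtOiX, self.X.T @ Oi_y)
        r = self.y_obs - self.X @ mu
        quad = float(r @ cho_solve(cf, r))
        n = len(self.y_obs)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        return ll, mu

    # -- fitting -------------------------------------------------------------

    def fit(self, restarts: int = 10, seed: int = 0, maxiter: int = 500,
            gtol: float = 1e-5) -> VarianceComponentsResults:
        """Best-of-restarts ML fit; stops at the first converged restart.

        Restart initializations draw each standard-deviation parameter
        log-uniformly on [1e-3, 1] (the first restart starts from an
        equal-split heuristic).
        """
        rng = np.random.default_rng(seed)
        n_par = 3 * (len(self.names) + 1)
        # fit on unit-variance data so the optimizer sees O(1) parameters;
        # components are rescaled afterwards (fractions are unaffected)
        sd_y = float(np.nanstd(self.Y))
        if sd_y == 0:
            sd_y = 1.0
        y_orig = self.y_obs
        self.y_obs = y_orig / sd_y

        def neg(theta):
            ll, _ = self.loglik(theta)
            return -ll if np.isfinite(ll) else 1e12

        try:
            best = None
            used = 0
            for r in range(max(1, restarts)):
                used = r + 1
                if r == 0:
                    x0 = np.full(n_par, 1.0 / np.sqrt(n_par))
                else:
                    x0 = np.exp(rng.uniform(np.log(1e-3), 0.0, size=n_par))
                res = minimize(neg, x0, method="L-BFGS-B",
                               options={"maxiter": maxiter, "gtol": gtol,
                                        "ftol": 1e-10, "eps": 1e-6})
                cand = (res.fun, res.x, bool(res.success))
                if best is None or cand[0] < best[0]:
                    best = cand
                if cand[2]:
                    break
            fun, theta, converged = best
            comps, sigma = self._unpack(theta)
            ll, mu = self.loglik(theta)
        finally:
            self.y_obs = y_orig
        comps = {k: C * sd_y ** 2 for k, C in comps.items()}
        sigma = sigma * sd_y ** 2
        mu = mu * sd_y
        ll = float(ll) - len(self.y_obs) * np.log(sd_y)
        return VarianceComponentsResults(
            mu=mu, components=comps, sigma=sigma, loglik=ll,
            converged=converged, n_restarts_used=used,
            n_per_env=self.n_per_env)


def fit_varcomp(Y: np.ndarray, R_cmt2: np.ndarray | None,
                R_cis: np.ndarray | None, R_trans: np.ndarray | None,
                restarts: int = 10, seed: int = 0) -> VarianceComponentsResults:
    """Functional wrapper: fit the two-environment model for one phenotype."""
    R = {}
    if R_cmt2 is not None:
        R["cmt2"] = R_cmt2
    if R_cis is not None:
        R["cis"] = R_cis
    if R_trans is not None:
        R["trans"] = R_trans
    return TwoEnvVarianceModel(Y, R).fit(restarts=restarts, seed=seed)


def partition_variance(fit: VarianceComponentsResults) -> pd.Series:
    """Variance-fraction table of a converged fit (sums to 1)."""
    return pd.Series(fit.fractions, name="fraction")


def bin_by_total_variance(fits: list[VarianceComponentsResults],
                          n_bins: int = 10) -> pd.DataFrame:
    """Mean fractions and phenotype density, binned by total variance explained.

    Equal-width bins on [0, 1] of ``1 - noise fraction``; mirrors the
    stacked-bar presentation of per-DMR decompositions.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to bin")
    tot = np.array([f.total_explained for f in fits])
    frac = pd.DataFrame([f.fractions for f in fits])
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(tot, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1],
               "density": m.mean(), "n": int(m.sum())}
        if m.any():
            row.update(frac[m].mean().to_dict())
        else:
            row.update({k: np.nan for k in FRACTION_KEYS})
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# simulation from the generative model (for parameter recovery)

def simulate_varcomp_phenotype(
    R: dict[str, np.ndarray],
    fractions: dict[str, float],
    mu: tuple[float, float] = (0.0, 0.0),
    total_var: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw an N x 2 phenotype with planted variance fractions.

    ``fractions`` uses the keys of :data:`FRACTION_KEYS` except ``E``
    (environment means are passed explicitly); shared components use
    C = a^2 J, interaction components C = diag(b^2, b^2).
    """
    rng = np.random.default_rng(seed)
    some_R = next(iter(R.values()))
    N = some_R.shape[0]
    Y = np.tile(np.asarray(mu, float), (N, 1))

    def draw(C: np.ndarray, Rk: np.ndarray) -> np.ndarray:
        Lc = np.linalg.cholesky(C + 1e-12 * np.eye(2))
        wr, Ur = np.linalg.eigh(Rk)
        Lr = Ur * np.sqrt(np.clip(wr, 0, None))
        Z = rng.standard_normal((N, 2))
        return Lr @ Z @ Lc.T

    for name, Rk in R.items():
        key = "CMT2" if name == "cmt2" else name
        a2 = fractions.get(key, 0.0) * total_var
        b2 = fractions.get(key + "xE", 0.0) * total_var
        C = a2 * np.ones((2, 2)) + b2 * np.eye(2)
        if a2 + b2 > 0:
            Y += draw(C, Rk)
    s2 = fractions.get("noise", 0.0) * total_var
    if s2 > 0:
        Y += rng.standard_normal((N, 2)) * np.sqrt(s2)
    return Y
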