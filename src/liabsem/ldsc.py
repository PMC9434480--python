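"""LD score regression: heritabilities, genetic covariances, block jackknife.

LD score regression separates polygenic signal from confounding and sample
overlap by regressing per-variant association statistics on LD scores
``l_j`` (the summed squared correlation of variant j with its neighbours):

* univariate: ``E[chi2_j] = 1 + N h2 l_j / M`` — the slope estimates the
  SNV heritability on the observed scale, the free intercept absorbs
  confounding inflation;
* bivariate: ``E[z1_j z2_j] = rho_ns + sqrt(N1 N2) rho_g l_j / M`` — the
  slope estimates the genetic covariance and the intercept absorbs the
  correlation of estimation errors induced by overlapping samples.

Sampling covariances of all fitted quantities come from a delete-one-block
jackknife over contiguous variant blocks, giving the joint sampling matrix
``V`` required by the structural model downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeData

DEFAULT_WINDOW = 1_000_000  # bp; ~1 cM-equivalent
DEFAULT_N_BLOCKS = 200


class LdscError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# LD scores

def compute_ld_scores(genotypes: GenotypeData, window: int = DEFAULT_WINDOW,
                      chunk: int = 512) -> pd.DataFrame:
    """Per-variant LD scores from a reference genotype panel.

    ``l_j = sum_k r2_adj(j, k)`` over variants k on the same chromosome
    within ``window`` bp of j, with the unbiased small-sample adjustment
    ``r2_adj = r2 - (1 - r2) / (n_ref - 2)`` applied to every cross term and
    the self term fixed at 1.

    Returns a DataFrame ``variant_id, chrom, pos, ld_score``.
    """
    n_ref = genotypes.n_samples
    if n_ref < 3:
        raise LdscError("LD score estimation needs at least 3 reference samples")
    if window <= 0:
        raise ValueError("window must be positive")
    var = genotypes.variants
    order = np.lexsort((var["pos"].to_numpy(), var["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(var))):
        raise ValueError("variants must be sorted by chromosome and position")
    Z = genotypes.standardized()
    pos = var["pos"].to_numpy()
    chrom = var["chrom"].to_numpy()
    m = len(var)
    ell = np.ones(m)
    adj = 1.0 / (n_ref - 2)
    # window bounds located by searchsorted on a combined chrom/pos key
    key = chrom.astype(np.int64) * 10_000_000_000 + pos
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        lo = np.searchsorted(key, key[a] - window)
        hi = np.searchsorted(key, key[b - 1] + window, side="right")
        R = (Z[:, a:b].T @ Z[:, lo:hi]) / n_ref
        r2 = R * R
        r2_adj = r2 - (1.0 - r2) * adj
        in_win = (
            (np.abs(pos[a:b, None] - pos[None, lo:hi]) <= window)
            & (chrom[a:b, None] == chrom[None, lo:hi])
        )
        idx_self = np.arange(a, b) - lo
        r2_adj[np.arange(b - a), idx_self] = 0.0  # self term added as exactly 1
        ell[a:b] += (r2_adj * in_win).sum(axis=1)
    return pd.DataFrame(
        {
            "variant_id": var["variant_id"].to_numpy(),
            "chrom": chrom,
            "pos": pos,
            "ld_score": ell,
        }
    )


# ---------------------------------------------------------------------------
# Regression machinery

@dataclass
class LdscFit:
    """One LDSC regression with its delete-one-block jackknife resamples."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    delete_slopes: np.ndarray  # (n_blocks,)
    delete_intercepts: np.ndarray
    n_blocks: int
    n_snps: int
    mean_stat: float


def _jackknife_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   block_ids: np.ndarray, n_blocks: int) -> LdscFit:
    """Weighted regression of y on [x, 1] with delete-one-block resamples."""
    X = np.column_stack([x, np.ones_like(x)])
    Xw = X * w[:, None]
    A = X.T @ Xw                      # 2x2
    bvec = Xw.T @ y
    theta = np.linalg.solve(A, bvec)
    # per-block contributions
    A_blocks = np.zeros((n_blocks, 2, 2))
    b_blocks = np.zeros((n_blocks, 2))
    P = np.stack([x * x * w, x * w, w], axis=1)
    for which, (i, j) in enumerate([(0, 0), (0, 1), (1, 1)]):
        sums = np.bincount(block_ids, weights=P[:, which], minlength=n_blocks)
        A_blocks[:, i, j] = sums
        A_blocks[:, j, i] = sums
    b_blocks[:, 0] = np.bincount(block_ids, weights=x * w * y, minlength=n_blocks)
    b_blocks[:, 1] = np.bincount(block_ids, weights=w * y, minlength=n_blocks)
    deletes = np.linalg.solve(A[None] - A_blocks, (bvec[None] - b_blocks)[..., None])[..., 0]
    dbar = deletes.mean(axis=0)
    var = (n_blocks - 1) / n_blocks * ((deletes - dbar) ** 2).sum(axis=0)
    return LdscFit(
        slope=float(theta[0]),
        intercept=float(theta[1]),
        se_slope=float(np.sqrt(var[0])),
        se_intercept=float(np.sqrt(var[1])),
        delete_slopes=deletes[:, 0],
        delete_intercepts=deletes[:, 1],
        n_blocks=n_blocks,
        n_snps=len(x),
        mean_stat=float(y.mean()),
    )


def make_block_ids(m: int, n_blocks: int = DEFAULT_N_BLOCKS) -> np.ndarray:
    """Contiguous, equal-count block assignment for m ordered variants."""
    if m < n_blocks:
        raise LdscError(f"{m} variants cannot form {n_blocks} jackknife blocks")
    return (np.arange(m) * n_blocks // m).astype(np.int64)


def _chi2_cap(n: np.ndarray) -> float:
    return max(80.0, 0.001 * float(np.mean(n)))


def fit_univariate_ldsc(z: np.ndarray, n: np.ndarray, ld: np.ndarray,
                        M: int | None = None,
                        n_blocks: int = DEFAULT_N_BLOCKS,
                        block_ids: np.ndarray | None = None) -> LdscFit:
    """Estimate observed-scale SNV heritability for one study.

    Weighted regression of ``chi2_j`` on ``n_j l_j / M`` with a free
    intercept.  Heteroskedasticity weights ``1 / (max(l,1) (1 + N h~2 l/M)^2)``
    use a provisional slope from an unweighted first pass.  Variants with
    ``chi2 > max(80, 0.001 N)`` are excluded from the regression (their
    blocks remain in the partition).
    """
    z = np.asarray(z, float)
    n = np.broadcast_to(np.asarray(n, float), z.shape)
    ld = np.asarray(ld, float)
    m = len(z)
    if m < 200:
        raise LdscError("univariate LDSC requires at least 200 variants")
    if M is None:
        M = m
    if block_ids is None:
        block_ids = make_block_ids(m, n_blocks)
    chi2 = z * z
    keep = chi2 <= _chi2_cap(n)
    x = n * ld / M
    # provisional slope, unweighted
    h_prov = np.polyfit(x[keep], chi2[keep], 1)[0]
    h_prov = float(np.clip(h_prov, 0.0, 2.0))
    N_bar = float(n.mean())
    w = 1.0 / (np.maximum(ld, 1.0) * (1.0 + N_bar * h_prov * ld / M) ** 2)
    return _jackknife_wls(x[keep], chi2[keep], w[keep], block_ids[keep], n_blocks)


def fit_bivariate_ldsc(z1: np.ndarray, z2: np.ndarray, n1, n2, ld: np.ndarray,
                       M: int | None = None,
                       n_blocks: int = DEFAULT_N_BLOCKS,
                       block_ids: np.ndarray | None = None) -> LdscFit:
    """Estimate the genetic covariance between two studies.

    Regression of ``z1_j z2_j`` on ``sqrt(n1 n2) l_j / M``; the intercept
    absorbs the sample-overlap term ``rho N_s / sqrt(n1 n2)`` and is
    reported, not subtracted.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), z1.shape)
    n2 = np.broadcast_to(np.asarray(n2, float), z2.shape)
    ld = np.asarray(ld, float)
    m = len(z1)
    if m < 200:
        raise LdscError("bivariate LDSC requires at least 200 variants")
    if M is None:
        M = m
    if block_ids is None:
        block_ids = make_block_ids(m, n_blocks)
    keep = (z1 * z1 <= _chi2_cap(n1)) & (z2 * z2 <= _chi2_cap(n2))
    x = np.sqrt(n1 * n2) * ld / M
    y = z1 * z2
    h1 = float(np.clip(np.polyfit(n1 * ld / M, z1 * z1, 1)[0], 0.0, 2.0))
    h2 = float(np.clip(np.polyfit(n2 * ld / M, z2 * z2, 1)[0], 0.0, 2.0))
    w = 1.0 / (
        np.maximum(ld, 1.0)
        * (1.0 + float(n1.mean()) * h1 * ld / M)
        * (1.0 + float(n2.mean()) * h2 * ld / M)
    )
    return _jackknife_wls(x[keep], y[keep], w[keep], block_ids[keep], n_blocks)


# ---------------------------------------------------------------------------
# Assembling S and V

def upper_triangle_index(K: int) -> list:
    """Row-major upper-triangle (i <= j) index pairs of a K x K matrix."""
    return [(i, j) for i in range(K) for j in range(i, K)]


@dataclass
class GeneticCovariance:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    ``S`` is K x K (diagonal: observed-scale SNV heritabilities;
    off-diagonal: genetic covariances).  ``V`` is the sampling covariance of
    the K(K+1)/2 unique elements of S in row-major upper-triangle order.
    ``intercepts`` holds the univariate LDSC intercepts on the diagonal and
    the cross-trait (sample overlap) intercepts off it.
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    M: int
    studies: list
    n_blocks: int = DEFAULT_N_BLOCKS
    psd_adjustment: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.S.shape[0]

    def to_json(self, path: str) -> None:
        payload = {
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
            "M": self.M,
            "studies": list(self.studies),
            "n_blocks": self.n_blocks,
            "psd_adjustment": self.psd_adjustment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GeneticCovariance":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            S=np.array(d["S"]),
            V=np.array(d["V"]),
            intercepts=np.array(d["intercepts"]),
            M=d["M"],
            studies=d["studies"],
            n_blocks=d["n_blocks"],
            psd_adjustment=d.get("psd_adjustment", 0.0),
        )


def nearest_psd(V: np.ndarray, eps: float = 1e-12):
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Returns the projected matrix and the magnitude of the adjustment
    (most negative eigenvalue clipped, 0 if none).
    """
    V = (V + V.T) / 2
    vals, vecs = np.linalg.eigh(V)
    worst = float(min(vals.min(), 0.0))
    if worst < 0:
        vals = np.clip(vals, eps * max(vals.max(), 1.0), None)
        V = (vecs * vals) @ vecs.T
    return (V + V.T) / 2, -worst


def assemble_covariance(fits: dict, studies: list, M: int,
                        n_blocks: int = DEFAULT_N_BLOCKS) -> GeneticCovariance:
    """Build S, V and the intercept matrix from LDSC fits.

    ``fits`` maps index pairs to :class:`LdscFit`: ``(k, k)`` univariate and
    ``(k, l)`` with k < l bivariate, all computed on the same variant set
    with the same block partition.  V is the jackknife covariance across
    delete-one-block estimate vectors, smoothed to the nearest PSD matrix
    when needed.
    """
    K = len(studies)
    pairs = upper_triangle_index(K)
    nb = {fits[p].n_blocks for p in pairs}
    if nb != {n_blocks} or len({fits[p].delete_slopes.shape for p in pairs}) != 1:
        raise LdscError("inconsistent jackknife block partitions across fits")
    S = np.zeros((K, K))
    intercepts = np.zeros((K, K))
    deletes = np.zeros((n_blocks, len(pairs)))
    for idx, (i, j) in enumerate(pairs):
        f = fits[(i, j)]
        S[i, j] = S[j, i] = f.slope
        intercepts[i, j] = intercepts[j, i] = f.intercept
        deletes[:, idx] = f.delete_slopes
    dbar = deletes.mean(axis=0)
    V = (n_blocks - 1) / n_blocks * (deletes - dbar).T @ (deletes - dbar)
    V, adj = nearest_psd(V)
    if (np.diag(S) < 0).any():
        import logging

        logging.getLogger(__name__).warning(
            "negative heritability estimate(s): %s", np.diag(S)
        )
    return GeneticCovariance(
        S=S, V=V, intercepts=intercepts, M=M, studies=list(studies),
        n_blocks=n_blocks, psd_adjustment=adj,
    )


def panel_covariance(panel, ld_scores: pd.DataFrame,
                     n_blocks: int = DEFAULT_N_BLOCKS) -> GeneticCovariance:
    """All univariate and bivariate LDSC fits for a harmonized panel."""
    merged = panel.df.merge(ld_scores[["variant_id", "ld_score"]], on="variant_id")
    if len(merged) != len(panel.df):
        raise LdscError("LD scores missing for some panel variants")
    ld = merged["ld_score"].to_numpy(float)
    M = len(merged)
    block_ids = make_block_ids(M, n_blocks)
    fits = {}
    K = len(panel.studies)
    for i in range(K):
        zi = merged[f"z_{panel.studies[i]}"].to_numpy(float)
        ni = merged[f"n_{panel.studies[i]}"].to_numpy(float)
        fits[(i, i)] = fit_univariate_ldsc(zi, ni, ld, M, n_blocks, block_ids)
        for j in range(i + 1, K):
            zj = merged[f"z_{panel.studies[j]}"].to_numpy(float)
            nj = merged[f"n_{panel.studies[j]}"].to_numpy(float)
            fits[(i, j)] = fit_bivariate_ldsc(zi, zj, ni, nj, ld, M, n_blocks, block_ids)
    return assemble_covariance(fits, panel.studies, M, n_blocks)


# ---------------------------------------------------------------------------
# Scale conversion (optional utility; main path reports observed scale)

def observed_to_liability_h2(h2_obs: float, prevalence: float,
                             case_fraction: float) -> float:
    """Convert an observed-scale (0/1 regression) h2 in an ascertained
    case-control sample to the liability scale (Lee transformation)."""
    K = prevalence
    P = case_fraction
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return h2_obs * (K * (1 - K)) ** 2 / (P * (1 - P) * z * z)


def liability_to_observed_h2(h2_liab: float, prevalence: float,
                             case_fraction: float) -> float:
    K = prevalence
    P = case_fraction
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return h2_liab * P * (1 - P) * z * z / (K * (1 - K)) ** 2
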