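"""Common-factor structural model on GWAS genetic covariances.

The baseline model expresses the K x K genetic covariance matrix S through a
single latent shared-liability factor F with unit variance:

    sigma_kl = lambda_k lambda_l   (k != l)
    sigma_kk = lambda_k^2 + psi_k

Parameters are estimated by diagonally weighted least squares (DWLS):
minimize ``(s - sigma(theta))' D^-1 (s - sigma(theta))`` with
``D = diag(V)``, the jackknife sampling variances of the stacked unique
elements ``s`` of S.  Standard errors use the sandwich
``(J'D^-1 J)^-1 J'D^-1 V D^-1 J (J'D^-1 J)^-1`` with J the Jacobian of the
model-implied moments at the optimum.

Per variant, the covariance matrix is expanded with the SNV as an extra
unit-variance variable whose covariances with the traits are the
standardized effects ``beta_std_k = z_k / sqrt(n_k)``.  Two per-SNV models
are then fitted with all loadings free:

* shared effect: the factor is regressed on the SNV
  (``trait_k = lambda_k F + u_k``, ``F = b SNV + d``) — ``b`` is the effect
  of the variant that is common to all disorders;
* differentiating effect for disorder t: the same model plus a simultaneous
  direct path ``SNV -> trait_t`` — the direct-path coefficient is the part
  of the variant's effect on disorder t not explained by the shared factor.

Sampling variances of the SNV moments are ``1/n_k``, with cross-study error
covariances ``intercept_kl / sqrt(n_k n_l)`` taken from the LDSC intercept
matrix (the sample-overlap correction).

Genome-wide application runs a vectorized Levenberg–Marquardt DWLS over all
variants simultaneously, with a per-variant scipy refit as fallback for the
rare non-converged cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import GeneticCovariance, upper_triangle_index

logger = logging.getLogger(__name__)

SHARED = "shared"


class GsemError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Baseline common-factor model

@dataclass
class FactorFit:
    """Common-factor model estimates for the K source disorders."""

    loadings: np.ndarray           # lambda_k
    residual_variances: np.ndarray  # psi_k
    se_loadings: np.ndarray
    se_residuals: np.ndarray
    model_chi2: float
    df: int
    heywood: np.ndarray            # flags: psi clamped at 0
    studies: list = field(default_factory=list)

    def implied_S(self) -> np.ndarray:
        lam = self.loadings
        S = np.outer(lam, lam)
        S[np.diag_indices_from(S)] += self.residual_variances
        return S


def _stack_unique(S: np.ndarray) -> np.ndarray:
    return np.array([S[i, j] for i, j in upper_triangle_index(S.shape[0])])


def _closed_form_start(S: np.ndarray) -> tuple:
    """Path-tracing start values for the just-identified K=3 factorization."""
    K = S.shape[0]
    lam = np.zeros(K)
    if K == 3:
        s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            cand = np.array(
                [s12 * s13 / s23 if s23 != 0 else np.nan,
                 s12 * s23 / s13 if s13 != 0 else np.nan,
                 s13 * s23 / s12 if s12 != 0 else np.nan]
            )
        if np.all(np.isfinite(cand)) and np.all(cand >= 0):
            lam = np.sqrt(cand)
            lam[1] *= np.sign(s12) if s12 != 0 else 1.0
            lam[2] *= np.sign(s13) if s13 != 0 else 1.0
        else:
            off = S.copy()
            np.fill_diagonal(off, np.nan)
            scale = np.sqrt(np.nanmean(np.abs(off))) if np.nanmax(np.abs(off)) > 0 else 0.0
            lam = np.full(K, scale)
    else:
        vals, vecs = np.linalg.eigh(S)
        lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    psi = np.maximum(np.diag(S) - lam**2, 1e-6)
    return lam, psi


def fit_common_factor(cov: GeneticCovariance | np.ndarray,
                      V: np.ndarray | None = None,
                      studies: list | None = None) -> FactorFit:
    """DWLS fit of the one-factor model to (S, V).

    Accepts a :class:`GeneticCovariance` or a bare S matrix (then ``V`` may
    be given separately; without V the weights default to identity and the
    sandwich reduces to the naive covariance).  The factor variance is fixed
    to 1 and the loading sign convention is ``lambda_1 >= 0``.
    """
    if isinstance(cov, GeneticCovariance):
        S, V_, studies = cov.S, cov.V, list(cov.studies)
    else:
        S, V_ = np.asarray(cov, float), V
    K = S.shape[0]
    if K < 3:
        raise GsemError("the common-factor model needs at least 3 studies")
    pairs = upper_triangle_index(K)
    P = len(pairs)
    s = _stack_unique(S)
    D = np.diag(V_).copy() if V_ is not None else np.ones(P)
    D = np.maximum(D, 1e-12)
    w_sqrt = 1.0 / np.sqrt(D)

    def implied(theta):
        lam, psi = theta[:K], theta[K:]
        out = np.array([lam[i] * lam[j] for i, j in pairs])
        diag_idx = [pairs.index((k, k)) for k in range(K)]
        out[diag_idx] += psi
        return out

    def resid(theta):
        return w_sqrt * (s - implied(theta))

    lam0, psi0 = _closed_form_start(S)
    sol = optimize.least_squares(
        resid, np.concatenate([lam0, psi0]), method="lm", xtol=1e-12, ftol=1e-12
    )
    if not sol.success:
        for k in range(5):
            rng = np.random.default_rng(k)
            start = np.concatenate([lam0, psi0]) * (1 + 0.1 * rng.standard_normal(2 * K))
            sol = optimize.least_squares(resid, start, method="lm",
                                         xtol=1e-12, ftol=1e-12)
            if sol.success:
                break
        else:
            raise GsemError(f"common-factor DWLS did not converge: {sol.message}")
    lam, psi = sol.x[:K].copy(), sol.x[K:].copy()
    if lam[0] < 0:
        lam = -lam
    heywood = psi < 0
    if heywood.any():
        logger.warning("Heywood case: residual variance clamped at 0 for %s",
                       np.where(heywood)[0])
        psi = np.maximum(psi, 0.0)

    # sandwich standard errors
    J = _numeric_jacobian(implied, np.concatenate([lam, psi]))
    Vfull = V_ if V_ is not None else np.eye(P)
    bread = np.linalg.pinv(J.T @ (J / D[:, None]))
    meat = (J / D[:, None]).T @ Vfull @ (J / D[:, None])
    cov_theta = bread @ meat @ bread
    se = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))

    r = s - implied(np.concatenate([lam, psi]))
    chi2 = float(r @ np.linalg.pinv(Vfull) @ r)
    return FactorFit(
        loadings=lam, residual_variances=psi,
        se_loadings=se[:K], se_residuals=se[K:],
        model_chi2=chi2, df=P - 2 * K, heywood=heywood,
        studies=studies or [f"study{i}" for i in range(K)],
    )


def _numeric_jacobian(fun, theta, h=1e-7):
    f0 = fun(theta)
    J = np.zeros((len(f0), len(theta)))
    for i in range(len(theta)):
        t = theta.copy()
        t[i] += h
        J[:, i] = (fun(t) - f0) / h
    return J


# ---------------------------------------------------------------------------
# SNV expansion

@dataclass
class ExpandedCovariance:
    """(K+1) x (K+1) covariance with the SNV bordered as variable 0.

    ``S`` has Var(SNV) fixed at 1 (standardized genotype) and
    ``Cov(SNV, trait_k) = beta_std_k``.  ``V`` is the sampling covariance of
    the 10 stacked unique elements; the row/column of the fixed SNV variance
    moment is zero and that moment is excluded from estimation.
    """

    S: np.ndarray
    V: np.ndarray
    studies: list


def expand_with_snv(cov: GeneticCovariance, beta_std: np.ndarray,
                    n: np.ndarray) -> ExpandedCovariance:
    """Border (S, V) with one variant's standardized effects.

    ``beta_std`` and ``n`` are length-K vectors for the variant.  Sampling
    variance of ``beta_std_k`` is ``1/n_k``; the cross-study error
    covariance is ``intercept_kl / sqrt(n_k n_l)`` from the LDSC
    cross-trait intercepts (zero when samples do not overlap).
    """
    beta_std = np.asarray(beta_std, float)
    n = np.asarray(n, float)
    K = cov.K
    if beta_std.shape != (K,) or not np.all(np.isfinite(beta_std)):
        raise GsemError("beta_std must be a finite length-K vector")
    S_exp = np.zeros((K + 1, K + 1))
    S_exp[0, 0] = 1.0
    S_exp[0, 1:] = S_exp[1:, 0] = beta_std
    S_exp[1:, 1:] = cov.S
    pairs = upper_triangle_index(K + 1)
    P = len(pairs)
    V_exp = np.zeros((P, P))
    # SNV-trait moments occupy stacked indices 1..K
    for a in range(K):
        for b in range(K):
            if a == b:
                V_exp[1 + a, 1 + a] = 1.0 / n[a]
            else:
                V_exp[1 + a, 1 + b] = cov.intercepts[a, b] / np.sqrt(n[a] * n[b])
    # trait-trait moments: original V in the trailing block
    V_exp[K + 1:, K + 1:] = cov.V
    return ExpandedCovariance(S=S_exp, V=V_exp, studies=list(cov.studies))


# ---------------------------------------------------------------------------
# Batched per-SNV DWLS engine
#
# Moment order per variant (9 free moments; Var(SNV)=1 is a fixed constraint):
#   [c_1, c_2, c_3, s_11, s_12, s_13, s_22, s_23, s_33]
# Parameter order: [lam_1, lam_2, lam_3, q_1, q_2, q_3, b (, c)] with
# psi_k = q_k^2: the square keeps residual variances non-negative, turns the
# psi = 0 (Heywood) boundary into a stationary point, and removes the
# improper escape ray lam -> inf, psi -> -inf.

_TRAIT_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def _batched_implied(theta: np.ndarray, diff_trait: int | None) -> np.ndarray:
    lam = theta[:, 0:3]
    psi = theta[:, 3:6] ** 2
    b = theta[:, 6]
    out = np.empty((theta.shape[0], 9))
    out[:, 0:3] = lam * b[:, None]
    if diff_trait is not None:
        out[:, diff_trait] += theta[:, 7]
    for idx, (i, j) in enumerate(_TRAIT_PAIRS):
        out[:, 3 + idx] = lam[:, i] * lam[:, j]
        if i == j:
            out[:, 3 + idx] += psi[:, i]
    return out


def _batched_jacobian(theta: np.ndarray, diff_trait: int | None) -> np.ndarray:
    m, P = theta.shape
    lam = theta[:, 0:3]
    b = theta[:, 6]
    J = np.zeros((m, 9, P))
    for k in range(3):
        J[:, k, k] = b
        J[:, k, 6] = lam[:, k]
    if diff_trait is not None:
        J[:, diff_trait, 7] = 1.0
    for idx, (i, j) in enumerate(_TRAIT_PAIRS):
        if i == j:
            J[:, 3 + idx, i] = 2 * lam[:, i]
            J[:, 3 + idx, 3 + i] = 2 * theta[:, 3 + i]
        else:
            J[:, 3 + idx, i] = lam[:, j]
            J[:, 3 + idx, j] = lam[:, i]
    return J


def _batched_dwls(y: np.ndarray, d: np.ndarray, theta0: np.ndarray,
                  diff_trait: int | None, max_iter: int = 80,
                  gtol: float = 1e-7, mu_max: float = 1e8):
    """Vectorized Levenberg–Marquardt DWLS over many variants at once.

    ``y``: (m, 9) observed moments; ``d``: (m, 9) diagonal weights (sampling
    variances); ``theta0``: (m, P) start values.  Returns (theta, converged).
    A variant is converged when the weighted-least-squares gradient drops
    below ``gtol``, or when damping has reached its numerical ceiling with
    the gradient already small (objective at machine floor).
    """
    theta = theta0.copy()
    w = 1.0 / np.maximum(d, 1e-12)
    mu = np.full(theta.shape[0], 1e-4)
    r = y - _batched_implied(theta, diff_trait)
    F = np.einsum("mi,mi,mi->m", r, w, r)
    active = np.ones(theta.shape[0], dtype=bool)
    eyeP = np.eye(theta.shape[1])
    F_last = F.copy()
    for it in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        th = theta[idx]
        J = _batched_jacobian(th, diff_trait)
        Wr = w[idx] * r[idx]
        g = np.einsum("mip,mi->mp", J, Wr)
        H = np.einsum("mip,mi,miq->mpq", J, w[idx], J)
        gnorm = np.abs(g).max(axis=1)
        done = (gnorm < gtol) | ((mu[idx] >= mu_max) & (gnorm < 1e-3))
        if it >= 5:
            # boundary (psi = 0) optima are approached quartically slowly in
            # the q parameterization: a stalled objective with a small
            # gradient is an accepted optimum
            stalled = (F_last[idx] - F[idx]) < 1e-12 * (1.0 + F[idx])
            done |= stalled & (gnorm < 1e-3)
        F_last[idx] = F[idx]
        sub = np.where(~done)[0]
        active_idx = idx[sub]
        if done.any():
            active[idx[done]] = False
        if len(sub) == 0:
            continue
        # damped step with per-variant mu adaptation
        for _ in range(10):
            if len(active_idx) == 0:
                break
            Hd = H[sub] + mu[active_idx][:, None, None] * eyeP[None]
            try:
                step = np.linalg.solve(Hd, g[sub][..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.einsum(
                    "mpq,mq->mp", np.linalg.pinv(Hd), g[sub]
                )
            trial = theta[active_idx] + step
            r_t = y[active_idx] - _batched_implied(trial, diff_trait)
            F_t = np.einsum("mi,mi,mi->m", r_t, w[active_idx], r_t)
            better = F_t <= F[active_idx] * (1 + 1e-12) + 1e-15
            ok = active_idx[better]
            theta[ok] = trial[better]
            r[ok] = r_t[better]
            F[ok] = F_t[better]
            mu[ok] = np.maximum(mu[ok] * 0.3, 1e-8)
            bad = active_idx[~better]
            mu[bad] = np.minimum(mu[bad] * 10.0, mu_max)
            active_idx = bad
            sub = sub[~better]
    if active.any():
        # final sweep: snap near-boundary residual parameters to exactly
        # psi = 0 (their gradient then vanishes identically) and accept a
        # small weighted gradient as an optimum when the iteration budget
        # ran out on the flat boundary
        idx = np.where(active)[0]
        q = theta[idx, 3:6]
        q[np.abs(q) < 1e-2] = 0.0
        theta[idx, 3:6] = q
        r[idx] = y[idx] - _batched_implied(theta[idx], diff_trait)
        F[idx] = np.einsum("mi,mi,mi->m", r[idx], w[idx], r[idx])
        J = _batched_jacobian(theta[idx], diff_trait)
        g = np.einsum("mip,mi->mp", J, w[idx] * r[idx])
        active[idx[np.abs(g).max(axis=1) < 5e-3]] = False
    return theta, ~active


def _sandwich_se(theta: np.ndarray, d: np.ndarray, V: np.ndarray,
                 diff_trait: int | None) -> np.ndarray:
    """Batched sandwich covariance; returns SEs for all parameters.

    ``V``: (m, 9, 9) full sampling covariance per variant.
    """
    J = _batched_jacobian(theta, diff_trait)
    w = 1.0 / np.maximum(d, 1e-12)
    Jw = J * w[:, :, None]
    bread = np.linalg.pinv(np.einsum("mip,miq->mpq", Jw, J))
    meat = np.einsum("mip,mij,mjq->mpq", Jw, V, Jw)
    cov = np.einsum("mpq,mqr,mrs->mps", bread, meat, bread)
    return np.sqrt(np.maximum(np.einsum("mpp->mp", cov), 0.0))


def _per_variant_moments(cov: GeneticCovariance, B: np.ndarray, N: np.ndarray):
    """Stack observed moments, weights and sampling covariances per variant."""
    m = B.shape[0]
    s_trait = _stack_unique(cov.S)
    y = np.empty((m, 9))
    y[:, 0:3] = B
    y[:, 3:] = s_trait
    d = np.empty((m, 9))
    d[:, 0:3] = 1.0 / N
    d[:, 3:] = np.maximum(np.diag(cov.V), 1e-12)
    Vfull = np.zeros((m, 9, 9))
    for a in range(3):
        Vfull[:, a, a] = 1.0 / N[:, a]
        for b in range(3):
            if a != b:
                Vfull[:, a, b] = cov.intercepts[a, b] / np.sqrt(N[:, a] * N[:, b])
    Vfull[:, 3:, 3:] = cov.V
    return y, d, Vfull


def _start_values(base: FactorFit, B: np.ndarray, N: np.ndarray,
                  diff_trait: int | None) -> np.ndarray:
    m = B.shape[0]
    P = 7 if diff_trait is None else 8
    theta0 = np.zeros((m, P))
    theta0[:, 0:3] = base.loadings
    theta0[:, 3:6] = np.sqrt(np.maximum(base.residual_variances, 1e-6))
    lam = base.loadings
    # GLS-ish start for b: weight each study's beta by n_k lam_k
    num = (B * lam[None, :] * N).sum(axis=1)
    den = (lam[None, :] ** 2 * N).sum(axis=1)
    b0 = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    theta0[:, 6] = b0
    if diff_trait is not None:
        theta0[:, 7] = B[:, diff_trait] - lam[diff_trait] * b0
    return theta0


@dataclass
class EffectEstimate:
    beta: float
    se: float
    p: float
    converged: bool
    params: np.ndarray


def _estimate_batch(cov: GeneticCovariance, base: FactorFit, B: np.ndarray,
                    N: np.ndarray, diff_trait: int | None):
    y, d, Vfull = _per_variant_moments(cov, B, N)
    theta0 = _start_values(base, B, N, diff_trait)
    theta, conv = _batched_dwls(y, d, theta0, diff_trait)
    # scipy fallback for stragglers
    bad = np.where(~conv)[0]
    for j in bad:
        sw = 1.0 / np.sqrt(np.maximum(d[j], 1e-12))

        def f(t):
            return sw * (y[j] - _batched_implied(t[None], diff_trait)[0])

        def jac(t):
            return -sw[:, None] * _batched_jacobian(t[None], diff_trait)[0]

        best = None
        for start in (theta[j], theta0[j]):
            res = optimize.least_squares(f, start, jac=jac, method="lm",
                                         xtol=1e-14, ftol=1e-14, max_nfev=2000)
            if best is None or res.cost < best.cost:
                best = res
        grad = np.abs(jac(best.x).T @ f(best.x)).max()
        if best.success and grad < 1e-3:
            theta[j] = best.x
            conv[j] = True
    se = _sandwich_se(theta, d, Vfull, diff_trait)
    col = 6 if diff_trait is None else 7
    est = theta[:, col].copy()
    if diff_trait is None:
        # sign convention lambda_1 >= 0 transfers to b
        flip = theta[:, 0] < 0
        est[flip] = -est[flip]
    se_est = se[:, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se_est > 0, est / se_est, 0.0)
    p = 2 * stats.norm.sf(np.abs(zstat))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return est, se_est, p, conv


def estimate_shared_effect(expanded: ExpandedCovariance,
                           cov: GeneticCovariance,
                           base: FactorFit | None = None) -> EffectEstimate:
    """Shared (common-factor) effect of one variant from its expanded matrix."""
    return _estimate_single(expanded, cov, base, diff_trait=None)


def estimate_differentiating_effect(expanded: ExpandedCovariance,
                                    cov: GeneticCovariance,
                                    disorder: int,
                                    base: FactorFit | None = None) -> EffectEstimate:
    """Differentiating (residual direct-path) effect for one disorder."""
    return _estimate_single(expanded, cov, base, diff_trait=int(disorder))


def _estimate_single(expanded, cov, base, diff_trait):
    if base is None:
        base = fit_common_factor(cov)
    B = expanded.S[0, 1:][None, :]
    # recover n from the expanded sampling variances
    n = 1.0 / np.diag(expanded.V)[1:4]
    est, se, p, conv = _estimate_batch(cov, base, B, n[None, :], diff_trait)
    return EffectEstimate(float(est[0]), float(se[0]), float(p[0]), bool(conv[0]),
                          params=None)


# ---------------------------------------------------------------------------
# Genome-wide application

@dataclass
class SnvEffectSet:
    """Four derived genome-wide summary-statistic tables.

    ``tables`` maps component name (``shared`` and ``<study>_diff`` for each
    source study) to a sumstats-format DataFrame with columns
    ``variant_id, chrom, pos, effect_allele, other_allele, beta, se, p, n_eff``.
    """

    tables: dict
    baseline: FactorFit
    n_failed: int = 0

    def components(self) -> list:
        return list(self.tables)


def run_genomewide(panel, cov: GeneticCovariance,
                   max_failure_rate: float = 0.01) -> SnvEffectSet:
    """Estimate shared and differentiating effects for every panel variant.

    ``panel`` must carry ``beta_std_<study>`` columns
    (:func:`liabsem.sumstats.standardize_effects`).  Deterministic given its
    inputs; raises if more than ``max_failure_rate`` of the per-variant fits
    fail to converge.
    """
    df = panel.df
    if len(df) == 0:
        raise GsemError("empty variant panel")
    studies = panel.studies
    missing = [s for s in studies if f"beta_std_{s}" not in df.columns]
    if missing:
        raise GsemError(f"panel lacks standardized effects for studies {missing}")
    B = df[[f"beta_std_{s}" for s in studies]].to_numpy(float)
    N = df[[f"n_{s}" for s in studies]].to_numpy(float)
    ok_rows = np.isfinite(B).all(axis=1)
    if not ok_rows.all():
        logger.info("skipping %d variants with missing effects", (~ok_rows).sum())
        df = df.loc[ok_rows].reset_index(drop=True)
        B, N = B[ok_rows], N[ok_rows]

    base = fit_common_factor(cov)
    meta = df[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    n_eff = np.median(N, axis=1)
    tables = {}
    total_failed = 0
    jobs = [(SHARED, None)] + [(f"{s}_diff", k) for k, s in enumerate(studies)]
    for name, trait in jobs:
        est, se, p, conv = _estimate_batch(cov, base, B, N, trait)
        total_failed += int((~conv).sum())
        out = meta.copy()
        out["beta"] = est
        out["se"] = se
        out["p"] = p
        out["n_eff"] = n_eff
        tables[name] = out
    if total_failed > max_failure_rate * len(df) * len(jobs):
        raise GsemError(
            f"per-variant estimation failed for {total_failed} fits "
            f"({len(df)} variants x {len(jobs)} models)"
        )
    return SnvEffectSet(tables=tables, baseline=base, n_failed=total_failed)


def write_effect_sets(effects: SnvEffectSet, prefix: str) -> None:
    for name, tab in effects.tables.items():
        tab.to_csv(f"{prefix}{name}.tsv", sep="\t", index=False)
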