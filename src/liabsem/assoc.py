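"""Symptom-dimension phenotypes and the PRS association suite.

Phenotype derivation follows the dimensional rating convention of the
target cohort: lifetime psychosis is present when the ordinal psychosis
scale (BADDS-P) is 10 or more; mood-incongruent psychotic symptoms (MIPS)
are present when the incongruence scale (BADDS-I) is 20 or more, and
BADDS-I is only rated in individuals who meet the psychosis criterion, so
MIPS models are fitted on the psychosis-present subsample.

The association suite regresses each symptom phenotype on each of the four
standardized liability-component PRS — logistic regression for the
dichotomous phenotypes (psychosis, MIPS), proportional-odds ordinal
logistic regression for the ordinal scales (mania, depression, and the
ordinal sensitivity analyses of BADDS-P/I) — always adjusting for age at
interview, genotyping platform and 10 principal components, with
conditional analyses (psychosis given mania; mania given psychosis) and a
sensitivity pass excluding schizoaffective-bipolar participants.
Phenotype-pair dependence is summarized by polychoric correlation with a
permutation-bootstrap p value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

PSYCHOSIS_THRESHOLD = 10   # BADDS-P >= 10
MIPS_THRESHOLD = 20        # BADDS-I >= 20

PRS_COMPONENTS = ["shared", "scz_diff", "bd_diff", "mdd_diff"]
DEFAULT_COVARIATES = ["age_at_interview", "platform"] + [f"pc{i}" for i in range(1, 11)]


class AssocError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Phenotype derivation

def derive_phenotypes(raw: pd.DataFrame) -> pd.DataFrame:
    """Add binary ``psychosis`` and ``mips`` flags to a BADDS table.

    ``psychosis = 1`` iff ``badds_p >= 10``; ``mips`` is defined only where
    psychosis is present (``badds_i >= 20``), missing otherwise.  Records
    with a rated BADDS-I despite absent psychosis violate the rating rule:
    they are flagged (``mips_inconsistent``) and excluded from MIPS
    analyses, with ``mips`` left missing.
    """
    if "badds_p" not in raw.columns:
        raise AssocError("badds_p column is required")
    out = raw.copy()
    out["psychosis"] = (out["badds_p"] >= PSYCHOSIS_THRESHOLD).astype(int)
    badds_i = out["badds_i"] if "badds_i" in out.columns else pd.Series(
        np.nan, index=out.index
    )
    inconsistent = badds_i.notna() & (out["psychosis"] == 0)
    if inconsistent.any():
        logger.warning("%d records have BADDS-I rated without psychosis; "
                       "excluded from MIPS analysis", int(inconsistent.sum()))
    out["mips_inconsistent"] = inconsistent
    mips = np.where(badds_i >= MIPS_THRESHOLD, 1.0, 0.0)
    mips = np.where(badds_i.notna() & (out["psychosis"] == 1), mips, np.nan)
    out["mips"] = mips
    return out


# ---------------------------------------------------------------------------
# Design-matrix helpers

def _design(cohort: pd.DataFrame, covariates: list,
            extra: pd.DataFrame | None = None) -> pd.DataFrame:
    cols = []
    for c in covariates:
        if c not in cohort.columns:
            continue
        col = cohort[c]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=cohort.index)
    if extra is not None:
        X = pd.concat([X, extra], axis=1)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        _, R = np.linalg.qr(arr)
        bad = np.where(np.abs(np.diag(R)) < 1e-8)[0]
        names = ["const"] + list(X.columns)
        raise AssocError(
            f"rank-deficient design; collinear columns: {[names[i] for i in bad]}"
        )


@dataclass
class AssociationResult:
    phenotype: str
    component: str
    model: str                  # logistic | ordinal
    condition: str              # none | mania | psychosis
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    subset: str = "all"
    status: str = "ok"


# ---------------------------------------------------------------------------
# Single-model fits

def fit_logistic(outcome: pd.Series, prs: pd.Series,
                 covariates: pd.DataFrame,
                 phenotype: str = "outcome", component: str = "prs",
                 condition: str = "none", subset: str = "all") -> AssociationResult:
    """Maximum-likelihood logistic regression; Wald CI and p for the PRS term."""
    y = np.asarray(outcome, float)
    if len(np.unique(y[np.isfinite(y)])) != 2:
        raise AssocError(f"{phenotype}: outcome must have exactly two classes")
    X = pd.concat([prs.rename("prs").astype(float), covariates], axis=1)
    _check_rank(X)
    try:
        fit = sm.Logit(y, sm.add_constant(X.to_numpy(float))).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:
        raise AssocError(f"{phenotype}: complete separation in logistic fit") from exc
    beta = float(np.asarray(fit.params)[1])
    se = float(np.asarray(fit.bse)[1])
    ci = (beta - 1.959964 * se, beta + 1.959964 * se)
    return AssociationResult(
        phenotype, component, "logistic", condition,
        beta, float(ci[0]), float(ci[1]), float(np.asarray(fit.pvalues)[1]),
        int(len(y)), subset,
    )


def fit_ordinal(outcome: pd.Series, prs: pd.Series,
                covariates: pd.DataFrame,
                phenotype: str = "outcome", component: str = "prs",
                condition: str = "none", subset: str = "all") -> AssociationResult:
    """Proportional-odds (cumulative logit) regression by ML.

    Categories are taken as the observed ordered values, which implicitly
    merges empty categories with their neighbours.
    """
    levels = np.sort(pd.unique(outcome.dropna()))
    if len(levels) < 2:
        raise AssocError(f"{phenotype}: fewer than two observed categories")
    y = pd.Series(
        pd.Categorical(outcome, categories=levels, ordered=True),
        index=outcome.index, name=phenotype,
    )
    X = pd.concat([prs.rename("prs").astype(float), covariates], axis=1)
    _check_rank(X)
    model = OrderedModel(y, X.astype(float), distr="logit")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        # BFGS pushed to (and usually past) its numerical floor; convergence
        # is then judged on the score vector itself rather than the
        # optimizer's flag, which trips on the last unimprovable iteration
        fit = model.fit(method="bfgs", disp=0, maxiter=2000, gtol=1e-9)

        def _gnorm(f):
            return float(np.abs(model.score(np.asarray(f.params))).max())

        if _gnorm(fit) > 1e-4:
            refit = model.fit(method="lbfgs", disp=0, maxiter=5000)
            if _gnorm(refit) < _gnorm(fit):
                fit = refit
        if _gnorm(fit) > 1e-4:
            raise AssocError(f"{phenotype}: ordinal model did not converge")
    beta = float(np.asarray(fit.params)[0])
    se = float(np.asarray(fit.bse)[0])
    ci = (beta - 1.959964 * se, beta + 1.959964 * se)
    return AssociationResult(
        phenotype, component, "ordinal", condition,
        beta, float(ci[0]), float(ci[1]), float(np.asarray(fit.pvalues)[0]),
        int(len(y)), subset,
    )


# ---------------------------------------------------------------------------
# The full suite

def _restandardize(series: pd.Series) -> pd.Series:
    sd = series.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise AssocError("PRS constant within analysis subset")
    return (series - series.mean()) / sd


def _one_model(kind, cohort, rows, outcome_col, comp, covariates, extra,
               phenotype, condition, subset):
    sub = cohort.loc[rows]
    ok = sub[outcome_col].notna() & sub[comp].notna()
    sub = sub.loc[ok]
    prs = _restandardize(sub[comp])
    X = _design(sub, covariates, None if extra is None else extra.loc[sub.index])
    fn = fit_logistic if kind == "logistic" else fit_ordinal
    return fn(sub[outcome_col], prs, X, phenotype, comp, condition, subset)


def run_association_suite(cohort: pd.DataFrame,
                          components: list = PRS_COMPONENTS,
                          covariates: list = DEFAULT_COVARIATES) -> pd.DataFrame:
    """The full grid of main, conditional and sensitivity models.

    Per PRS component and per subset (all individuals; schizoaffective-BD
    excluded): logistic psychosis and MIPS (MIPS on the psychosis-present,
    consistently rated subsample); ordinal mania and depression; psychosis
    conditioned on mania (category indicators); mania conditioned on
    psychosis; ordinal sensitivity models of BADDS-P and BADDS-I.  PRS are
    re-standardized within each analysis subset.  Individual model failures
    are recorded with an error status; the suite continues.
    """
    needed = {"psychosis", "mips", "badds_m", "badds_d", "badds_p"}
    if not needed.issubset(cohort.columns):
        cohort = derive_phenotypes(cohort)
    results = []
    subsets = {"all": cohort.index}
    if "diagnosis_subtype" in cohort.columns:
        subsets["sab_excluded"] = cohort.index[cohort["diagnosis_subtype"] != "SAB"]
    mips_ok = (
        (cohort["psychosis"] == 1)
        & ~cohort.get("mips_inconsistent", pd.Series(False, index=cohort.index))
    )
    mania_dummies = pd.get_dummies(
        cohort["badds_m"], prefix="mania_cat", drop_first=True, dtype=float
    )
    psychosis_cov = cohort[["psychosis"]].astype(float)

    grid = [
        # kind, rows-builder, outcome, phenotype label, condition, extra covs
        ("logistic", lambda ix: ix, "psychosis", "psychosis", "none", None),
        ("logistic", lambda ix: ix.intersection(cohort.index[mips_ok]),
         "mips", "mips", "none", None),
        ("ordinal", lambda ix: ix, "badds_m", "badds_m", "none", None),
        ("ordinal", lambda ix: ix, "badds_d", "badds_d", "none", None),
        ("logistic", lambda ix: ix, "psychosis", "psychosis", "mania", mania_dummies),
        ("ordinal", lambda ix: ix, "badds_m", "badds_m", "psychosis", psychosis_cov),
        ("ordinal", lambda ix: ix, "badds_p", "badds_p_ordinal", "none", None),
        ("ordinal", lambda ix: ix.intersection(cohort.index[mips_ok]),
         "badds_i", "badds_i_ordinal", "none", None),
    ]
    for subset_name, subset_ix in subsets.items():
        for kind, rows_fn, outcome_col, phen, condition, extra in grid:
            for comp in components:
                try:
                    res = _one_model(
                        kind, cohort, rows_fn(subset_ix), outcome_col, comp,
                        covariates, extra, phen, condition, subset_name,
                    )
                except Exception as exc:  # failures recorded, suite continues
                    res = AssociationResult(
                        phen, comp, kind, condition,
                        np.nan, np.nan, np.nan, np.nan, 0, subset_name,
                        status=f"error: {exc}",
                    )
                results.append(res)
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Polychoric correlation

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T."""
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    out = np.empty(np.broadcast(h, k).shape)
    h, k = np.broadcast_arrays(h, k)
    hi_h = np.isposinf(h)
    hi_k = np.isposinf(k)
    lo = np.isneginf(h) | np.isneginf(k)
    fin = ~(hi_h | hi_k | lo)
    out[lo] = 0.0
    out[hi_h & ~lo] = stats.norm.cdf(k[hi_h & ~lo])
    out[hi_k & ~hi_h & ~lo] = stats.norm.cdf(h[hi_k & ~hi_h & ~lo])
    if fin.any():
        hf = h[fin].copy()
        kf = k[fin].copy()
        # nudge exact zeros off the singular axis of the Owen's T formula
        hf[hf == 0] = 1e-13
        kf[kf == 0] = 1e-13
        if abs(rho) < 1e-12:
            out[fin] = stats.norm.cdf(hf) * stats.norm.cdf(kf)
        elif abs(rho) > 1 - 1e-9:
            s = np.sign(rho)
            if s > 0:
                out[fin] = stats.norm.cdf(np.minimum(hf, kf))
            else:
                out[fin] = np.maximum(
                    stats.norm.cdf(hf) + stats.norm.cdf(kf) - 1.0, 0.0
                )
        else:
            denom = np.sqrt(1.0 - rho * rho)
            t1 = special.owens_t(hf, (kf - rho * hf) / (hf * denom))
            t2 = special.owens_t(kf, (hf - rho * kf) / (kf * denom))
            adj = np.where(hf * kf > 0, 0.0, 0.5)
            out[fin] = (
                0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf)) - t1 - t2 - adj
            )
    return out


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a bivariate normal over threshold grids."""
    A, B = np.meshgrid(a, b, indexing="ij")
    F = _bvn_cdf(A, B, rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def _polychoric_rho(table: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    def negll(rho):
        p = np.clip(_cell_probs(a, b, rho), 1e-300, None)
        return -(table * np.log(p)).sum()

    res = optimize.minimize_scalar(
        negll, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def polychoric_correlation(x, y, n_boot: int = 10_000,
                           seed: int | None = None) -> tuple:
    """Two-step polychoric correlation with a permutation-bootstrap p value.

    Thresholds come from the inverse-normal of the marginal cumulative
    proportions; rho maximizes the bivariate-normal likelihood of the
    contingency table.  The p value is the fraction of |rho*| under
    row/column independence (permutation of one margin) at least as large
    as |rho|, with an add-one correction keeping p in (0, 1].
    """
    x = pd.Series(x)
    y = pd.Series(y)
    ok = x.notna() & y.notna()
    xc = np.unique(x[ok], return_inverse=True)[1]
    yc = np.unique(y[ok], return_inverse=True)[1]
    K = xc.max() + 1
    L = yc.max() + 1
    if K < 2 or L < 2:
        raise AssocError("polychoric correlation needs >=2 categories per variable")
    n = len(xc)
    table = np.bincount(xc * L + yc, minlength=K * L).reshape(K, L).astype(float)
    a = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(table.sum(1))[:-1] / n),
                        [np.inf]])
    b = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(table.sum(0))[:-1] / n),
                        [np.inf]])
    rho = _polychoric_rho(table, a, b)
    if n_boot <= 0:
        return rho, np.nan
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        perm = rng.permutation(yc)
        t = np.bincount(xc * L + perm, minlength=K * L).reshape(K, L).astype(float)
        if abs(_polychoric_rho(t, a, b)) >= abs(rho):
            exceed += 1
    p = (1 + exceed) / (1 + n_boot)
    return rho, p
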