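"""LD clumping and unthresholded polygenic risk scoring.

Clumping follows the classical greedy PLINK procedure: variants are visited
in order of ascending association p value; each index variant retires every
unretired variant within +/-500 kb whose squared genotype correlation with
it (computed on the target sample's best-estimate genotypes) exceeds 0.2.
Variants failing the MAF (>= 0.1) or imputation-info (>= 0.7) pre-filters
never become indices and are never scored.  Because optimal p-value
thresholds are unknowable for factor-derived summary statistics, all
retained variants contribute to the score (no p-value thresholding), and
scores are standardized (mean 0, SD 1) before any association analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeData

logger = logging.getLogger(__name__)

R2_MAX = 0.2
WINDOW = 500_000
MAF_MIN = 0.1
INFO_MIN = 0.7


class PrsError(RuntimeError):
    pass


@dataclass
class ClumpResult:
    """Index variants retained by greedy clumping.

    ``kept`` lists retained variant ids in selection order; ``displaced``
    maps each removed variant id to the index variant that retired it;
    ``kept_idx`` are the positions of kept variants in the effect table.
    """

    kept: list
    displaced: dict
    kept_idx: np.ndarray
    n_prefiltered: int = 0


def _clump_order(effects: pd.DataFrame) -> np.ndarray:
    """Deterministic visiting order: p, then chrom, pos, variant_id."""
    return np.lexsort(
        (
            effects["variant_id"].astype(str).to_numpy(),
            effects["pos"].to_numpy(),
            effects["chrom"].to_numpy(),
            effects["p"].to_numpy(),
        )
    )


def clump(effects: pd.DataFrame, genotypes: GenotypeData,
          r2_max: float = R2_MAX, window: int = WINDOW,
          maf_min: float = MAF_MIN, info_min: float = INFO_MIN,
          info: np.ndarray | None = None) -> ClumpResult:
    """Greedy LD clumping of one derived summary-statistic table.

    ``effects`` must carry ``variant_id, chrom, pos, p``; the genotype
    columns are matched by variant id and must cover every effect variant.
    ``info`` optionally supplies per-variant imputation quality (defaults
    to 1, i.e. hard-called genotypes).
    """
    gmap = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    try:
        gcol = np.array([gmap[v] for v in effects["variant_id"]])
    except KeyError as exc:
        raise PrsError(f"genotypes missing for effect variant {exc}") from exc
    maf_all = genotypes.allele_frequency()[gcol]
    maf_all = np.minimum(maf_all, 1 - maf_all)
    info = np.ones(len(effects)) if info is None else np.asarray(info, float)
    eligible = (maf_all >= maf_min) & (info >= info_min)
    if not eligible.any():
        raise PrsError("no variants pass the clumping MAF/info pre-filters")

    chrom = effects["chrom"].to_numpy()
    pos = effects["pos"].to_numpy()
    ids = effects["variant_id"].to_numpy()
    Z = genotypes.standardized()[:, gcol]
    n = Z.shape[0]

    order = _clump_order(effects)
    alive = eligible.copy()
    kept_idx = []
    displaced: dict = {}
    for j in order:
        if not alive[j]:
            continue
        alive[j] = False
        kept_idx.append(j)
        cand = np.where(
            alive
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= window)
        )[0]
        if len(cand) == 0:
            continue
        r = (Z[:, cand].T @ Z[:, j]) / n
        hits = cand[r * r > r2_max]
        alive[hits] = False
        for h in hits:
            displaced[ids[h]] = ids[j]
    kept_idx = np.array(kept_idx, dtype=int)
    logger.info(
        "clumping kept %d of %d variants (%d failed pre-filters)",
        len(kept_idx), len(effects), int((~eligible).sum()),
    )
    return ClumpResult(
        kept=[ids[i] for i in kept_idx],
        displaced=displaced,
        kept_idx=kept_idx,
        n_prefiltered=int((~eligible).sum()),
    )


@dataclass
class ScoreVector:
    """Per-individual polygenic score for one liability component."""

    raw: np.ndarray
    standardized: np.ndarray
    component: str
    sample_ids: list = field(default_factory=list)
    missing_flag: np.ndarray | None = None


def standardize_scores(raw: np.ndarray) -> np.ndarray:
    """Mean 0, SD 1 (sample SD, ddof=1), ignoring missing entries."""
    ok = np.isfinite(raw)
    mu = raw[ok].mean()
    sd = raw[ok].std(ddof=1)
    if sd == 0:
        raise PrsError("degenerate score vector: zero variance")
    out = np.full_like(raw, np.nan, dtype=float)
    out[ok] = (raw[ok] - mu) / sd
    return out


def compute_prs(effects: pd.DataFrame, clump_result: ClumpResult,
                genotypes: GenotypeData, component: str = "prs",
                max_missing: float = 0.05) -> ScoreVector:
    """Unthresholded PRS over the clump-retained variants.

    ``raw_i = sum_j beta_j g_ij`` with g the 0/1/2 effect-allele count;
    missing genotypes are mean-imputed unless an individual misses more
    than ``max_missing`` of the retained variants, in which case the score
    is set missing and flagged.
    """
    kept = effects.iloc[clump_result.kept_idx]
    gmap = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    gcol = np.array([gmap[v] for v in kept["variant_id"]])
    G = genotypes.genotypes[:, gcol].astype(np.float64)
    miss = genotypes.genotypes[:, gcol] == MISSING
    beta = kept["beta"].to_numpy(float)
    if miss.any():
        col_mean = np.where(miss, 0, G).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
        G[miss] = np.take(col_mean, np.where(miss)[1])
    raw = G @ beta
    miss_rate = miss.mean(axis=1)
    flagged = miss_rate > max_missing
    if flagged.any():
        logger.warning("%d individuals exceed %.0f%% missingness; scores set missing",
                       flagged.sum(), 100 * max_missing)
        raw = raw.astype(float)
        raw[flagged] = np.nan
    std = standardize_scores(raw) if np.nanstd(raw) > 0 else np.zeros_like(raw)
    if np.all(beta == 0):
        std = np.zeros_like(raw)
    return ScoreVector(
        raw=raw, standardized=std, component=component,
        sample_ids=list(genotypes.sample_ids), missing_flag=flagged,
    )


def prs_correlation_matrix(scores: list) -> pd.DataFrame:
    """Pairwise Pearson correlations between standardized score vectors."""
    if len(scores) < 2:
        raise PrsError("need at least two score vectors")
    ids0 = scores[0].sample_ids
    for s in scores[1:]:
        if s.sample_ids != ids0:
            raise PrsError("score vectors computed on different individuals")
    mat = np.vstack([s.standardized for s in scores])
    ok = np.isfinite(mat).all(axis=0)
    corr = np.corrcoef(mat[:, ok])
    names = [s.component for s in scores]
    return pd.DataFrame(corr, index=names, columns=names)


def scores_to_frame(scores: list) -> pd.DataFrame:
    """Long-format TSV layout: individual_id, component, raw, standardized."""
    frames = []
    for s in scores:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": s.sample_ids,
                    "component": s.component,
                    "raw": s.raw,
                    "standardized": s.standardized,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
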