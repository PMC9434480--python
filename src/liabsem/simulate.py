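"""Synthetic study generator with known ground truth.

Emulates the full design that the analysis pipeline expects: three
case-control GWAS of psychiatric disorders whose genetic liabilities share
one common factor plus disorder-specific polygenic components, with
partially overlapping control sets; a reference genotype panel for LD; and
a target cohort of bipolar-disorder cases with four ordinal BADDS-like
symptom scales generated from configured linear combinations of the
liability components.

Genotypes follow a blockwise latent-Gaussian haplotype model: within an LD
block, latent haplotype values have correlation ``rho^|i-j|`` (rho drawn
per block), thresholded at the MAF quantile; a genotype is the sum of two
independent haplotypes, so single-site frequencies are Hardy–Weinberg and
LD decays within blocks and vanishes between them.

Liability for disorder k of individual i is

    L_ik = lambda_k * G_shared,i + G_ik + eps_ik,   Var(L_ik) = 1,

with polygenic scores ``G_shared = sum_j gamma_j x~_ij`` (gamma on a random
causal subset, Var(G_shared) = 1) and ``G_k`` analogous with variance
``v_k``.  Disease status is the liability-threshold rule at the configured
prevalence.  GWAS z statistics are the case-control score test on
standardized genotype (for a binary outcome with an intercept-only null
this equals the Cochran–Armitage trend test, i.e. the logistic score test;
it is also the linear-regression z, the two coincide).

All randomness flows from one ``numpy.random.default_rng`` (PCG64) seed, so
output is reproducible bit-for-bit for a given seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeData

STUDIES = ("scz", "bd", "mdd")
COMPONENTS = ("shared", "scz", "bd", "mdd")

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


class SimulationError(RuntimeError):
    pass


def _default_W() -> np.ndarray:
    # rows: badds_p, badds_i, badds_m, badds_d
    # cols: shared, scz-specific, bd-specific, mdd-specific
    return np.array(
        [
            [0.25, 0.20, 0.15, -0.25],
            [0.00, 0.30, 0.00, 0.00],
            [0.30, 0.00, 0.25, -0.25],
            [0.00, 0.00, -0.25, 0.25],
        ]
    )


def _default_scale_levels() -> dict:
    return {
        "badds_p": [0, 5, 15, 30, 50, 70],
        "badds_i": [0, 10, 20, 30, 40],
        "badds_m": [10, 20, 30, 40, 50, 60],
        "badds_d": [10, 20, 30, 40, 50, 60],
    }


def _default_cutpoints() -> dict:
    return {
        "badds_p": [-1.2, -0.1, 0.6, 1.2, 1.8],
        "badds_i": [-1.0, 0.2, 0.9, 1.5],
        "badds_m": [-1.5, -0.7, 0.0, 0.7, 1.5],
        "badds_d": [-1.5, -0.7, 0.0, 0.7, 1.5],
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    The factor loadings and specific variances are in liability units on
    liabilities scaled to total variance 1, chosen so pairwise genetic
    correlations (~0.5-0.6) and SNV heritabilities (~0.15-0.24) sit in the
    range reported for the three adult psychiatric disorders; prevalence is
    a desk-scale 15% so case ascertainment is feasible at these sample
    sizes.  Symptom weights follow the headline cross-disorder pattern:
    mania loads on shared and BD-specific (negatively on MDD-specific)
    liability, depression on MDD-specific (negatively BD-specific),
    incongruent psychosis on the schizophrenia-specific component only.
    """

    m: int = 20_000
    block_size: int = 20
    rho_block_range: tuple = (0.5, 0.95)
    maf_range: tuple = (0.05, 0.5)
    n_chromosomes: int = 22
    spacing: int = 1_000  # bp between adjacent variants

    studies: tuple = STUDIES
    loadings: tuple = (0.37, 0.36, 0.25)
    specific_variances: tuple = (0.10, 0.07, 0.09)
    prevalences: tuple = (0.15, 0.15, 0.15)
    n_cases: tuple = (5_000, 5_000, 5_000)
    n_controls: tuple = (5_000, 5_000, 5_000)
    control_overlap: float = 0.5
    causal_fraction: float = 0.2

    n_reference: int = 2_000
    n_target: int = 5_000
    target_study: str = "bd"

    W: np.ndarray = field(default_factory=_default_W)
    scale_levels: dict = field(default_factory=_default_scale_levels)
    cutpoints: dict = field(default_factory=_default_cutpoints)
    min_symptom_noise: float = 0.05
    age_mean: float = 46.2
    age_sd: float = 12.3
    platforms: tuple = ("chipA", "chipB")
    platform_probs: tuple = (0.6, 0.4)
    n_pcs: int = 10
    subtype_probs: tuple = (0.60, 0.25, 0.10, 0.05)  # BD-I, BD-II, SAB, other

    def __post_init__(self) -> None:
        K = len(self.studies)
        lam = np.asarray(self.loadings, float)
        v = np.asarray(self.specific_variances, float)
        prev = np.asarray(self.prevalences, float)
        if not (len(lam) == len(v) == len(prev) == K):
            raise SimulationError("per-study parameter lengths disagree")
        if (v < 0).any():
            raise SimulationError("specific variances must be non-negative")
        if ((prev <= 0) | (prev >= 1)).any():
            raise SimulationError("prevalences must lie in (0, 1)")
        if (lam**2 + v > 1).any():
            raise SimulationError("liability variance components exceed 1")
        for scale, cuts in self.cutpoints.items():
            if not np.all(np.diff(cuts) > 0):
                raise SimulationError(f"cutpoints for {scale} not strictly increasing")
            if len(self.scale_levels[scale]) != len(cuts) + 1:
                raise SimulationError(f"levels/cutpoints mismatch for {scale}")

    @property
    def K(self) -> int:
        return len(self.studies)

    def required_population(self) -> int:
        """Population size so that cases (and BD target cases) suffice."""
        need = []
        for k in range(self.K):
            extra = self.n_target if self.studies[k] == self.target_study else 0
            need.append((self.n_cases[k] + extra) / self.prevalences[k])
        return int(np.ceil(max(need) * 1.12))


@dataclass
class SimulatedTruth:
    """Ground truth underlying one simulated study."""

    gamma: np.ndarray            # (m,) shared per-variant effects
    delta: np.ndarray            # (m, K) specific per-variant effects
    scores: np.ndarray           # (n_pop, 1+K): G_shared, G_k (raw scale)
    liabilities: np.ndarray      # (n_pop, K)
    thresholds: np.ndarray       # (K,)
    case: np.ndarray             # (n_pop, K) boolean
    realized_h2_liab: np.ndarray  # (K,) realized liability-scale h2
    study_rows: dict = field(default_factory=dict)   # study -> row indices
    study_y: dict = field(default_factory=dict)      # study -> 0/1 outcome
    target_rows: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Genotypes

def _variant_map(config: SimulationConfig, rng: np.random.Generator):
    m = config.m
    bs = config.block_size
    n_blocks = int(np.ceil(m / bs))
    block_id = np.arange(m) // bs
    chrom = 1 + (block_id * config.n_chromosomes) // n_blocks
    pos = np.zeros(m, dtype=np.int64)
    for c in range(1, config.n_chromosomes + 1):
        sel = chrom == c
        pos[sel] = (np.arange(sel.sum()) + 1) * config.spacing
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": chrom.astype(int),
            "pos": pos,
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
        }
    )
    maf = rng.uniform(*config.maf_range, size=m)
    rho = rng.uniform(*config.rho_block_range, size=n_blocks)
    return variants, maf, rho, block_id


def _block_chol(bs: int, rho: float) -> np.ndarray:
    idx = np.arange(bs)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(R).astype(np.float32)


def _generate_matrix(n: int, config: SimulationConfig, maf: np.ndarray,
                     rho: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n x m int8 genotype matrix under the blockwise haplotype model."""
    m = config.m
    bs = config.block_size
    out = np.empty((n, m), dtype=np.int8)
    thresholds = stats.norm.ppf(maf).astype(np.float32)
    for b in range(len(rho)):
        a = b * bs
        z = min(a + bs, m)
        L = _block_chol(z - a, float(rho[b]))
        t = thresholds[a:z]
        g = np.zeros((n, z - a), dtype=np.int8)
        for _hap in range(2):
            lat = rng.standard_normal((n, z - a), dtype=np.float32) @ L.T
            g += (lat < t).astype(np.int8)
        out[:, a:z] = g
    return out


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    """Reference panel, GWAS/target population, and the variant map.

    Returns ``(reference, population)`` as :class:`GenotypeData`; the GWAS
    samples and the target cohort are ascertained rows of ``population``
    (see :func:`simulate_liabilities_and_gwas` and
    :func:`simulate_target_cohort`), all sharing one variant map.
    """
    if stats.norm.ppf(config.maf_range[0]) < -8:
        raise SimulationError("minimum MAF too extreme for the latent threshold model")
    variants, maf, rho, _ = _variant_map(config, rng)
    n_pop = config.required_population()
    reference = GenotypeData(
        _generate_matrix(config.n_reference, config, maf, rho, rng),
        variants.assign(freq=maf),
        [f"ref{i}" for i in range(config.n_reference)],
    )
    population = GenotypeData(
        _generate_matrix(n_pop, config, maf, rho, rng),
        variants.assign(freq=maf),
        [f"pop{i}" for i in range(n_pop)],
    )
    return reference, population


# ---------------------------------------------------------------------------
# Liabilities and GWAS

def _standardized_scores(geno: np.ndarray, weights: np.ndarray,
                         maf: np.ndarray, chunk: int = 2_000) -> np.ndarray:
    """X_std @ weights computed in variant chunks; weights is (m, c)."""
    n = geno.shape[0]
    out = np.zeros((n, weights.shape[1]))
    mean = 2 * maf
    sd = np.sqrt(2 * maf * (1 - maf))
    for a in range(0, geno.shape[1], chunk):
        z = slice(a, min(a + chunk, geno.shape[1]))
        X = (geno[:, z].astype(np.float32) - mean[z].astype(np.float32)) / sd[
            z
        ].astype(np.float32)
        out += X @ weights[z].astype(np.float32)
    return out


def _score_test_z(geno: np.ndarray, rows: np.ndarray, y: np.ndarray,
                  chunk: int = 4_000) -> np.ndarray:
    """Per-variant trend-test z for a 0/1 outcome: z = sqrt(N) * corr(g, y)."""
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    N = len(y)
    m = geno.shape[1]
    z = np.zeros(m)
    sub = geno[rows]  # one int8 copy of the study rows
    for a in range(0, m, chunk):
        sl = slice(a, min(a + chunk, m))
        G = sub[:, sl].astype(np.float32)
        gc = G - G.mean(axis=0)
        num = yc.astype(np.float32) @ gc
        den = np.sqrt((gc * gc).sum(axis=0) * ss_y)
        den[den == 0] = np.inf
        z[sl] = np.sqrt(N) * (num / den)
    return z


def simulate_liabilities_and_gwas(config: SimulationConfig,
                                  population: GenotypeData,
                                  rng: np.random.Generator):
    """Draw effects and liabilities, ascertain studies, compute sumstats.

    Returns ``(tables, truth)``: ``tables`` maps study name to a
    sumstats-format DataFrame; ``truth`` is the :class:`SimulatedTruth`
    with per-variant effects, per-individual scores, case status and the
    rows/outcomes of each study sample.
    """
    m = config.m
    K = config.K
    n_pop = population.n_samples
    maf = population.variants["freq"].to_numpy(float)
    m_c = max(int(round(config.causal_fraction * m)), 1)

    gamma = np.zeros(m)
    causal = rng.choice(m, size=m_c, replace=False)
    gamma[causal] = rng.standard_normal(m_c) / np.sqrt(m_c)
    delta = np.zeros((m, K))
    for k in range(K):
        v = config.specific_variances[k]
        if v > 0:
            causal_k = rng.choice(m, size=m_c, replace=False)
            delta[causal_k, k] = rng.standard_normal(m_c) * np.sqrt(v / m_c)

    weights = np.column_stack([gamma, delta])
    scores = _standardized_scores(population.genotypes, weights, maf)
    lam = np.asarray(config.loadings, float)
    v_spec = np.asarray(config.specific_variances, float)
    eps_sd = np.sqrt(1 - lam**2 - v_spec)
    liab = (
        lam[None, :] * scores[:, [0]]
        + scores[:, 1:]
        + rng.standard_normal((n_pop, K)) * eps_sd[None, :]
    )
    thresholds = stats.norm.isf(np.asarray(config.prevalences))
    case = liab > thresholds[None, :]

    gen_part = lam[None, :] * scores[:, [0]] + scores[:, 1:]
    realized_h2 = gen_part.var(axis=0) / liab.var(axis=0)

    # ascertainment: the shared control pool must be control-eligible for
    # every study (never a case); study-specific controls are screened only
    # for their own disorder, as in typical single-disorder GWAS
    never_case = ~case.any(axis=1)
    pool_order = rng.permutation(np.where(never_case)[0])
    n_shared = int(round(config.control_overlap * max(config.n_controls)))
    shared_pool = pool_order[:n_shared]
    in_shared = np.zeros(n_pop, dtype=bool)
    in_shared[shared_pool] = True
    used_control = np.zeros(n_pop, dtype=bool)

    tables = {}
    truth = SimulatedTruth(
        gamma=gamma, delta=delta, scores=scores, liabilities=liab,
        thresholds=thresholds, case=case, realized_h2_liab=realized_h2,
    )
    # the target cohort (cases of the target disorder) is reserved first and
    # excluded from every source GWAS, mirroring a custom GWAS that leaves
    # out the PRS target sample
    reserved_target = np.zeros(n_pop, dtype=bool)
    tgt_k = config.studies.index(config.target_study)
    tgt_cases = np.where(case[:, tgt_k])[0]
    if len(tgt_cases) < config.n_cases[tgt_k] + config.n_target:
        raise SimulationError(
            f"only {len(tgt_cases)} {config.target_study} cases at prevalence "
            f"{config.prevalences[tgt_k]}; population of >= "
            f"{config.required_population()} required"
        )
    tgt = rng.choice(tgt_cases, size=config.n_target, replace=False)
    truth.target_rows = np.sort(tgt)
    reserved_target[tgt] = True

    for k, study in enumerate(config.studies):
        cases_k = np.where(case[:, k] & ~reserved_target)[0]
        if len(cases_k) < config.n_cases[k]:
            raise SimulationError(
                f"only {len(cases_k)} {study} cases at prevalence "
                f"{config.prevalences[k]}; population of >= "
                f"{config.required_population()} required"
            )
        chosen_cases = rng.choice(cases_k, size=config.n_cases[k], replace=False)
        n_sh = int(round(config.control_overlap * config.n_controls[k]))
        n_own = config.n_controls[k] - n_sh
        own_candidates = np.where(
            ~case[:, k] & ~in_shared & ~used_control & ~reserved_target
        )[0]
        if len(own_candidates) < n_own:
            raise SimulationError("control pool exhausted; increase population")
        own = rng.choice(own_candidates, size=n_own, replace=False)
        used_control[own] = True
        controls = np.concatenate([shared_pool[:n_sh], own])
        rows = np.concatenate([chosen_cases, controls])
        y = np.concatenate([np.ones(len(chosen_cases)), np.zeros(len(controls))])
        order = np.argsort(rows, kind="stable")
        rows, y = rows[order], y[order]
        z = _score_test_z(population.genotypes, rows, y)
        sub_freq = population.genotypes[rows].mean(axis=0) / 2.0
        tables[study] = pd.DataFrame(
            {
                "variant_id": population.variants["variant_id"],
                "chrom": population.variants["chrom"],
                "pos": population.variants["pos"],
                "effect_allele": population.variants["a1"],
                "other_allele": population.variants["a2"],
                "freq": sub_freq,
                "info": 1.0,
                "z": z,
                "n": float(len(rows)),
            }
        )
        truth.study_rows[study] = rows
        truth.study_y[study] = y
    return tables, truth


# ---------------------------------------------------------------------------
# Target cohort

def simulate_target_cohort(config: SimulationConfig,
                           population: GenotypeData,
                           truth: SimulatedTruth,
                           rng: np.random.Generator):
    """BADDS-like symptom scales and covariates for the BD-case target set.

    The four latent symptom liabilities are ``W @ G*`` plus Gaussian noise,
    where ``G*`` are the population-standardized genetic components
    (shared; per-disorder specific).  Ordinal scores are fixed cutpoints on
    the latent scales; the incongruence scale is generated only for
    individuals whose psychosis scale reaches the rating criterion.

    Returns ``(cohort, target_genotypes)``; ``cohort`` holds the raw BADDS
    inputs (phenotype flags are derived downstream by
    :func:`liabsem.assoc.derive_phenotypes`).
    """
    if truth.target_rows is None:
        raise SimulationError("truth carries no target rows; run the GWAS step first")
    rows = truth.target_rows
    n = len(rows)
    v_spec = np.maximum(np.asarray(config.specific_variances, float), 1e-12)
    G = truth.scores[rows]
    G_std = np.column_stack([G[:, 0], G[:, 1:] / np.sqrt(v_spec)[None, :]])
    W = np.asarray(config.W, float)
    noise_var = np.maximum(1 - (W**2).sum(axis=1), config.min_symptom_noise)
    latent = G_std @ W.T + rng.standard_normal((n, 4)) * np.sqrt(noise_var)[None, :]

    scales = ["badds_p", "badds_i", "badds_m", "badds_d"]
    cohort = pd.DataFrame({"individual_id": [population.sample_ids[i] for i in rows]})
    for s_idx, scale in enumerate(scales):
        cuts = np.asarray(config.cutpoints[scale], float)
        levels = np.asarray(config.scale_levels[scale])
        cohort[scale] = levels[np.searchsorted(cuts, latent[:, s_idx])]
    # incongruence is rated only when the psychosis criterion is met
    from .assoc import PSYCHOSIS_THRESHOLD

    rated = cohort["badds_p"] >= PSYCHOSIS_THRESHOLD
    cohort.loc[~rated, "badds_i"] = np.nan

    cohort["diagnosis_subtype"] = rng.choice(
        ["BD-I", "BD-II", "SAB", "other"], size=n, p=config.subtype_probs
    )
    cohort["age_at_interview"] = config.age_mean + config.age_sd * rng.standard_normal(n)
    cohort["platform"] = rng.choice(
        list(config.platforms), size=n, p=config.platform_probs
    )
    for i in range(1, config.n_pcs + 1):
        cohort[f"pc{i}"] = rng.standard_normal(n)

    target_geno = population.subset_samples(rows)
    return cohort, target_geno


# ---------------------------------------------------------------------------
# One-call bundle

@dataclass
class SimulatedStudy:
    reference: GenotypeData
    sumstats: dict
    cohort: pd.DataFrame
    target_genotypes: GenotypeData
    truth: SimulatedTruth
    config: SimulationConfig


def simulate_study(config: SimulationConfig | None = None,
                   seed: int = 0) -> SimulatedStudy:
    """Generate a complete synthetic study from one seed.

    The population genotype matrix is released after ascertainment; only
    the reference panel and the target cohort's genotypes are retained.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    reference, population = simulate_genotypes(config, rng)
    tables, truth = simulate_liabilities_and_gwas(config, population, rng)
    cohort, target = simulate_target_cohort(config, population, truth, rng)
    return SimulatedStudy(
        reference=reference, sumstats=tables, cohort=cohort,
        target_genotypes=target, truth=truth, config=config,
    )


def small_config(**overrides) -> SimulationConfig:
    """A fast reduced-scale configuration for examples and smoke tests."""
    base = dict(
        m=2_000, n_cases=(800, 800, 800), n_controls=(800, 800, 800),
        n_reference=500, n_target=800,
    )
    base.update(overrides)
    return SimulationConfig(**base)
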