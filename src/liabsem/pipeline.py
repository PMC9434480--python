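"""End-to-end orchestration: munge -> LDSC -> SEM -> PRS -> association.

Ties the module chain together for in-memory inputs (typically a
:class:`liabsem.simulate.SimulatedStudy`); each step remains individually
usable and file-driven through the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import assoc as assoc_mod
from . import gsem, ldsc, prs, sumstats
from .genotypes import GenotypeData
from .simulate import SimulatedStudy


@dataclass
class PipelineResult:
    panel: sumstats.HarmonizedPanel
    ld_scores: pd.DataFrame
    covariance: ldsc.GeneticCovariance
    effects: gsem.SnvEffectSet
    scores: dict = field(default_factory=dict)        # component -> ScoreVector
    source_scores: dict = field(default_factory=dict)  # study -> ScoreVector
    prs_correlations: pd.DataFrame | None = None
    cohort: pd.DataFrame | None = None
    associations: pd.DataFrame | None = None

    @property
    def baseline(self) -> gsem.FactorFit:
        return self.effects.baseline


def source_effect_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sumstats-format effect table for a raw source GWAS (beta = z/sqrt(n))."""
    out = table[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    n = table["n"].to_numpy(float)
    out["beta"] = table["z"].to_numpy(float) / np.sqrt(n)
    out["se"] = 1.0 / np.sqrt(n)
    out["p"] = np.clip(2 * _stats.norm.sf(np.abs(table["z"].to_numpy(float))),
                       np.finfo(float).tiny, 1.0)
    out["n_eff"] = n
    return out


def build_panel(tables: dict, reference: pd.DataFrame) -> sumstats.HarmonizedPanel:
    """Validate, harmonize, QC-filter and standardize the study tables."""
    validated = [
        sumstats.validate_sumstats(t, label=name) for name, t in tables.items()
    ]
    panel = sumstats.harmonize(validated, reference, studies=list(tables))
    panel = sumstats.filter_variants(panel)
    return sumstats.standardize_effects(panel)


def score_components(effect_tables: dict, genotypes: GenotypeData,
                     clump_kwargs: dict | None = None) -> dict:
    """Clump and score every derived component against the target sample."""
    out = {}
    for name, tab in effect_tables.items():
        cl = prs.clump(tab, genotypes, **(clump_kwargs or {}))
        out[name] = prs.compute_prs(tab, cl, genotypes, component=name)
    return out


def run_pipeline(study: SimulatedStudy, run_associations: bool = True,
                 score_sources: bool = False,
                 ld_window: int = ldsc.DEFAULT_WINDOW) -> PipelineResult:
    """The full analysis chain on one simulated study."""
    reference = study.reference.variants.copy()  # variant_id, chrom, pos, a1, a2, freq
    panel = build_panel(study.sumstats, reference)
    scores_tab = ldsc.compute_ld_scores(study.reference, window=ld_window)
    cov = ldsc.panel_covariance(panel, scores_tab)
    effects = gsem.run_genomewide(panel, cov)

    comp_scores = score_components(effects.tables, study.target_genotypes)
    source_scores = {}
    if score_sources:
        src_tables = {s: source_effect_table(t) for s, t in study.sumstats.items()}
        source_scores = score_components(src_tables, study.target_genotypes)
    all_scores = list(comp_scores.values()) + list(source_scores.values())
    corr = prs.prs_correlation_matrix(all_scores) if len(all_scores) >= 2 else None

    cohort = None
    suite = None
    if run_associations:
        cohort = assoc_mod.derive_phenotypes(study.cohort)
        name_map = {"shared": "shared"}
        for s in panel.studies:
            name_map[f"{s}_diff"] = f"{s}_diff"
        for name, sv in comp_scores.items():
            cohort[name] = sv.standardized
        components = [c for c in ["shared"] + [f"{s}_diff" for s in panel.studies]]
        suite = assoc_mod.run_association_suite(cohort, components=components)
    return PipelineResult(
        panel=panel, ld_scores=scores_tab, covariance=cov, effects=effects,
        scores=comp_scores, source_scores=source_scores,
        prs_correlations=corr, cohort=cohort, associations=suite,
    )
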