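"""Reading, harmonization and filtering of GWAS summary statistics.

A single study's summary statistics are carried as a validated
:class:`pandas.DataFrame` with the canonical columns

``variant_id, chrom, pos, effect_allele, other_allele, freq, info, z, n``

where ``z`` is the association z-statistic signed toward the effect allele.
Multiple studies are merged into a :class:`HarmonizedPanel`: one row per
variant present in every study, all effect sizes oriented to a single
reference allele, strand-ambiguous variants removed.  Quality-control
filters reproduce a standard cross-disorder meta-analytic setup: reference
minor-allele frequency above 1%, imputation info of at least 0.7 in every
study, and exclusion of the extended MHC (chromosome 6, 25–35 Mb), whose
exceptional LD would otherwise dominate LD-score based analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import complement, is_palindromic

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "freq",
    "info",
    "n",
]

MHC_CHROM = 6
MHC_START = 25_000_000
MHC_END = 35_000_000

VALID_ALLELES = {"A", "C", "G", "T"}


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics input."""


@dataclass
class HarmonizedPanel:
    """Variants present in all studies, aligned to one effect allele.

    ``df`` holds one row per variant with columns ``variant_id, chrom, pos,
    effect_allele, other_allele, p_ref`` plus per-study ``z_<study>``,
    ``n_<study>``, ``info_<study>`` and ``freq_<study>`` columns (and
    ``beta_std_<study>`` once :func:`standardize_effects` has run).
    ``report`` accumulates per-step kept/dropped counts.
    """

    df: pd.DataFrame
    studies: list
    report: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def study_col(self, base: str, study: str) -> pd.Series:
        return self.df[f"{base}_{study}"]

    def zmat(self) -> np.ndarray:
        """(m, K) matrix of per-study z statistics."""
        return self.df[[f"z_{s}" for s in self.studies]].to_numpy(float)

    def nmat(self) -> np.ndarray:
        return self.df[[f"n_{s}" for s in self.studies]].to_numpy(float)


def read_sumstats(path: str, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate one study's summary statistics.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with a header row.
    column_map
        Optional mapping from the file's column names to canonical names,
        e.g. ``{"SNP": "variant_id", "A1": "effect_allele"}``.

    The file must provide either a ``z`` column or both ``beta`` and ``se``
    (then ``z = beta / se``).  Rows violating the type invariants
    (duplicate id, identical or non-ACGT alleles, frequency outside the
    open unit interval, info outside [0, 1]) are dropped with a logged
    count; an empty result or a missing mandatory column is fatal.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SumstatsError(f"mandatory column missing from {path}: {col!r}")
    if "z" not in df.columns:
        if "beta" in df.columns and "se" in df.columns:
            df["z"] = df["beta"] / df["se"]
        else:
            raise SumstatsError(
                f"mandatory column missing from {path}: 'z' (or 'beta'+'se')"
            )
    return validate_sumstats(df, label=path)


def validate_sumstats(df: pd.DataFrame, label: str = "sumstats") -> pd.DataFrame:
    """Apply the row-level invariants, dropping offending rows."""
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    n_in = len(df)
    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["freq"] > 0)
        & (df["freq"] < 1)
        & (df["info"] >= 0)
        & (df["info"] <= 1)
        & (df["n"] > 0)
        & np.isfinite(df["z"])
        & ~df["variant_id"].duplicated(keep=False)
    )
    df = df.loc[ok].reset_index(drop=True)
    dropped = n_in - len(df)
    if dropped:
        logger.info("%s: dropped %d/%d rows failing validation", label, dropped, n_in)
    if not len(df):
        raise SumstatsError(f"{label}: no rows survived validation")
    return df[MANDATORY_COLUMNS[:5] + ["freq", "info", "z", "n"]]


def _orient(effect, other, ref_a1, ref_a2):
    """Orientation of a study's allele pair against the reference.

    Returns +1 (same orientation), -1 (flipped: study effect allele is the
    reference other allele), or 0 (irreconcilable).  Strand complements are
    resolved; palindromic pairs must be excluded beforehand.
    """
    pairs = {(effect, other): 1, (other, effect): -1}
    comp = (complement(effect), complement(other))
    pairs.setdefault(comp, 1)
    pairs.setdefault(comp[::-1], -1)
    return pairs.get((ref_a1, ref_a2), 0)


def harmonize(tables: list, reference: pd.DataFrame, studies: list | None = None) -> HarmonizedPanel:
    """Align >=2 studies to the reference panel's allele orientation.

    Keeps only variants present in every study whose alleles match the
    reference directly or as strand complements; removes strand-ambiguous
    (A/T, C/G) variants; flips each study's z sign (and frequency) where its
    effect allele is the reference's other allele.  The reference must
    provide ``variant_id, chrom, pos, a1, a2`` and, if available, ``freq``
    (a1 frequency) used as ``p_ref`` downstream.
    """
    if len(tables) < 2:
        raise SumstatsError("harmonize requires at least two studies")
    if studies is None:
        studies = [f"study{i}" for i in range(len(tables))]
    ref = reference.copy().reset_index(drop=True)
    ref["a1"] = ref["a1"].astype(str).str.upper()
    ref["a2"] = ref["a2"].astype(str).str.upper()
    report: dict = {"n_reference": len(ref)}

    palin = ref.apply(lambda r: is_palindromic(r.a1, r.a2), axis=1).to_numpy()
    report["dropped_palindromic"] = int(palin.sum())
    ref = ref.loc[~palin].reset_index(drop=True)

    panel = ref.rename(
        columns={"a1": "effect_allele", "a2": "other_allele", "freq": "p_ref"}
    )
    if "p_ref" not in panel.columns:
        panel["p_ref"] = np.nan
    panel = panel[["variant_id", "chrom", "pos", "effect_allele", "other_allele", "p_ref"]]

    mismatched = 0
    for name, tab in zip(studies, tables):
        merged = panel.merge(
            tab[["variant_id", "effect_allele", "other_allele", "freq", "info", "z", "n"]],
            on="variant_id",
            suffixes=("", "_study"),
            how="inner",
        )
        sign = np.array(
            [
                _orient(e, o, a1, a2)
                for e, o, a1, a2 in zip(
                    merged["effect_allele_study"],
                    merged["other_allele_study"],
                    merged["effect_allele"],
                    merged["other_allele"],
                )
            ]
        )
        mismatched += int((sign == 0).sum())
        merged = merged.loc[sign != 0]
        s = sign[sign != 0]
        merged[f"z_{name}"] = merged["z"] * s
        merged[f"freq_{name}"] = np.where(s == 1, merged["freq"], 1 - merged["freq"])
        merged[f"info_{name}"] = merged["info"]
        merged[f"n_{name}"] = merged["n"]
        keep = ["variant_id", f"z_{name}", f"freq_{name}", f"info_{name}", f"n_{name}"]
        panel = panel.merge(merged[keep], on="variant_id", how="inner")

    report["dropped_allele_mismatch"] = mismatched
    report["n_harmonized"] = len(panel)
    if not len(panel):
        raise SumstatsError("no variants shared by all studies after harmonization")
    logger.info(
        "harmonized %d variants across %d studies (%d palindromic, %d mismatched removed)",
        len(panel), len(studies), report["dropped_palindromic"], mismatched,
    )
    return HarmonizedPanel(panel.reset_index(drop=True), list(studies), report)


def filter_variants(panel: HarmonizedPanel, maf_min: float = 0.01,
                    info_min: float = 0.7) -> HarmonizedPanel:
    """QC filter: reference MAF > 1%, info >= 0.7 everywhere, MHC excluded.

    The MHC window is the closed interval chr6:[25e6, 35e6].  The filter is
    idempotent; counts for each rule are recorded in the panel report.
    """
    df = panel.df
    p = df["p_ref"].to_numpy(float)
    maf = np.minimum(p, 1 - p)
    pass_maf = maf > maf_min
    info_cols = [f"info_{s}" for s in panel.studies]
    pass_info = (df[info_cols].to_numpy(float) >= info_min).all(axis=1)
    in_mhc = (
        (df["chrom"].to_numpy() == MHC_CHROM)
        & (df["pos"].to_numpy() >= MHC_START)
        & (df["pos"].to_numpy() <= MHC_END)
    )
    keep = pass_maf & pass_info & ~in_mhc
    report = dict(panel.report)
    report.update(
        n_input=len(df),
        dropped_maf=int((~pass_maf).sum()),
        dropped_info=int((pass_maf & ~pass_info).sum()),
        dropped_mhc=int((pass_maf & pass_info & in_mhc).sum()),
        n_filtered=int(keep.sum()),
    )
    if not keep.any():
        raise SumstatsError("no variants survived QC filtering")
    logger.info(
        "QC filter: %d -> %d variants (maf %d, info %d, MHC %d dropped)",
        len(df), keep.sum(), report["dropped_maf"], report["dropped_info"],
        report["dropped_mhc"],
    )
    return HarmonizedPanel(df.loc[keep].reset_index(drop=True), panel.studies, report)


def standardize_effects(panel: HarmonizedPanel) -> HarmonizedPanel:
    """Add per-study standardized effects ``beta_std = z / sqrt(n)``.

    This is the per-SD effect of the standardized genotype on the
    standardized trait scale, the parameterization under which the
    SNV-to-trait covariances enter the structural model.
    """
    df = panel.df.copy()
    for s in panel.studies:
        n = df[f"n_{s}"].to_numpy(float)
        if (n <= 0).any():
            raise SumstatsError(f"non-positive sample size in study {s}")
        df[f"beta_std_{s}"] = df[f"z_{s}"] / np.sqrt(n)
    return HarmonizedPanel(df, panel.studies, dict(panel.report))


def write_panel(panel: HarmonizedPanel, path: str) -> None:
    panel.df.to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> HarmonizedPanel:
    df = pd.read_csv(path, sep="\t")
    studies = [c[2:] for c in df.columns if c.startswith("z_")]
    return HarmonizedPanel(df, studies)
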