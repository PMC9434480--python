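"""In-memory genotype container with VCF and variant-list I/O.

Genotypes are additively coded 0/1/2 copies of the first (``a1``) allele,
stored as ``int8`` with ``-1`` marking missing calls.  The container is the
common currency between the simulator, LD-score computation, clumping and
PRS scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical columns of a variant map
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Complementary base of a single-nucleotide allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class GenotypeData:
    """A sample-by-variant additive genotype matrix plus its variant map.

    Attributes
    ----------
    genotypes
        ``(n_samples, n_variants)`` int8 array of a1-allele counts, -1 missing.
    variants
        DataFrame with columns ``variant_id, chrom, pos, a1, a2`` (and
        optionally ``freq``), one row per genotype column, same order.
    sample_ids
        Sequence of sample identifiers, one per genotype row.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        if len(self.variants) != self.genotypes.shape[1]:
            raise ValueError("variant map length does not match genotype columns")
        if not self.sample_ids:
            self.sample_ids = [f"I{i}" for i in range(self.genotypes.shape[0])]
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Observed a1-allele frequency per variant (missing calls skipped)."""
        g = self.genotypes
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, g, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def standardized(self, dtype=np.float32, chunk: int = 2048) -> np.ndarray:
        """Mean-imputed, column-standardized genotype matrix.

        Monomorphic columns standardize to all-zero rather than dividing by
        zero, so they contribute nothing to correlations or scores.  Built
        chunkwise into a single output buffer to keep peak memory near the
        size of the result.
        """
        n, m = self.genotypes.shape
        out = np.empty((n, m), dtype=dtype)
        for a in range(0, m, chunk):
            sl = slice(a, min(a + chunk, m))
            g = self.genotypes[:, sl].astype(dtype)
            miss = self.genotypes[:, sl] == MISSING
            if miss.any():
                col_mean = np.where(miss, 0, g).sum(axis=0) / np.maximum(
                    (~miss).sum(axis=0), 1
                )
                g[miss] = np.take(col_mean, np.where(miss)[1])
            mean = g.mean(axis=0)
            sd = g.std(axis=0)
            sd[sd == 0] = np.inf
            out[:, sl] = (g - mean) / sd
        return out

    def subset_samples(self, index) -> "GenotypeData":
        idx = np.asarray(index)
        return GenotypeData(
            self.genotypes[idx],
            self.variants.copy(),
            [self.sample_ids[i] for i in idx],
        )

    def subset_variants(self, index) -> "GenotypeData":
        idx = np.asarray(index)
        return GenotypeData(
            self.genotypes[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )


def read_vcf(path: str) -> GenotypeData:
    """Read hard-call genotypes from a VCF into a :class:`GenotypeData`.

    The REF allele is coded as ``a2`` and the first ALT allele as ``a1``
    (counted by the additive code), matching the writer below.  Multiallelic
    records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    genos = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        gt = rec.genotype.array()
        counts = gt[:, 0] + gt[:, 1]
        counts = np.where((gt[:, 0] < 0) | (gt[:, 1] < 0), MISSING, counts)
        genos.append(counts.astype(np.int8))
        chrom = str(rec.CHROM)
        chrom = int(chrom[3:]) if chrom.lower().startswith("chr") else int(chrom)
        rows.append((rec.ID or f"{chrom}:{rec.POS}", chrom, rec.POS, rec.ALT[0], rec.REF))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeData(np.array(genos, dtype=np.int8).T, variants, samples)


def write_vcf(data: GenotypeData, path: str) -> None:
    """Write hard-call genotypes as an uncompressed VCFv4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(data.variants["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in data.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, var in data.variants.iterrows():
            calls = "\t".join(gt_codes[int(g)] for g in data.genotypes[:, j])
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.variant_id}\t{var.a2}\t{var.a1}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def read_variant_reference(path: str) -> pd.DataFrame:
    """Read a PLINK ``.bim``-style variant list, optionally with frequencies.

    Accepts either a 6-column headerless ``.bim`` layout
    (chrom, variant_id, cm, pos, a1, a2), the same with a seventh ``freq``
    column, or a headered whitespace/tab table containing the canonical
    column names.  Returns columns ``variant_id, chrom, pos, a1, a2[, freq]``.
    """
    probe = pd.read_csv(path, sep=r"\s+", nrows=1, header=None)
    first = str(probe.iloc[0, 0]).lower()
    if first in {"variant_id", "chrom", "id", "snp"}:
        df = pd.read_csv(path, sep=r"\s+")
        df = df.rename(columns={"id": "variant_id", "snp": "variant_id"})
    else:
        ncol = probe.shape[1]
        names = ["chrom", "variant_id", "cm", "pos", "a1", "a2"]
        if ncol == 7:
            names.append("freq")
        df = pd.read_csv(path, sep=r"\s+", header=None, names=names)
        df = df.drop(columns=["cm"])
    cols = [c for c in VARIANT_COLUMNS + ["freq"] if c in df.columns]
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference panel is missing columns: {missing}")
    return df[cols]
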