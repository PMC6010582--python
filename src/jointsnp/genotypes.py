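"""Genotype dosage matrices, readers (VCF / dosage table) and variant QC.

Genotypes are stored as additive dosages of the effect allele, values in
[0, 2] with NaN marking missing calls.  For VCF input the counted allele is
ALT; dosage tables declare their own effect allele (or default to "ALT").

Variant-level quality control follows common GWAS practice: per-variant call
rate, minor allele frequency on non-missing calls, and an exact conditional
test of Hardy-Weinberg equilibrium (Wigginton-style, two-sided by probability
ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_dosage_table",
    "qc_filter_variants",
    "hwe_exact_pvalue",
]


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix, variants x individuals.

    Attributes
    ----------
    variants : list of str
        Variant identifiers (rows).
    individuals : list
        Individual ids (columns).
    dosages : ndarray, shape (n_variants, n_individuals)
        Effect-allele dosages in [0, 2]; NaN = missing call.
    effect_alleles : list of str
        Counted allele per variant.
    """

    variants: List[str]
    individuals: List
    dosages: np.ndarray
    effect_alleles: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.individuals)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage outside [0, 2]: variant {self.variants[i]}, "
                f"individual {self.individuals[j]}, value {self.dosages[i, j]}"
            )
        if not self.effect_alleles:
            self.effect_alleles = ["ALT"] * len(self.variants)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages_for(self, variant: str, ids: Sequence) -> np.ndarray:
        """Dosage vector for one variant, aligned to the requested id order."""
        try:
            row = self.variants.index(variant)
        except ValueError:
            raise KeyError(f"unknown variant {variant!r}") from None
        col = pd.Index(self.individuals).get_indexer(list(ids))
        if (col < 0).any():
            missing = [i for i, c in zip(ids, col) if c < 0]
            raise KeyError(f"individuals absent from genotype matrix: {missing[:5]}")
        return self.dosages[row, col]

    def subset(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variants.index(v) for v in keep]
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            list(self.individuals),
            self.dosages[idx],
            [self.effect_alleles[i] for i in idx],
        )

    # -- per-variant summaries -----------------------------------------
    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Effect-allele frequency on non-missing calls."""
        return np.nanmean(self.dosages, axis=1) / 2.0

    def genotype_counts(self) -> np.ndarray:
        """Hard-call genotype counts (n0, n1, n2) per variant.

        Fractional dosages are rounded to the nearest genotype for the HWE
        test only; association analyses use the raw dosage.
        """
        counts = np.zeros((self.n_variants, 3), dtype=int)
        rounded = np.round(self.dosages)
        for g in (0, 1, 2):
            counts[:, g] = np.nansum(rounded == g, axis=1)
        return counts


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------
def read_genotypes(path, format: Optional[str] = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (GT or DS) or a dosage TSV.

    Parameters
    ----------
    path : str or Path
    format : {"vcf", "dosage_table"}, optional
        Inferred from the file extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage_table"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    variants, alleles, rows = [], [], []
    for rec in vcf:
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = np.asarray(rec.gt_types)
            row = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        variants.append(vid)
        alleles.append(rec.ALT[0] if rec.ALT else "ALT")
        rows.append(row)
    if not variants:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(variants, individuals, np.vstack(rows), alleles)


def _read_dosage_table(path) -> GenotypeMatrix:
    """Tab-delimited dosage file: rows = variants, header row of individual ids.

    First column = variant id; an optional second column ``effect_allele``.
    Missing entries are empty cells or "NA".
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"dosage table {path} has no individual columns")
    variant_col = df.columns[0]
    if "effect_allele" in df.columns:
        alleles = df["effect_allele"].astype(str).tolist()
        dose = df.drop(columns=[variant_col, "effect_allele"])
    else:
        alleles = []
        dose = df.drop(columns=[variant_col])
    return GenotypeMatrix(
        df[variant_col].astype(str).tolist(),
        list(dose.columns),
        dose.to_numpy(dtype=float),
        alleles,
    )


def write_dosage_table(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=[str(i) for i in gm.individuals])
    df.insert(0, "variant", gm.variants)
    df.insert(1, "effect_allele", gm.effect_alleles)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (two-sided
    by probability ordering).  Symmetric in the two homozygote counts.

    Returns p in (0, 1]; a monomorphic variant gives p = 1.
    """
    counts = (int(n_hom_major), int(n_het), int(n_hom_minor))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all calls missing: cannot test HWE")
    n_rare = 2 * min(counts[0], counts[2]) + counts[1]
    if n_rare == 0:
        return 1.0

    # log P(n_het | n_rare, n) up to a shared constant, over feasible n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + hets <= n]  # rare homs + hets fit in n
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]

    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()

    observed = counts[1]
    p_obs = prob[hets == observed]
    if p_obs.size == 0:  # inconsistent counts cannot occur by construction
        raise ValueError("observed heterozygote count infeasible")
    # small relative tolerance so ties with the observed probability count
    p = prob[prob <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ----------------------------------------------------------------------
# QC filtering
# ----------------------------------------------------------------------
def qc_filter_variants(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants on call rate, MAF and Hardy-Weinberg equilibrium.

    A variant is retained only if its call rate is >= ``call_rate_min``, its
    minor allele frequency (computed on non-missing calls) is > ``maf_min``
    and its HWE exact p-value is > ``hwe_p_min``.

    Returns the filtered matrix and an exclusion report with columns
    ``variant``, ``reason``, ``statistic`` (one row per failed check).
    """
    for name, thr in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                      ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    call = gm.call_rates()
    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    counts = gm.genotype_counts()

    records, keep = [], []
    for i, v in enumerate(gm.variants):
        ok = True
        if call[i] < call_rate_min:
            records.append((v, "call_rate", call[i]))
            ok = False
        if not np.isnan(maf[i]) and maf[i] <= maf_min:
            records.append((v, "maf", maf[i]))
            ok = False
        if counts[i].sum() > 0:
            p_hwe = hwe_exact_pvalue(*counts[i])
            if p_hwe <= hwe_p_min:
                records.append((v, "hwe", p_hwe))
                ok = False
        else:
            records.append((v, "call_rate", 0.0))
            ok = False
        if ok:
            keep.append(v)

    report = pd.DataFrame(records, columns=["variant", "reason", "statistic"])
    return gm.subset(keep), report
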