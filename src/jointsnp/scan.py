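"""Per-SNP association scan over a QC'd genotype matrix.

Variants are analysed one at a time against a fixed phenotype: the fast
two-step estimator (TS) serves as a pre-filter, the joint likelihood (JM)
as the refinement.  Each variant's fit is independent, so results are
invariant to variant ordering and to how the matrix is partitioned across
workers; failures are logged and flagged, never fatal to the scan.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortData
from .genotypes import GenotypeMatrix, qc_filter_variants
from .joint import JointModel, QuadratureSpec, lrt_snp_effect
from .twostep import TwoStepError, TwoStepModel

__all__ = ["scan", "two_stage_scan", "bonferroni_threshold"]

logger = logging.getLogger("jointsnp.scan")

RESULT_COLUMNS = [
    "variant", "effect_allele", "freq", "method",
    "gamma", "gamma_se", "gamma_p",
    "alpha", "alpha_se", "alpha_p",
    "beta", "beta_se", "beta_p",
    "lrt_stat", "lrt_p", "converged", "note",
]


def bonferroni_threshold(nominal: float, n_tested: int) -> float:
    """Family-wise threshold: nominal level divided by the number of tests."""
    if n_tested < 1:
        raise ValueError("need at least one tested variant")
    return nominal / n_tested


def _blank_row(variant, allele, freq, method, note, converged=False):
    row = dict.fromkeys(RESULT_COLUMNS, np.nan)
    row.update(variant=variant, effect_allele=allele, freq=freq,
               method=method, converged=converged, note=note)
    return row


def _fit_ts_row(cohort, z, variant, allele, freq, covariate_columns):
    try:
        res = TwoStepModel(cohort, genotype=z,
                           covariate_columns=covariate_columns).fit()
    except TwoStepError as exc:
        logger.warning("variant %s: TS failed (%s)", variant, exc)
        return _blank_row(variant, allele, freq, "TS", f"fit_failed:{exc.stage}")
    row = _blank_row(variant, allele, freq, "TS",
                     "" if res.converged else "non-convergence",
                     converged=res.converged)
    for par in ("gamma", "alpha", "beta"):
        try:
            zval, p = res.wald_test(par)
        except ValueError:
            continue
        est = {"gamma": res.gamma, "alpha": res.alpha, "beta": res.beta}[par]
        se = (res.gamma_se if par == "gamma" else res.cox.se(par))
        row.update({par: est, f"{par}_se": se, f"{par}_p": p})
    return row


def _fit_jm_row(cohort, z, variant, allele, freq, covariate_columns, quad,
                with_lrt):
    try:
        model = JointModel(cohort, genotype=z,
                           covariate_columns=covariate_columns, quad=quad)
        res = model.fit()
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("variant %s: JM failed (%s)", variant, exc)
        return _blank_row(variant, allele, freq, "JM", "fit_failed")
    row = _blank_row(variant, allele, freq, "JM",
                     "" if res.converged else "non-convergence",
                     converged=res.converged)
    for par in ("gamma", "alpha", "beta"):
        try:
            zval, p = res.wald_test(par)
        except (ValueError, KeyError):
            continue
        row.update({par: res.estimates[par],
                    f"{par}_se": float(res.standard_errors()[par]),
                    f"{par}_p": p})
    if with_lrt:
        try:
            stat, _, p = lrt_snp_effect(cohort, z,
                                        covariate_columns=covariate_columns,
                                        quad=quad, full=res)
            row.update(lrt_stat=stat, lrt_p=p)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("variant %s: LRT failed (%s)", variant, exc)
    return row


def scan(
    cohort: CohortData,
    genotypes: GenotypeMatrix,
    method: str = "TS",
    covariate_columns: Optional[Sequence[str]] = None,
    qc_thresholds: Optional[Dict[str, float]] = None,
    quad: QuadratureSpec = QuadratureSpec(),
    jm_lrt: bool = True,
) -> pd.DataFrame:
    """Independent association fit of every variant against the phenotype.

    ``qc_thresholds`` maps any of call_rate_min / maf_min / hwe_p_min to a
    value; pass an empty dict to skip QC (e.g. when the matrix is already
    clean).  Returns one row per (variant, method) with estimates, SEs and
    Wald p-values for gamma (trajectory), alpha (hazard), beta (link), plus
    the SNP likelihood-ratio test for JM rows.
    """
    if method not in ("TS", "JM"):
        raise ValueError("method must be 'TS' or 'JM'")
    if qc_thresholds is None:
        genotypes, report = qc_filter_variants(genotypes)
    elif qc_thresholds:
        genotypes, report = qc_filter_variants(genotypes, **qc_thresholds)
    if genotypes.n_variants == 0:
        raise ValueError("zero variants after quality control")

    rows = []
    freqs = genotypes.allele_frequencies()
    for i, variant in enumerate(genotypes.variants):
        allele = genotypes.effect_alleles[i]
        z = genotypes.dosages_for(variant, cohort.ids)
        missing = np.isnan(z)
        if missing.any():
            z = np.where(missing, np.nanmean(z), z)  # mean-impute rare holes
        if np.nanstd(z) == 0:
            rows.append(_blank_row(variant, allele, freqs[i], method,
                                   "no variation"))
            continue
        if method == "TS":
            rows.append(_fit_ts_row(cohort, z, variant, allele, freqs[i],
                                    covariate_columns))
        else:
            rows.append(_fit_jm_row(cohort, z, variant, allele, freqs[i],
                                    covariate_columns, quad, jm_lrt))
        logger.info("variant %s: %s done", variant, method)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def two_stage_scan(
    cohort: CohortData,
    genotypes: GenotypeMatrix,
    prefilter_p: float = 0.05,
    covariate_columns: Optional[Sequence[str]] = None,
    qc_thresholds: Optional[Dict[str, float]] = None,
    quad: QuadratureSpec = QuadratureSpec(),
    jm_lrt: bool = True,
) -> pd.DataFrame:
    """TS scan of every variant, JM refit of the promising ones.

    A variant is promoted to the joint-likelihood stage when its TS gamma-
    or alpha-test p-value falls below ``prefilter_p``; both stages' rows are
    returned, labelled by the ``method`` column.  JM rows are numerically
    identical to what a full JM scan would produce for those variants.
    """
    if not 0.0 < prefilter_p <= 1.0:
        raise ValueError("prefilter_p must lie in (0, 1]")
    ts = scan(cohort, genotypes, method="TS",
              covariate_columns=covariate_columns, qc_thresholds=qc_thresholds)
    gp = ts["gamma_p"].fillna(1.0)
    ap = ts["alpha_p"].fillna(1.0)
    promoted = ts.loc[(gp <= prefilter_p) | (ap <= prefilter_p), "variant"]
    frames = [ts]
    if len(promoted):
        sub = genotypes.subset(list(promoted))
        frames.append(scan(cohort, sub, method="JM",
                           covariate_columns=covariate_columns,
                           qc_thresholds={}, quad=quad, jm_lrt=jm_lrt))
    return pd.concat(frames, ignore_index=True)
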