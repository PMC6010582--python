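"""Cohort data containers and delimited-file I/O.

A cohort couples a long-format longitudinal phenotype table (one row per
biomarker measurement), a survival table (one row per individual, holding the
observed follow-up time and the event indicator), and, optionally, a genotype
dosage matrix and a baseline covariate table.

Times are expressed in years since baseline (0-based).  Because the biomarker
stops being measured once the event occurs (event-driven dropout), a valid
cohort never contains a measurement strictly after the individual's observed
follow-up time; `CohortData.validate` enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortData",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

LONGITUDINAL_COLUMNS = ("id", "time", "value")
SURVIVAL_COLUMNS = ("id", "time", "status")


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant.

    Attributes
    ----------
    offending : pandas.DataFrame or None
        The records responsible for the failure, when identifiable.
    """

    def __init__(self, message: str, offending: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.offending = offending


@dataclass
class CohortData:
    """One analysis-ready cohort.

    Parameters
    ----------
    longitudinal : pandas.DataFrame
        Columns ``id``, ``time`` (years since baseline), ``value``.
    survival : pandas.DataFrame
        Columns ``id``, ``time`` (observed time = min(event, censoring)),
        ``status`` (1 = event, 0 = censored); exactly one row per individual.
    covariates : pandas.DataFrame, optional
        One row per individual, ``id`` column plus numeric covariates.
    genotypes : GenotypeMatrix, optional
        Dosage matrix; attached lazily by the scan machinery.
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None
    genotypes: Optional["GenotypeMatrix"] = None  # noqa: F821
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.longitudinal = self.longitudinal.reset_index(drop=True)
        self.survival = self.survival.reset_index(drop=True)
        if not self._validated:
            self.validate()
            self._validated = True

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for col in LONGITUDINAL_COLUMNS:
            if col not in self.longitudinal.columns:
                raise CohortValidationError(
                    f"longitudinal table missing column {col!r}"
                )
        for col in SURVIVAL_COLUMNS:
            if col not in self.survival.columns:
                raise CohortValidationError(f"survival table missing column {col!r}")
        if len(self.survival) == 0:
            raise CohortValidationError("no survival records")
        if self.survival["id"].duplicated().any():
            dup = self.survival[self.survival["id"].duplicated(keep=False)]
            raise CohortValidationError("duplicate survival records", dup)
        if not np.isfinite(self.survival["time"]).all() or (
            self.survival["time"] <= 0
        ).any():
            bad = self.survival[
                ~np.isfinite(self.survival["time"]) | (self.survival["time"] <= 0)
            ]
            raise CohortValidationError("survival times must be finite and > 0", bad)
        if not self.survival["status"].isin([0, 1]).all():
            raise CohortValidationError("status must be 0 or 1")

        long_ids = set(self.longitudinal["id"])
        surv_ids = set(self.survival["id"])
        if long_ids - surv_ids:
            raise CohortValidationError(
                f"{len(long_ids - surv_ids)} longitudinal ids have no survival record"
            )
        if surv_ids - long_ids:
            raise CohortValidationError(
                f"{len(surv_ids - long_ids)} individuals have no longitudinal record"
            )
        if (self.longitudinal["time"] < 0).any() or not np.isfinite(
            self.longitudinal[["time", "value"]]
        ).all().all():
            raise CohortValidationError("longitudinal times/values must be finite, t >= 0")
        if self.longitudinal.duplicated(["id", "time"]).any():
            dup = self.longitudinal[
                self.longitudinal.duplicated(["id", "time"], keep=False)
            ]
            raise CohortValidationError("duplicated measurement times within individual", dup)

        # event-driven dropout: no measurement after the observed follow-up time
        tobs = self.survival.set_index("id")["time"]
        merged = self.longitudinal["time"].to_numpy() > tobs.reindex(
            self.longitudinal["id"]
        ).to_numpy()
        if merged.any():
            bad = self.longitudinal[merged]
            raise CohortValidationError(
                f"{len(bad)} measurements fall after the observed follow-up time "
                "(dropout invariant violated)",
                bad,
            )

        if self.covariates is not None:
            if "id" not in self.covariates.columns:
                raise CohortValidationError("covariate table missing 'id' column")
            if set(self.covariates["id"]) != surv_ids:
                raise CohortValidationError("covariate ids do not match cohort ids")
            numeric = self.covariates.drop(columns="id")
            if numeric.isna().any().any():
                raise CohortValidationError("covariate table contains missing values")

    # ------------------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        """Individual ids in survival-table order (the canonical order)."""
        return self.survival["id"].to_numpy()

    @property
    def n_individuals(self) -> int:
        return len(self.survival)

    @property
    def n_events(self) -> int:
        return int(self.survival["status"].sum())

    def covariate_matrix(self, columns: Optional[Sequence[str]] = None) -> np.ndarray:
        """Baseline covariates as an (n, p) array in canonical id order."""
        if self.covariates is None:
            return np.empty((self.n_individuals, 0))
        tab = self.covariates.set_index("id").reindex(self.ids)
        if columns is not None:
            tab = tab[list(columns)]
        return tab.to_numpy(dtype=float)

    def dosage_vector(self, variant: str) -> np.ndarray:
        """Dosages for one variant aligned to canonical id order."""
        if self.genotypes is None:
            raise ValueError("cohort carries no genotypes")
        return self.genotypes.dosages_for(variant, self.ids)


# ----------------------------------------------------------------------
def _read_table(path, required, label) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{label} table {path} missing columns {missing}")
    for col in required[1:]:
        if not np.issubdtype(df[col].dtype, np.number):
            raise CohortValidationError(f"{label} column {col!r} is not numeric")
    return df


def read_cohort(
    longitudinal_path,
    survival_path,
    covariate_path=None,
) -> CohortData:
    """Read and validate a cohort from delimited files.

    Files may be CSV or TSV (by extension) and must carry headers
    ``id,time,value`` / ``id,time,status`` / ``id,<covariates...>``.
    """
    long_df = _read_table(longitudinal_path, LONGITUDINAL_COLUMNS, "longitudinal")
    surv_df = _read_table(survival_path, SURVIVAL_COLUMNS, "survival")
    cov_df = None
    if covariate_path is not None:
        cov_df = pd.read_csv(
            covariate_path, sep="\t" if str(covariate_path).endswith((".tsv", ".txt")) else ","
        )
        if "id" not in cov_df.columns:
            raise CohortValidationError("covariate table missing 'id' column")
    return CohortData(long_df, surv_df, covariates=cov_df)


def write_cohort(cohort: CohortData, directory, prefix: str = "cohort") -> dict:
    """Write the cohort tables as TSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["longitudinal"] = directory / f"{prefix}_longitudinal.tsv"
    cohort.longitudinal.to_csv(paths["longitudinal"], sep="\t", index=False)
    paths["survival"] = directory / f"{prefix}_survival.tsv"
    cohort.survival.to_csv(paths["survival"], sep="\t", index=False)
    if cohort.covariates is not None:
        paths["covariates"] = directory / f"{prefix}_covariates.tsv"
        cohort.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    return paths
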