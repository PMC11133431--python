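"""Obesity-map construction: per-parcel BMI regressions over a cohort.

An obesity map is the parcel-wise t-statistic of the BMI coefficient
from an ordinary least-squares regression of cortical thickness on BMI
plus covariates (age, sex, imaging site, education, socioeconomic
status, optionally scan date), fitted independently per parcel with one
shared covariate roster.  Subjects with implausible BMI (outside
[10, 50] kg/m^2) are excluded first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .correspondence import bh_fdr
from .parcellation import ParcelMap, SphericalParcellation

logger = logging.getLogger(__name__)

BMI_MIN, BMI_MAX = 10.0, 50.0  # kg/m^2 cohort inclusion bounds

#: covariates treated as categorical (indicator-coded) by default
CATEGORICAL_COVARIATES = ("sex", "site")


@dataclass
class SubjectTable:
    """Per-subject BMI, covariates, and per-parcel thickness (mm).

    ``data`` must contain ``subject_id`` and ``bmi`` columns plus one
    thickness column named exactly by each parcel_id of
    ``parcellation``.  ``bmi_units`` is ``"kg/m2"`` for raw BMI or
    ``"standardized"`` for a precomputed standard-deviation score (the
    inclusion filter only applies to raw BMI).
    """

    data: pd.DataFrame
    parcellation: SphericalParcellation
    bmi_units: str = "kg/m2"

    def __post_init__(self):
        for col in ("subject_id", "bmi"):
            if col not in self.data.columns:
                raise ValueError(f"subject table missing column {col!r}")
        missing = [p for p in self.parcellation.parcel_ids
                   if p not in self.data.columns]
        if missing:
            raise ValueError(f"missing thickness columns for parcels: {missing[:5]}")
        thick = self.data[list(self.parcellation.parcel_ids)]
        if thick.isna().any().any():
            raise ValueError("missing thickness values among subjects")
        if self.bmi_units not in ("kg/m2", "standardized"):
            raise ValueError(f"unknown bmi_units {self.bmi_units!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def thickness(self, parcel_id: str) -> np.ndarray:
        return self.data[parcel_id].to_numpy(dtype=float)


@dataclass
class ObesityMapResult:
    """Per-parcel BMI-association statistics plus the fitted t-map."""

    tmap: ParcelMap
    beta: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_subjects: int
    covariates: tuple = ()
    failed_parcels: dict = field(default_factory=dict)


def apply_inclusion_filters(subjects: SubjectTable) -> SubjectTable:
    """Remove subjects with BMI outside [10, 50] kg/m^2.

    Skipped (with a logged notice) when the BMI column holds
    standardized scores rather than raw kg/m^2.
    """
    if subjects.bmi_units != "kg/m2":
        logger.info("BMI column is standardized; inclusion filter skipped")
        return subjects
    bmi = subjects.data["bmi"].to_numpy(dtype=float)
    keep = (bmi >= BMI_MIN) & (bmi <= BMI_MAX)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("inclusion filter removed %d of %d subjects "
                    "(BMI outside [%g, %g])", n_removed, len(bmi),
                    BMI_MIN, BMI_MAX)
    if not keep.any():
        raise ValueError("inclusion filter removed every subject (empty cohort)")
    if n_removed == 0:
        return subjects
    return SubjectTable(subjects.data.loc[keep].reset_index(drop=True),
                        subjects.parcellation, subjects.bmi_units)


def _design_matrix(subjects: SubjectTable, covariates) -> pd.DataFrame:
    """Intercept + BMI + covariate columns, categoricals indicator-coded.

    Single-level categorical covariates are dropped with a logged
    notice (they are collinear with the intercept).
    """
    df = subjects.data
    cols = {"const": np.ones(len(df)), "bmi": df["bmi"].to_numpy(dtype=float)}
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in subject table")
        series = df[cov]
        if cov in CATEGORICAL_COVARIATES or series.dtype == object:
            levels = series.unique()
            if len(levels) < 2:
                logger.info("covariate %r has a single level; dropped", cov)
                continue
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
        else:
            cols[cov] = series.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns from the R diagonal of a pivoted QR
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def fit_parcel_regression(subjects: SubjectTable, parcel_id: str,
                          covariates=()):
    """OLS of one parcel's thickness on BMI + covariates.

    Returns ``(beta, t, p)`` for the BMI term: beta in mm per BMI unit,
    t = beta / SE, p two-sided from the t distribution with
    n - n_model_terms degrees of freedom.
    """
    X = _design_matrix(subjects, covariates)
    if subjects.n_subjects <= X.shape[1]:
        raise ValueError(
            f"need more than {X.shape[1]} subjects for {X.shape[1]} model terms")
    _check_rank(X)
    y = subjects.thickness(parcel_id)
    fit = sm.OLS(y, X).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.var(y)) * len(y)):
        raise ValueError(f"zero residual variance at parcel {parcel_id!r}")
    return (float(fit.params["bmi"]), float(fit.tvalues["bmi"]),
            float(fit.pvalues["bmi"]))


def build_obesity_map(subjects: SubjectTable, covariates=()) -> ObesityMapResult:
    """Fit every parcel and assemble the t-map with BH-adjusted q-values.

    A parcel whose fit fails is masked (with the error recorded) rather
    than aborting the whole map; BH runs across the parcels that fitted.
    """
    parc = subjects.parcellation
    n = parc.n_parcels
    beta = np.full(n, np.nan)
    t = np.full(n, np.nan)
    p = np.full(n, np.nan)
    failed = {}
    for i, pid in enumerate(parc.parcel_ids):
        try:
            beta[i], t[i], p[i] = fit_parcel_regression(subjects, pid, covariates)
        except ValueError as exc:
            failed[pid] = str(exc)
            logger.warning("parcel %s masked: %s", pid, exc)
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("every parcel failed to fit")
    q = np.full(n, np.nan)
    q[ok] = bh_fdr(p[ok])
    tmap = ParcelMap(parc, t, missing=~ok, name="obesity_tmap")
    return ObesityMapResult(tmap=tmap, beta=beta, p=p, q=q,
                            n_subjects=subjects.n_subjects,
                            covariates=tuple(covariates),
                            failed_parcels=failed)


def read_subject_table(path, parcellation: SphericalParcellation,
                       bmi_units: str = "kg/m2") -> SubjectTable:
    """Read a subject CSV (header row, ``subject_id`` and ``bmi`` required)."""
    return SubjectTable(pd.read_csv(path), parcellation, bmi_units)
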