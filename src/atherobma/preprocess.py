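"""Turn a raw cohort into a regression-ready problem.

The modelling convention throughout the package: every dependent and
independent variable of the diet-treated (HF, HHF) cases is divided by the
mean of the standard-diet control (CNTL) cases and natural-log transformed,
so a value equal to the control average maps to 0 and all variables live on
a common dimensionless log scale.  Plasma analytes keep their two
timepoints (baseline BAS and end-of-diet END) as distinct candidate
predictors; artery-secretome abundances are first rescaled to a common
per-case total protein content.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four per-case histomorphometric outcome indexes.
OUTCOME_INDEXES = ("IT_mean", "IT_median", "LA_mean", "LA_median")

#: Triglyceride level (mg/dL) above which the Friedewald approximation is
#: considered unreliable.
FRIEDEWALD_TG_LIMIT = 400.0

TREATED_GROUPS = ("HF", "HHF")


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Friedewald estimate of LDL cholesterol: ``tc - hdl - tg/5``.

    All inputs are mass concentrations (mg/dL convention).  A negative
    result is flagged invalid and returned as missing (NaN) with a warning;
    triglycerides above :data:`FRIEDEWALD_TG_LIMIT` also warn because the
    one-fifth VLDL approximation breaks down there.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("Friedewald inputs must be non-negative concentrations")
    if tg > FRIEDEWALD_TG_LIMIT:
        warnings.warn(
            f"triglycerides {tg:g} mg/dL exceed the Friedewald validity "
            f"range (> {FRIEDEWALD_TG_LIMIT:g} mg/dL)",
            stacklevel=2,
        )
    ldl = tc - hdl - tg / 5.0
    if ldl < 0:
        warnings.warn(
            f"Friedewald LDL is negative ({ldl:g} mg/dL); returning missing",
            stacklevel=2,
        )
        return float("nan")
    return float(ldl)


def normalize_total_protein(matrix: pd.DataFrame) -> pd.DataFrame:
    """Global total-protein normalization of a case x protein matrix.

    Each case's row is rescaled so that every row total equals the grand
    mean of the original row totals; within-case relative proportions are
    preserved.  Rows index cases, columns index proteins.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("protein abundances must be non-negative")
    totals = values.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"zero total protein content for case(s): "
            f"{', '.join(str(matrix.index[i]) for i in bad)}"
        )
    scale = totals.mean() / totals
    return pd.DataFrame(
        values * scale[:, None], index=matrix.index, columns=matrix.columns
    )


@dataclass(frozen=True)
class CaseIndexSet:
    """The four per-case outcome indexes pooled over all arteries."""

    case_id: str
    it_mean: float
    it_median: float
    la_mean: float
    la_median: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "IT_mean": self.it_mean,
                "IT_median": self.it_median,
                "LA_mean": self.la_mean,
                "LA_median": self.la_median,
            },
            name=self.case_id,
        )


def aggregate_histology(records: Iterable, case_id: str) -> CaseIndexSet:
    """Pool all lesion cross-sections of one case into mean/median IT and LA.

    Segments from every artery of the case are pooled before aggregation;
    the even-count median is the midpoint of the two central order
    statistics (numpy convention).
    """
    it = [r.it_mm for r in records if r.case_id == case_id]
    la = [r.la_mm2 for r in records if r.case_id == case_id]
    if not it:
        raise ValueError(f"no histology records for case {case_id!r}")
    return CaseIndexSet(
        case_id=case_id,
        it_mean=float(np.mean(it)),
        it_median=float(np.median(it)),
        la_mean=float(np.mean(la)),
        la_median=float(np.median(la)),
    )


def floor_nonpositive(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace non-positive entries by half the column's smallest positive value.

    Keeps the downstream log transform finite while preserving ranks.  A
    column with no positive entry at all cannot be floored and raises.
    """
    out = matrix.copy()
    for col in out.columns:
        vals = out[col].to_numpy(dtype=float)
        nonpos = vals <= 0
        if not nonpos.any():
            continue
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError(f"variable {col!r} has no positive values to floor against")
        floor = positive.min() / 2.0
        logger.warning(
            "floored %d non-positive value(s) of %r at %g", nonpos.sum(), col, floor
        )
        vals[nonpos] = floor
        out[col] = vals
    return out


def control_normalize_log(
    values: pd.DataFrame, control_means: pd.Series
) -> pd.DataFrame:
    """ln(value / control mean), per variable.

    ``control_means`` must be strictly positive; a treated value equal to
    the control mean maps to exactly 0.
    """
    for name, m in control_means.items():
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"non-positive control mean for variable {name!r}")
    aligned = control_means.reindex(values.columns)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()])
        raise ValueError(f"missing control means for: {missing}")
    vals = values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError(
            "non-positive values reached the log transform; apply "
            "floor_nonpositive first"
        )
    return pd.DataFrame(
        np.log(vals / aligned.to_numpy(dtype=float)[None, :]),
        index=values.index,
        columns=values.columns,
    )


@dataclass
class ProcessedDataset:
    """Control-normalized, log-scale outcomes and candidate predictors.

    Rows cover exactly the treated (HF, HHF) cases; CNTL cases enter only
    through the normalizing means.  ``catalog`` records each variable's
    provenance (circulatory vs secreted) and timepoint tag.
    """

    outcomes: pd.DataFrame  # case x 4 outcome indexes
    predictors: pd.DataFrame  # case x candidate variable
    catalog: pd.DataFrame  # variable, provenance, timepoint
    groups: pd.Series  # case_id -> group (treated cases only)

    def __post_init__(self) -> None:
        if list(self.outcomes.index) != list(self.predictors.index):
            raise ValueError("outcome and predictor tables must share case rows")
        if not np.isfinite(self.outcomes.to_numpy()).all():
            raise ValueError("non-finite outcome values")
        if not np.isfinite(self.predictors.to_numpy()).all():
            raise ValueError("non-finite predictor values")


@dataclass
class RegressionProblem:
    """One outcome vector and its candidate predictor matrix."""

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    case_ids: list[str]
    outcome: str
    group_filter: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y and X disagree on the number of cases")
        if self.X.shape[1] != len(self.names):
            raise ValueError("X and names disagree on the number of variables")

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def p(self) -> int:
        return int(self.X.shape[1])


def _plasma_wide(plasma: pd.DataFrame) -> pd.DataFrame:
    wide = plasma.pivot_table(
        index="case_id", columns=["analyte", "timepoint"], values="value"
    )
    wide.columns = [f"{a}_{t}" for a, t in wide.columns]
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"incomplete plasma panel for variables: {missing}")
    return wide


def _ensure_ldl(wide: pd.DataFrame) -> pd.DataFrame:
    """Add Friedewald LDL columns when the panel lacks measured/derived LDL."""
    for tp in ("BAS", "END"):
        col = f"LDL_{tp}"
        if col in wide.columns:
            continue
        needed = [f"CHOL_{tp}", f"HDL_{tp}", f"TG_{tp}"]
        if not all(c in wide.columns for c in needed):
            raise ValueError(f"cannot derive {col}: panel lacks {needed}")
        ldl = [
            friedewald_ldl(tc, hdl, tg)
            for tc, hdl, tg in wide[needed].itertuples(index=False)
        ]
        if any(np.isnan(v) for v in ldl):
            bad = [c for c, v in zip(wide.index, ldl) if np.isnan(v)]
            raise ValueError(f"invalid (negative) Friedewald LDL for case(s) {bad}")
        wide[col] = ldl
    return wide


def preprocess_cohort(
    cohort,
    exclude_analytes: Sequence[str] = ("TG",),
    normalize_proteins: bool = True,
) -> ProcessedDataset:
    """Full preprocessing: derived lipids, protein normalization, histology
    aggregation, control-normalized log transform.

    ``exclude_analytes`` removes plasma analytes from the candidate set
    (default excludes triglycerides, which enter only through the
    Friedewald LDL derivation).
    """
    cases = cohort.cases.set_index("case_id")["group"]
    cntl_ids = cases.index[cases == "CNTL"].tolist()
    treated_ids = cases.index[cases.isin(TREATED_GROUPS)].tolist()
    if not cntl_ids:
        raise ValueError("no CNTL cases: control normalization is undefined")
    if not treated_ids:
        raise ValueError("no treated (HF/HHF) cases to model")

    # --- plasma panel -----------------------------------------------------
    wide = _ensure_ldl(_plasma_wide(cohort.plasma))
    drop = [
        c for c in wide.columns if any(c.startswith(f"{a}_") for a in exclude_analytes)
    ]
    if drop:
        logger.info("excluding plasma variables from candidates: %s", drop)
    wide = wide.drop(columns=drop)

    # --- secretome matrix -------------------------------------------------
    proteins = cohort.proteins.astype(float)
    if normalize_proteins:
        proteins = normalize_total_protein(proteins)
    proteins = floor_nonpositive(proteins)

    # --- histology outcome indexes ---------------------------------------
    index_rows = [
        aggregate_histology(cohort.histology, cid).as_series()
        for cid in cases.index
        if any(r.case_id == cid for r in cohort.histology)
    ]
    outcomes_raw = pd.DataFrame(index_rows)
    missing_hist = [cid for cid in cases.index if cid not in outcomes_raw.index]
    if missing_hist:
        raise ValueError(f"cases without histology records: {missing_hist}")

    # --- control-normalized log scale ------------------------------------
    # Control means are taken per variable; plasma variables are per
    # timepoint by construction (BAS columns normalized by CNTL BAS means).
    predictors_raw = wide.join(proteins, how="inner")
    control_means = predictors_raw.loc[cntl_ids].mean(axis=0)
    outcome_control_means = outcomes_raw.loc[cntl_ids].mean(axis=0)

    predictors = control_normalize_log(
        predictors_raw.loc[treated_ids], control_means
    )
    outcomes = control_normalize_log(
        outcomes_raw.loc[treated_ids, list(OUTCOME_INDEXES)], outcome_control_means
    )

    outcomes.index.name = "case_id"
    predictors.index.name = "case_id"

    catalog_rows = []
    for col in wide.columns:
        analyte, tp = col.rsplit("_", 1)
        catalog_rows.append({"variable": col, "provenance": "circulatory", "timepoint": tp})
    for col in proteins.columns:
        catalog_rows.append({"variable": col, "provenance": "secreted", "timepoint": "n/a"})
    catalog = pd.DataFrame(catalog_rows)

    return ProcessedDataset(
        outcomes=outcomes,
        predictors=predictors[catalog["variable"].tolist()],
        catalog=catalog,
        groups=cases.loc[treated_ids],
    )


def build_problem(
    dataset: ProcessedDataset,
    outcome: str = "IT_mean",
    group_filter: str = "pooled",
) -> RegressionProblem:
    """Restrict a processed dataset to one outcome index and one case group.

    Zero-variance predictor columns (constant across the filtered cases)
    are dropped with a logged warning; fewer than 3 cases is refused
    because the subset regressions downstream need n - 2 residual degrees
    of freedom.
    """
    if outcome not in OUTCOME_INDEXES:
        raise ValueError(f"unknown outcome index {outcome!r}; expected one of {OUTCOME_INDEXES}")
    if group_filter == "pooled":
        case_ids = list(dataset.groups.index)
    elif group_filter in TREATED_GROUPS:
        case_ids = list(dataset.groups.index[dataset.groups == group_filter])
    else:
        raise ValueError(f"unknown group filter {group_filter!r}")
    if len(case_ids) < 3:
        raise ValueError(
            f"group filter {group_filter!r} leaves {len(case_ids)} case(s); "
            "at least 3 are required for subset regression"
        )
    X = dataset.predictors.loc[case_ids]
    variances = X.to_numpy().var(axis=0)
    keep = variances > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d zero-variance predictor(s) under filter %s: %s",
            len(dropped), group_filter, dropped,
        )
    X = X.loc[:, keep]
    y = dataset.outcomes.loc[case_ids, outcome]
    return RegressionProblem(
        y=y.to_numpy(),
        X=X.to_numpy(),
        names=list(X.columns),
        case_ids=case_ids,
        outcome=outcome,
        group_filter=group_filter,
    )


def write_processed_dataset(dataset: ProcessedDataset, directory) -> None:
    """Persist processed_dataset.csv plus the variables.csv catalog sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = pd.concat(
        [dataset.groups.rename("group"), dataset.outcomes, dataset.predictors], axis=1
    )
    table.index.name = "case_id"
    table.to_csv(directory / "processed_dataset.csv")
    dataset.catalog.to_csv(directory / "variables.csv", index=False)


def read_processed_dataset(directory) -> ProcessedDataset:
    directory = Path(directory)
    table = pd.read_csv(
        directory / "processed_dataset.csv", index_col="case_id",
        float_precision="round_trip",
    )
    catalog = pd.read_csv(directory / "variables.csv")
    return ProcessedDataset(
        outcomes=table[list(OUTCOME_INDEXES)],
        predictors=table[catalog["variable"].tolist()],
        catalog=catalog,
        groups=table["group"],
    )
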