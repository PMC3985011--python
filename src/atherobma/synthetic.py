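"""Seed-reproducible synthetic cohorts with the structure the pipeline assumes.

The generator emulates a high-cholesterol-diet swine atherogenesis study:
three diet groups (standard-diet controls CNTL, 8-week HF, 16-week HHF), a
plasma panel measured at baseline (BAS) and end of diet (END), an
artery-secretome protein abundance matrix, and per-segment coronary
histology (intimal thickness IT in mm, lesional area LA in mm^2).

Ground truth is a sparse linear model on the log-log scale: each treated
case's log lesion burden is an intercept plus planted signed effects times
the log of designated generated variables plus Gaussian noise, and the
per-case mean IT equals exp(burden) exactly.  Lesion profiles are either
``localized`` (mass concentrated in a third of the segments, median well
below mean) or ``diffuse`` (uniform spread, median close to mean),
reproducing the divergence between the two aggregation conventions seen in
mild focal versus advanced diffuse disease.

All distributions here are modelling stand-ins chosen for plausibility,
not estimates fitted to any real cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import friedewald_ldl

GROUPS = ("CNTL", "HF", "HHF")
TIMEPOINTS = ("BAS", "END")

#: Default plasma panel (8 analytes; LDL is derived via Friedewald).
PLASMA_ANALYTES = ("CHOL", "HDL", "TG", "LDL", "OXLDL", "IL6", "TNFA", "ICAM1")

#: Baseline (standard-diet) reference concentrations, mg/dL for lipids and
#: assay units for the immunologic analytes.
ANALYTE_BASELINES = {
    "CHOL": 80.0,
    "HDL": 40.0,
    "TG": 30.0,
    "OXLDL": 50.0,
    "IL6": 10.0,
    "TNFA": 15.0,
    "ICAM1": 200.0,
}

DEFAULT_DIET_FOLD_CHANGES = {
    "CHOL": 4.0,
    "HDL": 1.2,
    "TG": 1.5,
    "OXLDL": 3.0,
    "IL6": 1.8,
    "TNFA": 1.6,
    "ICAM1": 1.4,
}

DEFAULT_LESION_PATTERN = {"CNTL": "diffuse", "HF": "localized", "HHF": "diffuse"}

#: Typical log mean-IT (mm) per treated group: mild fatty streaks after 8
#: weeks, larger atheromas after 16.
DEFAULT_GROUP_BURDEN_INTERCEPT = {"HF": math.log(0.2), "HHF": math.log(0.45)}


def protein_names(n_proteins: int) -> list[str]:
    """Accession-style names for the synthetic secretome ("SYN0001", ...)."""
    return [f"SYN{i:04d}" for i in range(1, n_proteins + 1)]


@dataclass(frozen=True)
class HistologyRecord:
    """One lesion cross-section: maximal radial intimal expansion and area."""

    case_id: str
    artery: str
    segment: int
    it_mm: float
    la_mm2: float

    def __post_init__(self) -> None:
        if self.it_mm < 0 or self.la_mm2 < 0:
            raise ValueError("IT and LA must be non-negative")


@dataclass
class GeneratorConfig:
    """Study-shaped cohort description; defaults mirror the 3/4/6 design."""

    n_cntl: int = 3
    n_hf: int = 4
    n_hhf: int = 6
    n_proteins: int = 40
    analytes: Sequence[str] = PLASMA_ANALYTES
    true_effect_map: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    segments_per_case: int = 9
    lesion_pattern: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LESION_PATTERN)
    )
    diet_fold_changes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_FOLD_CHANGES)
    )
    abundance_logmean: float = 3.0
    abundance_logsd: float = 0.8
    baseline_intima_mm: float = 0.05
    group_burden_intercept: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_BURDEN_INTERCEPT)
    )
    plasma_logsd: float = 0.25
    end_diet_logsd: float = 0.15
    la_width_mm: float = 2.0
    la_width_logsd: float = 0.25
    seed: int = 0

    def variable_names(self) -> list[str]:
        names = [
            f"{a}_{tp}" for a in self.analytes for tp in TIMEPOINTS
        ]
        return names + protein_names(self.n_proteins)

    def validate(self) -> None:
        for name in ("n_cntl", "n_hf", "n_hhf", "n_proteins", "segments_per_case"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_intima_mm <= 0:
            raise ValueError(
                "baseline_intima_mm must be > 0 so control means are nonzero"
            )
        if self.segments_per_case < 3:
            raise ValueError("segments_per_case must be >= 3")
        known = set(self.variable_names())
        unknown = set(self.true_effect_map) - known
        if unknown:
            raise ValueError(f"true_effect_map names unknown variables: {sorted(unknown)}")
        for group in GROUPS:
            if self.lesion_pattern.get(group, "diffuse") not in ("localized", "diffuse"):
                raise ValueError(f"invalid lesion pattern for group {group}")


@dataclass
class RawCohort:
    """Full study-shaped dataset, one table per experimental layer."""

    cases: pd.DataFrame  # case_id, group
    plasma: pd.DataFrame  # case_id, timepoint, analyte, value
    proteins: pd.DataFrame  # index case_id, one column per protein
    histology: list[HistologyRecord]

    def histology_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "artery": r.artery,
                    "segment": r.segment,
                    "it_mm": r.it_mm,
                    "la_mm2": r.la_mm2,
                }
                for r in self.histology
            ],
            columns=["case_id", "artery", "segment", "it_mm", "la_mm2"],
        )


def _lesion_values(
    rng: np.random.Generator,
    log_burden: float,
    pattern: str,
    n_segments: int,
    la_width_mm: float,
    la_width_logsd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """IT/LA values across segments whose mean IT equals exp(log_burden)."""
    target_mean = math.exp(log_burden)
    if pattern == "localized":
        n_hot = math.ceil(n_segments / 3)
        weights = rng.uniform(0.1, 0.3, size=n_segments)
        hot = rng.choice(n_segments, size=n_hot, replace=False)
        weights[hot] = rng.uniform(0.8, 1.2, size=n_hot)
    elif pattern == "diffuse":
        weights = rng.uniform(0.6, 1.4, size=n_segments)
    else:
        raise ValueError(f"unknown lesion pattern {pattern!r}")
    it = weights * (target_mean * n_segments / weights.sum())
    width = la_width_mm * np.exp(rng.normal(0.0, la_width_logsd, size=n_segments))
    return it, it * width


def generate_lesion_profile(
    case_burden: float,
    pattern: str,
    n_segments: int,
    seed: int,
    case_id: str = "case",
    artery: str = "LAD",
    la_width_mm: float = 2.0,
    la_width_logsd: float = 0.25,
) -> list[HistologyRecord]:
    """Segment-level lesion profile for one artery of one case.

    ``localized`` concentrates lesion mass in at most a third of the
    segments (median well below mean); ``diffuse`` spreads it near
    uniformly (median close to mean).  The per-case mean IT equals
    ``exp(case_burden)`` exactly by construction.
    """
    if n_segments < 3:
        raise ValueError("n_segments must be >= 3")
    rng = np.random.default_rng(seed)
    it, la = _lesion_values(
        rng, case_burden, pattern, n_segments, la_width_mm, la_width_logsd
    )
    return [
        HistologyRecord(case_id=case_id, artery=artery, segment=i + 1,
                        it_mm=float(t), la_mm2=float(a))
        for i, (t, a) in enumerate(zip(it, la))
    ]


def generate_cohort(config: GeneratorConfig) -> RawCohort:
    """Draw one full cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    case_rows = []
    for group, count in (("CNTL", config.n_cntl), ("HF", config.n_hf),
                         ("HHF", config.n_hhf)):
        for i in range(1, count + 1):
            case_rows.append({"case_id": f"{group}_{i:02d}", "group": group})
    cases = pd.DataFrame(case_rows)
    case_ids = cases["case_id"].tolist()
    groups = dict(zip(cases["case_id"], cases["group"]))
    n_cases = len(case_ids)

    # --- plasma panel: lognormal around references, diet fold changes at END
    measured = [a for a in config.analytes if a != "LDL"]
    values: dict[str, np.ndarray] = {}
    chol_bas = ANALYTE_BASELINES["CHOL"] * np.exp(
        rng.normal(0.0, config.plasma_logsd, n_cases)
    )
    for analyte in measured:
        if analyte == "CHOL":
            bas = chol_bas
        elif analyte == "HDL":
            # HDL tracks total cholesterol at baseline so Friedewald stays positive
            bas = chol_bas * 0.5 * np.exp(rng.normal(0.0, 0.1, n_cases))
        else:
            bas = ANALYTE_BASELINES[analyte] * np.exp(
                rng.normal(0.0, config.plasma_logsd, n_cases)
            )
        fold = np.array(
            [
                config.diet_fold_changes.get(analyte, 1.0)
                if groups[cid] != "CNTL"
                else 1.0
                for cid in case_ids
            ]
        )
        end = bas * fold * np.exp(rng.normal(0.0, config.end_diet_logsd, n_cases))
        values[f"{analyte}_BAS"] = bas
        values[f"{analyte}_END"] = end

    if "LDL" in config.analytes:
        import warnings as _warnings

        for tp in TIMEPOINTS:
            with _warnings.catch_warnings():
                # the rare negative draw is clipped below, no need to warn
                _warnings.simplefilter("ignore", UserWarning)
                ldl = np.array(
                    [
                        friedewald_ldl(tc, hdl, tg)
                        for tc, hdl, tg in zip(
                            values[f"CHOL_{tp}"], values[f"HDL_{tp}"], values[f"TG_{tp}"]
                        )
                    ]
                )
            # honour the strictly-positive concentration invariant
            values[f"LDL_{tp}"] = np.where(np.isnan(ldl) | (ldl <= 0), 1.0, ldl)

    plasma = pd.DataFrame(
        [
            {"case_id": cid, "timepoint": tp, "analyte": a, "value": values[f"{a}_{tp}"][i]}
            for i, cid in enumerate(case_ids)
            for tp in TIMEPOINTS
            for a in config.analytes
        ]
    )

    # --- secretome abundances --------------------------------------------
    pnames = protein_names(config.n_proteins)
    abundances = np.exp(
        rng.normal(config.abundance_logmean, config.abundance_logsd,
                   size=(n_cases, config.n_proteins))
    )
    proteins = pd.DataFrame(abundances, index=pd.Index(case_ids, name="case_id"),
                            columns=pnames)
    for j, name in enumerate(pnames):
        values[name] = abundances[:, j]

    # --- true log lesion burden ------------------------------------------
    noise = rng.normal(0.0, config.noise_sd, n_cases) if config.noise_sd > 0 else np.zeros(n_cases)
    burden = np.empty(n_cases)
    for i, cid in enumerate(case_ids):
        group = groups[cid]
        if group == "CNTL":
            b = math.log(config.baseline_intima_mm)
        else:
            b = config.group_burden_intercept[group]
            for var, effect in config.true_effect_map.items():
                b += effect * math.log(values[var][i])
        burden[i] = b + noise[i]

    # --- histology: profile split over two arteries per case --------------
    histology: list[HistologyRecord] = []
    arteries = ("LAD", "RCA")
    for i, cid in enumerate(case_ids):
        pattern = config.lesion_pattern.get(groups[cid], "diffuse")
        it, la = _lesion_values(
            rng, burden[i], pattern, config.segments_per_case,
            config.la_width_mm, config.la_width_logsd,
        )
        split = math.ceil(config.segments_per_case / 2)
        for s in range(config.segments_per_case):
            artery = arteries[0] if s < split else arteries[1]
            segment = s + 1 if s < split else s - split + 1
            histology.append(
                HistologyRecord(case_id=cid, artery=artery, segment=segment,
                                it_mm=float(it[s]), la_mm2=float(la[s]))
            )

    return RawCohort(cases=cases, plasma=plasma, proteins=proteins,
                     histology=histology)


def write_cohort(cohort: RawCohort, directory) -> None:
    """Persist cases.csv, plasma.csv, proteins.csv, histology.csv (UTF-8)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        cohort.cases.to_csv(directory / "cases.csv", index=False)
        cohort.plasma.to_csv(directory / "plasma.csv", index=False)
        cohort.proteins.to_csv(directory / "proteins.csv")
        cohort.histology_frame().to_csv(directory / "histology.csv", index=False)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing cohort file under {directory}: {exc}") from exc


def read_cohort(directory) -> RawCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    cases = pd.read_csv(directory / "cases.csv")
    plasma = pd.read_csv(directory / "plasma.csv", float_precision="round_trip")
    proteins = pd.read_csv(
        directory / "proteins.csv", index_col="case_id", float_precision="round_trip"
    )
    hist = pd.read_csv(directory / "histology.csv", float_precision="round_trip")
    histology = [
        HistologyRecord(
            case_id=str(r.case_id), artery=str(r.artery), segment=int(r.segment),
            it_mm=float(r.it_mm), la_mm2=float(r.la_mm2),
        )
        for r in hist.itertuples(index=False)
    ]
    return RawCohort(cases=cases, plasma=plasma, proteins=proteins,
                     histology=histology)
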