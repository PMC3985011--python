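"""End-to-end orchestration: simulate/load -> preprocess -> per-index BMA ->
congruence ledger -> reports, with a manifest for re-run reproducibility."""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bma import BMAResult, BMASettings, run_all_indexes, write_bma_results
from .congruence import (
    CongruenceLedger,
    SelectionTable,
    apply_coefficient_congruence,
    apply_index_congruence,
    build_selection_table,
    render_report,
    summarize_ledger,
    write_ledger,
)
from .preprocess import preprocess_cohort, write_processed_dataset
from .synthetic import GeneratorConfig, RawCohort, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class CongruenceSettings:
    magnitude_floor: float = 0.001
    size_ratio_cap: float = 10.0
    strict_sign: bool = True


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    output_dir: str = "out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    group_filter: str = "pooled"
    per_group_runs: bool = False
    bma: BMASettings = field(default_factory=BMASettings)
    congruence: CongruenceSettings = field(default_factory=CongruenceSettings)
    exclude_analytes: tuple[str, ...] = ("TG",)

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of a generator block or an input directory must be given"
            )
        if not 0 < self.congruence.magnitude_floor < 1:
            raise ValueError("magnitude_floor must lie in (0, 1)")
        if self.congruence.size_ratio_cap < 1:
            raise ValueError("size_ratio_cap must be >= 1")
        if not 0 < self.bma.retention_threshold < 1:
            raise ValueError("retention_threshold must lie in (0, 1)")
        if self.bma.occam_ratio < 1:
            raise ValueError("occam_ratio must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        gen = raw.pop("generator", None)
        bma = raw.pop("bma", None)
        cong = raw.pop("congruence", None)
        cfg = cls(
            generator=GeneratorConfig(**gen) if gen is not None else None,
            bma=BMASettings(**bma) if bma else BMASettings(),
            congruence=CongruenceSettings(**cong) if cong else CongruenceSettings(),
            **{k: v for k, v in raw.items() if v is not None},
        )
        if cfg.generator is not None and "seed" not in (gen or {}):
            cfg.generator.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_analytes"] = list(self.exclude_analytes)
        if self.generator is not None:
            d["generator"]["analytes"] = list(self.generator.analytes)
            d["generator"]["true_effect_map"] = dict(self.generator.true_effect_map)
        return d


@dataclass
class PipelineResult:
    cohort: RawCohort
    dataset: object
    results: dict[str, BMAResult]
    table: SelectionTable
    ledger: CongruenceLedger
    output_dir: Path
    per_group: dict[str, dict[str, BMAResult]] = field(default_factory=dict)


def render_figure_data(
    results: Mapping[str, BMAResult], ledger: CongruenceLedger
) -> pd.DataFrame:
    """Long-format coefficient-vs-index table for the selected variables.

    One row per (index, variable) cell where the variable was selected for
    that index, carrying the averaged coefficient and whether the
    congruence ledger finally retained the variable.
    """
    retained = set(ledger.retained)
    rows = []
    for index, res in results.items():
        for v in res.retained:
            rows.append(
                {
                    "index": index,
                    "variable": v,
                    "coefficient": float(res.avg_coefficient[v]),
                    "retained": v in retained,
                }
            )
    return pd.DataFrame(rows, columns=["index", "variable", "coefficient", "retained"])


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    return wrap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all artifacts.

    Identical config + seed produce byte-identical artifacts, and every
    output is derivable from the manifest alone.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        cohort = _stage("simulate")(generate_cohort, config.generator)
        _stage("simulate")(write_cohort, cohort, outdir / "cohort")
    else:
        cohort = _stage("load")(read_cohort, config.input_dir)
    if not (cohort.cases["group"] == "CNTL").any():
        raise PipelineError("[load] cohort has no CNTL group; normalization undefined")

    dataset = _stage("preprocess")(
        preprocess_cohort, cohort, exclude_analytes=config.exclude_analytes
    )
    _stage("preprocess")(write_processed_dataset, dataset, outdir)

    results = _stage("select")(
        run_all_indexes, dataset, config.group_filter, config.bma
    )
    _stage("select")(write_bma_results, results, outdir)

    per_group: dict[str, dict[str, BMAResult]] = {}
    if config.per_group_runs:
        for group in ("HF", "HHF"):
            per_group[group] = _stage("select")(
                run_all_indexes, dataset, group, config.bma
            )
            _stage("select")(write_bma_results, per_group[group], outdir / f"group_{group}")

    table = _stage("congruence")(build_selection_table, results)
    ledger = _stage("congruence")(apply_index_congruence, table)
    ledger = _stage("congruence")(
        apply_coefficient_congruence,
        ledger,
        table,
        magnitude_floor=config.congruence.magnitude_floor,
        size_ratio_cap=config.congruence.size_ratio_cap,
        strict_sign=config.congruence.strict_sign,
    )
    _stage("congruence")(write_ledger, ledger, outdir)

    figure = _stage("report")(render_figure_data, results, ledger)
    figure.to_csv(outdir / "figure_data.csv", index=False)
    (outdir / "report.md").write_text(render_report(ledger, table))

    artifacts = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        if p.name != "manifest.yaml"
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return PipelineResult(
        cohort=cohort, dataset=dataset, results=results, table=table,
        ledger=ledger, output_dir=outdir, per_group=per_group,
    )
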