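"""Delimited-table I/O, run configuration, and the pipeline entry point.

Table dialect: comma-separated, UTF-8, period decimal separator, ``NA`` as
the explicit missing marker. A dataset serialises to four files —
``patients.csv``, ``visits.csv``, ``wpai.csv``, ``resource.csv`` — with the
column dictionary documented on :mod:`trialcea.datasets`. Loaders validate
the schema and report the offending file/row/column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cea import ScenarioSpec, WTPConfig
from .costing import StratifiedTable, UnitCostTable
from .datasets import (PATIENT_COLUMNS, RESOURCE_COLUMNS, VISIT_COLUMNS,
                       WPAI_COLUMNS, TrialDataset)
from .exceptions import LoadError, ValidationError

NA_MARKER = "NA"
TABLE_FILES = {
    "patients": "patients.csv",
    "visits": "visits.csv",
    "wpai": "wpai.csv",
    "resource": "resource.csv",
}


def write_trial_tables(dataset: TrialDataset, directory: str | Path) -> dict[str, Path]:
    """Serialise the dataset; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        getattr(dataset, name).to_csv(path, index=False, na_rep=NA_MARKER)
        paths[name] = path
    meta = {"assessment_weeks": list(dataset.assessment_weeks)}
    (directory / "dataset.yaml").write_text(yaml.safe_dump(meta))
    paths["meta"] = directory / "dataset.yaml"
    return paths


def _read_table(path: Path, name: str, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"required table file missing: {path} "
                        f"(expected files: {sorted(TABLE_FILES.values())})")
    df = pd.read_csv(path, na_values=[NA_MARKER], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing column(s) {missing}")
    return df


def load_trial_tables(directory: str | Path) -> TrialDataset:
    """Load and validate the four tables written by :func:`write_trial_tables`."""
    directory = Path(directory)
    patients = _read_table(directory / TABLE_FILES["patients"], "patients", PATIENT_COLUMNS)
    visits = _read_table(directory / TABLE_FILES["visits"], "visits", VISIT_COLUMNS)
    wpai = _read_table(directory / TABLE_FILES["wpai"], "wpai", WPAI_COLUMNS)
    resource = _read_table(directory / TABLE_FILES["resource"], "resource", RESOURCE_COLUMNS)

    for col in ("eq5d_utility", "sf6d_utility"):
        vals = visits[col]
        bad = vals.notna() & ((vals < -1) | (vals > 1))
        if bad.any():
            row = int(bad.idxmax())
            raise LoadError(
                f"visits.csv row {row}: {col} = {vals[row]} outside the utility "
                f"bounds [-1, 1]")
    emp = patients["employed"]
    if emp.dtype == object:
        mapped = emp.map({"True": True, "False": False, "true": True, "false": False})
        if mapped.isna().any():
            bad = emp[mapped.isna()].iloc[0]
            raise LoadError(f"patients.csv: employed must be True/False, got {bad!r}")
        patients["employed"] = mapped.astype(bool)
    else:
        patients["employed"] = emp.astype(bool)

    weeks = (0, 7, 13)
    meta_path = directory / "dataset.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        weeks = tuple(meta.get("assessment_weeks", weeks))
    try:
        return TrialDataset(patients, visits, wpai, resource, assessment_weeks=weeks)
    except ValidationError as exc:
        raise LoadError(f"tables in {directory} are inconsistent: {exc}") from exc


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    data_dir: str
    out_dir: str
    scenario: str = "main"
    seed: int = 0
    m: int = 20
    B: int = 500
    wtp_threshold: float = 26374.0
    unit_costs: str | None = None       # YAML path; defaults to base case
    benefit_table: str | None = None    # YAML path; defaults to toy fixture
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d)
        if not Path(cfg.data_dir).exists():
            raise LoadError(f"data_dir does not exist: {cfg.data_dir}")
        return cfg

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("data_dir", "out_dir", "scenario", "seed", "m", "B",
                 "wtp_threshold", "unit_costs", "benefit_table", "make_plots")}


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig):
    """Load tables, fit the configured scenario, write reports.

    Outputs in ``out_dir``: ``summary.csv`` and ``summary.txt`` (the
    Table-4-style incremental results), ``outcomes.json`` (machine-readable
    estimates, quadrants, CEAC), ``manifest.json`` (seed, config hash,
    package version), and CE-plane / CEAC plots per perspective × measure.
    Identical config + seed ⇒ identical outputs.
    """
    from . import __version__
    from .model import CostUtilityAnalysis

    dataset = load_trial_tables(config.data_dir)
    uc = UnitCostTable.from_yaml(config.unit_costs) if config.unit_costs else None
    bt = StratifiedTable.from_yaml(config.benefit_table) if config.benefit_table else None
    model = CostUtilityAnalysis(
        dataset, unit_costs=uc, benefit_table=bt,
        wtp=WTPConfig(threshold=config.wtp_threshold),
        scenario=ScenarioSpec.named(config.scenario))
    results = model.fit(m=config.m, B=config.B, seed=config.seed)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = results.summary_frame()
    df.to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")

    payload = {}
    for (persp, measure), o in results.outcomes.items():
        c_lo, c_hi = o.delta_cost.ci()
        q_lo, q_hi = o.delta_qaly.ci()
        payload[f"{persp}/{measure}"] = {
            "delta_cost": o.delta_cost.estimate,
            "delta_cost_ci": [c_lo, c_hi],
            "delta_qaly": o.delta_qaly.estimate,
            "delta_qaly_ci": [q_lo, q_hi],
            "icer": o.icer if isinstance(o.icer, str) else float(o.icer),
            "prob_ce_at_wtp": o.prob_at_threshold,
            "quadrants": o.quadrants,
            "ceac": {"wtp": list(map(float, o.ceac_grid)),
                     "probability": list(map(float, o.ceac_probs))},
        }
    (out / "outcomes.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    manifest = {
        "package": "trialcea",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "n_patients": dataset.n_patients,
        "cloud_size": next(iter(results.outcomes.values())).cloud.size,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for (persp, measure), o in results.outcomes.items():
            ax = results.plot_ce_plane(persp, measure)
            ax.figure.savefig(out / f"ce_plane_{persp}_{measure}.png", dpi=120)
            plt.close(ax.figure)
            ax = results.plot_ceac(persp, measure)
            ax.figure.savefig(out / f"ceac_{persp}_{measure}.png", dpi=120)
            plt.close(ax.figure)
    return results
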