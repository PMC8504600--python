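"""Experiment orchestration: dataset -> Makima -> training -> evaluation.

`run_experiment` reproduces the full study design: simulate the measurement
campaign (7 field sizes x 3 depths x 2 planes), upsample every measurement
with Makima, train plane-specific and/or combined networks on the
{2, 4, 6, 10} cm^2 fields, reconstruct all geometries, and score every
reconstruction against its ground truth with PWD, 1-D gamma (1%/1 mm) and
MSE.  The {3, 5, 8} cm^2 fields are never seen in training and act as the
test fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ann import ANNFitResults, DataPairSet, TrainingConfig, extract_pairs, train_lm
from .interp import makima_resample
from .metrics import gamma_1d, mse, penumbra, pwd
from .simulate import (
    DatasetRecord,
    Profile,
    SimulationConfig,
    generate_dataset,
    normalize_plane,
)

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "run_experiment",
    "compare_models",
    "read_profile",
    "write_profile",
    "truth_on_grid",
]

log = logging.getLogger("profile_restore")

# re-exported here because the experiment layer owns the file dialect
read_profile = pio.read_profile
write_profile = pio.write_profile

TRAIN_FIELDS_CM = (2.0, 4.0, 6.0, 10.0)
TEST_FIELDS_CM = (3.0, 5.0, 8.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun the experiment deterministically."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    grid_step_mm: float = 0.5
    window_mm: float = 15.0
    n_hidden: int = 18
    train_fields_cm: tuple[float, ...] = TRAIN_FIELDS_CM
    test_fields_cm: tuple[float, ...] = TEST_FIELDS_CM
    planes_to_train: tuple[str, ...] = ("in", "cross", "combined")
    sweep: bool = False
    out_dir: str | None = None

    def __post_init__(self):
        overlap = set(self.train_fields_cm) & set(self.test_fields_cm)
        if overlap:
            raise ValueError(f"train and test field sets overlap: {sorted(overlap)}")
        available = set(self.simulation.field_sizes_cm)
        missing = (set(self.train_fields_cm) | set(self.test_fields_cm)) - available
        if missing:
            raise ValueError(f"fields {sorted(missing)} not present in the simulated dataset")
        for p in self.planes_to_train:
            if p != "combined":
                normalize_plane(p)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in doc.get("simulation", {}).items()
        })
        tr_kwargs = doc.get("training", {})
        if "split" in tr_kwargs:
            tr_kwargs["split"] = tuple(tr_kwargs["split"])
        if "sweep_range" in tr_kwargs:
            tr_kwargs["sweep_range"] = tuple(tr_kwargs["sweep_range"])
        training = TrainingConfig(**tr_kwargs)
        exp = doc.get("experiment", {})
        for key in ("train_fields_cm", "test_fields_cm", "planes_to_train"):
            if key in exp:
                exp[key] = tuple(exp[key])
        return cls(simulation=sim, training=training, **exp)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "simulation": {
                    "fields": self.simulation.field_sizes_cm,
                    "depths": self.simulation.depths_cm,
                    "planes": self.simulation.planes,
                    "aperture_mm": self.simulation.aperture_mm,
                    "noise_sd": self.simulation.noise_sd,
                    "seed": self.simulation.seed,
                    "replicates": self.simulation.replicates,
                },
                "training": {
                    "epochs": self.training.epochs,
                    "restarts": self.training.restarts,
                    "seed": self.training.seed,
                    "split": self.training.split,
                },
                "grid_step_mm": self.grid_step_mm,
                "window_mm": self.window_mm,
                "n_hidden": self.n_hidden,
                "train_fields_cm": self.train_fields_cm,
                "planes_to_train": self.planes_to_train,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def truth_on_grid(record: DatasetRecord, grid_step_mm: float = 0.5, span_mm: float = 160.0) -> Profile:
    """Ground truth decimated from the fine simulation grid onto the
    reconstruction grid (the fine grid contains the coarse one exactly)."""
    t = record.truth
    step = t.grid_step_mm
    stride = int(round(grid_step_mm / step))
    if abs(stride * step - grid_step_mm) > 1e-9:
        raise ValueError("reconstruction grid step must be a multiple of the fine grid step")
    sel = (t.positions_mm >= -span_mm - 1e-9) & (t.positions_mm <= span_mm + 1e-9)
    pos = t.positions_mm[sel][::stride]
    val = t.values[sel][::stride]
    return Profile(pos, val, geometry=t.geometry)


@dataclass
class EvaluationReport:
    """Per-geometry metric rows plus per-depth aggregates."""

    rows: pd.DataFrame
    models: dict[str, ANNFitResults]
    config: ExperimentConfig

    @property
    def aggregates(self) -> pd.DataFrame:
        """Mean +/- SD of signed PWD per (plane, depth), per model family."""
        value_cols = [c for c in self.rows.columns if c.startswith("pwd_")]
        agg = self.rows.groupby(["plane", "depth_cm"])[value_cols].agg(["mean", "std", lambda v: np.mean(np.abs(v))])
        agg.columns = [
            f"{col}_{('mean_abs' if name == '<lambda_0>' else name)}" for col, name in agg.columns
        ]
        return agg.reset_index()

    def summary(self) -> str:
        pd.set_option("display.width", 120)
        lines = ["Experiment evaluation (PWD in mm, gamma pass rate in %)", "=" * 56]
        agg = self.aggregates
        lines.append(agg.to_string(index=False, float_format=lambda v: f"{v:6.2f}"))
        return "\n".join(lines)


def _pair_sets(
    records: list[DatasetRecord], config: ExperimentConfig
) -> tuple[dict[str, DataPairSet], dict]:
    baselines = {}
    sets: dict[str, list] = {"in": [], "cross": []}
    for rec in records:
        base = makima_resample(rec.measurement, config.grid_step_mm)
        tg = truth_on_grid(rec, config.grid_step_mm)
        baselines[id(rec)] = (base, tg)
        if rec.geometry.field_size_cm in config.train_fields_cm and rec.replicate == 0:
            sets[rec.geometry.plane].append(extract_pairs(base, tg, config.window_mm))
    out: dict[str, DataPairSet] = {}
    for plane in ("in", "cross"):
        if sets[plane]:
            out[plane] = DataPairSet.concat(sets[plane])
    if len(out) == 2:
        out["combined"] = DataPairSet.concat([out["in"], out["cross"]])
    return out, baselines


def run_experiment(config: ExperimentConfig | None = None) -> EvaluationReport:
    """Run the full workflow; returns the report (and writes artifacts if
    ``config.out_dir`` is set).  Deterministic given the config seeds."""
    config = config or ExperimentConfig()
    log.info("simulating dataset (seed=%d)", config.simulation.seed)
    records = generate_dataset(config.simulation)
    log.info("dataset: %d measurement/truth pairs", len(records))
    pair_sets, baselines = _pair_sets(records, config)

    models: dict[str, ANNFitResults] = {}
    for name in config.planes_to_train:
        if name not in pair_sets:
            raise ValueError(f"no training pairs available for model family {name!r}")
        pairs = pair_sets[name]
        log.info("training %s model: %d pairs, N_hn=%d", name, len(pairs), config.n_hidden)
        if config.sweep:
            from .ann import SlidingWindowANN

            sweep = SlidingWindowANN(pairs, config.n_hidden, config.training).fit_sweep()
            models[name] = sweep.selected
            log.info("sweep for %s:\n%s", name, sweep.summary())
        else:
            models[name] = train_lm(pairs, config.n_hidden, config.training)
        log.info("%s model: %s", name, models[name].summary().replace("\n", " | "))

    rows = []
    for rec in records:
        base, tg = baselines[id(rec)]
        base_pwd = pwd(penumbra(base), penumbra(tg))
        row = {
            "plane": rec.geometry.plane,
            "field_cm": rec.geometry.field_size_cm,
            "depth_cm": rec.geometry.depth_cm,
            "replicate": rec.replicate,
            "role": "train" if rec.geometry.field_size_cm in config.train_fields_cm else "test",
            "pwd_makima": base_pwd,
            "gamma_makima": gamma_1d(base, rec.truth).pass_rate,
        }
        for name, res in models.items():
            if name not in ("combined", rec.geometry.plane):
                continue
            recon = res.reconstruct(base)
            row[f"pwd_{name}"] = pwd(penumbra(recon), penumbra(tg))
            row[f"gamma_{name}"] = gamma_1d(recon, rec.truth).pass_rate
            row[f"mse_{name}"] = mse(recon.values, tg.values)
        rows.append(row)
    report = EvaluationReport(pd.DataFrame(rows), models, config)
    if config.out_dir:
        _write_artifacts(report, records, baselines)
    return report


def _write_artifacts(report: EvaluationReport, records, baselines) -> None:
    out = Path(report.config.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "profiles").mkdir(exist_ok=True)
    report.rows.to_csv(out / "metrics.csv", index=False)
    report.aggregates.to_csv(out / "aggregates.csv", index=False)
    manifest_rows = []
    for rec in records:
        tag = f"{rec.geometry.plane}_f{rec.geometry.field_size_cm:g}_d{rec.geometry.depth_cm:g}_r{rec.replicate}"
        write_profile(rec.measurement, out / "profiles" / f"meas_{tag}.csv")
        write_profile(rec.truth, out / "profiles" / f"truth_{tag}.csv")
        manifest_rows.append(
            {
                "plane": rec.geometry.plane,
                "field_cm": rec.geometry.field_size_cm,
                "depth_cm": rec.geometry.depth_cm,
                "replicate": rec.replicate,
                "seed": rec.seed,
                "measurement": f"profiles/meas_{tag}.csv",
                "truth": f"profiles/truth_{tag}.csv",
            }
        )
    for name, res in report.models.items():
        res.save(out / "models" / f"ann_{name}.json")
    manifest = {
        "config_hash": report.config.config_hash(),
        "n_records": len(records),
        "files": manifest_rows,
        "models": sorted(report.models),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def compare_models(report: EvaluationReport) -> pd.DataFrame:
    """Plane-specific vs combined reconstruction, per (plane, depth).

    Reports the mean and max difference of |PWD| (combined minus
    plane-specific); values near zero mean a single network serves both axes.
    """
    rows = report.rows
    needed = {"pwd_combined"}
    if not needed <= set(rows.columns) or not ({"pwd_in", "pwd_cross"} & set(rows.columns)):
        raise ValueError("report must contain both plane-specific and combined model columns")
    specific = rows.apply(
        lambda r: r["pwd_in"] if r["plane"] == "in" else r["pwd_cross"], axis=1
    )
    diff = rows["pwd_combined"].abs() - specific.abs()
    out = (
        rows.assign(abs_pwd_diff=diff)
        .groupby(["plane", "depth_cm"])["abs_pwd_diff"]
        .agg(["mean", "max"])
        .reset_index()
        .rename(columns={"mean": "mean_abs_pwd_diff", "max": "max_abs_pwd_diff"})
    )
    return out
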