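"""Reproducible end-to-end experiments.

``run_experiment`` executes generate -> oracle -> featurize -> train ->
evaluate from a single validated configuration, stamps every artifact with
the configuration hash and seed, and is bit-reproducible for identical
configurations.  All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .errors import DataError, ParameterError
from .evaluation import EvalReport, evaluate_predictions
from .features1d import build_case_1d, stack_cases
from .features3d import build_case_3d, planes_to_centerline
from .geometry import CohortRanges, classify_arch, sample_cohort
from .io import list_cases, load_case, save_case, write_dataset_1d
from .models import BRNNRegressor, UNet3DRegressor
from .oracle import OracleConfig, solve_case


class CohortSpec(BaseModel):
    n_cases: int = Field(gt=0)
    gothic_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    ranges: dict = Field(default_factory=dict)


class ModelSpec(BaseModel):
    arch: str = Field(default="brnn1d", pattern="^(brnn1d|cnn3d)$")
    params: dict = Field(default_factory=dict)


class EvalSpec(BaseModel):
    threshold_mmhg: float = 20.0
    stenosis_window: int = 10


class ExperimentConfig(BaseModel):
    """Fully serializable experiment description."""

    seed: int = 0
    cohort: CohortSpec
    mode: str = Field(default="1d", pattern="^(1d|3d)$")
    model: ModelSpec = Field(default_factory=ModelSpec)
    test_fraction: float = Field(default=0.15, gt=0.0, lt=0.5)
    evaluation: EvalSpec = Field(default_factory=EvalSpec)
    out_dir: str = "experiment_out"

    def config_hash(self) -> str:
        # out_dir is a deployment detail: the same experiment written to
        # two locations must hash (and reproduce) identically
        payload = self.model_dump()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        try:
            return cls.model_validate(yaml.safe_load(Path(path).read_text()))
        except ValidationError as exc:
            raise ParameterError(f"invalid experiment config: {exc}") from exc


def _solve_cohort(config: ExperimentConfig):
    ranges = CohortRanges(**config.cohort.ranges) if config.cohort.ranges else None
    cohort = sample_cohort(
        config.cohort.n_cases,
        ranges=ranges,
        seed=config.seed,
        gothic_fraction=config.cohort.gothic_fraction,
    )
    oracle_cfg = OracleConfig()
    return [(g, bc, solve_case(g, bc, config=oracle_cfg)) for g, bc in cohort]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns the manifest of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    rng = np.random.default_rng(config.seed)

    solved = _solve_cohort(config)
    case_ids = [g.case_id for g, _, _ in solved]
    labels = {g.case_id: classify_arch(g) for g, _, _ in solved}

    n = len(solved)
    n_test = max(1, int(round(config.test_fraction * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "mode": config.mode,
        "case_ids": case_ids,
        "arch_labels": labels,
        "test_case_ids": [case_ids[i] for i in test_idx],
        "artifacts": {},
    }

    if config.mode == "1d":
        cases = [build_case_1d(g, bc, prof) for g, bc, prof in solved]
        X, Y, lengths = stack_cases(cases)
        ds_path = out / "dataset_1d.h5"
        write_dataset_1d(ds_path, X, Y, lengths, manifest | {"artifacts": {}})
        manifest["artifacts"]["dataset"] = str(ds_path)

        est = BRNNRegressor(random_state=config.seed, **config.model.params)
        est.fit(X[train_idx], Y[train_idx], lengths[train_idx])
        pred = est.predict(X[test_idx])
        report = evaluate_predictions(
            pred,
            Y[test_idx],
            lengths[test_idx],
            radius=X[test_idx][:, :, 0],
            threshold=config.evaluation.threshold_mmhg,
            stenosis_window=config.evaluation.stenosis_window,
            case_ids=[case_ids[i] for i in test_idx],
        )
    else:
        cases3 = [build_case_3d(g, bc, prof) for g, bc, prof in solved]
        X = np.stack([c.inputs for c in cases3]).astype(np.float32)
        Y = np.stack([c.outputs for c in cases3]).astype(np.float32)
        M = np.stack([c.lumen_mask for c in cases3])
        est = UNet3DRegressor(random_state=config.seed, **config.model.params)
        est.fit(X[train_idx], Y[train_idx], M[train_idx])
        pred3 = est.predict(X[test_idx])
        # collapse to per-plane 1D curves for the clinical evaluation
        curves_pred, curves_ref, lengths_t = [], [], []
        n_planes = X.shape[3]
        for j, i in enumerate(test_idx):
            cp = planes_to_centerline(pred3[j], M[i])
            cr = planes_to_centerline(Y[i], M[i])
            nv = cases3[i].n_valid_planes
            cp, cr = np.nan_to_num(cp), np.nan_to_num(cr)
            row_p = np.zeros((n_planes, 8))
            row_r = np.zeros((n_planes, 8))
            row_p[:, 0] = cp
            row_r[:, 0] = cr
            curves_pred.append(row_p)
            curves_ref.append(row_r)
            lengths_t.append(nv)
        report = evaluate_predictions(
            np.stack(curves_pred),
            np.stack(curves_ref),
            np.array(lengths_t),
            threshold=config.evaluation.threshold_mmhg,
            case_ids=[case_ids[i] for i in test_idx],
        )

    report.save(out)
    log = pd.DataFrame(
        {
            "epoch": est.history_.epoch,
            "train_loss": est.history_.train_loss,
            "val_loss": est.history_.val_loss,
            "lr": est.history_.lr,
        }
    )
    log_path = out / "training_log.csv"
    log.to_csv(log_path, index=False)
    manifest["artifacts"]["training_log"] = str(log_path)
    manifest["artifacts"]["eval_report"] = str(out / "eval_report.json")
    manifest["median_rmse_mmHg"] = report.median_rmse
    manifest["n_epochs"] = est.history_.n_epochs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def generate_cases(
    n_cases: int,
    seed: int,
    gothic_fraction: float,
    out_dir: str | Path,
    solve: bool = True,
) -> list[str]:
    """Generate (and optionally solve) a cohort, one JSON+CSV pair per case."""
    cohort = sample_cohort(n_cases, seed=seed, gothic_fraction=gothic_fraction)
    ids = []
    for geom, bc in cohort:
        profile = solve_case(geom, bc) if solve else None
        save_case(out_dir, geom, bc, profile)
        ids.append(geom.case_id)
    return ids


def import_deposited(archive_path: str | Path) -> list[tuple]:
    """Best-effort adapter for an externally deposited cohort.

    Reads every case record found under ``archive_path`` in the native
    JSON+CSV layout; unknown metadata fields are collected and reported,
    never silently dropped.  Raises :class:`DataError` when the archive is
    absent or contains no readable cases.
    """
    path = Path(archive_path)
    if not path.exists():
        raise DataError(f"deposited archive not found: {path}")
    ids = list_cases(path)
    if not ids:
        raise DataError(f"no case records found under {path}")
    cases = []
    unknown_report: dict[str, dict] = {}
    for cid in ids:
        geom, bc, profile, unknown = load_case(path, cid)
        if unknown:
            unknown_report[cid] = unknown
        cases.append((geom, bc, profile))
    if unknown_report:
        import warnings

        warnings.warn(f"unmapped fields in deposited records: {unknown_report}")
    return cases
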