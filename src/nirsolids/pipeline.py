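"""End-to-end workflow: simulate -> outlier removal -> SPXY split -> smooth ->
select -> fit -> evaluate -> explain, driven by one :class:`RunConfig`.

A single global seed is fanned out deterministically per stage (hash of
``"<seed>:<stage>"``), so one knob reproduces the whole run while stages keep
independent random streams. Every run writes a metrics CSV (one row per
model x selector, calibration and prediction columns side by side), the
selected wavelengths, and a plain-text log of all seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import make_default_benchmark
from .dataset import SpectraSet, read_spectra_csv
from .interpret import plsr_importance, shapley_attribution
from .metrics import evaluate, paired_t_test
from .moecnn import CNNRegressor, MoECNNRegressor
from .preprocess import remove_outliers, sg_smooth, spxy_split
from .regression import (
    EpsilonSVR,
    GRNNRegressor,
    LSSVMRegressor,
    PLSRegressorNIPALS,
    grid_search_cv,
    select_n_lv,
)
from .selection import make_selector

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "compare_models", "fit_model"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 42
    input_csv: str | None = None          # when None, the simulate stage runs
    outdir: str = "nirsolids_run"
    n_samples: int = 180
    outlier_fraction: float = 0.045       # injected by the simulator
    smooth: bool = True
    window: int = 11
    polyorder: int = 2
    screen_outliers: bool = True
    contamination: float = 0.045
    fraction: float = 0.7
    method: str = "fs"                    # uve | vip | cars | fs
    model: str = "plsr"                   # plsr | grnn | lssvm | svr | moecnn | cnn
    n_runs: int = 100
    cv_folds: int = 5
    max_lv: int = 15
    epochs: int = 500
    batch_size: int = 32
    lr: float = 0.001
    explain: str = "none"                 # none | loading | shapley
    bins: int = 20
    n_coalitions: int = 256

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return Path(path)


def fit_model(name: str, X, y, seed: int, config: RunConfig | None = None):
    """Fit one named regressor with its conventional CV hyperparameter search."""
    cfg = config or RunConfig()
    if name == "plsr":
        n_lv, _ = select_n_lv(X, y, max_lv=cfg.max_lv, folds=cfg.cv_folds, seed=seed)
        return PLSRegressorNIPALS(n_lv=n_lv).fit(X, y)
    if name == "grnn":
        scale = float(np.sqrt(np.mean(np.var(X, axis=0))) * np.sqrt(X.shape[1]))
        grid = [{"sigma": s * max(scale, 1e-6)} for s in (0.05, 0.1, 0.3, 1.0, 3.0)]
        best = grid_search_cv(GRNNRegressor, grid, X, y, folds=cfg.cv_folds, seed=seed)
        return GRNNRegressor(sigma=best["sigma"]).fit(X, y)
    if name == "lssvm":
        scale = float(np.sqrt(np.mean(np.var(X, axis=0))) * np.sqrt(X.shape[1]))
        grid = [
            {"gamma": g, "width": w * max(scale, 1e-6)}
            for g in (1.0, 10.0, 100.0)
            for w in (0.1, 0.3, 1.0, 3.0)
        ]
        best = grid_search_cv(LSSVMRegressor, grid, X, y, folds=cfg.cv_folds, seed=seed)
        return LSSVMRegressor(gamma=best["gamma"], width=best["width"]).fit(X, y)
    if name == "svr":
        return EpsilonSVR().fit(X, y)
    if name == "moecnn":
        return MoECNNRegressor(
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr, seed=seed
        ).fit(X, y)
    if name == "cnn":
        return CNNRegressor(
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr, seed=seed
        ).fit(X, y)
    raise ValueError(f"unknown model {name!r}")


def _prepare(config: RunConfig, log: list[str]) -> tuple[SpectraSet, object]:
    if config.input_csv:
        data = read_spectra_csv(config.input_csv)
        log.append(f"loaded {data.n_samples} spectra from {config.input_csv}")
    else:
        sim_seed = stage_seed(config.seed, "simulate")
        data = make_default_benchmark(seed=sim_seed, n=config.n_samples)
        log.append(f"simulated n={config.n_samples} benchmark (stage seed {sim_seed})")
    if data.reference is None:
        raise ValueError("pipeline requires reference values")
    report = None
    if config.screen_outliers:
        data, report = remove_outliers(
            data,
            contamination=config.contamination,
            seed=stage_seed(config.seed, "outliers"),
        )
        log.append(
            f"outlier screen removed {report.removed_indices.size} samples "
            f"(contamination {config.contamination})"
        )
    if config.smooth:
        data = sg_smooth(data, window=config.window, polyorder=config.polyorder)
        log.append(f"SG smoothing window={config.window} polyorder={config.polyorder}")
    return data, report


def _run_one(
    data: SpectraSet, split, method: str, model_name: str, config: RunConfig, log: list[str]
) -> dict:
    Xc = data.absorbance[split.calibration_indices]
    yc = data.reference[split.calibration_indices]
    Xp = data.absorbance[split.prediction_indices]
    yp = data.reference[split.prediction_indices]

    sel_seed = stage_seed(config.seed, f"select:{method}")
    selector = make_selector(
        method,
        n_lv=min(config.max_lv, 10),
        seed=sel_seed,
        n_runs=config.n_runs,
        cv_folds=config.cv_folds,
    )
    selector.fit(Xc, yc)
    idx = selector.get_support()
    log.append(f"{method}: retained {idx.size}/{data.n_wavelengths} wavelengths")

    fit_seed = stage_seed(config.seed, f"fit:{model_name}")
    model = fit_model(model_name, Xc[:, idx], yc, seed=fit_seed, config=config)
    cal = evaluate(yc, model.predict(Xc[:, idx]), set_label="calibration")
    pred = evaluate(yp, model.predict(Xp[:, idx]), set_label="prediction")
    ttest = paired_t_test(yp, model.predict(Xp[:, idx]))
    log.append(
        f"{model_name}x{method}: RMSEC {cal.rmse:.3f} Rc {cal.r:.3f} "
        f"RMSEP {pred.rmse:.3f} Rp {pred.r:.3f} RPD {pred.rpd:.3f} "
        f"t-test p {ttest.p_value:.3f}"
    )
    return {
        "model": model_name,
        "method": method,
        "n_wavelengths": int(idx.size),
        "RMSEC (%)": cal.rmse,
        "R_c": cal.r,
        "RMSEP (%)": pred.rmse,
        "R_p": pred.r,
        "RPD": pred.rpd,
        "MAE_p (%)": pred.mae,
        "t_p_value": ttest.p_value,
        "_fitted": (model, idx, selector),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the run report dict."""
    t0 = time.time()
    log: list[str] = [f"seed {config.seed}"]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    data, outlier_report = _prepare(config, log)
    split = spxy_split(data, fraction=config.fraction)
    log.append(
        f"SPXY split: {split.calibration_indices.size} calibration / "
        f"{split.prediction_indices.size} prediction (fraction {config.fraction})"
    )
    row = _run_one(data, split, config.method, config.model, config, log)
    model, idx, _ = row.pop("_fitted")

    if config.explain != "none":
        Xc = data.absorbance[split.calibration_indices][:, idx]
        if config.explain == "loading":
            if not isinstance(model, PLSRegressorNIPALS):
                raise ValueError("loading importance needs a PLSR model")
            imap = plsr_importance(model, wavelengths=data.wavelengths[idx])
        else:
            Xp = data.absorbance[split.prediction_indices][:, idx]
            imap = shapley_attribution(
                model, Xc, Xp[: min(10, Xp.shape[0])],
                n_coalitions=config.n_coalitions, bins=min(config.bins, idx.size),
                seed=stage_seed(config.seed, "shapley"),
                wavelengths=data.wavelengths[idx],
            )
        pd.DataFrame(
            {"wavelength_nm": imap.wavelengths, "importance": imap.importance}
        ).to_csv(outdir / "importance.csv", index=False)
        log.append(f"importance map ({imap.method}) written")

    metrics = pd.DataFrame([row])
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
    np.savetxt(
        outdir / "selected_wavelengths.txt", data.wavelengths[idx], fmt="%.1f"
    )
    (outdir / "run.log").write_text(
        "\n".join(f"[{time.time() - t0:7.2f}s] {line}" for line in log) + "\n"
    )
    report = {
        "metrics": metrics,
        "split": split,
        "outliers": outlier_report,
        "log": log,
        "model": model,
        "selected_wavelengths": data.wavelengths[idx],
    }
    return report


def compare_models(
    config: RunConfig, specs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """One row per (model, selector) pair on a shared split and seed."""
    specs = specs or [("plsr", "fs"), ("plsr", "cars"), ("moecnn", "fs")]
    if len(specs) < 2:
        raise ValueError("compare_models needs at least 2 model specs")
    log: list[str] = []
    data, _ = _prepare(config, log)
    split = spxy_split(data, fraction=config.fraction)
    rows = []
    for model_name, method in specs:
        row = _run_one(data, split, method, model_name, config, log)
        row.pop("_fitted")
        rows.append(row)
    return pd.DataFrame(rows)
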