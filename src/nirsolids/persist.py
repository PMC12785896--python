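"""Portable parameter archive for fitted models.

A fitted estimator is stored as a single ``.npz``: numeric arrays under
flattened keys, and a JSON document (class name, scalar attributes,
constructor parameters) under ``__meta__``. Every estimator in this package
round-trips; the epsilon-SVR delegate stores its training data and refits on
load (the solver is deterministic), so no foreign binary state is archived.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import moecnn, regression

_REGISTRY = {
    cls.__name__: cls
    for cls in (
        regression.PLSRegressorNIPALS,
        regression.GRNNRegressor,
        regression.LSSVMRegressor,
        regression.EpsilonSVR,
        moecnn.MoECNNRegressor,
        moecnn.CNNRegressor,
    )
}

__all__ = ["save_model", "load_model"]


def _flatten(prefix: str, value, arrays: dict, meta: dict) -> None:
    if isinstance(value, np.ndarray):
        arrays[prefix] = value
        meta[prefix] = {"__kind__": "array"}
    elif isinstance(value, dict):
        meta[prefix] = {"__kind__": "dict", "keys": list(value)}
        for k, v in value.items():
            _flatten(f"{prefix}/{k}", v, arrays, meta)
    elif isinstance(value, (bool, int, float, str, type(None))):
        meta[prefix] = {"__kind__": "scalar", "value": value}
    elif isinstance(value, (np.integer, np.floating)):
        meta[prefix] = {"__kind__": "scalar", "value": value.item()}
    elif isinstance(value, (list, tuple)):
        meta[prefix] = {"__kind__": "json", "value": json.loads(json.dumps(value))}
    elif prefix.endswith("config_") and hasattr(value, "__dict__"):
        meta[prefix] = {"__kind__": "config", "value": dict(value.__dict__)}
    else:
        raise TypeError(f"cannot archive attribute {prefix!r} of type {type(value)}")


def save_model(model, path) -> Path:
    path = Path(path)
    cls = type(model).__name__
    if cls not in _REGISTRY:
        raise TypeError(f"unsupported model class {cls}")
    arrays: dict = {}
    meta: dict = {"__class__": cls, "params": model.get_params()}
    fitted = {
        k: v for k, v in model.__dict__.items()
        if k.endswith("_") and not k.startswith("__")
    }
    if isinstance(model, regression.EpsilonSVR):
        fitted = {"X_": model._X_train_, "y_": model._y_train_}
    meta["attrs"] = sorted(fitted)
    for k, v in fitted.items():
        _flatten(k, v, arrays, meta)
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)
    return path


def _rebuild(prefix: str, meta: dict, arrays) -> object:
    entry = meta[prefix]
    kind = entry["__kind__"]
    if kind == "array":
        return arrays[prefix]
    if kind == "scalar" or kind == "json":
        return entry["value"]
    if kind == "dict":
        return {k: _rebuild(f"{prefix}/{k}", meta, arrays) for k in entry["keys"]}
    if kind == "config":
        return moecnn.MoECNNConfig(**entry["value"])
    raise ValueError(f"unknown archive entry kind {kind!r}")


def load_model(path):
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        cls = _REGISTRY[meta["__class__"]]
        model = cls(**meta["params"])
        if cls is regression.EpsilonSVR:
            X = archive["X_"]
            y = archive["y_"]
            return model.fit(X, y)
        for attr in meta["attrs"]:
            setattr(model, attr, _rebuild(attr, meta, dict(archive)))
    return model
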