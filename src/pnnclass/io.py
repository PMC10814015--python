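"""CSV data loading and JSON model serialization.

The model file is a plain JSON document holding everything prediction needs:
the training features and encoded labels, the neighbor brackets, the cycle
census, the per-rank maximum-likelihood fits, the label codebook
(``classes``), and the selected neighborhood size.  Loading rebuilds a fitted
:class:`~pnnclass.classifier.PNNClassifier` without refitting, so save/load
round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import PNNClassifier
from .cycles import CycleCounts
from .datasets import LabeledDataset
from .partition import NonlocalFit

__all__ = [
    "read_labeled_csv",
    "write_labeled_csv",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


def read_labeled_csv(path, label_column: str):
    """Read a labeled feature table.

    Parameters
    ----------
    path : path-like
        CSV file with one row per sample unit, numeric feature columns and
        one label column.
    label_column : str
        Name of the label column; remaining columns are features.

    Returns
    -------
    X : numpy.ndarray of shape (n, p)
    y : numpy.ndarray of shape (n,)
        Labels exactly as they appear in the file (strings allowed).
    feature_names : list of str
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: file contains no data rows")
    if label_column not in frame.columns:
        raise ValueError(
            f"{path}: label column {label_column!r} not found; "
            f"available columns: {list(frame.columns)}"
        )
    y = frame[label_column].to_numpy()
    feats = frame.drop(columns=[label_column])
    for col in feats.columns:
        converted = pd.to_numeric(feats[col], errors="coerce")
        bad = converted.isna() & feats[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {feats[col][row]!r} in feature "
                f"column {col!r}, row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        feats[col] = converted
    return feats.to_numpy(dtype=float), y, list(feats.columns)


def read_feature_csv(path):
    """Read an unlabeled numeric feature table (all columns are features)."""
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: file contains no data rows")
    try:
        X = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric feature value ({exc})") from exc
    return X, list(frame.columns)


def write_labeled_csv(path, dataset: LabeledDataset, label_column: str = "y") -> None:
    """Write a :class:`LabeledDataset` as CSV (features x1..xp plus label)."""
    frame = pd.DataFrame(
        dataset.X, columns=[f"x{j + 1}" for j in range(dataset.p)]
    )
    frame[label_column] = dataset.y
    frame.to_csv(path, index=False)


def _fit_to_dict(f: NonlocalFit) -> dict:
    return {
        "r": f.r,
        "beta_hat": f.beta_hat,
        "T": f.T,
        "log_Z": f.log_Z,
        "converged": f.converged,
        "clipped": f.clipped,
    }


def save_model(model: PNNClassifier, path) -> None:
    """Serialize a fitted classifier to a documented JSON file."""
    classes = model.classes_
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "classes": classes.tolist(),
        "classes_dtype": str(classes.dtype),
        "n_features_in": int(model.n_features_in_),
        "X_train": None if model._X_train is None else model._X_train.tolist(),
        "distance_matrix": model.distance_matrix_.tolist(),
        "y_encoded": model._y_enc.tolist(),
        "brackets": model.brackets_.tolist(),
        "cycle_counts": model.cycle_counts_.c.tolist(),
        "fits": [_fit_to_dict(f) for f in model.fits_],
        "k_max": int(model.k_max_),
        "k_selected": int(model.k_),
        "loocv_error": model.loocv_error_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PNNClassifier:
    """Rebuild a fitted classifier from :func:`save_model` output."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version "
            f"{payload.get('format_version')!r}"
        )
    model = PNNClassifier(**payload["params"])
    model.classes_ = np.asarray(payload["classes"], dtype=payload["classes_dtype"])
    model.n_features_in_ = payload["n_features_in"]
    model._X_train = (
        None if payload["X_train"] is None else np.asarray(payload["X_train"], dtype=float)
    )
    model.distance_matrix_ = np.asarray(payload["distance_matrix"], dtype=float)
    model._y_enc = np.asarray(payload["y_encoded"], dtype=np.intp)
    model.brackets_ = np.asarray(payload["brackets"], dtype=np.intp)
    model.cycle_counts_ = CycleCounts(
        c=np.asarray(payload["cycle_counts"], dtype=np.intp),
        n=model.brackets_.shape[0],
    )
    model.fits_ = [NonlocalFit(**d) for d in payload["fits"]]
    model.betas_ = np.array([f.beta_hat for f in model.fits_])
    model.k_max_ = payload["k_max"]
    model.k_ = payload["k_selected"]
    model.loocv_error_ = np.asarray(payload["loocv_error"], dtype=float)
    return model
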