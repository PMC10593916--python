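"""Personalized encoding models as linear ensembles of base-subject models.

A novel subject's regional response is predicted as a weighted sum of the
predictions of B frozen base encoding models plus a bias,

    yhat(img) = sum_i w_i * base_i(img) + b,

with (w, b) fitted by ordinary least squares on a small stratified sample
of the subject's Session-1 image-response pairs (image-level responses are
averaged over repeats before fitting).  No constraint or penalty is placed
on the weights by default; an optional ridge penalty is available for
ill-conditioned cases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fwrf import EncodingModel, _extract_batch, _stack_pixels, predict_batch


@dataclass
class EnsembleModel:
    """Weighted sum of base encoding-model predictions plus a bias."""

    base_models: list[EncodingModel]
    ensemble_weights: np.ndarray
    bias: float
    subject_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        self.ensemble_weights = np.asarray(self.ensemble_weights, dtype=float)
        if len(self.ensemble_weights) != len(self.base_models):
            raise ValueError("one weight per base model required")

    def predict(self, image) -> float:
        return predict_ensemble(self, image)

    def predict_batch(self, pixels: np.ndarray) -> np.ndarray:
        return predict_batch(self, pixels)


def base_prediction_matrix(base_models: Sequence[EncodingModel],
                           stimuli) -> np.ndarray:
    """(n_images, B) matrix of base-model predictions, one extraction pass."""
    px = _stack_pixels(stimuli)
    bank = base_models[0]._require_bank()
    if any(m.bank_id != bank.bank_id for m in base_models):
        raise ValueError("base models must share one feature bank")
    levels = _extract_batch(px, bank)
    return np.column_stack([m.predict_from_levels(levels)
                            for m in base_models])


def split_session1(table: pd.DataFrame, manifest: pd.DataFrame,
                   n_train_per_cell: int, seed: int
                   ) -> tuple[list[str], list[str]]:
    """Stratified train/test split of Session-1 images.

    From every (condition, designed-target-region) cell of the manifest,
    ``n_train_per_cell`` image ids are sampled without replacement (seeded);
    all remaining images form the test set.  At the full-scale design
    (32 per cell, 4 conditions x 3 regions) this yields 384 training images.
    """
    cells = manifest.groupby(["condition", "target_region"], sort=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    present = set(table["image_id"])
    train: list[str] = []
    test: list[str] = []
    for _, cell in cells:
        ids = sorted(set(cell["image_id"]) & present)
        if len(ids) < n_train_per_cell:
            raise ValueError(
                f"cell has {len(ids)} images, need {n_train_per_cell}")
        pick = rng.choice(len(ids), size=n_train_per_cell, replace=False)
        chosen = {ids[i] for i in pick}
        train.extend(sorted(chosen))
        test.extend(i for i in ids if i not in chosen)
    return train, test


def image_mean_responses(table: pd.DataFrame, subject_id: str, region: str
                         ) -> pd.Series:
    """Per-image response averaged over repeats for one subject and region."""
    sub = table[(table["subject_id"] == subject_id)
                & (table["region"] == region)]
    return sub.groupby("image_id")["response"].mean()


def fit_ensemble(base_models: Sequence[EncodingModel], stimuli,
                 responses: np.ndarray, *, ridge: float = 0.0,
                 subject_id: str = "", region: str = "",
                 prediction_matrix: np.ndarray | None = None) -> EnsembleModel:
    """Least-squares fit of ensemble weights and bias.

    ``responses`` are image-level (repeat-averaged) measurements aligned
    with ``stimuli``.  The fit is ordinary least squares with an
    unpenalized intercept (minimum-norm under rank deficiency); ``ridge``
    optionally penalizes the weights only.
    """
    y = np.asarray(responses, dtype=float)
    P = (prediction_matrix if prediction_matrix is not None
         else base_prediction_matrix(base_models, stimuli))
    n, B = P.shape
    if n != len(y):
        raise ValueError("stimuli and responses differ in length")
    if n < B + 1:
        warnings.warn("fewer training pairs than ensemble parameters; "
                      "returning the minimum-norm solution")
    if ridge > 0:
        Pm, ym = P.mean(axis=0), y.mean()
        w = np.linalg.solve((P - Pm).T @ (P - Pm) + ridge * np.eye(B),
                            (P - Pm).T @ (y - ym))
        b = ym - float(Pm @ w)
    else:
        A = np.column_stack([P, np.ones(n)])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        w, b = coef[:B], float(coef[B])
    return EnsembleModel(base_models=list(base_models), ensemble_weights=w,
                         bias=b, subject_id=subject_id, region=region)


def predict_ensemble(model: EnsembleModel, image) -> float:
    """Deterministic weighted sum of base predictions plus bias."""
    if len(model.ensemble_weights) != len(model.base_models):
        raise ValueError("weight/base length mismatch")
    return float(predict_batch(model, _stack_pixels([image]))[0])


def save_ensemble(model: EnsembleModel, path: str,
                  base_refs: Sequence[str] | None = None,
                  split_seed: int | None = None,
                  train_manifest_hash: str | None = None) -> None:
    payload = {
        "subject_id": model.subject_id,
        "region": model.region,
        "weights": model.ensemble_weights.tolist(),
        "bias": model.bias,
        "base_models": list(base_refs) if base_refs is not None
        else [m.subject_id for m in model.base_models],
        "split_seed": split_seed,
        "train_manifest_hash": train_manifest_hash,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_ensemble(path: str, base_models: Sequence[EncodingModel]
                  ) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    return EnsembleModel(base_models=list(base_models),
                         ensemble_weights=np.asarray(payload["weights"]),
                         bias=float(payload["bias"]),
                         subject_id=payload["subject_id"],
                         region=payload["region"])
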