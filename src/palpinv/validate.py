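"""Hold-out and leave-one-out validation of the inversion network.

Two error modes are reported for each run:

* ``rms_relative`` (headline): per output, the root-mean-square of the
  relative residual (T - Y)/T over the evaluated records, in percent.
* ``as_printed``: per output, the plain average of the signed residual on
  min-max-scaled values, in percent.  Signed residuals cancel, so this mode
  can read near zero for a badly scattered predictor; it is retained for
  comparability and never used as the headline number.

Both schemes refit the input/output scalers on the training portion of every
split, so no information from held-out records leaks into training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import Dataset, TrainConfig, fit_scalers, forward_pass, init_network, train

__all__ = ["ValidationResult", "error_metric", "holdout_validate", "loocv_validate", "results_to_csv"]

_OUTPUTS = ("size", "depth", "modulus")


@dataclass
class ValidationResult:
    """Per-output train/test errors for one (scheme, algorithm, budget) cell."""

    scheme: str  # "HOV" or "LOOCV"
    algorithm: str
    iterations: int
    train_pct: np.ndarray  # rms_relative, shape (3,)
    test_pct: np.ndarray
    train_signed_pct: np.ndarray  # as_printed on scaled values
    test_signed_pct: np.ndarray
    repeats: int
    seeds: list[int]

    def __post_init__(self) -> None:
        for arr in (self.train_pct, self.test_pct):
            if np.asarray(arr).shape != (3,):
                raise ValueError("per-output error arrays must have length 3")
            if np.any(np.asarray(arr) < 0):
                raise ValueError("rms errors must be nonnegative")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def error_metric(T: np.ndarray, Y: np.ndarray, mode: str = "rms_relative") -> np.ndarray:
    """Per-output error in percent between targets T and predictions Y.

    ``rms_relative``: 100 * sqrt(mean(((T - Y)/T)^2)) per column (errors on a
    zero target).  ``as_printed``: 100 * mean(T - Y) per column — the signed
    average; pass scaled values for the conventional reading.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if T.shape != Y.shape:
        raise ValueError(f"shape mismatch: targets {T.shape} vs predictions {Y.shape}")
    if mode == "as_printed":
        return 100.0 * (T - Y).mean(axis=0)
    if mode == "rms_relative":
        if np.any(T == 0):
            raise ValueError("zero target encountered: relative error undefined")
        rel = (T - Y) / T
        return 100.0 * np.sqrt((rel**2).mean(axis=0))
    raise ValueError("mode must be 'as_printed' or 'rms_relative'")


def _fit_eval(
    train_set: Dataset, test_set: Dataset, cfg: TrainConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Train from a fresh seeded init and return per-output train/test errors."""
    w = init_network(seed=seed)
    xin, xout = fit_scalers(train_set)
    w = dataclasses.replace(w, input_scaler=xin, output_scaler=xout)
    w, _ = train(w, train_set, cfg)
    yhat_tr = forward_pass(w, train_set.X)
    yhat_te = forward_pass(w, test_set.X)
    tr = error_metric(train_set.Y, yhat_tr, "rms_relative")
    te = error_metric(test_set.Y, yhat_te, "rms_relative")
    tr_s = error_metric(xout.scale(train_set.Y), xout.scale(yhat_tr), "as_printed")
    te_s = error_metric(xout.scale(test_set.Y), xout.scale(yhat_te), "as_printed")
    return tr, te, tr_s, te_s


def holdout_validate(
    data: Dataset,
    test_ids: Sequence,
    cfg: TrainConfig,
    repeats: int = 10,
    base_seed: int = 0,
) -> ValidationResult:
    """Hold-out validation: train on the complement of ``test_ids``.

    Each repeat reinitializes the network with seed ``base_seed + repeat``;
    scalers are fitted on the training split only.
    """
    test_ids = np.asarray(list(test_ids))
    if len(test_ids) == 0:
        raise ValueError("test_ids is empty")
    mask_test = np.isin(data.ids, test_ids)
    if mask_test.sum() != len(np.unique(test_ids)) or not np.all(np.isin(test_ids, data.ids)):
        raise ValueError("test_ids must be a subset of dataset ids")
    if mask_test.all():
        raise ValueError("test_ids must be a proper subset (empty training split)")
    train_set = data.subset(~mask_test)
    test_set = data.subset(mask_test)
    if np.intersect1d(train_set.ids, test_set.ids).size:
        raise ValueError("train/test id overlap")

    seeds = [base_seed + r for r in range(repeats)]
    acc = [np.zeros(3) for _ in range(4)]
    for seed in seeds:
        out = _fit_eval(train_set, test_set, cfg, seed)
        for a, o in zip(acc, out):
            a += o
    return ValidationResult(
        scheme="HOV",
        algorithm=cfg.algorithm,
        iterations=cfg.max_iter,
        train_pct=acc[0] / repeats,
        test_pct=acc[1] / repeats,
        train_signed_pct=acc[2] / repeats,
        test_signed_pct=acc[3] / repeats,
        repeats=repeats,
        seeds=seeds,
    )


def loocv_validate(
    data: Dataset,
    cfg: TrainConfig,
    repeats: int = 10,
    base_seed: int = 0,
) -> ValidationResult:
    """Leave-one-out cross-validation: n folds, each record tested once.

    The reported error is the average of the per-fold errors, averaged again
    over ``repeats`` reinitialization seeds.  For a single held-out record the
    per-fold rms-relative error reduces to its absolute relative error.
    """
    n = len(data)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 records")
    seeds = [base_seed + r for r in range(repeats)]
    acc = [np.zeros(3) for _ in range(4)]
    for seed in seeds:
        fold_acc = [np.zeros(3) for _ in range(4)]
        tested: list = []
        for i in range(n):
            mask = np.zeros(n, dtype=bool)
            mask[i] = True
            out = _fit_eval(data.subset(~mask), data.subset(mask), cfg, seed)
            for a, o in zip(fold_acc, out):
                a += o
            tested.append(data.ids[i])
        if sorted(tested) != sorted(data.ids.tolist()):
            raise AssertionError("LOOCV bookkeeping: each record must be tested exactly once")
        for a, fa in zip(acc, fold_acc):
            a += fa / n
    return ValidationResult(
        scheme="LOOCV",
        algorithm=cfg.algorithm,
        iterations=cfg.max_iter,
        train_pct=acc[0] / repeats,
        test_pct=acc[1] / repeats,
        train_signed_pct=acc[2] / repeats,
        test_signed_pct=acc[3] / repeats,
        repeats=repeats,
        seeds=seeds,
    )


def results_to_csv(results: Sequence[ValidationResult], path_or_buf) -> None:
    """Tabulate results: algorithm x scheme x iterations x output x train/test."""
    rows = []
    for res in results:
        for j, name in enumerate(_OUTPUTS):
            rows.append(
                {
                    "algorithm": res.algorithm,
                    "scheme": res.scheme,
                    "iterations": res.iterations,
                    "output": name,
                    "train_pct": res.train_pct[j],
                    "test_pct": res.test_pct[j],
                    "train_signed_pct": res.train_signed_pct[j],
                    "test_signed_pct": res.test_signed_pct[j],
                    "repeats": res.repeats,
                }
            )
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)
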