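"""Classifier evaluation: Se/Sp, threshold scans and cross-validation.

Sensitivity is the proportion of true STU pairs called STU; specificity the
proportion of true DTU pairs called DTU.  Three evaluation schemes are
provided:

* resubstitution — fit once on all pairs, score all of them (an optimistic
  bound on generalization error, useful as an uncertainty indicator);
* holdout — fit on a seeded, label-stratified 80% split, score the 20%;
* leave-one-out — refit N times, classify each held-out pair once, and pool
  the N single-pair outcomes into one confusion table per threshold.

A scan sweeps the probability threshold over a grid in [0.05, 1] (default
step 0.05) and records (Se, Sp) at each point; the operating point chosen is
the one nearest the ROC's perfect corner, i.e. minimizing
(1-Se)^2 + (1-Sp)^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import model as dm
from .pairs import AdjacentPair

__all__ = [
    "ConfusionCounts",
    "ThresholdScan",
    "sensitivity_specificity",
    "confusion_at_threshold",
    "threshold_scan",
    "best_threshold",
    "default_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(Se, Sp) = (tp/(tp+fn), tn/(tn+fp)); STU is the positive class."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        raise ValueError("Se/Sp undefined: one class has no evaluated pairs")
    return counts.tp / pos, counts.tn / neg


def default_grid(step: float = 0.05) -> np.ndarray:
    """Threshold grid over [0.05, 1] at the given step."""
    n = int(round((1.0 - 0.05) / step)) + 1
    return np.round(np.linspace(0.05, 1.0, n), 10)


def confusion_at_threshold(
    posteriors: Sequence[float], labels: Sequence[str], threshold: float
) -> ConfusionCounts:
    post = np.asarray(posteriors, dtype=float)
    is_stu = np.asarray([lab == "STU" for lab in labels])
    call_stu = post > threshold
    return ConfusionCounts(
        tp=int(np.sum(call_stu & is_stu)),
        fn=int(np.sum(~call_stu & is_stu)),
        tn=int(np.sum(~call_stu & ~is_stu)),
        fp=int(np.sum(call_stu & ~is_stu)),
    )


@dataclass(frozen=True)
class ThresholdScan:
    thresholds: tuple[float, ...]
    se: tuple[float, ...]
    sp: tuple[float, ...]
    scheme: str
    chosen_threshold: float

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if len(t) == 0:
            raise ValueError("empty threshold grid")
        if np.any(np.diff(t) <= 0) or t[0] < 0.05 - 1e-12 or t[-1] > 1 + 1e-12:
            raise ValueError("grid must be strictly increasing within [0.05, 1]")

    @property
    def cost(self) -> tuple[float, ...]:
        return tuple(
            (1 - se) ** 2 + (1 - sp) ** 2 for se, sp in zip(self.se, self.sp)
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.se,
                "specificity": self.sp,
                "cost": self.cost,
            }
        ).to_csv(path, sep="\t", index=False)


def best_threshold(scan: ThresholdScan) -> float:
    """Grid threshold minimizing (1-Se)^2 + (1-Sp)^2 (nearest ROC corner).

    Ties are broken toward 0.5, then toward the smaller threshold.
    """
    ranked = sorted(
        zip(scan.cost, scan.thresholds),
        key=lambda ct: (round(ct[0], 12), abs(ct[1] - 0.5), ct[1]),
    )
    return ranked[0][1]


def _stratified_split(
    pairs: Sequence[AdjacentPair], train_frac: float, rng: np.random.Generator
) -> tuple[list[AdjacentPair], list[AdjacentPair]]:
    train: list[AdjacentPair] = []
    test: list[AdjacentPair] = []
    for label in ("STU", "DTU"):
        members = [p for p in pairs if p.label == label]
        idx = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        for j, i in enumerate(idx):
            (train if j < n_train else test).append(members[i])
    if not train or not test:
        raise ValueError("holdout split left a fold empty; use more pairs")
    for fold, name in ((train, "training"), (test, "test")):
        labs = {p.label for p in fold}
        if labs != {"STU", "DTU"}:
            raise ValueError(
                f"holdout {name} fold lost a class; change the stratification seed"
            )
    return train, test


def threshold_scan(
    pairs: Sequence[AdjacentPair],
    config: int = 2,
    scheme: str = "resubstitution",
    grid: Sequence[float] | None = None,
    seed: int | None = None,
    smoothing_alpha: float = 1.0,
    prior_mode: str = "empirical",
    mean_tu_length: float | None = None,
    train_frac: float = 0.8,
    on_fit: Callable[[], None] | None = None,
) -> ThresholdScan:
    """Sweep classification thresholds under one evaluation scheme.

    Posteriors are computed once per scheme (so Se is non-increasing and Sp
    non-decreasing along the grid by construction), then thresholded.  The
    prior is re-estimated inside every training fold: under the geometric
    TU-length model the fold's STU fraction is the maximum-likelihood
    estimate of the geometric parameter from pair data, which the default
    empirical mode uses; passing ``mean_tu_length`` fixes an
    externally-estimated geometric prior for all folds instead.
    ``on_fit`` is an instrumentation hook invoked once per model fit.
    """
    grid_arr = default_grid() if grid is None else np.asarray(grid, dtype=float)
    labeled = [p for p in pairs if p.label in ("STU", "DTU")]

    def _fit(fold: Sequence[AdjacentPair]) -> dm.DisTerModel:
        if on_fit is not None:
            on_fit()
        return dm.fit(
            fold,
            config=config,
            smoothing_alpha=smoothing_alpha,
            prior_mode=prior_mode,
            mean_tu_length=mean_tu_length,
        )

    if scheme == "resubstitution":
        model = _fit(labeled)
        scored = [(dm.posterior_stu(model, p), p.label) for p in labeled]
    elif scheme == "holdout":
        rng = np.random.default_rng(seed)
        train, test = _stratified_split(labeled, train_frac, rng)
        model = _fit(train)
        scored = [(dm.posterior_stu(model, p), p.label) for p in test]
    elif scheme == "loo":
        scored = []
        for i, held_out in enumerate(labeled):
            fold = labeled[:i] + labeled[i + 1 :]
            model = _fit(fold)
            scored.append((dm.posterior_stu(model, held_out), held_out.label))
    else:
        raise ValueError(f"unknown evaluation scheme {scheme!r}")

    posteriors = [s for s, _ in scored]
    labels = [lab for _, lab in scored]
    se, sp = [], []
    for t in grid_arr:
        s, p_ = sensitivity_specificity(
            confusion_at_threshold(posteriors, labels, float(t))
        )
        se.append(s)
        sp.append(p_)
    scan = ThresholdScan(
        thresholds=tuple(float(t) for t in grid_arr),
        se=tuple(se),
        sp=tuple(sp),
        scheme=scheme,
        chosen_threshold=0.0,
    )
    chosen = best_threshold(scan)
    return ThresholdScan(
        thresholds=scan.thresholds,
        se=scan.se,
        sp=scan.sp,
        scheme=scheme,
        chosen_threshold=chosen,
    )
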