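"""Stratified B-random K-fold cross-validation with a classification
threshold calibrated to a preset mortality-class accuracy.

With a ~4% death rate, raw accuracy is dominated by survivors, so the
classifier is operated at a fixed sensitivity instead: on each training
split the threshold is set to the largest predicted-risk value among
training nonsurvivors such that at least ``preset_sensitivity`` of them are
classified as deaths (predict nonsurvivor iff risk >= t).  Per-class
accuracies on the held-out folds are then pooled within a replication and
averaged over B independent stratified partitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .cohort import Cohort
from .glm import ModelSpec, build_design, fit_logistic_xy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvConfig:
    B: int = 1000
    K: int = 4
    preset_sensitivity: float = 0.70
    min_deaths_per_fold: int = 2
    seed: int = 0
    pooled_calibration: bool = False
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0 < self.preset_sensitivity < 1:
            raise ValueError("preset_sensitivity must lie strictly in (0, 1)")
        if self.min_deaths_per_fold < 1:
            raise ValueError("min_deaths_per_fold must be positive")


@dataclass
class CvSummary:
    """Per-class accuracies averaged over replications, plus their spread."""

    model: ModelSpec
    survivor_accuracy: float
    nonsurvivor_accuracy: float
    survivor_accuracy_sd: float
    nonsurvivor_accuracy_sd: float
    B: int
    K: int
    redraws: int
    survivor_by_rep: np.ndarray = field(repr=False, default=None)
    nonsurvivor_by_rep: np.ndarray = field(repr=False, default=None)


def stratified_folds(
    outcomes: np.ndarray,
    K: int,
    rng: np.random.Generator,
    min_deaths_per_fold: int = 2,
) -> list[np.ndarray]:
    """One random partition into K folds stratified on the binary outcome.

    Death counts per fold differ by at most one (likewise survivors), and
    each fold receives at least ``min_deaths_per_fold`` deaths.
    """
    y = np.asarray(outcomes)
    deaths = np.flatnonzero(y == 1)
    survivors = np.flatnonzero(y == 0)
    need = K * min_deaths_per_fold
    if deaths.size < need:
        raise ValueError(
            f"stratified {K}-fold CV with >= {min_deaths_per_fold} deaths per "
            f"fold needs at least {need} deaths; cohort has {deaths.size}"
        )
    if survivors.size < K:
        raise ValueError(f"need at least {K} survivors, have {survivors.size}")
    d_chunks = np.array_split(rng.permutation(deaths), K)
    s_chunks = np.array_split(rng.permutation(survivors), K)
    order = rng.permutation(K)  # decouple which fold gets the larger chunks
    return [
        np.sort(np.concatenate([d_chunks[i], s_chunks[order[i]]]))
        for i in range(K)
    ]


def calibrate_threshold(risks_of_nonsurvivors: np.ndarray, preset_sensitivity: float) -> float:
    """Largest candidate risk t with fraction(risks >= t) >= preset.

    Classification rule: predict nonsurvivor iff risk >= t, so the achieved
    (training) sensitivity is the smallest attainable value at or above the
    preset.
    """
    r = np.sort(np.asarray(risks_of_nonsurvivors, dtype=float))
    if r.size == 0:
        raise ValueError("no nonsurvivor risks to calibrate on")
    if not 0 < preset_sensitivity < 1:
        raise ValueError("preset_sensitivity must lie strictly in (0, 1)")
    k = math.ceil(preset_sensitivity * r.size)  # deaths that must be caught
    return float(r[r.size - k])


def _replication_rngs(seed: int, B: int) -> list[np.random.Generator]:
    # one substream per replication: results invariant to evaluation order
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(B)]


def compare_models(
    cohort: Cohort, specs: list[ModelSpec], cfg: CvConfig
) -> list[CvSummary]:
    """Cross-validate several model specs on identical fold partitions.

    Sharing the partitions across specs within each replication makes the
    comparison paired, so between-model differences are not confounded with
    partition noise.
    """
    data = cohort.data
    used = sorted({p for s in specs for p in s.predictors})
    complete = data[["outcome", *used]].notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "excluded %d record(s) with missing values in %s",
            int((~complete).sum()),
            used,
        )
        data = data.loc[complete]
    y = data["outcome"].to_numpy(dtype=float)
    designs = [build_design(data, s.predictors) for s in specs]
    n = len(y)
    K = cfg.K

    surv_acc = np.empty((cfg.B, len(specs)))
    nonsurv_acc = np.empty((cfg.B, len(specs)))
    redraws = 0

    for b, rng in enumerate(_replication_rngs(cfg.seed, cfg.B)):
        folds = None
        for _ in range(cfg.max_redraws):
            cand = stratified_folds(y, K, rng, cfg.min_deaths_per_fold)
            ok = True
            for k in range(K):
                train_mask = np.ones(n, dtype=bool)
                train_mask[cand[k]] = False
                yt = y[train_mask]
                if yt.min() == yt.max():  # a training split lost a class
                    ok = False
                    break
            if ok:
                folds = cand
                break
            redraws += 1
        if folds is None:
            raise RuntimeError(
                f"could not draw a valid partition in {cfg.max_redraws} attempts"
            )
        train_masks = []
        for k in range(K):
            m = np.ones(n, dtype=bool)
            m[folds[k]] = False
            train_masks.append(m)

        for s, X in enumerate(designs):
            if cfg.pooled_calibration:
                # out-of-fold risks pooled, then one threshold per replication
                oof = np.empty(n)
                for k in range(K):
                    m = train_masks[k]
                    fit = fit_logistic_xy(y[m], X[m], spec=specs[s])
                    oof[folds[k]] = expit(X[folds[k]] @ fit.params)
                t = calibrate_threshold(oof[y == 1], cfg.preset_sensitivity)
                pred = oof >= t
                tp = int(np.sum(pred & (y == 1)))
                fn = int(np.sum(~pred & (y == 1)))
                tn = int(np.sum(~pred & (y == 0)))
                fp = int(np.sum(pred & (y == 0)))
            else:
                tp = fn = tn = fp = 0
                for k in range(K):
                    m = train_masks[k]
                    fit = fit_logistic_xy(y[m], X[m], spec=specs[s])
                    risk = expit(X @ fit.params)
                    t = calibrate_threshold(
                        risk[m & (y == 1)], cfg.preset_sensitivity
                    )
                    test = folds[k]
                    pred = risk[test] >= t
                    yt = y[test]
                    tp += int(np.sum(pred & (yt == 1)))
                    fn += int(np.sum(~pred & (yt == 1)))
                    tn += int(np.sum(~pred & (yt == 0)))
                    fp += int(np.sum(pred & (yt == 0)))
            surv_acc[b, s] = tn / (tn + fp)
            nonsurv_acc[b, s] = tp / (tp + fn)

    out = []
    for s, spec in enumerate(specs):
        out.append(
            CvSummary(
                model=spec,
                survivor_accuracy=float(surv_acc[:, s].mean()),
                nonsurvivor_accuracy=float(nonsurv_acc[:, s].mean()),
                survivor_accuracy_sd=float(surv_acc[:, s].std(ddof=1)) if cfg.B > 1 else 0.0,
                nonsurvivor_accuracy_sd=float(nonsurv_acc[:, s].std(ddof=1)) if cfg.B > 1 else 0.0,
                B=cfg.B,
                K=cfg.K,
                redraws=redraws,
                survivor_by_rep=surv_acc[:, s].copy(),
                nonsurvivor_by_rep=nonsurv_acc[:, s].copy(),
            )
        )
    if redraws:
        logger.warning("redrew %d degenerate partition(s)", redraws)
    return out


def cross_validate(cohort: Cohort, spec: ModelSpec, cfg: CvConfig) -> CvSummary:
    """Stratified B-random K-fold cross-validation of one model spec."""
    return compare_models(cohort, [spec], cfg)[0]
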