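"""Multivoxel pattern analysis with permutation inference.

For each region of interest the 100 most stimulus-activated voxels are
selected, their time courses z-scored, the ROI-mean time course projected
out of every voxel (removing the univariate signal), and labels shifted by
one volume to offset the hemodynamic lag.  One input pattern is the average
of two same-condition trials.  A linear support vector machine (C = 1.0)
is evaluated with 5-fold cross-validation; the analysis is iterated with
re-randomized trial pairing and fold assignment, and significance is
assessed against an empirical null built by re-running the identical
analysis with shuffled labels.

Three comparisons are supported, defined from the viewpoint of the cylinder
contralateral to the ROI's hemisphere: ``attended_vs_unattended`` (spatial
attention; all active trials, hence twice as many patterns as the feature
comparisons), ``cw_vs_ccw`` (rotation direction of the attended cylinder;
contralateral-attended trials only) and ``same_vs_different`` (global
feature attention; contralateral-unattended trials only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .bold import BoldDataset, contralateral_side

__all__ = [
    "COMPARISONS",
    "PatternSet",
    "ClassifierResult",
    "PermutationResult",
    "localizer_stats",
    "select_voxels",
    "extract_timeseries",
    "preprocess",
    "build_patterns",
    "classify",
    "permutation_test",
    "decode",
]

log = logging.getLogger("dsfm_attention")

COMPARISONS = ("attended_vs_unattended", "cw_vs_ccw", "same_vs_different")


@dataclass
class PatternSet:
    """Labeled multivoxel patterns (rows) with pairing provenance."""

    X: np.ndarray              # (n_patterns, n_voxels)
    y: np.ndarray              # (n_patterns,) string labels, two classes
    comparison: str
    provenance: list[tuple[int, ...]]  # trial indices averaged into each row
    groups: np.ndarray | None = None   # block id per pattern; folds respect it

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]


@dataclass
class ClassifierResult:
    accuracies: np.ndarray     # per-iteration cross-validated accuracy
    mean_accuracy: float
    ci: tuple[float, float]    # Bonferroni-corrected 95% CI over iterations
    alpha: float
    n_areas: int


@dataclass
class PermutationResult:
    observed_mean: float
    null: np.ndarray
    null_mean: float
    null_ci: tuple[float, float]  # Bonferroni-corrected 95% interval
    significant: bool             # strictly outside the corrected interval
    n_perm: int


def localizer_stats(dataset: BoldDataset, shift: int = 1) -> np.ndarray:
    """Per-voxel stimulus-activation t statistic (active vs passive volumes).

    A synthetic stand-in for an independent localizer contrast: a two-sample
    t of %-normalized intensity between hemodynamically shifted active-trial
    volumes and passive-trial volumes.  Returns a 3-D map.
    """
    data = dataset.data.reshape(-1, dataset.data.shape[-1]).astype(float)
    pct = 100.0 * (data / data.mean(axis=1, keepdims=True) - 1.0)
    vps = dataset.volumes_per_scan
    active = np.zeros(data.shape[1], dtype=bool)
    passive = np.zeros(data.shape[1], dtype=bool)
    for row in dataset.events.itertuples():
        v = int(row.volume) + shift
        if v >= vps:
            continue
        g = int(row.scan) * vps + v
        if row.condition.startswith("passive"):
            passive[g] = True
        else:
            active[g] = True
    a, p = pct[:, active], pct[:, passive]
    na, npv = a.shape[1], p.shape[1]
    pooled = np.sqrt(a.var(axis=1, ddof=1) / na + p.var(axis=1, ddof=1) / npv)
    pooled[pooled == 0] = np.inf
    t = (a.mean(axis=1) - p.mean(axis=1)) / pooled
    return t.reshape(dataset.data.shape[:3])


def select_voxels(stat_map: np.ndarray, roi_mask: np.ndarray,
                  k: int = 100) -> np.ndarray:
    """Flat indices of the ``k`` most activated voxels within a mask.

    Ties are broken deterministically by voxel index (stable sort on the
    negated statistic).
    """
    mask_idx = np.flatnonzero(np.asarray(roi_mask).ravel())
    if mask_idx.size < k:
        raise ValueError(
            f"ROI has only {mask_idx.size} voxels, cannot select {k}")
    vals = np.asarray(stat_map).ravel()[mask_idx]
    order = np.argsort(-vals, kind="stable")[:k]
    return np.sort(mask_idx[order])


def extract_timeseries(dataset: BoldDataset, voxel_idx: np.ndarray) -> np.ndarray:
    """Raw time courses (n_voxels, T) for the given flat voxel indices."""
    return dataset.data.reshape(-1, dataset.data.shape[-1])[voxel_idx].astype(float)


def preprocess(ts: np.ndarray, volumes_per_scan: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Detrend and z-score each voxel, then project out the ROI-mean course.

    Per-voxel linear trend removal (the minimal preprocessing step), then
    z-scoring to mean 0 / SD 1, then regression of the ROI-mean time course
    out of every voxel (removing the univariate signal).  All steps are
    applied per scan when ``volumes_per_scan`` is given.  Zero-variance
    voxels are excluded (logged); returns ``(ts, kept_idx)`` where
    ``kept_idx`` maps rows of the output to rows of the input.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[-1] < 2:
        raise ValueError("need at least two volumes")
    T = ts.shape[1]
    vps = volumes_per_scan or T
    if T % vps:
        raise ValueError("time axis is not a whole number of scans")
    sd = ts.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < ts.shape[0]:
        log.warning("excluding %d zero-variance voxel(s)",
                    ts.shape[0] - kept.size)
    ts = ts[kept]
    out = np.empty_like(ts)
    for s in range(T // vps):
        blk = signal.detrend(ts[:, s * vps:(s + 1) * vps], axis=1)
        z = (blk - blk.mean(axis=1, keepdims=True))
        z /= z.std(axis=1, keepdims=True)
        m = z.mean(axis=0)
        m = m / np.linalg.norm(m) if np.linalg.norm(m) > 0 else m
        out[:, s * vps:(s + 1) * vps] = z - np.outer(z @ m, m)
    return out, kept


def _trial_labels(events: pd.DataFrame, comparison: str, side: str) -> pd.DataFrame:
    ev = events[~events["condition"].str.startswith("passive")].copy()
    if comparison == "attended_vs_unattended":
        ev["label"] = np.where(ev["cue_side"] == side, "attended", "unattended")
    elif comparison == "cw_vs_ccw":
        ev = ev[ev["cue_side"] == side].copy()
        ev["label"] = ev["attended_direction"]
    elif comparison == "same_vs_different":
        ev = ev[ev["cue_side"] != side].copy()
        ev["label"] = ev["similarity"]
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    return ev


def build_patterns(ts: np.ndarray, events: pd.DataFrame, comparison: str,
                   side: str, volumes_per_scan: int, shift: int = 1,
                   rng: np.random.Generator | None = None,
                   pair: bool = True) -> PatternSet:
    """Extract trial patterns at the shifted lag and pair-average them.

    ``ts`` is the preprocessed (voxels, T) matrix; ``side`` is the visual
    field of the cylinder the ROI responds to.  Trials are paired within
    their block (randomized pairing within the four same-condition trials
    of a block), and every pattern carries its block as a group id so that
    cross-validation folds never split a block between training and test —
    temporally adjacent trials share autocorrelated noise, and separating
    them is what keeps null-signal accuracy at chance.  A trial whose
    shifted volume would fall past the end of the scan is clamped to the
    last acquired volume (logged); odd unpaired trials are dropped (logged).
    """
    rng = rng or np.random.default_rng()
    ev = _trial_labels(events, comparison, side)
    vols, labels, trial_ids, blocks = [], [], [], []
    clamped = 0
    for row in ev.itertuples():
        v = int(row.volume) + shift
        if v >= volumes_per_scan:
            v = volumes_per_scan - 1
            clamped += 1
        vols.append(int(row.scan) * volumes_per_scan + v)
        labels.append(row.label)
        trial_ids.append(row.Index)
        blocks.append(int(row.scan) * 10_000 + int(row.block))
    if clamped:
        log.debug("clamped %d trial(s) whose shifted volume left the scan",
                  clamped)
    vols = np.asarray(vols)
    labels = np.asarray(labels)
    trial_ids = np.asarray(trial_ids)
    blocks = np.asarray(blocks)
    trials = ts[:, vols].T  # (n_trials, n_voxels)
    if not pair:
        return PatternSet(X=trials, y=labels, comparison=comparison,
                          provenance=[(int(t),) for t in trial_ids],
                          groups=blocks)
    X_rows, y_rows, prov, grp = [], [], [], []
    for blk in np.unique(blocks):
        sel = np.flatnonzero(blocks == blk)
        lab = labels[sel[0]]
        idx = rng.permutation(sel)
        if idx.size % 2:
            log.debug("dropping one unpaired %r trial", lab)
            idx = idx[:-1]
        for a, b in idx.reshape(-1, 2):
            X_rows.append((trials[a] + trials[b]) / 2.0)
            y_rows.append(lab)
            prov.append((int(trial_ids[a]), int(trial_ids[b])))
            grp.append(blk)
    return PatternSet(X=np.asarray(X_rows), y=np.asarray(y_rows),
                      comparison=comparison, provenance=prov,
                      groups=np.asarray(grp))


def _group_folds(y: np.ndarray, groups: np.ndarray,
                 rng: np.random.Generator, folds: int) -> np.ndarray:
    """Fold index per pattern: blocks stay intact, classes stay balanced.

    Each group (block) is assigned whole to one fold; groups are stratified
    by their majority label and dealt round-robin after shuffling, keeping
    class balance within +-1 group.  Re-drawn (logged) if some training
    split would lack a class.
    """
    uniq = np.unique(groups)
    grp_label = np.array([pd.Series(y[groups == g]).mode()[0] for g in uniq])
    for attempt in range(50):
        fold_of = {}
        for lab in np.unique(grp_label):
            gs = rng.permutation(uniq[grp_label == lab])
            offset = int(rng.integers(folds))
            for i, g in enumerate(gs):
                fold_of[g] = (i + offset) % folds
        fold_idx = np.array([fold_of[g] for g in groups])
        ok = all(np.unique(y[fold_idx != f]).size == np.unique(y).size
                 and np.any(fold_idx == f) for f in range(folds))
        if ok:
            return fold_idx
        log.debug("re-drawing stratified group folds (attempt %d)", attempt + 1)
    raise ValueError("could not build folds with every class in training")


def _cv_accuracy(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                 C: float, folds: int,
                 groups: np.ndarray | None = None) -> float:
    """One stratified ``folds``-fold cross-validated accuracy.

    With ``groups`` given, folds are built over whole groups (blocks).
    """
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < folds:
        raise ValueError("too few patterns per class for the requested folds")
    if groups is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        splits = skf.split(X, y)
    else:
        fold_idx = _group_folds(y, groups, rng, folds)
        splits = ((np.flatnonzero(fold_idx != f), np.flatnonzero(fold_idx == f))
                  for f in range(folds))
    correct = total = 0
    for train, test in splits:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
        total += len(test)
    return correct / total


def classify(patterns, C: float = 1.0, folds: int = 5,
             iterations: int = 10_000, seed: int = 0, alpha: float = 0.05,
             n_areas: int = 7) -> ClassifierResult:
    """Iterated cross-validated linear-SVM accuracy.

    ``patterns`` is a :class:`PatternSet` (iterations re-randomize the fold
    assignment) or a callable ``rng -> PatternSet`` (iterations re-randomize
    trial pairing as well).  The confidence interval over iterations is the
    Bonferroni-corrected 95% percentile interval (correction over
    ``n_areas`` simultaneously tested areas).
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(iterations)
    for i in range(iterations):
        ps = patterns(rng) if callable(patterns) else patterns
        accs[i] = _cv_accuracy(ps.X, ps.y, rng, C, folds, groups=ps.groups)
    a = alpha / n_areas
    ci = (float(np.percentile(accs, 100 * a / 2)),
          float(np.percentile(accs, 100 * (1 - a / 2))))
    return ClassifierResult(accuracies=accs, mean_accuracy=float(accs.mean()),
                            ci=ci, alpha=alpha, n_areas=n_areas)


def permutation_test(patterns, n_perm: int = 10_000, seed: int = 0,
                     C: float = 1.0, folds: int = 5, alpha: float = 0.05,
                     n_areas: int = 7,
                     observed: ClassifierResult | None = None,
                     observed_iterations: int = 100) -> PermutationResult:
    """Label-shuffled empirical null for the classification analysis.

    Classifier parameters are identical to the observed analysis; only the
    labels are permuted.  The observed mean accuracy is significant when it
    falls strictly outside the null's Bonferroni-corrected 95% interval
    (values on the boundary are non-significant).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable null distribution",
                      stacklevel=2)
        log.warning("permutation test with n_perm=%d (<100): unstable null",
                    n_perm)
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = classify(patterns, C=C, folds=folds,
                            iterations=observed_iterations,
                            seed=int(rng.integers(2 ** 31)),
                            alpha=alpha, n_areas=n_areas)
    null = np.empty(n_perm)
    for i in range(n_perm):
        ps = patterns(rng) if callable(patterns) else patterns
        y_perm = rng.permutation(ps.y)
        null[i] = _cv_accuracy(ps.X, y_perm, rng, C, folds, groups=ps.groups)
    a = alpha / n_areas
    lo = float(np.percentile(null, 100 * a / 2))
    hi = float(np.percentile(null, 100 * (1 - a / 2)))
    obs = observed.mean_accuracy
    return PermutationResult(observed_mean=obs, null=null,
                             null_mean=float(null.mean()), null_ci=(lo, hi),
                             significant=bool(obs < lo or obs > hi),
                             n_perm=n_perm)


def decode(dataset: BoldDataset, roi_name: str, hemisphere: str,
           comparison: str, k: int = 100, iterations: int = 100,
           seed: int = 0, C: float = 1.0, folds: int = 5, shift: int = 1,
           alpha: float = 0.05, n_areas: int = 7,
           stat_map: np.ndarray | None = None,
           n_perm: int = 0) -> tuple[ClassifierResult, PermutationResult | None]:
    """Full decoding pipeline for one ROI and one comparison.

    Voxel selection -> z-scoring and ROI-mean projection -> shifted trial
    patterns with randomized pairing per iteration -> iterated 5-fold SVM.
    With ``n_perm > 0`` a permutation null is run with identical parameters.
    """
    if stat_map is None:
        stat_map = localizer_stats(dataset, shift=shift)
    try:
        mask = dataset.roi_mask(roi_name, hemisphere)
    except KeyError:
        raise
    voxels = select_voxels(stat_map, mask, k=k)
    ts = extract_timeseries(dataset, voxels)
    ts, _ = preprocess(ts, dataset.volumes_per_scan)
    side = contralateral_side(hemisphere)

    def builder(rng: np.random.Generator) -> PatternSet:
        return build_patterns(ts, dataset.events, comparison, side,
                              dataset.volumes_per_scan, shift=shift, rng=rng)

    result = classify(builder, C=C, folds=folds, iterations=iterations,
                      seed=seed, alpha=alpha, n_areas=n_areas)
    perm = None
    if n_perm > 0:
        perm = permutation_test(builder, n_perm=n_perm, seed=seed + 1, C=C,
                                folds=folds, alpha=alpha, n_areas=n_areas,
                                observed=result)
    return result, perm
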