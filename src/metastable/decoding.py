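"""Sliding-window linear decoding of stimulus identity.

Spike counts in 100 ms windows (10 ms steps for recordings, 20 ms for the
model) form a units x trials x windows tensor; a multiclass linear
discriminant classifier is evaluated per window with ten repeats of
stratified 5-fold cross-validation (50 train-test fits).  Significance of
the peak accuracy is assessed against 100 label shuffles.  Arousal
conditioning splits trials by pre-stimulus pupil-diameter deciles with
per-tone balancing; session pooling z-scores the per-decile peak
accuracies within a session and bins them by pupil diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import wilcoxon
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

# Small ridge on the pooled covariance guards against singular
# within-class covariance for sparse spike counts.
LDA_SHRINKAGE = 0.01


class _PooledCovLDA:
    """Multiclass LDA decision rule with a shrunk pooled covariance.

    Implements exactly the lsqr/shrinkage linear discriminant: class means
    mu_c, pooled within-class covariance S shrunk toward its scaled
    identity, scores x @ S^-1 mu_c - mu_c S^-1 mu_c / 2 + log pi_c.  It is
    equivalent to scikit-learn's ``LinearDiscriminantAnalysis(solver='lsqr',
    shrinkage=...)`` (asserted in the test suite) but without per-fit
    validation overhead, which dominates at tens of thousands of small
    fits.
    """

    def __init__(self, shrinkage: float = LDA_SHRINKAGE):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        classes, inv = np.unique(y, return_inverse=True)
        n, p = X.shape
        means = np.stack([X[inv == k].mean(axis=0)
                          for k in range(classes.size)])
        Xc = X - means[inv]
        cov = (Xc.T @ Xc) / n
        mu = np.trace(cov) / p
        cov = (1.0 - self.shrinkage) * cov + self.shrinkage * mu * np.eye(p)
        priors = np.bincount(inv) / n
        coef = np.linalg.solve(cov, means.T).T
        intercept = -0.5 * np.einsum("cp,cp->c", means, coef) + np.log(priors)
        self.classes_, self.coef_, self.intercept_ = classes, coef, intercept
        return self

    def predict(self, X):
        scores = np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_
        return self.classes_[np.argmax(scores, axis=1)]


def _classifier():
    return _PooledCovLDA(shrinkage=LDA_SHRINKAGE)


@dataclass
class TrialTensor:
    counts: np.ndarray        # (units, trials, windows), integer spike counts
    labels: np.ndarray        # stimulus id per trial
    window_starts: np.ndarray  # (windows,), seconds relative to onset
    window: float = 0.1

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window / 2.0

    def select_trials(self, idx) -> "TrialTensor":
        return TrialTensor(self.counts[:, idx, :], self.labels[idx],
                           self.window_starts, self.window)

    def select_units(self, idx) -> "TrialTensor":
        return TrialTensor(self.counts[idx], self.labels, self.window_starts,
                           self.window)


def sliding_counts(trials: Sequence, units: np.ndarray,
                   window: float = 0.1, step: float = 0.02,
                   t_range: tuple = (-0.1, 0.6)) -> TrialTensor:
    """Bin spikes of the given units in a sliding window per trial.

    ``trials`` is a sequence of :class:`metastable.simulate.SpikeData`
    (times are aligned to stimulus onset internally).  Window start times
    run from ``t_range[0]`` to ``t_range[1] - window``.
    """
    units = np.asarray(units)
    starts = np.arange(t_range[0], t_range[1] - window + 1e-9, step)
    counts = np.zeros((units.size, len(trials), starts.size), dtype=np.int64)
    labels = np.empty(len(trials), dtype=np.int64)
    for k, sd in enumerate(trials):
        labels[k] = -1 if sd.stimulus_id is None else sd.stimulus_id
        t = sd.align()
        order = np.lexsort((t, sd.ids))
        ids_s, t_s = sd.ids[order], t[order]
        bounds = np.searchsorted(ids_s, np.stack([units, units + 1]))
        for u in range(units.size):
            ut = t_s[bounds[0, u]:bounds[1, u]]
            counts[u, k] = (np.searchsorted(ut, starts + window)
                            - np.searchsorted(ut, starts))
    return TrialTensor(counts=counts, labels=labels, window_starts=starts,
                       window=window)


@dataclass
class DecodingResult:
    accuracy: np.ndarray
    window_starts: np.ndarray
    peak_accuracy: float
    peak_window: tuple
    null_accuracies: Optional[np.ndarray] = None
    significant: Optional[bool] = None
    meta: dict = field(default_factory=dict)


def decode_timecourse(tensor: TrialTensor, seed: int, n_folds: int = 5,
                      n_repeats: int = 10) -> DecodingResult:
    """Cross-validated accuracy per window; ties broken by earliest window."""
    classes, cnt = np.unique(tensor.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("decoding requires at least two stimulus classes")
    if cnt.min() < n_folds:
        raise ValueError(
            f"class with {cnt.min()} trials cannot be split into {n_folds} folds")
    n_windows = tensor.window_starts.size
    acc = np.zeros(n_windows)
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                 random_state=seed % (2**32 - 1))
    splits = list(cv.split(np.zeros(tensor.labels.size), tensor.labels))
    for w in range(n_windows):
        X = tensor.counts[:, :, w].T.astype(float)
        scores = []
        for tr_idx, te_idx in splits:
            clf = _classifier()
            clf.fit(X[tr_idx], tensor.labels[tr_idx])
            scores.append(np.mean(clf.predict(X[te_idx]) == tensor.labels[te_idx]))
        acc[w] = np.mean(scores)
    peak = int(np.argmax(acc))     # argmax returns the earliest tie
    return DecodingResult(
        accuracy=acc, window_starts=tensor.window_starts,
        peak_accuracy=float(acc[peak]),
        peak_window=(float(tensor.window_starts[peak]),
                     float(tensor.window_starts[peak] + tensor.window)),
        meta={"n_splits": len(splits)})


def shuffle_null(tensor: TrialTensor, window_index: int, seed: int,
                 n_shuffles: int = 100, test_size: float = 0.2,
                 true_accuracy: Optional[float] = None):
    """Label-shuffle null distribution of accuracy at one window.

    Each shuffle permutes the stimulus labels, then evaluates one
    stratified 80/20 train-test split.  Returns the null accuracies and,
    when ``true_accuracy`` is given, whether it exceeds the null's 95th
    percentile.
    """
    rng = np.random.default_rng(seed)
    X = tensor.counts[:, :, window_index].T.astype(float)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        y = rng.permutation(tensor.labels)
        tr_idx, te_idx = train_test_split(
            np.arange(y.size), test_size=test_size, stratify=y,
            random_state=int(rng.integers(2**32 - 1)))
        clf = _classifier()
        clf.fit(X[tr_idx], y[tr_idx])
        null[s] = np.mean(clf.predict(X[te_idx]) == y[te_idx])
    significant = None
    if true_accuracy is not None:
        significant = bool(true_accuracy > np.percentile(null, 95))
    return null, significant


@dataclass
class PupilPartition:
    edges: np.ndarray             # decile edges of pre-stimulus pupil diameter
    assignment: np.ndarray        # decile index per trial (-1 = excluded)
    balanced_trials: list         # per-decile trial indices, tone-balanced
    centers: np.ndarray           # mean pupil diameter per decile


def pupil_partition(pupil_values: np.ndarray, labels: np.ndarray, seed: int,
                    velocity: Optional[np.ndarray] = None,
                    velocity_threshold: float = 1.0,
                    n_bins: int = 10) -> PupilPartition:
    """Decile partition of trials by pre-stimulus pupil diameter.

    Optionally excludes locomotion trials (pre-stimulus treadmill velocity
    above 1 cm/s) before computing the deciles.  Within each decile, trials
    are randomly subsampled so every stimulus has the same count.
    """
    rng = np.random.default_rng(seed)
    pupil_values = np.asarray(pupil_values, dtype=float)
    keep = np.ones(pupil_values.size, dtype=bool)
    if velocity is not None:
        keep &= np.asarray(velocity) <= velocity_threshold
    idx = np.flatnonzero(keep)
    edges = np.quantile(pupil_values[idx], np.linspace(0, 1, n_bins + 1))
    assignment = np.full(pupil_values.size, -1, dtype=np.int64)
    bins = np.clip(np.searchsorted(edges[1:-1], pupil_values[idx],
                                   side="right"), 0, n_bins - 1)
    assignment[idx] = bins
    balanced, centers = [], []
    for b in range(n_bins):
        sel = np.flatnonzero(assignment == b)
        per_tone = [sel[labels[sel] == c] for c in np.unique(labels[sel])]
        n_min = min((len(g) for g in per_tone), default=0)
        chosen = np.sort(np.concatenate(
            [rng.choice(g, n_min, replace=False) for g in per_tone])) \
            if n_min else np.array([], dtype=np.int64)
        balanced.append(chosen)
        centers.append(pupil_values[sel].mean() if sel.size else np.nan)
    return PupilPartition(edges=edges, assignment=assignment,
                          balanced_trials=balanced,
                          centers=np.asarray(centers))


def model_feature_sample(tensor: TrialTensor, unit_ids: np.ndarray,
                         membership_E: np.ndarray, seed: int,
                         n_runs: int = 25, uniform: bool = False,
                         n_folds: int = 5, n_repeats: int = 10) -> DecodingResult:
    """Decoding with the model's feature-sampling scheme, averaged over runs.

    Clustered networks: one E cell per cluster plus one background cell
    (p+1 features).  Uniform networks: p+1 E cells at random.  ``tensor``
    must contain all candidate units (``unit_ids`` gives the neuron id of
    each tensor row).
    """
    rng = np.random.default_rng(seed)
    p = int(membership_E.max()) - 1
    acc = None
    for run in range(n_runs):
        if uniform:
            rows = rng.choice(unit_ids.size, size=p + 1, replace=False)
        else:
            rows = []
            for c in range(1, p + 2):
                members = np.flatnonzero(membership_E[unit_ids] == c)
                rows.append(rng.choice(members))
            rows = np.array(rows)
        res = decode_timecourse(tensor.select_units(rows),
                                seed=int(rng.integers(2**31 - 1)),
                                n_folds=n_folds, n_repeats=n_repeats)
        acc = res.accuracy if acc is None else acc + res.accuracy
    acc = acc / n_runs
    peak = int(np.argmax(acc))
    return DecodingResult(
        accuracy=acc, window_starts=tensor.window_starts,
        peak_accuracy=float(acc[peak]),
        peak_window=(float(tensor.window_starts[peak]),
                     float(tensor.window_starts[peak] + tensor.window)),
        meta={"n_runs": n_runs, "n_features": p + 1})


def pool_sessions(session_accuracies: Sequence[np.ndarray],
                  session_pupil_centers: Sequence[np.ndarray],
                  bin_width: float = 0.1) -> dict:
    """Pool per-decile peak accuracies across sessions.

    Accuracies are z-scored within each session, assigned to non-overlapping
    pupil bins of width 10% of maximum diameter (diameters are fractions of
    max), same-session points in one bin are averaged first, and the
    session values are then averaged per bin.
    """
    n_bins = int(round(1.0 / bin_width))
    per_bin = [[] for _ in range(n_bins)]
    for acc, centers in zip(session_accuracies, session_pupil_centers):
        acc = np.asarray(acc, dtype=float)
        z = (acc - acc.mean()) / acc.std(ddof=0)
        bins = np.clip((np.asarray(centers) / bin_width).astype(int), 0, n_bins - 1)
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                per_bin[b].append(float(z[sel].mean()))
    mean = np.array([np.mean(v) if v else np.nan for v in per_bin])
    sd = np.array([np.std(v) if v else np.nan for v in per_bin])
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return {"bin_centers": centers, "mean": mean, "sd": sd,
            "values": per_bin}


def mid_vs_extreme(session_accuracies: Sequence[np.ndarray],
                   session_pupil_centers: Sequence[np.ndarray],
                   low_cut: float = 0.25, high_cut: float = 0.75) -> dict:
    """Compare the most-central pupil decile against the first/last decile.

    The central decile is the one centered closest to 50% of maximum
    dilation.  Sessions enter the low comparison only when their first
    decile is centered below 25% of maximum, and the high comparison only
    when their last decile is centered above 75%.  Paired Wilcoxon
    signed-rank tests.
    """
    mid_low, low, mid_high, high = [], [], [], []
    for acc, centers in zip(session_accuracies, session_pupil_centers):
        acc = np.asarray(acc, dtype=float)
        centers = np.asarray(centers, dtype=float)
        c_idx = int(np.argmin(np.abs(centers - 0.5)))
        if centers[0] < low_cut:
            mid_low.append(acc[c_idx])
            low.append(acc[0])
        if centers[-1] > high_cut:
            mid_high.append(acc[c_idx])
            high.append(acc[-1])
    out = {"n_low_sessions": len(low), "n_high_sessions": len(high)}
    if len(low) >= 5:
        out["p_mid_vs_low"] = float(wilcoxon(mid_low, low).pvalue)
        out["mid_minus_low"] = float(np.mean(np.array(mid_low) - np.array(low)))
    if len(high) >= 5:
        out["p_mid_vs_high"] = float(wilcoxon(mid_high, high).pvalue)
        out["mid_minus_high"] = float(np.mean(np.array(mid_high) - np.array(high)))
    return out
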