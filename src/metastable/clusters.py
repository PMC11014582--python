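"""Cluster-level summaries of simulated activity.

Cluster firing rates are single-neuron rates (25 ms Gaussian kernel, 1 ms
grid) averaged over the cluster's members.  A cluster is "active" at a
time point when its rate is at least 15 spikes/s; the number of active
clusters nA, its distribution, conditional active/inactive rates and the
mean activation duration summarize the metastable dynamics.  Evoked
metrics (cluster signal and reliability) compare stimulus-targeted to
non-targeted clusters inside the peak decoding window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .params import CLUSTER_ACTIVE_THRESHOLD
from .simulate import SpikeData

KERNEL_SD_S = 0.025     # "width" of the rate kernel, interpreted as the SD
RATE_DT_S = 0.001


@dataclass
class ClusterRateMatrix:
    """Per-cluster rates on a 1 ms grid; ``t`` is relative to trial start."""

    rates: np.ndarray      # (n_clusters, n_bins)
    t: np.ndarray          # bin centers (s)
    t_stim: Optional[float] = None

    def aligned_t(self) -> np.ndarray:
        return self.t - (self.t_stim or 0.0)

    def window_mask(self, window: tuple) -> np.ndarray:
        ta = self.aligned_t()
        return (ta >= window[0]) & (ta < window[1])


def cluster_rates(spikes: SpikeData, membership_E: np.ndarray,
                  n_clusters: Optional[int] = None,
                  kernel_sd: float = KERNEL_SD_S) -> ClusterRateMatrix:
    """Kernel-smoothed cluster rates averaged over member neurons.

    ``membership_E`` assigns each E cell a cluster label (1..p, background
    p+1); only clustered cells (label <= p) contribute.
    """
    if n_clusters is None:
        n_clusters = int(membership_E.max()) - 1
    n_bins = int(round(spikes.T / RATE_DT_S))
    edges = np.arange(n_bins + 1) * RATE_DT_S
    sigma_bins = kernel_sd / RATE_DT_S
    in_E = spikes.ids < membership_E.size
    ids, times = spikes.ids[in_E], spikes.times[in_E]
    labels = membership_E[ids]
    clustered = labels <= n_clusters
    H = np.histogram2d(labels[clustered].astype(float), times[clustered],
                       bins=[np.arange(0.5, n_clusters + 1.5), edges])[0]
    members = np.array([(membership_E == c).sum()
                        for c in range(1, n_clusters + 1)], dtype=float)
    members[members == 0] = np.inf
    R = gaussian_filter1d(H, sigma_bins, axis=1, truncate=4.0) \
        / (RATE_DT_S * members[:, None])
    return ClusterRateMatrix(rates=R, t=0.5 * (edges[:-1] + edges[1:]),
                             t_stim=spikes.t_stim)


def baseline_subtract(trials: Sequence[ClusterRateMatrix],
                      baseline_window: tuple = (-0.8, 0.0)) -> list:
    """gc(t): subtract each cluster's time- and trial-averaged baseline."""
    base = np.mean([tr.rates[:, tr.window_mask(baseline_window)].mean(axis=1)
                    for tr in trials], axis=0)
    return [ClusterRateMatrix(rates=tr.rates - base[:, None], t=tr.t,
                              t_stim=tr.t_stim) for tr in trials]


@dataclass
class ClusterStateSummary:
    P_nA: np.ndarray
    r_up: np.ndarray       # active-cluster rate conditioned on nA
    r_down: np.ndarray
    nA_star: int
    tau_activation: float


def _active(rates: np.ndarray,
            threshold: float = CLUSTER_ACTIVE_THRESHOLD) -> np.ndarray:
    return rates >= threshold


def state_summary(trials: Sequence[ClusterRateMatrix],
                  window: tuple = (-0.8, -0.1),
                  threshold: float = CLUSTER_ACTIVE_THRESHOLD) -> ClusterStateSummary:
    """P(nA) and conditional active/inactive rates, pooled over time points."""
    p = trials[0].rates.shape[0]
    counts = np.zeros(p + 1)
    sum_up = np.zeros(p + 1)
    n_up = np.zeros(p + 1)
    sum_dn = np.zeros(p + 1)
    n_dn = np.zeros(p + 1)
    for tr in trials:
        R = tr.rates[:, tr.window_mask(window)]
        act = _active(R, threshold)
        nA = act.sum(axis=0)
        for k in range(p + 1):
            sel = nA == k
            if not sel.any():
                continue
            counts[k] += sel.sum()
            sum_up[k] += R[:, sel][act[:, sel]].sum()
            n_up[k] += act[:, sel].sum()
            sum_dn[k] += R[:, sel][~act[:, sel]].sum()
            n_dn[k] += (~act[:, sel]).sum()
    P = counts / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_up = np.where(n_up > 0, sum_up / n_up, np.nan)
        r_down = np.where(n_dn > 0, sum_dn / n_dn, np.nan)
    return ClusterStateSummary(P_nA=P, r_up=r_up, r_down=r_down,
                               nA_star=int(np.argmax(P)),
                               tau_activation=activation_timescale(trials, window,
                                                                   threshold))


def activation_durations(active: np.ndarray, dt: float = RATE_DT_S) -> list:
    """Durations of True-runs in a boolean series, including runs clipped
    by the window edges (counted with their visible length)."""
    d = np.diff(active.astype(np.int8))
    on = np.flatnonzero(d == 1) + 1
    off = np.flatnonzero(d == -1) + 1
    if active.size and active[0]:
        on = np.r_[0, on]
    if active.size and active[-1]:
        off = np.r_[off, active.size]
    return list((off - on) * dt)


def activation_timescale(trials: Sequence[ClusterRateMatrix],
                         window: tuple = (-0.8, -0.1),
                         threshold: float = CLUSTER_ACTIVE_THRESHOLD) -> float:
    """Mean duration of cluster activation periods inside the window."""
    durs = []
    for tr in trials:
        act = _active(tr.rates[:, tr.window_mask(window)], threshold)
        for c in range(act.shape[0]):
            durs += activation_durations(act[c])
    return float(np.mean(durs)) if durs else np.nan


def cluster_signal(trials: Sequence[ClusterRateMatrix],
                   targeted: Sequence[np.ndarray],
                   stimulus_ids: Sequence[int],
                   peak_window: tuple) -> float:
    """Mean targeted-minus-nontargeted cluster rate in the peak window.

    ``targeted[s]`` holds the 1-based targeted cluster indices of stimulus
    s; the difference is averaged across the window per trial and then
    across trials and stimuli.
    """
    vals = []
    for tr, s in zip(trials, stimulus_ids):
        mask = tr.window_mask(peak_window)
        tset = np.zeros(tr.rates.shape[0], dtype=bool)
        tset[np.asarray(targeted[s]) - 1] = True
        rT = tr.rates[tset][:, mask].mean(axis=0)
        rN = tr.rates[~tset][:, mask].mean(axis=0)
        vals.append(float(np.mean(rT - rN)))
    return float(np.mean(vals))


def cluster_reliability(baseline_trials: Sequence[ClusterRateMatrix],
                        targeted: Sequence[np.ndarray],
                        stimulus_ids: Sequence[int],
                        peak_window: tuple,
                        min_duration: float = 0.025,
                        threshold: float = 1.0) -> float:
    """Difference in the fractions of targeted / non-targeted clusters that
    stay activated above baseline (gc > 1 spk/s) for at least 25 ms of the
    peak decoding window."""
    vals = []
    for tr, s in zip(baseline_trials, stimulus_ids):
        mask = tr.window_mask(peak_window)
        act = tr.rates[:, mask] > threshold
        long_on = np.array([max(activation_durations(a), default=0.0) >= min_duration
                            for a in act])
        tset = np.zeros(tr.rates.shape[0], dtype=bool)
        tset[np.asarray(targeted[s]) - 1] = True
        vals.append(float(long_on[tset].mean() - long_on[~tset].mean()))
    return float(np.mean(vals))


def auxiliary_metrics(trials: Sequence[ClusterRateMatrix],
                      baseline_trials: Sequence[ClusterRateMatrix],
                      targeted: Sequence[np.ndarray],
                      stimulus_ids: Sequence[int],
                      peak_window: tuple,
                      threshold: float = CLUSTER_ACTIVE_THRESHOLD) -> dict:
    """f_up_in_T (spontaneous and evoked) and the activation-time difference.

    f_up_in_T(t) is the fraction of active clusters belonging to the
    targeted subset; the spontaneous value averages the 100 ms before
    onset, the evoked value the peak decoding window.  delta_tau is the
    targeted-minus-nontargeted mean fraction of the peak window spent
    activated above baseline.
    """
    f_spont, f_evoked, dtau = [], [], []
    for tr, btr, s in zip(trials, baseline_trials, stimulus_ids):
        tset = np.zeros(tr.rates.shape[0], dtype=bool)
        tset[np.asarray(targeted[s]) - 1] = True

        def f_in_T(mask):
            act = _active(tr.rates[:, mask], threshold)
            nact = act.sum(axis=0).astype(float)
            with np.errstate(invalid="ignore"):
                frac = act[tset].sum(axis=0) / nact
            return float(np.nanmean(frac)) if np.any(nact > 0) else np.nan

        f_spont.append(f_in_T(tr.window_mask((-0.1, 0.0))))
        f_evoked.append(f_in_T(tr.window_mask(peak_window)))
        act_base = btr.rates[:, btr.window_mask(peak_window)] > 1.0
        tau_frac = act_base.mean(axis=1)
        dtau.append(float(tau_frac[tset].mean() - tau_frac[~tset].mean()))
    return {
        "f_up_in_T_spont": float(np.nanmean(f_spont)),
        "f_up_in_T_evoked": float(np.nanmean(f_evoked)),
        "delta_tau": float(np.mean(dtau)),
    }
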