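"""Single-cell discriminability, Fano factors and multitaper spike spectra.

d' quantifies the separation of a cell's responses to two stimuli:
|mu_a - mu_b| / sqrt((sigma_a^2 + sigma_b^2)/2) on windowed spike counts.
The Fano factor is the across-trial spike-count variance over the mean; the
evoked value is read out at the time of the minimum of the cell-averaged
Fano timecourse.  Spectra use the multitaper point-process estimator
(1 ms bins, time-bandwidth product TW=5, 2TW-1=9 DPSS tapers) normalized
by the firing rate, so a homogeneous Poisson train has unit spectrum; the
low-frequency power P_L is the 1-4 Hz band average (inclusive bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import dpss

from .decoding import TrialTensor

MT_TW = 5.0
MT_N_TAPERS = int(2 * MT_TW - 1)
MT_BIN_S = 0.001
LOW_FREQ_BAND = (1.0, 4.0)


def dprime_pair(responses_a: np.ndarray, responses_b: np.ndarray) -> float:
    """d' between two response samples (non-negative).

    Degenerate case: zero pooled variance with equal means yields 0; with
    unequal means the pair is undefined and NaN is returned for the caller
    to exclude.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    var = 0.5 * (a.var(ddof=0) + b.var(ddof=0))
    diff = abs(a.mean() - b.mean())
    if var == 0.0:
        return 0.0 if diff == 0.0 else np.nan
    return float(diff / np.sqrt(var))


@dataclass
class DPrimeResult:
    d_cell_time: np.ndarray     # (cells, windows): pair-averaged d'
    d_time: np.ndarray          # cell-averaged timecourse
    t_star_index: int
    D_sc_cell: np.ndarray       # per-cell index at t*
    D_sc: float                 # population index = max of d_time
    window_starts: np.ndarray


def dsc_pipeline(tensor: TrialTensor) -> DPrimeResult:
    """Pairwise-averaged single-cell discriminability over time."""
    classes = np.unique(tensor.labels)
    n_units, _, n_windows = tensor.counts.shape
    groups = [tensor.counts[:, tensor.labels == c, :] for c in classes]
    mus = np.stack([g.mean(axis=1) for g in groups])        # (cls, units, win)
    vs = np.stack([g.var(axis=1, ddof=0) for g in groups])
    pairs = [(i, j) for i in range(len(classes)) for j in range(i + 1, len(classes))]
    d = np.zeros((len(pairs), n_units, n_windows))
    for k, (i, j) in enumerate(pairs):
        var = 0.5 * (vs[i] + vs[j])
        diff = np.abs(mus[i] - mus[j])
        with np.errstate(invalid="ignore", divide="ignore"):
            dk = diff / np.sqrt(var)
        dk[(var == 0) & (diff == 0)] = 0.0
        dk[(var == 0) & (diff != 0)] = np.nan
        d[k] = dk
    d_cell_time = np.nanmean(d, axis=0)
    d_time = np.nanmean(d_cell_time, axis=0)
    t_star = int(np.argmax(d_time))
    return DPrimeResult(d_cell_time=d_cell_time, d_time=d_time,
                        t_star_index=t_star,
                        D_sc_cell=d_cell_time[:, t_star],
                        D_sc=float(d_time[t_star]),
                        window_starts=tensor.window_starts)


@dataclass
class FanoResult:
    ff_cell_time: np.ndarray    # (cells, windows); NaN where mean count = 0
    ff_time: np.ndarray         # cell-averaged timecourse
    window_starts: np.ndarray
    ff_spont: np.ndarray        # per cell, bin immediately preceding onset
    t_ff_min_index: Optional[int] = None
    ff_evoked: Optional[np.ndarray] = None
    delta_ff: Optional[np.ndarray] = None


def fano_timecourse(tensor: TrialTensor, evoked_range: tuple = (0.0, 0.2),
                    cells: Optional[np.ndarray] = None) -> FanoResult:
    """Fano factor per cell and window; evoked FF at the timecourse minimum.

    The spontaneous FF is the window immediately preceding stimulus onset;
    the evoked FF is evaluated at the minimum of the cell-averaged trace
    among windows ending within ``evoked_range`` after onset.  Cells with
    zero mean count in a window are excluded (NaN) there.
    """
    counts = tensor.counts if cells is None else tensor.counts[cells]
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    ff_time = np.nanmean(ff, axis=0)
    ends = tensor.window_starts + tensor.window
    pre = np.flatnonzero(ends <= 0.0)
    spont_idx = int(pre[-1]) if pre.size else 0
    evoked = np.flatnonzero((ends > 0.0) & (ends <= evoked_range[1] + tensor.window))
    res = FanoResult(ff_cell_time=ff, ff_time=ff_time,
                     window_starts=tensor.window_starts,
                     ff_spont=ff[:, spont_idx])
    if evoked.size:
        t_min = int(evoked[np.nanargmin(ff_time[evoked])])
        res.t_ff_min_index = t_min
        res.ff_evoked = ff[:, t_min]
        res.delta_ff = res.ff_spont - res.ff_evoked
    return res


_DPSS_CACHE: dict = {}


def _dpss_cached(n: int, TW: float, k: int) -> np.ndarray:
    key = (n, TW, k)
    if key not in _DPSS_CACHE:
        _DPSS_CACHE[key] = dpss(n, TW, Kmax=k)
    return _DPSS_CACHE[key]


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    S_norm: np.ndarray          # trial-averaged rate-normalized spectrum
    P_low: float                # band average over 1-4 Hz
    n_trials: int
    params: dict = field(default_factory=dict)


def multitaper_spectrum(spike_trains: Sequence[np.ndarray], T: float = 2.5,
                        bin_s: float = MT_BIN_S, TW: float = MT_TW,
                        n_tapers: int = MT_N_TAPERS) -> SpectrumResult:
    """Rate-normalized multitaper spectrum of a point process.

    ``spike_trains`` holds one array of spike times in [0, T) per trial.
    Each trial is binned at 1 ms, mean-centered, tapered with DPSS
    sequences (unit energy) and averaged over tapers; the estimate is
    divided by the trial's mean rate so that a homogeneous Poisson process
    has expectation 1 at all frequencies.  Trials without spikes are
    excluded; if no trial has spikes a ValueError is raised (such units
    are excluded upstream).
    """
    n = int(round(T / bin_s))
    tapers = _dpss_cached(n, TW, n_tapers)       # rows have unit energy
    freqs = np.fft.rfftfreq(n, d=bin_s)
    acc = np.zeros(freqs.size)
    used = 0
    for st in spike_trains:
        st = np.asarray(st)
        x, _ = np.histogram(st, bins=n, range=(0.0, T))
        total = x.sum()
        if total == 0:
            continue
        xc = x - x.mean()
        spec = np.abs(np.fft.rfft(tapers * xc[None, :], axis=1)) ** 2
        S_raw = spec.mean(axis=0)
        acc += S_raw / (total / n)               # divide by mean count/bin
        used += 1
    if used == 0:
        raise ValueError("no spikes in any trial; unit must be excluded")
    S = acc / used
    band = (freqs >= LOW_FREQ_BAND[0]) & (freqs <= LOW_FREQ_BAND[1])
    return SpectrumResult(freqs=freqs, S_norm=S, P_low=float(S[band].mean()),
                          n_trials=used,
                          params={"TW": TW, "n_tapers": n_tapers,
                                  "bin_s": bin_s, "T": T})


def low_freq_power(spectra: Sequence[SpectrumResult]) -> dict:
    """Per-cell P_L and the population average."""
    vals = np.array([s.P_low for s in spectra])
    return {"per_cell": vals, "population": float(vals.mean())}


def pupil_conditioned_variability(window_counts: np.ndarray,
                                  window_pupil: np.ndarray,
                                  seed: int,
                                  bin_edges=(0.25, 0.35, 0.45, 0.55, 0.65,
                                             0.75, 1.0),
                                  n_subsamples: int = 100) -> dict:
    """Spontaneous FF per pupil bin with subsample balancing.

    ``window_counts`` is (units, windows) spike counts of spontaneous 100 ms
    windows and ``window_pupil`` the mean pupil diameter (fraction of max)
    per window.  Windows are assigned to bins by the given upper
    boundaries; every bin is subsampled to the size of the smallest bin,
    and the per-unit FF is averaged over ``n_subsamples`` random
    subsamples.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges, dtype=float)
    bins = np.searchsorted(edges[:-1], window_pupil, side="left")
    groups = [np.flatnonzero(bins == b) for b in range(edges.size)]
    n_min = min(g.size for g in groups)
    if n_min < 2:
        raise ValueError("a pupil bin has fewer than 2 windows")
    n_units = window_counts.shape[0]
    ff = np.zeros((edges.size, n_units))
    for b, g in enumerate(groups):
        acc = np.zeros(n_units)
        for _ in range(n_subsamples):
            sub = rng.choice(g, size=n_min, replace=False)
            c = window_counts[:, sub]
            m = c.mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                acc += np.where(m > 0, c.var(axis=1, ddof=1) / m, np.nan)
        ff[b] = acc / n_subsamples
    return {"bin_upper_bounds": edges, "ff": ff,
            "ff_population": np.nanmean(ff, axis=1)}
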