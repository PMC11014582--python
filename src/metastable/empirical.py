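"""Data-side procedures for Neuropixels-style sessions.

Covers the preprocessing and classification steps applied to recordings:
cleaning of pupillometry traces (artifact removal, smoothing,
max-normalization), template-amplitude quality control of sorted units
(multimodality and noise-floor drift), tone-responsiveness testing
(sliding-window Mann-Whitney U with Bonferroni correction), and
classification of rate-pupil / rate-arousal relationships via Spearman
correlations over decile bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde, mannwhitneyu, spearmanr

PUPIL_DT_S = 0.001
PUPIL_JUMP_THRESHOLD = 0.08
PUPIL_REMOVE_BEFORE_S = 0.25
PUPIL_REMOVE_AFTER_S = 0.5
PUPIL_SMOOTH_S = 1.0 / 30.0

QC_WINDOW_S = 300.0
QC_PEAK_RATIO_MAX = 10.0
QC_PEAK_SEP_MIN = 40.0
QC_MULTIMODAL_FRAC = 0.10
QC_FLOOR_SEP_MAX = 15.0
QC_FLOOR_RANGE_MIN = 25.0
QC_FLOOR_FRAC = 0.10
QC_MIN_RATE = 0.25


@dataclass
class RecordingSession:
    """One session: spikes, template amplitudes, pupil, velocity, tones."""

    spike_times: list                    # per-unit arrays (s)
    amp_times: list                      # per-unit template-amplitude times
    amplitudes: list                     # per-unit template amplitudes
    pupil_t: np.ndarray
    pupil: np.ndarray                    # cleaned, normalized to max = 1
    velocity_t: Optional[np.ndarray] = None
    velocity: Optional[np.ndarray] = None
    tone_times: Optional[np.ndarray] = None
    tone_freqs: Optional[np.ndarray] = None
    spont_blocks: list = field(default_factory=list)   # [(t0, t1), ...]
    duration: float = 0.0
    meta: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [(u, t) for u, st in enumerate(self.spike_times) for t in st]
        pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
            out / "spikes.csv", index=False)
        rows = [(u, t, a) for u, (ts, amps) in
                enumerate(zip(self.amp_times, self.amplitudes))
                for t, a in zip(ts, amps)]
        pd.DataFrame(rows, columns=["unit_id", "time_s", "amplitude"]).to_csv(
            out / "amplitudes.csv", index=False)
        pd.DataFrame({"time_s": self.pupil_t, "diameter": self.pupil}).to_csv(
            out / "pupil.csv", index=False)
        if self.velocity is not None:
            pd.DataFrame({"time_s": self.velocity_t,
                          "cm_per_s": self.velocity}).to_csv(
                out / "velocity.csv", index=False)
        if self.tone_times is not None:
            pd.DataFrame({"time_s": self.tone_times,
                          "freq_hz": self.tone_freqs}).to_csv(
                out / "events.csv", index=False)
        manifest = {"n_units": len(self.spike_times),
                    "duration": self.duration,
                    "spont_blocks": [list(b) for b in self.spont_blocks],
                    **self.meta}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir) -> "RecordingSession":
        d = Path(in_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        n = manifest["n_units"]
        sp = pd.read_csv(d / "spikes.csv")
        spikes = [np.sort(sp.loc[sp.unit_id == u, "time_s"].to_numpy())
                  for u in range(n)]
        am = pd.read_csv(d / "amplitudes.csv")
        amp_t, amps = [], []
        for u in range(n):
            sub = am[am.unit_id == u].sort_values("time_s")
            amp_t.append(sub["time_s"].to_numpy())
            amps.append(sub["amplitude"].to_numpy())
        pupil = pd.read_csv(d / "pupil.csv")
        vel_t = vel = None
        if (d / "velocity.csv").exists():
            v = pd.read_csv(d / "velocity.csv")
            vel_t, vel = v["time_s"].to_numpy(), v["cm_per_s"].to_numpy()
        tt = tf = None
        if (d / "events.csv").exists():
            ev = pd.read_csv(d / "events.csv")
            tt, tf = ev["time_s"].to_numpy(), ev["freq_hz"].to_numpy()
        return cls(spike_times=spikes, amp_times=amp_t, amplitudes=amps,
                   pupil_t=pupil["time_s"].to_numpy(),
                   pupil=pupil["diameter"].to_numpy(),
                   velocity_t=vel_t, velocity=vel,
                   tone_times=tt, tone_freqs=tf,
                   spont_blocks=[tuple(b) for b in manifest["spont_blocks"]],
                   duration=manifest["duration"])


# ---------------------------------------------------------------------------
# Pupil cleaning
# ---------------------------------------------------------------------------

def clean_pupil_trace(t: np.ndarray, diameter: np.ndarray,
                      threshold: float = PUPIL_JUMP_THRESHOLD,
                      jump_lag_s: float = PUPIL_DT_S) -> dict:
    """Artifact removal, smoothing and max-normalization of a pupil trace.

    The trace is resampled to a 1 ms grid; jumps are detected on the
    max-normalized trace as absolute differences across ``jump_lag_s``
    exceeding ``threshold``, and data from 250 ms before to 500 ms after a
    detected jump is removed (NaN).  The surviving samples are smoothed
    with a 1/30 s moving average stepped at 1 ms and re-normalized to the
    maximum.  Raises if everything is removed.
    """
    t = np.asarray(t, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    grid = np.arange(t[0], t[-1], PUPIL_DT_S)
    d = np.interp(grid, t, diameter)
    norm = d / np.nanmax(d)
    lag = max(1, int(round(jump_lag_s / PUPIL_DT_S)))
    jumps = np.abs(norm[lag:] - norm[:-lag]) > threshold
    bad = np.zeros(grid.size, dtype=bool)
    pre = int(round(PUPIL_REMOVE_BEFORE_S / PUPIL_DT_S))
    post = int(round(PUPIL_REMOVE_AFTER_S / PUPIL_DT_S))
    for idx in np.flatnonzero(jumps):
        bad[max(0, idx - pre):idx + post + 1] = True
    cleaned = np.where(bad, np.nan, d)
    if np.all(np.isnan(cleaned)):
        raise ValueError("pupil trace fully removed by artifact cleaning")
    win = int(round(PUPIL_SMOOTH_S / PUPIL_DT_S))
    sm = pd.Series(cleaned).rolling(win, center=True, min_periods=1).mean()
    sm = sm.to_numpy()
    sm[bad] = np.nan
    sm = sm / np.nanmax(sm)
    return {"t": grid, "diameter": sm, "removed": bad,
            "artifact_indices": np.flatnonzero(jumps)}


# ---------------------------------------------------------------------------
# Unit quality control on template amplitudes
# ---------------------------------------------------------------------------

def _percent_difference(a: float, b: float) -> float:
    m = 0.5 * (abs(a) + abs(b))
    return 0.0 if m == 0 else abs(a - b) / m * 100.0


def _window_peaks(amps: np.ndarray, n_grid: int = 256):
    """KDE peak locations and heights for one window's amplitudes."""
    if amps.size < 5 or np.ptp(amps) < 1e-12:
        loc = amps.mean() if amps.size else np.nan
        return np.array([loc]), np.array([1.0])
    kde = gaussian_kde(amps)
    lo, hi = amps.min(), amps.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    pdf = kde(grid)
    peaks = argrelextrema(pdf, np.greater)[0]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(pdf))])
    order = np.argsort(pdf[peaks])[::-1]
    return grid[peaks][order], pdf[peaks][order]


@dataclass
class UnitQCReport:
    retained: bool
    low_rate: bool
    multimodal: bool
    floor_drift: bool
    frac_multimodal_windows: float
    frac_near_floor_windows: float
    max_peak_location_difference: float
    window_diagnostics: pd.DataFrame


def unit_qc(amp_times: np.ndarray, amplitudes: np.ndarray, duration: float,
            overall_rate: float, window_s: float = QC_WINDOW_S) -> UnitQCReport:
    """Template-amplitude QC in non-overlapping 5-minute windows.

    Multimodality: a window counts as flagged when its amplitude density
    has two or more peaks with height ratio <= 10 and percent difference
    between peak locations >= 40; the unit is rejected when at least 10%
    of windows are flagged.  Floor drift: with the noise floor estimated
    as the smallest amplitude in the recording, windows whose tallest peak
    lies within 15% (percent difference) of the floor are "near floor";
    the unit is rejected when more than 10% (but not all) of windows are
    near the floor and the percent difference between the smallest and
    largest tallest-peak locations is >= 25.  Units with overall rate
    below 0.25 spikes/s are rejected regardless.
    """
    amp_times = np.asarray(amp_times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_win = max(1, int(np.ceil(duration / window_s)))
    floor = amplitudes.min() if amplitudes.size else np.nan
    rows = []
    for w in range(n_win):
        sel = (amp_times >= w * window_s) & (amp_times < (w + 1) * window_s)
        amps = amplitudes[sel]
        if amps.size < 5:
            continue
        locs, heights = _window_peaks(amps)
        multimodal = False
        ratio = np.inf
        sep = 0.0
        if locs.size >= 2:
            ratio = heights[0] / heights[1]
            sep = _percent_difference(locs[0], locs[1])
            multimodal = (ratio <= QC_PEAK_RATIO_MAX) and (sep >= QC_PEAK_SEP_MIN)
        near_floor = _percent_difference(locs[0], floor) <= QC_FLOOR_SEP_MAX
        rows.append(dict(window=w, n=amps.size, top_peak=locs[0],
                         peak_height_ratio=ratio, peak_separation_pct=sep,
                         multimodal=multimodal, near_floor=near_floor))
    diag = pd.DataFrame(rows)
    if len(diag):
        frac_mm = diag.multimodal.mean()
        frac_floor = diag.near_floor.mean()
        max_diff = _percent_difference(diag.top_peak.min(), diag.top_peak.max())
    else:
        frac_mm = frac_floor = max_diff = 0.0
    low_rate = overall_rate < QC_MIN_RATE
    multimodal = frac_mm >= QC_MULTIMODAL_FRAC
    floor_drift = (QC_FLOOR_FRAC < frac_floor < 1.0) and \
        (max_diff >= QC_FLOOR_RANGE_MIN)
    return UnitQCReport(
        retained=not (low_rate or multimodal or floor_drift),
        low_rate=low_rate, multimodal=multimodal, floor_drift=floor_drift,
        frac_multimodal_windows=float(frac_mm),
        frac_near_floor_windows=float(frac_floor),
        max_peak_location_difference=float(max_diff),
        window_diagnostics=diag)


# ---------------------------------------------------------------------------
# Tone responsiveness
# ---------------------------------------------------------------------------

def _sliding_counts_1ms(spike_times, event_times, t_range, window=0.1,
                        step=0.001):
    starts = np.arange(t_range[0], t_range[1] - window + 1e-9, step)
    st = np.sort(np.asarray(spike_times))
    n_bins = int(round((t_range[1] - t_range[0]) / step))
    lo = np.searchsorted(st, event_times + t_range[0])
    hi = np.searchsorted(st, event_times + t_range[1])
    rows = np.repeat(np.arange(event_times.size), hi - lo)
    rel = st[np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])] \
        - event_times[rows] - t_range[0]
    cols = np.minimum((rel / step).astype(np.int64), n_bins - 1)
    fine = np.bincount(rows * n_bins + cols,
                       minlength=event_times.size * n_bins) \
        .reshape(event_times.size, n_bins)
    csum = np.cumsum(np.pad(fine, ((0, 0), (1, 0))), axis=1)
    w = int(round(window / step))
    out = csum[:, w:w + starts.size] - csum[:, :starts.size]
    return starts, out


def _mwu_pvalues_counts(evoked: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Two-sided asymptotic Mann-Whitney U p-values, vectorized over bins.

    ``evoked`` is (n_bins, n1) integer counts, ``baseline`` (n2,) pooled
    counts shared by all bins.  Mid-ranks are computed from frequency
    tables (counts are small integers), with tie correction and continuity
    correction, matching the asymptotic Mann-Whitney U test.
    """
    from scipy.stats import norm
    evoked = np.asarray(evoked, dtype=np.int64)
    baseline = np.asarray(baseline, dtype=np.int64)
    n_bins, n1 = evoked.shape
    n2 = baseline.size
    n = n1 + n2
    K = int(max(evoked.max(initial=0), baseline.max(initial=0))) + 1
    base_freq = np.bincount(baseline, minlength=K)
    flat = (np.arange(n_bins)[:, None] * K + evoked).ravel()
    ev_freq = np.bincount(flat, minlength=n_bins * K).reshape(n_bins, K)
    freq = ev_freq + base_freq[None, :]
    cum = np.cumsum(freq, axis=1) - freq
    midrank = cum + (freq + 1) / 2.0
    R1 = (ev_freq * midrank).sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    tie_term = ((freq ** 3 - freq).sum(axis=1)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(U1 - mu) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * norm.sf(np.clip(z, 0.0, None))
    p[~np.isfinite(z)] = 1.0
    return np.minimum(p, 1.0)


def tone_responsiveness(spike_times: np.ndarray, tone_times: np.ndarray,
                        tone_freqs: np.ndarray, alpha: float = 0.05,
                        min_run_ms: int = 5) -> dict:
    """Per-tone responsive flags via sliding-window Mann-Whitney U tests.

    For each tone frequency, 100 ms windows stepped at 1 ms are compared
    between each evoked bin (ending within 200 ms after onset) and the
    pooled baseline bins (fully contained in the 200 ms before onset).
    P-values are Bonferroni-corrected over the evoked bins; a cell is
    responsive to a tone when corrected p < 0.05 for at least 5 consecutive
    milliseconds.
    """
    out = {}
    for f in np.unique(tone_freqs):
        ev = tone_times[tone_freqs == f]
        if ev.size < 2:
            out[float(f)] = False
            continue
        starts, counts = _sliding_counts_1ms(spike_times, ev, (-0.2, 0.4))
        ends = starts + 0.1
        base_idx = np.flatnonzero(ends <= 0.0)
        ev_idx = np.flatnonzero((ends > 0.0) & (ends <= 0.2))
        baseline = counts[:, base_idx].ravel()
        evoked = counts[:, ev_idx]        # (trials, n_evoked_bins)
        if evoked.max() == 0 and baseline.max() == 0:
            out[float(f)] = False
            continue
        p_raw = _mwu_pvalues_counts(evoked.T, baseline)
        p = np.minimum(p_raw * ev_idx.size, 1.0)
        sig = p < alpha
        run, best = 0, 0
        for s in sig:
            run = run + 1 if s else 0
            best = max(best, run)
        out[float(f)] = bool(best >= min_run_ms)
    return out


# ---------------------------------------------------------------------------
# Rate-arousal relationships
# ---------------------------------------------------------------------------

def rate_pupil_modulation(spike_times: np.ndarray, pupil_t: np.ndarray,
                          pupil: np.ndarray, spont_blocks: Sequence,
                          window_s: float = 0.1, alpha: float = 0.05) -> dict:
    """Sign of the spontaneous rate-pupil relationship over decile bins.

    Spontaneous periods are cut into 100 ms windows; windows are grouped
    by pupil-diameter deciles; the Spearman correlation between per-decile
    mean rate and mean pupil decides {positive, negative, none}.
    """
    counts, pupil_means = [], []
    st = np.asarray(spike_times)
    for t0, t1 in spont_blocks:
        starts = np.arange(t0, t1 - window_s + 1e-9, window_s)
        c = np.searchsorted(st, starts + window_s) - np.searchsorted(st, starts)
        pm = np.interp(starts + window_s / 2, pupil_t, pupil)
        counts.append(c)
        pupil_means.append(pm)
    counts = np.concatenate(counts)
    pupil_means = np.concatenate(pupil_means)
    ok = np.isfinite(pupil_means)
    counts, pupil_means = counts[ok], pupil_means[ok]
    edges = np.quantile(pupil_means, np.linspace(0, 1, 11))
    bins = np.clip(np.searchsorted(edges[1:-1], pupil_means, side="right"), 0, 9)
    rate_bin = np.array([counts[bins == b].mean() / window_s for b in range(10)])
    pupil_bin = np.array([pupil_means[bins == b].mean() for b in range(10)])
    rho, p = spearmanr(rate_bin, pupil_bin)
    if np.isnan(rho) or p >= alpha:
        label = "none"
    else:
        label = "positive" if rho > 0 else "negative"
    return {"label": label, "rho": float(rho) if np.isfinite(rho) else np.nan,
            "p": float(p) if np.isfinite(p) else np.nan,
            "rate_per_decile": rate_bin, "pupil_per_decile": pupil_bin}


def arousal_modulation_model(rates: np.ndarray, delta_grid: np.ndarray,
                             alpha: float = 0.05) -> dict:
    """Fractions of cells whose spontaneous rate rises/falls with arousal.

    ``rates`` is (cells, n_delta) trial-averaged spontaneous rates across
    the arousal-modulation grid.  Spearman correlation per cell; p < 0.05
    sets the sign, otherwise "none".
    """
    labels = []
    for r in np.asarray(rates, dtype=float):
        if np.ptp(r) == 0:
            labels.append("none")
            continue
        rho, p = spearmanr(r, delta_grid)
        labels.append("positive" if (p < alpha and rho > 0)
                      else "negative" if (p < alpha and rho < 0) else "none")
    labels = np.array(labels)
    n = labels.size
    return {"labels": labels,
            "frac_positive": float((labels == "positive").sum() / n),
            "frac_negative": float((labels == "negative").sum() / n)}
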