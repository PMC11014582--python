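"""Synthetic Neuropixels-style sessions with known ground truth.

The generators emulate the statistical structure of awake head-fixed
recordings so every empirical-pipeline stage is testable without data:

* a slowly varying, bounded pupil trace (clipped Ornstein-Uhlenbeck
  process with a tens-of-seconds timescale) with sharp tracking artifacts
  at known times;
* units with mixed-sign rate-pupil coupling, tone tuning (preferred
  frequency, evoked gain, latency), and optional built-in inverted-U
  structure where tone responses are strongest at mid pupil dilation;
* doubly stochastic spiking (inhomogeneous Poisson by thinning, with slow
  multiplicative gain noise whose amplitude decreases with pupil so the
  Fano factor falls with arousal);
* spike-template-amplitude series of three classes - stable, bimodal,
  and floor-drifting - exercising the unit-selection rules.

Every generator returns its ground truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .empirical import RecordingSession

TONE_FREQS_HZ = (2000.0, 4000.0, 8000.0, 16000.0, 32000.0)
GRID_DT = 0.01          # rate-function resolution (s)


@dataclass
class SyntheticSessionSpec:
    n_units: int = 120
    duration: float = 1800.0
    block_plan: Optional[tuple] = None   # derived from duration when None

    def blocks(self) -> tuple:
        if self.block_plan is not None:
            return tuple((t0, min(t1, self.duration), kind)
                         for t0, t1, kind in self.block_plan
                         if t0 < self.duration)
        out, t, kind = [], 0.0, "spont"
        while t < self.duration:
            span = 300.0 if kind == "spont" else 600.0
            out.append((t, min(t + span, self.duration), kind))
            t += span
            kind = "evoked" if kind == "spont" else "spont"
        return tuple(out)
    # pupil dynamics
    pupil_mean: float = 0.55
    pupil_sd: float = 0.15
    pupil_tau: float = 45.0
    artifact_rate: float = 1.0 / 120.0      # per second
    # arousal coupling of spontaneous rates
    frac_positive: float = 0.40
    frac_negative: float = 0.35
    coupling_strength: float = 2.0          # log-rate slope per unit pupil
    # tone responses
    frac_responsive: float = 0.6
    evoked_gain: float = 4.0                # peak rate multiple of baseline
    tone_isi: float = 0.8
    tone_duration: float = 0.025
    inverted_u: bool = False
    inverted_u_width: float = 0.18
    # variability structure
    gain_noise_sd: float = 0.7              # at pupil = 0
    gain_noise_pupil_slope: float = 0.6     # reduction per unit pupil
    gain_noise_tau: float = 0.3
    base_rate_median: float = 3.0
    seed: int = 0


def gen_pupil_trace(spec: SyntheticSessionSpec, rng=None) -> dict:
    """Clipped OU pupil trace plus injected step artifacts.

    Returns the raw (artifact-laden) trace on a 1 ms grid, the clean
    trace, and ground-truth artifact onset times.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    dt = GRID_DT
    n = int(round(spec.duration / dt))
    x = np.empty(n)
    x[0] = spec.pupil_mean
    drive = spec.pupil_sd * np.sqrt(2 * dt / spec.pupil_tau)
    noise = rng.standard_normal(n - 1)
    for k in range(n - 1):
        x[k + 1] = x[k] + (spec.pupil_mean - x[k]) * dt / spec.pupil_tau \
            + drive * noise[k]
    np.clip(x, 0.02, 1.0, out=x)
    t_fine = np.arange(0.0, spec.duration, 0.001)
    clean = np.interp(t_fine, np.arange(n) * dt, x)
    raw = clean.copy()
    n_art = rng.poisson(spec.artifact_rate * spec.duration)
    art_times = np.sort(rng.uniform(1.0, spec.duration - 1.0, n_art))
    for ta in art_times:
        i0 = int(ta / 0.001)
        width = int(rng.uniform(0.05, 0.2) / 0.001)
        size = rng.choice([-1, 1]) * rng.uniform(0.12, 0.3)
        raw[i0:i0 + width] = np.clip(raw[i0:i0 + width] + size, 0.01, 1.2)
    return {"t": t_fine, "raw": raw, "clean": clean,
            "artifact_times": art_times}


def gen_template_amplitudes(kind: str, duration: float, spike_times: np.ndarray,
                            rng) -> np.ndarray:
    """Template-amplitude series of a given QC class at the spike times."""
    t = np.asarray(spike_times)
    base = 100.0 + 3.0 * np.sin(2 * np.pi * t / max(duration, 1.0))
    amps = base + rng.normal(0.0, 5.0, t.size)
    if kind == "stable":
        return np.clip(amps, 20.0, None)
    if kind == "bimodal":
        # two well-separated amplitude groups in ~20% of the session
        lo, hi = 0.3 * duration, 0.5 * duration
        in_seg = (t >= lo) & (t < hi)
        split = rng.random(t.size) < 0.45
        amps[in_seg & split] = 45.0 + rng.normal(0.0, 4.0, int((in_seg & split).sum()))
        return np.clip(amps, 15.0, None)
    if kind == "floor_drift":
        # drift toward the noise floor over the last third of the session
        floor = 10.0
        onset = 0.65 * duration
        frac = np.clip((t - onset) / (0.15 * duration), 0.0, 1.0)
        amps = amps * (1 - frac) + (floor + 1.0 + rng.normal(0, 0.8, t.size)) * frac
        amps[np.argmin(np.abs(t - onset))] = floor   # pin the floor estimate
        return np.clip(amps, floor, None)
    raise ValueError(f"unknown amplitude class {kind!r}")


@dataclass
class SyntheticGroundTruth:
    coupling_sign: list
    responsive_freqs: list
    qc_class: list
    artifact_times: np.ndarray
    inverted_u: bool
    unit_params: list = field(default_factory=list)


def _tone_kernel(latency: float, tau: float, dt: float = GRID_DT) -> np.ndarray:
    t = np.arange(0.0, 0.25, dt)
    k = np.clip(t - latency, 0.0, None) / tau * np.exp(1 - np.clip(t - latency, 0, None) / tau)
    return k


def gen_session(spec: SyntheticSessionSpec):
    """Full synthetic session plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    pup = gen_pupil_trace(spec, rng)
    tg = np.arange(0.0, spec.duration, GRID_DT)
    pupil_g = np.interp(tg, pup["t"], pup["clean"])

    # tone events in evoked blocks
    tone_times, tone_freqs = [], []
    for t0, t1, kind in spec.blocks():
        if kind != "evoked":
            continue
        times = np.arange(t0 + 1.0, t1 - 1.0, spec.tone_isi)
        tone_times.append(times)
        tone_freqs.append(rng.choice(TONE_FREQS_HZ, size=times.size))
    tone_times = np.concatenate(tone_times) if tone_times else np.array([])
    tone_freqs = np.concatenate(tone_freqs) if tone_freqs else np.array([])

    n = spec.n_units
    signs = np.array(["none"] * n, dtype=object)
    k_pos = int(round(spec.frac_positive * n))
    k_neg = int(round(spec.frac_negative * n))
    order = rng.permutation(n)
    signs[order[:k_pos]] = "positive"
    signs[order[k_pos:k_pos + k_neg]] = "negative"
    responsive = rng.random(n) < spec.frac_responsive
    log_freqs = np.log2(TONE_FREQS_HZ)
    qc_classes = np.array(["stable"] * n, dtype=object)
    qc_classes[order[: max(2, n // 10)]] = "bimodal"
    qc_classes[order[max(2, n // 10): 2 * max(2, n // 10)]] = "floor_drift"

    spike_times, amp_times, amplitudes = [], [], []
    resp_sets, unit_params = [], []
    u_factor = np.exp(-(pupil_g - 0.5) ** 2 / (2 * spec.inverted_u_width ** 2)) \
        if spec.inverted_u else np.ones_like(pupil_g)
    kernel_cache = {}
    for u in range(n):
        lam0 = spec.base_rate_median * np.exp(rng.normal(0.0, 0.5))
        g = {"positive": spec.coupling_strength,
             "negative": -spec.coupling_strength, "none": 0.0}[signs[u]]
        rate = lam0 * np.exp(g * (pupil_g - spec.pupil_mean))
        # slow multiplicative gain noise, weaker at large pupil
        sd_g = np.clip(spec.gain_noise_sd
                       * (1 - spec.gain_noise_pupil_slope * pupil_g), 0.05, None)
        eta = np.empty(tg.size)
        eta[0] = 0.0
        a = np.exp(-GRID_DT / spec.gain_noise_tau)
        wn = rng.standard_normal(tg.size - 1) * np.sqrt(1 - a * a)
        for k in range(tg.size - 1):
            eta[k + 1] = a * eta[k] + wn[k]
        rate = rate * np.exp(sd_g * eta - 0.5 * sd_g ** 2)
        # tone responses
        rset = set()
        pref = rng.uniform(log_freqs[0], log_freqs[-1])
        latency = rng.uniform(0.01, 0.03)
        if responsive[u] and tone_times.size:
            key = round(latency, 3)
            if key not in kernel_cache:
                kernel_cache[key] = _tone_kernel(latency, 0.03)
            kern = kernel_cache[key]
            for fi, f in enumerate(TONE_FREQS_HZ):
                tuning = np.exp(-(log_freqs[fi] - pref) ** 2 / (2 * 1.0 ** 2))
                amp = spec.evoked_gain * lam0 * tuning
                if amp < 1.0 * lam0:
                    continue
                rset.add(float(f))
                ev = tone_times[tone_freqs == f]
                idx = (ev / GRID_DT).astype(int)
                for j, i0 in enumerate(idx):
                    seg = slice(i0, min(i0 + kern.size, tg.size))
                    rate[seg] += amp * kern[:seg.stop - seg.start] * u_factor[i0]
        resp_sets.append(rset if responsive[u] else set())
        # thinning
        lam_max = float(rate.max()) * 1.001
        n_cand = rng.poisson(lam_max * spec.duration)
        cand = np.sort(rng.uniform(0.0, spec.duration, n_cand))
        accept = rng.random(n_cand) < np.interp(cand, tg, rate) / lam_max
        st = cand[accept]
        spike_times.append(st)
        amp_times.append(st)
        amplitudes.append(gen_template_amplitudes(qc_classes[u], spec.duration,
                                                  st, rng))
        unit_params.append({"lam0": lam0, "coupling": g, "pref_log_freq": pref,
                            "latency": latency})

    velocity_t = np.arange(0.0, spec.duration, 0.1)
    velocity = np.zeros_like(velocity_t)
    t_run = 1.0
    while t_run < spec.duration:
        t_run += rng.exponential(300.0)
        dur = rng.uniform(5.0, 20.0)
        sel = (velocity_t >= t_run) & (velocity_t < t_run + dur)
        velocity[sel] = rng.uniform(3.0, 10.0)
        t_run += dur

    session = RecordingSession(
        spike_times=spike_times, amp_times=amp_times, amplitudes=amplitudes,
        pupil_t=pup["t"], pupil=pup["raw"],
        velocity_t=velocity_t, velocity=velocity,
        tone_times=tone_times, tone_freqs=tone_freqs,
        spont_blocks=[(t0, t1) for t0, t1, k in spec.blocks() if k == "spont"],
        duration=spec.duration,
        meta={"synthetic": True})
    truth = SyntheticGroundTruth(
        coupling_sign=list(signs), responsive_freqs=resp_sets,
        qc_class=list(qc_classes), artifact_times=pup["artifact_times"],
        inverted_u=spec.inverted_u, unit_params=unit_params)
    return session, truth
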