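"""Single-unit responsiveness and firing properties.

A unit counts as *excited auditory responsive* when its per-trial evoked
rate (tone onset to 50 ms after tone offset) exceeds its per-trial baseline
rate (200 to 50 ms before onset) under a right-sided Wilcoxon signed-rank
test at alpha = 0.05.  Suppressed and non-responsive units are excluded
from downstream analyses.

Two distinct baseline conventions coexist deliberately: the responsiveness
test uses [-0.2, -0.05) s, while the spontaneous firing rate reported in
:class:`FiringProperties` uses the full [-0.2, 0) s preceding onset.

Lifetime sparseness over the set of learned tones:

    S = (1 - (sum r_i / n)^2 / (sum r_i^2 / n)) / (1 - 1/n)

with ``r_i`` the mean evoked rate to learned frequency ``i``; S near 0
means a dense code (the unit responds to everything), near 1 a sparse one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import wilcoxon

from .io import Session, Unit

__all__ = [
    "PSTH",
    "FiringProperties",
    "trial_counts",
    "trial_rates",
    "responsiveness_test",
    "responsive_units",
    "compute_psth",
    "firing_properties",
    "lifetime_sparseness",
    "BASELINE_TEST_WINDOW",
    "SPONT_WINDOW",
]

BASELINE_TEST_WINDOW = (-0.2, -0.05)
SPONT_WINDOW = (-0.2, 0.0)


def trial_counts(
    unit: Unit, onsets: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Spike counts per trial in the half-open window [w0, w1) relative to onset."""
    st = np.asarray(unit.spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    lo = np.searchsorted(st, onsets + window[0])
    hi = np.searchsorted(st, onsets + window[1])
    return (hi - lo).astype(float)


def trial_rates(
    unit: Unit, onsets: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Per-trial firing rates (Hz) in a window relative to onset.

    The width is rounded at nanosecond resolution so that equal-duration
    windows yield exactly comparable rates despite float arithmetic.
    """
    width = round(window[1] - window[0], 9)
    if width <= 0:
        raise ValueError("window must have positive width")
    return trial_counts(unit, onsets, window) / width


def responsiveness_test(
    unit: Unit,
    trials: pd.DataFrame,
    baseline_window: tuple[float, float] = BASELINE_TEST_WINDOW,
    evoked_window: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Right-sided Wilcoxon signed-rank test of evoked > baseline rate.

    The evoked window defaults to [0, tone_dur + 0.05) s.  Zero-difference
    trials are excluded (standard Wilcoxon practice); if every trial ties,
    the unit is not excited and p = 1.  Returns ``(is_excited, p)``.
    """
    if len(trials) < 10:
        raise ValueError("responsiveness test needs at least 10 trials")
    onsets = trials["t_onset"].to_numpy(dtype=float)
    if evoked_window is None:
        dur = float(trials["tone_dur"].iloc[0])
        evoked_window = (0.0, dur + 0.05)
    base = trial_rates(unit, onsets, baseline_window)
    ev = trial_rates(unit, onsets, evoked_window)
    diff = ev - base
    # rates below ~1e-9 Hz apart are ties (float error in window widths)
    diff[np.abs(diff) < 1e-9] = 0.0
    if np.all(diff == 0):
        return False, 1.0
    mode = "exact" if np.count_nonzero(diff) < 25 else "approx"
    res = wilcoxon(diff, alternative="greater", zero_method="wilcox", method=mode)
    p = float(res.pvalue)
    return p < alpha, p


def responsive_units(
    session: Session,
    alpha: float = 0.05,
    baseline_window: tuple[float, float] = BASELINE_TEST_WINDOW,
) -> list[Unit]:
    """Excited auditory-responsive units of a session (inclusion filter)."""
    keep = []
    for u in session.units:
        excited, _ = responsiveness_test(
            u, session.trials, baseline_window=baseline_window, alpha=alpha
        )
        if excited:
            keep.append(u)
    return keep


@dataclass
class PSTH:
    """Trial-averaged firing rate vs time from tone onset."""

    bin_centers: np.ndarray
    rate: np.ndarray  # Hz
    binsize: float
    smoothing_sd: float
    n_trials: int


def compute_psth(
    unit: Unit,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.2, 0.6),
    binsize: float = 0.001,
    smoothing_sd: float = 0.005,
) -> PSTH:
    """Peri-stimulus time histogram in Hz, Gaussian-smoothed (5 ms default).

    Smoothing uses reflective boundaries, so total spike mass is preserved
    up to edge effects (within 1% for interior mass).
    """
    if binsize <= 0:
        raise ValueError("binsize must be > 0")
    if len(trials) == 0:
        raise ValueError("empty trial set")
    onsets = trials["t_onset"].to_numpy(dtype=float)
    edges = np.arange(window[0], window[1] + binsize / 2, binsize)
    st = np.asarray(unit.spike_times, dtype=float)
    rel = []
    for t0 in onsets:
        s = st[np.searchsorted(st, t0 + window[0]) : np.searchsorted(st, t0 + window[1])]
        rel.append(s - t0)
    rel = np.concatenate(rel) if rel else np.empty(0)
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (len(onsets) * binsize)
    if smoothing_sd > 0:
        rate = gaussian_filter1d(rate, sigma=smoothing_sd / binsize, mode="reflect")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return PSTH(
        bin_centers=centers,
        rate=rate,
        binsize=binsize,
        smoothing_sd=smoothing_sd,
        n_trials=len(onsets),
    )


def lifetime_sparseness(rates: np.ndarray) -> float:
    """Lifetime sparseness S in [0, 1] of a non-negative rate vector.

    0 for a uniform (dense) response profile, 1 for a one-hot (sparse) one.
    Invariant to rescaling the rates.  An all-zero vector returns 0.
    """
    r = np.asarray(rates, dtype=float)
    n = len(r)
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    mean_sq = np.mean(r**2)
    if mean_sq == 0:
        return 0.0
    return float((1.0 - np.mean(r) ** 2 / mean_sq) / (1.0 - 1.0 / n))


@dataclass
class FiringProperties:
    spont_rate: float  # Hz, [-0.2, 0) s
    evoked_rate: float  # Hz, [0, tone_dur + 0.05) s
    frac_responsive_trials: float
    evoked_cv: float
    latency_to_peak: float  # s, argmax of smoothed PSTH in evoked window
    min_latency: float  # s, median over trials of first spike after onset
    fwhm: float  # s, PSTH width at half height above the spontaneous floor
    sparseness: float  # lifetime sparseness over learned tones
    valid: bool = True


def firing_properties(
    unit: Unit,
    trials: pd.DataFrame,
    psth_window: tuple[float, float] = (-0.2, 0.6),
    binsize: float = 0.001,
    smoothing_sd: float = 0.005,
) -> FiringProperties:
    """Firing properties of a responsive unit (see module docstring).

    A unit with zero evoked spikes yields a record flagged ``valid=False``
    with NaN temporal properties.
    """
    onsets = trials["t_onset"].to_numpy(dtype=float)
    dur = float(trials["tone_dur"].iloc[0])
    evoked_window = (0.0, dur + 0.05)

    spont = trial_rates(unit, onsets, SPONT_WINDOW)
    ev = trial_rates(unit, onsets, evoked_window)
    spont_rate = float(np.mean(spont))
    evoked_rate = float(np.mean(ev))
    frac_resp = float(np.mean(ev > spont))  # strict inequality
    evoked_cv = float(np.std(ev) / np.mean(ev)) if np.mean(ev) > 0 else np.nan

    # learned-tone sparseness over the non-probe stimulus set
    learned = trials[trials["category"].isin(["go", "nogo"])]
    rates_by_freq = [
        float(np.mean(trial_rates(unit, g["t_onset"].to_numpy(), evoked_window)))
        for _, g in learned.groupby("freq")
    ]
    sparse = lifetime_sparseness(np.array(rates_by_freq)) if len(rates_by_freq) >= 2 else np.nan

    if np.sum(ev) == 0:
        return FiringProperties(
            spont_rate=spont_rate, evoked_rate=evoked_rate,
            frac_responsive_trials=frac_resp, evoked_cv=np.nan,
            latency_to_peak=np.nan, min_latency=np.nan, fwhm=np.nan,
            sparseness=sparse, valid=False,
        )

    psth = compute_psth(unit, trials, window=psth_window, binsize=binsize,
                        smoothing_sd=smoothing_sd)
    in_evoked = (psth.bin_centers >= evoked_window[0]) & (psth.bin_centers < evoked_window[1])
    i_peak_local = int(np.argmax(psth.rate[in_evoked]))
    i_peak = int(np.flatnonzero(in_evoked)[i_peak_local])
    latency_to_peak = float(psth.bin_centers[i_peak])

    # median across trials of the first spike after tone onset
    st = np.asarray(unit.spike_times, dtype=float)
    firsts = []
    for t0 in onsets:
        i = np.searchsorted(st, t0)
        if i < len(st) and st[i] - t0 < psth_window[1]:
            firsts.append(st[i] - t0)
    min_latency = float(np.median(firsts)) if firsts else np.nan

    peak = psth.rate[i_peak]
    half = spont_rate + (peak - spont_rate) / 2.0
    if peak <= spont_rate:
        fwhm = np.nan
        warnings.warn("PSTH peak does not exceed the spontaneous rate", stacklevel=2)
    else:
        above = psth.rate >= half
        lo = i_peak
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i_peak
        while hi < len(above) - 1 and above[hi + 1]:
            hi += 1
        fwhm = float((hi - lo + 1) * psth.binsize)

    return FiringProperties(
        spont_rate=spont_rate, evoked_rate=evoked_rate,
        frac_responsive_trials=frac_resp, evoked_cv=evoked_cv,
        latency_to_peak=latency_to_peak, min_latency=min_latency,
        fwhm=fwhm, sparseness=sparse,
    )
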