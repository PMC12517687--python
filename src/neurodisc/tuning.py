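"""Passive-listening frequency-response-area (FRA) analysis.

The passive protocol presents 20 log-spaced pure tones (4-40 kHz, 0.1661
octaves apart) at five sound levels, 16 repetitions each.  Responses are
mean firing rates from tone onset to 50 ms after offset.  All tuning
statistics are evaluated at a single analysis level (62 dB SPL by default,
close to the level used in the behavioral task): per-frequency significance
is a right-sided Wilcoxon signed-rank test of evoked vs baseline rate, the
bandwidth counts significant adjacent frequencies corrected for the
expected number of false positives (alpha x n_freqs), and the pairwise
neural d' between two frequencies is the distance between their mean rates
divided by the mean cross-trial distance:

    d'(p, q) = |mu_p - mu_q| / mean_{i,j} |p_i - q_j|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .io import Unit
from .synthetic import FRA_OCTAVE_STEP
from .unit_metrics import trial_rates

__all__ = [
    "FRA",
    "PairwiseDPrime",
    "compute_fra",
    "bandwidth",
    "population_sparseness",
    "bf_distance_to_go",
    "pairwise_dprime",
    "DEFAULT_ANALYSIS_LEVEL",
]

DEFAULT_ANALYSIS_LEVEL = 62.0
_RESPONSE_WINDOW = (0.0, 0.15)  # tone onset to 50 ms after the 100 ms tone
_BASELINE_WINDOW = (-0.2, -0.05)


@dataclass
class FRA:
    """Frequency-response area of one unit.

    ``rates`` is (n_freqs, n_levels) in Hz; the significance mask and best
    frequency are defined only at the analysis level.  ``responsive`` is
    False when no frequency reaches significance there.
    """

    rates: np.ndarray
    freqs: np.ndarray
    levels: np.ndarray
    sig_mask: np.ndarray  # (n_freqs,) bool, at analysis_level
    best_frequency: float | None
    analysis_level: float
    responsive: bool


def compute_fra(
    unit: Unit,
    fra_trials: pd.DataFrame,
    response_window: tuple[float, float] = _RESPONSE_WINDOW,
    analysis_level: float = DEFAULT_ANALYSIS_LEVEL,
    alpha: float = 0.05,
    baseline_window: tuple[float, float] = _BASELINE_WINDOW,
) -> FRA:
    """Mean-rate FRA with per-frequency significance at the analysis level.

    Every (frequency, level) cell of the protocol must be present.  The
    best frequency is the significant frequency with the maximal rate at
    the analysis level; an untuned unit gets ``best_frequency=None`` and
    ``responsive=False``.
    """
    freqs = np.sort(fra_trials["freq"].unique())
    levels = np.sort(fra_trials["level"].unique())
    rates = np.empty((len(freqs), len(levels)))
    groups = fra_trials.groupby(["freq", "level"])
    for i, f in enumerate(freqs):
        for j, lv in enumerate(levels):
            if (f, lv) not in groups.groups:
                raise ValueError(f"FRA protocol malformed: missing cell ({f} Hz, {lv} dB)")
            onsets = groups.get_group((f, lv))["t_onset"].to_numpy(dtype=float)
            rates[i, j] = float(np.mean(trial_rates(unit, onsets, response_window)))

    if analysis_level not in levels:
        raise ValueError(f"analysis level {analysis_level} dB not in protocol levels {levels}")

    # overall excitation gate at the analysis level: without it, ~alpha of
    # the per-frequency tests fire on a purely spontaneous unit
    lvl_trials = fra_trials[fra_trials["level"] == analysis_level]
    all_onsets = lvl_trials["t_onset"].to_numpy(dtype=float)
    overall_diff = trial_rates(unit, all_onsets, response_window) - trial_rates(
        unit, all_onsets, baseline_window
    )
    overall_diff[np.abs(overall_diff) < 1e-9] = 0.0
    if np.all(overall_diff == 0):
        overall_excited = False
    else:
        p_overall = wilcoxon(
            overall_diff, alternative="greater", zero_method="wilcox", method="approx"
        ).pvalue
        overall_excited = p_overall < alpha

    sig = np.zeros(len(freqs), dtype=bool)
    for i, f in enumerate(freqs):
        onsets = groups.get_group((f, analysis_level))["t_onset"].to_numpy(dtype=float)
        ev = trial_rates(unit, onsets, response_window)
        base = trial_rates(unit, onsets, baseline_window)
        diff = ev - base
        if np.all(diff == 0):
            continue
        mode = "exact" if np.count_nonzero(diff) < 25 else "approx"
        p = wilcoxon(diff, alternative="greater", zero_method="wilcox", method=mode).pvalue
        sig[i] = p < alpha

    if not overall_excited:
        sig[:] = False

    j_level = int(np.flatnonzero(levels == analysis_level)[0])
    if sig.any():
        cand = np.flatnonzero(sig)
        bf = float(freqs[cand[np.argmax(rates[cand, j_level])]])
        responsive = True
    else:
        bf, responsive = None, False
    return FRA(
        rates=rates, freqs=freqs, levels=levels, sig_mask=sig,
        best_frequency=bf, analysis_level=analysis_level, responsive=responsive,
    )


def bandwidth(
    fra: FRA,
    alpha: float = 0.05,
    octave_step: float = FRA_OCTAVE_STEP,
) -> float:
    """Octave bandwidth at the analysis level, false-positive corrected.

    Counts the largest contiguous run of significant frequencies containing
    the best frequency, subtracts the expected number of false positives
    (``alpha * n_freqs``, fractional values allowed), floors at zero, and
    multiplies by the octave spacing of the protocol.
    """
    n_freqs = len(fra.freqs)
    if not fra.sig_mask.any() or fra.best_frequency is None:
        return 0.0
    i_bf = int(np.argmin(np.abs(fra.freqs - fra.best_frequency)))
    lo = i_bf
    while lo > 0 and fra.sig_mask[lo - 1]:
        lo -= 1
    hi = i_bf
    while hi < n_freqs - 1 and fra.sig_mask[hi + 1]:
        hi += 1
    n_adjacent = hi - lo + 1
    corrected = max(0.0, n_adjacent - alpha * n_freqs)
    return corrected * octave_step


def population_sparseness(fras: list[FRA]) -> float:
    """Fraction of significant excited (unit, frequency) responses at the analysis level."""
    if len(fras) == 0:
        raise ValueError("empty population")
    n_sig = sum(int(f.sig_mask.sum()) for f in fras)
    n_total = sum(len(f.freqs) for f in fras)
    return n_sig / n_total


def bf_distance_to_go(fra: FRA, go_freq: float = 7070.0) -> float | None:
    """|log2(BF / go frequency)| in octaves; None when the BF is undefined."""
    if fra.best_frequency is None:
        return None
    return float(abs(np.log2(fra.best_frequency / go_freq)))


@dataclass
class PairwiseDPrime:
    """Neural d' over all frequency pairs at one level.

    ``matrix`` is symmetric with a zero diagonal; ``mean_learned`` averages
    the pairs whose both frequencies lie inside the learned spectrum.
    """

    matrix: np.ndarray
    freqs: np.ndarray
    level: float
    mean_learned: float


def pairwise_dprime(
    unit: Unit,
    fra_trials: pd.DataFrame,
    level: float = DEFAULT_ANALYSIS_LEVEL,
    response_window: tuple[float, float] = _RESPONSE_WINDOW,
    learned_band: tuple[float, float] = (7070.0, 14140.0),
) -> PairwiseDPrime:
    """Pairwise neural discriminability between pure-tone frequencies.

    For frequencies p, q the numerator is the distance between mean
    per-trial rates, the denominator the mean over all cross-trial pairs
    (i, j) of |p_i - q_j|.  A zero denominator (all trials identical across
    both frequencies) yields d' = 0 with a warning.
    """
    at_level = fra_trials[fra_trials["level"] == level]
    freqs = np.sort(at_level["freq"].unique())
    per_freq = []
    for f in freqs:
        onsets = at_level.loc[at_level["freq"] == f, "t_onset"].to_numpy(dtype=float)
        if len(onsets) < 2:
            raise ValueError(f"need >= 2 trials per frequency at {level} dB (freq {f})")
        per_freq.append(trial_rates(unit, onsets, response_window))

    n = len(freqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = abs(float(np.mean(per_freq[i]) - np.mean(per_freq[j])))
            den = float(np.mean(np.abs(per_freq[i][:, None] - per_freq[j][None, :])))
            if den == 0.0:
                if num > 0:
                    warnings.warn(
                        f"zero cross-trial distance for pair ({freqs[i]}, {freqs[j]})",
                        stacklevel=2,
                    )
                d = 0.0
            else:
                d = num / den
            mat[i, j] = mat[j, i] = d

    in_band = (freqs >= learned_band[0] - 1e-9) & (freqs <= learned_band[1] + 1e-9)
    idx = np.flatnonzero(in_band)
    vals = [mat[i, j] for k, i in enumerate(idx) for j in idx[k + 1 :]]
    mean_learned = float(np.mean(vals)) if vals else float("nan")
    return PairwiseDPrime(matrix=mat, freqs=freqs, level=level, mean_learned=mean_learned)
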