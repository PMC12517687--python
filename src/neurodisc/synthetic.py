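"""Synthetic Go/No-Go sessions with planted, recoverable structure.

The generator emulates the statistical structure the analysis assumes:

* **Behavior** follows the equal-variance Gaussian signal-detection model.
  On a go trial the animal licks with probability ``Phi(d/2 - c)`` and on a
  no-go trial with ``Phi(-d/2 - c)``, with sensitivity ``d`` set per task
  difficulty and a shared criterion ``c`` (negative = liberal).  Probe tones
  are licked at the criterion-only rate ``Phi(-c)``.  Responding trials
  receive a lick train inside the 2 s response window after tone offset, so
  the planted ``(d, c)`` are exactly the quantities the behavior module
  estimates from classified outcomes.
* **Spiking** is an inhomogeneous Poisson process per unit:

  ``rate(t) = baseline
            + g_trial * evoked_gain * G(freq) * K(t)
            + g_trial * choice_gain * 1[lick trial] * 1[t >= choice_onset]``

  where ``G`` is a Gaussian tuning curve in log2 frequency (peak 1 at the
  best frequency), ``K`` an alpha-shaped onset kernel
  ``(t/tau) * exp(1 - t/tau)`` delayed by the evoked latency (peak 1 at
  latency + tau), and ``g_trial`` a per-trial multiplicative gamma gain with
  mean 1 and coefficient of variation ``gain_noise_cv``.  Spike times are
  exact: the baseline is a homogeneous Poisson process over the whole
  session and the stimulus/choice components are drawn by thinning against
  their analytic rate ceiling, then merged (a superposition of independent
  Poisson processes is Poisson with the summed rate).

Trial-to-trial noise is independent across units by default; shared gain
can be enabled via ``shared_gain=True`` to mimic correlated population
noise.  All randomness flows from a single seeded generator per call, so a
given ``(params, seed)`` pair reproduces the identical session bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    EASY_FREQS_HZ,
    HARD_FREQS_HZ,
    PROBE_FREQS_HZ,
    Session,
    Unit,
)

__all__ = [
    "BehaviorParams",
    "UnitParams",
    "GroundTruth",
    "simulate_behavior",
    "simulate_units",
    "simulate_session",
    "simulate_fra_protocol",
    "fra_frequencies",
    "FRA_LEVELS_DB",
    "FRA_OCTAVE_STEP",
    "FRA_N_REPS",
]

#: Passive pure-tone protocol: 20 log-spaced frequencies covering the
#: decade 4-40 kHz, i.e. log2(10)/20 = 0.16610 octaves per step.
FRA_OCTAVE_STEP = math.log2(10.0) / 20.0
FRA_LEVELS_DB = (32.0, 42.0, 52.0, 62.0, 72.0)
FRA_N_REPS = 16


def fra_frequencies() -> np.ndarray:
    """The 20 pure-tone frequencies (Hz) of the passive protocol."""
    return 4000.0 * 2.0 ** (FRA_OCTAVE_STEP * np.arange(20))


@dataclass
class BehaviorParams:
    """Planted parameters of the signal-detection behavior model.

    ``d_easy``/``d_hard`` are the sensitivities for the 1-octave and
    0.25-octave tone pairs; ``c_bias`` the shared criterion.  Lick trains on
    responding trials start ``lick_latency_mean`` (+- sd, truncated > 0)
    after tone offset and contain at least ``lick_threshold`` licks.
    """

    d_easy: float = 2.5
    d_hard: float = 1.0
    c_bias: float = 0.0
    n_trials: int = 300
    p_nogo: float = 0.45
    p_probe: float = 0.10
    lick_latency_mean: float = 0.35
    lick_latency_sd: float = 0.10
    licks_per_response_mean: float = 7.0
    lick_threshold: int = 1
    tone_dur: float = 0.1
    response_window: float = 2.0
    iti_range: tuple[float, float] = (6.0, 8.0)

    def validate(self) -> None:
        if not (0.0 <= self.p_nogo <= 1.0 and 0.0 <= self.p_probe <= 1.0):
            raise ValueError("p_nogo and p_probe must lie in [0, 1]")
        if self.p_nogo + self.p_probe > 1.0:
            raise ValueError("p_nogo + p_probe must not exceed 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.lick_latency_mean <= 0 or self.lick_latency_sd <= 0:
            raise ValueError("lick latency parameters must be > 0")
        if self.lick_threshold < 1:
            raise ValueError("lick_threshold must be >= 1")
        if self.tone_dur <= 0 or self.response_window <= 0:
            raise ValueError("tone_dur and response_window must be > 0")
        if not (0 < self.iti_range[0] <= self.iti_range[1]):
            raise ValueError("iti_range must satisfy 0 < low <= high")


@dataclass
class UnitParams:
    """Planted parameters of the Poisson spiking model (shared by units).

    ``bf_log2`` is the tuning center in log2(kHz) (e.g. log2(7.07) for the
    easy Go tone); ``bf_spread_oct`` optionally scatters per-unit best
    frequencies around it.  ``choice_gain`` adds a rate step of that many Hz
    from ``choice_onset`` (s after tone onset) to the end of the response
    window on lick trials only, regardless of trial category, so the
    false-alarm vs correct-reject contrast carries the planted choice
    signal.
    """

    n_units: int = 10
    baseline_rate: float = 5.0
    evoked_gain: float = 30.0
    bf_log2: float = math.log2(7.07)
    bf_spread_oct: float = 0.0
    tuning_sd_oct: float = 0.6
    evoked_latency: float = 0.015
    evoked_decay: float = 0.04
    choice_gain: float = 0.0
    choice_onset: float = 0.2
    gain_noise_cv: float = 0.2
    shared_gain: bool = False

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.baseline_rate < 0 or self.evoked_gain < 0 or self.choice_gain < 0:
            raise ValueError("rates must be >= 0")
        if self.tuning_sd_oct <= 0:
            raise ValueError("tuning_sd_oct must be > 0")
        if not (0.0 <= self.choice_onset <= 0.6):
            raise ValueError("choice_onset must lie in [0, 0.6] s")
        if self.evoked_decay <= 0 or self.evoked_latency < 0:
            raise ValueError("evoked kernel parameters invalid")
        if self.gain_noise_cv < 0:
            raise ValueError("gain_noise_cv must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters and realized outcome counts for recovery tests."""

    seed: int
    behavior: dict | None = None
    units: list[dict] = field(default_factory=list)
    outcome_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "behavior": self.behavior,
            "units": self.units,
            "outcome_counts": self.outcome_counts,
        }


def _tuning(freq_hz: np.ndarray, bf_log2: float, sd_oct: float) -> np.ndarray:
    x = np.log2(np.asarray(freq_hz, dtype=float) / 1000.0)
    return np.exp(-0.5 * ((x - bf_log2) / sd_oct) ** 2)


def _alpha_kernel(t: np.ndarray, latency: float, tau: float) -> np.ndarray:
    """Alpha-shaped onset kernel, peak value 1 at t = latency + tau."""
    s = (np.asarray(t, dtype=float) - latency) / tau
    out = np.where(s > 0, s * np.exp(1.0 - s), 0.0)
    return out


def simulate_behavior(
    params: BehaviorParams, seed: int
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Draw a trial table and lick stream from the planted SDT model.

    Returns ``(trials, licks, truth)``.  Outcomes in the returned table are
    already consistent with the behavior module's outcome classifier
    (offset-anchored response window, ``lick_threshold`` licks).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_trials

    u_cat = rng.random(n)
    is_probe = u_cat < params.p_probe
    is_nogo = (~is_probe) & (u_cat < params.p_probe + params.p_nogo)
    task = np.where(is_probe, "probe", np.where(rng.random(n) < 0.5, "easy", "hard"))
    category = np.where(is_probe, "probe", np.where(is_nogo, "nogo", "go"))

    freq = np.empty(n)
    d_trial = np.empty(n)
    probe_freqs = np.array(PROBE_FREQS_HZ)
    for i in range(n):
        if category[i] == "probe":
            freq[i] = probe_freqs[rng.integers(len(probe_freqs))]
            d_trial[i] = 0.0
        else:
            pair = EASY_FREQS_HZ if task[i] == "easy" else HARD_FREQS_HZ
            freq[i] = pair[0] if category[i] == "go" else pair[1]
            d_trial[i] = params.d_easy if task[i] == "easy" else params.d_hard

    sign = np.where(category == "go", 0.5, np.where(category == "nogo", -0.5, 0.0))
    p_lick = norm.cdf(sign * d_trial - params.c_bias)
    responds = rng.random(n) < p_lick

    onsets = np.empty(n)
    onsets[0] = 5.0
    gaps = rng.uniform(params.iti_range[0], params.iti_range[1], size=n - 1) if n > 1 else []
    onsets[1:] = onsets[0] + np.cumsum(gaps)

    lick_times: list[float] = []
    lick_count = np.zeros(n, dtype=int)
    first_latency = np.full(n, np.nan)
    win = params.response_window
    for i in range(n):
        if not responds[i]:
            continue
        # first lick after tone offset; truncated-normal latency keeps it
        # strictly inside the response window
        lat = rng.normal(params.lick_latency_mean, params.lick_latency_sd)
        while lat <= 0.02 or lat >= win - 0.2:
            lat = rng.normal(params.lick_latency_mean, params.lick_latency_sd)
        n_licks = params.lick_threshold + rng.poisson(
            max(0.0, params.licks_per_response_mean - params.lick_threshold)
        )
        gaps_l = rng.uniform(0.08, 0.15, size=n_licks - 1)
        rel = np.concatenate([[lat], lat + np.cumsum(gaps_l)])
        rel = rel[rel < win - 1e-6]
        if len(rel) < params.lick_threshold:
            # compress the train so the minimum count stays in the window
            rel = np.linspace(lat, win - 0.05, params.lick_threshold)
        t0 = onsets[i] + params.tone_dur
        lick_times.extend(t0 + rel)
        lick_count[i] = len(rel)
        first_latency[i] = params.tone_dur + rel[0]

    outcome = np.where(
        category == "go",
        np.where(responds, "hit", "miss"),
        np.where(
            category == "nogo",
            np.where(responds, "fa", "cr"),
            "probe",
        ),
    )

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n, dtype=int),
            "t_onset": onsets,
            "freq": freq,
            "level": 72.0,
            "category": category,
            "task": task,
            "tone_dur": params.tone_dur,
            "outcome": outcome,
            "lick_count": lick_count,
            "first_lick_latency": first_latency,
        }
    )
    counts = trials["outcome"].value_counts().to_dict()
    truth = GroundTruth(
        seed=seed,
        behavior=asdict(params),
        outcome_counts={k: int(v) for k, v in counts.items()},
    )
    return trials, np.sort(np.array(lick_times)), truth


def _draw_unit_spikes(
    rng: np.random.Generator,
    trials: pd.DataFrame,
    p: UnitParams,
    bf_log2: float,
    gains: np.ndarray,
    session_end: float,
) -> np.ndarray:
    """Exact inhomogeneous-Poisson spike train for one unit (superposition)."""
    spikes = []
    # homogeneous baseline over the whole session
    n_base = rng.poisson(p.baseline_rate * session_end)
    spikes.append(rng.uniform(0.0, session_end, size=n_base))

    onsets = trials["t_onset"].to_numpy()
    freqs = trials["freq"].to_numpy()
    lick_trial = trials["lick_count"].to_numpy() >= 1
    tone_dur = trials["tone_dur"].to_numpy()
    g_freq = _tuning(freqs, bf_log2, p.tuning_sd_oct)

    tau = p.evoked_decay
    evoked_span = p.evoked_latency + 10.0 * tau
    for i in range(len(trials)):
        g = gains[i]
        # evoked transient by thinning; analytic ceiling = peak of the kernel
        peak = p.evoked_gain * g_freq[i] * g
        if peak > 0:
            n_cand = rng.poisson(peak * evoked_span)
            t_cand = rng.uniform(0.0, evoked_span, size=n_cand)
            accept = rng.random(n_cand) * peak < peak * _alpha_kernel(
                t_cand, p.evoked_latency, tau
            )
            spikes.append(onsets[i] + t_cand[accept])
        # choice step on lick trials: homogeneous over its support
        if p.choice_gain > 0 and lick_trial[i]:
            t0, t1 = p.choice_onset, tone_dur[i] + 2.0
            if t1 > t0:
                n_ch = rng.poisson(p.choice_gain * g * (t1 - t0))
                spikes.append(onsets[i] + rng.uniform(t0, t1, size=n_ch))
    return np.sort(np.concatenate(spikes))


def simulate_units(
    trials: pd.DataFrame, params: UnitParams, seed: int
) -> tuple[list[Unit], GroundTruth]:
    """Simulate a population of Poisson units aligned to an existing trial table."""
    params.validate()
    if len(trials) == 0:
        raise ValueError("trials table is empty")
    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    session_end = float(trials["t_onset"].iloc[-1]) + 12.0

    cv = params.gain_noise_cv
    if cv > 0:
        shape = 1.0 / cv**2
        shared = rng.gamma(shape, scale=cv**2, size=n_trials)
    else:
        shared = np.ones(n_trials)

    units: list[Unit] = []
    truths: list[dict] = []
    for k in range(params.n_units):
        bf = params.bf_log2 + (
            rng.normal(0.0, params.bf_spread_oct) if params.bf_spread_oct > 0 else 0.0
        )
        if params.shared_gain or cv == 0:
            gains = shared
        else:
            gains = rng.gamma(1.0 / cv**2, scale=cv**2, size=n_trials)
        st = _draw_unit_spikes(rng, trials, params, bf, gains, session_end)
        units.append(
            Unit(
                unit_id=f"u{k:03d}",
                spike_times=st,
                depth_um=800.0 + 20.0 * k,
                region=("AUDp", "AUDd", "AUDv", "TEa")[k % 4],
                layer="L5/6",
                quality="good",
            )
        )
        t = asdict(params)
        t["bf_log2"] = float(bf)
        t["unit_id"] = units[-1].unit_id
        truths.append(t)
    return units, GroundTruth(seed=seed, units=truths)


def simulate_session(
    behavior_params: BehaviorParams,
    unit_params: UnitParams,
    seed: int,
    meta: dict | None = None,
) -> tuple[Session, GroundTruth]:
    """Full synthetic session: SDT behavior plus planted Poisson population."""
    trials, licks, btruth = simulate_behavior(behavior_params, seed)
    units, utruth = simulate_units(trials, unit_params, seed + 1)
    m = {"protocol": "task", "generator": "neurodisc.synthetic", "seed": seed}
    if meta:
        m.update(meta)
    truth = GroundTruth(
        seed=seed,
        behavior=btruth.behavior,
        units=utruth.units,
        outcome_counts=btruth.outcome_counts,
    )
    return Session(trials=trials, licks=licks, units=units, meta=m), truth


def simulate_fra_protocol(
    params: UnitParams, seed: int, n_reps: int = FRA_N_REPS
) -> Session:
    """Passive pure-tone session: 20 frequencies x 5 levels x 16 repetitions.

    Tones are 100 ms, presented once per second in randomized order.  The
    evoked gain scales monotonically with sound level (linear ramp from 0.2
    at 32 dB to 1.0 at 72 dB SPL); there is no lick stream and no choice
    signal.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    freqs = fra_frequencies()
    cells = [(f, lv) for f in freqs for lv in FRA_LEVELS_DB for _ in range(n_reps)]
    order = rng.permutation(len(cells))
    n = len(cells)

    onsets = 1.0 + np.arange(n, dtype=float) * 1.0
    freq = np.array([cells[i][0] for i in order])
    level = np.array([cells[i][1] for i in order])

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n, dtype=int),
            "t_onset": onsets,
            "freq": freq,
            "level": level,
            "category": "probe",
            "task": "probe",
            "tone_dur": 0.1,
            "outcome": "unclassified",
            "lick_count": 0,
            "first_lick_latency": np.nan,
        }
    )

    # level-dependent gain folded into the per-trial gain vector
    level_gain = 0.2 + 0.8 * (level - FRA_LEVELS_DB[0]) / (
        FRA_LEVELS_DB[-1] - FRA_LEVELS_DB[0]
    )
    cv = params.gain_noise_cv
    session_end = float(onsets[-1]) + 12.0
    units: list[Unit] = []
    for k in range(params.n_units):
        bf = params.bf_log2 + (
            rng.normal(0.0, params.bf_spread_oct) if params.bf_spread_oct > 0 else 0.0
        )
        noise = (
            rng.gamma(1.0 / cv**2, scale=cv**2, size=n) if cv > 0 else np.ones(n)
        )
        st = _draw_unit_spikes(rng, trials, params, bf, level_gain * noise, session_end)
        units.append(
            Unit(
                unit_id=f"u{k:03d}",
                spike_times=st,
                depth_um=800.0 + 20.0 * k,
                region=("AUDp", "AUDd", "AUDv", "TEa")[k % 4],
                layer="L5/6",
                quality="good",
            )
        )
    meta = {"protocol": "fra", "generator": "neurodisc.synthetic", "seed": seed}
    return Session(trials=trials, licks=np.empty(0), units=units, meta=meta)
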