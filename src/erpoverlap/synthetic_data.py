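"""Component-based synthetic EEG for a two-condition semantic-priming study.

The generator emulates a judgement-of-association (JAM) experiment: on each
trial a prime word is shown for 200 ms, the target word follows at an SOA of
500 ms, and the subject presses one of two buttons to judge the pair related
or unrelated. In the *speeded* condition the response follows the target as
fast as possible (RT decreases with the log association strength of the pair);
in the *delayed* condition a colour cue 1 s after target onset triggers the
response, so the reaction time (~1.26 s from target onset) carries no
association information.

The simulated EEG is a sum of smooth component waveforms with fixed scalp
topographies on a 32-channel 10-20 montage:

* a stimulus-evoked P2 after both prime and target onsets,
* an N400 peaking ~400 ms after the target, centro-parietal, whose (negative)
  amplitude shrinks linearly in log association strength,
* a decision-related P3 whose single-trial latency tracks the RT (speeded
  condition only by default),
* motor-related potentials locked to the button press (a negative ramp plus a
  biphasic motor potential with a left/right asymmetric topography),
* a cue-evoked P2 in the delayed condition,

plus 1/f ("pink") background noise, posterior alpha, and ocular artifacts
propagated from an EOG channel with known per-channel leakage gains. Ground
truth (true P3 latency, true N400 amplitude, response onset) is returned for
every trial so downstream estimators can be validated.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .containers import (
    CHANNELS_32,
    ComponentSpec,
    ContinuousRecording,
    SimulationConfig,
    SubjectProfile,
    WordPair,
    round_half_away,
)

__all__ = [
    "generate_stimulus_list",
    "default_profiles",
    "simulate_behavior",
    "default_components",
    "default_eog_propagation",
    "simulate_eeg",
    "stimulus_list_frame",
]

TRIAL_COLUMNS = [
    "trial_id", "subject_id", "pair_id", "as_score", "condition",
    "rt_s", "response", "missed",
]


# ---------------------------------------------------------------------------
# Stimulus list
# ---------------------------------------------------------------------------

def generate_stimulus_list(n_total=800, n_zero=100, n_top=100,
                           top_range=(69, 95), seed=0):
    """Compose a stimulus list of word-pairs with graded association strength.

    The list has three blocks: ``n_zero`` pairs with AS = 0 (random pairings
    absent from the association norms), ``n_top`` pairs with AS drawn uniformly
    from ``top_range`` (the strongest associates), and a middle block whose
    log(AS) is uniform on [log 1, log top_range[0]] so the full range between
    unrelated and top pairs is covered on a log scale.

    Returns a list of :class:`WordPair`, shuffled into presentation order.
    """
    lo, hi = int(top_range[0]), int(top_range[1])
    if not (1 <= lo <= hi <= 100):
        raise ValueError(f"top_range must lie within 1-100, got {top_range}")
    if n_zero < 0 or n_top < 0 or n_zero + n_top > n_total:
        raise ValueError(
            f"block counts invalid: n_zero({n_zero}) + n_top({n_top}) "
            f"must not exceed n_total({n_total})"
        )
    rng = np.random.default_rng(seed)
    n_mid = n_total - n_zero - n_top

    as_zero = np.zeros(n_zero, dtype=int)
    as_top = rng.integers(lo, hi + 1, size=n_top)
    log_u = rng.uniform(0.0, math.log(lo), size=n_mid)
    # keep the middle block strictly below the top range after rounding
    as_mid = np.clip(round_half_away(np.exp(log_u)), 1, lo - 1)

    as_all = np.concatenate([as_zero, as_mid, as_top])
    order = rng.permutation(n_total)
    as_all = as_all[order]

    # lexical covariates: short, common, well-connected words
    lengths = rng.integers(4, 7, size=n_total)
    in_degree = 5 + rng.poisson(12, size=n_total)
    return [
        WordPair(pair_id=i, as_score=int(a), target_length=int(l),
                 in_degree=int(d))
        for i, (a, l, d) in enumerate(zip(as_all, lengths, in_degree))
    ]


def stimulus_list_frame(pairs):
    """Stimulus list as a DataFrame (pair_id, as_score, target_length, in_degree)."""
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "as_score": [p.as_score for p in pairs],
            "target_length": [p.target_length for p in pairs],
            "in_degree": [p.in_degree for p in pairs],
        }
    )


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def default_profiles(n_subjects=10, condition="speeded", seed=0):
    """Subject profiles with mild between-subject variability.

    The population means are calibrated to the binned descriptives of a
    speeded JAM task: bin-mean RT rising from ~0.49 s (strong associates) to
    ~0.67 s (unrelated pairs) and the related-response ratio falling from
    ~0.98 to ~0.26. Miss (no-response) rates default to 3% speeded and 0.6%
    delayed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    miss = 0.03 if condition == "speeded" else 0.006
    profiles = []
    for s in range(n_subjects):
        profiles.append(SubjectProfile(
            subject_id=s,
            rt_intercept=float(rng.normal(0.67, 0.04)),
            rt_logas_slope=float(-abs(rng.normal(0.042, 0.007))),
            rt_noise_sd=float(abs(rng.normal(0.125, 0.01))),
            bias_midpoint=float(rng.normal(-1.3, 0.15)),
            bias_slope=float(abs(rng.normal(0.7, 0.05))),
            miss_rate=miss,
        ))
    return profiles


def simulate_behavior(pairs, profiles, condition, seed=0, deadline=1.0,
                      delayed_rt_mean=1.26, delayed_rt_sd=0.131, cue_delay=1.0,
                      trial_id_start=0):
    """Simulate one JAM session per subject: RT, binary judgement, misses.

    Every pair is presented once per subject. Speeded RTs follow the subject's
    log-AS model clipped to the response deadline; delayed RTs are drawn around
    ``delayed_rt_mean`` seconds from target onset, independent of AS, and
    confined to the post-cue response window. Returns a trial table with
    columns ``trial_id, subject_id, pair_id, as_score, condition, rt_s,
    response, missed`` (rt_s and response are NaN for missed trials).
    """
    if condition not in {"speeded", "delayed"}:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    as_scores = np.array([p.as_score for p in pairs], dtype=float)
    logas = np.log(np.maximum(as_scores, 1.0))
    n = len(pairs)

    rows = []
    trial_id = trial_id_start
    for prof in profiles:
        if condition == "speeded":
            rt = prof.rt_intercept + prof.rt_logas_slope * logas
            rt = rt + rng.normal(0.0, prof.rt_noise_sd, size=n)
            rt = np.clip(rt, 0.15, deadline)
        else:
            rt = rng.normal(delayed_rt_mean, delayed_rt_sd, size=n)
            rt = np.clip(rt, cue_delay + 0.05, cue_delay + deadline)

        latent = np.where(as_scores >= 1, logas, prof.zero_as_latent)
        p_rel = 1.0 / (1.0 + np.exp(-prof.bias_slope * (latent - prof.bias_midpoint)))
        resp = (rng.uniform(size=n) < p_rel).astype(float)
        missed = rng.uniform(size=n) < prof.miss_rate

        for i, p in enumerate(pairs):
            rows.append((
                trial_id, prof.subject_id, p.pair_id, p.as_score, condition,
                np.nan if missed[i] else float(rt[i]),
                np.nan if missed[i] else float(resp[i]),
                bool(missed[i]),
            ))
            trial_id += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Component inventory
# ---------------------------------------------------------------------------

def _topo(**gains):
    return dict(gains)


TOPO_P2 = _topo(Fz=1.0, Cz=0.9, FC1=0.8, FC2=0.8, F3=0.7, F4=0.7, AF3=0.5,
                AF4=0.5, Fp1=0.4, Fp2=0.4, C3=0.5, C4=0.5, CP1=0.35, CP2=0.35,
                Pz=0.3)
TOPO_N400 = _topo(Pz=1.0, CP1=0.85, CP2=0.85, Cz=0.8, P3=0.7, P4=0.7,
                  CP5=0.5, CP6=0.5, PO3=0.45, PO4=0.45, C3=0.45, C4=0.45,
                  Fz=0.3, Oz=0.25)
TOPO_P3 = _topo(Pz=1.0, P3=0.9, CP1=0.85, CP5=0.6, P4=0.7, CP2=0.75,
                PO3=0.6, PO4=0.5, Oz=0.5, O1=0.45, O2=0.4, Cz=0.6, P7=0.45,
                P8=0.35, C3=0.35, C4=0.3)
TOPO_NS = _topo(Cz=1.0, FC1=0.8, FC2=0.8, Fz=0.7, C3=0.65, C4=0.55,
                CP1=0.45, CP2=0.45)
TOPO_MP = _topo(CP5=0.8, P7=0.7, P3=0.6, CP1=0.4, C3=0.3,      # left-posterior +
                Cz=-1.0, Fz=-0.8, FC1=-0.7, FC2=-0.6, F3=-0.4, F4=-0.35)
TOPO_CUEP2 = _topo(F4=1.0, FC2=0.8, AF4=0.7, Fz=0.7, F8=0.6, Cz=0.5,
                   FC6=0.5, C4=0.4)
TOPO_ALPHA = _topo(Oz=1.0, O1=0.9, O2=0.9, PO3=0.8, PO4=0.8, Pz=0.6, P3=0.6,
                   P4=0.6, P7=0.5, P8=0.5, CP1=0.3, CP2=0.3, CP5=0.3, CP6=0.3)


def default_components(condition="speeded", p3_amplitude=8.0,
                       n400_base=-4.0, n400_logas_slope=0.7,
                       p3_jitter_sd=0.05, include_p3=None):
    """Default ERP component inventory for one condition.

    ``include_p3=None`` follows the condition default: an RT-coupled P3 in the
    speeded condition, no decision-locked P3 in the delayed condition.
    """
    if include_p3 is None:
        include_p3 = condition == "speeded"
    comps = [
        ComponentSpec("P2_prime", TOPO_P2, "prime", 0.25, "gaussian", 0.05, 4.0),
        ComponentSpec("P2", TOPO_P2, "stimulus", 0.25, "gaussian", 0.05, 5.0),
        ComponentSpec("N400", TOPO_N400, "stimulus", 0.40, "gaussian", 0.08,
                      n400_base, amplitude_rule="logas",
                      amplitude_logas_slope=n400_logas_slope),
        ComponentSpec("NS", TOPO_NS, "response", 0.0, "ramp", 0.30, -2.0),
        ComponentSpec("MP", TOPO_MP, "response", 0.0, "biphasic", 0.05, 3.0),
    ]
    if include_p3:
        comps.append(ComponentSpec("P3", TOPO_P3, "rt", 0.0, "gaussian", 0.12,
                                   p3_amplitude, latency_jitter_sd=p3_jitter_sd))
    if condition == "delayed":
        comps.append(ComponentSpec("cueP2", TOPO_CUEP2, "cue", 0.30,
                                   "gaussian", 0.06, 5.0))
    return tuple(comps)


def default_eog_propagation(channel_names=CHANNELS_32):
    """Front-to-back decaying blink leakage gains, one per EEG channel."""
    by_prefix = [("Fp", 0.35), ("AF", 0.25), ("F", 0.15), ("FC", 0.08),
                 ("CP", 0.03), ("C", 0.05), ("PO", 0.012), ("P", 0.02),
                 ("O", 0.01), ("T", 0.04)]
    gains = {}
    for ch in channel_names:
        for prefix, g in by_prefix:
            if ch.startswith(prefix):
                gains[ch] = g
                break
        else:
            gains[ch] = 0.02
    return gains


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def component_waveform(times, spec, center):
    """Evaluate a unit-amplitude component waveform on absolute time points.

    ``center`` is the component's latency anchor in recording time: the peak
    for ``gaussian``/``biphasic``, the end of the rise for ``ramp``.
    """
    t = np.asarray(times, dtype=float) - center
    if spec.waveform == "gaussian":
        return np.exp(-0.5 * (t / spec.width) ** 2)
    if spec.waveform == "ramp":
        # linear rise over [-width, 0], linear decay back to 0 over 0.1 s
        rise = np.clip(1.0 + t / spec.width, 0.0, None) * (t <= 0)
        decay = np.clip(1.0 - t / 0.1, 0.0, None) * (t > 0)
        return np.clip(rise + decay, 0.0, 1.0)
    if spec.waveform == "biphasic":
        w = -t / spec.width * np.exp(0.5 - 0.5 * (t / spec.width) ** 2)
        return w
    raise ValueError(f"unknown waveform {spec.waveform!r}")


def _waveform_support(spec):
    """Half-width (seconds) outside which the waveform is negligible."""
    if spec.waveform == "gaussian":
        return 5.0 * spec.width
    if spec.waveform == "ramp":
        return spec.width + 0.1
    return 6.0 * spec.width


def component_amplitude(spec, as_score):
    if spec.amplitude_rule == "constant":
        return spec.amplitude
    if spec.amplitude_rule == "logas":
        return spec.amplitude + spec.amplitude_logas_slope * math.log(max(as_score, 1.0))
    raise ValueError(f"unknown amplitude_rule {spec.amplitude_rule!r}")


# ---------------------------------------------------------------------------
# Noise and artifacts
# ---------------------------------------------------------------------------

def pink_noise(n_samples, n_channels, sfreq, exponent, rms, rng):
    """1/f^exponent noise, each channel independent, scaled to a target RMS.

    Synthesised in the frequency domain at the next FFT-friendly length and
    truncated (arbitrary lengths can hit slow prime-factor transforms).
    """
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    n_fft = sp_fft.next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * scale
    x = np.fft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    x = np.ascontiguousarray(x)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def alpha_noise(n_samples, sfreq, freq, rms, rng):
    """Narrowband (freq +/- 2 Hz) oscillatory noise with unit spatial gain."""
    if rms == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    sos = signal.butter(4, [freq - 2.0, freq + 2.0], btype="bandpass",
                        output="sos", fs=sfreq)
    x = signal.sosfiltfilt(sos, white)
    return x * (rms / np.sqrt(np.mean(x ** 2)))


def blink_train(n_samples, sfreq, rate, amplitude, rng, refractory=0.5):
    """EOG blink signal: Gaussian bumps at quasi-Poisson times."""
    duration = n_samples / sfreq
    x = np.zeros(n_samples)
    t = rng.exponential(1.0 / rate) if rate > 0 else np.inf
    times = np.arange(n_samples) / sfreq
    while t < duration:
        amp = amplitude * rng.uniform(0.7, 1.3)
        lo = max(0, int((t - 0.4) * sfreq))
        hi = min(n_samples, int((t + 0.4) * sfreq) + 1)
        x[lo:hi] += amp * np.exp(-0.5 * ((times[lo:hi] - t) / 0.06) ** 2)
        t += refractory + rng.exponential(1.0 / rate)
    return x


# ---------------------------------------------------------------------------
# Continuous EEG
# ---------------------------------------------------------------------------

def trial_event_times(trials, config):
    """Absolute event times per trial: prime, target, cue, response onsets.

    Target onsets are spaced ``config.trial_interval`` apart with a 2 s lead-in.
    Raises if a response would precede its target (event collision).
    """
    n = len(trials)
    target = 2.0 + np.arange(n) * config.trial_interval
    prime = target - config.soa
    rt = trials["rt_s"].to_numpy(dtype=float)
    response = target + rt
    bad = np.where(rt <= 0)[0]
    if len(bad):
        ids = trials.iloc[bad]["trial_id"].tolist()
        raise ValueError(f"event collision: response at/before target for trials {ids}")
    cue = target + config.cue_delay if config.condition == "delayed" else None
    return prime, target, cue, response


def simulate_eeg(trials, config, seed=0):
    """Render a continuous multichannel recording for a table of trials.

    Returns ``(recording, ground_truth)`` where ``ground_truth`` has one row
    per trial: ``trial_id, true_p3_latency_s`` (seconds from target onset, NaN
    when no decision-locked P3 was injected), ``true_n400_amp_uv`` and
    ``true_response_onset_s`` (NaN for missed trials).
    """
    trials = trials.reset_index(drop=True)
    specs = config.component_specs or default_components(config.condition)
    propagation = config.eog_propagation or default_eog_propagation(config.channel_names)
    sfreq = config.sfreq_raw
    ss = np.random.SeedSequence((seed, 101))
    rng_noise, rng_lat, rng_blink = (np.random.default_rng(c) for c in ss.spawn(3))

    prime_t, target_t, cue_t, response_t = trial_event_times(trials, config)
    n_samples = int(round((target_t[-1] + 3.0) * sfreq))
    channels = list(config.all_channels)
    n_eeg = len(config.channel_names)
    data = np.zeros((len(channels), n_samples))
    times = np.arange(n_samples) / sfreq

    # background noise
    data[:n_eeg] += pink_noise(n_samples, n_eeg, sfreq, config.pink_exponent,
                               config.pink_rms, rng_noise)
    if config.alpha_rms > 0:
        alpha = alpha_noise(n_samples, sfreq, config.alpha_freq,
                            config.alpha_rms, rng_noise)
        gains = np.array([TOPO_ALPHA.get(ch, 0.15) for ch in config.channel_names])
        data[:n_eeg] += gains[:, None] * alpha[None, :]

    # ocular artifacts: blink train on EOG, propagated with known gains
    eog = blink_train(n_samples, sfreq, config.blink_rate,
                      config.blink_amplitude, rng_blink)
    data[n_eeg] = eog
    prop = np.array([propagation.get(ch, 0.0) for ch in config.channel_names])
    data[:n_eeg] += prop[:, None] * eog[None, :]

    # ERP components
    topo_cache = {
        spec.name: np.array([spec.topography.get(ch, 0.0)
                             for ch in config.channel_names])
        for spec in specs
    }
    gt = {
        "trial_id": trials["trial_id"].to_numpy(),
        "true_p3_latency_s": np.full(len(trials), np.nan),
        "true_n400_amp_uv": np.zeros(len(trials)),
        "true_response_onset_s": np.full(len(trials), np.nan),
    }
    events = []
    for i in range(len(trials)):
        tid = trials.at[i, "trial_id"]
        missed = bool(trials.at[i, "missed"])
        as_score = float(trials.at[i, "as_score"])
        events.append((round_half_away(prime_t[i] * sfreq), "prime", tid))
        events.append((round_half_away(target_t[i] * sfreq), "target", tid))
        if cue_t is not None:
            events.append((round_half_away(cue_t[i] * sfreq), "cue", tid))
        if not missed:
            events.append((round_half_away(response_t[i] * sfreq), "response", tid))
            gt["true_response_onset_s"][i] = response_t[i] - target_t[i]

        for spec in specs:
            if spec.latency_rule == "prime":
                center = prime_t[i] + spec.latency_offset
            elif spec.latency_rule == "stimulus":
                center = target_t[i] + spec.latency_offset
            elif spec.latency_rule == "cue":
                if cue_t is None:
                    continue
                center = cue_t[i] + spec.latency_offset
            elif spec.latency_rule in ("rt", "response"):
                if missed:
                    continue
                center = response_t[i] + spec.latency_offset
                if spec.latency_rule == "rt" and spec.latency_jitter_sd > 0:
                    center += rng_lat.normal(0.0, spec.latency_jitter_sd)
            amp = component_amplitude(spec, as_score)
            if spec.name == "N400":
                gt["true_n400_amp_uv"][i] = amp
            elif spec.name == "P3":
                gt["true_p3_latency_s"][i] = center - target_t[i]
            if amp == 0.0:
                continue
            half = _waveform_support(spec)
            lo = max(0, int((center - half) * sfreq))
            hi = min(n_samples, int((center + half) * sfreq) + 1)
            if hi <= lo:
                continue
            wf = amp * component_waveform(times[lo:hi], spec, center)
            data[:n_eeg, lo:hi] += topo_cache[spec.name][:, None] * wf[None, :]

    events = pd.DataFrame(events, columns=["sample", "label", "trial_id"])
    events = events.sort_values("sample", kind="stable").reset_index(drop=True)
    rec = ContinuousRecording(
        data=data, sfreq=sfreq, channel_names=channels, events=events,
        history=[{"stage": "simulate_eeg", "seed": seed,
                  "condition": config.condition, "n_trials": len(trials)}],
    )
    return rec, pd.DataFrame(gt)
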