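"""Core data containers shared across the pipeline.

All signal amplitudes are in microvolts, all times in seconds, all sampling
rates in Hz. Event tables and trial metadata are plain :class:`pandas.DataFrame`
objects so they can be exported as TSV without conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WordPair",
    "SubjectProfile",
    "ComponentSpec",
    "SimulationConfig",
    "ContinuousRecording",
    "EpochSet",
    "round_half_away",
]


def round_half_away(x):
    """Round to nearest integer, halves away from zero (not banker's rounding)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64) if out.ndim else int(out)


@dataclass(frozen=True)
class WordPair:
    """One stimulus item: a (prime, target) pair with its association strength.

    Association strength (AS) is the number of norm-study participants (of 100)
    who produced the target as their first free associate of the prime.
    ``target_length`` and ``in_degree`` are lexical covariates carried along for
    realism; they do not drive any simulated effect.
    """

    pair_id: int
    as_score: int
    target_length: int
    in_degree: int

    def __post_init__(self):
        if self.as_score < 0:
            raise ValueError("as_score must be >= 0")
        if not 4 <= self.target_length <= 6:
            raise ValueError("target_length must be within 4-6 letters")
        if self.in_degree < 5:
            raise ValueError("in_degree must be >= 5")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative behavioural parameters for one simulated subject.

    The speeded reaction time model is
    ``RT = rt_intercept + rt_logas_slope * log(max(AS, 1)) + N(0, rt_noise_sd)``
    clipped to the response deadline. The binary related/unrelated judgement is
    a logistic in latent log-association ``x``:
    ``P(related) = 1 / (1 + exp(-bias_slope * (x - bias_midpoint)))`` where
    ``x = log(AS)`` for AS >= 1 and ``x = zero_as_latent`` for AS = 0 (random
    pairings sit below AS=1 pairs on the latent relatedness scale).
    """

    subject_id: int
    rt_intercept: float = 0.67
    rt_logas_slope: float = -0.042
    rt_noise_sd: float = 0.13
    bias_midpoint: float = -1.3
    bias_slope: float = 0.7
    miss_rate: float = 0.02
    zero_as_latent: float = -2.8

    def __post_init__(self):
        if self.rt_intercept <= 0:
            raise ValueError("rt_intercept must be positive")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ComponentSpec:
    """One simulated ERP component.

    ``topography`` maps channel name to unit gain; channels not listed get 0.
    ``latency_rule`` is one of ``stimulus`` (fixed offset from target onset),
    ``prime`` (fixed offset from prime onset), ``rt`` (offset = RT + jitter),
    ``cue`` (fixed offset from the response cue) or ``response`` (locked to the
    button press). ``waveform`` is ``gaussian``, ``ramp`` (linear rise ending at
    the latency) or ``biphasic`` (Gaussian derivative).
    ``amplitude_rule`` is ``constant`` or ``logas`` (linear in log(max(AS,1))).
    """

    name: str
    topography: dict
    latency_rule: str
    latency_offset: float
    waveform: str
    width: float
    amplitude: float
    amplitude_rule: str = "constant"
    amplitude_logas_slope: float = 0.0
    latency_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("waveform width must be positive")
        if self.latency_rule not in {"stimulus", "prime", "rt", "cue", "response"}:
            raise ValueError(f"unknown latency_rule {self.latency_rule!r}")
        if self.waveform not in {"gaussian", "ramp", "biphasic"}:
            raise ValueError(f"unknown waveform {self.waveform!r}")


#: 32-channel extended 10-20 montage (BioSemi ordering); EOG is appended last.
CHANNELS_32 = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)


@dataclass
class SimulationConfig:
    """Full description of one simulated recording session."""

    n_subjects: int = 10
    n_pairs: int = 800
    condition: str = "speeded"
    sfreq_raw: float = 512.0
    channel_names: tuple = CHANNELS_32
    eog_name: str = "EOG"
    component_specs: tuple = ()           # filled by synthetic_data defaults
    pink_exponent: float = 1.0
    pink_rms: float = 13.5                # broadband pink-noise RMS per channel
    alpha_rms: float = 3.0                # 8-12 Hz narrowband RMS at Oz
    alpha_freq: float = 10.0
    blink_rate: float = 0.15              # blinks per second on the EOG channel
    blink_amplitude: float = 150.0
    eog_propagation: dict = field(default_factory=dict)
    trial_interval: float = 3.2           # target-onset to target-onset spacing
    soa: float = 0.5                      # prime-to-target onset asynchrony
    cue_delay: float = 1.0                # target onset to response cue (delayed)
    response_deadline: float = 1.0        # from target (speeded) / cue (delayed)
    seed: int = 0

    def __post_init__(self):
        if self.sfreq_raw < 512.0:
            raise ValueError(
                "sfreq_raw must be >= 512 Hz so the 0.1-50 Hz filter and "
                "256 Hz resampling stage are exercised"
            )
        if "Pz" not in self.channel_names:
            raise ValueError("channel montage must include Pz")
        if self.condition not in {"speeded", "delayed"}:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def all_channels(self):
        return tuple(self.channel_names) + (self.eog_name,)


@dataclass
class ContinuousRecording:
    """Multichannel continuous time series with event markers.

    ``events`` is a DataFrame with columns ``sample`` (int index into the time
    axis), ``label`` (``prime``/``target``/``cue``/``response``) and
    ``trial_id``.
    """

    data: np.ndarray                       # channels x samples, microvolt
    sfreq: float
    channel_names: Sequence[str]
    events: pd.DataFrame
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.events) and (
            (self.events["sample"] < 0).any()
            or (self.events["sample"] >= self.data.shape[1]).any()
        ):
            raise ValueError("event sample indices must lie within the data")

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def duration(self):
        return self.n_samples / self.sfreq

    def channel_index(self, name):
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy_with(self, data=None, sfreq=None, events=None, history_entry=None):
        hist = list(self.history)
        if history_entry is not None:
            hist.append(history_entry)
        return ContinuousRecording(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq if sfreq is None else sfreq,
            channel_names=tuple(self.channel_names),
            events=(self.events if events is None else events).copy(),
            history=hist,
        )

    def save(self, path):
        _save_container(path, {"data": self.data}, {
            "kind": "recording",
            "sfreq": self.sfreq,
            "channel_names": list(self.channel_names),
            "events": self.events.to_dict(orient="list"),
            "history": self.history,
        })

    @classmethod
    def load(cls, path):
        arrays, meta = _load_container(path, "recording")
        return cls(
            data=arrays["data"],
            sfreq=meta["sfreq"],
            channel_names=tuple(meta["channel_names"]),
            events=pd.DataFrame(meta["events"]),
            history=meta.get("history", []),
        )


@dataclass
class EpochSet:
    """Trials x channels x samples array locked to an event.

    ``t0`` is the time of the first sample relative to the lock event (negative
    for pre-event baseline). ``metadata`` has one row per epoch, aligned with
    the first axis of ``data``, and always carries ``trial_id``.
    """

    data: np.ndarray
    t0: float
    sfreq: float
    lock: str
    channel_names: Sequence[str]
    metadata: pd.DataFrame
    history: list = field(default_factory=list)
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial_id", "reason"])
    )

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count must equal trial count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match data channels")
        if not (self.t0 < 0 <= self.t0 + self.data.shape[2] / self.sfreq):
            raise ValueError("epoch must contain t=0 (t0 < 0 <= t0 + span)")

    @property
    def n_epochs(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[2]

    @property
    def times(self):
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def channel_index(self, name):
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def time_index(self, t):
        """Sample index of time ``t`` (round-half-away-from-zero on the grid)."""
        idx = int(round_half_away((t - self.t0) * self.sfreq))
        if not 0 <= idx < self.n_samples:
            raise ValueError(f"time {t} s outside epoch span")
        return idx

    def copy_with(self, data=None, metadata=None, history_entry=None, **kw):
        hist = list(self.history)
        if history_entry is not None:
            hist.append(history_entry)
        return EpochSet(
            data=self.data.copy() if data is None else data,
            t0=kw.get("t0", self.t0),
            sfreq=kw.get("sfreq", self.sfreq),
            lock=kw.get("lock", self.lock),
            channel_names=tuple(self.channel_names),
            metadata=(self.metadata if metadata is None else metadata).copy(),
            history=hist,
            drop_log=kw.get("drop_log", self.drop_log).copy(),
        )

    def save(self, path):
        _save_container(path, {"data": self.data}, {
            "kind": "epochs",
            "t0": self.t0,
            "sfreq": self.sfreq,
            "lock": self.lock,
            "channel_names": list(self.channel_names),
            "metadata": self.metadata.to_dict(orient="list"),
            "drop_log": self.drop_log.to_dict(orient="list"),
            "history": self.history,
        })

    @classmethod
    def load(cls, path):
        arrays, meta = _load_container(path, "epochs")
        return cls(
            data=arrays["data"],
            t0=meta["t0"],
            sfreq=meta["sfreq"],
            lock=meta["lock"],
            channel_names=tuple(meta["channel_names"]),
            metadata=pd.DataFrame(meta["metadata"]),
            history=meta.get("history", []),
            drop_log=pd.DataFrame(meta.get("drop_log", {"trial_id": [], "reason": []})),
        )


def _save_container(path, arrays, meta):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, default=_json_default, indent=1))


def _load_container(path, kind):
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("kind") != kind:
        raise ValueError(f"expected a {kind} container, found {meta.get('kind')!r}")
    return arrays, meta


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
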