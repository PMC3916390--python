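"""Trial binning and event-related-potential construction.

Trials are sorted by association strength (descending, so bin 1 holds the
strongest associates) or by reaction time (ascending, so bin 1 holds the
fastest responses) and split into equal-size contiguous bins. Per-subject bin
ERPs are plain trial averages; the grand average is the unweighted mean of the
subject ERPs. Response-locked ERPs are obtained by re-cutting stimulus-locked
epochs around each trial's button press.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, round_half_away

__all__ = [
    "BinAssignment",
    "ErpSet",
    "bin_trials",
    "average_erp",
    "grand_average",
    "relock_to_response",
    "mean_amplitude",
    "topography",
]


@dataclass
class BinAssignment:
    """Mapping trial_id -> bin index (1..n_bins) plus per-bin descriptives."""

    assignment: pd.DataFrame          # columns: trial_id, bin
    sort_key: str                     # "as" or "rt"
    n_bins: int
    descriptives: pd.DataFrame        # bin, n, mean_as, sd_as, mean_rt, sd_rt, response_ratio
    notes: list = field(default_factory=list)

    def bin_of(self, trial_ids):
        lut = dict(zip(self.assignment["trial_id"], self.assignment["bin"]))
        return np.array([lut[t] for t in trial_ids])


def bin_trials(metadata, key="as", n_bins=8):
    """Sort trials by AS (descending) or RT (ascending) into equal-size bins.

    The sort is stable with ties broken by ``trial_id``; bins are contiguous
    blocks, bin 1 holding the highest-AS (or shortest-RT) trials. When the
    trial count is not divisible by ``n_bins`` the lowest-index bins each
    receive one extra trial (noted in ``notes``).
    """
    if key not in {"as", "rt"}:
        raise ValueError("key must be 'as' or 'rt'")
    col = "as_score" if key == "as" else "rt_s"
    meta = metadata.copy()
    vals = meta[col].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{col} must be present and finite for all trials "
                         "(reject missed trials first)")
    n = len(meta)
    if n_bins > n:
        raise ValueError(f"n_bins ({n_bins}) exceeds trial count ({n})")
    ascending = key == "rt"
    order = meta.sort_values([col, "trial_id"],
                             ascending=[ascending, True],
                             kind="stable").reset_index(drop=True)
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if b < extra else 0) for b in range(n_bins)]
    notes = []
    if extra:
        notes.append(f"{extra} remainder trial(s) assigned to bins 1..{extra}")
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    order["bin"] = bins

    rows = []
    for b, grp in order.groupby("bin"):
        resp = grp["response"].dropna()
        rows.append({
            "bin": b,
            "n": len(grp),
            "mean_as": grp["as_score"].mean(),
            "sd_as": grp["as_score"].std(ddof=1),
            "mean_rt": grp["rt_s"].mean(),
            "sd_rt": grp["rt_s"].std(ddof=1),
            "response_ratio": resp.mean() if len(resp) else np.nan,
        })
    return BinAssignment(
        assignment=order[["trial_id", "bin"]].reset_index(drop=True),
        sort_key=key, n_bins=n_bins,
        descriptives=pd.DataFrame(rows), notes=notes,
    )


@dataclass
class ErpSet:
    """Bin-wise averaged waveforms (subject level or grand average)."""

    waveforms: np.ndarray             # bins x channels x samples
    t0: float
    sfreq: float
    lock: str
    level: str                        # "subject" or "grand"
    channel_names: tuple
    n_trials: np.ndarray              # trials per bin
    history: list = field(default_factory=list)

    @property
    def times(self):
        return self.t0 + np.arange(self.waveforms.shape[2]) / self.sfreq

    def channel_index(self, name):
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in ErpSet") from None

    def time_index(self, t):
        idx = int(round_half_away((t - self.t0) * self.sfreq))
        if not 0 <= idx < self.waveforms.shape[2]:
            raise ValueError(f"time {t} s outside epoch span")
        return idx


def average_erp(epochs, assignment):
    """Average epochs within each bin of a :class:`BinAssignment`."""
    bins = assignment.bin_of(epochs.metadata["trial_id"].to_numpy())
    waves, counts = [], []
    for b in range(1, assignment.n_bins + 1):
        mask = bins == b
        if not mask.any():
            raise ValueError(f"bin {b} contains no epochs")
        waves.append(epochs.data[mask].mean(axis=0))
        counts.append(int(mask.sum()))
    return ErpSet(
        waveforms=np.stack(waves), t0=epochs.t0, sfreq=epochs.sfreq,
        lock=epochs.lock, level="subject",
        channel_names=tuple(epochs.channel_names),
        n_trials=np.array(counts),
        history=list(epochs.history) + [{"stage": "average_erp",
                                         "key": assignment.sort_key}],
    )


def grand_average(erp_sets):
    """Unweighted mean of per-subject ErpSets (each bin averaged across subjects)."""
    erp_sets = list(erp_sets)
    if not erp_sets:
        raise ValueError("no ErpSets given")
    ref = erp_sets[0]
    for e in erp_sets[1:]:
        if e.waveforms.shape != ref.waveforms.shape or e.sfreq != ref.sfreq:
            raise ValueError("all subjects must share bin structure and sampling")
    stack = np.stack([e.waveforms for e in erp_sets])
    return ErpSet(
        waveforms=stack.mean(axis=0), t0=ref.t0, sfreq=ref.sfreq,
        lock=ref.lock, level="grand", channel_names=ref.channel_names,
        n_trials=np.sum([e.n_trials for e in erp_sets], axis=0),
        history=[{"stage": "grand_average", "n_subjects": len(erp_sets)}],
    )


def relock_to_response(epochs, window=(-0.5, 0.5)):
    """Re-cut stimulus-locked epochs around each trial's response onset.

    Trials without a response, or whose response window exceeds the source
    epoch, are dropped and logged.
    """
    if "rt_s" not in epochs.metadata.columns:
        raise ValueError("metadata lacks rt_s (response onsets unknown)")
    sfreq = epochs.sfreq
    offset = int(round_half_away(window[0] * sfreq))
    n_samp = int(round_half_away((window[1] - window[0]) * sfreq))
    cuts, kept_rows, dropped = [], [], []
    rts = epochs.metadata["rt_s"].to_numpy(dtype=float)
    for i in range(epochs.n_epochs):
        tid = epochs.metadata.at[i, "trial_id"]
        if not np.isfinite(rts[i]):
            dropped.append((tid, "no response onset"))
            continue
        center = int(round_half_away((rts[i] - epochs.t0) * sfreq))
        start = center + offset
        if start < 0 or start + n_samp > epochs.n_samples:
            dropped.append((tid, "response window exceeds source epoch"))
            continue
        cuts.append(epochs.data[i, :, start:start + n_samp])
        kept_rows.append(i)
    if not cuts:
        raise ValueError("no trials survive response re-locking")
    drop_log = pd.concat(
        [epochs.drop_log, pd.DataFrame(dropped, columns=["trial_id", "reason"])],
        ignore_index=True)
    return EpochSet(
        data=np.stack(cuts), t0=offset / sfreq, sfreq=sfreq, lock="response",
        channel_names=tuple(epochs.channel_names),
        metadata=epochs.metadata.iloc[kept_rows].reset_index(drop=True),
        history=list(epochs.history) + [{"stage": "relock_to_response",
                                         "window": list(window),
                                         "n_dropped": len(dropped)}],
        drop_log=drop_log,
    )


def _window_slice(t0, sfreq, n_samples, window):
    i0 = int(round_half_away((window[0] - t0) * sfreq))
    i1 = int(round_half_away((window[1] - t0) * sfreq))
    if i0 < 0 or i1 > n_samples or i1 <= i0:
        raise ValueError(f"window {window} outside epoch span")
    return i0, i1


def mean_amplitude(obj, channel, window):
    """Mean voltage over a time window at one channel.

    For an :class:`EpochSet` returns one value per trial; for an
    :class:`ErpSet` one value per bin. The window is half-open in sample space.
    """
    ci = obj.channel_index(channel)
    if isinstance(obj, EpochSet):
        i0, i1 = _window_slice(obj.t0, obj.sfreq, obj.n_samples, window)
        return obj.data[:, ci, i0:i1].mean(axis=1)
    i0, i1 = _window_slice(obj.t0, obj.sfreq, obj.waveforms.shape[2], window)
    return obj.waveforms[:, ci, i0:i1].mean(axis=1)


def topography(erp_set, time_s, bin_a=1, bin_b=None):
    """Channel-wise voltage snapshot at the sample nearest ``time_s``.

    With ``bin_b`` given, returns the difference map ``bin_a - bin_b``
    (bin indices are 1-based).
    """
    times = erp_set.times
    if not times[0] <= time_s <= times[-1]:
        raise ValueError(f"time {time_s} s outside epoch span")
    idx = int(np.argmin(np.abs(times - time_s)))
    snap = erp_set.waveforms[bin_a - 1, :, idx]
    if bin_b is not None:
        snap = snap - erp_set.waveforms[bin_b - 1, :, idx]
    return snap.copy()
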