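"""Offline EEG signal chain: zero-phase IIR filtering, resampling, EOG
regression, epoching, baseline correction and no-response rejection.

The canonical chain order is fixed (see :func:`run_chain`): a wide 0.1-50 Hz
band-pass on the raw record, resampling to 256 Hz, ocular-artifact attenuation
by least-squares regression on the EOG channel, a narrow 0.5-15 Hz band-pass,
stimulus-locked epoching (-0.1 to 1.5 s), baseline correction on the 100 ms
pre-stimulus interval, and rejection of trials without a valid button
response. All filters are Butterworth applied forward and backward
("two-way"), so the net phase response is zero. No stage mutates its input;
each returns a copy whose ``history`` records the stage parameters.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochSet, round_half_away

__all__ = [
    "bandpass_iir",
    "resample",
    "regress_eog",
    "epoch",
    "baseline_correct",
    "reject_no_response",
    "run_chain",
    "select_channels",
    "concatenate_epochs",
]


def _bandpass_sos(low_hz, high_hz, order, sfreq):
    nyq = sfreq / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}-{high_hz} Hz) must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         output="sos", fs=sfreq)


def _padlen(low_hz, sfreq, n_samples):
    # reflect-pad by >= 3x the slowest time constant of the band edge
    return int(min(n_samples - 1, round(3 * sfreq / low_hz)))


def bandpass_iir(recording, low_hz, high_hz, order=3):
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The effective magnitude response is the square of the designed one-pass
    filter; the phase response is identically zero.
    """
    sos = _bandpass_sos(low_hz, high_hz, order, recording.sfreq)
    padlen = _padlen(low_hz, recording.sfreq, recording.n_samples)
    out = signal.sosfiltfilt(sos, recording.data, axis=1, padtype="even",
                             padlen=padlen)
    return recording.copy_with(
        data=out,
        history_entry={"stage": "bandpass_iir", "low_hz": low_hz,
                       "high_hz": high_hz, "order": order, "two_way": True},
    )


def filter_epochs(epochs, low_hz, high_hz, order=3):
    """Zero-phase band-pass applied per epoch (used by the latency estimator)."""
    sos = _bandpass_sos(low_hz, high_hz, order, epochs.sfreq)
    padlen = _padlen(low_hz, epochs.sfreq, epochs.n_samples)
    out = signal.sosfiltfilt(sos, epochs.data, axis=2, padtype="even",
                             padlen=padlen)
    return epochs.copy_with(
        data=out,
        history_entry={"stage": "filter_epochs", "low_hz": low_hz,
                       "high_hz": high_hz, "order": order},
    )


def resample(recording, target_hz=256):
    """Polyphase resampling; event indices are remapped by the rate ratio.

    Remapping uses round-half-away-from-zero so an event at raw sample 1024 of
    a 512 Hz record lands exactly on sample 512 at 256 Hz.
    """
    if target_hz == recording.sfreq:
        return recording.copy_with(history_entry={"stage": "resample",
                                                  "target_hz": target_hz,
                                                  "identity": True})
    if target_hz > recording.sfreq:
        warnings.warn("upsampling requested; proceeding, but the default chain "
                      "expects downsampling", stacklevel=2)
    frac = Fraction(target_hz).limit_denominator(10**6) / \
        Fraction(recording.sfreq).limit_denominator(10**6)
    out = signal.resample_poly(recording.data, frac.numerator,
                               frac.denominator, axis=1)
    events = recording.events.copy()
    ratio = float(frac)
    events["sample"] = round_half_away(events["sample"].to_numpy() * ratio)
    events["sample"] = events["sample"].clip(0, out.shape[1] - 1)
    return recording.copy_with(
        data=out, sfreq=float(target_hz), events=events,
        history_entry={"stage": "resample", "target_hz": target_hz},
    )


def regress_eog(recording, eog_channel_names=("EOG",)):
    """Attenuate ocular artifacts by least-squares regression on EOG channels.

    Leakage coefficients are estimated over the whole recording by OLS of each
    EEG channel onto the (demeaned) EOG regressors and subtracted. The EOG
    channels themselves are retained unmodified.
    """
    eog_idx = [recording.channel_index(ch) for ch in eog_channel_names]
    eeg_idx = [i for i in range(len(recording.channel_names)) if i not in eog_idx]
    eog = recording.data[eog_idx]
    eog_dm = eog - eog.mean(axis=1, keepdims=True)
    if np.allclose(eog_dm, 0.0):
        warnings.warn("EOG channels carry no variance; regression skipped",
                      stacklevel=2)
        return recording.copy_with(history_entry={"stage": "regress_eog",
                                                  "skipped": "zero variance"})
    out = recording.data.copy()
    eeg = out[eeg_idx]
    eeg_dm = eeg - eeg.mean(axis=1, keepdims=True)
    # coefficients: solve (EOG EOG') B = EOG EEG'
    gram = eog_dm @ eog_dm.T
    coef = np.linalg.solve(gram, eog_dm @ eeg_dm.T)      # n_eog x n_eeg
    out[eeg_idx] = eeg - coef.T @ eog_dm
    return recording.copy_with(
        data=out,
        history_entry={"stage": "regress_eog",
                       "eog_channels": list(eog_channel_names),
                       "coefficients": coef.T.tolist()},
    )


def epoch(recording, lock_label="target", tmin=-0.1, tmax=1.5):
    """Cut fixed-length epochs around every event with ``lock_label``.

    Sample windows are half-open: an epoch spans ``round((tmax-tmin)*sfreq)``
    samples starting at ``event_sample + round(tmin*sfreq)``; t = 0 is the
    sample at/after the lock event. Epochs that would exceed the record bounds
    are dropped and logged.
    """
    sel = recording.events[recording.events["label"] == lock_label]
    if sel.empty:
        raise ValueError(f"no events labelled {lock_label!r} in recording")
    sfreq = recording.sfreq
    offset = int(round_half_away(tmin * sfreq))
    n_samp = int(round_half_away((tmax - tmin) * sfreq))
    cuts, kept, dropped = [], [], []
    for _, ev in sel.iterrows():
        start = int(ev["sample"]) + offset
        if start < 0 or start + n_samp > recording.n_samples:
            dropped.append((ev["trial_id"], "epoch exceeds record bounds"))
            continue
        cuts.append(recording.data[:, start:start + n_samp])
        kept.append(ev["trial_id"])
    drop_log = pd.DataFrame(dropped, columns=["trial_id", "reason"])
    data = np.stack(cuts) if cuts else np.empty((0, len(recording.channel_names), n_samp))
    meta = pd.DataFrame({"trial_id": kept})
    return EpochSet(
        data=data, t0=offset / sfreq, sfreq=sfreq, lock=lock_label,
        channel_names=tuple(recording.channel_names), metadata=meta,
        history=list(recording.history) + [{
            "stage": "epoch", "lock": lock_label, "tmin": tmin, "tmax": tmax,
            "n_kept": len(kept), "n_dropped": len(dropped)}],
        drop_log=drop_log,
    )


def attach_metadata(epochs, trials):
    """Join per-trial metadata (by trial_id) onto an EpochSet."""
    meta = epochs.metadata[["trial_id"]].merge(trials, on="trial_id", how="left")
    if len(meta) != epochs.n_epochs:
        raise ValueError("metadata join changed the row count; duplicate trial_id?")
    return epochs.copy_with(metadata=meta,
                            history_entry={"stage": "attach_metadata"})


def baseline_correct(epochs, window=(-0.1, 0.0)):
    """Subtract the per-trial, per-channel mean over ``window`` (half-open)."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("baseline window must have positive length")
    sfreq = epochs.sfreq
    i0 = int(round_half_away((lo - epochs.t0) * sfreq))
    i1 = int(round_half_away((hi - epochs.t0) * sfreq))
    if i0 < 0 or i1 > epochs.n_samples or i1 <= i0:
        raise ValueError("baseline window outside epoch span (or empty)")
    base = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return epochs.copy_with(
        data=epochs.data - base,
        history_entry={"stage": "baseline_correct", "window": list(window)},
    )


def reject_no_response(epochs):
    """Drop trials flagged ``missed`` (no or too-late button response)."""
    if "missed" not in epochs.metadata.columns:
        raise ValueError("metadata lacks a 'missed' flag; attach trial metadata first")
    keep = ~epochs.metadata["missed"].astype(bool).to_numpy()
    n_miss = int((~keep).sum())
    if n_miss == len(keep) and len(keep) > 0:
        warnings.warn("all trials missed; returning an empty EpochSet",
                      stacklevel=2)
    dropped = epochs.metadata.loc[~keep, ["trial_id"]].assign(reason="no response")
    drop_log = pd.concat([epochs.drop_log, dropped], ignore_index=True)
    return epochs.copy_with(
        data=epochs.data[keep],
        metadata=epochs.metadata.loc[keep].reset_index(drop=True),
        drop_log=drop_log,
        history_entry={"stage": "reject_no_response",
                       "n_in": len(keep), "n_rejected": n_miss},
    )


def select_channels(epochs, names):
    """Restrict an EpochSet to a channel subset (keeps metadata and history)."""
    idx = [epochs.channel_index(ch) for ch in names]
    return EpochSet(
        data=epochs.data[:, idx, :], t0=epochs.t0, sfreq=epochs.sfreq,
        lock=epochs.lock, channel_names=tuple(names),
        metadata=epochs.metadata.copy(),
        history=list(epochs.history) + [{"stage": "select_channels",
                                         "channels": list(names)}],
        drop_log=epochs.drop_log.copy(),
    )


def concatenate_epochs(epoch_sets):
    """Stack EpochSets (e.g. one per subject) sharing geometry and lock."""
    epoch_sets = list(epoch_sets)
    if not epoch_sets:
        raise ValueError("no EpochSets to concatenate")
    ref = epoch_sets[0]
    for e in epoch_sets[1:]:
        if (e.sfreq != ref.sfreq or e.t0 != ref.t0 or e.lock != ref.lock
                or tuple(e.channel_names) != tuple(ref.channel_names)
                or e.n_samples != ref.n_samples):
            raise ValueError("EpochSets differ in geometry, lock or montage")
    return EpochSet(
        data=np.concatenate([e.data for e in epoch_sets], axis=0),
        t0=ref.t0, sfreq=ref.sfreq, lock=ref.lock,
        channel_names=tuple(ref.channel_names),
        metadata=pd.concat([e.metadata for e in epoch_sets],
                           ignore_index=True),
        history=[{"stage": "concatenate_epochs", "n_sets": len(epoch_sets)}],
        drop_log=pd.concat([e.drop_log for e in epoch_sets],
                           ignore_index=True),
    )


def run_chain(recording, trials, *, wide_band=(0.1, 50.0), narrow_band=(0.5, 15.0),
              order=3, target_hz=256, eog_channels=("EOG",),
              lock_label="target", tmin=-0.1, tmax=1.5,
              baseline=(-0.1, 0.0)):
    """Run the full canonical chain and return a clean stimulus-locked EpochSet.

    Order: wide band-pass -> resample -> EOG regression -> narrow band-pass ->
    epoch -> metadata join -> baseline -> no-response rejection.
    """
    rec = bandpass_iir(recording, *wide_band, order=order)
    rec = resample(rec, target_hz)
    rec = regress_eog(rec, eog_channels)
    rec = bandpass_iir(rec, *narrow_band, order=order)
    ep = epoch(rec, lock_label, tmin, tmax)
    ep = attach_metadata(ep, trials)
    ep = baseline_correct(ep, baseline)
    return reject_no_response(ep)
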