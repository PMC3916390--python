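"""Single-trial P3 latency estimation by iterative template matching.

The estimator is a Woody-style iteration on one channel (Pz by default):

1. band-pass the epochs 0.5-6 Hz (zero-phase, 3rd-order Butterworth) to
   suppress alpha activity;
2. start from an initial latency estimate per trial (the reaction time in a
   speeded task);
3. cut the signal of every trial from -0.5 to +0.5 s around its current
   estimate (edge-truncated cuts contribute their overlapping part) and
   average the cuts into a "P3-locked" template;
4. slide the template over the 0.35-0.9 s post-stimulus search window and
   score every candidate center by the correlation of template and signal
   segment; locate local maxima of the score sequence by derivative sign
   change and take the largest positive one as the new latency;
5. repeat steps 3-4 (four times by default).

Trials whose score sequence has no positive local maximum keep their previous
estimate and are flagged; they still contribute to subsequent templates. For a
condition in which reaction times cannot seed the iteration (a delayed
response task), a template estimated elsewhere can be re-used as the
first-iteration template (:func:`reuse_template`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import round_half_away
from .preprocess import filter_epochs

__all__ = ["WoodyConfig", "LatencyTable", "estimate_latencies", "reuse_template"]


@dataclass(frozen=True)
class WoodyConfig:
    prefilter_band: tuple = (0.5, 6.0)      # None to skip pre-filtering
    prefilter_order: int = 3
    search_window: tuple = (0.35, 0.90)     # seconds post-stimulus
    template_halfwidth: float = 0.5         # seconds
    n_iterations: int = 4
    channel: str = "Pz"
    normalized: bool = True                 # Pearson score; False = raw dot product

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.search_window[0] >= self.search_window[1]:
            raise ValueError("search window must have positive length")


@dataclass
class LatencyTable:
    """Per-trial latency estimates plus the template that produced them."""

    table: pd.DataFrame                 # trial_id, latency_s, score, flagged
    template: np.ndarray
    template_times: np.ndarray          # seconds relative to template center
    sfreq: float
    iteration_mean_latency: list = field(default_factory=list)
    iteration_mean_abs_change: list = field(default_factory=list)
    config: WoodyConfig = None

    @property
    def latencies(self):
        return self.table["latency_s"].to_numpy()

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _build_template(x, est_idx, half):
    """Average +/-half-sample cuts around per-trial estimates (edge-truncated)."""
    n = x.shape[1]
    length = 2 * half + 1
    acc = np.zeros(length)
    cnt = np.zeros(length)
    for i, e in enumerate(est_idx):
        lo = max(0, e - half)
        hi = min(n, e + half + 1)
        if hi <= lo:
            continue
        a = lo - (e - half)
        acc[a:a + hi - lo] += x[i, lo:hi]
        cnt[a:a + hi - lo] += 1
    template = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return template


def _full_support_scores(x, template, centers, half, normalized):
    """Scores at candidate centers whose full +/-half support fits the epoch."""
    n_trials, n = x.shape
    L = 2 * half + 1
    tvec = (template - template.mean()) if normalized else template
    starts = centers - half
    dots = np.empty((n_trials, len(centers)))
    win = np.lib.stride_tricks.sliding_window_view(x, L, axis=1)
    chunk = max(1, int(2e7 // (len(centers) * L)))
    for i0 in range(0, n_trials, chunk):
        dots[i0:i0 + chunk] = win[i0:i0 + chunk, starts, :] @ tvec
    if not normalized:
        return dots
    # sliding sums for the mean/variance of each window
    csum = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(x, axis=1)], axis=1)
    csq = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(x ** 2, axis=1)], axis=1)
    wsum = csum[:, starts + L] - csum[:, starts]
    wsq = csq[:, starts + L] - csq[:, starts]
    st = np.sqrt((tvec ** 2).sum())
    sx = np.sqrt(np.maximum(wsq - wsum ** 2 / L, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = dots / (sx * st)
    return np.where((sx > 0) & (st > 0), r, 0.0)


def _truncated_scores(x, template, centers, half, normalized):
    """Scores at edge candidates, correlating over the overlapping support only."""
    n_trials, n = x.shape
    L = 2 * half + 1
    out = np.zeros((n_trials, len(centers)))
    for j, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        a = lo - (c - half)
        seg = x[:, lo:hi]
        tseg = template[a:a + hi - lo]
        if normalized:
            tc = tseg - tseg.mean()
            st = np.sqrt((tc ** 2).sum())
            sc = seg - seg.mean(axis=1, keepdims=True)
            sx = np.sqrt((sc ** 2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (sc @ tc) / (sx * st)
            out[:, j] = np.where((sx > 0) & (st > 0), r, 0.0)
        else:
            # renormalise the dot product by the overlap fraction
            out[:, j] = (seg @ tseg) * (L / max(len(tseg), 1))
    return out


def _score_matrix(x, template, c0, c1, half, normalized):
    n = x.shape[1]
    centers = np.arange(c0, c1 + 1)
    full = (centers - half >= 0) & (centers + half + 1 <= n)
    scores = np.empty((x.shape[0], len(centers)))
    if full.any():
        scores[:, full] = _full_support_scores(x, template, centers[full],
                                               half, normalized)
    if (~full).any():
        scores[:, ~full] = _truncated_scores(x, template, centers[~full],
                                             half, normalized)
    return scores, centers


def pick_largest_positive_peak(scores):
    """Per row: the largest positive local maximum (derivative sign change).

    Returns ``(positions, values, found)``; positions are column indices into
    ``scores``, ties broken toward the earliest position. Rows with no positive
    local maximum get ``found=False``.
    """
    scores = np.atleast_2d(scores)
    n_trials, n_pts = scores.shape
    d = np.diff(scores, axis=1)
    rising = d[:, :-1] > 0
    falling = d[:, 1:] <= 0
    is_peak = np.zeros_like(scores, dtype=bool)
    is_peak[:, 1:-1] = rising & falling
    is_peak &= scores > 0
    masked = np.where(is_peak, scores, -np.inf)
    pos = np.argmax(masked, axis=1)       # first occurrence wins ties
    vals = masked[np.arange(n_trials), pos]
    found = np.isfinite(vals)
    return pos, vals, found


def _match_pass(x, template, c0, c1, half, prev_idx, normalized):
    scores, centers = _score_matrix(x, template, c0, c1, half, normalized)
    pos, vals, found = pick_largest_positive_peak(scores)
    new_idx = np.where(found, centers[pos], prev_idx)
    score_out = np.where(found, vals, np.nan)
    return new_idx.astype(int), score_out, ~found


def _prepare(epochs, config):
    if config.prefilter_band is not None:
        epochs = filter_epochs(epochs, *config.prefilter_band,
                               order=config.prefilter_order)
    ci = epochs.channel_index(config.channel)
    x = np.ascontiguousarray(epochs.data[:, ci, :])
    sfreq = epochs.sfreq
    half = int(round_half_away(config.template_halfwidth * sfreq))
    c0 = int(round_half_away((config.search_window[0] - epochs.t0) * sfreq))
    c1 = int(round_half_away((config.search_window[1] - epochs.t0) * sfreq))
    c0 = max(c0, 0)
    c1 = min(c1, x.shape[1] - 1)
    if c1 <= c0:
        raise ValueError("search window empty after clipping to the epoch span")
    return epochs, x, sfreq, half, c0, c1


def _finish(epochs, x, est_idx, scores, flagged, template, half, sfreq,
            mean_hist, change_hist, config):
    latencies = epochs.t0 + est_idx / sfreq
    table = pd.DataFrame({
        "trial_id": epochs.metadata["trial_id"].to_numpy(),
        "latency_s": latencies,
        "score": scores,
        "flagged": flagged,
    })
    return LatencyTable(
        table=table, template=template,
        template_times=np.arange(-half, half + 1) / sfreq, sfreq=sfreq,
        iteration_mean_latency=mean_hist,
        iteration_mean_abs_change=change_hist, config=config,
    )


def estimate_latencies(epochs, init_latencies, config=WoodyConfig()):
    """Iterative Woody estimation seeded by per-trial initial latencies.

    ``init_latencies`` are seconds from the lock event (reaction times for a
    speeded task), one per epoch. Returns a :class:`LatencyTable` whose
    latencies are expressed on the same axis.
    """
    init = np.asarray(init_latencies, dtype=float)
    if init.shape != (epochs.n_epochs,):
        raise ValueError("need exactly one initial latency per epoch")
    epochs, x, sfreq, half, c0, c1 = _prepare(epochs, config)
    est_idx = round_half_away((init - epochs.t0) * sfreq).astype(int)
    scores = np.full(epochs.n_epochs, np.nan)
    flagged = np.zeros(epochs.n_epochs, dtype=bool)
    mean_hist, change_hist = [], []
    template = None
    for _ in range(config.n_iterations):
        template = _build_template(x, est_idx, half)
        prev = est_idx
        est_idx, scores, flagged = _match_pass(
            x, template, c0, c1, half, est_idx, config.normalized)
        if flagged.all():
            warnings.warn("no positive score peak for any trial this iteration",
                          stacklevel=2)
        mean_hist.append(float(np.mean(epochs.t0 + est_idx / sfreq)))
        change_hist.append(float(np.mean(np.abs(est_idx - prev)) / sfreq))
    return _finish(epochs, x, est_idx, scores, flagged, template, half, sfreq,
                   mean_hist, change_hist, config)


def reuse_template(template, epochs, config=WoodyConfig(), template_sfreq=None):
    """Match with a fixed externally estimated template, then refine.

    The given template (sampled at the epochs' rate) drives the first matching
    pass; the remaining ``n_iterations - 1`` loops rebuild the template from
    the current estimates as usual. Trials with no positive score peak in the
    first pass fall back to the search-window midpoint and are flagged.
    """
    if template_sfreq is not None and template_sfreq != epochs.sfreq:
        raise ValueError(
            f"template rate ({template_sfreq} Hz) does not match epochs "
            f"({epochs.sfreq} Hz)")
    template = np.asarray(template, dtype=float)
    epochs, x, sfreq, half, c0, c1 = _prepare(epochs, config)
    expected = 2 * half + 1
    if len(template) != expected:
        raise ValueError(
            f"template length {len(template)} does not match the configured "
            f"halfwidth ({expected} samples at {sfreq} Hz)")
    mid = (c0 + c1) // 2
    est_idx, scores, flagged = _match_pass(
        x, template, c0, c1, half, np.full(x.shape[0], mid), config.normalized)
    mean_hist = [float(np.mean(epochs.t0 + est_idx / sfreq))]
    change_hist = []
    final_template = template
    for _ in range(config.n_iterations - 1):
        final_template = _build_template(x, est_idx, half)
        prev = est_idx
        est_idx, scores, flagged = _match_pass(
            x, final_template, c0, c1, half, est_idx, config.normalized)
        mean_hist.append(float(np.mean(epochs.t0 + est_idx / sfreq)))
        change_hist.append(float(np.mean(np.abs(est_idx - prev)) / sfreq))
    return _finish(epochs, x, est_idx, scores, flagged, final_template, half,
                   sfreq, mean_hist, change_hist, config)
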