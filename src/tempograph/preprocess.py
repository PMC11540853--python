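"""Spike-train preprocessing: binning, moving-sum smoothing, baseline
correction and z-scoring around stimulus onsets.

The canonical pipeline is bin -> smooth -> baseline-correct (-> z-score);
each step records itself in the tensor's provenance so downstream analyses
can assert the order they require.  Windows are expressed in seconds
relative to stimulus onset; bins are half-open ``[t, t + bin_width)``.

Named presets bundle the window/smoothing combinations used by the
different analyses:

``selection``  0.1–1.2 s response window, ±0.25 s moving sum (neuron
               classification).
``decoding``   0.1–1.0 s window, ±0.25 s moving sum, summed counts
               (population decoder).
``distance``   0.1–1.0 s window, ±0.15 s moving sum (neural distance
               matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BinnedResponses",
    "bin_spikes",
    "smooth_moving_sum",
    "baseline_correct",
    "zscore_neuron",
    "response_window_mean",
    "PRESETS",
]

PRESETS = {
    "selection": {"window": (0.1, 1.2), "smooth_halfwidth": 0.25, "mode": "mean"},
    "decoding": {"window": (0.1, 1.0), "smooth_halfwidth": 0.25, "mode": "sum"},
    "distance": {"window": (0.1, 1.0), "smooth_halfwidth": 0.15, "mode": "mean"},
}


@dataclass
class BinnedResponses:
    """neuron x trial x bin response tensor with processing provenance."""

    counts: np.ndarray
    bin_width: float
    window: tuple
    neuron_ids: np.ndarray
    events: pd.DataFrame  # one row per trial, aligned with axis 1
    provenance: tuple = ()
    silent_neurons: tuple = ()

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(self.n_bins)

    def bin_slice(self, window) -> slice:
        """Indices of bins whose start lies in [window[0], window[1])."""
        lo, hi = window
        if lo < self.window[0] - 1e-9 or hi > self.window[1] + 1e-9:
            raise ValueError(f"window {window} outside tensor range {self.window}")
        starts = self.bin_starts
        sel = np.flatnonzero((starts >= lo - 1e-9) & (starts < hi - 1e-9))
        if sel.size == 0:
            raise ValueError(f"window {window} selects no bins")
        return slice(sel[0], sel[-1] + 1)

    def select_trials(self, mask) -> "BinnedResponses":
        return replace(
            self,
            counts=self.counts[:, mask, :],
            events=self.events.loc[mask].reset_index(drop=True),
        )


def bin_spikes(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple = (-1.0, 2.0),
    bin_width: float = 0.1,
) -> BinnedResponses:
    """Count spikes of every neuron in half-open bins around each onset."""
    onsets = events["onset"].to_numpy()
    if not np.all(np.diff(onsets) >= 0):
        raise ValueError("event onsets must be sorted")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    neuron_ids = np.unique(spikes["neuron"])
    counts = np.zeros((neuron_ids.size, onsets.size, n_bins), dtype=float)
    grouped = spikes.groupby("neuron")["time"]
    for i, nid in enumerate(neuron_ids):
        t = np.sort(grouped.get_group(nid).to_numpy())
        # searchsorted('left') at every trial x edge implements [t, t+w) bins
        pos = np.searchsorted(t, onsets[:, None] + edges[None, :], side="left")
        counts[i] = np.diff(pos, axis=1)
    return BinnedResponses(
        counts,
        bin_width,
        tuple(window),
        neuron_ids,
        events.reset_index(drop=True),
        provenance=("binned",),
    )


def smooth_moving_sum(b: BinnedResponses, halfwidth: float = 0.25) -> BinnedResponses:
    """Replace each bin by the sum over bins within +-halfwidth.

    Edge windows are truncated to the available bins (no padding).
    """
    k = int(round(halfwidth / b.bin_width))
    if k < 1:
        import warnings

        warnings.warn("halfwidth smaller than one bin; smoothing is a no-op")
        return replace(b, provenance=b.provenance + (f"smoothed(+-{halfwidth})",))
    from scipy.ndimage import convolve1d

    kernel = np.ones(2 * k + 1)
    # constant zero padding == truncated window: absent bins contribute 0
    out = convolve1d(b.counts, kernel, axis=2, mode="constant", cval=0.0)
    return replace(
        b, counts=out, provenance=b.provenance + (f"smoothed(+-{halfwidth})",)
    )


def baseline_correct(
    b: BinnedResponses, baseline: tuple = (-0.5, 0.0)
) -> BinnedResponses:
    """Subtract each neuron-trial's mean activity over the baseline bins."""
    sl = b.bin_slice(baseline)
    base = b.counts[:, :, sl].mean(axis=2, keepdims=True)
    return replace(
        b,
        counts=b.counts - base,
        provenance=b.provenance + (f"baseline_corrected({baseline})",),
    )


def zscore_neuron(b: BinnedResponses) -> BinnedResponses:
    """Z-score each neuron over all bins of all trials of the session.

    Neurons with zero variance are flagged silent (listed in
    ``silent_neurons``) and their values set to zero; downstream analyses
    exclude them.
    """
    flat = b.counts.reshape(b.counts.shape[0], -1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1)
    silent = sd == 0
    sd_safe = np.where(silent, 1.0, sd)
    out = (b.counts - mu[:, None, None]) / sd_safe[:, None, None]
    out[silent] = 0.0
    return replace(
        b,
        counts=out,
        provenance=b.provenance + ("zscored(session)",),
        silent_neurons=tuple(b.neuron_ids[silent]),
    )


def response_window_mean(
    b: BinnedResponses, window: tuple = (0.1, 1.2), mode: str = "mean"
) -> np.ndarray:
    """Mean (or sum) over the window's bins -> neuron x trial matrix."""
    sl = b.bin_slice(window)
    block = b.counts[:, :, sl]
    if mode == "mean":
        return block.mean(axis=2)
    if mode == "sum":
        return block.sum(axis=2)
    raise ValueError(f"unknown mode {mode!r}")


def preprocess(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    preset: str = "selection",
    window: tuple = (-1.0, 2.0),
    bin_width: float = 0.1,
    baseline: tuple = (-0.5, 0.0),
    zscore: bool = False,
) -> BinnedResponses:
    """Run the canonical pipeline (bin -> smooth -> baseline [-> z])."""
    p = PRESETS[preset]
    b = bin_spikes(spikes, events, window, bin_width)
    b = smooth_moving_sum(b, p["smooth_halfwidth"])
    b = baseline_correct(b, baseline)
    if zscore:
        b = zscore_neuron(b)
    return b
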