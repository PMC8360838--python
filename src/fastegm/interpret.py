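"""Grad-CAM importance traces over the electrogram timeline.

For a probed residual block, channel weights are the time-averaged
gradients of the classifier logit with respect to that block's activation
maps; the importance trace is the rectified, channel-weighted sum of the
maps, linearly interpolated to the input length and max-normalized.  Peaks
of the trace indicate input regions that drove the FaST call — on true
focal-source recordings they should coincide with atrial QS complexes and
ignore far-field ventricular complexes.

By default the trace is additionally multiplied by a rectified
guided-backpropagation saliency over the input (guided Grad-CAM), which
restores sample-level sharpness that the strided layer map alone lacks;
``guided=False`` yields the plain layer-level map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .nn.layers import ReLU
from .nn.resnet import ResNet1d

__all__ = ["ImportanceTrace", "gradcam_trace", "peak_alignment",
           "DEFAULT_LAYER"]

#: First block of the third stage — "convolutional layer 3.0".
DEFAULT_LAYER = "stage3.block0"


@dataclass
class ImportanceTrace:
    values: np.ndarray      # length == classifier input length, in [0, 1]
    layer_id: str
    record_id: str = ""


def _input_gradient(model: ResNet1d, x: np.ndarray, guided: bool) -> np.ndarray:
    """d(logit)/d(input), optionally with guided-backprop ReLU gating."""
    relus = [m for blk in model.blocks.values()
             for m in vars(blk).values() if isinstance(m, ReLU)]
    originals = [m.backward for m in relus]
    if guided:
        def make_guided(m):
            def backward(grad, _m=m):
                return np.where((_m._mask) & (grad > 0), grad, 0.0)
            return backward
        for m in relus:
            m.backward = make_guided(m)
    try:
        model.forward(x, train=False)
        grad_in = model.backward(np.ones(x.shape[0]))
    finally:
        for m, orig in zip(relus, originals):
            m.backward = orig
    return grad_in[:, 0, :]


def gradcam_trace(model: ResNet1d, signal: np.ndarray,
                  layer_id: str = DEFAULT_LAYER, record_id: str = "",
                  guided: bool = True) -> ImportanceTrace:
    """Compute the 1-D Grad-CAM importance trace for one preprocessed trace.

    Parameters
    ----------
    model : ResNet1d
        A (trained) network.
    signal : ndarray
        One scaled trace of ``model.input_length`` samples.
    layer_id : str
        Name of the probed residual block, e.g. ``"stage3.block0"``.
    guided : bool
        Multiply by rectified guided-backpropagation input saliency
        (default).  The plain layer-level map localizes only as finely as
        the probed layer's stride; the guided product restores sample-level
        sharpness, which is what makes the peaks track individual QS
        complexes reliably.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    x = x[None, :]
    model.forward(x, train=False, probe=layer_id)
    model.backward(np.ones(1))
    acts = model.probe_activation[0]     # (C, Lp)
    grads = model.probe_gradient[0]      # (C, Lp)
    weights = grads.mean(axis=1)         # time-averaged gradient per channel
    cam = np.maximum((weights[:, None] * acts).sum(axis=0), 0.0)
    n = model.input_length
    pos = np.linspace(0, len(cam) - 1, n) if len(cam) > 1 else np.zeros(n)
    trace = np.interp(pos, np.arange(len(cam)), cam)
    if guided:
        sal = np.maximum(_input_gradient(model, x, guided=True)[0], 0.0)
        trace = trace * sal
    peak = trace.max()
    if peak > 0:
        trace = trace / peak
    return ImportanceTrace(values=trace, layer_id=layer_id, record_id=record_id)


def peak_alignment(trace: ImportanceTrace, truth_onsets: np.ndarray,
                   window: float, sampling_rate: float = 200.0,
                   peak_height: float = 0.5,
                   peak_separation_ms: float = 50.0) -> dict:
    """Quantify how well importance peaks align with true complex onsets.

    Peaks are local maxima of the normalized trace above ``peak_height``
    separated by at least ``peak_separation_ms``.  Returns the fraction of
    peaks within ``window`` ms of an onset (``hit_fraction``; NaN when there
    are no peaks), the symmetric onset recall, and the median peak-to-onset
    distance in ms.
    """
    values = np.asarray(trace.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty importance trace")
    onsets = np.asarray(truth_onsets, dtype=float)
    distance = max(int(round(peak_separation_ms * sampling_rate / 1000.0)), 1)
    peaks, _ = sps.find_peaks(values, height=peak_height, distance=distance)
    peak_times = peaks * 1000.0 / sampling_rate
    if len(peak_times) == 0:
        return {"n_peaks": 0, "hit_fraction": float("nan"),
                "onset_recall": 0.0 if len(onsets) else float("nan"),
                "median_distance_ms": float("nan")}
    if len(onsets) == 0:
        return {"n_peaks": int(len(peak_times)), "hit_fraction": 0.0,
                "onset_recall": float("nan"),
                "median_distance_ms": float("nan")}
    d_peak = np.min(np.abs(peak_times[:, None] - onsets[None, :]), axis=1)
    d_onset = np.min(np.abs(onsets[:, None] - peak_times[None, :]), axis=1)
    return {
        "n_peaks": int(len(peak_times)),
        "hit_fraction": float(np.mean(d_peak <= window)),
        "onset_recall": float(np.mean(d_onset <= window)),
        "median_distance_ms": float(np.median(d_peak)),
    }


def importance_at(trace: ImportanceTrace, times_ms: np.ndarray,
                  half_window_ms: float = 25.0,
                  sampling_rate: float = 200.0) -> float:
    """Mean of the trace's maxima in windows around the given times."""
    values = np.asarray(trace.values, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if times.size == 0:
        return float("nan")
    w = int(round(half_window_ms * sampling_rate / 1000.0))
    vals = []
    for t in times:
        c = int(round(t * sampling_rate / 1000.0))
        lo, hi = max(c - w, 0), min(c + w + 1, len(values))
        if hi > lo:
            vals.append(values[lo:hi].max())
    return float(np.mean(vals)) if vals else float("nan")
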