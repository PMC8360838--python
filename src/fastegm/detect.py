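"""Rule-based hierarchical FaST (focal source and trigger) detection.

A recording site is called FaST when its bipolar electrogram shows sustained
spectral periodicity at an atrial cycle length (100-250 ms) and the unipolar
electrogram shows a dominant QS pattern (R/S ratio < 0.1) in more than 90%
of the annotated complexes over the 5-s recording.

The pipeline has four stages:

1. ``preprocess_bipolar`` — Botteron-style envelope: zero-phase 40-250 Hz
   bandpass, rectification, zero-phase 0.5-20 Hz bandpass.
2. ``spectral_periodicity`` — FFT of the envelope; periodicity is present
   when the dominant spectral peak inside the 4-10 Hz atrial window carries
   at least 10% of the total spectral power, and the periodicity cycle
   length is the inverse of that frequency.
3. ``detect_candidates`` + ``select_periodic_train`` — candidate local
   activations (amplitude > 0.05 mV, slew rate > 0.014 mV/ms) chained by a
   dynamic-programming graph search into the longest train of consecutive
   activations at the extracted cycle length, ties broken by the smallest
   total deviation from that cycle length.
4. ``classify_morphology`` — candidate times transposed onto the unipolar
   trace; each complex is QS when its R/S amplitude ratio is below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import EgmRecord

__all__ = [
    "FaSTParams",
    "PeriodicityResult",
    "ActivationTrain",
    "MorphologyCall",
    "FaSTDecision",
    "preprocess_bipolar",
    "spectral_periodicity",
    "detect_candidates",
    "select_periodic_train",
    "classify_morphology",
    "classify_fast",
]


@dataclass
class FaSTParams:
    """Thresholds and windows of the rule-based algorithm (units in names)."""

    band1: tuple[float, float] = (40.0, 250.0)   # Hz, bipolar bandpass
    band2: tuple[float, float] = (0.5, 20.0)     # Hz, envelope bandpass
    power_fraction_threshold: float = 0.10
    cl_min: float = 100.0                        # ms
    cl_max: float = 250.0                        # ms
    noise_threshold: float = 0.05                # mV
    slew_threshold: float = 0.014                # mV/ms
    rs_ratio_threshold: float = 0.1
    qs_fraction_threshold: float = 0.9
    chain_tolerance_fraction: float = 0.25       # of the periodicity CL
    min_refractory: float = 50.0                 # ms
    morphology_window: tuple[float, float] = (-20.0, 80.0)  # ms around onset
    baseline_window: float = 10.0                # ms before the window
    slew_window: float = 10.0                    # ms around the candidate
    sustained_coverage_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.cl_min < self.cl_max):
            raise ValueError("need 0 < cl_min < cl_max")
        if not (0.0 < self.qs_fraction_threshold < 1.0):
            raise ValueError("qs_fraction_threshold must lie in (0, 1)")
        for name in ("power_fraction_threshold", "noise_threshold",
                     "slew_threshold", "rs_ratio_threshold",
                     "chain_tolerance_fraction", "min_refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PeriodicityResult:
    is_periodic: bool
    peak_frequency: float        # Hz
    periodicity_cl: float        # ms, 1000 / peak_frequency
    peak_power_fraction: float   # in [0, 1]


@dataclass
class ActivationTrain:
    candidates: np.ndarray       # ms
    chain: np.ndarray            # ms, subset of candidates
    chain_length: int
    total_cost: float            # ms, sum |interval - periodicity_cl|


@dataclass
class MorphologyCall:
    onset: float                 # ms
    r_amplitude: float           # mV >= 0
    s_amplitude: float           # mV >= 0
    rs_ratio: float
    is_qs: bool
    indeterminate: bool = False  # S wave below the noise threshold


@dataclass
class FaSTDecision:
    is_fast: bool
    periodicity: PeriodicityResult
    qs_fraction: float
    calls: list[MorphologyCall] = field(default_factory=list)
    sustained: bool = False
    train: ActivationTrain | None = None


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (applied forward and backward)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess_bipolar(bipolar: np.ndarray, sampling_rate: float,
                       params: FaSTParams | None = None) -> np.ndarray:
    """Rectified-envelope preprocessing of the bipolar trace.

    Band1 bandpass, full-wave rectification, band2 bandpass; all filtering
    is zero-phase so activation timing is preserved.  Output has the same
    length as the input.
    """
    params = params or FaSTParams()
    x = np.asarray(bipolar, dtype=float)
    if sampling_rate <= 2.0 * params.band1[1]:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low for the "
            f"{params.band1} Hz bandpass")
    if len(x) < 2 * sampling_rate:
        raise ValueError("need at least 2 s of signal")
    y = _bandpass(x, params.band1, sampling_rate)
    y = np.abs(y)
    return _bandpass(y, params.band2, sampling_rate)


def spectral_periodicity(envelope: np.ndarray, sampling_rate: float,
                         params: FaSTParams | None = None) -> PeriodicityResult:
    """Dominant-frequency periodicity test on the rectified envelope.

    The dominant peak is searched over the whole band2 passband; its power
    (the FFT bin plus one adjacent bin on each side) must carry at least
    ``power_fraction_threshold`` of the total band2 power, and the
    corresponding cycle length must lie in [cl_min, cl_max].  A recording
    whose dominant frequency falls outside the physiologic atrial window —
    e.g. a 2 Hz train — is therefore not periodic even if it has harmonics
    inside the window.
    """
    params = params or FaSTParams()
    x = np.asarray(envelope, dtype=float)
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    band = (freqs >= params.band2[0]) & (freqs <= params.band2[1])
    total = spec[band].sum()
    if total <= 0.0:
        return PeriodicityResult(False, 0.0, 0.0, 0.0)
    idx = np.flatnonzero(band)
    peak = idx[np.argmax(spec[idx])]
    lo, hi = max(peak - 1, 0), min(peak + 1, len(spec) - 1)
    fraction = float(spec[lo:hi + 1].sum() / total)
    peak_freq = float(freqs[peak])
    cl = 1000.0 / peak_freq
    ok = fraction >= params.power_fraction_threshold and params.cl_min <= cl <= params.cl_max
    return PeriodicityResult(bool(ok), peak_freq, cl, fraction)


def detect_candidates(bipolar: np.ndarray, sampling_rate: float,
                      params: FaSTParams | None = None) -> np.ndarray:
    """Candidate local activation times (ms) on the bipolar trace.

    Candidates are local maxima of the absolute bipolar signal (already
    hardware-bandpassed at acquisition), separated by at least the
    refractory period, whose amplitude exceeds the noise threshold and
    whose peak slew rate within the surrounding window exceeds the slew
    threshold.  Both thresholds act on the recorded amplitudes, so a
    0.049 mV deflection is rejected and a 0.051 mV one is kept.
    """
    params = params or FaSTParams()
    x = np.asarray(bipolar, dtype=float)
    absx = np.abs(x)
    distance = max(int(round(params.min_refractory * sampling_rate / 1000.0)), 1)
    peaks, _ = sps.find_peaks(absx, height=params.noise_threshold,
                              distance=distance)
    if len(peaks) == 0:
        return np.empty(0)
    slew = np.abs(np.diff(x)) * sampling_rate / 1000.0  # mV/ms per sample step
    w = int(round(params.slew_window * sampling_rate / 1000.0))
    keep = []
    for p in peaks:
        lo, hi = max(p - w, 0), min(p + w, len(slew))
        if hi > lo and slew[lo:hi].max() > params.slew_threshold:
            keep.append(p)
    return np.asarray(keep, dtype=float) * 1000.0 / sampling_rate


def select_periodic_train(candidates: np.ndarray, periodicity_cl: float,
                          params: FaSTParams | None = None) -> ActivationTrain:
    """Longest chain of consecutive candidates at the extracted cycle length.

    Graph search by dynamic programming: an edge joins two candidates whose
    interval deviates from ``periodicity_cl`` by strictly less than the
    chain tolerance (a fraction of the cycle length).  Among
    all chains the longest wins; ties are broken by the smallest total cost
    (sum of |interval - periodicity_cl|), then by the earliest start time.
    Equals exhaustive enumeration over increasing subsequences.
    """
    params = params or FaSTParams()
    cand = np.asarray(sorted(candidates), dtype=float)
    m = len(cand)
    if m == 0:
        return ActivationTrain(cand, np.empty(0), 0, 0.0)
    tol = params.chain_tolerance_fraction * periodicity_cl
    # best[j] = (length, cost, start_time, predecessor) of the best chain ending at j
    length = np.ones(m, dtype=int)
    cost = np.zeros(m)
    start = cand.copy()
    pred = np.full(m, -1, dtype=int)
    for j in range(m):
        for i in range(j):
            dt = cand[j] - cand[i]
            if abs(dt - periodicity_cl) < tol:
                cand_len = length[i] + 1
                cand_cost = cost[i] + abs(dt - periodicity_cl)
                key = (-cand_len, cand_cost, start[i])
                cur = (-length[j], cost[j], start[j])
                if key < cur:
                    length[j] = cand_len
                    cost[j] = cand_cost
                    start[j] = start[i]
                    pred[j] = i
    best = min(range(m), key=lambda j: (-length[j], cost[j], start[j], cand[j]))
    chain = []
    j = best
    while j >= 0:
        chain.append(cand[j])
        j = pred[j]
    chain = np.asarray(chain[::-1])
    return ActivationTrain(cand, chain, int(length[best]), float(cost[best]))


def classify_morphology(unipolar: np.ndarray, sampling_rate: float,
                        onsets: np.ndarray,
                        params: FaSTParams | None = None) -> list[MorphologyCall]:
    """Classify each annotated unipolar complex as QS or non-QS.

    For each onset the baseline is the median of the 10 ms preceding the
    morphology window; R is the maximum positive deviation from baseline
    within the window, S the maximum negative deviation magnitude.  A
    complex is QS when S is present and R/S < the ratio threshold.
    Complexes whose S wave is below the noise threshold are flagged
    indeterminate and excluded from QS-fraction counts downstream.
    """
    params = params or FaSTParams()
    x = np.asarray(unipolar, dtype=float)
    n = len(x)
    calls: list[MorphologyCall] = []
    w_lo, w_hi = params.morphology_window
    for onset in np.asarray(onsets, dtype=float):
        i_lo = int(round((onset + w_lo) * sampling_rate / 1000.0))
        i_hi = int(round((onset + w_hi) * sampling_rate / 1000.0))
        i_lo_c, i_hi_c = max(i_lo, 0), min(i_hi, n)
        if i_hi_c <= i_lo_c:
            continue
        b_lo = max(i_lo - int(round(params.baseline_window * sampling_rate / 1000.0)), 0)
        baseline = float(np.median(x[b_lo:i_lo_c])) if i_lo_c > b_lo else 0.0
        seg = x[i_lo_c:i_hi_c] - baseline
        r = float(max(seg.max(), 0.0))
        s = float(max(-seg.min(), 0.0))
        indeterminate = s < params.noise_threshold
        ratio = r / s if s > 0 else np.inf
        is_qs = bool(s > 0 and ratio < params.rs_ratio_threshold)
        calls.append(MorphologyCall(onset=float(onset), r_amplitude=r,
                                    s_amplitude=s, rs_ratio=ratio,
                                    is_qs=is_qs, indeterminate=indeterminate))
    return calls


def classify_fast(record: EgmRecord,
                  params: FaSTParams | None = None) -> FaSTDecision:
    """Full hierarchical FaST decision for one record.

    Non-periodic records short-circuit to a negative call.  Otherwise the
    periodic activation train is selected, the call is *sustained* when the
    chain covers at least ``sustained_coverage_fraction`` of the beats
    expected over the recording at the extracted cycle length, and FaST
    requires sustained periodicity plus a QS fraction above the threshold
    among determinate complexes of the chain.
    """
    params = params or FaSTParams()
    if record.duration < 2.0:
        raise ValueError("record must be at least 2 s long")
    env = preprocess_bipolar(record.bipolar, record.sampling_rate, params)
    periodicity = spectral_periodicity(env, record.sampling_rate, params)
    if not periodicity.is_periodic:
        return FaSTDecision(False, periodicity, 0.0, [], False, None)
    candidates = detect_candidates(record.bipolar, record.sampling_rate, params)
    train = select_periodic_train(candidates, periodicity.periodicity_cl, params)
    expected_beats = record.duration * 1000.0 / periodicity.periodicity_cl
    sustained = train.chain_length >= params.sustained_coverage_fraction * expected_beats
    calls = classify_morphology(record.unipolar, record.sampling_rate,
                                train.chain, params)
    determinate = [c for c in calls if not c.indeterminate]
    qs_fraction = (sum(c.is_qs for c in determinate) / len(determinate)
                   if determinate else 0.0)
    is_fast = bool(sustained and qs_fraction > params.qs_fraction_threshold)
    return FaSTDecision(is_fast, periodicity, float(qs_fraction), calls,
                        bool(sustained), train)
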