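"""Synthetic 5-s atrial-fibrillation electrogram generator with ground truth.

Generates paired unipolar/bipolar records spanning the morphology classes a
focal-source (FaST) detector must discriminate: sustained periodic unipolar
QS trains (the FaST-positive phenotype, including low-amplitude and
broad/slurred variants), periodic RS and small-r rS trains, recordings that
switch morphology mid-trace, non-sustained QS trains, fractionated
electrograms, and aperiodic activity.  Far-field ventricular complexes —
broad, low-amplitude, at ventricular rates — can be superimposed on the
unipolar channel.

The unipolar channel is the sum of morphology templates placed at activation
times plus baseline wander and amplifier noise.  The bipolar channel carries
a sharp biphasic deflection at each activation time (a scaled derivative-of-
Gaussian kernel), generated independently of the unipolar trace so that
detector thresholds can be exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import EgmRecord, GroundTruth

__all__ = [
    "SynthConfig",
    "FAST_CLASSES",
    "ALL_CLASSES",
    "default_class_mix",
    "make_complex_template",
    "synth_record",
    "synth_cohort",
]

#: Classes whose records are FaST-positive: dominant sustained periodic QS.
FAST_CLASSES = ("FAST_QS", "LOW_AMP_QS", "SLURRED_QS")

ALL_CLASSES = (
    "FAST_QS",
    "LOW_AMP_QS",
    "SLURRED_QS",
    "PERIODIC_RS",
    "SMALL_R_RS",
    "SWITCHING",
    "NONSUSTAINED_QS",
    "FRACTIONATED",
    "APERIODIC",
)

#: QS fraction above which a periodic, sustained train is called FaST.
QS_FRACTION_THRESHOLD = 0.9


@dataclass
class SynthConfig:
    """Generation parameters.  Defaults are the study conditions.

    Amplitude and width defaults are stated modelling choices (the
    morphologies are described qualitatively in the clinical literature,
    without canonical amplitudes):
    typical atrial unipolar complexes 0.5-1.5 mV and 30-50 ms wide,
    low-amplitude pulmonary-vein-ostial QS 0.15-0.35 mV, slurred QS 60-90 ms
    wide, amplifier noise 5 uV RMS, baseline wander 0.05 mV at 0.4 Hz.
    """

    duration: float = 5.0              # s
    sampling_rate: float = 1000.0      # Hz
    cl_range: tuple[float, float] = (100.0, 250.0)   # ms, atrial cycle length
    qs_amplitude_range: tuple[float, float] = (0.5, 1.5)     # mV (S wave)
    low_amp_range: tuple[float, float] = (0.15, 0.35)        # mV
    qs_width_range: tuple[float, float] = (30.0, 50.0)       # ms
    slurred_width_range: tuple[float, float] = (60.0, 90.0)  # ms
    rs_ratio_range: tuple[float, float] = (0.3, 0.8)         # R/S for RS class
    small_r_ratio_range: tuple[float, float] = (0.15, 0.3)   # R/S for rS class
    jitter_sd: float = 3.0             # ms, truncated at +/- jitter_max
    jitter_max: float = 10.0           # ms
    noise_sd: float = 0.005            # mV, white amplifier noise
    baseline_wander_amplitude: float = 0.05   # mV
    baseline_wander_frequency: float = 0.4    # Hz
    ventricular_cl_range: tuple[float, float] = (600.0, 1000.0)  # ms
    ventricular_amplitude_range: tuple[float, float] = (0.05, 0.15)  # mV
    ventricular_prob: float = 0.5      # chance a record carries far-field
    bipolar_amplitude_range: tuple[float, float] = (0.3, 0.8)  # mV
    switch_time: float = 1400.0        # ms, morphology switch (SWITCHING)
    nonsustained_fraction_range: tuple[float, float] = (0.45, 0.6)
    prevalence: float = 0.092          # fraction of FaST records in a cohort
    records_per_patient: int = 50
    patient_scale_sd: float = 0.15     # lognormal sd of per-patient amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        lo, hi = self.cl_range
        if not (0 < lo < hi < self.duration * 1000.0):
            raise ValueError("cl_range must be ordered and within the record duration")


def default_class_mix(prevalence: float = 0.092) -> dict[str, float]:
    """Class probabilities with the FaST classes summing to ``prevalence``.

    The non-FaST mass is dominated by periodic RS trains, with smaller
    shares of borderline morphologies (small-r rS, switching, non-sustained
    QS, fractionation) and aperiodic activity.
    """
    fast = {"FAST_QS": 0.65, "LOW_AMP_QS": 0.175, "SLURRED_QS": 0.175}
    nonfast = {
        "PERIODIC_RS": 0.385,
        "SMALL_R_RS": 0.165,
        "SWITCHING": 0.11,
        "NONSUSTAINED_QS": 0.11,
        "FRACTIONATED": 0.12,
        "APERIODIC": 0.11,
    }
    mix = {k: v * prevalence for k, v in fast.items()}
    mix.update({k: v * (1.0 - prevalence) for k, v in nonfast.items()})
    return mix


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine bump over n samples (endpoints at zero)."""
    x = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))
    m = x.max()
    return x / m if m > 0 else x


def make_complex_template(
    kind: str,
    width: float,
    amplitude: float,
    r_to_s_ratio: float = 0.0,
    sampling_rate: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build one unipolar complex template, in mV.

    Parameters
    ----------
    kind : {"QS", "RS", "rS", "fractionated", "ventricular"}
        QS is a monophasic negative (inverted raised-cosine) dip.  RS/rS is
        a positive lobe followed by a negative lobe whose sampled-peak ratio
        equals ``r_to_s_ratio`` exactly.  Fractionated complexes are 2-4
        jittered biphasic sub-deflections within the template width.
        Ventricular far-field is a broad (>= 80 ms), dominantly negative
        low-frequency wave with a small positive lead-in.
    width : float
        Template width in ms.
    amplitude : float
        Dominant (negative) deflection amplitude in mV.
    r_to_s_ratio : float
        Positive-to-negative peak amplitude ratio; forced to 0 for QS.
    """
    if width <= 0 or amplitude <= 0:
        raise ValueError("width and amplitude must be positive")
    if r_to_s_ratio < 0:
        raise ValueError("r_to_s_ratio must be non-negative")
    n = max(int(round(width * sampling_rate / 1000.0)), 4)
    if kind == "QS":
        return -amplitude * _raised_cosine(n)
    if kind in ("RS", "rS"):
        n_r = max(int(round(0.4 * n)), 2)
        n_s = n - n_r
        tpl = np.zeros(n)
        tpl[:n_r] = r_to_s_ratio * amplitude * _raised_cosine(n_r)
        tpl[n_r:] = -amplitude * _raised_cosine(n_s)
        return tpl
    if kind == "fractionated":
        rng = rng if rng is not None else np.random.default_rng(0)
        n_sub = int(rng.integers(2, 5))
        tpl = np.zeros(n)
        sub_n = max(n // (2 * n_sub), 3)
        sub = _raised_cosine(sub_n)
        positions = np.sort(rng.integers(0, max(n - sub_n, 1), size=n_sub))
        for i, pos in enumerate(positions):
            sign = 1.0 if i % 2 == 0 else -1.0
            scale = amplitude * rng.uniform(0.4, 1.0)
            tpl[pos:pos + sub_n] += sign * scale * sub
        # guarantee the dominant deflection is negative at full amplitude
        if tpl.min() >= 0.0:
            mid = n // 2
            seg = min(sub_n, n - mid)
            tpl[mid:mid + seg] -= amplitude * sub[:seg]
        tpl *= amplitude / (-tpl.min())
        return tpl
    if kind == "ventricular":
        if width < 80.0:
            raise ValueError("ventricular far-field templates must be >= 80 ms wide")
        n_r = max(int(round(0.25 * n)), 2)
        tpl = np.zeros(n)
        tpl[:n_r] = 0.15 * amplitude * _raised_cosine(n_r)
        tpl[n_r:] = -amplitude * _raised_cosine(n - n_r)
        return tpl
    raise ValueError(f"unknown template kind {kind!r}")


def _bipolar_kernel(sampling_rate: float, sigma_ms: float = 5.0) -> np.ndarray:
    """Unit-peak biphasic activation kernel (derivative of a Gaussian)."""
    sigma = sigma_ms * sampling_rate / 1000.0
    half = int(round(4 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    k = -t * np.exp(-t * t / (2.0 * sigma * sigma))
    return k / np.abs(k).max()


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float,
                      size: int) -> np.ndarray:
    x = rng.normal(0.0, sd, size=size)
    return np.clip(x, -bound, bound)


def _add_at(trace: np.ndarray, start_idx: int, template: np.ndarray) -> None:
    """Add a template into the trace, clipping at the record edges."""
    n = len(trace)
    a = max(start_idx, 0)
    b = min(start_idx + len(template), n)
    if b > a:
        trace[a:b] += template[a - start_idx: b - start_idx]


def _activation_times(rng: np.random.Generator, cl: float, config: SynthConfig,
                      t_start: float, t_stop: float) -> np.ndarray:
    """Jittered periodic train of onsets in [t_start, t_stop)."""
    base = np.arange(t_start, t_stop, cl)
    jit = _truncated_normal(rng, config.jitter_sd, config.jitter_max, len(base))
    times = np.sort(base + jit)
    # jitter is bounded well below cl/2, so ordering is preserved; enforce anyway
    times = times[(times >= 0) & (times < t_stop)]
    return times


def synth_record(
    class_name: str,
    config: SynthConfig | None = None,
    seed: int = 0,
    cycle_length: float | None = None,
    record_id: str = "rec0",
    patient_id: str = "p0",
    amplitude_scale: float = 1.0,
    force_ventricular: bool | None = None,
) -> tuple[EgmRecord, GroundTruth]:
    """Generate one labelled record.

    Identical ``(class_name, config, seed)`` produce bit-identical output.
    ``cycle_length`` pins the atrial CL (must lie within ``config.cl_range``);
    otherwise it is drawn uniformly from that range.
    """
    config = config if config is not None else SynthConfig()
    if class_name not in ALL_CLASSES:
        raise ValueError(f"unknown class {class_name!r}")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(fs * config.duration))
    dur_ms = config.duration * 1000.0

    aperiodic = class_name == "APERIODIC"
    if aperiodic:
        cl: float | None = None
    elif cycle_length is not None:
        lo, hi = config.cl_range
        if not (lo <= cycle_length <= hi):
            raise ValueError(
                f"cycle_length {cycle_length} outside cl_range {config.cl_range}")
        cl = float(cycle_length)
    else:
        cl = float(rng.uniform(*config.cl_range))

    # --- activation times --------------------------------------------------
    edge = 60.0  # keep complexes clear of the record end
    if aperiodic:
        times = []
        t = rng.uniform(40.0, 200.0)
        while t < dur_ms - edge:
            times.append(t)
            t += rng.uniform(120.0, 400.0)
        times = np.asarray(times)
    elif class_name == "NONSUSTAINED_QS":
        frac = rng.uniform(*config.nonsustained_fraction_range)
        t0 = rng.uniform(40.0, 160.0)
        times = _activation_times(rng, cl, config, t0, t0 + frac * dur_ms)
    else:
        t0 = rng.uniform(40.0, 160.0)
        times = _activation_times(rng, cl, config, t0, dur_ms - edge)

    # --- per-complex morphology --------------------------------------------
    if class_name in ("FAST_QS", "LOW_AMP_QS", "SLURRED_QS", "NONSUSTAINED_QS"):
        morph = ["QS"] * len(times)
    elif class_name in ("PERIODIC_RS", "SMALL_R_RS", "FRACTIONATED"):
        morph = ["NONQS"] * len(times)
    elif class_name == "SWITCHING":
        morph = ["NONQS" if t < config.switch_time else "QS" for t in times]
    else:  # APERIODIC: mixed morphology, non-periodic so never FaST
        morph = ["QS" if rng.random() < 0.5 else "NONQS" for _ in times]

    # --- amplitudes and widths ----------------------------------------------
    if class_name == "LOW_AMP_QS":
        s_amp = rng.uniform(*config.low_amp_range)
    else:
        s_amp = rng.uniform(*config.qs_amplitude_range)
    s_amp *= amplitude_scale
    if class_name == "SLURRED_QS":
        width = rng.uniform(*config.slurred_width_range)
    else:
        width = rng.uniform(*config.qs_width_range)
    if class_name == "PERIODIC_RS":
        ratio = rng.uniform(*config.rs_ratio_range)
    elif class_name == "SMALL_R_RS":
        ratio = rng.uniform(*config.small_r_ratio_range)
    else:
        ratio = 0.0

    # --- unipolar channel ----------------------------------------------------
    uni = np.zeros(n)
    for t, m in zip(times, morph):
        amp_i = s_amp * rng.uniform(0.9, 1.1)
        if class_name == "FRACTIONATED":
            tpl = make_complex_template("fractionated", 60.0, amp_i, rng=rng)
        elif m == "QS":
            tpl = make_complex_template("QS", width, amp_i)
        else:
            kind = "rS" if ratio < 0.3 else "RS"
            r = ratio if ratio > 0 else rng.uniform(*config.rs_ratio_range)
            tpl = make_complex_template(kind, width, amp_i, r_to_s_ratio=r)
        _add_at(uni, int(round(t * fs / 1000.0)), tpl)

    if force_ventricular is None:
        has_vent = rng.random() < config.ventricular_prob
    else:
        has_vent = bool(force_ventricular)
    vent_times = np.empty(0)
    if has_vent:
        v_cl = rng.uniform(*config.ventricular_cl_range)
        v_amp = rng.uniform(*config.ventricular_amplitude_range) * amplitude_scale
        v0 = rng.uniform(0.0, v_cl)
        vent_times = np.arange(v0, dur_ms - 120.0, v_cl)
        v_tpl = make_complex_template("ventricular", 120.0, v_amp)
        for t in vent_times:
            _add_at(uni, int(round(t * fs / 1000.0)), v_tpl)

    t_s = np.arange(n) / fs
    wander_phase = rng.uniform(0, 2 * np.pi)
    uni += config.baseline_wander_amplitude * np.sin(
        2 * np.pi * config.baseline_wander_frequency * t_s + wander_phase)
    uni += rng.normal(0.0, config.noise_sd, size=n)

    # --- bipolar channel -----------------------------------------------------
    bip = np.zeros(n)
    kernel = _bipolar_kernel(fs)
    half = len(kernel) // 2
    b_amp = rng.uniform(*config.bipolar_amplitude_range) * amplitude_scale
    for t in times:
        amp_i = b_amp * rng.uniform(0.9, 1.1)
        _add_at(bip, int(round(t * fs / 1000.0)) - half, amp_i * kernel)
    if has_vent:
        # far field is attenuated and slow in the bipolar channel: below both
        # the amplitude and the slew thresholds of candidate detection
        v_bip = make_complex_template("ventricular", 120.0, 0.03)
        for t in vent_times:
            _add_at(bip, int(round(t * fs / 1000.0)), v_bip)
    bip += rng.normal(0.0, 0.2 * config.noise_sd, size=n)

    record = EgmRecord(record_id=record_id, patient_id=patient_id,
                       sampling_rate=fs, unipolar=uni, bipolar=bip,
                       duration=config.duration)
    truth = GroundTruth(
        class_name=class_name,
        is_fast=class_name in FAST_CLASSES,
        cycle_length=cl,
        activation_times=times,
        per_complex_morphology=morph,
        has_ventricular_farfield=has_vent,
        ventricular_times=vent_times,
    )
    return record, truth


def synth_cohort(
    n_records: int,
    config: SynthConfig | None = None,
    class_mix: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[tuple[EgmRecord, GroundTruth]]]:
    """Generate a cohort of records grouped into synthetic patients.

    Records are assigned to patients in blocks of ``config.records_per_patient``
    with a patient-specific lognormal amplitude scale, so that patient-level
    cross-validation splits are meaningful.  The manifest has columns
    ``record_path`` (a placeholder file name until records are written),
    ``patient_id``, ``label`` and ``class_name``.
    """
    config = config if config is not None else SynthConfig()
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if class_mix is None:
        class_mix = default_class_mix(config.prevalence)
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mix probabilities sum to {probs.sum()}, not 1")

    master = np.random.SeedSequence(config.seed if seed is None else seed)
    root = np.random.default_rng(master)
    n_patients = int(np.ceil(n_records / config.records_per_patient))
    scales = np.exp(root.normal(0.0, config.patient_scale_sd, size=n_patients))
    chosen = root.choice(len(classes), size=n_records, p=probs)
    child_seeds = master.spawn(n_records)

    rows = []
    out: list[tuple[EgmRecord, GroundTruth]] = []
    for i in range(n_records):
        p = i // config.records_per_patient
        cname = classes[chosen[i]]
        rid = f"r{i:05d}"
        pid = f"pt{p:03d}"
        rec_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        rec, truth = synth_record(cname, config, seed=rec_seed, record_id=rid,
                                  patient_id=pid, amplitude_scale=scales[p])
        rows.append({"record_path": f"{rid}.egm", "patient_id": pid,
                     "label": int(truth.is_fast), "class_name": cname})
        out.append((rec, truth))
    manifest = pd.DataFrame(rows)
    return manifest, out
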