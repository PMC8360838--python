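"""Electrogram record containers and plain-text I/O.

A record pairs a unipolar and a bipolar trace recorded simultaneously at one
site.  The on-disk format is deliberately simple and diff-friendly:
``#``-prefixed ``key=value`` header lines followed by tab-separated columns
``t_ms``, ``unipolar_mv``, ``bipolar_mv``.  Manifests are TSV tables with
columns ``record_path``, ``patient_id``, ``label``, ``class_name``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EgmRecord",
    "GroundTruth",
    "FormatError",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
]


class FormatError(ValueError):
    """A record or manifest file violates the on-disk contract."""


@dataclass
class EgmRecord:
    """Paired unipolar/bipolar electrogram traces from one recording site.

    Parameters
    ----------
    record_id, patient_id : str
        Opaque identifiers.
    sampling_rate : float
        Samples per second (Hz).
    unipolar, bipolar : ndarray
        Voltage traces in mV, equal length ``round(sampling_rate * duration)``.
    duration : float
        Recording length in seconds.
    """

    record_id: str
    patient_id: str
    sampling_rate: float
    unipolar: np.ndarray
    bipolar: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.unipolar = np.asarray(self.unipolar, dtype=float)
        self.bipolar = np.asarray(self.bipolar, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        n = int(round(self.sampling_rate * self.duration))
        if len(self.unipolar) != n or len(self.bipolar) != n:
            raise ValueError(
                f"trace lengths ({len(self.unipolar)}, {len(self.bipolar)}) do not "
                f"match round(sampling_rate * duration) = {n}"
            )
        if not (np.all(np.isfinite(self.unipolar)) and np.all(np.isfinite(self.bipolar))):
            raise ValueError("traces must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.unipolar)

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from record start (sample 0 at t = 0 ms)."""
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate


@dataclass
class GroundTruth:
    """Generator-side labels attached to a synthetic record.

    ``is_fast`` is True only for classes whose complexes are dominantly QS
    and whose activation train is periodic and sustained over the recording.
    """

    class_name: str
    is_fast: bool
    cycle_length: float | None  # ms; None for APERIODIC
    activation_times: np.ndarray  # ms, strictly increasing
    per_complex_morphology: list[str]  # "QS" | "NONQS" per activation
    has_ventricular_farfield: bool
    ventricular_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.activation_times = np.asarray(self.activation_times, dtype=float)
        self.ventricular_times = np.asarray(self.ventricular_times, dtype=float)
        if len(self.activation_times) > 1 and not np.all(np.diff(self.activation_times) > 0):
            raise ValueError("activation_times must be strictly increasing")
        if len(self.per_complex_morphology) != len(self.activation_times):
            raise ValueError("per_complex_morphology length must match activation_times")

    @property
    def qs_fraction(self) -> float:
        if not self.per_complex_morphology:
            return 0.0
        qs = sum(1 for m in self.per_complex_morphology if m == "QS")
        return qs / len(self.per_complex_morphology)


_REQUIRED_HEADER = ("record_id", "patient_id", "sampling_rate_hz", "duration_s")


def write_record(record: EgmRecord, path: str | os.PathLike,
                 label: int | None = None, class_name: str | None = None) -> None:
    """Write a record to the plain-text tab-separated format."""
    t = record.times_ms
    with open(path, "w") as fh:
        fh.write(f"#record_id={record.record_id}\n")
        fh.write(f"#patient_id={record.patient_id}\n")
        fh.write(f"#sampling_rate_hz={record.sampling_rate:g}\n")
        fh.write(f"#duration_s={record.duration:g}\n")
        if label is not None:
            fh.write(f"#label={int(label)}\n")
        if class_name is not None:
            fh.write(f"#class_name={class_name}\n")
        fh.write("t_ms\tunipolar_mv\tbipolar_mv\n")
        for ti, u, b in zip(t, record.unipolar, record.bipolar):
            fh.write(f"{ti:.3f}\t{u:.10g}\t{b:.10g}\n")


def read_record(path: str | os.PathLike) -> EgmRecord:
    """Read a record written by :func:`write_record`.

    Raises
    ------
    FormatError
        On missing header keys, ragged columns or non-monotone ``t_ms``,
        naming the offending line.
    """
    header: dict[str, str] = {}
    t, uni, bip = [], [], []
    with open(path) as fh:
        saw_columns = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
                continue
            if not saw_columns:
                saw_columns = True  # column-name row
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                t.append(float(parts[0]))
                uni.append(float(parts[1]))
                bip.append(float(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric sample: {exc}") from None
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    tarr = np.asarray(t)
    if len(tarr) > 1 and not np.all(np.diff(tarr) > 0):
        bad = int(np.argmax(np.diff(tarr) <= 0)) + 2
        raise FormatError(f"{path}: t_ms not strictly increasing near data row {bad}")
    return EgmRecord(
        record_id=header["record_id"],
        patient_id=header["patient_id"],
        sampling_rate=float(header["sampling_rate_hz"]),
        unipolar=np.asarray(uni),
        bipolar=np.asarray(bip),
        duration=float(header["duration_s"]),
    )


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["record_path", "patient_id", "label", "class_name"]
    manifest.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"record_path": str, "patient_id": str,
                                            "label": int, "class_name": str})
    missing = {"record_path", "patient_id", "label", "class_name"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = df["record_path"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate record_path {df['record_path'][dup].iloc[0]!r}")
    return df
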