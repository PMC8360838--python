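"""Classifier input preparation: FFT resampling, min-max scaling, augmentation.

Unipolar traces are downsampled from 1,000 Hz to 200 Hz in the Fourier
domain and min-max scaled to [0, 1] before classification.  Four stochastic
augmentations regularize training: baseline shifting (one normal constant),
Gaussian noise (i.i.d. per sample), cropping (a contiguous segment replaced
by zeros) and resampling (a segment deleted, the shorter signal stretched
back to the original length in the Fourier domain).  Each augmentation fires
independently with a configurable probability, so both clean and corrupted
examples are seen during training; scaling is applied last so outputs stay
in [0, 1].

The sklearn-style transformers (:class:`FFTResampler`,
:class:`MinMaxSignalScaler`, :class:`EgmAugmenter`) wrap the functional API
and compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AugmentConfig",
    "PreprocSignal",
    "resample_fft",
    "minmax_scale",
    "augment",
    "augment_pipeline",
    "preprocess_record",
    "FFTResampler",
    "MinMaxSignalScaler",
    "EgmAugmenter",
]

AUGMENT_MODES = ("baseline_shift", "gaussian_noise", "crop", "resample")


@dataclass
class AugmentConfig:
    """Augmentation magnitudes (on the pre-scaling signal) and firing odds."""

    probability: float = 0.5
    baseline_shift_sd: float = 0.1
    noise_sd: float = 0.05
    crop_fraction_range: tuple[float, float] = (0.05, 0.15)
    resample_fraction_range: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        for name in ("crop_fraction_range", "resample_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi):
                raise ValueError(f"{name} must be ordered and non-negative")
            if hi >= 1.0:
                raise ValueError(f"{name} fractions must be < 1")


@dataclass
class PreprocSignal:
    """A scaled 200-Hz classifier input and the augmentations applied to it."""

    values: np.ndarray
    sampling_rate: float = 200.0
    applied_augmentations: list[str] = field(default_factory=list)


def resample_fft(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Fourier-domain resampling to ``round(len(x) * rate_out / rate_in)``."""
    if rate_out <= 0:
        raise ValueError("rate_out must be positive")
    if rate_out > rate_in:
        raise ValueError("upsampling beyond the input rate is not supported")
    x = np.asarray(x, dtype=float)
    n_out = int(round(len(x) * rate_out / rate_in))
    if n_out == len(x):
        return x.copy()
    return sps.resample(x, n_out)


def minmax_scale(x: np.ndarray) -> np.ndarray:
    """Min-max feature scaling to [0, 1]; constant inputs map to all 0.5."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def augment(x: np.ndarray, mode: str, config: AugmentConfig | None = None,
            seed: int = 0) -> np.ndarray:
    """Apply one augmentation; output length always equals input length."""
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if mode == "baseline_shift":
        return x + rng.normal(0.0, config.baseline_shift_sd)
    if mode == "gaussian_noise":
        return x + rng.normal(0.0, config.noise_sd, size=n)
    if mode == "crop":
        frac = rng.uniform(*config.crop_fraction_range)
        length = int(np.floor(frac * n))
        if length == 0:
            return x.copy()
        start = int(rng.integers(0, n - length + 1))
        out = x.copy()
        out[start:start + length] = 0.0
        return out
    if mode == "resample":
        frac = rng.uniform(*config.resample_fraction_range)
        length = int(np.floor(frac * n))
        if length == 0:
            return x.copy()
        start = int(rng.integers(0, n - length + 1))
        shorter = np.concatenate([x[:start], x[start + length:]])
        return sps.resample(shorter, n)
    raise ValueError(f"unknown augmentation mode {mode!r}")


def augment_pipeline(x: np.ndarray, config: AugmentConfig | None = None,
                     seed: int = 0) -> PreprocSignal:
    """Apply each augmentation independently with ``config.probability``,
    then min-max scale.  Deterministic under a fixed seed."""
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    out = np.asarray(x, dtype=float)
    applied: list[str] = []
    for mode in AUGMENT_MODES:
        fire = rng.random() < config.probability
        sub_seed = int(rng.integers(0, 2**31))
        if fire:
            out = augment(out, mode, config, seed=sub_seed)
            applied.append(mode)
    return PreprocSignal(values=minmax_scale(out), sampling_rate=200.0,
                         applied_augmentations=applied)


def preprocess_record(unipolar: np.ndarray, rate_in: float = 1000.0,
                      rate_out: float = 200.0) -> np.ndarray:
    """Deterministic inference-time preparation: resample then scale."""
    return minmax_scale(resample_fft(unipolar, rate_in, rate_out))


class FFTResampler(TransformerMixin, BaseEstimator):
    """Sklearn transformer: Fourier-domain downsampling of each row."""

    def __init__(self, rate_in: float = 1000.0, rate_out: float = 200.0):
        self.rate_in = rate_in
        self.rate_out = rate_out

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([resample_fft(row, self.rate_in, self.rate_out)
                         for row in X])


class MinMaxSignalScaler(TransformerMixin, BaseEstimator):
    """Sklearn transformer: per-row min-max scaling to [0, 1]."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([minmax_scale(row) for row in X])


class EgmAugmenter(TransformerMixin, BaseEstimator):
    """Sklearn transformer applying the stochastic augmentation pipeline.

    Intended for training-time use only; pass ``probability=0`` (the
    transform then reduces to min-max scaling) for inference.
    """

    def __init__(self, probability: float = 0.5, baseline_shift_sd: float = 0.1,
                 noise_sd: float = 0.05,
                 crop_fraction_range: tuple[float, float] = (0.05, 0.15),
                 resample_fraction_range: tuple[float, float] = (0.05, 0.15),
                 seed: int = 0):
        self.probability = probability
        self.baseline_shift_sd = baseline_shift_sd
        self.noise_sd = noise_sd
        self.crop_fraction_range = crop_fraction_range
        self.resample_fraction_range = resample_fraction_range
        self.seed = seed

    def _config(self) -> AugmentConfig:
        return AugmentConfig(probability=self.probability,
                             baseline_shift_sd=self.baseline_shift_sd,
                             noise_sd=self.noise_sd,
                             crop_fraction_range=self.crop_fraction_range,
                             resample_fraction_range=self.resample_fraction_range,
                             seed=self.seed)

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        config = self._config()
        rng = np.random.default_rng(self.seed)
        rows = []
        for row in np.asarray(X, dtype=float):
            rows.append(augment_pipeline(row, config,
                                         seed=int(rng.integers(0, 2**31))).values)
        return np.stack(rows)
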