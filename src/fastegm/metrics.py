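"""ROC analysis, operating points at prespecified sensitivities, agreement.

Operating points follow the convention ``score >= threshold -> FaST``
(closed on the positive side).  Two exact identities hold for every
report: F1 is the harmonic mean of PPV and sensitivity, and accuracy is
the prevalence-weighted mean of sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "roc_auc",
    "threshold_at_sensitivity",
    "metrics_at_threshold",
    "f1_from_ppv_sensitivity",
    "accuracy_from_rates",
    "cohen_kappa",
]


@dataclass
class MetricsReport:
    """Operating-point metrics plus the underlying confusion counts."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    accuracy: float
    prevalence: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(d["auc_ci"])
        return d


def f1_from_ppv_sensitivity(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of positive predictive value and sensitivity."""
    if ppv + sensitivity <= 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def accuracy_from_rates(prevalence: float, sensitivity: float,
                        specificity: float) -> float:
    """Accuracy as the prevalence-weighted mean of sensitivity/specificity."""
    return prevalence * sensitivity + (1.0 - prevalence) * specificity


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0,
            ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney ranking probability, ties at half) with a
    seeded percentile-bootstrap confidence interval over records."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    alpha = (1.0 - ci) / 2.0
    lo, hi = (np.quantile(boots, [alpha, 1.0 - alpha]) if boots
              else (float("nan"), float("nan")))
    return auc, (float(lo), float(hi))


def threshold_at_sensitivity(scores, labels, target_sensitivity: float) -> float:
    """Largest threshold whose achieved sensitivity is >= the target.

    With the ``score >= threshold`` rule this is the k-th largest positive
    score, k = ceil(target * n_positives).  All-positive input degenerates
    to the minimum score.
    """
    if not (0.0 < target_sensitivity <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    if len(pos) == 0:
        raise ValueError("no positive labels")
    if np.all(labels == 1):
        return float(scores.min())
    k = int(np.ceil(target_sensitivity * len(pos)))
    return float(np.sort(pos)[::-1][k - 1])


def metrics_at_threshold(scores, labels, threshold: float) -> MetricsReport:
    """Confusion-matrix metrics at a threshold (rule: score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) == 0:
        raise ValueError("empty input")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    p, n = tp + fn, fp + tn
    sens = tp / p if p else float("nan")
    spec = tn / n if n else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    npv = tn / (tn + fn) if (tn + fn) else 0.0
    prevalence = p / len(labels)
    return MetricsReport(
        threshold=float(threshold), sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, f1=f1_from_ppv_sensitivity(ppv, sens),
        accuracy=accuracy_from_rates(prevalence, sens, spec)
        if p and n else (tp + tn) / len(labels),
        prevalence=prevalence, tp=tp, fp=fp, tn=tn, fn=fn)


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa for two binary label sequences.

    Chance agreement comes from the marginal products; when both raters are
    constant and identical (chance agreement 1) kappa is defined as 1.
    """
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("label sequences must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label sequences")
    p_o = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else -1.0
    return float((p_o - p_e) / (1.0 - p_e))
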