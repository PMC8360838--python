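"""Cross-validation with patient-level splits, repeated over seeds.

Patients — not records — are the resampling unit: all records of a patient
fall in the same fold, so validation performance is not inflated by
within-patient correlation.  The default plan is three folds repeated with
five seeds, each seed producing both a different fold assignment and a
different network initialization.  An optional list of subsample fractions
re-runs training on nested subsets of training patients to chart AUC
against training-cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import metrics_at_threshold, roc_auc, threshold_at_sensitivity

__all__ = ["CvPlan", "patient_folds", "cross_validate"]


@dataclass
class CvPlan:
    n_folds: int = 3
    n_seeds: int = 5
    subsample_fractions: list[float] | None = None
    target_sensitivities: tuple[float, ...] = (0.85, 0.90, 0.95)


def patient_folds(patient_ids, n_folds: int, seed: int = 0):
    """Partition records into folds by patient; yields (train_idx, test_idx)."""
    patient_ids = np.asarray(patient_ids)
    uniq = np.unique(patient_ids)
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} patients cannot form {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    parts = np.array_split(order, n_folds)
    folds = []
    for part in parts:
        test = np.isin(patient_ids, part)
        folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
    return folds


def cross_validate(X, y, patient_ids, make_estimator, plan: CvPlan | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Repeated patient-level k-fold cross-validation.

    Parameters
    ----------
    make_estimator : callable
        ``make_estimator(seed) -> estimator`` with sklearn ``fit`` and a
        continuous score (``predict_proba`` or ``decision_function``).
    plan : CvPlan
        Folds, seed repeats, operating points and optional training-size
        subsample fractions.

    Returns
    -------
    table : DataFrame
        One row per (seed, fold[, fraction]) with AUC and operating-point
        metrics at each target sensitivity.
    summary : dict
        Mean and across-seed standard deviation of AUC (and per operating
        point) pooled over folds, plus the fold assignments per seed.
    """
    plan = plan or CvPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    patient_ids = np.asarray(patient_ids)
    fractions = plan.subsample_fractions or [1.0]
    rows = []
    assignments = []
    for s in range(plan.n_seeds):
        fold_seed = seed + 1000 * s
        folds = patient_folds(patient_ids, plan.n_folds, seed=fold_seed)
        for f, (tr, te) in enumerate(folds):
            assignments.append({"seed": fold_seed, "fold": f,
                                "test_patients": sorted(set(patient_ids[te]))})
            tr_patients = np.unique(patient_ids[tr])
            rng = np.random.default_rng(fold_seed + f)
            shuffled = rng.permutation(tr_patients)
            for frac in fractions:
                n_keep = max(int(round(frac * len(shuffled))), 1)
                keep = set(shuffled[:n_keep])  # nested subsets across fracs
                sub = tr[np.isin(patient_ids[tr], list(keep))]
                if len(np.unique(y[sub])) < 2:
                    continue
                est = make_estimator(fold_seed + f)
                try:
                    est.fit(X[sub], y[sub], groups=patient_ids[sub])
                except TypeError:
                    est.fit(X[sub], y[sub])
                if hasattr(est, "decision_function"):
                    scores = np.asarray(est.decision_function(X[te]), dtype=float)
                else:
                    scores = np.asarray(est.predict_proba(X[te])[:, 1], dtype=float)
                if len(np.unique(y[te])) < 2:
                    continue
                auc, ci = roc_auc(scores, y[te], n_boot=200, seed=fold_seed)
                row = {"seed": fold_seed, "fold": f, "fraction": frac,
                       "auc": auc, "auc_ci_lo": ci[0], "auc_ci_hi": ci[1],
                       "n_test": len(te)}
                for t in plan.target_sensitivities:
                    thr = threshold_at_sensitivity(scores, y[te], t)
                    rep = metrics_at_threshold(scores, y[te], thr)
                    key = f"sens{int(round(t * 100))}"
                    row[f"specificity_at_{key}"] = rep.specificity
                    row[f"accuracy_at_{key}"] = rep.accuracy
                    row[f"f1_at_{key}"] = rep.f1
                rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict = {"fold_assignments": assignments}
    if not table.empty:
        for frac in fractions:
            sub = table[table["fraction"] == frac]
            per_seed = sub.groupby("seed")["auc"].mean()
            key = "" if len(fractions) == 1 else f"_frac{frac:g}"
            summary[f"auc_mean{key}"] = float(per_seed.mean())
            summary[f"auc_sd{key}"] = float(per_seed.std(ddof=1)) if len(per_seed) > 1 else 0.0
    return table, summary
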