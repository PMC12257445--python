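"""Statistical comparison harness: repeated stratified 80/20 splits,
logistic regression on diffusion-model parameters, ROC/accuracy, coefficient
normalization, and Mann-Whitney tests of each model against the model-free
classifier.

The AUC is computed as the Mann-Whitney pairwise statistic (probability a
random positive outscores a random negative, ties counting one half), which
equals the area under the empirical ROC curve.  Accuracy uses a 0.5
probability threshold.  Per-model logistic regressions are maximum
likelihood with an intercept and a mild ridge penalty so that perfect
separation degrades gracefully instead of diverging.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .classifier import (MLPSpec, normalize_signals, predict_proba,
                         smote_balance, train_modem)
from .models import MODEL_NAMES, fit_params, fit_table
from .protocol import AcquisitionProtocol

METHODS_ALL = ("modem",) + MODEL_NAMES


@dataclass
class EvaluationReport:
    """Per-iteration AUC/accuracy records with summaries and comparisons."""

    records: pd.DataFrame                       # iteration, method, auc, accuracy
    summary: pd.DataFrame                       # method, mean/SD of auc & accuracy
    p_values: pd.DataFrame                      # model vs MODEM, auc & accuracy
    coefficients: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def split_80_20(n_samples: int, labels: np.ndarray, seed: int = 0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, class-stratified 80/20 index split."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 5):
        raise ValueError(f"need >= 5 samples per class, got {counts}")
    idx = np.arange(n_samples)
    train, test = train_test_split(idx, test_size=0.2, stratify=labels,
                                   random_state=seed % (2 ** 31))
    return np.sort(train), np.sort(test)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy(labels: np.ndarray, scores: np.ndarray,
             threshold: float = 0.5) -> float:
    """Fraction of correct classifications at a probability threshold."""
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float(np.mean(pred == labels))


def logistic_on_params(train_x: np.ndarray, train_y: np.ndarray,
                       test_x: np.ndarray, ridge_c: float = 1e4
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary logistic regression with intercept on model parameters.

    Features are standardized internally (training mean/SD); returned
    coefficients are on the original feature scale.  Returns
    (test probabilities, coefficients, training-feature SDs).
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    zx = (train_x - mu) / sd_safe
    clf = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=2000)
    clf.fit(zx, np.asarray(train_y).astype(int))
    proba = clf.predict_proba((test_x - mu) / sd_safe)[:, 1]
    beta = clf.coef_.ravel() / sd_safe
    return proba, beta, sd


def normalize_coefficients(coefficients: np.ndarray,
                           feature_sds: np.ndarray) -> np.ndarray:
    """Scale-invariant weights w_i = |b_i| SD_i / sum_j |b_j| SD_j.

    The intercept is excluded by the caller.  Absolute values are used
    because signed coefficients cannot in general sum to one.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    feature_sds = np.asarray(feature_sds, dtype=float)
    if coefficients.size == 0:
        raise ValueError("no coefficients to normalize")
    scaled = np.abs(coefficients) * feature_sds
    total = scaled.sum()
    if total == 0:
        raise ValueError("all coefficients are zero")
    return scaled / total


def mann_whitney_compare(a, b) -> float:
    """Two-sided rank-sum p-value comparing two samples of AUC (or accuracy).

    Exact enumeration of the permutation distribution of U when both groups
    have <= 8 values (correct under ties); tie-corrected normal
    approximation otherwise.  Identical constant pooled input returns p = 1
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled input; p-value set to 1", stacklevel=2)
        return 1.0
    if a.size <= 8 and b.size <= 8:
        return _mw_exact(a, b)
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue)


def _u_stat(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _mw_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    values; two-sidedness via symmetric deviation of U from its mean."""
    pooled = np.concatenate([a, b])
    n1 = a.size
    center = n1 * b.size / 2.0
    d_obs = abs(_u_stat(a, b) - center)
    n_total = pooled.size
    count = 0
    total = 0
    for comb in itertools.combinations(range(n_total), n1):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(comb)] = True
        u = _u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= d_obs - 1e-12:
            count += 1
    return count / total


def probability_map_export(probabilities: np.ndarray,
                           coords: pd.DataFrame) -> pd.DataFrame:
    """Per-voxel probability table (voxel id, x, y, slice, probability)."""
    probabilities = np.asarray(probabilities, dtype=float)
    if len(coords) != probabilities.size:
        raise ValueError("coordinate table length != number of probabilities")
    out = coords.reset_index(drop=True).copy()
    if "voxel_id" not in out.columns:
        out.insert(0, "voxel_id", np.arange(len(out)))
    out["probability"] = probabilities
    return out


def run_study(table: pd.DataFrame,
              methods=("modem", "mono", "dki", "froc", "ctrw"),
              protocol: AcquisitionProtocol | None = None,
              n_iterations: int = 100,
              master_seed: int = 0,
              mlp_overrides: dict | None = None,
              min_converged_fraction: float = 0.9) -> EvaluationReport:
    """Repeated split/train/evaluate comparison of all requested methods.

    Model fits are computed once per sample and cached across iterations
    (they do not depend on the split).  Rows whose fit failed are dropped
    from that model's regressions; if more than 10% of rows fail the model
    is reported as NaN for the affected iteration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    labels = table["label"].to_numpy().astype(int)
    features = normalize_signals(table)

    # fit cache: model -> (param matrix, converged mask)
    fit_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    param_names: dict[str, list[str]] = {}
    for m in methods:
        if m == "modem":
            continue
        fits = fit_table(table, m, protocol)
        names = list(fit_params(fits[0]).keys())
        mat = np.array([[getattr(f, p) for p in names] for f in fits])
        conv = np.array([f.converged and np.all(np.isfinite(
            [getattr(f, p) for p in names])) for f in fits])
        fit_cache[m] = (mat, conv)
        param_names[m] = names

    ss = np.random.SeedSequence(master_seed)
    iter_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(n_iterations)]

    records = []
    coef_accum: dict[str, list[np.ndarray]] = {m: [] for m in methods
                                               if m != "modem"}
    for it, seed in enumerate(iter_seeds):
        tr, te = split_80_20(len(table), labels, seed=seed)
        y_tr, y_te = labels[tr], labels[te]
        for m in methods:
            if m == "modem":
                x_tr, y_bal = smote_balance(features[tr], y_tr, seed=seed)
                spec = MLPSpec(n_inputs=features.shape[1], seed=seed,
                               **(mlp_overrides or {}))
                model = train_modem(x_tr, y_bal, spec)
                proba = predict_proba(model, features[te])
            else:
                mat, conv = fit_cache[m]
                ok_tr = tr[conv[tr]]
                ok_te = te[conv[te]]
                if (conv[tr].mean() < min_converged_fraction
                        or len(ok_te) == 0
                        or np.unique(labels[ok_tr]).size < 2):
                    records.append({"iteration": it, "method": m,
                                    "auc": np.nan, "accuracy": np.nan})
                    continue
                proba_ok, beta, sds = logistic_on_params(
                    mat[ok_tr], labels[ok_tr], mat[ok_te])
                coef_accum[m].append(normalize_coefficients(beta, sds))
                proba = proba_ok
                y_te = labels[ok_te]
            records.append({
                "iteration": it, "method": m,
                "auc": roc_auc(y_te, proba),
                "accuracy": accuracy(y_te, proba)})
            y_te = labels[te]  # restore for next method

    rec = pd.DataFrame(records)
    summary = rec.groupby("method")[["auc", "accuracy"]].agg(["mean", "std"])
    p_rows = []
    if "modem" in methods:
        modem_auc = rec.loc[rec.method == "modem", "auc"].to_numpy()
        modem_acc = rec.loc[rec.method == "modem", "accuracy"].to_numpy()
        for m in methods:
            if m == "modem":
                continue
            m_auc = rec.loc[rec.method == m, "auc"].dropna().to_numpy()
            m_acc = rec.loc[rec.method == m, "accuracy"].dropna().to_numpy()
            if m_auc.size >= 2 and modem_auc.size >= 2:
                p_rows.append({
                    "method": m,
                    "p_auc": mann_whitney_compare(m_auc, modem_auc),
                    "p_accuracy": mann_whitney_compare(m_acc, modem_acc)})
    coefs = {}
    for m, acc_list in coef_accum.items():
        if acc_list:
            mean_w = np.mean(np.vstack(acc_list), axis=0)
            mean_w = mean_w / mean_w.sum()
            coefs[m] = pd.DataFrame({"parameter": param_names[m],
                                     "normalized_coefficient": mean_w})
    return EvaluationReport(
        records=rec, summary=summary, p_values=pd.DataFrame(p_rows),
        coefficients=coefs,
        metadata={"n_iterations": n_iterations, "master_seed": master_seed,
                  "methods": list(methods), "n_samples": len(table)})
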