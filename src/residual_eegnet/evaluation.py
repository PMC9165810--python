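"""Cross-subject evaluation: prediction, confusion/accuracy metrics,
k-fold orchestration and the Welch + Benjamini-Hochberg model comparisons.

Model comparisons treat the cross-validation fold as the experimental
unit (n = fold count of accuracies per variant): each variant is tested
against the reference with Welch's unequal-variance t-test, two-tailed,
and the family of comparisons is corrected with the Benjamini-Hochberg
step-up FDR procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from residual_eegnet.architecture import ModelConfig, build_model
from residual_eegnet.data_model import EEGEpoch, SplitPlan, TaskLabel, epochs_by_subject
from residual_eegnet.preprocessing import AugmentParams
from residual_eegnet.training import TrainConfig, prepare_arrays, train_model
from residual_eegnet import nn

log = logging.getLogger(__name__)

N_CLASS = len(TaskLabel)


@dataclass
class StatTestResult:
    t: float
    df: float
    p: float
    rejected: bool = False
    q: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class FoldResults:
    fold_index: int
    accuracy: float
    per_subject_accuracy: pd.Series
    confusion: np.ndarray
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must be a fraction in [0, 1]")


@dataclass
class CrossValResult:
    folds: list[FoldResults]
    mean_accuracy: float
    sd_accuracy: float
    states: list = field(default_factory=list)


def predict(model: nn.Model, x: np.ndarray, batch_size: int = 200):
    """Argmax class per trial; exact ties go to the lowest label index.

    ``x`` is a stacked, normalized ``(N, 1, C, T)`` array.  Returns
    ``(labels, tie_count)``.
    """
    preds = []
    ties = 0
    for i in range(0, x.shape[0], batch_size):
        scores = model.forward(x[i : i + batch_size], train=False)
        top = scores.max(axis=1, keepdims=True)
        ties += int(((scores == top).sum(axis=1) > 1).sum())
        preds.append(scores.argmax(axis=1))
    if ties:
        log.info("%d prediction tie(s) broken toward the lowest label index", ties)
    return np.concatenate(preds), ties


def confusion_and_accuracy(preds, labels, subjects=None):
    """3x3 confusion counts (rows = actual), overall and per-subject accuracy."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.size == 0:
        raise ValueError("empty prediction set")
    if preds.shape != labels.shape:
        raise ValueError("preds and labels length mismatch")
    counts = np.zeros((N_CLASS, N_CLASS), dtype=np.int64)
    np.add.at(counts, (labels, preds), 1)
    accuracy = float(np.trace(counts)) / float(counts.sum())
    per_subject = None
    if subjects is not None:
        df = pd.DataFrame({"subject": np.asarray(subjects), "hit": preds == labels})
        per_subject = df.groupby("subject")["hit"].mean()
    return counts, accuracy, per_subject


def welch_t_test(group_a, group_b, q: float = 0.05) -> StatTestResult:
    """Welch's unequal-variance two-tailed t-test.

    Each group is either a 1-D sample array or a ``(mean, sd, n)`` summary
    (sd is the n-1 sample standard deviation).  Degrees of freedom follow
    Welch-Satterthwaite.
    """

    def as_stats(g):
        if isinstance(g, tuple) and len(g) == 3:
            m, s, n = g
        else:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise ValueError("each group needs n >= 2")
            m, s, n = arr.mean(), arr.std(ddof=1), arr.size
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if s < 0:
            raise ValueError("sd must be non-negative")
        return float(m), float(s), int(n)

    m1, s1, n1 = as_stats(group_a)
    m2, s2, n2 = as_stats(group_b)
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    va, vb = s1**2 / n1, s2**2 / n2
    if va + vb == 0:
        df = float(n1 + n2 - 2)
        t, p = 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    return StatTestResult(t=float(t), df=float(df), p=float(p), q=q)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def compare_variants(variants: dict, reference: str, q: float = 0.05) -> pd.DataFrame:
    """Welch-test every variant against ``reference``; BH over the family.

    ``variants`` maps a name to fold accuracies or a ``(mean, sd, n)``
    summary.  Returns a table with both raw and BH-adjusted decisions.
    """
    if reference not in variants:
        raise KeyError(f"unknown reference variant {reference!r}")
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    names = [nm for nm in variants if nm != reference]
    results = {nm: welch_t_test(variants[nm], variants[reference], q=q) for nm in names}
    pvals = np.array([results[nm].p for nm in names])
    rejected = bh_fdr(pvals, q=q)
    p_adj = multipletests(pvals, alpha=q, method="fdr_bh")[1] if names else []
    rows = []
    for nm, rej, padj in zip(names, rejected, p_adj):
        r = results[nm]
        rows.append({"variant": nm, "t": r.t, "df": r.df, "p": r.p,
                     "p_bh": float(padj), "rejected": bool(rej)})
    return pd.DataFrame(rows).set_index("variant")


def run_cross_validation(config: ModelConfig, train_cfg: TrainConfig,
                         epochs: list[EEGEpoch], plan: SplitPlan,
                         augment: AugmentParams | None = None,
                         dtype=np.float64) -> CrossValResult:
    """Train one model per fold and evaluate each on the fixed test subjects.

    Raises on any subject leakage before any training starts.
    """
    augment = augment if augment is not None else AugmentParams()
    have = {ep.subject_id for ep in epochs}
    needed = set(plan.test_subjects) | set(plan.non_test_subjects)
    if not needed <= have:
        raise ValueError(f"plan subjects missing from dataset: {sorted(needed - have)}")
    for i, (tr, va) in enumerate(plan.folds):
        if (tr | va) & plan.test_subjects:
            raise ValueError(f"fold {i} shares subjects with the test set")
    test_eps = epochs_by_subject(epochs, plan.test_subjects)
    x_te, y_te, subj_te = prepare_arrays(test_eps, train_cfg.zscore_scope, dtype)
    folds: list[FoldResults] = []
    states = []
    for i, (tr, va) in enumerate(plan.folds):
        fold_seed = train_cfg.seed + i
        cfg_i = TrainConfig(**{**train_cfg.__dict__, "seed": fold_seed})
        model = build_model(config, seed=fold_seed, dtype=dtype)
        state = train_model(model, epochs_by_subject(epochs, tr),
                            epochs_by_subject(epochs, va), augment, cfg_i)
        preds, _ = predict(model, x_te)
        counts, acc, per_subj = confusion_and_accuracy(preds, y_te, subj_te)
        log.info("fold %d: test accuracy %.3f", i, acc)
        folds.append(FoldResults(i, acc, per_subj, counts, fold_seed))
        states.append(state)
    accs = np.array([f.accuracy for f in folds])
    return CrossValResult(folds=folds, mean_accuracy=float(accs.mean()),
                          sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                          states=states)
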