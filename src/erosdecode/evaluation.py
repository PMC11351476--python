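"""Metrics, confidence intervals, above-chance tests, data-quality ANOVA.

Held-out accuracy and AUROC are averaged over the five cross-validation fold
models; 95% confidence intervals are t-based across the five fold metrics
(df = 4).  Above-chance performance is tested with a one-sided exact binomial
test on the pooled held-out predictions against p = 0.5.  The data-quality
analyses regress test accuracy on a montage quality measure with subject as a
factor, using Type-I (sequential) or Type-II (order-invariant) sums of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Metrics:
    accuracy: float
    auroc: float
    n_test: int
    predictions: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if np.isfinite(self.auroc) and not (0.0 <= self.auroc <= 1.0):
            raise ValueError("AUROC must lie in [0, 1]")


@dataclass
class SubjectSummary:
    fold_accuracy: list[float]
    fold_auroc: list[float]
    mean_accuracy: float
    mean_auroc: float
    ci_accuracy: tuple[float, float]
    ci_auroc: tuple[float, float]
    above_chance_accuracy: bool
    above_chance_auroc: bool
    p_accuracy: float
    p_auroc: float
    n_test: int


def accuracy_score(predicted, labels) -> float:
    predicted = np.asarray(predicted).astype(int)
    labels = np.asarray(labels).astype(int)
    return float(np.mean(predicted == labels))


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a randomly drawn positive trial scores above
    a randomly drawn negative one, with ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)   # mid-ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if len(values) < 2:
        return (np.nan, np.nan)
    se = values.std(ddof=1) / np.sqrt(len(values))
    tq = stats.t.ppf(0.5 + level / 2.0, df=len(values) - 1)
    return (float(mean - tq * se), float(mean + tq * se))


def summarize_subject(fold_metrics: list[Metrics]) -> SubjectSummary:
    """Aggregate the five fold models of one subject/condition.

    Pooled held-out predictions (across folds) feed the one-sided exact
    binomial test against chance; for AUROC the pooled scores feed a
    one-sided Mann-Whitney U test against 0.5.
    """
    if len(fold_metrics) < 2:
        raise ValueError("confidence intervals need at least 2 fold metrics")
    accs = np.array([m.accuracy for m in fold_metrics])
    aucs = np.array([m.auroc for m in fold_metrics])

    p_acc = p_auc = np.nan
    if all(m.predictions is not None for m in fold_metrics):
        preds = np.concatenate([m.predictions for m in fold_metrics])
        labs = np.concatenate([m.labels for m in fold_metrics])
        correct = int(((preds > 0.5).astype(int) == labs).sum())
        p_acc = float(stats.binomtest(correct, len(labs), 0.5,
                                      alternative="greater").pvalue)
        pos, neg = preds[labs == 1], preds[labs == 0]
        if len(pos) and len(neg):
            p_auc = float(stats.mannwhitneyu(pos, neg, alternative="greater").pvalue)
    return SubjectSummary(
        fold_accuracy=accs.tolist(), fold_auroc=aucs.tolist(),
        mean_accuracy=float(accs.mean()), mean_auroc=float(np.nanmean(aucs)),
        ci_accuracy=_t_ci(accs), ci_auroc=_t_ci(aucs),
        above_chance_accuracy=bool(accs.mean() > 0.5),
        above_chance_auroc=bool(np.nanmean(aucs) > 0.5),
        p_accuracy=p_acc, p_auroc=p_auc,
        n_test=fold_metrics[0].n_test)


# ---------------------------------------------------------------------------
# data-quality ANOVA
# ---------------------------------------------------------------------------

def quality_table(rows: list[dict]) -> pd.DataFrame:
    """Rows: subject, montage, viable-voxel counts (total and per hemisphere),
    mean channels per viable voxel, held-out test accuracy."""
    df = pd.DataFrame(rows)
    required = {"subject", "montage", "accuracy"}
    if not required <= set(df.columns):
        raise ValueError(f"quality table must contain {sorted(required)}")
    if ((df["accuracy"] < 0) | (df["accuracy"] > 1)).any():
        raise ValueError("accuracy must lie in [0, 1]")
    return df


def quality_anova(table: pd.DataFrame, quality_measure: str,
                  anova_type: str = "II") -> pd.DataFrame:
    """ANOVA of ``accuracy ~ quality_measure + C(subject)``.

    ``anova_type`` selects Type-I (sequential, quality measure entered first)
    or Type-II (order-invariant) sums of squares.  Raises on rank-deficient
    designs (e.g. a constant quality measure).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if anova_type not in ("I", "II", 1, 2):
        raise ValueError("anova_type must be 'I' or 'II'")
    if table[quality_measure].nunique() < 2:
        raise ValueError(f"rank-deficient design: {quality_measure} is constant")
    model = smf.ols(f"accuracy ~ {quality_measure} + C(subject)", data=table).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix; check factor coding")
    typ = 1 if anova_type in ("I", 1) else 2
    return sm.stats.anova_lm(model, typ=typ)


def quality_pvalue(table: pd.DataFrame, quality_measure: str,
                   anova_type: str = "II") -> float:
    """p-value of the quality measure's F test in the requested ANOVA."""
    tab = quality_anova(table, quality_measure, anova_type)
    return float(tab.loc[quality_measure, "PR(>F)"])


def pairwise_posthoc(values: np.ndarray, groups: np.ndarray):
    """Tukey-HSD-style all-pairs comparison of group means (studentized-range
    criterion), as provided by statsmodels."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    return pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups))


# ---------------------------------------------------------------------------
# experiment-grid aggregation
# ---------------------------------------------------------------------------

def aggregate_experiment(summaries: dict[tuple, list[SubjectSummary]]) -> pd.DataFrame:
    """Cross-subject table: one row per (input, band, paradigm) cell with the
    mean accuracy/AUROC, a t-based 95% CI half-width across subjects, and the
    count of subjects above chance on each metric."""
    rows = []
    for key, subs in summaries.items():
        input_signal, band, paradigm = key
        accs = np.array([s.mean_accuracy for s in subs])
        aucs = np.array([s.mean_auroc for s in subs])
        lo_a, hi_a = _t_ci(accs)
        lo_u, hi_u = _t_ci(aucs)
        rows.append({
            "input_signal": input_signal, "band": band, "paradigm": paradigm,
            "n_subjects": len(subs),
            "accuracy_mean": float(accs.mean()),
            "accuracy_ci_halfwidth": float((hi_a - lo_a) / 2) if np.isfinite(hi_a) else np.nan,
            "auroc_mean": float(aucs.mean()),
            "auroc_ci_halfwidth": float((hi_u - lo_u) / 2) if np.isfinite(hi_u) else np.nan,
            "n_above_chance_accuracy": int(sum(s.mean_accuracy > 0.5 for s in subs)),
            "n_above_chance_auroc": int(sum(s.mean_auroc > 0.5 for s in subs)),
        })
    return pd.DataFrame(rows)
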