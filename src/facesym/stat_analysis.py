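"""Statistics layer: consensus labels, agreement, group tests, ROC, PPV/NPV.

The diagnostic framing throughout: *symmetric* is the positive class, and a
higher degree of symmetry predicts it.  Consensus labels come from a fixed
rater panel with a 70% agreement rule; panel reliability is summarised by
Fleiss' multi-rater kappa (two categories).  Group differences use the
independent two-sample t-test (pooled variance as the headline, Welch
available), diagnostic performance uses ROC analysis with a Youden-index
cut-off, and subjective/objective consistency uses Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .mesh_core import RaterPanel

__all__ = [
    "ConsensusResult",
    "ROCResult",
    "GroupTestResult",
    "consensus_labels",
    "fleiss_kappa",
    "independent_t_test",
    "t_test_from_summary",
    "roc_analysis",
    "predictive_values",
    "pearson_correlation",
]


# ---------------------------------------------------------------------------
# Consensus + agreement
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-subject consensus of a binary rater panel.

    ``labels`` maps subject -> "symmetric" | "asymmetric" | "excluded";
    a subject is excluded iff its majority agreement falls below
    ``min_fraction``.
    """

    labels: dict
    agreement: dict
    retained: list
    min_fraction: float

    def retained_binary(self) -> dict:
        """Retained subjects only, coded 1 = symmetric, 0 = asymmetric."""
        return {s: 1 if self.labels[s] == "symmetric" else 0 for s in self.retained}


def consensus_labels(panel: RaterPanel, min_fraction: float = 0.7) -> ConsensusResult:
    """Majority label where agreement reaches ``min_fraction``, else excluded.

    With 10 raters and the default 0.7, at least 7 of 10 must agree — the
    70% reading of the "more than seven (7/10)" rule.
    """
    if panel.n_subjects == 0:
        raise ValueError("empty rater panel")
    if not 0.5 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0.5, 1]")
    frac_sym = panel.ratings.mean(axis=1)
    agreement = np.maximum(frac_sym, 1.0 - frac_sym)
    labels, agree, retained = {}, {}, []
    for i, subject in enumerate(panel.subjects):
        agree[subject] = float(agreement[i])
        if agreement[i] >= min_fraction - 1e-12:
            labels[subject] = "symmetric" if frac_sym[i] >= 0.5 else "asymmetric"
            retained.append(subject)
        else:
            labels[subject] = "excluded"
    return ConsensusResult(labels, agree, retained, min_fraction)


def fleiss_kappa(panel: RaterPanel) -> float:
    """Fleiss' multi-rater kappa over the two categories.

    (P-bar - Pe-bar) / (1 - Pe-bar) with standard per-subject agreement
    terms.  If every rating falls in one category, chance agreement is 1
    and kappa is undefined; it is reported as 1.0 with a warning.
    """
    if panel.n_raters < 2:
        raise ValueError("Fleiss kappa needs at least 2 raters")
    n_sym = panel.ratings.sum(axis=1)
    table = np.column_stack([panel.n_raters - n_sym, n_sym])  # (subjects, 2 cats)
    p_cat = table.sum(axis=0) / table.sum()
    if (p_cat == 0).any():
        warnings.warn(
            "all ratings fall in a single category; chance agreement is 1 and "
            "kappa is undefined — reporting 1.0",
            stacklevel=2,
        )
        return 1.0
    kappa = float(_sm_fleiss_kappa(table, method="fleiss"))
    if np.isnan(kappa):  # perfect observed agreement edge case
        return 1.0
    return kappa


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Two-sample t-test summary (two-sided)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    variant: str

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _t_df(t_stat, n1, s1, n2, s2, variant):
    if variant == "pooled":
        return float(n1 + n2 - 2)
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    return float((v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1)))


def _degenerate_t(m1, m2):
    """Convention for zero variance in both groups: identical means give
    t = 0, p = 1; distinct means an infinitely significant difference."""
    if np.isclose(m1, m2):
        return 0.0, 1.0
    return float(np.sign(m1 - m2)) * float("inf"), 0.0


def independent_t_test(x, y, variant: str = "pooled") -> GroupTestResult:
    """Independent two-sample t-test on raw data.

    ``variant`` is "pooled" (classic equal-variance test, the SPSS headline
    row) or "welch".
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups: test degenerates
        t, p = _degenerate_t(float(x.mean()), float(y.mean()))
        df = float(len(x) + len(y) - 2)
    return GroupTestResult(
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)), n1=len(x),
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)), n2=len(y),
        t=t, df=df, p=p, variant=variant,
    )


def t_test_from_summary(m1, s1, n1, m2, s2, n2,
                        variant: str = "pooled") -> GroupTestResult:
    """Two-sample t-test from printed summary statistics (mean, SD, n)."""
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                   equal_var=(variant == "pooled"))
    t, p = float(res.statistic), float(res.pvalue)
    df = float(n1 + n2 - 2) if variant == "pooled" else _t_df(t, n1, s1, n2, s2, variant)
    if np.isnan(t):
        t, p = _degenerate_t(float(m1), float(m2))
        df = float(n1 + n2 - 2)
    return GroupTestResult(
        mean1=float(m1), sd1=float(s1), n1=int(n1),
        mean2=float(m2), sd2=float(s2), n2=int(n2),
        t=t, df=df, p=p, variant=variant,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """ROC over all distinct-score thresholds, with a Youden cut-off.

    ``thresholds`` are SPSS-style candidate cut-offs (midpoints between
    consecutive distinct scores, plus below-minimum and above-maximum
    sentinels); a subject tests positive when its score is >= the cut-off.
    ``sensitivity`` is non-increasing and ``specificity`` non-decreasing in
    the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_j: float = field(default=float("nan"))

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def roc_analysis(scores, labels) -> ROCResult:
    """ROC analysis with higher scores predicting the positive class.

    AUC is the trapezoidal area over all distinct-score thresholds —
    equivalently the normalised Mann-Whitney U statistic, with ties given
    half credit.  The reported cut-off maximises Youden's J = sens + spec
    - 1 over midpoint thresholds; ties in J break toward the *higher*
    cut-off.
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    auc = float(roc_auc_score(labels, scores))

    distinct = np.unique(scores)
    mid = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mid, [distinct[-1] + 1.0]])
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    sens = np.array([(pos_scores >= t).mean() for t in thresholds])
    spec = np.array([(neg_scores < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[-1])  # ties -> higher cut-off
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc,
        cutoff=float(thresholds[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# Predictive values and correlation
# ---------------------------------------------------------------------------

def predictive_values(sens: float, spec: float, n_pos: int, n_neg: int):
    """PPV and NPV from operating characteristics and class sizes.

    PPV = sens*n_pos / (sens*n_pos + (1-spec)*n_neg);
    NPV = spec*n_neg / (spec*n_neg + (1-sens)*n_pos).
    """
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty")
    tp = sens * n_pos
    fp = (1.0 - spec) * n_neg
    tn = spec * n_neg
    fn = (1.0 - sens) * n_pos
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return ppv, npv


def pearson_correlation(x, y):
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
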