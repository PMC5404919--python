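"""CSF-biomarker diagnostics: ROC/Youden analysis, ratio markers,
hippocampal occupancy, correlation tables and two-group tests.

A cohort is a pandas DataFrame with one row per subject, a ``subject_id``
column, a ``group`` column taking values ``control``/``case``, analyte
concentrations in pg/ml, cognitive scores in test points, and (optionally)
``hippocampal_volume`` / ``temporal_horn_volume`` in mm³. Missing cells are
NaN and handled pairwise-complete per analysis, so each correlation row may
have its own n.

The ROC curve is built by sweeping a cutoff over midpoints between
consecutive distinct analyte values (plus sentinels at +/-inf); AUC is the
trapezoidal area, equal to the Mann-Whitney U statistic scaled by n1*n2
with ties counted 1/2. The diagnostic cutoff maximises the Youden index
J = sensitivity + specificity - 1; accuracy is (TP+TN)/N at that cutoff.
Because markers can run in either direction (NPTX2 is *low* in cases, tau
is *high*), direction "auto" orients the curve so AUC >= 0.5 and records
the orientation used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

GROUP_CONTROL = "control"
GROUP_CASE = "case"


def validate_cohort(table: pd.DataFrame, require_groups: bool = True) -> pd.DataFrame:
    """Check the cohort frame's minimal contract and return it unchanged."""
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column '{col}'")
    if table["group"].isna().any():
        raise ValueError("cohort table has missing group labels")
    bad = set(table["group"].unique()) - {GROUP_CONTROL, GROUP_CASE}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if require_groups:
        for g in (GROUP_CONTROL, GROUP_CASE):
            if not (table["group"] == g).any():
                raise ValueError(f"cohort table has no '{g}' subjects")
    return table


@dataclass
class RocResult:
    """ROC curve with its AUC and Youden-optimal operating point.

    ``direction`` is ``"high_is_positive"`` if larger values call a case
    (tau-like) or ``"low_is_positive"`` if smaller values do (NPTX2-like).
    ``thresholds`` are in the analyte's units; a subject is called positive
    when its value is beyond the threshold in the direction indicated.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    optimal_cutoff: float
    youden_j: float
    accuracy: float
    n_positive: int
    n_negative: int


def _oriented_roc(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """ROC operating points for 'higher score = positive'.

    Thresholds are midpoints between consecutive distinct pooled values,
    bracketed by -inf/+inf; predicted positive = score > threshold.
    Returned in ascending false-positive-rate order.
    """
    pooled = np.unique(np.concatenate([scores_pos, scores_neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    sens = np.array([(scores_pos > t).mean() for t in thresholds])
    spec = np.array([(scores_neg <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return thresholds, sens, spec, auc


def roc_curve(values, labels, direction: str = "auto") -> RocResult:
    """ROC analysis of one analyte against a binary label.

    Parameters
    ----------
    values : array-like
        Analyte values (finite).
    labels : array-like
        Boolean/0-1 per subject, True/1 marking the positive (case) class.
    direction : {"auto", "high_is_positive", "low_is_positive"}
        "auto" picks the orientation with AUC >= 0.5.
    """
    v = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    pos, neg = v[y], v[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    if direction not in ("auto", "high_is_positive", "low_is_positive"):
        raise ValueError("direction must be auto | high_is_positive | low_is_positive")
    if direction == "auto":
        _, _, _, auc_high = _oriented_roc(pos, neg)
        direction = "high_is_positive" if auc_high >= 0.5 else "low_is_positive"

    if direction == "high_is_positive":
        thr, sens, spec, auc = _oriented_roc(pos, neg)
    else:
        thr_s, sens, spec, auc = _oriented_roc(-pos, -neg)
        thr = -thr_s  # back to original units; positive = value < threshold

    result = RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        direction=direction,
        optimal_cutoff=np.nan,
        youden_j=np.nan,
        accuracy=np.nan,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )
    cutoff, j, acc = youden_cutoff(result)
    result.optimal_cutoff, result.youden_j, result.accuracy = cutoff, j, acc
    return result


def youden_cutoff(roc: RocResult) -> tuple:
    """Cutoff maximising J = sensitivity + specificity - 1, with accuracy.

    Ties in J are broken by higher accuracy, then by the lower cutoff
    (in the analyte's original units), so the result is deterministic.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    n = roc.n_positive + roc.n_negative
    acc = (roc.sensitivity * roc.n_positive + roc.specificity * roc.n_negative) / n
    j_max = j.max()
    tied = np.flatnonzero(j >= j_max - 1e-12)
    tied = tied[acc[tied] >= acc[tied].max() - 1e-12]
    finite_cut = np.where(np.isfinite(roc.thresholds[tied]), roc.thresholds[tied], np.inf)
    best = tied[int(np.argmin(finite_cut))]
    return float(roc.thresholds[best]), float(j[best]), float(acc[best])


def diagnostic_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """Proportion of true results: (TP + TN)/(TP + FP + TN + FN)."""
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("confusion-matrix counts must sum to a positive total")
    return (tp + tn) / total


def roc_from_table(
    table: pd.DataFrame, analyte: str, direction: str = "auto"
) -> RocResult:
    """ROC of one analyte column with ``case`` as the positive class."""
    validate_cohort(table)
    sub = table[["group", analyte]].dropna()
    return roc_curve(
        sub[analyte].to_numpy(), (sub["group"] == GROUP_CASE).to_numpy(), direction
    )


def ratio_biomarker(
    table: pd.DataFrame, numerator: str, denominator: str, name: Optional[str] = None
) -> pd.DataFrame:
    """Append a per-subject ratio analyte (e.g. tau/NPTX2) as a new column.

    A non-positive denominator is a per-record error naming the subject.
    """
    for col in (numerator, denominator):
        if col not in table.columns:
            raise ValueError(f"analyte '{col}' not in table")
    den = table[denominator]
    bad = table.loc[den.notna() & (den <= 0), "subject_id"]
    if len(bad):
        raise ValueError(
            f"non-positive {denominator} for subject(s): {', '.join(map(str, bad))}"
        )
    out = table.copy()
    out[name or f"{numerator}/{denominator}"] = table[numerator] / den
    return out


def hippocampal_occupancy(hippocampal_volume, temporal_horn_volume):
    """Hippocampal occupancy: h / (h + temporal horn), in [0, 1].

    Robust to overall atrophy scale because the ex-vacuo expansion of the
    temporal horn grows as the hippocampus shrinks. Accepts scalars or
    arrays; a zero total volume is an error.
    """
    h = np.asarray(hippocampal_volume, dtype=np.float64)
    t = np.asarray(temporal_horn_volume, dtype=np.float64)
    if np.any(h < 0) or np.any(t < 0):
        raise ValueError("volumes must be non-negative")
    total = h + t
    if np.any(total == 0):
        raise ValueError("hippocampal and temporal-horn volumes are both zero")
    out = h / total
    return float(out) if out.ndim == 0 else out


@dataclass
class CorrelationEntry:
    analyte: str
    score_name: str
    n: int
    pearson_r: float
    p_value: float


def correlate(table: pd.DataFrame, analyte: str, score_name: str) -> CorrelationEntry:
    """Pearson correlation of an analyte with a cognitive score.

    Pairwise-complete: rows missing either value are dropped, so each
    (analyte, score) pair carries its own n. Two-sided p from the
    t-transform with n-2 degrees of freedom.
    """
    for col in (analyte, score_name):
        if col not in table.columns:
            raise ValueError(f"column '{col}' not in table")
    sub = table[[analyte, score_name]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    x = sub[analyte].to_numpy(dtype=np.float64)
    y = sub[score_name].to_numpy(dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined: zero variance in one variable")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationEntry(analyte, score_name, n, float(r), float(p))


def correlation_table(
    table: pd.DataFrame,
    analytes: Sequence[str],
    scores: Sequence[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """All (analyte, score) Pearson correlations as a tidy frame.

    Columns: analyte, score, n, pearson_r, p_value — the structure of a
    published biomarker-vs-cognition correlation table (raw p values; an
    optional Benjamini-Hochberg column is appended when ``fdr=True``).
    """
    rows = []
    for a in analytes:
        for s in scores:
            e = correlate(table, a, s)
            rows.append(
                {"analyte": a, "score": s, "n": e.n, "pearson_r": e.pearson_r, "p_value": e.p_value}
            )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        p = out["p_value"].to_numpy()
        m = p.size
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            q[i] = running
        out["q_bh"] = q
    return out


def group_compare(
    table: pd.DataFrame, analyte: str, welch: bool = False
) -> tuple:
    """Two-tailed two-sample t test of an analyte between control and case.

    Student's pooled-variance by default; ``welch=True`` drops the
    equal-variance assumption. Returns (t, two-sided p). If both groups are
    constant with different values the statistic diverges and (inf, 0.0) is
    returned, flagging the degenerate zero-variance limit.
    """
    validate_cohort(table)
    sub = table[["group", analyte]].dropna()
    a = sub.loc[sub["group"] == GROUP_CONTROL, analyte].to_numpy(dtype=np.float64)
    b = sub.loc[sub["group"] == GROUP_CASE, analyte].to_numpy(dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.std(a) == 0 and np.std(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float(np.inf) * np.sign(a[0] - b[0]), 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple:
    """One-way ANOVA across k groups; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 observations per group")
    f, p = scipy.stats.f_oneway(*arrays)
    return float(f), float(p)
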