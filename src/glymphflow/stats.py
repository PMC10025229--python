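"""Group comparisons, ROC diagnostics, rank correlations and severity classes.

Implements the statistical layer of the analysis: two-sided Mann-Whitney
U-tests (exact for small untied samples, normal approximation with tie and
continuity corrections otherwise), Pearson chi-square on 2x2 tables, ROC
analysis with a Youden-index operating point, pairwise-complete Spearman
correlation matrices with qualitative strength categories, and the clinical
severity cutoffs for OSA (AHI 5 / 30 events/h) and nocturnal hypoxemia
(LSaO2 80 / 90 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationMatrix",
    "RocResult",
    "Subject",
    "chi_square_2x2",
    "mann_whitney",
    "roc_analysis",
    "severity_grouping",
    "spearman_matrix",
]


@dataclass(frozen=True)
class Subject:
    """Clinical record of one participant."""

    subject_id: str
    group: str  # NC | OSA_pre | OSA_post
    AHI: float | None = None  # apnea-hypopnea index, events/h
    ODI: float | None = None  # oxygen desaturation index, events/h
    LSaO2: float | None = None  # lowest oxygen saturation, %
    BMI: float | None = None  # kg/m^2
    MMSE: float | None = None
    MoCA: float | None = None
    PSQI: float | None = None
    ESS: float | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("NC", "OSA_pre", "OSA_post"):
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("AHI", "ODI"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.LSaO2 is not None and not 0 <= self.LSaO2 <= 100:
            raise ValueError("LSaO2 must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def mann_whitney(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test.

    ``mode='auto'`` uses the exact null distribution when the pooled sample
    has at most 20 observations and no ties, otherwise the normal
    approximation with tie and continuity corrections.  Returns ``(U, p)``
    where U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test (df = 1, no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """ROC diagnostic accuracy with a Youden-optimal operating point."""

    auroc: float
    sensitivity: float
    specificity: float
    threshold: float
    p_value: float  # two-sided, vs AUROC = 0.5 (Mann-Whitney on the scores)
    direction: str  # 'greater' if higher scores indicate the positive class
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray, direction: str = "auto"
) -> RocResult:
    """ROC curve, AUROC and Youden-index operating point.

    AUROC is computed by the trapezoidal rule over all score thresholds.
    With ``direction='auto'`` the orientation giving AUROC >= 0.5 is chosen;
    ``'greater'``/``'less'`` fix it.  The operating point maximises Youden's
    J = sensitivity + specificity - 1, ties resolved toward higher
    specificity.  The p-value against chance discrimination is the two-sided
    Mann-Whitney p between the scores of the two classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def _curve(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        order = np.argsort(-s, kind="mergesort")
        sorted_scores = s[order]
        sorted_labels = labels[order]
        distinct = np.nonzero(np.diff(sorted_scores))[0]
        idx = np.r_[distinct, sorted_labels.size - 1]
        tps = np.cumsum(sorted_labels)[idx]
        fps = (idx + 1) - tps
        tpr = np.r_[0.0, tps / n_pos]
        fpr = np.r_[0.0, fps / n_neg]
        thr = np.r_[np.inf, sorted_scores[idx]]
        return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))

    fpr, tpr, thr, auc = _curve(scores)
    used = "greater"
    if direction == "less" or (direction == "auto" and auc < 0.5):
        fpr, tpr, thr, auc = _curve(-scores)
        thr = -thr
        used = "less"
    elif direction not in ("auto", "greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")

    j = tpr - fpr
    best = max(range(len(j)), key=lambda i: (round(j[i], 12), -fpr[i]))
    _, p = mann_whitney(scores[labels], scores[~labels], mode="asymptotic")
    return RocResult(
        auroc=float(auc),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thr[best]),
        p_value=p,
        direction=used,
        fpr=fpr,
        tpr=tpr,
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

DEFAULT_STRENGTH_THRESHOLDS = {"strong": 0.6, "moderate": 0.4, "weak": 0.2}


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with p-values and strength categories."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    strength: pd.DataFrame


def _strength_category(r: float, thresholds: dict[str, float]) -> str:
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a >= thresholds["strong"]:
        return "strong"
    if a >= thresholds["moderate"]:
        return "moderate"
    if a >= thresholds["weak"]:
        return "weak"
    return "negligible"


def spearman_matrix(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    strength_thresholds: dict[str, float] | None = None,
    bh_correction: bool = False,
) -> CorrelationMatrix:
    """Spearman correlation matrix with pairwise-complete missing handling.

    Rho uses midranks for ties; p-values come from the t-approximation.  A
    constant variable yields NaN with a warning.  ``bh_correction`` applies
    Benjamini-Hochberg to the off-diagonal p-values.
    """
    thresholds = strength_thresholds or DEFAULT_STRENGTH_THRESHOLDS
    cols = variables or list(table.columns)
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({cols[i]}, {cols[j]})"
                )
            a, b = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant variable in pair ({cols[i]}, {cols[j]}); rho undefined",
                    RuntimeWarning, stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(a, b)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    if bh_correction:
        iu = np.triu_indices(k, 1)
        pvals = pmat[iu]
        ok = ~np.isnan(pvals)
        if ok.any():
            adj = pvals.copy()
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            pmat[iu] = adj
            pmat.T[iu] = adj
    strength = np.vectorize(lambda r: _strength_category(r, thresholds))(rho)
    return CorrelationMatrix(
        variables=cols,
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pmat, index=cols, columns=cols),
        strength=pd.DataFrame(strength, index=cols, columns=cols),
    )


def plot_correlation_heatmap(corr: CorrelationMatrix, path: str) -> None:
    """Render the Spearman matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(corr.variables),) * 2)
    im = ax.imshow(corr.rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.variables)), corr.variables, rotation=90)
    ax.set_yticks(range(len(corr.variables)), corr.variables)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Clinical severity grouping
# ---------------------------------------------------------------------------

def severity_grouping(subject: Subject) -> tuple[str | None, str | None]:
    """OSA severity and hypoxemia class from AHI and LSaO2.

    Cutoffs: AHI < 5 no OSA; 5 <= AHI < 30 mild-moderate; AHI >= 30 severe.
    LSaO2 >= 90 no hypoxemia; 80 <= LSaO2 < 90 mild; LSaO2 < 80 severe.
    Missing values yield ``None`` with a warning.
    """
    osa_class: str | None
    hyp_class: str | None
    if subject.AHI is None:
        warnings.warn(f"{subject.subject_id}: AHI missing, OSA class undefined",
                      RuntimeWarning, stacklevel=2)
        osa_class = None
    elif subject.AHI < 5:
        osa_class = "no_OSA"
    elif subject.AHI < 30:
        osa_class = "mild_moderate_OSA"
    else:
        osa_class = "severe_OSA"
    if subject.LSaO2 is None:
        warnings.warn(f"{subject.subject_id}: LSaO2 missing, hypoxemia class undefined",
                      RuntimeWarning, stacklevel=2)
        hyp_class = None
    elif subject.LSaO2 < 80:
        hyp_class = "severe_hypoxemia"
    elif subject.LSaO2 < 90:
        hyp_class = "mild_hypoxemia"
    else:
        hyp_class = "no_hypoxemia"
    return osa_class, hyp_class
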