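"""Evaluation statistics for three-class breath-sound discrimination.

Everything derives from the 3x3 confusion matrix (rows = gold standard,
columns = prediction, class order crackle / wheeze / normal): per-class
one-vs-rest sensitivity, precision, specificity and F1, the macro mean
over the two adventitious classes, and overall accuracy. Rater-agreement
statistics — Cohen's (weighted) kappa with its asymptotic 95% CI,
Kendall's coefficient of concordance W with mid-rank tie correction, and
the Pearson chi-square test — complete the suite.

Percentages are kept at full precision internally; ``round1`` applies
the half-up one-decimal rounding used in reports. Metrics whose
denominator vanishes are ``None`` (a distinct undefined marker), never
silently zero.
"""

from __future__ import annotations

import dataclasses
import decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

CLASS_ORDER = ("crackle", "wheeze", "normal")

#: Default ordinal embedding for nominal labels in Kendall's W. The order
#: is arbitrary (nominal data); it is a config parameter and reports state
#: which embedding was used.
DEFAULT_CATEGORY_ORDER = ("normal", "crackle", "wheeze")


def round1(x: float | None) -> float | None:
    """Half-up rounding to one decimal, applied only at reporting time.

    Works on the shortest decimal representation of the float, so a value
    like (94.1 + 83.0) / 2 — stored as 88.549999... — rounds as 88.55.
    """
    if x is None:
        return None
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix3:
    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a 3x3 non-negative integer matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics as percentages; None marks an undefined value."""

    sensitivity: float | None
    precision: float | None
    specificity: float | None
    f1: float | None


def _align(gs, pred) -> tuple[pd.Series, pd.Series]:
    gs = pd.Series(gs).astype(str)
    pred = pd.Series(pred).astype(str)
    gs_ids, pred_ids = set(gs.index), set(pred.index)
    if gs_ids != pred_ids:
        only_gs = sorted(gs_ids - pred_ids)
        only_pred = sorted(pred_ids - gs_ids)
        raise ValueError(
            f"label tables cover different recordings; only in gold standard: "
            f"{only_gs}; only in predictions: {only_pred}"
        )
    pred = pred.reindex(gs.index)
    return gs, pred


def confusion(gs, pred, class_order: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix3:
    """3x3 confusion matrix from two recording_id -> label mappings."""
    gs, pred = _align(gs, pred)
    bad = set(gs) | set(pred)
    if not bad <= set(class_order):
        raise ValueError(f"labels outside {class_order}: {sorted(bad - set(class_order))}")
    counts = _sk_confusion(gs, pred, labels=list(class_order))
    return ConfusionMatrix3(counts, class_order)


def class_metrics(cm: ConfusionMatrix3, target_class: str) -> ClassMetrics:
    """One-vs-rest reduction for a single class, in percent."""
    c = cm.class_order.index(target_class)
    m = cm.counts
    tp = int(m[c, c])
    fn = int(m[c].sum()) - tp
    fp = int(m[:, c].sum()) - tp
    tn = cm.total - tp - fn - fp
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    prec = 100.0 * tp / (tp + fp) if tp + fp else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    f1 = f1_score(sens, prec)
    return ClassMetrics(sens, prec, spec, f1)


def f1_score(sensitivity: float | None, precision: float | None) -> float | None:
    """Harmonic mean of sensitivity and precision (percent scale)."""
    if sensitivity is None or precision is None:
        return None
    if sensitivity + precision == 0:
        return None
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def macro_mean(crackle: ClassMetrics, wheeze: ClassMetrics) -> ClassMetrics:
    """Arithmetic mean over the two adventitious classes only.

    An undefined component in either input propagates as undefined.
    """
    def mean(a, b):
        return None if a is None or b is None else (a + b) / 2.0

    return ClassMetrics(
        mean(crackle.sensitivity, wheeze.sensitivity),
        mean(crackle.precision, wheeze.precision),
        mean(crackle.specificity, wheeze.specificity),
        mean(crackle.f1, wheeze.f1),
    )


def accuracy(cm: ConfusionMatrix3) -> float:
    """Percent of recordings classified identically to the gold standard."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


@dataclasses.dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    ci_low: float | None
    ci_high: float | None
    weighting: str


def cohens_kappa(
    a,
    b,
    weighting: str = "none",
    category_order: tuple[str, ...] = CLASS_ORDER,
) -> KappaResult:
    """Cohen's kappa between two raters with an asymptotic 95% CI.

    ``weighting`` is one of none / linear / quadratic; the category order
    fixes the distance between categories for the weighted variants.
    Returns an undefined marker (None fields) when expected agreement is
    1 (both raters constant and equal).
    """
    if weighting not in ("none", "linear", "quadratic"):
        raise ValueError(f"unknown weighting {weighting!r}")
    a, b = _align(a, b)
    observed = set(a) | set(b)
    if not observed <= set(category_order):
        raise ValueError(f"labels outside category order: {sorted(observed - set(category_order))}")
    if len(observed) < 2:
        return KappaResult(None, None, None, weighting)
    cats = list(category_order)
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).to_numpy()
    res = _sm_kappa(table, wt=None if weighting == "none" else weighting)
    if not np.isfinite(res.kappa):
        return KappaResult(None, None, None, weighting)
    return KappaResult(float(res.kappa), float(res.kappa_low),
                       float(res.kappa_upp), weighting)


def kendalls_w(
    ratings: pd.DataFrame,
    category_order: tuple[str, ...] = DEFAULT_CATEGORY_ORDER,
) -> float | None:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    ``ratings``: raters x subjects frame of labels (or numeric scores).
    Labels are embedded ordinally via ``category_order``. W = 12 S /
    (m^2 (n^3 - n) - m T) where S is the sum of squared deviations of
    subject rank sums and T the tie correction. Returns None when every
    rater gives every subject the same rating (zero variance).
    """
    m, n = ratings.shape
    if m < 2 or n < 2:
        raise ValueError("Kendall's W needs at least 2 raters and 2 subjects")
    values = ratings.to_numpy()
    if values.dtype == object or values.dtype.kind in "US":
        index = {cat: i for i, cat in enumerate(category_order)}
        try:
            values = np.vectorize(index.__getitem__)(values).astype(float)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in category order") from exc
    ranks = np.vstack([stats.rankdata(row) for row in values])  # mid-ranks
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    t = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        t += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * t
    if denom <= 0:
        return None
    return 12.0 * s / denom


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, degrees of freedom, upper-tail p). Requires all
    expected counts to be positive (no zero marginals).
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires non-zero row and column marginals")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def evaluation_report(
    gs,
    pred,
    kappa_weighting: str = "none",
    category_order: tuple[str, ...] = CLASS_ORDER,
) -> dict:
    """Full metric tree for one gold-standard / prediction pair.

    Reported percentages are rounded half-up to one decimal; the raw
    confusion matrix is included so full precision can be recovered.
    """
    cm = confusion(gs, pred, category_order)
    per_class = {cls: class_metrics(cm, cls) for cls in category_order}
    mean_adv = macro_mean(per_class["crackle"], per_class["wheeze"])

    def as_dict(m: ClassMetrics) -> dict:
        return {"sensitivity": round1(m.sensitivity), "precision": round1(m.precision),
                "specificity": round1(m.specificity), "f1": round1(m.f1)}

    kappa = cohens_kappa(gs, pred, kappa_weighting, category_order)
    return {
        "n": cm.total,
        "confusion_matrix": cm.counts.tolist(),
        "class_order": list(cm.class_order),
        "accuracy": round1(accuracy(cm)),
        "per_class": {cls: as_dict(m) for cls, m in per_class.items()},
        "mean_adventitious": as_dict(mean_adv),
        "kappa": {"value": None if kappa.kappa is None else round(kappa.kappa, 3),
                  "ci95": None if kappa.ci_low is None else
                  [round(kappa.ci_low, 3), round(kappa.ci_high, 3)],
                  "weighting": kappa.weighting},
    }


def report_table(report: dict) -> pd.DataFrame:
    """Flat per-class CSV layout (rows: classes + mean; metric columns)."""
    rows = []
    for cls in report["class_order"]:
        rows.append({"group": cls, **report["per_class"][cls]})
    rows.append({"group": "mean_adventitious", **report["mean_adventitious"]})
    return pd.DataFrame(rows, columns=["group", "sensitivity", "precision",
                                       "specificity", "f1"])
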