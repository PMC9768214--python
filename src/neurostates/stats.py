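"""Group statistics: two-sample t-tests, Cohen's d, ROI aggregation, and
subjective-scale mental-state labeling.

The study design compares two independent groups of subjects per contrast
(resting vs fatigue, attentive vs inattentive, positive vs negative) on
range-averaged small-world parameters, reporting the t statistic, the
two-sided p-value, and Cohen's d as the effect size. Mental-state labels
come from a six-indicator subjective scale (five ordinal grades each)
matched against a fixed rule table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .montage import LEFT_ROI, RIGHT_ROI, LOBES, MontageSpec

__all__ = [
    "GRADES",
    "SubjectiveScaleVector",
    "ComparisonResult",
    "two_sample_ttest",
    "cohens_d",
    "roi_aggregate",
    "label_state",
    "compare_conditions",
    "compare_table",
    "compare_scores",
    "GLOBAL_METRICS",
]

logger = logging.getLogger(__name__)

#: Five-level ordinal grades of every subjective indicator, low to high.
GRADES = ("very_low", "low", "medium", "high", "very_high")
_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}

#: Global small-world parameters compared across conditions.
GLOBAL_METRICS = ("sigma", "gamma", "lambda", "E_g", "E_loc")


@dataclass(frozen=True)
class SubjectiveScaleVector:
    """One subjective rating: six indicators, each a five-level grade."""

    effort: str
    temporal_demand: str
    performance: str
    fatigue_degree: str
    arousal: str
    valence: str

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value not in GRADES:
                raise ValueError(
                    f"indicator {name!r} has malformed grade {value!r}; "
                    f"expected one of {GRADES}"
                )


# Rule table mapping indicator patterns to states, evaluated in order;
# None = unlimited ("/"), ("eq", g) = exact grade, ("ge", g) = at least g.
_STATE_RULES: tuple[tuple[str, dict[str, tuple[str, str]]], ...] = (
    ("attentive", {
        "temporal_demand": ("eq", "medium"),
        "arousal": ("ge", "medium"),
        "valence": ("eq", "medium"),
    }),
    ("inattentive", {
        "effort": ("eq", "low"),
        "temporal_demand": ("eq", "low"),
        "arousal": ("eq", "low"),
        "valence": ("eq", "low"),
    }),
    ("fatigue", {
        "fatigue_degree": ("eq", "high"),
        "arousal": ("eq", "low"),
        "valence": ("eq", "medium"),
    }),
    ("positive", {
        "performance": ("eq", "high"),
        "arousal": ("ge", "medium"),
        "valence": ("eq", "high"),
    }),
    ("negative", {
        "performance": ("eq", "low"),
        "arousal": ("ge", "medium"),
        "valence": ("eq", "low"),
    }),
)


def _matches(scale: SubjectiveScaleVector, rule: dict[str, tuple[str, str]]) -> bool:
    for indicator, (op, grade) in rule.items():
        value = getattr(scale, indicator)
        if op == "eq" and value != grade:
            return False
        if op == "ge" and _GRADE_RANK[value] < _GRADE_RANK[grade]:
            return False
    return True


def label_state(scale: SubjectiveScaleVector) -> str:
    """Mental-state label of a subjective rating, or ``"unclassified"``.

    Rules are evaluated in fixed order (attentive, inattentive, fatigue,
    positive, negative) and the first match wins; a multi-match is logged
    at debug level. Unlimited indicators match any grade and ">= medium"
    is an inclusive ordinal threshold.
    """
    matches = [state for state, rule in _STATE_RULES if _matches(scale, rule)]
    if not matches:
        return "unclassified"
    if len(matches) > 1:
        logger.debug("scale %s matches multiple states %s; first wins", scale, matches)
    return matches[0]


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison: means, t, two-sided p, and Cohen's d."""

    metric_name: str
    group_means: tuple[float, float]
    t: float
    p: float
    d: float
    n: tuple[int, int]


def _validate_groups(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 observations, got {a.size} and {b.size}"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups contain non-finite values")
    return a, b


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return float(
        np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
    )


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    Pooled-variance Student's t by default (df = n_a + n_b - 2); Welch's
    unequal-variance variant behind the ``welch`` flag. Two groups with
    zero variance and equal means give (t=0, p=1); zero variance with
    unequal means is rejected (the statistic is undefined).
    """
    a, b = _validate_groups(a, b)
    if _pooled_sd(a, b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError(
            "zero within-group variance with unequal means: t undefined"
        )
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled standard deviation."""
    a, b = _validate_groups(a, b)
    sd = _pooled_sd(a, b)
    if sd == 0.0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation: d undefined")
    return float((a.mean() - b.mean()) / sd)


def roi_aggregate(
    nodal_values: np.ndarray,
    montage: MontageSpec,
    grouping: str | dict[str, tuple[str, ...]] = "lobe",
) -> dict[str, float]:
    """Mean nodal value over each region of interest.

    ``grouping`` may be ``"lobe"`` (the five lobes), ``"hemisphere"``
    (the hemispheric left/right fronto-central-temporal ROIs), or a custom
    mapping of ROI name to channel labels.
    """
    nodal_values = np.asarray(nodal_values, dtype=np.float64)
    if nodal_values.shape != (montage.n_channels,):
        raise ValueError(
            f"expected one value per montage channel "
            f"({montage.n_channels}), got shape {nodal_values.shape}"
        )
    if grouping == "lobe":
        rois = {lobe: montage.channels_in_lobe(lobe) for lobe in LOBES}
    elif grouping == "hemisphere":
        rois = {"left": LEFT_ROI, "right": RIGHT_ROI}
    elif isinstance(grouping, dict):
        rois = grouping
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = {}
    for roi, channels in rois.items():
        for ch in channels:
            if ch not in montage.channel_names:
                raise KeyError(
                    f"ROI {roi!r} requests channel {ch!r} absent from montage"
                )
        idx = [montage.index_of(ch) for ch in channels]
        out[roi] = float(nodal_values[idx].mean())
    return out


def compare_conditions(
    cohort_metrics: pd.DataFrame,
    metric: str,
    conditions: tuple[str, str] | None = None,
    welch: bool = False,
) -> ComparisonResult:
    """Compare one metric between two conditions of a per-subject table.

    ``cohort_metrics`` is tidy: one row per subject (x band if present),
    with a ``condition`` column and one column per metric.
    """
    if metric not in cohort_metrics.columns:
        raise KeyError(
            f"metric {metric!r} not in table columns "
            f"{list(cohort_metrics.columns)}"
        )
    if conditions is None:
        levels = tuple(pd.unique(cohort_metrics["condition"]))
        if len(levels) != 2:
            raise ValueError(
                f"table has {len(levels)} condition levels {levels}; pass "
                "`conditions` explicitly"
            )
        conditions = levels  # type: ignore[assignment]
    a = cohort_metrics.loc[cohort_metrics["condition"] == conditions[0], metric].to_numpy()
    b = cohort_metrics.loc[cohort_metrics["condition"] == conditions[1], metric].to_numpy()
    t, p = two_sample_ttest(a, b, welch=welch)
    d = cohens_d(a, b)
    return ComparisonResult(
        metric_name=metric,
        group_means=(float(a.mean()), float(b.mean())),
        t=t, p=p, d=d,
        n=(a.size, b.size),
    )


def compare_table(
    cohort_metrics: pd.DataFrame,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
    conditions: tuple[str, str] | None = None,
    welch: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Tidy comparison table over several metrics.

    No multiple-testing correction by default (each metric's raw p is
    reported); ``bonferroni=True`` multiplies p by the number of metrics.
    """
    rows = []
    for metric in metrics:
        r = compare_conditions(cohort_metrics, metric, conditions, welch=welch)
        p = min(1.0, r.p * len(metrics)) if bonferroni else r.p
        rows.append(
            {
                "metric": r.metric_name,
                "mean_a": r.group_means[0],
                "mean_b": r.group_means[1],
                "t": r.t,
                "p": p,
                "cohens_d": r.d,
                "n_a": r.n[0],
                "n_b": r.n[1],
            }
        )
    return pd.DataFrame(rows)


def compare_scores(before: np.ndarray, after: np.ndarray) -> ComparisonResult:
    """Two-group comparison of scalar behavioral scores (e.g. game points)."""
    before, after = _validate_groups(before, after)
    t, p = two_sample_ttest(after, before)
    d = cohens_d(after, before)
    return ComparisonResult(
        metric_name="score",
        group_means=(float(after.mean()), float(before.mean())),
        t=t, p=p, d=d,
        n=(after.size, before.size),
    )
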