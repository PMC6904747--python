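"""Segmentation evaluation and screening statistics.

Pixel-level scoring compares an automatically extracted colony mask with a
manual reference mask using the four-way pixel confusion (TP/FP/FN/TN) and
the three derived ratios: undetected = FN/total, over-detected = FP/total,
accurate = (TP+TN)/total.

Group comparisons follow the original screening readouts: the sampling unit
is the per-colony mean speed (pixelwise samples are for violin plots only,
never for tests — that would be pseudo-replication).  Two groups are
compared by an unpaired two-tailed Mann-Whitney U-test (exact distribution
for small samples); three or more by Kruskal-Wallis with Dunn's post-hoc
z-tests against a designated control, Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import ColonyMask

__all__ = [
    "PixelConfusion",
    "GroupComparison",
    "pixel_confusion",
    "compare_two_groups",
    "compare_multi_groups",
]

EXACT_MAX_N = 10    # exact Mann-Whitney distribution up to this group size


@dataclass
class PixelConfusion:
    """Four-way pixel counts plus the standard derived ratios."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def undetected_frac(self) -> float:
        return self.fn / self.total

    @property
    def overdetected_frac(self) -> float:
        return self.fp / self.total

    @property
    def accurate_frac(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass
class GroupComparison:
    """Result record for a two- or multi-group nonparametric comparison."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    posthoc: Optional[pd.DataFrame] = None
    adjustment: Optional[str] = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.group_sizes,
            "notes": self.notes,
        }
        if self.adjustment is not None:
            d["adjustment"] = self.adjustment
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def pixel_confusion(predicted: ColonyMask | np.ndarray,
                    manual: np.ndarray) -> PixelConfusion:
    """Pixel-level confusion of a predicted colony mask vs a manual mask."""
    pred = predicted.pixels if isinstance(predicted, ColonyMask) else \
        np.asarray(predicted, bool)
    man = np.asarray(manual, bool)
    if pred.shape != man.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {man.shape}")
    tp = int(np.sum(pred & man))
    fp = int(np.sum(pred & ~man))
    fn = int(np.sum(~pred & man))
    tn = int(np.sum(~pred & ~man))
    return PixelConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Unpaired two-tailed Mann-Whitney U-test on per-colony mean speeds.

    The exact null distribution is used when both groups have at most
    ``EXACT_MAX_N`` values and no ties; otherwise the normal approximation
    with midranks, with a note recorded (the exact method assumes
    continuity).  With 5 vs 5 colonies and complete separation the exact
    two-tailed p is 2/C(10,5) = 0.0079.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 per-colony values")
    notes: list[str] = []
    ties = _has_ties(a, b)
    if ties:
        notes.append("ties present: midranks with normal approximation")
    exact = (not ties) and max(len(a), len(b)) <= EXACT_MAX_N
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return GroupComparison(
        test_name="mann-whitney-u-" + ("exact" if exact else "asymptotic"),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes={labels[0]: len(a), labels[1]: len(b)},
        notes=notes,
    )


def _dunn_vs_control(groups: Mapping[str, np.ndarray], control: str,
                     adjustment: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z-tests against the control on pooled midranks."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for g in labels:
        if g == control:
            continue
        se = np.sqrt(var_base * (1.0 / sizes[g] + 1.0 / sizes[control]))
        z = (mean_ranks[g] - mean_ranks[control]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"comparison": f"{g} vs {control}", "z": z,
                     "p_unadjusted": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_unadjusted"], method=adjustment)[1]
        # an adjusted p can never undercut its raw p
        df["p_adjusted"] = np.maximum(df["p_adjusted"], df["p_unadjusted"])
    return df


def compare_multi_groups(groups: Mapping[str, Sequence[float]],
                         control: str | None = None,
                         adjustment: str = "holm") -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) + Dunn's post-hoc vs a control.

    ``control`` defaults to the first group in mapping order.  Three or
    more groups are required; with two, use :func:`compare_two_groups`.
    All-identical data (H undefined, every observation tied) is reported
    as H = 0, p = 1 under the tie-corrected convention.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use compare_two_groups for two")
    arrs = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrs.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 values")
    if control is None:
        control = next(iter(arrs))
    if control not in arrs:
        raise ValueError(f"control label {control!r} not among groups")

    notes: list[str] = []
    pooled = np.concatenate(list(arrs.values()))
    if np.all(pooled == pooled[0]):
        notes.append("all observations identical: H = 0, p = 1 by convention")
        H, p = 0.0, 1.0
        posthoc = _dunn_vs_control(arrs, control, adjustment)
    else:
        H, p = sps.kruskal(*arrs.values())
        posthoc = _dunn_vs_control(arrs, control, adjustment)
    return GroupComparison(
        test_name="kruskal-wallis+dunn",
        statistic=float(H),
        p_value=float(p),
        group_sizes={k: len(v) for k, v in arrs.items()},
        posthoc=posthoc,
        adjustment=adjustment,
        notes=notes,
    )
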