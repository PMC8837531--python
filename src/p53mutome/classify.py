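"""Activity and frequency classification of TP53 missense variants.

A variant's yeast transactivation (mean over 8 response elements, % of
wild-type) is binned into four half-open activity classes:

    [0, 10)   LOF            complete loss of transactivation
    [10, 20)  PARTIAL_LOW    partial LOF, low residual activity
    [20, 50)  PARTIAL_HIGH   partial LOF, high residual activity
    [50, inf) RETAINED       wild-type-like activity

and its share of database occurrences into five frequency classes
(HOTSPOT = the 10 largest counts; then VERY_FREQUENT, FREQUENT, RARE,
UNIQUE by configurable share boundaries). Prevalence summaries can be
taken at the variant level (each variant once) or the tumor level (each
variant weighted by its occurrence count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ACTIVITY_COLUMNS, PREDICTOR_COLUMNS
from .types import EmptyInputError

ACTIVITY_CLASSES = ("LOF", "PARTIAL_LOW", "PARTIAL_HIGH", "RETAINED")
FREQUENCY_CLASSES = ("HOTSPOT", "VERY_FREQUENT", "FREQUENT", "RARE", "UNIQUE")
RFS_CLASSES = ("RFS_LOF", "RFS_INTERMEDIATE", "RFS_WTLIKE")


class FilterEmptyError(ValueError):
    """A summary filter removed every variant."""


@dataclass
class ClassifierConfig:
    """Bin edges and class boundaries.

    activity_edges are the upper edges of LOF, PARTIAL_LOW and
    PARTIAL_HIGH (lower edge inclusive, upper exclusive; activity of
    exactly 50 is RETAINED). Frequency shares are fractions of all
    database occurrences; only the 0.05% FREQUENT boundary is anchored
    in the published analysis, the 0.5% VERY_FREQUENT boundary is a
    default assumption.
    """

    activity_edges: Sequence[float] = (10.0, 20.0, 50.0)
    hotspot_n: int = 10
    very_frequent_share: float = 0.005
    frequent_share: float = 0.0005
    rfs_bounds: Sequence[float] = (-2.0, 0.0)
    cooperativity_codons: Sequence[int] = (180, 181)

    def __post_init__(self):
        e = tuple(float(x) for x in self.activity_edges)
        if len(e) != 3 or not (0 < e[0] < e[1] < e[2]):
            raise ValueError("activity_edges must be three increasing positives")
        self.activity_edges = e
        if not (0 < self.frequent_share < self.very_frequent_share < 1):
            raise ValueError("need 0 < frequent_share < very_frequent_share < 1")

    def to_dict(self):
        return asdict(self)


DEFAULT_CONFIG = ClassifierConfig()


def mean_activity(re_activity) -> float:
    """Arithmetic mean of the 8 per-response-element activities (%WT)."""
    vals = np.asarray(re_activity, dtype=float)
    if vals.shape != (8,):
        raise ValueError(f"expected 8 response-element values, got {vals.shape}")
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("activities must be finite and non-negative")
    return float(vals.mean())


def classify_activity(activity: float, config: ClassifierConfig = DEFAULT_CONFIG) -> str:
    """Bin a mean activity (%WT) into one of the four activity classes."""
    if not np.isfinite(activity) or activity < 0:
        raise ValueError(f"activity must be finite and >= 0, got {activity}")
    lof, low, high = config.activity_edges
    if activity < lof:
        return "LOF"
    if activity < low:
        return "PARTIAL_LOW"
    if activity < high:
        return "PARTIAL_HIGH"
    return "RETAINED"


def classify_rfs(rfs: float, config: ClassifierConfig = DEFAULT_CONFIG) -> Optional[str]:
    """Bin a relative fitness score; open interval marks intermediates.

    Higher RFS means stronger loss of antiproliferative activity:
    rfs >= upper bound -> RFS_LOF, lower < rfs < upper ->
    RFS_INTERMEDIATE, rfs <= lower bound -> RFS_WTLIKE. NaN maps to None
    (RFS is an optional annotation).
    """
    if rfs is None or (isinstance(rfs, float) and np.isnan(rfs)):
        return None
    lower, upper = config.rfs_bounds
    if rfs >= upper:
        return "RFS_LOF"
    if rfs > lower:
        return "RFS_INTERMEDIATE"
    return "RFS_WTLIKE"


def assign_frequency_classes(variants: pd.DataFrame,
                             config: ClassifierConfig = DEFAULT_CONFIG) -> pd.Series:
    """Assign HOTSPOT .. UNIQUE frequency classes per variant.

    HOTSPOT is the fixed set of the `hotspot_n` largest counts (ties
    broken by larger share -- identical for equal totals -- then by
    lexicographic protein change). Among the rest, shares of total
    occurrences decide VERY_FREQUENT/FREQUENT, single occurrences are
    UNIQUE, and remaining low-share multi-occurrence variants are RARE.
    """
    if variants.empty:
        raise EmptyInputError("empty variant table")
    counts = variants["count"].to_numpy(float)
    total = counts.sum()
    if total <= 0:
        raise EmptyInputError("total occurrence count is zero")
    share = counts / total

    order = np.lexsort((variants["protein_change"].to_numpy(), -counts))
    hotspots = set(order[: config.hotspot_n])

    labels = np.empty(len(variants), dtype=object)
    for i in range(len(variants)):
        if i in hotspots:
            labels[i] = "HOTSPOT"
        elif counts[i] <= 1:
            labels[i] = "UNIQUE"
        elif share[i] >= config.very_frequent_share:
            labels[i] = "VERY_FREQUENT"
        elif share[i] >= config.frequent_share:
            labels[i] = "FREQUENT"
        else:
            labels[i] = "RARE"
    return pd.Series(labels, index=variants.index, name="frequency_class")


def classify_variants(variants: pd.DataFrame,
                      config: ClassifierConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Full per-variant classification table.

    Adds ``mean_activity`` (recomputed from the 8 RE columns when
    missing), ``activity_class``, ``frequency_class``,
    ``is_cooperativity`` (codon at the intermolecular salt bridge),
    ``is_damaging`` (any of the three pathogenicity predictors) and
    ``rfs_class``.
    """
    out = variants.copy()
    if "mean_activity" not in out.columns:
        out["mean_activity"] = out[list(ACTIVITY_COLUMNS)].mean(axis=1)
    out["activity_class"] = [classify_activity(a, config)
                             for a in out["mean_activity"]]
    out["frequency_class"] = assign_frequency_classes(out, config)
    out["is_cooperativity"] = out["codon"].isin(config.cooperativity_codons)
    pred = [c for c in PREDICTOR_COLUMNS if c in out.columns]
    out["is_damaging"] = out[pred].any(axis=1) if pred else False
    if "rfs" in out.columns:
        out["rfs_class"] = [classify_rfs(r, config) for r in out["rfs"]]
    return out


@dataclass
class PrevalenceSummary:
    """Class proportions and activity spread at variant or tumor level."""

    level: str
    name: str
    n: int
    proportions: dict
    partial_lof_share: float
    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    extra: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


def summarize(classified: pd.DataFrame, level: str = "variant",
              mask=None, name: str = "all") -> PrevalenceSummary:
    """Prevalence summary over (a filtered subset of) classified variants.

    At ``level="variant"`` every variant contributes once; at
    ``level="tumor"`` each variant is weighted by its occurrence count,
    so the two coincide exactly when all counts are 1.
    """
    if level not in ("variant", "tumor"):
        raise ValueError(f"unknown level {level!r}")
    sub = classified if mask is None else classified.loc[mask]
    if sub.empty:
        raise FilterEmptyError(f"no variants left after filter {name!r}")
    if level == "tumor":
        weights = sub["count"].to_numpy(int)
        if weights.sum() == 0:
            raise FilterEmptyError(f"no tumor occurrences after filter {name!r}")
    else:
        weights = np.ones(len(sub), dtype=int)

    activity = np.repeat(sub["mean_activity"].to_numpy(float), weights)
    classes = np.repeat(sub["activity_class"].to_numpy(), weights)
    n = int(weights.sum())
    proportions = {c: float((classes == c).sum()) / n for c in ACTIVITY_CLASSES}
    p10, q1, med, q3, p90 = np.percentile(activity, [10, 25, 50, 75, 90])
    return PrevalenceSummary(
        level=level, name=name, n=n, proportions=proportions,
        partial_lof_share=proportions["PARTIAL_LOW"] + proportions["PARTIAL_HIGH"],
        median=float(med), q1=float(q1), q3=float(q3),
        p10=float(p10), p90=float(p90),
    )


def activity_frequency_profile(classified: pd.DataFrame) -> pd.DataFrame:
    """Median and percentile spread of mean activity per frequency class.

    Rows are ordered HOTSPOT .. UNIQUE; classes absent from the table
    are omitted.
    """
    rows = []
    for fc in FREQUENCY_CLASSES:
        sub = classified.loc[classified["frequency_class"] == fc, "mean_activity"]
        if sub.empty:
            continue
        p10, q1, med, q3, p90 = np.percentile(sub.to_numpy(float),
                                              [10, 25, 50, 75, 90])
        rows.append({"frequency_class": fc, "n": len(sub), "median": med,
                     "q1": q1, "q3": q3, "p10": p10, "p90": p90})
    return pd.DataFrame(rows)
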