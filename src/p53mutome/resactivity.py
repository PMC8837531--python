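"""Expression-side statistics: fold changes, DE filtering, residual activity.

All fold changes are taken against the p53-null condition:
``log2FC_c(g) = log2((mean_c(g)+eps) / (mean_null(g)+eps))`` with a
pseudocount ``eps`` (default 1 expression unit). Differential expression
uses per-gene Welch t-tests on ``log2(x+eps)`` with Benjamini-Hochberg
correction; the published filter is mean log2FC >= 1 at corrected
p <= 0.05.

The residual transactivation of a mutant is the ratio of the median
mutant fold change to the median wild-type fold change over a target
gene set, expressed in percent of wild-type regulation. Activated and
repressed targets are scored separately (their fold changes have
opposite signs); genes whose wild-type response is below a
responsiveness floor are excluded to keep the denominator stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionStudy, NULL_CONDITION, WT_CONDITION


class WTUnresponsiveError(ValueError):
    """The WT fold-change median over the restricted set is below the floor."""


@dataclass
class ResidualConfig:
    """Knobs of the residual-activity statistic."""

    responsiveness_floor: float = 0.25  # log2 units of required WT response
    statistic: str = "ratio_of_medians"  # or "median_of_ratios"
    direction: str = "activated"  # or "repressed"

    def __post_init__(self):
        if self.statistic not in ("ratio_of_medians", "median_of_ratios"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.direction not in ("activated", "repressed"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.responsiveness_floor <= 0:
            raise ValueError("responsiveness_floor must be > 0")

    def to_dict(self):
        return asdict(self)


def condition_means(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene mean expression for every condition."""
    return pd.DataFrame(
        {c: study.values(c).mean(axis=1) for c in study.condition_names},
        index=study.genes,
    )


def log2fc_vs_null(study: ExpressionStudy, pseudocount=None) -> pd.DataFrame:
    """Per-gene log2 fold change of every non-null condition vs null."""
    eps = study.pseudocount if pseudocount is None else float(pseudocount)
    if eps <= 0:
        raise ValueError("pseudocount must be > 0")
    means = condition_means(study)
    if NULL_CONDITION not in means.columns:
        raise ValueError("study has no null condition")
    base = means[NULL_CONDITION].to_numpy() + eps
    cols = [c for c in means.columns if c != NULL_CONDITION]
    return pd.DataFrame(
        {c: np.log2((means[c].to_numpy() + eps) / base) for c in cols},
        index=study.genes,
    )


def welch_de(study: ExpressionStudy, condition: str = WT_CONDITION,
             reference: str = NULL_CONDITION) -> pd.DataFrame:
    """Per-gene Welch t-test of `condition` vs `reference` on log2(x+eps).

    Returns a DataFrame with ``log2FC``, ``p`` and BH-adjusted ``q``
    per gene. Genes with zero variance in both groups and equal means
    get p = 1.
    """
    for cond in (condition, reference):
        if study.n_replicates(cond) < 2:
            raise ValueError(f"condition {cond!r} has <2 replicates; "
                             "cannot run a variance-based test")
    eps = study.pseudocount
    a = np.log2(study.values(condition) + eps)
    b = np.log2(study.values(reference) + eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame({"log2FC": fc, "p": p, "q": q}, index=study.genes)


def de_filter(diff: pd.DataFrame, fc_threshold: float = 1.0,
              q_threshold: float = 0.05) -> set:
    """Genes with |log2FC| >= fc_threshold and q <= q_threshold."""
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be >= 0")
    if not (0 < q_threshold <= 1):
        raise ValueError("q_threshold must be in (0, 1]")
    keep = (diff["log2FC"].abs() >= fc_threshold) & (diff["q"] <= q_threshold)
    genes = set(diff.index[keep])
    if not genes:
        warnings.warn("DE filter retained no genes")
    return genes


def direct_target_set(de_genes, chip_genes) -> set:
    """Direct targets: differentially expressed AND carrying a ChIP peak."""
    de_genes, chip_genes = set(de_genes), set(chip_genes)
    if not de_genes or not chip_genes:
        raise ValueError("both input gene sets must be non-empty")
    return de_genes & chip_genes


@dataclass
class ResidualActivityResult:
    """Residual transactivation of one mutant over one gene set."""

    mutant: str
    set_name: str
    direction: str
    statistic: str
    n_genes: int
    residual_percent: float
    reduction_percent: float
    wt_median_log2fc: float
    mutant_median_log2fc: float
    out_of_range: bool
    per_gene: pd.Series = field(repr=False, default=None)

    def to_dict(self):
        d = asdict(self)
        d.pop("per_gene")
        return d


def residual_activity(study: ExpressionStudy, mutant: str, genes,
                      set_name: str = "", config: ResidualConfig = None,
                      ) -> ResidualActivityResult:
    """Score a mutant's residual regulation of a target set, % of WT.

    The set is first restricted to WT-responsive genes in the requested
    direction (WT log2FC >= floor for activated sets, <= -floor for
    repressed). The default statistic is the ratio of medians:
    ``100 * median_g(log2FC_mutant) / median_g(log2FC_WT)``. Values
    below 0 or above 100 are reported unclamped with ``out_of_range``
    set. ``reduction_percent = 100 - residual_percent``.
    """
    if config is None:
        config = ResidualConfig()
    genes = getattr(genes, "genes", genes)  # accept GeneSet or iterable
    fc = log2fc_vs_null(study)
    if WT_CONDITION not in fc.columns:
        raise ValueError("study has no WT condition")
    if mutant not in fc.columns:
        raise KeyError(f"no condition named {mutant!r}")
    present = fc.index.intersection(pd.Index(sorted(genes)))
    if len(present) == 0:
        raise WTUnresponsiveError(f"no genes of set {set_name!r} in the matrix")
    wt = fc.loc[present, WT_CONDITION]
    floor = config.responsiveness_floor
    keep = wt >= floor if config.direction == "activated" else wt <= -floor
    wt = wt[keep]
    if len(wt) == 0 or abs(float(np.median(wt))) < floor:
        raise WTUnresponsiveError(
            f"WT-unresponsive set {set_name!r} ({config.direction}): "
            f"median |WT log2FC| below floor {floor}")
    mut = fc.loc[wt.index, mutant]
    wt_med = float(np.median(wt))
    mut_med = float(np.median(mut))
    if config.statistic == "ratio_of_medians":
        residual = 100.0 * mut_med / wt_med
    else:
        residual = 100.0 * float(np.median(mut / wt))
    return ResidualActivityResult(
        mutant=mutant, set_name=set_name, direction=config.direction,
        statistic=config.statistic, n_genes=int(len(wt)),
        residual_percent=float(residual),
        reduction_percent=float(100.0 - residual),
        wt_median_log2fc=wt_med, mutant_median_log2fc=mut_med,
        out_of_range=bool(residual < 0 or residual > 100),
        per_gene=100.0 * mut / wt,
    )
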