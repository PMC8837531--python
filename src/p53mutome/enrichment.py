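"""Gene-set enrichment: weighted running-sum score with a permutation null.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-like running sum over a ranked gene list: genes in
the set advance the sum by ``|metric|^weight`` (normalized over in-set
genes), genes outside retreat by ``1/(N - N_hit)``. ``weight=0`` gives
the classic unweighted statistic; the default is ``weight=1``.

Significance comes from a gene-label null: set membership is reassigned
uniformly at random with the set size preserved. When the number of
distinct membership assignments is small (<= `exhaustive_limit`) the
null is enumerated exhaustively and the nominal p is the exact
probability that a random assignment scores at least as extreme in the
observed direction. Otherwise Monte-Carlo sampling is used and the
nominal p follows the sign-conditional add-one convention of published
GSEA, ``p = (1 + #{same-sign null ES >= ES}) / (1 + #same-sign null)``,
which is calibrated (type-I error ~= nominal level). NES divides ES by
the mean magnitude of same-sign null scores; FDRq compares null and
observed NES tail fractions within each sign class, with FDRq < 0.25 as
the significance rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from math import comb

import numpy as np

from .resactivity import log2fc_vs_null
from .types import EmptyInputError, ExpressionStudy, NULL_CONDITION


class NESUndefinedError(ValueError):
    """No same-sign null scores; raise n_perm to stabilize the null."""


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken by id."""

    genes: np.ndarray
    metric: np.ndarray
    name: str = "log2fc"

    def __post_init__(self):
        self.genes = np.asarray(self.genes)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.shape != self.metric.shape or self.genes.ndim != 1:
            raise ValueError("genes and metric must be 1-D and aligned")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("non-finite ranking metric")
        order = np.lexsort((self.genes, -self.metric))
        self.genes = self.genes[order]
        self.metric = self.metric[order]

    def __len__(self):
        return len(self.genes)


def rank_genes(study: ExpressionStudy, cond_a: str, cond_b: str,
               metric: str = "log2fc", variance_floor: float = 0.125,
               ) -> RankedList:
    """Rank all genes by a pairwise contrast, cond_a over cond_b.

    ``log2fc`` ranks by ``log2((mean_a+eps)/(mean_b+eps))``;
    ``s2n`` by the signal-to-noise ratio on log2(x+eps) with a variance
    floor added to each group's standard deviation.
    """
    if cond_a == cond_b:
        raise ValueError("contrast conditions must differ")
    eps = study.pseudocount
    a = study.values(cond_a)
    b = study.values(cond_b)
    if metric == "log2fc":
        m = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    elif metric == "s2n":
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("s2n needs >=2 replicates per condition")
        la, lb = np.log2(a + eps), np.log2(b + eps)
        m = (la.mean(axis=1) - lb.mean(axis=1)) / (
            la.std(axis=1, ddof=1) + lb.std(axis=1, ddof=1) + variance_floor)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return RankedList(genes=study.genes.to_numpy(), metric=m,
                      name=f"{metric}:{cond_a}_vs_{cond_b}")


def rank_from_contrast(study: ExpressionStudy, contrast, metric="log2fc"):
    """Contrast given as ``(cond_a, cond_b)`` or ``"A:B"``."""
    if isinstance(contrast, str):
        cond_a, cond_b = contrast.split(":", 1)
    else:
        cond_a, cond_b = contrast
    return rank_genes(study, cond_a, cond_b, metric=metric)


def _es_from_hits(metric: np.ndarray, hit: np.ndarray, weight: float):
    """Core running-sum statistic for one membership assignment."""
    n = len(metric)
    n_hit = int(hit.sum())
    w = np.abs(metric[hit]) ** weight
    total = w.sum()
    steps = np.full(n, -1.0 / (n - n_hit))
    steps[hit] = (w / total) if total > 0 else (1.0 / n_hit)
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), run


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0):
    """ES and running-sum profile of one gene set on a ranked list.

    The set must overlap the ranked genes and be a proper subset of
    them (the statistic is undefined when every gene is a hit).
    """
    genes = getattr(gene_set, "genes", gene_set)
    hit = np.isin(ranked.genes, list(genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise EmptyInputError("gene set does not overlap the ranked list")
    if n_hit == len(ranked):
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    return _es_from_hits(ranked.metric, hit, weight)


@dataclass
class EnrichmentResult:
    """GSEA output for one gene set."""

    set_name: str
    n_genes: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    significant: bool
    method: str  # "exhaustive" or "permutation"
    n_null: int

    def to_dict(self):
        return asdict(self)


def _null_scores(metric, n, k, weight, rng, n_perm, exhaustive_limit):
    """Null ES distribution for set size k; exhaustive when feasible."""
    if comb(n, k) <= exhaustive_limit:
        null = np.empty(comb(n, k))
        for j, pos in enumerate(itertools.combinations(range(n), k)):
            hit = np.zeros(n, dtype=bool)
            hit[list(pos)] = True
            null[j] = _es_from_hits(metric, hit, weight)[0]
        return null, "exhaustive"
    null = np.empty(n_perm)
    for j in range(n_perm):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=k, replace=False)] = True
        null[j] = _es_from_hits(metric, hit, weight)[0]
    return null, "permutation"


def _nominal_p(es, null, method):
    if es >= 0:
        tail = null >= es
        same_sign = null >= 0
    else:
        tail = null <= es
        same_sign = null < 0
    if method == "exhaustive":
        # exact probability of an assignment at least as extreme, same
        # direction, over all assignments
        return float(tail.sum()) / len(null)
    m = int(same_sign.sum())
    return float(1 + tail.sum()) / (1 + m)


def _normalize(scores, pos_mean, neg_mean):
    """Signed ES -> NES using per-sign mean magnitudes."""
    out = np.empty_like(scores)
    pos = scores >= 0
    out[pos] = scores[pos] / pos_mean if pos_mean > 0 else np.nan
    out[~pos] = scores[~pos] / neg_mean if neg_mean > 0 else np.nan
    return out


def permutation_significance(ranked: RankedList, sets, n_perm: int = 1000,
                             seed=None, weight: float = 1.0,
                             exhaustive_limit: int = 10000,
                             fdr_threshold: float = 0.25):
    """GSEA over several gene sets with a gene-label permutation null.

    Returns one :class:`EnrichmentResult` per set. `seed` is mandatory
    for the Monte-Carlo path (any integer).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("seed is required for reproducible permutations")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    metric = ranked.metric

    records = []
    for gene_set in sets:
        es, _ = enrichment_score(ranked, gene_set, weight)
        k = int(np.isin(ranked.genes, list(getattr(gene_set, "genes", gene_set))).sum())
        null, method = _null_scores(metric, n, k, weight, rng, n_perm,
                                    exhaustive_limit)
        p = _nominal_p(es, null, method)
        pos_mean = float(np.mean(null[null >= 0])) if (null >= 0).any() else 0.0
        neg_mean = float(np.mean(-null[null < 0])) if (null < 0).any() else 0.0
        if (es >= 0 and pos_mean == 0) or (es < 0 and neg_mean == 0):
            raise NESUndefinedError(
                f"no same-sign null ES for set {getattr(gene_set, 'name', '?')!r}; "
                "raise n_perm")
        nes = es / (pos_mean if es >= 0 else neg_mean)
        null_nes = _normalize(null, pos_mean, neg_mean)
        records.append((gene_set, k, es, nes, p, method, null_nes, len(null)))

    # GSEA-convention FDR within sign classes, null NES pooled over sets
    pooled = np.concatenate([r[6] for r in records])
    pooled = pooled[np.isfinite(pooled)]
    obs_nes = np.array([r[3] for r in records])
    results = []
    for gene_set, k, es, nes, p, method, _, n_null in records:
        if nes >= 0:
            null_frac = _tail_fraction(pooled[pooled >= 0], nes, "ge")
            obs_frac = _tail_fraction(obs_nes[obs_nes >= 0], nes, "ge")
        else:
            null_frac = _tail_fraction(pooled[pooled < 0], nes, "le")
            obs_frac = _tail_fraction(obs_nes[obs_nes < 0], nes, "le")
        q = min(1.0, null_frac / obs_frac) if obs_frac > 0 else min(1.0, null_frac)
        results.append(EnrichmentResult(
            set_name=getattr(gene_set, "name", str(gene_set)),
            n_genes=k, es=es, nes=nes, p_nominal=p, fdr_q=q,
            significant=bool(q < fdr_threshold), method=method, n_null=n_null))
    return results


def _tail_fraction(values, threshold, side):
    if len(values) == 0:
        return 0.0
    if side == "ge":
        return float((values >= threshold).sum()) / len(values)
    return float((values <= threshold).sum()) / len(values)
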