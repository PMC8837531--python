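"""Seeded generators for mutome tables, tumor cohorts and expression studies.

Every generator draws from a single RNG stream derived from
``(seed, call_tag)``, so adding one generator call never perturbs
another's output and a fixed seed reproduces outputs byte-identically.

The mutome generator emulates the shape of a curated TP53 missense
cohort: ~1209 DNA-binding-domain variants whose occurrence counts follow
a Zipf-like law (top-10 variants ~30% of all occurrences) and whose
yeast transactivation anticorrelates with frequency. Two planting modes
exist:

* default (``class_proportions=None``): each frequency class gets its
  own mixture over the four activity classes, calibrated so that the
  hotspot median is ~2.6 %WT, the unique-variant median ~75 %WT, and the
  variant-level partial-LOF share ~32%;
* flat (``class_proportions={...}``): activity classes drawn iid from
  the given proportions for every variant, for parameter-recovery tests.

The expression generator plants a per-mutant residual fraction alpha:
each mutant's target-gene log2FC is ``alpha x WT log2FC`` plus Gaussian
noise, zero off-target, with log-normal baselines and log-scale
replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import io as mio
from .classify import ACTIVITY_CLASSES, assign_frequency_classes, DEFAULT_CONFIG
from .types import ExpressionStudy, GeneSet

_TAG_MUTOME, _TAG_COHORT, _TAG_EXPRESSION = 11, 13, 17


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _trunc_lognormal(rng, median, sigma, lo, hi, size):
    """Inverse-CDF sampling of a lognormal truncated to [lo, hi)."""
    mu = np.log(median)
    f_lo = ndtr((np.log(max(lo, 1e-12)) - mu) / sigma) if lo > 0 else 0.0
    f_hi = ndtr((np.log(hi) - mu) / sigma)
    u = rng.uniform(f_lo, f_hi, size=size)
    return np.exp(mu + sigma * ndtri(u))


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Inverse-CDF sampling of a normal truncated to [lo, hi]."""
    f_lo = ndtr((lo - mean) / sd)
    f_hi = ndtr((hi - mean) / sd)
    u = rng.uniform(f_lo, f_hi, size=size)
    return mean + sd * ndtri(u)


# Latent activity distribution per activity class:
# (lognormal median %WT, log-sd, lower, upper)
ACTIVITY_DISTS = {
    "LOF": (3.0, 0.7, 0.0, 10.0),
    "PARTIAL_LOW": (14.5, 0.25, 10.0, 20.0),
    "PARTIAL_HIGH": (30.0, 0.35, 20.0, 50.0),
    "RETAINED": (82.0, 0.30, 50.0, 140.0),
}

# Frequency-conditional overrides used by the default planting: frequent
# LOF variants sit deep in the LOF bin (hotspots ~2.6 %WT) while the few
# very-frequent LOF variants sit near its upper edge, mirroring the
# observed gradient of median activity with frequency.
ACTIVITY_DIST_OVERRIDES = {
    ("HOTSPOT", "LOF"): (2.6, 0.5, 0.0, 10.0),
    ("VERY_FREQUENT", "LOF"): (6.5, 0.3, 3.0, 10.0),
    ("FREQUENT", "LOF"): (5.0, 0.6, 0.0, 10.0),
}

# Activity-class mixture per frequency class (default planting).
DEFAULT_CLASS_MIX = {
    "HOTSPOT": {"LOF": 1.0},
    "VERY_FREQUENT": {"LOF": 0.70, "PARTIAL_LOW": 0.20,
                      "PARTIAL_HIGH": 0.08, "RETAINED": 0.02},
    "FREQUENT": {"LOF": 0.40, "PARTIAL_LOW": 0.22,
                 "PARTIAL_HIGH": 0.23, "RETAINED": 0.15},
    "RARE": {"LOF": 0.28, "PARTIAL_LOW": 0.12,
             "PARTIAL_HIGH": 0.30, "RETAINED": 0.30},
    "UNIQUE": {"LOF": 0.10, "PARTIAL_LOW": 0.05,
               "PARTIAL_HIGH": 0.12, "RETAINED": 0.73},
}

# Reference amino acids for structurally prominent codons; other codons
# get a random (but per-table fixed) reference residue.
_KNOWN_REF = {175: "R", 179: "H", 180: "E", 181: "R", 245: "G",
              248: "R", 249: "R", 273: "R", 282: "R"}
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MutomeConfig:
    """Planted parameters of a synthetic mutome table."""

    n_variants: int = 1209
    total_occurrences: int = 6000
    zipf_exponent: float = 0.9
    re_noise_sd: float = 3.0  # %WT, per response element
    class_proportions: Optional[Mapping[str, float]] = None  # flat mode
    rfs_noise_sd: float = 0.3
    damaging_prob_low_activity: float = 0.95
    damaging_prob_high_activity: float = 0.4
    codon_window: tuple = (100, 300)

    def __post_init__(self):
        if self.n_variants < 20:
            raise ValueError("n_variants must be >= 20")
        if self.re_noise_sd < 0 or self.rfs_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.class_proportions is not None:
            p = np.array([self.class_proportions.get(c, 0.0)
                          for c in ACTIVITY_CLASSES], float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("class_proportions must be a distribution "
                                 "over the four activity classes")
            if (p > 0).sum() == 0:
                raise ValueError("all activity classes empty")

    def to_dict(self):
        return asdict(self)


def _protein_changes(rng, config):
    lo, hi = config.codon_window
    codons = np.arange(lo, hi + 1)
    refs = {c: _KNOWN_REF.get(c, _AA[rng.integers(len(_AA))]) for c in codons}
    pool = [(c, refs[c], a) for c in codons for a in _AA if a != refs[c]]
    if config.n_variants > len(pool):
        raise ValueError("n_variants exceeds distinct protein changes")
    idx = rng.choice(len(pool), size=config.n_variants, replace=False)
    return [pool[i] for i in idx]


def _zipf_counts(rng, config):
    r = np.arange(1, config.n_variants + 1, dtype=float)
    p = r ** -config.zipf_exponent
    p /= p.sum()
    counts = rng.poisson(config.total_occurrences * p)
    counts = np.maximum(counts, 1)
    return -np.sort(-counts)  # descending


def _draw_latent(rng, activity_class, frequency_class, use_overrides):
    key = (frequency_class, activity_class)
    params = ACTIVITY_DIST_OVERRIDES.get(key) if use_overrides else None
    if params is None:
        params = ACTIVITY_DISTS[activity_class]
    median, sigma, lo, hi = params
    return float(_trunc_lognormal(rng, median, sigma, lo, hi, size=1)[0])


def gen_mutome(seed: int, config: MutomeConfig = None, **overrides):
    """Generate a synthetic UMD-style variant table with known truth.

    Returns ``(variants, truth)``: `variants` in exactly the dialect
    :func:`p53mutome.io.read_variant_table` accepts, `truth` holding the
    planted activity class, latent activity, frequency class and count
    per variant (keep it out of analysis inputs).
    """
    if config is None:
        config = MutomeConfig(**overrides)
    elif overrides:
        config = MutomeConfig(**{**config.to_dict(), **overrides})
    rng = _rng(seed, _TAG_MUTOME)

    changes = _protein_changes(rng, config)
    counts = _zipf_counts(rng, config)

    base = pd.DataFrame({
        "protein_change": [f"{r}{c}{a}" for c, r, a in changes],
        "count": counts,
    })
    freq_class = assign_frequency_classes(base, DEFAULT_CONFIG)

    if config.class_proportions is not None:
        probs = [config.class_proportions.get(c, 0.0) for c in ACTIVITY_CLASSES]
        planted = rng.choice(ACTIVITY_CLASSES, size=config.n_variants, p=probs)
        use_overrides = False
    else:
        planted = np.empty(config.n_variants, dtype=object)
        for i, fc in enumerate(freq_class):
            mix = DEFAULT_CLASS_MIX[fc]
            classes = list(mix)
            planted[i] = rng.choice(classes, p=[mix[c] for c in classes])
        use_overrides = True

    latent = np.array([
        _draw_latent(rng, planted[i], freq_class.iloc[i], use_overrides)
        for i in range(config.n_variants)
    ])

    re_act = latent[:, None] + rng.normal(0.0, config.re_noise_sd,
                                          size=(config.n_variants, 8))
    re_act = np.maximum(re_act, 0.0)

    p_dmg = np.where(latent < 50.0, config.damaging_prob_low_activity,
                     config.damaging_prob_high_activity)
    flags = rng.random((config.n_variants, 3)) < p_dmg[:, None]
    rfs = -3.0 * latent / 100.0 + rng.normal(0.0, config.rfs_noise_sd,
                                             config.n_variants)

    variants = base.copy()
    variants["ref_aa"] = [r for _, r, _ in changes]
    variants["codon"] = [c for c, _, _ in changes]
    variants["alt_aa"] = [a for _, _, a in changes]
    for j, col in enumerate(mio.ACTIVITY_COLUMNS):
        variants[col] = re_act[:, j]
    for j, col in enumerate(mio.PREDICTOR_COLUMNS):
        variants[col] = flags[:, j]
    variants["rfs"] = rfs
    variants["mean_activity"] = re_act.mean(axis=1)

    truth = pd.DataFrame({
        "protein_change": variants["protein_change"],
        "planted_class": planted,
        "latent_activity": latent,
        "frequency_class": freq_class.to_numpy(),
        "count": counts,
        "seed": seed,
    })
    return variants, truth


def gen_cohort(variants: pd.DataFrame, seed: int = 0, mode: str = "exact",
               n_tumors: Optional[int] = None) -> pd.DataFrame:
    """Tumor occurrences from a variant table.

    ``mode="exact"`` expands each variant into exactly `count` rows
    (identical to :func:`p53mutome.io.expand_to_tumors`);
    ``mode="sample"`` draws `n_tumors` occurrences with probability
    proportional to counts.
    """
    if mode == "exact":
        return mio.expand_to_tumors(variants)
    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}")
    if not n_tumors or n_tumors < 1:
        raise ValueError("sampling mode needs n_tumors >= 1")
    rng = _rng(seed, _TAG_COHORT)
    counts = variants["count"].to_numpy(float)
    if counts.sum() <= 0:
        raise ValueError("no occurrences to sample from")
    idx = rng.choice(len(variants), size=n_tumors, p=counts / counts.sum())
    out = variants.iloc[idx].reset_index(drop=True)
    out.insert(0, "tumor_id", [f"T{i:06d}" for i in range(len(out))])
    return out


#: Residual fractions used for the default mutant panel; they span the
#: 5-79% residual-transactivation continuum of the cooperativity-mutant
#: class, with one complete-LOF mutant.
DEFAULT_MUTANT_ALPHAS = {
    "R181L": 0.79, "E180R": 0.60, "R181H": 0.45,
    "R181C": 0.20, "E180K": 0.05, "R181P": 0.0,
}


@dataclass
class ExpressionConfig:
    """Planted parameters of a synthetic expression study."""

    n_genes: int = 2000
    n_activated: int = 200
    n_repressed: int = 100
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    activated_mean: float = 2.0
    activated_sd: float = 0.5
    activated_min: float = 1.0
    repressed_mean: float = -1.5
    repressed_sd: float = 0.5
    repressed_max: float = -1.0
    mutant_noise_sd: float = 0.2  # log2 units on target genes
    replicate_sd: float = 0.25  # log2 units per sample
    n_replicates: int = 3
    unit: str = "TPM"
    pseudocount: float = 1.0
    n_chip_targets: Optional[int] = None  # subset of activated targets
    n_chip_background: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if min(self.mutant_noise_sd, self.replicate_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if self.n_activated + self.n_repressed > self.n_genes:
            raise ValueError("more targets than genes")
        if self.n_chip_targets is not None and \
                self.n_chip_targets > self.n_activated:
            raise ValueError("n_chip_targets exceeds activated targets")

    def to_dict(self):
        return asdict(self)


@dataclass
class ExpressionTruth:
    """Planted ground truth of one synthetic expression study."""

    seed: int
    alphas: dict
    activated: list
    repressed: list
    chip: Optional[list]
    wt_log2fc: pd.Series = field(repr=False, default=None)
    config: dict = field(default_factory=dict)


def gen_expression(seed: int, mutants: Mapping[str, float] = None,
                   config: ExpressionConfig = None, **overrides):
    """Generate an expression study with planted residual fractions.

    Returns ``(study, gene_sets, truth)`` where `gene_sets` maps
    ``activated_targets``/``repressed_targets`` (and ``chip_peaks`` if
    configured) to :class:`GeneSet` objects.
    """
    if mutants is None:
        mutants = DEFAULT_MUTANT_ALPHAS
    if not mutants:
        raise ValueError("need at least one mutant condition")
    for name, alpha in mutants.items():
        if name in ("null", "WT"):
            raise ValueError(f"{name!r} is a reserved condition label")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha for {name!r} outside [0, 1]: {alpha}")
    if config is None:
        config = ExpressionConfig(**overrides)
    elif overrides:
        config = ExpressionConfig(**{**config.to_dict(), **overrides})
    rng = _rng(seed, _TAG_EXPRESSION)

    g = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(1, g + 1)])
    target_idx = rng.choice(g, size=config.n_activated + config.n_repressed,
                            replace=False)
    act_idx = np.sort(target_idx[: config.n_activated])
    rep_idx = np.sort(target_idx[config.n_activated:])

    fc_wt = np.zeros(g)
    fc_wt[act_idx] = _trunc_normal(rng, config.activated_mean,
                                   config.activated_sd, config.activated_min,
                                   np.inf, len(act_idx))
    fc_wt[rep_idx] = _trunc_normal(rng, config.repressed_mean,
                                   config.repressed_sd, -np.inf,
                                   config.repressed_max, len(rep_idx))

    null_mean = 2.0 ** rng.normal(config.baseline_log2_mean,
                                  config.baseline_log2_sd, g)

    cond_fc = {"null": np.zeros(g), "WT": fc_wt}
    tgt = np.concatenate([act_idx, rep_idx])
    for name, alpha in mutants.items():
        fc_m = alpha * fc_wt.copy()
        # regulatory scatter around the attenuated program: full at
        # complete LOF, vanishing as the mutant approaches WT so that
        # alpha=1 is statistically indistinguishable from WT
        fc_m[tgt] += rng.normal(0.0, config.mutant_noise_sd * (1.0 - alpha),
                                len(tgt))
        fc_m[np.setdiff1d(np.arange(g), tgt)] = 0.0
        cond_fc[name] = fc_m

    columns, data, labels = [], [], {}
    for cond, fc in cond_fc.items():
        mean = null_mean * 2.0 ** fc
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_{rep}"
            noise = rng.normal(0.0, config.replicate_sd, g)
            data.append(mean * 2.0 ** noise)
            columns.append(sample)
            labels[sample] = cond

    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    study = ExpressionStudy(matrix=matrix, conditions=pd.Series(labels),
                            unit=config.unit, pseudocount=config.pseudocount)

    gene_sets = {
        "activated_targets": GeneSet("activated_targets",
                                     frozenset(genes[act_idx]),
                                     "planted WT-activated targets"),
        "repressed_targets": GeneSet("repressed_targets",
                                     frozenset(genes[rep_idx]),
                                     "planted WT-repressed targets"),
    }
    chip = None
    if config.n_chip_targets is not None:
        with_peak = rng.choice(act_idx, size=config.n_chip_targets,
                               replace=False)
        non_target = np.setdiff1d(np.arange(g), tgt)
        background = rng.choice(non_target, size=config.n_chip_background,
                                replace=False)
        chip = sorted(genes[np.concatenate([with_peak, background])])
        gene_sets["chip_peaks"] = GeneSet("chip_peaks", frozenset(chip),
                                          "simulated ChIP-seq peak genes")

    truth = ExpressionTruth(
        seed=seed, alphas={str(k): float(v) for k, v in mutants.items()},
        activated=[str(g) for g in genes[act_idx]],
        repressed=[str(g) for g in genes[rep_idx]],
        chip=[str(g) for g in chip] if chip is not None else None,
        wt_log2fc=pd.Series(fc_wt, index=genes),
        config=config.to_dict(),
    )
    return study, gene_sets, truth
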