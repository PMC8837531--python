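"""Composed analysis workflows.

``run_mutome_analysis`` reproduces the variant/tumor prevalence view of
a mutome table: classification, summaries at the variant level, the
tumor level, the non-hotspot tumor level and the cooperativity subset,
plus the per-frequency-class activity profile.

``run_expression_analysis`` reproduces the transcriptome view: DE
filtering of WT vs null, optional direct-target-set construction from a
ChIP gene list, residual-activity scoring of every mutant over every
gene set (activated and repressed directions), and GSEA over the
standard contrasts (WT vs each mutant; each condition vs null; treated
vs control when treatment labels exist).

Both return a plain serializable bundle carrying an audit block (config
hash, input checksums, seed, package version) and are idempotent: the
same inputs produce bit-identical outputs.
"""

from __future__ import annotations

import json

import pandas as pd

from . import __version__
from . import io as mio
from .classify import (activity_frequency_profile, classify_variants,
                       summarize)
from .config import RunConfig
from .enrichment import permutation_significance, rank_genes
from .resactivity import (WTUnresponsiveError, de_filter, direct_target_set,
                          residual_activity, welch_de)
from .types import ExpressionStudy, NULL_CONDITION, WT_CONDITION


def _audit(config: RunConfig, checksums, seed=None):
    return {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "input_sha256": checksums,
        "seed": seed,
    }


def run_mutome_analysis(config: RunConfig, variants: pd.DataFrame = None):
    """Classify a mutome table and summarize prevalence at four levels."""
    checksums = {}
    read_audit = None
    if variants is None:
        if not config.variants:
            raise ValueError("no variant table configured")
        schema = mio.load_schema(config.variant_schema) \
            if config.variant_schema else None
        variants, read_audit = mio.read_variant_table(config.variants, schema)
        checksums["variants"] = read_audit.sha256
    classified = classify_variants(variants, config.classifier)

    summaries = {
        "variant": summarize(classified, "variant", name="all variants"),
        "tumor": summarize(classified, "tumor", name="all tumors"),
        "tumor_non_hotspot": summarize(
            classified, "tumor",
            mask=classified["frequency_class"] != "HOTSPOT",
            name="non-hotspot tumors"),
    }
    coop = classified["is_cooperativity"]
    if coop.any():
        summaries["cooperativity_variant"] = summarize(
            classified, "variant", mask=coop, name="cooperativity variants")

    bundle = {
        "summaries": {k: v.to_dict() for k, v in summaries.items()},
        "profile": activity_frequency_profile(classified).to_dict("records"),
        "audit": _audit(config, checksums),
    }
    if read_audit is not None:
        bundle["audit"]["read_audit"] = read_audit.to_dict()
    return classified, bundle


def _gsea_contrasts(study: ExpressionStudy):
    contrasts = [(WT_CONDITION, m) for m in study.mutant_conditions]
    contrasts += [(c, NULL_CONDITION) for c in study.condition_names
                  if c != NULL_CONDITION]
    return contrasts


def run_expression_analysis(config: RunConfig, study: ExpressionStudy = None,
                            gene_sets=None, treatment=None):
    """DE filter, direct targets, residual activity and GSEA per contrast."""
    checksums = {}
    if study is None:
        if not (config.expression and config.labels):
            raise ValueError("no expression matrix / labels configured")
        labels, treatment = mio.load_labels(config.labels)
        study = mio.read_expression(config.expression, labels,
                                    pseudocount=config.pseudocount)
        checksums["expression"] = mio.sha256_of(config.expression)
    if gene_sets is None:
        if not config.gene_sets:
            raise ValueError("no gene sets configured")
        gene_sets = mio.read_gmt(config.gene_sets)
        checksums["gene_sets"] = mio.sha256_of(config.gene_sets)

    de = welch_de(study)
    de_genes = de_filter(de, config.de.fc_threshold, config.de.q_threshold)

    direct_targets = None
    if config.chip_genes:
        chip = {g for s in mio.read_gmt(config.chip_genes) for g in s.genes}
        checksums["chip_genes"] = mio.sha256_of(config.chip_genes)
        direct_targets = direct_target_set(de_genes, chip)

    residual_rows = []
    for mutant in study.mutant_conditions:
        for gene_set in gene_sets:
            for direction in ("activated", "repressed"):
                rc = type(config.residual)(
                    responsiveness_floor=config.residual.responsiveness_floor,
                    statistic=config.residual.statistic, direction=direction)
                try:
                    res = residual_activity(study, mutant, gene_set,
                                            set_name=gene_set.name, config=rc)
                except WTUnresponsiveError:
                    continue
                residual_rows.append(res.to_dict())

    gsea_rows = []
    for cond_a, cond_b in _gsea_contrasts(study):
        ranked = rank_genes(study, cond_a, cond_b, metric=config.gsea.metric)
        results = permutation_significance(
            ranked, gene_sets, n_perm=config.gsea.n_perm,
            seed=config.gsea.seed, weight=config.gsea.weight,
            exhaustive_limit=config.gsea.exhaustive_limit,
            fdr_threshold=config.gsea.fdr_threshold)
        for r in results:
            row = r.to_dict()
            row["contrast"] = f"{cond_a}_vs_{cond_b}"
            gsea_rows.append(row)

    if treatment:
        tstudy = ExpressionStudy(matrix=study.matrix,
                                 conditions=pd.Series(dict(treatment)),
                                 unit=study.unit,
                                 pseudocount=study.pseudocount)
        ranked = rank_genes(tstudy, "treated", "control",
                            metric=config.gsea.metric)
        for r in permutation_significance(
                ranked, gene_sets, n_perm=config.gsea.n_perm,
                seed=config.gsea.seed, weight=config.gsea.weight,
                exhaustive_limit=config.gsea.exhaustive_limit,
                fdr_threshold=config.gsea.fdr_threshold):
            row = r.to_dict()
            row["contrast"] = "treated_vs_control"
            gsea_rows.append(row)

    bundle = {
        "n_de_genes": len(de_genes),
        "de_genes": sorted(de_genes),
        "direct_targets": sorted(direct_targets) if direct_targets is not None
        else None,
        "residual_activity": residual_rows,
        "gsea": gsea_rows,
        "warnings": list(study.warnings),
        "audit": _audit(config, checksums, seed=config.gsea.seed),
    }
    return bundle


def write_bundle(bundle, path):
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
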