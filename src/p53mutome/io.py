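"""Readers and writers for variant tables, tumor tables, expression and GMT.

All tabular inputs are flat TSV with a header row. Variant tables use the
UMD-style convention of one row per protein change with an occurrence
count and per-response-element yeast transactivation values expressed as
% of wild-type activity. Every writer also drops a small JSON audit
sidecar next to its output (``<path>.audit.json``).
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .types import EmptyInputError, ExpressionStudy, GeneSet, SchemaError

#: The 8 p53 response elements scored per variant in the yeast reporter
#: panel (14-3-3 sigma appears under its gene symbol SFN).
RESPONSE_ELEMENTS = ("WAF1", "MDM2", "BAX", "SFN", "AIP1", "GADD45", "NOXA", "P53R2")
ACTIVITY_COLUMNS = tuple(f"act_{r}" for r in RESPONSE_ELEMENTS)
PREDICTOR_COLUMNS = ("sift_damaging", "mutassessor_damaging", "provean_damaging")

MANDATORY_COLUMNS = ("protein_change", "count") + ACTIVITY_COLUMNS
OPTIONAL_COLUMNS = PREDICTOR_COLUMNS + ("rfs",)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_RE = re.compile(rf"^([{_AA}])(\d+)([{_AA}])$")


def parse_protein_change(text):
    """Parse e.g. ``"R175H"`` into ``("R", 175, "H")`` or return None."""
    m = _PROTEIN_RE.match(str(text).strip())
    if m is None:
        return None
    ref, codon, alt = m.group(1), int(m.group(2)), m.group(3)
    if codon < 1:
        return None
    return ref, codon, alt


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ReadAudit:
    """What happened while loading a variant table."""

    path: str
    sha256: str
    n_rows_in: int = 0
    n_retained: int = 0
    dropped_unparseable: int = 0
    dropped_missing_activity: int = 0
    merged_duplicates: int = 0
    notes: list = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.dropped_unparseable + self.dropped_missing_activity

    def to_dict(self):
        d = asdict(self)
        d["dropped"] = self.dropped
        return d


def load_schema(path):
    """Read a YAML column-name mapping {canonical: file column}."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError("schema file must contain a mapping")
    return mapping


def read_variant_table(path, schema=None):
    """Load a UMD-style variant TSV.

    Parameters
    ----------
    path : str or Path
        TSV with header. Mandatory columns (after renaming through
        `schema`): ``protein_change``, ``count`` and the 8 ``act_*``
        transactivation columns. Optional: three predictor flags and
        ``rfs``.
    schema : mapping, optional
        ``{canonical_name: column_name_in_file}`` for files using other
        headers.

    Returns
    -------
    (pandas.DataFrame, ReadAudit)
        One row per protein change. Rows whose protein change does not
        parse or that miss any of the 8 activity values are dropped and
        counted in the audit; duplicate protein changes are merged by
        summing counts.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if schema:
        rename = {v: k for k, v in schema.items()}
        raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")
    audit = ReadAudit(path=str(path), sha256=sha256_of(path), n_rows_in=len(raw))

    parsed = raw["protein_change"].map(parse_protein_change)
    bad_pc = parsed.isna()
    audit.dropped_unparseable = int(bad_pc.sum())
    df = raw.loc[~bad_pc].copy()
    parsed = parsed.loc[~bad_pc]

    act = df[list(ACTIVITY_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad_act = act.isna().any(axis=1) | (act < 0).any(axis=1)
    audit.dropped_missing_activity = int(bad_act.sum())
    df = df.loc[~bad_act]
    act = act.loc[~bad_act]
    parsed = parsed.loc[~bad_act]

    if df.empty:
        raise EmptyInputError(f"no usable variant rows in {path}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        audit.notes.append("non-numeric counts coerced to 0")
    counts = counts.fillna(0)
    if (counts < 0).any():
        raise ValueError("negative occurrence count")

    out = pd.DataFrame({
        "protein_change": df["protein_change"].str.strip(),
        "ref_aa": [p[0] for p in parsed],
        "codon": [p[1] for p in parsed],
        "alt_aa": [p[2] for p in parsed],
        "count": np.rint(counts.to_numpy(float)).astype(int),
    })
    for col in ACTIVITY_COLUMNS:
        out[col] = act[col].to_numpy(float)
    for col in PREDICTOR_COLUMNS:
        if col in df.columns:
            out[col] = (
                df[col].astype(str).str.strip().str.lower()
                .isin({"1", "true", "yes", "damaging"})
            )
        else:
            out[col] = False
    if "rfs" in df.columns:
        out["rfs"] = pd.to_numeric(df["rfs"], errors="coerce")
    else:
        out["rfs"] = np.nan

    # distinct nucleotide changes with the same protein change are merged
    n_before = len(out)
    agg = {c: "mean" for c in ACTIVITY_COLUMNS}
    agg.update({"ref_aa": "first", "codon": "first", "alt_aa": "first",
                "count": "sum", "rfs": "mean"})
    agg.update({c: "any" for c in PREDICTOR_COLUMNS})
    out = out.groupby("protein_change", as_index=False, sort=False).agg(agg)
    audit.merged_duplicates = n_before - len(out)

    out["mean_activity"] = out[list(ACTIVITY_COLUMNS)].mean(axis=1)
    audit.n_retained = len(out)
    return out.reset_index(drop=True), audit


def write_variant_table(df, path, audit=None):
    """Write a variant table as TSV plus a JSON audit sidecar."""
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"path": str(path), "sha256": sha256_of(path), "n_rows": len(df)}
    if audit is not None:
        sidecar["read_audit"] = audit.to_dict() if hasattr(audit, "to_dict") else audit
    with open(f"{path}.audit.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar


def expand_to_tumors(variants: pd.DataFrame) -> pd.DataFrame:
    """Expand per-variant counts into one row per tumor occurrence.

    A variant with count ``k`` yields exactly ``k`` rows, so the output
    has ``sum(count)`` rows and per-variant recounting recovers the
    original count column exactly.
    """
    counts = variants["count"].to_numpy(int)
    if (counts < 0).any():
        raise ValueError("negative occurrence count")
    idx = np.repeat(np.arange(len(variants)), counts)
    out = variants.iloc[idx].reset_index(drop=True)
    out.insert(0, "tumor_id", [f"T{i:06d}" for i in range(len(out))])
    return out


def load_labels(path):
    """Read a YAML sample-to-condition map.

    Either a flat ``{sample: condition}`` mapping, or a mapping with a
    ``conditions`` key and an optional ``treatment`` key
    (``{sample: treated|control}``).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise SchemaError("labels file must contain a mapping")
    if "conditions" in data:
        conditions = data["conditions"]
        treatment = data.get("treatment")
    else:
        conditions, treatment = data, None
    return conditions, treatment


def read_expression(path, labels, unit="TPM", pseudocount=1.0,
                    require_baselines=True):
    """Load a gene-by-sample TSV into an :class:`ExpressionStudy`.

    `labels` maps sample name to condition; ``null`` and ``WT`` need at
    least 2 replicates each and at least one mutant condition must be
    present (disable with ``require_baselines=False`` for partial
    studies such as treatment-only contrasts).
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    conditions = pd.Series(dict(labels))
    study = ExpressionStudy(matrix=matrix, conditions=conditions,
                            unit=unit, pseudocount=pseudocount)
    if require_baselines:
        counts = study.conditions.value_counts()
        for needed in ("null", "WT"):
            if counts.get(needed, 0) < 2:
                raise SchemaError(
                    f"condition {needed!r} needs >=2 replicates, "
                    f"found {counts.get(needed, 0)}")
        if not study.mutant_conditions:
            raise SchemaError("no mutant condition in labels")
    return study


def write_expression(study: ExpressionStudy, path, labels_path=None):
    study.matrix.to_csv(path, sep="\t")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            yaml.safe_dump({"conditions": study.conditions.to_dict()}, fh,
                           sort_keys=True)
    with open(f"{path}.audit.json", "w") as fh:
        json.dump({"path": str(path), "sha256": sha256_of(path),
                   "n_genes": int(study.matrix.shape[0]),
                   "n_samples": int(study.matrix.shape[1]),
                   "unit": study.unit}, fh, indent=2, sort_keys=True)


def read_gmt(path):
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EmptyInputError(
                    f"{path}:{lineno}: gene set line with no genes")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise EmptyInputError(
                    f"{path}:{lineno}: gene set {name!r} is empty")
            if len(set(genes)) < len(genes):
                warnings.warn(f"duplicate genes in set {name!r}; deduplicated")
            sets.append(GeneSet(name=name, genes=frozenset(genes),
                                description=desc))
    if not sets:
        raise EmptyInputError(f"no gene sets in {path}")
    return sets


def write_gmt(sets, path):
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")
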