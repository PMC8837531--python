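"""Shared domain containers.

The two objects that travel between pipeline stages are :class:`GeneSet`
(an immutable named set of gene identifiers, the GMT unit) and
:class:`ExpressionStudy` (a gene-by-sample expression matrix with a
condition label per sample and a pseudocount used by all fold-change
arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical condition labels. Everything that is neither ``null`` nor
#: ``WT`` is treated as a mutant condition.
NULL_CONDITION = "null"
WT_CONDITION = "WT"


class SchemaError(ValueError):
    """An input file does not provide a required column or label."""


class EmptyInputError(ValueError):
    """An input is empty (possibly after mandatory filtering)."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (one GMT line)."""

    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise EmptyInputError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in self.genes


@dataclass
class ExpressionStudy:
    """Gene-by-sample expression matrix with condition labels.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Non-negative expression values (FPKM, TPM or UMI-TPM), genes as
        the index and samples as columns.
    conditions : pandas.Series
        Condition label per sample, indexed by sample name. ``null`` and
        ``WT`` are reserved labels; anything else names a mutant.
    unit : str
        Expression unit, recorded for provenance only.
    pseudocount : float
        Regularizer (in expression units) added to every mean before a
        ratio is formed; must be > 0.
    """

    matrix: pd.DataFrame
    conditions: pd.Series
    unit: str = "TPM"
    pseudocount: float = 1.0
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise SchemaError(f"duplicate gene identifier: {dup!r}")
        vals = self.matrix.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        unlabeled = [s for s in self.matrix.columns if s not in self.conditions.index]
        if unlabeled:
            raise SchemaError(f"sample without condition label: {unlabeled[0]!r}")
        self.conditions = self.conditions.loc[self.matrix.columns]
        for cond, n in self.conditions.value_counts().items():
            if n < 2:
                self.warnings.append(
                    f"condition {cond!r} has {n} replicate(s); "
                    "variance-based statistics will refuse it"
                )

    # -- convenience -----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def condition_names(self) -> list:
        seen = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def mutant_conditions(self) -> list:
        return [c for c in self.condition_names
                if c not in (NULL_CONDITION, WT_CONDITION)]

    def samples(self, condition: str) -> list:
        if condition not in set(self.conditions):
            raise KeyError(f"no samples for condition {condition!r}")
        return list(self.conditions.index[self.conditions == condition])

    def n_replicates(self, condition: str) -> int:
        return int((self.conditions == condition).sum())

    def values(self, condition: str) -> np.ndarray:
        """Genes x replicates array for one condition."""
        return self.matrix[self.samples(condition)].to_numpy(float)
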