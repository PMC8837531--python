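import numpy as np
import pandas as pd
import pytest

from p53mutome.io import ACTIVITY_COLUMNS, PREDICTOR_COLUMNS
from p53mutome.types import ExpressionStudy


def make_variants(activities, counts=None, protein_changes=None, rfs=None,
                  re_spread=0.0):
    """Variant table with controlled mean activities.

    Each variant's 8 RE values are its activity (optionally +- an
    alternating spread that cancels in the mean).
    """
    n = len(activities)
    counts = [1] * n if counts is None else list(counts)
    if protein_changes is None:
        refs = "RGHLKPQSTV"
        protein_changes = [f"{refs[i % len(refs)]}{100 + i}W" for i in range(n)]
    from p53mutome import parse_protein_change
    rows = {"protein_change": protein_changes, "count": counts}
    df = pd.DataFrame(rows)
    parsed = [parse_protein_change(p) or ("X", 0, "X")
              for p in protein_changes]
    df["ref_aa"] = [p[0] for p in parsed]
    df["codon"] = [p[1] for p in parsed]
    df["alt_aa"] = [p[2] for p in parsed]
    offsets = np.array([re_spread * (1 if j % 2 == 0 else -1) for j in range(8)])
    for j, col in enumerate(ACTIVITY_COLUMNS):
        df[col] = [max(0.0, a + offsets[j]) for a in activities]
    for col in PREDICTOR_COLUMNS:
        df[col] = True
    df["rfs"] = rfs if rfs is not None else np.nan
    df["mean_activity"] = df[list(ACTIVITY_COLUMNS)].mean(axis=1)
    return df


def make_study(cond_means, n_replicates=3, pseudocount=1.0, jitter=None,
               seed=0):
    """ExpressionStudy from exact per-condition mean vectors.

    cond_means: {condition: array of per-gene means}; replicates are
    identical copies unless `jitter` (log2 sd) is given.
    """
    rng = np.random.default_rng(seed)
    genes = None
    data, labels = {}, {}
    for cond, means in cond_means.items():
        means = np.asarray(means, dtype=float)
        if genes is None:
            genes = [f"g{i:03d}" for i in range(len(means))]
        for rep in range(1, n_replicates + 1):
            vals = means.copy()
            if jitter:
                vals = vals * 2.0 ** rng.normal(0, jitter, len(vals))
            name = f"{cond}_{rep}"
            data[name] = vals
            labels[name] = cond
    matrix = pd.DataFrame(data, index=genes)
    return ExpressionStudy(matrix=matrix, conditions=pd.Series(labels),
                           pseudocount=pseudocount)


@pytest.fixture
def small_variants():
    return make_variants([5.0, 15.0, 30.0, 60.0, 8.0])
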