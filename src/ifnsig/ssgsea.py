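"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ordered by decreasing expression (ties broken by
gene identifier for determinism).  Walking down the ordered list, the score
accumulates the difference between the weighted empirical CDF of the in-set
genes and the uniform empirical CDF of the out-of-set genes:

    score = sum_i [ P_in(i) - P_out(i) ]

where an in-set gene at descending-rank position ``i`` contributes weight
``r_i ** alpha`` (``r_i`` = N - i, i.e. the top gene carries rank N) to
P_in, and every out-of-set gene contributes 1/(N - |S|) to P_out.  With
``alpha = 0`` all weights are equal and the score depends only on gene
ranks, hence is invariant under strictly monotone transforms of the
expression values.  The default ``alpha = 0.25`` follows the published
ssGSEA convention.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one tab-separated line per set (name, description,
    then gene identifiers)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {line_no} has fewer than 3 fields")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: set {name!r} is empty")
            sets[name] = genes
    return sets


def ssgsea_score(
    sample_values: Mapping[str, float],
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of one gene set in one sample."""
    items = list(sample_values.items())
    values = np.array([v for _, v in items], dtype=float)
    if np.isnan(values).any():
        raise ValueError("sample contains NaN expression values")
    genes = [g for g, _ in items]
    members = set(gene_set)
    in_set = np.array([g in members for g in genes])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has empty intersection with the sample's "
                         "gene universe")
    # descending by value, ties broken by gene id
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    n = len(genes)
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    in_sorted = in_set[order]
    weights = np.where(in_sorted, ranks ** alpha, 0.0)
    total_in = weights.sum()
    n_out = n - n_in
    p_in = np.cumsum(weights) / total_in
    if n_out:
        p_out = np.cumsum(~in_sorted) / n_out
    else:
        p_out = np.zeros(n)
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Samples x sets score table for a genes-by-samples expression matrix.

    Per-set failures (e.g. empty intersection with the matrix's genes) yield
    NaN for that column rather than aborting the whole run.
    """
    if expr.index.duplicated().any():
        raise ValueError("expression matrix has duplicate gene identifiers")
    if len(expr.index) < 2:
        raise ValueError("expression matrix needs at least 2 genes")
    out = pd.DataFrame(index=expr.columns, columns=list(sets), dtype=float)
    for set_name, genes in sets.items():
        for sample in expr.columns:
            try:
                out.loc[sample, set_name] = ssgsea_score(
                    expr[sample], genes, alpha=alpha)
            except ValueError:
                out.loc[sample, set_name] = np.nan
    return out
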