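"""Shared-enhancer detection and the Var I / Var II subtype split.

An enhancer is *Shared* when it links to the same gene in strictly more
than half of all cell types (at even M, exactly M/2 is not Shared). Var
genes that pass an expression filter are classified Var I when they have
at least one Shared enhancer and Var II otherwise; genes whose maximum
expression never exceeds the threshold (default TPM <= 1) or that lack
expression data altogether are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from eselect.selectivity import EPMatrix

__all__ = [
    "detect_shared",
    "shared_enhancers_by_gene",
    "expression_filter",
    "assign_var_subtypes",
    "quantile_normalize",
]


def detect_shared(matrix: EPMatrix) -> set[str]:
    """Enhancer ids linked to the gene in strictly more than half of cell types."""
    half = matrix.M / 2
    return {
        eid for eid, m in zip(matrix.enhancer_ids, matrix.m) if m > half
    }


def shared_enhancers_by_gene(
    interactions: pd.DataFrame, M: int
) -> dict[str, set[str]]:
    """Per-gene Shared enhancer sets computed directly from an interaction table.

    ``M`` is the total number of cell types in the dataset (it cannot be
    inferred per gene because cell types with no interaction still count).
    """
    dedup = interactions.drop_duplicates(subset=["gene", "enhancer_id", "cell_type"])
    counts = dedup.groupby(["gene", "enhancer_id"], sort=False).size()
    shared = counts[counts > M / 2]
    out: dict[str, set[str]] = {g: set() for g in dedup["gene"].unique()}
    for (gene, eid), _ in shared.items():
        out[gene].add(eid)
    return out


def expression_filter(
    expr: pd.DataFrame,
    gene: str,
    tpm_min: float = 1.0,
    inclusive: bool = True,
) -> bool:
    """Whether a gene passes the expression filter (True = keep).

    A gene fails when it is missing from the table or when its maximum
    expression over all cell types is <= ``tpm_min`` (``inclusive=True``,
    default) or < ``tpm_min`` (``inclusive=False``).
    """
    if gene not in expr.index:
        return False
    peak = float(np.nanmax(expr.loc[gene].to_numpy(dtype=float)))
    if np.isnan(peak):
        return False
    return peak > tpm_min if inclusive else peak >= tpm_min


def assign_var_subtypes(
    var_genes,
    interactions: pd.DataFrame,
    expr: pd.DataFrame,
    M: int,
    tpm_min: float = 1.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Split Var-pattern genes into Var I / Var II / excluded.

    A gene is ``excluded`` when it fails :func:`expression_filter`,
    ``VarI`` when it carries at least one Shared enhancer, ``VarII``
    otherwise. Returns one row per gene with columns
    ``gene, subtype, n_shared, shared_enhancer_ids``.

    Raises
    ------
    ValueError
        If a Var gene has no interactions (inconsistent inputs).
    """
    var_genes = list(var_genes)
    shared = shared_enhancers_by_gene(
        interactions[interactions["gene"].isin(set(var_genes))], M
    )
    rows = []
    for gene in var_genes:
        if gene not in shared:
            raise ValueError(f"Var gene {gene!r} has no interactions")
        ids = sorted(shared[gene])
        if not expression_filter(expr, gene, tpm_min=tpm_min, inclusive=inclusive):
            subtype = "excluded"
        elif ids:
            subtype = "VarI"
        else:
            subtype = "VarII"
        rows.append((gene, subtype, len(ids), ",".join(ids)))
    return pd.DataFrame(
        rows, columns=["gene", "subtype", "n_shared", "shared_enhancer_ids"]
    )


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Column-wise quantile normalization of an expression table.

    Each column's values are replaced by the mean, across columns, of the
    column-sorted values at the corresponding rank; tied values receive the
    mean over their rank range. After normalization every column carries
    the same sorted value multiset, and the operation is idempotent.
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[1] < 1:
        raise ValueError("expression table needs at least one column")
    rank_means = np.sort(values, axis=0).mean(axis=1)
    # prefix sums give the mean of rank_means over any tied rank range
    csum = np.concatenate([[0.0], np.cumsum(rank_means)])
    frame = pd.DataFrame(values)
    lo = frame.rank(method="min").to_numpy(dtype=int)  # 1-based
    hi = frame.rank(method="max").to_numpy(dtype=int)
    out = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
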