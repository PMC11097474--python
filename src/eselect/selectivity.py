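"""Per-gene binary E-P matrices and the SPE / SEL scoring metrics.

For a gene ``g`` observed across ``M`` cell types with ``N`` distinct
enhancers, the presence/absence of each enhancer-promoter link forms a
binary matrix ``x`` of shape ``M x N``. Two summary metrics follow:

* enhancer specificity ``SPE(e) = (M - m + 1) / M`` where ``m`` is the
  number of cell types in which enhancer ``e`` links to ``g`` — 1 for a
  fully cell-specific enhancer, ``1/M`` for a ubiquitous one;
* cell-type selectivity ``SEL(c) = n / N`` where ``n`` is the number of
  the gene's enhancers active in cell type ``c``.

The per-gene **SPE score** is the mean SPE over the gene's enhancers and
the **SEL score** is the relative standard deviation (sd / mean) of the
SEL values over all ``M`` cell types, zeros included. Because
``sum_j m_j = sum_i n_i``, the two scores obey the exact identity
``spe_score + mean(SEL) = (M + 1) / M``, which the test-suite exploits
as a cross-check of both formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EPMatrix",
    "GeneSelectivity",
    "build_matrix",
    "enhancer_spe",
    "cell_sel",
    "gene_scores",
    "score_all",
]


class SingleEnhancerGene(ValueError):
    """Raised when scoring is attempted for a gene with fewer than two enhancers."""


@dataclass
class EPMatrix:
    """Binary cell-type x enhancer presence matrix for one gene.

    Rows follow the dataset-wide cell-type order (including cell types with
    no interaction for this gene); columns are the gene's enhancers in
    genomic order.
    """

    gene: str
    cell_types: list[str]
    enhancer_ids: list[str]
    x: np.ndarray  # shape (M, N), values in {0, 1}

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int8)
        if self.x.shape != (len(self.cell_types), len(self.enhancer_ids)):
            raise ValueError("matrix shape does not match label lengths")

    @property
    def M(self) -> int:
        return len(self.cell_types)

    @property
    def N(self) -> int:
        return len(self.enhancer_ids)

    @property
    def m(self) -> np.ndarray:
        """Per-enhancer count of cell types with a link (column sums)."""
        return self.x.sum(axis=0)

    @property
    def n(self) -> np.ndarray:
        """Per-cell-type count of linked enhancers (row sums)."""
        return self.x.sum(axis=1)

    @property
    def T(self) -> int:
        """Total number of E-P interactions in the matrix."""
        return int(self.x.sum())


@dataclass
class GeneSelectivity:
    """SPE / SEL summary for one gene."""

    gene: str
    spe_per_enhancer: np.ndarray
    sel_per_cell: np.ndarray
    spe_score: float
    sel_score: float
    M: int = field(default=0)
    N: int = field(default=0)
    T: int = field(default=0)


def _genomic_sort_key(eid: str):
    chrom, _, span = eid.partition(":")
    start, _, end = span.partition("-")
    try:
        return (chrom, int(start), int(end))
    except ValueError:
        return (chrom, 0, 0)


def build_matrix(
    interactions: pd.DataFrame, gene: str, all_cell_types: list[str]
) -> EPMatrix:
    """Build the binary presence matrix for one gene.

    ``x[i, j] = 1`` iff an interaction (enhancer j, gene, cell type i)
    exists. Column order is the genomic order of enhancer ids; row order
    follows ``all_cell_types``. Construction is invariant to the input row
    order.
    """
    if not all_cell_types:
        raise ValueError("all_cell_types must be non-empty")
    sub = interactions[interactions["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} has no interactions")
    eids = sorted(sub["enhancer_id"].unique(), key=_genomic_sort_key)
    cell_index = {c: i for i, c in enumerate(all_cell_types)}
    eid_index = {e: j for j, e in enumerate(eids)}
    x = np.zeros((len(all_cell_types), len(eids)), dtype=np.int8)
    for eid, cell in zip(sub["enhancer_id"], sub["cell_type"]):
        if cell not in cell_index:
            raise ValueError(f"cell type {cell!r} absent from all_cell_types")
        x[cell_index[cell], eid_index[eid]] = 1
    return EPMatrix(gene=gene, cell_types=list(all_cell_types), enhancer_ids=eids, x=x)


def enhancer_spe(m: int, M: int) -> float:
    """Cell-type specificity of one enhancer: ``(M - m + 1) / M``."""
    if not 1 <= m <= M:
        raise ValueError(f"m must satisfy 1 <= m <= M, got m={m}, M={M}")
    return (M - m + 1) / M


def cell_sel(n: int, N: int) -> float:
    """Selectivity of one cell type: fraction ``n / N`` of the gene's enhancers."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError(f"n must satisfy 0 <= n <= N, got n={n}, N={N}")
    return n / N


def _rsd(values: np.ndarray, sd: str) -> float:
    ddof = 1 if sd == "sample" else 0
    mean = values.mean()
    return float(values.std(ddof=ddof) / mean)


def gene_scores(matrix: EPMatrix, sd: str = "sample") -> GeneSelectivity:
    """Compute the SPE score and SEL score for one gene's matrix.

    Parameters
    ----------
    matrix
        The gene's presence matrix; must have at least two enhancers
        (single-enhancer genes are excluded from pattern analysis).
    sd
        ``"sample"`` (ddof=1, default) or ``"population"`` (ddof=0)
        standard deviation in the relative-standard-deviation SEL score.
    """
    if sd not in ("sample", "population"):
        raise ValueError("sd must be 'sample' or 'population'")
    if matrix.N < 2:
        raise SingleEnhancerGene(
            f"gene {matrix.gene!r} has {matrix.N} enhancer(s); at least 2 required"
        )
    M = matrix.M
    m = matrix.m
    if (m < 1).any():
        raise ValueError("every enhancer column must have at least one interaction")
    spe = (M - m + 1) / M
    sel = matrix.n / matrix.N
    return GeneSelectivity(
        gene=matrix.gene,
        spe_per_enhancer=spe,
        sel_per_cell=sel,
        spe_score=float(spe.mean()),
        sel_score=_rsd(sel, sd),
        M=M,
        N=matrix.N,
        T=matrix.T,
    )


def score_all(
    interactions: pd.DataFrame,
    all_cell_types: list[str] | None = None,
    sd: str = "sample",
) -> tuple[pd.DataFrame, list[str]]:
    """Score every gene with at least two enhancers.

    Returns a ``(scores, excluded)`` pair: one row per scored gene with
    columns ``gene, M, N, T, spe_score, sel_score``, plus the list of
    single-enhancer genes that were excluded. When ``all_cell_types`` is
    not given it is taken as the sorted set of cell types present in the
    interactions.
    """
    if sd not in ("sample", "population"):
        raise ValueError("sd must be 'sample' or 'population'")
    cols = ["gene", "M", "N", "T", "spe_score", "sel_score"]
    if interactions.empty:
        return pd.DataFrame(columns=cols), []
    if all_cell_types is None:
        all_cell_types = sorted(interactions["cell_type"].unique())
    M = len(all_cell_types)
    ddof = 1 if sd == "sample" else 0

    dedup = interactions.drop_duplicates(subset=["gene", "enhancer_id", "cell_type"])
    rows, excluded = [], []
    for gene, sub in dedup.groupby("gene", sort=True):
        m = sub.groupby("enhancer_id", sort=False).size().to_numpy()
        N = len(m)
        if N < 2:
            excluded.append(gene)
            continue
        T = int(m.sum())
        spe_score = float(((M - m + 1) / M).mean())
        n = np.zeros(M, dtype=np.int64)
        counts = sub.groupby("cell_type", sort=False).size()
        cell_pos = {c: i for i, c in enumerate(all_cell_types)}
        for cell, cnt in counts.items():
            n[cell_pos[cell]] = cnt
        sel = n / N
        rows.append((gene, M, N, T, spe_score, float(sel.std(ddof=ddof) / sel.mean())))
    scores = pd.DataFrame(rows, columns=cols)
    return scores, excluded
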