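"""Synthetic E-P datasets with planted regulation-pattern structure.

The generator plants the four qualitative gene classes by construction so
every downstream stage has a known truth to recover:

* **Con** — every enhancer active in (almost) every cell type;
* **Spe** — all enhancers active only in a small fixed set of cells;
* **Var II** — each enhancer active in 1-3 private cells, so enhancers
  rarely co-occur in one cell type while their union spans many cells;
* **Var I** — Var II structure plus one "Shared" enhancer active in more
  than half of all cell types.

Each presence bit is then flipped with a small noise rate. Expression
values are coupled to the planted class (log-normal draws; Spe genes are
expressed only in their active cells). Generation is a pure function of
the spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from eselect.ep_io import enhancer_id

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "generate_snp_track",
    "make_score_blobs",
    "write_fixture",
]

_GENE_BLOCK = 100_000  # bp of genome reserved per gene
_DEFAULT_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults give a desk-scale 20-cell dataset."""

    M: int = 20
    genes_per_pattern: dict = field(
        default_factory=lambda: {"Spe": 50, "VarI": 50, "VarII": 50, "Con": 50}
    )
    enhancers_per_gene: tuple = (8, 15)
    p_active: float = 0.9
    noise_rate: float = 0.02
    spe_cell_count: int = 3
    shared_cell_fraction: float = 0.6
    genome: dict = field(default_factory=lambda: dict(_DEFAULT_GENOME))
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if not self.shared_cell_fraction > 0.5:
            raise ValueError("shared_cell_fraction must exceed 0.5")
        if not 1 <= self.spe_cell_count < self.M / 4:
            raise ValueError("spe_cell_count must satisfy 1 <= count < M/4")
        lo, hi = self.enhancers_per_gene
        if lo < 2 or hi < lo:
            raise ValueError("enhancers_per_gene must be a range with low end >= 2")
        n_genes = sum(self.genes_per_pattern.values())
        capacity = sum(size // _GENE_BLOCK for size in self.genome.values())
        if n_genes > capacity:
            raise ValueError(
                f"genome too small: {n_genes} genes need {n_genes * _GENE_BLOCK} bp"
            )


@dataclass
class SyntheticDataset:
    """Generated interactions, expression and the planted truth behind them."""

    interactions: pd.DataFrame
    expression: pd.DataFrame
    truth_genes: pd.DataFrame  # gene, pattern, subtype
    truth_enhancers: pd.DataFrame  # enhancer_id, gene, planted_class
    cell_types: list[str]
    tss: pd.DataFrame  # chrom, start, end, name (BED-like, start = TSS)
    genome: dict
    spec: SyntheticSpec


def _plant_matrix(
    pattern: str, M: int, N: int, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Noise-free activity matrix (M x N) and the planted Shared column (or -1)."""
    x = np.zeros((M, N), dtype=np.int8)
    shared_col = -1
    if pattern == "Con":
        x[:] = rng.random((M, N)) < spec.p_active
    elif pattern == "Spe":
        cells = rng.choice(M, size=spec.spe_cell_count, replace=False)
        x[cells] = rng.random((spec.spe_cell_count, N)) < spec.p_active
    else:  # VarI / VarII
        for j in range(N):
            k = rng.integers(1, 4)
            cells = rng.choice(M, size=k, replace=False)
            x[cells, j] = rng.random(k) < spec.p_active
        if pattern == "VarI":
            shared_col = int(rng.integers(N))
            n_shared_cells = math.ceil(spec.shared_cell_fraction * M)
            cells = rng.choice(M, size=n_shared_cells, replace=False)
            x[:, shared_col] = 0
            x[cells, shared_col] = 1
    return x, shared_col


def _expression_row(
    pattern: str, active_cells: np.ndarray, M: int, rng: np.random.Generator
) -> np.ndarray:
    if pattern in ("Con", "VarII"):
        return np.exp(rng.normal(np.log(50.0), 0.3, size=M))
    if pattern == "VarI":
        return np.exp(rng.normal(np.log(10.0), 0.8, size=M))
    row = np.zeros(M)
    row[active_cells] = np.exp(rng.normal(np.log(20.0), 0.5, size=len(active_cells)))
    return row


def generate_dataset(spec: SyntheticSpec | None = None, **overrides) -> SyntheticDataset:
    """Generate a full synthetic dataset from a spec (pure in spec + seed).

    Keyword overrides are applied to the (default) spec, e.g.
    ``generate_dataset(M=10, noise_rate=0.0)``.
    """
    spec = replace(spec or SyntheticSpec(), **overrides)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cell_types = [f"cell{c:02d}" for c in range(spec.M)]
    chroms = list(spec.genome)

    inter_rows, expr_rows, gene_rows, enh_rows, tss_rows = [], [], [], [], []
    gene_idx = 0
    lo, hi = spec.enhancers_per_gene
    for pattern in ("Spe", "VarI", "VarII", "Con"):
        for _ in range(spec.genes_per_pattern.get(pattern, 0)):
            chrom = chroms[gene_idx % len(chroms)]
            block = (gene_idx // len(chroms)) * _GENE_BLOCK
            gene = f"G{gene_idx:04d}"
            tss = block + 1000
            tss_rows.append((chrom, tss, tss + 1, gene))

            N = int(rng.integers(lo, hi + 1))
            x, shared_col = _plant_matrix(pattern, spec.M, N, spec, rng)
            active_cells = np.flatnonzero(x.any(axis=1))
            if spec.noise_rate > 0:
                flips = rng.random(x.shape) < spec.noise_rate
                x = np.where(flips, 1 - x, x).astype(np.int8)

            starts = block + 4000 + 1200 * np.arange(N)
            widths = rng.integers(200, 801, size=N)
            eids = [enhancer_id(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)]
            for j, eid in enumerate(eids):
                klass = "Shared" if j == shared_col else "Other"
                enh_rows.append((eid, gene, klass, chrom, int(starts[j]), int(starts[j] + widths[j])))
                for i in np.flatnonzero(x[:, j]):
                    inter_rows.append(
                        (chrom, int(starts[j]), int(starts[j] + widths[j]), eid, gene, cell_types[i])
                    )
            label = "Var" if pattern in ("VarI", "VarII") else pattern
            subtype = pattern if pattern in ("VarI", "VarII") else ""
            gene_rows.append((gene, label, subtype))
            expr_rows.append(_expression_row(pattern, active_cells, spec.M, rng))
            gene_idx += 1

    interactions = pd.DataFrame(
        inter_rows, columns=["chrom", "start", "end", "enhancer_id", "gene", "cell_type"]
    )
    truth_genes = pd.DataFrame(gene_rows, columns=["gene", "pattern", "subtype"])
    expression = pd.DataFrame(
        np.array(expr_rows), index=truth_genes["gene"], columns=cell_types
    )
    truth_enhancers = pd.DataFrame(
        enh_rows, columns=["enhancer_id", "gene", "planted_class", "chrom", "start", "end"]
    )
    tss = pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name"])
    return SyntheticDataset(
        interactions=interactions,
        expression=expression,
        truth_genes=truth_genes,
        truth_enhancers=truth_enhancers,
        cell_types=cell_types,
        tss=tss,
        genome=dict(spec.genome),
        spec=spec,
    )


def generate_snp_track(
    dataset: SyntheticDataset,
    odds_shared: float = 1.0,
    background_rate: float = 1e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Place SNPs at a Poisson background rate, boosted inside Shared enhancers.

    The per-base rate is ``background_rate`` genome-wide and
    ``odds_shared * background_rate`` inside planted Shared enhancers.
    Returns a frame with columns ``chrom, pos`` (0-based points).
    """
    if odds_shared < 1:
        raise ValueError("odds_shared must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size in dataset.genome.items():
        k = rng.poisson(background_rate * size)
        for pos in rng.integers(0, size, size=k):
            rows.append((chrom, int(pos)))
    extra_rate = background_rate * (odds_shared - 1.0)
    if extra_rate > 0:
        shared = dataset.truth_enhancers.query("planted_class == 'Shared'")
        for chrom, s, e in zip(shared["chrom"], shared["start"], shared["end"]):
            k = rng.poisson(extra_rate * (e - s))
            for pos in rng.integers(s, e, size=k):
                rows.append((chrom, int(pos)))
    return pd.DataFrame(rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], ignore_index=True
    )


def make_score_blobs(
    n_per: int = 50,
    centers: dict[str, tuple[float, float]] | None = None,
    sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian blobs directly in (spe_score, sel_score) space with truth labels.

    Default centers follow the qualitative geometry of the three patterns:
    Spe high SPE / high SEL score, Var high SPE / low SEL score, Con low
    SPE / low SEL score.
    """
    centers = centers or {"Spe": (0.95, 1.8), "Var": (0.9, 0.6), "Con": (0.3, 0.4)}
    rng = np.random.default_rng(seed)
    rows = []
    for label, (cx, cy) in centers.items():
        pts = rng.normal([cx, cy], sd, size=(n_per, 2))
        for i, (sx, sy) in enumerate(pts):
            rows.append((f"{label}_{i:03d}", float(sx), float(sy), label))
    return pd.DataFrame(rows, columns=["gene", "spe_score", "sel_score", "true_pattern"])


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write a dataset to disk in the plain-text formats the readers accept.

    Emits an ABC-style predictions TSV (with a constant score above the
    default threshold), a TPM table, truth tables, a TSS BED and a
    chrom.sizes file; re-reading the predictions through
    :func:`eselect.ep_io.read_abc_predictions` round-trips losslessly.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    pred = dataset.interactions.rename(
        columns={"chrom": "chr", "gene": "TargetGene", "cell_type": "CellType"}
    )[["chr", "start", "end", "TargetGene", "CellType"]]
    pred["ABC.Score"] = 0.05
    paths["predictions"] = str(out / "predictions.tsv")
    pred.to_csv(paths["predictions"], sep="\t", index=False)

    paths["expression"] = str(out / "tpm.tsv")
    dataset.expression.to_csv(paths["expression"], sep="\t", index_label="gene")

    paths["truth_genes"] = str(out / "truth_genes.tsv")
    dataset.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_enhancers"] = str(out / "truth_enhancers.tsv")
    dataset.truth_enhancers.to_csv(paths["truth_enhancers"], sep="\t", index=False)

    paths["tss"] = str(out / "tss.bed")
    dataset.tss.to_csv(paths["tss"], sep="\t", index=False, header=False)

    paths["genome"] = str(out / "chrom.sizes")
    with open(paths["genome"], "w") as fh:
        for chrom, size in dataset.genome.items():
            fh.write(f"{chrom}\t{size}\n")
    return paths
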