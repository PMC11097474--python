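"""I/O and interval arithmetic for enhancer-promoter interaction tables.

Interactions are held in a :class:`pandas.DataFrame` with the columns
``chrom, start, end, enhancer_id, gene, cell_type`` (plus ``abc_score``
when present). Coordinates are 0-based half-open throughout (BED
convention); ABC prediction tables are BED-derived and read as-is.
Overlap always means at least one shared base.
"""

from __future__ import annotations

import gzip
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TssAnnotation",
    "read_abc_predictions",
    "read_bed",
    "read_tss_bed",
    "merge_intervals",
    "unify_coordinates",
    "split_promoters_enhancers",
    "write_interactions",
    "enhancer_id",
]

#: canonical column names and the aliases accepted in ABC-style tables
_COLUMN_ALIASES = {
    "chrom": ("chrom", "chr", "chromosome", "#chr"),
    "start": ("start", "chromstart"),
    "end": ("end", "chromend", "stop"),
    "gene": ("gene", "targetgene", "target_gene", "genesymbol"),
    "cell_type": ("cell_type", "celltype", "cell", "biosample"),
    "abc_score": ("abc_score", "abc.score", "abcscore", "score"),
}

INTERACTION_COLUMNS = ["chrom", "start", "end", "enhancer_id", "gene", "cell_type"]


class GenomicInterval(NamedTuple):
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint of the interval."""
        return (self.start + self.end) // 2


class TssAnnotation(NamedTuple):
    """A transcription start site; one gene may have several (one per transcript)."""

    gene: str
    chrom: str
    tss: int
    strand: str = "+"


def enhancer_id(chrom: str, start: int, end: int) -> str:
    """Stable enhancer identifier derived from unified coordinates."""
    return f"{chrom}:{start}-{end}"


def _resolve_columns(columns: Sequence[str]) -> dict:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_abc_predictions(
    path,
    score_threshold: float = 0.015,
    cell_types: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read an ABC-style tab-separated prediction table into interactions.

    Rows are kept only when their score is strictly greater than
    ``score_threshold`` (pass ``score_threshold=None`` or a table without a
    score column to skip filtering), and, when ``cell_types`` is given, when
    their cell-type label is in that allow-list. Duplicate
    (enhancer, gene, cell type) rows collapse to one. The file may be
    gzip-compressed.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message) or a
        coordinate fails to parse (reported with its line number).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)

    resolved = _resolve_columns(df.columns)
    for required in ("chrom", "start", "end", "gene", "cell_type"):
        if required not in resolved:
            raise ValueError(f"required column missing from {path!s}: {required!r}")
    out = pd.DataFrame(
        {canon: df[resolved[canon]] for canon in resolved if canon in resolved}
    )

    for coord in ("start", "end"):
        parsed = pd.to_numeric(out[coord], errors="coerce")
        bad = parsed.isna() & out[coord].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"unparseable {coord} coordinate at line {line}: {out[coord].iloc[line - 2]!r}"
            )
        out[coord] = parsed.astype(np.int64)

    if "abc_score" in out.columns:
        out["abc_score"] = pd.to_numeric(out["abc_score"], errors="coerce")
        if score_threshold is not None:
            out = out[out["abc_score"] > score_threshold]

    if cell_types is not None:
        allowed = set(cell_types)
        out = out[out["cell_type"].isin(allowed)]

    out = out.drop_duplicates(subset=["chrom", "start", "end", "gene", "cell_type"])
    out = out.reset_index(drop=True)
    out["enhancer_id"] = [
        enhancer_id(c, s, e) for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    cols = INTERACTION_COLUMNS + (["abc_score"] if "abc_score" in out.columns else [])
    return out[cols]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a ``chrom/start/end[/name/score/strand]`` frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_tss_bed(path) -> list[TssAnnotation]:
    """Read TSS annotations from BED (start column = TSS position, name = gene)."""
    df = read_bed(path)
    strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        TssAnnotation(gene=str(name), chrom=str(chrom), tss=int(start), strand=str(strand))
        for chrom, start, name, strand in zip(df["chrom"], df["start"], df["name"], strands)
    ]


def _as_interval_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals[["chrom", "start", "end"]].copy()
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals],
        columns=["chrom", "start", "end"],
    )


def merge_intervals(intervals) -> pd.DataFrame:
    """Merge overlapping and book-ended intervals into a non-overlapping set.

    Book-ended intervals (``end == next start``) merge, mirroring
    distance-0 ``bedtools merge`` semantics. Output is sorted by
    (chrom, start) and covers exactly the union of input bases.

    Accepts a DataFrame with ``chrom/start/end`` or an iterable of
    :class:`GenomicInterval`; returns a DataFrame.
    """
    df = _as_interval_frame(intervals)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                rows.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    rows.append((cur_chrom, cur_start, cur_end))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def unify_coordinates(
    interactions: pd.DataFrame, merged: pd.DataFrame
) -> pd.DataFrame:
    """Replace every interaction's enhancer by the merged peak containing it.

    ``merged`` must come from :func:`merge_intervals` over the union of all
    enhancer intervals, so each original peak is contained in exactly one
    merged peak. Interactions whose peaks fell in the same merged peak end
    up sharing an ``enhancer_id``; duplicates created this way collapse.

    Raises
    ------
    ValueError
        If some enhancer interval is not contained in any merged interval.
    """
    out = interactions.copy()
    new_start = np.empty(len(out), dtype=np.int64)
    new_end = np.empty(len(out), dtype=np.int64)
    for chrom, idx in out.groupby("chrom", sort=False).indices.items():
        m = merged[merged["chrom"] == chrom]
        if m.empty:
            raise ValueError(f"no merged intervals on {chrom}; inconsistent merge input")
        starts = m["start"].to_numpy()
        ends = m["end"].to_numpy()
        pos = np.searchsorted(starts, out["start"].to_numpy()[idx], side="right") - 1
        ok = (pos >= 0) & (out["end"].to_numpy()[idx] <= ends[np.clip(pos, 0, None)])
        if not ok.all():
            bad = out.iloc[idx[~ok][0]]
            raise ValueError(
                f"enhancer {bad['chrom']}:{bad['start']}-{bad['end']} not contained "
                "in any merged interval"
            )
        new_start[idx] = starts[pos]
        new_end[idx] = ends[pos]
    out["start"] = new_start
    out["end"] = new_end
    out["enhancer_id"] = [
        enhancer_id(c, s, e) for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    out = out.drop_duplicates(subset=["enhancer_id", "gene", "cell_type"])
    return out.reset_index(drop=True)


def split_promoters_enhancers(
    peaks,
    tss: Iterable[TssAnnotation],
    flank_bp: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition peaks into (enhancers, promoter_peaks) by TSS proximity.

    A peak overlapping any window of ``tss - flank_bp .. tss + flank_bp``
    (inclusive of both ends, i.e. 2*flank_bp + 1 bases) by at least one
    base is a promoter peak; all others are enhancers. Windows are
    symmetric around the TSS regardless of strand.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    df = _as_interval_frame(peaks) if not isinstance(peaks, pd.DataFrame) else peaks.copy()
    windows = pd.DataFrame(
        [(t.chrom, max(0, t.tss - flank_bp), t.tss + flank_bp + 1) for t in tss],
        columns=["chrom", "start", "end"],
    )
    windows = merge_intervals(windows)
    is_promoter = np.zeros(len(df), dtype=bool)
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        w = windows[windows["chrom"] == chrom]
        if w.empty:
            continue
        ws = w["start"].to_numpy()
        we = w["end"].to_numpy()
        ps = df["start"].to_numpy()[idx]
        pe = df["end"].to_numpy()[idx]
        # window index whose end is first to exceed the peak start
        pos = np.searchsorted(we, ps, side="right")
        hit = (pos < len(ws)) & (ws[np.clip(pos, 0, len(ws) - 1)] < pe)
        is_promoter[idx] = hit
    enhancers = df[~is_promoter].reset_index(drop=True)
    promoters = df[is_promoter].reset_index(drop=True)
    return enhancers, promoters


def write_interactions(interactions: pd.DataFrame, path) -> None:
    """Write unified interactions as TSV (chrom, start, end, enhancer_id, gene, cell_type)."""
    cols = [c for c in INTERACTION_COLUMNS if c in interactions.columns]
    interactions[cols].to_csv(path, sep="\t", index=False)
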