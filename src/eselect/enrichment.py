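"""Interval-overlap statistics: SNP enrichment, SE overlap, distances, signal.

SNP enrichment compares the fraction of enhancers containing at least one
SNP against the same fraction in random genomic control regions:

    fold = (hits_obs / total_obs) / (hits_ctrl / total_ctrl)

with a one-sided (upper-tail) binomial test of ``hits_obs`` successes in
``total_obs`` trials at success probability ``hits_ctrl / total_ctrl``.
Before counting, enhancers and controls are unified to a common length
(default 500 bp around the floor-midpoint center). Controls are drawn
uniformly over the genome excluding a supplied interval set (typically
promoters); chromosomes are not matched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from eselect.ep_io import GenomicInterval, merge_intervals

__all__ = [
    "EnrichmentResult",
    "unify_length",
    "sample_random_regions",
    "count_hits",
    "snp_enrichment",
    "se_overlap_fractions",
    "ep_distance",
    "mean_signal_over_intervals",
]


@dataclass
class EnrichmentResult:
    """SNP-overlap contingency for an enhancer set versus genomic controls."""

    hits_obs: int
    total_obs: int
    hits_ctrl: int
    total_ctrl: int
    fold: float
    p_value: float
    ctrl_rate_zero: bool = False


def unify_length(intervals: pd.DataFrame, target_len: int = 500) -> pd.DataFrame:
    """Recenter every interval to ``target_len`` bp around its floor midpoint.

    The new span is ``[center - target_len/2, center + target_len/2)``;
    a negative low end is clipped to 0 without re-expanding the high end.
    """
    if target_len <= 0 or target_len % 2:
        raise ValueError("target_len must be even and positive")
    half = target_len // 2
    out = intervals.copy()
    center = (out["start"].to_numpy(np.int64) + out["end"].to_numpy(np.int64)) // 2
    out["start"] = np.maximum(center - half, 0)
    out["end"] = center + half
    return out


def sample_random_regions(
    genome_sizes: dict[str, int],
    exclude: pd.DataFrame | None,
    n_regions: int,
    length_bp: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample fixed-length regions uniformly over a genome, avoiding `exclude`.

    Placement is uniform over all valid start positions (those whose
    region fits in a gap between excluded intervals and chromosome ends);
    positions are drawn independently, so regions may overlap each other.
    Deterministic for a given seed.

    Raises
    ------
    ValueError
        If no gap can hold a region of ``length_bp``.
    """
    rng = np.random.default_rng(seed)
    gaps = []  # (chrom, gap_start, n_valid_starts)
    excl = (
        merge_intervals(exclude)
        if exclude is not None and len(exclude)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    for chrom, size in genome_sizes.items():
        e = excl[excl["chrom"] == chrom]
        edges = [0]
        for s, t in zip(e["start"], e["end"]):
            edges.extend([int(s), int(t)])
        edges.append(int(size))
        for gs, ge in zip(edges[::2], edges[1::2]):
            n_starts = ge - gs - length_bp + 1
            if n_starts > 0:
                gaps.append((chrom, gs, n_starts))
    if not gaps:
        raise ValueError("no eligible genomic space for the requested region length")
    weights = np.array([g[2] for g in gaps], dtype=float)
    picks = rng.choice(len(gaps), size=n_regions, p=weights / weights.sum())
    offsets = rng.integers(0, weights[picks].astype(np.int64))
    rows = [
        (gaps[g][0], gaps[g][1] + off, gaps[g][1] + off + length_bp)
        for g, off in zip(picks, offsets)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_hits(regions: pd.DataFrame, snps: pd.DataFrame) -> int:
    """Number of regions containing >= 1 SNP position (half-open containment).

    ``snps`` is a frame with ``chrom`` and either ``pos`` (0-based point)
    or BED-style ``start``.
    """
    pos_col = "pos" if "pos" in snps.columns else "start"
    hits = 0
    by_chrom = {c: np.sort(g[pos_col].to_numpy(np.int64)) for c, g in snps.groupby("chrom")}
    for chrom, sub in regions.groupby("chrom", sort=False):
        pos = by_chrom.get(chrom)
        if pos is None:
            continue
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        hits += int((np.searchsorted(pos, e, "left") > np.searchsorted(pos, s, "left")).sum())
    return hits


def snp_enrichment(
    enhancers: pd.DataFrame,
    snps: pd.DataFrame,
    controls: pd.DataFrame,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fold enrichment of SNP-containing enhancers over genomic controls.

    Inputs are expected to be length-unified already (see
    :func:`unify_length`). When no control region contains a SNP the fold
    change is undefined and reported as NaN with a warning; the p-value is
    still the exact binomial tail at the (zero) control rate.
    """
    hits_obs = count_hits(enhancers, snps)
    hits_ctrl = count_hits(controls, snps)
    total_obs, total_ctrl = len(enhancers), len(controls)
    if hits_ctrl > 0:
        fold = (hits_obs / total_obs) / (hits_ctrl / total_ctrl)
        zero = False
    else:
        warnings.warn(
            "control SNP hit count is zero; fold change undefined (NaN)", stacklevel=2
        )
        fold = float("nan")
        zero = True
    p_ctrl = hits_ctrl / total_ctrl
    p_value = binomtest(hits_obs, total_obs, p_ctrl, alternative=alternative).pvalue
    return EnrichmentResult(
        hits_obs=hits_obs,
        total_obs=total_obs,
        hits_ctrl=hits_ctrl,
        total_ctrl=total_ctrl,
        fold=fold,
        p_value=float(p_value),
        ctrl_rate_zero=zero,
    )


def _overlaps_any(sub: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each interval in `sub` overlap >= 1 bp of `track`."""
    out = np.zeros(len(sub), dtype=bool)
    merged = merge_intervals(track)
    for chrom, idx in sub.groupby("chrom", sort=False).indices.items():
        t = merged[merged["chrom"] == chrom]
        if t.empty:
            continue
        ts = t["start"].to_numpy(np.int64)
        te = t["end"].to_numpy(np.int64)
        s = sub["start"].to_numpy(np.int64)[idx]
        e = sub["end"].to_numpy(np.int64)[idx]
        pos = np.searchsorted(te, s, side="right")
        out[idx] = (pos < len(ts)) & (ts[np.clip(pos, 0, len(ts) - 1)] < e)
    return out


def se_overlap_fractions(
    enhancers_by_pattern: dict[str, pd.DataFrame],
    se_regions: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-cell-type share (in %) of SE-overlapping enhancers by pattern.

    For each cell type, counts the enhancers of every pattern overlapping
    any super-enhancer, then scales the per-pattern counts to sum to 100%.
    A cell type with no overlapping enhancer in any pattern gets NaN shares
    and ``flagged=True``.
    """
    patterns = list(enhancers_by_pattern)
    rows = []
    for cell, se in se_regions.items():
        counts = {
            p: int(_overlaps_any(enh, se).sum()) for p, enh in enhancers_by_pattern.items()
        }
        total = sum(counts.values())
        if total == 0:
            shares = {p: float("nan") for p in patterns}
            flagged = True
        else:
            shares = {p: 100.0 * counts[p] / total for p in patterns}
            flagged = False
        rows.append({"cell_type": cell, **shares, "flagged": flagged})
    return pd.DataFrame(rows)


def ep_distance(enhancer: GenomicInterval, tss: int, tss_chrom: str | None = None) -> int:
    """Distance in bp from the enhancer's floor-midpoint center to a TSS."""
    if tss_chrom is not None and tss_chrom != enhancer.chrom:
        raise ValueError(
            f"enhancer on {enhancer.chrom} but TSS on {tss_chrom}: distance undefined"
        )
    return abs(enhancer.center - tss)


def mean_signal_over_intervals(
    intervals: pd.DataFrame, signal: pd.DataFrame
) -> np.ndarray:
    """Per-interval mean of a per-base step signal (bedGraph-style records).

    ``signal`` holds non-overlapping records ``chrom/start/end/value``;
    the mean is taken over covered bases only — bases without a record
    contribute to neither numerator nor denominator, and an interval with
    no covered base yields NaN.
    """
    result = np.full(len(intervals), np.nan)
    for chrom, idx in intervals.groupby("chrom", sort=False).indices.items():
        rec = signal[signal["chrom"] == chrom].sort_values("start")
        if rec.empty:
            continue
        rs = rec["start"].to_numpy(np.int64)
        re_ = rec["end"].to_numpy(np.int64)
        rv = rec["value"].to_numpy(float)
        starts = intervals["start"].to_numpy(np.int64)[idx]
        ends = intervals["end"].to_numpy(np.int64)[idx]
        for k, (s, e) in enumerate(zip(starts, ends)):
            lo = np.searchsorted(re_, s, side="right")
            hi = np.searchsorted(rs, e, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(re_[lo:hi], e) - np.maximum(rs[lo:hi], s)
            covered = int(ov.sum())
            if covered > 0:
                result[idx[k]] = float((ov * rv[lo:hi]).sum() / covered)
    return result
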