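"""Sex-chromosome assembly coverage and haplotype-resolved methylation.

Window coverage: the chromosome is partitioned into fixed windows
(default 1 Mbp); a window qualifies when the union of contig alignment
blocks covers at least ``min_align_fraction`` (default 95%) of its
unmasked length and no more than ``max_contigs`` (default 3) distinct
contigs overlap it.  Windows lying entirely inside the exclusion mask
(PAR, centromere, Yq12) leave the denominator.

XCI skew: per CpG island (with flanks), the mean methylated fraction is
computed for each haplotype; a chromosome is called skewed when the mean
haplotype difference exceeds a threshold with most islands agreeing in
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from svsieve.io import PafRecord
from svsieve.types import ExclusionMask


@dataclass(frozen=True)
class CoverageParams:
    window: int = 1_000_000
    min_align_fraction: float = 0.95
    max_contigs: int = 3
    mask: Optional[ExclusionMask] = None

    def __post_init__(self):
        if not (0 < self.min_align_fraction <= 1):
            raise ValueError("min_align_fraction must lie in (0, 1]")
        if self.max_contigs < 1:
            raise ValueError("max_contigs must be >= 1")


@dataclass
class WindowResult:
    start: int
    end: int
    assessed: bool  # False when fully masked
    covered_fraction: float
    n_contigs: int
    qualified: bool


def _masked_length(mask: Optional[ExclusionMask], chrom: str, start: int, end: int) -> int:
    if mask is None:
        return 0
    total = 0
    for s, e in mask.intervals.get(chrom, []):
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            total += hi - lo
    return total


def _union_unmasked(
    blocks: list[tuple[int, int]], mask: Optional[ExclusionMask], chrom: str,
    start: int, end: int,
) -> int:
    """Length of (union of blocks) intersect [start, end) minus masked bases."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in blocks if min(e, end) > max(s, start)
    )
    merged: list[list[int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for s, e in merged:
        total += (e - s) - _masked_length(mask, chrom, s, e)
    return total


def window_coverage(
    alignments: Sequence[PafRecord],
    chrom: str,
    chrom_length: int,
    params: Optional[CoverageParams] = None,
) -> tuple[list[WindowResult], float]:
    """Qualified-window flags and the chromosome coverage percentage.

    The percentage is qualified windows / assessed windows * 100.  Raises
    when no window is assessable (chromosome fully masked or zero length).
    """
    params = params or CoverageParams()
    aln = [a for a in alignments if a.tname == chrom]
    results: list[WindowResult] = []
    n_assessed = n_qualified = 0
    for wstart in range(0, chrom_length, params.window):
        wend = min(wstart + params.window, chrom_length)
        wlen = wend - wstart
        masked = _masked_length(params.mask, chrom, wstart, wend)
        unmasked = wlen - masked
        if unmasked <= 0:
            results.append(WindowResult(wstart, wend, False, 0.0, 0, False))
            continue
        blocks = [(a.tstart, a.tend) for a in aln if a.tend > wstart and a.tstart < wend]
        contigs = {a.qname for a in aln if a.tend > wstart and a.tstart < wend}
        covered = _union_unmasked(blocks, params.mask, chrom, wstart, wend)
        frac = covered / unmasked
        ok = frac >= params.min_align_fraction and len(contigs) <= params.max_contigs
        results.append(WindowResult(wstart, wend, True, frac, len(contigs), ok))
        n_assessed += 1
        n_qualified += int(ok)
    if n_assessed == 0:
        raise ValueError(f"no assessable windows on {chrom}")
    return results, 100.0 * n_qualified / n_assessed


# ---------------------------------------------------------------------------
# methylation skew

@dataclass
class SkewResult:
    per_island: pd.DataFrame  # island_id, chrom, start, end, mean_hap1, mean_hap2, diff, n_cpg
    mean_difference: float  # hap1 - hap2 over covered islands
    frac_hap1_higher: float
    frac_hap2_higher: float
    n_islands: int
    n_excluded: int


def methylation_skew(
    hap1_pileup: pd.DataFrame,
    hap2_pileup: pd.DataFrame,
    cpg_islands: pd.DataFrame,
    flank: int = 5_000,
) -> SkewResult:
    """Per-island haplotype methylation means over island +/- flank.

    Pileups are bedMethyl-style frames (chrom/start/end/.../frac, fractions
    in [0, 1]); ``cpg_islands`` is a BED frame.  Islands with zero covered
    CpGs on either haplotype are excluded from the chromosome summary.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rows = []
    n_excluded = 0
    for i, isl in enumerate(cpg_islands.itertuples()):
        lo, hi = int(isl.start) - flank, int(isl.end) + flank
        means = []
        ns = []
        for pile in (hap1_pileup, hap2_pileup):
            sel = pile[(pile["chrom"] == isl.chrom) & (pile["start"] >= lo) & (pile["start"] < hi)]
            ns.append(len(sel))
            means.append(float(sel["frac"].mean()) if len(sel) else np.nan)
        if 0 in ns:
            n_excluded += 1
            continue
        rows.append({
            "island_id": getattr(isl, "name", None) or f"CpGI_{i}",
            "chrom": isl.chrom, "start": int(isl.start), "end": int(isl.end),
            "mean_hap1": means[0], "mean_hap2": means[1],
            "diff": means[0] - means[1], "n_cpg": min(ns),
        })
    if not rows:
        raise ValueError("no CpG island has coverage on both haplotypes")
    per_island = pd.DataFrame(rows)
    diffs = per_island["diff"].to_numpy()
    return SkewResult(
        per_island=per_island,
        mean_difference=float(diffs.mean()),
        frac_hap1_higher=float((diffs > 0).mean()),
        frac_hap2_higher=float((diffs < 0).mean()),
        n_islands=len(per_island),
        n_excluded=n_excluded,
    )


def xci_call(
    skew: SkewResult,
    threshold: float = 0.25,
    agreement: float = 0.80,
    hap1_parent: str = "paternal",
    hap2_parent: str = "maternal",
) -> str:
    """'paternal_skewed' / 'maternal_skewed' / 'balanced'.

    Skewed requires |mean difference| >= threshold with >= ``agreement`` of
    islands agreeing in direction.  The hypermethylated (inactive) haplotype
    names the call: hap1 hypermethylated => hap1's parent-of-origin X is
    preferentially inactivated.
    """
    d = skew.mean_difference
    if abs(d) >= threshold:
        if d > 0 and skew.frac_hap1_higher >= agreement:
            return f"{hap1_parent}_skewed"
        if d < 0 and skew.frac_hap2_higher >= agreement:
            return f"{hap2_parent}_skewed"
    return "balanced"
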