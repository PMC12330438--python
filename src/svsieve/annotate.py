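"""Functional annotation of rare SVs against interval tracks.

An SV's footprint ([pos-1, end) for DEL, the insertion-point base for INS)
is intersected (>= 1 bp) with gene-model and regulatory tracks.  The
primary class is assigned by precedence Exon > UTR > Intron > Inter;
independent boolean flags mark overlap with NDD-gene, regulatory (REG),
brain-derived regulatory (brainREG), tandem-repeat (TR) and segmental-
duplication (SegDup) tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from svsieve.types import SVRecord

PRIMARY_PRECEDENCE = ("Exon", "UTR", "Intron", "Inter")
FLAG_CLASSES = ("NDD", "REG", "brainREG", "TR", "SegDup")


@dataclass
class AnnotationTrack:
    """A named interval track (0-based half-open, per-chromosome)."""

    name: str
    cls: str  # exon | utr | intron | promoter | enhancer | tf_cluster | cpg_island | tr | segdup | custom
    intervals: dict[str, list[tuple]] = field(default_factory=dict)
    # each interval tuple: (start, end) or (start, end, gene_label)

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in self.intervals.items():
            tree = IntervalTree()
            for iv in sorted(ivs):
                start, end = iv[0], iv[1]
                if start < 0 or end <= start:
                    raise ValueError(f"bad interval {iv} on {chrom} in track {self.name}")
                label = iv[2] if len(iv) > 2 else None
                tree[start:end] = label
            self._trees[chrom] = tree

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(start, end), key=lambda i: (i.begin, i.end))

    @classmethod
    def from_bed(cls, name: str, track_class: str, bed_df) -> "AnnotationTrack":
        intervals: dict[str, list[tuple]] = {}
        has_name = "name" in bed_df.columns
        for row in bed_df.itertuples():
            label = getattr(row, "name", None) if has_name else None
            intervals.setdefault(row.chrom, []).append((int(row.start), int(row.end), label))
        return cls(name=name, cls=track_class, intervals=intervals)


@dataclass(frozen=True)
class FunctionalLabel:
    primary_class: str  # Exon | UTR | Intron | Inter
    flags: frozenset = frozenset()
    genes: tuple = ()

    def __post_init__(self):
        if self.primary_class not in PRIMARY_PRECEDENCE:
            raise ValueError(f"bad primary class {self.primary_class!r}")


#: which track classes feed each primary class / flag
_PRIMARY_FOR_CLASS = {"exon": "Exon", "utr": "UTR", "intron": "Intron"}
_FLAG_FOR_CLASS = {
    "promoter": "REG",
    "enhancer": "REG",
    "tf_cluster": "REG",
    "brain_reg": "brainREG",
    "tr": "TR",
    "segdup": "SegDup",
    "ndd_gene": "NDD",
}


def intersect(sv: SVRecord, tracks: Sequence[AnnotationTrack]) -> FunctionalLabel:
    """Assign the functional label of one SV from >= 1 bp track overlaps."""
    start, end = sv.interval0()
    hit_primary: set[str] = set()
    flags: set[str] = set()
    genes: list[str] = []
    for track in tracks:
        hits = track.overlapping(sv.chrom, start, end)
        if not hits:
            continue
        if track.cls in _PRIMARY_FOR_CLASS:
            hit_primary.add(_PRIMARY_FOR_CLASS[track.cls])
        if track.cls in _FLAG_FOR_CLASS:
            flags.add(_FLAG_FOR_CLASS[track.cls])
        for h in hits:
            if h.data:
                genes.append(str(h.data))
    primary = next((p for p in PRIMARY_PRECEDENCE[:-1] if p in hit_primary), "Inter")
    seen = set()
    uniq_genes = tuple(g for g in genes if not (g in seen or seen.add(g)))
    return FunctionalLabel(primary_class=primary, flags=frozenset(flags), genes=uniq_genes)


def annotate_all(
    svs: Sequence[SVRecord], tracks: Sequence[AnnotationTrack]
) -> dict[str, FunctionalLabel]:
    return {sv.id: intersect(sv, tracks) for sv in svs}


def reg_gain(
    labels_without: dict[str, FunctionalLabel],
    labels_with: dict[str, FunctionalLabel],
) -> float:
    """Fractional increase in regulatory SV count from the brain track.

    ``(count(REG u brainREG) - count(REG)) / count(REG)`` over a labelled
    SV set; 0.0 when the brain track adds nothing, and 0.0 by convention
    when there are no baseline regulatory SVs at all.
    """
    base = sum(1 for l in labels_without.values() if "REG" in l.flags)
    both = sum(1 for l in labels_with.values() if l.flags & {"REG", "brainREG"})
    if base == 0:
        return 0.0
    return (both - base) / base
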