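"""Shared domain types and coordinate conventions.

Coordinates are 1-based (VCF convention) on :class:`SVRecord` fields and
0-based half-open everywhere intervals are manipulated; the conversion
happens in exactly one place (`SVRecord.interval0`) so interval arithmetic
never mixes conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

logger = logging.getLogger("svsieve")

#: caller labels: one assembly-based caller validated by two alignment-based ones
ASSEMBLY = "assembly"
ALIGNER_A = "aligner_a"
ALIGNER_B = "aligner_b"
ALL_CALLERS = (ASSEMBLY, ALIGNER_A, ALIGNER_B)

MIN_SVLEN = 50  # an SV affects >= 50 bp by definition


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant allele (DEL or INS).

    ``pos`` is the 1-based reference position; for a DEL, ``end`` is the
    1-based inclusive end (``pos + svlen``); for an INS the variant is a
    point event and ``end == pos``.  ``seq`` carries the inserted sequence
    for an INS (mandatory in simulated data) and optionally the deleted
    reference sequence for a DEL.
    """

    id: str
    chrom: str
    pos: int
    svtype: str  # "DEL" | "INS"
    svlen: int
    qual: float = 0.0
    seq: Optional[str] = None
    callers: frozenset = field(default_factory=frozenset)
    sample: Optional[str] = None

    def __post_init__(self):
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"unsupported SVTYPE {self.svtype!r} (only DEL/INS)")
        if self.svlen < 1:
            raise ValueError(f"svlen must be positive, got {self.svlen}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        if self.seq is not None and self.svtype == "INS" and len(self.seq) != self.svlen:
            raise ValueError(
                f"INS sequence length {len(self.seq)} != svlen {self.svlen} for {self.id}"
            )

    @property
    def end(self) -> int:
        """1-based inclusive end: pos + svlen for DEL, pos for INS."""
        return self.pos + self.svlen if self.svtype == "DEL" else self.pos

    def interval0(self) -> tuple[int, int]:
        """Affected reference footprint ``[pos-1, end)``, 0-based half-open.

        A DEL spans its anchor base through the deleted stretch; an INS is a
        point event whose footprint is the single base at the insertion
        site, ``[pos-1, pos)``.
        """
        return (self.pos - 1, self.end)

    def with_sample(self, sample: str) -> "SVRecord":
        return replace(self, sample=sample)


@dataclass(frozen=True)
class Genotype:
    """A genotype call at one SV locus.

    ``alleles`` holds 0 (ref), 1 (alt) or None (missing); length equals
    ``ploidy``.  Hemizygous calls (male non-PAR chrX, male chrY) have
    ploidy 1.
    """

    alleles: tuple
    phased: bool = False

    def __post_init__(self):
        if len(self.alleles) not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        for a in self.alleles:
            if a not in (0, 1, None):
                raise ValueError(f"allele must be 0/1/None, got {a!r}")

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.alleles if a == 1)

    @property
    def has_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_hom_alt(self) -> bool:
        return self.ploidy == 2 and self.n_alt == 2

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.n_alt == 1 and None not in self.alleles

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


GT_MISSING_DIP = Genotype((None, None))
GT_REF_DIP = Genotype((0, 0))
GT_HET = Genotype((0, 1))
GT_HOM = Genotype((1, 1))
GT_HEMI_REF = Genotype((0,))
GT_HEMI_ALT = Genotype((1,))
GT_HEMI_MISSING = Genotype((None,))


@dataclass(frozen=True)
class MergeParams:
    """Thresholds for deciding that two SV calls are the same allele.

    Mirrors the conventional merge flags by name: ``refdist`` is the
    maximum breakpoint distance, ``pctsize`` the minimum reciprocal size
    ratio, ``pctseq`` the minimum sequence identity (skipped when either
    sequence is absent).
    """

    pctseq: float = 0.90
    pctsize: float = 0.90
    refdist: int = 500
    sizemin: int = 0
    sizemax: int = 1_000_000
    keep_rule: str = "maxqual"  # or "common": representative carried by most samples

    def __post_init__(self):
        if not (0.0 <= self.pctsize <= 1.0 and 0.0 <= self.pctseq <= 1.0):
            raise ValueError("pctseq/pctsize must lie in [0, 1]")
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        if self.sizemin > self.sizemax:
            raise ValueError("sizemin must not exceed sizemax")
        if self.keep_rule not in ("maxqual", "common"):
            raise ValueError(f"unknown keep_rule {self.keep_rule!r}")


@dataclass(frozen=True)
class PedigreeEntry:
    sample_id: str
    family_id: str
    role: str  # father | mother | proband | sibling
    sex: str  # male | female
    affected: bool
    superpop: str = "non-AFR"  # AFR | non-AFR

    def __post_init__(self):
        if self.role not in ("father", "mother", "proband", "sibling"):
            raise ValueError(f"bad role {self.role!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r}")

    @property
    def is_child(self) -> bool:
        return self.role in ("proband", "sibling")


class Pedigree:
    """Family structure for a cohort of trios and quads."""

    def __init__(self, entries: Iterable[PedigreeEntry]):
        self.entries = list(entries)
        self._by_id = {e.sample_id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise ValueError("duplicate sample ids in pedigree")
        for fam in self.families:
            members = self.family_members(fam)
            fathers = [e for e in members if e.role == "father"]
            mothers = [e for e in members if e.role == "mother"]
            if len(fathers) != 1 or len(mothers) != 1:
                raise ValueError(f"family {fam} must have exactly one father and one mother")
            if fathers[0].sex != "male" or mothers[0].sex != "female":
                raise ValueError(f"parental sexes inconsistent in family {fam}")
            for child in members:
                if child.role == "proband" and not child.affected:
                    raise ValueError(f"proband {child.sample_id} must be affected")
                if child.role == "sibling" and child.affected:
                    raise ValueError(f"sibling {child.sample_id} must be unaffected")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> PedigreeEntry:
        return self._by_id[sample_id]

    @property
    def samples(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def families(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.family_id not in seen:
                seen.append(e.family_id)
        return seen

    def family_members(self, family_id: str) -> list[PedigreeEntry]:
        return [e for e in self.entries if e.family_id == family_id]

    @property
    def children(self) -> list[PedigreeEntry]:
        return [e for e in self.entries if e.is_child]

    @property
    def parents(self) -> list[PedigreeEntry]:
        return [e for e in self.entries if not e.is_child]

    def parents_of(self, sample_id: str) -> tuple[str, str]:
        """(father_id, mother_id) of a child."""
        child = self._by_id[sample_id]
        if not child.is_child:
            raise ValueError(f"{sample_id} is not a child")
        members = self.family_members(child.family_id)
        father = next(e.sample_id for e in members if e.role == "father")
        mother = next(e.sample_id for e in members if e.role == "mother")
        return father, mother


class ExclusionMask:
    """Named interval sets (0-based half-open) of regions to exclude.

    Holds gaps, telomeres, centromeres, PARs and (for chrY) the Yq12
    heterochromatin; also used for the PAR lookup that drives sex-aware
    ploidy on chrX/chrY.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None,
                 par: dict[str, list[tuple[int, int]]] | None = None):
        self.intervals = {c: sorted(iv) for c, iv in (intervals or {}).items()}
        self.par = {c: sorted(iv) for c, iv in (par or {}).items()}
        for table in (self.intervals, self.par):
            for chrom, ivs in table.items():
                for s, e in ivs:
                    if s < 0 or e < s:
                        raise ValueError(f"bad interval ({s}, {e}) on {chrom}")

    @staticmethod
    def _overlaps(ivs: list[tuple[int, int]], start: int, end: int) -> bool:
        for s, e in ivs:
            if s >= end:
                break
            if start < e:
                return True
        return False

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any mask interval by >= 1 bp."""
        return self._overlaps(self.intervals.get(chrom, []), start, end)

    def in_par(self, chrom: str, pos1: int) -> bool:
        """True iff the 1-based position lies in a pseudoautosomal region."""
        for s, e in self.par.get(chrom, []):
            if s <= pos1 - 1 < e:
                return True
        return False


def is_sex_chrom(chrom: str) -> bool:
    return chrom.replace("chr", "") in ("X", "Y")


def expected_ploidy(chrom: str, sex: str, mask: ExclusionMask | None, pos1: int) -> int:
    """Ploidy of a genotype at ``chrom:pos1`` given sample sex.

    Male non-PAR chrX and chrY are haploid; everything else is diploid.
    Females have no chrY (callers should never report one; see
    ``rarefilter.classify_category``).
    """
    c = chrom.replace("chr", "")
    if sex == "male" and c in ("X", "Y"):
        if mask is not None and mask.in_par(chrom, pos1):
            return 2
        return 1
    return 2
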