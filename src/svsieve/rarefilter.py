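"""Pangenome-control frequency filtering and rare-SV classification.

A child's SV is common when it matches (same-allele predicate) any control
locus carried by at least one control individual; on the sex chromosomes
only same-sex controls count.  Surviving (rare) SVs are assigned exactly
one of six genotype categories and, in a second pass, class labels:
de novo (set by the transmission module), private inherited (allele carried
by exactly one parent cohort-wide and transmitted), and biparental
homozygous (child hom-alt, both parents het, never hom in any control,
single family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from svsieve.merge import GenotypeMatrix, sv_match
from svsieve.types import Genotype, MergeParams, Pedigree, SVRecord, is_sex_chrom

logger = logging.getLogger("svsieve")

AUTO_HET = "AUTO_HET"
AUTO_HOM = "AUTO_HOM"
X_HET = "X_HET"
X_HOM = "X_HOM"
MALE_HEMI_X = "MALE_HEMI_X"
MALE_HEMI_Y = "MALE_HEMI_Y"
CATEGORIES = (AUTO_HET, AUTO_HOM, X_HET, X_HOM, MALE_HEMI_X, MALE_HEMI_Y)


@dataclass(frozen=True)
class RareClassLabel:
    value: str  # de_novo | private_inherited | biparental_hom | rare_other
    origin: str = "unknown"  # paternal | maternal | both | none | unknown

    def __post_init__(self):
        if self.value == "biparental_hom" and self.origin != "both":
            raise ValueError("biparental_hom implies origin 'both'")


def _control_carried_loci(
    control_matrix: GenotypeMatrix,
    control_sexes: Optional[dict[str, str]] = None,
    sex: Optional[str] = None,
) -> dict[str, list[SVRecord]]:
    """Control loci carried by >= 1 (optionally sex-restricted) control,
    bucketed by chromosome and sorted by position.

    Loci with only missing genotypes count as not carried.
    """
    buckets: dict[str, list[SVRecord]] = {}
    for locus in control_matrix.loci:
        carriers = control_matrix.carriers(locus.id)
        if sex is not None and is_sex_chrom(locus.chrom):
            carriers = [c for c in carriers if (control_sexes or {}).get(c) == sex]
        if carriers:
            buckets.setdefault(locus.chrom, []).append(locus)
    for chrom in buckets:
        buckets[chrom].sort(key=lambda r: r.pos)
    return buckets


def filter_common(
    child_loci: Sequence[SVRecord],
    control_matrix: GenotypeMatrix,
    child_sex: str,
    params: MergeParams,
    control_sexes: Optional[dict[str, str]] = None,
) -> list[SVRecord]:
    """Return the child loci not matching any carried control locus.

    Autosomal loci are compared against all controls; chrX/chrY loci only
    against controls of the child's sex.  An empty control panel passes
    everything through with a prominent warning.
    """
    if not control_matrix.loci or not control_matrix.samples:
        logger.warning("EMPTY CONTROL PANEL: no frequency filtering applied; "
                       "all %d child loci retained", len(child_loci))
        return list(child_loci)
    all_buckets = _control_carried_loci(control_matrix)
    sex_buckets = _control_carried_loci(control_matrix, control_sexes, child_sex)
    rare = []
    for sv in child_loci:
        buckets = sex_buckets if is_sex_chrom(sv.chrom) else all_buckets
        hit = False
        for ctrl in buckets.get(sv.chrom, ()):
            if ctrl.pos < sv.pos - params.refdist:
                continue
            if ctrl.pos > sv.pos + params.refdist:
                break
            if sv_match(sv, ctrl, params).matched:
                hit = True
                break
        if not hit:
            rare.append(sv)
    return rare


def classify_category(locus: SVRecord, child_gt: Genotype, child_sex: str) -> str:
    """Assign one of the six mutually exclusive rare-SV genotype categories."""
    c = locus.chrom.replace("chr", "")
    if c == "Y":
        if child_sex == "female":
            raise ValueError(f"chrY call in female at {locus.id}")
        return MALE_HEMI_Y
    if c == "X":
        if child_sex == "male":
            if child_gt.ploidy != 1:
                raise ValueError(f"male chrX genotype must be hemizygous at {locus.id}")
            return MALE_HEMI_X
        return X_HOM if child_gt.is_hom_alt else X_HET
    return AUTO_HOM if child_gt.is_hom_alt else AUTO_HET


def _parent_carriers_cohortwide(
    matrix: GenotypeMatrix, locus_id: str, pedigree: Pedigree
) -> list[str]:
    parent_ids = {e.sample_id for e in pedigree.parents}
    return [s for s in matrix.carriers(locus_id) if s in parent_ids]


def extract_private_inherited(
    rare_by_child: dict[str, list[SVRecord]],
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
) -> dict[tuple[str, str], RareClassLabel]:
    """Label (child, locus) pairs where the allele is carried by exactly one
    parent across all cohort parents and that parent transmitted it.

    Returns {(child, sv_id): label}.  The 'observed only once' rule counts
    carrier parents, so one carrier parent with several carrier children in
    a multi-child family still qualifies.
    """
    out: dict[tuple[str, str], RareClassLabel] = {}
    for child_id, loci in rare_by_child.items():
        fa, mo = pedigree.parents_of(child_id)
        for sv in loci:
            cgt = matrix.genotype(sv.id, child_id)
            if cgt is None or not cgt.has_alt:
                continue
            carriers = _parent_carriers_cohortwide(matrix, sv.id, pedigree)
            if len(carriers) != 1:
                continue
            parent = carriers[0]
            if parent not in (fa, mo):
                continue  # carried by an unrelated parent, not inherited
            origin = "paternal" if parent == fa else "maternal"
            out[(child_id, sv.id)] = RareClassLabel("private_inherited", origin)
    return out


def extract_biparental_hom(
    rare_by_child: dict[str, list[SVRecord]],
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    control_matrix: Optional[GenotypeMatrix] = None,
    control_params: Optional[MergeParams] = None,
) -> dict[tuple[str, str], RareClassLabel]:
    """Label autosomal loci where the child is hom-alt, both parents het,
    the configuration occurs in exactly one family, and no control is
    homozygous for a matching allele."""
    params = control_params or MergeParams()

    hom_controls: dict[str, list[SVRecord]] = {}
    if control_matrix is not None:
        for locus in control_matrix.loci:
            if any(
                (g := control_matrix.genotype(locus.id, s)) is not None and g.is_hom_alt
                for s in control_matrix.samples
            ):
                hom_controls.setdefault(locus.chrom, []).append(locus)
        for chrom in hom_controls:
            hom_controls[chrom].sort(key=lambda r: r.pos)

    candidates: dict[tuple[str, str], str] = {}  # (child, sv) -> family
    for child_id, loci in rare_by_child.items():
        fam = pedigree[child_id].family_id
        fa, mo = pedigree.parents_of(child_id)
        for sv in loci:
            if is_sex_chrom(sv.chrom):
                continue
            cgt = matrix.genotype(sv.id, child_id)
            fgt = matrix.genotype(sv.id, fa)
            mgt = matrix.genotype(sv.id, mo)
            if cgt is None or fgt is None or mgt is None:
                continue
            if not (cgt.is_hom_alt and fgt.is_het and mgt.is_het):
                continue
            hom_in_control = any(
                sv_match(sv, ctrl, params).matched
                for ctrl in hom_controls.get(sv.chrom, ())
                if abs(ctrl.pos - sv.pos) <= params.refdist
            )
            if hom_in_control:
                continue
            candidates[(child_id, sv.id)] = fam

    families_per_sv: dict[str, set[str]] = {}
    for (child_id, sv_id), fam in candidates.items():
        families_per_sv.setdefault(sv_id, set()).add(fam)
    return {
        key: RareClassLabel("biparental_hom", "both")
        for key, fam in candidates.items()
        if len(families_per_sv[key[1]]) == 1
    }
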