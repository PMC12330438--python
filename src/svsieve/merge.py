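"""SV comparison, callerset validation, and inter-sample collapse.

Two calls are the same allele when they are of the same type, their
breakpoints lie within ``refdist`` bp, their sizes agree to within
``pctsize`` (reciprocal ratio), and — when both carry sequence — their
sequences are ``pctseq``-identical under global edit distance normalised
by the longer length.  Collapse is greedy single-linkage in sorted order,
reproducing the order-dependent behaviour of the conventional merging
tools: a call joins the first existing cluster whose current representative
it matches, otherwise it founds a new cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from svsieve.types import (
    Genotype,
    GT_HET,
    GT_HOM,
    MergeParams,
    Pedigree,
    SVRecord,
    expected_ploidy,
    is_sex_chrom,
)

logger = logging.getLogger("svsieve")


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    breakpoint_distance: int
    size_similarity: float
    seq_similarity: Optional[float] = None


def seq_similarity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit_distance / max(len_a, len_b)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def sv_match(a: SVRecord, b: SVRecord, params: MergeParams) -> MatchResult:
    """Decide whether two calls on the same chromosome are the same allele.

    Symmetric in its arguments.  The sequence test is skipped when either
    record lacks a sequence (DEL records routinely do).
    """
    if a.chrom != b.chrom:
        raise ValueError(f"sv_match requires same chromosome, got {a.chrom} vs {b.chrom}")
    dist = abs(a.pos - b.pos)
    size_sim = min(a.svlen, b.svlen) / max(a.svlen, b.svlen)
    ssim = None
    ok = a.svtype == b.svtype and dist <= params.refdist and size_sim >= params.pctsize
    if ok and a.seq is not None and b.seq is not None:
        ssim = seq_similarity(a.seq, b.seq)
        ok = ssim >= params.pctseq
    return MatchResult(matched=ok, breakpoint_distance=dist,
                       size_similarity=size_sim, seq_similarity=ssim)


def validate_callerset(
    assembly_calls: Sequence[SVRecord],
    aligner_callsets: Sequence[Sequence[SVRecord]],
    params: MergeParams,
) -> tuple[list[SVRecord], list[SVRecord]]:
    """Keep assembly calls supported by >= 1 alignment-based caller.

    Output coordinates are the assembly call's own (the assembly callset is
    the merge base).  Returns (validated, rejected).
    """
    by_chrom: dict[str, list[SVRecord]] = {}
    for cs in aligner_callsets:
        for r in cs:
            by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.pos)

    validated, rejected = [], []
    for call in assembly_calls:
        support = False
        for other in by_chrom.get(call.chrom, ()):
            if other.pos < call.pos - params.refdist:
                continue
            if other.pos > call.pos + params.refdist:
                break
            if sv_match(call, other, params).matched:
                support = True
                break
        (validated if support else rejected).append(call)
    return validated, rejected


@dataclass
class Cluster:
    representative: SVRecord
    members: list[SVRecord] = field(default_factory=list)  # carry .sample labels

    def samples(self) -> set[str]:
        return {m.sample for m in self.members if m.sample is not None}


@dataclass
class GenotypeMatrix:
    """Nonredundant SV loci x samples.

    ``genotypes[locus_id][sample]`` is the sample's genotype at the locus;
    samples with no collapsed member call are absent (treated as missing).
    ``provenance`` records, per locus, the member call ids collapsed into it
    and any phase-unknown het/het merges flagged as ambiguous.
    """

    loci: list[SVRecord]
    samples: list[str]
    genotypes: dict[str, dict[str, Genotype]]
    provenance: dict[str, dict] = field(default_factory=dict)

    def locus_by_id(self, locus_id: str) -> SVRecord:
        for l in self.loci:
            if l.id == locus_id:
                return l
        raise KeyError(locus_id)

    def carriers(self, locus_id: str) -> list[str]:
        return [s for s, gt in self.genotypes.get(locus_id, {}).items() if gt.has_alt]

    def genotype(self, locus_id: str, sample: str) -> Optional[Genotype]:
        return self.genotypes.get(locus_id, {}).get(sample)


def _select_representative(cluster: Cluster, params: MergeParams) -> SVRecord:
    members = cluster.members
    if params.keep_rule == "common":
        # representative = the member whose exact (pos, svlen, type) signature
        # is shared by the most distinct samples, ties broken by quality
        sig_samples: dict[tuple, set] = {}
        for m in members:
            sig_samples.setdefault((m.pos, m.svlen, m.svtype), set()).add(m.sample)
        best = max(
            members,
            key=lambda m: (
                len(sig_samples[(m.pos, m.svlen, m.svtype)]),
                m.qual,
                -m.pos,
                m.id,
            ),
        )
        return best
    # maxqual: highest quality; ties -> leftmost pos, then lexicographic id
    return max(members, key=lambda m: (m.qual, -m.pos, _revlex(m.id)))


def _revlex(s: str):
    # lexicographically smallest id wins under max(): invert byte order
    return tuple(-b for b in s.encode())


def _combine_genotypes(
    member_calls: list[SVRecord],
    member_gts: list[Optional[Genotype]],
    intra_same_hap: bool,
) -> tuple[Genotype, bool]:
    """Merge one sample's genotypes for all its member calls in a cluster.

    Repeated reports of one allele by different callers are a single call;
    two genuinely distinct het calls (same caller reporting twice, or
    unlabelled duplicates) merge to hom-alt -- except that a phase-known
    pair on the same haplotype is one allele seen twice and stays het.
    Returns (genotype, ambiguous_flag): ambiguous marks a phase-unknown
    het/het merge.
    """
    from collections import Counter

    caller_counts: Counter = Counter()
    for m in member_calls:
        if m.callers:
            caller_counts.update(m.callers)
        else:
            caller_counts[None] += 1
    distinct = any(v >= 2 for v in caller_counts.values())

    gts = [g for g in member_gts if g is not None]
    if not gts:
        if len(member_calls) == 1 or not distinct or intra_same_hap:
            return GT_HET, False
        return GT_HOM, True
    if len(gts) == 1:
        return gts[0], False
    if any(g.ploidy == 1 for g in gts):
        alt = any(g.has_alt for g in gts)
        return Genotype((1,) if alt else (0,)), False
    if all(g.is_het for g in gts):
        if not distinct or intra_same_hap:
            return GT_HET, False
        phase_known = all(g.phased for g in gts)
        return GT_HOM, not phase_known
    if any(g.is_hom_alt for g in gts):
        return GT_HOM, False
    alt = any(g.has_alt for g in gts)
    return (GT_HET if alt else gts[0]), False


def collapse(
    calls: Sequence[SVRecord],
    params: MergeParams,
    genotypes: Optional[dict[str, dict[str, Genotype]]] = None,
    samples: Optional[Sequence[str]] = None,
    haplotypes: Optional[dict[str, int]] = None,
) -> GenotypeMatrix:
    """Greedy single-linkage collapse of calls into nonredundant loci.

    ``calls`` must be sorted by (chrom, pos) and carry ``sample`` labels.
    ``genotypes`` maps call id -> {sample -> Genotype} (as from
    :func:`svsieve.io.read_sv_vcf`).  ``haplotypes`` optionally maps call id
    -> haplotype index for phase-aware within-sample merging.
    """
    calls = list(calls)
    for prev, cur in zip(calls, calls[1:]):
        if (prev.chrom, prev.pos) > (cur.chrom, cur.pos):
            raise ValueError("collapse requires calls sorted by (chrom, pos)")

    clusters_by_chrom: dict[str, list[Cluster]] = {}
    for call in calls:
        chrom_clusters = clusters_by_chrom.setdefault(call.chrom, [])
        target = None
        for cl in chrom_clusters:
            if abs(cl.representative.pos - call.pos) > params.refdist:
                continue
            if sv_match(cl.representative, call, params).matched:
                target = cl
                break
        if target is None:
            chrom_clusters.append(Cluster(representative=call, members=[call]))
        else:
            target.members.append(call)
            target.representative = _select_representative(target, params)

    all_clusters = [cl for chrom in sorted(clusters_by_chrom)
                    for cl in sorted(clusters_by_chrom[chrom], key=lambda c: c.representative.pos)]

    sample_list = list(samples) if samples is not None else sorted(
        {c.sample for c in calls if c.sample is not None}
    )
    loci: list[SVRecord] = []
    out_gts: dict[str, dict[str, Genotype]] = {}
    provenance: dict[str, dict] = {}
    for cl in all_clusters:
        rep = cl.representative
        loci.append(rep)
        per_sample: dict[str, Genotype] = {}
        flags: list[str] = []
        by_sample: dict[str, list[SVRecord]] = {}
        for m in cl.members:
            if m.sample is not None:
                by_sample.setdefault(m.sample, []).append(m)
        for s, ms in by_sample.items():
            gts = [(genotypes or {}).get(m.id, {}).get(s) for m in ms]
            same_hap = False
            if haplotypes is not None and len(ms) > 1:
                haps = {haplotypes.get(m.id) for m in ms}
                same_hap = len(haps) == 1 and None not in haps
            gt, ambiguous = _combine_genotypes(ms, gts, same_hap)
            per_sample[s] = gt
            if ambiguous:
                flags.append(f"phase_unknown_het_merge:{s}")
        out_gts[rep.id] = per_sample
        provenance[rep.id] = {
            "members": [m.id for m in cl.members],
            "member_samples": {m.id: m.sample for m in cl.members},
            "flags": flags,
        }
    return GenotypeMatrix(loci=loci, samples=sample_list, genotypes=out_gts,
                          provenance=provenance)


def count_memberships(matrix: GenotypeMatrix) -> int:
    return sum(len(p["members"]) for p in matrix.provenance.values())


# ---------------------------------------------------------------------------
# Mendelian concordance

def _consistent(child: Genotype, fa: Genotype, mo: Genotype,
                chrom: str, child_sex: str) -> Optional[bool]:
    """None when a required parental genotype is missing."""
    from svsieve.transmission import mendelian_check

    res = mendelian_check(child, fa, mo, chrom, child_sex)
    if res == "unknown":
        return None
    return res == "consistent"


def mendelian_concordance(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
) -> tuple[dict[str, float], float]:
    """Per-trio and mean fraction of child-carried loci consistent with
    Mendelian transmission from the parents' genotypes (sex-aware on X/Y).

    Trios whose parents are absent from the matrix sample list are skipped
    with a warning; loci where a required parental genotype is missing do
    not count toward the denominator.
    """
    rates: dict[str, float] = {}
    for child in pedigree.children:
        fa_id, mo_id = pedigree.parents_of(child.sample_id)
        if fa_id not in matrix.samples or mo_id not in matrix.samples:
            logger.warning("trio for %s incomplete in matrix; skipped", child.sample_id)
            continue
        n_checked = n_ok = 0
        for locus in matrix.loci:
            cgt = matrix.genotype(locus.id, child.sample_id)
            if cgt is None or not cgt.has_alt:
                continue
            fgt = matrix.genotype(locus.id, fa_id)
            mgt = matrix.genotype(locus.id, mo_id)
            ok = _consistent(cgt, fgt or Genotype((None, None)),
                             mgt or Genotype((None, None)), locus.chrom, child.sex)
            if ok is None:
                continue
            n_checked += 1
            n_ok += int(ok)
        if n_checked:
            rates[child.sample_id] = n_ok / n_checked
    mean = sum(rates.values()) / len(rates) if rates else float("nan")
    return rates, mean
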