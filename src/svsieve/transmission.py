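"""Stepwise transmission curation of rare SVs that deviate from clean
Mendelian inheritance.

A child SV that follows Mendelian transmission of the collapsed parental
genotypes is a high-confidence inherited call.  Everything else runs a
fixed chain, stopping at the first step that finds parental support:

1. relaxed re-match against the parents' raw (pre-validation) callsets;
2. callable-region score from parental read support / mapping quality
   (a documented logistic rule with threshold 0.5);
3. re-genotyper support (parental alt call at a matching locus);
4. tandem-repeat allele-length comparison for TR-overlapping SVs;
5. raw read-support tiers (>=3 reads moderate, 1-2 reads low confidence).

A candidate with no parental support at any step is a de novo SV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from svsieve.merge import sv_match
from svsieve.types import Genotype, MergeParams, SVRecord

STATUS_HIGH = "high_confidence"
STATUS_MODERATE = "moderate"
STATUS_LOW = "low_confidence"
STATUS_DENOVO = "de_novo"
STATUS_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class CallableScoreParams:
    """Weights of the rule-based callable-region score.

    ``score = logistic(w0 + w1*log1p(n_reads) + w2*(mean_mapq/60)
    - w3*frac_clipped)``; a parent locus with score >= ``threshold`` is
    treated as supporting transmission.
    """

    w0: float = -2.0
    w1: float = 1.5
    w2: float = 1.0
    w3: float = 2.0
    threshold: float = 0.5


@dataclass(frozen=True)
class TransmissionVerdict:
    sv_id: str
    child: str
    status: str
    decided_by: str  # mendelian | relaxed_rematch | callable_score | genotyper | tr_allele | read_support
    origin: str = "unknown"  # paternal | maternal | both | none | unknown
    evidence: dict = field(default_factory=dict)


def mendelian_check(
    child_gt: Genotype,
    father_gt: Genotype,
    mother_gt: Genotype,
    chrom: str,
    child_sex: str,
) -> str:
    """'consistent' | 'violation' | 'unknown' (missing required parent).

    Sex-aware: a male child's X alleles come from the mother only and his Y
    alleles from the father only; autosomes and female X draw one allele
    from each parent.  Hemizygous parental genotypes contribute their single
    allele.
    """
    c = chrom.replace("chr", "")

    def alleles(gt: Genotype) -> Optional[set]:
        if gt is None or gt.is_missing:
            return None
        return {a for a in gt.alleles if a is not None}

    child_alleles = [a for a in child_gt.alleles if a is not None]
    if not child_alleles:
        return "unknown"

    if c == "Y":
        fa = alleles(father_gt)
        if fa is None:
            return "unknown"
        return "consistent" if all(a in fa for a in child_alleles) else "violation"

    if c == "X" and child_sex == "male":
        mo = alleles(mother_gt)
        if mo is None:
            return "unknown"
        return "consistent" if all(a in mo for a in child_alleles) else "violation"

    fa, mo = alleles(father_gt), alleles(mother_gt)
    if fa is None or mo is None:
        return "unknown"
    if len(child_alleles) == 1:
        # haploid child genotype on a diploid locus: from either parent
        a = child_alleles[0]
        return "consistent" if (a in fa or a in mo) else "violation"
    a1, a2 = child_alleles
    ok = (a1 in fa and a2 in mo) or (a1 in mo and a2 in fa)
    return "consistent" if ok else "violation"


def relaxed_rematch(
    sv: SVRecord,
    parental_raw_callsets: dict[str, Sequence[SVRecord]],
    params: Optional[MergeParams] = None,
) -> tuple[Optional[str], Optional[float]]:
    """Search the parents' raw callsets for a matching call.

    Returns (parent_sample or None, best size/seq similarity).  Uses the
    standard thresholds (pctseq/pctsize 0.9) against pre-validation calls,
    recovering inheritance evidence lost at callerset validation.
    """
    params = params or MergeParams()
    best: tuple[Optional[str], Optional[float]] = (None, None)
    for parent, calls in parental_raw_callsets.items():
        for call in calls:
            if call.chrom != sv.chrom:
                continue
            res = sv_match(sv, call, params)
            if res.matched:
                sim = res.seq_similarity if res.seq_similarity is not None else res.size_similarity
                if best[0] is None or (sim or 0) > (best[1] or 0):
                    best = (parent, sim)
    return best


def callable_score(
    n_reads: float,
    mean_mapq: float,
    frac_clipped: float,
    params: Optional[CallableScoreParams] = None,
) -> float:
    """Callable-region transmission score in [0, 1].

    Monotone non-decreasing in supporting reads and mean mapping quality,
    non-increasing in the clipped-read fraction.
    """
    p = params or CallableScoreParams()
    x = p.w0 + p.w1 * math.log1p(max(n_reads, 0)) + p.w2 * (mean_mapq / 60.0) - p.w3 * frac_clipped
    return 1.0 / (1.0 + math.exp(-x))


def genotyper_support(
    sv_id: str,
    parental_genotyper_calls: dict[str, dict[str, Genotype]],
    father: str,
    mother: str,
) -> Optional[str]:
    """Parent carrying a re-genotyped alt allele at the locus, if any."""
    carriers = []
    for parent in (father, mother):
        gt = parental_genotyper_calls.get(sv_id, {}).get(parent)
        if gt is not None and gt.has_alt:
            carriers.append(parent)
    if not carriers:
        return None
    return carriers[0] if len(carriers) == 1 else "both"


def tr_allele_compare(
    child_allele_len: int,
    parental_allele_lens: Sequence[int],
    tol_bp: int = 10,
    tol_frac: float = 0.1,
) -> str:
    """'inherited' | 'expanded_de_novo' | 'unresolved' from TR allele lengths.

    Inherited when some parental allele length lies within
    ``max(tol_bp, tol_frac * child_len)`` of the child's; expanded de novo
    when the child allele exceeds every parental allele by more than the
    tolerance; unresolved otherwise (e.g. child allele shorter than all
    parental alleles by more than tolerance, or no parental data).
    """
    if not parental_allele_lens:
        return "unresolved"
    tol = max(tol_bp, tol_frac * child_allele_len)
    for pl in parental_allele_lens:
        if abs(child_allele_len - pl) <= tol:
            return "inherited"
    if child_allele_len > max(parental_allele_lens) + tol:
        return "expanded_de_novo"
    return "unresolved"


def read_support_tier(n_reads: int) -> str:
    """'moderate' (>=3 reads), 'low' (1-2 reads), 'none' (0)."""
    if n_reads >= 3:
        return "moderate"
    if n_reads >= 1:
        return "low"
    return "none"


@dataclass
class FamilyEvidence:
    """Everything the curation chain can consult for one child SV."""

    child_gt: Genotype
    father_gt: Genotype
    mother_gt: Genotype
    child_sex: str
    parental_raw_callsets: dict[str, Sequence[SVRecord]]  # parent id -> raw calls
    father: str = "fa"
    mother: str = "mo"
    # read-support rows per parent: (n_reads, mean_mapq, frac_clipped)
    read_support: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    genotyper_calls: dict[str, dict[str, Genotype]] = field(default_factory=dict)
    tr_flag: bool = False
    child_tr_allele_len: Optional[int] = None
    parental_tr_allele_lens: Sequence[int] = ()


def _origin_for(parent: str, ev: FamilyEvidence) -> str:
    if parent == ev.father:
        return "paternal"
    if parent == ev.mother:
        return "maternal"
    return parent  # "both"


def curate(
    sv: SVRecord,
    child: str,
    ev: FamilyEvidence,
    params: Optional[MergeParams] = None,
    score_params: Optional[CallableScoreParams] = None,
    tr_tol_bp: int = 10,
    tr_tol_frac: float = 0.1,
) -> TransmissionVerdict:
    """Run the full curation chain for one rare SV in one child."""
    params = params or MergeParams()
    score_params = score_params or CallableScoreParams()

    mres = mendelian_check(ev.child_gt, ev.father_gt, ev.mother_gt, sv.chrom, ev.child_sex)
    if mres == "consistent":
        fa_carries = ev.father_gt is not None and ev.father_gt.has_alt
        mo_carries = ev.mother_gt is not None and ev.mother_gt.has_alt
        origin = ("both" if (fa_carries and mo_carries)
                  else "paternal" if fa_carries
                  else "maternal" if mo_carries else "none")
        return TransmissionVerdict(sv.id, child, STATUS_HIGH, "mendelian", origin=origin)

    # step 1: relaxed re-match against parental raw callsets
    parent, sim = relaxed_rematch(sv, ev.parental_raw_callsets, params)
    if parent is not None:
        return TransmissionVerdict(sv.id, child, STATUS_MODERATE, "relaxed_rematch",
                                   origin=_origin_for(parent, ev),
                                   evidence={"similarity": sim})

    # step 2: callable-region score on parental read support
    for p in (ev.father, ev.mother):
        row = ev.read_support.get(p)
        if row is None:
            continue
        score = callable_score(*row, params=score_params)
        if score >= score_params.threshold:
            return TransmissionVerdict(sv.id, child, STATUS_MODERATE, "callable_score",
                                       origin=_origin_for(p, ev),
                                       evidence={"score": score, "parent": p})

    # step 3: re-genotyper support
    g = genotyper_support(sv.id, ev.genotyper_calls, ev.father, ev.mother)
    if g is not None:
        return TransmissionVerdict(sv.id, child, STATUS_MODERATE, "genotyper",
                                   origin=_origin_for(g, ev))

    # step 4: TR allele-length comparison
    if ev.tr_flag and ev.child_tr_allele_len is not None:
        tr = tr_allele_compare(ev.child_tr_allele_len, list(ev.parental_tr_allele_lens),
                               tol_bp=tr_tol_bp, tol_frac=tr_tol_frac)
        if tr == "inherited":
            return TransmissionVerdict(sv.id, child, STATUS_MODERATE, "tr_allele",
                                       evidence={"tr": tr})
        if tr == "expanded_de_novo":
            return TransmissionVerdict(sv.id, child, STATUS_DENOVO, "tr_allele",
                                       origin="none", evidence={"tr": tr})

    # step 5: raw read-support tiers
    best_reads = 0
    best_parent = None
    for p in (ev.father, ev.mother):
        row = ev.read_support.get(p)
        if row is not None and row[0] > best_reads:
            best_reads, best_parent = int(row[0]), p
    tier = read_support_tier(best_reads)
    if tier == "moderate":
        return TransmissionVerdict(sv.id, child, STATUS_MODERATE, "read_support",
                                   origin=_origin_for(best_parent, ev),
                                   evidence={"n_reads": best_reads})
    if tier == "low":
        return TransmissionVerdict(sv.id, child, STATUS_LOW, "read_support",
                                   origin=_origin_for(best_parent, ev),
                                   evidence={"n_reads": best_reads})

    return TransmissionVerdict(sv.id, child, STATUS_DENOVO, "read_support",
                               origin="none", evidence={"n_reads": best_reads})
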