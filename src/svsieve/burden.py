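"""Proband-versus-sibling rare-SV burden statistics and control-panel
scaling curves.

The headline comparison is a rate test: with k1 events among n1 probands
and k2 among n2 siblings, the reported "OR" is the per-individual rate
ratio (k1/n1)/(k2/n2), tested with a chi-square (Yates continuity
correction) on the 2x2 table (k1, n1-k1; k2, n2-k2).  Per-child count
distributions are compared with a two-sided Mann-Whitney U test (normal
approximation with tie correction, Z signed probands-minus-siblings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from svsieve.merge import GenotypeMatrix, sv_match
from svsieve.types import MergeParams, Pedigree, SVRecord, is_sex_chrom


@dataclass(frozen=True)
class BurdenTestResult:
    stratum: str
    proband_count: int
    proband_n: int
    sib_count: int
    sib_n: int
    rate_ratio: float
    odds_ratio: float  # classical 2x2 odds ratio, for reference
    chi2: float
    p_nominal: float
    p_adjusted: float = float("nan")
    mwu_z: float = float("nan")
    mwu_p: float = float("nan")
    rate_ratio_infinite: bool = False


def chisq_rate_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float, float]:
    """(rate_ratio, chi2_yates, p) for k1 events in n1 individuals vs k2 in n2.

    The chi-square uses the 2x2 table (k1, n1-k1; k2, n2-k2) with Yates
    continuity correction and a chi2(1) tail.  k2 = 0 yields an infinite
    rate ratio (p still computed).  When events outnumber individuals
    (k > n, e.g. total-SV strata) the carrier table is undefined, so the
    statistic falls back to a Yates-corrected goodness-of-fit of the event
    split (k1, k2) against expectations proportional to (n1, n2).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    rate_ratio = math.inf if k2 == 0 else (k1 / n1) / (k2 / n2)
    if k1 > n1 or k2 > n2:
        k = k1 + k2
        if k == 0:
            return rate_ratio, 0.0, 1.0
        exp1 = k * n1 / (n1 + n2)
        exp2 = k * n2 / (n1 + n2)
        dev = max(0.0, abs(k1 - exp1) - 0.5)
        chi2 = dev**2 / exp1 + dev**2 / exp2
        return rate_ratio, chi2, float(stats.chi2.sf(chi2, df=1))
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return rate_ratio, 0.0, 1.0
    chi2 = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return rate_ratio, chi2, p


def mwu_counts(
    proband_counts: Sequence[float], sib_counts: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-child counts.

    Normal approximation with tie correction; Z is signed so that probands
    having systematically larger counts gives Z > 0.
    """
    x = np.asarray(proband_counts, dtype=float)
    y = np.asarray(sib_counts, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """p_adj = min(1, m * p) with m = number of tests in the family."""
    m = len(p_values)
    return [min(1.0, m * p) for p in p_values]


# ---------------------------------------------------------------------------
# burden table

CATEGORY_COLS = ["AUTO_HET", "AUTO_HOM", "X_HET", "X_HOM", "MALE_HEMI_X", "MALE_HEMI_Y"]
CLASS_COLS = ["de_novo", "private_inherited", "biparental_hom", "rare_other"]
PRIMARY_COLS = ["Exon", "UTR", "Intron", "Inter"]
FLAG_COLS = ["NDD", "REG", "brainREG", "TR", "SegDup"]
ORIGIN_COLS = ["Pat", "Mat"]
TYPE_COLS = ["DEL", "INS"]


def count_burden(
    rare_by_child: dict[str, list[SVRecord]],
    categories: dict[tuple[str, str], str],
    pedigree: Pedigree,
    labels: Optional[dict[str, "object"]] = None,
    class_labels: Optional[dict[tuple[str, str], "object"]] = None,
    chroms: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-child rare-SV counts stratified by category, type, functional
    class, flags and parental origin.

    One row per child (with ``affected`` and ``sex``); each SV counts once
    per stratum it belongs to.  ``chroms`` restricts counting to a subset
    of chromosomes (used for the female-only chrX analysis).
    """
    cols = (["total"] + TYPE_COLS + CATEGORY_COLS + PRIMARY_COLS + FLAG_COLS
            + CLASS_COLS + ORIGIN_COLS)
    rows = {}
    for child in pedigree.children:
        counts = dict.fromkeys(cols, 0)
        for sv in rare_by_child.get(child.sample_id, []):
            if chroms is not None and sv.chrom not in chroms:
                continue
            counts["total"] += 1
            counts[sv.svtype] += 1
            cat = categories.get((child.sample_id, sv.id))
            if cat in counts:
                counts[cat] += 1
            lab = (labels or {}).get(sv.id)
            if lab is not None:
                counts[lab.primary_class] += 1
                for f in lab.flags:
                    counts[f] += 1
            cl = (class_labels or {}).get((child.sample_id, sv.id))
            if cl is not None:
                counts[cl.value] += 1
                if cl.origin == "paternal":
                    counts["Pat"] += 1
                elif cl.origin == "maternal":
                    counts["Mat"] += 1
        rows[child.sample_id] = {
            "affected": child.affected,
            "sex": child.sex,
            **counts,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def burden_tests(
    table: pd.DataFrame,
    strata: Optional[Sequence[str]] = None,
    sex: Optional[str] = None,
) -> list[BurdenTestResult]:
    """Run the rate-ratio chi-square and Mann-Whitney tests per stratum,
    Bonferroni-adjusting across all strata tested in the run."""
    df = table if sex is None else table[table["sex"] == sex]
    probands = df[df["affected"]]
    sibs = df[~df["affected"]]
    if len(probands) == 0 or len(sibs) == 0:
        raise ValueError("need at least one proband and one sibling")
    strata = list(strata) if strata is not None else [
        c for c in df.columns if c not in ("affected", "sex")
    ]
    results = []
    for col in strata:
        k1, k2 = int(probands[col].sum()), int(sibs[col].sum())
        n1, n2 = len(probands), len(sibs)
        rr, chi2, p = chisq_rate_test(k1, n1, k2, n2)
        a, b, c, d = k1, n1 - k1, k2, n2 - k2
        if b < 0 or d < 0:
            odds = math.nan  # carrier table undefined when events outnumber children
        elif b * c != 0:
            odds = (a * d) / (b * c)
        else:
            odds = math.inf
        z, mp = mwu_counts(probands[col].to_numpy(), sibs[col].to_numpy())
        results.append(
            BurdenTestResult(
                stratum=col, proband_count=k1, proband_n=n1, sib_count=k2, sib_n=n2,
                rate_ratio=rr, odds_ratio=odds, chi2=chi2, p_nominal=p,
                mwu_z=z, mwu_p=mp, rate_ratio_infinite=not math.isfinite(rr),
            )
        )
    adj = bonferroni([r.p_nominal for r in results])
    return [
        BurdenTestResult(**{**r.__dict__, "p_adjusted": pa})
        for r, pa in zip(results, adj)
    ]


# ---------------------------------------------------------------------------
# pangenome scaling curves

def discovery_curve(
    control_matrix: GenotypeMatrix,
    sample_order: Optional[Sequence[str]] = None,
) -> list[int]:
    """Cumulative nonredundant SV count: entry k-1 is the number of loci
    carried by >= 1 of the first k control samples."""
    order = list(sample_order) if sample_order is not None else list(control_matrix.samples)
    first_carrier_index: list[int] = []
    pos = {s: i for i, s in enumerate(order)}
    for locus in control_matrix.loci:
        idxs = [pos[s] for s in control_matrix.carriers(locus.id) if s in pos]
        if idxs:
            first_carrier_index.append(min(idxs))
    counts = np.zeros(len(order), dtype=int)
    for i in first_carrier_index:
        counts[i] += 1
    return np.cumsum(counts).tolist()


def rare_pool_curve(
    rare_input_by_child: dict[str, list[SVRecord]],
    control_matrix: GenotypeMatrix,
    child_sexes: dict[str, str],
    params: MergeParams,
    sample_order: Optional[Sequence[str]] = None,
    control_sexes: Optional[dict[str, str]] = None,
    panel_sizes: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Mean rare-SV count per child as a function of control-panel size.

    For each child locus, the panel prefix at which it is first filtered is
    the earliest carrier (in ``sample_order``) among matching control loci;
    the per-child rare count at panel size k counts loci not yet filtered.
    Monotone non-increasing in k by construction.
    """
    order = list(sample_order) if sample_order is not None else list(control_matrix.samples)
    pos = {s: i for i, s in enumerate(order)}
    panel_sizes = list(panel_sizes) if panel_sizes is not None else list(range(0, len(order) + 1))

    ctrl_by_chrom: dict[str, list[SVRecord]] = {}
    for locus in control_matrix.loci:
        ctrl_by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in ctrl_by_chrom:
        ctrl_by_chrom[chrom].sort(key=lambda r: r.pos)

    rows = []
    for child, loci in rare_input_by_child.items():
        sex = child_sexes.get(child)
        removal_k: list[float] = []
        for sv in loci:
            first = math.inf
            for ctrl in ctrl_by_chrom.get(sv.chrom, ()):
                if ctrl.pos < sv.pos - params.refdist:
                    continue
                if ctrl.pos > sv.pos + params.refdist:
                    break
                if not sv_match(sv, ctrl, params).matched:
                    continue
                carriers = control_matrix.carriers(ctrl.id)
                if is_sex_chrom(sv.chrom) and control_sexes is not None:
                    carriers = [c for c in carriers if control_sexes.get(c) == sex]
                idxs = [pos[c] for c in carriers if c in pos]
                if idxs:
                    first = min(first, min(idxs) + 1)  # filtered once panel includes this sample
            removal_k.append(first)
        for k in panel_sizes:
            n_rare = sum(1 for f in removal_k if f > k)
            rows.append({"child": child, "panel_size": k, "n_rare": n_rare})
    return pd.DataFrame(rows)
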