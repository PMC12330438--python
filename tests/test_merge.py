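"""SV match predicate, callerset validation, and collapse engine."""

import numpy as np
import pytest

from svsieve.merge import (
    collapse,
    count_memberships,
    mendelian_concordance,
    seq_similarity,
    sv_match,
    validate_callerset,
)
from svsieve.types import Genotype, MergeParams, Pedigree, PedigreeEntry, SVRecord


def sv(id, pos, svlen=100, svtype="DEL", chrom="chr1", qual=50.0, seq=None, sample=None):
    return SVRecord(id=id, chrom=chrom, pos=pos, svtype=svtype, svlen=svlen,
                    qual=qual, seq=seq, sample=sample)


def dp_edit_distance(a: str, b: str) -> int:
    """Independent dynamic-programming Levenshtein oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestSvMatch:
    def test_identical_records(self, params):
        a = sv("a", 10_000)
        res = sv_match(a, sv("b", 10_000), params)
        assert res.matched and res.breakpoint_distance == 0
        assert res.size_similarity == 1.0

    def test_refdist_boundary_exact(self, params):
        a = sv("a", 10_000)
        assert sv_match(a, sv("b", 10_500), params).matched  # distance 500
        assert not sv_match(a, sv("b", 10_501), params).matched  # distance 501

    def test_size_ratio_boundary_exact(self, params):
        a = sv("a", 1000, svlen=100)
        assert sv_match(a, sv("b", 1000, svlen=90), params).matched  # 0.90
        assert not sv_match(a, sv("b", 1000, svlen=89), params).matched  # 0.89

    def test_type_mismatch_never_matches(self, params):
        a = sv("a", 1000, svtype="DEL")
        b = SVRecord(id="b", chrom="chr1", pos=1000, svtype="INS", svlen=100)
        assert not sv_match(a, b, params).matched

    def test_seq_similarity_against_dp_oracle(self, params):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        s = "".join(rng.choice(bases, size=300))
        # 35 substitutions at distinct positions -> identity 1 - 35/300 = 0.8833
        t = list(s)
        for i in rng.choice(300, size=35, replace=False):
            t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
        t = "".join(t)
        d = dp_edit_distance(s, t)
        assert seq_similarity(s, t) == pytest.approx(1 - d / 300, abs=1e-12)
        assert seq_similarity(s, t) < 0.90
        a = SVRecord(id="a", chrom="chr1", pos=1000, svtype="INS", svlen=300, seq=s)
        b = SVRecord(id="b", chrom="chr1", pos=1000, svtype="INS", svlen=300, seq=t)
        assert not sv_match(a, b, params).matched

    def test_seq_test_skipped_when_absent(self, params):
        a = sv("a", 1000, svtype="DEL")  # no sequences: position+size only
        assert sv_match(a, sv("b", 1100), params).matched

    def test_symmetry_on_random_pairs(self, params):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            la, lb = int(rng.integers(50, 400)), int(rng.integers(50, 400))
            svtype = "INS" if rng.random() < 0.5 else "DEL"
            a = SVRecord(id="a", chrom="chr1", pos=int(rng.integers(1, 5000)),
                         svtype=svtype, svlen=la,
                         seq="".join(rng.choice(bases, la)) if svtype == "INS" else None)
            b = SVRecord(id="b", chrom="chr1", pos=int(rng.integers(1, 5000)),
                         svtype=svtype, svlen=lb,
                         seq="".join(rng.choice(bases, lb)) if svtype == "INS" else None)
            assert sv_match(a, b, params).matched == sv_match(b, a, params).matched

    def test_cross_chromosome_is_an_error(self, params):
        with pytest.raises(ValueError):
            sv_match(sv("a", 1, chrom="chr1"), sv("b", 1, chrom="chr2"), params)


class TestValidateCallerset:
    def test_supported_and_unsupported(self, params):
        base = [sv("a", 1000), sv("b", 50_000)]
        aligner = [[sv("a2", 1050)]]  # supports only the first
        validated, rejected = validate_callerset(base, aligner, params)
        assert [r.id for r in validated] == ["a"]
        assert [r.id for r in rejected] == ["b"]

    def test_empty_assembly_callset(self, params):
        assert validate_callerset([], [[sv("x", 1)]], params) == ([], [])

    def test_keeps_assembly_coordinates(self, params):
        base = [sv("a", 1000)]
        validated, _ = validate_callerset(base, [[sv("a2", 1400)]], params)
        assert validated[0].pos == 1000


def brute_force_clusters(calls, params):
    """Transitive closure of the match relation (union-find oracle)."""
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if calls[i].chrom != calls[j].chrom:
                continue
            if sv_match(calls[i], calls[j], params).matched:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(len(calls))})


def jittered_instance(rng, n_loci=20, copies=10, spacing=5000, jitter=100):
    """Well-separated true loci with tightly jittered copies: greedy and
    transitive-closure clustering provably agree."""
    calls = []
    for li in range(n_loci):
        base = 10_000 + li * spacing
        svlen = int(rng.integers(100, 400))
        for ci in range(int(rng.integers(1, copies))):
            calls.append(sv(f"l{li}c{ci}", base + int(rng.integers(-jitter, jitter + 1)),
                            svlen=svlen, qual=float(rng.uniform(1, 60)),
                            sample=f"s{ci}"))
    calls.sort(key=lambda r: (r.chrom, r.pos, r.id))
    return calls


class TestCollapse:
    def test_three_matching_calls_one_locus(self, params):
        calls = sorted([sv("a", 1000, sample="s1"), sv("b", 1050, sample="s2"),
                        sv("c", 980, sample="s3")], key=lambda r: r.pos)
        m = collapse(calls, params)
        assert len(m.loci) == 1
        assert sorted(m.carriers(m.loci[0].id)) == ["s1", "s2", "s3"]

    def test_600bp_apart_two_loci(self, params):
        calls = [sv("a", 1000, sample="s1"), sv("b", 1600, sample="s2")]
        m = collapse(calls, params)
        assert len(m.loci) == 2

    def test_unsorted_input_rejected(self, params):
        with pytest.raises(ValueError):
            collapse([sv("a", 2000), sv("b", 1000)], params)

    def test_maxqual_representative(self, params):
        calls = [sv("lo", 1000, qual=10, sample="s1"), sv("hi", 1020, qual=55, sample="s2")]
        m = collapse(calls, params)
        assert m.loci[0].id == "hi"

    def test_common_representative_most_samples(self):
        params = MergeParams(keep_rule="common")
        calls = sorted([
            sv("a", 1000, qual=60, sample="s1"),
            sv("b", 1050, qual=10, sample="s2"),
            sv("c", 1050, qual=20, sample="s3"),
        ], key=lambda r: r.pos)
        m = collapse(calls, params)
        # the pos-1050 signature is shared by two samples; beats the maxqual call
        assert m.loci[0].pos == 1050

    def test_cluster_counts_equal_bruteforce_oracle(self, params):
        rng = np.random.default_rng(11)
        for _ in range(50):
            calls = jittered_instance(rng)
            m = collapse(calls, params)
            assert len(m.loci) == brute_force_clusters(calls, params)

    def test_conservation_of_calls(self, params):
        rng = np.random.default_rng(5)
        calls = jittered_instance(rng)
        m = collapse(calls, params)
        assert count_memberships(m) == len(calls)

    def test_nonredundancy_of_output(self, params):
        rng = np.random.default_rng(13)
        calls = jittered_instance(rng)
        m = collapse(calls, params)
        for i, a in enumerate(m.loci):
            for b in m.loci[i + 1:]:
                if a.chrom == b.chrom:
                    assert not sv_match(a, b, params).matched

    def test_idempotence(self, params):
        rng = np.random.default_rng(17)
        calls = jittered_instance(rng)
        m = collapse(calls, params)
        loci = sorted(m.loci, key=lambda r: (r.chrom, r.pos, r.id))
        again = collapse(loci, params)
        assert [l.id for l in again.loci] == [l.id for l in sorted(
            m.loci, key=lambda r: (r.chrom, r.pos, r.id))]

    def test_relaxing_thresholds_never_shrinks_clusters(self):
        rng = np.random.default_rng(19)
        calls = jittered_instance(rng, n_loci=10, copies=8)
        strict = collapse(calls, MergeParams(refdist=150))
        loose = collapse(calls, MergeParams(refdist=500))
        assert len(loose.loci) <= len(strict.loci)

    def test_same_sample_het_pair_phase_unknown_merges_hom(self, params):
        calls = [sv("a", 1000, sample="s1"), sv("b", 1050, sample="s1")]
        gts = {"a": {"s1": Genotype((0, 1))}, "b": {"s1": Genotype((0, 1))}}
        m = collapse(calls, params, genotypes=gts)
        locus = m.loci[0]
        assert m.genotype(locus.id, "s1").is_hom_alt
        assert m.provenance[locus.id]["flags"]  # flagged as ambiguous

    def test_same_sample_het_pair_same_haplotype_stays_het(self, params):
        calls = [sv("a", 1000, sample="s1"), sv("b", 1050, sample="s1")]
        gts = {"a": {"s1": Genotype((0, 1), phased=True)},
               "b": {"s1": Genotype((0, 1), phased=True)}}
        m = collapse(calls, params, genotypes=gts, haplotypes={"a": 1, "b": 1})
        assert m.genotype(m.loci[0].id, "s1").is_het

    def test_caller_duplicates_keep_het(self, params):
        # one allele reported by three callers is not two alleles
        calls = [
            SVRecord(id=f"a{i}", chrom="chr1", pos=1000 + i * 10, svtype="DEL",
                     svlen=100, qual=50, callers=frozenset([c]), sample="s1")
            for i, c in enumerate(["assembly", "aligner_a", "aligner_b"])
        ]
        gts = {c.id: {"s1": Genotype((0, 1))} for c in calls}
        m = collapse(calls, params, genotypes=gts)
        assert len(m.loci) == 1
        assert m.genotype(m.loci[0].id, "s1").is_het


class TestMendelianConcordance:
    def _ped(self):
        return Pedigree([
            PedigreeEntry("fa", "f1", "father", "male", False),
            PedigreeEntry("mo", "f1", "mother", "female", False),
            PedigreeEntry("p1", "f1", "proband", "female", True),
        ])

    def test_consistent_trio_scores_one(self, params):
        calls = [sv("a", 1000, sample="fa"), sv("b", 1010, sample="mo"),
                 sv("c", 1020, sample="p1")]
        gts = {"a": {"fa": Genotype((0, 1))}, "b": {"mo": Genotype((0, 1))},
               "c": {"p1": Genotype((1, 1))}}
        m = collapse(calls, params, genotypes=gts, samples=["fa", "mo", "p1"])
        rates, mean = mendelian_concordance(m, self._ped())
        assert rates["p1"] == 1.0 and mean == 1.0

    def test_hom_child_with_ref_parent_is_discordant(self, params):
        from svsieve.merge import GenotypeMatrix

        locus = sv("a", 1000)
        m = GenotypeMatrix(
            [locus], ["fa", "mo", "p1"],
            {"a": {"fa": Genotype((0, 1)), "mo": Genotype((0, 0)),
                   "p1": Genotype((1, 1))}},
        )
        rates, _ = mendelian_concordance(m, self._ped())
        assert rates["p1"] == 0.0

    def test_errorfree_simulation_fully_concordant(self, perfect_run):
        # every checked (non-missing-parent) locus follows transmission
        assert perfect_run.mean_concordance == 1.0
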