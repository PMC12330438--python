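"""Synthetic-cohort generator: determinism, ledger completeness, and the
statistical structure of the emitted data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svsieve.merge import validate_callerset
from svsieve.sim import (
    SimulationConfig,
    _hw_genotype,
    simulate_alignments,
    simulate_cohort,
    simulate_methylation,
    simulate_read_support,
)
from svsieve.types import ALIGNER_A, ALIGNER_B, ASSEMBLY
from tests.conftest import perfect_config


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = SimulationConfig(seed=5, n_common_sv=200, n_controls=20)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimulationConfig(seed=5, n_common_sv=200, n_controls=20))
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        assert a.callsets.keys() == b.callsets.keys()
        for s in a.callsets:
            assert a.callsets[s] == b.callsets[s]

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(seed=5, n_common_sv=200, n_controls=20))
        b = simulate_cohort(SimulationConfig(seed=6, n_common_sv=200, n_controls=20))
        assert not a.ledger.equals(b.ledger)


class TestConfigValidation:
    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            SimulationConfig(breakpoint_jitter_sd=400.0)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genotype_error_rate=1.5)


class TestHardyWeinberg:
    def test_af_one_every_sample_carries(self):
        rng = np.random.default_rng(0)
        for sex in ("male", "female"):
            for chrom in ("chr1", "chrX"):
                gt = _hw_genotype(rng, 1.0, chrom, sex)
                assert gt.has_alt

    def test_female_has_no_y_genotype(self):
        rng = np.random.default_rng(0)
        assert _hw_genotype(rng, 0.5, "chrY", "female") is None

    def test_control_genotypes_match_hw_proportions(self):
        # aggregate goodness of fit over loci, autosomes, no AFR boost
        cfg = SimulationConfig(seed=9, n_common_sv=300, n_controls=400,
                               afr_fraction=0.0, frac_x=0.0, frac_y=0.0,
                               af_beta=(2.0, 2.0), families=())
        cohort = simulate_cohort(cfg)
        chi2_total, dof = 0.0, 0
        for row in cohort.ledger.itertuples():
            p = row.af
            gts = cohort.truth_genotypes[row.sv_id]
            n_hom = sum(1 for s in cohort.panel.samples
                        if (g := gts.get(s)) is not None and g.is_hom_alt)
            n_het = sum(1 for s in cohort.panel.samples
                        if (g := gts.get(s)) is not None and g.is_het)
            n = len(cohort.panel.samples)
            n_ref = n - n_hom - n_het
            exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
            if exp.min() < 5:
                continue
            obs = np.array([n_ref, n_het, n_hom])
            chi2_total += ((obs - exp) ** 2 / exp).sum()
            dof += 2
        assert dof > 100
        # total chi2 ~ chi2(dof) under HW; reject only at extreme quantile
        assert stats.chi2.sf(chi2_total, dof) > 1e-4

    def test_afr_controls_carry_more_svs(self):
        cfg = SimulationConfig(seed=9, n_common_sv=400, n_controls=200,
                               afr_fraction=0.5, families=())
        cohort = simulate_cohort(cfg)
        counts = {"AFR": [], "non-AFR": []}
        for s in cohort.panel.samples:
            n = sum(1 for tid in cohort.panel.genotypes
                    if (g := cohort.panel.genotypes[tid].get(s)) is not None and g.has_alt)
            counts[cohort.control_superpops[s]].append(n)
        assert np.mean(counts["AFR"]) > np.mean(counts["non-AFR"])

    def test_af_spectrum_matches_beta(self):
        cfg = SimulationConfig(seed=21, n_common_sv=10_000, n_controls=0,
                               families=(), af_beta=(0.3, 2.0))
        cohort = simulate_cohort(cfg)
        ks = stats.kstest(cohort.ledger["af"], stats.beta(0.3, 2.0).cdf)
        assert ks.pvalue > 0.01


class TestLedger:
    def test_every_call_is_ledger_traceable(self, perfect_cohort):
        ids = set(perfect_cohort.ledger["sv_id"])
        for sample, sets in perfect_cohort.callsets.items():
            for calls in sets.values():
                for c in calls:
                    assert perfect_cohort.truth_id_of(c.id) in ids

    def test_full_sensitivity_emits_every_carrier(self, perfect_cohort):
        co = perfect_cohort
        for tid, gts in co.truth_genotypes.items():
            for sample in co.pedigree.samples:
                gt = gts.get(sample)
                if gt is not None and gt.has_alt:
                    assert any(c.id == f"{tid}@{sample}@{ASSEMBLY}"
                               for c in co.callsets[sample][ASSEMBLY])

    def test_planted_de_novo_counts(self, perfect_cohort):
        led = perfect_cohort.ledger
        dn = led[led["planted_class"] == "de_novo"]
        per_child = dn.groupby("child").size()
        for child in perfect_cohort.pedigree.children:
            assert per_child.get(child.sample_id, 0) == \
                perfect_cohort.config.n_denovo_per_child

    def test_planted_loci_absent_from_controls(self, perfect_cohort):
        co = perfect_cohort
        planted = co.ledger.loc[co.ledger["planted_class"] != "common", "sv_id"]
        for tid in planted:
            assert co.control_carriers(tid) == []

    def test_size_distribution_is_bimodal(self):
        cfg = SimulationConfig(seed=2, n_common_sv=4000, n_controls=0, families=())
        cohort = simulate_cohort(cfg)
        sizes = cohort.ledger["svlen"]
        # Alu-like and LINE-like modes both populated
        assert ((sizes > 200) & (sizes < 400)).mean() > 0.3
        assert ((sizes > 4000) & (sizes < 8000)).mean() > 0.05


class TestCallersetClosedForm:
    def test_validated_fraction_matches_one_minus_miss_squared(self):
        cfg = perfect_config(seed=13, n_common_sv=2000, n_controls=10,
                             caller_sensitivity={ASSEMBLY: 1.0, ALIGNER_A: 0.8,
                                                 ALIGNER_B: 0.8})
        cohort = simulate_cohort(cfg)
        n_val = n_tot = 0
        for sample in cohort.pedigree.samples:
            sets = cohort.callsets[sample]
            v, r = validate_callerset(sets[ASSEMBLY],
                                      [sets[ALIGNER_A], sets[ALIGNER_B]],
                                      cfg.params)
            n_val += len(v)
            n_tot += len(v) + len(r)
        frac = n_val / n_tot
        se = np.sqrt(0.96 * 0.04 / n_tot)
        assert frac == pytest.approx(1 - 0.2**2, abs=4 * se)


class TestReadSupport:
    def test_zero_noise_means_zero_de_novo_support(self, perfect_cohort):
        support = simulate_read_support(perfect_cohort)
        dn_ids = set(perfect_cohort.ledger.loc[
            perfect_cohort.ledger["planted_class"] == "de_novo", "sv_id"])
        dn_rows = support[support["sv_id"].isin(dn_ids)]
        assert len(dn_rows) and (dn_rows["n_reads"] == 0).all()

    def test_carrier_support_matches_poisson_tail(self, perfect_cohort):
        co = perfect_cohort
        support = simulate_read_support(co)
        carrier = []
        for r in support.itertuples():
            gt = co.truth_genotypes[r.sv_id].get(r.sample)
            if gt is not None and gt.has_alt:
                carrier.append(r.n_reads)
        carrier = np.array(carrier)
        lam = co.config.lambda_carrier
        expected = 1 - stats.poisson.cdf(2, lam)
        frac = (carrier >= 3).mean()
        se = np.sqrt(expected * (1 - expected) / len(carrier))
        assert frac == pytest.approx(expected, abs=4 * se + 1e-9)

    def test_reproducible(self, perfect_cohort):
        a = simulate_read_support(perfect_cohort)
        b = simulate_read_support(perfect_cohort)
        pd.testing.assert_frame_equal(a, b)


class TestAlignments:
    def test_single_contig_covers_everything(self):
        recs = simulate_alignments(1, 5_000_000, seed=0)
        assert len(recs) == 1
        assert recs[0].tstart == 0 and recs[0].tend == 5_000_000

    def test_deterministic(self):
        assert simulate_alignments(5, 10**6, seed=4) == simulate_alignments(5, 10**6, seed=4)


class TestMethylation:
    def _islands(self, n=10):
        return pd.DataFrame({
            "chrom": "chrX",
            "start": np.arange(n) * 100_000 + 20_000,
            "end": np.arange(n) * 100_000 + 21_000,
            "name": [f"cgi{i}" for i in range(n)],
        })

    def test_zero_skew_equal_means(self):
        h1, h2 = simulate_methylation(self._islands(), skew=0.0, noise_sd=0.01, seed=1)
        assert abs(h1["frac"].mean() - h2["frac"].mean()) < 0.01

    def test_noise_free_skew_is_exact(self):
        h1, h2 = simulate_methylation(self._islands(), skew=0.8, noise_sd=0.0, seed=1)
        merged = h1["frac"].to_numpy() - h2["frac"].to_numpy()
        assert np.allclose(merged, 0.8)

    def test_fractions_clipped_to_unit_interval(self):
        h1, h2 = simulate_methylation(self._islands(), skew=1.2, noise_sd=0.3, seed=1)
        for df in (h1, h2):
            assert df["frac"].between(0, 1).all()
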