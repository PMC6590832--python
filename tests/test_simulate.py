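"""Synthetic cohort generator: founder pools, drift, pooled reads, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from evopool.pedigree import PAPER_DESIGNS, expected_het_retention, expected_inbreeding
from evopool.simulate import (
    CohortConfig,
    LineConfig,
    PhenotypeParams,
    generate_cohort,
    make_founder_pool,
    simulate_drift,
    simulate_pair_mating_ibd,
    simulate_phenotypes,
    simulate_pool_reads,
    write_cohort,
)


class TestFounderPool:
    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            make_founder_pool(0)

    def test_deterministic_under_seed(self):
        a = make_founder_pool(500, seed=42).loci
        b = make_founder_pool(500, seed=42).loci
        pd.testing.assert_frame_equal(a, b)

    def test_point_mass_half_gives_quarter_het_per_locus(self):
        pool = make_founder_pool(400, freq_law=("point", 0.5), seed=0)
        assert pool.founder_het == pytest.approx(400 * 0.25)

    def test_positions_strictly_increasing_within_chromosome(self):
        pool = make_founder_pool(2000, seed=1)
        for _, sub in pool.loci.groupby("chrom"):
            assert np.all(np.diff(sub["pos"].to_numpy()) > 0)

    def test_frequencies_truncated(self):
        pool = make_founder_pool(5000, seed=2)
        assert pool.p0.min() >= 0.05 and pool.p0.max() <= 0.95


class TestDrift:
    def test_absorbing_states(self):
        freqs = np.array([0.0, 1.0, 0.0, 1.0])
        out = simulate_drift(freqs, PAPER_DESIGNS["High"], seed=3)
        assert np.array_equal(out, freqs)

    def test_huge_census_preserves_frequencies(self):
        from evopool.pedigree import BottleneckDesign

        design = BottleneckDesign(bottleneck_size=10**7, n_bottleneck_gens=3, flush_size=10**7)
        p0 = np.linspace(0.1, 0.9, 50)
        out = simulate_drift(p0, design, seed=4, n_flush_gens=1)
        assert np.allclose(out, p0, atol=0.01)

    def test_mean_het_retention_matches_wf_oracle(self):
        """1000 one-generation bottleneck lines at N=4 retain ~7/8 of het."""
        p0 = make_founder_pool(300, seed=5).p0
        h0 = np.sum(p0 * (1 - p0))
        rng = np.random.default_rng(6)
        p = np.broadcast_to(p0, (1000, 300)).copy()
        p = rng.binomial(8, p) / 8.0
        retention = np.sum(p * (1 - p), axis=1) / h0
        se = retention.std(ddof=1) / np.sqrt(1000)
        assert abs(retention.mean() - 0.875) < 3 * se

    def test_pair_mating_autozygosity_tracks_recursion(self):
        est = simulate_pair_mating_ibd(2, 100_000, seed=8)
        assert est == pytest.approx(expected_inbreeding(4, 2).final, abs=0.005)


class TestPoolReads:
    def test_all_zero_frequencies_give_zero_counts(self):
        t = simulate_pool_reads(np.zeros(200), seed=9)
        assert (t["variant_count"] == 0).all()

    def test_zero_depth_gives_empty_table(self):
        t = simulate_pool_reads(np.full(50, 0.5), depth_law=("point", 0), seed=10)
        assert len(t) == 0

    def test_counts_bounded_by_coverage(self):
        t = simulate_pool_reads(np.random.default_rng(11).uniform(0.05, 0.95, 500), seed=12)
        assert (t["variant_count"] <= t["coverage"]).all()
        assert (t["coverage"] <= 600).all()

    def test_binomial_sampling_moment(self):
        """At coverage c, E[p(1-p)] = q(1-q)(1-1/c) for the pool frequency q."""
        c, q, m = 30, 0.3, 120_000
        rng = np.random.default_rng(13)
        phat = rng.binomial(c, q, size=m) / c
        vals = phat * (1 - phat)
        se = vals.std(ddof=1) / np.sqrt(m)
        assert abs(vals.mean() - q * (1 - q) * (1 - 1 / c)) < 3 * se


class TestPhenotypes:
    def _params(self, **kw):
        base = dict(productivity_sd=0.0, body_mass_ind_sd=0.0, out_sd=0.0)
        base.update(kw)
        return PhenotypeParams(**base)

    def test_zero_response_zero_noise_gives_flat_traits(self):
        params = self._params(productivity_beta=0.0)
        traits, _, ext = simulate_phenotypes("x", 1.0, params, np.random.default_rng(1))
        assert ext is None
        prod = traits[traits["trait"] == "productivity"]["value"]
        assert np.allclose(prod, params.productivity_baseline)

    def test_full_diversity_recovers_beta_exactly(self):
        from scipy.stats import linregress

        params = self._params()
        traits, _, _ = simulate_phenotypes("x", 1.0, params, np.random.default_rng(2))
        prod = traits[traits["trait"] == "productivity"]
        res = linregress(prod["generation"], prod["value"])
        assert res.slope == pytest.approx(params.productivity_beta, abs=1e-12)

    def test_extinct_lines_have_lower_diversity_on_average(self):
        params = PhenotypeParams()
        rng = np.random.default_rng(3)
        relhets = rng.uniform(0.3, 1.0, size=600)
        ext_flag = []
        for i, rh in enumerate(relhets):
            _, _, ext = simulate_phenotypes("x", rh, params, np.random.default_rng(100 + i))
            ext_flag.append(ext is not None)
        ext_flag = np.array(ext_flag)
        assert ext_flag.any() and (~ext_flag).any()
        assert relhets[ext_flag].mean() < relhets[~ext_flag].mean()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(productivity_sd=-1.0)


class TestLineConfig:
    def test_group_design_consistency_enforced(self):
        with pytest.raises(ValueError):
            LineConfig("x", "Low", PAPER_DESIGNS["High"], 1.0, 0)
        with pytest.raises(ValueError):
            LineConfig("x", "OB", PAPER_DESIGNS["Low"], 2.5, 0)
        LineConfig("x", "OB", None, 2.5, 0)  # valid


class TestCohort:
    def test_default_cohort_has_132_lines(self):
        cfg = CohortConfig(master_seed=0, n_loci=10)  # loci count irrelevant here
        cohort = generate_cohort(cfg)
        assert len(cohort.lines) == 132
        assert cohort.manifest["group"].value_counts().to_dict() == {
            "Low": 42, "Medium": 40, "High": 40, "OB": 10,
        }

    def test_group_ordering_of_retained_diversity(self, small_cohort):
        means = small_cohort.manifest.groupby("group")["relative_het"].mean()
        assert means["OB"] > means["Low"] > means["Medium"] > means["High"]

    def test_realized_het_bounded_by_founder_het(self, small_cohort):
        fh = small_cohort.pool.founder_het
        assert all(l.realized_het <= fh for l in small_cohort.lines)

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        cfg = CohortConfig(
            master_seed=11, group_sizes={"Low": 2, "Medium": 2, "High": 2, "OB": 2},
            n_loci=300,
        )
        p1 = write_cohort(generate_cohort(cfg), tmp_path / "a")
        p2 = write_cohort(generate_cohort(cfg), tmp_path / "b")
        for key in ("traits", "viability", "manifest"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
        for f1 in sorted(p1["variants_dir"].glob("*.tsv")):
            f2 = p2["variants_dir"] / f1.name
            assert f1.read_bytes() == f2.read_bytes()

    def test_minimal_cohort_smoke(self):
        cfg = CohortConfig(
            master_seed=1, group_sizes={"Low": 1, "Medium": 1, "High": 1, "OB": 1},
            n_loci=50,
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.lines) == 4

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(effective_copies_range=(1, 14))
        with pytest.raises(ValueError):
            CohortConfig(p_seq_fail=1.5)
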