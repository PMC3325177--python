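"""Per-SNP joint-tail p, ensemble resampling test, and FST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popdiff.differentiation import (
    build_ensemble_pools,
    empirical_two_sided_p,
    ensemble_null,
    ensemble_test,
    fst_enrichment,
    fst_nei,
    fst_weir_cockerham,
    genome_fst,
    snp_directional_p,
    snp_fst,
)
from popdiff.errors import DataError, InsufficientDataError, ParameterError

from conftest import make_table


def brute_force_directional_p(table, rsid, risk, region_map, tol=0.01):
    """Independent oracle: explicit loop over every allele of every other SNP."""
    obs_ref = table.raf(rsid, risk, "European", region_map)
    obs_high = table.raf(rsid, risk, "African", region_map)
    obs_low = table.raf(rsid, risk, "Asian", region_map)
    count = size = 0
    for other in table.rsids:
        if other == rsid:
            continue
        a, b = table.alleles(other)
        # the candidate allele matched on the reference-region frequency
        da = abs(table.raf(other, a, "European", region_map) - obs_ref)
        db = abs(table.raf(other, b, "European", region_map) - obs_ref)
        if da <= tol and (da <= db or db > tol):
            allele = a
        elif db <= tol:
            allele = b
        else:
            continue
        size += 1
        if (
            table.raf(other, allele, "African", region_map) > obs_high
            and table.raf(other, allele, "Asian", region_map) < obs_low
        ):
            count += 1
    p = count / size if count else 1.0 / (size + 1)
    return p, size


class TestSnpDirectionalP:
    def _table(self, member_freqs):
        """Target rs0 (ref 0.5, high 0.6, low 0.4) plus members (high, low) at ref 0.5."""
        rows = []
        profiles = [("rs0", 0.6, 0.4, 0.5)] + [
            (f"rs{i + 1}", h, l, 0.5) for i, (h, l) in enumerate(member_freqs)
        ]
        for rsid, high, low, ref in profiles:
            for pop, f in (("YRI", high), ("LWK", high), ("CEU", ref), ("TSI", ref),
                           ("CHB", low), ("JPT", low)):
                rows.append((rsid, "A", "G", pop, f, 100))
        return make_table(rows)

    def test_enumerated_toy_pool(self, region_map):
        # exactly one of five members beats the target on both sides
        t = self._table([(0.7, 0.3), (0.65, 0.45), (0.55, 0.35), (0.5, 0.5), (0.6, 0.4)])
        res = snp_directional_p(
            t, "rs0", "A", region_map, "African", "Asian", "European",
            tolerance=0.01, min_pool=1,
        )
        assert res.pool_size == 5
        assert res.p_value == pytest.approx(1 / 5)

    def test_strict_inequalities_floor_degenerate_pool(self, region_map):
        t = self._table([(0.6, 0.4)] * 4)  # every member ties the target exactly
        res = snp_directional_p(
            t, "rs0", "A", region_map, "African", "Asian", "European",
            tolerance=0.01, min_pool=1,
        )
        assert res.n_extreme == 0
        assert res.p_value == pytest.approx(1 / (4 + 1))

    def test_matches_brute_force_enumeration(self, region_map):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(400):
            base = rng.uniform(0.1, 0.9)
            for pop in ("YRI", "LWK", "CEU", "TSI", "CHB", "JPT"):
                rows.append(
                    (f"rs{i}", "A", "G", pop, float(np.clip(base + rng.normal(0, 0.05), 0, 1)), 100)
                )
        t = make_table(rows)
        for rsid in ("rs0", "rs7", "rs100"):
            res = snp_directional_p(
                t, rsid, "A", region_map, "African", "Asian", "European",
                tolerance=0.05, min_pool=1,
            )
            p_oracle, size_oracle = brute_force_directional_p(
                t, rsid, "A", region_map, tol=0.05
            )
            assert res.pool_size == size_oracle
            assert res.p_value == pytest.approx(p_oracle)

    def test_null_target_has_quarter_tail(self, region_map):
        """Two independent sign events: P(higher AND lower) -> 1/4 on a balanced pool."""
        rng = np.random.default_rng(5)
        members = [(0.5 + rng.normal(0, 0.1), 0.5 + rng.normal(0, 0.1)) for _ in range(4000)]
        rows = []
        for rsid, high, low, ref in [("rs0", 0.5, 0.5, 0.5)] + [
            (f"rs{i + 1}", float(np.clip(h, 0, 1)), float(np.clip(l, 0, 1)), 0.5)
            for i, (h, l) in enumerate(members)
        ]:
            for pop, f in (("YRI", high), ("LWK", high), ("CEU", ref), ("TSI", ref),
                           ("CHB", low), ("JPT", low)):
                rows.append((rsid, "A", "G", pop, f, 100))
        res = snp_directional_p(
            make_table(rows), "rs0", "A", region_map, "African", "Asian", "European",
            tolerance=0.01, min_pool=1,
        )
        assert res.p_value == pytest.approx(0.25, abs=0.03)


class TestEnsemble:
    def test_point_mass_null_for_identical_member(self, region_map):
        rows = []
        for rsid in ("rs0", "rs1", "rsX"):  # rsX identical in profile to rs0
            high, low = (0.6, 0.4) if rsid != "rs1" else (0.55, 0.45)
            for pop, f in (("YRI", high), ("LWK", high), ("CEU", 0.5), ("TSI", 0.5),
                           ("CHB", low), ("JPT", low)):
                rows.append((rsid, "A", "G", pop, f, 100))
        t = make_table(rows)
        pools = build_ensemble_pools(
            t, [("rs0", "A")], region_map, "European", tolerance=0.0, min_pool=1
        )
        # tolerance 0 leaves rsX and rs1 (both at ref 0.5); restrict to rsX
        pool = pools[0]
        keep = pool.members == "rsX"
        pool.members, pool.orient_a, pool.member_freq = (
            pool.members[keep], pool.orient_a[keep], pool.member_freq[keep],
        )
        null = ensemble_null(t, [pool], region_map, ("African", "European"),
                             n_resamples=50, seed=1)
        assert np.allclose(null, 0.6 - 0.5)

    def test_zero_delta_members_give_zero_null(self, region_map):
        rows = []
        for i in range(30):
            for pop in ("YRI", "LWK", "CEU", "TSI", "CHB", "JPT"):
                rows.append((f"rs{i}", "A", "G", pop, 0.4, 100))
        t = make_table(rows)
        pools = build_ensemble_pools(t, [("rs0", "A")], region_map, "European",
                                     tolerance=0.01, min_pool=1)
        null = ensemble_null(t, pools, region_map, ("African", "European"),
                             n_resamples=100, seed=0)
        assert np.all(null == 0.0)

    def test_same_seed_reproduces_null(self, null_corpus):
        t = null_corpus.frequencies
        rm = null_corpus.config.region_map()
        snps = [(r, t.alleles(r)[0]) for r in null_corpus.disease_rsids[:5]]
        pools = build_ensemble_pools(t, snps, rm, "European", tolerance=0.05)
        a = ensemble_null(t, pools, rm, ("African", "European"), 500, seed=7)
        b = ensemble_null(t, pools, rm, ("African", "European"), 500, seed=7)
        assert np.array_equal(a, b)
        c = ensemble_null(t, pools, rm, ("African", "European"), 500, seed=8)
        assert not np.array_equal(a, c)

    def test_two_sided_p_continuity_rules(self):
        null = np.linspace(-1, 1, 999)
        assert empirical_two_sided_p(null, 0.0) == 1.0
        assert empirical_two_sided_p(null, 2.0) == pytest.approx(2 / 1000)
        assert empirical_two_sided_p(null, -2.0) == pytest.approx(2 / 1000)

    def test_missing_snp_dropped_with_named_warning(self, cline_corpus):
        t = cline_corpus.frequencies
        rm = cline_corpus.config.region_map()
        df = t.df[~((t.df.rsid == "rs1") & t.df.population.isin(["JPT", "CHB", "CHD"]))]
        import popdiff

        t2 = popdiff.FrequencyTable(df)
        snps = [(r, t2.alleles(r)[0]) for r in cline_corpus.disease_rsids]
        with pytest.warns(UserWarning, match="rs1"):
            res = ensemble_test(t2, snps, rm, ("Asian", "European"),
                                n_resamples=200, seed=1)
        assert "rs1" in res.dropped and "rs1" not in res.snps

    def test_all_snps_missing_is_an_error(self, region_map):
        t = make_table([("rs0", "A", "G", "CEU", 0.5, 100),
                        ("rs1", "A", "G", "CEU", 0.5, 100)])
        with pytest.raises((DataError, InsufficientDataError)):
            ensemble_test(t, [("rs0", "A"), ("rs1", "A")], region_map,
                          ("African", "European"), n_resamples=100, seed=0)

    def test_disease_null_pool_drawn_from_source_list(self, cline_corpus):
        t = cline_corpus.frequencies
        rm = cline_corpus.config.region_map()
        targets = [(r, t.alleles(r)[0]) for r in cline_corpus.disease_rsids[:3]]
        source = [(f"rs{i}", t.alleles(f"rs{i}")[0]) for i in range(500, 1500)]
        pools = build_ensemble_pools(t, targets, rm, "European",
                                     tolerance=0.05, source_alleles=source)
        allowed = {r for r, _ in source}
        for pool in pools:
            assert set(pool.members) <= allowed

    def test_null_p_values_approximately_uniform(self, null_corpus):
        """Kolmogorov-Smirnov check of the two-sided p under the null."""
        t = null_corpus.frequencies
        rm = null_corpus.config.region_map()
        genome = t.rsids
        rng = np.random.default_rng(21)
        ps = []
        for run in range(200):
            idx = rng.choice(len(genome), 10, replace=False)
            snps = []
            for i in idx:
                a, b = t.alleles(genome[i])
                snps.append((genome[i], a if rng.random() < 0.5 else b))
            res = ensemble_test(t, snps, rm, ("African", "European"),
                                n_resamples=500, seed=int(rng.integers(2**31)))
            ps.append(res.p_two_sided)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFst:
    def test_no_differentiation(self):
        assert fst_nei(np.array([0.5, 0.5])) == pytest.approx(0.0)

    def test_opposite_fixation(self):
        assert fst_nei(np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p = (0.2, 0.8): H_T = 0.5, H_S = 0.32, FST = 0.36
        assert fst_nei(np.array([0.2, 0.8])) == pytest.approx(0.36)

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, size=(200, 3))
        w = rng.integers(50, 500, size=(200, 3))
        assert np.allclose(fst_nei(p, w), fst_nei(1 - p, w))
        assert np.allclose(fst_weir_cockerham(p, w), fst_weir_cockerham(1 - p, w))

    def test_single_region_rejected(self):
        with pytest.raises(ParameterError):
            fst_nei(np.array([0.5]))
        with pytest.raises(ParameterError):
            snp_fst({"Africa": 0.5})

    def test_snp_fst_reports_all_pairs(self):
        res = snp_fst({"Africa": 0.8, "Europe": 0.5, "Asia": 0.2})
        assert set(res.fst_pairwise) == {"Africa-Europe", "Africa-Asia", "Europe-Asia"}
        assert res.fst_pairwise["Africa-Asia"] > res.fst_pairwise["Africa-Europe"]

    def test_weir_cockerham_tracks_nei(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(500, 3))
        w = np.full((500, 3), 200.0)
        wc = fst_weir_cockerham(p, w)
        nei = fst_nei(p, np.full((500, 3), 1.0))
        assert np.corrcoef(wc, nei)[0, 1] > 0.99

    def test_genome_fst_recovers_drift_parameter(self):
        """Population-level Nei FST estimates the Balding-Nichols F."""
        import popdiff

        cfg = popdiff.SimulationConfig(n_genome_snps=2000, n_disease_snps=0,
                                       f_drift=0.1, seed=7)
        t = popdiff.simulate_frequency_table(cfg)
        fst = fst_nei(t.freq_matrix().to_numpy())
        assert 0.08 <= float(np.mean(fst)) <= 0.12


class TestFstEnrichment:
    def test_max_fst_in_bin_gets_percentile_100(self, cline_corpus):
        t = cline_corpus.frequencies
        rm = cline_corpus.config.region_map()
        fst = genome_fst(t, rm, ["African", "European", "Asian"])
        pooled, _, _ = t.pooled(rm, "European")
        from popdiff.frequencies import maf_bin

        bins = maf_bin(pooled.to_numpy())
        target_bin = bins[0]
        in_bin = fst["global"][bins == target_bin]
        top = in_bin.idxmax()
        res = fst_enrichment([top], t, rm, ["African", "European", "Asian"], "European")
        assert res.per_snp.loc[top, "percentile_global"] == pytest.approx(100.0)

    def test_cline_loci_are_enriched(self, cline_corpus):
        res = fst_enrichment(
            cline_corpus.disease_rsids,
            cline_corpus.frequencies,
            cline_corpus.config.region_map(),
            ["African", "European", "Asian"],
            "European",
        )
        assert res.p_values["global"] < 0.01
        assert res.p_values["African-Asian"] < 0.01

    def test_calibrated_on_null_subsets(self, null_corpus):
        """Disease sets drawn from the genome itself give uniform-ish U-test p."""
        t = null_corpus.frequencies
        rm = null_corpus.config.region_map()
        rng = np.random.default_rng(2)
        genome = np.array(t.rsids, dtype=object)
        ps = []
        for _ in range(60):
            chosen = list(rng.choice(genome, 20, replace=False))
            res = fst_enrichment(chosen, t, rm, ["African", "European", "Asian"], "European")
            ps.append(res.p_values["global"])
        assert 0.25 <= float(np.median(ps)) <= 0.75

    def test_zero_variance_bin_excluded_with_warning(self, region_map):
        rows = []
        for i in range(30):  # identical frequencies: every FST is 0 in every bin
            for pop in ("YRI", "LWK", "CEU", "TSI", "CHB", "JPT"):
                rows.append((f"rs{i}", "A", "G", pop, 0.3, 100))
        t = make_table(rows)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fst_enrichment(["rs0"], t, region_map,
                                 ["African", "European", "Asian"], "European")
        assert res.excluded == ["rs0"]
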