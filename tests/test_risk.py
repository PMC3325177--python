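"""Genotype LRs, PGR/GRS scores, and the permutation contrast test."""

import math

import numpy as np
import pandas as pd
import pytest

from popdiff.errors import DataError, MissingDataError, ParameterError
from popdiff.risk import (
    GenotypeMatrix,
    LocusRiskModel,
    StudyLR,
    build_locus_models,
    combine_study_lrs,
    genotype_lr,
    grs,
    hwe_fallback_model,
    permutation_contrast_test,
    pgr,
    score_matrix,
)


def model(rsid, lrs, ln_or=None):
    return LocusRiskModel(
        rsid=rsid, risk_allele="A",
        lr_by_genotype={"hom_risk": lrs[0], "het": lrs[1], "hom_other": lrs[2]},
        ln_or=ln_or,
    )


class TestGenotypeLr:
    def test_direct_arithmetic(self):
        lr = genotype_lr((50, 30, 20), (25, 50, 25))
        assert lr == pytest.approx({"hom_risk": 2.0, "het": 0.6, "hom_other": 0.8})

    def test_null_locus(self):
        lr = genotype_lr((10, 20, 10), (10, 20, 10))
        assert lr == pytest.approx({"hom_risk": 1.0, "het": 1.0, "hom_other": 1.0})

    def test_zero_cell_continuity_correction(self):
        # +0.5 on all six cells: case (50.5, 30.5, 20.5)/101.5; control (25.5, 50.5, 0.5)/76.5
        lr = genotype_lr((50, 30, 20), (25, 50, 0))
        case = np.array([50.5, 30.5, 20.5]) / 101.5
        ctrl = np.array([25.5, 50.5, 0.5]) / 76.5
        assert lr["hom_risk"] == pytest.approx(case[0] / ctrl[0])
        assert lr["hom_other"] == pytest.approx(case[2] / ctrl[2])
        assert all(np.isfinite(v) for v in lr.values())

    def test_all_zero_triple_is_error(self):
        with pytest.raises(DataError):
            genotype_lr((0, 0, 0), (10, 10, 10))


class TestCombineStudyLrs:
    def _study(self, lr, n, study="s", allele="A"):
        return StudyLR(rsid="rs1", risk_allele=allele, n_total=n,
                       lr_by_genotype={"hom_risk": lr, "het": 1.0, "hom_other": 1.0})

    def test_sqrt_n_weighted_mean(self):
        # (2*10 + 3*20) / 30 = 2.6667
        combined = combine_study_lrs([self._study(2.0, 100), self._study(3.0, 400)])
        assert combined.lr_by_genotype["hom_risk"] == pytest.approx(8 / 3)

    def test_single_study_identity(self):
        combined = combine_study_lrs([self._study(1.7, 500)])
        assert combined.lr_by_genotype["hom_risk"] == pytest.approx(1.7)

    def test_equal_weights(self):
        combined = combine_study_lrs([self._study(1.5, 900), self._study(2.5, 900)])
        assert combined.lr_by_genotype["hom_risk"] == pytest.approx(2.0)

    def test_conflicting_risk_alleles_rejected(self):
        with pytest.raises(DataError, match="rs1"):
            combine_study_lrs([self._study(1.5, 100), self._study(2.0, 100, allele="G")])

    def test_matches_hand_computed_oracle_on_random_cases(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            lrs = rng.uniform(0.5, 3.0, size=4)
            ns = rng.integers(50, 5000, size=4)
            studies = [self._study(float(l), int(n)) for l, n in zip(lrs, ns)]
            w = np.sqrt(ns)
            expected = float(np.sum(w * lrs) / np.sum(w))
            combined = combine_study_lrs(studies)
            assert combined.lr_by_genotype["hom_risk"] == pytest.approx(expected, rel=1e-12)


class TestHweFallback:
    def test_null_effect(self):
        assert hwe_fallback_model(0.3, 1.0) == pytest.approx(
            {"hom_risk": 1.0, "het": 1.0, "hom_other": 1.0}
        )

    def test_multiplicative_model_hand_evaluation(self):
        # raf 0.5, OR 2: control (0.25, 0.5, 0.25); case ∝ (0.25, 1.0, 1.0), sum 2.25
        lr = hwe_fallback_model(0.5, 2.0)
        assert lr["hom_other"] == pytest.approx(4 / 9)
        assert lr["het"] == pytest.approx(8 / 9)
        assert lr["hom_risk"] == pytest.approx(16 / 9)

    def test_allele_swap_symmetry(self):
        a = hwe_fallback_model(0.3, 2.0)
        b = hwe_fallback_model(0.7, 0.5)  # swapped allele: raf -> 1-raf, OR -> 1/OR
        assert a["hom_risk"] == pytest.approx(b["hom_other"])
        assert a["het"] == pytest.approx(b["het"])
        assert a["hom_other"] == pytest.approx(b["hom_risk"])

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ParameterError):
            hwe_fallback_model(0.0, 1.5)


class TestScores:
    def test_pgr_product_contract(self):
        models = [model("rs1", (2.0, 1.0, 1.0)), model("rs2", (3.0, 1.0, 1.0))]
        log_pgr, used = pgr({"rs1": 2, "rs2": 2}, models)
        assert log_pgr == pytest.approx(math.log(6.0))
        assert used == 2

    def test_pgr_cancellation(self):
        models = [model("rs1", (2.0, 1.0, 1.0)), model("rs2", (0.5, 1.0, 1.0))]
        log_pgr, _ = pgr({"rs1": 2, "rs2": 2}, models)
        assert log_pgr == pytest.approx(0.0)

    def test_missing_dosage_skips_locus(self):
        models = [model(f"rs{i}", (2.0, 1.5, 1.0)) for i in (1, 2, 3)]
        log_pgr, used = pgr({"rs1": 2, "rs2": float("nan"), "rs3": 1}, models)
        assert used == 2
        assert log_pgr == pytest.approx(math.log(2.0) + math.log(1.5))

    def test_all_missing_is_error(self):
        with pytest.raises(DataError):
            pgr({"rs1": None}, [model("rs1", (2.0, 1.0, 1.0))])

    def test_log_pgr_additive_over_disjoint_model_sets(self):
        rng = np.random.default_rng(4)
        models = [
            model(f"rs{i}", tuple(rng.uniform(0.5, 3.0, size=3))) for i in range(8)
        ]
        dosages = {f"rs{i}": int(rng.integers(0, 3)) for i in range(8)}
        whole, _ = pgr(dosages, models)
        first, _ = pgr(dosages, models[:3])
        rest, _ = pgr(dosages, models[3:])
        assert abs(whole - (first + rest)) < 1e-12

    def test_grs_direct_formula(self):
        models = [
            model("rs1", (1, 1, 1), ln_or=math.log(1.5)),
            model("rs2", (1, 1, 1), ln_or=math.log(2.0)),
            model("rs3", (1, 1, 1), ln_or=math.log(1.2)),
        ]
        val = grs({"rs1": 2, "rs2": 1, "rs3": 0}, models)
        assert val == pytest.approx(2 * math.log(1.5) + math.log(2.0))

    def test_grs_null_effects(self):
        models = [model("rs1", (1, 1, 1), ln_or=0.0), model("rs2", (1, 1, 1), ln_or=0.0)]
        assert grs({"rs1": 2, "rs2": 1}, models) == 0.0
        models2 = [model("rs1", (1, 1, 1), ln_or=0.3)]
        assert grs({"rs1": 0}, models2) == 0.0

    def test_grs_and_pgr_agree_on_single_locus(self):
        lrs = hwe_fallback_model(0.4, 1.5)
        m = model("rs1", (lrs["hom_risk"], lrs["het"], lrs["hom_other"]),
                  ln_or=math.log(1.5))
        logs = [pgr({"rs1": d}, [m])[0] for d in (0, 1, 2)]
        gvals = [grs({"rs1": d}, [m]) for d in (0, 1, 2)]
        assert logs == sorted(logs) and gvals == sorted(gvals)


class TestGenotypeMatrix:
    def test_tsv_loader(self, tmp_path):
        (tmp_path / "geno.tsv").write_text(
            "individual\trsid\tdosage\nI1\trs1\t2\nI1\trs2\t0\nI2\trs1\t1\nI2\trs2\t1\n"
        )
        (tmp_path / "samples.tsv").write_text(
            "individual\tpopulation\nI1\tYRI\nI2\tCEU\n"
        )
        m = GenotypeMatrix.from_tsv(tmp_path / "geno.tsv", tmp_path / "samples.tsv")
        assert m.dosages.loc["I1", "rs1"] == 2
        assert m.populations.loc["I2"] == "CEU"

    def test_vcf_round_trip(self, tmp_path, cline_corpus):
        from popdiff.synthetic_data import write_genotype_vcf

        geno = cline_corpus.genotypes
        write_genotype_vcf(geno, cline_corpus.frequencies, tmp_path / "g.vcf")
        pd.DataFrame(
            {"individual": geno.individuals, "population": geno.populations.to_numpy()}
        ).to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        back = GenotypeMatrix.from_vcf(tmp_path / "g.vcf", tmp_path / "s.tsv")
        assert np.array_equal(
            back.dosages[geno.rsids].to_numpy(), geno.dosages.to_numpy(), equal_nan=True
        )
        assert back.counted_allele == geno.counted_allele

    def test_invalid_dosage_rejected(self):
        with pytest.raises(Exception):
            GenotypeMatrix(
                pd.DataFrame({"rs1": [3.0]}, index=["I1"]),
                pd.Series(["YRI"], index=["I1"]),
            )


class TestPermutationContrast:
    def test_null_lr_model_gives_unit_p(self, null_corpus):
        models = [model(r, (1.0, 1.0, 1.0)) for r in null_corpus.disease_rsids]
        res = permutation_contrast_test(
            null_corpus.genotypes, models, null_corpus.config.region_map(),
            null_corpus.frequencies, n_perm=200, seed=0,
        )
        assert all(v == 0.0 for v in res.observed.values())
        assert all(p == 1.0 for p in res.p_values.values())

    def test_cline_produces_opposite_extreme_tails(self, cline_corpus):
        models = build_locus_models(
            [r for r in _records(cline_corpus) if r.rsid in set(cline_corpus.disease_rsids)]
        )
        res = permutation_contrast_test(
            cline_corpus.genotypes, models, cline_corpus.config.region_map(),
            cline_corpus.frequencies, n_perm=500, seed=3,
            exclusions=cline_corpus.disease_rsids,
        )
        assert res.observed["African"] > 0 > res.observed["Asian"]
        assert res.p_values["African"] < 0.05
        assert res.p_values["Asian"] < 0.05

    def test_same_seed_reproduces(self, null_corpus):
        models = [model(r, (1.3, 1.1, 0.9)) for r in null_corpus.disease_rsids[:4]]
        kw = dict(
            region_map=null_corpus.config.region_map(),
            table=null_corpus.frequencies, n_perm=150, seed=8,
        )
        a = permutation_contrast_test(null_corpus.genotypes, models, **kw)
        b = permutation_contrast_test(null_corpus.genotypes, models, **kw)
        assert a.p_values == b.p_values
        assert all(np.array_equal(a.null[g], b.null[g]) for g in a.null)

    def test_tiny_n_perm_warns(self, null_corpus):
        models = [model(r, (1.2, 1.1, 1.0)) for r in null_corpus.disease_rsids[:3]]
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_contrast_test(
                null_corpus.genotypes, models, null_corpus.config.region_map(),
                null_corpus.frequencies, n_perm=50, seed=0,
            )

    def test_unmatchable_locus_is_error(self, null_corpus):
        models = [model(r, (1.2, 1.1, 1.0)) for r in null_corpus.disease_rsids[:3]]
        with pytest.raises((DataError, MissingDataError)):
            permutation_contrast_test(
                null_corpus.genotypes, models, null_corpus.config.region_map(),
                null_corpus.frequencies, n_perm=150, seed=0, tolerance=1e-9,
            )


def _records(corpus):
    from popdiff.catalog import parse_catalog
    import io, tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        corpus.catalog.to_csv(fh, sep="\t", index=False)
        path = fh.name
    try:
        return parse_catalog(path).records
    finally:
        os.unlink(path)


class TestBuildLocusModels:
    def test_models_from_corpus_catalog(self, cline_corpus):
        recs = [r for r in _records(cline_corpus)
                if r.rsid in set(cline_corpus.disease_rsids)]
        models = build_locus_models(recs)
        assert len(models) == len(cline_corpus.disease_rsids)
        for m in models:
            assert all(v > 0 for v in m.lr_by_genotype.values())
            assert m.ln_or is not None
            # risk alleles carry OR > 1 on average, so hom-risk LR should exceed hom-other
            assert m.lr_by_genotype["hom_risk"] > m.lr_by_genotype["hom_other"]

    def test_score_matrix_matches_per_individual_pgr(self, cline_corpus):
        recs = [r for r in _records(cline_corpus)
                if r.rsid in set(cline_corpus.disease_rsids)]
        models = build_locus_models(recs)
        scores = score_matrix(cline_corpus.genotypes, models)
        one = scores[17]
        log_one, used = pgr(
            cline_corpus.genotypes.dosages.loc[one.individual].to_dict(), models
        )
        assert one.log_pgr == pytest.approx(log_one)
        assert one.n_loci_used == used
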