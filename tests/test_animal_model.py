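"""Design construction and REML estimation tests."""

import numpy as np
import pandas as pd
import pytest

from greyherit import (
    GenotypeTable,
    ModelSpec,
    Pedigree,
    StudyDesign,
    TraitConfig,
    build_A,
    build_A_inverse,
    build_design,
    drop_genotypes,
    predict_ebv,
    reml_bivariate,
    reml_univariate,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
    standardize_ebv,
)
from greyherit.animal_model import (
    RankDeficiencyError,
    _BivariateMME,
    _UnivariateMME,
    reml_loglik_univariate,
)

from conftest import dense_reml_loglik, dense_reml_loglik_bivariate, tiny_study


def _two_animal_records():
    return pd.DataFrame(
        {
            "animal": ["A", "A", "B", "B"],
            "value": [1.0, 2.0, 3.0, 4.0],
            "age_months": [90, 100, 90, 100],
        }
    )


class TestBuildDesign:
    def test_intercept_only_design(self):
        ped = Pedigree.from_records(
            [dict(id="A", sire=None, dam=None), dict(id="B", sire=None, dam=None)]
        )
        spec = ModelSpec(age_covariate=False)
        d = build_design(_two_animal_records(), spec, ped=ped)
        assert d.X.shape == (4, 1)
        assert np.all(d.X == 1.0)
        # W incidence: two records per animal
        assert np.bincount(d.rec_animal).tolist() == [2, 2]

    def test_stx17_covariate_column(self):
        ped = Pedigree.from_records(
            [dict(id="A", sire=None, dam=None), dict(id="B", sire=None, dam=None)]
        )
        gt = GenotypeTable(pd.DataFrame({"id": ["A", "B"], "stx17": ["GG", "Gg"]}))
        spec = ModelSpec(age_covariate=False, stx17_covariate=True)
        d = build_design(_two_animal_records(), spec, gt=gt, ped=ped)
        col = d.X[:, d.x_names.index("alpha_stx17")]
        assert col.tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_missing_genotypes_dropped_and_counted(self):
        ped = Pedigree.from_records(
            [dict(id=a, sire=None, dam=None) for a in "ABC"]
        )
        gt = GenotypeTable(
            pd.DataFrame({"id": ["A", "B"], "stx17": ["GG", "Gg"]})
        )
        recs = pd.DataFrame(
            {
                "animal": ["A", "B", "C", "C"],
                "value": [1.0, 2.0, 3.0, 4.0],
                "age_months": [90, 95, 100, 105],
            }
        )
        spec = ModelSpec(age_covariate=False, stx17_covariate=True)
        d = build_design(recs, spec, gt=gt, ped=ped)
        assert d.n == 2
        assert d.n_dropped == 2

    def test_confounded_covariate_raises(self):
        ped = Pedigree.from_records(
            [dict(id="A", sire=None, dam=None), dict(id="B", sire=None, dam=None)]
        )
        gt = GenotypeTable(pd.DataFrame({"id": ["A", "B"], "stx17": ["Gg", "Gg"]}))
        spec = ModelSpec(age_covariate=False, stx17_covariate=True)
        with pytest.raises(RankDeficiencyError, match="alpha_stx17"):
            build_design(_two_animal_records(), spec, gt=gt, ped=ped)

    def test_class_reparameterization_gives_full_rank(self):
        ped, design = tiny_study(seed=50)
        XtX = design.X.T @ design.X
        assert np.linalg.matrix_rank(XtX) == design.n_fixed


class TestRemlUnivariate:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_loglik_matches_dense_oracle(self, seed):
        """MME-based restricted likelihood equals the brute-force
        projection-form criterion on <=10-animal fixtures."""
        ped, design = tiny_study(seed=seed)
        assert ped.n <= 10
        A = build_A(ped)
        A_inv = build_A_inverse(ped)
        for theta in ([2.0, 1.0, 1.5], [0.5, 0.2, 2.5], [1.0, 1.0, 1.0]):
            mme_ll = reml_loglik_univariate(design, A_inv, theta)
            dense_ll = dense_reml_loglik(design, A, theta)
            assert mme_ll == pytest.approx(dense_ll, abs=1e-6)

    def test_score_matches_finite_differences(self):
        ped, design = tiny_study(seed=6)
        mme = _UnivariateMME(design, build_A_inverse(ped))
        theta = np.array([1.2, 0.7, 1.1])
        st = mme.evaluate(theta)
        eps = 1e-6
        for i in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (
                mme.evaluate(tp, need_info=False)["loglik"]
                - mme.evaluate(tm, need_info=False)["loglik"]
            ) / (2 * eps)
            assert st["score"][i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_em_steps_never_decrease_loglik(self):
        ped, design = tiny_study(seed=7, n_founders=6, n_offspring=4,
                                 mean_records=3.0)
        mme = _UnivariateMME(design, build_A_inverse(ped))
        theta = np.array([5.0, 4.0, 0.1])  # deliberately poor start
        last = -np.inf
        for _ in range(15):
            st = mme.evaluate(theta)
            assert st["loglik"] >= last - 1e-9
            last = st["loglik"]
            theta = np.array(
                [st["em"]["v_poly"], st["em"]["v_pe"], st["em"]["v_e"]]
            )

    def test_zero_polygenic_variance_hits_boundary(self):
        """Data simulated with V_POLY = 0 on a structured pedigree: the
        vanishing covariance between relatives drives the V_POLY estimate
        to the boundary while V_pe and V_e stay identified by the repeated
        records."""
        cfg = TraitConfig(
            name="null", v_poly=0.0, v_pe=0.3, v_e=1.0, alpha_stx17=0.0,
            beta_age=0.0, class_variance=0.0, age_window="old", p_g=1.0,
        )
        design = StudyDesign(
            n_founders=80, n_generations=3, offspring_per_generation=120,
            mean_records_per_animal=3.0, seed=44,
        )
        ped = simulate_pedigree(design)
        gt, _ = drop_genotypes(ped, p_g=1.0, seed=44)
        u = simulate_breeding_values(ped, 0.0, seed=44)
        recs = simulate_phenotypes(ped, gt, u, cfg, design, seed=44)
        d = build_design(recs, ModelSpec(age_covariate=False), ped=ped)
        fit = reml_univariate(d, build_A_inverse(ped))
        assert fit.components["v_poly"] < 0.05
        assert fit.components["v_e"] == pytest.approx(1.0, abs=0.1)
        assert fit.components["v_pe"] == pytest.approx(0.3, abs=0.15)

    def test_record_permutation_invariance(self):
        design_s = StudyDesign(
            n_founders=20, n_generations=2, offspring_per_generation=25, seed=9
        )
        ped = simulate_pedigree(design_s)
        gt, _ = drop_genotypes(ped, seed=9)
        u = simulate_breeding_values(ped, 1.0, seed=9)
        cfg = TraitConfig(name="t", v_poly=1.0, v_pe=0.5, v_e=1.0,
                          alpha_stx17=-0.8, age_window="old")
        recs = simulate_phenotypes(ped, gt, u, cfg, design_s, seed=9)
        A_inv = build_A_inverse(ped)
        spec = ModelSpec(trait="t")
        fit1 = reml_univariate(build_design(recs, spec, gt=gt, ped=ped), A_inv)
        shuffled = recs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = reml_univariate(build_design(shuffled, spec, gt=gt, ped=ped), A_inv)
        for k in ("v_poly", "v_pe", "v_e"):
            assert fit1.components[k] == pytest.approx(
                fit2.components[k], abs=1e-10
            )
        assert np.abs(fit1.ebv["ebv"] - fit2.ebv["ebv"]).max() < 1e-10


class TestRemlBivariate:
    def test_loglik_matches_dense_oracle(self):
        ped, d1 = tiny_study(seed=11)
        _, d2 = tiny_study(seed=11, v=(1.0, 0.4, 0.8))
        # rebuild d2 on the same pedigree object
        d2 = build_design_from(d1, d2)
        A = build_A(ped)
        A_inv = build_A_inverse(ped)
        mme = _BivariateMME(d1, d2, A_inv)
        theta = np.array([1.5, 0.4, 0.9, 0.8, 0.1, 0.4, 1.2, 0.9])
        G0, PE0, R0 = mme.unpack(theta)
        ll = mme.evaluate(theta, need_info=False)["loglik"]
        dense = dense_reml_loglik_bivariate(
            d1, d2, A, G0, PE0, R0, mme.pe_positions
        )
        assert ll == pytest.approx(dense, abs=1e-6)

    def test_score_matches_finite_differences(self):
        ped, d1 = tiny_study(seed=12)
        _, d2 = tiny_study(seed=12, v=(1.0, 0.4, 0.8))
        d2 = build_design_from(d1, d2)
        mme = _BivariateMME(d1, d2, build_A_inverse(ped))
        theta = np.array([1.5, 0.4, 0.9, 0.8, 0.1, 0.4, 1.2, 0.9])
        st = mme.evaluate(theta)
        eps = 1e-6
        for i in range(8):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (
                mme.evaluate(tp, need_info=False)["loglik"]
                - mme.evaluate(tm, need_info=False)["loglik"]
            ) / (2 * eps)
            assert st["score"][i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_positive_polygenic_correlation_recovered(self):
        """A generating polygenic correlation of 0.67 (the published
        greying-vitiligo value, used as simulation truth) is recovered
        within 2 SE in most replicates."""
        c1 = TraitConfig(name="y1", v_poly=2.0, v_pe=0.5, v_e=1.5,
                         alpha_stx17=-0.8, age_window="old")
        c2 = TraitConfig(name="y2", v_poly=1.0, v_pe=0.3, v_e=1.0,
                         alpha_stx17=-0.5, age_window="old")
        r_true = 0.67
        G0 = r_true * np.sqrt(2.0) * (np.ones((2, 2)) - np.eye(2))
        G0 += np.diag([2.0, 1.0])
        hits = 0
        for seed in (20, 21, 22):
            design = StudyDesign(n_founders=100, n_generations=3,
                                 offspring_per_generation=130, seed=seed)
            ped = simulate_pedigree(design)
            gt, _ = drop_genotypes(ped, seed=seed)
            U = simulate_breeding_values(ped, G0, seed=seed)
            r1 = simulate_phenotypes(ped, gt, U[:, 0], c1, design, seed=seed)
            r2 = simulate_phenotypes(ped, gt, U[:, 1], c2, design,
                                     seed=seed + 100)
            d1 = build_design(r1, ModelSpec(trait="y1"), gt=gt, ped=ped)
            d2 = build_design(r2, ModelSpec(trait="y2"), gt=gt, ped=ped)
            fit = reml_bivariate(d1, d2, build_A_inverse(ped))
            if abs(fit.r_poly - r_true) <= 2.0 * fit.r_poly_se:
                hits += 1
        assert hits >= 2

    def test_paired_residual_correlation_recovered(self):
        """With one-to-one paired records the residual covariance is
        estimable; the analytic score matches finite differences and the
        fitted r_e recovers the generating value."""
        design = StudyDesign(n_founders=60, n_generations=3,
                             offspring_per_generation=80, n_studs=2, seed=90)
        ped = simulate_pedigree(design)
        gt, _ = drop_genotypes(ped, p_g=1.0, seed=90)
        U = simulate_breeding_values(ped, np.diag([1.0, 0.8]), seed=90)
        rng = np.random.default_rng(91)
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        pe1 = rng.normal(0, np.sqrt(0.3), ped.n)
        pe2 = rng.normal(0, np.sqrt(0.2), ped.n)
        rows1, rows2 = [], []
        for i, a in enumerate(ped.ids):
            for _ in range(3):
                age = int(rng.integers(84, 200))
                year = int(rng.choice(design.years))
                e = L @ rng.standard_normal(2)
                common = dict(animal=a, age_months=age, stud="S1",
                              sex=ped.sex[i], year=year)
                rows1.append(dict(trait="t1", value=U[i, 0] + pe1[i] + e[0],
                                  **common))
                rows2.append(dict(trait="t2", value=U[i, 1] + pe2[i] + e[1],
                                  **common))
        d1 = build_design(pd.DataFrame(rows1), ModelSpec(trait="t1"),
                          gt=gt, ped=ped)
        d2 = build_design(pd.DataFrame(rows2), ModelSpec(trait="t2"),
                          gt=gt, ped=ped)
        A_inv = build_A_inverse(ped)
        mme = _BivariateMME(d1, d2, A_inv, paired=True)
        theta = np.array([0.8, 0.2, 0.6, 0.25, 0.05, 0.15, 0.9, 0.8, 0.35])
        st = mme.evaluate(theta)
        eps = 1e-6
        for i in range(9):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (
                mme.evaluate(tp, need_info=False)["loglik"]
                - mme.evaluate(tm, need_info=False)["loglik"]
            ) / (2 * eps)
            assert st["score"][i] == pytest.approx(num, rel=1e-4, abs=1e-6)
        fit = reml_bivariate(d1, d2, A_inv, paired=True)
        assert fit.r_e == pytest.approx(0.5, abs=3 * fit.r_e_se)
        assert fit.R0[0, 1] == fit.R0[1, 0]

    def test_null_polygenic_correlation_recovered(self):
        c1 = TraitConfig(name="x1", v_poly=2.0, v_pe=0.5, v_e=1.5,
                         alpha_stx17=-0.8, age_window="old")
        c2 = TraitConfig(name="x2", v_poly=1.0, v_pe=0.3, v_e=1.0,
                         alpha_stx17=-0.5, age_window="old")
        design = StudyDesign(n_founders=80, n_generations=3,
                             offspring_per_generation=110, seed=13)
        ped = simulate_pedigree(design)
        gt, _ = drop_genotypes(ped, seed=13)
        U = simulate_breeding_values(ped, np.diag([2.0, 1.0]), seed=13)
        r1 = simulate_phenotypes(ped, gt, U[:, 0], c1, design, seed=13)
        r2 = simulate_phenotypes(ped, gt, U[:, 1], c2, design, seed=14)
        d1 = build_design(r1, ModelSpec(trait="x1"), gt=gt, ped=ped)
        d2 = build_design(r2, ModelSpec(trait="x2"), gt=gt, ped=ped)
        fit = reml_bivariate(d1, d2, build_A_inverse(ped))
        assert abs(fit.r_poly) < 2 * fit.r_poly_se


class TestEbv:
    def test_standardization_contract(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.5, size=200)
        z = standardize_ebv(x)
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_ebvs_raise(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_ebv(np.ones(10))

    def test_parent_average_predicts_offspring_ebv(self):
        design = StudyDesign(n_founders=60, n_generations=3,
                             offspring_per_generation=80, seed=15)
        ped = simulate_pedigree(design)
        gt, _ = drop_genotypes(ped, seed=15)
        u = simulate_breeding_values(ped, 2.0, seed=15)
        cfg = TraitConfig(name="t", v_poly=2.0, v_pe=0.3, v_e=1.0,
                          alpha_stx17=-0.5, age_window="old")
        recs = simulate_phenotypes(ped, gt, u, cfg, design, seed=16)
        d = build_design(recs, ModelSpec(trait="t"), gt=gt, ped=ped)
        fit = reml_univariate(d, build_A_inverse(ped))
        ebv = predict_ebv(fit)["ebv"].values
        both = (ped.sire >= 0) & (ped.dam >= 0)
        mid = 0.5 * (ebv[ped.sire[both]] + ebv[ped.dam[both]])
        r = np.corrcoef(mid, ebv[both])[0, 1]
        assert r > 0.3


def build_design_from(d1, d2):
    """Rebind d2's records to d1's pedigree (tiny_study re-simulates the
    same pedigree from the same seed, but as a distinct object)."""
    assert d2.ped.ids == d1.ped.ids
    d2.ped = d1.ped
    return d2


class TestConsistency:
    def test_h2_bias_shrinks_with_sample_size(self):
        """Mean absolute error of the heritability estimate decreases from
        n=100 to n=900 pedigree members (melanoma-style configuration)."""
        from greyherit import pipeline as pl

        cfg = TraitConfig(
            name="melanoma", v_poly=0.19, v_pe=0.27, v_e=0.39,
            alpha_stx17=-0.85, asip_a=0.19, beta_age=0.11, age_window="old",
        )
        h2_true = (cfg.v_poly + cfg.v_stx17 + cfg.v_asip) / cfg.v_phenotypic
        sizes = {100: (30, 35), 300: (80, 110), 900: (220, 340)}
        err = {}
        for n, (nf, off) in sizes.items():
            errors = []
            for rep in range(6):
                design = StudyDesign(
                    n_founders=nf, n_generations=3,
                    offspring_per_generation=off, seed=100 * n + rep,
                )
                ped, gt, _, recs = __import__("greyherit").simulate_study(
                    cfg, design
                )
                prep = pl.prepare(recs, cfg, enforce_scale=False)
                _, dec = pl.run_univariate_analysis(ped, gt, prep, cfg,
                                                    scenario=2)
                errors.append(abs(dec.h2 - h2_true))
            err[n] = np.mean(errors)
        assert err[900] < err[100]
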