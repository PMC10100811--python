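"""Pedigree relationship matrices and the REML animal model."""

import numpy as np
import pandas as pd
import pytest

from rumiherit import heritability as her
from rumiherit import synthio
from tests.conftest import random_pedigree_records


def gene_drop_relationship(ped: her.Pedigree, n_rep: int, rng) -> np.ndarray:
    """Independent oracle for A: simulate Mendelian transmission of unique
    founder alleles and estimate a_ij = 2 * kinship_ij by allele identity."""
    n = len(ped)
    idx = ped.index()
    alleles = np.zeros((n_rep, n, 2), dtype=np.int32)
    next_allele = 0
    for a in ped.animals:
        i = idx[a]
        for slot, parent in enumerate((ped.sire[a], ped.dam[a])):
            if parent is None:
                alleles[:, i, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[:, i, slot] = alleles[np.arange(n_rep), idx[parent], pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ai, aj = alleles[:, i, :], alleles[:, j, :]
            ibd = sum((ai[:, k] == aj[:, m]).mean()
                      for k in range(2) for m in range(2)) / 4.0
            A[i, j] = A[j, i] = 2.0 * ibd
    return A


@pytest.fixture(scope="module")
def nuclear_pedigree():
    # sire + dam, two full-sib offspring, and a half sib through the sire
    return her.make_pedigree([
        ("sire1", None, None), ("dam1", None, None), ("dam2", None, None),
        ("kid1", "sire1", "dam1"), ("kid2", "sire1", "dam1"),
        ("half", "sire1", "dam2"),
    ])


class TestPedigreeValidation:
    def test_founders_no_inbreeding(self):
        ped = her.make_pedigree([("a", None, None), ("b", None, None)])
        assert all(f == 0 for f in ped.inbreeding.values())

    def test_child_before_parent_reordered(self):
        ped = her.make_pedigree([("kid", "pa", "ma"), ("pa", None, None),
                                 ("ma", None, None)])
        order = {a: i for i, a in enumerate(ped.animals)}
        assert order["pa"] < order["kid"] and order["ma"] < order["kid"]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            her.make_pedigree([("a", "c", None), ("b", "a", None),
                               ("c", "b", None)])

    def test_duplicate_animal_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            her.make_pedigree([("a", None, None), ("a", None, None)])

    def test_both_sexes_rejected(self):
        with pytest.raises(ValueError, match="both sire and dam"):
            her.make_pedigree([("p", None, None), ("q", None, None),
                               ("k1", "p", "q"), ("k2", "q", "p")])

    def test_csv_round_trip(self, nuclear_pedigree, tmp_path):
        path = tmp_path / "ped.csv"
        her.write_pedigree(nuclear_pedigree, path)
        back = her.load_pedigree(path)
        assert set(back.animals) == set(nuclear_pedigree.animals)
        assert back.sire == nuclear_pedigree.sire


class TestAMatrix:
    def test_hand_derived_relationships(self, nuclear_pedigree):
        A = her.a_matrix(nuclear_pedigree)
        assert A.loc["sire1", "kid1"] == 0.5          # parent-offspring
        assert A.loc["kid1", "kid2"] == 0.5           # full sibs
        assert A.loc["kid1", "half"] == 0.25          # half sibs
        assert A.loc["kid1", "kid1"] == 1.0           # non-inbred diagonal

    def test_parent_offspring_mating_inbreeding(self):
        ped = her.make_pedigree([
            ("s", None, None), ("d", None, None),
            ("child", "s", "d"), ("inbred", "s", "child"),
        ])
        A = her.a_matrix(ped)
        assert ped.inbreeding["inbred"] == pytest.approx(0.25)
        assert A.loc["inbred", "inbred"] == pytest.approx(1.25)

    def test_gene_dropping_oracle_small(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        A = her.a_matrix(nuclear_pedigree).to_numpy()
        est = gene_drop_relationship(nuclear_pedigree, 100_000, rng)
        assert np.abs(A - est).max() < 0.02


class TestAInverse:
    def test_unrelated_founders_identity(self):
        ped = her.make_pedigree([("a", None, None), ("b", None, None)])
        Ainv = her.a_inverse(ped)
        assert np.allclose(Ainv.to_numpy(), np.eye(2))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_dense_inverse(self, seed):
        rng = np.random.default_rng(seed)
        ped = her.make_pedigree(random_pedigree_records(10, 40, rng))
        A = her.a_matrix(ped).to_numpy()
        Ainv = her.a_inverse(ped).to_numpy()
        assert np.abs(A @ Ainv - np.eye(len(ped))).max() < 1e-8

    def test_inbred_pedigree(self):
        ped = her.make_pedigree([
            ("s", None, None), ("d", None, None),
            ("child", "s", "d"), ("inbred", "s", "child"),
        ])
        A = her.a_matrix(ped).to_numpy()
        Ainv = her.a_inverse(ped).to_numpy()
        assert np.abs(Ainv - np.linalg.inv(A)).max() < 1e-8


def _toy_metadata(animals, rng, groups=None, ages=None, seasons=None):
    n = len(animals)
    return pd.DataFrame({
        "animal": animals,
        "group": groups if groups is not None else rng.choice(["dam", "lamb"], n),
        "age": ages if ages is not None else rng.normal(100, 20, n),
        "year_season": seasons if seasons is not None
        else rng.choice(["sp", "su"], n),
    }, index=[f"smp{i}" for i in range(n)])


class TestDesign:
    def test_full_rank_dimensions(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        meta = _toy_metadata(nuclear_pedigree.animals[:6], rng,
                             groups=["dam", "lamb", "dam", "lamb", "dam", "lamb"],
                             seasons=["sp", "sp", "su", "su", "sp", "su"])
        design = her.build_design(meta, nuclear_pedigree)
        assert design.X.shape[1] == 4  # intercept + season + group + age
        assert np.linalg.matrix_rank(design.X) == 4

    def test_aliased_column_dropped_and_reported(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        # age perfectly collinear with group
        meta = _toy_metadata(nuclear_pedigree.animals[:6], rng,
                             groups=["dam", "dam", "dam", "lamb", "lamb", "lamb"],
                             ages=[100, 100, 100, 30, 30, 30],
                             seasons=["sp", "su", "sp", "su", "sp", "su"])
        design = her.build_design(meta, nuclear_pedigree)
        assert len(design.dropped_fixed) == 1
        assert np.linalg.matrix_rank(design.X) == design.X.shape[1]

    def test_maternal_incidence_points_at_dam(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        meta = _toy_metadata(["kid1", "kid2", "half", "dam1"], rng)
        design = her.build_design(meta, nuclear_pedigree)
        j1 = design.maternal_levels.index("dam1")
        assert design.W[0, j1] == 1.0 and design.W[1, j1] == 1.0
        # dam1 is a founder: her own row has no maternal effect
        assert design.W[3].sum() == 0.0

    def test_missing_animal_rejected(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        meta = _toy_metadata(["ghost"], rng)
        with pytest.raises(ValueError, match="ghost"):
            her.build_design(meta, nuclear_pedigree)


@pytest.fixture(scope="module")
def fitted_family_model():
    """A family-structured simulated data set and its REML fit."""
    params = synthio.SynthParams(n_dams=60, n_asvs=3, n_trait_asvs=1,
                                 sigma_a2=0.4, sigma_m2=0.1, sigma_e2=0.5,
                                 seed=21)
    ped, litters = synthio.simulate_pedigree(params)
    _, meta, latent = synthio.simulate_asv_table(ped, litters, params)
    design = her.build_design(meta, ped)
    A = her.a_matrix(ped)
    vc = her.reml_fit(design, A, latent.iloc[:, 0].to_numpy())
    return design, A, latent, vc


class TestReml:
    def test_converges_with_positive_variances(self, fitted_family_model):
        _, _, _, vc = fitted_family_model
        assert vc.converged
        assert vc.sigma_a2 >= 0 and vc.sigma_m2 >= 0 and vc.sigma_e2 > 0

    def test_local_optimality(self, fitted_family_model):
        design, A, latent, vc = fitted_family_model
        y = latent.iloc[:, 0].to_numpy()
        theta = np.array([vc.sigma_a2, vc.sigma_m2, vc.sigma_e2])
        Va = design.Z @ A.to_numpy() @ design.Z.T
        Vm = design.W @ design.W.T
        for i in range(3):
            for f in (0.9, 1.1):
                pert = theta.copy()
                pert[i] = max(pert[i] * f, 1e-10)
                res = her._reml_pieces(pert, y, design.X, Va, Vm)
                assert res is None or res[0] <= vc.loglik + 1e-6

    def test_sum_matches_residual_variance_iid(self):
        # A = I, no maternal term: sigma_a2 + sigma_e2 recovers the OLS
        # residual variance
        rng = np.random.default_rng(3)
        n = 150
        ped = her.make_pedigree([(f"a{i}", None, None) for i in range(n)])
        meta = _toy_metadata(ped.animals, rng)
        design = her.build_design(meta, ped)
        A = her.a_matrix(ped)
        y = rng.normal(0, 1.3, n)
        vc = her.reml_fit(design, A, y)
        resid = y - design.X @ np.linalg.lstsq(design.X, y, rcond=None)[0]
        s2 = resid @ resid / (n - design.X.shape[1])
        assert vc.sigma_a2 + vc.sigma_e2 == pytest.approx(s2, rel=0.05)

    def test_zero_additive_variance_hits_boundary(self):
        # family structure identifies sigma_a2; with pure-noise data the
        # non-negativity constraint concentrates it at/near zero
        params = synthio.SynthParams(n_dams=50, n_asvs=3, n_trait_asvs=1,
                                     seed=9)
        ped, litters = synthio.simulate_pedigree(params)
        _, meta, _ = synthio.simulate_asv_table(ped, litters, params)
        design = her.build_design(meta, ped)
        A = her.a_matrix(ped)
        rng = np.random.default_rng(10)
        ratios = []
        at_floor = 0
        n_rep = 30
        for _ in range(n_rep):
            y = rng.normal(0, 1, len(meta))
            vc = her.reml_fit(design, A, y)
            ratios.append(vc.sigma_a2 / vc.total)
            at_floor += vc.boundary[0]
        # non-negativity constraint: roughly half the replicates sit exactly
        # at the floor and the distribution concentrates near zero
        assert at_floor / n_rep >= 0.4
        assert np.median(ratios) < 0.02
        assert np.mean(ratios) < 0.1

    def test_scale_invariance_of_h2(self, fitted_family_model):
        design, A, latent, vc = fitted_family_model
        y = latent.iloc[:, 0].to_numpy()
        vc2 = her.reml_fit(design, A, 13.7 * y)
        assert her.heritability(vc2) == pytest.approx(her.heritability(vc),
                                                      abs=1e-6)

    def test_too_few_samples_rejected(self, nuclear_pedigree):
        rng = np.random.default_rng(0)
        meta = _toy_metadata(nuclear_pedigree.animals[:4], rng)
        design = her.build_design(meta, nuclear_pedigree)
        A = her.a_matrix(nuclear_pedigree)
        with pytest.raises(ValueError, match="n_samples"):
            her.reml_fit(design, A, rng.normal(size=4))


class TestHeritabilityStats:
    def test_h2_arithmetic(self):
        vc = her.VarianceComponents(0.3, 0.1, 0.6, 0.0, np.zeros((3, 3)),
                                    True, 1, (False,) * 3, 100, 4)
        assert her.heritability(vc) == pytest.approx(0.3)

    def test_h2_zero_and_limit(self):
        vc0 = her.VarianceComponents(0.0, 0.1, 0.9, 0.0, np.zeros((3, 3)),
                                     True, 1, (True, False, False), 100, 4)
        assert her.heritability(vc0) == 0.0
        vc1 = her.VarianceComponents(1.0, 1e-8, 1e-8, 0.0, np.zeros((3, 3)),
                                     True, 1, (False, True, True), 100, 4)
        assert her.heritability(vc1) == pytest.approx(1.0, abs=1e-6)

    def test_delta_method_hand_value(self):
        # gradient at (0.3, 0.1, 0.6), T=1: (0.7, -0.3, -0.3);
        # V = 0.01 I -> SE = sqrt(0.01 * (0.49 + 0.09 + 0.09))
        vc = her.VarianceComponents(0.3, 0.1, 0.6, 0.0, 0.01 * np.eye(3),
                                    True, 1, (False,) * 3, 100, 4)
        se, p = her.heritability_se_p(vc)
        assert se == pytest.approx(np.sqrt(0.0067), abs=1e-6)
        assert se == pytest.approx(0.0819, abs=1e-3)
        assert 0 < p < 1e-3  # t = 0.3/0.0819 = 3.66 at df 96

    def test_zero_covariance_zero_se(self):
        vc = her.VarianceComponents(0.3, 0.1, 0.6, 0.0, np.zeros((3, 3)),
                                    True, 1, (False,) * 3, 100, 4)
        se, _ = her.heritability_se_p(vc)
        assert se == 0.0


class TestScreen:
    @staticmethod
    def _results(h2s, ps):
        return pd.DataFrame({"h2": h2s, "p": ps},
                            index=[f"ASV{i+1}" for i in range(len(h2s))])

    def test_strict_boundaries(self, small_population):
        pop, _ = small_population
        table, meta = pop["table"], pop["metadata"]
        res = self._results([0.2, 0.21, 0.3, 0.3],
                            [0.01, 0.01, 0.05, 0.049])
        out = her.screen_heritable(res, table, meta)
        # h2 = 0.2 exactly and p = 0.05 exactly both fail the strict rule
        assert out["heritable_asvs"] == ["ASV2", "ASV4"]

    def test_percentage_rounding(self, small_population):
        pop, _ = small_population
        n = 40
        h2s = [0.5] + [0.0] * (n - 1)
        ps = [0.001] + [0.9] * (n - 1)
        out = her.screen_heritable(self._results(h2s, ps), pop["table"],
                                   pop["metadata"])
        assert out["pct_heritable"] == pytest.approx(100.0 / 40, abs=0.05)

    def test_empty_screen(self, small_population):
        pop, _ = small_population
        out = her.screen_heritable(self._results([0.1], [0.9]),
                                   pop["table"], pop["metadata"])
        assert out["n_heritable"] == 0
        for g in out["combined_abundance"].values():
            assert g["mean_pct"] == 0.0
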