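"""Synthetic family-study generator: structure, moments, ascertainment."""

import numpy as np
import pytest
from scipy import stats

from famvc.pedigree import classify_relationships, kinship_matrix
from famvc.simulate import (
    DISEASE,
    TraitSpec,
    ascertain_families,
    default_config,
    generate_phenotypes,
    generate_study_fixture,
    simulate_pedigree_set,
)


class TestPedigreeGeneration:
    def test_deterministic_under_seed(self):
        cfg = default_config(n_families=15, seed=7)
        p1 = simulate_pedigree_set(cfg)
        p2 = simulate_pedigree_set(cfg)
        assert p1.table.equals(p2.table)

    def test_two_generations_have_no_grandparent_pairs(self):
        cfg = default_config(n_families=15, seed=9, generations=2)
        counts = classify_relationships(simulate_pedigree_set(cfg))
        assert counts["grandparent-grandchild"] == 0
        assert counts["avuncular"] == 0

    def test_family_sizes_within_bounds_and_mean(self):
        cfg = default_config(n_families=60, seed=11)
        ped = simulate_pedigree_set(cfg)
        sizes = np.array([len(ped.family_members(f)) for f in ped.families])
        assert sizes.min() >= cfg.family_size_min
        assert sizes.max() <= cfg.family_size_cap
        # mean within 3 SE of an independent large sample of the size law
        from famvc.simulate import _draw_family_size

        rng = np.random.default_rng(123)
        draws = np.array([_draw_family_size(rng, cfg) for _ in range(20000)])
        se = np.sqrt(draws.var() / sizes.size + draws.var() / draws.size)
        assert abs(sizes.mean() - draws.mean()) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            default_config(family_size_min=2)
        with pytest.raises(ValueError):
            default_config(generations=5)
        with pytest.raises(ValueError):
            default_config(prevalence=0.0)
        with pytest.raises(ValueError):
            default_config(traits=[TraitSpec("x", 1.5)])

    def test_non_psd_correlation_rejected(self):
        bad = -np.ones((19, 19))
        with pytest.raises(ValueError, match="positive semidefinite"):
            default_config(rhoG=bad)


class TestTraitMoments:
    @staticmethod
    def _po_pairs(ped):
        pairs = []
        for _, row in ped.table.iterrows():
            for p in (row["father"], row["mother"]):
                if p is not None and not (isinstance(p, float) and np.isnan(p)):
                    pairs.append((p, row["id"]))
        return pairs

    def _panel(self, h2, seed, n_families=400, rho=None):
        traits = [TraitSpec("a", h2[0]), TraitSpec("b", h2[1])] if len(h2) == 2 \
            else [TraitSpec("a", h2[0])]
        k = len(traits) + 1
        rg = np.eye(k)
        re = np.eye(k)
        if rho is not None:
            rg[0, 1] = rg[1, 0] = rho
        cfg = default_config(n_families=n_families, seed=seed, traits=traits,
                             rhoG=rg, rhoE=re)
        ped = simulate_pedigree_set(cfg)
        _, panel = generate_phenotypes(ped, cfg)
        return ped, panel

    def test_null_heritability_gives_no_parent_offspring_covariance(self):
        ped, panel = self._panel([0.0], seed=1, n_families=400)
        pairs = self._po_pairs(ped)
        x = np.array([panel.loc[p, "a"] for p, _ in pairs])
        y = np.array([panel.loc[c, "a"] for _, c in pairs])
        cov = np.mean(x * y) - x.mean() * y.mean()
        se = np.std(x * y, ddof=1) / np.sqrt(len(pairs))
        assert abs(cov) < 3 * se

    def test_parent_offspring_covariance_is_half_h2(self):
        ped, panel = self._panel([0.5], seed=2, n_families=500)
        pairs = self._po_pairs(ped)
        x = np.array([panel.loc[p, "a"] for p, _ in pairs])
        y = np.array([panel.loc[c, "a"] for _, c in pairs])
        cov = np.mean(x * y) - x.mean() * y.mean()
        se = np.std(x * y, ddof=1) / np.sqrt(len(pairs))
        assert abs(cov - 0.25) < 3 * se

    def test_cross_trait_parent_offspring_covariance(self):
        # cov(parent A, child B) = rhoG * sqrt(h2A h2B) / 2 = 0.15
        ped, panel = self._panel([0.5, 0.5], seed=3, n_families=500, rho=0.6)
        pairs = self._po_pairs(ped)
        x = np.array([panel.loc[p, "a"] for p, _ in pairs])
        y = np.array([panel.loc[c, "b"] for _, c in pairs])
        cov = np.mean(x * y) - x.mean() * y.mean()
        se = np.std(x * y, ddof=1) / np.sqrt(len(pairs))
        assert abs(cov - 0.15) < 3 * se

    def test_pair_covariance_matches_kinship_for_sibs(self):
        ped, panel = self._panel([0.5], seed=4, n_families=400)
        K = kinship_matrix(ped)
        sibs = []
        t = ped.table.set_index("id")
        for fam in ped.families:
            members = ped.family_members(fam)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if K.pair(a, b) == 0.5 and t.loc[a, "father"] is not None \
                            and t.loc[a, "father"] == t.loc[b, "father"]:
                        sibs.append((a, b))
        x = np.array([panel.loc[a, "a"] for a, _ in sibs])
        y = np.array([panel.loc[b, "a"] for _, b in sibs])
        cov = np.mean(x * y) - x.mean() * y.mean()
        se = np.std(x * y, ddof=1) / np.sqrt(len(sibs))
        assert abs(cov - 0.25) < 3 * se


class TestDisease:
    def test_half_prevalence_no_heritability(self):
        cfg = default_config(n_families=300, seed=5, prevalence=0.5,
                             disease_h2=0.0)
        ped = simulate_pedigree_set(cfg)
        pheno, _ = generate_phenotypes(ped, cfg)
        n = len(pheno)
        assert abs(pheno[DISEASE].mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_sibling_recurrence_exceeds_prevalence(self):
        # closed form: P(both sibs affected) is the bivariate normal orthant
        # with correlation h2/2; recurrence ratio > 1 whenever h2 > 0
        from scipy.stats import multivariate_normal

        K_prev, h2 = 0.35, 0.35
        thr = stats.norm.ppf(1 - K_prev)
        rho = h2 * 0.5
        both = multivariate_normal(mean=[0, 0],
                                   cov=[[1, rho], [rho, 1]]).cdf([-thr, -thr])
        lam_truth = both / K_prev**2
        assert lam_truth > 1.0

        cfg = default_config(n_families=500, seed=6, prevalence=K_prev,
                             disease_h2=h2)
        ped = simulate_pedigree_set(cfg)
        pheno, _ = generate_phenotypes(ped, cfg)
        d = pheno.set_index("id")[DISEASE]
        K = kinship_matrix(ped)
        t = ped.table.set_index("id")
        pairs = []
        for fam in ped.families:
            members = ped.family_members(fam)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    fa, fb = t.loc[a, "father"], t.loc[b, "father"]
                    if K.pair(a, b) == 0.5 and fa is not None and fa == fb:
                        pairs.append((a, b))
        both_hat = np.mean([d.loc[a] * d.loc[b] for a, b in pairs])
        se = np.sqrt(both_hat * (1 - both_hat) / len(pairs))
        assert abs(both_hat - both) < 3 * se + 0.01

    def test_disease_linked_trait_shifts_in_affected(self):
        # truncated bivariate normal: E[trait | affected] =
        # rhoG*sqrt(h2_t*h2_d) * phi(thr)/K
        rho_td = 0.77
        h2_t, h2_d, K_prev = 0.4, 0.35, 0.35
        traits = [TraitSpec("a", h2_t)]
        rg = np.array([[1.0, rho_td], [rho_td, 1.0]])
        cfg = default_config(n_families=500, seed=7, traits=traits, rhoG=rg,
                             rhoE=np.eye(2), prevalence=K_prev, disease_h2=h2_d)
        ped = simulate_pedigree_set(cfg)
        pheno, panel = generate_phenotypes(ped, cfg)
        thr = stats.norm.ppf(1 - K_prev)
        rho_obs = rho_td * np.sqrt(h2_t * h2_d)
        expect = rho_obs * stats.norm.pdf(thr) / K_prev
        vals = panel["a"].to_numpy()
        aff = pheno[DISEASE].to_numpy() == 1
        shift = vals[aff].mean() - 0.0
        se = vals[aff].std(ddof=1) / np.sqrt(aff.sum())
        assert abs(shift - expect) < 3 * se


class TestAscertainment:
    def _fixture(self, seed, prevalence=0.35):
        cfg = default_config(n_families=150, seed=seed, prevalence=prevalence)
        ped = simulate_pedigree_set(cfg)
        pheno, _ = generate_phenotypes(ped, cfg)
        return cfg, ped, pheno.set_index("id")[DISEASE]

    def test_mode_none_is_identity(self):
        _, ped, d = self._fixture(8)
        kept, probands = ascertain_families(ped, d, mode="none")
        assert kept.ids == ped.ids
        assert probands == []

    def test_probands_are_affected_and_families_have_cases(self):
        _, ped, d = self._fixture(9)
        kept, probands = ascertain_families(ped, d, seed=1)
        assert len(probands) == len(kept.families)
        for fam, pro in zip(kept.families, probands):
            assert d.loc[pro] == 1
            assert d.loc[kept.family_members(fam)].sum() >= 1

    def test_low_prevalence_induces_upward_bias(self):
        _, ped, d = self._fixture(10, prevalence=0.05)
        kept, _ = ascertain_families(ped, d, seed=2)
        kept_prev = d.loc[kept.ids].mean()
        assert kept_prev > 0.05 + 0.02

    def test_complete_mode_keeps_all_affected_families(self):
        _, ped, d = self._fixture(11)
        kept, probands = ascertain_families(ped, d, mode="complete")
        expect = [f for f in ped.families
                  if d.loc[ped.family_members(f)].sum() >= 1]
        assert kept.families == expect


class TestFixture:
    def test_round_trip_through_readers(self, tmp_path):
        from famvc.pedigree import read_pedigree
        from famvc.traits import derive_indexes, inverse_normalize

        fx = generate_study_fixture(seed=2, outdir=tmp_path)
        ped = read_pedigree(tmp_path / "pedigree.csv")
        assert ped.n == fx["truth"]["n_individuals"]
        import pandas as pd

        pheno = pd.read_csv(tmp_path / "phenotypes.csv")
        out = derive_indexes(pheno.rename(columns={}))
        assert out["bmi"].notna().all()
        z = inverse_normalize(pheno["waist"])
        assert abs(np.nanmean(z)) < 0.01

    def test_two_seeds_differ_in_values_not_schema(self):
        a = generate_study_fixture(seed=4)
        b = generate_study_fixture(seed=5)
        assert list(a["phenotypes"].columns) == list(b["phenotypes"].columns)
        assert not a["phenotypes"]["height"].equals(b["phenotypes"]["height"])

    def test_truth_records_ascertainment_invariants(self):
        fx = generate_study_fixture(seed=6)
        truth = fx["truth"]
        assert truth["n_families"] == 112
        assert truth["rhoG_biceps_disease"] == pytest.approx(0.77)
        assert all(v >= 1 for v in truth["affected_per_family"].values())
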