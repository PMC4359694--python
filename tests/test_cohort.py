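"""Synthetic cohort generator: pedigree structure, genotypes, LD, kinship."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famgrs.cohort import (
    CohortConfig,
    ConfigError,
    generate_genotypes,
    generate_pedigrees,
    inject_longevity_effect,
    kinship_matrix,
)

from conftest import founders_pedigree, small_cohort_config, trio_pedigree


# ---------------------------------------------------------------------------
# pedigree structure
# ---------------------------------------------------------------------------


class TestPedigrees:
    def test_default_config_reproduces_study_generation_sizes(self):
        ped = generate_pedigrees(CohortConfig())
        g1 = ped[ped["generation"] == 1]
        g2 = ped[ped["generation"] == 2]
        assert len(g1) == 1562
        assert (g1["longevity_member"] == 0).sum() == 175
        assert len(g2) == 3102
        assert ped["family_id"].nunique() == 583

    def test_minimal_family_is_proband_plus_spouse(self):
        cfg = CohortConfig(
            n_families=1,
            g1_sibs_per_family={"kind": "fixed", "value": 0},
            g1_spouses_total=1,
            g2_offspring_per_family={"kind": "fixed", "value": 0},
            spouse_fraction_g2=0.0,
        )
        ped = generate_pedigrees(cfg)
        assert len(ped) == 2
        assert set(ped["role"]) == {"proband", "spouse_g1"}

    def test_fixed_seed_reproduces_pedigree_byte_identically(self, small_config):
        a = generate_pedigrees(small_config).to_csv()
        b = generate_pedigrees(small_config).to_csv()
        assert a == b

    def test_role_and_membership_invariants(self, small_pedigree):
        ped = small_pedigree
        blood = ped["role"].isin(["proband", "sibling", "offspring"])
        assert (ped["longevity_member"].astype(bool) == blood).all()
        assert (ped.groupby("family_id")["role"].apply(lambda r: (r == "proband").sum()) == 1).all()
        spouses = ped[ped["role"].str.startswith("spouse")]
        assert (spouses["father_id"] == "0").all() and (spouses["mother_id"] == "0").all()

    def test_offspring_parents_recorded_consistently(self, small_pedigree):
        ped = small_pedigree
        ids = set(ped["individual_id"])
        for row in ped[ped["role"] == "offspring"].itertuples():
            in_ped = (row.father_id in ids) + (row.mother_id in ids)
            assert in_ped >= 1  # one blood parent always genotyped
            assert row.father_id != "0" and row.mother_id != "0"

    def test_invalid_distribution_spec_raises(self):
        with pytest.raises(ConfigError):
            generate_pedigrees(small_cohort_config(g1_sibs_per_family={"mean": 2}))
        with pytest.raises(ConfigError):
            generate_pedigrees(small_cohort_config(g1_sibs_per_family={"kind": "weird"}))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


class TestGenotypes:
    def test_mendelian_certainty_homozygous_parents(self):
        cfg = CohortConfig(allele_freq_range=(0.8, 0.95), missing_rate=0.0, seed=3)
        gm = generate_genotypes(trio_pedigree(), 60, cfg)
        d = gm.to_frame()
        both_hom = (d.loc["dad"] == 2) & (d.loc["mom"] == 2)
        assert both_hom.sum() > 5
        assert (d.loc["kid"][both_hom] == 2).all()

    def test_unlinked_snps_are_empirically_independent(self):
        cfg = CohortConfig(
            ld_block_sizes=(1,), within_block_r2=0.0, missing_rate=0.0, seed=3
        )
        gm = generate_genotypes(founders_pedigree(200), 200, cfg)
        r2 = np.corrcoef(gm.dosage.T) ** 2
        iu = np.triu_indices_from(r2, 1)
        assert np.nanmean(r2[iu]) < 0.05

    def test_within_block_r2_hits_target(self):
        cfg = CohortConfig(
            ld_block_sizes=(3,), within_block_r2=0.9, missing_rate=0.0, seed=11
        )
        gm = generate_genotypes(founders_pedigree(5000), 9, cfg)
        r2 = np.corrcoef(gm.dosage.T) ** 2
        within = [
            r2[i, j]
            for b in range(3)
            for i, j in itertools.combinations(range(3 * b, 3 * b + 3), 2)
        ]
        assert all(0.8 <= v <= 1.0 for v in within)
        across = [r2[0, 3], r2[1, 4], r2[0, 8]]
        assert all(v < 0.05 for v in across)

    def test_missingness_matches_configured_rate(self):
        cfg = CohortConfig(missing_rate=0.05, seed=5)
        gm = generate_genotypes(founders_pedigree(300), 100, cfg)
        frac = np.isnan(gm.dosage).mean()
        assert abs(frac - 0.05) < 0.01

    def test_fixed_seed_reproduces_genotypes(self, small_config, small_pedigree):
        a = generate_genotypes(small_pedigree, 30, small_config)
        b = generate_genotypes(small_pedigree, 30, small_config)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.snps == b.snps and list(a.risk_allele) == list(b.risk_allele)


# ---------------------------------------------------------------------------
# longevity effect injection
# ---------------------------------------------------------------------------


def _half_controls(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped.copy()
    ped.loc[ped.index[len(ped) // 2 :], "longevity_member"] = 0
    return ped


class TestLongevityEffect:
    def test_null_rate_ratio_leaves_matrix_unchanged(self):
        cfg = CohortConfig(missing_rate=0.0, seed=5)
        ped = founders_pedigree(100)
        gm = generate_genotypes(ped, 30, cfg)
        out = inject_longevity_effect(gm, ped, 1.0, 0.0, seed=9)
        np.testing.assert_array_equal(gm.dosage, out.dosage)

    def test_strong_thinning_matches_target_ratio(self):
        # brute force: many allele draws, members thinned at 0.90
        cfg = CohortConfig(missing_rate=0.0, seed=5)
        ped = _half_controls(founders_pedigree(1000))
        gm = generate_genotypes(ped, 20, cfg)
        out = inject_longevity_effect(gm, ped, 0.90, 0.0, seed=9)
        mem = ped["longevity_member"].to_numpy().astype(bool)
        before = gm.dosage[mem].sum()
        after = out.dosage[mem].sum()
        mc_se = np.sqrt(before) / before  # Poisson-scale error on the ratio
        assert abs(after / before - 0.90) < 2 * mc_se + 0.01
        np.testing.assert_array_equal(gm.dosage[~mem], out.dosage[~mem])

    def test_percent_level_thinning_detected_at_scale(self):
        cfg = CohortConfig(missing_rate=0.0, seed=5)
        ped = _half_controls(founders_pedigree(3000))
        gm = generate_genotypes(ped, 431, cfg)
        out = inject_longevity_effect(gm, ped, 0.99, 0.01, seed=9)
        mem = ped["longevity_member"].to_numpy().astype(bool)
        ratio = out.dosage[mem].mean() / out.dosage[~mem].mean()
        base = gm.dosage[mem].mean() / gm.dosage[~mem].mean()
        assert 0.985 < ratio / base < 0.995

    def test_boosting_beyond_unit_rate_raises(self):
        cfg = CohortConfig(allele_freq_range=(0.85, 0.95), missing_rate=0.0, seed=5)
        ped = founders_pedigree(200)
        gm = generate_genotypes(ped, 20, cfg)
        with pytest.raises(ValueError, match="above 1"):
            inject_longevity_effect(gm, ped, 1.5, 0.0, seed=9)

    def test_null_scores_exchangeable_between_members_and_controls(self):
        # under rate_ratio=1 / sd=0 the member-control mean difference is null
        rejections = 0
        for seed in range(50):
            cfg = CohortConfig(missing_rate=0.0, seed=seed)
            ped = _half_controls(founders_pedigree(120))
            gm = generate_genotypes(ped, 30, cfg)
            out = inject_longevity_effect(gm, ped, 1.0, 0.0, seed=seed)
            mem = ped["longevity_member"].to_numpy().astype(bool)
            _, p = stats.ttest_ind(out.dosage[mem].sum(axis=1), out.dosage[~mem].sum(axis=1))
            rejections += p < 0.01
        assert rejections <= 2


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_by_gene_drop_enumeration(ped: pd.DataFrame) -> pd.DataFrame:
    """Exact kinship by exhaustive enumeration of inheritance vectors.

    Independent of the tabular recursion: every meiosis picks one of two
    parental alleles; averaging allele-identity over all 4^(non-founders)
    equally likely inheritance patterns gives phi exactly.
    """
    members = list(ped["individual_id"])
    parents = {r.individual_id: (r.father_id, r.mother_id) for r in ped.itertuples()}
    referenced = set(ped["father_id"]) | set(ped["mother_id"])
    latent = sorted(referenced - set(members) - {"0"})
    for l in latent:
        parents[l] = ("0", "0")
    ids = latent + members
    founders = [i for i in ids if parents[i] == ("0", "0")]
    nonf = [i for i in ids if i not in founders]
    # topological order over non-founders
    ordered: list[str] = []
    placed = set(founders)
    while len(ordered) < len(nonf):
        for i in nonf:
            if i in placed:
                continue
            fa, mo = parents[i]
            if (fa in placed or fa == "0") and (mo in placed or mo == "0"):
                ordered.append(i)
                placed.add(i)
    n_bits = 2 * len(ordered)
    assert n_bits <= 20, "enumeration oracle limited to small pedigrees"
    acc = np.zeros((len(members), len(members)))
    for bits in itertools.product((0, 1), repeat=n_bits):
        alleles = {f: (f + ".p", f + ".m") for f in founders}
        for k, ind in enumerate(ordered):
            fa, mo = parents[ind]
            alleles[ind] = (alleles[fa][bits[2 * k]], alleles[mo][bits[2 * k + 1]])
        for a, i in enumerate(members):
            for b, j in enumerate(members):
                if b < a:
                    continue
                same = sum(
                    alleles[i][x] == alleles[j][y] for x in (0, 1) for y in (0, 1)
                )
                acc[a, b] += same / 4.0
                if a != b:
                    acc[b, a] += same / 4.0
    acc /= 2.0**n_bits
    return pd.DataFrame(acc, index=members, columns=members)


def three_generation_pedigree() -> pd.DataFrame:
    rows = [
        ("F1", "gpa", "0", "0", "M", 0, "proband", 1),
        ("F1", "gma", "0", "0", "F", 0, "spouse_g1", 0),
        ("F1", "dad", "gpa", "gma", "M", 1, "offspring", 1),
        ("F1", "unc", "gpa", "gma", "M", 1, "offspring", 1),
        ("F1", "mom", "0", "0", "F", 1, "spouse_g2", 0),
        ("F1", "kid1", "dad", "mom", "F", 2, "offspring", 1),
        ("F1", "kid2", "dad", "mom", "M", 2, "offspring", 1),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "individual_id", "father_id", "mother_id",
            "sex", "generation", "role", "longevity_member",
        ],
    )


class TestKinship:
    def test_textbook_coefficients(self):
        K = kinship_matrix(trio_pedigree())
        assert K.loc["dad", "kid"] == pytest.approx(0.25)
        assert K.loc["dad", "mom"] == 0.0
        assert K.loc["kid", "kid"] == pytest.approx(0.5)

    @pytest.mark.parametrize("builder", [trio_pedigree, three_generation_pedigree])
    def test_matches_gene_drop_enumeration_oracle(self, builder):
        ped = builder()
        K = kinship_matrix(ped)
        oracle = kinship_by_gene_drop_enumeration(ped)
        np.testing.assert_allclose(K.to_numpy(), oracle.to_numpy(), atol=1e-12)

    def test_matches_oracle_on_generated_family_with_latent_parents(self, small_pedigree):
        # pick a 5..12-member family whose enumeration stays tractable
        chosen = None
        for fam, sub in small_pedigree.groupby("family_id"):
            n_nonf = (sub["father_id"] != "0").sum()
            if 5 <= len(sub) <= 12 and n_nonf <= 6:
                chosen = fam
                break
        assert chosen is not None
        sub = small_pedigree[small_pedigree["family_id"] == chosen].reset_index(drop=True)
        K = kinship_matrix(sub)
        oracle = kinship_by_gene_drop_enumeration(sub)
        np.testing.assert_allclose(K.to_numpy(), oracle.to_numpy(), atol=1e-12)

    def test_positive_semidefinite(self, small_pedigree):
        sub = small_pedigree[small_pedigree["family_id"].isin(small_pedigree["family_id"].unique()[:5])]
        K = kinship_matrix(sub)
        w = np.linalg.eigvalsh(K.to_numpy())
        assert w.min() > -1e-10

    def test_cycle_detected(self):
        ped = trio_pedigree()
        ped.loc[ped["individual_id"] == "dad", "father_id"] = "kid"
        with pytest.raises(ValueError, match="cycle"):
            kinship_matrix(ped)
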