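import numpy as np
import pandas as pd
import pytest

from commphylo.community import CommunityTable
from commphylo.metrics import faith_pd, mntd_within
from commphylo.nullmodels import (
    NullDistribution,
    NullModelConfig,
    NullModelError,
    UndefinedSESError,
    pdi_nti_report,
    sample_null,
    ses,
    site_rng,
)
from commphylo.synth import SynthConfig, generate_communities, generate_tree
from commphylo.tree import cophenetic

from conftest import random_tree


def neutral_fixture(n_tips=60, n_sites=20, richness=(5, 25), seed=0):
    cfg = SynthConfig(
        n_tips=n_tips, n_sites=n_sites, richness_range=richness, seed=seed
    )
    tree = generate_tree(cfg)
    return tree, generate_communities(tree, cfg)


class TestSampleNull:
    def test_cardinality(self):
        pool = [f"s{i}" for i in range(10)]
        out = sample_null(pool, 4, np.random.default_rng(0))
        assert len(out) == 4 and len(set(out)) == 4
        assert set(out) <= set(pool)

    def test_full_pool(self):
        pool = list("abcde")
        out = sample_null(pool, 5, np.random.default_rng(0))
        assert sorted(out) == sorted(pool)

    def test_deterministic_under_seed(self):
        pool = [f"s{i}" for i in range(30)]
        a = sample_null(pool, 10, np.random.default_rng(42))
        b = sample_null(pool, 10, np.random.default_rng(42))
        assert a == b

    def test_richness_exceeding_pool_errors(self):
        with pytest.raises(NullModelError):
            sample_null(list("abc"), 4, np.random.default_rng(0))


class TestSES:
    def test_basic(self):
        null = NullDistribution("pd", np.array([2.0, 3.0, 4.0]))
        assert null.mean == pytest.approx(3.0)
        assert ses(5.0, null) == pytest.approx(2.0)

    def test_negate_sign_convention(self):
        null = NullDistribution("mntd", np.array([2.5, 3.0, 3.5]))
        assert null.sd == pytest.approx(0.5)
        assert ses(2.0, null, negate=True) == pytest.approx(2.0)

    def test_observed_equal_mean_is_zero(self):
        null = NullDistribution("pd", np.array([1.0, 2.0, 3.0]))
        assert ses(2.0, null) == 0.0

    def test_zero_sd_raises_with_payload(self):
        null = NullDistribution("pd", np.array([3.0, 3.0, 3.0]))
        with pytest.raises(UndefinedSESError) as err:
            ses(5.0, null)
        assert err.value.observed == 5.0
        assert err.value.null_mean == 3.0

    def test_sd_uses_n_minus_one(self):
        values = np.array([1.0, 2.0, 4.0, 5.0])
        null = NullDistribution("pd", values)
        assert null.sd == pytest.approx(values.std(ddof=1))


class TestReport:
    def test_whole_pool_site_gives_missing_with_reason(self, tree4):
        table = CommunityTable(
            ("s1", "s2"),
            ("A", "B", "C", "D"),
            np.array([[1, 1, 1, 1], [1, 1, 1, 1]]),
        )
        rep = pdi_nti_report(tree4, table, NullModelConfig(replicates=9))
        row = rep.table.iloc[0]
        assert np.isnan(row.pdi) and np.isnan(row.nti)
        assert "null sd is 0" in row.note

    def test_richness_one_site_has_missing_nti(self):
        tree = random_tree(10, 3)
        labels = tree.tip_labels
        inc = np.zeros((2, 10), dtype=np.int8)
        inc[0, 0] = 1
        inc[1, :5] = 1
        table = CommunityTable(("s1", "s2"), tuple(labels), inc)
        rep = pdi_nti_report(tree, table, NullModelConfig(replicates=49))
        assert "richness < 2" in rep.table.iloc[0].note
        assert np.isnan(rep.table.iloc[0].nti)
        assert np.isfinite(rep.table.iloc[0].pdi) or np.isnan(rep.table.iloc[0].pdi)

    def test_bit_reproducible(self):
        tree, table = neutral_fixture(seed=5)
        cfg = NullModelConfig(replicates=49, seed=9)
        a = pdi_nti_report(tree, table, cfg).table
        b = pdi_nti_report(tree, table, cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_adding_site_preserves_other_sites(self):
        tree, table = neutral_fixture(seed=6)
        cfg = NullModelConfig(replicates=49, seed=9)
        full = pdi_nti_report(tree, table, cfg).table
        shrunk = CommunityTable(
            table.sites[:-1], table.species, table.incidence[:-1]
        )
        part = pdi_nti_report(tree, shrunk, cfg).table
        pd.testing.assert_frame_equal(full.iloc[:-1].reset_index(drop=True),
                                      part.reset_index(drop=True))

    def test_observed_values_match_direct_metrics(self):
        tree, table = neutral_fixture(seed=7, n_sites=5)
        cfg = NullModelConfig(replicates=9, seed=1)
        rep = pdi_nti_report(tree, table, cfg).table
        d = cophenetic(tree)
        for _, row in rep.iterrows():
            species = table.site_species(row.site)
            assert row.pd_obs == pytest.approx(faith_pd(tree, species))
            if len(species) >= 2:
                assert row.mntd_obs == pytest.approx(mntd_within(d, species))

    def test_nti_equals_negated_mntd_ses(self):
        tree, table = neutral_fixture(seed=8, n_sites=8)
        rep = pdi_nti_report(tree, table, NullModelConfig(replicates=99, seed=2)).table
        recomputed = -(rep.mntd_obs - rep.mntd_null_mean) / rep.mntd_null_sd
        np.testing.assert_allclose(rep.nti, recomputed)

    def test_pdi_matches_formula(self):
        tree, table = neutral_fixture(seed=8, n_sites=8)
        rep = pdi_nti_report(tree, table, NullModelConfig(replicates=99, seed=2)).table
        recomputed = (rep.pd_obs - rep.pd_null_mean) / rep.pd_null_sd
        np.testing.assert_allclose(rep.pdi, recomputed)

    def test_relabeling_invariance(self):
        # renaming species consistently on tree and table leaves PDI unchanged
        tree, table = neutral_fixture(seed=10, n_sites=6)
        cfg = NullModelConfig(replicates=99, seed=4)
        base = pdi_nti_report(tree, table, cfg).table
        from commphylo.tree import parse_newick, write_newick
        text = write_newick(tree)
        mapping = {lab: f"x_{lab}" for lab in tree.tip_labels}
        for old, new in mapping.items():
            text = text.replace(old + ":", new + ":")
        tree2 = parse_newick(text)
        table2 = CommunityTable(
            table.sites,
            tuple(mapping[sp] for sp in table.species),
            table.incidence,
        )
        again = pdi_nti_report(tree2, table2, cfg).table
        np.testing.assert_allclose(base.pdi, again.pdi)
        np.testing.assert_allclose(base.nti, again.nti)

    def test_pool_smaller_than_max_richness_errors(self, tree4):
        table = CommunityTable(
            ("s1",), ("A", "B", "C"), np.array([[1, 1, 1]])
        )
        cfg = NullModelConfig(replicates=9, pool=("A", "B"))
        with pytest.raises(NullModelError, match="pool smaller"):
            pdi_nti_report(tree4, table, cfg)

    def test_occurrence_weighting_runs(self):
        tree, table = neutral_fixture(seed=11, n_sites=6)
        cfg = NullModelConfig(replicates=49, seed=3, weighting="occurrence")
        rep = pdi_nti_report(tree, table, cfg).table
        assert np.isfinite(rep.pdi).all()


class TestCalibrationSmoke:
    """Small always-on version of the null-calibration acceptance check."""

    def test_neutral_sites_have_near_standard_ses(self):
        cfg = SynthConfig(
            n_tips=80, n_sites=60, richness_range=(5, 30), seed=12
        )
        tree = generate_tree(cfg)
        table = generate_communities(tree, cfg)
        rep = pdi_nti_report(
            tree, table, NullModelConfig(replicates=199, seed=13)
        ).table
        for col in ("pdi", "nti"):
            vals = rep[col].to_numpy(float)
            assert abs(np.nanmean(vals)) < 0.3
            assert 0.7 < np.nanstd(vals, ddof=1) < 1.3

    def test_pdi_nti_negatively_correlated_on_neutral_data(self):
        cfg = SynthConfig(
            n_tips=80, n_sites=40, richness_range=(5, 30), seed=14
        )
        tree = generate_tree(cfg)
        table = generate_communities(tree, cfg)
        rep = pdi_nti_report(
            tree, table, NullModelConfig(replicates=199, seed=15)
        ).table
        r = np.corrcoef(rep.pdi, rep.nti)[0, 1]
        assert r < 0
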