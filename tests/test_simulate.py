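"""Synthetic-data generator: determinism, bounds, planted-effect truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfbsmeth import (
    ConfigurationError,
    SimulationConfig,
    simulate_binding_sites,
    simulate_cohort,
    simulate_ihc,
    simulate_tss_and_gene_sets,
)
from tfbsmeth.simulate import simulate_ihc_cores
from tfbsmeth import io as gio

GENOME = [("chr1", 10_000_000)]


class TestBindingSites:
    def test_rejects_empty_or_degenerate_requests(self):
        with pytest.raises(ConfigurationError):
            simulate_binding_sites([], 10)
        with pytest.raises(ConfigurationError):
            simulate_binding_sites(GENOME, 0)
        with pytest.raises(ConfigurationError):
            simulate_binding_sites([("chr1", 100)], 5, site_width=200)

    def test_intervals_within_chromosome_bounds(self):
        sites = simulate_binding_sites(GENOME, 1000, site_width=200, seed=3)
        assert len(sites) == 1000
        assert (sites["start"] >= 0).all()
        assert (sites["start"] < sites["end"]).all()
        assert (sites["end"] <= 10_000_000).all()

    def test_fixed_seed_gives_byte_identical_bed(self, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        gio.write_bed(simulate_binding_sites(GENOME, 200, seed=7), p1)
        gio.write_bed(simulate_binding_sites(GENOME, 200, seed=7), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCohort:
    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(baseline_mean=0.2, effect_delta=0.25).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_group_b=1).validate()

    def test_beta_values_bounded_and_missingness_calibrated(self, small_bundle, small_config):
        vals = small_bundle.beta.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()
        total = vals.size
        n_na = int(np.isnan(vals).sum())
        expected = small_config.missing_rate * total
        sd = np.sqrt(total * small_config.missing_rate * (1 - small_config.missing_rate))
        assert abs(n_na - expected) <= 3 * sd

    def test_planted_group_b_mean_matches_theory(self):
        cfg = SimulationConfig(n_sites=400, n_background_probes=0, missing_rate=0.0, seed=5)
        sites = simulate_binding_sites(GENOME, cfg.n_sites, seed=5)
        beta, manifest, sheet, truth = simulate_cohort(cfg, sites, GENOME)
        b_samples = sheet.loc[sheet["group"] == cfg.group_b_label, "sample_id"]
        planted = beta.loc[list(truth.planted_probe_ids), b_samples].to_numpy()
        mu = cfg.baseline_mean - cfg.effect_delta
        se = np.sqrt(mu * (1 - mu) / (cfg.precision + 1) / planted.size)
        assert abs(planted.mean() - mu) <= 3 * se

    def test_null_dataset_keeps_planted_bookkeeping(self):
        cfg = SimulationConfig(n_sites=100, effect_delta=0.0, n_background_probes=0,
                               missing_rate=0.0, seed=2)
        sites = simulate_binding_sites(GENOME, 100, seed=2)
        beta, _, sheet, truth = simulate_cohort(cfg, sites, GENOME)
        assert len(truth.planted_probe_ids) == round(cfg.planted_fraction * 100)
        a = beta[sheet.loc[sheet["group"] == "NFPA", "sample_id"]].to_numpy().mean()
        b = beta[sheet.loc[sheet["group"] == "GHPA", "sample_id"]].to_numpy().mean()
        assert abs(a - b) < 0.02  # sampling noise only

    def test_planted_probes_lie_inside_their_sites(self, small_bundle):
        sites = small_bundle.sites.set_index("site_id")
        manifest = small_bundle.manifest.set_index("probe_id")
        for probe, site in small_bundle.truth.probe_site.items():
            pos0 = manifest.loc[probe, "pos"] - 1
            assert sites.loc[site, "start"] <= pos0 < sites.loc[site, "end"]
            assert manifest.loc[probe, "chrom"] == sites.loc[site, "chrom"]

    def test_background_probes_outside_all_sites(self, small_bundle):
        from tfbsmeth import assign_probes_to_sites
        assignment = assign_probes_to_sites(small_bundle.manifest, small_bundle.sites)
        in_site_probes = {p for p, s in assignment.probe_to_sites.items() if s}
        n_expected = len(small_bundle.sites)  # one probe per site by default
        assert len(in_site_probes) >= n_expected

    def test_unplanted_group_means_agree(self, small_bundle, small_config):
        """At unplanted probes the pooled group means differ by < 4 SE for >= 95%."""
        beta, sheet = small_bundle.beta, small_bundle.sample_sheet
        planted = set(small_bundle.truth.planted_probe_ids)
        unplanted = [p for p in beta.index if p not in planted]
        A = beta.loc[unplanted, sheet.loc[sheet["group"] == "NFPA", "sample_id"]].to_numpy()
        B = beta.loc[unplanted, sheet.loc[sheet["group"] == "GHPA", "sample_id"]].to_numpy()
        mu = small_config.baseline_mean
        var = mu * (1 - mu) / (small_config.precision + 1)
        na = (~np.isnan(A)).sum(axis=1)
        nb = (~np.isnan(B)).sum(axis=1)
        se = np.sqrt(var / na + var / nb)
        diff = np.abs(np.nanmean(A, axis=1) - np.nanmean(B, axis=1))
        assert (diff < 4 * se).mean() >= 0.95


class TestTssAndGeneSets:
    def test_members_within_gene_universe(self):
        tss, sets = simulate_tss_and_gene_sets(GENOME, 200, 20, (5, 20), seed=4)
        universe = set(tss["gene_id"])
        assert tss["gene_id"].is_unique
        assert tss["strand"].isin(["+", "-"]).all()
        assert ((tss["tss"] >= 1) & (tss["tss"] <= 10_000_000)).all()
        for _, members in sets.values():
            assert set(members) <= universe

    def test_zero_sets_yield_valid_empty_gmt(self, tmp_path):
        _, sets = simulate_tss_and_gene_sets(GENOME, 50, 0, (5, 10), seed=1)
        path = tmp_path / "empty.gmt"
        gio.write_gmt(sets, path)
        assert gio.read_gmt(path) == {}

    def test_oversized_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_tss_and_gene_sets(GENOME, 10, 2, (5, 50), seed=0)

    def test_gmt_determinism(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            _, sets = simulate_tss_and_gene_sets(GENOME, 100, 10, (5, 20), seed=9)
            p = tmp_path / f"{name}.gmt"
            gio.write_gmt(sets, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestIHCSimulation:
    def test_row_count_and_clipping(self):
        df = simulate_ihc(n_group_a=23, n_group_b=39, seed=0)
        assert len(df) == 62
        assert df["score"].between(0, 14).all()

    def test_negative_n_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_ihc(n_group_a=-1)

    def test_equal_means_rarely_significant(self):
        """Under the null (identical score distributions) a t-test at
        alpha=0.05 should be non-significant in >= 90 of 100 replicates."""
        nonsig = 0
        for seed in range(100):
            df = simulate_ihc(n_group_a=20, n_group_b=20, mean_a=7.0, sd_a=3.0,
                              mean_b=7.0, sd_b=3.0, seed=seed)
            a = df.loc[df["group"] == "NFPA", "score"]
            b = df.loc[df["group"] == "GHPA", "score"]
            if stats.ttest_ind(a, b).pvalue >= 0.05:
                nonsig += 1
        assert nonsig >= 90

    def test_core_decomposition_recovers_totals(self):
        from tfbsmeth.ihc import sample_scores
        df = simulate_ihc(seed=3)
        cores = simulate_ihc_cores(df, cores_per_sample=2)
        assert cores["intensity"].between(0, 3).all()
        recovered = sample_scores(cores, "sum").set_index("sample_id")["score"]
        expect = df.set_index("sample_id")["score"]
        pd.testing.assert_series_equal(recovered.sort_index(), expect.sort_index(),
                                       check_names=False, check_dtype=False)


def test_bundle_determinism(tmp_path, small_config):
    """Identical config + seed gives byte-identical on-disk bundles."""
    from tfbsmeth import simulate_bundle, write_bundle
    d1, d2 = tmp_path / "one", tmp_path / "two"
    p1 = write_bundle(simulate_bundle(small_config), d1)
    p2 = write_bundle(simulate_bundle(small_config), d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
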