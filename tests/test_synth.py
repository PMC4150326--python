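"""Generator: determinism, structure, calibration, degenerate settings."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from ecohurdle.errors import ConfigurationError
from ecohurdle.spatial import haversine_km
from ecohurdle.synth import (
    GeneratorConfig,
    NDVIParams,
    generate_dataset,
    generate_observations,
    generate_studies,
    generate_world,
)


class TestConfigValidation:
    def test_bad_shares_rejected(self):
        with pytest.raises(ConfigurationError, match="group_shares"):
            GeneratorConfig(group_shares=(0.5, 0.5, 0.5, 0.5))

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError, match="sd_study_occ"):
            GeneratorConfig(sd_study_occ=-1.0)

    def test_nonzero_baseline_offset_rejected(self):
        cfg = GeneratorConfig()
        coefs = dict(cfg.true_occ_coefs)
        coefs[("birds", "primary_forest")] = 0.5
        with pytest.raises(ConfigurationError, match="baseline"):
            GeneratorConfig(true_occ_coefs=coefs)


class TestWorld:
    def test_seeded_determinism_byte_identical(self):
        cfg = small_config(seed=3)
        t1, _ = generate_world(cfg)
        t2, _ = generate_world(small_config(seed=3))
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_degenerate_share_all_one_group(self):
        cfg = small_config(group_shares=(1.0, 0.0, 0.0, 0.0))
        taxa, _ = generate_world(cfg)
        assert (taxa["group"] == "invertebrates").all()

    def test_large_pool_shares_within_3se(self):
        shares = (0.55, 0.10, 0.06, 0.29)
        cfg = small_config(taxa_pool_size=10_000, group_shares=shares)
        taxa, _ = generate_world(cfg)
        n = len(taxa)
        counts = taxa["group"].value_counts()
        for g, p in zip(
            ("invertebrates", "herptiles", "mammals", "birds"), shares
        ):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[g] / n - p) <= 3 * se

    def test_hierarchy_depth_and_traits(self):
        taxa, tree = generate_world(small_config())
        assert (taxa["hierarchy"].str.count("/") >= 2).all()
        vert = taxa["group"].isin(["birds", "mammals"])
        assert set(taxa.loc[vert, "specialist_true"]) <= {
            "specialist", "generalist"
        }
        assert (taxa.loc[~vert, "specialist_true"] == "unknown").all()
        assert len(list(tree.leaf_node_iter())) == len(taxa)


class TestStudies:
    def test_constant_series_under_degenerate_ndvi(self):
        cfg = small_config(
            n_studies=2,
            ndvi=NDVIParams(amplitude=0.0, noise_sd=0.0, spike_depth=0.0,
                            flagged_cloud_prob=0.0, unflagged_cloud_prob=0.0,
                            offtake_depth=0.0),
        )
        taxa, _ = generate_world(cfg)
        _, ndvi_long, true_indvi = generate_studies(cfg, taxa)
        assert np.allclose(ndvi_long["ndvi"], cfg.ndvi.baseline)
        assert all(v == 0.0 for v in true_indvi.values())

    def test_all_flagged_when_cloud_prob_one(self):
        cfg = small_config(n_studies=2, ndvi=NDVIParams(flagged_cloud_prob=1.0))
        taxa, _ = generate_world(cfg)
        _, ndvi_long, _ = generate_studies(cfg, taxa)
        assert (ndvi_long["qa"] != 0).all()

    def test_within_study_distances_much_smaller_than_between(self):
        cfg = GeneratorConfig(n_studies=20, sites_per_study=(10, 30), seed=5,
                              taxa_pool_size=60, taxa_per_study=(3, 6))
        taxa, _ = generate_world(cfg)
        sites, _, _ = generate_studies(cfg, taxa)
        d = haversine_km(sites["lon"].to_numpy(), sites["lat"].to_numpy())
        same = (
            sites["study_id"].to_numpy()[:, None]
            == sites["study_id"].to_numpy()[None, :]
        )
        np.fill_diagonal(same, False)
        within = d[same]
        between = d[~same & ~np.eye(len(sites), dtype=bool)]
        assert np.median(within) < 0.01 * np.median(between)

    def test_pressure_ranges(self, small_dataset):
        s = small_dataset.sites
        assert s["forest_cover"].between(0, 100).all()
        assert (s["hpd"] >= 0).all()
        assert s["lat"].abs().le(40).all()


class TestObservations:
    def test_logit_zero_gives_half_presence(self):
        cfg = small_config(
            n_studies=6, sites_per_study=(20, 30),
            sd_study_occ=0.0, sd_site_occ=0.0, sd_taxon_occ=0.0,
            occ_intercept=0.0,
            occ_slopes={(g, v): 0.0 for g in
                        ("invertebrates", "herptiles", "mammals", "birds")
                        for v in ("hpd", "forest_cover", "indvi")},
            true_occ_coefs={(g, lu): 0.0 for g in
                            ("invertebrates", "herptiles", "mammals", "birds")
                            for lu in ("primary_forest", "secondary_vegetation",
                                       "wood_plantation", "cropland", "pasture",
                                       "urban")},
        )
        ds = generate_dataset(cfg)
        rate = (ds.records["value"] > 0).mean()
        n = len(ds.records)
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_nonzero_fraction_hits_target(self):
        cfg = GeneratorConfig(seed=2)
        ds = generate_dataset(cfg)
        assert abs((ds.records["value"] > 0).mean() - 0.26) < 0.02

    def test_effort_recording_rule_hand_example(self):
        """Deterministic abundance log(10), no noise, effort 2 -> value 20
        for effort-sensitive measures."""
        cfg = small_config(
            n_studies=3, sites_per_study=(3, 5),
            sd_study_ab=0.0, sd_site_ab=0.0, sd_taxon_ab=0.0,
            sigma_resid=1e-9,
            abund_intercept=float(np.log(10.0)),
            occ_intercept=10.0,  # ~ all present
            effort_range=(2.0, 2.0),
            true_abund_coefs={(g, lu): 0.0 for g in
                              ("invertebrates", "herptiles", "mammals", "birds")
                              for lu in ("primary_forest",
                                         "secondary_vegetation",
                                         "wood_plantation", "cropland",
                                         "pasture", "urban")},
            abund_slopes={(g, v): 0.0 for g in
                          ("invertebrates", "herptiles", "mammals", "birds")
                          for v in ("hpd", "forest_cover", "indvi")},
        )
        ds = generate_dataset(cfg)
        sensitive = ds.records["measure_type"].isin(
            ["abundance", "group_abundance"]
        )
        vals = ds.records.loc[sensitive & (ds.records["value"] > 0), "value"]
        if len(vals):
            np.testing.assert_allclose(vals, 20.0, rtol=1e-6)
        other = ds.records.loc[~sensitive & (ds.records["value"] > 0), "value"]
        if len(other):
            np.testing.assert_allclose(other, 10.0, rtol=1e-6)

    def test_conservation_every_record_resolves(self, small_dataset):
        ds = small_dataset
        assert ds.records["site_id"].isin(ds.sites["site_id"]).all()
        assert ds.records["taxon_id"].isin(ds.taxa["taxon_id"]).all()
        assert ds.records["study_id"].isin(ds.sites["study_id"]).all()

    def test_truth_reconstructs_linear_predictor_exactly(self, small_dataset):
        ds = small_dataset
        sub = ds.records.head(100)
        eta = ds.truth.linear_predictor(sub, ds.sites, ds.taxa, "occurrence")
        np.testing.assert_allclose(eta, ds.truth.eta_occ[:100], atol=1e-12)
        eta_ab = ds.truth.linear_predictor(sub, ds.sites, ds.taxa, "abundance")
        np.testing.assert_allclose(eta_ab, ds.truth.eta_ab[:100], atol=1e-12)

    def test_study_variance_grows_with_sd_study(self):
        """Empirical variance of study-level mean logits is monotone in
        sd_study over three settings."""
        spreads = []
        for sd in (0.0, 1.0, 2.5):
            cfg = small_config(
                n_studies=12, sites_per_study=(10, 15), seed=21,
                sd_study_occ=sd, occ_intercept=0.0,
            )
            ds = generate_dataset(cfg)
            rec = ds.records.copy()
            rec["present"] = (rec["value"] > 0).astype(float)
            rates = rec.groupby("study_id")["present"].mean().clip(0.01, 0.99)
            spreads.append(np.var(np.log(rates / (1 - rates))))
        assert spreads[0] < spreads[1] < spreads[2]


def test_full_dataset_determinism(tmp_path):
    from ecohurdle.synth import write_dataset

    cfg = small_config(seed=9)
    for sub in ("a", "b"):
        write_dataset(generate_dataset(small_config(seed=9)), tmp_path / sub)
    for name in ("sites.csv", "records.csv", "taxa.csv", "ndvi_long.csv",
                 "points.csv", "truth.json", "taxonomy.nwk"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()
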