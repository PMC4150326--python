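"""Design construction, LRTs, backward selection, R2, post-hoc scans."""

import numpy as np
import pandas as pd
import pytest

from conftest import model_frame, small_config
from ecohurdle.errors import (
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)
from ecohurdle.hurdle import (
    ModelSpec,
    backward_select,
    build_design,
    fit_abundance,
    fit_cubic_submodel,
    fit_model,
    fit_occurrence,
    full_spec,
    lrt,
    posthoc_trait_scan,
    r2_from_components,
    r2_glmm,
    selection_table,
    term_name,
)
from ecohurdle.prep import GROUPS, LAND_USES
from ecohurdle.synth import generate_dataset


def balanced_frame(n_rep=2, rng=None):
    """One row per land-use x group cell (x replicates), all cells filled."""
    rng = rng or np.random.default_rng(0)
    rows = []
    i = 0
    for lu in LAND_USES:
        for g in GROUPS:
            for r in range(n_rep):
                rows.append(
                    {
                        "study_id": f"s{i % 7}", "site_id": f"p{i}",
                        "taxon_id": f"t{i % 13}", "land_use": lu, "group": g,
                        "hpd": float(rng.lognormal(2, 1)),
                        "forest_cover": float(rng.uniform(0, 100)),
                        "indvi": float(rng.uniform(0, 20)),
                        "present": int(rng.random() < 0.5),
                    }
                )
                i += 1
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_treatment_coding_cell_count(self):
        data = balanced_frame()
        spec = ModelSpec(
            "occurrence",
            terms=[{"land_use"}, {"group"}, {"land_use", "group"}],
        )
        design = build_design(data, spec)
        # 6 x 4 cells -> 23 non-reference columns plus the intercept
        assert len(design.colnames) == 24
        assert design.colnames[0] == "(Intercept)"
        assert not design.dropped_columns

    def test_zero_variance_covariate_named(self):
        data = balanced_frame()
        data["indvi"] = 3.0
        with pytest.raises(ValidationError, match="indvi"):
            build_design(data, ModelSpec("occurrence", terms=[{"indvi"}]))

    def test_site_factor_counts_distinct_sites(self):
        data = balanced_frame()
        design = build_design(
            data, ModelSpec("occurrence", terms=[{"land_use"}])
        )
        site = next(f for f in design.factors if f.name == "site")
        assert site.n_levels == data["site_id"].nunique()

    def test_unknown_land_use_rejected(self):
        data = balanced_frame()
        data.loc[0, "land_use"] = "savannah"
        with pytest.raises(ValidationError, match="savannah"):
            build_design(data, ModelSpec("occurrence", terms=[{"land_use"}]))

    def test_empty_cells_dropped_and_recorded(self):
        data = balanced_frame()
        data = data[
            ~((data["land_use"] == "urban") & (data["group"] == "birds"))
        ]
        spec = ModelSpec(
            "occurrence", terms=[{"land_use"}, {"group"}, {"land_use", "group"}]
        )
        design = build_design(data, spec)
        assert "land_use[urban]:group[birds]" in design.dropped_columns


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ConfigurationError, match="marginality"):
            ModelSpec("occurrence", terms=[{"hpd", "forest_cover"}])

    def test_droppable_excludes_contained_terms(self):
        spec = ModelSpec(
            "occurrence",
            terms=[{"hpd"}, {"forest_cover"}, {"hpd", "forest_cover"}],
        )
        droppable = {term_name(t) for t in spec.droppable()}
        assert droppable == {"hpd:forest_cover"}

    def test_full_spec_term_count(self):
        spec = full_spec("occurrence")
        assert len(spec.terms) == 15
        spec2 = full_spec("occurrence", three_way=False)
        assert len(spec2.terms) == 12


class TestLRT:
    def test_identical_models(self, small_occ_frame):
        spec = ModelSpec("occurrence", terms=[{"land_use"}])
        f1 = fit_occurrence(small_occ_frame, spec)
        test = lrt(f1, f1)
        assert test.chisq == 0.0 and test.p == 1.0

    def test_non_nested_rejected(self, small_occ_frame):
        fa = fit_occurrence(
            small_occ_frame, ModelSpec("occurrence", terms=[{"hpd"}])
        )
        fb = fit_occurrence(
            small_occ_frame, ModelSpec("occurrence", terms=[{"indvi"}])
        )
        with pytest.raises(ValidationError, match="nested"):
            lrt(fa, fb)


class TestBackwardSelect:
    def test_marginality_respected_in_trace(self, small_ab_frame):
        spec = full_spec("log_abundance", three_way=False)
        min_model, trace = backward_select(small_ab_frame, spec, alpha=0.05)
        # the retained set is marginality-closed (would raise otherwise)
        ModelSpec("log_abundance", terms=min_model.spec.terms)
        # mains under retained interactions are never dropped
        for t in min_model.spec.terms:
            if len(t) > 1:
                for v in t:
                    assert any(term_name(s) == v for s in min_model.spec.terms)
        # every trace entry names a term of the full spec
        names = {term_name(t) for t in spec.terms}
        assert all(test.term in names for test in trace)

    def test_min_model_aic_not_worse(self, small_ab_frame):
        spec = full_spec("log_abundance", three_way=False)
        full_fit = fit_model(small_ab_frame, spec)
        min_model, _ = backward_select(small_ab_frame, spec, alpha=0.05)
        assert min_model.aic <= full_fit.aic + 2.0

    def test_selection_table_covers_all_terms(self, small_ab_frame):
        spec = full_spec("log_abundance", three_way=False)
        min_model, table = selection_table(small_ab_frame, spec, alpha=0.05)
        assert set(table["term"]) == {term_name(t) for t in spec.terms}
        assert table["chisq"].notna().all()
        assert (table["df"] >= 1).all()


class TestR2:
    def test_closed_form_lmm(self):
        r2 = r2_from_components(
            var_fixed=1.0, var_random=1.0 + 0.5 + 0.5, var_resid=1.0,
            family="gaussian",
        )
        assert r2.marginal == pytest.approx(0.25)
        assert r2.conditional == pytest.approx(0.75)

    def test_binomial_distribution_variance(self):
        r2 = r2_from_components(
            var_fixed=np.pi**2 / 3, var_random=0.0, var_resid=0.0,
            family="binomial",
        )
        assert r2.marginal == pytest.approx(0.5)

    def test_conditional_at_least_marginal(self, small_occ_frame):
        fit = fit_occurrence(
            small_occ_frame, ModelSpec("occurrence", terms=[{"land_use"}])
        )
        r2 = r2_glmm(fit)
        assert 0.0 <= r2.marginal <= r2.conditional <= 1.0

    def test_intercept_only_marginal_zero(self, small_occ_frame):
        fit = fit_occurrence(small_occ_frame, ModelSpec("occurrence", terms=[]))
        assert r2_glmm(fit).marginal == pytest.approx(0.0, abs=1e-12)


class TestPosthoc:
    def test_null_trait_penalises_aic(self, small_occ_frame, rng):
        data = small_occ_frame.copy()
        taxa = data["taxon_id"].unique()
        flag = dict(zip(taxa, rng.random(len(taxa)) < 0.5))
        data["specialist"] = np.where(
            data["taxon_id"].map(flag), "specialist", "generalist"
        )
        min_spec = ModelSpec("occurrence", terms=[{"land_use"}])
        scan = posthoc_trait_scan(data, min_spec, "specialist")
        assert len(scan) == 1
        assert scan["delta_aic"].iloc[0] > -6  # no real improvement

    def test_redundant_augmentation_flagged(self, small_occ_frame):
        data = small_occ_frame.copy()
        # indicator identical to an existing group dummy -> rank deficient
        data["specialist"] = np.where(
            data["group"] == data["group"].unique()[0], "specialist",
            "generalist",
        )
        min_spec = ModelSpec(
            "occurrence", terms=[{"land_use"}, {"group"},
                                 {"land_use", "group"}]
        )
        scan = posthoc_trait_scan(data, min_spec, "specialist")
        assert scan["redundant"].any()


class TestCubicSubmodel:
    def test_constant_covariate_rejected(self, small_occ_frame):
        data = small_occ_frame.copy()
        data["hpd"] = 5.0
        with pytest.raises(InsufficientDataError, match="distinct"):
            fit_cubic_submodel(data)

    def test_u_shape_recovered(self):
        """A U-shaped logit in the covariate yields a fitted curve whose
        interior minimum sits between the arms."""
        rng = np.random.default_rng(12)
        n_st, n_si, n_tx = 10, 12, 8
        study = np.repeat(np.arange(n_st), n_si * n_tx)
        site = np.repeat(np.arange(n_st * n_si), n_tx)
        x = np.exp(rng.uniform(0, 5, n_st * n_si))[site]
        z = np.log1p(x)
        zc = (z - z.mean()) / z.std()
        eta = 0.8 * zc**2 - 0.5 + rng.normal(0, 0.5, n_st)[study]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        data = pd.DataFrame(
            {
                "study_id": study, "site_id": site,
                "taxon_id": np.tile(np.arange(n_tx), n_st * n_si),
                "hpd": x, "present": y,
            }
        )
        cubic = fit_cubic_submodel(data, "hpd")
        grid = np.linspace(x.min(), x.max(), 41)
        pred = cubic.linear_predictor(grid)
        interior = pred[5:-5]
        assert interior.min() < pred[0] and interior.min() < pred[-1]


def test_abundance_requires_positive_values(small_ab_frame):
    data = small_ab_frame.copy()
    data.loc[data.index[0], "value"] = 0.0
    with pytest.raises(ValidationError, match="non-positive"):
        fit_abundance(data, ModelSpec("log_abundance", terms=[{"land_use"}]))
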