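"""Derived quantities, reporting and the end-to-end pipeline.

Relative effects express each land use's impact as the linear-predictor
difference from primary forest (logit scale for occurrence, natural-log
scale for abundance) per taxonomic group.  The community-abundance index
multiplies the back-transformed relative probability of occurrence with the
relative abundance of persisting species, a crude but interpretable measure
of how much total community abundance a land use retains (1 = primary
forest).  ``run_pipeline`` wires all stages together: simulate -> pressures
-> preprocess -> hurdle fits with backward selection -> diagnostics ->
summaries, writing every table plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .diagnostics import moran_by_study, phylo_signal, refit_excluding
from .errors import ValidationError
from .hurdle import (
    FittedModel,
    full_spec,
    posthoc_trait_scan,
    r2_glmm,
    selection_table,
)
from .ndvi import compute_pressures
from .prep import correct_effort, derive_occurrence, classify_range, flag_specialists
from .spatial import autocorr_meta
from .synth import GeneratorConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "relative_effects",
    "reference_intercepts",
    "community_index",
    "prediction_surface",
    "variance_ordering",
    "build_model_frames",
    "run_pipeline",
    "PipelineResult",
]


def _reference_row(design, land_use: str, group: str | None) -> pd.DataFrame:
    """One prediction row: given cell, continuous covariates at their centre."""
    row = {}
    if "land_use" in design.cat_levels:
        row["land_use"] = land_use
    if "group" in design.cat_levels and group is not None:
        row[design.spec.group_col] = group
    for var, (use_log, mean, sd) in design.transforms.items():
        row[var] = float(np.expm1(mean)) if use_log else mean
    return pd.DataFrame([row])


def relative_effects(
    fitted: FittedModel, baseline: str = "primary_forest"
) -> pd.DataFrame:
    """Land-use contrasts vs primary forest per group, with delta-method SEs.

    delta is the fixed-effect linear-predictor difference between the land
    use and the baseline for that group, continuous covariates held at
    their reference (centred) values; se comes from the coefficient
    covariance through the contrast vector.  Cells absent from the data
    (dropped design columns) are reported with NaN.
    """
    design = fitted.design
    if "land_use" not in design.cat_levels:
        raise ValidationError("fit contains no land-use term")
    lu_levels = design.cat_levels["land_use"][0]
    groups = list(design.cat_levels.get("group", ((None,), None))[0])
    rows = []
    for g in groups:
        base_X = design.matrix(_reference_row(design, baseline, g))
        for lu in lu_levels:
            if lu == baseline:
                rows.append({"group": g, "land_use": lu, "delta": 0.0, "se": 0.0})
                continue
            cell_col = f"land_use[{lu}]:group[{g}]"
            if cell_col in design.dropped_columns:
                rows.append(
                    {"group": g, "land_use": lu, "delta": np.nan, "se": np.nan}
                )
                continue
            X = design.matrix(_reference_row(design, lu, g))
            c = (X - base_X)[0]
            delta = float(c @ fitted.fit.beta)
            se = float(np.sqrt(max(c @ fitted.fit.vcov_beta @ c, 0.0)))
            rows.append({"group": g, "land_use": lu, "delta": delta, "se": se})
    return pd.DataFrame(rows)


def reference_intercepts(fitted: FittedModel, baseline: str = "primary_forest") -> dict:
    """Per-group fixed-effect linear predictor in primary forest.

    Random effects at zero, continuous covariates at their reference;
    this is the occurrence model's baseline logit used to back-transform
    relative effects into probability ratios.
    """
    design = fitted.design
    groups = list(design.cat_levels.get("group", ((None,), None))[0])
    return {
        g: float(design.matrix(_reference_row(design, baseline, g))[0] @ fitted.fit.beta)
        for g in groups
    }


def community_index(
    rel_occ: pd.DataFrame, rel_abund: pd.DataFrame, ref_intercepts: dict
) -> pd.DataFrame:
    """Occurrence x abundance community-abundance index per group/land use.

    value = [invlogit(b0 + d_occ) / invlogit(b0)] * exp(d_abund), with b0
    the group's primary-forest occurrence logit.  Exactly 1 for primary
    forest.  Pairs missing from either stage are skipped with a warning.
    A stage whose selected model carries no group term (group None in its
    relative effects) applies its common land-use effect to every group.
    """
    groups = sorted(
        {
            g
            for g in pd.concat([rel_occ["group"], rel_abund["group"]])
            if g is not None and pd.notna(g)
        }
    )

    def _expand(df):
        if groups and df["group"].isna().all():
            return pd.concat(
                [df.assign(group=g) for g in groups], ignore_index=True
            )
        return df

    rel_occ = _expand(rel_occ)
    rel_abund = _expand(rel_abund)
    merged = rel_occ.merge(
        rel_abund, on=["group", "land_use"], suffixes=("_occ", "_ab"), how="inner"
    )
    skipped = set(map(tuple, rel_occ[["group", "land_use"]].to_numpy())) - set(
        map(tuple, merged[["group", "land_use"]].to_numpy())
    )
    if skipped:
        logger.warning("community index skipped unmatched pairs: %s", sorted(skipped))
    rows = []
    for r in merged.itertuples(index=False):
        if not (np.isfinite(r.delta_occ) and np.isfinite(r.delta_ab)):
            logger.warning("community index undefined for %s/%s", r.group, r.land_use)
            continue
        b0 = ref_intercepts.get(r.group, ref_intercepts.get(None))
        value = float(expit(b0 + r.delta_occ) / expit(b0) * np.exp(r.delta_ab))
        rows.append({"group": r.group, "land_use": r.land_use, "value": value})
    return pd.DataFrame(rows)


def prediction_surface(
    fitted: FittedModel,
    data: pd.DataFrame,
    covariates,
    group: str | None = None,
    land_use: str = "primary_forest",
    n: int = 25,
    grid: dict | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Natural-scale predictions over a 1- or 2-covariate grid.

    Non-plotted covariates sit at their observed medians, land use at
    primary forest, random effects at zero.  Grids default to the observed
    covariate range; explicit grids beyond it are refused unless
    ``force=True``.
    """
    covariates = list(covariates)
    if not 1 <= len(covariates) <= 2:
        raise ValidationError("surface takes one or two covariates")
    axes = {}
    for cov in covariates:
        obs = data[cov].to_numpy(float)
        lo, hi = float(obs.min()), float(obs.max())
        if grid and cov in grid:
            glo, ghi = grid[cov]
            if (glo < lo or ghi > hi) and not force:
                raise ValidationError(
                    f"grid for {cov!r} extrapolates beyond observed "
                    f"[{lo:.3g}, {hi:.3g}]; pass force=True to override"
                )
            lo, hi = glo, ghi
        axes[cov] = np.linspace(lo, hi, n)
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    frame = {cov: m.ravel() for cov, m in zip(axes, mesh)}
    npts = len(frame[covariates[0]])
    for var in fitted.design.transforms:
        if var not in frame:
            frame[var] = np.full(npts, float(np.median(data[var])))
    if "land_use" in fitted.design.cat_levels:
        frame["land_use"] = [land_use] * npts
    if "group" in fitted.design.cat_levels:
        if group is None:
            raise ValidationError("model has a group term; pass group=")
        frame[fitted.design.spec.group_col] = [group] * npts
    X = fitted.design.matrix(pd.DataFrame(frame))
    eta = X @ fitted.fit.beta
    pred = expit(eta) if fitted.spec.family == "binomial" else np.exp(eta)
    out = pd.DataFrame({cov: frame[cov] for cov in covariates})
    out["predicted"] = pred
    if group is not None:
        out.insert(0, "group", group)
    return out


def variance_ordering(fitted: FittedModel, tie_rel_tol: float = 0.10) -> pd.DataFrame:
    """Random-effect variances ranked largest-first, with a tie flag.

    Components within ``tie_rel_tol`` (relative to the largest) of their
    neighbour are flagged as effectively tied, since the ranking is then
    unstable.
    """
    comps = {k: v**2 for k, v in fitted.fit.sigma.items()}
    items = sorted(comps.items(), key=lambda kv: -kv[1])
    vmax = items[0][1] if items else 0.0
    rows = []
    for rank, (name, var) in enumerate(items, start=1):
        tied = any(
            abs(var - other) <= tie_rel_tol * max(vmax, 1e-300)
            for nm, other in items
            if nm != name
        )
        rows.append({"component": name, "variance": var, "rank": rank, "tied": tied})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


def build_model_frames(sites, records, taxa, pressures):
    """Model-ready frames for the two hurdle stages.

    Returns (occurrence frame, abundance frame): effort-corrected records,
    the derived presence/absence table, and site covariates (pressures from
    the iNDVI pipeline) merged in, with taxon group and trait columns.
    """
    corrected = correct_effort(records)
    occ = derive_occurrence(records)
    covar = sites[["study_id", "site_id", "land_use"]].merge(
        pressures[["site_id", "forest_cover", "hpd", "indvi"]], on="site_id"
    )
    tax_cols = ["taxon_id", "group"] + [
        c for c in ("specialist", "range_class") if c in taxa.columns
    ]
    occ_data = occ.merge(covar, on=["study_id", "site_id"]).merge(
        taxa[tax_cols], on="taxon_id"
    )
    ab_data = (
        corrected[corrected["value"] > 0]
        .merge(covar, on=["study_id", "site_id"])
        .merge(taxa[tax_cols], on="taxon_id")
        .reset_index(drop=True)
    )
    return occ_data.reset_index(drop=True), ab_data


@dataclass
class PipelineResult:
    config: GeneratorConfig
    dataset: object
    pressures: pd.DataFrame
    occ_data: pd.DataFrame
    ab_data: pd.DataFrame
    occ_model: FittedModel
    ab_model: FittedModel
    term_table: pd.DataFrame
    r2: pd.DataFrame
    rel_occ: pd.DataFrame
    rel_ab: pd.DataFrame
    index: pd.DataFrame
    varcomps: pd.DataFrame
    phylo: dict
    moran: pd.DataFrame
    autocorr: dict
    posthoc: pd.DataFrame | None
    refit_comparison: pd.DataFrame | None


def run_pipeline(
    config: GeneratorConfig,
    outdir=None,
    alpha: float = 0.05,
    moran_alpha: float = 0.05,
    posthoc: bool = True,
    refit_check: bool = True,
) -> PipelineResult:
    """Simulate, extract pressures, preprocess, fit, diagnose, summarise.

    Any stage failure propagates with the stage named.  With ``outdir``
    set, all declared tables are written there along with a run manifest.
    """
    stage = "simulate"
    try:
        ds = generate_dataset(config)
        stage = "pressures"
        pressures = compute_pressures(ds.ndvi_long, ds.sites)
        stage = "preprocess"
        taxa = classify_range(ds.points, ds.taxa)
        taxa = flag_specialists(taxa, ds.habitat)
        occ_data, ab_data = build_model_frames(ds.sites, ds.records, taxa, pressures)
        stage = "fit"
        occ_model, occ_table = selection_table(
            occ_data, full_spec("occurrence"), alpha=alpha
        )
        ab_model, ab_table = selection_table(
            ab_data, full_spec("log_abundance"), alpha=alpha
        )
        occ_table.insert(0, "response", "occurrence")
        ab_table.insert(0, "response", "abundance")
        term_table = pd.concat([occ_table, ab_table], ignore_index=True)
        r2 = pd.DataFrame(
            [
                {"response": "occurrence", **dataclasses.asdict(r2_glmm(occ_model))},
                {"response": "abundance", **dataclasses.asdict(r2_glmm(ab_model))},
            ]
        )
        stage = "diagnostics"
        phylo = {}
        for name, model, frame in (
            ("occurrence", occ_model, occ_data),
            ("abundance", ab_model, ab_data),
        ):
            sig = phylo_signal(model, frame, ds.tree)
            phylo[name] = dataclasses.asdict(sig)
        moran_rows, autocorr = [], {}
        flagged = {}
        for name, model, frame in (
            ("occurrence", occ_model, occ_data),
            ("abundance", ab_model, ab_data),
        ):
            results = moran_by_study(model, frame, ds.sites)
            meta = autocorr_meta(results, alpha=moran_alpha)
            autocorr[name] = dataclasses.asdict(meta)
            flagged[name] = [
                r.study_id for r in results if np.isfinite(r.p) and r.p < moran_alpha
            ]
            for r in results:
                moran_rows.append({"response": name, **dataclasses.asdict(r)})
        moran = pd.DataFrame(moran_rows)
        refit_comparison = None
        if refit_check and flagged["occurrence"]:
            _, refit_comparison = refit_excluding(
                occ_data, flagged["occurrence"], occ_model.spec
            )
        stage = "posthoc"
        posthoc_tbl = None
        if posthoc:
            ph = []
            for trait in ("specialist", "range_class"):
                try:
                    scan = posthoc_trait_scan(occ_data, occ_model.spec, trait)
                    scan.insert(0, "trait", trait)
                    ph.append(scan)
                except ValidationError as exc:
                    logger.info("post-hoc %s scan skipped: %s", trait, exc)
            posthoc_tbl = pd.concat(ph, ignore_index=True) if ph else None
        stage = "summaries"
        empty = pd.DataFrame(columns=["group", "land_use", "delta", "se"])
        try:
            rel_occ = relative_effects(occ_model)
        except ValidationError:
            logger.info("occurrence model retained no land-use term")
            rel_occ = empty.copy()
        try:
            rel_ab = relative_effects(ab_model)
        except ValidationError:
            logger.info("abundance model retained no land-use term")
            rel_ab = empty.copy()
        if len(rel_occ) and len(rel_ab):
            index = community_index(rel_occ, rel_ab, reference_intercepts(occ_model))
        else:
            index = pd.DataFrame(columns=["group", "land_use", "value"])
        varcomps = pd.concat(
            [
                variance_ordering(occ_model).assign(response="occurrence"),
                variance_ordering(ab_model).assign(response="abundance"),
            ],
            ignore_index=True,
        )
    except Exception as exc:
        raise type(exc)(f"[pipeline stage: {stage}] {exc}") from exc

    result = PipelineResult(
        config=config, dataset=ds, pressures=pressures,
        occ_data=occ_data, ab_data=ab_data,
        occ_model=occ_model, ab_model=ab_model,
        term_table=term_table, r2=r2, rel_occ=rel_occ, rel_ab=rel_ab,
        index=index, varcomps=varcomps, phylo=phylo, moran=moran,
        autocorr=autocorr, posthoc=posthoc_tbl,
        refit_comparison=refit_comparison,
    )
    if outdir is not None:
        _write_report(result, Path(outdir))
    return result


def _write_report(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset(res.dataset, outdir / "data")
    report = outdir / "report"
    report.mkdir(exist_ok=True)
    res.pressures.to_csv(report / "pressures.csv", index=False)
    res.occ_data.to_csv(report / "occurrence.csv", index=False)
    res.term_table.to_csv(report / "model_terms.csv", index=False)
    res.r2.to_csv(report / "r2.csv", index=False)
    coef = pd.concat(
        [
            pd.DataFrame(
                {
                    "response": name,
                    "column": m.design.colnames,
                    "estimate": m.fit.beta,
                    "se": m.fit.se_beta,
                }
            )
            for name, m in (
                ("occurrence", res.occ_model), ("abundance", res.ab_model)
            )
        ],
        ignore_index=True,
    )
    coef.to_csv(report / "coefficients.csv", index=False)
    res.varcomps.to_csv(report / "varcomps.csv", index=False)
    res.rel_occ.to_csv(report / "relative_effects_occurrence.csv", index=False)
    res.rel_ab.to_csv(report / "relative_effects_abundance.csv", index=False)
    res.index.to_csv(report / "community_index.csv", index=False)
    res.moran.to_csv(report / "moran_by_study.csv", index=False)
    if res.posthoc is not None:
        res.posthoc.to_csv(report / "posthoc_daic.csv", index=False)
    if res.refit_comparison is not None:
        res.refit_comparison.to_csv(report / "refit_comparison.csv", index=False)
    with open(report / "autocorr_meta.json", "w") as fh:
        json.dump(res.autocorr, fh, indent=1)
    with open(report / "phylo_signal.json", "w") as fh:
        json.dump(res.phylo, fh, indent=1)
    manifest = {
        "package": "ecohurdle",
        "version": __version__,
        "seed": res.config.seed,
        "n_studies": res.config.n_studies,
        "n_sites": int(len(res.dataset.sites)),
        "n_records": int(len(res.dataset.records)),
        "nonzero_fraction": float((res.dataset.records["value"] > 0).mean()),
        "occurrence_terms": [
            t for t in res.term_table.query(
                "response == 'occurrence' and retained"
            )["term"]
        ],
        "abundance_terms": [
            t for t in res.term_table.query(
                "response == 'abundance' and retained"
            )["term"]
        ],
        "decisions": {
            "estimation": "maximum likelihood (Laplace for occurrence)",
            "effort_rescaling": "to within-study maximum effort",
            "hpd_transform": "log(x+1), standardised",
            "moran_weights": "inverse great-circle distance, row-standardised",
            "residual_types": "deviance (occurrence) / response (abundance)",
            "lambda_reference": "chi-square(1) upper tail",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
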