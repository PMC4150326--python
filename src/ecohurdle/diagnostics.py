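"""Residual model criticism for the fitted hurdle stages.

Two failure modes of the independence assumptions are probed: phylogenetic
signal in taxon-averaged residuals (Pagel's lambda on the Grafen-scaled
taxonomy tree, with a boundary LRT against the star tree) and residual
spatial autocorrelation within studies (per-study Moran's I with a binomial
meta-test, followed by a refit that drops the flagged studies).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .hurdle import FittedModel, fit_model
from .phylo import (
    PhyloSignalResult,
    build_tree,
    grafen_lengths,
    lambda_lrt,
    pagel_lambda,
    tree_covariance,
)
from .spatial import AutocorrMeta, MoranResult, autocorr_meta, morans_i

logger = logging.getLogger(__name__)

__all__ = [
    "residuals_by_taxon",
    "phylo_signal",
    "moran_by_study",
    "refit_excluding",
    "build_tree",
    "grafen_lengths",
    "tree_covariance",
    "pagel_lambda",
    "lambda_lrt",
    "autocorr_meta",
    "morans_i",
    "PhyloSignalResult",
    "MoranResult",
    "AutocorrMeta",
]


def residuals_by_taxon(fitted: FittedModel, data: pd.DataFrame) -> pd.Series:
    """Record-level residuals averaged per taxon.

    Deviance residuals for the occurrence stage, response residuals for the
    abundance stage; taxa with no records simply do not appear.
    """
    if len(data) != fitted.n_obs:
        raise ValidationError("data does not match the fitted model's rows")
    res = pd.Series(fitted.residuals(), index=data["taxon_id"].to_numpy())
    return res.groupby(level=0).mean()


def phylo_signal(fitted: FittedModel, data: pd.DataFrame, tree) -> PhyloSignalResult:
    """Pagel's lambda of the model's taxon-averaged residuals on the tree."""
    taxon_res = residuals_by_taxon(fitted, data)
    labels, V = tree_covariance(tree)
    keep = [i for i, lab in enumerate(labels) if lab in taxon_res.index]
    if len(keep) < 3:
        raise InsufficientDataError("fewer than 3 taxa shared between tree and fit")
    idx = np.asarray(keep)
    values = taxon_res.loc[[labels[i] for i in keep]].to_numpy()
    return pagel_lambda(V[np.ix_(idx, idx)], values)


def moran_by_study(
    fitted: FittedModel,
    data: pd.DataFrame,
    sites: pd.DataFrame,
    weights_spec: str = "inverse_distance",
) -> list[MoranResult]:
    """Moran's I of site-averaged residuals, separately per study.

    Studies with fewer than three sites or constant residuals are skipped
    (with the reason logged), mirroring the statistic's domain.
    """
    if len(data) != fitted.n_obs:
        raise ValidationError("data does not match the fitted model's rows")
    frame = data[["study_id", "site_id"]].copy()
    frame["resid"] = fitted.residuals()
    site_res = (
        frame.groupby(["study_id", "site_id"], sort=True)["resid"].mean().reset_index()
    )
    coords = sites.set_index("site_id")[["lon", "lat"]]
    results = []
    for study_id, sub in site_res.groupby("study_id", sort=True):
        xy = coords.loc[sub["site_id"]]
        try:
            results.append(
                morans_i(
                    sub["resid"].to_numpy(),
                    xy["lon"].to_numpy(),
                    xy["lat"].to_numpy(),
                    study_id=str(study_id),
                    weights_spec=weights_spec,
                )
            )
        except ValidationError as exc:
            logger.info("study %s skipped for Moran's I: %s", study_id, exc)
    return results


def refit_excluding(
    data: pd.DataFrame,
    flagged_studies,
    spec,
) -> tuple[FittedModel, pd.DataFrame]:
    """Refit a selected model without the spatially-autocorrelated studies.

    Returns the new fit and a side-by-side coefficient table; contrasts
    whose design column vanished with the dropped studies appear as NaN in
    the refit columns rather than raising.
    """
    flagged = set(map(str, flagged_studies))
    reduced = data[~data["study_id"].astype(str).isin(flagged)].reset_index(drop=True)
    if not len(reduced):
        raise InsufficientDataError("all studies flagged; nothing left to refit")
    original = fit_model(data, spec)
    refit = fit_model(reduced, spec)
    ref_coef = refit.coefficients
    ref_se = refit.se
    comparison = pd.DataFrame(
        {
            "coef_full": original.coefficients,
            "se_full": original.se,
            "coef_refit": ref_coef.reindex(original.design.colnames),
            "se_refit": ref_se.reindex(original.design.colnames),
        }
    )
    comparison.index.name = "column"
    return refit, comparison.reset_index()
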