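"""Synthetic multi-study community datasets with known ground truth.

Emulates the hierarchical structure of a compiled land-use/biodiversity
dataset: a few dozen studies, each sampling one taxonomic group at a
cluster of sites in one of six land-use classes, recording abundances of
the taxa it sampled at every site (zeros included), under study-, site- and
taxon-level random variation.  Sites carry MODIS-like 16-day NDVI composite
series (with flagged and unflagged cloud contamination) whose latent
vegetation-offtake signal drives the site's true iNDVI, plus forest cover
and human population density correlated with land use.

Occurrence is Bernoulli through a logit link; abundance given presence is
log-normal; recorded values are scaled by sampling effort for the
effort-sensitive measure types.  Taxon-level random effects are drawn on
the taxonomy tree with a Pagel transform at ``lambda_true``, so residual
phylogenetic-signal diagnostics have a known target.

All randomness flows from one root seed through named ``SeedSequence``
children (world, studies, observations, points), so identical configs give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError
from .ndvi import NDVISeries, compute_indvi, window_for_study
from .phylo import build_tree, grafen_lengths, simulate_trait, tree_covariance
from .prep import EFFORT_SENSITIVE_MEASURES, GROUPS, LAND_USES

__all__ = [
    "NDVIParams",
    "GeneratorConfig",
    "TrueModel",
    "SyntheticDataset",
    "generate_world",
    "generate_studies",
    "generate_observations",
    "generate_range_points",
    "generate_dataset",
    "write_dataset",
]

MEASURE_TYPES = (
    "abundance",
    "relative_abundance",
    "group_abundance",
    "density",
    "reporting_rate",
)

# land-use conditioned means for the correlated pressures
_FOREST_COVER_MEAN = {
    "primary_forest": 85.0,
    "secondary_vegetation": 60.0,
    "wood_plantation": 70.0,
    "cropland": 25.0,
    "pasture": 20.0,
    "urban": 15.0,
}
_LOG_HPD_MEAN = {
    "primary_forest": 1.0,
    "secondary_vegetation": 2.2,
    "wood_plantation": 2.2,
    "cropland": 3.0,
    "pasture": 2.5,
    "urban": 5.0,
}
_OFFTAKE_MEAN = {
    "primary_forest": 0.05,
    "secondary_vegetation": 0.20,
    "wood_plantation": 0.50,
    "cropland": 0.60,
    "pasture": 0.40,
    "urban": 0.30,
}

# default land-use impacts on the logit of occurrence (vs primary forest),
# modulated per group; human-dominated classes depress occurrence
_DEFAULT_OCC_LU = {
    "primary_forest": 0.0,
    "secondary_vegetation": -0.3,
    "wood_plantation": -0.5,
    "cropland": -1.0,
    "pasture": -0.8,
    "urban": -1.5,
}
# persisting species often become more abundant in disturbed classes,
# except in urban habitats
_DEFAULT_AB_LU = {
    "primary_forest": 0.0,
    "secondary_vegetation": 0.25,
    "wood_plantation": 0.3,
    "cropland": 0.2,
    "pasture": -0.1,
    "urban": -0.6,
}
_GROUP_MOD = {"invertebrates": 1.0, "herptiles": 0.7, "mammals": 1.3, "birds": 1.1}

_DEFAULT_OCC_SLOPES = {
    ("invertebrates", "hpd"): -0.15, ("invertebrates", "forest_cover"): 0.10,
    ("invertebrates", "indvi"): -0.15,
    ("herptiles", "hpd"): 0.20, ("herptiles", "forest_cover"): 0.10,
    ("herptiles", "indvi"): -0.10,
    ("mammals", "hpd"): -0.25, ("mammals", "forest_cover"): 0.15,
    ("mammals", "indvi"): -0.10,
    ("birds", "hpd"): -0.20, ("birds", "forest_cover"): 0.15,
    ("birds", "indvi"): -0.10,
}
_DEFAULT_AB_SLOPES = {
    ("invertebrates", "hpd"): -0.05, ("invertebrates", "forest_cover"): 0.05,
    ("invertebrates", "indvi"): -0.10,
    ("herptiles", "hpd"): -0.20, ("herptiles", "forest_cover"): 0.15,
    ("herptiles", "indvi"): -0.15,
    ("mammals", "hpd"): 0.05, ("mammals", "forest_cover"): 0.05,
    ("mammals", "indvi"): -0.10,
    ("birds", "hpd"): -0.05, ("birds", "forest_cover"): 0.05,
    ("birds", "indvi"): -0.10,
}


@dataclass
class NDVIParams:
    """Shape of the synthetic 16-day NDVI composite series.

    ``offtake_depth`` scales how deeply a site's latent vegetation-offtake
    level (0-1, land-use dependent) cuts into the canopy signal during
    harvest episodes; it is what creates true between-site iNDVI contrast.
    ``spike_depth`` is the magnitude of cloud-contamination drops, both for
    composites the quality band catches (flagged) and for those it misses
    (unflagged).
    """

    baseline: float = 0.7
    amplitude: float = 0.08
    noise_sd: float = 0.02
    flagged_cloud_prob: float = 0.10
    unflagged_cloud_prob: float = 0.02
    spike_depth: float = 0.3
    offtake_depth: float = 0.35
    dips_per_year: int = 3


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 20-study, ~600-site network sampling four taxonomic
    groups across six land-use classes, with roughly a quarter of records
    non-zero.  Land-use and group frequencies follow the published site and
    taxon tallies this structure emulates.
    """

    n_studies: int = 20
    sites_per_study: tuple = (10, 50)
    taxa_pool_size: int = 400
    taxa_per_study: tuple = (10, 30)
    group_shares: tuple = (0.55, 0.10, 0.06, 0.29)
    land_use_probs: tuple = (0.4377, 0.1182, 0.4013, 0.0088, 0.0252, 0.0088)
    measure_probs: tuple = (0.924, 0.0685, 0.0033, 0.0019, 0.0023)
    true_occ_coefs: dict | None = None   # (group, land_use) -> logit offset
    true_abund_coefs: dict | None = None # (group, land_use) -> log offset
    occ_slopes: dict | None = None       # (group, pressure) -> per-SD coefficient
    abund_slopes: dict | None = None
    occ_intercept: float | None = None   # None: calibrated to target_presence
    target_presence: float = 0.26
    abund_intercept: float = float(np.log(5.0))
    sd_study_occ: float = 1.2
    sd_site_occ: float = 0.4
    sd_taxon_occ: float = 0.8
    sd_study_ab: float = 1.0
    sd_site_ab: float = 0.3
    sd_taxon_ab: float = 0.6
    sigma_resid: float = 1.0
    effort_range: tuple = (0.5, 2.0)
    ndvi: NDVIParams = field(default_factory=NDVIParams)
    lambda_true: float = 0.1
    specialist_prob: float = 0.35
    site_jitter_deg: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.true_occ_coefs is None:
            self.true_occ_coefs = {
                (g, lu): round(_DEFAULT_OCC_LU[lu] * _GROUP_MOD[g], 4)
                for g in GROUPS for lu in LAND_USES
            }
        if self.true_abund_coefs is None:
            self.true_abund_coefs = {
                (g, lu): round(_DEFAULT_AB_LU[lu] * _GROUP_MOD[g], 4)
                for g in GROUPS for lu in LAND_USES
            }
        if self.occ_slopes is None:
            self.occ_slopes = dict(_DEFAULT_OCC_SLOPES)
        if self.abund_slopes is None:
            self.abund_slopes = dict(_DEFAULT_AB_SLOPES)
        self.validate()

    def validate(self):
        for name, probs, k in (
            ("group_shares", self.group_shares, 4),
            ("land_use_probs", self.land_use_probs, 6),
            ("measure_probs", self.measure_probs, 5),
        ):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-6 or min(probs) < 0:
                raise ConfigurationError(f"{name} must be {k} proportions summing to 1")
        for name in (
            "sd_study_occ", "sd_site_occ", "sd_taxon_occ",
            "sd_study_ab", "sd_site_ab", "sd_taxon_ab",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.sigma_resid <= 0:
            raise ConfigurationError("sigma_resid must be positive")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ConfigurationError("lambda_true must be in [0, 1]")
        if self.effort_range[0] <= 0 or self.effort_range[1] < self.effort_range[0]:
            raise ConfigurationError("effort_range must be a positive interval")
        for g in GROUPS:
            for coefs in (self.true_occ_coefs, self.true_abund_coefs):
                if coefs.get((g, "primary_forest"), 0.0) != 0.0:
                    raise ConfigurationError(
                        "primary-forest (baseline) offsets must be exactly 0"
                    )

    def rngs(self) -> dict:
        """Named child generators from the root seed (documented splitting)."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("world", "studies", "observations", "points")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TrueModel:
    """Ground-truth parameters and realised random-effect draws."""

    occ_intercept: float
    abund_intercept: float
    occ_coefs: dict
    abund_coefs: dict
    occ_slopes: dict
    abund_slopes: dict
    sd: dict
    sigma_resid: float
    lambda_true: float
    pressure_scaling: dict              # var -> (mean, sd) on the model scale
    ranef_occ: dict                     # factor -> {level: draw}
    ranef_ab: dict
    true_indvi: dict                    # site_id -> latent iNDVI
    eta_occ: np.ndarray = field(repr=False, default=None)
    eta_ab: np.ndarray = field(repr=False, default=None)

    def linear_predictor(self, records: pd.DataFrame, sites: pd.DataFrame,
                         taxa: pd.DataFrame, stage: str = "occurrence") -> np.ndarray:
        """Rebuild the linear predictor from stored parts (exactness check)."""
        occ = stage == "occurrence"
        coefs = self.occ_coefs if occ else self.abund_coefs
        slopes = self.occ_slopes if occ else self.abund_slopes
        ranef = self.ranef_occ if occ else self.ranef_ab
        icpt = self.occ_intercept if occ else self.abund_intercept
        smap = sites.set_index("site_id")
        gmap = taxa.set_index("taxon_id")["group"]
        eta = np.full(len(records), icpt)
        for i, row in enumerate(records.itertuples(index=False)):
            g = gmap[row.taxon_id]
            site = smap.loc[row.site_id]
            eta[i] += coefs[(g, site["land_use"])]
            for var in ("hpd", "forest_cover", "indvi"):
                mean, sd = self.pressure_scaling[var]
                raw = (
                    self.true_indvi[row.site_id] if var == "indvi" else site[var]
                )
                x = np.log1p(raw) if var == "hpd" else raw
                eta[i] += slopes[(g, var)] * (x - mean) / sd
            eta[i] += (
                ranef["study"][row.study_id]
                + ranef["site"][row.site_id]
                + ranef["taxon"][row.taxon_id]
            )
        return eta

    def to_jsonable(self) -> dict:
        def keymap(d):
            return {"|".join(k): v for k, v in d.items()}
        return {
            "occ_intercept": self.occ_intercept,
            "abund_intercept": self.abund_intercept,
            "occ_coefs": keymap(self.occ_coefs),
            "abund_coefs": keymap(self.abund_coefs),
            "occ_slopes": keymap(self.occ_slopes),
            "abund_slopes": keymap(self.abund_slopes),
            "sd": self.sd,
            "sigma_resid": self.sigma_resid,
            "lambda_true": self.lambda_true,
            "pressure_scaling": self.pressure_scaling,
            "ranef_occ": self.ranef_occ,
            "ranef_ab": self.ranef_ab,
            "true_indvi": self.true_indvi,
        }


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    taxa: pd.DataFrame
    tree: object
    sites: pd.DataFrame
    ndvi_long: pd.DataFrame
    records: pd.DataFrame
    points: pd.DataFrame
    habitat: pd.DataFrame
    truth: TrueModel


# ---------------------------------------------------------------------------


def generate_world(config: GeneratorConfig, rng=None):
    """Taxa pool with groups, traits and a ranked taxonomic hierarchy.

    Each taxon gets a group (multinomial on ``group_shares``), a specialist
    flag (birds/mammals only), a true range width (degrees, log-normal) and
    a class/order/family/genus path; returns the taxa table and the
    Grafen-scaled taxonomy tree.
    """
    config.validate()
    rng = rng or config.rngs()["world"]
    n = config.taxa_pool_size
    groups = rng.choice(GROUPS, size=n, p=config.group_shares)
    taxa_rows, hierarchies = [], {}
    counters = {g: 0 for g in GROUPS}
    for i in range(n):
        g = groups[i]
        counters[g] += 1
        tid = f"t{i:05d}"
        order = f"{g}_ord{rng.integers(max(2, n // 80))}"
        family = f"{order}_fam{rng.integers(3)}"
        genus = f"{family}_gen{rng.integers(3)}"
        hierarchies[tid] = (g, order, family, genus)
        spec = "unknown"
        if g in ("mammals", "birds"):
            spec = (
                "specialist" if rng.random() < config.specialist_prob else "generalist"
            )
        taxa_rows.append(
            {
                "taxon_id": tid,
                "group": g,
                "specialist_true": spec,
                "range_width_deg": float(np.exp(rng.normal(0.5, 1.0))),
                "hierarchy": "/".join(hierarchies[tid]),
            }
        )
    taxa = pd.DataFrame(taxa_rows)
    tree = grafen_lengths(build_tree(hierarchies))
    return taxa, tree


def _latent_ndvi(params: NDVIParams, offtake: float, dates: np.ndarray,
                 dip_starts: np.ndarray) -> np.ndarray:
    """Noise- and contamination-free canopy signal at the composite dates."""
    doy = (dates - dates.astype("datetime64[Y]")).astype(int).astype(float)
    t = (dates - dates[0]).astype(int).astype(float)
    v = params.baseline + params.amplitude * np.sin(2 * np.pi * doy / 365.25)
    for start in dip_starts:
        # triangular harvest dip, 48-day half-width
        v -= params.offtake_depth * offtake * np.maximum(
            0.0, 1.0 - np.abs(t - start) / 48.0
        )
    return v


def generate_studies(config: GeneratorConfig, taxa: pd.DataFrame, rng=None):
    """Site network plus per-site NDVI composite series.

    Studies are spatial clusters (centre within +/-40 degrees latitude,
    normal jitter per site); each study samples one taxonomic group and one
    measure type.  Site land use is multinomial; forest cover (percent) and
    human population density (persons/km^2, log-normal) are drawn with
    land-use-dependent means; the latent offtake level sets the depth of
    harvest dips in the NDVI series and thereby the site's true iNDVI.

    Returns (sites, ndvi_long, true_indvi dict).
    """
    config.validate()
    rng = rng or config.rngs()["studies"]
    site_rows, ndvi_rows = [], []
    true_indvi = {}
    for s in range(config.n_studies):
        study_id = f"s{s:03d}"
        group = rng.choice(GROUPS, p=config.group_shares)
        measure = rng.choice(MEASURE_TYPES, p=config.measure_probs)
        centre_lon = rng.uniform(-180, 180)
        centre_lat = rng.uniform(-40, 40)
        n_sites = int(rng.integers(config.sites_per_study[0],
                                   config.sites_per_study[1] + 1))
        year = int(rng.integers(2001, 2013))
        for j in range(n_sites):
            site_id = f"{study_id}_p{j:03d}"
            lu = rng.choice(LAND_USES, p=config.land_use_probs)
            lon = centre_lon + rng.normal(0, config.site_jitter_deg)
            lat = float(np.clip(centre_lat + rng.normal(0, config.site_jitter_deg),
                                -40, 40))
            fc = float(np.clip(rng.normal(_FOREST_COVER_MEAN[lu], 10.0), 0, 100))
            hpd = float(rng.lognormal(_LOG_HPD_MEAN[lu], 1.0))
            offtake = float(np.clip(rng.normal(_OFFTAKE_MEAN[lu], 0.08), 0, 1))
            effort = float(rng.uniform(*config.effort_range))
            end = np.datetime64(window_for_study(year), "D")
            start = end - np.timedelta64(3 * 366 + 16, "D")
            dates = np.arange(start, end + np.timedelta64(17, "D"),
                              np.timedelta64(16, "D"))
            t = (dates - dates[0]).astype(int).astype(float)
            n_dips = config.ndvi.dips_per_year * 3
            dip_starts = rng.uniform(0, t[-1], size=n_dips)
            latent = _latent_ndvi(config.ndvi, offtake, dates, dip_starts)
            true_indvi[site_id] = compute_indvi(
                NDVISeries(site_id, dates, latent), window_for_study(year)
            )
            observed = latent + rng.normal(0, config.ndvi.noise_sd, len(dates))
            qa = (rng.random(len(dates)) < config.ndvi.flagged_cloud_prob).astype(int)
            observed = np.where(
                qa != 0, observed - config.ndvi.spike_depth * rng.random(len(dates)),
                observed,
            )
            unflagged = (qa == 0) & (
                rng.random(len(dates)) < config.ndvi.unflagged_cloud_prob
            )
            observed = np.where(unflagged, observed - config.ndvi.spike_depth, observed)
            observed = np.clip(observed, -1.0, 1.0)
            site_rows.append(
                {
                    "study_id": study_id, "site_id": site_id,
                    "lon": lon, "lat": lat, "land_use": lu,
                    "sample_year_first": year, "sample_year_last": year,
                    "forest_cover": fc, "hpd": hpd, "effort": effort,
                    "group": group, "measure_type": measure,
                }
            )
            for d, v, q in zip(dates, observed, qa):
                ndvi_rows.append(
                    {"site_id": site_id, "date": str(d), "ndvi": float(v),
                     "qa": int(q)}
                )
    sites = pd.DataFrame(site_rows)
    ndvi_long = pd.DataFrame(ndvi_rows)
    return sites, ndvi_long, true_indvi


def generate_observations(
    config: GeneratorConfig,
    taxa: pd.DataFrame,
    sites: pd.DataFrame,
    true_indvi: dict,
    tree=None,
    rng=None,
):
    """Abundance records under the two-stage generative model.

    Each study samples a subset of its group's taxa pool; every sampled
    taxon gets one record at every site of the study.  Presence is
    Bernoulli on the logit scale; abundance given presence is log-normal;
    recorded value = abundance x effort for effort-sensitive measure types,
    abundance as-is otherwise; absent records have value 0.  Taxon random
    effects are drawn on the taxonomy tree with a Pagel transform at
    ``lambda_true``.  When ``occ_intercept`` is None it is calibrated so the
    realised expected presence fraction equals ``target_presence``.
    """
    config.validate()
    rng = rng or config.rngs()["observations"]
    if tree is None:
        tree = grafen_lengths(build_tree(
            {r.taxon_id: tuple(r.hierarchy.split("/")) for r in taxa.itertuples()}
        ))
    labels, V = tree_covariance(tree)
    b_tax_occ = dict(zip(labels, simulate_trait(
        V, config.lambda_true, config.sd_taxon_occ, rng)))
    b_tax_ab = dict(zip(labels, simulate_trait(
        V, config.lambda_true, config.sd_taxon_ab, rng)))
    b_st_occ = {s: rng.normal(0, config.sd_study_occ)
                for s in sites["study_id"].unique()}
    b_st_ab = {s: rng.normal(0, config.sd_study_ab)
               for s in sites["study_id"].unique()}
    b_si_occ = {s: rng.normal(0, config.sd_site_occ) for s in sites["site_id"]}
    b_si_ab = {s: rng.normal(0, config.sd_site_ab) for s in sites["site_id"]}

    # pressures on the model scale (log1p for HPD), standardised across sites
    scaling = {}
    zvals = {}
    for var in ("hpd", "forest_cover", "indvi"):
        raw = (
            np.array([true_indvi[s] for s in sites["site_id"]])
            if var == "indvi" else sites[var].to_numpy(float)
        )
        x = np.log1p(raw) if var == "hpd" else raw
        sd = float(np.std(x)) or 1.0
        scaling[var] = (float(np.mean(x)), sd)
        zvals[var] = dict(zip(sites["site_id"], (x - np.mean(x)) / sd))

    rows = []
    for study_id, ssites in sites.groupby("study_id", sort=True):
        group = ssites["group"].iloc[0]
        measure = ssites["measure_type"].iloc[0]
        pool = taxa.loc[taxa["group"] == group, "taxon_id"].to_numpy()
        n_taxa = min(
            len(pool),
            int(rng.integers(config.taxa_per_study[0], config.taxa_per_study[1] + 1)),
        )
        if n_taxa == 0:
            continue
        chosen = rng.choice(pool, size=n_taxa, replace=False)
        for site in ssites.itertuples(index=False):
            for tid in chosen:
                rows.append((study_id, site.site_id, tid, group, site.land_use,
                             measure, site.effort))
    rec = pd.DataFrame(
        rows,
        columns=["study_id", "site_id", "taxon_id", "group", "land_use",
                 "measure_type", "effort"],
    )

    def eta_parts(coefs, slopes, b_st, b_si, b_tax):
        eta = np.zeros(len(rec))
        for i, r in enumerate(rec.itertuples(index=False)):
            eta[i] = coefs[(r.group, r.land_use)] + sum(
                slopes[(r.group, v)] * zvals[v][r.site_id]
                for v in ("hpd", "forest_cover", "indvi")
            ) + b_st[r.study_id] + b_si[r.site_id] + b_tax[r.taxon_id]
        return eta

    base_occ = eta_parts(config.true_occ_coefs, config.occ_slopes,
                         b_st_occ, b_si_occ, b_tax_occ)
    if config.occ_intercept is None:
        target = config.target_presence
        icpt = float(brentq(
            lambda c: expit(c + base_occ).mean() - target, -20.0, 20.0
        ))
    else:
        icpt = float(config.occ_intercept)
    eta_occ = icpt + base_occ
    eta_ab = config.abund_intercept + eta_parts(
        config.true_abund_coefs, config.abund_slopes, b_st_ab, b_si_ab, b_tax_ab
    )
    present = rng.random(len(rec)) < expit(eta_occ)
    abund = np.exp(eta_ab + rng.normal(0, config.sigma_resid, len(rec)))
    sensitive = rec["measure_type"].isin(EFFORT_SENSITIVE_MEASURES).to_numpy()
    value = np.where(
        present, abund * np.where(sensitive, rec["effort"].to_numpy(), 1.0), 0.0
    )
    records = rec[["study_id", "site_id", "taxon_id", "measure_type", "effort"]].copy()
    records["value"] = value
    truth = TrueModel(
        occ_intercept=icpt,
        abund_intercept=config.abund_intercept,
        occ_coefs=dict(config.true_occ_coefs),
        abund_coefs=dict(config.true_abund_coefs),
        occ_slopes=dict(config.occ_slopes),
        abund_slopes=dict(config.abund_slopes),
        sd={
            "study_occ": config.sd_study_occ, "site_occ": config.sd_site_occ,
            "taxon_occ": config.sd_taxon_occ, "study_ab": config.sd_study_ab,
            "site_ab": config.sd_site_ab, "taxon_ab": config.sd_taxon_ab,
        },
        sigma_resid=config.sigma_resid,
        lambda_true=config.lambda_true,
        pressure_scaling=scaling,
        ranef_occ={"study": b_st_occ, "site": b_si_occ, "taxon": b_tax_occ},
        ranef_ab={"study": b_st_ab, "site": b_si_ab, "taxon": b_tax_ab},
        true_indvi=dict(true_indvi),
        eta_occ=eta_occ,
        eta_ab=eta_ab,
    )
    return records, truth


def generate_range_points(config: GeneratorConfig, taxa: pd.DataFrame, rng=None):
    """Occurrence points for range-size estimation plus the habitat table.

    Point clouds are normal around a taxon-specific centre with spread
    equal to the taxon's true range width, so wide-ranged taxa occupy more
    half-degree cells.  The habitat table encodes the specialist truth the
    way real trait sources would: forest importance classes for birds,
    habitat-layer breadth for mammals.
    """
    rng = rng or config.rngs()["points"]
    pt_rows, hab_rows = [], []
    for t in taxa.itertuples(index=False):
        centre_lon = rng.uniform(-170, 170)
        centre_lat = rng.uniform(-35, 35)
        n_pts = int(rng.integers(3, 8) + round(3 * t.range_width_deg))
        pt_lon = centre_lon + rng.normal(0, t.range_width_deg, n_pts)
        pt_lat = centre_lat + rng.normal(0, t.range_width_deg, n_pts)
        for lo, la in zip(pt_lon, pt_lat):
            pt_rows.append({"taxon_id": t.taxon_id, "lon": float(lo),
                            "lat": float(np.clip(la, -89.9, 89.9))})
        row = {"taxon_id": t.taxon_id}
        if t.group == "birds":
            row["forest_importance"] = (
                "major" if t.specialist_true == "specialist"
                else rng.choice(["suitable", "marginal"])
            )
        elif t.group == "mammals":
            row["habitat_breadth"] = (
                1 if t.specialist_true == "specialist" else int(rng.integers(2, 5))
            )
        hab_rows.append(row)
    return pd.DataFrame(pt_rows), pd.DataFrame(hab_rows)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Run all generator stages under the documented seed-splitting scheme."""
    rngs = config.rngs()
    taxa, tree = generate_world(config, rngs["world"])
    sites, ndvi_long, true_indvi = generate_studies(config, taxa, rngs["studies"])
    records, truth = generate_observations(
        config, taxa, sites, true_indvi, tree=tree, rng=rngs["observations"]
    )
    points, habitat = generate_range_points(config, taxa, rngs["points"])
    return SyntheticDataset(
        config=config, taxa=taxa, tree=tree, sites=sites, ndvi_long=ndvi_long,
        records=records, points=points, habitat=habitat, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write sites/records/taxa/ndvi_long/points/habitat CSVs plus truth.json."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.sites.to_csv(outdir / "sites.csv", index=False)
    ds.records.to_csv(outdir / "records.csv", index=False)
    ds.taxa.to_csv(outdir / "taxa.csv", index=False)
    ds.ndvi_long.to_csv(outdir / "ndvi_long.csv", index=False)
    ds.points.to_csv(outdir / "points.csv", index=False)
    ds.habitat.to_csv(outdir / "habitat.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth.to_jsonable(), fh, indent=1)
    ds.tree.write(path=str(outdir / "taxonomy.nwk"), schema="newick")
    with open(outdir / "config.json", "w") as fh:
        cfg = dataclasses.asdict(ds.config)
        cfg["true_occ_coefs"] = {"|".join(k): v for k, v in cfg["true_occ_coefs"].items()}
        cfg["true_abund_coefs"] = {
            "|".join(k): v for k, v in cfg["true_abund_coefs"].items()
        }
        cfg["occ_slopes"] = {"|".join(k): v for k, v in cfg["occ_slopes"].items()}
        cfg["abund_slopes"] = {"|".join(k): v for k, v in cfg["abund_slopes"].items()}
        json.dump(cfg, fh, indent=1)
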