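"""Two-stage (hurdle) occurrence-abundance models with stepwise selection.

Stage one models presence/absence with a binomial-logit GLMM; stage two
models natural-log abundance, given presence, with a Gaussian LMM.  Both
carry random intercepts for study, site-within-study and taxon, and a
shared fixed-effect vocabulary: land use crossed with taxonomic group, plus
three continuous pressures (human population density, forest cover, iNDVI),
their pairwise interactions, their interactions with group, and the
pair-by-group three-ways.

Backward stepwise selection removes terms by likelihood-ratio test while
respecting marginality (a main effect is never tested while an interaction
containing it is retained); model fit is summarised by marginal and
conditional R2 for mixed models; post-hoc scans ask whether trait
interactions (habitat specialisation, range size) improve the selected
model by AIC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .mixedlm import MixedFit, MixedModel, RandomFactor
from .prep import GROUPS, LAND_USES

logger = logging.getLogger(__name__)

__all__ = [
    "CONTINUOUS",
    "ModelSpec",
    "Design",
    "FittedModel",
    "TermTest",
    "R2Summary",
    "full_spec",
    "term_name",
    "build_design",
    "fit_occurrence",
    "fit_abundance",
    "fit_model",
    "lrt",
    "backward_select",
    "selection_table",
    "r2_glmm",
    "r2_from_components",
    "posthoc_trait_scan",
    "fit_cubic_submodel",
]

CONTINUOUS = ("hpd", "forest_cover", "indvi")
_VAR_ORDER = ("land_use", "group", "hpd", "forest_cover", "indvi")
_DISTRIBUTION_VARIANCE = {"binomial": np.pi**2 / 3.0, "gaussian": 0.0}


def term_name(term: frozenset) -> str:
    return ":".join(sorted(term, key=_VAR_ORDER.index))


def _canonical(terms) -> tuple:
    """Deterministic term order: by interaction order, then by name."""
    return tuple(
        sorted(
            (frozenset(t) for t in terms),
            key=lambda t: (len(t), term_name(t)),
        )
    )


@dataclass(frozen=True)
class ModelSpec:
    """Fixed- and random-effect structure of one hurdle stage.

    ``terms`` is a collection of variable sets; marginality is enforced:
    every term's proper non-empty subsets must be present.
    """

    response: str  # "occurrence" | "log_abundance"
    terms: tuple = ()
    random_intercepts: tuple = ("study", "site", "taxon")
    hpd_log: bool = True
    group_col: str = "group"

    def __post_init__(self):
        if self.response not in ("occurrence", "log_abundance"):
            raise ConfigurationError(f"unknown response {self.response!r}")
        object.__setattr__(self, "terms", _canonical(self.terms))
        terms = set(self.terms)
        for t in terms:
            for r in range(1, len(t)):
                for sub in itertools.combinations(sorted(t), r):
                    if frozenset(sub) not in terms:
                        raise ConfigurationError(
                            f"term {term_name(t)} violates marginality: "
                            f"{term_name(frozenset(sub))} missing"
                        )

    @property
    def link(self) -> str:
        return "logit" if self.response == "occurrence" else "identity"

    @property
    def family(self) -> str:
        return "binomial" if self.response == "occurrence" else "gaussian"

    def drop(self, term: frozenset) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def droppable(self) -> list:
        """Terms contained in no other retained term (testable now)."""
        return [
            t for t in self.terms
            if not any(t < other for other in self.terms)
        ]


def full_spec(
    response: str,
    continuous: tuple = CONTINUOUS,
    three_way: bool = True,
    **kw,
) -> ModelSpec:
    """The full candidate fixed-effect structure for one hurdle stage."""
    terms = [{"land_use"}, {"group"}, {"land_use", "group"}]
    terms += [{c} for c in continuous]
    pairs = list(itertools.combinations(continuous, 2))
    terms += [set(p) for p in pairs]
    terms += [{c, "group"} for c in continuous]
    if three_way:
        terms += [set(p) | {"group"} for p in pairs]
    return ModelSpec(response=response, terms=tuple(map(frozenset, terms)), **kw)


@dataclass
class Design:
    """A realised design: matrix, term layout and the transforms that built it.

    Keeps the categorical level sets and continuous centring/scaling so the
    same mapping can be applied to prediction data (unseen categorical
    levels are an error)."""

    spec: ModelSpec
    colnames: list
    term_cols: dict            # term -> list of column indices (intercept excl.)
    transforms: dict           # var -> (log1p: bool, mean, sd)
    cat_levels: dict           # var -> (levels tuple, baseline)
    dropped_columns: list
    X: np.ndarray = field(repr=False, default=None)
    factors: list = field(repr=False, default_factory=list)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for (possibly new) data under the stored mapping."""
        base = {}
        for var, (levels, baseline) in self.cat_levels.items():
            col = self.spec.group_col if var == "group" else var
            vals = data[col].astype(str)
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValidationError(f"unseen {var} levels: {sorted(unseen)}")
            base[var] = {
                lev: (vals == lev).to_numpy(float) for lev in levels if lev != baseline
            }
        for var, (use_log, mean, sd) in self.transforms.items():
            x = data[var].to_numpy(float)
            if use_log:
                x = np.log1p(x)
            base[var] = {var: (x - mean) / sd}
        X = np.ones((len(data), len(self.colnames)))
        for j, name in enumerate(self.colnames):
            if name == "(Intercept)":
                continue
            col = np.ones(len(data))
            for part in name.split(":"):
                if "[" in part:
                    var, lev = part[:-1].split("[")
                    col = col * base[var][lev]
                else:
                    col = col * base[part][part]
            X[:, j] = col
        return X


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Treatment-coded fixed design plus random-factor codes.

    Land use is coded against the primary-forest baseline and group against
    the first group of the standard ordering present in the data;
    continuous covariates (HPD optionally log(x+1)-transformed) are centred
    and scaled to unit SD.  Interaction columns that are identically zero
    (empty cells) are dropped and recorded.
    """
    needed = {v for t in spec.terms for v in t}
    cat_levels, transforms = {}, {}
    for var in needed & {"land_use", "group"}:
        col = spec.group_col if var == "group" else var
        observed = list(dict.fromkeys(data[col].astype(str)))
        if var == "land_use":
            unseen = set(observed) - set(LAND_USES)
            if unseen:
                raise ValidationError(f"unknown land_use classes: {sorted(unseen)}")
            levels = tuple(l for l in LAND_USES if l in observed)
            baseline = "primary_forest"
            if baseline not in levels:
                baseline = levels[0]
        else:
            order = [g for g in GROUPS if g in observed]
            order += [g for g in sorted(observed) if g not in order]
            levels, baseline = tuple(order), order[0]
        cat_levels[var] = (levels, baseline)
    for var in needed & set(CONTINUOUS):
        x = data[var].to_numpy(float)
        if spec.hpd_log and var == "hpd":
            x = np.log1p(x)
        sd = float(np.std(x))
        if sd == 0.0:
            raise ValidationError(f"covariate {var!r} has zero variance")
        transforms[var] = (bool(spec.hpd_log and var == "hpd"), float(np.mean(x)), sd)

    # per-variable contrast columns on the fitting data
    base = {}
    for var, (levels, baseline) in cat_levels.items():
        col = spec.group_col if var == "group" else var
        vals = data[col].astype(str)
        base[var] = {
            lev: ((vals == lev).to_numpy(float), f"{var}[{lev}]")
            for lev in levels
            if lev != baseline
        }
    for var, (use_log, mean, sd) in transforms.items():
        x = data[var].to_numpy(float)
        if use_log:
            x = np.log1p(x)
        base[var] = {var: ((x - mean) / sd, var)}

    colnames = ["(Intercept)"]
    columns = [np.ones(len(data))]
    term_cols, dropped = {}, []
    for term in spec.terms:
        idxs = []
        parts = sorted(term, key=_VAR_ORDER.index)
        for combo in itertools.product(*(base[v].items() for v in parts)):
            col = np.ones(len(data))
            names = []
            for _, (vec, nm) in combo:
                col = col * vec
                names.append(nm)
            name = ":".join(names)
            if not np.any(col):
                dropped.append(name)
                continue
            idxs.append(len(colnames))
            colnames.append(name)
            columns.append(col)
        term_cols[term] = idxs
    if dropped:
        logger.info("dropped %d empty-cell design columns: %s", len(dropped), dropped)
    X = np.column_stack(columns)

    factors = []
    for fac in spec.random_intercepts:
        if fac == "site":
            labels = (
                data["study_id"].astype(str) + "/" + data["site_id"].astype(str)
            )
        else:
            labels = data[f"{fac}_id" if not fac.endswith("_id") else fac].astype(str)
        factors.append(RandomFactor.from_labels(fac, labels.to_numpy()))
    return Design(
        spec=spec,
        colnames=colnames,
        term_cols=term_cols,
        transforms=transforms,
        cat_levels=cat_levels,
        dropped_columns=dropped,
        X=X,
        factors=factors,
    )


@dataclass
class FittedModel:
    """A fitted hurdle stage: spec, realised design and engine result."""

    spec: ModelSpec
    design: Design
    fit: MixedFit
    y: np.ndarray = field(repr=False, default=None)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=self.design.colnames)

    @property
    def se(self) -> pd.Series:
        return pd.Series(self.fit.se_beta, index=self.design.colnames)

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def n_obs(self) -> int:
        return self.fit.n_obs

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def var_components(self) -> dict:
        return self.fit.var_components

    def residuals(self) -> np.ndarray:
        return self.fit.deviance_residuals(self.y)

    def linear_predictor(
        self, data: pd.DataFrame, include_ranef: bool = False
    ) -> np.ndarray:
        """Linear predictor for new data under the stored design mapping.

        With ``include_ranef=True`` the estimated random intercepts (BLUPs)
        for study, site and taxon are added where the levels were seen in
        fitting; unseen levels contribute zero.
        """
        eta = self.design.matrix(data) @ self.fit.beta
        if not include_ranef:
            return eta
        for fac in self.design.factors:
            if fac.name == "site":
                labels = (
                    data["study_id"].astype(str) + "/" + data["site_id"].astype(str)
                )
            else:
                labels = data[f"{fac.name}_id"].astype(str)
            arr = self.fit.ranef[fac.name]
            lut = {lev: arr[i] for i, lev in enumerate(fac.levels)}
            eta = eta + np.array([lut.get(l, 0.0) for l in labels])
        return eta


@dataclass
class TermTest:
    """One likelihood-ratio test from the stepwise sequence."""

    term: str
    chisq: float
    df: int
    p: float


@dataclass
class R2Summary:
    marginal: float
    conditional: float


def _response_vector(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if spec.response == "occurrence":
        y = data["present"].to_numpy(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("occurrence response must be 0/1")
        return y
    if "log_abund" in data.columns:
        return data["log_abund"].to_numpy(float)
    vals = data["value"].to_numpy(float)
    if np.any(vals <= 0):
        raise ValidationError(
            f"{int((vals <= 0).sum())} non-positive values in abundance stage"
        )
    return np.log(vals)


def _glm_init(X: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Cheap fixed-effects-only start values (IRLS logistic / least squares)."""
    from scipy.special import expit

    if family == "gaussian":
        return np.linalg.lstsq(X, y, rcond=None)[0]
    beta = np.zeros(X.shape[1])
    for _ in range(12):
        eta = X @ beta
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / W
        A = X.T @ (W[:, None] * X) + 1e-6 * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ (W * z))
    return beta


def fit_model(
    data: pd.DataFrame, spec: ModelSpec, init_from: FittedModel | None = None, **kw
) -> FittedModel:
    """Fit one hurdle stage by (Laplace) maximum likelihood."""
    design = build_design(data, spec)
    y = _response_vector(data, spec)
    model = MixedModel(y, design.X, design.factors, family=spec.family)
    beta0 = theta0 = None
    if init_from is None and design.X.shape[1] > 1:
        beta0 = _glm_init(design.X, y, spec.family)
    elif init_from is not None:
        lookup = dict(zip(init_from.design.colnames, init_from.fit.beta))
        beta0 = np.array([lookup.get(c, 0.0) for c in design.colnames])
        theta0 = np.log(
            np.maximum(
                [init_from.fit.sigma[f.name] for f in design.factors], 1e-4
            )
        )
    fit = model.fit(beta0=beta0, theta0=theta0, **kw)
    if not fit.converged:
        logger.warning(
            "%s model (%d terms) flagged non-converged: %s",
            spec.response, len(spec.terms), fit.message,
        )
    return FittedModel(spec=spec, design=design, fit=fit, y=y)


def fit_occurrence(data: pd.DataFrame, spec: ModelSpec, **kw) -> FittedModel:
    """Binomial-logit GLMM for presence/absence (Laplace ML)."""
    if spec.response != "occurrence":
        raise ConfigurationError("spec response must be 'occurrence'")
    return fit_model(data, spec, **kw)


def fit_abundance(data: pd.DataFrame, spec: ModelSpec, **kw) -> FittedModel:
    """Gaussian LMM for natural-log abundance given presence (exact ML)."""
    if spec.response != "log_abundance":
        raise ConfigurationError("spec response must be 'log_abundance'")
    return fit_model(data, spec, **kw)


def lrt(full: FittedModel, reduced: FittedModel) -> TermTest:
    """Likelihood-ratio test of nested fixed-effect structures.

    chisq = 2 (logLik_full - logLik_reduced), df = parameter-count
    difference, p from the chi-square upper tail.
    """
    if not set(reduced.spec.terms) <= set(full.spec.terms):
        raise ValidationError("reduced spec is not nested in full spec")
    if reduced.n_obs != full.n_obs:
        raise ValidationError("LRT requires identical data in both fits")
    df = full.fit.n_params - reduced.fit.n_params
    dropped = set(full.spec.terms) - set(reduced.spec.terms)
    name = " + ".join(sorted(term_name(t) for t in dropped)) or "(none)"
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df < 1:
        return TermTest(term=name, chisq=stat, df=df, p=1.0)
    return TermTest(term=name, chisq=stat, df=df, p=float(chi2.sf(stat, df)))


def backward_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    _cache: dict | None = None,
) -> tuple[FittedModel, list]:
    """Backward stepwise elimination by marginality-respecting LRTs.

    At each round only currently-highest-order terms (contained in no other
    retained term) are tested; the least significant with p >= alpha is
    removed (ties broken toward the smaller chi-square per df).  The trace
    records, in order, the test of every candidate at the round it was
    examined, ending with the tests that retained the final terms.
    """
    cache = _cache if _cache is not None else {}

    def get_fit(terms, init=None):
        key = frozenset(terms)
        if key not in cache:
            cache[key] = fit_model(data, replace(spec, terms=tuple(terms)), init_from=init)
        return cache[key]

    current = get_fit(spec.terms)
    trace = []
    while True:
        tests = []
        for t in current.spec.droppable():
            reduced = get_fit(current.spec.drop(t).terms, init=current)
            test = lrt(current, reduced)
            tests.append((test, reduced))
        removable = [
            (test, red) for test, red in tests if test.p >= alpha and test.df >= 1
        ]
        if not removable:
            trace.extend(test for test, _ in tests)
            break
        test, reduced = max(
            removable, key=lambda tr: (tr[0].p, -tr[0].chisq / max(tr[0].df, 1))
        )
        trace.append(test)
        current = reduced
        if not current.spec.terms:
            break
    return current, trace


def selection_table(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> tuple[FittedModel, pd.DataFrame]:
    """Backward selection plus a term-by-term chi-square/p table.

    Interaction terms carry the test from the round they were dropped (or a
    drop-one test from the selected model if retained); main effects are
    tested after removing all interaction terms, in the mains-only model.
    """
    cache: dict = {}
    min_model, trace = backward_select(data, spec, alpha=alpha, _cache=cache)
    when_tested = {}
    for test in trace:
        when_tested.setdefault(test.term, test)
    rows = []
    retained = set(min_model.spec.terms)
    mains_spec = replace(spec, terms=tuple(t for t in spec.terms if len(t) == 1))
    mains_fit = None
    for term in spec.terms:
        name = term_name(term)
        if len(term) == 1:
            if mains_fit is None:
                mains_fit = fit_model(data, mains_spec)
            reduced = fit_model(data, mains_spec.drop(term))
            test = lrt(mains_fit, reduced)
            test = TermTest(term=name, chisq=test.chisq, df=test.df, p=test.p)
        else:
            test = when_tested.get(name)
            if test is None and term in retained:
                try:
                    reduced_terms = min_model.spec.drop(term).terms
                    reduced = fit_model(data, replace(spec, terms=reduced_terms))
                    test = lrt(min_model, reduced)
                except ConfigurationError:
                    test = None  # shielded by a retained higher-order term
        rows.append(
            {
                "term": name,
                "chisq": round(test.chisq, 6) if test else np.nan,
                "df": test.df if test else 0,
                "p": test.p if test else np.nan,
                "retained": term in retained,
            }
        )
    return min_model, pd.DataFrame(rows)


def r2_from_components(
    var_fixed: float,
    var_random: float,
    var_resid: float,
    family: str,
) -> R2Summary:
    """Marginal/conditional R2 for mixed models.

    marginal = var_f / (var_f + var_random + var_resid + var_d), where var_d
    is the distribution-specific variance (pi^2/3 for binomial-logit, 0 for
    Gaussian, whose residual variance enters var_resid); conditional adds
    the random-effect variance to the numerator.
    """
    var_d = _DISTRIBUTION_VARIANCE[family]
    denom = var_fixed + var_random + var_resid + var_d
    return R2Summary(
        marginal=var_fixed / denom,
        conditional=(var_fixed + var_random) / denom,
    )


def r2_glmm(fitted: FittedModel) -> R2Summary:
    """Marginal and conditional R2 of a fitted hurdle stage."""
    var_f = float(np.var(fitted.design.X @ fitted.fit.beta))
    var_random = float(sum(v**2 for v in fitted.fit.sigma.values()))
    var_resid = (
        fitted.fit.sigma_resid**2 if fitted.fit.sigma_resid is not None else 0.0
    )
    return r2_from_components(var_f, var_random, var_resid, fitted.spec.family)


def posthoc_trait_scan(
    data: pd.DataFrame,
    min_spec: ModelSpec,
    trait: str,
) -> pd.DataFrame:
    """AIC scan of trait interactions added to the selected model.

    For ``trait="specialist"`` the indicator is 1 for forest/habitat
    specialists (birds and mammals only; other groups, and unknowns, stay
    unsplit at 0).  For ``trait="range_class"`` it is 1 for narrow-ranged
    taxa.  Each term of the minimum adequate model is augmented with its
    interaction with the indicator and the change in AIC reported
    (negative = improvement).  Rank-deficient augmentations are flagged.
    """
    if trait == "specialist":
        ind = (data["specialist"] == "specialist").to_numpy(float)
    elif trait == "range_class":
        ind = (data["range_class"] == "narrow").to_numpy(float)
    else:
        raise ConfigurationError(f"unknown trait {trait!r}")
    if ind.std() == 0:
        raise ValidationError(f"trait {trait!r} does not vary in these data")
    base = fit_model(data, min_spec)
    rows = []
    for term in min_spec.terms:
        cols = [0] + base.design.term_cols[term]  # intercept-level + term columns
        added = base.design.X[:, cols] * ind[:, None]
        keep = np.any(added != 0.0, axis=0)
        added = added[:, keep]
        X_aug = np.column_stack([base.design.X, added])
        model = MixedModel(base.y, X_aug, base.design.factors, family=min_spec.family)
        beta0 = np.concatenate([base.fit.beta, np.zeros(added.shape[1])])
        theta0 = np.log(np.maximum(list(base.fit.sigma.values()), 1e-4))
        fit = model.fit(beta0=beta0, theta0=theta0)
        rank_full = np.linalg.matrix_rank(X_aug)
        redundant = rank_full < base.design.X.shape[1] + added.shape[1]
        rows.append(
            {
                "term": term_name(term),
                "delta_aic": fit.aic - base.fit.aic,
                "added_df": added.shape[1],
                "redundant": bool(redundant),
            }
        )
        if redundant:
            logger.warning(
                "trait augmentation of %s is rank deficient", term_name(term)
            )
    return pd.DataFrame(rows)


@dataclass
class CubicFit:
    """Occurrence GLMM with an orthogonal cubic polynomial of one covariate."""

    fit: MixedFit
    covariate: str
    x_ref: np.ndarray = field(repr=False, default=None)
    basis_r: np.ndarray = field(repr=False, default=None)
    x_mean: float = 0.0
    x_sd: float = 1.0
    use_log: bool = True

    def linear_predictor(self, x_raw: np.ndarray) -> np.ndarray:
        x = np.log1p(x_raw) if self.use_log else np.asarray(x_raw, float)
        z = (x - self.x_mean) / self.x_sd
        P = np.column_stack([np.ones_like(z), z, z**2, z**3])
        basis = np.linalg.solve(self.basis_r.T, P.T).T * np.sqrt(len(self.x_ref))
        return basis @ self.fit.beta


def fit_cubic_submodel(
    data: pd.DataFrame,
    covariate: str = "hpd",
    use_log: bool = True,
    random_intercepts: tuple = ("study", "site", "taxon"),
) -> CubicFit:
    """Single-group occurrence model with a cubic polynomial response shape.

    Used for groups whose occurrence-density relationship may be
    non-monotonic (e.g. reptiles vs amphibians along the human population
    density gradient).  The polynomial basis is orthonormalised for
    numerical stability.
    """
    x_raw = data[covariate].to_numpy(float)
    x = np.log1p(x_raw) if use_log else x_raw
    if len(np.unique(x)) < 4:
        raise InsufficientDataError(
            f"cubic polynomial in {covariate!r} needs >= 4 distinct values"
        )
    mean, sd = float(np.mean(x)), float(np.std(x))
    z = (x - mean) / sd
    P = np.column_stack([np.ones_like(z), z, z**2, z**3])
    Q, R = np.linalg.qr(P)
    X = Q * np.sqrt(len(z))  # orthonormal columns scaled to unit variance
    y = data["present"].to_numpy(float)
    factors = []
    for fac in random_intercepts:
        if fac == "site":
            labels = data["study_id"].astype(str) + "/" + data["site_id"].astype(str)
        else:
            labels = data[f"{fac}_id"].astype(str)
        lab = labels.to_numpy()
        if len(np.unique(lab)) >= 2:
            factors.append(RandomFactor.from_labels(fac, lab))
    model = MixedModel(y, X, factors, family="binomial")
    fit = model.fit()
    return CubicFit(
        fit=fit, covariate=covariate, x_ref=x, basis_r=R,
        x_mean=mean, x_sd=sd, use_log=use_log,
    )
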