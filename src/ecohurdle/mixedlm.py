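"""Mixed-effects engine: crossed random intercepts by Laplace-approximate ML.

Fits two families used by the hurdle analysis:

* Bernoulli responses with a logit link (occurrence models).  The marginal
  likelihood integrates the random intercepts out of the joint density; the
  integral is approximated by Laplace's method around the joint mode of the
  random effects, the same approximation used by mainstream mixed-model
  software for this model class.
* Gaussian responses with an identity link (log-abundance models), for which
  the same expressions are the exact marginal likelihood.

Random structure: any number of crossed random-intercept factors, each with
its own variance.  Estimation is maximum likelihood (never REML) so that
likelihood-ratio tests and AICs are comparable across fixed-effect
structures.

The Laplace objective and its exact gradient
--------------------------------------------
With linear predictor eta = X beta + Z b, b ~ N(0, D), D block-diagonal with
sigma_k^2 per factor, and b-hat the maximiser of the penalised log-likelihood
f(b) = l(eta) - b' D^-1 b / 2, the approximate marginal log-likelihood is

    logL = l(eta-hat) - b-hat' D^-1 b-hat / 2 - log det(D H) / 2,

where H = Z' W Z + D^-1 and W = -diag(d^2 l / d eta^2).  The gradient with
respect to beta and log sigma_k is computed analytically, including the
terms that flow through W and b-hat (third derivatives of l); for the
Gaussian family those terms vanish and the gradient is exact.  Gradient
correctness is property-tested against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit

from .errors import ValidationError

__all__ = ["RandomFactor", "MixedFit", "MixedModel"]

_LOG2PI = float(np.log(2.0 * np.pi))
_THETA_LO, _THETA_HI = -10.0, 6.0  # bounds on log(sigma); lower bound ~ sigma 0


@dataclass
class RandomFactor:
    """A random-intercept grouping factor given by integer level codes."""

    name: str
    codes: np.ndarray
    n_levels: int
    levels: np.ndarray | None = None  # label per code, when built from labels

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomFactor":
        uniques, codes = np.unique(np.asarray(labels), return_inverse=True)
        return cls(
            name=name,
            codes=codes.astype(np.int64),
            n_levels=len(uniques),
            levels=uniques,
        )


@dataclass
class MixedFit:
    """Result of a mixed-model fit.

    Variance components are reported as standard deviations in ``sigma``
    (per random factor) and ``sigma_resid`` (Gaussian only).  ``vcov_beta``
    is the fixed-effect covariance conditional on the estimated variance
    components, the conventional Wald covariance for this model class.
    """

    family: str
    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    sigma: dict
    sigma_resid: float | None
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    message: str
    eta: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    ranef: dict = field(repr=False, default_factory=dict)
    n_iter: int = 0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def var_components(self) -> dict:
        out = {k: v**2 for k, v in self.sigma.items()}
        if self.sigma_resid is not None:
            out["residual"] = self.sigma_resid**2
        return out

    def deviance_residuals(self, y: np.ndarray) -> np.ndarray:
        """Record-level residuals: deviance residuals (Bernoulli) or
        response residuals (Gaussian), both conditional on the BLUPs."""
        if self.family == "gaussian":
            return y - self.eta
        mu = np.clip(self.mu, 1e-12, 1 - 1e-12)
        dev = -2.0 * (y * np.log(mu) + (1 - y) * np.log1p(-mu))
        return np.sign(y - mu) * np.sqrt(np.maximum(dev, 0.0))


class MixedModel:
    """Random-intercept mixed model for one response vector.

    Parameters
    ----------
    y : (n,) response; {0,1} for ``family="binomial"``.
    X : (n, p) dense fixed-effect design matrix (include the intercept).
    factors : list of RandomFactor, the crossed random-intercept structure.
    family : "binomial" (Bernoulli, logit link) or "gaussian".
    """

    def __init__(self, y, X, factors, family: str = "binomial"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValidationError("X must be (n, p) matching y")
        if family not in ("binomial", "gaussian"):
            raise ValidationError(f"unknown family {family!r}")
        if family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValidationError("binomial family requires a 0/1 response")
        self.family = family
        self.factors = list(factors)
        for f in self.factors:
            if f.codes.min() < 0 or f.codes.max() >= f.n_levels:
                raise ValidationError(f"factor {f.name}: codes out of range")
            if f.n_levels < 2:
                raise ValidationError(
                    f"factor {f.name}: needs >= 2 levels, got {f.n_levels}"
                )
        self.n, self.p = self.X.shape
        self.offsets = np.cumsum([0] + [f.n_levels for f in self.factors])
        self.q = int(self.offsets[-1])
        self._build_structure()

    # -- structure ---------------------------------------------------------

    def _build_structure(self):
        n, q = self.n, self.q
        if not self.factors:
            self.Z = self.Zt = None
            self._flat_idx = np.zeros(0, dtype=np.int64)
            self._n_pairs = 0
            self._block = []
            self._pair_idx = []
            return
        cols = np.concatenate(
            [f.codes + off for f, off in zip(self.factors, self.offsets[:-1])]
        )
        rows = np.tile(np.arange(n), len(self.factors))
        data = np.ones(len(cols))
        self.Z = sp.csr_matrix((data, (rows, cols)), shape=(n, q))
        self.Zt = self.Z.T.tocsr()
        # Flattened q*q indices for accumulating Z' diag(w) Z by bincount:
        # one block of n entries per ordered factor pair.
        idx = [f.codes + off for f, off in zip(self.factors, self.offsets[:-1])]
        self._flat_idx = np.concatenate(
            [a.astype(np.int64) * q + b for a in idx for b in idx]
        )
        self._n_pairs = len(self.factors) ** 2
        self._block = [
            slice(int(self.offsets[i]), int(self.offsets[i + 1]))
            for i in range(len(self.factors))
        ]
        self._pair_idx = idx

    def _ZtWZ(self, w: np.ndarray) -> np.ndarray:
        flat = np.bincount(
            self._flat_idx, weights=np.tile(w, self._n_pairs), minlength=self.q**2
        )
        return flat.reshape(self.q, self.q)

    def _s_diag(self, Hinv: np.ndarray) -> np.ndarray:
        """Per-observation s_i = z_i' H^-1 z_i."""
        s = np.zeros(self.n)
        for a in self._pair_idx:
            for b in self._pair_idx:
                s += Hinv[a, b]
        return s

    # -- family ------------------------------------------------------------

    def _loglik_terms(self, eta, sigma2_eps=None):
        """Return (l, l', W, W') for the observation log-likelihood."""
        if self.family == "binomial":
            mu = expit(eta)
            l = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
            lp = self.y - mu
            W = np.clip(mu * (1.0 - mu), 1e-12, None)
            Wp = W * (1.0 - 2.0 * mu)
            return l, lp, W, Wp, mu
        r = self.y - eta
        l = float(
            -0.5 * self.n * (_LOG2PI + np.log(sigma2_eps))
            - 0.5 * np.dot(r, r) / sigma2_eps
        )
        lp = r / sigma2_eps
        W = np.full(self.n, 1.0 / sigma2_eps)
        return l, lp, W, np.zeros(self.n), eta

    # -- inner mode-finding -------------------------------------------------

    def _penalized(self, b, beta, dinv, sigma2_eps):
        eta = self.X @ beta + self.Z @ b
        l = self._loglik_terms(eta, sigma2_eps)[0]
        return l - 0.5 * float(np.sum(dinv * b * b))

    def _solve_b(self, beta, dinv, sigma2_eps, b0):
        """Newton maximisation of the penalised log-likelihood over b.

        For the Gaussian family a single solve is exact.  Returns
        (b_hat, cho_factor(H), eta, loglik pieces at the mode).
        """
        b = b0.copy()
        Xbeta = self.X @ beta
        if self.family == "gaussian":
            w = 1.0 / sigma2_eps
            H = self._ZtWZ(np.full(self.n, w))
            H[np.diag_indices_from(H)] += dinv
            ch = cho_factor(H, lower=True, check_finite=False)
            b = cho_solve(ch, self.Zt @ (self.y - Xbeta) * w, check_finite=False)
            eta = Xbeta + self.Z @ b
            return b, ch, eta
        f = self._penalized(b, beta, dinv, sigma2_eps)
        ch = None
        for _ in range(100):
            eta = Xbeta + self.Z @ b
            _, lp, W, _, _ = self._loglik_terms(eta)
            grad = self.Zt @ lp - dinv * b
            H = self._ZtWZ(W)
            H[np.diag_indices_from(H)] += dinv
            ch = cho_factor(H, lower=True, check_finite=False)
            if np.max(np.abs(grad)) < 1e-9 * (1.0 + abs(f)):
                break
            step = cho_solve(ch, grad, check_finite=False)
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                f_new = self._penalized(b_new, beta, dinv, sigma2_eps)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            if f_new < f - 1e-10:
                break
            b, f = b_new, f_new
        eta = Xbeta + self.Z @ b
        return b, ch, eta

    # -- Laplace objective and gradient --------------------------------------

    def _objective(self, params, state):
        p, K = self.p, len(self.factors)
        beta = params[:p]
        if K == 0:
            return self._objective_fixed_only(params, state)
        theta = params[p : p + K]
        sigma2 = np.exp(2.0 * theta)
        if self.family == "gaussian":
            sigma2_eps = float(np.exp(2.0 * params[p + K]))
        else:
            sigma2_eps = None
        dinv = np.concatenate(
            [np.full(f.n_levels, 1.0 / s2) for f, s2 in zip(self.factors, sigma2)]
        )
        b, ch, eta = self._solve_b(beta, dinv, sigma2_eps, state["b"])
        state["b"] = b
        l, lp, W, Wp, mu = self._loglik_terms(eta, sigma2_eps)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(ch[0]))))
        logdet_D = 2.0 * float(
            np.sum([f.n_levels * t for f, t in zip(self.factors, theta)])
        )
        pen = 0.5 * float(np.sum(dinv * b * b))
        loglik = l - pen - 0.5 * (logdet_D + logdet_H)

        Hinv = cho_solve(ch, np.eye(self.q), check_finite=False)
        s = self._s_diag(Hinv)
        c = s * Wp                                  # zero for gaussian
        u = self.Zt @ c
        a = Hinv @ u
        # d logL / d beta
        gb = self.X.T @ lp - 0.5 * self.X.T @ (c - W * (self.Z @ a))
        # d logL / d log sigma_k
        gt = np.zeros(K)
        hdiag = np.diag(Hinv)
        for k, blk in enumerate(self._block):
            bk = b[blk]
            gt[k] = (
                np.dot(bk, bk) + np.sum(hdiag[blk]) - np.dot(a[blk], bk)
            ) / sigma2[k] - self.factors[k].n_levels
        grad = np.concatenate([gb, gt])
        if self.family == "gaussian":
            rss = float(np.sum((self.y - eta) ** 2))
            g_eps = -self.n + (rss + float(np.sum(s))) / sigma2_eps
            grad = np.concatenate([grad, [g_eps]])
        state["last"] = dict(
            eta=eta, mu=mu, W=W, b=b, ch=ch, sigma2=sigma2, sigma2_eps=sigma2_eps
        )
        return -loglik, -grad

    def _objective_fixed_only(self, params, state):
        """No random factors: the exact GLM/OLS log-likelihood."""
        p = self.p
        beta = params[:p]
        sigma2_eps = float(np.exp(2.0 * params[p])) if self.family == "gaussian" else None
        eta = self.X @ beta
        l, lp, W, _, mu = self._loglik_terms(eta, sigma2_eps)
        grad = self.X.T @ lp
        if self.family == "gaussian":
            rss = float(np.sum((self.y - eta) ** 2))
            grad = np.concatenate([grad, [-self.n + rss / sigma2_eps]])
        state["last"] = dict(
            eta=eta, mu=mu, W=W, b=np.zeros(0), ch=None,
            sigma2=np.zeros(0), sigma2_eps=sigma2_eps,
        )
        return -l, -grad

    # -- public fit ----------------------------------------------------------

    def fit(
        self,
        beta0: np.ndarray | None = None,
        theta0: np.ndarray | None = None,
        maxiter: int = 500,
        gtol: float = 1e-6,
        ftol: float = 1e-10,
    ) -> MixedFit:
        p, K = self.p, len(self.factors)
        if beta0 is None:
            beta0 = np.zeros(p)
            col0 = self.X[:, 0]
            if np.allclose(col0, 1.0):
                if self.family == "binomial":
                    m = float(np.clip(self.y.mean(), 1e-3, 1 - 1e-3))
                    beta0[0] = np.log(m / (1 - m))
                else:
                    beta0[0] = float(self.y.mean())
        if theta0 is None:
            theta0 = np.full(K, np.log(0.5))
        x0 = np.concatenate([beta0, theta0])
        bounds = [(None, None)] * p + [(_THETA_LO, _THETA_HI)] * K
        if self.family == "gaussian":
            s0 = max(float(np.std(self.y)), 1e-3)
            x0 = np.concatenate([x0, [np.log(s0)]])
            bounds.append((_THETA_LO, _THETA_HI))
        state = {"b": np.zeros(self.q), "last": None}
        res = minimize(
            self._objective,
            x0,
            args=(state,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=maxiter, gtol=gtol, ftol=ftol, maxcor=25),
        )
        # refresh cached quantities at the solution
        neg_ll, neg_grad = self._objective(res.x, state)
        last = state["last"]
        beta = res.x[:p]
        sigma = {
            f.name: float(np.exp(res.x[p + k]))
            for k, f in enumerate(self.factors)
        }
        sigma_resid = (
            float(np.exp(res.x[p + K])) if self.family == "gaussian" else None
        )
        vcov = self._vcov_beta(last)
        n_params = p + K + (1 if self.family == "gaussian" else 0)
        grad_ok = np.max(np.abs(neg_grad[:p])) < 1e-2
        ranef = {
            f.name: last["b"][blk].copy()
            for f, blk in zip(self.factors, self._block)
        }
        return MixedFit(
            family=self.family,
            beta=beta,
            se_beta=np.sqrt(np.clip(np.diag(vcov), 0.0, None)),
            vcov_beta=vcov,
            sigma=sigma,
            sigma_resid=sigma_resid,
            loglik=-neg_ll,
            n_obs=self.n,
            n_params=n_params,
            converged=bool(res.success or grad_ok),
            message=str(res.message),
            eta=last["eta"],
            mu=last["mu"] if self.family == "binomial" else last["eta"],
            ranef=ranef,
            n_iter=int(res.nit),
        )

    def _vcov_beta(self, last) -> np.ndarray:
        """Fixed-effect covariance conditional on the variance components:
        inverse of X' W X - X' W Z H^-1 Z' W X."""
        W = last["W"]
        WX = W[:, None] * self.X
        A = self.X.T @ WX
        if last["ch"] is not None:
            ZtWX = self.Zt @ WX
            A = A - ZtWX.T @ cho_solve(last["ch"], ZtWX, check_finite=False)
        try:
            return np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(A)
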