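"""Hurdle-Beta spatial Bayesian regression for per-population gene diversity.

Gene diversity (H_S) over many populations is semi-continuous: a sizable
fraction of populations are (near-)monomorphic while the rest take values in
(0, 1).  The hurdle model factorizes the two regimes:

    z_i ~ Bernoulli(pi_i),          logit(pi_i) = alpha_z + X_i beta_z + u_z(s_i)
    y_i | z_i = 1 ~ Beta(mu_i phi, (1 - mu_i) phi),
                                    logit(mu_i) = alpha_y + X_i beta_y + u_y(s_i)

where z_i indicates H_S above a small threshold (default 0.009) and u_z, u_y
are independent zero-mean Gaussian processes with exponential covariance
sigma^2 exp(-d / range) absorbing residual spatial autocorrelation.

Inference is a latent-Gaussian scheme: for fixed hyperparameters
theta = (sigma, range[, phi]) the latent block x = (u, alpha, beta) is
integrated out by a Laplace approximation (inner Fisher-scoring Newton), and
the low-dimensional marginal posterior p(theta | y) is explored either by a
Gaussian approximation at its mode (default; fast and deterministic up to the
posterior-draw seed) or by an emcee ensemble sampler.  Posterior draws of the
latent block given each theta draw come from the Gaussian Laplace
conditional, yielding full joint draws from which coefficients, WAIC/LCPO
scores and prediction surfaces are computed.

Priors (weakly informative over standardized covariates): Normal(0, 5) on
intercepts and slopes, half-Normal(1) on the spatial SDs, Gamma(2, 0.1) on
the Beta precision phi, and LogNormal centered on a quarter of the domain
diameter for the spatial range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from scipy.special import polygamma, psi
from scipy.spatial.distance import cdist

from .raster import Raster

__all__ = [
    "HurdleBetaModel",
    "HurdleBetaResults",
    "ModelScore",
    "split_hurdle",
    "model_scores",
    "select_model",
    "predict_surface",
]


def split_hurdle(hs: np.ndarray, threshold: float = 0.009) -> tuple[np.ndarray, np.ndarray]:
    """Binary presence indicators and the positive subset of H_S values.

    ``z_i = 1`` iff ``hs_i > threshold`` (strict); the positive subset holds
    exactly the values with z = 1.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    hs = np.asarray(hs, dtype=float)
    z = (hs > threshold).astype(int)
    return z, hs[z == 1]


# ---------------------------------------------------------------------------
# Observation models (log-likelihood, gradient, Fisher weight in eta)
# ---------------------------------------------------------------------------

def _bernoulli_terms(eta: np.ndarray, z: np.ndarray):
    p = expit(eta)
    ll = z * eta - np.logaddexp(0.0, eta)
    grad = z - p
    w = np.clip(p * (1.0 - p), 1e-10, None)
    return ll, grad, w


def _beta_terms(eta: np.ndarray, y: np.ndarray, phi: float):
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
    dmu = mu * (1.0 - mu)
    t = psi(b) - psi(a) + np.log(y) - np.log1p(-y)
    grad = phi * t * dmu
    w = np.clip(phi**2 * dmu**2 * (polygamma(1, a) + polygamma(1, b)), 1e-10, None)
    return ll, grad, w


# ---------------------------------------------------------------------------
# One hurdle component as a latent-Gaussian model
# ---------------------------------------------------------------------------

@dataclass
class _Part:
    """One component (Bernoulli or Beta) of the hurdle model."""

    kind: str                    # "bernoulli" | "beta"
    y: np.ndarray                # response (z indicators, or positive H_S)
    X: np.ndarray                # (n, p) standardized covariates
    coords: np.ndarray | None    # (n, 2) projected coordinates, None = no GP
    beta_prior_sd: float = 5.0
    sigma_prior_scale: float = 1.0
    range_prior_logloc: float = 0.0
    range_prior_logsd: float = 1.0
    phi_prior: tuple[float, float] = (2.0, 0.1)   # Gamma(shape, rate)

    def __post_init__(self) -> None:
        self.n, self.p = self.X.shape
        self.spatial = self.coords is not None
        self.d_latent = (self.n if self.spatial else 0) + 1 + self.p
        if self.spatial:
            self.dist = cdist(self.coords, self.coords)
        # hyperparameters on log scale
        self.theta_names: list[str] = []
        if self.spatial:
            self.theta_names += ["log_sigma", "log_range"]
        if self.kind == "beta":
            self.theta_names += ["log_phi"]
        self.n_theta = len(self.theta_names)
        self._mode_cache: np.ndarray | None = None
        self._A_cache: np.ndarray | None = None

    # -- pieces ------------------------------------------------------------

    def _design_eta(self, x: np.ndarray) -> np.ndarray:
        if self.spatial:
            return x[: self.n] + x[self.n] + self.X @ x[self.n + 1 :]
        return x[0] + self.X @ x[1:]

    def _A(self) -> np.ndarray:
        if self._A_cache is None:
            cols = []
            if self.spatial:
                cols.append(np.eye(self.n))
            cols.append(np.ones((self.n, 1)))
            cols.append(self.X)
            self._A_cache = np.hstack(cols)
        return self._A_cache

    def _prior_precision(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        """Latent prior precision Q and log det Q at hyperparameters theta."""
        fixed = np.full(1 + self.p, self.beta_prior_sd**-2)
        if not self.spatial:
            Q = np.diag(fixed)
            return Q, float(np.log(fixed).sum())
        sigma = np.exp(theta[0])
        rng = np.exp(theta[1])
        K = sigma**2 * np.exp(-self.dist / rng)
        jitter = 1e-8 * max(sigma**2, 1e-8)
        for _ in range(4):
            try:
                L = np.linalg.cholesky(K + jitter * np.eye(self.n))
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:
            raise np.linalg.LinAlgError("spatial kernel not positive definite after jitter")
        from scipy.linalg.lapack import dpotri

        inv_tri, info = dpotri(L, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("kernel inversion failed")
        Kinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        logdet_k = 2.0 * np.log(np.diag(L)).sum()
        Q = np.zeros((self.d_latent, self.d_latent))
        Q[: self.n, : self.n] = Kinv
        Q[self.n :, self.n :] = np.diag(fixed)
        return Q, float(-logdet_k + np.log(fixed).sum())

    def _obs_terms(self, eta: np.ndarray, theta: np.ndarray):
        if self.kind == "bernoulli":
            return _bernoulli_terms(eta, self.y)
        phi = np.exp(theta[-1])
        return _beta_terms(eta, self.y, phi)

    # -- inner Laplace ------------------------------------------------------

    def _mode(self, theta: np.ndarray, x0: np.ndarray | None = None, max_iter: int = 60):
        """Fisher-scoring Newton for the latent mode at fixed theta."""
        Q, logdet_q = self._prior_precision(theta)
        A = self._A()
        x = np.zeros(self.d_latent) if x0 is None else x0.copy()
        obj = -np.inf
        H = None
        for _ in range(max_iter):
            eta = self._design_eta(x)
            ll, grad, w = self._obs_terms(eta, theta)
            f = ll.sum() - 0.5 * x @ Q @ x
            g = A.T @ grad - Q @ x
            H = Q + (A.T * w) @ A
            step = np.linalg.solve(H, g)
            # backtracking line search on the penalized likelihood
            t = 1.0
            for _ in range(30):
                x_new = x + t * step
                ll_new, _, _ = self._obs_terms(self._design_eta(x_new), theta)
                f_new = ll_new.sum() - 0.5 * x_new @ Q @ x_new
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            x = x_new
            if abs(f_new - obj) < 1e-9 * (1.0 + abs(f_new)):
                obj = f_new
                break
            obj = f_new
        eta = self._design_eta(x)
        ll, _, w = self._obs_terms(eta, theta)
        H = Q + (self._A().T * w) @ self._A()
        return x, obj, H, logdet_q

    def log_marginal(self, theta: np.ndarray) -> float:
        """Laplace-approximate log p(y | theta)."""
        try:
            x, obj, H, logdet_q = self._mode(theta, self._mode_cache)
        except np.linalg.LinAlgError:
            return -np.inf
        self._mode_cache = x
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        return obj + 0.5 * logdet_q - 0.5 * logdet_h

    def log_prior_theta(self, theta: np.ndarray) -> float:
        lp = 0.0
        i = 0
        if self.spatial:
            sigma = np.exp(theta[0])
            lp += -0.5 * (sigma / self.sigma_prior_scale) ** 2 + theta[0]  # half-N + Jacobian
            lp += (
                -0.5 * ((theta[1] - self.range_prior_logloc) / self.range_prior_logsd) ** 2
            )
            i = 2
        if self.kind == "beta":
            shape, rate = self.phi_prior
            phi = np.exp(theta[i])
            lp += (shape - 1.0) * np.log(phi) - rate * phi + theta[i]
        return lp

    def log_posterior_theta(self, theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 30):
            return -np.inf
        lp = self.log_prior_theta(theta)
        if not np.isfinite(lp):
            return -np.inf
        return self.log_marginal(theta) + lp

    # -- hyperparameter posterior -------------------------------------------

    def _theta_init(self) -> np.ndarray:
        init = []
        if self.spatial:
            init += [np.log(0.5 * self.sigma_prior_scale), self.range_prior_logloc]
        if self.kind == "beta":
            init += [np.log(10.0)]
        return np.array(init)

    def _theta_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Mode and covariance of the hyperparameter posterior (Gaussian approx)."""
        from scipy.optimize import minimize

        if self.n_theta == 0:
            return np.zeros(0), np.zeros((0, 0))
        res = minimize(
            lambda t: -self.log_posterior_theta(t),
            self._theta_init(),
            method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 1e-3, "maxiter": 150 * self.n_theta},
        )
        theta_hat = np.atleast_1d(res.x)
        d = self.n_theta
        h = 5e-2  # well above inner-Laplace evaluation noise
        Hm = np.zeros((d, d))
        f0 = self.log_posterior_theta(theta_hat)
        for i in range(d):
            ei = np.zeros(d); ei[i] = h
            fpp = self.log_posterior_theta(theta_hat + ei)
            fmm = self.log_posterior_theta(theta_hat - ei)
            Hm[i, i] = (fpp - 2 * f0 + fmm) / h**2
            for j in range(i + 1, d):
                ej = np.zeros(d); ej[j] = h
                fij = self.log_posterior_theta(theta_hat + ei + ej)
                fi_j = self.log_posterior_theta(theta_hat + ei - ej)
                f_ij = self.log_posterior_theta(theta_hat - ei + ej)
                f__ = self.log_posterior_theta(theta_hat - ei - ej)
                Hm[i, j] = Hm[j, i] = (fij - fi_j - f_ij + f__) / (4 * h**2)
        prec = -Hm
        # flat or noisy directions fall back to prior-scale curvature
        evals, evecs = np.linalg.eigh(prec)
        evals = np.clip(evals, 0.5, None)
        cov = (evecs / evals) @ evecs.T
        return theta_hat, cov

    # -- sampling ------------------------------------------------------------

    def sample(
        self,
        draws: int,
        chains: int,
        rng: np.random.Generator,
        method: str = "laplace",
        warmup: int = 200,
    ) -> dict[str, np.ndarray]:
        """Joint posterior draws of (theta, latent block).

        ``laplace``: theta from the Gaussian approximation at the marginal
        posterior mode.  ``emcee``: theta from an ensemble sampler on the
        Laplace-marginal posterior (thinned to the requested draw count).
        In both cases the latent block is drawn from its Gaussian Laplace
        conditional at each sampled theta.
        """
        total = draws * chains
        if self.n_theta == 0:
            thetas = np.zeros((total, 0))
        elif method == "laplace":
            theta_hat, cov = self._theta_map()
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(self.n_theta))
            thetas = theta_hat + rng.standard_normal((total, self.n_theta)) @ L.T
        elif method == "emcee":
            import emcee

            theta_hat, cov = self._theta_map()
            nwalkers = max(2 * self.n_theta + 2, 8)
            p0 = theta_hat + 0.1 * rng.standard_normal((nwalkers, self.n_theta))
            sampler = emcee.EnsembleSampler(
                nwalkers, self.n_theta, self.log_posterior_theta
            )
            steps = warmup + int(np.ceil(total / nwalkers))
            sampler.run_mcmc(p0, steps, progress=False, skip_initial_state_check=True)
            thetas = sampler.get_chain(discard=warmup, flat=True)[:total]
        else:
            raise ValueError(f"unknown sampling method: {method!r}")

        xs = np.empty((total, self.d_latent))
        x_warm = self._mode_cache
        for s in range(total):
            x_hat, _, H, _ = self._mode(thetas[s], x_warm, max_iter=25)
            x_warm = x_hat
            Lh = np.linalg.cholesky(H)
            noise = np.linalg.solve(Lh.T, rng.standard_normal(self.d_latent))
            xs[s] = x_hat + noise
        out: dict[str, np.ndarray] = {}
        ofs = self.n if self.spatial else 0
        if self.spatial:
            out["u"] = xs[:, : self.n]
            out["sigma"] = np.exp(thetas[:, 0])
            out["range"] = np.exp(thetas[:, 1])
        out["alpha"] = xs[:, ofs]
        out["beta"] = xs[:, ofs + 1 :]
        if self.kind == "beta":
            out["phi"] = np.exp(thetas[:, -1])
        out["eta"] = np.array([self._design_eta(x) for x in xs])
        return out

    def pointwise_loglik(self, draws: dict[str, np.ndarray]) -> np.ndarray:
        eta = draws["eta"]
        total = eta.shape[0]
        ll = np.empty_like(eta)
        for s in range(total):
            theta_phi = (
                np.array([np.log(draws["phi"][s])]) if self.kind == "beta" else np.zeros(0)
            )
            ll[s] = self._obs_terms(eta[s], np.r_[np.zeros(2) if self.spatial else [], theta_phi])[0]
        return ll


# ---------------------------------------------------------------------------
# Public model / results
# ---------------------------------------------------------------------------

class HurdleBetaModel:
    """Two-part (hurdle) Beta regression with spatial Gaussian-process effects.

    Parameters
    ----------
    table : DataFrame
        One row per population with columns ``x``, ``y`` (projected
        coordinates, km), the diversity column, and the covariates.
    covariates : list of str
        Covariate columns, used in both components.
    diversity : str
        Column holding gene diversity, default ``"hs"``.
    threshold : float
        H_S cutoff separating the zero from the positive class.
    spatial : bool
        Include the Gaussian-process term in each component.
    standardize : bool
        Z-score covariates before fitting (recommended; priors assume it).
    allow_small_coords : bool
        Accept coordinates that fall inside the lon/lat range.  By default
        such input is rejected because the exponential kernel needs projected
        (km) coordinates, not degrees.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        covariates: list[str],
        diversity: str = "hs",
        threshold: float = 0.009,
        spatial: bool = True,
        standardize: bool = True,
        allow_small_coords: bool = False,
        beta_prior_sd: float = 5.0,
        sigma_prior_scale: float = 1.0,
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.covariates = list(covariates)
        self.threshold = float(threshold)
        self.spatial = bool(spatial)
        hs = self.table[diversity].to_numpy(dtype=float)
        if ((hs < 0) | (hs > 1)).any():
            raise ValueError("gene diversity must lie in [0, 1]")
        coords = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if spatial and not allow_small_coords:
            if (np.abs(coords[:, 0]) <= 180).all() and (np.abs(coords[:, 1]) <= 90).all():
                raise ValueError(
                    "coordinates look like lon/lat degrees; project to km first "
                    "(or pass allow_small_coords=True if they really are km)"
                )
        self.coords = coords
        self.z, positive = split_hurdle(hs, threshold)
        self.hs = hs
        self.positive_index = np.flatnonzero(self.z == 1)
        if self.positive_index.size == 0:
            raise ValueError("positive class is empty; nothing for the Beta component")
        X = self.table[self.covariates].to_numpy(dtype=float) if self.covariates else np.zeros((len(hs), 0))
        if standardize and X.shape[1]:
            mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
            if (sd == 0).any():
                raise ValueError("constant covariate cannot be standardized")
            X = (X - mean) / sd
            self.covariate_scale = (mean, sd)
        else:
            self.covariate_scale = (np.zeros(X.shape[1]), np.ones(X.shape[1]))
        self.X = X
        span = coords.max(axis=0) - coords.min(axis=0)
        diam = float(np.hypot(*span)) if spatial else 1.0
        self._range_logloc = np.log(max(diam / 4.0, 1e-6))
        self._priors = dict(
            beta_prior_sd=beta_prior_sd,
            sigma_prior_scale=sigma_prior_scale,
            range_prior_logloc=self._range_logloc,
        )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, covariates: list[str], **kw) -> "HurdleBetaModel":
        return cls(table, covariates, **kw)

    def _parts(self) -> tuple[_Part, _Part]:
        pos = self.positive_index
        part_z = _Part(
            "bernoulli", self.z.astype(float), self.X,
            self.coords if self.spatial else None, **self._priors,
        )
        part_y = _Part(
            "beta", self.hs[pos], self.X[pos],
            self.coords[pos] if self.spatial else None, **self._priors,
        )
        return part_z, part_y

    def fit(
        self,
        draws: int = 300,
        chains: int = 2,
        seed: int = 0,
        method: str = "laplace",
        warmup: int = 150,
    ) -> "HurdleBetaResults":
        rng = np.random.default_rng(seed)
        part_z, part_y = self._parts()
        dz = part_z.sample(draws, chains, rng, method, warmup)
        dy = part_y.sample(draws, chains, rng, method, warmup)
        ll_z = part_z.pointwise_loglik(dz)               # (S, n) all populations
        ll_y = part_y.pointwise_loglik(dy)               # (S, n_pos)
        ll = ll_z.copy()
        ll[:, self.positive_index] += ll_y
        res = HurdleBetaResults(
            model=self,
            draws_z=dz,
            draws_y=dy,
            loglik=ll,
            loglik_binary=ll_z,
            loglik_beta=ll_y,
            n_draws=draws,
            n_chains=chains,
            seed=seed,
            method=method,
        )
        bad = res.diagnostics().query("rhat > 1.05")
        if len(bad):
            res.warnings.append(f"possible non-convergence (rhat > 1.05): {list(bad.index)}")
            warnings.warn(res.warnings[-1], RuntimeWarning, stacklevel=2)
        return res


@dataclass
class HurdleBetaResults:
    """Posterior draws, diagnostics and scores for a fitted hurdle model."""

    model: HurdleBetaModel
    draws_z: dict[str, np.ndarray]
    draws_y: dict[str, np.ndarray]
    loglik: np.ndarray            # (S, n) hurdle pointwise log-likelihood
    loglik_binary: np.ndarray
    loglik_beta: np.ndarray
    n_draws: int
    n_chains: int
    seed: int
    method: str
    warnings: list[str] = field(default_factory=list)

    # -- parameter access ----------------------------------------------------

    def _scalar_draws(self) -> dict[str, np.ndarray]:
        covs = self.model.covariates
        out: dict[str, np.ndarray] = {"alpha_z": self.draws_z["alpha"]}
        for k, c in enumerate(covs):
            out[f"beta_z[{c}]"] = self.draws_z["beta"][:, k]
        out["alpha_y"] = self.draws_y["alpha"]
        for k, c in enumerate(covs):
            out[f"beta_y[{c}]"] = self.draws_y["beta"][:, k]
        out["phi"] = self.draws_y["phi"]
        if self.model.spatial:
            out["sigma_z"] = self.draws_z["sigma"]
            out["range_z"] = self.draws_z["range"]
            out["sigma_y"] = self.draws_y["sigma"]
            out["range_y"] = self.draws_y["range"]
        return out

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and effective sample size per scalar parameter."""
        import arviz as az

        rows = {}
        for name, d in self._scalar_draws().items():
            arr = d.reshape(self.n_chains, -1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows[name] = (float(az.rhat(arr)), float(az.ess(arr)))
        return pd.DataFrame(rows, index=["rhat", "ess"]).T

    def summary(self, orientation: str = "presence") -> pd.DataFrame:
        """Posterior summary table (mean, sd, 95% interval, diagnostics).

        ``orientation='presence'`` reports the binary component as modeling
        P(H_S above threshold); ``'absence'`` flips the signs of alpha_z and
        beta_z so the component reads as modeling P(H_S ~ 0).
        """
        if orientation not in ("presence", "absence"):
            raise ValueError("orientation must be 'presence' or 'absence'")
        diag = self.diagnostics()
        rows = []
        for name, d in self._scalar_draws().items():
            vals = d
            if orientation == "absence" and (name.startswith("beta_z") or name == "alpha_z"):
                vals = -d
            rows.append(
                {
                    "parameter": name,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "q2.5": float(np.quantile(vals, 0.025)),
                    "q97.5": float(np.quantile(vals, 0.975)),
                    "rhat": diag.at[name, "rhat"],
                    "ess": diag.at[name, "ess"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        d = self._scalar_draws()[name]
        a = (1.0 - prob) / 2.0
        return float(np.quantile(d, a)), float(np.quantile(d, 1 - a))


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass
class ModelScore:
    """WAIC (deviance scale), its effective parameters, lppd and mean log CPO."""

    waic: float
    p_waic: float
    lppd: float
    lcpo: float


def model_scores(fit: HurdleBetaResults | np.ndarray) -> ModelScore:
    """WAIC and LCPO from pointwise posterior log-likelihoods.

    lppd = sum_i log mean_s p(y_i | theta_s); p_WAIC = sum_i var_s log p;
    WAIC = -2 (lppd - p_WAIC).  CPO_i is the harmonic-mean estimator
    1 / mean_s (1 / p(y_i | theta_s)); LCPO is the mean of log CPO_i.
    """
    ll = fit.loglik if isinstance(fit, HurdleBetaResults) else np.asarray(fit, dtype=float)
    if not np.isfinite(ll).all():
        bad = np.argwhere(~np.isfinite(ll).all(axis=0)).ravel()
        raise ValueError(f"non-finite pointwise likelihood at observation(s) {bad.tolist()}")
    S = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - np.log(S)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    waic = -2.0 * (lppd - p_waic)
    log_cpo = -(logsumexp(-ll, axis=0) - np.log(S))
    lcpo = float(log_cpo.mean())
    return ModelScore(waic, p_waic, lppd, lcpo)


def select_model(
    table: pd.DataFrame,
    candidate_sets: list[list[str]],
    fit_kwargs: dict | None = None,
    **model_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], HurdleBetaResults]]:
    """Fit one hurdle model per covariate set and rank by WAIC (LCPO ties).

    Failures are recorded with the reason and excluded from the ranking.
    """
    if not candidate_sets:
        raise ValueError("need at least one candidate covariate set")
    fit_kwargs = fit_kwargs or {}
    rows = []
    fits: dict[tuple[str, ...], HurdleBetaResults] = {}
    for covs in candidate_sets:
        name = " + ".join(covs) if covs else "(intercept)"
        try:
            res = HurdleBetaModel(table, list(covs), **model_kwargs).fit(**fit_kwargs)
            sc = model_scores(res)
            fits[tuple(covs)] = res
            rows.append(
                {"model": name, "covariates": tuple(covs), "WAIC": sc.waic,
                 "p_WAIC": sc.p_waic, "LCPO": sc.lcpo, "error": ""}
            )
        except Exception as exc:  # noqa: BLE001
            rows.append(
                {"model": name, "covariates": tuple(covs), "WAIC": np.nan,
                 "p_WAIC": np.nan, "LCPO": np.nan, "error": str(exc)}
            )
    out = pd.DataFrame(rows).sort_values(
        ["WAIC", "LCPO"], ascending=[True, False], na_position="last"
    )
    return out.reset_index(drop=True), fits


# ---------------------------------------------------------------------------
# Prediction surfaces
# ---------------------------------------------------------------------------

def predict_surface(
    fit: HurdleBetaResults, covariate_rasters: dict[str, Raster]
) -> dict[str, Raster]:
    """Posterior mean and SD surfaces for pi (presence) and mu (diversity).

    Covariates are read per pixel from ``covariate_rasters`` (one raster per
    model covariate, identical grids) and standardized with the training
    scale; the spatial field is kriged to pixel centers at the posterior-mean
    hyperparameters, with independent conditional noise per pixel.  Pixels
    with NoData in any covariate are NoData in every output.
    """
    model = fit.model
    missing = [c for c in model.covariates if c not in covariate_rasters]
    if missing:
        raise ValueError(f"covariate raster(s) missing: {missing}")
    template = next(iter(covariate_rasters.values())) if covariate_rasters else None
    if template is None:
        raise ValueError("need at least one covariate raster as the prediction grid")
    shapes = {r.values.shape for r in covariate_rasters.values()}
    if len(shapes) > 1:
        raise ValueError("covariate rasters must share one grid")
    stack = np.stack([covariate_rasters[c].values for c in model.covariates], axis=-1)
    valid = ~np.isnan(stack).any(axis=-1)
    mean, sd = model.covariate_scale
    Xpix = (stack[valid] - mean) / sd
    # pixel centers
    rows, cols = np.nonzero(valid)
    xy = np.array([template.cell_center(r, c) for r, c in zip(rows, cols)])

    out = {}
    for label, dr, obs_coords in (
        ("p", fit.draws_z, model.coords),
        ("mu", fit.draws_y, model.coords[model.positive_index]),
    ):
        S = dr["alpha"].shape[0]
        eta = dr["alpha"][:, None] + dr["beta"] @ Xpix.T
        if model.spatial:
            sig = float(dr["sigma"].mean())
            rng_ = float(dr["range"].mean())
            K = sig**2 * np.exp(-cdist(obs_coords, obs_coords) / rng_)
            K += 1e-8 * sig**2 * np.eye(len(obs_coords))
            Kstar = sig**2 * np.exp(-cdist(obs_coords, xy) / rng_)
            W = np.linalg.solve(K, Kstar)               # kriging weights
            cond_var = np.clip(sig**2 - (Kstar * W).sum(axis=0), 0.0, None)
            rng = np.random.default_rng(fit.seed + 1)
            eta += dr["u"] @ W + np.sqrt(cond_var) * rng.standard_normal((S, len(xy)))
        p = expit(eta)
        for stat, arr in (("mean", p.mean(axis=0)), ("sd", p.std(axis=0, ddof=1))):
            grid = np.full(template.values.shape, np.nan)
            grid[valid] = arr
            out[f"{label}_{stat}"] = template.like(grid)
    return out
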