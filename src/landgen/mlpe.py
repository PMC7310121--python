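"""Maximum-likelihood population-effects (MLPE) regression for pairwise
distance matrices, with nested spatial-location groups (NMLPE).

Pairwise genetic-distance responses (here F_ST) are not independent: two pairs
sharing a population are correlated.  MLPE handles this with an additive
Gaussian random effect per population, so the response for pair p = (i, j) is

    fst_p = beta0 + x_p . beta + g_{loc(i)} + g_{loc(j)} + c_i + c_j + eps_p

with g ~ N(0, sigma_g^2) per spatial-location group, c ~ N(0, sigma_c^2) per
population nested in its location, eps ~ N(0, sigma_e^2).  Two pairs sharing
exactly one population then have residual correlation
rho = (sigma_g^2 + sigma_c^2) / (2 (sigma_g^2 + sigma_c^2) + sigma_e^2).
When every population forms its own location the two variance components are
not separately identifiable and the model collapses to classic MLPE
(sigma_g fixed at 0).

Fitting is by maximum likelihood (not REML) so AIC is comparable across fixed
-effect structures: the variance ratios are optimized on the log scale with
the residual variance and the GLS coefficients profiled out; all linear
algebra goes through the Woodbury identity on the low-rank random-effect
structure, so tables with tens of thousands of pairs stay cheap.
`dredge` enumerates all subsets of pairwise non-collinear predictors and
ranks them by AIC; `model_average` combines the Delta-AIC < 2 subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp

__all__ = [
    "assemble_pairwise",
    "standardize",
    "NMLPEModel",
    "NMLPEResults",
    "fit_nmlpe",
    "dredge",
    "model_average",
]


# ---------------------------------------------------------------------------
# Pairwise table assembly
# ---------------------------------------------------------------------------

def assemble_pairwise(
    fst: pd.DataFrame,
    distance_matrices: dict[str, pd.DataFrame],
    subset: list[str] | None = None,
    locations: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Long-format table over unordered population pairs.

    ``fst`` is a symmetric matrix (as produced by ``pairwise_fst(...).matrix``);
    ``distance_matrices`` maps predictor names to matrices over the same
    populations.  Rows whose response is NaN are dropped; the count of dropped
    pairs is returned alongside.  ``locations`` maps populations to
    spatial-location groups (default: each population its own location).
    """
    pops = subset if subset is not None else list(fst.index)
    if not pops:
        raise ValueError("empty population subset")
    for name, mat in distance_matrices.items():
        miss = [p for p in pops if p not in mat.index]
        if miss:
            raise ValueError(f"predictor {name!r} missing populations: {miss}")
    miss = [p for p in pops if p not in fst.index]
    if miss:
        raise ValueError(f"F_ST matrix missing populations: {miss}")
    loc = locations or {}
    rows = []
    dropped = 0
    for a, b in itertools.combinations(pops, 2):
        y = fst.at[a, b]
        if pd.isna(y):
            dropped += 1
            continue
        row = {
            "pop_i": a,
            "pop_j": b,
            "loc_i": loc.get(a, a),
            "loc_j": loc.get(b, b),
            "fst": float(y),
        }
        for name, mat in distance_matrices.items():
            row[name] = float(mat.at[a, b])
        rows.append(row)
    return pd.DataFrame(rows), dropped


def standardize(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Z-score predictor columns (response left untouched)."""
    out = table.copy()
    for name in predictors:
        v = out[name].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance predictor: {name!r}")
        out[name] = (v - v.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _incidence(labels_i: np.ndarray, labels_j: np.ndarray) -> tuple[sp.csr_matrix, list]:
    levels = list(dict.fromkeys(np.concatenate([labels_i, labels_j])))
    index = {l: k for k, l in enumerate(levels)}
    m = len(labels_i)
    rows = np.repeat(np.arange(m), 2)
    cols = np.array([[index[a], index[b]] for a, b in zip(labels_i, labels_j)]).ravel()
    Z = sp.coo_matrix((np.ones(2 * m), (rows, cols)), shape=(m, len(levels))).tocsr()
    return Z, levels


@dataclass
class _Profile:
    """Profiled quantities at fixed variance ratios gamma."""

    beta: np.ndarray
    sigma_e2: float
    llf: float
    xtwx_inv: np.ndarray


class NMLPEModel:
    """Nested maximum-likelihood population-effects regression.

    Parameters
    ----------
    table : DataFrame
        One row per unordered population pair with columns ``pop_i``,
        ``pop_j``, the response, the predictors, and optionally ``loc_i``/
        ``loc_j`` spatial-location groups.
    predictors : list of str
        Predictor columns entering the fixed-effect design (an intercept is
        always added).
    response : str
        Response column, default ``"fst"``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: list[str],
        response: str = "fst",
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.predictors = list(predictors)
        self.response = response
        self.y = self.table[response].to_numpy(dtype=float)
        m = len(self.y)
        if m < 3:
            raise ValueError("need at least 3 pairs")
        X = np.column_stack(
            [np.ones(m)] + [self.table[p].to_numpy(dtype=float) for p in self.predictors]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient fixed-effect design")
        self.X = X
        self.Zc, self.pop_levels = _incidence(
            self.table["pop_i"].to_numpy(object), self.table["pop_j"].to_numpy(object)
        )
        if len(self.pop_levels) < 4:
            raise ValueError("need at least 4 populations")
        has_loc = {"loc_i", "loc_j"}.issubset(self.table.columns)
        if has_loc:
            Zg, loc_levels = _incidence(
                self.table["loc_i"].to_numpy(object), self.table["loc_j"].to_numpy(object)
            )
            # unique location per population -> sigma_g not identifiable
            pop_loc = {}
            distinct = True
            for _, r in self.table.iterrows():
                for p, l in ((r["pop_i"], r["loc_i"]), (r["pop_j"], r["loc_j"])):
                    pop_loc.setdefault(p, l)
            if len(set(pop_loc.values())) == len(pop_loc):
                distinct = False
            self.has_location_effect = distinct
            self.Zg = Zg if distinct else None
        else:
            self.has_location_effect = False
            self.Zg = None

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, predictors: list[str], response: str = "fst"
    ) -> "NMLPEModel":
        return cls(table, predictors, response)

    # -- likelihood machinery ------------------------------------------------

    def _blocks(self):
        blocks = [self.Zc]
        if self.Zg is not None:
            blocks.append(self.Zg)
        return blocks

    def _profile(self, log_gamma: np.ndarray) -> _Profile:
        """Profile beta and sigma_e^2 at fixed variance ratios.

        With W = I + sum_k gamma_k Z_k Z_k', the ML solution at fixed gamma is
        the GLS beta, sigma_e^2 = r' W^-1 r / m, and the profiled log
        likelihood -m/2 (log 2 pi + log sigma_e^2 + 1) - 1/2 log|W|, computed
        via the Woodbury identity on U = [sqrt(gamma_k) Z_k].
        """
        gammas = np.exp(log_gamma)
        U = sp.hstack([np.sqrt(g) * Z for g, Z in zip(gammas, self._blocks())]).tocsr()
        m = len(self.y)
        q = U.shape[1]
        utu = (U.T @ U).toarray()
        M = np.eye(q) + utu                     # I + U'U
        cho = sla.cho_factor(M, lower=True)
        sign, logdet_m = np.linalg.slogdet(M)
        ut_y = U.T @ self.y
        ut_x = U.T @ self.X

        def winv_quad(A_ut, A, B_ut, B):
            # A' W^-1 B = A'B - (U'A)' M^-1 (U'B)
            return A.T @ B - A_ut.T @ sla.cho_solve(cho, B_ut)

        xtwx = winv_quad(ut_x, self.X, ut_x, self.X)
        xtwy = winv_quad(ut_x, self.X, ut_y[:, None], self.y[:, None]).ravel()
        xtwx_inv = np.linalg.inv(xtwx)
        beta = xtwx_inv @ xtwy
        r = self.y - self.X @ beta
        ut_r = ut_y - ut_x @ beta
        rss = float(r @ r - ut_r @ sla.cho_solve(cho, ut_r))
        sigma_e2 = max(rss / m, 1e-300)
        llf = -0.5 * (m * (np.log(2 * np.pi) + np.log(sigma_e2) + 1.0) + logdet_m)
        return _Profile(beta, sigma_e2, llf, xtwx_inv)

    def loglike(
        self,
        beta: np.ndarray,
        sigma_g2: float,
        sigma_c2: float,
        sigma_e2: float,
    ) -> float:
        """Marginal Gaussian log likelihood at explicit parameter values.

        Exposed so the structured solver can be checked against a dense
        multivariate-normal computation on small tables.
        """
        m = len(self.y)
        gam = [sigma_c2 / sigma_e2]
        if self.Zg is not None:
            gam.append(sigma_g2 / sigma_e2)
        U = sp.hstack(
            [np.sqrt(max(g, 0.0)) * Z for g, Z in zip(gam, self._blocks())]
        ).tocsr()
        q = U.shape[1]
        M = np.eye(q) + (U.T @ U).toarray()
        cho = sla.cho_factor(M, lower=True)
        _, logdet_m = np.linalg.slogdet(M)
        r = self.y - self.X @ np.asarray(beta, dtype=float)
        ut_r = U.T @ r
        quad = (r @ r - ut_r @ sla.cho_solve(cho, ut_r)) / sigma_e2
        return -0.5 * (m * np.log(2 * np.pi * sigma_e2) + logdet_m + quad)

    # -- fitting -------------------------------------------------------------

    def fit(self, n_starts: int = 4, tol: float = 1e-8) -> "NMLPEResults":
        """Maximize the marginal likelihood over the variance ratios.

        The variance ratios gamma_k = sigma_k^2 / sigma_e^2 are optimized on
        the log scale from several starting points (Nelder-Mead; the profiled
        objective is 1- or 2-dimensional and smooth).
        """
        n_gam = len(self._blocks())
        starts = [np.full(n_gam, v) for v in (-4.0, -1.0, 1.0, 3.0)][:n_starts]
        best = None
        trace = []
        for s in starts:
            res = opt.minimize(
                lambda lg: -self._profile(lg).llf,
                s,
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": tol, "maxiter": 4000},
            )
            trace.append((s.tolist(), float(-res.fun), bool(res.success)))
            if best is None or -res.fun > -best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"NMLPE optimizer failed; trace: {trace}")
        log_gamma = np.atleast_1d(best.x)
        prof = self._profile(log_gamma)
        gammas = np.exp(log_gamma)
        sigma_e2 = prof.sigma_e2
        sigma_c2 = float(gammas[0] * sigma_e2)
        sigma_g2 = float(gammas[1] * sigma_e2) if self.Zg is not None else 0.0
        cov_beta = prof.xtwx_inv * sigma_e2
        k = self.X.shape[1] + 1 + n_gam  # slopes+intercept, sigma_e, ratios
        names = ["intercept"] + self.predictors
        return NMLPEResults(
            model=self,
            params=pd.Series(prof.beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
            cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
            sigma_g2=sigma_g2,
            sigma_c2=sigma_c2,
            sigma_e2=float(sigma_e2),
            llf=float(prof.llf),
            aic=float(2 * k - 2 * prof.llf),
            df_model=k,
            n_pairs=len(self.y),
            converged=bool(best.success),
            optimizer_trace=trace,
        )


@dataclass
class NMLPEResults:
    """Fitted NMLPE model: estimates, uncertainties and fit statistics."""

    model: NMLPEModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma_g2: float
    sigma_c2: float
    sigma_e2: float
    llf: float
    aic: float
    df_model: int
    n_pairs: int
    converged: bool
    optimizer_trace: list = field(repr=False, default_factory=list)

    @property
    def rho(self) -> float:
        """Residual correlation between pairs sharing one population."""
        s = self.sigma_g2 + self.sigma_c2
        return s / (2.0 * s + self.sigma_e2)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "ci_lo": self.params - z * self.bse,
                "ci_hi": self.params + z * self.bse,
            }
        )

    def significant(self, alpha: float = 0.05) -> pd.Series:
        ci = self.conf_int(alpha)
        return (ci["ci_lo"] > 0) | (ci["ci_hi"] < 0)

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "ci_lo": ci["ci_lo"],
                "ci_hi": ci["ci_hi"],
                "significant": self.significant(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Nested maximum-likelihood population-effects model (ML)",
            f"  pairs: {self.n_pairs}   populations: {len(self.model.pop_levels)}",
            f"  logLik: {self.llf:.4f}   AIC: {self.aic:.4f}   k: {self.df_model}",
            f"  sigma_g^2: {self.sigma_g2:.6g}   sigma_c^2: {self.sigma_c2:.6g}"
            f"   sigma_e^2: {self.sigma_e2:.6g}   rho: {self.rho:.4f}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v: .5f}"),
        ]
        return "\n".join(lines)


def fit_nmlpe(
    table: pd.DataFrame, predictors: list[str], response: str = "fst"
) -> NMLPEResults:
    """Convenience wrapper: build an :class:`NMLPEModel` and fit it."""
    return NMLPEModel(table, predictors, response).fit()


# ---------------------------------------------------------------------------
# Model selection and averaging
# ---------------------------------------------------------------------------

def admissible_subsets(
    table: pd.DataFrame, predictors: list[str], r_max: float = 0.6
) -> list[tuple[str, ...]]:
    """All predictor subsets whose members are pairwise non-collinear.

    Two predictors are collinear when |Pearson r| >= ``r_max`` over the table
    rows; the empty (intercept-only) subset is always admissible.
    """
    corr = table[predictors].corr().abs()
    subsets: list[tuple[str, ...]] = []
    for r in range(len(predictors) + 1):
        for combo in itertools.combinations(predictors, r):
            ok = all(
                corr.at[a, b] < r_max for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                subsets.append(combo)
    return subsets


def dredge(
    table: pd.DataFrame,
    predictors: list[str],
    r_max: float = 0.6,
    response: str = "fst",
) -> tuple[pd.DataFrame, dict[tuple[str, ...], NMLPEResults]]:
    """All-subsets AIC selection over non-collinear predictor combinations.

    Returns the ranking table (model, AIC, dAIC, weight; ascending AIC) and
    the fitted results per subset.  Individual fit failures are recorded in
    the table with NaN scores and excluded from the ranking weights.
    """
    subsets = admissible_subsets(table, predictors, r_max)
    if not subsets:
        raise ValueError("no admissible predictor subset")
    fits: dict[tuple[str, ...], NMLPEResults] = {}
    rows = []
    for combo in subsets:
        name = " + ".join(combo) if combo else "(intercept)"
        try:
            res = fit_nmlpe(table, list(combo), response)
            fits[combo] = res
            rows.append({"model": name, "predictors": combo, "AIC": res.aic,
                         "logLik": res.llf, "error": ""})
        except Exception as exc:  # noqa: BLE001 - failure is data, not fatal
            rows.append({"model": name, "predictors": combo, "AIC": np.nan,
                         "logLik": np.nan, "error": str(exc)})
    rank = pd.DataFrame(rows)
    ok = rank["AIC"].notna()
    if not ok.any():
        raise RuntimeError("every candidate model failed to fit")
    best = rank.loc[ok, "AIC"].min()
    rank["dAIC"] = rank["AIC"] - best
    w = np.exp(-0.5 * rank.loc[ok, "dAIC"])
    rank.loc[ok, "weight"] = w / w.sum()
    rank = rank.sort_values("AIC", na_position="last").reset_index(drop=True)
    return rank, fits


def model_average(
    rank: pd.DataFrame,
    fits: dict[tuple[str, ...], NMLPEResults],
    delta_max: float = 2.0,
) -> pd.DataFrame:
    """Conditional (natural) model averaging over the Delta-AIC top set.

    For each predictor appearing in any model with dAIC < ``delta_max``, the
    weight-renormalized average coefficient over the top models containing it
    is reported, with the Buckland unconditional standard error
    sum_m w_m sqrt(se_m^2 + (beta_m - beta_bar)^2) and a 95%-CI significance
    flag.
    """
    top = rank[(rank["dAIC"] < delta_max) & rank["AIC"].notna()]
    if top.empty:
        raise ValueError("no model within delta_max of the best AIC")
    terms: dict[str, list[tuple[float, float, float]]] = {}
    for _, row in top.iterrows():
        res = fits[tuple(row["predictors"])]
        for term in row["predictors"]:
            terms.setdefault(term, []).append(
                (float(row["weight"]), float(res.params[term]), float(res.bse[term]))
            )
    out = []
    for term, triples in terms.items():
        w = np.array([t[0] for t in triples])
        b = np.array([t[1] for t in triples])
        s = np.array([t[2] for t in triples])
        w = w / w.sum()
        bbar = float(w @ b)
        se = float(w @ np.sqrt(s**2 + (b - bbar) ** 2))
        lo, hi = bbar - 1.96 * se, bbar + 1.96 * se
        out.append(
            {
                "term": term,
                "beta": bbar,
                "se": se,
                "ci_lo": lo,
                "ci_hi": hi,
                "significant": (lo > 0) or (hi < 0),
                "n_models": len(triples),
            }
        )
    return pd.DataFrame(out).set_index("term")
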