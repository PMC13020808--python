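"""Hierarchical zero-one-inflated beta regression.

``ZOIBModel`` fits trial-level shares in [0, 1] with a logit-linear model
for the beta mean, intercept-only inflation parts, and a participant
random intercept::

    y_ij ~ ZOIB(mu_ij, phi, zoi, coi)
    logit(mu_ij) = x_ij' beta + u_j,     u_j ~ Normal(0, sigma_u^2)

The random intercepts are integrated out with a per-group Laplace
approximation, so the working posterior is over the low-dimensional
vector (beta, log phi, logit zoi, logit coi, log sigma_u).  Two engines
share that marginal posterior:

``laplace`` (default)
    MAP via L-BFGS plus a Gaussian (Laplace) approximation at the mode;
    draws come from that Gaussian.  Seconds per fit.
``mcmc``
    Affine-invariant ensemble sampling (emcee) of the same posterior;
    R-hat is computed over walker groups treated as chains.

Weakly-informative priors (declared, fixed): Normal(0, 2.5) on fixed
effects, Normal(log 10, 1.5) on log phi, Normal(0, 2) on the inflation
logits, half-Normal(0, 1) on sigma_u.

Results expose posterior summaries, estimated marginal means and trends
(with pairwise contrasts as odds ratios / slope differences and 95% HPD
intervals), pointwise log-likelihoods, and PSIS-LOO model comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import patsy
from scipy import optimize
from scipy.special import digamma, gammaln

from .formula import parse_mixed_formula

__all__ = ["ZOIBModel", "ZOIBResults", "compare_models", "hpd_interval"]

_PRIOR_BETA_SD = 2.5
_PRIOR_LOGPHI_MEAN = np.log(10.0)
_PRIOR_LOGPHI_SD = 1.5
_PRIOR_INFL_SD = 2.0

#: preferred category orders so treatment coding uses the field's reference
#: levels (self-irrelevant, simple, both) without user intervention
REFERENCE_ORDERS = {
    "condition": ["OforO", "SforS", "SforO", "OforS"],
    "self_relevance": ["other", "self"],
    "source": ["other", "self"],
    "criterion": ["simple", "additive", "disjunctive"],
    "contribution_category": ["both", "player1_only", "player2_only"],
}


def _trigamma(x):
    """psi'(x) for x > 0: recurrence to x >= 8, then the asymptotic series.

    scipy's polygamma routes through Hurwitz zeta, which dominates the fit
    time; this vectorized version is ~100x faster at the same accuracy
    (~1e-12 relative) for the argument ranges the beta likelihood produces.
    """
    x = np.asarray(x, dtype=float).copy()
    out = np.zeros_like(x)
    for _ in range(8):
        small = x < 8.0
        if not small.any():
            break
        out[small] += 1.0 / (x[small] * x[small])
        x[small] += 1.0
    z = 1.0 / x
    z2 = z * z
    out += z * (1.0 + 0.5 * z + z2 * (1.0 / 6.0 - z2 * (1.0 / 30.0 - z2 * (1.0 / 42.0 - z2 / 30.0))))
    return out


def _logit(p):
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval holding ``prob`` of the draws (ties -> lower bound)."""
    x = np.sort(np.asarray(draws))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) on ties
    return float(x[i]), float(x[i + k])


@dataclass
class _Settings:
    engine: str = "laplace"
    n_draws: int = 4000
    seed: int = 0
    chains: int = 8
    iterations: int = 3000
    warmup: int = 1000
    maxiter: int = 500


class ZOIBModel:
    """Zero-one-inflated beta mixed model built from a formula and a table."""

    def __init__(self, y, X, groups, design_info, data, response_name, group_name,
                 response_transform="none"):
        y = np.asarray(y, float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("response must lie in [0, 1] (after any transform)")
        self.y = y
        self.X = np.asarray(X, float)
        self.design_info = design_info
        self.exog_names = list(design_info.column_names)
        self.data = data
        self.response_name = response_name
        self.group_name = group_name
        self.response_transform = response_transform
        codes, levels = pd.factorize(np.asarray(groups))
        if len(levels) < 2:
            raise ValueError("need at least 2 groups for a hierarchical fit")
        self.group_codes = codes
        self.group_levels = list(levels)
        self.n_groups = len(levels)

        self._interior = (y > 0) & (y < 1)
        self._n0 = int(np.sum(y == 0))
        self._n1 = int(np.sum(y == 1))
        yc = y[self._interior]
        self._logy = np.log(yc)
        self._log1my = np.log1p(-yc)
        self._logity = self._logy - self._log1my
        self._Xc = self.X[self._interior]
        self._gc = codes[self._interior]
        self._u_cache = np.zeros(self.n_groups)

        self.param_names = self.exog_names + ["log_phi", "logit_zoi", "logit_coi", "log_sigma_u"]
        self.n_params = len(self.param_names)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "ZOIBModel":
        """Build the model from a mixed formula with one ``(1|group)`` term.

        Known design columns (condition, criterion, contribution category,
        self-relevance) are ordered so that the self-irrelevant / simple /
        "both" levels are the treatment-coding references.  A response
        outside [0, 1] (the self-allocation bias, in [-1, 1]) is mapped
        through ``y -> (y + 1) / 2`` so the same family applies; the
        transform is recorded on the model.
        """
        pf = parse_mixed_formula(formula)
        if pf.group not in data.columns:
            raise ValueError(f"grouping column {pf.group!r} not in data")
        data = data.copy()
        for col, order in REFERENCE_ORDERS.items():
            if col in data.columns and not isinstance(data[col].dtype, pd.CategoricalDtype):
                present = [l for l in order if l in set(data[col].dropna())]
                extra = sorted(set(data[col].dropna()) - set(present))
                if present:
                    data[col] = pd.Categorical(data[col], categories=present + extra)
        transform = "none"
        if pf.response in data.columns:
            resp = pd.to_numeric(data[pf.response], errors="raise")
            if resp.min() < 0:
                if resp.min() < -1 or resp.max() > 1:
                    raise ValueError("response must lie in [0, 1] or [-1, 1]")
                data[pf.response] = (resp + 1.0) / 2.0
                transform = "shift_scale"
        ymat, X = patsy.dmatrices(pf.fixed, data, return_type="dataframe")
        idx = X.index  # patsy drops NA rows consistently
        return cls(
            ymat.values.ravel(),
            X.values,
            data.loc[idx, pf.group].values,
            X.design_info,
            data.loc[idx],
            pf.response,
            pf.group,
            response_transform=transform,
        )

    # -- likelihood machinery --------------------------------------------
    def _beta_terms(self, eta, phi, order=2):
        """Interior beta log-lik and its first/second eta-derivatives."""
        mu = _invlogit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (a - 1.0) * self._logy + (b - 1.0) * self._log1my \
            + gammaln(phi) - gammaln(a) - gammaln(b)
        if order == 0:
            return ll, None, None
        m = mu * (1.0 - mu)
        resid = self._logity - digamma(a) + digamma(b)
        d1 = phi * m * resid
        if order == 1:
            return ll, d1, None
        d2 = phi * (1.0 - 2.0 * mu) * m * resid \
            - (phi * m) ** 2 * (_trigamma(a) + _trigamma(b))
        return ll, d1, d2

    def _inner_modes(self, beta, phi, sigma, tol=1e-9, max_newton=40):
        """Per-group Laplace for the random intercepts (vectorized Newton)."""
        eta0 = self._Xc @ beta
        u = self._u_cache.copy()
        inv_s2 = 1.0 / max(sigma**2, 1e-12)
        for _ in range(max_newton):
            ll, d1, d2 = self._beta_terms(eta0 + u[self._gc], phi)
            g = np.bincount(self._gc, weights=d1, minlength=self.n_groups) - u * inv_s2
            h = np.bincount(self._gc, weights=d2, minlength=self.n_groups) - inv_s2
            h = np.minimum(h, -1e-8)
            step = np.clip(g / -h, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(step)) < tol:
                break
        ll, _, d2 = self._beta_terms(eta0 + u[self._gc], phi)
        H = np.bincount(self._gc, weights=d2, minlength=self.n_groups)
        self._u_cache = u
        return u, ll, H

    def marginal_logpost(self, theta: np.ndarray) -> float:
        """Log posterior with random intercepts integrated out by Laplace."""
        p = len(self.exog_names)
        beta = theta[:p]
        phi = np.exp(theta[p])
        zoi = _invlogit(theta[p + 1])
        coi = _invlogit(theta[p + 2])
        sigma = np.exp(theta[p + 3])
        if not np.all(np.isfinite(theta)) or phi > 1e6 or sigma > 1e3:
            return -np.inf
        u, ll, H = self._inner_modes(beta, phi, sigma)
        quad = np.sum(u**2) / (2.0 * sigma**2)
        # log det correction: prod_j (1 + sigma^2 * (-H_j)) ** -1/2
        corr = 0.5 * np.sum(np.log1p(np.maximum(sigma**2 * (-H), -0.999999)))
        n_c = len(self._logy)
        out = (
            np.sum(ll)
            - quad
            - corr
            + n_c * np.log1p(-zoi)
            + self._n0 * (np.log(zoi) + np.log1p(-coi))
            + self._n1 * (np.log(zoi) + np.log(coi))
        )
        # priors
        out -= np.sum(beta**2) / (2.0 * _PRIOR_BETA_SD**2)
        out -= (theta[p] - _PRIOR_LOGPHI_MEAN) ** 2 / (2.0 * _PRIOR_LOGPHI_SD**2)
        out -= (theta[p + 1] ** 2 + theta[p + 2] ** 2) / (2.0 * _PRIOR_INFL_SD**2)
        out += -0.5 * sigma**2 + np.log(sigma)  # half-Normal(0,1) + log-scale Jacobian
        if not np.isfinite(out):
            return -np.inf
        return float(out)

    def _start(self) -> np.ndarray:
        p = len(self.exog_names)
        theta = np.zeros(self.n_params)
        ybar = float(np.mean(self.y[self._interior])) if self._interior.any() else 0.5
        icpt = [i for i, n in enumerate(self.exog_names) if n == "Intercept"]
        if icpt:
            theta[icpt[0]] = _logit(np.clip(ybar, 0.01, 0.99))
        n = len(self.y)
        bfrac = (self._n0 + self._n1 + 0.5) / (n + 1.0)
        theta[p] = np.log(10.0)
        theta[p + 1] = _logit(np.clip(bfrac, 1e-4, 0.99))
        theta[p + 2] = _logit((self._n1 + 0.5) / (self._n0 + self._n1 + 1.0))
        theta[p + 3] = np.log(0.3)
        return theta

    # -- fitting ----------------------------------------------------------
    def fit(self, engine: str = "laplace", n_draws: int = 4000, seed: int = 0,
            chains: int = 8, iterations: int = 3000, warmup: int = 1000,
            maxiter: int = 500) -> "ZOIBResults":
        """Fit the model and return a :class:`ZOIBResults`.

        ``engine='laplace'`` (default) is MAP + Gaussian approximation;
        ``engine='mcmc'`` runs the ensemble sampler with ``iterations``
        post-warmup steps and reports split R-hat per parameter.
        """
        settings = _Settings(engine, n_draws, seed, chains, iterations, warmup, maxiter)
        theta0 = self._start()
        nll = lambda t: -self.marginal_logpost(t)
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "maxfun": 10 * maxiter * self.n_params})
        converged = bool(res.success)
        mode = res.x
        if engine == "laplace":
            cov = self._laplace_cov(mode)
            rng = np.random.default_rng(seed)
            L = np.linalg.cholesky(cov)
            draws = mode + rng.standard_normal((n_draws, self.n_params)) @ L.T
            rhat = None
        elif engine == "mcmc":
            draws, rhat, cov = self._run_mcmc(mode, settings)
            if rhat is not None and np.any(rhat > 1.05):
                converged = False
        else:
            raise ValueError("engine must be 'laplace' or 'mcmc'")
        if not converged:
            warnings.warn("fit did not converge cleanly; results are flagged", RuntimeWarning)
        return ZOIBResults(self, mode, cov, draws, converged, rhat, settings)

    def _laplace_cov(self, mode: np.ndarray) -> np.ndarray:
        d = self.n_params
        H = np.zeros((d, d))
        h = 1e-4 * np.maximum(1.0, np.abs(mode))
        f0 = self.marginal_logpost(mode)
        fp = np.zeros(d)
        fm = np.zeros(d)
        for i in range(d):
            e = np.zeros(d); e[i] = h[i]
            fp[i] = self.marginal_logpost(mode + e)
            fm[i] = self.marginal_logpost(mode - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = self.marginal_logpost(mode + ei + ej)
                fmm = self.marginal_logpost(mode - ei - ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                    2 * h[i] * h[j]
                )
        prec = -H
        w, V = np.linalg.eigh((prec + prec.T) / 2)
        w = np.maximum(w, 1e-8)
        return (V / w) @ V.T

    def _run_mcmc(self, mode: np.ndarray, s: _Settings):
        import emcee

        d = self.n_params
        nwalkers = max(2 * d + 2, s.chains)
        nwalkers += nwalkers % 2
        rng = np.random.default_rng(s.seed)
        cov0 = self._laplace_cov(mode)
        L = np.linalg.cholesky(cov0)
        p0 = mode + 0.5 * rng.standard_normal((nwalkers, d)) @ L.T
        np.random.seed(s.seed % (2**31))  # emcee moves draw from the global state
        sampler = emcee.EnsembleSampler(nwalkers, d, self.marginal_logpost)
        state = sampler.run_mcmc(p0, s.warmup, progress=False,
                                 skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, s.iterations, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain()  # (steps, walkers, d)
        import arviz as az

        # walker groups as pseudo-chains for the split-R-hat diagnostic
        arr = np.moveaxis(chain, 1, 0)  # (walkers, steps, d)
        rhat = np.array([float(az.rhat(arr[:, :, i])) for i in range(d)])
        flat = chain.reshape(-1, d)
        take = rng.choice(len(flat), size=min(s.n_draws, len(flat)), replace=False)
        draws = flat[take]
        cov = np.cov(flat.T)
        return draws, rhat, cov


def _require_numeric(model: ZOIBModel, name: str):
    infos = {f.name(): fi for f, fi in model.design_info.factor_infos.items()}
    if name not in infos:
        raise ValueError(f"covariate {name!r} is not in the model")
    if infos[name].type != "numerical":
        raise ValueError(f"covariate {name!r} is not numeric")


class ZOIBResults:
    """Posterior summaries and post-hoc machinery for a fitted ZOIB model."""

    def __init__(self, model, params, cov_params, draws, converged, rhat, settings):
        self.model = model
        self.params = pd.Series(params, index=model.param_names)
        self.cov_params = pd.DataFrame(cov_params, index=model.param_names,
                                       columns=model.param_names)
        self.draws = pd.DataFrame(draws, columns=model.param_names)
        self.converged = converged
        self.rhat = None if rhat is None else pd.Series(rhat, index=model.param_names)
        self.settings = settings
        p = len(model.exog_names)
        self._beta_draws = draws[:, :p]
        self._ll_cache: dict = {}

    # -- summaries --------------------------------------------------------
    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.params["log_sigma_u"]))

    @property
    def random_effects(self) -> pd.Series:
        """Conditional modes of the participant intercepts at the MAP."""
        m = self.model
        p = len(m.exog_names)
        u, _, _ = m._inner_modes(
            self.params.values[:p], np.exp(self.params["log_phi"]), self.sigma_u
        )
        return pd.Series(u, index=m.group_levels)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and HPD interval per parameter (natural scales
        appended for phi, zoi, coi, sigma_u)."""
        rows = []
        for name in self.model.param_names:
            d = self.draws[name].values
            lo, hi = hpd_interval(d, prob)
            rows.append({"term": name, "estimate": float(np.mean(d)),
                         "sd": float(np.std(d, ddof=1)), "lower": lo, "upper": hi,
                         "rhat": float(self.rhat[name]) if self.rhat is not None else np.nan})
        extra = {"phi": np.exp(self.draws["log_phi"]),
                 "zoi": _invlogit(self.draws["logit_zoi"]),
                 "coi": _invlogit(self.draws["logit_coi"]),
                 "sigma_u": np.exp(self.draws["log_sigma_u"])}
        for name, d in extra.items():
            d = d.values
            lo, hi = hpd_interval(d, prob)
            rows.append({"term": name, "estimate": float(np.mean(d)),
                         "sd": float(np.std(d, ddof=1)), "lower": lo, "upper": hi,
                         "rhat": np.nan})
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        s = self.summary()
        head = (f"<ZOIBResults: {self.model.response_name} ~ ..., "
                f"{len(self.model.y)} obs, {self.model.n_groups} groups, "
                f"engine={self.settings.engine}, converged={self.converged}>\n")
        return head + s.to_string(index=False, float_format=lambda v: f"{v:9.4f}")

    # -- reference grid ---------------------------------------------------
    def _grid(self, at: dict) -> pd.DataFrame:
        m = self.model
        infos = {f.name(): fi for f, fi in m.design_info.factor_infos.items()}
        cols, values = [], []
        for name, fi in infos.items():
            if fi.type == "categorical":
                if name in at:
                    levels = list(at[name])
                    bad = set(levels) - set(fi.categories)
                    if bad:
                        raise ValueError(f"level(s) {sorted(bad)} not found for factor {name!r}")
                else:
                    levels = list(fi.categories)
                cols.append(name)
                values.append(levels)
            else:
                ref = at.get(name, float(np.asarray(m.data[name], float).mean()))
                cols.append(name)
                values.append([ref])
        grid = pd.DataFrame(list(itertools.product(*values)), columns=cols)
        return grid

    def _eta_draws(self, grid: pd.DataFrame) -> np.ndarray:
        (Xg,) = patsy.build_design_matrices([self.model.design_info], grid)
        return np.asarray(Xg) @ self._beta_draws.T  # (G, S)

    def marginal_means(self, at: Union[Sequence[str], dict], prob: float = 0.95):
        """Estimated marginal means over the requested factor cells.

        ``at`` is a list of factor names (all observed levels) or a mapping
        ``{factor: levels}``.  Non-requested factors are averaged over on
        the link scale with equal weights; numeric covariates sit at their
        sample means.  Returns a :class:`MarginalMeans` with the per-cell
        means (response scale) and all pairwise contrasts as odds ratios,
        both with HPD intervals.
        """
        if not isinstance(at, dict):
            at = {name: None for name in at}
        req = {k: v for k, v in at.items()}
        infos = {f.name(): fi for f, fi in self.model.design_info.factor_infos.items()}
        for k in req:
            if k not in infos:
                raise ValueError(f"factor {k!r} is not in the model")
        grid_at = {k: v for k, v in req.items() if v is not None}
        grid = self._grid(grid_at)
        eta = self._eta_draws(grid)
        keys = list(req)
        cells = grid[keys].astype(str).agg(" | ".join, axis=1)
        uniq = list(dict.fromkeys(cells))
        cell_eta = {c: eta[np.asarray(cells == c)].mean(axis=0) for c in uniq}
        mean_rows = []
        for c in uniq:
            mu = _invlogit(cell_eta[c])
            lo, hi = hpd_interval(mu, prob)
            mean_rows.append({"cell": c, "mean": float(np.mean(mu)),
                              "median": float(np.median(mu)), "lower": lo, "upper": hi})
        contrast_rows = []
        for a, b in itertools.combinations(uniq, 2):
            delta = cell_eta[a] - cell_eta[b]
            orr = np.exp(delta)
            lo, hi = hpd_interval(orr, prob)
            contrast_rows.append({
                "contrast": f"{a} / {b}",
                "odds_ratio": float(np.median(orr)),
                "log_or": float(np.mean(delta)),
                "lower": lo, "upper": hi,
            })
        return MarginalMeans(pd.DataFrame(mean_rows), pd.DataFrame(contrast_rows), keys)

    def marginal_slopes(self, of: str, by: Union[Sequence[str], dict], prob: float = 0.95,
                        delta: float = 1e-3):
        """Link-scale trends of a numeric covariate by factor cells.

        The per-cell slope of ``of`` (finite difference on the linear
        predictor, exact for linear terms) is averaged over non-requested
        factors; pairwise slope differences carry HPD intervals.
        """
        _require_numeric(self.model, of)
        if not isinstance(by, dict):
            by = {name: None for name in by}
        grid_at = {k: v for k, v in by.items() if v is not None}
        c0 = float(np.asarray(self.model.data[of], float).mean())
        up = self._grid({**grid_at, of: c0 + delta})
        dn = self._grid({**grid_at, of: c0 - delta})
        slope = (self._eta_draws(up) - self._eta_draws(dn)) / (2 * delta)  # (G, S)
        keys = list(by)
        cells = up[keys].astype(str).agg(" | ".join, axis=1)
        uniq = list(dict.fromkeys(cells))
        cell_slope = {c: slope[np.asarray(cells == c)].mean(axis=0) for c in uniq}
        rows = []
        for c in uniq:
            s = cell_slope[c]
            lo, hi = hpd_interval(s, prob)
            rows.append({"cell": c, "slope": float(np.mean(s)), "lower": lo, "upper": hi})
        diffs = []
        for a, b in itertools.combinations(uniq, 2):
            d = cell_slope[a] - cell_slope[b]
            lo, hi = hpd_interval(d, prob)
            diffs.append({"contrast": f"{a} - {b}", "difference": float(np.mean(d)),
                          "lower": lo, "upper": hi})
        return MarginalSlopes(pd.DataFrame(rows), pd.DataFrame(diffs), of, keys)

    # -- predictive density ----------------------------------------------
    def pointwise_loglik(self, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
        """(draws, observations) conditional log-likelihood matrix.

        For each retained posterior draw the random intercepts are set to
        their conditional Laplace mean plus Gaussian noise, so the matrix
        reflects within-participant predictive uncertainty.
        """
        key = (n_draws, seed)
        if key in self._ll_cache:
            return self._ll_cache[key]
        m = self.model
        p = len(m.exog_names)
        rng = np.random.default_rng(seed)
        S = min(n_draws, len(self.draws))
        idx = rng.choice(len(self.draws), size=S, replace=False)
        out = np.empty((S, len(m.y)))
        interior = m._interior
        y0 = m.y == 0
        y1 = m.y == 1
        for s, i in enumerate(idx):
            th = self.draws.values[i]
            beta = th[:p]
            phi = np.exp(th[p])
            zoi = _invlogit(th[p + 1])
            coi = _invlogit(th[p + 2])
            sigma = np.exp(th[p + 3])
            u_hat, _, H = m._inner_modes(beta, phi, sigma, max_newton=5)
            tau = 1.0 / np.sqrt(np.maximum(1.0 / sigma**2 - H, 1e-12))
            u = u_hat + tau * rng.standard_normal(m.n_groups)
            eta = m._Xc @ beta + u[m._gc]
            ll_int, _, _ = m._beta_terms(eta, phi, order=0)
            row = np.empty(len(m.y))
            row[interior] = np.log1p(-zoi) + ll_int
            row[y0] = np.log(zoi) + np.log1p(-coi)
            row[y1] = np.log(zoi) + np.log(coi)
            out[s] = row
        self._ll_cache[key] = out
        return out

    def loo(self, n_draws: int = 1000, seed: int = 0):
        """PSIS-LOO expected log predictive density (via arviz)."""
        import arviz as az

        ll = self.pointwise_loglik(n_draws, seed)
        # arviz requires a posterior group alongside the log-likelihood
        idata = az.from_dict(
            posterior={"theta": np.zeros((1, ll.shape[0]))},
            log_likelihood={"y": ll[None]},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(idata, pointwise=True)

    def compare(self, other: "ZOIBResults", n_draws: int = 1000, seed: int = 0) -> dict:
        """Difference in elpd (self minus other) with its standard error."""
        return compare_models(self, other, n_draws=n_draws, seed=seed)


@dataclass
class MarginalMeans:
    means: pd.DataFrame
    contrasts: pd.DataFrame
    factors: list

    def __repr__(self) -> str:
        return ("Estimated marginal means (response scale)\n"
                + self.means.to_string(index=False)
                + "\n\nPairwise contrasts (odds ratios, 95% HPD)\n"
                + self.contrasts.to_string(index=False))


@dataclass
class MarginalSlopes:
    slopes: pd.DataFrame
    differences: pd.DataFrame
    of: str
    factors: list

    def __repr__(self) -> str:
        return (f"Marginal trends of {self.of} (link scale)\n"
                + self.slopes.to_string(index=False)
                + "\n\nPairwise slope differences\n"
                + self.differences.to_string(index=False))


def compare_models(res_a: ZOIBResults, res_b: ZOIBResults,
                   n_draws: int = 1000, seed: int = 0) -> dict:
    """PSIS-LOO elpd difference (a minus b) and its SE.

    Both fits must be to the same observations of the same response; the
    SE follows the usual paired pointwise formula sqrt(n * var(diff_i)).
    """
    ma, mb = res_a.model, res_b.model
    if len(ma.y) != len(mb.y) or not np.allclose(ma.y, mb.y):
        raise ValueError("models were fitted to different datasets")
    la = res_a.loo(n_draws, seed)
    lb = res_b.loo(n_draws, seed)
    da = np.asarray(la.loo_i) if hasattr(la, "loo_i") else np.asarray(la.elpd_i)
    db = np.asarray(lb.loo_i) if hasattr(lb, "loo_i") else np.asarray(lb.elpd_i)
    diff = da - db
    n = len(diff)
    se = float(np.sqrt(n * np.var(diff, ddof=1))) if np.any(diff != 0) else 0.0
    return {"elpd_diff": float(np.sum(diff)), "se": se,
            "elpd_a": float(np.sum(da)), "elpd_b": float(np.sum(db))}
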