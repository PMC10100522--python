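"""Hierarchical Bayesian gradient models for diversity metrics.

Each model regresses one per-lake metric on first- and second-order
orthogonal polynomials of a standardized predictor (elevation, latitude,
mean annual temperature, or seasonal temperature difference), with
zone-level random intercepts and polynomial slopes: latitudinal zones group
the elevation models and elevational zones group the latitude models, so
the random effects carry the geographic interaction.

Families: Poisson (log) for richness counts with a negative-binomial
fallback, Gamma (log) for phylogenetic richness, Gaussian for SES and CWM
responses, and a two-component Gaussian mixture (ordered intercepts) for
the bimodal functional-richness response.  Population-level coefficients
get N(0, 5) priors; random-effect scales and dispersion parameters get
half-Student-t(3) priors; random effects are non-centered with independent
per-term scales.

Posteriors are sampled with the adaptive HMC sampler in
:mod:`lakediv.hmc`; convergence (split R-hat, effective sample size,
divergence count) is checked on every parameter and non-converged fits are
flagged rather than silently returned.  Model comparison uses WAIC computed
from the pointwise log-likelihood matrix and PSIS-LOO (LOOIC) via arviz.

Design-scale note: the fixed-effect columns are the unit-norm orthogonal
polynomials rescaled by sqrt(n) so each column has roughly unit standard
deviation; slope coefficients are therefore per-SD effects, the natural
scale for the N(0, 5) prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, log_expit, logsumexp

from .hmc import sample_hmc
from .zoning import DesignColumns, orthogonal_poly

__all__ = [
    "ModelSpec", "ModelFit", "ModelComparison", "ModelError",
    "fit_hierarchical", "fit_mixture", "ci_sign", "information_criteria",
    "predict_curves", "run_model_battery", "default_battery",
]

_HALF_T_DF = 3.0


class ModelError(RuntimeError):
    """Invalid data or sampler failure for a gradient model."""


@dataclass
class ModelSpec:
    """One metric-predictor model: design, family, priors, MCMC settings."""

    response: str
    predictor: str
    family: str = "gaussian"   # poisson | negbin | gaussian | gamma | mixture
    grouping: str | None = None
    covariates: tuple = ()
    include_poly2: bool = True
    random_effects: bool = True
    response_transform: str | None = None  # None | "logit"
    slope_prior_sd: float = 5.0
    scale_prior_sd: float = 2.5
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 32

    def label(self) -> str:
        group = self.grouping if (self.grouping and self.random_effects) else "none"
        return f"{self.response}~{self.predictor}[{self.family}|{group}]"


# --------------------------------------------------------------- families

def _half_t_logp_grad(x_unconstrained: float, scale: float):
    """log-density (+ Jacobian) of s = exp(x), s ~ half-Student-t(3, scale)."""
    s2 = np.exp(2.0 * np.clip(x_unconstrained, -200.0, 200.0))
    denom = _HALF_T_DF * scale * scale
    lp = -0.5 * (_HALF_T_DF + 1.0) * np.log1p(s2 / denom) + x_unconstrained
    grad = -(_HALF_T_DF + 1.0) * (s2 / denom) / (1.0 + s2 / denom) + 1.0
    return lp, grad


class _Family:
    name = ""
    n_params = 0
    param_names: tuple = ()
    param_prior_scales: tuple = ()

    def ll_grad(self, y, eta, extra):
        raise NotImplementedError

    def loglik(self, y, eta, extra):
        raise NotImplementedError

    def inverse_link(self, eta):
        raise NotImplementedError


class _Poisson(_Family):
    name = "poisson"

    def ll_grad(self, y, eta, extra):
        mu = np.exp(np.clip(eta, -700, 30))
        ll = y * eta - mu - gammaln(y + 1.0)
        return ll, y - mu, np.empty(0)

    def loglik(self, y, eta, extra):
        mu = np.exp(np.clip(eta, -700, 30))
        return y * eta - mu - gammaln(y + 1.0)

    def inverse_link(self, eta):
        return np.exp(eta)


class _NegBin(_Family):
    name = "negbin"
    n_params = 1
    param_names = ("log_phi",)
    param_prior_scales = (10.0,)

    def ll_grad(self, y, eta, extra):
        # stable form: log(mu + phi) = logaddexp(eta, log phi),
        # mu/(mu+phi) = expit(eta - log phi); no clipping plateaus
        log_phi = np.clip(extra[0], -30.0, 30.0)
        phi = np.exp(log_phi)
        log_denom = np.logaddexp(eta, log_phi)
        frac_mu = expit(eta - log_phi)          # mu / (mu + phi)
        ll = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
              + phi * (log_phi - log_denom) + y * (eta - log_denom))
        deta = y - (y + phi) * frac_mu
        dphi = phi * np.sum(
            digamma(y + phi) - digamma(phi) + (log_phi - log_denom)
            + 1.0 - (y + phi) / phi * (1.0 - frac_mu)
        )
        return ll, deta, np.array([dphi])

    def loglik(self, y, eta, extra):
        return self.ll_grad(y, eta, extra)[0]

    def inverse_link(self, eta):
        return np.exp(eta)


class _Gaussian(_Family):
    name = "gaussian"
    n_params = 1
    param_names = ("log_sigma",)
    param_prior_scales = (2.5,)

    def ll_grad(self, y, eta, extra):
        sigma = np.exp(np.clip(extra[0], -200.0, 200.0))
        resid = (y - eta) / sigma
        ll = -0.5 * np.log(2 * np.pi) - extra[0] - 0.5 * resid * resid
        deta = resid / sigma
        dlogsig = np.sum(resid * resid - 1.0)
        return ll, deta, np.array([dlogsig])

    def loglik(self, y, eta, extra):
        sigma = np.exp(np.clip(extra[0], -200.0, 200.0))
        resid = (y - eta) / sigma
        return -0.5 * np.log(2 * np.pi) - extra[0] - 0.5 * resid * resid

    def inverse_link(self, eta):
        return eta


class _Gamma(_Family):
    name = "gamma"
    n_params = 1
    param_names = ("log_shape",)
    param_prior_scales = (10.0,)

    def ll_grad(self, y, eta, extra):
        a = np.exp(np.clip(extra[0], -30.0, 30.0))
        eta_c = np.clip(eta, -30, 30)
        ye = y * np.exp(-eta_c)
        ll = a * (extra[0] - eta_c) + (a - 1.0) * np.log(y) - a * ye - gammaln(a)
        deta = -a + a * ye
        dloga = a * np.sum(extra[0] + 1.0 - eta_c + np.log(y) - ye - digamma(a))
        return ll, deta, np.array([dloga])

    def loglik(self, y, eta, extra):
        return self.ll_grad(y, eta, extra)[0]

    def inverse_link(self, eta):
        return np.exp(eta)


_FAMILIES = {f.name: f for f in (_Poisson(), _NegBin(), _Gaussian(), _Gamma())}


# ------------------------------------------------------------------- fits

@dataclass
class ModelFit:
    spec: ModelSpec
    param_names: list
    draws: dict                  # name -> (chains, draws) array
    summary: pd.DataFrame
    diagnostics: dict
    design: dict                 # basis, scaling, group levels, data sizes
    _loglik_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def flagged(self) -> bool:
        return bool(self.diagnostics.get("flagged", False))

    def stacked(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def log_likelihood_matrix(self) -> np.ndarray:
        """(chains, draws, n_obs) pointwise log-likelihood."""
        if self._loglik_cache is None:
            self._loglik_cache = self.design["loglik_fn"](self.draws)
        return self._loglik_cache

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior={k: v for k, v in self.draws.items() if v.ndim == 2},
            log_likelihood={"y": self.log_likelihood_matrix()},
        )


def _design_matrices(spec: ModelSpec, data: pd.DataFrame):
    """Response, fixed design, random design, group codes from a data frame."""
    needed = [spec.response, spec.predictor] + list(spec.covariates)
    if spec.grouping is not None and spec.random_effects:
        needed.append(spec.grouping)
    for col in needed:
        if col not in data.columns:
            raise ModelError(f"data lacks column {col!r}")
    sub = data.dropna(subset=[spec.response, spec.predictor] + list(spec.covariates))
    n_dropped = len(data) - len(sub)
    y = sub[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ModelError(f"non-finite response values in {spec.response!r}")
    if spec.response_transform == "logit":
        y = np.clip(y, 1e-6, 1.0 - 1e-6)
        y = np.log(y / (1.0 - y))
    elif spec.response_transform == "zscore":
        sd = y.std(ddof=1)
        if sd == 0:
            raise ModelError(f"constant response {spec.response!r}")
        y = (y - y.mean()) / sd
    n = len(sub)
    basis = orthogonal_poly(sub[spec.predictor].to_numpy(dtype=float))
    scale = np.sqrt(n)  # per-SD coefficient scale (see module docstring)
    cols = [np.ones(n), basis.poly1 * scale]
    names = ["intercept", "beta1"]
    if spec.include_poly2:
        cols.append(basis.poly2 * scale)
        names.append("beta2")
    for cov in spec.covariates:
        x = sub[cov].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        cols.append((x - x.mean()) / sd if sd > 0 else np.zeros(n))
        names.append(f"b_{cov}")
    x_mat = np.column_stack(cols)

    groups = levels = None
    if spec.random_effects:
        if spec.grouping is None:
            raise ModelError("random_effects=True requires a grouping column")
        codes, levels = pd.factorize(sub[spec.grouping], sort=True)
        if len(levels) < 2:
            raise ModelError(f"grouping {spec.grouping!r} has a single level")
        groups = codes.astype(int)
    n_re = (3 if spec.include_poly2 else 2) if spec.random_effects else 0
    xr = x_mat[:, :n_re] if n_re else None
    return y, x_mat, names, xr, groups, levels, basis, scale, n_dropped, sub


def _make_logp_grad(y, x_mat, xr, groups, n_groups, family: _Family,
                    spec: ModelSpec):
    n_fixed = x_mat.shape[1]
    t_re = xr.shape[1] if xr is not None else 0
    n_extra = family.n_params
    prior_sd = np.full(n_fixed, spec.slope_prior_sd)
    prior_sd[0] = 10.0  # weakly informative intercept

    def logp_grad(theta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _logp_grad_impl(theta)

    def _logp_grad_impl(theta):
        b = theta[:n_fixed]
        pos = n_fixed
        eta = x_mat @ b
        if t_re:
            z = theta[pos:pos + n_groups * t_re].reshape(n_groups, t_re)
            pos += n_groups * t_re
            log_tau = theta[pos:pos + t_re]
            pos += t_re
            tau = np.exp(np.clip(log_tau, -200.0, 200.0))
            u = z * tau
            eta = eta + np.sum(u[groups] * xr, axis=1)
        extra = theta[pos:pos + n_extra]

        ll, deta, dextra = family.ll_grad(y, eta, extra)
        lp = float(ll.sum())
        grad = np.empty_like(theta)
        grad[:n_fixed] = x_mat.T @ deta

        lp += float(np.sum(-0.5 * (b / prior_sd) ** 2))
        grad[:n_fixed] += -b / prior_sd**2

        pos = n_fixed
        if t_re:
            acc = np.zeros((n_groups, t_re))
            np.add.at(acc, groups, deta[:, None] * xr)
            dz = acc * tau - z
            lp += float(-0.5 * np.sum(z * z))
            dlog_tau = np.sum(acc * z, axis=0) * tau
            for t in range(t_re):
                lp_t, g_t = _half_t_logp_grad(log_tau[t], spec.scale_prior_sd)
                lp += lp_t
                dlog_tau[t] += g_t
            grad[pos:pos + n_groups * t_re] = dz.reshape(-1)
            pos += n_groups * t_re
            grad[pos:pos + t_re] = dlog_tau
            pos += t_re
        for k in range(n_extra):
            lp_k, g_k = _half_t_logp_grad(extra[k], family.param_prior_scales[k])
            lp += lp_k
            grad[pos + k] = dextra[k] + g_k
        return lp, grad

    return logp_grad


def _split_diagnostics(draw_arrays: dict) -> pd.DataFrame:
    """Split R-hat and bulk ESS per scalar parameter via arviz."""
    rows = {}
    for name, arr in draw_arrays.items():
        rows[name] = {
            "rhat": float(az.rhat(arr.copy())),
            "ess": float(az.ess(arr.copy())),
        }
    return pd.DataFrame(rows).T


def _summarize(draw_arrays: dict) -> pd.DataFrame:
    diag = _split_diagnostics(draw_arrays)
    rows = []
    for name, arr in draw_arrays.items():
        flat = arr.reshape(-1)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "median": float(np.median(flat)),
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "rhat": diag.loc[name, "rhat"],
            "ess": diag.loc[name, "ess"],
        })
    return pd.DataFrame(rows).set_index("parameter")


def fit_hierarchical(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Sample one multilevel gradient model and summarize its posterior."""
    if spec.family == "mixture":
        return fit_mixture(spec, data)
    if spec.family not in _FAMILIES:
        raise ModelError(f"unknown family {spec.family!r}")
    family = _FAMILIES[spec.family]
    (y, x_mat, names, xr, groups, levels, basis, scale,
     n_dropped, sub) = _design_matrices(spec, data)
    if spec.family in ("poisson", "negbin") and np.any(y < 0):
        raise ModelError("count family requires non-negative response")
    if spec.family == "gamma" and np.any(y <= 0):
        raise ModelError("gamma family requires positive response")

    n_groups = len(levels) if levels is not None else 0
    t_re = xr.shape[1] if xr is not None else 0
    dim = x_mat.shape[1] + n_groups * t_re + t_re + family.n_params
    logp_grad = _make_logp_grad(y, x_mat, xr, groups, n_groups, family, spec)

    init = np.zeros(dim)
    if spec.family in ("poisson", "negbin", "gamma"):
        init[0] = np.log(max(y.mean(), 0.1))
        if spec.family == "negbin":
            excess = max(y.var() - y.mean(), 0.1 * y.mean())
            init[-1] = np.log(np.clip(y.mean() ** 2 / excess, 0.2, 50.0))
        elif spec.family == "gamma":
            cv2 = max(y.var(), 1e-6) / max(y.mean(), 1e-6) ** 2
            init[-1] = np.log(np.clip(1.0 / cv2, 0.2, 50.0))
    else:
        init[0] = y.mean()
        if family.n_params:
            init[-1] = np.log(max(y.std(), 1e-3))
    if t_re:
        init[x_mat.shape[1] + n_groups * t_re:
             x_mat.shape[1] + n_groups * t_re + t_re] = np.log(0.3)

    res = sample_hmc(
        logp_grad, init, chains=spec.chains, warmup=spec.warmup,
        draws=spec.draws, seed=spec.seed, target_accept=spec.target_accept,
        max_leapfrog=spec.max_leapfrog,
    )

    c, d = spec.chains, spec.draws
    arrs = {}
    pos = 0
    for name in names:
        arrs[name] = res.draws[:, :, pos]
        pos += 1
    z_draws = None
    if t_re:
        z_draws = res.draws[:, :, pos:pos + n_groups * t_re].reshape(c, d, n_groups, t_re)
        pos += n_groups * t_re
        re_names = ["intercept", "poly1", "poly2"][:t_re]
        for t, rn in enumerate(re_names):
            arrs[f"tau_{rn}"] = np.exp(res.draws[:, :, pos + t])
        pos += t_re
    for k, pn in enumerate(family.param_names):
        arrs[pn.replace("log_", "")] = np.exp(res.draws[:, :, pos + k])
    pos += family.n_params

    summary = _summarize(arrs)
    max_rhat = float(summary["rhat"].max())
    flags = []
    if max_rhat > 1.01:
        flags.append(f"max split R-hat {max_rhat:.3f} > 1.01")
    if res.divergences > 0:
        flags.append(f"{res.divergences} divergent transitions")
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": float(summary["ess"].min()),
        "divergences": res.divergences,
        "accept_rate": res.accept_rate,
        "flagged": bool(flags),
        "flags": flags,
        "n_obs": len(y),
        "n_dropped": n_dropped,
    }

    group_effects = None
    if t_re:
        tau_stack = np.stack(
            [arrs[f"tau_{rn}"] for rn in ["intercept", "poly1", "poly2"][:t_re]],
            axis=-1,
        )
        group_effects = z_draws * tau_stack[:, :, None, :]

    design = {
        "basis": basis,
        "poly_scale": scale,
        "fixed_names": names,
        "group_levels": list(levels) if levels is not None else [],
        "t_re": t_re,
        "family": family,
        "y": y,
        "x_mat": x_mat,
        "xr": xr,
        "groups": groups,
        "group_effects": group_effects,
    }

    def loglik_fn(draw_arrays, design=design, family=family):
        xm, yv = design["x_mat"], design["y"]
        beta = np.stack([draw_arrays[n] for n in design["fixed_names"]], axis=-1)
        eta = np.einsum("cdk,nk->cdn", beta, xm)
        if design["t_re"]:
            u = design["group_effects"]  # (c, d, G, T)
            eta = eta + np.einsum("cdnt,nt->cdn", u[:, :, design["groups"], :],
                                  design["xr"])
        extras = [np.log(draw_arrays[pn.replace("log_", "")])
                  for pn in family.param_names]
        out = np.empty(eta.shape)
        for ci in range(eta.shape[0]):
            for di in range(eta.shape[1]):
                ex = np.array([e[ci, di] for e in extras])
                out[ci, di] = family.loglik(yv, eta[ci, di], ex)
        return out

    design["loglik_fn"] = loglik_fn
    return ModelFit(spec=spec, param_names=list(arrs), draws=arrs,
                    summary=summary, diagnostics=diagnostics, design=design)


# ------------------------------------------------------------------ mixture

def fit_mixture(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Two-component Gaussian mixture with shared predictors.

    Component intercepts are ordered (mu1 < mu2) by construction via an
    exponentiated gap, which pins the labels; each component carries its own
    polynomial coefficients, matching how a bimodal response can answer the
    gradient differently in its two modes.  The mixing proportion is the
    posterior weight of the lower-intercept component.
    """
    (y, x_mat, names, _xr, _groups, _levels, basis, scale,
     n_dropped, sub) = _design_matrices(replace(spec, random_effects=False), data)
    n_slope = x_mat.shape[1] - 1
    x_slopes = x_mat[:, 1:]
    # theta: a1, delta, slopes1 (n_slope), slopes2 (n_slope), logit_w, log_sigma
    dim = 2 + 2 * n_slope + 2

    def unpack(theta):
        a1 = theta[0]
        a2 = a1 + np.exp(theta[1])
        b1 = theta[2:2 + n_slope]
        b2 = theta[2 + n_slope:2 + 2 * n_slope]
        logit_w, log_sigma = theta[-2], theta[-1]
        return a1, a2, b1, b2, logit_w, log_sigma

    def logp_grad(theta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _logp_grad_impl(theta)

    def _logp_grad_impl(theta):
        a1, a2, b1, b2, logit_w, log_sigma = unpack(theta)
        log_sigma_c = np.clip(log_sigma, -200.0, 200.0)
        sigma = np.exp(log_sigma_c)
        inv_s2 = np.exp(-2.0 * log_sigma_c)
        w1 = expit(logit_w)
        eta1 = a1 + x_slopes @ b1
        eta2 = a2 + x_slopes @ b2
        r1sq = ((y - eta1) / sigma) ** 2
        r2sq = ((y - eta2) / sigma) ** 2
        base = -0.5 * np.log(2 * np.pi) - log_sigma
        c1 = log_expit(logit_w) + base - 0.5 * r1sq
        c2 = log_expit(-logit_w) + base - 0.5 * r2sq
        ll = np.logaddexp(c1, c2)
        lp = float(ll.sum())
        resp1 = np.exp(c1 - ll)
        resp2 = 1.0 - resp1
        d1 = resp1 * (y - eta1) * inv_s2
        d2 = resp2 * (y - eta2) * inv_s2
        grad = np.empty(dim)
        grad[0] = d1.sum() + d2.sum()
        grad[1] = np.exp(theta[1]) * d2.sum()
        grad[2:2 + n_slope] = x_slopes.T @ d1
        grad[2 + n_slope:2 + 2 * n_slope] = x_slopes.T @ d2
        grad[-2] = float(np.sum(resp1 - w1))
        grad[-1] = float(np.sum(resp1 * (r1sq - 1.0) + resp2 * (r2sq - 1.0)))
        # priors: intercept/slopes N(0,5); gap N(0,1.5); mixing logit N(0,1.5)
        sd_b = spec.slope_prior_sd
        lp += -0.5 * (a1 / sd_b) ** 2
        grad[0] += -a1 / sd_b**2
        lp += -0.5 * (theta[1] / 1.5) ** 2
        grad[1] += -theta[1] / 1.5**2
        for sl in (slice(2, 2 + n_slope), slice(2 + n_slope, 2 + 2 * n_slope)):
            lp += float(np.sum(-0.5 * (theta[sl] / sd_b) ** 2))
            grad[sl] += -theta[sl] / sd_b**2
        lp += -0.5 * (logit_w / 1.5) ** 2
        grad[-2] += -logit_w / 1.5**2
        lp_s, g_s = _half_t_logp_grad(log_sigma, spec.scale_prior_sd)
        lp += lp_s
        grad[-1] += g_s
        return lp, grad

    init = np.zeros(dim)
    lo, hi = np.quantile(y, [0.25, 0.75])
    init[0] = lo
    init[1] = np.log(max(hi - lo, 0.1))
    init[-1] = np.log(max(y.std() / 2.0, 1e-3))

    res = sample_hmc(
        logp_grad, init, chains=spec.chains, warmup=spec.warmup,
        draws=spec.draws, seed=spec.seed, target_accept=spec.target_accept,
        max_leapfrog=spec.max_leapfrog,
    )
    slope_names = names[1:]
    arrs = {
        "mu1_intercept": res.draws[:, :, 0],
        "mu2_intercept": res.draws[:, :, 0] + np.exp(res.draws[:, :, 1]),
    }
    for i, nm in enumerate(slope_names):
        arrs[f"mu1_{nm}"] = res.draws[:, :, 2 + i]
        arrs[f"mu2_{nm}"] = res.draws[:, :, 2 + n_slope + i]
    arrs["mixing"] = expit(res.draws[:, :, -2])
    arrs["sigma"] = np.exp(res.draws[:, :, -1])

    summary = _summarize(arrs)
    max_rhat = float(summary["rhat"].max())
    crossings = float(np.mean(arrs["mu1_intercept"] >= arrs["mu2_intercept"]))
    flags = []
    if max_rhat > 1.01:
        flags.append(f"max split R-hat {max_rhat:.3f} > 1.01")
    if res.divergences > 0:
        flags.append(f"{res.divergences} divergent transitions")
    if crossings > 0.01:
        flags.append(f"label switching: components cross in {crossings:.1%} of draws")
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": float(summary["ess"].min()),
        "divergences": res.divergences,
        "accept_rate": res.accept_rate,
        "component_crossing_rate": crossings,
        "flagged": bool(flags),
        "flags": flags,
        "n_obs": len(y),
        "n_dropped": n_dropped,
    }
    design = {
        "basis": basis, "poly_scale": scale, "fixed_names": names,
        "group_levels": [], "t_re": 0, "family": None,
        "y": y, "x_mat": x_mat, "x_slopes": x_slopes,
    }

    def loglik_fn(draw_arrays, design=design):
        yv, xs = design["y"], design["x_slopes"]
        a1 = draw_arrays["mu1_intercept"][..., None]
        a2 = draw_arrays["mu2_intercept"][..., None]
        b1 = np.stack([draw_arrays[f"mu1_{nm}"] for nm in slope_names], axis=-1)
        b2 = np.stack([draw_arrays[f"mu2_{nm}"] for nm in slope_names], axis=-1)
        w1 = draw_arrays["mixing"][..., None]
        sig = draw_arrays["sigma"][..., None]
        eta1 = a1 + np.einsum("cdk,nk->cdn", b1, xs)
        eta2 = a2 + np.einsum("cdk,nk->cdn", b2, xs)
        base = -0.5 * np.log(2 * np.pi) - np.log(sig)
        c1 = np.log(w1) + base - 0.5 * ((yv - eta1) / sig) ** 2
        c2 = np.log1p(-w1) + base - 0.5 * ((yv - eta2) / sig) ** 2
        return np.logaddexp(c1, c2)

    design["loglik_fn"] = loglik_fn
    return ModelFit(spec=spec, param_names=list(arrs), draws=arrs,
                    summary=summary, diagnostics=diagnostics, design=design)


# --------------------------------------------------------------- inference

def ci_sign(fit: ModelFit, parameter: str, level: float = 0.95) -> str:
    """'positive'/'negative' when the credible interval excludes zero."""
    if parameter not in fit.draws:
        raise KeyError(f"parameter {parameter!r} not in fit "
                       f"(have {fit.param_names})")
    flat = fit.stacked(parameter)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(flat, [alpha, 1.0 - alpha])
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "uncertain"


def waic_from_loglik(ll: np.ndarray) -> tuple[float, float]:
    """WAIC = -2(lppd - p_waic) and its SE from a pointwise log-lik matrix."""
    flat = ll.reshape(-1, ll.shape[-1])
    s = flat.shape[0]
    lppd_i = logsumexp(flat, axis=0) - np.log(s)
    p_i = flat.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic = -2.0 * float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(elpd_i.size * elpd_i.var(ddof=1)))
    return waic, se


@dataclass
class ModelComparison:
    table: pd.DataFrame  # index: model labels; columns: waic, waic_se, looic, looic_se, deltas

    @property
    def best_waic(self) -> str:
        return self.table["waic"].idxmin()

    @property
    def best_looic(self) -> str:
        return self.table["looic"].idxmin()


def information_criteria(fits: dict | list) -> ModelComparison:
    """WAIC and PSIS-LOO LOOIC with deltas against the best model."""
    if not isinstance(fits, dict):
        fits = {f.spec.label(): f for f in fits}
    n_obs = {k: f.diagnostics["n_obs"] for k, f in fits.items()}
    if len(set(n_obs.values())) > 1:
        raise ModelError(f"fits compare different observation sets: {n_obs}")
    rows = {}
    for key, fit in fits.items():
        ll = fit.log_likelihood_matrix()
        waic, waic_se = waic_from_loglik(ll)
        loo = az.loo(fit.to_inference_data(), pointwise=False)
        rows[key] = {
            "waic": waic, "waic_se": waic_se,
            "looic": -2.0 * float(loo.elpd_loo),
            "looic_se": 2.0 * float(loo.se),
        }
    table = pd.DataFrame(rows).T
    table["delta_waic"] = table["waic"] - table["waic"].min()
    table["delta_looic"] = table["looic"] - table["looic"].min()
    return ModelComparison(table=table)


def predict_curves(fit: ModelFit, grid, level: str = "population") -> pd.DataFrame:
    """Posterior median and 95% interval of the inverse-linked predictor.

    ``level='population'`` sets group effects to zero; ``'group'`` adds each
    zone's random effects and returns one block of rows per zone.  Grid
    points outside the training predictor range are allowed (extrapolation).
    """
    basis: DesignColumns = fit.design["basis"]
    grid = np.asarray(grid, dtype=float)
    p1, p2 = basis.evaluate(grid)
    scale = fit.design["poly_scale"]
    names = fit.design["fixed_names"]
    if fit.spec.family == "mixture":
        return _predict_mixture(fit, grid, p1 * scale, p2 * scale)
    cols = {"intercept": np.ones_like(grid), "beta1": p1 * scale}
    if "beta2" in names:
        cols["beta2"] = p2 * scale
    for nm in names:
        if nm not in cols:
            cols[nm] = np.zeros_like(grid)  # covariates held at their mean
    x_grid = np.column_stack([cols[nm] for nm in names])
    beta = np.stack([fit.draws[nm] for nm in names], axis=-1)  # (c, d, k)
    eta = np.einsum("cdk,nk->cdn", beta, x_grid)

    family = fit.design["family"]
    inv = family.inverse_link if family is not None else (lambda e: e)

    def summarise(eta_block, label):
        mu = inv(eta_block.reshape(-1, eta_block.shape[-1]))
        return pd.DataFrame({
            "group": label,
            "x": grid,
            "median": np.median(mu, axis=0),
            "q2.5": np.quantile(mu, 0.025, axis=0),
            "q97.5": np.quantile(mu, 0.975, axis=0),
        })

    if level == "population" or not fit.design["t_re"]:
        return summarise(eta, "population")
    if level != "group":
        raise ValueError(f"unknown level {level!r}")
    u = fit.design["group_effects"]  # (c, d, G, T)
    t_re = fit.design["t_re"]
    xr_grid = x_grid[:, :t_re]
    out = []
    for gi, glabel in enumerate(fit.design["group_levels"]):
        eta_g = eta + np.einsum("cdt,nt->cdn", u[:, :, gi, :], xr_grid)
        out.append(summarise(eta_g, glabel))
    return pd.concat(out, ignore_index=True)


def _predict_mixture(fit: ModelFit, grid, p1s, p2s) -> pd.DataFrame:
    """Population curve for the mixture family: the mixture mean."""
    names = fit.design["fixed_names"]
    cols = [np.ones_like(grid), p1s]
    if "beta2" in names:
        cols.append(p2s)
    x_grid = np.column_stack(cols)[:, 1:]  # slopes only
    slope_names = names[1:]
    eta = {}
    for comp in ("mu1", "mu2"):
        b = np.stack([fit.draws[f"{comp}_{nm}"] for nm in slope_names], axis=-1)
        eta[comp] = (fit.draws[f"{comp}_intercept"][..., None]
                     + np.einsum("cdk,nk->cdn", b, x_grid))
    w1 = fit.draws["mixing"][..., None]
    mu = (w1 * eta["mu1"] + (1.0 - w1) * eta["mu2"]).reshape(-1, grid.size)
    return pd.DataFrame({
        "group": "population",
        "x": grid,
        "median": np.median(mu, axis=0),
        "q2.5": np.quantile(mu, 0.025, axis=0),
        "q97.5": np.quantile(mu, 0.975, axis=0),
    })


# ---------------------------------------------------------------- battery

FAMILY_MAP = {
    "richness": "poisson",
    "pd": "gamma",
    "fric": "mixture",
    "ses_pd": "gaussian",
    "ses_mpd": "gaussian",
    "ses_fdis": "gaussian",
    "ses_fric": "gaussian",
    "cwm_length": "gaussian",
    "cwm_guild": "gaussian",
    "mpd": "gaussian",
    "fdis": "gaussian",
    "mat": "gaussian",
    "seasonal_diff": "gaussian",
    "elevation": "gaussian",
    "latitude": "gaussian",
}

COMPLEMENT_GROUPING = {"elevation": "lat_zone", "latitude": "elev_zone"}


def default_battery(
    metrics=("richness", "pd", "ses_pd", "ses_mpd", "ses_fdis", "cwm_length",
             "cwm_guild", "fric", "ses_fric"),
    predictors=("elevation", "latitude"),
    climate_responses=("richness",),
    climate_predictors=("mat", "seasonal_diff"),
    geography_on_climate: bool = True,
    sensitivity_covariates: tuple = (),
    mcmc: dict | None = None,
) -> list[ModelSpec]:
    """Model specs for the standard analysis battery.

    Geography models pair each metric with elevation and latitude (grouped
    by the complementary zoning); climate models regress selected responses
    on mean annual temperature and seasonality under both groupings; the
    Gaussian geography-on-climate models quantify how strongly the climate
    surface tracks each geographic axis.
    """
    mcmc = mcmc or {}
    specs = []

    def make(response, predictor, grouping, **kw):
        fam = kw.pop("family", FAMILY_MAP.get(response, "gaussian"))
        transform = kw.pop("response_transform",
                           "logit" if fam == "mixture" else None)
        specs.append(ModelSpec(
            response=response, predictor=predictor, family=fam,
            grouping=grouping, response_transform=transform,
            random_effects=(fam != "mixture"),
            covariates=tuple(kw.pop("covariates", ())), **{**mcmc, **kw},
        ))

    for resp in metrics:
        for pred in predictors:
            make(resp, pred, COMPLEMENT_GROUPING[pred])
    for resp in climate_responses:
        for pred in climate_predictors:
            for grouping in ("lat_zone", "elev_zone"):
                make(resp, pred, grouping)
    if geography_on_climate:
        # geography and climate both enter as z-scores, so these slopes
        # read directly as correlation strengths
        for resp in ("elevation", "latitude"):
            for pred in climate_predictors:
                grouping = COMPLEMENT_GROUPING[resp]
                make(resp, pred, grouping, family="gaussian",
                     response_transform="zscore")
    for cov in sensitivity_covariates:
        for pred in predictors:
            make("richness", pred, COMPLEMENT_GROUPING[pred], covariates=(cov,))
    return specs


def run_model_battery(data: pd.DataFrame, specs: list[ModelSpec],
                      compare_without_re: bool = False) -> tuple[pd.DataFrame, dict]:
    """Fit every spec and tabulate slopes, sign calls, and diagnostics.

    Returns (summary table, dict of fits).  Flagged fits keep their row with
    a status column and are excluded from any information-criteria deltas.
    With ``compare_without_re`` each random-effects model is also refit
    without group effects (and without the quadratic term) and the WAIC and
    LOOIC differences (fixed-only minus multilevel) are reported.
    """
    rows, fits = [], {}
    for spec in specs:
        label = spec.label()
        try:
            fit = fit_hierarchical(spec, data)
        except ModelError as exc:
            rows.append({"model": label, "status": f"error: {exc}"})
            continue
        fits[label] = fit
        b1 = "beta1" if "beta1" in fit.draws else "mu1_beta1"
        b2 = "beta2" if "beta2" in fit.draws else ("mu1_beta2" if "mu1_beta2" in fit.draws else None)
        row = {
            "model": label,
            "response": spec.response,
            "predictor": spec.predictor,
            "family": spec.family,
            "grouping": spec.grouping,
            "n_obs": fit.diagnostics["n_obs"],
            "beta1_median": fit.summary.loc[b1, "median"],
            "beta1_low": fit.summary.loc[b1, "q2.5"],
            "beta1_high": fit.summary.loc[b1, "q97.5"],
            "beta1_sign": ci_sign(fit, b1),
            "status": "flagged" if fit.flagged else "ok",
            "max_rhat": fit.diagnostics["max_rhat"],
            "divergences": fit.diagnostics["divergences"],
        }
        if b2 is not None:
            row.update({
                "beta2_median": fit.summary.loc[b2, "median"],
                "beta2_sign": ci_sign(fit, b2),
            })
        if "tau_poly1" in fit.draws:
            row["tau_poly1_median"] = fit.summary.loc["tau_poly1", "median"]
            row["tau_poly1_low"] = fit.summary.loc["tau_poly1", "q2.5"]
        if compare_without_re and spec.random_effects and not fit.flagged:
            fixed_spec = replace(spec, random_effects=False, include_poly2=False,
                                 seed=spec.seed + 1)
            try:
                fixed_fit = fit_hierarchical(fixed_spec, data)
                comp = information_criteria(
                    {"multilevel": fit, "fixed_only": fixed_fit})
                row["delta_waic_fixed"] = float(
                    comp.table.loc["fixed_only", "waic"]
                    - comp.table.loc["multilevel", "waic"])
                row["delta_looic_fixed"] = float(
                    comp.table.loc["fixed_only", "looic"]
                    - comp.table.loc["multilevel", "looic"])
            except ModelError as exc:
                row["delta_waic_fixed"] = np.nan
                row["status"] = f"comparison error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows), fits
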