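"""Posterior sampling and convergence diagnostics.

Two gradient-free samplers are provided:

* ``ensemble`` (default) — the affine-invariant ensemble sampler of
  Goodman & Weare via :mod:`emcee`.  Each requested chain is an
  independent ensemble whose walkers' draws are pooled, so the requested
  burn-in and kept-draw counts are spread over the walkers.

* ``metropolis_within_gibbs`` — a single-coordinate adaptive random-walk
  Metropolis sweep, the gradient-free analogue of the component-wise Gibbs
  updates classically used for these models.  Proposal scales adapt toward
  a 44% acceptance rate during burn-in only, so the kept chain targets the
  exact posterior.  It is considerably slower per effective draw and is
  intended for small problems and cross-checks.

Defaults keep the historically standard run lengths for this analysis
(2 chains, 50,000 burn-in, 100,000 kept draws per chain); `fast()` gives a
short ESS-justified profile.  Everything is deterministic given the seed.
Diagnostics (bulk ESS, split-chain R-hat) are computed with :mod:`arviz`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np


@dataclass(frozen=True)
class McmcConfig:
    """Run-length and sampler settings.

    ``samples`` is the number of kept draws per chain; for the ensemble
    sampler the draws are pooled over walkers (steps = samples/walkers).
    """

    chains: int = 2
    burn_in: int = 50_000
    samples: int = 100_000
    seed: int = 0
    sampler: str = "metropolis_within_gibbs"
    nwalkers: int | None = None
    init: str = "default"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.samples < 1_000:
            raise ValueError("need at least 1,000 kept draws per chain")
        if self.sampler not in ("ensemble", "metropolis_within_gibbs"):
            raise ValueError(f"unknown sampler {self.sampler!r}")

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "McmcConfig":
        """Short profile (4 chains, 2,500 kept each) for quick runs."""
        return cls(chains=4, burn_in=4_000, samples=2_500, seed=seed, **kw)


@dataclass
class PosteriorSamples:
    """Named posterior draws, shaped (chain, draw[, dim])."""

    draws: dict[str, np.ndarray]
    coords: dict[str, list[str]]
    config: McmcConfig
    spec: object

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (chain*draw[, dim])."""
        x = self.draws[name]
        return x.reshape(-1, *x.shape[2:])

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def to_inference_data(self) -> az.InferenceData:
        dims, coords = {}, {}
        for name, labels in self.coords.items():
            coords[f"{name}_dim"] = list(labels)
            dims[name] = [f"{name}_dim"]
        return az.from_dict(posterior=self.draws, dims=dims, coords=coords)


def _unpack(model, chains: np.ndarray, config: McmcConfig) -> PosteriorSamples:
    """Split flat chains (C, N, ndim) into named blocks on natural scale."""
    L = model.layout
    spec = model.spec
    draws: dict[str, np.ndarray] = {}
    coords: dict[str, list[str]] = {}
    draws["a"] = chains[..., L.slices["a"]]
    coords["a"] = list(spec.drugs)
    if spec.mtx_adjust:
        draws["b"] = chains[..., L.slices["b"]][..., 0]
    if model.priors.sigma_fixed is None:
        draws["sigma"] = chains[..., L.slices["sigma"]][..., 0]
    if spec.likelihood == "binomial":
        draws["mu"] = chains[..., L.slices["mu"]]
        coords["mu"] = list(model.study_labels)
    if spec.covariate_gamma:
        draws["gamma"] = chains[..., L.slices["gamma"]][..., 0]
    if not (model.priors.sigma_fixed == 0):
        re = chains[..., L.slices["re"]]
        if model.parameterization == "noncentered":
            if model.priors.sigma_fixed is None:
                sigma = draws["sigma"][..., None]
            else:
                sigma = model.priors.sigma_fixed
            alpha = draws["a"][..., model.group_drug] + sigma * re
        else:
            alpha = re
        draws["study_effects"] = alpha
        coords["study_effects"] = list(model.group_labels)
    return PosteriorSamples(draws, coords, config, spec)


def _valid_initial(model, n, rng, init, max_tries=100):
    theta = model.initial_points(n, rng, init=init)
    for _ in range(max_tries):
        lp = model.log_posterior(theta)
        bad = ~np.isfinite(lp)
        if not bad.any():
            return theta
        theta[bad] = model.initial_points(int(bad.sum()), rng, init=init)
    raise RuntimeError("could not find finite-density starting points")


def _run_ensemble(model, config: McmcConfig):
    import emcee

    ndim = model.ndim
    nwalkers = config.nwalkers or max(2 * ndim + 2, 32)
    nwalkers += nwalkers % 2
    steps_burn = math.ceil(config.burn_in / nwalkers)
    steps_keep = math.ceil(config.samples / nwalkers)
    # differential-evolution moves handle the correlated, mixed-scale
    # posterior far better than the default stretch move here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    per_chain = []
    for c in range(config.chains):
        ss = np.random.SeedSequence([config.seed, c])
        rng = np.random.default_rng(ss)
        p0 = _valid_initial(model, nwalkers, rng, config.init)
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, model.log_posterior, vectorize=True, moves=moves
        )
        sampler._random = np.random.RandomState(ss.generate_state(1)[0] % 2**31)
        sampler.run_mcmc(p0, steps_burn + steps_keep, progress=False)
        chain = sampler.get_chain(discard=steps_burn)  # (steps, walkers, ndim)
        acc = sampler.acceptance_fraction.mean()
        if acc < 0.05:
            warnings.warn(
                f"chain {c}: low ensemble acceptance rate ({acc:.2f}); "
                "inspect diagnostics"
            )
        per_chain.append(chain.reshape(-1, ndim))
    n = min(x.shape[0] for x in per_chain)
    return np.stack([x[:n] for x in per_chain]), model


class _BlockedMwg:
    """Blocked Metropolis-within-Gibbs on the centered parameterization.

    Study effects and control logits get single-coordinate random-walk
    Metropolis updates whose acceptance only needs the likelihood terms
    touching that coordinate (they decompose by group / by study); the
    basic effects a_k and the between-trial SD σ are drawn exactly from
    their conjugate full conditionals (normal, and truncated inverse-gamma
    on σ²).  Proposal scales adapt toward ~44% acceptance during burn-in
    only.
    """

    def __init__(self, model, rng: np.random.Generator):
        from scipy.stats import invgamma  # local: scipy is a hard dep anyway

        self.m = model
        self.rng = rng
        self.invgamma = invgamma
        spec = model.spec
        self.pooled = model.priors.sigma_fixed == 0
        G, K = model.n_groups, model.n_drugs
        # 0/1 incidence matrices: arm -> group / study, group -> drug
        if spec.likelihood == "binomial":
            J, S = len(model.r_t), model.n_studies
            self.Ms = np.zeros((J, S))
            self.Ms[np.arange(J), model.study_idx] = 1.0
        else:
            J = len(model.delta)
        self.Mg = np.zeros((J, G))
        if G:
            self.Mg[np.arange(J), model.group_idx] = 1.0
        self.Mgd = np.zeros((G, K))
        if G:
            self.Mgd[np.arange(G), model.group_drug] = 1.0
        self.n_per_drug = self.Mgd.sum(axis=0)
        if self.pooled:
            self.Md = np.zeros((J, K))
            self.Md[np.arange(J), model.drug_idx] = 1.0
        # adaptive proposal scales
        self.s_re = np.full(G, 0.2)
        self.s_a = np.full(K, 0.2)
        self.s_b = 0.2
        self.s_gamma = 0.1
        self.s_mu = np.full(getattr(model, "n_studies", 0), 0.2)
        self.s_sigma = 0.2
        self.acc = {}

    # likelihood of all treatment-arm terms given their linear predictor
    def _lik_t(self, x):
        m = self.m
        if m.spec.likelihood == "binomial":
            from scipy.special import log_expit
            return m.r_t * log_expit(x) + (m.n_t - m.r_t) * log_expit(-x)
        return -0.5 * ((m.delta - x) / m.se) ** 2

    def _lik_c(self, x):
        from scipy.special import log_expit
        m = self.m
        return m.r_c * log_expit(x) + (m.n_c - m.r_c) * log_expit(-x)

    def _x_t(self, st):
        """Linear predictor (continuous: likelihood mean) of each arm."""
        m, spec = self.m, self.m.spec
        eff = st["a"][:, m.drug_idx] if self.pooled else st["re"][:, m.group_idx]
        if spec.likelihood == "binomial":
            x = st["mu"][:, m.study_idx] + eff
            if spec.mtx_adjust:
                x = x + st["b"][:, None] * m.i_t
            if spec.covariate_gamma:
                x = x + st["gamma"][:, None] * m.lam_study[m.study_idx]
        else:
            x = eff * m.lam if spec.baseline_multiplier else eff
            if spec.mtx_adjust:
                x = x + st["b"][:, None] * m.mtx_diff
        return x

    def _track(self, name, accept):
        n, s = self.acc.get(name, (0, 0.0))
        self.acc[name] = (n + 1, s + np.mean(accept, axis=0))

    def _adapt(self):
        for name, (n, s) in self.acc.items():
            rate = s / max(n, 1)
            factor = np.exp(np.clip(rate - 0.44, -1.0, 1.0) * 0.5)
            setattr(self, name, getattr(self, name) * factor)
        self.acc = {}

    def _mh_vector(self, st, key, scales, dlog_fn, name):
        """Coordinate-wise MH on an entire block with decomposed deltas."""
        cur = st[key]
        prop = cur + scales * self.rng.standard_normal(cur.shape)
        dlog = dlog_fn(cur, prop)
        accept = np.log(self.rng.random(cur.shape)) < dlog
        st[key] = np.where(accept, prop, cur)
        self._track(name, accept)

    def _mh_scalar(self, st, key, scale, dlog_fn, name):
        """MH step for a scalar parameter, vectorized over chains."""
        cur = st[key]
        prop = cur + scale * self.rng.standard_normal(cur.shape)
        dlog = dlog_fn(cur, prop)
        accept = np.log(self.rng.random(cur.shape)) < dlog
        st[key] = np.where(accept, prop, cur)
        self._track(name, accept[:, None])

    def sweep(self, st: dict, adapt: bool, it: int) -> None:
        m, spec, priors = self.m, self.m.spec, self.m.priors
        v = priors.effect_variance
        sigma = st["sigma"]

        if not self.pooled:
            # study effects: per-group MH, likelihood decomposes by group
            def d_re(cur, prop):
                x = self._x_t(st)
                shift = (prop - cur)[:, m.group_idx]
                if spec.likelihood == "continuous" and spec.baseline_multiplier:
                    xp = x + shift * m.lam
                else:
                    xp = x + shift
                dlik = (self._lik_t(xp) - self._lik_t(x)) @ self.Mg
                ag = st["a"][:, m.group_drug]
                dhier = -0.5 * ((prop - ag) ** 2 - (cur - ag) ** 2) \
                    / sigma[:, None] ** 2
                return dlik + dhier

            self._mh_vector(st, "re", self.s_re, d_re, "s_re")

        if spec.likelihood == "binomial":
            def d_mu(cur, prop):
                dmu = prop - cur
                xc = cur + (st["b"][:, None] * m.i_c if spec.mtx_adjust else 0.0)
                xt = self._x_t(st)
                dlik = (self._lik_c(xc + dmu) - self._lik_c(xc)) \
                    + (self._lik_t(xt + dmu[:, m.study_idx])
                       - self._lik_t(xt)) @ self.Ms
                dpri = 0.0 if np.isinf(v) else -0.5 * (prop**2 - cur**2) / v
                return dlik + dpri

            self._mh_vector(st, "mu", self.s_mu, d_mu, "s_mu")

        if spec.mtx_adjust:
            def d_b(cur, prop):
                db = (prop - cur)[:, None]
                xt = self._x_t(st)
                if spec.likelihood == "binomial":
                    xc = st["mu"] + cur[:, None] * m.i_c
                    d = (self._lik_c(xc + db * m.i_c) - self._lik_c(xc)).sum(1) \
                        + (self._lik_t(xt + db * m.i_t) - self._lik_t(xt)).sum(1)
                else:
                    d = (self._lik_t(xt + db * m.mtx_diff)
                         - self._lik_t(xt)).sum(1)
                dpri = 0.0 if np.isinf(v) else -0.5 * (prop**2 - cur**2) / v
                return d + dpri

            self._mh_scalar(st, "b", self.s_b, d_b, "s_b")

        if spec.covariate_gamma:
            def d_gamma(cur, prop):
                dg = (prop - cur)[:, None] * m.lam_study[m.study_idx]
                xt = self._x_t(st)
                d = (self._lik_t(xt + dg) - self._lik_t(xt)).sum(1)
                dpri = 0.0 if np.isinf(v) else -0.5 * (prop**2 - cur**2) / v
                return d + dpri

            self._mh_scalar(st, "gamma", self.s_gamma, d_gamma, "s_gamma")

        if self.pooled:
            # common-effect model: a enters the likelihood directly
            def d_a(cur, prop):
                x = self._x_t(st)
                shift = (prop - cur)[:, m.drug_idx]
                if spec.likelihood == "continuous" and spec.baseline_multiplier:
                    xp = x + shift * m.lam
                else:
                    xp = x + shift
                dlik = (self._lik_t(xp) - self._lik_t(x)) @ self.Md
                dpri = 0.0 if np.isinf(v) else -0.5 * (prop**2 - cur**2) / v
                return dlik + dpri

            self._mh_vector(st, "a", self.s_a, d_a, "s_a")
        else:
            # a_k | alpha, sigma — conjugate normal draw
            sum_alpha = st["re"] @ self.Mgd
            prec = self.n_per_drug / sigma[:, None] ** 2
            if not np.isinf(v):
                prec = prec + 1.0 / v
            mean = (sum_alpha / sigma[:, None] ** 2) / prec
            st["a"] = mean + self.rng.standard_normal(mean.shape) / np.sqrt(prec)

            # sigma² | alpha, a — truncated inverse-gamma draw
            if priors.sigma_fixed is None:
                G = m.n_groups
                dev = st["re"] - st["a"][:, m.group_drug]
                ss = np.sum(dev**2, axis=1)
                if G >= 2:
                    shape = (G - 1) / 2.0
                    upper = priors.sd_upper**2
                    cap = self.invgamma.cdf(upper, shape, scale=ss / 2.0)
                    q = self.rng.random(ss.shape) * cap
                    var = self.invgamma.ppf(q, shape, scale=ss / 2.0)
                    new = np.sqrt(var)
                    ok = np.isfinite(new) & (new > 0) & (new < priors.sd_upper)
                    st["sigma"] = np.where(ok, new, sigma)
                else:
                    def d_sig(cur, prop):
                        bad = (prop <= 0) | (prop >= priors.sd_upper)
                        safe = np.where(bad, 1.0, prop)
                        dev_ = st["re"] - st["a"][:, m.group_drug]
                        ssum = np.sum(dev_**2, axis=1)
                        d = (-0.5 * ssum / safe**2 - G * np.log(safe)
                             + 0.5 * ssum / cur**2 + G * np.log(cur))
                        return np.where(bad, -np.inf, d)

                    self._mh_scalar(st, "sigma", self.s_sigma, d_sig, "s_sigma")

        if adapt and (it + 1) % 50 == 0:
            self._adapt()


def _state_from_theta(model, theta: np.ndarray) -> dict:
    L, spec = model.layout, model.spec
    st = {"a": L.get(theta, "a").copy()}
    st["b"] = L.get(theta, "b")[:, 0].copy() if spec.mtx_adjust \
        else np.zeros(theta.shape[0])
    st["gamma"] = L.get(theta, "gamma")[:, 0].copy() if spec.covariate_gamma \
        else np.zeros(theta.shape[0])
    if model.priors.sigma_fixed is not None:
        st["sigma"] = np.full(theta.shape[0], model.priors.sigma_fixed)
    else:
        st["sigma"] = L.get(theta, "sigma")[:, 0].copy()
    if spec.likelihood == "binomial":
        st["mu"] = L.get(theta, "mu").copy()
    if not (model.priors.sigma_fixed == 0):
        st["re"] = L.get(theta, "re").copy()
    return st


def _theta_from_state(model, st: dict) -> np.ndarray:
    L, spec = model.layout, model.spec
    C = st["a"].shape[0]
    theta = np.zeros((C, model.ndim))
    theta[:, L.slices["a"]] = st["a"]
    if spec.mtx_adjust:
        theta[:, L.slices["b"]] = st["b"][:, None]
    if model.priors.sigma_fixed is None:
        theta[:, L.slices["sigma"]] = st["sigma"][:, None]
    if spec.likelihood == "binomial":
        theta[:, L.slices["mu"]] = st["mu"]
    if spec.covariate_gamma:
        theta[:, L.slices["gamma"]] = st["gamma"][:, None]
    if not (model.priors.sigma_fixed == 0):
        theta[:, L.slices["re"]] = st["re"]
    return theta


def _run_mwg(model, config: McmcConfig):
    """Blocked MWG chains; returns (draws, model-as-sampled)."""
    import copy

    if model.parameterization != "centered":
        model = copy.copy(model)
        model.parameterization = "centered"
    C = config.chains
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 987]))
    theta = _valid_initial(model, C, rng, config.init)
    st = _state_from_theta(model, theta)
    kernel = _BlockedMwg(model, rng)
    out = np.empty((C, config.samples, model.ndim))
    for it in range(config.burn_in + config.samples):
        kernel.sweep(st, adapt=it < config.burn_in, it=it)
        if it >= config.burn_in:
            out[:, it - config.burn_in] = _theta_from_state(model, st)
    return out, model


def run_mcmc(model, config: McmcConfig | None = None, **kw) -> PosteriorSamples:
    """Sample the posterior of a built model.

    Identical seed and configuration give bit-identical draws.
    """
    if config is None:
        config = McmcConfig(**kw)
    if config.sampler == "ensemble":
        chains, model_used = _run_ensemble(model, config)
    else:
        chains, model_used = _run_mwg(model, config)
    return _unpack(model_used, chains, config)


# ---------------------------------------------------------------------------
# diagnostics


def _as_idata(samples) -> az.InferenceData:
    if isinstance(samples, PosteriorSamples):
        return samples.to_inference_data()
    if isinstance(samples, az.InferenceData):
        return samples
    x = np.asarray(samples)
    if x.ndim == 1:
        x = x[None, :]
    return az.from_dict(posterior={"x": x})


def effective_sample_size(samples) -> dict[str, np.ndarray]:
    """Autocorrelation-based bulk ESS per parameter.

    Constant chains have no autocorrelation scale; their ESS is reported
    as NaN with a warning.
    """
    idata = _as_idata(samples)
    out = {}
    for name, da in idata.posterior.items():
        arr = da.values
        if np.allclose(arr.std(), 0):
            warnings.warn(f"{name}: constant chain, ESS undefined")
            out[name] = np.full(arr.shape[2:], np.nan)
            continue
        out[name] = np.asarray(az.ess(idata, var_names=[name])[name])
    return out


def rhat(samples) -> dict[str, np.ndarray]:
    """Split-chain potential scale reduction factor (≈1 at convergence)."""
    idata = _as_idata(samples)
    n_chains = idata.posterior.sizes["chain"]
    if n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    return {
        name: np.asarray(az.rhat(idata, var_names=[name])[name])
        for name in idata.posterior
    }
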