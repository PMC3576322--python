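"""Hierarchical mixed-treatment-comparison models for a star network.

The evidence structure is a set of placebo-controlled trials of K active
treatments (here the five anti-TNF agents).  Every active treatment k has a
*basic parameter* ``a_k`` — its pooled effect versus placebo — and any
pairwise comparison is a difference of basic parameters,
``IC_{k,l} = a_k − a_l``.

Two likelihoods are supported:

* **continuous** — each treatment arm j contributes its observed
  arm-vs-control difference Δ_j with sampling SE σ_j:

      Δ_j ~ N(α_{s(j),k} · λ_j + b · (I.t_j − I.c_{s(j)}),  σ_j²)

  where λ_j is the arm's baseline HAQ (the multiplier is optional: with it
  the basic parameters are *fractions of baseline*, without it plain
  differences), b is an additive effect of concurrent methotrexate, and
  α_{s,k} is the study-level true effect.

* **binomial** — responder counts with a logit link; each study's control
  arm enters once:

      r.c_s ~ Bin(n.c_s, p.c_s),   logit(p.c_s) = μ_s + b·I.c_s
      r.t_j ~ Bin(n.t_j, p.t_j),   logit(p.t_j) = μ_{s(j)} + b·I.t_j
                                                 + α_{s(j),k} [+ γ·λ_{s(j)}]

  Basic parameters are pooled log odds ratios.

In both cases the hierarchy is random effects between trials and fixed
effects within a trial: all arms of the same (study, drug) share one

      α_{s,k} ~ N(a_k, σ²)

and the between-trial SD σ is common to all comparisons.  Priors are vague
normals N(0, v) (default variance v = 10000) on a_k, b, μ_s and γ, and a
Uniform(0, u) prior (default u = 2) on σ.

:class:`MTCModel` is built from data plus a :class:`ModelSpec`, exposes the
joint log density both on natural parameters (:meth:`MTCModel.log_density`)
and on a flat vector for samplers, and its :meth:`MTCModel.fit` returns an
:class:`~ra_mtc.summaries.MTCResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit

from .trial_data import Contrast, Trial, ValidationError

_LOG_2PI = math.log(2 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant defines the joint density."""

    likelihood: str = "continuous"
    mtx_adjust: bool = True
    baseline_multiplier: bool = False
    covariate_gamma: bool = False
    treatments: tuple[str, ...] = ("P", "Ada", "Inf", "Eta", "Gol", "Cert")

    def __post_init__(self) -> None:
        if self.likelihood not in ("continuous", "binomial"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.baseline_multiplier and self.likelihood != "continuous":
            raise ValueError("baseline multiplier applies to the continuous model")
        if self.covariate_gamma and self.likelihood != "binomial":
            raise ValueError("baseline meta-regression applies to the binomial model")
        if self.treatments[0] != "P":
            raise ValueError("first treatment must be the placebo reference 'P'")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("duplicate treatments")

    @property
    def drugs(self) -> tuple[str, ...]:
        """Active treatments (reference excluded)."""
        return self.treatments[1:]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the vague priors.

    ``effect_variance`` is the variance of the N(0, v) prior on effects
    (``inf`` gives an improper flat prior); ``sd_upper`` the upper bound of
    the uniform prior on the between-trial SD.  ``sigma_fixed`` pins σ to a
    known value instead (0 collapses the hierarchy to common effects).
    """

    effect_variance: float = 10000.0
    sd_upper: float = 2.0
    sigma_fixed: float | None = None

    def __post_init__(self) -> None:
        if not self.effect_variance > 0:
            raise ValueError("effect_variance must be positive")
        if not self.sd_upper > 0:
            raise ValueError("sd_upper must be positive")
        if self.sigma_fixed is not None and self.sigma_fixed < 0:
            raise ValueError("sigma_fixed must be >= 0")


@dataclass
class ParameterSet:
    """Natural (centered) parameters of one point in parameter space."""

    a: np.ndarray                       # (K,) basic effects, spec.drugs order
    b: float = 0.0                      # additive MTX effect
    sigma: float | None = None          # between-trial SD
    mu: np.ndarray | None = None        # (S,) control-arm logits (binomial)
    gamma: float = 0.0                  # baseline meta-regression coefficient
    study_effects: np.ndarray | None = None  # (G,) α per (study, drug) group


class _Layout:
    """Flat-vector layout: name -> slice, in a fixed order."""

    def __init__(self, blocks: list[tuple[str, int]]):
        self.slices: dict[str, slice] = {}
        start = 0
        for name, size in blocks:
            self.slices[name] = slice(start, start + size)
            start += size
        self.size = start

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[..., self.slices[name]]


class MTCModel:
    """A mixed-treatment-comparison model bound to a dataset.

    Build with :meth:`from_contrasts` (continuous likelihood),
    :meth:`from_trials` (binomial likelihood on an ACR outcome) or
    :meth:`from_counts` (binomial likelihood on an arbitrary responder
    table, e.g. dichotomized HAQ).
    """

    def __init__(self, spec: ModelSpec, priors: PriorSpec | None = None,
                 parameterization: str = "noncentered"):
        if parameterization not in ("noncentered", "centered"):
            raise ValueError("parameterization must be 'noncentered' or 'centered'")
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.parameterization = parameterization
        self.n_drugs = len(spec.drugs)
        self._drug_index = {d: i for i, d in enumerate(spec.drugs)}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_contrasts(cls, contrasts: Sequence[Contrast], spec: ModelSpec,
                       priors: PriorSpec | None = None, **kw) -> "MTCModel":
        if spec.likelihood != "continuous":
            raise ValidationError("contrast data requires the continuous likelihood")
        self = cls(spec, priors, **kw)
        contrasts = list(contrasts)
        for c in contrasts:
            if c.drug not in self._drug_index:
                raise ValidationError(f"drug {c.drug!r} not in model spec")
        if spec.baseline_multiplier and any(c.baseline is None for c in contrasts):
            raise ValidationError("baseline multiplier requires baseline HAQ on every contrast")
        missing = set(spec.drugs) - {c.drug for c in contrasts}
        if contrasts and missing:
            raise ValidationError(f"no data for treatments {sorted(missing)}")
        groups: dict[tuple[str, str], int] = {}
        gidx, gdrug = [], []
        for c in contrasts:
            key = (c.trial_id, c.drug)
            if key not in groups:
                groups[key] = len(groups)
                gdrug.append(self._drug_index[c.drug])
            gidx.append(groups[key])
        self.contrasts = contrasts
        self.delta = np.array([c.delta_obs for c in contrasts])
        self.se = np.array([c.se for c in contrasts])
        self.lam = np.array([
            c.baseline if c.baseline is not None else 1.0 for c in contrasts
        ])
        self.mtx_diff = np.array([c.mtx_diff for c in contrasts], dtype=float)
        self.drug_idx = np.array([self._drug_index[c.drug] for c in contrasts])
        self.group_idx = np.array(gidx, dtype=int)
        self.group_drug = np.array(gdrug, dtype=int)
        self.group_labels = [f"{t}:{d}" for t, d in groups]
        self.n_groups = len(groups)
        self.n_studies = 0
        self.study_labels = []
        self._finalize()
        return self

    @classmethod
    def from_trials(cls, trials: Sequence[Trial], outcome: str, spec: ModelSpec,
                    priors: PriorSpec | None = None, **kw) -> "MTCModel":
        """Binomial model from trials, counts taken from the ACR fields."""
        if outcome not in ("acr20", "acr50", "acr70"):
            raise ValidationError(f"no responder counts stored for {outcome!r}")
        rows = []
        for t in trials:
            for a in t.arms:
                rows.append({
                    "trial_id": t.trial_id, "drug": a.drug, "n": a.n,
                    "r": getattr(a, outcome), "mtx": a.mtx,
                    "haq_baseline": a.haq_baseline,
                })
        return cls.from_counts(pd.DataFrame(rows), spec, priors, **kw)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, spec: ModelSpec,
                    priors: PriorSpec | None = None, **kw) -> "MTCModel":
        """Binomial model from a responder table.

        ``counts`` needs columns trial_id, drug, n, r, mtx and (for the
        meta-regression variant) haq_baseline; one placebo row per trial.
        Rows with a missing responder count are dropped.
        """
        if spec.likelihood != "binomial":
            raise ValidationError("count data requires the binomial likelihood")
        self = cls(spec, priors, **kw)
        df = counts.dropna(subset=["r"]).reset_index(drop=True)
        studies: dict[str, int] = {}
        r_c, n_c, i_c, lam_s = [], [], [], []
        for _, row in df[df["drug"] == "P"].iterrows():
            if row["trial_id"] in studies:
                raise ValidationError(f"{row['trial_id']}: duplicate placebo row")
            studies[row["trial_id"]] = len(studies)
            r_c.append(int(row["r"]))
            n_c.append(int(row["n"]))
            i_c.append(int(row["mtx"]))
            lam_s.append(float(row.get("haq_baseline", np.nan)))
        treat = df[df["drug"] != "P"]
        for d in treat["drug"]:
            if d not in self._drug_index:
                raise ValidationError(f"drug {d!r} not in model spec")
        missing = set(spec.drugs) - set(treat["drug"])
        if len(treat) and missing:
            raise ValidationError(f"no data for treatments {sorted(missing)}")
        groups: dict[tuple[str, str], int] = {}
        r_t, n_t, i_t, didx, sidx, gidx, gdrug = [], [], [], [], [], [], []
        for _, row in treat.iterrows():
            tid = row["trial_id"]
            if tid not in studies:
                raise ValidationError(f"{tid}: treatment arm without placebo row")
            key = (tid, row["drug"])
            if key not in groups:
                groups[key] = len(groups)
                gdrug.append(self._drug_index[row["drug"]])
            r_t.append(int(row["r"]))
            n_t.append(int(row["n"]))
            i_t.append(int(row["mtx"]))
            didx.append(self._drug_index[row["drug"]])
            sidx.append(studies[tid])
            gidx.append(groups[key])
        if spec.covariate_gamma and np.any(np.isnan(lam_s)):
            raise ValidationError("meta-regression requires baseline HAQ per study")
        self.r_c = np.array(r_c)
        self.n_c = np.array(n_c)
        self.i_c = np.array(i_c, dtype=float)
        self.lam_study = np.array(lam_s)
        self.r_t = np.array(r_t)
        self.n_t = np.array(n_t)
        self.i_t = np.array(i_t, dtype=float)
        self.drug_idx = np.array(didx)
        self.study_idx = np.array(sidx)
        self.group_idx = np.array(gidx)
        self.group_drug = np.array(gdrug, dtype=int)
        self.group_labels = [f"{t}:{d}" for t, d in groups]
        self.study_labels = list(studies)
        self.n_groups = len(groups)
        self.n_studies = len(studies)
        self._finalize()
        return self

    # -- layout -------------------------------------------------------------

    def _finalize(self) -> None:
        spec, priors = self.spec, self.priors
        blocks: list[tuple[str, int]] = [("a", self.n_drugs)]
        if spec.mtx_adjust:
            blocks.append(("b", 1))
        if priors.sigma_fixed is None:
            blocks.append(("sigma", 1))
        if spec.likelihood == "binomial":
            blocks.append(("mu", self.n_studies))
        if spec.covariate_gamma:
            blocks.append(("gamma", 1))
        if not (priors.sigma_fixed == 0):
            blocks.append(("re", self.n_groups))  # z (noncentered) or alpha
        self.layout = _Layout(blocks)
        self.ndim = self.layout.size
        # binomial normalizing constants (independent of parameters)
        if spec.likelihood == "binomial":
            self._lchoose = float(
                np.sum(gammaln(self.n_c + 1) - gammaln(self.r_c + 1)
                       - gammaln(self.n_c - self.r_c + 1))
                + np.sum(gammaln(self.n_t + 1) - gammaln(self.r_t + 1)
                         - gammaln(self.n_t - self.r_t + 1))
            )

    @property
    def param_names(self) -> list[str]:
        return list(self.layout.slices)

    # -- densities ----------------------------------------------------------

    def _sigma_of(self, ps: ParameterSet) -> float:
        if self.priors.sigma_fixed is not None:
            return self.priors.sigma_fixed
        if ps.sigma is None:
            raise ValueError("sigma required by this model")
        return ps.sigma

    def _alpha_of(self, ps: ParameterSet) -> np.ndarray:
        if self.priors.sigma_fixed == 0 or ps.study_effects is None:
            return np.asarray(ps.a)[self.group_drug]
        return np.asarray(ps.study_effects, dtype=float)

    def log_density(self, ps: ParameterSet) -> float:
        """Joint log density (likelihood + hierarchy + priors), natural scale.

        Evaluated on the centered parameters regardless of the sampling
        parameterization.  Binomial coefficients are included.
        """
        spec, priors = self.spec, self.priors
        a = np.asarray(ps.a, dtype=float)
        if a.shape != (self.n_drugs,):
            raise ValueError(f"a must have shape ({self.n_drugs},)")
        sigma = self._sigma_of(ps)
        alpha = self._alpha_of(ps)
        total = 0.0
        # likelihood
        if spec.likelihood == "continuous":
            mean = alpha[self.group_idx]
            if spec.baseline_multiplier:
                mean = mean * self.lam
            if spec.mtx_adjust:
                mean = mean + ps.b * self.mtx_diff
            z = (self.delta - mean) / self.se
            total += float(np.sum(-0.5 * z**2 - np.log(self.se) - 0.5 * _LOG_2PI))
        else:
            mu = np.asarray(ps.mu, dtype=float)
            logit_c = mu + (ps.b * self.i_c if spec.mtx_adjust else 0.0)
            logit_t = mu[self.study_idx] + alpha[self.group_idx]
            if spec.mtx_adjust:
                logit_t = logit_t + ps.b * self.i_t
            if spec.covariate_gamma:
                logit_t = logit_t + ps.gamma * self.lam_study[self.study_idx]
            total += float(
                np.sum(self.r_c * log_expit(logit_c)
                       + (self.n_c - self.r_c) * log_expit(-logit_c))
                + np.sum(self.r_t * log_expit(logit_t)
                         + (self.n_t - self.r_t) * log_expit(-logit_t))
                + self._lchoose
            )
            total += self._normal_logpdf_sum(mu)
        # hierarchy
        if not (priors.sigma_fixed == 0):
            if sigma <= 0:
                return -np.inf
            dev = (alpha - a[self.group_drug]) / sigma
            total += float(np.sum(-0.5 * dev**2 - math.log(sigma) - 0.5 * _LOG_2PI))
        # priors
        total += self._normal_logpdf_sum(a)
        if spec.mtx_adjust:
            total += self._normal_logpdf_sum(np.array([ps.b]))
        if spec.covariate_gamma:
            total += self._normal_logpdf_sum(np.array([ps.gamma]))
        if priors.sigma_fixed is None:
            if not 0 < sigma < priors.sd_upper:
                return -np.inf
            total += -math.log(priors.sd_upper)
        return total

    def _normal_logpdf_sum(self, x: np.ndarray) -> float:
        v = self.priors.effect_variance
        if np.isinf(v):
            return 0.0
        return float(np.sum(-0.5 * x**2 / v - 0.5 * math.log(v) - 0.5 * _LOG_2PI))

    # flat-vector density for samplers -------------------------------------

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior on the flat parameterization.

        ``theta`` has shape (..., ndim); the random-effects block holds
        standardized effects z (α = a_k + σ z) under the default
        non-centered parameterization, or α itself under the centered one.
        Returns log densities of shape (...,).
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        spec, priors = self.spec, self.priors
        L = self.layout
        a = L.get(theta, "a")
        b = L.get(theta, "b")[..., 0] if spec.mtx_adjust else 0.0
        gamma = L.get(theta, "gamma")[..., 0] if spec.covariate_gamma else 0.0
        out = np.zeros(theta.shape[0])
        if priors.sigma_fixed is not None:
            sigma = np.full(theta.shape[0], priors.sigma_fixed)
        else:
            sigma = L.get(theta, "sigma")[..., 0]
            bad = (sigma <= 0) | (sigma >= priors.sd_upper)
            out = np.where(bad, -np.inf, -math.log(priors.sd_upper))
            sigma = np.where(bad, 1.0, sigma)  # placeholder, masked later
        # random effects
        if priors.sigma_fixed == 0:
            alpha = a[:, self.group_drug]
        else:
            re = L.get(theta, "re")
            if self.parameterization == "noncentered":
                alpha = a[:, self.group_drug] + sigma[:, None] * re
                out += np.sum(-0.5 * re**2 - 0.5 * _LOG_2PI, axis=1)
            else:
                alpha = re
                dev = (alpha - a[:, self.group_drug]) / sigma[:, None]
                out += np.sum(-0.5 * dev**2 - 0.5 * _LOG_2PI, axis=1)
                out -= self.n_groups * np.log(sigma)
        # likelihood
        if spec.likelihood == "continuous":
            mean = alpha[:, self.group_idx]
            if spec.baseline_multiplier:
                mean = mean * self.lam
            if spec.mtx_adjust:
                mean = mean + np.outer(b, self.mtx_diff)
            z = (self.delta - mean) / self.se
            out += np.sum(-0.5 * z**2 - np.log(self.se) - 0.5 * _LOG_2PI, axis=1)
        else:
            mu = L.get(theta, "mu")
            logit_c = mu + (b[:, None] * self.i_c if spec.mtx_adjust else 0.0)
            logit_t = mu[:, self.study_idx] + alpha[:, self.group_idx]
            if spec.mtx_adjust:
                logit_t = logit_t + b[:, None] * self.i_t
            if spec.covariate_gamma:
                logit_t = logit_t + np.asarray(gamma)[:, None] \
                    * self.lam_study[self.study_idx]
            out += np.sum(self.r_c * log_expit(logit_c)
                          + (self.n_c - self.r_c) * log_expit(-logit_c), axis=1)
            out += np.sum(self.r_t * log_expit(logit_t)
                          + (self.n_t - self.r_t) * log_expit(-logit_t), axis=1)
            out += self._lchoose
            out += self._prior_quad(mu)
        # priors on effects
        out += self._prior_quad(a)
        if spec.mtx_adjust:
            out += self._prior_quad(b[:, None])
        if spec.covariate_gamma:
            out += self._prior_quad(np.asarray(gamma)[:, None])
        return out

    def _prior_quad(self, x: np.ndarray) -> np.ndarray:
        v = self.priors.effect_variance
        if np.isinf(v):
            return 0.0
        return np.sum(-0.5 * x**2 / v - 0.5 * math.log(v) - 0.5 * _LOG_2PI, axis=1)

    # -- initialization -----------------------------------------------------

    def initial_points(self, n: int, rng: np.random.Generator,
                       init: str = "default") -> np.ndarray:
        """Starting points: effects near 0, σ spread over its support,
        control logits near their empirical values, jittered per point."""
        L = self.layout
        theta = np.zeros((n, self.ndim))
        pr = self.priors
        if init == "prior":
            sd = math.sqrt(min(pr.effect_variance, 1e8))
            theta[:, L.slices["a"]] = rng.normal(0, sd, (n, self.n_drugs))
            if self.spec.mtx_adjust:
                theta[:, L.slices["b"]] = rng.normal(0, sd, (n, 1))
            if pr.sigma_fixed is None:
                theta[:, L.slices["sigma"]] = rng.uniform(0, pr.sd_upper, (n, 1))
            if self.spec.likelihood == "binomial":
                theta[:, L.slices["mu"]] = rng.normal(0, sd, (n, self.n_studies))
            if self.spec.covariate_gamma:
                theta[:, L.slices["gamma"]] = rng.normal(0, sd, (n, 1))
            if not (pr.sigma_fixed == 0):
                theta[:, L.slices["re"]] = rng.normal(0, 1, (n, self.n_groups))
            return theta
        emp_a, emp_g = self._empirical_effects()
        theta[:, L.slices["a"]] = emp_a + rng.normal(0, 0.2, (n, self.n_drugs))
        if self.spec.mtx_adjust:
            theta[:, L.slices["b"]] = rng.normal(0, 0.1, (n, 1))
        if pr.sigma_fixed is None:
            theta[:, L.slices["sigma"]] = rng.uniform(
                0.01 * pr.sd_upper, 0.5 * pr.sd_upper, (n, 1))
        if self.spec.likelihood == "binomial":
            emp = np.log((self.r_c + 0.5) / (self.n_c - self.r_c + 0.5))
            theta[:, L.slices["mu"]] = emp + rng.normal(0, 0.2, (n, self.n_studies))
        if self.spec.covariate_gamma:
            theta[:, L.slices["gamma"]] = rng.normal(0, 0.1, (n, 1))
        if not (pr.sigma_fixed == 0):
            if self.parameterization == "noncentered":
                theta[:, L.slices["re"]] = rng.normal(0, 1, (n, self.n_groups))
            else:
                theta[:, L.slices["re"]] = emp_g + rng.normal(
                    0, 0.1, (n, self.n_groups))
        return theta

    def _empirical_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """Crude per-drug and per-group effect estimates for initialization."""
        if self.spec.likelihood == "binomial":
            if len(self.r_t) == 0:
                return np.zeros(self.n_drugs), np.zeros(self.n_groups)
            lor_c = np.log((self.r_c + 0.5) / (self.n_c - self.r_c + 0.5))
            lor_t = np.log((self.r_t + 0.5) / (self.n_t - self.r_t + 0.5))
            per_arm = lor_t - lor_c[self.study_idx]
        else:
            if len(self.delta) == 0:
                return np.zeros(self.n_drugs), np.zeros(self.n_groups)
            per_arm = self.delta / (self.lam if self.spec.baseline_multiplier
                                    else 1.0)
        emp_g = np.array([
            per_arm[self.group_idx == g].mean() for g in range(self.n_groups)
        ]) if self.n_groups else np.zeros(0)
        emp_a = np.array([
            per_arm[self.drug_idx == k].mean() if np.any(self.drug_idx == k)
            else 0.0
            for k in range(self.n_drugs)
        ])
        return emp_a, emp_g

    # -- fitting ------------------------------------------------------------

    def fit(self, config=None, **kw):
        """Run MCMC and wrap the draws in an :class:`MTCResults`."""
        from .inference import McmcConfig, run_mcmc
        from .summaries import MTCResults

        if config is None:
            config = McmcConfig(**kw)
        elif kw:
            raise TypeError("pass either a config or keyword overrides, not both")
        samples = run_mcmc(self, config)
        return MTCResults(self, samples)


def build_model(data, spec: ModelSpec, priors: PriorSpec | None = None,
                outcome: str | None = None, **kw) -> MTCModel:
    """Dispatching constructor mirroring the two likelihoods.

    Contrast lists build the continuous model; trial lists (with
    ``outcome``) or responder tables build the binomial model.
    """
    data = list(data) if not isinstance(data, pd.DataFrame) else data
    if isinstance(data, pd.DataFrame):
        return MTCModel.from_counts(data, spec, priors, **kw)
    if data and isinstance(data[0], Contrast):
        if spec.likelihood == "binomial":
            raise ValidationError("binomial spec cannot be fit to contrast data")
        return MTCModel.from_contrasts(data, spec, priors, **kw)
    if data and isinstance(data[0], Trial):
        if spec.likelihood == "continuous":
            raise ValidationError(
                "build contrasts first for the continuous likelihood"
            )
        if outcome is None:
            raise ValueError("binomial model from trials needs an outcome")
        return MTCModel.from_trials(data, outcome, spec, priors, **kw)
    raise TypeError("data must be contrasts, trials, or a responder table")


def pairwise_contrast_fn(spec: ModelSpec):
    """Function mapping a ParameterSet to the full IC_{k,l} matrix.

    The matrix is indexed by ``spec.treatments`` (placebo first, a_P = 0);
    entry (k, l) is a_k − a_l, so it is antisymmetric and transitive by
    construction.
    """
    if len(spec.treatments) < 2:
        raise ValueError("need at least two treatments")

    def fn(ps: ParameterSet) -> np.ndarray:
        a_full = np.concatenate([[0.0], np.asarray(ps.a, dtype=float)])
        return a_full[:, None] - a_full[None, :]

    return fn
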