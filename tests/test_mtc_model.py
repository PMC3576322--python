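"""Model densities against independent term-by-term oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from ra_mtc.mtc_model import (
    ModelSpec,
    MTCModel,
    ParameterSet,
    PriorSpec,
    build_model,
    pairwise_contrast_fn,
)
from ra_mtc.trial_data import Arm, Contrast, ValidationError, group_arms, build_contrasts

# ---------------------------------------------------------------------------
# independent density oracles: plain loops over scipy.stats log-densities


def _group_order(items):
    seen = {}
    for key in items:
        if key not in seen:
            seen[key] = len(seen)
    return seen


def oracle_continuous(contrasts, spec, priors, ps):
    groups = _group_order([(c.trial_id, c.drug) for c in contrasts])
    total = 0.0
    for c in contrasts:
        alpha = ps.study_effects[groups[(c.trial_id, c.drug)]]
        mean = alpha * c.baseline if spec.baseline_multiplier else alpha
        if spec.mtx_adjust:
            mean += ps.b * c.mtx_diff
        total += stats.norm.logpdf(c.delta_obs, mean, c.se)
    for (tid, drug), g in groups.items():
        k = spec.drugs.index(drug)
        total += stats.norm.logpdf(ps.study_effects[g], ps.a[k], ps.sigma)
    sd0 = np.sqrt(priors.effect_variance)
    total += sum(stats.norm.logpdf(ai, 0, sd0) for ai in ps.a)
    if spec.mtx_adjust:
        total += stats.norm.logpdf(ps.b, 0, sd0)
    total += stats.uniform.logpdf(ps.sigma, 0, priors.sd_upper)
    return total


def oracle_binomial(trials, outcome, spec, priors, ps):
    studies = _group_order([t.trial_id for t in trials])
    groups = _group_order(
        [(t.trial_id, a.drug) for t in trials for a in t.treatment_arms])
    total = 0.0
    for t in trials:
        s = studies[t.trial_id]
        c = t.control_arm
        p_c = expit(ps.mu[s] + ps.b * c.mtx)
        total += stats.binom.logpmf(getattr(c, outcome), c.n, p_c)
        for a in t.treatment_arms:
            alpha = ps.study_effects[groups[(t.trial_id, a.drug)]]
            p_t = expit(ps.mu[s] + ps.b * a.mtx + alpha)
            total += stats.binom.logpmf(getattr(a, outcome), a.n, p_t)
    for (tid, drug), g in groups.items():
        k = spec.drugs.index(drug)
        total += stats.norm.logpdf(ps.study_effects[g], ps.a[k], ps.sigma)
    sd0 = np.sqrt(priors.effect_variance)
    total += sum(stats.norm.logpdf(ai, 0, sd0) for ai in ps.a)
    total += sum(stats.norm.logpdf(m, 0, sd0) for m in ps.mu)
    total += stats.norm.logpdf(ps.b, 0, sd0)
    total += stats.uniform.logpdf(ps.sigma, 0, priors.sd_upper)
    return total


def random_params(rng, n_drugs, n_groups, n_studies=0, scale=0.5):
    return ParameterSet(
        a=rng.normal(0, scale, n_drugs),
        b=float(rng.normal(0, scale)),
        sigma=float(rng.uniform(0.05, 1.5)),
        mu=rng.normal(-1, 0.5, n_studies) if n_studies else None,
        study_effects=rng.normal(0, scale, n_groups),
    )


class TestLogDensityOracle:
    def test_continuous_haq_model(self, haq_contrasts, rng):
        spec = ModelSpec(likelihood="continuous", baseline_multiplier=True)
        priors = PriorSpec()
        model = MTCModel.from_contrasts(haq_contrasts, spec, priors)
        for _ in range(5):
            ps = random_params(rng, 5, model.n_groups)
            expected = oracle_continuous(haq_contrasts, spec, priors, ps)
            assert model.log_density(ps) == pytest.approx(expected, abs=1e-10)

    def test_binomial_acr20_model(self, trials, rng):
        spec = ModelSpec(likelihood="binomial")
        priors = PriorSpec()
        model = MTCModel.from_trials(trials, "acr20", spec, priors)
        for _ in range(5):
            ps = random_params(rng, 5, model.n_groups, model.n_studies)
            expected = oracle_binomial(trials, "acr20", spec, priors, ps)
            assert model.log_density(ps) == pytest.approx(expected, abs=1e-10)

    def test_flat_sampler_density_matches_natural(self, haq_contrasts, rng):
        """The flat-vector density used by the samplers agrees with the
        natural-parameter density up to the (constant) Jacobian-free
        centered evaluation."""
        spec = ModelSpec(likelihood="continuous", baseline_multiplier=True)
        model = MTCModel.from_contrasts(haq_contrasts, spec,
                                        parameterization="centered")
        ps = random_params(rng, 5, model.n_groups)
        L = model.layout
        theta = np.zeros(model.ndim)
        theta[L.slices["a"]] = ps.a
        theta[L.slices["b"]] = ps.b
        theta[L.slices["sigma"]] = ps.sigma
        theta[L.slices["re"]] = ps.study_effects
        flat = model.log_posterior(theta[None, :])[0]
        # the flat density omits only the constant sigma-prior normalizer
        assert flat == pytest.approx(model.log_density(ps), abs=1e-8)

    def test_empty_data_is_prior_only(self):
        spec = ModelSpec(likelihood="continuous",
                         treatments=("P", "Ada"), mtx_adjust=False)
        priors = PriorSpec(effect_variance=100.0, sd_upper=2.0)
        model = MTCModel.from_contrasts([], spec, priors)
        ps = ParameterSet(a=np.array([0.5]), sigma=1.0,
                          study_effects=np.zeros(0))
        expected = stats.norm.logpdf(0.5, 0, 10) + stats.uniform.logpdf(1.0, 0, 2)
        assert model.log_density(ps) == pytest.approx(expected, abs=1e-12)

    def test_sigma_outside_support_is_minus_inf(self, haq_contrasts, rng):
        spec = ModelSpec(likelihood="continuous", baseline_multiplier=True)
        model = MTCModel.from_contrasts(haq_contrasts, spec)
        ps = random_params(rng, 5, model.n_groups)
        ps.sigma = 2.5
        assert model.log_density(ps) == -np.inf

    def test_density_vanishes_for_extreme_effects(self, haq_contrasts, rng):
        spec = ModelSpec(likelihood="continuous", baseline_multiplier=True)
        model = MTCModel.from_contrasts(haq_contrasts, spec)
        ps = random_params(rng, 5, model.n_groups)
        ref = model.log_density(ps)
        ps_far = ParameterSet(a=ps.a + 1e4, b=ps.b, sigma=ps.sigma,
                              study_effects=ps.study_effects)
        assert model.log_density(ps_far) < ref - 1e4


class TestModelStructure:
    def test_mtx_reduction_when_no_mismatch(self, rng):
        """With no MTX imbalance the adjusted model reduces to the plain
        one: likelihood identical, density differs only by b's prior."""
        arms = [
            Arm("T1", "P", 80, 1, 0.1, 0.5, haq_baseline=1.5),
            Arm("T1", "Ada", 80, 1, 0.4, 0.5, haq_baseline=1.5),
            Arm("T2", "P", 60, 1, 0.0, 0.4, haq_baseline=1.6),
            Arm("T2", "Eta", 60, 1, 0.3, 0.4, haq_baseline=1.6),
        ]
        contrasts = [c for t in group_arms(arms) for c in build_contrasts(t)]
        assert all(c.mtx_diff == 0 for c in contrasts)
        priors = PriorSpec()
        on = MTCModel.from_contrasts(
            contrasts, ModelSpec(treatments=("P", "Ada", "Eta")), priors)
        off = MTCModel.from_contrasts(
            contrasts,
            ModelSpec(treatments=("P", "Ada", "Eta"), mtx_adjust=False), priors)
        ps = random_params(rng, 2, 2)
        b_prior = stats.norm.logpdf(ps.b, 0, 100)
        assert on.log_density(ps) - b_prior == pytest.approx(
            off.log_density(ps), abs=1e-10)

    def test_treatment_relabeling_invariance(self, haq_contrasts, rng):
        """Permuting the treatment labels permutes a consistently."""
        spec1 = ModelSpec(likelihood="continuous", baseline_multiplier=True)
        perm = ("P", "Cert", "Eta", "Ada", "Inf", "Gol")
        spec2 = ModelSpec(likelihood="continuous", baseline_multiplier=True,
                          treatments=perm)
        m1 = MTCModel.from_contrasts(haq_contrasts, spec1)
        m2 = MTCModel.from_contrasts(haq_contrasts, spec2)
        ps1 = random_params(rng, 5, m1.n_groups)
        # permute a; study-effect groups are discovered in the same data
        # order in both models, so they carry over unchanged
        a2 = np.array([ps1.a[spec1.drugs.index(d)] for d in spec2.drugs])
        ps2 = ParameterSet(a=a2, b=ps1.b, sigma=ps1.sigma,
                           study_effects=ps1.study_effects)
        assert m1.log_density(ps1) == pytest.approx(
            m2.log_density(ps2), abs=1e-10)

    def test_unknown_drug_rejected(self):
        c = Contrast("T:1", "T", "Ada", 0.3, 0.1, 0, 1.5)
        with pytest.raises(ValidationError):
            MTCModel.from_contrasts([c], ModelSpec(treatments=("P", "Eta")))

    def test_binomial_spec_on_contrasts_rejected(self, haq_contrasts):
        with pytest.raises(ValidationError):
            build_model(haq_contrasts, ModelSpec(likelihood="binomial"))

    def test_baseline_multiplier_requires_continuous(self):
        with pytest.raises(ValueError):
            ModelSpec(likelihood="binomial", baseline_multiplier=True)

    def test_shared_control_groups(self, trials):
        """Multi-dose arms of one study share a single study effect."""
        model = MTCModel.from_trials(trials, "acr20", ModelSpec("binomial"))
        assert model.n_groups == 16  # one active drug per study in this network
        assert len(model.r_t) == 34


class TestPairwiseContrasts:
    def test_indirect_comparison_from_basic_effects(self):
        spec = ModelSpec()
        fn = pairwise_contrast_fn(spec)
        ps = ParameterSet(a=np.array([0.20, 0.10, 0.31, 0.23, 0.25]))
        ic = fn(ps)
        t = list(spec.treatments)
        assert ic[t.index("Inf"), t.index("Ada")] == pytest.approx(-0.10)
        assert ic[t.index("Ada"), t.index("P")] == pytest.approx(0.20)

    def test_self_comparison_zero(self, rng):
        fn = pairwise_contrast_fn(ModelSpec())
        ic = fn(ParameterSet(a=rng.normal(size=5)))
        assert np.allclose(np.diag(ic), 0)

    def test_antisymmetry_and_transitivity(self, rng):
        fn = pairwise_contrast_fn(ModelSpec())
        ic = fn(ParameterSet(a=rng.normal(size=5)))
        assert np.allclose(ic, -ic.T)
        for k, l, m in [(1, 2, 3), (0, 4, 2)]:
            assert ic[k, l] + ic[l, m] == pytest.approx(ic[k, m], abs=1e-12)
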