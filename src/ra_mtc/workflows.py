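"""End-to-end fitting recipes for each endpoint of the RA analysis.

One call takes arm-level trials to an :class:`~ra_mtc.summaries.MTCResults`
for a named outcome, applying the endpoint's preprocessing convention:

* ``haq`` — filter to trials reporting HAQ improvement in every arm,
  impute missing SDs with the dataset maximum, build contrasts, fit the
  continuous model with the baseline-HAQ multiplier (basic parameters are
  fractions of baseline).
* ``acrcont`` — reconstruct the continuous ACR response per arm, build
  contrasts, fit the continuous model without the multiplier (the measure
  is already relative to baseline).
* ``acr20/acr50/acr70`` — fit the binomial logit model to the reported
  responder counts of all complete trials.
* ``haq20/haq50`` — fit the binomial model to dichotomized-HAQ responder
  counts, either supplied (e.g. the bundled reference table) or
  regenerated from the continuous summaries.
"""

from __future__ import annotations

import pandas as pd

from . import outcome_transforms, trial_data
from .inference import McmcConfig
from .mtc_model import ModelSpec, MTCModel

CONTINUOUS = ("haq", "acrcont")
BINARY = ("acr20", "acr50", "acr70", "haq20", "haq50")


def _present_drugs(trials) -> tuple[str, ...]:
    seen = {a.drug for t in trials for a in t.treatment_arms}
    return ("P", *[d for d in trial_data.DRUGS[1:] if d in seen])


def build_outcome_model(
    trials,
    outcome: str,
    means_source: str = "meanACR",
    counts: pd.DataFrame | None = None,
    dichotomize_mode: str = "analytic",
    seed: int | None = None,
) -> MTCModel:
    """Assemble the MTC model for one outcome from arm-level trials."""
    if outcome == "haq":
        sel = trial_data.filter_trials(trials, "haq")
        sel, _ = trial_data.impute_missing_sd(sel)
        data = [c for t in sel for c in trial_data.build_contrasts(t, "haq")]
        spec = ModelSpec(likelihood="continuous", baseline_multiplier=True,
                         treatments=_present_drugs(sel))
        return MTCModel.from_contrasts(data, spec)
    if outcome == "acrcont":
        sel = trial_data.filter_trials(trials, "acrcont")
        data = outcome_transforms.acrcont_contrasts(sel, means_source)
        spec = ModelSpec(likelihood="continuous", treatments=_present_drugs(sel))
        return MTCModel.from_contrasts(data, spec)
    if outcome in ("acr20", "acr50", "acr70"):
        sel = trial_data.filter_trials(trials, outcome)
        spec = ModelSpec(likelihood="binomial", treatments=_present_drugs(sel))
        return MTCModel.from_trials(sel, outcome, spec)
    if outcome in ("haq20", "haq50"):
        sel = trial_data.filter_trials(trials, outcome)
        if counts is None:
            imputed, _ = trial_data.impute_missing_sd(sel)
            counts = outcome_transforms.transform_dataset(
                imputed, outcome, seed=seed, mode=dichotomize_mode)
        df = counts.rename(columns={outcome: "r"})
        spec = ModelSpec(likelihood="binomial", treatments=_present_drugs(sel))
        return MTCModel.from_counts(df, spec)
    raise ValueError(f"unknown outcome {outcome!r}")


def fit_outcome(trials, outcome: str, config: McmcConfig | None = None, **kw):
    """Fit one outcome end to end; returns an ``MTCResults``."""
    model = build_outcome_model(trials, outcome, **kw)
    return model.fit(config or McmcConfig())
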