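"""Bundled arm-level data for the rheumatoid-arthritis anti-TNF network.

Three small tables ship with the package:

``anti_tnf_trials``
    Arm-level summaries of 16 placebo-controlled RCTs of the five anti-TNF
    agents (adalimumab, infliximab, etanercept, golimumab, certolizumab) in
    methotrexate-experienced RA patients: sample sizes, mean (SD) HAQ
    improvement, nested ACR20/50/70 responder counts, baseline HAQ and a
    methotrexate co-medication flag.  ``-`` marks values the publications
    did not report.

``derived_outcomes``
    The derived per-arm endpoints used by the binary-vs-continuous power
    comparison: HAQ20/HAQ50 responder counts obtained by simulating 1000
    patient improvements per arm, and the reconstructed continuous ACR
    response (mean and SD).  Kept as a reference table; every column can be
    regenerated from ``anti_tnf_trials`` via :mod:`ra_mtc.outcome_transforms`.

``acr_group_means``
    Mean continuous-ACR improvement of the four nested response groups
    (non-responder, ACR20-only, ACR50-only, ACR70), estimated from an
    external patient-level cohort for treated patients (``meanACR`` and
    ``ACRhybrid`` rows) and taken as interval midpoints for control arms.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import trial_data

_PKG = "ra_mtc.datafiles"


def _path(name: str):
    return resources.files(_PKG).joinpath(name)


def anti_tnf_trials(as_frame: bool = False):
    """The 16-trial anti-TNF network (list of ``Trial`` or a DataFrame)."""
    with resources.as_file(_path("anti_tnf_trials.csv")) as p:
        trials = trial_data.load_trials(p)
    if as_frame:
        return trial_data.trials_to_frame(trials)
    return trials


def derived_outcomes() -> pd.DataFrame:
    """Reference table of derived endpoints, joined with mtx/baseline.

    Arms are matched to the trial table by position within (trial, drug);
    two high-dose arms of one trial are printed with transposed sample
    sizes in the reference table, so matching by ``n`` would mispair them.
    """
    with resources.as_file(_path("derived_outcomes.csv")) as p:
        df = pd.read_csv(p, na_values=[trial_data.MISSING_TOKEN])
    base = anti_tnf_trials(as_frame=True)
    for col in ("mtx", "haq_baseline", "haq_mean", "haq_sd"):
        df[col] = base[col].values
    df["n_trial_table"] = base["n"].values
    return df


def haq_responder_counts(outcome: str) -> pd.DataFrame:
    """Bundled dichotomized-HAQ responder counts, ready for model building.

    Returns one row per arm with the responder count of ``haq20`` or
    ``haq50`` and the sample size from the trial table (the reference
    table prints two sample sizes transposed; counts stay as printed).
    """
    if outcome not in ("haq20", "haq50"):
        raise ValueError(f"no bundled responder counts for {outcome!r}")
    df = derived_outcomes()
    out = df[["trial_id", "drug", "mtx", "haq_baseline", outcome]].copy()
    out["n"] = df["n_trial_table"]
    return out


def acr_group_means(source: str = "meanACR"):
    """Group means m₁..m₄ for one row of the bundled cohort table."""
    with resources.as_file(_path("acr_group_means.csv")) as p:
        df = pd.read_csv(p)
    row = df[df["source"] == source]
    if row.empty:
        raise KeyError(
            f"unknown group-means source {source!r}; choose from {list(df['source'])}"
        )
    return row[["m1", "m2", "m3", "m4"]].to_numpy(dtype=float)[0]
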