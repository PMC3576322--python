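"""Arm-level trial data: containers, validation, preprocessing.

The atomic record is an :class:`Arm` — one randomized arm of one trial with
its summary statistics (sample size, mean/SD of HAQ improvement, nested
ACR responder counts, baseline HAQ, methotrexate co-medication flag).
Trials bundle one placebo control arm with one or more active arms; for the
continuous models each active arm is reduced to a :class:`Contrast`
(arm-vs-control difference with its sampling standard error).

Missing summary statistics are represented by ``None`` (written as ``-`` in
the delimited files), never by zero.  The preprocessing rules are the
standard evidence-synthesis ones for published summaries: SDs estimated
from interquartile ranges by a normal approximation, remaining missing SDs
replaced by the maximum SD observed across the dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

#: Treatment coding: placebo reference plus the five anti-TNF agents.
DRUGS = ("P", "Ada", "Inf", "Eta", "Gol", "Cert")

#: Outcomes an analysis can be filtered on.
OUTCOMES = ("haq", "haq20", "haq50", "acr20", "acr50", "acr70", "acrcont")

#: Column layout of the arm-level delimited files.
COLUMNS = (
    "trial_id", "drug", "n", "mtx", "haq_mean", "haq_sd",
    "acr20", "acr50", "acr70", "haq_baseline",
)

MISSING_TOKEN = "-"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class Arm:
    """Summary statistics of a single trial arm.

    ``haq_mean``/``haq_sd`` are the mean and SD of the within-patient HAQ
    improvement (HAQ units, 0–3 scale); ``acr20/50/70`` are nested responder
    counts; ``haq_baseline`` is the arm's baseline HAQ (the λ multiplier of
    the continuous model); ``mtx`` flags concurrent methotrexate.
    """

    trial_id: str
    drug: str
    n: int
    mtx: int
    haq_mean: float | None = None
    haq_sd: float | None = None
    acr20: int | None = None
    acr50: int | None = None
    acr70: int | None = None
    haq_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(f"{self.trial_id}: unknown drug {self.drug!r}")
        if self.n < 1:
            raise ValidationError(f"{self.trial_id}/{self.drug}: n must be >= 1")
        if self.mtx not in (0, 1):
            raise ValidationError(f"{self.trial_id}/{self.drug}: mtx must be 0 or 1")
        if self.haq_sd is not None and self.haq_sd < 0:
            raise ValidationError(f"{self.trial_id}/{self.drug}: negative haq_sd")
        if self.haq_baseline is not None and not 0 <= self.haq_baseline <= 3:
            raise ValidationError(
                f"{self.trial_id}/{self.drug}: baseline HAQ outside [0, 3]"
            )
        counts = (self.acr70, self.acr50, self.acr20)
        if any(c is not None for c in counts):
            if any(c is None for c in counts):
                raise ValidationError(
                    f"{self.trial_id}/{self.drug}: partial ACR counts"
                )
            if not 0 <= self.acr70 <= self.acr50 <= self.acr20 <= self.n:
                raise ValidationError(
                    f"{self.trial_id}/{self.drug}: ACR counts not nested "
                    f"(need 0 <= ACR70 <= ACR50 <= ACR20 <= n, got "
                    f"{self.acr70}/{self.acr50}/{self.acr20}/{self.n})"
                )

    @property
    def is_control(self) -> bool:
        return self.drug == "P"

    def has_outcome(self, outcome: str) -> bool:
        """Whether this arm reports everything the given outcome needs."""
        if outcome in ("haq", "haq20", "haq50"):
            # SD may still be missing; it is imputable, the mean is not.
            return self.haq_mean is not None and self.haq_baseline is not None
        if outcome in ("acr20", "acr50", "acr70", "acrcont"):
            return self.acr20 is not None
        raise ValueError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class Trial:
    """One randomized trial: a placebo control arm plus active arms."""

    trial_id: str
    control_arm: Arm
    treatment_arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        if not self.control_arm.is_control:
            raise ValidationError(f"{self.trial_id}: control arm is not placebo")
        if not self.treatment_arms:
            raise ValidationError(f"{self.trial_id}: no treatment arms")
        for arm in self.arms:
            if arm.trial_id != self.trial_id:
                raise ValidationError(f"{self.trial_id}: arm from another trial")
        if any(a.is_control for a in self.treatment_arms):
            raise ValidationError(f"{self.trial_id}: more than one placebo arm")

    @property
    def arms(self) -> tuple[Arm, ...]:
        return (self.control_arm, *self.treatment_arms)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(a.drug for a in self.treatment_arms))


@dataclass(frozen=True)
class Contrast:
    """Arm-vs-control difference Δ_j with its sampling SE σ_j.

    ``mtx_diff`` is I.t − I.c ∈ {−1, 0, 1}; ``baseline`` is the treatment
    arm's baseline HAQ λ_j.  Contrasts sharing a control arm are treated as
    independent in the likelihood (the model's own simplification).
    """

    arm_ref: str
    trial_id: str
    drug: str
    delta_obs: float
    se: float
    mtx_diff: int
    baseline: float | None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.arm_ref}: SE must be positive")
        if self.mtx_diff not in (-1, 0, 1):
            raise ValidationError(f"{self.arm_ref}: mtx_diff outside {{-1,0,1}}")


# ---------------------------------------------------------------------------
# loading / writing


def _parse_cell(value, kind, row_label, column):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", MISSING_TOKEN):
            return None
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row_label}: cannot parse {column}={value!r}"
        ) from exc


def load_trials(path: str | Path, schema: dict[str, str] | None = None) -> list[Trial]:
    """Read a delimited arm-level table into validated :class:`Trial` objects.

    Parameters
    ----------
    path
        CSV/TSV file, one row per arm, columns as in :data:`COLUMNS`.
        ``-`` (or an empty cell) marks a missing value.
    schema
        Optional mapping from our column names to the file's column names.

    Row order is preserved; each trial must contain exactly one placebo arm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing_cols = set(COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"missing required columns: {sorted(missing_cols)}")
    return trials_from_frame(df)


def trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    """Build trials from a DataFrame with the :data:`COLUMNS` layout."""
    arms: list[Arm] = []
    for i, row in df.iterrows():
        label = f"{i + 1} ({row['trial_id']})"
        arms.append(Arm(
            trial_id=str(row["trial_id"]).strip(),
            drug=str(row["drug"]).strip(),
            n=_parse_cell(row["n"], int, label, "n"),
            mtx=_parse_cell(row["mtx"], int, label, "mtx"),
            haq_mean=_parse_cell(row["haq_mean"], float, label, "haq_mean"),
            haq_sd=_parse_cell(row["haq_sd"], float, label, "haq_sd"),
            acr20=_parse_cell(row["acr20"], int, label, "acr20"),
            acr50=_parse_cell(row["acr50"], int, label, "acr50"),
            acr70=_parse_cell(row["acr70"], int, label, "acr70"),
            haq_baseline=_parse_cell(row["haq_baseline"], float, label, "haq_baseline"),
        ))
    return group_arms(arms)


def group_arms(arms: Sequence[Arm]) -> list[Trial]:
    """Group a flat arm list into trials, preserving first-appearance order."""
    by_trial: dict[str, list[Arm]] = {}
    for arm in arms:
        by_trial.setdefault(arm.trial_id, []).append(arm)
    trials = []
    for trial_id, trial_arms in by_trial.items():
        controls = [a for a in trial_arms if a.is_control]
        if len(controls) != 1:
            raise ValidationError(
                f"{trial_id}: expected exactly one placebo arm, found {len(controls)}"
            )
        treatment = tuple(a for a in trial_arms if not a.is_control)
        trials.append(Trial(trial_id, controls[0], treatment))
    return trials


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Flatten trials back to the arm-level table (inverse of loading)."""
    rows = []
    for trial in trials:
        for arm in trial.arms:
            rows.append({c: getattr(arm, c) for c in COLUMNS})
    return pd.DataFrame(rows, columns=COLUMNS)


def write_trials(trials: Iterable[Trial], path: str | Path) -> None:
    df = trials_to_frame(trials)
    df = df.astype(object).where(pd.notna(df), MISSING_TOKEN)
    for col in ("n", "mtx", "acr20", "acr50", "acr70"):
        df[col] = [v if v == MISSING_TOKEN else int(v) for v in df[col]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def sd_from_iqr(iqr: float) -> float:
    """SD from an interquartile range under a normal approximation.

    For a normal distribution IQR = 2 z_{0.75} SD, so SD = IQR / 1.349.
    """
    if iqr < 0:
        raise ValueError("IQR must be non-negative")
    return iqr / (2 * stats.norm.ppf(0.75))


def impute_missing_sd(trials: Sequence[Trial]) -> tuple[list[Trial], list[dict]]:
    """Replace missing HAQ-improvement SDs by the maximum observed SD.

    Only arms that do report a mean improvement are imputed.  Returns the
    new trials and a report with one entry per imputed cell.
    """
    observed = [a.haq_sd for t in trials for a in t.arms if a.haq_sd is not None]
    if not observed:
        raise ValidationError("cannot impute SDs: no arm reports one")
    sd_max = max(observed)
    report: list[dict] = []

    def fix(arm: Arm) -> Arm:
        if arm.haq_mean is not None and arm.haq_sd is None:
            report.append(
                {"trial_id": arm.trial_id, "drug": arm.drug, "n": arm.n,
                 "imputed_sd": sd_max}
            )
            return replace(arm, haq_sd=sd_max)
        return arm

    out = [
        Trial(t.trial_id, fix(t.control_arm), tuple(fix(a) for a in t.treatment_arms))
        for t in trials
    ]
    return out, report


def build_contrasts(
    trial: Trial,
    outcome: str = "haq",
    values: dict[str, tuple[float, float]] | None = None,
) -> list[Contrast]:
    """Reduce a trial to arm-vs-control contrasts for a continuous outcome.

    ``delta_obs`` is treatment minus control mean improvement and
    ``se = sqrt(sd_t²/n_t + sd_c²/n_c)`` — the two-sample standard error of
    a difference in means.  Arms missing a mean are skipped with a warning;
    a missing SD is an error (impute first).

    ``values`` optionally supplies ``arm_ref -> (mean, sd)`` for derived
    continuous outcomes (e.g. reconstructed continuous ACR); otherwise the
    reported HAQ improvement summaries are used.
    """
    if outcome not in ("haq", "acrcont"):
        raise ValueError(f"unsupported continuous outcome {outcome!r}")

    def mean_sd(arm: Arm, ref: str) -> tuple[float | None, float | None]:
        if values is not None:
            return values.get(ref, (None, None))
        return arm.haq_mean, arm.haq_sd

    c_ref = arm_ref(trial, trial.control_arm)
    c_mean, c_sd = mean_sd(trial.control_arm, c_ref)
    contrasts: list[Contrast] = []
    if c_mean is None:
        warnings.warn(f"{trial.trial_id}: control arm has no mean; trial skipped")
        return contrasts
    if c_sd is None:
        raise ValidationError(f"{trial.trial_id}: control arm SD missing; impute first")
    for arm in trial.treatment_arms:
        ref = arm_ref(trial, arm)
        t_mean, t_sd = mean_sd(arm, ref)
        if t_mean is None:
            warnings.warn(f"{ref}: no mean reported; arm skipped")
            continue
        if t_sd is None:
            raise ValidationError(f"{ref}: SD missing; impute first")
        se = math.sqrt(t_sd**2 / arm.n + c_sd**2 / trial.control_arm.n)
        contrasts.append(Contrast(
            arm_ref=ref,
            trial_id=trial.trial_id,
            drug=arm.drug,
            delta_obs=t_mean - c_mean,
            se=se,
            mtx_diff=arm.mtx - trial.control_arm.mtx,
            baseline=arm.haq_baseline,
        ))
    return contrasts


def arm_ref(trial: Trial, arm: Arm) -> str:
    """Stable identifier of an arm: trial id plus position within the trial."""
    return f"{trial.trial_id}:{trial.arms.index(arm)}"


def filter_trials(trials: Sequence[Trial], outcome: str) -> list[Trial]:
    """Trials for which *every* arm reports the requested outcome."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    return [t for t in trials if all(a.has_outcome(outcome) for a in t.arms)]
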