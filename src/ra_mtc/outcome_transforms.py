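"""Measurement construction: binary ↔ continuous endpoint transforms.

Two procedures connect the continuous and binary endpoints of the
rheumatoid-arthritis analysis:

* **HAQ dichotomization** — an arm reporting mean (SD) HAQ improvement is
  turned into HAQ20/HAQ50 responder counts.  A patient responds when the
  improvement is at least 20% (50%) of the arm's baseline HAQ.  The
  reference procedure simulates 1000 normal patient improvements per arm
  and scales the responder proportion to the arm size; the analytic mode
  evaluates the same quantity in the infinite-draw limit with the normal
  CDF.

* **Continuous ACR reconstruction (ACRcont)** — nested ACR20/50/70 counts
  partition an arm into four response groups (non-responder, ACR20-only,
  ACR50-only, ACR70).  Given a mean continuous improvement m_i per group,
  the arm's ACRcont mean is the group-size weighted mean

      mean = (1/N) Σ N_i m_i

  and its SD is the population-form weighted spread

      sd = sqrt((1/N) Σ N_i (m_i − mean)²).

  Treatment arms use cohort-estimated group means (``meanACR`` by default,
  ``ACRhybrid`` as a sensitivity option); control arms use conservative
  interval midpoints (0.00, 0.35, 0.60, 0.85).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .trial_data import Arm, Contrast, ValidationError, arm_ref

_GROUP_SOURCES = ("meanACR", "ACRhybrid", "control")


@dataclass(frozen=True)
class GroupMeans:
    """Mean continuous-ACR response of the four nested response groups."""

    m: np.ndarray
    source: str

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "m", m)
        if m.shape != (4,):
            raise ValidationError("group means must be a 4-vector")
        if np.any(np.diff(m) < 0):
            raise ValidationError("group means must be non-decreasing")
        if np.any((m < -1) | (m > 1)):
            raise ValidationError("group means must lie in [-1, 1]")

    @classmethod
    def from_source(cls, source: str) -> "GroupMeans":
        if source not in _GROUP_SOURCES:
            raise KeyError(f"unknown group-means source {source!r}")
        return cls(datasets.acr_group_means(source), source)


@dataclass(frozen=True)
class GroupCounts:
    """Patient counts N₁..N₄ of the four response groups in one arm."""

    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=int)
        object.__setattr__(self, "n", n)
        if n.shape != (4,) or np.any(n < 0):
            raise ValidationError("group counts must be a non-negative 4-vector")

    @property
    def total(self) -> int:
        return int(self.n.sum())


def partition_acr_groups(arm: Arm) -> GroupCounts:
    """Split an arm's nested ACR counts into the four response groups."""
    if arm.acr20 is None:
        raise ValidationError(f"{arm.trial_id}/{arm.drug}: ACR counts missing")
    return GroupCounts(np.array([
        arm.n - arm.acr20,
        arm.acr20 - arm.acr50,
        arm.acr50 - arm.acr70,
        arm.acr70,
    ]))


def acrcont_mean(groups: GroupCounts, means: GroupMeans) -> float:
    """Group-size weighted mean continuous ACR response of an arm."""
    if groups.total == 0:
        raise ValueError("empty arm")
    return float(groups.n @ means.m / groups.total)


def acrcont_sd(groups: GroupCounts, means: GroupMeans) -> float:
    """Population-form (divide-by-N) weighted SD of the reconstruction."""
    mu = acrcont_mean(groups, means)
    return float(math.sqrt(groups.n @ (means.m - mu) ** 2 / groups.total))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * math.copysign(1, x))


def dichotomize_haq(
    arm: Arm,
    cutoff: float,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "analytic",
) -> int:
    """Responder count for a relative-improvement threshold (HAQ20/HAQ50).

    The response threshold is ``cutoff × baseline HAQ`` of the arm; a
    patient responds when the improvement is ≥ the threshold.  ``analytic``
    evaluates the normal tail probability exactly; ``montecarlo`` draws
    ``n_draws`` patient improvements (the reference procedure).  The
    proportion is scaled to the arm size and rounded half away from zero.
    """
    if arm.haq_baseline is None:
        raise ValidationError(f"{arm.trial_id}/{arm.drug}: baseline HAQ missing")
    if arm.haq_mean is None or arm.haq_sd is None:
        raise ValidationError(
            f"{arm.trial_id}/{arm.drug}: HAQ mean/SD missing (impute SDs first)"
        )
    threshold = cutoff * arm.haq_baseline
    if arm.haq_sd == 0:  # point mass
        prop = 1.0 if arm.haq_mean >= threshold else 0.0
    elif mode == "analytic":
        prop = float(stats.norm.sf(threshold, loc=arm.haq_mean, scale=arm.haq_sd))
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        draws = rng.normal(arm.haq_mean, arm.haq_sd, size=n_draws)
        prop = float(np.mean(draws >= threshold))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    count = _round_half_away(prop * arm.n)
    return min(max(count, 0), arm.n)


def transform_dataset(
    trials,
    target: str,
    means_source: str = "meanACR",
    control_source: str = "control",
    seed: int | None = None,
    mode: str = "analytic",
    n_draws: int = 1000,
) -> pd.DataFrame:
    """Apply a per-arm transform to every eligible arm of a dataset.

    ``target`` is ``haq20``, ``haq50`` or ``acrcont``.  Arms missing the
    required inputs yield missing outputs.  Monte-Carlo mode derives one
    independent child seed per arm from ``seed``, so the whole table is
    reproducible from a single integer.
    """
    if target not in ("haq20", "haq50", "acrcont"):
        raise ValueError(f"unknown target {target!r}")
    trials = list(trials)
    n_arms = sum(len(t.arms) for t in trials)
    arm_seeds = np.random.SeedSequence(seed).spawn(n_arms)
    rows = []
    i = 0
    for trial in trials:
        for arm in trial.arms:
            row = {
                "trial_id": trial.trial_id, "drug": arm.drug, "n": arm.n,
                "mtx": arm.mtx, "haq_baseline": arm.haq_baseline,
            }
            if target == "acrcont":
                if arm.acr20 is None:
                    row["acrcont_mean"] = np.nan
                    row["acrcont_sd"] = np.nan
                else:
                    source = control_source if arm.is_control else means_source
                    means = GroupMeans.from_source(source)
                    groups = partition_acr_groups(arm)
                    row["acrcont_mean"] = acrcont_mean(groups, means)
                    row["acrcont_sd"] = acrcont_sd(groups, means)
            else:
                cutoff = 0.2 if target == "haq20" else 0.5
                ok = (arm.haq_mean is not None and arm.haq_sd is not None
                      and arm.haq_baseline is not None)
                if not ok:
                    row[target] = np.nan
                else:
                    rng = np.random.default_rng(arm_seeds[i])
                    row[target] = dichotomize_haq(
                        arm, cutoff, n_draws=n_draws, seed=rng, mode=mode
                    )
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


def acrcont_contrasts(
    trials,
    means_source: str = "meanACR",
    control_source: str = "control",
) -> list[Contrast]:
    """Arm-vs-control contrasts on the reconstructed continuous ACR scale."""
    from .trial_data import build_contrasts  # local import to keep surface flat

    out: list[Contrast] = []
    for trial in trials:
        values = {}
        for arm in trial.arms:
            if arm.acr20 is None:
                continue
            source = control_source if arm.is_control else means_source
            means = GroupMeans.from_source(source)
            groups = partition_acr_groups(arm)
            values[arm_ref(trial, arm)] = (
                acrcont_mean(groups, means), acrcont_sd(groups, means)
            )
        out.extend(build_contrasts(trial, outcome="acrcont", values=values))
    return out
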