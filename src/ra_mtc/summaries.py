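"""Posterior reporting: pairwise comparisons, credible intervals, forest plots.

The reporting convention follows the analysis this package reproduces:
every ordered treatment pair is summarized by the posterior mean and an
80% equal-tailed credible interval, flagged significant when the interval
excludes the null (0 for differences, 1 for odds ratios).  Odds ratios are
summarized by exponentiating the log-odds-ratio draws draw-wise *before*
averaging, i.e. the posterior mean of the OR itself (note that
mean(exp(x)) > exp(mean(x))).  A final row summarizes the between-trial SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSamples, effective_sample_size, rhat


@dataclass(frozen=True)
class ComparisonSummary:
    """One pairwise treatment comparison on its reporting scale."""

    pair: tuple[str, str]          # (treatment k, comparator l)
    scale: str                     # "difference" | "odds_ratio" | "sd"
    mean: float
    lo80: float
    hi80: float
    significant: bool

    @property
    def label(self) -> str:
        return f"{self.pair[0]} vs {self.pair[1]}" if self.pair[1] else self.pair[0]


def credible_interval(draws, level: float = 0.8) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws."""
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("no draws")
    if draws.size < 100:
        raise ValueError("too few draws for a stable interval (need >= 100)")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1 - level) / 2
    lo, hi = np.quantile(draws, [tail, 1 - tail])
    return float(lo), float(hi)


def _pairs(drugs: tuple[str, ...]) -> list[tuple[str, str]]:
    """Reporting order: each drug vs placebo, then later-vs-earlier pairs."""
    out = [(d, "P") for d in drugs]
    for i, k in enumerate(drugs):
        for l in drugs[:i]:
            out.append((k, l))
    return out


def summarize_comparisons(
    samples: PosteriorSamples, spec=None, level: float = 0.8
) -> list[ComparisonSummary]:
    """All pairwise comparisons plus the between-trial SD row.

    Difference scale summarizes a_k − a_l draws directly; the odds-ratio
    scale exponentiates the LOR draws draw-wise first.  Significance means
    the equal-tailed interval excludes the null.
    """
    spec = spec if spec is not None else samples.spec
    if "a" not in samples.draws:
        raise KeyError("samples do not contain basic parameters 'a'")
    a = samples.stacked("a")  # (draws, K)
    index = {d: i for i, d in enumerate(spec.drugs)}
    odds = spec.likelihood == "binomial"
    scale = "odds_ratio" if odds else "difference"
    null = 1.0 if odds else 0.0
    out = []
    for k, l in _pairs(spec.drugs):
        diff = a[:, index[k]] - (a[:, index[l]] if l != "P" else 0.0)
        rep = np.exp(diff) if odds else diff
        lo, hi = credible_interval(rep, level)
        out.append(ComparisonSummary(
            pair=(k, l), scale=scale, mean=float(rep.mean()),
            lo80=lo, hi80=hi, significant=bool(lo > null or hi < null),
        ))
    if "sigma" in samples.draws:
        sig = samples.stacked("sigma")
        lo, hi = credible_interval(sig, level)
        out.append(ComparisonSummary(
            pair=("sigma", ""), scale="sd", mean=float(sig.mean()),
            lo80=lo, hi80=hi, significant=False,
        ))
    return out


def comparisons_frame(summaries: list[ComparisonSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"comparison": s.label, "scale": s.scale, "mean": s.mean,
         "lo80": s.lo80, "hi80": s.hi80, "significant": s.significant}
        for s in summaries
    ])


def forest_export(summaries: list[ComparisonSummary], path, format: str = "csv"):
    """Write comparisons as CSV or render a forest plot.

    Odds-ratio panels are drawn on a log axis; significant comparisons are
    drawn in red.
    """
    if not summaries:
        raise ValueError("nothing to export")
    if format == "csv":
        comparisons_frame(summaries).to_csv(path, index=False)
        return path
    if format != "plot":
        raise ValueError(f"unknown format {format!r}")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rows = [s for s in summaries if s.scale != "sd"]
    odds = rows[0].scale == "odds_ratio"
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.2))
    for y, s in enumerate(reversed(rows)):
        color = "red" if s.significant else "black"
        ax.plot([s.lo80, s.hi80], [y, y], color=color, lw=1.5)
        ax.plot([s.mean], [y], "o", color=color, ms=4)
    ax.axvline(1.0 if odds else 0.0, color="grey", lw=0.8, ls="--")
    if odds:
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (80% CrI)")
    else:
        ax.set_xlabel("difference (80% CrI)")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([s.label for s in reversed(rows)], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


class MTCResults:
    """Fit results: posterior draws plus reporting helpers."""

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def spec(self):
        return self.model.spec

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.samples.stacked(name).mean(axis=0)

    def basic_effect(self, drug: str) -> np.ndarray:
        """Posterior draws of a_{drug,P} (log-odds scale for binomial)."""
        idx = {d: i for i, d in enumerate(self.spec.drugs)}[drug]
        return self.samples.stacked("a")[:, idx]

    def contrast_draws(self, k: str, l: str = "P") -> np.ndarray:
        """Draws of IC_{k,l} = a_k − a_l on the linear (log-odds) scale."""
        d = self.basic_effect(k)
        if l != "P":
            d = d - self.basic_effect(l)
        return d

    def comparisons(self, level: float = 0.8) -> pd.DataFrame:
        return comparisons_frame(summarize_comparisons(self.samples, self.spec, level))

    def summary(self, level: float = 0.8) -> str:
        """Text table of all pairwise comparisons and diagnostics."""
        df = self.comparisons(level).copy()
        for c in ("mean", "lo80", "hi80"):
            df[c] = df[c].map(lambda v: f"{v:.2f}")
        df["significant"] = np.where(df["significant"], "*", "")
        diag = self.diagnostics()
        lines = [
            f"MTC results ({self.spec.likelihood} likelihood, "
            f"{self.samples.n_chains} chains x {self.samples.n_draws} draws)",
            df.to_string(index=False),
            f"min ESS {diag['ess'].min():.0f}, max R-hat {diag['rhat'].max():.3f}",
        ]
        return "\n".join(lines)

    def diagnostics(self) -> pd.DataFrame:
        """Bulk ESS and split R-hat per scalar parameter component."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = effective_sample_size(self.samples)
            rh = rhat(self.samples)
        rows = []
        for name in ess:
            e, r = np.atleast_1d(ess[name]), np.atleast_1d(rh[name])
            labels = self.samples.coords.get(name, [""] * e.size)
            for lab, ei, ri in zip(labels, e.ravel(), r.ravel()):
                rows.append({
                    "parameter": f"{name}[{lab}]" if lab else name,
                    "ess": ei, "rhat": ri,
                })
        return pd.DataFrame(rows)

    def forest_plot(self, path, level: float = 0.8):
        return forest_export(
            summarize_comparisons(self.samples, self.spec, level), path, "plot"
        )

    def to_csv(self, path, level: float = 0.8):
        return forest_export(
            summarize_comparisons(self.samples, self.spec, level), path, "csv"
        )
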