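"""Posterior summaries of divergence dates and evolutionary rates.

Node ages are summarised as mean, sample SD and central 95% credibility
interval per clade (clades are matched by taxon set, so summaries are
robust to node renumbering).  Per-taxon rates come from terminal-branch
effective rates; group contrasts report the ratio of group means with a
two-tailed Welch t test, and dating schemes are compared by ordinary least
squares on shared-clade mean ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mcmc import PosteriorTrace

__all__ = [
    "CladeAgeSummary",
    "DatingResult",
    "RateTable",
    "ComparisonStats",
    "summarize_node_ages",
    "terminal_rates",
    "group_rate_contrast",
    "compare_dating_schemes",
]


@dataclass
class CladeAgeSummary:
    clade: FrozenSet[str]
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float

    def __str__(self) -> str:
        # Table convention: mean +/- SD [upper-lower]
        return (
            f"{self.mean:.0f} ± {self.sd:.0f}"
            f"[{self.ci_upper:.0f}–{self.ci_lower:.0f}]"
        )


@dataclass
class DatingResult:
    clock: str
    entries: Dict[FrozenSet[str], CladeAgeSummary]

    def mean_ages(self) -> Dict[FrozenSet[str], float]:
        return {c: e.mean for c, e in self.entries.items()}

    def to_frame(self, names: Optional[Dict[FrozenSet[str], str]] = None):
        import pandas as pd

        rows = []
        for clade, e in self.entries.items():
            rows.append(
                {
                    "clade": (names or {}).get(clade, ",".join(sorted(clade)[:3]) + ("..." if len(clade) > 3 else "")),
                    "n_taxa": len(clade),
                    "mean": e.mean,
                    "sd": e.sd,
                    "ci_lower": e.ci_lower,
                    "ci_upper": e.ci_upper,
                }
            )
        return pd.DataFrame(rows).sort_values("mean", ascending=False)


def summarize_node_ages(
    trace: PosteriorTrace, burnin: Optional[int] = None
) -> DatingResult:
    """Mean, sample SD and central 95% CI of each internal clade's age."""
    if trace.mode != "chronogram" or trace.ages is None:
        raise ValueError("need a chronogram-mode trace with age samples")
    sl = trace.retained(burnin)
    ages = trace.ages[sl]
    if ages.shape[0] < 2:
        raise ValueError("need at least two retained samples")
    entries: Dict[FrozenSet[str], CladeAgeSummary] = {}
    for idx, clade in enumerate(trace.clades):
        if clade is None or len(clade) < 2:
            continue
        col = ages[:, idx]
        lo, hi = np.percentile(col, [2.5, 97.5])
        entries[clade] = CladeAgeSummary(
            clade,
            float(col.mean()),
            float(col.std(ddof=1)),
            float(lo),
            float(hi),
        )
    return DatingResult(trace.model_name, entries)


@dataclass
class RateTable:
    """Posterior mean terminal-branch rate per taxon (subs/site/Mya)."""

    rates: Dict[str, float]
    groups: Dict[str, str] = field(default_factory=dict)

    def group_values(self, group: str) -> np.ndarray:
        return np.array(
            [r for t, r in self.rates.items() if self.groups.get(t) == group]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "taxon": list(self.rates),
                "rate": list(self.rates.values()),
                "group": [self.groups.get(t, "") for t in self.rates],
            }
        )


def terminal_rates(
    trace: PosteriorTrace,
    burnin: Optional[int] = None,
    groups: Optional[Dict[str, str]] = None,
) -> RateTable:
    """Posterior mean effective rate of each terminal branch."""
    if trace.mode != "chronogram" or trace.branch_rates is None:
        raise ValueError("terminal rates require a chronogram-mode trace")
    sl = trace.retained(burnin)
    rates = trace.branch_rates[sl]
    out: Dict[str, float] = {}
    for idx, name in enumerate(trace.leaf_names):
        if name is None:
            continue
        out[name] = float(rates[:, idx].mean())
    if any(r <= 0 for r in out.values()):
        raise ValueError("non-positive terminal rate in trace")
    return RateTable(out, dict(groups or {}))


@dataclass
class ComparisonStats:
    ratio: Optional[float] = None
    t_stat: Optional[float] = None
    p_value: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    note: str = ""


def group_rate_contrast(
    table: RateTable,
    group_a: Iterable[str],
    group_b: Iterable[str],
    *,
    equal_var: bool = False,
) -> ComparisonStats:
    """Ratio of group mean rates with a two-tailed t test (Welch default).

    A singleton group yields the ratio only, with an explanatory note (a
    two-sample t test is not applicable to one observation).
    """
    a = np.array([table.rates[t] for t in group_a])
    b = np.array([table.rates[t] for t in group_b])
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ratio = float(a.mean() / b.mean())
    if a.size < 2 or b.size < 2:
        return ComparisonStats(
            ratio=ratio, note="t test not applicable with a single-taxon group"
        )
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonStats(ratio=ratio, t_stat=float(t_stat), p_value=float(p))


def compare_dating_schemes(
    result_a: DatingResult,
    result_b: DatingResult,
    clades: Optional[Sequence[FrozenSet[str]]] = None,
) -> ComparisonStats:
    """OLS of scheme B mean ages on scheme A over shared clades (R2, slope).

    ``clades`` optionally restricts the comparison to a clade subset (e.g.
    vertebrates only).
    """
    mean_a = result_a.mean_ages()
    mean_b = result_b.mean_ages()
    shared = set(mean_a) & set(mean_b)
    if clades is not None:
        shared &= set(clades)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared clades for a regression")
    keys = sorted(shared, key=lambda c: sorted(c))
    x = np.array([mean_a[c] for c in keys])
    y = np.array([mean_b[c] for c in keys])
    fit = stats.linregress(x, y)
    return ComparisonStats(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
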