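"""Population-level statistics over fiber ratio measurements.

The workhorse comparison is Cliff's delta — the probability that a ratio
drawn from one condition exceeds one drawn from the other, minus the
reverse — with a seeded percentile-bootstrap confidence interval.  A
condition differs significantly from the reference when its 95% interval
excludes zero.  The reference condition, unless given explicitly, is the
one whose median ratio sits at the midpoint of all condition medians, and
its median normalizes every condition's median.  Classical tests are also
exposed: the two-sided Mann-Whitney U test on ratio distributions (exact
for small untied samples, normal approximation with tie correction
otherwise) and the Pearson chi-square test on structure-type counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size of x over y, in [-1, 1].

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), computed in
    O((n_x + n_y) log n_y) via a sorted scan rather than explicit pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (y.size - np.searchsorted(ys, x, side="right")).sum()
    return float((greater - less) / (x.size * y.size))


def bootstrap_delta_ci(
    x,
    y,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for Cliff's delta.

    Both samples are resampled independently with replacement ``n_boot``
    times; the interval is the central ``level`` percentile range of the
    resampled deltas.  Fully determined by ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = np.sort(y[rng.integers(0, y.size, y.size)])
        greater = np.searchsorted(yb, xb, side="left").sum()
        less = (y.size - np.searchsorted(yb, xb, side="right")).sum()
        deltas[b] = (greater - less) / (x.size * y.size)
    tail = (1.0 - level) / 2.0
    lo, hi = np.percentile(deltas, [100 * tail, 100 * (1 - tail)])
    return float(lo), float(hi)


def select_reference(conditions: dict[str, np.ndarray]) -> str:
    """Condition whose median ratio is the midpoint of all condition medians."""
    if not conditions:
        raise ValueError("no conditions")
    medians = sorted(
        (float(np.median(np.asarray(v, dtype=float))), name)
        for name, v in conditions.items()
    )
    return medians[(len(medians) - 1) // 2][1]


@dataclass
class ConditionTable:
    """Per-condition ratio samples with a designated reference condition."""

    conditions: dict[str, np.ndarray]
    reference: str | None = None
    grader: str = ""

    def __post_init__(self) -> None:
        self.conditions = {
            k: np.asarray(v, dtype=float) for k, v in self.conditions.items()
        }
        if any(v.size == 0 for v in self.conditions.values()):
            raise ValueError("every condition needs at least one value")
        if self.reference is None:
            self.reference = select_reference(self.conditions)
        elif self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not among conditions")


def compare_to_reference(
    table: ConditionTable,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect size of every condition against the reference.

    One row per condition: median, median normalized by the reference
    median, Cliff's delta with its bootstrap CI, and a significance flag
    (CI excludes zero).  The reference row carries delta 0 and is never
    significant.
    """
    ref = table.conditions[table.reference]
    ref_median = float(np.median(ref))
    rows = []
    for i, (name, values) in enumerate(sorted(table.conditions.items())):
        med = float(np.median(values))
        if name == table.reference:
            delta, lo, hi = 0.0, 0.0, 0.0
        else:
            delta = cliffs_delta(values, ref)
            lo, hi = bootstrap_delta_ci(
                values, ref, n_boot=n_boot, level=level, seed=seed + i
            )
        rows.append(
            {
                "condition": name,
                "n": int(values.size),
                "median": med,
                "normalized_median": med / ref_median if ref_median else float("nan"),
                "delta": delta,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "reference": name == table.reference,
            }
        )
    return pd.DataFrame(rows)


def grader_disagreement(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Flag conditions where exactly one grader calls a significant difference."""
    a = report_a.set_index("condition")["significant"]
    b = report_b.set_index("condition")["significant"]
    common = a.index.intersection(b.index)
    return pd.DataFrame(
        {
            "condition": common,
            "significant_a": a[common].to_numpy(),
            "significant_b": b[common].to_numpy(),
            "disagree": (a[common] ^ b[common]).to_numpy(),
        }
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic for x over y, p-value).

    Uses exact enumeration for small untied samples and the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = min(x.size, y.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_types(counts_a, counts_b) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k table of structure-type counts."""
    obs = np.array([counts_a, counts_b], dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("need two count vectors over >= 2 types")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; merge sparse structure categories and retry"
        )
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def swarm_plot(
    table: ConditionTable,
    out_path,
    seed: int = 0,
    point_size: float = 6.0,
) -> None:
    """Save a jittered per-fiber ratio plot with condition medians.

    Requires matplotlib (optional dependency); conditions are ordered by
    median, the reference drawn in red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    names = sorted(table.conditions, key=lambda n: np.median(table.conditions[n]))
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    for i, name in enumerate(names):
        vals = table.conditions[name]
        x = i + rng.uniform(-0.25, 0.25, vals.size)
        color = "crimson" if name == table.reference else "steelblue"
        ax.scatter(x, vals, s=point_size, alpha=0.5, color=color, linewidths=0)
        ax.hlines(np.median(vals), i - 0.3, i + 0.3, color="black", lw=2)
    ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
    ax.set_ylabel("IdU/CldU ratio")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def type1_error_rate(
    n_per_condition: int = 200,
    replicates: int = 200,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Bootstrap-CI false-positive rate when both conditions share a distribution.

    Draws both samples from the same log-normal ratio distribution and
    reports how often the delta CI excludes zero — a calibration smoke test
    for the significance rule.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(replicates):
        x = np.exp(rng.normal(np.log(1.2), 0.4, n_per_condition))
        y = np.exp(rng.normal(np.log(1.2), 0.4, n_per_condition))
        lo, hi = bootstrap_delta_ci(
            x, y, n_boot=n_boot, level=level, seed=int(rng.integers(2**31))
        )
        if lo > 0 or hi < 0:
            hits += 1
    return hits / replicates
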