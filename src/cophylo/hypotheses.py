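"""Randomization null distributions and codivergence test statistics.

The statistical layer mirrors how cophylogeny tools are used in practice:
the observed reconciliation cost (or event count) is compared against the
same quantity recomputed under randomized tip associations, keeping both
tree topologies fixed.  Three statistics are provided:

* a one-sided z-test with a safety margin: is the mean randomized cost at
  least ``margin`` (default 5%) higher than the real cost?
* the relative cophylogeny cost: real cost divided by the median randomized
  cost (0 for perfect cophylogeny, 1 -- i.e. 100% -- for none);
* event-count ratios (cospeciation, host switch) between real and
  randomized associations, aggregated over bootstrap replicates and all
  rootings, with permutation p-values.

Two randomization modes exist.  ``target_permutation`` shuffles the
independent-tip targets among dependent tips (preserving the target
multiset); ``host_tip_renaming`` applies a uniform random permutation of
the full independent tip-label set to the targets (preserving the
association structure).  The latter is the default for the event-ratio
test, the former for cost nulls.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .reconcile import (
    COREPA_REWARD_COSTS,
    EventCosts,
    Reconciliation,
    reconcile,
)
from .treeio import AssociationTable, PhyloTree, TreeSet, enumerate_rootings

__all__ = [
    "NullDistribution",
    "CosegTestResult",
    "EventRatioResult",
    "randomize_associations",
    "cost_null",
    "margin_z_test",
    "relative_cost",
    "relative_cost_percent",
    "event_ratio_test",
    "paired_cost_comparison",
]

RANDOMIZATION_MODES = ("target_permutation", "host_tip_renaming")


@dataclass
class NullDistribution:
    """Real cost plus the costs of N randomized-association reconciliations."""

    real_cost: float
    randomized_costs: np.ndarray
    N: int
    seed: int
    randomization_mode: str

    def __post_init__(self):
        self.randomized_costs = np.asarray(self.randomized_costs, dtype=float)
        if self.N < 1 or len(self.randomized_costs) != self.N:
            raise ValidationError(
                "randomized_costs length must equal N >= 1")

    def sorted_costs(self) -> np.ndarray:
        """Randomized costs sorted ascending (cumulative-curve convention)."""
        return np.sort(self.randomized_costs)


@dataclass
class CosegTestResult:
    """Outcome of the margin z-test plus the relative cost statistic."""

    z_statistic: float
    p_value: float
    margin: float
    significant: bool
    relative_cost_percent: float | None
    degenerate: bool = False


@dataclass
class EventRatioResult:
    """Real/randomized event-count ratios across replicates and rootings.

    Count matrices are retained in full: ``real_*`` has shape
    (n_trees, n_rootings) and ``randomized_*`` (n_trees, n_rootings, N),
    so any alternative aggregation can be recomputed.
    """

    cospeciation_ratio: float
    switch_ratio: float
    p_cospeciation: float
    p_switch: float
    real_cospeciation: np.ndarray
    real_switch: np.ndarray
    randomized_cospeciation: np.ndarray
    randomized_switch: np.ndarray
    n_randomizations: int
    seed: int


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def randomize_associations(assoc: AssociationTable, mode: str,
                           seed: int) -> AssociationTable:
    """Return a randomized copy of an association table (seed-deterministic).

    ``target_permutation`` permutes the multiset of independent-tip targets
    among the dependent tips; ``host_tip_renaming`` draws one uniform
    permutation of the independent tip labels and applies it to the targets.
    """
    if mode not in RANDOMIZATION_MODES:
        raise ValidationError(
            f"unknown randomization mode {mode!r}; "
            f"expected one of {RANDOMIZATION_MODES}")
    rng = random.Random(seed)
    deps = list(assoc.dependents)
    targets = list(assoc.targets)
    if mode == "target_permutation":
        rng.shuffle(targets)
        new_pairs = tuple(zip(deps, targets))
    else:
        universe = list(assoc.independent_labels
                        if assoc.independent_labels
                        else sorted(set(targets)))
        renamed = universe[:]
        rng.shuffle(renamed)
        rename = dict(zip(universe, renamed))
        new_pairs = tuple((d, rename[t]) for d, t in zip(deps, targets))
    return AssociationTable(pairs=new_pairs,
                            independent_labels=assoc.independent_labels,
                            missing_dependents=assoc.missing_dependents)


def cost_null(ind: PhyloTree, dep: PhyloTree, assoc: AssociationTable,
              costs: EventCosts, N: int, mode: str = "target_permutation",
              seed: int = 0) -> NullDistribution:
    """Reconciliation cost of the real association vs N randomized ones."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    real = reconcile(ind, dep, assoc, costs).total_cost
    randomized = np.empty(N, dtype=float)
    for i in range(N):
        r_assoc = randomize_associations(assoc, mode, seed + i)
        randomized[i] = reconcile(ind, dep, r_assoc, costs).total_cost
    return NullDistribution(real_cost=real, randomized_costs=randomized,
                            N=N, seed=seed, randomization_mode=mode)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def margin_z_test(nd: NullDistribution, margin: float = 0.05,
                  alpha: float = 0.05) -> CosegTestResult:
    """One-sided z-test: are randomized costs > (1 + margin) x real cost?

    z = (mean(null) - (1+margin) * real) / (sd(null) / sqrt(N)); the p-value
    is the upper normal tail.  The margin guards against declaring
    significance on minuscule cost differences.  Zero-variance nulls are
    handled as flagged degenerate cases.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    if nd.N < 2:
        raise ValidationError("margin_z_test requires N >= 2")
    rc = nd.randomized_costs
    mean = float(np.mean(rc))
    sd = float(np.std(rc, ddof=1))
    threshold = (1.0 + margin) * nd.real_cost
    rel = _relative_percent_or_none(nd)
    if sd == 0.0:
        if np.all(rc > threshold):
            return CosegTestResult(math.inf, 0.0, margin, True, rel,
                                   degenerate=True)
        return CosegTestResult(0.0 if mean == nd.real_cost else -math.inf,
                               1.0, margin, False, rel, degenerate=True)
    z = (mean - threshold) / (sd / math.sqrt(nd.N))
    p = float(stats.norm.sf(z))
    return CosegTestResult(z, p, margin, p < alpha, rel)


def _relative_percent_or_none(nd: NullDistribution) -> float | None:
    try:
        return relative_cost_percent(nd)
    except DegenerateStatisticError:
        return None


def relative_cost(nd: NullDistribution) -> float:
    """Real cost / median randomized cost: 0 = perfect cophylogeny, 1 = none."""
    med = float(np.median(nd.randomized_costs))
    if med == 0.0:
        raise DegenerateStatisticError(
            "relative cophylogeny cost undefined: median randomized cost is 0")
    return nd.real_cost / med

def relative_cost_percent(nd: NullDistribution) -> float:
    """:func:`relative_cost` expressed as a percentage."""
    return 100.0 * relative_cost(nd)


def event_ratio_test(ind: PhyloTree, dep_trees: TreeSet,
                     assoc: AssociationTable,
                     costs: EventCosts = COREPA_REWARD_COSTS,
                     n_randomizations: int = 100,
                     seed: int = 0) -> EventRatioResult:
    """Cospeciation / host-switch count ratios over rootings x replicates.

    Every dependent tree (unrooted) is rooted on every edge; each rooted
    version is reconciled with the real association and with
    ``n_randomizations`` host-tip-renaming randomizations (one renaming per
    iteration, shared across all cells).  Ratios are means of real counts
    over means of randomized counts; the permutation p-value for each ratio
    is (1 + #{randomized iteration mean >= real mean}) / (1 + N).
    """
    if n_randomizations < 1:
        raise ValidationError("n_randomizations must be >= 1")
    rand_assocs = [
        randomize_associations(assoc, "host_tip_renaming", seed + i)
        for i in range(n_randomizations)
    ]
    per_tree_rootings = []
    for t in dep_trees:
        if t.rooted:
            raise ValidationError(
                "event_ratio_test expects unrooted dependent trees")
        per_tree_rootings.append(enumerate_rootings(t))
    n_root = len(per_tree_rootings[0])
    if any(len(r) != n_root for r in per_tree_rootings):
        raise ValidationError(
            "all dependent trees must yield the same number of rootings")
    J = len(dep_trees)
    real_c = np.zeros((J, n_root))
    real_s = np.zeros((J, n_root))
    rand_c = np.zeros((J, n_root, n_randomizations))
    rand_s = np.zeros((J, n_root, n_randomizations))
    for j, rootings in enumerate(per_tree_rootings):
        for k, rt in enumerate(rootings):
            rec = reconcile(ind, rt, assoc, costs)
            real_c[j, k] = rec.n_cospeciation
            real_s[j, k] = rec.n_switch
            for i, ra in enumerate(rand_assocs):
                rr = reconcile(ind, rt, ra, costs)
                rand_c[j, k, i] = rr.n_cospeciation
                rand_s[j, k, i] = rr.n_switch
    mean_real_c = float(real_c.mean())
    mean_real_s = float(real_s.mean())
    iter_means_c = rand_c.mean(axis=(0, 1))
    iter_means_s = rand_s.mean(axis=(0, 1))
    mean_rand_c = float(iter_means_c.mean())
    mean_rand_s = float(iter_means_s.mean())
    ratio_c = mean_real_c / mean_rand_c if mean_rand_c != 0 else math.inf
    ratio_s = mean_real_s / mean_rand_s if mean_rand_s != 0 else math.inf
    p_c = (1 + int(np.sum(iter_means_c >= mean_real_c))) / \
        (1 + n_randomizations)
    p_s = (1 + int(np.sum(iter_means_s >= mean_real_s))) / \
        (1 + n_randomizations)
    return EventRatioResult(
        cospeciation_ratio=ratio_c, switch_ratio=ratio_s,
        p_cospeciation=p_c, p_switch=p_s,
        real_cospeciation=real_c, real_switch=real_s,
        randomized_cospeciation=rand_c, randomized_switch=rand_s,
        n_randomizations=n_randomizations, seed=seed)


def paired_cost_comparison(costs_a, costs_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired cost vectors."""
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired cost vectors must have equal length")
    if len(a) < 5:
        raise ValidationError("paired comparison requires length >= 5")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
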