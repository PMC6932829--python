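"""Event-based cophylogeny reconciliation.

Maps a dependent tree (virus, or a genome segment) onto an independent tree
(host, or the RdRp reference segment) under the classical four-event grammar:

* cospeciation -- a dependent node tracks a split of its host node, its two
  children descending into the two host child subtrees;
* duplication  -- a dependent node splits with both children staying at or
  below the current host node;
* host switch  -- one child stays at or below the current host node, the
  other jumps to a host node incomparable to it (untimed transfer model);
* loss (sorting) -- charged once per host edge descended while placing a
  child below its parent's host node.

The model is the untimed vertex-mapping formulation: a polynomial dynamic
program over (dependent node, host node) pairs.  Event costs may be negative
(reward semantics, e.g. cospeciation -1000 / switch -0.001 with sorting and
duplication at 0); the loss cost must be non-negative, which keeps the
recurrences bounded below.

``reconcile_bruteforce`` is an independent exhaustive oracle over all
placements of dependent internal nodes, used to verify the DP on small
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import SizeGuardError, ValidationError
from .treeio import AssociationTable, PhyloTree

__all__ = [
    "EventCosts",
    "Reconciliation",
    "reconcile",
    "reconcile_bruteforce",
    "count_events",
    "JANE_DEFAULT_COSTS",
    "COREPA_REWARD_COSTS",
]

_INF = math.inf


@dataclass(frozen=True)
class EventCosts:
    """Per-event costs; negative values are rewards, loss must be >= 0."""

    cospeciation: float
    duplication: float
    switch: float
    loss: float

    def __post_init__(self):
        for name in ("cospeciation", "duplication", "switch", "loss"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} cost must be finite, got {v}")
        if self.loss < 0:
            raise ValidationError("loss cost must be non-negative")

    def as_tuple(self) -> tuple:
        return (self.cospeciation, self.duplication, self.switch, self.loss)


#: costs assumed for the Jane-style cost-curve analyses
JANE_DEFAULT_COSTS = EventCosts(0.0, 1.0, 2.0, 1.0)
#: reward scheme used for the CoRe-PA-style event-count analyses
COREPA_REWARD_COSTS = EventCosts(-1000.0, 0.0, -0.001, 0.0)


@dataclass
class Reconciliation:
    """Optimal event-labeled mapping of the dependent tree onto the host."""

    total_cost: float
    n_cospeciation: int
    n_duplication: int
    n_switch: int
    n_loss: int
    node_map: dict
    costs: EventCosts
    optimal: bool = True

    @property
    def counts(self) -> tuple:
        return (self.n_cospeciation, self.n_duplication,
                self.n_switch, self.n_loss)

    def to_json_dict(self) -> dict:
        return {
            "total_cost": self.total_cost,
            "counts": {
                "cospeciation": self.n_cospeciation,
                "duplication": self.n_duplication,
                "switch": self.n_switch,
                "loss": self.n_loss,
            },
            "costs": {
                "cospeciation": self.costs.cospeciation,
                "duplication": self.costs.duplication,
                "switch": self.costs.switch,
                "loss": self.costs.loss,
            },
            "node_map": self.node_map,
            "optimal": self.optimal,
        }

    def event_table(self) -> list:
        """Rows (dependent_node, host_node, event) for TSV export."""
        return [(d, v["host"], v["event"])
                for d, v in sorted(self.node_map.items())]


def count_events(r: Reconciliation) -> tuple:
    """(n_cospeciation, n_switch, n_duplication, n_loss) of a reconciliation."""
    return (r.n_cospeciation, r.n_switch, r.n_duplication, r.n_loss)


# ---------------------------------------------------------------------------
# Host indexing
# ---------------------------------------------------------------------------

class _HostIndex:
    """Preorder-indexed arrays for the host tree.

    Node i's subtree occupies the contiguous index range [i, i + size[i]),
    which makes descendant/ancestor tests O(1).
    """

    __slots__ = ("n", "left", "right", "depth", "size", "tip_index", "ids")

    def __init__(self, tree: PhyloTree):
        if not tree.rooted:
            raise ValidationError("independent tree must be rooted")
        tree.validate(require_binary=True)
        nodes = list(tree.preorder())
        self.n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.left = [-1] * self.n
        self.right = [-1] * self.n
        self.depth = [0] * self.n
        self.size = [1] * self.n
        self.tip_index = {}
        self.ids = [None] * self.n
        for i, nd in enumerate(nodes):
            if nd.is_tip:
                self.tip_index[nd.label] = i
                self.ids[i] = nd.label
            else:
                self.ids[i] = f"node{i}"
                self.left[i] = index[id(nd.children[0])]
                self.right[i] = index[id(nd.children[1])]
            if nd.parent is not None:
                p = index[id(nd.parent)]
                self.depth[i] = self.depth[p] + 1
        for i in range(self.n - 1, 0, -1):
            if self.left[i] >= 0:
                self.size[i] = 1 + self.size[self.left[i]] + \
                    self.size[self.right[i]]
        if self.left[0] >= 0:
            self.size[0] = self.n


def _check_dep(dep: PhyloTree) -> None:
    if not dep.rooted:
        raise ValidationError("dependent tree must be rooted")
    dep.validate(require_binary=True)


# ---------------------------------------------------------------------------
# Dynamic program
# ---------------------------------------------------------------------------

def reconcile(ind: PhyloTree, dep: PhyloTree, assoc: AssociationTable,
              costs: EventCosts) -> Reconciliation:
    """Minimum-cost reconciliation of ``dep`` onto ``ind``.

    Deterministic: ties are broken cospeciation > duplication > switch, and
    among host nodes by smallest preorder index.  The returned total cost is
    the event-count identity sum (it equals the DP optimum).
    """
    H = _HostIndex(ind)
    _check_dep(dep)
    mapping = assoc.mapping
    cc, cd, cs, cl = costs.as_tuple()
    M = H.n
    left, right, size, depth = H.left, H.right, H.size, H.depth

    store: dict = {}
    for p in dep.postorder():
        if p.is_tip:
            if p.label not in mapping:
                raise ValidationError(
                    f"dependent tip {p.label!r} has no association entry")
            target = mapping[p.label]
            if target not in H.tip_index:
                raise ValidationError(
                    f"association target {target!r} is not a tip of the "
                    "independent tree")
            C = [_INF] * M
            C[H.tip_index[target]] = 0.0
        else:
            a, b = p.children
            _, INa, OUTa = store[id(a)]
            _, INb, OUTb = store[id(b)]
            C = [0.0] * M
            for h in range(M):
                ia = INa[h]
                ib = INb[h]
                v = cd + ia + ib
                s1 = ia + OUTb[h]
                s2 = ib + OUTa[h]
                sv = cs + (s1 if s1 <= s2 else s2)
                if sv < v:
                    v = sv
                l = left[h]
                if l >= 0:
                    r = right[h]
                    c1 = INa[l] + INb[r]
                    c2 = INa[r] + INb[l]
                    cv = cc + (c1 if c1 <= c2 else c2)
                    if cv < v:
                        v = cv
                C[h] = v
        # IN[h]: cheapest placement at-or-below h, charging loss per edge
        # BEST[h]: cheapest C over the subtree of h (no loss charge)
        IN = C[:]
        BEST = C[:]
        for h in range(M - 1, -1, -1):
            l = left[h]
            if l >= 0:
                r = right[h]
                m = IN[l] if IN[l] <= IN[r] else IN[r]
                m += cl
                if m < IN[h]:
                    IN[h] = m
                bb = BEST[l] if BEST[l] <= BEST[r] else BEST[r]
                if bb < BEST[h]:
                    BEST[h] = bb
        # OUT[h]: cheapest C over nodes incomparable to h
        OUT = [_INF] * M
        for h in range(M):
            l = left[h]
            if l >= 0:
                r = right[h]
                o = OUT[h]
                OUT[l] = o if o <= BEST[r] else BEST[r]
                OUT[r] = o if o <= BEST[l] else BEST[l]
        store[id(p)] = (C, IN, OUT)

    Croot = store[id(dep.root)][0]
    best = min(Croot)
    if best == _INF:
        raise ValidationError("no feasible reconciliation (check associations)")
    h_root = Croot.index(best)

    counts = [0, 0, 0, 0]  # cosp, dup, switch, loss
    node_map: dict = {}
    dep_ids = {}
    for i, nd in enumerate(dep.preorder()):
        dep_ids[id(nd)] = nd.label if nd.is_tip else f"node{i}"

    def trace_in(x, s):
        Cx = store[id(x)][0]
        base = depth[s]
        bh, bv = -1, _INF
        for h2 in range(s, s + size[s]):
            val = Cx[h2] + cl * (depth[h2] - base)
            if val < bv:
                bv, bh = val, h2
        counts[3] += depth[bh] - base
        assign(x, bh)

    def trace_out(x, h):
        Cx = store[id(x)][0]
        bh, bv = -1, _INF
        for h2 in range(M):
            if h <= h2 < h + size[h]:
                continue  # descendant of h (or h itself)
            if h2 <= h < h2 + size[h2]:
                continue  # ancestor of h
            if Cx[h2] < bv:
                bv, bh = Cx[h2], h2
        assign(x, bh)

    def assign(p, h):
        if p.is_tip:
            node_map[dep_ids[id(p)]] = {"host": H.ids[h], "event": "tip"}
            return
        a, b = p.children
        Cp, _, _ = store[id(p)]
        _, INa, OUTa = store[id(a)]
        _, INb, OUTb = store[id(b)]
        target = Cp[h]
        l = left[h]
        if l >= 0:
            r = right[h]
            c1 = INa[l] + INb[r]
            c2 = INa[r] + INb[l]
            if cc + (c1 if c1 <= c2 else c2) == target:
                node_map[dep_ids[id(p)]] = {"host": H.ids[h],
                                            "event": "cospeciation"}
                counts[0] += 1
                if c1 <= c2:
                    trace_in(a, l)
                    trace_in(b, r)
                else:
                    trace_in(a, r)
                    trace_in(b, l)
                return
        if cd + INa[h] + INb[h] == target:
            node_map[dep_ids[id(p)]] = {"host": H.ids[h],
                                        "event": "duplication"}
            counts[1] += 1
            trace_in(a, h)
            trace_in(b, h)
            return
        s1 = INa[h] + OUTb[h]
        s2 = INb[h] + OUTa[h]
        if cs + (s1 if s1 <= s2 else s2) == target:
            node_map[dep_ids[id(p)]] = {"host": H.ids[h], "event": "switch"}
            counts[2] += 1
            if s1 <= s2:
                trace_in(a, h)
                trace_out(b, h)
            else:
                trace_in(b, h)
                trace_out(a, h)
            return
        raise RuntimeError(  # pragma: no cover - internal consistency
            "traceback failed to reproduce the DP optimum")

    assign(dep.root, h_root)

    total = (counts[0] * cc + counts[1] * cd +
             counts[2] * cs + counts[3] * cl)
    if not math.isclose(total, best, rel_tol=1e-9, abs_tol=1e-9):
        raise RuntimeError(  # pragma: no cover - internal consistency
            f"cost identity violated: {total} != DP optimum {best}")
    return Reconciliation(
        total_cost=total,
        n_cospeciation=counts[0], n_duplication=counts[1],
        n_switch=counts[2], n_loss=counts[3],
        node_map=node_map, costs=costs, optimal=True)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def reconcile_bruteforce(ind: PhyloTree, dep: PhyloTree,
                         assoc: AssociationTable,
                         costs: EventCosts) -> Reconciliation:
    """Exhaustive enumeration over all internal-node placements.

    Independent of the DP: every assignment of dependent internal nodes to
    host nodes is enumerated; for each node the cheapest feasible event
    label given its children's placements is charged.  Guarded to dep <= 6
    and ind <= 7 tips.
    """
    if dep.n_tips > 6 or ind.n_tips > 7:
        raise SizeGuardError(
            "brute force guarded to dep<=6 and ind<=7 tips")
    H = _HostIndex(ind)
    _check_dep(dep)
    mapping = assoc.mapping
    cc, cd, cs, cl = costs.as_tuple()
    M = H.n
    size, depth, left, right = H.size, H.depth, H.left, H.right

    place: dict = {}
    for t in dep.tips():
        if t.label not in mapping:
            raise ValidationError(
                f"dependent tip {t.label!r} has no association entry")
        target = mapping[t.label]
        if target not in H.tip_index:
            raise ValidationError(
                f"association target {target!r} is not a tip of the "
                "independent tree")
        place[id(t)] = H.tip_index[target]

    internals = [n for n in dep.postorder() if not n.is_tip]
    if not internals:
        tip = dep.root
        node_map = {tip.label: {"host": H.ids[place[id(tip)]],
                                "event": "tip"}}
        return Reconciliation(0.0, 0, 0, 0, 0, node_map, costs)

    def event_options(h, ha, hb):
        """Cheapest feasible (cost, event, losses) at host h, or None."""
        best = None
        l = left[h]
        if l >= 0:
            r = right[h]
            a_in_l = l <= ha < l + size[l]
            b_in_r = r <= hb < r + size[r]
            a_in_r = r <= ha < r + size[r]
            b_in_l = l <= hb < l + size[l]
            if a_in_l and b_in_r:
                losses = (depth[ha] - depth[l]) + (depth[hb] - depth[r])
                best = (cc + cl * losses, "cospeciation", losses)
            elif a_in_r and b_in_l:
                losses = (depth[ha] - depth[r]) + (depth[hb] - depth[l])
                best = (cc + cl * losses, "cospeciation", losses)
        a_below = h <= ha < h + size[h]
        b_below = h <= hb < h + size[h]
        if a_below and b_below:
            losses = (depth[ha] - depth[h]) + (depth[hb] - depth[h])
            cand = (cd + cl * losses, "duplication", losses)
            if best is None or cand[0] < best[0]:
                best = cand
        a_inc = not a_below and not (ha <= h < ha + size[ha])
        b_inc = not b_below and not (hb <= h < hb + size[hb])
        if a_below and b_inc:
            losses = depth[ha] - depth[h]
            cand = (cs + cl * losses, "switch", losses)
            if best is None or cand[0] < best[0]:
                best = cand
        if b_below and a_inc:
            losses = depth[hb] - depth[h]
            cand = (cs + cl * losses, "switch", losses)
            if best is None or cand[0] < best[0]:
                best = cand
        return best

    best_cost = [_INF]
    best_counts = [(0, 0, 0, 0)]
    best_place = [None]
    K = len(internals)

    def recurse(i, acc, k_c, k_d, k_s, k_l):
        if i == K:
            if acc < best_cost[0]:
                best_cost[0] = acc
                best_counts[0] = (k_c, k_d, k_s, k_l)
                best_place[0] = {k: v for k, v in place.items()}
            return
        p = internals[i]
        a, b = p.children
        ha = place[id(a)]
        hb = place[id(b)]
        for h in range(M):
            opt = event_options(h, ha, hb)
            if opt is None:
                continue
            cost, ev, losses = opt
            place[id(p)] = h
            dc = 1 if ev == "cospeciation" else 0
            dd = 1 if ev == "duplication" else 0
            ds = 1 if ev == "switch" else 0
            recurse(i + 1, acc + cost, k_c + dc, k_d + dd,
                    k_s + ds, k_l + losses)
        place.pop(id(p), None)

    recurse(0, 0.0, 0, 0, 0, 0)
    if best_cost[0] == _INF:
        raise ValidationError("no feasible reconciliation (brute force)")

    k_c, k_d, k_s, k_l = best_counts[0]
    node_map = {}
    dep_ids = {}
    for i, nd in enumerate(dep.preorder()):
        dep_ids[id(nd)] = nd.label if nd.is_tip else f"node{i}"
    for nd in dep.preorder():
        h = best_place[0].get(id(nd))
        if h is not None:
            node_map[dep_ids[id(nd)]] = {
                "host": H.ids[h],
                "event": "tip" if nd.is_tip else "placed"}
    total = k_c * cc + k_d * cd + k_s * cs + k_l * cl
    return Reconciliation(total, k_c, k_d, k_s, k_l, node_map, costs)
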