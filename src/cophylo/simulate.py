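"""Synthetic cophylogenies with known event histories.

The generator propagates virus lineages along a host tree under the same
four-event grammar the reconciliation solver uses, so ground-truth recovery
tests are well defined:

* at each host speciation the lineage cospeciates with probability
  ``p_cospeciation``; otherwise it follows one child uniformly (a loss on
  the other side);
* along each host edge, host switches and duplications occur as Poisson
  draws (``switch_rate``, ``duplication_rate``); a switching lineage splits,
  one copy jumping to a uniformly chosen host node incomparable to the
  current position (untimed transfer, mirroring the solver's model);
* ``loss_rate`` is a per-edge Poisson extinction rate; a fully extinct
  virus tree triggers bounded resampling.

Every decision is logged; :func:`replay_event_log` rebuilds the virus tree
from the log alone, which the test suite uses as a consistency oracle.
Companion generators produce genome-segment tree pairs with a controlled
number of reassortment events (modeled as leaf-position exchanges) and
bootstrap-style sets of NNI-perturbed unrooted trees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .treeio import AssociationTable, Node, PhyloTree, TreeSet

__all__ = [
    "CophyloSimParams",
    "SimulatedDataset",
    "simulate_host_tree",
    "simulate_cophylogeny",
    "simulate_segment_pair",
    "simulate_bootstrap_set",
    "replay_event_log",
]


@dataclass(frozen=True)
class CophyloSimParams:
    """Generative parameters for one simulated cophylogeny.

    Defaults describe a strongly codiverging association (the regime the
    real virus-host data supported): 16 host tips, 90% cospeciation
    probability per host speciation, rare switches and duplications
    (0.05 expected events per host edge), no extinction, one virus lineage.
    """

    n_host_tips: int = 16
    p_cospeciation: float = 0.9
    switch_rate: float = 0.05
    duplication_rate: float = 0.05
    loss_rate: float = 0.0
    viruses_per_host: int = 1
    seed: int = 0
    max_attempts: int = 100

    def __post_init__(self):
        if self.n_host_tips < 2:
            raise ValidationError("n_host_tips must be >= 2")
        if not 0.0 <= self.p_cospeciation <= 1.0:
            raise ValidationError("p_cospeciation must be in [0, 1]")
        for name in ("switch_rate", "duplication_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.viruses_per_host < 1:
            raise ValidationError("viruses_per_host must be >= 1")
        if self.max_attempts < 1:
            raise ValidationError("max_attempts must be >= 1")


@dataclass
class SimulatedDataset:
    """Host tree, virus tree(s), associations, and the true event history."""

    host_tree: PhyloTree
    virus_trees: list
    associations: list
    event_logs: list
    true_counts: dict
    params: CophyloSimParams

    @property
    def virus_tree(self) -> PhyloTree:
        return self.virus_trees[0]

    @property
    def association(self) -> AssociationTable:
        return self.associations[0]

    def combined_association(self) -> AssociationTable:
        pairs = tuple(p for a in self.associations for p in a.pairs)
        return AssociationTable(
            pairs=pairs,
            independent_labels=tuple(self.host_tree.tip_labels))

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.host_tree.write(out / "host.nwk")
        (out / "virus.nwk").write_text(
            "".join(t.newick() + "\n" for t in self.virus_trees))
        self.combined_association().to_tsv(out / "assoc.tsv")
        (out / "truth.json").write_text(json.dumps({
            "true_counts": self.true_counts,
            "event_logs": self.event_logs,
        }, indent=2, sort_keys=True) + "\n")
        (out / "config.yaml").write_text(
            yaml.safe_dump(asdict(self.params), sort_keys=True))


# ---------------------------------------------------------------------------
# Yule host trees
# ---------------------------------------------------------------------------

def _yule_topology(n_tips: int, rng: np.random.Generator) -> Node:
    root = Node()
    root.add_child(Node())
    root.add_child(Node())
    leaves = list(root.children)
    while len(leaves) < n_tips:
        i = int(rng.integers(len(leaves)))
        leaf = leaves[i]
        c1, c2 = Node(), Node()
        leaf.add_child(c1)
        leaf.add_child(c2)
        leaves[i] = c1
        leaves.append(c2)
    return root


def _label_tips(root: Node, prefix: str) -> None:
    i = 1
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    for node in order:
        if not node.children:
            node.label = f"{prefix}{i}"
            i += 1


def simulate_host_tree(n_tips: int, seed: int = 0) -> PhyloTree:
    """Rooted binary Yule tree with tips H1..Hn (seed-deterministic)."""
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_tips, rng)
    _label_tips(root, "H")
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Cophylogeny propagation
# ---------------------------------------------------------------------------

class _HostView:
    """Preorder-indexed host tree with incomparable-node candidate lists."""

    def __init__(self, tree: PhyloTree):
        self.nodes = list(tree.preorder())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.size = [1] * n
        for i in range(n - 1, -1, -1):
            nd = self.nodes[i]
            if nd.children:
                self.size[i] = 1 + sum(
                    self.size[self.index[id(c)]] for c in nd.children)
        self.incomparable = []
        for i in range(n):
            cands = [j for j in range(n)
                     if not (i <= j < i + self.size[i])
                     and not (j <= i < j + self.size[j])]
            self.incomparable.append(cands)


class _RngDecisions:
    """Draws generative decisions from a RNG while logging them."""

    def __init__(self, rng: np.random.Generator, params: CophyloSimParams):
        self.rng = rng
        self.p = params
        self.log: list = []

    def at_host(self, h: int):
        if self.rng.random() < self.p.p_cospeciation:
            self.log.append({"at": h, "decision": "cospeciate"})
            return ("cospeciate", None)
        child = int(self.rng.integers(2))
        self.log.append({"at": h, "decision": "follow", "child": child})
        return ("follow", child)

    def edge(self, h: int, candidates: list):
        extinct = (self.p.loss_rate > 0 and
                   int(self.rng.poisson(self.p.loss_rate)) > 0)
        if extinct:
            entry = {"edge": h, "extinct": True,
                     "n_duplications": 0, "switch_targets": []}
            self.log.append(entry)
            return True, 0, []
        n_dup = int(self.rng.poisson(self.p.duplication_rate))
        n_sw = int(self.rng.poisson(self.p.switch_rate))
        targets = []
        if candidates:
            for _ in range(n_sw):
                targets.append(
                    candidates[int(self.rng.integers(len(candidates)))])
        self.log.append({"edge": h, "extinct": False,
                         "n_duplications": n_dup,
                         "switch_targets": list(targets)})
        return False, n_dup, targets


class _LogDecisions:
    """Replays a recorded decision log (consistency oracle for the log)."""

    def __init__(self, log: list):
        self._entries = iter(log)

    def at_host(self, h: int):
        e = next(self._entries)
        if e.get("at") != h:
            raise ValidationError(f"log replay mismatch at host node {h}")
        if e["decision"] == "cospeciate":
            return ("cospeciate", None)
        return ("follow", e["child"])

    def edge(self, h: int, candidates: list):
        e = next(self._entries)
        if e.get("edge") != h:
            raise ValidationError(f"log replay mismatch on edge into {h}")
        return e["extinct"], e["n_duplications"], list(e["switch_targets"])


def _propagate(view: _HostView, dec) -> Node | None:
    """Run one virus lineage from the host root; returns virus root or None."""

    def at_node(h: int) -> Node | None:
        host = view.nodes[h]
        if not host.children:
            leaf = Node(label=f"@{h}")  # placeholder; host tip index
            return leaf
        kind, child = dec.at_host(h)
        ci = [view.index[id(c)] for c in host.children]
        if kind == "cospeciate":
            lft = along_edge(ci[0])
            rgt = along_edge(ci[1])
            return _join(lft, rgt)
        return along_edge(ci[child])

    def along_edge(h: int) -> Node | None:
        extinct, n_dup, targets = dec.edge(h, view.incomparable[h])
        if extinct:
            return None
        pieces = []
        for _ in range(n_dup):
            pieces.append(("duplication", at_node(h)))
        for tgt in targets:
            pieces.append(("switch", at_node(tgt)))
        node = at_node(h)
        for _, piece in reversed(pieces):
            node = _join(node, piece)
        return node

    return at_node(0)


def _join(x: Node | None, y: Node | None) -> Node | None:
    if x is None:
        return y
    if y is None:
        return x
    joined = Node()
    joined.add_child(x)
    joined.add_child(y)
    return joined


def _log_counts(log: list) -> dict:
    counts = {"cospeciations": 0, "duplications": 0,
              "switches": 0, "losses": 0}
    for e in log:
        if "at" in e:
            if e["decision"] == "cospeciate":
                counts["cospeciations"] += 1
            else:
                counts["losses"] += 1
        else:
            if e["extinct"]:
                counts["losses"] += 1
            else:
                counts["duplications"] += e["n_duplications"]
                counts["switches"] += len(e["switch_targets"])
    return counts


def _finalize_virus(root: Node, view: _HostView,
                    prefix: str) -> tuple:
    """Label virus tips V1.. in preorder and build the association pairs."""
    stack, order = [root], []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    pairs = []
    i = 1
    for node in order:
        if not node.children:
            h = int(node.label[1:])
            node.label = f"{prefix}{i}"
            pairs.append((node.label, view.nodes[h].label))
            i += 1
    return PhyloTree(root, rooted=True), pairs


def simulate_cophylogeny(host: PhyloTree,
                         params: CophyloSimParams) -> SimulatedDataset:
    """Propagate virus lineage(s) along ``host`` under ``params``.

    Returns the host tree, one virus tree per starting lineage
    (``viruses_per_host``), tip associations, per-lineage event logs, and
    aggregated true event counts.  Fully extinct lineages are resampled up
    to ``params.max_attempts`` times, then an error is raised.
    """
    if not host.rooted:
        raise ValidationError("host tree must be rooted")
    host.validate(require_binary=True)
    view = _HostView(host)
    rng = np.random.default_rng(params.seed)
    virus_trees, associations, logs = [], [], []
    for v in range(params.viruses_per_host):
        prefix = "V" if params.viruses_per_host == 1 else f"V{v + 1}_"
        root = None
        dec = None
        for _ in range(params.max_attempts):
            dec = _RngDecisions(rng, params)
            root = _propagate(view, dec)
            if root is not None:
                break
        if root is None:
            raise ValidationError(
                f"virus lineage went extinct in all {params.max_attempts} "
                "attempts; lower loss_rate or raise max_attempts")
        tree, pairs = _finalize_virus(root, view, prefix)
        virus_trees.append(tree)
        associations.append(AssociationTable(
            pairs=tuple(pairs),
            independent_labels=tuple(host.tip_labels)))
        logs.append(dec.log)
    totals = {"cospeciations": 0, "duplications": 0,
              "switches": 0, "losses": 0}
    for log in logs:
        for k, v in _log_counts(log).items():
            totals[k] += v
    return SimulatedDataset(
        host_tree=host, virus_trees=virus_trees,
        associations=associations, event_logs=logs,
        true_counts=totals, params=params)


def replay_event_log(host: PhyloTree, log: list,
                     prefix: str = "V") -> PhyloTree:
    """Rebuild the virus tree implied by a recorded event log."""
    view = _HostView(host)
    root = _propagate(view, _LogDecisions(log))
    if root is None:
        raise ValidationError("event log describes a fully extinct lineage")
    tree, _ = _finalize_virus(root, view, prefix)
    return tree


# ---------------------------------------------------------------------------
# Segment pairs with controlled reassortment
# ---------------------------------------------------------------------------

def simulate_segment_pair(base_tips: int, n_reassortments: int,
                          seed: int = 0) -> tuple:
    """Two genome-segment trees differing by ``n_reassortments`` leaf swaps.

    Segment A is a Yule tree (tips S1..Sn); segment B is a copy in which
    ``n_reassortments`` disjoint tip pairs exchange positions (each swap
    models one reassorted lineage).  Returns (segment_a, segment_b,
    identity association of segment-B tips onto segment-A tips).
    """
    if base_tips < 4:
        raise ValidationError("base_tips must be >= 4")
    if n_reassortments < 0:
        raise ValidationError("n_reassortments must be >= 0")
    if n_reassortments > base_tips // 2:
        raise ValidationError(
            "n_reassortments cannot exceed floor(base_tips / 2)")
    rng = np.random.default_rng(seed)
    root = _yule_topology(base_tips, rng)
    _label_tips(root, "S")
    seg_a = PhyloTree(root, rooted=True)
    seg_b = seg_a.copy()
    tips = [t for t in seg_b.tips()]
    chosen = rng.choice(len(tips), size=2 * n_reassortments, replace=False)
    for k in range(n_reassortments):
        t1 = tips[int(chosen[2 * k])]
        t2 = tips[int(chosen[2 * k + 1])]
        t1.label, t2.label = t2.label, t1.label
    seg_b = PhyloTree(seg_b.root, rooted=True)
    assoc = AssociationTable(
        pairs=tuple((l, l) for l in seg_b.tip_labels),
        independent_labels=tuple(seg_a.tip_labels))
    return seg_a, seg_b, assoc


# ---------------------------------------------------------------------------
# Bootstrap-style tree sets
# ---------------------------------------------------------------------------

def simulate_bootstrap_set(tree: PhyloTree, n_trees: int,
                           perturbation: int = 0,
                           seed: int = 0) -> TreeSet:
    """Unrooted copies of ``tree``, each perturbed by ``perturbation`` NNIs.

    A stand-in for bootstrap replicate sets: topological noise grows with
    the number of nearest-neighbor interchanges applied per copy.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if perturbation < 0:
        raise ValidationError("perturbation must be >= 0")
    rng = np.random.default_rng(seed)
    base = tree.unroot() if tree.rooted else tree.copy()
    out = []
    for _ in range(n_trees):
        c = base.copy()
        for _ in range(perturbation):
            _random_nni(c, rng)
        out.append(PhyloTree(c.root, rooted=False))
    return TreeSet(out)


def _random_nni(tree: PhyloTree, rng: np.random.Generator) -> None:
    candidates = [v for v in tree.preorder()
                  if v.parent is not None and v.children]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    x = v.children[int(rng.integers(len(v.children)))]
    i = u.children.index(s)
    j = v.children.index(x)
    u.children[i] = x
    x.parent = u
    v.children[j] = s
    s.parent = v
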