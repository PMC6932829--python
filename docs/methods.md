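# Methods

## Reconciliation model

The solver computes a minimum-cost *vertex mapping* of a rooted binary
dependent tree P onto a rooted binary independent tree H under four events.
Let c(p, h) be the cheapest cost of resolving the subtree of dependent node
p with p placed at host node h. For tips, c(p, h) = 0 if the association
maps p to h and +inf otherwise. For internal p with children p1, p2:

* in(p, h)  = min over h' in subtree(h) of c(p, h') + loss_cost ×
  edge-distance(h, h') — place p at or below h, paying one loss per host
  edge descended;
* out(p, h) = min over h' *incomparable* to h (neither ancestor nor
  descendant) of c(p, h') — the landing cost of a switched child;
* c(p, h) = min of
  * cospeciation (h internal with children l, r):
    c_co + min(in(p1,l) + in(p2,r), in(p1,r) + in(p2,l)),
  * duplication: c_dup + in(p1,h) + in(p2,h),
  * switch: c_sw + min(in(p1,h) + out(p2,h), in(p2,h) + out(p1,h)).

The answer is min over h of c(root(P), h); no losses are charged above the
chosen root placement. With host nodes indexed in preorder the subtree of a
node is a contiguous index range, so ancestry tests are O(1) and the whole
DP is O(|P|·|H|) per in/out pass — well under a millisecond for 20-tip
trees, which makes 10^5 reconciliations per analysis practical.

Model assumptions and conventions:

* **Untimed transfers.** A switch may target any node incomparable to the
  current host; no timing consistency is enforced across switches. This is
  the untimed (CoRe-PA-style) convention; timed solvers (Jane) restrict
  transfers to contemporaneous lineages. Because every statistic in this
  package is *comparative* (real cost vs randomized-association cost on the
  same trees with the same solver), the solver convention cancels out of
  the tests.
* **Negative costs.** Reward schemes are supported
  (`COREPA_REWARD_COSTS` = cospeciation −1000, duplication 0, switch
  −0.001, loss 0). The loss cost is constrained ≥ 0: since losses are the
  only event whose count is not bounded by the number of dependent internal
  nodes, a negative loss cost would make the optimum unbounded below on
  deep host trees.
* **Determinism.** Ties are broken by a fixed event preference
  (cospeciation > duplication > switch) and, among host placements, by the
  smallest preorder index. Co-optimal reconciliations exist in general;
  the reported event counts are one valid optimum, chosen reproducibly.
  The reported total cost is the event-count identity
  Σ count × cost, which equals the DP optimum by construction.
* **Failure-to-diverge is not modeled**: each dependent tip maps to exactly
  one independent tip (host assignments at, e.g., order level are encoded
  as many-to-one tip associations instead).
* Both trees are used as cladograms; branch lengths are parsed and ignored.
* Default cost vector `JANE_DEFAULT_COSTS` = (cospeciation 0, duplication
  1, switch 2, loss 1). This is an assumption — a conventional
  parsimony vector of the kind event-based tools default to — not a value
  with independent empirical support; all conclusions drawn from cost
  *comparisons* are insensitive to it in the regimes tested.

The brute-force oracle enumerates every assignment of dependent internal
nodes to host nodes and charges each node the cheapest event consistent
with its children's placements; it shares no code path with the DP beyond
the host index, and is guarded to ≤ 6 dependent / ≤ 7 independent tips.

## Hypothesis tests

* **Randomization modes.** `target_permutation` permutes the multiset of
  association targets among dependent tips; `host_tip_renaming` applies one
  uniform permutation of the full host tip-label set to the targets,
  preserving the association structure (which viruses share a host).
  Host-tip renaming is the default for the event-ratio test, target
  permutation for cost nulls; both are exposed everywhere.
* **Margin z-test.** z = (mean(null) − (1+margin)·real) / (sd(null)/√N)
  with the sample standard deviation of the randomized costs and a
  one-sided upper-tail normal p-value; margin defaults to 0.05 so that
  minuscule cost differences are not declared significant. Zero-variance
  nulls short-circuit to p = 1 (all equal to the real cost) or p = 0 (all
  above threshold), flagged `degenerate`.
  *Calibration caveat:* with a null draw as the "real" association the
  rejection probability is approximately Φ(−margin/CV), where CV is the
  coefficient of variation of the null cost distribution. For 20-tip trees
  CV ≈ 5–6%, comparable to the margin, so the realized type-I rate under
  random association is ~15–20% rather than ≤ α; the margin only makes the
  test conservative once trees are large enough (roughly ≥ 40 tips at
  these costs) that CV falls well below the margin. The test suite
  documents this behavior at the 20-tip simulation scale.
* **Relative cophylogeny cost** = real cost / median randomized cost,
  reported also as a percentage: 0 for perfect cophylogeny, 100% for none.
  A zero median raises an error rather than silently reporting 0.
* **Event-ratio test.** Every unrooted dependent tree (e.g. bootstrap
  replicates) is rooted on each of its edges; each rooted version is
  reconciled under reward costs with the real association and with N
  host-tip renamings (one renaming per iteration, shared across all
  trees × rootings so that per-iteration means are well defined). Ratios
  are mean real count / mean randomized count; permutation p-values use
  the +1 correction, p = (1 + #{iteration mean ≥ real mean}) / (1 + N).
  Full count matrices (trees × rootings, and × iterations) are retained so
  any other aggregation can be recomputed.
* **Paired comparison** of two cost sets uses the two-sided Wilcoxon
  signed-rank test (scipy); all-zero differences return p = 1.

## Synthetic data

The generator propagates virus lineages along a host tree under the same
event grammar the solver uses, so ground-truth recovery is well defined:
at each host speciation the lineage cospeciates with probability
`p_cospeciation` or follows one child uniformly (a loss on the other
side); along each host edge, duplications and switches are Poisson draws
(`duplication_rate`, `switch_rate` expected events per edge), a switching
copy jumping to a uniformly chosen incomparable host node. `loss_rate` is
a per-edge Poisson extinction rate (default 0); a fully extinct lineage is
resampled up to `max_attempts` = 100 times, then reported as an error.
Defaults (16 host tips, p_cospeciation 0.9, switch and duplication rates
0.05, one lineage) describe a strongly codiverging association, the regime
the virus–host analyses support.

Every stochastic decision is logged; `replay_event_log` rebuilds the virus
tree from the log alone and the suite asserts byte equality — the log is
therefore a complete, replayable event history, and true counts are read
off it. Reassortment between genome segments is modeled as disjoint
leaf-position exchanges between two copies of a Yule tree (tanglegram-style
misplaced taxa); an SPR-based mode would be a natural extension but is not
implemented. Bootstrap-style uncertainty is emulated by
nearest-neighbor-interchange perturbations of an unrooted tree.

What the generator does *not* emulate: sequence-level noise and
alignment/inference error, branch-length realism, timing constraints on
transfers, within-host dynamics, or correlated topological error across
bootstrap replicates. Passing tests therefore show that the inference
machinery is correct and calibrated under its own generative assumptions,
not that real transcriptome-derived trees satisfy those assumptions.

## Numerical and design choices

* Rootedness of parsed Newick follows topology: a basal polytomy means
  unrooted. Rooting enumeration creates one rooted tree per edge (2n−3 for
  binary n-tip trees).
* Polytomies are resolved into seeded-random caterpillars of zero-length
  edges (k−2 new nodes per k-tomy), preserving all existing bipartitions.
* Association files are two tab-separated columns, dependent tip first,
  `#` comments ignored; dependent tips absent from the table are an error
  unless the caller opts into `allow_missing` (placeholder-host mapping via
  `augment_host_tree` is the intended remedy).
* All stochastic stages take explicit integer seeds and are
  bit-reproducible; dataset directories include a YAML config echo that
  regenerates them byte-identically.
* Simulation scales in the test suite (16–20-tip trees, 100–1000
  randomizations, 20–100 replicates) were chosen as the smallest sizes at
  which the statistics' analytic anchors (relative cost 0 and ~1) and
  power/calibration behavior are cleanly observable.

## Known limitations

* Only one optimal reconciliation is reported; co-optima are not
  enumerated, and event counts of degenerate optima depend on the
  (deterministic) tie-breaking.
* The untimed switch model can accept transfer scenarios a timed model
  would reject.
* The margin z-test's calibration depends on tree size (see above); the
  permutation p-values of the event-ratio test do not suffer from this.
* No automatic cost estimation (CoRe-PA's adaptive mode) and no
  distance-based congruence tests (ParaFit/PACo); NEXUS input is not
  supported.
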