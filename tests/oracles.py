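"""Independent oracles used by the test suite.

The DTL oracle here is deliberately *not* the package's dynamic program: it
is a uniform-cost (Dijkstra) search over global scenario states.  A state is
(slice index, set of gene-lineage tasks), where a task places one pending
gene subtree on a species branch segment.  Expanding a state enumerates, for
every task, all bounded within-slice event chains (duplications, transfers,
transfer-with-donor-loss jumps) and all boundary outcomes (speciation,
speciation-loss, continuation, leaf matching), and crosses the slice
boundary.  The first goal state popped from the priority queue gives the
exact minimum penalty over all time-consistent scenarios with chains up to
the stated depth.
"""

from __future__ import annotations

import heapq
import itertools
from typing import Optional

from genechron.reconcile import PenaltyScheme, TimeSlicedTree
from genechron.trees import GeneTree, TreeNode

INF = float("inf")


def dtl_min_cost_oracle(gene: GeneTree, sliced: TimeSlicedTree,
                        pen: PenaltyScheme, chain_depth: Optional[int] = None) -> float:
    """Exact minimum DTL penalty by exhaustive time-consistent scenario search.

    ``chain_depth`` bounds successive within-slice events along one lineage
    path; the default (gene-tree node count + 2) covers any chain a minimal
    scenario of this size can use.
    """
    gnodes = list(gene.postorder())
    gidx = {id(n): i for i, n in enumerate(gnodes)}
    children = {i: [gidx[id(c)] for c in n.children] for i, n in enumerate(gnodes)}
    label = {i: n.label for i, n in enumerate(gnodes)}
    root_gi = gidx[id(gene.root)]
    if chain_depth is None:
        chain_depth = len(gnodes) + 2

    m = sliced.n_slices
    B = sliced.boundaries
    seg_ids = [[s.id for s in segs] for segs in sliced.segments]
    seg_node = {s.id: s for segs in sliced.segments for s in segs}

    # -- within-slice chain options --------------------------------------
    # options[(gi, sid, k, depth)] = {frozenset of (gi', sid') at slice bottom: cost}
    memo: dict = {}

    def combine(a: dict, b: dict) -> dict:
        out: dict = {}
        for ta, ca in a.items():
            for tb, cb in b.items():
                key = ta | tb
                cost = ca + cb
                if cost < out.get(key, INF):
                    out[key] = cost
        return out

    def options(gi: int, sid: str, k: int, depth: int) -> dict:
        key = (gi, sid, k, depth)
        if key in memo:
            return memo[key]
        out = {frozenset([(gi, sid)]): 0.0}
        if depth > 0:
            kids = children[gi]
            if kids:
                c1, c2 = kids
                o1 = options(c1, sid, k, depth - 1)
                o2 = options(c2, sid, k, depth - 1)
                for t, c in combine(o1, o2).items():
                    cost = pen.dup + c
                    if cost < out.get(t, INF):
                        out[t] = cost
                for f in seg_ids[k]:
                    if f == sid:
                        continue
                    for oa, ob in ((options(c1, sid, k, depth - 1),
                                    options(c2, f, k, depth - 1)),
                                   (options(c1, f, k, depth - 1),
                                    options(c2, sid, k, depth - 1))):
                        for t, c in combine(oa, ob).items():
                            cost = pen.hgt + c
                            if cost < out.get(t, INF):
                                out[t] = cost
            for f in seg_ids[k]:
                if f == sid:
                    continue
                for t, c in options(gi, f, k, depth - 1).items():
                    cost = pen.hgt + pen.los + c
                    if cost < out.get(t, INF):
                        out[t] = cost
        memo[key] = out
        return out

    # -- boundary crossing ------------------------------------------------
    bmemo: dict = {}

    def boundary(gi: int, sid: str, k: int) -> list[tuple[float, frozenset]]:
        """Ways one bottom-of-slice-k task crosses into slice k+1."""
        key = (gi, sid, k)
        if key in bmemo:
            return bmemo[key]
        e = seg_node[sid]
        bottom = B[k + 1]
        if abs(e.age - bottom) <= 1e-9:
            if e.is_leaf:
                if not children[gi] and label[gi] == e.label:
                    outs = [(0.0, frozenset())]
                else:
                    outs = []
            else:
                f1, f2 = (c.id for c in e.children)
                outs = []
                kids = children[gi]
                if kids:
                    c1, c2 = kids
                    outs.append((pen.spc, frozenset([(c1, f1), (c2, f2)])))
                    outs.append((pen.spc, frozenset([(c1, f2), (c2, f1)])))
                outs.append((pen.los, frozenset([(gi, f1)])))
                outs.append((pen.los, frozenset([(gi, f2)])))
        else:
            outs = [(0.0, frozenset([(gi, sid)]))]
        bmemo[key] = outs
        return outs

    # -- one task's complete slice crossing -------------------------------
    # cross[(gi, sid, k)] = {tasks entering slice k+1: min cost}, combining
    # every within-slice chain with every boundary outcome of its products.
    cross_memo: dict = {}

    def cross(gi: int, sid: str, k: int) -> dict:
        key = (gi, sid, k)
        if key in cross_memo:
            return cross_memo[key]
        out: dict = {}
        for bottom_tasks, c_within in options(gi, sid, k, chain_depth).items():
            per_task = []
            feasible = True
            for g2, s2 in sorted(bottom_tasks):
                outs = boundary(g2, s2, k)
                if not outs:
                    feasible = False
                    break
                per_task.append(outs)
            if not feasible:
                continue
            for combo in itertools.product(*per_task):
                c = c_within + sum(c0 for c0, _ in combo)
                t = frozenset().union(*(t0 for _, t0 in combo)) if combo else frozenset()
                if c < out.get(t, INF):
                    out[t] = c
        cross_memo[key] = out
        return out

    # -- Dijkstra over (slice, task set) ----------------------------------
    heap: list[tuple[float, int, int, frozenset]] = []
    tie = itertools.count()

    def push(cost: float, k: int, tasks: frozenset) -> None:
        heapq.heappush(heap, (cost, next(tie), k, tasks))

    for k in range(m):
        for sid in seg_ids[k]:
            push(0.0, k, frozenset([(root_gi, sid)]))
    if children[root_gi]:
        c1, c2 = children[root_gi]
        sroot = sliced.tree.root
        f1, f2 = (c.id for c in sroot.children)
        push(pen.spc, 0, frozenset([(c1, f1), (c2, f2)]))
        push(pen.spc, 0, frozenset([(c1, f2), (c2, f1)]))

    best: dict = {}
    while heap:
        cost, _, k, tasks = heapq.heappop(heap)
        if not tasks and k >= m:
            return cost
        key = (k, tasks)
        if cost > best.get(key, INF) + 1e-12 or best.get(key, INF) == -1.0:
            continue
        best[key] = -1.0  # mark expanded; any later pop of this state is stale
        if k >= m:
            continue
        # fold every task's complete slice crossing
        folded = {frozenset(): 0.0}
        for gi, sid in sorted(tasks):
            folded = combine(folded, cross(gi, sid, k))
        for new_tasks, c in folded.items():
            c_total = cost + c
            nk = (k + 1, new_tasks)
            if c_total < best.get(nk, INF) - 1e-12:
                best[nk] = c_total
                push(c_total, k + 1, new_tasks)
    return INF


def jc_expected_difference(rate: float, total_time: float, K: int = 4) -> float:
    """Closed-form expected proportion of differing sites between two leaves
    separated by ``total_time`` under the equal-rates K-state model."""
    import math

    d = rate * total_time
    return (K - 1) / K * (1.0 - math.exp(-K / (K - 1) * d))
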