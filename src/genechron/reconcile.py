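"""Time-consistent duplication–transfer–loss (DTL) parsimony reconciliation.

A gene tree is mapped onto a dated species tree by charging penalties for
horizontal transfers (default 3), duplications (2), losses (1) and
speciations (0), subject to the temporal constraint that a transfer can only
connect species branches that are alive at the same time.  The chronogram is
cut into *slices* at the distinct node ages; within a slice the set of living
branch segments is constant, and a transfer in slice *s* may only connect two
segments of *s*.

The optimisation is a dynamic program over (gene node × species segment ×
slice), run bottom-up in time.  Within a slice a gene lineage may branch by
duplication or transfer, or jump to another segment via a transfer whose
donor copy is immediately lost (one HGT plus one LOS); at a slice boundary it
either continues on its branch, speciates (both children survive; one SPC
logged), or passes through the speciation losing one side (one LOS logged,
no SPC).  The gene birth is free and may sit on any segment in any slice.
Each event is reported with the temporal region in which it could have
occurred — the donor/recipient coexistence window for a transfer, the host
branch's span for duplications, losses and births, the node age for a
speciation — and the reported event date is that interval's midpoint.

Unrooted gene trees are handled by trying every branch as the root and
keeping the cheapest rooting; ties are broken by the lexicographically
smallest (HGT, DUP, LOS) count vector, then by branch index.
"""

from __future__ import annotations

import dataclasses
import math
import statistics
from typing import Optional, Sequence

import pandas as pd

from .trees import DatedTree, GeneTree, TreeNode

__all__ = [
    "PenaltyScheme",
    "TimeSlicedTree",
    "EventRecord",
    "ReconciliationResult",
    "slice_tree",
    "reconcile",
    "reconcile_bootstraps",
    "count_events",
]

INF = math.inf
_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class PenaltyScheme:
    """Per-event-class penalties (all nonnegative)."""

    hgt: float = 3.0
    dup: float = 2.0
    los: float = 1.0
    spc: float = 0.0

    def __post_init__(self) -> None:
        if min(self.hgt, self.dup, self.los, self.spc) < 0:
            raise ValueError("penalties must be nonnegative")


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """One inferred (or planted) event with its feasible time interval."""

    event_class: str                 # BIRTH | SPC | DUP | HGT | LOS
    branch: str                      # species branch id (donor for HGT; node id for SPC)
    older: float                     # Mya, start of the feasible interval
    younger: float                   # Mya, end of the feasible interval
    recipient: Optional[str] = None  # HGT only
    support: float = 1.0

    def __post_init__(self) -> None:
        if self.older < self.younger - _TOL:
            raise ValueError("feasible interval must run older -> younger")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)

    def key(self) -> tuple:
        return (self.event_class, self.branch, self.recipient,
                round(self.older, 6), round(self.younger, 6))


@dataclasses.dataclass
class TimeSlicedTree:
    """A chronogram plus its time slices.

    ``boundaries`` are the distinct node ages in descending order (root age
    first, 0 last).  Slice ``k`` (1-based) is the interval
    ``(boundaries[k], boundaries[k-1])``; ``segments[k-1]`` lists the species
    branches (identified by their child node) alive throughout that slice.
    """

    tree: DatedTree
    boundaries: list[float]
    segments: list[list[TreeNode]]

    @property
    def n_slices(self) -> int:
        return len(self.segments)

    def slice_span(self, k: int) -> tuple[float, float]:
        """(older, younger) bounds of 1-based slice ``k``."""
        return self.boundaries[k - 1], self.boundaries[k]


def slice_tree(tree: DatedTree) -> TimeSlicedTree:
    """Cut ``tree`` at its distinct node ages.  Raises on non-ultrametric input."""
    tree.validate()
    ages = sorted({round(n.age, 12) for n in tree.postorder()}, reverse=True)
    if ages[-1] != 0.0:
        raise ValueError("chronogram leaves must sit at age 0")
    branches = tree.branches()
    segments = []
    for k in range(1, len(ages)):
        top, bottom = ages[k - 1], ages[k]
        segs = [b for b in branches if b.parent.age >= top - _TOL and b.age <= bottom + _TOL]
        segments.append(segs)
    return TimeSlicedTree(tree=tree, boundaries=ages, segments=segments)


@dataclasses.dataclass
class ReconciliationResult:
    total_penalty: float
    events: list[EventRecord]
    mapping: dict[str, tuple[str, int]]     # gene node id -> (segment id, slice)
    gene_tree: GeneTree                     # the rooting actually used
    penalties: PenaltyScheme

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in ("BIRTH", "SPC", "DUP", "HGT", "LOS")}
        for e in self.events:
            out[e.event_class] += 1
        return out

    def events_frame(self, gene: str = "") -> pd.DataFrame:
        rows = [
            {
                "gene": gene,
                "event_class": e.event_class,
                "donor": e.branch,
                "recipient": e.recipient or "",
                "older_Mya": e.older,
                "younger_Mya": e.younger,
                "midpoint_Mya": e.midpoint,
                "support": e.support,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "event_class", "donor", "recipient",
                     "older_Mya", "younger_Mya", "midpoint_Mya", "support"],
        )


class _DP:
    """One rooted DP instance: tables plus backtracking."""

    def __init__(self, gene: GeneTree, sliced: TimeSlicedTree, pen: PenaltyScheme):
        self.gene = gene
        self.sliced = sliced
        self.pen = pen
        self.gnodes = list(gene.postorder())
        self.gindex = {id(n): i for i, n in enumerate(self.gnodes)}
        taxa = sliced.tree.taxa
        for leaf in gene.leaves:
            if leaf.label not in taxa:
                raise ValueError(f"gene leaf {leaf.label!r} not in species tree")
        m = sliced.n_slices
        # per slice: segment position lookup and boundary behaviour
        self.seg_pos: list[dict[int, int]] = []
        for k in range(m):
            self.seg_pos.append({id(s): j for j, s in enumerate(sliced.segments[k])})
        self._solve()

    # -- forward tables --------------------------------------------------
    def _solve(self) -> None:
        sliced, pen = self.sliced, self.pen
        m = sliced.n_slices
        B = sliced.boundaries
        G = len(self.gnodes)
        # IN[k][g][e] with k 0-based slice index
        self.IN: list[list[list[float]]] = [[None] * G for _ in range(m)]  # type: ignore
        self.BASE: list[list[list[float]]] = [[None] * G for _ in range(m)]  # type: ignore
        # MIN[k][g] = (min1, argmin, min2) over segments of IN[k][g]
        self.MIN: list[list[tuple[float, int, float]]] = [[None] * G for _ in range(m)]  # type: ignore
        for k in range(m - 1, -1, -1):
            segs = sliced.segments[k]
            bottom = B[k + 1]
            for gi, g in enumerate(self.gnodes):
                g_leaf = g.is_leaf
                if not g_leaf:
                    c1 = self.gindex[id(g.children[0])]
                    c2 = self.gindex[id(g.children[1])]
                base = []
                for j, e in enumerate(segs):
                    best = self._cb(gi, g, j, e, k)
                    if not g_leaf:
                        in_k = self.IN[k]
                        v = pen.dup + in_k[c1][j] + in_k[c2][j]
                        if v < best:
                            best = v
                        m1a, a1a, m2a = self.MIN[k][c1]
                        m1b, a1b, m2b = self.MIN[k][c2]
                        away_b = m1b if a1b != j else m2b
                        away_a = m1a if a1a != j else m2a
                        v = pen.hgt + min(in_k[c1][j] + away_b, in_k[c2][j] + away_a)
                        if v < best:
                            best = v
                    base.append(best)
                # transfer-loss closure: one jump to the cheapest other segment
                m1, a1, m2 = _min2(base)
                jump = pen.hgt + pen.los
                closed = []
                for j, b in enumerate(base):
                    away = m1 if a1 != j else m2
                    closed.append(min(b, jump + away))
                self.BASE[k][gi] = base
                self.IN[k][gi] = closed
                self.MIN[k][gi] = _min2(closed)

    def _cb(self, gi: int, g: TreeNode, j: int, e: TreeNode, k: int) -> float:
        """Cost of crossing the bottom boundary of slice ``k`` on segment ``e``."""
        sliced, pen = self.sliced, self.pen
        bottom = sliced.boundaries[k + 1]
        if abs(e.age - bottom) <= _TOL:
            if e.is_leaf:
                return 0.0 if (g.is_leaf and g.label == e.label) else INF
            f1, f2 = e.children
            nxt = self.seg_pos[k + 1]
            p1, p2 = nxt[id(f1)], nxt[id(f2)]
            in_next = self.IN[k + 1]
            best = pen.los + min(in_next[gi][p1], in_next[gi][p2])
            if not g.is_leaf:
                c1 = self.gindex[id(g.children[0])]
                c2 = self.gindex[id(g.children[1])]
                v = pen.spc + min(in_next[c1][p1] + in_next[c2][p2],
                                  in_next[c1][p2] + in_next[c2][p1])
                if v < best:
                    best = v
            return best
        if k + 1 >= sliced.n_slices:
            return INF
        nxt = self.seg_pos[k + 1]
        pos = nxt.get(id(e))
        if pos is None:
            return INF
        return self.IN[k + 1][self.gindex[id(g)]][pos]

    # -- answer ----------------------------------------------------------
    def best(self) -> tuple[float, tuple]:
        """(min cost, birth choice).  Birth choice is ('seg', k, j) or ('rootspc',)."""
        best, choice = INF, None
        groot = self.gindex[id(self.gene.root)]
        for k in range(self.sliced.n_slices):
            row = self.IN[k][groot]
            for j, v in enumerate(row):
                if v < best - _TOL:
                    best, choice = v, ("seg", k, j)
        if not self.gene.root.is_leaf:
            c1 = self.gindex[id(self.gene.root.children[0])]
            c2 = self.gindex[id(self.gene.root.children[1])]
            sroot = self.sliced.tree.root
            nxt = self.seg_pos[0]
            p1, p2 = nxt[id(sroot.children[0])], nxt[id(sroot.children[1])]
            in0 = self.IN[0]
            v = self.pen.spc + min(in0[c1][p1] + in0[c2][p2],
                                   in0[c1][p2] + in0[c2][p1])
            if v < best - _TOL:
                best, choice = v, ("rootspc",)
        return best, choice

    # -- backtracking ----------------------------------------------------
    def extract(self) -> tuple[float, list[EventRecord], dict[str, tuple[str, int]]]:
        cost, choice = self.best()
        if choice is None or cost == INF:
            raise ValueError("gene tree cannot be reconciled with the species tree")
        events: list[EventRecord] = []
        mapping: dict[str, tuple[str, int]] = {}
        if choice[0] == "seg":
            _, k, j = choice
            e = self.sliced.segments[k][j]
            events.append(EventRecord("BIRTH", e.id, e.parent.age, e.age))
            self._trace(self.gindex[id(self.gene.root)], j, k, events, mapping,
                        allow_jump=True)
        else:
            sroot = self.sliced.tree.root
            top = self.sliced.boundaries[0]
            older_child = max(sroot.children, key=lambda c: c.age)
            events.append(EventRecord("BIRTH", "root", top, older_child.age))
            events.append(EventRecord("SPC", sroot.id, top, top))
            groot = self.gene.root
            mapping[groot.id] = ("root", 0)
            c1 = self.gindex[id(groot.children[0])]
            c2 = self.gindex[id(groot.children[1])]
            nxt = self.seg_pos[0]
            p1, p2 = nxt[id(sroot.children[0])], nxt[id(sroot.children[1])]
            in0 = self.IN[0]
            if in0[c1][p1] + in0[c2][p2] <= in0[c1][p2] + in0[c2][p1]:
                self._trace(c1, p1, 0, events, mapping, True)
                self._trace(c2, p2, 0, events, mapping, True)
            else:
                self._trace(c1, p2, 0, events, mapping, True)
                self._trace(c2, p1, 0, events, mapping, True)
        return cost, events, mapping

    def _trace(self, gi: int, j: int, k: int, events: list[EventRecord],
               mapping: dict[str, tuple[str, int]], allow_jump: bool) -> None:
        pen, sliced = self.pen, self.sliced
        g = self.gnodes[gi]
        segs = sliced.segments[k]
        e = segs[j]
        target = self.IN[k][gi][j]
        base = self.BASE[k][gi][j]
        top, bottom = sliced.slice_span(k + 1)
        if allow_jump and target < base - _TOL:
            # transfer-loss jump to the cheapest other segment
            row = self.BASE[k][gi]
            m1, a1, m2 = _min2(row)
            f = a1 if a1 != j else _argmin_excluding(row, j)
            older, younger = _overlap_window(e, segs[f])
            events.append(EventRecord("HGT", e.id, older, younger, recipient=segs[f].id))
            events.append(EventRecord("LOS", e.id, e.parent.age, e.age))
            self._trace(gi, f, k, events, mapping, allow_jump=False)
            return
        # boundary/descent is preferred on ties, then duplication, then transfer
        cbv = self._cb(gi, g, j, e, k)
        if cbv <= base + _TOL:
            if abs(e.age - bottom) <= _TOL:
                if e.is_leaf:
                    mapping[g.id] = (e.id, k + 1)
                    return
                f1, f2 = e.children
                nxt = self.seg_pos[k + 1]
                p1, p2 = nxt[id(f1)], nxt[id(f2)]
                in_next = self.IN[k + 1]
                if not g.is_leaf:
                    c1 = self.gindex[id(g.children[0])]
                    c2 = self.gindex[id(g.children[1])]
                    spcv = pen.spc + min(in_next[c1][p1] + in_next[c2][p2],
                                         in_next[c1][p2] + in_next[c2][p1])
                    if spcv <= cbv + _TOL:
                        events.append(EventRecord("SPC", e.id, e.age, e.age))
                        mapping[g.id] = (e.id, k + 1)
                        if in_next[c1][p1] + in_next[c2][p2] <= in_next[c1][p2] + in_next[c2][p1]:
                            self._trace(c1, p1, k + 1, events, mapping, True)
                            self._trace(c2, p2, k + 1, events, mapping, True)
                        else:
                            self._trace(c1, p2, k + 1, events, mapping, True)
                            self._trace(c2, p1, k + 1, events, mapping, True)
                        return
                # speciation-loss pass-through
                if in_next[gi][p1] <= in_next[gi][p2]:
                    lost, pk = f2, p1
                else:
                    lost, pk = f1, p2
                events.append(EventRecord("LOS", lost.id, lost.parent.age, lost.age))
                self._trace(gi, pk, k + 1, events, mapping, True)
                return
            # plain descent into the next slice
            nxt = self.seg_pos[k + 1]
            self._trace(gi, nxt[id(e)], k + 1, events, mapping, True)
            return
        c1 = self.gindex[id(g.children[0])]
        c2 = self.gindex[id(g.children[1])]
        in_k = self.IN[k]
        dupv = pen.dup + in_k[c1][j] + in_k[c2][j]
        if dupv <= base + _TOL:
            events.append(EventRecord("DUP", e.id, e.parent.age, e.age))
            mapping[g.id] = (e.id, k + 1)
            self._trace(c1, j, k, events, mapping, True)
            self._trace(c2, j, k, events, mapping, True)
            return
        m1a, a1a, m2a = self.MIN[k][c1]
        m1b, a1b, m2b = self.MIN[k][c2]
        away_b = m1b if a1b != j else m2b
        away_a = m1a if a1a != j else m2a
        mapping[g.id] = (e.id, k + 1)
        if in_k[c1][j] + away_b <= in_k[c2][j] + away_a:
            f = a1b if a1b != j else _argmin_excluding(in_k[c2], j)
            older, younger = _overlap_window(e, segs[f])
            events.append(EventRecord("HGT", e.id, older, younger, recipient=segs[f].id))
            self._trace(c1, j, k, events, mapping, True)
            self._trace(c2, f, k, events, mapping, True)
        else:
            f = a1a if a1a != j else _argmin_excluding(in_k[c1], j)
            older, younger = _overlap_window(e, segs[f])
            events.append(EventRecord("HGT", e.id, older, younger, recipient=segs[f].id))
            self._trace(c2, j, k, events, mapping, True)
            self._trace(c1, f, k, events, mapping, True)


def _overlap_window(a: TreeNode, b: TreeNode) -> tuple[float, float]:
    """Coexistence window of two species branches: the temporal region in
    which an event connecting them could occur."""
    older = min(a.parent.age, b.parent.age)
    younger = max(a.age, b.age)
    return older, younger


def _min2(row: Sequence[float]) -> tuple[float, int, float]:
    """(smallest value, its index, second-smallest value) of ``row``."""
    m1, a1, m2 = INF, -1, INF
    for j, v in enumerate(row):
        if v < m1:
            m2, m1, a1 = m1, v, j
        elif v < m2:
            m2 = v
    return m1, a1, m2


def _argmin_excluding(row: Sequence[float], skip: int) -> int:
    best, arg = INF, -1
    for j, v in enumerate(row):
        if j != skip and v < best:
            best, arg = v, j
    return arg


def reconcile(gene: GeneTree, sliced: TimeSlicedTree,
              penalties: PenaltyScheme = PenaltyScheme(),
              root_search: Optional[bool] = None) -> ReconciliationResult:
    """Minimum-penalty time-consistent DTL reconciliation.

    ``root_search`` defaults to ``not gene.rooted``: unrooted gene trees try
    every branch as root and keep the cheapest (ties broken by the smallest
    (HGT, DUP, LOS) count vector, then branch index).
    """
    if not gene.leaves:
        raise ValueError("empty gene tree")
    if root_search is None:
        root_search = not gene.rooted
    candidates = gene.all_rootings() if root_search else [gene]
    best_cost = INF
    best_dp: list[tuple[int, _DP]] = []
    for idx, cand in enumerate(candidates):
        dp = _DP(cand, sliced, penalties)
        cost, _ = dp.best()
        if cost < best_cost - _TOL:
            best_cost, best_dp = cost, [(idx, dp)]
        elif cost <= best_cost + _TOL:
            best_dp.append((idx, dp))
    if not best_dp or best_cost == INF:
        raise ValueError("no feasible reconciliation found")
    chosen = None
    for idx, dp in best_dp:
        cost, events, mapping = dp.extract()
        counts = {c: 0 for c in ("HGT", "DUP", "LOS")}
        for e in events:
            if e.event_class in counts:
                counts[e.event_class] += 1
        key = (counts["HGT"], counts["DUP"], counts["LOS"], idx)
        if chosen is None or key < chosen[0]:
            chosen = (key, cost, events, mapping, dp.gene)
    _, cost, events, mapping, used = chosen
    result = ReconciliationResult(cost, events, mapping, used, penalties)
    _check_penalty_identity(result)
    return result


def _check_penalty_identity(result: ReconciliationResult) -> None:
    counts = result.class_counts()
    pen = result.penalties
    total = (pen.hgt * counts["HGT"] + pen.dup * counts["DUP"]
             + pen.los * counts["LOS"] + pen.spc * counts["SPC"])
    if not math.isclose(total, result.total_penalty, rel_tol=1e-9, abs_tol=1e-6):
        raise AssertionError(
            f"penalty bookkeeping mismatch: DP {result.total_penalty} vs "
            f"recount {total} ({counts})"
        )


def reconcile_bootstraps(replicates: Sequence[GeneTree], sliced: TimeSlicedTree,
                         penalties: PenaltyScheme = PenaltyScheme(),
                         support_threshold: float = 0.5,
                         root_search: Optional[bool] = None) -> ReconciliationResult:
    """Reconcile each bootstrap replicate and keep events whose support (the
    fraction of replicates containing them, matched by class, location and
    slice) reaches ``support_threshold``.  The reported total penalty is the
    median across replicates; the mapping and rooting come from the first
    replicate."""
    if not replicates:
        raise ValueError("need at least one bootstrap replicate")
    results = [reconcile(r, sliced, penalties, root_search=root_search)
               for r in replicates]
    n = len(results)
    tally: dict[tuple, list[EventRecord]] = {}
    for res in results:
        for ev in res.events:
            tally.setdefault(ev.key(), []).append(ev)
    consensus = []
    for key, evs in tally.items():
        support = len(evs) / n
        if support >= support_threshold - _TOL:
            proto = evs[0]
            consensus.append(dataclasses.replace(proto, support=support))
    consensus.sort(key=lambda e: (-e.older, e.event_class, e.branch, e.recipient or ""))
    total = statistics.median(r.total_penalty for r in results)
    return ReconciliationResult(total, consensus, results[0].mapping,
                                results[0].gene_tree, penalties)


def count_events(result: ReconciliationResult) -> pd.Series:
    """Per-class event counts (HGT, SPC, LOS, DUP); births are not events of
    the gene's later history and are excluded."""
    counts = result.class_counts()
    return pd.Series(
        {c: counts[c] for c in ("HGT", "SPC", "LOS", "DUP")}, name="count"
    )
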