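"""Synthetic data generation for every pipeline stage.

The generators here produce the statistical structure that the downstream
stages assume, with the ground truth retained so recovery can be measured:

* :func:`simulate_dated_tree` — constant-rate birth–death species trees,
  conditioned on the number of surviving tips by bounded rejection, rescaled
  to a chosen root age (extant-only, strictly bifurcating, ultrametric).
* :func:`simulate_gene_family` — a gene family evolving down a dated species
  tree with Poisson duplication/transfer/loss, a chosen birth lineage and
  time, and a full planted event log.  Transfers are additive (a new copy in
  the recipient) and the recipient is drawn uniformly among branches alive at
  the event time, excluding the donor.
* :func:`perturb_gene_tree` — topological noise via random nearest-neighbour
  interchanges, standing in for gene-tree estimation error.
* :func:`simulate_alignment` — an equal-rates, equal-frequency K-state
  substitution process (Jukes–Cantor for K=4) along the chronogram.
* :func:`simulate_hit_table` — mock homology-search hit tables in BLAST
  outfmt-6 column order with per-row ground-truth pass/fail labels under the
  screening thresholds.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import DatedTree, GeneTree, TreeNode

__all__ = [
    "SimulationParams",
    "TrueEvent",
    "TrueEventLog",
    "Alignment",
    "simulate_dated_tree",
    "forward_lineage_count",
    "simulate_gene_family",
    "perturb_gene_tree",
    "simulate_alignment",
    "simulate_hit_table",
    "HIT_TABLE_COLUMNS",
]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# parameters and event log
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulationParams:
    """Rates are events per gene lineage per Myr; times in Mya."""

    dup_rate: float = 0.0
    hgt_rate: float = 0.0
    loss_rate: float = 0.0
    birth_branch: str = "root"   # branch id (child-node id) or "root"
    birth_time: Optional[float] = None  # defaults to top of the birth branch
    subst_rate: float = 1e-4     # substitutions / site / Myr
    alphabet_size: int = 4
    sites: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dup_rate, self.hgt_rate, self.loss_rate) < 0:
            raise ValueError("event rates must be nonnegative")
        if self.sites < 1:
            raise ValueError("sites must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be >= 2")


@dataclasses.dataclass
class TrueEvent:
    event_class: str            # BIRTH | SPC | DUP | HGT | LOS
    time: float                 # Mya
    branch: str                 # species branch id (donor for HGT); node id for SPC
    donor: Optional[str] = None
    recipient: Optional[str] = None
    visible: Optional[bool] = None  # left a trace in the surviving gene tree?


@dataclasses.dataclass
class TrueEventLog:
    """Planted ground truth for one simulated gene family.

    ``observable`` holds the event multiset a perfect parsimony
    reconciliation of the *surviving* gene tree would report: events inside
    fully extinct subtrees leave no trace and are excluded; a speciation
    surviving on one side only collapses to a single loss; a transfer whose
    donor copy died collapses to a transfer plus a loss.
    """

    events: list[TrueEvent]
    observable: Optional[dict[str, int]] = None

    def of_class(self, event_class: str) -> list[TrueEvent]:
        return [e for e in self.events if e.event_class == event_class]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in ("BIRTH", "SPC", "DUP", "HGT", "LOS")}
        for e in self.events:
            out[e.event_class] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_class": e.event_class,
                "time_Mya": e.time,
                "branch_id": e.branch,
                "donor_id": e.donor if e.donor is not None else "",
                "recipient_id": e.recipient if e.recipient is not None else "",
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["event_class", "time_Mya", "branch_id", "donor_id", "recipient_id"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dated species trees
# ---------------------------------------------------------------------------

def forward_lineage_count(birth_rate: float, death_rate: float, duration: float,
                          rng: np.random.Generator, max_lineages: int = 100_000) -> int:
    """Number of extant lineages after running an unconditioned birth–death
    process forward from one lineage for ``duration`` time units.

    Used both by the tree simulator and as a Monte-Carlo check of the Yule
    growth law E[N(t)] = exp(birth_rate * t) when death_rate is 0.
    """
    # Gillespie over the lineage count: waiting time ~ Exp(n * (b + d)).
    n = 1
    t = 0.0
    total = birth_rate + death_rate
    if total == 0:
        return 1
    while n > 0:
        t += rng.exponential(1.0 / (n * total))
        if t >= duration:
            break
        if rng.random() < birth_rate / total:
            n += 1
            if n > max_lineages:
                raise RuntimeError("lineage count exploded; lower birth_rate or duration")
        else:
            n -= 1
    return n


def _simulate_bd_once(n_tips: int, birth_rate: float, death_rate: float,
                      rng: np.random.Generator) -> Optional[TreeNode]:
    """One forward birth–death attempt, stopped at the n_tips-th birth.

    Returns the root of the surviving genealogy (pruned of extinct lineages,
    unary nodes suppressed) or ``None`` if the process died out first.
    Node ``age`` temporarily holds the forward time of the node event.
    """
    root = TreeNode()
    root.age = 0.0
    alive: list[TreeNode] = [root]
    t = 0.0
    total = birth_rate + death_rate
    while len(alive) < n_tips:
        if not alive:
            return None
        t += rng.exponential(1.0 / (len(alive) * total)) if total > 0 else math.inf
        if total == 0:
            return None
        idx = rng.integers(len(alive))
        node = alive.pop(int(idx))
        node.age = t
        if rng.random() < birth_rate / total:
            for _ in range(2):
                child = TreeNode()
                alive.append(node.add_child(child))
        else:
            node.label = "__dead__"
    # the process holds n_tips lineages for one more exponential waiting
    # time; survivors become extant leaves there (avoids zero-length tips)
    t += rng.exponential(1.0 / (len(alive) * total))
    for node in alive:
        node.age = t
    # prune extinct lineages
    pruned = _prune(root, keep=lambda n: n.is_leaf and n.label != "__dead__")
    if pruned is None or len(pruned.leaves()) != n_tips:
        return None
    return pruned


def _prune(root: TreeNode, keep) -> Optional[TreeNode]:
    """Keep only leaves satisfying ``keep``; suppress unary nodes."""

    def rec(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return node if keep(node) else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].parent = node.parent
            return kept[0]
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    out = rec(root)
    if out is not None:
        out.parent = None
    return out


def simulate_dated_tree(n_tips: int, birth_rate: float, death_rate: float,
                        root_age: float, seed: int,
                        max_attempts: int = 10_000) -> DatedTree:
    """Constant-rate birth–death chronogram with exactly ``n_tips`` extant
    leaves, rescaled so the root (MRCA of the survivors) sits at ``root_age``.

    Conditioning on ``n_tips`` is by rejection with a bounded attempt count;
    exhausting the bound raises ``RuntimeError`` rather than silently
    retrying forever.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0 or death_rate < 0:
        raise ValueError("need birth_rate > 0 and death_rate >= 0")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        root = _simulate_bd_once(n_tips, birth_rate, death_rate, rng)
        if root is None:
            continue
        # forward times -> ages; rescale so the root is at root_age
        tip_time = max(n.age for n in root.leaves())
        span = tip_time - root.age
        if span <= 0:
            continue
        scale = root_age / span
        for node in root.postorder():
            node.age = (tip_time - node.age) * scale if not node.is_leaf else 0.0
        for i, leaf in enumerate(root.leaves()):
            leaf.label = f"t{i:02d}"
        tree = DatedTree(root)
        tree.validate()
        return tree
    raise RuntimeError(
        f"birth–death simulation failed to yield {n_tips} survivors "
        f"in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# gene families with planted events
# ---------------------------------------------------------------------------

def simulate_gene_family(tree: DatedTree, params: SimulationParams
                         ) -> tuple[Optional[GeneTree], TrueEventLog]:
    """Evolve one gene family down ``tree``; return its tree and planted log.

    Gene lineages copy at speciation nodes (SPC logged per passage),
    duplicate/transfer/die at exponential waiting times, and become leaves at
    age 0 labelled with their host taxon.  A family with no surviving leaf is
    extinct: the gene tree is ``None`` and the log still records what
    happened.
    """
    rng = np.random.default_rng(params.seed)
    events: list[TrueEvent] = []

    if params.birth_branch == "root":
        start_branch = None  # conceptual stem above the root
        top = tree.root_age
    else:
        start_node = tree.node_by_id(params.birth_branch)
        if start_node.parent is None:
            start_branch = None
            top = tree.root_age
        else:
            start_branch = start_node
            top = start_node.parent.age
    birth_time = params.birth_time if params.birth_time is not None else top
    if not (0.0 <= birth_time <= tree.root_age):
        raise ValueError("birth time outside [0, root age]")
    if start_branch is not None and not (start_branch.age <= birth_time <= start_branch.parent.age):
        raise ValueError("birth time outside the span of the birth branch")

    birth_event = TrueEvent("BIRTH", birth_time,
                            start_branch.id if start_branch is not None else "root")
    events.append(birth_event)
    links: list[tuple[TrueEvent, TreeNode]] = []  # branching events -> gene node

    total_rate = params.dup_rate + params.hgt_rate + params.loss_rate

    def spawn(branch: Optional[TreeNode], t: float) -> TreeNode:
        """Evolve one gene lineage on species ``branch`` from age ``t`` toward 0.

        ``branch is None`` means the stem above the species root.  Returns the
        gene-tree node for this lineage (possibly flagged dead).
        """
        gnode = TreeNode()
        while True:
            end = branch.age if branch is not None else tree.root_age
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if t - wait <= end:
                # reach the bottom of the branch (a species node) untouched
                t = end
                target = branch if branch is not None else tree.root
                if branch is not None and branch.is_leaf:
                    gnode.label = branch.label
                    return gnode
                ev = TrueEvent("SPC", t, target.id)
                events.append(ev)
                links.append((ev, gnode))
                for sp_child in target.children:
                    gnode.add_child(spawn(sp_child, t))
                return gnode
            t -= wait
            u = rng.random() * total_rate
            if u < params.dup_rate:
                ev = TrueEvent("DUP", t, branch.id if branch is not None else "root")
                events.append(ev)
                links.append((ev, gnode))
                gnode.add_child(spawn(branch, t))
                gnode.add_child(spawn(branch, t))
                return gnode
            if u < params.dup_rate + params.hgt_rate:
                donor_id = branch.id if branch is not None else "root"
                candidates = [b for b in tree.branches_alive_at(t) if b is not branch]
                if not candidates:
                    continue  # nowhere to transfer to; lineage carries on
                recipient = candidates[int(rng.integers(len(candidates)))]
                ev = TrueEvent("HGT", t, donor_id,
                               donor=donor_id, recipient=recipient.id)
                events.append(ev)
                links.append((ev, gnode))
                gnode.add_child(spawn(branch, t))      # donor copy carries on
                gnode.add_child(spawn(recipient, t))   # new copy in recipient
                return gnode
            events.append(TrueEvent("LOS", t, branch.id if branch is not None else "root",
                                    visible=False))
            gnode.label = "__dead__"
            return gnode

    root = spawn(start_branch, birth_time)
    observable = _observable_counts(root, birth_event, links)
    pruned = _prune(root, keep=lambda n: n.label is not None and n.label != "__dead__")
    log = TrueEventLog(events, observable=observable)
    if pruned is None:
        return None, log
    return GeneTree(pruned, rooted=True), log


def _observable_counts(root: TreeNode, birth_event: TrueEvent,
                       links: list[tuple[TrueEvent, TreeNode]]) -> dict[str, int]:
    """Event multiset a perfect parsimony reconciliation could report.

    Events inside fully extinct subtrees leave no trace; a branching with one
    surviving side collapses (speciation -> one loss; duplication -> nothing;
    transfer with only the recipient surviving -> transfer + donor loss).
    The per-event ``visible`` flags are set as a side effect.
    """
    survives: dict[int, bool] = {}
    for n in root.postorder():
        if n.is_leaf:
            survives[id(n)] = n.label is not None and n.label != "__dead__"
        else:
            survives[id(n)] = any(survives[id(c)] for c in n.children)
    obs = {c: 0 for c in ("BIRTH", "SPC", "DUP", "HGT", "LOS")}
    birth_event.visible = survives[id(root)]
    obs["BIRTH"] = int(birth_event.visible)
    # one-sided branchings above the first surviving split leave no trace at
    # all: a minimal scenario just places the (free) birth below them
    collapsed: set[int] = set()
    cur = root
    while cur.children and survives[id(cur)]:
        alive = [c for c in cur.children if survives[id(c)]]
        if len(alive) == 2:
            break
        collapsed.add(id(cur))
        cur = alive[0]
    for ev, node in links:
        if id(node) in collapsed:
            ev.visible = False
            continue
        sides = [survives[id(c)] for c in node.children]
        if ev.event_class == "SPC":
            if all(sides):
                ev.visible = True
                obs["SPC"] += 1
            else:
                ev.visible = False
                if any(sides):
                    obs["LOS"] += 1  # pass-through speciation-loss
        elif ev.event_class == "DUP":
            ev.visible = all(sides)
            obs["DUP"] += int(ev.visible)
        else:  # HGT: children are (donor copy, recipient copy)
            donor_side, recipient_side = sides
            ev.visible = bool(recipient_side)
            if recipient_side:
                obs["HGT"] += 1
                if not donor_side:
                    obs["LOS"] += 1  # transfer whose donor copy died
    return obs


# ---------------------------------------------------------------------------
# topological noise
# ---------------------------------------------------------------------------

def perturb_gene_tree(tree: GeneTree, n_nni: int, seed: int) -> GeneTree:
    """Apply ``n_nni`` random nearest-neighbour interchanges; leaves unchanged."""
    if n_nni < 0:
        raise ValueError("n_nni must be nonnegative")
    out = tree.copy()
    if n_nni == 0:
        return out
    if len(out.leaves) < 4:
        raise ValueError("NNI requires at least 4 leaves")
    rng = np.random.default_rng(seed)
    for _ in range(n_nni):
        nodes = list(out.postorder())
        # internal edges of the *unrooted* topology: the edge above each
        # internal node with a non-root parent, plus (once) the edge running
        # through the root when both root children are internal.
        edges: list[tuple[str, TreeNode]] = []
        for n in nodes:
            if n.is_leaf or n.parent is None:
                continue
            if n.parent.parent is not None:
                edges.append(("up", n))
            elif n is out.root.children[0]:
                sib = out.root.children[1]
                if not sib.is_leaf:
                    edges.append(("root", n))
        if not edges:
            raise ValueError("tree has no internal edge to rearrange")
        kind, edge_child = edges[int(rng.integers(len(edges)))]
        i = int(rng.integers(2))
        if kind == "up":
            parent = edge_child.parent
            sibling = next(c for c in parent.children if c is not edge_child)
            moved = edge_child.children[i]
            parent.children[parent.children.index(sibling)] = moved
            edge_child.children[i] = sibling
            moved.parent, sibling.parent = parent, edge_child
        else:
            # edge between the two root children: swap one grandchild across it
            sib = out.root.children[1]
            j = int(rng.integers(2))
            a, b = edge_child.children[i], sib.children[j]
            edge_child.children[i], sib.children[j] = b, a
            a.parent, b.parent = sib, edge_child
    return GeneTree(out.root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Alignment:
    """Leaf-labelled character matrix (rows follow ``labels``)."""

    labels: list[str]
    matrix: np.ndarray          # shape (n_taxa, n_sites), integer states
    alphabet: str

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, label: str) -> str:
        row = self.matrix[self.labels.index(label)]
        return "".join(self.alphabet[s] for s in row)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label in self.labels:
                fh.write(f">{label}\n{self.sequence(label)}\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        letters = sorted({c for r in records for c in str(r.seq).upper()})
        alphabet = "ACGT" if set(letters) <= set("ACGT") else "".join(letters)
        index = {c: i for i, c in enumerate(alphabet)}
        labels = [r.id for r in records]
        matrix = np.array(
            [[index[c] for c in str(r.seq).upper()] for r in records], dtype=np.int8
        )
        return cls(labels, matrix, alphabet)


def default_alphabet(size: int) -> str:
    if size == 4:
        return "ACGT"
    if size <= 20:
        return _AMINO[:size]
    raise ValueError("alphabet size must be <= 20")


def simulate_alignment(tree: DatedTree, rate: float, sites: int,
                       alphabet_size: int = 4, seed: int = 0) -> Alignment:
    """Equal-rates, equal-frequency K-state substitution along the chronogram.

    The expected number of substitutions per site on a branch of duration
    ``t`` is ``rate * t``; with probability ``exp(-K/(K-1) * d)`` a site keeps
    its parent state, otherwise it redraws uniformly over the K states (which
    reproduces the Jukes–Cantor transition probabilities for K=4).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if sites < 1:
        raise ValueError("sites must be >= 1")
    K = alphabet_size
    if K < 2:
        raise ValueError("alphabet size must be >= 2")
    rng = np.random.default_rng(seed)
    states: dict[TreeNode, np.ndarray] = {}
    states[tree.root] = rng.integers(0, K, size=sites)
    for node in tree.preorder():
        if node is tree.root:
            continue
        d = rate * (node.parent.age - node.age)
        eps = math.exp(-K / (K - 1) * d)
        seq = states[node.parent].copy()
        redraw = rng.random(sites) >= eps
        seq[redraw] = rng.integers(0, K, size=int(redraw.sum()))
        states[node] = seq
    leaves = tree.leaves
    labels = [n.label for n in leaves]
    matrix = np.vstack([states[n] for n in leaves]).astype(np.int8)
    return Alignment(labels, matrix, default_alphabet(K))


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "query_length", "truth_label",
]


def simulate_hit_table(n_hits: int, seed: int = 0, gene: str = "gene",
                       log10_evalue_range: tuple[float, float] = (-40.0, -2.0),
                       length_fraction_range: tuple[float, float] = (0.2, 1.0),
                       evalue_ceiling: float = 1e-12,
                       min_length_fraction: float = 0.5) -> pd.DataFrame:
    """Mock homology-search table in BLAST outfmt-6 column order.

    Each row carries ``query_length`` and a ``truth_label`` computed from the
    screening thresholds at generation time: pass iff the e-value is at most
    ``evalue_ceiling`` and the aligned fraction of the query is at least
    ``min_length_fraction``.
    """
    if n_hits < 0:
        raise ValueError("n_hits must be nonnegative")
    rng = np.random.default_rng(seed)
    lo, hi = log10_evalue_range
    evalues = 10.0 ** rng.uniform(lo, hi, size=n_hits)
    qlen = rng.integers(100, 600, size=n_hits)
    frac = rng.uniform(*length_fraction_range, size=n_hits)
    alen = np.maximum(1, np.rint(frac * qlen).astype(int))
    pident = np.round(rng.uniform(30, 100, size=n_hits), 1)
    mismatch = np.rint(alen * (1 - pident / 100)).astype(int)
    rows = pd.DataFrame(
        {
            "qseqid": [f"{gene}_q{i}" for i in range(n_hits)],
            "sseqid": [f"subj{i}" for i in range(n_hits)],
            "pident": pident,
            "length": alen,
            "mismatch": mismatch,
            "gapopen": rng.integers(0, 5, size=n_hits),
            "qstart": np.ones(n_hits, dtype=int),
            "qend": alen,
            "sstart": np.ones(n_hits, dtype=int),
            "send": alen,
            "evalue": evalues,
            "bitscore": np.round(rng.uniform(50, 900, size=n_hits), 1),
            "query_length": qlen,
        },
        columns=[c for c in HIT_TABLE_COLUMNS if c != "truth_label"],
    )
    rows["truth_label"] = (rows["evalue"] <= evalue_ceiling) & (
        rows["length"] / rows["query_length"] >= min_length_fraction
    )
    return rows
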