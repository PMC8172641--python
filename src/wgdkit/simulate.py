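"""Synthetic genome evolution: gene trees, Ks tables, counts, polyploid orders.

Gene families evolve by a linear birth--death process inside an ultrametric
species tree: one gene lineage enters the root; along every branch each
extant lineage duplicates at rate ``birth_rate`` and dies at rate
``death_rate`` (events per gene per time unit).  Episodic whole-genome
duplications double every lineage alive on the affected branch, each new
copy surviving with an independent per-lineage ``retention`` probability —
the positive-simulation convention of MAPS-style tests, which enforce at
least 20% retention.

A strict molecular clock maps node ages to synonymous divergence,
``ks = 2 * ks_rate * age``, with optional multiplicative gamma noise
(mean 1) to give Ks peaks realistic width.  Polyploid gene orders are
produced by whole-genome copying with per-gene fractionation loss and
random segmental inversions, yielding the doubled/fractionated synteny a
depth-ratio analysis must recover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Genome, GeneRecord
from .trees import Node, Tree, leaf_species, make_leaf_label

_INF = float("inf")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BDParams:
    """Linear birth--death rates, events per gene per time unit."""

    birth_rate: float = 0.002
    death_rate: float = 0.002

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth/death rates must be non-negative")


@dataclass(frozen=True)
class WGDEvent:
    """Episodic WGD on a species-tree branch.

    ``branch`` names the node *below* the edge (label, or post-order id as
    str/int); ``time_on_branch`` is measured from the parent node;
    ``retention`` is the per-lineage probability the extra copy survives.
    """

    branch: str
    time_on_branch: float
    retention: float = 1.0

    def __post_init__(self):
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        if self.time_on_branch < 0:
            raise ValueError("time_on_branch must be non-negative")


@dataclass(frozen=True)
class ClockParams:
    """Strict clock for the Ks axis: ks = 2 * ks_rate * age, gamma noise."""

    ks_rate: float = 0.01
    noise_cv: float = 0.15

    def __post_init__(self):
        if self.ks_rate <= 0:
            raise ValueError("ks_rate must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class FractionationParams:
    """Post-WGD duplicate loss and genome shuffling."""

    loss_prob: float = 0.0
    n_inversions: int = 0

    def __post_init__(self):
        if not (0 <= self.loss_prob < 1):
            raise ValueError("loss_prob must be in [0, 1)")
        if self.n_inversions < 0:
            raise ValueError("n_inversions must be non-negative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _resolve_branch(species_tree: Tree, branch) -> Node:
    key = str(branch)
    for node in species_tree.preorder():
        if node.label == key or str(node.id) == key:
            return node
    raise SimulationError(f"unknown WGD branch id {branch!r}")


# --------------------------------------------------------------------------
# gene-tree simulation
# --------------------------------------------------------------------------

def simulate_gene_tree(
    species_tree: Tree,
    bd: BDParams,
    wgds: list[WGDEvent] = (),
    seed=0,
) -> Tree:
    """Simulate one gene tree inside an ultrametric species tree.

    Returns a time-ultrametric gene tree with leaves labelled
    ``SPECIES|gene``; extinct subtrees are pruned and unifurcations
    suppressed.  Internal nodes carry ``depth`` (time from the species-tree
    root), from which duplicate ages are read.
    """
    if not species_tree.is_ultrametric():
        raise SimulationError("species tree must be ultrametric")
    rng = _as_rng(seed)
    species_tree.set_depths()

    events: dict[int, list[WGDEvent]] = {}
    for ev in wgds:
        snode = _resolve_branch(species_tree, ev.branch)
        if snode.parent is None:
            raise SimulationError("cannot place a WGD above the root")
        if ev.time_on_branch > (snode.length or 0.0):
            raise SimulationError(
                f"WGD time {ev.time_on_branch} exceeds branch length of {ev.branch!r}"
            )
        events.setdefault(snode.id, []).append(ev)
    for lst in events.values():
        lst.sort(key=lambda e: e.time_on_branch)

    lam, mu = bd.birth_rate, bd.death_rate
    total = lam + mu
    counters = itertools.count(1)

    def combine(depth: float, kids: list[Node]) -> Node | None:
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node()
        node.depth = depth
        for k in kids:
            node.add_child(k)
        return node

    def at_node(snode: Node) -> Node | None:
        """One gene lineage sitting exactly at species node ``snode``."""
        if snode.is_leaf:
            leaf = Node(make_leaf_label(snode.label, f"g{next(counters)}"))
            leaf.depth = snode.depth
            return leaf
        kids = [evolve_edge(c.parent.depth, c, 0) for c in snode.children]
        return combine(snode.depth, kids)

    def evolve_edge(d: float, snode: Node, ev_i: int) -> Node | None:
        """One gene lineage at depth ``d`` on the edge above ``snode``."""
        edge_events = events.get(snode.id, ())
        while True:
            if ev_i < len(edge_events):
                stop = snode.parent.depth + edge_events[ev_i].time_on_branch
            else:
                stop = snode.depth
            wait = rng.exponential(1.0 / total) if total > 0 else _INF
            if d + wait < stop:
                d += wait
                if rng.random() * total < lam:  # duplication
                    kids = [evolve_edge(d, snode, ev_i), evolve_edge(d, snode, ev_i)]
                    return combine(d, kids)
                return None  # death
            d = stop
            if ev_i < len(edge_events):
                ev = edge_events[ev_i]
                ev_i += 1
                if rng.random() < ev.retention:
                    kids = [evolve_edge(d, snode, ev_i), evolve_edge(d, snode, ev_i)]
                    return combine(d, kids)
                # extra copy lost immediately; original continues
            else:
                return at_node(snode)

    root = at_node(species_tree.root)
    if root is None:
        raise SimulationError("gene family went extinct before the present")
    root.depth = root.depth if root.depth is not None else 0.0
    # derive branch lengths from depths
    def _lengths(n: Node):
        for c in n.children:
            c.length = c.depth - n.depth
            _lengths(c)

    if root.parent is None:
        root.length = None
    _lengths(root)
    return Tree(root)


def simulate_tree_set(
    species_tree: Tree,
    bd: BDParams,
    wgds: list[WGDEvent] = (),
    n: int = 1,
    require_full_coverage: bool = False,
    seed=0,
    max_attempts: int = 10**6,
) -> tuple[list[Tree], float]:
    """Simulate ``n`` gene trees; optionally rejection-sample for coverage.

    With ``require_full_coverage`` each accepted tree has at least one tip
    per species.  Returns ``(trees, acceptance_rate)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    all_species = set(species_tree.leaf_labels())
    trees: list[Tree] = []
    attempts = 0
    while len(trees) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"acceptance rate {len(trees)/attempts:.2e} too low after "
                f"{max_attempts} attempts; rates incompatible with coverage"
            )
        try:
            tree = simulate_gene_tree(species_tree, bd, wgds, rng)
        except SimulationError as exc:
            if "extinct" in str(exc):
                continue
            raise
        if require_full_coverage and leaf_species(tree) != all_species:
            continue
        trees.append(tree)
        if attempts >= 1000 and len(trees) / attempts < 1e-3:
            raise SimulationError(
                f"acceptance rate {len(trees)/attempts:.2e} below 1e-3; "
                "rates incompatible with coverage"
            )
    return trees, len(trees) / attempts


# --------------------------------------------------------------------------
# Ks assignment
# --------------------------------------------------------------------------

def assign_pairwise_ks(gene_tree: Tree, clock: ClockParams, seed=0) -> pd.DataFrame:
    """Pairwise Ks for every leaf pair: ``2 * ks_rate * MRCA age`` with
    multiplicative gamma noise (mean 1, CV ``noise_cv``).

    The returned table has columns gene_a, gene_b, ks, node_id, where
    node_id is the post-order id of the pair's MRCA in ``gene_tree``.
    """
    rng = _as_rng(seed)
    if not gene_tree.is_ultrametric(tol=1e-6):
        raise SimulationError("gene tree must be ultrametric")
    gene_tree.set_depths()
    height = max(lf.depth for lf in gene_tree.leaves())

    rows = []
    # leaves under each node, built post-order; cross-child pairs have that
    # node as MRCA
    cache: dict[int, list[Node]] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            cache[node.id] = [node]
            continue
        groups = [cache[c.id] for c in node.children]
        age = height - node.depth
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        rows.append((a.label, b.label, age, node.id))
        cache[node.id] = [lf for grp in groups for lf in grp]

    ages = np.array([r[2] for r in rows], dtype=float)
    ks = 2.0 * clock.ks_rate * ages
    if clock.noise_cv > 0 and len(ks):
        shape = 1.0 / clock.noise_cv**2
        ks = ks * rng.gamma(shape, 1.0 / shape, size=len(ks))
    return pd.DataFrame(
        {
            "gene_a": [r[0] for r in rows],
            "gene_b": [r[1] for r in rows],
            "ks": ks,
            "node_id": [r[3] for r in rows],
        }
    )


# --------------------------------------------------------------------------
# polyploid gene orders
# --------------------------------------------------------------------------

def simulate_polyploid_genome(
    base: Genome,
    rounds: int,
    fract: FractionationParams = FractionationParams(),
    seed=0,
    copies: int = 2,
) -> Genome:
    """Apply ``rounds`` of whole-genome multiplication with fractionation.

    Each round multiplies every chromosome to ``copies`` total copies
    (default 2: a WGD; 3 emulates a triplication), deletes each gene of the
    *new* copies with probability ``loss_prob``, then applies
    ``n_inversions`` random rank-interval reversals per chromosome.
    Family ids are preserved so cross-genome anchors exist; ``rounds=0``
    returns the base unchanged.
    """
    if base.n_genes == 0:
        raise ValueError("empty base genome")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if copies < 2:
        raise ValueError("copies must be >= 2")
    rng = _as_rng(seed)
    chroms = {c: list(genes) for c, genes in base.chromosomes.items()}
    if rounds == 0:
        return Genome(chroms).validate()

    for rnd in range(1, rounds + 1):
        new_chroms: dict[str, list[GeneRecord]] = {}
        for chrom, genes in chroms.items():
            new_chroms[chrom] = list(genes)
            for copy_i in range(2, copies + 1):
                suffix = f"_r{rnd}c{copy_i}"
                kept = []
                for g in genes:
                    if fract.loss_prob > 0 and rng.random() < fract.loss_prob:
                        continue
                    kept.append(
                        GeneRecord(g.gene_id + suffix, g.family_id, 0, g.strand)
                    )
                new_chroms[chrom + suffix] = kept
        # segmental inversions, then re-rank gapless
        for chrom, genes in new_chroms.items():
            for _ in range(fract.n_inversions):
                if len(genes) < 2:
                    break
                i, j = sorted(rng.integers(0, len(genes), size=2))
                seg = [
                    GeneRecord(
                        g.gene_id,
                        g.family_id,
                        0,
                        {"+": "-", "-": "+"}.get(g.strand, g.strand),
                    )
                    for g in reversed(genes[i : j + 1])
                ]
                genes[i : j + 1] = seg
            new_chroms[chrom] = [
                GeneRecord(g.gene_id, g.family_id, rank, g.strand)
                for rank, g in enumerate(genes)
            ]
        chroms = new_chroms
    return Genome(chroms).validate()


def make_base_genome(
    n_chromosomes: int = 2, genes_per_chromosome: int = 500, prefix: str = "base"
) -> Genome:
    """A single-copy ancestral genome: one family per gene, '+' strand."""
    chroms: dict[str, list[GeneRecord]] = {}
    fam = itertools.count()
    for c in range(n_chromosomes):
        name = f"{prefix}_chr{c + 1}"
        chroms[name] = [
            GeneRecord(f"{name}_g{r}", f"fam{next(fam)}", r, "+")
            for r in range(genes_per_chromosome)
        ]
    return Genome(chroms).validate()


# --------------------------------------------------------------------------
# gene counts
# --------------------------------------------------------------------------

def simulate_gene_counts(
    species_tree: Tree,
    bd: BDParams,
    n_families: int,
    seed=0,
) -> pd.DataFrame:
    """Family-by-species gene counts: tip census of independent gene trees.

    No coverage filter is applied; families extinct in every species appear
    as all-zero rows.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = _as_rng(seed)
    species = sorted(species_tree.leaf_labels())
    rows = np.zeros((n_families, len(species)), dtype=int)
    idx = {s: i for i, s in enumerate(species)}
    for f in range(n_families):
        try:
            tree = simulate_gene_tree(species_tree, bd, (), rng)
        except SimulationError as exc:
            if "extinct" in str(exc):
                continue
            raise
        for lf in tree.leaves():
            sp = lf.label.split("|", 1)[0]
            rows[f, idx[sp]] += 1
    return pd.DataFrame(
        rows, columns=species, index=[f"family_{i}" for i in range(n_families)]
    )
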