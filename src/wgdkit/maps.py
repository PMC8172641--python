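"""MAPS-style phylogenomic placement of WGDs on a ladderized species tree.

For a strictly ladderized (caterpillar) species tree, each internal node
N1..N(k-1) of the ingroup ladder defines a nested taxon set.  Every gene
tree is rooted at a designated outgroup tip; each internal gene-tree node is
mapped to the species-tree node that is the LCA of its leaf-species set,
and flagged as a duplication when its children's species sets overlap
(species-overlap reconciliation).  Counting maximal subtrees and shared
duplications at each node gives the observed duplication percentages,
which are compared with birth--death null simulations (and retention
>= 0.2 positive simulations) by one-sided Fisher's exact tests, with
uncertainty from resampling 1000 trees without replacement 100 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import fisher_exact

from .simulate import BDParams, WGDEvent, simulate_tree_set
from .trees import Node, Tree, split_leaf_label

DEFAULT_N_NULL = 3000
DEFAULT_RESAMPLE_SIZE = 1000
DEFAULT_RESAMPLE_REPS = 100
DEFAULT_ALPHA = 0.05
RETENTION_MIN = 0.2


class LadderError(ValueError):
    pass


# --------------------------------------------------------------------------
# ladder specification
# --------------------------------------------------------------------------

@dataclass
class LadderSpec:
    """A ladderized species tree split into ingroup ladder and outgroups.

    ``ingroup`` is ordered tip-to-root; node ``N{i}`` is the ancestor of
    ``ingroup[: i + 1]``.  The tree (when carried) must be strictly
    ladderized and ultrametric so null/positive simulations can run on it.
    """

    ingroup: list[str]
    outgroup: list[str]
    tree: Tree | None = None

    def __post_init__(self):
        if len(self.ingroup) < 2:
            raise LadderError("need at least two ingroup taxa")
        if set(self.ingroup) & set(self.outgroup):
            raise LadderError("ingroup and outgroup overlap")
        if self.tree is not None:
            have = set(self.tree.leaf_labels())
            want = set(self.ingroup) | set(self.outgroup)
            if have != want:
                raise LadderError(f"tree taxa {sorted(have)} != spec taxa {sorted(want)}")
            if not self.tree.is_ladder():
                raise LadderError("species tree is not strictly ladderized")

    @property
    def node_names(self) -> list[str]:
        return [f"N{i}" for i in range(1, len(self.ingroup))]

    def node_taxa(self, name: str) -> frozenset[str]:
        i = int(name[1:])
        return frozenset(self.ingroup[: i + 1])

    def all_species(self) -> set[str]:
        return set(self.ingroup) | set(self.outgroup)

    @classmethod
    def from_tree(cls, tree: Tree, outgroup: list[str]) -> "LadderSpec":
        """Derive the tip-to-root ingroup order from a ladder tree."""
        if not tree.is_ladder():
            raise LadderError("species tree is not strictly ladderized")
        order: list[str] = []
        node = tree.root
        rootward: list[str] = []
        while not node.is_leaf:
            leaf_kids = [c for c in node.children if c.is_leaf]
            internal = [c for c in node.children if not c.is_leaf]
            if not internal:
                # terminal cherry: keep child order after the final reversal
                rootward.extend(lf.label for lf in reversed(leaf_kids))
                break
            rootward.extend(lf.label for lf in leaf_kids)
            (node,) = internal
        order = rootward[::-1]
        ingroup = [t for t in order if t not in set(outgroup)]
        return cls(ingroup, outgroup, tree)


def make_ladder_tree(
    ingroup: list[str],
    outgroup: list[str],
    node_ages: list[float],
) -> tuple[Tree, LadderSpec]:
    """Build an ultrametric caterpillar species tree.

    ``node_ages`` are the ages (time before present) of the successive
    ancestors, tip-to-root: first the (ingroup[0], ingroup[1]) ancestor,
    then one age per additional ingroup taxon, then one per outgroup.
    Internal nodes are labelled N1, N2, ... up the ingroup ladder.
    """
    taxa = ingroup[1:] + outgroup
    if len(node_ages) != len(taxa):
        raise LadderError(
            f"need {len(taxa)} node ages (one per taxon beyond the first)"
        )
    if any(b <= a for a, b in zip(node_ages, node_ages[1:])):
        raise LadderError("node ages must increase tip-to-root")
    height = node_ages[-1]

    core = Node(ingroup[0])
    core_age = 0.0
    for i, (taxon, age) in enumerate(zip(taxa, node_ages), start=1):
        parent = Node(f"N{i}" if i <= len(ingroup) - 1 else f"R{i}")
        leaf = Node(taxon, length=age)
        core.length = age - core_age
        parent.add_child(core)
        parent.add_child(leaf)
        core, core_age = parent, age
    core.length = None
    tree = Tree(core)
    tree.set_depths()
    spec = LadderSpec(list(ingroup), list(outgroup), tree)
    return tree, spec


# --------------------------------------------------------------------------
# duplication mapping
# --------------------------------------------------------------------------

def map_duplications(
    gene_tree: Tree, ladder: LadderSpec
) -> tuple[dict[str, int], dict[str, int]]:
    """Count subtrees and shared duplications at each ladder node.

    The gene tree is rooted at the first outgroup tip (sorted by label).
    Each internal node maps to the species-tree node that is the LCA of its
    leaf-species set; it is a duplication when its children's species sets
    intersect.  The counting unit is the *maximal* subtree at a node: a
    gene-tree node mapping to N whose parent maps elsewhere.  Nodes mapping
    to the same ladder node form parent-linked regions, so each maximal
    subtree is counted once and flagged duplicated when any node of its
    region is a duplication.  Counting subtrees rather than whole trees
    keeps the percentage comparable between null and WGD simulations: an
    extra retained genome copy contributes both extra duplications and
    extra subtrees at descendant nodes.

    Returns ``(totals, duplicated)``: per ladder node, the number of
    maximal subtrees and how many of them contain a shared duplication.
    """
    og_tips = sorted(
        lf.label for lf in gene_tree.leaves()
        if split_leaf_label(lf.label)[0] in set(ladder.outgroup)
    )
    if not og_tips:
        raise LadderError("gene tree has no outgroup tip")
    rooted = gene_tree.rerooted_at_leaf(og_tips[0])

    ingroup_set = set(ladder.ingroup)
    pos = {t: i for i, t in enumerate(ladder.ingroup)}
    totals = {n: 0 for n in ladder.node_names}
    duplicated = {n: 0 for n in ladder.node_names}

    species_below: dict[int, set[str]] = {}
    ladder_idx: dict[int, int] = {}  # -1: not on the ladder
    region_dup: dict[int, bool] = {}
    for node in rooted.postorder():
        if node.is_leaf:
            species_below[node.id] = {split_leaf_label(node.label)[0]}
            ladder_idx[node.id] = -1
            region_dup[node.id] = False
            continue
        child_sets = [species_below[c.id] for c in node.children]
        sp = set().union(*child_sets)
        species_below[node.id] = sp
        if not sp <= ingroup_set or len(sp) < 2:
            idx = -1
        else:
            idx = max(pos[s] for s in sp)  # LCA on the ladder, tip-to-root
        ladder_idx[node.id] = idx
        is_dup = idx >= 1 and any(
            child_sets[i] & child_sets[j]
            for i in range(len(child_sets))
            for j in range(i + 1, len(child_sets))
        )
        region_dup[node.id] = is_dup or any(
            region_dup[c.id] for c in node.children if ladder_idx[c.id] == idx
        )
        # children mapping to a shallower ladder node than this one head
        # their own maximal subtrees
        for c in node.children:
            ci = ladder_idx[c.id]
            if ci >= 1 and ci != idx:
                totals[f"N{ci}"] += 1
                duplicated[f"N{ci}"] += int(region_dup[c.id])
    # the root of the rooted tree closes any remaining region
    ri = ladder_idx[rooted.root.id]
    if ri >= 1:
        totals[f"N{ri}"] += 1
        duplicated[f"N{ri}"] += int(region_dup[rooted.root.id])
    return totals, duplicated


@dataclass
class MapsResult:
    """Per-node subtree totals, shared-duplication counts and percentages."""

    table: pd.DataFrame  # index: node names; columns subtree_total, shared_dups, pct
    n_trees: int
    n_skipped: int = 0
    flags: np.ndarray | None = None  # (n_trees, n_nodes, 2) subtree/dup counts
    resample_ci: pd.DataFrame | None = None
    fisher: pd.DataFrame | None = None


def maps_table(gene_trees: list[Tree], ladder: LadderSpec) -> MapsResult:
    """Observed MAPS table over a collection of gene trees.

    Trees missing any species (no full coverage) or lacking an outgroup tip
    are skipped and counted.  Percentages are 100 * shared / total per node.
    """
    names = ladder.node_names
    want = ladder.all_species()
    flags = []
    skipped = 0
    for tree in gene_trees:
        species = {split_leaf_label(lf.label)[0] for lf in tree.leaves()}
        if species != want:
            skipped += 1
            continue
        try:
            total, dup = map_duplications(tree, ladder)
        except LadderError:
            skipped += 1
            continue
        flags.append([[total[n], dup[n]] for n in names])
    if not flags:
        raise LadderError("zero usable gene trees")
    arr = np.array(flags, dtype=np.int64)
    total = arr[:, :, 0].sum(axis=0)
    shared = arr[:, :, 1].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * shared / np.maximum(total, 1), 0.0)
    table = pd.DataFrame(
        {"subtree_total": total, "shared_dups": shared, "pct": pct}, index=names
    )
    return MapsResult(table, n_trees=len(flags), n_skipped=skipped, flags=arr)


# --------------------------------------------------------------------------
# null / positive simulation wrappers
# --------------------------------------------------------------------------

@dataclass
class NullModel:
    bd: BDParams
    n_trees: int = DEFAULT_N_NULL
    provenance: str = "supplied"  # or "estimated"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def run_null(ladder: LadderSpec, null: NullModel, seed=0) -> MapsResult:
    """Simulate coverage-filtered birth--death gene trees and tabulate."""
    if ladder.tree is None:
        raise LadderError("ladder has no species tree to simulate on")
    trees, _rate = simulate_tree_set(
        ladder.tree, null.bd, (), n=null.n_trees,
        require_full_coverage=True, seed=seed,
    )
    return maps_table(trees, ladder)


def run_positive(
    ladder: LadderSpec,
    null: NullModel,
    wgd_node: str,
    retention: float = RETENTION_MIN,
    time_fraction: float = 0.5,
    seed=0,
    allow_low_retention: bool = False,
) -> MapsResult:
    """As :func:`run_null` with one WGD on the branch above ``wgd_node``.

    Retention below 0.2 is rejected unless explicitly allowed (the positive
    simulations assume at least 20% of genes retained).  The event is placed
    ``time_fraction`` of the way down the branch.
    """
    if retention < RETENTION_MIN and not allow_low_retention:
        raise ValueError(
            f"retention {retention} < {RETENTION_MIN}; pass allow_low_retention=True"
        )
    if ladder.tree is None:
        raise LadderError("ladder has no species tree to simulate on")
    target = ladder.tree.find(wgd_node)
    if target is None:
        raise LadderError(f"unknown species-tree node {wgd_node!r}")
    wgd = WGDEvent(
        branch=wgd_node,
        time_on_branch=time_fraction * (target.length or 0.0),
        retention=retention,
    )
    trees, _rate = simulate_tree_set(
        ladder.tree, null.bd, [wgd], n=null.n_trees,
        require_full_coverage=True, seed=seed,
    )
    return maps_table(trees, ladder)


# --------------------------------------------------------------------------
# resampling and Fisher comparison
# --------------------------------------------------------------------------

def resample_percentages(
    result: MapsResult,
    ladder: LadderSpec,
    size: int = DEFAULT_RESAMPLE_SIZE,
    reps: int = DEFAULT_RESAMPLE_REPS,
    seed=0,
) -> pd.DataFrame:
    """Percentile CI of per-node percentages from without-replacement
    resamples of the tree pool (size 1000, 100 repetitions by default)."""
    if result.flags is None:
        raise ValueError("result carries no per-tree flags")
    pool = result.flags
    n = pool.shape[0]
    if n < size:
        raise ValueError(
            f"pool of {n} trees smaller than resample size {size}; reduce size"
        )
    rng = np.random.default_rng(seed)
    pcts = np.empty((reps, pool.shape[1]))
    for r in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        sub = pool[idx]
        total = sub[:, :, 0].sum(axis=0)
        shared = sub[:, :, 1].sum(axis=0)
        pcts[r] = np.where(total > 0, 100.0 * shared / np.maximum(total, 1), 0.0)
    lo, hi = np.percentile(pcts, [2.5, 97.5], axis=0)
    ci = pd.DataFrame(
        {"pct_lo": lo, "pct_hi": hi}, index=ladder.node_names
    )
    result.resample_ci = ci
    return ci


def fisher_compare(
    observed: MapsResult,
    null: MapsResult,
    alpha: float = DEFAULT_ALPHA,
    positive: MapsResult | None = None,
) -> pd.DataFrame:
    """One-sided Fisher's exact tests for duplication enrichment per node.

    Each node's 2x2 table is [(shared, not-shared) x (observed, null)],
    tested with alternative='greater'; no cross-node multiple-testing
    correction is applied.  Nodes with a zero total get p = 1.  When a
    positive simulation (with resampling CI) is supplied, nodes are also
    flagged ``consistent_with_positive`` when significant *and* the observed
    percentage reaches the positive simulation's lower resampling bound.
    """
    if list(observed.table.index) != list(null.table.index):
        raise ValueError("observed and null results use different ladders")
    rows = []
    for node in observed.table.index:
        o = observed.table.loc[node]
        nl = null.table.loc[node]
        if o["subtree_total"] == 0 or nl["subtree_total"] == 0:
            p = 1.0
        else:
            table = [
                [int(o["shared_dups"]), int(o["subtree_total"] - o["shared_dups"])],
                [int(nl["shared_dups"]), int(nl["subtree_total"] - nl["shared_dups"])],
            ]
            p = float(fisher_exact(table, alternative="greater")[1])
        significant = p < alpha
        consistent = None
        if positive is not None and positive.resample_ci is not None:
            lower = positive.resample_ci.loc[node, "pct_lo"]
            consistent = bool(significant and o["pct"] >= lower)
        rows.append((node, p, significant, consistent))
    df = pd.DataFrame(
        rows, columns=["node", "p", "significant", "consistent_with_positive"]
    ).set_index("node")
    observed.fisher = df
    return df


# --------------------------------------------------------------------------
# birth--death rate estimation from gene counts
# --------------------------------------------------------------------------

def _transition_matrix(t: float, lam: float, mu: float, nmax: int) -> np.ndarray:
    """P(i -> j) in time t for the linear BDP truncated at ``nmax`` copies."""
    n = nmax + 1
    Q = np.zeros((n, n))
    idx = np.arange(1, nmax)
    Q[idx, idx + 1] = idx * lam
    Q[idx, idx - 1] = idx * mu
    Q[nmax, nmax - 1] = nmax * mu
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return expm(Q * t)


def estimate_bd_rates(
    gene_counts: pd.DataFrame,
    species_tree: Tree,
    nmax: int = 100,
) -> tuple[BDParams, dict]:
    """Maximum-likelihood global (λ, μ) from family-by-species gene counts.

    Counts are per-family tip censuses; all-zero families are dropped and
    the likelihood conditions on at least one surviving gene.  Returns the
    rates and a diagnostics dict (loglik, boundary warnings, n_families).
    """
    if not species_tree.is_ultrametric():
        raise ValueError("species tree must be ultrametric")
    counts = gene_counts.to_numpy(dtype=int)
    if (counts < 0).any():
        raise ValueError("negative gene counts")
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    if counts.shape[0] == 0:
        raise ValueError("no families with surviving genes")
    # compress duplicate count patterns for speed
    patterns, inverse, weights = np.unique(
        counts, axis=0, return_inverse=True, return_counts=True
    )

    order = sorted(species_tree.leaf_labels())
    if list(gene_counts.columns) != order:
        patterns = patterns[:, [list(gene_counts.columns).index(s) for s in order]]

    def nll(logrates: np.ndarray) -> float:
        lam, mu = np.exp(logrates)
        ll_patterns = _counts_loglik_per_pattern(patterns, species_tree, lam, mu, nmax)
        return -float(np.dot(weights, ll_patterns))

    best = None
    for start in ([-6.0, -6.0], [-5.0, -7.0], [-7.0, -5.0]):
        res = minimize(
            nll, np.array(start), method="L-BFGS-B",
            bounds=[(-14.0, 1.0)] * 2,
        )
        if best is None or res.fun < best.fun:
            best = res
    lam, mu = np.exp(best.x)
    diag = {
        "loglik": -float(best.fun),
        "n_families": int(weights.sum()),
        "boundary": bool(np.any(best.x <= -13.5)),
    }
    if diag["boundary"]:
        diag["warning"] = "rate estimate at boundary (degenerate counts)"
    return BDParams(float(lam), float(mu)), diag


def _counts_loglik_per_pattern(
    patterns: np.ndarray, tree: Tree, lam: float, mu: float, nmax: int
) -> np.ndarray:
    tree.set_depths()
    species = sorted({lf.label for lf in tree.leaves()})
    col = {s: i for i, s in enumerate(species)}
    n_fam = patterns.shape[0]
    nmax_eff = min(nmax, max(1, int(patterns.max()) + 5))
    nstates = nmax_eff + 1
    partial: dict[int, np.ndarray] = {}
    extinct: dict[int, np.ndarray] = {}
    mats: dict[float, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            P = np.zeros((n_fam, nstates))
            obs = np.clip(patterns[:, col[node.label]], 0, nmax_eff)
            P[np.arange(n_fam), obs] = 1.0
            E = np.zeros(nstates)
            E[0] = 1.0
        else:
            P = np.ones((n_fam, nstates))
            E = np.ones(nstates)
            for c in node.children:
                t = round(c.length or 0.0, 12)
                if t not in mats:
                    mats[t] = _transition_matrix(t, lam, mu, nmax_eff)
                M = mats[t]
                P *= partial[c.id] @ M.T
                E *= extinct[c.id] @ M.T
        partial[node.id] = P
        extinct[node.id] = E
    lik = partial[tree.root.id][:, 1]
    p_ext = extinct[tree.root.id][1]
    lik = np.maximum(lik, 1e-300) / max(1.0 - p_ext, 1e-12)
    return np.log(lik)
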