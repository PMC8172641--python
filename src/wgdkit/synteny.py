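"""Collinear anchor chaining and syntenic depth ratios.

Anchors are cross-genome gene pairs sharing a homology-family label (the
stand-in for all-against-all alignment hits).  Chains are maximal collinear
runs of anchors found per chromosome pair by longest-increasing-chain
dynamic programming, with a gap cut-off of ten genes on both genomes and at
least five pairs per block — the classic MCScan-style thresholds.  Depth is
the number of block spans covering each gene of the opposite genome; the
modal nonzero depths of the two profiles give the A:B multiplicity ratio
(1:2 for one extra WGD in B, 2:3 against a triplicated genome, and so on),
reported unreduced.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Genome

DEFAULT_MAX_GAP = 10
DEFAULT_MIN_PAIRS = 5
DEFAULT_FAMILY_CAP = 10


@dataclass(frozen=True)
class AnchorPair:
    chrom_a: str
    rank_a: int
    gene_a: str
    chrom_b: str
    rank_b: int
    gene_b: str
    family_id: str


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # same | inverted

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks) + 1

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks) + 1

    def __len__(self) -> int:
        return len(self.anchors)


def find_anchors(
    genome_a: Genome, genome_b: Genome, family_cap: int = DEFAULT_FAMILY_CAP
) -> list[AnchorPair]:
    """All cross-genome pairs within shared families.

    Families with more than ``family_cap`` members in either genome are
    skipped entirely (tandem-array guard).  Returns an empty list when the
    genomes share no families.
    """
    fams_a = genome_a.families()
    fams_b = genome_b.families()
    anchors: list[AnchorPair] = []
    for fam in sorted(set(fams_a) & set(fams_b)):
        mem_a, mem_b = fams_a[fam], fams_b[fam]
        if len(mem_a) > family_cap or len(mem_b) > family_cap:
            continue
        for chrom_a, ga in mem_a:
            for chrom_b, gb in mem_b:
                anchors.append(
                    AnchorPair(
                        chrom_a, ga.rank, ga.gene_id, chrom_b, gb.rank, gb.gene_id, fam
                    )
                )
    return anchors


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

def _gap_ok(prev: AnchorPair, nxt: AnchorPair, sign: int, max_gap: int) -> bool:
    da = nxt.rank_a - prev.rank_a
    db = sign * (nxt.rank_b - prev.rank_b)
    return 0 < da <= max_gap + 1 and 0 < db <= max_gap + 1


def _best_chain(
    anchors: list[AnchorPair], sign: int, max_gap: int
) -> list[AnchorPair]:
    """Maximal-cardinality collinear chain by O(n^2) DP.

    ``sign`` +1 requires rank_b strictly increasing, -1 strictly decreasing.
    Both-side gaps between consecutive chain members are <= max_gap
    intervening genes.  Ties resolved toward larger combined span, then
    lexicographically earliest anchors (deterministic).
    """
    if not anchors:
        return []
    srt = sorted(anchors, key=lambda a: (a.rank_a, sign * a.rank_b))
    n = len(srt)
    length = [1] * n
    parent = [-1] * n
    for i in range(n):
        for j in range(i):
            if _gap_ok(srt[j], srt[i], sign, max_gap) and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                parent[i] = j
    # deterministic tie-break among equal-length ends: widest span, then order
    max_len = max(length)
    candidates = [i for i in range(n) if length[i] == max_len]

    def span_of(end: int) -> int:
        chain = []
        k = end
        while k != -1:
            chain.append(srt[k])
            k = parent[k]
        ra = [a.rank_a for a in chain]
        rb = [a.rank_b for a in chain]
        return (max(ra) - min(ra)) + (max(rb) - min(rb))

    best_end = max(candidates, key=lambda i: (span_of(i), -i))
    chain = []
    k = best_end
    while k != -1:
        chain.append(srt[k])
        k = parent[k]
    chain.reverse()
    return chain


def chain_anchors(
    anchors: list[AnchorPair],
    max_gap: int = DEFAULT_MAX_GAP,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks, best-first with anchor consumption.

    Per chromosome pair, the best chain over both orientations is extracted,
    its anchors removed, and the search repeated; chains shorter than
    ``min_pairs`` are discarded.  Output order and content are independent
    of input anchor order.
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for key in sorted(by_pair):
        remaining = sorted(by_pair[key], key=lambda a: (a.rank_a, a.rank_b, a.gene_a))
        while True:
            same = _best_chain(remaining, +1, max_gap)
            inv = _best_chain(remaining, -1, max_gap)

            def score(chain):
                if not chain:
                    return (0, 0)
                ra = [a.rank_a for a in chain]
                rb = [a.rank_b for a in chain]
                return (len(chain), (max(ra) - min(ra)) + (max(rb) - min(rb)))

            if score(same) >= score(inv):
                chain, orientation = same, "same"
            else:
                chain, orientation = inv, "inverted"
            if len(chain) < min_pairs:
                break
            blocks.append(SyntenyBlock(key[0], key[1], chain, orientation))
            consumed = set(id(a) for a in chain)
            remaining = [a for a in remaining if id(a) not in consumed]
    return blocks


def validate_block(
    block: SyntenyBlock, max_gap: int = DEFAULT_MAX_GAP, min_pairs: int = DEFAULT_MIN_PAIRS
) -> bool:
    """Post-hoc check of the block invariants (size, monotonicity, gaps)."""
    if len(block) < min_pairs:
        return False
    sign = +1 if block.orientation == "same" else -1
    for prev, nxt in zip(block.anchors, block.anchors[1:]):
        if not _gap_ok(prev, nxt, sign, max_gap):
            return False
    return True


# --------------------------------------------------------------------------
# depth profiles and ratios
# --------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Per-gene coverage counts for one genome by blocks of the other."""

    per_gene: pd.DataFrame  # columns: chrom, rank, gene_id, depth
    histogram: Counter = field(default_factory=Counter)

    @property
    def total_depth(self) -> int:
        return int(self.per_gene["depth"].sum())

    def modal_nonzero_depth(self) -> int:
        nonzero = {d: c for d, c in self.histogram.items() if d > 0}
        if not nonzero:
            raise ValueError("all-zero depth profile")
        top = max(nonzero.values())
        return min(d for d, c in nonzero.items() if c == top)


def _profile(genome: Genome, spans: dict[str, list[tuple[int, int]]]) -> DepthProfile:
    rows = []
    for chrom, genes in genome.chromosomes.items():
        depth = np.zeros(len(genes) + 1, dtype=int)
        for lo, hi in spans.get(chrom, ()):  # difference array over ranks
            depth[lo] += 1
            depth[min(hi, len(genes))] -= 1
        depth = np.cumsum(depth[:-1])
        for g, d in zip(genes, depth):
            rows.append((chrom, g.rank, g.gene_id, int(d)))
    df = pd.DataFrame(rows, columns=["chrom", "rank", "gene_id", "depth"])
    return DepthProfile(df, Counter(df["depth"].tolist()))


def depth_profiles(
    blocks: list[SyntenyBlock], genome_a: Genome, genome_b: Genome
) -> tuple[DepthProfile, DepthProfile]:
    """Coverage of each genome's genes by the blocks' spans.

    The A-profile counts, for each gene of A, how many block spans (regions
    collinear with B) cover its rank; likewise for B.  Genes with zero
    coverage stay in histogram bin 0.
    """
    spans_a: dict[str, list[tuple[int, int]]] = {}
    spans_b: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        spans_a.setdefault(blk.chrom_a, []).append(blk.span_a)
        spans_b.setdefault(blk.chrom_b, []).append(blk.span_b)
    return _profile(genome_a, spans_a), _profile(genome_b, spans_b)


_WORDS = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five",
    6: "six", 7: "seven", 8: "eight", 9: "nine", 10: "ten",
}


@dataclass
class DepthRatio:
    """Unreduced syntenic multiplicity ratio between two genomes.

    ``mult_a`` is the modal depth of A-side coverage measured on B's genes
    (how many A regions align over a typical B gene) and vice versa, so an
    unduplicated A against a 1-WGD B prints "one-to-two".
    """

    mult_a: int
    mult_b: int
    histogram_a: Counter
    histogram_b: Counter

    def phrase(self, name_a: str = "A", name_b: str = "B") -> str:
        wa = _WORDS.get(self.mult_a, str(self.mult_a))
        wb = _WORDS.get(self.mult_b, str(self.mult_b))
        return f"{wa}-to-{wb} between {name_a} and {name_b}"

    def __str__(self) -> str:
        return f"{self.mult_a}:{self.mult_b}"


def depth_ratio(profile_a: DepthProfile, profile_b: DepthProfile) -> DepthRatio:
    """Modal multiplicity ratio from the two depth profiles.

    Modal depths are computed over covered genes only (bin 0 excluded);
    histograms are returned so bin 0 can be inspected.  The ratio is
    reported unreduced (2:4 stays 2:4).
    """
    mult_a = profile_b.modal_nonzero_depth()  # A-coverage measured on B
    mult_b = profile_a.modal_nonzero_depth()  # B-coverage measured on A
    return DepthRatio(mult_a, mult_b, profile_a.histogram, profile_b.histogram)


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for i, blk in enumerate(blocks):
        rows.append(
            (
                i, blk.chrom_a, blk.chrom_b, blk.orientation, len(blk),
                blk.span_a[0], blk.span_a[1], blk.span_b[0], blk.span_b[1],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block", "chrom_a", "chrom_b", "orientation", "n_anchors",
            "start_a", "end_a", "start_b", "end_b",
        ],
    )
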