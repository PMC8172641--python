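"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately re-derive results by enumeration, not by calling the
implementation under test.
"""

import itertools
import math

import numpy as np

from wgdkit.ks import STOP_CODONS, _CODON_TABLE

BASES = "ACGT"


# ----------------------------------------------------------- NG86 (site counting)

def oracle_sites(codon):
    """Synonymous/nonsynonymous site counts by enumerating all single-base
    mutations; stop-codon mutations excluded from the denominator."""
    syn = tot = 0
    for pos, alt in itertools.product(range(3), BASES):
        if alt == codon[pos]:
            continue
        mut = codon[:pos] + alt + codon[pos + 1:]
        if mut in STOP_CODONS:
            continue
        tot += 1
        syn += _CODON_TABLE[mut] == _CODON_TABLE[codon]
    return 3.0 * syn / tot, 3.0 * (tot - syn) / tot


def oracle_diffs(ca, cb):
    """Average syn/nonsyn steps over all stop-free mutational orderings;
    None when every ordering passes through a stop codon."""
    positions = [p for p in range(3) if ca[p] != cb[p]]
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            sd += _CODON_TABLE[nxt] == _CODON_TABLE[cur]
            nd += _CODON_TABLE[nxt] != _CODON_TABLE[cur]
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_ks(ca, cb):
    """Single-codon-pair Ks: None (undefined), 'saturated', or the value."""
    sa, _ = oracle_sites(ca)
    sb, _ = oracle_sites(cb)
    d = oracle_diffs(ca, cb)
    if d is None:
        return None
    S = (sa + sb) / 2
    ps = d[0] / S if S > 0 else 0.0
    if ps >= 0.75:
        return "saturated"
    return -0.75 * np.log(1 - 4 * ps / 3)


# ----------------------------------------------------- collinear chain search

def brute_force_chain_sizes(pairs, max_gap=10, min_pairs=5):
    """Best-first chain extraction by exhaustive subset enumeration.

    ``pairs`` are (rank_a, rank_b) anchors on one chromosome pair; returns
    the sorted multiset of extracted block sizes.
    """
    remaining = sorted(pairs)
    sizes = []
    while True:
        best = ()
        best_span = -1
        n = len(remaining)
        for mask in range(1, 1 << n):
            subset = [remaining[i] for i in range(n) if mask >> i & 1]
            subset.sort()
            for sign in (1, -1):
                ok = True
                for (a1, b1), (a2, b2) in zip(subset, subset[1:]):
                    da, db = a2 - a1, sign * (b2 - b1)
                    if not (0 < da <= max_gap + 1 and 0 < db <= max_gap + 1):
                        ok = False
                        break
                if ok:
                    ra = [p[0] for p in subset]
                    rb = [p[1] for p in subset]
                    span = (max(ra) - min(ra)) + (max(rb) - min(rb))
                    if (len(subset), span) > (len(best), best_span):
                        best = subset
                        best_span = span
        if len(best) < min_pairs:
            break
        sizes.append(len(best))
        remaining = [p for p in remaining if p not in best]
    return sorted(sizes)


# ------------------------------------------------------- hypergeometric tail

def hypergeom_tail(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total
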