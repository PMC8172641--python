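"""Duplicate-age (Ks) distributions, mixture-model peak detection, placement.

The WGD signal in a paranome is a secondary peak in the distribution of
synonymous divergence (Ks) between duplicate pairs.  This module provides:

* an NG86 synonymous/nonsynonymous estimator with Jukes--Cantor correction
  (a self-contained stand-in for codon-model ML; it systematically
  underestimates Ks at high divergence, see the methods note);
* node-weighted Ks distributions, in which every duplication node
  contributes total weight 1 split equally over its descendant pairs, so
  large families do not dominate the histogram;
* a weighted Gaussian EM mixture on ln(Ks) with component count chosen by a
  sequential parametric-bootstrap likelihood-ratio test;
* ortholog-divergence medians via reciprocal-best-pair selection, and the
  placement call (shared-ancestral vs lineage-specific) from CI comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

# --------------------------------------------------------------------------
# NG86 Ks estimator
# --------------------------------------------------------------------------

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                16 * _i + 4 * _j + _k
            ]
            _CODON_TABLE[_b1 + _b2 + _b3] = _aa

STOP_CODONS = {c for c, a in _CODON_TABLE.items() if a == "*"}
SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in STOP_CODONS)


class SaturationError(ValueError):
    """Synonymous differences at or beyond the Jukes--Cantor ceiling."""


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Of the codon's nine possible single-base changes, the fraction that is
    synonymous (over all positions jointly) is scaled to the codon's three
    sites; changes creating a stop codon are excluded from the denominator.
    """
    aa = _CODON_TABLE[codon]
    s = n = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if _CODON_TABLE[mut] == aa:
                s += 1
            else:
                n += 1
    return 3.0 * s / (s + n), 3.0 * n / (s + n)


_SITES = {c: _codon_sites(c) for c in SENSE_CODONS}


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All mutational orderings between the two codons are averaged; orderings
    passing through a stop codon are discarded.  Raises ValueError when no
    stop-free pathway exists.
    """
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0

    paths: list[tuple[float, float]] = []

    def walk(current: str, remaining: list[int], sd: float, nd: float):
        if not remaining:
            paths.append((sd, nd))
            return
        for i, pos in enumerate(remaining):
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                continue
            step_syn = _CODON_TABLE[nxt] == _CODON_TABLE[current]
            walk(
                nxt,
                remaining[:i] + remaining[i + 1 :],
                sd + (1.0 if step_syn else 0.0),
                nd + (0.0 if step_syn else 1.0),
            )

    walk(ca, diff_pos, 0.0, 0.0)
    if not paths:
        raise ValueError(f"no stop-free mutational pathway between {ca} and {cb}")
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor saturated")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_ks(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """Nei--Gojobori (1986) Ks and Ka with Jukes--Cantor correction.

    Sequences must be aligned coding sequences of equal length, a multiple
    of 3, without internal stop codons; codons containing gaps or ambiguous
    bases in either sequence are dropped pairwise.  Returns
    ``(ks, ka, syn_sites, nonsyn_sites)`` with site counts averaged over the
    two sequences.  Symmetric in its arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")

    syn_sites = nonsyn_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(b not in _BASES for b in ca + cb):
            continue  # gapped or ambiguous codon dropped pairwise
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {i}")
        sa = _SITES[ca]
        sb = _SITES[cb]
        syn_sites += (sa[0] + sb[0]) / 2.0
        nonsyn_sites += (sa[1] + sb[1]) / 2.0
        d = _pathway_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = sd / syn_sites if syn_sites > 0 else 0.0
    pn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    # only synonymous saturation is an error; a saturated ka is reported NaN
    ka = _jc_correct(pn) if pn < 0.75 else float("nan")
    return _jc_correct(ps), ka, syn_sites, nonsyn_sites


# --------------------------------------------------------------------------
# node-weighted distribution
# --------------------------------------------------------------------------

@dataclass
class KsDistribution:
    """Windowed, weighted Ks observations for mixture fitting."""

    values: pd.DataFrame  # columns: ks, weight, node_id
    window: tuple[float, float]

    @property
    def n_effective(self) -> float:
        return float(self.values["weight"].sum())

    def __len__(self) -> int:
        return len(self.values)


def node_weighted_distribution(
    ks_table: pd.DataFrame,
    window: tuple[float, float] = (0.01, 3.0),
    node_weighted: bool = True,
) -> KsDistribution:
    """Build a duplicate-age distribution from a Ks table.

    Values outside ``window`` are dropped first; then, when node ids are
    present and ``node_weighted``, each duplication node's surviving pairs
    share total weight 1 equally.  Pairs without node tags (or with
    ``node_weighted=False``) get weight 1 each, so the weighted mass equals
    the number of retained nodes (or pairs).
    """
    lo, hi = window
    df = ks_table.copy()
    df = df[(df["ks"] >= lo) & (df["ks"] <= hi)].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no ks values inside window [{lo}, {hi}]")
    if node_weighted and "node_id" in df.columns and df["node_id"].notna().all():
        sizes = df.groupby("node_id")["ks"].transform("size")
        df["weight"] = 1.0 / sizes
    else:
        df["weight"] = 1.0
        df["node_id"] = df.get("node_id", pd.Series(range(len(df))))
    return KsDistribution(df[["ks", "weight", "node_id"]], window)


# --------------------------------------------------------------------------
# weighted Gaussian EM on ln(Ks)
# --------------------------------------------------------------------------

@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray  # means of ln Ks
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    selection_trace: list[dict] = field(default_factory=list)

    @property
    def medians(self) -> np.ndarray:
        """Component medians on the Ks scale (lognormal identity e^mean)."""
        return np.exp(self.means)

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        return norm.logpdf(
            x[:, None], self.means[None, :], self.sds[None, :]
        ) + np.log(self.weights[None, :])


_SD_FLOOR = 1e-3

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _njit(**kw):
        return lambda f: f


@_njit(cache=True, fastmath=True)
def _em_core(x, w, means, sds, pis, tol, max_iter):  # pragma: no cover - jitted
    n = x.shape[0]
    k = means.shape[0]
    wsum = w.sum()
    prev_ll = -1e300
    ll = prev_ll
    converged = False
    decreased = False
    it = 0
    lp = np.empty(k)
    e = np.empty(k)
    logc = np.empty(k)
    inv2v = np.empty(k)
    nk = np.empty(k)
    sx = np.empty(k)
    sxx = np.empty(k)
    halflog2pi = 0.9189385332046727
    for it in range(1, max_iter + 1):
        ll = 0.0
        for j in range(k):
            nk[j] = 0.0
            sx[j] = 0.0
            sxx[j] = 0.0
            logc[j] = np.log(pis[j]) - np.log(sds[j]) - halflog2pi
            inv2v[j] = 0.5 / (sds[j] * sds[j])
        for i in range(n):
            xi = x[i]
            mx = -1e300
            for j in range(k):
                d = xi - means[j]
                lp[j] = logc[j] - d * d * inv2v[j]
                if lp[j] > mx:
                    mx = lp[j]
            s = 0.0
            for j in range(k):
                e[j] = np.exp(lp[j] - mx)
                s += e[j]
            ll += w[i] * (mx + np.log(s))
            wi_s = w[i] / s
            for j in range(k):
                r = e[j] * wi_s
                nk[j] += r
                sx[j] += r * xi
                sxx[j] += r * xi * xi
        if ll < prev_ll - 1e-6 * (abs(prev_ll) + 1.0):
            decreased = True
            break
        for j in range(k):
            nkj = max(nk[j], 1e-12)
            pis[j] = nkj / wsum
            m = sx[j] / nkj
            v = sxx[j] / nkj - m * m
            means[j] = m
            sds[j] = np.sqrt(max(v, _SD_FLOOR * _SD_FLOOR))
        if abs(ll - prev_ll) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    return means, sds, pis, ll, it, converged, decreased


def _em_once(
    x: np.ndarray,
    w: np.ndarray,
    k: int,
    means0: np.ndarray,
    sds0: np.ndarray,
    pis0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    means, sds, pis, ll, it, converged, decreased = _em_core(
        np.ascontiguousarray(x, dtype=float),
        np.ascontiguousarray(w, dtype=float),
        means0.astype(float).copy(),
        sds0.astype(float).copy(),
        pis0.astype(float).copy(),
        tol,
        max_iter,
    )
    # EM guarantee: the log-likelihood never decreases across iterations
    assert not decreased, "EM loglik decreased"
    return means, sds, pis, float(ll), int(it), bool(converged)


def _weighted_quantile_init(
    x: np.ndarray, w: np.ndarray, k: int, rng: np.random.Generator, jitter: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) / ws.sum()
    edges = np.searchsorted(cum, np.linspace(0, 1, k + 1)[1:-1])
    groups = np.split(np.arange(len(xs)), edges)
    means, sds, pis = [], [], []
    for g in groups:
        if len(g) == 0:
            means.append(xs.mean())
            sds.append(max(xs.std(), _SD_FLOOR))
            pis.append(1.0 / k)
            continue
        gw = ws[g]
        gm = np.average(xs[g], weights=gw)
        gv = np.average((xs[g] - gm) ** 2, weights=gw)
        means.append(gm)
        sds.append(max(np.sqrt(gv), _SD_FLOOR))
        pis.append(gw.sum() / ws.sum())
    means = np.array(means) + jitter * rng.normal(size=k) * (np.std(xs) + _SD_FLOOR)
    sds = np.maximum(np.array(sds), _SD_FLOOR)
    pis = np.array(pis)
    pis /= pis.sum()
    return means, sds, pis


def _fit_fixed_k(
    x: np.ndarray,
    w: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    if k == 1:
        # closed form: weighted moments of ln Ks
        m = np.average(x, weights=w)
        v = np.average((x - m) ** 2, weights=w)
        sd = max(np.sqrt(v), _SD_FLOOR)
        ll = float(np.dot(w, norm.logpdf(x, m, sd)))
        return MixtureFit(1, np.array([1.0]), np.array([m]), np.array([sd]), ll, 0, True)
    best = None
    for r in range(n_restarts):
        init = _weighted_quantile_init(x, w, k, rng, jitter=0.0 if r == 0 else 0.5)
        means, sds, pis, ll, it, conv = _em_once(
            x, w, k, *init, tol=tol, max_iter=max_iter
        )
        if best is None or ll > best.loglik:
            order = np.argsort(means)
            best = MixtureFit(k, pis[order], means[order], sds[order], ll, it, conv)
    return best


def fit_ks_mixture(
    dist: KsDistribution,
    k_max: int = 4,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed=0,
    n_restarts: int = 10,
    boot_restarts: int = 3,
) -> MixtureFit:
    """Fit a Gaussian mixture on ln(Ks) with bootstrap-LRT model selection.

    Components are added sequentially (k vs k+1); each step is tested with a
    parametric bootstrap of the likelihood-ratio statistic under the
    k-component fit, stopping at the first test with p > ``alpha`` or at
    ``k_max``.  Observation weights from the node-weighted distribution are
    honoured in every fit; bootstrap replicates are simulated unweighted at
    the rounded effective sample size.
    """
    rng = np.random.default_rng(seed)
    x = np.log(dist.values["ks"].to_numpy(dtype=float))
    w = dist.values["weight"].to_numpy(dtype=float)
    if w.sum() < 50:
        raise ValueError(f"need >= 50 effective observations, have {w.sum():.1f}")

    trace: list[dict] = []
    fit_k = _fit_fixed_k(x, w, 1, rng, n_restarts)
    n_eff = int(round(w.sum()))
    for k in range(1, k_max):
        fit_k1 = _fit_fixed_k(x, w, k + 1, rng, n_restarts)
        # the observed statistic is computed with the same fit settings as
        # the bootstrap refits, so optimisation quality cancels in the test
        test_k = _fit_fixed_k(x, w, k, rng, boot_restarts, max_iter=200, tol=1e-6)
        test_k1 = _fit_fixed_k(x, w, k + 1, rng, boot_restarts, max_iter=200, tol=1e-6)
        stat = 2.0 * (test_k1.loglik - test_k.loglik)
        # curtailed sampling: once enough null replicates exceed the observed
        # statistic, the test cannot reach significance and sampling stops
        stop_at = int(np.ceil(alpha * (n_boot + 1)))
        exceed = 0
        done = 0
        for _ in range(n_boot):
            comp = rng.choice(fit_k.k, size=n_eff, p=fit_k.weights)
            xb = rng.normal(fit_k.means[comp], fit_k.sds[comp])
            wb = np.ones(n_eff)
            # bootstrap refits run at a looser tolerance: only the LRT
            # statistic's null spread matters, not parameter precision
            b_k = _fit_fixed_k(xb, wb, k, rng, boot_restarts, max_iter=200, tol=1e-6)
            b_k1 = _fit_fixed_k(
                xb, wb, k + 1, rng, boot_restarts, max_iter=200, tol=1e-6
            )
            done += 1
            if 2.0 * (b_k1.loglik - b_k.loglik) >= stat:
                exceed += 1
                if exceed >= stop_at:
                    break
        pval = (1 + exceed) / (done + 1)
        trace.append({"k_null": k, "k_alt": k + 1, "lrt": stat, "p": pval})
        if pval > alpha:
            break
        fit_k = fit_k1
    fit_k.selection_trace = trace
    return fit_k


# --------------------------------------------------------------------------
# ortholog divergence and placement
# --------------------------------------------------------------------------

def _bootstrap_median_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, float]:
    meds = np.median(
        values[rng.integers(0, len(values), size=(n_boot, len(values)))], axis=1
    )
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(lo), float(hi)


def ortholog_divergence_ks(
    genome_a,
    genome_b,
    ks_table: pd.DataFrame,
    n_boot: int = 1000,
    seed=0,
) -> tuple[float, tuple[float, float]]:
    """Median ortholog Ks between two genomes with a bootstrap CI.

    Cross-genome pairs are reduced to reciprocal best pairs using minimum
    Ks as the similarity proxy (each gene's lowest-Ks partner, kept only
    when mutual); the median Ks over those pairs estimates the divergence
    of the two lineages on the Ks axis.
    """
    rng = np.random.default_rng(seed)
    ids_a, ids_b = genome_a.gene_ids(), genome_b.gene_ids()

    mask_ab = ks_table["gene_a"].isin(ids_a) & ks_table["gene_b"].isin(ids_b)
    mask_ba = ks_table["gene_a"].isin(ids_b) & ks_table["gene_b"].isin(ids_a)
    cross = ks_table[mask_ab | mask_ba].copy()
    if cross.empty:
        raise ValueError("no cross-genome pairs in ks table")
    a_side = np.where(cross["gene_a"].isin(ids_a), cross["gene_a"], cross["gene_b"])
    b_side = np.where(cross["gene_a"].isin(ids_a), cross["gene_b"], cross["gene_a"])
    cross = pd.DataFrame({"a": a_side, "b": b_side, "ks": cross["ks"].to_numpy()})

    best_ab = cross.loc[cross.groupby("a")["ks"].idxmin()]
    best_ba = cross.loc[cross.groupby("b")["ks"].idxmin()]
    rbh = best_ab.merge(best_ba[["a", "b"]], on=["a", "b"], how="inner")
    vals = rbh["ks"].to_numpy(dtype=float)
    median = float(np.median(vals))
    return median, _bootstrap_median_ci(vals, rng, n_boot)


@dataclass
class PlacementCall:
    peak_median: float
    peak_ci: tuple[float, float]
    ortholog_median: float
    ortholog_ci: tuple[float, float]
    call: str  # shared-ancestral | lineage-specific | ambiguous


def classify_placement(
    peak_median: float,
    peak_ci: tuple[float, float],
    ortholog_median: float,
    ortholog_ci: tuple[float, float],
) -> PlacementCall:
    """Place a Ks peak relative to an ortholog divergence.

    ``shared-ancestral`` when the peak CI lies wholly above the ortholog CI
    (the duplication predates the speciation), ``lineage-specific`` when
    wholly below, ``ambiguous`` otherwise.
    """
    if peak_ci[0] > ortholog_ci[1]:
        call = "shared-ancestral"
    elif peak_ci[1] < ortholog_ci[0]:
        call = "lineage-specific"
    else:
        call = "ambiguous"
    return PlacementCall(peak_median, peak_ci, ortholog_median, ortholog_ci, call)


def bootstrap_peak_ci(
    dist: KsDistribution,
    k: int,
    component: int,
    n_boot: int = 100,
    seed=0,
) -> tuple[float, float]:
    """Bootstrap CI for one component's median Ks by weighted resampling and
    fixed-k refitting (components matched by sorted mean)."""
    rng = np.random.default_rng(seed)
    x = np.log(dist.values["ks"].to_numpy(dtype=float))
    w = dist.values["weight"].to_numpy(dtype=float)
    p = w / w.sum()
    meds = []
    for _ in range(n_boot):
        idx = rng.choice(len(x), size=len(x), p=p)
        fit = _fit_fixed_k(x[idx], np.ones(len(idx)), k, rng, n_restarts=2)
        meds.append(fit.medians[component])
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(lo), float(hi)
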