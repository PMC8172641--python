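"""NG86 estimator vs enumeration oracle; weighted mixture; placement calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wgdkit.io import Genome, GeneRecord
from wgdkit.ks import (
    SENSE_CODONS,
    STOP_CODONS,
    KsDistribution,
    SaturationError,
    _CODON_TABLE,
    _fit_fixed_k,
    bootstrap_peak_ci,
    classify_placement,
    fit_ks_mixture,
    ng86_ks,
    node_weighted_distribution,
    ortholog_divergence_ks,
)

from _oracles import oracle_ks, oracle_sites


class TestNG86:
    def test_identical_sequences_zero(self):
        ks, ka, s, n = ng86_ks("ATGGCT", "ATGGCT")
        assert ks == 0 and ka == 0
        assert s + n == pytest.approx(6.0)

    def test_single_synonymous_difference(self):
        ks, ka, s, n = ng86_ks("TTTGGGAAA", "TTCGGGAAA")
        assert oracle_ks("TTT", "TTC") is not None
        # whole-sequence oracle: S = S(TTT/TTC avg) + S(GGG) + S(AAA)
        S = (oracle_sites("TTT")[0] + oracle_sites("TTC")[0]) / 2
        S += oracle_sites("GGG")[0] + oracle_sites("AAA")[0]
        expected = -0.75 * np.log(1 - 4 * (1.0 / S) / 3)
        assert ks == pytest.approx(expected)
        assert ka == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_all_sense_codon_pairs(self):
        """Estimator equals the brute-force oracle wherever both are defined."""
        checked = 0
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            expected = oracle_ks(ca, cb)
            if expected is None:
                with pytest.raises(ValueError):
                    ng86_ks(ca, cb)
                continue
            if expected == "saturated":
                with pytest.raises(SaturationError):
                    ng86_ks(ca, cb)
                continue
            ks, _, _, _ = ng86_ks(ca, cb)
            assert ks == pytest.approx(expected, abs=1e-12), (ca, cb)
            checked += 1
        assert checked > 1500  # most pairs; short codon pairs often saturate

    def test_symmetry(self, rng):
        codons = [c for c in SENSE_CODONS]
        for _ in range(200):
            seq_a = "".join(rng.choice(codons, size=6))
            seq_b = "".join(rng.choice(codons, size=6))
            try:
                fwd = ng86_ks(seq_a, seq_b)
            except ValueError:
                with pytest.raises(ValueError):
                    ng86_ks(seq_b, seq_a)
                continue
            rev = ng86_ks(seq_b, seq_a)
            assert fwd == pytest.approx(rev, nan_ok=True)

    def test_gapped_codons_dropped_pairwise(self):
        full = ng86_ks("TTTGGGGGG", "TTCGGGGGG")
        gapped = ng86_ks("TTTGGGGGGA-A", "TTCGGGGGGAAA")
        assert gapped == pytest.approx(full)  # gapped AAA codon dropped

    @pytest.mark.parametrize(
        "a,b,err",
        [
            ("ATG", "ATGATG", "length"),
            ("ATGA", "ATGA", "multiple of 3"),
            ("TAAGGG", "TTTGGG", "stop"),
        ],
    )
    def test_invalid_input(self, a, b, err):
        with pytest.raises(ValueError, match=err):
            ng86_ks(a, b)


class TestNodeWeighting:
    def test_node_with_four_pairs_weight_quarter(self):
        df = pd.DataFrame({
            "gene_a": list("abcd"), "gene_b": list("efgh"),
            "ks": [0.5] * 4, "node_id": [7] * 4,
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        assert (dist.values["weight"] == 0.25).all()

    def test_untagged_pairs_weight_one(self):
        df = pd.DataFrame({
            "gene_a": list("ab"), "gene_b": list("cd"), "ks": [0.5, 1.0]
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        assert (dist.values["weight"] == 1.0).all()

    def test_mass_equals_retained_nodes(self, rng):
        n = 500
        df = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "ks": rng.uniform(0, 4, n),
            "node_id": rng.integers(0, 60, n),
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        kept_nodes = dist.values["node_id"].nunique()
        assert dist.n_effective == pytest.approx(kept_nodes)

    def test_empty_window_rejected(self):
        df = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "ks": [5.0]})
        with pytest.raises(ValueError, match="window"):
            node_weighted_distribution(df, (0.01, 3.0))


class TestMixture:
    def test_fixed_k1_equals_weighted_moments(self, rng):
        x = rng.lognormal(0.0, 0.4, size=300)
        w = rng.uniform(0.2, 1.0, size=300)
        fit = _fit_fixed_k(np.log(x), w, 1, rng)
        m = np.average(np.log(x), weights=w)
        v = np.average((np.log(x) - m) ** 2, weights=w)
        assert fit.means[0] == pytest.approx(m, abs=1e-8)
        assert fit.sds[0] == pytest.approx(np.sqrt(v), abs=1e-8)

    def test_loglik_nondecreasing_with_k(self, rng):
        x = np.log(np.concatenate([
            rng.lognormal(np.log(0.3), 0.25, 400),
            rng.lognormal(np.log(1.1), 0.2, 400),
        ]))
        w = np.ones(len(x))
        lls = [_fit_fixed_k(x, w, k, rng).loglik for k in (1, 2, 3)]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_two_component_recovery_single_seed(self, rng):
        ks = np.concatenate([
            rng.lognormal(np.log(1.08), 0.2, 2000),
            rng.lognormal(np.log(0.30), 0.25, 1500),
        ])
        df = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(len(ks))],
            "gene_b": [f"b{i}" for i in range(len(ks))],
            "ks": ks,
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        fit = fit_ks_mixture(dist, k_max=3, n_boot=100, alpha=0.05, seed=1)
        assert fit.k == 2
        assert fit.medians[0] == pytest.approx(0.30, abs=0.05)
        assert fit.medians[1] == pytest.approx(1.08, abs=0.05)
        assert np.sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
        assert (fit.sds > 0).all()

    def test_medians_order_follows_means(self, rng):
        ks = np.concatenate([
            rng.lognormal(np.log(0.3), 0.2, 500),
            rng.lognormal(np.log(1.0), 0.2, 500),
        ])
        fit = _fit_fixed_k(np.log(ks), np.ones(len(ks)), 2, rng)
        assert list(fit.medians) == sorted(fit.medians)
        assert np.allclose(fit.medians, np.exp(fit.means))

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({
            "gene_a": list("abc"), "gene_b": list("xyz"), "ks": [0.5, 0.6, 0.7]
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        with pytest.raises(ValueError, match="50"):
            fit_ks_mixture(dist, seed=1)


def _two_genomes(n, ks_values, extra_pairs=()):
    ga = Genome({"A_c1": [GeneRecord(f"a{i}", f"f{i}", i) for i in range(n)]})
    gb = Genome({"B_c1": [GeneRecord(f"b{i}", f"f{i}", i) for i in range(n)]})
    rows = [(f"a{i}", f"b{i}", ks_values[i]) for i in range(n)]
    rows += list(extra_pairs)
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "ks"])
    return ga, gb, table


class TestOrthologDivergence:
    def test_identical_genomes_zero_median(self):
        ga, gb, table = _two_genomes(20, [0.0] * 20)
        med, ci = ortholog_divergence_ks(ga, gb, table, seed=1)
        assert med == 0.0

    def test_recovers_clock_divergence(self, rng):
        n = 1000
        noise = rng.gamma(1 / 0.15**2, 0.15**2, n)
        ga, gb, table = _two_genomes(n, 0.67 * noise)
        # paralog decoys at higher ks must lose the reciprocal-best contest
        decoys = [(f"a{i}", f"b{(i + 7) % n}", 1.4) for i in range(0, n, 3)]
        table = pd.concat(
            [table, pd.DataFrame(decoys, columns=table.columns)], ignore_index=True
        )
        med, (lo, hi) = ortholog_divergence_ks(ga, gb, table, seed=1)
        assert med == pytest.approx(0.67, abs=0.03)
        assert lo <= med <= hi

    def test_within_genome_pairs_only_is_error(self):
        ga, gb, _ = _two_genomes(5, [0.5] * 5)
        within = pd.DataFrame(
            [("a0", "a1", 0.2)], columns=["gene_a", "gene_b", "ks"]
        )
        with pytest.raises(ValueError, match="cross-genome"):
            ortholog_divergence_ks(ga, gb, within)


class TestPlacement:
    def test_peak_above_ortholog_is_shared_ancestral(self):
        call = classify_placement(1.08, (1.02, 1.14), 0.67, (0.64, 0.70))
        assert call.call == "shared-ancestral"

    def test_peak_below_ortholog_is_lineage_specific(self):
        call = classify_placement(0.30, (0.27, 0.33), 0.67, (0.64, 0.70))
        assert call.call == "lineage-specific"

    def test_overlapping_cis_ambiguous(self):
        call = classify_placement(0.70, (0.60, 0.80), 0.67, (0.64, 0.70))
        assert call.call == "ambiguous"

    def test_bootstrap_peak_ci_brackets_median(self, rng):
        ks = rng.lognormal(np.log(1.08), 0.2, 1500)
        df = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(len(ks))],
            "gene_b": [f"b{i}" for i in range(len(ks))],
            "ks": ks,
        })
        dist = node_weighted_distribution(df, (0.01, 3.0))
        lo, hi = bootstrap_peak_ci(dist, k=1, component=0, n_boot=50, seed=1)
        assert lo < 1.08 < hi
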