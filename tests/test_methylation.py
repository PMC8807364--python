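"""Beta-values, replicate averaging, promoter windows, delta-beta, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylscreen import (
    BetaMatrix,
    DataError,
    assign_promoter_probes,
    average_replicates,
    beta_matrix_from_intensities,
    cluster_by_chromosome,
    compute_beta,
    delta_beta,
    summarize_delta_beta,
)
from methylscreen.methylation import PromoterAssignment, promoter_window


class TestComputeBeta:
    @pytest.mark.parametrize("M, U, expected", [
        (0, 0, 0.0),
        (100, 0, 0.5),
        (900, 0, 0.9),
        (50, 50, 0.25),
    ])
    def test_known_values(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected, abs=1e-15)

    def test_rejects_negative_intensity(self):
        with pytest.raises(DataError):
            compute_beta(-1, 10)
        with pytest.raises(DataError):
            compute_beta(10, -1)
        with pytest.raises(DataError):
            compute_beta(10, 10, offset=0)

    @settings(derandomize=True, max_examples=200)
    @given(M=st.floats(0, 1e6), U=st.floats(0, 1e6))
    def test_bounds(self, M, U):
        beta = compute_beta(M, U)
        assert 0.0 <= beta < 1.0

    def test_monotone_in_M_and_U(self):
        ms = np.linspace(0, 5000, 50)
        betas = compute_beta(ms, np.full(50, 300.0))
        assert np.all(np.diff(betas) > 0)
        us = np.linspace(0, 5000, 50)
        betas = compute_beta(np.full(50, 300.0), us)
        assert np.all(np.diff(betas) < 0)

    def test_offset_limit_is_plain_ratio(self):
        # as offset -> 0 the value approaches M / (M + U)
        assert compute_beta(300, 700, offset=1e-9) == pytest.approx(0.3, abs=1e-9)


class TestAverageReplicates:
    def test_mean_of_two_replicates(self):
        beta = pd.DataFrame({"s1": [0.2], "s2": [0.4]}, index=["p1"])
        out = average_replicates(beta, {"s1": "c", "s2": "c"})
        assert out.beta.loc["p1", "c"] == pytest.approx(0.3)
        assert out.replicate_count == {"c": 2}

    def test_single_replicate_passthrough(self):
        beta = pd.DataFrame({"s1": [0.7]}, index=["p1"])
        out = average_replicates(beta, {"s1": "c"})
        assert out.beta.loc["p1", "c"] == pytest.approx(0.7)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 0.99), k=st.integers(1, 6))
    def test_mean_of_equal_values_is_identity(self, x, k):
        beta = pd.DataFrame({f"s{i}": [x] for i in range(k)}, index=["p"])
        out = average_replicates(beta, {f"s{i}": "c" for i in range(k)})
        assert out.beta.loc["p", "c"] == pytest.approx(x)

    def test_unmapped_sample_rejected(self):
        beta = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["p"])
        with pytest.raises(DataError):
            average_replicates(beta, {"s1": "c"})

    def test_from_intensities_duplicate_pair_rejected(self):
        df = pd.DataFrame({
            "probe_id": ["p", "p"], "sample_id": ["s", "s"],
            "M": [1, 2], "U": [3, 4]})
        with pytest.raises(DataError):
            beta_matrix_from_intensities(df, {"s": "c"})


class TestPromoterAssignment:
    def _assign(self, probes, genes, upstream=500):
        manifest = pd.DataFrame(
            [(f"p{i}", c, p) for i, (c, p) in enumerate(probes)],
            columns=["probe_id", "chrom", "pos"])
        annotation = pd.DataFrame(
            [(f"g{i}", c, s, t, 1000) for i, (c, s, t) in enumerate(genes)],
            columns=["gene_id", "chrom", "strand", "tss", "exonic_length"])
        return assign_promoter_probes(manifest, annotation, upstream)

    @pytest.mark.parametrize("pos, expected", [
        (600, {"g0"}),   # inside [500, 1000)
        (500, {"g0"}),   # inclusive lower bound: TSS - 500
        (1000, set()),   # half-open: the TSS base itself is excluded
        (499, set()),
    ])
    def test_plus_strand_window(self, pos, expected):
        a = self._assign([("chr1", pos)], [("chr1", "+", 1000)])
        assert a.genes_for("p0") == expected

    @pytest.mark.parametrize("pos, expected", [
        (1200, {"g0"}),  # inside [1001, 1501)
        (1001, {"g0"}),
        (1000, set()),   # TSS base excluded
        (1500, {"g0"}),
        (1501, set()),
    ])
    def test_minus_strand_window(self, pos, expected):
        a = self._assign([("chr1", pos)], [("chr1", "-", 1000)])
        assert a.genes_for("p0") == expected

    def test_unknown_chromosome_left_unassigned(self):
        a = self._assign([("chrX", 600)], [("chr1", "+", 1000)])
        assert a.genes_for("p0") == set()

    def test_probe_can_map_to_two_genes(self):
        a = self._assign([("chr1", 900)],
                         [("chr1", "+", 1000), ("chr1", "+", 1200)])
        assert a.genes_for("p0") == {"g0", "g1"}

    def test_matches_interval_oracle_on_random_cases(self, rng):
        """Strand-aware membership equals an independent containment check."""
        n = 1000
        tss = rng.integers(1000, 50_000, n)
        strand = rng.choice(["+", "-"], n)
        probe_pos = tss + rng.integers(-700, 700, n)
        for i in range(n):
            a = self._assign([("chr1", int(probe_pos[i]))],
                             [("chr1", strand[i], int(tss[i]))])
            # oracle: enumerate the window's positions literally
            if strand[i] == "+":
                window = range(tss[i] - 500, tss[i])
            else:
                window = range(tss[i] + 1, tss[i] + 501)
            expected = {"g0"} if int(probe_pos[i]) in window else set()
            assert a.genes_for("p0") == expected


class TestDeltaBeta:
    def _matrix(self, beta):
        return BetaMatrix(beta=beta)

    def test_gene_summary_is_probe_mean(self, toy_beta_inputs):
        beta, mapping = toy_beta_inputs
        table = delta_beta(self._matrix(beta), PromoterAssignment(mapping),
                           "parental", "derivative_1")
        assert table.genes.loc["gA", "mean_delta_beta"] == pytest.approx(0.4)
        assert table.genes.loc["gB", "mean_delta_beta"] == pytest.approx(-0.05)
        assert table.genes.loc["gB", "max_abs_delta_beta"] == pytest.approx(0.1)
        assert int(table.genes.loc["gA", "n_probes"]) == 2

    def test_same_condition_gives_zero(self, toy_beta_inputs):
        beta, mapping = toy_beta_inputs
        table = delta_beta(self._matrix(beta), PromoterAssignment(mapping),
                           "parental", "parental")
        assert (table.genes["mean_delta_beta"] == 0).all()

    def test_antisymmetry(self, toy_beta_inputs):
        beta, mapping = toy_beta_inputs
        m = self._matrix(beta)
        fwd = delta_beta(m, PromoterAssignment(mapping), "parental", "derivative_1")
        rev = delta_beta(m, PromoterAssignment(mapping), "derivative_1", "parental")
        pd.testing.assert_series_equal(fwd.genes["mean_delta_beta"],
                                       -rev.genes["mean_delta_beta"])

    def test_unknown_condition_rejected(self, toy_beta_inputs):
        beta, mapping = toy_beta_inputs
        with pytest.raises(DataError):
            delta_beta(self._matrix(beta), PromoterAssignment(mapping),
                       "parental", "nope")

    def test_matches_bruteforce_on_random_instance(self, rng):
        """Gene summaries equal probe-by-probe recomputation on 50 probes."""
        probes = [f"p{i}" for i in range(50)]
        beta = pd.DataFrame({
            "a": rng.uniform(0, 0.99, 50),
            "b": rng.uniform(0, 0.99, 50),
        }, index=pd.Index(probes, name="probe_id"))
        mapping = {p: {f"g{rng.integers(8)}"} for p in probes}
        table = delta_beta(self._matrix(beta), PromoterAssignment(mapping),
                           "a", "b")
        for gene in table.genes.index:
            vals = [beta.loc[p, "b"] - beta.loc[p, "a"]
                    for p, gs in mapping.items() if gene in gs]
            assert table.genes.loc[gene, "mean_delta_beta"] == \
                pytest.approx(float(np.mean(vals)), abs=1e-12)
            assert table.genes.loc[gene, "max_abs_delta_beta"] == \
                pytest.approx(float(np.max(np.abs(vals))), abs=1e-12)

    def test_summarize_modes(self, toy_beta_inputs):
        beta, mapping = toy_beta_inputs
        m = self._matrix(beta)
        t = delta_beta(m, PromoterAssignment(mapping), "parental", "derivative_1")
        mean_summary = summarize_delta_beta([t, t], mode="mean")
        assert mean_summary.loc["gA", "delta_beta"] == pytest.approx(0.4)
        # "any" keeps the extreme derivative per gene
        shifted = t.genes.copy()
        t2 = delta_beta(m, PromoterAssignment(mapping), "derivative_1", "parental")
        any_summary = summarize_delta_beta([t, t2], mode="any")
        assert abs(any_summary.loc["gA", "delta_beta"]) == pytest.approx(0.4)
        del shifted


def _bruteforce_average_linkage(dist: np.ndarray) -> list[frozenset]:
    """Independent average-linkage oracle: greedy merge by mean pairwise
    distance between clusters, ties by smallest member index."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                key = (d, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


class TestClusterByChromosome:
    def _beta(self, rows, conds=("a", "b")):
        return BetaMatrix(beta=pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=pd.Index([f"p{i}" for i in range(len(rows))], name="probe_id"),
            columns=list(conds)))

    def _manifest(self, n, chrom="chr1"):
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom, "pos": np.arange(n) * 10})

    def test_identical_profiles_adjacent(self):
        beta = self._beta([[0.1, 0.2], [0.9, 0.8], [0.1, 0.2]])
        order = cluster_by_chromosome(beta, self._manifest(3))["chr1"]
        pos = {p: i for i, p in enumerate(order)}
        assert abs(pos["p0"] - pos["p2"]) == 1  # the duplicates merge first

    def test_three_probe_order_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            rows = rng.uniform(0, 1, size=(3, 2))
            beta = self._beta(rows)
            order = cluster_by_chromosome(beta, self._manifest(3))["chr1"]
            dist = np.sqrt(((rows[:, None, :] - rows[None, :, :]) ** 2).sum(-1))
            first_merge = _bruteforce_average_linkage(dist)[0]
            pos = {p: i for i, p in enumerate(order)}
            a, b = sorted(first_merge)
            assert abs(pos[f"p{a}"] - pos[f"p{b}"]) == 1

    def test_singleton_chromosome(self):
        beta = self._beta([[0.5, 0.5]])
        order = cluster_by_chromosome(beta, self._manifest(1))
        assert order["chr1"] == ["p0"]

    def test_row_permutation_preserves_merge_partner(self, rng):
        rows = rng.uniform(0, 1, size=(5, 3))
        beta = self._beta(rows, conds=("a", "b", "c"))
        base = cluster_by_chromosome(beta, self._manifest(5))["chr1"]
        perm = rng.permutation(5)
        beta2 = BetaMatrix(beta=beta.beta.iloc[perm])
        man2 = self._manifest(5)
        man2["probe_id"] = [f"p{i}" for i in perm]
        order2 = cluster_by_chromosome(beta2, man2)["chr1"]
        # the closest pair stays adjacent regardless of input order
        dist = np.sqrt(((rows[:, None, :] - rows[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        a, b = np.unravel_index(np.argmin(dist), dist.shape)
        for order in (base, order2):
            pos = {p: i for i, p in enumerate(order)}
            assert abs(pos[f"p{a}"] - pos[f"p{b}"]) == 1
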