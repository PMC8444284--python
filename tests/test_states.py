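"""Consensus clustering, k selection, singscore assignment and signatures."""

import numpy as np
import pandas as pd
import pytest

from stag import (
    ExpressionMatrix,
    StateSignature,
    bootstrap_network_robustness,
    choose_k,
    consensus_cluster,
    fisher_overlap_enrichment,
    signature_from_states,
    singscore_assign,
)
from stag.states import ConsensusResult


def blob_matrix(rng, n_per=30, n_blobs=2, n_genes=40, shift=3.0):
    n = n_per * n_blobs
    X = rng.normal(0, 0.3, (n_genes, n))
    for b in range(n_blobs):
        X[5 * b: 5 * (b + 1), n_per * b: n_per * (b + 1)] += shift
    return ExpressionMatrix(
        X,
        tuple(f"g{i}" for i in range(n_genes)),
        tuple(f"c{i}" for i in range(n)),
    )


class TestConsensus:
    def test_two_blobs_recover_block_pattern(self, rng):
        expr = blob_matrix(rng)
        cons = consensus_cluster(expr, (2,), reps=30, seed=1)
        C = cons.consensus[2]
        block = np.zeros((60, 60))
        block[:30, :30] = 1.0
        block[30:, 30:] = 1.0
        iu = np.triu_indices(60, 1)
        defined = ~np.isnan(C[iu])
        assert np.abs((C - block)[iu][defined]).max() <= 0.05

    def test_single_rep_gives_binary_or_undefined(self, rng):
        expr = blob_matrix(rng, n_per=10)
        cons = consensus_cluster(expr, (2,), reps=1, seed=2)
        C = cons.consensus[2]
        vals = C[~np.isnan(C)]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert cons.n_undefined[2] > 0  # some pairs never co-sampled in one rep

    def test_same_seed_reproduces(self, rng):
        expr = blob_matrix(rng, n_per=12)
        a = consensus_cluster(expr, (2, 3), reps=5, seed=7)
        b = consensus_cluster(expr, (2, 3), reps=5, seed=7)
        for k in (2, 3):
            np.testing.assert_array_equal(a.consensus[k], b.consensus[k])

    def test_consensus_symmetric_in_range(self, rng):
        expr = blob_matrix(rng, n_per=12)
        C = consensus_cluster(expr, (3,), reps=10, seed=3).consensus[3]
        m = ~np.isnan(C)
        assert np.array_equal(m, m.T)
        assert np.allclose(C[m], C.T[m])
        assert C[m].min() >= 0.0 and C[m].max() <= 1.0

    def test_invalid_k_rejected(self, rng):
        expr = blob_matrix(rng, n_per=5)
        with pytest.raises(ValueError):
            consensus_cluster(expr, (1,), reps=2, seed=0)


class TestChooseK:
    def test_planted_three_clusters(self, rng):
        expr = blob_matrix(rng, n_per=30, n_blobs=3)
        cons = consensus_cluster(expr, (2, 3, 4, 5), reps=30, seed=4)
        best, table = choose_k(cons)
        assert best == 3
        assert set(table.columns) >= {"k", "delta_k", "elbow", "score"}

    def test_flat_consensus_reports_tie(self):
        """Degenerate input: identical consensus at every k -> explicit tie."""
        ks = (2, 3, 4)
        C = np.full((6, 6), 0.5)
        cons = ConsensusResult(
            ks, {k: C for k in ks}, {k: 0.5 for k in ks},
            {k: 0.0 for k in ks}, {k: 0 for k in ks},
        )
        with pytest.warns(UserWarning, match="tie"):
            best, table = choose_k(cons)
        assert table["tied_top"].sum() > 1
        assert best == 2  # smallest of the tied candidates

    def test_robustness_scores_enter_ranking(self, rng):
        expr = blob_matrix(rng, n_per=20, n_blobs=2)
        cons = consensus_cluster(expr, (2, 3, 4), reps=15, seed=5)
        best, table = choose_k(cons, robustness={2: 1.0, 3: 0.2, 4: 0.2})
        assert "robustness" in table.columns
        assert best == 2


class TestNetworkRobustness:
    def _cells(self, rng, n=400):
        times = np.repeat([7.0, 14.0, 21.0], n // 3 + 1)[:n]
        return pd.DataFrame({
            "cell_id": [f"cell{i}" for i in range(n)],
            "barcode": rng.choice([f"bc{j}" for j in range(40)], n),
            "time_days": times,
        })

    def test_minimal_run_returns_finite_scores(self, rng):
        cells = self._cells(rng)
        labels = {
            k: pd.Series(
                rng.choice([f"S{i+1}" for i in range(k)], len(cells)),
                index=cells["cell_id"],
            )
            for k in (2, 3)
        }
        etas = {7.0: 0.8, 14.0: 0.8, 21.0: 0.8}
        scores = bootstrap_network_robustness(cells, labels, etas, reps=2, seed=0)
        assert set(scores) == {2, 3}
        for v in scores.values():
            assert np.isfinite(v) and 0.0 <= v <= 1.0


class TestSingscore:
    def _ladder(self, n=40):
        vals = np.arange(n, dtype=float).reshape(n, 1)
        return ExpressionMatrix(
            vals, tuple(f"g{i}" for i in range(n)), ("c0",)
        )

    def test_extremes(self):
        expr = self._ladder()
        top = StateSignature("top", tuple(f"g{i}" for i in range(35, 40)))
        bot = StateSignature("bot", tuple(f"g{i}" for i in range(5)))
        out = singscore_assign(expr, [top, bot])
        assert out["top"].iloc[0] == 1.0
        assert out["bot"].iloc[0] == 0.0
        assert out["state"].iloc[0] == "top"

    def test_random_signature_scores_half(self, rng):
        n_genes, n_cells = 60, 1000
        expr = ExpressionMatrix(
            rng.normal(0, 1, (n_genes, n_cells)),
            tuple(f"g{i}" for i in range(n_genes)),
            tuple(f"c{i}" for i in range(n_cells)),
        )
        sig = StateSignature("s", tuple(f"g{i}" for i in rng.choice(n_genes, 10, replace=False)))
        out = singscore_assign(expr, [sig])
        assert abs(out["s"].mean() - 0.5) < 0.02

    def test_monotone_transform_invariance(self, rng):
        """Rank-based scores ignore any strictly increasing transform."""
        n = 30
        X = rng.normal(0, 1, (n, 5))
        genes = tuple(f"g{i}" for i in range(n))
        cells = tuple(f"c{i}" for i in range(5))
        sig = StateSignature("s", genes[:7])
        a = singscore_assign(ExpressionMatrix(X, genes, cells), [sig])
        b = singscore_assign(ExpressionMatrix(np.exp(3 * X), genes, cells), [sig])
        assert np.allclose(a["s"], b["s"])

    def test_signature_covering_all_genes_rejected(self):
        expr = self._ladder(5)
        sig = StateSignature("s", tuple(f"g{i}" for i in range(5)))
        with pytest.raises(ValueError):
            singscore_assign(expr, [sig])


class TestSignatures:
    def test_planted_markers_recovered(self, rng):
        expr = blob_matrix(rng)
        labels = {f"c{i}": "A" if i < 30 else "B" for i in range(60)}
        sigs = {s.state: set(s.genes) for s in signature_from_states(expr, labels)}
        assert {"g0", "g1", "g2", "g3", "g4"} <= sigs["A"]
        assert {"g5", "g6", "g7", "g8", "g9"} <= sigs["B"]

    def test_permuted_labels_yield_empty_signatures(self, rng):
        expr = blob_matrix(rng)
        perm = rng.permutation(60)
        labels = {f"c{i}": ("A" if perm[i] < 30 else "B") for i in range(60)}
        sigs = signature_from_states(expr, labels)
        assert sum(len(s.genes) for s in sigs) <= 2  # near-zero false positives

    def test_identical_expression_gives_nothing(self):
        X = np.ones((20, 10))
        expr = ExpressionMatrix(
            X, tuple(f"g{i}" for i in range(20)), tuple(f"c{i}" for i in range(10))
        )
        labels = {f"c{i}": "A" if i < 5 else "B" for i in range(10)}
        assert signature_from_states(expr, labels) == []

    def test_tiny_state_excluded_with_warning(self, rng):
        expr = blob_matrix(rng, n_per=10)
        labels = {f"c{i}": "A" if i < 10 else ("B" if i < 19 else "C")
                  for i in range(20)}
        with pytest.warns(UserWarning, match="excluded"):
            signature_from_states(expr, labels)


class TestFisherOverlap:
    UNIVERSE = {f"g{i}" for i in range(500)}

    def test_identical_sets_large_positive(self):
        s = {f"g{i}" for i in range(10)}
        assert fisher_overlap_enrichment(s, s, self.UNIVERSE) > 5.0

    def test_disjoint_sets_negative(self):
        a = {f"g{i}" for i in range(40)}
        b = {f"g{i}" for i in range(40, 80)}
        universe = {f"g{i}" for i in range(90)}
        assert fisher_overlap_enrichment(a, b, universe) < 0.0

    def test_independent_sets_small_magnitude(self, rng):
        scores = []
        genes = sorted(self.UNIVERSE)
        for _ in range(50):
            a = set(rng.choice(genes, 30, replace=False))
            b = set(rng.choice(genes, 30, replace=False))
            scores.append(abs(fisher_overlap_enrichment(a, b, self.UNIVERSE)))
        assert np.median(scores) < 3.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap_enrichment(set(), set(), set())
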