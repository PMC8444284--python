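"""Defining and assigning transcriptional states from expression data.

States are discovered by consensus k-means clustering of a processed
(log-normalized, row-centered) genes x cells matrix: repeatedly subsample
cells, cluster, and record how often each pair of cells co-clusters when
co-sampled. The consensus CDF area and its relative change across k
support the choice of the number of states, optionally combined with how
reproducible the downstream growth-rate estimates are under cell
subsampling.

New cells are assigned to existing states by rank-based single-sample
signature scoring (the singscore statistic): within each cell, genes are
ranked by expression and a signature's score is its mean gene rank,
min-max normalized to [0, 1]; the cell takes the argmax state. Signatures
themselves come from one-vs-rest rank-sum differential expression with
Benjamini-Hochberg correction. A signed Fisher-overlap score compares
gene-set collections: positive for over-represented overlap (-log P),
negative for under-represented (+log P).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "StateSignature",
    "ConsensusResult",
    "consensus_cluster",
    "choose_k",
    "bootstrap_network_robustness",
    "singscore_assign",
    "signature_from_states",
    "fisher_overlap_enrichment",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells real matrix (assumed log-normalized, row-centered)."""

    values: np.ndarray
    genes: tuple[str, ...]
    cells: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        genes = tuple(self.genes)
        cells = tuple(self.cells)
        if values.shape != (len(genes), len(cells)):
            raise ValueError("values shape must be (n_genes, n_cells)")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if len(set(genes)) != len(genes) or len(set(cells)) != len(cells):
            raise ValueError("gene and cell ids must be unique")
        self.values, self.genes, self.cells = values, genes, cells

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class StateSignature:
    """Up-regulated marker gene set for one state."""

    state: str
    genes: tuple[str, ...]
    effect_sizes: dict[str, float] | None = None

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"signature for state {self.state!r} is empty")
        self.genes = genes


@dataclass
class ConsensusResult:
    """Per-k consensus matrices with CDF-area summaries."""

    k_values: tuple[int, ...]
    consensus: dict[int, np.ndarray]     # cells x cells, NaN = never co-sampled
    cdf_area: dict[int, float]
    delta_k: dict[int, float]            # relative change in CDF area
    n_undefined: dict[int, int]
    seed: int | None = None


def _cdf_area(C: np.ndarray) -> tuple[float, int]:
    """Area under the empirical CDF of defined off-diagonal consensus values."""
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = C[iu]
    undef = int(np.isnan(vals).sum())
    vals = np.sort(vals[~np.isnan(vals)])
    if vals.size == 0:
        return 0.0, undef
    # CDF step integral over [0, 1]
    grid = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, vals.size + 1) / vals.size
    widths = np.diff(np.concatenate([[0.0], grid]))
    heights = np.concatenate([[0.0], cdf])
    area = float(np.sum(heights * widths[: heights.size]))
    return area, undef


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range: tuple[int, ...] = tuple(range(2, 9)),
    reps: int = 100,
    frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus k-means over repeated cell subsamples.

    For each candidate k: ``reps`` times, sample ``frac`` of the cells,
    run k-means (10 seeded restarts), and accumulate co-clustering counts;
    consensus(i, j) = co-clustered / co-sampled. Pairs never co-sampled
    are NaN and excluded from the CDF-area summary.
    """
    n = expr.n_cells
    k_range = tuple(int(k) for k in k_range)
    if any(k < 2 or k >= n for k in k_range):
        raise ValueError("each k must satisfy 2 <= k < n_cells")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    X = expr.values.T  # cells x genes for sklearn
    m = max(2, int(round(frac * n)))
    consensus, areas, deltas, undefined = {}, {}, {}, {}
    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=10,
                        random_state=int(rng.integers(2**31 - 1)))
            labels = km.fit_predict(X[idx])
            sub = np.zeros((m, m))
            for c in range(k):
                members = labels == c
                sub += np.outer(members, members)
            together[np.ix_(idx, idx)] += sub
            cosampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = together / cosampled
        np.fill_diagonal(C, np.where(np.diag(cosampled) > 0, 1.0, np.nan))
        consensus[k] = C
        areas[k], undefined[k] = _cdf_area(C)
    ks = sorted(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    return ConsensusResult(tuple(ks), consensus, areas, deltas, undefined, seed)


def choose_k(
    consensus: ConsensusResult,
    robustness: dict[int, float] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Rank candidate k by the consensus elbow (and optional robustness).

    The elbow score of k is the drop in the relative CDF-area change after
    k (``delta_k[k] - delta_k[k+1]``, last k scored by its own delta): a
    large drop means adding one more cluster stops improving consensus.
    When growth-rate consistency scores are supplied they are min-max
    normalized and averaged with the normalized elbow score. Returns the
    top-ranked k and the full ranking; exact ties are flagged in the
    table rather than broken silently.
    """
    ks = list(consensus.k_values)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate k")
    elbow = {}
    for i, k in enumerate(ks):
        nxt = consensus.delta_k[ks[i + 1]] if i + 1 < len(ks) else 0.0
        elbow[k] = consensus.delta_k[k] - nxt
    def _norm(d: dict[int, float]) -> dict[int, float]:
        v = np.array([d[k] for k in ks], dtype=float)
        rng_ = v.max() - v.min()
        if rng_ == 0:
            return {k: 0.5 for k in ks}
        return {k: float((d[k] - v.min()) / rng_) for k in ks}

    score = _norm(elbow)
    if robustness is not None:
        rob = _norm({k: robustness.get(k, np.nan) for k in ks})
        score = {k: 0.5 * (score[k] + rob[k]) for k in ks}
    table = pd.DataFrame({
        "k": ks,
        "cdf_area": [consensus.cdf_area[k] for k in ks],
        "delta_k": [consensus.delta_k[k] for k in ks],
        "elbow": [elbow[k] for k in ks],
        "score": [score[k] for k in ks],
    })
    if robustness is not None:
        table["robustness"] = [robustness.get(k, np.nan) for k in ks]
    table = table.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    top = table["score"].iloc[0]
    table["tied_top"] = np.isclose(table["score"], top)
    if table["tied_top"].sum() > 1:
        warnings.warn("multiple k tie for the top score; reporting the smallest")
        tied = table[table["tied_top"]]["k"].min()
        return int(tied), table
    return int(table["k"].iloc[0]), table


def bootstrap_network_robustness(
    cells: pd.DataFrame,
    labels_per_k: dict[int, pd.Series],
    etas: dict[float, float],
    reps: int = 100,
    frac: float = 0.8,
    seed: int | None = None,
    lam: float = np.inf,
) -> dict[int, float]:
    """Growth-rate consistency of the fitted network under cell subsampling.

    ``cells`` is a per-cell table with columns cell_id, barcode, time_days;
    ``labels_per_k[k]`` maps cell_id -> state label for the k-state
    partition. Per k and rep: subsample ``frac`` of the cells, aggregate
    to counts, fit, and record the net growth rates; consistency is
    ``1 - mean_i(std_i / |mean_i|)`` across reps, clipped to [0, 1].
    Degenerate subsamples (fit failure) are skipped and counted.
    """
    from .io import aggregate_cells

    rng = np.random.default_rng(seed)
    n = len(cells)
    m = max(2, int(round(frac * n)))
    out: dict[int, float] = {}
    for k, labels in labels_per_k.items():
        growth = []
        skipped = 0
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            sub = cells.iloc[idx].copy()
            sub["state"] = labels.reindex(sub["cell_id"]).to_numpy()
            try:
                data = aggregate_cells(sub, etas)
                from .inference import fit_stag

                growth.append(fit_stag(data, lam=lam).net_growth)
            except (ValueError, RuntimeError):
                skipped += 1
        if len(growth) < 2:
            out[k] = np.nan
            continue
        G = np.asarray(growth)
        mean = G.mean(axis=0)
        std = G.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean) > 0, std / np.abs(mean), np.inf)
        out[k] = float(np.clip(1.0 - np.mean(cv), 0.0, 1.0))
        if skipped:
            warnings.warn(f"k={k}: {skipped}/{reps} subsamples skipped")
    return out


def singscore_assign(
    expr: ExpressionMatrix,
    signatures: list[StateSignature],
) -> pd.DataFrame:
    """Assign each cell to the state whose signature scores highest.

    Per cell, all n genes are ranked ascending by expression (ties get
    average ranks). A signature of m genes scores its mean gene rank,
    normalized as ``(raw - (m+1)/2) / (n - m)`` so that 0 means the
    signature occupies the bottom m ranks and 1 the top m. Ties in the
    argmax are broken by signature order and flagged.
    """
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    n = expr.n_genes
    sig_rows = []
    for sig in signatures:
        present = [gene_index[g] for g in sig.genes if g in gene_index]
        missing = len(sig.genes) - len(present)
        if missing:
            warnings.warn(
                f"signature {sig.state!r}: {missing} gene(s) absent from the matrix"
            )
        m = len(present)
        if m == 0:
            raise ValueError(f"signature {sig.state!r} has no genes in the matrix")
        if m >= n:
            raise ValueError(
                f"signature {sig.state!r} covers every gene; score undefined"
            )
        sig_rows.append((sig.state, np.asarray(present), m))

    ranks = stats.rankdata(expr.values, axis=0)  # ascending, average ties
    scores = np.zeros((expr.n_cells, len(sig_rows)))
    for s, (_, idx, m) in enumerate(sig_rows):
        raw = ranks[idx].mean(axis=0)
        scores[:, s] = (raw - (m + 1) / 2.0) / (n - m)
    best = scores.argmax(axis=1)
    top = scores[np.arange(expr.n_cells), best]
    tie = (np.isclose(scores, top[:, None]).sum(axis=1)) > 1
    out = pd.DataFrame(scores, columns=[s for s, _, _ in sig_rows])
    out.insert(0, "cell_id", expr.cells)
    out["state"] = [sig_rows[b][0] for b in best]
    out["tie"] = tie
    return out


def signature_from_states(
    expr: ExpressionMatrix,
    labels: pd.Series | dict[str, str],
    lfc_min: float = 0.25,
    alpha: float = 0.01,
) -> list[StateSignature]:
    """Up-regulated marker signatures by one-vs-rest rank-sum tests.

    Per state and gene: Wilcoxon rank-sum of in-state vs rest,
    Benjamini-Hochberg adjustment across genes, keep genes with adjusted
    p < ``alpha`` and log fold change > ``lfc_min`` (values are treated as
    log-scale, so the fold change is a mean difference). States with
    fewer than 2 cells are excluded with a warning; states with no
    significant genes yield no signature.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    lab = labels.reindex(expr.cells)
    if lab.isna().any():
        raise ValueError("every cell needs a state label")
    states = [s for s in pd.unique(lab)]
    usable = [s for s in states if (lab == s).sum() >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 states with >= 2 cells each")
    for s in states:
        if s not in usable:
            warnings.warn(f"state {s!r} has < 2 cells; excluded")
    signatures = []
    V = expr.values
    for s in usable:
        ingrp = (lab == s).to_numpy()
        a, b = V[:, ingrp], V[:, ~ingrp]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.ranksums(a, b, axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        adj = multipletests(p, method="fdr_bh")[1]
        keep = (adj < alpha) & (lfc > lfc_min)
        genes = tuple(np.asarray(expr.genes)[keep])
        if genes:
            signatures.append(
                StateSignature(str(s), genes, dict(zip(genes, lfc[keep])))
            )
    return signatures


def fisher_overlap_enrichment(
    setA: set[str] | tuple,
    setB: set[str] | tuple,
    universe: set[str] | tuple,
) -> float:
    """Signed Fisher exact overlap score between two gene sets.

    Two-sided Fisher test of the 2x2 overlap table within ``universe``.
    The score is ``-log(P)`` (positive) when the observed overlap exceeds
    its independence expectation, ``+log(P)`` (negative) otherwise.
    Natural log.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    A = set(setA) & universe
    B = set(setB) & universe
    if set(setA) - universe or set(setB) - universe:
        raise ValueError("gene sets must be subsets of the universe")
    n = len(universe)
    a = len(A & B)
    table = [
        [a, len(A) - a],
        [len(B) - a, n - len(A) - len(B) + a],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    expected = len(A) * len(B) / n
    logp = float(np.log(max(p, np.finfo(float).tiny)))
    return -logp if a > expected else logp
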