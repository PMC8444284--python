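"""File formats, count aggregation, clone summaries and seed derivation.

The native interchange format is a long-format TSV of harvested counts
(columns ``time_days, barcode, state, count, condition``), diffable and
round-trip exact. Matrices travel as square CSV with state labels on both
axes (column = source state, row = destination state); networks as
3-column TSV or GraphML; signatures as GMT; expression as a 10x-style MTX
triplet or dense genes x cells TSV. Exact column names are documented in
FORMATS.md at the repository root.

A single top-level seed fans out to per-module streams by stable hashing
of the module name (:func:`derive_seed`), so adding a consumer never
perturbs another's stream.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ObservedDataset
from .model import StateSpace, TransitionGrowthMatrix, TransitionNetwork

__all__ = [
    "CellTable",
    "CloneSummary",
    "derive_seed",
    "write_counts",
    "read_counts",
    "read_cell_table",
    "aggregate_cells",
    "clone_summary",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_network",
    "write_network_graphml",
    "read_gmt",
    "write_gmt",
    "read_expression_mtx",
    "read_expression_tsv",
]

COUNT_COLUMNS = ["time_days", "barcode", "state", "count", "condition"]
CELL_COLUMNS = ["cell_id", "barcode", "state", "time_days", "condition"]

SMALL_CLONE_MAX = 6
LARGE_CLONE_MIN = 17


def derive_seed(base_seed: int, name: str) -> int:
    """Stable per-module seed below 2**31 from a single top-level seed."""
    return int(np.random.SeedSequence(
        [int(base_seed), zlib.crc32(name.encode())]
    ).generate_state(1)[0] % (2**31))


@dataclass
class CellTable:
    """Per-cell rows (cell_id, barcode, state, time_days, condition)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS[:4] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cell table missing required columns: {missing}")
        if "condition" not in self.frame.columns:
            self.frame = self.frame.assign(condition="untreated")
        if self.frame["cell_id"].duplicated().any():
            raise ValueError("cell_id values must be unique")


@dataclass
class CloneSummary:
    """Clone sizes, distinct-barcode tallies and size classes."""

    sizes: pd.DataFrame            # columns: time_days, barcode, cells
    distinct_per_time: pd.Series   # time_days -> number of observed barcodes
    membership: dict[float, set]   # time_days -> set of observed barcodes
    size_class: pd.Series          # barcode -> small/intermediate/large
    class_time: float              # analysis time point used for classing

    def shared_barcodes(self, times: tuple[float, ...]) -> int:
        """Barcodes observed at *every* one of the given time points."""
        sets = [self.membership[t] for t in times]
        return len(set.intersection(*sets)) if sets else 0


def write_counts(frame_or_series, path: str | Path) -> None:
    """Write a long-format count table (TSV). Accepts a SampledSeries too."""
    frame = frame_or_series
    if hasattr(frame, "to_frame") and not isinstance(frame, pd.DataFrame):
        frame = frame.to_frame()
    frame = frame[COUNT_COLUMNS]
    frame.to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    etas: dict[float, float],
    states: StateSpace | None = None,
    condition: str | None = None,
) -> ObservedDataset:
    """Read a long-format count TSV into an ObservedDataset.

    ``etas`` maps each observed sampling day to its harvest fraction; a
    missing entry is a hard error, as is a count that cannot be parsed or
    a state label outside the declared state space.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise ValueError(f"count table missing required columns: {missing}")
    if "condition" not in frame.columns:
        frame["condition"] = "untreated"
    if condition is not None:
        frame = frame[frame["condition"] == condition]
        if frame.empty:
            raise ValueError(f"no rows for condition {condition!r}")
    frame["count"] = pd.to_numeric(frame["count"], errors="raise")
    frame["time_days"] = pd.to_numeric(frame["time_days"], errors="raise")
    return _pivot_counts(frame, etas, states)


def _pivot_counts(
    frame: pd.DataFrame,
    etas: dict[float, float],
    states: StateSpace | None,
) -> ObservedDataset:
    times = sorted(frame["time_days"].unique())
    for t in times:
        if t not in etas:
            raise ValueError(f"missing harvest fraction eta for time {t}")
    seen_states = list(pd.unique(frame["state"].astype(str)))
    if states is None:
        states = StateSpace(len(seen_states), tuple(sorted(seen_states)))
    else:
        unknown = sorted(set(seen_states) - set(states.labels))
        if unknown:
            raise ValueError(f"unknown state label(s): {unknown}")
    barcodes = tuple(sorted(frame["barcode"].astype(str).unique()))
    b_index = {b: i for i, b in enumerate(barcodes)}
    s_index = {s: i for i, s in enumerate(states.labels)}
    X = np.zeros((len(times), states.k, len(barcodes)))
    t_index = {t: i for i, t in enumerate(times)}
    for row in frame.itertuples(index=False):
        X[t_index[row.time_days], s_index[str(row.state)], b_index[str(row.barcode)]] += row.count
    condition = str(frame["condition"].iloc[0]) if len(frame) else "untreated"
    return ObservedDataset(
        tuple(times), tuple(etas[t] for t in times), X,
        states=states, barcodes=barcodes, condition=condition,
    )


def read_cell_table(path: str | Path) -> CellTable:
    """Read a per-cell TSV (cell_id, barcode, state, time_days[, condition])."""
    frame = pd.read_csv(path, sep="\t")
    frame["time_days"] = pd.to_numeric(frame["time_days"], errors="raise")
    return CellTable(frame)


def aggregate_cells(
    cells: CellTable | pd.DataFrame,
    etas: dict[float, float],
    states: StateSpace | None = None,
) -> ObservedDataset:
    """Aggregate per-cell rows to barcode x state counts per time point."""
    frame = cells.frame if isinstance(cells, CellTable) else cells
    counts = (
        frame.groupby(["time_days", "barcode", "state"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["condition"] = (
        frame["condition"].iloc[0] if "condition" in frame.columns else "untreated"
    )
    return _pivot_counts(counts, etas, states)


def clone_summary(
    data: ObservedDataset | "SampledSeries",
    small_max: int = SMALL_CLONE_MAX,
    large_min: int = LARGE_CLONE_MIN,
    class_time: float | None = None,
) -> CloneSummary:
    """Clone sizes per (time, barcode) with small/intermediate/large classes.

    A clone is *small* when its barcode covers <= ``small_max`` cells and
    *large* when it covers >= ``large_min`` cells at the analysis time
    point (default: the last sampling time); anything between is
    intermediate.
    """
    if not isinstance(data, ObservedDataset):
        data = ObservedDataset.from_sampled_series(data)
    rows = []
    membership: dict[float, set] = {}
    for s, t in enumerate(data.times):
        sizes = data.X[s].sum(axis=0)
        obs = np.nonzero(sizes > 0)[0]
        membership[t] = {data.barcodes[b] for b in obs}
        for b in obs:
            rows.append((t, data.barcodes[b], int(sizes[b])))
    sizes_df = pd.DataFrame(rows, columns=["time_days", "barcode", "cells"])
    distinct = sizes_df.groupby("time_days")["barcode"].nunique()
    distinct = distinct.reindex(list(data.times), fill_value=0)
    if class_time is None:
        class_time = data.times[-1]
    at_t = sizes_df[sizes_df["time_days"] == class_time].set_index("barcode")["cells"]
    def classify(n: int) -> str:
        if n <= small_max:
            return "small"
        if n >= large_min:
            return "large"
        return "intermediate"
    size_class = at_t.map(classify)
    return CloneSummary(sizes_df, distinct, membership, size_class, float(class_time))


def write_matrix_csv(A: TransitionGrowthMatrix | np.ndarray, path: str | Path,
                     labels: tuple[str, ...] | None = None) -> None:
    """Square CSV with state labels as header row and index column."""
    if isinstance(A, TransitionGrowthMatrix):
        labels = labels or A.states.labels
        M = A.A
    else:
        M = np.asarray(A, dtype=float)
        labels = labels or tuple(f"S{i + 1}" for i in range(M.shape[0]))
    pd.DataFrame(M, index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix_csv(path: str | Path) -> TransitionGrowthMatrix:
    frame = pd.read_csv(path, index_col=0)
    labels = tuple(str(c) for c in frame.columns)
    states = StateSpace(len(labels), labels)
    return TransitionGrowthMatrix(frame.to_numpy(dtype=float), states=states)


def write_network(net: TransitionNetwork, path: str | Path) -> None:
    """3-column TSV: source, target, rate_per_day."""
    pd.DataFrame(
        list(net.edges), columns=["source", "target", "rate_per_day"]
    ).to_csv(path, sep="\t", index=False)


def write_network_graphml(net: TransitionNetwork, path: str | Path) -> None:
    import networkx as nx

    G = nx.DiGraph()
    G.add_nodes_from(net.states.labels)
    for src, dst, rate in net.edges:
        G.add_edge(src, dst, rate_per_day=float(rate))
    nx.write_graphml(G, path)


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = tuple(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, tuple[str, ...]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_mtx(directory: str | Path):
    """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    from scipy.io import mmread

    from .states import ExpressionMatrix

    directory = Path(directory)
    M = mmread(directory / "matrix.mtx").toarray().astype(float)
    genes = [
        line.split("\t")[0]
        for line in (directory / "features.tsv").read_text().splitlines()
        if line.strip()
    ]
    cells = [
        line.strip()
        for line in (directory / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    return ExpressionMatrix(M, tuple(genes), tuple(cells))


def read_expression_tsv(path: str | Path):
    """Dense genes x cells TSV with gene ids in the first column."""
    from .states import ExpressionMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        frame.to_numpy(dtype=float),
        tuple(str(g) for g in frame.index),
        tuple(str(c) for c in frame.columns),
    )


def write_json_report(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
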