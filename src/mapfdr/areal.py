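"""Areal count data: per-area observed/expected counts and spatial adjacency.

The tabular backbone of a disease map is one row per small area with an
observed disease count ``y`` and an expected count ``e`` obtained by indirect
standardization (reference age-specific rates applied to the area population).
The standardized mortality ratio SMR = y/e is the maximum-likelihood estimate
of the area relative risk, with variance 1/e under the Poisson model, so
``e`` doubles as the precision of the estimate.

Adjacency is a symmetric neighbour structure used by the intrinsic CAR
(spatial) prior.  Two on-disk dialects are supported: a plain two-column edge
list (symmetrized on read) and the positional ``num``/``adj`` vector pair
familiar from the WinBUGS ecosystem.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AreaRecord",
    "AreaTable",
    "AdjacencyMap",
    "SmrTable",
    "MapDiagnostics",
    "read_area_table",
    "read_adjacency",
    "compute_smr",
    "validate_map",
]


class AreaDataError(ValueError):
    """Raised when areal inputs violate the data model."""


@dataclass(frozen=True)
class AreaRecord:
    """One area: identifier, observed count ``y`` >= 0, expected count ``e`` > 0."""

    area_id: str
    y: int
    e: float


@dataclass
class AreaTable:
    """Ordered collection of areas; row order is the canonical area ordering.

    Every per-area output elsewhere in the package (p-values, posterior
    probabilities, truth vectors) aligns positionally with this order.
    """

    ids: list[str]
    y: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.y = np.asarray(self.y)
        self.e = np.asarray(self.e, dtype=float)
        if len(self.ids) == 0:
            raise AreaDataError("area table must contain at least one area")
        if not (len(self.ids) == self.y.shape[0] == self.e.shape[0]):
            raise AreaDataError("ids, y and e must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AreaDataError(f"duplicate area identifiers: {dupes}")
        if np.any(self.y != np.floor(self.y)) or np.any(self.y < 0):
            bad = int(np.flatnonzero((self.y != np.floor(self.y)) | (self.y < 0))[0])
            raise AreaDataError(
                f"observed count must be a non-negative integer (row {bad + 1}, "
                f"area {self.ids[bad]!r})"
            )
        self.y = self.y.astype(np.int64)
        if np.any(~np.isfinite(self.e)) or np.any(self.e <= 0):
            bad = int(np.flatnonzero(~np.isfinite(self.e) | (self.e <= 0))[0])
            raise AreaDataError(
                f"expected count must be positive and finite (row {bad + 1}, "
                f"area {self.ids[bad]!r})"
            )

    @property
    def m(self) -> int:
        """Number of areas."""
        return len(self.ids)

    @property
    def records(self) -> list[AreaRecord]:
        return [AreaRecord(i, int(y), float(e)) for i, y, e in zip(self.ids, self.y, self.e)]

    @classmethod
    def from_records(cls, records: Iterable[AreaRecord]) -> "AreaTable":
        recs = list(records)
        return cls([r.area_id for r in recs], [r.y for r in recs], [r.e for r in recs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"area_id": self.ids, "observed": self.y, "expected": self.e})

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}


def read_area_table(
    source,
    sep: str | None = None,
    id_col: str = "area_id",
    observed_col: str = "observed",
    expected_col: str = "expected",
) -> AreaTable:
    """Read an area table from delimited text (path, stream or string buffer).

    The file must have a header row.  ``sep=None`` sniffs comma vs tab.
    Raises :class:`AreaDataError` naming the missing column or offending row.
    """
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    for col in (id_col, observed_col, expected_col):
        if col not in df.columns:
            raise AreaDataError(
                f"missing required column {col!r}; found {list(df.columns)}"
            )
    return AreaTable(
        df[id_col].astype(str).tolist(),
        df[observed_col].to_numpy(),
        df[expected_col].to_numpy(dtype=float),
    )


@dataclass
class AdjacencyMap:
    """Symmetric neighbour sets S_i keyed by area id; no self-loops.

    ``n_i = |S_i|`` is the neighbour count driving the ICAR conditional
    precision.  Areas may legitimately have no neighbours ("islands");
    downstream samplers decide how to treat them.
    """

    neighbours: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for a, nbrs in self.neighbours.items():
            clean[str(a)] = frozenset(str(b) for b in nbrs)
        self.neighbours = clean
        for a, nbrs in self.neighbours.items():
            if a in nbrs:
                raise AreaDataError(f"self-loop on area {a!r}")
            for b in nbrs:
                if a not in self.neighbours.get(b, frozenset()):
                    raise AreaDataError(f"asymmetric adjacency: {a!r} -> {b!r}")

    @property
    def n(self) -> dict[str, int]:
        """Neighbour counts n_i."""
        return {a: len(s) for a, s in self.neighbours.items()}

    @property
    def areas(self) -> list[str]:
        return list(self.neighbours)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], areas: Sequence[str] | None = None) -> "AdjacencyMap":
        """Build from an (unordered) edge list, symmetrizing; optionally seed
        with a full area list so unconnected areas appear with empty sets."""
        nbrs: dict[str, set[str]] = {str(a): set() for a in (areas or [])}
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise AreaDataError(f"self-loop edge ({a!r}, {b!r})")
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        return cls({a: frozenset(s) for a, s in nbrs.items()})

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.neighbours)
        for a, nbrs in self.neighbours.items():
            g.add_edges_from((a, b) for b in nbrs)
        return g

    def edge_list(self) -> list[tuple[str, str]]:
        """Each undirected edge once, lexicographically ordered."""
        return sorted({tuple(sorted((a, b))) for a, s in self.neighbours.items() for b in s})

    def neighbour_indices(self, table: AreaTable) -> list[np.ndarray]:
        """Neighbour index arrays aligned to the table's row order.

        Raises if the adjacency references an id absent from the table; areas
        missing from the adjacency get an empty neighbour set (islands).
        """
        idx = table.index_of()
        for a, nbrs in self.neighbours.items():
            for b in (a, *nbrs):
                if b not in idx:
                    raise AreaDataError(f"adjacency references unknown area {b!r}")
        out = []
        for a in table.ids:
            nbrs = self.neighbours.get(a, frozenset())
            out.append(np.array(sorted(idx[b] for b in nbrs), dtype=np.int64))
        return out

    def write_edges(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edge_list():
                fh.write(f"{a}\t{b}\n")


def _read_winbugs_adj(text: str, table: AreaTable) -> AdjacencyMap:
    # key: value file with whitespace-separated integer vectors `num` and `adj`;
    # adj entries are 1-based positions in the table's row order.
    fields: dict[str, list[int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise AreaDataError(f"expected 'key: values' line, got {line!r}")
        key, _, vals = line.partition(":")
        fields.setdefault(key.strip(), []).extend(int(v) for v in vals.split())
    for key in ("num", "adj"):
        if key not in fields:
            raise AreaDataError(f"winbugs-adj input missing {key!r} vector")
    num, adj = fields["num"], fields["adj"]
    if len(num) != table.m:
        raise AreaDataError(
            f"'num' has {len(num)} entries but the table has {table.m} areas"
        )
    if sum(num) != len(adj):
        raise AreaDataError("'adj' length does not match sum of 'num'")
    nbrs: dict[str, set[str]] = {a: set() for a in table.ids}
    pos = 0
    for i, n_i in enumerate(num):
        for j in adj[pos : pos + n_i]:
            if not 1 <= j <= table.m:
                raise AreaDataError(f"'adj' index {j} outside 1..{table.m}")
            if j == i + 1:
                raise AreaDataError(f"self-loop on area {table.ids[i]!r}")
            nbrs[table.ids[i]].add(table.ids[j - 1])
        pos += n_i
    for a, s in nbrs.items():
        for b in s:
            if a not in nbrs[b]:
                raise AreaDataError(f"asymmetric winbugs-adj input: {a!r} -> {b!r}")
    return AdjacencyMap({a: frozenset(s) for a, s in nbrs.items()})


def read_adjacency(source, dialect: str = "edge-list", table: AreaTable | None = None) -> AdjacencyMap:
    """Read adjacency from text.

    ``edge-list``: two whitespace/comma-separated id columns, one edge per
    line, symmetrized.  ``winbugs-adj``: positional ``num``/``adj`` vectors
    interpreted against the row order of *table* (required); asymmetry is an
    error rather than repaired, since the dialect encodes both directions.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    if dialect == "edge-list":
        edges = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise AreaDataError(f"expected two ids per edge line, got {line!r}")
            edges.append((parts[0], parts[1]))
        adj = AdjacencyMap.from_edges(edges, areas=table.ids if table else None)
    elif dialect == "winbugs-adj":
        if table is None:
            raise AreaDataError("winbugs-adj dialect requires an AreaTable for positional ids")
        adj = _read_winbugs_adj(text, table)
    else:
        raise AreaDataError(f"unknown adjacency dialect {dialect!r}")
    if table is not None:
        known = set(table.ids)
        unknown = sorted(set(adj.neighbours) - known)
        if unknown:
            raise AreaDataError(f"adjacency references unknown areas: {unknown}")
    return adj


@dataclass
class SmrTable:
    """Per-area SMR = y/e with variance 1/e and precision e."""

    ids: list[str]
    smr: np.ndarray
    variance: np.ndarray

    @property
    def precision(self) -> np.ndarray:
        return 1.0 / self.variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_id": self.ids, "smr": self.smr, "variance": self.variance,
             "precision": self.precision}
        )


def compute_smr(table: AreaTable) -> SmrTable:
    """Standardized mortality ratios: the ML estimate of each area's relative risk."""
    return SmrTable(list(table.ids), table.y / table.e, 1.0 / table.e)


@dataclass
class MapDiagnostics:
    """Read-only consistency report for a table + adjacency pair."""

    islands: list[str]
    n_components: int
    missing_from_adjacency: list[str] = field(default_factory=list)
    unknown_in_adjacency: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.islands or self.missing_from_adjacency or self.unknown_in_adjacency)


def validate_map(table: AreaTable, adj: AdjacencyMap) -> MapDiagnostics:
    """Diagnose islands, connected components and id coverage; mutates nothing.

    Areas present in the table but absent from (or neighbourless in) the
    adjacency are reported as islands; components are counted on the subgraph
    of table areas.
    """
    known = set(table.ids)
    unknown = sorted(set(adj.neighbours) - known)
    missing = sorted(known - set(adj.neighbours))
    g = adj.to_graph().subgraph(known).copy()
    g.add_nodes_from(known)
    islands = sorted((a for a in table.ids if g.degree(a) == 0), key=table.ids.index)
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    return MapDiagnostics(islands, n_comp, missing, unknown)
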