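"""Synthetic areal maps with known truth, and truth-based evaluation.

Real small-area mortality tables are rarely redistributable, so benchmarking
multiple-testing procedures relies on simulated maps that reproduce their
salient geometry: a few hundred areas, expected counts spanning two to three
orders of magnitude (village to city), and a small fraction of truly
divergent areas.  The generator draws areas on a rook-contiguity lattice
(neighbour counts 2-4, like a contiguity map), samples heterogeneous expected
counts, marks a configurable fraction of areas as divergent — scattered at
random or as one contiguous spatial cluster — and draws observed counts from
the Poisson law.  The default fraction of divergent areas is 3%, a typical
prior belief in regional mortality screening, and effects are two-sided
(half the divergent areas above the null relative risk, half below).

Truth is encoded as the null indicator r_i: r_i = 1 means the area truly
sits at the null (theta_i = 1 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areal import AdjacencyMap, AreaTable, validate_map

__all__ = [
    "SyntheticMap",
    "FdpReport",
    "lattice_adjacency",
    "generate_map",
    "evaluate_fdp",
    "replicate_study",
]


@dataclass
class SyntheticMap:
    """A generated map: data table, lattice adjacency, truth, and the
    generator settings that produced it (echoed for the run manifest)."""

    table: AreaTable
    adj: AdjacencyMap
    truth: pd.DataFrame  # area_id, true_null (r_i), true_rr
    settings: dict

    @property
    def true_null(self) -> np.ndarray:
        return self.truth["true_null"].to_numpy()

    @property
    def true_rr(self) -> np.ndarray:
        return self.truth["true_rr"].to_numpy()


def lattice_adjacency(n_rows: int, n_cols: int, drop_last: int = 0) -> tuple[list[str], AdjacencyMap]:
    """Rook-contiguity lattice ids and adjacency, row-major ``A0001``...;
    ``drop_last`` trims cells off the end (e.g. a 17x17 lattice minus 2 cells
    gives 287 areas)."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice must be at least 1x1")
    m = n_rows * n_cols - drop_last
    if m < 1:
        raise ValueError("drop_last removes every cell")
    ids = [f"A{i + 1:04d}" for i in range(m)]
    edges = []
    for i in range(m):
        row, col = divmod(i, n_cols)
        if col + 1 < n_cols and i + 1 < m:
            edges.append((ids[i], ids[i + 1]))
        if row + 1 < n_rows and i + n_cols < m:
            edges.append((ids[i], ids[i + n_cols]))
    return ids, AdjacencyMap.from_edges(edges, areas=ids)


def _divergent_rr(rng, n_div: int, effect_model: str, effect_size: float, two_sided: bool):
    if n_div == 0:
        return np.empty(0)
    if effect_model in ("fixed", "cluster"):
        rr = np.full(n_div, float(effect_size))
    elif effect_model == "lognormal":
        # effect_size acts as the log-scale dispersion around the null
        rr = np.exp(rng.normal(0.0, np.log(effect_size), size=n_div))
    else:
        raise ValueError(f"unknown effect model {effect_model!r}")
    if two_sided and effect_model != "lognormal":
        flip = np.zeros(n_div, dtype=bool)
        flip[rng.permutation(n_div)[: n_div // 2]] = True
        rr = np.where(flip, 1.0 / rr, rr)
    return rr


def generate_map(
    n_rows: int = 17,
    n_cols: int = 17,
    drop_last: int = 2,
    e_range: tuple[float, float] = (0.5, 200.0),
    pi0_true: float = 0.97,
    effect_model: str = "fixed",
    effect_size: float = 2.0,
    two_sided: bool = True,
    seed: int = 0,
) -> SyntheticMap:
    """Generate a seeded synthetic areal map with known truth.

    Expected counts are log-uniform over ``e_range`` (heavy mass on small
    areas, as in municipal population distributions).  Each area is truly
    null with probability ``pi0_true``; under ``effect_model='cluster'`` the
    divergent areas instead form one contiguous lattice patch (grown
    breadth-first from a random seed area) to exercise spatially structured
    alternatives.  Observed counts are Poisson(e_i * theta_i).  The map is
    bit-reproducible from ``seed``.
    """
    if not 0 < pi0_true <= 1:
        raise ValueError("pi0_true must lie in (0, 1]")
    if e_range[0] <= 0 or e_range[1] < e_range[0]:
        raise ValueError("invalid expected-count range")
    rng = np.random.default_rng(seed)
    ids, adj = lattice_adjacency(n_rows, n_cols, drop_last)
    m = len(ids)
    e = np.exp(rng.uniform(np.log(e_range[0]), np.log(e_range[1]), size=m))
    null = np.ones(m, dtype=np.int8)
    if pi0_true < 1:
        if effect_model == "cluster":
            n_div = max(1, int(round((1 - pi0_true) * m)))
            nbr_idx = adj.neighbour_indices(AreaTable(ids, np.zeros(m), e))
            start = int(rng.integers(m))
            patch = [start]
            seen = {start}
            frontier = [start]
            while len(patch) < n_div and frontier:
                nxt = []
                for i in frontier:
                    for j in rng.permutation(nbr_idx[i]):
                        if int(j) not in seen:
                            seen.add(int(j))
                            patch.append(int(j))
                            nxt.append(int(j))
                            if len(patch) >= n_div:
                                break
                    if len(patch) >= n_div:
                        break
                frontier = nxt
            null[np.array(patch[:n_div])] = 0
        else:
            null = (rng.random(m) < pi0_true).astype(np.int8)
    rr = np.ones(m)
    div_idx = np.flatnonzero(null == 0)
    rr[div_idx] = _divergent_rr(rng, div_idx.size, effect_model, effect_size, two_sided)
    y = rng.poisson(e * rr)
    table = AreaTable(ids, y, e)
    diag = validate_map(table, adj)
    assert diag.n_components >= 1
    truth = pd.DataFrame({"area_id": ids, "true_null": null, "true_rr": rr})
    settings = {"n_rows": n_rows, "n_cols": n_cols, "drop_last": drop_last,
                "e_range": list(e_range), "pi0_true": pi0_true,
                "effect_model": effect_model, "effect_size": effect_size,
                "two_sided": two_sided, "seed": int(seed)}
    return SyntheticMap(table, adj, truth, settings)


@dataclass
class FdpReport:
    """Truth-based scorecard of one rejection rule on one map."""

    V: int            # false rejections (truly null areas rejected)
    R: int            # total rejections
    n_divergent: int  # truly divergent areas in the map
    sensitivity: float

    @property
    def fdp(self) -> float:
        """False discovery proportion V/R, defined as 0 when nothing is rejected."""
        return self.V / self.R if self.R > 0 else 0.0


def evaluate_fdp(flags, true_null) -> FdpReport:
    """Score rejections against truth: V = sum(r_i * I_i), R = sum(I_i),
    sensitivity = fraction of truly divergent areas rejected."""
    flags = np.asarray(flags, dtype=int)
    r = np.asarray(true_null, dtype=int)
    if flags.shape != r.shape:
        raise ValueError("flags and truth must have equal length")
    V = int((r * flags).sum())
    R = int(flags.sum())
    n_div = int((r == 0).sum())
    sens = float(flags[r == 0].mean()) if n_div else float("nan")
    return FdpReport(V, R, n_div, sens)


def replicate_study(
    procedure,
    n_replicates: int = 200,
    seed: int = 0,
    **map_kwargs,
) -> pd.DataFrame:
    """Repeat generate -> test -> score over independent maps.

    ``procedure`` maps an :class:`AreaTable` to a 0/1 rejection vector.
    Returns one row per replicate (V, R, FDP, sensitivity); the FDR is the
    mean FDP column, with Monte-Carlo standard error mean_fdp_se attached in
    ``DataFrame.attrs``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    rows = []
    for s in child_seeds:
        smap = generate_map(seed=int(s), **map_kwargs)
        rep = evaluate_fdp(procedure(smap.table), smap.true_null)
        rows.append({"seed": int(s), "V": rep.V, "R": rep.R,
                     "fdp": rep.fdp, "sensitivity": rep.sensitivity})
    df = pd.DataFrame(rows)
    df.attrs["mean_fdp"] = float(df["fdp"].mean())
    df.attrs["mean_fdp_se"] = float(df["fdp"].std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else float("nan")
    return df
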