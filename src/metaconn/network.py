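"""Metabolic covariance networks: correlation, thresholding, edge accounting.

A group-level network is built by correlating every pair of regional SUVR
columns across the subjects of one group (Pearson r), then binarizing the
90x90 matrix over a grid of thresholds: entry r >= tau becomes an edge.
The working threshold is chosen from the normal-control group as the
largest grid value at which every one of the 90 regions still has at least
one edge ("full coverage"); that single tau is then applied to all groups
so edge counts are comparable. Edges are partitioned by hemisphere class
(intra-left, intra-right, inter-hemispheric) and by the unordered pair of
lobe categories of their endpoints.

Thresholds act on signed r — the default grid is positive, so negative
correlations never produce edges — and ties are resolved as r >= tau.
The 45x45 inter-hemispheric matrix (left rows, right columns, homologue
pairs on the diagonal) is the submatrix of the full matrix restricted to
cross-hemisphere pairs; its suprathreshold cell count equals the
inter-hemispheric class of the full partition by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Hemisphere, Lobe, RegionAtlas
from .suvr import SuvrDataset

__all__ = [
    "CorrMatrix",
    "BinaryNetwork",
    "EdgePartition",
    "ConnectivityReport",
    "DEFAULT_GRID",
    "default_grid",
    "correlation_matrix",
    "interhemispheric_matrix",
    "binarize",
    "threshold_sweep",
    "select_threshold",
    "partition_edges",
    "connectivity_report",
    "ThresholdSelectionError",
]

GROUP_ORDER = ("NC", "sMCI", "pMCI", "AD")


def default_grid() -> np.ndarray:
    """The standard threshold grid: 0.50 to 0.90 in steps of 0.02 (21 values)."""
    return np.round(np.arange(25, 46) * 0.02, 10)


DEFAULT_GRID = default_grid()


class ThresholdSelectionError(RuntimeError):
    """No grid threshold keeps every region connected in the reference group."""


@dataclass
class CorrMatrix:
    """Interregional Pearson correlations for one group.

    ``kind`` is "FULL" (90x90, symmetric, unit diagonal) or "INTERHEMI"
    (45x45, rows = left regions, columns = right regions in
    homologue-aligned order; generally asymmetric).
    """

    kind: str
    group_label: str
    row_regions: list[str]
    col_regions: list[str]
    values: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("FULL", "INTERHEMI"):
            raise ValueError(f"unknown CorrMatrix kind: {self.kind!r}")
        if self.values.shape != (len(self.row_regions), len(self.col_regions)):
            raise ValueError("correlation matrix shape inconsistent with labels")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_regions, columns=self.col_regions
        )


@dataclass
class BinaryNetwork:
    """A thresholded network with its threshold and edge bookkeeping.

    For FULL networks edges are unordered region pairs (upper triangle,
    diagonal excluded); for INTERHEMI networks every (left, right) cell
    including the homologue diagonal is a potential edge.
    ``n_connected_nodes`` counts regions with degree >= 1.
    """

    kind: str
    group_label: str
    threshold: float
    row_regions: list[str]
    col_regions: list[str]
    adjacency: np.ndarray
    edge_list: list[tuple[str, str]] = field(init=False)
    n_edges: int = field(init=False)
    n_connected_nodes: int = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        if self.kind == "FULL":
            if not np.array_equal(self.adjacency, self.adjacency.T):
                raise ValueError("FULL adjacency must be symmetric")
            if np.any(np.diag(self.adjacency) != 0):
                raise ValueError("FULL adjacency must have zero diagonal")
            iu, ju = np.where(np.triu(self.adjacency, k=1))
            self.edge_list = [
                (self.row_regions[i], self.row_regions[j]) for i, j in zip(iu, ju)
            ]
            degree = self.adjacency.sum(axis=0)
            self.n_connected_nodes = int((degree > 0).sum())
        elif self.kind == "INTERHEMI":
            iu, ju = np.where(self.adjacency)
            self.edge_list = [
                (self.row_regions[i], self.col_regions[j]) for i, j in zip(iu, ju)
            ]
            row_deg = self.adjacency.sum(axis=1)
            col_deg = self.adjacency.sum(axis=0)
            self.n_connected_nodes = int((row_deg > 0).sum() + (col_deg > 0).sum())
        else:
            raise ValueError(f"unknown network kind: {self.kind!r}")
        self.n_edges = len(self.edge_list)


@dataclass
class EdgePartition:
    """Edge counts by hemisphere class and by unordered lobe pair."""

    group_label: str
    threshold: float
    intra_left: int
    intra_right: int
    inter: int
    total: int
    lobe_pair_counts: dict[tuple[str, str], int]

    def lobe_pair_frame(self) -> pd.DataFrame:
        pairs = all_lobe_pairs()
        return pd.DataFrame(
            {
                "lobe_pair": [f"{a}-{b}" for a, b in pairs],
                "n_edges": [self.lobe_pair_counts.get(p, 0) for p in pairs],
            }
        )


def all_lobe_pairs() -> list[tuple[str, str]]:
    """The 28 unordered pairs of the 7 lobe categories, sorted."""
    cats = sorted(l.value for l in Lobe)
    return list(itertools.combinations_with_replacement(cats, 2))


def correlation_matrix(dataset: SuvrDataset) -> CorrMatrix:
    """Full interregional Pearson correlation matrix across subjects."""
    if dataset.n_subjects < 3:
        raise ValueError("Pearson correlation needs at least 3 subjects")
    sds = dataset.values.std(axis=0)
    dead = [n for n, s in zip(dataset.region_names, sds) if s == 0]
    if dead:
        raise ValueError(f"zero-variance regions (correlation undefined): {dead}")
    r = np.corrcoef(dataset.values, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrMatrix(
        kind="FULL",
        group_label=dataset.group_label,
        row_regions=list(dataset.region_names),
        col_regions=list(dataset.region_names),
        values=r,
        n_subjects=dataset.n_subjects,
    )


def interhemispheric_matrix(
    dataset: SuvrDataset, atlas: RegionAtlas, full: CorrMatrix | None = None
) -> CorrMatrix:
    """45x45 left-vs-right correlation matrix in homologue-aligned order.

    Entries coincide with the corresponding cells of the FULL matrix;
    homologue pairs sit on the diagonal.
    """
    if full is None:
        full = correlation_matrix(dataset)
    left, right = atlas.hemisphere_split()
    sub = full.values[np.ix_(left, right)]
    return CorrMatrix(
        kind="INTERHEMI",
        group_label=dataset.group_label,
        row_regions=[atlas.regions[i].name for i in left],
        col_regions=[atlas.regions[j].name for j in right],
        values=sub,
        n_subjects=dataset.n_subjects,
    )


def binarize(corr: CorrMatrix, tau: float) -> BinaryNetwork:
    """Threshold a correlation matrix: edge iff r >= tau (FULL diagonal excluded)."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {tau}")
    adj = (corr.values >= tau).astype(np.int8)
    if corr.kind == "FULL":
        np.fill_diagonal(adj, 0)
    return BinaryNetwork(
        kind=corr.kind,
        group_label=corr.group_label,
        threshold=float(tau),
        row_regions=list(corr.row_regions),
        col_regions=list(corr.col_regions),
        adjacency=adj,
    )


def threshold_sweep(corr: CorrMatrix, grid=None) -> list[BinaryNetwork]:
    """Binarize over an increasing threshold grid (default 0.50:0.90:0.02)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    if grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("threshold grid must lie within (0, 1)")
    return [binarize(corr, float(tau)) for tau in grid]


def select_threshold(
    corr_nc: CorrMatrix, grid=None, rule: str = "largest"
) -> float:
    """Choose the working threshold from the reference (NC) full matrix.

    ``rule="largest"`` (default) returns the largest grid value at which
    every region keeps degree >= 1 — the highest threshold whose NC network
    still contains all 90 nodes. ``rule="smallest"`` returns the smallest
    such grid value instead.
    """
    if corr_nc.kind != "FULL":
        raise ValueError("threshold selection requires the FULL reference matrix")
    if rule not in ("largest", "smallest"):
        raise ValueError(f"unknown selection rule: {rule!r}")
    nets = threshold_sweep(corr_nc, grid)
    n_nodes = len(corr_nc.row_regions)
    covering = [net for net in nets if net.n_connected_nodes == n_nodes]
    if not covering:
        best = max(net.n_connected_nodes for net in nets)
        raise ThresholdSelectionError(
            f"no grid threshold keeps all {n_nodes} nodes connected "
            f"(best coverage: {best} nodes)"
        )
    chosen = covering[-1] if rule == "largest" else covering[0]
    return chosen.threshold


def partition_edges(net: BinaryNetwork, atlas: RegionAtlas) -> EdgePartition:
    """Classify each edge by hemisphere class and unordered lobe pair."""
    if net.kind != "FULL":
        raise ValueError("edge partition is defined on FULL networks")
    intra_left = intra_right = inter = 0
    lobe_counts: dict[tuple[str, str], int] = {}
    for a, b in net.edge_list:
        ra, rb = atlas[a], atlas[b]
        if ra.hemisphere is not rb.hemisphere:
            inter += 1
        elif ra.hemisphere is Hemisphere.LEFT:
            intra_left += 1
        else:
            intra_right += 1
        key = tuple(sorted((ra.lobe.value, rb.lobe.value)))
        lobe_counts[key] = lobe_counts.get(key, 0) + 1
    return EdgePartition(
        group_label=net.group_label,
        threshold=net.threshold,
        intra_left=intra_left,
        intra_right=intra_right,
        inter=inter,
        total=net.n_edges,
        lobe_pair_counts=lobe_counts,
    )


@dataclass
class ConnectivityReport:
    """End-to-end four-group analysis at a shared threshold."""

    threshold: float
    tau_mode: str  # "auto" | "fixed"
    grid: np.ndarray
    group_order: tuple[str, ...]
    full_matrices: dict[str, CorrMatrix]
    interhemi_matrices: dict[str, CorrMatrix]
    networks: dict[str, BinaryNetwork]
    interhemi_networks: dict[str, BinaryNetwork]
    partitions: dict[str, EdgePartition]
    n_subjects: dict[str, int]

    def summary_frame(self) -> pd.DataFrame:
        """Per-group nodes / intra / inter / total edge counts."""
        rows = []
        for g in self.group_order:
            net, part = self.networks[g], self.partitions[g]
            rows.append(
                {
                    "group": g,
                    "n_subjects": self.n_subjects[g],
                    "threshold": self.threshold,
                    "nodes": net.n_connected_nodes,
                    "intra_left_edges": part.intra_left,
                    "intra_right_edges": part.intra_right,
                    "intra_edges": part.intra_left + part.intra_right,
                    "inter_edges": part.inter,
                    "total_edges": part.total,
                }
            )
        return pd.DataFrame(rows)

    def lobe_pair_frame(self) -> pd.DataFrame:
        """28 lobe-pair rows x one edge-count column per group."""
        pairs = all_lobe_pairs()
        data = {"lobe_pair": [f"{a}-{b}" for a, b in pairs]}
        for g in self.group_order:
            counts = self.partitions[g].lobe_pair_counts
            data[g] = [counts.get(p, 0) for p in pairs]
        return pd.DataFrame(data)

    def lobe_pair_ratios(self) -> pd.DataFrame:
        """Pairwise group ratios of lobe-pair edge counts (NaN where 0/0 or x/0)."""
        counts = self.lobe_pair_frame().set_index("lobe_pair")
        data = {}
        for ga, gb in itertools.permutations(self.group_order, 2):
            num, den = counts[ga].to_numpy(float), counts[gb].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(den > 0, num / den, np.nan)
            data[f"{ga}/{gb}"] = ratio
        return pd.DataFrame(data, index=counts.index)


def connectivity_report(
    cohort: dict[str, SuvrDataset],
    atlas: RegionAtlas,
    grid=None,
    tau: float | None = None,
    selection_rule: str = "largest",
    reference_group: str = "NC",
) -> ConnectivityReport:
    """Run the full group-network analysis on a four-group cohort.

    Builds FULL and inter-hemispheric correlation matrices per group,
    selects the working threshold from the reference group (unless ``tau``
    is fixed), binarizes every group at that shared threshold, and
    partitions edges by hemisphere class and lobe pair.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    order = tuple(g for g in GROUP_ORDER if g in cohort) or tuple(cohort)
    if reference_group not in cohort:
        raise ValueError(f"reference group {reference_group!r} not in cohort")

    full = {g: correlation_matrix(cohort[g]) for g in order}
    inter = {
        g: interhemispheric_matrix(cohort[g], atlas, full=full[g]) for g in order
    }
    if tau is None:
        tau_mode = "auto"
        tau = select_threshold(full[reference_group], grid, rule=selection_rule)
    else:
        tau_mode = "fixed"
        tau = float(tau)
    nets = {g: binarize(full[g], tau) for g in order}
    inter_nets = {g: binarize(inter[g], tau) for g in order}
    parts = {g: partition_edges(nets[g], atlas) for g in order}
    return ConnectivityReport(
        threshold=tau,
        tau_mode=tau_mode,
        grid=grid,
        group_order=order,
        full_matrices=full,
        interhemi_matrices=inter,
        networks=nets,
        interhemi_networks=inter_nets,
        partitions=parts,
        n_subjects={g: cohort[g].n_subjects for g in order},
    )
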