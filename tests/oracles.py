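"""Independent brute-force reference implementations used as test oracles.

Everything here is written from first principles (explicit loops over the
definitions) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

from metaconn.atlas import Hemisphere, Lobe, Region, RegionAtlas


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from its covariance definition, one pair at a time."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def correlation_matrix_brute(values: np.ndarray) -> np.ndarray:
    """O(N^2 M) per-pair correlation matrix."""
    n = values.shape[1]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if i == j else pearson_brute(values[:, i], values[:, j])
    return out


def count_edges_brute(corr: np.ndarray, tau: float) -> int:
    """Suprathreshold upper-triangle cells, counted one by one."""
    n = corr.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] >= tau:
                count += 1
    return count


def connected_nodes_brute(corr: np.ndarray, tau: float) -> int:
    """Nodes with at least one suprathreshold partner (diagonal excluded)."""
    n = corr.shape[0]
    count = 0
    for i in range(n):
        if any(corr[i, j] >= tau for j in range(n) if j != i):
            count += 1
    return count


def select_threshold_brute(corr: np.ndarray, grid) -> float | None:
    """Largest grid value keeping every node connected, by exhaustive check."""
    n = corr.shape[0]
    best = None
    for tau in grid:
        if connected_nodes_brute(corr, float(tau)) == n:
            best = float(tau)
    return best


def partition_brute(edges, atlas: RegionAtlas):
    """Classify edges by hemisphere class and lobe pair, one edge at a time."""
    intra_left = intra_right = inter = 0
    lobe_counts: dict[tuple[str, str], int] = {}
    for a, b in edges:
        ha, hb = atlas[a].hemisphere, atlas[b].hemisphere
        if ha != hb:
            inter += 1
        elif ha is Hemisphere.LEFT:
            intra_left += 1
        else:
            intra_right += 1
        la, lb = atlas[a].lobe.value, atlas[b].lobe.value
        key = (la, lb) if la <= lb else (lb, la)
        lobe_counts[key] = lobe_counts.get(key, 0) + 1
    return intra_left, intra_right, inter, lobe_counts


def make_toy_atlas(n_pairs: int, rng: np.random.Generator) -> RegionAtlas:
    """A random bilateral parcellation of ``n_pairs`` homologue pairs."""
    lobes = list(Lobe)
    regions = []
    for k in range(n_pairs):
        lobe = lobes[int(rng.integers(len(lobes)))]
        xyz = tuple(float(v) for v in rng.uniform(-60, 60, size=3))
        regions.append(
            Region(2 * k + 1, f"Toy{k}_L", Hemisphere.LEFT, lobe, xyz)
        )
        regions.append(
            Region(2 * k + 2, f"Toy{k}_R", Hemisphere.RIGHT, lobe, xyz)
        )
    order = rng.permutation(len(regions))
    shuffled = [regions[i] for i in order]
    for i, r in enumerate(shuffled):
        shuffled[i] = Region(i + 1, r.name, r.hemisphere, r.lobe, r.centroid)
    return RegionAtlas(shuffled)
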