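"""Zonal statistics on label rasters.

All admin/zone machinery in this package operates on integer label rasters
(unit id per cell, 0 = outside any unit).  These helpers are the single
implementation of zonal sums and means used by every stage, so that
mass-conservation checks compare against one consistent definition.
"""

from __future__ import annotations

import numpy as np


def zone_ids(labels: np.ndarray) -> np.ndarray:
    """Sorted array of positive unit ids present in a label raster."""
    ids = np.unique(labels)
    return ids[ids > 0]


def zonal_sum(values: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Sum of ``values`` over each labelled zone (label > 0)."""
    lab = np.asarray(labels).ravel()
    val = np.asarray(values, dtype=float).ravel()
    if lab.shape != val.shape:
        raise ValueError("values and labels must share grid geometry")
    ok = lab > 0
    sums = np.bincount(lab[ok], weights=val[ok])
    return {int(i): float(sums[i]) for i in np.nonzero(np.bincount(lab[ok]))[0]}


def zonal_mean(
    values: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> dict[int, float]:
    """Per-zone mean of ``values``, optionally weighted.

    Zones whose total weight is zero are omitted from the result.
    """
    lab = np.asarray(labels).ravel()
    val = np.asarray(values, dtype=float).ravel()
    ok = lab > 0
    if weights is None:
        w = np.ones(val.shape)
    else:
        w = np.asarray(weights, dtype=float).ravel()
    num = np.bincount(lab[ok], weights=(val * w)[ok])
    den = np.bincount(lab[ok], weights=w[ok])
    out: dict[int, float] = {}
    for i in np.nonzero(den > 0)[0]:
        out[int(i)] = float(num[i] / den[i])
    return out


def zone_centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """Centroid (row, col) of each labelled zone, in cell coordinates."""
    rows, cols = np.indices(labels.shape)
    r = zonal_mean(rows, labels)
    c = zonal_mean(cols, labels)
    return {i: (r[i], c[i]) for i in r}


def rook_adjacency(labels: np.ndarray) -> dict[int, set[int]]:
    """Rook (edge-sharing) adjacency graph among labelled zones."""
    adj: dict[int, set[int]] = {int(i): set() for i in zone_ids(labels)}
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
    return adj
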