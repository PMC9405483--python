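"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own code paths: overlaps are computed
on Python sets of pixel tuples, Feret diameters by the O(n^2) pairwise loop,
and linking by explicit enumeration with the stated tie-break order.
"""

from __future__ import annotations

import numpy as np


def brute_feret(boundary_px: np.ndarray, um_per_px_y: float, um_per_px_x: float) -> float:
    """Max pairwise distance between boundary pixel centres, O(n^2)."""
    pts = [(r * um_per_px_y, c * um_per_px_x) for r, c in boundary_px]
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = ((pts[i][0] - pts[j][0]) ** 2 + (pts[i][1] - pts[j][1]) ** 2) ** 0.5
            best = max(best, d)
    return best


def boundary_of(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """4-neighbour boundary pixels of a coordinate set (set-based)."""
    members = {(int(r), int(c)) for r, c in coords}
    out = []
    for r, c in sorted(members):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in members:
                out.append((r, c))
                break
    return np.array(out)


def exhaustive_link(blobs_by_layer: dict[int, list], min_overlap_frac: float):
    """Reference linking: enumerate all eligible pairs per adjacent layer,
    take them in (largest pixel overlap, smallest centroid distance, layer
    order) priority, one predecessor/successor per blob; return the set of
    tracks as tuples of blob ids."""
    pixel_sets = {}
    for layer, blobs in blobs_by_layer.items():
        for b in blobs:
            pixel_sets[id(b)] = {(int(r), int(c)) for r, c in b.coords}

    succ: dict[int, object] = {}
    pred: dict[int, object] = {}
    for layer in sorted(blobs_by_layer):
        if layer + 1 not in blobs_by_layer:
            continue
        pairs = []
        for ai, a in enumerate(blobs_by_layer[layer]):
            for bi, b in enumerate(blobs_by_layer[layer + 1]):
                inter = len(pixel_sets[id(a)] & pixel_sets[id(b)])
                if inter == 0:
                    continue
                frac = inter / min(len(pixel_sets[id(a)]), len(pixel_sets[id(b)]))
                if frac >= min_overlap_frac:
                    dist = ((a.centroid_um[0] - b.centroid_um[0]) ** 2
                            + (a.centroid_um[1] - b.centroid_um[1]) ** 2) ** 0.5
                    pairs.append((-inter, dist, ai, bi, a, b))
        for _, _, _, _, a, b in sorted(pairs, key=lambda t: t[:4]):
            if id(a) in succ or id(b) in pred:
                continue
            succ[id(a)] = b
            pred[id(b)] = a

    tracks = set()
    for layer in sorted(blobs_by_layer):
        for blob in blobs_by_layer[layer]:
            if id(blob) in pred:
                continue
            chain = [blob]
            while id(chain[-1]) in succ:
                chain.append(succ[id(chain[-1])])
            tracks.add(tuple(id(b) for b in chain))
    return tracks


def brute_kindled_at(scores) -> int | None:
    """Linear scan for the first pair of consecutive generalized seizures."""
    for i in range(len(scores) - 1):
        if scores[i] >= 4 and scores[i + 1] >= 4:
            return i + 2  # 1-based index of the second injection
    return None


def random_blob_layers(rng: np.random.Generator, shape=(64, 64), n_layers=3,
                       max_blobs=6, max_radius=7):
    """Random disk masks per layer for linking-oracle scenes."""
    from hippoquant import extract_blobs
    from conftest import ISO_1UM, disk_mask

    blobs_by_layer = {}
    for k in range(n_layers):
        mask = np.zeros(shape, dtype=bool)
        for _ in range(rng.integers(0, max_blobs + 1)):
            r = rng.uniform(6, shape[0] - 7)
            c = rng.uniform(6, shape[1] - 7)
            mask |= disk_mask(shape, r, c, rng.uniform(2, max_radius))
        blobs_by_layer[k] = extract_blobs(mask, ISO_1UM, exclude_border=False,
                                          layer_index=k)
    return blobs_by_layer
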