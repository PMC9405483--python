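"""Layered cell detection in calibrated fluorescence z-stacks.

The counting algorithm runs per layer and then reasons across layers:

1. Gaussian blurring suppresses background noise (sigma given in um,
   converted per axis).
2. Adaptive thresholding marks a pixel as foreground when it exceeds the
   local mean over a physical neighbourhood by a fixed offset; this is what
   makes the segmentation robust to uneven background/illumination.
3. Morphological opening then closing with a physical structuring element
   removes speckle and seals small gaps.
4. Connected components (8-connectivity) become :class:`Blob` objects with
   pixel-exact area and Feret (longest) diameter in um.
5. Blobs in consecutive layers are greedily linked into :class:`CellTrack`
   chains when they overlap by at least ``min_overlap_frac`` of the smaller
   blob's area.
6. A track is a cell when it spans at least ``min_layer_support`` layers and
   its largest Feret diameter strictly exceeds ``min_cell_diag_um``.
7. Neuronal debris are NeuN fragments of 2.5-6.5 um that belong to no cell
   and whose surrounding ring is sufficiently covered by astrocyte (GFAP)
   signal.

Every size parameter is physical (um) so results are invariant to raster
resolution; blur/threshold/morphology settings are calibration choices
recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.morphology import closing as _morph_closing
from skimage.morphology import opening as _morph_opening

from .stack_io import Calibration, ZStack

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class DetectionParams:
    """All tunables of the counting algorithm.

    The classification rules carry the published constants: a 60% area
    overlap links blobs across layers, a longest diagonal strictly above
    6.5 um (over at least two linked layers) makes a cell, and NeuN
    fragments between 2.5 and 6.5 um ringed by GFAP make debris.  The
    preprocessing settings (blur, threshold block/offset, morphology
    radius) are declared calibration defaults, echoed into every result;
    the default blur sigma and threshold offset were fixed by a bead-style
    calibration (drawn disks of known diameter) so that measured Feret
    diameters are unbiased across the 2.5-15 um range.
    """

    blur_sigma_um: float = 0.6
    thresh_block_um: float = 30.0
    thresh_offset: float = 6.0
    thresh_method: str = "mean"  # "mean" or "gaussian" local reference
    morph_radius_um: float = 0.8
    apply_morphology: bool = True
    min_overlap_frac: float = 0.60
    min_cell_diag_um: float = 6.5
    debris_diag_um: tuple[float, float] = (2.5, 6.5)
    encircle_frac: float = 0.5
    ring_width_um: float = 1.0
    min_layer_support: int = 2
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_frac <= 1):
            raise ValueError("min_overlap_frac must lie in (0, 1]")
        if self.min_layer_support < 2:
            raise ValueError("min_layer_support must be >= 2")
        lo, hi = self.debris_diag_um
        if not (0 < lo < hi):
            raise ValueError("debris_diag_um must be an increasing positive interval")
        if hi != self.min_cell_diag_um:
            raise ValueError(
                "debris upper bound must equal the minimum cell diagonal"
            )
        for name in ("blur_sigma_um", "thresh_block_um", "morph_radius_um",
                     "ring_width_um", "min_cell_diag_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thresh_method not in ("mean", "gaussian"):
            raise ValueError("thresh_method must be 'mean' or 'gaussian'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["debris_diag_um"] = list(self.debris_diag_um)
        return d


# ---------------------------------------------------------------------------
# per-layer segmentation
# ---------------------------------------------------------------------------


def preprocess(layer: np.ndarray, calibration: Calibration,
               params: DetectionParams) -> np.ndarray:
    """Gaussian-blur one layer; sigma is physical and converted per axis."""
    if params.blur_sigma_um <= 0:
        raise ValueError("blur sigma must be positive")
    sigma = (params.blur_sigma_um / calibration.um_per_px_y,
             params.blur_sigma_um / calibration.um_per_px_x)
    return ndi.gaussian_filter(np.asarray(layer, dtype=float), sigma=sigma,
                               mode="reflect")


def _odd_block(size_um: float, um_per_px: float) -> int:
    n = int(round(size_um / um_per_px))
    if n % 2 == 0:
        n += 1
    return n


def threshold_layer(layer: np.ndarray, calibration: Calibration,
                    params: DetectionParams) -> np.ndarray:
    """Adaptive threshold: foreground iff pixel > local mean + offset.

    The local reference is the (uniform or Gaussian-weighted) mean over a
    ``thresh_block_um`` neighbourhood, converted to an odd pixel count per
    axis.  A constant raster therefore yields an empty mask for any positive
    offset, and a constant added to the whole image leaves the mask unchanged.
    """
    by = _odd_block(params.thresh_block_um, calibration.um_per_px_y)
    bx = _odd_block(params.thresh_block_um, calibration.um_per_px_x)
    if by < 3 or bx < 3:
        raise ValueError(
            f"threshold block {params.thresh_block_um} um is below 3 px "
            f"({by}x{bx}) at this calibration"
        )
    img = np.asarray(layer, dtype=float)
    if params.thresh_method == "mean":
        local = ndi.uniform_filter(img, size=(by, bx), mode="reflect")
    else:
        local = ndi.gaussian_filter(img, sigma=(by / 4.0, bx / 4.0), mode="reflect")
    return img > local + params.thresh_offset


def _elliptical_footprint(radius_um: float, calibration: Calibration) -> np.ndarray | None:
    ry = radius_um / calibration.um_per_px_y
    rx = radius_um / calibration.um_per_px_x
    ny, nx = int(ry), int(rx)
    if ny < 1 and nx < 1:
        return None
    yy, xx = np.mgrid[-ny:ny + 1, -nx:nx + 1]
    return (yy / max(ry, 1e-9)) ** 2 + (xx / max(rx, 1e-9)) ** 2 <= 1.0


def refine_mask(mask: np.ndarray, calibration: Calibration,
                params: DetectionParams) -> np.ndarray:
    """Morphological opening then closing with a physical disk element.

    The open-close composition is an idempotent morphological filter, so
    re-applying this function changes nothing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not params.apply_morphology:
        return mask.copy()
    fp = _elliptical_footprint(params.morph_radius_um, calibration)
    if fp is None:  # element degenerates to a single pixel: identity
        return mask.copy()
    return _morph_closing(_morph_opening(mask, fp), fp)


# ---------------------------------------------------------------------------
# blob extraction and measurement
# ---------------------------------------------------------------------------


@dataclass
class Blob:
    """One 8-connected foreground component of a single layer."""

    layer_index: int
    label: int
    coords: np.ndarray          # (n, 2) int (row, col) member pixels
    contour: np.ndarray         # (m, 2) float (row, col) traced outline
    area_um2: float
    feret_um: float
    centroid_um: tuple[float, float]  # (x_um, y_um)
    touches_border: bool
    lin: np.ndarray = field(repr=False, default=None)  # sorted ravelled indices
    shape: tuple[int, int] = (0, 0)

    @property
    def n_px(self) -> int:
        return len(self.coords)


def feret_diameter(points_um: np.ndarray) -> float:
    """Longest pairwise distance between contour points (in um).

    Uses the convex hull for large point sets; equals the brute-force
    pairwise maximum exactly.
    """
    pts = np.asarray(points_um, dtype=float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 40:
        uniq = np.unique(pts, axis=0)
        if len(uniq) >= 3 and not _collinear(uniq):
            pts = uniq[ConvexHull(uniq).vertices]
        else:
            pts = uniq
    diff = pts[:, np.newaxis, :] - pts[np.newaxis, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def _collinear(pts: np.ndarray) -> bool:
    if len(pts) <= 2:
        return True
    v = pts - pts[0]
    cross = v[1, 0] * v[1:, 1] - v[1, 1] * v[1:, 0]
    return bool(np.abs(cross).max() < 1e-12)


def _boundary_pixels(region_mask: np.ndarray) -> np.ndarray:
    """Pixels of a region having at least one 4-neighbour outside it."""
    interior = ndi.binary_erosion(region_mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), border_value=0)
    return np.argwhere(region_mask & ~interior)


def extract_blobs(mask: np.ndarray, calibration: Calibration,
                  exclude_border: bool = True, layer_index: int = 0) -> list[Blob]:
    """Trace 8-connected components into measured :class:`Blob` objects.

    Area is pixel count x pixel area; the Feret diameter is the maximum
    pairwise distance between boundary-pixel centres with per-axis um
    scaling.  Components touching the raster edge are flagged and, when
    ``exclude_border``, dropped (edge scatter is excluded from analysis).
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labelled = measure.label(mask, connectivity=2)
    ux, uy = calibration.um_per_px_x, calibration.um_per_px_y
    blobs: list[Blob] = []
    for region in measure.regionprops(labelled):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if touches and exclude_border:
            continue
        sub = labelled[r0:r1, c0:c1] == region.label
        boundary = _boundary_pixels(sub) + (r0, c0)
        pts_um = np.column_stack((boundary[:, 0] * uy, boundary[:, 1] * ux))
        # traced closed outline (sub-pixel) for QC overlays
        padded = np.pad(sub, 1)
        outlines = measure.find_contours(padded.astype(float), 0.5)
        contour = max(outlines, key=len) + (r0 - 1, c0 - 1)
        cy, cx = region.centroid
        coords = region.coords
        blobs.append(Blob(
            layer_index=layer_index,
            label=int(region.label),
            coords=coords,
            contour=contour,
            area_um2=float(region.area) * calibration.px_area_um2,
            feret_um=feret_diameter(pts_um),
            centroid_um=(cx * ux, cy * uy),
            touches_border=touches,
            lin=np.sort(coords[:, 0].astype(np.int64) * w + coords[:, 1]),
            shape=(h, w),
        ))
    return blobs


# ---------------------------------------------------------------------------
# cross-layer linking and classification
# ---------------------------------------------------------------------------


@dataclass
class CellTrack:
    """A maximal chain of blobs in strictly consecutive layers."""

    blobs: list[Blob]
    is_cell: bool | None = None

    @property
    def layer_indices(self) -> tuple[int, ...]:
        return tuple(b.layer_index for b in self.blobs)

    @property
    def layer_span(self) -> int:
        return len(self.blobs)

    @property
    def max_feret_um(self) -> float:
        return max(b.feret_um for b in self.blobs)

    @property
    def centroid_um(self) -> tuple[float, float]:
        rep = max(self.blobs, key=lambda b: b.area_um2)
        return rep.centroid_um


def overlap_fraction(a: Blob, b: Blob) -> float:
    """Shared pixel count divided by the smaller blob's pixel count."""
    if a.shape != b.shape:
        raise ValueError("blobs come from rasters of different dimensions")
    inter = len(np.intersect1d(a.lin, b.lin, assume_unique=True))
    return inter / min(a.n_px, b.n_px)


def link_layers(blobs_by_layer: dict[int, list[Blob]] | list[list[Blob]],
                params: DetectionParams) -> list[CellTrack]:
    """Greedily chain blobs across consecutive layers into tracks.

    Blob A in layer i links to blob B in layer i+1 iff their pixel overlap
    is at least ``min_overlap_frac`` of the smaller area.  Candidate links
    are taken largest-overlap first, ties broken by centroid distance; each
    blob gets at most one predecessor and one successor, so tracks are
    maximal chains.  Unlinked blobs become single-blob tracks.
    """
    if isinstance(blobs_by_layer, dict):
        layers = {k: list(v) for k, v in blobs_by_layer.items()}
    else:
        layers = {i: list(v) for i, v in enumerate(blobs_by_layer)}
    ids = [id(b) for lst in layers.values() for b in lst]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate blob identities passed to link_layers")

    successor: dict[int, Blob] = {}
    predecessor: dict[int, Blob] = {}
    for i in sorted(layers):
        if i + 1 not in layers:
            continue
        candidates = []
        for ai, a in enumerate(layers[i]):
            for bi, b in enumerate(layers[i + 1]):
                inter = len(np.intersect1d(a.lin, b.lin, assume_unique=True))
                if inter == 0:
                    continue
                frac = inter / min(a.n_px, b.n_px)
                if frac >= params.min_overlap_frac:
                    dist = float(np.hypot(a.centroid_um[0] - b.centroid_um[0],
                                          a.centroid_um[1] - b.centroid_um[1]))
                    candidates.append((-inter, dist, ai, bi, a, b))
        for _, _, _, _, a, b in sorted(candidates, key=lambda t: t[:4]):
            if id(a) in successor or id(b) in predecessor:
                continue
            successor[id(a)] = b
            predecessor[id(b)] = a

    tracks: list[CellTrack] = []
    for i in sorted(layers):
        for blob in layers[i]:
            if id(blob) in predecessor:
                continue  # not a chain head
            chain = [blob]
            while id(chain[-1]) in successor:
                chain.append(successor[id(chain[-1])])
            tracks.append(CellTrack(blobs=chain))
    return tracks


def classify_cells(tracks: list[CellTrack], params: DetectionParams) -> list[CellTrack]:
    """Mark tracks as cells: layer span >= support AND max Feret > 6.5 um.

    The Feret comparison is strict ("exceeded"), so a track whose longest
    diagonal is exactly the threshold is not a cell.  Each cell is one
    track, counted once regardless of how many layers it spans.
    """
    for t in tracks:
        t.is_cell = (t.layer_span >= params.min_layer_support
                     and t.max_feret_um > params.min_cell_diag_um)
    return tracks


# ---------------------------------------------------------------------------
# neuronal debris
# ---------------------------------------------------------------------------


@dataclass
class DebrisParticle:
    """A NeuN fragment candidate with its astrocyte-ring coverage."""

    blob: Blob
    encirclement: float
    accepted: bool


def _ring_coverage(blob: Blob, gfap_mask: np.ndarray, calibration: Calibration,
                   ring_width_um: float) -> float:
    """Fraction of the blob's surrounding ring covered by the GFAP mask.

    The ring is the blob dilated by ``ring_width_um`` (per-axis) minus the
    blob itself, evaluated on the same raster as the GFAP mask.
    """
    h, w = blob.shape
    if gfap_mask.shape != (h, w):
        raise ValueError("GFAP mask dimensions do not match the blob's raster")
    ry = max(1, int(round(ring_width_um / calibration.um_per_px_y)))
    rx = max(1, int(round(ring_width_um / calibration.um_per_px_x)))
    r0 = max(0, blob.coords[:, 0].min() - ry - 1)
    r1 = min(h, blob.coords[:, 0].max() + ry + 2)
    c0 = max(0, blob.coords[:, 1].min() - rx - 1)
    c1 = min(w, blob.coords[:, 1].max() + rx + 2)
    sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    sub[blob.coords[:, 0] - r0, blob.coords[:, 1] - c0] = True
    fp = _elliptical_footprint(ring_width_um, calibration)
    if fp is None:
        fp = np.ones((3, 3), dtype=bool)
    ring = ndi.binary_dilation(sub, structure=fp) & ~sub
    n_ring = int(ring.sum())
    if n_ring == 0:
        return 0.0
    return float((gfap_mask[r0:r1, c0:c1] & ring).sum()) / n_ring


def detect_debris(neun_blobs: list[Blob] | list[list[Blob]],
                  gfap_masks: np.ndarray | list[np.ndarray],
                  cell_tracks: list[CellTrack],
                  params: DetectionParams,
                  calibration: Calibration) -> list[DebrisParticle]:
    """Classify NeuN fragments as neuronal debris.

    A candidate is a NeuN blob whose Feret diameter lies in the closed
    debris interval and which is not part of any cell track; it is accepted
    when at least ``encircle_frac`` of its surrounding ring is covered by
    GFAP signal of the same layer.  Candidates belonging to the same
    (non-cell) track are collapsed to one particle — the blob with the
    highest encirclement — so a fragment segmented in two adjacent layers
    is never counted twice.
    """
    if isinstance(gfap_masks, np.ndarray) and gfap_masks.ndim == 2:
        gfap_by_layer = {0: gfap_masks}
    else:
        gfap_by_layer = {i: m for i, m in enumerate(gfap_masks)}

    cell_blob_ids = {id(b) for t in cell_tracks if t.is_cell for b in t.blobs}
    blob_to_track = {id(b): t for t in cell_tracks for b in t.blobs}

    flat: list[Blob] = []
    for item in neun_blobs:
        flat.extend(item) if isinstance(item, list) else flat.append(item)

    lo, hi = params.debris_diag_um
    per_track: dict[int, DebrisParticle] = {}
    loose: list[DebrisParticle] = []
    for blob in flat:
        if id(blob) in cell_blob_ids:
            continue
        if not (lo <= blob.feret_um <= hi):
            continue
        gmask = gfap_by_layer.get(blob.layer_index)
        if gmask is None:
            raise ValueError(f"no GFAP mask for layer {blob.layer_index}")
        cov = _ring_coverage(blob, np.asarray(gmask, dtype=bool), calibration,
                             params.ring_width_um)
        particle = DebrisParticle(blob=blob, encirclement=cov,
                                  accepted=cov >= params.encircle_frac)
        track = blob_to_track.get(id(blob))
        if track is None:
            loose.append(particle)
        else:
            best = per_track.get(id(track))
            if best is None or particle.encirclement > best.encirclement:
                per_track[id(track)] = particle
    return loose + list(per_track.values())


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class DetectionResult:
    channel: str
    tracks: list[CellTrack]
    debris: list[DebrisParticle]
    blobs_by_layer: dict[int, list[Blob]]
    masks: np.ndarray           # refined binary masks, (layers, H, W)
    params: DetectionParams

    @property
    def cells(self) -> list[CellTrack]:
        return [t for t in self.tracks if t.is_cell]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def accepted_debris(self) -> list[DebrisParticle]:
        return [d for d in self.debris if d.accepted]

    @property
    def n_debris(self) -> int:
        return len(self.accepted_debris)

    def cell_contours(self) -> list[np.ndarray]:
        return [b.contour for t in self.cells for b in t.blobs]


def segment_channel(stack: ZStack, channel: str,
                    params: DetectionParams) -> np.ndarray:
    """Blur + adaptive-threshold + morphology for every layer of a channel."""
    cal = stack.calibration
    masks = [
        refine_mask(threshold_layer(preprocess(layer, cal, params), cal, params),
                    cal, params)
        for layer in stack.channel(channel)
    ]
    return np.stack(masks)


def run_detector(stack: ZStack, channel: str = "NeuN",
                 params: DetectionParams | None = None,
                 gfap_channel: str | None = "GFAP") -> DetectionResult:
    """Run the full counting pipeline on one channel of a calibrated stack.

    Composition: preprocess -> threshold -> refine -> extract -> link ->
    classify; debris detection additionally runs when a GFAP channel is
    supplied (meaningful for the NeuN channel).  Deterministic for fixed
    inputs and parameters.
    """
    params = params or DetectionParams()
    cal = stack.calibration
    masks = segment_channel(stack, channel, params)
    blobs_by_layer = {
        i: extract_blobs(masks[i], cal, exclude_border=params.exclude_border,
                         layer_index=i)
        for i in range(stack.n_layers)
    }
    tracks = classify_cells(link_layers(blobs_by_layer, params), params)

    debris: list[DebrisParticle] = []
    if gfap_channel is not None and gfap_channel in stack.channels:
        gfap_masks = segment_channel(stack, gfap_channel, params)
        debris = detect_debris(list(blobs_by_layer.values()), gfap_masks,
                               tracks, params, cal)
    return DetectionResult(channel=channel, tracks=tracks, debris=debris,
                           blobs_by_layer=blobs_by_layer, masks=masks,
                           params=params)
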