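"""Synthetic calibrated 3-channel z-stacks with exported ground truth.

The generator emulates the imaging substrate the counting pipeline was built
for: hippocampal ROIs of 600 x 400 um rasterised at 1024 x 1024 px (hence
anisotropic pixels), three z-layers 5 um apart, and three stains —

* NeuN: bright neuronal somata, modelled as spheres sampled by the z planes
  (per-layer disk radius from chord geometry), so each soma spans at least
  two consecutive layers with concentric, shrinking cross-sections — exactly
  the situation the 60% cross-layer overlap rule has to handle.  Optionally a
  dense pyramidal band, and small sub-somatic NeuN fragments (debris).
* GFAP: astrocyte somata with straight radiating processes, plus an annulus
  of signal painted around each true debris fragment at a configurable arc
  coverage, making the "encircled" predicate satisfiable by construction.
  Decoy fragments get no annulus.
* IBA1: small microglial somata with thin processes.

A planar background gradient plus additive Gaussian noise is applied last
(optional Poisson shot noise, off by default); the gradient is steep enough
to defeat a single global threshold, which is what motivates adaptive
thresholding.  Ground truth (object lists and per-channel binary masks) is
recorded before noise.  Identical spec + seed gives bit-identical output.

Photometric defaults (object amplitude ~15 over a background of 20 with
noise SD 4) were fixed by a pre-build calibration so that the adaptive
threshold (local mean + 5) cuts object profiles near half-maximum, keeping
measured Feret diameters close to the drawn ones; they are generator
properties, not facts about any particular microscope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .stack_io import (CHANNELS, Calibration, ZStack, write_calibration,
                       write_stack)


class PlacementError(RuntimeError):
    """The requested object count cannot be placed without overcrowding."""


@dataclass(frozen=True)
class BandSpec:
    """Geometry of the simulated pyramidal cell layer (a horizontal stripe)."""

    center_um: float = 200.0       # y of the band axis
    thickness_um: float = 60.0
    angle_deg: float = 0.0         # reserved; generator draws at 0 deg
    relative_amplitude: float = 1.0  # band brightness / object amplitude


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic ROI scene."""

    roi_width_um: float = 600.0
    roi_height_um: float = 400.0
    px_per_um_x: float = 1024.0 / 600.0
    px_per_um_y: float = 1024.0 / 400.0
    n_layers: int = 3
    z_step_um: float = 5.0

    n_neurons: int = 25
    soma_diameter_um: tuple[float, float] = (8.0, 15.0)
    n_astrocytes: int = 8
    n_microglia: int = 10
    n_debris: int = 15
    debris_diameter_um: tuple[float, float] = (2.5, 6.5)
    n_debris_decoys: int = 10
    debris_ring_coverage: float = 0.8
    debris_ring_width_um: float = 2.5

    band: BandSpec | None = None

    background_offset: float = 20.0
    background_gradient: float = 10.0
    object_amplitude: float = 15.0
    noise_sd: float = 4.0
    poisson_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_neurons, self.n_astrocytes, self.n_microglia,
                  self.n_debris, self.n_debris_decoys)
        if any(c < 0 for c in counts):
            raise ValueError("object counts must be non-negative")
        sizes = (self.roi_width_um, self.roi_height_um, self.px_per_um_x,
                 self.px_per_um_y, self.z_step_um, self.object_amplitude)
        if any(s <= 0 for s in sizes):
            raise ValueError("physical sizes must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.debris_diameter_um[1] > self.soma_diameter_um[0]:
            raise ValueError(
                "debris upper bound must not exceed the smallest soma diameter"
            )
        if self.n_layers < 2:
            raise ValueError("need at least two layers for cross-layer linking")

    @property
    def calibration(self) -> Calibration:
        return Calibration(um_per_px_x=1.0 / self.px_per_um_x,
                           um_per_px_y=1.0 / self.px_per_um_y,
                           z_step_um=self.z_step_um)

    @property
    def shape_px(self) -> tuple[int, int]:
        return (int(round(self.roi_height_um * self.px_per_um_y)),
                int(round(self.roi_width_um * self.px_per_um_x)))

    @property
    def area_mm2(self) -> float:
        return self.roi_width_um * self.roi_height_um / 1.0e6


@dataclass
class TruthObject:
    """One ground-truth object: physical centre, drawn size, layer span."""

    kind: str                   # neuron | astrocyte | microglia | debris | debris_decoy
    x_um: float
    y_um: float
    diameter_um: float
    layers: tuple[int, ...]
    per_layer_diameter_um: tuple[float, ...] = ()


@dataclass
class GroundTruth:
    """Everything the generator drew, recorded before noise was applied."""

    objects: list[TruthObject] = field(default_factory=list)
    band_polygon_um: list[tuple[float, float]] | None = None
    band_thickness_um: float | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # channel -> (L,H,W) bool

    def of_kind(self, kind: str) -> list[TruthObject]:
        return [o for o in self.objects if o.kind == kind]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.objects:
            out[o.kind] = out.get(o.kind, 0) + 1
        return out

    def to_rows(self) -> list[dict]:
        return [
            {"class": o.kind, "x_um": round(o.x_um, 3), "y_um": round(o.y_um, 3),
             "diameter_um": round(o.diameter_um, 3),
             "layer_span": "-".join(str(i) for i in o.layers)}
            for o in self.objects
        ]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


class _Placer:
    """Rejection-sampling placement with pairwise exclusion radii."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator,
                 clearance_um: float = 3.0, border_margin_um: float = 4.0,
                 max_tries: int = 4000):
        self.spec = spec
        self.rng = rng
        self.clearance = clearance_um
        self.margin = border_margin_um
        self.max_tries = max_tries
        self.placed: list[tuple[float, float, float]] = []  # x, y, radius
        if spec.band is not None:
            self.band_lo = spec.band.center_um - spec.band.thickness_um / 2
            self.band_hi = spec.band.center_um + spec.band.thickness_um / 2
        else:
            self.band_lo = self.band_hi = None

    def place(self, extent_radius_um: float) -> tuple[float, float]:
        s = self.spec
        m = extent_radius_um + self.margin
        if s.roi_width_um <= 2 * m or s.roi_height_um <= 2 * m:
            raise PlacementError("object extent exceeds the ROI")
        for _ in range(self.max_tries):
            x = self.rng.uniform(m, s.roi_width_um - m)
            y = self.rng.uniform(m, s.roi_height_um - m)
            if self.band_lo is not None and (
                    self.band_lo - extent_radius_um - self.clearance < y
                    < self.band_hi + extent_radius_um + self.clearance):
                continue
            ok = all(np.hypot(x - px, y - py)
                     >= extent_radius_um + pr + self.clearance
                     for px, py, pr in self.placed)
            if ok:
                self.placed.append((x, y, extent_radius_um))
                return x, y
        raise PlacementError(
            f"could not place an object of radius {extent_radius_um:.1f} um; "
            "the scene specification is over-crowded"
        )


# ---------------------------------------------------------------------------
# rasterisation helpers (all take um coordinates)
# ---------------------------------------------------------------------------


def _paint_disk(img: np.ndarray, spec: SceneSpec, x_um: float, y_um: float,
                diameter_um: float, amplitude: float) -> None:
    r = y_um * spec.px_per_um_y
    c = x_um * spec.px_per_um_x
    ry = diameter_um / 2 * spec.px_per_um_y
    rx = diameter_um / 2 * spec.px_per_um_x
    rr, cc = draw_ellipse(r, c, max(ry, 0.8), max(rx, 0.8), shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], amplitude)


def _paint_segment(img: np.ndarray, spec: SceneSpec, x0: float, y0: float,
                   x1: float, y1: float, amplitude: float,
                   thick: bool = False) -> None:
    h, w = img.shape
    r0 = int(np.clip(round(y0 * spec.px_per_um_y), 0, h - 1))
    c0 = int(np.clip(round(x0 * spec.px_per_um_x), 0, w - 1))
    r1 = int(np.clip(round(y1 * spec.px_per_um_y), 0, h - 1))
    c1 = int(np.clip(round(x1 * spec.px_per_um_x), 0, w - 1))
    rr, cc = draw_line(r0, c0, r1, c1)
    img[rr, cc] = np.maximum(img[rr, cc], amplitude)
    if thick:  # widen to ~2 px so thin processes survive blurring
        rr2 = np.clip(rr + 1, 0, h - 1)
        img[rr2, cc] = np.maximum(img[rr2, cc], amplitude)
        cc2 = np.clip(cc + 1, 0, w - 1)
        img[rr, cc2] = np.maximum(img[rr, cc2], amplitude)


def _paint_annulus_arcs(img: np.ndarray, spec: SceneSpec, x_um: float,
                        y_um: float, r_in_um: float, r_out_um: float,
                        coverage: float, amplitude: float,
                        rng: np.random.Generator) -> None:
    """Paint an annulus with ``coverage`` fraction of its angular extent."""
    h, w = img.shape
    pad = r_out_um + 1.0
    r0 = int(max(0, (y_um - pad) * spec.px_per_um_y))
    r1 = int(min(h, (y_um + pad) * spec.px_per_um_y + 2))
    c0 = int(max(0, (x_um - pad) * spec.px_per_um_x))
    c1 = int(min(w, (x_um + pad) * spec.px_per_um_x + 2))
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    yy = rows[:, None] / spec.px_per_um_y - y_um
    xx = cols[None, :] / spec.px_per_um_x - x_um
    rad = np.hypot(yy, xx)
    ring = (rad >= r_in_um) & (rad <= r_out_um)
    if coverage < 1.0:
        gap_start = rng.uniform(0, 2 * np.pi)
        gap_len = 2 * np.pi * (1.0 - coverage)
        ang = np.mod(np.arctan2(yy, xx) - gap_start, 2 * np.pi)
        ring &= ang >= gap_len
    sub = img[r0:r1, c0:c1]
    sub[ring] = np.maximum(sub[ring], amplitude)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _sphere_layer_diameters(diameter_um: float, z_center_um: float,
                            z_planes_um: np.ndarray) -> list[tuple[int, float]]:
    """Chord diameters where the z planes cut a sphere; empty cuts omitted."""
    r = diameter_um / 2
    out = []
    for k, z in enumerate(z_planes_um):
        dz = abs(z - z_center_um)
        if dz < r:
            out.append((k, 2.0 * float(np.sqrt(r * r - dz * dz))))
    return out


def _sample_soma_z(rng: np.random.Generator, radius_um: float,
                   z_planes_um: np.ndarray, z_step: float) -> float:
    """Pick a sphere centre depth so the soma is countable by construction.

    Constraints: the nearest plane cuts a chord comfortably above the 6.5 um
    cell threshold, and a second plane is also cut (>= 2-layer support).
    """
    mid = z_planes_um[len(z_planes_um) // 2]
    margin_half = 3.7  # nearest-plane chord radius >= 3.7 um -> diameter >= 7.4
    hi = min(z_step / 2, float(np.sqrt(max(radius_um ** 2 - margin_half ** 2, 0.0))))
    lo = max(0.0, z_step - radius_um + 0.3)
    if hi <= lo:  # small soma: place as close to a plane as support allows
        lo, hi = max(0.0, z_step - radius_um + 0.3), max(hi, z_step - radius_um + 0.4)
    delta = rng.uniform(lo, hi)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return float(mid + sign * delta)


def generate_scene(spec: SceneSpec) -> tuple[ZStack, GroundTruth]:
    """Render a complete scene and its ground truth.

    Raises :class:`PlacementError` when the requested object counts cannot
    be placed with the generator's exclusion radii (over-crowded spec).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    L = spec.n_layers
    amp = spec.object_amplitude

    signal = np.zeros((L, len(CHANNELS), h, w), dtype=float)
    neun, gfap, iba1 = signal[:, 0], signal[:, 1], signal[:, 2]
    truth = GroundTruth(masks={})
    z_planes = (np.arange(L) + 0.5) * spec.z_step_um
    placer = _Placer(spec, rng)

    # --- pyramidal band (drawn first; other objects avoid it) -------------
    if spec.band is not None:
        b = spec.band
        lo_px = int(round((b.center_um - b.thickness_um / 2) * spec.px_per_um_y))
        hi_px = int(round((b.center_um + b.thickness_um / 2) * spec.px_per_um_y))
        lo_px, hi_px = max(lo_px, 0), min(hi_px, h)
        # rendered confluent: somata in the stratum pyramidale are packed
        # beyond single-cell resolution, so the band reads as one envelope
        band_amp = amp * b.relative_amplitude
        for k in range(L):
            neun[k, lo_px:hi_px, :] = band_amp
        truth.band_polygon_um = [
            (0.0, b.center_um - b.thickness_um / 2),
            (spec.roi_width_um, b.center_um - b.thickness_um / 2),
            (spec.roi_width_um, b.center_um + b.thickness_um / 2),
            (0.0, b.center_um + b.thickness_um / 2),
        ]
        truth.band_thickness_um = b.thickness_um

    # --- astrocytes (largest exclusion first) ------------------------------
    for _ in range(spec.n_astrocytes):
        soma_d = rng.uniform(6.0, 8.0)
        n_proc = rng.integers(4, 7)
        proc_len = rng.uniform(14.0, 24.0, size=n_proc)
        x, y = placer.place(float(proc_len.max()) + soma_d / 2)
        k0 = int(rng.integers(0, L - 1))
        angles = rng.uniform(0, 2 * np.pi, size=n_proc)
        for k in (k0, k0 + 1):
            _paint_disk(gfap[k], spec, x, y, soma_d, amp)
            for ang, ln in zip(angles, proc_len):
                _paint_segment(gfap[k], spec, x, y,
                               x + ln * np.cos(ang), y + ln * np.sin(ang),
                               amp, thick=True)
        truth.objects.append(TruthObject("astrocyte", x, y, soma_d, (k0, k0 + 1)))

    # --- neurons as z-sampled spheres --------------------------------------
    for _ in range(spec.n_neurons):
        d = rng.uniform(*spec.soma_diameter_um)
        x, y = placer.place(d / 2)
        zc = _sample_soma_z(rng, d / 2, z_planes, spec.z_step_um)
        cuts = _sphere_layer_diameters(d, zc, z_planes)
        cuts = [(k, cd) for k, cd in cuts if cd >= 1.5]  # sub-pixel slivers
        for k, chord_d in cuts:
            _paint_disk(neun[k], spec, x, y, chord_d, amp)
        truth.objects.append(TruthObject(
            "neuron", x, y, d, tuple(k for k, _ in cuts),
            tuple(round(cd, 3) for _, cd in cuts)))

    # --- microglia ---------------------------------------------------------
    for _ in range(spec.n_microglia):
        soma_d = rng.uniform(4.5, 6.0)
        n_proc = rng.integers(3, 6)
        proc_len = rng.uniform(8.0, 13.0, size=n_proc)
        x, y = placer.place(float(proc_len.max()) + soma_d / 2)
        k0 = int(rng.integers(0, L - 1))
        angles = rng.uniform(0, 2 * np.pi, size=n_proc)
        for k in (k0, k0 + 1):
            _paint_disk(iba1[k], spec, x, y, soma_d, amp)
            for ang, ln in zip(angles, proc_len):
                _paint_segment(iba1[k], spec, x, y,
                               x + ln * np.cos(ang), y + ln * np.sin(ang),
                               amp, thick=True)
        truth.objects.append(TruthObject("microglia", x, y, soma_d, (k0, k0 + 1)))

    # --- debris: NeuN fragments ringed by GFAP; decoys without a ring ------
    for kind, count in (("debris", spec.n_debris),
                        ("debris_decoy", spec.n_debris_decoys)):
        for _ in range(count):
            d = rng.uniform(*spec.debris_diameter_um)
            x, y = placer.place(d / 2 + spec.debris_ring_width_um + 1.0)
            k = int(rng.integers(0, L))
            _paint_disk(neun[k], spec, x, y, d, amp)
            if kind == "debris":
                _paint_annulus_arcs(
                    gfap[k], spec, x, y, d / 2 + 0.2,
                    d / 2 + 0.2 + spec.debris_ring_width_um,
                    spec.debris_ring_coverage, amp, rng)
            truth.objects.append(TruthObject(kind, x, y, d, (k,)))

    # --- ground-truth masks, then background + noise -----------------------
    for ci, name in enumerate(CHANNELS):
        truth.masks[name] = signal[:, ci] > 0

    gx, gy = rng.uniform(-1, 1, size=2)
    norm = max(np.hypot(gx, gy), 1e-9)
    gx, gy = gx / norm, gy / norm
    cols = np.arange(w) / max(w - 1, 1)
    rows = np.arange(h) / max(h - 1, 1)
    plane = spec.background_gradient * (gx * cols[None, :] + gy * rows[:, None]
                                        - min(gx, 0) - min(gy, 0))
    data = signal + spec.background_offset + plane[None, None, :, :]
    if spec.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0, None).astype(np.float32)

    stack = ZStack(data=data, channels=CHANNELS, calibration=spec.calibration,
                   provenance={"synthetic_seed": spec.seed})
    return stack, truth


def ground_truth_density(truth: GroundTruth, spec: SceneSpec) -> dict[str, float]:
    """Objects per mm^2 for each ground-truth class (exact arithmetic)."""
    area = spec.area_mm2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    return {kind: count / area for kind, count in truth.counts().items()}


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------


def save_scene(stack: ZStack, truth: GroundTruth, spec: SceneSpec,
               outdir: str | Path) -> dict[str, Path]:
    """Write stack (TIFF + calibration sidecar), truth CSV and truth masks."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": write_stack(stack, outdir / "stack.tiff",
                             sidecar=outdir / "calibration.yaml"),
        "truth": outdir / "ground_truth.csv",
        "masks": outdir / "truth_masks.tiff",
        "spec": outdir / "scene.yaml",
    }
    rows = truth.to_rows()
    with open(paths["truth"], "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["class", "x_um", "y_um", "diameter_um", "layer_span"])
        writer.writeheader()
        writer.writerows(rows)
    mask_arr = np.stack([truth.masks[c] for c in CHANNELS], axis=1)
    tifffile.imwrite(paths["masks"], mask_arr.astype(np.uint8),
                     metadata={"axes": "ZCYX", "channels": list(CHANNELS)})
    d = asdict(spec)
    d["band"] = asdict(spec.band) if spec.band is not None else None
    d["soma_diameter_um"] = list(spec.soma_diameter_um)
    d["debris_diameter_um"] = list(spec.debris_diameter_um)
    Path(paths["spec"]).write_text(yaml.safe_dump(d))
    return paths


def load_scene_spec(path: str | Path) -> SceneSpec:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("band"):
        d["band"] = BandSpec(**d["band"])
    for key in ("soma_diameter_um", "debris_diameter_um"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneSpec(**d)
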