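"""Synthesis of the 64-shape stimulus set (4 groups x 8 pairs x 2 members).

The set mirrors the structure of classic abstract-shape experiments on
inferotemporal cortex:

* **R** — Regular shapes with at least one axis of symmetry; the two members of
  a pair differ in a single non-accidental property (NAP), e.g. parallel vs
  non-parallel sides or straight vs curved contour.
* **ISC** — Irregular Simple Curved shapes, built from radial Fourier boundary
  descriptors r(theta) = r0 + sum_k a_k cos(f_k theta + phi_k); pair members
  differ in a metric property (phase, frequency or amplitude of the
  descriptors).
* **ISS** — Irregular Simple Straight shapes, derived from ISC contours by
  replacing the curves with straight segments through the curvature extrema
  (a NAP change that preserves the overall shape).
* **IC** — Irregular Complex shapes, made by increasing the number and
  frequency of the boundary descriptors.

Within each of the 8 columns the 4 pairs are matched in overall area and
aspect ratio, and the average within-pair pixel graylevel difference is
balanced across groups by :func:`balance_pixel_differences`. Shapes render as
binary silhouettes (uniform fill on a gray background), which is also what an
image-computable model would be shown.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

GROUPS = ("R", "IC", "ISC", "ISS")
MEMBERS = ("a", "b")

# ---------------------------------------------------------------------------
# domain types


@dataclass
class ContourDescriptor:
    """Radial Fourier boundary descriptor about the centroid."""

    base_radius: float
    harmonics: list[tuple[int, float, float]]  # (frequency, amplitude, phase)
    family: str = "irregular"

    def __post_init__(self):
        freqs = [f for f, _, _ in self.harmonics]
        if any(f <= 0 for f in freqs):
            raise ValueError("harmonic frequencies must be strictly positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("harmonic frequencies must be unique")
        if any(a < 0 for _, a, _ in self.harmonics):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.full_like(np.asarray(theta, dtype=float), self.base_radius)
        for f, a, p in self.harmonics:
            r = r + a * np.cos(f * np.asarray(theta) + p)
        return r

    @property
    def max_frequency(self) -> int:
        return max((f for f, _, _ in self.harmonics), default=0)


@dataclass
class ContourShape:
    """Closed polyline (first vertex implicitly follows the last)."""

    vertices: np.ndarray  # (N, 2), ordered
    boundary_style: str  # "curved" | "straight"
    group: str = "ISC"
    pair_index: int = 1
    member: str = "a"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValueError("a contour needs at least 3 vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon().area)

    def is_simple(self) -> bool:
        p = self.polygon()
        return p.is_valid and p.area > 0


@dataclass
class StimulusImage:
    """Binary grayscale rendering of one shape."""

    pixels: np.ndarray  # uint8, origin top-left, row-major
    canvas_size: int
    background_level: int
    fill_level: int
    scale_factor: float = 1.0


@dataclass
class Stimulus:
    stimulus_id: str
    group: str
    pair_index: int
    member: str
    shape: ContourShape
    image: StimulusImage
    descriptor: ContourDescriptor | None = None


@dataclass
class StimulusConfig:
    """Generator settings; defaults give a 96-px canvas with shapes spanning
    ~60% of the canvas height (the on-screen size stand-in)."""

    canvas_size: int = 96
    background_level: int = 128
    fill_level: int = 255
    scale_factor: float = 1.0
    n_vertices: int = 512
    base_radius: float = 1.0
    # per-group magnitude of the a->b difference (the balancing knob)
    group_magnitudes: dict = field(
        default_factory=lambda: {"R": 1.0, "IC": 1.0, "ISC": 1.0, "ISS": 1.0}
    )
    perturb_modes: dict = field(
        default_factory=lambda: {"IC": "amplitude", "ISC": "phase", "ISS": "phase"}
    )
    # ISC descriptors: harmonic count and frequency band
    isc_harmonics: tuple = (3, 5)
    isc_max_frequency: int = 6
    ic_added_harmonics: int = 4
    ic_max_frequency: int = 12
    # column matching targets as fractions of canvas^2 (area) and w/h (aspect)
    area_fraction_range: tuple = (0.09, 0.13)
    aspect_range: tuple = (0.8, 1.25)
    matching_tolerance: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["isc_harmonics"] = list(self.isc_harmonics)
        d["area_fraction_range"] = list(self.area_fraction_range)
        d["aspect_range"] = list(self.aspect_range)
        return d


@dataclass
class ShapeSet:
    stimuli: list[Stimulus]
    column_matching: dict  # pair_index -> {"area": ..., "aspect": ...}
    config: StimulusConfig
    seed: int
    balance_report: dict | None = None

    def __post_init__(self):
        labels = {(s.group, s.pair_index, s.member) for s in self.stimuli}
        expected = {(g, j, m) for g in GROUPS for j in range(1, 9) for m in MEMBERS}
        if labels != expected:
            raise ValueError("shape set must contain exactly 4 groups x 8 pairs x 2 members")

    def ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    def images(self) -> list[StimulusImage]:
        return [s.image for s in self.stimuli]

    def get(self, group: str, pair_index: int, member: str) -> Stimulus:
        for s in self.stimuli:
            if (s.group, s.pair_index, s.member) == (group, pair_index, member):
                return s
        raise KeyError(f"no stimulus {group}{pair_index:02d}{member}")


def stimulus_id(group: str, pair_index: int, member: str) -> str:
    return f"{group}{pair_index:02d}{member}"


# ---------------------------------------------------------------------------
# contour construction


def make_irregular_contour(descriptor: ContourDescriptor, n_vertices: int = 512,
                           seed: int = 0) -> ContourShape:
    """Sample the descriptor at uniform polar angle into a closed polyline.

    The construction is deterministic given the descriptor; the seed is part
    of the operation signature for provenance but does not affect sampling.
    Rejects descriptors whose radius is not strictly positive or whose contour
    self-intersects (amplitude too large for the base radius).
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = descriptor.radius(theta)
    if np.any(r <= 0):
        raise ValueError("descriptor radius is non-positive for some angle")
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    shape = ContourShape(verts, "curved")
    if not shape.is_simple():
        raise ValueError("descriptor yields a self-intersecting contour")
    return shape


def complexify(descriptor: ContourDescriptor, added_harmonics: int,
               max_frequency: int, seed: int = 0) -> ContourDescriptor:
    """Add higher-frequency harmonics, increasing boundary complexity.

    New frequencies are drawn above the current maximum and at most
    ``max_frequency``; amplitudes shrink with frequency (a_f ~ 0.5 r0 / f) so
    the contour stays simple. If positivity fails, the new amplitudes are
    halved a few times before giving up.
    """
    if added_harmonics < 1:
        raise ValueError("added_harmonics must be >= 1")
    prior_max = descriptor.max_frequency
    if max_frequency <= prior_max:
        raise ValueError("max_frequency must exceed the existing maximum frequency")
    slots = list(range(prior_max + 1, max_frequency + 1))
    if len(slots) < added_harmonics:
        raise ValueError("not enough frequency slots below max_frequency")
    rng = np.random.default_rng(seed)
    freqs = sorted(rng.choice(slots, size=added_harmonics, replace=False).tolist())
    scale = 1.0
    for _ in range(6):
        new = [
            (int(f),
             scale * 0.5 * descriptor.base_radius / f * rng.uniform(0.7, 1.0),
             float(rng.uniform(0, 2 * np.pi)))
            for f in freqs
        ]
        cand = ContourDescriptor(descriptor.base_radius,
                                 list(descriptor.harmonics) + new,
                                 family="irregular")
        theta = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
        if np.all(cand.radius(theta) > 0.05 * descriptor.base_radius):
            try:
                make_irregular_contour(cand, 512)
            except ValueError:
                scale *= 0.5
                continue
            return cand
        scale *= 0.5
    raise ValueError("could not satisfy contour positivity after amplitude rescaling")


def perturb_pair(descriptor: ContourDescriptor, mode: str, magnitude: float,
                 seed: int = 0) -> ContourDescriptor:
    """Derive the b-member descriptor by changing one parameter class only.

    ``phase``: each phase shifts by +-magnitude * U(0.5, 1) radians.
    ``amplitude``: each amplitude scales by 1 +- magnitude * U(0.5, 1)
    (kept non-negative). ``frequency``: one harmonic's frequency shifts by
    max(1, round(magnitude)) steps, keeping uniqueness.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    if mode not in ("phase", "frequency", "amplitude"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    harmonics = [list(h) for h in descriptor.harmonics]
    if mode == "phase":
        for h in harmonics:
            h[2] = float(h[2] + magnitude * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0]))
    elif mode == "amplitude":
        for h in harmonics:
            factor = 1.0 + magnitude * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            h[1] = float(max(0.0, h[1] * factor))
    else:  # frequency
        step = max(1, int(round(magnitude)))
        used = {h[0] for h in harmonics}
        order = rng.permutation(len(harmonics))
        for k in order:
            for delta in (step, -step):
                f_new = harmonics[k][0] + delta
                if f_new >= 1 and f_new not in used:
                    used.discard(harmonics[k][0])
                    harmonics[k][0] = int(f_new)
                    used.add(f_new)
                    break
            else:
                continue
            break
        else:
            raise ValueError("no admissible frequency shift found")
    out = ContourDescriptor(descriptor.base_radius,
                            [tuple(h) for h in harmonics], descriptor.family)
    theta = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    if np.any(out.radius(theta) <= 0):
        raise ValueError("perturbation violates contour positivity")
    return out


# ---------------------------------------------------------------------------
# curvature and straightening


def discrete_curvature(vertices: np.ndarray) -> np.ndarray:
    """Signed discrete curvature (turn angle / local arc length) of a closed polyline."""
    v = np.asarray(vertices, dtype=float)
    e_prev = v - np.roll(v, 1, axis=0)
    e_next = np.roll(v, -1, axis=0) - v
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    dot = (e_prev * e_next).sum(axis=1)
    turn = np.arctan2(cross, dot)
    ds = 0.5 * (np.linalg.norm(e_prev, axis=1) + np.linalg.norm(e_next, axis=1))
    return turn / np.where(ds == 0, 1.0, ds)


def _circular_smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    xp = np.concatenate([x[-window:], x, x[:window]])
    sm = np.convolve(xp, kernel, mode="same")
    return sm[window:-window]


def curvature_extrema(vertices: np.ndarray, prominence: float = 0.05) -> np.ndarray:
    """Indices of isolated local extrema of smoothed discrete curvature.

    A flat (constant-curvature) contour such as a circle has no isolated
    extrema and yields an empty result.
    """
    kappa = discrete_curvature(vertices)
    n = len(kappa)
    kappa = _circular_smooth(kappa, max(3, n // 128))
    span = float(kappa.max() - kappa.min())
    if span < 1e-9 * (1.0 + abs(kappa).max()):
        return np.array([], dtype=int)
    prev = np.roll(kappa, 1)
    nxt = np.roll(kappa, -1)
    is_max = (kappa > prev) & (kappa >= nxt)
    is_min = (kappa < prev) & (kappa <= nxt)
    cand = np.where(is_max | is_min)[0]
    # keep alternating extrema with sufficient prominence
    keep = [i for i in cand if True]
    vals = kappa[cand]
    strong = cand[np.abs(vals - np.median(kappa)) >= 0.0]
    # prominence filter: difference to neighbouring candidate values
    out = []
    m = len(cand)
    for idx in range(m):
        i = cand[idx]
        j_prev = cand[(idx - 1) % m]
        j_next = cand[(idx + 1) % m]
        if min(abs(kappa[i] - kappa[j_prev]), abs(kappa[i] - kappa[j_next])) >= prominence * span:
            out.append(i)
    return np.asarray(sorted(out), dtype=int)


def straighten_contour(shape: ContourShape) -> ContourShape:
    """Replace curves by straight chords through the curvature extrema.

    The retained vertices are exactly the curvature-extremum points of the
    input, preserving the overall shape. Identity on an already-straight
    contour (so the operation is idempotent). Fewer than 3 isolated extrema
    (e.g. a circle) is an error: no polygon can be formed.
    """
    if shape.boundary_style == "straight":
        return copy.deepcopy(shape)
    idx = curvature_extrema(shape.vertices)
    if len(idx) < 3:
        raise ValueError("fewer than 3 curvature extrema; cannot straighten")
    verts = shape.vertices[idx]
    out = ContourShape(verts, "straight", shape.group, shape.pair_index, shape.member)
    if not out.is_simple():
        raise ValueError("straightened contour is self-intersecting")
    return out


# ---------------------------------------------------------------------------
# regular shapes

_REGULAR_KINDS = ("parallel_sides", "nonparallel_sides", "straight_contour",
                  "curved_contour")


def _densify(corners: np.ndarray, n_vertices: int) -> np.ndarray:
    """Resample a corner polygon to ~n_vertices points, uniform per edge."""
    m = len(corners)
    per_edge = max(2, int(np.ceil(n_vertices / m)))
    pts = []
    for k in range(m):
        a, b = corners[k], corners[(k + 1) % m]
        t = np.linspace(0, 1, per_edge, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def _bulge_edges(corners: np.ndarray, bulge: float, n_vertices: int) -> np.ndarray:
    """Bow each edge outward by a sine arch of height bulge * edge length."""
    m = len(corners)
    centroid = corners.mean(axis=0)
    per_edge = max(2, int(np.ceil(n_vertices / m)))
    pts = []
    for k in range(m):
        a, b = corners[k], corners[(k + 1) % m]
        edge = b - a
        normal = np.array([edge[1], -edge[0]])
        mid = (a + b) / 2
        if np.dot(normal, mid - centroid) < 0:
            normal = -normal
        normal = normal / (np.linalg.norm(normal) + 1e-12)
        t = np.linspace(0, 1, per_edge, endpoint=False)[:, None]
        arch = bulge * np.linalg.norm(edge) * np.sin(np.pi * t)
        pts.append(a + t * edge + arch * normal)
    return np.vstack(pts)


def make_regular_shape(kind: str, params: dict) -> ContourShape:
    """Regular-group shape with a vertical axis of symmetry.

    kinds: ``parallel_sides`` (rectangle; params width, height),
    ``nonparallel_sides`` (isosceles trapezoid; width, height, skew),
    ``straight_contour`` (regular n-gon; n_sides, size),
    ``curved_contour`` (n-gon with outward-bowed edges; n_sides, size, bulge).
    """
    if kind not in _REGULAR_KINDS:
        raise ValueError(f"unsupported regular shape kind {kind!r}")
    n_vertices = int(params.get("n_vertices", 256))
    if kind in ("parallel_sides", "nonparallel_sides"):
        w = float(params["width"])
        h = float(params["height"])
        skew = float(params.get("skew", 0.0)) if kind == "nonparallel_sides" else 0.0
        if kind == "nonparallel_sides" and skew == 0.0:
            raise ValueError("nonparallel_sides requires a non-zero skew")
        top_w = w * (1.0 - skew)
        corners = np.array([
            [-top_w / 2, h / 2], [top_w / 2, h / 2],
            [w / 2, -h / 2], [-w / 2, -h / 2],
        ])
        verts = _densify(corners, n_vertices)
        style = "straight"
    else:
        n_sides = int(params["n_sides"])
        size = float(params["size"])
        ang = np.pi / 2 + np.arange(n_sides) * 2 * np.pi / n_sides
        corners = size * np.column_stack([np.cos(ang), np.sin(ang)])
        if kind == "curved_contour":
            bulge = float(params.get("bulge", 0.2))
            if bulge <= 0:
                raise ValueError("curved_contour requires bulge > 0")
            verts = _bulge_edges(corners, bulge, n_vertices)
            style = "curved"
        else:
            verts = _densify(corners, n_vertices)
            style = "straight"
    shape = ContourShape(verts, style, group="R")
    if not shape.is_simple():
        raise ValueError("regular shape is degenerate")
    return shape


def regular_pair(pair_index: int, magnitude: float = 1.0,
                 n_vertices: int = 256) -> tuple[ContourShape, ContourShape]:
    """The catalog of 8 Regular pairs; members differ in exactly one NAP.

    Odd entries contrast parallel vs non-parallel sides; the rest contrast
    straight vs curved contours on n-gons. ``magnitude`` scales the NAP
    difference (trapezoid skew or edge bulge) and is the knob used by
    pixel-difference balancing.
    """
    if not 1 <= pair_index <= 8:
        raise ValueError("pair_index must be 1..8")
    skew = min(0.8, 0.4 * magnitude)
    bulge = min(0.45, 0.22 * magnitude)
    if pair_index == 1:
        a = make_regular_shape("parallel_sides", dict(width=1.0, height=1.4, n_vertices=n_vertices))
        b = make_regular_shape("nonparallel_sides", dict(width=1.0, height=1.4, skew=skew, n_vertices=n_vertices))
    elif pair_index == 5:
        a = make_regular_shape("parallel_sides", dict(width=1.5, height=1.0, n_vertices=n_vertices))
        b = make_regular_shape("nonparallel_sides", dict(width=1.5, height=1.0, skew=skew, n_vertices=n_vertices))
    else:
        n_sides = {2: 4, 3: 3, 4: 5, 6: 6, 7: 7, 8: 8}[pair_index]
        a = make_regular_shape("straight_contour", dict(n_sides=n_sides, size=1.0, n_vertices=n_vertices))
        b = make_regular_shape("curved_contour", dict(n_sides=n_sides, size=1.0, bulge=bulge, n_vertices=n_vertices))
    for s, member in ((a, "a"), (b, "b")):
        s.group, s.pair_index, s.member = "R", pair_index, member
    return a, b


def symmetry_axis_error(shape: ContourShape) -> float:
    """RMS mismatch (relative to size) of reflecting the vertex set about the
    vertical axis through the centroid; near 0 for a symmetric shape."""
    v = shape.vertices - shape.vertices.mean(axis=0)
    mirrored = v * np.array([-1.0, 1.0])
    from scipy.spatial import cKDTree
    tree = cKDTree(v)
    d, _ = tree.query(mirrored)
    scale = np.abs(v).max()
    return float(np.sqrt(np.mean(d**2)) / (scale + 1e-12))


# ---------------------------------------------------------------------------
# matching and rendering


def match_contour(vertices: np.ndarray, target_area: float,
                  target_aspect: float) -> np.ndarray:
    """Anisotropically rescale a centred contour to an exact polygon area and
    bounding-box aspect ratio (width / height)."""
    v = np.asarray(vertices, dtype=float)
    v = v - v.mean(axis=0)
    w0 = float(v[:, 0].max() - v[:, 0].min())
    h0 = float(v[:, 1].max() - v[:, 1].min())
    area0 = float(Polygon(v).area)
    q = target_area / area0
    p = target_aspect * h0 / w0
    sx = np.sqrt(q * p)
    sy = np.sqrt(q / p)
    return v * np.array([sx, sy])


def contour_aspect(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float((v[:, 0].max() - v[:, 0].min()) / (v[:, 1].max() - v[:, 1].min()))


def render(shape: ContourShape, canvas_size: int = 96, fill_level: int = 255,
           background_level: int = 128, scale_factor: float = 1.0) -> StimulusImage:
    """Binary scan-fill of the contour, centred on the canvas.

    No anti-aliasing: every pixel is exactly background or fill level.
    ``scale_factor`` linearly scales the contour before rasterization (0.5
    realizes a size-reduced condition). A contour exceeding the canvas is an
    error.
    """
    if fill_level == background_level:
        raise ValueError("fill_level must differ from background_level")
    v = shape.vertices * scale_factor
    center = (canvas_size - 1) / 2.0
    rows = center + v[:, 1]
    cols = center + v[:, 0]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > canvas_size - 1 or cols.max() > canvas_size - 1:
        raise ValueError("contour exceeds canvas after scaling")
    img = np.full((canvas_size, canvas_size), background_level, dtype=np.uint8)
    rr, cc = draw_polygon(rows, cols, shape=img.shape)
    img[rr, cc] = fill_level
    return StimulusImage(img, canvas_size, background_level, fill_level, scale_factor)


def pixel_distance(img_a: StimulusImage, img_b: StimulusImage) -> float:
    """Normalized Euclidean graylevel distance between two renderings."""
    a = img_a.pixels.astype(float).ravel()
    b = img_b.pixels.astype(float).ravel()
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# full set construction


def _sample_isc_descriptor(cfg: StimulusConfig, rng: np.random.Generator) -> ContourDescriptor:
    """Draw a valid simple-curved descriptor; retries until the contour is simple."""
    lo, hi = cfg.isc_harmonics
    for _ in range(100):
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.choice(np.arange(2, cfg.isc_max_frequency + 1), size=k, replace=False)
        harmonics = [
            (int(f),
             float(cfg.base_radius * rng.uniform(0.06, 0.18) * 2.0 / f),
             float(rng.uniform(0, 2 * np.pi)))
            for f in sorted(freqs.tolist())
        ]
        desc = ContourDescriptor(cfg.base_radius, harmonics)
        try:
            shape = make_irregular_contour(desc, cfg.n_vertices)
            if len(curvature_extrema(shape.vertices)) >= 4:
                return desc
        except ValueError:
            continue
    raise RuntimeError("failed to sample a valid irregular descriptor")


def build_shape_set(config: StimulusConfig | None = None, seed: int = 0) -> ShapeSet:
    """Generate the full 64-stimulus set with matched columns.

    Per column j: an ISC descriptor is drawn; its b-member is a metric
    perturbation; IC is a complexified fresh descriptor (with its own
    perturbation); ISS members are straightened ISC-family contours; the R
    pair comes from the regular catalog. All 8 contours of the column are then
    rescaled to the column's target area and aspect ratio, and rendered.
    """
    cfg = config or StimulusConfig()
    rng = np.random.default_rng(seed)
    stimuli: list[Stimulus] = []
    column_matching: dict[int, dict] = {}
    mags = cfg.group_magnitudes
    canvas2 = cfg.canvas_size**2

    for j in range(1, 9):
        col_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        target_area = canvas2 * col_rng.uniform(*cfg.area_fraction_range)
        target_aspect = col_rng.uniform(*cfg.aspect_range)
        column_matching[j] = {"area": target_area, "aspect": target_aspect}

        isc_seed = int(col_rng.integers(0, 2**31 - 1))
        ic_seed = int(col_rng.integers(0, 2**31 - 1))
        pert_seed = int(col_rng.integers(0, 2**31 - 1))

        # retry loop: perturbations or straightening can occasionally fail
        for attempt in range(30):
            try:
                d_rng = np.random.default_rng(isc_seed + attempt)
                isc_a_desc = _sample_isc_descriptor(cfg, d_rng)
                isc_b_desc = perturb_pair(isc_a_desc, cfg.perturb_modes["ISC"],
                                          max(mags["ISC"], 1e-6), seed=pert_seed)
                iss_b_desc = perturb_pair(isc_a_desc, cfg.perturb_modes["ISS"],
                                          max(mags["ISS"], 1e-6), seed=pert_seed)
                ic_rng = np.random.default_rng(ic_seed + attempt)
                ic_base = _sample_isc_descriptor(cfg, ic_rng)
                ic_a_desc = complexify(ic_base, cfg.ic_added_harmonics,
                                       cfg.ic_max_frequency, seed=ic_seed + attempt)
                ic_b_desc = perturb_pair(ic_a_desc, cfg.perturb_modes["IC"],
                                         max(mags["IC"], 1e-6), seed=pert_seed)

                isc_a = make_irregular_contour(isc_a_desc, cfg.n_vertices)
                isc_b = make_irregular_contour(isc_b_desc, cfg.n_vertices)
                ic_a = make_irregular_contour(ic_a_desc, cfg.n_vertices)
                ic_b = make_irregular_contour(ic_b_desc, cfg.n_vertices)
                iss_a = straighten_contour(isc_a)
                iss_b = straighten_contour(make_irregular_contour(iss_b_desc, cfg.n_vertices))
                r_a, r_b = regular_pair(j, magnitude=mags["R"])
                col = {
                    ("R", "a"): (r_a, None), ("R", "b"): (r_b, None),
                    ("IC", "a"): (ic_a, ic_a_desc), ("IC", "b"): (ic_b, ic_b_desc),
                    ("ISC", "a"): (isc_a, isc_a_desc), ("ISC", "b"): (isc_b, isc_b_desc),
                    ("ISS", "a"): (iss_a, isc_a_desc), ("ISS", "b"): (iss_b, iss_b_desc),
                }
                rendered = {}
                for (g, m), (shape, desc) in col.items():
                    verts = match_contour(shape.vertices, target_area, target_aspect)
                    matched = ContourShape(verts, shape.boundary_style, g, j, m)
                    if not matched.is_simple():
                        raise ValueError("matched contour degenerate")
                    img = render(matched, cfg.canvas_size, cfg.fill_level,
                                 cfg.background_level, cfg.scale_factor)
                    rendered[(g, m)] = Stimulus(stimulus_id(g, j, m), g, j, m,
                                                matched, img, desc)
                break
            except (ValueError, RuntimeError):
                if attempt == 29:
                    raise RuntimeError(f"column {j}: could not build a valid column")
                continue
        for g in GROUPS:
            for m in MEMBERS:
                stimuli.append(rendered[(g, m)])

    order = {g: i for i, g in enumerate(GROUPS)}
    stimuli.sort(key=lambda s: (order[s.group], s.pair_index, s.member))
    return ShapeSet(stimuli, column_matching, cfg, seed)


def group_pixel_imbalance(shape_set: ShapeSet) -> dict:
    """Within-pair pixel distances per group and their imbalance vs the grand mean."""
    means = {}
    for g in GROUPS:
        dists = [
            pixel_distance(shape_set.get(g, j, "a").image, shape_set.get(g, j, "b").image)
            for j in range(1, 9)
        ]
        means[g] = float(np.mean(dists))
    grand = float(np.mean(list(means.values())))
    rel = {g: (means[g] - grand) / grand for g in GROUPS}
    return {"group_means": means, "grand_mean": grand, "relative_deviation": rel,
            "max_abs_relative_deviation": max(abs(r) for r in rel.values())}


class BalanceError(RuntimeError):
    def __init__(self, msg, report):
        super().__init__(msg)
        self.report = report


def balance_pixel_differences(shape_set: ShapeSet, tolerance: float = 0.1,
                              max_iter: int = 20) -> ShapeSet:
    """Equalize the mean within-pair pixel distance across the four groups.

    Multiplicative, derivative-free update: each group's perturbation
    magnitude is scaled by (grand mean / group mean)^0.5 and the set is
    regenerated with the same seed, until every group mean lies within
    ``tolerance`` (relative) of the grand mean. Returns the input unchanged if
    it is already balanced; raises :class:`BalanceError` carrying the best
    achieved imbalance on non-convergence.
    """
    report = group_pixel_imbalance(shape_set)
    if report["max_abs_relative_deviation"] <= tolerance:
        out = copy.copy(shape_set)
        out.balance_report = {**report, "iterations": 0, "converged": True}
        return out
    current = shape_set
    best = report
    mags = dict(shape_set.config.group_magnitudes)
    for it in range(1, max_iter + 1):
        grand = report["grand_mean"]
        for g in GROUPS:
            ratio = grand / max(report["group_means"][g], 1e-12)
            mags[g] = float(np.clip(mags[g] * ratio**0.5, 1e-3, 1e3))
        cfg = copy.deepcopy(current.config)
        cfg.group_magnitudes = dict(mags)
        current = build_shape_set(cfg, seed=shape_set.seed)
        report = group_pixel_imbalance(current)
        if report["max_abs_relative_deviation"] < best["max_abs_relative_deviation"]:
            best = report
        if report["max_abs_relative_deviation"] <= tolerance:
            current.balance_report = {**report, "iterations": it, "converged": True}
            return current
    raise BalanceError(
        f"pixel-difference balancing did not reach tolerance {tolerance} in "
        f"{max_iter} iterations (best {best['max_abs_relative_deviation']:.3f})",
        best,
    )


# ---------------------------------------------------------------------------
# I/O


def save_shape_set(shape_set: ShapeSet, out_dir, write_png: bool = True) -> Path:
    """Write one 8-bit grayscale PNG per stimulus plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in shape_set.stimuli:
        fname = f"{s.stimulus_id}.png"
        if write_png:
            Image.fromarray(s.image.pixels, mode="L").save(out / fname)
        entry = {
            "id": s.stimulus_id, "group": s.group, "pair_index": s.pair_index,
            "member": s.member, "file": fname,
            "boundary_style": s.shape.boundary_style,
        }
        if s.descriptor is not None:
            entry["descriptor"] = {
                "base_radius": s.descriptor.base_radius,
                "harmonics": [list(h) for h in s.descriptor.harmonics],
            }
        entries.append(entry)
    manifest = {
        "seed": shape_set.seed,
        "config": shape_set.config.to_dict(),
        "column_matching": {str(k): v for k, v in shape_set.column_matching.items()},
        "balance_report": shape_set.balance_report,
        "stimuli": entries,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return out / "manifest.json"
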