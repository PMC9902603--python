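"""Synthetic Giemsa-style single-chromosome image generator.

Renders cropped metaphase-chromosome images of the three sister-chromatid
cohesion (SCC) morphology classes used in chromosome-spread scoring:

* **type A** — tightly cohered sisters: the two chromatids lie appressed and
  appear as a single dark body;
* **type B** — arms separated: the chromatids splay apart along the arms but
  remain joined at the centromere (the classic "X" shape);
* **type C** — fully separated: the sister chromatids are disjoint bodies,
  including at the centromere.

Each chromatid is modelled as a thickened, slightly bowed curve — two arms
meeting at a centromere waist — rasterised with anti-aliasing onto a light
background, with per-image stain-shade variation, additive noise, a faint
purple Giemsa tint, and (optionally) small "photobombing" fragments near the
image border.  The geometric parameters that produced each image are stored
with it, so labels are verifiable against the geometry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SynthConfig",
    "ChromosomeGeometry",
    "LabeledImage",
    "GeometryError",
    "generate_chromosome",
    "generate_dataset",
    "generate_genotype_pair",
    "geometric_label",
    "save_dataset",
]

LABELS = ("A", "B", "C")


class GeometryError(ValueError):
    """Raised when sampled chromosome geometry cannot fit in the image."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic chromosome renderer.

    Geometry is sampled per image; the class-discriminating parameters are
    the arm half-opening angle (A vs B; the sampled ranges must be disjoint
    so that every label is geometrically realisable) and the centromere gap
    (zero for A/B, strictly positive for C).
    """

    image_size: int = 224
    #: total chromatid length in pixels (tip to tip), sampled uniformly
    chromatid_length_range: tuple[float, float] = (80.0, 120.0)
    #: full chromatid width in pixels, sampled uniformly
    chromatid_width_range: tuple[float, float] = (10.0, 16.0)
    #: half-opening angle of the arms, in degrees, per label
    arm_angle_by_type: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (0.0, 6.0), "B": (18.0, 40.0), "C": (0.0, 15.0)}
    )
    #: edge-to-edge centromere separation of the sisters, in pixels, per label
    centromere_gap_by_type: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (0.0, 0.0), "B": (0.0, 0.0), "C": (14.0, 30.0)}
    )
    #: minimum admissible gap for type C (bodies must be clearly disjoint)
    min_c_gap: float = 8.0
    #: mean chromatin intensity (8-bit); Giemsa chromatin is dark
    stain_mean_range: tuple[float, float] = (20.0, 55.0)
    #: within-body intensity texture SD (8-bit)
    stain_sd_range: tuple[float, float] = (4.0, 12.0)
    #: additive Gaussian pixel noise SD (8-bit)
    noise_sd: float = 5.0
    #: probability that a small chromatin fragment photobombs the crop
    fragment_probability: float = 0.0
    #: chromosome orientation sampled uniformly from [0, rotation) degrees
    rotation: float = 180.0
    #: background intensity range (light field)
    background_range: tuple[float, float] = (238.0, 252.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        a_lo, a_hi = self.arm_angle_by_type["A"]
        b_lo, b_hi = self.arm_angle_by_type["B"]
        if not (a_lo <= a_hi < b_lo <= b_hi):
            raise ValueError(
                "arm angle ranges for types A and B must be disjoint with A < B; "
                f"got A={self.arm_angle_by_type['A']}, B={self.arm_angle_by_type['B']}"
            )
        for lab in ("A", "B"):
            if self.centromere_gap_by_type[lab] != (0.0, 0.0):
                raise ValueError(f"centromere gap must be 0 for type {lab}")
        c_lo, c_hi = self.centromere_gap_by_type["C"]
        if not (c_lo >= self.min_c_gap > 0):
            raise ValueError(
                f"type C centromere gap must be >= min_c_gap={self.min_c_gap}; got {c_lo}"
            )
        if c_hi < c_lo:
            raise ValueError("centromere gap range inverted")
        # worst-case footprint: the longest arm (with bow) extends along the
        # main axis, the sister offset along the perpendicular, so the radial
        # reach is their quadrature sum plus body radius and centre jitter
        l_max = self.chromatid_length_range[1]
        w_max = self.chromatid_width_range[1]
        along = 0.675 * l_max + w_max / 2.0  # 0.64 arm fraction + bow margin
        across = (c_hi + w_max) / 2.0 + w_max / 2.0
        half_extent = float(np.hypot(along, across)) + 6.0
        if half_extent > self.image_size / 2.0:
            raise GeometryError(
                f"sampled geometry may exceed image bounds: worst-case half-extent "
                f"{half_extent:.1f}px > {self.image_size / 2.0:.1f}px"
            )


@dataclass(frozen=True)
class ChromosomeGeometry:
    """Ground-truth draw of the renderer for one image."""

    label: str
    arm_angle_deg: float
    centromere_gap_px: float
    length_px: float
    width_px: float
    orientation_deg: float
    center: tuple[float, float]
    stain_mean: float
    #: bounding boxes (r0, c0, r1, c1) of each rendered chromatid body
    body_boxes: tuple[tuple[int, int, int, int], ...]
    #: boolean mask of photobombing fragments (None when no fragment drawn)
    fragment_mask: np.ndarray | None


@dataclass
class LabeledImage:
    """A cropped single-chromosome image with its label and provenance."""

    pixels: np.ndarray  # H x W x 3 uint8, origin top-left
    label: str
    cell_id: str
    genotype: str = "WT"
    geometry: ChromosomeGeometry | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.cell_id:
            raise ValueError("cell_id must be non-empty")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _arm_points(origin, direction, length, width, bow, n=None):
    """Sample centreline points and local radii along one chromatid arm.

    The radius profile has a waist at the centromere (t=0) and a taper
    toward the telomere (t=1), so rendered bodies read as chromatids rather
    than capsules.
    """
    if n is None:
        n = max(8, int(np.ceil(length / 0.8)))
    t = np.linspace(0.0, 1.0, n)
    perp = np.array([-direction[1], direction[0]])
    pts = (
        origin[None, :]
        + t[:, None] * length * direction[None, :]
        + (bow * np.sin(np.pi * t))[:, None] * perp[None, :]
    )
    base = width / 2.0
    waist = 0.62 + 0.38 * np.clip(t / 0.25, 0.0, 1.0)  # narrow at centromere
    taper = 1.0 - 0.45 * t**2  # thin toward the tip
    radii = base * waist * taper
    return pts, radii


def _render_bodies(size: int, pts: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Anti-aliased coverage map in [0,1] of a union of discs along curves."""
    cover = np.zeros((size, size), dtype=np.float64)
    r_max = float(radii.max())
    lo = np.maximum(np.floor(pts.min(axis=0) - r_max - 2).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0) + r_max + 2).astype(int), size - 1)
    ys = np.arange(lo[1], hi[1] + 1)
    xs = np.arange(lo[0], hi[0] + 1)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float64)
    tree = cKDTree(pts)
    k = min(6, len(pts))
    dist, idx = tree.query(grid, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    # signed distance to the nearest disc boundary, softened over ~1.2px
    signed = dist - radii[idx]
    alpha = np.clip(0.5 - signed.min(axis=1) / 1.2, 0.0, 1.0)
    cover[gy.ravel(), gx.ravel()] = np.maximum(cover[gy.ravel(), gx.ravel()], alpha)
    return cover


def _smooth_noise(size: int, rng: np.random.Generator, scale: int = 8) -> np.ndarray:
    """Band-limited unit-variance noise for stain texture."""
    coarse = rng.standard_normal((size // scale + 2, size // scale + 2))
    up = np.kron(coarse, np.ones((scale, scale)))[:size, :size]
    return up


def generate_chromosome(
    label: str,
    config: SynthConfig | None = None,
    rng: np.random.Generator | int | None = None,
    cell_id: str = "cell0000",
    genotype: str = "WT",
) -> LabeledImage:
    """Render one labelled synthetic chromosome image.

    Parameters
    ----------
    label:
        Morphology class, one of ``"A"``, ``"B"``, ``"C"``.
    config:
        Renderer parameters; defaults to :class:`SynthConfig`.
    rng:
        A :class:`numpy.random.Generator`, an integer seed, or None (uses
        ``config.seed``).  Identical (config, seed) yield byte-identical
        images.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    config = config or SynthConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    size = config.image_size
    center = np.array([size / 2.0, size / 2.0]) + rng.uniform(-4, 4, size=2)
    phi = rng.uniform(0.0, config.rotation)
    length = rng.uniform(*config.chromatid_length_range)
    width = rng.uniform(*config.chromatid_width_range)
    theta = rng.uniform(*config.arm_angle_by_type[label])
    gap = rng.uniform(*config.centromere_gap_by_type[label])
    # centromere position along the chromatid (p-arm fraction)
    p_frac = rng.uniform(0.36, 0.50)
    bows = rng.uniform(-0.07, 0.07, size=4) * length / 2.0

    u = _rot(np.array([1.0, 0.0]), phi)  # main axis
    v = np.array([-u[1], u[0]])  # sister-offset axis
    if label == "C":
        half_sep = (gap + width) / 2.0  # centre-to-centre; edge gap ~= gap
    else:
        half_sep = width * 0.34  # appressed sisters: bodies touch/overlap

    all_pts, all_radii = [], []
    body_boxes = []
    for s_i, s in enumerate((-1.0, 1.0)):
        cent = center + s * half_sep * v
        pts_s = []
        radii_s = []
        for a_i, (sign, arm_len) in enumerate(
            ((1.0, length * p_frac), (-1.0, length * (1.0 - p_frac)))
        ):
            d = _rot(sign * u, s * sign * theta)
            pts, radii = _arm_points(cent, d, arm_len, width, bows[2 * s_i + a_i])
            pts_s.append(pts)
            radii_s.append(radii)
        pts_s = np.concatenate(pts_s)
        radii_s = np.concatenate(radii_s)
        margin = radii_s.max() + 1.5
        if (pts_s - margin < 0).any() or (pts_s + margin > size - 1).any():
            raise GeometryError(
                f"sampled geometry (label {label}, length {length:.0f}px, "
                f"gap {gap:.0f}px) exceeds {size}x{size} image bounds"
            )
        all_pts.append(pts_s)
        all_radii.append(radii_s)
        lo = np.floor(pts_s.min(axis=0) - margin).astype(int)
        hi = np.ceil(pts_s.max(axis=0) + margin).astype(int)
        body_boxes.append((int(lo[1]), int(lo[0]), int(hi[1]), int(hi[0])))

    cover = _render_bodies(size, np.concatenate(all_pts), np.concatenate(all_radii))

    # photobombing fragment: small chromatin-like ellipse near the border
    fragment_mask = None
    if rng.uniform() < config.fragment_probability:
        fragment_mask = np.zeros((size, size), dtype=bool)
        n_frag = rng.integers(1, 3)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_frag):
            edge_margin = rng.uniform(8, 26)
            side = rng.integers(0, 4)
            fx = rng.uniform(edge_margin, size - edge_margin)
            fy = rng.uniform(edge_margin, size - edge_margin)
            if side == 0:
                fy = edge_margin
            elif side == 1:
                fy = size - edge_margin
            elif side == 2:
                fx = edge_margin
            else:
                fx = size - edge_margin
            ra, rb = rng.uniform(3.0, 8.0, size=2)
            ang = rng.uniform(0, np.pi)
            ca, sa = np.cos(ang), np.sin(ang)
            dx, dy = xx - fx, yy - fy
            ell = ((ca * dx + sa * dy) / ra) ** 2 + ((-sa * dx + ca * dy) / rb) ** 2
            frag_cover = np.clip((1.0 - ell) * 3.0, 0.0, 1.0)
            inside = frag_cover > 0.5
            cover = np.maximum(cover, frag_cover)
            fragment_mask |= inside

    bg = rng.uniform(*config.background_range)
    stain_mean = rng.uniform(*config.stain_mean_range)
    stain_sd = rng.uniform(*config.stain_sd_range)
    texture = np.clip(stain_mean + stain_sd * _smooth_noise(size, rng), 2.0, 200.0)
    # faint Giemsa (purple) tint: chromatin slightly brighter in R/B than G
    tint = np.array([1.10, 0.88, 1.14]) + rng.uniform(-0.03, 0.03, size=3)
    chromatin = texture[:, :, None] * tint[None, None, :]
    img = bg * (1.0 - cover[:, :, None]) + cover[:, :, None] * chromatin
    img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    geometry = ChromosomeGeometry(
        label=label,
        arm_angle_deg=float(theta),
        centromere_gap_px=float(gap),
        length_px=float(length),
        width_px=float(width),
        orientation_deg=float(phi),
        center=(float(center[0]), float(center[1])),
        stain_mean=float(stain_mean),
        body_boxes=tuple(body_boxes),
        fragment_mask=fragment_mask,
    )
    return LabeledImage(
        pixels=pixels, label=label, cell_id=cell_id, genotype=genotype, geometry=geometry
    )


def geometric_label(geometry: ChromosomeGeometry, config: SynthConfig) -> str:
    """Rule-based classification from ground-truth geometry parameters.

    The decision mirrors the class definitions: a positive centromere gap is
    type C; otherwise the arm half-opening angle decides A (below the
    midpoint of the disjoint A/B ranges) vs B.
    """
    if geometry.centromere_gap_px > 0:
        return "C"
    boundary = (config.arm_angle_by_type["A"][1] + config.arm_angle_by_type["B"][0]) / 2.0
    return "B" if geometry.arm_angle_deg >= boundary else "A"


#: average images per synthetic cell; mirrors ~2,144 images from ~150 cells
IMAGES_PER_CELL = 14


def generate_dataset(
    counts: dict[str, int],
    config: SynthConfig | None = None,
    genotype: str = "WT",
    seed: int | None = None,
) -> list[LabeledImage]:
    """Generate a labelled dataset with exact per-label counts.

    Each image is assigned a synthetic ``cell_id`` drawn uniformly from
    ``round(n / IMAGES_PER_CELL)`` cells, so cells group on average
    :data:`IMAGES_PER_CELL` images of mixed labels with naturally variable
    per-cell counts (as in real spreads, where the number of usable
    chromosomes differs between cells).  This enables cell-level splitting
    downstream, including splits that must hit an exact image count.
    """
    config = config or SynthConfig()
    for lab, n in counts.items():
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        if n < 0:
            raise ValueError(f"negative count for label {lab}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    labels = [lab for lab in LABELS for _ in range(counts.get(lab, 0))]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_cells = max(1, round(len(labels) / IMAGES_PER_CELL))
    cell_of = rng.integers(0, n_cells, size=len(labels))
    images = []
    for i, lab in enumerate(labels):
        cell = f"{genotype}_cell{cell_of[i]:04d}"
        images.append(
            generate_chromosome(lab, config, rng, cell_id=cell, genotype=genotype)
        )
    return images


def generate_genotype_pair(
    wt_distribution,
    mutant_distribution,
    n_per_genotype: int,
    config: SynthConfig | None = None,
    seed: int = 0,
    genotype_names: tuple[str, str] = ("WT", "mutant"),
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Generate paired datasets whose label mixes follow two multinomials.

    Used to emulate a wild-type sample against a cohesion-defective mutant
    whose type B/C rates are elevated.
    """
    datasets = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    for dist, name, sub_seed in zip(
        (wt_distribution, mutant_distribution), genotype_names, child_seeds
    ):
        dist = np.asarray(dist, dtype=float)
        # printed percentages are rounded, so allow a small slack and renormalize
        if dist.shape != (3,) or abs(dist.sum() - 1.0) > 1e-2 or (dist < 0).any():
            raise ValueError(
                f"distribution for {name} must be 3 non-negative proportions "
                f"summing to 1; got {dist}"
            )
        dist = dist / dist.sum()
        rng = np.random.default_rng(sub_seed)
        draw = rng.multinomial(n_per_genotype, dist)
        counts = dict(zip(LABELS, (int(c) for c in draw)))
        datasets.append(
            generate_dataset(counts, config, genotype=name, seed=sub_seed + 1)
        )
    return datasets[0], datasets[1]


def save_dataset(images: list[LabeledImage], outdir: str | Path) -> Path:
    """Write PNGs plus a ``path,label,cell_id,genotype`` CSV manifest.

    Returns the manifest path.  Filenames encode index and label for easy
    inspection; the manifest is the authoritative record.
    """
    from PIL import Image

    from .manifest import write_manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        name = f"img{i:05d}_{im.label}.png"
        Image.fromarray(im.pixels).save(outdir / name)
        im.path = name
        rows.append(
            {"path": name, "label": im.label, "cell_id": im.cell_id, "genotype": im.genotype}
        )
    import pandas as pd

    manifest_path = outdir / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path
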