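"""Synthetic H&E-like line-scan hyperspectral phantoms with full ground truth.

The real acquisition pairs a brightfield microscope with a wedge line-scan
hyperspectral camera: sensor rows sense different wavelength channels
("virtual bands"), and the motorized stage sweeps the sample so that each
scene line is eventually observed by every band.  A vendor correction matrix
then maps the raw virtual bands onto calibrated spectral bands.

This module emulates that whole acquisition chain on synthetic tissue:

* :func:`make_phantom_scene` draws elliptical nuclei on an H&E-like
  background (tumor scenes dense and touching, healthy scenes sparse) and
  builds a noiseless ideal transmittance cube plus exhaustive ground truth;
* :func:`render_linescan_frames` runs the *forward* sensor model — inverse
  calibration against white/dark references, expansion to virtual bands,
  per-band spatial shift injection, line-scan frame slicing and 8-bit
  quantization — producing raw frames the preprocessing chain can consume;
* :func:`phantom_suite` generates whole multi-patient datasets with
  leakage-free train/validation/test splits.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import (
    BACKGROUND,
    NUCLEI,
    WAVELENGTH_MAX_NM,
    WAVELENGTH_MIN_NM,
    HsinucdbError,
    HyperCube,
)


class PlacementError(HsinucdbError):
    """Requested nucleus density cannot be realized on the canvas."""


class RenderError(HsinucdbError):
    """Invalid inputs to the line-scan forward model."""


class SplitError(HsinucdbError):
    """Requested patient-level split cannot be satisfied."""


# --------------------------------------------------------------------------
# Sensor model
# --------------------------------------------------------------------------

@dataclass
class SensorModel:
    """Geometry and spectral layout of the wedge line-scan sensor.

    ``row_to_band[r]`` is the virtual band sensed by sensor row ``r`` and
    ``row_offset[r]`` the spatial line offset of that row: frame ``t``
    contributes scene line ``t * scan_step + row_offset[r]`` for row ``r``.
    The generator and the stitcher share this model, which makes stitching
    well-defined.
    """

    n_virtual_bands: int
    n_spectral_bands: int
    row_to_band: np.ndarray
    row_offset: np.ndarray
    wavelength_grid: np.ndarray
    scan_step: int = 1

    def __post_init__(self) -> None:
        self.row_to_band = np.asarray(self.row_to_band, dtype=np.int64)
        self.row_offset = np.asarray(self.row_offset, dtype=np.int64)
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.row_to_band.shape != self.row_offset.shape:
            raise ValueError("row_to_band and row_offset must align")
        if set(np.unique(self.row_to_band)) != set(range(self.n_virtual_bands)):
            raise ValueError("row_to_band must be surjective onto virtual bands")
        if np.any(self.row_offset < 0):
            raise ValueError("row offsets must be non-negative")
        if self.wavelength_grid.shape != (self.n_spectral_bands,):
            raise ValueError("wavelength grid length must equal n_spectral_bands")
        if np.any(np.diff(self.wavelength_grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return int(self.row_to_band.shape[0])

    @property
    def max_offset(self) -> int:
        return int(self.row_offset.max())

    @classmethod
    def wedge(
        cls,
        n_spectral_bands: int = 16,
        n_virtual_bands: Optional[int] = None,
        wavelength_grid: Optional[np.ndarray] = None,
    ) -> "SensorModel":
        """Desk-scale wedge sensor: one row per virtual band, offset = row.

        The default grid is linear over the camera range 470–890 nm.
        """
        if n_virtual_bands is None:
            # a handful of virtual bands collapse pairwise onto spectral ones
            n_virtual_bands = n_spectral_bands + max(2, n_spectral_bands // 4)
        if n_virtual_bands < n_spectral_bands:
            raise ValueError("need at least as many virtual as spectral bands")
        if wavelength_grid is None:
            wavelength_grid = np.linspace(
                WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_spectral_bands
            )
        rows = np.arange(n_virtual_bands)
        return cls(
            n_virtual_bands=n_virtual_bands,
            n_spectral_bands=n_spectral_bands,
            row_to_band=rows,
            row_offset=rows.copy(),
            wavelength_grid=wavelength_grid,
        )

    @classmethod
    def full_scale(cls) -> "SensorModel":
        """Full camera layout: 192 virtual bands mapping to 145 spectral."""
        return cls.wedge(n_spectral_bands=145, n_virtual_bands=192)


# --------------------------------------------------------------------------
# Correction matrix (synthetic stand-in for the vendor matrix)
# --------------------------------------------------------------------------

def _band_groups(n_virtual: int, n_spectral: int) -> list[np.ndarray]:
    """Partition virtual bands into adjacent groups, one per spectral band.

    Each group has one to three members; extra virtual bands are spread
    evenly over the spectral axis.
    """
    extra = n_virtual - n_spectral
    if extra < 0 or extra > 2 * n_spectral:
        raise ValueError("virtual band count must be in [n_spectral, 3*n_spectral]")
    sizes = np.ones(n_spectral, dtype=np.int64)
    for i in range(extra):
        sizes[(i * n_spectral) // extra if extra else 0] += 1
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return [np.arange(s, s + k) for s, k in zip(starts, sizes)]


def make_correction_matrix(sensor: SensorModel) -> np.ndarray:
    """Build the (n_virtual x n_spectral) spectral correction matrix.

    Each output (spectral) band is a normalized average of up to three
    adjacent virtual bands; columns sum to one.  A stand-in for the vendor
    matrix, constructed from the sensor layout alone.
    """
    groups = _band_groups(sensor.n_virtual_bands, sensor.n_spectral_bands)
    M = np.zeros((sensor.n_virtual_bands, sensor.n_spectral_bands))
    for s, g in enumerate(groups):
        M[g, s] = 1.0 / len(g)
    return M


def expand_to_virtual(ideal_cube: np.ndarray, sensor: SensorModel) -> np.ndarray:
    """Generator-side right inverse of the correction matrix.

    Replicates each spectral band into its virtual-band group, which is an
    exact right inverse of :func:`make_correction_matrix` and keeps values
    inside the physical (0, 1) transmittance range.
    """
    groups = _band_groups(sensor.n_virtual_bands, sensor.n_spectral_bands)
    virtual = np.empty(ideal_cube.shape[:2] + (sensor.n_virtual_bands,))
    for s, g in enumerate(groups):
        virtual[:, :, g] = ideal_cube[:, :, s : s + 1]
    return virtual


def spectral_band_of_virtual(sensor: SensorModel) -> np.ndarray:
    """Map each virtual band index to its spectral band index."""
    groups = _band_groups(sensor.n_virtual_bands, sensor.n_spectral_bands)
    out = np.empty(sensor.n_virtual_bands, dtype=np.int64)
    for s, g in enumerate(groups):
        out[g] = s
    return out


# --------------------------------------------------------------------------
# Scene specification and ground truth
# --------------------------------------------------------------------------

def default_class_spectra(wavelengths_nm: np.ndarray) -> dict[str, np.ndarray]:
    """H&E-like two-chromophore transmittance curves.

    Background (eosin-tinted cytoplasm/glass) transmits strongly with a mild
    red-leaning slope; nuclei (hematoxylin) are darker with a broad
    absorption dip near 600 nm.  Values stay strictly inside (0, 1).
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    t = (lam - WAVELENGTH_MIN_NM) / (WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM)
    background = 0.75 + 0.15 * t
    nuclei = 0.45 + 0.10 * t - 0.25 * np.exp(-(((lam - 600.0) / 80.0) ** 2))
    return {"background": background, "nuclei": nuclei}


# nuclei per 10^4 px^2; tumor tissue is several times denser than healthy
DEFAULT_DENSITY = {"tumor": 8.0, "healthy": 1.5}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tissue scene."""

    height: int = 256
    width: int = 256
    n_bands: int = 16
    tissue_class: str = "healthy"
    nucleus_density: Optional[float] = None  # nuclei per 10^4 px^2
    nucleus_axes: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 9.0), (3.0, 7.0))
    class_spectra: Optional[dict[str, np.ndarray]] = None
    noise_sd: float = 0.01
    texture_sd: float = 0.01
    band_shifts: Optional[np.ndarray] = None  # (n_bands, 2) integer (dy, dx)
    min_gap_px: float = 3.0  # minimum mask gap enforced for healthy scenes
    max_overlap_fraction: float = 0.05  # tolerated per-nucleus overlap in tumor scenes
    seed: int = 0
    wavelength_grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.tissue_class not in ("tumor", "healthy"):
            raise ValueError("tissue_class must be 'tumor' or 'healthy'")
        if self.nucleus_density is None:
            self.nucleus_density = DEFAULT_DENSITY[self.tissue_class]
        if self.wavelength_grid is None:
            self.wavelength_grid = np.linspace(
                WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, self.n_bands
            )
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.class_spectra is None:
            self.class_spectra = default_class_spectra(self.wavelength_grid)
        for name, spec in self.class_spectra.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != (self.n_bands,):
                raise ValueError(f"class spectrum '{name}' must have {self.n_bands} bands")
            if np.any(spec <= 0) or np.any(spec >= 1):
                raise ValueError(f"class spectrum '{name}' must lie strictly in (0, 1)")
            self.class_spectra[name] = spec
        if self.band_shifts is None:
            self.band_shifts = np.zeros((self.n_bands, 2), dtype=np.int64)
        self.band_shifts = np.asarray(self.band_shifts, dtype=np.int64)
        if self.band_shifts.shape != (self.n_bands, 2):
            raise ValueError("band_shifts must be (n_bands, 2)")
        max_axis = max(self.nucleus_axes[0][1], self.nucleus_axes[1][1])
        if min(self.height, self.width) < 2 * max_axis:
            raise ValueError("scene dimensions must be at least twice the max nucleus axis")


@dataclass
class PhantomTruth:
    """Generator-side ground truth for one scene."""

    instance_map: np.ndarray
    class_mask: np.ndarray  # {0, 2}: background / nuclei, no border class
    nucleus_count: int
    injected_shifts: np.ndarray
    ideal_cube: np.ndarray  # H x W x B noiseless transmittance
    class_spectra: dict[str, np.ndarray]
    spec: PhantomSpec

    def __post_init__(self) -> None:
        labels = np.unique(self.instance_map)
        n_pos = int((labels > 0).sum())
        if n_pos != self.nucleus_count:
            raise ValueError("nucleus_count must equal number of instance labels")
        if not np.array_equal(self.class_mask == NUCLEI, self.instance_map > 0):
            raise ValueError("class_mask nuclei must coincide with instance_map > 0")


@dataclass
class RawScanSequence:
    """Ordered 8-bit line-scan frames plus the sensor that produced them."""

    frames: np.ndarray  # (n_frames, n_rows, width) uint8
    sensor: SensorModel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.dtype != np.uint8:
            raise ValueError("frames must be a (T, rows, W) uint8 array")
        if self.frames.shape[1] != self.sensor.n_rows:
            raise ValueError("frame row count must match the sensor model")


@dataclass
class ReferencePair:
    """White (blank glass) and dark (covered channel) reference frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share shape")
        if np.any(self.white.astype(np.int64) < self.dark.astype(np.int64)):
            raise ValueError("white reference must dominate dark elementwise")


def make_references(
    sensor: SensorModel,
    width: int,
    white_level: float = 250.0,
    dark_level: float = 5.0,
) -> ReferencePair:
    """Build smooth, slightly non-flat reference frames for a sensor."""
    rows = sensor.n_rows
    yy, xx = np.meshgrid(np.arange(rows), np.arange(width), indexing="ij")
    # gentle illumination falloff toward frame corners
    shading = 8.0 * np.cos(np.pi * (xx / max(width - 1, 1) - 0.5)) - 4.0
    white = np.clip(np.round(white_level + shading + 0.02 * yy), 0, 255).astype(np.uint8)
    dark = np.full((rows, width), dark_level)
    dark = np.clip(np.round(dark), 0, 255).astype(np.uint8)
    return ReferencePair(white=white, dark=dark)


# --------------------------------------------------------------------------
# Scene generation
# --------------------------------------------------------------------------

def _ellipse_mask(
    height: int,
    width: int,
    cy: float,
    cx: float,
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse (semi-axes a, b; rotation theta)."""
    y0 = max(int(np.floor(cy - a - b)), 0)
    y1 = min(int(np.ceil(cy + a + b)) + 1, height)
    x0 = max(int(np.floor(cx - a - b)), 0)
    x1 = min(int(np.ceil(cx + a + b)) + 1, width)
    yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    dy = yy - cy
    dx = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dy + s * dx
    v = -s * dy + c * dx
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros((height, width), dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def make_phantom_scene(spec: PhantomSpec) -> PhantomTruth:
    """Place elliptical nuclei by rejection sampling and build the ideal cube.

    Tumor scenes permit touching and bounded overlap; healthy scenes enforce
    a minimum gap between nucleus masks.  The nucleus count is drawn from a
    Poisson law at the requested density.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    expected = spec.nucleus_density * H * W / 1e4
    target = int(rng.poisson(expected))

    instance = np.zeros((H, W), dtype=np.int64)
    occupied = np.zeros((H, W), dtype=bool)
    # dilated footprint used to enforce the healthy-tissue gap
    gap = int(np.ceil(spec.min_gap_px))
    blocked = np.zeros((H, W), dtype=bool)

    (a_lo, a_hi), (b_lo, b_hi) = spec.nucleus_axes
    placed = 0
    attempts_budget = max(200, 200 * target)
    attempts = 0
    while placed < target:
        if attempts >= attempts_budget:
            raise PlacementError(
                f"could not place {target} nuclei on a {H}x{W} canvas "
                f"after {attempts} attempts (density infeasible)"
            )
        attempts += 1
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b)
        cy = rng.uniform(margin, H - margin)
        cx = rng.uniform(margin, W - margin)
        mask = _ellipse_mask(H, W, cy, cx, a, b, theta)
        area = int(mask.sum())
        if area == 0:
            continue
        if spec.tissue_class == "healthy":
            if np.any(mask & blocked):
                continue
        else:  # tumor: touching allowed, overlap bounded per nucleus
            overlap = int((mask & occupied).sum())
            if overlap > spec.max_overlap_fraction * area:
                continue
        placed += 1
        instance[mask] = placed
        occupied |= mask
        if spec.tissue_class == "healthy":
            from scipy.ndimage import binary_dilation

            blocked |= binary_dilation(mask, iterations=gap) if gap else mask

    instance = _relabel_raster_order(instance)
    count = int(instance.max())
    class_mask = np.where(instance > 0, NUCLEI, BACKGROUND).astype(np.int64)

    bg = spec.class_spectra["background"]
    nuc = spec.class_spectra["nuclei"]
    ideal = np.empty((H, W, spec.n_bands))
    ideal[:] = bg  # broadcast over bands
    inside = instance > 0
    ideal[inside] = nuc
    if spec.texture_sd > 0 and inside.any():
        # chromatin texture: low-amplitude multiplicative field inside nuclei
        texture = 1.0 + spec.texture_sd * rng.standard_normal((H, W))
        ideal[inside] *= texture[inside][:, None]
    np.clip(ideal, 0.005, 0.995, out=ideal)

    return PhantomTruth(
        instance_map=instance,
        class_mask=class_mask,
        nucleus_count=count,
        injected_shifts=spec.band_shifts.copy(),
        ideal_cube=ideal,
        class_spectra={k: v.copy() for k, v in spec.class_spectra.items()},
        spec=spec,
    )


def _relabel_raster_order(instance: np.ndarray) -> np.ndarray:
    """Relabel surviving instances 1..K in raster order of first pixel."""
    flat = instance.ravel()
    labels, first = np.unique(flat, return_index=True)
    keep = labels > 0
    order = np.argsort(first[keep])
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    mapping[labels[keep][order]] = np.arange(1, keep.sum() + 1)
    return mapping[instance]


# --------------------------------------------------------------------------
# Forward line-scan rendering
# --------------------------------------------------------------------------

def render_linescan_frames(
    truth: PhantomTruth,
    sensor: SensorModel,
    references: ReferencePair,
    noise_sd: Optional[float] = None,
    shifts: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> RawScanSequence:
    """Render raw 8-bit line-scan frames from an ideal cube.

    Inverse of the preprocessing chain: ideal transmittance is expanded to
    virtual bands (replication right inverse of the correction matrix),
    per-band spatial shifts are injected (circular roll), the scene is
    sliced into wedge frames, converted to intensity through the white/dark
    references, and quantized to 8 bits.  Lines beyond the scene are blank
    glass (transmittance 1).
    """
    spec = truth.spec
    if shifts is None:
        shifts = truth.injected_shifts
    shifts = np.asarray(shifts, dtype=np.int64)
    if truth.ideal_cube.shape[2] != sensor.n_spectral_bands:
        raise RenderError(
            f"ideal cube has {truth.ideal_cube.shape[2]} bands but the sensor "
            f"defines {sensor.n_spectral_bands} spectral bands"
        )
    if shifts.shape != (sensor.n_spectral_bands, 2):
        raise RenderError("shifts must be (n_spectral_bands, 2)")
    H, W, _ = truth.ideal_cube.shape
    if np.any(np.abs(shifts[:, 0]) >= H) or np.any(np.abs(shifts[:, 1]) >= W):
        raise RenderError("shift magnitude must be smaller than the image dimension")
    white = references.white.astype(float)
    dark = references.dark.astype(float)
    if white.shape != (sensor.n_rows, W):
        raise RenderError("reference shape must match (sensor rows, scene width)")
    if not np.any(white > dark):
        raise RenderError("degenerate references: white equals dark everywhere")

    if noise_sd is None:
        noise_sd = spec.noise_sd
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    virtual = expand_to_virtual(truth.ideal_cube, sensor)
    band_spectral = spectral_band_of_virtual(sensor)
    for v in range(sensor.n_virtual_bands):
        dy, dx = shifts[band_spectral[v]]
        if dy or dx:
            virtual[:, :, v] = np.roll(virtual[:, :, v], (dy, dx), axis=(0, 1))
    if noise_sd > 0:
        virtual = virtual + noise_sd * rng.standard_normal(virtual.shape)

    max_o = sensor.max_offset
    n_frames = H + max_o
    # pad the scene with blank glass so edge frames index valid lines
    padded = np.ones((H + 2 * max_o, W, sensor.n_virtual_bands))
    padded[max_o : max_o + H] = virtual

    frames = np.empty((n_frames, sensor.n_rows, W), dtype=np.uint8)
    for r in range(sensor.n_rows):
        o = int(sensor.row_offset[r])
        v = int(sensor.row_to_band[r])
        # frame t, row r sees padded line t + o (scene line t + o - max_o)
        lines = padded[o : o + n_frames, :, v]
        intensity = dark[r] + lines * (white[r] - dark[r])
        frames[:, r, :] = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    return RawScanSequence(frames=frames, sensor=sensor)


# --------------------------------------------------------------------------
# Multi-cube suites with patient-level splits
# --------------------------------------------------------------------------

# Split fractions per tissue class mirroring the study design:
# tumor patients 5/2/3 of 10, healthy 15/2/3 of 20 (train/val/test).
SPLIT_FRACTIONS = {
    "tumor": (0.5, 0.2, 0.3),
    "healthy": (0.75, 0.1, 0.15),
}
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitSpec:
    """Patient-level split assignment (no patient appears in two splits)."""

    assignment: dict[str, str]  # patient id -> split name

    def patients(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def validate_no_leakage(self) -> None:
        sets = [set(self.patients(s)) for s in SPLIT_NAMES]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise SplitError("patient appears in multiple splits")


@dataclass
class PhantomCube:
    """One synthetic capture: normalized cube + truth + identity."""

    cube: HyperCube
    truth: PhantomTruth
    cube_id: str
    patient_id: str
    tissue_class: str


@dataclass
class PhantomDataset:
    cubes: list[PhantomCube]
    split: SplitSpec

    def subset(self, split: str) -> list[PhantomCube]:
        patients = set(self.split.patients(split))
        return [c for c in self.cubes if c.patient_id in patients]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    out = [int(np.floor(x)) for x in raw]
    rem = n - sum(out)
    order = np.argsort([o - x for o, x in zip(out, raw)])  # most negative first
    for i in range(rem):
        out[int(order[i])] += 1
    return out


def allocate_split(
    n_tumor: int,
    n_healthy: int,
    split_counts: Optional[dict[str, tuple[int, int, int]]] = None,
) -> dict[str, tuple[int, int, int]]:
    """Per-class (train, val, test) patient counts.

    Defaults mirror the study proportions; explicit counts override them.
    Raises :class:`SplitError` when any split would be empty overall.
    """
    default = split_counts is None
    if default:
        split_counts = {
            "tumor": tuple(_largest_remainder(n_tumor, SPLIT_FRACTIONS["tumor"])),
            "healthy": tuple(_largest_remainder(n_healthy, SPLIT_FRACTIONS["healthy"])),
        }
    for cls, n in (("tumor", n_tumor), ("healthy", n_healthy)):
        if sum(split_counts[cls]) != n:
            raise SplitError(f"{cls} split counts must sum to {n}")
    if default:
        # the standard design needs all three splits populated; explicit
        # counts may deliberately leave a split empty
        totals = [split_counts["tumor"][i] + split_counts["healthy"][i] for i in range(3)]
        if any(t == 0 for t in totals):
            raise SplitError(
                f"too few patients for a 3-way split (train/val/test = {totals})"
            )
    return split_counts


def phantom_suite(
    n_tumor: int,
    n_healthy: int,
    base_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
    split_counts: Optional[dict[str, tuple[int, int, int]]] = None,
) -> PhantomDataset:
    """Generate a multi-patient dataset with a leakage-free split.

    One synthetic patient per cube.  Each cube's scene seed is derived from
    the master seed via :class:`numpy.random.SeedSequence` spawning.  The
    delivered cube is the min–max normalized ideal cube plus sensor noise —
    i.e. what the preprocessing chain would deliver for a clean capture (the
    render/stitch round trip is exercised separately by the preprocessing
    tests rather than re-run for every cube).
    """
    if n_tumor < 0 or n_healthy < 0:
        raise ValueError("cube counts must be non-negative")
    if base_spec is None:
        base_spec = PhantomSpec()
    counts = allocate_split(n_tumor, n_healthy, split_counts)

    children = np.random.SeedSequence(seed).spawn(n_tumor + n_healthy)
    cube_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    classes = ["tumor"] * n_tumor + ["healthy"] * n_healthy
    assignment: dict[str, str] = {}
    per_class_index = {"tumor": 0, "healthy": 0}
    cubes: list[PhantomCube] = []
    for idx, tissue in enumerate(classes):
        i = per_class_index[tissue]
        per_class_index[tissue] += 1
        # deterministic block assignment within each class
        bounds = np.cumsum(counts[tissue])
        split = SPLIT_NAMES[int(np.searchsorted(bounds, i, side="right"))]
        patient_id = f"P{idx:03d}"
        cube_id = f"cube{idx:03d}"
        spec = replace(
            base_spec,
            tissue_class=tissue,
            nucleus_density=None if base_spec.tissue_class != tissue else base_spec.nucleus_density,
            seed=cube_seeds[idx],
        )
        truth = make_phantom_scene(spec)
        rng = np.random.default_rng(cube_seeds[idx] + 1)
        data = truth.ideal_cube + spec.noise_sd * rng.standard_normal(truth.ideal_cube.shape)
        lo, hi = data.min(), data.max()
        data = (data - lo) / (hi - lo)
        cube = HyperCube(
            data=data,
            wavelengths_nm=spec.wavelength_grid,
            meta={"cube_id": cube_id, "patient_id": patient_id, "tissue": tissue},
        )
        assignment[patient_id] = split
        cubes.append(
            PhantomCube(
                cube=cube,
                truth=truth,
                cube_id=cube_id,
                patient_id=patient_id,
                tissue_class=tissue,
            )
        )
    split_spec = SplitSpec(assignment=assignment)
    split_spec.validate_no_leakage()
    return PhantomDataset(cubes=cubes, split=split_spec)
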