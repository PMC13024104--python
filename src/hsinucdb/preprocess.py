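"""Six-step preprocessing: raw line-scan frames -> aligned, normalized cubes.

The chain mirrors how a wedge line-scan capture is turned into analysable
data:

1. **Calibration** — per-pixel transmittance against white/dark references,
   ``T = (frame - dark) / (white - dark)``.
2. **Stitching** — rearranging frame rows into a raw cube of virtual bands.
3. **Spectral correction** — multiplying by the (virtual x spectral)
   correction matrix.
4. **Shift correction** — phase-correlation registration of every band to
   the first band, translation, and cropping by the maximum shift; cubes
   whose estimated shift exceeds a threshold (default 100 px) are discarded.
5. **Normalization** — global min–max scaling to [0, 1].
6. **RGB synthesis** — a 3-channel image from the bands nearest the
   reference red/green/blue wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import RGB_TARGETS_NM, HsinucdbError, HyperCube
from .phantom import RawScanSequence, ReferencePair, SensorModel


class CalibrationError(HsinucdbError):
    pass


class StitchError(HsinucdbError):
    pass


class UndefinedShiftError(HsinucdbError):
    pass


class NormalizationError(HsinucdbError):
    pass


# --------------------------------------------------------------------------
# Step 1: calibration
# --------------------------------------------------------------------------

def calibrate_frames(raw: RawScanSequence, refs: ReferencePair) -> np.ndarray:
    """Convert raw frames to transmittance using white/dark references.

    Pixels where ``white == dark`` (dead pixels) are set to 0; negative
    values are clamped to 0.  Returns a float array of shape
    ``(n_frames, rows, width)``.
    """
    frames = raw.frames.astype(float)
    white = refs.white.astype(float)
    dark = refs.dark.astype(float)
    if white.shape != frames.shape[1:]:
        raise CalibrationError(
            f"reference shape {white.shape} does not match frame shape {frames.shape[1:]}"
        )
    denom = white - dark
    dead = denom == 0
    if dead.all():
        raise CalibrationError("white and dark references are identical everywhere")
    safe = np.where(dead, 1.0, denom)
    trans = (frames - dark) / safe
    trans[:, dead] = 0.0
    np.clip(trans, 0.0, None, out=trans)
    return trans


# --------------------------------------------------------------------------
# Step 2: stitching
# --------------------------------------------------------------------------

def stitch(calibrated: np.ndarray, sensor: SensorModel) -> HyperCube:
    """Reassemble calibrated frames into a cube of virtual bands.

    Frame ``t``, sensor row ``r`` carries scan line
    ``t * scan_step + row_offset[r]`` of virtual band ``row_to_band[r]``.
    Only lines sampled by every band are kept, so the stitched height is
    ``n_frames * scan_step - max(row_offset)`` (edges trimmed).
    """
    calibrated = np.asarray(calibrated, dtype=float)
    if calibrated.ndim != 3 or calibrated.shape[1] != sensor.n_rows:
        raise StitchError("calibrated frames must be (T, sensor rows, W)")
    n_frames, _, width = calibrated.shape
    max_o = sensor.max_offset
    height = n_frames * sensor.scan_step - max_o
    if height <= 0:
        raise StitchError(
            f"insufficient frames: {n_frames} frames cover no fully sampled lines"
        )
    cube = np.zeros((height, width, sensor.n_virtual_bands))
    hits = np.zeros(sensor.n_virtual_bands, dtype=np.int64)
    for r in range(sensor.n_rows):
        v = int(sensor.row_to_band[r])
        o = int(sensor.row_offset[r])
        # stitched line y corresponds to scan coordinate y + max_o
        # -> frame index t = (y + max_o - o) / scan_step
        t0 = max_o - o
        if sensor.scan_step == 1:
            block = calibrated[t0 : t0 + height, r, :]
        else:
            idx = t0 + np.arange(height) * sensor.scan_step
            block = calibrated[idx, r, :]
        if hits[v] == 0:
            cube[:, :, v] = block
        else:  # several rows sense the same band: average them
            cube[:, :, v] += block
        hits[v] += 1
    cube /= hits[None, None, :]
    # virtual-band placeholder grid (strictly increasing indices)
    grid = np.arange(sensor.n_virtual_bands, dtype=float)
    return HyperCube(data=cube, wavelengths_nm=grid, meta={"stage": "virtual"})


# --------------------------------------------------------------------------
# Step 3: spectral correction
# --------------------------------------------------------------------------

def apply_spectral_correction(
    cube: HyperCube,
    matrix: np.ndarray,
    wavelengths_nm: Optional[np.ndarray] = None,
) -> HyperCube:
    """Contract the virtual-band axis with the correction matrix.

    ``out[y, x, s] = sum_v cube[y, x, v] * M[v, s]``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if cube.data is None or cube.data.shape[2] != matrix.shape[0]:
        raise HsinucdbError(
            f"cube band count does not match correction matrix rows {matrix.shape[0]}"
        )
    out = np.tensordot(cube.data, matrix, axes=([2], [0]))
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(matrix.shape[1], dtype=float)
    meta = dict(cube.meta)
    meta["stage"] = "spectral"
    meta["log"] = list(cube.meta.get("log", []))
    return HyperCube(data=out, wavelengths_nm=wavelengths_nm, meta=meta)


# --------------------------------------------------------------------------
# Step 4: shift estimation and correction
# --------------------------------------------------------------------------

def estimate_band_shift(band_img: np.ndarray, ref_img: np.ndarray) -> tuple[int, int]:
    """Integer translation of ``band_img`` relative to ``ref_img``.

    Uses phase correlation; the subpixel peak is rounded to the nearest
    integer.  If ``band_img == roll(ref_img, (dy, dx))``, returns
    ``(dy, dx)``.
    """
    band_img = np.asarray(band_img, dtype=float)
    ref_img = np.asarray(ref_img, dtype=float)
    if band_img.shape != ref_img.shape:
        raise HsinucdbError("band and reference images must share shape")
    if np.ptp(band_img) == 0 or np.ptp(ref_img) == 0:
        raise UndefinedShiftError("shift is undefined for a constant image")
    shift, _, _ = phase_cross_correlation(band_img, ref_img, normalization=None)
    dy, dx = (int(np.round(s)) for s in shift)
    return dy, dx


def correct_shifts(cube: HyperCube, threshold_px: int = 100) -> HyperCube:
    """Register every band to the first band and crop the shift margins.

    Each band is translated by the negated estimated shift (constant fill,
    no wrap-around) and the cube is cropped by the extreme shifts per axis,
    which removes every filled pixel.  If any estimated shift component
    exceeds ``threshold_px`` in magnitude the cube is marked ``discarded``
    and no aligned data is returned.
    """
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    if cube.data.shape[2] < 2:
        raise HsinucdbError("shift correction requires at least two bands")
    anchor = cube.data[:, :, 0]
    n_bands = cube.data.shape[2]
    shifts = np.zeros((n_bands, 2), dtype=np.int64)
    for b in range(1, n_bands):
        shifts[b] = estimate_band_shift(cube.data[:, :, b], anchor)
    meta = dict(cube.meta)
    meta["log"] = list(cube.meta.get("log", []))
    meta["band_shifts"] = shifts.copy()
    for b in range(1, n_bands):
        meta["log"].append(f"band {b}: estimated shift {tuple(shifts[b])}")

    if np.abs(shifts).max() > threshold_px:
        meta["log"].append(
            f"max |shift| {np.abs(shifts).max()} exceeds threshold {threshold_px}: cube discarded"
        )
        return HyperCube(
            data=None, wavelengths_nm=cube.wavelengths_nm, status="discarded", meta=meta
        )

    aligned = np.empty_like(cube.data)
    aligned[:, :, 0] = anchor
    for b in range(1, n_bands):
        dy, dx = shifts[b]
        if dy == 0 and dx == 0:
            aligned[:, :, b] = cube.data[:, :, b]
        else:
            aligned[:, :, b] = ndimage.shift(
                cube.data[:, :, b], (-dy, -dx), order=0, mode="constant", cval=0.0
            )
    # fill appears at the bottom/right for positive shifts and at the
    # top/left for negative ones; crop the extremes per axis
    top = int(max(-shifts[:, 0].min(), 0))
    bottom = int(max(shifts[:, 0].max(), 0))
    left = int(max(-shifts[:, 1].min(), 0))
    right = int(max(shifts[:, 1].max(), 0))
    H, W = aligned.shape[:2]
    aligned = aligned[top : H - bottom or None, left : W - right or None]
    meta["log"].append(f"crop margins (top,bottom,left,right)=({top},{bottom},{left},{right})")
    return HyperCube(data=aligned, wavelengths_nm=cube.wavelengths_nm, meta=meta)


# --------------------------------------------------------------------------
# Step 5: normalization
# --------------------------------------------------------------------------

def minmax_normalize(cube: HyperCube, mode: str = "global") -> HyperCube:
    """Min–max normalize to [0, 1].

    ``mode='global'`` (default) uses one (min, max) pair for the whole
    cube, which preserves relative band intensities; ``mode='per_band'``
    normalizes each band independently.
    """
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    data = cube.data.astype(float)
    if mode == "global":
        lo, hi = float(data.min()), float(data.max())
        if hi <= lo:
            raise NormalizationError("cannot normalize a constant cube")
        out = (data - lo) / (hi - lo)
    elif mode == "per_band":
        lo = data.min(axis=(0, 1), keepdims=True)
        hi = data.max(axis=(0, 1), keepdims=True)
        if np.any(hi <= lo):
            raise NormalizationError("cannot normalize a constant band")
        out = (data - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization mode '{mode}'")
    meta = dict(cube.meta)
    meta["log"] = list(cube.meta.get("log", [])) + [f"minmax normalized ({mode})"]
    return HyperCube(data=out, wavelengths_nm=cube.wavelengths_nm, meta=meta)


# --------------------------------------------------------------------------
# Step 6: RGB synthesis
# --------------------------------------------------------------------------

def synthesize_rgb(
    cube: HyperCube,
    targets_nm: tuple[float, float, float] = RGB_TARGETS_NM,
    as_uint8: bool = False,
) -> np.ndarray:
    """Pick the bands nearest the reference R/G/B wavelengths.

    Targets outside the wavelength grid clamp to the nearest grid end.
    Returns an ``H x W x 3`` array in (R, G, B) channel order.
    """
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    if cube.wavelengths_nm.size == 0:
        raise HsinucdbError("cube has no wavelength grid")
    idx = [int(np.argmin(np.abs(cube.wavelengths_nm - t))) for t in targets_nm]
    rgb = np.stack([cube.data[:, :, i] for i in idx], axis=-1)
    if as_uint8:
        rgb = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return rgb


def rgb_band_indices(
    wavelengths_nm: np.ndarray,
    targets_nm: tuple[float, float, float] = RGB_TARGETS_NM,
) -> tuple[int, int, int]:
    """Band indices selected for the (R, G, B) channels."""
    w = np.asarray(wavelengths_nm, dtype=float)
    return tuple(int(np.argmin(np.abs(w - t))) for t in targets_nm)


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    cube: HyperCube
    rgb: Optional[np.ndarray]
    log: list[str] = field(default_factory=list)

    @property
    def discarded(self) -> bool:
        return self.cube.status == "discarded"


def preprocess_pipeline(
    raw: RawScanSequence,
    refs: ReferencePair,
    matrix: np.ndarray,
    sensor: SensorModel,
    threshold_px: int = 100,
    normalize_mode: str = "global",
) -> PreprocessResult:
    """Chain steps 1–6 and collect a processing log.

    Discarded cubes (shift threshold exceeded) are reported in the result,
    not raised.
    """
    calibrated = calibrate_frames(raw, refs)
    virtual = stitch(calibrated, sensor)
    virtual.log(f"stitched {raw.frames.shape[0]} frames -> {virtual.data.shape}")
    spectral = apply_spectral_correction(virtual, matrix, sensor.wavelength_grid)
    aligned = correct_shifts(spectral, threshold_px=threshold_px)
    if aligned.status == "discarded":
        return PreprocessResult(cube=aligned, rgb=None, log=list(aligned.meta["log"]))
    normalized = minmax_normalize(aligned, mode=normalize_mode)
    rgb = synthesize_rgb(normalized)
    normalized.log("synthesized RGB")
    return PreprocessResult(cube=normalized, rgb=rgb, log=list(normalized.meta["log"]))
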