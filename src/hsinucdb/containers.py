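"""Core in-memory containers shared across the pipeline.

A :class:`HyperCube` is the central object: an ``H x W x B`` float array of
transmittance (or normalized) values with a strictly increasing wavelength
axis and provenance metadata.  Segmentation maps and instance maps are plain
``numpy`` integer arrays with conventions documented in
:data:`BACKGROUND` / :data:`BORDER` / :data:`NUCLEI`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

# Class codes used by every segmentation map in the package.
BACKGROUND = 0
BORDER = 1
NUCLEI = 2

# Spectral range of the line-scan camera, in nm.
WAVELENGTH_MIN_NM = 470.0
WAVELENGTH_MAX_NM = 890.0

# Reference wavelengths for synthetic RGB rendering (R, G, B order).
RGB_TARGETS_NM = (605.61, 543.65, 462.14)


class HsinucdbError(Exception):
    """Base class for all package errors."""


@dataclass
class HyperCube:
    """Hyperspectral cube with wavelength axis and provenance.

    Parameters
    ----------
    data:
        ``H x W x B`` float array, or ``None`` for a discarded cube.
    wavelengths_nm:
        ``B`` strictly increasing wavelengths in nm.
    status:
        ``"ok"`` or ``"discarded"`` (set by shift correction when the
        registration threshold is exceeded).
    meta:
        Free-form provenance: cube id, patient id, tissue label and a
        ``log`` list of processing messages.
    """

    data: Optional[np.ndarray]
    wavelengths_nm: np.ndarray
    status: str = "ok"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be one-dimensional")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.data is not None:
            self.data = np.asarray(self.data)
            if self.data.ndim != 3:
                raise ValueError("cube data must be H x W x B")
            if self.data.shape[2] != self.wavelengths_nm.shape[0]:
                raise ValueError(
                    f"band count {self.data.shape[2]} does not match "
                    f"wavelength grid length {self.wavelengths_nm.shape[0]}"
                )
        self.meta.setdefault("log", [])

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.shape[0])

    @property
    def shape(self) -> tuple[int, ...]:
        if self.data is None:
            return ()
        return tuple(self.data.shape)

    def log(self, message: str) -> None:
        self.meta["log"].append(message)


def validate_segmap(seg: np.ndarray) -> np.ndarray:
    """Check a segmentation map and return it as ``int`` array."""
    seg = np.asarray(seg)
    if seg.ndim != 2:
        raise ValueError("segmentation map must be 2-D")
    bad = np.setdiff1d(np.unique(seg), [BACKGROUND, BORDER, NUCLEI])
    if bad.size:
        raise ValueError(f"segmentation map contains invalid labels {bad}")
    return seg.astype(np.int64, copy=False)


def validate_instance_map(instances: np.ndarray) -> np.ndarray:
    instances = np.asarray(instances)
    if instances.ndim != 2:
        raise ValueError("instance map must be 2-D")
    if instances.min(initial=0) < 0:
        raise ValueError("instance labels must be non-negative")
    return instances.astype(np.int64, copy=False)
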