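"""On-disk formats: band-major multipage TIFF cubes with YAML sidecars,
paletted PNG masks, CSV truth tables and sensor-model YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .containers import HsinucdbError, HyperCube
from .phantom import SensorModel


def write_cube(cube: HyperCube, path) -> None:
    """Write a cube as band-major multipage TIFF plus a ``.yaml`` sidecar."""
    if cube.data is None:
        raise HsinucdbError("cannot write a discarded cube")
    path = Path(path)
    tifffile.imwrite(
        path,
        np.moveaxis(cube.data, -1, 0).astype(np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths_nm],
        "status": cube.status,
        "meta": {k: v for k, v in cube.meta.items() if isinstance(v, (str, int, float, list))},
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_cube(path) -> HyperCube:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, -1).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if sidecar_path.exists():
        sidecar = yaml.safe_load(sidecar_path.read_text())
        wavelengths = np.asarray(sidecar["wavelengths_nm"], dtype=float)
        meta = dict(sidecar.get("meta", {}))
        status = sidecar.get("status", "ok")
    else:
        wavelengths = np.arange(data.shape[2], dtype=float)
        meta, status = {}, "ok"
    return HyperCube(data=data, wavelengths_nm=wavelengths, status=status, meta=meta)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1,2} label image as single-channel PNG."""
    iio.imwrite(Path(path), np.asarray(mask).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int64)


def write_sensor(sensor: SensorModel, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "n_virtual_bands": sensor.n_virtual_bands,
                "n_spectral_bands": sensor.n_spectral_bands,
                "row_to_band": sensor.row_to_band.tolist(),
                "row_offset": sensor.row_offset.tolist(),
                "wavelength_grid": [float(w) for w in sensor.wavelength_grid],
                "scan_step": sensor.scan_step,
            }
        )
    )


def read_sensor(path) -> SensorModel:
    d = yaml.safe_load(Path(path).read_text())
    return SensorModel(
        n_virtual_bands=d["n_virtual_bands"],
        n_spectral_bands=d["n_spectral_bands"],
        row_to_band=np.asarray(d["row_to_band"]),
        row_offset=np.asarray(d["row_offset"]),
        wavelength_grid=np.asarray(d["wavelength_grid"]),
        scan_step=d.get("scan_step", 1),
    )


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(Path(path), matrix, delimiter=",")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",")
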