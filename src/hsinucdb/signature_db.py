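"""Hyperspectral nuclei database: per-nucleus mean spectral signatures.

A segmentation map is turned into an instance map by grouping spatially
adjacent nucleus pixels (8-connectivity); each instance contributes one
record holding its mean spectrum over the normalized cube, its area and
centroid, and a diagnosis label joined from a clinical metadata table on
patient id.  Averaging over the instance suppresses pixel-level noise and
gives one stable signature per cell.  Border-class pixels never enter a
signature: they are auxiliary boundary markers, not nuclear material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import NUCLEI, HsinucdbError, HyperCube, validate_segmap
from .evaluation import EIGHT_CONNECTED

SCHEMA_VERSION = 1


class LabelingError(HsinucdbError):
    pass


class SchemaError(HsinucdbError):
    pass


# --------------------------------------------------------------------------
# instance labeling
# --------------------------------------------------------------------------

def label_instances(seg: np.ndarray) -> np.ndarray:
    """Label 8-connected nuclei components 1..K in raster order.

    Border and background pixels map to 0.  The instance count always
    equals :func:`hsinucdb.evaluation.count_instances` on the same map.
    """
    seg = validate_segmap(seg)
    labeled, n = ndimage.label(seg == NUCLEI, structure=EIGHT_CONNECTED)
    if n == 0:
        return labeled.astype(np.int64)
    # enforce raster order of each component's first pixel
    flat = labeled.ravel()
    labels, first = np.unique(flat, return_index=True)
    keep = labels > 0
    order = np.argsort(first[keep])
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    mapping[labels[keep][order]] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labeled]


# --------------------------------------------------------------------------
# signature extraction
# --------------------------------------------------------------------------

@dataclass
class SignatureRecord:
    cube_id: str
    patient_id: str
    instance_id: int
    area: int
    centroid: tuple[float, float]
    mean_spectrum: np.ndarray
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("instance area must be >= 1")
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)


def extract_mean_signatures(
    cube: HyperCube, instances: np.ndarray
) -> list[SignatureRecord]:
    """One record per instance: per-band arithmetic mean over its pixels."""
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    instances = np.asarray(instances)
    if instances.shape != cube.data.shape[:2]:
        raise HsinucdbError("instance map shape must match cube spatial shape")
    n = int(instances.max())
    records: list[SignatureRecord] = []
    if n == 0:
        return records
    cube_id = str(cube.meta.get("cube_id", "cube"))
    patient_id = str(cube.meta.get("patient_id", "unknown"))
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(instances), instances, ids)
    cys = ndimage.mean(np.arange(instances.shape[0])[:, None] * np.ones_like(instances, dtype=float), instances, ids)
    cxs = ndimage.mean(np.arange(instances.shape[1])[None, :] * np.ones_like(instances, dtype=float), instances, ids)
    B = cube.data.shape[2]
    means = np.empty((n, B))
    for b in range(B):
        means[:, b] = ndimage.mean(cube.data[:, :, b], instances, ids)
    for i, inst in enumerate(ids):
        records.append(
            SignatureRecord(
                cube_id=cube_id,
                patient_id=patient_id,
                instance_id=int(inst),
                area=int(areas[i]),
                centroid=(float(cys[i]), float(cxs[i])),
                mean_spectrum=means[i],
            )
        )
    return records


# --------------------------------------------------------------------------
# clinical auto-labeling
# --------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Patient id -> diagnosis mapping (ids unique)."""

    diagnoses: dict[str, str]

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, dtype=str)
        if df["patient_id"].duplicated().any():
            raise SchemaError("duplicate patient ids in clinical table")
        return cls(diagnoses=dict(zip(df["patient_id"], df["diagnosis"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"patient_id": list(self.diagnoses), "diagnosis": list(self.diagnoses.values())}
        ).to_csv(path, index=False)


def auto_label(
    records: Sequence[SignatureRecord], clinical: ClinicalTable
) -> list[SignatureRecord]:
    """Copy each patient's diagnosis onto their records.

    Raises :class:`LabelingError` naming every unresolvable patient id.
    """
    missing = sorted({r.patient_id for r in records} - set(clinical.diagnoses))
    if missing:
        raise LabelingError(f"no diagnosis for patient ids: {missing}")
    out = []
    for r in records:
        out.append(
            SignatureRecord(
                cube_id=r.cube_id,
                patient_id=r.patient_id,
                instance_id=r.instance_id,
                area=r.area,
                centroid=r.centroid,
                mean_spectrum=r.mean_spectrum.copy(),
                diagnosis=clinical.diagnoses[r.patient_id],
            )
        )
    return out


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def _band_columns(wavelengths_nm: np.ndarray) -> list[str]:
    return [f"band_{w:.2f}nm" for w in wavelengths_nm]


def records_to_frame(
    records: Sequence[SignatureRecord], wavelengths_nm: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Wide-format table: one row per nucleus, one column per band."""
    widths = {r.mean_spectrum.shape[0] for r in records}
    if len(widths) > 1:
        raise SchemaError(f"inconsistent spectrum widths across records: {sorted(widths)}")
    n_bands = widths.pop() if widths else (len(wavelengths_nm) if wavelengths_nm is not None else 0)
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(n_bands, dtype=float)
    if len(wavelengths_nm) != n_bands:
        raise SchemaError("wavelength grid length does not match spectrum width")
    base = pd.DataFrame(
        {
            "schema_version": SCHEMA_VERSION,
            "cube_id": [r.cube_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "instance_id": [r.instance_id for r in records],
            "area": [r.area for r in records],
            "centroid_y": [r.centroid[0] for r in records],
            "centroid_x": [r.centroid[1] for r in records],
            "diagnosis": [r.diagnosis for r in records],
        },
        index=range(len(records)),
    )
    spec = pd.DataFrame(
        np.vstack([r.mean_spectrum for r in records]) if records else np.empty((0, n_bands)),
        columns=_band_columns(np.asarray(wavelengths_nm)),
        index=base.index,
    )
    df = pd.concat([base, spec], axis=1)
    if not records:
        df["schema_version"] = pd.Series(dtype=int)
        df = df.astype({"schema_version": "int64"}, errors="ignore")
    return df


def frame_to_records(df: pd.DataFrame) -> tuple[list[SignatureRecord], np.ndarray]:
    band_cols = [c for c in df.columns if c.startswith("band_")]
    required = {"schema_version", "cube_id", "patient_id", "instance_id", "area",
                "centroid_y", "centroid_x", "diagnosis"}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing columns: {sorted(required - set(df.columns))}")
    if len(df) and not (df["schema_version"] == SCHEMA_VERSION).all():
        raise SchemaError("unsupported schema version")
    wavelengths = np.array([float(c[len("band_"):-2]) for c in band_cols])
    records = []
    for _, row in df.iterrows():
        diag = row["diagnosis"]
        records.append(
            SignatureRecord(
                cube_id=str(row["cube_id"]),
                patient_id=str(row["patient_id"]),
                instance_id=int(row["instance_id"]),
                area=int(row["area"]),
                centroid=(float(row["centroid_y"]), float(row["centroid_x"])),
                mean_spectrum=row[band_cols].to_numpy(dtype=float),
                diagnosis=None if pd.isna(diag) else str(diag),
            )
        )
    return records, wavelengths


def write_db(
    records: Sequence[SignatureRecord],
    path,
    wavelengths_nm: Optional[np.ndarray] = None,
) -> None:
    """Write the signature database (CSV, or Parquet for ``.parquet`` paths)."""
    df = records_to_frame(records, wavelengths_nm)
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_db(path) -> list[SignatureRecord]:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    records, _ = frame_to_records(df)
    return records


def build_database(
    cubes_and_segs: Sequence[tuple[HyperCube, np.ndarray]],
    clinical: ClinicalTable,
) -> list[SignatureRecord]:
    """Full build: label instances, extract signatures, join diagnoses.

    Cubes are processed in canonical (cube id) order so the database does
    not depend on input ordering.
    """
    ordered = sorted(cubes_and_segs, key=lambda cs: str(cs[0].meta.get("cube_id", "")))
    records: list[SignatureRecord] = []
    for cube, seg in ordered:
        instances = label_instances(seg)
        records.extend(extract_mean_signatures(cube, instances))
    return auto_label(records, clinical)
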