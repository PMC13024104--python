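"""Method 1 — spectral-only per-pixel nucleus classification.

Each pixel's spectrum is treated as an independent sample: cubes are
flattened to an ``N x B`` table, the heavy background majority is
undersampled to class balance, and a gradient-boosted decision-tree
classifier (XGBoost) is trained to separate nucleus from background
spectra.  Hyperparameters are tuned by random search over the standard
ranges (number of estimators 100–2000, depth 5–15, learning rate
0.01–0.5), maximizing the validation Dice of the nuclei class computed
per cube and averaged.  The border class never exists at this stage:
segmentation maps are two-class {background, nuclei}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from xgboost import XGBClassifier

from .containers import BACKGROUND, NUCLEI, HsinucdbError, HyperCube, validate_segmap


class ClassAbsentError(HsinucdbError):
    pass


# --------------------------------------------------------------------------
# pixel tables
# --------------------------------------------------------------------------

@dataclass
class PixelTable:
    """Flattened pixel spectra with binary labels and per-row origin."""

    spectra: np.ndarray  # N x B
    labels: np.ndarray  # N, values in {BACKGROUND, NUCLEI}
    origin: np.ndarray  # N x 3 structured-ish: (cube index, y, x)
    cube_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.labels = np.asarray(self.labels)
        if self.spectra.ndim != 2 or self.labels.shape != (self.spectra.shape[0],):
            raise ValueError("spectra must be N x B with N labels")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, NUCLEI])
        if bad.size:
            raise ValueError(f"labels must be binary background/nuclei, got {bad}")

    def class_counts(self) -> dict[int, int]:
        return {
            BACKGROUND: int((self.labels == BACKGROUND).sum()),
            NUCLEI: int((self.labels == NUCLEI).sum()),
        }


def flatten_cube(
    cube: HyperCube, mask: Optional[np.ndarray] = None, cube_index: int = 0
) -> PixelTable:
    """Flatten a cube to a pixel table in raster order.

    Border pixels in the mask (if any) are mapped to background, since this
    method is strictly two-class.
    """
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    H, W, B = cube.data.shape
    spectra = cube.data.reshape(H * W, B)
    if mask is not None:
        mask = validate_segmap(mask)
        if mask.shape != (H, W):
            raise HsinucdbError("mask shape does not match cube spatial shape")
        labels = np.where(mask == NUCLEI, NUCLEI, BACKGROUND).reshape(-1)
    else:
        labels = np.full(H * W, BACKGROUND, dtype=np.int64)
    ys, xs = np.divmod(np.arange(H * W), W)
    origin = np.column_stack([np.full(H * W, cube_index), ys, xs])
    return PixelTable(
        spectra=spectra, labels=labels, origin=origin,
        cube_ids=[str(cube.meta.get("cube_id", cube_index))],
    )


def concat_tables(tables: Sequence[PixelTable]) -> PixelTable:
    return PixelTable(
        spectra=np.concatenate([t.spectra for t in tables]),
        labels=np.concatenate([t.labels for t in tables]),
        origin=np.concatenate([t.origin for t in tables]),
        cube_ids=[cid for t in tables for cid in t.cube_ids],
    )


# --------------------------------------------------------------------------
# class balancing
# --------------------------------------------------------------------------

def balanced_class_counts(counts: Mapping[str, int] | Mapping[int, int]) -> dict:
    """Per-class sample counts after undersampling to the minority class.

    Pure bookkeeping rule shared by :func:`undersample_balance`: every class
    is brought down to the minority count, so all post-balance counts equal
    ``min(counts)`` and the total is ``n_classes * min(counts)``.
    """
    if not counts:
        raise ValueError("no class counts given")
    m = min(counts.values())
    out = {k: m for k in counts}
    out["total"] = m * len(counts)
    return out


def undersample_balance(table: PixelTable, seed: int = 0) -> PixelTable:
    """Randomly subsample the majority class down to the minority count."""
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ClassAbsentError(f"both classes must be present, got counts {counts}")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (BACKGROUND, NUCLEI):
        idx = np.flatnonzero(table.labels == cls)
        if idx.size > m:
            idx = rng.choice(idx, size=m, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    return PixelTable(
        spectra=table.spectra[keep],
        labels=table.labels[keep],
        origin=table.origin[keep],
        cube_ids=list(table.cube_ids),
    )


# --------------------------------------------------------------------------
# boosted-tree classifier
# --------------------------------------------------------------------------

@dataclass
class BoostParams:
    n_estimators: int = 300
    max_depth: int = 5
    learning_rate: float = 0.1

    def validate_in_search_space(self, space: "BoostSearchSpace") -> bool:
        return (
            space.n_estimators[0] <= self.n_estimators <= space.n_estimators[1]
            and space.max_depth[0] <= self.max_depth <= space.max_depth[1]
            and space.learning_rate[0] <= self.learning_rate <= space.learning_rate[1]
        )


@dataclass
class BoostSearchSpace:
    """Hyperparameter search ranges for the boosted-tree classifier."""

    n_estimators: tuple[int, int] = (100, 2000)
    max_depth: tuple[int, int] = (5, 15)
    learning_rate: tuple[float, float] = (0.01, 0.5)
    n_trials: int = 25
    seed: int = 0


# tuned values reported for the full-scale study
FULLSCALE_TUNED_PARAMS = BoostParams(n_estimators=1187, max_depth=5, learning_rate=0.011)


def train_pixel_classifier(
    train: PixelTable, params: Optional[BoostParams] = None, seed: int = 0
) -> XGBClassifier:
    """Fit the boosted-tree pixel classifier on a (preferably balanced) table."""
    if train.spectra.shape[0] == 0:
        raise HsinucdbError("empty training table")
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ClassAbsentError(f"training table must contain both classes: {counts}")
    if params is None:
        params = BoostParams()
    model = XGBClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        n_jobs=1,
        random_state=seed,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(train.spectra, (train.labels == NUCLEI).astype(np.int64))
    return model


def predict_pixel_map(model: XGBClassifier, cube: HyperCube) -> np.ndarray:
    """Predict a two-class {0, 2} segmentation map with the cube's shape."""
    if cube.data is None:
        raise HsinucdbError("cube has no data")
    H, W, B = cube.data.shape
    if B != model.n_features_in_:
        raise HsinucdbError(
            f"cube has {B} bands but the model was trained on {model.n_features_in_}"
        )
    pred = model.predict(cube.data.reshape(H * W, B))
    return np.where(pred.reshape(H, W) == 1, NUCLEI, BACKGROUND).astype(np.int64)


def tune_pixel_classifier(
    space: BoostSearchSpace,
    train: PixelTable,
    val_pairs: Sequence[tuple[HyperCube, np.ndarray]],
    train_patients: Optional[set] = None,
    val_patients: Optional[set] = None,
) -> tuple[BoostParams, list[dict]]:
    """Random search maximizing per-cube-averaged validation nuclei Dice.

    Returns the best parameters and the trial history.  When patient sets
    are provided, train/validation disjointness is enforced.
    """
    from .evaluation import region_dsc

    if space.n_trials < 1:
        raise ValueError("search space must allow at least one trial")
    if train_patients is not None and val_patients is not None:
        if train_patients & val_patients:
            raise HsinucdbError("validation patients overlap training patients")
    rng = np.random.default_rng(space.seed)
    history: list[dict] = []
    best: Optional[BoostParams] = None
    best_score = -np.inf
    for trial in range(space.n_trials):
        params = BoostParams(
            n_estimators=int(rng.integers(space.n_estimators[0], space.n_estimators[1] + 1)),
            max_depth=int(rng.integers(space.max_depth[0], space.max_depth[1] + 1)),
            learning_rate=float(
                np.exp(rng.uniform(np.log(space.learning_rate[0]), np.log(space.learning_rate[1])))
            ),
        )
        model = train_pixel_classifier(train, params, seed=space.seed)
        preds = [predict_pixel_map(model, cube) for cube, _ in val_pairs]
        gts = [np.where(gt == NUCLEI, NUCLEI, BACKGROUND) for _, gt in val_pairs]
        dsc = region_dsc(preds, gts, classes=(NUCLEI,))[NUCLEI]
        history.append({"trial": trial, "params": params, "nuclei_dsc": dsc})
        if dsc > best_score:
            best_score = dsc
            best = params
    return best, history
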