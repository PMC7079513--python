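"""File formats used at the module boundaries.

Plain, inspectable formats throughout: 8-bit PNG/TIFF for images, CSV for
centers (`cell_id,row,col[,score]`), clinical tables
(`patient_id,days_to_death,days_to_last_followup`), cohorts
(`patient_id,time_days,event,f_1..f_M`) and patient vectors, NPY for
confidence maps and descriptor/codebook matrices (with a JSON sidecar for
metadata).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "save_image",
    "load_image",
    "save_centers",
    "load_centers",
    "save_cohort",
    "load_cohort",
    "save_matrix",
    "load_matrix",
    "save_json",
    "load_json",
    "sha256_file",
]


def save_image(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, float), 0, 1)
    iio.imwrite(str(path), (arr * 255).round().astype(np.uint8))


def load_image(path) -> np.ndarray:
    arr = iio.imread(str(path))
    if arr.ndim == 3:  # RGB(A) -> grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float) / 255.0


def save_centers(path, centers: np.ndarray, scores: np.ndarray | None = None,
                 class_labels: np.ndarray | None = None) -> None:
    centers = np.asarray(centers).reshape(-1, 2)
    df = pd.DataFrame(
        {"cell_id": np.arange(len(centers)), "row": centers[:, 0],
         "col": centers[:, 1]}
    )
    if scores is not None:
        df["score"] = scores
    if class_labels is not None:
        df["class"] = class_labels
    df.to_csv(path, index=False)


def load_centers(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy(dtype=int)


def save_cohort(path, patient_ids, times, deltas, F: np.ndarray) -> None:
    F = np.atleast_2d(np.asarray(F, float))
    df = pd.DataFrame(F, columns=[f"f_{m + 1}" for m in range(F.shape[1])])
    df.insert(0, "event", np.asarray(deltas, int))
    df.insert(0, "time_days", np.asarray(times, float))
    df.insert(0, "patient_id", list(patient_ids))
    df.to_csv(path, index=False)


def load_cohort(path):
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f_")]
    return (
        df["patient_id"].tolist(),
        df["time_days"].to_numpy(float),
        df["event"].to_numpy(int),
        df[fcols].to_numpy(float),
    )


def save_matrix(path, matrix: np.ndarray, meta: dict | None = None) -> None:
    """NPY array with an optional JSON sidecar (<path>.json)."""
    np.save(str(path), np.asarray(matrix))
    if meta is not None:
        save_json(str(path) + ".json", meta)


def load_matrix(path) -> np.ndarray:
    return np.load(str(path))


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_json(path):
    return json.loads(Path(path).read_text())


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
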