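"""File formats: TIFF kymographs with JSON sidecars, tracer CSVs, 1D curves.

* Kymographs: grayscale float32 TIFF (axis 0 = time, axis 1 = space) plus an
  adjacent ``<name>.json`` sidecar holding the physical calibration and the
  generator's ground truth — calibration lives in the sidecar rather than in
  TIFF tags for portability.
* Tracer tracks: CSV with header ``track,t_s,x_um,y_um``.
* 1D scattering curves: whitespace-delimited text, columns
  ``q_nm_inv  I  sigma``; ``#`` lines are comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bleach import Kymograph
from .saxs_model import ScatteringCurve

TRACK_COLUMNS = ["track", "t_s", "x_um", "y_um"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_kymograph(kymo: Kymograph, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32))
    meta = dict(kymo.meta)
    meta.setdefault("pixel_size_um", kymo.pixel_size)
    meta.setdefault("frame_interval_s", kymo.frame_interval)
    meta.setdefault("bleach_frame", kymo.bleach_frame)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_kymograph(path) -> Kymograph:
    path = Path(path)
    intensity = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    return Kymograph(intensity=intensity,
                     pixel_size=meta["pixel_size_um"],
                     frame_interval=meta["frame_interval_s"],
                     bleach_frame=int(meta["bleach_frame"]),
                     meta=meta)


def save_tracks(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=TRACK_COLUMNS)
    return path


def load_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    return df


def save_curve(curve: ScatteringCurve, path, comment: str = "") -> Path:
    path = Path(path)
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    header = (comment + "\n" if comment else "") + "q_nm_inv I sigma"
    np.savetxt(path, np.column_stack([curve.q, curve.I, sigma]),
               header=header)
    return path


def load_curve(path, label: str = "") -> ScatteringCurve:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected a 3-column (q, I, sigma) text file")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if sigma is not None and not np.any(sigma > 0):
        sigma = None
    return ScatteringCurve(q=data[:, 0], I=data[:, 1], sigma=sigma,
                           label=label or Path(path).stem)
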