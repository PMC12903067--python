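"""Plain-text CSV bundle reader/writer for datacubes.

A bundle directory holds three UTF-8 CSV files with mandatory headers:
``matrix.csv`` (pixels x features intensities), ``pixels.csv``
(x, y, section_id, slide_id, batch, time_s, tissue) and ``features.csv``
(mz). The round-trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datacube import Datacube, PIXEL_COLUMNS

_FLOAT_FMT = "%.17g"  # shortest lossless decimal for float64


def write_csv_bundle(cube: Datacube, directory: str | Path) -> list[Path]:
    """Write a cube as matrix.csv + pixels.csv + features.csv under *directory*."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    matrix = d / "matrix.csv"
    cols = [f"f{i}" for i in range(cube.n_features)]
    pd.DataFrame(cube.intensities, columns=cols).to_csv(
        matrix, index=False, float_format=_FLOAT_FMT
    )
    pixels = d / "pixels.csv"
    cube.pixel_table().to_csv(pixels, index=False, float_format=_FLOAT_FMT)
    features = d / "features.csv"
    pd.DataFrame({"mz": cube.mz}).to_csv(features, index=False, float_format=_FLOAT_FMT)
    return [matrix, pixels, features]


def read_csv_bundle(directory: str | Path) -> Datacube:
    """Read a CSV bundle written by :func:`write_csv_bundle`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    the three tables disagree on pixel or feature counts.
    """
    d = Path(directory)
    for name in ("matrix.csv", "pixels.csv", "features.csv"):
        if not (d / name).is_file():
            raise FileNotFoundError(f"bundle file missing: {d / name}")
    matrix = pd.read_csv(d / "matrix.csv", float_precision="round_trip")
    pixels = pd.read_csv(
        d / "pixels.csv",
        dtype={"section_id": str, "slide_id": str, "tissue": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    features = pd.read_csv(d / "features.csv", float_precision="round_trip")
    if len(pixels) != len(matrix):
        raise ValueError(
            f"pixel table has {len(pixels)} rows but matrix has {len(matrix)}"
        )
    if len(features) != matrix.shape[1]:
        raise ValueError(
            f"feature table has {len(features)} rows but matrix has {matrix.shape[1]} columns"
        )
    missing = [c for c in PIXEL_COLUMNS if c not in pixels.columns]
    if missing:
        raise ValueError(f"pixels.csv missing columns: {missing}")
    return Datacube(
        intensities=matrix.to_numpy(dtype=float).reshape(len(matrix), matrix.shape[1]),
        mz=features["mz"].to_numpy(dtype=float),
        pixel_x=pixels["x"].to_numpy(dtype=int) if len(pixels) else np.empty(0, int),
        pixel_y=pixels["y"].to_numpy(dtype=int) if len(pixels) else np.empty(0, int),
        section_id=pixels["section_id"].to_numpy(dtype=object),
        slide_id=pixels["slide_id"].to_numpy(dtype=object),
        batch=pixels["batch"].to_numpy(dtype=int) if len(pixels) else np.empty(0, int),
        time_s=pixels["time_s"].to_numpy(dtype=float),
        tissue=pixels["tissue"].to_numpy(dtype=object),
    )
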