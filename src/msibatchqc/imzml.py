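"""imzML input/output for datacubes via pyimzML.

Continuous-mode files map directly onto the cube's common m/z axis.
Processed-mode files (per-pixel axes) are merged onto a common axis by
nearest-bin assignment within a user-supplied tolerance; without a tolerance
they are rejected, since the datacube model assumes one axis for the study.

imzML carries no batch/tissue/timing metadata, so those per-pixel fields are
initialized to neutral defaults (batch 1, time 0, tissue ``sample``, section
and slide ``"0"``) and are expected to be filled in from the study design.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .datacube import Datacube


class ImzmlParseError(RuntimeError):
    """Raised when a spectrum cannot be read; carries the spectrum index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"spectrum {index}: {message}")
        self.index = index


def _merge_axes(axes: list[np.ndarray], tolerance: float) -> np.ndarray:
    """Single-linkage merge of per-pixel m/z axes into one common axis."""
    allmz = np.sort(np.concatenate(axes))
    if allmz.size == 0:
        return allmz
    breaks = np.flatnonzero(np.diff(allmz) > tolerance)
    groups = np.split(allmz, breaks + 1)
    return np.array([g.mean() for g in groups])


def read_imzml(path: str | Path, merge_tolerance: float | None = None) -> Datacube:
    """Read an imzML file into a :class:`Datacube`, one row per spectrum.

    Parameters
    ----------
    path
        The ``.imzML`` file (its ``.ibd`` must sit alongside).
    merge_tolerance
        Required for processed-mode files: per-pixel axes whose bins lie
        within this tolerance (Da) are merged onto a common axis by
        nearest-bin assignment; intensities landing on the same common bin
        are summed. Default 0.005 Da is a sensible choice for profile data
        rebinned at sub-mDa widths; pass it explicitly to accept
        processed-mode input.
    """
    parser = ImzMLParser(str(path))
    n = len(parser.coordinates)
    if n == 0:
        raise ValueError(f"{path}: imzML contains no spectra")

    axes, spectra, coords = [], [], []
    for i in range(n):
        try:
            mzs, ints = parser.getspectrum(i)
        except Exception as exc:  # pragma: no cover - malformed binary payloads
            raise ImzmlParseError(i, str(exc)) from exc
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if mzs.ndim != 1 or mzs.shape != ints.shape:
            raise ImzmlParseError(i, "m/z and intensity arrays disagree in shape")
        axes.append(mzs)
        spectra.append(ints)
        coords.append(parser.coordinates[i])

    same_axis = all(a.shape == axes[0].shape and np.array_equal(a, axes[0]) for a in axes)
    if same_axis:
        mz = axes[0]
        matrix = np.vstack(spectra) if n else np.empty((0, 0))
    else:
        if merge_tolerance is None:
            raise ValueError(
                "processed-mode imzML with per-pixel m/z axes: supply merge_tolerance "
                "to merge them onto a common axis"
            )
        mz = _merge_axes(axes, merge_tolerance)
        matrix = np.zeros((n, mz.size))
        for i, (a, s) in enumerate(zip(axes, spectra)):
            idx = np.clip(np.searchsorted(mz, a), 0, mz.size - 1)
            left_closer = (idx > 0) & (np.abs(a - mz[np.maximum(idx - 1, 0)]) < np.abs(a - mz[idx]))
            idx[left_closer] -= 1
            np.add.at(matrix[i], idx, s)

    xs = np.array([c[0] for c in coords], dtype=int)
    ys = np.array([c[1] for c in coords], dtype=int)
    return Datacube(
        intensities=matrix,
        mz=mz,
        pixel_x=xs - xs.min(),
        pixel_y=ys - ys.min(),
        section_id=np.full(n, "0", dtype=object),
        slide_id=np.full(n, "0", dtype=object),
        batch=np.ones(n, dtype=int),
        time_s=np.zeros(n),
        tissue=np.full(n, "sample", dtype=object),
        provenance=[f"read_imzml:{Path(path).name}"],
    )


def write_imzml(cube: Datacube, path: str | Path) -> Path:
    """Write a cube as continuous-mode imzML (float64 payloads, lossless)."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pyimzml emits spec-polarity warnings
        with ImzMLWriter(
            str(path), mz_dtype=np.float64, intensity_dtype=np.float64, mode="continuous"
        ) as w:
            for i in range(cube.n_pixels):
                # imzML coordinates are 1-based
                w.addSpectrum(
                    cube.mz,
                    cube.intensities[i],
                    (int(cube.pixel_x[i]) + 1, int(cube.pixel_y[i]) + 1, 1),
                )
    return path
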