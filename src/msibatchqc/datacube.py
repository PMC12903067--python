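"""The MSI datacube: a pixels x features intensity matrix with acquisition metadata.

Every pixel carries grid coordinates, a section/slide identity, an integer
batch label, an acquisition time on the study-wide clock, and a tissue label.
Feature identity is the m/z axis. All correctors and metrics in this package
key off this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUE_LABELS = ("qc_homogeneous", "qc_heterogeneous", "sample", "background")

PIXEL_COLUMNS = ("x", "y", "section_id", "slide_id", "batch", "time_s", "tissue")


@dataclass
class Datacube:
    """Pixel-by-feature intensity matrix plus per-pixel acquisition metadata.

    Parameters
    ----------
    intensities
        ``(n_pixels, n_features)`` array of non-negative intensities
        (arbitrary units). Normalized/corrected cubes may contain negative
        values; the non-negativity invariant applies to raw data only.
    mz
        Per-feature mass-to-charge centres in Da, strictly increasing.
    pixel_x, pixel_y
        Integer grid coordinates, 0-based, row-major within a section.
    section_id, slide_id
        Per-pixel string identifiers of the physical tissue section and the
        slide it was mounted on.
    batch
        Per-pixel integer batch label in ``1..B``; for the studies this
        package targets, one batch per slide-day.
    time_s
        Per-pixel acquisition time in seconds on the unified study clock
        (see :func:`unify_timestamps`).
    tissue
        Per-pixel categorical label, one of ``qc_homogeneous``,
        ``qc_heterogeneous``, ``sample``, ``background``.
    provenance
        Ordered list of transform tags applied to this cube.
    """

    intensities: np.ndarray
    mz: np.ndarray
    pixel_x: np.ndarray
    pixel_y: np.ndarray
    section_id: np.ndarray
    slide_id: np.ndarray
    batch: np.ndarray
    time_s: np.ndarray
    tissue: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D pixels x features array")
        self.mz = np.asarray(self.mz, dtype=float)
        self.pixel_x = np.asarray(self.pixel_x, dtype=int)
        self.pixel_y = np.asarray(self.pixel_y, dtype=int)
        self.section_id = np.asarray(self.section_id, dtype=object)
        self.slide_id = np.asarray(self.slide_id, dtype=object)
        self.batch = np.asarray(self.batch, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype=object)
        self.validate()

    # -- basic shape/metadata accessors -------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def batches(self) -> np.ndarray:
        """Sorted unique batch labels."""
        return np.unique(self.batch)

    @property
    def sections(self) -> np.ndarray:
        """Unique section ids in order of first appearance."""
        _, idx = np.unique(self.section_id, return_index=True)
        return self.section_id[np.sort(idx)]

    def validate(self) -> None:
        n = self.n_pixels
        for name in ("pixel_x", "pixel_y", "section_id", "slide_id", "batch", "time_s", "tissue"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected ({n},)")
        if self.mz.shape != (self.n_features,):
            raise ValueError("mz length must equal n_features")
        if self.n_features > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(~np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        # one batch per section
        for sec in self.sections:
            b = np.unique(self.batch[self.section_id == sec])
            if b.size > 1:
                raise ValueError(f"section {sec!r} carries multiple batch labels {b.tolist()}")

    # -- convenience ---------------------------------------------------------

    def copy(self) -> "Datacube":
        return Datacube(
            intensities=self.intensities.copy(),
            mz=self.mz.copy(),
            pixel_x=self.pixel_x.copy(),
            pixel_y=self.pixel_y.copy(),
            section_id=self.section_id.copy(),
            slide_id=self.slide_id.copy(),
            batch=self.batch.copy(),
            time_s=self.time_s.copy(),
            tissue=self.tissue.copy(),
            provenance=list(self.provenance),
        )

    def with_intensities(self, x: np.ndarray, tag: str | None = None) -> "Datacube":
        """Return a copy of this cube with a replaced intensity matrix."""
        x = np.asarray(x, dtype=float)
        if x.shape != self.intensities.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {self.intensities.shape}")
        out = self.copy()
        out.intensities = x
        if tag is not None:
            out.provenance.append(tag)
        return out

    def select(self, mask: np.ndarray) -> "Datacube":
        """Subset pixels by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return Datacube(
            intensities=self.intensities[mask],
            mz=self.mz.copy(),
            pixel_x=self.pixel_x[mask],
            pixel_y=self.pixel_y[mask],
            section_id=self.section_id[mask],
            slide_id=self.slide_id[mask],
            batch=self.batch[mask],
            time_s=self.time_s[mask],
            tissue=self.tissue[mask],
            provenance=list(self.provenance),
        )

    def tissue_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.tissue, labels)

    def pixel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.pixel_x,
                "y": self.pixel_y,
                "section_id": self.section_id,
                "slide_id": self.slide_id,
                "batch": self.batch,
                "time_s": self.time_s,
                "tissue": self.tissue,
            }
        )

    def section_image(self, section: str, values: np.ndarray) -> np.ndarray:
        """Render a per-pixel value vector as a 2-D image for one section.

        Unvisited grid positions are NaN.
        """
        values = np.asarray(values, dtype=float)
        m = self.section_id == section
        if not m.any():
            raise KeyError(f"unknown section {section!r}")
        xs, ys = self.pixel_x[m], self.pixel_y[m]
        img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
        img[ys, xs] = values[m]
        return img

    def equals(self, other: "Datacube", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-by-field equality (numeric arrays compared with tolerances)."""
        if self.intensities.shape != other.intensities.shape:
            return False
        num_ok = np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol) and np.allclose(
            self.mz, other.mz, rtol=rtol, atol=atol
        ) and np.allclose(self.time_s, other.time_s, rtol=rtol, atol=atol)
        meta_ok = (
            np.array_equal(self.pixel_x, other.pixel_x)
            and np.array_equal(self.pixel_y, other.pixel_y)
            and np.array_equal(self.section_id, other.section_id)
            and np.array_equal(self.slide_id, other.slide_id)
            and np.array_equal(self.batch, other.batch)
            and np.array_equal(self.tissue, other.tissue)
        )
        return bool(num_ok and meta_ok)


@dataclass
class SlideSchedule:
    """Acquisition schedule of one slide on the study clock.

    ``start_offset_s`` is the slide's start time relative to the first
    acquired slide (which therefore has offset 0); ``rel_times_s`` are
    per-pixel times relative to the slide's own start.
    """

    slide_id: str
    start_offset_s: float
    rel_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.rel_times_s = np.asarray(self.rel_times_s, dtype=float)
        if self.start_offset_s < 0:
            raise ValueError("start_offset_s must be >= 0")
        if np.any(self.rel_times_s < 0):
            raise ValueError(f"slide {self.slide_id!r} has negative relative times")


def unify_timestamps(schedules: list[SlideSchedule]) -> dict[str, np.ndarray]:
    """Put all slides on one study clock anchored at the first acquired slide.

    Per-slide relative acquisition times are shifted by each slide's start
    offset so the whole study shares a single, consistent time array. Exactly
    one schedule (the first acquired slide) must have offset 0.

    Returns a mapping ``slide_id -> absolute time_s array``; within-slide
    ordering is preserved, and the result does not depend on the order in
    which schedules are passed.
    """
    if not schedules:
        raise ValueError("no schedules given")
    n_zero = sum(1 for s in schedules if s.start_offset_s == 0)
    if n_zero != 1:
        raise ValueError(f"exactly one schedule must have start offset 0, found {n_zero}")
    return {s.slide_id: s.start_offset_s + s.rel_times_s for s in schedules}


def assign_batch_labels(cube: Datacube, section_to_batch: dict | str = "auto") -> Datacube:
    """Attach per-pixel batch labels from a section -> batch mapping.

    With ``"auto"``, sections are numbered contiguously from 1 in
    chronological order of their start time (min ``time_s``), mirroring the
    convention of coding the temporal acquisition order as the batch label.
    An explicit mapping must cover every section in the cube.
    """
    sections = cube.sections
    if isinstance(section_to_batch, str):
        if section_to_batch != "auto":
            raise ValueError("section_to_batch must be a mapping or 'auto'")
        starts = {sec: cube.time_s[cube.section_id == sec].min() for sec in sections}
        ordered = sorted(sections, key=lambda s: (starts[s], str(s)))
        mapping = {sec: i + 1 for i, sec in enumerate(ordered)}
    else:
        missing = [s for s in sections if s not in section_to_batch]
        if missing:
            raise KeyError(f"sections without a batch mapping: {missing}")
        mapping = section_to_batch
    out = cube.copy()
    out.batch = np.array([int(mapping[s]) for s in cube.section_id], dtype=int)
    return out
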