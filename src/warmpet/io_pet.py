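"""I/O and core containers for dynamic PET data.

The module defines the four in-memory objects the rest of the package works
with — :class:`FrameSchedule`, :class:`DynamicImage`, :class:`RegionMask` and
:class:`TimeActivityCurve` — plus readers/writers for 4D NIfTI-1 volumes,
frame-timing tables and per-region TAC tables.

Conventions
-----------
* All times are in **minutes**; activity is in kBq/mL and assumed
  decay-corrected upstream.
* Frame-timing tables are 2-column CSV ``start_minutes, duration_minutes``
  (optional header). A 3-column SIF-style dialect ``start, end, counts`` is
  also accepted and converted to start/duration internally.
* Region masks are integer-labelled 3D volumes on the same grid as the
  dynamic image; label 0 is background. Spatial registration is out of
  scope: masks must already live on the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, RegionError, ScheduleError

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "RegionMask",
    "TimeActivityCurve",
    "default_schedule",
    "read_frame_schedule",
    "write_frame_schedule",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_region_mask",
    "write_region_mask",
    "extract_tac",
    "read_tac_table",
    "write_tac_table",
]

#: Canonical region abbreviations: frontal, parietal, temporal and occipital
#: lobes, white matter, cerebellum grey matter (the reference tissue).
STANDARD_REGIONS = ("FL", "PL", "TL", "OL", "WM", "CERB")


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (minutes) of the frames of a dynamic scan.

    Frames must be ordered, strictly positive in duration and
    non-overlapping. ``mid_times`` (start + duration/2) is the temporal
    sampling grid used by every quantification routine.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_times, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "durations", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ScheduleError("start_times and durations must be 1D and equal length")
        if len(start) == 0:
            raise ScheduleError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ScheduleError("schedule times must be finite")
        if np.any(dur <= 0):
            raise ScheduleError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ScheduleError("frame start times must be strictly increasing")
        if np.any(start[1:] < start[:-1] + dur[:-1] - 1e-9):
            raise ScheduleError("frames overlap: start[i+1] < start[i] + duration[i]")

    @property
    def mid_times(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return self.start_times + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    def __len__(self) -> int:
        return len(self.start_times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start_times, other.start_times) and np.array_equal(
            self.durations, other.durations
        )


def default_schedule() -> FrameSchedule:
    """The acquisition schedule used throughout: 4x30 s, 9x1 min, 3x3 min,
    10x6 min and 2x10 min frames (28 frames, 100 min total)."""
    durations = np.concatenate(
        [np.full(4, 0.5), np.full(9, 1.0), np.full(3, 3.0), np.full(10, 6.0), np.full(2, 10.0)]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) per frame for one voxel or region."""

    schedule: FrameSchedule
    activity: np.ndarray
    source: str | tuple = "unknown"

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.ndim != 1 or len(act) != len(self.schedule):
            raise ScheduleError(
                f"TAC length {act.shape} does not match schedule of {len(self.schedule)} frames"
            )
        if not np.all(np.isfinite(act)):
            raise FormatError("TAC contains non-finite activity values")

    @property
    def mid_times(self) -> np.ndarray:
        return self.schedule.mid_times

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.activity * factor, self.source)


@dataclass
class DynamicImage:
    """A 4D dynamic PET volume (x, y, z, frame) bound to a FrameSchedule."""

    voxels: np.ndarray
    schedule: FrameSchedule
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise FormatError(f"dynamic image must be 4D, got {self.voxels.ndim}D")
        if self.voxels.shape[3] != len(self.schedule):
            raise ScheduleError(
                f"image has {self.voxels.shape[3]} frames but schedule has "
                f"{len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("dynamic image contains non-finite values")
        # negatives are legal reconstruction noise but worth surfacing
        self.n_negative_voxels = int(np.count_nonzero((self.voxels < 0).any(axis=3)))

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class RegionMask:
    """Integer-labelled 3D mask with a label -> region-name map."""

    labels: np.ndarray
    label_names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"region mask must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise FormatError("region mask labels must be integers")
            self.labels = rounded.astype(np.int32)
        self.label_names = dict(self.label_names)
        if 0 in self.label_names:
            raise FormatError("label 0 is reserved for background")
        for label, name in self.label_names.items():
            if not np.any(self.labels == label):
                raise RegionError(f"region {name!r} (label {label}) has no voxels")

    @property
    def region_names(self) -> list[str]:
        return list(self.label_names.values())

    def label_of(self, region: str) -> int:
        for label, name in self.label_names.items():
            if name == region:
                return label
        raise RegionError(f"region {region!r} not defined in mask "
                          f"(known: {sorted(self.label_names.values())})")

    def indices(self, region: str) -> np.ndarray:
        mask = self.labels == self.label_of(region)
        if not np.any(mask):
            raise RegionError(f"region {region!r} is empty")
        return mask

    def n_voxels(self, region: str) -> int:
        return int(np.count_nonzero(self.indices(region)))


# ---------------------------------------------------------------------------
# frame-timing tables
# ---------------------------------------------------------------------------

def read_frame_schedule(path: str | Path) -> FrameSchedule:
    """Read a frame-timing table.

    Two dialects are accepted:

    * 2 columns: ``start_minutes, duration_minutes`` (optional header);
    * 3+ columns (SIF-style): ``start, end, counts...`` — converted to
      start/duration, extra columns ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse frame-timing table {path}: {exc}") from exc
    # drop a header row if the first row is not numeric
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:]
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric entries in frame-timing table {path}") from exc
    if values.shape[1] == 2:
        start, dur = values[:, 0], values[:, 1]
    elif values.shape[1] >= 3:
        start, end = values[:, 0], values[:, 1]
        dur = end - start
    else:
        raise FormatError(f"frame-timing table {path} needs 2 or 3 columns")
    return FrameSchedule(start, dur)


def write_frame_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {"start_minutes": schedule.start_times, "duration_minutes": schedule.durations}
    ).to_csv(path, index=False)


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# NIfTI images and masks
# ---------------------------------------------------------------------------

def read_dynamic_image(path: str | Path, schedule_path: str | Path) -> DynamicImage:
    """Load a 4D NIfTI-1 volume with its frame-timing table.

    Raises :class:`ScheduleError` if the frame counts disagree and
    :class:`FormatError` for non-4D input.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D dynamic volume, got {data.ndim}D")
    schedule = read_frame_schedule(schedule_path)
    if data.shape[3] != len(schedule):
        raise ScheduleError(
            f"{path}: image has {data.shape[3]} frames but timing table "
            f"{schedule_path} has {len(schedule)} rows"
        )
    return DynamicImage(data.astype(float), schedule, affine=img.affine)


def write_dynamic_image(image: DynamicImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), image.affine), str(path))


def read_region_mask(path: str | Path, labels_path: str | Path | None = None) -> RegionMask:
    """Load an integer mask volume; region names come from a 2-column CSV
    ``label, name`` or default to the standard six-region set."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: region mask must be 3D, got {data.ndim}D")
    if labels_path is not None:
        table = pd.read_csv(labels_path)
        cols = [c for c in table.columns if c.lower() in ("label", "name", "region")]
        if len(cols) < 2:
            table = pd.read_csv(labels_path, header=None, names=["label", "name"])
        label_names = {int(r.iloc[0]): str(r.iloc[1]) for _, r in table.iterrows()}
    else:
        present = sorted(int(v) for v in np.unique(data) if v != 0)
        label_names = {lab: STANDARD_REGIONS[i] if i < len(STANDARD_REGIONS) else f"R{lab}"
                       for i, lab in enumerate(present)}
    return RegionMask(data, label_names)


def write_region_mask(mask: RegionMask, path: str | Path,
                      labels_path: str | Path | None = None,
                      affine: np.ndarray | None = None) -> None:
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), aff), str(path))
    if labels_path is not None:
        pd.DataFrame(
            {"label": list(mask.label_names), "name": list(mask.label_names.values())}
        ).to_csv(labels_path, index=False)


# ---------------------------------------------------------------------------
# TAC extraction and tables
# ---------------------------------------------------------------------------

def extract_tac(image: DynamicImage, mask: RegionMask, region: str) -> TimeActivityCurve:
    """Mean time-activity curve over the voxels of one region."""
    if image.voxels.shape[:3] != mask.labels.shape:
        raise FormatError(
            f"mask grid {mask.labels.shape} does not match image grid "
            f"{image.voxels.shape[:3]}"
        )
    idx = mask.indices(region)
    return TimeActivityCurve(image.schedule, image.voxels[idx].mean(axis=0), source=region)


def write_tac_table(tacs: Sequence[TimeActivityCurve], path: str | Path) -> None:
    """Write per-region TACs as long-format CSV
    (region, frame_index, mid_time_min, activity_kbq_ml)."""
    rows = []
    for tac in tacs:
        for i, (t, a) in enumerate(zip(tac.mid_times, tac.activity)):
            rows.append({"region": str(tac.source), "frame_index": i,
                         "mid_time_min": t, "activity_kbq_ml": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tac_table(path: str | Path, schedule: FrameSchedule) -> dict[str, TimeActivityCurve]:
    """Read a long-format TAC table back into per-region curves."""
    df = pd.read_csv(path)
    out: dict[str, TimeActivityCurve] = {}
    for region, sub in df.groupby("region"):
        sub = sub.sort_values("frame_index")
        if len(sub) != len(schedule):
            raise ScheduleError(
                f"region {region!r}: {len(sub)} rows but schedule has {len(schedule)} frames"
            )
        out[str(region)] = TimeActivityCurve(
            schedule, sub["activity_kbq_ml"].to_numpy(), source=str(region)
        )
    return out
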