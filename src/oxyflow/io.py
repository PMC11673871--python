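"""File formats and shared conventions for the breath-hold NIRS pipeline.

Every stage of the pipeline shares one coordinate convention: 0-based
(row, col) pixel indexing, time in seconds since acquisition start, and
frame index = round(t * sampling_hz).  Image stacks travel as one
multi-frame TIFF per wavelength (frame order = time order), calibration
references as single-frame TIFFs, masks as 8-bit PNG or TIFF, and all
tabular output as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "WAVELENGTHS_NM",
    "Paradigm",
    "ReflectanceStack",
    "CalibrationFrame",
    "RoiMask",
    "make_rect_roi",
    "read_stack",
    "write_stack",
    "read_calibration",
    "write_calibration",
    "read_mask",
    "write_mask",
    "load_yaml",
    "dump_yaml",
]

#: Wavelength order used everywhere: index 0 -> 682 nm, index 1 -> 826 nm.
WAVELENGTHS_NM: tuple[int, int] = (682, 826)


@dataclass(frozen=True)
class Paradigm:
    """Timing of the breath-hold stimulus paradigm.

    The default mirrors the acquisition protocol this pipeline targets:
    40 s of rest, a 20 s end-exhalation breath-hold, and a 60 s recovery,
    sampled at 1 frame per second per wavelength.  The analysis onset
    ``t0`` (used for percent-change normalization) is the end of the rest
    phase; the hold window is the half-open interval ``(rest_s,
    rest_s + hold_s]``.
    """

    rest_s: float = 40.0
    hold_s: float = 20.0
    recovery_s: float = 60.0
    sampling_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rest_s", "hold_s", "recovery_s", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Paradigm.{name} must be positive, got {getattr(self, name)}")

    @property
    def total_s(self) -> float:
        return self.rest_s + self.hold_s + self.recovery_s

    @property
    def n_frames(self) -> int:
        """Frames per wavelength over the whole paradigm."""
        return int(round(self.total_s * self.sampling_hz))

    @property
    def onset_s(self) -> float:
        """Breath-hold onset = analysis t0 (seconds)."""
        return self.rest_s

    @property
    def hold_end_s(self) -> float:
        return self.rest_s + self.hold_s

    def timestamps(self) -> np.ndarray:
        """Per-frame acquisition times in seconds: 0, 1/hz, 2/hz, ..."""
        return np.arange(self.n_frames, dtype=float) / self.sampling_hz

    def frame_index(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_hz))

    def to_dict(self) -> dict:
        return {
            "rest_s": self.rest_s,
            "hold_s": self.hold_s,
            "recovery_s": self.recovery_s,
            "sampling_hz": self.sampling_hz,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Paradigm":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class ReflectanceStack:
    """Time-ordered dual-wavelength diffuse-reflectance frames.

    ``frames`` has shape (2, T, H, W); axis 0 follows :data:`WAVELENGTHS_NM`.
    ``valid`` (T, H, W) marks pixels whose values are trustworthy; motion
    correction marks pixels resampled from outside the frame as invalid.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    wavelengths_nm: tuple[int, int] = WAVELENGTHS_NM
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[0] != 2:
            raise ValueError(f"frames must have shape (2, T, H, W), got {self.frames.shape}")
        if self.timestamps_s.shape != (self.frames.shape[1],):
            raise ValueError("timestamps length must match frame count")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.asarray(self.frames) < 0):
            raise ValueError("reflectance intensities must be non-negative")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.frames.shape[1:]:
                raise ValueError("valid mask must have shape (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def channel(self, wavelength_nm: int) -> np.ndarray:
        """(T, H, W) array for one wavelength."""
        return self.frames[self.wavelengths_nm.index(wavelength_nm)]

    def validity(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.frames.shape[1:], dtype=bool)
        return self.valid


@dataclass
class CalibrationFrame:
    """Reference frames from the uniformly diffusing calibration sheet.

    ``images`` has shape (2, H, W) for a single static reference, or
    (2, T, H, W) after motion correction has been propagated to the
    reference (one warped reference per acquisition frame).
    """

    images: np.ndarray
    wavelengths_nm: tuple[int, int] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim not in (3, 4) or self.images.shape[0] != 2:
            raise ValueError(
                f"calibration images must have shape (2, H, W) or (2, T, H, W), got {self.images.shape}"
            )

    @property
    def per_frame(self) -> bool:
        return self.images.ndim == 4

    def channel(self, wavelength_nm: int) -> np.ndarray:
        return self.images[self.wavelengths_nm.index(wavelength_nm)]


@dataclass
class RoiMask:
    """Binary region-of-interest mask over the frame grid."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def make_rect_roi(
    top_left: tuple[int, int], size: int | tuple[int, int], frame_shape: tuple[int, int], label: str = "roi"
) -> RoiMask:
    """Rectangular ROI (e.g. the 50x50-pixel regions used for profile comparison).

    ``top_left`` is (row, col); ``size`` is a side length or (height, width).
    Raises ``ValueError`` if the rectangle does not fit inside the frame.
    """
    r0, c0 = int(top_left[0]), int(top_left[1])
    if np.isscalar(size):
        h = w = int(size)
    else:
        h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError("ROI size must be positive")
    H, W = frame_shape
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(
            f"ROI rows {r0}:{r0 + h}, cols {c0}:{c0 + w} out of bounds for frame {H}x{W}"
        )
    mask = np.zeros(frame_shape, dtype=bool)
    mask[r0 : r0 + h, c0 : c0 + w] = True
    return RoiMask(mask=mask, label=label)


# ---------------------------------------------------------------------------
# TIFF / PNG / YAML round trips
# ---------------------------------------------------------------------------

def write_stack(stack: ReflectanceStack, paths: Mapping[int, str | Path] | Sequence[str | Path]) -> None:
    """Write one multi-frame TIFF per wavelength, frame order = time order."""
    paths = _as_path_map(paths)
    for wl in stack.wavelengths_nm:
        tifffile.imwrite(str(paths[wl]), stack.channel(wl))


def read_stack(
    paths: Mapping[int, str | Path] | Sequence[str | Path],
    paradigm: Paradigm,
    meta: dict | None = None,
) -> ReflectanceStack:
    """Read a dual-wavelength stack and validate it against the paradigm.

    Frame counts must equal ``paradigm.n_frames`` for both wavelengths and
    the two channels must share a frame shape; timestamps are regenerated
    from ``paradigm.sampling_hz``.
    """
    paths = _as_path_map(paths)
    channels = {}
    for wl in WAVELENGTHS_NM:
        arr = tifffile.imread(str(paths[wl]))
        if arr.ndim == 2:
            arr = arr[None]
        channels[wl] = arr
    n_expected = paradigm.n_frames
    for wl, arr in channels.items():
        if arr.shape[0] != n_expected:
            raise ValueError(
                f"{wl} nm stack has {arr.shape[0]} frames but the paradigm "
                f"({paradigm.total_s:.0f} s at {paradigm.sampling_hz} Hz) expects {n_expected}"
            )
    if channels[WAVELENGTHS_NM[0]].shape != channels[WAVELENGTHS_NM[1]].shape:
        raise ValueError(
            f"wavelength stacks disagree in shape: "
            f"{channels[WAVELENGTHS_NM[0]].shape} vs {channels[WAVELENGTHS_NM[1]].shape}"
        )
    frames = np.stack([channels[wl] for wl in WAVELENGTHS_NM], axis=0)
    return ReflectanceStack(
        frames=frames,
        timestamps_s=paradigm.timestamps(),
        meta=dict(meta or {}),
    )


def write_calibration(cal: CalibrationFrame, paths: Mapping[int, str | Path] | Sequence[str | Path]) -> None:
    paths = _as_path_map(paths)
    for wl in cal.wavelengths_nm:
        tifffile.imwrite(str(paths[wl]), cal.channel(wl))


def read_calibration(paths: Mapping[int, str | Path] | Sequence[str | Path]) -> CalibrationFrame:
    paths = _as_path_map(paths)
    images = np.stack([tifffile.imread(str(paths[wl])) for wl in WAVELENGTHS_NM], axis=0)
    return CalibrationFrame(images=images)


def write_mask(roi: RoiMask, path: str | Path) -> None:
    """8-bit mask image: 255 inside the region, 0 outside (PNG or TIFF)."""
    img = (roi.mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), img)
    else:
        iio.imwrite(str(path), img)


def read_mask(path: str | Path, label: str | None = None) -> RoiMask:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(str(path))
    else:
        img = iio.imread(str(path))
    if img.ndim == 3:  # drop any color channels
        img = img[..., 0]
    return RoiMask(mask=img > 0, label=label or path.stem)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def _as_path_map(paths) -> dict[int, Path]:
    if isinstance(paths, Mapping):
        return {int(k): Path(v) for k, v in paths.items()}
    seq = list(paths)
    if len(seq) != 2:
        raise ValueError("expected one path per wavelength (682, 826)")
    return {WAVELENGTHS_NM[0]: Path(seq[0]), WAVELENGTHS_NM[1]: Path(seq[1])}
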