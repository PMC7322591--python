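"""Raster image and manifest I/O for fundus photographs.

Images are plain numpy arrays: an RGB image is a ``(H, W, 3)`` uint8 array
(red, green, blue planes), a gray plane is a ``(H, W)`` uint8 array.
Row-major, origin at the top-left, 0-based indexing throughout.

The luminance conversion used for the "gray level" input is the Rec. 601
weighting ``0.299 R + 0.587 G + 0.114 B``, rounded half-up to an integer so
that downstream local-histogram entropy operates on discrete intensities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import ChannelCountError, ConfigError, DataError

__all__ = [
    "ImageRecord",
    "load_image",
    "save_image",
    "resize",
    "extract_green",
    "to_luminance",
    "round_half_up",
    "read_manifest",
    "write_manifest",
    "validate_rgb",
    "validate_plane",
]

#: minimum side length accepted by :func:`resize`
MIN_SIDE = 8

#: Rec. 601 luminance weights for (R, G, B)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: grade at or above which an image is referable (moderate or worse DR)
REFERABLE_GRADE = 2


@dataclass(frozen=True)
class ImageRecord:
    """A labeled fundus image: opaque id, file reference and DR grade 0-4.

    ``referable`` is derived, never stored: grade >= 2 (moderate
    non-proliferative or worse) warrants specialist referral and is the
    binary target of the screening task.
    """

    image_id: str
    path: str
    grade: int

    def __post_init__(self) -> None:
        if not 0 <= int(self.grade) <= 4:
            raise DataError(f"grade must be in 0..4, got {self.grade!r}")

    @property
    def referable(self) -> bool:
        return self.grade >= REFERABLE_GRADE


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an RGB image array: (H, W, 3), intensities in [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ChannelCountError(f"expected (H, W, 3) array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise DataError("intensities must lie in [0, 255]")
    return arr


def validate_plane(plane: np.ndarray) -> np.ndarray:
    """Check a gray plane: 2-D, intensities in [0, 255]."""
    arr = np.asarray(plane)
    if arr.ndim != 2:
        raise DataError(f"expected 2-D plane, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise DataError("intensities must lie in [0, 255]")
    return arr


def load_image(source: str | Path) -> np.ndarray:
    """Read an 8-bit color raster (PNG/JPEG) into a (H, W, 3) uint8 array.

    Raises
    ------
    DataError
        If the file is missing or cannot be decoded.
    ChannelCountError
        If the raster is not a 3-channel color image (e.g. grayscale).
    """
    path = Path(source)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "P":  # palette PNGs decode to their stored color triplets
                im = im.convert("RGB")
                mode = "RGB"
            if mode != "RGB":
                raise ChannelCountError(
                    f"{path.name}: expected a 3-channel color raster, got mode {mode!r}"
                )
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError as exc:
        raise DataError(f"image file not found: {path}") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise DataError(f"cannot decode image {path}: {exc}") from exc


def save_image(image: np.ndarray, target: str | Path) -> None:
    """Write a (H, W, 3) uint8 array or a (H, W) uint8 plane as PNG/JPEG."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = validate_rgb(arr)
    else:
        arr = validate_plane(arr)
    Image.fromarray(arr.astype(np.uint8)).save(Path(target))


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round half-up (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


def resize(image: np.ndarray, side: int) -> np.ndarray:
    """Resize to ``side x side`` with anti-aliased bilinear interpolation."""
    arr = validate_rgb(image)
    if side < MIN_SIDE:
        raise ConfigError(f"side must be >= {MIN_SIDE}, got {side}")
    if arr.shape[0] == side and arr.shape[1] == side:
        return arr.astype(np.uint8, copy=True)
    out = _sk_resize(
        arr.astype(np.float64),
        (side, side, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


def extract_green(image: np.ndarray) -> np.ndarray:
    """Return the green plane; it carries the strongest vessel/lesion contrast."""
    return validate_rgb(image)[:, :, 1].astype(np.uint8, copy=True)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 gray level: 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    arr = validate_rgb(image).astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * arr[:, :, 0] + wg * arr[:, :, 1] + wb * arr[:, :, 2]
    return np.clip(round_half_up(luma), 0, 255).astype(np.uint8)


def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Read a label manifest CSV with header ``image_id,path,grade``.

    The referable flag is derived from the grade, never read from disk.
    """
    path = Path(path)
    records: list[ImageRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image_id", "path", "grade"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise DataError(
                f"manifest {path} must have columns image_id,path,grade; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            try:
                grade = int(row["grade"])
            except ValueError as exc:
                raise DataError(f"non-integer grade {row['grade']!r} in {path}") from exc
            records.append(ImageRecord(row["image_id"], row["path"], grade))
    return records


def write_manifest(records: list[ImageRecord], path: str | Path) -> None:
    """Write a label manifest CSV (image_id,path,grade), sorted by image_id."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "path", "grade"])
        for rec in sorted(records, key=lambda r: r.image_id):
            writer.writerow([rec.image_id, rec.path, rec.grade])
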