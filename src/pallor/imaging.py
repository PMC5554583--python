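"""Image I/O, resizing and scalar color-feature extraction.

Cropped palpebral-conjunctiva images arrive in unequal, usually non-square
sizes (under 150x150 px). Each is enlarged to a common square size (default
500x500, bicubic) and reduced to a single recognition feature:

- ``mean_red``: arithmetic mean of the R channel — pallor of the conjunctiva
  tracks hemoglobin, and the red component carries most of that signal;
- ``erythema``: log10 of the mean R value, the erythema-index variant;
- ``hue``: circular mean of the per-pixel HSI hue angle in degrees.

Pixel intensities are treated as 0-255 integers on input and real-valued
after interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageRecord",
    "FEATURE_NAMES",
    "load_image",
    "resize_image",
    "extract_mean_red",
    "extract_erythema",
    "extract_hue",
    "extract_feature",
    "read_manifest",
    "extract_feature_table",
]

FEATURE_NAMES = ("mean_red", "erythema", "hue")


@dataclass
class ImageRecord:
    """An RGB image with optional ground-truth hemoglobin level.

    ``pixels`` is H x W x 3 with channels interpreted as R, G, B in that
    order; ``hb_g_dl`` may be absent at test time.
    """

    subject_id: str
    pixels: np.ndarray
    hb_g_dl: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"{self.subject_id}: expected an H x W x 3 RGB array, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"{self.subject_id}: empty image")


def load_image(path: str | Path, subject_id: str | None = None,
               hb_g_dl: float | None = None) -> ImageRecord:
    """Read an 8-bit RGB PNG/JPEG into an :class:`ImageRecord`."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return ImageRecord(subject_id=subject_id or path.stem, pixels=arr, hb_g_dl=hb_g_dl)


def resize_image(img: ImageRecord, side: int = 500) -> ImageRecord:
    """Enlarge (or shrink) to ``side`` x ``side`` with bicubic interpolation.

    Output pixels are real-valued, clipped to [0, 255]. An image already at
    the target size is returned unchanged.
    """
    if side < 1:
        raise ValueError(f"target side must be >= 1, got {side}")
    if img.pixels.shape[:2] == (side, side):
        return img
    # per-channel float interpolation: no premature re-quantization to uint8
    chans = [
        np.asarray(
            Image.fromarray(img.pixels[:, :, c].astype(np.float32), mode="F").resize(
                (side, side), Image.BICUBIC
            )
        )
        for c in range(3)
    ]
    out = np.clip(np.stack(chans, axis=-1).astype(float), 0.0, 255.0)
    return ImageRecord(subject_id=img.subject_id, pixels=out, hb_g_dl=img.hb_g_dl)


def extract_mean_red(img: ImageRecord) -> float:
    """Arithmetic mean of the R channel over all pixels."""
    return float(np.mean(img.pixels[:, :, 0]))


def extract_erythema(img: ImageRecord) -> float:
    """Erythema index: log10 of the image-mean R value.

    The logarithm is applied to the single mean value, not per pixel.
    """
    mean_r = extract_mean_red(img)
    if mean_r <= 0:
        raise ValueError(
            f"{img.subject_id}: mean R is {mean_r}; erythema index undefined"
        )
    return float(np.log10(mean_r))


def _hsi_hue_degrees(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel HSI hue in degrees via the arccos formulation, NaN for gray."""
    r = pixels[:, :, 0].astype(float)
    g = pixels[:, :, 1].astype(float)
    b = pixels[:, :, 2].astype(float)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    gray = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / np.where(gray, np.nan, den), -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    return np.where(gray, np.nan, hue)


def extract_hue(img: ImageRecord) -> float:
    """Circular mean of per-pixel HSI hue, in degrees in [0, 360).

    Hue is an angle, so pixels are averaged as unit vectors; a plain
    arithmetic mean of angles would be wrong near the 0/360 wrap where red
    lives. Gray pixels (R = G = B) have no hue and are excluded; an all-gray
    image is assigned hue 0 by convention.
    """
    hue = _hsi_hue_degrees(img.pixels)
    valid = ~np.isnan(hue)
    if not np.any(valid):
        return 0.0
    ang = np.radians(hue[valid])
    mean_angle = np.degrees(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    return float(mean_angle % 360.0)


_EXTRACTORS = {
    "mean_red": extract_mean_red,
    "erythema": extract_erythema,
    "hue": extract_hue,
}


def extract_feature(img: ImageRecord, feature_name: str) -> float:
    """Dispatch to one of the named feature extractors."""
    try:
        return _EXTRACTORS[feature_name](img)
    except KeyError:
        raise ValueError(
            f"unknown feature {feature_name!r}; choose from {FEATURE_NAMES}"
        ) from None


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset manifest CSV.

    Required columns: ``filename`` and ``hb_g_dl`` (``label`` optional).
    Filenames are resolved relative to the manifest's directory; every image
    file must exist and every Hb level must be positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    for col in ("filename", "hb_g_dl"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} is missing required column {col!r}")
    root = path.parent
    for idx, row in df.iterrows():
        hb = row["hb_g_dl"]
        if not np.isfinite(hb) or hb <= 0:
            raise ValueError(f"manifest row {idx}: nonpositive Hb level {hb!r}")
        img_path = root / str(row["filename"])
        if not img_path.exists():
            raise FileNotFoundError(
                f"manifest row {idx}: image file {row['filename']!r} not found"
            )
    df["path"] = [str(root / f) for f in df["filename"]]
    return df


def extract_feature_tables(
    manifest: pd.DataFrame | str | Path,
    feature_names=FEATURE_NAMES,
    resize_side: int = 500,
) -> dict[str, pd.DataFrame]:
    """Extract several features per image in a single load/resize pass.

    Returns ``{feature_name: DataFrame}`` with columns subject_id, hb_g_dl,
    feature_name, value (plus label when the manifest has one). Resizing to
    the working size dominates the cost, so extracting all features at once
    is much cheaper than one pass per feature.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    rows: dict[str, list] = {name: [] for name in feature_names}
    for _, row in manifest.iterrows():
        img = load_image(row["path"], hb_g_dl=row["hb_g_dl"])
        img = resize_image(img, side=resize_side)
        for name in feature_names:
            rec = {
                "subject_id": img.subject_id,
                "hb_g_dl": float(row["hb_g_dl"]),
                "feature_name": name,
                "value": extract_feature(img, name),
            }
            if "label" in manifest.columns:
                rec["label"] = row["label"]
            rows[name].append(rec)
    return {name: pd.DataFrame(recs) for name, recs in rows.items()}


def extract_feature_table(
    manifest: pd.DataFrame | str | Path,
    feature_name: str = "mean_red",
    resize_side: int = 500,
) -> pd.DataFrame:
    """Extract one scalar feature per manifest image.

    Returns a DataFrame with columns subject_id, hb_g_dl, feature_name, value
    (plus label when the manifest has one).
    """
    return extract_feature_tables(manifest, (feature_name,), resize_side)[feature_name]
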