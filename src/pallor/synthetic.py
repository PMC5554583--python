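"""Synthetic conjunctiva-like datasets for testing and benchmarking.

No public dataset of cropped palpebral-conjunctiva images with paired
hemoglobin levels exists, so this module generates image sets (and pure
feature tables) with the statistical structure the screening method assumes:
a red-dominant image whose mean R value rises linearly with hemoglobin, plus
per-pixel sensor noise, per-subject biological scatter, and optional
saturated specular bright spots of the kind a flash reflection leaves on the
moist conjunctiva surface.

The defaults emulate a clinical screening set: 100 subjects, Hb drawn
uniformly on [6, 16] g/dL, anemia threshold 11 g/dL, images of random
non-square sizes under 150x150 px. These are deliberately simple images —
flat color fields, not conjunctiva textures — which is exactly what the
downstream mean-color features consume.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["SyntheticSpec", "generate_dataset", "generate_feature_table", "write_dataset"]

# Green/blue channel baselines relative to the red mean: conjunctiva is
# red-dominant, and only R and hue are consumed downstream.
G_FRACTION = 0.5
B_FRACTION = 0.4
SPOT_RADIUS_FRACTION = 0.10


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic conjunctiva dataset.

    The mean red intensity of subject k is
    ``intercept + slope * hb_k + N(0, subject_noise_sd)``, and each pixel of
    the R channel adds independent ``N(0, pixel_noise_sd)`` noise before
    clipping to [0, 255]. With probability ``spot_probability`` a saturated
    disk (radius 10% of the shorter side) is stamped on all three channels.
    """

    n_subjects: int = 100
    hb_min: float = 6.0
    hb_max: float = 16.0
    anemia_threshold: float = 11.0
    slope: float = 8.0            # feature units per g/dL
    intercept: float = 60.0       # feature units
    pixel_noise_sd: float = 5.0   # 8-bit intensity units
    subject_noise_sd: float = 4.0  # feature units
    spot_probability: float = 0.1
    spot_intensity: int = 250
    img_min_side: int = 80
    img_max_side: int = 149
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if not (self.hb_min < self.anemia_threshold < self.hb_max):
            raise ValueError(
                f"need hb_min < anemia_threshold < hb_max, got "
                f"{self.hb_min}, {self.anemia_threshold}, {self.hb_max}"
            )
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if self.pixel_noise_sd < 0 or self.subject_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.spot_probability <= 1.0):
            raise ValueError(f"spot_probability must be in [0, 1], got {self.spot_probability}")
        if not (1 <= self.img_min_side <= self.img_max_side < 150):
            raise ValueError(
                "image sides must satisfy 1 <= img_min_side <= img_max_side < 150"
            )


def _subject_table(
    spec: SyntheticSpec, rng: np.random.Generator, hb=None
) -> pd.DataFrame:
    """Draw per-subject Hb, noiseless mean-R target, and anemia label."""
    if hb is None:
        hb = rng.uniform(spec.hb_min, spec.hb_max, size=spec.n_subjects)
    else:
        hb = np.asarray(hb, dtype=float)
        if len(hb) != spec.n_subjects:
            raise ValueError(
                f"explicit hb has {len(hb)} values but n_subjects={spec.n_subjects}"
            )
    mean_r = spec.intercept + spec.slope * hb
    if spec.subject_noise_sd > 0:
        mean_r = mean_r + rng.normal(0.0, spec.subject_noise_sd, size=spec.n_subjects)
    return pd.DataFrame(
        {
            "subject_id": [f"subj{k:04d}" for k in range(spec.n_subjects)],
            "hb_g_dl": hb,
            "feature": mean_r,
            "label": np.where(hb < spec.anemia_threshold, "anemic", "nonanemic"),
        }
    )


def generate_feature_table(spec: SyntheticSpec, hb=None) -> pd.DataFrame:
    """Generate (subject_id, hb_g_dl, feature, label) rows without images.

    Same generative model as :func:`generate_dataset` at the feature level
    (pixel noise averages out over an image and is omitted here). Subjects
    that happen to share an Hb value each keep their own row; collapsing
    duplicates is the consumer's job.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return _subject_table(spec, rng, hb=hb)


def _render_image(mean_r: float, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h = int(rng.integers(spec.img_min_side, spec.img_max_side + 1))
    w = int(rng.integers(spec.img_min_side, spec.img_max_side + 1))
    base = np.array([mean_r, G_FRACTION * mean_r, B_FRACTION * mean_r])
    pixels = np.broadcast_to(base, (h, w, 3)).copy()
    if spec.pixel_noise_sd > 0:
        pixels += rng.normal(0.0, spec.pixel_noise_sd, size=(h, w, 3))
    if rng.uniform() < spec.spot_probability:
        radius = max(1, int(round(SPOT_RADIUS_FRACTION * min(h, w))))
        cy = int(rng.integers(radius, h - radius + 1))
        cx = int(rng.integers(radius, w - radius + 1))
        yy, xx = np.ogrid[:h, :w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        pixels[disk] = spec.spot_intensity
    return np.clip(np.rint(pixels), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec, hb=None):
    """Generate synthetic images plus their manifest.

    Returns ``(images, manifest)`` where ``images`` is a list of H x W x 3
    uint8 arrays and ``manifest`` a DataFrame with columns
    (filename, hb_g_dl, label) aligned with the list. Deterministic under
    ``spec.seed``. An explicit ``hb`` array replaces the uniform Hb draw
    (useful for controlled fixtures).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    table = _subject_table(spec, rng, hb=hb)
    images = [_render_image(m, spec, rng) for m in table["feature"]]
    manifest = pd.DataFrame(
        {
            "filename": [f"{sid}.png" for sid in table["subject_id"]],
            "hb_g_dl": table["hb_g_dl"],
            "label": table["label"],
        }
    )
    return images, manifest


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Generate a dataset and write PNGs, manifest.csv and a spec echo.

    Returns the path to the manifest. Output is byte-identical for identical
    specs (PNG encoding is deterministic).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, manifest = generate_dataset(spec)
    for fname, img in zip(manifest["filename"], images):
        Image.fromarray(img).save(out_dir / fname)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return manifest_path
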