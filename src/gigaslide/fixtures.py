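"""Synthetic pseudo-whole-slide images with planted, recoverable class signal.

Real gigapixel pathology slides are proprietary and enormous; every stage of
this package is instead exercised on generated "slides": a bright background
(so Otsu thresholding cleanly separates tissue from glass) containing dark
textured disks whose stripe period encodes a planted class label. Each slide
carries a short template report naming the class, so the vision-language
stage has a learnable association too.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "FixtureSpec", "PseudoWSI", "generate_slide", "generate_arrangement_slide",
    "generate_cohort", "class_name", "report_text", "save_slide", "load_slide",
    "save_cohort",
]

# human-readable planted classes, indexed by label
_CLASS_NAMES = [
    "fine striped lesion",
    "medium striped lesion",
    "coarse striped lesion",
    "broad striped lesion",
    "giant striped lesion",
]

_REPORT_TEMPLATE = "final diagnosis: {name}."


def class_name(label: int) -> str:
    return _CLASS_NAMES[label]


def report_text(label: int, gene_status: dict[str, bool] | None = None) -> str:
    """Fixed report template; optional per-gene status sentences are appended."""
    text = _REPORT_TEMPLATE.format(name=class_name(label))
    if gene_status:
        for gene, mutated in sorted(gene_status.items()):
            text += f" {gene} {'mutated' if mutated else 'wild-type'}."
    return text


@dataclass(frozen=True)
class FixtureSpec:
    image_height_px: int = 1024
    image_width_px: int = 1024
    mpp: float = 1.0  # so normalization to 0.5 MPP (x2 upsample) is exercised
    n_blobs: int = 3
    blob_radius_px: int = 140
    n_classes: int = 2
    texture_period_by_class: tuple[int, ...] = (4, 10, 24, 48, 96)
    background_gray: int = 235
    noise_sd: float = 4.0
    period_jitter_sd: float = 0.0  # per-blob jitter of the class period
    seed: int = 0

    def __post_init__(self):
        if self.background_gray <= 200:
            raise ValueError("background_gray must exceed 200 for reliable Otsu separation")
        periods = self.texture_period_by_class[: self.n_classes]
        if len(periods) < self.n_classes:
            raise ValueError("need one texture period per class")
        if len(set(periods)) != len(periods):
            raise ValueError("texture periods must be pairwise distinct")


@dataclass
class PseudoWSI:
    pixels: np.ndarray  # HxWx3 uint8
    mpp: float
    truth_mask: np.ndarray  # HxW bool, 1 on blob pixels
    label: int
    report_text: str
    slide_id: str = "slide"
    patient_id: str = "patient"
    blob_centers: np.ndarray | None = None  # K x 2 (row, col), for geometry oracles


def _blob_centers(spec: FixtureSpec, rng: np.random.Generator,
                  h: int, w: int) -> np.ndarray:
    r = spec.blob_radius_px
    if h < 2 * r + 2 or w < 2 * r + 2:
        raise ValueError("blobs do not fit inside image bounds")
    cy = rng.integers(r + 1, h - r - 1, size=spec.n_blobs)
    cx = rng.integers(r + 1, w - r - 1, size=spec.n_blobs)
    return np.stack([cy, cx], axis=1)


def generate_slide(spec: FixtureSpec, label: int,
                   size_override: tuple[int, int] | None = None,
                   seed_override: int | None = None) -> PseudoWSI:
    """Render one pseudo-slide: dark disks striped at the class's period.

    The stripe runs along the image x axis: inside a blob the gray level is
    ``base + amp * sin(2*pi*x / period)``, darker than background everywhere.
    """
    if not 0 <= label < spec.n_classes:
        raise ValueError(f"label {label} out of range for {spec.n_classes} classes")
    h, w = size_override or (spec.image_height_px, spec.image_width_px)
    seed = spec.seed if seed_override is None else seed_override
    rng = np.random.default_rng(seed)

    img = np.full((h, w), float(spec.background_gray))
    mask = np.zeros((h, w), dtype=bool)
    centers = np.zeros((0, 2), dtype=int)
    if spec.n_blobs > 0:
        base_period = spec.texture_period_by_class[label]
        yy, xx = np.mgrid[0:h, 0:w]
        centers = _blob_centers(spec, rng, h, w)
        for cy, cx in centers:
            period = base_period
            if spec.period_jitter_sd > 0:
                period = max(2.0, base_period + rng.normal(0.0, spec.period_jitter_sd))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.blob_radius_px**2
            stripe = 110.0 + 55.0 * np.sin(2 * np.pi * xx / period)
            img[disk] = stripe[disk]
            mask |= disk
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pixels = np.repeat(pixels[:, :, None], 3, axis=2)
    return PseudoWSI(pixels=pixels, mpp=spec.mpp, truth_mask=mask, label=label,
                     report_text=report_text(label), blob_centers=centers)


def generate_arrangement_slide(spec: FixtureSpec, label: int,
                               seed_override: int | None = None) -> PseudoWSI:
    """A slide whose class is a spatial *arrangement*, not a texture.

    Both classes contain the same mixture of textures — half the blobs carry
    the first period in ``texture_period_by_class``, half the second — but
    the association between position and texture is flipped between classes:
    label 0 puts the finer texture on the left half of the slide, label 1 on
    the right. Tile-marginal statistics are therefore class-uninformative by
    construction; only the joint (coordinate, texture) pattern carries the
    label. This is the planted signal for context-dependent representation
    tests.
    """
    if label not in (0, 1):
        raise ValueError("arrangement slides are binary: label must be 0 or 1")
    h, w = spec.image_height_px, spec.image_width_px
    seed = spec.seed if seed_override is None else seed_override
    rng = np.random.default_rng(seed)
    p_fine, p_coarse = spec.texture_period_by_class[:2]
    img = np.full((h, w), float(spec.background_gray))
    mask = np.zeros((h, w), dtype=bool)
    centers = _blob_centers(spec, rng, h, w)
    rank_by_x = np.empty(len(centers), dtype=int)
    rank_by_x[np.argsort(centers[:, 1])] = np.arange(len(centers))
    half = len(centers) // 2
    yy, xx = np.mgrid[0:h, 0:w]
    # paint in generation (random) order so overlap overwrites carry no
    # systematic texture bias between classes
    for idx, (cy, cx) in enumerate(centers):
        left = rank_by_x[idx] < half
        period = (p_fine if left == (label == 0) else p_coarse)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.blob_radius_px**2
        stripe = 110.0 + 55.0 * np.sin(2 * np.pi * xx / period)
        img[disk] = stripe[disk]
        mask |= disk
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.repeat(np.clip(np.rint(img), 0, 255).astype(np.uint8)[:, :, None], 3, axis=2)
    return PseudoWSI(pixels=pixels, mpp=spec.mpp, truth_mask=mask, label=label,
                     report_text=report_text(label), blob_centers=centers)


def generate_cohort(spec: FixtureSpec, n_patients: int, slides_per_patient: int = 1,
                    gene_by_class: dict[str, int] | None = None,
                    ) -> tuple[list[PseudoWSI], pd.DataFrame]:
    """Balanced cohort: patient i gets class ``i % n_classes``; all of a
    patient's slides share the patient's label and vary in size so a
    "largest slide per patient" rule is well defined.

    ``gene_by_class`` plants synthetic gene tokens: gene g is reported
    "mutated" exactly on patients of the mapped class, else "wild-type".
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(spec.seed)
    slides: list[PseudoWSI] = []
    rows = []
    for i in range(n_patients):
        label = i % spec.n_classes
        patient_id = f"P{i:04d}"
        status = ({g: (label == c) for g, c in gene_by_class.items()}
                  if gene_by_class else None)
        for j in range(slides_per_patient):
            # vary size by whole tiles-at-target-MPP so areas differ distinctly
            scale = 1.0 + 0.25 * float(rng.integers(0, 3))
            h = int(round(spec.image_height_px * scale))
            w = int(round(spec.image_width_px * scale))
            sub_seed = int(zlib.crc32(f"{spec.seed}/{patient_id}/{j}".encode()) & 0x7FFFFFFF)
            s = generate_slide(spec, label, size_override=(h, w), seed_override=sub_seed)
            s.slide_id = f"{patient_id}_S{j}"
            s.patient_id = patient_id
            s.report_text = report_text(label, status)
            slides.append(s)
            rows.append({"slide_id": s.slide_id, "patient_id": patient_id,
                         "label": label, "width": w, "height": h})
    table = pd.DataFrame(rows, columns=["slide_id", "patient_id", "label", "width", "height"])
    return slides, table


# ------------------------------------------------------------------------- IO
def save_slide(slide: PseudoWSI, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{slide.slide_id}.png"
    Image.fromarray(slide.pixels).save(img_path)
    meta = {"mpp": slide.mpp, "label": int(slide.label), "patient_id": slide.patient_id,
            "report_text": slide.report_text}
    (out_dir / f"{slide.slide_id}.json").write_text(json.dumps(meta, indent=1))
    return img_path


def load_slide(img_path: str | Path) -> tuple[np.ndarray, dict]:
    img_path = Path(img_path)
    pixels = np.asarray(Image.open(img_path).convert("RGB"))
    meta = json.loads(img_path.with_suffix(".json").read_text())
    return pixels, meta


def save_cohort(slides: list[PseudoWSI], table: pd.DataFrame, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in slides:
        save_slide(s, out_dir)
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    return csv_path
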