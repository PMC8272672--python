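"""Synthetic knee-MRI phantom generator.

Produces 2-D grayscale slices that mimic the qualitative appearance of
T2-weighted knee MRI in three anatomical planes: moderately bright soft
tissue, a low-signal (dark) anterior cruciate ligament, and a low-signal
meniscus wedge.  A tear shows up as a focal region of elevated signal —
a bright gap interrupting the dark ligament band (ACL task) or a bright
line crossing the meniscus wedge (meniscus task) — which is how acute
tears present on fluid-sensitive sequences.

The geometry is deliberately minimal: it is a phantom for exercising and
validating the feature-extraction and fusion pipeline, not a physical MR
simulation.  Per-image jitter (band offset, orientation, tear position)
plus additive Gaussian noise provide the variability; every image records
the sampled geometry and the lesion masks so tests can measure lesion
contrast exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, DataIOError

PLANES = ("sagittal", "coronal", "transverse")

# Base intensities on the [0, 1] scale, kept away from 0/1 so that additive
# noise is rarely clipped.
_BACKGROUND = 0.55
_LIGAMENT = 0.25
_MENISCUS = 0.30


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic dataset."""

    image_size: int = 64
    plane: str = "sagittal"
    acl_tear_prob: float = 0.5
    meniscus_tear_prob: float = 0.5
    lesion_contrast: float = 0.4
    noise_sd: float = 0.1
    n_images: int = 200
    seed: int = 0
    noise_model: str = "gaussian"  # "gaussian" or "rician"

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("phantom.image_size must be >= 32")
        if self.plane not in PLANES:
            raise ConfigurationError(
                f"phantom.plane must be one of {PLANES}, got {self.plane!r}"
            )
        for name in ("acl_tear_prob", "meniscus_tear_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"phantom.{name} must lie in [0, 1], got {p}")
        if self.lesion_contrast < 0:
            raise ConfigurationError("phantom.lesion_contrast must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("phantom.noise_sd must be >= 0")
        if self.n_images < 1:
            raise ConfigurationError("phantom.n_images must be >= 1")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(
                "phantom.noise_model must be 'gaussian' or 'rician'"
            )


@dataclass
class LabeledImage:
    """One grayscale slice with its plane tag and binary task labels.

    ``meta`` carries the sampled geometry parameters and the boolean lesion
    masks (``acl_lesion_mask``, ``meniscus_lesion_mask``).  The masks are
    recorded for every image, positive or not, so the intensity inside the
    would-be lesion region can be compared across labels.
    """

    pixels: np.ndarray
    plane: str
    acl_tear: int
    meniscus_tear: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ConfigurationError("LabeledImage.pixels must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ConfigurationError("LabeledImage.pixels must lie in [0, 1]")
        if self.plane not in PLANES:
            raise ConfigurationError(f"unknown plane {self.plane!r}")
        if self.acl_tear not in (0, 1) or self.meniscus_tear not in (0, 1):
            raise ConfigurationError("labels must be 0 or 1")

    def label(self, task: str) -> int:
        if task == "acl_tear":
            return self.acl_tear
        if task == "meniscus_tear":
            return self.meniscus_tear
        raise ConfigurationError(f"unknown task {task!r}")


def _coordinate_grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    r, c = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return r.astype(float), c.astype(float)


def _band_mask(size: int, angle: float, offset: float, half_width: float) -> np.ndarray:
    """Straight ligament band: pixels within half_width of a center line."""
    r, c = _coordinate_grids(size)
    # Line through the (offset-shifted) image center at the given angle.
    cr = size / 2.0 + offset
    cc = size / 2.0
    n_r, n_c = -np.sin(angle), np.cos(angle)  # unit normal of the line
    dist = (r - cr) * n_c - (c - cc) * n_r
    return np.abs(dist) <= half_width


def _band_coordinate(size: int, angle: float, offset: float) -> np.ndarray:
    """Signed position of each pixel along the band's center line."""
    r, c = _coordinate_grids(size)
    cr = size / 2.0 + offset
    cc = size / 2.0
    # unit direction along the line is the normal rotated 90 degrees
    return -(r - cr) * np.sin(angle) + (c - cc) * np.cos(angle)


def _wedge_mask(size: int, apex_r: float, apex_c: float, height: float,
                base_half: float) -> np.ndarray:
    """Meniscus wedge: triangle with apex pointing toward the joint center."""
    r, c = _coordinate_grids(size)
    depth = r - apex_r  # grows toward the image bottom (tibial side)
    inside = (depth >= 0) & (depth <= height)
    with np.errstate(divide="ignore", invalid="ignore"):
        spread = np.abs(c - apex_c) <= base_half * np.where(height > 0, depth / height, 0.0)
    return inside & spread


def _sample_geometry(size: int, plane: str, rng: np.random.Generator) -> dict:
    """Per-image anatomy with jitter; all lengths in pixels."""
    geo: dict = {"plane": plane}
    jitter = lambda scale: rng.uniform(-scale, scale)  # noqa: E731
    if plane in ("sagittal", "coronal"):
        base_angle = np.deg2rad(45.0) if plane == "sagittal" else np.deg2rad(90.0)
        geo["band_angle"] = base_angle + np.deg2rad(jitter(8.0))
        geo["band_offset"] = jitter(0.08 * size)
        geo["band_half_width"] = max(2.0, 0.045 * size) + jitter(0.5)
        geo["tear_center"] = jitter(0.15 * size)
        geo["tear_half_len"] = max(2.5, 0.06 * size) + jitter(0.5)
    else:
        # Transverse slice: the ligament is seen in cross-section as a small
        # dark ellipse near the intercondylar notch.
        geo["acl_center"] = (size * (0.45 + 0.05 * rng.uniform(-1, 1)),
                            size * (0.5 + 0.05 * rng.uniform(-1, 1)))
        geo["acl_radius"] = max(3.0, 0.06 * size) + jitter(0.5)
    # Meniscus wedge near the bottom (posterior horn), all planes.
    geo["wedge_apex"] = (size * (0.68 + 0.04 * rng.uniform(-1, 1)),
                        size * (0.5 + 0.10 * rng.uniform(-1, 1)))
    geo["wedge_height"] = max(5.0, 0.16 * size) + jitter(1.0)
    geo["wedge_base_half"] = max(4.0, 0.14 * size) + jitter(1.0)
    geo["meniscus_tear_col"] = geo["wedge_apex"][1] + jitter(0.05 * size)
    geo["meniscus_tear_half_width"] = max(1.0, 0.018 * size)
    return geo


def _render(size: int, geo: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free anatomy plus the two lesion masks."""
    img = np.full((size, size), _BACKGROUND)
    plane = geo["plane"]
    if plane in ("sagittal", "coronal"):
        band = _band_mask(size, geo["band_angle"], geo["band_offset"],
                          geo["band_half_width"])
        img[band] = _LIGAMENT
        along = _band_coordinate(size, geo["band_angle"], geo["band_offset"])
        acl_mask = band & (np.abs(along - geo["tear_center"]) <= geo["tear_half_len"])
    else:
        r, c = _coordinate_grids(size)
        cr, cc = geo["acl_center"]
        disc = (r - cr) ** 2 + (c - cc) ** 2 <= geo["acl_radius"] ** 2
        img[disc] = _LIGAMENT
        acl_mask = disc
    wedge = _wedge_mask(size, geo["wedge_apex"][0], geo["wedge_apex"][1],
                        geo["wedge_height"], geo["wedge_base_half"])
    img[wedge] = _MENISCUS
    _, cgrid = _coordinate_grids(size)
    men_mask = wedge & (np.abs(cgrid - geo["meniscus_tear_col"])
                        <= geo["meniscus_tear_half_width"])
    return img, acl_mask, men_mask


def _add_noise(img: np.ndarray, sd: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.clip(img, 0.0, 1.0)
    if model == "gaussian":
        noisy = img + rng.normal(0.0, sd, size=img.shape)
    else:  # Rician: magnitude of complex Gaussian noise around the signal
        re = img + rng.normal(0.0, sd, size=img.shape)
        im = rng.normal(0.0, sd, size=img.shape)
        noisy = np.hypot(re, im)
    return np.clip(noisy, 0.0, 1.0)


def generate_dataset(config: PhantomConfig) -> list[LabeledImage]:
    """Generate ``config.n_images`` labeled phantom slices.

    Tear labels are sampled independently per image at the configured
    probabilities.  For a positive label, the corresponding lesion mask is
    brightened by ``lesion_contrast`` before noise is added; the mask itself
    is recorded in ``meta`` for every image.  Identical config (including
    seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    images: list[LabeledImage] = []
    for _ in range(config.n_images):
        acl = int(rng.random() < config.acl_tear_prob)
        men = int(rng.random() < config.meniscus_tear_prob)
        geo = _sample_geometry(config.image_size, config.plane, rng)
        img, acl_mask, men_mask = _render(config.image_size, geo)
        if acl:
            img[acl_mask] += config.lesion_contrast
        if men:
            img[men_mask] += config.lesion_contrast
        img = _add_noise(img, config.noise_sd, config.noise_model, rng)
        images.append(LabeledImage(
            pixels=img, plane=config.plane, acl_tear=acl, meniscus_tear=men,
            meta={"geometry": geo, "acl_lesion_mask": acl_mask,
                  "meniscus_lesion_mask": men_mask},
        ))
    return images


# ---------------------------------------------------------------------------
# Dataset I/O: 8-bit grayscale PNG (default) or 16-bit NIfTI-1, plus a CSV
# manifest with columns file, plane, acl_tear, meniscus_tear.
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["file", "plane", "acl_tear", "meniscus_tear"]


def write_dataset(images: Sequence[LabeledImage], directory: str | os.PathLike,
                  fmt: str = "png") -> str:
    """Write images plus a CSV manifest; returns the manifest path.

    ``fmt='png'`` stores 8-bit grayscale PNG (quantization error <= 1/255);
    ``fmt='nifti16'`` stores uint16 NIfTI-1 (error <= 1/65535).
    """
    if fmt not in ("png", "nifti16"):
        raise ConfigurationError(f"unknown dataset format {fmt!r}")
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        if fmt == "png":
            fname = f"img_{i:05d}.png"
            data = np.round(im.pixels * 255.0).astype(np.uint8)
            Image.fromarray(data, mode="L").save(os.path.join(directory, fname))
        else:
            import nibabel as nib

            fname = f"img_{i:05d}.nii"
            data = np.round(im.pixels * 65535.0).astype(np.uint16)
            nii = nib.Nifti1Image(data, affine=np.eye(4))
            nii.to_filename(os.path.join(directory, fname))
        rows.append({"file": fname, "plane": im.plane,
                     "acl_tear": im.acl_tear, "meniscus_tear": im.meniscus_tear})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = os.path.join(directory, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(directory: str | os.PathLike) -> list[LabeledImage]:
    """Read a dataset written by :func:`write_dataset`."""
    manifest_path = os.path.join(directory, "manifest.csv")
    if not os.path.exists(manifest_path):
        raise DataIOError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataIOError(f"manifest missing columns: {missing}")
    if manifest["file"].duplicated().any():
        dups = manifest.loc[manifest["file"].duplicated(), "file"].tolist()
        raise DataIOError(f"duplicate manifest rows for files: {dups}")
    images: list[LabeledImage] = []
    for row in manifest.itertuples(index=False):
        path = os.path.join(directory, row.file)
        if not os.path.exists(path):
            raise DataIOError(f"image listed in manifest but missing: {path}")
        if row.file.endswith(".png"):
            arr = np.asarray(Image.open(path), dtype=np.float64) / 255.0
        elif row.file.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            arr = np.asarray(nib.load(path).dataobj, dtype=np.float64) / 65535.0
        else:
            raise DataIOError(f"unsupported image format: {row.file}")
        images.append(LabeledImage(pixels=arr, plane=row.plane,
                                   acl_tear=int(row.acl_tear),
                                   meniscus_tear=int(row.meniscus_tear)))
    return images
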