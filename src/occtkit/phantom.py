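"""Seeded synthetic OCT-like phantoms.

Renders grayscale images with stacked horizontal reflectance bands
(mimicking retinal layers), class-specific lesions, multiplicative
speckle noise and a white frame, so every downstream stage of the
pipeline can be exercised without any external dataset.

Class archetypes
----------------
NORMAL  clean band stack.
DRUSEN  small bright bumps deforming a deep band upward.
DME     dark elliptical cavities inside the mid bands.
CNV     one irregular bright mass below the band stack.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASSES = ("CNV", "DME", "DRUSEN", "NORMAL")

# Alternating hyper-/hypo-reflective band palette spanning [40, 200].
_BRIGHT, _DARK = 200, 40
_BACKGROUND = 8


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded recipe for one class-labeled synthetic OCT image."""

    label: str
    height: int = 224
    width: int = 224
    n_layers: int = 8
    curvature: float = 6.0
    lesion_count: int = 4
    lesion_radius: float = 9.0
    speckle_sigma: float = 0.05
    border_width: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASSES:
            raise PhantomError(
                f"unknown class label {self.label!r}; expected one of {CLASSES}")
        if self.height <= 0 or self.width <= 0:
            raise PhantomError("height and width must be positive")
        if not (0 <= self.border_width < min(self.height, self.width) / 2):
            raise PhantomError("border_width must lie in [0, min(H,W)/2)")
        if self.speckle_sigma < 0:
            raise PhantomError("speckle_sigma must be non-negative")
        if self.n_layers < 1:
            raise PhantomError("n_layers must be >= 1")


def _band_palette(n: int) -> np.ndarray:
    vals = np.empty(n)
    for i in range(n):
        step = 20 * (i // 2)
        vals[i] = (_BRIGHT - step) if i % 2 == 0 else (_DARK + step)
    return np.clip(vals, _DARK, _BRIGHT)


def _render_noiseless(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    img = np.full((h, w), _BACKGROUND, dtype=np.float64)

    # sinusoidally displaced band stack between 0.25 H and 0.75 H
    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    disp = spec.curvature * np.sin(2 * np.pi * x / w + phase)
    top = 0.25 * h + disp
    bottom = 0.75 * h + disp
    thickness = (bottom - top) / spec.n_layers
    rows = np.arange(h)[:, None]
    palette = _band_palette(spec.n_layers)
    for i in range(spec.n_layers):
        lo = top + i * thickness
        hi = top + (i + 1) * thickness
        img[(rows >= lo) & (rows < hi)] = palette[i]

    if spec.label == "DRUSEN":
        # bright bumps sitting on a deep band (second from the bottom)
        band_idx = max(spec.n_layers - 2, 0)
        for _ in range(spec.lesion_count):
            cx = rng.integers(spec.border_width + 5, w - spec.border_width - 5)
            r = spec.lesion_radius * rng.uniform(0.8, 1.3)
            cy = top[cx % w] + band_idx * thickness[cx % w]
            yy, xx = np.ogrid[:h, :w]
            bump = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2) & (yy <= cy)
            img[bump] = _BRIGHT
    elif spec.label == "DME":
        # dark elliptical cavities inside the mid bands
        for _ in range(spec.lesion_count):
            cx = rng.integers(spec.border_width + 5, w - spec.border_width - 5)
            cy = rng.uniform(0.35 * h, 0.6 * h)
            a = spec.lesion_radius * rng.uniform(1.0, 1.8)
            b = spec.lesion_radius * rng.uniform(0.5, 1.0)
            yy, xx = np.ogrid[:h, :w]
            cavity = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
            img[cavity] = 15
    elif spec.label == "CNV":
        # one irregular bright mass below the band stack
        cx = rng.integers(w // 4, 3 * w // 4)
        cy = rng.uniform(0.80 * h, 0.88 * h)
        yy, xx = np.ogrid[:h, :w]
        mass = np.zeros((h, w), dtype=bool)
        for _ in range(max(spec.lesion_count, 3)):
            ox = cx + rng.normal(0, spec.lesion_radius)
            oy = cy + rng.normal(0, spec.lesion_radius * 0.5)
            r = spec.lesion_radius * rng.uniform(0.7, 1.4)
            mass |= (xx - ox) ** 2 + (yy - oy) ** 2 <= r ** 2
        img[mass] = 220

    # smooth band boundaries
    img = gaussian_filter(img, sigma=1.0, mode="nearest")
    return img


def render_noiseless(spec: PhantomSpec) -> np.ndarray:
    """The band/lesion render with no speckle and no frame, as uint8."""
    rng = np.random.default_rng(spec.seed)
    return np.rint(np.clip(_render_noiseless(spec, rng), 0, 255)).astype(np.uint8)


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, str]:
    """Render a phantom, returning a (H, W) uint8 image and its label.

    Same spec (including seed) renders bit-identically.
    """
    rng = np.random.default_rng(spec.seed)
    img = _render_noiseless(spec, rng)
    if spec.speckle_sigma > 0:
        eps = rng.normal(0.0, spec.speckle_sigma, size=img.shape)
        img = img * (1.0 + eps)
    img = np.clip(img, 0, 255)
    bw = spec.border_width
    if bw > 0:
        img[:bw, :] = 255
        img[-bw:, :] = 255
        img[:, :bw] = 255
        img[:, -bw:] = 255
    return np.rint(img).astype(np.uint8), spec.label


def _child_seed(base_seed: int, class_index: int, i: int) -> int:
    ss = np.random.SeedSequence(entropy=(base_seed, class_index, i))
    return int(ss.generate_state(1)[0])


def render_dataset(counts_per_class: dict[str, int], base_seed: int,
                   out_root, spec_template: PhantomSpec | None = None) -> list[dict]:
    """Render a folder-per-class dataset of phantoms plus a CSV manifest.

    Returns the manifest records: ``{"path", "label", "seed"}`` per image.
    """
    out_root = Path(out_root)
    for label, n in counts_per_class.items():
        if label not in CLASSES:
            raise PhantomError(f"unknown class label {label!r}")
        if n < 0:
            raise PhantomError("counts must be non-negative")
    records = []
    for label in sorted(counts_per_class):
        cls_dir = out_root / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        ci = CLASSES.index(label)
        for i in range(counts_per_class[label]):
            seed = _child_seed(base_seed, ci, i)
            if spec_template is None:
                spec = PhantomSpec(label=label, seed=seed)
            else:
                spec = replace(spec_template, label=label, seed=seed)
            img, _ = render_phantom(spec)
            path = cls_dir / f"{label.lower()}_{i:05d}.png"
            Image.fromarray(img).save(path)
            records.append({"path": str(path), "label": label, "seed": seed})
    manifest_path = out_root / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "seed"])
        writer.writeheader()
        writer.writerows(records)
    return records


def render_array_dataset(counts_per_class: dict[str, int], base_seed: int,
                         spec_template: PhantomSpec | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """In-memory variant of :func:`render_dataset`.

    Returns (images, labels): uint8 array (N, H, W) and integer labels
    indexing into :data:`CLASSES`.
    """
    imgs, labels = [], []
    for label in sorted(counts_per_class):
        if label not in CLASSES:
            raise PhantomError(f"unknown class label {label!r}")
        ci = CLASSES.index(label)
        for i in range(counts_per_class[label]):
            seed = _child_seed(base_seed, ci, i)
            if spec_template is None:
                spec = PhantomSpec(label=label, seed=seed)
            else:
                spec = replace(spec_template, label=label, seed=seed)
            img, _ = render_phantom(spec)
            imgs.append(img)
            labels.append(ci)
    return np.stack(imgs), np.asarray(labels, dtype=np.int64)
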