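"""PSNR / SSIM computation and the paired real-vs-synthetic quality report.

SSIM follows the reference Gaussian-window formulation: 11x11 window,
sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 255, averaged over the
'valid' interior (windows fully inside the image).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import correlate

from .phantom import CLASSES

_K1, _K2 = 0.01, 0.03
_WIN, _SIGMA = 11, 1.5
_L = 255.0


class QualityError(ValueError):
    pass


def _to_gray_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img.astype(np.float64)


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(255^2 / MSE).

    Identical images yield ``math.inf`` (never a finite number).
    """
    a, b = _to_gray_float(a), _to_gray_float(b)
    if a.shape != b.shape:
        raise QualityError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(_L * _L / mse)


def gaussian_window(size: int = _WIN, sigma: float = _SIGMA) -> np.ndarray:
    half = (size - 1) / 2
    coords = np.arange(size) - half
    g = np.exp(-(coords ** 2) / (2 * sigma ** 2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local structural similarity over valid Gaussian windows."""
    a, b = _to_gray_float(a), _to_gray_float(b)
    if a.shape != b.shape:
        raise QualityError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < _WIN:
        raise QualityError(f"image smaller than the {_WIN}x{_WIN} SSIM window")
    w = gaussian_window()

    def filt(x):
        return correlate(x, w, mode="constant")

    mu_a, mu_b = filt(a), filt(b)
    sig_a = filt(a * a) - mu_a ** 2
    sig_b = filt(b * b) - mu_b ** 2
    sig_ab = filt(a * b) - mu_a * mu_b
    c1 = (_K1 * _L) ** 2
    c2 = (_K2 * _L) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * sig_ab + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (sig_a + sig_b + c2)
    smap = num / den
    half = _WIN // 2
    interior = smap[half:-half, half:-half]
    return float(interior.mean())


@dataclass(frozen=True)
class ClassQuality:
    label: str
    n_pairs: int
    mean_psnr: float          # arithmetic mean over pairs with finite PSNR
    psnr_infinite_count: int  # identical pairs, excluded from the mean
    mean_ssim: float
    pairs: tuple              # per-pair (real, synth, psnr, ssim) log


@dataclass(frozen=True)
class QualityReport:
    classes: tuple[ClassQuality, ...]

    @property
    def overall_psnr(self) -> float:
        return float(np.mean([c.mean_psnr for c in self.classes]))

    @property
    def overall_ssim(self) -> float:
        return float(np.mean([c.mean_ssim for c in self.classes]))

    def to_dict(self) -> dict:
        def _num(v):
            return None if math.isinf(v) or math.isnan(v) else v
        return {
            "classes": {
                c.label: {"n_pairs": c.n_pairs, "mean_psnr": _num(c.mean_psnr),
                          "psnr_infinite_count": c.psnr_infinite_count,
                          "mean_ssim": c.mean_ssim}
                for c in self.classes},
            "overall_psnr": _num(self.overall_psnr),
            "overall_ssim": self.overall_ssim,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


def _list_images(root: Path) -> list[Path]:
    return sorted(p for p in root.iterdir()
                  if p.suffix.lower() in _IMAGE_EXTS)


def _class_dirs(root: Path) -> dict[str, Path]:
    subs = {p.name.upper(): p for p in root.iterdir() if p.is_dir()}
    matched = {k: v for k, v in subs.items() if k in CLASSES}
    if matched:
        return matched
    return {"ALL": root}


def quality_report(real_dir, synth_dir, n_per_side: int = 50,
                   seed: int = 0) -> QualityReport:
    """Seeded paired PSNR/SSIM report between real and synthetic folders.

    ``n_per_side`` images are sampled (without replacement) from each
    side per class; the i-th sampled real image is paired with the i-th
    sampled synthetic image.
    """
    real_dir, synth_dir = Path(real_dir), Path(synth_dir)
    real_classes = _class_dirs(real_dir)
    synth_classes = _class_dirs(synth_dir)
    labels = sorted(set(real_classes) & set(synth_classes))
    if not labels:
        raise QualityError("no common class folders between the two roots")
    classes = []
    for ci, label in enumerate(labels):
        reals = _list_images(real_classes[label])
        synths = _list_images(synth_classes[label])
        for side, files in (("real", reals), ("synthetic", synths)):
            if len(files) < n_per_side:
                raise QualityError(
                    f"class {label}: need {n_per_side} {side} images, "
                    f"found {len(files)} ({n_per_side - len(files)} short)")
        # each side samples with an identically seeded stream, so two
        # identical folders sample (and hence pair) the same files
        entropy = np.random.SeedSequence((seed, ci)).generate_state(1)[0]
        ridx = np.random.default_rng(entropy).choice(
            len(reals), size=n_per_side, replace=False)
        sidx = np.random.default_rng(entropy).choice(
            len(synths), size=n_per_side, replace=False)
        pairs = []
        for ri, si in zip(ridx, sidx):
            a = np.asarray(Image.open(reals[ri]))
            b = np.asarray(Image.open(synths[si]))
            pairs.append((str(reals[ri]), str(synths[si]),
                          psnr(a, b), ssim(a, b)))
        psnrs = [p[2] for p in pairs]
        finite = [v for v in psnrs if math.isfinite(v)]
        mean_psnr = float(np.mean(finite)) if finite else math.inf
        classes.append(ClassQuality(
            label=label, n_pairs=n_per_side, mean_psnr=mean_psnr,
            psnr_infinite_count=sum(1 for v in psnrs if math.isinf(v)),
            mean_ssim=float(np.mean([p[3] for p in pairs])),
            pairs=tuple(pairs)))
    return QualityReport(tuple(classes))
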