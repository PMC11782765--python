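"""Dataset folder I/O, resizing, run configuration and the pipeline driver."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import dcgan, phantom, preprocess as pp, traineval
from .occt import OCCT, OCCTConfig, build_occt, count_parameters
from .phantom import CLASSES

log = logging.getLogger("occtkit")

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# Manifest and folder loading
# ---------------------------------------------------------------------------

@dataclass
class ManifestRecord:
    path: str
    label: str
    origin: str = "real"       # real | synthetic
    split: str = ""            # train | test | ""


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    unreadable: list[str] = field(default_factory=list)

    def histogram(self) -> dict[str, int]:
        hist = {c: 0 for c in CLASSES}
        for r in self.records:
            hist[r.label] += 1
        return hist

    def save(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "label", "origin", "split"])
            for r in self.records:
                w.writerow([r.path, r.label, r.origin, r.split])


def load_image_folder(root) -> DatasetManifest:
    """Enumerate a one-subdirectory-per-class image folder.

    Class folder names are matched case-insensitively against the 4-class
    vocabulary; any other subdirectory is an error. Unreadable images are
    reported in ``manifest.unreadable``, not silently dropped.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError_(f"{root} is not a directory")
    records, unreadable = [], []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        label = sub.name.upper()
        if label not in CLASSES:
            raise IOError_(f"unexpected class folder {sub.name!r}; expected "
                           f"one of {CLASSES} (case-insensitive)")
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in _IMAGE_EXTS:
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
                records.append(ManifestRecord(str(f), label))
            except Exception:
                unreadable.append(str(f))
    return DatasetManifest(records, unreadable)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def load_arrays(manifest: DatasetManifest, side: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Read all manifest images (optionally resized) as uint8 arrays."""
    imgs, labels = [], []
    for r in manifest.records:
        img = read_image(r.path)
        if side is not None:
            img = resize(img, side)
        imgs.append(img)
        labels.append(CLASSES.index(r.label))
    return np.stack(imgs), np.asarray(labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------

def resize(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to side x side (grayscale or 3-channel uint8)."""
    if side < 1:
        raise IOError_("side must be >= 1")
    img = np.asarray(img)
    if img.shape[:2] == (side, side):
        return img
    return np.asarray(Image.fromarray(img).resize((side, side),
                                                  Image.BILINEAR))


def to_rgb(img: np.ndarray) -> np.ndarray:
    """Replicate a grayscale image to 3 channels (no-op on 3-channel input)."""
    img = np.asarray(img)
    if img.ndim == 2:
        return np.repeat(img[..., None], 3, axis=2)
    return img


# ---------------------------------------------------------------------------
# Model checkpointing
# ---------------------------------------------------------------------------

def save_model(model: OCCT, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=json.dumps(dataclasses.asdict(model.cfg)),
             **model.state_dict())


def load_model(path) -> OCCT:
    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(data["__config__"]))
    cfg_dict["tokenizer_channels"] = tuple(cfg_dict["tokenizer_channels"])
    model = build_occt(OCCTConfig(**cfg_dict))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model.eval()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Nested configuration for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "runs/pipeline"
    # data: either a folder of class subdirectories, or phantom counts
    data_root: str = ""
    phantom_counts: dict = field(default_factory=lambda: {c: 40 for c in CLASSES})
    phantom_size: int = 64
    # gan section
    gan_enabled: bool = False
    gan_classes: tuple = ("DME", "DRUSEN")
    gan_steps: int = 50
    gan_image_size: int = 32
    gan_batch_size: int = 16
    gan_generate: dict = field(default_factory=lambda: {"DME": 8, "DRUSEN": 8})
    # preprocess section
    preprocess_enabled: bool = True
    erosion_kernel: int = 5
    median_window: int = 3
    alpha: float = 1.0
    beta: float = 2.0
    # model section
    n_blocks: int = 1
    tokenizer_kernel: int = 3
    activation: str = "elu"
    pool: str = "max"
    input_size: int = 32
    # train section
    epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    test_frac: float = 0.3

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gan_classes"] = list(d["gan_classes"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "gan_classes" in d:
            d["gan_classes"] = tuple(d["gan_classes"])
        return cls(**d)

    def model_config(self) -> OCCTConfig:
        return OCCTConfig(n_blocks=self.n_blocks,
                          tokenizer_kernel=self.tokenizer_kernel,
                          activation=self.activation, pool=self.pool,
                          input_size=self.input_size)

    def train_config(self) -> traineval.TrainConfig:
        return traineval.TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, optimizer=self.optimizer,
            loss=self.loss, seed=self.seed)

    def preprocess_config(self) -> pp.PreprocessConfig:
        return pp.PreprocessConfig(erosion_kernel=self.erosion_kernel,
                                   median_window=self.median_window,
                                   alpha=self.alpha, beta=self.beta)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute augment -> preprocess -> train -> evaluate, logging each stage.

    Returns a dict of artifact paths; every artifact is written under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    artifacts = {"config": str(out / "config.yaml")}

    # -- stage: data --------------------------------------------------------
    try:
        if cfg.data_root:
            manifest = load_image_folder(cfg.data_root)
            images, labels = load_arrays(manifest)
        else:
            log.info("rendering phantom dataset: %s", cfg.phantom_counts)
            spec = phantom.PhantomSpec(label="NORMAL", height=cfg.phantom_size,
                                       width=cfg.phantom_size, curvature=3.0,
                                       lesion_radius=6.0, border_width=4,
                                       seed=0)
            images, labels = phantom.render_array_dataset(
                cfg.phantom_counts, cfg.seed, spec_template=spec)
    except Exception as e:
        raise IOError_(f"[stage: data] {e}") from e

    origins = ["real"] * len(images)

    # -- stage: augment -----------------------------------------------------
    if cfg.gan_enabled:
        try:
            gan_cfg = dcgan.GanConfig(image_size=cfg.gan_image_size,
                                      batch_size=cfg.gan_batch_size,
                                      seed=cfg.seed)
            for label in cfg.gan_classes:
                ci = CLASSES.index(label)
                pool_imgs = np.stack([resize(im, cfg.gan_image_size)
                                      for im in images[labels == ci]])
                gen, _ = dcgan.train_dcgan(pool_imgs, gan_cfg,
                                           steps=cfg.gan_steps)
                n_new = int(cfg.gan_generate.get(label, 0))
                if n_new <= 0:
                    continue
                synth = dcgan.synthesize(gen, n_new, seed=cfg.seed)
                synth_gray = np.stack([
                    resize(s.mean(axis=2).astype(np.uint8), images.shape[1])
                    for s in synth])
                images = np.concatenate([images, synth_gray])
                labels = np.concatenate([labels, np.full(n_new, ci)])
                origins += ["synthetic"] * n_new
        except Exception as e:
            raise IOError_(f"[stage: augment] {e}") from e

    # -- stage: preprocess --------------------------------------------------
    processed = "unprocessed"
    if cfg.preprocess_enabled:
        try:
            pcfg = cfg.preprocess_config()
            images = np.stack([
                resize(pp.preprocess(im, pcfg), images.shape[1])
                for im in images])
            processed = "preprocessed"
        except Exception as e:
            raise IOError_(f"[stage: preprocess] {e}") from e

    manifest = DatasetManifest([
        ManifestRecord(path=f"<memory:{i}:{processed}>",
                       label=CLASSES[l], origin=o)
        for i, (l, o) in enumerate(zip(labels, origins))])

    # -- stage: train -------------------------------------------------------
    try:
        side = cfg.input_size
        X = traineval.prepare_inputs(
            np.stack([resize(im, side) for im in images]))
        Xtr, ytr, Xte, yte = traineval.split_arrays(X, labels, cfg.test_frac,
                                                    cfg.seed)
        model = build_occt(cfg.model_config(), seed=cfg.seed)
        log.info("model parameters: %d", count_parameters(model))
        history = traineval.train_classifier(model, Xtr, ytr, cfg.train_config())
    except Exception as e:
        raise IOError_(f"[stage: train] {e}") from e

    # -- stage: evaluate ----------------------------------------------------
    try:
        cm = traineval.evaluate(model, Xte, yte)
        report = traineval.compute_metrics(cm)
    except Exception as e:
        raise IOError_(f"[stage: evaluate] {e}") from e

    manifest.save(out / "manifest.csv")
    np.savetxt(out / "confusion.csv", cm.counts, fmt="%d", delimiter=",")
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "history.json").write_text(json.dumps(history, indent=2))
    save_model(model, out / "model.npz")
    artifacts.update({
        "manifest": str(out / "manifest.csv"),
        "confusion": str(out / "confusion.csv"),
        "metrics": str(out / "metrics.json"),
        "history": str(out / "history.json"),
        "model": str(out / "model.npz"),
    })
    return artifacts
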