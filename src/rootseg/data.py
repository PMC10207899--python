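"""Dataset I/O, five-way augmentation, group-aware splitting, tiled inference.

Annotations come either as LabelMe polygon JSON or as paletted PNG masks
using the red-root / black-background convention; both rasterize to
binary masks (root = 1).  Augmentation produces exactly five variants per
original (luminance up/down, isometric scale up/down, salt-and-pepper
noise); photometric variants share the original's mask, geometric
variants resample it with nearest-neighbour interpolation.  Splitting is
group-aware: all augmented copies of one source image stay in the same
partition, so augmentations of a test image can never leak into training.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize as sk_resize

from .errors import DataError, ShapeError
from .nn import autograd as ag

AUGMENTATION_KINDS = ("luminance_up", "luminance_down", "scale_up",
                      "scale_down", "salt_pepper")
PROVENANCES = ("original",) + AUGMENTATION_KINDS

RED = (255, 0, 0)
BLACK = (0, 0, 0)


@dataclass
class RootSample:
    """One image/mask pair with provenance bookkeeping."""

    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) in {0, 1}
    id: str
    provenance: str = "original"
    group_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ShapeError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                f"dims differ for sample {self.id}")
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError(f"mask of {self.id} is not binary")
        if self.provenance not in PROVENANCES:
            raise DataError(f"unknown provenance {self.provenance!r}")
        if not self.group_id:
            self.group_id = self.id


@dataclass(frozen=True)
class AugmentationSpec:
    """Factors of the five augmentation variants."""

    luminance_up: float = 1.2
    luminance_down: float = 0.8
    scale_up: float = 1.2
    scale_down: float = 0.8
    salt_pepper_density: float = 0.02

    def __post_init__(self):
        for name in ("luminance_up", "luminance_down", "scale_up",
                     "scale_down"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if not 0 < self.salt_pepper_density < 0.5:
            raise DataError("salt_pepper_density must be in (0, 0.5)")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test id lists covering the dataset."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    ratio: tuple[int, int, int] = (6, 2, 2)
    seed: int = 0


# ---------------------------------------------------------------------
# annotation reading / writing
# ---------------------------------------------------------------------

def read_labelme(json_path, root_label: str = "root") -> np.ndarray:
    """Rasterize a LabelMe polygon annotation to a binary root mask.

    Polygons labeled `root_label` are filled and unioned; shapes with
    other labels are skipped with a warning.
    """
    path = Path(json_path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise DataError(f"cannot read LabelMe JSON {path}: {e}") from e
    try:
        h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
        shapes = doc.get("shapes", [])
    except (KeyError, TypeError) as e:
        raise DataError(f"malformed LabelMe JSON {path}: {e}") from e
    mask = np.zeros((h, w), dtype=np.uint8)
    for shape in shapes:
        if shape.get("label") != root_label:
            warnings.warn(
                f"{path.name}: skipping shape with label "
                f"{shape.get('label')!r}", stacklevel=2)
            continue
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(f"{path.name}: skipping degenerate polygon",
                          stacklevel=2)
            continue
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=mask.shape)
        mask[rr, cc] = 1
    return mask


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as a paletted PNG (root red, background black)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise DataError("mask must be binary to write")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(list(BLACK) + list(RED))
    img.save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a red/black mask PNG back to a binary array."""
    img = Image.open(path)
    rgb = np.asarray(img.convert("RGB"))
    is_red = (rgb == RED).all(axis=-1)
    is_black = (rgb == BLACK).all(axis=-1)
    ok = is_red | is_black
    if not ok.all():
        bad = np.unique(rgb[~ok].reshape(-1, 3), axis=0)[:5]
        raise DataError(
            f"mask {path} contains colors other than red/black: "
            f"{bad.tolist()}")
    return is_red.astype(np.uint8)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def _scale(sample: RootSample, factor: float, kind: str) -> RootSample:
    h, w = sample.mask.shape
    nh, nw = int(round(h * factor)), int(round(w * factor))
    img = sk_resize(sample.image, (nh, nw), order=1, preserve_range=True,
                    anti_aliasing=factor < 1.0)
    msk = sk_resize(sample.mask, (nh, nw), order=0, preserve_range=True,
                    anti_aliasing=False)
    return RootSample(image=np.round(img).astype(np.uint8),
                      mask=msk.astype(np.uint8),
                      id=f"{sample.id}-{kind}", provenance=kind,
                      group_id=sample.group_id)


def _luminance(sample: RootSample, factor: float, kind: str) -> RootSample:
    img = np.clip(sample.image.astype(np.float64) * factor, 0, 255)
    return RootSample(image=np.round(img).astype(np.uint8),
                      mask=sample.mask.copy(),
                      id=f"{sample.id}-{kind}", provenance=kind,
                      group_id=sample.group_id)


def _salt_pepper(sample: RootSample, density: float,
                 rng: np.random.Generator) -> RootSample:
    img = sample.image.copy()
    h, w = sample.mask.shape
    hits = rng.random((h, w)) < density
    salt = rng.random((h, w)) < 0.5
    img[hits & salt] = 255
    img[hits & ~salt] = 0
    return RootSample(image=img, mask=sample.mask.copy(),
                      id=f"{sample.id}-salt_pepper",
                      provenance="salt_pepper", group_id=sample.group_id)


def augment_sample(sample: RootSample, spec: AugmentationSpec | None = None,
                   rng: np.random.Generator | None = None) -> list[RootSample]:
    """The five augmentation variants of one original sample.

    Photometric variants (luminance, salt-and-pepper) keep the mask
    bit-identical; geometric variants resample image (bilinear) and mask
    (nearest) together.
    """
    spec = spec or AugmentationSpec()
    rng = rng or np.random.default_rng(0)
    return [
        _luminance(sample, spec.luminance_up, "luminance_up"),
        _luminance(sample, spec.luminance_down, "luminance_down"),
        _scale(sample, spec.scale_up, "scale_up"),
        _scale(sample, spec.scale_down, "scale_down"),
        _salt_pepper(sample, spec.salt_pepper_density, rng),
    ]


def build_dataset(originals: Sequence[RootSample],
                  spec: AugmentationSpec | None = None,
                  seed: int = 0) -> list[RootSample]:
    """Originals plus their five variants: 6n samples grouped by source."""
    ids = [s.id for s in originals]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sample ids in originals")
    rng = np.random.default_rng(seed)
    out: list[RootSample] = []
    for s in originals:
        out.append(s)
        out.extend(augment_sample(s, spec, rng))
    return out


# ---------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------

def split_dataset(dataset: Sequence[RootSample],
                  ratio: tuple[int, int, int] = (6, 2, 2),
                  seed: int = 0) -> DatasetSplit:
    """Group-aware 6:2:2 split.

    Whole groups (an original plus its augmentations) are shuffled by
    seed; floor(train_fraction * G) groups go to training, and the
    remaining samples are divided equally between validation and test
    (an odd remainder goes to validation).  With 92 groups of 6 this
    yields the canonical 330/111/111 partition.
    """
    groups: dict[str, list[RootSample]] = {}
    for s in dataset:
        groups.setdefault(s.group_id, []).append(s)
    if len(groups) < 3:
        raise DataError(f"need at least 3 groups to split, got {len(groups)}")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    train_frac = ratio[0] / sum(ratio)
    n_train_groups = int(np.floor(train_frac * len(keys)))
    train_ids = [s.id for k in keys[:n_train_groups] for s in groups[k]]
    rest = [s.id for k in keys[n_train_groups:] for s in groups[k]]
    n_val = (len(rest) + 1) // 2
    return DatasetSplit(train=tuple(train_ids), val=tuple(rest[:n_val]),
                        test=tuple(rest[n_val:]), ratio=ratio, seed=seed)


def write_split_manifest(path, split: DatasetSplit,
                         dataset: Sequence[RootSample]) -> None:
    by_id = {s.id: s for s in dataset}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "group_id", "partition"])
        for part in ("train", "val", "test"):
            for sid in getattr(split, part):
                w.writerow([sid, by_id[sid].group_id, part])


# ---------------------------------------------------------------------
# on-disk dataset directories
# ---------------------------------------------------------------------

def write_dataset_dir(directory, samples: Sequence[RootSample]) -> None:
    """images/<id>.png + masks/<id>.png + manifest.csv."""
    d = Path(directory)
    (d / "images").mkdir(parents=True, exist_ok=True)
    (d / "masks").mkdir(parents=True, exist_ok=True)
    with open(d / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "group_id", "provenance"])
        for s in samples:
            Image.fromarray(s.image).save(d / "images" / f"{s.id}.png")
            write_mask_png(d / "masks" / f"{s.id}.png", s.mask)
            w.writerow([s.id, s.group_id, s.provenance])


def read_dataset_dir(directory) -> list[RootSample]:
    d = Path(directory)
    manifest = d / "manifest.csv"
    if not manifest.exists():
        raise DataError(f"no manifest.csv under {d}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(
                Image.open(d / "images" / f"{row['id']}.png").convert("RGB"))
            mask = read_mask_png(d / "masks" / f"{row['id']}.png")
            samples.append(RootSample(image=img, mask=mask, id=row["id"],
                                      provenance=row["provenance"],
                                      group_id=row["group_id"]))
    return samples


# ---------------------------------------------------------------------
# tiled inference
# ---------------------------------------------------------------------

def _forward_logits(model, images: np.ndarray) -> np.ndarray:
    """Final logits of the model on a normalized batch, no graph."""
    with ag.no_grad():
        out = model(images)
    logits = out.final_logits if hasattr(out, "final_logits") else out
    return logits.data if isinstance(logits, ag.Tensor) else np.asarray(logits)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 CHW in [0, 1] (the network's input range)."""
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)


def _round_up(n: int, multiple: int) -> int:
    return int(np.ceil(n / multiple) * multiple)


def tiled_predict(model, image: np.ndarray, tile: int = 512,
                  overlap: int = 256) -> np.ndarray:
    """Full-resolution binary mask via overlapping sliding-window logits.

    The image is reflect-padded to tile/stride alignment, per-tile final
    logits are averaged over every window covering a pixel, and the
    argmax over the two classes gives the mask at the original
    resolution.  Images no larger than one tile take a single unpadded
    forward pass when their dims allow it, so the single-tile case
    equals a whole-image forward exactly.
    """
    if overlap >= tile:
        raise ValueError(f"overlap {overlap} must be < tile {tile}")
    h, w = image.shape[:2]
    x = normalize_image(image)[None]

    if h <= tile and w <= tile:
        ph, pw = _round_up(h, 32), _round_up(w, 32)
        if (ph, pw) != (h, w):
            x = np.pad(x, ((0, 0), (0, 0), (0, ph - h), (0, pw - w)),
                       mode="reflect")
        logits = _forward_logits(model, x)[:, :, :h, :w]
        if not np.isfinite(logits).all():
            raise ValueError("non-finite logits from model")
        return np.argmax(logits[0], axis=0).astype(np.uint8)

    stride = tile - overlap
    ph = max(tile, _round_up(h, stride))
    pw = max(tile, _round_up(w, stride))
    xp = np.pad(x, ((0, 0), (0, 0), (0, ph - h), (0, pw - w)),
                mode="reflect")
    acc = np.zeros((2, ph, pw), dtype=np.float64)
    cover = np.zeros((ph, pw), dtype=np.int64)
    ys = sorted({min(y, ph - tile) for y in range(0, ph - tile + stride,
                                                  stride)})
    xs = sorted({min(xo, pw - tile) for xo in range(0, pw - tile + stride,
                                                    stride)})
    for y0 in ys:
        for x0 in xs:
            patch = xp[:, :, y0:y0 + tile, x0:x0 + tile]
            logits = _forward_logits(model, patch)[0]
            if not np.isfinite(logits).all():
                raise ValueError("non-finite logits from model")
            acc[:, y0:y0 + tile, x0:x0 + tile] += logits
            cover[y0:y0 + tile, x0:x0 + tile] += 1
    assert (cover > 0).all()
    acc /= cover
    return np.argmax(acc[:, :h, :w], axis=0).astype(np.uint8)
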