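"""Synthetic minirhizotron scene generator.

Emulates the imagery the segmenter is built for: bright curvilinear
roots (random-walk polylines with tapering width) drawn over textured
soil, plus the background distractors that make real minirhizotron
scans hard — stones (bright ellipses), soil cracks (thin dark
polylines), residual plastic-film patches (large bright polygons) and
worms (short thick bright segments).  Root tone is drawn from a narrow
band overlapping the soil tones, so the root/soil contrast is low by
default; contrast is the main difficulty knob.

Only root strokes enter the ground-truth mask; distractors are model
challenges, never labels.  Every scene is a pure function of
(spec, seed) through a PCG64 generator, so scenes are bit-reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import RootSample
from .errors import ConfigurationError


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, texture and distractor parameters of one scene."""

    width: int = 512
    height: int = 512
    n_roots: int = 4
    root_width_range: tuple[float, float] = (2.0, 12.0)
    step_length: float = 6.0
    angle_jitter: float = 0.25        # radians, per step
    soil_brightness: float = 0.42     # mean soil tone in [0, 1]
    root_contrast: float = 0.18       # mean root tone above soil tone
    texture_octaves: tuple[float, ...] = (4.0, 16.0, 48.0)
    texture_strength: float = 0.10
    n_stones: int = 6
    n_cracks: int = 3
    n_film_patches: int = 1
    n_worms: int = 2
    noise_sigma: float = 0.015        # sensor noise

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ConfigurationError(
                f"scene dims must be >= 64, got {self.width}x{self.height}")
        if self.n_roots < 0:
            raise ConfigurationError(f"n_roots must be >= 0, got {self.n_roots}")
        lo, hi = self.root_width_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"root_width_range must be positive and ordered, "
                f"got {self.root_width_range}")
        for name in ("n_stones", "n_cracks", "n_film_patches", "n_worms"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _stamp_disk(canvas: np.ndarray, cy: float, cx: float, r: float) -> None:
    """Max-combine an anti-aliased disk of radius r into `canvas`."""
    h, w = canvas.shape
    pad = int(np.ceil(r)) + 1
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], alpha, out=canvas[y0:y1, x0:x1])


def _stroke(canvas: np.ndarray, points: np.ndarray,
            widths: np.ndarray) -> None:
    """Render a polyline as overlapping AA disks (sub-pixel stepping)."""
    for (y0, x0), (y1, x1), w0, w1 in zip(points[:-1], points[1:],
                                          widths[:-1], widths[1:]):
        seg = float(np.hypot(y1 - y0, x1 - x0))
        n = max(2, int(seg / 0.75) + 1)
        for t in np.linspace(0.0, 1.0, n):
            _stamp_disk(canvas, y0 + t * (y1 - y0), x0 + t * (x1 - x0),
                        max(0.5, (w0 + t * (w1 - w0)) / 2.0))


def _random_walk(rng: np.random.Generator, h: int, w: int, step: float,
                 jitter: float, n_steps: int) -> np.ndarray:
    """A smooth random-walk path; mostly downward like a taproot."""
    y = rng.uniform(0, h * 0.3)
    x = rng.uniform(w * 0.1, w * 0.9)
    theta = rng.uniform(np.pi * 0.25, np.pi * 0.75)  # heading, 0=right
    pts = [(y, x)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, jitter)
        y += step * np.sin(theta)
        x += step * np.cos(theta)
        pts.append((y, x))
        if not (-0.1 * h < y < 1.1 * h and -0.1 * w < x < 1.1 * w):
            break
    return np.asarray(pts)


def _soil_texture(rng: np.random.Generator, h: int, w: int,
                  spec: SceneSpec) -> np.ndarray:
    tex = np.zeros((h, w), dtype=np.float64)
    for octave in spec.texture_octaves:
        layer = ndimage.gaussian_filter(rng.standard_normal((h, w)), octave)
        std = layer.std()
        if std > 0:
            tex += layer / std
    tex *= spec.texture_strength / max(len(spec.texture_octaves), 1)
    return spec.soil_brightness + tex


def _render_distractors(rng: np.random.Generator, base: np.ndarray,
                        spec: SceneSpec) -> None:
    h, w = base.shape
    for _ in range(spec.n_stones):        # bright ellipses
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(4, 14, size=2)
        ang = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ys = (yy - cy) * np.cos(ang) + (xx - cx) * np.sin(ang)
        xs = -(yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
        q = (ys / ry) ** 2 + (xs / rx) ** 2
        alpha = np.clip(1.0 - q, 0.0, 1.0) ** 0.5
        tone = spec.soil_brightness + rng.uniform(0.10, 0.25)
        base[:] = base * (1 - alpha) + tone * alpha
    for _ in range(spec.n_cracks):        # thin dark polylines
        canvas = np.zeros_like(base)
        pts = _random_walk(rng, h, w, spec.step_length * 1.5, 0.4,
                           n_steps=int(1.2 * max(h, w) / spec.step_length))
        widths = np.full(len(pts), rng.uniform(1.0, 2.5))
        _stroke(canvas, pts, widths)
        tone = max(0.02, spec.soil_brightness - rng.uniform(0.15, 0.3))
        base[:] = base * (1 - canvas) + tone * canvas
    for _ in range(spec.n_film_patches):  # large bright polygons
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        n_vert = rng.integers(4, 8)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        radii = rng.uniform(0.08, 0.22, n_vert) * min(h, w)
        vy = np.clip(cy + radii * np.sin(angles), 0, h - 1)
        vx = np.clip(cx + radii * np.cos(angles), 0, w - 1)
        from skimage.draw import polygon
        rr, cc = polygon(vy, vx, shape=base.shape)
        alpha = np.zeros_like(base)
        alpha[rr, cc] = 1.0
        alpha = ndimage.gaussian_filter(alpha, 1.5)
        tone = min(0.95, spec.soil_brightness + rng.uniform(0.25, 0.4))
        base[:] = base * (1 - alpha) + tone * alpha
    for _ in range(spec.n_worms):         # short thick bright segments
        canvas = np.zeros_like(base)
        pts = _random_walk(rng, h, w, spec.step_length, 0.15,
                           n_steps=rng.integers(5, 12))
        widths = np.full(len(pts), rng.uniform(4.0, 8.0))
        _stroke(canvas, pts, widths)
        tone = spec.soil_brightness + rng.uniform(0.12, 0.22)
        base[:] = base * (1 - canvas) + tone * canvas


def generate_scene(spec: SceneSpec, seed: int) -> RootSample:
    """Render one scene; deterministic in (spec, seed).

    Texture, distractors and roots draw from three independent PCG64
    streams spawned from the seed, so the root geometry (and hence the
    mask) does not depend on the distractor configuration.
    """
    tex_ss, dis_ss, root_ss = np.random.SeedSequence(seed).spawn(3)
    tex_rng = np.random.Generator(np.random.PCG64(tex_ss))
    dis_rng = np.random.Generator(np.random.PCG64(dis_ss))
    rng = np.random.Generator(np.random.PCG64(root_ss))
    h, w = spec.height, spec.width

    base = _soil_texture(tex_rng, h, w, spec)
    _render_distractors(dis_rng, base, spec)

    root_alpha = np.zeros((h, w), dtype=np.float64)
    lo, hi = spec.root_width_range
    for _ in range(spec.n_roots):
        pts = _random_walk(rng, h, w, spec.step_length, spec.angle_jitter,
                           n_steps=int(1.5 * h / spec.step_length))
        start_w = rng.uniform(lo, hi)
        taper = np.linspace(1.0, rng.uniform(0.3, 0.6), len(pts))
        _stroke(root_alpha, pts, np.maximum(lo, start_w * taper))
        # a lateral branch off the taproot
        if len(pts) > 6 and rng.random() < 0.8:
            j = rng.integers(2, len(pts) - 2)
            side = _random_walk(rng, h, w, spec.step_length,
                                spec.angle_jitter * 1.5,
                                n_steps=int(0.4 * h / spec.step_length))
            side = side - side[0] + pts[j]
            bw = max(lo, 0.5 * start_w)
            _stroke(root_alpha, side,
                    np.maximum(lo * 0.8, np.linspace(bw, lo * 0.8,
                                                     len(side))))

    root_tone = np.clip(
        spec.soil_brightness + spec.root_contrast
        + rng.normal(0.0, 0.02, size=(h, w)), 0.0, 1.0)
    gray = base * (1 - root_alpha) + root_tone * root_alpha
    gray += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    gray = np.clip(gray, 0.0, 1.0)

    # brownish soil tinting: red slightly above, blue below the mean tone
    rgb = np.stack([np.clip(gray * 1.08, 0, 1), gray,
                    np.clip(gray * 0.80, 0, 1)], axis=-1)
    image = np.round(rgb * 255.0).astype(np.uint8)
    mask = (root_alpha >= 0.5).astype(np.uint8)
    return RootSample(image=image, mask=mask, id=f"synthetic-{seed}",
                      provenance="original", group_id=f"synthetic-{seed}")


def generate_dataset(n: int, spec: SceneSpec | None = None,
                     seed: int = 0) -> list[RootSample]:
    """n scenes with per-scene seeds derived from a master seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec = spec or SceneSpec()
    master = np.random.SeedSequence(seed)
    samples = []
    for i, child in enumerate(master.spawn(n)):
        scene_seed = int(child.generate_state(1)[0] % (2 ** 31))
        s = generate_scene(spec, scene_seed)
        samples.append(replace_ids(s, f"scene-{i:04d}"))
    return samples


def replace_ids(sample: RootSample, new_id: str) -> RootSample:
    return RootSample(image=sample.image, mask=sample.mask, id=new_id,
                      provenance=sample.provenance, group_id=new_id)
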