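"""Schematic face rendering with exact 68-landmark ground truth.

All face-geometry code in this package is exercised against synthetic
schematic faces: a bright elliptical face on a dark background with dark
elliptical eyes, brows, a nose ridge and a mouth.  The renderer knows
where it painted everything, so it emits the 68 landmark coordinates
(1-based iBUG-style numbering: 37-42 / 43-48 are the eyes, 40 and 43 the
inner corners) for any position, scale and in-plane rotation — which is
what the detector training, landmark accuracy and alignment tests need.

Coordinates are (x, y) = (column, row) pixels, y growing downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

# canonical face frame: origin at face centre, unit = half face width;
# the face ellipse has half-axes (1.0, 1.3), y grows toward the chin.
FACE_HALF_AXES = (1.0, 1.3)
EYE_CENTERS = ((-0.42, -0.35), (0.42, -0.35))
EYE_HALF_AXES = (0.18, 0.09)
BROW_CENTERS = ((-0.42, -0.58), (0.42, -0.58))
BROW_HALF_AXES = (0.24, 0.05)
MOUTH_CENTER = (0.0, 0.55)
MOUTH_HALF_AXES = (0.30, 0.11)
NOSE_TOP, NOSE_BOTTOM, NOSE_HALF_WIDTH = -0.20, 0.18, 0.035

SKIN, BACKGROUND, EYE, BROW, MOUTH, NOSE = 205.0, 35.0, 40.0, 75.0, 60.0, 150.0


def canonical_landmarks() -> np.ndarray:
    """The 68 landmarks in the canonical face frame, ordered 1..68."""
    pts: list[tuple[float, float]] = []
    a, b = FACE_HALF_AXES
    # 1-17 jaw: left temple around the chin to the right temple
    for i in range(17):
        phi = np.pi - i * np.pi / 16
        pts.append((a * np.cos(phi), b * np.sin(phi) * 0.999))
    # 18-27 brows, five points each along the brow bar
    for (cx, cy), sgn in zip(BROW_CENTERS, (1, 1)):
        for u in np.linspace(-1, 1, 5):
            pts.append((cx + u * BROW_HALF_AXES[0], cy - 0.02 * (1 - u * u)))
    # 28-31 nose bridge, 32-36 nostril row
    for v in np.linspace(NOSE_TOP - 0.12, NOSE_BOTTOM, 4):
        pts.append((0.0, v))
    for u in np.linspace(-1, 1, 5):
        pts.append((u * 0.12, NOSE_BOTTOM + 0.05))
    # 37-42 first (image-left) eye: outer corner, two top, inner corner, two bottom
    (lx, ly), (rx, ry) = EYE_CENTERS
    ex, ey = EYE_HALF_AXES
    pts += [
        (lx - ex, ly), (lx - ex * 0.45, ly - ey), (lx + ex * 0.45, ly - ey),
        (lx + ex, ly), (lx + ex * 0.45, ly + ey), (lx - ex * 0.45, ly + ey),
    ]
    # 43-48 second (image-right) eye: inner corner first
    pts += [
        (rx - ex, ry), (rx - ex * 0.45, ry - ey), (rx + ex * 0.45, ry - ey),
        (rx + ex, ry), (rx + ex * 0.45, ry + ey), (rx - ex * 0.45, ry + ey),
    ]
    # 49-60 outer mouth ring, 61-68 inner ring
    mx, my = MOUTH_CENTER
    ma, mb = MOUTH_HALF_AXES
    for i in range(12):
        phi = np.pi + i * 2 * np.pi / 12
        pts.append((mx + ma * np.cos(phi), my - mb * np.sin(phi)))
    for i in range(8):
        phi = np.pi + i * 2 * np.pi / 8
        pts.append((mx + 0.6 * ma * np.cos(phi), my - 0.6 * mb * np.sin(phi)))
    out = np.asarray(pts, dtype=float)
    assert out.shape == (68, 2)
    return out


@dataclass(frozen=True)
class SchematicFace:
    """A rendered face with its ground-truth geometry.

    ``landmarks`` are the 68 points in image pixels (row index 0 is
    landmark 1); ``eye_boxes`` are (x0, y0, x1, y1) boxes around the two
    inner eye corners (landmarks 40 and 43) for annotation tests.
    """

    image: np.ndarray  # float64 in [0, 255], grayscale
    landmarks: np.ndarray
    center: tuple[float, float]
    scale: float  # pixels per canonical unit
    angle_deg: float

    @property
    def eye_boxes(self) -> dict[int, tuple[float, float, float, float]]:
        half = 0.08 * self.scale
        boxes = {}
        for idx in (40, 43):
            x, y = self.landmarks[idx - 1]
            boxes[idx] = (x - half, y - half, x + half, y + half)
        return boxes


def _rotation(angle_deg: float) -> np.ndarray:
    r = np.deg2rad(angle_deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def render_face(
    size: int | tuple[int, int] = 160,
    center: tuple[float, float] | None = None,
    scale: float | None = None,
    angle_deg: float = 0.0,
    noise_sd: float = 0.0,
    shading: bool = False,
    blur_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SchematicFace:
    """Render one schematic face.

    ``scale`` is pixels per canonical unit (default: face fills ~70% of
    the shorter image side); ``angle_deg`` rotates the face in the image
    plane (positive = the image-right eye moves downward).  ``shading``
    adds a smooth illumination gradient, for photo-like fixtures.
    """
    h, w = (size, size) if isinstance(size, int) else size
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if scale is None:
        scale = 0.35 * min(h, w) / FACE_HALF_AXES[1]
    R = _rotation(angle_deg)
    ys, xs = np.mgrid[0:h, 0:w]
    # map pixel -> canonical coords (inverse rotation)
    dx = (xs - center[0]) / scale
    dy = (ys - center[1]) / scale
    X = R[0, 0] * dx + R[1, 0] * dy
    Y = R[0, 1] * dx + R[1, 1] * dy

    img = np.full((h, w), BACKGROUND)
    a, b = FACE_HALF_AXES
    face = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    img[face] = SKIN

    def ellipse(cx, cy, ax_, ay_):
        return ((X - cx) / ax_) ** 2 + ((Y - cy) / ay_) ** 2 <= 1.0

    for cx, cy in BROW_CENTERS:
        img[ellipse(cx, cy, *BROW_HALF_AXES)] = BROW
    for cx, cy in EYE_CENTERS:
        img[ellipse(cx, cy, *EYE_HALF_AXES)] = EYE
    nose = (np.abs(X) <= NOSE_HALF_WIDTH) & (Y >= NOSE_TOP) & (Y <= NOSE_BOTTOM)
    img[nose] = NOSE
    img[ellipse(*MOUTH_CENTER, *MOUTH_HALF_AXES)] = MOUTH

    if shading:
        img = img * (0.85 + 0.15 * (xs / max(w - 1, 1))) + 10.0 * (ys / max(h - 1, 1))
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    lm = canonical_landmarks() @ R.T * scale + np.asarray(center)
    return SchematicFace(img, lm, center, float(scale), float(angle_deg))


def render_composite(gap: int = 24, size: int = 160, **kwargs) -> np.ndarray:
    """Two schematic faces side by side (detector multi-face fixture)."""
    left = render_face(size=size, **kwargs).image
    right = render_face(size=size, **kwargs).image
    spacer = np.full((size, gap), BACKGROUND)
    return np.concatenate([left, spacer, right], axis=1)
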