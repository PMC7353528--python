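"""Face preprocessing: frame -> four aligned, equalized 64x64 sections.

The eight-step pipeline applied to every video frame:

1. convert to grayscale (ITU-R BT.601 luminance weights);
2. detect faces with a histogram-of-oriented-gradients (HoG) sliding
   window detector;
3. locate 68 landmarks on the first face detected (highest score,
   leftmost on ties);
4. rotate image + landmarks so the line between landmarks 40 and 43
   (the inner eye corners) is horizontal;
5. split the face into four sections: left/right eyes, left/right
   nose-mouth;
6. flip the right sections horizontally so left and right feed the same
   network;
7. contrast-limited adaptive histogram equalization (CLAHE) per section;
8. normalize pixel values from [0, 255] to [0, 1].

The detector is a linear scorer over HoG features trained once, lazily,
on this package's own schematic-face renders (positives) and structured
non-face patterns (negatives); it is a minimal detector for synthetic
imagery, not a general-purpose face detector.  Landmark localization
anchors the canonical 68-point shape to the detected face through the
two dark eye blobs, which captures translation, scale and in-plane roll.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, transform

from . import schematic

# BT.601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])

SECTION_SIZE = 64
SECTION_NAMES = ("eye_left", "eye_right_flipped", "mouth_left", "mouth_right_flipped")


class FormatError(ValueError):
    """Unsupported image format (channel count)."""


class DegenerateGeometryError(ValueError):
    """Coincident landmarks make the requested geometry undefined."""


class LandmarkError(RuntimeError):
    """Landmark localization failed; the frame is unusable."""


@dataclass(frozen=True)
class FacePrepConfig:
    clahe_clip: float = 0.02          # normalized CLAHE clip limit
    clahe_grid: tuple[int, int] = (8, 8)
    section_margin: float = 0.10      # fractional margin around section extents
    detector_window: int = 64         # sliding-window side, pixels
    detector_face_fill: float = 0.75  # face height as a fraction of the window
    detector_stride_cells: int = 1    # window stride in HoG cells
    min_face_height: int = 40         # smallest face height searched, pixels
    pyramid_ratio: float = 1.25
    detector_seed: int = 20200611     # seed for the detector's training set


DEFAULT_CONFIG = FacePrepConfig()


@dataclass(frozen=True)
class RawFrame:
    """One frame: 2-D grayscale or 3-D color pixel matrix in [0, 255]."""

    pixels: np.ndarray
    frame_index: int = 0
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3):
            raise FormatError(f"frame must be 2-D or 3-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass(frozen=True)
class FaceDetection:
    """One detected face: bbox = (x0, y0, x1, y1) in pixel coordinates."""

    bbox: tuple[float, float, float, float]
    score: float


@dataclass(frozen=True)
class LandmarkSet:
    """68 (x, y) landmark coordinates, addressed 1-based as in the
    standard 68-point scheme (40 and 43 are the inner eye corners)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) points, got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def point(self, number: int) -> np.ndarray:
        """Landmark by its 1-based number."""
        if not 1 <= number <= 68:
            raise IndexError("landmark numbers run 1..68")
        return self.points[number - 1]


@dataclass(frozen=True)
class FaceSections:
    """Four 64x64 face sections; right sections are stored mirrored."""

    eye_left: np.ndarray
    eye_right_flipped: np.ndarray
    mouth_left: np.ndarray
    mouth_right_flipped: np.ndarray
    frame_index: int = 0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in SECTION_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (SECTION_SIZE, SECTION_SIZE):
                raise ValueError(f"section {name} must be {SECTION_SIZE}x{SECTION_SIZE}, got {arr.shape}")
            object.__setattr__(self, name, arr)

    def map(self, fn) -> "FaceSections":
        return replace(self, **{name: fn(getattr(self, name)) for name in SECTION_NAMES})

    def stack(self) -> np.ndarray:
        """Sections as a (4, 64, 64) array in the canonical order."""
        return np.stack([getattr(self, name) for name in SECTION_NAMES])


# ---------------------------------------------------------------------------
# steps 1-2: grayscale and detection


def to_grayscale(frame: RawFrame) -> RawFrame:
    """BT.601 luminance conversion; single-channel frames pass through."""
    px = frame.pixels
    if px.ndim == 2:
        return frame
    if px.ndim == 3 and px.shape[2] == 1:
        return replace(frame, pixels=px[:, :, 0])
    if px.ndim == 3 and px.shape[2] == 3:
        return replace(frame, pixels=px @ _LUMA)
    raise FormatError(f"unsupported channel count: shape {px.shape}")


_HOG_KW = dict(orientations=9, pixels_per_cell=(8, 8), cells_per_block=(2, 2), block_norm="L2-Hys")


class HogFaceDetector:
    """Multi-scale sliding-window HoG detector with a linear scorer.

    The scorer is ridge-regressed to +/-1 targets on schematic-face
    positives (jittered in position, scale, roll, illumination and noise)
    against structured negatives, at construction time, deterministically
    from the config seed.
    """

    def __init__(self, config: FacePrepConfig = DEFAULT_CONFIG):
        self.config = config
        self._train()

    # -- training set ------------------------------------------------------
    def _positives(self, rng) -> list[np.ndarray]:
        w = self.config.detector_window
        base_scale = self.config.detector_face_fill * w / (2 * schematic.FACE_HALF_AXES[1])
        out = []
        for _ in range(90):
            face = schematic.render_face(
                size=w,
                center=((w - 1) / 2 + rng.uniform(-3, 3), (w - 1) / 2 + rng.uniform(-3, 3)),
                scale=base_scale * rng.uniform(0.88, 1.12),
                angle_deg=rng.uniform(-12, 12),
                noise_sd=rng.uniform(0, 6),
                shading=rng.random() < 0.5,
                blur_sigma=rng.uniform(0, 0.8),
                rng=rng,
            )
            out.append(face.image)
        return out

    def _negatives(self, rng) -> list[np.ndarray]:
        w = self.config.detector_window
        out = []
        ys, xs = np.mgrid[0:w, 0:w]
        for _ in range(40):  # flat-ish with noise
            out.append(np.clip(rng.uniform(20, 230) + rng.normal(0, rng.uniform(1, 10), (w, w)), 0, 255))
        for _ in range(40):  # linear gradients
            gx, gy = rng.uniform(-2, 2, 2)
            out.append(np.clip(rng.uniform(40, 200) + gx * xs + gy * ys, 0, 255))
        for _ in range(30):  # checkerboards / stripes
            p = rng.integers(4, 16)
            out.append(np.where(((xs // p) + (ys // p) * rng.integers(0, 2)) % 2 == 0, 40.0, 200.0))
        for _ in range(40):  # smooth random blobs
            img = ndimage.gaussian_filter(rng.normal(0, 1, (w, w)), rng.uniform(4, 12))
            img = (img - img.min()) / (np.ptp(img) + 1e-9) * 255
            out.append(img)
        for _ in range(30):  # adjacent half-faces (between two side-by-side faces)
            base_scale = self.config.detector_face_fill * w / (2 * schematic.FACE_HALF_AXES[1])
            off = rng.uniform(0.55, 0.85) * w
            left_half = schematic.render_face(size=w, center=((w - 1) / 2 - off, (w - 1) / 2),
                                              scale=base_scale, rng=rng).image
            right_half = schematic.render_face(size=w, center=((w - 1) / 2 + off, (w - 1) / 2),
                                               scale=base_scale, rng=rng).image
            out.append(np.maximum(left_half, right_half))
        for _ in range(50):  # badly framed / badly scaled faces
            base_scale = self.config.detector_face_fill * w / (2 * schematic.FACE_HALF_AXES[1])
            off = rng.choice([-1, 1], 2) * rng.uniform(0.5, 0.9, 2) * w
            bad_scale = base_scale * (rng.uniform(0.3, 0.5) if rng.random() < 0.5 else rng.uniform(1.8, 2.6))
            which = rng.random()
            face = schematic.render_face(
                size=w,
                center=((w - 1) / 2 + (off[0] if which < 0.5 else 0),
                        (w - 1) / 2 + (off[1] if which < 0.5 else 0)),
                scale=base_scale if which < 0.5 else bad_scale,
                angle_deg=rng.uniform(-12, 12),
                noise_sd=rng.uniform(0, 6),
                rng=rng,
            )
            out.append(face.image)
        return out

    def _train(self) -> None:
        rng = np.random.default_rng(self.config.detector_seed)
        pos = self._positives(rng)
        neg = self._negatives(rng)
        A = np.stack([feature.hog(img, **_HOG_KW) for img in pos + neg])
        b = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
        lam = 1e-2 * len(b)
        G = A.T @ A + lam * np.eye(A.shape[1])
        self.weights_ = np.linalg.solve(G, A.T @ b)
        scores = A @ self.weights_
        pos_scores, neg_scores = scores[: len(pos)], scores[len(pos):]
        lo, hi = float(neg_scores.max()), float(pos_scores.min())
        self.threshold_ = lo + 0.6 * (hi - lo) if hi > lo else 0.0

    # -- detection ---------------------------------------------------------
    def _scales(self, h: int, w: int):
        cfg = self.config
        target = cfg.detector_face_fill * cfg.detector_window
        fh = float(cfg.min_face_height)
        while fh <= 1.2 * min(h, w):
            yield target / fh
            fh *= cfg.pyramid_ratio

    def detect(self, image: np.ndarray) -> list[FaceDetection]:
        """All face detections, sorted by descending score (ties: leftmost)."""
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise FormatError("detector expects a single-channel image")
        cfg = self.config
        win = cfg.detector_window
        cells_per_win = win // 8
        blocks_per_win = cells_per_win - 1
        candidates: list[FaceDetection] = []
        for f in self._scales(*img.shape):
            sh, sw = int(round(img.shape[0] * f)), int(round(img.shape[1] * f))
            if min(sh, sw) < win:
                continue
            scaled = transform.resize(img, (sh, sw), anti_aliasing=f < 1, preserve_range=True)
            blocks = feature.hog(scaled, feature_vector=False, **_HOG_KW)
            nbr, nbc = blocks.shape[:2]
            step = cfg.detector_stride_cells
            for bi in range(0, nbr - blocks_per_win + 1, step):
                for bj in range(0, nbc - blocks_per_win + 1, step):
                    vec = blocks[bi:bi + blocks_per_win, bj:bj + blocks_per_win].ravel()
                    score = float(vec @ self.weights_)
                    if score > self.threshold_:
                        x0, y0 = bj * 8 / f, bi * 8 / f
                        candidates.append(FaceDetection((x0, y0, x0 + win / f, y0 + win / f), score))
        return _nms(candidates)


def _iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def _center_inside(det: FaceDetection, box) -> bool:
    cx = (det.bbox[0] + det.bbox[2]) / 2
    cy = (det.bbox[1] + det.bbox[3]) / 2
    return box[0] <= cx <= box[2] and box[1] <= cy <= box[3]


def _nms(candidates: list[FaceDetection], iou_threshold: float = 0.2) -> list[FaceDetection]:
    """Greedy suppression: drop any candidate overlapping a kept box
    (IoU above threshold) or centred inside one (cross-scale duplicates)."""
    ordered = sorted(candidates, key=lambda d: (-d.score, d.bbox[0]))
    kept: list[FaceDetection] = []
    for det in ordered:
        if all(_iou(det.bbox, k.bbox) <= iou_threshold and not _center_inside(det, k.bbox)
               and not _center_inside(k, det.bbox) for k in kept):
            kept.append(det)
    return kept


_default_detector: HogFaceDetector | None = None


def get_default_detector() -> HogFaceDetector:
    global _default_detector
    if _default_detector is None:
        _default_detector = HogFaceDetector()
    return _default_detector


def detect_faces(frame: RawFrame, detector: HogFaceDetector | None = None) -> list[FaceDetection]:
    """Step 2: HoG face detection on a grayscale frame.

    Returns zero or more detections sorted by descending score; an empty
    list means no face (downstream records get face_count = -1).
    """
    if not frame.is_gray:
        raise FormatError("detect_faces expects a grayscale frame; run to_grayscale first")
    detector = detector or get_default_detector()
    return detector.detect(frame.pixels)


# ---------------------------------------------------------------------------
# step 3: landmarks


_EYE_SEP_CANONICAL = schematic.EYE_CENTERS[1][0] - schematic.EYE_CENTERS[0][0]
_EYE_MID_CANONICAL = np.array([0.0, schematic.EYE_CENTERS[0][1]])


def _find_eye_centers(crop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the two dark eye blobs inside a face crop."""
    lo, hi = crop.min(), crop.max()
    if hi - lo < 20:
        raise LandmarkError("crop has no contrast; cannot localize eyes")
    bright = crop > lo + 0.5 * (hi - lo)
    face_mask = ndimage.binary_fill_holes(bright)
    labels, n = ndimage.label(face_mask)
    if n == 0:
        raise LandmarkError("no face region in crop")
    largest = 1 + np.argmax(ndimage.sum_labels(np.ones_like(crop), labels, range(1, n + 1)))
    face_mask = labels == largest
    rows = np.where(face_mask.any(axis=1))[0]
    cols = np.where(face_mask.any(axis=0))[0]
    face_h = rows[-1] - rows[0] + 1
    face_w = cols[-1] - cols[0] + 1

    dark = face_mask & (crop < lo + 0.35 * (hi - lo))
    labels, n = ndimage.label(dark)
    if n < 2:
        raise LandmarkError("fewer than two dark blobs; eye localization failed")
    areas = ndimage.sum_labels(np.ones_like(crop), labels, range(1, n + 1))
    centroids = np.array(ndimage.center_of_mass(dark, labels, range(1, n + 1)))  # (row, col)
    order = np.argsort(-areas)
    best_pair, best_area = None, -1.0
    for ii in range(min(len(order), 6)):
        for jj in range(ii + 1, min(len(order), 6)):
            a_, b_ = order[ii], order[jj]
            (ra, ca), (rb, cb) = centroids[a_], centroids[b_]
            if abs(ra - rb) > 0.18 * face_h:
                continue
            sep = abs(ca - cb)
            if not 0.2 * face_w <= sep <= 0.75 * face_w:
                continue
            if max(ra, rb) > rows[0] + 0.6 * face_h:  # below mid-face: mouth, not eyes
                continue
            pair_area = areas[a_] + areas[b_]
            if pair_area > best_area:
                best_area, best_pair = pair_area, (a_, b_)
    if best_pair is None:
        raise LandmarkError("no plausible eye pair found")
    pa, pb = centroids[best_pair[0]], centroids[best_pair[1]]
    left, right = (pa, pb) if pa[1] <= pb[1] else (pb, pa)
    return np.array([left[1], left[0]]), np.array([right[1], right[0]])  # (x, y)


def locate_landmarks(
    frame: RawFrame,
    detection: FaceDetection,
    margin: float = 0.1,
) -> LandmarkSet:
    """Step 3: 68 landmarks for one detected face.

    The canonical 68-point shape is similarity-transformed onto the face:
    the two dark eye blobs inside the (margin-expanded) detection box fix
    translation, scale (from the interocular distance) and in-plane roll.
    Raises :class:`LandmarkError` when the eyes cannot be found; such
    frames are excluded from training and inference.
    """
    gray = to_grayscale(frame)
    x0, y0, x1, y1 = detection.bbox
    mw, mh = margin * (x1 - x0), margin * (y1 - y0)
    h, w = gray.pixels.shape
    cx0, cy0 = max(0, int(x0 - mw)), max(0, int(y0 - mh))
    cx1, cy1 = min(w, int(np.ceil(x1 + mw))), min(h, int(np.ceil(y1 + mh)))
    crop = gray.pixels[cy0:cy1, cx0:cx1]
    if crop.size == 0:
        raise LandmarkError("detection box lies outside the frame")
    eye_l, eye_r = _find_eye_centers(crop)
    eye_l = eye_l + [cx0, cy0]
    eye_r = eye_r + [cx0, cy0]
    d = eye_r - eye_l
    dist = float(np.hypot(*d))
    if dist < 2.0:
        raise LandmarkError("eye blobs are degenerate")
    phi = np.arctan2(d[1], d[0])
    s = dist / _EYE_SEP_CANONICAL
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    mid = (eye_l + eye_r) / 2
    pts = (schematic.canonical_landmarks() - _EYE_MID_CANONICAL) @ R.T * s + mid
    return LandmarkSet(pts)


# ---------------------------------------------------------------------------
# step 4: alignment


def alignment_angle(p40: Sequence[float], p43: Sequence[float]) -> float:
    """Inclination (degrees) of the landmark 40 -> 43 line.

    Convention: angle = atan2(delta_row, delta_column) in image
    coordinates (y down), so p40=(0,0), p43=(10,10) gives +45.  Rotating
    the image plane by the negative of this angle about the segment
    midpoint makes the two points share a row.
    """
    p40 = np.asarray(p40, dtype=float)
    p43 = np.asarray(p43, dtype=float)
    d = p43 - p40
    if np.hypot(*d) < 1e-9:
        raise DegenerateGeometryError("landmarks 40 and 43 coincide")
    return float(np.degrees(np.arctan2(d[1], d[0])))


def align_face(frame: RawFrame, landmarks: LandmarkSet) -> tuple[RawFrame, LandmarkSet, float]:
    """Step 4: derotate so the inner eye corners are horizontal.

    Returns (rotated frame, rotated landmarks, applied angle in degrees).
    Bilinear resampling; pixels rotated in from outside the frame are
    edge-padded.
    """
    angle = alignment_angle(landmarks.point(40), landmarks.point(43))
    center = (landmarks.point(40) + landmarks.point(43)) / 2
    r = np.deg2rad(angle)
    c, s = np.cos(r), np.sin(r)
    R_inv = np.array([[c, s], [-s, c]])  # rotation by -angle
    matrix = np.eye(3)
    matrix[:2, :2] = R_inv
    matrix[:2, 2] = center - R_inv @ center
    tf = transform.AffineTransform(matrix=matrix)
    rotated = transform.warp(frame.pixels, inverse_map=tf.inverse, order=1,
                             mode="edge", preserve_range=True)
    new_pts = landmarks.points @ R_inv.T + (center - R_inv @ center)
    return replace(frame, pixels=rotated), LandmarkSet(new_pts), angle


# ---------------------------------------------------------------------------
# steps 5-6: sections


def _sample_section(img: np.ndarray, x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """Bilinear 64x64 sampling of the box [x0,x1]x[y0,y1].

    Sub-pixel sampling keeps mirror-symmetric boxes exactly mirror
    consistent (an integer crop would shift left and right sections by up
    to a pixel); coordinates outside the frame are edge-padded.
    """
    xs = np.linspace(x0, x1, SECTION_SIZE)
    ys = np.linspace(y0, y1, SECTION_SIZE)
    coords = np.stack(np.meshgrid(ys, xs, indexing="ij"))
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def extract_sections(
    frame: RawFrame,
    landmarks: LandmarkSet,
    config: FacePrepConfig = DEFAULT_CONFIG,
) -> FaceSections:
    """Steps 5-6: four 64x64 sections from an aligned face.

    The eyes region spans the vertical extent of landmarks 18-48 (brows
    through eyes), the nose-mouth region that of landmarks 28-68; both
    are split left/right at the vertical midline through the nose bridge
    (landmarks 28-31), expanded by the configured margin, edge-padded
    where a crop exceeds the frame, and resampled to 64x64.  Right
    sections are mirrored before storage.  Values stay on the input
    intensity scale (CLAHE and normalization follow separately).
    """
    pts = landmarks.points
    mid_x = float(pts[27:31, 0].mean())

    def region(idx0: int, idx1: int) -> tuple[np.ndarray, np.ndarray]:
        block = pts[idx0:idx1]
        x0, y0 = block.min(axis=0)
        x1, y1 = block.max(axis=0)
        mh = config.section_margin * (y1 - y0)
        mw = config.section_margin * (x1 - x0)
        left = _sample_section(frame.pixels, x0 - mw, y0 - mh, mid_x, y1 + mh)
        right = _sample_section(frame.pixels, mid_x, y0 - mh, x1 + mw, y1 + mh)
        return left, np.fliplr(right)

    eye_left, eye_right_flipped = region(17, 48)    # landmarks 18-48
    mouth_left, mouth_right_flipped = region(27, 68)  # landmarks 28-68
    return FaceSections(
        eye_left, eye_right_flipped, mouth_left, mouth_right_flipped,
        frame_index=frame.frame_index,
        geometry={"mid_x": mid_x, "margin": config.section_margin},
    )


# ---------------------------------------------------------------------------
# steps 7-8: equalization and normalization


def clahe_equalize(
    section: np.ndarray,
    clip: float = DEFAULT_CONFIG.clahe_clip,
    grid: tuple[int, int] = DEFAULT_CONFIG.clahe_grid,
) -> np.ndarray:
    """Step 7: CLAHE on a [0, 255] section; output stays in [0, 255].

    ``clip`` is the normalized clip limit of
    :func:`skimage.exposure.equalize_adapthist`; ``grid`` the tile grid.
    Constant sections pass through unchanged (nothing to equalize).
    """
    section = np.asarray(section, dtype=float)
    if section.max() - section.min() < 1e-9:
        return section.copy()
    kernel = (max(1, section.shape[0] // grid[0]), max(1, section.shape[1] // grid[1]))
    return exposure.equalize_adapthist(np.clip(section, 0, 255) / 255.0,
                                       kernel_size=kernel, clip_limit=clip) * 255.0


def normalize(section: np.ndarray) -> np.ndarray:
    """Step 8: linear map v / 255 from [0, 255] to [0, 1]."""
    return np.asarray(section, dtype=float) / 255.0


# ---------------------------------------------------------------------------
# composite pipeline


@dataclass(frozen=True)
class PreprocessedFrame:
    """Outcome of preprocessing one frame.

    ``face_count`` is -1 when no face was detected; ``sections`` is None
    for no-face or unusable (landmark-failure) frames.
    """

    frame_index: int
    source_path: str
    face_count: int
    sections: FaceSections | None = None
    landmarks: LandmarkSet | None = None
    error: str | None = None

    @property
    def usable(self) -> bool:
        return self.sections is not None


def preprocess(
    frame: RawFrame,
    config: FacePrepConfig = DEFAULT_CONFIG,
    detector: HogFaceDetector | None = None,
) -> PreprocessedFrame:
    """Run the full eight-step pipeline on one frame.

    Deterministic given (frame, config): returns a complete
    :class:`FaceSections` in [0, 1], or a no-face record with
    face_count = -1, or an unusable record when landmarks fail.
    """
    gray = to_grayscale(frame)
    detections = detect_faces(gray, detector)
    if not detections:
        return PreprocessedFrame(frame.frame_index, frame.source_path, -1)
    try:
        lms = locate_landmarks(gray, detections[0])
        aligned, lms_aligned, _ = align_face(gray, lms)
        sections = extract_sections(aligned, lms_aligned, config)
    except (LandmarkError, DegenerateGeometryError) as exc:
        return PreprocessedFrame(frame.frame_index, frame.source_path,
                                 len(detections), error=str(exc))
    sections = sections.map(lambda s: normalize(clahe_equalize(s, config.clahe_clip, config.clahe_grid)))
    return PreprocessedFrame(frame.frame_index, frame.source_path,
                             len(detections), sections=sections, landmarks=lms_aligned)


def load_frame(path, frame_index: int = 0) -> RawFrame:
    """Read a PNG/JPEG image file as a RawFrame."""
    import imageio.v3 as iio
    return RawFrame(iio.imread(path), frame_index=frame_index, source_path=str(path))


def save_sections(results: Sequence[PreprocessedFrame], array_path, provenance_path) -> None:
    """Persist usable sections as a (n, 4, 64, 64) array + provenance CSV."""
    import pandas as pd
    usable = [r for r in results if r.usable]
    np.save(array_path, np.stack([r.sections.stack() for r in usable]) if usable
            else np.empty((0, 4, SECTION_SIZE, SECTION_SIZE)))
    pd.DataFrame([
        {"frame_index": r.frame_index, "face_count": r.face_count, "source_path": r.source_path}
        for r in results
    ]).to_csv(provenance_path, index=False)
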