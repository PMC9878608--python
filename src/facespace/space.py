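"""Warp-texture PCA face space: alignment, warping, synthesis, stimuli.

Each training face is represented by a *warp-texture vector*: its
shape-free texture (the image backward-warped into the average geometry)
concatenated with the dense x/y warp fields that carry its shape.  PCA on
these vectors gives an orthonormal basis ("components") ordered by
variance explained; positions in the space are expressed in units of one
standard deviation of the training loadings per component, so a
coordinate of +6 along a component is a face caricatured six loading-SDs
from the average along that direction.

Dense warps are estimated by thin-plate-spline interpolation of landmark
displacements.  All warp fields use the backward convention: the field
value at an output pixel says where to sample in the source image, in
pixels, 0-based, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import map_coordinates
from skimage.transform import SimilarityTransform, warp as sk_warp

from .faces import LandmarkSet


@dataclass
class WarpTextureVector:
    """Shape-free texture plus x/y warp fields for one face."""

    texture: np.ndarray  # (H, W) or (H, W, C), float
    warp_x: np.ndarray  # (H, W) pixels
    warp_y: np.ndarray  # (H, W) pixels

    def __post_init__(self) -> None:
        if self.texture.shape[:2] != self.warp_x.shape or self.warp_x.shape != self.warp_y.shape:
            raise ValueError("texture and warp fields must share H, W")
        for a in (self.texture, self.warp_x, self.warp_y):
            if not np.all(np.isfinite(a)):
                raise ValueError("warp-texture entries must be finite")

    @property
    def layout(self) -> tuple[int, int, int]:
        h, w = self.warp_x.shape
        c = 1 if self.texture.ndim == 2 else self.texture.shape[2]
        return h, w, c

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.texture.ravel(), self.warp_x.ravel(), self.warp_y.ravel()]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, layout: tuple[int, int, int]) -> "WarpTextureVector":
        h, w, c = layout
        nt = h * w * c
        if vec.size != nt + 2 * h * w:
            raise ValueError("vector length does not match layout")
        tex = vec[:nt].reshape((h, w) if c == 1 else (h, w, c))
        wx = vec[nt : nt + h * w].reshape(h, w)
        wy = vec[nt + h * w :].reshape(h, w)
        return cls(tex.copy(), wx.copy(), wy.copy())


def align_by_eyes(
    image: np.ndarray,
    landmarks: LandmarkSet,
    canonical_eyes: tuple[tuple[float, float], tuple[float, float]],
    output_shape: tuple[int, int] | None = None,
    background: float = 0.25,
) -> tuple[np.ndarray, LandmarkSet, SimilarityTransform]:
    """Similarity-align an image so its eye landmarks hit canonical positions.

    The two eye landmarks determine translation, rotation and uniform
    scale exactly (computed in closed form via the complex ratio of the
    inter-eye vectors).  The image is resampled bilinearly; all landmarks
    are returned transformed.
    """
    le = complex(*landmarks["left_eye"])
    re = complex(*landmarks["right_eye"])
    cle = complex(*canonical_eyes[0])
    cre = complex(*canonical_eyes[1])
    if abs(re - le) < 1e-9:
        raise ValueError("coincident eye landmarks")
    a = (cre - cle) / (re - le)  # rotation+scale
    b = cle - a * le  # translation

    s = abs(a)
    theta = np.angle(a)
    tform = SimilarityTransform(
        scale=s, rotation=theta, translation=(b.real, b.imag)
    )
    out_shape = output_shape or image.shape[:2]
    aligned = sk_warp(
        image.astype(float),
        inverse_map=tform.inverse,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=background,
        preserve_range=True,
    )
    new_pts = {}
    for name, (x, y) in landmarks.points.items():
        z = a * complex(x, y) + b
        new_pts[name] = (z.real, z.imag)
    return aligned, LandmarkSet(new_pts), tform


def mean_landmarks(landmark_sets: list[LandmarkSet]) -> LandmarkSet:
    names = landmark_sets[0].names
    arrs = np.stack([ls.as_array(names) for ls in landmark_sets])
    avg = arrs.mean(axis=0)
    return LandmarkSet({n: (float(x), float(y)) for n, (x, y) in zip(names, avg)})


def estimate_warp(
    source_landmarks: LandmarkSet,
    target_landmarks: LandmarkSet,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Dense backward warp field from target (average) geometry to source.

    Thin-plate-spline interpolation of the landmark displacements: at
    every target-geometry pixel the field gives the displacement to the
    corresponding source-image location, interpolating the landmark
    displacements exactly.
    """
    names = source_landmarks.names
    if set(names) != set(target_landmarks.names):
        raise ValueError("landmark sets must share names")
    if len(names) < 3:
        raise ValueError("need at least 3 landmarks for a dense warp")
    tgt = target_landmarks.as_array(names)
    src = source_landmarks.as_array(names)
    disp = src - tgt
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    if np.allclose(disp, 0.0):
        z = np.zeros((h, w))
        return z, z.copy()
    interp = RBFInterpolator(tgt, disp, kernel="thin_plate_spline")
    dense = interp(grid)
    warp_x = dense[:, 0].reshape(h, w)
    warp_y = dense[:, 1].reshape(h, w)
    return warp_x, warp_y


def _backward_sample(
    image: np.ndarray, warp_x: np.ndarray, warp_y: np.ndarray, background: float
) -> np.ndarray:
    h, w = warp_x.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + warp_y, xx + warp_x])
    if image.ndim == 2:
        return map_coordinates(image, coords, order=1, mode="constant", cval=background)
    out = np.stack(
        [
            map_coordinates(image[..., c], coords, order=1, mode="constant", cval=background)
            for c in range(image.shape[2])
        ],
        axis=-1,
    )
    return out


def extract_shape_free_texture(
    image: np.ndarray,
    warp_x: np.ndarray,
    warp_y: np.ndarray,
    background: float = 0.25,
) -> np.ndarray:
    """Sample the image through a backward warp into average geometry."""
    if image.shape[:2] != warp_x.shape:
        raise ValueError("warp field shape must match image")
    return _backward_sample(image, warp_x, warp_y, background)


@dataclass
class FaceSpaceModel:
    """PCA face space over warp-texture vectors.

    ``components`` rows are orthonormal; ``loading_sd[i]`` is the SD
    (ddof=1) of the training projections on component i, so coordinates
    in this space are in loading-SD units and the average face sits at
    the origin.
    """

    mean: np.ndarray  # (d,)
    components: np.ndarray  # (k, d) orthonormal rows
    loading_sd: np.ndarray  # (k,)
    layout: tuple[int, int, int]
    explained_variance: np.ndarray = field(default=None)  # (k,)
    manifest: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"layout": list(self.layout), "manifest": self.manifest})
        np.savez_compressed(
            path,
            mean=self.mean,
            components=self.components,
            loading_sd=self.loading_sd,
            explained_variance=self.explained_variance,
            meta=np.frombuffer(meta.encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FaceSpaceModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return cls(
                mean=z["mean"],
                components=z["components"],
                loading_sd=z["loading_sd"],
                layout=tuple(meta["layout"]),
                explained_variance=z["explained_variance"],
                manifest=meta.get("manifest", {}),
            )


def build_face_space(
    training: list[WarpTextureVector], k: int | str = "max"
) -> FaceSpaceModel:
    """PCA over the training warp-texture vectors via SVD of the centred data.

    Components are ordered by decreasing variance explained; at most
    n_train - 1 non-degenerate components exist.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training faces")
    layout = training[0].layout
    if any(t.layout != layout for t in training):
        raise ValueError("training faces must share dimensions")
    X = np.stack([t.to_vector() for t in training])
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max() * max(Xc.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    kmax = min(n - 1, rank)
    if k == "max":
        k_use = kmax
    else:
        k_use = int(k)
        if k_use > n - 1:
            raise ValueError(f"k={k_use} exceeds n-1={n - 1}")
        k_use = min(k_use, kmax)
    components = Vt[:k_use]
    loadings = Xc @ components.T
    loading_sd = loadings.std(axis=0, ddof=1)
    loading_sd = np.maximum(loading_sd, np.finfo(float).tiny)
    expl = S[:k_use] ** 2 / (n - 1)
    return FaceSpaceModel(
        mean=mean,
        components=components,
        loading_sd=loading_sd,
        layout=layout,
        explained_variance=expl,
    )


def project(face: WarpTextureVector | np.ndarray, model: FaceSpaceModel) -> np.ndarray:
    """Coordinates of a face in loading-SD units."""
    vec = face.to_vector() if isinstance(face, WarpTextureVector) else np.asarray(face)
    if vec.size != model.mean.size:
        raise ValueError("dimension mismatch with model")
    return (vec - model.mean) @ model.components.T / model.loading_sd


def synthesize(coords: np.ndarray, model: FaceSpaceModel) -> WarpTextureVector:
    """mean + sum_i coords[i] * loading_sd[i] * component_i."""
    coords = np.asarray(coords, dtype=float)
    if coords.size > model.k:
        raise ValueError("more coordinates than components")
    full = np.zeros(model.k)
    full[: coords.size] = coords
    vec = model.mean + (full * model.loading_sd) @ model.components
    return WarpTextureVector.from_vector(vec, model.layout)


def render_face(
    vec: WarpTextureVector, background: float = 0.25, clip: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Reconstruct an image: displace the texture through its own warp field."""
    img = _backward_sample(vec.texture, vec.warp_x, vec.warp_y, background)
    return np.clip(img, *clip)


def prepare_stimulus(
    image: np.ndarray,
    background: float | np.ndarray = 0.5,
    orientation: str = "upright",
    feather_px: int = 5,
) -> np.ndarray:
    """Feather the image into the background; optionally invert (vertical flip).

    The alpha ramp rises linearly with distance from the nearest edge over
    ``feather_px`` pixels; inversion is applied after feathering.
    """
    h, w = image.shape[:2]
    if feather_px >= min(h, w) / 2:
        raise ValueError("feather margin too large for image")
    if orientation not in ("upright", "inverted"):
        raise ValueError("orientation must be 'upright' or 'inverted'")
    out = image.astype(float).copy()
    if feather_px > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        edge_dist = np.minimum.reduce([xx, yy, w - 1 - xx, h - 1 - yy]) + 0.0
        alpha = np.clip(edge_dist / feather_px, 0.0, 1.0)
        if image.ndim == 3:
            alpha = alpha[..., None]
        out = alpha * out + (1 - alpha) * background
    if orientation == "inverted":
        out = out[::-1].copy()
    return out


def make_noise_mask(
    stimuli: list[np.ndarray], shape: tuple[int, ...], seed: int = 0
) -> np.ndarray:
    """Gaussian noise image with per-channel mean/SD taken from the stimuli."""
    if not stimuli:
        raise ValueError("empty stimulus set")
    stack = np.concatenate([np.atleast_3d(s).reshape(-1, np.atleast_3d(s).shape[-1]) for s in stimuli])
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0)
    n_ch = mu.size
    rng = np.random.default_rng(seed)
    out_shape = shape if len(shape) == 3 else (*shape, n_ch)
    if out_shape[-1] != n_ch:
        raise ValueError("requested channel count does not match stimuli")
    mask = rng.normal(mu, sd, size=out_shape)
    mask = np.clip(mask, 0.0, 1.0)
    return mask.squeeze()


def vectorize_faces(
    images: list[np.ndarray],
    landmark_sets: list[LandmarkSet],
    canonical_eyes: tuple[tuple[float, float], tuple[float, float]] | None = None,
    background: float = 0.25,
) -> tuple[list[WarpTextureVector], LandmarkSet]:
    """Full front end: eye-align, average geometry, per-face TPS warp + texture.

    Returns the training warp-texture vectors and the average-geometry
    landmark set they are expressed in.
    """
    h, w = images[0].shape[:2]
    if canonical_eyes is None:
        sep = np.mean(
            [ls["right_eye"][0] - ls["left_eye"][0] for ls in landmark_sets]
        )
        ey = np.mean([ls["left_eye"][1] for ls in landmark_sets])
        cx = (w - 1) / 2.0
        canonical_eyes = ((cx - sep / 2, ey), (cx + sep / 2, ey))
    aligned = [
        align_by_eyes(img, lms, canonical_eyes, background=background)[:2]
        for img, lms in zip(images, landmark_sets)
    ]
    avg_lms = mean_landmarks([lm for _, lm in aligned])
    vectors = []
    for img, lms in aligned:
        wx, wy = estimate_warp(lms, avg_lms, (h, w))
        tex = extract_shape_free_texture(img, wx, wy, background)
        vectors.append(WarpTextureVector(tex, wx, wy))
    return vectors, avg_lms
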