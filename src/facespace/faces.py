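"""Parametric synthetic face images with exact landmarks.

Faces are vector-drawn from smooth analytic primitives (shaded head
ellipse, Gaussian-profile eyes, brows, nose and mouth) so that a
population of them carries correlated shape + texture variation while
every landmark coordinate is known exactly.  They are deliberately not
photorealistic: the face-space mathematics downstream only needs smooth
images whose generative dimensions are controlled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: order of the numeric generative parameters used for sampling
PARAM_NAMES = (
    "head_width",
    "head_height",
    "eye_separation",
    "eye_height",
    "eye_size",
    "nose_length",
    "mouth_width",
    "mouth_height",
    "brow_height",
    "texture_tone",
)


@dataclass(frozen=True)
class FaceParams:
    """Generative parameters of one synthetic face (pixel units).

    ``eye_height`` is the vertical offset of the eye line above the face
    centre; ``brow_height`` the offset of the brows above the eye line.
    ``texture_tone`` in [0, 1] sets the overall skin brightness.
    """

    head_width: float = 64.0
    head_height: float = 92.0
    eye_separation: float = 30.0
    eye_height: float = 14.0
    eye_size: float = 5.0
    nose_length: float = 18.0
    mouth_width: float = 24.0
    mouth_height: float = 5.0
    brow_height: float = 9.0
    texture_tone: float = 0.62
    seed: int = 0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, seed: int = 0) -> "FaceParams":
        kwargs = {n: float(v) for n, v in zip(PARAM_NAMES, values)}
        return cls(seed=seed, **kwargs)

    def validate(self) -> None:
        geo = self.to_array()[:9]
        if np.any(geo <= 0):
            raise ValueError("all geometric parameters must be strictly positive")
        if self.eye_separation >= self.head_width:
            raise ValueError("eye_separation must be smaller than head_width")
        if not 0.0 <= self.texture_tone <= 1.0:
            raise ValueError("texture_tone must lie in [0, 1]")


@dataclass
class LandmarkSet:
    """Named 2-D landmarks, 0-based pixel coordinates, origin top-left."""

    points: dict[str, tuple[float, float]]

    REQUIRED = ("left_eye", "right_eye", "nose_tip", "mouth_left", "mouth_right", "chin")

    def __post_init__(self) -> None:
        for name in self.REQUIRED:
            if name not in self.points:
                raise ValueError(f"missing required landmark {name!r}")
        if not all(np.isfinite(v).all() for v in map(np.asarray, self.points.values())):
            raise ValueError("landmark coordinates must be finite")
        if self.points["left_eye"][0] >= self.points["right_eye"][0]:
            raise ValueError("left_eye must lie left of right_eye")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    @property
    def names(self) -> list[str]:
        return list(self.points)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([self.points[n] for n in names], dtype=float)

    def to_frame(self, file: str = "") -> pd.DataFrame:
        rows = [(file, n, x, y) for n, (x, y) in self.points.items()]
        return pd.DataFrame(rows, columns=["file", "landmark_name", "x", "y"])


# parameter clipping bounds used by sample_population (lower, upper); None = open
_BOUNDS = {
    "head_width": (24.0, None),
    "head_height": (32.0, None),
    "eye_separation": (6.0, None),
    "eye_height": (4.0, None),
    "eye_size": (1.5, 12.0),
    "nose_length": (4.0, None),
    "mouth_width": (6.0, None),
    "mouth_height": (1.5, 14.0),
    "brow_height": (3.0, 18.0),
    "texture_tone": (0.05, 0.95),
}


def default_covariance(scale: float = 1.0) -> np.ndarray:
    """Covariance over PARAM_NAMES with correlated shape and texture.

    Head size, feature sizes and skin tone co-vary, emulating the
    correlated shape+texture variation of a natural photo set.
    """
    sd = np.array([3.5, 4.5, 2.0, 1.5, 0.7, 2.0, 2.2, 0.9, 1.0, 0.07]) * scale
    corr = np.eye(len(sd))

    def set_r(a, b, r):
        i, j = PARAM_NAMES.index(a), PARAM_NAMES.index(b)
        corr[i, j] = corr[j, i] = r

    set_r("head_width", "head_height", 0.6)
    set_r("head_width", "eye_separation", 0.5)
    set_r("head_width", "mouth_width", 0.4)
    set_r("head_height", "nose_length", 0.4)
    set_r("texture_tone", "head_width", 0.3)
    set_r("texture_tone", "mouth_height", -0.2)
    cov = np.outer(sd, sd) * corr
    return cov


def sample_population(
    n: int,
    mean_params: FaceParams | None = None,
    covariance: np.ndarray | None = None,
    seed: int = 0,
) -> list[FaceParams]:
    """Draw ``n`` parameter sets from a multivariate normal, clipped to validity.

    Deterministic for a given seed.  Clipping events are logged at DEBUG
    level with the parameter name and count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean_params = mean_params or FaceParams()
    covariance = default_covariance() if covariance is None else np.asarray(covariance, float)
    p = len(PARAM_NAMES)
    if covariance.shape != (p, p):
        raise ValueError(f"covariance must be {p}x{p}")
    if not np.allclose(covariance, covariance.T):
        raise ValueError("covariance must be symmetric")
    eigs = np.linalg.eigvalsh(covariance)
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        raise ValueError("covariance must be positive semi-definite")

    rng = np.random.default_rng(seed)
    mu = mean_params.to_array()
    draws = rng.multivariate_normal(mu, covariance, size=n, method="svd")

    for j, name in enumerate(PARAM_NAMES):
        lo, hi = _BOUNDS[name]
        col = draws[:, j]
        n_clip = 0
        if lo is not None:
            n_clip += int((col < lo).sum())
            np.clip(col, lo, None, out=col)
        if hi is not None:
            n_clip += int((col > hi).sum())
            np.clip(col, None, hi, out=col)
        if n_clip:
            logger.debug("clipped %d samples of %s to bounds", n_clip, name)
    # keep eyes inside the head
    sep_cap = 0.8 * draws[:, PARAM_NAMES.index("head_width")]
    j = PARAM_NAMES.index("eye_separation")
    n_clip = int((draws[:, j] > sep_cap).sum())
    if n_clip:
        logger.debug("clipped %d samples of eye_separation below 0.8*head_width", n_clip)
    draws[:, j] = np.minimum(draws[:, j], sep_cap)

    return [FaceParams.from_array(row, seed=seed) for row in draws]


def _soft_ellipse(xx, yy, cx, cy, rx, ry, edge=1.2):
    """Smooth inside-mask of an ellipse; 1 inside, 0 outside, ~edge px rolloff."""
    d = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    # convert normalized distance to approximate pixel distance from boundary
    px = (1.0 - d) * min(rx, ry)
    return np.clip(0.5 + px / (2.0 * edge), 0.0, 1.0)


def _blob(xx, yy, cx, cy, sx, sy):
    return np.exp(-0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2))


def render_face(
    params: FaceParams, width: int = 100, height: int = 120
) -> tuple[np.ndarray, LandmarkSet]:
    """Render one face; returns (H, W) float image in [0, 1] and its landmarks.

    Landmark coordinates are exactly the analytic feature centres used in
    drawing.  Raises if any feature would fall within 4 px of the canvas
    edge.
    """
    if width < 32 or height < 32:
        raise ValueError("canvas must be at least 32x32 px")
    params.validate()
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    eye_y = cy - params.eye_height
    eye_lx = cx - params.eye_separation / 2.0
    eye_rx = cx + params.eye_separation / 2.0
    nose_y = eye_y + params.nose_length
    mouth_y = nose_y + 0.12 * params.head_height
    chin_y = cy + params.head_height / 2.0
    top_y = cy - params.head_height / 2.0

    lm = {
        "left_eye": (eye_lx, eye_y),
        "right_eye": (eye_rx, eye_y),
        "nose_tip": (cx, nose_y),
        "mouth_left": (cx - params.mouth_width / 2.0, mouth_y),
        "mouth_right": (cx + params.mouth_width / 2.0, mouth_y),
        "chin": (cx, chin_y),
        "brow_left": (eye_lx, eye_y - params.brow_height),
        "brow_right": (eye_rx, eye_y - params.brow_height),
    }
    # outline points on the head ellipse, offset so none coincides with the chin
    rx, ry = params.head_width / 2.0, params.head_height / 2.0
    for i, ang in enumerate(np.linspace(0, 2 * np.pi, 8, endpoint=False) + np.pi / 8):
        lm[f"outline_{i}"] = (cx + rx * np.cos(ang), cy + ry * np.sin(ang))

    coords = np.array(list(lm.values()))
    if (
        coords[:, 0].min() < 4
        or coords[:, 1].min() < 4
        or coords[:, 0].max() > width - 5
        or coords[:, 1].max() > height - 5
    ):
        raise ValueError("face parameters place features off-canvas (need >= 4 px margin)")

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    img = np.full((height, width), 0.25)

    head = _soft_ellipse(xx, yy, cx, cy, rx, ry)
    r2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    shade = params.texture_tone * (1.0 - 0.25 * np.clip(r2, 0, 1))
    img = img * (1 - head) + shade * head

    dark = 0.12 * params.texture_tone + 0.03
    for ex in (eye_lx, eye_rx):
        img -= (params.texture_tone - dark) * _blob(
            xx, yy, ex, eye_y, params.eye_size, 0.6 * params.eye_size
        )
        img -= 0.5 * params.texture_tone * _blob(
            xx, yy, ex, eye_y - params.brow_height, 1.3 * params.eye_size, 1.2
        )
    # nose: faint vertical ridge ending at nose_tip
    t = np.clip((yy - eye_y) / max(params.nose_length, 1e-6), 0, 1)
    ridge = np.exp(-0.5 * ((xx - cx) / 1.8) ** 2) * np.where(
        (yy >= eye_y) & (yy <= nose_y), 0.3 * t, 0.0
    )
    img -= 0.25 * params.texture_tone * ridge
    img -= 0.35 * params.texture_tone * _blob(
        xx, yy, cx, nose_y, 2.2, 1.4
    )
    img -= 0.6 * params.texture_tone * _blob(
        xx, yy, cx, mouth_y, params.mouth_width / 2.2, params.mouth_height / 2.0
    )

    img = np.clip(img, 0.0, 1.0)
    return img, LandmarkSet(lm)


def generate_dataset(
    n_per_class: int,
    classes: tuple[str, ...] = ("A", "B"),
    out_dir: str | Path = ".",
    seed: int = 0,
    width: int = 100,
    height: int = 120,
    mean_params: dict[str, FaceParams] | None = None,
    covariance: np.ndarray | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write PNG faces + landmark TSVs + a manifest TSV; returns the manifest.

    Two classes stand in for the gender-specific training sets the space
    is built from: class means differ slightly in head geometry and tone.
    Deterministic for a given seed (per-class child seeds are spawned from
    it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    base = FaceParams()
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(classes))
    for ci, (cls, ss) in enumerate(zip(classes, children)):
        if mean_params and cls in mean_params:
            mean = mean_params[cls]
        else:
            tweak = base.to_array()
            tweak[0] += 3.0 * (ci - (len(classes) - 1) / 2)  # head_width
            tweak[9] = np.clip(tweak[9] + 0.06 * (ci - (len(classes) - 1) / 2), 0.1, 0.9)
            mean = FaceParams.from_array(tweak)
        cls_seed = int(ss.generate_state(1)[0] % (2**31))
        pop = sample_population(n_per_class, mean, covariance, seed=cls_seed)
        lm_rows = []
        for i, p in enumerate(pop):
            img, lm = render_face(p, width, height)
            fname = f"{cls}_{i:03d}.png"
            iio.imwrite(out_dir / fname, (img * 255).round().astype(np.uint8))
            lm_rows.append(lm.to_frame(fname))
            rows.append(
                {
                    "file": fname,
                    "class": cls,
                    "index": i,
                    "seed": cls_seed,
                    **{k: getattr(p, k) for k in PARAM_NAMES},
                }
            )
        pd.concat(lm_rows).to_csv(out_dir / f"landmarks_{cls}.tsv", sep="\t", index=False)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest


def checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_landmarks(tsv: str | Path) -> dict[str, LandmarkSet]:
    """Read a landmarks TSV back into per-file LandmarkSets."""
    df = pd.read_csv(tsv, sep="\t")
    out = {}
    for fname, grp in df.groupby("file", sort=False):
        out[fname] = LandmarkSet(
            {r.landmark_name: (float(r.x), float(r.y)) for r in grp.itertuples()}
        )
    return out
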