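"""Landmark-based morphometry of the larval zebrafish pronephros.

The pronephros is measured on a dorsal-view kidney thumbnail through 16 named
reference points, 8 per side (left/right of the embryo midline):

* ``vertex`` — junction of the neck segment and the proximal convoluted
  tubule; the "pronephric angle" is measured here.
* ``neck_ray`` — a point on the neck segment, defining one leg of the angle.
* ``tubule_ray`` — a point on the medial edge of the proximal convoluted
  tubule; defines the other leg of the angle and the medial edge for the
  tubular-diameter measurement.
* ``tubule_lateral`` — the lateral edge of the proximal tubule; shared
  between the tubular diameter and the (left-lateral to right-lateral)
  tubular distance.
* ``glom_anterior`` / ``glom_posterior`` — anterior and posterior poles of
  the glomerular lobe (glomerular height).
* ``glom_medial`` / ``glom_lateral`` — medial and lateral poles of the
  glomerular lobe (glomerular width); the two medial poles also define the
  glomerular separation.

From these points ten quantitative parameters are computed: ``angleL``,
``angleR`` (degrees), ``tubDist``, ``glomHeightL``, ``glomHeightR``,
``glomSep``, ``glomWidthL``, ``glomWidthR``, ``tubDiamL``, ``tubDiamR``
(pixels, or micrometres when a pixel-size calibration is given).

Coordinates are (x, y) with x = column and y = row, origin at the top-left
of the image, consistent with the rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "POINT_NAMES",
    "LandmarkSet",
    "MorphometricFeatures",
    "angle_at_vertex",
    "compute_features",
    "load_landmarks",
    "write_landmarks",
    "features_table",
]

#: Canonical order of the ten morphometric parameters.
PARAM_NAMES: Tuple[str, ...] = (
    "angleL",
    "angleR",
    "tubDist",
    "glomHeightL",
    "glomHeightR",
    "glomSep",
    "glomWidthL",
    "glomWidthR",
    "tubDiamL",
    "tubDiamR",
)

_SIDE_POINTS = (
    "vertex",
    "neck_ray",
    "tubule_ray",
    "tubule_lateral",
    "glom_anterior",
    "glom_posterior",
    "glom_medial",
    "glom_lateral",
)

#: The 16 named reference points ("L_vertex", ..., "R_glom_lateral").
POINT_NAMES: Tuple[str, ...] = tuple(
    f"{side}_{name}" for side in ("L", "R") for name in _SIDE_POINTS
)


class DegenerateGeometryError(ValueError):
    """A landmark configuration admits no well-defined measurement."""


Point = Tuple[float, float]


@dataclass(frozen=True)
class LandmarkSet:
    """The 16 named reference points of one embryo, in pixel coordinates."""

    points: Dict[str, Point]

    def __post_init__(self) -> None:
        missing = [n for n in POINT_NAMES if n not in self.points]
        extra = [n for n in self.points if n not in POINT_NAMES]
        if missing or extra:
            raise ValueError(
                f"landmark set must contain exactly the 16 reference points; "
                f"missing={missing}, unexpected={extra}"
            )
        for name, (x, y) in self.points.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for point {name!r}")
        for side in ("L", "R"):
            v = self.points[f"{side}_vertex"]
            for ray in ("neck_ray", "tubule_ray"):
                if self.points[f"{side}_{ray}"] == v:
                    raise DegenerateGeometryError(
                        f"{side}_{ray} coincides with {side}_vertex"
                    )

    def __getitem__(self, name: str) -> Point:
        return self.points[name]

    def transformed(self, fn) -> "LandmarkSet":
        """Return a new set with ``fn((x, y)) -> (x, y)`` applied to every point."""
        return LandmarkSet({n: tuple(fn(p)) for n, p in self.points.items()})

    def mirrored(self, axis_x: float = 0.0) -> "LandmarkSet":
        """Reflect across the vertical line x = ``axis_x``, swapping sides."""
        out = {}
        for side, other in (("L", "R"), ("R", "L")):
            for name in _SIDE_POINTS:
                x, y = self.points[f"{other}_{name}"]
                out[f"{side}_{name}"] = (2.0 * axis_x - x, y)
        return LandmarkSet(out)

    def as_array(self) -> np.ndarray:
        """16 × 2 array in :data:`POINT_NAMES` order."""
        return np.array([self.points[n] for n in POINT_NAMES], dtype=float)


@dataclass(frozen=True)
class MorphometricFeatures:
    """The ten quantitative pronephros parameters of one embryo.

    Angles are in degrees in (0, 180]; lengths are in pixels, or µm when a
    pixel size was supplied to :func:`compute_features`.
    """

    angleL: float
    angleR: float
    tubDist: float
    glomHeightL: float
    glomHeightR: float
    glomSep: float
    glomWidthL: float
    glomWidthR: float
    tubDiamL: float
    tubDiamR: float

    def __post_init__(self) -> None:
        for name in ("angleL", "angleR"):
            a = getattr(self, name)
            if not 0.0 < a <= 180.0:
                raise ValueError(f"{name}={a!r} outside (0, 180] degrees")
        for name in PARAM_NAMES[2:]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        """Values in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def as_dict(self) -> Dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}


def angle_at_vertex(vertex: Point, ray_a: Point, ray_b: Point) -> float:
    """Interior angle at ``vertex`` between the rays to ``ray_a`` and ``ray_b``.

    Returns degrees in (0, 180].  Raises :class:`DegenerateGeometryError`
    when either ray point coincides with the vertex.
    """
    v = np.asarray(vertex, dtype=float)
    a = np.asarray(ray_a, dtype=float) - v
    b = np.asarray(ray_b, dtype=float) - v
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("ray point coincides with the vertex")
    # atan2 of cross/dot is numerically stable near 0 and 180 degrees
    cross = a[0] * b[1] - a[1] * b[0]
    dot = float(a @ b)
    ang = math.degrees(math.atan2(abs(cross), dot))
    if ang == 0.0:
        # coincident ray directions: undefined interior angle
        raise DegenerateGeometryError("rays are coincident; angle undefined")
    return ang


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def compute_features(
    landmarks: LandmarkSet, pixel_size: float = 1.0
) -> MorphometricFeatures:
    """Compute the ten morphometric parameters from a 16-point landmark set.

    Parameters
    ----------
    landmarks
        A validated :class:`LandmarkSet`.
    pixel_size
        Calibration in µm per pixel; every length is multiplied by it.
        The default 1.0 reports lengths in pixels — absolute calibration
        cancels in the downstream control-normalized fold changes.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    p = landmarks
    s = pixel_size
    return MorphometricFeatures(
        angleL=angle_at_vertex(p["L_vertex"], p["L_neck_ray"], p["L_tubule_ray"]),
        angleR=angle_at_vertex(p["R_vertex"], p["R_neck_ray"], p["R_tubule_ray"]),
        tubDist=s * _dist(p["L_tubule_lateral"], p["R_tubule_lateral"]),
        glomHeightL=s * _dist(p["L_glom_anterior"], p["L_glom_posterior"]),
        glomHeightR=s * _dist(p["R_glom_anterior"], p["R_glom_posterior"]),
        glomSep=s * _dist(p["L_glom_medial"], p["R_glom_medial"]),
        glomWidthL=s * _dist(p["L_glom_medial"], p["L_glom_lateral"]),
        glomWidthR=s * _dist(p["R_glom_medial"], p["R_glom_lateral"]),
        tubDiamL=s * _dist(p["L_tubule_ray"], p["L_tubule_lateral"]),
        tubDiamR=s * _dist(p["R_tubule_ray"], p["R_tubule_lateral"]),
    )


# ---------------------------------------------------------------------------
# Landmark CSV ingestion (columns: plate, well, embryo, point_name, x, y)
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ("plate", "well", "embryo", "point_name", "x", "y")


def load_landmarks(path) -> Dict[Tuple[str, str, int], LandmarkSet]:
    """Read a landmark CSV into one :class:`LandmarkSet` per embryo.

    The file must carry the columns ``plate, well, embryo, point_name, x, y``
    with exactly the 16 :data:`POINT_NAMES` per (plate, well, embryo) key.
    """
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark file {path} lacks columns {sorted(missing)}")
    out: Dict[Tuple[str, str, int], LandmarkSet] = {}
    for key, grp in df.groupby(["plate", "well", "embryo"], sort=True):
        dup = grp["point_name"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate landmark names for embryo {key} in {path}")
        pts = {
            str(r.point_name): (float(r.x), float(r.y)) for r in grp.itertuples()
        }
        out[(str(key[0]), str(key[1]), int(key[2]))] = LandmarkSet(pts)
    return out


def write_landmarks(
    landmarks: Mapping[Tuple[str, str, int], LandmarkSet], path
) -> None:
    """Write per-embryo landmark sets to the ingestion CSV format."""
    rows = []
    for (plate, well, embryo), lset in landmarks.items():
        for name in POINT_NAMES:
            x, y = lset[name]
            rows.append((plate, well, embryo, name, x, y))
    pd.DataFrame(rows, columns=list(LANDMARK_COLUMNS)).to_csv(path, index=False)


def features_table(
    landmarks: Mapping[Tuple[str, str, int], LandmarkSet],
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Per-embryo feature table: identifier columns plus the 10 parameters."""
    rows = []
    for (plate, well, embryo), lset in sorted(landmarks.items()):
        feats = compute_features(lset, pixel_size=pixel_size)
        rows.append({"plate": plate, "well": well, "embryo": embryo, **feats.as_dict()})
    return pd.DataFrame(rows, columns=["plate", "well", "embryo", *PARAM_NAMES])
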