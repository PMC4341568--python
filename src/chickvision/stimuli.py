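"""Viewpoint space, animation structure, and synthetic object rendering.

The experiment presents an object across a 9 x 9 grid of (azimuth,
elevation) rotations in 15-degree steps, organized into 27 three-frame
animations (azimuth centers -45/0/+45 crossed with the 9 elevations), each
looping at 1 image/second.  The frontal +/-15-degree azimuth range at
elevation 0 is the familiar (imprinting) range.

Because the original virtual objects are not available, this module renders
synthetic stand-in objects: assemblies of 3D boxes and ellipsoids drawn by
an orthographic ray-cast projection onto a uniform white background.  The
renderer is deterministic: identical (object, viewpoint, size) always
yields a byte-identical raster.

Sign convention (fixed, documented; all downstream analyses are symmetric
in sign): positive azimuth rotates the object rightward about the vertical
axis, positive elevation tilts it upward about the horizontal axis; azimuth
is applied first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "GRID_ANGLES",
    "AZIMUTH_CENTERS",
    "FAMILIAR_RANGE_ID",
    "ViewpointSpec",
    "AnimationSpec",
    "GrayImage",
    "Part",
    "ObjectSpec",
    "build_viewpoint_grid",
    "build_test_animations",
    "input_animation",
    "range_id_for",
    "range_center",
    "render_viewpoint",
    "render_animation",
    "foreground_pixel_count",
    "mean_foreground_luminance",
    "default_objects",
    "save_png",
    "load_png",
    "viewpoint_filename",
    "save_object_spec",
    "load_object_spec",
]

GRID_ANGLES = (-60, -45, -30, -15, 0, 15, 30, 45, 60)
AZIMUTH_CENTERS = (-45, 0, 45)


@dataclass(frozen=True, order=True)
class ViewpointSpec:
    """One object pose: (azimuth, elevation) rotation in degrees."""

    azimuth_deg: float
    elevation_deg: float


@dataclass(frozen=True)
class AnimationSpec:
    """An ordered triple of viewpoints looped at ``frame_rate`` images/s.

    Frames share one elevation and their azimuths form the arithmetic
    triple {c-15, c, c+15} around the animation's center azimuth.
    """

    object_id: str
    frames: tuple[ViewpointSpec, ViewpointSpec, ViewpointSpec]
    frame_rate: float = 1.0
    range_id: int | None = None
    is_familiar: bool = False

    def __post_init__(self):
        if len(self.frames) != 3:
            raise ValueError("an animation has exactly 3 frames")
        elevs = {f.elevation_deg for f in self.frames}
        if len(elevs) != 1:
            raise ValueError("all frames must share one elevation")
        az = [f.azimuth_deg for f in self.frames]
        if not (az[1] - az[0] == 15 and az[2] - az[1] == 15):
            raise ValueError("azimuths must form the triple {c-15, c, c+15}")

    @property
    def center_azimuth(self) -> float:
        return self.frames[1].azimuth_deg

    @property
    def elevation(self) -> float:
        return self.frames[0].elevation_deg


@dataclass(frozen=True)
class GrayImage:
    """A luminance raster in [0, 1] on a uniform background (white = 1.0)."""

    values: np.ndarray
    background_level: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("luminance values must lie in [0, 1]")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Part:
    """An axis-aligned 3D primitive in the object's canonical frame."""

    kind: str  # "box" | "ellipsoid"
    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    shade: float  # foreground luminance in [0, 1)

    def __post_init__(self):
        if self.kind not in ("box", "ellipsoid"):
            raise ValueError(f"unknown part kind {self.kind!r}")
        if min(self.half_extents) <= 0:
            raise ValueError("half extents must be positive")
        if not 0.0 <= self.shade < 1.0:
            raise ValueError("shade must be in [0, 1) to contrast with background")


@dataclass(frozen=True)
class ObjectSpec:
    object_id: str
    parts: tuple[Part, ...]

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))


def build_viewpoint_grid() -> set[ViewpointSpec]:
    """All 81 combinations of the 9 azimuth and 9 elevation rotations."""
    return {
        ViewpointSpec(float(a), float(e)) for a in GRID_ANGLES for e in GRID_ANGLES
    }


def range_id_for(center_azimuth: float, elevation: float) -> int:
    """Viewpoint-range id in 1..27, elevation-major then azimuth-center."""
    ei = GRID_ANGLES.index(int(elevation))
    ai = AZIMUTH_CENTERS.index(int(center_azimuth))
    return 3 * ei + ai + 1


def range_center(range_id: int) -> tuple[float, float]:
    """Inverse of :func:`range_id_for`: (center_azimuth, elevation)."""
    if not 1 <= range_id <= 27:
        raise ValueError("range_id must be in 1..27")
    ei, ai = divmod(range_id - 1, 3)
    return float(AZIMUTH_CENTERS[ai]), float(GRID_ANGLES[ei])


FAMILIAR_RANGE_ID = range_id_for(0, 0)


def _animation(object_id: str, center_az: float, elevation: float) -> AnimationSpec:
    frames = tuple(
        ViewpointSpec(center_az + d, elevation) for d in (-15.0, 0.0, 15.0)
    )
    rid = range_id_for(center_az, elevation)
    return AnimationSpec(
        object_id=object_id,
        frames=frames,
        range_id=rid,
        is_familiar=(center_az == 0 and elevation == 0),
    )


def build_test_animations(object_id: str) -> list[AnimationSpec]:
    """The 27 test animations partitioning the 81-viewpoint grid.

    Azimuth centers {-45, 0, +45} crossed with the 9 elevations; each
    animation rocks +/-15 degrees in azimuth around its center.
    """
    return [
        _animation(object_id, float(c), float(e))
        for e in GRID_ANGLES
        for c in AZIMUTH_CENTERS
    ]


def input_animation(object_id: str) -> AnimationSpec:
    """The imprinting (input-phase) animation: frontal range, elevation 0."""
    return _animation(object_id, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _rotation_matrix(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    e = np.deg2rad(elevation_deg)
    ry = np.array(
        [[np.cos(a), 0.0, np.sin(a)], [0.0, 1.0, 0.0], [-np.sin(a), 0.0, np.cos(a)]]
    )
    rx = np.array(
        [[1.0, 0.0, 0.0], [0.0, np.cos(e), -np.sin(e)], [0.0, np.sin(e), np.cos(e)]]
    )
    return rx @ ry  # azimuth applied first


def _ray_box(o: np.ndarray, d: np.ndarray, center, half) -> np.ndarray:
    n = o.shape[0]
    tmin = np.full(n, -np.inf)
    tmax = np.full(n, np.inf)
    hit = np.ones(n, dtype=bool)
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            t1 = (center[ax] - half[ax] - o[:, ax]) / d[ax]
            t2 = (center[ax] + half[ax] - o[:, ax]) / d[ax]
            tmin = np.maximum(tmin, np.minimum(t1, t2))
            tmax = np.minimum(tmax, np.maximum(t1, t2))
        else:
            hit &= np.abs(o[:, ax] - center[ax]) <= half[ax]
    hit &= tmax >= tmin
    return np.where(hit, tmin, np.inf)


def _ray_ellipsoid(o: np.ndarray, d: np.ndarray, center, half) -> np.ndarray:
    c = np.asarray(center)
    h = np.asarray(half)
    q = (o - c) / h
    dd = d / h
    A = float(np.dot(dd, dd))
    B = 2.0 * q @ dd
    C = np.sum(q * q, axis=1) - 1.0
    disc = B * B - 4.0 * A * C
    hit = disc >= 0.0
    t = np.full(o.shape[0], np.inf)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t[hit] = ((-B - sq) / (2.0 * A))[hit]
    return t


def render_viewpoint(
    obj: ObjectSpec, vp: ViewpointSpec, size: int = 128, extent: float = 1.0
) -> GrayImage:
    """Orthographic projection of the rotated part assembly.

    Deterministic painter-style ray cast: per pixel, the nearest
    intersected part's shade; background white.  ``extent`` is the world
    half-width mapped onto the raster.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if not obj.parts:
        raise ValueError(f"object {obj.object_id!r} has no parts")
    R = _rotation_matrix(vp.azimuth_deg, vp.elevation_deg)
    # pixel rays in world frame: origin on the near plane, direction +z
    px = (np.arange(size) + 0.5) / size * 2.0 * extent - extent
    py = extent - (np.arange(size) + 0.5) / size * 2.0 * extent
    X, Y = np.meshgrid(px, py)
    origins_w = np.stack(
        [X.ravel(), Y.ravel(), np.full(size * size, -10.0)], axis=1
    )
    d_w = np.array([0.0, 0.0, 1.0])
    # into the object's canonical frame
    origins = origins_w @ R  # == (R.T @ o.T).T
    d = R.T @ d_w

    depth = np.full(size * size, np.inf)
    shade = np.full(size * size, 1.0)
    for part in obj.parts:
        if part.kind == "box":
            t = _ray_box(origins, d, part.center, part.half_extents)
        else:
            t = _ray_ellipsoid(origins, d, part.center, part.half_extents)
        closer = t < depth
        depth[closer] = t[closer]
        shade[closer] = part.shade
    return GrayImage(values=shade.reshape(size, size))


def render_animation(
    obj: ObjectSpec, anim: AnimationSpec, size: int = 128, extent: float = 1.0
) -> list[GrayImage]:
    return [render_viewpoint(obj, f, size=size, extent=extent) for f in anim.frames]


def foreground_pixel_count(img: GrayImage, tol: float = 0.5 / 255.0) -> int:
    """Pixels whose luminance differs from the background by more than tol."""
    return int(np.sum(np.abs(img.values - img.background_level) > tol))


def mean_foreground_luminance(img: GrayImage, tol: float = 0.5 / 255.0) -> float:
    mask = np.abs(img.values - img.background_level) > tol
    if not mask.any():
        raise ValueError("image has no foreground pixels")
    return float(img.values[mask].mean())


def default_objects() -> tuple[ObjectSpec, ObjectSpec]:
    """The two stand-in imprinting objects.

    Different part arrangements (shape) but matched bounding size, part
    count, and shade palette, so their mean rendered foreground luminance
    agrees within the experiment's similarity contract while their shapes
    clearly differ.
    """
    obj1 = ObjectSpec(
        "obj1",
        (
            Part("box", (0.0, 0.0, 0.0), (0.66, 0.34, 0.30), 0.35),
            Part("box", (0.0, 0.55, 0.0), (0.16, 0.32, 0.16), 0.55),
            Part("ellipsoid", (0.58, -0.05, 0.12), (0.28, 0.22, 0.22), 0.45),
            Part("box", (-0.40, -0.50, -0.08), (0.22, 0.22, 0.20), 0.70),
        ),
    )
    obj2 = ObjectSpec(
        "obj2",
        (
            Part("box", (0.0, 0.05, 0.0), (0.34, 0.66, 0.28), 0.35),
            Part("box", (0.48, 0.38, 0.10), (0.34, 0.16, 0.16), 0.55),
            Part("ellipsoid", (-0.45, -0.40, 0.05), (0.26, 0.26, 0.26), 0.45),
            Part("box", (0.42, -0.48, -0.10), (0.20, 0.18, 0.18), 0.70),
        ),
    )
    return obj1, obj2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _fmt_signed(x: float) -> str:
    return f"{int(round(x)):+d}"


def viewpoint_filename(object_id: str, vp: ViewpointSpec) -> str:
    return f"{object_id}_az{_fmt_signed(vp.azimuth_deg)}_el{_fmt_signed(vp.elevation_deg)}.png"


def save_png(img: GrayImage, path: str | os.PathLike) -> None:
    arr = np.round(img.values * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_png(path: str | os.PathLike) -> GrayImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return GrayImage(values=arr)


def save_object_spec(obj: ObjectSpec, path: str | os.PathLike) -> None:
    doc = {
        "object_id": obj.object_id,
        "parts": [
            {
                "kind": p.kind,
                "center": list(p.center),
                "half_extents": list(p.half_extents),
                "shade": p.shade,
            }
            for p in obj.parts
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_object_spec(path: str | os.PathLike) -> ObjectSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    parts = tuple(
        Part(
            kind=p["kind"],
            center=tuple(float(v) for v in p["center"]),
            half_extents=tuple(float(v) for v in p["half_extents"]),
            shade=float(p["shade"]),
        )
        for p in doc["parts"]
    )
    return ObjectSpec(object_id=str(doc["object_id"]), parts=parts)
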