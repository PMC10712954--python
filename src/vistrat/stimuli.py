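"""Parametric object family, renderer, and discrimination-protocol definitions.

The stimulus space is a two-dimensional shape family: a rounded-box body whose
side walls bow inward (concave) or outward (convex), with three spheres attached
to its top edge that are either horizontally aligned or displaced diagonally
(left sphere up, right sphere down).  Eleven concavity levels cross four
alignment levels; identity-preserving transformations (3D rotations in 30-degree
steps, five light locations, size scaling, position shifts) multiply the family
into the full stimulus set.

Images are rendered deterministically at 100 x 100 pixels by sphere-tracing a
signed-distance scene under a single directional light with Lambert shading and
an orthographic camera.  The same spec always produces bit-identical pixels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ROTATION_ANGLES",
    "LIGHT_LOCATIONS",
    "SIZE_SCALES",
    "POSITIONS",
    "N_CONCAVITY",
    "N_ALIGNMENT",
    "ShapeParams",
    "Transform",
    "IDENTITY_TRANSFORM",
    "StimulusSpec",
    "StimulusImage",
    "RenderConfig",
    "render",
    "brightness",
    "pixel_dissimilarity",
    "enumerate_space",
    "space_size",
    "Subgrid",
    "select_subgrid",
    "ProtocolDef",
    "protocol_pairs",
    "training_stimuli",
    "TEST_PROTOCOLS",
    "TRAINING_PROTOCOLS",
]

N_CONCAVITY = 11
N_ALIGNMENT = 4
ROTATION_ANGLES = (0, 30, 60, 90, 120, 150, 180)
LIGHT_LOCATIONS = ("front", "left", "right", "up", "under")
SIZE_SCALES = (1.0, 0.8, 0.6)
POSITIONS = ("center", "lower_left", "lower_right", "upper_left", "upper_right")

TRAINING_PROTOCOLS = ("training", "dimension_learning", "transformations")
TEST_PROTOCOLS = (
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "light_location",
    "size",
    "position",
    "combination_rotation",
    "zero_vs_high",
    "high_vs_zero",
)


class ValidationError(ValueError):
    """Raised for specs outside the declared parameter sets."""


@dataclass(frozen=True)
class ShapeParams:
    """One point of the concavity x alignment shape family.

    concavity_level
        0..10; mapped to a signed wall-bulge parameter, negative = concave
        (level 0, the trained target end), positive = convex (level 10),
        level 5 flat.  The mapping is strictly monotone.
    alignment_level
        0..3; 0 = spheres horizontally aligned, 3 = maximally misaligned
        (left sphere raised and right sphere lowered by one sphere radius).
    """

    concavity_level: int
    alignment_level: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.concavity_level) < N_CONCAVITY):
            raise ValidationError(f"concavity_level {self.concavity_level} not in 0..10")
        if not (0 <= int(self.alignment_level) < N_ALIGNMENT):
            raise ValidationError(f"alignment_level {self.alignment_level} not in 0..3")


@dataclass(frozen=True)
class Transform:
    """Identity-preserving transformation state of one stimulus."""

    rot_x: int = 0
    rot_y: int = 0
    rot_z: int = 0
    light_location: str = "front"
    size_scale: float = 1.0
    position: str = "center"

    def __post_init__(self) -> None:
        for name in ("rot_x", "rot_y", "rot_z"):
            if getattr(self, name) not in ROTATION_ANGLES:
                raise ValidationError(f"{name}={getattr(self, name)} not in {ROTATION_ANGLES}")
        if self.light_location not in LIGHT_LOCATIONS:
            raise ValidationError(f"light_location {self.light_location!r} unknown")
        if self.size_scale not in SIZE_SCALES:
            raise ValidationError(f"size_scale {self.size_scale} not in {SIZE_SCALES}")
        if self.position not in POSITIONS:
            raise ValidationError(f"position {self.position!r} unknown")


IDENTITY_TRANSFORM = Transform()

ROLES = ("target", "distractor", "ambiguous", "unassigned")


@dataclass(frozen=True)
class StimulusSpec:
    """Full parametric description of one rendered image."""

    shape: ShapeParams
    transform: Transform = IDENTITY_TRANSFORM
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role {self.role!r} unknown")

    def with_transform(self, **kwargs) -> "StimulusSpec":
        return replace(self, transform=replace(self.transform, **kwargs))


@dataclass(frozen=True)
class StimulusImage:
    """A rendered 100x100 luminance image plus the spec that produced it."""

    pixels: np.ndarray
    spec: StimulusSpec

    def __post_init__(self) -> None:
        px = self.pixels
        if px.shape != (100, 100):
            raise ValidationError(f"image shape {px.shape} != (100, 100)")
        if not np.all(np.isfinite(px)) or px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("pixel values must be finite and in [0, 1]")


# --------------------------------------------------------------------------- #
# Renderer
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RenderConfig:
    """Geometry and shading parameters of the deterministic renderer.

    Scene units: the orthographic window spans [-window, window] in x and y.
    """

    resolution: int = 100
    window: float = 1.15
    base_half: tuple = (0.62, 0.40, 0.35)   # box half-extents (x, y, z)
    rounding: float = 0.06                  # box edge rounding radius
    bulge_max: float = 0.22                 # |wall bulge| at concavity level 0/10
    sphere_radius: float = 0.16
    sphere_x: float = 0.45                  # lateral offset of outer spheres
    sphere_sink: float = 0.40               # sphere centre sits r*(1-sink) above top
    align_step: float = 0.16 / 3            # vertical offset per alignment level
    position_offset: float = 0.34           # scene-unit shift of named positions
    max_steps: int = 110
    step_scale: float = 0.7                 # conservative sphere-tracing factor
    hit_eps: float = 2e-3
    far: float = 6.0
    ambient: float = 0.10
    diffuse: float = 0.85

    def bulge(self, concavity_level: int) -> float:
        # strictly monotone signed mapping; level 5 is flat
        return (concavity_level - 5) / 5.0 * self.bulge_max


_LIGHT_DIRS = {
    "front": (0.0, 0.0, 1.0),
    "left": (-1.0, 0.0, 0.5),
    "right": (1.0, 0.0, 0.5),
    "up": (0.0, 1.0, 0.5),
    "under": (0.0, -1.0, 0.5),
}

_POSITION_OFFSETS = {
    "center": (0.0, 0.0),
    "lower_left": (-1.0, -1.0),
    "lower_right": (1.0, -1.0),
    "upper_left": (-1.0, 1.0),
    "upper_right": (1.0, 1.0),
}


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    # object rotated about x, then y, then z
    return Rz @ Ry @ Rx


def _sdf(p: np.ndarray, shape: ShapeParams, cfg: RenderConfig) -> np.ndarray:
    """Signed distance (conservative lower bound) from points ``p`` (N,3)."""
    bx, by, bz = cfg.base_half
    c = cfg.bulge(shape.concavity_level)
    x, y, z = p[:, 0], p[:, 1], p[:, 2]

    # wall bow: scale x/z cross-section by s(y); s>1 bulges out, s<1 caves in
    s = 1.0 + c * (1.0 - np.clip(y / by, -1.0, 1.0) ** 2)
    s = np.maximum(s, 0.2)
    qx = np.abs(x / s) - bx + cfg.rounding
    qy = np.abs(y) - by + cfg.rounding
    qz = np.abs(z / s) - bz + cfg.rounding
    ox = np.maximum(qx, 0.0)
    oy = np.maximum(qy, 0.0)
    oz = np.maximum(qz, 0.0)
    outside = np.sqrt(ox * ox + oy * oy + oz * oz)
    inside = np.minimum(np.maximum(qx, np.maximum(qy, qz)), 0.0)
    d = (outside + inside - cfg.rounding) * np.minimum(s, 1.0)

    # three spheres on the top edge; alignment tilts outer spheres diagonally
    r = cfg.sphere_radius
    cy = by + r * (1.0 - cfg.sphere_sink)
    dy = shape.alignment_level * cfg.align_step
    for sx_, dy_ in ((-cfg.sphere_x, +dy), (0.0, 0.0), (cfg.sphere_x, -dy)):
        ds = np.sqrt((x - sx_) ** 2 + (y - (cy + dy_)) ** 2 + z * z) - r
        d = np.minimum(d, ds)
    return d


def _normals(p: np.ndarray, shape: ShapeParams, cfg: RenderConfig) -> np.ndarray:
    eps = 1e-4
    n = np.empty_like(p)
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = eps
        n[:, i] = _sdf(p + dp, shape, cfg) - _sdf(p - dp, shape, cfg)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    return n / norm


def render(spec: StimulusSpec, cfg: RenderConfig | None = None) -> StimulusImage:
    """Render one stimulus deterministically (cached; same spec -> same pixels)."""
    cfg = cfg or RenderConfig()
    return _render_cached(spec, cfg)


@lru_cache(maxsize=8192)
def _render_cached(spec: StimulusSpec, cfg: RenderConfig) -> StimulusImage:
    res = cfg.resolution
    t = spec.transform

    # pixel centres; row-major, origin top-left, y decreasing down the rows
    u = (np.arange(res) + 0.5) / res * 2.0 - 1.0
    xs = u * cfg.window
    ys = -(u * cfg.window)
    X, Y = np.meshgrid(xs, ys)

    # size about the image centre, then shift to the named position
    offx, offy = _POSITION_OFFSETS[t.position]
    offx *= cfg.position_offset
    offy *= cfg.position_offset
    sx = (X - offx) / t.size_scale
    sy = (Y - offy) / t.size_scale

    n_px = res * res
    origins = np.column_stack([sx.ravel(), sy.ravel(), np.full(n_px, 3.0)])
    dirs = np.tile(np.array([0.0, 0.0, -1.0]), (n_px, 1))

    R = _rotation_matrix(t.rot_x, t.rot_y, t.rot_z)
    origins = origins @ R          # p_obj = R.T @ p_world, row-vector form
    dirs = dirs @ R

    # sphere tracing
    tdist = np.zeros(n_px)
    alive = np.ones(n_px, dtype=bool)
    hit = np.zeros(n_px, dtype=bool)
    for _ in range(cfg.max_steps):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        p = origins[idx] + tdist[idx, None] * dirs[idx]
        d = _sdf(p, spec.shape, cfg)
        newly_hit = d < cfg.hit_eps
        hit[idx[newly_hit]] = True
        tdist[idx] += np.maximum(d, cfg.hit_eps * 0.5) * cfg.step_scale
        escaped = tdist[idx] > cfg.far
        alive[idx] = ~(newly_hit | escaped)

    if not hit.any():
        raise ValidationError("object projected fully outside the frame")

    img = np.zeros(n_px)
    hidx = np.flatnonzero(hit)
    p_hit = origins[hidx] + tdist[hidx, None] * dirs[hidx]
    n = _normals(p_hit, spec.shape, cfg)
    light = np.asarray(_LIGHT_DIRS[t.light_location], dtype=float)
    light = (light / np.linalg.norm(light)) @ R
    lambert = np.clip(n @ light, 0.0, None)
    img[hidx] = np.clip(cfg.ambient + cfg.diffuse * lambert, 0.0, 1.0)

    pixels = img.reshape(res, res)
    pixels.flags.writeable = False
    return StimulusImage(pixels=pixels, spec=spec)


def brightness(img: StimulusImage | np.ndarray) -> float:
    """Mean luminance over all pixels."""
    px = img.pixels if isinstance(img, StimulusImage) else np.asarray(img)
    return float(px.mean())


def pixel_dissimilarity(a: StimulusImage | np.ndarray, b: StimulusImage | np.ndarray) -> float:
    """Euclidean distance between flattened pixel vectors."""
    pa = a.pixels if isinstance(a, StimulusImage) else np.asarray(a)
    pb = b.pixels if isinstance(b, StimulusImage) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValidationError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    return float(np.linalg.norm(pa.ravel() - pb.ravel()))


# --------------------------------------------------------------------------- #
# Space enumeration
# --------------------------------------------------------------------------- #

_AXIS_VALUES: Mapping[str, tuple] = {
    "alignment": tuple(range(N_ALIGNMENT)),
    "concavity": tuple(range(N_CONCAVITY)),
    "rot_x": ROTATION_ANGLES,
    "rot_y": ROTATION_ANGLES,
    "rot_z": ROTATION_ANGLES,
    "light_location": LIGHT_LOCATIONS,
    "size_scale": SIZE_SCALES,
    "position": POSITIONS,
}

#: the axes whose product is the published 75,460-image stimulus set
FULL_SPACE_AXES = ("alignment", "concavity", "rot_x", "rot_y", "rot_z", "light_location")


def _axis_values(axes: Sequence[str], values: Mapping[str, Sequence] | None) -> dict:
    out = {}
    for ax in axes:
        if ax not in _AXIS_VALUES:
            raise ValidationError(f"unknown axis {ax!r}")
        out[ax] = tuple((values or {}).get(ax, _AXIS_VALUES[ax]))
    return out


def space_size(axes: Sequence[str] = FULL_SPACE_AXES,
               values: Mapping[str, Sequence] | None = None) -> int:
    """Number of stimuli in the space spanned by ``axes`` (product of cardinalities)."""
    vals = _axis_values(axes, values)
    n = 1
    for v in vals.values():
        n *= len(v)
    return n


def enumerate_space(axes: Sequence[str] = FULL_SPACE_AXES,
                    values: Mapping[str, Sequence] | None = None,
                    ) -> tuple[int, Iterator[StimulusSpec]]:
    """Enumerate every stimulus spec of a sub-space exactly once.

    Axes not listed stay at their default (level 0 shape axes, identity
    transform axes).  Returns ``(count, iterator)``.
    """
    vals = _axis_values(axes, values)

    def _iter() -> Iterator[StimulusSpec]:
        names = list(vals)
        for combo in itertools.product(*(vals[n] for n in names)):
            d = dict(zip(names, combo))
            shape = ShapeParams(
                concavity_level=d.pop("concavity", 0),
                alignment_level=d.pop("alignment", 0),
            )
            yield StimulusSpec(shape=shape, transform=Transform(**d))

    return space_size(axes, values), _iter()


# --------------------------------------------------------------------------- #
# 4 x 4 sub-grid selection and roles
# --------------------------------------------------------------------------- #

def _role_for_cell(row: int, col: int, k: int = 4) -> str:
    """Diagonal rule on the k x k grid: the anti-diagonal joining the
    (aligned, convex) and (misaligned, concave) corners is ambiguous; the side
    containing the trained target corner (aligned, concave) is the target
    sub-grid, the other side the distractor sub-grid."""
    s = row + col
    if s == k - 1:
        return "ambiguous"
    return "target" if s < k - 1 else "distractor"


@dataclass(frozen=True)
class Subgrid:
    """A k x k shape grid (rows = alignment, columns = chosen concavity levels)."""

    concavity_columns: tuple
    k: int = 4

    def shape_at(self, row: int, col: int) -> ShapeParams:
        return ShapeParams(concavity_level=self.concavity_columns[col], alignment_level=row)

    def spec_at(self, row: int, col: int) -> StimulusSpec:
        return StimulusSpec(shape=self.shape_at(row, col), role=_role_for_cell(row, col, self.k))

    def cells(self) -> Iterator[tuple[int, int, StimulusSpec]]:
        for row in range(self.k):
            for col in range(self.k):
                yield row, col, self.spec_at(row, col)

    def specs_with_role(self, role: str) -> list[StimulusSpec]:
        return [s for _, _, s in self.cells() if s.role == role]

    @property
    def base_target(self) -> StimulusSpec:
        return self.spec_at(0, 0)

    @property
    def base_distractor(self) -> StimulusSpec:
        return self.spec_at(self.k - 1, self.k - 1)


# the output of select_subgrid() under the default render configuration,
# frozen here so the rest of the pipeline uses a fixed design
DEFAULT_SUBGRID = Subgrid(concavity_columns=(0, 3, 6, 10))


def select_subgrid(k: int = 4,
                   cfg: RenderConfig | None = None,
                   column_dissimilarity: Mapping[tuple[int, int], float] | None = None,
                   ) -> Subgrid:
    """Choose ``k`` concavity columns of the 4 x 11 grid spanning the full range
    with maximally uniform adjacent-column pixel dissimilarity.

    The two extreme columns are always included (the trained base pair sits at
    the grid corners); the interior columns minimise the variance of
    adjacent-column dissimilarities, with ties broken toward symmetric spacing.
    ``column_dissimilarity`` may supply precomputed ``(col_i, col_j) -> value``
    entries (used by tests); otherwise the identity-transform images of the
    4 x 11 grid are rendered and compared.
    """
    if k > N_CONCAVITY:
        raise ValidationError(f"k={k} exceeds grid width {N_CONCAVITY}")
    if k == N_CONCAVITY:
        return Subgrid(concavity_columns=tuple(range(N_CONCAVITY)), k=k)
    if k < 2:
        raise ValidationError("need at least the two extreme columns")

    if column_dissimilarity is None:
        imgs = {
            (a, c): render(StimulusSpec(ShapeParams(c, a)), cfg)
            for a in range(N_ALIGNMENT) for c in range(N_CONCAVITY)
        }

        def dis(ci: int, cj: int) -> float:
            return float(np.mean([
                pixel_dissimilarity(imgs[(a, ci)], imgs[(a, cj)])
                for a in range(N_ALIGNMENT)
            ]))
    else:
        def dis(ci: int, cj: int) -> float:
            key = (ci, cj) if (ci, cj) in column_dissimilarity else (cj, ci)
            return float(column_dissimilarity[key])

    last = N_CONCAVITY - 1
    best = None
    for middle in itertools.combinations(range(1, last), k - 2):
        cols = (0, *middle, last)
        adj = [dis(cols[i], cols[i + 1]) for i in range(k - 1)]
        var = float(np.var(adj))
        gaps = tuple(cols[i + 1] - cols[i] for i in range(k - 1))
        asym = sum(abs(g1 - g2) for g1, g2 in zip(gaps, reversed(gaps)))
        key = (round(var, 12), asym, cols)
        if best is None or key < best[0]:
            best = (key, cols)
    return Subgrid(concavity_columns=best[1], k=k)


# --------------------------------------------------------------------------- #
# Protocols
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ProtocolDef:
    """A named training/testing protocol: its stimulus pairs and the old pair."""

    name: str
    pairs: tuple  # of (target StimulusSpec, distractor StimulusSpec)
    old_pair: tuple

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


_TRANSFORM_VARIANTS = (
    dict(rot_x=30),
    dict(rot_y=30),
    dict(rot_z=30),
    dict(light_location="under"),
    dict(size_scale=0.8),
)


def _base_pair(subgrid: Subgrid) -> tuple[StimulusSpec, StimulusSpec]:
    return subgrid.base_target, subgrid.base_distractor


def protocol_pairs(name: str,
                   subgrid: Subgrid = DEFAULT_SUBGRID,
                   informed_pairs: Sequence[tuple[StimulusSpec, StimulusSpec]] | None = None,
                   ) -> ProtocolDef:
    """Enumerate the stimulus pairs of a named protocol.

    The two computationally informed protocols (``zero_vs_high``,
    ``high_vs_zero``) take their pairs from the pair-selection stage via
    ``informed_pairs``.
    """
    T, D = _base_pair(subgrid)
    old = (T, D)
    angles = [a for a in ROTATION_ANGLES if a != 0]

    def cross(ts: Iterable[StimulusSpec], ds: Iterable[StimulusSpec]) -> tuple:
        return tuple((t, d) for t in ts for d in ds)

    if name == "training":
        pairs = ((T, D),)
    elif name == "dimension_learning":
        # one pair differs only in concavity, one only in alignment; drawn
        # from the sub-grid interior so each member has a proper role
        pairs = (
            (subgrid.spec_at(1, 0), subgrid.spec_at(1, subgrid.k - 1)),
            (subgrid.spec_at(0, 1), subgrid.spec_at(subgrid.k - 1, 1)),
        )
    elif name == "transformations":
        ts = [T.with_transform(**kw) for kw in _TRANSFORM_VARIANTS]
        ds = [D.with_transform(**kw) for kw in _TRANSFORM_VARIANTS]
        pairs = cross(ts, ds)
    elif name in ("rotation_x", "rotation_y", "rotation_z"):
        axis = {"rotation_x": "rot_x", "rotation_y": "rot_y", "rotation_z": "rot_z"}[name]
        pairs = cross([T.with_transform(**{axis: a}) for a in angles],
                      [D.with_transform(**{axis: a}) for a in angles])
    elif name == "combination_rotation":
        pairs = cross([T.with_transform(rot_x=a, rot_y=a, rot_z=a) for a in angles],
                      [D.with_transform(rot_x=a, rot_y=a, rot_z=a) for a in angles])
    elif name == "light_location":
        lights = [l for l in LIGHT_LOCATIONS if l != "front"]
        pairs = cross([T.with_transform(light_location=l) for l in lights],
                      [D.with_transform(light_location=l) for l in lights])
    elif name == "size":
        sizes = [s for s in SIZE_SCALES if s != 1.0]
        pairs = cross([T.with_transform(size_scale=s) for s in sizes],
                      [D.with_transform(size_scale=s) for s in sizes])
    elif name == "position":
        pairs = cross([T.with_transform(size_scale=0.8, position=p) for p in POSITIONS],
                      [D.with_transform(size_scale=0.8, position=p) for p in POSITIONS])
    elif name in ("zero_vs_high", "high_vs_zero"):
        if informed_pairs is None:
            raise ValidationError(
                f"protocol {name!r} requires pairs from the pair-selection stage")
        pairs = tuple(informed_pairs)
    else:
        raise ValidationError(f"unknown protocol {name!r}")

    return ProtocolDef(name=name, pairs=pairs, old_pair=old)


def training_stimuli(subgrid: Subgrid = DEFAULT_SUBGRID,
                     ) -> tuple[list[StimulusSpec], np.ndarray]:
    """The labelled training stimuli used to fit the layer readouts.

    The set is the union of the distinct stimuli of the three training
    protocols: the base pair, the two dimension-learning pairs (one differing
    only in concavity, one only in alignment), and the five transformed
    versions of each base-pair member from the transformations protocol —
    16 stimuli, 8 targets and 8 distractors.  Labels are +1 for targets,
    -1 for distractors.
    """
    specs: list[StimulusSpec] = []
    labels: list[int] = []
    seen = set()
    for proto in TRAINING_PROTOCOLS:
        for t, d in protocol_pairs(proto, subgrid).pairs:
            for s, lab in ((t, +1), (d, -1)):
                if s not in seen:
                    seen.add(s)
                    specs.append(s)
                    labels.append(lab)
    return specs, np.asarray(labels, dtype=int)
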