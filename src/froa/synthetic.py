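"""Synthetic stimuli and scanpaths with known ground truth.

The generator emulates the structure of the experiment this package analyses:
families of multi-part closed silhouettes (unions of smooth convex primitives
whose junctions create paired boundary concavities, standing in for the
novel-object families used in recognition-training studies), and per-trial
scanpaths with a controllable preference for a target ROI, gamma step-length
and gamma fixation-duration distributions.

Every adjacent primitive pair contributes one ground-truth junction chord
(``true_cuts``) — the segment joining the two boundary intersection points —
which the minima/short-cut part segmentation should recover.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from scipy import ndimage as ndi
from shapely import affinity
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .contour import Silhouette, extract_contour
from .geometry import DEFAULT_GEOMETRY, ViewingGeometry
from .roi import RoiMask, build_all_models

__all__ = [
    "PartPrimitive",
    "SyntheticShape",
    "ScanPathConfig",
    "ScanPath",
    "FamilySpec",
    "GroupSpec",
    "ExperimentDesign",
    "BUILTIN_FAMILIES",
    "generate_shape",
    "generate_scanpath",
    "simulate_experiment",
    "generate_experiment",
]

FIXATION_COLUMNS = [
    "participant",
    "group",
    "trial",
    "stimulus",
    "fix_index",
    "x_px",
    "y_px",
    "duration_ms",
]


class ShapeGenerationError(RuntimeError):
    """Raised when a valid connected silhouette cannot be placed."""


@dataclass(frozen=True)
class PartPrimitive:
    """One convex part: an ellipse, a capsule, or a rectangle.

    ``size`` holds semi-axes / half-extents in px; for capsules the first
    component is the half-length of the whole capsule and the second its cap
    radius.  ``angle`` rotates the primitive counter-clockwise in image
    coordinates, in degrees.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, float]
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "capsule", "rectangle"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if min(self.size) <= 0:
            raise ValueError("primitive sizes must be positive")

    def geometry(self) -> shapely.Geometry:
        a, b = self.size
        if self.kind == "ellipse":
            g = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64), a, b)
        elif self.kind == "capsule":
            half = max(a - b, 1.0)
            g = LineString([(-half, 0), (half, 0)]).buffer(b, quad_segs=32)
        else:
            g = box(-a, -b, a, b)
        g = affinity.rotate(g, self.angle, origin=(0, 0))
        return affinity.translate(g, *self.center)


@dataclass
class SyntheticShape:
    """A generated silhouette with known part structure."""

    silhouette: Silhouette
    parts: list[PartPrimitive]
    true_cuts: list[np.ndarray]  # each (2, 2): endpoints (x, y) px
    family_id: str
    exemplar_id: int

    @property
    def mask(self) -> np.ndarray:
        return self.silhouette.mask


@dataclass(frozen=True)
class _Link:
    src: int
    dst: int
    direction_deg: float
    overlap: float = 0.8  # centre distance as a fraction of summed extents


@dataclass(frozen=True)
class FamilySpec:
    """Part templates plus adjacency links defining one shape family."""

    name: str
    parts: tuple[tuple[str, tuple[float, float], float], ...]
    links: tuple[_Link, ...]


BUILTIN_FAMILIES: dict[str, FamilySpec] = {
    "dumbbell": FamilySpec(
        "dumbbell",
        (("ellipse", (60, 60), 0), ("ellipse", (60, 60), 0)),
        (_Link(0, 1, 0.0, 100 / 120),),
    ),
    "chain3": FamilySpec(
        "chain3",
        (("ellipse", (55, 55), 0), ("ellipse", (55, 55), 0), ("ellipse", (55, 55), 0)),
        (_Link(0, 1, 0.0, 0.82), _Link(1, 2, 0.0, 0.82)),
    ),
    "elbow": FamilySpec(
        "elbow",
        (("ellipse", (60, 60), 0), ("ellipse", (50, 50), 0), ("ellipse", (50, 50), 0)),
        (_Link(0, 1, 0.0, 0.8), _Link(1, 2, 40.0, 0.8)),
    ),
    "pear": FamilySpec(
        "pear",
        (("ellipse", (85, 60), 0), ("ellipse", (45, 45), 0)),
        (_Link(0, 1, 270.0, 0.8),),
    ),
    "club": FamilySpec(
        "club",
        (("capsule", (95, 30), 0), ("ellipse", (50, 50), 0)),
        (_Link(0, 1, 0.0, 0.8),),
    ),
    "mallet": FamilySpec(
        "mallet",
        (("rectangle", (95, 30), 0), ("ellipse", (48, 48), 0)),
        (_Link(0, 1, 0.0, 0.8),),
    ),
}


def _extent_along(geom: shapely.Geometry, u: np.ndarray) -> float:
    pts = np.asarray(geom.exterior.coords)
    return float(np.max(pts @ u))


def _pair_chord(g1: shapely.Geometry, g2: shapely.Geometry) -> np.ndarray | None:
    """Endpoints of the junction chord of two overlapping convex parts."""
    inter = g1.exterior.intersection(g2.exterior)
    pts: list[tuple[float, float]] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if geom.geom_type == "Point":
            pts.append((geom.x, geom.y))
        else:  # tiny collinear overlaps from polygonal approximation
            pts.extend(geom.coords)
    if len(pts) < 2:
        return None
    arr = np.asarray(pts)
    if len(arr) > 2:
        # keep the two mutually farthest points
        d = np.sum((arr[:, None] - arr[None]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        arr = arr[[i, j]]
    return arr


def _rasterize(union: shapely.Geometry, frame_px: int) -> np.ndarray:
    mask = np.zeros((frame_px, frame_px), dtype=bool)
    minx, miny, maxx, maxy = union.bounds
    c0, c1 = max(int(minx) - 1, 0), min(int(maxx) + 2, frame_px)
    r0, r1 = max(int(miny) - 1, 0), min(int(maxy) + 2, frame_px)
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(union, cols.ravel(), rows.ravel())
    mask[rows.ravel()[inside], cols.ravel()[inside]] = True
    return mask


def generate_shape(
    family_spec: str | FamilySpec,
    metric_jitter: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    frame_px: int = 800,
    exemplar_id: int = 0,
    max_attempts: int = 8,
) -> SyntheticShape:
    """Build one exemplar of a shape family.

    ``metric_jitter`` gives the (lo, hi) range of multiplicative size factors
    (drawn independently per primitive axis) that create within-family metric
    variants; factors must stay within (0.5, 2).  Deterministic under a fixed
    seed.  Raises :class:`ShapeGenerationError` if no valid connected
    placement is found within ``max_attempts``.
    """
    spec = BUILTIN_FAMILIES[family_spec] if isinstance(family_spec, str) else family_spec
    lo, hi = metric_jitter
    if not (0.5 < lo <= hi < 2.0):
        raise ValueError("metric_jitter factors must lie within (0.5, 2)")
    if not spec.parts:
        raise ValueError("family_spec must name at least one primitive")
    rng = np.random.default_rng(seed)
    jit = rng.uniform(lo, hi, size=(len(spec.parts), 2))

    overlaps = {k: link.overlap for k, link in enumerate(spec.links)}
    last_err = "no attempt made"
    for _ in range(max_attempts):
        templates = [
            PartPrimitive(kind, (0.0, 0.0), (a * j[0], b * j[1]), angle)
            for (kind, (a, b), angle), j in zip(spec.parts, jit)
        ]
        centers: dict[int, np.ndarray] = {0: np.zeros(2)}
        geoms: dict[int, shapely.Geometry] = {0: templates[0].geometry()}
        for k, link in enumerate(spec.links):
            th = np.deg2rad(link.direction_deg)
            u = np.array([np.cos(th), np.sin(th)])
            src_geom = templates[link.src].geometry()
            dst_geom = templates[link.dst].geometry()
            dist = overlaps[k] * (_extent_along(src_geom, u) + _extent_along(dst_geom, -u))
            centers[link.dst] = centers[link.src] + u * dist
            geoms[link.dst] = affinity.translate(dst_geom, *centers[link.dst])
            if link.src not in (0,) and link.src not in geoms:
                raise ValueError("links must be ordered so sources are already placed")
        geoms[0] = affinity.translate(geoms[0], 0, 0)

        linked = {(link.src, link.dst) for link in spec.links}
        linked |= {(b, a) for a, b in linked}
        for a in geoms:
            for b in geoms:
                if a < b and (a, b) not in linked and geoms[a].distance(geoms[b]) < 2.0:
                    raise ShapeGenerationError(
                        f"family {spec.name!r}: unlinked parts {a} and {b} collide; "
                        "the ground-truth junction chords would be incomplete"
                    )
        union = unary_union(list(geoms.values()))
        if union.geom_type != "Polygon" or union.interiors:
            last_err = "union is disconnected or has holes"
            overlaps = {k: max(v - 0.04, 0.55) for k, v in overlaps.items()}
            continue
        # centre in frame
        cx, cy = union.centroid.x, union.centroid.y
        shift = np.array([frame_px / 2 - cx, frame_px / 2 - cy])
        geoms = {k: affinity.translate(g, *shift) for k, g in geoms.items()}
        union = affinity.translate(union, *shift)
        minx, miny, maxx, maxy = union.bounds
        if minx < 5 or miny < 5 or maxx > frame_px - 5 or maxy > frame_px - 5:
            raise ShapeGenerationError(
                f"family {spec.name!r} does not fit the {frame_px} px frame"
            )

        chords = []
        ok = True
        for k, link in enumerate(spec.links):
            chord = _pair_chord(geoms[link.src], geoms[link.dst])
            if chord is None or not union.covers(LineString(chord)):
                ok = False
                overlaps[k] = max(overlaps[k] - 0.04, 0.55)
        if not ok:
            last_err = "adjacent primitives do not intersect in a single chord"
            continue
        chords = [
            _pair_chord(geoms[link.src], geoms[link.dst]) for link in spec.links
        ]

        # the union polygon is hole-free; fill single-pixel raster artifacts
        mask = ndi.binary_fill_holes(_rasterize(union, frame_px))
        _, n_comp = ndi.label(mask)
        if n_comp != 1:
            last_err = "rasterised mask is disconnected"
            overlaps = {k: max(v - 0.04, 0.55) for k, v in overlaps.items()}
            continue
        sil = extract_contour(mask)
        parts = [replace(t, center=tuple(centers[i] + shift)) for i, t in enumerate(templates)]
        return SyntheticShape(
            silhouette=sil,
            parts=parts,
            true_cuts=[np.asarray(c) for c in chords],
            family_id=spec.name,
            exemplar_id=exemplar_id,
        )
    raise ShapeGenerationError(f"shape placement failed for {spec.name!r}: {last_err}")


# ---------------------------------------------------------------------------
# Scanpaths
# ---------------------------------------------------------------------------


@dataclass
class ScanPathConfig:
    """Statistical structure of a synthetic scanpath.

    With ``step_mean`` unset, fixation locations follow a mixture model: with
    probability ``roi_preference`` a point is sampled uniformly inside the
    target ROI, otherwise from the null density.  With ``step_mean`` set
    (degrees), fixations form a random walk whose step lengths are
    gamma-distributed with that mean and shape ``step_shape``; directions are
    re-drawn (lengths kept) until the step lands inside the frame, which
    preserves the step-length distribution.  Durations are i.i.d.
    gamma(``duration_shape``, scale=``duration_mean/duration_shape``) ms.
    """

    n_fixations: int = 8
    roi_preference: float = 0.0
    null_density: str = "uniform_object"
    step_mean: float | None = None
    step_shape: float = 3.0
    duration_mean: float = 197.0
    duration_shape: float = 18.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.roi_preference <= 1:
            raise ValueError("roi_preference must lie in [0, 1]")
        if self.step_mean is not None and self.step_mean <= 0:
            raise ValueError("step_mean must be positive")
        if self.duration_mean <= 0 or self.duration_shape <= 0:
            raise ValueError("duration parameters must be positive")
        if self.n_fixations < 1:
            raise ValueError("n_fixations must be >= 1")


@dataclass
class ScanPath:
    """Ordered fixations of one trial: positions in px, durations in ms."""

    x: np.ndarray
    y: np.ndarray
    duration_ms: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


def _roi_sampler(target_roi, rng: np.random.Generator):
    """Uniform sampler over one ROI or a weighted list of ROIs."""
    if isinstance(target_roi, (list, tuple)) and target_roi and isinstance(
        target_roi[0], (list, tuple)
    ):
        rois = [(np.asarray(getattr(r, "mask", r), bool), float(w)) for r, w in target_roi]
    else:
        rois = [(np.asarray(getattr(target_roi, "mask", target_roi), bool), 1.0)]
    pix = []
    weights = []
    for m, w in rois:
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise ValueError("target ROI is empty")
        pix.append((idx, m.shape[1]))
        weights.append(w)
    p = np.asarray(weights) / np.sum(weights)

    def sample() -> tuple[float, float]:
        idx, width = pix[rng.choice(len(pix), p=p)]
        lin = idx[rng.integers(idx.size)]
        return float(lin % width), float(lin // width)

    return sample


def generate_scanpath(
    shape: SyntheticShape | np.ndarray,
    target_roi,
    cfg: ScanPathConfig,
    geometry: ViewingGeometry = DEFAULT_GEOMETRY,
    rng: np.random.Generator | None = None,
    null_map: np.ndarray | None = None,
) -> ScanPath:
    """One synthetic scanpath over a stimulus.

    The first fixation is always pinned to the frame centre (mimicking central
    fixation at trial onset, and exercising the pipeline's first-fixation
    discard); all fixations lie inside the frame.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h = w = geometry.frame_px
    obj_mask = np.asarray(getattr(shape, "mask", shape), bool)
    n = cfg.n_fixations
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = (w - 1) / 2, (h - 1) / 2

    if cfg.step_mean is not None:
        scale_px = geometry.deg_to_px(cfg.step_mean) / cfg.step_shape
        for i in range(1, n):
            while True:
                step = rng.gamma(cfg.step_shape, scale_px)
                for _ in range(200):
                    th = rng.uniform(0, 2 * np.pi)
                    nx = xs[i - 1] + step * np.cos(th)
                    ny = ys[i - 1] + step * np.sin(th)
                    if 0 <= nx <= w - 1 and 0 <= ny <= h - 1:
                        break
                else:
                    continue  # no direction fits this length: redraw length
                break
            xs[i], ys[i] = nx, ny
    else:
        roi_sample = _roi_sampler(target_roi, rng) if cfg.roi_preference > 0 else None
        if cfg.null_density == "uniform_frame":
            def null_sample():
                return rng.uniform(0, w - 1), rng.uniform(0, h - 1)
        elif cfg.null_density == "uniform_object":
            idx = np.flatnonzero(obj_mask)
            if idx.size == 0:
                raise ValueError("object mask is empty")
            def null_sample():
                lin = idx[rng.integers(idx.size)]
                return float(lin % w), float(lin // w)
        elif cfg.null_density in ("saliency", "custom"):
            if null_map is None:
                raise ValueError(f"null_density={cfg.null_density!r} requires null_map")
            flat = np.asarray(null_map, float).ravel()
            if flat.sum() <= 0:
                raise ValueError("null_map has zero mass")
            cum = np.cumsum(flat / flat.sum())
            def null_sample():
                lin = int(np.searchsorted(cum, rng.random()))
                return float(lin % w), float(lin // w)
        else:
            raise ValueError(f"unknown null_density {cfg.null_density!r}")
        for i in range(1, n):
            if roi_sample is not None and rng.random() < cfg.roi_preference:
                xs[i], ys[i] = roi_sample()
            else:
                xs[i], ys[i] = null_sample()

    durations = rng.gamma(cfg.duration_shape, cfg.duration_mean / cfg.duration_shape, n)
    return ScanPath(x=xs, y=ys, duration_ms=durations)


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One between-subjects task group and its scanpath statistics."""

    name: str
    n_participants: int
    config: ScanPathConfig
    target_model: str | None = None  # which ROI model fixations prefer


@dataclass
class ExperimentDesign:
    groups: list[GroupSpec]
    n_trials: int = 10
    families: tuple[str, ...] = ("dumbbell", "elbow")
    metric_jitter: tuple[float, float] = (0.9, 1.2)
    stimuli: dict[str, SyntheticShape] | None = None  # prebuilt stimuli override
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)


def _build_stimuli(design: ExperimentDesign, ss: np.random.SeedSequence):
    if design.stimuli is not None:
        return dict(design.stimuli)
    seeds = ss.generate_state(len(design.families))
    return {
        f"{fam}_0": generate_shape(
            fam, design.metric_jitter, seed=int(s) % (2**31), frame_px=design.geometry.frame_px
        )
        for fam, s in zip(design.families, seeds)
    }


def simulate_experiment(
    design: ExperimentDesign, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, SyntheticShape], dict[str, dict[str, RoiMask]], dict]:
    """Generate a full two-group experiment in memory.

    Returns the fixation table (one row per fixation, schema
    ``participant,group,trial,stimulus,fix_index,x_px,y_px,duration_ms``),
    the stimuli, their ROI models (only built when some group targets one),
    and a manifest of the generating parameters.
    """
    ss = np.random.SeedSequence(seed)
    stim_ss, path_ss = ss.spawn(2)
    stimuli = _build_stimuli(design, stim_ss)
    stim_names = sorted(stimuli)

    need_models = any(g.target_model and g.config.roi_preference > 0 for g in design.groups)
    models: dict[str, dict[str, RoiMask]] = {}
    if need_models:
        models = {name: build_all_models(stimuli[name].silhouette) for name in stim_names}

    rows = []
    streams = iter(path_ss.spawn(sum(g.n_participants for g in design.groups)))
    for group in design.groups:
        for p in range(group.n_participants):
            participant = f"{group.name}{p + 1:02d}"
            rng = np.random.default_rng(next(streams))
            for trial in range(1, design.n_trials + 1):
                stim = stim_names[(trial - 1) % len(stim_names)]
                target = None
                if group.target_model and group.config.roi_preference > 0:
                    target = models[stim][group.target_model]
                path = generate_scanpath(
                    stimuli[stim], target, group.config, design.geometry, rng=rng
                )
                for k in range(len(path)):
                    rows.append(
                        (
                            participant,
                            group.name,
                            trial,
                            stim,
                            k + 1,
                            path.x[k],
                            path.y[k],
                            path.duration_ms[k],
                        )
                    )
    df = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    manifest = {
        "seed": seed,
        "n_trials": design.n_trials,
        "stimuli": ",".join(stim_names),
        "frame_px": design.geometry.frame_px,
        "frame_deg": design.geometry.frame_deg,
    }
    for g in design.groups:
        manifest[f"group.{g.name}"] = (
            f"n={g.n_participants} pi={g.config.roi_preference} "
            f"step_mean={g.config.step_mean} target={g.target_model}"
        )
    return df, stimuli, models, manifest


def generate_experiment(design: ExperimentDesign, outdir: str | Path, seed: int = 0) -> Path:
    """Write a complete synthetic dataset (stimulus PNGs + fixation CSV +
    manifest) under ``outdir``.  Partial outputs are removed on failure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        df, stimuli, _, manifest = simulate_experiment(design, seed)
        stim_dir = outdir / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        for name in sorted(stimuli):
            path = stim_dir / f"{name}.png"
            Image.fromarray(stimuli[name].mask.astype(np.uint8) * 255).save(path)
            created.append(path)
        csv_path = outdir / "fixations.csv"
        df.to_csv(csv_path, index=False, float_format="%.3f", lineterminator="\n")
        created.append(csv_path)
        man_path = outdir / "manifest.txt"
        man_path.write_text(
            "".join(f"{k}={v}\n" for k, v in manifest.items()), encoding="utf-8"
        )
        created.append(man_path)
        return outdir
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        if (outdir / "stimuli").exists() and not any((outdir / "stimuli").iterdir()):
            shutil.rmtree(outdir / "stimuli")
        raise
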