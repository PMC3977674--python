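"""Theoretical ROI models built from a silhouette.

Three region-of-interest models are derived from the bounding contour:

* **convex** / **concave** polarity masks — every contour sample whose
  absolute curvature exceeds a threshold contributes a filled disk whose
  radius grows linearly with |kappa| (saturating at ``kappa_sat``); disks are
  accumulated into separate masks by curvature sign.
* **part_boundary** — internal part boundaries found with the minima /
  short-cut rule: negative curvature minima are paired greedily by shortest
  interior chord, and each accepted chord is dilated into a band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from shapely.geometry import LineString, Point, Polygon
from skimage import draw

from .contour import CurvatureMap, Silhouette

__all__ = [
    "RoiMask",
    "PartCut",
    "PolarityParams",
    "build_polarity_masks",
    "detect_concavity_extrema",
    "compute_part_cuts",
    "build_part_boundary_mask",
]

ROI_LABELS = ("concave", "convex", "part_boundary", "custom")


@dataclass
class RoiMask:
    """Binary region-of-interest mask over the stimulus frame."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class PartCut:
    """A part-boundary chord joining two paired concavity extrema."""

    endpoints: np.ndarray  # (2, 2) array of (x, y) px
    length: float
    concavity_indices: tuple[int, int]


@dataclass(frozen=True)
class PolarityParams:
    """Disk-accumulation parameters for the curvature-polarity masks.

    Each qualifying sample (|kappa| >= ``kappa_min``) stamps a disk of radius

        r = r_min + (r_max - r_min) * min(|kappa| / kappa_sat, 1)

    so sharper curvature produces proportionally larger disks, clamped to
    [r_min, r_max].  Defaults are scaled for an 800 px frame.
    """

    kappa_min: float = 0.005
    r_min: float = 2.0
    r_max: float = 20.0
    kappa_sat: float = 0.05

    def __post_init__(self) -> None:
        if min(self.kappa_min, self.r_min, self.r_max, self.kappa_sat) <= 0:
            raise ValueError("all polarity parameters must be positive")
        if self.r_min > self.r_max:
            raise ValueError("r_min must not exceed r_max")

    def radius(self, kappa_abs: np.ndarray) -> np.ndarray:
        frac = np.minimum(kappa_abs / self.kappa_sat, 1.0)
        return self.r_min + (self.r_max - self.r_min) * frac


def build_polarity_masks(
    curvmap: CurvatureMap,
    silhouette: Silhouette | None = None,
    params: PolarityParams | None = None,
) -> tuple[RoiMask, RoiMask]:
    """Accumulate per-sample curvature disks into (concave, convex) ROI masks."""
    sil = silhouette or curvmap.silhouette
    params = params or PolarityParams()
    kappa = curvmap.kappa
    shape = sil.mask.shape
    masks = {s: np.zeros(shape, dtype=bool) for s in ("concave", "convex")}
    sel = np.abs(kappa) >= params.kappa_min
    radii = params.radius(np.abs(kappa[sel]))
    for (x, y), r, k in zip(sil.contour[sel], radii, kappa[sel]):
        rr, cc = draw.disk((y, x), r, shape=shape)
        masks["convex" if k > 0 else "concave"][rr, cc] = True
    return RoiMask(masks["concave"], "concave"), RoiMask(masks["convex"], "convex")


def detect_concavity_extrema(curvmap: CurvatureMap, prominence: float = 0.01) -> list[int]:
    """Indices of negative-curvature minima with at least the given prominence.

    Peaks are found on ``-kappa`` with periodic wrap-around handling; only
    minima with kappa < 0 qualify.  Indices are returned in contour order.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    kappa = curvmap.kappa
    n = len(kappa)
    tiled = np.tile(-kappa, 3)
    peaks, _ = find_peaks(tiled, prominence=prominence)
    middle = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    return sorted(int(i) for i in middle if kappa[i] < 0)


def _arc_lengths(i: int, j: int, n: int, ds: float) -> tuple[float, float]:
    steps = (j - i) % n
    return steps * ds, (n - steps) * ds


def compute_part_cuts(silhouette: Silhouette, extrema: list[int]) -> list[PartCut]:
    """Pair concavity extrema into part-boundary chords (minima / short-cut rule).

    All extremum pairs whose connecting chord lies inside the silhouette are
    enumerated; candidates are accepted greedily in order of increasing chord
    length (ties broken by lower contour index), each extremum used at most
    once.  A chord must be shorter than both boundary arcs it separates (the
    short-cut condition) and must traverse the interior rather than skim the
    boundary: its midpoint must lie at least a quarter of the chord length
    away from the contour, which rejects chords joining two concavities that
    share a nearly straight stretch of boundary.
    """
    if len(extrema) < 2:
        return []
    contour = silhouette.contour
    n, ds = silhouette.n_samples, silhouette.spacing
    # Tolerant point-in-polygon test: the rasterised mask and the traced
    # contour disagree by up to ~1 px, so test against a slightly grown hull.
    interior = Polygon(contour)
    poly = interior.buffer(1.0)
    candidates = []
    for a_pos, i in enumerate(extrema):
        for j in extrema[a_pos + 1 :]:
            p, q = contour[i], contour[j]
            length = float(np.hypot(*(p - q)))
            arc1, arc2 = _arc_lengths(i, j, n, ds)
            if length >= min(arc1, arc2):
                continue
            if not poly.covers(LineString([p, q])):
                continue
            mid = Point((p + q) / 2)
            if interior.exterior.distance(mid) < 0.25 * length:
                continue
            candidates.append((length, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    used: set[int] = set()
    cuts: list[PartCut] = []
    for length, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        cuts.append(
            PartCut(
                endpoints=np.vstack([contour[i], contour[j]]),
                length=length,
                concavity_indices=(i, j),
            )
        )
    return cuts


def build_part_boundary_mask(
    silhouette: Silhouette, cuts: list[PartCut], band_px: float = 8.0
) -> RoiMask:
    """Union of flat-capped bands of half-width ``band_px`` around each cut,
    clipped to the silhouette interior."""
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    shape = silhouette.mask.shape
    out = np.zeros(shape, dtype=bool)
    for cut in cuts:
        band = LineString(cut.endpoints).buffer(band_px, cap_style="flat")
        for geom in getattr(band, "geoms", [band]):
            xy = np.asarray(geom.exterior.coords)
            rr, cc = draw.polygon(xy[:, 1], xy[:, 0], shape=shape)
            out[rr, cc] = True
    out &= silhouette.mask
    return RoiMask(out, "part_boundary")


def build_all_models(
    silhouette: Silhouette,
    smoothing_sigma: float = 15.0,
    polarity: PolarityParams | None = None,
    prominence: float = 0.01,
    band_px: float = 8.0,
) -> dict[str, RoiMask]:
    """Convenience: the three ROI models for one silhouette, keyed by label."""
    from .contour import compute_curvature

    curv = compute_curvature(silhouette, smoothing_sigma)
    concave, convex = build_polarity_masks(curv, silhouette, polarity)
    extrema = detect_concavity_extrema(curv, prominence)
    cuts = compute_part_cuts(silhouette, extrema)
    part = build_part_boundary_mask(silhouette, cuts, band_px)
    return {"concave": concave, "convex": convex, "part_boundary": part}
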