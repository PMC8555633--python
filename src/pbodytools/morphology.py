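"""Condensate morphology, shape relaxation, particle tracking and fusion.

Segmentation uses a global automatic (Otsu) threshold after optional
rolling-ball background subtraction, followed by connected-component
labelling.  Shape descriptors follow the standard particle-analysis
definitions: aspect ratio is the major/minor axis ratio of the
moment-equivalent ellipse, and circularity is 4π·area/perimeter² (1 for a
perfect circle).  The perimeter uses a Crofton-style multi-direction
estimator, since naive boundary-pixel counting overestimates circular
perimeters by 5-10%.

Shape relaxation of an elongated condensate toward a sphere is summarized by
fitting AR(t) = 1 + (AR0 − 1)·exp(−t/τs).  Particle tracking is a simple
linear (greedy nearest-neighbour) frame-to-frame linker with a maximum
linking distance and no gap closing or merge/split handling; per-track total
displacements are compared between conditions with Wilcoxon tests.  Fusion
events are summarized by the scaled fusion time: the relaxation time constant
of the deformation signal divided by condensate radius, a size-independent
viscosity proxy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball


class FitError(RuntimeError):
    """A shape-relaxation or fusion fit failed."""


@dataclass(frozen=True)
class LabeledRegion:
    """A segmented 2-D particle with shape descriptors (physical units)."""

    label: int
    area: float          # μm²
    perimeter: float     # μm (Crofton estimator)
    centroid: tuple[float, float]   # (y, x) μm
    major_axis: float    # μm, from second central moments
    minor_axis: float    # μm
    n_pixels: int
    pixel_size: float    # μm / pixel

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("region area must be positive")
        if not self.major_axis >= self.minor_axis:
            raise ValueError("major axis must be >= minor axis")


def segment(
    image: np.ndarray,
    pixel_size: float = 1.0,
    min_area: float = 0.0,
    threshold: float | None = None,
    subtract_background: bool = False,
    background_radius: float = 50.0,
) -> list[LabeledRegion]:
    """Threshold a grayscale frame and return labelled particles.

    ``min_area`` is in μm².  ``threshold=None`` uses Otsu's global automatic
    threshold; a blank (constant) image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment expects a single 2-D grayscale frame")
    if subtract_background:
        img = img - rolling_ball(img, radius=background_radius)
    if threshold is None:
        if np.ptp(img) == 0:
            return []
        threshold = threshold_otsu(img)
    mask = img > threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        area = rp.area * pixel_size**2
        if area < min_area:
            continue
        out.append(
            LabeledRegion(
                label=int(rp.label),
                area=float(area),
                perimeter=float(rp.perimeter_crofton * pixel_size),
                centroid=(float(rp.centroid[0] * pixel_size), float(rp.centroid[1] * pixel_size)),
                major_axis=float(rp.axis_major_length * pixel_size),
                minor_axis=float(rp.axis_minor_length * pixel_size),
                n_pixels=int(rp.area),
                pixel_size=float(pixel_size),
            )
        )
    return out


def aspect_ratio(region: LabeledRegion) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (≥ 1)."""
    if region.n_pixels < 2 or region.minor_axis <= 0:
        raise ValueError("aspect ratio undefined for a degenerate region")
    return region.major_axis / region.minor_axis


def circularity(area: float, perimeter: float) -> float:
    """Circularity 4π·area/perimeter² (1 for a perfect circle)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def region_circularity(region: LabeledRegion) -> float:
    return circularity(region.area, region.perimeter)


# ---------------------------------------------------------------------------
# shape relaxation


@dataclass(frozen=True)
class RelaxationFit:
    tau: float        # relaxation time, units of the input times
    ar0: float        # initial aspect ratio
    unidentifiable: bool  # flat series at AR ~ 1: tau carries no information


def relaxation_fit(time: np.ndarray, ar: np.ndarray) -> RelaxationFit:
    """Fit AR(t) = 1 + (AR0 − 1)·exp(−t/τs) by least squares."""
    t = np.asarray(time, float)
    y = np.asarray(ar, float)
    if len(t) < 4:
        raise ValueError("relaxation fit needs at least 4 time points")
    if np.any(y < 1.0 - 1e-9):
        raise ValueError("aspect ratios must be >= 1")
    span = float(t[-1] - t[0])
    if np.allclose(y, 1.0, atol=1e-3):
        return RelaxationFit(tau=float("nan"), ar0=float(np.mean(y)), unidentifiable=True)

    def model(tt, tau, ar0):
        return 1.0 + (ar0 - 1.0) * np.exp(-tt / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t - t[0], y,
                p0=[max(span / 3.0, 1e-6), max(float(y[0]), 1.0 + 1e-6)],
                bounds=([1e-9, 1.0], [np.inf, np.inf]), maxfev=20000,
            )
    except (RuntimeError, ValueError) as err:
        raise FitError(f"relaxation fit did not converge: {err}") from err
    return RelaxationFit(tau=float(popt[0]), ar0=float(popt[1]), unidentifiable=False)


# ---------------------------------------------------------------------------
# tracking


@dataclass
class Track:
    """Linked particle positions over frames."""

    frames: list[int] = field(default_factory=list)
    points: list[tuple[float, float]] = field(default_factory=list)

    def append(self, frame: int, point: tuple[float, float]) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(int(frame))
        self.points.append((float(point[0]), float(point[1])))

    @property
    def total_displacement(self) -> float:
        """Total path length (sum of consecutive step lengths)."""
        pts = np.asarray(self.points)
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    @property
    def net_displacement(self) -> float:
        pts = np.asarray(self.points)
        if len(pts) < 2:
            return 0.0
        return float(np.linalg.norm(pts[-1] - pts[0]))


def link_tracks(detections: list[np.ndarray], max_disp: float) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking (simple linear tracker).

    ``detections[f]`` is an (n_f, 2) array of centroids in frame f.  Pairs are
    linked in order of increasing distance; links longer than ``max_disp`` are
    forbidden; unmatched detections start new tracks.  No gap closing, no
    merge/split handling.
    """
    tracks: list[Track] = []
    active: list[Track] = []
    for f, pts in enumerate(detections):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        assigned = [False] * len(pts)
        new_active: list[Track] = []
        if active and len(pts):
            prev = np.asarray([tr.points[-1] for tr in active])
            dist = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
            dist = np.where(dist <= max_disp, dist, np.inf)
            used_tracks = [False] * len(active)
            order = np.argsort(dist, axis=None)
            for flat in order:
                i, j = divmod(int(flat), len(pts))
                if not np.isfinite(dist[i, j]):
                    break
                if used_tracks[i] or assigned[j]:
                    continue
                active[i].append(f, tuple(pts[j]))
                used_tracks[i] = True
                assigned[j] = True
                new_active.append(active[i])
        for j, pt in enumerate(pts):
            if not assigned[j]:
                tr = Track()
                tr.append(f, tuple(pt))
                tracks.append(tr)
                new_active.append(tr)
        active = new_active
    # tracks that were started mid-stream are already in `tracks`; ensure all
    # tracks opened in frame 0 are included exactly once
    return tracks


def displacement_compare(
    tracks_a: list[Track], tracks_b: list[Track], paired: bool = False
) -> tuple[float, float]:
    """Compare per-track total displacements between two conditions.

    Paired: Wilcoxon signed-rank test (zero differences dropped, standard
    convention; all-zero differences return statistic 0, p = 1).  The
    reported paired statistic is the signed rank sum of (b − a), so swapping
    the condition labels flips its sign.  Unpaired: Mann-Whitney rank-sum
    test, reporting the U statistic.  Returns (statistic, p_value).
    """
    a = np.asarray([t.total_displacement for t in tracks_a], dtype=float)
    b = np.asarray([t.total_displacement for t in tracks_b], dtype=float)
    if min(len(a), len(b)) < 5:
        warnings.warn("fewer than 5 tracks per condition: test is underpowered")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal numbers of tracks")
        diff = b - a
        nz = diff[diff != 0]
        if len(nz) == 0:
            return 0.0, 1.0
        ranks = stats.rankdata(np.abs(nz))
        signed_rank_sum = float(np.sum(np.sign(nz) * ranks))
        pvalue = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        return signed_rank_sum, pvalue
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# fusion


@dataclass(frozen=True)
class FusionTrace:
    """Deformation signal of a condensate fusion event.

    The signal is normalized to 1 at contact and decays to 0 once the pair
    has merged into a sphere; ``radius`` is the condensate radius in μm.
    """

    time: np.ndarray     # s
    signal: np.ndarray   # dimensionless in [0, 1.5]
    radius: float        # μm

    def __post_init__(self):
        t = np.asarray(self.time, float)
        s = np.asarray(self.signal, float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.any(s < 0) or np.any(s > 1.5):
            raise ValueError("deformation signal must lie in [0, 1.5]")


def fusion_time_constant(trace: FusionTrace) -> float:
    """Relaxation time constant τf from fitting signal(t) = exp(−t/τf).

    Raises :class:`FitError` for non-decaying signals (e.g. aggregated
    condensates whose fusion never completes).
    """
    t = trace.time - trace.time[0]
    s = trace.signal
    slope = np.polyfit(t, s, 1)[0]
    if slope >= 0 or s[-1] >= 0.9 * max(s[0], 1e-12):
        raise FitError("deformation signal does not decay: fusion not quantifiable")

    def model(tt, tau):
        return np.exp(-tt / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, s, p0=[max(float(t[-1]) / 3.0, 1e-9)],
                bounds=([1e-12], [np.inf]), maxfev=20000,
            )
    except (RuntimeError, ValueError) as err:
        raise FitError(f"fusion fit did not converge: {err}") from err
    return float(popt[0])


def scaled_fusion_time(trace: FusionTrace) -> float:
    """Relaxation time constant divided by condensate radius (s/μm)."""
    return fusion_time_constant(trace) / trace.radius


def roi_mean_intensity(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean intensity of a fixed ROI mask over the frames of a stack."""
    stack = np.asarray(stack, float)
    mask = np.asarray(mask, bool)
    if stack.ndim != 3 or mask.shape != stack.shape[1:]:
        raise ValueError("stack must be (T, H, W) with a matching 2-D mask")
    return stack[:, mask].mean(axis=1)
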