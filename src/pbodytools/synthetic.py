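"""Seeded synthetic-data generators for every pipeline stage.

Each generator emits data with the statistical structure its consuming module
assumes — single-exponential FRAP recoveries with Gaussian noise, time-lapse
stacks of an ellipse relaxing to a circle, proteome disorder tables with an
enriched subset, random-walk particle detections, and exponential fusion
traces — together with a machine-readable ground-truth table.  All noise is
independent Gaussian; every generator is bit-reproducible given (preset,
seed).  Preset parameter values are emulation parameters chosen to mirror the
qualitative experimental contrasts (arrested oocyte P bodies vs dynamic
embryo P bodies, hexanediol-fluidized condensates, actin-released particles,
aggregates that never fuse); where a preset encodes a measured quantity it
is the mobile fraction (0.15 oocyte, 0.57 embryo) and the oocyte recovery
time constant implied by a 62.79 s half-time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .disorder import ProteomeTable, fraction_disordered
from .frap import LN2, RecoveryCurve, recovery_model
from .morphology import FusionTrace


@dataclass(frozen=True)
class FrapPreset:
    name: str
    P: float
    tau: float      # s
    y0: float
    noise_sd: float = 0.02
    n_points: int = 60
    span: float = 600.0  # s

    @property
    def mobile_fraction(self) -> float:
        return self.P / (1.0 - self.y0)


# Mobile fractions 0.15 (mature oocyte) and 0.57 (early embryo); the oocyte
# time constant 62.79 / ln 2 ≈ 90.59 s reproduces the measured half-time.
# Hexanediol-treated condensates recover rapidly to ~60%.
FRAP_PRESETS = {
    "oocyte": FrapPreset("oocyte", P=0.15 * 0.8, tau=62.79 / LN2, y0=0.2),
    "embryo": FrapPreset("embryo", P=0.57 * 0.8, tau=30.0, y0=0.2),
    "1,6-HD": FrapPreset("1,6-HD", P=0.60 * 0.9, tau=45.0, y0=0.1),
    # fit-validation conditions (large amplitude, tau well inside the span)
    "reference": FrapPreset("reference", P=0.5, tau=60.0, y0=0.1),
}


def gen_frap_curves(
    preset: FrapPreset | str, n_curves: int, seed: int
) -> tuple[list[RecoveryCurve], pd.DataFrame]:
    """Noisy single-exponential recovery curves plus their ground truth."""
    if isinstance(preset, str):
        preset = FRAP_PRESETS[preset]
    if preset.noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, preset.span, preset.n_points)
    curves, rows = [], []
    for i in range(n_curves):
        clean = recovery_model(t, preset.P, preset.tau, preset.y0)
        noisy = np.clip(clean + rng.normal(0.0, preset.noise_sd, size=t.shape), 0.0, None)
        curves.append(RecoveryCurve(t.copy(), noisy))
        rows.append(
            {
                "curve": i, "P": preset.P, "tau": preset.tau, "y0": preset.y0,
                "mobile_fraction": preset.mobile_fraction, "noise_sd": preset.noise_sd,
            }
        )
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condensate relaxation stacks


@dataclass(frozen=True)
class StackPreset:
    name: str
    n_frames: int = 20
    frame_interval: float = 2.0   # min
    tau_relax: float = 10.0       # min: AR(t) = 1 + 2 exp(-t/tau)
    ar0: float = 3.0
    area_px: float = 1200.0       # constant condensate area in pixels
    shape: tuple[int, int] = (128, 128)
    noise_sd: float = 0.0
    n_condensates: int = 1


STACK_PRESETS = {
    "relaxation": StackPreset("relaxation"),
    "relaxation-noisy": StackPreset("relaxation-noisy", noise_sd=0.05),
    "blank": StackPreset("blank", n_condensates=0),
}


def gen_condensate_stack(
    preset: StackPreset | str, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Time-lapse of ellipses relaxing from AR0 to a circle at constant area.

    Returns a float stack (T, H, W) in [0, 1] plus ground truth (frame, time,
    centroid, aspect ratio, semi-axes in pixels).
    """
    if isinstance(preset, str):
        preset = STACK_PRESETS[preset]
    rng = np.random.default_rng(seed)
    T, (H, W) = preset.n_frames, preset.shape
    stack = np.zeros((T, H, W), dtype=float)
    rows = []
    centers = []
    for k in range(preset.n_condensates):
        cy = H / 2 + (k - (preset.n_condensates - 1) / 2) * H / max(preset.n_condensates, 1) * 0.6
        centers.append((cy, W / 2))
    for f in range(T):
        t = f * preset.frame_interval
        ar = 1.0 + (preset.ar0 - 1.0) * math.exp(-t / preset.tau_relax)
        # a·b·π = area with a/b = ar
        b = math.sqrt(preset.area_px / (math.pi * ar))
        a = ar * b
        for k, (cy, cx) in enumerate(centers):
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(H, W), rotation=0.0)
            stack[f, rr, cc] = 1.0
            rows.append(
                {
                    "frame": f, "time": t, "condensate": k, "cy": cy, "cx": cx,
                    "aspect_ratio": ar, "semi_major_px": a, "semi_minor_px": b,
                }
            )
        if preset.noise_sd > 0:
            stack[f] += rng.normal(0.0, preset.noise_sd, size=(H, W))
    return stack, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteome tables


@dataclass(frozen=True)
class ProteomePreset:
    name: str
    n_proteins: int = 2000
    set_size: int = 17
    background_beta: tuple[float, float] = (2.0, 6.0)   # mean 0.25
    subset_beta: tuple[float, float] = (6.0, 6.0)       # mean 0.50
    length_range: tuple[int, int] = (100, 1000)
    min_idr_len: int = 25


PROTEOME_PRESETS = {
    "enriched": ProteomePreset("enriched"),
    "null": ProteomePreset("null", subset_beta=(2.0, 6.0)),  # zero effect
}


def gen_proteome(
    preset: ProteomePreset | str, seed: int
) -> tuple[ProteomeTable, list[str]]:
    """A proteome disorder table with an optionally enriched subset.

    Background fractions are Beta-distributed; the subset's fractions come
    from a shifted Beta.  One IDR interval per protein is synthesized so that
    interval-derived fractions reproduce the drawn ones up to rounding (and
    the ≥ min_idr_len floor for very short targets).
    """
    if isinstance(preset, str):
        preset = PROTEOME_PRESETS[preset]
    rng = np.random.default_rng(seed)
    n = preset.n_proteins
    lengths = rng.integers(preset.length_range[0], preset.length_range[1] + 1, size=n)
    frac = rng.beta(*preset.background_beta, size=n)
    subset_rows = rng.choice(n, size=preset.set_size, replace=False)
    frac[subset_rows] = rng.beta(*preset.subset_beta, size=preset.set_size)
    rows, ivmap = [], {}
    for i in range(n):
        pid = f"P{i:05d}"
        L = int(lengths[i])
        n_idr = int(round(frac[i] * L))
        if 0 < n_idr < preset.min_idr_len:
            n_idr = 0  # below the calling floor: no reportable IDR
        ivs = [(1, n_idr)] if n_idr else []
        ivmap[pid] = ivs
        rows.append(
            {
                "protein_id": pid,
                "length": L,
                "fraction_disordered": fraction_disordered(ivs, L),
            }
        )
    table = ProteomeTable(pd.DataFrame(rows), ivmap)
    protein_set = [f"P{i:05d}" for i in sorted(subset_rows)]
    return table, protein_set


# ---------------------------------------------------------------------------
# particle tracks


@dataclass(frozen=True)
class TrackPreset:
    name: str
    n_particles: int = 20
    n_frames: int = 30
    step_sd: float = 0.1          # μm per frame per axis
    spacing: float = 10.0         # μm between initial positions
    guaranteed_separation: bool = False
    max_disp: float = 2.0         # μm, the intended linking distance


# Cytochalasin-D-released particles move ~3x more than anchored controls.
TRACK_PRESETS = {
    "control": TrackPreset("control", step_sd=0.1),
    "cytochalasin-D": TrackPreset("cytochalasin-D", step_sd=0.3),
    "separated": TrackPreset(
        "separated", step_sd=0.3, spacing=10.0, guaranteed_separation=True
    ),
}


def gen_tracks(
    preset: TrackPreset | str, seed: int
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Random-walk detections per frame plus ground-truth correspondence.

    With ``guaranteed_separation``, particles start on a grid with spacing
    > 2·max_disp and steps are clipped below max_disp/2, so greedy
    nearest-neighbour linking provably recovers the true correspondence.
    """
    if isinstance(preset, str):
        preset = TRACK_PRESETS[preset]
    rng = np.random.default_rng(seed)
    n = preset.n_particles
    side = math.ceil(math.sqrt(n))
    spacing = preset.spacing
    if preset.guaranteed_separation:
        spacing = max(spacing, 2.0 * preset.max_disp + 1.0)
    starts = np.array(
        [[(i % side) * spacing, (i // side) * spacing] for i in range(n)], dtype=float
    )
    pos = starts.copy()
    detections, rows = [], []
    for f in range(preset.n_frames):
        if f > 0:
            steps = rng.normal(0.0, preset.step_sd, size=(n, 2))
            if preset.guaranteed_separation:
                lim = 0.45 * preset.max_disp / math.sqrt(2.0)
                steps = np.clip(steps, -lim, lim)
            pos = pos + steps
        detections.append(pos.copy())
        for p in range(n):
            rows.append({"frame": f, "particle": p, "x": pos[p, 0], "y": pos[p, 1]})
    return detections, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fusion traces


@dataclass(frozen=True)
class FusionPreset:
    name: str
    scaled_time: float = 1.0      # s/μm: tau_f = scaled_time * radius
    radii: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    n_points: int = 40
    span_factor: float = 6.0      # trace length in units of tau_f
    noise_sd: float = 0.0
    decaying: bool = True


FUSION_PRESETS = {
    "wildtype": FusionPreset("wildtype"),
    "wildtype-noisy": FusionPreset("wildtype-noisy", noise_sd=0.03),
    "aggregate": FusionPreset("aggregate", decaying=False),
}


def gen_fusion_traces(
    preset: FusionPreset | str, seed: int
) -> tuple[list[FusionTrace], pd.DataFrame]:
    """Exponential fusion deformation decays with radius-scaled time constants.

    The "aggregate" preset emits non-decaying signals (aggregated condensates
    whose fusion never completes), on which the fusion fit must fail.
    """
    if isinstance(preset, str):
        preset = FUSION_PRESETS[preset]
    rng = np.random.default_rng(seed)
    traces, rows = [], []
    for i, r in enumerate(preset.radii):
        tau_f = preset.scaled_time * r
        t = np.linspace(0.0, preset.span_factor * tau_f, preset.n_points)
        if preset.decaying:
            clean = np.exp(-t / tau_f)
        else:
            clean = np.full_like(t, 1.0)
        sig = np.clip(clean + rng.normal(0.0, preset.noise_sd, size=t.shape), 0.0, 1.5)
        traces.append(FusionTrace(t, sig, r))
        rows.append(
            {
                "trace": i, "radius": r, "tau_f": tau_f if preset.decaying else np.nan,
                "scaled_time": preset.scaled_time if preset.decaying else np.nan,
                "decaying": preset.decaying,
            }
        )
    return traces, pd.DataFrame(rows)
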