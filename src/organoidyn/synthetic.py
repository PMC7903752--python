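"""Seeded generators for every input shape the analysis modules consume.

Real inputs to this package are segmentation outputs (projected-area tables,
cell-count curves, centroid clouds).  The generators here emulate those
shapes with known ground truth attached, so every analysis operation can be
exercised as a round trip: the generator injects a feature, the analysis must
recover it.  All generators are deterministic for a fixed seed.

Trace generators build organoid area series as piecewise-linear excursions
around a linear growth trend: at each injected oscillation event the area
drops by a fixed fraction in one frame and then recovers linearly back to the
trend, so each recovery is an exactly linear expansion phase and the final
area is independent of how many events were injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AreaTrace
from .mechanics import fibonacci_sphere
from .morphometry import CentroidSet
from .scaling import GrowthCurve

FRAME_INTERVAL_H = 0.5   # 30-min acquisition interval


@dataclass(frozen=True)
class FixtureSpec:
    """A named synthetic-input recipe: kind, parameters and seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = ("sawtooth_trace", "growth_curve", "shell_cloud", "well_ensemble")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def generate(spec: FixtureSpec):
    """Dispatch a FixtureSpec to the matching generator."""
    maker = {
        "sawtooth_trace": make_sawtooth_trace,
        "growth_curve": make_growth_curve,
        "shell_cloud": make_shell_cloud,
        "well_ensemble": make_well_ensemble,
    }[spec.kind]
    return maker(seed=spec.seed, **spec.params)


# ---------------------------------------------------------------------------
# Area traces
# ---------------------------------------------------------------------------

def _inject_drops(
    trend: np.ndarray, drop_frames: list[int], drop_fraction: float
) -> np.ndarray:
    """Drop by ``drop_fraction`` at each given frame, then rejoin the trend.

    Between a drop and the frame before the next drop (or the trace end) the
    values interpolate linearly back to the trend, so each recovery segment
    is exactly collinear.
    """
    values = trend.copy()
    n = len(values)
    boundaries = [d - 1 for d in drop_frames[1:]] + [n - 1]
    for d, nxt in zip(drop_frames, boundaries):
        post = (1.0 - drop_fraction) * values[d - 1]
        ramp = np.linspace(post, trend[nxt], nxt - d + 1)
        values[d : nxt + 1] = ramp
    return values


def make_sawtooth_trace(
    n_events: int = 7,
    drop_fraction: float = 0.3,
    recovery_frames: int = 8,
    baseline_slope: float = 0.02,
    lead_frames: int = 8,
    tail_frames: int = 8,
    initial_area: float = 0.1,
    circularity_target: float | None = None,
    seed: int = 0,
    organoid_id: str = "org-1",
    well_id: str = "well-1",
) -> tuple[AreaTrace, dict]:
    """A noiseless oscillating trace with exactly ``n_events`` injected drops.

    Each drop exceeds the 5% decline threshold when ``drop_fraction > 0.05``
    and is followed by a linear recovery of ``recovery_frames`` frames, so the
    downstream event count equals ``n_events`` exactly.  ``baseline_slope`` is
    the relative growth of the underlying trend per hour.
    """
    if n_events < 0 or recovery_frames < 1:
        raise ValueError("n_events must be >= 0 and recovery_frames >= 1")
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    n_frames = lead_frames + n_events * (recovery_frames + 1) + tail_frames
    times = np.arange(n_frames) * FRAME_INTERVAL_H
    trend = initial_area * (1.0 + baseline_slope * times)
    drop_frames = [
        lead_frames + j * (recovery_frames + 1) for j in range(n_events)
    ]
    area = _inject_drops(trend, drop_frames, drop_fraction)
    perimeter = (
        np.sqrt(4.0 * math.pi * area / circularity_target)
        if circularity_target is not None
        else None
    )
    trace = AreaTrace(organoid_id, well_id, times, area, perimeter=perimeter)
    truth = {
        "n_events": n_events,
        "drop_frames": drop_frames,
        "drop_fraction": drop_fraction,
        "baseline_slope": baseline_slope,
        "seed": seed,
    }
    return trace, truth


def make_well_ensemble(
    n_organoids: int = 34,
    median_area: float = 0.017,
    area_sigma: float = 0.8,
    growth_per_hour: float = 0.104,
    heterogeneity: float = 1.0,
    event_scale: float = 0.015,
    max_events: int = 6,
    drop_fraction: float = 0.2,
    t_end: float = 48.0,
    circularity_target: float = 0.9,
    seed: int = 0,
    well_id: str = "well-1",
) -> tuple[list[AreaTrace], pd.DataFrame]:
    """A heterogeneous well of organoid traces with size-dependent oscillations.

    Initial areas are lognormal around ``median_area`` (mm²); each organoid
    grows linearly (about six-fold over 48 h at the default rate); smaller
    organoids receive more injected oscillation events (``event_scale`` mm²
    divided by the initial area, capped), emulating the observed tendency.
    With ``heterogeneity = 0`` all organoids are identical apart from event
    placement, and final areas coincide exactly because recoveries rejoin the
    growth trend.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(t_end / FRAME_INTERVAL_H)) + 1
    times = np.arange(n_frames) * FRAME_INTERVAL_H
    traces: list[AreaTrace] = []
    records = []
    for i in range(n_organoids):
        a0 = median_area * math.exp(area_sigma * heterogeneity * rng.standard_normal())
        growth = growth_per_hour * max(
            0.1, 1.0 + 0.2 * heterogeneity * rng.standard_normal()
        )
        k = min(max_events, int(round(event_scale / a0)))
        trend = a0 * (1.0 + growth * times)
        drop_frames = _spaced_drop_frames(n_frames, k, rng)
        area = _inject_drops(trend, drop_frames, drop_fraction)
        perimeter = np.sqrt(4.0 * math.pi * area / circularity_target)
        oid = f"org-{i + 1:03d}"
        traces.append(AreaTrace(oid, well_id, times, area, perimeter=perimeter))
        records.append(
            {
                "organoid_id": oid,
                "well_id": well_id,
                "initial_area": a0,
                "growth_per_hour": growth,
                "n_events": k,
                "final_area": float(trend[-1]),
            }
        )
    return traces, pd.DataFrame.from_records(records)


def _spaced_drop_frames(
    n_frames: int, k: int, rng: np.random.Generator
) -> list[int]:
    """k drop frames with gaps of at least 9 frames, away from both ends."""
    if k <= 0:
        return []
    first, last = 10, n_frames - 8
    spacing = (last - first) // k
    if spacing < 9:
        raise ValueError(f"cannot place {k} events in {n_frames} frames")
    frames = []
    for j in range(k):
        jitter = int(rng.integers(0, max(1, spacing - 8)))
        frames.append(first + j * spacing + jitter)
    return frames


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def make_growth_curve(
    mode: str = "piecewise_exp_linear",
    n0: float = 8.0,
    rate: float = 0.05,
    t_star: float = 60.0,
    slope: float = 4.0,
    noise_cv: float = 0.0,
    t_end: float = 144.0,
    dt_h: float = FRAME_INTERVAL_H,
    seed: int = 0,
) -> tuple[GrowthCurve, dict]:
    """Cell-count curve from the piecewise exponential--linear family.

    Modes: ``exponential`` (``n0*e^{rate*t}``), ``linear`` (``n0 + slope*t``)
    and ``piecewise_exp_linear`` (exponential until ``t_star``, continuous
    linear continuation with the given slope).  ``noise_cv`` applies
    multiplicative lognormal noise with that coefficient of variation.
    """
    times = np.arange(dt_h, t_end + dt_h / 2.0, dt_h)
    if mode == "exponential":
        values = n0 * np.exp(rate * times)
    elif mode == "linear":
        values = n0 + slope * times
    elif mode == "piecewise_exp_linear":
        c = n0 * math.exp(rate * t_star)
        values = np.where(
            times <= t_star,
            n0 * np.exp(rate * times),
            c + slope * (times - t_star),
        )
    else:
        raise ValueError(f"unknown growth mode {mode!r}")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        values = values * np.exp(sigma * rng.standard_normal(len(values)))
    truth = {
        "mode": mode, "n0": n0, "rate": rate, "t_star": t_star,
        "slope": slope, "noise_cv": noise_cv, "seed": seed,
    }
    return GrowthCurve(times, values, kind="count"), truth


# ---------------------------------------------------------------------------
# Centroid clouds
# ---------------------------------------------------------------------------

def make_shell_cloud(
    n: int = 200,
    radius: float = 100.0,
    jitter_sd: float = 2.0,
    fp_rate: float = 0.05,
    fn_rate: float = 0.05,
    displacement_sd: float = 1.0,
    seed: int = 0,
) -> tuple[CentroidSet, CentroidSet, dict]:
    """Ground-truth nuclei on a spherical shell plus a corrupted segmentation.

    The segmentation displaces every kept ground-truth point by an isotropic
    Gaussian of ``displacement_sd`` voxels, deletes points independently with
    probability ``fn_rate`` and adds spurious detections (a Binomial(n,
    ``fp_rate``) draw) deep inside the lumen, where they cannot shadow a
    shell point within the matching radius.
    """
    rng = np.random.default_rng(seed)
    gt_pts = fibonacci_sphere(n, radius) + jitter_sd * rng.standard_normal((n, 3))
    keep = rng.random(n) >= fn_rate
    seg_pts = gt_pts[keep] + displacement_sd * rng.standard_normal((keep.sum(), 3))
    n_fp = int(rng.binomial(n, fp_rate)) if fp_rate > 0 else 0
    if n_fp:
        direction = rng.standard_normal((n_fp, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radii = radius * 0.6 * rng.random(n_fp) ** (1.0 / 3.0)
        seg_pts = np.vstack([seg_pts, direction * radii[:, None]])
    truth = {
        "n_gt": n,
        "n_kept": int(keep.sum()),
        "n_fp": n_fp,
        "fn_rate": fn_rate,
        "fp_rate": fp_rate,
        "displacement_sd": displacement_sd,
        "seed": seed,
    }
    return CentroidSet(gt_pts), CentroidSet(seg_pts), truth
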