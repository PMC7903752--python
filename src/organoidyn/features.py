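"""Mesoscale feature extraction from projected-area time series.

Bright-field time lapses of organoid cultures yield, per organoid, a
projected luminal area trace sampled every 30 minutes (optionally with a
perimeter trace).  This module turns those traces into the quantitative
features used to characterise a culture:

* normalisation of a well's traces to the median fifth-time-point area,
* decline phases (a drop of more than 5% relative to the running local
  maximum, ending when the area rises again),
* expansion phases (intervals between declines, accepted when they span at
  least five time points and a linear fit correlates above 0.9),
* size-oscillation events (a decline immediately followed by an accepted
  expansion),
* average / maximum expansion factors (slopes of accepted expansions),
* circularity ``4*pi*area/perimeter**2`` with the 0.6 segmentation-quality
  exclusion, Tukey-fence outliers and per-well summaries compared by a
  Kruskal-Wallis test.

The first four frames of every trace cover organoid formation, where the
segmentation is unreliable; they are kept but excluded from phase detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import DomainError

logger = logging.getLogger(__name__)

DECLINE_FRACTION = 0.05        # "declines by 5%"
MIN_EXPANSION_FRAMES = 5       # "greater than or equal to five time points"
MIN_EXPANSION_R = 0.9          # "correlation coefficient ... above 0.9"
CIRCULARITY_EXCLUDE = 0.6      # below this the segmentation is deemed deficient
FORMATION_FRAMES = 4           # frames before the normalisation anchor
NORMALISATION_FRAME = 4        # zero-based index of the fifth time point


@dataclass(frozen=True)
class AreaTrace:
    """Projected-area time series of one organoid within one well."""

    organoid_id: str
    well_id: str
    times: np.ndarray              # hours
    area: np.ndarray               # mm² (or dimensionless once normalised)
    perimeter: np.ndarray | None = None   # mm
    area_raw: np.ndarray | None = None    # raw mm² kept through normalisation
    normalised: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and area must be 1-D arrays of equal length")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        finite = np.isfinite(a)
        if (a[finite] <= 0).any():
            raise ValueError("areas must be positive where present")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "area", a)
        if self.perimeter is not None:
            p = np.asarray(self.perimeter, dtype=float)
            if p.shape != t.shape:
                raise ValueError("perimeter must match times in length")
            object.__setattr__(self, "perimeter", p)
        if self.area_raw is not None:
            object.__setattr__(
                self, "area_raw", np.asarray(self.area_raw, dtype=float)
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Phase:
    """A contiguous decline or expansion interval of a trace."""

    kind: str                  # "decline" or "expansion"
    start: int                 # frame index (inclusive)
    end: int                   # frame index (inclusive)
    t_start: float
    t_end: float
    slope: float               # least-squares slope, per hour
    r: float | None = None     # Pearson r of the linear fit (expansions)

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    @property
    def duration_h(self) -> float:
        return self.t_end - self.t_start


@dataclass
class FeatureSet:
    """Per-organoid feature vector extracted from one area trace."""

    organoid_id: str
    well_id: str
    declines: list[Phase] = field(default_factory=list)
    expansions: list[Phase] = field(default_factory=list)
    events: list[tuple[Phase, Phase]] = field(default_factory=list)
    n_events: int = 0
    initial_area: float = math.nan
    final_area: float = math.nan
    min_area: float = math.nan
    max_area: float = math.nan
    avg_expansion: float | None = None
    max_expansion: float | None = None
    circularity: np.ndarray | None = None
    excluded: bool = False
    exclude_reason: str | None = None
    outlier: bool = False


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalise_well(traces: list[AreaTrace]) -> tuple[list[AreaTrace], float, list[str]]:
    """Normalise all traces of one well to the median fifth-time-point area.

    Returns the normalised traces, the divisor, and the ids of traces that
    were excluded for having fewer than five time points.
    """
    kept, excluded = [], []
    for tr in traces:
        if tr.n_frames <= NORMALISATION_FRAME:
            logger.warning(
                "trace %s excluded: %d frames (< 5) cannot be normalised",
                tr.organoid_id, tr.n_frames,
            )
            excluded.append(tr.organoid_id)
        else:
            kept.append(tr)
    if not kept:
        raise DomainError("no trace in the well has at least five time points")
    divisor = float(np.median([tr.area[NORMALISATION_FRAME] for tr in kept]))
    out = [
        replace(
            tr,
            area=tr.area / divisor,
            area_raw=tr.area if tr.area_raw is None else tr.area_raw,
            normalised=True,
        )
        for tr in kept
    ]
    return out, divisor, excluded


# ---------------------------------------------------------------------------
# Phase detection
# ---------------------------------------------------------------------------

def _fit_line(times: np.ndarray, values: np.ndarray) -> tuple[float, float | None]:
    """Slope per hour and Pearson r of a degree-1 fit (r None if degenerate)."""
    dt = times - times.mean()
    dv = values - values.mean()
    denom = float((dt * dt).sum())
    if denom == 0.0:  # single-frame phase at the trace end
        return 0.0, None
    slope = float((dt * dv).sum() / denom)
    if np.ptp(values) == 0 or np.ptp(times) == 0:
        return slope, None
    r = float(stats.pearsonr(times, values)[0])
    return slope, r


def detect_decline_phases(
    times: np.ndarray, area: np.ndarray, start_frame: int = 0
) -> list[Phase]:
    """Find all decline phases of a trace.

    A decline starts at the first frame whose area falls below 95% of the
    running maximum observed since the end of the previous phase, and ends at
    the first frame at which the area increases again (or at the last frame).
    """
    times = np.asarray(times, dtype=float)
    area = np.asarray(area, dtype=float)
    n = len(area)
    phases: list[Phase] = []
    if n - start_frame < 2:
        return phases
    ref = area[start_frame]
    i = start_frame + 1
    while i < n:
        ref = max(ref, area[i])
        if area[i] < (1.0 - DECLINE_FRACTION) * ref:
            j = i + 1
            while j < n and area[j] <= area[j - 1]:
                j += 1
            end = j if j < n else n - 1
            slope, _ = _fit_line(times[i : end + 1], area[i : end + 1])
            phases.append(
                Phase("decline", i, end, times[i], times[end], slope)
            )
            ref = area[end]
            i = end + 1
        else:
            i += 1
    return phases


def detect_expansion_phases(
    times: np.ndarray,
    area: np.ndarray,
    declines: list[Phase],
    start_frame: int = 0,
) -> list[Phase]:
    """Accepted expansion phases between consecutive declines.

    Candidates run from the end of a decline (the trace start counts as a
    virtual decline end) to the frame before the next decline starts, or to
    the trace end.  A candidate is accepted when it spans at least five time
    points and the Pearson correlation of its linear fit exceeds 0.9.
    """
    times = np.asarray(times, dtype=float)
    area = np.asarray(area, dtype=float)
    n = len(area)
    bounds: list[tuple[int, int]] = []
    prev_end = start_frame
    for ph in declines:
        bounds.append((prev_end, ph.start - 1))
        prev_end = ph.end
    bounds.append((prev_end, n - 1))

    accepted: list[Phase] = []
    for s, e in bounds:
        if e - s + 1 < MIN_EXPANSION_FRAMES:
            continue
        slope, r = _fit_line(times[s : e + 1], area[s : e + 1])
        if r is not None and r > MIN_EXPANSION_R:
            accepted.append(Phase("expansion", s, e, times[s], times[e], slope, r=r))
    return accepted


def oscillation_events(
    declines: list[Phase], expansions: list[Phase]
) -> list[tuple[Phase, Phase]]:
    """Pair each decline with the accepted expansion that starts at its end."""
    by_start = {exp.start: exp for exp in expansions}
    return [(d, by_start[d.end]) for d in declines if d.end in by_start]


def expansion_factors(
    expansions: list[Phase],
) -> tuple[float | None, float | None]:
    """Average and maximum slope over accepted expansion phases.

    Organoids without an accepted expansion get ``(None, None)`` and are
    excluded from culture medians rather than contributing zeros.
    """
    if not expansions:
        return None, None
    slopes = [p.slope for p in expansions]
    return float(np.mean(slopes)), float(np.max(slopes))


# ---------------------------------------------------------------------------
# Shape and outlier helpers
# ---------------------------------------------------------------------------

def circularity(area, perimeter):
    """Shape descriptor ``4*pi*area/perimeter**2`` (1 for a circle)."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if (perimeter <= 0).any():
        raise DomainError("perimeter must be positive")
    out = 4.0 * math.pi * area / perimeter**2
    return float(out) if out.ndim == 0 else out


def iqr_outliers(values) -> np.ndarray:
    """Tukey-fence mask: outside Q1 - 1.5*IQR .. Q3 + 1.5*IQR.

    Quartiles use linear interpolation so that the mask is reproducible.
    """
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def extract_features(trace: AreaTrace, start_frame: int | None = None) -> FeatureSet:
    """Full feature vector of one (normalised) trace.

    ``start_frame`` defaults to 4: the formation frames are kept in the trace
    but excluded from phase detection and summary areas.
    """
    if start_frame is None:
        start_frame = FORMATION_FRAMES
    fs = FeatureSet(trace.organoid_id, trace.well_id)
    area = trace.area
    analysed = area[start_frame:]
    if len(analysed) == 0:
        fs.excluded = True
        fs.exclude_reason = "trace shorter than the formation window"
        return fs
    fs.initial_area = float(analysed[0])
    fs.final_area = float(analysed[-1])
    fs.min_area = float(analysed.min())
    fs.max_area = float(analysed.max())

    fs.declines = detect_decline_phases(trace.times, area, start_frame)
    fs.expansions = detect_expansion_phases(trace.times, area, fs.declines, start_frame)
    fs.events = oscillation_events(fs.declines, fs.expansions)
    fs.n_events = len(fs.events)
    fs.avg_expansion, fs.max_expansion = expansion_factors(fs.expansions)

    if trace.perimeter is not None:
        raw = trace.area_raw if trace.area_raw is not None else trace.area
        fs.circularity = circularity(raw, trace.perimeter)
        if (fs.circularity < CIRCULARITY_EXCLUDE).any():
            fs.excluded = True
            fs.exclude_reason = (
                f"circularity below {CIRCULARITY_EXCLUDE} (deficient segmentation)"
            )
    return fs


def analyse_well(traces: list[AreaTrace]) -> list[FeatureSet]:
    """Normalise one well's traces, extract features, flag expansion outliers."""
    normalised, _, _ = normalise_well(traces)
    sets = [extract_features(tr) for tr in normalised]
    usable = [
        fs for fs in sets if not fs.excluded and fs.avg_expansion is not None
    ]
    if len(usable) >= 4:
        mask = iqr_outliers([fs.avg_expansion for fs in usable])
        for fs, is_out in zip(usable, mask):
            fs.outlier = bool(is_out)
    return sets


@dataclass(frozen=True)
class WellSummary:
    well_id: str
    n_organoids: int
    median_final_area: float
    iqr_final_area: tuple[float, float]
    median_avg_expansion: float | None
    iqr_avg_expansion: tuple[float, float] | None


@dataclass(frozen=True)
class CultureSummary:
    wells: list[WellSummary]
    kruskal_h: float | None
    kruskal_p: float | None
    message: str | None = None


def culture_summary(feature_sets: list[FeatureSet]) -> CultureSummary:
    """Per-well medians/IQRs and a Kruskal-Wallis comparison across wells.

    The test is run on the normalised final areas.  With a single well the
    comparison is skipped; if every observation is identical across wells the
    tie-corrected statistic is reported as H = 0, p = 1.
    """
    by_well: dict[str, list[FeatureSet]] = {}
    for fs in feature_sets:
        if not fs.excluded:
            by_well.setdefault(fs.well_id, []).append(fs)
    summaries = []
    samples = []
    for well_id in sorted(by_well):
        group = by_well[well_id]
        finals = np.array([fs.final_area for fs in group])
        expansions = [
            fs.avg_expansion for fs in group if fs.avg_expansion is not None
        ]
        q1, q3 = np.percentile(finals, [25, 75], method="linear")
        if expansions:
            e1, e3 = np.percentile(expansions, [25, 75], method="linear")
            med_e, iqr_e = float(np.median(expansions)), (float(e1), float(e3))
        else:
            med_e, iqr_e = None, None
        summaries.append(
            WellSummary(
                well_id, len(group), float(np.median(finals)),
                (float(q1), float(q3)), med_e, iqr_e,
            )
        )
        samples.append(finals)
    if len(samples) < 2:
        return CultureSummary(
            summaries, None, None,
            message="single well: cross-well comparison skipped",
        )
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # every observation identical: no rank variation, nothing to detect
        return CultureSummary(summaries, 0.0, 1.0)
    h, p = stats.kruskal(*samples)
    return CultureSummary(summaries, float(h), float(p))
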