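"""Trace analysis pipeline: contour conversion, pauses, slips, velocities.

The analysis mirrors standard optical-tweezer practice for fast DNA
translocases:

1. convert (extension, force) samples to contour length by inverting the
   worm-like-chain relation per sample;
2. detect pauses with an information-criterion-penalized changepoint search
   on the contour series (piecewise-linear segments; a segment whose speed
   falls below a threshold for long enough is a pause);
3. excise pauses and measure the pause-free velocity by a straight-line fit
   of contour vs time, per 2-pN force window in passive mode;
4. correct pause counts and mean durations for pauses shorter than the
   detection threshold using the censored-exponential maximum-likelihood
   estimator;
5. detect slips as abrupt contour increases and compute slip densities;
6. pool per-window velocities across near-saturating [ATP] cells and re-bin
   them into the canonical force intervals (consolidated curve).

Pause density is reported per kbp of pause-free translocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import BP_RISE_NM, DEFAULT_SCALE, ThermalScale
from .model_fitting import CANONICAL_FORCE_BIN_EDGES, VelocityPoint
from .synthetic_data import Trace, wlc_relative_extension

__all__ = [
    "SegmentedFit",
    "PauseEvent",
    "SlipEvent",
    "PauseStats",
    "extension_to_contour",
    "detect_pauses",
    "pause_free_velocity",
    "correct_pause_stats",
    "detect_slips",
    "slip_density",
    "consolidate_force_velocity",
    "detection_threshold",
]

log = logging.getLogger(__name__)


def detection_threshold(atp: float) -> float:
    """Minimum reliably detectable pause duration (s) at a given [ATP] (μM).

    50 ms at 0.5 mM ATP and below, 30 ms above: at low [ATP] the baseline
    velocity is slower, so longer pauses are needed to stand out of the
    noise.
    """
    return 0.050 if atp <= 500.0 else 0.030


@dataclass(frozen=True)
class PauseEvent:
    start: float      # s
    duration: float   # s
    force: float      # pN, mean over the pause


@dataclass(frozen=True)
class SlipEvent:
    time: float          # s
    released_bp: float   # contour released
    force_before: float  # pN


@dataclass
class SegmentedFit:
    """Piecewise-linear segmentation of a contour series."""

    changepoints: np.ndarray      # sample indices, strictly increasing
    segment_velocities: np.ndarray  # bp/s per segment
    penalty_score: float          # SIC value of the accepted segmentation

    @property
    def n_segments(self) -> int:
        return len(self.segment_velocities)


@dataclass
class PauseStats:
    """Observed and missed-pause-corrected pause statistics."""

    observed_count: int
    observed_mean_duration: float  # s
    tau_hat: float                 # s, censored-exponential MLE
    detected_fraction: float
    corrected_count: float
    pause_density: float = np.nan        # pauses / kbp (observed)
    corrected_density: float = np.nan
    detection_threshold: float = 0.0
    valid: bool = True


# --------------------------------------------------------------------------
# WLC inversion
# --------------------------------------------------------------------------

def extension_to_contour(
    trace: Trace,
    persistence: float = 50.0,
    scale: ThermalScale = DEFAULT_SCALE,
    stretch_modulus: float | None = None,
) -> np.ndarray:
    """Contour length (bp) per sample from (extension, force).

    Inverts the Marko-Siggia relation sample-by-sample: the relative
    extension z(F) is solved from the measured force, then
    L = x / z (inextensible) or L = x / (z + F/S). Samples with F <= 0 are
    returned as NaN and logged.
    """
    F = np.asarray(trace.force, dtype=float)
    x = np.asarray(trace.extension, dtype=float)
    bad = F <= 0
    if bad.any():
        log.warning("%d samples with non-positive force excluded", int(bad.sum()))
    Fs = np.where(bad, 1.0, F)
    z = wlc_relative_extension(Fs, persistence, scale)
    if stretch_modulus is not None:
        z = z + Fs / stretch_modulus
    L_nm = np.where(bad, np.nan, x / z)
    return L_nm / BP_RISE_NM


# --------------------------------------------------------------------------
# SIC-penalized changepoint segmentation
# --------------------------------------------------------------------------

class _LinFitCost:
    """O(1) residual sum of squares of a straight-line fit on any interval."""

    def __init__(self, t: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.n = len(t)
        self.ct = np.concatenate([z, np.cumsum(t)])
        self.ct2 = np.concatenate([z, np.cumsum(t * t)])
        self.cy = np.concatenate([z, np.cumsum(y)])
        self.cy2 = np.concatenate([z, np.cumsum(y * y)])
        self.cty = np.concatenate([z, np.cumsum(t * y)])

    def rss(self, i, j):
        """RSS of the least-squares line on samples [i, j) (vectorized in i/j)."""
        n = j - i
        st = self.ct[j] - self.ct[i]
        st2 = self.ct2[j] - self.ct2[i]
        sy = self.cy[j] - self.cy[i]
        sy2 = self.cy2[j] - self.cy2[i]
        sty = self.cty[j] - self.cty[i]
        stt = st2 - st * st / n
        sxy = sty - st * sy / n
        syy = sy2 - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            out = syy - np.where(stt > 0, sxy * sxy / np.where(stt > 0, stt, 1.0), 0.0)
        return np.maximum(out, 0.0)

    def slope(self, i: int, j: int) -> float:
        n = j - i
        st = self.ct[j] - self.ct[i]
        st2 = self.ct2[j] - self.ct2[i]
        sy = self.cy[j] - self.cy[i]
        sty = self.cty[j] - self.cty[i]
        stt = st2 - st * st / n
        if stt <= 0:
            return 0.0
        return (sty - st * sy / n) / stt


def _sic(total_rss: float, n: int, n_changepoints: int) -> float:
    """Schwarz-type criterion: Gaussian log-likelihood term + ln(n) per split."""
    var = max(total_rss / n, 1e-300)
    return n * np.log(var) + (n_changepoints + 1) * np.log(n)


def _best_split(cost: _LinFitCost, i: int, j: int, min_size: int):
    if j - i < 2 * min_size:
        return None
    cands = np.arange(i + min_size, j - min_size + 1)
    if len(cands) == 0:
        return None
    left = cost.rss(np.full(len(cands), i), cands)
    right = cost.rss(cands, np.full(len(cands), j))
    k = int(np.argmin(left + right))
    return int(cands[k]), float(left[k]), float(right[k])


def _segment_contour(
    t: np.ndarray, y: np.ndarray, min_size: int
) -> tuple[list[int], _LinFitCost]:
    """Best-first binary segmentation accepting splits that lower the SIC.

    Candidate splits are taken largest-RSS-reduction-first across all
    current segments, so small pauses are still refined once the dominant
    structure has been captured; the search stops when the best remaining
    split no longer lowers the criterion.
    """
    import heapq

    cost = _LinFitCost(t, y)
    n = len(t)
    boundaries = [0, n]
    rss_map = {(0, n): float(cost.rss(0, n))}

    heap: list[tuple[float, int, int, int, float, float]] = []

    def push(i: int, j: int) -> None:
        found = _best_split(cost, i, j, min_size)
        if found is None:
            return
        split, lft, rgt = found
        gain = rss_map[(i, j)] - (lft + rgt)
        heapq.heappush(heap, (-gain, i, j, split, lft, rgt))

    push(0, n)
    while heap:
        neg_gain, i, j, split, lft, rgt = heapq.heappop(heap)
        if (i, j) not in rss_map:
            continue
        total_rss = sum(rss_map.values())
        new_total = total_rss + neg_gain
        m = len(rss_map)  # segments before the split
        if _sic(new_total, n, m) >= _sic(total_rss, n, m - 1):
            break  # all remaining candidates have smaller gains
        del rss_map[(i, j)]
        rss_map[(i, split)] = lft
        rss_map[(split, j)] = rgt
        boundaries.append(split)
        push(i, split)
        push(split, j)
    return sorted(boundaries), cost


def detect_pauses(
    trace: Trace,
    min_duration: float | None = None,
    velocity_threshold: float | None = None,
    contour: np.ndarray | None = None,
    min_segment_samples: int = 8,
) -> tuple[SegmentedFit, list[PauseEvent]]:
    """Changepoint-based pause detection on the contour series.

    A pause is a maximal run of segments whose absolute speed is below
    ``velocity_threshold`` (default: 10% of the median absolute segment
    speed) and whose total duration is at least ``min_duration`` (default:
    the [ATP]-dependent detection threshold if the trace metadata records
    the ATP concentration, else 30 ms). Adjacent sub-threshold segments are
    merged before the duration test.
    """
    if len(trace.time) == 0:
        raise ValueError("empty trace")
    if contour is None:
        contour = np.asarray(trace.contour_length, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    if min_duration is None:
        atp = trace.metadata.get("cycle", {}).get("atp")
        min_duration = detection_threshold(atp) if atp is not None else 0.030
    if len(t) < 2 * max(min_segment_samples, 2):
        raise ValueError("trace shorter than twice the minimum segment size")

    boundaries, cost = _segment_contour(t, contour, min_segment_samples)
    seg_velocities = np.array(
        [-cost.slope(i, j) for i, j in zip(boundaries[:-1], boundaries[1:])]
    )  # translocation shortens the contour; report positive speeds
    total_rss = sum(
        float(cost.rss(i, j)) for i, j in zip(boundaries[:-1], boundaries[1:])
    )
    fit = SegmentedFit(
        changepoints=np.array(boundaries[1:-1], dtype=int),
        segment_velocities=seg_velocities,
        penalty_score=_sic(total_rss, len(t), len(boundaries) - 2),
    )

    if velocity_threshold is None:
        # reference translocation speed: high duration-weighted quantile of
        # the segment speeds, robust even when pauses occupy most of the
        # trace (pause segments sit near zero, moving segments near v)
        durations = np.array(
            [t[j - 1] - t[i] for i, j in zip(boundaries[:-1], boundaries[1:])]
        )
        speeds = np.abs(seg_velocities)
        order = np.argsort(speeds)
        cum = np.cumsum(durations[order])
        ref = speeds[order][np.searchsorted(cum, 0.9 * cum[-1])]
        velocity_threshold = 0.1 * ref

    # Classify on merged runs: short segments inside a pause carry noisy
    # slope estimates, so segments are first gated loosely, then the run's
    # overall slope decides. Runs failing the merged test fall back to the
    # strict per-segment criterion.
    gate = 5.0 * velocity_threshold
    segs = list(zip(boundaries[:-1], boundaries[1:]))

    def emit(i: int, j: int, out: list[PauseEvent]) -> None:
        start, stop = t[i], t[j - 1]
        if stop - start >= min_duration:
            out.append(
                PauseEvent(
                    start=start,
                    duration=stop - start,
                    force=float(np.mean(trace.force[i:j])),
                )
            )

    pauses: list[PauseEvent] = []
    k = 0
    while k < len(segs):
        if abs(seg_velocities[k]) < gate:
            k2 = k
            while k2 + 1 < len(segs) and abs(seg_velocities[k2 + 1]) < gate:
                k2 += 1
            i, j = segs[k][0], segs[k2][1]
            if abs(cost.slope(i, j)) < velocity_threshold:
                emit(i, j, pauses)
            else:
                # strict sub-runs within the gated stretch
                kk = k
                while kk <= k2:
                    if abs(seg_velocities[kk]) < velocity_threshold:
                        kk2 = kk
                        while (kk2 + 1 <= k2
                               and abs(seg_velocities[kk2 + 1]) < velocity_threshold):
                            kk2 += 1
                        emit(segs[kk][0], segs[kk2][1], pauses)
                        kk = kk2 + 1
                    else:
                        kk += 1
            k = k2 + 1
        else:
            k += 1
    return fit, pauses


# --------------------------------------------------------------------------
# pause-free velocity
# --------------------------------------------------------------------------

def _pause_mask(t: np.ndarray, pauses: list[PauseEvent]) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for p in pauses:
        mask |= (t >= p.start) & (t <= p.start + p.duration)
    return mask


def pause_free_velocity(
    trace: Trace,
    pauses: list[PauseEvent],
    force_window: tuple[float, float] | None = None,
    contour: np.ndarray | None = None,
    min_samples: int = 10,
) -> VelocityPoint | None:
    """Straight-line pause-free velocity within a half-open force window.

    Returns None (with a logged warning) when fewer than ``min_samples``
    pause-free samples fall inside the window.
    """
    if contour is None:
        contour = np.asarray(trace.contour_length, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    keep = ~_pause_mask(t, pauses) & np.isfinite(contour)
    if force_window is not None:
        lo, hi = force_window
        keep &= (trace.force >= lo) & (trace.force < hi)
        center = 0.5 * (lo + hi)
    else:
        center = float(np.mean(trace.force))
    if keep.sum() < min_samples:
        log.warning("force window %s skipped: %d pause-free samples",
                    force_window, int(keep.sum()))
        return None
    # stitch out the excised pause time so the straight-line slope measures
    # the translocation rate of the productive stretches only
    t_stitched = t.copy()
    for p in sorted(pauses, key=lambda p: p.start):
        after = t > p.start + p.duration
        t_stitched[after] -= p.duration
    slope, _ = np.polyfit(t_stitched[keep], contour[keep], 1)
    meta = trace.metadata.get("cycle", {})
    return VelocityPoint(
        force_bin_center=center,
        atp=float(meta.get("atp", np.nan)),
        adp=float(meta.get("adp", 0.0)),
        pi=float(meta.get("pi", 0.0)),
        velocity=max(-slope, 0.0),
        sem=np.nan,
        n_obs=1,
    )


# --------------------------------------------------------------------------
# censored-exponential pause correction
# --------------------------------------------------------------------------

def correct_pause_stats(
    observed_durations: list[float] | np.ndarray,
    min_duration: float,
    translocated_kbp: float | None = None,
) -> PauseStats:
    """Missed-pause correction from the censored-exponential MLE.

    For exponential durations observed only above ``min_duration``, the
    maximum-likelihood mean is ``τ̂ = mean(observed) - min_duration`` by
    memorylessness; the detected fraction is ``exp(-min_duration/τ̂)`` and
    the corrected count rescales the observed count by its inverse. When
    ``translocated_kbp`` is given, observed and corrected densities
    (pauses/kbp) are filled in.
    """
    durations = np.asarray(observed_durations, dtype=float)
    if durations.size == 0:
        return PauseStats(
            observed_count=0, observed_mean_duration=np.nan, tau_hat=np.nan,
            detected_fraction=np.nan, corrected_count=0.0,
            detection_threshold=min_duration, valid=False,
        )
    if np.any(durations < min_duration - 1e-12):
        raise ValueError("observed durations must all be >= min_duration")
    mean_obs = float(durations.mean())
    tau = mean_obs - min_duration
    if tau <= 0:
        # all durations at the threshold: no information about the tail
        return PauseStats(
            observed_count=int(durations.size), observed_mean_duration=mean_obs,
            tau_hat=np.nan, detected_fraction=np.nan,
            corrected_count=float(durations.size),
            detection_threshold=min_duration, valid=False,
        )
    detected = float(np.exp(-min_duration / tau))
    corrected = durations.size / detected
    dens = corr_dens = np.nan
    if translocated_kbp is not None and translocated_kbp > 0:
        dens = durations.size / translocated_kbp
        corr_dens = corrected / translocated_kbp
    return PauseStats(
        observed_count=int(durations.size),
        observed_mean_duration=mean_obs,
        tau_hat=tau,
        detected_fraction=detected,
        corrected_count=corrected,
        pause_density=dens,
        corrected_density=corr_dens,
        detection_threshold=min_duration,
    )


# --------------------------------------------------------------------------
# slips
# --------------------------------------------------------------------------

def detect_slips(
    trace: Trace,
    min_release: float = 50.0,
    max_interval: float = 0.02,
    contour: np.ndarray | None = None,
) -> list[SlipEvent]:
    """Detect abrupt contour increases of >= ``min_release`` bp.

    A slip is scored when the contour rises by at least ``min_release``
    within at most ``max_interval`` seconds; overlapping detections are
    collapsed onto the first sample of the rise.
    """
    if contour is None:
        contour = np.asarray(trace.contour_length, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    n = len(t)
    if n < 2:
        return []
    w = max(int(round(max_interval * n / max(t[-1] - t[0], 1e-12))), 1)
    events: list[SlipEvent] = []
    i = 0
    while i < n - 1:
        j_hi = min(i + w, n - 1)
        window = contour[i + 1 : j_hi + 1]
        rise = window.max() - contour[i] if len(window) else 0.0
        if rise >= min_release:
            j = i + 1 + int(np.argmax(window))
            # measure the release from the last pre-jump sample, not from
            # the start of the search window (the motor keeps translocating
            # up to the slip itself)
            k0 = i + int(np.argmin(contour[i:j]))
            events.append(
                SlipEvent(
                    time=float(t[j]),
                    released_bp=float(contour[j] - contour[k0]),
                    force_before=float(trace.force[k0]),
                )
            )
            i = j + 1
        else:
            i += 1
    return events


def slip_density(
    cells: dict[tuple[float, float], tuple[list[SlipEvent], float]],
) -> pd.DataFrame:
    """Slip density per (force, [ATP]) cell, events per kbp translocated.

    ``cells`` maps (force, atp) to (slip events, kbp translocated). The
    counting error of N events is reported as sqrt(N).
    """
    rows = []
    for (force, atp), (events, kbp) in sorted(cells.items()):
        n = len(events)
        rows.append(
            {"force": force, "atp": atp, "n_slips": n,
             "kbp_translocated": kbp,
             "density": n / kbp if kbp > 0 else np.nan,
             "density_err": np.sqrt(n) / kbp if kbp > 0 else np.nan}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# consolidation
# --------------------------------------------------------------------------

def consolidate_force_velocity(
    cells: list[list[VelocityPoint]],
    bin_edges: np.ndarray = CANONICAL_FORCE_BIN_EDGES,
) -> list[VelocityPoint]:
    """Pool per-window velocities across cells, then re-bin by force.

    All cells must use force windows compatible with ``bin_edges`` (each
    window center must fall inside a bin). Pooled means carry the SEM over
    all contributing measurements.
    """
    pooled: list[VelocityPoint] = [p for cell in cells for p in cell]
    if not pooled:
        return []
    forces = np.array([p.force_bin_center for p in pooled])
    if forces.min() < bin_edges[0] or forces.max() >= bin_edges[-1]:
        raise ValueError("incompatible binning: window centers outside the bin range")
    idx = np.digitize(forces, bin_edges) - 1
    out: list[VelocityPoint] = []
    for b in range(len(bin_edges) - 1):
        sel = [p for p, i in zip(pooled, idx) if i == b]
        if not sel:
            continue
        v = np.array([p.velocity for p in sel])
        atp = float(np.mean([p.atp for p in sel]))
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        out.append(
            VelocityPoint(
                force_bin_center=0.5 * (bin_edges[b] + bin_edges[b + 1]),
                atp=atp,
                adp=float(np.mean([p.adp for p in sel])),
                pi=float(np.mean([p.pi for p in sel])),
                velocity=float(v.mean()),
                sem=sem if sem and sem > 0 else max(float(v.mean()) * 0.01, 1e-9),
                n_obs=len(sel),
            )
        )
    return out
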