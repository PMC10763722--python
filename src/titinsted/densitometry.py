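"""Gel lane densitometry: band quantification, mobility calibration, titin ratios.

Quantifies optical-density lane traces from SDS-agarose electrophoresis of
giant sarcomeric proteins.  Bands are integrated above a linear baseline
interpolated between window-edge levels; a log-linear mobility calibration
(migration vs log10 MW) converts band centroids to molecular-weight
estimates, which lets a putative truncated-titin band be matched against
the mass predicted from the truncating variant's protein position.

The stoichiometry ratios are the standard titin-gel readouts: N2BA/N2B
isoform ratio, full-length titin over myosin heavy chain (T1/MyHC with
T1 = N2BA + N2B), proteolytic-fragment fraction T2/T1, truncated/T1, and
the integrated titin pools (T1+T2)/MyHC and (T1+T2+truncated)/MyHC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)


class DensitometryError(ValueError):
    """Raised for invalid lanes, calibrations, or ratio requests."""


@dataclass(frozen=True)
class GelLaneProfile:
    """Densitometric trace of one gel lane on a uniform migration grid."""

    migration_mm: np.ndarray
    od: np.ndarray
    lane_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.migration_mm, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if x.ndim != 1 or x.size < 2 or y.shape != x.shape:
            raise DensitometryError("migration grid and OD must be 1D arrays of equal length")
        steps = np.diff(x)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DensitometryError("migration grid must be uniform and increasing")
        if not np.all(np.isfinite(y)):
            raise DensitometryError("OD values must be finite")
        object.__setattr__(self, "migration_mm", x)
        object.__setattr__(self, "od", y)

    @property
    def step_mm(self) -> float:
        return float(self.migration_mm[1] - self.migration_mm[0])


@dataclass(frozen=True)
class BandQuantification:
    label: str
    window_mm: tuple[float, float]
    integrated_od: float
    centroid_mm: float
    estimated_mw_kda: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TitinRatios:
    n2ba_over_n2b: float
    t1_over_myhc: float
    t2_over_t1: float
    trunc_over_t1: float
    t1t2_over_myhc: float
    integrated_titin_over_myhc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n2ba_over_n2b": self.n2ba_over_n2b,
            "t1_over_myhc": self.t1_over_myhc,
            "t2_over_t1": self.t2_over_t1,
            "trunc_over_t1": self.trunc_over_t1,
            "t1t2_over_myhc": self.t1t2_over_myhc,
            "integrated_titin_over_myhc": self.integrated_titin_over_myhc,
        }


@dataclass(frozen=True)
class MobilityCalibration:
    """Log-linear mobility law migration = intercept + slope × log10(MW)."""

    intercept: float
    slope: float
    residual_rms: float = 0.0

    def mw_to_migration(self, mw_kda: float) -> float:
        if mw_kda <= 0:
            raise DensitometryError("MW must be > 0")
        return self.intercept + self.slope * math.log10(mw_kda)

    def migration_to_mw(self, migration_mm: float) -> float:
        return float(10.0 ** ((migration_mm - self.intercept) / self.slope))


def calibrate_mobility(standards: Sequence[tuple[float, float]]) -> MobilityCalibration:
    """Least-squares mobility calibration from (MW kDa, migration mm) standards."""
    if len(standards) < 2:
        raise DensitometryError("need >= 2 calibration standards")
    mws = np.asarray([s[0] for s in standards], dtype=float)
    migs = np.asarray([s[1] for s in standards], dtype=float)
    if np.any(mws <= 0):
        raise DensitometryError("standard MWs must be > 0")
    if len(np.unique(mws)) < 2:
        raise DensitometryError("standards must span >= 2 distinct MWs")
    logmw = np.log10(mws)
    slope, intercept = np.polyfit(logmw, migs, 1)
    resid = migs - (intercept + slope * logmw)
    return MobilityCalibration(
        intercept=float(intercept),
        slope=float(slope),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


#: expected band order by decreasing MW on a titin gel; truncated titin has
#: variable MW and is identified separately via a mass prediction.
DEFAULT_LANE_TEMPLATE = (("N2BA", 3300.0), ("N2B", 3000.0), ("T2", 2200.0), ("MyHC", 223.0))

#: fraction of the smaller neighbouring peak that the valley between two
#: bands may reach before the bands are quantified as one merged group
MERGE_VALLEY_FRACTION = 0.20

#: half-width of the margin over which window-edge baseline levels are averaged
EDGE_MARGIN_MM = 0.3


def _auto_windows(lane: GelLaneProfile, min_prominence: float):
    """Detect bands and tile the lane into per-group windows split at valleys.

    Returns a list of groups; each group is (window, [(sub_window, peak_idx)]).
    Adjacent bands whose valley exceeds ``MERGE_VALLEY_FRACTION`` of the
    smaller peak share one group (and hence one baseline chord).
    """
    x, y = lane.migration_mm, lane.od
    smooth = ndimage.uniform_filter1d(y, size=max(3, int(0.2 / lane.step_mm)))
    idx, _ = signal.find_peaks(smooth, prominence=min_prominence)
    if idx.size == 0:
        raise DensitometryError(f"no bands detected in lane {lane.lane_id!r}")

    # merge decision per adjacent pair
    groups: list[list[int]] = [[int(idx[0])]]
    valleys: list[list[int]] = [[]]
    for prev, cur in zip(idx[:-1], idx[1:]):
        vi = int(prev + np.argmin(smooth[prev:cur + 1]))
        valley = smooth[vi]
        floor = min(smooth[prev], smooth[cur])
        if valley > MERGE_VALLEY_FRACTION * floor if floor > 0 else False:
            groups[-1].append(int(cur))
            valleys[-1].append(vi)
        else:
            groups.append([int(cur)])
            valleys.append([])

    out = []
    for gi, (members, vls) in enumerate(zip(groups, valleys)):
        left = 0 if gi == 0 else int((groups[gi - 1][-1] + members[0]) / 2)
        right = len(x) - 1 if gi == len(groups) - 1 else int((members[-1] + groups[gi + 1][0]) / 2)
        bounds = [left] + vls + [right]
        subs = [((bounds[k], bounds[k + 1]), members[k]) for k in range(len(members))]
        out.append(((left, right), subs))
    return out


def _edge_level(lane: GelLaneProfile, index: int) -> float:
    half = max(1, int(EDGE_MARGIN_MM / lane.step_mm / 2))
    lo = max(0, index - half)
    hi = min(len(lane.od), index + half + 1)
    return float(np.mean(lane.od[lo:hi]))


def _integrate_window(lane: GelLaneProfile, i0: int, i1: int, base0: float, base1: float):
    """Trapezoidal area above the linear baseline chord over samples [i0, i1]."""
    x = lane.migration_mm[i0 : i1 + 1]
    y = lane.od[i0 : i1 + 1]
    baseline = np.interp(x, [lane.migration_mm[i0], lane.migration_mm[i1]], [base0, base1])
    net = y - baseline
    area = float(np.trapezoid(net, x))
    # centroid over the contiguous band core (>= 10% of the band maximum):
    # wide windows would otherwise let baseline noise drag the centroid
    imax = int(np.argmax(net))
    level = 0.1 * net[imax]
    a = imax
    while a > 0 and net[a - 1] >= level:
        a -= 1
    b = imax
    while b < net.size - 1 and net[b + 1] >= level:
        b += 1
    w = np.clip(net[a : b + 1], 0.0, None)
    total = w.sum()
    centroid = float((x[a : b + 1] * w).sum() / total) if total > 0 else float(x.mean())
    return area, centroid


def quantify_lane(
    lane: GelLaneProfile,
    band_windows: Mapping[str, tuple[float, float]] | None = None,
    calibration: MobilityCalibration | None = None,
    template: Sequence[tuple[str, float]] = DEFAULT_LANE_TEMPLATE,
    truncated_mw_predictions: Sequence[float] = (),
    truncated_mw_tolerance: float = 0.10,
    min_prominence: float | None = None,
    saturation_od: float | None = None,
) -> list[BandQuantification]:
    """Quantify the bands of one lane.

    With explicit ``band_windows`` ({label: (lo_mm, hi_mm)}), each window is
    integrated above its own baseline chord.  In auto mode, bands are
    detected as prominent maxima, windows are tiled at midpoints between
    band groups, a shared baseline chord is used for bands merged into one
    group, and labels are assigned by calibrated-MW proximity to the lane
    template; an unassigned band matching one of
    ``truncated_mw_predictions`` (within ``truncated_mw_tolerance``,
    fractional) is labelled ``truncated``, others ``other``.

    A run of >= 5 samples at the lane's maximum OD flags the affected band
    as saturated.
    """
    results: list[BandQuantification] = []
    x = lane.migration_mm

    sat_mask = _saturation_mask(lane, saturation_od)

    if band_windows is not None:
        for label, (lo, hi) in band_windows.items():
            if lo < x[0] or hi > x[-1] or hi <= lo:
                raise DensitometryError(f"window {label!r} = ({lo}, {hi}) outside the lane grid")
            i0 = int(np.searchsorted(x, lo, side="left"))
            i1 = int(np.searchsorted(x, hi, side="right")) - 1
            area, centroid = _integrate_window(lane, i0, i1, _edge_level(lane, i0), _edge_level(lane, i1))
            flags = ("saturated",) if sat_mask[i0 : i1 + 1].any() else ()
            mw = calibration.migration_to_mw(centroid) if calibration is not None else None
            results.append(BandQuantification(label, (lo, hi), area, centroid, mw, flags))
        return sorted(results, key=lambda b: b.window_mm[0])

    if min_prominence is None:
        noise = np.median(np.abs(np.diff(lane.od))) / 0.6745 / math.sqrt(2)
        min_prominence = max(5.0 * noise, 1e-9)
    groups = _auto_windows(lane, min_prominence)

    raw: list[BandQuantification] = []
    for (g0, g1), subs in groups:
        base0, base1 = _edge_level(lane, g0), _edge_level(lane, g1)
        xg = [x[g0], x[g1]]
        for (i0, i1), peak_idx in subs:
            b0 = float(np.interp(x[i0], xg, [base0, base1]))
            b1 = float(np.interp(x[i1], xg, [base0, base1]))
            area, centroid = _integrate_window(lane, i0, i1, b0, b1)
            flags = ("saturated",) if sat_mask[i0 : i1 + 1].any() else ()
            mw = calibration.migration_to_mw(centroid) if calibration is not None else None
            raw.append(BandQuantification("", (float(x[i0]), float(x[i1])), area, centroid, mw, flags))

    return _assign_labels(raw, calibration, template, truncated_mw_predictions, truncated_mw_tolerance)


def _saturation_mask(lane: GelLaneProfile, saturation_od: float | None) -> np.ndarray:
    level = float(np.max(lane.od)) if saturation_od is None else saturation_od
    at_max = lane.od >= level - 1e-12
    mask = np.zeros_like(at_max)
    run = 0
    for i, flag in enumerate(at_max):
        run = run + 1 if flag else 0
        if run >= 5:
            mask[i - run + 1 : i + 1] = True
    return mask


def _assign_labels(bands, calibration, template, trunc_predictions, tol):
    """Greedy nearest-log-MW assignment of template labels; leftovers get
    'truncated' on a mass-prediction match, else 'other'."""
    if calibration is None:
        # without a calibration fall back to migration-order assignment
        ordered = sorted(bands, key=lambda b: b.centroid_mm)
        labels = [t[0] for t in template]
        out = []
        for i, b in enumerate(ordered):
            label = labels[i] if i < len(labels) else "other"
            out.append(BandQuantification(label, b.window_mm, b.integrated_od,
                                          b.centroid_mm, b.estimated_mw_kda, b.flags))
        return out

    remaining = list(range(len(bands)))
    assignment: dict[int, str] = {}
    pairs = []
    for label, mw in template:
        for bi in remaining:
            est = bands[bi].estimated_mw_kda
            if est and est > 0:
                pairs.append((abs(math.log10(est) - math.log10(mw)), label, bi))
    pairs.sort()
    used_labels: set[str] = set()
    for dist, label, bi in pairs:
        if label in used_labels or bi in assignment:
            continue
        assignment[bi] = label
        used_labels.add(label)
    out = []
    for bi, b in enumerate(bands):
        label = assignment.get(bi)
        if label is None:
            label = "other"
            est = b.estimated_mw_kda
            if est is not None:
                for pred in trunc_predictions:
                    if match_truncated_band(est, pred, tol):
                        label = "truncated"
                        break
        out.append(BandQuantification(label, b.window_mm, b.integrated_od,
                                      b.centroid_mm, b.estimated_mw_kda, b.flags))
    return sorted(out, key=lambda b: b.window_mm[0])


def compute_titin_ratios(bands: Sequence[BandQuantification]) -> TitinRatios:
    """Titin stoichiometry ratios from quantified bands (T1 = N2BA + N2B)."""
    areas: dict[str, float] = {}
    for b in bands:
        areas[b.label] = areas.get(b.label, 0.0) + b.integrated_od
    for required in ("N2BA", "N2B", "MyHC"):
        if required not in areas:
            raise DensitometryError(f"band {required!r} missing from the lane quantification")
    n2ba, n2b = areas["N2BA"], areas["N2B"]
    myhc = areas["MyHC"]
    if myhc == 0:
        raise DensitometryError("MyHC area is zero; ratios undefined")
    if n2b == 0:
        raise DensitometryError("N2B area is zero; N2BA/N2B undefined")
    t1 = n2ba + n2b
    t2 = areas.get("T2", 0.0)
    trunc = areas.get("truncated", 0.0)
    return TitinRatios(
        n2ba_over_n2b=n2ba / n2b,
        t1_over_myhc=t1 / myhc,
        t2_over_t1=t2 / t1,
        trunc_over_t1=trunc / t1,
        t1t2_over_myhc=(t1 + t2) / myhc,
        integrated_titin_over_myhc=(t1 + t2 + trunc) / myhc,
    )


def match_truncated_band(
    estimated_mw_kda: float, predicted_mw_kda: float, tolerance_frac: float = 0.10
) -> bool:
    """True iff the densitometric MW estimate matches the predicted truncated mass."""
    if estimated_mw_kda <= 0 or predicted_mw_kda <= 0:
        raise DensitometryError("masses must be > 0")
    return abs(estimated_mw_kda - predicted_mw_kda) / predicted_mw_kda <= tolerance_frac
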