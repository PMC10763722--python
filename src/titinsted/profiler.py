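"""STED line-profile analysis: peak fitting, sarcomere assignment, QC, metrics.

The analysis mirrors how sarcomere nanostructure is measured from
two-channel (MIR / A170 anti-titin) STED images:

1. extract a thick-line intensity profile along the myofibril axis;
2. detect local maxima and fit each neighbourhood with Gaussian(s) plus a
   constant baseline to get epitope centre, height and FWHM;
3. scan the fitted peaks for the per-sarcomere grammar
   ``[MIR, A170, A170, MIR]`` — an A170 doublet bounded by a MIR pair —
   and derive the metrics: sarcomere length (from consecutive A170-doublet
   midpoints, the M-line estimate), A-band titin length (MIR-to-MIR),
   M-line-to-titin-kinase distance (half the doublet separation), epitope
   FWHMs and the A170/MIR height ratio;
4. discard sarcomeres whose MIR or A170 peak heights fluctuate across the
   M-line by more than 20% of their mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize, signal, stats as sstats

logger = logging.getLogger(__name__)

SIGMA_TO_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

MIR_CHANNEL = "mir"
A170_CHANNEL = "a170"


class ProfileError(ValueError):
    """Raised for malformed profiles or invalid analysis requests."""


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D multi-channel intensity trace on a uniform nm grid."""

    positions: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ProfileError("positions must be a 1D grid with >= 2 samples")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ProfileError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ProfileError("positions must be uniformly spaced")
        for name, arr in self.channels.items():
            if np.asarray(arr).shape != pos.shape:
                raise ProfileError(f"channel {name!r} length differs from the grid")
        object.__setattr__(self, "positions", pos)

    @property
    def pixel_nm(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class FittedPeak:
    """One fitted Gaussian epitope band."""

    channel: str
    center_nm: float
    height: float
    fwhm_nm: float
    center_se_nm: float
    baseline: float
    flags: tuple[str, ...] = ()

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / SIGMA_TO_FWHM


@dataclass
class SarcomereMeasurement:
    """Per-sarcomere metrics derived from one matched epitope quadruple."""

    sl_nm: float
    aband_titin_len_nm: float
    m_position_nm: float
    dtk_nm: float
    a170_separation_nm: float
    mir_fwhm_nm: float
    a170_fwhm_nm: float
    a170_over_mir_intensity: float | None
    qc_pass: bool
    qc_reasons: tuple[str, ...]
    genotype: str | None = None
    peaks: dict[str, FittedPeak] = field(default_factory=dict)
    # ratio of FWHM to peak height (nm per intensity unit), per channel
    mir_fwhm_over_height: float | None = None
    a170_fwhm_over_height: float | None = None


@dataclass(frozen=True)
class FitConfig:
    """Settings of peak detection and Gaussian fitting."""

    prominence_k: float = 3.0          # prominence threshold in units of noise SD
    rel_prominence_floor: float = 0.02  # noise floor as a fraction of the largest prominence
    local_noise_window_nm: float = 150.0  # window of the local (heteroscedastic) noise estimate
    min_separation_nm: float = 20.0    # minimum detected-peak spacing
    cluster_gap_nm: float = 250.0      # peaks closer than this are fitted jointly
    window_pad_nm: float = 80.0        # fit window padding beyond outermost peak
    init_fwhm_nm: float = 40.0         # initial FWHM guess
    max_fwhm_nm: float = 400.0
    shoulder_split: bool = True        # try a 2-Gaussian fit on broad single peaks
    shoulder_fwhm_factor: float = 1.6  # "broad" means fitted FWHM > factor*init_fwhm
    f_alpha: float = 0.01              # F-test level for accepting the split
    unresolved_fwhm_factor: float | None = None  # flag peaks broader than factor*init_fwhm


@dataclass(frozen=True)
class AssignConfig:
    """Settings of the sarcomere-assignment grammar."""

    doublet_window_nm: tuple[float, float] = (60.0, 260.0)
    qc_threshold: float = 0.20
    # peaks below this fraction of the tallest peak between a MIR pair are
    # ignored when pairing the A170 doublet (guards against residual noise
    # components masquerading as doublet partners)
    relative_height_floor: float = 0.10


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

def extract_line_profile(
    image: Mapping[str, np.ndarray],
    pixel_nm: float,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 5,
    background_window_px: int = 101,
) -> IntensityProfile:
    """Extract a thick-line profile from a multi-channel 2D image.

    ``start``/``end`` are 0-based (row, col) endpoints; intensities are
    averaged over ``width_px`` samples perpendicular to the line at each
    axial position (averaging across a thick line compensates for labeling
    inhomogeneity along the epitope bands).  A rolling-minimum background
    estimate per channel is stored in the metadata.
    """
    from skimage.measure import profile_line

    if width_px < 1:
        raise ProfileError("width_px must be >= 1")
    channels = {}
    for name, arr in image.items():
        arr = np.asarray(arr, dtype=float)
        for pt in (start, end):
            if not (0 <= pt[0] <= arr.shape[0] - 1 and 0 <= pt[1] <= arr.shape[1] - 1):
                raise ProfileError(f"line endpoint {pt} outside image bounds {arr.shape}")
        channels[name] = profile_line(
            arr, start, end, linewidth=width_px, reduce_func=np.mean,
            order=1, mode="reflect",
        )
    n = len(next(iter(channels.values())))
    positions = np.arange(n) * pixel_nm
    background = {
        name: ndimage.minimum_filter1d(y, size=min(background_window_px, n))
        for name, y in channels.items()
    }
    return IntensityProfile(
        positions=positions,
        channels=channels,
        metadata={"source": "extract_line_profile", "pixel_nm": pixel_nm,
                  "width_px": width_px, "background": background},
    )


# ---------------------------------------------------------------------------
# peak detection and Gaussian fitting
# ---------------------------------------------------------------------------

def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust global noise-SD estimate from first differences (MAD-based)."""
    d = np.diff(np.asarray(y, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6745 / math.sqrt(2.0)) if mad > 0 else 0.0


def local_noise_sd(y: np.ndarray, window_samples: int) -> np.ndarray:
    """Per-sample noise-SD estimate from a rolling median of |first differences|.

    Shot-noise-limited traces are strongly heteroscedastic (the noise scale
    follows the signal), so peak-significance thresholds must be local: a
    global robust estimate collapses to ~0 on profiles that are mostly
    empty baseline.
    """
    d = np.abs(np.diff(np.asarray(y, dtype=float)))
    med = ndimage.median_filter(d, size=max(3, window_samples), mode="nearest")
    scale = med / 0.6745 / math.sqrt(2.0)
    return np.append(scale, scale[-1])


def _multi_gauss(x: np.ndarray, *params: float) -> np.ndarray:
    """constant + sum of Gaussians; params = (c, amp1, cen1, sig1, amp2, ...)."""
    y = np.full_like(x, params[0])
    for i in range(1, len(params), 3):
        amp, cen, sig = params[i : i + 3]
        y = y + amp * np.exp(-0.5 * ((x - cen) / sig) ** 2)
    return y


def _fit_cluster(x, y, centers_init, config: FitConfig):
    """Least-squares multi-Gaussian + constant fit; returns (popt, pcov, rss)."""
    base0 = float(np.min(y))
    sig0 = config.init_fwhm_nm / SIGMA_TO_FWHM
    p0 = [base0]
    lower = [-np.inf]
    upper = [np.inf]
    span = x[-1] - x[0]
    centers_init = np.clip(centers_init, x[0], x[-1])
    for c in centers_init:
        amp0 = max(float(np.interp(c, x, y)) - base0, 1e-6)
        p0 += [amp0, c, sig0]
        lower += [0.0, x[0], (x[1] - x[0]) / 2.0]
        upper += [np.inf, x[-1], max(config.max_fwhm_nm / SIGMA_TO_FWHM, span)]
    popt, pcov = optimize.curve_fit(
        _multi_gauss, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
    )
    rss = float(np.sum((y - _multi_gauss(x, *popt)) ** 2))
    return popt, pcov, rss


def _peaks_from_fit(channel, popt, pcov, flags=()) -> list[FittedPeak]:
    peaks = []
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf)) if pcov is not None else None
    for i in range(1, len(popt), 3):
        amp, cen, sig = popt[i : i + 3]
        se = float(perr[i + 1]) if perr is not None and np.isfinite(perr[i + 1]) else float("nan")
        peaks.append(
            FittedPeak(
                channel=channel,
                center_nm=float(cen),
                height=float(amp),
                fwhm_nm=float(sig * SIGMA_TO_FWHM),
                center_se_nm=se,
                baseline=float(popt[0]),
                flags=tuple(flags),
            )
        )
    return peaks


def detect_and_fit_peaks(
    profile: IntensityProfile,
    channel: str,
    config: FitConfig = FitConfig(),
    diagnostics: list | None = None,
) -> list[FittedPeak]:
    """Detect local maxima and fit them as Gaussian epitope bands.

    Candidate peaks are local maxima whose prominence exceeds
    ``prominence_k`` times the robust noise SD.  Nearby candidates (within
    ``cluster_gap_nm``) are fitted jointly as a multi-Gaussian with a
    shared constant baseline.  A broad single peak is refitted with two
    components and the split is kept only if an F-test on the residual
    variance passes at ``f_alpha``.  Non-converged clusters are excluded
    from the result, logged, and reported through ``diagnostics``.
    """
    if channel not in profile.channels:
        raise ProfileError(f"channel {channel!r} not present (have {list(profile.channels)})")
    y = np.asarray(profile.channels[channel], dtype=float)
    x = profile.positions
    if y.size < 20:
        raise ProfileError("profile too short (need >= 20 samples)")
    # candidate maxima with a heteroscedastic significance threshold: a
    # candidate's prominence must exceed prominence_k times the larger of
    # the local and global noise scales, with a floor relative to the
    # strongest peak so isolated single-count fluctuations on an empty
    # baseline cannot qualify.
    global_sd = estimate_noise_sd(y)
    window = max(3, int(round(config.local_noise_window_nm / profile.pixel_nm)))
    local_sd = local_noise_sd(y, window)
    distance = max(1, int(round(config.min_separation_nm / profile.pixel_nm)))
    idx, props = signal.find_peaks(y, prominence=1e-12, distance=distance)
    if idx.size == 0:
        return []
    prominences = props["prominences"]
    floor = config.rel_prominence_floor * float(prominences.max())
    threshold = config.prominence_k * np.maximum.reduce(
        [local_sd[idx], np.full(idx.shape, global_sd), np.full(idx.shape, floor)]
    )
    keep = prominences >= np.maximum(threshold, 1e-12)
    idx = idx[keep]
    if idx.size == 0:
        return []
    height_floor = config.prominence_k * max(global_sd, floor)

    # group candidate maxima into clusters fitted jointly
    clusters: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if x[i] - x[clusters[-1][-1]] <= config.cluster_gap_nm:
            clusters[-1].append(int(i))
        else:
            clusters.append([int(i)])

    peaks: list[FittedPeak] = []
    for ci, cluster in enumerate(clusters):
        left_lim = x[0] if ci == 0 else (x[cluster[0]] + x[clusters[ci - 1][-1]]) / 2.0
        right_lim = x[-1] if ci == len(clusters) - 1 else (x[cluster[-1]] + x[clusters[ci + 1][0]]) / 2.0
        lo = max(left_lim, x[cluster[0]] - config.window_pad_nm)
        hi = min(right_lim, x[cluster[-1]] + config.window_pad_nm)
        sel = (x >= lo) & (x <= hi)
        xs, ys = x[sel], y[sel]
        centers = [x[i] for i in cluster]
        if xs.size < 3 * len(centers) + 2:
            continue
        try:
            popt, pcov, rss = _fit_cluster(xs, ys, centers, config)
        except RuntimeError as exc:
            logger.warning("fit non-convergence in %s cluster at %.0f-%.0f nm: %s",
                           channel, lo, hi, exc)
            if diagnostics is not None:
                diagnostics.append({"channel": channel, "window_nm": (lo, hi),
                                    "reason": "fit_non_convergence"})
            continue
        flags: list[str] = []
        if len(centers) == 1:
            fwhm = popt[3] * SIGMA_TO_FWHM
            if config.shoulder_split and fwhm > config.shoulder_fwhm_factor * config.init_fwhm_nm:
                split = _try_shoulder_split(xs, ys, popt, rss, config)
                if split is not None:
                    popt, pcov, rss = split
                    flags.append("shoulder_split")
        for pk in _peaks_from_fit(channel, popt, pcov, flags):
            if pk.height < height_floor:
                continue  # fitted component below the significance floor
            if (config.unresolved_fwhm_factor is not None
                    and pk.fwhm_nm > config.unresolved_fwhm_factor * config.init_fwhm_nm
                    and "shoulder_split" not in pk.flags):
                pk = replace(pk, flags=pk.flags + ("unresolved",))
            peaks.append(pk)
    return sorted(peaks, key=lambda p: p.center_nm)


def _try_shoulder_split(xs, ys, popt1, rss1, config: FitConfig):
    """Refit a broad single Gaussian as two; keep only if the F-test passes."""
    cen, sig = popt1[2], popt1[3]
    try:
        popt2, pcov2, rss2 = _fit_cluster(xs, ys, [cen - sig / 2, cen + sig / 2], config)
    except RuntimeError:
        return None
    n = xs.size
    p1, p2 = 4, 7
    if rss2 >= rss1 or n <= p2:
        return None
    if rss2 <= 0:  # perfect two-component fit
        return popt2, pcov2, rss2
    f = ((rss1 - rss2) / (p2 - p1)) / (rss2 / (n - p2))
    p_value = sstats.f.sf(f, p2 - p1, n - p2)
    if p_value < config.f_alpha:
        return popt2, pcov2, rss2
    return None


# ---------------------------------------------------------------------------
# sarcomere assignment and QC
# ---------------------------------------------------------------------------

def assign_sarcomeres(
    mir_peaks: Sequence[FittedPeak],
    a170_peaks: Sequence[FittedPeak],
    config: AssignConfig = AssignConfig(),
    genotype: str | None = None,
) -> list[SarcomereMeasurement]:
    """Match the per-sarcomere epitope grammar ``[MIR, A170, A170, MIR]``.

    A sarcomere is a MIR pair with no other MIR between, bounding exactly
    one A170 doublet whose separation lies in ``doublet_window_nm``.  The
    M-line is the doublet midpoint; sarcomere length is taken from
    consecutive M positions (interior sarcomeres average their two
    neighbouring gaps, terminal ones use their single neighbour).
    Overlapping candidate matches are resolved by smallest MIR span, then
    leftmost.  Fewer than two matches yields an empty result (no SL is
    measurable) and a log diagnostic.
    """
    mir = sorted(mir_peaks, key=lambda p: p.center_nm)
    a170 = sorted(a170_peaks, key=lambda p: p.center_nm)
    lo_sep, hi_sep = config.doublet_window_nm

    candidates = []
    for i in range(len(mir) - 1):
        left, right = mir[i], mir[i + 1]
        inside = [p for p in a170 if left.center_nm < p.center_nm < right.center_nm]
        if inside:
            h_max = max(p.height for p in inside)
            inside = [p for p in inside if p.height >= config.relative_height_floor * h_max]
        best = None
        mir_mid = (left.center_nm + right.center_nm) / 2.0
        for j in range(len(inside) - 1):
            a, b = inside[j], inside[j + 1]
            sep = b.center_nm - a.center_nm
            if not lo_sep <= sep <= hi_sep:
                continue
            mid = (a.center_nm + b.center_nm) / 2.0
            score = abs(mid - mir_mid)
            if best is None or score < best[0]:
                best = (score, a, b)
        if best is not None:
            candidates.append((left, best[1], best[2], right))

    # resolve overlapping matches by smallest MIR-to-MIR span, then leftmost
    candidates.sort(key=lambda q: (q[3].center_nm - q[0].center_nm, q[0].center_nm))
    accepted: list[tuple[FittedPeak, FittedPeak, FittedPeak, FittedPeak]] = []
    for quad in candidates:
        span = (quad[0].center_nm, quad[3].center_nm)
        if any(not (span[1] <= a[0].center_nm or span[0] >= a[3].center_nm) for a in accepted):
            continue
        accepted.append(quad)
    accepted.sort(key=lambda q: q[0].center_nm)

    if len(accepted) < 2:
        logger.info("sarcomere assignment: %d grammar match(es); need >= 2 to measure SL",
                    len(accepted))
        return []

    m_positions = [(q[1].center_nm + q[2].center_nm) / 2.0 for q in accepted]
    gaps = np.diff(m_positions)
    measurements = []
    for k, quad in enumerate(accepted):
        if k == 0:
            sl = gaps[0]
        elif k == len(accepted) - 1:
            sl = gaps[-1]
        else:
            sl = (gaps[k - 1] + gaps[k]) / 2.0
        mir_l, a_l, a_r, mir_r = quad
        sep = a_r.center_nm - a_l.center_nm
        meas = SarcomereMeasurement(
            sl_nm=float(sl),
            aband_titin_len_nm=mir_r.center_nm - mir_l.center_nm,
            m_position_nm=m_positions[k],
            dtk_nm=sep / 2.0,
            a170_separation_nm=sep,
            mir_fwhm_nm=(mir_l.fwhm_nm + mir_r.fwhm_nm) / 2.0,
            a170_fwhm_nm=(a_l.fwhm_nm + a_r.fwhm_nm) / 2.0,
            a170_over_mir_intensity=None,
            qc_pass=True,
            qc_reasons=(),
            genotype=genotype,
            peaks={"mir_left": mir_l, "a170_left": a_l, "a170_right": a_r, "mir_right": mir_r},
        )
        mir_h = (mir_l.height + mir_r.height) / 2.0
        a_h = (a_l.height + a_r.height) / 2.0
        meas.mir_fwhm_over_height = meas.mir_fwhm_nm / mir_h if mir_h > 0 else None
        meas.a170_fwhm_over_height = meas.a170_fwhm_nm / a_h if a_h > 0 else None
        measurements.append(meas)
    return measurements


def qc_filter(
    measurement: SarcomereMeasurement,
    threshold: float = 0.20,
) -> tuple[bool, tuple[str, ...]]:
    """Apply the across-the-M-line intensity-fluctuation rule.

    For each channel the fluctuation is |h_left − h_right| / mean(h_left,
    h_right); the sarcomere fails if the fluctuation of either the MIR or
    the A170 epitope pair exceeds ``threshold``.  The measurement's
    ``qc_pass``/``qc_reasons`` fields are updated in place and returned.
    """
    reasons: list[str] = []
    pairs = {"MIR": ("mir_left", "mir_right"), "A170": ("a170_left", "a170_right")}
    for name, (lk, rk) in pairs.items():
        left = measurement.peaks.get(lk)
        right = measurement.peaks.get(rk)
        if left is None or right is None:
            reasons.append("incomplete")
            continue
        mean_h = (left.height + right.height) / 2.0
        if mean_h <= 0:
            reasons.append("incomplete")
            continue
        fluctuation = abs(left.height - right.height) / mean_h
        if fluctuation > threshold:
            reasons.append(name)
    passed = not reasons
    measurement.qc_pass = passed
    measurement.qc_reasons = tuple(reasons)
    return passed, tuple(reasons)


def normalize_a170_intensity(measurement: SarcomereMeasurement) -> float:
    """A170/MIR intensity ratio of one sarcomere from baseline-corrected heights."""
    p = measurement.peaks
    try:
        mir_h = (p["mir_left"].height + p["mir_right"].height) / 2.0
        a_h = (p["a170_left"].height + p["a170_right"].height) / 2.0
    except KeyError as exc:
        raise ProfileError(f"measurement lacks peak {exc.args[0]!r}") from None
    if mir_h <= 0:
        raise ProfileError("MIR height is zero; A170/MIR ratio undefined")
    ratio = a_h / mir_h
    measurement.a170_over_mir_intensity = ratio
    return ratio


def intensity_ratio_contrast(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Between-group ratio and percent reduction of two mean intensity ratios.

    Returns ``(mean_a / mean_b, 100 × (1 − mean_a / mean_b))``.
    """
    if mean_b == 0:
        raise ProfileError("reference mean is zero")
    ratio = mean_a / mean_b
    return ratio, 100.0 * (1.0 - ratio)


def measure_profile(
    profile: IntensityProfile,
    fit_config: FitConfig = FitConfig(),
    assign_config: AssignConfig = AssignConfig(),
    diagnostics: list | None = None,
) -> list[SarcomereMeasurement]:
    """Full per-profile pipeline: fit both channels, assign, QC, intensity ratio."""
    mir = detect_and_fit_peaks(profile, MIR_CHANNEL, fit_config, diagnostics)
    a170 = detect_and_fit_peaks(profile, A170_CHANNEL, fit_config, diagnostics)
    measurements = assign_sarcomeres(
        mir, a170, assign_config, genotype=profile.metadata.get("genotype")
    )
    for meas in measurements:
        qc_filter(meas, assign_config.qc_threshold)
        if meas.qc_pass:
            normalize_a170_intensity(meas)
    return measurements
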