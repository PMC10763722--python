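"""Seeded generators for STED-like sarcomere profiles and titin gel lanes.

The STED generator draws per-molecule epitope positions from the
:mod:`~titinsted.geometry` layout model — six titin molecules per half
thick filament, a Bernoulli truncation draw per molecule in TTNtv+
sarcomeres, Gaussian registration jitter per epitope — convolves them
with a 1D Gaussian point-spread function (40 nm FWHM by default) on a
uniform pixel grid, and applies Poisson shot noise at a configurable
photon scale.  Truncated molecules carry no A170 epitope and a Z-ward
shifted MIR epitope, so the A170 channel loses intensity while the MIR
channel broadens.

The gel generator renders lanes as area-normalised Gaussian bands at
migration distances given by a log-linear mobility law, on a linear
background ramp with additive Gaussian read noise.

Every generator records its ground truth and is bit-reproducible from its
seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import (
    EpitopeLayout,
    GenotypeParams,
    expected_positions,
    genotype_defaults,
)
from .profiler import IntensityProfile

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

MIR_CHANNEL = "mir"
A170_CHANNEL = "a170"


class SimulationError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class StedSimParams:
    """Parameters of one simulated two-channel sarcomere line profile.

    ``genotype`` may be a label (resolved through the default parameter
    table) or an explicit :class:`GenotypeParams`.  ``sl_um`` is a single
    sarcomere length here; stretch series are built by
    :func:`simulate_stretch_series`.
    """

    genotype: str | GenotypeParams = "TTNTV_NEG"
    sl_um: float = 1.8
    n_sarcomeres_per_profile: int = 4
    n_titin_per_half_filament: int = 6
    psf_fwhm_nm: float = 40.0
    pixel_nm: float = 10.0
    registration_jitter_sd_nm: float = 15.0
    peak_photon_count: float = 400.0
    labeling_efficiency: float = 1.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm <= 0:
            raise SimulationError("psf_fwhm_nm must be > 0")
        if self.pixel_nm > self.psf_fwhm_nm / 2:
            raise SimulationError(
                f"pixel_nm {self.pixel_nm} violates Nyquist-safe sampling "
                f"(must be <= psf_fwhm_nm/2 = {self.psf_fwhm_nm / 2})"
            )
        if self.n_sarcomeres_per_profile < 3:
            raise SimulationError("n_sarcomeres_per_profile must be >= 3")
        if self.n_titin_per_half_filament < 1:
            raise SimulationError("n_titin_per_half_filament must be >= 1")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise SimulationError("labeling_efficiency must lie in [0, 1]")
        if self.registration_jitter_sd_nm < 0:
            raise SimulationError("registration_jitter_sd_nm must be >= 0")

    def genotype_params(self) -> GenotypeParams:
        if isinstance(self.genotype, GenotypeParams):
            return self.genotype
        return genotype_defaults(self.genotype)


@dataclass(frozen=True)
class GroundTruth:
    """Recorded generative state of one simulated profile."""

    layouts: tuple[EpitopeLayout, ...]
    fluorophores: dict[str, np.ndarray]  # channel -> axial positions (nm)
    noiseless: dict[str, np.ndarray]     # channel -> noiseless intensity
    sl_um: float
    genotype_label: str


def _gaussian_bands(grid: np.ndarray, centers: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """Sum of equal-amplitude Gaussian kernels over ``centers`` on ``grid``."""
    if centers.size == 0:
        return np.zeros_like(grid)
    d = grid[:, None] - centers[None, :]
    return amplitude * np.exp(-0.5 * (d / sigma) ** 2).sum(axis=1)


def simulate_profile(params: StedSimParams) -> tuple[IntensityProfile, GroundTruth]:
    """Render one two-channel sarcomere line profile with recorded ground truth.

    The profile spans ``n_sarcomeres_per_profile`` sarcomeres plus a
    half-sarcomere margin on each side, so edge sarcomeres can be excluded
    by the assignment grammar downstream.
    """
    geno = params.genotype_params()
    base = expected_positions(geno, params.sl_um)
    sl_nm = base.sl_nm
    margin = sl_nm / 2.0
    n = params.n_sarcomeres_per_profile
    span = n * sl_nm + 2 * margin
    grid = np.arange(0.0, span + params.pixel_nm / 2, params.pixel_nm)
    rng = np.random.default_rng(params.seed)
    sigma = params.psf_fwhm_nm * FWHM_TO_SIGMA
    per_mol_amp = params.peak_photon_count / params.n_titin_per_half_filament

    layouts = []
    mir_pos: list[float] = []
    a170_pos: list[float] = []
    for k in range(n):
        layout = base.shifted(margin + k * sl_nm)
        layouts.append(layout)
        # each half-sarcomere carries its own complement of titin molecules
        for side in (0, 1):
            truncated = rng.random(params.n_titin_per_half_filament) < geno.trunc_fraction
            for is_trunc in truncated:
                if is_trunc:
                    mir_layout = layout.mir_trunc_nm[side]  # type: ignore[index]
                else:
                    mir_layout = layout.mir_full_nm[side]
                if rng.random() < params.labeling_efficiency:
                    mir_pos.append(mir_layout + rng.normal(0.0, params.registration_jitter_sd_nm)
                                   if params.registration_jitter_sd_nm > 0 else mir_layout)
                if not is_trunc and rng.random() < params.labeling_efficiency:
                    a_layout = layout.a170_nm[side]
                    a170_pos.append(a_layout + rng.normal(0.0, params.registration_jitter_sd_nm)
                                    if params.registration_jitter_sd_nm > 0 else a_layout)

    fluorophores = {
        MIR_CHANNEL: np.asarray(mir_pos, dtype=float),
        A170_CHANNEL: np.asarray(a170_pos, dtype=float),
    }
    noiseless = {
        ch: _gaussian_bands(grid, pos, per_mol_amp, sigma) for ch, pos in fluorophores.items()
    }
    if params.poisson_noise:
        channels = {ch: rng.poisson(y).astype(float) for ch, y in noiseless.items()}
    else:
        channels = {ch: y.copy() for ch, y in noiseless.items()}

    profile = IntensityProfile(
        positions=grid,
        channels=channels,
        metadata={
            "source": "simulate_profile",
            "pixel_nm": params.pixel_nm,
            "genotype": geno.label,
            "sl_um": params.sl_um,
            "seed": params.seed,
        },
    )
    truth = GroundTruth(
        layouts=tuple(layouts),
        fluorophores=fluorophores,
        noiseless=noiseless,
        sl_um=params.sl_um,
        genotype_label=geno.label,
    )
    return profile, truth


def simulate_stretch_series(
    params: StedSimParams,
    sl_um_values: Sequence[float],
    n_profiles_per_sl: int,
) -> list[tuple[IntensityProfile, GroundTruth]]:
    """Independent profiles at each sarcomere length of a stretch series.

    Child seeds are derived deterministically from the master seed as
    ``params.seed + running_index``, so the same master seed reproduces the
    whole dataset bit-for-bit.
    """
    dataset: list[tuple[IntensityProfile, GroundTruth]] = []
    index = 0
    for sl in sl_um_values:
        for _ in range(n_profiles_per_sl):
            child = replace(params, sl_um=sl, seed=params.seed + index)
            dataset.append(simulate_profile(child))
            index += 1
    return dataset


def profile_to_image(
    profile: IntensityProfile,
    truth: GroundTruth,
    n_rows: int = 21,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Render a profile's noiseless trace as a 2D two-channel image.

    Epitope bands run as straight lines across ``n_rows`` transverse
    pixels with the same axial PSF; Poisson noise is drawn independently
    per pixel.  Useful for exercising thick-line profile extraction.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for ch, y in truth.noiseless.items():
        img = np.tile(y, (n_rows, 1))
        out[ch] = rng.poisson(img).astype(float)
    return out


# ---------------------------------------------------------------------------
# gel lanes
# ---------------------------------------------------------------------------

#: default TTNtv+ lane composition: (label, MW kDa, quantity in OD·mm).
#: The truncated band carries 0.19 × T1 (T1 = N2BA + N2B) and its MW equals
#: the average-mass prediction for a truncation at residue 14,000.
DEFAULT_TTNTV_POS_BANDS = (
    ("N2BA", 3300.0, 0.5),
    ("N2B", 3000.0, 0.5),
    ("T2", 2200.0, 0.3),
    ("truncated", 1555.4, 0.19),
    ("MyHC", 223.0, 2.5),
)

#: default log-linear mobility law: migration_mm = intercept + slope*log10(MW)
DEFAULT_GEL_CALIBRATION = (100.0, -26.0)


@dataclass(frozen=True)
class GelSimParams:
    """Parameters of one simulated densitometric gel lane."""

    band_set: tuple[tuple[str, float, float], ...] = DEFAULT_TTNTV_POS_BANDS
    calibration: tuple[float, float] = DEFAULT_GEL_CALIBRATION
    band_width_mm: float = 0.3
    background: tuple[float, float] = (0.02, 0.001)  # (offset OD, ramp OD/mm)
    noise_sd: float = 0.005
    lane_span_mm: tuple[float, float] = (0.0, 45.0)
    sample_step_mm: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration[1] >= 0:
            raise SimulationError("mobility slope must be negative (migration decreases with log MW)")
        for label, mw, q in self.band_set:
            if mw <= 0:
                raise SimulationError(f"band {label!r} has non-positive MW")
            if q < 0:
                raise SimulationError(f"band {label!r} has negative quantity")
        if self.band_width_mm <= 0:
            raise SimulationError("band_width_mm must be > 0")

    def migration_mm(self, mw_kda: float) -> float:
        intercept, slope = self.calibration
        return intercept + slope * math.log10(mw_kda)


@dataclass(frozen=True)
class GelGroundTruth:
    band_areas: dict[str, float]
    band_migrations_mm: dict[str, float]
    background: tuple[float, float]
    merge_risk: tuple[str, ...] = ()


def simulate_gel_lane(params: GelSimParams):
    """Render one lane: OD(x) = background + area-normalised Gaussian bands + noise.

    Returns ``(GelLaneProfile, GelGroundTruth)``.  Bands whose centres lie
    closer than half a band width are flagged as merge risks in the ground
    truth and a warning is emitted.
    """
    from .densitometry import GelLaneProfile  # local import to avoid a cycle

    lo, hi = params.lane_span_mm
    x = np.arange(lo, hi + params.sample_step_mm / 2, params.sample_step_mm)
    offset, ramp = params.background
    od = offset + ramp * x
    migrations = {}
    for label, mw, q in params.band_set:
        m = params.migration_mm(mw)
        migrations[label] = m
        od = od + q * np.exp(-0.5 * ((x - m) / params.band_width_mm) ** 2) / (
            params.band_width_mm * math.sqrt(2 * math.pi)
        )
    merge_risk = []
    labels = [b[0] for b in params.band_set]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if abs(migrations[labels[i]] - migrations[labels[j]]) < 0.5 * params.band_width_mm:
                merge_risk.append((labels[i], labels[j]))
    if merge_risk:
        warnings.warn(f"bands at merge-risk separation: {merge_risk}", stacklevel=2)
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    lane = GelLaneProfile(migration_mm=x, od=od, lane_id=f"sim-{params.seed}")
    truth = GelGroundTruth(
        band_areas={label: q for label, _, q in params.band_set},
        band_migrations_mm=migrations,
        background=params.background,
        merge_risk=tuple(f"{a}/{b}" for a, b in merge_risk),
    )
    return lane, truth
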