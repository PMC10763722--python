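"""Genotype-parameterized model of titin epitope axial positions.

A single titin molecule spans a half-sarcomere from the Z-disk to the
M-line.  Two sequence-specific antibody epitopes are modelled: MIR at the
I/A junction (so the MIR-to-MIR distance across one sarcomere is the
apparent A-band titin length) and A170 in the kinase-adjacent A168–A170
region near the M-line (so half the A170 doublet separation is the
M-line-to-titin-kinase distance, d_TK).

Both distances are treated as affine functions of sarcomere length (SL)
over the physiological working range, with genotype-specific slack values
and slopes.  Truncated titin molecules (present only in the TTNtv+
genotype) carry a MIR epitope that is displaced toward the Z-disk and no
A170 epitope at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

NM_PER_UM = 1000.0

#: sarcomere length at slack, the reference point of every affine law (µm)
SLACK_SL_UM = 1.8

#: admissible sarcomere-length interval (µm)
SL_RANGE_UM = (1.6, 3.0)

GENOTYPES = ("TTNTV_NEG", "TTNTV_POS", "CONTROL")


class GeometryError(ValueError):
    """Raised for out-of-range sarcomere lengths or inconsistent parameters."""


@dataclass(frozen=True)
class GenotypeParams:
    """Affine epitope-position model for one genotype.

    Parameters
    ----------
    label
        One of ``TTNTV_NEG``, ``TTNTV_POS``, ``CONTROL``.
    aband_len_slack_nm
        Apparent A-band titin length (MIR-to-MIR across the M-line) at the
        slack SL of 1.8 µm.
    aband_slope_nm_per_um
        Increase of the A-band titin length per µm of sarcomere length.
    dtk_slack_nm
        M-line-to-titin-kinase distance (half the A170 doublet separation)
        at slack.
    dtk_slope_nm_per_um
        Change of d_TK per µm of SL (negative for TTNtv+ sarcomeres).
    trunc_fraction
        Fraction of titin molecules that are truncated; 0 outside TTNTV_POS.
    trunc_mir_shift_slack_nm
        Extra Z-ward displacement of the MIR epitope of truncated molecules
        at slack.
    trunc_shift_relax_nm_per_um
        Rate at which that displacement closes with stretch; the shift is
        clamped at zero.
    """

    label: str = "TTNTV_NEG"
    aband_len_slack_nm: float = 1400.0
    aband_slope_nm_per_um: float = 236.0
    dtk_slack_nm: float = 70.0
    dtk_slope_nm_per_um: float = 25.0
    trunc_fraction: float = 0.0
    trunc_mir_shift_slack_nm: float = 0.0
    trunc_shift_relax_nm_per_um: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in GENOTYPES:
            raise GeometryError(f"unknown genotype label {self.label!r}; expected one of {GENOTYPES}")
        for name in ("aband_len_slack_nm", "dtk_slack_nm", "trunc_mir_shift_slack_nm"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")
        if not 0.0 <= self.trunc_fraction <= 1.0:
            raise GeometryError("trunc_fraction must lie in [0, 1]")
        if self.label in ("TTNTV_NEG", "CONTROL") and self.trunc_fraction != 0.0:
            raise GeometryError(f"trunc_fraction must be 0 for genotype {self.label}")

    # -- affine laws ----------------------------------------------------

    def aband_len_nm(self, sl_um: float) -> float:
        """Apparent A-band titin length (MIR-to-MIR) at sarcomere length ``sl_um``."""
        return self.aband_len_slack_nm + self.aband_slope_nm_per_um * (sl_um - SLACK_SL_UM)

    def dtk_nm(self, sl_um: float) -> float:
        """M-line-to-titin-kinase distance at sarcomere length ``sl_um``."""
        return self.dtk_slack_nm + self.dtk_slope_nm_per_um * (sl_um - SLACK_SL_UM)

    def trunc_mir_shift_nm(self, sl_um: float) -> float:
        """Z-ward MIR displacement of truncated molecules; non-negative, closes with stretch."""
        shift = self.trunc_mir_shift_slack_nm - self.trunc_shift_relax_nm_per_um * (sl_um - SLACK_SL_UM)
        return max(0.0, shift)


#: default parameter sets per genotype.  TTNTV_NEG carries the measured
#: slack values (1,400 nm A-band titin length, 70 nm d_TK) and slopes
#: (236 nm/µm A-band extension; d_TK +25 nm/µm, i.e. +20 nm from SL 1.8 to
#: 2.6 µm).  TTNTV_POS halves the full-length complement, starts d_TK
#: ~10 nm further out, extends its A-band less steeply and shows a negative
#: d_TK slope; its truncated molecules sit 30 nm Z-ward of the full-length
#: MIR at slack, a displacement that relaxes with stretch.  CONTROL shows a
#: 44 nm A-band intercept offset and a flat d_TK.
_DEFAULTS = {
    "TTNTV_NEG": GenotypeParams(label="TTNTV_NEG"),
    "TTNTV_POS": GenotypeParams(
        label="TTNTV_POS",
        aband_slope_nm_per_um=150.0,
        dtk_slack_nm=80.0,
        dtk_slope_nm_per_um=-12.0,
        trunc_fraction=0.5,
        trunc_mir_shift_slack_nm=30.0,
        trunc_shift_relax_nm_per_um=35.0,
    ),
    "CONTROL": GenotypeParams(
        label="CONTROL",
        aband_len_slack_nm=1444.0,
        dtk_slope_nm_per_um=0.0,
    ),
}


def genotype_defaults(label: str, **overrides) -> GenotypeParams:
    """Return the default :class:`GenotypeParams` for ``label``, with overrides."""
    if label not in _DEFAULTS:
        raise GeometryError(f"unknown genotype label {label!r}; expected one of {GENOTYPES}")
    params = _DEFAULTS[label]
    return replace(params, **overrides) if overrides else params


@dataclass(frozen=True)
class EpitopeLayout:
    """Expected epitope positions of one sarcomere, mirror-symmetric about the M-line.

    All coordinates are nm along the myofibril axis with the left Z-disk at 0.
    ``mir_full_nm`` / ``a170_nm`` are (left, right) pairs of the full-length
    molecules; ``mir_trunc_nm`` is the truncated-molecule MIR pair or ``None``.
    """

    sl_nm: float
    z_positions_nm: tuple[float, float]
    m_position_nm: float
    mir_full_nm: tuple[float, float]
    a170_nm: tuple[float, float]
    mir_trunc_nm: tuple[float, float] | None = None

    @property
    def a170_separation_nm(self) -> float:
        return self.a170_nm[1] - self.a170_nm[0]

    @property
    def dtk_nm(self) -> float:
        return self.a170_separation_nm / 2.0

    @property
    def aband_titin_len_nm(self) -> float:
        return self.mir_full_nm[1] - self.mir_full_nm[0]

    def shifted(self, offset_nm: float) -> "EpitopeLayout":
        """Return the same layout translated along the axis by ``offset_nm``."""
        pair = lambda p: (p[0] + offset_nm, p[1] + offset_nm)
        return EpitopeLayout(
            sl_nm=self.sl_nm,
            z_positions_nm=pair(self.z_positions_nm),
            m_position_nm=self.m_position_nm + offset_nm,
            mir_full_nm=pair(self.mir_full_nm),
            a170_nm=pair(self.a170_nm),
            mir_trunc_nm=None if self.mir_trunc_nm is None else pair(self.mir_trunc_nm),
        )


def expected_positions(params: GenotypeParams, sl_um: float) -> EpitopeLayout:
    """Expected axial epitope positions at sarcomere length ``sl_um`` (µm).

    The M-line sits at SL/2; full-length MIR epitopes at M ± L_A(SL)/2,
    A170 epitopes at M ± d_TK(SL), and (when ``trunc_fraction > 0``) the
    truncated-molecule MIR pair is displaced Z-ward from the full-length
    pair by the genotype's shift law.
    """
    lo, hi = SL_RANGE_UM
    if not lo <= sl_um <= hi:
        raise GeometryError(f"sarcomere length {sl_um} µm outside the working range [{lo}, {hi}] µm")
    sl_nm = sl_um * NM_PER_UM
    la = params.aband_len_nm(sl_um)
    if la >= sl_nm:
        raise GeometryError(
            f"A-band titin length {la:.1f} nm >= sarcomere length {sl_nm:.1f} nm; inconsistent parameters"
        )
    dtk = params.dtk_nm(sl_um)
    if dtk < 0:
        raise GeometryError(f"d_TK(SL={sl_um}) = {dtk:.1f} nm is negative; inconsistent parameters")
    m = sl_nm / 2.0
    mir_full = (m - la / 2.0, m + la / 2.0)
    a170 = (m - dtk, m + dtk)
    mir_trunc = None
    if params.trunc_fraction > 0:
        shift = params.trunc_mir_shift_nm(sl_um)
        # Z-ward: left-half molecules move toward the left Z-disk, right-half
        # molecules toward the right one.
        mir_trunc = (mir_full[0] - shift, mir_full[1] + shift)
    return EpitopeLayout(
        sl_nm=sl_nm,
        z_positions_nm=(0.0, sl_nm),
        m_position_nm=m,
        mir_full_nm=mir_full,
        a170_nm=a170,
        mir_trunc_nm=mir_trunc,
    )


def layouts_for_series(params: GenotypeParams, sl_um_values: Sequence[float]) -> list[EpitopeLayout]:
    """Convenience: expected layouts for a stretch series of sarcomere lengths."""
    return [expected_positions(params, sl) for sl in sl_um_values]
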