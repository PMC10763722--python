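"""Residue-coordinate model of the titin IC isoform.

Titin isoform IC comprises 35,991 amino acids spanning the half-sarcomere
from the Z-disk to the M-line.  This module classifies protein positions
into sarcomeric band regions, types variant consequences from
HGVS-protein-like descriptions, and predicts the molecular mass of the
truncated protein produced by a premature stop.

Region boundaries are configurable; the packaged defaults are anchored to
the residue ranges of the four sequence-specific antibody epitopes (T12,
MIR, A170, M8M10) so that each epitope falls inside exactly one region.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

#: mean average residue mass (Da) used when no sequence is available
MEAN_RESIDUE_MASS_DA = 111.1

#: average mass of one water molecule (Da), added once per chain
WATER_MASS_DA = 18.02

#: average (isotope-abundance weighted) residue masses, Da.  A residue mass
#: is the free amino-acid mass minus one water.
AVERAGE_RESIDUE_MASS_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

CONSEQUENCES = ("frameshift", "nonsense", "splice", "other")


class IsoformError(ValueError):
    """Raised for invalid residue coordinates or malformed model definitions."""


@dataclass(frozen=True)
class TitinIsoformModel:
    """Band-region map of a titin isoform in protein (residue) coordinates.

    ``region_boundaries`` is an ordered list of ``(label, first, last)``
    with 1-based inclusive residue bounds; regions must be contiguous,
    non-overlapping and cover ``[1, total_residues]`` exactly (the boundary
    residue ``last`` belongs to the earlier region).
    """

    total_residues: int = 35991
    region_boundaries: tuple[tuple[str, int, int], ...] = ()
    epitope_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.total_residues < 1:
            raise IsoformError("total_residues must be >= 1")
        if not self.region_boundaries:
            raise IsoformError("region_boundaries must be non-empty")
        expected_first = 1
        for label, first, last in self.region_boundaries:
            if first != expected_first:
                raise IsoformError(
                    f"region {label!r} starts at {first}, expected {expected_first}: "
                    "regions must tile the isoform contiguously"
                )
            if last < first:
                raise IsoformError(f"region {label!r} has last < first")
            expected_first = last + 1
        if expected_first != self.total_residues + 1:
            raise IsoformError(
                f"regions end at {expected_first - 1}, expected {self.total_residues}"
            )
        for name, (first, last) in self.epitope_ranges.items():
            r1 = self.region_of(first)
            r2 = self.region_of(last)
            if r1 != r2:
                raise IsoformError(
                    f"epitope {name!r} ({first}-{last}) straddles regions {r1!r} and {r2!r}"
                )
        if self.sequence is not None and len(self.sequence) != self.total_residues:
            raise IsoformError(
                f"sequence length {len(self.sequence)} != total_residues {self.total_residues}"
            )

    def region_of(self, residue: int) -> str:
        return classify_variant_region(self, residue)


def load_isoform_model(path: str | Path | None = None, sequence: str | None = None) -> TitinIsoformModel:
    """Load an isoform model from JSON; the packaged IC-isoform map by default."""
    if path is None:
        raw = resources.files("titinsted.data").joinpath("isoform_ic.json").read_text()
    else:
        raw = Path(path).read_text()
    spec = json.loads(raw)
    return TitinIsoformModel(
        total_residues=int(spec["total_residues"]),
        region_boundaries=tuple((str(l), int(a), int(b)) for l, a, b in spec["region_boundaries"]),
        epitope_ranges={str(k): (int(a), int(b)) for k, (a, b) in spec["epitope_ranges"].items()},
        sequence=sequence,
    )


def read_fasta_sequence(path: str | Path) -> str:
    """Read the first record of a FASTA file as an upper-case amino-acid string."""
    seq_lines: list[str] = []
    with open(path) as fh:
        started = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if started:
                    break
                started = True
                continue
            seq_lines.append(line)
    if not seq_lines:
        raise IsoformError(f"no sequence found in FASTA file {path}")
    return "".join(seq_lines).upper()


def classify_variant_region(model: TitinIsoformModel, residue: int) -> str:
    """Label of the unique band region containing 1-based ``residue``."""
    if not 1 <= residue <= model.total_residues:
        raise IsoformError(
            f"residue {residue} outside the valid interval [1, {model.total_residues}]"
        )
    for label, first, last in model.region_boundaries:
        if first <= residue <= last:
            return label
    raise AssertionError("unreachable: regions tile the isoform")  # pragma: no cover


def predict_truncated_mass(
    model: TitinIsoformModel,
    truncation_residue: int,
    mean_residue_mass_da: float = MEAN_RESIDUE_MASS_DA,
) -> float:
    """Predicted molecular mass (kDa) of the protein truncated after ``truncation_residue``.

    With a sequence on the model, the mass is the sum of average residue
    masses over residues 1..truncation_residue plus one water; otherwise the
    approximation ``truncation_residue × mean_residue_mass_da + water`` is
    used.  Strictly increasing in the truncation position either way.
    """
    if not 1 <= truncation_residue <= model.total_residues:
        raise IsoformError(
            f"truncation residue {truncation_residue} outside [1, {model.total_residues}]"
        )
    if model.sequence is not None:
        mass_da = sequence_mass_da(model.sequence[:truncation_residue])
    else:
        mass_da = truncation_residue * mean_residue_mass_da + WATER_MASS_DA
    return mass_da / 1000.0


def sequence_mass_da(sequence: str) -> float:
    """Average molecular mass (Da) of a polypeptide, including one water."""
    try:
        residue_sum = sum(AVERAGE_RESIDUE_MASS_DA[aa] for aa in sequence)
    except KeyError as exc:
        raise IsoformError(f"unknown amino-acid code {exc.args[0]!r}") from None
    return residue_sum + WATER_MASS_DA


_FS_RE = re.compile(r"fs", re.IGNORECASE)
_TER_RE = re.compile(r"(Ter\b|Ter\d*$|\*|(?<=\d)X$)", re.IGNORECASE)
_SPLICE_RE = re.compile(r"splic|\bspl\b", re.IGNORECASE)


def classify_consequence(description: str) -> str:
    """Map an HGVS-protein-like or keyword description to a consequence class.

    ``fs`` anywhere marks a frameshift (even when followed by ``Ter``);
    a termination token (``Ter``, ``*``, trailing ``X``) without a frame
    change is a nonsense variant; splice keywords map to ``splice``;
    anything else is ``other``.
    """
    if not description or not description.strip():
        raise IsoformError("empty variant description")
    text = description.strip()
    lowered = text.lower()
    if lowered in CONSEQUENCES:
        return lowered
    if lowered in ("stop_gained", "stopgain"):
        return "nonsense"
    if _FS_RE.search(text) or "frameshift" in lowered:
        return "frameshift"
    if _SPLICE_RE.search(text):
        return "splice"
    if _TER_RE.search(text) or "nonsense" in lowered:
        return "nonsense"
    return "other"


@dataclass(frozen=True)
class TruncationVariant:
    """One truncating (or candidate) variant in protein coordinates."""

    sample_id: str
    gene: str
    protein_position: int
    consequence: str
    zygosity: str = "het"
    region: str | None = None
    predicted_mass_kda: float | None = None

    def annotate(self, model: TitinIsoformModel) -> "TruncationVariant":
        """Return a copy with region and predicted truncated mass filled in."""
        return TruncationVariant(
            sample_id=self.sample_id,
            gene=self.gene,
            protein_position=self.protein_position,
            consequence=self.consequence,
            zygosity=self.zygosity,
            region=classify_variant_region(model, self.protein_position),
            predicted_mass_kda=predict_truncated_mass(model, self.protein_position),
        )


def annotate_variants(
    model: TitinIsoformModel, variants: Iterable[TruncationVariant]
) -> list[TruncationVariant]:
    return [v.annotate(model) for v in variants]
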