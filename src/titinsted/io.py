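"""CSV/TSV/TIFF readers and writers for profiles, measurements, and lanes.

All CSV writers emit a header and round-trip through their readers.
Distances are nm, sarcomere lengths are reported in µm in measurement
tables, gel migration in mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .densitometry import GelLaneProfile
from .profiler import IntensityProfile, SarcomereMeasurement

PROFILE_COLUMNS = ("position_nm", "mir_intensity", "a170_intensity")

MEASUREMENT_COLUMNS = (
    "sl_um",
    "aband_titin_len_nm",
    "m_position_nm",
    "dtk_nm",
    "a170_separation_nm",
    "mir_fwhm_nm",
    "a170_fwhm_nm",
    "a170_over_mir_intensity",
    "mir_fwhm_over_height",
    "qc_pass",
    "qc_reasons",
    "genotype",
)


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position_nm": profile.positions,
            "mir_intensity": profile.channels["mir"],
            "a170_intensity": profile.channels["a170"],
        }
    )
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> IntensityProfile:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV {path} lacks column(s) {missing}")
    positions = df["position_nm"].to_numpy(dtype=float)
    return IntensityProfile(
        positions=positions,
        channels={
            "mir": df["mir_intensity"].to_numpy(dtype=float),
            "a170": df["a170_intensity"].to_numpy(dtype=float),
        },
        metadata={"source": str(path),
                  "pixel_nm": float(positions[1] - positions[0])},
    )


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "sl_um": m.sl_nm / 1000.0,
                "aband_titin_len_nm": m.aband_titin_len_nm,
                "m_position_nm": m.m_position_nm,
                "dtk_nm": m.dtk_nm,
                "a170_separation_nm": m.a170_separation_nm,
                "mir_fwhm_nm": m.mir_fwhm_nm,
                "a170_fwhm_nm": m.a170_fwhm_nm,
                "a170_over_mir_intensity": m.a170_over_mir_intensity,
                "mir_fwhm_over_height": m.mir_fwhm_over_height,
                "qc_pass": m.qc_pass,
                "qc_reasons": ";".join(m.qc_reasons),
                "genotype": m.genotype,
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements_csv(measurements, path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lane_csv(lane: GelLaneProfile, path: str | Path) -> None:
    pd.DataFrame({"migration_mm": lane.migration_mm, "od": lane.od}).to_csv(path, index=False)


def read_lane_csv(path: str | Path, lane_id: str | None = None) -> GelLaneProfile:
    df = pd.read_csv(path)
    for col in ("migration_mm", "od"):
        if col not in df.columns:
            raise ValueError(f"lane CSV {path} lacks column {col!r}")
    return GelLaneProfile(
        migration_mm=df["migration_mm"].to_numpy(dtype=float),
        od=df["od"].to_numpy(dtype=float),
        lane_id=lane_id or str(path),
    )


def write_image_tiff(image: dict[str, np.ndarray], path: str | Path) -> None:
    """Write a channel dict as a multi-page TIFF (one page per channel, sorted)."""
    import tifffile

    names = sorted(image)
    stack = np.stack([image[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"channels": names})


def read_image_tiff(path: str | Path, channel_names=("a170", "mir")) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF into a channel dict (pages in sorted-name order)."""
    import tifffile

    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    names = sorted(channel_names)
    if stack.shape[0] != len(names):
        raise ValueError(f"TIFF {path} has {stack.shape[0]} pages, expected {len(names)}")
    return {n: stack[i].astype(float) for i, n in enumerate(names)}
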