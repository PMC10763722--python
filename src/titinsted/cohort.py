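"""Cohort-level summaries of truncating-variant screens.

Ingests per-sample variant tables (TSV: sample_id, gene, protein_position,
consequence, pathogenicity) and computes sample-level occurrence of TTN
truncating variants (TTNtv) and of qualifying variants in dilated-
cardiomyopathy (DCM) genes.  Counting is per sample: a sample carrying
several qualifying variants contributes once per category.

The packaged fixture is a synthetic cohort (the per-patient table of the
original screen is not public): 127 samples, 19 of them TTNtv carriers
(8 frameshift, 11 nonsense) and 35 carrying a qualifying variant in a DCM
gene, matching the tallies of the screen it emulates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .isoform import classify_consequence

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "gene", "protein_position", "consequence", "pathogenicity")

#: consequence classes that make a TTN variant truncating
TRUNCATING_CONSEQUENCES = frozenset({"frameshift", "nonsense", "splice"})

#: pathogenicity labels that make a variant qualify for counting
QUALIFYING_PATHOGENICITY = frozenset({"pathogenic", "likely_pathogenic", "novel_truncating"})

#: default DCM-associated gene set (the genes named in the screen)
DEFAULT_DCM_GENES = frozenset({
    "TTN", "LMNA", "DSP", "BAG3", "FKTN", "LAMA2",
    "MYBPC3", "MYH6", "MYH7", "PLN", "RBM20", "TNNI3",
})


class CohortError(ValueError):
    """Raised for malformed variant tables or empty cohorts."""


@dataclass(frozen=True)
class CohortTable:
    """Validated per-sample variant table."""

    samples: tuple[str, ...]
    variants: pd.DataFrame  # columns = REQUIRED_COLUMNS

    def __post_init__(self) -> None:
        known = set(self.samples)
        stray = set(self.variants["sample_id"]) - known
        if stray:
            raise CohortError(f"variants reference unknown samples: {sorted(stray)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CohortSummary:
    n_samples: int
    n_ttntv_pos: int
    pct_ttntv: float
    n_dcm_gene_pos: int
    pct_dcm_gene: float
    consequence_counts: dict[str, int] = field(default_factory=dict)
    per_gene_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_ttntv_pos": self.n_ttntv_pos,
            "pct_ttntv": self.pct_ttntv,
            "n_dcm_gene_pos": self.n_dcm_gene_pos,
            "pct_dcm_gene": self.pct_dcm_gene,
            "consequence_counts": dict(self.consequence_counts),
            "per_gene_counts": dict(self.per_gene_counts),
        }


def load_variant_table(
    path: str | Path,
    sample_manifest: str | Path | Sequence[str] | None = None,
) -> CohortTable:
    """Load and validate a variant TSV.

    ``sample_manifest`` supplies the full cohort sample list (a file with
    one sample id per line, or a sequence of ids); without it the cohort is
    taken to be the samples appearing in the table.  Rows failing
    validation are reported with their line numbers; duplicated
    (sample, gene, position, consequence) rows are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"variant table {path} lacks required column(s): {missing}")
    df = df[list(REQUIRED_COLUMNS)].copy()

    bad_rows: list[str] = []
    positions = pd.to_numeric(df["protein_position"], errors="coerce")
    for idx in df.index[positions.isna() | (positions < 1)]:
        # +2: one for the header line, one for 0-based indexing
        bad_rows.append(f"line {idx + 2}: non-positive or non-integer protein_position "
                        f"{df.at[idx, 'protein_position']!r}")
    if bad_rows:
        raise CohortError("invalid rows in variant table:\n" + "\n".join(bad_rows))
    df["protein_position"] = positions.astype(int)

    n_before = len(df)
    df = df.drop_duplicates(subset=["sample_id", "gene", "protein_position", "consequence"])
    if len(df) < n_before:
        warnings.warn(
            f"dropped {n_before - len(df)} duplicated variant row(s)", stacklevel=2
        )
    df = df.reset_index(drop=True)
    df["consequence_class"] = [classify_consequence(c) for c in df["consequence"]]

    if sample_manifest is None:
        samples: tuple[str, ...] = tuple(pd.unique(df["sample_id"]))
    elif isinstance(sample_manifest, (str, Path)):
        samples = tuple(
            line.strip() for line in Path(sample_manifest).read_text().splitlines() if line.strip()
        )
    else:
        samples = tuple(sample_manifest)
    return CohortTable(samples=samples, variants=df)


def load_cohort_fixture() -> CohortTable:
    """The packaged synthetic 127-sample cohort fixture."""
    data = resources.files("titinsted.data")
    with resources.as_file(data.joinpath("cohort_variants_synthetic.tsv")) as vp, \
            resources.as_file(data.joinpath("cohort_samples_synthetic.txt")) as sp:
        return load_variant_table(vp, sample_manifest=sp)


def summarize_cohort(
    table: CohortTable,
    dcm_genes: Iterable[str] = DEFAULT_DCM_GENES,
) -> CohortSummary:
    """Sample-level cohort summary.

    A sample is TTNtv+ if it carries >= 1 TTN variant whose consequence
    class is truncating (frameshift/nonsense/splice) and whose
    pathogenicity qualifies; it is DCM-gene-positive if it carries >= 1
    qualifying variant in the DCM gene set.  Each sample counts once per
    category regardless of how many qualifying variants it carries.
    """
    dcm_genes = frozenset(dcm_genes)
    if table.n_samples == 0:
        raise CohortError("empty cohort")
    if not dcm_genes:
        raise CohortError("empty DCM gene set")
    df = table.variants
    qualifying = df["pathogenicity"].isin(QUALIFYING_PATHOGENICITY)
    ttntv_rows = (
        (df["gene"] == "TTN")
        & df["consequence_class"].isin(TRUNCATING_CONSEQUENCES)
        & qualifying
    )
    dcm_rows = df["gene"].isin(dcm_genes) & qualifying

    ttntv_samples = set(df.loc[ttntv_rows, "sample_id"])
    dcm_samples = set(df.loc[dcm_rows, "sample_id"])
    n = table.n_samples
    consequence_counts = (
        df.loc[ttntv_rows, "consequence_class"].value_counts().to_dict()
    )
    per_gene_counts = df.loc[dcm_rows, "gene"].value_counts().to_dict()
    summary = CohortSummary(
        n_samples=n,
        n_ttntv_pos=len(ttntv_samples),
        pct_ttntv=100.0 * len(ttntv_samples) / n,
        n_dcm_gene_pos=len(dcm_samples),
        pct_dcm_gene=100.0 * len(dcm_samples) / n,
        consequence_counts=consequence_counts,
        per_gene_counts=per_gene_counts,
    )
    logger.info(
        "cohort summary: %d samples, %d TTNtv+ (%.1f%%), %d DCM-gene+ (%.1f%%)",
        n, summary.n_ttntv_pos, summary.pct_ttntv, summary.n_dcm_gene_pos, summary.pct_dcm_gene,
    )
    return summary
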