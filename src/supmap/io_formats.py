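"""Tables, configuration and file formats shared by all pipeline stages.

Internal genomic coordinates are 1-based inclusive (VCF convention); BED
export converts to 0-based half-open. The "alt" allele of an allele-count
table is, by convention, the wild-parent allele, so that downstream
frequency tracks are wild-allele frequencies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("supmap")

TEMPERATURES = ("permissive", "restrictive")

SCREEN_COLUMNS = [
    "query_id",
    "gene",
    "strain_id",
    "temperature",
    "biological_rep",
    "technical_rep",
    "plate",
    "row",
    "col",
    "colony_size",
]

SCREEN_KEY = ["query_id", "strain_id", "temperature", "biological_rep", "technical_rep"]


class FormatError(ValueError):
    """Raised when an input file violates a table contract."""


# ---------------------------------------------------------------------------
# Screen tables
# ---------------------------------------------------------------------------


@dataclass
class ScreenTable:
    """Replicated colony sizes from an SGA-style suppression screen.

    One row per (query allele, strain, temperature, biological replicate,
    technical replicate) colony. ``colony_size`` is in pixels; NaN marks a
    missing colony measurement (distinct from a size of 0, which is a dead
    pinning position).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"screen table missing columns: {missing}")
        df = self.data
        sizes = df["colony_size"]
        bad = sizes.dropna() < 0
        if bad.any():
            idx = bad[bad].index[0]
            raise FormatError(f"negative colony_size at row {idx}")
        bad_temp = ~df["temperature"].isin(TEMPERATURES)
        if bad_temp.any():
            raise FormatError(
                f"unknown temperature {df.loc[bad_temp, 'temperature'].iloc[0]!r}"
            )
        dup = df.duplicated(SCREEN_KEY)
        if dup.any():
            key = tuple(df.loc[dup[dup].index[0], SCREEN_KEY])
            raise FormatError(f"duplicate replicate key {key}")

    def __len__(self) -> int:
        return len(self.data)


def read_screen_table(path: str | Path, dialect: str = "tsv",
                      column_map: Mapping[str, str] | None = None) -> ScreenTable:
    """Read a screen table from TSV/CSV, validating types and key uniqueness.

    ``column_map`` maps file column names to the canonical names in
    :data:`SCREEN_COLUMNS` when the file uses a different header.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("biological_rep", "technical_rep", "plate", "row", "col"):
        if col in df.columns:
            try:
                df[col] = df[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"non-integer value in column {col!r}: {exc}") from exc
    try:
        df["colony_size"] = pd.to_numeric(df["colony_size"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed colony_size column: {exc}") from exc
    return ScreenTable(df[SCREEN_COLUMNS].copy())


def write_screen_table(table: ScreenTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref_count", "alt_count"]


@dataclass
class AlleleCountTable:
    """Per-site ref/alt read counts for pooled-segregant samples.

    ``alt_count`` counts reads supporting the wild-parent allele. Sample
    metadata maps ``sample_id`` to ``{cross_id, temperature, replicate}``.
    """

    data: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"allele count table missing columns: {missing}")
        df = self.data
        if (df[["ref_count", "alt_count"]] < 0).to_numpy().any():
            raise FormatError("negative read counts")
        for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(
                    f"positions not strictly increasing for {sample}/{chrom}"
                )

    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"].unique())

    def sample(self, sample_id: str) -> pd.DataFrame:
        return self.data[self.data["sample_id"] == sample_id]


def read_allele_counts(path: str | Path,
                       metadata: Mapping[str, dict] | None = None) -> AlleleCountTable:
    """Read allele counts from a VCF with per-sample AD, or a TSV.

    The TSV dialect carries explicit ``sample_id/chrom/pos/ref_count/alt_count``
    columns. VCF samples become sample ids; AD[0] is the ref count and AD[1]
    the alt (wild-parent) count. Zero-depth sites are retained.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        rows = _read_vcf_counts(path)
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"allele count TSV missing columns: {missing}")
        df = df[COUNT_COLUMNS]
    df = df.astype({"pos": int, "ref_count": int, "alt_count": int})
    return AlleleCountTable(df, dict(metadata or {}))


def _read_vcf_counts(path: Path) -> list[tuple]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple] = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"no AD field at {variant.CHROM}:{variant.POS}")
        for i, sample in enumerate(samples):
            ref = max(int(ad[i][0]), 0)
            alt = max(int(ad[i][1]), 0) if ad.shape[1] > 1 else 0
            rows.append((sample, variant.CHROM, int(variant.POS), ref, alt))
    # VCF is ordered by site; regroup per sample with positions in file order
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return rows


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

#: General modifier genes affecting expression of thousands of genes, always
#: considered as candidates regardless of functional connection to the query.
KNOWN_GENERAL_MODIFIERS = ("MKT1", "HAP1")


@dataclass
class AnnotationSet:
    """Functional gene annotations used for consistency tests and ranking."""

    complexes: dict[str, set[str]] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)
    coexpression_partners: set[frozenset[str]] = field(default_factory=set)
    localization: dict[str, set[str]] = field(default_factory=dict)
    essential: set[str] = field(default_factory=set)
    known_general_modifiers: tuple[str, ...] = KNOWN_GENERAL_MODIFIERS

    def co_complex(self, a: str, b: str) -> bool:
        return any(a in m and b in m for m in self.complexes.values())

    def co_pathway(self, a: str, b: str) -> bool:
        return any(a in m and b in m for m in self.pathways.values())

    def co_expressed(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.coexpression_partners

    def co_localized(self, a: str, b: str) -> bool:
        return bool(self.localization.get(a, set()) & self.localization.get(b, set()))


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (set_id, gene) into a gene-set map."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["set_id", "gene"], header=0)
    return {k: set(g["gene"]) for k, g in df.groupby("set_id")}


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(k, g) for k, genes in sets.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["set_id", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QTL regions and BED export
# ---------------------------------------------------------------------------


@dataclass
class QTLRegion:
    """Genomic interval with a temperature-specific allele-frequency change.

    Coordinates are 1-based inclusive. ``delta_peak`` is the signed
    wild-allele frequency change (restrictive − permissive) at ``peak_pos``;
    positive means the wild allele is beneficial at high temperature.
    """

    chrom: str
    start: int
    end: int
    peak_pos: int
    delta_peak: float
    direction: str  # "wild_beneficial" | "reference_beneficial"
    tier: str  # "stringent" | "lenient"
    cross_id: str = "cross"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def write_qtl_bed(regions: Iterable[QTLRegion], path: str | Path) -> None:
    """Write QTL regions as BED6.

    Score is round(1000·|delta_peak|) capped at 1000; strand "+" when the
    wild allele is beneficial, "-" when the reference allele is.
    """
    regions = list(regions)
    _warn_overlaps(regions)
    with open(path, "w") as fh:
        fh.write("# QTL regions (BED6); score=round(1000*|delta_peak|); "
                 "strand +=wild allele beneficial\n")
        for r in regions:
            score = min(int(round(1000 * abs(r.delta_peak))), 1000)
            strand = "+" if r.direction == "wild_beneficial" else "-"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cross_id}\t{score}\t{strand}\n")


def _warn_overlaps(regions: list[QTLRegion]) -> None:
    by_cross: dict[tuple[str, str], list[QTLRegion]] = {}
    for r in regions:
        by_cross.setdefault((r.cross_id, r.chrom), []).append(r)
    for (cross, chrom), rs in by_cross.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end and a.tier == b.tier:
                logger.warning("overlapping QTL regions in %s on %s: %s-%s and %s-%s",
                               cross, chrom, a.start, a.end, b.start, b.end)


def read_qtl_bed(path: str | Path, tier: str = "stringent") -> list[QTLRegion]:
    """Read BED6 QTL regions back (peak position is not stored in BED; the
    interval midpoint is used and |delta_peak| is recovered from the score)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            start_i, end_i = int(start) + 1, int(end)
            delta = int(score) / 1000.0
            if strand == "-":
                delta = -delta
            regions.append(QTLRegion(
                chrom=chrom, start=start_i, end=end_i,
                peak_pos=(start_i + end_i) // 2, delta_peak=delta,
                direction="wild_beneficial" if strand == "+" else "reference_beneficial",
                tier=tier, cross_id=name))
    return regions


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All thresholds and parameters of the pipeline stages, plus the seed.

    Nested parameter dataclasses are stored as plain dicts so a YAML
    round-trip is lossless.
    """

    seed: int = 0
    scoring: dict = field(default_factory=dict)
    mapper: dict = field(default_factory=dict)
    screen_sim: dict = field(default_factory=dict)
    consistency: dict = field(default_factory=dict)
    prioritization: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
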