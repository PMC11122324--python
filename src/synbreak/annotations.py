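"""Reading and writing of gene, repeat, and marker-localization tables.

All intervals are held 0-based half-open internally.  GFF3 (1-based,
inclusive) is converted at the boundary; BED is native.  A marker's single
reference position is the integer midpoint of its gene interval, because
whole-gene FISH probes need one point for ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import yaml

__all__ = [
    "GeneAnnotation",
    "RepeatElement",
    "MarkerLocalization",
    "ChromosomeConfig",
    "DEFAULT_FAMILY_MAP",
    "classify_repeat_family",
    "read_gff3",
    "write_gff3",
    "read_repeat_bed",
    "write_repeat_bed",
    "read_marker_table",
    "write_marker_table",
    "read_config",
    "gene_midpoint",
]

REPEAT_GROUPS = ("retrotransposon", "dna_transposon", "unknown_te", "simple_repeat")


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A gene's location in the reference genome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, order=True)
class RepeatElement:
    """A repeat-annotation record with its coarse family group."""

    chrom: str
    start: int
    end: int
    family_label: str
    group: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"repeat {self.family_label}@{self.chrom}:{self.start}: "
                f"end {self.end} must be > start {self.start}"
            )
        if self.group not in REPEAT_GROUPS:
            raise ValueError(f"unknown repeat group {self.group!r}")


@dataclass(frozen=True)
class MarkerLocalization:
    """One FISH observation: a probe gene seen in a cytogenetic zone."""

    gene_id: str
    ref_coord: int
    zone: str
    round: int
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.round < 1:
            raise ValueError(f"marker {self.gene_id}: round must be >= 1")


@dataclass(frozen=True)
class ChromosomeConfig:
    """Declares the target chromosome: name, length, ordered zone labels."""

    name: str
    length: int
    zone_order: tuple[str, ...]

    def zone_rank(self, zone: str) -> int:
        try:
            return self.zone_order.index(zone)
        except ValueError:
            raise ValueError(
                f"zone {zone!r} not in declared zone order "
                f"({', '.join(self.zone_order)})"
            ) from None


def gene_midpoint(gene: GeneAnnotation) -> int:
    return gene.midpoint


# ---------------------------------------------------------------------------
# Repeat family grouping
# ---------------------------------------------------------------------------

# Coarse grouping of repeat-family labels into the four analysis groups:
# class I (retrotransposons), class II (DNA transposons), unclassified TEs,
# and simple/low-complexity repeats.  Matching is by case-insensitive token.
DEFAULT_FAMILY_MAP: tuple[tuple[str, str], ...] = (
    # simple repeats first: their labels never collide with TE tokens
    ("low_complexity", "simple_repeat"),
    ("simple_repeat", "simple_repeat"),
    ("satellite", "simple_repeat"),
    # class I
    ("gypsy", "retrotransposon"),
    ("copia", "retrotransposon"),
    ("line", "retrotransposon"),
    ("ltr", "retrotransposon"),
    ("sine", "retrotransposon"),
    # class II
    ("cacta", "dna_transposon"),
    ("mutator", "dna_transposon"),
    ("harbinger", "dna_transposon"),
    ("pif", "dna_transposon"),
    ("mariner", "dna_transposon"),
    ("tc1", "dna_transposon"),
    ("hat", "dna_transposon"),
    ("helitron", "dna_transposon"),
    ("mite", "dna_transposon"),
    ("tir", "dna_transposon"),
    ("dtc", "dna_transposon"),
    ("dta", "dna_transposon"),
    ("dth", "dna_transposon"),
    ("dtt", "dna_transposon"),
    ("dtm", "dna_transposon"),
    ("dna", "dna_transposon"),
    # unclassified TEs
    ("repeat_region", "unknown_te"),
    ("unknown", "unknown_te"),
)


def classify_repeat_family(
    family_label: str,
    family_map: Sequence[tuple[str, str]] = DEFAULT_FAMILY_MAP,
    warn_unmatched: bool = True,
) -> str:
    """Map a repeat family label to one of the four coarse groups.

    Unmatched labels fall back to ``unknown_te`` with a warning.
    """
    low = family_label.lower()
    for token, group in family_map:
        if token in low:
            return group
    if warn_unmatched:
        warnings.warn(
            f"repeat family label {family_label!r} matched no known token; "
            "assigning group 'unknown_te'",
            stacklevel=2,
        )
    return "unknown_te"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read gene records from a GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open.
    Raises on duplicate gene IDs within a chromosome.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip() or all(
        line.startswith("#") or not line.strip() for line in text.splitlines()
    ):
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils wraps sqlite + parse errors
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    genes: list[GeneAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        key = (feat.seqid, gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene ID {gene_id!r} on {feat.seqid}")
        seen.add(key)
        genes.append(
            GeneAnnotation(
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                end=feat.end,
                gene_id=gene_id,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(
    genes: Iterable[GeneAnnotation],
    path: str | Path,
    source: str = "synbreak",
    header_comment: str | None = None,
) -> None:
    lines = ["##gff-version 3"]
    if header_comment:
        lines.append(f"# {header_comment}")
    for g in sorted(genes):
        lines.append(
            "\t".join(
                (
                    g.chrom,
                    source,
                    "gene",
                    str(g.start + 1),  # back to 1-based inclusive
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED repeats
# ---------------------------------------------------------------------------


def read_repeat_bed(
    path: str | Path,
    family_map: Sequence[tuple[str, str]] = DEFAULT_FAMILY_MAP,
) -> list[RepeatElement]:
    """Read a BED4+ repeat track; column 4 carries the family label."""
    out: list[RepeatElement] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: need >= 4 BED columns, got {len(fields)}")
        chrom, start_s, end_s, label = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
        out.append(
            RepeatElement(
                chrom=chrom,
                start=start,
                end=end,
                family_label=label,
                group=classify_repeat_family(label, family_map),
            )
        )
    out.sort()
    return out


def write_repeat_bed(
    elements: Iterable[RepeatElement],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    for el in sorted(elements):
        lines.append(f"{el.chrom}\t{el.start}\t{el.end}\t{el.family_label}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Marker localization table
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["gene_id", "ref_coord", "zone", "round", "channel"]


def read_marker_table(
    path: str | Path,
    zone_order: Sequence[str],
) -> list[MarkerLocalization]:
    """Read the FISH marker TSV, validating zones against the declared order.

    Duplicate (gene, round) rows keep the first occurrence with a warning.
    Result is stably sorted by (round, ref_coord).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "zone": str})
    missing = [c for c in ("gene_id", "ref_coord", "zone", "round") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    allowed = set(zone_order)
    bad = sorted(set(df["zone"]) - allowed)
    if bad:
        raise ValueError(
            f"{path}: unknown zone labels {bad}; allowed: {list(zone_order)}"
        )
    records: list[MarkerLocalization] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        key = (row.gene_id, int(row.round))
        if key in seen:
            warnings.warn(
                f"duplicate marker row for gene {row.gene_id} round {row.round}; "
                "keeping first",
                stacklevel=2,
            )
            continue
        seen.add(key)
        channel = getattr(row, "channel", None)
        if pd.isna(channel):
            channel = None
        records.append(
            MarkerLocalization(
                gene_id=row.gene_id,
                ref_coord=int(row.ref_coord),
                zone=row.zone,
                round=int(row.round),
                channel=channel,
            )
        )
    records.sort(key=lambda m: (m.round, m.ref_coord))
    return records


def write_marker_table(
    markers: Iterable[MarkerLocalization],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "ref_coord": m.ref_coord,
            "zone": m.zone,
            "round": m.round,
            "channel": m.channel if m.channel is not None else "",
        }
        for m in markers
    ]
    df = pd.DataFrame(rows, columns=_MARKER_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> ChromosomeConfig:
    """Read the YAML chromosome config (name, length, zone_order)."""
    data: Mapping = yaml.safe_load(Path(path).read_text())
    try:
        return ChromosomeConfig(
            name=str(data["chromosome"]),
            length=int(data["length"]),
            zone_order=tuple(str(z) for z in data["zone_order"]),
        )
    except KeyError as exc:
        raise ValueError(f"config {path}: missing key {exc}") from exc
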