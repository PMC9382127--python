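"""Family-table I/O, candidate screening, and protein physicochemical descriptors.

Coordinates in external files (family table, GFF3) are 1-based inclusive;
they are kept that way on :class:`GeneRecord` because the table itself is the
unit of exchange.  Anything that needs interval arithmetic converts to
0-based half-open locally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneRecord",
    "FamilyTable",
    "CandidateHit",
    "ExonIntronHistogram",
    "load_family_table",
    "write_family_table",
    "bundled_family_table",
    "filter_candidates",
    "exon_histogram",
    "protein_mw",
    "isoelectric_point",
    "range_summary",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "read_gff3_genes",
    "write_gff3",
    "round2",
]

FAMILY_COLUMNS = (
    "gene_name",
    "accession",
    "chromosome",
    "start",
    "end",
    "orf_len",
    "exon_count",
    "aa_len",
    "mw_kda",
    "pi",
)

# Average (isotope-abundance weighted) residue masses in daltons, ExPASy set.
# X carries the mean of the 20 standard residues.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
AVERAGE_RESIDUE_MASS["X"] = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0
WATER_MASS = 18.0153

# EMBOSS iep pKa values; overridable per call.
EMBOSS_PKA = {
    "N_term": 8.6,
    "C_term": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
}
_ACIDIC = ("C_term", "D", "E", "C", "Y")
_BASIC = ("N_term", "H", "K", "R")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (matches printed percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneRecord:
    """One family member: coordinates, gene structure, and physchem fields."""

    gene_name: str
    accession: str
    chromosome: str
    start: int
    end: int
    orf_len: int
    exon_count: int
    aa_len: int
    mw_kda: float
    pi: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_name}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_name}: exon_count must be >= 1")
        if self.aa_len < 1:
            raise ValueError(f"{self.gene_name}: aa_len must be >= 1")
        if self.mw_kda <= 0:
            raise ValueError(f"{self.gene_name}: mw must be positive")
        if not 0 < self.pi < 14:
            raise ValueError(f"{self.gene_name}: pI {self.pi} outside (0, 14)")


class FamilyTable:
    """Ordered collection of :class:`GeneRecord` with unique-name lookup."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        self.name_index: dict[str, GeneRecord] = {}
        accessions: set[str] = set()
        for rec in self.records:
            if rec.gene_name in self.name_index:
                raise ValueError(f"duplicate gene_name {rec.gene_name!r}")
            if rec.accession in accessions:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self.name_index[rec.gene_name] = rec
            accessions.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, gene_name: str) -> GeneRecord:
        return self.name_index[gene_name]

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self.name_index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FamilyTable) and self.records == other.records


@dataclass(frozen=True)
class CandidateHit:
    """One screening hit: a homology-search or keyword-search record."""

    query_id: str
    subject_id: str
    evalue: float = 0.0
    identity_pct: float = 100.0
    source: str = "homology_search"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.source not in ("homology_search", "keyword"):
            raise ValueError(f"unknown hit source {self.source!r}")


@dataclass
class ExonIntronHistogram:
    counts: dict[int, int]
    total: int

    @property
    def intron_counts(self) -> dict[int, int]:
        """Companion view keyed by intron count (= exon count - 1)."""
        return {k - 1: v for k, v in self.counts.items()}

    def percentages(self) -> dict[int, float]:
        return {k: round2(100.0 * v / self.total) for k, v in self.counts.items()}


def _parse_int(cell: str, row: str, column: str) -> int:
    try:
        return int(cell.replace(",", "").strip())
    except ValueError:
        raise ValueError(f"row {row!r}: unparseable integer in column {column!r}: {cell!r}")


def _parse_float(cell: str, row: str, column: str) -> float:
    try:
        return float(cell.replace(",", "").strip())
    except ValueError:
        raise ValueError(f"row {row!r}: unparseable number in column {column!r}: {cell!r}")


def load_family_table(path: str | Path) -> FamilyTable:
    """Read a tab-separated family characteristics table.

    Coordinates may come as separate ``start``/``end`` columns or as a single
    ``location`` column written ``start–end`` (en dash or hyphen); thousands
    separators are accepted in any numeric cell.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    idx = {name: i for i, name in enumerate(header)}
    split_coords = "start" in idx and "end" in idx
    if not split_coords and "location" not in idx:
        raise ValueError(f"{path}: need start/end columns or a location column")

    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        name = cells[idx["gene_name"]].strip()
        if split_coords:
            start = _parse_int(cells[idx["start"]], name, "start")
            end = _parse_int(cells[idx["end"]], name, "end")
        else:
            loc = cells[idx["location"]].strip()
            m = re.match(r"^([\d,]+)\s*[–-]\s*([\d,]+)$", loc)
            if not m:
                raise ValueError(f"row {name!r}: unparseable location {loc!r}")
            start = _parse_int(m.group(1), name, "location")
            end = _parse_int(m.group(2), name, "location")
        records.append(
            GeneRecord(
                gene_name=name,
                accession=cells[idx["accession"]].strip(),
                chromosome=cells[idx["chromosome"]].strip(),
                start=start,
                end=end,
                orf_len=_parse_int(cells[idx["orf_len"]], name, "orf_len"),
                exon_count=_parse_int(cells[idx["exon_count"]], name, "exon_count"),
                aa_len=_parse_int(cells[idx["aa_len"]], name, "aa_len"),
                mw_kda=_parse_float(cells[idx["mw_kda"]], name, "mw_kda"),
                pi=_parse_float(cells[idx["pi"]], name, "pi"),
            )
        )
    return FamilyTable(records)


def write_family_table(table: FamilyTable, path: str | Path) -> None:
    lines = ["\t".join(FAMILY_COLUMNS)]
    for r in table:
        lines.append(
            "\t".join(
                str(getattr(r, col)) for col in FAMILY_COLUMNS
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_family_table() -> FamilyTable:
    """The in-repo 78-gene family characteristics fixture."""
    ref = resources.files("famdup.data").joinpath("acprx_family.tsv")
    with resources.as_file(ref) as p:
        return load_family_table(p)


def filter_candidates(
    hits: Iterable[CandidateHit],
    evalue_max: float = 1e-5,
    identity_min_pct: float = 50.0,
) -> set[str]:
    """Screen candidate hits and deduplicate by subject identifier.

    Homology hits must satisfy ``evalue <= evalue_max`` (inclusive) and
    ``identity_pct > identity_min_pct`` (strict); keyword hits bypass the
    numeric filter.  The union is deduplicated by ``subject_id``.
    """
    if evalue_max <= 0 or identity_min_pct <= 0:
        raise ValueError("thresholds must be positive")
    kept: set[str] = set()
    for hit in hits:
        if hit.source == "keyword":
            kept.add(hit.subject_id)
        elif hit.evalue <= evalue_max and hit.identity_pct > identity_min_pct:
            kept.add(hit.subject_id)
    return kept


def exon_histogram(table: FamilyTable) -> ExonIntronHistogram:
    if len(table) == 0:
        raise ValueError("empty family table")
    counts: dict[int, int] = {}
    for rec in table:
        counts[rec.exon_count] = counts.get(rec.exon_count, 0) + 1
    return ExonIntronHistogram(counts=dict(sorted(counts.items())), total=len(table))


def protein_mw(sequence: str) -> float:
    """Average molecular weight of an unmodified chain, in kilodaltons."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence.upper()):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"illegal residue {aa!r} at position {pos}")
    return total / 1000.0


def _net_charge(counts: Mapping[str, int], ph: float, pka: Mapping[str, float]) -> float:
    charge = 0.0
    for grp in _BASIC:
        n = counts.get(grp, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[grp]))
    for grp in _ACIDIC:
        n = counts.get(grp, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[grp] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] | None = None,
    tol: float = 1e-3,
) -> float:
    """pH at which the chain's Henderson–Hasselbalch net charge is zero.

    The charge function is strictly decreasing in pH, so bisection on
    [0, 14] finds the unique root; termini are always counted, so a root
    always exists in practice.
    """
    if not sequence:
        raise ValueError("empty sequence")
    table = dict(EMBOSS_PKA)
    if pka:
        table.update(pka)
    counts: dict[str, int] = {"N_term": 1, "C_term": 1}
    for aa in sequence.upper():
        if aa in ("D", "E", "C", "Y", "H", "K", "R"):
            counts[aa] = counts.get(aa, 0) + 1
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(counts, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def range_summary(
    table: FamilyTable, column: str
) -> tuple[tuple[float, str], tuple[float, str]]:
    """Extrema of a numeric column with the gene attaining each.

    Returns ``((min_value, gene), (max_value, gene))``; ties broken by first
    occurrence in table order.
    """
    if column not in ("aa_len", "mw_kda", "pi"):
        raise ValueError(f"unsupported column {column!r}")
    if len(table) == 0:
        raise ValueError("empty family table")
    lo_rec = hi_rec = table.records[0]
    for rec in table.records[1:]:
        if getattr(rec, column) < getattr(lo_rec, column):
            lo_rec = rec
        if getattr(rec, column) > getattr(hi_rec, column):
            hi_rec = rec
    return (
        (getattr(lo_rec, column), lo_rec.gene_name),
        (getattr(hi_rec, column), hi_rec.gene_name),
    )


# --- standard-format helpers -------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_blast_tabular(path: str | Path, source: str = "homology_search") -> list[CandidateHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into CandidateHits."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 12:
            raise ValueError(f"{path}: expected 12 tab-separated columns, got {len(cells)}")
        hits.append(
            CandidateHit(
                query_id=cells[0],
                subject_id=cells[1],
                identity_pct=float(cells[2]),
                evalue=float(cells[10]),
                source=source,
            )
        )
    return hits


@dataclass(frozen=True)
class Gff3Gene:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive, as in the file
    end: int
    strand: str = "+"


def read_gff3_genes(path: str | Path) -> list[Gff3Gene]:
    """Gene features of a GFF3 file, in file order."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 9:
            raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
        if cells[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cells[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"{path}: gene feature without ID: {line!r}")
        genes.append(
            Gff3Gene(
                gene_id=gene_id,
                chromosome=cells[0],
                start=int(cells[3]),
                end=int(cells[4]),
                strand=cells[6],
            )
        )
    return genes


def write_gff3(genes: Sequence[Gff3Gene], path: str | Path, source: str = "famdup") -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};Name={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chromosome, source, "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
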