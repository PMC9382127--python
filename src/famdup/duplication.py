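"""Duplicate-pair detection and tandem/segmental classification.

A pair is a duplicate when (1) global-alignment identity, with the shorter
sequence length as denominator, exceeds ``identity_min`` and (2) the
shorter/longer amino-acid length ratio exceeds ``ratio_min`` (both strict,
defaults 0.70).  Tandem classification takes precedence over segmental, so
the two classes are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_io import FamilyTable, Gff3Gene

__all__ = [
    "DuplicatePair",
    "SyntenyBlock",
    "DuplicationSummary",
    "global_identity",
    "find_duplicate_pairs",
    "classify_tandem",
    "classify_segmental",
    "summarize",
    "read_synteny_blocks",
    "write_pair_report",
]

TANDEM_SPAN_BP = 200_000
WINDOW_BP = 100_000
WINDOW_MAX_INTERVENING = 5


@dataclass(frozen=True)
class DuplicatePair:
    """An unordered duplicate gene pair, stored with canonical name order."""

    gene_a: str
    gene_b: str
    identity: float | None = None
    length_ratio: float | None = None
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.gene_a > self.gene_b:  # canonical unordered representation
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)
        if self.identity is not None and not 0 <= self.identity <= 1:
            raise ValueError("identity must lie in [0, 1]")
        if self.length_ratio is not None and not 0 < self.length_ratio <= 1:
            raise ValueError("length_ratio must lie in (0, 1]")
        if self.classification not in ("tandem", "segmental", "unclassified"):
            raise ValueError(f"unknown classification {self.classification!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _canonical(gene_a: str, gene_b: str) -> tuple[str, str]:
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


def make_pair(gene_a: str, gene_b: str, **kw) -> DuplicatePair:
    a, b = _canonical(gene_a, gene_b)
    return DuplicatePair(gene_a=a, gene_b=b, **kw)


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    chrom_a: str
    span_a: tuple[int, int]
    chrom_b: str
    span_b: tuple[int, int]
    member_pairs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.span_a[0] > self.span_a[1] or self.span_b[0] > self.span_b[1]:
            raise ValueError(f"block {self.block_id}: malformed span")


@dataclass(frozen=True)
class DuplicationSummary:
    tandem_pairs: int
    segmental_pairs: int
    tandem_genes: int
    segmental_genes: int
    tandem_chromosomes: int


def global_identity(seq_a: str, seq_b: str, open_gap: float = -10.0,
                    extend_gap: float = -0.5) -> float:
    """Global-alignment identity with the shorter length as denominator.

    Needleman–Wunsch with BLOSUM62 and affine gaps (biopython's
    PairwiseAligner); identity = exact matches / min(len_a, len_b).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return matches / min(len(seq_a), len(seq_b))


def find_duplicate_pairs(
    table: FamilyTable,
    proteins: Mapping[str, str],
    identity_min: float = 0.70,
    ratio_min: float = 0.70,
) -> list[DuplicatePair]:
    """All unordered pairs passing both duplicate criteria, canonically sorted.

    The length ratio is computed from the table's amino-acid lengths; the
    identity from a global alignment of the attached protein sequences.
    """
    missing = [r.gene_name for r in table if r.gene_name not in proteins]
    if missing:
        raise ValueError(f"missing protein sequence for: {', '.join(missing)}")
    names = [r.gene_name for r in table]
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            la, lb = table[a].aa_len, table[b].aa_len
            ratio = min(la, lb) / max(la, lb)
            if ratio <= ratio_min:
                continue
            ident = global_identity(proteins[a], proteins[b])
            if ident > identity_min:
                pairs.append(make_pair(a, b, identity=ident, length_ratio=ratio))
    return sorted(pairs, key=lambda p: p.key)


def classify_tandem(
    pairs: Iterable[DuplicatePair],
    table: FamilyTable,
    rule: str = "span_200kb",
    all_genes: Sequence[Gff3Gene] | None = None,
) -> list[DuplicatePair]:
    """Mark pairs as tandem under the chosen proximity rule.

    ``span_200kb``: same chromosome and start-to-start distance < 200 kb.
    ``window_100kb_5genes``: same chromosome, <= 5 intervening genes in the
    chromosome's full gene order, and starts within 100 kb; requires
    ``all_genes``.
    """
    if rule not in ("span_200kb", "window_100kb_5genes"):
        raise ValueError(f"unknown tandem rule {rule!r}")
    if rule == "window_100kb_5genes":
        if all_genes is None:
            raise ValueError("window_100kb_5genes requires the full gene order (all_genes)")
        order: dict[str, int] = {}
        by_chrom: dict[str, list[Gff3Gene]] = {}
        for g in all_genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, genes in by_chrom.items():
            for rank, g in enumerate(sorted(genes, key=lambda g: g.start)):
                order[g.gene_id] = rank

    out = []
    for pair in pairs:
        ra, rb = table[pair.gene_a], table[pair.gene_b]
        tandem = False
        if ra.chromosome == rb.chromosome:
            dist = abs(ra.start - rb.start)
            if rule == "span_200kb":
                tandem = dist < TANDEM_SPAN_BP
            else:
                ids = (table[pair.gene_a].accession, table[pair.gene_b].accession)
                ranks = []
                for acc, name in zip(ids, (pair.gene_a, pair.gene_b)):
                    key = acc if acc in order else name
                    if key not in order:
                        raise ValueError(f"gene {name} absent from the supplied gene order")
                    ranks.append(order[key])
                intervening = abs(ranks[0] - ranks[1]) - 1
                tandem = intervening <= WINDOW_MAX_INTERVENING and dist < WINDOW_BP
        out.append(replace(pair, classification="tandem" if tandem else pair.classification))
    return out


def classify_segmental(
    pairs: Iterable[DuplicatePair],
    blocks: Iterable[SyntenyBlock],
    table: FamilyTable | None = None,
) -> list[DuplicatePair]:
    """Mark non-tandem pairs appearing in a synteny block as segmental.

    A pair qualifies when its canonical key is in a block's member list, or
    (when a table with coordinates is given) both genes fall inside the two
    paired spans of one block.  Tandem pairs are left untouched.
    """
    blocks = list(blocks)
    out = []
    for pair in pairs:
        if pair.classification == "tandem":
            out.append(pair)
            continue
        segmental = False
        for block in blocks:
            members = {_canonical(*mp) for mp in block.member_pairs}
            if pair.key in members:
                segmental = True
                break
            if table is not None and pair.gene_a in table and pair.gene_b in table:
                ra, rb = table[pair.gene_a], table[pair.gene_b]
                if _in_block(ra, rb, block) or _in_block(rb, ra, block):
                    segmental = True
                    break
        out.append(replace(pair, classification="segmental" if segmental else pair.classification))
    return out


def _in_block(rec_a, rec_b, block: SyntenyBlock) -> bool:
    return (
        rec_a.chromosome == block.chrom_a
        and block.span_a[0] <= rec_a.start and rec_a.end <= block.span_a[1]
        and rec_b.chromosome == block.chrom_b
        and block.span_b[0] <= rec_b.start and rec_b.end <= block.span_b[1]
    )


def summarize(
    pairs: Iterable[DuplicatePair], table: FamilyTable | None = None
) -> DuplicationSummary:
    """Pair, distinct-gene, and tandem-chromosome counts per class."""
    tandem = [p for p in pairs if p.classification == "tandem"]
    segmental = [p for p in pairs if p.classification == "segmental"]
    tandem_genes = {g for p in tandem for g in p.key}
    segmental_genes = {g for p in segmental for g in p.key}
    chroms: set[str] = set()
    if table is not None:
        chroms = {table[g].chromosome for g in tandem_genes if g in table}
    return DuplicationSummary(
        tandem_pairs=len(tandem),
        segmental_pairs=len(segmental),
        tandem_genes=len(tandem_genes),
        segmental_genes=len(segmental_genes),
        tandem_chromosomes=len(chroms),
    )


def read_synteny_blocks(path: str | Path) -> list[SyntenyBlock]:
    """Tab-separated block table:
    block_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b, gene_a, gene_b.
    Multiple rows may share a block_id; their gene pairs accumulate.
    """
    rows: dict[str, dict] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if not line.strip() or line.lower().startswith("block_id"):
            continue
        c = line.split("\t")
        entry = rows.setdefault(
            c[0],
            {
                "chrom_a": c[1], "span_a": (int(c[2]), int(c[3])),
                "chrom_b": c[4], "span_b": (int(c[5]), int(c[6])),
                "pairs": set(),
            },
        )
        if len(c) >= 9 and c[7] and c[8]:
            entry["pairs"].add(_canonical(c[7], c[8]))
    return [
        SyntenyBlock(
            block_id=bid,
            chrom_a=e["chrom_a"], span_a=e["span_a"],
            chrom_b=e["chrom_b"], span_b=e["span_b"],
            member_pairs=frozenset(e["pairs"]),
        )
        for bid, e in rows.items()
    ]


def write_pair_report(pairs: Iterable[DuplicatePair], path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tidentity\tlength_ratio\tclassification"]
    for p in sorted(pairs, key=lambda p: p.key):
        ident = "" if p.identity is None else f"{p.identity:.4f}"
        ratio = "" if p.length_ratio is None else f"{p.length_ratio:.4f}"
        lines.append(f"{p.gene_a}\t{p.gene_b}\t{ident}\t{ratio}\t{p.classification}")
    Path(path).write_text("\n".join(lines) + "\n")
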