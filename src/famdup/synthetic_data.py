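"""Seeded synthetic inputs with the structure every analysis stage assumes.

One root seed is split hierarchically (``SeedSequence(seed, spawn_key=...)``)
so each component draws from its own stream: adding or resizing one component
never perturbs the draws of another.  All outputs are deterministic given the
config, and every planted structure is recorded in a truth table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation_io as aio
from .annotation_io import GeneRecord, FamilyTable, Gff3Gene
from .molevol import BASES, GENETIC_CODE, STOP_CODONS, codon_sites, translate
from .phenotype import IBCohort

__all__ = [
    "SimConfig",
    "TandemClusterSpec",
    "SegmentalSpec",
    "ExpressionSpec",
    "CohortSpec",
    "SimulatedGenome",
    "simulate_genome",
    "evolve_pair",
    "random_cds",
    "simulate_expression",
    "simulate_cohorts",
]

_STREAM = {"genome": 0, "codon": 1, "expression": 2, "cohort": 3}


def _rng(seed: int, component: str, *extra: int) -> np.random.Generator:
    key = (_STREAM[component],) + tuple(extra)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class TandemClusterSpec:
    count: int = 2
    size: int = 3
    target_ks: float = 0.08      # low divergence -> intra-cluster identity >= ~0.9
    omega: float = 0.3
    max_spacing_bp: int = 5_000  # start-to-start gap between cluster neighbours


@dataclass(frozen=True)
class SegmentalSpec:
    count: int = 3
    target_ks: float = 0.25
    omega: float = 0.3


@dataclass(frozen=True)
class ExpressionSpec:
    conditions: tuple[str, ...] = ("day0", "day4", "day6")
    baseline: str = "day0"
    replicates: int = 1
    planted_folds: tuple[tuple[str, str, float], ...] = ()  # (gene, condition, fold)
    dropout: float = 0.0
    log_fpkm_mean: float = 3.0
    log_fpkm_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[str, ...] = ("control", "treated")
    days: tuple[int, ...] = (3, 6, 9)
    n_fruits: int = 30
    # grade distribution per (group, day); falls back to `default_dist`
    distributions: Mapping[tuple[str, int], Sequence[float]] = field(default_factory=dict)
    default_dist: tuple[float, ...] = (0.5, 0.2, 0.1, 0.1, 0.05, 0.05)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chromosomes: tuple[int, ...] = (1_000_000, 1_000_000, 1_000_000)
    background_genes: int = 20
    codon_length: int = 300  # codons per gene
    tandem: TandemClusterSpec = TandemClusterSpec()
    segmental: SegmentalSpec = SegmentalSpec()
    expression: ExpressionSpec = ExpressionSpec()
    cohorts: CohortSpec = CohortSpec()


SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS of sense codons (no stops anywhere)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _evolve_one(cds: str, omega: float, target_ks: float, rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply substitutions until synonymous events per synonymous site reach
    target_ks; returns (sequence, syn_events, nonsyn_events)."""
    seq = list(cds)
    s_sites = sum(codon_sites(cds[i : i + 3])[0] for i in range(0, len(cds), 3))
    target_events = target_ks * s_sites
    syn = non = 0
    while syn < target_events:
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        cstart = 3 * (pos // 3)
        codon = "".join(seq[cstart : cstart + 3])
        mutated = codon[: pos - cstart] + new + codon[pos - cstart + 1 :]
        if mutated in STOP_CODONS:
            continue
        if GENETIC_CODE[codon] == GENETIC_CODE[mutated]:
            seq[pos] = new
            syn += 1
        elif rng.random() < omega:
            seq[pos] = new
            non += 1
    return "".join(seq), syn, non


def evolve_pair(
    ancestor_cds: str, omega: float, target_ks: float, seed: int
) -> tuple[str, str, dict]:
    """Evolve two descendants of an ancestor to a total pairwise synonymous
    divergence of ``target_ks`` (half per lineage).

    Substitutions are proposed uniformly over positions and nucleotides,
    accepted with probability 1 when synonymous and ``omega`` when
    nonsynonymous; proposals creating stop codons are rejected.  Returns the
    pair plus a truth record of realized event counts.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be nonnegative")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if translate(ancestor_cds).find("*") != -1:
        raise ValueError("ancestor contains a stop codon")
    if target_ks == 0:
        return ancestor_cds, ancestor_cds, {"syn_events": 0, "nonsyn_events": 0}
    rng = _rng(seed, "codon")
    a, syn_a, non_a = _evolve_one(ancestor_cds, omega, target_ks / 2.0, rng)
    b, syn_b, non_b = _evolve_one(ancestor_cds, omega, target_ks / 2.0, rng)
    return a, b, {"syn_events": syn_a + syn_b, "nonsyn_events": non_a + non_b}


@dataclass
class SimulatedGenome:
    table: FamilyTable
    genes: list[Gff3Gene]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth_pairs: list[tuple[str, str, str]]  # (gene_a, gene_b, class)
    blocks_rows: list[tuple]

    def truth_by_class(self, classification: str) -> set[tuple[str, str]]:
        return {
            tuple(sorted((a, b)))
            for a, b, c in self.truth_pairs
            if c == classification
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "table": outdir / "family_table.tsv",
            "gff3": outdir / "genes.gff3",
            "cds": outdir / "cds.fa",
            "proteins": outdir / "proteins.fa",
            "blocks": outdir / "synteny_blocks.tsv",
            "truth": outdir / "truth_pairs.tsv",
        }
        aio.write_family_table(self.table, paths["table"])
        aio.write_gff3(self.genes, paths["gff3"])
        aio.write_fasta(self.cds, paths["cds"])
        aio.write_fasta(self.proteins, paths["proteins"])
        lines = ["block_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tgene_a\tgene_b"]
        lines += ["\t".join(str(x) for x in row) for row in self.blocks_rows]
        paths["blocks"].write_text("\n".join(lines) + "\n")
        tlines = ["gene_a\tgene_b\tclassification"]
        tlines += [f"{a}\t{b}\t{c}" for a, b, c in self.truth_pairs]
        paths["truth"].write_text("\n".join(tlines) + "\n")
        return paths


def _make_record(name: str, chrom: str, start: int, cds: str,
                 rng: np.random.Generator) -> tuple[GeneRecord, str]:
    prot = translate(cds)
    exons = int(rng.integers(2, 9))
    end = start + len(cds) + 200 * (exons - 1)  # pad for pretend introns
    rec = GeneRecord(
        gene_name=name,
        accession=f"Syn{name.removeprefix('SimPRX'):>06}",
        chromosome=chrom,
        start=start,
        end=end,
        orf_len=len(cds),
        exon_count=exons,
        aa_len=len(prot),
        mw_kda=round(aio.protein_mw(prot), 2),
        pi=round(aio.isoelectric_point(prot), 2),
    )
    return rec, prot


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Plant tandem clusters, segmental pairs, and background genes on a toy
    multi-chromosome genome, with truth tables for every planted duplicate."""
    rng = _rng(cfg.seed, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chromosomes))]
    # disjoint 25-kb slots: genes never overlap, and a whole tandem cluster
    # fits one slot; unrelated genes may share the tandem window harmlessly
    # because they can never pass the duplicate identity criterion
    slot_span = 25_000
    slots = [
        (chrom_names[ci], s)
        for ci, clen in enumerate(cfg.chromosomes)
        for s in range(10_000, clen - slot_span, slot_span)
    ]
    gene_span = 3 * cfg.codon_length + 2_000
    needed = cfg.tandem.count + 2 * cfg.segmental.count + cfg.background_genes
    if needed > len(slots):
        raise ValueError(
            f"placement infeasible: {needed} slots needed, {len(slots)} available"
        )
    slot_order = list(rng.permutation(len(slots)))

    records: list[GeneRecord] = []
    genes: list[Gff3Gene] = []
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    truth: list[tuple[str, str, str]] = []
    blocks_rows: list[tuple] = []
    counter = itertools.count(1)

    def place(name: str, chrom: str, start: int, seq: str) -> None:
        rec, prot = _make_record(name, chrom, start, seq, rng)
        records.append(rec)
        genes.append(Gff3Gene(gene_id=name, chromosome=chrom, start=rec.start, end=rec.end))
        cds[name] = seq
        proteins[name] = prot

    slot_iter = iter(slot_order)

    # tandem clusters: every member evolved from one ancestor, placed within
    # the configured spacing inside one slot
    for _ in range(cfg.tandem.count):
        chrom, base = slots[next(slot_iter)]
        ancestor = random_cds(cfg.codon_length, rng)
        members = []
        for k in range(cfg.tandem.size):
            _, desc, _ = evolve_pair(
                ancestor, cfg.tandem.omega, cfg.tandem.target_ks,
                seed=cfg.seed * 1_000_003 + len(records) + k,
            )
            members.append(desc)
        start = base
        names = []
        for seq in members:
            name = f"SimPRX{next(counter)}"
            place(name, chrom, start, seq)
            names.append(name)
            start += min(cfg.tandem.max_spacing_bp, gene_span + 500)
        for a, b in itertools.combinations(names, 2):
            truth.append((a, b, "tandem"))

    # segmental pairs: the two copies go to slots on distinct chromosomes and
    # are recorded in a synteny block
    block_no = 0
    for _ in range(cfg.segmental.count):
        ancestor = random_cds(cfg.codon_length, rng)
        a_cds, b_cds, _ = evolve_pair(
            ancestor, cfg.segmental.omega, cfg.segmental.target_ks,
            seed=cfg.seed * 2_000_003 + len(records),
        )
        while True:
            sa = slots[next(slot_iter)]
            sb = slots[next(slot_iter)]
            if sa[0] != sb[0]:
                break
        name_a = f"SimPRX{next(counter)}"
        name_b = f"SimPRX{next(counter)}"
        place(name_a, sa[0], sa[1], a_cds)
        place(name_b, sb[0], sb[1], b_cds)
        truth.append((name_a, name_b, "segmental"))
        block_no += 1
        blocks_rows.append(
            (f"block{block_no}", sa[0], sa[1] - 5_000, sa[1] + gene_span + 5_000,
             sb[0], sb[1] - 5_000, sb[1] + gene_span + 5_000, name_a, name_b)
        )

    # unrelated background genes
    for _ in range(cfg.background_genes):
        chrom, start = slots[next(slot_iter)]
        place(f"SimPRX{next(counter)}", chrom, start, random_cds(cfg.codon_length, rng))

    genes.sort(key=lambda g: (g.chromosome, g.start))
    return SimulatedGenome(
        table=FamilyTable(records),
        genes=genes,
        cds=cds,
        proteins=proteins,
        truth_pairs=truth,
        blocks_rows=blocks_rows,
    )


def simulate_expression(cfg: SimConfig, genes: Sequence[str] | None = None):
    """FPKM matrix with planted fold changes plus the truth call table.

    Baselines are log-normal per gene; a planted (gene, condition, fold)
    multiplies the baseline; dropout zeroes a random fraction of cells.
    Returns (ExpressionMatrix, truth DataFrame of intended directions).
    """
    from .expression import ExpressionMatrix, UP, DOWN, UNCHANGED

    spec = cfg.expression
    rng = _rng(cfg.seed, "expression")
    if genes is None:
        genes = [f"SimPRX{i + 1}" for i in range(20)]
    genes = list(genes)
    base = np.exp(rng.normal(spec.log_fpkm_mean, spec.log_fpkm_sd, size=len(genes)))
    folds = {(g, c): f for g, c, f in spec.planted_folds}
    cols = {}
    meta = {}
    for cond in spec.conditions:
        vals = np.array([base[i] * folds.get((g, cond), 1.0) for i, g in enumerate(genes)])
        for rep in range(spec.replicates):
            sample = f"{cond}_r{rep + 1}" if spec.replicates > 1 else cond
            v = vals.copy()
            if spec.dropout > 0:
                v[rng.random(len(genes)) < spec.dropout] = 0.0
            cols[sample] = v
            meta[sample] = cond
    mat = ExpressionMatrix(
        values=pd.DataFrame(cols, index=genes), sample_conditions=meta
    )
    truth_rows = []
    for g, c, f in spec.planted_folds:
        lfc = np.log2(f)
        call = UP if lfc >= 1 else DOWN if lfc <= -1 else UNCHANGED
        truth_rows.append({"gene": g, "condition": c, "fold": f, "call": call})
    truth = pd.DataFrame(truth_rows, columns=["gene", "condition", "fold", "call"])
    return mat, truth


def simulate_cohorts(cfg: SimConfig) -> list[IBCohort]:
    """Multinomial grade counts per (group, day) cohort."""
    spec = cfg.cohorts
    rng = _rng(cfg.seed, "cohort")
    cohorts = []
    for group in spec.groups:
        for day in spec.days:
            dist = np.asarray(
                spec.distributions.get((group, day), spec.default_dist), dtype=float
            )
            if dist.size != MAX_GRADES or not np.isclose(dist.sum(), 1.0):
                raise ValueError(
                    f"grade distribution for ({group}, {day}) must have "
                    f"{MAX_GRADES} entries summing to 1"
                )
            counts = rng.multinomial(spec.n_fruits, dist)
            cohorts.append(
                IBCohort(
                    grade_counts={g: int(c) for g, c in enumerate(counts)},
                    n_total=spec.n_fruits,
                    group=group,
                    day=day,
                )
            )
    return cohorts


MAX_GRADES = 6  # grades 0..5
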