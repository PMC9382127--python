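"""Ka/Ks estimation by the Nei–Gojobori counting method and divergence dating.

Site counting, pathway enumeration, and the Jukes–Cantor correction are
implemented from scratch on the standard nuclear code.  Mutational steps
through stop codons are excluded from both site counting and pathway
enumeration; if every pathway between a codon pair is blocked by stops the
pair falls back to unrestricted pathways (documented deviation, vanishingly
rare on real CDS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GENETIC_CODE",
    "CodonAlignment",
    "KaKsResult",
    "translate",
    "codon_sites",
    "codon_pair_differences",
    "back_translate_alignment",
    "ng86",
    "divergence_time",
    "write_kaks_report",
]

BASES = "TCAG"
AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    a + b + c: AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(BASES)
    for j, b in enumerate(BASES)
    for k, c in enumerate(BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
GAP_CODON = "---"

DEFAULT_LAMBDA = 6.1e-9  # synonymous substitutions / site / year


def translate(cds: str) -> str:
    """Translate an in-frame CDS with the standard nuclear code."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    cds = cds.upper().replace("U", "T")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-consistent paired CDS; gaps occur only in whole-codon units."""

    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        a, b = self.cds_a.upper(), self.cds_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned CDS rows differ in length")
        if len(a) % 3:
            raise ValueError("aligned length not a multiple of 3")
        for row in (a, b):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(f"partial-codon gap at column {i}: {codon!r}")
            ungapped = row.replace("-", "")
            for i in range(0, len(ungapped) - 3, 3):
                if ungapped[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon at ungapped position {i}")
        object.__setattr__(self, "cds_a", a)
        object.__setattr__(self, "cds_b", b)

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Aligned codon pairs with any gapped column dropped pairwise."""
        pairs = []
        for i in range(0, len(self.cds_a), 3):
            ca, cb = self.cds_a[i : i + 3], self.cds_b[i : i + 3]
            if GAP_CODON in (ca, cb):
                continue
            pairs.append((ca, cb))
        return pairs


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    omega: float | None
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    t_mya: float | None
    status: str  # ok | saturated | undefined_omega


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes one site, split by the synonymous fraction of
    its one-step changes; changes into stop codons are excluded from the
    denominator.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or len(codon) != 3:
        raise ValueError(f"invalid sense codon {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            counted += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if counted:
            s += syn / counted
    return s, 3.0 - s


def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Multi-nucleotide differences are averaged uniformly over all orderings of
    single steps; orderings passing through a stop codon are excluded.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("stop codon in aligned pair")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = non = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [w for order in permutations(diff_pos) if (w := walk(order, False)) is not None]
    if not paths:  # all orderings blocked by stops; fall back to unrestricted
        paths = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def back_translate_alignment(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand a pairwise protein alignment to a codon alignment.

    A trailing stop codon on either CDS is stripped.  Each CDS must translate
    exactly to its ungapped protein row.
    """
    if len(protein_a) != len(protein_b):
        raise ValueError("protein alignment rows differ in length")
    rows = []
    for prot, cds in ((protein_a, cds_a), (protein_b, cds_b)):
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot.replace("-", "").upper()
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS has {len(cds) // 3} codons but protein row has {len(ungapped)} residues"
            )
        aligned, k = [], 0
        for aa in prot.upper():
            if aa == "-":
                aligned.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            got = GENETIC_CODE.get(codon, "?")
            if got != aa and not (aa == "X" or got == "?"):
                raise ValueError(
                    f"codon {k} ({codon}) translates to {got!r}, protein row has {aa!r}"
                )
            aligned.append(codon)
            k += 1
        rows.append("".join(aligned))
    return CodonAlignment(cds_a=rows[0], cds_b=rows[1])


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment, lambda_rate: float = DEFAULT_LAMBDA) -> KaKsResult:
    """Nei–Gojobori Ka/Ks with Jukes–Cantor multiple-hit correction.

    Site counts are averaged over the two sequences; proportions ``ps = Sd/S``
    and ``pn = Nd/N`` are corrected as ``-(3/4) ln(1 - 4p/3)``.  When either
    proportion reaches 3/4 the logarithm leaves its domain and the result is
    flagged ``saturated`` (Ka/Ks reported as NaN).
    """
    pairs = aln.codon_pairs()
    if not pairs:
        raise ValueError("no ungapped codon pairs in alignment")
    s_a = n_a = s_b = n_b = sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s; nd += d_n
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return KaKsResult(
            ka=math.nan, ks=math.nan, omega=None,
            s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
            t_mya=None, status="saturated",
        )
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ks > 0:
        omega, status = ka / ks, "ok"
    else:
        omega, status = None, "undefined_omega" if ka > 0 else "ok"
    return KaKsResult(
        ka=ka, ks=ks, omega=omega,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        t_mya=divergence_time(ks, lambda_rate), status=status,
    )


def divergence_time(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Duplication age in million years: T = Ks / (2 * lambda) * 1e-6."""
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    if lambda_rate <= 0:
        raise ValueError("substitution rate must be positive")
    return ks / (2.0 * lambda_rate) * 1e-6


def write_kaks_report(
    results: Iterable[tuple[str, str, KaKsResult]], path: str | Path
) -> None:
    lines = ["gene_a\tgene_b\tka\tks\tomega\ts_sites\tn_sites\tsd\tnd\tt_mya\tstatus"]
    fmt = lambda v: "NA" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.4f}"
    for a, b, r in results:
        lines.append(
            "\t".join(
                [a, b, fmt(r.ka), fmt(r.ks), fmt(r.omega), fmt(r.s_sites),
                 fmt(r.n_sites), fmt(r.sd), fmt(r.nd), fmt(r.t_mya), r.status]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
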