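"""NG86 estimator tests, including an independent pathway-enumeration oracle.

The oracle recomputes per-codon site fractions and per-pair difference counts
by direct recursion over mutation orderings, sharing nothing with the
implementation except the genetic code table.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famdup.molevol import (
    GENETIC_CODE,
    STOP_CODONS,
    CodonAlignment,
    back_translate_alignment,
    codon_pair_differences,
    codon_sites,
    divergence_time,
    ng86,
    translate,
)
from famdup.synthetic_data import SENSE_CODONS, evolve_pair, random_cds

# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    """Synonymous site count by direct per-position enumeration."""
    total = 0.0
    for pos in range(3):
        changes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            changes.append(GENETIC_CODE[alt] == GENETIC_CODE[codon])
        if changes:
            total += sum(changes) / len(changes)
    return total


def oracle_differences(ca, cb):
    """(syn, nonsyn) averaged over stop-free mutation orderings, by recursion."""

    def paths(cur, remaining):
        if not remaining:
            return [(0, 0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                continue
            step = (1, 0) if GENETIC_CODE[cur] == GENETIC_CODE[nxt] else (0, 1)
            for s, n in paths(nxt, [p for p in remaining if p != pos]):
                out.append((step[0] + s, step[1] + n))
        return out

    remaining = [i for i in range(3) if ca[i] != cb[i]]
    results = paths(ca, remaining)
    if not results:
        # all orderings stop-blocked: oracle falls back to unrestricted, as documented
        def paths_any(cur, rem):
            if not rem:
                return [(0, 0)]
            out = []
            for pos in rem:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                step = (1, 0) if GENETIC_CODE.get(cur, "?") == GENETIC_CODE.get(nxt, "?") else (0, 1)
                for s, n in paths_any(nxt, [p for p in rem if p != pos]):
                    out.append((step[0] + s, step[1] + n))
            return out

        results = paths_any(ca, remaining)
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


# ---------------------------------------------------------------------------


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon,expected", [("TTT", 1 / 3), ("GGG", 1.0), ("AAA", 1 / 3)]
    )
    def test_hand_counts(self, codon, expected):
        s, n = codon_sites(codon)
        assert s == pytest.approx(expected)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            s, _ = codon_sites(codon)
            assert s == pytest.approx(oracle_sites(codon)), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")


class TestCodonPairDifferences:
    def test_all_single_codon_pairs_match_oracle(self):
        for ca, cb in itertools.product(SENSE_CODONS, SENSE_CODONS):
            got = codon_pair_differences(ca, cb)
            want = oracle_differences(ca, cb)
            assert got == pytest.approx(want), (ca, cb)

    def test_total_differences_equal_hamming(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ca, cb = rng.choice(SENSE_CODONS, size=2)
            sd, nd = codon_pair_differences(ca, cb)
            assert sd + nd == pytest.approx(sum(a != b for a, b in zip(ca, cb)))


class TestCodonAlignment:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment("TTTGGG", "TTT")

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="partial-codon"):
            CodonAlignment("T--TTT", "TTTTTT")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment("TAAGGG", "TTTGGG")

    def test_gapped_columns_dropped_pairwise(self):
        aln = CodonAlignment("TTT---GGG", "TTTAAAGGG")
        assert aln.codon_pairs() == [("TTT", "TTT"), ("GGG", "GGG")]


class TestBackTranslate:
    def test_gap_expansion(self):
        aln = back_translate_alignment("MA-V", "MAGV", "ATGGCAGTT", "ATGGCAGGAGTC")
        assert aln.cds_a == "ATGGCA---GTT"
        assert aln.cds_b == "ATGGCAGGAGTC"

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 1"):
            back_translate_alignment("MV", "MV", "ATGGCA", "ATGGTC")

    def test_identical_rows_identity_alignment(self):
        cds = "ATGGCAGTT"
        aln = back_translate_alignment("MAV", "MAV", cds, cds)
        assert aln.cds_a == aln.cds_b == cds

    def test_terminal_stop_stripped(self):
        aln = back_translate_alignment("MAV", "MAV", "ATGGCAGTTTAA", "ATGGCAGTT")
        assert aln.cds_a == "ATGGCAGTT"


class TestNg86:
    def test_identical_cds(self):
        r = ng86(CodonAlignment("ATGGCAGTT", "ATGGCAGTT"))
        assert r.ka == 0 and r.ks == 0 and r.status == "ok"

    def test_hand_derived_case(self):
        r = ng86(CodonAlignment("TTTGGGAAA", "TTCGGGAAA"))
        assert r.s_sites == pytest.approx(5 / 3)
        assert r.sd == pytest.approx(1.0)
        assert r.nd == pytest.approx(0.0)
        assert r.ks == pytest.approx(1.2071, abs=1e-4)
        assert r.ka == 0.0
        assert r.status == "ok"

    def test_site_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            a, b = random_cds(n, rng), random_cds(n, rng)
            r = ng86(CodonAlignment(a, b))
            assert r.s_sites + r.n_sites == pytest.approx(3 * n)

    def test_saturation_flagged(self):
        # maximally different synonymous-rich pair: force ps >= 0.75 via
        # many repeated highly divergent codons
        a = "GGG" * 10
        b = "GGA" * 10  # ps = 10 / 10 = 1 at synonymous sites only? construct:
        r = ng86(CodonAlignment(a, b))
        assert r.status == "saturated"
        assert math.isnan(r.ks)

    def test_omega_undefined_when_ks_zero(self):
        # one nonsynonymous difference, zero synonymous
        r = ng86(CodonAlignment("ATGGCA", "ATGTCA"))  # A->S at codon 2
        assert r.ks == 0 and r.ka > 0
        assert r.status == "undefined_omega"
        assert r.omega is None

    def test_multicodon_agreement_with_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 5))
            a, b = random_cds(n, rng), random_cds(n, rng)
            r = ng86(CodonAlignment(a, b))
            exp_sd = exp_nd = exp_s = 0.0
            for ca, cb in zip(
                [a[i : i + 3] for i in range(0, len(a), 3)],
                [b[i : i + 3] for i in range(0, len(b), 3)],
            ):
                s, n_ = oracle_differences(ca, cb)
                exp_sd += s
                exp_nd += n_
                exp_s += 0.5 * (oracle_sites(ca) + oracle_sites(cb))
            assert r.sd == pytest.approx(exp_sd)
            assert r.nd == pytest.approx(exp_nd)
            assert r.s_sites == pytest.approx(exp_s)

    def test_all_gap_alignment_errors(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment("---", "---"))


class TestEstimatorRecovery:
    def test_neutral_omega_recovered(self):
        rng = np.random.default_rng(0)
        estimates = []
        for rep in range(200):
            anc = random_cds(300, rng)
            a, b, _ = evolve_pair(anc, omega=1.0, target_ks=0.4, seed=rep)
            r = ng86(CodonAlignment(a, b))
            if r.omega is not None:
                estimates.append(r.omega)
        assert abs(np.mean(estimates) - 1.0) < 0.1

    def test_monotone_in_omega(self):
        rng = np.random.default_rng(1)
        low, high = [], []
        for rep in range(40):
            anc = random_cds(300, rng)
            a, b, _ = evolve_pair(anc, omega=0.2, target_ks=0.4, seed=500 + rep)
            low.append(ng86(CodonAlignment(a, b)).omega)
            a, b, _ = evolve_pair(anc, omega=1.0, target_ks=0.4, seed=900 + rep)
            high.append(ng86(CodonAlignment(a, b)).omega)
        assert np.mean(low) < np.mean(high)


class TestDivergenceTime:
    def test_zero(self):
        assert divergence_time(0.0) == 0.0

    def test_derived_point(self):
        assert divergence_time(1.0) == pytest.approx(81.97, abs=0.01)

    def test_negative_ks_errors(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    @given(
        st.floats(min_value=0, max_value=5, allow_nan=False),
        st.floats(min_value=1e-10, max_value=1e-7),
    )
    def test_linear_in_ks_inverse_in_lambda(self, ks, lam):
        t = divergence_time(ks, lam)
        assert divergence_time(2 * ks, lam) == pytest.approx(2 * t, rel=1e-9)
        assert divergence_time(ks, 2 * lam) == pytest.approx(t / 2, rel=1e-9)


def test_translate_standard_code():
    assert translate("ATGGCAGTTTAA") == "MAV*"
    with pytest.raises(ValueError):
        translate("ATGG")
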