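"""Modified Nei–Gojobori machinery against exhaustive enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcdiv import (
    CodonAlignment,
    PbrMask,
    SelectionConfig,
    jc_correct,
    jc_invert,
    kb_statistic,
    pairwise_dn_ds,
    partitioned_dnds,
    pi_s,
    tmrca,
)
from mhcdiv.selection import tmrca_from_distance

# ---------------------------------------------------------------------------
# independent oracles (fresh transcriptions, no shared code with the package)
# ---------------------------------------------------------------------------

TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str, R: float) -> tuple[float, float]:
    """Per-codon potential syn/nonsyn sites; stop targets dropped, renormalised."""
    s_total = 0.0
    n_pos = 0
    s = 0.0
    for pos in range(3):
        wsum = syn = 0.0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            new = codon[:pos] + b + codon[pos + 1 :]
            if aa(new) == "*":
                continue
            w = R if b == TS[codon[pos]] else 1.0
            wsum += w
            if aa(new) == aa(codon):
                syn += w
        s += syn / wsum if wsum else 0.0
    return s, 3.0 - s


def oracle_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged syn/nonsyn differences, stop pathways excluded."""
    diff = [k for k in range(3) if a[k] != b[k]]
    paths = []
    for order in itertools.permutations(diff):
        cur, syn, non, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa(nxt) == "*":
                blocked = True
            if aa(nxt) == aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((blocked, syn, non))
    usable = [p for p in paths if not p[0]] or paths
    return (
        sum(p[1] for p in usable) / len(usable),
        sum(p[2] for p in usable) / len(usable),
    )


SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if aa("".join(c)) != "*"
]


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------


@given(st.floats(min_value=0.0, max_value=0.74))
@settings(max_examples=50, derandomize=True)
def test_jc_round_trip(p):
    assert jc_invert(jc_correct(p)) == pytest.approx(p, abs=1e-12)


def test_jc_saturation_is_infinite():
    assert math.isinf(jc_correct(0.75))
    assert math.isinf(jc_correct(0.9))


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


class TestPairwiseDnDs:
    def test_identical_sequences(self):
        r = pairwise_dn_ds("ATGAAA", "ATGAAA")
        assert r.d_n == 0 and r.d_s == 0

    def test_single_codon_leu_phe(self):
        # TTT<->TTA with R=1: averaged sites N=2.5 (TTA position 1 has the
        # synonymous Leu change T->C), one nonsynonymous difference, so
        # p_N = 1/2.5 = 0.4
        r = pairwise_dn_ds("TTT", "TTA", cfg=SelectionConfig(R=1.0))
        s1, n1 = oracle_sites("TTT", 1.0)
        s2, n2 = oracle_sites("TTA", 1.0)
        assert r.n_nonsyn_sites == pytest.approx((n1 + n2) / 2)
        assert r.p_n == pytest.approx(0.4)
        assert r.p_s == 0
        assert r.d_n == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))

    def test_two_step_pathway_average(self):
        # TTT<->GTA: the two orderings classify as (1 syn, 1 non) and
        # (0 syn, 2 non); the average is 0.5 / 1.5
        r = pairwise_dn_ds("TTT", "GTA", cfg=SelectionConfig(R=1.0))
        assert r.syn_diffs == pytest.approx(0.5)
        assert r.nonsyn_diffs == pytest.approx(1.5)

    def test_synonymous_only_pair_ratio_zero(self):
        r = pairwise_dn_ds("TTA", "TTG")
        assert r.d_n == 0 and r.d_s > 0

    def test_saturation_flagged_not_nan(self):
        with pytest.warns(UserWarning, match="saturated"):
            r = pairwise_dn_ds("AAA" * 3, "GGG" * 3)
        assert r.saturated
        assert math.isinf(r.d_n)

    @pytest.mark.parametrize("R", [1.0, 1.58])
    def test_counts_match_enumeration_oracle(self, R):
        rng = np.random.default_rng(2024)
        pairs = [
            (SENSE_CODONS[i], SENSE_CODONS[j])
            for i, j in rng.integers(len(SENSE_CODONS), size=(150, 2))
        ]
        cfg = SelectionConfig(R=R)
        for a, b in pairs:
            r = pairwise_dn_ds(a, b, cfg=cfg)
            sd, nd = oracle_diffs(a, b)
            sa, na = oracle_sites(a, R)
            sb, nb = oracle_sites(b, R)
            assert r.syn_diffs == pytest.approx(sd)
            assert r.nonsyn_diffs == pytest.approx(nd)
            assert r.n_syn_sites == pytest.approx((sa + sb) / 2)
            assert r.n_nonsyn_sites == pytest.approx((na + nb) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_dn_ds("ATG", "ATGATG")


# ---------------------------------------------------------------------------
# partitioned dN/dS
# ---------------------------------------------------------------------------


class TestPartitionedDnDs:
    def test_site_count_partition_additivity(self, default_coding, mask):
        cfg = SelectionConfig(seed=0, bootstrap_reps=2)
        parts = partitioned_dnds(default_coding, mask, cfg)
        assert parts["pbr"].n_syn_sites + parts["non_pbr"].n_syn_sites == pytest.approx(
            parts["entire"].n_syn_sites
        )
        assert parts["pbr"].n_nonsyn_sites + parts["non_pbr"].n_nonsyn_sites == pytest.approx(
            parts["entire"].n_nonsyn_sites
        )
        assert parts["pbr"].n_codons + parts["non_pbr"].n_codons == parts["entire"].n_codons

    def test_duplicates_removed_before_averaging(self, mask):
        aln = CodonAlignment(
            {"a": "TTTAAA" * 10, "b": "TTTAAA" * 10, "c": "TTAAAA" * 10}
        )
        cfg = SelectionConfig(seed=0, bootstrap_reps=2)
        parts = partitioned_dnds(aln, mask, cfg)
        two_only = partitioned_dnds(aln.subset(["a", "c"]), mask, cfg)
        assert parts["entire"].d_s == pytest.approx(two_only["entire"].d_s)

    def test_deterministic_given_seed(self, default_coding, mask):
        cfg = SelectionConfig(seed=9, bootstrap_reps=20)
        a = partitioned_dnds(default_coding, mask, cfg)
        b = partitioned_dnds(default_coding, mask, cfg)
        assert a["pbr"].se_d_n == b["pbr"].se_d_n


# ---------------------------------------------------------------------------
# K_B, pi_S, TMRCA
# ---------------------------------------------------------------------------


class TestKb:
    def test_identical_sequences_zero(self, mask):
        aln = CodonAlignment({"a": "ATGAAA" * 10, "b": "ATGAAG" * 10})
        # only synonymous Lys third-position differences -> no PBR signal
        kb, _ = kb_statistic(aln, PbrMask(frozenset(range(6, 66)), offset=5))
        assert kb == 0

    def test_two_nonsynonymous_pbr_differences(self):
        # codons 1 and 2 are PBR; each carries one single-step
        # nonsynonymous difference (K->N at AAA->AAT? AAT is Asn: yes;
        # and M->L at ATG->CTG)
        a = "AAAATGGGG"
        b = "AATCTGGGG"
        mask = PbrMask(frozenset([6, 7]), offset=5)
        aln = CodonAlignment({"x": a, "y": b})
        kb, lineages = kb_statistic(aln, mask)
        assert kb == pytest.approx(2.0)
        assert lineages == 2


class TestPiS:
    def test_monomorphic_unit(self):
        aln = CodonAlignment({"a": "TTAGGG"})
        assert pi_s(aln, {"a": 10}) == 0.0

    def test_two_allele_closed_form(self):
        # frequencies 0.5 / 0.5, pairwise d_S = d: pi_S = 2 * 0.25 * d
        aln = CodonAlignment({"a": "TTA" * 30, "b": "TTG" + "TTA" * 29})
        d = pairwise_dn_ds(aln["a"], aln["b"]).d_s
        assert pi_s(aln, {"a": 5, "b": 5}) == pytest.approx(2 * 0.25 * d)

    def test_unweighted_mode_ignores_frequencies(self):
        aln = CodonAlignment({"a": "TTA" * 30, "b": "TTG" + "TTA" * 29})
        d = pairwise_dn_ds(aln["a"], aln["b"]).d_s
        assert pi_s(aln, weighted=False) == pytest.approx(d)


class TestTmrca:
    def test_worked_clock_example(self):
        # d_S-max 0.08 at 3.5e-9 per site per year -> about 11 million years
        years = tmrca_from_distance(0.08, 3.5e-9)
        assert years == pytest.approx(11.43e6, rel=0.01)

    def test_genealogy_shape_ratio(self):
        assert 0.078 / 0.028 == pytest.approx(2.79, abs=0.01)

    def test_identical_panel(self):
        aln = CodonAlignment({"a": "ATGAAA", "b": "ATGAAA"})
        with pytest.raises(ValueError):
            tmrca(aln)  # deduplicates to a single variant

    def test_max_at_least_mean(self, default_coding):
        cfg = SelectionConfig(seed=0, bootstrap_reps=1)
        d_max, years, ratio = tmrca(default_coding, cfg)
        assert ratio >= 1.0
        assert years == pytest.approx(d_max / (2 * cfg.mu))
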