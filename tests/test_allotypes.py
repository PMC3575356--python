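"""Translation flags, Wu–Kabat variability, PBR types and NJ clustering."""

import numpy as np
import pytest

from mhcdiv import (
    CodonAlignment,
    PbrMask,
    classify_pbr_types,
    heterozygote_pbr_mismatch,
    nj_pbr_tree,
    site_variability,
    translate_and_flag,
)
from mhcdiv.allotypes import neighbor_joining


def panel_from(seqs: dict[str, str]):
    return translate_and_flag(CodonAlignment(seqs))


class TestTranslateAndFlag:
    def test_internal_stop_flags_pseudogene(self):
        panel = panel_from({"ok": "ATGAAAATG", "ps": "ATGTAAATG"})
        assert panel.pseudogenes == {"ps"}
        assert panel.coding_variants == ["ok"]

    def test_all_atg_translates_clean(self):
        panel = panel_from({"v": "ATGATGATG"})
        assert panel.peptides["v"] == "MMM"
        assert not panel.pseudogenes

    def test_synthetic_panel_counts(self, default_panel):
        aln, truth = default_panel
        panel = translate_and_flag(aln)
        assert panel.pseudogenes == {truth["pseudogene"]}
        assert panel.n_allotypes == truth["config"]["n_allotypes"]


class TestSiteVariability:
    def test_invariant_position_has_v_one(self):
        seqs = {f"v{i}": "ATGAAA" for i in range(5)}
        seqs["v5"] = "ATGAGA"  # K -> R at codon 2
        panel = panel_from(seqs)
        mask = PbrMask(frozenset([6]), offset=5)
        var = site_variability(panel, mask)
        assert var.loc[6, "wu_kabat"] == 1.0
        assert not var.loc[6, "polymorphic"]

    def test_wu_kabat_formula(self):
        # 31 allotypes, one position with residues {A x30, S x1}:
        # V = k N / n_max = 2 * 31 / 30
        seqs = {}
        for i in range(31):
            aa1 = "GCT" if i < 30 else "TCT"
            # trailing codons cycle through distinct amino-acid pairs so the
            # 31 peptides are distinct allotypes
            seqs[f"v{i:02d}"] = aa1 + _distinct_codon(i)
        panel = panel_from(seqs)
        assert panel.n_allotypes == 31
        var = site_variability(panel, PbrMask(frozenset(), offset=5))
        v = var.loc[6, "wu_kabat"]
        assert v == pytest.approx(2 * 31 / 30)

    def test_polymorphic_split_by_mask(self, default_panel, mask):
        aln, _ = default_panel
        panel = translate_and_flag(aln)
        var = site_variability(panel, mask)
        from mhcdiv.allotypes import polymorphic_site_summary

        s = polymorphic_site_summary(var)
        assert s["polymorphic_pbr"] + s["polymorphic_non_pbr"] == s["polymorphic_sites"]


def _distinct_codon(i: int) -> str:
    # 31 distinct amino acids needed across two codons; use codon pairs
    from mhcdiv.selection import AA, CODONS

    sense = sorted({AA[c] for c in CODONS} - {"*"})
    aa_pair = (sense[i % 20], sense[(i // 20) % 20])
    first = {v: k for k, v in AA.items()}
    return "".join(
        next(c for c in CODONS if AA[c] == a) for a in aa_pair
    )


class TestPbrTypes:
    def test_identical_pbr_peptides_single_type(self):
        seqs = {"a": "ATGAAA", "b": "ATGAGA"}  # differ only at codon 2
        panel = panel_from(seqs)
        types = classify_pbr_types(panel, PbrMask(frozenset([6]), offset=5))
        assert len(types) == 1

    def test_planted_partition_recovered(self):
        # four allotypes, two planted PBR haplotypes at codon 1
        seqs = {
            "a": "ATGAAA",
            "b": "ATGAGA",
            "c": "CTGAAA",
            "d": "CTGCTG",
        }
        panel = panel_from(seqs)
        types = classify_pbr_types(panel, PbrMask(frozenset([6]), offset=5))
        grouped = sorted(sorted(panel.allotypes[m][0] for m in ms) for ms in types.values())
        assert grouped == [["a", "b"], ["c", "d"]]

    def test_type_count_invariant_under_reordering(self, default_panel, mask):
        aln, _ = default_panel
        panel = translate_and_flag(aln)
        n1 = len(classify_pbr_types(panel, mask))
        rev = CodonAlignment({v: aln[v] for v in reversed(aln.ids)})
        n2 = len(classify_pbr_types(translate_and_flag(rev), mask))
        assert n1 == n2


class TestHeterozygotePbrMismatch:
    MASK = PbrMask(frozenset([6]), offset=5)

    def _setup(self):
        seqs = {"a": "ATGAAA", "b": "ATGAGA", "c": "CTGAAA"}
        panel = panel_from(seqs)
        types = classify_pbr_types(panel, self.MASK)
        return panel, types

    def test_homozygotes_only(self):
        panel, types = self._setup()
        assert heterozygote_pbr_mismatch([("a", "a")], panel, types) == (0, 0)

    def test_within_and_across_types(self):
        panel, types = self._setup()
        # a/b share the PBR codon (within type); a/c differ (across)
        assert heterozygote_pbr_mismatch([("a", "b"), ("a", "c")], panel, types) == (1, 2)

    def test_unknown_variant_is_error(self):
        panel, types = self._setup()
        with pytest.raises(KeyError):
            heterozygote_pbr_mismatch([("a", "zzz")], panel, types)

    def test_random_genotypes_match_analytic_expectation(self):
        # sampling alleles uniformly from PBR types with frequencies q_t,
        # the across-type fraction of heterozygotes approximates
        # (1 - sum q_t^2) renormalised to heterozygote draws
        rng = np.random.default_rng(42)
        panel, types = self._setup()
        variants = ["a", "b", "c"]
        draws = [tuple(rng.choice(variants, 2)) for _ in range(4000)]
        mm, het = heterozygote_pbr_mismatch(draws, panel, types)
        # alleles uniform over {a,b,c}: type1={a,b} q=2/3, type2={c} q=1/3
        # P(het variants) = 2/3; P(across types) = 2*2/3*1/3 = 4/9
        assert mm / het == pytest.approx((4 / 9) / (2 / 3), abs=0.05)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        nwk = neighbor_joining(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        assert "A:1" in nwk and "B:1" in nwk and "C:3" in nwk

    def test_additive_four_taxon_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); AB vs CD split
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        nwk = neighbor_joining(["A", "B", "C", "D"], d)
        assert ("(A:1,B:2)" in nwk.replace(" ", "")) or ("(B:2,A:1)" in nwk.replace(" ", ""))

    def test_matches_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(7)
        # random additive matrix from a random tree via path lengths
        n = 6
        labels = [f"t{i}" for i in range(n)]
        # build caterpillar with random branch lengths
        bl = rng.integers(1, 6, size=2 * n).astype(float)
        d = np.zeros((n, n))
        coords = np.cumsum(bl[:n])
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = abs(coords[i] - coords[j]) + bl[n + i] + bl[n + j]
        ours = neighbor_joining(labels, d)
        theirs = sk_nj(DistanceMatrix(d, labels))
        import io

        from skbio import TreeNode

        t1 = TreeNode.read(io.StringIO(ours))
        t2 = theirs
        assert t1.compare_rfd(t2) == 0.0

    def test_identical_peptides_collapsed(self):
        tree = nj_pbr_tree({"a": "MK", "b": "MK", "c": "ML", "d": "MM"})
        assert "b" not in tree
        assert all(x in tree for x in ("a", "c", "d"))

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_pbr_tree({"a": "MK", "b": "MK", "c": "MK"})
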