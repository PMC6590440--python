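"""Rate-class parsing, trimming, and the codon/nucleotide ML engines."""

import math

import numpy as np
import pytest

from plastevol.io import Alignment
from plastevol.rates import (
    CodonModel,
    NucleotideModel,
    compare_rates,
    ds_from_t,
    parse_rate_class,
    trim_alignment,
)
from plastevol.rates import RateTree
from plastevol.trees import parse_newick

from conftest import RATE_TREE


class TestRateClasses:
    def test_published_class_string(self):
        spec = parse_rate_class("012232")
        assert spec.free_count == 4
        classes = spec.pair_classes()
        assert classes[("A", "C")] == 0
        assert classes[("A", "G")] == 1
        assert classes[("A", "T")] == 2
        assert classes[("C", "G")] == 2
        assert classes[("C", "T")] == 3
        assert classes[("G", "T")] == 2

    def test_single_class_and_full_gtr(self):
        assert parse_rate_class("000000").free_count == 1
        assert parse_rate_class("012345").free_count == 6

    def test_dense_renumbering(self):
        spec = parse_rate_class("505050")
        assert spec.assignment == (0, 1, 0, 1, 0, 1)
        assert spec.free_count == 2

    @pytest.mark.parametrize("bad", ["01223", "0122334", "01223a"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_rate_class(bad)


class TestTrimming:
    def test_gappy_column_removed_at_threshold(self):
        aln = Alignment(["a", "b", "c", "d"],
                        ["A-G", "A-G", "AAG", "A-G"], "nucleotide")
        out = trim_alignment(aln, max_gap_fraction=0.5)
        assert out.n_sites == 2

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(["a", "b"], ["ACGTAA", "ACGTAA"], "codon")
        out = trim_alignment(aln)
        assert out.rows == aln.rows

    def test_codon_mode_drops_whole_triplets(self):
        aln = Alignment(["a", "b"], ["ATG---", "ATGAAA"], "codon")
        out = trim_alignment(aln, mode="codon", max_gap_fraction=0.4)
        assert out.n_codons == 1

    def test_every_retained_column_within_threshold(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT-"), size=60)) for _ in range(6)]
        aln = Alignment([f"t{i}" for i in range(6)], rows, "nucleotide")
        out = trim_alignment(aln, max_gap_fraction=0.5)
        for col in range(out.n_sites):
            gaps = sum(1 for r in out.rows if r[col] == "-")
            assert gaps / 6 <= 0.5

    def test_empty_result_rejected(self):
        aln = Alignment(["a", "b"], ["---", "---"], "nucleotide")
        with pytest.raises(ValueError):
            trim_alignment(aln, max_gap_fraction=0.4)


class TestNucleotideModel:
    def test_jukes_cantor_closed_form(self):
        rng = np.random.default_rng(0)
        n = 6000
        a = rng.choice(list("ACGT"), size=n)
        b = a.copy()
        for i in np.where(rng.random(n) < 0.1)[0]:
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        p = float(np.mean(a != b))
        aln = Alignment(["A", "B"], ["".join(a), "".join(b)], "nucleotide")
        res = NucleotideModel(aln, "(A:0.05,B:0.05);", rate_classes="000000",
                              gamma_categories=0, invariant=False,
                              frequencies="equal").fit()
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert abs(sum(res.branch_d.values()) - expected) < 1e-4

    def test_zero_divergence_gives_zero_branches(self):
        row = "ACGTAAGGCC" * 30
        aln = Alignment(["A", "B", "C"], [row, row, row], "nucleotide")
        res = NucleotideModel(aln, "(A:0.1,B:0.1,C:0.1);", invariant=False,
                              gamma_categories=0).fit(max_sweeps=5)
        assert all(d < 1e-6 for d in res.branch_d.values())

    def test_loglik_invariant_to_root_placement(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(4)]
        aln = Alignment(list("ABCD"), rows, "nucleotide")
        t1 = "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.05);"
        t2 = "(A:0.1,B:0.2,(C:0.15,D:0.1):0.1);"  # same unrooted tree
        m1 = NucleotideModel(aln, t1, gamma_categories=0, invariant=False)
        m2 = NucleotideModel(aln, t2, gamma_categories=0, invariant=False)
        theta = np.ones(6)
        t_of1 = {b.label: (b.length or 0.1) for b in m1.engine.branches}
        t_of2 = {b.label: (b.length or 0.1) for b in m2.engine.branches}
        ll1 = m1._loglik(theta, None, 0.0, t_of1)
        ll2 = m2._loglik(theta, None, 0.0, t_of2)
        assert abs(ll1 - ll2) < 1e-8


class TestCodonModel:
    def test_zero_divergence_gives_zero_ds(self):
        row = "ATGGCTGCTAAAGCT" * 20
        aln = Alignment(["A", "B", "C"], [row, row, row], "codon")
        res = CodonModel(aln, "(A:0.1,B:0.1,C:0.1);").fit(max_sweeps=3)
        assert all(ds < 1e-6 for ds in res.branch_ds.values())

    def test_internal_stop_codon_rejected(self):
        aln = Alignment(["A", "B"], ["ATGTAAGCT", "ATGAAAGCT"], "codon")
        with pytest.raises(ValueError, match="internal stop"):
            CodonModel(aln, "(A:0.1,B:0.1);")

    def test_ds_zero_at_zero_branch_length(self):
        spec = parse_rate_class("012345")
        assert ds_from_t(0.0, np.ones(6), 0.3, np.full((3, 4), 0.25), spec) == 0.0

    def test_rate_class_nesting(self):
        """More exchangeability classes can only improve the likelihood."""
        from plastevol.simulate import SimulationConfig, evolve_sequences

        tree = "(A:0.15,B:0.2,(C:0.1,D:0.25)CD:0.1);"
        cfg = SimulationConfig(seed=4, codon_sites=400, tree=tree)
        sim = evolve_sequences(tree, cfg)
        lls = {}
        for cls in ("012345", "012232", "000000"):
            lls[cls] = CodonModel(sim.sc_codon, tree, cls).fit(max_sweeps=4, tol=1e-4).loglik
        assert lls["012345"] >= lls["012232"] - 0.1
        assert lls["012232"] >= lls["000000"] - 0.1

    def test_recovery_smoke(self):
        """Moderate-size recovery: dS within 20% per branch at 1000 codons."""
        from plastevol.simulate import SimulationConfig, evolve_sequences

        cfg = SimulationConfig(seed=6, codon_sites=1000, tree=RATE_TREE)
        sim = evolve_sequences(RATE_TREE, cfg)
        res = CodonModel(sim.sc_codon, RATE_TREE).fit(max_sweeps=4, tol=1e-4)
        for b, ds in sim.true_ds_sc.items():
            assert abs(res.branch_ds[b] - ds) / ds < 0.25, b

    def test_summary_mentions_model_and_branches(self):
        row = "ATGGCTAAAGCTTTT" * 10
        aln = Alignment(["A", "B"], [row, row], "codon")
        res = CodonModel(aln, "(A:0.01,B:0.01);", "012232").fit(max_sweeps=2)
        text = res.summary()
        assert "MG94" in text and "012232" in text and "dS" in text


class TestComparison:
    def _tree(self, values):
        t = parse_newick("(A:1,B:1,C:1)r;")
        return RateTree(tree=t, values=values, kind="dS")

    def test_identical_trees_ratio_one(self):
        t = self._tree({"A": 0.3, "B": 0.2, "C": 0.1})
        cmp = compare_rates(t, t, "A")
        assert cmp.ratio == 1.0

    def test_published_style_ratio(self):
        dup = self._tree({"A": 0.184, "B": 0.2, "C": 0.1})
        sc = self._tree({"A": 0.544, "B": 0.2, "C": 0.1})
        cmp = compare_rates(dup, sc, "A")
        assert abs(cmp.ratio - 0.338) < 0.001

    def test_zero_denominator_flagged(self):
        dup = self._tree({"A": 0.1})
        sc = self._tree({"A": 0.0})
        cmp = compare_rates(dup, sc, "A")
        assert cmp.flagged and cmp.ratio is None

    def test_unknown_species_raises(self):
        t = self._tree({"A": 0.1})
        with pytest.raises(KeyError):
            compare_rates(t, t, "Z")
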