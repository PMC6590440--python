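"""Gene-status scoring, content matrices and parsimony loss mapping."""

from itertools import product

import pytest

from plastevol.content import (
    DEFAULT_COSTS,
    STATES,
    build_content_matrix,
    load_catalog,
    reconstruct_losses,
    replay_events,
    sankoff_cost,
    score_gene_status,
)
from plastevol.io import GeneFeature, PlastomeRecord
from plastevol.trees import parse_newick


def _cds_record(seq: str, name="rbcL", exons=()):
    feat = GeneFeature(name, "protein", 0, len(seq), 1, exons=tuple(exons))
    return feat, PlastomeRecord(id="x", sequence=seq, features=[feat])


class TestScoring:
    def test_absent_without_feature(self):
        assert score_gene_status(None, None) == "absent"

    def test_full_open_frame_intact(self):
        seq = "ATG" + "GCT" * 50 + "TAA"
        feat, rec = _cds_record(seq)
        assert score_gene_status(feat, rec, reference_length=len(seq)) == "intact"

    def test_frameshift_is_pseudogene(self):
        # 301 bp: exon sum mod 3 == 1
        seq = "ATG" + "A" * 298
        feat, rec = _cds_record(seq)
        assert score_gene_status(feat, rec) == "pseudogene"

    def test_internal_stops_only_matter_without_editing(self):
        seq = "ATG" + "GCT" * 10 + "TAA" + "GCT" * 10 + "TAA"
        feat, rec = _cds_record(seq)
        assert score_gene_status(feat, rec, no_uc_editing=True) == "pseudogene"
        assert score_gene_status(feat, rec, no_uc_editing=False) == "intact"

    def test_substantial_truncation(self):
        seq = "ATG" + "GCT" * 20 + "TAA"
        feat, rec = _cds_record(seq)
        assert score_gene_status(feat, rec, reference_length=600) == "pseudogene"
        assert score_gene_status(feat, rec, reference_length=90) == "intact"

    def test_rna_genes_scored_by_presence(self):
        feat = GeneFeature("trnH-GUG", "tRNA", 0, 72, 1)
        rec = PlastomeRecord(id="x", sequence="A" * 72, features=[feat])
        assert score_gene_status(feat, rec) == "intact"


class TestMatrix:
    def test_simulated_losses_recovered(self, mini_clade):
        records, truth = mini_clade
        matrix = build_content_matrix(list(records.values()))
        # the static clade lost trnT-GGU by script
        for tip in ("T1", "T2", "T3"):
            assert matrix.states.loc[tip, "trnT-GGU"] == "absent"
        for tip in ("T4", "T5", "T6", "T7"):
            assert matrix.states.loc[tip, "trnT-GGU"] == "intact"

    def test_pseudogene_detected_from_frameshift(self):
        from plastevol.simulate import SimulationConfig, simulate_history

        cfg = SimulationConfig(
            seed=9, n_inversions=0, loss_rate=0.0,
            tree="((P:1,Q:1)PQ:1,R:1)Root;",
            branch_events={"P": [("pseudo", "atpA")]})
        records, truth = simulate_history(cfg)
        matrix = build_content_matrix(list(records.values()))
        assert matrix.states.loc["P", "atpA"] == "pseudogene"
        assert matrix.states.loc["Q", "atpA"] == "intact"

    def test_empty_record_scores_all_absent(self):
        rec = PlastomeRecord(id="void", sequence="ACGT" * 100, features=[])
        matrix = build_content_matrix([rec])
        assert (matrix.states.loc["void"].isin(["absent"])).all()

    def test_category_totals_count_intact_only(self, content_matrix):
        tot = content_matrix.totals()
        # published per-genome counts
        assert tot.loc["Dobs", "protein"] == 87
        assert tot.loc["Ifla", "protein"] == 82
        assert tot.loc["Dobs", "intron"] == 22
        assert tot.loc["Stam", "tRNA"] == 6
        assert tot.loc["Stam", "genes"] == 68


class TestSankoff:
    def _brute(self, tips, tree, costs):
        internals = [n for n in tree.postorder() if not n.is_leaf]
        best = float("inf")
        for combo in product(STATES, repeat=len(internals)):
            assign = dict(zip([id(n) for n in internals], combo))
            cost = 0.0
            for n in tree.postorder():
                if n.parent is None:
                    continue
                a = assign[id(n.parent)]
                b = tips[n.label] if n.is_leaf else assign[id(n)]
                cost += costs[(a, b)]
            best = min(best, cost)
        return best

    @pytest.mark.parametrize("newick", [
        "((A,B)ab,(C,D)cd)r;",
        "(((A,B)ab,C)abc,((D,E)de,(F,G)fg)defg)r;",
        "((A,B,C)abc,(D,(E,F,G)efg)defg,H)r;",  # polytomies
    ])
    def test_dp_equals_exhaustive_enumeration(self, newick):
        import random

        rng = random.Random(13)
        tree = parse_newick(newick)
        for _ in range(25):
            tips = {t: rng.choice(STATES) for t in tree.leaf_names()}
            assert sankoff_cost(tips, tree, DEFAULT_COSTS) == self._brute(tips, tree, DEFAULT_COSTS)

    def test_four_taxon_unit_cost_example(self):
        tree = parse_newick("((A,B)ab,(C,D)cd)r;")
        tips = {"A": "intact", "B": "absent", "C": "intact", "D": "intact"}
        unit = {(a, b): (0.0 if a == b else 1.0) for a in STATES for b in STATES}
        assert sankoff_cost(tips, tree, unit) == 1.0


class TestReconstruction:
    def test_all_intact_element_has_no_events(self, content_matrix, lycophyte_tree):
        res = reconstruct_losses(content_matrix, lycophyte_tree)
        assert res.element_events("rrn16") == []
        assert res.per_element_cost["rrn16"] == 0

    def test_published_placements(self, content_matrix, lycophyte_tree):
        """Single loss of trnT-GGU on the clubmoss stem; independent losses
        of the ndh complex in the two ndh-less spikemoss termini."""
        res = reconstruct_losses(content_matrix, lycophyte_tree)
        trnt = dict(res.element_events("trnT-GGU"))
        assert trnt.get("Lycopodiaceae") == "loss"
        for gene in ("ndhA", "ndhF", "ndhK"):
            branches = {br for br, ev in res.element_events(gene)}
            assert branches == {"Stam", "Slep"}, gene
        # spikemoss-wide losses map to the genus stem
        shared = dict(res.element_events("rps15"))
        assert shared.get("Selaginella") == "loss"

    def test_no_gains_under_quasi_dollo_costs(self, content_matrix, lycophyte_tree):
        res = reconstruct_losses(content_matrix, lycophyte_tree)
        for branch, events in res.events.items():
            for el, ev, _a, _b in events:
                assert ev != "gain", (branch, el)

    def test_replay_reproduces_tip_states(self, content_matrix, lycophyte_tree):
        res = reconstruct_losses(content_matrix, lycophyte_tree)
        replayed = replay_events(res, lycophyte_tree)
        for el in res.root_states:
            observed = content_matrix.states[el].replace({"present": "intact"})
            for taxon in content_matrix.taxa:
                assert replayed.loc[taxon, el] == observed[taxon], (el, taxon)

    def test_missing_taxon_raises(self, content_matrix):
        small = parse_newick("((Dobs,Ddig)a,Lcla)r;")
        with pytest.raises(ValueError, match="absent from tree"):
            reconstruct_losses(content_matrix, small)
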