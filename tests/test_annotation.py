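"""Evidence cascade, synteny resolution and coverage reporting."""

import numpy as np
import pandas as pd
import pytest

from axiswitch import annotation as ann
from axiswitch.simulate import SimulationConfig, simulate_annotations_and_orthologs


def vendor_frame(rows):
    return pd.DataFrame(rows, columns=["probeset_id", "gene_id", "est_ids"])


class TestEstChaining:
    def test_vendor_annotation_takes_precedence(self):
        vendor = vendor_frame([("PS0", "G_vendor", "e1,e2")])
        est = pd.DataFrame({"est_id": ["e1", "e2"], "gene_id": ["G_other", "G_other"]})
        out = ann.map_probesets_to_genes(vendor, est)
        assert out.loc[0, "gene_id"] == "G_vendor"
        assert out.loc[0, "evidence"] == "vendor"

    def test_consistent_est_chain_assigns_gene(self):
        vendor = vendor_frame([("PS0", "", "e1,e2,e3")])
        est = pd.DataFrame({"est_id": ["e1", "e2", "e3"], "gene_id": ["G"] * 3})
        out = ann.map_probesets_to_genes(vendor, est)
        assert out.loc[0, "gene_id"] == "G" and out.loc[0, "evidence"] == "est_chain"

    def test_conflicting_ests_leave_probeset_unresolved_and_flagged(self):
        vendor = vendor_frame([("PS0", "", "e1,e2")])
        est = pd.DataFrame({"est_id": ["e1", "e2"], "gene_id": ["G1", "G2"]})
        out = ann.map_probesets_to_genes(vendor, est)
        assert pd.isna(out.loc[0, "gene_id"]) and bool(out.loc[0, "conflict"])

    def test_unmapped_ests_give_null_without_conflict(self):
        vendor = vendor_frame([("PS0", "", "e9")])
        out = ann.map_probesets_to_genes(vendor, pd.DataFrame(columns=["est_id", "gene_id"]))
        assert pd.isna(out.loc[0, "gene_id"]) and not bool(out.loc[0, "conflict"])


def toy_synteny(decoy_neighbours=0):
    """One ambiguous source a3 with true partner b3 and decoy bX.

    Species A chromosome: a1..a5 in order; species B mirrors it.  The decoy
    sits on its own chromosome surrounded by ``decoy_neighbours`` genes whose
    orthologs neighbour a3 (symmetric ties when equal to the true side).
    """
    orders_a = {"cA": [f"a{i}" for i in range(1, 6)]}
    orders_b = {"cB": [f"b{i}" for i in range(1, 6)], "cD": []}
    table = [{"gene_A": f"a{i}", "gene_B": f"b{i}"} for i in (1, 2, 4, 5)]
    table.append({"gene_A": "a3", "gene_B": "b3"})
    table.append({"gene_A": "a3", "gene_B": "bX"})
    decoy_chrom = ["bX"]
    for j in range(decoy_neighbours):
        # move a true neighbour's ortholog next to the decoy instead
        orders_b["cB"].remove(f"b{j + 1}")
        decoy_chrom.append(f"b{j + 1}")
    orders_b["cD"] = decoy_chrom
    return pd.DataFrame(table), orders_a, orders_b


class TestSynteny:
    def test_one_to_one_rows_pass_through(self):
        table = pd.DataFrame({"gene_A": ["a1"], "gene_B": ["b1"]})
        res = ann.resolve_orthologs_by_synteny(table, {"c": ["a1"]}, {"c": ["b1"]})
        assert res.resolved.loc[0, "method"] == "one_to_one"
        assert len(res.unresolved) == 0

    def test_dominant_candidate_wins(self):
        table, oa, ob = toy_synteny(decoy_neighbours=0)
        res = ann.resolve_orthologs_by_synteny(table, oa, ob, window=5, min_margin=1)
        chosen = res.resolved.set_index("gene_A").loc["a3"]
        assert chosen["gene_B"] == "b3" and chosen["method"] == "synteny"
        assert chosen["score"] >= 3  # b1,b2,b4,b5 all neighbour b3

    def test_symmetric_tie_stays_unresolved(self):
        table, oa, ob = toy_synteny(decoy_neighbours=4)  # decoy matches true side
        res = ann.resolve_orthologs_by_synteny(table, oa, ob, window=5, min_margin=1)
        assert "a3" in set(res.unresolved["gene_A"])
        assert "a3" not in set(res.resolved["gene_A"])

    def test_resolution_invariant_to_candidate_order(self):
        table, oa, ob = toy_synteny()
        shuffled = table.iloc[::-1].reset_index(drop=True)
        r1 = ann.resolve_orthologs_by_synteny(table, oa, ob)
        r2 = ann.resolve_orthologs_by_synteny(shuffled, oa, ob)
        pd.testing.assert_frame_equal(
            r1.resolved.sort_values("gene_A").reset_index(drop=True),
            r2.resolved.sort_values("gene_A").reset_index(drop=True),
        )

    def test_gene_missing_from_order_map_scores_zero_with_warning(self):
        table = pd.DataFrame(
            {"gene_A": ["a3", "a3"], "gene_B": ["b3", "ghost"]}
        )
        oa = {"cA": ["a1", "a2", "a3"]}
        ob = {"cB": ["b1", "b2", "b3"]}
        with pytest.warns(UserWarning, match="absent from gene order"):
            ann.resolve_orthologs_by_synteny(table, oa, ob, min_margin=0)

    def test_generator_planted_orthologs_fully_recovered(self):
        cfg = SimulationConfig(n_probesets=300, probes_per_probeset=2, seed=13)
        bundle, truth = simulate_annotations_and_orthologs(cfg)
        res = ann.resolve_orthologs_by_synteny(
            bundle.orthologs, bundle.orders_a, bundle.orders_b
        )
        resolved = res.resolved.set_index("gene_A")["gene_B"]
        truth_pairs = truth.ortholog_truth
        assert all(
            resolved.get(a) == b
            for a, b in zip(truth_pairs["gene_A"], truth_pairs["gene_B"])
        )
        assert len(res.unresolved) == 0


class TestSimilarity:
    HITS = pd.DataFrame(
        {
            "probeset_id": ["PS0", "PS0", "PS1", "PS1", "PS2"],
            "protein_id": ["P1", "P2", "P3", "P4", "P5"],
            "gene_id": ["G1", "G2", "G3", "G4", "G5"],
            "identity": [95.0, 80.0, 91.0, 91.0, 99.0],
            "length": [100] * 5,
            "evalue": [1e-20, 1e-20, 1e-20, 1e-20, 0.5],
        }
    )

    def test_best_passing_hit_assigns_its_gene(self):
        out = ann.assign_by_similarity(["PS0"], self.HITS, min_identity=90)
        assert list(out["gene_id"]) == ["G1"]
        assert (out["evidence"] == "similarity").all()

    def test_equal_best_identities_to_different_genes_stay_unresolved(self):
        out = ann.assign_by_similarity(["PS1"], self.HITS, min_identity=90)
        assert len(out) == 0

    def test_evalue_and_identity_thresholds_filter(self):
        assert len(ann.assign_by_similarity(["PS2"], self.HITS, max_evalue=1e-5)) == 0
        assert len(ann.assign_by_similarity(["PS0"], self.HITS, min_identity=99.5)) == 0


class TestEvidencePrecedence:
    def test_precedence_is_total_and_enforced(self):
        frames = [
            pd.DataFrame(
                [{"probeset_id": "PS0", "gene_id": "G_sim", "evidence": "similarity",
                  "est_ids": "", "conflict": False}]
            ),
            pd.DataFrame(
                [{"probeset_id": "PS0", "gene_id": "G_est", "evidence": "est_chain",
                  "est_ids": "e1", "conflict": False},
                 {"probeset_id": "PS1", "gene_id": "G_syn", "evidence": "ortholog_synteny",
                  "est_ids": "", "conflict": False}]
            ),
        ]
        merged = ann.merge_evidence(*frames).set_index("probeset_id")
        assert merged.loc["PS0", "gene_id"] == "G_est"
        assert merged.loc["PS1", "evidence"] == "ortholog_synteny"


class TestCoverageReport:
    def test_no_change_reports_zero_newly_annotated(self):
        before = vendor_frame([("PS0", "G1", ""), ("PS1", "", "")])
        rep = ann.annotation_coverage_report(before, before)
        assert rep.loc["all", "newly_annotated"] == 0

    def test_planted_gap_closure_reported_as_35_to_16(self):
        cfg = SimulationConfig(n_probesets=400, probes_per_probeset=2, seed=17)
        bundle, _ = simulate_annotations_and_orthologs(cfg)
        mapped = ann.map_probesets_to_genes(bundle.annotation, bundle.est_to_gene)
        rep = ann.annotation_coverage_report(bundle.annotation, mapped)
        assert rep.loc["all", "frac_unannotated_before"] == pytest.approx(0.35, abs=0.01)
        assert rep.loc["all", "frac_unannotated_after"] == pytest.approx(0.16, abs=0.01)

    def test_empty_significant_list_reported_not_applicable(self):
        before = vendor_frame([("PS0", "G1", "")])
        rep = ann.annotation_coverage_report(before, before, {"sig": set()})
        assert np.isnan(rep.loc["sig", "frac_unannotated_after"])
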