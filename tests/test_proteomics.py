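import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import tryptic_peptides_bruteforce
from uhpscan.proteomics import (
    compute_pec,
    discriminating_peptides,
    filter_evidence,
    tissue_specificity,
    tryptic_digest,
)

proteins = st.text(alphabet="ACDKRPGLS", min_size=1, max_size=30)


def evidence_frame(rows):
    return pd.DataFrame(
        rows, columns=["peptide", "pep_score", "experiment_id", "tissue"]
    )


class TestTrypticDigest:
    def test_simple_protein_by_hand(self):
        prot = "MAAAAAKGGGGGGRSSSSSSS"
        peps = {s.sequence for s in tryptic_digest(prot, max_missed=0)}
        assert peps == {"MAAAAAK", "GGGGGGR", "SSSSSSS"}

    def test_missed_cleavage_adds_joined_peptides(self):
        prot = "MAAAAAKGGGGGGRSSSSSSS"
        peps = {s.sequence for s in tryptic_digest(prot, max_missed=1)}
        assert "MAAAAAKGGGGGGR" in peps
        assert "GGGGGGRSSSSSSS" in peps
        assert "MAAAAAKGGGGGGRSSSSSSS" not in peps  # two missed cleavages

    def test_proline_blocks_cleavage(self):
        prot = "MAAAAAKPGGGGGR"
        peps = {s.sequence for s in tryptic_digest(prot, max_missed=0)}
        assert peps == {"MAAAAAKPGGGGGR"}

    def test_short_peptides_dropped(self):
        assert tryptic_digest("MAKGGR", max_missed=0) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(proteins, st.integers(0, 2), st.integers(1, 7))
    def test_matches_bruteforce_oracle(self, prot, max_missed, min_len):
        got = {s.sequence for s in tryptic_digest(prot, max_missed, min_len)}
        assert got == tryptic_peptides_bruteforce(prot, max_missed, min_len)

    def test_spans_are_correct_substrings(self):
        prot = "MAAAAAKGGGGGGRSSSSSSS"
        for span in tryptic_digest(prot):
            assert prot[span.start : span.end] == span.sequence


class TestFilterEvidence:
    PROTEOME = {
        "g1": ["MAAAAAKGGGGGGR"],
        "g2": ["MWWWWWKGGGGGGR"],  # shares GGGGGGR with g1
    }

    def base_rows(self):
        return [
            ("MAAAAAK", 0.0001, "e1", "T1"),
            ("MAAAAAK", 0.0001, "e2", "T1"),
        ]

    def test_passing_records_kept(self):
        out = filter_evidence(evidence_frame(self.base_rows()), self.PROTEOME)
        assert len(out) == 2

    def test_pep_boundary_inclusive(self):
        rows = [
            ("MAAAAAK", 0.001, "e1", "T1"),
            ("MAAAAAK", 0.001, "e2", "T1"),
            ("MAAAAAK", 0.0011, "e3", "T1"),
        ]
        out = filter_evidence(evidence_frame(rows), self.PROTEOME)
        assert len(out) == 2
        assert set(out["experiment_id"]) == {"e1", "e2"}

    def test_shared_peptide_removed(self):
        rows = self.base_rows() + [
            ("GGGGGGR", 0.0001, "e1", "T1"),
            ("GGGGGGR", 0.0001, "e2", "T1"),
        ]
        out = filter_evidence(evidence_frame(rows), self.PROTEOME)
        assert set(out["peptide"]) == {"MAAAAAK"}

    def test_nontryptic_peptide_removed(self):
        rows = [
            ("AAAAAKG", 0.0001, "e1", "T1"),  # substring but not tryptic
            ("AAAAAKG", 0.0001, "e2", "T1"),
        ]
        out = filter_evidence(evidence_frame(rows), self.PROTEOME)
        assert out.empty

    def test_single_experiment_peptide_removed(self):
        rows = [("MAAAAAK", 0.0001, "e1", "T1")]
        out = filter_evidence(evidence_frame(rows), self.PROTEOME)
        assert out.empty

    def test_order_independence(self):
        rows = self.base_rows() + [("GGGGGGR", 0.0001, "e1", "T1")]
        a = filter_evidence(evidence_frame(rows), self.PROTEOME)
        b = filter_evidence(evidence_frame(rows[::-1]), self.PROTEOME)
        assert sorted(map(tuple, a.values)) == sorted(map(tuple, b.values))

    def test_missing_column_is_error(self):
        with pytest.raises(ValueError):
            filter_evidence(pd.DataFrame({"peptide": []}), self.PROTEOME)

    def test_equate_il_merges_isobaric_peptides(self):
        proteome = {"g1": ["MAIAAAKGGGGGGR"], "g2": ["MALAAAKGGGGGGR"]}
        rows = [("MAIAAAK", 0.0001, "e1", "T1"), ("MAIAAAK", 0.0001, "e2", "T1")]
        strict = filter_evidence(evidence_frame(rows), proteome)
        merged = filter_evidence(evidence_frame(rows), proteome, equate_il=True)
        assert len(strict) == 2  # unique under exact matching
        assert merged.empty  # ambiguous once I == L


class TestDiscriminatingPeptides:
    UHP_A = "DDDDDDDDDD"
    UHP_B = "EEEEEEEEEE"
    ISO_A = "MAAAAAK" + UHP_A + "KGGGGGGR"
    ISO_B = "MAAAAAK" + UHP_B + "KGGGGGGR"

    def proteome(self, extra=None):
        base = {"g1": [self.ISO_A, self.ISO_B]}
        base.update(extra or {})
        return base

    def test_uhp_overlapping_peptides_assigned(self):
        out = discriminating_peptides(
            [self.ISO_A], [self.ISO_B], self.UHP_A, self.UHP_B, "g1",
            self.proteome(),
        )
        assert self.UHP_A + "K" in out["A"]
        assert self.UHP_B + "K" in out["B"]
        for pep in out["A"]:
            assert any(c == "D" for c in pep)

    def test_junction_spanning_peptides_count(self):
        out = discriminating_peptides(
            [self.ISO_A], [self.ISO_B], self.UHP_A, self.UHP_B, "g1",
            self.proteome(), max_missed=1,
        )
        assert "MAAAAAK" + self.UHP_A + "K" in out["A"]

    def test_flanking_peptides_shared_not_counted(self):
        out = discriminating_peptides(
            [self.ISO_A], [self.ISO_B], self.UHP_A, self.UHP_B, "g1",
            self.proteome(),
        )
        # MAAAAAK does not overlap the UHP; never a candidate
        assert "MAAAAAK" not in out["A"] | out["B"] | out["shared"]

    def test_peptide_in_other_gene_excluded(self):
        extra = {"g2": ["MW" + self.UHP_A + "KW"]}
        out = discriminating_peptides(
            [self.ISO_A], [self.ISO_B], self.UHP_A, self.UHP_B, "g1",
            self.proteome(extra),
        )
        assert all(self.UHP_A not in p or p not in out["A"]
                   for p in [self.UHP_A + "K"])
        assert self.UHP_A + "K" not in out["A"]

    def test_peptide_on_both_sides_is_shared(self):
        iso_a = "MAAAAAK" + "DDDDDSSSSS" + "KGGGGGGR"
        iso_b = "MAAAAAK" + "EEEEESSSSS" + "KGGGGGGR"
        # peptide spanning the shared tail + flank appears in both isoforms?
        # Here the full UHP+K peptides differ, but a hypothetical common
        # peptide must be shared: simulate by using identical UHPs.
        out = discriminating_peptides(
            [iso_a], [iso_a], "DDDDDSSSSS", "DDDDDSSSSS", "g1",
            {"g1": [iso_a]},
        )
        assert out["A"] == set() and out["B"] == set()
        assert out["shared"]


class TestComputePec:
    def test_distinctness_per_peptide_experiment(self):
        records = evidence_frame([
            ("P1", 0.0001, "e1", "T1"),
            ("P1", 0.0001, "e1", "T1"),  # duplicate spectrum: counts once
            ("P1", 0.0001, "e2", "T1"),
            ("P2", 0.0001, "e1", "T1"),  # second peptide, same experiment
            ("P3", 0.0001, "e1", "T2"),
        ])
        assignment = {"P1": ("ev1", "A"), "P2": ("ev1", "A"), "P3": ("ev1", "B")}
        pec = compute_pec(records, assignment).set_index(
            ["event_id", "side", "tissue"]
        )["pec"]
        assert pec[("ev1", "A", "T1")] == 3
        assert pec[("ev1", "B", "T2")] == 1

    def test_unassigned_peptides_ignored(self):
        records = evidence_frame([("P9", 0.0001, "e1", "T1")])
        assert compute_pec(records, {}).empty


def pec_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "side", "tissue", "pec"])


class TestTissueSpecificity:
    def test_hand_built_specific_event(self):
        pec = pec_frame([
            ("ev1", "A", "T1", 9), ("ev1", "A", "T2", 1),
            ("ev1", "B", "T1", 1), ("ev1", "B", "T2", 9),
        ])
        results = tissue_specificity(pec)
        by = {r.tissue_or_group: r for r in results}
        assert by["T1"].specific_side == "A"
        assert by["T2"].specific_side == "B"
        assert by["T1"].table == ((9, 1), (1, 9))
        from scipy.stats import fisher_exact

        assert by["T1"].p == pytest.approx(
            fisher_exact([[9, 1], [1, 9]])[1], rel=1e-9
        )

    def test_min_pec_boundary(self):
        # side B total PEC = 2 < 3 -> non-evaluable
        pec = pec_frame([
            ("ev1", "A", "T1", 5), ("ev1", "B", "T1", 2),
        ])
        (res,) = tissue_specificity(pec)
        assert not res.evaluable
        assert np.isnan(res.p)
        # exactly 3 on both sides -> evaluable
        pec = pec_frame([
            ("ev1", "A", "T1", 3), ("ev1", "B", "T1", 3),
        ])
        assert all(r.evaluable for r in tissue_specificity(pec))

    def test_group_pooling(self):
        groups = {"T1": "g", "T2": "g", "T3": "h"}
        pec = pec_frame([
            ("ev1", "A", "T1", 3), ("ev1", "A", "T2", 3),
            ("ev1", "B", "T3", 6),
        ])
        results = tissue_specificity(pec, groups)
        by = {(r.tissue_or_group, r.is_group): r for r in results}
        assert by[("g", True)].table == ((6, 0), (0, 6))
        assert by[("g", True)].specific_side == "A"
        assert by[("h", True)].specific_side == "B"

    def test_unknown_tissue_in_group_map_errors(self):
        pec = pec_frame([("ev1", "A", "TX", 3), ("ev1", "B", "TX", 3)])
        with pytest.raises(KeyError):
            tissue_specificity(pec, {"T1": "g"})

    def test_balanced_pecs_not_specific(self):
        pec = pec_frame([
            ("ev1", "A", "T1", 5), ("ev1", "A", "T2", 5),
            ("ev1", "B", "T1", 5), ("ev1", "B", "T2", 5),
        ])
        assert all(r.specific_side == "none" for r in tissue_specificity(pec))

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        pec = pec_frame([
            ("ev1", "A", "T1", 9), ("ev1", "A", "T2", 1),
            ("ev1", "B", "T1", 1), ("ev1", "B", "T2", 9),
            ("ev2", "A", "T1", 4), ("ev2", "B", "T1", 4),
        ])
        results = [r for r in tissue_specificity(pec) if r.evaluable]
        raw = [r.p for r in results]
        expect = multipletests(raw, method="fdr_bh")[1]
        assert [r.adjusted_p for r in results] == pytest.approx(list(expect))

    def test_empty_table(self):
        assert tissue_specificity(pec_frame([])) == []
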