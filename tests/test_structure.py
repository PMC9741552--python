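import numpy as np
import pytest

from uhpscan.simulate import (
    EXTENDED_PHI_PSI,
    HELIX_PHI_PSI,
    SimulationConfig,
    build_helix_coords,
    simulate_structures,
    write_pdb,
)
from uhpscan.structure import (
    MAX_ASA,
    Residue,
    ResidueAnnotation,
    assign_ss3_from_coords,
    call_disorder,
    collapse_ss8,
    compute_sasa,
    exposure_contingency,
    read_chunked_model,
    read_model,
    resolve_uhp_in_model,
    rsa_from_asa,
)


def toy_pdb(tmp_path, name, sequence, plddt, phi_psi=None):
    coords = build_helix_coords(phi_psi or [HELIX_PHI_PSI] * len(sequence))
    path = tmp_path / f"{name}.pdb"
    write_pdb(path, sequence, coords, plddt)
    return path


MMCIF_TEMPLATE = """data_model
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
{rows}
"""


def toy_mmcif(tmp_path, name, sequence, plddt):
    from uhpscan.simulate import build_helix_coords

    three = {"A": "ALA", "G": "GLY", "S": "SER"}
    coords = build_helix_coords([HELIX_PHI_PSI] * len(sequence))
    rows = []
    serial = 1
    for i, aa in enumerate(sequence, start=1):
        for atom in ("N", "CA", "C", "O"):
            x, y, z = coords[i - 1][atom]
            rows.append(
                f"ATOM {serial} {atom[0]} {atom} . {three[aa]} A 1 {i} ? "
                f"{x:.3f} {y:.3f} {z:.3f} 1.00 {plddt[i-1]:.2f} {i} "
                f"{three[aa]} A {atom} 1"
            )
            serial += 1
    path = tmp_path / f"{name}.cif"
    path.write_text(MMCIF_TEMPLATE.format(rows="\n".join(rows)))
    return path


class TestReadModel:
    def test_plddt_from_ca_bfactor(self, tmp_path):
        path = toy_pdb(tmp_path, "toy", "AGS", [90.0, 45.0, 30.0])
        residues = read_model(path)
        assert [r.plddt for r in residues] == [90.0, 45.0, 30.0]
        assert [r.aa for r in residues] == ["A", "G", "S"]

    def test_mmcif_and_pdb_agree(self, tmp_path):
        plddt = [90.0, 45.0, 30.0]
        p1 = toy_pdb(tmp_path, "m", "AGS", plddt)
        p2 = toy_mmcif(tmp_path, "m", "AGS", plddt)
        r_pdb, r_cif = read_model(p1), read_model(p2)
        assert [r.plddt for r in r_pdb] == [r.plddt for r in r_cif]
        assert [r.aa for r in r_pdb] == [r.aa for r in r_cif]
        for a, b in zip(r_pdb, r_cif):
            np.testing.assert_allclose(a.coords["CA"], b.coords["CA"], atol=1e-3)

    def test_chunk_merge_earlier_file_wins(self, tmp_path):
        # chunk 1 covers 1-6, chunk 2 covers 5-10; overlap 5-6 from chunk 1
        p1 = toy_pdb(tmp_path, "c1", "AAAAAA", [80.0] * 6)
        p2 = toy_pdb(tmp_path, "c2", "SSSSSS", [40.0] * 6)
        merged = read_chunked_model([(p1, 1), (p2, 5)])
        assert [r.position for r in merged] == list(range(1, 11))
        assert [r.aa for r in merged[:6]] == ["A"] * 6
        assert [r.aa for r in merged[6:]] == ["S"] * 4
        assert merged[4].plddt == 80.0  # overlap resolved by first file


class TestCallDisorder:
    @pytest.mark.parametrize(
        "plddt, expected",
        [
            ([60, 40, 40, 40, 70], [False, True, True, True, False]),
            ([60, 40, 40, 70], [False] * 4),  # run of 2 is not disorder
            ([50, 50, 50], [True] * 3),  # boundary 50 inclusive
            ([51, 51, 51], [False] * 3),
            ([], []),
        ],
    )
    def test_run_rule(self, plddt, expected):
        assert call_disorder(plddt).tolist() == expected

    def test_idempotent_and_reversal_invariant(self, rng):
        plddt = rng.uniform(0, 100, size=200)
        mask = call_disorder(plddt)
        assert call_disorder(plddt).tolist() == mask.tolist()
        assert call_disorder(plddt[::-1]).tolist() == mask[::-1].tolist()


class TestSasa:
    def test_isolated_glycine_fully_exposed(self):
        res = Residue(1, "G", 90.0, {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([1.458, 0.0, 0.0]),
            "C": np.array([2.0, 1.4, 0.0]),
            "O": np.array([3.2, 1.5, 0.0]),
        })
        asa = compute_sasa([res])
        rsa = rsa_from_asa(asa[0], "G")
        assert rsa == pytest.approx(1.0, abs=0.1)

    def test_center_of_close_packed_cluster_buried(self, rng):
        center = Residue(1, "G", 90.0, {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([1.458, 0.0, 0.0]),
            "C": np.array([2.0, 1.4, 0.0]),
            "O": np.array([3.2, 1.5, 0.0]),
        })
        shell = []
        idx = 2
        # dense cage of carbon atoms on two spherical shells
        for radius in (4.0, 6.5):
            n = 200
            k = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * k / n)
            theta = np.pi * (1 + 5**0.5) * k
            pts = radius * np.stack(
                [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
                axis=1,
            ) + np.array([1.6, 0.7, 0.0])
            coords = {f"C{j}": p for j, p in enumerate(pts)}
            shell.append(Residue(idx, "G", 90.0, coords))
            idx += 1
        asa = compute_sasa([center] + shell)
        assert rsa_from_asa(asa[0], "G") < 0.05

    def test_removing_neighbors_never_decreases_asa(self):
        seq_len = 12
        coords = build_helix_coords([HELIX_PHI_PSI] * seq_len)
        residues = [Residue(i + 1, "A", 90.0, c) for i, c in enumerate(coords)]
        full = compute_sasa(residues)
        trimmed = compute_sasa(residues[:6])
        assert all(trimmed[i] >= full[i] - 1e-9 for i in range(6))

    def test_point_density_convergence_on_toy_helix(self):
        coords = build_helix_coords([HELIX_PHI_PSI] * 8)
        residues = [Residue(i + 1, "A", 90.0, c) for i, c in enumerate(coords)]
        lo = compute_sasa(residues, n_points=960)
        hi = compute_sasa(residues, n_points=10000)
        rel = np.abs(lo - hi) / np.maximum(hi, 1e-9)
        assert rel.max() < 0.02

    def test_unknown_element_warns_and_defaults(self):
        res = Residue(1, "G", 90.0, {"Q1": np.zeros(3)})
        with pytest.warns(UserWarning):
            compute_sasa([res])

    def test_rsa_clipped_to_unit_interval(self):
        assert rsa_from_asa(1e5, "A") == 1.0
        assert rsa_from_asa(0.0, "A") == 0.0


class TestSecondaryStructure:
    def test_eight_state_collapse(self):
        assert collapse_ss8("HHHEECTT") == (
            ["helix"] * 3 + ["strand"] * 2 + ["coil"] * 3
        )

    def test_three_ten_helix_counts_as_helix(self):
        assert collapse_ss8("GGG") == ["helix"] * 3

    def test_ideal_helix_coordinates_classified_helix(self):
        coords = build_helix_coords([HELIX_PHI_PSI] * 10)
        residues = [Residue(i + 1, "A", 90.0, c) for i, c in enumerate(coords)]
        ss3 = assign_ss3_from_coords(residues)
        assert all(s == "helix" for s in ss3[1:-1])

    def test_extended_coordinates_classified_strand(self):
        coords = build_helix_coords([EXTENDED_PHI_PSI] * 8)
        residues = [Residue(i + 1, "A", 90.0, c) for i, c in enumerate(coords)]
        assert all(s == "strand" for s in assign_ss3_from_coords(residues)[1:-1])


class TestResolveUhp:
    def test_only_side_a_present(self):
        m = resolve_uhp_in_model("DEFG", "QRST", "ABCDEFGHIK")
        assert (m.side, m.start, m.end) == ("A", 4, 7)

    def test_both_present_keeps_ordered_side(self):
        display = "MAAADEFGAAAQRSTV"
        plddt = np.full(len(display), 90.0)
        plddt[11:16] = 30.0  # QRSTV region disordered
        m = resolve_uhp_in_model("DEFG", "QRST", display, plddt)
        assert m.side == "A"
        m2 = resolve_uhp_in_model("QRST", "DEFG", display, plddt)
        assert m2.side == "B"

    def test_neither_present_excluded_with_reason(self):
        m = resolve_uhp_in_model("WWWWW", "YYYYY", "MAAAAAAAAK")
        assert m.side is None
        assert m.reason == "uhp_not_in_display"

    def test_fuzzy_match_tolerates_two_mismatches(self):
        m = resolve_uhp_in_model("DEFGHIKL", "WWWWWWWW", "AADEFGAIKLAA")
        assert (m.side, m.start) == ("A", 3)


class TestExposureContingency:
    @staticmethod
    def annotations_from_counts(e_in, b_in, e_out, b_out):
        out = []
        spec = [
            (e_in, True, "A"), (b_in, False, "A"),
            (e_out, True, "none"), (b_out, False, "none"),
        ]
        pos = 1
        for n, exposed, side in spec:
            for _ in range(n):
                out.append(
                    ResidueAnnotation(
                        "p", pos, "A", 90.0, False, 50.0,
                        0.5 if exposed else 0.05, exposed, "helix", side,
                    )
                )
                pos += 1
        return out

    def test_equal_exposure_is_null(self):
        ann = self.annotations_from_counts(50, 50, 50, 50)
        res = exposure_contingency(ann)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_chi2_on_unbalanced_table(self):
        ann = self.annotations_from_counts(700, 300, 640, 360)
        res = exposure_contingency(ann)
        t = np.array([[700, 640], [300, 360]], dtype=float)
        row, col = t.sum(1, keepdims=True), t.sum(0, keepdims=True)
        e = row * col / t.sum()
        assert res.chi2 == pytest.approx((((t - e) ** 2) / e).sum(), rel=1e-12)

    def test_disordered_residues_removed_first(self):
        ann = self.annotations_from_counts(10, 10, 10, 10)
        for a in ann[:5]:
            a.disordered = True
        res = exposure_contingency(ann)
        assert res.table.sum() == 35

    def test_planted_uhp_exposure_excess_detected(self):
        ann = self.annotations_from_counts(900, 100, 600, 400)
        res = exposure_contingency(ann)
        assert res.p < 1e-5
        assert res.table[0, 0] == 900


class TestSimulatedDisorderRecovery:
    def test_planted_tails_recovered_within_one_residue(self, tmp_path):
        cfg = SimulationConfig(seed=3)
        proteins = {f"p{i}": "A" * 60 for i in range(8)}
        paths, truth = simulate_structures(cfg, proteins, tmp_path)
        for pid, path in paths.items():
            residues = read_model(path)
            called = call_disorder([r.plddt for r in residues])
            planted = truth[pid]
            assert abs(int(called.sum()) - int(planted.sum())) <= 1

    def test_zero_tail_means_no_disorder(self, tmp_path):
        cfg = SimulationConfig(seed=4, tail_len_range=(0, 0))
        paths, truth = simulate_structures(cfg, {"p0": "A" * 40}, tmp_path)
        residues = read_model(paths["p0"])
        assert not call_disorder([r.plddt for r in residues]).any()
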