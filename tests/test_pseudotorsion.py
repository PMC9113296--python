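"""End-to-end pseudo-torsion pipeline checks against raw-coordinate oracles."""

import math

import gemmi
import numpy as np
import pytest

from naworm.fixtures import AFORM, delete_residue, make_helix, coarse_grain
from naworm.geometry import TorsionAngle
from naworm.pseudotorsion import (
    DEFAULT_HELICAL_WINDOW,
    HELICAL,
    NON_HELICAL,
    UNKNOWN_HELICITY,
    HelicalWindow,
    classify_helical,
    compute_pseudotorsions,
)
from naworm.structure_io import read_structure

from oracles import oracle_dihedral


def _write_pdb(st, path):
    st.write_pdb(str(path))
    return path


def _atom(chain, i, name):
    return chain.nucleotides[i].atom_pos(name)


class TestAngleDefinitions:
    def test_pipeline_matches_raw_coordinate_oracle(self, aform_chain, aform_records):
        """eta(i)/theta(i) (and primed) from the pipeline equal the torsions
        recomputed directly from the parsed file coordinates."""
        ch = aform_chain
        for i in range(1, len(ch) - 1):
            rec = aform_records[i]
            eta = oracle_dihedral(
                _atom(ch, i - 1, "C4'"),
                _atom(ch, i, "P"),
                _atom(ch, i, "C4'"),
                _atom(ch, i + 1, "P"),
            )
            theta = oracle_dihedral(
                _atom(ch, i, "P"),
                _atom(ch, i, "C4'"),
                _atom(ch, i + 1, "P"),
                _atom(ch, i + 1, "C4'"),
            )
            eta_p = oracle_dihedral(
                _atom(ch, i - 1, "C1'"),
                _atom(ch, i, "P"),
                _atom(ch, i, "C1'"),
                _atom(ch, i + 1, "P"),
            )
            theta_p = oracle_dihedral(
                _atom(ch, i, "P"),
                _atom(ch, i, "C1'"),
                _atom(ch, i + 1, "P"),
                _atom(ch, i + 1, "C1'"),
            )
            assert rec.eta.value == pytest.approx(eta, abs=1e-6)
            assert rec.theta.value == pytest.approx(theta, abs=1e-6)
            assert rec.eta_prime.value == pytest.approx(eta_p, abs=1e-6)
            assert rec.theta_prime.value == pytest.approx(theta_p, abs=1e-6)

    def test_interior_angles_helically_uniform(self, aform_records):
        # one repeated rigid step => interior dihedrals agree within 2 deg
        etas = [r.eta.value for r in aform_records[1:-1]]
        thetas = [r.theta.value for r in aform_records[1:-1]]
        assert max(etas) - min(etas) < 2.0
        assert max(thetas) - min(thetas) < 2.0

    def test_record_count_equals_nucleotide_count(self, aform_chain, bform_chains):
        for chain in [aform_chain, *bform_chains]:
            assert len(compute_pseudotorsions(chain)) == len(chain)

    def test_terminal_semantics(self, aform_records):
        first, last = aform_records[0], aform_records[-1]
        assert not first.eta.defined and first.theta.defined
        assert not first.eta_prime.defined and first.theta_prime.defined
        # the last residue lacks P(i+1), so eta(N) is undefined as well
        assert not last.eta.defined and not last.theta.defined
        assert not last.theta_prime.defined
        # second-to-last residue still has everything
        assert aform_records[-2].eta.defined and aform_records[-2].theta.defined
        for rec in aform_records[1:-1]:
            assert rec.eta.defined and rec.theta.defined
            assert rec.eta_prime.defined and rec.theta_prime.defined

    def test_two_nucleotide_chain_all_quadruple_angles_undefined(self, tmp_path):
        _write_pdb(make_helix(AFORM, 2), tmp_path / "dimer.pdb")
        (chain,) = read_structure(tmp_path / "dimer.pdb")
        for rec in compute_pseudotorsions(chain, mode="both"):
            assert not rec.eta.defined
            # theta(1) needs only residues 1 and 2 and is still defined;
            # theta(2) is not
        recs = compute_pseudotorsions(chain, mode="both")
        assert recs[0].theta.defined and not recs[1].theta.defined

    def test_deleted_residue_undefines_exactly_the_spanning_angles(self, tmp_path):
        st = delete_residue(make_helix(AFORM, 12), 6)
        _write_pdb(st, tmp_path / "gap.pdb")
        (chain,) = read_structure(tmp_path / "gap.pdb")
        recs = {r.seq_id: r for r in compute_pseudotorsions(chain, mode="c4")}
        assert sorted(recs) == [1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 12]
        # residue 5: eta and theta both span the 5->7 gap
        assert not recs[5].eta.defined and not recs[5].theta.defined
        # residue 7: eta spans the gap, theta (7->8) does not
        assert not recs[7].eta.defined and recs[7].theta.defined
        # untouched interior neighbours keep everything
        assert recs[4].eta.defined and recs[4].theta.defined
        assert recs[8].eta.defined and recs[8].theta.defined
        # eta(4) needs P(5): still defined because 3-4-5 are contiguous
        assert recs[3].theta.defined

    def test_single_mode_runs_agree_with_both(self, aform_chain):
        both = compute_pseudotorsions(aform_chain, mode="both")
        c4 = compute_pseudotorsions(aform_chain, mode="c4")
        c1 = compute_pseudotorsions(aform_chain, mode="c1")
        for rb, r4, r1 in zip(both, c4, c1):
            assert rb.eta == r4.eta and rb.theta == r4.theta
            assert rb.eta_prime == r1.eta_prime
            assert rb.theta_prime == r1.theta_prime

    def test_rigid_transformation_leaves_angles_unchanged(self, tmp_path, aform_records):
        st = make_helix(AFORM, 12)
        # arbitrary rotation + translation applied to every atom
        angle = math.radians(37.0)
        rot = np.array(
            [
                [math.cos(angle), 0, math.sin(angle)],
                [0, 1, 0],
                [-math.sin(angle), 0, math.cos(angle)],
            ]
        )
        shift = np.array([11.0, -7.0, 3.0])
        for res in st[0]["A"]:
            for atom in res:
                p = rot @ np.array([atom.pos.x, atom.pos.y, atom.pos.z]) + shift
                atom.pos = gemmi.Position(*p)
        _write_pdb(st, tmp_path / "moved.pdb")
        (chain,) = read_structure(tmp_path / "moved.pdb")
        moved = compute_pseudotorsions(chain, mode="both")
        for a, b in zip(aform_records, moved):
            for attr in ("eta", "theta", "eta_prime", "theta_prime"):
                ta, tb = getattr(a, attr), getattr(b, attr)
                assert ta.defined == tb.defined
                if ta.defined:
                    # writing transformed coords re-rounds to 3 decimals, so
                    # allow slightly more than the 1e-6 rigid-math drift
                    assert ta.value == pytest.approx(tb.value, abs=0.2)

    def test_rigid_transform_in_memory_exact(self):
        # Without coordinate re-rounding the drift is at machine precision.
        from naworm.geometry import dihedral

        rng = np.random.default_rng(11)
        quad = rng.normal(size=(4, 3)) * 8
        angle = math.radians(123.0)
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(angle), -math.sin(angle)],
                [0, math.sin(angle), math.cos(angle)],
            ]
        )
        moved = [rot @ p + np.array([3.0, 4.0, 5.0]) for p in quad]
        assert dihedral(*quad).value == pytest.approx(
            dihedral(*moved).value, abs=1e-9
        )


class TestPucker:
    def test_aform_all_c3_endo(self, aform_records):
        assert all(r.pucker == "C3'-endo" for r in aform_records)

    def test_bform_all_c2_endo(self, bform_chains):
        for chain in bform_chains:
            recs = compute_pseudotorsions(chain, mode="c4")
            assert all(r.pucker == "C2'-endo" for r in recs)

    def test_coarse_grained_unknown_pucker_but_angles_defined(self, tmp_path):
        st = coarse_grain(make_helix(AFORM, 8), keep=("P", "C4'"))
        _write_pdb(st, tmp_path / "cg.pdb")
        (chain,) = read_structure(tmp_path / "cg.pdb")
        recs = compute_pseudotorsions(chain, mode="c4")
        assert all(r.pucker == "unknown" for r in recs)
        assert all(r.eta.defined and r.theta.defined for r in recs[1:-1])


class TestClassifyHelical:
    def test_fixture_interior_is_helical_under_default_window(self, aform_records):
        for rec in aform_records[1:-1]:
            assert rec.helical == HELICAL

    def test_undefined_angle_gives_unknown(self):
        assert (
            classify_helical(TorsionAngle(None), TorsionAngle(100.0))
            == UNKNOWN_HELICITY
        )

    def test_far_displacement_is_non_helical(self, aform_records):
        rec = aform_records[5]
        shifted = TorsionAngle((rec.eta.value + 120.0) % 360.0)
        assert classify_helical(shifted, rec.theta) == NON_HELICAL

    def test_window_containment_wraps_through_zero(self):
        window = HelicalWindow(
            eta_center=5.0, theta_center=355.0, eta_halfwidth=20.0, theta_halfwidth=20.0
        )
        assert classify_helical(TorsionAngle(350.0), TorsionAngle(10.0), window) == HELICAL
        assert (
            classify_helical(TorsionAngle(40.0), TorsionAngle(10.0), window)
            == NON_HELICAL
        )

    def test_default_window_centered_on_fixture_cluster(self, aform_records):
        etas = [r.eta.value for r in aform_records[1:-1]]
        thetas = [r.theta.value for r in aform_records[1:-1]]
        assert DEFAULT_HELICAL_WINDOW.eta_center == pytest.approx(
            sum(etas) / len(etas), abs=0.5
        )
        assert DEFAULT_HELICAL_WINDOW.theta_center == pytest.approx(
            sum(thetas) / len(thetas), abs=0.5
        )
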