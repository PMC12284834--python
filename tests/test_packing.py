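"""Knobs-into-holes and salt-bridge detection."""

import numpy as np
import pytest

from coilspect.crick_synth import CrickParams, build_bundle
from coilspect.geometry import CoiledCoilFit, fit_coiled_coil
from coilspect.packing import (
    detect_kih,
    detect_salt_bridges,
    layer_summary,
    side_chain_center,
)

from conftest import make_model, make_residue


def minimal_fit_with_registers(registers: dict[str, str],
                               seq_ids: dict[str, list[int]]) -> CoiledCoilFit:
    """A hand-built fit object carrying only register information."""
    return CoiledCoilFit(
        axis_origin=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]),
        r0_fit=5.0, pitch_fit=150.0, handedness="left",
        orientation={}, arrangement=[], stagger={}, extent=0.0,
        crick_phase={}, register=registers, n_heptads={},
        seq_ids=seq_ids,
    )


class TestKih:
    def test_silk_bundle_knobs_avoid_surface_positions(self, silk_bundle,
                                                       silk_fit):
        model, _ = silk_bundle
        contacts = detect_kih(model, silk_fit)
        assert contacts
        registers = {c.knob_register for c in contacts}
        assert registers.isdisjoint(set("bcf"))
        core = sum(c.knob_register in "ad" for c in contacts)
        assert core / len(contacts) > 0.5

    def test_hole_residues_on_single_other_chain(self, silk_bundle, silk_fit):
        model, _ = silk_bundle
        for c in detect_kih(model, silk_fit):
            hole_chains = {h[0] for h in c.hole}
            assert len(hole_chains) == 1
            assert c.knob[0] not in hole_chains
            assert len(c.hole) == 4

    def test_distant_helices_give_no_contacts(self):
        params = CrickParams(
            n_chains=2, orientations=("U", "U"), r0=15.0, pitch=500.0,
            n_res=40,
        )
        model, _ = build_bundle(params)
        fit = fit_coiled_coil(model)
        assert detect_kih(model, fit) == []

    def test_symmetric_dimer_knobs_are_reciprocal(self):
        params = CrickParams(
            n_chains=2, orientations=("U", "U"), r0=4.8, pitch=140.0,
            n_res=56,
        )
        model, _ = build_bundle(params, sequence="A")
        fit = fit_coiled_coil(model)
        contacts = detect_kih(model, fit)
        knobs_a = {c.knob[1] for c in contacts if c.knob[0] == "A"}
        knobs_b = {c.knob[1] for c in contacts if c.knob[0] == "B"}
        assert knobs_a and knobs_a == knobs_b

    def test_no_side_chain_information_raises(self):
        model = make_model(
            {"A": [make_residue(i, "GLY", CA=(0, 0, float(i)))
                   for i in range(1, 9)]}
        )
        with pytest.raises(ValueError, match="side-chain"):
            detect_kih(model)

    def test_side_chain_center_prefers_heavy_sidechain_atoms(self):
        res = make_residue(1, "LYS", CA=(0, 0, 0), CB=(1, 0, 0), NZ=(3, 0, 0))
        np.testing.assert_allclose(side_chain_center(res), [2.0, 0.0, 0.0])
        assert side_chain_center(make_residue(2, "GLY", CA=(0, 0, 0))) is None


class TestLayers:
    def test_silk_core_layers_alternate(self, silk_bundle, silk_fit):
        model, _ = silk_bundle
        report = layer_summary(detect_kih(model, silk_fit))
        assert len(report.layers) > 10
        assert report.alternating
        assert {reg for reg, _, _ in report.layers} == {"a", "d"}

    def test_single_contact_is_trivially_alternating(self, silk_bundle,
                                                     silk_fit):
        model, _ = silk_bundle
        contacts = detect_kih(model, silk_fit)[:1]
        report = layer_summary(contacts)
        assert len(report.layers) == 1
        assert report.alternating

    def test_order_invariance(self, silk_bundle, silk_fit):
        model, _ = silk_bundle
        contacts = detect_kih(model, silk_fit)
        shuffled = list(reversed(contacts))
        assert layer_summary(contacts) == layer_summary(shuffled)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            layer_summary([])


class TestSaltBridges:
    def toy_model(self, nz=(0.0, 0.0, 0.0), oe1=(3.5, 0.0, 0.0)):
        return make_model(
            {
                "A": [make_residue(10, "LYS", CA=(0, 0, -5), NZ=nz)],
                "B": [make_residue(20, "GLU", CA=(3.5, 0, -5), OE1=oe1)],
            }
        )

    def test_engineered_pair_detected_with_register_class(self):
        fit = minimal_fit_with_registers(
            registers={"A": "c", "B": "c"}, seq_ids={"A": [10], "B": [20]}
        )
        bridges = detect_salt_bridges(self.toy_model(), fit)
        assert len(bridges) == 1
        b = bridges[0]
        assert b.basic == ("A", 10, "LYS")
        assert b.acidic == ("B", 20, "GLU")
        assert abs(b.min_distance - 3.5) < 1e-9
        assert b.position_class == "c-c"
        assert b.is_intermolecular

    def test_engineered_classes_match_silk_pattern(self):
        # c-c, g-c and b-b pairings at non-core positions, as seen between
        # adjacent chains of an antiparallel tetramer.
        model = make_model(
            {
                "A": [
                    make_residue(1, "LYS", CA=(0, 0, 0), NZ=(0, 0, 1)),
                    make_residue(2, "ARG", CA=(0, 0, 5), NH1=(0, 0, 6)),
                    make_residue(3, "LYS", CA=(0, 0, 10), NZ=(0, 0, 11)),
                ],
                "B": [
                    make_residue(1, "GLU", CA=(0, 0, 2), OE1=(0, 0, 1.5)),
                    make_residue(2, "ASP", CA=(0, 0, 5), OD1=(0, 0, 6.5)),
                    make_residue(3, "GLU", CA=(0, 0, 10), OE1=(0, 0, 11.5)),
                ],
            }
        )
        fit = minimal_fit_with_registers(
            registers={"A": "cgb", "B": "ccb"},
            seq_ids={"A": [1, 2, 3], "B": [1, 2, 3]},
        )
        classes = {b.position_class for b in detect_salt_bridges(model, fit)}
        assert classes == {"c-c", "g-c", "b-b"}

    def test_poly_alanine_has_no_bridges(self):
        params = CrickParams(n_chains=2, orientations=("U", "D"), r0=5.0,
                             pitch=150.0, n_res=35)
        model, _ = build_bundle(params, sequence="A")
        with pytest.warns(UserWarning, match="fit"):
            assert detect_salt_bridges(model) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        residues = {"A": [], "B": []}
        names = [("LYS", "NZ"), ("ARG", "NH1"), ("ASP", "OD1"), ("GLU", "OE1")]
        pts = {}
        for cid in residues:
            for i in range(1, 13):
                res_name, atom = names[rng.integers(len(names))]
                pos = rng.uniform(-6, 6, 3)
                residues[cid].append(
                    make_residue(i, res_name, CA=pos + 0.5, **{atom: pos})
                )
                pts[(cid, i)] = (res_name, pos)
        model = make_model(residues)
        with pytest.warns(UserWarning):
            found = {
                (b.basic[:2], b.acidic[:2])
                for b in detect_salt_bridges(model, cutoff=4.0)
            }
        basic_names = {"LYS", "ARG"}
        expected = set()
        for (ca, sa), (na, pa) in pts.items():
            for (cb, sb), (nb, pb) in pts.items():
                if na in basic_names and nb not in basic_names:
                    if np.linalg.norm(pa - pb) <= 4.0:
                        expected.add(((ca, sa), (cb, sb)))
        assert found == expected

    def test_histidine_not_basic(self):
        model = make_model(
            {
                "A": [make_residue(1, "HIS", CA=(0, 0, 0), ND1=(0, 0, 1))],
                "B": [make_residue(1, "GLU", CA=(0, 0, 2), OE1=(0, 0, 1.5))],
            }
        )
        with pytest.warns(UserWarning):
            assert detect_salt_bridges(model) == []

    def test_scope_filters_intra_and_inter(self):
        model = make_model(
            {
                "A": [
                    make_residue(1, "LYS", CA=(0, 0, 0), NZ=(0, 0, 1)),
                    make_residue(2, "GLU", CA=(0, 0, 2), OE1=(0, 0, 1.5)),
                ],
                "B": [make_residue(1, "ASP", CA=(0, 0, 0), OD1=(0, 0, 0.5))],
            }
        )
        with pytest.warns(UserWarning):
            inter = detect_salt_bridges(model, scope="inter")
            intra = detect_salt_bridges(model, scope="intra")
            both = detect_salt_bridges(model, scope="both")
        assert len(inter) == 1 and inter[0].is_intermolecular
        assert len(intra) == 1 and not intra[0].is_intermolecular
        assert len(both) == 2
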