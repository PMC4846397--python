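"""Bead-model construction and the crosslink observation model."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from httxl.simulate import (
    SimulationParams,
    build_solenoid_bead_model,
    perturb_allele,
    simulate_crosslinks,
)

CUTOFF = SimulationParams().crosslink_cutoff


def domain_pair_count(model, name_a, name_b, cutoff=CUTOFF):
    labels = model.domain_labels
    lys = model.lysine_positions
    a = lys[labels[lys - 1] == name_a]
    b = lys[labels[lys - 1] == name_b]
    return int((cdist(model.coordinates[a - 1], model.coordinates[b - 1]) <= cutoff).sum())


class TestBeadModel:
    def test_same_seed_reproduces_coordinates_and_mask(self, base_model):
        again = build_solenoid_bead_model(seed=1)
        assert np.array_equal(again.coordinates, base_model.coordinates)
        assert np.array_equal(again.lysine_mask, base_model.lysine_mask)

    def test_different_seeds_differ(self, base_model):
        other = build_solenoid_bead_model(seed=2)
        assert not np.array_equal(other.lysine_mask, base_model.lysine_mask)

    def test_consecutive_bead_spacing_within_virtual_calpha_band(self, base_model):
        d = np.linalg.norm(np.diff(base_model.coordinates, axis=0), axis=1)
        assert d.min() >= 2.5 and d.max() <= 4.5

    def test_all_beads_inside_outer_sphere_and_outside_void(self, base_model):
        r = np.linalg.norm(base_model.coordinates, axis=1)
        assert r.max() <= base_model.params.outer_diameter / 2
        assert r.min() >= base_model.params.inner_void_radius

    def test_arm_ends_in_proximity(self, base_model):
        end_to_end = np.linalg.norm(
            base_model.coordinates[0] - base_model.coordinates[-1]
        )
        assert end_to_end <= 25.0

    def test_arms_meet_at_the_hinge(self, base_model):
        h = base_model.hinge_residue
        gap = np.linalg.norm(
            base_model.coordinates[h - 1] - base_model.coordinates[h]
        )
        assert gap <= 15.0

    def test_amino_terminus_at_particle_surface(self, base_model):
        r0 = np.linalg.norm(base_model.coordinates[0])
        assert r0 >= 0.85 * base_model.params.outer_diameter / 2

    def test_ucd_lysines_depleted_of_close_partners(self, base_model):
        lys = base_model.lysine_positions
        dists = squareform(pdist(base_model.coordinates[lys - 1]))
        np.fill_diagonal(dists, np.inf)
        partners = (dists <= CUTOFF).sum(axis=1)
        in_ucd = (lys >= 1800) & (lys <= 2300)
        assert in_ucd.sum() >= 3
        assert partners[in_ucd].mean() <= 0.10 * partners[~in_ucd].mean()

    def test_explicit_sequence_controls_lysine_mask(self):
        seq = "".join("K" if i % 40 == 0 else "A" for i in range(3144))
        model = build_solenoid_bead_model(seed=0, lysine_sequence=seq)
        assert model.lysine_mask.sum() == seq.count("K")

    def test_pdb_export_round_trips_through_biotite(self, base_model, tmp_path):
        import biotite.structure.io.pdb as pdb

        path = tmp_path / "model.pdb"
        base_model.to_pdb(path)
        atoms = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert len(atoms) == base_model.chain_length
        assert np.allclose(atoms.coord, base_model.coordinates, atol=1e-2)


class TestPerturbAllele:
    def test_shortest_tract_is_the_reference_fold(self, base_model):
        q2 = perturb_allele(base_model, 2)
        assert np.allclose(q2.coordinates, base_model.coordinates)

    def test_zero_displacement_scales_change_nothing(self, base_model):
        params = SimulationParams(
            ctd2_rotation_deg=0, ctd2_shift_A=0, ntd1_rotation_deg=0, ntd1_shift_A=0
        )
        model = build_solenoid_bead_model(seed=1, params=params)
        assert np.allclose(
            perturb_allele(model, 78).coordinates, model.coordinates
        )

    def test_expanded_tract_gains_ctd2_ctd1_proximity(self, base_model):
        q23 = perturb_allele(base_model, 23)
        q78 = perturb_allele(base_model, 78)
        assert domain_pair_count(q78, "CTD-II", "CTD-I") > domain_pair_count(
            q23, "CTD-II", "CTD-I"
        )

    def test_perturbed_chain_keeps_bond_geometry(self, base_model):
        for q in (23, 46, 78):
            d = np.linalg.norm(
                np.diff(perturb_allele(base_model, q).coordinates, axis=0), axis=1
            )
            assert d.min() >= 2.5 and d.max() <= 4.5

    def test_lysine_mask_is_allele_invariant(self, base_model):
        q78 = perturb_allele(base_model, 78)
        assert np.array_equal(q78.lysine_mask, base_model.lysine_mask)

    def test_tract_below_two_rejected(self, base_model):
        with pytest.raises(ValueError):
            perturb_allele(base_model, 1)


class TestSimulateCrosslinks:
    def test_every_true_link_satisfies_the_distance_cutoff(self, base_model, simulated):
        coords = base_model.coordinates
        for p in simulated.within_cutoff:
            assert np.linalg.norm(coords[p.i - 1] - coords[p.j - 1]) <= CUTOFF

    def test_every_decoy_violates_the_cutoff(self, base_model, simulated):
        coords = base_model.coordinates
        for p in simulated.decoys:
            assert np.linalg.norm(coords[p.i - 1] - coords[p.j - 1]) > CUTOFF

    def test_perfect_detection_recovers_exactly_the_cutoff_set(self, base_model):
        params = SimulationParams(p_detect=1.0, fp_rate=0.0)
        sim = simulate_crosslinks(base_model, params, seed=5)
        assert sim.true_contacts == sim.within_cutoff
        assert not sim.decoys

    def test_fixed_seed_reproduces_the_table(self, base_model):
        a = simulate_crosslinks(base_model, allele_label="Q23", seed=7)
        b = simulate_crosslinks(base_model, allele_label="Q23", seed=7)
        assert a.psms == b.psms

    def test_different_seeds_give_different_tables(self, base_model):
        a = simulate_crosslinks(base_model, allele_label="Q23", seed=7)
        b = simulate_crosslinks(base_model, allele_label="Q23", seed=8)
        assert a.psms != b.psms

    def test_detected_support_matches_psm_count(self, simulated):
        true_psms = sum(
            p.support for p in simulated.true_contacts
        )
        assert true_psms + len(simulated.decoys) == len(simulated.psms)

    def test_model_without_lysines_rejected(self, base_model):
        import dataclasses

        bare = dataclasses.replace(
            base_model, lysine_mask=np.zeros(base_model.chain_length, bool)
        )
        with pytest.raises(ValueError):
            simulate_crosslinks(bare)
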