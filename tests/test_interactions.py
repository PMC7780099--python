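"""Hydrogen-bond, salt-bridge and water-bridge detection; loop census."""

import numpy as np
import pytest

from dimerflex import (
    active_site_separation,
    detect_hbonds,
    detect_salt_bridges,
    detect_water_bridges,
    loop_interaction_summary,
)
from dimerflex.errors import ConfigError, ResidueLookupError
from dimerflex.structure_io import AtomRecord, ChainModel, ResidueRecord, StructureModel
from dimerflex.synthetic import PlantedInteraction, ToyDimerSpec, make_toy_dimer

from conftest import brute_force_hbond_pairs, brute_force_min_group_distance


def simple_pair_model(res1, atoms1, res2, atoms2, chain2="A", seq2=2):
    """Two residues with explicit atoms at explicit coordinates."""
    c1 = ChainModel(chain_id="A")
    r1 = ResidueRecord(name=res1, seq_num=1)
    for name, xyz in atoms1:
        r1.atoms.append(AtomRecord(name=name, element=name[0],
                                   coords=np.asarray(xyz, float),
                                   is_mainchain=name in ("N", "CA", "C", "O")))
    c1.residues.append(r1)
    r2 = ResidueRecord(name=res2, seq_num=seq2)
    for name, xyz in atoms2:
        r2.atoms.append(AtomRecord(name=name, element=name[0],
                                   coords=np.asarray(xyz, float),
                                   is_mainchain=name in ("N", "CA", "C", "O")))
    chains = [c1]
    if chain2 == "A":
        c1.residues.append(r2)
    else:
        cb = ChainModel(chain_id=chain2)
        cb.residues.append(r2)
        chains.append(cb)
    return StructureModel("pair", chains)


class TestHbondClasses:
    @pytest.mark.parametrize(
        "distance,expected_kind",
        [(2.8, "strong-hbond"), (4.0, "weak-hbond"), (5.5, None)],
    )
    def test_distance_classes(self, distance, expected_kind):
        model = simple_pair_model(
            "SER", [("OG", (0, 0, 0))], "ASN", [("OD1", (distance, 0, 0))]
        )
        found = detect_hbonds(model)
        if expected_kind is None:
            assert found == []
        else:
            assert len(found) == 1
            assert found[0].kind == expected_kind
            assert found[0].distance == pytest.approx(distance)

    def test_below_contact_floor_excluded(self):
        model = simple_pair_model(
            "SER", [("OG", (0, 0, 0))], "ASN", [("OD1", (2.0, 0, 0))]
        )
        assert detect_hbonds(model) == []

    def test_donor_donor_pair_not_a_bond(self):
        model = simple_pair_model(
            "LYS", [("NZ", (0, 0, 0))], "ARG", [("NH1", (2.8, 0, 0))]
        )
        assert detect_hbonds(model) == []

    def test_same_residue_excluded(self):
        chain = ChainModel(chain_id="A")
        res = ResidueRecord(name="SER", seq_num=1)
        res.atoms.append(AtomRecord(name="OG", element="O", coords=np.zeros(3)))
        res.atoms.append(AtomRecord(name="N", element="N",
                                    coords=np.array([2.8, 0, 0]), is_mainchain=True))
        chain.residues.append(res)
        assert detect_hbonds(StructureModel("x", [chain])) == []

    def test_threshold_validation(self):
        model = simple_pair_model(
            "SER", [("OG", (0, 0, 0))], "ASN", [("OD1", (2.8, 0, 0))]
        )
        with pytest.raises(ConfigError):
            detect_hbonds(model, d_strong=6.0, d_weak_max=5.0)
        with pytest.raises(ConfigError):
            detect_hbonds(model, d_min=3.5, d_strong=3.0)

    def test_helix_backbone_bond_count_closed_form(self, helix_dimer):
        """An n-residue ideal helix has n-4 i->i+4 backbone strong bonds."""
        model, truth = helix_dimer
        bonds = detect_hbonds(model)
        mc_strong_a = [
            b for b in bonds
            if b.kind == "strong-hbond"
            and b.backbone_class == "mainchain-mainchain"
            and b.partner1.chain == b.partner2.chain == "A"
        ]
        assert len(mc_strong_a) == truth.expected_helix_mainchain_hbonds == 16

    def test_strong_weak_partition_exact(self, planted_contacts_dimer):
        """No pair is in both classes, and raising d_strong only reclassifies."""
        model, _ = planted_contacts_dimer
        base = detect_hbonds(model, d_strong=3.0)
        wider = detect_hbonds(model, d_strong=4.5)
        assert {b.pair_key for b in base} == {b.pair_key for b in wider}
        strong_base = {b.pair_key for b in base if b.kind == "strong-hbond"}
        strong_wide = {b.pair_key for b in wider if b.kind == "strong-hbond"}
        assert strong_base <= strong_wide

    def test_order_independence(self, planted_contacts_dimer):
        """Permuting atom records leaves the canonical edge set unchanged."""
        import copy

        model, _ = planted_contacts_dimer
        shuffled = copy.deepcopy(model)
        rng = np.random.default_rng(9)
        for chain in shuffled.chains:
            rng.shuffle(chain.residues)
            for res in chain.residues:
                rng.shuffle(res.atoms)
        key = lambda bonds: {(b.pair_key, b.kind, round(b.distance, 6)) for b in bonds}
        assert key(detect_hbonds(model)) == key(detect_hbonds(shuffled))

    def test_equals_brute_force_scan(self, planted_contacts_dimer):
        """KD-tree detection equals an exhaustive all-pairs distance scan."""
        model, _ = planted_contacts_dimer
        assert model.n_atoms() <= 500
        oracle = brute_force_hbond_pairs(model)
        found = {
            frozenset([b.partner1.key(), b.partner2.key()]): (b.kind, b.distance)
            for b in detect_hbonds(model)
        }
        assert set(found) == set(oracle)
        for k, (kind, d) in found.items():
            assert oracle[k][0] == kind
            assert oracle[k][1] == pytest.approx(d, abs=1e-9)

    def test_equals_brute_force_on_helix(self, helix_dimer):
        model, _ = helix_dimer
        oracle = brute_force_hbond_pairs(model)
        found = {
            frozenset([b.partner1.key(), b.partner2.key()])
            for b in detect_hbonds(model)
        }
        assert found == set(oracle)


class TestSaltBridges:
    def test_planted_minimum_distance(self):
        model = simple_pair_model(
            "ARG",
            [("NH1", (0, 0, 0)), ("NH2", (-1.0, 1.0, 0))],
            "ASP",
            [("OD1", (3.5, 0, 0)), ("OD2", (4.5, 1.0, 0))],
        )
        bridges = detect_salt_bridges(model)
        assert len(bridges) == 1
        # exhaustive minimum over the 2x2 group-atom combinations
        r1, r2 = model.chains[0].residues
        expected = brute_force_min_group_distance(r1.atoms, r2.atoms)
        assert bridges[0].distance == pytest.approx(expected)
        assert bridges[0].distance == pytest.approx(3.5)

    def test_beyond_cutoff_excluded(self):
        model = simple_pair_model(
            "ARG", [("NH1", (0, 0, 0))], "ASP", [("OD1", (6.0, 0, 0))]
        )
        assert detect_salt_bridges(model, cutoff=5.0) == []

    def test_his_cationic_configurable(self):
        model = simple_pair_model(
            "HIS", [("NE2", (0, 0, 0))], "GLU", [("OE1", (4.0, 0, 0))]
        )
        assert len(detect_salt_bridges(model, his_cationic=True)) == 1
        assert detect_salt_bridges(model, his_cationic=False) == []

    def test_interchain_bridge_on_planted_dimer(self, planted_contacts_dimer):
        model, truth = planted_contacts_dimer
        inter = [b for b in detect_salt_bridges(model) if b.topology == "inter-chain"]
        assert len(inter) == 1
        assert inter[0].distance == pytest.approx(3.5, abs=1e-3)


class TestWaterBridges:
    def _model_with_water(self, leg1, leg2):
        model = simple_pair_model(
            "SER", [("OG", (0, 0, 0))], "ASN", [("OD1", (leg1 + leg2, 0, 0))],
            chain2="B", seq2=5,
        )
        w = ChainModel(chain_id="W")
        res = ResidueRecord(name="HOH", seq_num=1, kind="water")
        res.atoms.append(AtomRecord(name="O", element="O",
                                    coords=np.array([leg1, 0.0, 0.0])))
        w.residues.append(res)
        model.chains.append(w)
        return model

    def test_bridging_water_detected(self):
        model = self._model_with_water(2.9, 2.9)
        bridges = detect_water_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].topology == "inter-chain"
        assert bridges[0].distance == pytest.approx(2.9)
        assert bridges[0].water_label == "W/1"

    def test_single_contact_water_no_bridge(self):
        model = self._model_with_water(2.9, 10.0)
        assert detect_water_bridges(model) == []

    def test_no_waters_empty(self, symmetric_dimer):
        model, _ = symmetric_dimer
        assert detect_water_bridges(model) == []


class TestLoopCensus:
    def test_planted_census_matches_exhaustive_scan(self):
        """Census counts equal those derived from an all-pairs oracle scan
        plus the planted cross-chain salt bridge."""
        spec = ToyDimerSpec(
            n_residues=40,
            geometry="extended",
            helical_segments=[(5, 9)],  # short helix: backbone mc-mc bonds
            planted_interactions=[
                PlantedInteraction("A", 12, "OG", "A", 14, "OD1", 2.8, "strong-hbond"),
                PlantedInteraction("A", 16, "OG", "A", 18, "OD1", 2.8, "strong-hbond"),
                PlantedInteraction("A", 20, "OG", "B", 30, "OD1", 2.8, "strong-hbond"),
                PlantedInteraction("A", 24, "NH1", "B", 34, "OD1", 4.5, "salt-bridge"),
            ],
            seed=11,
        )
        model, truth = make_toy_dimer(spec)
        lo, hi = 5, 25
        net = loop_interaction_summary(model, "A", (lo, hi))

        oracle = brute_force_hbond_pairs(model)

        def in_loop(key):
            chain, label, _ = key
            return chain == "A" and lo <= int(label) <= hi

        oracle_intra_strong = [
            pair for pair, (kind, _) in oracle.items()
            if kind == "strong-hbond" and all(in_loop(k) for k in pair)
        ]
        oracle_inter_strong = [
            pair for pair, (kind, _) in oracle.items()
            if kind == "strong-hbond"
            and len({k[0] for k in pair}) == 2
            and any(in_loop(k) for k in pair)
        ]
        assert net.summary["n_intra_loop_hbonds"] == len(oracle_intra_strong)
        # both planted intra pairs are among the oracle's strong bonds
        assert net.summary["n_intra_loop_hbonds"] >= 2
        assert net.summary["n_inter_salt"] == 1
        assert net.summary["n_intersubunit_bonds"] == len(oracle_inter_strong) + 1
        # mainchain-mainchain subcount equals the generator's backbone scan
        # restricted to the loop
        mc_pairs = [
            e for e in net.edges
            if e.kind == "strong-hbond"
            and e.backbone_class == "mainchain-mainchain"
            and e.partner1.chain == e.partner2.chain == "A"
        ]
        assert len(mc_pairs) <= truth.expected_helix_mainchain_hbonds

    def test_quiet_range_zero_counts(self, symmetric_dimer):
        model, _ = symmetric_dimer
        net = loop_interaction_summary(model, "A", (30, 35))
        assert net.summary["n_intra_loop_hbonds"] == 0
        assert net.summary["n_intersubunit_bonds"] == 0

    def test_summary_counts_consistent(self, planted_contacts_dimer):
        model, _ = planted_contacts_dimer
        net = loop_interaction_summary(model, "A", (1, 40))
        s = net.summary
        assert s["n_edges"] == len(net.edges)
        assert s["n_intersubunit_bonds"] <= s["n_intersubunit_pairs_any"]
        assert s["n_intra_loop_hbonds"] == s["n_intra_loop_strong"]

    def test_empty_range_errors(self, symmetric_dimer):
        model, _ = symmetric_dimer
        with pytest.raises(ConfigError):
            loop_interaction_summary(model, "A", (20, 10))

    def test_thresholds_recorded(self, symmetric_dimer):
        model, _ = symmetric_dimer
        net = loop_interaction_summary(model, "A", (10, 20), d_strong=3.2)
        assert net.thresholds["d_strong"] == 3.2


class TestActiveSiteSeparation:
    def test_two_single_atom_sites(self):
        model = simple_pair_model(
            "ALA", [("CA", (0, 0, 0))], "ALA", [("CA", (0, 0, 10))], chain2="B"
        )
        d = active_site_separation(
            model, "A", "B", site_atoms={"A": [(1, "CA")], "B": [(2, "CA")]}
        )
        assert d == pytest.approx(10.0)

    def test_planted_metal_centroids(self, planted_contacts_dimer):
        model, truth = planted_contacts_dimer
        d = active_site_separation(model, "A", "B")
        assert d == pytest.approx(truth.expected_site_separation, abs=1e-9)
        assert d == pytest.approx(10.0)

    def test_missing_site_errors(self, symmetric_dimer):
        model, _ = symmetric_dimer  # no metals planted
        with pytest.raises(ResidueLookupError):
            active_site_separation(model, "A", "B")
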