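"""Ion-pair and disulfide-candidate detection and their aggregate statistics."""

import numpy as np
import pytest

from _oracles import brute_force_disulfides, brute_force_ion_pairs, pair_key_set
from conftest import asp_lys_model, make_model, make_residue
from lyase_profile.bridge_analysis import (
    DisulfideConfig,
    IonPairConfig,
    bridge_report,
    find_disulfide_candidates,
    find_salt_bridges,
    ion_pair_stats,
)
from lyase_profile.errors import ConsistencyError
from lyase_profile.structure_io import ResidueRef
from lyase_profile.synthetic_data import SyntheticStructureSpec, generate_structure


class TestFindSaltBridges:
    def test_cutoff_is_inclusive(self):
        pairs = find_salt_bridges(asp_lys_model(distance=3.2))
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(3.2)

    def test_beyond_cutoff_excluded(self):
        assert find_salt_bridges(asp_lys_model(distance=3.2001)) == []

    def test_polyalanine_is_empty(self):
        ala = [make_residue("A", i, "ALA", "A", [("CA", "C", (4.0 * i, 0, 0))])
               for i in range(1, 11)]
        assert find_salt_bridges(make_model({"A": ala})) == []

    def test_pair_reported_once_despite_multiple_contacts(self):
        asp = make_residue("A", 1, "ASP", "D", [
            ("OD1", "O", (0.0, 0.0, 0.0)), ("OD2", "O", (0.5, 0.0, 0.0))])
        arg = make_residue("A", 2, "ARG", "R", [
            ("NE", "N", (2.5, 0.0, 0.0)), ("NH1", "N", (2.6, 0.0, 0.0)),
            ("NH2", "N", (2.7, 0.0, 0.0))])
        pairs = find_salt_bridges(make_model({"A": [asp, arg]}))
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(2.0)  # OD2-NE

    def test_planted_pairs_recovered(self):
        model, truth = generate_structure(SyntheticStructureSpec(seed=7))
        pairs = find_salt_bridges(model)
        assert len(pairs) == len(truth.planted_ion_pairs) == 12
        assert sum(p.inter_chain for p in pairs) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_brute_force(self, seed):
        model, _ = generate_structure(SyntheticStructureSpec(
            seed=seed, n_chains=3, residues_per_chain=30,
            n_salt_bridges=6, n_inter_chain_bridges=2, n_decoys=4,
            n_disulfides=2, n_inter_chain_disulfides=1))
        detected = pair_key_set(find_salt_bridges(model))
        assert detected == set(brute_force_ion_pairs(model))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonic_in_cutoff(self, seed):
        model, _ = generate_structure(SyntheticStructureSpec(seed=40 + seed))
        previous = set()
        for cutoff in (2.0, 2.8, 3.2, 4.5, 6.0):
            current = pair_key_set(find_salt_bridges(model, IonPairConfig(cutoff=cutoff)))
            assert previous <= current
            previous = current

    def test_relabeling_chains_preserves_counts(self):
        model, _ = generate_structure(SyntheticStructureSpec(seed=2))
        n_before = len(find_salt_bridges(model))
        ss_before = len(find_disulfide_candidates(model))
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        for chain in model.chains:
            chain.chain_id = mapping[chain.chain_id]
            for res in chain.residues:
                res.ref = ResidueRef(mapping[res.ref.chain_id], res.ref.residue_number,
                                     res.ref.insertion_code, res.ref.residue_name)
                res.atoms = list(reversed(res.atoms))  # atom order permuted too
        assert len(find_salt_bridges(model)) == n_before
        assert len(find_disulfide_candidates(model)) == ss_before

    def test_single_chain_has_no_inter_chain_pairs(self):
        model, _ = generate_structure(SyntheticStructureSpec(
            n_chains=1, residues_per_chain=40, n_salt_bridges=5,
            n_inter_chain_bridges=0, n_disulfides=1, n_inter_chain_disulfides=0,
            seed=13))
        stats = ion_pair_stats(find_salt_bridges(model), model)
        assert stats.n_inter_chain == 0

    def test_histidine_only_with_flag(self):
        asp = make_residue("A", 1, "ASP", "D", [("OD1", "O", (0.0, 0.0, 0.0))])
        his = make_residue("A", 2, "HIS", "H", [("ND1", "N", (3.0, 0.0, 0.0)),
                                                ("NE2", "N", (4.2, 0.0, 0.0))])
        model = make_model({"A": [asp, his]})
        assert find_salt_bridges(model) == []
        pairs = find_salt_bridges(model, IonPairConfig(include_his=True))
        assert len(pairs) == 1


class TestIonPairStats:
    def test_empty(self):
        model = asp_lys_model(distance=5.0)
        stats = ion_pair_stats([], model)
        assert stats.n_pairs == 0
        assert stats.fraction_in_sb == 0.0

    def test_count_once_rule(self):
        """3 bridges sharing one acidic residue in a 100-residue model:
        4 unique residues -> 4.0% participation."""
        glu = make_residue("A", 1, "GLU", "E", [("OE1", "O", (0.0, 0.0, 0.0))])
        lysines = [
            make_residue("A", 2 + k, "LYS", "K", [("NZ", "N", pos)])
            for k, pos in enumerate([(3.0, 0, 0), (0, 3.0, 0), (0, 0, 3.0)])
        ]
        fillers = [
            make_residue("A", 10 + i, "ALA", "A", [("CA", "C", (100.0 + 5.0 * i, 0, 0))])
            for i in range(96)
        ]
        model = make_model({"A": [glu, *lysines, *fillers]})
        pairs = find_salt_bridges(model)
        stats = ion_pair_stats(pairs, model)
        assert stats.n_pairs == 3
        assert stats.n_unique_residues == 4
        assert stats.total_residues == 100
        assert stats.fraction_in_sb == pytest.approx(4.0)

    def test_foreign_pair_rejected(self):
        model = asp_lys_model(distance=3.0)
        pairs = find_salt_bridges(model)
        other = asp_lys_model(distance=3.0)
        other.chains[0].chain_id = "Q"
        for res in other.chains[0].residues:
            res.ref = ResidueRef("Q", res.ref.residue_number, "", res.ref.residue_name)
        foreign = find_salt_bridges(other)
        with pytest.raises(ConsistencyError):
            ion_pair_stats(pairs + foreign, model)


class TestDisulfides:
    def test_cutoff_is_strict(self):
        def cys_pair(d):
            a = make_residue("A", 1, "CYS", "C", [("SG", "S", (0.0, 0.0, 0.0))])
            b = make_residue("A", 2, "CYS", "C", [("SG", "S", (d, 0.0, 0.0))])
            return make_model({"A": [a, b]})

        assert find_disulfide_candidates(cys_pair(6.0)) == []
        assert len(find_disulfide_candidates(cys_pair(5.999))) == 1

    def test_cys_free_model_empty(self):
        assert find_disulfide_candidates(asp_lys_model(3.0)) == []

    def test_planted_disulfide_recovered_with_subunit_flag(self):
        model, truth = generate_structure(SyntheticStructureSpec(seed=21))
        found = find_disulfide_candidates(model)
        assert pair_key_set(found) == set(brute_force_disulfides(model))
        assert sum(p.inter_subunit for p in found) == sum(
            p.inter_chain for p in truth.planted_disulfides)

    def test_cb_fallback_flagged(self):
        a = make_residue("A", 1, "CYS", "C", [("CB", "C", (0.0, 0.0, 0.0))])
        b = make_residue("A", 2, "CYS", "C", [("SG", "S", (3.0, 0.0, 0.0))])
        pairs = find_disulfide_candidates(make_model({"A": [a, b]}))
        assert len(pairs) == 1
        assert pairs[0].fallback_atoms

    def test_pairs_ordered_deterministically(self):
        model, _ = generate_structure(SyntheticStructureSpec(seed=21))
        found = find_disulfide_candidates(model)
        keys = [(p.cys_a.chain_id, p.cys_a.residue_number,
                 p.cys_b.chain_id, p.cys_b.residue_number) for p in found]
        assert keys == sorted(keys)
        for p in found:
            assert (p.cys_a.chain_id, p.cys_a.residue_number) <= (
                p.cys_b.chain_id, p.cys_b.residue_number)


class TestBridgeReport:
    def test_synthetic_tetramer_matches_planted_truth(self):
        spec = SyntheticStructureSpec(seed=31)
        model, truth = generate_structure(spec)
        rep = bridge_report(model)
        assert rep.stats.n_pairs == spec.n_salt_bridges
        assert rep.n_disulfides == spec.n_disulfides
        assert rep.n_inter_subunit_disulfides == spec.n_inter_chain_disulfides
        # planted pairs are residue-disjoint, so each contributes 2 residues
        assert rep.stats.n_unique_residues == 2 * spec.n_salt_bridges
        expected_fraction = 100.0 * 2 * spec.n_salt_bridges / model.n_residues
        assert rep.stats.fraction_in_sb == pytest.approx(expected_fraction)
        # per-chain Cys counts agree with the generated sequences
        for chain, seq in zip(model.chains, truth.chain_sequences):
            assert rep.cys_per_chain[chain.chain_id] == seq.count("C")

    def test_config_recorded_for_provenance(self):
        model, _ = generate_structure(SyntheticStructureSpec(seed=31))
        rep = bridge_report(model, IonPairConfig(cutoff=4.0), DisulfideConfig(cutoff=5.0))
        assert rep.ion_config.cutoff == 4.0
        assert rep.ss_config.cutoff == 5.0
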