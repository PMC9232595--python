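import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepos import (
    DEFAULT_SCHEMA,
    EnergySchema,
    Structure,
    binding_energy,
    binding_energy_from_structure,
    gen_toy_complex,
    load_energy_table,
    save_energy_table,
    score_structure,
    total_energy,
)
from pepos.energy import PerResidueEnergyTable

from conftest import make_atoms


def term(table, name):
    return table.schema.index(name)


class TestBackendPairTerms:
    def test_beyond_all_cutoffs_everything_is_zero(self):
        atoms = make_atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("C", 1, "GLY", "CA", "C", (10, 0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        assert np.all(t.values == 0.0)

    def test_lj_minimum_carbon_pair(self):
        # C-C at exactly sigma = 3.4 A: repulsion zero, attraction -epsilon,
        # split -0.05 to each residue.
        atoms = make_atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("C", 1, "GLY", "CA", "C", (3.4, 0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        atr, rep = term(t, "fa_atr"), term(t, "fa_rep")
        assert t.totals[rep] == pytest.approx(0.0, abs=1e-12)
        assert t.totals[atr] == pytest.approx(-0.1)
        np.testing.assert_allclose(t.values[:, atr], [-0.05, -0.05])

    def test_repulsion_is_capped_per_pair(self):
        atoms = make_atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("C", 1, "GLY", "CA", "C", (0.5, 0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        assert t.totals[term(t, "fa_rep")] == pytest.approx(10.0)

    def test_short_range_backbone_hbond(self):
        # Backbone N (res i) and backbone O (res i+2, same chain) at 2.9 A.
        atoms = make_atoms([
            ("A", 1, "GLY", "N", "N", (0, 0, 0)),
            ("A", 2, "GLY", "CA", "C", (20, 20, 20)),  # spacer, no contacts
            ("A", 3, "GLY", "O", "O", (2.9, 0, 0)),
            ("C", 1, "GLY", "CA", "C", (40, 40, 40)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        hb = term(t, "hbond_sr_bb")
        assert t.totals[hb] == pytest.approx(-1.0)
        assert t.row("A", 1)[hb] == pytest.approx(-0.5)
        assert t.row("A", 3)[hb] == pytest.approx(-0.5)
        for other in ("hbond_lr_bb", "hbond_bb_sc", "hbond_sc"):
            assert t.totals[term(t, other)] == 0.0

    def test_hbond_routing_by_atom_class(self):
        # Backbone N to side-chain O in another chain -> bb_sc channel.
        atoms = make_atoms([
            ("A", 1, "SER", "N", "N", (0, 0, 0)),
            ("C", 1, "SER", "OG", "O", (3.0, 0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        assert t.totals[term(t, "hbond_bb_sc")] == pytest.approx(-1.0)
        assert t.totals[term(t, "hbond_sr_bb")] == 0.0
        assert t.totals[term(t, "hbond_lr_bb")] == 0.0

    def test_electrostatics_between_charged_sidechains(self):
        # First side-chain atom of ASP (-1) vs LYS (+1) at 4 A:
        # 332 * (-1) / 16 = -20.75, split -10.375 each.
        atoms = make_atoms([
            ("A", 1, "ASP", "CB", "C", (0, 0, 0)),
            ("C", 1, "LYS", "CB", "C", (4.0, 0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        el = term(t, "fa_elec")
        assert t.totals[el] == pytest.approx(-20.75)
        np.testing.assert_allclose(t.values[:, el], [-10.375, -10.375])

    def test_burial_proxy_counts_foreign_neighbours(self):
        # N and O 3 A apart (different residues): each polar atom gains +0.05.
        atoms = make_atoms([
            ("A", 1, "GLY", "N", "N", (0, 0, 0)),
            ("C", 1, "GLY", "O", "O", (0, 3.0, 0)),
        ])
        t = score_structure(Structure(atoms, "C", "A"))
        sol = term(t, "fa_sol")
        np.testing.assert_allclose(t.values[:, sol], [0.05, 0.05])

    def test_unmodeled_terms_are_exactly_zero(self, toy_table):
        modeled = {"fa_atr", "fa_rep", "fa_sol", "fa_elec",
                   "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc"}
        for name in DEFAULT_SCHEMA.term_names:
            if name not in modeled:
                assert np.all(toy_table.values[:, term(toy_table, name)] == 0.0)

    def test_errors(self):
        atoms = make_atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("C", 1, "MSE", "SE", "SE", (3, 0, 0)),
        ])
        with pytest.raises(ValueError, match="unknown element"):
            score_structure(Structure(atoms, "C", "A"))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_column_sums_equal_totals(self, seed):
        t = score_structure(gen_toy_complex(seed=seed, perturbation_scale=0.3))
        np.testing.assert_allclose(t.values.sum(axis=0), t.totals, atol=1e-9)

    def test_rigid_motion_leaves_energies_unchanged(self, toy_complex, toy_table):
        theta = 1.1
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        moved = toy_complex.transformed(R, np.array([12.0, -7.0, 3.0]))
        t2 = score_structure(moved)
        np.testing.assert_allclose(t2.totals, toy_table.totals, atol=1e-6)
        np.testing.assert_allclose(t2.values, toy_table.values, atol=1e-6)

    def test_toy_complex_produces_multi_term_signal(self, toy_table):
        nonzero = {n for n in toy_table.schema.term_names
                   if abs(toy_table.totals[term(toy_table, n)]) > 1e-9}
        assert {"fa_atr", "fa_rep", "fa_sol", "fa_elec"} <= nonzero


class TestTotalAndBindingEnergy:
    def test_zero_table_gives_zero(self):
        t = PerResidueEnergyTable([("A", 1)], np.zeros((1, 19)), DEFAULT_SCHEMA)
        assert total_energy(t) == 0.0

    def test_unit_totals_with_unit_weights(self):
        t = PerResidueEnergyTable([("A", 1)], np.ones((1, 19)), DEFAULT_SCHEMA)
        assert total_energy(t) == pytest.approx(19.0)

    def test_matches_elementwise_multiply_and_sum(self, rng):
        values = rng.normal(size=(7, 19))
        weights = rng.normal(size=19)
        schema = EnergySchema(term_weights=tuple(weights))
        t = PerResidueEnergyTable([("A", i + 1) for i in range(7)], values, schema)
        brute = sum(values[:, j].sum() * weights[j] for j in range(19))
        assert total_energy(t) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize("triple,expected", [
        ((-100.0, -60.0, -30.0), -10.0),
        ((0.0, 5.0, -5.0), 0.0),
    ])
    def test_binding_energy_arithmetic(self, triple, expected):
        assert binding_energy(*triple) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_binding_energy_identity(self, a, b):
        assert binding_energy(a + b, a, b) == pytest.approx(0.0, abs=1e-6)

    def test_binding_energy_from_structure_isolates_interchain_terms(self, toy_complex):
        # Rigid separation: complex minus chain internals = inter-chain part,
        # which must be nonzero for a peptide sitting in the groove.
        e = binding_energy_from_structure(toy_complex)
        assert np.isfinite(e) and e != 0.0


class TestEnergyTableIO:
    def test_round_trip(self, toy_table, tmp_path):
        p = tmp_path / "t.tsv"
        save_energy_table(toy_table, p)
        back = load_energy_table(p)
        assert back.residue_keys == toy_table.residue_keys
        np.testing.assert_allclose(back.values, toy_table.values, rtol=1e-6)

    def test_missing_term_column_is_named(self, toy_table, tmp_path):
        p = tmp_path / "t.tsv"
        save_energy_table(toy_table, p)
        text = p.read_text().replace("fa_elec", "zapped")
        p.write_text(text)
        with pytest.raises(ValueError, match="fa_elec"):
            load_energy_table(p)

    def test_shuffled_columns_load_identically(self, toy_table, tmp_path, rng):
        import pandas as pd

        p, q = tmp_path / "a.tsv", tmp_path / "b.tsv"
        save_energy_table(toy_table, p)
        df = pd.read_csv(p, sep="\t")
        meta = ["chain", "residue_index"]
        terms = [c for c in df.columns if c not in meta]
        df[meta + list(rng.permutation(terms))].to_csv(q, sep="\t", index=False)
        np.testing.assert_allclose(
            load_energy_table(q).values, load_energy_table(p).values)

    def test_duplicate_residue_key_rejected(self, toy_table, tmp_path):
        p = tmp_path / "t.tsv"
        save_energy_table(toy_table, p)
        lines = p.read_text().splitlines()
        lines.append(lines[1])
        p.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="duplicate residue"):
            load_energy_table(p)

    def test_non_numeric_cell_rejected(self, toy_table, tmp_path):
        p = tmp_path / "t.tsv"
        save_energy_table(toy_table, p)
        lines = p.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[3] = "oops"
        lines[1] = "\t".join(parts)
        p.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="non-numeric"):
            load_energy_table(p)
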