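"""Structure/energy-log I/O, editing and disulfide detection."""

import numpy as np
import pytest

from confens import structio
from confens.structio import (Atom, EnergyLogError, EnsembleMismatchError,
                              MultiModelError, PDBParseError, StructureModel,
                              UnsupportedMutationError, delete_cterminal,
                              detect_disulfides, mutate_to_alanine, read_pdb,
                              read_energy_log, read_ensemble_pdb, write_pdb,
                              write_ensemble_pdb)


def _atom_line(serial, name, res_name, chain, res_seq, x, y, z,
               altloc=" ", occ=1.00, icode=" ", element=None):
    if element is None:
        element = name[0]
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {nm:<4.4s}{altloc}{res_name:<3s} {chain}"
            f"{res_seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{0.0:6.2f}          {element:>2s}\n")


def _ala_lines(res_seq, offset=0.0, chain="A", start_serial=1):
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
    out = []
    for i, (nm, el) in enumerate(names):
        out.append(_atom_line(start_serial + i, nm, "ALA", chain, res_seq,
                              offset + i, 0.0, 0.0, element=el))
    return out


class TestReadPDB:
    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            _atom_line(1, "N", "SER", "A", 1, 0, 0, 0),
            _atom_line(2, "CA", "SER", "A", 1, 1.5, 0, 0),
            _atom_line(3, "OG", "SER", "A", 1, 2.0, 1, 0, altloc="A", occ=0.6),
            _atom_line(4, "OG", "SER", "A", 1, 2.0, -1, 0, altloc="B", occ=0.4),
        ]
        p = tmp_path / "altloc.pdb"
        p.write_text("".join(lines) + "END\n")
        model = read_pdb(p)
        ogs = [a for a in model.atoms if a.name == "OG"]
        assert len(ogs) == 1
        assert ogs[0].coords[1] == pytest.approx(1.0)  # the 0.6 conformer

    def test_altloc_tie_keeps_first(self, tmp_path):
        lines = [
            _atom_line(1, "N", "SER", "A", 1, 0, 0, 0),
            _atom_line(2, "OG", "SER", "A", 1, 5.0, 0, 0, altloc="A", occ=0.5),
            _atom_line(3, "OG", "SER", "A", 1, 9.0, 0, 0, altloc="B", occ=0.5),
        ]
        p = tmp_path / "tie.pdb"
        p.write_text("".join(lines))
        model = read_pdb(p)
        og = [a for a in model.atoms if a.name == "OG"]
        assert len(og) == 1 and og[0].coords[0] == pytest.approx(5.0)

    def test_single_ala_atom_count_preserved(self, tmp_path):
        p = tmp_path / "ala.pdb"
        p.write_text("".join(_ala_lines(1)))
        model = read_pdb(p)
        assert len(model.atoms) == 5
        assert model.residues == [("A", 1, "ALA")]

    def test_short_atom_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(_ala_lines(1)[0] + "ATOM      2  CA\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(p)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0, icode="A"))
        with pytest.raises(PDBParseError, match="insertion"):
            read_pdb(p)

    def test_multimodel_redirects(self, tmp_path):
        body = "".join(_ala_lines(1))
        p = tmp_path / "multi.pdb"
        p.write_text(f"MODEL        1\n{body}ENDMDL\n"
                     f"MODEL        2\n{body}ENDMDL\n")
        with pytest.raises(MultiModelError, match="read_ensemble_pdb"):
            read_pdb(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBParseError):
            read_pdb(p)

    def test_gzip_transparent(self, tmp_path):
        import gzip
        p = tmp_path / "ala.pdb.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("".join(_ala_lines(1)))
        assert len(read_pdb(p).atoms) == 5


class TestEnsemblePDB:
    def _multi(self, tmp_path, n_models, drop_atom_in=None):
        parts = []
        for m in range(1, n_models + 1):
            lines = []
            for r in range(1, 11):
                lines.extend(_ala_lines(r, offset=3.8 * r + 0.01 * m,
                                        start_serial=(r - 1) * 5 + 1))
            if drop_atom_in == m:
                lines = lines[:-1]
            parts.append(f"MODEL     {m:4d}\n" + "".join(lines) + "ENDMDL\n")
        p = tmp_path / "ens.pdb"
        p.write_text("".join(parts))
        return p

    def test_five_models_ten_residues(self, tmp_path):
        ens = read_ensemble_pdb(self._multi(tmp_path, 5))
        assert ens.n_frames == 5
        assert len(ens.topology.residues) == 10

    def test_single_model_degenerate_allowed(self, tmp_path):
        ens = read_ensemble_pdb(self._multi(tmp_path, 1))
        assert ens.n_frames == 1

    def test_missing_atom_cites_model(self, tmp_path):
        with pytest.raises(EnsembleMismatchError, match="model 3"):
            read_ensemble_pdb(self._multi(tmp_path, 5, drop_atom_in=3))

    def test_roundtrip_to_3_decimals(self, tmp_path, helix20):
        rng = np.random.default_rng(5)
        from confens.structio import Ensemble
        frames = [helix20.coords + rng.normal(scale=0.3,
                                              size=(len(helix20.atoms), 3))
                  for _ in range(3)]
        ens = Ensemble(topology=helix20, frames=frames)
        p = tmp_path / "rt.pdb"
        write_ensemble_pdb(ens, p)
        back = read_ensemble_pdb(p)
        assert [a.name for a in back.topology.atoms] == \
            [a.name for a in helix20.atoms]
        assert [a.res_seq for a in back.topology.atoms] == \
            [a.res_seq for a in helix20.atoms]
        for f1, f2 in zip(frames, back.frames):
            np.testing.assert_allclose(f1, f2, atol=5e-4)


class TestEnergyLog:
    def test_basic_table(self, tmp_path):
        p = tmp_path / "e.xvg"
        p.write_text("# comment\n@ title \"E\"\n@ s0 legend \"Potential\"\n"
                     "0 -100.0\n10 -101.0\n20 -99.0\n30 -100.0\n")
        log = read_energy_log(p)
        assert len(log.values) == 4
        assert np.mean(log.values) == pytest.approx(-100.0)
        assert log.label == "Potential"

    def test_only_directives_is_empty_error(self, tmp_path):
        p = tmp_path / "e.xvg"
        p.write_text("# a\n@ b\n")
        with pytest.raises(EnergyLogError, match="no numeric"):
            read_energy_log(p)

    def test_third_column_ignored(self, tmp_path):
        p = tmp_path / "e.xvg"
        p.write_text("0 -1.0 99\n1 -2.0 98\n")
        log = read_energy_log(p)
        assert log.values == [-1.0, -2.0]

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "e.xvg"
        p.write_text("0 -1.0\n1 oops\n")
        with pytest.raises(EnergyLogError, match="line 2"):
            read_energy_log(p)


def _cys_model(sg_positions):
    """CYS residues with SG atoms at given coordinates."""
    atoms = []
    serial = 1
    for i, sg in enumerate(sg_positions):
        base = np.array([10.0 * i, 0.0, 0.0])
        for nm, el, off in (("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                            ("C", "C", (2.2, 1.2, 0)), ("O", "O", (1.9, 2.3, 0)),
                            ("CB", "C", (2.0, -1.2, 0))):
            atoms.append(Atom(serial, nm, el, i + 1, "CYS", "A", base + off))
            serial += 1
        atoms.append(Atom(serial, "SG", "S", i + 1, "CYS", "A",
                          np.asarray(sg, dtype=float)))
        serial += 1
    return StructureModel(atoms)


class TestEditing:
    def test_cys_to_ala_drops_sg_only(self):
        model = _cys_model([(3.0, -2.5, 0.0)])
        mutated = mutate_to_alanine(model, "A", 1)
        names = [a.name for a in mutated.atoms]
        assert names == ["N", "CA", "C", "O", "CB"]
        assert all(a.res_name == "ALA" for a in mutated.atoms)
        # retained coordinates untouched
        for a, b in zip(model.atoms[:5], mutated.atoms):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_ala_target_idempotent(self, helix20):
        out = mutate_to_alanine(helix20, "A", 5)
        assert len(out.atoms) == len(helix20.atoms)

    def test_gly_target_unsupported(self):
        atoms = [Atom(1, "N", "N", 1, "GLY", "A", (0, 0, 0)),
                 Atom(2, "CA", "C", 1, "GLY", "A", (1.5, 0, 0)),
                 Atom(3, "C", "C", 1, "GLY", "A", (2.2, 1.2, 0))]
        with pytest.raises(UnsupportedMutationError):
            mutate_to_alanine(StructureModel(atoms), "A", 1)

    def test_cterminal_deletion_counts(self, helix30):
        out = delete_cterminal(helix30, 25)
        assert len(out.residues) == 24
        # new C-terminal residue keeps its O
        last = out.residues[-1]
        assert any(a.name == "O" and a.res_seq == last[1] for a in out.atoms)

    def test_deletion_beyond_end_unchanged(self, helix30):
        out = delete_cterminal(helix30, 999)
        assert len(out.atoms) == len(helix30.atoms)

    def test_deletion_leaving_too_few_refused(self, helix20):
        with pytest.raises(ValueError, match="at least 3"):
            delete_cterminal(helix20, 2)


class TestDisulfides:
    def test_pair_at_2_05(self):
        model = _cys_model([(0, 0, 5), (2.05, 0, 5)])
        bonds = detect_disulfides(model)
        assert len(bonds) == 1
        assert bonds[0].sg_distance == pytest.approx(2.05)

    def test_pair_at_3_5_not_bonded(self):
        model = _cys_model([(0, 0, 5), (3.5, 0, 5)])
        assert detect_disulfides(model) == []

    def test_shortest_partner_wins_matches_bruteforce(self):
        # A-B at 2.0, B-C at 2.2: only A-B kept
        model = _cys_model([(0, 0, 5), (2.0, 0, 5), (4.2, 0, 5)])
        with pytest.warns(UserWarning, match="multiple"):
            bonds = detect_disulfides(model)
        # independent brute force: greedy shortest-first matching
        sgs = {a.res_seq: a.coords for a in model.atoms if a.name == "SG"}
        pairs = sorted(
            ((np.linalg.norm(sgs[i] - sgs[j]), i, j)
             for i in sgs for j in sgs if i < j
             and np.linalg.norm(sgs[i] - sgs[j]) <= 2.3))
        used, expected = set(), []
        for d, i, j in pairs:
            if i not in used and j not in used:
                used.update((i, j))
                expected.append((i, j))
        assert [(b.cys_a[1], b.cys_b[1]) for b in bonds] == expected == [(1, 2)]

    def test_invariant_under_rigid_motion(self):
        from conftest import random_rigid_motion
        model = _cys_model([(0, 0, 5), (2.05, 0, 5), (30, 0, 0)])
        rot, trans = random_rigid_motion(np.random.default_rng(3))
        moved = model.with_coords(model.coords @ rot.T + trans)
        b0, b1 = detect_disulfides(model), detect_disulfides(moved)
        assert [(b.cys_a, b.cys_b) for b in b0] == \
            [(b.cys_a, b.cys_b) for b in b1]
        assert b0[0].sg_distance == pytest.approx(b1[0].sg_distance)


def test_write_read_roundtrip_preserves_model(tmp_path, helix20):
    p = tmp_path / "helix.pdb"
    write_pdb(helix20, p)
    back = read_pdb(p)
    assert [(a.name, a.res_seq, a.res_name) for a in back.atoms] == \
        [(a.name, a.res_seq, a.res_name) for a in helix20.atoms]
    np.testing.assert_allclose(back.coords, helix20.coords, atol=5e-4)
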