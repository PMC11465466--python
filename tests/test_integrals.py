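"""Integral tables: FCIDUMP IO, model generators, symmetry handling."""

import numpy as np
import pytest

from spindmrg.integrals import (FcidumpParseError, IntegralTable,
                                hubbard_chain, hubbard_dimer_singlet_energy,
                                near_degenerate_spin_chain, random_cas,
                                read_fcidump, symmetrize_two_body,
                                write_fcidump)
from spindmrg.oracle import fci_ground_state


class TestFcidumpRoundTrip:
    def test_random_table_survives_round_trip(self, tmp_path):
        table = random_cas(4, 4, seed=11, scale=0.7)
        path = tmp_path / "t.fcidump"
        write_fcidump(table, path)
        back = read_fcidump(path)
        assert back.n_orb == table.n_orb
        assert back.n_elec == table.n_elec
        assert back.two_s_target == table.two_s_target
        np.testing.assert_allclose(back.one_body, table.one_body, atol=1e-14)
        np.testing.assert_allclose(back.two_body, table.two_body, atol=1e-14)

    def test_core_energy_only_writes_single_record(self, tmp_path):
        table = IntegralTable(2, 2, 0, 1.25, np.zeros((2, 2)),
                              np.zeros((2, 2, 2, 2)))
        path = tmp_path / "core.fcidump"
        write_fcidump(table, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln and not ln.startswith((" O", "&", " I"))]
        records = [ln for ln in lines if ln.strip()[0] in "0123456789-+."]
        assert len(records) == 1
        val, *idx = records[0].split()
        assert float(val) == 1.25 and idx == ["0"] * 4
        assert read_fcidump(path).core_energy == 1.25

    def test_single_two_body_record(self, tmp_path):
        path = tmp_path / "one.fcidump"
        path.write_text("&FCI NORB=1,NELEC=2,MS2=0,\n&END\n0.5 1 1 1 1\n")
        t = read_fcidump(path)
        assert t.two_body[0, 0, 0, 0] == 0.5
        assert np.all(t.one_body == 0.0)

    def test_one_body_symmetry_completion(self, tmp_path):
        path = tmp_path / "h.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n-1.0 1 2 0 0\n")
        t = read_fcidump(path)
        assert t.one_body[1, 0] == -1.0 and t.one_body[0, 1] == -1.0

    def test_two_body_orbit_completion(self, tmp_path):
        path = tmp_path / "g.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n0.25 2 1 1 1\n")
        g = read_fcidump(path).two_body
        for key in [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]:
            assert g[key] == 0.25

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.fcidump"
        path.write_text("&FCI NORB=2,MS2=0,\n&END\n")
        with pytest.raises(FcidumpParseError, match="NELEC"):
            read_fcidump(path)

    def test_bad_record_names_line_number(self, tmp_path):
        path = tmp_path / "bad2.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n0.5 1 1\n")
        with pytest.raises(FcidumpParseError, match="line 3"):
            read_fcidump(path)

    def test_inconsistent_duplicates_rejected(self, tmp_path):
        path = tmp_path / "dup.fcidump"
        path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n"
                        "0.5 1 2 1 1\n0.75 2 1 1 1\n")
        with pytest.raises(FcidumpParseError, match="duplicate"):
            read_fcidump(path)

    def test_refuses_to_write_asymmetric_table(self, tmp_path):
        table = hubbard_chain(2, 1.0, 4.0)
        table.two_body[0, 1, 0, 0] = 0.3   # break the 8-fold symmetry
        with pytest.raises(ValueError, match="8-fold"):
            write_fcidump(table, tmp_path / "x.fcidump")


class TestGenerators:
    def test_hubbard_dimer_matrix_elements(self):
        t = hubbard_chain(2, 1.0, 4.0)
        np.testing.assert_array_equal(t.one_body, [[0, -1], [-1, 0]])
        assert t.two_body[0, 0, 0, 0] == 4.0 and t.two_body[1, 1, 1, 1] == 4.0
        assert t.two_body.sum() == 8.0
        assert t.n_elec == 2 and t.two_s_target == 0

    def test_single_site_double_occupancy_energy(self):
        t = hubbard_chain(1, 1.0, 0.0, n_elec=2)
        e, _ = fci_ground_state(t, 2, 0)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_dimer_closed_form(self):
        t = hubbard_chain(2, 1.0, 4.0)
        e, _ = fci_ground_state(t, 2, 0)
        assert e == pytest.approx((4 - np.sqrt(16 + 16)) / 2, abs=1e-12)
        assert e == pytest.approx(hubbard_dimer_singlet_energy(1.0, 4.0),
                                  abs=1e-12)

    def test_random_cas_deterministic_and_symmetric(self):
        a = random_cas(4, 4, seed=7)
        b = random_cas(4, 4, seed=7)
        np.testing.assert_array_equal(a.one_body, b.one_body)
        np.testing.assert_array_equal(a.two_body, b.two_body)
        g = a.two_body
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            np.testing.assert_array_equal(g, np.transpose(g, perm))
        a.validate()  # exercises the full invariant set

    def test_energy_invariant_under_orbit_average(self):
        # a non-symmetric raw g and its orbit average give identical spectra
        rng = np.random.default_rng(5)
        raw = rng.standard_normal((3,) * 4)
        sym = symmetrize_two_body(raw)
        h = rng.standard_normal((3, 3))
        h = (h + h.T) / 2
        base = IntegralTable(3, 3, 1, 0.0, h, sym)
        e1, _ = fci_ground_state(base, 3, 1)
        resym = IntegralTable(3, 3, 1, 0.0, h, symmetrize_two_body(sym))
        e2, _ = fci_ground_state(resym, 3, 1)
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_near_degenerate_chain_valid_and_odd(self):
        t = near_degenerate_spin_chain(5)
        assert t.n_elec == 5 and t.two_s_target == 1
        t.validate()
        with pytest.raises(ValueError):
            near_degenerate_spin_chain(4)

    def test_spin_target_validation(self):
        with pytest.raises(ValueError):
            IntegralTable(2, 3, 0, 0.0, np.zeros((2, 2)), np.zeros((2,) * 4))
        with pytest.raises(ValueError):
            hubbard_chain(0, 1.0, 1.0)
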