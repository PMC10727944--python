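"""Search-space enumeration and dynamic multimer generation."""

import pytest

from muroseek.chemistry import canonical_name, mass_of
from muroseek.database import (
    CrosslinkRules,
    MonomerDBError,
    build_database,
    build_multimers,
    enumerate_monomer_space,
    gluconobacter_monomer_space,
    load_monomer_db,
    read_database,
    write_database,
)

NO_MODS = frozenset()


def _names(entries):
    out = set()
    for e in entries:
        out.update(e.names)
    return out


class TestMonomerEnumeration:
    def test_single_position_single_length(self):
        space = enumerate_monomer_space({1: ["A"]}, lengths={1})
        assert [canonical_name(m) for m in space] == ["gm-A"]

    def test_two_position_product(self):
        space = enumerate_monomer_space({1: ["A"], 2: ["E", "Q"]}, lengths={2})
        assert {canonical_name(m) for m in space} == {"gm-AE", "gm-AQ"}

    def test_gluconobacter_candidate_space_size(self):
        # 1 + 2 + 4 + 4*19 + 4*19 stems for lengths 1..5
        space = gluconobacter_monomer_space()
        assert len(space) == 159
        names = {canonical_name(m) for m in space}
        assert {"gm-A", "gm-AE", "gm-AQ", "gm-AEJ", "gm-AEJ_NH2",
                "gm-AEJA", "gm-AQJ_NH2AW"} <= names

    def test_empty_x_alphabet_is_an_error(self):
        with pytest.raises(ValueError, match="empty alphabet"):
            enumerate_monomer_space({1: ["X"]}, lengths={1}, x_alphabet=())


class TestMonomerDB:
    def test_load_reference_monomers(self, tmp_path, db0):
        path = tmp_path / "db0.csv"
        path.write_text("Structure\n" + "\n".join(db0) + "\n")
        entries = load_monomer_db(path)
        assert len(entries) == 28
        assert all(e.level == "monomer" for e in entries)
        assert all(e.warning is None for e in entries)

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("Structure\n")
        assert load_monomer_db(path) == []

    def test_mass_disagreement_attaches_warning(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("Structure,Mass\ngm-AE,700.0\n")
        (entry,) = load_monomer_db(path)
        assert entry.warning is not None
        assert "698.2858" in entry.warning
        assert entry.mass == pytest.approx(698.2859, abs=5e-4)

    def test_unparseable_name_reports_line_number(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("Structure\ngm-AE\ngm-AB*\n")
        with pytest.raises(MonomerDBError, match=r":3:"):
            load_monomer_db(path)


class TestMultimerGeneration:
    def test_one_three_dimers(self):
        entries = build_multimers(
            ["gm-AEJ_NH2", "gm-AEJA", "gm-A"],
            CrosslinkRules(enabled=frozenset({"1-3"})),
            modifications=NO_MODS,
        )
        by_name = {e.name: e for e in entries}
        assert set(by_name) == {"gm-AEJ_NH2=gm-A", "gm-AEJA=gm-A"}
        assert by_name["gm-AEJ_NH2=gm-A"].mass == pytest.approx(1420.6194, abs=5e-4)
        assert by_name["gm-AEJA=gm-A"].mass == pytest.approx(1492.6405, abs=5e-4)
        assert all(e.crosslink_types == {"1-3"} for e in entries)

    def test_no_dap_acceptor_no_dimers(self):
        assert build_multimers(["gm-A"], CrosslinkRules(
            enabled=frozenset({"1-3"})), modifications=NO_MODS) == []

    def test_four_three_self_dimer(self):
        entries = build_multimers(
            ["gm-AEJA"],
            CrosslinkRules(enabled=frozenset({"4-3"}), max_level=2),
            modifications=NO_MODS,
        )
        assert len(entries) == 1
        assert entries[0].names == ("gm-AEJA=gm-AEJA",)
        assert entries[0].mass == pytest.approx(1864.8047, abs=5e-4)

    def test_amidated_dap_cannot_donate_3_3(self):
        entries = build_multimers(
            ["gm-AEJ", "gm-AEJ_NH2"],
            CrosslinkRules(enabled=frozenset({"3-3"})),
            modifications=NO_MODS,
        )
        donors = {e.name.split("=")[-1] for e in entries}
        assert donors == {"gm-AEJ"}

    def test_restricted_1_3_dimers_all_contain_gmA(self, db0):
        entries = build_multimers(
            db0,
            CrosslinkRules(enabled=frozenset({"1-3"}),
                           restrict_1_3_to_gmA=True, max_level=2),
            modifications=NO_MODS,
        )
        assert entries
        assert all(e.name.endswith("=gm-A") for e in entries)


class TestGeneratedDatabase:
    def test_every_entry_mass_matches_chemistry_oracle(self, full_db):
        for e in full_db:
            for name in e.names:
                assert abs(mass_of(name) - e.mass) <= 1e-4

    def test_contains_all_reference_structures(self, composition_table, db_names):
        missing = [s for s in composition_table["structure"]
                   if s not in db_names]
        assert missing == []

    def test_disabling_1_3_removes_exactly_single_ala_donors(self, db0, db_names):
        no13 = build_database(
            db0, CrosslinkRules(enabled=frozenset({"4-3", "3-3"})))
        kept = _names(no13)
        removed = db_names - kept

        def has_single_ala_subunit(name):
            from muroseek.chemistry import parse_muropeptide
            m = parse_muropeptide(name)
            return m.crosslink_count > 0 and any(
                su.stem == ("A",) for su in m.subunits)

        assert removed
        assert all(has_single_ala_subunit(n) for n in removed)
        assert not any(has_single_ala_subunit(n) for n in kept)

    def test_size_monotone_in_rules_and_modifications(self, db0):
        sizes = []
        for enabled in [set(), {"4-3"}, {"4-3", "3-3"}, {"4-3", "3-3", "1-3"}]:
            sizes.append(len(build_database(
                db0, CrosslinkRules(enabled=frozenset(enabled)))))
        assert sizes == sorted(sizes)
        mod_sizes = []
        for mods in [set(), {"Anh"}, {"Anh", "DeAc"}]:
            mod_sizes.append(len(build_database(
                db0, CrosslinkRules(), modifications=frozenset(mods))))
        assert mod_sizes == sorted(mod_sizes)

    def test_csv_round_trip(self, tmp_path, full_db):
        path = tmp_path / "db.csv"
        write_database(full_db, path)
        back = read_database(path)
        assert len(back) == len(full_db)
        assert _names(back) == _names(full_db)
        for a, b in zip(full_db, back):
            assert b.mass == pytest.approx(a.mass, abs=1e-6)
            assert b.level == a.level
            assert b.crosslink_types == a.crosslink_types
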