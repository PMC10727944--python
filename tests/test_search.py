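"""ppm matching, satellite cleanup and replicate consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from muroseek.chemistry import ADDUCT_DELTAS, mass_of
from muroseek.database import TheoreticalEntry
from muroseek.msio import Feature, FeatureTable
from muroseek.search import (
    SearchConfig,
    cleanup,
    consolidate,
    match_features,
    ppm_diff,
)


def entry(name, mass=None, level="monomer"):
    return TheoreticalEntry(names=(name,), mass=mass or mass_of(name),
                            level=level)


class TestPpm:
    def test_zero_error(self):
        assert ppm_diff(870.3707, 870.3707) == 0.0

    def test_signed_error(self):
        assert ppm_diff(870.3725, 870.3707) == pytest.approx(2.068, abs=1e-3)
        assert ppm_diff(870.3689, 870.3707) == pytest.approx(-2.068, abs=1e-3)

    def test_boundary_is_inclusive(self):
        theo = 941.4078
        table = FeatureTable("s", [Feature(0, theo * (1 + 10e-6), 1.0, 5.0)])
        res = match_features(table, [entry("gm-AEJA", theo)], SearchConfig())
        assert len(res.matches) == 1
        assert res.matches[0].ppm_error == pytest.approx(10.0, abs=1e-6)


class TestMatching:
    def test_reference_spot_matches(self, full_db):
        table = FeatureTable("s", [
            Feature(0, 569.2433, 6.26, 100.0),
            Feature(1, 600.0000, 6.00, 50.0),
            Feature(2, 1420.6194, 8.60, 200.0),
        ])
        res = match_features(table, full_db, SearchConfig())
        primaries = {m.feature.id: m for m in res.matches if m.primary}
        assert "gm-A" in primaries[0].entry.names
        assert abs(primaries[0].ppm_error) < 1.0
        assert 1 not in primaries
        assert [f.id for f in res.unidentified] == [1]
        assert "gm-AEJ_NH2=gm-A" in primaries[2].entry.names
        assert "1-3" in primaries[2].entry.crosslink_types

    def test_multiple_matches_single_primary_intensity(self):
        db = [entry("a", 1000.000), entry("b", 1000.004)]
        table = FeatureTable("s", [Feature(0, 1000.001, 1.0, 100.0)])
        res = match_features(table, db, SearchConfig())
        assert len(res.matches) == 2
        primaries = [m for m in res.matches if m.primary]
        assert len(primaries) == 1
        assert primaries[0].entry.name == "a"  # lower |ppm|
        assert primaries[0].intensity_assigned == 100.0
        assert sum(m.intensity_assigned for m in res.matches) == 100.0

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_threshold_against_brute_force_oracle(self, data):
        """Features within tolerance match; beyond it never (guard band
        excludes the float-ambiguous sliver at the boundary itself)."""
        masses = data.draw(st.lists(
            st.floats(min_value=400, max_value=3000), min_size=1,
            max_size=8, unique=True))
        db = [entry(f"e{i}", m) for i, m in enumerate(sorted(masses))]
        offsets = data.draw(st.lists(
            st.floats(min_value=-25, max_value=25), min_size=1, max_size=10))
        offsets = [o for o in offsets if abs(abs(o) - 10.0) > 1e-3]
        features = [
            Feature(i, db[i % len(db)].mass * (1 + o * 1e-6), 1.0, 1.0)
            for i, o in enumerate(offsets)
        ]
        if not features:
            return
        res = match_features(FeatureTable("s", features), db, SearchConfig())
        got = {(m.feature.id, m.entry.name) for m in res.matches}
        expected = {
            (f.id, e.name)
            for f in features for e in db
            if abs(ppm_diff(f.neutral_mass, e.mass)) <= 10.0
        }
        assert got == expected


class TestCleanup:
    def _run(self, sat_rt, window=0.5):
        gm_a = mass_of("gm-A")
        db = [entry("gm-A", gm_a)]
        table = FeatureTable("s", [
            Feature(0, gm_a, 6.26, 100.0),
            Feature(1, gm_a + ADDUCT_DELTAS["Na"], sat_rt, 30.0),
        ])
        cfg = SearchConfig(cleanup_window=window)
        return cleanup(match_features(table, db, cfg))

    def test_sodium_satellite_merged_within_window(self):
        res = self._run(sat_rt=6.26 + 0.2)
        assert res.unidentified == []
        merged = [m for m in res.matches if m.provenance == "adduct-merged"]
        assert len(merged) == 1
        total = sum(m.intensity_assigned for m in res.matches
                    if "gm-A" in m.entry.names)
        assert total == 130.0

    def test_satellite_outside_window_not_merged(self):
        res = self._run(sat_rt=6.26 + 1.0)
        assert len(res.unidentified) == 1
        assert all(m.provenance == "direct" for m in res.matches)

    def test_no_satellites_cleanup_is_identity(self, full_db):
        table = FeatureTable("s", [Feature(0, mass_of("gm-AEJA"), 6.8, 10.0)])
        before = match_features(table, full_db, SearchConfig())
        after = cleanup(before)
        assert after.matches == before.matches
        assert after.unidentified == before.unidentified

    def test_cleanup_never_creates_new_structures(self, full_db):
        # a lone adduct-mass feature with no direct parent stays unidentified
        table = FeatureTable("s", [
            Feature(0, mass_of("gm-A") + ADDUCT_DELTAS["Na"], 6.26, 30.0)])
        res = cleanup(match_features(table, full_db, SearchConfig()))
        direct = [m for m in res.matches if m.provenance == "direct"]
        assert not any("gm-A" in m.entry.names for m in direct)
        assert not any(m.provenance != "direct" for m in res.matches)

    def test_intensity_conservation(self, full_db):
        rng = np.random.default_rng(42)
        features = [
            Feature(i, float(rng.uniform(400, 3000)), float(rng.uniform(0, 20)),
                    float(rng.uniform(0, 1e6)))
            for i in range(200)
        ]
        table = FeatureTable("s", features)
        res = match_features(table, full_db, SearchConfig())
        for stage in (res, cleanup(res)):
            assert (stage.assigned_intensity + stage.unidentified_intensity
                    == pytest.approx(table.total_intensity, rel=1e-12))


class TestConsolidate:
    def _result(self, rt, intensity, obs=None):
        gm_a = mass_of("gm-A")
        db = [entry("gm-A", gm_a)]
        table = FeatureTable("s", [Feature(0, obs or gm_a, rt, intensity)])
        return match_features(table, db, SearchConfig())

    def test_single_replicate_identity(self):
        df = consolidate([self._result(6.26, 100.0)])
        assert len(df) == 1
        row = df.iloc[0]
        assert row["intensity_mean"] == 100.0
        assert row["rt_mean"] == pytest.approx(6.26)
        assert np.isnan(row["rt_sd"])

    def test_rt_mean_and_sd_over_replicates(self):
        df = consolidate([self._result(5.28, 100.0), self._result(5.36, 300.0)])
        row = df.iloc[0]
        assert row["rt_mean"] == pytest.approx(5.32)
        assert row["rt_sd"] == pytest.approx(np.std([5.28, 5.36], ddof=1))
        assert row["intensity_mean"] == pytest.approx(200.0)
        assert row["n_replicates"] == 2

    def test_structure_absent_from_a_replicate(self):
        gm_a = mass_of("gm-A")
        db = [entry("gm-A", gm_a), entry("gm-AE", mass_of("gm-AE"))]
        r1 = match_features(FeatureTable("a", [
            Feature(0, gm_a, 6.26, 100.0),
            Feature(1, mass_of("gm-AE"), 6.79, 50.0),
        ]), db, SearchConfig())
        r2 = match_features(FeatureTable("b", [
            Feature(0, gm_a, 6.28, 120.0),
        ]), db, SearchConfig())
        df = consolidate([r1, r2]).set_index("structure")
        assert df.loc["gm-A", "n_replicates"] == 2
        assert df.loc["gm-A", "intensity_mean"] == pytest.approx(110.0)
        # absent replicate contributes nothing, not a zero
        assert df.loc["gm-AE", "n_replicates"] == 1
        assert df.loc["gm-AE", "intensity_mean"] == pytest.approx(50.0)
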