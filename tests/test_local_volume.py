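"""FL_Loc: candidate selection, windowed volumes, invariants."""

import numpy as np
import pytest

import aortamorph as am
from aortamorph.local_volume import SectionWindow, local_false_lumen_volume


def _profile(arclen, diameter, valid=None):
    arclen = np.asarray(arclen, float)
    diameter = np.asarray(diameter, float)
    if valid is None:
        valid = np.ones_like(arclen, bool)
    return am.DiameterProfile(arclen=arclen, diameter=diameter, valid=valid)


class TestSelectDiameterPositions:
    def test_nearby_runner_up_excluded_by_separation_rule(self):
        """The 38-mm peak 5 mm from the maximum is inside the 10-mm
        exclusion zone; the next largest eligible diameter wins s2."""
        arclen = np.arange(0.0, 101.0, 5.0)
        diameter = np.full_like(arclen, 30.0)
        diameter[arclen == 50.0] = 40.0
        diameter[arclen == 55.0] = 38.0
        diameter[arclen == 80.0] = 35.0
        s1, s2 = am.select_diameter_positions(_profile(arclen, diameter), 10.0)
        assert (s1, s2) == (50.0, 80.0)

    def test_monotone_profile_runner_up(self):
        arclen = np.arange(0.0, 51.0, 5.0)
        diameter = 20.0 + 0.2 * arclen  # max at the far end
        s1, s2 = am.select_diameter_positions(_profile(arclen, diameter), 10.0)
        assert s1 == 50.0
        assert s2 == 40.0  # largest among samples >= 10 mm away

    def test_short_profile_has_no_second_candidate(self):
        arclen = np.array([0.0, 2.0, 4.0, 6.0])
        s1, s2 = am.select_diameter_positions(
            _profile(arclen, [30.0, 31.0, 30.0, 29.0]), 10.0
        )
        assert s1 == 2.0
        assert s2 is None

    def test_ties_break_toward_smaller_arclen(self):
        arclen = np.arange(0.0, 41.0, 5.0)
        diameter = np.full_like(arclen, 30.0)
        s1, s2 = am.select_diameter_positions(_profile(arclen, diameter), 10.0)
        assert s1 == 0.0
        assert s2 == 10.0

    def test_no_valid_samples_rejected(self):
        prof = _profile([0.0, 1.0], [30.0, 30.0], valid=[False, False])
        with pytest.raises(ValueError, match="valid"):
            am.select_diameter_positions(prof, 10.0)


class TestLocalWindowVolume:
    def test_interior_window_proportionality(self, tube_1mm, tube_05mm):
        """On a uniform tube the 30-mm window holds 30/100 of FL_Glo.
        The voxel planes quantise the window content to +-1 plane, so
        the tolerance at 1 mm spacing is one plane (1/30); at 0.5 mm
        it tightens to 3%."""
        for ph, rel in ((tube_1mm, 1.0 / 30 + 0.01), (tube_05mm, 0.03)):
            got = local_false_lumen_volume(
                ph.vol, ph.cl, SectionWindow(center=50.0, half_width=15.0)
            )
            expect = ph.measures.FL_Glo * 30.0 / ph.cl.length
            assert got == pytest.approx(expect, rel=rel)

    def test_clipped_window_keeps_reduced_span(self, tube_1mm):
        """A window centered 5 mm from the end clips to [0, 20] mm."""
        got = local_false_lumen_volume(
            tube_1mm.vol, tube_1mm.cl, SectionWindow(center=5.0, half_width=15.0)
        )
        expect = tube_1mm.measures.FL_Glo * 20.0 / tube_1mm.cl.length
        assert got == pytest.approx(expect, rel=1.0 / 20 + 0.01)

    def test_empty_false_lumen_returns_zero(self):
        spec = am.PhantomSpec(fl_fraction=0.0, spacing=1.0)
        vol, _ = am.voxelize_phantom(spec)
        cl = am.extract_centerline(vol)
        assert local_false_lumen_volume(vol, cl, SectionWindow(50.0)) == 0.0

    def test_center_outside_rejected(self, tube_1mm):
        with pytest.raises(ValueError, match="center"):
            local_false_lumen_volume(
                tube_1mm.vol, tube_1mm.cl, SectionWindow(center=500.0)
            )

    def test_effective_span(self):
        w = SectionWindow(center=5.0, half_width=15.0)
        assert w.effective_span(100.0) == pytest.approx(20.0)
        assert w.effective_span(100.0) <= 2 * w.half_width


class TestFlLoc:
    def test_uniform_tube_closed_form(self, tube_1mm):
        got = tube_1mm.fl_loc(30.0)
        expect = tube_1mm.measures.FL_Glo * 30.0 / tube_1mm.cl.length
        assert got == pytest.approx(expect, rel=1.0 / 30 + 0.01)  # +-1 voxel plane

    def test_bulge_captures_local_false_lumen(self, bulge_1mm):
        """The window lands on the bulge and captures >= 90% of the
        analytic windowed false-lumen volume there."""
        got = bulge_1mm.fl_loc(30.0)
        assert got >= 0.90 * bulge_1mm.truth.FL_Loc

    def test_whole_vessel_window_equals_global(self, tube_1mm):
        with pytest.warns(UserWarning, match="non-standard"):
            got = am.fl_loc(
                tube_1mm.vol,
                tube_1mm.cl,
                tube_1mm.profile,
                section_length=2.0 * tube_1mm.cl.length,
                per_sample=tube_1mm.per_sample,
            )
        assert got == pytest.approx(float(tube_1mm.per_sample.sum()), abs=1e-12)

    def test_two_candidates_never_worse_than_one(self, bulge_1mm, tube_1mm):
        for ph in (bulge_1mm, tube_1mm):
            s1, _ = am.select_diameter_positions(ph.profile)
            single = local_false_lumen_volume(
                ph.vol, ph.cl, SectionWindow(s1, 15.0), ph.per_sample
            )
            assert ph.fl_loc(30.0) >= single - 1e-12

    @pytest.mark.parametrize(
        "fixture", ["tube_1mm", "bulge_1mm", "candy_cane_1mm", "tilted_tube_1mm"]
    )
    def test_monotone_in_section_length(self, fixture, request):
        ph = request.getfixturevalue(fixture)
        sweep = am.fl_loc_sweep(ph.vol, ph.cl, ph.profile)
        values = [sweep[L] for L in (10.0, 15.0, 30.0, 50.0)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= ph.measures.FL_Glo + 1e-12

    def test_window_tiling_reproduces_global_exactly(self, candy_cane_1mm):
        """Disjoint windows covering [0, L] partition the false lumen."""
        ph = candy_cane_1mm
        L = ph.cl.length
        edges = np.linspace(0.0, L, 6)
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            c, h = (lo + hi) / 2.0, (hi - lo) / 2.0
            total += local_false_lumen_volume(
                ph.vol, ph.cl, SectionWindow(c, h), ph.per_sample
            )
        assert total == pytest.approx(ph.measures.FL_Glo, abs=1e-9)

    def test_bad_section_length(self, tube_1mm):
        with pytest.raises(ValueError, match="section_length"):
            tube_1mm.fl_loc(-5.0)
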