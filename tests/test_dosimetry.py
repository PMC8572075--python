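"""Dosimetry: SSDE conversion, TCM averaging, DLP/ED identities, surrogate."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from scoutrange.core import CTVolume, ScanRange, TCMProfile
from scoutrange.dosimetry import (
    DoseReport,
    OrganGeometry,
    compare_scenarios,
    dlp,
    effective_diameter,
    effective_dose,
    load_organ_table,
    measure_body_diameters,
    normalize_to_reference_lung,
    organ_dose_surrogate,
    scenario_report,
    ssde,
    ssde_factor,
    tcm_region_average,
)
from scoutrange.phantom import (
    PhantomConfig,
    generate_phantom,
    range_from_mask3d,
    simulate_human_range,
)


class TestEffectiveDiameter:
    def test_equal_diameters(self):
        assert effective_diameter(10.0, 10.0) == pytest.approx(10.0)

    def test_geometric_mean(self):
        assert effective_diameter(23.3, 31.1) == pytest.approx(
            math.sqrt(23.3 * 31.1)
        )

    @pytest.mark.parametrize("pair", [(0.0, 30.0), (-5.0, 20.0)])
    def test_degenerate_rejected(self, pair):
        with pytest.raises(ValueError):
            effective_diameter(*pair)


class TestMeasureBodyDiameters:
    def test_phantom_round_trip(self, noiseless_phantom):
        cfg, volume, _ = noiseless_phantom
        d_ap, d_lat = measure_body_diameters(volume)
        assert abs(d_ap - 2 * cfg.body_semi_axes[0]) <= cfg.spacing[0] / 10
        assert abs(d_lat - 2 * cfg.body_semi_axes[1]) <= cfg.spacing[1] / 10

    def test_all_air_rejected(self):
        vol = CTVolume(np.full((10, 16, 16), -1000.0, np.float32), (2, 2, 2))
        with pytest.raises(ValueError, match="no body"):
            measure_body_diameters(vol)

    def test_isotropic_cylinder_symmetric(self):
        y, x = np.mgrid[:64, :64]
        disc = ((y - 31.5) ** 2 + (x - 31.5) ** 2) <= 20**2
        vox = np.where(disc, 40.0, -1000.0).astype(np.float32)[None].repeat(10, 0)
        vol = CTVolume(vox, (1.0, 1.0, 1.0))
        d_ap, d_lat = measure_body_diameters(vol)
        assert d_ap == pytest.approx(d_lat)
        assert abs(d_ap - 4.0) <= 0.2  # 2r = 40 voxels = 4 cm, +- 1 voxel


class TestSSDE:
    def test_zero_ctdi(self):
        assert ssde(0.0, 25.0) == 0.0

    def test_strictly_decreasing_in_diameter(self):
        d = np.linspace(6.0, 55.0, 60)
        f = np.array([ssde_factor(v) for v in d])
        assert np.all(np.diff(f) < 0)

    def test_fit_matches_published_table_values(self):
        # printed conversion factors for the 32 cm phantom
        for d_eff, expected in ((16.0, 2.06), (24.0, 1.53), (40.0, 0.85)):
            assert ssde_factor(d_eff) == pytest.approx(expected, rel=0.01)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            ssde(5.0, 4.0)
        with pytest.raises(ValueError):
            ssde(5.0, 60.0)


class TestTCMRegionAverage:
    def test_constant_profile(self):
        tcm = TCMProfile(np.full(20, 100.0))
        truth = ScanRange(5.0, 10.0)
        sel = ScanRange(2.0, 15.0)
        assert tcm_region_average(tcm, truth, sel) == (100.0, 100.0, 100.0)

    def test_exact_selection_has_empty_outer_regions(self):
        tcm = TCMProfile(np.arange(1.0, 21.0))
        truth = ScanRange(5.0, 10.0)
        lung, sup, inf = tcm_region_average(tcm, truth, truth)
        assert sup is None and inf is None and lung is not None

    def test_direct_means(self):
        # mA = slice index + 1 on slices 0..9; lung slices 3..6, selected all
        ma = np.arange(10.0) + 1.0
        tcm = TCMProfile(ma)
        truth = ScanRange(3.0, 6.0)
        sel = ScanRange(0.0, 9.0)
        lung, sup, inf = tcm_region_average(tcm, truth, sel, z0=0.0, dz=1.0)
        assert lung == pytest.approx(ma[3:7].mean())  # 5.5
        assert sup == pytest.approx(ma[0:3].mean())  # 2.0
        assert inf == pytest.approx(ma[7:10].mean())  # 9.0


class TestDLP:
    def test_product_and_zero(self):
        assert dlp(10.0, 30.0) == 300.0
        assert dlp(10.0, 0.0) == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            dlp(10.0, -1.0)


class TestNormalizeToReferenceLung:
    def test_equal_lengths_identity(self):
        r = ScanRange(-30.0, 270.0)
        out = normalize_to_reference_lung(r, 240.0, 240.0)
        assert out.superior_z == pytest.approx(-30.0)
        assert out.inferior_z == pytest.approx(270.0)

    def test_overscan_scales_by_ratio(self):
        # patient lung 300 mm with 30 mm overscan each way, reference 240
        r = ScanRange(-30.0, 330.0)
        out = normalize_to_reference_lung(r, 300.0, 240.0)
        assert out.superior_z == pytest.approx(-24.0)
        assert out.inferior_z == pytest.approx(264.0)

    def test_zero_overscan_stays_zero(self):
        out = normalize_to_reference_lung(ScanRange(0.0, 300.0), 300.0, 240.0)
        assert out.superior_z == 0.0 and out.inferior_z == pytest.approx(240.0)

    def test_non_positive_lengths_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference_lung(ScanRange(0.0, 100.0), 0.0, 240.0)


class TestOrganDoseSurrogate:
    ORGAN_IN = [OrganGeometry("lung", 0.0, 240.0, 1.0)]

    def test_fully_in_field_equals_regional_ssde(self):
        doses = organ_dose_surrogate(
            ScanRange(-20.0, 260.0), self.ORGAN_IN, {"lung": 8.0,
                                                     "superior": 8.0,
                                                     "inferior": 8.0},
        )
        assert doses["lung"] == pytest.approx(8.0)

    def test_distant_organ_negligible(self):
        organs = [OrganGeometry("gonads", 240.0 + 290.0, 240.0 + 310.0, 0.08)]
        doses = organ_dose_surrogate(
            ScanRange(0.0, 240.0), organs, {"lung": 10.0}, scatter_length_mm=30.0
        )
        assert doses["gonads"] < 1e-4 * 10.0

    def test_half_in_field_matches_numeric_integral(self):
        lam = 30.0
        s = 10.0
        organ = [OrganGeometry("x", -lam, lam, 0.5)]
        doses = organ_dose_surrogate(
            ScanRange(-500.0, 0.0), organ, {"lung": s, "superior": s}, lam
        )
        closed = s * (0.5 + 0.5 * (1 - math.exp(-1)))
        numeric = quad(
            lambda z: s if z <= 0 else s * math.exp(-z / lam), -lam, lam
        )[0] / (2 * lam)
        assert doses["x"] == pytest.approx(closed, abs=1e-6)
        assert doses["x"] == pytest.approx(numeric, abs=1e-6)

    def test_bounded_by_regional_ssde(self):
        organs = load_organ_table()
        doses = organ_dose_surrogate(
            ScanRange(-40.0, 300.0), organs,
            {"lung": 8.0, "superior": 9.5, "inferior": 7.0},
        )
        assert max(doses.values()) <= 9.5 + 1e-9

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            organ_dose_surrogate(ScanRange(0.0, 240.0), [], {"lung": 1.0})


class TestEffectiveDose:
    def test_weights_sum_to_one(self):
        organs = load_organ_table()
        assert sum(o.weight for o in organs) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_dose_equals_ed(self):
        organs = load_organ_table()
        doses = {o.organ: 7.3 for o in organs}
        assert effective_dose(doses, organs) == pytest.approx(7.3)

    def test_single_organ_weighting(self):
        organs = load_organ_table()
        assert effective_dose({"lung": 10.0}, organs) == pytest.approx(1.2)

    def test_all_zero(self):
        organs = load_organ_table()
        assert effective_dose({o.organ: 0.0 for o in organs}, organs) == 0.0

    def test_unknown_organ_rejected(self):
        organs = load_organ_table()
        with pytest.raises(KeyError):
            effective_dose({"flux_capacitor": 1.0}, organs)


@pytest.fixture(scope="module")
def scenario_setup():
    volume, mask3 = generate_phantom(PhantomConfig(noise_sd=0.0), seed=3)
    truth = range_from_mask3d(mask3)
    human = simulate_human_range(truth, seed=7)
    d_ap, d_lat = measure_body_diameters(volume)
    d_eff = effective_diameter(d_ap, d_lat)
    organs = load_organ_table()
    reports = {
        "exact": scenario_report("exact", truth, truth, volume, d_eff, organs),
        "human": scenario_report("human", truth, human, volume, d_eff, organs),
        "DL": scenario_report(
            "DL", truth,
            ScanRange(truth.superior_z - 3.0, truth.inferior_z + 4.0, "DL_Both"),
            volume, d_eff, organs,
        ),
    }
    return volume, truth, human, d_eff, organs, reports


class TestScenarioAccounting:
    def test_dlp_additive_over_regions(self, scenario_setup):
        *_, d_eff, _, reports = scenario_setup
        rep = reports["human"]
        f = ssde_factor(d_eff)
        parts = sum(
            (rep.regional_ssde[k] / f) * rep.regional_length_cm[k]
            for k in ("lung", "superior", "inferior")
            if rep.regional_ssde[k] is not None
        )
        assert abs(parts - rep.dlp) <= 1e-9 * rep.dlp

    def test_ed_decomposition_identity(self, scenario_setup):
        *_, reports = scenario_setup
        lhs = (
            reports["exact"].ed
            + reports["human"].ed_sup_extra
            + reports["human"].ed_inf_extra
        )
        assert abs(lhs - reports["human"].ed) <= 1e-6 * reports["human"].ed

    def test_ed_ordering_exact_dl_human(self, scenario_setup):
        *_, reports = scenario_setup
        assert reports["exact"].ed <= reports["DL"].ed <= reports["human"].ed

    def test_constant_ctdi_dlp_tracks_length(self, scenario_setup):
        volume, truth, human, d_eff, organs, _ = scenario_setup
        vol2 = CTVolume(
            volume.voxels, volume.spacing, ctdi_vol=volume.ctdi_vol,
            kvp=volume.kvp, tcm=TCMProfile(np.full(volume.n_slices, 150.0)),
            z0=volume.z0,
        )
        rep_h = scenario_report("human", truth, human, vol2, d_eff, organs)
        rep_e = scenario_report("exact", truth, truth, vol2, d_eff, organs)
        dlp_frac = (rep_h.dlp - rep_e.dlp) / rep_h.dlp
        len_frac = (rep_h.scan_length_cm - rep_e.scan_length_cm) / rep_h.scan_length_cm
        assert dlp_frac == pytest.approx(len_frac, abs=1e-12)
        assert rep_h.dlp == pytest.approx(vol2.ctdi_vol * rep_h.scan_length_cm)

    def test_ed_monotone_in_field_length(self, scenario_setup):
        volume, truth, _, d_eff, organs, _ = scenario_setup
        eds = []
        for extra in (0.0, 5.0, 15.0, 40.0, 80.0):
            sel = ScanRange(truth.superior_z - extra, truth.inferior_z + extra)
            sel = ScanRange(
                max(sel.superior_z, volume.z0),
                min(sel.inferior_z,
                    volume.z0 + (volume.n_slices - 1) * volume.slice_spacing),
            )
            eds.append(
                scenario_report("s", truth, sel, volume, d_eff, organs).ed
            )
        assert np.all(np.diff(eds) >= -1e-12)


class TestCompareScenarios:
    def _report(self, ed, sup=0.0, inf=0.0):
        return DoseReport(
            scenario="x", scan_length_cm=30.0, ssde=8.0, dlp=240.0,
            ctdi_vol=6.0, organ_doses={"lung": ed}, ed=ed,
            ed_base=ed - sup - inf, ed_sup_extra=sup, ed_inf_extra=inf,
        )

    def test_identical_scenarios_zero_reduction(self):
        hum = self._report(5.0)
        got = compare_scenarios(self._report(4.0), hum, hum)
        assert got.ed_reduction_percent == 0.0

    def test_reduction_arithmetic(self):
        got = compare_scenarios(
            self._report(4.9), self._report(5.93), self._report(4.90)
        )
        assert got.ed_reduction_percent == pytest.approx(
            100.0 * (5.93 - 4.90) / 5.93
        )

    def test_zero_human_ed_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios(
                self._report(0.0), self._report(0.0), self._report(0.0)
            )
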