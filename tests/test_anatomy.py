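"""Serial conductance partitioning and effective porosity."""

import pandas as pd
import pytest

from leafgm.anatomy import (
    airspace_conductance,
    average_technical_replicates,
    compose_gm,
    effective_porosity,
    membrane_conductance,
    partition_conductances,
    surface_areas_from_micrograph,
    wall_conductance_from_porosity,
    wall_thickness,
)
from leafgm.constants import PhysicalConstants
from leafgm.errors import InvalidArgumentError, NonphysicalPartitionError
from leafgm.synth import TruthSpec, generate_cohort


class TestMicrographTraits:
    def test_zero_mesophyll_length(self):
        out = surface_areas_from_micrograph(0.0, 0.0, 100.0, 1.2)
        assert out["s_m"] == 0.0

    def test_unit_case(self):
        assert surface_areas_from_micrograph(100.0, 50.0, 100.0, 1.0)["s_m"] == 1.0

    def test_full_chloroplast_coverage_ratio_one(self):
        out = surface_areas_from_micrograph(80.0, 80.0, 40.0, 1.7)
        assert out["sc_over_sm"] == pytest.approx(1.0)

    def test_zero_width_rejected(self):
        with pytest.raises(InvalidArgumentError):
            surface_areas_from_micrograph(10.0, 5.0, 0.0, 1.2)

    def test_wall_thickness_division_and_averaging(self):
        assert wall_thickness(650000.0, 6500.0) == pytest.approx(100.0)
        assert wall_thickness(0.0, 6500.0) == 0.0
        tbl = pd.DataFrame({
            "genotype": ["WT", "WT"], "replicate": ["r1", "r1"],
            "Tcw_nm": [100.0, 120.0],
        })
        out = average_technical_replicates(tbl)
        assert out["Tcw_nm"].iloc[0] == pytest.approx(110.0)

    def test_zero_wall_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wall_thickness(1.0, 0.0)


@pytest.fixture()
def pc():
    return PhysicalConstants()


class TestPartition:
    def test_forward_inverse_recovers_each_component(self, pc):
        g_ias = airspace_conductance(0.3, 250.0, pc)
        g_mem = membrane_conductance(12.0, pc)
        g_cw = wall_conductance_from_porosity(0.05, 160.0, 12.0, pc)
        gm = compose_gm(g_ias, g_cw, g_mem)
        comp = partition_conductances(gm, 0.3, 160.0, 250.0, 12.0, pc)
        assert comp.g_ias == pytest.approx(g_ias, rel=1e-12)
        assert comp.g_mem == pytest.approx(g_mem, rel=1e-12)
        assert comp.g_cw == pytest.approx(g_cw, rel=1e-10)
        assert comp.p_over_tau == pytest.approx(0.05, rel=1e-10)

    def test_series_identity_holds(self, pc):
        comp = partition_conductances(0.15, 0.3, 160.0, 250.0, 12.0, pc)
        assert comp.series_residual() < 1e-12

    def test_gm_at_airspace_ceiling_is_nonphysical(self, pc):
        g_ias = airspace_conductance(0.3, 250.0, pc)
        with pytest.raises(NonphysicalPartitionError):
            partition_conductances(g_ias, 0.3, 160.0, 250.0, 12.0, pc)

    def test_porosity_proportional_to_wall_thickness(self, pc):
        p1 = effective_porosity(0.2, 150.0, 12.0, pc)
        p2 = effective_porosity(0.2, 300.0, 12.0, pc)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_porosity_round_trip(self, pc):
        g_cw = wall_conductance_from_porosity(0.05, 200.0, 10.0, pc)
        assert effective_porosity(g_cw, 200.0, 10.0, pc) == pytest.approx(0.05, rel=1e-12)

    def test_implausible_porosity_flagged(self, pc):
        # an extremely conductive wall implies p/tau > 1
        g_ias = airspace_conductance(0.3, 250.0, pc)
        g_mem = membrane_conductance(12.0, pc)
        g_cw = wall_conductance_from_porosity(1.5, 160.0, 12.0, pc)
        gm = compose_gm(g_ias, g_cw, g_mem)
        comp = partition_conductances(gm, 0.3, 160.0, 250.0, 12.0, pc)
        assert comp.p_over_tau > 1.0 and not comp.plausible

    def test_thinner_wall_increases_wall_conductance(self, pc):
        g_thick = wall_conductance_from_porosity(0.05, 200.0, 12.0, pc)
        g_thin = wall_conductance_from_porosity(0.05, 150.0, 12.0, pc)
        assert g_thin > g_thick

    def test_module_forward_inverse_identity(self, pc):
        for p_tau, t_cw, f_ias, t_mes, s_c in [
            (0.02, 300.0, 0.2, 150.0, 8.0),
            (0.1, 120.0, 0.4, 300.0, 20.0),
        ]:
            g_ias = airspace_conductance(f_ias, t_mes, pc)
            g_mem = membrane_conductance(s_c, pc)
            g_cw = wall_conductance_from_porosity(p_tau, t_cw, s_c, pc)
            gm = compose_gm(g_ias, g_cw, g_mem)
            comp = partition_conductances(gm, f_ias, t_cw, t_mes, s_c, pc)
            assert comp.p_over_tau == pytest.approx(p_tau, rel=1e-10)


class TestCohortConsistency:
    def test_transgenic_wall_conductance_more_than_doubles(self, pc):
        """Default effect sizes (thinner wall x0.90, porosity x1.75) must
        reproduce a >100% increase in partition-recomputed g_cw."""
        truth = TruthSpec()
        truth.cohort.n_replicates = 60
        truth.cohort.n_technical = 1
        _, gm_tbl = generate_cohort(truth, seed=7)
        recomputed = []
        for _, r in gm_tbl.iterrows():
            comp = partition_conductances(
                r["gm"], r["f_ias"], r["Tcw_nm"], r["Tmes_um"], r["S_c"], pc,
                tleaf_c=r["Tleaf"],
            )
            recomputed.append({"genotype": r["genotype"], "g_cw": comp.g_cw})
        df = pd.DataFrame(recomputed)
        wt = df.loc[df["genotype"] == "WT", "g_cw"].mean()
        ev = df.loc[df["genotype"] != "WT", "g_cw"].mean()
        assert 100.0 * (ev - wt) / wt > 100.0
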