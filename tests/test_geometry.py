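import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handnir import (
    OUTSIDE,
    SYNOVIUM,
    TISSUE,
    ConcentrationMap,
    FluorophoreSpec,
    OpticalProperties,
    assign_concentrations,
    build_hand_slab,
    embed_synovial_shell,
    make_planar_source,
)


class TestOpticalProperties:
    def test_diffusion_coefficient(self):
        p = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        assert p.diffusion_coefficient == pytest.approx(1 / 3.03)

    @pytest.mark.parametrize(
        "kwargs", [{"mu_a": 0}, {"mu_s_prime": -1}, {"cr": 0}]
    )
    def test_rejects_nonpositive(self, kwargs):
        base = {"mu_a": 0.01, "mu_s_prime": 1.0}
        with pytest.raises(ValueError):
            OpticalProperties(**{**base, **kwargs})

    def test_fluorophore_validation(self):
        with pytest.raises(ValueError):
            FluorophoreSpec(quantum_yield=1.2, molar_absorption_ex=1e-4)
        with pytest.raises(ValueError):
            FluorophoreSpec(quantum_yield=0.5, molar_absorption_ex=0)


class TestBuildHandSlab:
    def test_voxel_counts(self):
        dom = build_hand_slab(60, 40, 20, 0.5)
        assert (dom.labels == TISSUE).sum() == 120 * 80 * 40
        assert dom.shape == (42, 122, 82)  # depth axis first, +2 border

    def test_under_resolved_rejected(self):
        with pytest.raises(ValueError):
            build_hand_slab(10, 10, 10, 5)

    def test_tissue_volume(self):
        dom = build_hand_slab(30, 30, 20, 1.0)
        vol = (dom.labels == TISSUE).sum() * dom.voxel_volume
        assert vol == pytest.approx(18_000)

    def test_border_is_outside(self):
        dom = build_hand_slab(20, 20, 10, 1.0)
        assert (dom.labels[0] == OUTSIDE).all()
        assert (dom.labels[:, 0] == OUTSIDE).all()
        assert (dom.labels[:, :, -1] == OUTSIDE).all()

    def test_non_dividing_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_hand_slab(10.3, 10, 10, 1.0)


class TestSynovialPocket:
    def test_crown_depth_at_request(self):
        for h in (0.5, 1.0):
            dom = build_hand_slab(60, 40, 25, h)
            dom = embed_synovial_shell(dom, center_depth=2.3)
            depths = (np.argwhere(dom.synovium_mask)[:, 0] - 1 + 0.5) * h
            assert abs(depths.min() - 2.3) <= h / 2

    def test_swelling_doubles_volume(self):
        dom = build_hand_slab(60, 40, 25, 0.5)
        n0 = embed_synovial_shell(dom, 2.3, swelling_percent=0).synovium_mask.sum()
        n1 = embed_synovial_shell(dom, 2.3, swelling_percent=100).synovium_mask.sum()
        assert n1 / n0 == pytest.approx(2.0, rel=0.10)

    def test_too_thin_pocket_rejected(self):
        dom = build_hand_slab(60, 40, 25, 0.5)
        with pytest.raises(ValueError, match="empty"):
            embed_synovial_shell(dom, 2.3, thickness=0.2)

    def test_escaping_pocket_rejected(self):
        dom = build_hand_slab(24, 24, 12, 1.0)
        with pytest.raises(ValueError):
            embed_synovial_shell(dom, 2.3, lateral_extent=(40, 40))

    def test_label_partition(self, small_domain):
        labels = small_domain.labels
        n = (
            (labels == OUTSIDE).sum()
            + (labels == TISSUE).sum()
            + (labels == SYNOVIUM).sum()
        )
        assert n == labels.size

    def test_pocket_not_adjacent_to_outside(self, small_domain):
        syn = small_domain.synovium_mask
        outside = small_domain.labels == OUTSIDE
        for axis in range(3):
            for shift in (-1, 1):
                assert not (syn & np.roll(outside, shift, axis=axis)).any()

    def test_depth_monotonicity(self):
        dom = build_hand_slab(60, 40, 25, 1.0)
        min_depths = []
        for depth in (2.3, 4.3, 6.3):
            d = embed_synovial_shell(dom, depth)
            min_depths.append(np.argwhere(d.synovium_mask)[:, 0].min())
        assert min_depths[0] < min_depths[1] < min_depths[2]

    def test_volume_grid_convergence(self):
        vols = []
        for h in (1.0, 0.5):
            dom = build_hand_slab(60, 40, 25, h)
            dom = embed_synovial_shell(dom, 2.3)
            vols.append(dom.synovium_mask.sum() * h**3)
        assert abs(vols[1] - vols[0]) / vols[1] < 0.05

    def test_input_domain_unmodified(self):
        dom = build_hand_slab(60, 40, 25, 1.0)
        embed_synovial_shell(dom, 2.3)
        assert not dom.synovium_mask.any()


class TestPlanarSource:
    def test_layer_at_one_scattering_length(self, props):
        dom = build_hand_slab(40, 30, 20, 0.5)
        src = make_planar_source(dom, props, power=1.0)
        iz = np.argwhere(src.any(axis=(1, 2)))[:, 0]
        assert len(iz) == 1
        # mu_s' = 1.0 -> source in the layer starting at 1.0 mm depth
        assert dom.depth_of_layer(iz[0]) == pytest.approx(1.25)

    def test_quarter_mm_grid_layer(self):
        props = OpticalProperties(mu_a=0.01, mu_s_prime=2.0)
        dom = build_hand_slab(20, 20, 10, 0.25)
        src = make_planar_source(dom, props, power=1.0)
        iz = int(np.argwhere(src.any(axis=(1, 2)))[0, 0])
        # 1/mu_s' = 0.5 mm -> layer spanning [0.5, 0.75) mm
        assert dom.depth_of_layer(iz) == pytest.approx(0.625)

    def test_total_power_normalized(self, small_domain, props):
        src = make_planar_source(small_domain, props, power=2.5)
        assert (src * small_domain.voxel_volume).sum() == pytest.approx(2.5)

    def test_zero_power(self, small_domain, props):
        src = make_planar_source(small_domain, props, power=0.0)
        assert (src == 0).all()

    def test_source_below_synovium_rejected(self, small_domain):
        shallow_scatter = OpticalProperties(mu_a=0.01, mu_s_prime=0.2)
        with pytest.raises(ValueError, match="inversion|fit"):
            make_planar_source(small_domain, shallow_scatter)

    def test_scattering_length_must_fit(self, props):
        dom = build_hand_slab(20, 20, 2, 0.5)
        thin = OpticalProperties(mu_a=0.01, mu_s_prime=0.4)
        with pytest.raises(ValueError):
            make_planar_source(dom, thin)


class TestConcentrations:
    @pytest.mark.parametrize("ratio,expected", [(10, 100.0), (5, 50.0), (1, 10.0)])
    def test_ratio_scaling(self, small_domain, ratio, expected):
        conc = assign_concentrations(small_domain, 10.0, ratio)
        assert conc.synovium_conc == pytest.approx(expected)
        assert conc.ratio == pytest.approx(ratio)

    def test_volume_rendering(self, small_domain):
        conc = assign_concentrations(small_domain, 10.0, 5)
        vol = conc.volume(small_domain)
        assert (vol[small_domain.labels == OUTSIDE] == 0).all()
        assert (vol[small_domain.tissue_mask] == 10.0).all()
        assert (vol[small_domain.synovium_mask] == 50.0).all()

    @given(bg=st.floats(0.1, 1000), ratio=st.floats(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_ratio_roundtrip(self, bg, ratio):
        c = ConcentrationMap(background_conc=bg, synovium_conc=ratio * bg)
        assert c.ratio == pytest.approx(ratio, abs=1e-9)

    def test_invalid_inputs(self, small_domain):
        with pytest.raises(ValueError):
            assign_concentrations(small_domain, 0.0, 5)
        with pytest.raises(ValueError):
            assign_concentrations(small_domain, 10.0, -1)
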