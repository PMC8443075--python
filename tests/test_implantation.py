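import numpy as np
import pytest
from shapely.geometry import MultiPoint

from icrsfem.geometry import CorneaGeometry, TunnelSpec
from icrsfem.implantation import (
    CrossSection,
    RingDesign,
    impose_ring,
    implant,
    ring_cross_section,
    tunnel_band_coords,
)
from icrsfem.mesh import carve_tunnel, generate_mesh


@pytest.fixture(scope="module")
def carved():
    return carve_tunnel(generate_mesh(CorneaGeometry()))


class TestRingCrossSection:
    @pytest.mark.parametrize("angle,thickness,base", [
        (0.0, 150.0, 600.0),
        (80.0, 225.0, 700.0),
        (160.0, 300.0, 800.0),
    ])
    def test_linear_interpolation_along_arc(self, angle, thickness, base):
        cs = ring_cross_section(RingDesign.asymmetric(), angle)
        assert cs.thickness == pytest.approx(thickness)
        assert cs.base == pytest.approx(base)

    def test_single_parameter_designs(self):
        cs = ring_cross_section(RingDesign.thickness_only(base=700.0), 80.0)
        assert (cs.thickness, cs.base) == (pytest.approx(225.0), pytest.approx(700.0))
        cs = ring_cross_section(RingDesign.base_only(thickness=225.0), 160.0)
        assert (cs.thickness, cs.base) == (pytest.approx(225.0), pytest.approx(800.0))

    def test_angle_outside_arc_rejected(self):
        with pytest.raises(ValueError):
            ring_cross_section(RingDesign.asymmetric(), 170.0)

    def test_outline_area_is_triangle_area(self):
        cs = CrossSection(thickness=300.0, base=800.0)
        assert cs.area_mm2 == pytest.approx(0.5 * 0.8 * 0.3)


class TestImposeRing:
    def test_implant_inside_cavity_makes_no_contact(self, carved):
        nodes, offsets = impose_ring(carved, CrossSection(thickness=20.0, base=700.0))
        assert len(nodes) == 0 and len(offsets) == 0

    def test_thick_end_opens_cavity_to_ring_thickness(self, carved):
        """800x30 um tunnel opened to the 300 um thick cross-section."""
        nodes, offsets = impose_ring(carved, CrossSection(thickness=300.0, base=800.0))
        local = tunnel_band_coords(carved, carved.nodes[nodes] + offsets)
        assert local[:, 1].max() == pytest.approx(0.300, abs=1e-6)
        assert local[:, 1].min() == pytest.approx(0.0, abs=1e-6)

    def test_imposed_outline_area_matches_triangle(self, carved):
        """Shoelace/hull area of the displaced boundary equals b*tau/2."""
        cs = CrossSection(thickness=300.0, base=800.0)
        nodes, offsets = impose_ring(carved, cs)
        local = tunnel_band_coords(carved, carved.nodes[nodes] + offsets)
        hull_area = MultiPoint(local.tolist()).convex_hull.area
        assert hull_area == pytest.approx(cs.area_mm2, rel=0.02)

    def test_wide_base_overhang_goes_inner(self, carved):
        """A base wider than the tunnel expands it toward the inner edge."""
        cs = CrossSection(thickness=300.0, base=900.0)
        nodes, offsets = impose_ring(carved, cs)
        xi = tunnel_band_coords(carved, carved.nodes[nodes] + offsets)[:, 0]
        w = carved.tunnel.width / 1000.0
        xl = w / 2.0 - 0.9
        assert xi.min() < -w / 2.0        # expanded beyond the inner end
        assert xi.min() >= xl - 1e-9
        assert xi.max() <= w / 2.0 + 1e-9


class TestImplantPipeline:
    def test_zero_size_cross_section_is_no_surgery(self, ax_ctx):
        post = implant(ax_ctx, CrossSection(thickness=0.0, base=0.0))
        assert post is ax_ctx.preop

    def test_rigid_ring_preserves_distances(self, ax_ctx):
        """Contacted tunnel-boundary nodes stay mutually rigid post-op."""
        cs = ring_cross_section(RingDesign.asymmetric(), 160.0)
        post = implant(ax_ctx, cs)
        carved = carve_tunnel(ax_ctx.mesh)
        nodes, offsets = impose_ring(carved, cs)
        shape = carved.nodes[nodes] + offsets     # the imposed ring outline
        xy = post.deformed_nodes[nodes]
        d_def = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        d_ref = np.linalg.norm(shape[:, None] - shape[None, :], axis=-1)
        assert np.abs(d_def - d_ref).max() < 1e-9

    def test_ring_settles_axially_only(self, ax_ctx):
        """With radial position and rotation retained, the contacted nodes all
        share one axial translation relative to the imposed outline."""
        cs = ring_cross_section(RingDesign.asymmetric(), 160.0)
        post = implant(ax_ctx, cs)
        carved = carve_tunnel(ax_ctx.mesh)
        nodes, offsets = impose_ring(carved, cs)
        shift = post.deformed_nodes[nodes] - (carved.nodes[nodes] + offsets)
        assert np.abs(shift[:, 0]).max() < 1e-9          # no radial drift
        assert np.ptp(shift[:, 1]) < 1e-9                # one shared settle
        assert abs(post.master_dofs[0]["uy"] - shift[0, 1]) < 1e-9

    def test_carved_cavity_under_iop_stays_valid(self, ax_ctx):
        """IOP on the carved (ring-free) tunnel: finite local sag, valid mesh."""
        post = implant(ax_ctx, CrossSection(thickness=25.0, base=700.0))
        d = np.abs(post.displacements - ax_ctx.preop.displacements)
        assert np.isfinite(d).all()
        assert d.max() < 0.1  # mm; a local effect, not a collapse
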