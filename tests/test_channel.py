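"""Conduit acoustics: celerity, compliance factor, design criteria."""

import numpy as np
import pytest

from cellhammer import (
    BOROSILICATE,
    STEEL,
    WATER,
    ChannelSpec,
    SolidMaterial,
    acoustics_report,
    celerity_general,
    celerity_rect,
    corrected_bulk_modulus,
    design_grid,
    fluid_loading,
    knudsen,
    phi_thorley,
)


def _chan(wall=BOROSILICATE, a=3e-3, b=3e-3, e=3e-3, l=60e-3):
    return ChannelSpec(a=a, b=b, e=e, l=l, wall=wall)


def _scaled(mat: SolidMaterial, k: float) -> SolidMaterial:
    return SolidMaterial(rho_s=mat.rho_s, c_s=mat.c_s, E=mat.E * k, G=mat.G * k)


def test_phi_positive_and_symmetric():
    phi = phi_thorley(3e-3, 3e-3, 3e-3, BOROSILICATE)
    assert phi > 0
    a, b = 5e-3, 2e-3
    assert phi_thorley(a, b, 1e-3, BOROSILICATE) == pytest.approx(
        phi_thorley(b, a, 1e-3, BOROSILICATE), rel=1e-12
    )


def test_phi_rejects_degenerate_geometry():
    with pytest.raises(ValueError):
        phi_thorley(0.0, 3e-3, 3e-3, BOROSILICATE)


def test_channel_spec_invariants():
    with pytest.raises(ValueError):
        ChannelSpec(a=1e-3, b=2e-3, e=1e-3, l=0.06, wall=BOROSILICATE)  # a < b
    ch = _chan()
    assert ch.area == pytest.approx(9e-6)
    assert ch.hydraulic_diameter == pytest.approx(3e-3)
    assert ch.mean_radius == pytest.approx(1.5e-3)


def test_celerity_rigid_limit_is_c0():
    stiff = _scaled(BOROSILICATE, 1e9)
    assert celerity_rect(WATER, _chan(wall=stiff)) == pytest.approx(
        WATER.c0, rel=1e-6
    )
    assert celerity_general(WATER, 0.0) == pytest.approx(WATER.c0, rel=1e-12)


def test_celerity_representative_channel_within_5pc_of_c0():
    """Stiff-walled (E >= 50 GPa) 3x3 mm channel: cf within 5% of c0,
    supporting the rigid-wall modelling choice."""
    cf = celerity_rect(WATER, _chan())
    assert cf <= WATER.c0
    assert cf > 0.95 * WATER.c0


def test_celerity_monotone_in_wall_modulus_and_thickness():
    cfs = [celerity_rect(WATER, _chan(wall=_scaled(BOROSILICATE, k)))
           for k in (0.1, 0.3, 1.0, 3.0, 10.0)]
    assert np.all(np.diff(cfs) > 0)
    cfe = [celerity_rect(WATER, _chan(e=e)) for e in (1e-3, 2e-3, 4e-3, 8e-3)]
    assert np.all(np.diff(cfe) > 0)


def test_celerity_general_agrees_with_rect_form():
    ch = _chan()
    phi = phi_thorley(ch.a, ch.b, ch.e, ch.wall)
    dist = phi / (ch.a * ch.b * ch.wall.E * ch.e**3)
    assert celerity_general(WATER, dist) == pytest.approx(
        celerity_rect(WATER, ch), rel=1e-12
    )


def test_corrected_bulk_modulus_round_trip():
    assert corrected_bulk_modulus(WATER, WATER.c0) == pytest.approx(WATER.K,
                                                                    rel=1e-12)
    assert corrected_bulk_modulus(WATER, 1353.6) == pytest.approx(1.832e9,
                                                                  rel=1e-3)
    cf = 1391.0
    assert np.sqrt(corrected_bulk_modulus(WATER, cf) / WATER.rho0) == pytest.approx(
        cf, rel=1e-14
    )


def test_kmod_ratio_identity():
    ch = _chan()
    cf = celerity_rect(WATER, ch)
    assert corrected_bulk_modulus(WATER, cf) / WATER.K == pytest.approx(
        (cf / WATER.c0) ** 2, rel=1e-12
    )


def test_fluid_loading_steel_duct_is_rigid():
    beta = fluid_loading(WATER, _chan(wall=STEEL))
    assert beta < 0.1


def test_fluid_loading_scalings():
    ch = _chan(wall=STEEL)
    cf = celerity_rect(WATER, ch)
    light = SolidMaterial(rho_s=STEEL.rho_s * 1e6, c_s=STEEL.c_s,
                          E=STEEL.E, G=STEEL.G)
    assert fluid_loading(WATER, _chan(wall=light), cf=cf) == pytest.approx(
        fluid_loading(WATER, ch, cf=cf) / 1e6, rel=1e-9
    )
    # beta scales linearly with the mean radius at fixed wall and cf
    big = _chan(wall=STEEL, a=6e-3, b=6e-3, l=60e-3)
    assert fluid_loading(WATER, big, cf=cf) == pytest.approx(
        2 * fluid_loading(WATER, ch, cf=cf), rel=1e-9
    )


def test_knudsen_values():
    assert knudsen(3e-3, 3e-10) == pytest.approx(1e-7, rel=1e-12)
    assert knudsen(1e-9, 1e-9) == 1.0
    assert knudsen(6e-3, 3e-10) == knudsen(3e-3, 3e-10) / 2


def test_design_grid_printed_discretization():
    """dz = 0.1 mm, dt = 0.7e-7 s at c0 gives Courant ~ 1.007 and 600
    steps over the 42 us window."""
    g = design_grid(WATER.c0, 0.06, 4.2e-5, dz=1e-4, dt=0.7e-7)
    assert g.courant == pytest.approx(1.0073, rel=1e-3)
    assert g.nt == 600
    assert g.nz == 600


def test_design_grid_courant_target_exact():
    g = design_grid(WATER.c0, 0.06, 4.2e-5, dz=1e-4, courant_target=1.0)
    assert g.dt == pytest.approx(1e-4 / WATER.c0, rel=1e-14)
    assert g.courant == pytest.approx(1.0, rel=1e-12)


def test_acoustics_report_flags_consistent_with_values():
    rep = acoustics_report(WATER, _chan())
    assert rep.rigid_ok == (rep.beta < 0.1)
    assert rep.continuum_ok == (rep.Kn < 1e-3)
    assert rep.Kmod == pytest.approx(WATER.rho0 * rep.cf**2, rel=1e-12)
    rigid = acoustics_report(WATER, _chan(), rigid_walls=True)
    assert rigid.cf == WATER.c0
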