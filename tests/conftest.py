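import numpy as np
import pytest

from occlumorph import (
    Asperity,
    AsperityKind,
    ChelaSpecimen,
    Cohort,
    Digit,
    GridProfile,
    LeverGeometry,
    ToothClass,
)
from occlumorph.profile_model import N_STATIONS


@pytest.fixture
def geometry():
    return LeverGeometry(
        L1U=22.0, L2M=40.0, L2F=38.8, x_ie_md=18.0, x_ie_fd=17.0, alpha_deg=55.0
    )


def make_profile(digit, axis_len=40.0, bump_station=5, bump_height=2.0):
    """Valid 18-station profile: zero tip, one triangular bump."""
    x = np.linspace(0.0, axis_len, N_STATIONS)
    y = np.zeros(N_STATIONS)
    y[bump_station - 1] = bump_height
    y[bump_station - 2] = 0.5 * bump_height
    y[bump_station] = 0.5 * bump_height
    return GridProfile(digit_kind=digit, x=x, y=y)


def make_specimen(
    specimen_id="S-001",
    species_code="SP",
    tip_offset=0.5,
    md_asperities=None,
    fd_asperities=None,
    geometry=None,
):
    geometry = geometry or LeverGeometry(
        L1U=22.0, L2M=40.0, L2F=38.8, x_ie_md=18.0, x_ie_fd=17.0, alpha_deg=55.0
    )
    default = [Asperity(x=5.0, y=2.0, kind=AsperityKind.PEAK)]
    return ChelaSpecimen(
        specimen_id=specimen_id,
        species_code=species_code,
        geometry=geometry,
        md_profile=make_profile(Digit.MOVEABLE, geometry.L2M),
        fd_profile=make_profile(Digit.FIXED, geometry.L2F),
        md_asperities=md_asperities if md_asperities is not None else list(default),
        fd_asperities=fd_asperities if fd_asperities is not None else list(default),
        tip_offset_um=tip_offset,
    )


@pytest.fixture
def make_cohort():
    def _make(offsets, species_code="SP", asperity_seqs=None):
        specimens = []
        for i, off in enumerate(offsets):
            kwargs = {}
            if asperity_seqs is not None:
                seq = asperity_seqs[i % len(asperity_seqs)]
                asps = [
                    Asperity(x=2.0 + 2.0 * j, y=1.0, kind=AsperityKind.PEAK,
                             tooth_class=ToothClass(c))
                    for j, c in enumerate(seq)
                ]
                kwargs = {"md_asperities": asps, "fd_asperities": asps}
            specimens.append(
                make_specimen(f"{species_code}-{i:03d}", species_code, off, **kwargs)
            )
        return Cohort(species_code=species_code, specimens=specimens)

    return _make


@pytest.fixture(scope="session")
def small_cohorts():
    """Four synthetic species cohorts at reduced n, shared across tests."""
    from occlumorph import generate_cohorts

    return generate_cohorts(n_per_species=5, seed=7)
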