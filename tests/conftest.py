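import pytest

from aavpack.cdms_synth import MixtureSpec
from aavpack.genome_model import ConstructDef, full_species_list
from aavpack.mass_model import (
    CapsidModel,
    MassModelParams,
    build_mass_table,
)

# Published subpopulation abundances (%) for the 848-nt unit construct from
# suspension cells: empty, then 1GOI-2ITR .. 6GOI-7ITR.  The residual up to
# 100% is unassigned "partial" material.
SUSPENSION_848_ABUNDANCES = {
    "empty": 79.8,
    "1GOI-2ITR": 2.8,
    "2GOI-3ITR": 2.96,
    "3GOI-4ITR": 2.36,
    "4GOI-5ITR": 1.68,
    "5GOI-6ITR": 0.54,
    "6GOI-7ITR": 0.19,
}

#: CD-MS termination profile (%) for the 1320-nt construct, ITRs 1..4.
CDMS_PROFILE_1320 = [30.6, 53.3, 15.7, 0.45]

#: Gel termination profile (%) for the 848-nt construct, ITRs 1..6.
GEL_PROFILE_848 = [5.2, 35.4, 24.1, 25.6, 6.2, 3.6]


@pytest.fixture
def construct_848() -> ConstructDef:
    return ConstructDef(name="TTR-848", unit_length=848, capacity=4700)


@pytest.fixture
def construct_1320() -> ConstructDef:
    return ConstructDef(name="TTR-1320", unit_length=1320, capacity=5200)


@pytest.fixture
def capsid() -> CapsidModel:
    return CapsidModel(vp1_mass=81_600.0, vp2_mass=66_600.0, vp3_mass=59_800.0)


@pytest.fixture
def mass_params() -> MassModelParams:
    return MassModelParams()


@pytest.fixture
def mass_table_848(construct_848, capsid, mass_params):
    return build_mass_table(full_species_list(construct_848), capsid, mass_params)


@pytest.fixture
def mass_table_1320(construct_1320, capsid, mass_params):
    return build_mass_table(full_species_list(construct_1320), capsid, mass_params)


@pytest.fixture
def suspension_mixture_848() -> MixtureSpec:
    abundances = dict(SUSPENSION_848_ABUNDANCES)
    abundances["partial"] = 100.0 - sum(abundances.values())
    return MixtureSpec.from_abundances(abundances)
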