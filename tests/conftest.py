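import pytest

from cortivox import MacroShape, ParameterSet, Range
from cortivox.cli import bundled_config_path, replicate_study
from cortivox.parameters import load_config


@pytest.fixture(scope="session")
def model_configs():
    """The three bundled validation configurations (healthy I/II, osteoporotic III)."""
    return {name: load_config(bundled_config_path(name)) for name in ("Model I", "Model II", "Model III")}


@pytest.fixture()
def small_params():
    """A quick, structurally valid healthy parameter set for unit tests."""
    return ParameterSet(
        osteon_diameter=Range(100, 250),
        osteon_density=22.0,
        osteon_inclination=Range(0, 10),
        cement_thickness=Range(0, 5),
        haversian_diameter=Range(50, 90),
        volkmann_diameter=Range(40, 50),
        volkmann_spacing=Range(150, 500),
        volkmann_inclination_max=15.0,
    )


@pytest.fixture()
def small_prism():
    return MacroShape(variant="prism", prism_dims=(0.6, 0.6, 0.4))


@pytest.fixture(scope="session")
def replication():
    """Seed-averaged porosities of the three validation models.

    20 seeds per model at 10 um voxels — the coarsened resolution the
    replication tolerances account for.  Shared across the acceptance
    tests so the simulation runs once per session.
    """
    return {row["model"]: row for row in replicate_study(n_seeds=20, voxel_size_um=10.0, base_seed=0)}
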