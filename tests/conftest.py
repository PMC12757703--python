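import pandas as pd
import pytest

from nicotine_pbpk import (
    build_reference_human,
    default_partition_coefficients,
    nicotine,
)
from nicotine_pbpk.scenarios import builtin_registry, run_scenario


@pytest.fixture(scope="session")
def physiology():
    return build_reference_human()


@pytest.fixture(scope="session")
def compound():
    return nicotine()


@pytest.fixture(scope="session")
def kps(physiology, compound):
    return default_partition_coefficients(physiology, compound)


@pytest.fixture(scope="session")
def registry_runs():
    """All nine verification scenarios, clearance mode: name -> (result, params, table)."""
    return {spec.name: run_scenario(spec) for spec in builtin_registry()}


@pytest.fixture(scope="session")
def validation_table(registry_runs):
    frames = [cmp for (_, _, cmp) in registry_runs.values() if cmp is not None]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def cyp_runs():
    """The six intravenous scenarios re-run in CYP2A6 kinetic mode."""
    return {
        spec.name: run_scenario(spec, mode="cyp2a6")
        for spec in builtin_registry()
        if spec.route in ("iv_infusion", "iv_bolus")
    }
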