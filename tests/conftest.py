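"""Shared fixtures: synthetic BCI-like inputs and the reference 5-year run.

The heavyweight paired simulations (with and without lianas) are
session-scoped so the conservation, climbing-invariant and directional
competition checks all share one pair of runs.
"""

import numpy as np
import pandas as pd
import pytest

from lianacomp import simulator, synth


@pytest.fixture(scope="session")
def bci_template():
    return synth.BCI_TEMPLATE


@pytest.fixture(scope="session")
def bci_met(bci_template):
    return synth.generate_met(bci_template, years=5, seed=42)


@pytest.fixture(scope="session")
def bci_inventory(bci_template):
    return synth.generate_inventory(bci_template, seed=43)


@pytest.fixture(scope="session")
def bci_forest(bci_inventory, bci_template):
    return simulator.initialize_from_inventory(
        bci_inventory, patch_area_m2=bci_template.patch_area_m2
    )


@pytest.fixture(scope="session")
def bci_run(bci_forest, bci_met):
    return simulator.run_simulation(bci_forest, bci_met, years=5, seed=0)


@pytest.fixture(scope="session")
def bci_run_no_lianas(bci_forest, bci_met):
    return simulator.run_simulation(
        simulator.remove_lianas(bci_forest), bci_met, years=5, seed=0
    )


@pytest.fixture()
def small_forest(bci_template):
    """Two-patch forest for fast unit runs."""
    inv = synth.generate_inventory(bci_template, seed=7)
    inv = inv[inv["patch_id"].isin(["patch-00", "patch-01"])]
    return simulator.initialize_from_inventory(
        inv, patch_area_m2=bci_template.patch_area_m2
    )


@pytest.fixture()
def small_met(bci_template):
    return synth.generate_met(bci_template, years=1, seed=5)


def make_inventory(rows):
    """Hand-built inventory table from (patch, stem, form, dbh, wd) tuples."""
    return pd.DataFrame(
        [
            {
                "patch_id": p, "stem_id": s, "growth_form": g, "dbh_cm": d,
                "wood_density_g_cm3": w, "density_multiplier": 1.0,
            }
            for p, s, g, d, w in rows
        ]
    )
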