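import numpy as np
import pytest

from pbpktk import voc
from pbpktk.engine import (FlowLimitedStructure, GasExchangeSpec, MetabolismSpec,
                           SolverSettings, TissueSpec, Transfer)


@pytest.fixture(scope="session")
def physiology():
    return voc.load_default_physiology()


@pytest.fixture(scope="session")
def tce():
    return voc.load_voc_parameters("TCE")


@pytest.fixture(scope="session")
def tce_no_metabolism(tce):
    from dataclasses import replace
    return replace(tce, vmax_c=0.0, k_first_order_per_h=0.0)


@pytest.fixture
def decay_pool_structure():
    """One pool with first-order loss to an excretion ledger."""
    def make(k_per_h=0.1):
        return FlowLimitedStructure(pools=("a",),
                                    transfers=(Transfer("a", "ledger:excreted", k_per_h),),
                                    extra_ledgers=("oral_intake",),
                                    name="decay")
    return make


@pytest.fixture
def three_compartment_toy():
    """Blood + two tissues with gas exchange, constant inhalation, saturable
    metabolism in tissue 'x' -- small enough for a fixed-step oracle."""
    tissues = (TissueSpec("x", volume_L=2.0, flow_L_per_h=6.0, partition=2.0),
               TissueSpec("y", volume_L=5.0, flow_L_per_h=4.0, partition=3.0))
    return FlowLimitedStructure(
        tissues=tissues, blood_volume_L=1.5, cardiac_output_L_per_h=10.0,
        gas_exchange=GasExchangeSpec(alveolar_ventilation_L_per_h=8.0,
                                     blood_air_partition=5.0,
                                     inhaled_mg_per_L=lambda t: 0.02),
        metabolism=MetabolismSpec(compartment="x", vmax_mg_per_h=0.5, km_mg_per_L=0.1),
        name="toy3")


@pytest.fixture(scope="session")
def tight_settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def quick_settings():
    return SolverSettings(rtol=1e-8, atol=1e-10, output_dt_h=0.1)
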