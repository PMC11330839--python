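import pandas as pd
import pytest

from faersig import TargetDrugSpec, ingest_quarters
from faersig.synthetic import InjectedSignal, SimulationConfig, simulate, write_dataset

GALSULFASE = TargetDrugSpec.from_names(["galsulfase", "naglazyme"])


def small_config(**overrides) -> SimulationConfig:
    """A small but fully featured simulation: injected signal, duplicates,
    partial dates, date-order violations."""
    defaults = dict(
        seed=11,
        n_cases=800,
        target_drug_fraction=0.15,
        injected_signals=[InjectedSignal("Synthetic PT A1", 6.0)],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_small():
    return simulate(small_config())


@pytest.fixture(scope="session")
def ingested_small(sim_small, tmp_path_factory):
    """The small simulation written as quarter files and re-ingested."""
    root = tmp_path_factory.mktemp("quarters")
    dirs = write_dataset(sim_small, root, split_quarters=False)
    tables, log = ingest_quarters(dirs)
    return tables, log


def demo_frame(rows):
    """DEMO frame from (primaryid, caseid, fda_dt) triples (test shorthand)."""
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    for col in ("event_dt", "sex", "age", "age_cod", "wt", "wt_cod",
                "occp_cod", "reporter_country"):
        df[col] = ""
    return df.astype(str)
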