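import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import qsippy as q

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_counts():
    """3 taxa x 4 samples count table with taxonomy."""
    data = pd.DataFrame(
        {
            "s1": [2, 3, 5],
            "s2": [0, 7, 3],
            "s3": [4, 4, 2],
            "s4": [1, 0, 9],
        },
        index=["t1", "t2", "t3"],
    )
    taxonomy = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P2"],
            "genus": ["GA", "GA", "GB"],
        },
        index=["t1", "t2", "t3"],
    )
    return q.FeatureTable(data, "read_count", taxonomy)


@pytest.fixture(scope="session")
def simulated():
    """One default-condition simulated experiment, preprocessed and fitted."""
    cfg = q.SimulationConfig(seed=1, dropout_p=0.0)
    table, metadata, qpcr, truth = q.simulate_experiment(cfg)
    absolute, report = q.preprocess_counts(table, qpcr)
    results = q.QsipModel(absolute, metadata).fit(seed=1001)
    return {
        "config": cfg,
        "counts": table,
        "metadata": metadata,
        "qpcr": qpcr,
        "truth": truth,
        "absolute": absolute,
        "report": report,
        "results": results,
    }
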