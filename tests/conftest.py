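import numpy as np
import pandas as pd
import pytest

import tcross_gs as t


@pytest.fixture(scope="session")
def small_study():
    """A small structured study shared by read-only tests.

    120 inbred lines in three subpopulations, 600 unlinked markers, 40 QTL,
    H2 = 0.7, 5% missing calls.
    """
    cfg = t.SimConfig(
        n_lines=120,
        subpop_sizes=(70, 35, 15),
        n_markers=600,
        fst=0.3,
        n_qtl=40,
        h2_target=0.7,
        missing_rate=0.05,
        seed=7,
    )
    panel, trials, truth = t.simulate_study(cfg)
    genotypes, report = t.qc_pipeline(panel)
    return {
        "config": cfg,
        "panel": panel,
        "trials": trials,
        "truth": truth,
        "genotypes": genotypes,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_panel(calls, line_prefix="L", marker_prefix="M"):
    """MarkerPanel from a plain nested list / array with NaN for missing."""
    arr = np.asarray(calls, dtype=float)
    return t.MarkerPanel(
        calls=pd.DataFrame(
            arr,
            index=[f"{line_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"{marker_prefix}{j}" for j in range(arr.shape[1])],
        )
    )
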