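import numpy as np
import pandas as pd
import pytest

import barseqfit as bf


@pytest.fixture(scope="session")
def small_library() -> bf.BarcodeLibrary:
    return bf.make_barcode_library(5, min_distance=3, seed=1)


@pytest.fixture(scope="session")
def neutral_experiment() -> bf.SimulatedExperiment:
    """20 neutral strains, default serial-batch design, seed 5."""
    return bf.simulate_experiment(bf.SerialBatchDesign(seed=5), n_strains=20)


@pytest.fixture(scope="session")
def two_condition_sheet() -> pd.DataFrame:
    """2 treatments x 2 timepoints x 3 replicates."""
    rows = []
    for trt in ("control", "copper"):
        for tp in ("T1", "T3"):
            for rep in (1, 2, 3):
                rows.append((f"{trt}_{tp}_r{rep}", trt, tp, rep))
    return pd.DataFrame(rows, columns=["sample", "treatment", "time", "replicate"])


def brute_force_match(
    read: str,
    library: bf.BarcodeLibrary,
    template: bf.AmpliconTemplate,
    max_mismatch: int,
) -> tuple[str | None, str]:
    """Independent all-pairs matcher: pure-python distances to every pair."""
    a, b = template.offset_up, template.offset_dn
    if len(read) < template.span:
        return None, "unassigned"
    observed = read[a : a + 12] + read[b : b + 12]
    dists = {
        sid: sum(x != y for x, y in zip(observed, up + dn))
        for sid, (up, dn) in library.pairs.items()
    }
    dmin = min(dists.values())
    if dmin > max_mismatch:
        return None, "unassigned"
    hits = [sid for sid, d in dists.items() if d == dmin]
    if len(hits) > 1:
        return None, "ambiguous"
    return hits[0], "assigned"
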