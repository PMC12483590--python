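import numpy as np
import pandas as pd
import pytest

from proteoscope.matrices import AbundanceMatrix, make_meta
from proteoscope.synthetic import SimConfig


@pytest.fixture
def small_config():
    """10 lines x 3 replicates, 2 lineages; desk-scale everything."""
    return SimConfig(
        n_lines=10,
        n_reps_per_line=3,
        n_proteins=120,
        n_phosphosites=300,
        n_lineages=2,
        lineage_sizes=(5, 5),
        n_markers_per_lineage=8,
        n_site_glycans=60,
        n_cis_genes=20,
        seed=11,
    )


@pytest.fixture
def noise_free_config(small_config):
    return small_config.replace(
        noise_sd=0.0, biological_sd=0.0, lineage_effect_sd=0.0, dropout_rate=0.0
    )


def build_matrix(values, lines, n_reps, lineage=None, scale="raw", features=None):
    """Hand-rolled AbundanceMatrix from a 2-D array (features x samples)."""
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"F{i:03d}" for i in range(values.shape[0])]
    replicates = {l: [f"{l}_R{r + 1}" for r in range(n_reps)] for l in lines}
    lineage = lineage or {l: "LIN1" for l in lines}
    meta = make_meta(list(lines), replicates, lineage)
    df = pd.DataFrame(values, index=features, columns=meta.index)
    return AbundanceMatrix(values=df, meta=meta, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
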