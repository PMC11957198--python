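import warnings

import numpy as np
import pandas as pd
import pytest

from sextwas import simulate as sim

# mixed-model variance-surface warnings are expected noise in simulations
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_male=60, n_female=120, n_genes_autosomal=60, n_genes_x=12,
        n_genes_y=4, seed=101,
        causal_table=[
            (0, "amyloid", "female", 0.5),
            (1, "tau", "male", 0.5),
            (2, "tau", "both", 0.5),
            (3, "cognition", "female", 0.06),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated bundle shared by read-only tests."""
    cohort = sim.generate_cohort(small_config)
    counts, samples, annotation, truth = sim.generate_counts(small_config, cohort)
    outcomes = sim.generate_outcomes(small_config, cohort, truth.latent)
    return {
        "config": small_config,
        "cohort": cohort,
        "counts": counts,
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "outcomes": outcomes,
    }


def gaussian_expression(n_genes, decedents, seed, prefix="GA"):
    """Latent-scale expression for model-level oracles (no count noise)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_genes, len(decedents))),
        index=[f"{prefix}{i:04d}" for i in range(n_genes)],
        columns=decedents,
    )
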