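import numpy as np
import pytest

from malines import SimConfig, run_ma_pipeline, simulate_ma_experiment


def clean_config(seed: int = 7, mu: float = 5e-8, n_lines: int = 5,
                 genome_length: int = 200_000) -> SimConfig:
    """Error-free, artifact-free config with constant in-band depth: every
    site callable, every true mutation detectable by construction."""
    return SimConfig(
        seed=seed,
        genome_length=genome_length,
        treatments=("outdoor-UV",),
        n_lines_per_treatment=n_lines,
        true_mu_per_treatment={"outdoor-UV": mu},
        depth_dispersion=None,
        seq_error_rate=0.0,
        artifact_site_rate=0.0,
        indel_artifact_rate=0.0,
        loh_rate=0.0,
    )


@pytest.fixture(scope="session")
def realistic_run():
    """One 300-kb simulated MA experiment with noise sources on, plus its
    pipeline result — shared across tests that only read it."""
    cfg = SimConfig(
        seed=11, genome_length=300_000, artifact_site_rate=3e-5,
        seq_error_rate=1e-3, n_ancestor_hets=80, indel_artifact_rate=1e-5,
        true_mu_per_treatment={"indoor": 0.0, "outdoor-noUV": 5e-8,
                               "outdoor-UV": 1e-7},
    )
    calls, depths, truth = simulate_ma_experiment(cfg)
    result = run_ma_pipeline(calls, depths)
    return cfg, calls, depths, truth, result
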