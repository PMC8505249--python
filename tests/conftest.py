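import numpy as np
import pandas as pd
import pytest

from celldmr.synthetic_data import (SimulationConfig, default_config,
                                    generate_annotation, generate_probe_layout,
                                    simulate_signals, simulate_truth)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small two-chromosome study used by most integration-style tests."""
    return default_config(
        n_genes=100, n_cases=6, n_controls=6,
        chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000)),
        gwas_n_loci=20, seed=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    annotation = generate_annotation(small_config)
    layout = generate_probe_layout(annotation, small_config.probe_spacing)
    truth = simulate_truth(annotation, small_config)
    signals = simulate_signals(annotation, layout, truth, small_config)
    return annotation, layout, truth, signals


def random_intervals(rng: np.random.Generator, n: int, genome: int = 200,
                     chroms=("chr1",), max_len: int = 30) -> pd.DataFrame:
    """Tiny random interval frame for oracle comparisons."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, genome - 1, size=n)
    length = rng.integers(1, max_len + 1, size=n)
    end = np.minimum(start + length, genome)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": end})


def coverage_mask(df: pd.DataFrame, genome: int, chrom: str) -> np.ndarray:
    """Per-base boolean oracle for a track on one chromosome."""
    mask = np.zeros(genome, dtype=bool)
    for _, row in df[df["chrom"] == chrom].iterrows():
        mask[row["start"]:row["end"]] = True
    return mask
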