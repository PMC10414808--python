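import numpy as np
import pytest

from ycharter.simulate import (
    SimulationConfig,
    SimulationTruth,
    simulate_coverage,
    simulate_genome,
    simulate_line_variants,
)


def small_config(**overrides) -> SimulationConfig:
    """A trimmed study design that keeps every pipeline stage fast.

    All non-short contigs stay above the 100 kb length gate so coverage
    calls behave as in the default design.
    """
    base = dict(
        n_autosomes=4,
        autosome_len=120_000,
        x_len=110_000,
        y_len=110_000,
        n_short_contigs=1,
        short_len=40_000,
        n_gametologs=3,
        n_paralogs=3,
        n_both=2,
        n_y_novel=1,
        n_short_homologs=1,
        n_amplicon_families=2,
        copies_per_family=(2, 3),
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """Trimmed genome + coverage + variants with its planted truth."""
    cfg = small_config()
    assembly, annotation, truth = simulate_genome(cfg)
    coverage = simulate_coverage(truth, cfg)
    records = simulate_line_variants(truth, cfg, assembly)
    return dict(cfg=cfg, assembly=assembly, annotation=annotation, truth=truth,
                coverage=coverage, records=records)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Default-scale design with zero depth noise and no mismapping."""
    cfg = SimulationConfig(seed=11, depth_dispersion=0.0, mismap_epsilon=0.0,
                           depth_outlier_fraction=0.0)
    assembly, annotation, truth = simulate_genome(cfg)
    coverage = simulate_coverage(truth, cfg)
    records = simulate_line_variants(truth, cfg, assembly)
    return dict(cfg=cfg, assembly=assembly, annotation=annotation, truth=truth,
                coverage=coverage, records=records)


def coverage_only_truth(n_autosomes: int = 6) -> SimulationTruth:
    """Contig classes/lengths without sequence, for coverage-only studies."""
    classes = {f"A{i}": "A" for i in range(1, n_autosomes + 1)}
    classes |= {"X1": "X", "Y_S": "Y", "Y_L": "Y", "SHORT1": "SHORT"}
    lengths = {
        c: (250_000 if v == "A" else 150_000 if v == "X" else 170_000 if v == "Y" else 50_000)
        for c, v in classes.items()
    }
    return SimulationTruth(
        contig_classes=classes, contig_lengths=lengths,
        gene_origins={}, amplicon_families={}, candidate_copies={},
    )


def rng_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
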