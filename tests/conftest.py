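import numpy as np
import pytest

import tnscreen as tn


@pytest.fixture(scope="session")
def small_pool():
    """A 500-gene pool at saturating insertion density, 2% defective."""
    return tn.build_pool(
        n_genes=500, sites_per_gene=36, frac_defective=0.02, seed=11
    )


@pytest.fixture(scope="session")
def small_screen(small_pool):
    """Counts + manifest sampled from the small pool at moderate depth."""
    traj = tn.simulate_abundances(small_pool)
    counts, manifest = tn.sample_reads(traj, depth=500_000, seed=11)
    return counts, manifest


@pytest.fixture(scope="session")
def small_results(small_pool, small_screen):
    counts, manifest = small_screen
    return tn.run_fitness_pipeline(counts, manifest, small_pool.genes)


@pytest.fixture
def normal_fit():
    """Fit to a clean Gaussian sample, reused by classification tests."""
    rng = np.random.default_rng(5)
    return tn.fit_normal_to_histogram(rng.normal(8.0, 1.2, 5000), 0.25)
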