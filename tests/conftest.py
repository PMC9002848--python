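import numpy as np
import pytest

from floraltime import (CountMatrix, NormalizationFactors, SampleInfo,
                        SimulationConfig, simulate)

TIMEPOINTS = (10, 15, 19, 29)


def make_samples(n_reps: int = 3, timepoints=TIMEPOINTS) -> list[SampleInfo]:
    return [SampleInfo(sample_id=f"T{t}_R{r}", timepoint_dap=t, replicate=r)
            for t in timepoints for r in range(1, n_reps + 1)]


def make_count_matrix(counts: np.ndarray, n_reps: int = 3,
                      timepoints=TIMEPOINTS) -> CountMatrix:
    counts = np.asarray(counts)
    return CountMatrix(gene_ids=[f"g{i}" for i in range(counts.shape[0])],
                       counts=counts, samples=make_samples(n_reps, timepoints))


def unit_factors(cm: CountMatrix) -> NormalizationFactors:
    return NormalizationFactors(sample_ids=cm.sample_ids,
                                library_sizes=cm.library_sizes,
                                tmm_factors=np.ones(cm.n_samples))


def nb_counts(rng, mu, phi):
    """NB(mu, phi) draws (gamma-Poisson mixture)."""
    if phi <= 0:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / phi, np.asarray(mu) * phi))


def null_matrix(seed: int, n_genes: int = 2000, n_reps: int = 3, phi: float = 0.1,
                planted_log2fc: float = 0.0, n_planted: int = 0,
                baseline_mean: float = 50.0) -> tuple[CountMatrix, np.ndarray]:
    """Equal-mean NB matrix over 4 groups, optionally with the first
    ``n_planted`` genes following a monotone log-linear trend of total
    ``planted_log2fc`` from a baseline mean count of ``baseline_mean``.

    Returns the matrix and the boolean planted mask.
    """
    rng = np.random.default_rng(seed)
    lib = rng.uniform(0.8, 1.2, 4 * n_reps)  # relative depth; offsets absorb it
    base = np.exp(rng.normal(np.log(50.0), 1.0, n_genes))
    planted = np.zeros(n_genes, dtype=bool)
    planted[:n_planted] = True
    base[planted] = baseline_mean
    frac = np.repeat(np.arange(4) / 3.0, n_reps)
    mu = base[:, None] * lib[None, :]
    mu[planted] = baseline_mean * 2.0 ** (planted_log2fc * frac)[None, :] * lib[None, :]
    y = nb_counts(rng, mu, phi)
    return make_count_matrix(y, n_reps=n_reps), planted


@pytest.fixture(scope="session")
def small_study():
    """One 1200-gene synthetic study shared across read-only tests."""
    return simulate(SimulationConfig(n_genes=1200, seed=42))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_study):
    from floraltime import write_study
    out = tmp_path_factory.mktemp("study")
    paths = write_study(small_study, out)
    return paths
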