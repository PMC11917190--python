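import numpy as np
import pytest

from cre4c.restriction_map import digest, filter_fragments
from cre4c.synthetic_data import SimConfig, simulate_4c_counts, simulate_genome

PLANTS = ((250_000, 10, 6.0), (800_000, 10, 6.0), (1_050_000, 10, 6.0))


def simulate_bundle(seed: int, plants=()):
    """Genome -> fragment map -> replicate profiles for one simulator seed."""
    cfg = SimConfig(seed=seed, planted_interactions=plants)
    genome = simulate_genome(cfg)
    fmap = filter_fragments(digest(genome), cfg.viewpoint_pos)
    profiles, truth = simulate_4c_counts(fmap, cfg)
    return cfg, genome, fmap, profiles, truth


@pytest.fixture(scope="session")
def background_bundle():
    """Background-only simulation (no planted interactions)."""
    return simulate_bundle(11)


@pytest.fixture(scope="session")
def planted_bundle():
    """Simulation with three fold-6 planted interactions."""
    return simulate_bundle(42, PLANTS)


def make_toy_map(n_units: int = 60, spacer: int = 96, viewpoint: int | None = None,
                 exclusion: int = 0):
    """Small regular NlaIII/DpnII map: alternating valid fragments of ~100 bp.

    The genome alternates A-spacers with CATG and GATC motifs, giving
    2 * n_units valid fragments (NlaIII-DpnII and DpnII-NlaIII alternating).
    """
    unit = "A" * spacer + "CATG" + "A" * spacer + "GATC"
    genome = unit * n_units + "A" * spacer
    fmap = digest(genome)
    if viewpoint is None:
        viewpoint = len(genome) // 2
    return genome, filter_fragments(fmap, viewpoint, exclusion=exclusion)


@pytest.fixture
def toy_map():
    return make_toy_map


def isotonic_decreasing_oracle(y: np.ndarray) -> np.ndarray:
    """Bounded-variable least-squares oracle for non-increasing isotonic fit.

    Parameterizes x_i = c + sum_{j>=i} d_j with d_j >= 0 and solves the QP
    with scipy's lsq_linear — independent of the PAVA path under test.
    """
    from scipy.optimize import lsq_linear

    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 1:
        return y.copy()
    A = np.zeros((n, n))
    A[:, 0] = 1.0
    for j in range(1, n):
        A[: j, j] = 1.0  # d_j = x_{j-1} - x_j contributes to x_0..x_{j-1}
    lb = np.full(n, 0.0)
    lb[0] = -np.inf
    res = lsq_linear(A, y, bounds=(lb, np.full(n, np.inf)), tol=1e-14)
    return A @ res.x


def mirror_fit(y, **kwargs):
    """Fit a non-increasing background to one test vector via both arms.

    fit_monotonic_background requires two arms; the vector is mirrored so
    each arm sees the same sequence, and the downstream fit is returned.
    """
    from cre4c.interaction_caller import fit_monotonic_background

    y = np.asarray(y, dtype=float)
    n = len(y)
    d = np.arange(1, n + 1) * 10
    distances = np.concatenate([-d[::-1], d])
    values = np.concatenate([y[::-1], y])
    fit = fit_monotonic_background(values, distances, min_points=1, **kwargs)
    return fit.fitted[n:], fit
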