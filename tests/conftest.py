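import numpy as np
import pytest

from edq import Scenario, TriangularDist, bundled_scenario_path, load_scenario


@pytest.fixture(scope="session")
def baseline() -> Scenario:
    """Bundled hospital baseline: CTAS arrival mix, 20 ED / 125 IU beds."""
    return load_scenario(bundled_scenario_path())


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """A compact two-class system convenient for exact cross-checks."""
    return Scenario(
        arrival_rates=(0.5, 0.5),
        lambda_direct=0.0,
        transfer_fraction=0.0,
        ed_service=TriangularDist(0.5, 1.0, 1.5),
        iu_los=TriangularDist(24.0, 96.0, 168.0),
        c1=2,
        c2=10,
    )


def mc_mean_min(dist: TriangularDist, c2: int, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of E[min of c2 draws]."""
    rng = np.random.default_rng(seed)
    chunk = max(1, min(n, 20_000_000 // max(c2, 1)))
    mins = np.empty(n)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        draws = rng.triangular(dist.lower, dist.mode, dist.upper, size=(m, c2))
        mins[done:done + m] = draws.min(axis=1)
        done += m
    return float(mins.mean()), float(mins.std(ddof=1) / np.sqrt(n))
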