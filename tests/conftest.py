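import numpy as np
import pandas as pd
import pytest


def tabular_a(sire, dam):
    """Brute-force numerator relationship matrix by the recursive
    a(i, j) table (parents precede offspring; -1 = unknown)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            aij = 0.5 * (
                (A[j, s] if s >= 0 else 0.0) + (A[j, d] if d >= 0 else 0.0)
            )
            A[i, j] = A[j, i] = aij
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def random_pedigree_df(n, rng, p_unknown=0.2):
    """A random valid pedigree DataFrame (parents from earlier animals)."""
    ids = [f"A{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 2 or rng.random() < p_unknown:
            sires.append("0")
        else:
            sires.append(ids[rng.integers(0, i)])
        if i < 2 or rng.random() < p_unknown:
            dams.append("0")
        else:
            d = ids[rng.integers(0, i)]
            while d == sires[-1]:
                d = ids[rng.integers(0, i)]
            dams.append(d)
    return pd.DataFrame({"animal": ids, "sire": sires, "dam": dams})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def trio_df():
    """Two unrelated founders and their offspring."""
    return pd.DataFrame(
        {"animal": ["s", "d", "x"], "sire": ["0", "0", "s"],
         "dam": ["0", "0", "d"]}
    )


@pytest.fixture
def toy_records_df():
    """Minimal valid records covering 2 years, 2 months, 2 ewes."""
    return pd.DataFrame(
        {
            "ewe": ["e1", "e1", "e2"],
            "year": [2001, 2002, 2001],
            "month": ["Sep", "Oct", "9"],
            "parity": [1, 2, 1],
            "litter_size": [1, 2, 3],
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated conventional flock, reused across tests."""
    import parityrrm as prm

    scen = prm.line_scenario("conventional", n_ewes=80, seed=5)
    return prm.simulate_dataset(scen)
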