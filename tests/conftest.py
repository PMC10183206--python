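import numpy as np
import pandas as pd
import pytest

from flocknet import ArrivalParams, SimConfig
from flocknet.simulate import simulate_population, simulate_visits


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated population with its visit stream."""
    sim = SimConfig(n_individuals=30, n_flocks=3,
                    event_windows=[("2015-11-01", "2015-11-15")],
                    arrivals_per_flock_per_day=8.0, seed=42)
    individuals, pedigree, truth = simulate_population(sim)
    visits = simulate_visits(individuals, truth, sim)
    return {"config": sim, "individuals": individuals, "pedigree": pedigree,
            "truth": truth, "visits": visits}


@pytest.fixture()
def params():
    return ArrivalParams()


def make_arrivals(times_by_bird: dict, label: str = "w0") -> pd.DataFrame:
    """ArrivalEventTable from {bird: [t, ...]} (bout_end == arrival)."""
    rows = [(b, float(t), float(t), label)
            for b, ts in times_by_bird.items() for t in ts]
    return pd.DataFrame(rows, columns=["individual_id", "arrival_time",
                                       "bout_end", "window_label"]) \
        .sort_values("arrival_time", kind="mergesort").reset_index(drop=True)


def make_visits(times_by_bird: dict) -> pd.DataFrame:
    rows = [(int(t), b, "feeder1")
            for b, ts in times_by_bird.items() for t in ts]
    return pd.DataFrame(rows, columns=["timestamp", "tag_id", "antenna_id"]) \
        .sort_values(["timestamp", "tag_id"], kind="mergesort") \
        .reset_index(drop=True)


def brute_force_dyad_counts(arrivals: pd.DataFrame, delta_t: float) -> dict:
    """Independent O(n^2) all-pairs greedy matcher.

    Enumerates every cross-individual arrival pair within delta_t,
    sorts candidates by (earlier time, later time, ids), and accepts
    greedily under the one-match-per-partner rule.  Deliberately
    different in structure from the production two-pointer matcher.
    """
    recs = list(arrivals[["individual_id", "arrival_time"]]
                .itertuples(index=False, name=None))
    cands = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            (a, ta), (b, tb) = recs[i], recs[j]
            if a != b and abs(ta - tb) <= delta_t:
                lo, hi = sorted((ta, tb))
                cands.append((lo, hi, min(a, b), max(a, b), i, j))
    cands.sort()
    used = set()  # (arrival index, partner id)
    counts: dict = {}
    for lo, hi, a, b, i, j in cands:
        if (i, recs[j][0]) in used or (j, recs[i][0]) in used:
            continue
        used.add((i, recs[j][0]))
        used.add((j, recs[i][0]))
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def random_arrival_stream(rng: np.random.Generator, n_max: int = 200):
    n_birds = int(rng.integers(2, 12))
    n = int(rng.integers(2, n_max + 1))
    birds = [f"B{k}" for k in rng.integers(0, n_birds, size=n)]
    times = np.sort(rng.integers(0, 5000, size=n)).astype(float)
    return pd.DataFrame({"individual_id": birds, "arrival_time": times,
                         "bout_end": times, "window_label": "w"})
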