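"""Arrival inference: from detection streams to dyadic association counts.

Three association definitions are implemented over the same feeder
stream:

* ``arrival_time`` — two birds are associated when their *arrivals*
  fall within ``delta_t`` seconds of each other (inclusive), where an
  arrival is a (re)appearance after an absence strictly greater than
  ``delta_i`` seconds.  Dyadic and deliberately non-transitive: A-B and
  B-C do not imply A-C.  Defaults delta_t=150 s, delta_i=300 s.
* ``gambit_of_group`` — single-linkage clustering of arrivals in time;
  every within-group dyad is associated (classic gambit of the group,
  which overestimates associations at a busy feeder).
* ``time_window_overlap`` — birds whose presence bouts, extended by
  delta_t, overlap in time; produces chain-like structures under
  near-constant visitation.

Counting conventions: each arrival can be matched to at most one
arrival of a given partner (greedy one-to-one in time order), so a dyad
accumulates at most min(n_a, n_b) co-arrivals per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArrivalParams

logger = logging.getLogger("flocknet.arrivals")

ARRIVAL_COLUMNS = ["individual_id", "arrival_time", "bout_end", "window_label"]

__all__ = [
    "DyadCounts", "detect_arrivals", "associate_arrivals", "gambit_of_group",
    "time_window_overlap", "slice_windows", "greedy_match_sorted",
]


@dataclass
class DyadCounts:
    """Symmetric dyadic co-occurrence counts for one window.

    ``x``: unordered dyad (a < b) -> co-arrival count;
    ``n``: individual -> total arrivals (sampling effort);
    ``method``: which association definition produced the counts.
    """

    x: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    method: str = "arrival_time"
    window_label: str | None = None

    def get(self, a, b) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.x.get(key, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, c) for (a, b), c in sorted(self.x.items())]
        return pd.DataFrame(rows, columns=["individual_a", "individual_b",
                                           "x_ab"])

    def validate(self) -> None:
        for (a, b), c in self.x.items():
            if c < 0:
                raise ValueError(f"negative dyad count for {(a, b)}")
            if c > min(self.n.get(a, 0), self.n.get(b, 0)):
                raise ValueError(
                    f"dyad count {c} for {(a, b)} exceeds min arrivals"
                )


def detect_arrivals(visits: pd.DataFrame, params: ArrivalParams | None = None,
                    window_label: str | None = None) -> pd.DataFrame:
    """Partition each bird's detections into bouts and extract arrivals.

    A detection starts a new bout iff its gap from the bird's previous
    detection strictly exceeds ``delta_i``; the bout's arrival_time is
    its first detection and bout_end its last.  Input must be sorted by
    timestamp.
    """
    params = params or ArrivalParams()
    if visits.empty:
        return pd.DataFrame(columns=ARRIVAL_COLUMNS)
    ts = visits["timestamp"].to_numpy()
    if np.any(np.diff(ts) < 0):
        raise ValueError("visit log must be sorted by timestamp")
    rows = []
    for bird, g in visits.groupby("tag_id", sort=True):
        t = g["timestamp"].to_numpy(dtype=float)
        new_bout = np.empty(len(t), dtype=bool)
        new_bout[0] = True
        new_bout[1:] = np.diff(t) > params.delta_i
        starts = np.flatnonzero(new_bout)
        ends = np.append(starts[1:], len(t)) - 1
        for s, e in zip(starts, ends):
            rows.append((bird, t[s], t[e]))
    out = pd.DataFrame(rows, columns=["individual_id", "arrival_time",
                                      "bout_end"])
    out["window_label"] = window_label
    return out.sort_values(["arrival_time", "individual_id"],
                           kind="mergesort").reset_index(drop=True)


def greedy_match_sorted(ta: np.ndarray, tb: np.ndarray,
                        delta_t: float) -> int:
    """Greedy one-to-one matching count between two sorted time arrays.

    Pairs with \\|ta_i - tb_j\\| <= delta_t are matched greedily in time
    order (each accepted pair consumes both arrivals); equivalent to
    accepting candidate pairs sorted by (earlier, later) time.
    """
    i = j = matched = 0
    while i < len(ta) and j < len(tb):
        if abs(ta[i] - tb[j]) <= delta_t:
            matched += 1
            i += 1
            j += 1
        elif ta[i] < tb[j]:
            i += 1
        else:
            j += 1
    return matched


def _arrival_arrays(arrivals: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        bird: np.sort(g["arrival_time"].to_numpy(dtype=float))
        for bird, g in arrivals.groupby("individual_id", sort=True)
    }


def _candidate_dyads(arrivals: pd.DataFrame, delta_t: float) -> set:
    """Unordered dyads with at least one arrival pair within delta_t."""
    srt = arrivals.sort_values("arrival_time", kind="mergesort")
    t = srt["arrival_time"].to_numpy(dtype=float)
    ids = srt["individual_id"].to_numpy()
    dyads = set()
    j_hi = 0
    for i in range(len(t)):
        if j_hi < i + 1:
            j_hi = i + 1
        while j_hi < len(t) and t[j_hi] - t[i] <= delta_t:
            j_hi += 1
        for j in range(i + 1, j_hi):
            if ids[i] != ids[j]:
                a, b = sorted((ids[i], ids[j]))
                dyads.add((a, b))
    return dyads


def associate_arrivals(arrivals: pd.DataFrame,
                       params: ArrivalParams | None = None,
                       dyad_counting: str = "per_event") -> DyadCounts:
    """Count co-arrivals per unordered dyad under the arrival-time rule.

    x_ab = number of greedily matched arrival pairs (one of a, one of
    b) with \\|t_a - t_b\\| <= delta_t; n_a = total arrivals of a.
    ``dyad_counting='binary_per_window'`` caps every x_ab at 1.
    """
    params = params or ArrivalParams()
    if dyad_counting not in ("per_event", "binary_per_window"):
        raise ValueError(f"unknown dyad_counting {dyad_counting!r}")
    label = arrivals["window_label"].iloc[0] if len(arrivals) else None
    counts = DyadCounts(method="arrival_time", window_label=label)
    if arrivals.empty:
        return counts
    per_bird = _arrival_arrays(arrivals)
    counts.n = {bird: len(t) for bird, t in per_bird.items()}
    for a, b in _candidate_dyads(arrivals, params.delta_t):
        m = greedy_match_sorted(per_bird[a], per_bird[b], params.delta_t)
        if m:
            counts.x[(a, b)] = 1 if dyad_counting == "binary_per_window" else m
    return counts


def gambit_of_group(arrivals: pd.DataFrame, gap: float) -> DyadCounts:
    """Gambit-of-the-group counts via single-linkage temporal clustering.

    Arrivals are clustered with threshold ``gap`` (a new group starts
    where the inter-arrival gap exceeds it); every unordered pair of
    distinct individuals in a group counts one association.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    label = arrivals["window_label"].iloc[0] if len(arrivals) else None
    counts = DyadCounts(method="gambit_of_group", window_label=label)
    if arrivals.empty:
        return counts
    srt = arrivals.sort_values("arrival_time", kind="mergesort")
    t = srt["arrival_time"].to_numpy(dtype=float)
    ids = srt["individual_id"].to_numpy()
    counts.n = dict(srt["individual_id"].value_counts())
    breaks = np.flatnonzero(np.diff(t) > gap) + 1
    for group in np.split(ids, breaks):
        members = sorted(set(group))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                key = (members[i], members[j])
                counts.x[key] = counts.x.get(key, 0) + 1
    return counts


def time_window_overlap(visits: pd.DataFrame,
                        params: ArrivalParams | None = None) -> DyadCounts:
    """Associations from overlapping presence bouts extended by delta_t.

    A bird is 'present' over [arrival, bout_end + delta_t]; a dyad is
    counted whenever two such intervals intersect, with greedy
    one-to-one matching of bouts so x_ab <= min(n_a, n_b).
    """
    params = params or ArrivalParams()
    arrivals = detect_arrivals(visits, params)
    counts = DyadCounts(method="time_window_overlap",
                        window_label=arrivals["window_label"].iloc[0]
                        if len(arrivals) else None)
    if arrivals.empty:
        return counts
    intervals = {
        bird: np.column_stack([
            g["arrival_time"].to_numpy(dtype=float),
            g["bout_end"].to_numpy(dtype=float) + params.delta_t,
        ])
        for bird, g in arrivals.groupby("individual_id", sort=True)
    }
    counts.n = {bird: len(v) for bird, v in intervals.items()}
    birds = sorted(intervals)
    for ai in range(len(birds)):
        for bi in range(ai + 1, len(birds)):
            a, b = birds[ai], birds[bi]
            ia, ib = intervals[a], intervals[b]
            i = j = m = 0
            while i < len(ia) and j < len(ib):
                if ia[i, 0] <= ib[j, 1] and ib[j, 0] <= ia[i, 1]:
                    m += 1
                    i += 1
                    j += 1
                elif ia[i, 1] < ib[j, 1]:
                    i += 1
                else:
                    j += 1
            if m:
                counts.x[(a, b)] = m
    return counts


def slice_windows(visits: pd.DataFrame, event_windows,
                  week_length: int = 7) -> list[dict]:
    """Assign detections to events and week blocks.

    Weeks are half-open ``week_length``-day blocks anchored at each
    event's start; detections outside every event are dropped with a
    logged count.  Empty weeks are retained (so downstream models see
    missing weeks as absent rows, not silently skipped labels).

    Returns a list of dicts with keys event (start-date label), week
    (0-based int), window_label, and visits (a VisitLog slice).
    """
    out = []
    assigned = np.zeros(len(visits), dtype=bool)
    ts = visits["timestamp"].to_numpy() if len(visits) else np.array([])
    starts = [w[0] for w in event_windows]
    if starts != sorted(starts):
        raise ValueError("event windows must be ordered")
    for (start, end) in event_windows:
        t0 = int(pd.Timestamp(start).timestamp())
        t1 = int(pd.Timestamp(end).timestamp())
        if t1 <= t0:
            raise ValueError(f"event window {start}..{end} inverted")
        n_weeks = int(np.ceil((t1 - t0) / (week_length * 86_400)))
        in_event = (ts >= t0) & (ts < t1) if len(ts) else np.array([], bool)
        assigned |= in_event
        week_of = ((ts - t0) // (week_length * 86_400)).astype(int) \
            if len(ts) else np.array([], int)
        for w in range(n_weeks):
            mask = in_event & (week_of == w)
            out.append({
                "event": start,
                "week": w,
                "window_label": f"{start}:W{w:02d}",
                "visits": visits.loc[mask].reset_index(drop=True),
            })
    dropped = int(len(visits) - assigned.sum())
    if dropped:
        logger.info("dropped %d detections outside all event windows", dropped)
    return out
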