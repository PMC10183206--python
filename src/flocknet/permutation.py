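"""Node-permutation null models, Elo dominance ratings, and checks.

The null model shuffles bird identities across the observed arrival
events (within event or within week), exactly conserving the multiset
of arrival times, the multiset of identities, and each bird's arrival
count, while breaking any individual-level link between network
position and fitness.  Null networks are rebuilt per permutation and
summarized by per-individual modal centralities (exact mode for
integer measures, half-sample mode for continuous ones).

Elo ratings summarize dominance from chronological dyadic
interactions: the winner gains k*(1 - p_win) with
p_win = 1 / (1 + 10^((R_loser - R_winner)/400)); total rating is
conserved (zero-sum).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .arrivals import associate_arrivals
from .config import ArrivalParams, EloConfig, PermutationConfig
from .mcmc import half_sample_mode
from .networks import MEASURES, build_network, compute_centralities, compute_sri

logger = logging.getLogger("flocknet.permutation")

__all__ = ["permute_identities", "null_centrality", "elo_ratings",
           "dominance_centrality_correlation"]

INTEGER_MEASURES = {"degree", "opposite_sex_degree"}


def _scope_keys(arrivals: pd.DataFrame, scope: str) -> pd.Series:
    labels = arrivals["window_label"].fillna("")
    if scope == "within_week":
        return labels
    return labels.str.split(":").str[0]


def permute_identities(arrivals: pd.DataFrame,
                       config: PermutationConfig | None = None,
                       rng: np.random.Generator | None = None
                       ) -> pd.DataFrame:
    """One uniform random reassignment of identities to arrival times.

    Within each scope group, the identity column is permuted across
    rows; arrival times, bout ends and window labels stay put, so the
    arrival-time multiset and every bird's arrival count are exactly
    conserved.
    """
    if arrivals.empty:
        return arrivals.copy()
    config = config or PermutationConfig()
    rng = rng or np.random.default_rng(config.seed)
    out = arrivals.reset_index(drop=True).copy()
    for _, idx in out.groupby(_scope_keys(out, config.scope)).groups.items():
        idx = np.asarray(idx)
        out.loc[idx, "individual_id"] = \
            out.loc[idx, "individual_id"].to_numpy()[rng.permutation(len(idx))]
    return out


def null_centrality(arrivals: pd.DataFrame, params: ArrivalParams,
                    config: PermutationConfig,
                    individuals: pd.DataFrame) -> pd.DataFrame:
    """Modal per-individual centralities across permuted networks.

    For each of ``config.n_permutations`` permutations the full network
    pipeline is rerun (association counts, SRI, weighted network and
    opposite-sex sub-graph, all four measures).  Integer measures take
    their exact mode across permutations; continuous measures the
    half-sample mode.  Birds absent from every permuted network get no
    row (logged).
    """
    rng = np.random.default_rng(config.seed)
    samples: dict[str, dict[str, list]] = {}
    for _ in range(config.n_permutations):
        perm = permute_identities(arrivals, config, rng)
        counts = associate_arrivals(perm, params)
        sri = compute_sri(counts)
        net = build_network(sri, individuals)
        if net.number_of_nodes() == 0:
            continue
        bip = build_network(sri, individuals, bipartite=True)
        cent = compute_centralities(net, bip)
        for _, r in cent.iterrows():
            d = samples.setdefault(r["individual_id"],
                                   {m: [] for m in MEASURES})
            for m in MEASURES:
                d[m].append(r[m])
    absent = set(arrivals["individual_id"]) - set(samples)
    if absent:
        logger.info("%d individuals absent from all permuted networks",
                    len(absent))
    rows = []
    for bird in sorted(samples):
        vals = samples[bird]
        row = {"individual_id": bird}
        for m in MEASURES:
            v = np.asarray(vals[m], dtype=float)
            if m in INTEGER_MEASURES:
                ints, counts_ = np.unique(v.astype(int), return_counts=True)
                row[m] = int(ints[int(np.argmax(counts_))])
            else:
                row[m] = half_sample_mode(v)
        rows.append(row)
    return pd.DataFrame(rows)


def elo_ratings(interactions: pd.DataFrame,
                config: EloConfig | None = None,
                initial_ratings: dict | None = None) -> pd.Series:
    """Sequential Elo ratings from a chronological winner/loser log.

    Rows with winner == loser are rejected (logged); birds never seen
    keep no rating (absent from the output).  Ratings are zero-sum
    around the start rating: their total equals n_birds * start_rating
    after every update.  ``initial_ratings`` seeds specific birds with
    non-default starting scores (e.g. carrying ratings across events).
    """
    config = config or EloConfig()
    ratings: dict[str, float] = dict(initial_ratings or {})
    bad = 0
    log = interactions.sort_values("timestamp", kind="mergesort")
    for _, r in log.iterrows():
        w, l = r["winner_id"], r["loser_id"]
        if w == l:
            bad += 1
            continue
        rw = ratings.setdefault(w, config.start_rating)
        rl = ratings.setdefault(l, config.start_rating)
        p_win = 1.0 / (1.0 + 10.0 ** ((rl - rw) / 400.0))
        delta = config.k_factor * (1.0 - p_win)
        ratings[w] = rw + delta
        ratings[l] = rl - delta
    if bad:
        logger.warning("rejected %d self-interaction rows", bad)
    return pd.Series(ratings, name="elo").sort_index()


def dominance_centrality_correlation(elo: pd.Series,
                                     centrality: pd.DataFrame,
                                     n_permutations: int = 10_000,
                                     seed: int = 0) -> pd.DataFrame:
    """Spearman rank correlation of dominance with each observed measure.

    Returns rho and a two-sided permutation p-value per measure
    (identities shuffled against ratings).  Fewer than 3 shared
    individuals makes the correlation undefined (NaN row, reported).
    Null-model (randomized) centralities must not be passed here.
    """
    rng = np.random.default_rng(seed)
    merged = centrality.merge(elo.rename("elo"), left_on="individual_id",
                              right_index=True)
    rows = []
    for m in MEASURES:
        sub = merged.dropna(subset=[m, "elo"])
        if len(sub) < 3:
            rows.append((m, np.nan, np.nan, len(sub)))
            continue
        x = sub["elo"].to_numpy(dtype=float)
        y = sub[m].to_numpy(dtype=float)
        rho = stats.spearmanr(x, y).statistic
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            null[k] = np.corrcoef(xr[rng.permutation(len(xr))], yr)[0, 1]
        p = (1.0 + np.sum(np.abs(null) >= abs(rho))) / (n_permutations + 1.0)
        rows.append((m, float(rho), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["measure", "rho", "p_value", "n"])
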