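"""Synthetic closed-population generator.

Produces everything the downstream analysis consumes — an individual
table, a multi-generational pedigree, latent ground truth, a visit
stream with flock-structured arrivals, and sociality-coupled fitness —
so that the full chain (arrival inference, networks, de-lifing, mixed
models, null models) is testable without field data.

The generative model, briefly: a founding population with a 3-year
cohort structure breeds in monogamous pairs each year (Poisson numbers
of surviving offspring), individuals die with a constant annual hazard,
and every individual belongs to one latent flock.  Flocks arrive at a
single feeder as a Poisson process within daily operating hours; a bird
joins a given flock arrival with a probability governed by its latent
sociality (a weekly realization of a stable individual propensity with
a target intraclass correlation), arriving with its flock up to Gaussian
jitter, or solo at a random time otherwise.  Each arrival spawns a short
bout of antenna detections, and re-arrivals of the same bird are
separated by more than the absence threshold used downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, FitnessCouplingConfig, SimConfig

ANTENNA_ID = "feeder1"

__all__ = ["simulate_population", "simulate_visits", "simulate_fitness",
           "simulate_weekly_trait"]


class SimulationError(RuntimeError):
    pass


def _event_year(start_date: str) -> int:
    return int(start_date[:4])


def _empty_tables():
    individuals = pd.DataFrame(
        columns=["individual_id", "tag_id", "sex", "cohort", "death_year",
                 "first_tagged"]
    )
    pedigree = pd.DataFrame(columns=["individual_id", "sire_id", "dam_id", "cohort"])
    truth = pd.DataFrame(
        columns=["individual_id", "true_flock", "true_sociality", "true_icc"]
    )
    return individuals, pedigree, truth


def simulate_population(config: SimConfig):
    """Simulate a closed population with pedigree and latent ground truth.

    Returns ``(individuals, pedigree, truth)`` DataFrames.  Founders span
    the three cohorts before the first event year (so age terms are
    estimable); breeding then runs annually through two years past the
    last event, producing the recruits and grand-offspring the fitness
    stage needs.  Every non-founder's sire and dam are rows of the table
    (closed pedigree).
    """
    if config.n_individuals == 0:
        if config.allow_empty:
            return _empty_tables()
        raise ConfigError("n_individuals=0 requires allow_empty=True")

    rng = np.random.default_rng(config.seed)
    y0 = _event_year(config.event_windows[0][0])
    y_last = _event_year(config.event_windows[-1][1])
    breeding_years = range(y0 + 1, y_last + 3)
    hazard_p = 1.0 - config.annual_survival

    rows = []  # individual_id, sire, dam, sex, cohort, death_year

    def death_year_for(cohort: int, floor: int | None) -> int:
        # geometric lifetime with constant annual hazard; death_year is the
        # last calendar year alive.  floor forces survival through a year.
        d = cohort + int(rng.geometric(hazard_p)) - 1
        if floor is not None and d < floor:
            d = floor + int(rng.geometric(hazard_p)) - 1
        return d

    founder_cohorts = rng.integers(y0 - 3, y0, size=config.n_individuals)
    founder_sex = (rng.random(config.n_individuals) < config.sex_ratio).astype(int)
    for k in range(config.n_individuals):
        # founders are guaranteed alive in the first event year
        rows.append(
            [None, None, int(founder_sex[k]), int(founder_cohorts[k]),
             death_year_for(int(founder_cohorts[k]), y0)]
        )

    for year in breeding_years:
        males = [i for i, r in enumerate(rows)
                 if r[2] == 1 and r[3] < year and r[4] >= year]
        females = [i for i, r in enumerate(rows)
                   if r[2] == 0 and r[3] < year and r[4] >= year]
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females))
        n_off = rng.poisson(config.mean_offspring, size=n_pairs)
        for p in range(n_pairs):
            for _ in range(int(n_off[p])):
                sex = int(rng.random() < config.sex_ratio)
                rows.append([males[p], females[p], sex, year,
                             death_year_for(year, None)])

    n = len(rows)
    ids = [f"S{k:05d}" for k in range(n)]
    individuals = pd.DataFrame(
        {
            "individual_id": ids,
            "tag_id": ids,
            "sex": [r[2] for r in rows],
            "cohort": [r[3] for r in rows],
            "death_year": [r[4] for r in rows],
            "first_tagged": [f"{r[3]}-06-01" for r in rows],
        }
    )
    pedigree = pd.DataFrame(
        {
            "individual_id": ids,
            "sire_id": [None if r[0] is None else ids[r[0]] for r in rows],
            "dam_id": [None if r[1] is None else ids[r[1]] for r in rows],
            "cohort": [r[3] for r in rows],
        }
    )
    truth = pd.DataFrame(
        {
            "individual_id": ids,
            "true_flock": [f"F{int(f)}" for f in
                           rng.integers(0, config.n_flocks, size=n)],
            "true_sociality": rng.standard_normal(n),
            "true_icc": config.true_icc,
        }
    )
    return individuals, pedigree, truth


def simulate_visits(individuals: pd.DataFrame, truth: pd.DataFrame,
                    config: SimConfig) -> pd.DataFrame:
    """Simulate the RFID detection stream for every event window.

    Returns a VisitLog DataFrame (timestamp: int seconds since epoch,
    tag_id, antenna_id) sorted by timestamp.  All detections fall inside
    the event windows and daily operating hours; flock-mates arrive in
    temporal clusters with Gaussian jitter; per bird, consecutive bouts
    are separated by more than the 300 s absence criterion plus an
    exponential revisit gap.
    """
    if not len(config.event_windows):
        raise ConfigError("event_windows must be non-empty")
    missing = set(individuals["individual_id"]) - set(truth["individual_id"])
    if missing:
        raise SimulationError(
            f"individuals without truth records: {sorted(missing)[:5]}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    info = individuals.merge(truth, on="individual_id")
    icc = float(config.true_icc)
    day_sec = 86_400
    op_start = int(config.operating_hours[0] * 3600)
    op_end = int(config.operating_hours[1] * 3600)

    arrivals: dict[str, list[float]] = {i: [] for i in info["individual_id"]}

    for start, end in config.event_windows:
        t0 = int(pd.Timestamp(start).timestamp())
        t1 = int(pd.Timestamp(end).timestamp())
        n_days = max((t1 - t0) // day_sec, 0)
        year = _event_year(start)
        active = info[(info["cohort"] <= year) & (info["death_year"] >= year)]
        if active.empty:
            continue
        active = active.reset_index(drop=True)
        flocks = {f: g for f, g in active.groupby("true_flock")}
        # weekly latent propensity per bird: stable part + weekly noise,
        # mixed so that corr(week w, week w') = true_icc
        n_weeks = (n_days + 6) // 7
        noise = rng.standard_normal((max(n_weeks, 1), len(active)))
        s_week_all = (np.sqrt(icc) * active["true_sociality"].to_numpy()
                      + np.sqrt(1.0 - icc) * noise)
        p_attend_all = 1.0 / (1.0 + np.exp(
            -(config.attendance_logit_base
              + config.attendance_logit_scale * s_week_all)))
        conc = config.flock_membership_concentration
        if conc in (0.0, 1.0) or config.sociality_concentration_scale == 0:
            p_flock_all = np.full_like(s_week_all, conc)
        else:
            p_flock_all = 1.0 / (1.0 + np.exp(
                -(np.log(conc / (1.0 - conc))
                  + config.sociality_concentration_scale * s_week_all)))
        for day in range(n_days):
            week = day // 7
            day_t0 = t0 + day * day_sec
            for flock_id, members in flocks.items():
                midx = members.index.to_numpy()
                p_attend = p_attend_all[week, midx]
                p_flock = p_flock_all[week, midx]
                if config.fixed_daily_arrivals:
                    n_arr = int(round(config.arrivals_per_flock_per_day))
                else:
                    n_arr = rng.poisson(config.arrivals_per_flock_per_day)
                if n_arr == 0:
                    continue
                times = np.sort(rng.integers(op_start, op_end - 1, size=n_arr))
                for T in times:
                    joins = rng.random(len(members)) < p_attend
                    if not joins.any():
                        continue
                    with_flock = rng.random(len(members)) < p_flock
                    jitter = rng.normal(
                        0.0, config.within_flock_arrival_jitter_sd,
                        size=len(members))
                    solo_t = rng.integers(op_start, op_end - 1,
                                          size=len(members))
                    ts = np.where(with_flock, T + jitter, solo_t)
                    for bird, j, t in zip(members["individual_id"], joins, ts):
                        if j:
                            tt = min(max(float(t), op_start), op_end - 1)
                            arrivals[bird].append(day_t0 + tt)

    out_t, out_id = [], []
    for bird in sorted(arrivals):
        cand = sorted(arrivals[bird])
        prev_end = -np.inf
        for t in cand:
            gap = 301.0 + rng.exponential(config.revisit_gap_mean)
            if t < prev_end + gap:
                continue
            dur = rng.exponential(config.bout_length_mean)
            # clamp bout to the operating day it started in
            day_end = (int(t) // day_sec) * day_sec + op_end - 1
            bout_end = min(t + dur, day_end)
            n_mid = int(rng.poisson(2))
            det = [t, *np.sort(rng.uniform(t, bout_end, size=n_mid)), bout_end]
            for d in det:
                out_t.append(int(round(d)))
                out_id.append(bird)
            prev_end = bout_end

    visits = pd.DataFrame(
        {"timestamp": out_t, "tag_id": out_id, "antenna_id": ANTENNA_ID}
    )
    visits = visits.drop_duplicates().sort_values(
        ["timestamp", "tag_id"], kind="mergesort").reset_index(drop=True)
    return visits


def simulate_weekly_trait(n_individuals: int, n_weeks: int, icc: float,
                          seed: int = 0, mean: float = 0.0,
                          total_var: float = 1.0) -> pd.DataFrame:
    """Repeated weekly measurements with a known intraclass correlation.

    y_iw = mean + a_i + e_iw with Var(a) = icc * total_var and
    Var(e) = (1 - icc) * total_var; the substrate of repeatability
    parameter-recovery experiments.  Returns a long DataFrame with
    columns individual_id, week, value.
    """
    if not 0.0 <= icc <= 1.0:
        raise ConfigError("icc must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    a = rng.normal(0.0, np.sqrt(icc * total_var), size=n_individuals)
    e = rng.normal(0.0, np.sqrt((1.0 - icc) * total_var),
                   size=(n_individuals, n_weeks))
    y = mean + a[:, None] + e
    return pd.DataFrame(
        {
            "individual_id": np.repeat(
                [f"S{k:05d}" for k in range(n_individuals)], n_weeks),
            "week": np.tile(np.arange(n_weeks), n_individuals),
            "value": y.ravel(),
        }
    )


def simulate_fitness(individuals: pd.DataFrame, sociality,
                     coupling: FitnessCouplingConfig,
                     year: int | None = None) -> pd.DataFrame:
    """Draw fitness values coupled to a sociality covariate.

    ``sociality`` is a mapping/Series from individual_id to a real
    covariate c.  Under ``poisson_recruits`` the response is
    Poisson(exp(b0 + b1 c + b2 c^2 + b_sex sex + b_age age)); under
    ``gaussian_delifed`` it is the same linear predictor plus
    N(0, noise_sd) noise.  ``year`` sets the age reference (defaults to
    the year after the youngest cohort).
    """
    rng = np.random.default_rng(np.random.SeedSequence([coupling.seed, 2]))
    soc = pd.Series(sociality)
    idx = individuals.set_index("individual_id")
    ids = [i for i in idx.index if i in soc.index]
    if not ids:
        raise SimulationError("no individuals with sociality values")
    if year is None:
        year = int(idx.loc[ids, "cohort"].max()) + 1

    c = soc.loc[ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(c)):
        bad = np.asarray(ids)[~np.isfinite(c)][0]
        raise SimulationError(f"non-finite sociality for individual {bad}")
    sex = idx.loc[ids, "sex"].to_numpy(dtype=float)
    age = year - idx.loc[ids, "cohort"].to_numpy(dtype=float)

    eta = (coupling.baseline_log_rate
           + coupling.beta_linear * c
           + coupling.beta_quadratic * c ** 2
           + coupling.beta_sex * sex
           + coupling.beta_age * age)
    if not np.all(np.isfinite(eta)):
        bad = np.asarray(ids)[~np.isfinite(eta)][0]
        raise SimulationError(f"non-finite linear predictor for individual {bad}")

    if coupling.family == "poisson_recruits":
        if coupling.overdispersion_sd > 0:
            eta = eta + rng.normal(0.0, coupling.overdispersion_sd,
                                   size=len(eta))
        resp = rng.poisson(np.exp(eta)).astype(int)
        col = "annual_recruits"
    else:
        resp = eta + rng.normal(0.0, coupling.noise_sd, size=len(eta))
        col = "annual_delifed"

    return pd.DataFrame(
        {"individual_id": ids, "year": year, "sex": sex.astype(int),
         "age": age.astype(int), "sociality": c, col: resp}
    )
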