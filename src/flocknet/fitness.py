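"""Pedigree-based fitness: recruit counts and de-lifed fitness.

A *recruit* is an offspring that survived and itself produced genetic
offspring (the grand-offspring criterion, read off the pedigree).
*De-lifed fitness* p_ti is an individual's realized contribution to
population growth in breeding year t:

    p_ti = (xi_t(i) - w_t) / (N_t - 1)

where xi_t(i) counts the individual's surviving offspring at the end
of the breeding period (each shared between its two genetic parents
under the default offspring share of 0.5) plus 1 if the individual
itself survived to the next breeding period; N_t is the population
size at the April census and w_t = N_{t+1} / N_t the realized growth
ratio.  With share 0.5 and a fully censused closed population the
contributions sum to zero each year (the de-lifing identity), which
the tests exploit to localize bookkeeping errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("flocknet.fitness")

__all__ = ["identify_recruits", "annual_recruits", "lifetime_recruits",
           "build_census", "delifed_annual", "delifed_lifetime",
           "fitness_table"]


def identify_recruits(pedigree: pd.DataFrame) -> pd.Series:
    """Flag each individual that appears as sire or dam of >= 1 row.

    Stable under row order and idempotent: the flag depends only on the
    parent columns' value sets.
    """
    parents = set(pedigree["sire_id"].dropna()) | set(pedigree["dam_id"].dropna())
    flags = pedigree["individual_id"].isin(parents)
    flags.index = pedigree["individual_id"]
    flags.name = "is_recruit"
    return flags


def annual_recruits(pedigree: pd.DataFrame, individuals: pd.DataFrame,
                    year: int) -> pd.DataFrame:
    """Per-parent count of recruits born in breeding year ``year``.

    Exclusion rules: birds that did not survive to the breeding season
    (death before ``year``) or were not yet born adults (cohort >=
    ``year``) are absent rows, as are yearlings (age 1) with zero
    recruits.
    """
    span = (int(pedigree["cohort"].min()), int(pedigree["cohort"].max()))
    if not span[0] <= year <= span[1]:
        logger.warning("year %d outside pedigree span %s", year, span)
        return pd.DataFrame(columns=["individual_id", "year",
                                     "annual_recruits"])
    recruit = identify_recruits(pedigree)
    born = pedigree[pedigree["cohort"] == year]
    counts: dict[str, int] = {}
    for col in ("sire_id", "dam_id"):
        for parent, child in zip(born[col], born["individual_id"]):
            if pd.isna(parent):
                continue
            counts[parent] = counts.get(parent, 0) + int(recruit.get(child, False))
    idx = individuals.set_index("individual_id")
    rows = []
    for _, r in individuals.iterrows():
        i = r["individual_id"]
        cohort = int(r["cohort"])
        death = r.get("death_year")
        if cohort >= year:
            continue
        if pd.notna(death) and int(death) < year:
            continue  # did not survive to breed
        n = counts.get(i, 0)
        if year - cohort == 1 and n == 0:
            continue  # yearling with zero recruits
        rows.append((i, year, n))
    _ = idx
    return pd.DataFrame(rows, columns=["individual_id", "year",
                                       "annual_recruits"])


def lifetime_recruits(pedigree: pd.DataFrame, individuals: pd.DataFrame,
                      censor_year: int | None = None) -> pd.Series:
    """Total recruits per parent across the pedigree, censored at
    ``censor_year`` (offspring born later are not counted)."""
    recruit = identify_recruits(pedigree)
    ped = pedigree if censor_year is None else \
        pedigree[pedigree["cohort"] <= censor_year]
    counts = pd.Series(0, index=individuals["individual_id"], dtype=int,
                       name="lifetime_recruits")
    for col in ("sire_id", "dam_id"):
        for parent, child in zip(ped[col], ped["individual_id"]):
            if pd.notna(parent) and parent in counts.index:
                counts[parent] += int(recruit.get(child, False))
    return counts


def _alive_at_census(individuals: pd.DataFrame, year: int) -> pd.Series:
    """Alive on April 1 of ``year``: born before it, not yet dead.

    death_year is the last calendar year alive; an open (missing)
    death_year means alive through the end of the table's span.
    """
    death = individuals["death_year"]
    alive = (individuals["cohort"] < year) & (death.isna() | (death >= year))
    alive.index = individuals["individual_id"]
    return alive


def build_census(individuals: pd.DataFrame, years) -> pd.DataFrame:
    """CensusTable: N_t, N_{t+1} and growth ratio w_t per breeding year."""
    years = list(years)
    sizes = {y: int(_alive_at_census(individuals, y).sum())
             for y in years + [max(years) + 1]}
    rows = []
    for y in years:
        n_t, n_t1 = sizes[y], sizes[y + 1]
        if n_t < 1:
            raise ValueError(f"census year {y}: N_t = 0")
        rows.append((y, n_t, n_t1, n_t1 / n_t))
    return pd.DataFrame(rows, columns=["year", "N_t", "N_t1", "w_t"])


def delifed_annual(pedigree: pd.DataFrame, census: pd.DataFrame,
                   individuals: pd.DataFrame, year: int,
                   offspring_share: float = 0.5) -> pd.DataFrame:
    """Annual de-lifed fitness p_ti for every bird censused in ``year``.

    xi_t(i) = offspring_share * (offspring of i born in t that survived
    to the next census) + 1 if i itself survived; p_ti =
    (xi - w_t) / (N_t - 1).  ``offspring_share=0.5`` splits each
    offspring between its two genetic parents (the convention under
    which the contributions of a closed, fully censused population sum
    to zero); 1.0 credits each parent fully.
    """
    if offspring_share not in (0.5, 1.0):
        raise ValueError("offspring_share must be 0.5 or 1.0")
    row = census[census["year"] == year]
    if row.empty:
        raise ValueError(f"census has no year {year}")
    n_t, w_t = int(row["N_t"].iloc[0]), float(row["w_t"].iloc[0])
    if n_t <= 1:
        raise ZeroDivisionError(
            f"year {year}: N_t = {n_t}, de-lifing undefined (N_t - 1 = 0)")

    alive_t = _alive_at_census(individuals, year)
    alive_t1 = _alive_at_census(individuals, year + 1)
    born = pedigree[pedigree["cohort"] == year]
    surv_child = set(
        born.loc[[bool(alive_t1.get(c, False))
                  for c in born["individual_id"]], "individual_id"])
    n_surv_off: dict[str, float] = {}
    for col in ("sire_id", "dam_id"):
        for parent, child in zip(born[col], born["individual_id"]):
            if pd.notna(parent) and child in surv_child:
                n_surv_off[parent] = n_surv_off.get(parent, 0) + 1

    rows = []
    for i in alive_t.index[alive_t]:
        xi = offspring_share * n_surv_off.get(i, 0) \
            + (1.0 if alive_t1.get(i, False) else 0.0)
        rows.append((i, year, xi, (xi - w_t) / (n_t - 1)))
    return pd.DataFrame(rows, columns=["individual_id", "year", "xi", "p_ti"])


def delifed_lifetime(annual: pd.DataFrame) -> pd.Series:
    """Lifetime de-lifed fitness p_i = sum of an individual's p_ti."""
    s = annual.groupby("individual_id")["p_ti"].sum()
    s.name = "p_i"
    return s


def fitness_table(pedigree: pd.DataFrame, individuals: pd.DataFrame,
                  years, offspring_share: float = 0.5,
                  censor_year: int | None = None,
                  recruits_only: bool = False):
    """Joined annual and lifetime fitness tables over ``years``.

    Returns ``(annual, lifetime)``.  With ``recruits_only`` the output
    is filtered to birds that produced at least one recruit (the
    published convention for de-lifed fitness); computation itself is
    unchanged.
    """
    years = list(years)
    census = build_census(individuals, years)
    annual_parts = []
    for y in years:
        rec = annual_recruits(pedigree, individuals, y)
        dl = delifed_annual(pedigree, census, individuals, y, offspring_share)
        annual_parts.append(dl.merge(rec, on=["individual_id", "year"],
                                     how="left"))
    annual = pd.concat(annual_parts, ignore_index=True)
    life = delifed_lifetime(annual).to_frame()
    life["lifetime_recruits"] = lifetime_recruits(
        pedigree, individuals, censor_year).reindex(life.index).fillna(0) \
        .astype(int)
    life = life.reset_index()
    if recruits_only:
        keep = life.loc[life["lifetime_recruits"] > 0, "individual_id"]
        annual = annual[annual["individual_id"].isin(set(keep))]
        life = life[life["lifetime_recruits"] > 0]
    return annual.reset_index(drop=True), life.reset_index(drop=True)
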