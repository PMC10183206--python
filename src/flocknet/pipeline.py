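"""End-to-end orchestration: simulate/load -> arrivals -> networks ->
fitness -> repeatability -> selection -> null models, with a manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config hash, seed, package version and per-stage row
counts, including every dropped-record count (out-of-window
detections, excluded birds) — the filters where analyses silently
diverge.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .arrivals import associate_arrivals, detect_arrivals, slice_windows
from .config import RunConfig, to_yaml
from .fitness import fitness_table
from .models import (RepeatabilityModel, SelectionModel,
                     mean_center_within_year)
from .networks import (MEASURES, build_network, compute_centralities,
                       compute_sri, summarize_event)
from .permutation import null_centrality
from .simulate import simulate_population, simulate_visits

logger = logging.getLogger("flocknet.pipeline")

__all__ = ["run_pipeline", "event_centralities", "weekly_centralities",
           "build_selection_data"]


def _window_networks(visits_slice: pd.DataFrame, params, individuals,
                     window_label: str):
    arr = detect_arrivals(visits_slice, params, window_label=window_label)
    counts = associate_arrivals(arr, params)
    sri = compute_sri(counts)
    net = build_network(sri, individuals)
    if net.number_of_nodes() == 0:
        return arr, None, None, None
    bip = build_network(sri, individuals, bipartite=True)
    cent = compute_centralities(net, bip)
    return arr, net, bip, cent


def event_centralities(visits: pd.DataFrame, event_windows, params,
                       individuals: pd.DataFrame):
    """Per-event networks and centrality tables.

    Returns (centrality DataFrame with an ``event`` column, dict of
    event -> network, dict of event -> bipartite network, arrivals).
    """
    cents, nets, bips, arrs = [], {}, {}, []
    for start, end in event_windows:
        t0 = int(pd.Timestamp(start).timestamp())
        t1 = int(pd.Timestamp(end).timestamp())
        sl = visits[(visits["timestamp"] >= t0)
                    & (visits["timestamp"] < t1)].reset_index(drop=True)
        arr, net, bip, cent = _window_networks(sl, params, individuals, start)
        arrs.append(arr)
        if cent is None:
            continue
        cent = cent.assign(event=start)
        cents.append(cent)
        nets[start], bips[start] = net, bip
    cent_df = pd.concat(cents, ignore_index=True) if cents else \
        pd.DataFrame(columns=["individual_id", *MEASURES, "event"])
    arr_df = pd.concat(arrs, ignore_index=True) if arrs else pd.DataFrame()
    return cent_df, nets, bips, arr_df


def weekly_centralities(visits: pd.DataFrame, event_windows, params,
                        individuals: pd.DataFrame) -> pd.DataFrame:
    """Weekly centrality tables across all events (empty weeks skipped
    in output but logged, so models see them as absent rows)."""
    out = []
    for w in slice_windows(visits, event_windows):
        _, _, _, cent = _window_networks(
            w["visits"], params, individuals, w["window_label"])
        if cent is None:
            logger.info("week %s has no dyads", w["window_label"])
            continue
        out.append(cent.assign(event=w["event"], week=w["week"]))
    if not out:
        return pd.DataFrame(columns=["individual_id", *MEASURES, "event",
                                     "week", "window_label"])
    return pd.concat(out, ignore_index=True)


def build_selection_data(event_cent: pd.DataFrame,
                         annual_fit: pd.DataFrame,
                         lifetime_fit: pd.DataFrame,
                         individuals: pd.DataFrame,
                         censor_year: int | None = None):
    """Join centralities with fitness into model-ready tables.

    The breeding year following an event (event start year + 1) is the
    fitness year matched to that event's centralities.  Measures are
    mean-centered within year; for the lifetime table a bird observed
    in both events contributes the mean of its centered measures.
    Returns (annual_data, lifetime_data).
    """
    idx = individuals.set_index("individual_id")
    cent = event_cent.copy()
    cent["year"] = cent["event"].str[:4].astype(int) + 1
    cent = mean_center_within_year(cent, MEASURES)
    annual = cent.merge(annual_fit, on=["individual_id", "year"])
    annual["cohort"] = annual["individual_id"].map(idx["cohort"])
    annual["sex"] = annual["individual_id"].map(idx["sex"])
    annual["age"] = annual["year"] - annual["cohort"]

    centered_cols = [f"{m}_c" for m in MEASURES]
    life_cent = cent.groupby("individual_id")[centered_cols].mean()
    life = lifetime_fit.merge(life_cent, on="individual_id")
    life["cohort"] = life["individual_id"].map(idx["cohort"])
    life["sex"] = life["individual_id"].map(idx["sex"])
    death = idx["death_year"]
    if censor_year is None:
        censor_year = int(np.nanmax(death.to_numpy(dtype=float)))
    life["lifespan"] = [
        (int(min(death[i], censor_year)) if pd.notna(death[i])
         else censor_year) - int(idx.loc[i, "cohort"])
        for i in life["individual_id"]
    ]
    return annual, life


def run_pipeline(config: RunConfig, measures=None,
                 run_repeatability: bool = True, run_selection: bool = True,
                 run_null: bool = True) -> dict:
    """Run the full analysis; write stage outputs; return the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    measures = list(measures or MEASURES)
    # hash the analysis configuration, not where it writes
    hash_cfg = dataclasses.replace(config, output_dir="")
    manifest: dict = {
        "config_hash": hashlib.sha256(
            to_yaml(hash_cfg).encode()).hexdigest()[:16],
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # --- stage: data ------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        individuals, pedigree, truth = simulate_population(sim)
        visits = simulate_visits(individuals, truth, sim)
        event_windows = sim.event_windows
        truth.to_csv(out_dir / "truth.csv", index=False)
    else:
        paths = config.input_paths
        for key in ("visits", "individuals", "pedigree"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(f"missing input path for {key!r}")
        visits = io.read_visit_log(paths["visits"],
                                   paths.get("visit_dialect"))
        individuals = io.read_individuals(paths["individuals"])
        pedigree = io.read_pedigree(paths["pedigree"])
        event_windows = paths["event_windows"]
    io.write_visit_log(visits, out_dir / "visits.csv")
    io.write_individuals(individuals, out_dir / "individuals.csv")
    io.write_pedigree(pedigree, out_dir / "pedigree.csv")
    manifest["stages"]["data"] = {
        "n_visits": int(len(visits)),
        "n_individuals": int(len(individuals)),
        "n_pedigree_rows": int(len(pedigree)),
    }

    # --- stage: arrivals & networks --------------------------------
    event_cent, nets, bips, arrivals = event_centralities(
        visits, event_windows, config.arrival, individuals)
    arrivals.to_csv(out_dir / "arrivals.csv", index=False)
    event_cent.to_csv(out_dir / "event_centrality.csv", index=False)
    for ev, net in nets.items():
        io.write_network(net, out_dir / f"network_{ev}.graphml")
    summaries = {ev: summarize_event(g) for ev, g in
                 event_cent.groupby("event")} if len(event_cent) else {}
    pd.concat([s.assign(event=ev) for ev, s in summaries.items()],
              ignore_index=True).to_csv(out_dir / "event_summary.csv",
                                        index=False) if summaries else None
    weekly = weekly_centralities(visits, event_windows, config.arrival,
                                 individuals)
    weekly.to_csv(out_dir / "weekly_centrality.csv", index=False)
    manifest["stages"]["networks"] = {
        "n_arrivals": int(len(arrivals)),
        "events": {ev: {"n_vertices": g.number_of_nodes(),
                        "n_edges": g.number_of_edges()}
                   for ev, g in nets.items()},
        "n_weekly_rows": int(len(weekly)),
    }

    # --- stage: fitness --------------------------------------------
    years = sorted({int(str(w[0])[:4]) + 1 for w in event_windows})
    annual_fit, lifetime_fit = fitness_table(pedigree, individuals, years)
    annual_fit.to_csv(out_dir / "fitness_annual.csv", index=False)
    lifetime_fit.to_csv(out_dir / "fitness_lifetime.csv", index=False)
    manifest["stages"]["fitness"] = {
        "years": years,
        "n_annual_rows": int(len(annual_fit)),
        "n_lifetime_rows": int(len(lifetime_fit)),
    }

    # --- stage: repeatability --------------------------------------
    if run_repeatability and len(weekly):
        reps = {}
        for m in measures:
            for ev, g in weekly.groupby("event"):
                try:
                    model = RepeatabilityModel.from_centrality(g, m)
                except ValueError as err:
                    logger.warning("repeatability %s/%s skipped: %s",
                                   m, ev, err)
                    continue
                res = model.fit(config.mcmc)
                reps[f"{m}@{ev}"] = {
                    "R_mode": res.r_mode, "ci": [res.ci_low, res.ci_high]}
                (out_dir / f"repeatability_{m}_{ev}.json").write_text(
                    res.to_json())
        manifest["stages"]["repeatability"] = reps

    # --- stage: selection ------------------------------------------
    annual_data, lifetime_data = build_selection_data(
        event_cent, annual_fit, lifetime_fit, individuals)
    sel_summary = {}
    if run_selection and len(annual_data):
        fits = []
        for m in measures:
            fits.append(("annual", "annual_recruits", "poisson_log",
                         annual_data, m))
            fits.append(("annual", "p_ti", "gaussian", annual_data, m))
            fits.append(("lifetime", "lifetime_recruits", "poisson_log",
                         lifetime_data, m))
            fits.append(("lifetime", "p_i", "gaussian", lifetime_data, m))
        for scale, resp, family, data, m in fits:
            model = SelectionModel(data, resp, f"{m}_c", family=family,
                                   scale=scale)
            res = model.fit(config.mcmc)
            key = f"{resp}~{m}"
            sel_summary[key] = {
                "linear_mode": float(res.term(f"{m}_c")["mode"]),
                "linear_significant": bool(res.term(f"{m}_c")["significant"]),
                "quadratic_mode": float(res.term(f"{m}_c^2")["mode"]),
                "quadratic_significant":
                    bool(res.term(f"{m}_c^2")["significant"]),
                "converged": res.converged,
            }
            (out_dir / f"selection_{resp}_{m}.json").write_text(res.to_json())
        manifest["stages"]["selection"] = sel_summary

    # --- stage: null models ----------------------------------------
    if run_null and len(arrivals):
        null_cent = null_centrality(arrivals, config.arrival,
                                    config.permutation, individuals)
        null_cent.to_csv(out_dir / "null_centrality.csv", index=False)
        manifest["stages"]["null"] = {
            "n_permutations": config.permutation.n_permutations,
            "n_individuals": int(len(null_cent)),
        }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    with open(out_dir / "config.yaml", "w") as fh:
        to_yaml(config, fh)
    return manifest
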