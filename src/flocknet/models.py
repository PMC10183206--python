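"""Repeatability and selection models with a Model -> fit() -> Results API.

``RepeatabilityModel`` estimates the within-individual repeatability
(intraclass correlation) of a weekly centrality measure from a
Gaussian intercept-only mixed model with an individual random effect:
R = V_id / (V_id + V_res), summarized over the posterior.

``SelectionModel`` fits the annual or lifetime selection models:

* annual:   response ~ c + c^2 + sex + age + age^2 + age:sex
            + (1 | bird) + (1 | cohort)
* lifetime: response ~ c + c^2 + sex + lifespan + lifespan:sex
            + (1 | cohort)

with a Poisson log link (annual/lifetime recruits; an additive latent
residual absorbs overdispersion) or Gaussian errors (de-lifed
fitness).  Centrality covariates are mean-centered within year before
fitting; age is not centered.  A fixed effect is flagged significant
when its central 95% credible interval excludes zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc
from .config import MCMCConfig

__all__ = ["mean_center_within_year", "RepeatabilityModel",
           "RepeatabilityResults", "SelectionModel", "SelectionResults"]


def mean_center_within_year(table: pd.DataFrame, measures,
                            year_col: str = "year") -> pd.DataFrame:
    """Mean-center each measure within each year (raw values retained).

    Adds a ``<measure>_c`` column per measure; a year with a single
    observation centers to exactly 0.  Idempotent on the centered
    columns.
    """
    out = table.copy()
    for m in measures:
        out[f"{m}_c"] = out[m] - out.groupby(year_col)[m].transform("mean")
    return out


def _summarize_chains(chains: dict, term_names) -> pd.DataFrame:
    rows = []
    for nm in term_names:
        c = chains[nm]
        lo, hi = np.quantile(c, [0.025, 0.975])
        mode = mcmc.posterior_mode(c)
        diag = mcmc.diagnose(c)
        rows.append((nm, mode, float(np.mean(c)), float(lo), float(hi),
                     bool(lo > 0 or hi < 0), diag["ess"],
                     diag["lag1_autocorr"]))
    return pd.DataFrame(rows, columns=["term", "mode", "mean", "ci_low",
                                       "ci_high", "significant", "ess",
                                       "lag1_autocorr"])


@dataclass
class RepeatabilityResults:
    measure: str
    r_mode: float
    r_mean: float
    ci_low: float
    ci_high: float
    v_id_mode: float
    v_res_mode: float
    diagnostics: pd.DataFrame
    chains: dict

    @property
    def r(self) -> float:
        return self.r_mode

    def summary(self) -> str:
        lines = [
            f"Repeatability of {self.measure}",
            f"  R (posterior mode) = {self.r_mode:.3f}  "
            f"95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}]  "
            f"(mean {self.r_mean:.3f})",
            f"  V_id = {self.v_id_mode:.4f}   V_res = {self.v_res_mode:.4f}",
            "  diagnostics:",
        ]
        for _, d in self.diagnostics.iterrows():
            lines.append(f"    {d['term']:<12} ESS {d['ess']:8.0f}  "
                         f"lag-1 {d['lag1_autocorr']:+.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "measure": self.measure, "R_mode": self.r_mode,
            "R_mean": self.r_mean,
            "ci": [self.ci_low, self.ci_high],
            "V_id_mode": self.v_id_mode, "V_res_mode": self.v_res_mode,
        }, indent=2)


class RepeatabilityModel:
    """Intercept-only Gaussian mixed model for weekly repeated measures.

    Parameters
    ----------
    data : long DataFrame with columns individual_id and ``value_col``;
        every row is one individual-week observation.
    measure : label used in reports.
    """

    def __init__(self, data: pd.DataFrame, measure: str = "value",
                 value_col: str | None = None):
        value_col = value_col or ("value" if "value" in data else measure)
        if value_col not in data:
            raise ValueError(f"no column {value_col!r} in data")
        self.data = data.dropna(subset=[value_col]).reset_index(drop=True)
        self.measure = measure
        self.value_col = value_col
        reps = self.data["individual_id"].value_counts()
        if len(self.data) < 4 or (reps > 1).sum() < 2:
            raise ValueError(
                "repeatability needs >= 2 individuals with repeated weeks")

    @classmethod
    def from_centrality(cls, weekly: pd.DataFrame, measure: str):
        """Build from a weekly CentralityTable (one row per bird-week)."""
        return cls(weekly[["individual_id", measure]].rename(
            columns={measure: "value"}), measure=measure)

    def fit(self, config: MCMCConfig | None = None) -> RepeatabilityResults:
        config = config or MCMCConfig()
        y = self.data[self.value_col].to_numpy(dtype=float)
        x = np.ones((len(y), 1))
        chains = mcmc.run_mixed_model(
            y, x, {"individual": self.data["individual_id"].to_numpy()},
            family="gaussian", config=config, column_names=["(Intercept)"])
        r_chain = chains["V_individual"] / (
            chains["V_individual"] + chains["V_residual"])
        chains["R"] = r_chain
        lo, hi = np.quantile(r_chain, [0.025, 0.975])
        diag = _summarize_chains(
            chains, ["(Intercept)", "V_individual", "V_residual", "R"]
        )[["term", "ess", "lag1_autocorr"]]
        return RepeatabilityResults(
            measure=self.measure,
            r_mode=mcmc.posterior_mode(r_chain),
            r_mean=float(np.mean(r_chain)),
            ci_low=float(lo), ci_high=float(hi),
            v_id_mode=mcmc.posterior_mode(chains["V_individual"]),
            v_res_mode=mcmc.posterior_mode(chains["V_residual"]),
            diagnostics=diag, chains=chains)


@dataclass
class SelectionResults:
    response: str
    family: str
    scale: str
    measure: str
    terms: pd.DataFrame
    random_terms: pd.DataFrame
    chains: dict
    converged: bool

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]

    @property
    def significant(self) -> dict:
        return dict(zip(self.terms["term"], self.terms["significant"]))

    def summary(self) -> str:
        head = (f"Selection model: {self.response} ~ {self.measure} "
                f"({self.family}, {self.scale} scale)")
        lines = [head, "-" * len(head),
                 f"{'term':<18}{'mode':>9}{'2.5%':>9}{'97.5%':>9}  sig"]
        for _, t in self.terms.iterrows():
            lines.append(
                f"{t['term']:<18}{t['mode']:>9.3f}{t['ci_low']:>9.3f}"
                f"{t['ci_high']:>9.3f}  {'*' if t['significant'] else ''}")
        lines.append("random/residual variances:")
        for _, t in self.random_terms.iterrows():
            lines.append(
                f"{t['term']:<18}{t['mode']:>9.3f}{t['ci_low']:>9.3f}"
                f"{t['ci_high']:>9.3f}")
        if not self.converged:
            lines.append("WARNING: chains failed the ESS/autocorrelation "
                         "thresholds; treat estimates with caution")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "response": self.response, "family": self.family,
            "scale": self.scale, "measure": self.measure,
            "converged": self.converged,
            "terms": self.terms.to_dict(orient="records"),
            "random_terms": self.random_terms.to_dict(orient="records"),
        }, indent=2)

    def plot(self, ax=None):
        """Fitted quadratic fitness surface over the centered covariate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.terms.set_index("term")
        c = np.linspace(-3, 3, 200)
        eta = (t.loc["(Intercept)", "mode"]
               + t.loc[self.measure, "mode"] * c
               + t.loc[f"{self.measure}^2", "mode"] * c ** 2)
        y = np.exp(eta) if self.family == "poisson_log" else eta
        ax.plot(c, y)
        ax.set_xlabel(f"{self.measure} (mean-centered)")
        ax.set_ylabel(self.response)
        return ax


class SelectionModel:
    """Linear+quadratic selection gradient model on one sociality measure.

    Parameters
    ----------
    data : one row per observation.  Annual scale requires columns
        individual_id, cohort, sex, age, the (centered) measure and the
        response; lifetime scale uses lifespan instead of age and one
        row per bird.
    response : response column name.
    measure : sociality covariate column (center it within year first;
        see :func:`mean_center_within_year`).
    family : 'poisson_log' for recruit counts, 'gaussian' for de-lifed
        fitness.
    scale : 'annual' or 'lifetime'.
    """

    def __init__(self, data: pd.DataFrame, response: str, measure: str,
                 family: str = "poisson_log", scale: str = "annual"):
        if scale not in ("annual", "lifetime"):
            raise ValueError(f"unknown scale {scale!r}")
        if family not in ("poisson_log", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        age_col = "age" if scale == "annual" else "lifespan"
        needed = {response, measure, "sex", age_col, "cohort",
                  "individual_id"}
        missing = needed - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns {sorted(missing)}")
        self.data = data.dropna(subset=[response, measure]).reset_index(
            drop=True)
        self.response, self.measure = response, measure
        self.family, self.scale = family, scale
        self.age_col = age_col

    def _design(self):
        d = self.data
        c = d[self.measure].to_numpy(dtype=float)
        sex = d["sex"].to_numpy(dtype=float)
        age = d[self.age_col].to_numpy(dtype=float)
        if self.scale == "annual":
            x = np.column_stack([np.ones_like(c), c, c ** 2, sex, age,
                                 age ** 2, age * sex])
            names = ["(Intercept)", self.measure, f"{self.measure}^2",
                     "sex", "age", "age^2", "age:sex"]
            random = {"bird": d["individual_id"].to_numpy(),
                      "cohort": d["cohort"].to_numpy()}
        else:
            x = np.column_stack([np.ones_like(c), c, c ** 2, sex, age,
                                 age * sex])
            names = ["(Intercept)", self.measure, f"{self.measure}^2",
                     "sex", "lifespan", "lifespan:sex"]
            random = {"cohort": d["cohort"].to_numpy()}
        return x, names, random

    def fit(self, config: MCMCConfig | None = None) -> SelectionResults:
        config = config or MCMCConfig()
        x, names, random = self._design()
        y = self.data[self.response].to_numpy(dtype=float)
        chains = mcmc.run_mixed_model(y, x, random, family=self.family,
                                      config=config, column_names=names)
        terms = _summarize_chains(chains, names)
        vnames = [f"V_{k}" for k in random] + ["V_residual"]
        random_terms = _summarize_chains(chains, vnames)
        converged = bool(terms["ess"].ge(1000).all()
                         and terms["lag1_autocorr"].abs().lt(0.1).all())
        return SelectionResults(
            response=self.response, family=self.family, scale=self.scale,
            measure=self.measure, terms=terms, random_terms=random_terms,
            chains=chains, converged=converged)
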