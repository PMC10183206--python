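"""Configuration objects for every pipeline stage.

All configs are plain dataclasses that round-trip through YAML
(:func:`to_yaml` / :func:`from_yaml`) and validate on construction.
Timestamps are handled as integer seconds since the Unix epoch,
timezone-naive, interpreted as local feeder time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import IO, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic population / visit-stream generator.

    The defaults emulate the study conditions: a closed island population
    of ~150 tagged house sparrows visiting a single RFID feeder over two
    non-breeding events of 15 and 13 weeks, recorded 06:00-24:00.

    Parameters
    ----------
    n_individuals : founding population size (birds alive at the first event).
    n_flocks : number of latent foraging flocks.
    flock_membership_concentration : probability an arrival happens with the
        bird's home flock rather than solo, in [0, 1].
    event_windows : ordered, non-overlapping (start, end) ISO dates, end
        exclusive.  Defaults: 15-week and 13-week November-February events.
    arrivals_per_flock_per_day : Poisson rate of flock arrival bouts per day.
    within_flock_arrival_jitter_sd : SD (seconds) of individual arrival times
        around their flock's arrival time.
    bout_length_mean : mean feeding-bout duration in seconds.
    revisit_gap_mean : mean extra gap (seconds) required before the same
        bird can re-arrive; drawn on top of a 301 s floor so that true
        re-arrivals are separated by more than the 300 s absence criterion.
    sex_ratio : probability an individual is male (male=1, female=0).
    true_icc : target week-to-week repeatability of the latent attendance
        propensity (intraclass correlation of weekly propensities).
    mean_offspring : mean surviving offspring per breeding pair per year.
    annual_survival : adult year-to-year survival probability.
    operating_hours : daily feeder recording window, hours [start, end).
    attendance_logit_base, attendance_logit_scale : intercept and slope of
        the logistic map from a bird's weekly latent propensity to its
        probability of joining any given flock arrival.  The slope
        defaults to 0 (equal sampling effort across birds), so that
        latent sociality expresses itself through *whom* a bird arrives
        with, not how often it is detected.
    sociality_concentration_scale : slope of the logistic map from the
        weekly latent propensity to the bird's probability of arriving
        with its flock (around logit(flock_membership_concentration));
        this is the channel through which sociable birds become central.
    fixed_daily_arrivals : replace the Poisson number of flock arrival
        bouts per day with its (rounded) expectation, removing
        flock-level sampling-effort variation; used by controlled
        experiments where effort must be orthogonal to sociality.
    """

    n_individuals: int = 150
    n_flocks: int = 10
    flock_membership_concentration: float = 0.9
    event_windows: Sequence[tuple[str, str]] = (
        ("2015-11-01", "2016-02-14"),  # 15 weeks
        ("2016-11-01", "2017-01-31"),  # 13 weeks
    )
    arrivals_per_flock_per_day: float = 8.0
    within_flock_arrival_jitter_sd: float = 20.0
    bout_length_mean: float = 60.0
    revisit_gap_mean: float = 900.0
    sex_ratio: float = 0.5
    true_icc: float = 0.3
    mean_offspring: float = 2.0
    annual_survival: float = 0.6
    operating_hours: tuple[float, float] = (6.0, 24.0)
    attendance_logit_base: float = 0.25
    attendance_logit_scale: float = 0.0
    sociality_concentration_scale: float = 1.0
    fixed_daily_arrivals: bool = False
    allow_empty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals == 0 and self.allow_empty:
            pass
        else:
            _check(self.n_individuals >= 2, "n_individuals must be >= 2")
        _check(self.n_flocks >= 1, "n_flocks must be >= 1")
        _check(
            0.0 <= self.flock_membership_concentration <= 1.0,
            "flock_membership_concentration must lie in [0, 1]",
        )
        _check(self.arrivals_per_flock_per_day >= 0, "arrival rate must be >= 0")
        _check(self.within_flock_arrival_jitter_sd >= 0, "jitter SD must be >= 0")
        _check(self.bout_length_mean > 0, "bout_length_mean must be > 0")
        _check(self.revisit_gap_mean > 0, "revisit_gap_mean must be > 0")
        _check(0.0 <= self.sex_ratio <= 1.0, "sex_ratio must lie in [0, 1]")
        _check(0.0 <= self.true_icc <= 1.0, "true_icc must lie in [0, 1]")
        _check(len(self.event_windows) >= 1, "at least one event window required")
        self.event_windows = [tuple(w) for w in self.event_windows]
        self.operating_hours = tuple(self.operating_hours)
        starts = [w[0] for w in self.event_windows]
        _check(starts == sorted(starts), "event windows must be ordered")
        for (s1, e1), (s2, _) in zip(self.event_windows, self.event_windows[1:]):
            _check(e1 <= s2, "event windows must not overlap")
        for s, e in self.event_windows:
            _check(s < e, f"event window {s}..{e} is empty or inverted")


@dataclass
class FitnessCouplingConfig:
    """Generative model linking sociality to expected fitness.

    ``poisson_recruits``: recruits ~ Poisson(exp(b0 + b1 c + b2 c^2 +
    b_sex sex + b_age age + e)) with optional additive overdispersion
    e ~ N(0, overdispersion_sd) on the log scale (0 = pure Poisson);
    ``gaussian_delifed``: the same linear predictor plus N(0, noise_sd)
    noise on the identity scale.
    """

    beta_linear: float = 0.0
    beta_quadratic: float = 0.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    baseline_log_rate: float = 0.0
    family: str = "poisson_recruits"
    noise_sd: float = 1.0
    overdispersion_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(
            self.family in ("poisson_recruits", "gaussian_delifed"),
            f"unknown family {self.family!r}",
        )
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.overdispersion_sd >= 0, "overdispersion_sd must be >= 0")


@dataclass
class ArrivalParams:
    """Arrival-inference thresholds.

    delta_t: co-arrival window in seconds (two birds arriving within
    delta_t of each other are associated; inclusive boundary).
    delta_i: minimum absence in seconds before a detection counts as a
    new arrival (strict: a gap must exceed delta_i).
    """

    delta_t: float = 150.0
    delta_i: float = 300.0

    def __post_init__(self) -> None:
        _check(self.delta_t > 0, "delta_t must be > 0")
        _check(self.delta_i > 0, "delta_i must be > 0")


@dataclass
class MCMCConfig:
    """Sampler contract: iterations, burn-in, thinning and priors.

    Defaults follow the published analysis: 343,000 iterations, burn-in
    3000, thinning 200 (1700 retained samples) with weakly-informative
    inverse-Wishart variance priors (V=1, nu=0.002).
    """

    n_iterations: int = 343_000
    burn_in: int = 3000
    thin: int = 200
    prior_variance_v: float = 1.0
    prior_variance_nu: float = 0.002
    fixed_effect_prior_variance: float = 1e8
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_iterations > self.burn_in, "n_iterations must exceed burn_in")
        _check(self.thin >= 1, "thin must be >= 1")
        _check(self.n_samples >= 1, "no retained samples under this contract")
        _check(self.prior_variance_v > 0 and self.prior_variance_nu >= 0,
               "variance prior hyperparameters invalid")

    @property
    def n_samples(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    def scaled(self, factor: float) -> "MCMCConfig":
        """A shorter run with the same shape (for desk-scale experiments)."""
        return dataclasses.replace(
            self,
            n_iterations=max(int(self.n_iterations * factor), 2 * self.thin),
            burn_in=max(int(self.burn_in * factor), 1),
        )


@dataclass
class PermutationConfig:
    """Node-permutation null-model settings."""

    n_permutations: int = 1000
    scope: str = "within_event"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_permutations >= 1, "n_permutations must be >= 1")
        _check(self.scope in ("within_event", "within_week"),
               f"unknown permutation scope {self.scope!r}")


@dataclass
class EloConfig:
    """Elo dominance-rating settings (behavioural-ecology convention)."""

    start_rating: float = 1000.0
    k_factor: float = 100.0

    def __post_init__(self) -> None:
        _check(self.k_factor > 0, "k_factor must be > 0")


@dataclass
class RunConfig:
    """Whole-pipeline configuration: exactly one of simulation / input paths."""

    simulation: SimConfig | None = None
    input_paths: dict | None = None
    arrival: ArrivalParams = field(default_factory=ArrivalParams)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    elo: EloConfig = field(default_factory=EloConfig)
    coupling: FitnessCouplingConfig | None = None
    output_dir: str = "flocknet_run"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(
            (self.simulation is None) != (self.input_paths is None),
            "exactly one of {simulation, input_paths} must be set",
        )


_CONFIG_TYPES = {
    "SimConfig": SimConfig,
    "FitnessCouplingConfig": FitnessCouplingConfig,
    "ArrivalParams": ArrivalParams,
    "MCMCConfig": MCMCConfig,
    "PermutationConfig": PermutationConfig,
    "EloConfig": EloConfig,
    "RunConfig": RunConfig,
}


def to_yaml(config, stream: IO[str] | None = None) -> str | None:
    """Serialize a config dataclass to YAML (nested configs included)."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            d = {"__type__": type(obj).__name__}
            for f in dataclasses.fields(obj):
                d[f.name] = encode(getattr(obj, f.name))
            return d
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, list):
            return [encode(v) for v in obj]
        return obj

    return yaml.safe_dump(encode(config), stream, sort_keys=False)


def from_yaml(source: str | IO[str]):
    """Rebuild a config dataclass from :func:`to_yaml` output."""

    def decode(obj):
        if isinstance(obj, dict) and "__type__" in obj:
            cls = _CONFIG_TYPES[obj["__type__"]]
            kwargs = {k: decode(v) for k, v in obj.items() if k != "__type__"}
            return cls(**kwargs)
        if isinstance(obj, list):
            return [decode(v) for v in obj]
        return obj

    return decode(yaml.safe_load(source))
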