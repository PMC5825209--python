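"""Sequential Monte Carlo ABC over promoter models and parameters.

A particle is a (model, parameter vector) pair; a population of particles
is refined iteratively: distances to the data are evaluated by fresh
stochastic simulation, the best 20% are retained, offspring are proposed
around them with per-parameter kernels, and offspring are accepted when
they beat the previous population's 80th-percentile distance.  The model
index itself is part of the particle, so the posterior carries joint
model/parameter mass over the full space of promoter-cycle topologies and
extrinsic-noise variants (5 x 8 = 40 models by default).

The multi-condition global fit reuses the same loop: each particle holds
one shared parameter set plus one local value (OFF-time or initiation
rate) per condition, and the per-condition distances are summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .promoter_sim import (
    DEFAULT_PROFILE,
    DEFAULT_TOPOLOGIES,
    KineticParams,
    PromoterModelSpec,
    Protocol,
    TraceDataset,
    build_topology,
    simulate_induction,
    simulate_population,
)
from .abc_distance import FeatureConfig, FeatureSet, compute_features, distance
from .synthetic_data import DEFAULT_NOISE, NoiseModel, add_measurement_noise

__all__ = [
    "PriorSpec",
    "Particle",
    "Posterior",
    "SMCConfig",
    "default_model_space",
    "related_models",
    "sample_prior",
    "perturb",
    "smc_fit",
    "model_frequencies",
    "posterior_quantiles",
    "global_fit",
]


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior families and bounds, plus a uniform model prior.

    Log-uniform priors bracket all plausible kinetic values with wide
    margins (ON-times well below a minute up to tens of minutes, OFF-times
    of minutes to many hours, burst sizes of one to a hundred transcripts);
    extrinsic CVs are uniform on [0, 1.5].
    """

    params: dict = field(
        default_factory=lambda: {
            "t_on": ("loguniform", 0.1, 30.0),
            "t_off": ("loguniform", 1.0, 1000.0),
            "b": ("loguniform", 1.0, 100.0),
            "cv": ("uniform", 0.0, 1.5),
        }
    )

    def resolve(self, name: str) -> tuple[str, float, float]:
        """Prior spec for a (possibly suffixed or cv_) parameter name."""
        if name in self.params:
            return self.params[name]
        if name.startswith("cv_"):
            return self.params["cv"]
        base = name.rsplit("_", 1)[0]  # local parameters: t_off_0, b_3, ...
        if base in self.params:
            return self.params[base]
        raise KeyError(f"no prior for parameter {name!r}")

    def sample(self, name: str, rng) -> float:
        kind, lo, hi = self.resolve(name)
        if kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))

    def is_log(self, name: str) -> bool:
        return self.resolve(name)[0] == "loguniform"

    def bounds(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.resolve(name)
        return lo, hi


@dataclass
class Particle:
    """One model/parameter hypothesis with its realized distance."""

    model: str
    params: dict
    distance: float = math.inf
    per_condition: list | None = None


@dataclass
class Posterior:
    """The evolving weighted population and its refinement history."""

    particles: list
    iterations: int
    threshold_history: list
    median_history: list
    notes: list = field(default_factory=list)

    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    def to_frame(self) -> pd.DataFrame:
        keys = sorted({k for p in self.particles for k in p.params})
        rows = []
        for p in self.particles:
            row = {"model": p.model, "distance": p.distance}
            for k in keys:
                row[k] = p.params.get(k, np.nan)
            if p.per_condition is not None:
                for i, d in enumerate(p.per_condition):
                    row[f"distance_{i}"] = d
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SMCConfig:
    """Tuning knobs of the SMC loop (defaults follow the full-scale study)."""

    n_particles: int = 2000
    keep_frac: float = 0.2
    n_cells_per_sim: int | None = None  # default: match the data's cell count
    max_iterations: int = 15
    stop_rel_improvement: float = 0.01
    target_median: float = 0.5
    model_jump_prob: float = 0.05
    kernel_scale: float = 1.0  # proposal width = scale * retained std
    min_width: float = 0.02
    max_attempt_factor: int = 5
    # refresh retained particles' distances each iteration so single lucky
    # simulation draws cannot survive selection indefinitely (the distance
    # is stochastic: one fresh simulation per evaluation)
    reevaluate_retained: bool = True
    # prior candidates drawn in the initial iteration, as a multiple of
    # n_particles (best n_particles are kept); >1 improves coverage of the
    # joint model/parameter space at small population sizes
    init_factor: int = 5


def default_model_space() -> list[str]:
    """All 40 default models: 5 cycle sizes x 8 extrinsic-noise variants."""
    return [
        f"{n_on}-{n_off}-{v}" for (n_on, n_off) in DEFAULT_TOPOLOGIES for v in range(8)
    ]


def related_models(code: str) -> set[str]:
    """The code itself plus its immediate neighbors in model space.

    Two models are immediate neighbors when they differ by one elementary
    move: one step along the default cycle-size ladder (same noise
    variant), or one edit of the resampled-parameter set — adding,
    removing, or substituting a single parameter (same cycle size).
    """
    from .promoter_sim import NOISE_VARIANTS

    topo = build_topology(code)
    out = {topo.code}
    shape = (topo.n_on, topo.n_off)
    if shape in DEFAULT_TOPOLOGIES:
        i = DEFAULT_TOPOLOGIES.index(shape)
        for j in (i - 1, i + 1):
            if 0 <= j < len(DEFAULT_TOPOLOGIES):
                on, off = DEFAULT_TOPOLOGIES[j]
                out.add(f"{on}-{off}-{topo.noise_variant}")
    mine = set(NOISE_VARIANTS[topo.noise_variant])
    for v, names in NOISE_VARIANTS.items():
        other = set(names)
        diff = len(mine.symmetric_difference(other))
        substitution = diff == 2 and len(mine) == len(other)
        if diff == 1 or substitution:
            out.add(f"{topo.n_on}-{topo.n_off}-{v}")
    return out


def param_names(code: str) -> list[str]:
    topo = build_topology(code)
    return ["t_on", "t_off", "b"] + [f"cv_{p}" for p in topo.resampled]


def sample_prior(prior: PriorSpec, model_space: list[str], rng) -> Particle:
    """Draw a particle from the joint model/parameter prior."""
    if not model_space:
        raise ValueError("empty model space")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    code = model_space[int(rng.integers(len(model_space)))]
    params = {name: prior.sample(name, rng) for name in param_names(code)}
    return Particle(model=code, params=params)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2 * width)
    return lo + (y if y <= width else 2 * width - y)


def _perturb_value(value: float, width: float, name: str, prior: PriorSpec, rng) -> float:
    lo, hi = prior.bounds(name)
    if prior.is_log(name):
        x = math.log(value) + rng.normal(0.0, width)
        return float(math.exp(_reflect(x, math.log(lo), math.log(hi))))
    x = value + rng.normal(0.0, width)
    return float(_reflect(x, lo, hi))


def perturb(
    particle: Particle,
    widths: dict,
    prior: PriorSpec,
    model_space: list[str],
    rng,
    model_jump_prob: float = 0.0,
    pool: dict | None = None,
) -> Particle:
    """Propose a new particle near an existing one.

    Parameters move under per-parameter Gaussian kernels (log scale for
    log-uniform priors) reflected into the prior support; with probability
    ``model_jump_prob`` the model index jumps to a uniformly chosen other
    model, keeping shared parameters.  Parameters the new model needs but
    the parent lacks are drawn from the retained population's values for
    that parameter (``pool``) when available, else from the prior.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    code = particle.model
    if model_jump_prob > 0 and len(model_space) > 1 and rng.random() < model_jump_prob:
        others = [m for m in model_space if m != code]
        code = others[int(rng.integers(len(others)))]
    params = {}
    for name in param_names(code):
        if name in particle.params:
            w = widths.get(name, 0.0)
            params[name] = (
                _perturb_value(particle.params[name], w, name, prior, rng)
                if w > 0
                else particle.params[name]
            )
        elif pool and name in pool and len(pool[name]):
            vals = pool[name]
            base = float(vals[int(rng.integers(len(vals)))])
            params[name] = _perturb_value(base, widths.get(name, 0.0), name, prior, rng)
        else:
            params[name] = prior.sample(name, rng)
    return Particle(model=code, params=params)


def particle_model(particle: Particle, profile=DEFAULT_PROFILE) -> PromoterModelSpec:
    """Materialize the promoter model a particle encodes."""
    topo = build_topology(particle.model)
    cv = {p: float(particle.params[f"cv_{p}"]) for p in topo.resampled}
    params = KineticParams(
        t_on=particle.params["t_on"],
        t_off=particle.params["t_off"],
        burst_size=particle.params["b"],
        cv_ext=cv,
    )
    return PromoterModelSpec(topo, params, profile)


# ---------------------------------------------------------------------------
# distance evaluation


class DatasetEvaluator:
    """Distance of a particle to one dataset, via one fresh simulation."""

    def __init__(
        self,
        data: TraceDataset,
        n_cells_per_sim: int | None = None,
        noise: NoiseModel = DEFAULT_NOISE,
        feature_config: FeatureConfig | None = None,
        weights: dict | None = None,
        profile=DEFAULT_PROFILE,
    ):
        if data.n_traces == 0:
            raise ValueError("empty dataset")
        self.protocol = data.protocol
        self.n_cells = n_cells_per_sim or int(len(np.unique(data.cell_ids)))
        self.noise = noise
        self.config = feature_config or FeatureConfig()
        self.weights = weights
        self.profile = profile
        self.data_features: FeatureSet = compute_features(data, self.config, profile)

    def simulate(self, model: PromoterModelSpec, rng) -> TraceDataset:
        if self.protocol.kind == "induction":
            ds = simulate_induction(model, self.n_cells, self.protocol, rng=rng)
        else:
            ds = simulate_population(model, self.n_cells, self.protocol, rng=rng)
        return add_measurement_noise(ds, self.noise, rng)

    def __call__(self, particle: Particle, rng) -> float:
        model = particle_model(particle, self.profile)
        ds = self.simulate(model, rng)
        fs = compute_features(ds, self.config, self.profile)
        return distance(fs, self.data_features, self.weights)


def _safe_eval(evaluate, particle, rng, notes) -> float:
    try:
        return float(evaluate(particle, rng))
    except (ValueError, FloatingPointError) as err:  # failed simulation = rejection
        notes.append(f"evaluation failed ({particle.model}): {err}")
        return math.inf


def _kernel_widths(retained: list, prior: PriorSpec, config: SMCConfig) -> dict:
    keys = sorted({k for p in retained for k in p.params})
    widths = {}
    for k in keys:
        vals = np.array([p.params[k] for p in retained if k in p.params])
        if prior.is_log(k):
            vals = np.log(vals)
        w = config.kernel_scale * float(vals.std()) if len(vals) > 1 else 0.0
        widths[k] = max(w, config.min_width)
    return widths


def _smc_loop(sample_fn, perturb_fn, evaluate, config: SMCConfig, prior, rng) -> Posterior:
    notes: list = []
    particles = []
    for _ in range(config.init_factor * config.n_particles):
        p = sample_fn(rng)
        p.distance = _safe_eval(evaluate, p, rng, notes)
        particles.append(p)
    particles.sort(key=lambda p: p.distance)
    particles = particles[: config.n_particles]
    median = float(np.median([p.distance for p in particles]))
    medians, thresholds = [median], []

    n_keep = max(1, int(math.ceil(config.keep_frac * config.n_particles)))
    for _iteration in range(config.max_iterations):
        if median <= config.target_median:
            break
        threshold = float(np.quantile([p.distance for p in particles], 0.8))
        thresholds.append(threshold)
        retained = particles[:n_keep]
        if config.reevaluate_retained:
            for p in retained:
                p.distance = _safe_eval(evaluate, p, rng, notes)
        widths = _kernel_widths(retained, prior, config)
        pool: dict = {}
        for p in retained:
            for k, v in p.params.items():
                pool.setdefault(k, []).append(v)

        n_new = config.n_particles - n_keep
        accepted, rejected = [], []
        attempts, cap = 0, config.max_attempt_factor * config.n_particles
        while len(accepted) < n_new and attempts < cap:
            parent = retained[int(rng.integers(n_keep))]
            child = perturb_fn(parent, widths, rng, pool)
            child.distance = _safe_eval(evaluate, child, rng, notes)
            attempts += 1
            (accepted if child.distance < threshold else rejected).append(child)
        if len(accepted) < n_new:  # keep the population size constant
            rejected.sort(key=lambda p: p.distance)
            fill = rejected[: n_new - len(accepted)]
            notes.append(
                f"iteration {_iteration}: filled {len(fill)} slots with best rejected"
            )
            accepted.extend(fill)
        particles = retained + accepted
        particles.sort(key=lambda p: p.distance)
        prev, median = median, float(np.median([p.distance for p in particles]))
        medians.append(median)
        if prev > 0 and (prev - median) / prev < config.stop_rel_improvement:
            break

    return Posterior(
        particles=particles,
        iterations=len(medians) - 1,
        threshold_history=thresholds,
        median_history=medians,
        notes=notes,
    )


def smc_fit(
    data: TraceDataset,
    model_space: list[str] | None = None,
    prior: PriorSpec | None = None,
    config: SMCConfig | None = None,
    rng=None,
    noise: NoiseModel = DEFAULT_NOISE,
    feature_config: FeatureConfig | None = None,
    weights: dict | None = None,
) -> Posterior:
    """Joint model selection and parameter inference on one dataset.

    Each particle evaluation simulates a population matched to the data's
    protocol (same frame interval and count, ``config.n_cells_per_sim``
    cells) with a fresh seed and measures the five-feature distance.  The
    loop stops when the population median distance improves by less than
    1% over an iteration, reaches the replicate floor (0.5), or hits the
    iteration cap.
    """
    model_space = model_space or default_model_space()
    prior = prior or PriorSpec()
    config = config or SMCConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    evaluate = DatasetEvaluator(
        data, config.n_cells_per_sim, noise, feature_config, weights
    )

    def sample_fn(rng):
        return sample_prior(prior, model_space, rng)

    def perturb_fn(parent, widths, rng, pool=None):
        return perturb(
            parent, widths, prior, model_space, rng, config.model_jump_prob, pool
        )

    return _smc_loop(sample_fn, perturb_fn, evaluate, config, prior, rng)


def model_frequencies(posterior: Posterior) -> pd.Series:
    """Relative posterior frequency of each model code (sums to 1)."""
    if not posterior.particles:
        raise ValueError("empty posterior")
    codes = pd.Series([p.model for p in posterior.particles])
    return codes.value_counts(normalize=True)


def posterior_quantiles(posterior: Posterior, name: str, qs=(0.05, 0.5, 0.95)) -> np.ndarray:
    """Quantiles of one parameter over the particles that carry it."""
    vals = np.array([p.params[name] for p in posterior.particles if name in p.params])
    if len(vals) == 0:
        raise ValueError(f"no particle carries parameter {name!r}")
    return np.quantile(vals, qs)


# ---------------------------------------------------------------------------
# multi-condition global fit


def _global_names(local_param: str, n_conditions: int, topo) -> tuple[list, list]:
    cv_names = [f"cv_{p}" for p in topo.resampled]
    if local_param == "t_off":
        globals_ = ["t_on", "b"] + cv_names
        locals_ = [f"t_off_{i}" for i in range(n_conditions)]
    elif local_param == "k_init":
        # k_init varies with condition through a local burst size (t_on global)
        globals_ = ["t_on", "t_off"] + cv_names
        locals_ = [f"b_{i}" for i in range(n_conditions)]
    else:
        raise ValueError("local_param must be 't_off' or 'k_init'")
    return globals_, locals_


def _global_particle_model(particle, i, local_param, topo) -> PromoterModelSpec:
    p = dict(particle.params)
    if local_param == "t_off":
        p["t_off"] = p.pop(f"t_off_{i}")
        for j in range(len(particle.params)):
            p.pop(f"t_off_{j}", None)
    else:
        p["b"] = p.pop(f"b_{i}")
        for j in range(len(particle.params)):
            p.pop(f"b_{j}", None)
    cv = {name: p[f"cv_{name}"] for name in topo.resampled}
    return PromoterModelSpec(
        topo,
        KineticParams(t_on=p["t_on"], t_off=p["t_off"], burst_size=p["b"], cv_ext=cv),
    )


def global_fit(
    datasets: list,
    local_param: str = "t_off",
    topology="1-1-5",
    prior: PriorSpec | None = None,
    config: SMCConfig | None = None,
    start: list | None = None,
    rng=None,
    noise: NoiseModel = DEFAULT_NOISE,
    feature_config: FeatureConfig | None = None,
    weights: dict | None = None,
) -> Posterior:
    """Fit several conditions at once with a single locally varying parameter.

    The model topology is fixed; every particle carries one global
    parameter set plus one local value per condition (OFF-time for
    burst-frequency modulation, or initiation rate — parameterized as a
    local burst size with the ON-time global — for burst-size modulation).
    The particle distance is the sum of the per-condition distances.  The
    start population is sampled from the prior, or, when per-condition
    posteriors are supplied, from the overlap of their global-parameter
    ranges.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    kinds = {d.protocol.kind for d in datasets}
    if len(kinds) > 1:
        raise ValueError("datasets mix protocols")
    topo = build_topology(topology)
    prior = prior or PriorSpec()
    config = config or SMCConfig(n_particles=1000)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    global_names, local_names = _global_names(local_param, len(datasets), topo)
    evaluators = [
        DatasetEvaluator(d, config.n_cells_per_sim, noise, feature_config, weights)
        for d in datasets
    ]

    ranges = _start_ranges(start, global_names, local_names, topo, prior) if start else None

    def sample_fn(rng):
        params = {}
        for name in global_names + local_names:
            if ranges and name in ranges:
                lo, hi = ranges[name]
                if prior.is_log(name):
                    params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    params[name] = float(rng.uniform(lo, hi))
            else:
                params[name] = prior.sample(name, rng)
        return Particle(model=topo.code, params=params)

    def perturb_fn(parent, widths, rng, pool=None):
        # the particle keeps its own key set (globals + one local per condition)
        params = {
            name: _perturb_value(value, widths.get(name, 0.0), name, prior, rng)
            for name, value in parent.params.items()
        }
        return Particle(model=parent.model, params=params)

    def evaluate(particle, rng):
        per = []
        for i, ev in enumerate(evaluators):
            model = _global_particle_model(particle, i, local_param, topo)
            ds = ev.simulate(model, rng)
            per.append(distance(compute_features(ds, ev.config, ev.profile),
                                ev.data_features, ev.weights))
        particle.per_condition = per
        return float(sum(per))

    return _smc_loop(sample_fn, perturb_fn, evaluate, config, prior, rng)


def _start_ranges(posteriors, global_names, local_names, topo, prior) -> dict:
    """Intersect per-condition posterior 5-95% ranges on global parameters."""
    ranges = {}
    for name in global_names:
        lo, hi = prior.bounds(name)
        for post in posteriors:
            vals = np.array(
                [p.params[name] for p in post.particles
                 if p.model == topo.code and name in p.params]
            )
            if len(vals) >= 2:
                lo = max(lo, float(np.quantile(vals, 0.05)))
                hi = min(hi, float(np.quantile(vals, 0.95)))
        if lo < hi:
            ranges[name] = (lo, hi)
    base = "t_off" if local_names and local_names[0].startswith("t_off") else "b"
    for i, name in enumerate(local_names):
        if i < len(posteriors):
            vals = np.array(
                [p.params[base] for p in posteriors[i].particles
                 if p.model == topo.code and base in p.params]
            )
            if len(vals) >= 2:
                lo, hi = float(np.quantile(vals, 0.05)), float(np.quantile(vals, 0.95))
                if lo < hi:
                    ranges[name] = (lo, hi)
    return ranges
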