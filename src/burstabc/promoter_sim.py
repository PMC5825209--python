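"""Stochastic promoter-cycle simulation and nascent-transcript trace rendering.

The promoter is modelled as an irreversible cycle through ``n_off``
sequential inactive states followed by ``n_on`` sequential active states.
Each state is left at a constant hazard, so the total OFF-time is
Erlang(``n_off``) with mean ``t_off`` and the total ON-time Erlang(``n_on``)
with mean ``t_on``; for a single state the dwell is exponential (the
classic two-state telegraph model).  While the promoter is in any active
state, transcripts initiate as a Poisson process with rate
``k_init = b / t_on``, so ``b`` transcripts are made per full ON passage on
average.

Elongation is deterministic: each initiated transcript contributes a fixed
trapezoidal fluorescence profile (rise while the stem-loop cassette is
transcribed, plateau of one RNA-equivalent, disappearance at
termination/release ~30 min after initiation).  The rendered trace is the
exact superposition of these profiles evaluated on the imaging grid.

Cell-to-cell (extrinsic) variability is introduced by resampling selected
kinetic parameters once per cell from a truncated normal around the
population mean; which parameters are resampled is encoded in the
topology's noise variant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NOISE_VARIANTS",
    "DEFAULT_TOPOLOGIES",
    "PromoterTopology",
    "KineticParams",
    "SignalProfile",
    "EventLog",
    "CellTrace",
    "Protocol",
    "TraceDataset",
    "PromoterModelSpec",
    "build_topology",
    "single_transcript_profile",
    "simulate_promoter",
    "render_trace",
    "sample_extrinsic",
    "simulate_population",
    "simulate_induction",
]

#: noise variant -> kinetic parameters resampled per cell
NOISE_VARIANTS: dict[int, tuple[str, ...]] = {
    0: (),
    1: ("k_elong",),
    2: ("k_init",),
    3: ("k_on",),
    4: ("k_off",),
    5: ("k_elong", "k_init"),
    6: ("k_on", "k_off"),
    7: ("k_elong", "k_init", "k_on", "k_off"),
}

#: default promoter-cycle sizes: 2, 4, 6, 8 and 10 total states
DEFAULT_TOPOLOGIES: tuple[tuple[int, int], ...] = ((1, 1), (1, 3), (1, 5), (1, 7), (1, 9))

_DASHES = "‐‑‒–—−"


@dataclass(frozen=True)
class PromoterTopology:
    """Promoter-cycle shape: ``n_on`` active and ``n_off`` inactive states."""

    n_on: int
    n_off: int
    noise_variant: int = 0

    def __post_init__(self) -> None:
        if self.n_on < 1 or self.n_off < 1:
            raise ValueError(
                f"topology needs at least one ON and one OFF state, got "
                f"({self.n_on}, {self.n_off})"
            )
        if self.n_on + self.n_off > 10:
            raise ValueError("promoter cycles above 10 total states are not supported")
        if self.noise_variant not in NOISE_VARIANTS:
            raise ValueError(f"noise_variant must be in 0..7, got {self.noise_variant}")

    @property
    def n_states(self) -> int:
        return self.n_on + self.n_off

    @property
    def resampled(self) -> tuple[str, ...]:
        """Parameter names resampled per cell under this noise variant."""
        return NOISE_VARIANTS[self.noise_variant]

    @property
    def code(self) -> str:
        return f"{self.n_on}-{self.n_off}-{self.noise_variant}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def build_topology(code) -> PromoterTopology:
    """Parse a topology code like ``"1-1-5"`` (any dash flavour) or a triple."""
    if isinstance(code, PromoterTopology):
        return code
    if isinstance(code, (tuple, list)):
        if len(code) == 2:
            n_on, n_off = code
            variant = 0
        elif len(code) == 3:
            n_on, n_off, variant = code
        else:
            raise ValueError(f"topology tuple must have 2 or 3 entries, got {code!r}")
    else:
        text = str(code).strip()
        for d in _DASHES:
            text = text.replace(d, "-")
        m = re.fullmatch(r"(\d+)-(\d+)(?:-(\d+))?", text)
        if m is None:
            raise ValueError(f"malformed topology code {code!r}; expected 'n_on-n_off-variant'")
        n_on, n_off = int(m.group(1)), int(m.group(2))
        variant = int(m.group(3)) if m.group(3) is not None else 0
    return PromoterTopology(int(n_on), int(n_off), int(variant))


@dataclass
class KineticParams:
    """Population-level kinetic parameters of the promoter cycle.

    ``t_on``/``t_off`` are the mean total ON/OFF times per cycle in minutes,
    ``burst_size`` the mean number of transcripts per full ON passage, and
    ``k_elong`` a dimensionless elongation-speed factor (1 = reference
    residence time).  ``cv_ext`` maps parameter names (``k_elong``,
    ``k_init``, ``k_on``, ``k_off``) to extrinsic coefficients of variation.
    """

    t_on: float
    t_off: float
    burst_size: float
    k_elong: float = 1.0
    cv_ext: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.t_on > 0 and self.t_off > 0 and self.burst_size > 0):
            raise ValueError("t_on, t_off and burst_size must be positive")
        if self.k_elong <= 0:
            raise ValueError("k_elong must be positive")
        for name, cv in self.cv_ext.items():
            if name not in ("k_elong", "k_init", "k_on", "k_off"):
                raise ValueError(f"unknown extrinsic-noise parameter {name!r}")
            if cv < 0:
                raise ValueError(f"cv_ext[{name!r}] must be >= 0, got {cv}")

    @property
    def k_init(self) -> float:
        """Initiation rate during ON states (RNA/min); always burst_size / t_on."""
        return self.burst_size / self.t_on

    def k_on(self, topology: PromoterTopology) -> float:
        """Exit rate of each OFF state (1/min)."""
        return topology.n_off / self.t_off

    def k_off(self, topology: PromoterTopology) -> float:
        """Exit rate of each ON state (1/min)."""
        return topology.n_on / self.t_on


@dataclass(frozen=True)
class SignalProfile:
    """Fluorescence contribution of one nascent transcript over time.

    Zero before ``delay``, linear rise over ``ramp`` minutes to a plateau of
    one RNA-equivalent, and disappearance at ``residence`` minutes after
    initiation (termination and release).  The defaults place the stem-loop
    cassette at the 5' end of the transcription unit (no delay, short ramp)
    with a total residence of 30 min.
    """

    delay: float = 0.0
    ramp: float = 2.0
    residence: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.delay and self.delay + self.ramp <= self.residence):
            raise ValueError("profile must satisfy 0 <= delay <= delay + ramp <= residence")

    @property
    def area(self) -> float:
        """Integral of the unit profile in RNA*min."""
        return self.residence - self.delay - self.ramp / 2.0

    def scaled(self, elong_scale: float) -> "SignalProfile":
        """Profile for elongation ``elong_scale`` times faster than reference."""
        if elong_scale <= 0:
            raise ValueError("elong_scale must be positive")
        return SignalProfile(
            self.delay / elong_scale, self.ramp / elong_scale, self.residence / elong_scale
        )

    def __call__(self, s):
        """Evaluate the unit profile at time ``s`` after initiation."""
        s = np.asarray(s, dtype=float)
        if self.ramp > 0:
            rise = np.clip((s - self.delay) / self.ramp, 0.0, 1.0)
        else:
            rise = (s >= self.delay).astype(float)
        return np.where((s >= self.delay) & (s < self.residence), rise, 0.0)


DEFAULT_PROFILE = SignalProfile()


def single_transcript_profile(
    elong_scale: float = 1.0, reference: SignalProfile = DEFAULT_PROFILE
) -> SignalProfile:
    """Single-transcript signal profile at a given elongation-speed factor.

    All time scales (delay, ramp, residence) shrink as ``1/elong_scale``;
    the plateau stays at one RNA-equivalent.
    """
    return reference.scaled(elong_scale)


@dataclass
class EventLog:
    """Raw output of one promoter simulation."""

    state_switch_times: np.ndarray  # time of entering each visited state, starts at 0
    state_indices: np.ndarray  # visited state index; 0..n_off-1 OFF, then ON
    initiation_times: np.ndarray  # sorted transcript initiation times
    duration: float
    n_off: int = 1
    n_on: int = 1

    def on_intervals(self) -> np.ndarray:
        """(n, 2) array of [entry, exit) spans of active states, clipped to duration."""
        t = self.state_switch_times
        ends = np.append(t[1:], self.duration)
        on = self.state_indices >= self.n_off
        iv = np.column_stack([t[on], np.minimum(ends[on], self.duration)])
        return iv[iv[:, 1] > iv[:, 0]]


@dataclass
class CellTrace:
    """One cell/allele transcription-site intensity time series."""

    cell_id: int
    allele_id: int
    times: np.ndarray  # minutes, uniform grid
    intensity: np.ndarray  # RNA-equivalent units
    condition: str = ""


@dataclass(frozen=True)
class Protocol:
    """Imaging protocol metadata.

    Steady-state movies discard an initial ``equilibration_min`` span so the
    promoter-state distribution relaxes; induction movies start all cells in
    the first OFF state with the stimulus added at ``stimulus_min`` after
    movie start.
    """

    kind: str = "steady_state"  # or "induction"
    frame_interval_min: float = 3.0
    n_frames: int = 250
    equilibration_min: float = 80.0
    stimulus_min: float = 51.0

    def __post_init__(self) -> None:
        if self.kind not in ("steady_state", "induction"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.frame_interval_min <= 0 or self.n_frames < 2:
            raise ValueError("protocol needs a positive frame interval and >= 2 frames")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    @property
    def span_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min


INDUCTION_PROTOCOL = Protocol(
    kind="induction", frame_interval_min=1.5, n_frames=200, equilibration_min=0.0,
    stimulus_min=51.0,
)


@dataclass
class TraceDataset:
    """A population of traces on a shared imaging grid.

    ``intensity`` has one row per trace; rows are grouped per cell when
    ``alleles_per_cell`` was 2 (``cell_ids``/``allele_ids`` identify them).
    """

    intensity: np.ndarray  # (n_traces, n_frames)
    times: np.ndarray  # (n_frames,)
    cell_ids: np.ndarray
    allele_ids: np.ndarray
    condition: str = ""
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        self.allele_ids = np.asarray(self.allele_ids)
        if self.intensity.shape != (len(self.cell_ids), len(self.times)):
            raise ValueError("intensity shape inconsistent with cell_ids/times")

    @property
    def n_traces(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def traces(self):
        for i in range(self.n_traces):
            yield CellTrace(
                int(self.cell_ids[i]), int(self.allele_ids[i]), self.times,
                self.intensity[i], self.condition,
            )


@dataclass
class PromoterModelSpec:
    """A complete promoter model: topology, kinetics, and signal profile."""

    topology: PromoterTopology
    params: KineticParams
    profile: SignalProfile = DEFAULT_PROFILE


# ---------------------------------------------------------------------------
# core simulation


def _state_rates(topology: PromoterTopology, params: KineticParams) -> np.ndarray:
    rates = np.empty(topology.n_states)
    rates[: topology.n_off] = params.k_on(topology)
    rates[topology.n_off:] = params.k_off(topology)
    return rates


def _initial_state(topology, rates, protocol_kind, rng) -> int:
    if protocol_kind == "induction":
        return 0
    # stationary occupancy of the cycle is proportional to the mean state dwell
    w = 1.0 / rates
    return int(rng.choice(topology.n_states, p=w / w.sum()))


def simulate_promoter(
    topology: PromoterTopology,
    params: KineticParams,
    duration: float,
    rng,
    initial_state=None,
) -> EventLog:
    """Simulate the promoter cycle with the stochastic simulation algorithm.

    The cycle visits its states in fixed order, each dwell drawn from an
    exponential with the per-state exit rate; initiations are a Poisson
    process at ``k_init`` while in any ON state.  ``initial_state`` may be a
    state index, ``"steady_state"`` (occupancy-weighted draw, default) or
    ``"induction"`` (first OFF state).

    Bit-reproducible for a given ``rng`` state.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates = _state_rates(topology, params)
    if initial_state is None or initial_state == "steady_state":
        s0 = _initial_state(topology, rates, "steady_state", rng)
    elif initial_state == "induction":
        s0 = 0
    else:
        s0 = int(initial_state)

    n_states = topology.n_states
    mean_cycle = params.t_on + params.t_off
    block = max(16, int(duration / mean_cycle * n_states * 1.3) + 2 * n_states)

    states_parts, dwell_parts, elapsed, offset = [], [], 0.0, 0
    while elapsed <= duration:
        seq = (s0 + offset + np.arange(block)) % n_states
        dw = rng.exponential(1.0, size=block) / rates[seq]
        states_parts.append(seq)
        dwell_parts.append(dw)
        elapsed += float(dw.sum())
        offset += block
    states = np.concatenate(states_parts)
    dwells = np.concatenate(dwell_parts)
    entry = np.concatenate([[0.0], np.cumsum(dwells)[:-1]])
    keep = entry < duration
    states, entry = states[keep], entry[keep]

    ends = np.append(entry[1:], np.inf)
    on_mask = states >= topology.n_off
    starts = entry[on_mask]
    stops = np.minimum(ends[on_mask], duration)
    lengths = stops - starts
    counts = rng.poisson(params.k_init * lengths)
    total = int(counts.sum())
    if total:
        u = rng.random(total)
        inits = np.repeat(starts, counts) + u * np.repeat(lengths, counts)
        inits.sort()
    else:
        inits = np.empty(0)

    return EventLog(
        state_switch_times=entry,
        state_indices=states,
        initiation_times=inits,
        duration=float(duration),
        n_off=topology.n_off,
        n_on=topology.n_on,
    )


def _render_intensity(inits: np.ndarray, profile: SignalProfile, grid: np.ndarray) -> np.ndarray:
    """Superposition of unit profiles via cumulative counts (O((n+m) log n))."""
    if len(inits) == 0:
        return np.zeros(len(grid))
    csum = np.concatenate([[0.0], np.cumsum(inits)])
    n_gone = np.searchsorted(inits, grid - profile.residence, side="right")
    n_plateau = np.searchsorted(inits, grid - profile.delay - profile.ramp, side="right")
    out = (n_plateau - n_gone).astype(float)
    if profile.ramp > 0:
        n_ramp = np.searchsorted(inits, grid - profile.delay, side="right")
        cnt = n_ramp - n_plateau
        ssum = csum[n_ramp] - csum[n_plateau]
        out += ((grid - profile.delay) * cnt - ssum) / profile.ramp
    return out


def render_trace(
    events: EventLog,
    profile: SignalProfile,
    grid: np.ndarray,
    cell_id: int = 0,
    allele_id: int = 0,
    condition: str = "",
) -> CellTrace:
    """Render the noise-free fluorescence trace on an imaging grid (minutes)."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) and (grid.min() < 0 or grid.max() > events.duration):
        raise ValueError("grid must lie within the simulated span")
    intensity = _render_intensity(events.initiation_times, profile, grid)
    return CellTrace(cell_id, allele_id, grid, intensity, condition)


# ---------------------------------------------------------------------------
# extrinsic noise


def _truncated_normal(mean: float, cv: float, rng, floor_frac: float = 0.05) -> float:
    """Normal(mean, cv*mean) resampled to stay above ``floor_frac * mean``."""
    if cv == 0:
        return mean
    floor = floor_frac * mean
    for _ in range(100):
        x = rng.normal(mean, cv * mean)
        if x >= floor:
            return float(x)
    return float(floor)


def sample_extrinsic(
    params: KineticParams, topology: PromoterTopology, rng
) -> KineticParams:
    """One per-cell realization of the extrinsic-noise model.

    Each parameter selected by the topology's noise variant is redrawn from
    a truncated normal around its population mean (sd = cv * mean, floored
    at 5% of the mean); unselected parameters are untouched.  Derived
    quantities are recomputed from the realized rates: resampling ``k_on``
    or ``k_off`` moves ``t_off``/``t_on``, resampling ``k_init`` moves the
    realized burst size, and ``k_elong`` rescales the signal profile.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    selected = topology.resampled
    if not selected:
        return replace(params, cv_ext=dict(params.cv_ext))

    t_on, t_off = params.t_on, params.t_off
    k_elong = params.k_elong
    k_init = params.k_init
    init_resampled = False

    # draw in fixed name order for reproducibility
    for name in ("k_elong", "k_init", "k_on", "k_off"):
        if name not in selected:
            continue
        cv = float(params.cv_ext.get(name, 0.0))
        if name == "k_elong":
            k_elong = _truncated_normal(params.k_elong, cv, rng)
        elif name == "k_init":
            k_init = _truncated_normal(params.k_init, cv, rng)
            init_resampled = True
        elif name == "k_on":
            t_off = topology.n_off / _truncated_normal(params.k_on(topology), cv, rng)
        elif name == "k_off":
            t_on = topology.n_on / _truncated_normal(params.k_off(topology), cv, rng)

    if init_resampled:
        burst = k_init * t_on
    else:
        burst = params.burst_size  # k_init follows any t_on change
    return KineticParams(
        t_on=t_on, t_off=t_off, burst_size=burst, k_elong=k_elong,
        cv_ext=dict(params.cv_ext),
    )


# ---------------------------------------------------------------------------
# populations


def _simulate_traces(
    model: PromoterModelSpec,
    n_cells: int,
    protocol: Protocol,
    alleles_per_cell: int,
    rng,
) -> TraceDataset:
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if alleles_per_cell not in (1, 2):
        raise ValueError("alleles_per_cell must be 1 or 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    grid_rel = protocol.times
    induction = protocol.kind == "induction"
    if induction:
        # promoter released at the stimulus; pre-stimulus signal is exactly 0
        sim_span = max(grid_rel[-1] - protocol.stimulus_min, protocol.frame_interval_min)
        grid_sim = grid_rel - protocol.stimulus_min
        post = grid_sim >= 0
    else:
        sim_span = protocol.equilibration_min + grid_rel[-1]
        grid_sim = protocol.equilibration_min + grid_rel
        post = np.ones(len(grid_rel), dtype=bool)

    n_traces = n_cells * alleles_per_cell
    intensity = np.zeros((n_traces, len(grid_rel)))
    cell_ids = np.repeat(np.arange(n_cells), alleles_per_cell)
    allele_ids = np.tile(np.arange(alleles_per_cell), n_cells)

    row = 0
    for _cell in range(n_cells):
        eff = sample_extrinsic(model.params, model.topology, rng)
        prof = model.profile.scaled(eff.k_elong / model.params.k_elong)
        for _allele in range(alleles_per_cell):
            ev = simulate_promoter(
                model.topology, eff, sim_span + 1e-9, rng,
                initial_state="induction" if induction else "steady_state",
            )
            intensity[row, post] = _render_intensity(
                ev.initiation_times, prof, grid_sim[post]
            )
            row += 1

    return TraceDataset(
        intensity=intensity, times=grid_rel, cell_ids=cell_ids,
        allele_ids=allele_ids, condition="", protocol=protocol,
    )


def simulate_population(
    model: PromoterModelSpec,
    n_cells: int,
    protocol: Protocol | None = None,
    alleles_per_cell: int = 1,
    rng=None,
    condition: str = "",
) -> TraceDataset:
    """Simulate a steady-state cell population.

    One extrinsic-noise realization is drawn per cell and shared across its
    alleles; promoter trajectories are independent between alleles.  The
    first ``protocol.equilibration_min`` minutes are simulated but not
    reported, so the promoter-state distribution has relaxed by frame 0.
    """
    protocol = protocol or Protocol()
    if protocol.kind != "steady_state":
        raise ValueError("simulate_population expects a steady_state protocol")
    ds = _simulate_traces(model, n_cells, protocol, alleles_per_cell, rng)
    ds.condition = condition
    return ds


def simulate_induction(
    model: PromoterModelSpec,
    n_cells: int,
    protocol: Protocol = INDUCTION_PROTOCOL,
    rng=None,
    condition: str = "",
) -> TraceDataset:
    """Simulate a synchronized induction experiment.

    All cells sit in the first OFF state until the stimulus at
    ``protocol.stimulus_min``; pre-stimulus frames carry zero true signal.
    """
    if protocol.kind != "induction":
        raise ValueError("simulate_induction expects an induction protocol")
    ds = _simulate_traces(model, n_cells, protocol, 1, rng)
    ds.condition = condition
    return ds
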