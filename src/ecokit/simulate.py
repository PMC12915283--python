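"""Synthetic-data generators for every pipeline input.

The generators emulate the structure of a dyadic emotional-contagion study:
tail-shock ladder sessions with sigmoid intensity-response pupil transients,
blink artifacts, per-region c-Fos density tables for control (CTR),
demonstrator (DEM) and observer (OBS) groups with planted group effects and
a planted within-dyad shared latent factor, weighted directed connectomes
with planted communities and hub/authority nodes, and the two visual-stimulus
frame transforms (Fourier phase scrambling and vertical inversion).

All generators are pure functions of their seed: the same config and seed
produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .preprocess import PUPIL, RawTrace, StimulusEvent
from .psychometrics import sigmoid

# Evoked pupil transient: smoothstep rise after a short latency, a flat
# plateau spanning the whole 1-2 s scoring window, then a slow smoothstep
# decay.  The plateau guarantees that the downstream window mean equals the
# planted peak amplitude after order-6 / 1.5 s Savitzky-Golay smoothing
# (verified to <0.3% at design time); a peaked kernel would make the window
# mean a shape-dependent fraction of the peak.
_KERNEL_LATENCY = 0.2  # s
_KERNEL_RISE = 0.5  # s
_KERNEL_PLATEAU_END = 2.9  # s
_KERNEL_DECAY = 2.0  # s


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def evoked_kernel(sampling_rate: float) -> np.ndarray:
    """Unit-amplitude evoked transient sampled at ``sampling_rate``."""
    t = np.arange(0.0, _KERNEL_PLATEAU_END + _KERNEL_DECAY + 0.25, 1.0 / sampling_rate)
    up = _smoothstep((t - _KERNEL_LATENCY) / _KERNEL_RISE)
    down = 1.0 - _smoothstep((t - _KERNEL_PLATEAU_END) / _KERNEL_DECAY)
    return up * down


@dataclass(frozen=True)
class SessionSimConfig:
    """Parameters of one simulated tail-shock ladder session.

    The defaults mirror the study protocol: 20 Hz acquisition, an ascending
    then descending ladder of 0/50/150/300/500 uA shocks repeated three
    times (six trials per level), 60 s between stimuli, and a generating
    sigmoid with threshold 250 uA.  ``noise_sd`` is Gaussian jitter on the
    per-trial peak amplitude, in z-units.
    """

    sampling_rate: float = 20.0
    ladder: tuple = (0.0, 50.0, 150.0, 300.0, 500.0)
    repeats_per_level: int = 3
    inter_stimulus_interval: float = 60.0
    true_params: tuple = (0.05, 0.9, 0.02, 250.0)  # (b, L, k, x0)
    noise_sd: float = 0.05
    blink_rate: float = 2.0  # events/min
    blink_amplitude: float = 5.0  # z-units
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.repeats_per_level < 1:
            raise ConfigurationError("repeats_per_level must be >= 1")
        if any(i < 0 for i in self.ladder) or not self.ladder:
            raise ConfigurationError("ladder intensities must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.blink_rate < 0:
            raise ConfigurationError("blink_rate must be nonnegative")


def ladder_sequence(config: SessionSimConfig) -> list[float]:
    """The per-session intensity sequence: ascending then descending ladder
    (each starting from the first rung), repeated ``repeats_per_level`` times,
    so every level occurs ``2 * repeats_per_level`` times."""
    asc = list(config.ladder)
    desc = [asc[0]] + list(reversed(asc[1:]))
    return (asc + desc) * config.repeats_per_level


def simulate_pupil_session(config: SessionSimConfig):
    """Simulate one session; returns ``(RawTrace, list[StimulusEvent])``.

    Each stimulus onset is followed by an evoked transient whose peak
    amplitude is ``sigmoid(intensity; true_params) + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    seq = ladder_sequence(config)
    lead, tail = 10.0, 10.0
    n = int(round((lead + len(seq) * config.inter_stimulus_interval + tail) * fs))
    values = np.zeros(n)
    kernel = evoked_kernel(fs)
    b, L, k, x0 = config.true_params
    events = []
    for i, intensity in enumerate(seq):
        onset = lead + i * config.inter_stimulus_interval
        events.append(StimulusEvent(onset=onset, intensity=intensity))
        amp = sigmoid(intensity, b, L, k, x0) + rng.normal(0.0, config.noise_sd)
        start = int(round(onset * fs))
        stop = min(start + kernel.size, n)
        values[start:stop] += amp * kernel[: stop - start]
    trace = RawTrace(values=values, sampling_rate=fs, channel=PUPIL)
    if config.blink_rate > 0:
        trace = inject_blinks(
            trace,
            rate=config.blink_rate,
            amplitude=config.blink_amplitude,
            seed=int(rng.integers(2**31)),
        )
    return trace, events


def inject_blinks(
    trace: RawTrace, rate: float, amplitude: float = 5.0, seed: int = 0
) -> RawTrace:
    """Insert V-shaped blink-like drops at Poisson-distributed times.

    Each artifact is a 2-5 sample V-shaped excursion of the given amplitude,
    producing the high-derivative signature the cleaning step targets.
    ``rate`` is in events per minute; rate 0 returns an unchanged copy.
    """
    if rate < 0:
        raise ConfigurationError("blink rate must be nonnegative")
    values = trace.values.copy()
    if rate == 0:
        return replace(trace, values=values)
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * trace.duration / 60.0)
    for _ in range(n_events):
        width = int(rng.integers(2, 6))  # 2-5 samples
        start = int(rng.integers(1, max(2, values.size - width - 1)))
        # V-shaped dip with a slightly off-center apex: adjacent depths are
        # always distinct, so every within-artifact first difference is
        # nonzero and the artifact cannot hide from the median-filtered
        # derivative track as a flat-bottomed notch would.
        dist = np.abs(np.arange(width) - (width - 1) / 2.0 - 0.3)
        depth = -amplitude * (1.0 - dist / (dist.max() + 1.0))
        values[start : start + width] += depth
    return replace(trace, values=values)


@dataclass(frozen=True)
class CfosSimConfig:
    """Parameters of a simulated three-group c-Fos study.

    Group sizes default to the study's 6 CTR / 7 DEM / 7 OBS animals.
    Densities are lognormal; activated regions are shifted by
    ``effect_log_fold`` on the log scale in the corresponding group(s);
    ``coupled_regions`` receive a dyad-level latent factor (one draw per
    dyad, loading on every coupled region in both animals) whose loading is
    compensated so the density-scale Pearson correlation between paired OBS
    and DEM animals equals ``dyad_coupling_r`` in each coupled region.
    """

    n_regions: int = 88
    n_per_group: tuple = (6, 7, 7)  # (CTR, DEM, OBS)
    activated_regions_dem: frozenset = frozenset()
    activated_regions_obs: frozenset = frozenset()
    effect_log_fold: float = 1.0
    dyad_coupling_r: float = 0.0
    coupled_regions: frozenset = frozenset()
    baseline_log_mean: float = float(np.log(300.0))  # ~300 cells/mm^3
    baseline_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "activated_regions_dem", frozenset(self.activated_regions_dem))
        object.__setattr__(self, "activated_regions_obs", frozenset(self.activated_regions_obs))
        object.__setattr__(self, "coupled_regions", frozenset(self.coupled_regions))
        if not 0 <= self.dyad_coupling_r < 1:
            raise ConfigurationError("dyad_coupling_r must lie in [0, 1)")
        if any(c < 1 for c in self.n_per_group) or len(self.n_per_group) != 3:
            raise ConfigurationError("n_per_group must be three counts >= 1")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        universe = set(range(self.n_regions))
        for s in (self.activated_regions_dem, self.activated_regions_obs, self.coupled_regions):
            if not s <= universe:
                raise ConfigurationError("region index sets must lie within range(n_regions)")
        shared = self.activated_regions_dem & self.activated_regions_obs
        if not self.coupled_regions <= shared:
            raise ConfigurationError(
                "coupled_regions must be activated in both DEM and OBS"
            )


@dataclass
class CfosStudy:
    """A simulated region table plus its ground truth."""

    table: pd.DataFrame
    activated_dem: frozenset
    activated_obs: frozenset
    coupled: frozenset
    pairing: list  # (obs_animal_id, dem_animal_id)
    regions: list


def _compensated_log_corr(r: float, s: float) -> float:
    """Log-scale correlation giving density-scale Pearson correlation r
    for lognormal margins with log-sd s."""
    if r == 0 or s == 0:
        return r
    return float(np.log1p(r * np.expm1(s**2)) / s**2)


def simulate_cfos_study(config: CfosSimConfig) -> CfosStudy:
    """Simulate per-animal per-region c-Fos counts, volumes and densities."""
    rng = np.random.default_rng(config.seed)
    n_ctr, n_dem, n_obs = config.n_per_group
    if n_dem != n_obs:
        raise ConfigurationError("dyad pairing requires equal DEM and OBS counts")
    regions = [f"R{i:03d}" for i in range(config.n_regions)]
    volumes = rng.lognormal(mean=0.0, sigma=0.3, size=config.n_regions)  # ~1 mm^3

    s = config.baseline_log_sd
    r_log = _compensated_log_corr(config.dyad_coupling_r, s)
    coupled = np.zeros(config.n_regions, dtype=bool)
    coupled[list(config.coupled_regions)] = True
    dem_fx = np.zeros(config.n_regions)
    dem_fx[list(config.activated_regions_dem)] = config.effect_log_fold
    obs_fx = np.zeros(config.n_regions)
    obs_fx[list(config.activated_regions_obs)] = config.effect_log_fold

    rows = []

    def emit(animal, group, dyad, log_density):
        density = np.exp(log_density)
        counts = np.round(density * volumes)
        for r_i, region in enumerate(regions):
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "dyad_id": dyad,
                    "region_acronym": region,
                    "count": counts[r_i],
                    "volume_mm3": volumes[r_i],
                }
            )

    for i in range(n_ctr):
        noise = rng.normal(size=config.n_regions)
        emit(f"CTR{i:02d}", "CTR", None, config.baseline_log_mean + s * noise)

    pairing = []
    lam = np.where(coupled, np.sqrt(r_log), 0.0)
    for d in range(n_dem):
        # one latent factor per dyad, loading on every coupled region: this
        # yields the target within-dyad correlation per region and, as a
        # side effect of the shared state, interregional co-activation among
        # coupled regions within each animal
        shared = rng.normal()
        for group, fx in (("DEM", dem_fx), ("OBS", obs_fx)):
            own = rng.normal(size=config.n_regions)
            noise = lam * shared + np.sqrt(1.0 - lam**2) * own
            emit(f"{group}{d:02d}", group, f"dyad{d:02d}", config.baseline_log_mean + fx + s * noise)
        pairing.append((f"OBS{d:02d}", f"DEM{d:02d}"))

    table = pd.DataFrame(rows)
    table["density"] = table["count"] / table["volume_mm3"]
    return CfosStudy(
        table=table,
        activated_dem=config.activated_regions_dem,
        activated_obs=config.activated_regions_obs,
        coupled=config.coupled_regions,
        pairing=pairing,
        regions=regions,
    )


@dataclass(frozen=True)
class NetworkSimConfig:
    """Parameters of a simulated weighted directed connectome."""

    n_nodes: int = 40
    module_sizes: tuple = (20, 20)
    p_within: float = 0.5
    p_between: float = 0.05
    weight_scale: float = 1.0
    planted_hub_nodes: frozenset = frozenset()
    planted_authority_nodes: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_hub_nodes", frozenset(self.planted_hub_nodes))
        object.__setattr__(
            self, "planted_authority_nodes", frozenset(self.planted_authority_nodes)
        )
        if sum(self.module_sizes) != self.n_nodes:
            raise ConfigurationError("module_sizes must sum to n_nodes")
        if not 0 <= self.p_between <= self.p_within <= 1:
            raise ConfigurationError("require 0 <= p_between <= p_within <= 1")
        if self.weight_scale <= 0:
            raise ConfigurationError("weight_scale must be positive")


def simulate_connectome(config: NetworkSimConfig) -> nx.DiGraph:
    """Simulate a weighted directed graph with planted modules and hubs.

    Node attribute ``module`` records the planted community; planted hub
    nodes receive strong out-edges to every planted authority node.  The
    graph never contains self-loops.
    """
    rng = np.random.default_rng(config.seed)
    module_of = np.repeat(np.arange(len(config.module_sizes)), config.module_sizes)
    names = [f"N{i:03d}" for i in range(config.n_nodes)]
    g = nx.DiGraph()
    for i, name in enumerate(names):
        g.add_node(name, module=int(module_of[i]))
    same = module_of[:, None] == module_of[None, :]
    p = np.where(same, config.p_within, config.p_between)
    np.fill_diagonal(p, 0.0)
    present = rng.random((config.n_nodes, config.n_nodes)) < p
    weights = config.weight_scale * rng.lognormal(mean=0.0, sigma=0.5, size=p.shape)
    for i, j in zip(*np.nonzero(present)):
        g.add_edge(names[i], names[j], weight=float(weights[i, j]))
    for h in config.planted_hub_nodes:
        for a in config.planted_authority_nodes:
            if h != a:
                g.add_edge(names[h], names[a], weight=5.0 * config.weight_scale)
    return g


def phase_scramble_frames(frames, seed: int = 0) -> np.ndarray:
    """Randomize the Fourier phase of each frame, preserving its amplitude
    spectrum (and hence luminance, contrast and spatial-frequency content).

    A fresh random phase field is drawn per frame as the phase of the FFT of
    white noise, which is conjugate-symmetric by construction so the output
    stays real; the zero-frequency phase offset is forced to 0 so the mean
    luminance is untouched.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise InputError("empty frame stack")
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    if stack.ndim != 3:
        raise InputError("expected a 2-D frame or a 3-D frame stack")
    rng = np.random.default_rng(seed)
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        spectrum = np.fft.fft2(frame)
        offset = np.angle(np.fft.fft2(rng.normal(size=frame.shape)))
        offset[0, 0] = 0.0
        out[i] = np.fft.ifft2(np.abs(spectrum) * np.exp(1j * (np.angle(spectrum) + offset))).real
    return out[0] if single else out


def invert_frames(frames) -> np.ndarray:
    """Vertically flip every frame (row order reversed); an involution."""
    frames = np.asarray(frames)
    if frames.size == 0:
        raise InputError("empty frame stack")
    if frames.ndim not in (2, 3):
        raise InputError("expected a 2-D frame or a 3-D frame stack")
    return np.flip(frames, axis=-2).copy()
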