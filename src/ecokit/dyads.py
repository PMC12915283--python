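"""Within-dyad coupling of regional c-Fos activation against a shuffled-pair null.

Each observer (OBS) is paired with the demonstrator (DEM) it actually
watched.  For each region of interest the Pearson correlation of densities
across true OBS-DEM pairs is compared with a surrogate distribution built
from re-pairings in which *no* observer keeps its true demonstrator
(derangements of the pair map), and a region is flagged as coupled only if
its observed correlation strictly exceeds the 95th percentile (Weibull
plotting positions, linearly interpolating between the closest order
statistics) of its surrogate distribution — one-sided, positive only.

Note that with a handful of dyads this rule is anticonservative: the
surrogate correlations are anti-correlated with the observed one
(E[r_surrogate | data] ~ -r_observed/(n_dyads - 1)), so the effective null
flag rate exceeds the naive 5%.  The pipeline reproduces the rule as
published; its empirical null level is characterized in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfos import compute_density, density_matrix
from .exceptions import ConfigurationError, InputError
from .stats import count_derangements


@dataclass(frozen=True)
class DyadPairing:
    """True (observer, demonstrator) pairs; each animal in exactly one pair."""

    pairs: tuple  # of (obs_animal_id, dem_animal_id)

    def __init__(self, pairs):
        object.__setattr__(self, "pairs", tuple((o, d) for o, d in pairs))
        obs = [o for o, _ in self.pairs]
        dem = [d for _, d in self.pairs]
        if len(set(obs)) != len(obs) or len(set(dem)) != len(dem):
            raise InputError("an animal appears in more than one pair")
        if set(obs) & set(dem):
            raise InputError("OBS and DEM animal sets must be disjoint")

    @property
    def n_dyads(self) -> int:
        return len(self.pairs)

    @property
    def obs_ids(self):
        return [o for o, _ in self.pairs]

    @property
    def dem_ids(self):
        return [d for _, d in self.pairs]


def select_shared_regions(screen_obs_vs_ctr, screen_dem_vs_ctr) -> set:
    """Regions significantly *increased* versus control in both groups."""
    universe_a = set(screen_obs_vs_ctr.table["region_acronym"])
    universe_b = set(screen_dem_vs_ctr.table["region_acronym"])
    if universe_a != universe_b:
        raise InputError("screens cover different region universes")
    return screen_obs_vs_ctr.increased_regions() & screen_dem_vs_ctr.increased_regions()


def _paired_matrices(table: pd.DataFrame, pairing: DyadPairing, regions):
    if "density" not in table.columns:
        table = compute_density(table)
    regions = sorted(regions)
    obs = density_matrix(table, "OBS").loc[pairing.obs_ids]
    dem = density_matrix(table, "DEM").loc[pairing.dem_ids]
    for name, m in (("OBS", obs), ("DEM", dem)):
        missing = set(regions) - set(m.columns)
        if missing:
            raise InputError(f"{name} animals lack data for region(s) {sorted(missing)}")
    return obs[regions].to_numpy(), dem[regions].to_numpy(), regions


def _colwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, r) matrices."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ac * bc).sum(axis=0) / denom


def dyad_correlation(table: pd.DataFrame, pairing: DyadPairing, regions) -> pd.Series:
    """Observed per-region Pearson r across the true OBS-DEM pairs."""
    if pairing.n_dyads < 3:
        raise InputError("need >= 3 dyads for a correlation")
    obs, dem, regions = _paired_matrices(table, pairing, regions)
    return pd.Series(_colwise_pearson(obs, dem), index=regions, name="observed_r")


def sample_derangements(n: int, n_samples: int, seed: int = 0) -> np.ndarray:
    """Sample distinct fixed-point-free permutations of range(n) without replacement."""
    available = count_derangements(n)
    if n_samples > available:
        raise InputError(
            f"requested {n_samples} derangements but only {available} exist for n={n}"
        )
    rng = np.random.default_rng(seed)
    chosen: dict = {}
    while len(chosen) < n_samples:
        perm = rng.permutation(n)
        if np.all(perm != np.arange(n)):
            chosen.setdefault(tuple(perm), None)
    return np.array(list(chosen), dtype=int)


def surrogate_null(
    table: pd.DataFrame,
    pairing: DyadPairing,
    regions,
    n_shuffles: int = 42,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region surrogate r distribution from deranged re-pairings.

    Each surrogate re-pairs every observer with a wrong demonstrator
    (a derangement of the pair map); the ``n_shuffles`` derangements are
    drawn without replacement and reproducibly under ``seed``.
    """
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    if pairing.n_dyads < 3:
        raise InputError("need >= 3 dyads to form mismatched pairings")
    obs, dem, regions = _paired_matrices(table, pairing, regions)
    perms = sample_derangements(pairing.n_dyads, n_shuffles, seed=seed)
    rows = [_colwise_pearson(obs, dem[perm]) for perm in perms]
    return pd.DataFrame(rows, columns=regions)


@dataclass
class DyadCouplingResult:
    """Per-region dyad-coupling outcome against the surrogate null."""

    table: pd.DataFrame  # region, observed_r, threshold, significant
    surrogates: pd.DataFrame
    percentile: float

    @property
    def coupled_regions(self) -> set:
        return set(self.table.loc[self.table["significant"], "region_acronym"])


def flag_coupled_regions(
    observed: pd.Series,
    surrogates: pd.DataFrame,
    percentile: float = 95.0,
    pooled: bool = False,
) -> DyadCouplingResult:
    """Flag regions whose observed r strictly exceeds the surrogate percentile.

    The threshold is the given percentile (linear interpolation between
    closest ranks) of each region's own surrogate distribution, or of the
    pooled distribution across regions when ``pooled=True``.
    """
    if not 0 < percentile < 100:
        raise ConfigurationError("percentile must lie in (0, 100)")
    if surrogates.empty:
        raise InputError("surrogate distributions are empty")
    # Weibull (median-unbiased) plotting positions: the p-th percentile of
    # n sorted values interpolates between order statistics floor(p(n+1)) and
    # ceil(p(n+1)) -- for 42 surrogates the 95th lies between ranks 40 and 41.
    if pooled:
        thr_value = float(
            np.percentile(surrogates.to_numpy().ravel(), percentile, method="weibull")
        )
        thresholds = pd.Series(thr_value, index=surrogates.columns)
    else:
        thresholds = pd.Series(
            np.percentile(surrogates.to_numpy(), percentile, axis=0, method="weibull"),
            index=surrogates.columns,
        )
    table = pd.DataFrame(
        {
            "region_acronym": observed.index,
            "observed_r": observed.to_numpy(),
            "threshold": thresholds.loc[observed.index].to_numpy(),
        }
    )
    table["significant"] = table["observed_r"] > table["threshold"]
    return DyadCouplingResult(table=table, surrogates=surrogates, percentile=percentile)


def minmax_scale(values) -> np.ndarray:
    """Min-max scale to [0, 1]; display only, never used for the statistics."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.isclose(x.max(), x.min()):
        raise InputError("min-max scaling undefined for constant input")
    return (x - x.min()) / (x.max() - x.min())


def dyad_coupling_analysis(
    table: pd.DataFrame,
    pairing: DyadPairing,
    regions,
    n_shuffles: int = 42,
    percentile: float = 95.0,
    seed: int = 0,
    pooled: bool = False,
) -> DyadCouplingResult:
    """Observed correlations, surrogate null and flags in one call."""
    observed = dyad_correlation(table, pairing, regions)
    surrogates = surrogate_null(table, pairing, regions, n_shuffles=n_shuffles, seed=seed)
    return flag_coupled_regions(observed, surrogates, percentile=percentile, pooled=pooled)
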