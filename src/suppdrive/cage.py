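"""Discrete-generation cage population dynamics for a suppression drive.

Populations reproduce in non-overlapping generations: adults mate at random
(monandry), females contribute offspring in proportion to their genotype's
fecundity weight, the next adult genotype pool experiences one generation of
Wright-Fisher drift at effective size ``Ne``, and the census follows a
saturating (Beverton-Holt-style) density-dependent reproduction rule with an
optional Allee term.  Elimination — census zero or no fertile females left —
is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import (
    CARRIER_MASK,
    DriveParams,
    fertility_weights,
    offspring_tensor,
)

__all__ = [
    "CageState",
    "ReleaseConfig",
    "DemographyParams",
    "Trajectory",
    "initialize_release",
    "step_deterministic",
    "step_stochastic",
    "simulate_cage",
    "carrier_frequency",
    "genetic_load",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class CageState:
    """Adult population at one generation.

    ``freq_female`` / ``freq_male`` are genotype frequency vectors over the
    six allele pairs (W/W, D/W, R/W, D/D, D/R, R/R); at birth the two sexes
    are genetically identical, but both are kept so sex-specific extensions
    stay possible.  ``census`` is the adult count; ``eliminated`` marks a
    collapsed population (frequencies are then meaningless and zeroed).
    """

    generation: int
    freq_female: np.ndarray
    freq_male: np.ndarray
    census: int
    eliminated: bool = False

    def __post_init__(self) -> None:
        for name in ("freq_female", "freq_male"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (6,):
                raise ValueError(f"{name} must have shape (6,)")
            if not self.eliminated:
                if abs(v.sum() - 1.0) > _FREQ_TOL or (v < -_FREQ_TOL).any():
                    raise ValueError(f"{name} is not a probability vector: {v}")
        if self.census < 0:
            raise ValueError("census must be non-negative")


@dataclass(frozen=True)
class ReleaseConfig:
    """Release composition for generation 0.

    A fraction ``p0`` of individuals are drive carriers (default genotype
    D/W, heterozygous at the drive locus, on a Cas9-fixed background) and the
    rest wild-type at the drive locus.
    """

    p0: float
    n0: int = 500
    carrier_genotype_index: int = 1  # D/W
    background_genotype_index: int = 0  # W/W

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")


@dataclass(frozen=True)
class DemographyParams:
    """Drift and density-dependence parameters.

    ``ne``: effective population size for Wright-Fisher drift on genotypes.
    ``low_density_growth``: expected adult offspring per fully fertile female
    at low density.  ``capacity``: adult carrying capacity.
    ``allee_threshold``: optional census scale below which per-female output
    is reduced by the factor N/(N + threshold).
    """

    ne: float = 200.0
    low_density_growth: float = 6.0
    capacity: int = 2000
    allee_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.low_density_growth <= 0 or self.capacity <= 0:
            raise ValueError("ne, low_density_growth and capacity must be positive")
        if self.allee_threshold is not None and self.allee_threshold <= 0:
            raise ValueError("allee_threshold must be positive when set")


@dataclass
class Trajectory:
    """Ordered cage states plus the per-generation phenotype summary.

    In the experiments emulated here every adult of every generation is
    phenotyped for the drive fluorescence marker, so ``n_phenotyped`` equals
    the census and ``n_carriers`` is the drive-carrier count.
    """

    states: list[CageState] = field(default_factory=list)
    n_phenotyped: list[int] = field(default_factory=list)
    n_carriers: list[int] = field(default_factory=list)

    def append(self, state: CageState, n_phen: int, n_carr: int) -> None:
        if self.states and state.generation != self.states[-1].generation + 1:
            raise ValueError("generation indices must be consecutive")
        self.states.append(state)
        self.n_phenotyped.append(int(n_phen))
        self.n_carriers.append(int(n_carr))

    @property
    def generations(self) -> list[int]:
        return [s.generation for s in self.states]

    @property
    def eliminated(self) -> bool:
        return bool(self.states) and self.states[-1].eliminated

    def carrier_frequencies(self) -> np.ndarray:
        return np.array(
            [k / n if n else 0.0 for k, n in zip(self.n_carriers, self.n_phenotyped)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "n_phenotyped": self.n_phenotyped,
                "n_carriers": self.n_carriers,
                "census": [s.census for s in self.states],
                "eliminated": [s.eliminated for s in self.states],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        traj = cls()
        gen0 = int(df["generation"].iloc[0])
        for _, row in df.iterrows():
            n = int(row["census"])
            elim = bool(row["eliminated"])
            freq = np.zeros(6)
            if not elim:
                p = row["n_carriers"] / row["n_phenotyped"] if row["n_phenotyped"] else 0.0
                freq = np.array([1.0 - p, p, 0, 0, 0, 0])  # carriers folded into D/W
            traj.append(
                CageState(
                    int(row["generation"]),
                    freq,
                    freq,
                    n,
                    eliminated=elim,
                ),
                int(row["n_phenotyped"]),
                int(row["n_carriers"]),
            )
        return traj


def initialize_release(cfg: ReleaseConfig) -> CageState:
    """Generation-0 adult pool: fraction ``p0`` drive carriers, rest background."""
    freq = np.zeros(6)
    freq[cfg.carrier_genotype_index] += cfg.p0
    freq[cfg.background_genotype_index] += 1.0 - cfg.p0
    return CageState(0, freq.copy(), freq.copy(), cfg.n0)


def _eliminated_state(generation: int) -> CageState:
    return CageState(generation, np.zeros(6), np.zeros(6), 0, eliminated=True)


def _expected_offspring_frequencies(
    state: CageState, T: np.ndarray, fert: np.ndarray
) -> tuple[np.ndarray, float]:
    """Expected next-generation genotype frequencies and mean female fecundity.

    Random mating with monandry: each female of genotype m (weighted by her
    fecundity) pairs with a male drawn from the male frequency vector.
    """
    w = state.freq_female * fert
    mean_fec = w.sum()
    if mean_fec <= 0.0:
        return np.zeros(6), 0.0
    nxt = np.einsum("m,f,mfo->o", w / mean_fec, state.freq_male, T)
    nxt = np.clip(nxt, 0.0, None)
    return nxt / nxt.sum(), mean_fec


def _expected_census(
    state: CageState, mean_fecundity: float, dem: DemographyParams
) -> float:
    """Density-dependent reproduction: saturating output with optional Allee."""
    females = state.census / 2.0
    out = dem.low_density_growth * females * mean_fecundity
    if dem.allee_threshold is not None and state.census > 0:
        out *= state.census / (state.census + dem.allee_threshold)
    return min(float(dem.capacity), out)


def step_deterministic(
    state: CageState, dp: DriveParams, dem: DemographyParams, T: np.ndarray | None = None
) -> CageState:
    """Expected next generation: genetics + density dependence, no drift."""
    if state.eliminated:
        raise ValueError("cannot step an eliminated population")
    if T is None:
        T = offspring_tensor(dp)
    fert = fertility_weights(dp)
    nxt, mean_fec = _expected_offspring_frequencies(state, T, fert)
    if mean_fec <= 0.0:
        return _eliminated_state(state.generation + 1)
    census = int(round(_expected_census(state, mean_fec, dem)))
    if census == 0:
        return _eliminated_state(state.generation + 1)
    return CageState(state.generation + 1, nxt.copy(), nxt.copy(), census)


def step_stochastic(
    state: CageState,
    dp: DriveParams,
    dem: DemographyParams,
    rng: np.random.Generator,
    T: np.ndarray | None = None,
) -> CageState:
    """One stochastic generation.

    The deterministic expectation is perturbed by one multinomial draw of
    size ``Ne`` (genetic drift, sexes pooled), the census is drawn Poisson
    around the density-dependent expectation (capped at capacity), and the
    realised adult genotype counts are a multinomial of the census from the
    drifted frequencies.
    """
    if state.eliminated:
        raise ValueError("cannot step an eliminated population")
    if T is None:
        T = offspring_tensor(dp)
    fert = fertility_weights(dp)
    expected, mean_fec = _expected_offspring_frequencies(state, T, fert)
    if mean_fec <= 0.0:
        return _eliminated_state(state.generation + 1)
    census = int(min(dem.capacity, rng.poisson(_expected_census(state, mean_fec, dem))))
    if census == 0:
        return _eliminated_state(state.generation + 1)
    ne = int(round(dem.ne))
    drift_counts = rng.multinomial(ne, expected)
    drifted = drift_counts / ne
    adult_counts = rng.multinomial(census, drifted)
    freqs = adult_counts / census
    # a finite population with no possibly-fertile female genotype is done
    if (freqs * fert).sum() <= 0.0:
        return _eliminated_state(state.generation + 1)
    return CageState(state.generation + 1, freqs.copy(), freqs.copy(), census)


def carrier_frequency(state: CageState) -> float:
    """Fraction of individuals carrying at least one drive allele."""
    if state.eliminated:
        return 0.0
    return float(
        0.5 * (state.freq_female[CARRIER_MASK].sum() + state.freq_male[CARRIER_MASK].sum())
    )


def genetic_load(state: CageState, dp: DriveParams) -> float:
    """Proportional loss of female reproductive output relative to wild-type.

    ``1 - mean fecundity weight`` over the female genotype distribution; a
    pure wild-type population has load 0, an all-sterile-female population
    load 1.
    """
    if state.eliminated:
        return 1.0
    fert = fertility_weights(dp)
    return float(1.0 - (state.freq_female * fert).sum())


def simulate_cage(
    cfg: ReleaseConfig,
    dp: DriveParams,
    dem: DemographyParams,
    generations: int,
    seed: int | np.random.Generator,
) -> Trajectory:
    """Simulate a cage for up to ``generations`` stochastic steps.

    Every adult is phenotyped each generation (``n_phenotyped`` = census);
    the carrier count is binomial in the realised carrier frequency.  Stops
    early if the population is eliminated.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = offspring_tensor(dp)
    state = initialize_release(cfg)
    traj = Trajectory()

    def record(s: CageState) -> None:
        if s.eliminated:
            traj.append(s, 0, 0)
        else:
            # adult genotype counts are integral multiples of 1/census in the
            # frequency vector, so this recovers the exact carrier count
            k = int(round(s.census * 0.5 * (
                s.freq_female[CARRIER_MASK].sum() + s.freq_male[CARRIER_MASK].sum()
            )))
            traj.append(s, s.census, k)

    record(state)
    for _ in range(generations):
        if state.eliminated:
            break
        state = step_stochastic(state, dp, dem, rng, T=T)
        record(state)
    return traj
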