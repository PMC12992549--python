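"""Synthetic data generators for every input the pipeline consumes.

Each generator mirrors the statistical structure the corresponding estimator
assumes: vial-level inheritance counts are overdispersed binomials with a
logit-normal batch effect, fertility tables use negative-binomial daily egg
counts with binomial egg-to-adult survival, and cage observation tables come
from the stochastic cage simulator itself, with the ground truth returned
alongside for recovery studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import special

from .cage import DemographyParams, ReleaseConfig, simulate_cage
from .genetics import DriveParams, expected_inheritance_rate
from .inference import CageObservations

__all__ = [
    "gen_cross_vials",
    "gen_cage_obs",
    "gen_fertility_data",
    "CageTruth",
]


def gen_cross_vials(
    n_vials: int,
    seed: int | np.random.Generator,
    rate: float | None = None,
    dp: DriveParams | None = None,
    drive_parent_sex: str = "female",
    sigma_vial: float = 0.5,
    mean_offspring: float = 50.0,
    cross_class: str = "drive_het_x_wt",
) -> pd.DataFrame:
    """Per-vial drive inheritance counts with a logit-scale batch effect.

    Each vial draws a random intercept z ~ N(0, sigma_vial^2), an offspring
    count ~ Poisson(mean_offspring) conditioned positive, and a carrier count
    ~ Binomial(n, expit(logit(rate) + z)).  The mean rate defaults to the
    model's expected inheritance rate for the given drive parameters and
    drive-parent sex.  ``sigma_vial`` = 0 recovers a pure binomial.
    """
    if n_vials < 1:
        raise ValueError("n_vials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate is None:
        if dp is None:
            raise ValueError("provide either rate or dp")
        c = dp.c_f if drive_parent_sex == "female" else dp.c_m
        rate = expected_inheritance_rate(c, dp.germline_cut_rate)
    if not 0.0 < rate < 1.0:
        raise ValueError("mean rate must be strictly inside (0, 1)")
    rows = []
    mu = special.logit(rate)
    for i in range(n_vials):
        z = rng.normal(0.0, sigma_vial) if sigma_vial > 0 else 0.0
        n = 0
        while n == 0:
            n = int(rng.poisson(mean_offspring))
        p = float(special.expit(mu + z))
        k = int(rng.binomial(n, p))
        rows.append(
            {
                "vial_id": f"v{i:03d}",
                "cross_class": cross_class,
                "n_offspring": n,
                "n_carriers": k,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CageTruth:
    """Ground-truth parameters behind a generated cage observation table."""

    dp: DriveParams
    dem: DemographyParams
    release: ReleaseConfig
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "drive_params": asdict(self.dp),
            "demography": asdict(self.dem),
            "release": asdict(self.release),
            "seed": self.seed,
        }


def gen_cage_obs(
    release: ReleaseConfig,
    dp: DriveParams,
    dem: DemographyParams,
    generations: int,
    seed: int | np.random.Generator,
) -> tuple[CageObservations, CageTruth]:
    """Cage observation table from a stochastic simulation under known truth."""
    traj = simulate_cage(release, dp, dem, generations, seed)
    obs = CageObservations.from_trajectory(traj, release)
    truth = CageTruth(dp, dem, release, seed if isinstance(seed, int) else None)
    return obs, truth


def gen_fertility_data(
    n_per_group: dict[str, int],
    mu_eggs: dict[str, float],
    survival: dict[str, float],
    seed: int | np.random.Generator,
    dispersion: float = 10.0,
    days: int = 3,
) -> pd.DataFrame:
    """Per-female fecundity and egg-to-adult viability table.

    Daily egg counts are negative-binomial (mean per group, shared dispersion
    ``k``; batches of flies are overdispersed relative to Poisson) over
    ``days`` consecutive days; survivors are binomial in the group's
    egg-to-adult survival probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rows = []
    for group, n in n_per_group.items():
        mu = mu_eggs[group]
        v = survival[group]
        if not 0.0 <= v <= 1.0:
            raise ValueError("survival must be a probability")
        for i in range(n):
            if mu <= 0:
                eggs = np.zeros(days, dtype=int)
            else:
                p_nb = dispersion / (dispersion + mu)
                eggs = rng.negative_binomial(dispersion, p_nb, size=days)
            n_eggs = int(eggs.sum())
            n_adults = int(rng.binomial(n_eggs, v)) if n_eggs else 0
            row = {
                "female_id": f"{group}_{i:03d}",
                "group": group,
                "n_eggs": n_eggs,
                "n_adults": n_adults,
                "mean_eggs_per_day": n_eggs / days,
            }
            row.update({f"eggs_d{d + 1}": int(eggs[d]) for d in range(days)})
            rows.append(row)
    return pd.DataFrame(rows)
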