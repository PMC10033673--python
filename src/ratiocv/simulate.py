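"""Seeded synthetic trait tables with known log-normal structure.

Each group (stand-in for a species) draws its values from a log-normal
distribution: log-values ~ Normal(nu_g, theta_g), with the group
parameters sampled uniformly from configurable ranges.  The true CV of
group g is then sqrt(exp(theta_g**2) - 1) regardless of nu_g, which
gives every pipeline stage an exact ground truth to recover.  Optional
multiplicative contamination (a fraction of records multiplied by a
factor) emulates the occasional extreme field measurement; because the
contamination is multiplicative on the primary trait, it is asymmetric
under record-wise inversion — precisely the mechanism that makes the
plain CV disagree between a trait and its reciprocal.

Defaults emulate a community leaf-trait survey: 30 species, 100 records
each, log-mean range matching SLA of roughly 90-400 cm^2/g, log-SD
(theta) in [0.2, 1.0] giving true CVs of about 0.2-1.3.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence`; parameter draws, value draws and
contamination use independently spawned streams, so switching
contamination on does not perturb the base values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .measures import MomentSet, lognormal_cv
from .pipeline import GROUP_COL, VALUE_COL, TraitTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_groups",
    "contaminate",
    "simulate_bivariate_organs",
    "replicate_configs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic dataset.

    Parameters
    ----------
    n_groups, n_per_group
        Number of groups and records per group (scalar or one count per
        group).
    nu_range, theta_range
        Uniform sampling intervals for the per-group log-mean and log-SD.
    contamination_rate, contamination_factor
        Each record is independently multiplied by ``factor`` with
        probability ``rate`` (rate 0 disables contamination).
    seed
        Master seed; everything downstream is reproducible from it.
    """

    n_groups: int = 30
    n_per_group: int | Sequence[int] = 100
    nu_range: tuple[float, float] = (4.5, 6.0)
    theta_range: tuple[float, float] = (0.2, 1.0)
    contamination_rate: float = 0.0
    contamination_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        sizes = self.group_sizes()
        if len(sizes) != self.n_groups:
            raise ConfigurationError(
                f"n_per_group lists {len(sizes)} sizes for "
                f"{self.n_groups} groups"
            )
        if min(sizes) < 2:
            raise ConfigurationError("every group needs n_per_group >= 2")
        for name, (lo, hi) in (("nu_range", self.nu_range),
                               ("theta_range", self.theta_range)):
            if hi < lo:
                raise ConfigurationError(f"{name} must be ordered, got {lo, hi}")
        if self.theta_range[0] < 0:
            raise ConfigurationError("theta_range must be non-negative")
        if not 0 <= self.contamination_rate < 1:
            raise ConfigurationError("contamination_rate must be in [0, 1)")
        if self.contamination_rate > 0 and self.contamination_factor <= 1:
            raise ConfigurationError("contamination_factor must be > 1")

    def group_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_group):
            return [int(self.n_per_group)] * self.n_groups
        return [int(n) for n in self.n_per_group]


@dataclass(frozen=True)
class SyntheticDataset:
    """A trait table plus the ground truth it was generated from.

    ``truth`` is indexed by group with columns ``nu``, ``theta``,
    ``true_cv`` (= sqrt(exp(theta**2) - 1)) and ``n``;
    ``contaminated_ids`` lists the row labels of records that were
    multiplied by the contamination factor.
    """

    table: TraitTable
    truth: pd.DataFrame = field(repr=False)
    contaminated_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def truth_json(self, indent: int = 2) -> str:
        payload = {
            "groups": {
                gid: {k: (int(v) if k == "n" else float(v))
                      for k, v in row.items()}
                for gid, row in self.truth.iterrows()
            },
            "contaminated_ids": [int(i) for i in self.contaminated_ids],
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_groups(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset according to ``config``.

    Per group: nu_g ~ U(nu_range), theta_g ~ U(theta_range), values =
    exp(Normal(nu_g, theta_g, n_g)).  Contamination, if configured, is
    applied afterwards on an independent stream.
    """
    params_ss, values_ss, contam_ss = _spawn_seeds(config.seed, 3)
    rng_params = np.random.default_rng(params_ss)
    rng_values = np.random.default_rng(values_ss)

    sizes = config.group_sizes()
    group_ids = [f"group{i + 1:03d}" for i in range(config.n_groups)]
    nu = rng_params.uniform(*config.nu_range, size=config.n_groups)
    theta = rng_params.uniform(*config.theta_range, size=config.n_groups)

    frames = []
    for gid, n, nu_g, theta_g in zip(group_ids, sizes, nu, theta):
        values = np.exp(rng_values.normal(nu_g, theta_g, size=n))
        frames.append(pd.DataFrame({GROUP_COL: gid, VALUE_COL: values}))
    data = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({
        "nu": nu,
        "theta": theta,
        "true_cv": [lognormal_cv(t) for t in theta],
        "n": sizes,
    }, index=pd.Index(group_ids, name=GROUP_COL))

    ds = SyntheticDataset(
        table=TraitTable(data=data, trait_name="sim_trait", unit="cm^2/g"),
        truth=truth,
    )
    if config.contamination_rate > 0:
        contam_seed = int(contam_ss.generate_state(1)[0] % 2**31)
        ds = contaminate(ds, rate=config.contamination_rate,
                         factor=config.contamination_factor,
                         seed=contam_seed)
    return ds


def contaminate(dataset: SyntheticDataset, rate: float, factor: float,
                seed: int) -> SyntheticDataset:
    """Multiply each record by ``factor`` independently with probability ``rate``.

    Records not selected are bit-identical to the input; selected row
    labels are recorded in ``contaminated_ids`` even when ``factor`` is
    1 (identity multiplier).
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("rate must be in [0, 1)")
    if factor < 1:
        raise ConfigurationError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    data = dataset.table.data.copy()
    mask = rng.random(len(data)) < rate
    data.loc[mask, VALUE_COL] = data.loc[mask, VALUE_COL] * factor
    return SyntheticDataset(
        table=TraitTable(data=data, trait_name=dataset.table.trait_name,
                         unit=dataset.table.unit),
        truth=dataset.truth,
        contaminated_ids=data.index.to_numpy()[mask],
    )


def simulate_bivariate_organs(n: int, mu_x: float, mu_y: float,
                              sigma_x: float, sigma_y: float,
                              rho: float = 0.0, seed: int = 0,
                              ) -> tuple[pd.DataFrame, MomentSet]:
    """Paired positive organ measurements from a correlated bivariate normal.

    Requires both means at least 5 SDs above zero so the ratio x/y is
    well behaved; the rare non-positive draw is rejected and redrawn.
    Returns the paired table and the empirical :class:`MomentSet`
    (means, SDs, covariance of the accepted draws) for feeding the
    Taylor formulas.
    """
    if sigma_x < 0 or sigma_y < 0:
        raise ConfigurationError("sigmas must be non-negative")
    if abs(rho) > 1:
        raise ConfigurationError("rho must be in [-1, 1]")
    if mu_x < 5 * sigma_x or mu_y < 5 * sigma_y or mu_x <= 0 or mu_y <= 0:
        raise ConfigurationError(
            "means must be positive and at least 5 sigmas above zero"
        )
    rng = np.random.default_rng(seed)

    def draw(size: int) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.standard_normal(size)
        z2 = rng.standard_normal(size)
        x = mu_x + sigma_x * z1
        y = mu_y + sigma_y * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        return x, y

    x, y = draw(n)
    bad = (x <= 0) | (y <= 0)
    while bad.any():  # negligible rejection at >= 5 sigma
        x[bad], y[bad] = draw(int(bad.sum()))
        bad = (x <= 0) | (y <= 0)

    empirical = MomentSet(
        mu_x=float(x.mean()), mu_y=float(y.mean()),
        sigma_x=float(x.std(ddof=1)), sigma_y=float(y.std(ddof=1)),
        cov_xy=float(np.cov(x, y, ddof=1)[0, 1]),
    )
    return pd.DataFrame({"x": x, "y": y}), empirical


def replicate_configs(base: SimulationConfig, n_replicates: int,
                      seed: int) -> list[SimulationConfig]:
    """Derive ``n_replicates`` independent configs from one master seed."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % 2**31
    return [replace(base, seed=int(s)) for s in seeds]
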