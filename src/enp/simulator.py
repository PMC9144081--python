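"""Synthetic subjects and cohorts for hardware-free testing.

Two generators:

* a standing-subject stream generator producing eight-cell load frames with
  configurable quadrant shares, per-cell Gaussian sensor noise and linear
  drift — the signal an eight-load-cell plate would see; and
* a cohort generator producing study-style records (arch type, plantar
  pressures regressed on weight and height, and correlated torso/pelvis
  posture shifts per bag type).

Randomness discipline: a single integer seed fans out to per-component
child streams keyed by a CRC of the component name, so adding one component
never perturbs another component's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import CELL_POSITIONS, QUADRANT_REGIONS, LoadCellFrame
from .exceptions import UsageError

ARCH_TYPES = ("high", "medium", "low")
BAG_TYPES = ("backpack", "tote", "sling")

#: Quadrant body-weight shares of a balanced subject: the population
#: quadrant setpoints renormalized to sum to one.
BALANCED_SHARES: dict[str, float] = {
    q: s / 32.7 for q, s in {"L.toe": 6.4, "R.toe": 6.4, "L.heel": 10.1, "R.heel": 9.8}.items()
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Child RNG for one named component of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(component.encode())])
    )


@dataclass
class SubjectSpec:
    """One standing subject on the plate.

    Parameters
    ----------
    total_weight : float
        Body weight in kg.
    region_shares : dict
        Fraction of body weight on each of the four quadrants; must sum to 1.
    noise_sd : float
        Per-cell, per-frame Gaussian sensor noise SD in kg.
    drift_rate : float
        Linear drift of each quadrant load in kg/s (sensor creep or sway).
    medial_lateral_split : float
        Fraction of a quadrant's load carried by its medial cell.
    frame_interval_s : float
        Time between frames (50 Hz default).
    """

    total_weight: float = 70.0
    region_shares: dict[str, float] = field(default_factory=lambda: dict(BALANCED_SHARES))
    noise_sd: float = 0.05
    drift_rate: float = 0.0
    medial_lateral_split: float = 0.5
    frame_interval_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_weight <= 0:
            raise UsageError("total_weight must be positive")
        if set(self.region_shares) != set(QUADRANT_REGIONS):
            raise UsageError(f"region_shares must cover exactly {QUADRANT_REGIONS}")
        if any(s < 0 for s in self.region_shares.values()):
            raise UsageError("region shares must be non-negative")
        if abs(sum(self.region_shares.values()) - 1.0) > 1e-12:
            raise UsageError("region shares must sum to 1")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be non-negative")
        if not 0.0 <= self.medial_lateral_split <= 1.0:
            raise UsageError("medial_lateral_split must be in [0, 1]")


def simulate_frames(spec: SubjectSpec, n_frames: int) -> list[LoadCellFrame]:
    """Generate a reproducible stream of eight-cell frames for one subject.

    Per frame at time t: each quadrant carries
    ``total_weight * share + drift_rate * t`` kg, split between its medial
    and lateral cell by the split fraction, with independent Gaussian noise
    added per cell.
    """
    if n_frames < 1:
        raise UsageError("n_frames must be >= 1")
    rng = component_rng(spec.seed, "frames")
    split = {"medial": spec.medial_lateral_split, "lateral": 1.0 - spec.medial_lateral_split}
    frames = []
    for i in range(n_frames):
        t = i * spec.frame_interval_s
        noise = rng.normal(0.0, spec.noise_sd, size=8) if spec.noise_sd > 0 else np.zeros(8)
        readings = {}
        for j, p in enumerate(CELL_POSITIONS):
            quad = spec.total_weight * spec.region_shares[p.quadrant] + spec.drift_rate * t
            readings[p] = quad * split[p.side] + float(noise[j])
        frames.append(LoadCellFrame(timestamp=t, readings=readings))
    return frames


@dataclass
class PressureModel:
    """Linear model for plantar pressure (kPa) on weight and height."""

    mean: float
    slope_weight: float  # kPa per kg about the cohort mean weight
    slope_height: float  # kPa per cm about the cohort mean height
    noise_sd: float


@dataclass
class BagModel:
    """Torso/pelvis posture-shift model for one bag type (chart units)."""

    rho: float
    torso_mean: float = 4.0
    torso_sd: float = 2.0
    pelvis_mean: float = 3.0
    pelvis_sd: float = 2.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise UsageError("bag-model correlation must be in [-1, 1]")


@dataclass
class CohortSpec:
    """A synthetic study cohort of standing young adults.

    Defaults emulate the study conditions: 1034 subjects, arch frequencies
    31% high / 54% medium / 15% low, weak pressure-anthropometry
    correlations, and per-bag torso-pelvis correlations 0.82 (backpack),
    0.49 (tote) and 0.94 (sling).
    """

    n: int = 1034
    arch_frequencies: dict[str, float] = field(
        default_factory=lambda: {"high": 0.31, "medium": 0.54, "low": 0.15}
    )
    mean_height_cm: float = 170.0
    sd_height_cm: float = 8.0
    mean_weight_kg: float = 65.0
    sd_weight_kg: float = 10.0
    height_weight_rho: float = 0.5
    forefoot: PressureModel = field(
        default_factory=lambda: PressureModel(45.0, -0.16, 0.19, 12.0)
    )
    rearfoot: PressureModel = field(
        default_factory=lambda: PressureModel(55.0, 0.20, 0.19, 12.0)
    )
    bags: dict[str, BagModel] = field(
        default_factory=lambda: {
            "backpack": BagModel(rho=0.82),
            "tote": BagModel(rho=0.49),
            "sling": BagModel(rho=0.94),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise UsageError("cohort size n must be >= 1")
        if set(self.arch_frequencies) != set(ARCH_TYPES):
            raise UsageError(f"arch_frequencies must cover exactly {ARCH_TYPES}")
        if any(p < 0 for p in self.arch_frequencies.values()):
            raise UsageError("arch frequencies must be non-negative")
        if abs(sum(self.arch_frequencies.values()) - 1.0) > 1e-9:
            raise UsageError("arch frequencies must sum to 1")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort table, reproducible under the spec's seed.

    Columns: id, age, height_cm, weight_kg, shoe_size, arch_type,
    forefoot_kpa, rearfoot_kpa, then torso_shift_<bag> / pelvis_shift_<bag>
    for each bag type.  Torso/pelvis shifts per bag are bivariate normal
    with the configured correlation via the latent construction
    ``pelvis_z = rho * torso_z + sqrt(1 - rho^2) * eps``.
    """
    n = spec.n
    rng_anthro = component_rng(spec.seed, "anthropometry")
    rng_arch = component_rng(spec.seed, "arch")
    rng_press = component_rng(spec.seed, "pressure")

    # correlated height/weight via a latent bivariate normal
    z_h = rng_anthro.normal(size=n)
    z_w = spec.height_weight_rho * z_h + np.sqrt(1 - spec.height_weight_rho**2) * rng_anthro.normal(
        size=n
    )
    height = spec.mean_height_cm + spec.sd_height_cm * z_h
    weight = spec.mean_weight_kg + spec.sd_weight_kg * z_w
    age = rng_anthro.integers(18, 24, size=n)
    shoe = np.round(36.0 + 0.12 * (height - spec.mean_height_cm) + rng_anthro.normal(0, 1.2, n), 0)

    arch = rng_arch.choice(ARCH_TYPES, size=n, p=[spec.arch_frequencies[a] for a in ARCH_TYPES])

    def pressure(m: PressureModel) -> np.ndarray:
        return (
            m.mean
            + m.slope_weight * (weight - spec.mean_weight_kg)
            + m.slope_height * (height - spec.mean_height_cm)
            + rng_press.normal(0, m.noise_sd, n)
        )

    data = {
        "id": np.arange(1, n + 1),
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "shoe_size": shoe,
        "arch_type": arch,
        "forefoot_kpa": pressure(spec.forefoot),
        "rearfoot_kpa": pressure(spec.rearfoot),
    }

    for bag in BAG_TYPES:
        if bag not in spec.bags:
            continue
        m = spec.bags[bag]
        rng_bag = component_rng(spec.seed, f"bag:{bag}")
        torso_z = rng_bag.normal(size=n)
        eps = rng_bag.normal(size=n)
        pelvis_z = m.rho * torso_z + np.sqrt(max(0.0, 1 - m.rho**2)) * eps
        data[f"torso_shift_{bag}"] = m.torso_mean + m.torso_sd * torso_z
        data[f"pelvis_shift_{bag}"] = m.pelvis_mean + m.pelvis_sd * pelvis_z

    return pd.DataFrame(data)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
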