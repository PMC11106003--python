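"""Radiochemical arithmetic for single-particle work.

Decay correction, spherical-particle mass and activity-per-particle,
absolute particle counting against counting beads (flow cytometry),
percent injected dose per gram, and a stochastic model of the four-tube
serial-transfer fractionation protocol used to isolate one radiolabelled
particle from a suspension.

The fractionation protocol splits a 50 ul sample by serial transfer
(37.5 ul -> second tube, 25 ul -> third, 12.5 ul -> fourth), leaving
12.5 ul in every tube; for a well-mixed suspension each particle lands in
any tube with probability 1/4, while dissolved ("free") activity divides
deterministically by volume. A single particle is recognised because most
of the measured radioactivity concentrates in one tube.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import GA68_HALF_LIFE_S

__all__ = [
    "GA68_HALF_LIFE_S",
    "ParticleSpec",
    "CountingBeadAssay",
    "FractionationRecord",
    "decay_factor",
    "particle_mass",
    "particles_per_mass",
    "activity_per_particle",
    "absolute_count",
    "simulate_fractionation",
    "classify_fractions",
    "percent_id_per_gram",
]

#: serial-transfer tube probabilities implied by the 50/37.5/25/12.5 ul
#: volumes: 12.5/50, (37.5/50)(12.5/37.5), (37.5/50)(25/37.5)(12.5/25),
#: (37.5/50)(25/37.5)(12.5/25) -> exactly 1/4 each.
TUBE_PROBABILITIES = np.full(4, 0.25)


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical particle: diameter in nm, density in g/cm^3."""

    diameter_nm: float = 950.0
    density_g_cm3: float = 2.2

    def __post_init__(self) -> None:
        if not (self.diameter_nm > 0 and self.density_g_cm3 > 0):
            raise ValueError("diameter and density must be > 0")


@dataclass(frozen=True)
class CountingBeadAssay:
    """Flow-cytometry absolute-count inputs (events, ul, beads/ul)."""

    particle_count: float
    bead_count: float
    bead_volume_ul: float
    particle_volume_ul: float
    bead_concentration_per_ul: float

    def __post_init__(self) -> None:
        if self.particle_count < 0 or self.bead_count < 0:
            raise ValueError("counts must be >= 0")
        if not (self.bead_volume_ul > 0 and self.particle_volume_ul > 0):
            raise ValueError("volumes must be > 0")
        if self.bead_concentration_per_ul < 0:
            raise ValueError("bead concentration must be >= 0")


@dataclass(frozen=True)
class FractionationRecord:
    """One fractionation step: the four tube activities (Bq).

    ``particle_counts`` holds the simulated number of particles per tube;
    ``particle_tube`` is the single particle's tube index when exactly one
    particle was present, else None.
    """

    activities_bq: np.ndarray
    particle_counts: np.ndarray | None = None
    particle_tube: int | None = None

    @property
    def total_bq(self) -> float:
        return float(np.sum(self.activities_bq))

    @property
    def shares(self) -> np.ndarray:
        total = self.total_bq
        if total <= 0:
            raise ValueError("total activity must be > 0")
        return np.asarray(self.activities_bq, dtype=float) / total


# ---------------------------------------------------------------------- #
# closed forms


def decay_factor(elapsed_s: float, half_life_s: float = GA68_HALF_LIFE_S) -> float:
    """Back-correction factor to time zero: 2^(elapsed/half_life).

    Measured activity times this factor gives the activity decay-corrected
    to the reference (injection) time.
    """
    if not half_life_s > 0:
        raise ValueError("half_life_s must be > 0")
    return 2.0 ** (elapsed_s / half_life_s)


def particle_mass(spec: ParticleSpec) -> float:
    """Mass of one spherical particle in grams: density * (pi/6) d^3."""
    d_cm = spec.diameter_nm * 1e-7
    return spec.density_g_cm3 * (math.pi / 6.0) * d_cm**3


def particles_per_mass(spec: ParticleSpec, mass_mg: float = 1.0) -> float:
    """Number of particles in ``mass_mg`` milligrams of material."""
    if mass_mg < 0:
        raise ValueError("mass must be >= 0")
    return mass_mg * 1e-3 / particle_mass(spec)


def activity_per_particle(
    total_activity_bq: float, mass_mg: float, spec: ParticleSpec
) -> float:
    """Average Bq per particle given the total activity on a known mass."""
    if not mass_mg > 0:
        raise ValueError("mass_mg must be > 0")
    n = particles_per_mass(spec, mass_mg)
    return total_activity_bq / n


def absolute_count(assay: CountingBeadAssay) -> float:
    """Particles per microlitre from a counting-bead assay.

    absolute count = (particle events x bead volume)
                     / (bead events x particle volume) x bead concentration
    """
    if assay.bead_count == 0:
        raise ValueError("bead_count must be > 0 for evaluation")
    return (
        assay.particle_count
        * assay.bead_volume_ul
        / (assay.bead_count * assay.particle_volume_ul)
        * assay.bead_concentration_per_ul
    )


def percent_id_per_gram(
    organ_activity_bq: float, injected_activity_bq: float, organ_mass_g: float
) -> float:
    """Percent injected dose per gram of tissue (%ID/g)."""
    if not injected_activity_bq > 0:
        raise ValueError("injected_activity_bq must be > 0")
    if not organ_mass_g > 0:
        raise ValueError("organ_mass_g must be > 0")
    if organ_activity_bq < 0:
        raise ValueError("organ_activity_bq must be >= 0")
    return 100.0 * organ_activity_bq / injected_activity_bq / organ_mass_g


# ---------------------------------------------------------------------- #
# fractionation


def simulate_fractionation(
    n_particles: int,
    activity_per_particle_bq: float,
    free_activity_bq: float,
    n_steps: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[FractionationRecord]:
    """Simulate serial four-tube fractionation steps.

    Each step: every particle lands independently in one of the four tubes
    with probability 1/4 (the serial-transfer volumes make all four equal);
    free activity splits deterministically, 25% per tube. Subsequent steps
    re-fractionate the highest-activity tube after notional re-dilution to
    the starting volume, carrying that tube's particles and free share.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    if activity_per_particle_bq < 0 or free_activity_bq < 0:
        raise ValueError("activities must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    records: list[FractionationRecord] = []
    particles = n_particles
    free = free_activity_bq
    for _ in range(n_steps):
        counts = rng.multinomial(particles, TUBE_PROBABILITIES)
        activities = free * TUBE_PROBABILITIES + counts * activity_per_particle_bq
        tube = int(np.argmax(counts)) if particles == 1 else None
        records.append(
            FractionationRecord(
                activities_bq=activities,
                particle_counts=counts,
                particle_tube=tube,
            )
        )
        carried = int(np.argmax(activities))
        particles = int(counts[carried])
        free = free * float(TUBE_PROBABILITIES[carried])
    return records


def classify_fractions(
    record: FractionationRecord, single_threshold: float = 0.90
) -> str:
    """Label a fractionation outcome from the tube activity shares.

    ``single`` when one tube holds >= ``single_threshold`` of the total
    (a lone particle concentrates the radioactivity); ``colloid_or_free``
    when the maximum share is <= 0.40 (near-uniform spread, the signature
    of colloidal or dissolved activity partitioning by volume); otherwise
    ``ambiguous``. Scale-invariant: only shares matter.
    """
    shares = record.shares  # raises on zero total
    top = float(shares.max())
    if top >= single_threshold:
        return "single"
    if top <= 0.40:
        return "colloid_or_free"
    return "ambiguous"
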