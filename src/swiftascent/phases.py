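"""Annual-cycle phase assignment from position.

A position belongs to the breeding phase while within 200 km of the colony;
otherwise it is migration while still north of the southern border of the
Sahara (15° N), and non-breeding residence south of it.  Both boundaries are
inclusive on the migration side ("at least 200 km", "still north").  The
distance rule is applied first, so a hypothetical position < 200 km from the
colony but south of 15° N would still be labelled breeding.

Because light-level positions are uncertain, each twilight also gets a
probabilistic assignment: the posterior mass falling in each phase region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASES = ("breeding", "migration", "non-breeding")

DEFAULT_COLONY_RADIUS_KM = 200.0
DEFAULT_SAHARA_LAT = 15.0
EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine), vectorised."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return d if np.ndim(d) else float(d)


@dataclass(frozen=True)
class PhaseParams:
    colony_radius_km: float = DEFAULT_COLONY_RADIUS_KM
    sahara_lat: float = DEFAULT_SAHARA_LAT


@dataclass(frozen=True)
class PhaseAssignment:
    event_time: pd.Timestamp
    p_breeding: float
    p_migration: float
    p_nonbreeding: float

    def __post_init__(self):
        total = self.p_breeding + self.p_migration + self.p_nonbreeding
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"phase probabilities sum to {total}, not 1")

    @property
    def hard_label(self) -> str:
        probs = (self.p_breeding, self.p_migration, self.p_nonbreeding)
        return PHASES[int(np.argmax(probs))]


def phase_of_position(lat, lon, colony_lat, colony_lon, params: PhaseParams = PhaseParams()):
    """Hard phase label(s) for position(s); vectorised (returns an object
    array for array input, a string for scalars)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dist = np.asarray(great_circle_km(lat, lon, colony_lat, colony_lon))
    out = np.where(
        dist < params.colony_radius_km,
        "breeding",
        np.where(np.asarray(lat) >= params.sahara_lat, "migration", "non-breeding"),
    )
    return out if out.ndim else str(out)


def phase_region_masks(grid_lat, grid_lon, colony_lat, colony_lon, params: PhaseParams = PhaseParams()):
    """Boolean masks (breeding, migration, non-breeding) over a lat×lon grid;
    the three masks partition the grid."""
    lat2, lon2 = np.meshgrid(np.asarray(grid_lat), np.asarray(grid_lon), indexing="ij")
    dist = great_circle_km(lat2, lon2, colony_lat, colony_lon)
    breeding = dist < params.colony_radius_km
    migration = ~breeding & (lat2 >= params.sahara_lat)
    nonbreeding = ~breeding & ~migration
    return breeding, migration, nonbreeding


def phase_probabilities(posterior, colony_lat, colony_lon, params: PhaseParams = PhaseParams()):
    """Posterior mass per phase region for one twilight.

    ``posterior`` is a PositionPosterior (from swiftascent.geolocation) or
    any object with ``grid_lat``, ``grid_lon``, ``mass`` and ``event_time``.
    """
    masks = phase_region_masks(posterior.grid_lat, posterior.grid_lon, colony_lat, colony_lon, params)
    mass = posterior.mass
    pb, pm, pn = (float(mass[m].sum()) for m in masks)
    total = pb + pm + pn
    return PhaseAssignment(posterior.event_time, pb / total, pm / total, pn / total)
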