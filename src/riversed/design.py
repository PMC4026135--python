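"""Study design and planted-effect parameterisation for synthetic studies.

The default design mirrors a longitudinal river-transect survey: six sites
along a ~134 km stretch, sampled in two seasons over two years with two
replicate sediment samples per visit (48 samples in total).  Sites are
partitioned into three land-use groups used by the group-level pathway tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import InvalidDesignError

SEASONS = ("spring", "fall")

#: Default site positions (km along the transect) and group labels.
DEFAULT_POSITIONS = (0.0, 27.0, 54.0, 80.0, 107.0, 134.0)
DEFAULT_GROUPS = ("G1", "G1", "G2", "G2", "G3", "G3")


@dataclass(frozen=True)
class StudyDesign:
    """Spatial/temporal layout of a synthetic study.

    Parameters
    ----------
    n_sites : int
        Number of sampling sites along the one-dimensional transect (>= 2).
    site_positions_km : tuple of float
        Strictly increasing positions of the sites along the transect.
    n_seasons : int
        Seasons sampled per year (1 or 2; labels drawn from ``SEASONS``).
    n_years : int
        Years sampled.
    n_replicates : int
        Replicate samples per site visit (>= 1).
    site_groups : tuple of str
        Group label per site (e.g. land-use category); drives group-level
        pathway testing.  Defaults to contiguous thirds ``G1/G2/G3``.
    seed : int
        Root seed for every random draw derived from this design.
    """

    n_sites: int = 6
    site_positions_km: tuple[float, ...] = DEFAULT_POSITIONS
    n_seasons: int = 2
    n_years: int = 2
    n_replicates: int = 2
    site_groups: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise InvalidDesignError(f"n_sites must be >= 2, got {self.n_sites}")
        pos = tuple(float(p) for p in self.site_positions_km)
        if len(pos) != self.n_sites:
            raise InvalidDesignError(
                f"{len(pos)} site positions for {self.n_sites} sites"
            )
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidDesignError("site positions must be strictly increasing")
        if not 1 <= self.n_seasons <= len(SEASONS):
            raise InvalidDesignError(f"n_seasons must be in [1, {len(SEASONS)}]")
        if self.n_years < 1:
            raise InvalidDesignError("n_years must be >= 1")
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be >= 1")
        object.__setattr__(self, "site_positions_km", pos)
        groups = tuple(self.site_groups)
        if not groups:
            # contiguous thirds along the transect
            per = max(1, round(self.n_sites / 3))
            groups = tuple(
                f"G{min(i // per + 1, 3)}" for i in range(self.n_sites)
            )
        if len(groups) != self.n_sites:
            raise InvalidDesignError("site_groups must have one label per site")
        object.__setattr__(self, "site_groups", groups)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_sites))

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_seasons * self.n_years * self.n_replicates

    def site_distances(self) -> pd.DataFrame:
        """Pairwise along-transect distances (km) between sites."""
        pos = np.asarray(self.site_positions_km)
        d = np.abs(pos[:, None] - pos[None, :])
        return pd.DataFrame(d, index=self.site_ids, columns=self.site_ids)


@dataclass(frozen=True)
class EnzymeShift:
    """A planted group-specific log2 shift in one enzyme's gene abundance."""

    group: str
    enzyme: str
    log2_shift: float


@dataclass(frozen=True)
class PlantedEffects:
    """Known effects planted into the synthetic data, recoverable downstream.

    Parameters
    ----------
    distance_decay_rate : float
        Rate (per km) at which the correlation of per-OTU log-abundance
        deviations decays along the transect; 0 disables distance decay.
    salinity_baseline, salinity_slope_per_km, salinity_noise_sd : float
        Linear salinity gradient (ppt) along the transect plus Gaussian noise.
    core_fraction : float
        Expected fraction of reads attributable to the designated core taxa.
    enzyme_shifts : tuple of EnzymeShift
        Group-specific log2 shifts applied to enzyme-gene abundances before
        sampling; these induce known pathway flows.
    """

    distance_decay_rate: float = 0.02
    salinity_baseline: float = 0.2
    salinity_slope_per_km: float = 0.003
    salinity_noise_sd: float = 0.05
    core_fraction: float = 0.5
    enzyme_shifts: tuple[EnzymeShift, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.distance_decay_rate < 0:
            raise InvalidDesignError("distance_decay_rate must be >= 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise InvalidDesignError("core_fraction must be in [0, 1]")
        if self.salinity_noise_sd < 0:
            raise InvalidDesignError("salinity_noise_sd must be >= 0")
        object.__setattr__(self, "enzyme_shifts", tuple(self.enzyme_shifts))

    def shifts_for_group(self, group: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in self.enzyme_shifts:
            if s.group == group:
                out[s.enzyme] = out.get(s.enzyme, 0.0) + s.log2_shift
        return out
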