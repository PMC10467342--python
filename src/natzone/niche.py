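"""Nitrate-ammonium transition-zone (NAT) detection and niche confinement.

The NAT zone is the depth interval where downward-diffusing nitrate meets
upward-diffusing ammonium — the habitat of anammox bacteria in marine
sediments. It is bracketed here between the nitrate penetration depth (the
deepest point where NO3− still exceeds a detection threshold) and the
ammonium appearance depth (the shallowest point where NH4+ exceeds its
threshold), both located by linear interpolation between samples.

Confinement of a taxon to the zone is quantified as the fraction of its
summed relative abundance that falls at sampled depths inside the zone,
with significance from a permutation test that shuffles abundances over
depth labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .grid import Grid

__all__ = [
    "ConcentrationProfile",
    "NATZone",
    "AbundanceTable",
    "ConfinementResult",
    "NoTransitionZoneError",
    "detect_nat_zone",
    "rate_maximum_depth",
    "confinement_index",
    "confinement_pvalue",
]


class NoTransitionZoneError(ValueError):
    """Raised when a nitrate-ammonium transition zone cannot be reliably
    resolved from the available profiles (e.g. nitrate never depleted, or
    ammonium absent throughout)."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """A depth-sampled concentration profile (depths m, values µM)."""

    depths: np.ndarray
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)
        if d.size != v.size or d.size < 2:
            raise ValueError("profile needs >= 2 depth/value pairs of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("profile depths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class NATZone:
    """Detected nitrate-ammonium transition zone [z_top, z_bottom] (m).

    ``mode`` records whether the NO3− and NH4+ fronts overlap
    (ammonium appears above the nitrate penetration depth) or leave a gap.
    """

    z_top: float
    z_bottom: float
    eps_no3: float
    eps_nh4: float
    mode: str

    def __post_init__(self) -> None:
        if not 0 <= self.z_top <= self.z_bottom:
            raise ValueError("require 0 <= z_top <= z_bottom")

    def contains(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z >= self.z_top) & (z <= self.z_bottom)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_top + self.z_bottom)

    @property
    def width(self) -> float:
        return self.z_bottom - self.z_top


@dataclass(frozen=True)
class AbundanceTable:
    """Relative abundances of taxa (rows) across sampled depths (columns)."""

    taxa: tuple[str, ...]
    depths: np.ndarray
    values: np.ndarray  # shape (n_taxa, n_depths)

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.taxa), d.size):
            raise ValueError("abundance matrix shape does not match taxa x depths")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if np.any(v < 0):
            raise ValueError("relative abundances must be >= 0")
        if np.any(v.sum(axis=0) > 1 + 1e-9):
            raise ValueError("per-depth abundance sums must be <= 1")

    def taxon(self, name: str) -> np.ndarray:
        try:
            return self.values[self.taxa.index(name)]
        except ValueError:
            raise KeyError(f"unknown taxon {name!r}") from None


@dataclass(frozen=True)
class ConfinementResult:
    """Confinement index with its permutation p-value."""

    index: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.index <= 1):
            raise ValueError("confinement index must be in [0, 1]")
        if not self.p_value >= 1.0 / (self.n_permutations + 1):
            raise ValueError("p-value below the permutation-test floor")


def _final_downcrossing(depths: np.ndarray, values: np.ndarray, eps: float) -> float:
    """Deepest depth where values >= eps, interpolated at the final
    crossing from >= eps to < eps."""
    above = values >= eps
    idx = np.flatnonzero(above)
    k = idx[-1]
    if k == values.size - 1:
        raise NoTransitionZoneError(
            "no resolvable transition zone: profile still above threshold at the deepest sample")
    # linear interpolation inside [z_k, z_{k+1}]
    z0, z1 = depths[k], depths[k + 1]
    v0, v1 = values[k], values[k + 1]
    return float(z0 + (v0 - eps) / (v0 - v1) * (z1 - z0))


def _first_upcrossing(depths: np.ndarray, values: np.ndarray, eps: float) -> float:
    """Shallowest depth where values >= eps, interpolated at the first
    crossing from < eps to >= eps."""
    above = values >= eps
    k = int(np.argmax(above))  # first True
    if k == 0:
        return float(depths[0])
    z0, z1 = depths[k - 1], depths[k]
    v0, v1 = values[k - 1], values[k]
    return float(z0 + (eps - v0) / (v1 - v0) * (z1 - z0))


def detect_nat_zone(no3: ConcentrationProfile, nh4: ConcentrationProfile,
                    eps_no3: float = 1.0, eps_nh4: float = 1.0) -> NATZone:
    """Locate the nitrate-ammonium transition zone.

    ``z_NO3`` is the nitrate penetration depth (final down-crossing of
    ``eps_no3``); ``z_NH4`` is the ammonium appearance depth (first
    up-crossing of ``eps_nh4``). The zone is the interval between them,
    in either order; ``mode`` is ``"overlap"`` when ammonium appears above
    the nitrate penetration depth and ``"gap"`` otherwise.

    Raises
    ------
    NoTransitionZoneError
        If nitrate does not exceed the threshold at the surface, never
        falls below it, or ammonium never exceeds its threshold — the
        profile pattern in which the transition cannot be reliably
        resolved.
    """
    if eps_no3 <= 0 or eps_nh4 <= 0:
        raise ValueError("thresholds must be > 0")
    if no3.values[0] < eps_no3:
        raise NoTransitionZoneError(
            "no resolvable transition zone: NO3- below threshold at the shallowest sample")
    if nh4.values[-1] < eps_nh4:
        raise NoTransitionZoneError(
            "no resolvable transition zone: NH4+ below threshold at the deepest sample")
    z_no3 = _final_downcrossing(no3.depths, no3.values, eps_no3)
    z_nh4 = _first_upcrossing(nh4.depths, nh4.values, eps_nh4)
    mode = "overlap" if z_nh4 < z_no3 else "gap"
    return NATZone(z_top=min(z_no3, z_nh4), z_bottom=max(z_no3, z_nh4),
                   eps_no3=eps_no3, eps_nh4=eps_nh4, mode=mode)


def rate_maximum_depth(rates, grid: Grid) -> float:
    """Depth (m) of the cell with the maximal rate; ties break shallow."""
    r = np.asarray(rates, dtype=float)
    if r.shape != grid.cell_centers.shape:
        raise ValueError("rates do not match the grid")
    if not np.any(r > 0):
        raise ValueError("no active zone: all rates are zero")
    return float(grid.cell_centers[int(np.argmax(r))])


def confinement_index(abundance, depths, zone: NATZone) -> float:
    """Fraction of a taxon's summed relative abundance inside the zone."""
    a = np.asarray(abundance, dtype=float)
    z = np.asarray(depths, dtype=float)
    if a.shape != z.shape:
        raise ValueError("abundance and depth vectors differ in length")
    if np.any(a < 0):
        raise ValueError("abundances must be >= 0")
    total = a.sum()
    if total <= 0:
        raise ValueError("confinement index undefined: zero total abundance")
    # clamp round-off: the in-zone partial sum can exceed the total by 1 ulp
    return min(1.0, float(a[zone.contains(z)].sum() / total))


def confinement_pvalue(abundance, depths, zone: NATZone,
                       n_permutations: int = 999, seed: int | None = None,
                       method: str = "auto") -> ConfinementResult:
    """Permutation test of confinement to the zone.

    The null hypothesis exchanges abundances freely across depth labels;
    the p-value is the standard add-one estimate
    ``(1 + #{permuted index >= observed}) / (n_permutations + 1)``.
    With ``method="auto"`` the test enumerates all ``n!`` permutations
    exactly for up to 7 sampled depths and falls back to seeded Monte
    Carlo sampling otherwise; ``"exhaustive"`` and ``"mc"`` force a mode.
    """
    a = np.asarray(abundance, dtype=float)
    z = np.asarray(depths, dtype=float)
    if a.size != z.size:
        raise ValueError("abundance and depth vectors differ in length")
    if a.size < 2:
        raise ValueError("need >= 2 sampled depths for a permutation test")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    obs = confinement_index(a, z, zone)
    in_zone = zone.contains(z)

    if method == "auto":
        method = "exhaustive" if a.size <= 7 else "mc"
    if method == "exhaustive":
        total = a.sum()
        count = 0
        n_perm = 0
        for perm in permutations(range(a.size)):
            idx = a[list(perm)][in_zone].sum() / total
            count += idx >= obs - 1e-12
            n_perm += 1
        p = (1 + count) / (n_perm + 1)
        return ConfinementResult(index=obs, p_value=float(p), n_permutations=n_perm,
                                 seed=seed, exhaustive=True)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    if seed is None:
        raise ValueError("Monte-Carlo permutation test requires an explicit seed")
    rng = np.random.default_rng(seed)
    total = a.sum()
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(a)[in_zone].sum() / total
        count += idx >= obs - 1e-12
    p = (1 + count) / (n_permutations + 1)
    return ConfinementResult(index=obs, p_value=float(p), n_permutations=n_permutations,
                             seed=seed, exhaustive=False)
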