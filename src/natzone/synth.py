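"""Synthetic porewater profiles and depth-resolved community tables.

Every stage of the pipeline is testable without field data: the forward
model generates "true" porewater profiles which are sampled at discrete
depths with seeded Gaussian noise (truncated at zero), and taxon
depth-abundance distributions are drawn as Gaussian depth niches sampled
with multinomial read noise at a fixed read depth per sample — the
compositional noise structure of family-level 16S amplicon summaries.

Truncating negative noisy concentrations at zero introduces a slight
upward bias near zero-concentration depths; this is documented rather
than corrected, because real porewater data are reported non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import ForwardSetup, ObservedProfileSet
from .grid import SPECIES
from .niche import AbundanceTable
from .solver import solve_steady_state

__all__ = [
    "ScenarioSpec",
    "TaxonNicheSpec",
    "generate_observed",
    "generate_community",
]

OTHER_TAXON = "other"


@dataclass(frozen=True)
class ScenarioSpec:
    """A forward-model setup plus an observation design.

    ``noise_sd`` is the per-species measurement noise; scalar values apply
    to all species. Values are interpreted as absolute µM standard
    deviations.
    """

    setup: ForwardSetup
    sampling_depths: np.ndarray
    noise_sd: dict[str, float] = field(default_factory=lambda: {sp: 0.0 for sp in SPECIES})
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.sampling_depths, dtype=float)
        object.__setattr__(self, "sampling_depths", d)
        L = self.setup.grid.interfaces[-1]
        if np.any(d < 0) or np.any(d > L):
            raise ValueError(f"sampling depths must lie within [0, {L}] m")
        if isinstance(self.noise_sd, (int, float)):
            object.__setattr__(self, "noise_sd", {sp: float(self.noise_sd) for sp in SPECIES})
        for sp, s in self.noise_sd.items():
            if s < 0:
                raise ValueError(f"noise_sd[{sp!r}] must be >= 0")


@dataclass(frozen=True)
class TaxonNicheSpec:
    """Gaussian depth niche of one taxon.

    Expected (unnormalized) relative abundance at depth z is
    ``A * exp(-(z - mu)^2 / (2 sigma^2)) + b``: a peak of amplitude ``A``
    centered at ``mu`` (m) with width ``sigma`` (m) over a flat background
    ``b``.
    """

    name: str
    amplitude: float
    center: float
    width: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0 or not self.width > 0:
            raise ValueError("amplitude and width must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    def expected(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.amplitude * np.exp(-((z - self.center) ** 2) / (2 * self.width**2)) + self.background


def generate_observed(spec: ScenarioSpec) -> ObservedProfileSet:
    """Solve the scenario, sample it at the design depths and add noise.

    Deterministic given ``spec.seed``. Raises if the forward model does
    not converge (the scenario itself is then at fault).
    """
    s = spec.setup
    sol = solve_steady_state(s.grid, s.porosity, s.transport, s.kinetics, s.bc,
                             options=s.solver_options)
    if not sol.converged:
        raise RuntimeError(
            f"scenario forward model did not converge (relative residual {sol.residual_norm:.3e})")
    rng = np.random.default_rng(spec.seed)
    data = {}
    for sp in SPECIES:
        truth = np.interp(spec.sampling_depths, s.grid.cell_centers, sol.concentrations[sp])
        sd = spec.noise_sd.get(sp, 0.0)
        noisy = truth + rng.normal(0.0, sd, size=truth.shape) if sd > 0 else truth.copy()
        sigma = np.full_like(truth, sd if sd > 0 else 1.0)
        data[sp] = (spec.sampling_depths.copy(), np.maximum(noisy, 0.0), sigma)
    return ObservedProfileSet(data)


def generate_community(depths, niches: list[TaxonNicheSpec], reads_per_sample: int,
                       seed: int) -> AbundanceTable:
    """Draw a taxa × depths relative-abundance table.

    Expected proportions follow each taxon's Gaussian niche; a residual
    ``"other"`` taxon absorbs the remaining probability at each depth
    (expected proportions are renormalized if the named taxa alone exceed
    1). Observed proportions are a multinomial draw of
    ``reads_per_sample`` reads per depth divided by the read count, so
    per-depth sums are exactly 1.
    """
    depths = np.asarray(depths, dtype=float)
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if not niches:
        raise ValueError("need at least one taxon niche")
    names = [n.name for n in niches]
    if OTHER_TAXON in names or len(set(names)) != len(names):
        raise ValueError(f"taxon names must be unique and must not include {OTHER_TAXON!r}")

    raw = np.array([n.expected(depths) for n in niches])  # (taxa, depths)
    col_sums = raw.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = depths[col_sums <= 0]
        raise ValueError(f"degenerate composition: zero expected abundance at depths {bad}")
    other = np.maximum(0.0, 1.0 - col_sums)
    full = np.vstack([raw, other])
    probs = full / full.sum(axis=0, keepdims=True)

    rng = np.random.default_rng(seed)
    counts = np.empty_like(probs)
    for j in range(depths.size):
        counts[:, j] = rng.multinomial(reads_per_sample, probs[:, j])
    values = counts / reads_per_sample
    return AbundanceTable(taxa=tuple(names) + (OTHER_TAXON,), depths=depths, values=values)
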