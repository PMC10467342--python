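"""Delimited-text readers/writers for profiles, abundance tables, results.

All tabular I/O is plain text (comma or tab, auto-detected on read,
comma on write) with numbers serialized at 15 significant digits, so every
writer/reader pair round-trips bit-identically for values representable at
that precision.

Formats
-------
profiles
    header ``depth_m,species,concentration_uM[,sigma_uM]``, one row per
    observation.
abundance table
    first column ``taxon``, remaining column headers are depths in meters
    below seafloor; cells are relative abundances in [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult, ObservedProfileSet
from .niche import AbundanceTable, ConcentrationProfile, ConfinementResult, NATZone
from .solver import SolutionState

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_zone",
    "read_abundance_table",
    "write_abundance_table",
    "profiles_to_concentration",
    "write_solution",
    "write_zone",
    "write_confinement",
    "write_calibration",
]

_FMT = "%.15g"
REQUIRED_PROFILE_COLUMNS = ("depth_m", "species", "concentration_uM")


class FormatError(ValueError):
    """A data file violates its documented format."""


def _read_delimited(path) -> pd.DataFrame:
    # sniff comma vs tab from the header; round_trip parsing keeps floats
    # bit-exact so writer/reader pairs are lossless
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_profiles(path) -> ObservedProfileSet:
    """Read a porewater profile table into an :class:`ObservedProfileSet`.

    Rows are grouped by species and sorted by depth. ``sigma_uM`` is
    optional and defaults to 1 µM.
    """
    df = _read_delimited(path)
    for col in REQUIRED_PROFILE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad = df.index[pd.to_numeric(df["concentration_uM"], errors="coerce").isna()]
    if len(bad):
        raise FormatError(f"{path}: non-numeric concentration_uM in row {bad[0] + 2}")
    neg = df.index[df["concentration_uM"].astype(float) < 0]
    if len(neg):
        raise FormatError(f"{path}: negative concentration_uM in row {neg[0] + 2}")
    data = {}
    for sp, grp in df.groupby("species", sort=False):
        d = grp["depth_m"].to_numpy(dtype=float)
        c = grp["concentration_uM"].to_numpy(dtype=float)
        s = (grp["sigma_uM"].to_numpy(dtype=float)
             if "sigma_uM" in grp.columns else np.ones_like(d))
        data[str(sp)] = (d, c, s)
    return ObservedProfileSet(data)


def write_profiles(path, observed: ObservedProfileSet) -> None:
    rows = []
    for sp, (d, c, s) in observed.data.items():
        for di, ci, si in zip(d, c, s):
            rows.append((di, sp, ci, si))
    df = pd.DataFrame(rows, columns=["depth_m", "species", "concentration_uM", "sigma_uM"])
    df.to_csv(path, index=False, float_format=_FMT)


def profiles_to_concentration(observed: ObservedProfileSet, species: str) -> ConcentrationProfile:
    """Extract one species as a :class:`ConcentrationProfile` (sorted)."""
    if species not in observed.data:
        raise KeyError(f"species {species!r} not present in the profile set")
    d, c, _ = observed.data[species]
    return ConcentrationProfile(depths=d, values=c, species=species)


def read_abundance_table(path) -> AbundanceTable:
    """Read a taxa × depths relative-abundance table."""
    df = _read_delimited(path)
    first = df.columns[0]
    taxa = df[first].astype(str).tolist()
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise FormatError(f"{path}: duplicate taxon labels {dup}")
    try:
        depths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: abundance column headers must be depths in meters ({exc})") from exc
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape)
    for (i, j), cell in np.ndenumerate(raw):
        try:
            # python float() parses exactly (round-trip safe), unlike the
            # fast pandas numeric converter
            values[i, j] = float(cell)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric abundance {cell!r} at taxon "
                              f"{taxa[i]!r}, depth {depths[j]} m") from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"{path}: non-numeric abundance at taxon {taxa[i]!r}, depth {depths[j]} m")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(f"{path}: negative abundance at taxon {taxa[i]!r}, depth {depths[j]} m")
    return AbundanceTable(taxa=tuple(taxa), depths=depths, values=values)


def write_abundance_table(path, table: AbundanceTable) -> None:
    df = pd.DataFrame(table.values, index=list(table.taxa),
                      columns=[_FMT % d for d in table.depths])
    df.index.name = "taxon"
    df.to_csv(path, float_format=_FMT)


def write_solution(path, solution: SolutionState, grid) -> None:
    """Write concentrations and reaction rates per cell as delimited text."""
    cols = {"depth_m": grid.cell_centers}
    cols.update({f"{sp}_uM": solution.concentrations[sp] for sp in solution.concentrations})
    cols.update({f"{k}_uM_yr": v for k, v in solution.rates.as_dict().items()})
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FMT)


def _dump_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_zone(path, zone: NATZone) -> None:
    _dump_json(path, {
        "z_top_m": zone.z_top, "z_bottom_m": zone.z_bottom,
        "midpoint_m": zone.midpoint, "width_m": zone.width,
        "eps_no3_uM": zone.eps_no3, "eps_nh4_uM": zone.eps_nh4, "mode": zone.mode,
    })


def read_zone(path) -> NATZone:
    d = json.loads(Path(path).read_text())
    return NATZone(z_top=d["z_top_m"], z_bottom=d["z_bottom_m"],
                   eps_no3=d["eps_no3_uM"], eps_nh4=d["eps_nh4_uM"], mode=d["mode"])


def write_confinement(path, results: dict[str, ConfinementResult]) -> None:
    _dump_json(path, {
        taxon: {
            "index": r.index, "p_value": r.p_value,
            "n_permutations": r.n_permutations, "seed": r.seed,
            "exhaustive": r.exhaustive,
        }
        for taxon, r in results.items()
    })


def write_calibration(path, result: CalibrationResult) -> None:
    _dump_json(path, {
        "params": result.params,
        "objective": result.objective,
        "converged": result.converged,
        "n_forward_evaluations": result.n_forward_evaluations,
        "seed": result.seed,
    })
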