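"""COSMO-RS descriptor engineering for solubility QSPR in deep eutectic solvents.

Two feature sets are assembled per solubility record (one record = one
solute in one DES composition at one temperature):

* **set 1** (16 columns): the five energetic descriptors of the solute
  (total interaction energy and its misfit / hydrogen-bond / van der Waals
  components, plus the chemical potential), the same five for the solvent
  — each DES value being the mole-fraction-weighted mean over the
  solute-free mixture components — their five solute-minus-solvent
  differences (Δ-prefixed), and the COSMO-RS computed log solubility
  ``log_x_cosmo``.
* **set 2** (28 columns): set 1 plus the twelve relative binned
  σ-potential descriptors ΔHBD1..4, ΔHH1..4, ΔHBA1..4.

A σ-potential arrives as a 61-point curve on the screening-charge-density
grid [-0.03, +0.03] e/Å² and is reduced to a 12-step function by averaging
over 0.005-wide intervals; the three 4-bin regions correspond to
hydrogen-bond-donor, hydrophobic and hydrogen-bond-acceptor surface
charge.  Energies pass through in the units of the source tables; the log
solubilities are decadic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGMA_GRID_POINTS",
    "SIGMA_MIN",
    "SIGMA_MAX",
    "BIN_WIDTH",
    "BIN_NAMES",
    "ENERGETIC_FIELDS",
    "SigmaPotential",
    "BinnedSigmaDescriptors",
    "EnergeticDescriptors",
    "FusionData",
    "MixtureSpec",
    "SolubilityRecord",
    "DescriptorTable",
    "bin_sigma_potential",
    "gibbs_fusion",
    "mixture_descriptor",
    "relative_descriptor",
    "assemble_feature_sets",
    "load_energetics_csv",
    "load_sigma_potentials_csv",
    "load_fusion_csv",
    "load_solubility_csv",
]

SIGMA_GRID_POINTS = 61
SIGMA_MIN = -0.03
SIGMA_MAX = 0.03
BIN_WIDTH = 0.005

#: Region names in ascending charge density: donor, hydrophobic, acceptor.
BIN_NAMES: tuple[str, ...] = (
    "HBD1", "HBD2", "HBD3", "HBD4",
    "HH1", "HH2", "HH3", "HH4",
    "HBA1", "HBA2", "HBA3", "HBA4",
)

ENERGETIC_FIELDS: tuple[str, ...] = ("E_int", "E_misfit", "E_HB", "E_vdW", "mu")

SET1_COLUMNS: tuple[str, ...] = (
    tuple(f"{f}_API" for f in ENERGETIC_FIELDS)
    + tuple(f"{f}_DES" for f in ENERGETIC_FIELDS)
    + tuple(f"Δ{f}" for f in ENERGETIC_FIELDS)
    + ("log_x_cosmo",)
)
SET2_EXTRA_COLUMNS: tuple[str, ...] = tuple(f"Δ{b}" for b in BIN_NAMES)
SET2_COLUMNS: tuple[str, ...] = SET1_COLUMNS + SET2_EXTRA_COLUMNS


class DescriptorError(ValueError):
    """Raised on invalid descriptor inputs (bad grid, missing species...)."""


@dataclass(frozen=True)
class SigmaPotential:
    """A 61-point σ-potential curve for one species.

    ``sigma_grid`` holds the screening charge densities in e/Å², strictly
    increasing from -0.03 to +0.03; ``mu_values`` the potential at each
    grid point, in the energy units of the source table.
    """

    species_id: str
    sigma_grid: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.sigma_grid, dtype=float)
        mu = np.asarray(self.mu_values, dtype=float)
        object.__setattr__(self, "sigma_grid", grid)
        object.__setattr__(self, "mu_values", mu)
        if grid.shape != (SIGMA_GRID_POINTS,) or mu.shape != (SIGMA_GRID_POINTS,):
            raise DescriptorError(
                f"sigma potential for {self.species_id!r}: expected "
                f"{SIGMA_GRID_POINTS} grid points, got {grid.size} sigma / "
                f"{mu.size} mu values"
            )
        if not np.all(np.diff(grid) > 0):
            raise DescriptorError(
                f"sigma potential for {self.species_id!r}: grid not strictly increasing"
            )
        if abs(grid[0] - SIGMA_MIN) > 1e-12 or abs(grid[-1] - SIGMA_MAX) > 1e-12:
            raise DescriptorError(
                f"sigma potential for {self.species_id!r}: grid must span "
                f"[{SIGMA_MIN}, {SIGMA_MAX}], got [{grid[0]}, {grid[-1]}]"
            )


@dataclass(frozen=True)
class BinnedSigmaDescriptors:
    """The 12-step reduction of one σ-potential curve."""

    species_id: str
    values: np.ndarray  # ordered as BIN_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BIN_NAMES, map(float, self.values)))


@dataclass(frozen=True)
class EnergeticDescriptors:
    """Five COSMO-RS energetic descriptors of one species (source units)."""

    species_id: str
    E_int: float
    E_misfit: float
    E_HB: float
    E_vdW: float
    mu: float

    def __post_init__(self) -> None:
        for name in ENERGETIC_FIELDS:
            if not math.isfinite(getattr(self, name)):
                raise DescriptorError(
                    f"energetic descriptor {name} of {self.species_id!r} is not finite"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in ENERGETIC_FIELDS}


@dataclass(frozen=True)
class FusionData:
    """Fusion thermodynamics of a solid solute.

    The entropy of fusion is approximated by ΔH_fus / T_m (constant heat
    capacity of fusion), from which the Gibbs energy of fusion at any
    temperature follows.
    """

    solute_id: str
    T_m: float  # K
    dH_fus: float  # energy / mol

    def __post_init__(self) -> None:
        if self.T_m <= 0:
            raise DescriptorError(f"{self.solute_id!r}: T_m must be positive")
        if self.dH_fus <= 0:
            raise DescriptorError(f"{self.solute_id!r}: dH_fus must be positive")

    @property
    def dS_fus(self) -> float:
        return self.dH_fus / self.T_m

    def dG_fus(self, T: float) -> float:
        return gibbs_fusion(self, T)


@dataclass(frozen=True)
class MixtureSpec:
    """Solute-free solvent composition: (species_id, mole fraction) pairs.

    Water in water-diluted systems enters as an ordinary third component.
    """

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((str(s), float(x)) for s, x in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise DescriptorError("mixture must have at least one component")
        if any(x <= 0 for _, x in comps):
            raise DescriptorError("mole fractions must be positive")
        total = sum(x for _, x in comps)
        if abs(total - 1.0) > 1e-9:
            raise DescriptorError(f"mole fractions sum to {total}, expected 1")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.components)


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured point: solute, DES composition, temperature, log x."""

    solute_id: str
    mixture: MixtureSpec
    temperature: float  # K
    log_x: float  # decadic log mole-fraction solubility
    log_x_cosmo: float  # decadic log of the COSMO-RS computed solubility

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DescriptorError(f"{self.solute_id!r}: temperature must be positive")
        if self.log_x > 0:
            raise DescriptorError(
                f"{self.solute_id!r}: log_x = {self.log_x} > 0 implies mole fraction > 1"
            )


@dataclass(frozen=True)
class DescriptorTable:
    """Assembled feature matrix with set-membership tags and the target.

    ``frame`` holds one row per solubility record: the feature columns,
    then the target column.  ``set_tags`` maps every feature column to
    "set1" or "set2-extra"; set 1 is always a subset of set 2.
    """

    frame: pd.DataFrame
    set_tags: Mapping[str, str]
    target: str = "log_x"

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise DescriptorError(f"missing values in columns {bad}")
        unknown = set(self.set_tags.values()) - {"set1", "set2-extra"}
        if unknown:
            raise DescriptorError(f"unknown set tags {sorted(unknown)}")
        missing = set(self.set_tags) - set(self.frame.columns)
        if missing:
            raise DescriptorError(f"tagged columns absent from frame: {sorted(missing)}")

    @property
    def set1_columns(self) -> list[str]:
        return [c for c in self.frame.columns
                if self.set_tags.get(c) == "set1"]

    @property
    def set2_columns(self) -> list[str]:
        return [c for c in self.frame.columns
                if self.set_tags.get(c) in ("set1", "set2-extra")]

    def feature_columns(self, feature_set: str) -> list[str]:
        if feature_set == "set1":
            return self.set1_columns
        if feature_set == "set2":
            return self.set2_columns
        raise ValueError(f"unknown feature set {feature_set!r}")

    @property
    def y(self) -> pd.Series:
        return self.frame[self.target]

    def write_csvs(self, out_dir: str | Path, stem: str = "features") -> None:
        """Write ``<stem>_set1.csv``, ``<stem>_set2.csv`` and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, cols in (("set1", self.set1_columns), ("set2", self.set2_columns)):
            self.frame[cols + [self.target]].to_csv(
                out / f"{stem}_{name}.csv", index=False)
        manifest = {
            "target": self.target,
            "n_records": int(len(self.frame)),
            "set1_columns": self.set1_columns,
            "set2_columns": self.set2_columns,
            "log_base": "decadic",
        }
        (out / f"{stem}_manifest.json").write_text(
            json.dumps(manifest, indent=2, ensure_ascii=False))


# ---------------------------------------------------------------------------
# operations


def bin_sigma_potential(curve: SigmaPotential) -> BinnedSigmaDescriptors:
    """Average a σ-potential over twelve 0.005-wide charge-density bins.

    Bins are half-open ``[lo, lo + 0.005)`` except the last, which is
    closed at +0.03 so the final grid point joins bin 12.  On the standard
    uniform 61-point grid (step 0.001) this puts 5 points in bins 1–11 and
    6 in bin 12.
    """
    # bin index via floor((sigma - min)/width); the +0.03 endpoint lands in
    # bin 12 because of the clip.  A tiny epsilon guards points that sit on
    # an interior edge against float round-off pushing them down a bin.
    idx = np.floor((curve.sigma_grid - SIGMA_MIN) / BIN_WIDTH + 1e-9).astype(int)
    idx = np.clip(idx, 0, len(BIN_NAMES) - 1)
    values = np.empty(len(BIN_NAMES))
    for b in range(len(BIN_NAMES)):
        members = curve.mu_values[idx == b]
        if members.size == 0:
            raise DescriptorError(
                f"sigma potential for {curve.species_id!r}: no grid point falls "
                f"in bin {BIN_NAMES[b]}"
            )
        values[b] = members.mean()
    return BinnedSigmaDescriptors(species_id=curve.species_id, values=values)


def gibbs_fusion(fd: FusionData, T: float) -> float:
    """Gibbs energy of fusion ΔG_fus = ΔH_fus · (1 − T / T_m).

    Follows from ΔG_fus = ΔH_fus − T·ΔS_fus with ΔS_fus = ΔH_fus/T_m.
    Zero at the melting point; units follow ``dH_fus``.
    """
    if T <= 0:
        raise DescriptorError("temperature must be positive")
    return fd.dH_fus * (1.0 - T / fd.T_m)


def mixture_descriptor(values: Mapping[str, float], mix: MixtureSpec) -> float:
    """Mole-fraction-weighted mean of a per-species descriptor over a mixture."""
    missing = [s for s in mix.species_ids if s not in values]
    if missing:
        raise DescriptorError(f"no descriptor value for component(s) {missing}")
    return float(sum(x * float(values[s]) for s, x in mix.components))


def relative_descriptor(solute_value: float, des_value: float) -> float:
    """Solute-minus-solvent difference; reported under a Δ-prefixed name."""
    if not (math.isfinite(solute_value) and math.isfinite(des_value)):
        raise DescriptorError("relative descriptor requires finite inputs")
    return float(solute_value) - float(des_value)


def assemble_feature_sets(
    records: Sequence[SolubilityRecord],
    energetics: Mapping[str, EnergeticDescriptors],
    sigma_potentials: Mapping[str, SigmaPotential],
) -> DescriptorTable:
    """Build the 16-column set-1 / 28-column set-2 descriptor table.

    Every species referenced by a record must have energetic descriptors;
    solutes and all DES components must additionally have σ-potentials.
    Deterministic: identical inputs give identical column order and values.
    """
    if not records:
        raise DescriptorError("no records to assemble")

    binned: dict[str, dict[str, float]] = {}

    def binned_for(species: str) -> dict[str, float]:
        if species not in binned:
            if species not in sigma_potentials:
                raise DescriptorError(f"no sigma potential for species {species!r}")
            binned[species] = bin_sigma_potential(sigma_potentials[species]).as_dict()
        return binned[species]

    rows: list[dict[str, float]] = []
    for i, rec in enumerate(records):
        where = f"record {i} (solute {rec.solute_id!r})"
        if rec.solute_id not in energetics:
            raise DescriptorError(f"{where}: no energetic descriptors for solute")
        for s in rec.mixture.species_ids:
            if s not in energetics:
                raise DescriptorError(
                    f"{where}: no energetic descriptors for component {s!r}")
        row: dict[str, float] = {}
        solute_en = energetics[rec.solute_id].as_dict()
        for name in ENERGETIC_FIELDS:
            per_species = {s: getattr(energetics[s], name)
                           for s in rec.mixture.species_ids}
            des_val = mixture_descriptor(per_species, rec.mixture)
            row[f"{name}_API"] = solute_en[name]
            row[f"{name}_DES"] = des_val
            row[f"Δ{name}"] = relative_descriptor(solute_en[name], des_val)
        row["log_x_cosmo"] = rec.log_x_cosmo
        solute_bins = binned_for(rec.solute_id)
        for bname in BIN_NAMES:
            per_species = {s: binned_for(s)[bname] for s in rec.mixture.species_ids}
            des_val = mixture_descriptor(per_species, rec.mixture)
            row[f"Δ{bname}"] = relative_descriptor(solute_bins[bname], des_val)
        row["log_x"] = rec.log_x
        rows.append(row)

    frame = pd.DataFrame(rows, columns=list(SET2_COLUMNS) + ["log_x"])
    tags = {c: "set1" for c in SET1_COLUMNS}
    tags.update({c: "set2-extra" for c in SET2_EXTRA_COLUMNS})
    return DescriptorTable(frame=frame, set_tags=tags)


# ---------------------------------------------------------------------------
# CSV readers (plain-text interchange schemas)


def load_energetics_csv(path: str | Path) -> dict[str, EnergeticDescriptors]:
    """Read ``species_energetics.csv``: species_id, E_int, E_misfit, E_HB, E_vdW, mu."""
    df = pd.read_csv(path)
    return {
        str(r.species_id): EnergeticDescriptors(
            species_id=str(r.species_id), E_int=r.E_int, E_misfit=r.E_misfit,
            E_HB=r.E_HB, E_vdW=r.E_vdW, mu=r.mu)
        for r in df.itertuples(index=False)
    }


def load_sigma_potentials_csv(path: str | Path) -> dict[str, SigmaPotential]:
    """Read long-format ``sigma_potentials.csv``: species_id, sigma, value."""
    df = pd.read_csv(path)
    out: dict[str, SigmaPotential] = {}
    for species, grp in df.groupby("species_id", sort=True):
        grp = grp.sort_values("sigma")
        out[str(species)] = SigmaPotential(
            species_id=str(species),
            sigma_grid=grp["sigma"].to_numpy(),
            mu_values=grp["value"].to_numpy(),
        )
    return out


def load_fusion_csv(path: str | Path) -> dict[str, FusionData]:
    """Read ``fusion.csv``: solute_id, Tm_K, dHfus_kJmol."""
    df = pd.read_csv(path)
    return {
        str(r.solute_id): FusionData(
            solute_id=str(r.solute_id), T_m=r.Tm_K, dH_fus=r.dHfus_kJmol)
        for r in df.itertuples(index=False)
    }


def load_solubility_csv(path: str | Path) -> list[SolubilityRecord]:
    """Read ``solubility.csv``.

    Columns: solute_id; components (semicolon-separated species ids);
    mole_fractions (semicolon-separated, matching order); T_K; log_x;
    log_x_cosmo.
    """
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples(index=False):
        comps = str(r.components).split(";")
        fracs = [float(v) for v in str(r.mole_fractions).split(";")]
        if len(comps) != len(fracs):
            raise DescriptorError(
                f"solubility row for {r.solute_id!r}: {len(comps)} components "
                f"but {len(fracs)} mole fractions")
        records.append(SolubilityRecord(
            solute_id=str(r.solute_id),
            mixture=MixtureSpec(tuple(zip(comps, fracs))),
            temperature=float(r.T_K),
            log_x=float(r.log_x),
            log_x_cosmo=float(r.log_x_cosmo),
        ))
    return records
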