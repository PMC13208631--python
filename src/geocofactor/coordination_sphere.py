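"""Metal-site location and coordination-sphere profiling.

A coordination sphere is the set of standard amino-acid residues with at
least one atom within a distance cutoff (default 5 Å) of any atom of a
metal-bearing ligand.  Each sphere is summarised by its Kyte-Doolittle
hydropathy mean and sample standard deviation and by a 20-long normalized
amino-acid frequency vector; these per-site profiles are the input to the
cohort-level statistics.

Structure files are read with Bio.PDB (PDB format; mmCIF via file
extension).  Only the first model of multi-model files is used, and for
disordered atoms the highest-occupancy conformer is kept.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AA_ORDER",
    "AA_THREE_TO_ONE",
    "LigandRegistryEntry",
    "MetalSite",
    "SphereProfile",
    "StructureAtom",
    "StructureParseError",
    "StructureModel",
    "StructureResidue",
    "find_metal_sites",
    "frequency_vector",
    "hydropathy_stats",
    "load_hydropathy_scale",
    "load_ligand_registry",
    "load_residue_aliases",
    "parse_structure",
    "profile_site",
    "profile_structures",
    "sphere_residues",
]

#: Canonical one-letter amino-acid order used for all frequency vectors.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Element symbols treated as the metal atoms of a ligand.
METAL_ELEMENTS = frozenset({"FE", "NI"})


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class StructureAtom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class StructureResidue:
    chain: str
    serial: int
    name: str
    hetero: bool
    atoms: tuple[StructureAtom, ...]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class StructureModel:
    """First-model atom content of one structure file."""

    structure_id: str
    residues: tuple[StructureResidue, ...]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class LigandRegistryEntry:
    code: str
    description: str
    metal_class: str  # Fe | Ni | FeNi


@dataclass(frozen=True)
class MetalSite:
    """One metal-bearing ligand instance in one structure."""

    structure_id: str
    ligand_code: str
    chain: str
    serial: int
    ligand_atoms: tuple[StructureAtom, ...]

    @property
    def instance(self) -> str:
        return f"{self.chain}{self.serial}"


@dataclass(frozen=True)
class SphereProfile:
    """Residue-environment summary of one metal site at one cutoff."""

    site: MetalSite
    cutoff: float
    nearby_residues: tuple[StructureResidue, ...]
    aa_counts: Mapping[str, int]
    freq_vector: tuple[float, ...]
    hydropathy_mean: float
    hydropathy_sd: float

    @property
    def empty(self) -> bool:
        return len(self.nearby_residues) == 0


# ---------------------------------------------------------------------------
# bundled tables
# ---------------------------------------------------------------------------


def _read_tsv(filename: str) -> list[dict[str, str]]:
    text = (resources.files("geocofactor") / "data" / filename).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def load_hydropathy_scale() -> dict[str, float]:
    """Three-letter residue code → Kyte-Doolittle hydropathy value."""
    return {
        row["three_letter"]: float(row["hydropathy"])
        for row in _read_tsv("kyte_doolittle.tsv")
    }


def load_ligand_registry() -> dict[str, LigandRegistryEntry]:
    """Ligand code → registry entry for the recognised Fe/Ni metal centres."""
    return {
        row["code"]: LigandRegistryEntry(
            code=row["code"],
            description=row["description"],
            metal_class=row["metal_class"],
        )
        for row in _read_tsv("ligand_registry.tsv")
    }


def load_residue_aliases() -> dict[str, str]:
    """Modified-residue code → canonical parent three-letter code."""
    return {row["alias"]: row["parent"] for row in _read_tsv("residue_aliases.tsv")}


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------


def parse_structure(path, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB (or mmCIF) file into a flat first-model atom table.

    Altloc ambiguity is resolved to the highest-occupancy conformer; for
    multi-model files only the first model is kept.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise StructureParseError(f"unreadable or empty structure file: {path}")
    if structure_id is None:
        structure_id = path.stem
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in (".cif", ".mmcif")
        else PDBParser(QUIET=True)
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(structure_id, str(path))
    except Exception as exc:  # Bio.PDB reports the offending line itself
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise StructureParseError(f"no models in structure file: {path}")
    residues = []
    for chain in models[0]:
        for residue in chain:
            hetflag, resseq, _ = residue.id
            atoms = []
            # plain iteration yields the selected (highest-occupancy)
            # conformer of disordered atoms
            for atom in residue:
                coord = tuple(float(c) for c in atom.coord)
                if not all(math.isfinite(c) for c in coord):
                    raise StructureParseError(
                        f"non-finite coordinates for atom {atom.get_name()} in {path}"
                    )
                atoms.append(
                    StructureAtom(
                        name=atom.get_name(),
                        element=(atom.element or "").upper(),
                        coord=coord,
                    )
                )
            if atoms:
                residues.append(
                    StructureResidue(
                        chain=chain.id,
                        serial=int(resseq),
                        name=residue.get_resname().strip(),
                        hetero=hetflag.strip() != "",
                        atoms=tuple(atoms),
                    )
                )
    if not residues:
        raise StructureParseError(f"no ATOM/HETATM records in {path}")
    return StructureModel(structure_id=structure_id, residues=tuple(residues))


# ---------------------------------------------------------------------------
# site location and sphere extraction
# ---------------------------------------------------------------------------


def find_metal_sites(
    model: StructureModel,
    registry: Mapping[str, LigandRegistryEntry] | None = None,
) -> list[MetalSite]:
    """One MetalSite per hetero residue whose component code is registered.

    Order is deterministic: (chain, serial).
    """
    if registry is None:
        registry = load_ligand_registry()
    if not registry:
        raise ValueError("ligand registry is empty")
    sites = []
    for res in model.residues:
        if res.hetero and res.name in registry:
            sites.append(
                MetalSite(
                    structure_id=model.structure_id,
                    ligand_code=res.name,
                    chain=res.chain,
                    serial=res.serial,
                    ligand_atoms=res.atoms,
                )
            )
    sites.sort(key=lambda s: (s.chain, s.serial))
    return sites


def _canonical_name(
    residue: StructureResidue, aliases: Mapping[str, str]
) -> str | None:
    if residue.name in AA_THREE_TO_ONE:
        return residue.name
    return aliases.get(residue.name)


def sphere_residues(
    model: StructureModel,
    site: MetalSite,
    cutoff: float = 5.0,
    metal_atoms_only: bool = False,
    aliases: Mapping[str, str] | None = None,
) -> list[StructureResidue]:
    """Standard residues with any atom within ``cutoff`` Å of the ligand.

    The distance is the minimum over all (ligand atom, residue atom)
    pairs; with ``metal_atoms_only`` the search measures from the ligand's
    Fe/Ni atoms only.  Waters and other hetero groups are excluded;
    modified residues are mapped to their canonical parents.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if aliases is None:
        aliases = load_residue_aliases()
    if not any(
        r.chain == site.chain and r.serial == site.serial and r.name == site.ligand_code
        for r in model.residues
    ):
        raise ValueError(
            f"site {site.ligand_code} {site.instance} not found in model "
            f"{model.structure_id}"
        )
    ligand_coords = np.array(
        [
            a.coord
            for a in site.ligand_atoms
            if not metal_atoms_only or a.element in METAL_ELEMENTS
        ],
        dtype=float,
    )
    if ligand_coords.size == 0:
        raise ValueError(f"ligand {site.ligand_code} has no metal atoms")
    nearby = []
    for res in model.residues:
        if res.hetero or _canonical_name(res, aliases) is None:
            continue
        if cdist(res.coords(), ligand_coords).min() <= cutoff:
            nearby.append(res)
    return nearby


# ---------------------------------------------------------------------------
# per-sphere statistics
# ---------------------------------------------------------------------------


def hydropathy_stats(
    residues: Sequence[StructureResidue | str],
    scale: Mapping[str, float] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Mean and sample SD of per-residue Kyte-Doolittle values.

    Accepts residues or bare three-letter codes.  An empty list yields
    (nan, nan) so the caller can flag and exclude the site rather than
    crash; a singleton has SD 0.
    """
    if scale is None:
        scale = load_hydropathy_scale()
    if aliases is None:
        aliases = load_residue_aliases()
    names = [r if isinstance(r, str) else r.name for r in residues]
    names = [aliases.get(n, n) for n in names]
    if not names:
        return (math.nan, math.nan)
    values = np.array([scale[n] for n in names], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return (mean, sd)


def frequency_vector(
    residues: Sequence[StructureResidue | str],
    aliases: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Normalized 20-long amino-acid composition (order ``ACDEFGHIKLMNPQRSTVWY``).

    Entries sum to 1; an empty list yields the zero vector (flagged
    upstream).
    """
    if aliases is None:
        aliases = load_residue_aliases()
    counts = np.zeros(len(AA_ORDER), dtype=float)
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for r in residues:
        name = r if isinstance(r, str) else r.name
        name = aliases.get(name, name)
        one = AA_THREE_TO_ONE.get(name)
        if one is None:
            raise KeyError(f"residue {name!r} is not a canonical amino acid")
        counts[index[one]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def profile_site(
    model: StructureModel,
    site: MetalSite,
    cutoff: float = 5.0,
    scale: Mapping[str, float] | None = None,
    aliases: Mapping[str, str] | None = None,
    metal_atoms_only: bool = False,
) -> SphereProfile:
    """Full coordination-sphere profile of one metal site."""
    if aliases is None:
        aliases = load_residue_aliases()
    residues = sphere_residues(
        model, site, cutoff=cutoff, metal_atoms_only=metal_atoms_only, aliases=aliases
    )
    mean, sd = hydropathy_stats(residues, scale=scale, aliases=aliases)
    freq = frequency_vector(residues, aliases=aliases)
    counts: dict[str, int] = {aa: 0 for aa in AA_ORDER}
    for res in residues:
        name = aliases.get(res.name, res.name)
        counts[AA_THREE_TO_ONE[name]] += 1
    return SphereProfile(
        site=site,
        cutoff=cutoff,
        nearby_residues=tuple(residues),
        aa_counts=counts,
        freq_vector=tuple(float(v) for v in freq),
        hydropathy_mean=mean,
        hydropathy_sd=sd,
    )


def profile_structures(
    paths: Iterable,
    cutoff: float = 5.0,
    registry: Mapping[str, LigandRegistryEntry] | None = None,
    metal_atoms_only: bool = False,
):
    """Profile every registered metal site in a batch of structure files.

    Returns a pandas DataFrame with one row per (structure, ligand
    instance): identification columns, ``metal_class``, ``n_residues``,
    hydropathy statistics, then the 20 frequency columns ``freq_A`` …
    ``freq_Y``.  Sites with an empty sphere are kept with ``n_residues=0``
    and NaN statistics so downstream aggregation can exclude them
    explicitly.  Files that fail to parse are skipped with a warning so a
    batch survives a single bad structure.
    """
    import pandas as pd

    if registry is None:
        registry = load_ligand_registry()
    scale = load_hydropathy_scale()
    aliases = load_residue_aliases()
    rows = []
    for path in paths:
        try:
            model = parse_structure(path)
        except StructureParseError as exc:
            warnings.warn(f"skipping structure: {exc}")
            continue
        for site in find_metal_sites(model, registry):
            prof = profile_site(
                model,
                site,
                cutoff=cutoff,
                scale=scale,
                aliases=aliases,
                metal_atoms_only=metal_atoms_only,
            )
            row = {
                "structure_id": model.structure_id,
                "ligand_code": site.ligand_code,
                "ligand_instance": site.instance,
                "metal_class": registry[site.ligand_code].metal_class,
                "n_residues": len(prof.nearby_residues),
                "hydropathy_mean": prof.hydropathy_mean,
                "hydropathy_sd": prof.hydropathy_sd,
            }
            for aa, value in zip(AA_ORDER, prof.freq_vector):
                row[f"freq_{aa}"] = value
            rows.append(row)
    columns = [
        "structure_id", "ligand_code", "ligand_instance", "metal_class",
        "n_residues", "hydropathy_mean", "hydropathy_sd",
    ] + [f"freq_{aa}" for aa in AA_ORDER]
    return pd.DataFrame(rows, columns=columns)
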