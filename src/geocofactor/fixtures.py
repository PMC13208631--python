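"""Synthetic fixtures with known ground truth.

Three generators make every stage of the pipeline testable without any
external download:

* :func:`make_structure` writes a syntactically valid PDB file containing
  one metal-bearing ligand and amino-acid residues placed at exact,
  user-chosen minimum distances from the ligand (±0.01 Å), together with
  the resulting sphere-membership ground truth;
* :func:`make_cohort` builds an Fe/Ni structure batch whose coordination
  spheres realise Dirichlet-sampled amino-acid compositions with a
  planted cysteine-fraction difference between the Fe and Ni groups;
* :func:`make_mineral_table` writes a toy mineral CSV whose true wMEE_CV
  values are computed by an independent brute-force atom-expansion oracle.

Residues are written as minimal backbone+anchor atom sets — enough for
distance logic, with no claim of physical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from geocofactor.coordination_sphere import AA_ORDER, AA_THREE_TO_ONE

__all__ = [
    "CohortSpec",
    "SphereSpec",
    "make_cohort",
    "make_mineral_table",
    "make_structure",
    "oracle_wmee_cv",
    "sample_cohort_vectors",
]

AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

# Idealised ligand geometries (atom name, element, xyz in Å).  Shapes are
# schematic: correct atom identities and sensible bond-scale distances only.
_CUBE = 2.2
_LIGAND_GEOMETRIES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "SF4": [
        ("FE1", "FE", (0.0, 0.0, 0.0)),
        ("FE2", "FE", (_CUBE, _CUBE, 0.0)),
        ("FE3", "FE", (_CUBE, 0.0, _CUBE)),
        ("FE4", "FE", (0.0, _CUBE, _CUBE)),
        ("S1", "S", (_CUBE, 0.0, 0.0)),
        ("S2", "S", (0.0, _CUBE, 0.0)),
        ("S3", "S", (0.0, 0.0, _CUBE)),
        ("S4", "S", (_CUBE, _CUBE, _CUBE)),
    ],
    "FES": [
        ("FE1", "FE", (0.0, 0.0, 0.0)),
        ("FE2", "FE", (2.7, 0.0, 0.0)),
        ("S1", "S", (1.35, 1.6, 0.0)),
        ("S2", "S", (1.35, -1.6, 0.0)),
    ],
    "HEM": [
        ("FE", "FE", (0.0, 0.0, 0.0)),
        ("NA", "N", (2.0, 0.0, 0.0)),
        ("NB", "N", (0.0, 2.0, 0.0)),
        ("NC", "N", (-2.0, 0.0, 0.0)),
        ("ND", "N", (0.0, -2.0, 0.0)),
    ],
    "F43": [
        ("NI", "NI", (0.0, 0.0, 0.0)),
        ("N1", "N", (2.1, 0.0, 0.0)),
        ("N2", "N", (0.0, 2.1, 0.0)),
        ("N3", "N", (-2.1, 0.0, 0.0)),
        ("N4", "N", (0.0, -2.1, 0.0)),
    ],
    "NFU": [
        ("NI", "NI", (0.0, 0.0, 0.0)),
        ("FE", "FE", (2.6, 0.0, 0.0)),
        ("C1", "C", (3.9, 1.0, 0.0)),
        ("N1", "N", (4.7, 1.7, 0.0)),
        ("C2", "C", (3.9, -1.0, 0.0)),
        ("N2", "N", (4.7, -1.7, 0.0)),
        ("C3", "C", (2.6, 0.0, 1.8)),
        ("O1", "O", (2.6, 0.0, 2.9)),
    ],
    "NI": [("NI", "NI", (0.0, 0.0, 0.0))],
    "FE": [("FE", "FE", (0.0, 0.0, 0.0))],
    "FE2": [("FE", "FE", (0.0, 0.0, 0.0))],
}


@dataclass(frozen=True)
class SphereSpec:
    """Recipe for one synthetic metal-site structure file."""

    ligand_code: str
    placements: tuple[tuple[str, float], ...]  # (three-letter type, min distance Å)
    seed: int = 0
    structure_id: str = "SYNTH"
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.ligand_code not in _LIGAND_GEOMETRIES:
            raise ValueError(
                f"no geometry for ligand {self.ligand_code!r}; "
                f"known: {sorted(_LIGAND_GEOMETRIES)}"
            )
        for name, dist in self.placements:
            if dist <= 0:
                raise ValueError(f"distance for {name} must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic Fe-vs-Ni cohort with a planted cysteine effect."""

    n_per_group: int = 30
    effect: float = 0.15  # Fe-minus-Ni difference in mean cysteine fraction
    concentration: float = 50.0  # Dirichlet concentration (within-group spread)
    base_cys: float = 0.10  # Ni-group mean cysteine fraction
    n_residues: int = 12  # residues per sphere when files are written
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_cys <= 1 or not 0 <= self.base_cys + self.effect <= 1:
            raise ValueError("planted cysteine fractions must stay within [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------


def _pdb_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: Sequence[float],
    element: str,
) -> str:
    # element right-justified at cols 13-14 for two-letter elements,
    # otherwise offset by one
    field = name.ljust(4) if len(element) == 2 else (" " + name).ljust(4)
    return (
        f"{record:<6s}{serial:>5d} {field}{' '}{resname:>3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _min_dist(point: np.ndarray, coords: np.ndarray) -> float:
    return float(np.sqrt(((coords - point) ** 2).sum(axis=1)).min())


def _place_anchor(
    ligand_coords: np.ndarray, direction: np.ndarray, distance: float
) -> np.ndarray:
    """Point along ``direction`` from the ligand centroid whose minimum
    distance to any ligand atom equals ``distance`` (bisection)."""
    centroid = ligand_coords.mean(axis=0)
    lo, hi = 0.0, distance + float(
        np.sqrt(((ligand_coords - centroid) ** 2).sum(axis=1)).max()
    ) + 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _min_dist(centroid + mid * direction, ligand_coords) < distance:
            lo = mid
        else:
            hi = mid
    return centroid + hi * direction


_RESIDUE_ATOMS = ("CB", "CA", "N", "C", "O")  # anchor first; GLY drops CB


def _residue_atoms_for(
    restype: str, anchor: np.ndarray, direction: np.ndarray
) -> list[tuple[str, str, np.ndarray]]:
    names = _RESIDUE_ATOMS if restype != "GLY" else _RESIDUE_ATOMS[1:]
    atoms = []
    for k, name in enumerate(names):
        # atoms march outward so the anchor stays the unique nearest atom
        atoms.append((name, name[0], anchor + (1.5 * k) * direction))
    return atoms


def make_structure(
    spec: SphereSpec, out_dir, max_attempts: int = 100
) -> tuple[Path, pd.DataFrame]:
    """Write the structure file for ``spec`` and return its ground truth.

    Each placed residue's true minimum distance to the ligand equals the
    spec distance to within 0.01 Å; the returned table gives, per residue,
    its serial, type and true distance, from which membership at any
    cutoff follows.  Output is byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    geometry = _LIGAND_GEOMETRIES[spec.ligand_code]
    ligand_coords = np.array([xyz for _, _, xyz in geometry], dtype=float)

    placed: list[tuple[str, np.ndarray, float]] = []  # (type, atoms Nx3, dist)
    occupied: list[np.ndarray] = []
    for restype, distance in spec.placements:
        if restype not in AA_THREE_TO_ONE:
            raise ValueError(f"not a canonical residue type: {restype!r}")
        for attempt in range(max_attempts):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchor = _place_anchor(ligand_coords, direction, distance)
            atoms = _residue_atoms_for(restype, anchor, direction)
            coords = np.array([xyz for _, _, xyz in atoms])
            # the anchor must remain the unique nearest atom: verify the
            # realised minimum distance before accepting the placement
            realised = min(_min_dist(c, ligand_coords) for c in coords)
            clash = any(
                float(np.sqrt(((other[:, None] - coords[None]) ** 2).sum(-1)).min())
                < 1.5
                for other in occupied
            )
            overlap = realised < 1.2  # inside bond length: overlapping atoms
            if not clash and not overlap and abs(realised - distance) <= 0.01:
                break
        else:
            raise RuntimeError(
                f"could not place {restype} at {distance} Å after "
                f"{max_attempts} attempts"
            )
        occupied.append(coords)
        placed.append((restype, atoms, distance))

    lines = []
    serial = 1
    truth_rows = []
    for resseq, (restype, atoms, distance) in enumerate(placed, start=1):
        for name, element, xyz in atoms:
            lines.append(
                _pdb_atom_line(
                    "ATOM", serial, name, restype, spec.chain, resseq, xyz, element
                )
            )
            serial += 1
        truth_rows.append(
            {
                "chain": spec.chain,
                "serial": resseq,
                "residue": restype,
                "min_distance": distance,
            }
        )
    ligand_serial = len(placed) + 1
    for name, element, xyz in geometry:
        lines.append(
            _pdb_atom_line(
                "HETATM",
                serial,
                name,
                spec.ligand_code,
                spec.chain,
                ligand_serial,
                xyz,
                element,
            )
        )
        serial += 1
    lines.append("END")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{spec.structure_id}.pdb"
    path.write_text("\n".join(lines) + "\n")
    truth = pd.DataFrame(
        truth_rows, columns=["chain", "serial", "residue", "min_distance"]
    )
    return path, truth


# ---------------------------------------------------------------------------
# cohorts with a planted cysteine effect
# ---------------------------------------------------------------------------

# Baseline sphere composition (rough metal-site flavour: coordinating and
# second-shell residues over-represented); rescaled around the planted
# cysteine fraction per group.
_BASE_PROFILE = {
    "A": 0.06, "C": 0.10, "D": 0.05, "E": 0.06, "F": 0.04, "G": 0.08,
    "H": 0.07, "I": 0.05, "K": 0.04, "L": 0.07, "M": 0.03, "N": 0.04,
    "P": 0.04, "Q": 0.03, "R": 0.04, "S": 0.06, "T": 0.05, "V": 0.06,
    "W": 0.01, "Y": 0.02,
}

_FE_LIGANDS = ("SF4", "HEM", "FES")
_NI_LIGANDS = ("F43", "NI", "NFU")
_FAMILY_CYCLE = ("ACS", "CODH", "NiFe-hydrogenase")


def _group_profile(cys_fraction: float) -> np.ndarray:
    base = np.array([_BASE_PROFILE[aa] for aa in AA_ORDER])
    idx = AA_ORDER.index("C")
    out = base * (1 - cys_fraction) / (1 - base[idx])
    out[idx] = cys_fraction
    return out / out.sum()


def sample_cohort_vectors(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw structure-level frequency vectors for an Fe and a Ni group.

    Rows mimic the aggregated cohort table (one per structure and metal
    class, with Dirichlet-sampled frequency vectors and hydropathy columns
    derived from the sampled composition).  Returns the table and the true
    planted group means of the cysteine fraction.
    """
    rng = np.random.default_rng(spec.seed)
    scale_values = np.array(
        [
            {"A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
             "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
             "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
             "W": -0.9, "Y": -1.3}[aa]
            for aa in AA_ORDER
        ]
    )
    rows = []
    truth = {
        "Fe": spec.base_cys + spec.effect,
        "Ni": spec.base_cys,
    }
    for group in ("Fe", "Ni"):
        profile = _group_profile(truth[group])
        alphas = np.maximum(profile * spec.concentration, 1e-3)
        for i in range(spec.n_per_group):
            vec = rng.dirichlet(alphas)
            mean_h = float(vec @ scale_values)
            var_h = float(vec @ (scale_values - mean_h) ** 2)
            row = {
                "structure_id": f"{group.upper()}{i:03d}",
                "metal_class": group,
                "enzyme_family": _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)],
                "hydropathy_mean": mean_h,
                "hydropathy_sd": math.sqrt(var_h),
            }
            for aa, v in zip(AA_ORDER, vec):
                row[f"freq_{aa}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows), truth


def make_cohort(
    spec: CohortSpec, out_dir
) -> tuple[list[Path], pd.DataFrame, dict[str, float]]:
    """Write a batch of structure files realising a planted-effect cohort.

    Per structure a composition is drawn as in
    :func:`sample_cohort_vectors`, residue counts are sampled from it, and
    each residue is placed 2.2–4.8 Å from a group-appropriate ligand (so
    every placed residue is inside the 5 Å sphere), plus one decoy residue
    beyond the cutoff.  Returns the file paths, a metadata table
    (structure_id, enzyme_family, curation_source) and the planted group
    means of the cysteine fraction.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    paths: list[Path] = []
    meta_rows = []
    truth = {"Fe": spec.base_cys + spec.effect, "Ni": spec.base_cys}
    for group, ligands in (("Fe", _FE_LIGANDS), ("Ni", _NI_LIGANDS)):
        profile = _group_profile(truth[group])
        alphas = np.maximum(profile * spec.concentration, 1e-3)
        for i in range(spec.n_per_group):
            vec = rng.dirichlet(alphas)
            counts = rng.multinomial(spec.n_residues, vec)
            placements = []
            for aa, n in zip(AA_ORDER, counts):
                for _ in range(n):
                    placements.append(
                        (AA_ONE_TO_THREE[aa], float(rng.uniform(2.2, 4.8)))
                    )
            placements.append(("ALA", float(rng.uniform(6.0, 9.0))))  # decoy
            sid = f"{group.upper()}{i:03d}"
            sub = SphereSpec(
                ligand_code=ligands[i % len(ligands)],
                placements=tuple(placements),
                seed=int(rng.integers(0, 2**31 - 1)),
                structure_id=sid,
            )
            path, _ = make_structure(sub, out_dir)
            paths.append(path)
            meta_rows.append(
                {
                    "structure_id": sid,
                    "enzyme_family": _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)],
                    "curation_source": "synthetic",
                }
            )
    metadata = pd.DataFrame(
        meta_rows, columns=["structure_id", "enzyme_family", "curation_source"]
    )
    return paths, metadata, truth


# ---------------------------------------------------------------------------
# toy mineral tables
# ---------------------------------------------------------------------------


def oracle_wmee_cv(counts: Mapping[str, int], en: Mapping[str, float]) -> float:
    """Brute-force wMEE_CV: expand integer counts into an explicit per-atom
    electronegativity list and take sample SD over mean.

    Independent of the weighted closed form in
    :mod:`geocofactor.mineral_chem`; used as its oracle.
    """
    atoms: list[float] = []
    for sym, n in counts.items():
        atoms.extend([en[sym]] * int(n))
    if len(set(atoms)) == 1 or len(atoms) == 1:
        return 0.0
    values = np.array(atoms)
    return float(values.std(ddof=1) / values.mean())


_MINERAL_ELEMENT_POOL = (
    "Fe", "Ni", "O", "S", "Si", "As", "Ca", "Mg", "Al", "Cu", "P", "H", "Na", "Cl",
)


def make_mineral_table(
    n: int, seed: int, out_path=None
) -> pd.DataFrame:
    """Random small-integer-count mineral table with oracle truth.

    Always embeds three fixed rows — oregonite (FeNi2As2) and the native
    metals Fe and Ni — followed by ``n`` random formulas drawn from a
    common rock-forming element pool.  The ``true_wmee_cv`` column comes
    from :func:`oracle_wmee_cv`, not from the package's weighted formula.
    If ``out_path`` is given, the table (without the truth column) is also
    written as CSV in the standard mineral-table layout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from geocofactor.mineral_chem import load_element_table

    rng = np.random.default_rng(seed)
    en = {sym: info.pauling_en for sym, info in load_element_table().items()}
    rows = [
        {"mineral_name": "oregonite", "counts": {"Fe": 1, "Ni": 2, "As": 2}},
        {"mineral_name": "iron", "counts": {"Fe": 1}},
        {"mineral_name": "nickel", "counts": {"Ni": 1}},
    ]
    for i in range(n):
        k = int(rng.integers(1, 5))
        symbols = rng.choice(_MINERAL_ELEMENT_POOL, size=k, replace=False)
        counts = {str(s): int(rng.integers(1, 10)) for s in symbols}
        rows.append({"mineral_name": f"synthmin{i:03d}", "counts": counts})
    records = []
    for row in rows:
        counts = row["counts"]
        formula = "".join(
            f"{sym}{c}" if c > 1 else sym for sym, c in counts.items()
        )
        records.append(
            {
                "mineral_name": row["mineral_name"],
                "formula": formula,
                "max_age_ga": round(float(rng.uniform(0.0, 4.0)), 2),
                "locality_count": int(rng.integers(1, 1000)),
                "true_wmee_cv": oracle_wmee_cv(counts, en),
            }
        )
    table = pd.DataFrame(records)
    if out_path is not None:
        table.drop(columns=["true_wmee_cv"]).to_csv(out_path, index=False)
    return table
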