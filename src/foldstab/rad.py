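"""RAD burial scoring of backbone amide nitrogens.

RAD = D x RA x 100 combines two complementary views of how buried an amide
nitrogen is:

* **D** — exteriority of the atom, in [0, 1]: the fraction of test points on
  a probe sphere (default radius 4 A) centred on the atom that fall outside
  the protein's occupied volume (the union of heavy-atom van der Waals
  spheres).  An isolated atom scores 1; an atom deep inside a large body
  approaches 0.
* **RA** — relative accessibility at the atomic level, in [0, 1]: the
  solvent-accessible surface area (SASA) of the nitrogen divided by the
  SASA of all atoms of its residue.  SASA uses the Shrake-Rupley
  sphere-sampling construction (probe 1.4 A, >= 960 points per atom).

Small RAD identifies hydrophobic-core amides, the reliable reporters of
global unfolding in an HSQC melting series.  Hydrogens are ignored
throughout; van der Waals radii come from a fixed published set.

A precomputed-table input path (residue_label + D/RA, or RAD directly)
bypasses structure computation so published scores can be reused verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import gemmi

__all__ = [
    "StructureModel",
    "RADRecord",
    "VDW_RADII",
    "read_structure",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "relative_accessibility",
    "exteriority",
    "compute_rad",
    "select_by_rad",
    "rad_from_structure",
    "read_rad_table",
    "write_rad_table",
]

#: Heavy-atom van der Waals radii (A).  Fixed published set; no hydrogens.
VDW_RADII: dict[str, float] = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

#: Water-probe radius for SASA (A).
PROBE_RADIUS = 1.4

#: Probe-sphere radius for the exteriority index (A); must exceed van der
#: Waals contact distances so the index senses burial, not packing.
EXTERIORITY_RADIUS = 4.0


@dataclass
class StructureModel:
    """Heavy-atom coordinate model sufficient for burial scoring."""

    elements: np.ndarray          # element symbols, uppercase
    residue_numbers: np.ndarray   # author residue numbering (1-based)
    residue_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray            # (n, 3) A
    radii: np.ndarray             # vdW radii, A
    chain: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    def residue_mask(self, resnum: int) -> np.ndarray:
        return self.residue_numbers == resnum

    def backbone_n_index(self, resnum: int) -> int | None:
        idx = np.flatnonzero(self.residue_mask(resnum) & (self.atom_names == "N"))
        return int(idx[0]) if idx.size else None

    def residue_label(self, resnum: int) -> str:
        names = self.residue_names[self.residue_mask(resnum)]
        code = str(names[0]).capitalize() if names.size else "Unk"
        return f"{resnum} {code}"


def read_structure(path, chain: str | None = None) -> StructureModel:
    """Read a PDB file into a heavy-atom StructureModel (first model).

    Hydrogens are dropped; van der Waals radii are assigned from
    ``VDW_RADII`` (unlisted elements get 1.70 A).
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = st[0]
    chains = [c for c in model if chain is None or c.name == chain]
    if not chains:
        raise ValueError(f"{path}: chain {chain!r} not found")
    elements, resnums, resnames, atnames, xyz = [], [], [], [], []
    for c in chains[:1]:
        for res in c:
            for atom in res:
                el = atom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                elements.append(el)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atnames.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise ValueError(f"{path}: no heavy atoms parsed")
    elements = np.array(elements)
    return StructureModel(
        elements=elements,
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames),
        atom_names=np.array(atnames),
        coords=np.array(xyz, dtype=float),
        radii=np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]),
        chain=chains[0].name,
        source=str(path),
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(model: StructureModel, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom is expanded by the probe radius; ``n_points`` sphere points
    are tested against the expanded spheres of neighbouring atoms; SASA is
    the exposed-point fraction times the expanded-sphere area.
    """
    if n_points < 960:
        raise ValueError("sphere sampling needs >= 960 points per atom")
    unit = fibonacci_sphere(n_points)
    coords = model.coords
    radii_exp = model.radii + PROBE_RADIUS
    n = len(model)
    sasa = np.zeros(n)
    # neighbour cutoff: two expanded spheres can only intersect within this
    max_r = radii_exp.max()
    for i in range(n):
        pts = coords[i] + radii_exp[i] * unit
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.flatnonzero((d_atoms < radii_exp[i] + max_r) & (np.arange(n) != i))
        if nb.size == 0:
            exposed = n_points
        else:
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii_exp[nb] ** 2)[None, :]).any(axis=1)
            exposed = int(np.sum(~buried))
        sasa[i] = 4.0 * math.pi * radii_exp[i] ** 2 * exposed / n_points
    return sasa


def relative_accessibility(
    model: StructureModel,
    resnum: int,
    sasa: np.ndarray | None = None,
    n_points: int = 960,
) -> float | None:
    """RA of a residue's backbone amide nitrogen.

    SASA of the amide N divided by the summed SASA of all atoms of the
    residue; defined as 0 when the whole residue is buried (residue SASA 0).
    Returns None when the residue has no backbone N.
    """
    n_idx = model.backbone_n_index(resnum)
    if n_idx is None:
        return None
    if sasa is None:
        sasa = shrake_rupley_sasa(model, n_points=n_points)
    res_sasa = float(np.sum(sasa[model.residue_mask(resnum)]))
    if res_sasa <= 0:
        return 0.0
    return float(sasa[n_idx] / res_sasa)


def exteriority(
    model: StructureModel,
    atom_index: int,
    r_probe: float = EXTERIORITY_RADIUS,
    n_points: int = 960,
) -> float:
    """Exteriority index D in [0, 1] of one atom.

    Fraction of ``n_points`` test points on a sphere of radius ``r_probe``
    around the atom that lie outside every heavy atom's van der Waals
    sphere.  1 for an isolated atom; tends to 0 deep inside a large body.
    """
    pts = model.coords[atom_index] + r_probe * fibonacci_sphere(n_points)
    d2 = ((pts[:, None, :] - model.coords[None, :, :]) ** 2).sum(axis=2)
    inside = (d2 < (model.radii ** 2)[None, :]).any(axis=1)
    return float(np.sum(~inside) / n_points)


def compute_rad(D: float, RA: float) -> float:
    """RAD = D x RA x 100; both factors must lie in [0, 1]."""
    if not (0.0 <= D <= 1.0):
        raise ValueError(f"exteriority D out of [0, 1]: {D}")
    if not (0.0 <= RA <= 1.0):
        raise ValueError(f"relative accessibility RA out of [0, 1]: {RA}")
    return 100.0 * D * RA


@dataclass
class RADRecord:
    """Burial score of one residue's amide nitrogen."""

    residue_label: str
    RAD: float
    D: float | None = None
    RA: float | None = None

    def __post_init__(self) -> None:
        if self.RAD < 0:
            raise ValueError(f"{self.residue_label}: negative RAD")


def rad_from_structure(
    model: StructureModel,
    residues: list[int] | None = None,
    n_points: int = 960,
) -> list[RADRecord]:
    """Compute RAD records for backbone amide nitrogens of a structure.

    Residues without a backbone N (or outside ``residues`` when given) are
    skipped.
    """
    sasa = shrake_rupley_sasa(model, n_points=n_points)
    resnums = sorted(set(int(r) for r in model.residue_numbers))
    if residues is not None:
        wanted = set(residues)
        resnums = [r for r in resnums if r in wanted]
    records = []
    for rn in resnums:
        n_idx = model.backbone_n_index(rn)
        if n_idx is None:
            continue
        ra = relative_accessibility(model, rn, sasa=sasa)
        d = exteriority(model, n_idx, n_points=n_points)
        records.append(RADRecord(
            residue_label=model.residue_label(rn),
            RAD=compute_rad(d, ra),
            D=d,
            RA=ra,
        ))
    return records


def select_by_rad(records: list[RADRecord], threshold: float) -> list[RADRecord]:
    """Records with RAD strictly below ``threshold``, input order preserved."""
    return [r for r in records if r.RAD < threshold]


def read_rad_table(path) -> list[RADRecord]:
    """Read a precomputed burial table.

    TSV with residue_label plus either columns D and RA (RAD computed as
    their product x 100) or a RAD column used verbatim.  Rows with a blank
    RAD are skipped (residues with no published score).
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        label = str(row["residue_label"])
        if "D" in df.columns and "RA" in df.columns and pd.notna(row.get("D")):
            d, ra = float(row["D"]), float(row["RA"])
            records.append(RADRecord(label, compute_rad(d, ra), D=d, RA=ra))
        elif "RAD" in df.columns and pd.notna(row.get("RAD")):
            records.append(RADRecord(label, float(row["RAD"])))
    return records


def write_rad_table(records: list[RADRecord], path) -> pd.DataFrame:
    df = pd.DataFrame([
        {"residue_label": r.residue_label, "D": r.D, "RA": r.RA, "RAD": r.RAD}
        for r in records
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
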