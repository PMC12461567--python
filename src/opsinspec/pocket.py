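"""Retinal binding-pocket geometry from protein structures.

Given a structure containing a retinal ligand, locate the two chromophore
reference points — the centroid of the β-ionone ring (carbons C1–C6 of the
retinal, by standard RET nomenclature) and the Schiff-base nitrogen (the NZ
of the lysine covalently linked to retinal C15) — then measure, for every
amino-acid residue, the minimum side-chain distance to each point and select
pocket residues within a cutoff (10 Å by default).

A synthetic-structure generator emits minimal, valid PDB files with a
retinal-like ligand and residues at scripted distances, so the geometry code
is testable without any downloaded structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreFrame",
    "read_structure",
    "locate_chromophore",
    "residue_pocket_distances",
    "select_pocket_residues",
    "synthetic_pocket_structure",
    "write_pdb",
]

DEFAULT_RING_ATOMS = ("C1", "C2", "C3", "C4", "C5", "C6")
_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class ChromophoreFrame:
    """Chromophore reference points: β-ionone centroid and Schiff-base N."""

    beta_ionone_centroid: np.ndarray  # (3,) Å
    schiff_base_n: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        c = np.asarray(self.beta_ionone_centroid, dtype=float)
        n = np.asarray(self.schiff_base_n, dtype=float)
        if not (np.isfinite(c).all() and np.isfinite(n).all()):
            raise ValueError("chromophore coordinates must be finite")
        if np.linalg.norm(c - n) <= 5.0:
            raise ValueError(
                "β-ionone centroid and Schiff-base N are implausibly close "
                "(<= 5 Å); check the ligand pose"
            )
        object.__setattr__(self, "beta_ionone_centroid", c)
        object.__setattr__(self, "schiff_base_n", n)


def read_structure(path) -> gemmi.Structure:
    """Read a PDB (or mmCIF) structure."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_pdb(structure: gemmi.Structure, path) -> None:
    structure.write_pdb(str(path))


def _atom_xyz(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


def _iter_residues(structure: gemmi.Structure):
    for chain in structure[0]:
        for residue in chain:
            yield chain, residue


def locate_chromophore(
    structure: gemmi.Structure,
    ligand_name: str = "RET",
    ring_atoms: tuple[str, ...] = DEFAULT_RING_ATOMS,
    sb_residue: tuple[str, int] | None = None,
) -> ChromophoreFrame:
    """Locate the β-ionone ring centroid and Schiff-base nitrogen.

    The centroid is the unweighted mean of the named ring-atom coordinates.
    The Schiff-base lysine may be given as ``(chain, residue_number)``;
    otherwise the lysine whose NZ lies nearest the retinal C15 is chosen.
    Missing ligand or atoms raise an error naming what is absent.
    """
    ligand = None
    for _, residue in _iter_residues(structure):
        if residue.name == ligand_name:
            ligand = residue
            break
    if ligand is None:
        raise ValueError(f"ligand {ligand_name!r} not found in structure")

    by_name = {atom.name: atom for atom in ligand}
    missing = [a for a in ring_atoms if a not in by_name]
    if missing:
        raise ValueError(
            f"ligand {ligand_name} lacks ring atom(s): {', '.join(missing)}"
        )
    centroid = np.mean([_atom_xyz(by_name[a]) for a in ring_atoms], axis=0)

    if sb_residue is not None:
        chain_name, resnum = sb_residue
        nz = None
        for chain, residue in _iter_residues(structure):
            if (chain.name == chain_name and residue.seqid.num == resnum
                    and residue.name == "LYS"):
                for atom in residue:
                    if atom.name == "NZ":
                        nz = _atom_xyz(atom)
        if nz is None:
            raise ValueError(
                f"no LYS NZ at {chain_name}/{resnum} for the Schiff base"
            )
        return ChromophoreFrame(centroid, nz)

    # auto-detect: lysine NZ nearest the retinal C15
    if "C15" not in by_name:
        raise ValueError(
            f"ligand {ligand_name} lacks atom C15 needed for Schiff-base "
            "lysine auto-detection; pass sb_residue explicitly"
        )
    c15 = _atom_xyz(by_name["C15"])
    best: tuple[float, np.ndarray] | None = None
    for _, residue in _iter_residues(structure):
        if residue.name != "LYS":
            continue
        for atom in residue:
            if atom.name == "NZ":
                d = float(np.linalg.norm(_atom_xyz(atom) - c15))
                if best is None or d < best[0]:
                    best = (d, _atom_xyz(atom))
    if best is None:
        raise ValueError("no lysine NZ found for Schiff-base auto-detection")
    return ChromophoreFrame(centroid, best[1])


def _side_chain_atoms(residue: gemmi.Residue, side_chain_only: bool):
    atoms = []
    for atom in residue:
        if atom.element == gemmi.Element("H"):
            continue
        if side_chain_only and atom.name in _BACKBONE:
            continue
        atoms.append(atom)
    if side_chain_only and not atoms:  # glycine: fall back to Cα
        atoms = [a for a in residue if a.name == "CA"]
    return atoms


def residue_pocket_distances(
    structure: gemmi.Structure,
    frame: ChromophoreFrame,
    side_chain_only: bool = True,
    cutoff: float = 10.0,
) -> pd.DataFrame:
    """Minimum side-chain distances per residue to the two reference points.

    Side chain means all non-hydrogen atoms outside the backbone (N, CA, C,
    O, OXT), i.e. Cβ outward; glycine falls back to Cα.  ``within_cutoff``
    flags residues whose nearer distance is <= ``cutoff`` Å.
    """
    rows = []
    for chain, residue in _iter_residues(structure):
        if residue.name not in _AA3:
            continue
        atoms = _side_chain_atoms(residue, side_chain_only)
        if not atoms:
            continue
        xyz = np.array([_atom_xyz(a) for a in atoms])
        d_beta = float(np.min(np.linalg.norm(
            xyz - frame.beta_ionone_centroid, axis=1)))
        d_rsb = float(np.min(np.linalg.norm(xyz - frame.schiff_base_n, axis=1)))
        rows.append((chain.name, residue.seqid.num, residue.name,
                     d_beta, d_rsb, min(d_beta, d_rsb) <= cutoff))
    return pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "d_beta", "d_rsb",
                       "within_cutoff"]
    )


def select_pocket_residues(
    table: pd.DataFrame,
    cutoff: float = 10.0,
) -> pd.DataFrame:
    """Residues whose nearer reference distance is <= ``cutoff`` Å."""
    keep = table[np.minimum(table["d_beta"], table["d_rsb"]) <= cutoff]
    return keep.sort_values(["chain", "resnum"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic fixture generator
# ---------------------------------------------------------------------------

def _make_atom(name: str, element: str, xyz) -> gemmi.Atom:
    atom = gemmi.Atom()
    atom.name = name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*[float(v) for v in xyz])
    atom.occ = 1.0
    atom.b_iso = 20.0
    return atom


def _make_residue(name: str, num: int, het: bool = False) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(num, " ")
    res.het_flag = "H" if het else "A"
    return res


def synthetic_pocket_structure(
    seed: int = 0,
    residue_distances: dict[int, tuple[str, str, float]] | None = None,
) -> gemmi.Structure:
    """Build a minimal synthetic structure with a retinal-like ligand.

    The ligand (RET) has a planar C1–C6 hexagonal ring centred at the origin
    and a polyene chain C7–C15 extending along +x; a Schiff-base lysine's NZ
    sits 1.4 Å beyond C15.  ``residue_distances`` scripts additional
    single-side-chain-atom residues: ``{resnum: (resname, anchor, distance)}``
    with ``anchor`` either ``"beta"`` (ring centroid) or ``"rsb"`` (NZ); the
    Cβ of each residue is placed at exactly that distance, in a
    seed-dependent direction pointing away from the other anchor.

    Purely synthetic fixture: mimics real RET/LYS atom-naming conventions
    but encodes no measured structure.
    """
    rng = np.random.default_rng(seed)
    st = gemmi.Structure()
    st.name = "synthetic-retinal-pocket"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")

    # retinal-like ligand: hexagonal ring + chain
    ret = _make_residue("RET", 900, het=True)
    ring_r = 1.46
    for i, name in enumerate(DEFAULT_RING_ATOMS):
        ang = math.pi / 3.0 * i
        ret.add_atom(_make_atom(
            name, "C", (ring_r * math.cos(ang), ring_r * math.sin(ang), 0.0)))
    for j, name in enumerate(
            ["C7", "C8", "C9", "C10", "C11", "C12", "C13", "C14", "C15"]):
        ret.add_atom(_make_atom(name, "C", (2.8 + 1.3 * j, 0.0, 0.0)))
    c15 = np.array([2.8 + 1.3 * 8, 0.0, 0.0])

    # Schiff-base lysine with NZ 1.4 Å beyond C15
    lys = _make_residue("LYS", 296)
    nz = c15 + np.array([1.4, 0.0, 0.0])
    lys.add_atom(_make_atom("N", "N", nz + (6.0, 3.0, 1.0)))
    lys.add_atom(_make_atom("CA", "C", nz + (5.0, 2.5, 1.0)))
    lys.add_atom(_make_atom("C", "C", nz + (5.5, 3.5, 2.0)))
    lys.add_atom(_make_atom("O", "O", nz + (6.5, 3.8, 2.0)))
    lys.add_atom(_make_atom("CB", "C", nz + (3.8, 1.9, 0.8)))
    lys.add_atom(_make_atom("CG", "C", nz + (2.8, 1.4, 0.6)))
    lys.add_atom(_make_atom("CD", "C", nz + (1.9, 0.9, 0.4)))
    lys.add_atom(_make_atom("CE", "C", nz + (0.9, 0.5, 0.2)))
    lys.add_atom(_make_atom("NZ", "N", nz))

    residues = [lys]
    centroid = np.zeros(3)
    anchors = {"beta": centroid, "rsb": nz}
    if residue_distances:
        for resnum, (resname, anchor, dist) in sorted(residue_distances.items()):
            ref = anchors[anchor]
            other = anchors["rsb" if anchor == "beta" else "beta"]
            away = ref - other
            away = away / np.linalg.norm(away)
            jitter = rng.normal(0.0, 0.3, size=3)
            direction = away + jitter
            direction /= np.linalg.norm(direction)
            cb = ref + dist * direction
            res = _make_residue(resname, resnum)
            backbone_offset = cb + direction * 3.0
            res.add_atom(_make_atom("N", "N", backbone_offset + (1.2, 0, 0)))
            res.add_atom(_make_atom("CA", "C", backbone_offset))
            res.add_atom(_make_atom("C", "C", backbone_offset + (0, 1.2, 0)))
            res.add_atom(_make_atom("O", "O", backbone_offset + (0, 2.4, 0)))
            if resname != "GLY":
                res.add_atom(_make_atom("CB", "C", cb))
            residues.append(res)

    for res in sorted(residues, key=lambda r: r.seqid.num):
        chain.add_residue(res)
    chain.add_residue(ret)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st
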