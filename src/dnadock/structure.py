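"""Molecular structures as annotated atom-record arrays.

A :class:`Structure` is an ordered collection of heavy-atom records
(coordinates in Å, PDB-style naming) for a single molecule — one protein or
one DNA duplex.  Force-field annotations (partial charge, vdW parameters,
solvation coefficient, atom type) are attached as parallel arrays by
:func:`dnadock.forcefield.assign_forcefield`.

PDB reading goes through biotite; writing is done directly so that the output
layout (serials, TER records) is fully controlled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("dnadock")

#: three-letter / legacy residue names accepted for DNA, canonicalised to DA/DC/DG/DT
_DNA_ALIASES = {
    "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT",
    "A": "DA", "C": "DC", "G": "DG", "T": "DT",
    "ADE": "DA", "CYT": "DC", "GUA": "DG", "THY": "DT",
}

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_HIS_ALIASES = {"HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS"}

_WATER = {"HOH", "WAT", "DOD", "H2O"}


def canonical_resname(resname: str) -> str | None:
    """Map a PDB residue name to its canonical form, or None if unsupported."""
    r = resname.strip().upper()
    if r in _AA3:
        return r
    if r in _HIS_ALIASES:
        return _HIS_ALIASES[r]
    if r in _DNA_ALIASES:
        return _DNA_ALIASES[r]
    return None


def canonical_atom_name(name: str) -> str:
    """Normalise atom-name variants: ``*`` primes and O1P/O2P phosphate names."""
    n = name.strip().replace("*", "'")
    if n == "O1P":
        return "OP1"
    if n == "O2P":
        return "OP2"
    if n == "C5M":  # thymine methyl, old naming
        return "C7"
    return n


@dataclass
class AtomRecord:
    """One heavy atom of a structure."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    coord: np.ndarray
    element: str


@dataclass
class FFAnnotation:
    """Force-field annotation of one atom (see forcefield module)."""

    charge: float
    vdw_rstar: float
    vdw_eps: float
    atom_type: str
    asp: float


class Structure:
    """Ordered heavy-atom array for one molecule (protein or DNA).

    Internally column-based (numpy arrays) for vectorised geometry and
    energy evaluation; :attr:`atoms` exposes per-atom records.
    """

    def __init__(self, names, resnames, chains, resseqs, coords, elements,
                 moltype: str, serials=None):
        n = len(names)
        self.names = list(names)
        self.resnames = list(resnames)
        self.chains = list(chains)
        self.resseqs = np.asarray(resseqs, dtype=int)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.elements = list(elements)
        self.moltype = moltype
        self.serials = (np.arange(1, n + 1) if serials is None
                        else np.asarray(serials, dtype=int))
        # filled by assign_forcefield
        self.charges: np.ndarray | None = None
        self.vdw_rstar: np.ndarray | None = None
        self.vdw_eps: np.ndarray | None = None
        self.asp: np.ndarray | None = None
        self.atom_types: list[str] | None = None

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def annotated(self) -> bool:
        return self.charges is not None

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(int(self.serials[i]), self.names[i], self.resnames[i],
                       self.chains[i], int(self.resseqs[i]), self.coords[i],
                       self.elements[i])
            for i in range(len(self))
        ]

    @property
    def annotations(self) -> list[FFAnnotation]:
        if not self.annotated:
            raise ValueError("structure has not been annotated; "
                             "run assign_forcefield first")
        return [
            FFAnnotation(float(self.charges[i]), float(self.vdw_rstar[i]),
                         float(self.vdw_eps[i]), self.atom_types[i],
                         float(self.asp[i]))
            for i in range(len(self))
        ]

    def copy(self) -> "Structure":
        s = Structure(self.names, self.resnames, self.chains, self.resseqs,
                      self.coords.copy(), self.elements, self.moltype,
                      self.serials.copy())
        if self.annotated:
            s.charges = self.charges.copy()
            s.vdw_rstar = self.vdw_rstar.copy()
            s.vdw_eps = self.vdw_eps.copy()
            s.asp = self.asp.copy()
            s.atom_types = list(self.atom_types)
        return s

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy sharing all metadata/annotations but with new coordinates."""
        s = self.copy()
        s.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        return s

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def residue_index(self) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain, resseq) -> atom indices, preserving order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i in range(len(self)):
            out.setdefault((self.chains[i], int(self.resseqs[i])), []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}


def infer_moltype(resnames) -> str:
    """Majority vote over residues: protein vs dna."""
    n_prot = sum(1 for r in resnames if r in _AA3)
    n_dna = sum(1 for r in resnames if r in _DNA_ALIASES.values()
                or r in ("DA", "DC", "DG", "DT"))
    if n_prot and n_dna:
        logger.warning("mixed protein (%d) and DNA (%d) residues in one "
                       "molecule; moltype set by majority", n_prot, n_dna)
    return "protein" if n_prot >= n_dna else "dna"


def read_pdb(path, chains: set[str] | None = None) -> Structure:
    """Read a PDB file into a heavy-atom :class:`Structure`.

    Keeps only the selected chains (all if ``chains`` is None); collapses
    altLoc duplicates to the highest-occupancy copy; drops hydrogens, waters
    and residues without a shipped template (logged).
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - surface as one fatal parse error
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc

    if chains is not None:
        chains = {str(c) for c in chains}
        arr = arr[np.isin(arr.chain_id, list(chains))]
        if arr.array_length() == 0:
            raise ValueError(f"no atoms in selected chains {sorted(chains)}")

    names, resnames, chain_ids, resseqs, coords, elements = [], [], [], [], [], []
    dropped: set[str] = set()
    for i in range(arr.array_length()):
        rn = canonical_resname(arr.res_name[i])
        if rn is None:
            if arr.res_name[i].strip().upper() not in _WATER:
                dropped.add(arr.res_name[i])
            continue
        el = (arr.element[i] or "").strip().upper()
        name = canonical_atom_name(arr.atom_name[i])
        if not el:
            el = name[0] if name[0].isalpha() else name[1]
        if el in ("H", "D"):
            continue
        names.append(name)
        resnames.append(rn)
        chain_ids.append(str(arr.chain_id[i]))
        resseqs.append(int(arr.res_id[i]))
        coords.append(arr.coord[i])
        elements.append(el)

    if dropped:
        logger.warning("%s: dropped non-standard residues: %s", path.name,
                       ", ".join(sorted(dropped)))
    if not names:
        raise ValueError(f"no usable ATOM records in {path}")

    moltype = infer_moltype(resnames)
    return Structure(names, resnames, chain_ids, resseqs, np.asarray(coords),
                     elements, moltype)


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as standard PDB ATOM records.

    Serials are renumbered 1-based; a TER record separates chains; original
    chain IDs and residue numbers are preserved.
    """
    if len(s) == 0:
        raise ValueError("cannot write an empty structure")
    if np.any(np.abs(s.coords) >= 10000.0):
        raise ValueError("coordinate magnitude >= 10,000 A does not fit the "
                         "fixed-column PDB format")
    lines = []
    serial = 0
    for i in range(len(s)):
        if i > 0 and s.chains[i] != s.chains[i - 1]:
            serial += 1
            lines.append(f"TER   {serial:5d}      {s.resnames[i-1]:>3s} "
                         f"{s.chains[i-1]:1s}{int(s.resseqs[i-1]):4d}")
        serial += 1
        name = s.names[i]
        # PDB column rule: 4-char names start in col 13, shorter in col 14
        name_field = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {serial:5d} {name_field:<4s} {s.resnames[i]:>3s} "
            f"{s.chains[i]:1s}{int(s.resseqs[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {s.elements[i]:>2s}"
        )
    serial += 1
    lines.append(f"TER   {serial:5d}      {s.resnames[-1]:>3s} "
                 f"{s.chains[-1]:1s}{int(s.resseqs[-1]):4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def concat_structures(a: Structure, b: Structure) -> Structure:
    """Concatenate two structures into one (e.g. a docked complex).

    moltype is taken by majority without the mixed-content warning, since a
    complex is mixed by construction.  Annotations are carried over when both
    inputs are annotated.
    """
    n_prot = sum(len(s) for s in (a, b) if s.moltype == "protein")
    n_dna = sum(len(s) for s in (a, b) if s.moltype == "dna")
    out = Structure(a.names + b.names, a.resnames + b.resnames,
                    a.chains + b.chains,
                    np.concatenate([a.resseqs, b.resseqs]),
                    np.vstack([a.coords, b.coords]),
                    a.elements + b.elements,
                    "protein" if n_prot >= n_dna else "dna")
    if a.annotated and b.annotated:
        out.charges = np.concatenate([a.charges, b.charges])
        out.vdw_rstar = np.concatenate([a.vdw_rstar, b.vdw_rstar])
        out.vdw_eps = np.concatenate([a.vdw_eps, b.vdw_eps])
        out.asp = np.concatenate([a.asp, b.asp])
        out.atom_types = a.atom_types + b.atom_types
    return out


def max_span(s: Structure) -> float:
    """Longest distance between any pair of atoms (Å).

    Exact: the diameter is attained on the convex hull, which keeps the
    pairwise computation small for large molecules.
    """
    if len(s) < 2:
        raise ValueError("max_span requires at least 2 atoms")
    pts = s.coords
    if len(pts) > 50:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[np.unique(ConvexHull(pts).vertices)]
        except Exception:  # degenerate (collinear/coplanar) inputs
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))
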