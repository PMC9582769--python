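"""AMBER94-derived force-field annotation.

Structures are modelled with heavy atoms only (crystallographic PDB inputs
rarely carry hydrogens): every hydrogen partial charge of the all-atom AMBER94
template is summed into its bonded heavy atom, which preserves the template
net charge of each residue exactly.

Each heavy atom receives
  * a partial charge (elementary charges),
  * 6-12 vdW parameters r*/eps (Å, kcal/mol),
  * an atom type (the AMBER94 type key), and
  * an atomic solvation coefficient (asp, kcal/(mol·Å²)) used by the
    desolvation term.  Nucleotide-only atom types are mapped to the
    chemically nearest protein type for asp lookup (the nuc.dat analogue).

All tables are plain-text data files under ``dnadock/data`` so that users can
swap parameter sets (e.g. alternative solvation models) without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure import Structure, canonical_atom_name

logger = logging.getLogger("dnadock")

# neutral fallbacks for atoms without a template entry, keyed by element
_ELEMENT_DEFAULT_VDW = {
    "C": (1.9080, 0.0860),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
    "P": (2.1000, 0.2000),
}
_GENERIC_VDW = (1.7000, 0.1000)


@dataclass
class ParameterTables:
    """Residue charge/type templates plus per-type vdW and solvation tables."""

    # resname -> atomname -> (collapsed charge, atom_type)
    residues: dict[str, dict[str, tuple[float, str]]] = field(default_factory=dict)
    # atom_type -> (rstar, eps)
    vdw: dict[str, tuple[float, float]] = field(default_factory=dict)
    # atom_type -> asp (protein types only)
    asp: dict[str, float] = field(default_factory=dict)
    # nucleotide-only atom_type -> protein atom_type (asp lookup)
    nucmap: dict[str, str] = field(default_factory=dict)

    def asp_for(self, atom_type: str) -> float:
        if atom_type in self.asp:
            return self.asp[atom_type]
        mapped = self.nucmap.get(atom_type)
        if mapped is not None and mapped in self.asp:
            return self.asp[mapped]
        return 0.0

    def validate(self) -> None:
        for res, atoms in self.residues.items():
            for name, (_q, typ) in atoms.items():
                if typ not in self.vdw:
                    raise ValueError(
                        f"template {res}:{name} references unknown atom type {typ}")
        for nuc, prot in self.nucmap.items():
            if prot not in self.asp:
                raise ValueError(
                    f"nucleotide map {nuc}->{prot}: target type has no asp entry")


def _read_rows(package_file: str):
    text = (resources.files("dnadock") / "data" / package_file).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split()


def load_parameter_tables() -> ParameterTables:
    """Load the shipped parameter set (amino94 / nuc94 / atomtypes / nucmap)."""
    tables = ParameterTables()

    # pass 1: all-atom rows; collapse hydrogen charges into parents afterwards
    heavy: dict[str, dict[str, list]] = {}
    hydrogens: list[tuple[str, str, float]] = []  # (res, parent, charge)
    for fname in ("amino94.dat", "nuc94.dat"):
        for lineno, parts in _read_rows(fname):
            if len(parts) != 6:
                raise ValueError(f"{fname}:{lineno}: expected 6 columns")
            res, atom, element, parent, charge, typ = parts
            q = float(charge)
            if element == "H":
                hydrogens.append((res, parent, q))
            else:
                heavy.setdefault(res, {})[atom] = [q, typ]
    for res, parent, q in hydrogens:
        if res not in heavy or parent not in heavy[res]:
            raise ValueError(f"hydrogen in {res} references unknown parent {parent}")
        heavy[res][parent][0] += q
    tables.residues = {
        res: {atom: (q, typ) for atom, (q, typ) in atoms.items()}
        for res, atoms in heavy.items()
    }

    for lineno, parts in _read_rows("atomtypes.dat"):
        if len(parts) != 4:
            raise ValueError(f"atomtypes.dat:{lineno}: expected 4 columns")
        typ, rstar, eps, asp = parts
        tables.vdw[typ] = (float(rstar), float(eps))
        if asp != "-":
            tables.asp[typ] = float(asp)

    for lineno, parts in _read_rows("nucmap.dat"):
        if len(parts) != 2:
            raise ValueError(f"nucmap.dat:{lineno}: expected 2 columns")
        tables.nucmap[parts[0]] = parts[1]

    tables.validate()
    return tables


_DEFAULT_TABLES: ParameterTables | None = None


def default_tables() -> ParameterTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_parameter_tables()
    return _DEFAULT_TABLES


def assign_forcefield(s: Structure, tables: ParameterTables | None = None) -> Structure:
    """Annotate every heavy atom with charge, vdW, atom type and asp.

    Unmatched atoms (terminal OXT, unusual names, residues without a
    template) get zero charge, element-default vdW parameters, asp 0 and
    atom type ``UNK``; each is logged, never fatal.  Returns an annotated
    copy; the input is left untouched.
    """
    if tables is None:
        tables = default_tables()
    out = s.copy()
    n = len(out)
    charges = np.zeros(n)
    rstar = np.zeros(n)
    eps = np.zeros(n)
    asp = np.zeros(n)
    types: list[str] = []
    unmatched: list[str] = []

    for i in range(n):
        res = out.resnames[i]
        name = canonical_atom_name(out.names[i])
        entry = tables.residues.get(res, {}).get(name)
        if entry is None:
            el = out.elements[i]
            r, e = _ELEMENT_DEFAULT_VDW.get(el, _GENERIC_VDW)
            charges[i], rstar[i], eps[i], asp[i] = 0.0, r, e, 0.0
            types.append("UNK")
            unmatched.append(f"{res}:{out.chains[i]}{int(out.resseqs[i])}:{name}")
            continue
        q, typ = entry
        r, e = tables.vdw[typ]
        charges[i] = q
        rstar[i] = r
        eps[i] = e
        asp[i] = tables.asp_for(typ)
        types.append(typ)

    if unmatched:
        logger.warning("%d atom(s) without template entry, neutral defaults "
                       "applied: %s", len(unmatched),
                       ", ".join(unmatched[:10]) +
                       (" ..." if len(unmatched) > 10 else ""))
    out.charges = charges
    out.vdw_rstar = rstar
    out.vdw_eps = eps
    out.asp = asp
    out.atom_types = types
    return out
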