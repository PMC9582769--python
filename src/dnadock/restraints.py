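"""Residue–nucleotide distance restraints for rescoring docking models.

A restraint names one protein residue and one DNA nucleotide; it is satisfied
when their minimum heavy-atom distance is within the cutoff (default 6.5 Å,
inclusive).  Each satisfied restraint contributes −weight (default 1.0
kcal/mol) as a pseudo-energy reward added to the composite score, so models
consistent with external information rank better.

Restraint file format — one restraint per line:

    prot_chain:resseq dna_chain:resseq [cutoff] [weight]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import Structure

DEFAULT_RESTRAINT_CUTOFF = 6.5  # Å
DEFAULT_RESTRAINT_WEIGHT = 1.0  # kcal/mol


@dataclass
class Restraint:
    protein_chain: str
    protein_resseq: int
    dna_chain: str
    dna_resseq: int
    cutoff: float = DEFAULT_RESTRAINT_CUTOFF
    weight: float = DEFAULT_RESTRAINT_WEIGHT

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("restraint cutoff must be positive")


def _parse_residue(token: str, lineno: int):
    parts = token.split(":")
    if len(parts) != 2 or not parts[0]:
        raise ValueError(f"restraint file line {lineno}: expected "
                         f"'chain:resseq', got {token!r}")
    try:
        return parts[0], int(parts[1])
    except ValueError:
        raise ValueError(f"restraint file line {lineno}: residue number "
                         f"{parts[1]!r} is not an integer") from None


def parse_restraints(path) -> list[Restraint]:
    """Parse a restraint file; malformed lines raise with their line number."""
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2 or len(fields) > 4:
            raise ValueError(f"restraint file line {lineno}: expected 2-4 "
                             f"fields, got {len(fields)}")
        pc, pr = _parse_residue(fields[0], lineno)
        dc, dr = _parse_residue(fields[1], lineno)
        cutoff = float(fields[2]) if len(fields) > 2 else DEFAULT_RESTRAINT_CUTOFF
        weight = float(fields[3]) if len(fields) > 3 else DEFAULT_RESTRAINT_WEIGHT
        out.append(Restraint(pc, pr, dc, dr, cutoff, weight))
    return out


def _residue_coords(s: Structure, chain: str, resseq: int,
                    what: str) -> np.ndarray:
    mask = [i for i in range(len(s))
            if s.chains[i] == chain and int(s.resseqs[i]) == resseq]
    if not mask:
        raise ValueError(f"restraint references missing {what} residue "
                         f"{chain}:{resseq}")
    return s.coords[mask]


def satisfied(r: Restraint, receptor: Structure,
              posed_ligand: Structure) -> bool:
    """True iff min heavy-atom distance residue↔nucleotide ≤ cutoff."""
    protein, dna = ((receptor, posed_ligand)
                    if receptor.moltype == "protein"
                    else (posed_ligand, receptor))
    pc = _residue_coords(protein, r.protein_chain, r.protein_resseq, "protein")
    dc = _residue_coords(dna, r.dna_chain, r.dna_resseq, "DNA")
    d2 = np.sum((pc[:, None, :] - dc[None, :, :]) ** 2, axis=-1)
    return bool(np.sqrt(d2.min()) <= r.cutoff)


def restraint_energy(restraints: list[Restraint], receptor: Structure,
                     posed_ligand: Structure) -> float:
    """−Σ weight over satisfied restraints (more satisfied → better score)."""
    return -sum(r.weight for r in restraints
                if satisfied(r, receptor, posed_ligand))
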