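"""Canonical straight-fiber B-DNA duplex builder.

A duplex is assembled from per-nucleotide heavy-atom templates expressed in a
Watson-Crick base-pair reference frame (shipped in ``data/bdna_template.dat``):
base pair *i* is the template rotated by ``(i-1)·twist`` about the helix axis
(z) and translated ``(i-1)·rise`` along it.  Strand 2 is generated by the pair
dyad (180° rotation about the frame x axis) applied to the complementary base
template, giving an antiparallel second strand whose 5'→3' sequence is the
reverse complement of the input.

Defaults are the canonical B-form fiber values: twist 36.0°/bp and rise
3.38 Å/bp.  The template file is plain text and can be replaced wholesale,
e.g. with exact fiber-diffraction coordinates from 3DNA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure import Structure

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_FIVE_PRIME_ONLY = {"P", "OP1", "OP2"}  # absent from 5'-terminal residues


def complement(seq: str) -> str:
    """Reverse complement (the antiparallel Watson-Crick partner strand)."""
    seq = validate_sequence(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def validate_sequence(seq: str) -> str:
    s = seq.strip().upper()
    if not s:
        raise ValueError("empty DNA sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid DNA sequence characters: {sorted(bad)}")
    return s


@dataclass
class HelixParams:
    """Straight-fiber helical parameters and base-pair templates."""

    twist: float = 36.0   # degrees per base pair
    rise: float = 3.38    # Å per base pair
    # base -> (atom names, elements, coords (n,3)) in the pair frame
    templates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.twist < 360.0:
            raise ValueError("twist must be in (0, 360) degrees")
        if self.rise <= 0.0:
            raise ValueError("rise must be positive")
        if not self.templates:
            self.templates = _load_templates()


def _load_templates() -> dict:
    text = (resources.files("dnadock") / "data" / "bdna_template.dat").read_text()
    raw: dict[str, list] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        base, atom, element, x, y, z = line.split()
        raw.setdefault(base, []).append((atom, element, [float(x), float(y), float(z)]))
    out = {}
    for base, rows in raw.items():
        names = [r[0] for r in rows]
        elements = [r[1] for r in rows]
        coords = np.array([r[2] for r in rows])
        out[base] = (names, elements, coords)
    return out


def _rz(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_DYAD = np.diag([1.0, -1.0, -1.0])  # 180° about the pair-frame x axis


def build_bdna(seq: str, params: HelixParams | None = None,
               chain_ids: tuple[str, str] = ("A", "B")) -> Structure:
    """Build an idealized B-DNA duplex Structure from a sequence (5'→3').

    Chain ``chain_ids[0]`` carries ``seq``; chain ``chain_ids[1]`` the reverse
    complement, written 5'→3' (i.e. residue 1 of strand 2 pairs with the last
    residue of strand 1).  5'-terminal residues lack the phosphate group.
    """
    seq = validate_sequence(seq)
    if params is None:
        params = HelixParams()
    n = len(seq)

    def pair_transform(i: int):
        return _rz(params.twist * i), np.array([0.0, 0.0, params.rise * i])

    names, resnames, chains, resseqs, coords, elements = [], [], [], [], [], []

    def emit(base: str, strand2: bool, pair_idx: int, chain: str, resseq: int):
        t_names, t_elements, t_coords = params.templates[base]
        xyz = t_coords @ _DYAD.T if strand2 else t_coords
        R, t = pair_transform(pair_idx)
        xyz = xyz @ R.T + t
        five_prime = resseq == 1
        for nm, el, c in zip(t_names, t_elements, xyz):
            if five_prime and nm in _FIVE_PRIME_ONLY:
                continue
            names.append(nm)
            resnames.append(_RESNAME[base])
            chains.append(chain)
            resseqs.append(resseq)
            elements.append(el)
            coords.append(c)

    for i, base in enumerate(seq):
        emit(base, False, i, chain_ids[0], i + 1)
    for j, base in enumerate(complement(seq)):  # 5'→3' on strand 2
        pair_idx = n - 1 - j  # pairs with strand-1 residue pair_idx+1
        emit(base, True, pair_idx, chain_ids[1], j + 1)

    return Structure(names, resnames, chains, resseqs, np.array(coords),
                     elements, "dna")
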