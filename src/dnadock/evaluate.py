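"""Benchmark-style evaluation of docking models against a reference complex.

The quality metric is the ligand RMSD (L-RMSD): the model receptor is
superposed onto the reference receptor (least-squares, Kabsch) and the RMSD
of the transformed model ligand against the reference ligand is reported.
A model with L-RMSD ≤ 10 Å is *near-native*; the top-N success rate of a case
set is the percentage of cases with a near-native model ranked ≤ N.

Cases are also classifiable by conformational flexibility (RMSD between the
unbound input and its bound form): protein — low < 1 Å, 1 ≤ medium < 3,
high ≥ 3; DNA — low < 3 Å, 3 ≤ medium < 5, high ≥ 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch, rmsd
from .structure import Structure

NEAR_NATIVE_LRMSD = 10.0  # Å

# backbone atom selections for the optional reduced-atom RMSD mode
_BACKBONE_ATOMS = {"protein": {"CA"}, "dna": {"P", "C1'"}}
_DNA_RESNAMES = {"DA", "DC", "DG", "DT"}


def _is_backbone(resname: str, atom_name: str) -> bool:
    kind = "dna" if resname in _DNA_RESNAMES else "protein"
    return atom_name in _BACKBONE_ATOMS[kind]


@dataclass
class EvaluationReport:
    """Per-case evaluation of a ranked model list against a reference."""

    lrmsds: list[float]
    near_native: list[bool] = field(default_factory=list)
    first_hit_rank: int | None = None
    protein_class: str | None = None
    dna_class: str | None = None

    def __post_init__(self):
        if not self.near_native:
            self.near_native = [x <= NEAR_NATIVE_LRMSD for x in self.lrmsds]
        hits = [i + 1 for i, nn in enumerate(self.near_native) if nn]
        self.first_hit_rank = hits[0] if hits else None


def _atom_key(s: Structure, i: int) -> tuple:
    return (s.chains[i], int(s.resseqs[i]), s.names[i])


def _shared_coords(model: Structure, reference: Structure,
                   chains: set[str], backbone_only: bool,
                   mapping: dict[str, str] | None = None):
    """Paired coordinate arrays over shared atoms of the given chains.

    ``mapping`` optionally renames model chains to reference chains.
    """
    mapping = mapping or {}

    def keyed(s: Structure, selected: set[str], rename: bool):
        out = {}
        for i in range(len(s)):
            ch = mapping.get(s.chains[i], s.chains[i]) if rename else s.chains[i]
            if ch not in selected:
                continue
            if backbone_only and not _is_backbone(s.resnames[i], s.names[i]):
                continue
            out[(ch, int(s.resseqs[i]), s.names[i])] = s.coords[i]
        return out

    m = keyed(model, chains, rename=True)
    r = keyed(reference, chains, rename=False)
    shared = [k for k in m if k in r]
    if not shared:
        return np.zeros((0, 3)), np.zeros((0, 3)), 0
    return (np.array([m[k] for k in shared]),
            np.array([r[k] for k in shared]), len(shared))


def lrmsd_vs_reference(model: Structure, reference: Structure,
                       receptor_chains: set[str],
                       ligand_chains: set[str] | None = None,
                       backbone_only: bool = False,
                       mapping: dict[str, str] | None = None) -> float:
    """L-RMSD of a model complex vs the reference complex.

    Both structures hold receptor + ligand; atoms correspond by chain ID,
    residue number and atom name (an explicit chain mapping may override).
    The model receptor is Kabsch-superposed onto the reference receptor and
    that transform is applied to the model ligand before the RMSD.
    """
    receptor_chains = set(receptor_chains)
    if ligand_chains is None:
        ligand_chains = (set(reference.chains) - receptor_chains)
    mr, rr, n_rec = _shared_coords(model, reference, receptor_chains,
                                   backbone_only, mapping)
    if n_rec < 3:
        raise ValueError("no (or too few) shared receptor atoms for "
                         "superposition")
    ml, rl, n_lig = _shared_coords(model, reference, set(ligand_chains),
                                   backbone_only, mapping)
    if n_lig == 0:
        raise ValueError("no shared ligand atoms between model and reference")
    R, t, _ = kabsch(mr, rr)
    return rmsd(ml @ R.T + t, rl)


def success_rate(cases: list[EvaluationReport], n: int) -> float:
    """Percentage of cases with a near-native model within the top n."""
    if not cases:
        raise ValueError("empty case list")
    hits = sum(1 for c in cases
               if c.first_hit_rank is not None and c.first_hit_rank <= n)
    return 100.0 * hits / len(cases)


def flexibility_class(unbound_bound_rmsd: float, moltype: str) -> str:
    """Flexibility category from the unbound-bound RMSD (Å)."""
    if unbound_bound_rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    if moltype == "protein":
        low_hi, med_hi = 1.0, 3.0
    elif moltype == "dna":
        low_hi, med_hi = 3.0, 5.0
    else:
        raise ValueError("moltype must be 'protein' or 'dna'")
    if unbound_bound_rmsd < low_hi:
        return "low"
    if unbound_bound_rmsd < med_hi:
        return "medium"
    return "high"


def unbound_bound_rmsd(unbound: Structure, bound: Structure,
                       backbone_only: bool = False,
                       mapping: dict[str, str] | None = None) -> float:
    """RMSD over shared heavy atoms after optimal superposition (Kabsch)."""
    chains = set(bound.chains)
    mu, mb, n = _shared_coords(unbound, bound, chains, backbone_only, mapping)
    if n < 3:
        raise ValueError("fewer than 3 shared atoms between unbound and bound")
    _R, _t, value = kabsch(mu, mb)
    return value


def evaluate_models(models: list[Structure], reference: Structure,
                    receptor_chains: set[str],
                    backbone_only: bool = False,
                    mapping: dict[str, str] | None = None) -> EvaluationReport:
    """Evaluate a ranked model list: per-model L-RMSD and near-native flags."""
    lrmsds = [lrmsd_vs_reference(m, reference, receptor_chains,
                                 backbone_only=backbone_only, mapping=mapping)
              for m in models]
    return EvaluationReport(lrmsds=lrmsds)
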