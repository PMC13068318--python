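"""Reading peptide-HLA class II complexes and assigning chain roles.

A complex is reduced to three polymer chains: the groove-forming *alpha* and
*beta* chains and the bound *peptide*.  Structures are parsed with gemmi from
either PDB or mmCIF.  Author residue numbering (with insertion codes) is
preserved, heteroatoms/waters are discarded, and for alternate conformations
only the highest-occupancy conformer of each atom is kept.  Residues with a
non-standard chemical component (e.g. citrulline, phosphoserine) are retained
in the sequence but flagged ``modified``; residues without any heavy atom are
flagged ``unmodeled``.  Both kinds are excluded from contact counting
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .errors import AmbiguityError, FormatError, RoleAssignmentError

ROLES = ("alpha", "beta", "peptide")

#: default length window (inclusive) used to recognise the peptide chain;
#: CLIP fragments run 15-18 residues and minimal cores are 9.
DEFAULT_PEPTIDE_WINDOW = (9, 30)

_STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    """One polymer residue with author numbering preserved."""

    original_number: str          # author number + insertion code, e.g. "52" or "52A"
    three_letter_code: str
    one_letter_code: str          # 'X' for anything outside the 20 standard codes
    atoms: list[Atom] = field(default_factory=list)
    unmodeled: bool = False
    modified: bool = False

    @property
    def seq_num(self) -> int:
        digits = "".join(c for c in self.original_number if c.isdigit() or c == "-")
        return int(digits)

    @property
    def usable(self) -> bool:
        """True if the residue can enter contact analysis."""
        return not (self.unmodeled or self.modified)


@dataclass
class Chain:
    role: str | None
    residues: list[Residue]
    original_chain_id: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter_code for r in self.residues)


@dataclass
class ComplexStructure:
    structure_id: str
    chains: list[Chain]
    source_format: str  # "pdb" | "mmcif"

    def chain(self, role: str) -> Chain:
        for c in self.chains:
            if c.role == role:
                return c
        raise KeyError(f"no chain with role {role!r}")

    @property
    def alpha(self) -> Chain:
        return self.chain("alpha")

    @property
    def beta(self) -> Chain:
        return self.chain("beta")

    @property
    def peptide(self) -> Chain:
        return self.chain("peptide")

    def to_summary(self) -> dict:
        """Normalized JSON-ready summary of chains, roles and flags."""
        return {
            "structure_id": self.structure_id,
            "source_format": self.source_format,
            "chains": [
                {
                    "id": c.original_chain_id,
                    "role": c.role,
                    "length": len(c),
                    "sequence": c.sequence,
                    "unmodeled": [r.original_number for r in c.residues if r.unmodeled],
                    "modified": [r.original_number for r in c.residues if r.modified],
                }
                for c in self.chains
            ],
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_summary(), indent=2) + "\n")


def _one_letter(name: str) -> str:
    return _STANDARD_AA.get(name.upper(), "X")


def _convert_residue(res: gemmi.Residue) -> Residue:
    # keep highest-occupancy conformer per atom name
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = []
    for name in best:
        a = best[name]
        if np.isfinite([a.pos.x, a.pos.y, a.pos.z]).all():
            atoms.append(Atom(a.element.name, name, (a.pos.x, a.pos.y, a.pos.z)))
    code = res.name.upper()
    icode = res.seqid.icode.strip()
    return Residue(
        original_number=f"{res.seqid.num}{icode}",
        three_letter_code=code,
        one_letter_code=_one_letter(code),
        atoms=atoms,
        unmodeled=len(atoms) == 0,
        modified=code not in _STANDARD_AA,
    )


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # modified monomers often are not tabulated as amino acids; treat any
    # residue with backbone-like atoms as polymer
    names = {a.name for a in res}
    return bool({"CA", "N", "C"} & names)


def _fill_numbering_gaps(residues: list[Residue]) -> list[Residue]:
    """Insert atom-less placeholders for author-numbering gaps (no icodes)."""
    out: list[Residue] = []
    for res in residues:
        if out and not any(c.isalpha() for c in res.original_number):
            prev = out[-1]
            if not any(c.isalpha() for c in prev.original_number):
                for n in range(prev.seq_num + 1, res.seq_num):
                    out.append(Residue(str(n), "UNK", "X", [], unmodeled=True,
                                       modified=False))
        out.append(res)
    return out


def parse_chains(path: str | Path) -> tuple[list[Chain], str]:
    """Parse a PDB/mmCIF file into role-less chains (first model only)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no coordinate model")
    fmt = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    st.remove_hydrogens()
    st.remove_ligands_and_waters()
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues = [_convert_residue(r) for r in ch if _is_polymer_residue(r)]
        if not residues:
            continue
        chains.append(Chain(None, _fill_numbering_gaps(residues), ch.name))
    if not chains:
        raise FormatError(f"{path} contains no polymer chains")
    return chains, fmt


def assign_roles(
    chains: Sequence[Chain],
    length_window: tuple[int, int] = DEFAULT_PEPTIDE_WINDOW,
    prototype_seqs: Mapping[str, str] | None = None,
    chain_config: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map the three roles to chain ids.

    The peptide is the shortest polymer chain inside ``length_window``; alpha
    and beta are told apart by global-alignment score against the prototype
    chain sequences.  Extra chains (e.g. a bound T-cell receptor pair) are
    ignored.  The result is deterministic and permutation-invariant with
    respect to chain order in the file.
    """
    from .chain_numbering import alignment_score  # local import, no cycle

    chain_config = dict(chain_config or {})
    by_id = {c.original_chain_id: c for c in chains}
    roles: dict[str, str] = {}
    for role, cid in chain_config.items():
        if role not in ROLES:
            raise RoleAssignmentError(f"unknown role {role!r} in chain_config")
        if cid not in by_id:
            raise RoleAssignmentError(
                f"chain_config names chain {cid!r} which is not in the file",
                candidates=sorted(by_id))
        roles[role] = cid

    if "peptide" not in roles:
        lo, hi = length_window
        in_window = sorted(
            (c for c in chains
             if lo <= len(c) <= hi and c.original_chain_id not in roles.values()),
            key=lambda c: (len(c), c.original_chain_id),
        )
        if not in_window:
            raise RoleAssignmentError(
                "no chain falls in the peptide length window "
                f"{length_window}; pass chain_config",
                candidates=[(c.original_chain_id, len(c)) for c in chains])
        if len(in_window) > 1 and len(in_window[0]) == len(in_window[1]):
            raise AmbiguityError(
                "two chains tie for the peptide role; pass chain_config",
                candidates=[(c.original_chain_id, len(c)) for c in in_window])
        roles["peptide"] = in_window[0].original_chain_id

    missing = [r for r in ("alpha", "beta") if r not in roles]
    if missing:
        if prototype_seqs is None:
            from .datasets import synthetic_prototype_chains
            prototype_seqs = synthetic_prototype_chains()
        candidates = [c for c in chains
                      if c.original_chain_id not in roles.values()]
        if len(candidates) < len(missing):
            raise RoleAssignmentError(
                "not enough chains left for alpha/beta assignment",
                candidates=[c.original_chain_id for c in candidates])
        scores = {
            c.original_chain_id: {
                role: alignment_score(c.sequence, prototype_seqs[role])
                for role in ("alpha", "beta")
            }
            for c in candidates
        }
        best, best_assign = None, None
        for ca in candidates:
            for cb in candidates:
                if ca is cb:
                    continue
                assign = dict(roles)
                assign["alpha"] = ca.original_chain_id
                assign["beta"] = cb.original_chain_id
                if "alpha" in roles and assign["alpha"] != roles["alpha"]:
                    continue
                if "beta" in roles and assign["beta"] != roles["beta"]:
                    continue
                total = (scores[ca.original_chain_id]["alpha"]
                         + scores[cb.original_chain_id]["beta"])
                key = (total, assign["alpha"], assign["beta"])
                if best is None or key > best:
                    best, best_assign = key, assign
        ties = 0
        for ca in candidates:
            for cb in candidates:
                if ca is cb:
                    continue
                total = (scores[ca.original_chain_id]["alpha"]
                         + scores[cb.original_chain_id]["beta"])
                if best is not None and total == best[0]:
                    ties += 1
        if best_assign is None:
            raise RoleAssignmentError("alpha/beta assignment failed",
                                      candidates=sorted(scores))
        if ties > 1:
            raise AmbiguityError(
                "alpha/beta assignment is ambiguous; pass chain_config",
                candidates=sorted(scores))
        roles = best_assign
    return roles


def load_complex(
    path: str | Path,
    chain_config: Mapping[str, str] | None = None,
    length_window: tuple[int, int] = DEFAULT_PEPTIDE_WINDOW,
    prototype_seqs: Mapping[str, str] | None = None,
) -> ComplexStructure:
    """Load a structure file and return it with chain roles assigned.

    Residues are never silently dropped: non-standard monomers are flagged
    ``modified`` and coordinate-less residues ``unmodeled``.
    """
    path = Path(path)
    chains, fmt = parse_chains(path)
    if len(chains) < 3 and not (chain_config and len(chain_config) == 3):
        raise RoleAssignmentError(
            f"{path.name} has {len(chains)} polymer chains; need three roles "
            "or an explicit chain_config",
            candidates=[(c.original_chain_id, len(c)) for c in chains])
    roles = assign_roles(chains, length_window=length_window,
                         prototype_seqs=prototype_seqs,
                         chain_config=chain_config)
    by_id = {c.original_chain_id: c for c in chains}
    picked = []
    for role in ROLES:
        chain = by_id[roles[role]]
        chain.role = role
        picked.append(chain)
    return ComplexStructure(structure_id=path.stem, chains=picked,
                            source_format=fmt)


def pdb_text(complex_: ComplexStructure) -> str:
    """Render the (role-assigned) complex as minimal, deterministic PDB text."""
    lines = []
    serial = 1
    for chain in complex_.chains:
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.xyz
                num = res.seq_num
                icode = next((c for c in res.original_number if c.isalpha()), " ")
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{res.three_letter_code:>4s} "
                    f"{chain.original_chain_id[0]}{num:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(complex_: ComplexStructure, path: str | Path) -> None:
    Path(path).write_text(pdb_text(complex_))
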