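"""Synthetic, download-free test complexes with planted, known contacts.

A toy "groove" is built from three chains: a peptide laid out along the x
axis (one C-alpha per residue, 10 A apart), and alpha/beta chains whose
backbone sits on distant walls (y = +/-18 A).  Every planted contact triple
(peptide index, chain role, chain position) is realized by giving the chain
residue an extra side-chain pseudo-atom on a ring of slots around the partner
peptide residue, close enough to guarantee a positive contact surface area.
All non-planted peptide/chain atom pairs are kept beyond the geometric reach
of the contact construction, so contact recovery has exact ground truth
(precision and recall 1.0 at default parameters).  The chemistry is not
realistic and is not meant to be.

Slot geometry (default parameters): two rings of slots per peptide residue at
ring radius 4.3 A, offset +/-1.5 A along the peptide axis -- 14 slots in full
mode, or 7 when ``half_plane`` restricts partners to z < 0 (so that +z is an
unambiguous "out of the groove" direction for monotonicity experiments).
Chain IDs carry role hints (A = alpha, B = beta, C = peptide) so tests do not
have to rely on the role heuristic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .datasets import clip_peptide, synthetic_prototype_chains, unified_map
from .errors import GeometryError
from .structure_io import Atom, Chain, ComplexStructure, Residue, _STANDARD_AA

PlantedTriple = tuple[int, str, int]  # (peptide index 0-based, role, chain position 1-based)

_ONE_TO_THREE = {v: k for k, v in _STANDARD_AA.items()}

#: geometric constants (A); see module docstring
SPACING = 10.0
RING_RADIUS = 4.3
RING_XOFF = 1.5
WALL_Y = 18.0
WALL_STEP = 3.8
#: maximum centre distance at which the contact construction can attribute
#: surface area (max surface radius + max partner reach), plus margin
MIN_CLEAR = 7.7
MAX_PLANT = 6.4  # planted pairs stay inside the default 6.5 A prefilter


@dataclass(frozen=True)
class FixtureSpec:
    peptide_seq: str
    anchor_index: int                      # 0-based ground-truth anchor
    triples: tuple[PlantedTriple, ...]
    alpha_len: int = 95
    beta_len: int = 95
    half_plane: bool = False
    chain_mutation_rate: float = 0.0
    seed: int = 0

    @property
    def ground_truth(self) -> frozenset[PlantedTriple]:
        return frozenset(self.triples)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "peptide_seq", "anchor_index", "alpha_len", "beta_len",
            "half_plane", "chain_mutation_rate", "seed")}
        d["triples"] = [list(t) for t in self.triples]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        d["triples"] = tuple((int(a), str(b), int(c)) for a, b, c in d["triples"])
        return cls(**d)


@dataclass
class ToyComplex:
    complex: ComplexStructure
    ground_truth: frozenset[PlantedTriple]
    pdb_text: str
    spec: FixtureSpec

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.pdb_text)
        return path


def _slot_directions(half_plane: bool) -> list[tuple[float, float, float]]:
    """(x offset, y, z) of every slot relative to the peptide C-alpha."""
    slots = []
    if half_plane:
        # z < 0 only; 4 + 3 slots at >=47 deg spacing
        base = math.radians(196.0)
        step = math.radians(47.0)
        for k in range(4):
            t = base + k * step
            slots.append((-RING_XOFF, RING_RADIUS * math.cos(t),
                          RING_RADIUS * math.sin(t)))
        for k in range(3):
            t = base + (k + 0.5) * step
            slots.append((RING_XOFF, RING_RADIUS * math.cos(t),
                          RING_RADIUS * math.sin(t)))
    else:
        for k in range(7):
            t = 2.0 * math.pi * k / 7.0
            slots.append((-RING_XOFF, RING_RADIUS * math.cos(t),
                          RING_RADIUS * math.sin(t)))
        for k in range(7):
            t = 2.0 * math.pi * (k + 0.5) / 7.0
            slots.append((RING_XOFF, RING_RADIUS * math.cos(t),
                          RING_RADIUS * math.sin(t)))
    return slots


def _chain_sequence(role: str, length: int, rng: np.random.Generator,
                    mutation_rate: float) -> str:
    base = synthetic_prototype_chains()[role]
    seq = (base * (length // len(base) + 1))[:length]
    if mutation_rate > 0:
        letters = list(seq)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(length):
            if rng.random() < mutation_rate:
                letters[i] = str(rng.choice(aas))
        seq = "".join(letters)
    return seq


def _three(code: str) -> str:
    return _ONE_TO_THREE.get(code.upper(), "UNK")


def generate_toy_complex(spec: FixtureSpec,
                         out_path: str | Path | None = None) -> ToyComplex:
    """Build the toy complex and (optionally) write it as a PDB file.

    Deterministic: the same spec and seed give byte-identical files.  Raises
    :class:`GeometryError` for unrealizable specs (slot overflow, out-of-range
    indices, or a verification failure of the clearance rules).
    """
    pep = spec.peptide_seq.upper()
    if len(pep) < 9:
        raise GeometryError("peptide must be at least 9 residues long")
    if not 0 <= spec.anchor_index < len(pep):
        raise GeometryError("anchor index outside the peptide")
    chain_len = {"alpha": spec.alpha_len, "beta": spec.beta_len}
    per_residue: dict[int, list[PlantedTriple]] = {}
    seen = set()
    for t in spec.triples:
        i, role, pos = t
        if t in seen:
            raise GeometryError(f"duplicate planted triple {t}")
        seen.add(t)
        if not 0 <= i < len(pep):
            raise GeometryError(f"planted triple {t}: peptide index out of range")
        if role not in ("alpha", "beta"):
            raise GeometryError(f"planted triple {t}: unknown role")
        if not 1 <= pos <= chain_len[role]:
            raise GeometryError(f"planted triple {t}: chain position out of range")
        per_residue.setdefault(i, []).append(t)
    capacity = 7 if spec.half_plane else 14
    for i, ts in per_residue.items():
        if len(ts) > capacity:
            raise GeometryError(
                f"peptide residue {i} has {len(ts)} planted partners; "
                f"capacity is {capacity}")

    rng = np.random.default_rng(spec.seed)
    slots = _slot_directions(spec.half_plane)

    # pseudo-atom placement: (role, chain position) -> list of xyz
    pseudo: dict[tuple[str, int], list[tuple[float, float, float]]] = {}
    for i in sorted(per_residue):
        cx = SPACING * i
        for s, (pi, role, pos) in enumerate(sorted(per_residue[i])):
            dx, dy, dz = slots[s]
            pseudo.setdefault((role, pos), []).append((cx + dx, dy, dz))

    chains = []
    for role, cid, ysign in (("alpha", "A", 1.0), ("beta", "B", -1.0)):
        seq = _chain_sequence(role, chain_len[role], rng,
                              spec.chain_mutation_rate)
        residues = []
        for j, aa in enumerate(seq, start=1):
            atoms = [Atom("C", "CA", (WALL_STEP * j, ysign * WALL_Y, 0.0))]
            for k, xyz in enumerate(pseudo.get((role, j), ()), start=1):
                atoms.append(Atom("C", f"C{k}", xyz))
            residues.append(Residue(str(j), _three(aa), aa, atoms))
        chains.append(Chain(role, residues, cid))
    pep_residues = [
        Residue(str(i + 1), _three(aa), aa,
                [Atom("C", "CA", (SPACING * i, 0.0, 0.0))])
        for i, aa in enumerate(pep)
    ]
    chains.append(Chain("peptide", pep_residues, "C"))
    complex_ = ComplexStructure(structure_id=f"toy-{spec.seed}", chains=chains,
                                source_format="pdb")
    _verify_geometry(complex_, spec.ground_truth)

    from .structure_io import pdb_text as render_pdb
    toy = ToyComplex(complex=complex_, ground_truth=spec.ground_truth,
                     pdb_text=render_pdb(complex_), spec=spec)
    if out_path is not None:
        toy.write(out_path)
    return toy


def _verify_geometry(complex_: ComplexStructure,
                     planted: frozenset[PlantedTriple]) -> None:
    pep = complex_.peptide
    pep_xyz = [np.array([a.xyz for a in r.atoms]) for r in pep.residues]
    for chain in (complex_.alpha, complex_.beta):
        for j, res in enumerate(chain.residues, start=1):
            xyz = np.array([a.xyz for a in res.atoms])
            for i in range(len(pep.residues)):
                d = float(np.linalg.norm(
                    pep_xyz[i][:, None, :] - xyz[None, :, :], axis=-1).min())
                if (i, chain.role, j) in planted:
                    if d > MAX_PLANT:
                        raise GeometryError(
                            f"planted pair ({i}, {chain.role}, {j}) is {d:.1f} A "
                            "apart; not realizable")
                elif d < MIN_CLEAR:
                    raise GeometryError(
                        f"non-planted pair ({i}, {chain.role}, {j}) is only "
                        f"{d:.1f} A apart; would create a spurious contact")


def perturb_register(spec: FixtureSpec, shift: int) -> FixtureSpec:
    """Shift the planted peptide register; triples pushed off either end of
    the peptide are dropped and the ground truth updated accordingly."""
    if abs(shift) >= len(spec.peptide_seq):
        raise ValueError("shift must be smaller than the peptide length")
    moved = tuple((i + shift, role, pos) for (i, role, pos) in spec.triples
                  if 0 <= i + shift < len(spec.peptide_seq))
    return replace(spec, triples=moved,
                   anchor_index=min(max(spec.anchor_index + shift, 0),
                                    len(spec.peptide_seq) - 1))


# ----------------------------------------------------------- ready-made specs

def prototype_fixture_spec(group: str = "dr", seed: int = 0) -> FixtureSpec:
    """A toy prototype groove: the CLIP fragment of the group with the
    group's unified SC triples planted at their URN positions (URN position p
    maps to peptide index p - 1, anchor at URN 5)."""
    clip = clip_peptide(group)
    triples = tuple(sorted(
        (p - 1, role, pos) for (p, role, pos) in unified_map(group).triples))
    return FixtureSpec(peptide_seq=clip["sequence"], anchor_index=4,
                       triples=triples, seed=seed)


def random_register_spec(rng: np.random.Generator,
                         group: str = "dr",
                         keep_fraction: float = 0.85) -> FixtureSpec:
    """A random target complex sharing the prototype's contact architecture.

    The peptide gets a random sequence, length and anchor position; each
    prototype SC triple is re-indexed to the new register and kept with
    probability ``keep_fraction`` (anchor partners are always kept so the
    planted anchor stays recoverable).
    """
    proto = prototype_fixture_spec(group)
    length = int(rng.integers(12, 19))
    # anchor placed so that the URN core still fits on the peptide
    lo = 4 if group == "dr" else 3
    hi = length - 10
    if hi < lo:
        hi = lo
    anchor = int(rng.integers(lo, hi + 1))
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    seq = "".join(rng.choice(aas, size=length))
    triples = []
    for (i, role, pos) in proto.triples:
        j = i - proto.anchor_index + anchor
        if not 0 <= j < length:
            continue
        if j != anchor and rng.random() > keep_fraction:
            continue
        triples.append((j, role, pos))
    return FixtureSpec(peptide_seq=seq, anchor_index=anchor,
                       triples=tuple(sorted(triples)),
                       chain_mutation_rate=0.05,
                       seed=int(rng.integers(0, 2**31 - 1)))
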