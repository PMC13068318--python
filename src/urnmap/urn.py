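"""Unified residue numbering (URN): anchor detection, similar contacts and
validation.

The method aligns a peptide-HLA II complex to a prototype CLIP complex not by
sequence but by contacts.  The prototype's high-contact peptide position (URN
position 5 in both the DR and DQ grooves) defines a partner fingerprint: the
set of (chain role, chain position) residues it touches.  The target peptide
residue whose own partner set best overlaps that fingerprint becomes the
anchor and receives URN position 5; the rest of the peptide is numbered by
offset, which may run below 1 for long N-terminal flanks.  Contacts whose
(peptide URN position, chain role, chain position) triple also occurs in the
prototype map are *similar contacts* (SC) -- residue chemistry on either side
is deliberately ignored.  A numbering is accepted when at least 9 core
positions carry at least one SC and at least half of all core contacts are
similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chain_numbering import PositionMapping, align_to_prototype
from .contacts import ContactMap, ContactParams, residue_contacts
from .errors import NoAnchorError
from .structure_io import ComplexStructure

DEFAULT_ANCHOR_URN = 5
DEFAULT_OVERLAP_MIN = 0.6
CORE_RANGES = {"dr": (3, 14), "dq": (4, 14)}

Triple = tuple[int, str, int]  # (peptide URN position, chain role, chain position)


@dataclass
class UrnNumbering:
    positions: dict[int, int]     # peptide residue index -> URN position
    anchor_index: int
    anchor_urn: int = DEFAULT_ANCHOR_URN

    def urn_of(self, index: int) -> int:
        return self.positions[index]

    def index_of(self, urn: int) -> int | None:
        for idx, pos in self.positions.items():
            if pos == urn:
                return idx
        return None


@dataclass(frozen=True)
class SCRecord:
    peptide_urn: int
    chain_role: str
    chain_pos: int

    @property
    def triple(self) -> Triple:
        return (self.peptide_urn, self.chain_role, self.chain_pos)


@dataclass
class SCSet:
    records: frozenset[SCRecord]

    @classmethod
    def from_triples(cls, triples) -> "SCSet":
        return cls(frozenset(SCRecord(*t) for t in triples))

    @property
    def triples(self) -> frozenset[Triple]:
        return frozenset(r.triple for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self) -> set[int]:
        return {r.peptide_urn for r in self.records}

    def count(self, role: str) -> int:
        return sum(1 for r in self.records if r.chain_role == role)


@dataclass
class ValidationResult:
    positions_with_sc: int
    sc_count: int
    total_contacts_in_core: int
    sc_fraction: float
    valid: bool
    skipped_positions: list[int] = field(default_factory=list)
    core_range: tuple[int, int] = (3, 14)


@dataclass
class PrototypeReference:
    """A CLIP-bound complex reduced to what URN alignment needs."""

    group: str                              # "dr" | "dq" | custom label
    triples: frozenset[Triple]              # prototype contact map in URN
    anchor_urn: int
    anchor_partners: frozenset[tuple[str, int]]
    core_range: tuple[int, int]
    alpha_seq: str
    beta_seq: str
    alpha_positions: tuple[int, ...]        # author numbers of the alpha residues
    beta_positions: tuple[int, ...]
    peptide_len: int

    @classmethod
    def from_complex(cls, complex_: ComplexStructure, group: str,
                     params: ContactParams = ContactParams(),
                     anchor_urn: int | None = None,
                     core_range: tuple[int, int] | None = None,
                     ) -> "PrototypeReference":
        """Build the reference: the peptide is renumbered 1..n, the chain
        residues keep their author numbers, and the anchor defaults to the
        most-contacted peptide position (ties broken by alpha-chain count,
        then by the smaller position)."""
        cmap = residue_contacts(complex_, params)
        triples: set[Triple] = set()
        totals: dict[int, int] = {}
        alpha_counts: dict[int, int] = {}
        for rec in cmap.records:
            urn = rec.peptide_index + 1
            triples.add((urn, rec.chain_role, _num(rec.chain_number)))
            totals[urn] = totals.get(urn, 0) + 1
            if rec.chain_role == "alpha":
                alpha_counts[urn] = alpha_counts.get(urn, 0) + 1
        if not triples:
            raise NoAnchorError("prototype complex has no contacts")
        if anchor_urn is None:
            anchor_urn = max(totals,
                             key=lambda p: (totals[p], alpha_counts.get(p, 0), -p))
        partners = frozenset((role, pos) for (p, role, pos) in triples
                             if p == anchor_urn)
        if core_range is None:
            core_range = CORE_RANGES.get(group.lower(), (3, 14))
        return cls(
            group=group.lower(),
            triples=frozenset(triples),
            anchor_urn=anchor_urn,
            anchor_partners=partners,
            core_range=core_range,
            alpha_seq=complex_.alpha.sequence,
            beta_seq=complex_.beta.sequence,
            alpha_positions=tuple(r.seq_num for r in complex_.alpha.residues),
            beta_positions=tuple(r.seq_num for r in complex_.beta.residues),
            peptide_len=len(complex_.peptide),
        )

    def partner_set(self, urn: int) -> frozenset[tuple[str, int]]:
        return frozenset((role, pos) for (p, role, pos) in self.triples if p == urn)


def _num(author_number: str) -> int:
    return int("".join(c for c in str(author_number) if c.isdigit() or c == "-"))


def rank_registers(
    partner_sets: Mapping[int, set[tuple[str, int]]],
    prototype_partners: frozenset[tuple[str, int]],
) -> list[tuple[int, float, int]]:
    """Score every peptide residue as an anchor candidate.

    Returns (residue index, overlap with the prototype anchor partner set,
    total contact count), best first; ties favour more contacts, then the
    smaller residue index.
    """
    ranked = []
    denom = len(prototype_partners)
    for idx, partners in partner_sets.items():
        overlap = len(partners & prototype_partners) / denom if denom else 0.0
        ranked.append((idx, overlap, len(partners)))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return ranked


def find_anchor(
    target: ContactMap | Mapping[int, set[tuple[str, int]]],
    prototype: PrototypeReference,
    overlap_min: float = DEFAULT_OVERLAP_MIN,
) -> tuple[int, float]:
    """The target peptide residue matching the prototype's high-contact
    position.  Raises :class:`NoAnchorError` (with the ranked alternatives)
    when no residue reaches ``overlap_min`` of the prototype partner set."""
    partner_sets = target.partner_sets() if isinstance(target, ContactMap) else dict(target)
    if not partner_sets:
        raise NoAnchorError("target has no contacted peptide residue")
    ranked = rank_registers(partner_sets, prototype.anchor_partners)
    idx, overlap, _n = ranked[0]
    if overlap < overlap_min:
        raise NoAnchorError(
            f"best anchor candidate (residue index {idx}) shares only "
            f"{overlap:.2f} of the prototype anchor partner set "
            f"(overlap_min={overlap_min}); the complex cannot be put into "
            "the unified numbering", ranked=ranked)
    return idx, overlap


def assign_urn(peptide_len: int, anchor_index: int,
               anchor_urn: int = DEFAULT_ANCHOR_URN) -> UrnNumbering:
    """Offset numbering around the anchor; positions below 1 are kept, not
    clipped, so long N-terminal flanks stay addressable."""
    if not 0 <= anchor_index < peptide_len:
        raise ValueError("anchor_index outside the peptide")
    positions = {i: anchor_urn + (i - anchor_index) for i in range(peptide_len)}
    return UrnNumbering(positions=positions, anchor_index=anchor_index,
                        anchor_urn=anchor_urn)


def similar_contacts(target_triples, prototype: PrototypeReference | frozenset) -> SCSet:
    """SC = intersection of (URN position, chain role, chain position)
    triples; residue identity plays no part on either side."""
    proto = prototype.triples if isinstance(prototype, PrototypeReference) else frozenset(prototype)
    return SCSet.from_triples(frozenset(target_triples) & proto)


def validate_urn(
    sc: SCSet,
    target_core_triples,
    core_range: tuple[int, int],
    skipped_positions: Sequence[int] = (),
    min_positions: int = 9,
    min_fraction: float = 0.5,
) -> ValidationResult:
    """Accept the numbering iff >= ``min_positions`` core positions carry an SC
    and >= ``min_fraction`` of all core contacts are SC.  Positions whose
    residue was skipped (modified/unmodeled) are excluded from both sides of
    the fraction; they cannot carry contacts."""
    lo, hi = core_range
    skipped = [p for p in skipped_positions if lo <= p <= hi]
    core_sc = {t for t in sc.triples if lo <= t[0] <= hi and t[0] not in skipped}
    core_all = {t for t in frozenset(target_core_triples)
                if lo <= t[0] <= hi and t[0] not in skipped}
    positions_with_sc = len({t[0] for t in core_sc})
    total = len(core_all)
    sc_count = len(core_sc & core_all) if core_all else len(core_sc)
    fraction = sc_count / total if total else 0.0
    return ValidationResult(
        positions_with_sc=positions_with_sc,
        sc_count=sc_count,
        total_contacts_in_core=total,
        sc_fraction=fraction,
        valid=positions_with_sc >= min_positions and fraction >= min_fraction,
        skipped_positions=skipped,
        core_range=core_range,
    )


@dataclass
class UrnAlignment:
    """Full result of aligning one complex against a prototype."""

    structure_id: str
    group: str
    contact_map: ContactMap
    alpha_mapping: PositionMapping
    beta_mapping: PositionMapping
    urn: UrnNumbering
    anchor_overlap: float
    triples: frozenset[Triple]          # target contacts in URN (mapped chains only)
    sc: SCSet
    validation: ValidationResult
    modeled_core_positions: frozenset[int]

    def urn_tsv(self) -> str:
        lines = ["peptide_index\tpeptide_number\turn_position"]
        pep_numbers = {rec.peptide_index: rec.peptide_number
                       for rec in self.contact_map.records}
        for idx in sorted(self.urn.positions):
            lines.append(f"{idx}\t{pep_numbers.get(idx, '')}\t{self.urn.positions[idx]}")
        return "\n".join(lines) + "\n"

    def sc_tsv(self) -> str:
        lines = ["peptide_urn\tchain_role\tchain_pos"]
        for rec in sorted(self.sc.records, key=lambda r: r.triple):
            lines.append(f"{rec.peptide_urn}\t{rec.chain_role}\t{rec.chain_pos}")
        return "\n".join(lines) + "\n"


def align_complex(
    complex_: ComplexStructure,
    prototype: PrototypeReference,
    params: ContactParams = ContactParams(),
    overlap_min: float = DEFAULT_OVERLAP_MIN,
    identity_floor: float | None = None,
) -> UrnAlignment:
    """Run the whole protocol against one target complex: contacts, chain
    numbering transfer, anchor detection, URN assignment, SC detection and
    validation."""
    from .chain_numbering import DEFAULT_IDENTITY_FLOOR

    if identity_floor is None:
        identity_floor = DEFAULT_IDENTITY_FLOOR
    cmap = residue_contacts(complex_, params)
    alpha_map = align_to_prototype(complex_.alpha.sequence, prototype.alpha_seq,
                                   prototype.alpha_positions,
                                   identity_floor=identity_floor)
    beta_map = align_to_prototype(complex_.beta.sequence, prototype.beta_seq,
                                  prototype.beta_positions,
                                  identity_floor=identity_floor)
    chain_maps = {"alpha": alpha_map, "beta": beta_map}

    partner_sets: dict[int, set[tuple[str, int]]] = {}
    for rec in cmap.records:
        pos = chain_maps[rec.chain_role].get(rec.chain_index)
        if pos is not None:
            partner_sets.setdefault(rec.peptide_index, set()).add((rec.chain_role, pos))
        else:
            partner_sets.setdefault(rec.peptide_index, set())

    anchor_index, overlap = find_anchor(partner_sets, prototype,
                                        overlap_min=overlap_min)
    urn = assign_urn(len(complex_.peptide), anchor_index, prototype.anchor_urn)

    triples: set[Triple] = set()
    all_core: set[Triple] = set()
    lo, hi = prototype.core_range
    unmapped_serial = 0
    for rec in cmap.records:
        p = urn.positions[rec.peptide_index]
        pos = chain_maps[rec.chain_role].get(rec.chain_index)
        if pos is not None:
            triples.add((p, rec.chain_role, pos))
            if lo <= p <= hi:
                all_core.add((p, rec.chain_role, pos))
        elif lo <= p <= hi:
            # contact with a chain residue outside the prototype numbering:
            # cannot be an SC but still inflates the core denominator
            unmapped_serial -= 1
            all_core.add((p, rec.chain_role, unmapped_serial))

    sc = similar_contacts(triples, prototype)
    skipped_urn = [urn.positions[i] for i, _n, _r in cmap.skipped_peptide_residues]
    validation = validate_urn(sc, all_core, prototype.core_range,
                              skipped_positions=skipped_urn)
    modeled = frozenset(
        urn.positions[i] for i, res in enumerate(complex_.peptide.residues)
        if res.usable and res.atoms and lo <= urn.positions[i] <= hi)
    return UrnAlignment(
        structure_id=complex_.structure_id,
        group=prototype.group,
        contact_map=cmap,
        alpha_mapping=alpha_map,
        beta_mapping=beta_map,
        urn=urn,
        anchor_overlap=overlap,
        triples=frozenset(triples),
        sc=sc,
        validation=validation,
        modeled_core_positions=modeled,
    )
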