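"""Cross-structure aggregation: unified contact maps, DR/DQ comparison and
per-position physicochemical statistics.

Per-structure similar-contact sets (already in the unified numbering) are
combined into a unified contact map: for each SC triple, the percentage of
non-prototype structures exhibiting it.  Because some structures miss a
peptide position (unmodeled or modified residues), two denominators are
reported per triple: all structures, and only structures where the position
is modeled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import GroupMismatchError
from .physchem import (FLEX_CLASSES, HYDROPHOBIC, NEUTRAL,
                       VOLUME_CLASS_ORDER, VOLUME_CLASSES, PositionProfile)
from .urn import SCSet, Triple


@dataclass
class UnifiedEntry:
    pct_structures: float                 # over all non-prototype structures
    n_structures: int | None              # structures exhibiting the SC
    n_modeled: int | None                 # structures with the position modeled
    ss_unit: str | None = None
    pct_modeled: float | None = None      # over structures with the position modeled


@dataclass
class UnifiedContactMap:
    group: str
    entries: dict[Triple, UnifiedEntry]

    @property
    def triples(self) -> frozenset[Triple]:
        return frozenset(self.entries)

    def triples_for(self, role: str) -> frozenset[Triple]:
        return frozenset(t for t in self.entries if t[1] == role)

    def sc_total(self, role: str | None = None) -> int:
        return len(self.triples if role is None else self.triples_for(role))

    def chain_positions(self, role: str) -> frozenset[int]:
        return frozenset(t[2] for t in self.entries if t[1] == role)

    def restrict(self, pos_min: int, pos_max: int) -> "UnifiedContactMap":
        return UnifiedContactMap(
            group=self.group,
            entries={t: e for t, e in self.entries.items()
                     if pos_min <= t[0] <= pos_max})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (p, role, pos), e in sorted(self.entries.items()):
            rows.append({"group": self.group, "peptide_pos": p,
                         "chain_role": role, "chain_pos": pos,
                         "ss_unit": e.ss_unit, "pct_structures": e.pct_structures,
                         "pct_modeled": e.pct_modeled,
                         "n_structures": e.n_structures,
                         "n_modeled": e.n_modeled})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = self.to_frame().to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def pivot(self) -> pd.DataFrame:
        """Wide layout: one row per (peptide position, chain position, role)."""
        df = self.to_frame()
        return df.pivot_table(index=["peptide_pos", "chain_role", "chain_pos"],
                              values="pct_structures").reset_index()


def unify(
    sc_sets: Sequence[SCSet | Iterable[Triple]],
    group: str,
    groups: Sequence[str] | None = None,
    modeled_positions: Sequence[Iterable[int]] | None = None,
    units: Mapping[tuple[str, int], str] | None = None,
) -> UnifiedContactMap:
    """Combine per-structure SC sets (non-prototype structures only) into a
    unified contact map.  ``modeled_positions[i]`` optionally gives the core
    URN positions modeled in structure ``i``; triples at positions a structure
    does not model are excluded from that structure's denominator in
    ``pct_modeled``.  Invariant to input order."""
    if groups is not None:
        bad = [g for g in groups if g.lower() != group.lower()]
        if bad:
            raise GroupMismatchError(
                f"sc sets from groups {sorted(set(bad))} mixed into group "
                f"{group!r}")
    triple_sets = [frozenset(s.triples if isinstance(s, SCSet) else s)
                   for s in sc_sets]
    n = len(triple_sets)
    if n == 0:
        raise ValueError("no SC sets to unify")
    counts: Counter = Counter()
    for ts in triple_sets:
        counts.update(ts)
    modeled = [frozenset(m) for m in modeled_positions] if modeled_positions else None
    entries = {}
    for triple, c in counts.items():
        if modeled is not None:
            denom = sum(1 for m in modeled if triple[0] in m)
        else:
            denom = n
        entries[triple] = UnifiedEntry(
            pct_structures=100.0 * c / n,
            n_structures=c,
            n_modeled=denom,
            ss_unit=units.get((triple[1], triple[2])) if units else None,
            pct_modeled=100.0 * c / denom if denom else None,
        )
    return UnifiedContactMap(group=group.lower(), entries=entries)


@dataclass
class SharedSCReport:
    triples: frozenset[Triple]
    n_alpha: int
    n_beta: int

    @property
    def total(self) -> int:
        return len(self.triples)

    def per_position(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for p, _role, _pos in self.triples:
            out[p] = out.get(p, 0) + 1
        return out


def shared_sc(map_a: UnifiedContactMap, map_b: UnifiedContactMap) -> SharedSCReport:
    """SC triples present in both unified maps, split by chain role.
    Symmetric and idempotent."""
    common = map_a.triples & map_b.triples
    return SharedSCReport(
        triples=common,
        n_alpha=sum(1 for t in common if t[1] == "alpha"),
        n_beta=sum(1 for t in common if t[1] == "beta"),
    )


def _adjacent_pairs() -> list[tuple[str, str]]:
    order = VOLUME_CLASS_ORDER
    return [(order[i], order[i + 1]) for i in range(len(order) - 1)]


def position_statistics(
    profiles: Sequence[Sequence[PositionProfile] | Mapping[int, str]],
    group: str,
) -> pd.DataFrame:
    """Per-URN-position distributions over a set of structures.

    For each position: counts of flexibility classes (hf/mf/wf), hydropathy
    groups, volume classes, and the most common *adjacent* volume-class pair
    (e.g. very small + small) with its coverage percentage.
    """
    if not profiles:
        raise ValueError("need at least one structure profile")
    per_pos: dict[int, list[str]] = {}
    for prof in profiles:
        if isinstance(prof, Mapping):
            items = prof.items()
        else:
            items = ((p.urn_position, p.residue) for p in prof)
        for urn, aa in items:
            per_pos.setdefault(urn, []).append(aa.upper())
    rows = []
    for urn in sorted(per_pos):
        residues = [aa for aa in per_pos[urn] if aa in VOLUME_CLASSES]
        n = len(residues)
        flex = Counter(FLEX_CLASSES[aa] for aa in residues)
        vol = Counter(VOLUME_CLASSES[aa] for aa in residues)
        hyd = Counter(
            "hydrophobic" if aa in HYDROPHOBIC
            else "neutral" if aa in NEUTRAL else "hydrophilic"
            for aa in residues)
        best_pair, best_count = None, -1
        for a, b in _adjacent_pairs():
            c = vol.get(a, 0) + vol.get(b, 0)
            if c > best_count:
                best_pair, best_count = f"{a}+{b}", c
        rows.append({
            "group": group.lower(), "urn_position": urn, "n_structures": n,
            **{f"flex_{k}": flex.get(k, 0) for k in ("hf", "mf", "wf")},
            **{f"vol_{k.replace(' ', '_')}": vol.get(k, 0)
               for k in VOLUME_CLASS_ORDER},
            "hydrophobic": hyd.get("hydrophobic", 0),
            "hydrophilic": hyd.get("hydrophilic", 0),
            "neutral": hyd.get("neutral", 0),
            "top_adjacent_volume_pair": best_pair,
            "top_adjacent_volume_count": best_count,
            "top_adjacent_volume_pct": 100.0 * best_count / n if n else None,
        })
    return pd.DataFrame(rows)
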