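"""Position-wise physicochemical criteria for groove-bound peptides.

Four independent per-residue classifications are used to characterise what a
URN position tolerates:

* a three-way hydropathy grouping (hydrophobic +1 / hydrophilic -1 / Gly 0)
  whose signed sum over the core is the *hydrophobicity count*;
* named hydropathy scales (Kyte-Doolittle built in) summed over the core;
* Zamyatnin residue volumes binned into five classes -- very small
  (60-90 A^3), small (108-117), medium (138-154), large (162-174) and very
  large (189-228); every standard residue falls inside one printed interval;
* a conformational-flexibility proxy: highly (hf), moderately (mf) and weakly
  (wf) fluctuating residue sets;
* contact preference scores (CPS, 0-100 per unordered residue pair) classed
  strong (80-100) / intermediate (40-79) / weak (0-39).

The CPS reference table is external; :meth:`CpsTable.uniform` provides a
synthetic constant-score placeholder for value-independent tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TableError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------- hydropathy

#: Tyr counts as hydrophobic (large nonpolar face); Gly is neutral.
HYDROPHOBIC = frozenset("AVLIMFWYCP")
NEUTRAL = frozenset("G")
HYDROPHILIC = frozenset(STANDARD_AA) - HYDROPHOBIC - NEUTRAL

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

SCALES: dict[str, dict[str, float]] = {"kyte-doolittle": KYTE_DOOLITTLE}

# -------------------------------------------------------------------- volume

#: Zamyatnin residue volumes, A^3
VOLUMES = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

VOLUME_CLASS_INTERVALS = (
    ("very small", 60.0, 90.0),
    ("small", 108.0, 117.0),
    ("medium", 138.0, 154.0),
    ("large", 162.0, 174.0),
    ("very large", 189.0, 228.0),
)
VOLUME_CLASS_ORDER = tuple(name for name, _lo, _hi in VOLUME_CLASS_INTERVALS)


def _volume_class(volume: float) -> str:
    best, best_d = None, None
    for name, lo, hi in VOLUME_CLASS_INTERVALS:
        if lo <= volume <= hi:
            return name
        d = min(abs(volume - lo), abs(volume - hi))
        if best_d is None or d < best_d:
            best, best_d = name, d
    return best  # nearest interval; unreachable for the 20 standard residues


#: class membership fixed at table construction
VOLUME_CLASSES = {aa: _volume_class(v) for aa, v in VOLUMES.items()}

# --------------------------------------------------------------- flexibility

HF = frozenset("PSAGD")       # highly fluctuating
MF = frozenset("TNQKERVC")    # moderately fluctuating
WF = frozenset("ILMFYWH")     # weakly fluctuating
FLEX_CLASSES = {**{a: "hf" for a in HF}, **{a: "mf" for a in MF},
                **{a: "wf" for a in WF}}


def check_tables() -> None:
    """Sanity checks run at import: every classification is a total,
    single-valued function on the 20 standard residues."""
    aa = set(STANDARD_AA)
    assert HYDROPHOBIC | NEUTRAL | HYDROPHILIC == aa
    assert not (HYDROPHOBIC & HYDROPHILIC)
    assert HF | MF | WF == aa and not (HF & MF) and not (MF & WF) and not (HF & WF)
    assert set(VOLUMES) == aa and set(KYTE_DOOLITTLE) == aa
    for a, v in VOLUMES.items():
        name = VOLUME_CLASSES[a]
        lo, hi = next((lo, hi) for n, lo, hi in VOLUME_CLASS_INTERVALS if n == name)
        assert lo <= v <= hi, f"{a}: {v} outside {name} interval"


check_tables()


# ---------------------------------------------------------------- operations

def hydrophobicity_count(residues: Iterable[str],
                         hydrophobic: frozenset = HYDROPHOBIC,
                         neutral: frozenset = NEUTRAL) -> int:
    """Signed sum over residues: +1 hydrophobic, -1 hydrophilic, 0 neutral.
    Unknown residues ('X') contribute 0."""
    total = 0
    for aa in residues:
        aa = aa.upper()
        if aa not in STANDARD_AA:
            continue
        if aa in hydrophobic:
            total += 1
        elif aa not in neutral:
            total -= 1
    return total


def hydropathy_sum(residues: Iterable[str], scale: str | Mapping[str, float]
                   = "kyte-doolittle") -> float:
    """Plain sum of per-residue scale values over the residues."""
    if isinstance(scale, str):
        try:
            scale = SCALES[scale.lower()]
        except KeyError:
            raise KeyError(f"unknown hydropathy scale {scale!r}; "
                           f"known: {sorted(SCALES)}") from None
    total = 0.0
    for aa in residues:
        aa = aa.upper()
        if aa in scale:
            total += scale[aa]
        elif aa != "X":
            raise KeyError(f"scale does not cover residue {aa!r}")
    return total


def register_scale(name: str, values: Mapping[str, float]) -> None:
    if set(values) < set(STANDARD_AA):
        raise TableError(f"scale {name!r} does not cover the 20 standard residues")
    SCALES[name.lower()] = dict(values)


def load_scale(path: str | Path, name: str | None = None) -> dict[str, float]:
    """Load a hydropathy scale from a two-column TSV (residue, value)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["aa", "value"])
    values = {str(r.aa).upper(): float(r.value) for r in df.itertuples()}
    if name:
        register_scale(name, values)
    return values


@dataclass
class VolumeProfile:
    per_residue: list[tuple[str, float, str]]   # (aa, volume, class)
    class_counts: dict[str, int]
    total: float
    excluded: list[str] = field(default_factory=list)


def volume_profile(residues: Iterable[str]) -> VolumeProfile:
    """Per-residue volumes, class counts and the summed core volume."""
    per_residue, excluded = [], []
    counts = {name: 0 for name in VOLUME_CLASS_ORDER}
    total = 0.0
    for aa in residues:
        aa = aa.upper()
        if aa not in VOLUMES:
            excluded.append(aa)
            continue
        vol, cls = VOLUMES[aa], VOLUME_CLASSES[aa]
        per_residue.append((aa, vol, cls))
        counts[cls] += 1
        total += vol
    return VolumeProfile(per_residue=per_residue, class_counts=counts,
                         total=round(total, 1), excluded=excluded)


@dataclass
class FlexibilityProfile:
    per_residue: list[tuple[str, str]]          # (aa, class)
    counts: dict[str, int]
    excluded: list[str] = field(default_factory=list)


def flexibility_profile(residues: Iterable[str]) -> FlexibilityProfile:
    per_residue, excluded = [], []
    counts = {"hf": 0, "mf": 0, "wf": 0}
    for aa in residues:
        aa = aa.upper()
        cls = FLEX_CLASSES.get(aa)
        if cls is None:
            excluded.append(aa)
            continue
        per_residue.append((aa, cls))
        counts[cls] += 1
    return FlexibilityProfile(per_residue=per_residue, counts=counts,
                              excluded=excluded)


# ----------------------------------------------------------------------- CPS

def cps_class(score: float) -> str:
    """Strong 80-100, intermediate 40-79, weak 0-39."""
    if not 0 <= score <= 100:
        raise ValueError(f"CPS {score} outside [0, 100]")
    if score >= 80:
        return "strong"
    if score >= 40:
        return "intermediate"
    return "weak"


class CpsTable:
    """Contact preference scores for all 210 unordered standard-residue pairs."""

    def __init__(self, scores: Mapping[tuple[str, str], float]):
        self._scores: dict[frozenset, float] = {}
        for (a, b), s in scores.items():
            self._scores[frozenset((a.upper(), b.upper()))] = float(s)
        expected = {frozenset((a, b)) for i, a in enumerate(STANDARD_AA)
                    for b in STANDARD_AA[i:]}
        missing = expected - set(self._scores)
        if missing:
            raise TableError(
                f"CPS table incomplete: {len(missing)} of 210 pairs missing")

    @classmethod
    def uniform(cls, score: float = 50.0) -> "CpsTable":
        """Synthetic constant-score table for value-independent tests."""
        return cls({(a, b): score for i, a in enumerate(STANDARD_AA)
                    for b in STANDARD_AA[i:]})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CpsTable":
        """Three-column TSV: residue_a, residue_b, score (0-100)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = list(df.columns[:3])
        return cls({(str(r[cols[0]]), str(r[cols[1]])): float(r[cols[2]])
                    for _, r in df.iterrows()})

    def score(self, a: str, b: str) -> float:
        key = frozenset((a.upper(), b.upper()))
        try:
            return self._scores[key]
        except KeyError:
            raise TableError(f"no CPS entry for pair {a}-{b}") from None

    def classify(self, a: str, b: str) -> tuple[float, str]:
        s = self.score(a, b)
        return s, cps_class(s)


def average_cps(pairs: Sequence[tuple[str, str]], table: CpsTable) -> float:
    """Mean CPS over a group of contact residue pairs."""
    if not pairs:
        raise ValueError("no contact pairs to average")
    return fmean(table.score(a, b) for a, b in pairs)


def cps_class_counts(pairs: Sequence[tuple[str, str]],
                     table: CpsTable) -> dict[str, int]:
    counts = {"strong": 0, "intermediate": 0, "weak": 0}
    for a, b in pairs:
        counts[cps_class(table.score(a, b))] += 1
    return counts


# ------------------------------------------------------------------ profiles

@dataclass
class PositionProfile:
    """Physicochemical portrait of one peptide residue at a URN position."""

    urn_position: int
    residue: str
    hydropathy_group: str            # hydrophobic | hydrophilic | neutral | unknown
    volume: float | None
    volume_class: str | None
    flexibility: str | None
    cps_scores: list[float] = field(default_factory=list)

    @property
    def mean_cps(self) -> float | None:
        return fmean(self.cps_scores) if self.cps_scores else None


def position_profiles(
    urn_to_residue: Mapping[int, str],
    cps_partners: Mapping[int, Sequence[str]] | None = None,
    cps_table: CpsTable | None = None,
) -> list[PositionProfile]:
    """Build per-position profiles from a URN->residue map; optionally attach
    CPS scores for the chain residues each position contacts."""
    profiles = []
    for urn in sorted(urn_to_residue):
        aa = urn_to_residue[urn].upper()
        if aa in HYDROPHOBIC:
            group = "hydrophobic"
        elif aa in NEUTRAL:
            group = "neutral"
        elif aa in HYDROPHILIC:
            group = "hydrophilic"
        else:
            group = "unknown"
        scores = []
        if cps_partners and cps_table and aa in STANDARD_AA:
            scores = [cps_table.score(aa, partner)
                      for partner in cps_partners.get(urn, ())]
        profiles.append(PositionProfile(
            urn_position=urn,
            residue=aa,
            hydropathy_group=group,
            volume=VOLUMES.get(aa),
            volume_class=VOLUME_CLASSES.get(aa),
            flexibility=FLEX_CLASSES.get(aa),
            cps_scores=scores,
        ))
    return profiles


def profile_tsv(profiles: Sequence[PositionProfile]) -> str:
    lines = ["urn_position\tresidue\thydropathy_group\tvolume_A3\tvolume_class\t"
             "flexibility\tmean_cps"]
    for p in profiles:
        mean = f"{p.mean_cps:.1f}" if p.mean_cps is not None else ""
        lines.append(f"{p.urn_position}\t{p.residue}\t{p.hydropathy_group}\t"
                     f"{p.volume if p.volume is not None else ''}\t"
                     f"{p.volume_class or ''}\t{p.flexibility or ''}\t{mean}")
    return "\n".join(lines) + "\n"
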