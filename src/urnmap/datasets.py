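"""Loaders for the data files packaged with urnmap.

Bundled content:

* ``unified_contacts.tsv`` -- the unified DR/DQ contact maps: every similar
  contact (SC) triple (peptide URN position, chain role, chain position), the
  secondary-structure unit of the chain position, and the percentage of
  non-prototype structures in which the SC occurs.
* ``clip_peptides.tsv`` -- the CLIP invariant-chain fragments bound in the DR
  (18-mer, core 3-14) and DQ (15-mer, core 4-14) prototype grooves.
* ``prototype_chains_synthetic.fasta`` -- synthetic stand-in sequences for the
  groove alpha/beta chains, used for role discrimination and chain numbering
  in download-free tests.  They are NOT real HLA-II sequences; real prototype
  chains can be supplied through the corresponding function arguments.

User-supplied peptide tables (one row per structure, one column per URN
position) are loaded with :func:`load_peptide_table`; no real DR/DQ peptide
table ships with the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

_DATA = resources.files(__name__.split(".")[0]) / "data"


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def unified_contact_table(group: str | None = None) -> pd.DataFrame:
    """The bundled unified contact map as a long-format DataFrame."""
    df = _read_tsv("unified_contacts.tsv")
    if group is not None:
        df = df[df["group"] == group.lower()].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown group {group!r}; expected 'dr' or 'dq'")
    return df


def unified_map(group: str):
    """The bundled unified contact map as an :class:`~urnmap.aggregate.UnifiedContactMap`."""
    from .aggregate import UnifiedContactMap, UnifiedEntry

    df = unified_contact_table(group)
    entries = {}
    for row in df.itertuples(index=False):
        triple = (int(row.peptide_pos), row.chain_role, int(row.chain_pos))
        entries[triple] = UnifiedEntry(
            pct_structures=float(row.pct_structures),
            n_structures=None,
            n_modeled=None,
            ss_unit=row.ss_unit,
        )
    return UnifiedContactMap(group=group.lower(), entries=entries)


def ss_unit(group: str, role: str, position: int) -> str | None:
    """Secondary-structure unit of a chain position, if it carries an SC."""
    df = unified_contact_table(group)
    hit = df[(df["chain_role"] == role) & (df["chain_pos"] == position)]
    if hit.empty:
        return None
    return str(hit["ss_unit"].iloc[0])


def clip_peptide(group: str) -> dict:
    """CLIP fragment for a group: sequence and core URN range."""
    df = _read_tsv("clip_peptides.tsv")
    row = df[df["group"] == group.lower()]
    if row.empty:
        raise KeyError(f"unknown group {group!r}")
    r = row.iloc[0]
    return {"sequence": str(r["sequence"]),
            "core": (int(r["core_start"]), int(r["core_end"]))}


def core_range(group: str) -> tuple[int, int]:
    return clip_peptide(group)["core"]


def synthetic_prototype_chains() -> dict[str, str]:
    """Synthetic stand-in alpha/beta groove-chain sequences (not real HLA)."""
    with resources.as_file(_DATA / "prototype_chains_synthetic.fasta") as p:
        text = Path(p).read_text()
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith(">"):
            name = line[1:].split("_")[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line
    return seqs


def load_peptide_table(path: str | Path) -> pd.DataFrame:
    """Load a peptide table (one structure per row, URN positions as columns).

    Expected TSV schema: a ``structure_id`` column followed by columns ``p1``,
    ``p2``, ... holding one-letter residue codes; ``-`` marks a position absent
    from the peptide, a trailing ``*`` marks a modified or unmodeled residue
    (excluded from contact analysis but kept in the sequence).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "structure_id" not in df.columns:
        raise ValueError(f"{path}: missing 'structure_id' column")
    pos_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    if not pos_cols:
        raise ValueError(f"{path}: no URN position columns (p1, p2, ...)")
    return df.set_index("structure_id")[pos_cols]


def dr_peptide_table() -> pd.DataFrame:
    """The DR peptide table (48 structures, URN positions 1-18).

    The package does not bundle this table; place a TSV conforming to
    :func:`load_peptide_table` at ``<package>/data/dr_peptides.tsv`` or load
    your own copy explicitly.
    """
    with resources.as_file(_DATA / "dr_peptides.tsv") as p:
        if not Path(p).exists():
            raise FileNotFoundError(
                "dr_peptides.tsv is not bundled; supply a peptide table via "
                "urnmap.datasets.load_peptide_table(path)")
        return load_peptide_table(p)


def dq_peptide_table() -> pd.DataFrame:
    """The DQ peptide table (33 structures); see :func:`dr_peptide_table`."""
    with resources.as_file(_DATA / "dq_peptides.tsv") as p:
        if not Path(p).exists():
            raise FileNotFoundError(
                "dq_peptides.tsv is not bundled; supply a peptide table via "
                "urnmap.datasets.load_peptide_table(path)")
        return load_peptide_table(p)
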