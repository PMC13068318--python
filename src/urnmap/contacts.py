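"""Residue-residue contacts between the peptide and the groove chains.

A contact is a peptide/chain residue pair with positive contact surface area
(CSA).  The CSA is computed from Shrake-Rupley point surfaces: each heavy atom
of a residue carries a deterministic Fibonacci-sphere point set at radius
``r_vdw + probe``; points occluded by sibling atoms of the same residue are
discarded; each surviving point is attributed to the nearest atom outside the
residue, and contributes its share of sphere area to the pair if that atom
lies within ``r_partner + 2*probe`` of the point.  The two one-sided areas
(peptide->chain and chain->peptide) are averaged.  This reproduces the
"directly overlapping or in close proximity" contact-surface semantics of
CSU-style interface analysis with a documented, testable construction.

Putative hydrogen bonds are flagged purely geometrically (no hydrogens in the
inputs): any N/O/S heavy-atom pair across the interface within a distance
window, 2.5-3.5 A by default.

Only peptide<->alpha and peptide<->beta contacts are computed; peptide-internal
and alpha<->beta contacts are outside the method's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyContactMapError
from .structure_io import Atom, ComplexStructure, Residue

#: van der Waals radii (A) for the heavy elements found in polymer residues
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
_DEFAULT_RADIUS = 1.80

HBOND_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class ContactParams:
    probe: float = 1.4               # solvent probe radius, A
    points_per_atom: int = 256       # Shrake-Rupley point density
    csa_min: float = 0.0             # accept pairs with csa strictly above this
    prefilter: float | None = 6.5    # heavy-atom distance prefilter, A; None = all pairs
    hbond_min: float = 2.5
    hbond_max: float = 3.5

    @property
    def attribution_reach(self) -> float:
        """Largest point-to-partner-centre distance that can ever contribute."""
        return max(VDW_RADII.values()) + 2.0 * self.probe


@dataclass(frozen=True)
class ContactRecord:
    peptide_index: int        # index of the residue within the peptide chain
    peptide_number: str       # author numbering
    peptide_code: str         # one-letter
    chain_role: str           # "alpha" | "beta"
    chain_index: int          # index within the chain
    chain_number: str
    chain_code: str
    min_distance: float       # nearest heavy-atom centre distance, A
    csa: float                # contact surface area, A^2 (mean of both sides)
    csa_forward: float        # peptide-surface side
    csa_reverse: float        # chain-surface side
    hbond: bool


@dataclass
class ContactMap:
    structure_id: str
    records: list[ContactRecord]
    skipped_peptide_residues: list[tuple[int, str, str]] = field(default_factory=list)
    # (index, author number, reason in {"modified", "unmodeled"})

    def per_position(self) -> dict[int, list[ContactRecord]]:
        index: dict[int, list[ContactRecord]] = {}
        for rec in self.records:
            index.setdefault(rec.peptide_index, []).append(rec)
        return index

    def partner_sets(self) -> dict[int, set[tuple[str, int]]]:
        """Peptide residue index -> set of (chain role, chain residue index)."""
        out: dict[int, set[tuple[str, int]]] = {}
        for rec in self.records:
            out.setdefault(rec.peptide_index, set()).add(
                (rec.chain_role, rec.chain_index))
        return out

    def counts(self, role: str | None = None) -> dict[int, int]:
        out: dict[int, int] = {}
        for rec in self.records:
            if role is None or rec.chain_role == role:
                out[rec.peptide_index] = out.get(rec.peptide_index, 0) + 1
        return out

    def to_tsv(self, path: str | Path | None = None) -> str:
        header = ("structure_id\tpeptide_pos\tpep_res\tchain_role\tchain_pos\t"
                  "chain_res\tmin_dist_A\tcsa_A2\thbond\n")
        body = "".join(
            f"{self.structure_id}\t{r.peptide_number}\t{r.peptide_code}\t"
            f"{r.chain_role}\t{r.chain_number}\t{r.chain_code}\t"
            f"{r.min_distance:.3f}\t{r.csa:.3f}\t{int(r.hbond)}\n"
            for r in self.records)
        text = header + body
        if path is not None:
            Path(path).write_text(text)
        return text


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def detect_hbond(donor_candidate: Sequence[Atom], acceptor_candidate: Sequence[Atom],
                 params: ContactParams = ContactParams()) -> bool:
    """True iff some N/O/S heavy-atom pair across the two residues falls in
    the donor-acceptor distance window.  Symmetric in its arguments."""
    a = np.array([at.xyz for at in donor_candidate
                  if at.element.upper() in HBOND_ELEMENTS], dtype=float)
    b = np.array([at.xyz for at in acceptor_candidate
                  if at.element.upper() in HBOND_ELEMENTS], dtype=float)
    if a.size == 0 or b.size == 0:
        return False
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return bool(np.any((d >= params.hbond_min) & (d <= params.hbond_max)))


class _AtomArrays:
    """Flat atom arrays over the three chains with residue bookkeeping."""

    def __init__(self, complex_: ComplexStructure, params: ContactParams):
        coords, radii, res_ids, roles, chain_idx = [], [], [], [], []
        self.residues: list[tuple[str, int, Residue]] = []  # (role, index-in-chain, residue)
        rid = 0
        for chain in complex_.chains:
            for i, res in enumerate(chain.residues):
                if not res.atoms:
                    continue
                self.residues.append((chain.role, i, res))
                for atom in res.atoms:
                    coords.append(atom.xyz)
                    radii.append(vdw_radius(atom.element))
                    res_ids.append(rid)
                    roles.append(chain.role)
                    chain_idx.append(i)
                rid += 1
        self.coords = np.asarray(coords, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.tree = cKDTree(self.coords) if len(coords) else None
        self.params = params

    def residue_atoms(self, rid: int) -> tuple[np.ndarray, np.ndarray]:
        mask = self.res_ids == rid
        return self.coords[mask], self.radii[mask]


def _one_sided_areas(arrays: _AtomArrays, rid: int,
                     params: ContactParams) -> dict[int, float]:
    """Surface area of residue ``rid`` attributed to each other residue id."""
    coords, radii = arrays.residue_atoms(rid)
    n = params.points_per_atom
    dirs = fibonacci_sphere(n)
    reach = arrays.radii.max() + 2.0 * params.probe
    areas: dict[int, float] = {}
    for ci in range(len(coords)):
        center, r = coords[ci], radii[ci]
        pts = center + (r + params.probe) * dirs
        # occlusion by sibling atoms of the same residue
        if len(coords) > 1:
            others = np.delete(np.arange(len(coords)), ci)
            d = np.linalg.norm(pts[:, None, :] - coords[others][None, :, :], axis=-1)
            occluded = np.any(d < (radii[others] + params.probe)[None, :] - 1e-9, axis=1)
            pts = pts[~occluded]
        if len(pts) == 0:
            continue
        w = 4.0 * np.pi * (r + params.probe) ** 2 / n
        # nearest atom outside this residue, within attribution reach
        neighbor_lists = arrays.tree.query_ball_point(pts, reach + 1e-9)
        for p, neigh in enumerate(neighbor_lists):
            neigh = [j for j in neigh if arrays.res_ids[j] != rid]
            if not neigh:
                continue
            dists = np.linalg.norm(arrays.coords[neigh] - pts[p], axis=1)
            k = int(np.argmin(dists))
            j = neigh[k]
            if dists[k] <= arrays.radii[j] + 2.0 * params.probe:
                other = int(arrays.res_ids[j])
                areas[other] = areas.get(other, 0.0) + w
    return areas


def _candidate_pairs(arrays: _AtomArrays, pep_rids: list[int],
                     chain_rids: list[int], params: ContactParams
                     ) -> dict[tuple[int, int], float]:
    """(pep rid, chain rid) -> min heavy-atom distance, within the prefilter."""
    cutoff = params.prefilter
    if cutoff is None:
        # all-pairs brute force
        out = {}
        for pr in pep_rids:
            pc, _ = arrays.residue_atoms(pr)
            for cr in chain_rids:
                cc, _ = arrays.residue_atoms(cr)
                d = np.linalg.norm(pc[:, None, :] - cc[None, :, :], axis=-1).min()
                out[(pr, cr)] = float(d)
        return out
    pep_mask = np.isin(arrays.res_ids, pep_rids)
    chain_mask = np.isin(arrays.res_ids, chain_rids)
    pep_tree = cKDTree(arrays.coords[pep_mask])
    chain_tree = cKDTree(arrays.coords[chain_mask])
    pep_ids = arrays.res_ids[pep_mask]
    chain_ids = arrays.res_ids[chain_mask]
    out: dict[tuple[int, int], float] = {}
    pairs = pep_tree.query_ball_tree(chain_tree, cutoff)
    pep_coords = arrays.coords[pep_mask]
    chain_coords = arrays.coords[chain_mask]
    for ip, neigh in enumerate(pairs):
        for ic in neigh:
            key = (int(pep_ids[ip]), int(chain_ids[ic]))
            d = float(np.linalg.norm(pep_coords[ip] - chain_coords[ic]))
            if key not in out or d < out[key]:
                out[key] = d
    return out


def residue_contacts(complex_: ComplexStructure,
                     params: ContactParams = ContactParams()) -> ContactMap:
    """All peptide<->alpha and peptide<->beta residue contacts with csa > csa_min.

    Modified or unmodeled peptide residues yield no records but are listed in
    the skipped-residue report.  Deterministic for fixed parameters.
    """
    peptide = complex_.peptide
    skipped = []
    for i, res in enumerate(peptide.residues):
        if res.unmodeled:
            skipped.append((i, res.original_number, "unmodeled"))
        elif res.modified:
            skipped.append((i, res.original_number, "modified"))
    if not any(r.usable and r.atoms for r in peptide.residues):
        raise EmptyContactMapError(
            f"{complex_.structure_id}: peptide has no modeled standard residue")

    arrays = _AtomArrays(complex_, params)
    rid_of: dict[tuple[str, int], int] = {}
    for rid, (role, idx, _res) in enumerate(arrays.residues):
        rid_of[(role, idx)] = rid

    pep_rids = [rid_of[("peptide", i)] for i, res in enumerate(peptide.residues)
                if res.usable and res.atoms]
    chain_rids = [rid for rid, (role, _i, _r) in enumerate(arrays.residues)
                  if role in ("alpha", "beta")]
    candidates = _candidate_pairs(arrays, pep_rids, chain_rids, params)

    forward: dict[int, dict[int, float]] = {
        pr: _one_sided_areas(arrays, pr, params) for pr in pep_rids}
    involved_chain = sorted({cr for (_pr, cr) in candidates})
    reverse: dict[int, dict[int, float]] = {
        cr: _one_sided_areas(arrays, cr, params) for cr in involved_chain}

    records = []
    for (pr, cr), min_d in sorted(candidates.items()):
        f = forward.get(pr, {}).get(cr, 0.0)
        r = reverse.get(cr, {}).get(pr, 0.0)
        csa = 0.5 * (f + r)
        if csa <= params.csa_min or csa <= 0.0:
            continue
        prole, pidx, pres = arrays.residues[pr]
        crole, cidx, cres = arrays.residues[cr]
        records.append(ContactRecord(
            peptide_index=pidx,
            peptide_number=pres.original_number,
            peptide_code=pres.one_letter_code,
            chain_role=crole,
            chain_index=cidx,
            chain_number=cres.original_number,
            chain_code=cres.one_letter_code,
            min_distance=min_d,
            csa=csa,
            csa_forward=f,
            csa_reverse=r,
            hbond=detect_hbond(pres.atoms, cres.atoms, params),
        ))
    records.sort(key=lambda rec: (rec.peptide_index, rec.chain_role, rec.chain_index))
    return ContactMap(structure_id=complex_.structure_id, records=records,
                      skipped_peptide_residues=skipped)


def calibrate_csa_min(
    contact_map: ContactMap,
    reference_counts: dict[int, tuple[int, int]],
    candidates: Iterable[float] = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0),
) -> dict:
    """Sweep the csa acceptance threshold against reference per-position counts.

    ``reference_counts`` maps a peptide residue index to its expected
    (alpha, beta) contact counts (e.g. a prototype contact table).  Returns the
    threshold minimizing the total absolute count error (ties -> smallest
    threshold) together with the per-candidate error profile.
    """
    profile = []
    for thr in sorted(set(candidates)):
        alpha_counts: dict[int, int] = {}
        beta_counts: dict[int, int] = {}
        for rec in contact_map.records:
            if rec.csa > thr:
                d = alpha_counts if rec.chain_role == "alpha" else beta_counts
                d[rec.peptide_index] = d.get(rec.peptide_index, 0) + 1
        err = 0
        for pos, (na, nb) in reference_counts.items():
            err += abs(alpha_counts.get(pos, 0) - na)
            err += abs(beta_counts.get(pos, 0) - nb)
        profile.append({"csa_min": thr, "total_abs_error": err})
    best = min(profile, key=lambda e: (e["total_abs_error"], e["csa_min"]))
    return {"chosen_csa_min": best["csa_min"],
            "total_abs_error": best["total_abs_error"],
            "profile": profile}
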