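import dataclasses

import numpy as np
import pytest

from urnmap.contacts import (ContactParams, calibrate_csa_min, detect_hbond,
                             fibonacci_sphere, residue_contacts)
from urnmap.errors import EmptyContactMapError
from urnmap.fixtures import FixtureSpec, generate_toy_complex
from urnmap.structure_io import Atom, Chain, ComplexStructure, Residue

from .oracles import pair_csa_bruteforce


def mono_residue(number, name, atoms):
    return Residue(str(number), name, "A",
                   [Atom(e, f"A{i}", tuple(x)) for i, (e, x) in enumerate(atoms)])


def small_complex(pep_atoms, alpha_atoms, beta_atoms=None):
    """One residue per chain, atoms given as (element, xyz) lists."""
    beta_atoms = beta_atoms or [("C", (50.0, -50.0, 0.0))]
    chains = [
        Chain("alpha", [mono_residue(1, "ALA", alpha_atoms)], "A"),
        Chain("beta", [mono_residue(1, "ALA", beta_atoms)], "B"),
        Chain("peptide", [mono_residue(i + 1, "ALA", [a])
                          for i, a in enumerate(pep_atoms)], "C"),
    ]
    # pad the peptide to >=1 usable residue is enough here
    return ComplexStructure("small", chains, "pdb")


def test_far_apart_residues_make_no_contact():
    cx = small_complex([("C", (0.0, 0.0, 0.0))], [("C", (10.0, 0.0, 0.0))])
    cmap = residue_contacts(cx)
    assert cmap.records == []


def test_csa_matches_dense_grid_oracle():
    """Planted van-der-Waals overlaps agree with a 10x-density brute-force
    sphere-point oracle within 5% relative tolerance."""
    cases = [
        # single-atom overlap
        ([("C", (0.0, 0.0, 0.0))], [("C", (3.2, 0.5, 0.0))]),
        # close proximity without hard overlap
        ([("C", (0.0, 0.0, 0.0))], [("O", (4.3, 0.0, 0.5))]),
        # multi-atom residues
        ([("C", (0.0, 0.0, 0.0)), ("N", (1.4, 0.2, 0.0))],
         [("C", (3.5, 1.0, 0.0)), ("O", (4.2, -0.8, 0.4))]),
    ]
    for pep_atoms, alpha_atoms in cases:
        cx = small_complex([pep_atoms[0]], alpha_atoms)
        cx.chains[2] = Chain("peptide", [mono_residue(1, "ALA", pep_atoms)], "C")
        cmap = residue_contacts(cx, ContactParams(prefilter=None))
        rec = [r for r in cmap.records if r.chain_role == "alpha"]
        assert len(rec) == 1
        pep = [(e, x) for e, x in pep_atoms]
        alp = [(e, x) for e, x in alpha_atoms]
        beta = [("C", (50.0, -50.0, 0.0))]
        oracle = pair_csa_bruteforce(pep, alp, context={"beta": beta})
        assert oracle > 0
        assert rec[0].csa == pytest.approx(oracle, rel=0.05)


def test_spatial_index_equals_all_pairs_bruteforce():
    spec = FixtureSpec(peptide_seq="AVLIMFWYCPKR", anchor_index=5,
                       triples=((5, "alpha", 3), (5, "beta", 7),
                                (2, "alpha", 11), (8, "beta", 40)),
                       seed=11)
    cx = generate_toy_complex(spec).complex
    fast = residue_contacts(cx, ContactParams())
    slow = residue_contacts(cx, ContactParams(prefilter=None))

    def key(m):
        return {(r.peptide_index, r.chain_role, r.chain_index) for r in m.records}

    assert key(fast) == key(slow)
    for a, b in zip(fast.records, slow.records):
        assert a.csa == pytest.approx(b.csa, abs=1e-9)


def test_csa_is_symmetric_between_the_two_sides():
    cx = small_complex([("C", (0.0, 0.0, 0.0))], [("C", (3.4, 0.0, 0.0))])
    rec = residue_contacts(cx).records[0]
    assert rec.csa_forward == pytest.approx(rec.csa_reverse, rel=0.05)
    assert rec.csa == pytest.approx(
        0.5 * (rec.csa_forward + rec.csa_reverse), abs=1e-12)


def test_translation_away_never_increases_csa():
    """Rigidly lifting the peptide out of the groove shrinks every contact
    area monotonically; beyond reach all records vanish."""

    def build(dz):
        pep = [Residue(str(i + 1), "ALA", "A",
                       [Atom("C", "CA", (10.0 * i, 0.0, dz))])
               for i in range(9)]
        # partners strictly below the lowest peptide surface point so every
        # sphere point moves away under +z translation
        partners = {2: 10, 4: 30, 6: 60}
        alpha_res = []
        for j in range(1, 95):
            atoms = [Atom("C", "CA", (3.8 * j, 18.0, 0.0))]
            for i, jj in partners.items():
                if jj == j:
                    atoms.append(Atom("C", "C1", (10.0 * i + 0.3, 0.4, -4.28)))
            alpha_res.append(Residue(str(j), "ALA", "A", atoms))
        beta_res = [Residue(str(j), "ALA", "A",
                            [Atom("C", "CA", (3.8 * j, -18.0, 0.0))])
                    for j in range(1, 95)]
        chains = [Chain("alpha", alpha_res, "A"), Chain("beta", beta_res, "B"),
                  Chain("peptide", pep, "C")]
        return ComplexStructure("slide", chains, "pdb")

    prev = None
    for dz in [0.0, 0.8, 1.6, 2.4, 3.2, 4.5]:
        cmap = residue_contacts(build(dz), ContactParams(prefilter=None))
        areas = {(r.peptide_index, r.chain_index): r.csa for r in cmap.records}
        if prev is not None:
            for pair, a in areas.items():
                assert a <= prev.get(pair, 0.0) + 1e-9
        prev = areas
    far = residue_contacts(build(20.0), ContactParams(prefilter=None))
    assert far.records == []


def test_hbond_distance_window():
    params = ContactParams()
    n_at = [Atom("N", "N", (0.0, 0.0, 0.0))]
    o_29 = [Atom("O", "O", (2.9, 0.0, 0.0))]
    o_50 = [Atom("O", "O", (5.0, 0.0, 0.0))]
    carbons = [Atom("C", "CB", (3.0, 0.0, 0.0))]
    assert detect_hbond(n_at, o_29, params)
    assert detect_hbond(o_29, n_at, params)       # symmetric
    assert not detect_hbond(n_at, o_50, params)
    assert not detect_hbond(n_at, carbons, params)
    assert not detect_hbond([Atom("C", "CG", (0.0, 0.0, 0.0))], carbons, params)


def test_modified_peptide_residue_is_skipped_but_reported():
    cx = small_complex([("C", (0.0, 0.0, 0.0))], [("C", (3.4, 0.0, 0.0))])
    pep = cx.chains[2].residues
    pep.append(Residue("2", "SEP", "X",
                       [Atom("C", "CA", (10.0, 0.0, 0.0))], modified=True))
    cmap = residue_contacts(cx)
    assert (1, "2", "modified") in cmap.skipped_peptide_residues
    assert all(r.peptide_index == 0 for r in cmap.records)


def test_empty_peptide_raises():
    cx = small_complex([("C", (0.0, 0.0, 0.0))], [("C", (3.4, 0.0, 0.0))])
    cx.chains[2].residues[0].modified = True
    with pytest.raises(EmptyContactMapError):
        residue_contacts(cx)


def test_fibonacci_sphere_is_deterministic_and_unit():
    a = fibonacci_sphere(256)
    b = fibonacci_sphere(256)
    assert np.array_equal(a, b)
    assert np.allclose(np.linalg.norm(a, axis=1), 1.0)


def test_calibration_sweep_picks_best_matching_threshold():
    spec = FixtureSpec(peptide_seq="AVLIMFWYCPKR", anchor_index=5,
                       triples=((5, "alpha", 3), (5, "beta", 7),
                                (2, "alpha", 11)),
                       seed=2)
    cx = generate_toy_complex(spec).complex
    cmap = residue_contacts(cx)
    reference = {5: (1, 1), 2: (1, 0)}
    report = calibrate_csa_min(cmap, reference)
    assert report["total_abs_error"] == 0
    assert report["chosen_csa_min"] == 0.0
    # a reference demanding fewer contacts forces a higher threshold
    report2 = calibrate_csa_min(cmap, {5: (0, 0), 2: (0, 0)},
                                candidates=(0.0, 1000.0))
    assert report2["chosen_csa_min"] == 1000.0
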