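import itertools

import numpy as np
import pytest

from urnmap.errors import AmbiguityError, FormatError, RoleAssignmentError
from urnmap.fixtures import FixtureSpec, generate_toy_complex
from urnmap.structure_io import (Atom, Chain, ComplexStructure, Residue,
                                 assign_roles, load_complex, pdb_text,
                                 write_pdb)


def toy_spec(seed=0):
    return FixtureSpec(
        peptide_seq="ARNDCQEGHILKMT", anchor_index=5,
        triples=((5, "alpha", 10), (5, "beta", 20), (7, "alpha", 30)),
        seed=seed)


def test_roundtrip_preserves_residues_and_coordinates(tmp_path):
    toy = generate_toy_complex(toy_spec())
    p1 = tmp_path / "toy.pdb"
    toy.write(p1)
    cx1 = load_complex(p1)
    p2 = tmp_path / "toy2.pdb"
    write_pdb(cx1, p2)
    cx2 = load_complex(p2)
    for c1, c2 in zip(cx1.chains, cx2.chains):
        assert c1.role == c2.role
        assert len(c1) == len(c2)
        for r1, r2 in zip(c1.residues, c2.residues):
            assert r1.three_letter_code == r2.three_letter_code
            assert r1.original_number == r2.original_number
            x1 = np.array([a.xyz for a in r1.atoms])
            x2 = np.array([a.xyz for a in r2.atoms])
            assert np.allclose(x1, x2, atol=1e-3)


def test_load_assigns_all_three_roles(tmp_path):
    toy = generate_toy_complex(toy_spec())
    path = toy.write(tmp_path / "toy.pdb")
    cx = load_complex(path)
    assert {c.role for c in cx.chains} == {"alpha", "beta", "peptide"}
    assert len(cx.peptide) == 14
    assert cx.peptide.sequence == "ARNDCQEGHILKMT"


def test_role_assignment_is_permutation_invariant(tmp_path):
    toy = generate_toy_complex(toy_spec())
    chains = toy.complex.chains
    for perm in itertools.permutations(chains):
        bare = [Chain(None, c.residues, c.original_chain_id) for c in perm]
        roles = assign_roles(bare)
        assert roles == {"alpha": "A", "beta": "B", "peptide": "C"}


def test_two_chain_file_without_config_is_rejected(tmp_path):
    toy = generate_toy_complex(toy_spec())
    two = ComplexStructure("partial", toy.complex.chains[:2], "pdb")
    path = tmp_path / "two.pdb"
    write_pdb(two, path)
    with pytest.raises(RoleAssignmentError):
        load_complex(path)


def test_peptide_length_tie_is_ambiguous():
    def mono(cid, n, num0=1):
        residues = [Residue(str(num0 + i), "ALA", "A",
                            [Atom("C", "CA", (float(i), 0.0, 0.0))])
                    for i in range(n)]
        return Chain(None, residues, cid)

    chains = [mono("A", 95), mono("B", 95), mono("C", 15), mono("D", 15)]
    with pytest.raises(AmbiguityError):
        assign_roles(chains)


def test_chain_config_overrides_heuristic(tmp_path):
    toy = generate_toy_complex(toy_spec())
    path = toy.write(tmp_path / "toy.pdb")
    cx = load_complex(path, chain_config={"alpha": "A", "beta": "B",
                                          "peptide": "C"})
    assert cx.alpha.original_chain_id == "A"


def test_extra_chains_are_ignored_for_roles(tmp_path):
    # a structure that also carries a TCR-like chain pair: the peptide is
    # still the unique chain in the length window, the best-scoring chains
    # become alpha/beta and the extras are dropped
    toy = generate_toy_complex(toy_spec())

    def decoy(cid, n):
        residues = [Residue(str(i + 1), "GLY", "G",
                            [Atom("C", "CA", (500.0 + i, 100.0, 0.0))])
                    for i in range(n)]
        return Chain(None, residues, cid)

    chains = list(toy.complex.chains) + [decoy("T", 110), decoy("U", 115)]
    bare = [Chain(None, c.residues, c.original_chain_id) for c in chains]
    roles = assign_roles(bare)
    assert roles == {"alpha": "A", "beta": "B", "peptide": "C"}


def test_nonstandard_residue_is_flagged_modified(tmp_path):
    toy = generate_toy_complex(toy_spec())
    text = toy.pdb_text.replace("GLN C   6", "SEP C   6")
    path = tmp_path / "mod.pdb"
    path.write_text(text)
    cx = load_complex(path)
    res = cx.peptide.residues[5]
    assert res.modified and not res.unmodeled
    assert res.one_letter_code == "X"
    assert not res.usable


def test_numbering_gap_becomes_unmodeled_placeholder(tmp_path):
    toy = generate_toy_complex(toy_spec())
    lines = [l for l in toy.pdb_text.splitlines()
             if not ("GLN C   6" in l)]
    path = tmp_path / "gap.pdb"
    path.write_text("\n".join(lines) + "\n")
    cx = load_complex(path)
    assert len(cx.peptide) == 14          # the residue is not silently dropped
    res = cx.peptide.residues[5]
    assert res.unmodeled and res.atoms == []


def test_unparseable_file_raises_format_error(tmp_path):
    path = tmp_path / "junk.pdb"
    path.write_text("this is not a structure\n")
    with pytest.raises(FormatError):
        load_complex(path)


def test_summary_lists_roles_and_flags(tmp_path):
    toy = generate_toy_complex(toy_spec())
    path = toy.write(tmp_path / "toy.pdb")
    cx = load_complex(path)
    summary = cx.to_summary()
    assert {c["role"] for c in summary["chains"]} == {"alpha", "beta", "peptide"}
    assert all(c["unmodeled"] == [] for c in summary["chains"])
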