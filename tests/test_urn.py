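import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from urnmap.errors import NoAnchorError
from urnmap.fixtures import (FixtureSpec, generate_toy_complex,
                             perturb_register, prototype_fixture_spec,
                             random_register_spec)
from urnmap.urn import (PrototypeReference, SCSet, align_complex, assign_urn,
                        find_anchor, rank_registers, similar_contacts,
                        validate_urn)


def test_prototype_self_identity(dr_toy, dr_proto):
    """Aligning the prototype against itself recovers anchor URN 5, makes
    every contact an SC, and validates."""
    res = align_complex(dr_toy.complex, dr_proto)
    assert dr_proto.anchor_urn == 5
    assert res.urn.positions[res.urn.anchor_index] == 5
    assert res.anchor_overlap == 1.0
    assert res.sc.triples == dr_proto.triples
    assert res.validation.sc_fraction == 1.0
    assert res.validation.valid


def test_dq_prototype_self_identity(dq_toy, dq_proto):
    res = align_complex(dq_toy.complex, dq_proto)
    assert dq_proto.anchor_urn == 5
    assert res.validation.sc_fraction == 1.0 and res.validation.valid
    # the DQ groove anchor touches 9 alpha and 3 beta residues
    assert sum(1 for r, _ in dq_proto.anchor_partners if r == "alpha") == 9
    assert sum(1 for r, _ in dq_proto.anchor_partners if r == "beta") == 3


def test_dr_prototype_anchor_partner_counts(dr_proto):
    # the DR groove anchor touches 9 alpha and 4 beta residues
    assert sum(1 for r, _ in dr_proto.anchor_partners if r == "alpha") == 9
    assert sum(1 for r, _ in dr_proto.anchor_partners if r == "beta") == 4


def test_find_anchor_recovers_planted_index(dr_proto):
    rng = np.random.default_rng(42)
    spec = random_register_spec(rng)
    toy = generate_toy_complex(spec)
    res = align_complex(toy.complex, dr_proto)
    assert res.urn.anchor_index == spec.anchor_index


def test_find_anchor_rejects_poor_overlap(dr_proto):
    # a target whose best residue shares only 2 of the 13 prototype anchor
    # partners cannot be put into the unified numbering
    partners = sorted(dr_proto.anchor_partners)[:2]
    partner_sets = {0: set(partners), 1: set()}
    with pytest.raises(NoAnchorError) as err:
        find_anchor(partner_sets, dr_proto, overlap_min=0.5)
    assert err.value.ranked[0][0] == 0


def test_anchor_tie_broken_by_contact_count_then_index(dr_proto):
    partners = set(dr_proto.anchor_partners)
    sets = {3: set(partners), 7: set(partners) | {("alpha", 90)}}
    idx, overlap = find_anchor(sets, dr_proto)
    assert idx == 7 and overlap == 1.0     # same overlap, more contacts
    sets = {3: set(partners), 7: set(partners)}
    idx, _ = find_anchor(sets, dr_proto)
    assert idx == 3                        # full tie -> smaller index


@given(st.integers(min_value=9, max_value=25), st.data())
def test_urn_offsets_are_consecutive(n, data):
    anchor = data.draw(st.integers(min_value=0, max_value=n - 1))
    urn = assign_urn(n, anchor)
    assert urn.positions[anchor] == 5
    diffs = [urn.positions[i + 1] - urn.positions[i] for i in range(n - 1)]
    assert set(diffs) == {1}


def test_urn_examples_from_the_protocol():
    urn18 = assign_urn(18, 4)
    assert [urn18.positions[i] for i in (0, 17)] == [1, 18]
    urn15 = assign_urn(15, 4)
    assert [urn15.positions[i] for i in (0, 14)] == [1, 15]
    boundary = assign_urn(10, 0)
    assert boundary.positions[0] == 5 and boundary.positions[1] == 6


def test_urn_positions_below_one_are_kept():
    urn = assign_urn(18, 10)
    assert urn.positions[0] == -5           # long N-terminal flank, not clipped


def test_similar_contacts_ignore_residue_chemistry(dr_proto):
    # chemistry never enters: SC is a pure position-triple intersection
    triples = set(dr_proto.triples)
    sc = similar_contacts(triples, dr_proto)
    assert sc.triples == dr_proto.triples
    half = set(sorted(triples)[: len(triples) // 2])
    # move the other half to chain positions the prototype never touches
    shifted = {(p, role, pos + 500) for (p, role, pos) in triples - half}
    sc2 = similar_contacts(half | shifted, dr_proto)
    assert sc2.triples == frozenset(half)
    assert len(sc2) / len(half | shifted) == pytest.approx(0.5, abs=0.01)


def test_validity_rule_truth_table():
    """The 9-position and 50% clauses must hold independently."""

    def case(n_positions, sc_per_pos, extra_per_pos):
        sc, allc = set(), set()
        for p in range(3, 3 + n_positions):
            for k in range(sc_per_pos):
                t = (p, "alpha", 100 + k)
                sc.add(t)
                allc.add(t)
            for k in range(extra_per_pos):
                allc.add((p, "beta", 200 + k))
        return validate_urn(SCSet.from_triples(sc), allc, (3, 14))

    v = case(12, 3, 2)           # 12 positions, 60% SC
    assert v.valid and v.positions_with_sc == 12
    v = case(8, 9, 1)            # 90% SC but only 8 positions
    assert not v.valid and v.sc_fraction > 0.5
    v = case(10, 2, 3)           # 10 positions but only 40% SC
    assert not v.valid and v.positions_with_sc >= 9
    assert v.sc_fraction == pytest.approx(0.4)


def test_skipped_positions_drop_out_of_the_fraction():
    sc = {(p, "alpha", 50) for p in range(3, 13)}
    allc = set(sc) | {(13, "beta", 60), (13, "beta", 61)}
    full = validate_urn(SCSet.from_triples(sc), allc, (3, 14))
    skipped = validate_urn(SCSet.from_triples(sc), allc, (3, 14),
                           skipped_positions=[13])
    assert skipped.sc_fraction == 1.0 > full.sc_fraction
    assert skipped.skipped_positions == [13]


def test_sc_monotone_under_contact_deletion(dr_proto):
    """Removing target contacts never increases the SC count and never flips
    an invalid numbering to valid."""
    rng = np.random.default_rng(5)
    triples = sorted(dr_proto.triples)
    current = set(triples)
    prev_sc = None
    prev_valid = None
    while current:
        sc = similar_contacts(current, dr_proto)
        v = validate_urn(sc, current, dr_proto.core_range)
        if prev_sc is not None:
            assert len(sc) <= prev_sc
            if not prev_valid:
                assert not v.valid
        prev_sc, prev_valid = len(sc), v.valid
        drop = rng.integers(1, 9)
        current = set(sorted(current)[:-drop]) if len(current) > drop else set()


def test_register_shift_scores_below_true_register(dr_proto, dr_toy):
    from urnmap.contacts import residue_contacts

    cmap = residue_contacts(dr_toy.complex)
    partner_sets = {
        i: {(role, int(num)) for role, num in
            ((r.chain_role, r.chain_number) for r in cmap.records
             if r.peptide_index == i)}
        for i in {r.peptide_index for r in cmap.records}}
    ranked = rank_registers(partner_sets, dr_proto.anchor_partners)
    best_idx, best_overlap, _ = ranked[0]
    assert best_idx == 4
    for idx, overlap, _n in ranked[1:]:
        assert overlap < best_overlap


def test_register_shift_of_fixture_is_detected(dr_proto):
    spec = prototype_fixture_spec("dr")
    shifted = perturb_register(spec, 2)
    toy = generate_toy_complex(shifted)
    res = align_complex(toy.complex, dr_proto)
    # the register moved: URN still anchors on the moved high-contact residue
    assert res.urn.anchor_index == spec.anchor_index + 2
    assert res.validation.valid


def test_large_shift_evicts_anchor_and_fails(dr_proto):
    spec = prototype_fixture_spec("dr")
    shifted = perturb_register(spec, -5)    # anchor partners fall off the end
    toy = generate_toy_complex(shifted)
    with pytest.raises(NoAnchorError):
        align_complex(toy.complex, dr_proto)
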