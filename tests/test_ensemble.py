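import numpy as np
import pytest

from hingescan.ensemble import (CoverageError, EnsembleMember, filter_members,
                                make_member, match_modes, signature_profile)
from hingescan.errors import DegenerateEnsembleError, EmptyEnsembleError
from hingescan.gnm import ModeSet, modes_for_structure
from hingescan.structio import Structure
from hingescan.synthetic import DumbbellSpec, make_dumbbell, make_ensemble

from conftest import dummy_chain


def member(struct, seq_id=95.0, z=20.0, rmsd=1.0):
    mapping = {r.res_id: r.res_id for r in struct.residues}
    return EnsembleMember(structure=struct, mapping=mapping,
                          seq_identity=seq_id, z_score=z, rmsd_to_ref=rmsd)


@pytest.fixture
def small_ref():
    return Structure(id="ref", residues=dummy_chain(100))


class TestFilterMembers:
    def test_passing_member_kept(self, small_ref):
        m = member(small_ref, seq_id=90, z=15, rmsd=1.2)
        ens = filter_members(small_ref, [m])
        assert ens.m == 1

    def test_high_rmsd_dropped_small_profile(self, small_ref):
        good = member(small_ref, seq_id=90, z=15, rmsd=1.2)
        bad = member(small_ref, seq_id=90, z=15, rmsd=2.5)
        ens = filter_members(small_ref, [good, bad])
        assert ens.members == [good]

    def test_all_dropped_raises_with_reasons(self, small_ref):
        bad = member(small_ref, seq_id=50, z=15, rmsd=1.0)
        with pytest.raises(EmptyEnsembleError, match="seq_identity"):
            filter_members(small_ref, [bad])

    def test_large_profile_autoselected_above_size_boundary(self):
        big_ref = Structure(id="big", residues=dummy_chain(600))
        # 30% identity, 5 A rmsd: fails the small profile, passes the large
        m = member(big_ref, seq_id=30, z=15, rmsd=5.0)
        ens = filter_members(big_ref, [m])
        assert ens.m == 1
        with pytest.raises(EmptyEnsembleError):
            filter_members(big_ref, [m], profile="small")

    def test_missing_z_score_criterion_skipped(self, small_ref):
        m = member(small_ref, seq_id=90, z=None, rmsd=1.0)
        assert filter_members(small_ref, [m]).m == 1


@pytest.fixture
def dumbbell_modes():
    st = make_dumbbell(DumbbellSpec(seed=2))
    idx = np.arange(st.N)
    return st, modes_for_structure(st, cutoff=10.0), idx


class TestMatchModes:
    def test_identity_member(self, dumbbell_modes):
        st, ms, idx = dumbbell_modes
        pairs = match_modes(ms, ms, 2, idx, idx, st.N)
        assert [(p[0], p[1]) for p in pairs] == [(1, 1.0), (2, 1.0)]
        assert all(p[2] == pytest.approx(1.0) for p in pairs)

    def test_negated_member_mode_sign_flipped(self, dumbbell_modes):
        st, ms, idx = dumbbell_modes
        neg = ModeSet(eigenvalues=ms.eigenvalues,
                      eigenvectors=-ms.eigenvectors,
                      variance_fractions=ms.variance_fractions)
        pairs = match_modes(ms, neg, 2, idx, idx, st.N)
        assert [(p[0], p[1]) for p in pairs] == [(1, -1.0), (2, -1.0)]
        assert all(p[2] == pytest.approx(1.0) for p in pairs)

    def test_swapped_member_modes_cross_paired(self, dumbbell_modes):
        st, ms, idx = dumbbell_modes
        vecs = ms.eigenvectors.copy()
        vecs[:, [0, 1]] = vecs[:, [1, 0]]
        swapped = ModeSet(eigenvalues=ms.eigenvalues, eigenvectors=vecs,
                          variance_fractions=ms.variance_fractions)
        pairs = match_modes(ms, swapped, 2, idx, idx, st.N)
        assert pairs[0][0] == 2
        assert pairs[1][0] == 1

    def test_low_coverage_rejected(self, dumbbell_modes):
        st, ms, idx = dumbbell_modes
        few = idx[: st.N // 4]
        with pytest.raises(CoverageError):
            match_modes(ms, ms, 1, few, few, st.N)


class TestSignatureProfile:
    def test_identical_copies_mean_matches_sd_zero(self):
        spec = DumbbellSpec(seed=4)
        ens = make_ensemble(spec, m=5, jitter_sd=0.0)
        sigs = signature_profile(ens, k=1)
        single = modes_for_structure(ens.reference).profile(1)
        np.testing.assert_allclose(np.abs(sigs[0].mean), np.abs(single.values),
                                   atol=1e-8)
        np.testing.assert_allclose(sigs[0].sd, 0.0, atol=1e-8)
        assert np.all(sigs[0].coverage == 5)

    def test_fewer_than_two_members_degenerate(self):
        spec = DumbbellSpec(seed=4)
        ens = make_ensemble(spec, m=2, jitter_sd=0.0)
        ens.members = ens.members[:1]
        with pytest.raises(DegenerateEnsembleError):
            signature_profile(ens, k=1)

    def test_member_order_permutation_invariant(self):
        spec = DumbbellSpec(seed=6)
        ens = make_ensemble(spec, m=6, jitter_sd=0.3)
        sigs = signature_profile(ens, k=1)
        ens.members = ens.members[::-1]
        sigs_rev = signature_profile(ens, k=1)
        np.testing.assert_allclose(sigs[0].mean, sigs_rev[0].mean, atol=1e-12)
        np.testing.assert_allclose(sigs[0].sd, sigs_rev[0].sd, atol=1e-12)

    def test_sd_shrinks_with_jitter(self):
        """Mean signature SD decreases monotonically as coordinate jitter
        goes 0.5 -> 0.25 -> 0.1 A."""
        mean_sds = []
        for jitter in (0.5, 0.25, 0.1):
            ens = make_ensemble(DumbbellSpec(seed=8), m=8, jitter_sd=jitter)
            sigs = signature_profile(ens, k=1)
            mean_sds.append(float(np.nanmean(sigs[0].sd)))
        assert mean_sds[0] > mean_sds[1] > mean_sds[2]

    def test_hinges_on_mean_profile_fall_in_linker(self):
        from hingescan.hinges import hinge_set
        spec = DumbbellSpec(seed=9)
        ens = make_ensemble(spec, m=10, jitter_sd=0.3)
        sigs = signature_profile(ens, k=1)
        hs = hinge_set([sigs[0].as_profile()], ens.reference)
        lo, hi = spec.linker_range
        assert hs.h >= 2
        assert all(lo - 2 <= num <= hi + 2 for _, num, _ in hs.union)


def test_make_member_alignment_identity_and_rmsd():
    ref = make_dumbbell(DumbbellSpec(seed=10, with_ligand=False))
    mem_st = make_dumbbell(DumbbellSpec(seed=10, jitter_sd=0.2, with_ligand=False))
    mem = make_member(ref, mem_st)
    assert mem.seq_identity == pytest.approx(100.0)
    assert len(mem.mapping) == ref.N
    assert 0.0 < mem.rmsd_to_ref < 0.5
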