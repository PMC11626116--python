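import numpy as np
import pytest

from hingescan.errors import DisconnectedStructureError
from hingescan.gnm import (ModeSet, build_kirchhoff, gnm_modes,
                           modes_for_structure, select_modes)
from hingescan.structio import Structure
from hingescan.synthetic import DumbbellSpec, make_dumbbell

from conftest import dummy_chain


def path_structure(n, spacing=5.0):
    """Beads on a line; with cutoff 7 the contact graph is a path."""
    return Structure(id=f"path{n}", residues=dummy_chain(n, spacing=spacing))


class TestBuildKirchhoff:
    def test_collinear_beads_give_path_laplacian(self):
        """Beads 5 A apart with cutoff 7: only neighbours connect, so the
        matrix is the tridiagonal path Laplacian ([[1,-1,0],[-1,2,-1],...])."""
        n = 10
        st = Structure(id="p", residues=dummy_chain(n, spacing=5.0))
        k = build_kirchhoff(st, cutoff=7.0)
        expected = (np.diag([1.0] + [2.0] * (n - 2) + [1.0])
                    - np.diag(np.ones(n - 1), 1) - np.diag(np.ones(n - 1), -1))
        np.testing.assert_allclose(k.matrix, expected)

    def test_complete_graph_at_large_cutoff(self):
        st = Structure(id="k10", residues=dummy_chain(10, spacing=5.0))
        k = build_kirchhoff(st, cutoff=100.0)
        off = k.matrix[~np.eye(10, dtype=bool)]
        np.testing.assert_allclose(off, -1.0)
        np.testing.assert_allclose(np.diag(k.matrix), 9.0)

    def test_row_sums_zero(self):
        st = make_dumbbell(DumbbellSpec(seed=3, jitter_sd=0.2))
        k = build_kirchhoff(st, cutoff=10.0)
        np.testing.assert_allclose(k.matrix.sum(axis=1), 0.0, atol=0)
        np.testing.assert_allclose(k.matrix, k.matrix.T)

    def test_invalid_inputs(self):
        st = path_structure(10)
        with pytest.raises(ValueError):
            build_kirchhoff(st, cutoff=-1.0)


class TestGnmModes:
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_path_graph_analytic_spectrum(self, n):
        """Path-graph Laplacian eigenvalues are 2 - 2 cos(j pi / n)."""
        ms = gnm_modes(build_kirchhoff(path_structure(n), cutoff=7.0))
        expected = 2.0 - 2.0 * np.cos(np.arange(1, n) * np.pi / n)
        np.testing.assert_allclose(ms.eigenvalues, expected, atol=1e-8)

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_path_graph_mode1_single_midpoint_crossover(self, n):
        """Mode 1 of a path has one sign change at the chain midpoint,
        matching the analytic eigenvector cos(pi (i - 1/2) / n)."""
        ms = gnm_modes(build_kirchhoff(path_structure(n), cutoff=7.0))
        v = ms.eigenvectors[:, 0]
        signs = np.sign(v)
        changes = np.flatnonzero(signs[:-1] * signs[1:] < 0)
        assert len(changes) == 1
        assert changes[0] == n // 2 - 1
        analytic = np.cos(np.pi * (np.arange(1, n + 1) - 0.5) / n)
        analytic /= np.linalg.norm(analytic)
        if np.dot(analytic, v) < 0:
            analytic = -analytic
        np.testing.assert_allclose(np.abs(v), np.abs(analytic), atol=1e-8)

    def test_complete_graph_degenerate_eigenvalues(self):
        ms = gnm_modes(build_kirchhoff(path_structure(10), cutoff=100.0))
        np.testing.assert_allclose(ms.eigenvalues, 10.0, atol=1e-8)

    def test_disconnected_chains_error(self):
        res = dummy_chain(10, "A") + dummy_chain(10, "B", offset=(500, 0, 0))
        st = Structure(id="disc", residues=res)
        with pytest.raises(DisconnectedStructureError) as exc:
            gnm_modes(build_kirchhoff(st, cutoff=10.0))
        assert len(exc.value.components) == 2

    def test_orthonormality_and_reconstruction(self):
        st = make_dumbbell(DumbbellSpec(seed=5, jitter_sd=0.3))
        k = build_kirchhoff(st, cutoff=10.0)
        ms = gnm_modes(k)
        vecs = ms.eigenvectors
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(vecs.shape[1]), atol=1e-8)
        for j in range(ms.n_modes):
            np.testing.assert_allclose(k.matrix @ vecs[:, j],
                                       ms.eigenvalues[j] * vecs[:, j], atol=1e-7)

    def test_variance_fractions_sum_to_one_and_sorted(self):
        ms = gnm_modes(build_kirchhoff(path_structure(30), cutoff=7.0))
        assert ms.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(ms.variance_fractions) <= 1e-15)

    def test_sign_convention_largest_component_positive(self):
        ms = gnm_modes(build_kirchhoff(path_structure(20), cutoff=7.0))
        for j in range(ms.n_modes):
            v = ms.eigenvectors[:, j]
            assert v[np.argmax(np.abs(v))] > 0


def modeset_from_fractions(fractions):
    f = np.asarray(fractions, dtype=float)
    inv = f / f.sum()
    lam = 1.0 / inv
    n = len(f)
    return ModeSet(eigenvalues=lam, eigenvectors=np.eye(n),
                   variance_fractions=inv)


class TestSelectModes:
    def test_first_mode_suffices(self):
        # eigenvalues {1,2,4,8} -> fractions {8,4,2,1}/15
        ms = modeset_from_fractions([8, 4, 2, 1])
        assert select_modes(ms) == 1
        assert ms.sigma == pytest.approx(8 / 15)

    def test_three_modes_needed(self, caplog):
        ms = modeset_from_fractions([0.15, 0.15, 0.10, 0.30, 0.30])
        assert select_modes(ms) == 3
        assert ms.sigma == pytest.approx(0.40)

    def test_cap_binds_below_sigma_min(self, caplog):
        import logging
        ms = modeset_from_fractions([0.10, 0.10, 0.05, 0.375, 0.375])
        with caplog.at_level(logging.WARNING):
            k = select_modes(ms)
        assert k == 3
        assert ms.sigma == pytest.approx(0.25)
        assert any("cap" in r.message for r in caplog.records)


def test_modes_for_structure_dumbbell_mode1_dominates():
    st = make_dumbbell(DumbbellSpec(seed=1))
    ms = modes_for_structure(st)
    assert ms.selected_k == 1
    assert ms.sigma >= 1 / 3
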