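"""Simplex machinery: closure, core selection, zero replacement, ilr and
Aitchison distance, cross-checked against scikit-bio's compositional
transforms as an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import skbio.stats.composition as skb

from neocoda import composition as coda
from conftest import random_composition


def positive_compositions(d=4, n=3):
    elem = st.floats(0.05, 10.0, allow_nan=False)
    return st.lists(
        st.lists(elem, min_size=d, max_size=d), min_size=n, max_size=n
    ).map(lambda rows: coda.closure(np.array(rows)))


class TestClosure:
    def test_divides_by_row_sum(self):
        out = coda.closure([[2.0, 3.0, 5.0]])
        np.testing.assert_allclose(out.values[0], [0.2, 0.3, 0.5])

    def test_idempotent(self):
        once = coda.closure([[0.25, 0.25, 0.5]])
        np.testing.assert_array_equal(once.values[0], [0.25, 0.25, 0.5])

    def test_zero_row_names_sample(self):
        with pytest.raises(ValueError, match="bad"):
            coda.closure(np.array([[1.0, 1.0], [0.0, 0.0]]),
                         samples=["ok", "bad"])

    def test_matches_skbio(self, rng):
        x = rng.uniform(0.1, 5.0, size=(6, 5))
        np.testing.assert_allclose(coda.closure(x).values, skb.closure(x),
                                   atol=1e-12)


class TestSelectCore:
    def test_selects_largest_by_mean_and_recloses(self):
        comp = coda.closure([[0.4, 0.3, 0.2, 0.1]], parts=list("ABCD"))
        core = coda.select_core(comp, 2)
        assert core.parts == ["A", "B"]
        np.testing.assert_allclose(core.values[0], [4 / 7, 3 / 7])

    def test_k_equals_d_is_identity(self, rng):
        comp = random_composition(rng, 5, 4)
        core = coda.select_core(comp, 4)
        np.testing.assert_allclose(core.values, comp.values, atol=1e-12)

    def test_tie_broken_lexicographically(self):
        comp = coda.closure([[0.3, 0.2, 0.2, 0.3]], parts=["D", "B", "C", "A"])
        core = coda.select_core(comp, 3)
        # B and C tie at rank 3; B wins lexicographically
        assert set(core.parts) == {"A", "B", "D"}

    def test_commutes_with_closure(self, rng):
        raw = rng.uniform(0.0, 10.0, size=(6, 5))
        raw[raw < 1.0] = 0.0
        raw += 0.01  # keep rows closable after selection
        a = coda.select_core(coda.closure(raw), 3)
        b = coda.select_core(coda.closure(coda.closure(raw).values), 3)
        assert a.parts == b.parts
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestImputeZeros:
    def test_multiplicative_replacement_formula(self):
        comp = coda.closure([[0.5, 0.5, 0.0]])
        out = coda.impute_zeros(comp, delta=0.001)
        np.testing.assert_allclose(out.values[0], [0.4995, 0.4995, 0.001])

    def test_one_zero_free_part_row(self):
        comp = coda.closure([[1.0, 0.0, 0.0]])
        out = coda.impute_zeros(comp, delta=0.01)
        np.testing.assert_allclose(out.values[0], [0.98, 0.01, 0.01])

    def test_zero_free_rows_unchanged_and_sums_exact(self, rng):
        comp = random_composition(rng, 4, 5)
        out = coda.impute_zeros(comp, delta=1e-4)
        np.testing.assert_array_equal(out.values, comp.values)

    def test_preserves_row_sums_and_nonzero_ratios(self):
        comp = coda.closure([[0.3, 0.6, 0.0, 0.1]])
        out = coda.impute_zeros(comp, delta=0.005)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.values[0, 1] / out.values[0, 0], 2.0)
        np.testing.assert_allclose(out.values[0, 3] / out.values[0, 0], 1 / 3)

    def test_matches_skbio_multiplicative_replacement(self):
        comp = coda.closure([[0.5, 0.3, 0.0, 0.2], [0.25, 0.25, 0.25, 0.25]])
        out = coda.impute_zeros(comp, delta=0.01)
        np.testing.assert_allclose(
            out.values, skb.multi_replace(comp.values, delta=0.01), atol=1e-12)

    def test_delta_bounds_enforced(self):
        comp = coda.closure([[0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="delta"):
            coda.impute_zeros(comp, delta=0.5)
        with pytest.raises(ValueError, match="delta"):
            coda.impute_zeros(comp, delta=0.0)


class TestIlrBasis:
    def test_d2_closed_form(self):
        basis = coda.make_ilr_basis(["a", "b"])
        np.testing.assert_allclose(basis.contrasts,
                                   [[1 / np.sqrt(2), -1 / np.sqrt(2)]])

    @pytest.mark.parametrize("d", range(2, 21))
    def test_orthonormal_zero_sum(self, d):
        basis = coda.make_ilr_basis([f"p{i}" for i in range(d)])
        gram = basis.contrasts @ basis.contrasts.T
        np.testing.assert_allclose(gram, np.eye(d - 1), atol=1e-12)
        np.testing.assert_allclose(basis.contrasts.sum(axis=1), 0.0, atol=1e-12)

    def test_rejects_single_part(self):
        with pytest.raises(ValueError):
            coda.make_ilr_basis(["only"])


class TestIlr:
    def test_two_part_closed_form(self):
        comp = coda.closure([[0.7311, 0.2689]], parts=["a", "b"])
        out = coda.ilr(comp)
        expected = np.log(0.7311 / 0.2689) / np.sqrt(2)
        np.testing.assert_allclose(out.coords[0, 0], expected)
        # input composition printed to 4 decimals -> ~1e-4 slack in the coord
        assert out.coords[0, 0] == pytest.approx(0.70711, abs=5e-4)

    def test_uniform_maps_to_origin(self):
        comp = coda.closure([np.ones(6)])
        out = coda.ilr(comp)
        np.testing.assert_allclose(out.coords, 0.0, atol=1e-12)

    def test_zero_entry_directs_to_imputation(self):
        comp = coda.closure([[0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="impute_zeros"):
            coda.ilr(comp)

    def test_matches_skbio_ilr(self, rng):
        comp = random_composition(rng, 5, 6)
        ours = coda.ilr(comp).coords
        theirs = skb.ilr(comp.values)
        # same transform up to basis sign/rotation: compare norms and
        # pairwise distances (isometry invariants)
        np.testing.assert_allclose(np.linalg.norm(ours, axis=1),
                                   np.linalg.norm(theirs, axis=1), atol=1e-10)

    def test_perturbation_acts_as_translation(self, rng):
        """ilr(x o g) - ilr(x) = ilr(g): Aitchison perturbation becomes
        vector addition in coordinates."""
        for _ in range(10):
            x = random_composition(rng, 1, 5)
            g = random_composition(rng, 1, 5)
            xg = coda.closure(x.values * g.values, parts=x.parts)
            lhs = coda.ilr(xg).coords - coda.ilr(x).coords
            rhs = coda.ilr(g).coords
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestIlrInverse:
    def test_origin_maps_to_uniform(self):
        basis = coda.make_ilr_basis(list("abcd"))
        out = coda.ilr_inverse(np.zeros((1, 3)), basis)
        np.testing.assert_allclose(out.values[0], 0.25)

    def test_inverse_of_closed_form(self):
        basis = coda.make_ilr_basis(["a", "b"])
        out = coda.ilr_inverse(np.array([[0.70711]]), basis)
        np.testing.assert_allclose(out.values[0], [0.7311, 0.2689], atol=5e-5)

    def test_round_trip(self, rng):
        comp = random_composition(rng, 8, 7)
        back = coda.ilr_inverse(coda.ilr(comp), coda.make_ilr_basis(comp.parts))
        np.testing.assert_allclose(back.values, comp.values, atol=1e-10)

    def test_rejects_nonfinite(self):
        basis = coda.make_ilr_basis(list("abc"))
        with pytest.raises(ValueError, match="finite"):
            coda.ilr_inverse(np.array([[np.nan, 0.0]]), basis)


class TestAitchisonDistance:
    def test_identity_and_symmetry(self, rng):
        x = random_composition(rng, 2, 5).values
        assert coda.aitchison_distance(x[0], x[0]) == 0.0
        assert coda.aitchison_distance(x[0], x[1]) == pytest.approx(
            coda.aitchison_distance(x[1], x[0]))

    def test_scale_invariance(self):
        x = np.array([0.2, 0.3, 0.5])
        y = coda.closure(2 * x).values[0]
        assert coda.aitchison_distance(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_equals_ilr_euclidean_distance(self, rng):
        comp = random_composition(rng, 6, 5)
        coords = coda.ilr(comp).coords
        for i in range(5):
            d_ilr = np.linalg.norm(coords[i] - coords[i + 1])
            d_ait = coda.aitchison_distance(comp.values[i], comp.values[i + 1])
            assert d_ilr == pytest.approx(d_ait, abs=1e-10)

    def test_basis_independent(self, rng):
        """Distance identical under the default basis and a permuted-part
        basis (any orthonormal basis gives the same geometry)."""
        comp = random_composition(rng, 2, 6)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = coda.CompositionMatrix(
            [comp.parts[j] for j in perm], list(comp.samples),
            comp.values[:, perm])
        d1 = np.linalg.norm(np.diff(coda.ilr(comp).coords, axis=0))
        d2 = np.linalg.norm(np.diff(coda.ilr(permuted).coords, axis=0))
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestGroupMeans:
    def test_mean_of_two(self):
        comp = coda.closure([[0.2, 0.8], [0.6, 0.4]], samples=["a", "b"])
        out = coda.group_mean_composition(comp, {"a": "g", "b": "g"})
        np.testing.assert_allclose(out.values[0], [0.4, 0.6])

    def test_single_sample_group_is_identity(self):
        comp = coda.closure([[0.2, 0.8], [0.6, 0.4]], samples=["a", "b"])
        out = coda.group_mean_composition(comp, {"a": "g1", "b": "g2"})
        np.testing.assert_allclose(out.values, comp.values)

    def test_unassigned_sample_rejected(self):
        comp = coda.closure([[0.2, 0.8]], samples=["a"])
        with pytest.raises(KeyError):
            coda.group_mean_composition(comp, {})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(positive_compositions())
def test_ilr_round_trip_property(comp):
    """Property: inverse-ilr of ilr reproduces any strictly positive
    composition to near machine precision."""
    back = coda.ilr_inverse(coda.ilr(comp), coda.make_ilr_basis(comp.parts))
    np.testing.assert_allclose(back.values, comp.values, atol=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(positive_compositions(d=5, n=2))
def test_ilr_isometry_property(comp):
    """Property: Euclidean distance in ilr coordinates equals the
    Aitchison distance for every pair."""
    coords = coda.ilr(comp).coords
    d_ilr = float(np.linalg.norm(coords[0] - coords[1]))
    d_ait = coda.aitchison_distance(comp.values[0], comp.values[1])
    assert d_ilr == pytest.approx(d_ait, abs=1e-10)
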