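import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from como.chem import Analog, is_hydrogen_fragment
from como.diagnostics import (
    DEFAULT_DESCRIPTORS,
    NeighborhoodModel,
    SubstituentPool,
    build_reference_space,
    compute_nbh,
    enumerate_diagnostic_vas,
    score_progression,
    score_saturation,
)
from como.synthetic import LandscapeSpec, make_pool, make_series


def nbh_from_matrix(matrix: np.ndarray, radius: float = 1.0) -> NeighborhoodModel:
    n_va, n_ea = matrix.shape
    return NeighborhoodModel(
        radius=radius,
        ea_ids=[f"E{j}" for j in range(n_ea)],
        va_ids=[f"V{i}" for i in range(n_va)],
        membership=matrix.astype(bool),
    )


def brute_force_scores(matrix: np.ndarray):
    """Independent recomputation of C, d_mean, D, S from a membership matrix."""
    n_va = matrix.shape[0]
    m = [int(row.sum()) for row in matrix]
    in_nbh = [i for i in range(n_va) if m[i] > 0]
    c = len(in_nbh) / n_va
    if not in_nbh:
        return c, None, 0.0, 0.0
    nbh_o_va = sum(m[i] for i in in_nbh)
    d_mean = nbh_o_va / len(in_nbh)
    d = 1 - 1 / d_mean
    s = 0.0 if c + d == 0 else 2 * c * d / (c + d)
    return c, d_mean, d, s


def brute_force_progression(matrix: np.ndarray, potencies):
    num = den = 0.0
    for row in matrix:
        eas = [j for j in range(matrix.shape[1]) if row[j]]
        if len(eas) <= 1:
            continue
        pairs = list(itertools.combinations(eas, 2))
        delta = sum(abs(potencies[a] - potencies[b]) for a, b in pairs) / len(pairs)
        w = 1 / len(eas)
        num += w * delta
        den += w
    return None if den == 0 else num / den


class TestSubstituentPool:
    def test_rejects_multi_attachment(self):
        with pytest.raises(ValueError):
            SubstituentPool(fragments=["[*:1]CC[*:2]"])

    def test_rejects_oversized(self):
        with pytest.raises(ValueError):
            SubstituentPool(fragments=["[*:1]" + "C" * 20])

    def test_dedupes_by_canonical_key(self):
        pool = SubstituentPool(fragments=["[*:1]OC", "[*:2]OC", "COC"[::-1] + "[*]"])
        assert len(pool) == 2


class TestEnumerateVAs:
    def test_uniqueness_cap_with_tiny_pool(self):
        spec = LandscapeSpec(n_sites=1, substituents_per_site=2, seed=0)
        series, _ = make_series(spec)
        pool = SubstituentPool(fragments=["[*:1]Br"])
        vas = enumerate_diagnostic_vas(series, pool, n_va=5, seed=0)
        assert len(vas) == 1

    def test_determinism(self, noisy_series, pool):
        series, _ = noisy_series
        a = enumerate_diagnostic_vas(series, pool, n_va=50, seed=11)
        b = enumerate_diagnostic_vas(series, pool, n_va=50, seed=11)
        assert [v.smiles for v in a] == [v.smiles for v in b]

    def test_no_va_duplicates_an_ea(self, noisy_series, pool):
        series, _ = noisy_series
        vas = enumerate_diagnostic_vas(series, pool, n_va=100, seed=2)
        assert not ({v.key for v in vas} & series.member_keys)
        assert len({v.key for v in vas}) == len(vas)

    def test_hydrogen_frequency_respected(self, pool):
        # every EA has H at R2 -> VAs should nearly always carry H there
        spec = LandscapeSpec(
            n_sites=2, substituents_per_site=(4, 1), hydrogen_sites=(2,), seed=2
        )
        series, _ = make_series(spec)
        assert series.hydrogen_frequency("R2") == 1.0
        vas = enumerate_diagnostic_vas(series, pool, n_va=300, seed=5)
        from como.chem import decompose

        h = sum(
            1 for v in vas if is_hydrogen_fragment(decompose(v, series.core)["R2"])
        )
        assert h == len(vas)


class TestReferenceSpace:
    def test_two_compounds_single_descriptor(self):
        eas = [Analog("a", "CC"), Analog("b", "CCCCCCCC")]
        space = build_reference_space(eas, [], descriptor_names=("MolWt",))
        coords = space.ea_coords.ravel()
        assert coords[0] == pytest.approx(-1.0)
        assert coords[1] == pytest.approx(1.0)

    def test_normalization_contract(self, noisy_series, pool):
        series, _ = noisy_series
        vas = enumerate_diagnostic_vas(series, pool, n_va=50, seed=1)
        space = build_reference_space(series.members, vas, DEFAULT_DESCRIPTORS)
        both = np.vstack([space.ea_coords, space.va_coords])
        assert np.abs(both.mean(axis=0)).max() < 1e-9
        assert np.abs(both.std(axis=0) - 1).max() < 1e-9

    def test_duplicate_compound_identical_coordinates(self):
        eas = [Analog("a", "CCO"), Analog("b", "OCC"), Analog("c", "CCCC")]
        space = build_reference_space(eas, [])
        assert np.allclose(space.ea_coords[0], space.ea_coords[1])

    def test_zero_variance_descriptor_scale_one(self):
        eas = [Analog("a", "CCO"), Analog("b", "CCN")]
        space = build_reference_space(eas, [], descriptor_names=("RingCount",))
        assert space.scale[0] == 1.0


class TestComputeNBH:
    def test_tiny_radius_empty(self, noisy_series, pool):
        series, _ = noisy_series
        vas = enumerate_diagnostic_vas(series, pool, n_va=30, seed=1)
        space = build_reference_space(series.members, vas)
        nbh = compute_nbh(space, radius=1e-12)
        assert nbh.n_n == 0

    def test_huge_radius_full(self, noisy_series, pool):
        series, _ = noisy_series
        vas = enumerate_diagnostic_vas(series, pool, n_va=30, seed=1)
        space = build_reference_space(series.members, vas)
        nbh = compute_nbh(space, radius=1e9)
        assert nbh.n_n == len(vas)
        assert (nbh.multiplicity == len(series.members)).all()

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        ea = rng.normal(size=(20, 7))
        va = rng.normal(size=(100, 7))
        from como.diagnostics import ReferenceSpace

        space = ReferenceSpace(
            descriptor_names=tuple("d" * 7),
            center=np.zeros(7),
            scale=np.ones(7),
            ea_ids=[f"E{j}" for j in range(20)],
            va_ids=[f"V{i}" for i in range(100)],
            ea_coords=ea,
            va_coords=va,
        )
        nbh = compute_nbh(space, radius=2.5)
        for i in range(100):
            for j in range(20):
                expected = np.linalg.norm(va[i] - ea[j]) <= 2.5
                assert nbh.membership[i, j] == expected

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(1)
        from como.diagnostics import ReferenceSpace

        space = ReferenceSpace(
            descriptor_names=("x", "y"),
            center=np.zeros(2),
            scale=np.ones(2),
            ea_ids=["e1", "e2"],
            va_ids=[f"v{i}" for i in range(50)],
            ea_coords=rng.normal(size=(2, 2)),
            va_coords=rng.normal(size=(50, 2)),
        )
        previous = 0
        for r in (0.5, 1.0, 2.0, 4.0):
            n_n = compute_nbh(space, r).n_n
            assert n_n >= previous
            previous = n_n

    def test_invalid_radius(self, noisy_series):
        series, _ = noisy_series
        space = build_reference_space(series.members, [])
        with pytest.raises(ValueError):
            compute_nbh(space, radius=0)


class TestScoreSaturation:
    def test_no_vas_in_nbhs(self):
        nbh = nbh_from_matrix(np.zeros((10, 3)))
        c, d_mean, d, s = score_saturation(nbh)
        assert (c, d_mean, d, s) == (0.0, None, 0.0, 0.0)

    def test_single_membership_gives_zero_density(self):
        matrix = np.zeros((10, 5))
        matrix[:4, 0] = 1  # four VAs, each in exactly one NBH
        c, d_mean, d, s = score_saturation(nbh_from_matrix(matrix))
        assert c == pytest.approx(0.4)
        assert d_mean == pytest.approx(1.0)
        assert d == 0.0
        assert s == 0.0

    def test_hand_computed_example(self):
        # n_V=100, n_N=50, every in-NBH VA in exactly 2 NBHs
        matrix = np.zeros((100, 4))
        matrix[:50, :2] = 1
        c, d_mean, d, s = score_saturation(nbh_from_matrix(matrix))
        assert c == pytest.approx(0.5)
        assert d_mean == pytest.approx(2.0)
        assert d == pytest.approx(0.5)
        assert s == pytest.approx(0.5)

    def test_empty_va_population_errors(self):
        with pytest.raises(ValueError):
            score_saturation(nbh_from_matrix(np.zeros((0, 3))))

    @settings(max_examples=120, deadline=None)
    @given(st.integers(0, 2**40 - 1), st.integers(1, 40), st.integers(1, 8))
    def test_matches_brute_force_on_random_matrices(self, seed, n_va, n_ea):
        rng = np.random.default_rng(seed)
        matrix = rng.random((n_va, n_ea)) < 0.3
        c, d_mean, d, s = score_saturation(nbh_from_matrix(matrix))
        bc, bdm, bd, bs = brute_force_scores(matrix)
        assert c == pytest.approx(bc)
        assert (d_mean is None) == (bdm is None)
        if bdm is not None:
            assert d_mean == pytest.approx(bdm)
        assert d == pytest.approx(bd)
        assert s == pytest.approx(bs)
        # range and ordering invariants
        assert 0 <= c <= 1 and 0 <= d < 1 and 0 <= s <= 1
        if c > 0 and d > 0:
            assert min(c, d) - 1e-12 <= s <= max(c, d) + 1e-12


class TestScoreProgression:
    def test_single_shared_pair(self):
        matrix = np.array([[1, 1]])
        p = score_progression(
            nbh_from_matrix(matrix), {"E0": 6.0, "E1": 7.0}
        )
        assert p == pytest.approx(1.0)

    def test_all_singletons_undefined(self):
        matrix = np.eye(3)
        p = score_progression(
            nbh_from_matrix(matrix), {"E0": 5.0, "E1": 6.0, "E2": 7.0}
        )
        assert p is None

    def test_three_way_example(self):
        matrix = np.array([[1, 1, 1]])
        p = score_progression(
            nbh_from_matrix(matrix), {"E0": 5.0, "E1": 6.0, "E2": 9.0}
        )
        assert p == pytest.approx((1 + 4 + 3) / 3)

    def test_missing_potency_names_ea(self):
        matrix = np.array([[1, 1]])
        with pytest.raises(ValueError, match="E1"):
            score_progression(nbh_from_matrix(matrix), {"E0": 6.0})

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(5)
        matrix = rng.random((30, 6)) < 0.4
        pot = {f"E{j}": float(rng.normal(7, 1)) for j in range(6)}
        nbh = nbh_from_matrix(matrix)
        p = score_progression(nbh, pot)
        if p is None:
            pytest.skip("no shared VAs at this seed")
        shifted = {k: v + 3.5 for k, v in pot.items()}
        scaled = {k: v * 2.0 for k, v in pot.items()}
        assert score_progression(nbh, shifted) == pytest.approx(p)
        assert score_progression(nbh, scaled) == pytest.approx(2 * p)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**40 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_va, n_ea = int(rng.integers(1, 30)), int(rng.integers(2, 8))
        matrix = rng.random((n_va, n_ea)) < 0.35
        pots = rng.normal(7, 1, size=n_ea)
        pot_map = {f"E{j}": float(pots[j]) for j in range(n_ea)}
        p = score_progression(nbh_from_matrix(matrix), pot_map)
        expected = brute_force_progression(matrix, pots)
        assert (p is None) == (expected is None)
        if expected is not None:
            assert p == pytest.approx(expected)
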