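"""Target profiles, cosine score, local-network ratio, and screening."""

import numpy as np
import pytest

from csln.chem import FP_LENGTH, Fingerprint, tanimoto
from csln.errors import (
    DataError,
    DegenerateLocalNetworkError,
    UnscoreableTargetError,
)
from csln.network import DTINetwork
from csln.scoring import (
    binding_score,
    build_profile,
    cosine_score,
    local_similarity_ratio,
    screen,
)
from csln.synthetic import SyntheticSpec, generate
from csln.training import CSLNModel

from conftest import make_fp, random_fp


def star_network(n_members, target_id="t", extra_targets=()):
    """One target with n_members member drugs (plus optional empty targets)."""
    targets = (target_id,) + tuple(extra_targets)
    adjacency = np.zeros((n_members, len(targets)), dtype=np.uint8)
    adjacency[:, 0] = 1
    return DTINetwork(
        tuple(f"d{i}" for i in range(n_members)), targets, adjacency
    )


class TestBuildProfile:
    def test_elementwise_sum(self):
        net = star_network(2)
        fps = {"d0": make_fp({1, 2}), "d1": make_fp({2, 3})}
        prof = build_profile(net, fps, "t")
        expected = np.zeros(FP_LENGTH, dtype=np.int64)
        expected[1], expected[2], expected[3] = 1, 2, 1
        assert np.array_equal(prof.counts, expected)
        assert prof.member_ids == ("d0", "d1")

    def test_single_member_unscoreable(self):
        net = star_network(1)
        with pytest.raises(UnscoreableTargetError):
            build_profile(net, {"d0": make_fp({1})}, "t")

    def test_exclusion_can_make_unscoreable(self):
        net = star_network(2)
        fps = {"d0": make_fp({1}), "d1": make_fp({2})}
        with pytest.raises(UnscoreableTargetError):
            build_profile(net, fps, "t", exclude_drug="d0")

    def test_missing_fingerprint_names_drug(self):
        net = star_network(2)
        with pytest.raises(DataError, match="d1"):
            build_profile(net, {"d0": make_fp({1})}, "t")

    def test_brute_force_sum_and_count_bound(self, rng):
        net = star_network(5)
        fps = {f"d{i}": random_fp(rng) for i in range(5)}
        prof = build_profile(net, fps, "t")
        manual = np.zeros(FP_LENGTH, dtype=np.int64)
        for i in range(5):
            for pos in range(FP_LENGTH):
                manual[pos] += int(fps[f"d{i}"].bits[pos])
        assert np.array_equal(prof.counts, manual)
        assert prof.counts.max() <= prof.x
        assert prof.counts[0] == 0

    def test_exclusion_removes_contribution(self, rng):
        net = star_network(3)
        fps = {f"d{i}": random_fp(rng) for i in range(3)}
        full = build_profile(net, fps, "t")
        loo = build_profile(net, fps, "t", exclude_drug="d1")
        assert np.array_equal(full.counts - fps["d1"].bits, loo.counts)
        assert "d1" not in loo.member_ids


class TestCosineScore:
    def _profile(self, counts):
        arr = np.zeros(FP_LENGTH, dtype=np.int64)
        arr[1: 1 + len(counts)] = counts
        from csln.scoring import TargetProfile

        return TargetProfile(target_id="t", counts=arr, member_ids=("a", "b"))

    def test_standard_hand_arithmetic(self):
        # counts (2,1), query bits (1,1): 3 / (sqrt(5) * sqrt(2))
        prof = self._profile([2, 1])
        q = make_fp({1, 2})
        assert cosine_score(prof, q, "standard") == pytest.approx(
            3 / (np.sqrt(5) * np.sqrt(2)), abs=1e-12
        )

    def test_literal_hand_arithmetic_exceeds_one(self):
        # same vectors, literal denominator sqrt(3)*sqrt(2): value > 1
        prof = self._profile([2, 1])
        q = make_fp({1, 2})
        val = cosine_score(prof, q, "paper_literal")
        assert val == pytest.approx(3 / (np.sqrt(3) * np.sqrt(2)), abs=1e-12)
        assert val > 1.0

    def test_scaled_copies_give_one(self, rng):
        q = random_fp(rng)
        from csln.scoring import TargetProfile

        prof = TargetProfile(
            target_id="t", counts=q.bits.astype(np.int64) * 7, member_ids=tuple("ab")
        )
        assert cosine_score(prof, q, "standard") == pytest.approx(1.0, abs=1e-12)

    def test_zero_vectors_score_zero(self):
        prof = self._profile([0])
        assert cosine_score(prof, make_fp({5}), "standard") == 0.0
        assert cosine_score(self._profile([1]), make_fp(set()), "paper_literal") == 0.0

    def test_standard_bounded_literal_not(self, rng):
        """On random member sets: standard stays in [0,1], literal can leave."""
        exceeded = False
        for _ in range(200):
            q_bits = random_fp(rng).bits
            flips = rng.random((4, FP_LENGTH)) < 0.05
            members = np.where(flips, 1 - q_bits, q_bits).astype(np.uint8)
            members[:, 0] = 0
            counts = members.sum(axis=0).astype(np.int64)
            from csln.scoring import TargetProfile

            prof = TargetProfile(target_id="t", counts=counts, member_ids=tuple("abcd"))
            q = Fingerprint(bits=q_bits, molecule_id="q")
            std = cosine_score(prof, q, "standard")
            lit = cosine_score(prof, q, "paper_literal")
            assert 0.0 <= std <= 1.0 + 1e-12
            if lit > 1.0:
                exceeded = True
        assert exceeded

    def test_unknown_variant_rejected(self):
        with pytest.raises(DataError, match="variant"):
            cosine_score(self._profile([1]), make_fp({1}), "bogus")


class TestLocalSimilarityRatio:
    def test_identical_clique_is_unity(self):
        net = star_network(3)
        fp = make_fp({1, 2, 3})
        fps = {f"d{i}": fp for i in range(3)}
        s1, s2, ratio = local_similarity_ratio(net, fps, "t", fp)
        assert (s1, s2, ratio) == (1.0, 1.0, 1.0)

    def test_two_member_pair_enumeration(self):
        # all three pairwise Tanimoto values are exactly 0.5
        net = star_network(2)
        fps = {"d0": make_fp({1, 2, 3}), "d1": make_fp({2, 3, 4})}
        query = make_fp({2, 3, 5})
        s1, s2, ratio = local_similarity_ratio(net, fps, "t", query)
        assert s1 == pytest.approx(0.5)
        assert s2 == pytest.approx(1.5 / 3)
        assert ratio == pytest.approx(1.0)

    def test_query_lifts_ratio_above_one(self):
        # TN(d0,d1)=0.2; query is the union, TN to each member 0.6
        net = star_network(2)
        fps = {"d0": make_fp({1, 2, 3}), "d1": make_fp({3, 4, 5})}
        query = make_fp({1, 2, 3, 4, 5})
        s1, s2, ratio = local_similarity_ratio(net, fps, "t", query)
        assert s1 == pytest.approx(0.2)
        assert s2 == pytest.approx((0.2 + 0.6 + 0.6) / 3)
        assert ratio == pytest.approx(s2 / 0.2)
        assert ratio > 1.0

    def test_degenerate_local_network(self):
        net = star_network(2)
        fps = {"d0": make_fp({1}), "d1": make_fp({2})}
        with pytest.raises(DegenerateLocalNetworkError):
            local_similarity_ratio(net, fps, "t", make_fp({3}))

    def test_algebraic_identity(self, rng):
        """s2*x(x+1)/2 - s1*x(x-1)/2 equals the query-to-member Tanimoto sum."""
        for _ in range(100):
            x = int(rng.integers(2, 8))
            net = star_network(x)
            fps = {f"d{i}": random_fp(rng, density=0.3) for i in range(x)}
            query = random_fp(rng, density=0.3)
            try:
                s1, s2, _ = local_similarity_ratio(net, fps, "t", query)
            except DegenerateLocalNetworkError:
                continue
            lhs = s2 * x * (x + 1) / 2 - s1 * x * (x - 1) / 2
            rhs = sum(tanimoto(fps[f"d{i}"], query) for i in range(x))
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestBindingScore:
    @pytest.mark.parametrize(
        "w1,s_cos,ratio,expected",
        [(1.0, 0.7, 9.9, 0.7), (0.0, 0.7, 9.9, 9.9), (0.5, 0.8, 1.2, 1.0)],
    )
    def test_affine_combination(self, w1, s_cos, ratio, expected):
        assert binding_score(s_cos, ratio, w1) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_w1_out_of_range(self, bad):
        with pytest.raises(DataError, match="w1"):
            binding_score(0.5, 0.5, bad)

    def test_monotone_in_both_components(self, rng):
        for _ in range(50):
            w1 = float(rng.random())
            s, r = float(rng.random()), float(rng.random() * 3)
            eps = 0.01
            assert binding_score(s + eps, r, w1) >= binding_score(s, r, w1)
            assert binding_score(s, r + eps, w1) >= binding_score(s, r, w1)


def brute_force_screen(net, fps, query, model):
    """Independent recomputation of every target's score via the public ops."""
    out = []
    for t in net.target_ids:
        try:
            prof = build_profile(net, fps, t, exclude_drug=query.molecule_id or None)
            if prof.x < model.theta:
                continue
            s1, s2, ratio = local_similarity_ratio(
                net, fps, t, query, exclude_drug=query.molecule_id or None
            )
        except (UnscoreableTargetError, DegenerateLocalNetworkError):
            continue
        s_cos = cosine_score(prof, query, model.cosine_variant)
        out.append((t, binding_score(s_cos, ratio, model.w1)))
    out.sort(key=lambda r: (-r[1], r[0]))
    return out


class TestScreen:
    def test_dominant_target_ranked_first(self):
        # target A: clique identical to query; target B: disjoint bits
        adjacency = np.array(
            [[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.uint8
        )
        net = DTINetwork(("a1", "a2", "b1", "b2"), ("A", "B"), adjacency)
        q = make_fp({1, 2, 3}, molecule_id="query")
        fps = {
            "a1": make_fp({1, 2, 3}),
            "a2": make_fp({1, 2, 3}),
            "b1": make_fp({100, 101}),
            "b2": make_fp({100, 101}),
        }
        for w1 in (0.0, 0.3, 1.0):
            res = screen(net, fps, q, CSLNModel(w1=w1, theta=2))
            assert res[0].target_id == "A"
            assert res[0].rank == 1

    def test_matches_brute_force_on_random_networks(self, rng):
        for trial in range(100):
            spec = SyntheticSpec(
                n_targets=int(rng.integers(2, 6)),
                members_per_target=(2, 5),
                n_decoy_drugs=3,
                flip_rate=0.1,
                overlap_rate=0.2,
                seed=int(rng.integers(1 << 30)),
            )
            net, fps, _ = generate(spec)
            query = random_fp(rng, molecule_id="fresh")
            model = CSLNModel(w1=float(rng.random()), theta=2)
            got = screen(net, fps, query, model)
            expected = brute_force_screen(net, fps, query, model)
            assert [(r.target_id, r.rank) for r in got] == [
                (t, k + 1) for k, (t, _) in enumerate(expected)
            ]
            for r, (t, score) in zip(got, expected):
                assert r.score == pytest.approx(score, abs=1e-12)
                assert r.score == pytest.approx(
                    model.w1 * r.s_cos + (1 - model.w1) * r.ratio, abs=1e-12
                )

    def test_tie_broken_by_target_id(self):
        # two identical targets score identically; order must be by id
        adjacency = np.array([[1, 1], [1, 1]], dtype=np.uint8)
        net = DTINetwork(("d0", "d1"), ("zeta", "alpha"), adjacency)
        fp = make_fp({1, 2})
        fps = {"d0": fp, "d1": fp}
        res = screen(net, fps, make_fp({1, 2}, molecule_id="q"), CSLNModel(w1=0.5, theta=2))
        assert [r.target_id for r in res] == ["alpha", "zeta"]

    def test_no_leakage_from_query_row(self, rng):
        """Scores identical whether the query's edges are pre-deleted or
        excluded on the fly."""
        spec = SyntheticSpec(n_targets=4, members_per_target=4, seed=11)
        net, fps, _ = generate(spec)
        query_drug = "T0_D0"
        from csln.network import remove_drug

        pre_deleted, _, _ = remove_drug(net, query_drug)
        model = CSLNModel(w1=0.4, theta=2)
        res_excluded = screen(net, fps, fps[query_drug], model)
        res_deleted = screen(pre_deleted, fps, fps[query_drug], model)
        kept = {r.target_id for r in res_deleted}
        assert [
            (r.target_id, r.score) for r in res_excluded if r.target_id in kept
        ] == [(r.target_id, r.score) for r in res_deleted]

    def test_top_k_truncation(self, rng):
        spec = SyntheticSpec(n_targets=6, members_per_target=3, seed=5)
        net, fps, _ = generate(spec)
        q = random_fp(rng, molecule_id="fresh")
        model = CSLNModel(w1=0.5, theta=2)
        assert len(screen(net, fps, q, model, top_k=2)) == 2

    def test_empty_result_when_nothing_scoreable(self, caplog):
        net = star_network(1)
        res = screen(
            net, {"d0": make_fp({1})}, make_fp({1}, molecule_id="q"),
            CSLNModel(w1=0.5, theta=2),
        )
        assert res == []

    def test_normalize_ratio_flag(self, rng):
        spec = SyntheticSpec(n_targets=4, members_per_target=4, seed=9)
        net, fps, _ = generate(spec)
        q = random_fp(rng, molecule_id="fresh")
        res = screen(net, fps, q, CSLNModel(w1=0.5, theta=2), normalize_ratio=True)
        ratios = [r.ratio for r in res]
        assert min(ratios) >= 0.0 and max(ratios) <= 1.0
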