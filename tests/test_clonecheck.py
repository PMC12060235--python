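"""Clonal identity verification, Nei distance and MLG collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pinebreed import GenotypeMatrix, MISSING, clonecheck, syndata


def brute_nei(x_dos, y_dos):
    """Nei standard distance between two imputed dosage vectors (oracle)."""
    sxy = sxx = syy = 0.0
    for dx, dy in zip(x_dos, y_dos):
        x = (dx / 2, 1 - dx / 2)
        y = (dy / 2, 1 - dy / 2)
        sxy += x[0] * y[0] + x[1] * y[1]
        sxx += x[0] ** 2 + x[1] ** 2
        syy += y[0] ** 2 + y[1] ** 2
    return -np.log(sxy / np.sqrt(sxx * syy))


def brute_complete_linkage(dist, threshold):
    """Exhaustive-enumeration oracle: finest partition into cliques whose
    max internal distance <= threshold, built by greedy agglomeration over
    all pairs (equivalent to complete linkage for well-separated data)."""
    n = dist.shape[0]
    best = None
    # enumerate all partitions of n items (n <= 7)
    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [block + [first]] + part[i + 1 :]
            yield [[first]] + part
    for part in partitions(list(range(n))):
        if all(
            dist[i, j] <= threshold for block in part for i, j in itertools.combinations(block, 2)
        ):
            if best is None or len(part) < len(best):
                best = part
    return best


class TestMismatch:
    def test_identical_and_empty(self):
        a = np.array([0, 1, 2, MISSING])
        assert clonecheck.mismatch_count(a, a) == (0, 3)
        allmiss = np.full(4, MISSING)
        assert clonecheck.mismatch_count(allmiss, a) == (0, 0)

    def test_hand_count(self):
        a = np.array([0, 1, 2, MISSING, 2])
        b = np.array([0, 2, 2, 1, 0])
        assert clonecheck.mismatch_count(a, b) == (2, 4)
        # allele-level: |1-2| + |2-0| = 3
        assert clonecheck.mismatch_count(a, b, allele_level=True) == (3, 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clonecheck.mismatch_count(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_zero_iff_concordant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.choice([0, 1, 2, MISSING], size=30)
        b = rng.choice([0, 1, 2, MISSING], size=30)
        mm_ab = clonecheck.mismatch_count(a, b)
        mm_ba = clonecheck.mismatch_count(b, a)
        assert mm_ab == mm_ba
        both = (a != MISSING) & (b != MISSING)
        assert (mm_ab[0] == 0) == bool((a[both] == b[both]).all())


class TestConsensus:
    def test_single_member_and_majority(self):
        calls = np.array([[1, 0, 0], [1, 0, 2], [1, 2, 2], [2, 2, MISSING]])
        g = GenotypeMatrix(["a", "b", "c", "d"], ["L1", "L2", "L3"], calls)
        cons, support = clonecheck.build_consensus(g, ["a"])
        np.testing.assert_array_equal(cons, calls[0])
        cons, support = clonecheck.build_consensus(g, ["a", "b", "c", "d"])
        assert cons[0] == 1 and support[0] == 3
        assert cons[1] == MISSING  # 2-2 tie -> no call invented
        assert cons[2] == 2 and support[2] == 2

    def test_all_missing_locus(self):
        g = GenotypeMatrix(["a", "b"], ["L1"], np.full((2, 1), MISSING))
        cons, _ = clonecheck.build_consensus(g, ["a", "b"])
        assert cons[0] == MISSING

    def test_unknown_member(self, tiny_matrix):
        with pytest.raises(KeyError):
            clonecheck.build_consensus(tiny_matrix, ["nope"])


def _registry(meta_rows):
    return clonecheck.CloneRegistry.from_metadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "clone_id", "region", "registered"])
    )


class TestVerify:
    def test_threshold_edge(self):
        """A ramet just over the error threshold is excluded; one at it is kept."""
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 1000).astype(np.int8)
        ramets = np.stack([base] * 4)
        ramets[3, :30] = (ramets[3, :30] + 1) % 3  # 3% discordant
        g = GenotypeMatrix([f"r{i}" for i in range(4)], [f"L{j}" for j in range(1000)], ramets)
        reg = _registry([(f"r{i}", "c1", "ES1", True) for i in range(4)])
        reports, reg = clonecheck.verify_ramets(g, reg, error_threshold=0.025)
        assert reports.set_index("sample_id")["excluded"].tolist() == [False, False, False, True]
        assert reg.clones["c1"].retained == ["r0", "r1", "r2"]

    def test_idempotent_fixed_point(self, small_dataset):
        g, meta = small_dataset.ramets, small_dataset.sample_meta
        reports, reg = clonecheck.verify_ramets(g, clonecheck.CloneRegistry.from_metadata(meta))
        kept = reports.loc[~reports["excluded"], "sample_id"]
        meta2 = meta[meta["sample_id"].isin(kept)]
        reports2, _ = clonecheck.verify_ramets(
            g.subset(samples=list(kept)), clonecheck.CloneRegistry.from_metadata(meta2)
        )
        assert not reports2["excluded"].any()

    def test_mislabels_flagged_on_synthetic_cohort(self, small_dataset):
        reports, _ = clonecheck.verify_ramets(
            small_dataset.ramets,
            clonecheck.CloneRegistry.from_metadata(small_dataset.sample_meta),
        )
        mislabelled = {s for s, _ in small_dataset.truth.mislabelled_samples}
        excluded = set(reports.loc[reports["excluded"], "sample_id"])
        assert mislabelled <= excluded

    def test_unverifiable_clone_flagged(self):
        g = GenotypeMatrix(["a", "b"], ["L1", "L2"],
                           np.array([[0, 0], [2, 2]], dtype=np.int8))
        reg = _registry([("a", "c1", "ES1", True), ("b", "c1", "ES1", True)])
        # consensus is all-MISSING ties -> rates undefined -> retained;
        # force exclusion with a third discordant sample
        g2 = GenotypeMatrix(
            ["a", "b", "c"], ["L1", "L2"],
            np.array([[0, 0], [0, 0], [2, 2]], dtype=np.int8),
        )
        reg2 = _registry([(s, "c1", "ES1", True) for s in ("a", "b", "c")])
        reports, reg2 = clonecheck.verify_ramets(g2, reg2, error_threshold=0.1)
        assert reports.set_index("sample_id").loc["c", "excluded"]


class TestSnpErrorRates:
    def test_hand_count(self):
        base = np.zeros(4, dtype=np.int8)
        calls = np.stack([base, base, base])
        calls[2, 1] = 1  # one discordant call at locus L2
        g = GenotypeMatrix(["a", "b", "c"], ["L1", "L2", "L3", "L4"], calls)
        reg = _registry([(s, "c1", "ES1", True) for s in ("a", "b", "c")])
        _, reg = clonecheck.verify_ramets(g, reg, error_threshold=0.5)
        rates = clonecheck.snp_error_rates(g, reg)
        assert rates.loc["L2", "error_rate"] == pytest.approx(1 / 3)
        assert rates.loc["L1", "error_rate"] == 0.0

    def test_noise_free_cohort_all_zero(self, small_cfg):
        cfg = syndata.SimConfig(**{
            **small_cfg.__dict__,
            "geno_error_rate": 0.0, "missing_rate": 0.0, "mislabel_rate": 0.0,
        })
        ds = syndata.simulate_dataset(cfg)
        reports, reg = clonecheck.verify_ramets(
            ds.ramets, clonecheck.CloneRegistry.from_metadata(ds.sample_meta)
        )
        rates = clonecheck.snp_error_rates(ds.ramets, reg)
        assert (rates.loc[rates["defined"], "error_rate"] == 0).all()


class TestNeiDistance:
    def test_identity_and_symmetry(self, tiny_matrix):
        d = clonecheck.nei_distance_matrix(tiny_matrix)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        np.testing.assert_allclose(d, d.T, atol=1e-15)

    def test_matches_formula_oracle(self):
        calls = np.array(
            [[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 0, 2]], dtype=np.int8
        )
        g = GenotypeMatrix(list("abcd"), ["L1", "L2", "L3"], calls)
        d = clonecheck.nei_distance_matrix(g)
        dos = calls.astype(float)
        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(brute_nei(dos[i], dos[j]), abs=1e-12)

    def test_missing_replaced_by_locus_mean(self):
        calls = np.array([[0, MISSING], [2, 2], [0, 0]], dtype=np.int8)
        g = GenotypeMatrix(list("abc"), ["L1", "L2"], calls)
        d = clonecheck.nei_distance_matrix(g)
        imputed = np.array([[0.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
        assert d[0, 1] == pytest.approx(brute_nei(imputed[0], imputed[1]), abs=1e-12)


class TestMLG:
    def test_degenerate_thresholds(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, (5, 40)).astype(np.int8)
        g = GenotypeMatrix([f"s{i}" for i in range(5)], [f"L{j}" for j in range(40)], calls)
        d = clonecheck.nei_distance_matrix(g)
        assert clonecheck.collapse_mlg(d, 0.0).n_lineages == 5
        assert clonecheck.collapse_mlg(d, float(d.max()) + 1).n_lineages == 1
        with pytest.raises(ValueError):
            clonecheck.collapse_mlg(d, -0.1)

    def test_two_triplets_match_enumeration_oracle(self):
        # two tight triplets: within <= 0.01, between >= 0.3
        d = np.zeros((6, 6))
        within = [(0, 1, 0.008), (0, 2, 0.01), (1, 2, 0.006),
                  (3, 4, 0.007), (3, 5, 0.009), (4, 5, 0.01)]
        for i, j, v in within:
            d[i, j] = d[j, i] = v
        for i in range(3):
            for j in range(3, 6):
                d[i, j] = d[j, i] = 0.3 + 0.01 * (i + j)
        res = clonecheck.collapse_mlg(d, 0.05)
        assert res.n_lineages == 2
        oracle = brute_complete_linkage(d, 0.05)
        assert len(oracle) == 2
        blocks = {frozenset(b) for b in oracle}
        got = {
            frozenset(np.flatnonzero(res.assignment.to_numpy() == lab))
            for lab in res.assignment.unique()
        }
        assert {frozenset(map(int, b)) for b in got} == blocks

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_lineage_count_weakly_decreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        counts = [
            clonecheck.collapse_mlg(d, t).n_lineages
            for t in np.linspace(0, d.max() * 1.1, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPredictCutoff:
    def test_gap_midpoint_by_hand(self):
        ds = np.array([0.01, 0.02, 0.03, 0.40, 0.41])
        t = clonecheck.predict_cutoff(ds)
        assert 0.03 < t < 0.40
        assert t == pytest.approx(0.215)
        assert clonecheck.predict_cutoff(np.array([0.1, 0.9])) == pytest.approx(0.5)

    def test_no_gap_rejected(self):
        with pytest.raises(ValueError):
            clonecheck.predict_cutoff(np.array([0.2, 0.2, 0.2]))
        with pytest.raises(ValueError):
            clonecheck.predict_cutoff(np.array([0.2]))

    def test_separates_clones_on_synthetic_cohorts(self):
        """Predicted cutoff splits within-clone from between-clone distances."""
        hits = 0
        for seed in range(20):
            cfg = syndata.SimConfig(
                n_loci=600, regions={"ES1": 5, "ES2": 5, "ES3": 5, "ES6": 5},
                n_registered=10, ramets_per_registered=(3, 4),
                mislabel_rate=0.0, seed=500 + seed,
            )
            ds = syndata.simulate_dataset(cfg)
            dist = clonecheck.nei_distance_matrix(ds.ramets)
            base = clonecheck.collapse_mlg(dist, 0.0, ds.ramets.sample_ids)
            cutoff = clonecheck.predict_cutoff(base.merge_distances)
            clone_of = ds.sample_meta.set_index("sample_id")["clone_id"]
            ids = ds.ramets.sample_ids
            within, between = [], []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    (within if clone_of[ids[i]] == clone_of[ids[j]] else between).append(
                        dist[i, j]
                    )
            hits += max(within) < cutoff < min(between)
        assert hits >= 18
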