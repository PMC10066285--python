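"""7-mer scoring: normalization, trimmed means vs a naive oracle, robust Z."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpkit.kmers import KmerUniverse, code_to_kmer, kmer_to_code
from rbpkit.scoring import (
    IntensityProfile,
    ab_diagnostics,
    bonferroni_tail,
    compute_kmer_zscores,
    normalize_intensities,
    score_experiment,
    zscore_table_tsv,
)

from conftest import present_kmer_universe, random_probe_pool


def make_profile(pool, values, usable=None):
    n = len(pool)
    if usable is None:
        usable = np.ones(n, dtype=bool)
    return IntensityProfile(list(pool.ids), np.asarray(values, float), usable)


def naive_scores(pool, profile, universe, subset, trim):
    """Independent oracle: substring scan + sorted-slice trimmed mean."""
    mask = pool.subset_mask(subset)
    vals = dict(zip(profile.probe_ids, profile.values))
    scores = []
    for code in universe.member_codes:
        w = code_to_kmer(int(code), universe.k)
        obs = sorted(
            vals[pid]
            for pid, seq, m in zip(pool.ids, pool.sequences, mask)
            if m and pid in vals and w in seq
        )
        t = int(np.floor(len(obs) * trim))
        kept = obs[t : len(obs) - t]
        scores.append(sum(kept) / len(kept))
    scores = np.array(scores)
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    scale = 1.4826 * mad if mad > 0 else scores.std()
    z = (scores - med) / scale if scale > 0 else np.zeros_like(scores)
    return scores, z


class TestNormalize:
    def test_constant_intensities_become_zero(self):
        rng = np.random.default_rng(0)
        pool = random_probe_pool(rng, 8)
        prof = make_profile(pool, np.full(8, 37.5))
        out = normalize_intensities(prof)
        assert np.allclose(out.values, 0.0)

    def test_excluded_probe_dropped(self):
        rng = np.random.default_rng(1)
        pool = random_probe_pool(rng, 5)
        usable = np.array([True, True, False, True, True])
        out = normalize_intensities(make_profile(pool, np.arange(1.0, 6.0), usable))
        assert pool.ids[2] not in out.probe_ids
        assert len(out) == 4

    def test_all_excluded_errors(self):
        rng = np.random.default_rng(2)
        pool = random_probe_pool(rng, 3)
        with pytest.raises(ValueError, match="excluded"):
            normalize_intensities(make_profile(pool, [1, 2, 3], np.zeros(3, bool)))

    @given(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=50, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_preserving_and_median_zero(self, values):
        ids = [f"p{i}" for i in range(len(values))]
        prof = IntensityProfile(ids, np.array(values), np.ones(len(values), bool))
        out = normalize_intensities(prof)
        # rank-preserving up to float collapse of near-identical inputs
        for i in range(len(values)):
            for j in range(len(values)):
                if values[i] < values[j]:
                    assert out.values[i] <= out.values[j]
        assert abs(np.median(out.values)) < 1e-12


class TestZScores:
    @pytest.mark.parametrize("k,subset", [(3, "merged"), (3, "A"), (7, "merged")])
    def test_matches_naive_oracle(self, k, subset):
        rng = np.random.default_rng(10 + k)
        pool = random_probe_pool(rng, n_probes=40, min_len=25, max_len=35)
        universe = present_kmer_universe(pool, k)
        prof = make_profile(pool, rng.lognormal(4, 1, len(pool)))
        norm = normalize_intensities(prof)
        table = compute_kmer_zscores(norm, pool, subset, universe, trim_fraction=0.025)
        exp_scores, exp_z = naive_scores(pool, norm, universe, subset, 0.025)
        assert np.allclose(table.scores, exp_scores, atol=1e-12)
        assert np.allclose(table.zscores, exp_z, atol=1e-12)

    def test_degenerate_all_zero(self):
        rng = np.random.default_rng(3)
        pool = random_probe_pool(rng, 10)
        universe = present_kmer_universe(pool, 3)
        prof = IntensityProfile(
            list(pool.ids), np.zeros(10), np.ones(10, bool), normalized=True
        )
        table = compute_kmer_zscores(prof, pool, "merged", universe)
        assert np.allclose(table.scores, 0) and np.allclose(table.zscores, 0)

    def test_unique_kmers_of_raised_probe_attain_max_z(self):
        rng = np.random.default_rng(4)
        pool = random_probe_pool(rng, 10, min_len=20, max_len=20)
        universe = present_kmer_universe(pool, 4)
        values = np.zeros(10)
        values[0] = 5.0
        prof = IntensityProfile(
            list(pool.ids), values, np.ones(10, bool), normalized=True
        )
        table = compute_kmer_zscores(prof, pool, "merged", universe, trim_fraction=0.0)
        others = "".join(pool.sequences[1:])
        s0 = pool.sequences[0]
        unique = {
            s0[i : i + 4] for i in range(17) if s0[i : i + 4] not in others
        }
        assert unique, "toy construction should leave some unique 4-mers"
        zmax = table.zscores.max()
        for w in unique:
            assert table.z(w) == pytest.approx(zmax)

    def test_median_and_mad_invariants(self):
        rng = np.random.default_rng(5)
        pool = random_probe_pool(rng, 30)
        universe = present_kmer_universe(pool, 3)
        prof = normalize_intensities(make_profile(pool, rng.lognormal(4, 1, 30)))
        z = compute_kmer_zscores(prof, pool, "merged", universe).zscores
        assert abs(np.median(z)) < 1e-9
        assert abs(1.4826 * np.median(np.abs(z - np.median(z))) - 1.0) < 1e-9

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(6)
        pool = random_probe_pool(rng, 20)
        universe = present_kmer_universe(pool, 3)
        values = rng.lognormal(4, 1, 20)
        norm = normalize_intensities(make_profile(pool, values))
        t1 = compute_kmer_zscores(norm, pool, "merged", universe)
        perm = rng.permutation(20)
        pool2 = type(pool)(
            [pool.ids[i] for i in perm],
            [pool.sequences[i] for i in perm],
            pool.set_labels[perm],
        )
        t2 = compute_kmer_zscores(norm, pool2, "merged", universe)
        assert np.allclose(t1.scores, t2.scores)
        assert np.allclose(t1.zscores, t2.zscores)

    def test_missing_kmer_support_errors(self):
        pool = random_probe_pool(np.random.default_rng(7), 5)
        universe = KmerUniverse(k=7)  # full universe cannot be supported
        prof = normalize_intensities(make_profile(pool, np.arange(1.0, 6.0)))
        with pytest.raises(ValueError, match="no supporting probe"):
            compute_kmer_zscores(prof, pool, "merged", universe)


class TestBonferroni:
    def test_symmetry_point(self):
        assert bonferroni_tail(0.0, 1) == pytest.approx(0.5)

    def test_z5_over_universe_below_printed_bound(self):
        assert bonferroni_tail(5.0, 16_382) < 0.005

    def test_cap_at_one(self):
        assert bonferroni_tail(-np.inf, 3) == 1.0
        assert bonferroni_tail(-2.0, 10) == 1.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bonferroni_tail(1.0, 0)


class TestAbDiagnostics:
    def _table(self, pool, universe, values):
        prof = IntensityProfile(
            list(pool.ids), values, np.ones(len(pool), bool), normalized=True
        )
        return compute_kmer_zscores(prof, pool, "merged", universe)

    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(8)
        pool = random_probe_pool(rng, 20)
        universe = present_kmer_universe(pool, 3)
        t = self._table(pool, universe, rng.normal(0, 1, 20))
        r, overlap = ab_diagnostics(t, t)
        assert r == pytest.approx(1.0)
        assert overlap == 10
        neg = self._table(pool, universe, -np.array(
            [v for v in rng.normal(0, 1, 20)]
        ))
        # negate the table directly for exact antisymmetry
        import dataclasses

        t_neg = dataclasses.replace(t, scores=-t.scores, zscores=-t.zscores)
        r2, _ = ab_diagnostics(t, t_neg)
        assert r2 == pytest.approx(-1.0)

    def test_universe_mismatch_errors(self):
        rng = np.random.default_rng(9)
        pool = random_probe_pool(rng, 20)
        u3 = present_kmer_universe(pool, 3)
        u2 = present_kmer_universe(pool, 2)
        t3 = self._table(pool, u3, rng.normal(0, 1, 20))
        t2 = self._table(pool, u2, rng.normal(0, 1, 20))
        with pytest.raises(ValueError, match="universe"):
            ab_diagnostics(t3, t2)


def test_score_experiment_and_tsv(tmp_path):
    rng = np.random.default_rng(11)
    pool = random_probe_pool(rng, 30)
    # restrict to 3-mers so the toy pool supports the whole universe
    universe = present_kmer_universe(pool, 3)
    prof = make_profile(pool, rng.lognormal(4, 0.5, 30))
    tables = score_experiment(prof, pool, universe)
    assert set(tables) == {"A", "B", "merged"}
    out = tmp_path / "z.tsv"
    zscore_table_tsv(tables, out)
    import pandas as pd

    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["kmer", "scoreA", "zA", "scoreB", "zB", "zMerged"]
    assert (df["zMerged"].diff().dropna() <= 1e-12).all()  # sorted descending
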