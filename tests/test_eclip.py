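"""eCLIP peak preparation, 5-mer profiling, clustering, IUPAC rank."""

import numpy as np
import pytest

from rbpkit.eclip import (
    PeakSet,
    correlate_and_cluster,
    count_5mers,
    iupac_rank,
    linkage_to_newick,
    prepare_priesstess_inputs,
    revcomp,
    write_fasta,
)


@pytest.fixture(scope="module")
def genome(tmp_path_factory):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    path.write_text(f">chr1\n{seq}\n>chr2\n{seq[:1000]}\n")
    return path, seq


class TestPrepareInputs:
    def test_plus_strand_coordinates(self, genome):
        path, seq = genome
        peaks = PeakSet([("chr1", 1000, 1010, "+")], experiment_id="e1")
        pos, neg, dropped = prepare_priesstess_inputs(peaks, str(path))
        assert dropped == 0
        p, n = pos[0], neg[0]
        # core extended 20 nt upstream; context adds 50-nt flanks
        assert (p.start, p.end) == (980, 1010)
        assert p.core == seq[980:1010]
        assert p.with_context == seq[930:1060]
        # negative: same-size window 300 nt upstream of the extended peak
        assert (n.start, n.end) == (680, 710)
        assert n.core == seq[680:710]

    def test_negative_matches_extended_length(self, genome):
        path, _ = genome
        for length in (10, 35, 60):
            peaks = PeakSet([("chr1", 2000, 2000 + length, "+")])
            pos, neg, _ = prepare_priesstess_inputs(peaks, str(path))
            assert len(neg[0].core) == length + 20
            assert len(pos[0].core) == length + 20

    def test_minus_strand_reverse_complement(self, genome):
        path, seq = genome
        peaks = PeakSet([("chr1", 1200, 1230, "-")])
        pos, neg, _ = prepare_priesstess_inputs(peaks, str(path))
        # upstream is the high-coordinate side on the minus strand
        assert pos[0].core == revcomp(seq[1200:1250])
        assert neg[0].core == revcomp(seq[1500:1550])

    def test_out_of_bounds_dropped_and_counted(self, genome):
        path, _ = genome
        peaks = PeakSet(
            [("chr1", 5, 15, "+"), ("chr1", 1000, 1010, "+"), ("chr1", 4995, 4999, "-")]
        )
        pos, neg, dropped = prepare_priesstess_inputs(peaks, str(path))
        assert dropped == 2
        assert len(pos) == len(neg) == 1

    def test_missing_chrom_errors(self, genome):
        path, _ = genome
        peaks = PeakSet([("chrX", 1000, 1010, "+")])
        with pytest.raises(KeyError, match="chrX"):
            prepare_priesstess_inputs(peaks, str(path))

    def test_negative_never_overlaps_positive_for_short_peaks(self, genome):
        path, _ = genome
        rng = np.random.default_rng(1)
        intervals = [
            ("chr1", int(s), int(s) + int(l), "+")
            for s, l in zip(rng.integers(500, 4000, 20), rng.integers(10, 200, 20))
        ]
        peaks = PeakSet(intervals)
        pos, neg, _ = prepare_priesstess_inputs(peaks, str(path))
        for p, n in zip(pos, neg):
            if (p.end - p.start) <= 300:  # peak + 20 <= offset
                assert n.end <= p.start or n.start >= p.end

    def test_bed_parsing_and_fasta_output(self, genome, tmp_path):
        path, _ = genome
        bed = tmp_path / "peaks.bed"
        bed.write_text("chr1\t1000\t1010\tpeak1\t100\t+\nchr1\t1200\t1230\tpeak2\t50\t-\n")
        peaks = PeakSet.from_bed(bed, experiment_id="exp")
        assert len(peaks) == 2
        pos, neg, _ = prepare_priesstess_inputs(peaks, str(path))
        out = tmp_path / "pos.fa"
        write_fasta(pos, out)
        assert out.read_text().count(">") == 2

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            PeakSet([("chr1", 10, 10, "+")])
        with pytest.raises(ValueError):
            PeakSet([("chr1", 10, 20, "*")])


class TestCount5mers:
    def test_hand_counts(self):
        freq = count_5mers(["AAAAAA"])
        assert freq[0] == 1.0  # AAAAA is code 0, two windows, freq 1
        freq2 = count_5mers(["ACGTACGTA"])
        # 5 windows total, ACGUA appears twice
        from rbpkit.kmers import kmer_to_code

        assert freq2[kmer_to_code("ACGUA")] == pytest.approx(2 / 5)
        assert freq2.sum() == pytest.approx(1.0)

    def test_concatenation_invariance(self):
        a, b = "ACGTACGTAC", "GGGTTTACGT"
        from rbpkit.kmers import count_kmers

        sep = count_kmers([a, b], 5)
        assert sep.sum() == (len(a) - 4) + (len(b) - 4)

    def test_ambiguous_windows_skipped(self):
        from rbpkit.kmers import count_kmers

        # N poisons every window that overlaps it; the clean flanks count
        counts = count_kmers(["AAAAANCCCCC"], 5)
        assert counts.sum() == 2  # one AAAAA window + one CCCCC window
        freq = count_5mers(["AAAAANCCCCC"])
        assert freq[0] == pytest.approx(0.5)

    def test_no_windows_errors(self):
        with pytest.raises(ValueError, match="countable"):
            count_5mers(["ACGT", "NNNNNNN"])


def bruteforce_centroid_linkage(dist):
    """Independent Lance-Williams centroid agglomeration oracle.

    Operates on squared distances: d(k, i+j)^2 =
    (ni*d(k,i)^2 + nj*d(k,j)^2)/(ni+nj) - ni*nj*d(i,j)^2/(ni+nj)^2.
    Merges the globally closest pair at each step.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = {i: (i, 1) for i in range(n)}  # cluster id -> (index, size)
    cur = {i: {i} for i in range(n)}
    d2 = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        pair = min(
            (frozenset((a, b)) for i, a in enumerate(ids) for b in ids[i + 1 :]),
            key=lambda fs: (d2[fs], sorted(fs)),
        )
        i, j = sorted(pair)
        dij2 = d2[pair]
        merges.append((set(cur[i]) | set(cur[j]), np.sqrt(max(dij2, 0.0))))
        ni, nj = sizes[i], sizes[j]
        for k in ids:
            if k in (i, j):
                continue
            dik2 = d2[frozenset((i, k))]
            djk2 = d2[frozenset((j, k))]
            new = (ni * dik2 + nj * djk2) / (ni + nj) - ni * nj * dij2 / (ni + nj) ** 2
            d2[frozenset((next_id, k))] = new
        cur[next_id] = cur[i] | cur[j]
        sizes[next_id] = ni + nj
        ids = [k for k in ids if k not in (i, j)] + [next_id]
        next_id += 1
    return merges


class TestClustering:
    def test_duplicate_profiles_merge_first(self):
        rng = np.random.default_rng(2)
        base = rng.dirichlet(np.ones(64))
        other = rng.dirichlet(np.ones(64))
        res = correlate_and_cluster([base, base.copy(), other], min_peaks=0)
        assert res.corr[0, 1] == pytest.approx(1.0)
        # first merge joins the identical pair at distance ~0
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_three_profiles_pair_before_singleton(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet(np.ones(64))
        res = correlate_and_cluster([a, a * 1.0, rng.dirichlet(np.ones(64))], min_peaks=0)
        labels = res.labels
        assert labels[0] == labels[1] != labels[2]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_lance_williams_oracle(self, n):
        rng = np.random.default_rng(10 + n)
        profiles = [rng.dirichlet(np.ones(32)) for _ in range(n)]
        res = correlate_and_cluster(profiles, min_peaks=0)
        dist = 1.0 - res.corr
        np.fill_diagonal(dist, 0.0)
        oracle = bruteforce_centroid_linkage(dist)
        # compare merge heights and merged leaf-sets step by step
        from scipy.cluster.hierarchy import to_tree

        def scipy_merges(Z):
            out = []
            members = {i: {i} for i in range(n)}
            for step, (a, b, h, _) in enumerate(Z):
                merged = members[int(a)] | members[int(b)]
                members[n + step] = merged
                out.append((merged, h))
            return out

        got = scipy_merges(res.linkage)
        for (set_o, h_o), (set_s, h_s) in zip(oracle, got):
            assert set_o == set_s
            assert h_s == pytest.approx(h_o, abs=1e-9)

    def test_peak_filter_and_min_experiments(self):
        rng = np.random.default_rng(4)
        profiles = [rng.dirichlet(np.ones(64)) for _ in range(4)]
        res = correlate_and_cluster(profiles, peak_counts=[2000, 500, 1500, 3000])
        assert res.kept == [0, 2, 3]
        assert res.excluded == [1]
        with pytest.raises(ValueError, match="peak filter"):
            correlate_and_cluster(profiles, peak_counts=[10, 10, 2000, 10])

    def test_order_invariance_up_to_permutation(self):
        rng = np.random.default_rng(5)
        profiles = [rng.dirichlet(np.ones(64)) for _ in range(5)]
        r1 = correlate_and_cluster(profiles, min_peaks=0)
        perm = [4, 2, 0, 3, 1]
        r2 = correlate_and_cluster([profiles[i] for i in perm], min_peaks=0)
        for i in range(5):
            for j in range(5):
                assert r2.corr[i, j] == pytest.approx(r1.corr[perm[i], perm[j]])

    def test_newick_export(self):
        rng = np.random.default_rng(6)
        profiles = [rng.dirichlet(np.ones(64)) for _ in range(3)]
        res = correlate_and_cluster(profiles, min_peaks=0)
        nwk = linkage_to_newick(res.linkage, ["x", "y", "z"])
        assert nwk.endswith(";") and all(n in nwk for n in "xyz")


class TestIupacRank:
    def test_nnnnn_is_rank_one(self):
        rng = np.random.default_rng(7)
        profile = rng.dirichlet(np.ones(1024))
        assert iupac_rank(profile, "NNNNN") == 1

    def test_explicit_pattern_rank(self):
        from rbpkit.kmers import kmer_to_code

        profile = np.zeros(1024)
        profile[kmer_to_code("GUGUG")] = 0.5
        profile[kmer_to_code("AAAAA")] = 0.3
        profile[kmer_to_code("ACGUA")] = 0.2
        assert iupac_rank(profile, "GUGUG") == 1
        assert iupac_rank(profile, "ACGUA") == 3
        # degenerate symbols: KUGUG matches GUGUG (K = G/U)
        assert iupac_rank(profile, "KUGUG") == 1

    def test_longer_iupac_uses_windows(self):
        from rbpkit.kmers import kmer_to_code

        profile = np.zeros(1024)
        profile[kmer_to_code("UGUAA")] = 1.0
        # UGUAHAUA contains window UGUAH which matches UGUAA (H = A/C/U)
        assert iupac_rank(profile, "UGUAHAUA") == 1

    def test_absent_returns_none(self):
        from rbpkit.kmers import kmer_to_code

        profile = np.zeros(1024)
        profile[kmer_to_code("AAAAA")] = 1.0
        # only observed 5-mers are ranked; CCCCC never occurs -> absent
        assert iupac_rank(profile, "CCCCC") is None

    def test_invalid_symbols_and_length(self):
        profile = np.full(1024, 1 / 1024)
        with pytest.raises(ValueError, match="IUPAC"):
            iupac_rank(profile, "ACGUX")
        with pytest.raises(ValueError, match="at least"):
            iupac_rank(profile, "ACG")
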