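"""TIR detection, end homology, motif scan, dot plots and the banded aligner."""

import numpy as np
import pytest

from replichar.io_formats import Replicon, reverse_complement
from replichar.synthetic_data import _mutate_exact
from replichar.terminal_repeats import (banded_align, dotplot_kmers, end_homology,
                                        find_motif, find_tir)


def _random_seq(rng, n, gc=0.5):
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(bases[rng.choice(4, size=n, p=p)])


def _tir_replicon(rng, tir_len=5000, core_len=20000, rate=0.0, gc=0.5):
    """S = L + core + revcomp(L'), L' = L with round(rate*|L|) substitutions.
    The core is pinned to start and end with 'A' so the first alignment
    column beyond the repeat is a guaranteed mismatch."""
    L = _random_seq(rng, tir_len, gc)
    core = "A" + _random_seq(rng, core_len - 2, gc) + "A"
    Lp, k = _mutate_exact(rng, L, rate)
    seq = L + core + reverse_complement(Lp)
    return Replicon(id="t", sequence=seq, topology="linear"), k


class TestBandedAligner:
    def _full_dp_in_band(self, a, b, band):
        """Independent oracle: plain O(nm) edit-distance DP with cells outside
        the band forbidden."""
        n, m = len(a), len(b)
        INF = 10 ** 9
        dp = [[INF] * (m + 1) for _ in range(n + 1)]
        dp[0][0] = 0
        for j in range(1, min(m, band) + 1):
            dp[0][j] = j
        for i in range(1, n + 1):
            for j in range(max(0, i - band), min(m, i + band) + 1):
                best = INF
                if j > 0 and dp[i][j - 1] < INF:
                    best = min(best, dp[i][j - 1] + 1)
                if dp[i - 1][j] < INF:
                    best = min(best, dp[i - 1][j] + 1)
                if j > 0 and dp[i - 1][j - 1] < INF:
                    best = min(best, dp[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
                dp[i][j] = best
        return dp[n][m]

    @pytest.mark.parametrize("n,band", [(150, 10), (400, 25), (900, 50)])
    def test_cost_matches_full_dp_oracle(self, rng, n, band):
        a = _random_seq(rng, n)
        # b: a with substitutions and a couple of indels
        b_list = list(a)
        for p in rng.choice(n, size=n // 20, replace=False):
            b_list[p] = "ACGT"[rng.integers(4)]
        del b_list[n // 3]
        b_list.insert(2 * n // 3, "G")
        b = "".join(b_list)
        cost, cols = banded_align(a, b, band)
        assert cost == self._full_dp_in_band(a, b, band)
        # column bookkeeping reconstructs both lengths
        assert sum(c in "MXD" for c in cols) == len(a)
        assert sum(c in "MXI" for c in cols) == len(b)
        assert cost == sum(c in "XID" for c in cols)

    def test_identical_strings(self):
        cost, cols = banded_align("ACGTACGT", "ACGTACGT", 5)
        assert cost == 0 and cols == "M" * 8


class TestFindTir:
    def test_perfect_tir_recovered_exactly(self, rng):
        rep, _ = _tir_replicon(rng, tir_len=5000, rate=0.0)
        report = find_tir(rep)
        assert report is not None
        assert report.length == 5000
        assert report.percent_identity == pytest.approx(100.0)
        assert report.left_interval == (1, 5000)
        assert report.right_interval == (rep.length - 4999, rep.length)
        assert report.matches + report.mismatches + report.indels == report.length

    def test_five_point_mutations(self, rng):
        rep, k = _tir_replicon(rng, tir_len=5000, rate=0.001)  # 5 substitutions
        assert k == 5
        report = find_tir(rep)
        assert report.percent_identity == pytest.approx(99.9, abs=0.02)
        assert abs(report.length - 5000) <= 1000

    @pytest.mark.parametrize("rate", [0.0, 0.0005, 0.005, 0.05])
    def test_mutation_rate_sweep(self, rate):
        """Recovered identity tracks 100*(1 - rate) within 0.1 and length is
        within one window of the implanted repeat."""
        rng = np.random.default_rng(99)
        rep, _ = _tir_replicon(rng, tir_len=2100, core_len=15000, rate=rate, gc=0.7)
        # a 24-base exact seed still survives 5% divergence; a 100-base one
        # would often be broken by chance at that rate
        report = find_tir(rep, seed_len=24, min_identity=90.0)
        assert report is not None
        assert abs(report.length - 2100) <= 1000
        assert report.percent_identity == pytest.approx(100.0 * (1 - rate), abs=0.1)

    def test_monotone_degradation(self):
        """More divergence never increases the reported identity."""
        identities = []
        for rate in (0.0, 0.0005, 0.005, 0.05):
            rng = np.random.default_rng(7)
            rep, _ = _tir_replicon(rng, tir_len=2100, core_len=15000, rate=rate)
            identities.append(
                find_tir(rep, seed_len=24, min_identity=90.0).percent_identity)
        assert all(a >= b for a, b in zip(identities, identities[1:]))

    def test_reverse_complement_symmetry_exact_repeat(self, rng):
        rep, _ = _tir_replicon(rng, tir_len=3000, rate=0.0)
        mirrored = Replicon(id="m", sequence=reverse_complement(rep.sequence),
                            topology="linear")
        a = find_tir(rep)
        b = find_tir(mirrored)
        assert b.length == a.length
        assert b.percent_identity == pytest.approx(a.percent_identity)
        n = rep.length
        assert b.left_interval == (n - a.right_interval[1] + 1,
                                   n - a.right_interval[0] + 1)

    def test_reverse_complement_symmetry_with_mutations(self, rng):
        """With substitutions near the repeat edges the two orientations may
        trim a terminal mismatch column differently; the reports agree to
        within a couple of columns."""
        rep, _ = _tir_replicon(rng, tir_len=3000, rate=0.001)
        mirrored = Replicon(id="m", sequence=reverse_complement(rep.sequence),
                            topology="linear")
        a = find_tir(rep)
        b = find_tir(mirrored)
        assert abs(b.length - a.length) <= 2
        assert b.percent_identity == pytest.approx(a.percent_identity, abs=0.01)

    def test_circular_replicon_rejected(self):
        rep = Replicon(id="c", sequence="ACGT" * 100, topology="circular")
        with pytest.raises(ValueError):
            find_tir(rep)

    def test_no_seed_returns_none(self, rng):
        rep = Replicon(id="r", sequence=_random_seq(rng, 30_000), topology="linear")
        assert find_tir(rep) is None


class TestEndHomology:
    def test_identical_terminal_blocks(self, rng):
        block = _random_seq(rng, 2100, gc=0.7)
        rep_a = Replicon(id="a", sequence=block + "A" + _random_seq(rng, 20_000, 0.7),
                         topology="linear")
        rep_b = Replicon(id="b", sequence=block + "C" + _random_seq(rng, 15_000, 0.7),
                         topology="linear")
        report = end_homology(rep_a, "left", rep_b, "left")
        assert abs(report.length - 2100) <= 1000
        assert report.percent_identity == pytest.approx(100.0, abs=0.05)

    def test_mutated_terminal_blocks_match_binomial_oracle(self, rng):
        """One block carries exactly round(0.0005 * 2100) = 1 substitution, so
        identity lands within 0.05 of 99.95."""
        block = _random_seq(rng, 2100, gc=0.7)
        mutated, k = _mutate_exact(rng, block, 0.0005)
        assert k == 1
        rep_a = Replicon(id="a", sequence=block + "A" + _random_seq(rng, 20_000, 0.7),
                         topology="linear")
        rep_b = Replicon(id="b", sequence=mutated + "C" + _random_seq(rng, 15_000, 0.7),
                         topology="linear")
        report = end_homology(rep_a, "left", rep_b, "left")
        assert report.percent_identity == pytest.approx(99.95, abs=0.05)

    def test_right_ends_read_inward(self, rng):
        """A block at the right terminus of both replicons (reverse
        complemented on one) is found by the right/right comparison."""
        block = _random_seq(rng, 2100, gc=0.7)
        rep_a = Replicon(id="a", sequence=_random_seq(rng, 20_000, 0.7)
                         + reverse_complement(block), topology="linear")
        rep_b = Replicon(id="b", sequence=_random_seq(rng, 15_000, 0.7)
                         + reverse_complement(block), topology="linear")
        report = end_homology(rep_a, "right", rep_b, "right")
        assert report is not None and abs(report.length - 2100) <= 1000

    def test_shared_tir_in_generated_genome(self, embleya_dataset):
        """The chromosome-like and secondary-chromosome-like replicons share
        their terminal repeats at the generator's divergence."""
        genome = embleya_dataset.genome
        report = end_homology(genome.replicon("CHR"), "left",
                              genome.replicon("EEC1"), "left")
        assert report is not None
        assert report.percent_identity >= 99.8


class TestFindMotif:
    PARS = "GTTTCACGTGAAAC"

    def test_palindrome_scanned_once(self, rng):
        seq = _random_seq(rng, 5000)
        pos = 1000
        seq = seq[:pos - 1] + self.PARS + seq[pos - 1 + len(self.PARS):]
        rep = Replicon(id="r", sequence=seq)
        hits = find_motif(rep, self.PARS, 0)
        assert hits.palindromic
        assert all(strand == "+" for _, strand, _ in hits.hits)
        assert (pos, "+", 0) in hits.hits

    def test_implanted_sites_found_exactly(self, embleya_dataset):
        rep = embleya_dataset.genome.replicon("CHR")
        truth = [p for _, p in embleya_dataset.truth.motifs["CHR"]]
        hits = find_motif(rep, self.PARS, 0)
        assert sorted(p for p, _, _ in hits.hits) == sorted(truth)

    def test_single_mismatch_copy_reported(self, rng):
        seq = _random_seq(rng, 4000)
        copy = "GTTTCACGTGAAAA"  # one mismatch vs PARS
        seq = seq[:499] + copy + seq[499 + len(copy):]
        rep = Replicon(id="r", sequence=seq)
        hits = find_motif(rep, self.PARS, 1)
        assert any(p == 500 and mm == 1 for p, _, mm in hits.hits)
        assert not any(p == 500 for p, _, _ in find_motif(rep, self.PARS, 0).hits)

    def test_motif_longer_than_sequence(self):
        rep = Replicon(id="r", sequence="ACGT")
        assert find_motif(rep, self.PARS, 0).hits == []

    def test_non_palindromic_motif_reports_both_strands(self, rng):
        motif = "GATTACAGATTACA"
        seq = _random_seq(rng, 3000)
        seq = seq[:99] + motif + seq[99 + 14:]
        seq = seq[:1999] + reverse_complement(motif) + seq[1999 + 14:]
        hits = find_motif(Replicon(id="r", sequence=seq), motif, 0)
        strands = {s for _, s, _ in hits.hits}
        assert strands == {"+", "-"}


class TestDotPlot:
    def test_self_comparison_has_main_diagonal(self, rng):
        seq = _random_seq(rng, 2000)
        plot = dotplot_kmers(seq, seq, k=12)
        diag = {(a, b) for a, b, s in plot.points if s == "+"}
        assert all((i, i) in diag for i in range(1, len(seq) - 11, 97))

    def test_reverse_complement_on_reverse_channel(self, rng):
        seq = _random_seq(rng, 1500)
        plot = dotplot_kmers(seq, reverse_complement(seq), k=12)
        n = len(seq)
        rev = {(a, b) for a, b, s in plot.points if s == "-"}
        # k-mer starting at i in seq matches rc(seq) at n - k + 1 - i + 1 - 1
        assert all((i, n - 12 - i + 2) in rev for i in range(1, n - 11, 53))

    def test_shared_block_appears_as_off_diagonal_run(self, rng):
        block = _random_seq(rng, 5000)
        a = _random_seq(rng, 10_000) + block + _random_seq(rng, 5_000)
        b = _random_seq(rng, 2_000) + block + _random_seq(rng, 8_000)
        plot = dotplot_kmers(a, b, k=16)
        expected = {(10_001 + i, 2_001 + i) for i in range(0, 5000 - 15, 111)}
        fwd = {(x, y) for x, y, s in plot.points if s == "+"}
        assert expected <= fwd

    def test_downsampling_reports_full_count(self, rng):
        seq = _random_seq(rng, 3000)
        plot = dotplot_kmers(seq, seq, k=8, max_points=100)
        assert plot.n_total_points > 100
        assert len(plot.points) <= 100
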