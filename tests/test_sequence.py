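"""AT-richness scanner and GC content against naive oracles."""

import numpy as np
import pytest

from lsr2tools.sequence import (
    ATProfile,
    NucSequence,
    ScanConfig,
    at_profile,
    count_at_cores,
    count_at_windows,
    gc_content,
    read_fasta,
    sample_baseline_segments,
    write_fasta,
)

from conftest import random_sequence


def naive_counts(residues, length, min_at):
    """Enumerate every start; disjoint maximum by exact DP over interval scheduling."""
    starts = [
        i
        for i in range(len(residues) - length + 1)
        if sum(residues[i : i + length].count(b) for b in "AT") >= min_at
    ]
    # DP: best[i] = max windows using starts[i:]
    best = [0] * (len(starts) + 1)
    for i in range(len(starts) - 1, -1, -1):
        j = i + 1
        while j < len(starts) and starts[j] < starts[i] + length:
            j += 1
        best[i] = max(best[i + 1], 1 + best[j])
    return len(starts), best[0]


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5), ("GCAT", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", ["", "NNNN"])
    def test_undefined_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            gc_content(NucSequence("x", bad))

    def test_concatenation_is_length_weighted_mean(self, rng):
        a = random_sequence(rng, 120, p_at=0.3)
        b = random_sequence(rng, 60, p_at=0.8)
        combined = gc_content(a + b)
        weighted = (gc_content(a) * 120 + gc_content(b) * 60) / 180
        assert combined == pytest.approx(weighted)

    def test_case_folded_and_invalid_symbols_rejected(self):
        assert gc_content(NucSequence("x", "atgc")) == 0.5
        with pytest.raises(ValueError):
            NucSequence("x", "ATXG")


class TestWindowScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A" * 20, (1, 1)),
            ("G" * 100, (0, 0)),
            ("A" * 20 + "G" * 20, (10, 1)),
            ("A" * 10, (0, 0)),  # shorter than the window
        ],
    )
    def test_examples(self, seq, expected):
        assert count_at_windows(seq) == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAAAA", (1, 1)), ("GGGGGG", (0, 0)), ("AAAAAGAAAAAG", (7, 2))],
    )
    def test_core_examples(self, seq, expected):
        assert count_at_cores(seq) == expected

    def test_core_disjoint_hexamers(self):
        # hexamers at offsets 0 and 6 both qualify and do not overlap
        assert count_at_cores("AAAAAGAAAAAG")[1] == 2

    def test_window_with_n_can_still_qualify(self):
        # 11 A + 9 N: A/T count alone meets the threshold
        seq = "A" * 11 + "N" * 9
        assert count_at_windows(seq) == (1, 1)
        # 10 A + 10 N does not
        assert count_at_windows("A" * 10 + "N" * 10) == (0, 0)

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        cfg = ScanConfig()
        for _ in range(300):
            seq = random_sequence(rng, int(rng.integers(0, 201)), p_at=rng.uniform(0.3, 0.8))
            assert count_at_windows(seq, cfg) == naive_counts(seq, 20, 11)
            assert count_at_cores(seq, cfg) == naive_counts(seq, 6, 5)

    def test_greedy_equals_exact_maximum_on_short_sequences(self, rng):
        cfg = ScanConfig()
        for _ in range(300):
            seq = random_sequence(rng, int(rng.integers(6, 61)), p_at=0.6)
            assert count_at_cores(seq, cfg) == naive_counts(seq, 6, 5)

    def test_at_substitution_monotonicity(self, rng):
        """Replacing one G/C by A/T never decreases any count."""
        for _ in range(50):
            seq = random_sequence(rng, 80, p_at=0.5)
            gc_positions = [i for i, b in enumerate(seq) if b in "GC"]
            if not gc_positions:
                continue
            pos = int(rng.choice(gc_positions))
            mutated = seq[:pos] + "A" + seq[pos + 1 :]
            for counter in (count_at_windows, count_at_cores):
                before, after = counter(seq), counter(mutated)
                assert after[0] >= before[0]
                assert after[1] >= before[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(core_min_at=0)
        with pytest.raises(ValueError):
            ScanConfig(window_len=5, core_len=6)
        with pytest.raises(ValueError):
            ScanConfig(window_min_at=21)


class TestProfile:
    def test_all_gc_profile(self):
        p = at_profile(NucSequence("g", "G" * 50))
        assert not p.has_window and not p.has_core and p.gc_fraction == 1.0

    def test_all_at_profile(self):
        p = at_profile(NucSequence("a", "A" * 20))
        assert p.has_window and p.has_core

    def test_fields_match_component_operations(self, make_sequence):
        seq = make_sequence(150, p_at=0.55)
        p = at_profile(seq)
        assert (p.window_hits_overlapping, p.window_hits_disjoint) == count_at_windows(seq)
        assert (p.core_hits_overlapping, p.core_hits_disjoint) == count_at_cores(seq)
        assert p.gc_fraction == pytest.approx(gc_content(seq))
        assert p.window_hits_disjoint <= p.window_hits_overlapping
        assert p.core_hits_disjoint <= p.core_hits_overlapping


class TestBaselineSampling:
    def test_design_counts_and_lengths(self, make_sequence):
        chrom = make_sequence(10_000, p_at=0.28, id="chrom")
        segs = sample_baseline_segments(chrom, 15, [500, 1000], seed=11)
        assert len(segs) == 30
        assert sorted(len(s) for s in segs) == [500] * 15 + [1000] * 15
        for s in segs:
            src, start, end = s.source
            assert src == "chrom" and chrom.residues[start - 1 : end] == s.residues

    def test_zero_samples(self, make_sequence):
        assert sample_baseline_segments(make_sequence(100), 0, [50], seed=1) == []

    def test_deterministic_under_seed(self, make_sequence):
        chrom = make_sequence(5000)
        a = sample_baseline_segments(chrom, 5, [200], seed=7)
        b = sample_baseline_segments(chrom, 5, [200], seed=7)
        assert [s.residues for s in a] == [s.residues for s in b]

    def test_oversized_segment_rejected(self, make_sequence):
        with pytest.raises(ValueError):
            sample_baseline_segments(make_sequence(100), 1, [101], seed=1)


def test_fasta_round_trip(tmp_path, make_sequence):
    seqs = [make_sequence(137, id="s1"), make_sequence(301, id="s2")]
    path = tmp_path / "seqs.fasta"
    write_fasta(seqs, path)
    back = read_fasta(path)
    assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]
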