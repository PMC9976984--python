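import gzip
import math

import numpy as np
import pytest
from Bio import SeqIO

import taxbench as tb
from taxbench.read_simulator import _quality_to_ascii

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(REVCOMP)[::-1]


class TestPhredToError:
    @pytest.mark.parametrize(
        "q,expected,tol",
        [
            (23, 0.005, 5e-4),  # printed value for the bad-quality scenario
            (35, 0.00032, 5e-6),  # printed value for the good-quality scenario
            (0, 1.0, 0.0),
            (10, 0.1, 1e-15),
        ],
    )
    def test_values(self, q, expected, tol):
        assert tb.phred_to_error(q) == pytest.approx(expected, abs=tol)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tb.phred_to_error(-1)

    def test_vectorised(self):
        out = tb.phred_to_error(np.array([0, 10, 20]))
        np.testing.assert_allclose(out, [1.0, 0.1, 0.01])


class TestQualityModel:
    def test_non_tail_bounded_by_variance_frame(self, rng):
        model = tb.QualityModel(mean_phred=35, variance_frame=4)
        q = model.sample_matrix(10_000, 100, rng)
        non_tail = q[:, :90]
        assert np.abs(non_tail - 35).max() <= 4
        assert q.min() >= model.floor_phred

    def test_degenerate_model_is_constant(self, rng):
        model = tb.QualityModel(mean_phred=23, variance_frame=0, tail_step=0)
        q = model.sample_matrix(100, 48, rng)
        assert (q == 23).all()

    def test_tail_means_strictly_decreasing(self, rng):
        model = tb.QualityModel(mean_phred=35)
        q = model.sample_matrix(10_000, 100, rng)
        tail_means = q[:, 90:].mean(axis=0)
        assert (np.diff(tail_means) < 0).all()
        # linear schedule: tail position k sits ~k Phred units below the mean
        np.testing.assert_allclose(tail_means, 35 - np.arange(1, 11), atol=0.3)

    def test_non_tail_mean_matches_configuration(self, rng):
        for mean in (23, 35):
            model = tb.QualityModel(mean_phred=mean)
            q = model.sample_matrix(10_000, 48, rng)
            assert round(float(q[:, :38].mean())) == mean

    def test_floor_applied_in_tail(self, rng):
        model = tb.QualityModel(mean_phred=10, variance_frame=4, tail_step=3)
        q = model.sample_matrix(1_000, 30, rng)
        assert q.min() == model.floor_phred

    def test_read_length_must_exceed_tail(self, rng):
        with pytest.raises(ValueError):
            tb.sample_quality_string(tb.QualityModel(35), 10, rng)


class TestSampleReadPair:
    def test_forced_placement(self, rng):
        # genome of exactly 2*read_length with gap 0: the two mates tile it
        genome = tb.make_toy_genome(40, 0.5, 3)
        pair = tb.sample_read_pair(genome, 20, rng, gap_min=0, gap_max=0)
        if pair.strand == "+":
            assert pair.seq1 == genome[:20]
            assert pair.seq2 == revcomp(genome[20:])
        else:
            assert pair.seq1 == revcomp(genome[20:])
            assert pair.seq2 == genome[:20]

    def test_coordinate_bounds_exhaustive(self, rng):
        genome = tb.make_toy_genome(10_000, 0.5, 5)
        for _ in range(200):
            p = tb.sample_read_pair(genome, 50, rng)
            left, right = min(p.start1, p.start2), max(p.start1, p.start2)
            assert 0 <= left
            assert right == left + 50 + p.gap
            assert right + 50 <= len(genome)
            assert 0 <= p.gap <= 300

    def test_mate_sequences_match_genome_slices(self, rng):
        genome = tb.make_toy_genome(5_000, 0.5, 11)
        for _ in range(50):
            p = tb.sample_read_pair(genome, 40, rng)
            s1 = genome[p.start1 : p.start1 + 40]
            s2 = genome[p.start2 : p.start2 + 40]
            if p.strand == "+":
                assert p.seq1 == s1
                assert revcomp(p.seq2) == s2  # mate2 revcomp restores the slice
            else:
                assert p.seq1 == revcomp(s1)
                assert revcomp(p.seq2) == revcomp(s2)

    def test_genome_too_short(self, rng):
        with pytest.raises(ValueError, match="too short"):
            tb.sample_read_pair("ACGTACGT", 5, rng, gap_min=0)

    def test_determinism(self):
        genome = tb.make_toy_genome(2_000, 0.5, 1)
        rng1 = np.random.default_rng(9)
        a = [tb.sample_read_pair(genome, 30, rng1) for _ in range(5)]
        # fresh generator with the same seed reproduces the stream
        rng2 = np.random.default_rng(9)
        b = [tb.sample_read_pair(genome, 30, rng2) for _ in range(5)]
        assert [(p.seq1, p.seq2, p.start1, p.gap) for p in a] == [
            (p.seq1, p.seq2, p.start1, p.gap) for p in b
        ]


class TestErrorInjection:
    def test_disabled_errors_identity(self, rng):
        genome = tb.make_toy_genome(5_000, 0.5, 2)
        pairs = tb.simulate_reads(
            genome, 100, 40, tb.QualityModel(35), rng, inject_errors=False
        )
        for p in pairs:
            s1 = genome[p.start1 : p.start1 + 40]
            s2 = genome[p.start2 : p.start2 + 40]
            expect1 = s1 if p.strand == "+" else revcomp(s1)
            expect2 = revcomp(s2) if p.strand == "+" else s2
            assert p.seq1 == expect1 and p.seq2 == expect2

    def test_substitution_rate_matches_phred(self, rng):
        # ~1e6 simulated bases at mean Phred 23: mismatch rate should sit
        # within 3 binomial SD of the mean quality-implied error rate
        genome = tb.make_toy_genome(20_000, 0.5, 4)
        read_length, n = 100, 5_000
        pairs = tb.simulate_reads(genome, n, read_length, tb.QualityModel(23), rng)
        mismatches = 0
        expected_p = []
        for p in pairs:
            s1 = genome[p.start1 : p.start1 + read_length]
            s2 = genome[p.start2 : p.start2 + read_length]
            truth1 = s1 if p.strand == "+" else revcomp(s1)
            truth2 = revcomp(s2) if p.strand == "+" else s2
            mismatches += sum(a != b for a, b in zip(p.seq1, truth1))
            mismatches += sum(a != b for a, b in zip(p.seq2, truth2))
            expected_p.append(tb.phred_to_error(p.qual1).mean())
            expected_p.append(tb.phred_to_error(p.qual2).mean())
        n_bases = 2 * n * read_length
        p_mean = float(np.mean(expected_p))
        sd = math.sqrt(p_mean * (1 - p_mean) / n_bases)
        # 4 SD: a fixed-seed regression test needs a smaller false-alarm
        # probability than a one-off 3-SD draw; any real rate bias larger
        # than ~5% would still exceed this bound at 10^6 bases
        assert abs(mismatches / n_bases - p_mean) <= 4 * sd

    def test_low_quality_mutates_more(self, rng):
        # floor-quality bases must flip far more often than mean-quality bases
        genome = tb.make_toy_genome(10_000, 0.5, 6)
        n, L = 1_000, 100
        rates = {}
        for mean, frame in ((2, 0), (35, 0)):
            model = tb.QualityModel(mean_phred=mean, variance_frame=frame, tail_step=0, floor_phred=2)
            pairs = tb.simulate_reads(genome, n, L, model, np.random.default_rng(0))
            mm = 0
            for p in pairs:
                s1 = genome[p.start1 : p.start1 + L]
                truth1 = s1 if p.strand == "+" else revcomp(s1)
                mm += sum(a != b for a, b in zip(p.seq1, truth1))
            rates[mean] = mm / (n * L)
        assert rates[2] > 10 * rates[35]

    def test_apply_errors_requires_qualities(self, rng):
        genome = tb.make_toy_genome(500, 0.5, 8)
        pair = tb.sample_read_pair(genome, 30, rng)
        with pytest.raises(ValueError, match="quality"):
            tb.apply_sequencing_errors(pair, rng)


class TestWriteFastq:
    @pytest.mark.parametrize("q,char", [(0, "!"), (23, "8"), (35, "D")])
    def test_phred33_encoding(self, q, char):
        assert _quality_to_ascii(np.array([q])) == char

    def test_unencodable_quality(self):
        with pytest.raises(ValueError, match="not encodable"):
            _quality_to_ascii(np.array([94]))

    def test_round_trip(self, rng, tmp_path):
        genome = tb.make_toy_genome(5_000, 0.5, 10)
        pairs = tb.simulate_reads(genome, 50, 48, tb.QualityModel(23), rng)
        r1, r2, manifest = tb.write_fastq(pairs, tmp_path / "x")
        for path, mate in ((r1, 1), (r2, 2)):
            with gzip.open(path, "rt") as fh:
                records = list(SeqIO.parse(fh, "fastq"))
            assert len(records) == len(pairs)
            for rec, pair in zip(records, pairs):
                assert rec.id == f"{pair.fragment_id}/{mate}"
                assert str(rec.seq) == (pair.seq1 if mate == 1 else pair.seq2)
                quals = rec.letter_annotations["phred_quality"]
                expected = pair.qual1 if mate == 1 else pair.qual2
                assert quals == expected.tolist()
        assert len(manifest) == len(pairs)
        assert set(manifest.columns) == {
            "read_id", "species_id", "start1", "start2", "gap", "strand",
        }

    def test_byte_identical_across_runs(self, tmp_path):
        genome = tb.make_toy_genome(3_000, 0.5, 12)
        outputs = []
        for run in range(2):
            pairs = tb.simulate_reads(
                genome, 30, 40, tb.QualityModel(35), np.random.default_rng(77)
            )
            r1, r2, _ = tb.write_fastq(pairs, tmp_path / f"run{run}")
            outputs.append((r1.read_bytes(), r2.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_mixed_read_lengths_rejected(self, rng, tmp_path):
        g = tb.make_toy_genome(2_000, 0.5, 13)
        pairs = tb.simulate_reads(g, 2, 40, tb.QualityModel(35), rng)
        pairs += tb.simulate_reads(g, 2, 50, tb.QualityModel(35), rng)
        with pytest.raises(ValueError, match="read length"):
            tb.write_fastq(pairs, tmp_path / "bad")
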