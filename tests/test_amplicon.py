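"""Amplicon editing quantification: efficiency, spectra, PAM-relative maps."""

from __future__ import annotations

import random

import pytest

from editscan import (
    AmpliconSpec,
    GuideTarget,
    MutationRecord,
    quantify_editing,
    summarize_mutation_profile,
    variant_spectrum,
)
from editscan.amplicon import mutation_records_from_spectrum, read_fastq
from editscan.guides import reverse_complement
from editscan.simulate import simulate_amplicon_reads, write_fastq

from conftest import random_dna


@pytest.fixture(scope="module")
def spec():
    rng = random.Random(77)
    proto = random_dna(rng, 19)
    amplicon = random_dna(rng, 100) + proto + "TGG" + random_dna(rng, 100)
    guide = GuideTarget("g1", proto)
    return AmpliconSpec.from_guide("site1", amplicon, guide)


@pytest.fixture(scope="module")
def minus_spec():
    rng = random.Random(78)
    proto = random_dna(rng, 19)
    amplicon = (
        random_dna(rng, 90)
        + reverse_complement(proto + "AGG")
        + random_dna(rng, 90)
    )
    guide = GuideTarget("g2", proto)
    return AmpliconSpec.from_guide("site2", amplicon, guide)


def del_read(spec, size=1, at=None):
    cut = spec.cut_offset if at is None else at
    return spec.amplicon_seq[: cut + 1] + spec.amplicon_seq[cut + 1 + size :]


def ins_read(spec, ins="A"):
    cut = spec.cut_offset
    return spec.amplicon_seq[: cut + 1] + ins + spec.amplicon_seq[cut + 1 :]


class TestSpec:
    def test_cut_offset_points_at_blunt_cut(self, spec):
        # + strand: PAM starts 4 bases after the cut
        assert spec.amplicon_seq[spec.cut_offset + 5 : spec.cut_offset + 7] == "GG"

    def test_pam_relative_coordinates_roundtrip(self, spec, minus_spec):
        for s in (spec, minus_spec):
            for rel in (-25, -4, -3, -1, 1, 3, 10):
                assert s.to_pam_relative(s.from_pam_relative(rel)) == rel
        # -1 is the base immediately 5' of the PAM
        assert spec.from_pam_relative(-1) == spec.pam_start - 1

    def test_wrong_cut_offset_rejected(self, spec):
        with pytest.raises(ValueError):
            AmpliconSpec("bad", spec.amplicon_seq, spec.guide, spec.cut_offset + 1)


class TestQuantify:
    def test_quarter_of_reads_deleted_gives_025(self, spec):
        reads = [del_read(spec)] * 250 + [spec.amplicon_seq] * 750
        rep = quantify_editing(reads, spec)
        assert rep.total_reads == 1000
        assert rep.mutant_reads == 250
        assert rep.efficiency == pytest.approx(0.25)

    def test_low_frequency_signature_excluded_from_spectrum(self, spec):
        """A 0.0005-frequency signature is below the 1-per-mille bona-fide
        threshold: it stays in mutant_reads but is not reported; a
        0.002-frequency signature is reported."""
        reads = (
            [del_read(spec, size=1)] * 5      # 5 / 10000 = 0.0005
            + [del_read(spec, size=3)] * 20   # 20 / 10000 = 0.002
            + [spec.amplicon_seq] * 9975
        )
        rep = quantify_editing(reads, spec)
        assert rep.total_reads == 10_000
        assert rep.mutant_reads == 25
        assert len(rep.spectrum) == 1
        sig, count, freq = rep.spectrum[0]
        assert count == 20 and freq == pytest.approx(0.002)
        assert sig.startswith("-3nt")

    def test_singleton_signature_not_counted(self, spec):
        reads = [del_read(spec)] + [spec.amplicon_seq] * 99
        rep = quantify_editing(reads, spec)
        assert rep.mutant_reads == 0 and rep.efficiency == 0.0

    def test_substitution_only_reads_are_not_mutant(self, spec):
        base = spec.amplicon_seq
        i = spec.cut_offset
        sub = base[:i] + ("A" if base[i] != "A" else "C") + base[i + 1 :]
        rep = quantify_editing([sub] * 50 + [base] * 50, spec)
        assert rep.mutant_reads == 0

    def test_indel_outside_counting_window_not_mutant(self, spec):
        far = spec.cut_offset - spec.count_flank - 30
        reads = [del_read(spec, at=far)] * 50 + [spec.amplicon_seq] * 50
        rep = quantify_editing(reads, spec)
        assert rep.mutant_reads == 0

    def test_reads_not_spanning_window_excluded_from_total(self, spec):
        short = spec.amplicon_seq[spec.cut_offset :]  # misses the 5' flank
        reads = [spec.amplicon_seq] * 10 + [short] * 5
        rep = quantify_editing(reads, spec)
        assert rep.total_reads == 10

    def test_empty_read_set_flagged(self, spec):
        rep = quantify_editing([], spec)
        assert rep.flagged and rep.total_reads == 0 and rep.efficiency == 0.0

    def test_minus_strand_site_quantified(self, minus_spec):
        reads = [del_read(minus_spec)] * 30 + [minus_spec.amplicon_seq] * 70
        rep = quantify_editing(reads, minus_spec)
        assert rep.efficiency == pytest.approx(0.30)


class TestSpectrum:
    def test_single_insertion_signature(self, spec):
        reads = [ins_read(spec, "A")] * 40 + [spec.amplicon_seq] * 60
        spectrum = variant_spectrum(reads, spec)
        assert len(spectrum) == 1
        sig, count, freq = spectrum[0]
        assert count == 40 and freq == pytest.approx(0.4)
        assert sig.startswith("+1nt:")

    def test_no_mutant_reads_empty_spectrum(self, spec):
        assert variant_spectrum([spec.amplicon_seq] * 20, spec) == []

    def test_two_signature_proportions_recovered(self, spec):
        """Simulated 0.7/0.3 signature mixture is recovered within sampling
        error (multinomial, n = 4000 mutant reads)."""
        spectrum = [
            (MutationRecord("deletion", 3, -5, -3), 0.7),
            (MutationRecord("insertion", 1, -3, -3), 0.3),
        ]
        reads, truth = simulate_amplicon_reads(
            spec, efficiency=0.4, spectrum=spectrum, n_reads=10_000,
            subst_error_rate=0.0, seed=5,
        )
        out = variant_spectrum(reads, spec)
        assert len(out) == 2
        counts = {sig: c for sig, c, _ in out}
        total = sum(counts.values())
        props = sorted(c / total for c in counts.values())
        assert props[1] == pytest.approx(0.7, abs=0.03)

    def test_signature_encodes_pam_relative_span(self, spec):
        """A 3-nt deletion just 5' of the PAM is reported over the
        PAM-relative span of its canonical left-aligned form (derived
        independently by string diff)."""
        from oracles import canonical_representation

        lo = spec.from_pam_relative(-5)
        read = spec.amplicon_seq[:lo] + spec.amplicon_seq[lo + 3 :]
        pos, ref, alt = canonical_representation(spec.amplicon_seq, read)
        # deleted bases occupy 0-based [pos, pos + 2] in the amplicon
        want = sorted((spec.to_pam_relative(pos), spec.to_pam_relative(pos + 2)))
        out = variant_spectrum([read] * 10 + [spec.amplicon_seq] * 10, spec)
        assert out[0][0] == f"-3nt[{want[0]},{want[1]}]"


class TestEfficiencyRecovery:
    def test_simulated_040_recovered_within_binomial_bound(self, spec):
        reads, _ = simulate_amplicon_reads(
            spec, efficiency=0.40,
            spectrum=[(MutationRecord("deletion", 1, -3, -3), 1.0)],
            n_reads=10_000, seed=42,
        )
        rep = quantify_editing(reads, spec)
        assert rep.efficiency == pytest.approx(0.40, abs=0.015)

    @pytest.mark.parametrize("eff", [0.05, 0.95])
    def test_extreme_efficiencies(self, spec, eff):
        reads, _ = simulate_amplicon_reads(
            spec, efficiency=eff,
            spectrum=[(MutationRecord("insertion", 1, -3, -3), 1.0)],
            n_reads=5_000, seed=7,
        )
        rep = quantify_editing(reads, spec)
        assert rep.efficiency == pytest.approx(eff, abs=0.02)
        assert 0.0 <= rep.efficiency <= 1.0
        assert rep.mutant_reads <= rep.total_reads


class TestProfileHistograms:
    def test_one_deletion(self):
        h = summarize_mutation_profile([MutationRecord("deletion", 1, -3, -3)])
        assert h["size_histogram"] == {"1D": 1}
        assert h["deletion_start_histogram"] == {-3: 1}
        assert h["deletion_end_histogram"] == {-3: 1}

    def test_insertion_at_cut_anchored_minus3(self):
        h = summarize_mutation_profile([MutationRecord("insertion", 1, -3, -3)])
        assert h["size_histogram"] == {"1I": 1}
        assert h["insertion_position_histogram"] == {-3: 1}

    def test_empty_input(self):
        h = summarize_mutation_profile([])
        assert all(v == {} for v in h.values())

    def test_mass_conservation(self):
        rng = random.Random(3)
        records = [
            MutationRecord("deletion", s, a, a + s - 1)
            for s, a in [(rng.randrange(1, 6), rng.randrange(-20, -6)) for _ in range(50)]
        ] + [MutationRecord("insertion", 1, -3, -3)] * 10
        h = summarize_mutation_profile(records)
        assert sum(h["size_histogram"].values()) == 60
        assert sum(h["deletion_start_histogram"].values()) == 50
        assert sum(h["insertion_position_histogram"].values()) == 10

    def test_records_roundtrip_through_signatures(self, spec):
        reads = [del_read(spec)] * 20 + [ins_read(spec, "T")] * 10 + [spec.amplicon_seq] * 70
        spectrum = variant_spectrum(reads, spec)
        records = mutation_records_from_spectrum(spectrum)
        h = summarize_mutation_profile(records)
        assert sum(h["size_histogram"].values()) == 30


def test_fastq_roundtrip(tmp_path, spec):
    reads, _ = simulate_amplicon_reads(
        spec, efficiency=0.5,
        spectrum=[(MutationRecord("deletion", 2, -4, -3), 1.0)],
        n_reads=50, seed=1,
    )
    for name in ("r.fastq", "r.fastq.gz"):
        path = tmp_path / name
        write_fastq(reads, path)
        assert read_fastq(path) == reads
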