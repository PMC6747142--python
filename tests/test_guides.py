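"""Guide-site scanning: worked examples, oracle equivalence, invariants."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from editscan import GuideTarget, MatchParams, scan_genome, scan_sequence
from editscan.guides import SequenceError, load_guides, reverse_complement

from conftest import hits_as_tuples, random_dna
from oracles import brute_force_hits


def mutate(rng, s: str, positions) -> str:
    out = list(s)
    for i in positions:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestWorkedExamples:
    def test_identity_implant(self, rng, guide):
        seq = random_dna(rng, 50) + guide.protospacer + "TGG" + random_dna(rng, 50)
        hits = scan_sequence(seq, guide)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.strand, h.mismatches, h.bulge) == (50, 72, "+", 0, "none")
        assert h.pam_observed == "TGG"

    def test_strand_symmetry(self, rng, guide):
        seq = random_dna(rng, 50) + guide.protospacer + "TGG" + random_dna(rng, 50)
        hits = scan_sequence(reverse_complement(seq), guide)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].mismatches == 0
        # mirrored coordinates
        n = len(seq)
        assert (hits[0].start, hits[0].end) == (n - 72, n - 50)

    def test_two_mismatches_with_decoy(self, rng, guide):
        """A 2-substitution site is found; a 7-substitution decoy is not;
        the expectation is cross-checked against the brute-force oracle."""
        two = mutate(rng, guide.protospacer, [3, 11])
        seven = mutate(rng, guide.protospacer, [0, 2, 5, 8, 11, 14, 17])
        seq = (
            random_dna(rng, 40) + two + "AGG"
            + random_dna(rng, 40) + seven + "CGG" + random_dna(rng, 40)
        )
        hits = scan_sequence(seq, guide)
        expected = brute_force_hits(seq, guide)
        assert hits_as_tuples(hits) == expected
        assert len(hits) == 1
        assert hits[0].mismatches == 2

    def test_dna_bulge_implant(self, rng, guide):
        """One extra genomic base mid-protospacer is found as a dna_bulge
        when bulges are enabled, and never as a bulge when disabled."""
        bulged = guide.protospacer[:9] + rng.choice("ACGT") + guide.protospacer[9:]
        seq = random_dna(rng, 40) + bulged + "TGG" + random_dna(rng, 40)
        hits = scan_sequence(seq, guide)
        assert hits_as_tuples(hits) == brute_force_hits(seq, guide)
        assert any(h.bulge == "dna_bulge" and h.mismatches == 0 for h in hits)
        for h in scan_sequence(seq, guide, MatchParams(allow_bulge=False)):
            assert h.bulge == "none"

    def test_rna_bulge_implant(self, rng, guide):
        omitted = guide.protospacer[:7] + guide.protospacer[8:]
        seq = random_dna(rng, 40) + omitted + "TGG" + random_dna(rng, 40)
        hits = scan_sequence(seq, guide)
        assert hits_as_tuples(hits) == brute_force_hits(seq, guide)
        assert any(h.bulge == "rna_bulge" for h in hits)

    def test_cut_position_three_nt_from_pam(self, rng, guide):
        seq = random_dna(rng, 30) + guide.protospacer + "GGG" + random_dna(rng, 30)
        (h,) = scan_sequence(seq, guide)
        # + strand: PAM starts at end-3; the cut sits between pam-4 and pam-3
        assert h.cut_position == h.end - 3 - 4
        (hr,) = scan_sequence(reverse_complement(seq), guide)
        assert hr.cut_position == hr.start + 5


class TestValidation:
    def test_non_iupac_characters_rejected(self, guide):
        with pytest.raises(SequenceError):
            scan_sequence("ACGTQ" + "A" * 40, guide)

    def test_sequence_shorter_than_guide_is_empty(self, guide):
        assert scan_sequence("ACGTACGT", guide) == []

    def test_n_in_genome_counts_as_mismatch(self, rng, guide):
        proto = guide.protospacer
        seq = random_dna(rng, 30) + "N" + proto[1:] + "TGG" + random_dna(rng, 30)
        (h,) = scan_sequence(seq, guide, MatchParams(max_mismatches=1))
        assert h.mismatches == 1
        assert scan_sequence(seq, guide, MatchParams(max_mismatches=0, allow_bulge=False)) == []

    def test_guide_invariants(self):
        with pytest.raises(ValueError):
            GuideTarget("g", "ACGT")  # too short
        with pytest.raises(ValueError):
            GuideTarget("g", "ACGTACGTACGTACGTACN")  # non-ACGT
        with pytest.raises(ValueError):
            GuideTarget("g", "ACGTACGTACGTACGTACG", pam_patterns=frozenset({"NG"}))
        with pytest.raises(ValueError):
            GuideTarget(
                "g", "ACGTACGTACGTACGTACG",
                designed_locus=("c", 0, 10, "+"),  # wrong span
            )
        with pytest.raises(ValueError):
            MatchParams(max_mismatches=2, bulge_mismatch_cap=3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_sequences_match_brute_force(self, seed):
        rng = random.Random(seed)
        proto_len = rng.randrange(17, 24)
        g = GuideTarget(f"g{seed}", random_dna(rng, proto_len))
        seq = random_dna(rng, rng.randrange(300, 900))
        # make matches likely: implant some degraded copies
        for mm in (0, 2, 4, 6):
            p = rng.randrange(0, len(seq) - proto_len - 3)
            site = mutate(rng, g.protospacer, rng.sample(range(proto_len), mm)) + "TGG"
            if rng.random() < 0.5:
                site = reverse_complement(site)
            seq = seq[:p] + site + seq[p + len(site):]
        for max_mm in (0, 3, 6):
            for allow in (True, False):
                params = MatchParams(max_mismatches=max_mm, allow_bulge=allow)
                got = hits_as_tuples(scan_sequence(seq, g, params))
                want = brute_force_hits(seq, g, max_mm, allow)
                assert got == want, (seed, max_mm, allow)

    def test_pam_mismatch_counted_mode(self, rng, guide):
        seq = random_dna(rng, 30) + guide.protospacer + "TAT" + random_dna(rng, 30)
        params = MatchParams(max_mismatches=2, pam_mismatch_counted=True)
        got = hits_as_tuples(scan_sequence(seq, guide, params))
        want = brute_force_hits(seq, guide, 2, True, 0, True)
        assert got == want
        assert any(mm == 2 for _, _, _, mm, _ in got)  # TAT vs NGG = 2


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    max_mm=st.integers(0, 6),
    allow=st.booleans(),
)
def test_properties_monotonicity_and_strand_involution(seed, max_mm, allow):
    """Raising max_mismatches never removes a hit; disabling bulges removes
    only bulge hits; hit sets on seq and its reverse complement mirror."""
    rng = random.Random(seed)
    g = GuideTarget("g", random_dna(rng, 19))
    seq = random_dna(rng, 200)
    p = rng.randrange(0, len(seq) - 25)
    site = mutate(rng, g.protospacer, rng.sample(range(19), rng.randrange(0, max_mm + 1))) + "TGG"
    seq = seq[:p] + site + seq[p + len(site):]

    params = MatchParams(max_mismatches=max_mm, allow_bulge=allow)
    hits = scan_sequence(seq, g, params)
    assert all(h.mismatches <= max_mm for h in hits)

    if max_mm < 6:
        wider = scan_sequence(seq, g, MatchParams(max_mismatches=max_mm + 1, allow_bulge=allow))
        keys = {(h.strand, h.start, h.end) for h in wider}
        assert {(h.strand, h.start, h.end) for h in hits} <= keys

    if allow:
        no_bulge = scan_sequence(seq, g, MatchParams(max_mismatches=max_mm, allow_bulge=False))
        gapless = [h for h in hits if h.bulge == "none"]
        assert {(h.start, h.end, h.strand, h.mismatches) for h in no_bulge} >= {
            (h.start, h.end, h.strand, h.mismatches) for h in gapless
        }

    n = len(seq)
    mirrored = scan_sequence(reverse_complement(seq), g, params)
    assert sorted((n - h.end, n - h.start, h.mismatches, h.bulge) for h in hits) == sorted(
        (h.start, h.end, h.mismatches, h.bulge) for h in mirrored
    )


class TestScanGenome:
    def test_two_contigs_one_implant_each(self, rng, guide):
        seqs = {}
        for name in ("chr1", "chr2"):
            seqs[name] = (
                random_dna(rng, 60) + guide.protospacer + "TGG" + random_dna(rng, 60)
            )
        hits = scan_genome(seqs, [guide], MatchParams(max_mismatches=0, allow_bulge=False))
        assert [h.contig for h in hits[guide.name]] == ["chr1", "chr2"]

    def test_empty_guide_list(self, rng):
        assert scan_genome({"c": random_dna(rng, 100)}, []) == {}

    def test_missing_genome_is_io_error(self, guide, tmp_path):
        with pytest.raises(OSError):
            scan_genome({}, [guide])


def test_load_guides_roundtrip(tmp_path, rng):
    proto = random_dna(rng, 19)
    path = tmp_path / "guides.yaml"
    path.write_text(
        "guides:\n"
        f"  - name: g1\n    protospacer: {proto}\n    pam: NGG\n"
        "    locus: {contig: chr1, start: 100, end: 122, strand: '+'}\n"
        f"  - name: g2\n    protospacer: {proto}\n    pam: [NGG, NAG]\n"
    )
    g1, g2 = load_guides(path)
    assert g1.protospacer == proto
    assert g1.designed_locus == ("chr1", 100, 122, "+")
    assert g2.pam_patterns == frozenset({"NGG", "NAG"})
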