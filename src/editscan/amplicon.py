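"""Editing quantification from targeted amplicon deep sequencing.

A read is *mutant* when its alignment to the amplicon reference contains at
least one insertion or deletion overlapping the counting window around the
blunt cut (substitutions are sequencing noise plus SNPs and are excluded by
default). Editing efficiency is the ratio of mutant reads to total target
reads. Two noise filters mirror common deep-sequencing practice: a distinct
indel signature must be supported by at least ``min_variant_reads`` reads
(default 2) to count at all, and signatures below the bona-fide frequency
threshold (default 1 per mille) are excluded from the reported spectrum —
such low frequencies are indistinguishable from sequencing error.

Mutation positions are reported PAM-relative, Fig-1 style: −1 is the base
immediately 5' of the PAM, the blunt cut falls between −4 and −3, and
coordinate 0 is unused (+1 is the first PAM base).
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Optional

import edlib
from Bio import Align

from .guides import GuideTarget, reverse_complement

__all__ = [
    "AmpliconSpec",
    "EditingReport",
    "MutationRecord",
    "quantify_editing",
    "variant_spectrum",
    "summarize_mutation_profile",
    "read_fastq",
    "write_report_json",
]


@dataclasses.dataclass(frozen=True)
class AmpliconSpec:
    """One target amplicon: sequence, guide, cut position, counting window.

    ``cut_offset`` places the blunt cut between ``cut_offset`` and
    ``cut_offset + 1`` (0-based, amplicon coordinates); ``strand`` is the
    orientation of the guide site within the amplicon.
    """

    site_name: str
    amplicon_seq: str
    guide: GuideTarget
    cut_offset: int
    count_flank: int = 10
    strand: str = "+"

    def __post_init__(self):
        object.__setattr__(self, "amplicon_seq", self.amplicon_seq.upper())
        found = locate_guide(self.amplicon_seq, self.guide)
        if found is None or found != (self.cut_offset, self.strand):
            raise ValueError(
                f"protospacer+PAM of {self.guide.name!r} not found in the "
                f"amplicon at the position implied by cut_offset="
                f"{self.cut_offset} ({self.strand})"
            )

    @classmethod
    def from_guide(cls, site_name, amplicon_seq, guide, count_flank=10):
        """Locate the guide in the amplicon and derive ``cut_offset``."""
        found = locate_guide(amplicon_seq.upper(), guide)
        if found is None:
            raise ValueError(f"guide {guide.name!r} not found in amplicon")
        cut, strand = found
        return cls(site_name, amplicon_seq, guide, cut, count_flank, strand)

    @property
    def pam_start(self) -> int:
        """Amplicon coordinate of the PAM base adjacent to the protospacer."""
        if self.strand == "+":
            return self.cut_offset + 4
        return self.cut_offset - 3  # last PAM base in forward coordinates

    def to_pam_relative(self, pos: int) -> int:
        """Map an amplicon coordinate to the PAM-relative convention."""
        if self.strand == "+":
            d = pos - self.pam_start
            return d if d < 0 else d + 1
        d = self.pam_start - pos
        return d if d < 0 else d + 1

    def from_pam_relative(self, rel: int) -> int:
        """Inverse of :meth:`to_pam_relative` (``rel`` must be non-zero)."""
        if rel == 0:
            raise ValueError("PAM-relative coordinate 0 is unused")
        if self.strand == "+":
            return self.pam_start + (rel if rel < 0 else rel - 1)
        return self.pam_start - (rel if rel < 0 else rel - 1)


def locate_guide(amplicon: str, guide: GuideTarget) -> Optional[tuple[int, str]]:
    """Exact-match search for protospacer+PAM on both strands; returns
    (cut_offset, strand) or None."""
    L = len(guide.protospacer)

    def pam_ok(p: str, patterns) -> bool:
        from .guides import IUPAC

        return any(all(b in IUPAC[c] for b, c in zip(p, pat)) for pat in patterns)

    i = amplicon.find(guide.protospacer)
    while i != -1:
        pam = amplicon[i + L : i + L + 3]
        if len(pam) == 3 and pam_ok(pam, guide.pam_patterns):
            return i + L - 4, "+"
        i = amplicon.find(guide.protospacer, i + 1)
    rc = reverse_complement(guide.protospacer)
    i = amplicon.find(rc)
    while i != -1:
        pam = reverse_complement(amplicon[i - 3 : i])
        if len(pam) == 3 and pam_ok(pam, guide.pam_patterns):
            return i + 2, "-"  # cut between i+2 and i+3 in forward coords
        i = amplicon.find(rc, i + 1)
    return None


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One indel in PAM-relative coordinates (−1 = 1 nt 5' of the PAM)."""

    kind: str  # insertion | deletion
    size: int
    start_rel: int
    end_rel: int

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError("kind must be insertion or deletion")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.kind == "deletion":
            span = self.end_rel - self.start_rel + 1
            if self.end_rel < self.start_rel or span != self.size:
                raise ValueError("deletion size must equal end_rel - start_rel + 1")
        elif self.start_rel != self.end_rel:
            raise ValueError("insertion is anchored: start_rel must equal end_rel")


@dataclasses.dataclass(frozen=True)
class EditingReport:
    site_name: str
    total_reads: int
    mutant_reads: int
    efficiency: float
    spectrum: list[tuple[str, int, float]]
    bona_fide_threshold: float = 0.001
    flagged: bool = False  # True when total_reads == 0


# ---------------------------------------------------------------------------
# read alignment and indel extraction
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


# Affine-gap aligner for reads that contain indels: plain edit distance has
# no gap-open penalty and will scatter a multi-nt indel into several 1-nt
# gaps whenever an equal-cost path exists, which corrupts signatures.
# Mismatch (-3) is cheaper than an insertion/deletion pair; contiguous gaps
# beat split gaps; amplicon overhangs (partial reads) are free.
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -3
_ALIGNER.open_gap_score = -6
_ALIGNER.extend_gap_score = -0.2
try:
    _ALIGNER.end_deletion_score = 0
except AttributeError:  # older attribute name
    _ALIGNER.query_end_gap_score = 0


def _left_shift_del(amplicon: str, pos: int, size: int) -> int:
    while pos > 0 and amplicon[pos - 1] == amplicon[pos + size - 1]:
        pos -= 1
    return pos


def _left_shift_ins(amplicon: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ins[-1] == amplicon[pos - 1]:
        ins = ins[-1] + ins[:-1]
        pos -= 1
    return pos, ins


def _align_read(read: str, amplicon: str):
    """Align a read inside the amplicon; return (target_start, target_end
    inclusive, indels) where indels are (kind, pos, size, inserted_seq)
    left-normalized in amplicon coordinates, or None for an unalignable
    read. edlib gives a fast indel-presence check; indel-containing reads
    are realigned with affine gap scores."""
    res = edlib.align(read, amplicon, task="path", mode="HW")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    ops = list(_parse_cigar(res["cigar"] or ""))
    gap_runs = sum(1 for _, op in ops if op in "ID")
    t0, t1 = res["locations"][0]
    if gap_runs == 0:
        return t0, t1, []
    if gap_runs == 1:
        # a single contiguous indel is already affine-optimal; take it
        # straight from the edit-distance path
        indels = []
        tpos, qpos = t0, 0
        for length, op in ops:
            if op in "=XM":
                tpos += length
                qpos += length
            elif op == "D":
                pos = _left_shift_del(amplicon, tpos, length)
                indels.append(("deletion", pos, length, ""))
                tpos += length
            else:  # I
                pos, ins = _left_shift_ins(amplicon, tpos, read[qpos : qpos + length])
                indels.append(("insertion", pos, length, ins))
                qpos += length
        return t0, t1, indels
    aln = next(iter(_ALIGNER.align(amplicon, read)), None)
    if aln is None:
        return None
    tb, qb = aln.aligned
    if len(tb) == 0:
        return None
    indels = []
    for k in range(len(tb) - 1):
        tgap = int(tb[k + 1][0] - tb[k][1])
        qgap = int(qb[k + 1][0] - qb[k][1])
        if tgap > 0:  # read lacks bases present in the amplicon
            pos = _left_shift_del(amplicon, int(tb[k][1]), tgap)
            indels.append(("deletion", pos, tgap, ""))
        if qgap > 0:  # read carries extra bases
            ins = read[int(qb[k][1]) : int(qb[k + 1][0])]
            pos, ins = _left_shift_ins(amplicon, int(tb[k + 1][0]), ins)
            indels.append(("insertion", pos, qgap, ins))
    return int(tb[0][0]), int(tb[-1][1]) - 1, indels


def _signature(spec: AmpliconSpec, window_indels) -> str:
    parts = []
    for kind, pos, size, ins in window_indels:
        if kind == "deletion":
            rels = sorted(
                (spec.to_pam_relative(pos), spec.to_pam_relative(pos + size - 1))
            )
            parts.append(f"-{size}nt[{rels[0]},{rels[1]}]")
        else:
            if spec.strand == "-":
                ins = reverse_complement(ins)
            parts.append(f"+{size}nt:{ins}@{spec.to_pam_relative(pos)}")
    return ";".join(parts)


def _window_overlap(spec: AmpliconSpec, kind: str, pos: int, size: int) -> bool:
    lo = spec.cut_offset - spec.count_flank
    hi = spec.cut_offset + spec.count_flank  # inclusive
    if kind == "deletion":
        return pos <= hi and pos + size - 1 >= lo
    return pos - 1 <= hi and pos >= lo  # insertion junction between pos-1 and pos


def _classify_reads(reads, spec: AmpliconSpec, include_substitutions: bool):
    """Classify reads into window signatures ('' = unedited; None = does not
    span the counting window). Returns (total_spanning, Counter sig->count);
    identical reads are classified once."""
    amplicon = spec.amplicon_seq
    lo = spec.cut_offset - spec.count_flank
    hi = spec.cut_offset + spec.count_flank
    read_counts = Counter(r.upper() for r in reads)
    total = 0
    sig_counts: Counter = Counter()
    for read, k in read_counts.items():
        sig = _classify_one(read, amplicon, spec, lo, hi, include_substitutions)
        if sig is None:
            continue
        total += k
        if sig:
            sig_counts[sig] += k
    return total, sig_counts


def _classify_one(read, amplicon, spec, lo, hi, include_substitutions):
    # fast path: exact substring, no indels by construction
    j = amplicon.find(read)
    if j != -1:
        if j <= lo and j + len(read) - 1 >= hi:
            return ""
        return None  # does not span the counting window
    aln = _align_read(read, amplicon)
    if aln is None:
        return None
    t0, t1, indels = aln
    if not (t0 <= lo and t1 >= hi):
        return None
    window = [iv for iv in indels if _window_overlap(spec, iv[0], iv[1], iv[2])]
    if window:
        return _signature(spec, window)
    if include_substitutions:
        res = edlib.align(read, amplicon, mode="HW")
        if res["editDistance"] > 0 and not indels:
            return "substitution"
    return ""


def quantify_editing(
    reads,
    spec: AmpliconSpec,
    min_variant_reads: int = 2,
    bona_fide_threshold: float = 0.001,
    include_substitutions: bool = False,
) -> EditingReport:
    """Editing efficiency and mutation spectrum for one amplicon.

    Reads that do not span the counting window are excluded from
    ``total_reads``; distinct signatures supported by fewer than
    ``min_variant_reads`` reads are not counted as mutant; signatures below
    ``bona_fide_threshold`` stay in ``mutant_reads`` but are excluded from
    the spectrum.
    """
    total, counts = _classify_reads(reads, spec, include_substitutions)
    if total == 0:
        return EditingReport(spec.site_name, 0, 0, 0.0, [],
                             bona_fide_threshold, flagged=True)
    mutant = 0
    spectrum = []
    for sig, n in counts.items():
        if n < min_variant_reads:
            continue
        mutant += n
        freq = n / total
        if freq >= bona_fide_threshold:
            spectrum.append((sig, n, freq))
    spectrum.sort(key=lambda t: (-t[1], t[0]))
    return EditingReport(
        site_name=spec.site_name,
        total_reads=total,
        mutant_reads=mutant,
        efficiency=mutant / total,
        spectrum=spectrum,
        bona_fide_threshold=bona_fide_threshold,
    )


def variant_spectrum(reads, spec: AmpliconSpec, **kwargs) -> list[tuple[str, int, float]]:
    """The mutation-type spectrum alone (signature, count, frequency),
    sorted by descending count."""
    return quantify_editing(reads, spec, **kwargs).spectrum


def mutation_records_from_spectrum(spectrum) -> list[MutationRecord]:
    """Expand signature strings back into :class:`MutationRecord` lists
    (one record per indel, weighted by read count)."""
    records = []
    for sig, count, _freq in spectrum:
        for part in sig.split(";"):
            if not part or part == "substitution":
                continue
            for _ in range(count):
                records.append(_record_from_part(part))
    return records


def _record_from_part(part: str) -> MutationRecord:
    if part.startswith("-"):
        size, span = part[1:].split("nt[")
        a, b = span.rstrip("]").split(",")
        return MutationRecord("deletion", int(size), int(a), int(b))
    size, rest = part[1:].split("nt:")
    rel = int(rest.split("@")[1])
    return MutationRecord("insertion", int(size), rel, rel)


def summarize_mutation_profile(records: list[MutationRecord]) -> dict:
    """Fig-1-style histograms: indel-size spectrum (keys '1D', '2I', ...),
    insertion positions, deletion start and end positions (PAM-relative)."""
    size_hist: Counter = Counter()
    ins_pos: Counter = Counter()
    del_start: Counter = Counter()
    del_end: Counter = Counter()
    for r in records:
        if r.kind == "deletion":
            size_hist[f"{r.size}D"] += 1
            del_start[r.start_rel] += 1
            del_end[r.end_rel] += 1
        else:
            size_hist[f"{r.size}I"] += 1
            ins_pos[r.start_rel] += 1
    return {
        "size_histogram": dict(size_hist),
        "insertion_position_histogram": dict(sorted(ins_pos.items())),
        "deletion_start_histogram": dict(sorted(del_start.items())),
        "deletion_end_histogram": dict(sorted(del_end.items())),
    }


def read_fastq(path) -> list[str]:
    """Plain or gzipped FASTQ -> list of read sequences."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip())
    return reads


def write_report_json(path, report: EditingReport) -> None:
    doc = {
        "site_name": report.site_name,
        "total_reads": report.total_reads,
        "mutant_reads": report.mutant_reads,
        "efficiency": report.efficiency,
        "bona_fide_threshold": report.bona_fide_threshold,
        "flagged": report.flagged,
        "spectrum": [
            {"signature": s, "count": c, "frequency": f}
            for s, c, f in report.spectrum
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
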