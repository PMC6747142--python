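"""In-vitro cleavage-site calling from read-start pileups (Digenome-seq).

Genomic DNA digested in vitro by a Cas9 ribonucleoprotein and then
sequenced yields a characteristic signature at every cleavage position: a
column of read 5' ends on the forward strand immediately 3' of the blunt
cut, mirrored by read ends on the reverse strand immediately 5' of it.
This module accumulates per-position read-start/end counts and local depth,
calls positions where both strand signals exceed a minimum read count and a
minimum fraction of local depth, and filters the called sites against the
guides (up to 6 protospacer mismatches, or one bulge with no mismatch, by
default).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional

import numpy as np

from .guides import GuideTarget, MatchHit, MatchParams, scan_sequence
from .variants import as_fetcher

__all__ = [
    "ReadStartProfile",
    "CleavageSite",
    "CleavageParams",
    "build_read_start_profile",
    "call_cleavage_sites",
    "filter_cleavage_candidates",
    "mismatch_histogram",
    "read_alignment_tsv",
    "read_alignment_sam",
    "write_sites_tsv",
]


@dataclasses.dataclass
class ReadStartProfile:
    """Per-contig arrays of forward-read 5' starts, reverse-read 5' ends
    (rightmost aligned base), and coverage depth."""

    contigs: dict[str, dict[str, np.ndarray]] = dataclasses.field(default_factory=dict)

    def _ensure(self, contig: str, length: int):
        if contig not in self.contigs:
            self.contigs[contig] = {
                "forward_start": np.zeros(length, dtype=np.int64),
                "reverse_end": np.zeros(length, dtype=np.int64),
                "depth": np.zeros(length, dtype=np.int64),
            }
        return self.contigs[contig]


@dataclasses.dataclass(frozen=True)
class CleavageSite:
    """A blunt cut between ``cut`` and ``cut + 1`` (0-based)."""

    contig: str
    cut: int
    f_count: int
    r_count: int
    start_fraction: float
    matched: Optional[MatchHit] = None


@dataclasses.dataclass(frozen=True)
class CleavageParams:
    min_reads: int = 5
    min_start_fraction: float = 0.2
    window: int = 1


def read_alignment_tsv(path):
    """Plain-text alignment table: contig, strand(+/-), start, end
    (0-based half-open aligned span), tab-separated, optionally with a
    header line."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, strand, start, end = line.split("\t")[:4]
            if start == "start":
                continue
            records.append((contig, strand, int(start), int(end)))
    return records


def read_alignment_sam(path):
    """Aligned spans from a SAM/BAM file; secondary, supplementary,
    duplicate and unmapped records are excluded; soft clips never extend
    the span (pysam reference coordinates already exclude them)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path)) as af:
        for r in af:
            if (
                r.is_unmapped
                or r.is_secondary
                or r.is_supplementary
                or r.is_duplicate
            ):
                continue
            strand = "-" if r.is_reverse else "+"
            records.append((r.reference_name, strand, r.reference_start, r.reference_end))
    return records


def build_read_start_profile(alignments, contig_lengths) -> ReadStartProfile:
    """Accumulate strand-specific read 5'-end counts and depth.

    ``alignments`` must be coordinate-sorted tuples
    ``(contig, strand, start, end)``; forward reads contribute their
    leftmost aligned base, reverse reads their rightmost.
    """
    profile = ReadStartProfile()
    last: dict[str, int] = {}
    for contig, strand, start, end in alignments:
        if not 0 <= start < end <= contig_lengths[contig]:
            raise ValueError(f"alignment out of bounds: {contig}:{start}-{end}")
        if start < last.get(contig, 0):
            raise ValueError("alignments are not coordinate-sorted")
        last[contig] = start
        arrs = profile._ensure(contig, contig_lengths[contig])
        if strand == "+":
            arrs["forward_start"][start] += 1
        else:
            arrs["reverse_end"][end - 1] += 1
        arrs["depth"][start:end] += 1
    for contig, length in contig_lengths.items():
        profile._ensure(contig, length)
    return profile


def _window_max(a: np.ndarray, w: int) -> np.ndarray:
    """out[i] = max(a[i-w : i+w+1]) with edge clipping."""
    if w == 0:
        return a
    out = a.copy()
    for d in range(1, w + 1):
        out[d:] = np.maximum(out[d:], a[:-d])
        out[:-d] = np.maximum(out[:-d], a[d:])
    return out


def call_cleavage_sites(
    profile: ReadStartProfile,
    params: CleavageParams = CleavageParams(),
) -> list[CleavageSite]:
    """Call blunt-cut positions from the two-strand read-start signature.

    A cut between p and p+1 requires >= ``min_reads`` forward starts near
    p+1 (within ±``window``, tolerating staggered ends), >= ``min_reads``
    reverse ends exactly at p, and a combined start fraction of local depth
    >= ``min_start_fraction``. Runs of adjacent called positions are reduced
    to the local maximum of the combined signal.
    """
    sites: list[CleavageSite] = []
    for contig, arrs in profile.contigs.items():
        fwd, rev, depth = arrs["forward_start"], arrs["reverse_end"], arrs["depth"]
        n = fwd.size
        if n < 2:
            continue
        f_near = _window_max(fwd, params.window)[1:]  # f_near[p] ~ fwd[p+1 ± w]
        r_here = rev[:-1]
        local_depth = np.maximum(depth[:-1], depth[1:])
        score = f_near + r_here
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(local_depth > 0, score / np.maximum(local_depth, 1), 0.0)
        frac = np.minimum(frac, 1.0)
        called = (
            (f_near >= params.min_reads)
            & (r_here >= params.min_reads)
            & (frac >= params.min_start_fraction)
        )
        idx = np.flatnonzero(called)
        if idx.size == 0:
            continue
        # cluster adjacent/nearby called positions; keep the strongest
        gap = 2 * params.window + 1
        breaks = np.flatnonzero(np.diff(idx) > gap)
        for cluster in np.split(idx, breaks + 1):
            best = cluster[np.argmax(score[cluster])]
            sites.append(
                CleavageSite(
                    contig=contig,
                    cut=int(best),
                    f_count=int(f_near[best]),
                    r_count=int(r_here[best]),
                    start_fraction=float(frac[best]),
                )
            )
    sites.sort(key=lambda s: (s.contig, s.cut))
    return sites


def filter_cleavage_candidates(
    sites: list[CleavageSite],
    guides: list[GuideTarget],
    reference,
    params: MatchParams = MatchParams(),
    cut_tolerance: int = 1,
) -> list[CleavageSite]:
    """Keep called sites whose neighbourhood holds a guide match whose
    predicted blunt cut falls within ``cut_tolerance`` of the observed cut;
    the best such hit is attached."""
    fetch = as_fetcher(reference)
    retained = []
    for site in sites:
        best = None
        for guide in guides:
            span = len(guide.protospacer) + 3
            lo = max(0, site.cut - span - cut_tolerance)
            hi = site.cut + 1 + span + cut_tolerance
            seq = fetch(site.contig, lo, hi)
            for h in scan_sequence(seq, guide, params, contig=site.contig):
                cut_genome = h.cut_position + lo
                if abs(cut_genome - site.cut) > cut_tolerance:
                    continue
                h = dataclasses.replace(
                    h, start=h.start + lo, end=h.end + lo, cut_position=cut_genome
                )
                if best is None or (h.mismatches, h.bulge != "none") < (
                    best.mismatches, best.bulge != "none"
                ):
                    best = h
        if best is not None:
            retained.append(dataclasses.replace(site, matched=best))
    return retained


def mismatch_histogram(sites: list[CleavageSite]) -> dict[int, int]:
    """Counts of retained sites per mismatch number (Fig-2-style summary)."""
    return dict(sorted(Counter(s.matched.mismatches for s in sites if s.matched).items()))


def write_sites_tsv(path, sites: list[CleavageSite]) -> None:
    import pandas as pd

    rows = [
        {
            "contig": s.contig,
            "cut": s.cut,
            "f_count": s.f_count,
            "r_count": s.r_count,
            "start_fraction": round(s.start_fraction, 4),
            "matched_start": s.matched.start if s.matched else "",
            "matched_end": s.matched.end if s.matched else "",
            "strand": s.matched.strand if s.matched else "",
            "mismatches": s.matched.mismatches if s.matched else "",
            "bulge": s.matched.bulge if s.matched else "",
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
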