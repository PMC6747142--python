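"""Mismatch- and bulge-tolerant search for guide-RNA target sites.

This is the shared matching core of the toolkit: given a protospacer and a
PAM pattern (NGG for SpCas9), find every site in a DNA sequence that the
guide could direct Cas9 to, allowing up to ``max_mismatches`` substitutions
in the protospacer, or a single one-nucleotide bulge (an extra base on the
genomic strand, ``dna_bulge``, or a base of the guide left unpaired,
``rna_bulge``) carrying at most ``bulge_mismatch_cap`` substitutions.

Conventions
-----------
* Coordinates are 0-based half-open on the forward reference strand; a hit
  spans protospacer + PAM.
* PAM matching is an IUPAC pattern test and, by default, PAM positions never
  contribute to the mismatch count (set ``pam_mismatch_counted`` to change
  this).
* Cas9 cuts bluntly between the 3rd and 4th base 5' of the PAM;
  ``cut_position`` is the base immediately 5' of that cut, i.e. the cut lies
  between ``cut_position`` and ``cut_position + 1`` in forward coordinates.
* A genomic ``N`` (or any ambiguity code) never pairs with a protospacer
  base and is counted as a mismatch — conservative behaviour in masked or
  ambiguous regions.
* One physical site (one PAM on one strand) yields one hit: among a gapless
  and the possible one-bulge alignments sharing that PAM, the one with the
  fewest mismatches is reported, preferring bulge-free, then leftmost.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GuideTarget",
    "MatchParams",
    "MatchHit",
    "scan_sequence",
    "scan_genome",
    "reverse_complement",
    "load_guides",
    "write_hits_bed",
    "write_hits_tsv",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

_ALLOWED = np.zeros(256, dtype=bool)
for _c in IUPAC:
    _ALLOWED[ord(_c)] = True

# per IUPAC letter: 256-entry table of which sequence bytes satisfy it
_PAM_LUT = {}
for _c, _bases in IUPAC.items():
    t = np.zeros(256, dtype=bool)
    for _b in _bases:
        t[ord(_b)] = True
    _PAM_LUT[_c] = t


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class GuideTarget:
    """A designed guide: protospacer, PAM pattern(s), optional intended locus.

    ``designed_locus`` is ``(contig, start, end, strand)`` in 0-based
    half-open forward coordinates spanning protospacer + PAM.
    """

    name: str
    protospacer: str
    pam_patterns: frozenset[str] = frozenset({"NGG"})
    designed_locus: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self):
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        if not (17 <= len(proto) <= 23):
            raise ValueError(
                f"protospacer must be 17-23 nt, got {len(proto)}"
            )
        if set(proto) - set("ACGT"):
            raise ValueError("protospacer may contain only A/C/G/T")
        pams = frozenset(p.upper() for p in self.pam_patterns)
        object.__setattr__(self, "pam_patterns", pams)
        for p in pams:
            if len(p) != 3 or set(p) - set(IUPAC):
                raise ValueError(f"PAM pattern {p!r} must be 3 IUPAC characters")
        if self.designed_locus is not None:
            contig, start, end, strand = self.designed_locus
            if strand not in "+-":
                raise ValueError("designed_locus strand must be + or -")
            if end - start != len(proto) + 3:
                raise ValueError(
                    "designed_locus span must equal protospacer length + 3"
                )


@dataclasses.dataclass(frozen=True)
class MatchParams:
    max_mismatches: int = 6
    allow_bulge: bool = True
    bulge_mismatch_cap: int = 0
    pam_mismatch_counted: bool = False

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.bulge_mismatch_cap > self.max_mismatches:
            raise ValueError("bulge_mismatch_cap must be <= max_mismatches")


@dataclasses.dataclass(frozen=True)
class MatchHit:
    """One guide-to-DNA match (protospacer + PAM footprint)."""

    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    bulge: str  # none | dna_bulge | rna_bulge
    bulge_offset: Optional[int]
    pam_observed: str
    cut_position: int

    @property
    def guide_span(self) -> tuple[int, int]:
        """Span of the protospacer part (excludes the PAM)."""
        if self.strand == "+":
            return self.start, self.end - 3
        return self.start + 3, self.end


class SequenceError(ValueError):
    """Input sequence contains characters outside the IUPAC alphabet."""


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    if not _ALLOWED[arr].all():
        bad = sorted({chr(b) for b in arr[~_ALLOWED[arr]]})
        raise SequenceError(f"non-IUPAC characters in sequence: {bad}")
    return arr


def _pam_masks(arr: np.ndarray, pam_start: np.ndarray, patterns) -> tuple[np.ndarray, np.ndarray]:
    """For candidate PAM start positions, return (matches_any_pattern,
    min_mismatches_to_any_pattern)."""
    ok = np.zeros(pam_start.size, dtype=bool)
    mm = np.full(pam_start.size, 3, dtype=np.int64)
    for pat in patterns:
        pat_mm = np.zeros(pam_start.size, dtype=np.int64)
        for k, letter in enumerate(pat):
            pat_mm += ~_PAM_LUT[letter][arr[pam_start + k]]
        ok |= pat_mm == 0
        np.minimum(mm, pat_mm, out=mm)
    return ok, mm


def _scan_one_strand(arr: np.ndarray, guide: GuideTarget, params: MatchParams):
    """Yield raw candidates on the forward orientation of ``arr``.

    Candidates are tuples ``(start, span, mismatches, bulge, bulge_offset)``
    where ``span`` covers protospacer + PAM and the PAM occupies the last
    three positions.
    """
    proto = np.frombuffer(guide.protospacer.encode(), dtype=np.uint8)
    L = proto.size
    n = arr.size
    out = []
    if n < L + 3:
        return out

    A = sliding_window_view(arr, L) != proto  # (n-L+1, L)
    mm_full = A.sum(axis=1)
    ca = np.cumsum(A, axis=1)  # ca[i, g-1] = mismatches over first g bases

    def pam_terms(starts: np.ndarray):
        ok, pmm = _pam_masks(arr, starts, guide.pam_patterns)
        if params.pam_mismatch_counted:
            return np.ones_like(ok), pmm
        return ok, np.zeros_like(pmm)

    # --- gapless ---
    m = n - L - 2  # number of starts with room for a PAM
    starts = np.arange(m)
    ok, extra = pam_terms(starts + L)
    total = mm_full[:m] + extra
    keep = ok & (total <= params.max_mismatches)
    for i in np.flatnonzero(keep):
        out.append((int(i), L + 3, int(total[i]), "none", None))

    if not params.allow_bulge or L < 3:
        return out

    cap = params.bulge_mismatch_cap

    # --- dna bulge: one extra genomic base inside the protospacer ---
    # window = L+1 genomic bases; gap after protospacer position g (1..L-1)
    md = n - L - 3
    if md > 0:
        pref = ca[:, : L - 1]  # column g-1 -> mismatches over proto[:g]
        d = pref[:md] - pref[1 : md + 1] + mm_full[1 : md + 1, None]
        g_best = np.argmin(d, axis=1)
        v_best = d[np.arange(md), g_best]
        ok, extra = pam_terms(np.arange(md) + L + 1)
        total = v_best + extra
        keep = ok & (total <= cap)
        for i in np.flatnonzero(keep):
            out.append((int(i), L + 4, int(total[i]), "dna_bulge", int(g_best[i]) + 1))

    # --- rna bulge: one protospacer base unpaired (genomic base omitted) ---
    # window = L-1 genomic bases; proto position g skipped (1..L-2)
    mr = n - L - 1
    if L >= 4 and mr > 0:
        E = sliding_window_view(arr, L - 1) != proto[1:]
        ce = np.cumsum(E, axis=1)
        e_tot = E.sum(axis=1)
        # mism(i, g) = ca[i, g-1] + e_tot[i] - ce[i, g-1],  g = 1..L-2
        r = ca[:mr, : L - 2] - ce[:mr, : L - 2] + e_tot[:mr, None]
        g_best = np.argmin(r, axis=1)
        v_best = r[np.arange(mr), g_best]
        ok, extra = pam_terms(np.arange(mr) + L - 1)
        total = v_best + extra
        keep = ok & (total <= cap)
        for i in np.flatnonzero(keep):
            out.append((int(i), L + 2, int(total[i]), "rna_bulge", int(g_best[i]) + 1))

    return out


_BULGE_RANK = {"none": 0, "dna_bulge": 1, "rna_bulge": 2}


def scan_sequence(
    seq: str,
    guide: GuideTarget,
    params: MatchParams = MatchParams(),
    contig: str = "seq",
) -> list[MatchHit]:
    """Find every guide match in ``seq`` on both strands.

    Returns hits sorted by (start, strand), one per physical site (PAM and
    strand); among alternative alignments at one site the hit with fewest
    mismatches wins, bulge-free preferred, then leftmost.
    """
    arr = _encode(seq)
    n = arr.size
    seq_u = seq.upper()
    rc = reverse_complement(seq_u)
    candidates = {}  # (strand, pam_forward_start) -> best raw hit

    def consider(strand, start, end, mism, bulge, boff):
        pam_fwd = end - 3 if strand == "+" else start
        key = (strand, pam_fwd)
        rank = (mism, _BULGE_RANK[bulge] > 0, start)
        prev = candidates.get(key)
        if prev is None or rank < prev[0]:
            candidates[key] = (rank, (start, end, strand, mism, bulge, boff))

    for s2, span, mism, bulge, boff in _scan_one_strand(arr, guide, params):
        consider("+", s2, s2 + span, mism, bulge, boff)
    if n >= len(guide.protospacer) + 3:
        arr_rc = _encode(rc)
        for s2, span, mism, bulge, boff in _scan_one_strand(arr_rc, guide, params):
            consider("-", n - (s2 + span), n - s2, mism, bulge, boff)

    hits = []
    for _, (start, end, strand, mism, bulge, boff) in candidates.values():
        if strand == "+":
            pam = seq_u[end - 3 : end]
            cut = end - 7
        else:
            pam = reverse_complement(seq_u[start : start + 3])
            cut = start + 5
        hits.append(
            MatchHit(
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                mismatches=mism,
                bulge=bulge,
                bulge_offset=boff,
                pam_observed=pam,
                cut_position=cut,
            )
        )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def _iter_contigs(genome) -> Iterable[tuple[str, str]]:
    """Accept a mapping name->sequence, a pyfaidx.Fasta, or a FASTA path."""
    if isinstance(genome, Mapping):
        yield from genome.items()
        return
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        for name in fa.keys():
            yield name, str(fa[name][:])
        return
    # pyfaidx.Fasta-like object
    for name in genome.keys():
        yield name, str(genome[name][:])


def scan_genome(
    genome,
    guides: list[GuideTarget],
    params: MatchParams = MatchParams(),
) -> dict[str, list[MatchHit]]:
    """Scan every contig of ``genome`` for every guide.

    One contig is materialised at a time; hit order follows contig order in
    the input, then coordinate.
    """
    results: dict[str, list[MatchHit]] = {g.name: [] for g in guides}
    if not guides:
        return results
    any_contig = False
    for name, seq in _iter_contigs(genome):
        any_contig = True
        for g in guides:
            results[g.name].extend(scan_sequence(seq, g, params, contig=name))
    if not any_contig:
        raise IOError("genome has no contigs")
    return results


def load_guides(path) -> list[GuideTarget]:
    """Read guide definitions from a YAML config.

    Format::

        guides:
          - name: TRY
            protospacer: TAGTCAAGAAAGGTAAAGT
            pam: NGG              # string or list of patterns
            locus: {contig: chr1, start: 1200, end: 1222, strand: "+"}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["guides"] if isinstance(doc, dict) else doc
    guides = []
    for e in entries:
        pam = e.get("pam", "NGG")
        pams = frozenset([pam] if isinstance(pam, str) else pam)
        locus = None
        if e.get("locus"):
            lo = e["locus"]
            locus = (lo["contig"], int(lo["start"]), int(lo["end"]), lo["strand"])
        guides.append(
            GuideTarget(
                name=e["name"],
                protospacer=e["protospacer"],
                pam_patterns=pams,
                designed_locus=locus,
            )
        )
    return guides


def _hit_rows(hits_by_guide: dict[str, list[MatchHit]]):
    for gname, hits in hits_by_guide.items():
        for h in hits:
            yield (
                h.contig, h.start, h.end, gname, h.mismatches, h.strand,
                h.bulge, h.pam_observed, h.cut_position,
            )


def write_hits_bed(hits_by_guide: dict[str, list[MatchHit]], path) -> None:
    """BED6+3: contig, start, end, guide, mismatches, strand, bulge,
    pam_observed, cut_position."""
    with open(path, "w") as fh:
        for row in _hit_rows(hits_by_guide):
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_hits_tsv(hits_by_guide: dict[str, list[MatchHit]], path) -> None:
    import pandas as pd

    cols = [
        "contig", "start", "end", "guide", "mismatches", "strand",
        "bulge", "pam_observed", "cut_position",
    ]
    pd.DataFrame(list(_hit_rows(hits_by_guide)), columns=cols).to_csv(
        path, sep="\t", index=False
    )
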