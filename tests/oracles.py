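"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: exhaustive enumeration over every offset, strand and
bulge position with early-exit Hamming counting. Shares no code with the
vectorised scanner in editscan.guides.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _ham(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _pam_match(pam: str, patterns) -> bool:
    return any(all(b in IUPAC[c] for b, c in zip(pam, pat)) for pat in patterns)


def _pam_mm(pam: str, patterns) -> int:
    return min(
        sum(b not in IUPAC[c] for b, c in zip(pam, pat)) for pat in patterns
    )


def raw_candidates(seq, guide, max_mismatches=6, allow_bulge=True,
                   bulge_mismatch_cap=0, pam_mismatch_counted=False):
    """Every alignment (before per-locus deduplication) as tuples
    (strand, fwd_start, fwd_end, mismatches, bulge)."""
    proto = guide.protospacer
    pats = guide.pam_patterns
    L = len(proto)
    n = len(seq)
    out = []
    for strand in "+-":
        s = seq.upper() if strand == "+" else revcomp(seq.upper())

        def emit(start, span, mm, bulge):
            if strand == "+":
                out.append(("+", start, start + span, mm, bulge))
            else:
                out.append(("-", n - start - span, n - start, mm, bulge))

        def pam_terms(p):
            pam = s[p : p + 3]
            if pam_mismatch_counted:
                return True, _pam_mm(pam, pats)
            return _pam_match(pam, pats), 0

        for start in range(n - L - 2):
            ok, extra = pam_terms(start + L)
            if ok:
                mm = _ham(s[start : start + L], proto, max_mismatches) + extra
                if mm <= max_mismatches:
                    emit(start, L + 3, mm, "none")
            if not allow_bulge or s[start] != proto[0]:
                continue
            cap = bulge_mismatch_cap
            # dna bulge: extra genomic base after protospacer position g
            if start + L + 4 <= n:
                ok, extra = pam_terms(start + L + 1)
                if ok:
                    best = None
                    for g in range(1, L):
                        mm = _ham(s[start : start + g], proto[:g], cap)
                        if mm > cap:
                            continue
                        mm += _ham(
                            s[start + g + 1 : start + L + 1], proto[g:], cap - mm
                        )
                        mm += extra
                        if mm <= cap and (best is None or mm < best):
                            best = mm
                    if best is not None:
                        emit(start, L + 4, best, "dna_bulge")
            # rna bulge: protospacer position g unpaired (genomic base absent)
            if start + L + 2 <= n and L >= 3:
                ok, extra = pam_terms(start + L - 1)
                if ok:
                    best = None
                    for g in range(1, L - 1):
                        mm = _ham(s[start : start + g], proto[:g], cap)
                        if mm > cap:
                            continue
                        mm += _ham(
                            s[start + g : start + L - 1], proto[g + 1 :], cap - mm
                        )
                        mm += extra
                        if mm <= cap and (best is None or mm < best):
                            best = mm
                    if best is not None:
                        emit(start, L + 2, best, "rna_bulge")
    return out


def dedup(cands):
    """One hit per physical site (strand + PAM location): fewest mismatches,
    bulge-free preferred, then leftmost."""
    best = {}
    for strand, start, end, mm, bulge in cands:
        pam_fwd = end - 3 if strand == "+" else start
        key = (strand, pam_fwd)
        rank = (mm, bulge != "none", start)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, (strand, start, end, mm, bulge))
    return sorted(v for _, v in best.values())


def brute_force_hits(seq, guide, max_mismatches=6, allow_bulge=True,
                     bulge_mismatch_cap=0, pam_mismatch_counted=False):
    """Deduplicated hit set: sorted (strand, start, end, mismatches, bulge)."""
    return dedup(
        raw_candidates(
            seq, guide, max_mismatches, allow_bulge,
            bulge_mismatch_cap, pam_mismatch_counted,
        )
    )


def apply_variant(contig_seq: str, pos: int, ref: str, alt: str) -> str:
    """The edited haplotype produced by one variant (pos is 1-based)."""
    assert contig_seq[pos - 1 : pos - 1 + len(ref)] == ref
    return contig_seq[: pos - 1] + alt + contig_seq[pos - 1 + len(ref):]


def canonical_representation(contig_seq: str, edited: str):
    """Canonical left-aligned minimal (pos, ref, alt) of the single variant
    separating two haplotypes, derived by plain string diff — independent of
    any shifting algorithm."""
    limit = min(len(contig_seq), len(edited))
    # maximise the common suffix first: that is what left-aligns the indel
    s = 0
    while s < limit and contig_seq[len(contig_seq) - 1 - s] == edited[len(edited) - 1 - s]:
        s += 1
    p = 0
    while p < limit - s and contig_seq[p] == edited[p]:
        p += 1
    ref_core = contig_seq[p : len(contig_seq) - s]
    alt_core = edited[p : len(edited) - s]
    if len(ref_core) == 1 and len(alt_core) == 1:  # SNV
        return p + 1, ref_core, alt_core
    if p > 0:  # anchored indel
        return p, contig_seq[p - 1] + ref_core, edited[p - 1] + alt_core
    # indel at contig start: anchor on the following base
    return 1, ref_core + contig_seq[len(ref_core)], alt_core + contig_seq[len(ref_core)]
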