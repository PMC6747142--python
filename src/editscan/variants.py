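"""Multi-caller variant consensus with control subtraction.

Whole-genome discovery of editing-induced mutations is noisy: any single
caller reports background specific to its error model, and the same indel
can be written at different positions by different callers. This module
normalizes calls to a canonical left-aligned representation, intersects
callers (SNVs and indels each need support from a configurable number of
programs, SVs from both SV callers within a breakpoint tolerance), enforces
a minimum variant-supporting depth, and finally subtracts variants seen in
wild-type or different-target control plants.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from collections.abc import Mapping
from typing import Optional

__all__ = [
    "VariantCall",
    "ConsensusVariant",
    "ConsensusParams",
    "ReferenceMismatchError",
    "normalize_variant",
    "build_consensus",
    "subtract_controls",
    "as_fetcher",
    "read_caller_vcf",
    "read_consensus_vcf",
    "write_consensus_vcf",
    "write_consensus_tsv",
]


class ReferenceMismatchError(ValueError):
    """A call's REF allele disagrees with the reference sequence."""


def classify(ref: str, alt: str, sv_type: Optional[str] = None) -> str:
    if sv_type is not None:
        return "sv"
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(alt) > len(ref):
        return "ins"
    if len(ref) > len(alt):
        return "del"
    raise ValueError(f"unsupported allele pair {ref}>{alt} (MNV?)")


@dataclasses.dataclass(frozen=True)
class VariantCall:
    """One record from one caller. ``pos`` is 1-based (VCF convention)."""

    contig: str
    pos: int
    ref: str
    alt: str
    caller: str
    alt_depth: int = 0
    total_depth: int = 0
    sv_end: Optional[int] = None
    sv_type: Optional[str] = None

    def __post_init__(self):
        if self.alt_depth < 0 or self.total_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.sv_type is not None and (self.sv_end is None or self.sv_end < self.pos):
            raise ValueError("SV requires sv_end >= pos")

    @property
    def vclass(self) -> str:
        return classify(self.ref, self.alt, self.sv_type)

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclasses.dataclass(frozen=True)
class ConsensusVariant:
    """A normalized variant with its supporting-caller set."""

    contig: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    max_alt_depth: int
    total_depth: int = 0
    sv_end: Optional[int] = None
    sv_type: Optional[str] = None

    @property
    def vclass(self) -> str:
        return classify(self.ref, self.alt, self.sv_type)

    @property
    def sv_length(self) -> Optional[int]:
        if self.sv_type is None:
            return None
        return self.sv_end - self.pos

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def sort_key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt, self.sv_type or "")


@dataclasses.dataclass(frozen=True)
class ConsensusParams:
    snv_min_callers: int = 2
    indel_min_callers: int = 2
    sv_min_callers: int = 2
    min_depth: int = 2
    sv_max_len: int = 10_000
    sv_breakpoint_tol: int = 10
    known_callers: Optional[frozenset[str]] = None


def as_fetcher(reference):
    """Coerce ``reference`` into ``fetch(contig, start0, end0) -> str``.

    Accepts a callable, a mapping name->sequence, a pysam.FastaFile, or a
    pyfaidx.Fasta.
    """
    if callable(reference):
        return reference
    if isinstance(reference, Mapping):
        return lambda c, s, e: reference[c][s:e]
    if hasattr(reference, "fetch"):
        return lambda c, s, e: reference.fetch(c, s, e)
    return lambda c, s, e: str(reference[c][s:e])


def normalize_variant(v: VariantCall, reference) -> VariantCall:
    """Left-align and trim a variant to its canonical minimal form.

    Shared suffix then prefix bases are removed (one anchor base is kept for
    indels) and indels are shifted as far left as the reference allows.
    SVs pass through unchanged. Idempotent.
    """
    fetch = as_fetcher(reference)
    if v.sv_type is not None:
        return v
    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    obs = fetch(v.contig, pos - 1, pos - 1 + len(ref)).upper()
    if obs != ref:
        raise ReferenceMismatchError(
            f"{v.contig}:{pos} REF {ref!r} != reference {obs!r}"
        )
    if ref == alt:
        raise ValueError("REF and ALT are identical")
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            continue
        if len(ref) == 0 or len(alt) == 0:
            if pos == 1:
                # contig start: anchor on the base following the ref allele
                base = fetch(v.contig, len(ref), len(ref) + 1).upper()
                ref, alt = ref + base, alt + base
                break
            base = fetch(v.contig, pos - 2, pos - 1).upper()
            pos -= 1
            ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return dataclasses.replace(v, pos=pos, ref=ref, alt=alt)


def _sv_cluster(calls: list[VariantCall], tol: int):
    """Greedy single-linkage-to-representative clustering of SV calls."""
    clusters: list[list[VariantCall]] = []
    for c in sorted(calls, key=lambda x: (x.contig, x.pos, x.sv_end, x.caller)):
        placed = False
        for cl in clusters:
            rep = cl[0]
            if (
                rep.contig == c.contig
                and rep.sv_type == c.sv_type
                and abs(rep.pos - c.pos) <= tol
                and abs(rep.sv_end - c.sv_end) <= tol
            ):
                cl.append(c)
                placed = True
                break
        if not placed:
            clusters.append([c])
    return clusters


def build_consensus(
    calls_by_caller: Mapping[str, list[VariantCall]],
    params: ConsensusParams = ConsensusParams(),
) -> list[ConsensusVariant]:
    """Merge normalized calls across callers and apply the consensus filters.

    SNVs need ``snv_min_callers`` supporting programs, indels
    ``indel_min_callers``, SVs ``sv_min_callers`` (matched with breakpoint
    wobble ``sv_breakpoint_tol`` and identical SV type); every retained
    variant needs supporting depth >= ``min_depth`` in at least one caller,
    and SVs longer than ``sv_max_len`` are dropped. Output is sorted and
    deterministic.
    """
    if params.known_callers is not None:
        unknown = set(calls_by_caller) - set(params.known_callers)
        if unknown:
            raise ValueError(f"unknown caller identifier(s): {sorted(unknown)}")

    small: dict[tuple, list[VariantCall]] = defaultdict(list)
    svs: list[VariantCall] = []
    for caller, calls in calls_by_caller.items():
        for c in calls:
            if c.caller != caller:
                raise ValueError(
                    f"call attributed to {c.caller!r} grouped under {caller!r}"
                )
            if c.vclass == "sv":
                svs.append(c)
            else:
                small[c.key].append(c)

    out: list[ConsensusVariant] = []
    for key, group in small.items():
        callers = frozenset(c.caller for c in group)
        vclass = group[0].vclass
        need = params.snv_min_callers if vclass == "snv" else params.indel_min_callers
        if len(callers) < need:
            continue
        best = max(group, key=lambda c: (c.alt_depth, c.total_depth))
        if best.alt_depth < params.min_depth:
            continue
        out.append(
            ConsensusVariant(
                contig=key[0], pos=key[1], ref=key[2], alt=key[3],
                callers=callers, max_alt_depth=best.alt_depth,
                total_depth=best.total_depth,
            )
        )

    for cl in _sv_cluster(svs, params.sv_breakpoint_tol):
        callers = frozenset(c.caller for c in cl)
        if len(callers) < params.sv_min_callers:
            continue
        rep = cl[0]
        if rep.sv_end - rep.pos > params.sv_max_len:
            continue
        best = max(cl, key=lambda c: (c.alt_depth, c.total_depth))
        if best.alt_depth < params.min_depth:
            continue
        out.append(
            ConsensusVariant(
                contig=rep.contig, pos=rep.pos, ref=rep.ref, alt=rep.alt,
                callers=callers, max_alt_depth=best.alt_depth,
                total_depth=best.total_depth, sv_end=rep.sv_end,
                sv_type=rep.sv_type,
            )
        )

    out.sort(key=lambda v: v.sort_key)
    return out


def subtract_controls(
    consensus: list[ConsensusVariant],
    controls: list[list[ConsensusVariant]],
    sv_breakpoint_tol: int = 10,
) -> list[ConsensusVariant]:
    """Drop every variant also present in any control set.

    Small variants match on exact normalized (contig, pos, ref, alt); SVs
    match a control SV of the same type within the breakpoint tolerance.
    """
    small_keys = set()
    control_svs = []
    for ctrl in controls:
        for v in ctrl:
            if v.vclass == "sv":
                control_svs.append(v)
            else:
                small_keys.add(v.key)

    def in_controls(v: ConsensusVariant) -> bool:
        if v.vclass != "sv":
            return v.key in small_keys
        return any(
            c.contig == v.contig
            and c.sv_type == v.sv_type
            and abs(c.pos - v.pos) <= sv_breakpoint_tol
            and abs(c.sv_end - v.sv_end) <= sv_breakpoint_tol
            for c in control_svs
        )

    return [v for v in consensus if not in_controls(v)]


# ---------------------------------------------------------------------------
# VCF / TSV I/O (pysam-backed)
# ---------------------------------------------------------------------------

def read_caller_vcf(path, caller: str) -> list[VariantCall]:
    """Read one caller's VCF; multi-allelic records are split into biallelic
    calls; records outside the {snv, ins, del, sv} classes are skipped."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sv_type = rec.info.get("SVTYPE")
            if sv_type is not None:
                calls.append(
                    VariantCall(
                        contig=rec.contig, pos=rec.pos, ref=rec.ref,
                        alt=rec.alts[0] if rec.alts else "<%s>" % sv_type,
                        caller=caller,
                        alt_depth=_alt_depth(rec, 0),
                        total_depth=_total_depth(rec),
                        sv_end=rec.stop, sv_type=str(sv_type),
                    )
                )
                continue
            for i, alt in enumerate(rec.alts or ()):
                if alt.startswith("<") or alt == "*":
                    continue
                try:
                    classify(rec.ref, alt)
                except ValueError:
                    warnings.warn(
                        f"skipping unsupported record {rec.contig}:{rec.pos} "
                        f"{rec.ref}>{alt}"
                    )
                    continue
                calls.append(
                    VariantCall(
                        contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                        caller=caller, alt_depth=_alt_depth(rec, i),
                        total_depth=_total_depth(rec),
                    )
                )
    return calls


def _alt_depth(rec, alt_index: int) -> int:
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
            return int(ad[alt_index + 1])
    ao = rec.info.get("AO")
    if ao is not None:
        return int(ao[alt_index] if isinstance(ao, tuple) else ao)
    return 0


def _total_depth(rec) -> int:
    for sample in rec.samples.values():
        dp = sample.get("DP")
        if dp is not None:
            return int(dp)
    dp = rec.info.get("DP")
    return int(dp) if dp is not None else 0


def _consensus_header(contig_lengths: Mapping[str, int]):
    import pysam

    h = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        h.contigs.add(name, length=length)
    h.info.add("CALLERS", "1", "String", "Supporting callers (|-separated)")
    h.info.add("MAXAD", "1", "Integer", "Maximum variant-supporting depth")
    h.info.add("TDP", "1", "Integer", "Total depth at the max-support record")
    h.info.add("SVTYPE", "1", "String", "Structural variant type")
    h.info.add("END", "1", "Integer", "Structural variant end (1-based)")
    return h


def write_consensus_vcf(path, variants: list[ConsensusVariant],
                        contig_lengths: Mapping[str, int]) -> None:
    import pysam

    h = _consensus_header(contig_lengths)
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for v in sorted(variants, key=lambda x: x.sort_key):
            rec = vf.new_record(
                contig=v.contig, start=v.pos - 1,
                stop=(v.sv_end if v.sv_type else v.pos - 1 + len(v.ref)),
                alleles=(v.ref, v.alt),
            )
            rec.info["CALLERS"] = "|".join(sorted(v.callers))
            rec.info["MAXAD"] = v.max_alt_depth
            rec.info["TDP"] = v.total_depth
            if v.sv_type:
                rec.info["SVTYPE"] = v.sv_type
            vf.write(rec)


def read_consensus_vcf(path) -> list[ConsensusVariant]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sv_type = rec.info.get("SVTYPE")
            out.append(
                ConsensusVariant(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref,
                    alt=rec.alts[0],
                    callers=frozenset(str(rec.info["CALLERS"]).split("|")),
                    max_alt_depth=int(rec.info["MAXAD"]),
                    total_depth=int(rec.info.get("TDP", 0)),
                    sv_end=rec.stop if sv_type else None,
                    sv_type=str(sv_type) if sv_type else None,
                )
            )
    return out


def write_consensus_tsv(path, variants: list[ConsensusVariant]) -> None:
    import pandas as pd

    rows = [
        {
            "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "class": v.vclass, "callers": "|".join(sorted(v.callers)),
            "max_alt_depth": v.max_alt_depth, "total_depth": v.total_depth,
            "sv_type": v.sv_type or "", "sv_end": v.sv_end or "",
        }
        for v in sorted(variants, key=lambda x: x.sort_key)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
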