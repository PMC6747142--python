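"""Editing-site detection from filtered consensus variants.

The headline step of the workflow: for every consensus variant that
survived caller intersection and control subtraction, extract the reference
sequence 50 nt upstream and 50 nt downstream of the mutation (the flank
covers where CRISPR/Cas9 indels start and end relative to the cut) and
search that candidate window for guide matches. A variant whose window
contains the designed locus is an on-target call; a window with a qualifying
match elsewhere is an off-target call; variants with no qualifying match for
any guide are background (spontaneous or somaclonal) mutations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional

from .guides import GuideTarget, MatchHit, MatchParams, reverse_complement, scan_sequence
from .variants import ConsensusVariant, as_fetcher

__all__ = [
    "CandidateWindow",
    "EditingSiteCall",
    "extract_window",
    "detect_editing_sites",
    "site_mutation_frequency",
    "summarize_calls",
    "write_sites_tsv",
    "write_summary_json",
]


@dataclasses.dataclass(frozen=True)
class CandidateWindow:
    contig: str
    start: int
    end: int
    source_variant: ConsensusVariant
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")


@dataclasses.dataclass(frozen=True)
class EditingSiteCall:
    variant: ConsensusVariant
    guide: Optional[str]
    hit: Optional[MatchHit]
    label: str  # on_target | off_target | background
    mismatches: Optional[int]
    repeat_flag: bool = False


def _footprint(variant: ConsensusVariant) -> tuple[int, int]:
    """0-based half-open reference footprint of the mutated bases.

    SNV: the substituted base. Insertion: its anchor base. Deletion: the
    deleted bases (anchor excluded).
    """
    pos0 = variant.pos - 1
    vclass = variant.vclass
    if vclass == "del":
        return pos0 + 1, pos0 + len(variant.ref)
    if vclass == "sv":
        return pos0, variant.sv_end
    return pos0, pos0 + 1


def extract_window(
    variant: ConsensusVariant,
    reference,
    flank: int = 50,
    contig_length: Optional[int] = None,
) -> CandidateWindow:
    """Reference window of ``flank`` nt either side of the variant footprint,
    clipped at contig edges."""
    fetch = as_fetcher(reference)
    fs, fe = _footprint(variant)
    start = max(0, fs - flank)
    try:
        seq = fetch(variant.contig, start, fe + flank)
    except KeyError as exc:
        raise KeyError(f"contig {variant.contig!r} absent from reference") from exc
    if contig_length is not None:
        seq = seq[: max(0, contig_length - start)]
    end = start + len(seq)
    return CandidateWindow(
        contig=variant.contig, start=start, end=end,
        source_variant=variant, sequence=seq,
    )


def _sv_windows(variant, reference, flank, contig_length):
    """SVs are windowed at both breakpoints (editing-site identity is asked
    at either end)."""
    fetch = as_fetcher(reference)
    out = []
    for bp in (variant.pos - 1, variant.sv_end - 1):
        start = max(0, bp - flank)
        seq = fetch(variant.contig, start, bp + 1 + flank)
        if contig_length is not None:
            seq = seq[: max(0, contig_length - start)]
        out.append(
            CandidateWindow(
                contig=variant.contig, start=start, end=start + len(seq),
                source_variant=variant, sequence=seq,
            )
        )
    return out


def _best_hit_in_window(window: CandidateWindow, guide: GuideTarget,
                        params: MatchParams) -> Optional[MatchHit]:
    hits = scan_sequence(window.sequence, guide, params, contig=window.contig)
    if not hits:
        return None
    fs, fe = _footprint(window.source_variant)

    def shifted(h: MatchHit) -> MatchHit:
        return dataclasses.replace(
            h,
            start=h.start + window.start,
            end=h.end + window.start,
            cut_position=h.cut_position + window.start,
        )

    def rank(h: MatchHit):
        cut_dist = max(fs - (h.cut_position + 1), h.cut_position - (fe - 1), 0)
        return (h.mismatches, h.bulge != "none", cut_dist, h.start, h.strand == "-")

    return min((shifted(h) for h in hits), key=rank)


def _count_occurrences(reference_seqs: dict[str, str], probe: str) -> int:
    """Exact occurrence count of probe (either strand) across the reference."""
    rc = reverse_complement(probe)
    n = 0
    for seq in reference_seqs.values():
        n += seq.count(probe)
        if rc != probe:
            n += seq.count(rc)
    return n


def detect_editing_sites(
    variants,
    guides: list[GuideTarget],
    reference: dict[str, str],
    params: MatchParams = MatchParams(),
    flank: int = 50,
    flag_repeats: bool = True,
) -> list[EditingSiteCall]:
    """Label every surviving variant as on-target, off-target or background.

    One call is emitted per (variant, guide) pair that has a qualifying hit
    in the variant's candidate window (best hit: fewest mismatches, then
    bulge-free, then cut position nearest the variant, then leftmost);
    variants with no hit for any guide yield a single background call.
    ``reference`` must be a mapping contig -> sequence (the repeat flag
    needs whole-genome text search).
    """
    ref_upper = {k: v.upper() for k, v in reference.items()}
    calls: list[EditingSiteCall] = []
    for variant in sorted(variants, key=lambda v: v.sort_key):
        clen = len(ref_upper[variant.contig])
        if variant.vclass == "sv":
            windows = _sv_windows(variant, ref_upper, flank, clen)
        else:
            windows = [extract_window(variant, ref_upper, flank, clen)]
        matched = False
        for guide in guides:
            best = None
            best_window = None
            for w in windows:
                h = _best_hit_in_window(w, guide, params)
                if h is None:
                    continue
                if best is None or (h.mismatches, h.bulge != "none", h.start) < (
                    best.mismatches, best.bulge != "none", best.start
                ):
                    best, best_window = h, w
            if best is None:
                continue
            matched = True
            label = "off_target"
            if guide.designed_locus is not None:
                lc, ls, le, _ = guide.designed_locus
                if lc == variant.contig and best.start < le and best.end > ls:
                    label = "on_target"
            repeat = (
                flag_repeats
                and _count_occurrences(ref_upper, best_window.sequence) > 1
            )
            calls.append(
                EditingSiteCall(
                    variant=variant, guide=guide.name, hit=best, label=label,
                    mismatches=best.mismatches, repeat_flag=repeat,
                )
            )
        if not matched:
            calls.append(
                EditingSiteCall(
                    variant=variant, guide=None, hit=None,
                    label="background", mismatches=None,
                )
            )
    return calls


def site_mutation_frequency(variant: ConsensusVariant) -> float:
    """Supporting-read fraction at the site (the WGS mutation-frequency
    column). NaN flags a zero-depth record."""
    if variant.total_depth == 0:
        return math.nan
    return variant.max_alt_depth / variant.total_depth


def summarize_calls(calls: list[EditingSiteCall]) -> dict:
    """Per-guide on/off-target counts plus the background count."""
    summary: dict = {"background": 0, "guides": {}}
    for c in calls:
        if c.label == "background":
            summary["background"] += 1
            continue
        g = summary["guides"].setdefault(c.guide, {"on_target": 0, "off_target": 0})
        g[c.label] += 1
    return summary


def write_sites_tsv(path, calls: list[EditingSiteCall]) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        freq = site_mutation_frequency(c.variant)
        rows.append(
            {
                "contig": c.variant.contig,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "class": c.variant.vclass,
                "guide": c.guide or "",
                "label": c.label,
                "mismatches": "" if c.mismatches is None else c.mismatches,
                "bulge": c.hit.bulge if c.hit else "",
                "hit_start": c.hit.start if c.hit else "",
                "hit_end": c.hit.end if c.hit else "",
                "strand": c.hit.strand if c.hit else "",
                "mutation_frequency": "" if math.isnan(freq) else round(freq, 4),
                "repeat_flag": int(c.repeat_flag),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(path, calls: list[EditingSiteCall]) -> None:
    with open(path, "w") as fh:
        json.dump(summarize_calls(calls), fh, indent=2)
        fh.write("\n")
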