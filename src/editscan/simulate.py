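"""Deterministic synthetic data for every pipeline stage.

These generators define the study conditions under which the toolkit is
exercised end-to-end without any external download: a random reference
genome with implanted on-/off-target sites of chosen mismatch/bulge
structure, per-caller VCFs with configurable sensitivity and background,
amplicon read sets with a set editing efficiency and indel spectrum, and
digested-genome read-start pileups with blunt-cut signatures.

Every generator is reproducible for a fixed seed, and every truth record is
re-validated against the module that will consume it before being returned
(implants are verified with the production scanner; accidental background
matches are re-randomized away so truth tables are exact).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .amplicon import AmpliconSpec, MutationRecord
from .guides import GuideTarget, MatchParams, reverse_complement, scan_sequence
from .variants import VariantCall, normalize_variant

__all__ = [
    "TruthTable",
    "TruthVariant",
    "ImplantedSite",
    "make_reference",
    "write_fasta",
    "implant_guide_sites",
    "edit_variants_for_sites",
    "simulate_caller_vcfs",
    "write_caller_vcf",
    "simulate_amplicon_reads",
    "write_fastq",
    "simulate_digenome_readstarts",
    "write_alignment_tsv",
    "DEFAULT_CALLERS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: which variant classes each simulated caller reports (mirrors a typical
#: three-SNV-caller / three-indel-caller / two-SV-caller WGS setup)
DEFAULT_CALLERS: dict[str, frozenset] = {
    "lofreq": frozenset({"snv"}),
    "mutect2": frozenset({"snv", "ins", "del"}),
    "varscan2": frozenset({"snv", "ins", "del"}),
    "pindel": frozenset({"ins", "del", "sv"}),
    "delly": frozenset({"sv"}),
}


@dataclasses.dataclass(frozen=True)
class ImplantedSite:
    contig: str
    start: int  # 0-based start of protospacer+PAM footprint
    end: int
    strand: str
    guide: str
    mismatches: int
    bulge: str  # none | dna_bulge | rna_bulge

    @property
    def cut(self) -> int:
        """Blunt cut between ``cut`` and ``cut + 1`` (forward coords)."""
        return self.end - 7 if self.strand == "+" else self.start + 5


@dataclasses.dataclass(frozen=True)
class TruthVariant:
    contig: str
    pos: int  # 1-based, normalized
    ref: str
    alt: str
    frequency: float = 0.5

    @property
    def key(self):
        return (self.contig, self.pos, self.ref, self.alt)

    def to_consensus(self, alt_depth: int = 10, total_depth: int = 20):
        """View this truth record as a ConsensusVariant (e.g. to feed the
        detection stage directly, bypassing caller simulation)."""
        from .variants import ConsensusVariant

        return ConsensusVariant(
            contig=self.contig, pos=self.pos, ref=self.ref, alt=self.alt,
            callers=frozenset({"truth"}), max_alt_depth=alt_depth,
            total_depth=total_depth,
        )


@dataclasses.dataclass
class TruthTable:
    sites: list[ImplantedSite] = dataclasses.field(default_factory=list)
    variants: list[TruthVariant] = dataclasses.field(default_factory=list)
    efficiencies: dict = dataclasses.field(default_factory=dict)
    cleavage_sites: list = dataclasses.field(default_factory=list)

    def designed_locus_for(self, guide_name: str) -> Optional[tuple]:
        """Locus of the first exact (0-mismatch, bulge-free) implant — the
        natural choice of designed on-target site."""
        for s in self.sites:
            if s.guide == guide_name and s.mismatches == 0 and s.bulge == "none":
                return (s.contig, s.start, s.end, s.strand)
        return None

    def to_dict(self) -> dict:
        return {
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "efficiencies": self.efficiencies,
            "cleavage_sites": [list(c) for c in self.cleavage_sites],
        }


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def make_reference(seed: int, n_contigs: int = 1, length: int = 10_000,
                   gc: float = 0.36) -> dict[str, str]:
    """Random i.i.d. reference with a GC dial (no repeat structure).

    The default GC of 0.36 matches the Arabidopsis genome; contigs are named
    ``contig_1`` ... ``contig_n``.
    """
    if length < 200:
        raise ValueError("contig length must be >= 200")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    p = [at, gcp, gcp, at]  # A C G T
    out = {}
    for i in range(n_contigs):
        arr = rng.choice(_BASES, size=length, p=p)
        out[f"contig_{i + 1}"] = arr.tobytes().decode()
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70,
                build_index: bool = True) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    if build_index:
        import pyfaidx

        pyfaidx.Faidx(str(path))


# ---------------------------------------------------------------------------
# site implantation
# ---------------------------------------------------------------------------

def _random_base(rng, exclude: str = "") -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def _concretize_pam(rng, pattern: str) -> str:
    from .guides import IUPAC

    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in pattern)


def _build_site_seq(rng, guide: GuideTarget, mismatches: int, bulge: str) -> str:
    proto = list(guide.protospacer)
    L = len(proto)
    if mismatches > L:
        raise ValueError("mismatches cannot exceed protospacer length")
    for i in rng.choice(L, size=mismatches, replace=False):
        proto[i] = _random_base(rng, exclude=proto[i])
    if bulge == "dna_bulge":
        g = int(rng.integers(1, L))  # extra genomic base strictly inside
        proto.insert(g, _random_base(rng))
    elif bulge == "rna_bulge":
        g = int(rng.integers(1, L - 1))  # genomic base omitted
        del proto[g]
    elif bulge != "none":
        raise ValueError(f"unknown bulge kind {bulge!r}")
    pam = _concretize_pam(rng, sorted(guide.pam_patterns)[0])
    site = "".join(proto) + pam
    return site


def implant_guide_sites(
    reference: dict[str, str],
    guide: GuideTarget,
    specs: list[tuple[int, str, str]],
    seed: int = 0,
    params: MatchParams = MatchParams(),
    margin: int = 150,
    min_separation: int = 500,
    max_rounds: int = 60,
) -> tuple[dict[str, str], TruthTable]:
    """Implant one site per ``(mismatches, bulge, strand)`` spec.

    Postconditions are enforced by construction plus a validation loop: each
    implanted locus is recovered by :func:`scan_sequence` with exactly the
    requested mismatch count and bulge state, and no accidental extra site
    within ``params`` exists anywhere in the returned genome (accidental
    background matches are re-randomized until the scan is clean).
    """
    for mm, bulge, strand in specs:
        if bulge != "none" and mm > params.bulge_mismatch_cap:
            raise ValueError(
                "bulged implant cannot carry more mismatches than "
                "bulge_mismatch_cap"
            )
        if bulge == "none" and mm > params.max_mismatches:
            raise ValueError("implant mismatches exceed params.max_mismatches")
        if strand not in "+-":
            raise ValueError("strand must be + or -")

    rng = np.random.default_rng(seed)
    seqs = {k: v.upper() for k, v in reference.items()}
    names = list(seqs)

    def place(site_seq: str, occupied: list[tuple[str, int, int]]):
        for _ in range(200):
            contig = names[rng.integers(len(names))]
            lo, hi = margin, len(seqs[contig]) - margin - len(site_seq)
            if hi <= lo:
                continue
            p = int(rng.integers(lo, hi))
            if all(
                c != contig or p + len(site_seq) + min_separation <= s
                or p >= e + min_separation
                for c, s, e in occupied
            ):
                return contig, p
        raise ValueError("not enough non-overlapping room to implant sites")

    for round_no in range(max_rounds):
        placements = []  # (spec, contig, start, site_len)
        occupied: list[tuple[str, int, int]] = []
        work = {k: v for k, v in seqs.items()}
        ok = True
        for mm, bulge, strand in specs:
            site = _build_site_seq(rng, guide, mm, bulge)
            if strand == "-":
                site = reverse_complement(site)
            contig, p = place(site, occupied)
            work[contig] = work[contig][:p] + site + work[contig][p + len(site):]
            occupied.append((contig, p, p + len(site)))
            placements.append(((mm, bulge, strand), contig, p, len(site)))

        # validation + background sanitization
        for _ in range(30):
            extras = []
            truth_ok = True
            found_truth = set()
            for contig in names:
                for h in scan_sequence(work[contig], guide, params, contig=contig):
                    match = None
                    for spec, c, p, slen in placements:
                        if c == contig and h.start == p and h.end == p + slen:
                            match = (spec, c, p, slen)
                            break
                    if match is None:
                        extras.append((contig, h.start, h.end))
                    else:
                        (mm, bulge, strand), *_ = match
                        if (h.mismatches, h.bulge, h.strand) != (mm, bulge, strand):
                            truth_ok = False
                        found_truth.add((match[1], match[2]))
            if not truth_ok or len(found_truth) != len(placements):
                ok = False
                break
            if not extras:
                break
            # overwrite accidental matches with fresh random sequence
            for contig, s, e in extras:
                if any(
                    c == contig and s < oe and e > os_
                    for c, os_, oe in occupied
                ):
                    ok = False  # accidental hit tangled with an implant
                    break
                repl = rng.choice(_BASES, size=e - s).tobytes().decode()
                work[contig] = work[contig][:s] + repl + work[contig][e:]
            if not ok:
                break
        else:
            ok = False  # sanitization did not converge
        if not ok:
            continue

        truth = TruthTable(
            sites=[
                ImplantedSite(
                    contig=c, start=p, end=p + slen, strand=spec[2],
                    guide=guide.name, mismatches=spec[0], bulge=spec[1],
                )
                for spec, c, p, slen in placements
            ]
        )
        return work, truth
    raise RuntimeError("could not implant sites satisfying all specs")


# ---------------------------------------------------------------------------
# truth edit variants + per-caller VCFs
# ---------------------------------------------------------------------------

def edit_variants_for_sites(
    reference: dict[str, str],
    sites: list[ImplantedSite],
    seed: int = 0,
    frequency: float = 0.5,
) -> list[TruthVariant]:
    """One small indel per implanted site, at its blunt cut — the dominant
    CRISPR/Cas9 repair outcome. Alternates 1-nt insertions and deletions;
    returned normalized (left-aligned)."""
    rng = np.random.default_rng(seed)
    out = []
    for i, site in enumerate(sites):
        seq = reference[site.contig]
        cut = site.cut
        anchor = seq[cut]
        if i % 2 == 0:
            call = VariantCall(
                contig=site.contig, pos=cut + 1, ref=anchor,
                alt=anchor + _random_base(rng), caller="truth",
            )
        else:
            call = VariantCall(
                contig=site.contig, pos=cut + 1, ref=anchor + seq[cut + 1],
                alt=anchor, caller="truth",
            )
        norm = normalize_variant(call, reference)
        out.append(
            TruthVariant(
                contig=norm.contig, pos=norm.pos, ref=norm.ref, alt=norm.alt,
                frequency=frequency,
            )
        )
    return out


def random_snv_variants(
    reference: dict[str, str],
    n: int,
    seed: int = 0,
    frequency: float = 0.5,
    exclude: Optional[list[tuple[str, int, int]]] = None,
) -> list[TruthVariant]:
    """Random spontaneous SNVs (e.g. the shared wild-type variation used to
    exercise control subtraction); ``exclude`` spans (contig, start, end)
    are avoided."""
    rng = np.random.default_rng(seed)
    exclude = exclude or []
    contigs = list(reference)
    out = []
    used = set()
    while len(out) < n:
        contig = contigs[rng.integers(len(contigs))]
        pos = int(rng.integers(1, len(reference[contig]) + 1))
        if (contig, pos) in used:
            continue
        if any(c == contig and s < pos <= e for c, s, e in exclude):
            continue
        ref = reference[contig][pos - 1]
        if ref not in "ACGT":
            continue
        used.add((contig, pos))
        out.append(
            TruthVariant(
                contig=contig, pos=pos, ref=ref,
                alt=_random_base(rng, exclude=ref), frequency=frequency,
            )
        )
    out.sort(key=lambda v: v.key)
    return out


def _denormalize_right(contig_seq: str, pos: int, ref: str, alt: str, rng):
    """Right-shift an indel through its repeat context (if any) so different
    simulated callers disagree on representation."""
    shifts = int(rng.integers(0, 4))
    for _ in range(shifts):
        p0 = pos - 1  # anchor index, 0-based
        if len(ref) > len(alt):  # deletion of ref[1:] at p0+1 .. p0+k
            k = len(ref) - 1
            if p0 + k + 1 >= len(contig_seq):
                break
            if contig_seq[p0 + 1] != contig_seq[p0 + k + 1]:
                break
            pos += 1
            ref = contig_seq[p0 + 1 : p0 + 1 + k + 1]
            alt = contig_seq[p0 + 1]
        elif len(alt) > len(ref):  # insertion of alt[1:] after p0
            ins = alt[1:]
            if p0 + 1 >= len(contig_seq) or ins[0] != contig_seq[p0 + 1]:
                break
            pos += 1
            ins = ins[1:] + ins[0]
            ref = contig_seq[p0 + 1]
            alt = ref + ins
        else:
            break
    return pos, ref, alt


def simulate_caller_vcfs(
    truth_variants: list[TruthVariant],
    reference: dict[str, str],
    callers: dict[str, frozenset] = DEFAULT_CALLERS,
    sensitivity=1.0,
    n_background: int = 0,
    mean_depth: float = 50.0,
    seed: int = 0,
    denormalize: bool = True,
) -> dict[str, list[VariantCall]]:
    """Per-caller call sets over the truth set.

    Each caller reports a truth variant of a class it handles with
    probability ``sensitivity`` (scalar or per-caller mapping); background
    variants (SNVs, each private to a single random caller) are added on
    top; indel representations are randomly right-shifted to exercise
    normalization. Supporting depth of emitted truth variants is kept >= 2
    so the simulated calls are detectable by construction.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(sensitivity, dict):
        sensitivity = {c: float(sensitivity) for c in callers}
    out: dict[str, list[VariantCall]] = {c: [] for c in callers}

    def depths(freq):
        total = max(4, int(rng.poisson(mean_depth)))
        alt = int(rng.binomial(total, freq))
        alt = min(total, max(2, alt))
        return alt, total

    for tv in truth_variants:
        vclass = VariantCall(
            contig=tv.contig, pos=tv.pos, ref=tv.ref, alt=tv.alt, caller="x"
        ).vclass
        for caller, classes in callers.items():
            if vclass not in classes:
                continue
            if rng.random() > sensitivity[caller]:
                continue
            alt_d, tot_d = depths(tv.frequency)
            pos, ref, alt = tv.pos, tv.ref, tv.alt
            if denormalize and vclass in ("ins", "del") and rng.random() < 0.5:
                pos, ref, alt = _denormalize_right(
                    reference[tv.contig], pos, ref, alt, rng
                )
            out[caller].append(
                VariantCall(
                    contig=tv.contig, pos=pos, ref=ref, alt=alt,
                    caller=caller, alt_depth=alt_d, total_depth=tot_d,
                )
            )

    names = sorted(callers)
    contigs = list(reference)
    used = {(tv.contig, tv.pos) for tv in truth_variants}
    for _ in range(n_background):
        for _attempt in range(100):
            contig = contigs[rng.integers(len(contigs))]
            pos = int(rng.integers(1, len(reference[contig]) + 1))
            if (contig, pos) not in used:
                used.add((contig, pos))
                break
        ref = reference[contig][pos - 1]
        if ref not in "ACGT":
            continue
        alt = _random_base(rng, exclude=ref)
        caller = names[rng.integers(len(names))]
        tot = max(4, int(rng.poisson(mean_depth)))
        out[caller].append(
            VariantCall(
                contig=contig, pos=pos, ref=ref, alt=alt, caller=caller,
                alt_depth=int(rng.binomial(tot, 0.3)), total_depth=tot,
            )
        )
    for calls in out.values():
        calls.sort(key=lambda c: (c.contig, c.pos, c.ref, c.alt))
    return out


def write_caller_vcf(path, calls: list[VariantCall],
                     contig_lengths: dict[str, int]) -> None:
    """Write simulated caller output as a one-sample VCF with AD/DP."""
    import pysam

    h = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        h.contigs.add(name, length=length)
    h.formats.add("GT", "1", "String", "Genotype")
    h.formats.add("AD", "R", "Integer", "Allele depths")
    h.formats.add("DP", "1", "Integer", "Total depth")
    h.info.add("SVTYPE", "1", "String", "Structural variant type")
    h.info.add("END", "1", "Integer", "Structural variant end")
    h.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for c in sorted(calls, key=lambda x: (x.contig, x.pos, x.ref, x.alt)):
            rec = vf.new_record(
                contig=c.contig, start=c.pos - 1,
                stop=(c.sv_end if c.sv_type else c.pos - 1 + len(c.ref)),
                alleles=(c.ref, c.alt),
            )
            if c.sv_type:
                rec.info["SVTYPE"] = c.sv_type
            rec.samples["SAMPLE"]["GT"] = (0, 1)
            rec.samples["SAMPLE"]["AD"] = (c.total_depth - c.alt_depth, c.alt_depth)
            rec.samples["SAMPLE"]["DP"] = c.total_depth
            vf.write(rec)


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


def _apply_record(spec: AmpliconSpec, record: MutationRecord, ins_seq: str = "") -> str:
    """Apply one PAM-relative indel to the amplicon sequence."""
    amp = spec.amplicon_seq
    if record.kind == "deletion":
        a = spec.from_pam_relative(record.start_rel)
        b = spec.from_pam_relative(record.end_rel)
        lo, hi = min(a, b), max(a, b)
        if hi - lo + 1 != record.size:
            raise ValueError("deletion span inconsistent with size")
        return amp[:lo] + amp[hi + 1 :]
    ins = ins_seq or "A" * record.size
    if len(ins) != record.size:
        raise ValueError("inserted sequence length must equal size")
    anchor = spec.from_pam_relative(record.start_rel)
    if spec.strand == "+":
        return amp[:anchor] + ins + amp[anchor:]
    return amp[: anchor + 1] + reverse_complement(ins) + amp[anchor + 1 :]


def simulate_amplicon_reads(
    spec: AmpliconSpec,
    efficiency: float,
    spectrum: list[tuple[MutationRecord, float]],
    n_reads: int = 10_000,
    subst_error_rate: float = 0.001,
    seed: int = 0,
    ins_seqs: Optional[dict[int, str]] = None,
) -> tuple[list[str], dict]:
    """Full-length amplicon reads with a set editing efficiency.

    Mutant reads are Bernoulli(``efficiency``); their signatures follow the
    multinomial ``spectrum`` (proportions of mutant reads, summing to 1);
    substitution noise is applied i.i.d. per base at ``subst_error_rate``.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    props = [p for _, p in spectrum]
    if spectrum and abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("spectrum proportions must sum to 1")
    if efficiency > 0 and not spectrum:
        raise ValueError("need a spectrum when efficiency > 0")
    rng = np.random.default_rng(seed)
    templates = [spec.amplicon_seq] + [
        _apply_record(spec, rec, (ins_seqs or {}).get(i, ""))
        for i, (rec, _) in enumerate(spectrum)
    ]
    n_mut = int(rng.binomial(n_reads, efficiency))
    counts = [n_reads - n_mut] + (
        list(rng.multinomial(n_mut, props)) if spectrum else []
    )
    reads: list[str] = []
    for template, k in zip(templates, counts):
        if k == 0:
            continue
        arr = np.tile(np.frombuffer(template.encode(), dtype=np.uint8), (k, 1))
        if subst_error_rate > 0:
            mask = rng.random(arr.shape) < subst_error_rate
            n_err = int(mask.sum())
            if n_err:
                idx = _BYTE_TO_IDX[arr[mask]]
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                arr[mask] = _BASES[(idx + shift) % 4]
        reads.extend(row.tobytes().decode() for row in arr)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = {
        "efficiency": efficiency,
        "n_reads": n_reads,
        "n_mutant": n_mut,
        "signature_counts": {
            i: int(c) for i, c in enumerate(counts[1:])
        },
    }
    return reads, truth


def write_fastq(reads: list[str], path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read_{i}\n{r}\n+\n{'I' * len(r)}\n")


# ---------------------------------------------------------------------------
# digenome read starts
# ---------------------------------------------------------------------------

def simulate_digenome_readstarts(
    reference: dict[str, str],
    cuts: list[tuple[str, int, int, int]],
    background_depth: float = 20.0,
    read_length: int = 100,
    seed: int = 0,
) -> tuple[list[tuple[str, str, int, int]], dict]:
    """Uniform background reads plus clustered read starts at blunt cuts.

    ``cuts`` entries are ``(contig, cut, f_reads, r_reads)``: ``f_reads``
    forward reads start at ``cut + 1`` and ``r_reads`` reverse reads end at
    ``cut``. Returns coordinate-sorted ``(contig, strand, start, end)``
    records and the truth dict.
    """
    rng = np.random.default_rng(seed)
    records = []
    for contig, seq in reference.items():
        L = len(seq)
        if L <= read_length:
            raise ValueError("contigs must be longer than read_length")
        n = int(round(background_depth * L / read_length))
        starts = rng.integers(0, L - read_length, size=n)
        strands = rng.random(n) < 0.5
        for s, fwd in zip(starts, strands):
            records.append((contig, "+" if fwd else "-", int(s), int(s) + read_length))
    for contig, cut, f_reads, r_reads in cuts:
        L = len(reference[contig])
        if not 0 <= cut < L - 1:
            raise ValueError(f"cut {cut} outside contig {contig}")
        for _ in range(f_reads):
            records.append((contig, "+", cut + 1, min(cut + 1 + read_length, L)))
        for _ in range(r_reads):
            records.append((contig, "-", max(cut + 1 - read_length, 0), cut + 1))
    records.sort(key=lambda r: (r[0], r[2], r[3], r[1]))
    truth = {"cuts": [(c, p) for c, p, _, _ in cuts]}
    return records, truth


def write_alignment_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstrand\tstart\tend\n")
        for contig, strand, start, end in records:
            fh.write(f"{contig}\t{strand}\t{start}\t{end}\n")
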