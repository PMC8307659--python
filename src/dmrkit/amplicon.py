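"""Targeted bisulfite-amplicon methylation quantification.

Quantifies per-CpG and mean methylation of a single PCR amplicon from
bisulfite reads, the way a promoter amplicon (e.g. a TRIM25-style design) is
analysed after targeted NGS: reads are placed on the in-silico converted
reference with an ungapped matcher, CpG cytosines are read out as
methylated (C) or unmethylated (T), per-read patterns are aggregated into
epialleles, and conversion efficiency is estimated from non-CpG cytosines.

During alignment every CpG cytosine is a {C, T} wildcard so that methylation
state cannot bias mapping; every other cytosine is expected converted (T on
the top strand, A on the bottom-strand G image), and an unconverted base
simply counts as a mismatch.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class BisulfiteReference:
    """In-silico bisulfite images of an amplicon reference.

    ``cpg_offsets`` are the 0-based positions of the C of every top-strand
    CpG. ``top_image`` has non-CpG C replaced by T; ``bottom_image`` has
    non-CpG G replaced by A (the read-out of a converted bottom strand in
    top-strand coordinates). CpG positions stay wildcards during matching.
    """

    ref_seq: str
    cpg_offsets: np.ndarray
    top_image: np.ndarray  # S1 array, bisulfite-converted top strand
    bottom_image: np.ndarray  # S1 array, converted bottom strand (top coords)
    non_cpg_c: np.ndarray  # offsets of top-strand C outside CpG context
    non_cpg_g: np.ndarray  # offsets of top-strand G outside CpG context

    def __len__(self) -> int:
        return len(self.ref_seq)


@dataclasses.dataclass(frozen=True)
class AlignedRead:
    offset: int
    strand: str  # "top" or "bottom"
    n_mismatch: int
    length: int


@dataclasses.dataclass
class AmpliconProfile:
    """Per-CpG and summary methylation of one amplicon.

    ``mean_meth`` is the depth-weighted mean over CpGs with depth >=
    min_depth; ``mean_meth_unweighted`` averages the same per-CpG fractions
    without weights. ``conversion_efficiency`` = 1 - (unconverted fraction at
    covered non-CpG cytosines).
    """

    ref_name: str
    cpg_positions: np.ndarray
    per_cpg_meth: np.ndarray
    per_cpg_depth: np.ndarray
    depth_ok: np.ndarray
    mean_meth: float
    mean_meth_unweighted: float
    n_reads_used: int
    n_reads_discarded: int
    conversion_efficiency: float


@dataclasses.dataclass(frozen=True)
class EpiallelePattern:
    """One per-read CpG methylation string (M/U/N) and how many reads show it."""

    pattern: str
    count: int


def convert_reference(ref_seq: str) -> BisulfiteReference:
    """Build the top/bottom bisulfite images and the CpG offset list."""
    if not ref_seq:
        raise ValueError("empty reference sequence")
    ref_seq = ref_seq.upper()
    if set(ref_seq) - set("ACGTN"):
        raise ValueError("reference must be over A, C, G, T, N")
    arr = np.frombuffer(ref_seq.encode(), dtype="S1").copy()
    is_c = arr == b"C"
    is_g = arr == b"G"
    cpg = np.zeros(len(arr), dtype=bool)
    cpg[:-1] = is_c[:-1] & is_g[1:]
    cpg_g = np.zeros(len(arr), dtype=bool)
    cpg_g[1:] = cpg[:-1]
    top = arr.copy()
    top[is_c & ~cpg] = b"T"
    bottom = arr.copy()
    bottom[is_g & ~cpg_g] = b"A"
    return BisulfiteReference(
        ref_seq=ref_seq,
        cpg_offsets=np.flatnonzero(cpg).astype(np.int64),
        top_image=top,
        bottom_image=bottom,
        non_cpg_c=np.flatnonzero(is_c & ~cpg).astype(np.int64),
        non_cpg_g=np.flatnonzero(is_g & ~cpg_g).astype(np.int64),
    )


def _read_array(read: str) -> np.ndarray:
    return np.frombuffer(read.upper().encode(), dtype="S1")


def _mismatch_profile(read_arr: np.ndarray, image: np.ndarray, wildcard_mask: np.ndarray) -> np.ndarray:
    """Mismatch count of the read at every ungapped offset.

    ``wildcard_mask`` marks reference positions where both the converted and
    the unconverted base are acceptable (CpG cytosines / guanines).
    """
    L = len(read_arr)
    n_off = len(image) - L + 1
    counts = np.empty(n_off, dtype=np.int64)
    for o in range(n_off):
        win = image[o : o + L]
        wild = wildcard_mask[o : o + L]
        mm = (read_arr != win) & ~(wild & _wildcard_ok(read_arr, win))
        counts[o] = int(mm.sum())
    return counts


def _wildcard_ok(read_arr: np.ndarray, win: np.ndarray) -> np.ndarray:
    # a CpG C matches C or T; a CpG G (bottom image) matches G or A
    c_site = win == b"C"
    g_site = win == b"G"
    return (c_site & ((read_arr == b"C") | (read_arr == b"T"))) | (
        g_site & ((read_arr == b"G") | (read_arr == b"A"))
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def align_read(
    read: str, bref: BisulfiteReference, max_mismatch_frac: float = 0.1
) -> AlignedRead | None:
    """Best ungapped placement of a bisulfite read on the amplicon.

    Tries the top-strand image with the read as-is and the bottom-strand
    image with the reverse-complemented read. Ties prefer the top strand,
    then the leftmost offset. Returns None when the best mismatch fraction
    exceeds ``max_mismatch_frac``.
    """
    read = read.upper()
    L = len(read)
    if L == 0 or L > len(bref):
        return None
    cpg_c_mask = np.zeros(len(bref), dtype=bool)
    cpg_c_mask[bref.cpg_offsets] = True
    cpg_g_mask = np.zeros(len(bref), dtype=bool)
    cpg_g_mask[bref.cpg_offsets + 1] = True
    top_mm = _mismatch_profile(_read_array(read), bref.top_image, cpg_c_mask)
    bot_mm = _mismatch_profile(_read_array(reverse_complement(read)), bref.bottom_image, cpg_g_mask)
    best_top = int(np.argmin(top_mm))
    best_bot = int(np.argmin(bot_mm))
    if top_mm[best_top] <= bot_mm[best_bot]:
        offset, strand, mm = best_top, "top", int(top_mm[best_top])
    else:
        offset, strand, mm = best_bot, "bottom", int(bot_mm[best_bot])
    if mm / L > max_mismatch_frac:
        return None
    return AlignedRead(offset=offset, strand=strand, n_mismatch=mm, length=L)


def _read_cpg_states(read: str, aln: AlignedRead, bref: BisulfiteReference) -> str:
    """M/U/N string over the amplicon's CpGs for one aligned read."""
    states = []
    if aln.strand == "top":
        arr = _read_array(read)
        probe, meth_base, unmeth_base = bref.cpg_offsets, b"C", b"T"
    else:
        arr = _read_array(reverse_complement(read))
        probe, meth_base, unmeth_base = bref.cpg_offsets + 1, b"G", b"A"
    for pos in probe:
        i = pos - aln.offset
        if i < 0 or i >= aln.length:
            states.append("N")
        elif arr[i] == meth_base:
            states.append("M")
        elif arr[i] == unmeth_base:
            states.append("U")
        else:
            states.append("N")
    return "".join(states)


def _conversion_observations(read: str, aln: AlignedRead, bref: BisulfiteReference) -> tuple[int, int]:
    """(covered non-CpG cytosine positions, unconverted among them) for one read."""
    if aln.strand == "top":
        arr = _read_array(read)
        sites, unconverted = bref.non_cpg_c, b"C"
    else:
        arr = _read_array(reverse_complement(read))
        sites, unconverted = bref.non_cpg_g, b"G"
    rel = sites - aln.offset
    rel = rel[(rel >= 0) & (rel < aln.length)]
    return len(rel), int((arr[rel] == unconverted).sum())


def call_amplicon_methylation(
    reads: Sequence[str],
    ref_seq: str,
    min_depth: int = 10,
    max_mismatch_frac: float = 0.1,
    ref_name: str = "amplicon",
) -> AmpliconProfile:
    """Quantify per-CpG methylation of an amplicon from bisulfite reads.

    Per CpG, methylation = #C / (#C + #T) over aligned reads covering it
    (bottom-strand reads read out the G). CpGs under ``min_depth`` are
    reported but flagged and excluded from the mean. Reads exceeding the
    mismatch cap are discarded and counted.
    """
    bref = convert_reference(ref_seq)
    k = len(bref.cpg_offsets)
    meth = np.zeros(k, dtype=np.int64)
    total = np.zeros(k, dtype=np.int64)
    conv_n = conv_fail = 0
    used = discarded = 0
    for read in reads:
        aln = align_read(read, bref, max_mismatch_frac)
        if aln is None:
            discarded += 1
            continue
        used += 1
        states = _read_cpg_states(read, aln, bref)
        for j, s in enumerate(states):
            if s == "M":
                meth[j] += 1
                total[j] += 1
            elif s == "U":
                total[j] += 1
        n, fail = _conversion_observations(read, aln, bref)
        conv_n += n
        conv_fail += fail
    if used == 0:
        raise ValueError("no reads aligned to the amplicon")
    with np.errstate(invalid="ignore"):
        per_cpg = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    ok = total >= min_depth
    weight_mask = ok if ok.any() else total > 0
    mean_w = float(meth[weight_mask].sum() / total[weight_mask].sum())
    mean_u = float(np.nanmean(per_cpg[weight_mask]))
    conv = 1.0 - conv_fail / conv_n if conv_n else float("nan")
    return AmpliconProfile(
        ref_name=ref_name,
        cpg_positions=bref.cpg_offsets,
        per_cpg_meth=per_cpg,
        per_cpg_depth=total,
        depth_ok=ok,
        mean_meth=mean_w,
        mean_meth_unweighted=mean_u,
        n_reads_used=used,
        n_reads_discarded=discarded,
        conversion_efficiency=conv,
    )


def epiallele_patterns(
    reads: Sequence[str], ref_seq: str, max_mismatch_frac: float = 0.1
) -> list[EpiallelePattern]:
    """Aggregate per-read CpG state strings into epiallele counts.

    One M/U/N string per aligned read over the amplicon's CpG offsets;
    identical strings are merged, sorted by count descending (then pattern).
    """
    bref = convert_reference(ref_seq)
    counts: dict[str, int] = {}
    for read in reads:
        aln = align_read(read, bref, max_mismatch_frac)
        if aln is None:
            continue
        pat = _read_cpg_states(read, aln, bref)
        counts[pat] = counts.get(pat, 0) + 1
    return [
        EpiallelePattern(pattern=p, count=c)
        for p, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_fastq(path) -> list[str]:
    """Read sequences from a FASTQ file (qualities are ignored)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta_reference(path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no sequences in {path}")
    return str(recs[0].seq)


def profile_to_tsv(profile: AmpliconProfile, path) -> None:
    """Write the per-CpG table: offset, depth, methylation, depth_ok."""
    with open(path, "w") as fh:
        fh.write("cpg_offset\tdepth\tmethylation\tdepth_ok\n")
        for pos, d, m, ok in zip(
            profile.cpg_positions, profile.per_cpg_depth, profile.per_cpg_meth, profile.depth_ok
        ):
            mtxt = f"{m:.6f}" if m == m else "NA"
            fh.write(f"{pos}\t{d}\t{mtxt}\t{int(ok)}\n")


def patterns_to_tsv(patterns: Sequence[EpiallelePattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tcount\n")
        for p in patterns:
            fh.write(f"{p.pattern}\t{p.count}\n")
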