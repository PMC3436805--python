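"""Split-read refinement of paired-end SV calls to base-pair resolution.

Pipeline per candidate call: (i) collect unmapped mates of anchored pairs
near the predicted breakpoints, (ii) extract a local SV reference
rearranged into deletion-type geometry, (iii) count read k-mer hits per
alignment diagonal, (iv) vote on the best-supported diagonal offset,
(v) build a gapless majority-vote consensus of the supporting reads and
(vi) split-align the consensus with two affine-gap scoring passes to place
the breakpoints exactly, tolerating junction microinsertions and reporting
microhomology.  A refined call must confirm the paired-end size estimate
within 10% (for interchromosomal calls: breakpoints within the insert-size
cutoff of the paired-end estimates).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._align import prefix_scores
from ._util import encode, revcomp
from .libio import GenomeSource, LibraryProfile
from .pe_cluster import PECall


@dataclass
class Scoring:
    """Affine-gap scheme; a gap of length L costs open + (L-1)*extend."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class SRParams:
    k: int = 7
    k_min: int = 3
    min_split: int = 2
    max_candidates: int = 1000  # cap L on candidate reads per call
    size_consistency: float = 0.10  # c: max relative PE/SR length difference
    min_quality: float = 0.80  # consensus alignment identity floor
    scoring: Scoring = field(default_factory=Scoring)


@dataclass
class SplitCandidate:
    """An unmapped mate assigned to one call's breakpoint neighbourhood.

    The sequence is kept raw (as sequenced); the single enforced alignment
    direction is resolved against each call's rearranged SV reference from
    the anchor's strand and the strand of the reference segment the anchor
    falls in (an anchor inside an inverted segment flips the expectation).
    """

    raw_seq: str
    anchor_chrom: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    call_id: str
    library_id: str
    kind: str = "mate"  # "mate": unmapped mate; "clip": soft-clipped read

    def _segment_strand(self, sv_ref: "SVReference") -> str:
        mid = (self.anchor_start + self.anchor_end) // 2
        seg_strand = "+"
        best = None
        for seg in sv_ref.segments:
            if seg.chrom != self.anchor_chrom:
                continue
            dist = 0 if seg.start <= mid < seg.end else min(
                abs(mid - seg.start), abs(mid - seg.end))
            if best is None or dist < best:
                best = dist
                seg_strand = seg.strand
        return seg_strand

    def oriented(self, sv_ref: "SVReference") -> str:
        """Sequence on the forward strand of the rearranged SV reference."""
        seg_strand = self._segment_strand(sv_ref)
        if self.kind == "clip":
            # the sequence is already reference-forward at the anchor locus
            return self.raw_seq if seg_strand == "+" else revcomp(self.raw_seq)
        eff = self.anchor_strand if seg_strand == "+" else (
            "-" if self.anchor_strand == "+" else "+")
        return revcomp(self.raw_seq) if eff == "+" else self.raw_seq


@dataclass
class Segment:
    """One reference segment of the rearranged SV reference."""

    chrom: str
    start: int
    end: int
    strand: str
    cstart: int  # offset in the concatenated SV reference

    @property
    def cend(self) -> int:
        return self.cstart + (self.end - self.start)

    def to_genomic(self, cpos: int) -> int:
        off = cpos - self.cstart
        return self.start + off if self.strand == "+" else self.end - 1 - off


@dataclass
class SVReference:
    """Local reference rearranged so the junction is a deletion-type split."""

    sequence: str
    segments: list[Segment]
    sv_type: str
    orientation: str
    expected_offset: int  # concat distance between the PE-estimated junctions
    _kmer_index: dict | None = field(default=None, repr=False)

    def kmer_index(self, k: int) -> dict[str, list[int]]:
        if self._kmer_index is None or self._kmer_index.get("k") != k:
            index: dict[str, list[int]] = {}
            seq = self.sequence
            for p in range(len(seq) - k + 1):
                kmer = seq[p : p + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append(p)
            self._kmer_index = {"k": k, "index": index}
        return self._kmer_index["index"]

    def segment_at(self, cpos: int) -> Segment | None:
        for seg in self.segments:
            if seg.cstart <= cpos < seg.cend:
                return seg
        return None


@dataclass
class DiagonalProfile:
    """k-mer hit counts per alignment diagonal after used-k-mer resolution."""

    counts: dict[int, int]
    n_kmers: int  # total k-mers of the read (N-free or not)
    mean_offsets: dict[int, float]  # mean read offset of the k-mers per diagonal


@dataclass
class Breakpoint:
    """Consensus split and its genomic interpretation."""

    i: int  # consensus prefix length
    j: int  # 1-based consensus suffix start (j > i; j > i+1 => microinsertion)
    concat_prefix_end: int
    concat_suffix_start: int
    score: float
    microinsertion: str = ""
    microhomology: int = 0


@dataclass
class SRCall(PECall):
    """Split-read refined call: exact breakpoints, consensus and quality."""

    sr_support: int = 0
    consensus: str = ""
    consensus_alignment_quality: float = 0.0
    breakpoint: Breakpoint | None = None
    sv_length: int = 0


def collect_split_candidates(pe_calls: list[PECall], anchored: list[tuple],
                             profiles: dict[str, LibraryProfile],
                             max_candidates: int = 1000) -> dict[str, list[SplitCandidate]]:
    """Assign unmapped mates of anchored pairs to the closest call breakpoint.

    ``anchored`` records come from one pass over the alignment files (see
    :func:`svdelver.libio.extract_discordant`).  The anchor strand and the
    library orientation fix both the search direction and the enforced
    alignment direction of the candidate: the breakpoint must fall inside
    the window where the unmapped mate is expected to lie (the anchor's
    mate span widened by two insert-size standard deviations).  Each call
    keeps at most ``max_candidates`` reads.
    """
    bps: dict[str, list[tuple[int, str]]] = {}
    for call in pe_calls:
        bps.setdefault(call.chrom, []).append((call.start, call.id))
        if call.sv_type == "TRA":
            bps.setdefault(call.chrom2, []).append((call.pos2, call.id))
        else:
            bps.setdefault(call.chrom, []).append((call.end, call.id))
    for chrom in bps:
        bps[chrom].sort()
    out: dict[str, list[SplitCandidate]] = {c.id: [] for c in pe_calls}
    for chrom, astart, aend, strand, raw_seq, lib, kind in anchored:
        if chrom not in bps:
            continue
        prof = profiles[lib]
        sd2 = 2 * prof.sd_insert
        rl = len(raw_seq)
        if kind == "clip":
            # the junction sits at the clipped read end itself
            center = aend if strand == "+" else astart
            lo, hi = center - sd2, center + sd2
        elif strand == "+":
            lo, hi = aend - sd2, astart + prof.insert_max + sd2
            center = astart + prof.median_insert - rl / 2
        else:
            lo, hi = aend - prof.insert_max - sd2, astart + sd2
            center = aend - prof.median_insert + rl / 2
        best = None
        for pos, cid in bps[chrom]:
            if lo <= pos <= hi:
                cand = (abs(pos - center), pos, cid)
                if best is None or cand < best:
                    best = cand
        if best is None:
            continue
        cid = best[2]
        if len(out[cid]) < max_candidates:
            out[cid].append(SplitCandidate(raw_seq, chrom, astart, aend, strand,
                                           cid, lib, kind))
    return out


def build_sv_reference(genome: GenomeSource, call: PECall, window: int) -> SVReference:
    """Rearranged local reference putting the junction in deletion-type order.

    Deletions need a plain extraction of the call interval plus flanks; for
    tandem duplications the suffix-origin segment precedes the start, for
    inversions one side is reverse-complemented and translocations combine
    both transformations according to their orientation class, so that in
    every geometry the true junction appears as a prefix/suffix split with
    a positive diagonal offset.
    """
    w = int(window)
    lengths = genome.contigs

    def clamp(chrom, s, e):
        return max(0, s), min(e, lengths[chrom])

    def seg(chrom, s, e, strand, cstart):
        s, e = clamp(chrom, s, e)
        return Segment(chrom, s, e, strand, cstart)

    t, o = call.sv_type, call.orientation
    if t == "DEL":
        s1 = seg(call.chrom, call.start - w, call.end + w, "+", 0)
        segs = [s1]
        expected = call.end - call.start
    else:
        if t == "DUP":
            parts = [(call.chrom, call.end - w, call.end + w, "+", call.end),
                     (call.chrom, call.start - w, call.start + w, "+", call.start)]
        elif t == "INV" and o == "INV_LEFT":
            parts = [(call.chrom, call.start - w, call.start + w, "+", call.start),
                     (call.chrom, call.end - w, call.end + w, "-", call.end)]
        elif t == "INV" and o == "INV_RIGHT":
            parts = [(call.chrom, call.start - w, call.start + w, "-", call.start),
                     (call.chrom, call.end - w, call.end + w, "+", call.end)]
        elif t == "TRA":
            a = (call.chrom, call.start)
            b = (call.chrom2, call.pos2)
            if o == "TRA_1":
                parts = [(a[0], a[1] - w, a[1] + w, "+", a[1]),
                         (b[0], b[1] - w, b[1] + w, "+", b[1])]
            elif o == "TRA_2":
                parts = [(b[0], b[1] - w, b[1] + w, "+", b[1]),
                         (a[0], a[1] - w, a[1] + w, "+", a[1])]
            elif o == "TRA_3":
                parts = [(a[0], a[1] - w, a[1] + w, "+", a[1]),
                         (b[0], b[1] - w, b[1] + w, "-", b[1])]
            else:  # TRA_4
                parts = [(a[0], a[1] - w, a[1] + w, "-", a[1]),
                         (b[0], b[1] - w, b[1] + w, "+", b[1])]
        else:  # pragma: no cover
            raise ValueError(f"cannot build SV reference for {t}/{o}")
        segs = []
        cpos = 0
        junctions = []
        for chrom, s, e, strand, est in parts:
            sg = seg(chrom, s, e, strand, cpos)
            segs.append(sg)
            # concat position of the PE-estimated junction inside this segment
            junctions.append(cpos + (est - sg.start if strand == "+" else sg.end - est))
            cpos = sg.cend
        expected = junctions[1] - junctions[0]
    sequence = "".join(genome.fetch(s.chrom, s.start, s.end, s.strand) for s in segs)
    return SVReference(sequence, segs, t, o, int(expected))


def diagonal_hits(seq: str, sv_ref: SVReference, k: int = 7) -> DiagonalProfile | None:
    """Count read k-mer hits per alignment diagonal (reference - read offset).

    Counting happens on the single enforced alignment direction; k-mers
    containing N are skipped.  Repeat-induced multi-hits are resolved by
    processing diagonals in decreasing raw support and flagging each read
    k-mer as used once one of its diagonals has been taken, so every k-mer
    supports at most one diagonal.  Reads shorter than k are rejected.
    """
    if len(seq) < k:
        return None
    index = sv_ref.kmer_index(k)
    n_kmers = len(seq) - k + 1
    raw: dict[int, list[int]] = {}
    for off in range(n_kmers):
        kmer = seq[off : off + k]
        if "N" in kmer:
            continue
        for pos in index.get(kmer, ()):
            raw.setdefault(pos - off, []).append(off)
    counts: dict[int, int] = {}
    mean_offsets: dict[int, float] = {}
    used: set[int] = set()
    for diag in sorted(raw, key=lambda d: (-len(raw[d]), d)):
        assigned = [o for o in raw[diag] if o not in used]
        if assigned:
            counts[diag] = len(assigned)
            mean_offsets[diag] = sum(assigned) / len(assigned)
            used.update(assigned)
    return DiagonalProfile(counts, n_kmers, mean_offsets)


def select_read_offset(profile: DiagonalProfile, k_min: int = 3
                       ) -> tuple[int, int, int] | None:
    """Diagonal offset supported by one read, or None if the read is discarded.

    Diagonals below ``k_min`` hits are dropped; at least two must survive
    and the two most supported must jointly cover at least half the read's
    k-mers.  The offset between the two most supported diagonals, taken in
    diagonal-index order, is reported as ``(offset, d1, d2)``.  A
    deletion-type split places the early read portion on the smaller
    diagonal; reads whose best pair is mirrored (suffix before prefix, as
    produced by junction reads from the complementary spanning side) are
    rejected.
    """
    survivors = {d: c for d, c in profile.counts.items() if c >= k_min}
    if len(survivors) < 2:
        return None
    ranked = sorted(survivors, key=lambda d: (-survivors[d], d))
    d1, d2 = sorted(ranked[:2])
    if survivors[d1] + survivors[d2] < profile.n_kmers / 2:
        return None
    if profile.mean_offsets[d1] >= profile.mean_offsets[d2]:
        return None  # not deletion-type geometry on this SV reference
    return d2 - d1, d1, d2


def vote_offset(offsets: list[int], min_split: int = 2,
                expected: int | None = None) -> tuple[int, list[int]] | None:
    """Modal offset across candidate reads and the indices supporting it.

    The per-read search is unbiased; only vote *ties* are broken toward
    the paired-end expected offset, then toward the smaller offset.
    Returns None when support is below ``min_split``.
    """
    if not offsets:
        return None
    tally = Counter(offsets)
    top = max(tally.values())
    tied = sorted(o for o, c in tally.items() if c == top)
    if len(tied) > 1 and expected is not None:
        winner = min(tied, key=lambda o: (abs(o - expected), o))
    else:
        winner = tied[0]
    support = [i for i, o in enumerate(offsets) if o == winner]
    if len(support) < min_split:
        return None
    return winner, support


def consensus_sequence(reads: list[str], placements: list[int]
                       ) -> tuple[str, int] | None:
    """Gapless per-column majority vote over reads in a common frame.

    Each read is placed at its dominant prefix diagonal; columns covered by
    no read are trimmed at the edges, and a coverage gap inside the placed
    reads voids the consensus (returns None).  Column ties take the base of
    the lowest-index covering read that carries a tied base.
    """
    cols: dict[int, list[tuple[int, str]]] = {}
    for idx, (seq, d1) in enumerate(zip(reads, placements)):
        for t, base in enumerate(seq):
            cols.setdefault(d1 + t, []).append((idx, base))
    if not cols:
        return None
    positions = sorted(cols)
    if positions[-1] - positions[0] + 1 != len(positions):
        return None  # non-overlapping read placements
    out = []
    for pos in positions:
        votes = Counter(b for _, b in cols[pos])
        top = max(votes.values())
        tied = {b for b, c in votes.items() if c == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(b for _, b in sorted(cols[pos]) if b in tied))
    return "".join(out), positions[0]


def split_alignment(consensus: str, sv_ref: SVReference,
                    scoring: Scoring | None = None,
                    min_side: int = 7) -> Breakpoint | None:
    """Double dynamic programming: best prefix + best suffix placement.

    Forward scores ``f_i`` (best prefix consensus alignment) and reverse
    scores ``r_j`` (best suffix alignment) are combined to maximize
    ``f_i + r_j`` over splits with ``j >= i+1``; ``j > i+1`` leaves a
    non-template microinsertion, allowed up to half the consensus length.
    Each side must keep at least ``min_side`` consensus bases.  On clean
    junctions the breakpoint is left-aligned through any microhomology
    tract, whose length is reported.
    """
    sc = scoring or Scoring()
    c = encode(consensus)
    r = encode(sv_ref.sequence)
    n = len(c)
    if n < 2 * min_side:
        return None
    f, f_end = prefix_scores(c, r, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    rv, rv_end = prefix_scores(c[::-1], r[::-1], sc.match, sc.mismatch,
                               sc.gap_open, sc.gap_extend)
    m = len(r)
    best = None
    max_ins = n // 2
    for i in range(min_side, n - min_side + 1):
        # suffix starts at consensus position j (1-based), j >= i+1
        for j in range(i + 1, min(i + 1 + max_ins, n - min_side + 1) + 1):
            l = n - j + 1
            if l < min_side:
                continue
            total = f[i] + rv[l]
            key = (total, -(j - i), -i)
            if best is None or key > best[0]:
                best = (key, i, j)
    if best is None:
        return None
    (_, _, _), i, j = best[0], best[1], best[2]
    total = best[0][0]
    p = int(f_end[i])
    q = m - int(rv_end[n - j + 1])
    micro = consensus[i : j - 1]
    hom = 0
    if not micro:
        seg_p = sv_ref.segment_at(max(p - 1, 0))
        seg_q = sv_ref.segment_at(q) if q < m else None
        # left-align the split through shared junction sequence
        shift = 0
        while (p - shift > 0 and q - shift > 0 and i - shift > min_side
               and (seg_p is None or p - shift - 1 >= seg_p.cstart + 1)
               and (seg_q is None or q - shift - 1 >= seg_q.cstart)
               and sv_ref.sequence[p - shift - 1] == sv_ref.sequence[q - shift - 1]):
            shift += 1
        p -= shift
        q -= shift
        i -= shift
        j -= shift
        run = shift
        while (p + run - shift < len(sv_ref.sequence) and q + run - shift < len(sv_ref.sequence)
               and sv_ref.sequence[p + (run - shift)] == sv_ref.sequence[q + (run - shift)]):
            run += 1
        hom = run
    return Breakpoint(i, j, p, q, float(total), micro, hom)


def _genomic_junctions(bp: Breakpoint, sv_ref: SVReference):
    """Translate the concat split back to genomic junction coordinates.

    Returns ``(J1, J2, seg1, seg2)`` where J1 is the prefix-side junction
    (exclusive end on + segments, inclusive start on - segments) and J2 the
    suffix-side junction (inclusive start on +, exclusive end on -).
    """
    seg1 = sv_ref.segment_at(bp.concat_prefix_end - 1)
    seg2 = sv_ref.segment_at(bp.concat_suffix_start)
    if seg1 is None or seg2 is None:
        return None
    p, q = bp.concat_prefix_end, bp.concat_suffix_start
    j1 = (seg1.start + (p - seg1.cstart)) if seg1.strand == "+" else (seg1.end - (p - seg1.cstart))
    j2 = (seg2.start + (q - seg2.cstart)) if seg2.strand == "+" else (seg2.end - (q - seg2.cstart))
    return j1, j2, seg1, seg2


def refine_call(call: PECall, candidates: list[SplitCandidate],
                genome: GenomeSource, profiles: dict[str, LibraryProfile],
                params: SRParams | None = None) -> PECall:
    """Full split-read pipeline; degrades to the unchanged imprecise call.

    A successful refinement replaces the interval by the exact breakpoints
    and requires the split-read SV length to confirm the paired-end length
    within ``size_consistency`` (interchromosomal calls instead require
    both breakpoints within the insert-size cutoff of the PE estimates).
    """
    params = params or SRParams()
    if not candidates:
        return call
    window = max(prof.insert_max for prof in profiles.values())
    sv_ref = build_sv_reference(genome, call, window)
    selected = []
    for cand in candidates[: params.max_candidates]:
        seq = cand.oriented(sv_ref)
        prof = diagonal_hits(seq, sv_ref, params.k)
        if prof is None:
            continue
        sel = select_read_offset(prof, params.k_min)
        if sel is None:
            continue
        selected.append((seq, sel))
    if len(selected) < params.min_split:
        return call
    vote = vote_offset([s[1][0] for s in selected], params.min_split,
                       sv_ref.expected_offset)
    if vote is None:
        return call
    offset, support_idx = vote
    chosen = [selected[i] for i in support_idx]
    cons = consensus_sequence([seq for seq, _ in chosen], [s[1] for _, s in chosen])
    if cons is None:
        return call
    consensus, _ = cons
    bp = split_alignment(consensus, sv_ref, params.scoring, min_side=params.k)
    if bp is None:
        return call
    junc = _genomic_junctions(bp, sv_ref)
    if junc is None:
        return call
    j1, j2, seg1, seg2 = junc
    if call.sv_type == "DEL":
        start, end = j1, j2
    elif call.sv_type == "DUP":
        start, end = j2, j1
    elif call.sv_type == "INV":
        if seg1 is sv_ref.segments[0] and seg2 is sv_ref.segments[-1]:
            start, end = j1, j2
        else:
            return call  # split did not bridge the two junction segments
    else:  # TRA
        if len(sv_ref.segments) < 2 or seg1.chrom == seg2.chrom:
            return call
        pos_a, pos_b = (j1, j2) if seg1.chrom == call.chrom else (j2, j1)
        imax = max(prof.insert_max for prof in profiles.values())
        if abs(pos_a - call.start) > imax or abs(pos_b - call.pos2) > imax:
            return call
        quality = _junction_identity(consensus, sv_ref, bp)
        if quality < params.min_quality:
            return call
        return _make_srcall(call, len(chosen), consensus, quality, bp,
                            pos_a, pos_a + 1, pos_b, 0)
    if call.sv_type != "DEL" and not (seg1 is sv_ref.segments[0] and seg2 is sv_ref.segments[-1]):
        return call
    if end <= start:
        return call
    sv_length = end - start
    pe_length = call.end - call.start
    if abs(sv_length - pe_length) > params.size_consistency * pe_length:
        return call
    quality = _junction_identity(consensus, sv_ref, bp)
    if quality < params.min_quality:
        return call
    return _make_srcall(call, len(chosen), consensus, quality, bp,
                        start, end, call.pos2, sv_length)


def _junction_identity(consensus: str, sv_ref: SVReference, bp: Breakpoint) -> float:
    """Identity of the gapless prefix/suffix placement of the consensus."""
    seq = sv_ref.sequence
    n = len(consensus)
    matches = 0
    aligned = 0
    for t in range(bp.i):
        rp = bp.concat_prefix_end - bp.i + t
        if 0 <= rp < len(seq):
            aligned += 1
            matches += consensus[t] == seq[rp]
    for u, t in enumerate(range(bp.j - 1, n)):
        rp = bp.concat_suffix_start + u
        if 0 <= rp < len(seq):
            aligned += 1
            matches += consensus[t] == seq[rp]
    return matches / aligned if aligned else 0.0


def _make_srcall(call: PECall, sr_support: int, consensus: str, quality: float,
                 bp: Breakpoint, start: int, end: int, pos2, sv_length: int) -> SRCall:
    return SRCall(
        id=call.id, sv_type=call.sv_type, chrom=call.chrom, start=start, end=end,
        pe_support=call.pe_support, mapq_mean=call.mapq_mean,
        member_ids=call.member_ids, orientation=call.orientation,
        chrom2=call.chrom2, pos2=pos2, precise=True,
        sr_support=sr_support, consensus=consensus,
        consensus_alignment_quality=quality, breakpoint=bp, sv_length=sv_length)
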