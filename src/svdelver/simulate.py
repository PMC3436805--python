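"""Synthetic SV benchmark data: reference, planted variants, reads, truth BAM.

The generator plants non-overlapping deletions, tandem duplications,
inversions and translocated segments into a seeded random reference,
samples error-bearing FR read pairs from the rearranged donor genome and
projects them back onto the reference through an exact truth lift-over,
producing a coordinate-sorted, indexed BAM.  Pairs spanning an SV junction
become discordant by construction and reads crossing a junction by more
than a small margin are emitted as unmapped mates of mapped anchors, so the
whole caller is testable without an external aligner or any downloads.

Translocations follow the excision design: the translocated segment stays
in place in the donor (reads are sampled across its boundaries) but is
excised from the reference and appended as a separate contig, so
boundary-spanning pairs map interchromosomally.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._util import BASES, CODE_TO_BASE, decode, encode, revcomp

MAIN_CHROM = "chr1"


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the benchmark's default cell: 15x physical coverage,
    75 bp reads, outer insert ~ Normal(300, 30) and a 1% substitution
    error rate, with events of 500-5000 bp planted non-overlapping.
    """

    genome_length: int = 5_000_000
    n_del: int = 0
    n_dup: int = 0
    n_inv: int = 0
    n_tra: int = 0
    size_range: tuple[int, int] = (500, 5000)
    coverage: float = 15.0
    read_length: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.01
    seed: int = 1
    edge_margin: int = 1000  # keep events away from contig ends
    junction_margin: int = 5  # max bp a "mapped" read may overhang a junction
    mapq_policy: str = "constant"  # or "occurrence"

    def counts(self) -> dict[str, int]:
        return {"DEL": self.n_del, "DUP": self.n_dup, "INV": self.n_inv, "TRA": self.n_tra}


@dataclass
class TruthRecord:
    """One planted event, in reference and donor coordinates (0-based, half-open)."""

    id: str
    sv_type: str  # DEL / DUP / INV / TRA
    chrom: str
    start: int  # reference coords; for TRA the insertion point (start == end)
    end: int
    size: int
    donor_start: int
    donor_end: int
    chrom2: str | None = None  # TRA: the excised contig
    start2: int = 0
    end2: int = 0


@dataclass
class Block:
    """A maximal collinear donor<->reference alignment block."""

    donor_start: int
    donor_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'


@dataclass
class ReadBatch:
    """Simulated pairs as flat arrays (one row per pair).

    Sequences are stored donor-oriented: ``seq1``/``seq2`` are the donor
    forward-strand substrings under each read (errors applied); the raw
    sequenced read of mate 2 is the reverse complement of ``seq2``.
    """

    read_length: int
    start1: np.ndarray  # donor start of mate 1 (fragment 5' end, donor + strand)
    start2: np.ndarray  # donor start of mate 2 (donor - strand)
    seq1: np.ndarray  # (n, read_length) uint8 codes
    seq2: np.ndarray
    n_errors1: np.ndarray
    n_errors2: np.ndarray

    def __len__(self) -> int:
        return len(self.start1)


def generate_reference(length: int, seed: int, chrom: str = MAIN_CHROM) -> dict[str, str]:
    """Uniform random A/C/G/T reference, deterministic for a given seed."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return {chrom: CODE_TO_BASE[codes].tobytes().decode()}


def write_fasta(contigs: dict[str, str], path: str, width: int = 60) -> str:
    """Write contigs as FASTA and faidx-index the file."""
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pysam.faidx(path)
    return path


def _place_events(rng: np.random.Generator, genome_length: int, counts: dict[str, int],
                  size_range: tuple[int, int], edge_margin: int,
                  max_tries: int = 20000) -> list[tuple[int, int, str]]:
    """Sample non-overlapping (start, end, type) intervals on the source sequence."""
    lo, hi = size_range
    n_total = sum(counts.values())
    if n_total == 0:
        return []
    sizes = rng.integers(lo, hi + 1, size=n_total)
    if 2 * int(sizes.sum()) > genome_length:
        raise ValueError("planted SV footprint exceeds half the reference length")
    types = [t for t, n in counts.items() for _ in range(n)]
    placed: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for size, sv_type in zip(sizes, types):
        size = int(size)
        for _ in range(max_tries):
            start = int(rng.integers(edge_margin, genome_length - edge_margin - size))
            end = start + size
            # require a one-insert gap between events so clusters stay separable
            if all(end + edge_margin <= s or e + edge_margin <= start for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end, sv_type))
                break
        else:
            raise RuntimeError(
                f"could not place a non-overlapping {sv_type} of {size} bp "
                f"after {max_tries} tries; reduce counts or sizes"
            )
    placed.sort()
    return placed


def plant_variants(reference: dict[str, str], counts: dict[str, int],
                   size_range: tuple[int, int], seed: int,
                   edge_margin: int = 1000):
    """Plant SVs into the source sequence.

    Returns ``(donor, ref_contigs, truth, blocks)`` where ``donor`` is the
    rearranged genome reads are sampled from, ``ref_contigs`` is the
    reference the caller sees (translocated segments excised into separate
    contigs), ``truth`` the list of :class:`TruthRecord` and ``blocks`` the
    collinear donor<->reference block map used by the lift-over.
    """
    if len(reference) != 1:
        raise ValueError("plant_variants expects a single-contig source reference")
    (chrom, source), = reference.items()
    rng = np.random.default_rng(seed)
    events = _place_events(rng, len(source), counts, size_range, edge_margin)

    donor_parts: list[str] = []
    ref_parts: list[str] = []
    tra_contigs: dict[str, str] = {}
    truth: list[TruthRecord] = []
    blocks: list[Block] = []
    src = d = r = 0
    n_tra = 0
    counters: dict[str, int] = {}

    def flush_collinear(upto: int):
        nonlocal src, d, r
        seg = source[src:upto]
        if seg:
            donor_parts.append(seg)
            ref_parts.append(seg)
            blocks.append(Block(d, d + len(seg), chrom, r, r + len(seg), "+"))
            d += len(seg)
            r += len(seg)
        src = upto

    for start, end, sv_type in events:
        flush_collinear(start)
        seg = source[start:end]
        size = len(seg)
        counters[sv_type] = counters.get(sv_type, 0) + 1
        ev_id = f"truth_{sv_type}_{counters[sv_type]}"
        if sv_type == "DEL":
            ref_parts.append(seg)
            truth.append(TruthRecord(ev_id, "DEL", chrom, r, r + size, size, d, d))
            r += size
        elif sv_type == "DUP":
            donor_parts.append(seg + seg)
            ref_parts.append(seg)
            blocks.append(Block(d, d + size, chrom, r, r + size, "+"))
            blocks.append(Block(d + size, d + 2 * size, chrom, r, r + size, "+"))
            truth.append(TruthRecord(ev_id, "DUP", chrom, r, r + size, size, d, d + 2 * size))
            d += 2 * size
            r += size
        elif sv_type == "INV":
            donor_parts.append(revcomp(seg))
            ref_parts.append(seg)
            blocks.append(Block(d, d + size, chrom, r, r + size, "-"))
            truth.append(TruthRecord(ev_id, "INV", chrom, r, r + size, size, d, d + size))
            d += size
            r += size
        elif sv_type == "TRA":
            n_tra += 1
            tname = f"tra{n_tra}"
            donor_parts.append(seg)  # stays in place in the donor
            tra_contigs[tname] = seg  # excised from the main reference contig
            blocks.append(Block(d, d + size, tname, 0, size, "+"))
            truth.append(TruthRecord(ev_id, "TRA", chrom, r, r, size, d, d + size,
                                     chrom2=tname, start2=0, end2=size))
            d += size
        else:  # pragma: no cover - guarded by counts()
            raise ValueError(f"unknown SV type {sv_type}")
        src = end
    flush_collinear(len(source))

    donor = {chrom: "".join(donor_parts)}
    ref_contigs = {chrom: "".join(ref_parts), **tra_contigs}
    return donor, ref_contigs, truth, blocks


def simulate_reads(donor: dict[str, str], cfg: SimConfig, seed: int | None = None) -> ReadBatch:
    """Sample FR read pairs from the donor with i.i.d. substitution errors.

    The number of pairs is ``coverage * donor_length / (2 * read_length)``;
    outer fragment lengths are Normal(mean, sd) truncated at twice the read
    length, fragment starts are uniform.
    """
    if len(donor) != 1:
        raise ValueError("simulate_reads expects the single-contig donor")
    (_, seq), = donor.items()
    if not seq:
        raise ValueError("donor sequence is empty")
    rl = cfg.read_length
    if cfg.insert_mean < 2 * rl:
        raise ValueError("insert mean must be at least twice the read length")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_pairs = int(round(cfg.coverage * len(seq) / (2 * rl)))

    frag = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)).astype(np.int64)
    np.clip(frag, 2 * rl, len(seq), out=frag)
    start1 = rng.integers(0, len(seq) - frag + 1, size=n_pairs)
    start2 = start1 + frag - rl

    codes = encode(seq)
    offs = np.arange(rl, dtype=np.int64)
    seq1 = codes[start1[:, None] + offs]
    seq2 = codes[start2[:, None] + offs]

    def corrupt(mat: np.ndarray) -> np.ndarray:
        if cfg.error_rate <= 0:
            return np.zeros(len(mat), dtype=np.int32)
        mask = rng.random(mat.shape) < cfg.error_rate
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=mask.sum(), dtype=np.uint8)
        mat[mask] = (mat[mask] + shift) % 4
        return mask.sum(axis=1).astype(np.int32)

    ne1 = corrupt(seq1)
    ne2 = corrupt(seq2)
    return ReadBatch(rl, start1, start2, seq1, seq2, ne1, ne2)


def write_fastq(batch: ReadBatch, prefix: str) -> tuple[str, str]:
    """Export the raw sequenced reads (mate 2 reverse-complemented) as FASTQ."""
    rl = batch.read_length
    qual = "I" * rl
    paths = (prefix + "_1.fastq", prefix + "_2.fastq")
    for path, seqmat, rc in ((paths[0], batch.seq1, False), (paths[1], batch.seq2, True)):
        blob = CODE_TO_BASE[seqmat].tobytes().decode()
        with open(path, "w") as fh:
            for i in range(len(batch)):
                s = blob[i * rl : (i + 1) * rl]
                if rc:
                    s = revcomp(s)
                fh.write(f"@frag{i}/{2 if rc else 1}\n{s}\n+\n{qual}\n")
    return paths


def write_truth(truth: list[TruthRecord], path: str) -> str:
    """Truth table as a BED-like TSV (0-based, half-open)."""
    cols = [f.name for f in dataclasses.fields(TruthRecord)]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for rec in truth:
            fh.write("\t".join(str(getattr(rec, c)) for c in cols) + "\n")
    return path


def read_truth(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(TruthRecord(
                id=vals["id"], sv_type=vals["sv_type"], chrom=vals["chrom"],
                start=int(vals["start"]), end=int(vals["end"]), size=int(vals["size"]),
                donor_start=int(vals["donor_start"]), donor_end=int(vals["donor_end"]),
                chrom2=None if vals["chrom2"] == "None" else vals["chrom2"],
                start2=int(vals["start2"]), end2=int(vals["end2"])))
    return out


def _lift(blocks: list[Block], idx: np.ndarray, start: np.ndarray, rl: int):
    """Lift donor read starts through their block; returns (chrom_idx, pos, strand-)."""
    ds = np.array([b.donor_start for b in blocks])
    rs = np.array([b.ref_start for b in blocks])
    re_ = np.array([b.ref_end for b in blocks])
    neg = np.array([b.strand == "-" for b in blocks])
    off = start - ds[idx]
    pos_fwd = rs[idx] + off
    pos_rev = re_[idx] - off - rl
    is_neg = neg[idx]
    return np.where(is_neg, pos_rev, pos_fwd), is_neg


def project_alignments(batch: ReadBatch, blocks: list[Block], ref_contigs: dict[str, str],
                       cfg: SimConfig, out_bam: str) -> dict[str, int]:
    """Project simulated reads onto the reference via the truth block map.

    A read lying inside one collinear block (up to ``junction_margin`` bp of
    overhang, mimicking an aligner's sloppy ends) is emitted mapped at its
    lifted coordinate; a read crossing a junction further than that is
    emitted unmapped alongside its mapped mate.  Pairs with both reads
    unmapped are dropped.  Output is a coordinate-sorted, indexed BAM.
    """
    rl = batch.read_length
    m = cfg.junction_margin
    n = len(batch)
    dstarts = np.array([b.donor_start for b in blocks])
    dends = np.array([b.donor_end for b in blocks])
    nblocks = len(blocks)

    def classify(start: np.ndarray):
        """block index used for mapping, or -1 for unmapped."""
        i = np.searchsorted(dstarts, start, side="right") - 1
        end = start + rl
        tail = end - dends[i]
        ok_here = tail <= m
        # mostly in the next block with a small head overhang
        head = dends[i] - start
        nxt = np.minimum(i + 1, nblocks - 1)
        ok_next = (~ok_here) & (head <= m) & (end <= dends[nxt] + 0)
        idx = np.where(ok_here, i, np.where(ok_next, nxt, -1))
        return idx

    idx1 = classify(batch.start1)
    idx2 = classify(batch.start2)
    pos1, neg1 = _lift(blocks, np.maximum(idx1, 0), batch.start1, rl)
    pos2, neg2 = _lift(blocks, np.maximum(idx2, 0), batch.start2, rl)
    chroms = list(ref_contigs)
    chrom_of_block = np.array([chroms.index(b.chrom) for b in blocks])
    clen = np.array([len(ref_contigs[c]) for c in chroms])
    cid1 = chrom_of_block[np.maximum(idx1, 0)]
    cid2 = chrom_of_block[np.maximum(idx2, 0)]
    # sloppy extensions running off a contig end are unmappable
    mapped1 = (idx1 >= 0) & (pos1 >= 0) & (pos1 + rl <= clen[cid1])
    mapped2 = (idx2 >= 0) & (pos2 >= 0) & (pos2 + rl <= clen[cid2])
    # alignment strand: donor strand (mate1 +, mate2 -) flipped inside '-' blocks
    rev1 = neg1  # mate 1 is donor-forward: reverse iff its block is '-'
    rev2 = ~neg2  # mate 2: reverse iff block is '+'

    if cfg.mapq_policy == "occurrence":
        mapq1 = _occurrence_mapq(batch.seq1, ref_contigs)
        mapq2 = _occurrence_mapq(batch.seq2, ref_contigs)
    else:
        mapq1 = np.full(n, 60, dtype=np.int64)
        mapq2 = np.full(n, 60, dtype=np.int64)

    blob1 = CODE_TO_BASE[batch.seq1].tobytes().decode()
    blob2 = CODE_TO_BASE[batch.seq2].tobytes().decode()
    qual = "I" * rl
    cigar = f"{rl}M"

    tmp_sam = out_bam + ".tmp.sam"
    stats = {"pairs": n, "mapped": 0, "single_anchored": 0, "dropped": 0}
    with open(tmp_sam, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in chroms:
            sam.write(f"@SQ\tSN:{c}\tLN:{len(ref_contigs[c])}\n")
        for i in range(n):
            m1, m2 = mapped1[i], mapped2[i]
            if not (m1 or m2):
                stats["dropped"] += 1
                continue
            # donor-forward sequences; SEQ is ref-forward: flip for '-' alignments.
            s1 = blob1[i * rl : (i + 1) * rl]
            s2 = blob2[i * rl : (i + 1) * rl]
            name = f"frag{i}"
            if m1 and m2:
                stats["mapped"] += 1
                c1, c2 = chroms[cid1[i]], chroms[cid2[i]]
                p1, p2 = int(pos1[i]), int(pos2[i])
                r1, r2 = bool(rev1[i]), bool(rev2[i])
                proper = (
                    c1 == c2
                    and r1 != r2
                    and ((p1 <= p2 and not r1) or (p2 <= p1 and not r2))
                    and abs(max(p1, p2) + rl - min(p1, p2)) <= cfg.insert_mean + 10 * cfg.insert_sd
                )
                if c1 == c2:
                    outer = max(p1, p2) + rl - min(p1, p2)
                    t1 = outer if p1 < p2 or (p1 == p2 and not r1) else -outer
                    t2 = -t1
                else:
                    t1 = t2 = 0
                f1 = 1 | 64 | (2 if proper else 0) | (16 if r1 else 0) | (32 if r2 else 0)
                f2 = 1 | 128 | (2 if proper else 0) | (16 if r2 else 0) | (32 if r1 else 0)
                seq1 = revcomp(s1) if neg1[i] else s1
                seq2 = revcomp(s2) if neg2[i] else s2
                rn2 = "=" if c1 == c2 else c2
                rn1 = "=" if c1 == c2 else c1
                sam.write(f"{name}\t{f1}\t{c1}\t{p1+1}\t{int(mapq1[i])}\t{cigar}\t{rn2}\t{p2+1}\t{t1}\t{seq1}\t{qual}\tMQ:i:{int(mapq2[i])}\n")
                sam.write(f"{name}\t{f2}\t{c2}\t{p2+1}\t{int(mapq2[i])}\t{cigar}\t{rn1}\t{p1+1}\t{t2}\t{seq2}\t{qual}\tMQ:i:{int(mapq1[i])}\n")
            else:
                stats["single_anchored"] += 1
                if m1:
                    ca, pa = chroms[cid1[i]], int(pos1[i])
                    ra = bool(rev1[i])
                    qa, mqa = (revcomp(s1) if neg1[i] else s1), int(mapq1[i])
                    # raw sequenced read of the unmapped mate (mate 2 is sequenced as revcomp)
                    qu = revcomp(s2)
                    fa = 1 | 64 | 8 | (16 if ra else 0)
                    fu = 1 | 128 | 4 | (32 if ra else 0)
                else:
                    ca, pa = chroms[cid2[i]], int(pos2[i])
                    ra = bool(rev2[i])
                    qa, mqa = (revcomp(s2) if neg2[i] else s2), int(mapq2[i])
                    qu = s1
                    fa = 1 | 128 | 8 | (16 if ra else 0)
                    fu = 1 | 64 | 4 | (32 if ra else 0)
                sam.write(f"{name}\t{fa}\t{ca}\t{pa+1}\t{mqa}\t{cigar}\t=\t{pa+1}\t0\t{qa}\t{qual}\tMQ:i:0\n")
                sam.write(f"{name}\t{fu}\t{ca}\t{pa+1}\t0\t*\t=\t{pa+1}\t0\t{qu}\t{qual}\tMQ:i:{mqa}\n")
    pysam.sort("-o", out_bam, tmp_sam)
    os.remove(tmp_sam)
    pysam.index(out_bam)
    return stats


def _occurrence_mapq(seqmat: np.ndarray, ref_contigs: dict[str, str]) -> np.ndarray:
    """mapq 0 for reads whose (forward or reverse) sequence occurs >1 time."""
    genome = "\x00".join(ref_contigs.values())
    rl = seqmat.shape[1]
    blob = CODE_TO_BASE[seqmat].tobytes().decode()
    out = np.full(len(seqmat), 60, dtype=np.int64)
    for i in range(len(seqmat)):
        s = blob[i * rl : (i + 1) * rl]
        hits = genome.count(s) + genome.count(revcomp(s))
        if hits > 1:
            out[i] = 0
    return out


@dataclass
class Dataset:
    """File bundle produced by :func:`simulate_dataset`."""

    fasta: str
    bam: str
    truth_path: str
    truth: list[TruthRecord]
    config: SimConfig
    fastq: tuple[str, str] | None = None
    stats: dict[str, int] = field(default_factory=dict)


def simulate_dataset(cfg: SimConfig, outdir: str, write_reads_fastq: bool = False) -> Dataset:
    """Run the full generator: reference -> variants -> reads -> truth BAM."""
    os.makedirs(outdir, exist_ok=True)
    reference = generate_reference(cfg.genome_length, cfg.seed)
    donor, ref_contigs, truth, blocks = plant_variants(
        reference, cfg.counts(), cfg.size_range, cfg.seed + 1, cfg.edge_margin)
    fasta = write_fasta(ref_contigs, os.path.join(outdir, "ref.fa"))
    batch = simulate_reads(donor, cfg, cfg.seed + 2)
    bam = os.path.join(outdir, "reads.bam")
    stats = project_alignments(batch, blocks, ref_contigs, cfg, bam)
    truth_path = write_truth(truth, os.path.join(outdir, "truth.tsv"))
    fq = write_fastq(batch, os.path.join(outdir, "reads")) if write_reads_fastq else None
    return Dataset(fasta, bam, truth_path, truth, cfg, fq, stats)
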