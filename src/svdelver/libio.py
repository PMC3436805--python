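"""Alignment I/O: per-library insert profiling and discordant-pair extraction.

Each input BAM is one sequencing library with its own insert-size
distribution; all libraries are analyzed jointly downstream.  Coordinates
are 0-based half-open internally; text output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from ._util import revcomp

SIGNATURES = ("DEL", "DUP", "INV_LEFT", "INV_RIGHT", "TRA_1", "TRA_2", "TRA_3", "TRA_4")
CONCORDANT = "CONCORDANT"

# translocation class by normalized (strand_a, strand_b)
_TRA_CLASS = {("+", "-"): "TRA_1", ("-", "+"): "TRA_2", ("+", "+"): "TRA_3", ("-", "-"): "TRA_4"}


class ProfilingError(RuntimeError):
    """Raised when a library yields too few proper pairs to profile."""


@dataclass
class LibraryProfile:
    """Insert-size distribution and default orientation of one library.

    ``insert_max = median + cutoff_sd * sd`` is the discordance cutoff: a
    pair at default orientation with a larger outer insert supports a
    deletion.  The default cutoff is three standard deviations.
    """

    library_id: str
    median_insert: float
    sd_insert: float
    orientation: str = "FR"  # FR, RF or FF_like
    cutoff_sd: float = 3.0

    def __post_init__(self):
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be non-negative")

    @property
    def insert_max(self) -> float:
        return self.median_insert + self.cutoff_sd * self.sd_insert


@dataclass
class DiscordantPair:
    """A normalized discordant pair: node of the variant graph.

    Normalization puts the read with the (lexicographically chromosome,
    position)-smaller alignment first, as side ``a``.
    """

    pair_id: int
    chrom_a: str
    a_start: int
    a_end: int
    strand_a: str
    chrom_b: str
    b_start: int
    b_end: int
    strand_b: str
    mapq: int
    library_id: str
    signature: str

    @property
    def insert(self) -> int:
        """Outer distance, only meaningful intrachromosomally."""
        return self.b_end - self.a_start


@dataclass
class GenomeSource:
    """Random-access view of an indexed FASTA."""

    path: str
    _fa: pysam.FastaFile = field(init=False, repr=False)

    def __post_init__(self):
        self._fa = pysam.FastaFile(self.path)

    @property
    def contigs(self) -> dict[str, int]:
        return dict(zip(self._fa.references, self._fa.lengths))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        start = max(0, start)
        end = min(end, self._fa.get_reference_length(chrom))
        seq = self._fa.fetch(chrom, start, end).upper()
        return revcomp(seq) if strand == "-" else seq


def _pair_orientation(left_rev: bool, right_rev: bool) -> str:
    if left_rev == right_rev:
        return "FF_like"
    return "FR" if not left_rev else "RF"


def estimate_library_profile(bam_path: str, sample_size: int = 10_000,
                             cutoff_sd: float = 3.0, min_pairs: int = 1000,
                             library_id: str | None = None) -> LibraryProfile:
    """Median/SD of the outer insert and modal orientation of a library.

    Samples the first ``sample_size`` properly paired primary alignments.
    Raises :class:`ProfilingError` below ``min_pairs`` proper pairs.
    """
    library_id = library_id or bam_path
    inserts: list[int] = []
    orient: dict[str, int] = {"FR": 0, "RF": 0, "FF_like": 0}
    with pysam.AlignmentFile(bam_path) as af:
        for read in af.fetch(until_eof=True):
            if (not read.is_proper_pair or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.is_unmapped or read.template_length <= 0):
                continue
            inserts.append(read.template_length)
            left_rev = read.is_reverse
            right_rev = read.mate_is_reverse
            orient[_pair_orientation(left_rev, right_rev)] += 1
            if len(inserts) >= sample_size:
                break
    if len(inserts) < min_pairs:
        raise ProfilingError(
            f"library {library_id!r}: only {len(inserts)} proper pairs "
            f"(need >= {min_pairs}) - cannot profile insert sizes")
    arr = np.asarray(inserts, dtype=float)
    # modal orientation; ties broken toward FR
    orientation = max(("FR", "RF", "FF_like"), key=lambda k: orient[k])
    return LibraryProfile(library_id, float(np.median(arr)), float(arr.std()),
                          orientation, cutoff_sd)


def classify_pair(chrom_a: str, a_start: int, strand_a: str,
                  chrom_b: str, b_start: int, b_end: int, strand_b: str,
                  profile: LibraryProfile) -> str:
    """Signature of a normalized mapped pair, or CONCORDANT.

    The pair must already be normalized (side ``a`` first).  For an FR
    library: default orientation with an insert beyond ``insert_max`` is a
    deletion signature; everted order (a-, b+) a tandem duplication; equal
    strands an inversion (left-spanning ++, right-spanning --);
    interchromosomal pairs fall into four translocation classes keyed by
    the normalized strand combination.
    """
    if chrom_a != chrom_b:
        return _TRA_CLASS[(strand_a, strand_b)]
    if profile.orientation == "RF":
        # mirror an RF (outward-facing) library onto the FR logic
        strand_a, strand_b = strand_b, strand_a
    if strand_a == strand_b:
        return "INV_LEFT" if strand_a == "+" else "INV_RIGHT"
    if strand_a == "-":
        return "DUP"
    insert = b_end - a_start
    if insert > profile.insert_max:
        return "DEL"
    return CONCORDANT


def extract_discordant(bam_paths: list[str], profiles: dict[str, LibraryProfile],
                       map_qual: int = 1, collect_anchored: bool = False,
                       include_softclips: bool = False, min_clip: int = 20):
    """Single pass over every library: classified, normalized discordant pairs.

    Returns ``(bins, anchored)`` where ``bins`` maps
    ``(signature, chrom_a, chrom_b)`` to a list of :class:`DiscordantPair`
    sorted by left-most position, spanning all input libraries, and
    ``anchored`` (only if ``collect_anchored``) is the list of
    single-anchored pair records later used as split-read candidates:
    ``(chrom, anchor_start, anchor_end, anchor_strand, raw_seq, library_id,
    kind)`` with ``kind`` one of ``"mate"`` (unmapped mate of a mapped
    anchor) or ``"clip"`` (a soft-clipped read acting as its own anchor,
    collected only with ``include_softclips``).
    """
    bins: dict[tuple, list[DiscordantPair]] = {}
    anchored: list[tuple] = []
    pair_id = 0
    for path in bam_paths:
        lib = path
        profile = profiles[lib]
        with pysam.AlignmentFile(path) as af:
            for read in af.fetch(until_eof=True):
                if read.is_secondary or read.is_supplementary or read.is_duplicate:
                    continue
                if read.is_unmapped:
                    if collect_anchored and not read.mate_is_unmapped:
                        # convention: the unmapped record sits at its mate's coordinate
                        anchored.append((
                            read.reference_name, read.next_reference_start,
                            read.next_reference_start + read.query_length,
                            "-" if read.mate_is_reverse else "+",
                            read.query_sequence, lib, "mate"))
                    continue
                if collect_anchored and include_softclips and read.cigartuples:
                    first, last = read.cigartuples[0], read.cigartuples[-1]
                    # a long clip marks the junction at the clipped read end;
                    # the record carries the clip side as the anchor strand
                    if last[0] == 4 and last[1] >= min_clip:
                        anchored.append((read.reference_name, read.reference_start,
                                         read.reference_end, "+",
                                         read.query_sequence, lib, "clip"))
                    elif first[0] == 4 and first[1] >= min_clip:
                        anchored.append((read.reference_name, read.reference_start,
                                         read.reference_end, "-",
                                         read.query_sequence, lib, "clip"))
                if read.mate_is_unmapped or not read.is_paired:
                    continue
                if read.mapping_quality < map_qual:
                    continue
                mate_mapq = read.get_tag("MQ") if read.has_tag("MQ") else read.mapping_quality
                if mate_mapq < map_qual:
                    continue
                chrom, mchrom = read.reference_name, read.next_reference_name
                pos, mpos = read.reference_start, read.next_reference_start
                # process each pair once, from its normalized 'a' side
                if (chrom, pos) > (mchrom, mpos):
                    continue
                if (chrom, pos) == (mchrom, mpos) and not read.is_read1:
                    continue
                rlen = read.query_length
                sig = classify_pair(
                    chrom, pos, "-" if read.is_reverse else "+",
                    mchrom, mpos, mpos + rlen, "-" if read.mate_is_reverse else "+",
                    profile)
                if sig == CONCORDANT:
                    continue
                pair = DiscordantPair(
                    pair_id, chrom, pos, read.reference_end,
                    "-" if read.is_reverse else "+",
                    mchrom, mpos, mpos + rlen,
                    "-" if read.mate_is_reverse else "+",
                    int(min(read.mapping_quality, mate_mapq)), lib, sig)
                pair_id += 1
                bins.setdefault((sig, chrom, mchrom), []).append(pair)
    for key in bins:
        bins[key].sort(key=lambda p: (p.a_start, p.b_start, p.pair_id))
    if collect_anchored:
        return bins, anchored
    return bins
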