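"""Final call set assembly: merging complementary calls and writing output.

Inversions produce separate left- and right-spanning clusters; only
complementing pairs with at least 80% reciprocal overlap are merged,
best-first by breakpoint distance.  Translocation junction calls of
complementary orientation classes are merged when their predicted
insertion positions are less than ``z`` bp apart (default 300).  Output is
VCF 4.2 with symbolic ALTs (breakend pairs for translocations) plus a flat
TSV mirror; coordinates in text output are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pysam

from ._util import reciprocal_overlap
from .pe_cluster import PECall
from .sr_refine import SRCall

_TRA_COMPLEMENT = {"TRA_1": "TRA_2", "TRA_2": "TRA_1", "TRA_3": "TRA_4", "TRA_4": "TRA_3"}


@dataclass
class FinalCall:
    """Annotated, possibly merged call ready for output."""

    id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    precise: bool
    pe_support: int
    sr_support: int
    mapq_mean: float
    orientation: str
    filter: str = "PASS"
    chrom2: str | None = None
    pos2: int | None = None
    pos2_end: int | None = None  # merged TRA: far end of the inserted segment
    merged_from: list[str] = field(default_factory=list)
    consensus: str = ""
    consensus_quality: float = 0.0
    microinsertion: str = ""
    microhomology: int = 0

    @property
    def size(self) -> int:
        return self.end - self.start


def _call_filter(call: PECall) -> str:
    precise = getattr(call, "precise", False)
    if precise or (call.pe_support >= 3 and call.mapq_mean >= 20):
        return "PASS"
    return "LowQual"


def finalize(call: PECall, call_id: str | None = None) -> FinalCall:
    """Wrap a single (unmerged) PE or SR call."""
    sr = isinstance(call, SRCall)
    bp = call.breakpoint if sr else None
    return FinalCall(
        id=call_id or call.id, sv_type=call.sv_type, chrom=call.chrom,
        start=call.start, end=call.end, precise=bool(getattr(call, "precise", False)),
        pe_support=call.pe_support, sr_support=call.sr_support if sr else 0,
        mapq_mean=call.mapq_mean, orientation=call.orientation,
        filter=_call_filter(call), chrom2=call.chrom2, pos2=call.pos2,
        merged_from=[call.id],
        consensus=call.consensus if sr else "",
        consensus_quality=call.consensus_alignment_quality if sr else 0.0,
        microinsertion=bp.microinsertion if bp else "",
        microhomology=bp.microhomology if bp else 0)


def merge_inversions(inv_calls: list[PECall], min_reciprocal: float = 0.8) -> list[FinalCall]:
    """Best-first pairing of complementing left-/right-spanning inversions.

    Merging never moves a precise partner's breakpoints: with exactly one
    precise partner its coordinates win; two imprecise partners average.
    Unmerged calls pass through singly.
    """
    left = [c for c in inv_calls if c.orientation == "INV_LEFT"]
    right = [c for c in inv_calls if c.orientation == "INV_RIGHT"]
    pairs = []
    for li, lc in enumerate(left):
        for ri, rc in enumerate(right):
            if reciprocal_overlap(lc.start, lc.end, rc.start, rc.end) >= min_reciprocal:
                dist = abs(lc.start - rc.start) + abs(lc.end - rc.end)
                pairs.append((dist, li, ri))
    pairs.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    out: list[FinalCall] = []
    for _, li, ri in pairs:
        if li in used_l or ri in used_r:
            continue
        used_l.add(li)
        used_r.add(ri)
        lc, rc = left[li], right[ri]
        lp, rp = getattr(lc, "precise", False), getattr(rc, "precise", False)
        if lp and not rp:
            start, end = lc.start, lc.end
        elif rp and not lp:
            start, end = rc.start, rc.end
        elif lp and rp:
            start, end = lc.start, lc.end
        else:
            start, end = (lc.start + rc.start) // 2, (lc.end + rc.end) // 2
        precise_partner = lc if lp else rc if rp else None
        merged = FinalCall(
            id=lc.id, sv_type="INV", chrom=lc.chrom, start=start, end=end,
            precise=lp or rp, pe_support=lc.pe_support + rc.pe_support,
            sr_support=getattr(lc, "sr_support", 0) + getattr(rc, "sr_support", 0),
            mapq_mean=(lc.mapq_mean * lc.pe_support + rc.mapq_mean * rc.pe_support)
            / (lc.pe_support + rc.pe_support),
            orientation="INV_BOTH", merged_from=[lc.id, rc.id])
        if precise_partner is not None:
            src = finalize(precise_partner)
            merged.consensus = src.consensus
            merged.consensus_quality = src.consensus_quality
            merged.microinsertion = src.microinsertion
            merged.microhomology = src.microhomology
        merged.filter = "PASS" if merged.precise or (merged.pe_support >= 3 and merged.mapq_mean >= 20) else "LowQual"
        out.append(merged)
    for li, lc in enumerate(left):
        if li not in used_l:
            out.append(finalize(lc))
    for ri, rc in enumerate(right):
        if ri not in used_r:
            out.append(finalize(rc))
    return out


def merge_translocations(tra_calls: list[PECall], z: int = 300) -> list[FinalCall]:
    """Greedy minimal-distance pairing of complementary junction calls.

    Two junction calls merge when they share the chromosome pair, support
    complementary orientation classes (same inversion parity) and their
    predicted breakpoints on the insertion chromosome are less than ``z``
    bp apart; the closest pairs merge first.
    """
    pairs = []
    for i, a in enumerate(tra_calls):
        for j in range(i + 1, len(tra_calls)):
            b = tra_calls[j]
            if a.chrom != b.chrom or a.chrom2 != b.chrom2:
                continue
            if _TRA_COMPLEMENT.get(a.orientation) != b.orientation:
                continue
            d = min(abs(a.start - b.start), abs(a.pos2 - b.pos2))
            if d < z:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    out: list[FinalCall] = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = tra_calls[i], tra_calls[j]
        ap, bp = getattr(a, "precise", False), getattr(b, "precise", False)
        if abs(a.start - b.start) <= abs(a.pos2 - b.pos2):
            # insertion point on chrom; segment spans [pos2_a, pos2_b] on chrom2
            ins = a.start if ap else b.start if bp else (a.start + b.start) // 2
            seg_lo, seg_hi = sorted((a.pos2, b.pos2))
            merged = FinalCall(
                id=a.id, sv_type="TRA", chrom=a.chrom, start=ins, end=ins + 1,
                precise=ap or bp, pe_support=a.pe_support + b.pe_support,
                sr_support=getattr(a, "sr_support", 0) + getattr(b, "sr_support", 0),
                mapq_mean=(a.mapq_mean * a.pe_support + b.mapq_mean * b.pe_support)
                / (a.pe_support + b.pe_support),
                orientation=f"{a.orientation}+{b.orientation}",
                chrom2=a.chrom2, pos2=seg_lo, pos2_end=seg_hi,
                merged_from=[a.id, b.id])
        else:
            ins = a.pos2 if ap else b.pos2 if bp else (a.pos2 + b.pos2) // 2
            seg_lo, seg_hi = sorted((a.start, b.start))
            merged = FinalCall(
                id=a.id, sv_type="TRA", chrom=a.chrom2, start=ins, end=ins + 1,
                precise=ap or bp, pe_support=a.pe_support + b.pe_support,
                sr_support=getattr(a, "sr_support", 0) + getattr(b, "sr_support", 0),
                mapq_mean=(a.mapq_mean * a.pe_support + b.mapq_mean * b.pe_support)
                / (a.pe_support + b.pe_support),
                orientation=f"{a.orientation}+{b.orientation}",
                chrom2=a.chrom, pos2=seg_lo, pos2_end=seg_hi,
                merged_from=[a.id, b.id])
        precise_partner = a if ap else b if bp else None
        if precise_partner is not None:
            src = finalize(precise_partner)
            merged.consensus = src.consensus
            merged.consensus_quality = src.consensus_quality
        merged.filter = "PASS" if merged.precise or (merged.pe_support >= 3 and merged.mapq_mean >= 20) else "LowQual"
        out.append(merged)
    for i, c in enumerate(tra_calls):
        if i not in used:
            out.append(finalize(c))
    return out


def assemble_final(calls: list[PECall], z: int = 300,
                   min_reciprocal: float = 0.8) -> list[FinalCall]:
    """Merge inversion sides and translocation junctions; renumber and sort."""
    inv = [c for c in calls if c.sv_type == "INV"]
    tra = [c for c in calls if c.sv_type == "TRA"]
    rest = [finalize(c) for c in calls if c.sv_type not in ("INV", "TRA")]
    final = rest + merge_inversions(inv, min_reciprocal) + merge_translocations(tra, z)
    final.sort(key=lambda c: (c.chrom, c.start, c.end, c.sv_type, c.id))
    counters: dict[str, int] = {}
    for c in final:
        counters[c.sv_type] = counters.get(c.sv_type, 0) + 1
        c.id = f"{c.sv_type}{counters[c.sv_type]:05d}"
    return final


_INFO_HEADER = [
    ('INFO', 'SVTYPE', '1', 'String', 'Structural variant type'),
    ('INFO', 'END', '1', 'Integer', 'End position (1-based inclusive)'),
    ('INFO', 'SVLEN', '1', 'Integer', 'SV length'),
    ('INFO', 'PE', '1', 'Integer', 'Supporting discordant pairs'),
    ('INFO', 'SR', '1', 'Integer', 'Supporting split reads'),
    ('INFO', 'MAPQM', '1', 'Float', 'Mean mapping quality of supporting pairs'),
    ('INFO', 'SRQ', '1', 'Float', 'Split-read consensus alignment quality'),
    ('INFO', 'CONSENSUS', '1', 'String', 'Split-read consensus sequence'),
    ('INFO', 'CT', '1', 'String', 'Paired-end orientation class'),
    ('INFO', 'CHR2', '1', 'String', 'Partner chromosome (interchromosomal)'),
    ('INFO', 'POS2', '1', 'Integer', 'Partner breakpoint (1-based)'),
    ('INFO', 'POS2END', '1', 'Integer', 'Far end of inserted segment (1-based)'),
    ('INFO', 'INSLEN', '1', 'Integer', 'Length of junction microinsertion'),
    ('INFO', 'INSSEQ', '1', 'String', 'Junction microinsertion sequence'),
    ('INFO', 'HOMLEN', '1', 'Integer', 'Junction microhomology length'),
    ('INFO', 'CIPOS', '2', 'Integer', 'Confidence interval around POS'),
    ('INFO', 'CIEND', '2', 'Integer', 'Confidence interval around END'),
    ('INFO', 'MERGED', '.', 'String', 'Ids of merged source calls'),
    ('INFO', 'PRECISE', '0', 'Flag', 'Split-read refined breakpoints'),
    ('INFO', 'IMPRECISE', '0', 'Flag', 'Paired-end interval estimate only'),
]


def write_vcf(final_calls: list[FinalCall], path: str, fasta_path: str,
              ci: int = 0) -> str:
    """VCF 4.2 with symbolic ALTs; breakend pairs for translocations."""
    header = pysam.VariantHeader()
    for row in _INFO_HEADER:
        header.add_meta(row[0], items=[('ID', row[1]), ('Number', row[2]),
                                       ('Type', row[3]), ('Description', row[4])])
    header.filters.add('LowQual', None, None, 'Low-confidence imprecise call')
    for alt, desc in (('DEL', 'Deletion'), ('DUP', 'Tandem duplication'),
                      ('INV', 'Inversion')):
        header.add_meta('ALT', items=[('ID', alt), ('Description', desc)])
    with pysam.FastaFile(fasta_path) as fa:
        for name, length in zip(fa.references, fa.lengths):
            header.contigs.add(name, length=length)
    vcf = pysam.VariantFile(path, 'w', header=header)
    for call in sorted(final_calls, key=lambda c: (c.chrom, c.start, c.id)):
        common = dict(SVTYPE=call.sv_type, PE=call.pe_support, CT=call.orientation,
                      MAPQM=round(call.mapq_mean, 2))
        if call.precise:
            common.update(PRECISE=True, SR=call.sr_support,
                          SRQ=round(call.consensus_quality, 4))
            if call.consensus:
                common['CONSENSUS'] = call.consensus
            if call.microinsertion:
                common.update(INSLEN=len(call.microinsertion),
                              INSSEQ=call.microinsertion)
            if call.microhomology:
                common['HOMLEN'] = call.microhomology
        else:
            common['IMPRECISE'] = True
            if ci:
                common['CIPOS'] = (-ci, ci)
                common['CIEND'] = (-ci, ci)
        if len(call.merged_from) > 1:
            common['MERGED'] = call.merged_from
        if call.sv_type == 'TRA':
            common.update(CHR2=call.chrom2, POS2=call.pos2 + 1)
            if call.pos2_end is not None:
                common['POS2END'] = call.pos2_end + 1
            rec = vcf.new_record(contig=call.chrom, start=call.start,
                                 stop=call.start + 1, id=call.id,
                                 alleles=('N', f'N[{call.chrom2}:{call.pos2 + 1}['),
                                 filter=call.filter)
            rec.info['SVTYPE'] = 'BND'
            for k, v in common.items():
                if k != 'SVTYPE':
                    rec.info[k] = v
            vcf.write(rec)
        else:
            # padding-base convention for symbolic ALTs: POS is the base
            # before the event, so printed POS equals the 0-based start and
            # INFO END the 1-based inclusive (= 0-based exclusive) end.
            rec = vcf.new_record(contig=call.chrom, start=max(call.start - 1, 0),
                                 stop=call.end, id=call.id,
                                 alleles=('N', f'<{call.sv_type}>'),
                                 filter=call.filter)
            for k, v in common.items():
                rec.info[k] = v
            rec.info['SVLEN'] = call.size
            vcf.write(rec)
    vcf.close()
    return path


def read_vcf(path: str) -> list[FinalCall]:
    """Parse a call VCF back into :class:`FinalCall` records (round-trip)."""
    out: list[FinalCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            is_bnd = info.get('SVTYPE') == 'BND'
            sv_type = 'TRA' if is_bnd else info['SVTYPE']
            precise = bool(info.get('PRECISE', False))
            merged = list(info.get('MERGED', ())) or [rec.id]
            call = FinalCall(
                id=rec.id, sv_type=sv_type, chrom=rec.chrom,
                start=rec.start if is_bnd else rec.start + 1,
                end=rec.start + 1 if is_bnd else rec.stop,
                precise=precise, pe_support=info.get('PE', 0),
                sr_support=info.get('SR', 0), mapq_mean=float(info.get('MAPQM', 0.0)),
                orientation=info.get('CT', ''),
                filter=list(rec.filter)[0] if list(rec.filter) else 'PASS',
                chrom2=info.get('CHR2'),
                pos2=info['POS2'] - 1 if 'POS2' in info else None,
                pos2_end=info['POS2END'] - 1 if 'POS2END' in info else None,
                merged_from=merged, consensus=info.get('CONSENSUS', ''),
                consensus_quality=float(info.get('SRQ', 0.0)),
                microinsertion=info.get('INSSEQ', ''),
                microhomology=info.get('HOMLEN', 0))
            out.append(call)
    return out


def write_tsv(final_calls: list[FinalCall], path: str) -> str:
    """Flat TSV mirror of the call set (1-based inclusive coordinates)."""
    rows = []
    for c in sorted(final_calls, key=lambda x: (x.chrom, x.start, x.id)):
        rows.append(dict(
            id=c.id, sv_type=c.sv_type, chrom=c.chrom, start=c.start + 1, end=c.end,
            size=c.size, precise=c.precise, pe=c.pe_support, sr=c.sr_support,
            mapq_mean=round(c.mapq_mean, 2), filter=c.filter, orientation=c.orientation,
            chrom2=c.chrom2 or '.', pos2=c.pos2 + 1 if c.pos2 is not None else '.',
            pos2_end=c.pos2_end + 1 if c.pos2_end is not None else '.',
            srq=round(c.consensus_quality, 4), inslen=len(c.microinsertion),
            homlen=c.microhomology, merged_from=','.join(c.merged_from)))
    pd.DataFrame(rows).to_csv(path, sep='\t', index=False)
    return path
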