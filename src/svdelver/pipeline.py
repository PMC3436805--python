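"""End-to-end SV discovery: profile -> cluster -> refine -> merge -> write."""

from __future__ import annotations

from dataclasses import dataclass, field

from .callset import FinalCall, assemble_final, write_tsv, write_vcf
from .libio import GenomeSource, LibraryProfile, estimate_library_profile, extract_discordant
from .pe_cluster import PECall, call_paired_end
from .sr_refine import SRParams, collect_split_candidates, refine_call

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
_SIGS_BY_TYPE = {
    "DEL": ("DEL",), "DUP": ("DUP",), "INV": ("INV_LEFT", "INV_RIGHT"),
    "TRA": ("TRA_1", "TRA_2", "TRA_3", "TRA_4"),
}


@dataclass
class CallerParams:
    """Knobs of the whole caller, mirroring the command-line options."""

    sv_types: tuple[str, ...] = SV_TYPES
    map_qual: int = 1
    mad_cutoff: float = 3.0  # insert-size cutoff in standard deviations
    sample_size: int = 10_000
    min_pairs: int = 2
    include_softclips: bool = False
    tra_merge_distance: int = 300  # z
    inv_min_reciprocal: float = 0.8
    sr: SRParams = field(default_factory=SRParams)


@dataclass
class DiscoveryResult:
    profiles: dict[str, LibraryProfile]
    pe_calls: list[PECall]
    refined: list[PECall]  # SRCall where refinement succeeded
    final: list[FinalCall]

    @property
    def precise(self) -> list[FinalCall]:
        return [c for c in self.final if c.precise]


def discover(bam_paths: list[str], fasta_path: str,
             params: CallerParams | None = None,
             split_reads: bool = True) -> DiscoveryResult:
    """Run the integrated paired-end + split-read caller on one sample.

    Each BAM is treated as one library with its own insert-size profile;
    all libraries are analyzed jointly.  With ``split_reads=False`` the
    result contains merged paired-end calls only.
    """
    params = params or CallerParams()
    profiles = {
        path: estimate_library_profile(path, params.sample_size, params.mad_cutoff)
        for path in bam_paths
    }
    bins, anchored = extract_discordant(
        bam_paths, profiles, params.map_qual, collect_anchored=True,
        include_softclips=params.include_softclips)
    wanted = {sig for t in params.sv_types for sig in _SIGS_BY_TYPE[t]}
    bins = {k: v for k, v in bins.items() if k[0] in wanted}
    pe_calls = call_paired_end(bins, profiles, params.min_pairs)
    if not split_reads:
        final = assemble_final(pe_calls, params.tra_merge_distance,
                               params.inv_min_reciprocal)
        return DiscoveryResult(profiles, pe_calls, list(pe_calls), final)
    genome = GenomeSource(fasta_path)
    candidates = collect_split_candidates(pe_calls, anchored, profiles,
                                          params.sr.max_candidates)
    refined = [refine_call(c, candidates.get(c.id, []), genome, profiles, params.sr)
               for c in pe_calls]
    final = assemble_final(refined, params.tra_merge_distance,
                           params.inv_min_reciprocal)
    return DiscoveryResult(profiles, pe_calls, refined, final)


def discover_and_write(bam_paths: list[str], fasta_path: str, out_vcf: str,
                       params: CallerParams | None = None,
                       out_tsv: str | None = None) -> DiscoveryResult:
    """Run :func:`discover` and write the VCF (and optional TSV) output."""
    result = discover(bam_paths, fasta_path, params)
    ci = int(max(p.insert_max for p in result.profiles.values())) if result.profiles else 0
    write_vcf(result.final, out_vcf, fasta_path, ci=ci)
    if out_tsv:
        write_tsv(result.final, out_tsv)
    return result
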