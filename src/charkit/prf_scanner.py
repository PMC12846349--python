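"""-1 programmed ribosomal frameshift (PRF) scanner for tail-assembly-chaperone loci.

Tail assembly chaperones of many tailed phages are made as a short (TAC-N)
and a long (TAC-NC) isoform; the long form arises when the ribosome slips
back one nucleotide on a slippery sequence (here the hexamer GTTTTT) near
the 3' end of the TAC-N reading frame, bypassing the frame-0 stop codon.

The scanner locates the slippery motif inside a 3'-terminal window of an
annotated ORF, applies the -1 shift immediately after the motif's last
base, and checks that the -1 reading frame runs stop-free past the
original stop codon. A locus "passes" when a motif is present, no
premature -1 stop occurs before the original stop, and the read-through
extension reaches a threshold (default 200 nt). ``survey_locus`` repeats
the test across a genome set and summarizes allele diversity and
column-wise conservation of the locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import EmptyInputError
from .genome_io import STOP_CODONS, FeatureCoord, GenomeRecord, reverse_complement
from .seq_align import (Alignment, ConservationProfile, ScoringScheme,
                        DEFAULT_SCHEME, conservation_profile, star_msa)

DEFAULT_MOTIF = "GTTTTT"


@dataclass(frozen=True)
class SlipperySite:
    """A slippery-motif occurrence near the 3' end of an ORF.

    ``genome_pos`` is the 0-based genome coordinate of the motif start in
    coding-strand orientation. ``offset_from_stop`` counts the nucleotides
    between the end of the motif and the 3' end of the ORF (stop codon
    included): a motif immediately preceding the stop codon has offset 3.
    """

    genome_pos: int
    offset_from_stop: int
    motif: str


@dataclass
class FrameshiftResult:
    genome_id: str
    orf_id: str
    site: SlipperySite | None
    extension_nt: int
    premature_stop: bool
    unterminated: bool = False
    threshold_nt: int = 200

    @property
    def passes(self) -> bool:
        return (self.site is not None and not self.premature_stop
                and not self.unterminated and self.extension_nt >= self.threshold_nt)


@dataclass
class LocusSurvey:
    n_genomes: int
    n_unique_alleles: int
    per_genome: list[FrameshiftResult]
    alleles: list[tuple[str, int]] = field(default_factory=list)
    msa: Alignment | None = None
    conservation: ConservationProfile | None = None


def _coding_context(record: GenomeRecord, orf: FeatureCoord,
                    downstream_nt: int) -> str:
    """ORF sequence in coding orientation plus up to ``downstream_nt`` of
    downstream genomic context."""
    n = len(record)
    if orf.strand == "+":
        return record.sequence[orf.start:min(n, orf.end + downstream_nt)]
    seg = record.sequence[max(0, orf.start - downstream_nt):orf.end]
    return reverse_complement(seg)


def find_slippery(record: GenomeRecord, orf: FeatureCoord,
                  motif: str = DEFAULT_MOTIF,
                  window_nt: int = 60) -> list[SlipperySite]:
    """All exact motif occurrences whose start lies within the final
    ``window_nt`` of the ORF (stop codon included), 5'->3' on the coding
    strand. An ORF shorter than the window is searched in full.
    """
    if orf.end > len(record) or orf.start < 0:
        raise ValueError(f"ORF {orf.feature_id!r} outside genome {record.id!r}")
    motif = motif.upper()
    cds = record.feature_sequence(orf)
    L = len(cds)
    window = min(window_nt, L)
    lo = L - window
    sites = []
    pos = cds.find(motif, lo)
    while pos != -1:
        # motif must start within the window; it may run up to the ORF end
        if pos + len(motif) <= L:
            if orf.strand == "+":
                gpos = orf.start + pos
            else:
                gpos = orf.end - pos - len(motif)
            sites.append(SlipperySite(
                genome_pos=gpos,
                offset_from_stop=L - (pos + len(motif)),
                motif=motif,
            ))
        pos = cds.find(motif, pos + 1)
    return sites


def minus1_extension(record: GenomeRecord, orf: FeatureCoord,
                     site: SlipperySite, scan_limit_nt: int = 3000,
                     threshold_nt: int = 200) -> FrameshiftResult:
    """Apply the -1 frameshift at ``site`` and measure read-through.

    Translation proceeds in frame 0 through the motif, then resumes one
    nucleotide back immediately after the motif's last base. A -1 frame
    stop codon starting strictly before the original frame-0 stop codon is
    a premature stop (extension 0). Otherwise extension_nt is the distance
    from the start of the original stop codon to the end of the first -1
    frame stop at or beyond it. If no -1 stop occurs within
    ``scan_limit_nt`` past the ORF end the result is flagged unterminated.
    """
    if site is None:
        raise ValueError("minus1_extension requires a slippery site")
    seq = _coding_context(record, orf, scan_limit_nt)
    L = orf.end - orf.start
    # motif position in ORF-local coordinates
    if orf.strand == "+":
        m0 = site.genome_pos - orf.start
    else:
        m0 = orf.end - site.genome_pos - len(site.motif)
    slip = m0 + len(site.motif) - 1  # first base of the -1 frame
    orig_stop_start = L - 3
    premature = False
    ext = 0
    unterminated = True
    for pos in range(slip, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if codon in STOP_CODONS:
            unterminated = False
            if pos < orig_stop_start:
                premature = True
                ext = 0
            else:
                ext = (pos + 3) - orig_stop_start
            break
    if premature:
        unterminated = False
    return FrameshiftResult(
        genome_id=record.id, orf_id=orf.feature_id, site=site,
        extension_nt=ext, premature_stop=premature,
        unterminated=unterminated, threshold_nt=threshold_nt)


def dedupe_alleles(loci: list[str]) -> list[tuple[str, int]]:
    """Case-insensitive exact deduplication; alleles sorted by descending
    count then lexicographically. Counts sum to the input size."""
    if not loci:
        raise EmptyInputError("dedupe_alleles requires a non-empty list")
    counts = Counter(s.upper() for s in loci)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def scan_orf(record: GenomeRecord, orf: FeatureCoord,
             motif: str = DEFAULT_MOTIF, window_nt: int = 60,
             scan_limit_nt: int = 3000, threshold_nt: int = 200) -> FrameshiftResult:
    """find_slippery + minus1_extension for one ORF; when several motif
    occurrences fall in the window the one closest to the stop codon is
    tested."""
    sites = find_slippery(record, orf, motif=motif, window_nt=window_nt)
    if not sites:
        return FrameshiftResult(genome_id=record.id, orf_id=orf.feature_id,
                                site=None, extension_nt=0, premature_stop=False,
                                threshold_nt=threshold_nt)
    site = min(sites, key=lambda s: s.offset_from_stop)
    return minus1_extension(record, orf, site, scan_limit_nt=scan_limit_nt,
                            threshold_nt=threshold_nt)


def survey_locus(genomes: list[GenomeRecord], locus_ids: dict[str, str],
                 threshold_nt: int = 200, motif: str = DEFAULT_MOTIF,
                 window_nt: int = 60, scan_limit_nt: int = 3000,
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 align: bool = True) -> LocusSurvey:
    """Run the -1 PRF test on a named locus across a genome set.

    ``locus_ids`` maps genome id -> ORF feature id. Unique alleles (ORF
    nucleotide sequences, coding strand) are counted and, when ``align``
    is true and at least two unique alleles exist, aligned with the
    center-star aligner and summarized as a conservation profile.
    """
    results: list[FrameshiftResult] = []
    allele_seqs: list[str] = []
    for g in genomes:
        if g.id not in locus_ids:
            raise KeyError(f"no locus id supplied for genome {g.id!r}")
        try:
            orf = g.feature_by_id(locus_ids[g.id])
        except KeyError as exc:
            raise KeyError(f"genome {g.id!r} lacks ORF {locus_ids[g.id]!r}") from exc
        results.append(scan_orf(g, orf, motif=motif, window_nt=window_nt,
                                scan_limit_nt=scan_limit_nt,
                                threshold_nt=threshold_nt))
        allele_seqs.append(g.feature_sequence(orf))
    alleles = dedupe_alleles(allele_seqs)
    msa = None
    profile = None
    if align and len(alleles) >= 2:
        msa = star_msa([a for a, _ in alleles], scheme,
                       ids=[f"allele_{i}" for i in range(len(alleles))])
        profile = conservation_profile(msa)
    return LocusSurvey(
        n_genomes=len(genomes),
        n_unique_alleles=len(alleles),
        per_genome=results,
        alleles=alleles,
        msa=msa,
        conservation=profile,
    )
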