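"""Sequence record I/O and whole-genome statistics.

Reads FASTA/GenBank records into :class:`GenomeRecord` objects with 0-based
half-open, strand-aware feature coordinates, and provides the genome-level
computations consumed by the frameshift scanner: GC content, direct
terminal repeat (DTR) border detection, and ORF extraction.

Linear phage genomes are frequently deposited with the terminal repeat
present once at each end; ``detect_dtr`` finds the longest exact
prefix == suffix border, which is how such a repeat manifests in the
assembled sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ParseError, UndefinedValueError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureCoord:
    """A strand-aware feature interval in 0-based half-open genome coordinates."""

    feature_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A nucleotide sequence plus strand-aware feature coordinates."""

    id: str
    sequence: str
    features: list[FeatureCoord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.feature_id!r} [{f.start}, {f.end}) exceeds "
                    f"genome length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_id(self, feature_id: str) -> FeatureCoord:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"genome {self.id!r} has no feature {feature_id!r}")

    def feature_sequence(self, feat: FeatureCoord) -> str:
        """Coding-strand (5'->3') sequence of a feature."""
        s = self.sequence[feat.start:feat.end]
        return reverse_complement(s) if feat.strand == "-" else s


@dataclass(frozen=True)
class DtrResult:
    """Direct-terminal-repeat border: longest exact prefix == suffix match."""

    repeat_length: int
    unique_length: int
    found: bool


def _feature_id_of(biofeat: SeqFeature, index: int) -> str:
    q = biofeat.qualifiers
    for key in ("locus_tag", "gene", "protein_id", "ID"):
        if key in q and q[key]:
            return str(q[key][0])
    return f"feature_{index:04d}"


def read_genomes(path: str, format: str | None = None) -> list[GenomeRecord]:
    """Read FASTA or GenBank records.

    GenBank CDS features are converted to 0-based half-open
    :class:`FeatureCoord` preserving locus tags and strand (GenBank's
    1-based inclusive convention only exists at this boundary).
    ``format`` defaults from the file extension.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "genbank" if ext in (".gb", ".gbk", ".genbank", ".gbff") else "fasta"
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        seq_records = list(SeqIO.parse(path, format))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ParseError(f"cannot parse {path!r} as {format}: {exc}") from exc
    if not seq_records:
        raise EmptyInputError(f"no {format} records found in {path!r}")

    out: list[GenomeRecord] = []
    for rec in seq_records:
        feats: list[FeatureCoord] = []
        for i, bf in enumerate(rec.features):
            if bf.type != "CDS" or bf.location is None:
                continue
            strand = "-" if bf.location.strand == -1 else "+"
            feats.append(FeatureCoord(
                feature_id=_feature_id_of(bf, i),
                start=int(bf.location.start),
                end=int(bf.location.end),
                strand=strand,
                kind="CDS",
            ))
        if len(rec.seq) == 0:
            raise ParseError(f"record {rec.id!r} in {path!r} has an empty sequence")
        out.append(GenomeRecord(id=rec.id, sequence=str(rec.seq),
                                features=feats, source=path))
    return out


def write_genbank(records: list[GenomeRecord], path: str) -> None:
    """Write records with their CDS features as a GenBank flat file."""
    seq_records = []
    for g in records:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        for f in g.features:
            loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
            rec.features.append(SeqFeature(
                loc, type=f.kind if f.kind == "CDS" else "misc_feature",
                qualifiers={"locus_tag": [f.feature_id]}))
        seq_records.append(rec)
    SeqIO.write(seq_records, path, "genbank")


def write_fasta(records: list[GenomeRecord], path: str) -> None:
    seq_records = [SeqRecord(Seq(g.sequence), id=g.id, description="")
                   for g in records]
    SeqIO.write(seq_records, path, "fasta")


def read_gff3_features(path: str) -> dict[str, list[FeatureCoord]]:
    """Read CDS/gene features from a GFF3 file, keyed by sequence id.

    GFF3 is 1-based inclusive; coordinates are converted to the internal
    0-based half-open convention on read.
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out: dict[str, list[FeatureCoord]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        fid = (feat.attributes.get("locus_tag", [None])[0]
               or feat.attributes.get("ID", [feat.id])[0])
        out.setdefault(feat.seqid, []).append(FeatureCoord(
            feature_id=str(fid),
            start=feat.start - 1,
            end=feat.end,
            strand="-" if feat.strand == "-" else "+",
            kind="CDS" if feat.featuretype == "CDS" else "other",
        ))
    return out


def gc_content(record: GenomeRecord | str) -> float:
    """GC percentage over unambiguous bases only.

    100 * (G + C) / (A + C + G + T); N and ambiguity codes are excluded
    from both numerator and denominator.
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else record.upper()
    if not seq:
        raise EmptyInputError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedValueError("sequence contains no unambiguous A/C/G/T base")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def _border_lengths(seq: str) -> list[int]:
    """All border lengths of ``seq`` (prefix == suffix), descending.

    Computed with the Knuth-Morris-Pratt prefix function in O(n); the
    borders of a string form the chain pi[n-1], pi[pi[n-1]-1], ...
    """
    n = len(seq)
    pi = [0] * n
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = pi[k - 1]
        if seq[i] == seq[k]:
            k += 1
        pi[i] = k
    chain = []
    k = pi[n - 1]
    while k:
        chain.append(k)
        k = pi[k - 1]
    return chain


def detect_dtr(record: GenomeRecord | str, min_len: int = 20) -> DtrResult:
    """Longest exact terminal repeat border of an assembled linear genome.

    repeat_length is the longest k <= floor(n/2) with seq[:k] == seq[-k:];
    found requires repeat_length >= min_len. Exact matching only -- this is
    a border detector on the deposited assembly, not a read-coverage
    terminus predictor.
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else record.upper()
    n = len(seq)
    if n < 2 * min_len:
        raise ValueError(f"sequence length {n} < 2 * min_len ({2 * min_len})")
    repeat = 0
    for k in _border_lengths(seq):
        if k <= n // 2:
            repeat = k
            break
    found = repeat >= min_len
    return DtrResult(repeat_length=repeat,
                     unique_length=n - repeat if found else n,
                     found=found)


def _orfs_on_strand(seq: str, min_aa: int, starts: frozenset[str]) -> list[tuple[int, int]]:
    """Maximal ORFs on the forward strand of ``seq``: (start, end) half-open,
    end includes the stop codon; leftmost allowed start per stop-anchored frame."""
    n = len(seq)
    out = []
    for frame in range(3):
        region_start = frame  # left edge of the current inter-stop segment
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                # leftmost start codon in [region_start, pos)
                for s in range(region_start, pos, 3):
                    if seq[s:s + 3] in starts:
                        if (pos - s) // 3 >= min_aa:
                            out.append((s, pos + 3))
                        break
                region_start = pos + 3
    return out


def extract_orfs(record: GenomeRecord, min_aa: int = 30,
                 starts: frozenset[str] = DEFAULT_START_CODONS) -> list[FeatureCoord]:
    """All maximal ORFs on both strands, from an allowed start codon to the
    first in-frame stop, protein length >= min_aa codons.

    Coordinates are genome coordinates (half-open, stop codon included);
    minus-strand ORFs carry strand="-". Per stop-anchored frame the leftmost
    (longest) start is reported.
    """
    seq = record.sequence
    n = len(seq)
    feats = []
    for s, e in _orfs_on_strand(seq, min_aa, starts):
        feats.append(FeatureCoord(f"orf_{s}_{e}_+", s, e, "+"))
    rc = reverse_complement(seq)
    for s, e in _orfs_on_strand(rc, min_aa, starts):
        feats.append(FeatureCoord(f"orf_{n - e}_{n - s}_-", n - e, n - s, "-"))
    feats.sort(key=lambda f: (f.start, f.end, f.strand))
    return feats


def fetch_genome(accession: str, format: str = "fasta",
                 cache_dir: str | None = None,
                 timeout: float = 10.0) -> GenomeRecord:
    """Fetch a nucleotide record from NCBI by accession, with a local cache.

    Looks for ``<accession>.fasta`` / ``<accession>.gbk`` in ``cache_dir``
    (default ``~/.cache/charkit``) and in ``./data`` first; otherwise
    downloads via NCBI E-utilities and caches the result. Requires network
    access on the first call for a given accession. ``format="genbank"``
    retrieves the annotated record (CDS features with locus tags).
    """
    import urllib.request

    ext = "gbk" if format == "genbank" else "fasta"
    rettype = "gbwithparts" if format == "genbank" else "fasta"
    if cache_dir is None:
        cache_dir = os.path.join(os.path.expanduser("~"), ".cache", "charkit")
    for d in (cache_dir, "data"):
        path = os.path.join(d, f"{accession}.{ext}")
        if os.path.exists(path):
            return read_genomes(path, format=format)[0]
    url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           f"?db=nuccore&id={accession}&rettype={rettype}&retmode=text")
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except Exception as exc:
        raise IOError(
            f"accession {accession} is not cached locally and could not be "
            f"downloaded ({exc}); place {accession}.{ext} under {cache_dir!r} "
            "or ./data") from exc
    os.makedirs(cache_dir, exist_ok=True)
    out = os.path.join(cache_dir, f"{accession}.{ext}")
    with open(out, "w") as fh:
        fh.write(text)
    return read_genomes(out, format=format)[0]
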