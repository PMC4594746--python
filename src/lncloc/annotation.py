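"""Transcript/gene data model, GTF/GFF3/FASTA I/O and locus grouping.

Internal coordinates are 0-based half-open throughout; the GTF/GFF3
readers and writers convert to and from the 1-based inclusive convention
of those formats.  A *locus* is a connected component of transcripts
under same-strand exonic overlap (>= 1 bp), which mirrors how assembly
tools group transcript isoforms into genes.
"""

from __future__ import annotations

import logging
import re
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Raised for malformed GTF/GFF3 input; message names the line number."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """Genomic interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ExonInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "ExonInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "ExonInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered chain of exons on a chromosome strand.

    ``strand`` may be ``"."`` for assembled transcripts of unknown
    orientation; reference annotations reject those at load time.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(sorted(self.exons))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> ExonInterval:
        return ExonInterval(self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature) length in nt: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    def introns(self) -> list[ExonInterval]:
        """Gaps between consecutive exons, 5'->3' in genome order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(ExonInterval(a.end, b.start))
        return out


def transcript_length(t: TranscriptModel) -> int:
    return t.length


def introns(t: TranscriptModel) -> list[ExonInterval]:
    return t.introns()


@dataclass
class GeneModel:
    """A reference gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom:
                raise ValueError(
                    f"{self.gene_id}: transcript {t.transcript_id} on {t.chrom},"
                    f" gene on {self.chrom}"
                )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> ExonInterval:
        return ExonInterval(self.start, self.end)

    def exons(self) -> list[ExonInterval]:
        return [e for t in self.transcripts for e in t.exons]

    def merged_exons(self) -> list[ExonInterval]:
        """Union of exon intervals across isoforms, merged where overlapping."""
        out: list[ExonInterval] = []
        for e in sorted(self.exons()):
            if out and e.start <= out[-1].end:
                if e.end > out[-1].end:
                    out[-1] = ExonInterval(out[-1].start, e.end)
            else:
                out.append(e)
        return out

    def introns(self) -> list[ExonInterval]:
        return [i for t in self.transcripts for i in t.introns()]


class GenomeAnnotation:
    """Indexed reference annotation supporting strand-aware interval queries.

    Builds per-chromosome interval trees over gene spans, exons and
    introns, plus an exact-coordinate intron set for splice-junction
    matching.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._intron_set: set[tuple[str, str, int, int]] = set()
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            if g.strand == ".":
                raise ValueError(
                    f"{g.gene_id}: reference annotation requires a strand"
                )
            self.genes[g.gene_id] = g
            tree = self._span_trees.setdefault(g.chrom, IntervalTree())
            tree[g.start : g.end] = g.gene_id
            self._by_chrom.setdefault(g.chrom, []).append(g)
            for i in g.introns():
                self._intron_set.add((g.chrom, g.strand, i.start, i.end))
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: (g.start, g.gene_id))

    @classmethod
    def from_transcripts(cls, ts: Iterable[TranscriptModel]) -> "GenomeAnnotation":
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in ts:
            by_gene.setdefault(t.gene_id, []).append(t)
        genes = []
        for gid, members in by_gene.items():
            chroms = {t.chrom for t in members}
            strands = {t.strand for t in members}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(
                    f"gene {gid!r} spans multiple chroms/strands: {chroms}/{strands}"
                )
            genes.append(GeneModel(gid, members[0].chrom, members[0].strand, members))
        return cls(genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def genes_on_chrom(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end) by >= 1 bp, any strand."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end)})
        return [self.genes[gid] for gid in hits]

    def has_intron(self, chrom: str, strand: str, start: int, end: int) -> bool:
        """True if some reference transcript has exactly this intron."""
        return (chrom, strand, start, end) in self._intron_set


@dataclass(frozen=True)
class Locus:
    """Connected component of transcripts under same-strand exonic overlap."""

    locus_id: str
    chrom: str
    strand: str
    member_transcript_ids: tuple[str, ...]

    @property
    def n_isoforms(self) -> int:
        return len(self.member_transcript_ids)


# ---------------------------------------------------------------------------
# GTF / GFF3 I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(
    path: str | Path,
    *,
    require_strand: bool = False,
) -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModels.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open, and exons are sorted by start.  ``require_strand=True``
    rejects strand "." records (use for reference annotations);
    otherwise they are accepted with a warning.
    """
    path = Path(path)
    exons: dict[str, list[ExonInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(
                    f"{path}:{lineno}: exon end {end1} < start {start1}"
                )
            if strand not in STRANDS:
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attr = _parse_gtf_attributes(attrs)
            tid, gid = attr.get("transcript_id"), attr.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            if tid in meta:
                prev_gid, prev_chrom, prev_strand = meta[tid]
                if prev_chrom != chrom:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript_id {tid!r} appears on both"
                        f" {prev_chrom} and {chrom}"
                    )
                if prev_strand != strand:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript_id {tid!r} has inconsistent strand"
                    )
            else:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            exons.setdefault(tid, []).append(ExonInterval(start1 - 1, end1))

    out = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        if strand == ".":
            if require_strand:
                raise GtfParseError(
                    f"{path}: transcript {tid!r} has strand '.'; reference"
                    " annotations require a strand"
                )
            logger.warning(
                "transcript %s has unknown strand '.'; it will be excluded"
                " from strand-specific classes",
                tid,
            )
        out.append(TranscriptModel(tid, gid, chrom, strand, tuple(exons[tid])))
    return out


def write_gtf(
    ts: Iterable[TranscriptModel],
    path: str | Path,
    *,
    source: str = "lncloc",
    extra_attrs: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write transcripts as GTF exon features (1-based inclusive coords)."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for t in ts:
            extra = "".join(
                f' {k} "{v}";' for k, v in extra_attrs.get(t.transcript_id, {}).items()
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f'{t.strand}\t.\tgene_id "{t.gene_id}"; '
                    f'transcript_id "{t.transcript_id}";{extra}\n'
                )


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read a gene -> mRNA -> exon GFF3 hierarchy into TranscriptModels.

    The gene_id of each transcript is its Parent gene feature (falling
    back to the transcript's own ID when no parent is recorded).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for feat_type in ("mRNA", "transcript"):
        for mrna in db.features_of_type(feat_type):
            exon_ivs = tuple(
                ExonInterval(e.start - 1, e.end)
                for e in db.children(mrna, featuretype="exon")
            )
            if not exon_ivs:
                continue
            parents = mrna.attributes.get("Parent", [])
            gene_id = parents[0] if parents else mrna.id
            out.append(
                TranscriptModel(mrna.id, gene_id, mrna.seqid, mrna.strand, exon_ivs)
            )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a reference annotation as a gene/mRNA/exon GFF3 hierarchy."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(
            annotation.genes, key=lambda g: (annotation.genes[g].chrom, annotation.genes[g].start, g)
        ):
            g = annotation.genes[gid]
            fh.write(
                f"{g.chrom}\tlncloc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: (t.start, t.transcript_id)):
                fh.write(
                    f"{g.chrom}\tlncloc\tmRNA\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for k, e in enumerate(t.exons, start=1):
                    fh.write(
                        f"{g.chrom}\tlncloc\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\tID={t.transcript_id}.exon{k};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Genome sequence access
# ---------------------------------------------------------------------------

_CLEAN_RE = re.compile(r"[^ACGT]")


class GenomeSequence:
    """Random-access genome FASTA; uppercase, non-ACGT mapped to N."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def chrom_length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        n = len(self._fa[chrom])
        if start < 0 or end > n:
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} (length {n})"
            )
        seq = self._fa[chrom][start:end].seq.upper()
        return _CLEAN_RE.sub("N", seq)


class DictGenome:
    """In-memory genome (chrom -> sequence string) with the fetch protocol."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {c: _CLEAN_RE.sub("N", s.upper()) for c, s in seqs.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        n = len(self._seqs[chrom])
        if start < 0 or end > n:
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} (length {n})"
            )
        return self._seqs[chrom][start:end]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Locus grouping
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_loci(
    ts: Sequence[TranscriptModel], *, id_prefix: str = "LOC"
) -> list[Locus]:
    """Partition transcripts into loci.

    Two transcripts belong to the same locus when they are connected
    (transitively) by same-chromosome, same-strand exonic overlap of at
    least 1 bp.  Transcripts with strand "." only group among
    themselves.  Loci are numbered by (chrom, span start).

    Uses a sweep over start-sorted exons: an exon starting before the
    running maximum end of the current chain must overlap the exon
    attaining that maximum, so a single union per exon suffices.
    """
    ts = list(ts)
    uf = _UnionFind(len(ts))
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(ts):
        for e in t.exons:
            by_key.setdefault((t.chrom, t.strand), []).append((e.start, e.end, idx))
    for key, exon_list in by_key.items():
        exon_list.sort()
        max_end = -1
        max_owner = -1
        for start, end, idx in exon_list:
            if start < max_end:
                uf.union(max_owner, idx)
            if end > max_end:
                max_end, max_owner = end, uf.find(idx)
            else:
                max_owner = uf.find(max_owner)

    components: dict[int, list[int]] = {}
    for idx in range(len(ts)):
        components.setdefault(uf.find(idx), []).append(idx)

    loci = []
    for members in components.values():
        members.sort(key=lambda i: (ts[i].start, ts[i].transcript_id))
        chrom, strand = ts[members[0]].chrom, ts[members[0]].strand
        start = min(ts[i].start for i in members)
        loci.append(
            (chrom, start, strand, tuple(ts[i].transcript_id for i in members))
        )
    loci.sort()
    return [
        Locus(f"{id_prefix}{k}", chrom, strand, member_ids)
        for k, (chrom, _start, strand, member_ids) in enumerate(loci, start=1)
    ]
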