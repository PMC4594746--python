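"""Genomic-location classification of lncRNA candidates.

Each candidate transcript gets exactly one of seven classes relative to
a protein-coding reference annotation:

* ``JUNCTION_SHARED`` — same strand, at least one intron identical
  (both boundaries) to a reference intron;
* ``EXONIC_SENSE`` — same strand, >= 1 bp exon-exon overlap;
* ``EXONIC_ANTISENSE`` — opposite strand, >= 1 bp exon-exon overlap;
* ``INTRONIC_SENSE`` — same strand, entire span inside one reference
  intron;
* ``INTRONIC_ANTISENSE`` — opposite strand, exons overlap a reference
  intron but no reference exon of that gene;
* ``INTERGENIC`` — no overlap with any gene span;
* ``UNCLASSIFIED`` — residual: strand-unknown transcripts overlapping a
  gene, or overlap patterns matching no rule.

When several rules fire (possibly against different genes) the class is
resolved by a precedence ladder, strongest structural evidence first:
junction sharing > exonic sense > exonic antisense > intronic sense >
intronic antisense.  The partner gene is the overlapped gene, ties
broken by largest exonic overlap then smallest gene_id.

Names follow an HGNC-style scheme: intergenic loci ``<prefix>LINC<n>``,
intronic-sense ``<gene>-IT``, antisense (exonic or intronic)
``<gene>-AS``, sense-overlapping (exonic or junction-sharing)
``<gene>-OT``, unclassified ``<prefix>LNC-unc<n>``; isoforms within a
multi-isoform locus carry -RA, -RB, ... suffixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, Locus, TranscriptModel

logger = logging.getLogger(__name__)


class LncClass(str, Enum):
    INTERGENIC = "intergenic"
    INTRONIC_SENSE = "intronic_sense"
    INTRONIC_ANTISENSE = "intronic_antisense"
    EXONIC_SENSE = "exonic_sense"
    EXONIC_ANTISENSE = "exonic_antisense"
    JUNCTION_SHARED = "junction_shared"
    UNCLASSIFIED = "unclassified"


#: Precedence among overlap classes, strongest evidence first.
DEFAULT_PRECEDENCE = (
    LncClass.JUNCTION_SHARED,
    LncClass.EXONIC_SENSE,
    LncClass.EXONIC_ANTISENSE,
    LncClass.INTRONIC_SENSE,
    LncClass.INTRONIC_ANTISENSE,
)

#: Display order used in class tables.
TABLE_ORDER = (
    LncClass.INTERGENIC,
    LncClass.INTRONIC_SENSE,
    LncClass.INTRONIC_ANTISENSE,
    LncClass.EXONIC_SENSE,
    LncClass.EXONIC_ANTISENSE,
    LncClass.JUNCTION_SHARED,
    LncClass.UNCLASSIFIED,
)


@dataclass
class LncRNARecord:
    """A classified lncRNA candidate."""

    transcript: TranscriptModel
    lnc_class: LncClass
    partner_gene_id: str | None = None
    assigned_name: str = ""
    distance_to_nearest_gene: float = 0.0
    isoform_suffix: str = ""

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def _exonic_overlap_bp(t: TranscriptModel, gene: GeneModel) -> int:
    merged = gene.merged_exons()
    total = 0
    for e in t.exons:
        for m in merged:
            total += e.overlap_bp(m)
    return total


def _gene_classes(t: TranscriptModel, gene: GeneModel) -> set[LncClass]:
    """All overlap rules satisfied by t against a single reference gene."""
    same = t.strand == gene.strand
    classes: set[LncClass] = set()
    exonic_bp = _exonic_overlap_bp(t, gene)
    ref_introns = set(gene.introns())
    if same and any(i in ref_introns for i in t.introns()):
        classes.add(LncClass.JUNCTION_SHARED)
    if exonic_bp >= 1:
        classes.add(LncClass.EXONIC_SENSE if same else LncClass.EXONIC_ANTISENSE)
    if same and any(i.contains(t.span) for i in gene.introns()):
        classes.add(LncClass.INTRONIC_SENSE)
    if (
        not same
        and exonic_bp == 0
        and any(any(e.overlaps(i) for i in ref_introns) for e in t.exons)
    ):
        classes.add(LncClass.INTRONIC_ANTISENSE)
    return classes


def classify(
    t: TranscriptModel,
    ann: GenomeAnnotation,
    *,
    precedence: Sequence[LncClass] = DEFAULT_PRECEDENCE,
) -> tuple[LncClass, str | None]:
    """Classify one transcript against the reference annotation.

    Returns the class and the partner gene_id (None for INTERGENIC and
    UNCLASSIFIED).  A transcript on a chromosome absent from the
    annotation is classified against an empty annotation (INTERGENIC)
    with a warning.
    """
    if t.chrom not in ann.chroms:
        logger.warning(
            "transcript %s: chromosome %s absent from annotation; INTERGENIC",
            t.transcript_id,
            t.chrom,
        )
        return LncClass.INTERGENIC, None

    genes = ann.genes_overlapping(t.chrom, t.start, t.end)
    if not genes:
        return LncClass.INTERGENIC, None
    if t.strand == ".":
        return LncClass.UNCLASSIFIED, None

    per_gene: dict[str, set[LncClass]] = {
        g.gene_id: _gene_classes(t, g) for g in genes
    }
    for cls in precedence:
        candidates = [g for g in genes if cls in per_gene[g.gene_id]]
        if candidates:
            partner = max(
                candidates,
                key=lambda g: (_exonic_overlap_bp(t, g), _neg_lex(g.gene_id)),
            )
            return cls, partner.gene_id
    return LncClass.UNCLASSIFIED, None


class _neg_lex(str):
    """Inverts lexicographic order so max() picks the smallest gene_id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def classify_all(
    ts: Iterable[TranscriptModel],
    ann: GenomeAnnotation,
    *,
    precedence: Sequence[LncClass] = DEFAULT_PRECEDENCE,
) -> list[LncRNARecord]:
    from .coexpression import nearest_gene  # local import to avoid cycle

    records = []
    for t in ts:
        cls, partner = classify(t, ann, precedence=precedence)
        if partner is not None:
            dist = 0.0
        else:
            dist = float(nearest_gene(t, ann).distance)
        records.append(
            LncRNARecord(
                transcript=t,
                lnc_class=cls,
                partner_gene_id=partner,
                distance_to_nearest_gene=dist,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

_SUFFIX_BY_CLASS = {
    LncClass.INTRONIC_SENSE: "IT",
    LncClass.INTRONIC_ANTISENSE: "AS",
    LncClass.EXONIC_ANTISENSE: "AS",
    LncClass.EXONIC_SENSE: "OT",
    LncClass.JUNCTION_SHARED: "OT",
}


def _isoform_letters(k: int) -> str:
    """0 -> A, 1 -> B, ..., 25 -> Z, 26 -> AA, ..."""
    out = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def assign_names(
    records: list[LncRNARecord],
    loci: Sequence[Locus],
    *,
    prefix: str = "BPH",
) -> list[LncRNARecord]:
    """Assign locus-based names to classified records.

    Loci are named by their highest-precedence member class; intergenic
    and unclassified loci are numbered densely in (chrom, start) order;
    partner-based names reuse the partner gene_id with an -IT/-AS/-OT
    suffix, disambiguated numerically when several loci share a partner
    gene and suffix (-OT, -OT2, ...).  Isoform suffixes -RA, -RB, ...
    (ordered by start then transcript_id) are appended in multi-isoform
    loci.
    """
    by_tid = {r.transcript_id: r for r in records}
    rank = {cls: i for i, cls in enumerate(DEFAULT_PRECEDENCE)}

    locus_info = []
    for locus in loci:
        members = [by_tid[tid] for tid in locus.member_transcript_ids if tid in by_tid]
        if not members:
            continue
        overlap_members = [m for m in members if m.lnc_class in rank]
        if overlap_members:
            rep = min(overlap_members, key=lambda m: rank[m.lnc_class])
        else:
            rep = min(
                members,
                key=lambda m: 0 if m.lnc_class is LncClass.INTERGENIC else 1,
            )
        start = min(m.transcript.start for m in members)
        locus_info.append((locus.chrom, start, locus, members, rep))
    locus_info.sort(key=lambda x: (x[0], x[1], x[2].locus_id))

    n_linc = 0
    n_unc = 0
    suffix_seen: dict[tuple[str, str], int] = {}
    out: list[LncRNARecord] = []
    for _chrom, _start, _locus, members, rep in locus_info:
        if rep.lnc_class is LncClass.INTERGENIC:
            n_linc += 1
            base = f"{prefix}LINC{n_linc}"
        elif rep.lnc_class is LncClass.UNCLASSIFIED:
            n_unc += 1
            base = f"{prefix}LNC-unc{n_unc}"
        else:
            suffix = _SUFFIX_BY_CLASS[rep.lnc_class]
            key = (rep.partner_gene_id, suffix)
            count = suffix_seen.get(key, 0) + 1
            suffix_seen[key] = count
            base = f"{rep.partner_gene_id}-{suffix}"
            if count > 1:
                base += str(count)
        members_sorted = sorted(
            members, key=lambda m: (m.transcript.start, m.transcript_id)
        )
        multi = len(members_sorted) > 1
        for k, m in enumerate(members_sorted):
            iso = f"-R{_isoform_letters(k)}"
            name = base + iso if multi else base
            out.append(replace(m, assigned_name=name, isoform_suffix=iso))
    order = {r.transcript_id: i for i, r in enumerate(records)}
    out.sort(key=lambda r: order[r.transcript_id])
    return out


# ---------------------------------------------------------------------------
# Class tables
# ---------------------------------------------------------------------------


def _pct(count: int, total: int) -> float:
    """Percentage with 2-decimal half-up rounding."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def class_table_from_counts(counts: dict[LncClass, int]) -> pd.DataFrame:
    """Per-class counts and percentages, with a total row."""
    total = sum(counts.values())
    rows = []
    for cls in TABLE_ORDER:
        n = counts.get(cls, 0)
        rows.append({"class": cls.value, "count": n, "percentage": _pct(n, total)})
    rows.append({"class": "total", "count": total, "percentage": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def class_table(records: Sequence[LncRNARecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=["class", "count", "percentage"])
    counts: dict[LncClass, int] = {}
    for r in records:
        counts[r.lnc_class] = counts.get(r.lnc_class, 0) + 1
    return class_table_from_counts(counts)


def records_table(records: Sequence[LncRNARecord]) -> pd.DataFrame:
    """Flat per-transcript table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "assigned_name": r.assigned_name,
                "class": r.lnc_class.value,
                "partner_gene": r.partner_gene_id or "",
                "distance": r.distance_to_nearest_gene,
            }
            for r in records
        ]
    )


def write_bed12(records: Sequence[LncRNARecord], path) -> None:
    """BED12 export of classified transcripts (name = assigned name)."""
    with open(path, "w") as fh:
        for r in sorted(
            records, key=lambda r: (r.transcript.chrom, r.transcript.start)
        ):
            t = r.transcript
            sizes = ",".join(str(e.length) for e in t.exons) + ","
            starts = ",".join(str(e.start - t.start) for e in t.exons) + ","
            name = r.assigned_name or r.transcript_id
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t{t.strand}\t"
                f"{t.start}\t{t.start}\t0\t{t.n_exons}\t{sizes}\t{starts}\n"
            )
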