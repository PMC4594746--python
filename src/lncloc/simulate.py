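"""Synthetic fixtures with planted ground truth.

Generates a toy genome, a protein-coding reference annotation, lncRNA
candidate transcripts with known location classes, and FPKM matrices
with planted sample-specific rows, differential shifts and
lncRNA-neighbor correlation — so every pipeline stage can be tested
against known truth without any external data.

Two design points make the truth exact rather than probabilistic:

* The background genome contains no ATG on either strand (the patterns
  ``ATG`` and ``CAT`` are scrubbed), so the only complete open reading
  frames are the cassettes planted deliberately; cassette interiors use
  T-free codons, which can encode neither a start nor a stop in any
  frame or orientation.  Splice junctions of the emitted transcripts
  are scrubbed the same way.
* Expression rows that are not planted as sample-specific are redrawn
  if they accidentally satisfy the specificity rule, so the planted set
  is exactly the true set.

All randomness flows from a single mandatory seed; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    DictGenome,
    ExonInterval,
    GenomeAnnotation,
    TranscriptModel,
    group_loci,
    write_gff3,
    write_gtf,
)
from .classify import LncClass
from .coding_filter import EVIDENCE_LABELS, EvidenceSet, longest_orf, spliced_sequence
from .expression import write_fpkm

_FORBIDDEN = re.compile(b"ATG|CAT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: T-free codons: cannot contain a start or stop codon in any frame on
#: either strand (all stops contain T; their complements all contain A,
#: and a T-free sense codon has no T for the antisense A).
_SAFE_CODONS = [
    a + b + c for a in "ACG" for b in "ACG" for c in "ACG"
]

DEFAULT_SAMPLES = (
    "LFP_adult",
    "HFP_adult",
    "LFP_5th",
    "HFP_5th",
    "Mudgo_fat",
    "TN1_fat",
    "Mudgo_sal",
    "TN1_sal",
    "TN1_ant",
    "I87i",
    "C89i",
    "wild",
)


class GenerationError(RuntimeError):
    """Raised when a fixture spec cannot be realized (e.g. no space)."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Geometry defaults emulate the structural profile typical of insect
    lncRNA catalogs: lncRNAs mostly two-exon with long exons (~360 bp)
    and long introns, protein-coding genes with more but shorter exons
    (~250 bp) and ~2.6 kb introns.  Expression defaults: 12 samples,
    lognormal between-sample noise, neighbor correlation 0.5.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int | None = None  # None: sized automatically to fit
    n_coding_genes: int = 220
    per_class: dict[LncClass, int] = field(
        default_factory=lambda: {cls: 30 for cls in LncClass}
    )
    n_orf_planted: int = 5
    orf_length: int = 402  # must be a codon multiple (ATG..stop)
    n_short: int = 5  # planted failures of the length rule
    n_single_exon: int = 5  # planted failures of the exon-count rule
    n_evidence_per_label: int = 3
    n_multi_isoform_loci: int = 5
    # geometry
    coding_exon_count_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.40, 3: 0.25, 4: 0.12, 5: 0.12, 6: 0.11}
    )
    coding_exon_mean: float = 250.0
    coding_intron_mean: float = 2583.0
    lnc_exon_mean: float = 363.0
    lnc_intron_mean: float = 7792.0
    length_sigma: float = 0.5  # log-scale sd of the lognormal size draws
    # expression
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    n_specific: int = 20
    specific_hi: float = 3.0
    specific_lo: float = 1.0
    specific_fold: float = 10.0
    neighbor_rho: float = 0.5
    expression_sigma: float = 0.8  # between-sample lognormal sd (log scale)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.per_class = {LncClass(k): v for k, v in self.per_class.items()}
        n_hosted = sum(
            self.per_class.get(c, 0)
            for c in (
                LncClass.INTRONIC_SENSE,
                LncClass.INTRONIC_ANTISENSE,
                LncClass.EXONIC_SENSE,
                LncClass.EXONIC_ANTISENSE,
                LncClass.JUNCTION_SHARED,
                LncClass.UNCLASSIFIED,
            )
        )
        if n_hosted > self.n_coding_genes:
            raise GenerationError(
                f"{n_hosted} gene-hosted lncRNAs exceed {self.n_coding_genes} genes"
            )


@dataclass
class Fixture:
    """All artifacts of one generated dataset, in memory."""

    spec: FixtureSpec
    genome: DictGenome
    reference_transcripts: list[TranscriptModel]
    annotation: GenomeAnnotation
    lnc_transcripts: list[TranscriptModel]
    evidence: list[EvidenceSet]
    fpkm: pd.DataFrame
    truth_classes: pd.DataFrame  # transcript_id, true_class, host_gene
    truth_filter: pd.DataFrame  # transcript_id, expected_fate
    truth_specific: pd.DataFrame  # transcript_id, sample
    truth_rho: pd.DataFrame  # lnc_id, gene_id, rho

    @property
    def expected_survivors(self) -> set[str]:
        return set(
            self.truth_filter.loc[
                self.truth_filter["expected_fate"] == "survive", "transcript_id"
            ]
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "reference": outdir / "reference.gff3",
            "lnc_gtf": outdir / "lnc_candidates.gtf",
            "fpkm": outdir / "fpkm.tsv",
            "truth_classes": outdir / "truth_classes.tsv",
            "truth_filter": outdir / "truth_filter.tsv",
            "truth_specific": outdir / "truth_specific.tsv",
            "truth_rho": outdir / "truth_rho.tsv",
        }
        self.genome.write_fasta(paths["genome"])
        write_gff3(self.annotation, paths["reference"])
        write_gtf(self.lnc_transcripts, paths["lnc_gtf"])
        write_fpkm(self.fpkm, paths["fpkm"])
        self.truth_classes.to_csv(paths["truth_classes"], sep="\t", index=False)
        self.truth_filter.to_csv(paths["truth_filter"], sep="\t", index=False)
        self.truth_specific.to_csv(paths["truth_specific"], sep="\t", index=False)
        self.truth_rho.to_csv(
            paths["truth_rho"], sep="\t", index=False, float_format="%.6g"
        )
        for ev in self.evidence:
            p = outdir / f"evidence_{ev.label}.txt"
            p.write_text("".join(f"{tid}\n" for tid in sorted(ev.transcript_ids)))
            paths[f"evidence_{ev.label}"] = p
        return paths


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _lognormal(rng, mean: float, sigma: float, size=None):
    """Lognormal draws with the requested arithmetic mean."""
    mu = math.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=size)


def _scrub_bytes(b: bytearray, start: int = 0) -> int:
    """Remove every ATG/CAT by setting the middle base to C; returns count.

    Replacing the middle base with C can never create a new forbidden
    pattern, so one left-to-right pass suffices.
    """
    n = 0
    pos = start
    while True:
        m = _FORBIDDEN.search(b, pos)
        if m is None:
            return n
        b[m.start() + 1] = ord("C")
        n += 1
        pos = m.start()


def _random_orf_free(rng, n: int) -> bytearray:
    arr = _BASES[rng.integers(0, 4, size=n)]
    b = bytearray(arr.tobytes())
    _scrub_bytes(b)
    return b


def _orf_cassette(rng, orf_length: int) -> str:
    """ATG + T-free interior + TAA, exactly ``orf_length`` nt.

    The interior encodes no start/stop in any frame on either strand,
    so the planted ORF length is exact.
    """
    if orf_length % 3 or orf_length < 9:
        raise GenerationError("orf_length must be a multiple of 3, >= 9")
    n_interior = orf_length // 3 - 2
    codons = [_SAFE_CODONS[rng.integers(len(_SAFE_CODONS))] for _ in range(n_interior)]
    while codons and codons[-1].endswith("CA"):  # would form CAT with the stop
        codons[-1] = _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))]
    return "ATG" + "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def _sample_exon_chain(
    rng, start: int, n_exons: int, exon_lens: Sequence[int], intron_lens: Sequence[int]
) -> tuple[ExonInterval, ...]:
    exons = []
    pos = start
    for k in range(n_exons):
        exons.append(ExonInterval(pos, pos + exon_lens[k]))
        pos += exon_lens[k]
        if k < n_exons - 1:
            pos += intron_lens[k]
    return tuple(exons)


def _choice(rng, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def generate(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Generate the full fixture; optionally write all files to ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    # ---- protein-coding genes ------------------------------------------
    coding: list[TranscriptModel] = []
    cursors = {c: 1000 for c in chroms}
    for i in range(spec.n_coding_genes):
        chrom = chroms[i % len(chroms)]
        n_ex = _choice(rng, spec.coding_exon_count_probs)
        exon_lens = np.maximum(
            _lognormal(rng, spec.coding_exon_mean, spec.length_sigma, n_ex), 80
        ).astype(int)
        intron_lens = np.maximum(
            _lognormal(rng, spec.coding_intron_mean, spec.length_sigma, max(n_ex - 1, 1)),
            400,
        ).astype(int)
        gap = int(rng.integers(2500, 6000))
        start = cursors[chrom] + gap
        exons = _sample_exon_chain(rng, start, n_ex, exon_lens, intron_lens)
        cursors[chrom] = exons[-1].end
        strand = "+" if rng.integers(2) else "-"
        gid = f"OGS{i + 1:05d}"
        coding.append(TranscriptModel(f"{gid}-RA", gid, chrom, strand, exons))

    # ---- lncRNA transcripts with planted classes -----------------------
    lnc: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    hosted_classes = [
        LncClass.INTRONIC_SENSE,
        LncClass.INTRONIC_ANTISENSE,
        LncClass.EXONIC_SENSE,
        LncClass.EXONIC_ANTISENSE,
        LncClass.JUNCTION_SHARED,
        LncClass.UNCLASSIFIED,
    ]
    host_iter = iter(coding)
    tid_counter = 0

    def next_tid() -> str:
        nonlocal tid_counter
        tid_counter += 1
        return f"TCONS_{tid_counter:05d}"

    def opposite(strand: str) -> str:
        return "-" if strand == "+" else "+"

    def pick_host(need_intron: int = 0) -> TranscriptModel:
        for host in host_iter:
            intr = host.introns()
            if need_intron == 0 or (intr and max(i.length for i in intr) >= need_intron):
                return host
        raise GenerationError("ran out of host genes for planted classes")

    for cls in hosted_classes:
        for _ in range(spec.per_class.get(cls, 0)):
            if cls in (LncClass.INTRONIC_SENSE, LncClass.INTRONIC_ANTISENSE):
                e1 = int(rng.integers(110, 170))
                e2 = int(rng.integers(110, 170))
                gap = int(rng.integers(120, 320))
                span = e1 + gap + e2
                host = pick_host(need_intron=span + 60)
                intron = max(host.introns(), key=lambda i: i.length)
                offset = int(rng.integers(20, intron.length - span - 20))
                start = intron.start + offset
                strand = (
                    host.strand
                    if cls is LncClass.INTRONIC_SENSE
                    else opposite(host.strand)
                )
                exons = (
                    ExonInterval(start, start + e1),
                    ExonInterval(start + e1 + gap, start + span),
                )
            elif cls is LncClass.JUNCTION_SHARED:
                host = pick_host(need_intron=150)
                host_introns = host.introns()
                ref_intron = host_introns[rng.integers(len(host_introns))]
                a = int(rng.integers(110, 170))  # a + b >= 220 nt keeps the
                b = int(rng.integers(110, 170))  # transcript above min_length
                strand = host.strand
                exons = (
                    ExonInterval(ref_intron.start - a, ref_intron.start),
                    ExonInterval(ref_intron.end, ref_intron.end + b),
                )
            else:  # exonic sense/antisense and unclassified share geometry
                host = pick_host(need_intron=500)
                ref_exon = host.exons[0]
                ov = int(rng.integers(30, min(120, ref_exon.length)))
                out_len = int(rng.integers(120, 260))
                gap = int(rng.integers(150, 400))
                e1_start = ref_exon.start - out_len
                e1_end = ref_exon.start + ov
                e0_len = int(rng.integers(110, 170))
                e0_end = e1_start - gap
                exons = (
                    ExonInterval(e0_end - e0_len, e0_end),
                    ExonInterval(e1_start, e1_end),
                )
                if cls is LncClass.EXONIC_SENSE:
                    strand = host.strand
                elif cls is LncClass.EXONIC_ANTISENSE:
                    strand = opposite(host.strand)
                else:
                    strand = "."
            tid = next_tid()
            lnc.append(TranscriptModel(tid, f"XLOC_{tid}", host.chrom, strand, exons))
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "true_class": cls.value,
                    "host_gene": host.gene_id if cls is not LncClass.UNCLASSIFIED else "",
                }
            )

    # ---- intergenic lncRNAs (plus ORF/short/single-exon plants) --------
    def place_intergenic(
        chrom: str, exon_lens: list[int], intron_lens: list[int], gap: int
    ) -> tuple[ExonInterval, ...]:
        length = sum(exon_lens) + sum(intron_lens)
        start = cursors[chrom] + gap
        exons = _sample_exon_chain(rng, start, len(exon_lens), exon_lens, intron_lens)
        cursors[chrom] = exons[-1].end
        return exons

    orf_regions: list[tuple[str, int, int]] = []  # protected genome intervals
    intergenic_specs: list[tuple[str, int, int | None]] = []
    for _ in range(spec.per_class.get(LncClass.INTERGENIC, 0)):
        intergenic_specs.append(("intergenic", 2, None))
    for _ in range(spec.n_orf_planted):
        intergenic_specs.append(("orf", 2, spec.orf_length))
    for _ in range(spec.n_short):
        intergenic_specs.append(("short", 2, None))
    for _ in range(spec.n_single_exon):
        intergenic_specs.append(("single_exon", 1, None))

    multi_iso_parents: list[TranscriptModel] = []
    fate_by_tid: dict[str, str] = {}
    cassette_by_tid: dict[str, tuple[str, int, int]] = {}
    for j, (kind, n_ex, orf_len) in enumerate(intergenic_specs):
        chrom = chroms[j % len(chroms)]
        if kind == "short":
            e = [int(rng.integers(60, 95)) for _ in range(2)]  # total < 200
            i = [int(rng.integers(100, 300))]
        elif kind == "single_exon":
            e, i = [500], []
        elif kind == "orf":
            e = [orf_len + int(rng.integers(60, 120)), int(rng.integers(120, 200))]
            i = [int(rng.integers(200, 600))]
        else:
            e = np.maximum(
                _lognormal(rng, spec.lnc_exon_mean, spec.length_sigma, n_ex), 120
            ).astype(int).tolist()
            i = np.maximum(
                _lognormal(rng, spec.lnc_intron_mean, spec.length_sigma, n_ex - 1),
                200,
            ).astype(int).tolist()
        gap = int(rng.integers(1500, 9000))
        exons = place_intergenic(chrom, e, i, gap)
        strand = "+" if rng.integers(2) else "-"
        tid = next_tid()
        t = TranscriptModel(tid, f"XLOC_{tid}", chrom, strand, exons)
        lnc.append(t)
        if kind == "intergenic":
            truth_rows.append(
                {"transcript_id": tid, "true_class": LncClass.INTERGENIC.value,
                 "host_gene": ""}
            )
            fate_by_tid[tid] = "survive"
            multi_iso_parents.append(t)
        elif kind == "orf":
            truth_rows.append(
                {"transcript_id": tid, "true_class": LncClass.INTERGENIC.value,
                 "host_gene": ""}
            )
            fate_by_tid[tid] = "orf"
            off = int(rng.integers(10, 40))
            cassette_by_tid[tid] = (chrom, exons[0].start + off, exons[0].start + off + orf_len)
        else:
            fate_by_tid[tid] = "length_exons"

    # extra isoforms for a few intergenic loci (alternative splicing)
    for parent in multi_iso_parents[: spec.n_multi_isoform_loci]:
        e1 = parent.exons[0]
        shift = int(rng.integers(40, min(120, e1.length - 40)))
        new_last = ExonInterval(
            parent.exons[-1].start + 30, parent.exons[-1].end + 150
        )
        exons = (ExonInterval(e1.start + shift, e1.end),) + parent.exons[1:-1] + (
            new_last,
        )
        tid = next_tid()
        lnc.append(
            TranscriptModel(tid, parent.gene_id, parent.chrom, parent.strand, exons)
        )
        truth_rows.append(
            {"transcript_id": tid, "true_class": LncClass.INTERGENIC.value,
             "host_gene": ""}
        )
        fate_by_tid[tid] = "survive"
        cursors[parent.chrom] = max(cursors[parent.chrom], exons[-1].end)

    # ---- genome sequence -----------------------------------------------
    chrom_len: dict[str, int] = {}
    for c in chroms:
        needed = cursors[c] + 1000
        if spec.chrom_length is not None:
            if needed > spec.chrom_length:
                raise GenerationError(
                    f"{c}: layout needs {needed} bp > chrom_length {spec.chrom_length}"
                )
            chrom_len[c] = spec.chrom_length
        else:
            chrom_len[c] = needed
    seqs = {c: _random_orf_free(rng, chrom_len[c]) for c in chroms}

    # plant ORF cassettes (protected from scrubbing)
    for tid, (chrom, a, b) in cassette_by_tid.items():
        cassette = _orf_cassette(rng, b - a)
        seqs[chrom][a:b] = cassette.encode()
        if a > 0 and seqs[chrom][a - 1 : a] == b"C":  # would form CAT
            seqs[chrom][a - 1] = ord("G")
        seqs[chrom][b : b + 2] = b"CC"  # no ATG across the stop boundary
        orf_regions.append((chrom, a, b))

    # scrub splice-junction-created ATG/CAT in every transcript's exon
    # concatenation (genome orientation covers both transcript strands)
    protected = {
        (chrom, p) for chrom, a, b in orf_regions for p in range(a - 1, b + 2)
    }
    for _ in range(20):
        changed = 0
        for t in lnc:
            coords = np.concatenate(
                [np.arange(e.start, e.end) for e in t.exons]
            )
            concat = bytes(
                b"".join(bytes(seqs[t.chrom][e.start : e.end]) for e in t.exons)
            )
            for m in _FORBIDDEN.finditer(concat):
                pos3 = coords[m.start() : m.start() + 3]
                if any((t.chrom, int(p)) in protected for p in pos3):
                    continue
                seqs[t.chrom][int(pos3[1])] = ord("C")
                changed += 1
        if not changed:
            break
    else:  # pragma: no cover - defensive
        raise GenerationError("junction scrubbing did not converge")

    genome = DictGenome({c: seqs[c].decode() for c in chroms})

    # verify planted ORF truth exactly
    for t in lnc:
        observed = longest_orf(spliced_sequence(t, genome))
        if t.transcript_id in cassette_by_tid:
            if observed != spec.orf_length:
                raise GenerationError(
                    f"{t.transcript_id}: planted ORF {spec.orf_length}, got {observed}"
                )
        elif observed != 0:
            raise GenerationError(
                f"{t.transcript_id}: background ORF of {observed} nt survived scrubbing"
            )

    # ---- filter fates and evidence sets --------------------------------
    for row in truth_rows:
        fate_by_tid.setdefault(row["transcript_id"], "survive")
    candidates = [
        tid for tid, fate in fate_by_tid.items() if fate == "survive"
    ]
    rng.shuffle(candidates)
    evidence: list[EvidenceSet] = []
    k = 0
    for label in EVIDENCE_LABELS:
        ids = candidates[k : k + spec.n_evidence_per_label]
        k += spec.n_evidence_per_label
        for tid in ids:
            fate_by_tid[tid] = label
        evidence.append(EvidenceSet(label, frozenset(ids)))
    truth_filter = pd.DataFrame(
        [
            {"transcript_id": t.transcript_id,
             "expected_fate": fate_by_tid[t.transcript_id]}
            for t in lnc
        ]
    )

    # ---- expression matrix ---------------------------------------------
    annotation = GenomeAnnotation.from_transcripts(coding)
    survivors = [tid for tid, fate in fate_by_tid.items() if fate == "survive"]
    survivors.sort()
    host_by_tid = {
        r["transcript_id"]: r["host_gene"] for r in truth_rows if r["host_gene"]
    }
    lnc_by_tid = {t.transcript_id: t for t in lnc}
    gene_ids = [t.gene_id for t in coding]
    fpkm, truth_specific, truth_rho = _simulate_fixture_expression(
        rng,
        spec,
        survivors,
        gene_ids,
        host_by_tid,
        lnc_by_tid,
        annotation,
    )

    truth_classes = pd.DataFrame(truth_rows)
    fixture = Fixture(
        spec=spec,
        genome=genome,
        reference_transcripts=coding,
        annotation=annotation,
        lnc_transcripts=lnc,
        evidence=evidence,
        fpkm=fpkm,
        truth_classes=truth_classes,
        truth_filter=truth_filter,
        truth_specific=truth_specific,
        truth_rho=truth_rho,
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture


def _is_specific(row: np.ndarray, hi: float, lo: float, fold: float) -> bool:
    top = row.max()
    others = np.partition(row, -1)[:-1]
    return bool(top > hi and others.max() < lo and top >= fold * others.max())


def _simulate_fixture_expression(
    rng,
    spec: FixtureSpec,
    lnc_ids: list[str],
    gene_ids: list[str],
    host_by_tid: dict[str, str],
    lnc_by_tid,
    annotation: GenomeAnnotation,
):
    from .coexpression import nearest_gene

    n_s = len(spec.samples)
    sigma = spec.expression_sigma

    def redraw_until_not_specific(make_row):
        for _ in range(200):
            row = make_row()
            if not _is_specific(row, spec.specific_hi, spec.specific_lo, spec.specific_fold):
                return row
        raise GenerationError("could not draw a non-specific background row")

    # genes: independent lognormal profiles
    gene_rows = {}
    gene_z = {}
    for gid in gene_ids:
        base = float(np.exp(rng.normal(2.5, 0.8)))
        for _ in range(200):
            z = rng.normal(size=n_s)
            row = base * np.exp(sigma * z)
            if not _is_specific(
                row, spec.specific_hi, spec.specific_lo, spec.specific_fold
            ):
                break
        else:  # pragma: no cover - defensive
            raise GenerationError("could not draw a non-specific gene row")
        gene_z[gid] = z
        gene_rows[gid] = row

    # pick the specific-planted lncRNAs first
    specific_ids = list(lnc_ids[: spec.n_specific])
    specific_rows = []
    lnc_rows = {}
    rho_rows = []
    for k, tid in enumerate(specific_ids):
        row = rng.uniform(0.05, 0.3, size=n_s)
        s_idx = k % n_s
        row[s_idx] = rng.uniform(5.0, 50.0)
        lnc_rows[tid] = row
        specific_rows.append({"transcript_id": tid, "sample": spec.samples[s_idx]})

    for tid in lnc_ids:
        if tid in lnc_rows:
            continue
        partner = host_by_tid.get(tid)
        if partner is None:
            t = lnc_by_tid[tid]
            na = nearest_gene(t, annotation)
            partner = na.nearest_gene_id
        base = float(np.exp(rng.normal(1.5, 0.8)))
        if partner is not None and partner in gene_z and spec.neighbor_rho != 0:
            zg = gene_z[partner]
            eps = rng.normal(size=n_s)
            z = spec.neighbor_rho * zg + math.sqrt(1 - spec.neighbor_rho**2) * eps
            row = base * np.exp(sigma * z)
            if _is_specific(row, spec.specific_hi, spec.specific_lo, spec.specific_fold):
                row = redraw_until_not_specific(
                    lambda b=base: b
                    * np.exp(
                        sigma
                        * (
                            spec.neighbor_rho * zg
                            + math.sqrt(1 - spec.neighbor_rho**2)
                            * rng.normal(size=n_s)
                        )
                    )
                )
            rho_rows.append({"lnc_id": tid, "gene_id": partner, "rho": spec.neighbor_rho})
        else:
            row = redraw_until_not_specific(
                lambda b=base: b * np.exp(sigma * rng.normal(size=n_s))
            )
        lnc_rows[tid] = row

    index = list(lnc_ids) + list(gene_ids)
    data = np.vstack([lnc_rows[i] for i in lnc_ids] + [gene_rows[g] for g in gene_ids])
    fpkm = pd.DataFrame(data, index=index, columns=list(spec.samples))
    return (
        fpkm,
        pd.DataFrame(specific_rows, columns=["transcript_id", "sample"]),
        pd.DataFrame(rho_rows, columns=["lnc_id", "gene_id", "rho"]),
    )


# ---------------------------------------------------------------------------
# standalone expression simulators (matrix-only fixtures)
# ---------------------------------------------------------------------------


def simulate_specific_matrix(
    *,
    n_rows: int = 1000,
    n_samples: int = 6,
    n_specific: int = 50,
    hi: float = 3.0,
    lo: float = 1.0,
    fold: float = 10.0,
    seed: int,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """FPKM matrix with exactly ``n_specific`` sample-specific rows.

    Background rows are redrawn if they accidentally satisfy the
    specificity rule, so the planted set is the exact truth.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    ids = [f"T{i + 1:05d}" for i in range(n_rows)]
    planted = sorted(rng.choice(n_rows, size=n_specific, replace=False))
    planted_set = set(int(i) for i in planted)
    rows = np.empty((n_rows, n_samples))
    truth = []
    for i in range(n_rows):
        if i in planted_set:
            row = rng.uniform(0.05, lo * 0.3, size=n_samples)
            s = int(rng.integers(n_samples))
            row[s] = rng.uniform(max(hi, fold * row.max()) * 1.2, 60.0)
            truth.append((ids[i], samples[s]))
        else:
            while True:
                base = float(np.exp(rng.normal(1.0, 1.0)))
                row = base * np.exp(0.4 * rng.normal(size=n_samples))
                if not _is_specific(row, hi, lo, fold):
                    break
        rows[i] = row
    return pd.DataFrame(rows, index=ids, columns=samples), truth


def simulate_differential_matrix(
    *,
    n_transcripts: int = 2000,
    n_planted: int = 50,
    fold: float = 8.0,
    n_per_group: int = 3,
    sigma: float = 0.08,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, str], set[str]]:
    """Two-group FPKM matrix with ``n_planted`` fold-shifted rows.

    ``sigma`` is the log-scale sd of the lognormal between-replicate
    noise; the default emulates low-dispersion technical replicates and
    is sized so an 8-fold shift is reliably detectable by a 3 vs 3
    Welch test at FDR-corrected cutoffs — with three replicates the
    Welch degrees of freedom are tiny, so power collapses quickly as
    replicate noise grows.  ``n_planted=0`` gives a pure null matrix
    for calibration.  Returns (matrix, sample->group mapping, planted
    row ids).
    """
    rng = np.random.default_rng(seed)
    ids = [f"T{i + 1:05d}" for i in range(n_transcripts)]
    cols = [f"A{j + 1}" for j in range(n_per_group)] + [
        f"B{j + 1}" for j in range(n_per_group)
    ]
    groups = {c: c[0] for c in cols}
    base = np.exp(rng.normal(2.0, 1.0, size=n_transcripts))
    X = base[:, None] * np.exp(
        sigma * rng.normal(size=(n_transcripts, 2 * n_per_group))
    )
    planted = set()
    if n_planted:
        chosen = rng.choice(n_transcripts, size=n_planted, replace=False)
        X[chosen, :n_per_group] *= fold
        planted = {ids[int(i)] for i in chosen}
    return pd.DataFrame(X, index=ids, columns=cols), groups, planted


def simulate_coexpression_matrix(
    *,
    n_pairs: int = 40,
    n_extra_genes: int = 200,
    rho: float = 0.5,
    n_samples: int = 12,
    sigma: float = 0.8,
    seed: int,
) -> tuple[pd.DataFrame, list[tuple[str, str]], list[str]]:
    """Matrix of lncRNA/gene rows where each neighbor pair has latent
    correlation ``rho`` and all other pairs are independent.

    Returns (matrix, neighbor pairs, full gene-id pool for the null).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    rows = {}
    pairs = []
    for i in range(n_pairs):
        gid, lid = f"G{i + 1:04d}", f"L{i + 1:04d}"
        zg = rng.normal(size=n_samples)
        eps = rng.normal(size=n_samples)
        zl = rho * zg + math.sqrt(1 - rho**2) * eps
        rows[gid] = np.exp(rng.normal(2.5, 0.8)) * np.exp(sigma * zg)
        rows[lid] = np.exp(rng.normal(1.5, 0.8)) * np.exp(sigma * zl)
        pairs.append((lid, gid))
    gene_pool = [g for _, g in pairs]
    for i in range(n_extra_genes):
        gid = f"G{n_pairs + i + 1:04d}"
        rows[gid] = np.exp(rng.normal(2.5, 0.8)) * np.exp(
            sigma * rng.normal(size=n_samples)
        )
        gene_pool.append(gid)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return df, pairs, gene_pool
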