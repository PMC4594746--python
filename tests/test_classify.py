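"""Location classification, naming scheme and class tables."""

import numpy as np
import pytest

from lncloc.annotation import GenomeAnnotation, group_loci
from lncloc.classify import (
    DEFAULT_PRECEDENCE,
    LncClass,
    LncRNARecord,
    assign_names,
    class_table,
    class_table_from_counts,
    classify,
    classify_all,
)

from conftest import make_transcript

# one reference gene: exons 1000-1200, 2000-2300, 5000-5400 on +
REF = make_transcript(
    "gA-RA", gene="gA", strand="+", exons=((1000, 1200), (2000, 2300), (5000, 5400))
)
ANN = GenomeAnnotation.from_transcripts([REF])


def classify_oracle(t, genes):
    """Brute force: evaluate every rule against every gene, then precedence."""
    if not any(g.chrom == t.chrom for g in genes):
        return LncClass.INTERGENIC
    overlapping = [
        g
        for g in genes
        if g.chrom == t.chrom and g.start < t.end and t.start < g.end
    ]
    if not overlapping:
        return LncClass.INTERGENIC
    if t.strand == ".":
        return LncClass.UNCLASSIFIED
    feasible = set()
    for g in overlapping:
        same = g.strand == t.strand
        g_exons = [e for tr in g.transcripts for e in tr.exons]
        g_introns = [i for tr in g.transcripts for i in tr.introns()]
        exonic = any(a.overlaps(b) for a in t.exons for b in g_exons)
        if same and any(i in g_introns for i in t.introns()):
            feasible.add(LncClass.JUNCTION_SHARED)
        if exonic:
            feasible.add(
                LncClass.EXONIC_SENSE if same else LncClass.EXONIC_ANTISENSE
            )
        if same and any(
            i.start <= t.start and t.end <= i.end for i in g_introns
        ):
            feasible.add(LncClass.INTRONIC_SENSE)
        if not same and not exonic and any(
            a.overlaps(i) for a in t.exons for i in g_introns
        ):
            feasible.add(LncClass.INTRONIC_ANTISENSE)
    for cls in DEFAULT_PRECEDENCE:
        if cls in feasible:
            return cls
    return LncClass.UNCLASSIFIED


class TestClassifyRules:
    @pytest.mark.parametrize(
        "strand,exons,expected",
        [
            # entirely inside intron 1200-2000, same strand
            ("+", ((1300, 1400), (1600, 1700)), LncClass.INTRONIC_SENSE),
            ("-", ((1300, 1400), (1600, 1700)), LncClass.INTRONIC_ANTISENSE),
            # exon-exon overlap
            ("+", ((1100, 1250), (1600, 1700)), LncClass.EXONIC_SENSE),
            ("-", ((1100, 1250), (1600, 1700)), LncClass.EXONIC_ANTISENSE),
            # identical intron 1200-2000 shared
            ("+", ((1100, 1200), (2000, 2100)), LncClass.JUNCTION_SHARED),
            # same intron boundaries but opposite strand: exonic antisense
            ("-", ((1100, 1200), (2000, 2100)), LncClass.EXONIC_ANTISENSE),
            # far away
            ("+", ((9000, 9200), (9500, 9700)), LncClass.INTERGENIC),
            # strand-unknown overlapping the gene
            (".", ((1100, 1250),), LncClass.UNCLASSIFIED),
            # same strand, inside span, straddles intron/exon boundary? no:
            # exons in two different introns, not contained in one -> residual
            ("+", ((1300, 1400), (2400, 2500)), LncClass.UNCLASSIFIED),
        ],
    )
    def test_planted_geometries(self, strand, exons, expected):
        t = make_transcript("t", strand=strand, exons=exons)
        cls, partner = classify(t, ANN)
        assert cls is expected
        if expected in (LncClass.INTERGENIC, LncClass.UNCLASSIFIED):
            assert partner is None
        else:
            assert partner == "gA"

    def test_unknown_chromosome_is_intergenic(self):
        t = make_transcript("t", chrom="chrZ", exons=((0, 300),))
        assert classify(t, ANN) == (LncClass.INTERGENIC, None)

    def test_strand_flip_symmetry(self):
        flip = {"+": "-", "-": "+", ".": "."}
        ref_flipped = make_transcript(
            "gA-RA", gene="gA", strand="-", exons=tuple(
                (e.start, e.end) for e in REF.exons
            )
        )
        ann_flipped = GenomeAnnotation.from_transcripts([ref_flipped])
        rng = np.random.default_rng(3)
        for _ in range(40):
            a = int(rng.integers(500, 5500))
            b = a + int(rng.integers(50, 150))
            c = b + int(rng.integers(50, 400))
            d = c + int(rng.integers(50, 150))
            strand = "+-"[int(rng.integers(2))]
            t = make_transcript("t", strand=strand, exons=((a, b), (c, d)))
            t_f = make_transcript("t", strand=flip[strand], exons=((a, b), (c, d)))
            assert classify(t, ANN)[0] is classify(t_f, ann_flipped)[0]

    def test_partner_tiebreak_prefers_larger_overlap_then_smaller_id(self):
        g1 = make_transcript("g1-RA", gene="g1", strand="+", exons=((0, 100),))
        g2 = make_transcript("g2-RA", gene="g2", strand="+", exons=((50, 400),))
        ann = GenomeAnnotation.from_transcripts([g1, g2])
        t = make_transcript("t", exons=((40, 260), (300, 350)))
        assert classify(t, ann) == (LncClass.EXONIC_SENSE, "g2")  # larger overlap
        g3 = make_transcript("g3-RA", gene="g3", strand="+", exons=((0, 100),))
        ann2 = GenomeAnnotation.from_transcripts(
            [g1, make_transcript("g0-RA", gene="g0", strand="+", exons=((0, 100),))]
        )
        t2 = make_transcript("t", exons=((40, 100), (300, 350)))
        assert classify(t2, ann2) == (LncClass.EXONIC_SENSE, "g0")  # equal -> min id

    def test_every_transcript_gets_exactly_one_class(self, small_fixture):
        fx = small_fixture
        for t in fx.lnc_transcripts:
            cls, _ = classify(t, fx.annotation)
            assert isinstance(cls, LncClass)

    def test_fixture_truth_and_oracle_agreement(self, small_fixture):
        fx = small_fixture
        genes = list(fx.annotation.genes.values())
        truth = dict(
            zip(fx.truth_classes.transcript_id, fx.truth_classes.true_class)
        )
        for t in fx.lnc_transcripts:
            if t.transcript_id not in truth:
                continue
            cls, _ = classify(t, fx.annotation)
            assert cls.value == truth[t.transcript_id]
            assert cls is classify_oracle(t, genes)

    def test_moving_far_from_all_genes_yields_intergenic(self, small_fixture):
        fx = small_fixture
        t = fx.lnc_transcripts[0]
        span = max(g.end for g in fx.annotation.genes.values())
        shifted = make_transcript(
            "shifted",
            chrom=t.chrom,
            strand=t.strand if t.strand != "." else "+",
            exons=tuple((e.start + 2 * span, e.end + 2 * span) for e in t.exons),
        )
        assert classify(shifted, fx.annotation)[0] is LncClass.INTERGENIC


def _record(tid, cls, partner=None, chrom="chr1", start=0, strand="+"):
    t = make_transcript(tid, chrom=chrom, strand=strand, exons=((start, start + 100),))
    return LncRNARecord(transcript=t, lnc_class=cls, partner_gene_id=partner)


class TestNaming:
    def test_intergenic_numbering_by_position(self):
        recs = [
            _record("t2", LncClass.INTERGENIC, chrom="chr1", start=5000),
            _record("t1", LncClass.INTERGENIC, chrom="chr1", start=100),
        ]
        loci = group_loci([r.transcript for r in recs])
        named = {r.transcript_id: r.assigned_name
                 for r in assign_names(recs, loci, prefix="BPH")}
        assert named == {"t1": "BPHLINC1", "t2": "BPHLINC2"}

    def test_partner_suffixes(self):
        cases = {
            LncClass.INTRONIC_SENSE: "OGS1-IT",
            LncClass.INTRONIC_ANTISENSE: "OGS1-AS",
            LncClass.EXONIC_ANTISENSE: "OGS1-AS",
            LncClass.EXONIC_SENSE: "OGS1-OT",
            LncClass.JUNCTION_SHARED: "OGS1-OT",
        }
        for cls, expected in cases.items():
            recs = [_record("t1", cls, partner="OGS1")]
            loci = group_loci([recs[0].transcript])
            (named,) = assign_names(recs, loci)
            assert named.assigned_name == expected

    def test_collision_gets_numeric_suffix(self):
        recs = [
            _record("t1", LncClass.EXONIC_SENSE, partner="OGS7", start=100),
            _record("t2", LncClass.JUNCTION_SHARED, partner="OGS7", start=9000),
        ]
        loci = group_loci([r.transcript for r in recs])
        named = {r.transcript_id: r.assigned_name for r in assign_names(recs, loci)}
        assert named == {"t1": "OGS7-OT", "t2": "OGS7-OT2"}

    def test_ten_isoforms_get_ra_through_rj(self):
        ts, recs = [], []
        for k in range(10):
            t = make_transcript(f"t{k:02d}", exons=((k * 10, 1000 + k * 10),))
            ts.append(t)
            recs.append(
                LncRNARecord(transcript=t, lnc_class=LncClass.UNCLASSIFIED)
            )
        loci = group_loci(ts)
        assert len(loci) == 1
        named = assign_names(recs, loci, prefix="BPH")
        suffixes = [r.assigned_name[-3:] for r in sorted(
            named, key=lambda r: r.transcript_id
        )]
        assert suffixes == [f"-R{c}" for c in "ABCDEFGHIJ"]
        assert all(r.assigned_name.startswith("BPHLNC-unc1-") for r in named)


class TestClassTable:
    # published per-class catalog counts; their percentage arithmetic is
    # checked to the printed precision
    COUNTS = {
        LncClass.INTERGENIC: 853,
        LncClass.INTRONIC_SENSE: 80,
        LncClass.INTRONIC_ANTISENSE: 5,
        LncClass.EXONIC_SENSE: 385,
        LncClass.EXONIC_ANTISENSE: 211,
        LncClass.JUNCTION_SHARED: 264,
        LncClass.UNCLASSIFIED: 641,
    }

    def test_catalog_counts_arithmetic(self):
        tab = class_table_from_counts(self.COUNTS).set_index("class")
        assert tab.loc["total", "count"] == 2439
        assert tab.loc["intergenic", "percentage"] == 34.97
        assert tab.loc["intronic_sense", "percentage"] == 3.28
        assert tab.loc["intronic_antisense", "percentage"] == 0.21
        assert tab.loc["exonic_sense", "percentage"] == 15.79
        assert tab.loc["exonic_antisense", "percentage"] == 8.65
        assert tab.loc["unclassified", "percentage"] == 26.28

    def test_percentages_sum_to_100(self):
        tab = class_table_from_counts(self.COUNTS)
        body = tab[tab["class"] != "total"]
        assert abs(body["percentage"].sum() - 100.0) <= 0.02

    def test_single_class_is_100(self):
        recs = [_record("t1", LncClass.INTERGENIC)]
        tab = class_table(recs).set_index("class")
        assert tab.loc["intergenic", "percentage"] == 100.0
        assert tab.loc["intergenic", "count"] == 1

    def test_half_up_rounding(self):
        # 1 of 800 = 0.125 % -> 0.13 under half-up (banker's would give 0.12)
        tab = class_table_from_counts(
            {LncClass.INTERGENIC: 1, LncClass.UNCLASSIFIED: 799}
        ).set_index("class")
        assert tab.loc["intergenic", "percentage"] == 0.13

    def test_empty_input_empty_table(self):
        assert class_table([]).empty
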