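"""Data model, GTF/GFF3/FASTA I/O and locus grouping."""

import numpy as np
import pytest

from lncloc.annotation import (
    DictGenome,
    ExonInterval,
    GenomeAnnotation,
    GenomeSequence,
    GtfParseError,
    TranscriptModel,
    group_loci,
    read_gff3,
    read_gtf,
    write_gff3,
    write_gtf,
)

from conftest import make_transcript


class TestModel:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            ExonInterval(10, 10)
        with pytest.raises(ValueError):
            ExonInterval(-1, 5)
        assert ExonInterval(0, 5).length == 5

    def test_transcript_requires_exons_and_sorts_them(self):
        t = make_transcript("t", exons=((200, 300), (0, 100)))
        assert [e.start for e in t.exons] == [0, 200]
        with pytest.raises(ValueError):
            make_transcript("t", exons=())
        with pytest.raises(ValueError):
            make_transcript("t", exons=((0, 100), (50, 150)))  # overlap

    @pytest.mark.parametrize(
        "exons,length,introns",
        [
            (((0, 200),), 200, []),
            (((0, 100), (200, 300)), 200, [(100, 200)]),
            (((0, 50), (60, 100), (150, 200), (900, 1000)), 240,
             [(50, 60), (100, 150), (200, 900)]),
        ],
    )
    def test_length_and_introns(self, exons, length, introns):
        t = make_transcript("t", exons=exons)
        assert t.length == length
        assert [(i.start, i.end) for i in t.introns()] == introns

    def test_length_matches_bitmask_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_ex = int(rng.integers(1, 6))
            pos = np.sort(rng.choice(5000, size=2 * n_ex, replace=False))
            exons = [(int(pos[2 * k]), int(pos[2 * k + 1])) for k in range(n_ex)]
            t = make_transcript("t", exons=exons)
            mask = np.zeros(5000, dtype=bool)
            for a, b in exons:
                mask[a:b] = True
            assert t.length == int(mask.sum())

    def test_exons_and_introns_tile_the_span(self):
        t = make_transcript("t", exons=((10, 60), (100, 180), (300, 350), (400, 500)))
        pieces = sorted(list(t.exons) + t.introns())
        assert pieces[0].start == t.start and pieces[-1].end == t.end
        for a, b in zip(pieces, pieces[1:]):
            assert a.end == b.start
        assert t.length + sum(i.length for i in t.introns()) == t.end - t.start


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "one.gtf"
        p.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (t,) = read_gtf(p)
        assert (t.exons[0].start, t.exons[0].end) == (99, 200)
        assert t.length == 101

    def test_out_of_order_exons_sorted(self, tmp_path):
        p = tmp_path / "two.gtf"
        p.write_text(
            'chr1\ts\texon\t500\t600\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ts\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        (t,) = read_gtf(p)
        assert [e.start for e in t.exons] == [99, 499]

    def test_exon_counts_match_line_count_oracle(self, tmp_path):
        rng = np.random.default_rng(1)
        lines = []
        expected = {}
        pos = 100
        for k in range(5):
            tid = f"t{k}"
            n = int(rng.integers(1, 5))
            expected[tid] = n
            for _ in range(n):
                lines.append(
                    f'chr1\ts\texon\t{pos}\t{pos + 50}\t.\t+\t.\t'
                    f'gene_id "g{k}"; transcript_id "{tid}";'
                )
                pos += 200
        rng.shuffle(lines)
        p = tmp_path / "five.gtf"
        p.write_text("\n".join(lines) + "\n")
        ts = read_gtf(p)
        assert len(ts) == 5
        assert {t.transcript_id: t.n_exons for t in ts} == expected

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\ts\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "garbage line\n"
        )
        with pytest.raises(GtfParseError, match=":2"):
            read_gtf(p)

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ts\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(GtfParseError, match="end"):
            read_gtf(p)

    def test_duplicate_transcript_across_chroms_rejected(self, tmp_path):
        p = tmp_path / "dup.gtf"
        p.write_text(
            'chr1\ts\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr2\ts\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(GtfParseError, match="chr"):
            read_gtf(p)

    def test_unknown_strand_policy(self, tmp_path):
        p = tmp_path / "dot.gtf"
        p.write_text('chr1\ts\texon\t100\t200\t.\t.\t.\tgene_id "g"; transcript_id "t";\n')
        (t,) = read_gtf(p)  # accepted with warning for assembled transcripts
        assert t.strand == "."
        with pytest.raises(GtfParseError):
            read_gtf(p, require_strand=True)

    def test_round_trip(self, tmp_path):
        ts = [
            make_transcript("tA", exons=((0, 100), (250, 400)), strand="-"),
            make_transcript("tB", chrom="chr2", exons=((10, 60),)),
        ]
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(ts, p1)
        again = read_gtf(p1)
        write_gtf(again, p2)
        assert read_gtf(p2) == again == ts


class TestGff3:
    def test_gff3_round_trip_through_annotation(self, tmp_path):
        ts = [
            make_transcript("m1", gene="gene1", exons=((100, 200), (400, 600))),
            make_transcript("m2", gene="gene1", exons=((100, 250), (400, 500))),
            make_transcript("m3", gene="gene2", strand="-", exons=((5000, 5400),)),
        ]
        ann = GenomeAnnotation.from_transcripts(ts)
        p = tmp_path / "ref.gff3"
        write_gff3(ann, p)
        back = read_gff3(p)
        assert sorted(back, key=lambda t: t.transcript_id) == sorted(
            ts, key=lambda t: t.transcript_id
        )


class TestGenomeSequence:
    def test_fasta_access_matches_memory_and_normalizes(self, tmp_path):
        g = DictGenome({"chr1": "acgtrACGTN" * 10})
        p = tmp_path / "g.fa"
        g.write_fasta(p)
        fa = GenomeSequence(p)
        assert fa.fetch("chr1", 0, 10) == "ACGTNACGTN"  # lowercase + non-ACGT -> N
        assert fa.fetch("chr1", 3, 97) == g.fetch("chr1", 3, 97)
        with pytest.raises(ValueError):
            fa.fetch("chr1", 0, 1000)
        with pytest.raises(KeyError):
            fa.fetch("chrX", 0, 1)


def _bruteforce_loci(ts):
    """O(n^2) pairwise union-find over same-strand exonic overlap."""
    n = len(ts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ts[i], ts[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if any(ea.overlaps(eb) for ea in a.exons for eb in b.exons):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(ts[i].transcript_id)
    return {frozenset(g) for g in groups.values()}


class TestGroupLoci:
    def test_same_strand_overlap_merges(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((250, 400),))
        assert len(group_loci([a, b])) == 1

    def test_opposite_strands_stay_apart(self):
        a = make_transcript("a", exons=((0, 300),), strand="+")
        b = make_transcript("b", exons=((0, 300),), strand="-")
        assert len(group_loci([a, b])) == 2

    def test_intron_spanning_transcripts_do_not_merge(self):
        # b sits inside a's intron: span overlap but no exonic overlap
        a = make_transcript("a", exons=((0, 100), (900, 1000)))
        b = make_transcript("b", exons=((200, 300), (400, 500)))
        assert len(group_loci([a, b])) == 2

    def _random_transcripts(self, seed, n=50):
        rng = np.random.default_rng(seed)
        ts = []
        for k in range(n):
            start = int(rng.integers(0, 3000))
            n_ex = int(rng.integers(1, 4))
            exons = []
            pos = start
            for _ in range(n_ex):
                ln = int(rng.integers(30, 150))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(20, 400))
            ts.append(
                make_transcript(
                    f"t{k}",
                    chrom=f"chr{int(rng.integers(1, 3))}",
                    strand="+-"[int(rng.integers(2))],
                    exons=exons,
                )
            )
        return ts

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pairwise_bruteforce(self, seed):
        ts = self._random_transcripts(seed)
        got = {frozenset(l.member_transcript_ids) for l in group_loci(ts)}
        assert got == _bruteforce_loci(ts)

    def test_invariant_to_input_order(self):
        ts = self._random_transcripts(7)
        base = {frozenset(l.member_transcript_ids) for l in group_loci(ts)}
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(ts)
            rng.shuffle(perm)
            assert {
                frozenset(l.member_transcript_ids) for l in group_loci(perm)
            } == base

    def test_locus_ids_ordered_by_position(self):
        a = make_transcript("a", chrom="chr2", exons=((0, 100),))
        b = make_transcript("b", chrom="chr1", exons=((500, 600),))
        c = make_transcript("c", chrom="chr1", exons=((0, 100),))
        loci = group_loci([a, b, c])
        assert [l.member_transcript_ids[0] for l in loci] == ["c", "b", "a"]
        assert [l.locus_id for l in loci] == ["LOC1", "LOC2", "LOC3"]
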