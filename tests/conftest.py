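import logging

import pytest

from lncloc.annotation import ExonInterval, TranscriptModel
from lncloc.classify import LncClass
from lncloc.simulate import FixtureSpec, generate

logging.getLogger("lncloc").setLevel(logging.ERROR)


def make_transcript(tid, chrom="chr1", strand="+", exons=((0, 100),), gene=None):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"G_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(ExonInterval(a, b) for a, b in exons),
    )


def small_spec(seed, **overrides):
    """A fast fixture spec for unit tests (handful per class)."""
    defaults = dict(
        seed=seed,
        n_coding_genes=60,
        per_class={cls: 6 for cls in LncClass},
        n_orf_planted=3,
        n_short=3,
        n_single_exon=3,
        n_evidence_per_label=2,
        n_multi_isoform_loci=3,
        n_specific=8,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


@pytest.fixture(scope="session")
def small_fixture():
    return generate(small_spec(seed=42))


@pytest.fixture(scope="session")
def default_fixture():
    """Full-size fixture (30 transcripts per class) shared across tests."""
    return generate(FixtureSpec(seed=20240101))
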