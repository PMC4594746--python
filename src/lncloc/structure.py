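"""Structural feature summaries: exon counts, lengths, alternative splicing.

Means for exons and introns are computed per element by default (every
exon/intron contributes once), with an optional per-transcript mode
(average within each transcript, then across transcripts).  The
alternative-splicing fraction is the share of loci with two or more
isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Locus, TranscriptModel


@dataclass
class StructureSummary:
    n_transcripts: int
    n_loci: int
    exon_count_hist: dict[int, int]
    mean_transcript_length: float
    median_transcript_length: float
    mean_exon_length: float
    mean_intron_length: float | None
    as_fraction: float
    max_isoform_loci: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_transcripts": self.n_transcripts,
            "n_loci": self.n_loci,
            "mean_transcript_length": self.mean_transcript_length,
            "median_transcript_length": self.median_transcript_length,
            "mean_exon_length": self.mean_exon_length,
            "mean_intron_length": self.mean_intron_length,
            "as_fraction": self.as_fraction,
        }
        d["exon_count_hist"] = dict(sorted(self.exon_count_hist.items()))
        return d


def summarize(
    ts: Sequence[TranscriptModel],
    loci: Sequence[Locus],
    *,
    per_transcript_means: bool = False,
    top_isoform_loci: int = 3,
) -> StructureSummary:
    """Summarize transcript structure over a set of transcripts and loci.

    ``loci`` must partition ``ts`` (as produced by
    :func:`lncloc.annotation.group_loci`).
    """
    if not ts:
        raise ValueError("cannot summarize an empty transcript set")
    locus_tids = {tid for l in loci for tid in l.member_transcript_ids}
    if locus_tids != {t.transcript_id for t in ts}:
        raise ValueError("loci do not partition the transcript set")

    hist: dict[int, int] = {}
    for t in ts:
        hist[t.n_exons] = hist.get(t.n_exons, 0) + 1

    tlens = np.array([t.length for t in ts], dtype=float)
    exon_lens = [e.length for t in ts for e in t.exons]
    intron_lens = [i.length for t in ts for i in t.introns()]

    if per_transcript_means:
        mean_exon = float(
            np.mean([np.mean([e.length for e in t.exons]) for t in ts])
        )
        per_t_introns = [
            np.mean([i.length for i in t.introns()]) for t in ts if t.introns()
        ]
        mean_intron = float(np.mean(per_t_introns)) if per_t_introns else None
    else:
        mean_exon = float(np.mean(exon_lens))
        mean_intron = float(np.mean(intron_lens)) if intron_lens else None

    multi = [l for l in loci if l.n_isoforms >= 2]
    by_iso = sorted(loci, key=lambda l: (-l.n_isoforms, l.locus_id))
    return StructureSummary(
        n_transcripts=len(ts),
        n_loci=len(loci),
        exon_count_hist=hist,
        mean_transcript_length=float(np.mean(tlens)),
        median_transcript_length=float(np.median(tlens)),
        mean_exon_length=mean_exon,
        mean_intron_length=mean_intron,
        as_fraction=len(multi) / len(loci),
        max_isoform_loci=[
            (l.locus_id, l.n_isoforms) for l in by_iso[:top_isoform_loci]
        ],
    )


def compare_groups(
    a: StructureSummary, b: StructureSummary, labels: tuple[str, str] = ("a", "b")
) -> pd.DataFrame:
    """Side-by-side field comparison of two structure summaries."""
    fields = [
        "n_transcripts",
        "n_loci",
        "mean_transcript_length",
        "median_transcript_length",
        "mean_exon_length",
        "mean_intron_length",
        "as_fraction",
    ]
    rows = []
    for f in fields:
        va, vb = getattr(a, f), getattr(b, f)
        delta = None if va is None or vb is None else va - vb
        rows.append({"field": f, labels[0]: va, labels[1]: vb, "delta": delta})
    ha = a.exon_count_hist
    hb = b.exon_count_hist
    mode_a = max(ha, key=lambda k: (ha[k], -k))
    mode_b = max(hb, key=lambda k: (hb[k], -k))
    rows.append(
        {"field": "exon_count_mode", labels[0]: mode_a, labels[1]: mode_b,
         "delta": mode_a - mode_b}
    )
    return pd.DataFrame(rows)


def length_histogram(
    values: Sequence[float], *, bin_width: float, max_value: float | None = None
) -> pd.DataFrame:
    """Binned counts for density-style length distributions (TSV-ready).

    Bins are half-open [lo, lo + bin_width); values above ``max_value``
    are pooled into the final bin.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to bin")
    top = max_value if max_value is not None else float(v.max()) + bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(v, 0, top - 1e-9), bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "density": counts / (v.size * bin_width),
        }
    )
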