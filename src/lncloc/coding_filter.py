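"""Filter cascade reducing assembled transcripts to lncRNA candidates.

Seven steps, applied in order: (1) size/structure — spliced length >=
200 nt and >= 2 exons; (2) ORF — longest ATG-initiated, stop-terminated
open reading frame over all six frames must be < 300 nt; (3-7) removal
of transcripts named in externally produced evidence lists (protein
BLAST hits, UTR fragments of known mRNAs, coding-potential calls, Pfam
domain hits, structural ncRNA hits).  The evidence lists stand in for
live BLASTX/CPC/HMMER/Infernal runs, whose thresholds (e.g. e < 0.001,
CPC score <= -1) are applied by whoever produces the lists; a helper
for tabular BLAST output is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

#: Cascade order of the evidence-based steps.
EVIDENCE_LABELS = (
    "protein_hit",
    "utr_fragment",
    "coding_potential",
    "pfam_domain",
    "structural_ncrna",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _longest_orf_one_strand(seq: str) -> int:
    """Longest ATG..stop ORF (nt, stop included) in the three forward frames.

    For each frame we track the earliest unterminated ATG; an in-frame
    stop closes the longest ORF ending at that stop.  ORFs truncated by
    the sequence end do not count.  Codons containing N match neither
    start nor stop.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    best = max(best, i + 3 - start)
                    start = None
            elif start is None and codon == START_CODON:
                start = i
    return best


def longest_orf(seq: str, *, both_strands: bool = True) -> int:
    """Length (nt) of the longest complete ORF; 0 when none exists.

    ``both_strands=True`` scans all six frames (the reverse strand via
    reverse complement); ``False`` restricts to the three forward
    frames.
    """
    seq = seq.upper()
    best = _longest_orf_one_strand(seq)
    if both_strands:
        best = max(best, _longest_orf_one_strand(reverse_complement(seq)))
    return best


def spliced_sequence(t: TranscriptModel, genome) -> str:
    """Mature transcript sequence: exons concatenated 5'->3'.

    Minus-strand transcripts are reverse-complemented (exon order in
    the genome is reversed by the complement step itself).
    """
    seq = "".join(genome.fetch(t.chrom, e.start, e.end) for e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate filter.

    min_length/min_exons follow the retention rule "length >= 200 nt and
    exon number >= 2"; max_orf is an exclusive-keep threshold (survivors
    have longest ORF strictly below it, measured in nt including the
    stop codon).
    """

    min_length: int = 200
    min_exons: int = 2
    max_orf: int = 300
    orf_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_exons < 1 or self.max_orf < 1:
            raise ValueError("filter thresholds must be >= 1")


@dataclass(frozen=True)
class EvidenceSet:
    """Transcript IDs flagged by one external evidence source."""

    label: str
    transcript_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.label not in EVIDENCE_LABELS:
            raise ValueError(
                f"unknown evidence label {self.label!r}; expected one of {EVIDENCE_LABELS}"
            )
        object.__setattr__(self, "transcript_ids", frozenset(self.transcript_ids))


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    """Telescoping per-step accounting of the cascade."""

    steps: list[FilterStep] = field(default_factory=list)
    surviving_ids: list[str] = field(default_factory=list)
    stale_evidence: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_survivors(self) -> int:
        return len(self.surviving_ids)

    def telescopes(self) -> bool:
        """Each step's output count equals the next step's input count."""
        for a, b in zip(self.steps, self.steps[1:]):
            if a.n_out != b.n_in:
                return False
        return not self.steps or self.steps[-1].n_out == self.n_survivors

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": s.name,
                "n_in": s.n_in,
                "n_removed": s.n_removed,
                "n_out": s.n_out,
            }
            for s in self.steps
        ]


def run_cascade(
    ts: Sequence[TranscriptModel],
    genome,
    evidence: Iterable[EvidenceSet] = (),
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[TranscriptModel], FilterReport]:
    """Apply the seven-step filter; return survivors and the step report.

    Evidence labels must be unique; an evidence ID absent from the input
    is recorded under ``report.stale_evidence`` rather than raised.
    The final survivor set is order-insensitive (each rule is a pure
    predicate); only the per-step removal counts depend on step order.
    """
    ev_map: dict[str, frozenset[str]] = {}
    for ev in evidence:
        if ev.label in ev_map:
            raise ValueError(f"duplicate evidence label {ev.label!r}")
        ev_map[ev.label] = ev.transcript_ids

    report = FilterReport()
    input_ids = {t.transcript_id for t in ts}
    current = list(ts)

    def apply_step(name: str, keep) -> None:
        nonlocal current
        kept = [t for t in current if keep(t)]
        report.steps.append(FilterStep(name, len(current), len(current) - len(kept)))
        current = kept

    apply_step(
        "length_exons",
        lambda t: t.length >= cfg.min_length and t.n_exons >= cfg.min_exons,
    )
    apply_step(
        "orf",
        lambda t: longest_orf(
            spliced_sequence(t, genome), both_strands=cfg.orf_both_strands
        )
        < cfg.max_orf,
    )
    for label in EVIDENCE_LABELS:
        ids = ev_map.get(label, frozenset())
        stale = sorted(ids - input_ids)
        if stale:
            report.stale_evidence[label] = stale
        apply_step(label, lambda t, ids=ids: t.transcript_id not in ids)

    report.surviving_ids = [t.transcript_id for t in current]
    return current, report


# ---------------------------------------------------------------------------
# Evidence list files
# ---------------------------------------------------------------------------


def read_id_list(path: str | Path) -> set[str]:
    """One transcript ID per line; blank lines and '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    return ids


def read_blast_outfmt6(path: str | Path, *, max_evalue: float = 1e-3) -> set[str]:
    """Query IDs from tabular BLAST output (outfmt 6) passing the e-value cut.

    Column 1 is the query ID, column 11 the e-value; hits with
    e-value < ``max_evalue`` are returned.
    """
    ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 11 tab-delimited BLAST fields"
                )
            if float(fields[10]) < max_evalue:
                ids.add(fields[0])
    return ids


def read_evidence_file(
    path: str | Path, label: str, *, max_evalue: float = 1e-3
) -> EvidenceSet:
    """Load an evidence file, auto-detecting plain ID list vs BLAST outfmt 6."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.count("\t") >= 10:
        ids = read_blast_outfmt6(path, max_evalue=max_evalue)
    else:
        ids = read_id_list(path)
    return EvidenceSet(label, frozenset(ids))
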