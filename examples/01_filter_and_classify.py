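"""Filter assembled transcripts to lncRNA candidates and classify them.

Builds a small synthetic dataset (toy genome + reference annotation +
assembled transcripts with known truth), runs the seven-step filter
cascade, then assigns each survivor one of the seven genomic-location
classes and an HGNC-style name.
"""

from lncloc import FixtureSpec, classify_all, generate, group_loci, run_cascade
from lncloc.classify import LncClass, assign_names, class_table

fx = generate(
    FixtureSpec(
        seed=7,
        n_coding_genes=60,
        per_class={cls: 6 for cls in LncClass},
        n_orf_planted=3,
        n_short=3,
        n_single_exon=3,
        n_evidence_per_label=2,
    )
)

survivors, report = run_cascade(fx.lnc_transcripts, fx.genome, fx.evidence)
print("Filter cascade (input - removed = survivors at every step):")
for step in report.steps:
    print(f"  {step.name:<18} {step.n_in:>4} -> removed {step.n_removed:>2} -> {step.n_out:>4}")

records = classify_all(survivors, fx.annotation)
records = assign_names(records, group_loci(survivors), prefix="BPH")
print("\nClass table (counts and percentages over surviving candidates):")
print(class_table(records).to_string(index=False))

print("\nExample names (location class determines the suffix):")
for r in records[:5]:
    print(f"  {r.transcript_id} -> {r.assigned_name:<22} [{r.lnc_class.value}]")
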