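"""Generate a small synthetic dataset and look at what it contains.

The simulator builds a toy genome (one autosome plus a Z chromosome),
multi-isoform gene models with known alternative-splicing events, lncRNAs of
known class, negative-binomial expression counts with a male-biased Z, and
poly(A)-site read ends — all from a single seed.
"""

from zdosage.synthetic_data import ChromSpec, LncRNASpec, SimulationConfig, generate_annotation, simulate_expression

cfg = SimulationConfig(
    seed=1,
    chromosomes=[
        ChromSpec("1", 4_000_000, False, 30),
        ChromSpec("Z", 3_000_000, True, 20),
    ],
    lncrna_spec=LncRNASpec(count=8),
    tissues=["gonad"],
)

annotation, truth = generate_annotation(cfg)
counts, sheet = simulate_expression(annotation, truth, cfg)

print(f"genes: {len(annotation.genes)}  (coding: {len(annotation.coding_genes())})")
print(f"transcripts: {len(annotation.transcripts_by_id())}")
print(f"injected AS events: {len(truth.as_events)}")
print(f"lncRNA classes: { {t: truth.lncrna_class[t] for t in truth.noncoding[:4]} } ...")
print(f"count matrix: {counts.data.shape[0]} transcripts x {counts.data.shape[1]} samples")
print(sheet.table.head(4).to_string(index=False))
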