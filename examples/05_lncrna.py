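"""Classify lncRNAs by genomic context and link them to nearby target genes.

Classes: lincRNA (intergenic), antisense (opposite-strand overlap of a coding
gene), sense (same-strand overlap), intronic (inside an intron, same strand).
Targets are coding genes within 100 kb.
"""

from collections import Counter

from zdosage import lncrna, quantify
from zdosage.quantify import ExpressionMatrix
from zdosage.synthetic_data import SimulationConfig, generate_annotation, simulate_expression

cfg = SimulationConfig(seed=1, tissues=["gonad"])
annotation, truth = generate_annotation(cfg)
counts, sheet = simulate_expression(annotation, truth, cfg)

txs = annotation.transcripts_by_id()
lncs = [txs[t] for t in truth.noncoding]
classes = {t.transcript_id: lncrna.classify(t, annotation) for t in lncs}
print("class tally:", dict(Counter(classes.values())))
print(f"all match construction: {all(classes[t] == truth.lncrna_class[t] for t in classes)}")

pairs = lncrna.assign_targets(lncs, annotation)
print(f"\n{len(pairs)} lncRNA-target pairs within 100 kb")
print(pairs.head(4).to_string(index=False))

cpm_tx = quantify.normalize(counts)
lnc_expr = ExpressionMatrix(cpm_tx.data.loc[[t.transcript_id for t in lncs]])
bias = lncrna.call_bias(lnc_expr, sheet, tissue="gonad")
print(f"\nmale-biased lncRNAs in gonad: {int(bias['male_biased'].sum())} / {len(bias)}")
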