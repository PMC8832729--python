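"""Scan the Z chromosome in sliding windows and find the peak-bias region.

The simulator injects an extra 1.5-fold male bias into Z:31-36 Mb; the
3 Mb / 1 Mb sliding-window scan and the top-region merge should recover it.
"""

from zdosage import dosage, quantify
from zdosage.synthetic_data import SimulationConfig, generate_annotation, simulate_expression

cfg = SimulationConfig(seed=1, tissues=["gonad"])
annotation, truth = generate_annotation(cfg)
counts, sheet = simulate_expression(annotation, truth, cfg)
cpm = quantify.normalize(quantify.sum_by_gene(counts, annotation))

bias = dosage.sex_bias_table(cpm, sheet, annotation, tissue="gonad")
scan = dosage.window_scan(bias[bias["chrom"] == "Z"], annotation.chromosomes["Z"])
print(scan.sort_values("mean_log2_mf", ascending=False).head(5).to_string(index=False))

region = dosage.top_region(scan)
print(f"\ntop region: {region.chrom}:{region.start:,}-{region.end:,} "
      f"(peak mean log2 M:F = {region.value:.3f}, {region.n_windows} windows merged)")
chrom, start, end = truth.hotspot
print(f"injected hotspot: {chrom}:{start:,}-{end:,}")
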