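"""Run the whole analysis end to end and read the summary back from disk.

`run_pipeline` writes every intermediate table as TSV plus a summary.json;
`summarize` recomputes the summary purely from those tables, so the two must
agree byte for byte — a quick self-check of the on-disk format.
"""

import tempfile
from pathlib import Path

from zdosage.pipeline import RunConfig, run_pipeline, summarize
from zdosage.synthetic_data import SimulationConfig

outdir = Path(tempfile.mkdtemp()) / "run"
cfg = RunConfig(outdir=str(outdir), simulation=SimulationConfig(seed=1, tissues=["gonad"]))

summary = run_pipeline(cfg)
print("tables written:")
for name, rows in sorted(summary.table_rows.items()):
    print(f"  {name:28s} {rows:6d} rows")

print(f"\nconfig hash: {summary.config_hash[:12]}...  tables hash: {summary.tables_hash[:12]}...")
print(f"Z:AA p (gonad, F): {summary.stats['zaa_p|gonad|F']:.3g}")
print(f"Z:AA p (gonad, M): {summary.stats['zaa_p|gonad|M']:.3g}")
print(f"top region (gonad): {summary.stats['top_region|gonad']}")

recomputed = summarize(outdir)
print(f"\nsummarize() == run summary: {recomputed.to_json() == summary.to_json()}")
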