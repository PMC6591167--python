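"""One-call end-to-end run: simulate -> DEG -> DNB -> exploratory -> summary.

Equivalent to the CLI invocation `dnbkit run-all --seed 5 --outdir dnb_run`.
"""

import json

from dnbkit import RunConfig, run_pipeline

config = RunConfig(
    outdir="scratch/example_run",
    seed=5,
    synthetic={"n_genes": 200, "n_dnb": 20, "deg_cluster_size": 10},
    pa_shuffles=50,
)
summary = run_pipeline(config)
print(json.dumps(summary, indent=2, default=str)[:1200])
print("...")
print(f"outputs written to {config.outdir}/ (expression, DEG tables, scores, summary.json)")
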