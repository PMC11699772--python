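"""Run the whole synthetic study end to end.

Simulates a hybrid cross (wt and Kdm6a-KO-like conditions, before and
after differentiation), builds pseudo-genomes, tags and quantifies all
libraries, calls Xi peak gains with the wt sample as background, and
writes every table plus a checksummed manifest under ./scratch/demo_run.
"""

import json

import pandas as pd

from xciseq import run_pipeline

manifest = run_pipeline("scratch/demo_run", replicates=2)
print(f"outputs written : {len(manifest['outputs'])} files (see manifest.json)")

induction = pd.read_csv("scratch/demo_run/xist_induction.tsv", sep="\t")
print(induction[["condition", "fold", "log2_fold"]])
# The Xist-like locus is induced ~6-fold on differentiation in wt but
# only ~2.5-fold in the KO — the planted failure of Xist upregulation.

with open("scratch/demo_run/xi_gain_report.tsv") as fh:
    print(fh.read())
# Gained peaks are the KO-only Xi (G1-allele) enrichment domains.
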