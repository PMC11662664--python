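"""Run the orchestrated pipeline end to end and read its summary outputs.

One seeded config drives simulate -> deconvolve -> annotate -> call ->
differential -> summarize; afterwards the distance composition, saturation
behavior and Monte-Carlo chi-square sample comparison are printed from the
on-disk tables.
"""

import json
import os
import tempfile

import pandas as pd

from radip import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as outdir:
    cfg = RunConfig(outdir=outdir, seed=7, chrom_lengths=[500_000, 350_000],
                    n_genes=40, n_pairs=3_000, n_replicates=2, n_peaks=5)
    manifest = run_pipeline(cfg)
    print(f"pipeline produced {len(manifest['files'])} files "
          f"(config hash {manifest['config_hash']}; identical config+seed "
          "reproduces identical tables)")

    dist = pd.read_csv(os.path.join(outdir, "input.distance_summary.tsv"),
                       sep="\t")
    print("\nInput distance composition (fractions sum to 1):")
    print(dist.to_string(index=False))

    sat = pd.read_csv(os.path.join(outdir, "ip.saturation.tsv"), sep="\t")
    print("\nIP saturation (distinct bins / RNA species vs depth):")
    print(sat.to_string(index=False))

    sim = json.load(open(os.path.join(outdir, "similarity.json")))
    print(f"\nMC chi-square Input-vs-IP on per-RNA profiles: "
          f"chi2={sim['chisq']:.1f}, p={sim['p']:.3g} over "
          f"{sim['n_categories']} RNAs")
    print("a p-value at the 1/(B+1) floor means none of the randomized "
          "tables reached the observed statistic: the two libraries "
          "captured clearly different interaction profiles")
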