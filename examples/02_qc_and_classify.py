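"""Run QC and origin classification on one simulated sample.

Shows the Table-style origin tally (counts and percentages of the unmapped
input) and how closely it matches the planted truth.
"""

import pandas as pd

from readtriage import SimulationConfig, simulate_study
from readtriage.pipeline import Pipeline, category_agreement, pairs_from_sim

config = SimulationConfig(seed=7, n_strains=4, n_pairs=3000, genome_length=200_000)
study = simulate_study(config)

pipeline = Pipeline(study.references.refs)
name = study.strain_names[0]
sim = study.reads[name]
result = pipeline.run_sample(pairs_from_sim(sim, config), sim.half_mapped, sample=name)

print(f"sample {name}: {result.qc.input} pairs in, {result.qc.passed} pass QC, "
      f"{result.qc.low_qc} low quality, {result.qc.variation} explained by variation")
row = pd.Series(result.tally.percentages).round(1)
print("origin percentages (of all unmapped pairs):")
print(row.to_string())

agreement = category_agreement(result.tally, sim.truth)
mismatch = {c: v for c, v in agreement.items() if v[0] != v[1]}
print("categories disagreeing with planted truth:", mismatch or "none")
print("contaminant genera:", result.genus.genus_counts)
# 'remaining' pairs are the candidate novel sequences passed downstream.
print(f"{len(result.remaining)} remaining pairs for the similarity stage")
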