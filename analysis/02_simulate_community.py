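#!/usr/bin/env python
"""Generate the synthetic model cohort that stands in for a genome-scale
model database.

Defaults: a 60-metabolite basal environment with 26 flagged disease
metabolites, 200 toy models in 20 genera (5 disease genera), and
dependence strength 0.8 — disease-genus models draw 80% of their required
substrates from the disease set.  Everything is written in the same
tabular formats the scoring pipeline reads from disk.

Writes results/community/{models/, environment.tsv, labels.tsv,
disease_metabolites.tsv}.
"""

from pathlib import Path

import pandas as pd

from passengerscreen import io
from passengerscreen.synthetic import CommunitySpec, generate_community, generate_environment

OUT = Path(__file__).resolve().parents[1] / "results" / "community"
SEED = 101


def main() -> None:
    spec = CommunitySpec(seed=SEED)
    env, disease = generate_environment(spec)
    models, truth = generate_community(spec, env, disease)

    (OUT / "models").mkdir(parents=True, exist_ok=True)
    io.write_environment(env, OUT / "environment.tsv")
    for m in models:
        io.write_tabular_model(m, OUT / "models" / f"{m.model_id}.tsv")
    truth.to_csv(OUT / "labels.tsv", sep="\t", index=False)
    pd.DataFrame({"metabolite": sorted(disease)}).to_csv(
        OUT / "disease_metabolites.tsv", sep="\t", index=False)

    n_disease = truth["disease_enriched"].sum()
    print(f"environment: {len(env.uptake_limits)} metabolites, "
          f"{len(disease)} flagged as disease set")
    print(f"community: {len(models)} models in {truth['genus'].nunique()} genera; "
          f"{n_disease} models belong to disease genera "
          f"({truth.loc[truth.disease_enriched, 'genus'].nunique()} genera)")
    print(f"wrote inputs under {OUT}")


if __name__ == "__main__":
    main()
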