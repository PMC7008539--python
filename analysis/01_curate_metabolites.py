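#!/usr/bin/env python
"""Classify the transcribed metabolomics evidence into disease-enriched and
disease-depleted metabolite sets.

A metabolite counts as enriched (or depleted) when at least three distinct
studies report it in that direction; counting is per direction, not a
majority vote.  On the packaged CRC evidence matrix this yields 29
classified metabolites: 26 enriched and 3 depleted (glucose, glutamine,
myoinositol) — the depleted set is too small to screen against, which is
why the downstream scores use the enriched set only.

Writes results/metabolite_directory.tsv.
"""

from pathlib import Path

import pandas as pd

from passengerscreen.curation import classify_metabolites, load_crc_evidence, load_crc_genera

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    evidence = load_crc_evidence()
    directory = classify_metabolites(evidence, min_studies=3)
    print(f"evidence records: {len(evidence)} over "
          f"{evidence['study'].nunique()} studies")
    print(f"classified metabolites: {directory.n_classified}")
    print(f"  enriched: {len(directory.enriched)}")
    print(f"  depleted: {len(directory.depleted)} -> {sorted(directory.depleted)}")
    print(f"  excluded (insufficient support): {len(directory.excluded)}")

    genera = load_crc_genera()
    print(f"disease-enriched genera: {genera['genus'].nunique()} "
          f"({len(genera)} mOTU records)")

    OUT.mkdir(exist_ok=True)
    rows = [{"metabolite": m, "class": "enriched"} for m in sorted(directory.enriched)]
    rows += [{"metabolite": m, "class": "depleted"} for m in sorted(directory.depleted)]
    rows += [{"metabolite": m, "class": "excluded"} for m in sorted(directory.excluded)]
    pd.DataFrame(rows).to_csv(OUT / "metabolite_directory.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'metabolite_directory.tsv'}")


if __name__ == "__main__":
    main()
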