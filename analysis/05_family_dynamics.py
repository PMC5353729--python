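#!/usr/bin/env python
"""Profile CHS repertoire expansion and contraction across taxa.

Builds the species x class count matrix from the assignments and summarises
each taxon (mean CHSs per species; per-class fractions of species with
multiple/one/no members).  The planted early-diverging-like taxon shows the
expansion signature (extra unclassifiable Type B1 copies), the yeasts the
contraction signature.  Writes ``results/profile.tsv`` and
``results/taxon_summaries.json``.
"""

import json
from pathlib import Path

from chsfam.dynamics import profile_counts, taxon_summary
from chsfam.io_formats import parse_taxonomy
from chsfam.pipeline import read_assignments_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    taxonomy = parse_taxonomy(RESULTS / "data" / "taxonomy.tsv")
    assignments = read_assignments_tsv(RESULTS / "assignments.tsv")
    profile = profile_counts(assignments, taxonomy)
    profile.table.to_csv(RESULTS / "profile.tsv", sep="\t")

    taxa: list[str] = []
    for sp in taxonomy.species_ids:
        for name in taxonomy.lineage(sp) + taxonomy.tags(sp):
            if name not in taxa:
                taxa.append(name)
    summaries = {}
    for taxon in taxa:
        s = taxon_summary(profile, taxonomy, taxon)
        summaries[taxon] = {
            "n_species": s.n_species,
            "mean_chs": s.mean_chs,
            "presence": s.presence,
        }
        print(f"  {taxon}: {s.n_species} species, mean {s.mean_chs} CHS/species")
    (RESULTS / "taxon_summaries.json").write_text(
        json.dumps(summaries, indent=1, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
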