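#!/usr/bin/env python
"""Build ordered domain architectures and assign Group/Type labels.

Reads the screened dataset, resolves each accepted protein's focal domain
hits plus its CON1 token into an ordered architecture, labels it
(A1-A3 / B1-B4 / other) and writes ``results/architectures.tsv``.
"""

from pathlib import Path

from chsfam.architecture import assign_structure_type, build_architecture
from chsfam.pipeline import (
    extract_all_con1,
    load_dataset_dir,
    write_architecture_tsv,
)
from chsfam.screen import filter_candidates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records, hits, _, _, _, truth = load_dataset_dir(RESULTS / "data")
    con1 = extract_all_con1(records)
    screen = filter_candidates(records, hits, con1)
    accepted = {r.protein_id for r in screen if r.accepted}

    archs = {}
    types = {}
    for rec in records:
        if rec.protein_id not in accepted:
            continue
        arch = build_architecture(rec, hits, con1[rec.protein_id])
        archs[rec.protein_id] = arch
        types[rec.protein_id] = assign_structure_type(arch).type_label
    write_architecture_tsv(archs, types, RESULTS / "architectures.tsv")

    tally: dict[str, int] = {}
    for t in types.values():
        tally[t] = tally.get(t, 0) + 1
    print(f"typed {len(archs)} accepted proteins")
    for t, n in sorted(tally.items()):
        print(f"  {t}: {n}")
    if truth:
        mismatch = sum(
            1
            for pid, t in types.items()
            if truth["proteins"][pid]["type"] not in (t, None)
        )
        print(f"  disagreements with planted types: {mismatch}")


if __name__ == "__main__":
    main()
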