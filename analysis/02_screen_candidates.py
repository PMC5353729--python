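#!/usr/bin/env python
"""Screen candidate proteins with the three CHS selection criteria.

Reads ``results/data``, extracts CON1 regions, applies (1) characteristic
domain presence, (2) CON1 motif presence, (3) within-species duplicate
collapse, and writes ``results/screening.tsv`` + ``results/con1_regions.tsv``.
On the planted dataset every decoy is rejected and every true CHS accepted.
"""

from pathlib import Path

from chsfam.pipeline import (
    extract_all_con1,
    load_dataset_dir,
    write_con1_tsv,
    write_screen_tsv,
)
from chsfam.screen import filter_candidates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records, hits, _, _, _, truth = load_dataset_dir(RESULTS / "data")
    con1 = extract_all_con1(records)
    results = filter_candidates(records, hits, con1)
    write_screen_tsv(results, RESULTS / "screening.tsv")
    write_con1_tsv(con1, RESULTS / "con1_regions.tsv")

    accepted = sum(r.accepted for r in results)
    print(f"accepted {accepted}/{len(results)} candidates")
    by_reason: dict[str, int] = {}
    for r in results:
        for reason in r.reasons:
            by_reason[reason] = by_reason.get(reason, 0) + 1
    for reason, n in sorted(by_reason.items()):
        print(f"  rejected for {reason}: {n}")
    if truth:
        wrong = [
            r.protein_id
            for r in results
            if r.accepted == truth["proteins"][r.protein_id]["role"].startswith("decoy")
        ]
        print(f"  disagreements with planted truth: {len(wrong)}")


if __name__ == "__main__":
    main()
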