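"""Recovery/rejection experiments on planted synthetic data.

These drivers quantify, against planted truth, the properties the pipeline
is designed to have: class-recovery rates at given divergences, decoy
rejection, noisy-B1 flagging, head-to-head detector recall, and NJ topology
recovery on additive matrices.  They are used both by the test suite and by
the acceptance script; every experiment takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassAssignment, flag_noisy
from .io_formats import Tree, TreeNode
from .phylo import DistanceMatrix, bipartition_sets, build_nj_tree, place_query
from .pipeline import (
    AnalysisParams,
    analyze_dataset,
    extract_all_con1,
    reference_from_labeled,
)
from .screen import filter_candidates
from .simulate import ALL_CLASSES, SimConfig, SpeciesSpec, simulate_family
from .synteny import detect_head_to_head

__all__ = [
    "RecoveryResult",
    "class_recovery",
    "decoy_rejection",
    "noisy_b1_flagging",
    "synteny_performance",
    "nj_additive_recovery",
    "random_additive_tree",
    "tree_distance_matrix",
]


@dataclass(frozen=True)
class RecoveryResult:
    rate: float  # percentage in [0, 100]
    n: int


def _query_species_table(n_queries: int) -> tuple[SpeciesSpec, ...]:
    """Species specs planting exactly *n_queries* class members (classes
    cycling over I..VII, 23b), no decoys and no noisy copies."""
    species: list[SpeciesSpec] = []
    remaining = n_queries
    idx = 0
    while remaining > 0:
        take = min(len(ALL_CLASSES), remaining)
        counts = {cls: 1 for cls in ALL_CLASSES[:take]}
        species.append(
            SpeciesSpec(
                species_id=f"qs{idx:02d}",
                lineage=("Ascomycota", "Pezizomycotina", "Sordariomycetes"),
                class_counts=counts,
                n_decoy_no_motif=0,
                n_decoy_no_domain=0,
            )
        )
        remaining -= take
        idx += 1
    return tuple(species)


def class_recovery(
    within: float,
    between: float,
    n_queries: int = 100,
    *,
    n_reps: int = 100,
    seed: int = 0,
) -> RecoveryResult:
    """Fraction of planted class members recovered with their true class by
    the full screen -> type -> place -> classify chain."""
    config = SimConfig(
        seed=seed,
        species=_query_species_table(n_queries),
        within_class_divergence=within,
        between_class_divergence=between,
    )
    ds = simulate_family(config)
    reference = reference_from_labeled(ds.reference)
    result = analyze_dataset(
        ds.records,
        ds.domain_hits,
        ds.gene_models,
        ds.taxonomy,
        reference,
        AnalysisParams(n_reps=n_reps, seed=seed),
    )
    by_pid = {a.protein_id: a for a in result.assignments}
    total = correct = 0
    for pid, info in ds.truth.proteins.items():
        if not info["role"].startswith("class:"):
            continue
        total += 1
        a = by_pid.get(pid)
        if a is not None and a.class_label == info["class"]:
            correct += 1
    return RecoveryResult(rate=100.0 * correct / total, n=total)


def decoy_rejection(seed: int = 0) -> RecoveryResult:
    """Fraction of planted decoys (motif-free or domain-free) rejected by
    the three screening criteria on the default dataset."""
    ds = simulate_family(SimConfig(seed=seed))
    con1 = extract_all_con1(ds.records)
    results = {
        r.protein_id: r for r in filter_candidates(ds.records, ds.domain_hits, con1)
    }
    decoys = [
        pid
        for pid, info in ds.truth.proteins.items()
        if info["role"].startswith("decoy")
    ]
    rejected = sum(1 for pid in decoys if not results[pid].accepted)
    return RecoveryResult(rate=100.0 * rejected / len(decoys), n=len(decoys))


def noisy_b1_flagging(seed: int = 0, *, n_reps: int = 100) -> RecoveryResult:
    """Fraction of planted phylogenetically incoherent Type B1 proteins
    flagged noisy (placement-based Division 3 exemption applied)."""
    ds = simulate_family(SimConfig(seed=seed))
    reference = reference_from_labeled(ds.reference)
    con1 = extract_all_con1(ds.records)
    noisy_ids = sorted(
        pid for pid, info in ds.truth.proteins.items() if info["role"] == "noisy_b1"
    )
    flagged = 0
    for k, pid in enumerate(noisy_ids):
        region = con1[pid]
        assert region is not None
        placement = place_query(
            (pid, region.sequence),
            reference,
            n_reps=n_reps,
            seed=np.random.default_rng([seed, k]),
        )
        if flag_noisy("B1", placement):
            flagged += 1
    return RecoveryResult(rate=100.0 * flagged / len(noisy_ids), n=len(noisy_ids))


def synteny_performance(seed: int = 0) -> tuple[RecoveryResult, RecoveryResult]:
    """(recall on planted head-to-head pairs, false-positive rate on species
    planted without the arrangement), using planted class labels so the
    geometric detector is measured at zero annotation noise."""
    ds = simulate_family(SimConfig(seed=seed))
    assignments = [
        ClassAssignment(
            protein_id=pid,
            species_id=info["species"],
            class_label=info["class"],
            division=None,
            support=100.0,
            type_label=info["type"],
            host_clade_label=info["class"],
        )
        for pid, info in ds.truth.proteins.items()
        if info["role"] in ("class:V", "class:VII")
    ]
    calls = detect_head_to_head(ds.gene_models, assignments)
    detected = {
        c.species_id for c in calls if c.arrangement == "head_to_head"
    }
    planted = {
        sp for sp, info in ds.truth.species.items() if info["head_to_head"]
    }
    with_pair = {
        sp for sp, info in ds.truth.species.items() if info["has_pair"]
    }
    negatives = with_pair - planted
    recall = 100.0 * len(detected & planted) / len(planted) if planted else 100.0
    fp = 100.0 * len(detected & negatives) / len(negatives) if negatives else 0.0
    return (
        RecoveryResult(rate=recall, n=len(planted)),
        RecoveryResult(rate=fp, n=len(negatives)),
    )


# ---------------------------------------------------------------------------
# NJ recovery on additive matrices


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[Tree, list[str]]:
    """A random unrooted binary topology with branch lengths in [0.1, 1]."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes: list[TreeNode] = [
        TreeNode(label=nm, length=float(rng.uniform(0.1, 1.0))) for nm in names
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return Tree(root=root), names


def tree_distance_matrix(tree: Tree, names: list[str]) -> DistanceMatrix:
    """Exact leaf-to-leaf path lengths of a tree (an additive matrix)."""
    n = len(names)
    D = np.zeros((n, n))
    index = {nm: k for k, nm in enumerate(names)}

    def visit(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label or "": 0.0}
        blocks = []
        for c in node.children:
            d = visit(c)
            blocks.append({nm: dist + (c.length or 0.0) for nm, dist in d.items()})
        for bi in range(len(blocks)):
            for bj in range(bi + 1, len(blocks)):
                for nm_a, da in blocks[bi].items():
                    for nm_b, db in blocks[bj].items():
                        D[index[nm_a], index[nm_b]] = D[index[nm_b], index[nm_a]] = (
                            da + db
                        )
        merged: dict[str, float] = {}
        for b in blocks:
            merged.update(b)
        return merged

    visit(tree.root)
    return DistanceMatrix(ids=tuple(names), values=D)


def nj_additive_recovery(
    n_trials: int = 50, n_taxa: int = 6, seed: int = 0
) -> RecoveryResult:
    """Fraction of random additive matrices whose generating topology NJ
    reconstructs exactly (bipartition sets equal)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_trials):
        tree, names = random_additive_tree(n_taxa, rng)
        D = tree_distance_matrix(tree, names)
        rebuilt = build_nj_tree(D)
        if set(bipartition_sets(rebuilt)) == set(bipartition_sets(tree)):
            ok += 1
    return RecoveryResult(rate=100.0 * ok / n_trials, n=n_trials)
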