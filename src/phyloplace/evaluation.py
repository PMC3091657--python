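"""Leave-one-out validation: fragmentation, pruning, accuracy reports.

A target genome is removed from the reference (optionally together with
an increasingly large surrounding clade), its synthetic genome is cut
into non-overlapping 1000-bp fragments, and each fragment runs the full
pipeline — translation, frame selection, profile alignment, trimming,
length filter, placement.  Correctness is measured as the node distance
between observed and true placement branch (placements no more than two
nodes away count as correct) and as taxonomic agreement: a fragment is
assigned to the deepest rank on which all genomes in the clade below
its placement branch agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import FittedReference, optimize_all
from .models import load_empirical_model, uniform_model
from .msa import MSA
from .parsimony import place_query_mp
from .placement import QueryError, place_query_ml
from .preprocess import (
    TrimParams,
    align_to_reference,
    apply_trim_to_query,
    build_profile,
    detection_threshold,
    length_filter,
    select_frame,
    translate_six_frames,
    trim_columns,
)
from .refpkg import RefPackage
from .simulate import synth_genome
from .tree import clade_leaf_labels, prune_leaves


@dataclass
class EvaluationRecord:
    fragment_id: str
    true_branch: int | None
    observed_branch: int | None
    node_distance: int | None
    correct_at_2: bool
    assigned_lineage: tuple[str, ...]
    deepest_correct_rank: int
    method: str
    dropped: str | None = None  # reason, when the fragment never placed


def fragment_genome(sequence: str, size: int = 1000) -> list[tuple[str, int, str]]:
    """Non-overlapping consecutive fragments; the short remainder is discarded."""
    if size < 1:
        raise ValueError("fragment size must be positive")
    n = len(sequence) // size
    return [(f"frag{i}", i * size, sequence[i * size : (i + 1) * size]) for i in range(n)]


def prune_taxa(pkg: RefPackage, labels) -> tuple[RefPackage, int | None]:
    """Remove taxa from a package; returns (reduced package, true branch id)."""
    reduced_tree, true_branch = prune_leaves(pkg.tree, labels)
    gone = set(labels)
    taxonomy = None
    if pkg.taxonomy is not None:
        taxonomy = {k: v for k, v in pkg.taxonomy.items() if k not in gone}
    reduced = RefPackage(
        tree=reduced_tree,
        msa=pkg.msa.drop(gone),
        taxonomy=taxonomy,
        model_name=pkg.model_name,
        alpha=pkg.alpha,
        name=pkg.name,
    )
    return reduced, true_branch


def node_distance(tree, branch_a: int, branch_b: int) -> int:
    return tree.node_distance(branch_a, branch_b)


def assign_taxonomy(pkg: RefPackage, edge_id: int) -> tuple[str, ...]:
    """Longest lineage prefix shared by every leaf below the branch.

    "Below" is the leafward side in the rooted orientation; a pendant
    branch therefore returns that leaf's full lineage and the branch
    over two domains returns the empty prefix.
    """
    if pkg.taxonomy is None:
        raise ValueError("package has no taxonomy")
    node = pkg.tree.edge_nodes[edge_id]
    leaves = [n.label for n in node.postorder() if n.is_leaf]
    lineages = []
    for l in leaves:
        if l not in pkg.taxonomy:
            raise ValueError(f"missing lineage for leaf {l!r}")
        lineages.append(pkg.taxonomy[l])
    prefix = []
    for ranks in zip(*lineages):
        if len(set(ranks)) == 1:
            prefix.append(ranks[0])
        else:
            break
    return tuple(prefix)


def _lineage_agreement(assigned: tuple[str, ...], truth: tuple[str, ...]) -> int:
    d = 0
    for a, t in zip(assigned, truth):
        if a != t:
            break
        d += 1
    return d


@dataclass
class PipelineOptions:
    method: str = "ML"
    fragment_size: int = 1000
    min_residues: int = 50
    spacer_nt: int = 300
    estimate_alpha: bool = False
    fit_tol: float = 1e-2
    use_detection_threshold: bool = True
    n_shuffles: int = 50


def _place_fragment(
    fragment: str,
    fit: FittedReference,
    pkg: RefPackage,
    profile,
    background,
    opts: PipelineOptions,
    seed: int,
):
    """Run one fragment through the preprocessing + placement chain.

    Returns (result or None, trimmed aligned row, drop reason).
    """
    peptides = translate_six_frames(fragment)
    frame, score = select_frame(peptides, profile, background)
    if opts.use_detection_threshold:
        thresh = detection_threshold(
            peptides[frame], profile, background, n_shuffles=opts.n_shuffles, seed=seed
        )
        if score <= thresh:
            return None, None, "no marker detected"
    row = align_to_reference(peptides[frame], profile, background)
    combined = MSA({**pkg.msa.rows, "__query__": row})
    mask = trim_columns(combined, TrimParams(n_rows=combined.n_rows))
    trimmed = apply_trim_to_query(row, mask)
    if not length_filter(trimmed, opts.min_residues):
        return None, trimmed, f"fewer than {opts.min_residues} residues after trimming"
    try:
        if opts.method.upper() == "MP":
            res = place_query_mp(fit.tree, pkg.msa, trimmed)
        else:
            res = place_query_ml(fit, trimmed)
    except QueryError as exc:
        return None, trimmed, str(exc)
    return res, trimmed, None


def _model_for(pkg: RefPackage, alpha: float):
    if pkg.model_name.upper() == "UNIFORM":
        return uniform_model(alpha=alpha, n_categories=4)
    return load_empirical_model(pkg.model_name, alpha=alpha)


def leave_one_out(
    pkg: RefPackage,
    target_label: str,
    opts: PipelineOptions | None = None,
    seed: int = 0,
    prune_depth: int = 0,
) -> list[EvaluationRecord]:
    """Prune the target (clade), fragment its genome, place every fragment."""
    opts = opts or PipelineOptions()
    if target_label not in set(pkg.tree.leaf_labels):
        raise ValueError(f"unknown target {target_label!r}")
    labels = clade_leaf_labels(pkg.tree, target_label, prune_depth)
    if len(set(pkg.tree.leaf_labels) - set(labels)) < 3:
        raise ValueError("pruning this clade would leave fewer than 3 leaves")
    reduced, true_branch = prune_taxa(pkg, labels)
    peptide = pkg.msa[target_label].replace("-", "")
    genome, _ = synth_genome({"m1": peptide}, opts.spacer_nt, seed)
    fragments = fragment_genome(genome, opts.fragment_size)

    alpha = pkg.alpha if pkg.alpha is not None else 1.0
    model = _model_for(reduced, alpha)
    fit = optimize_all(
        reduced.tree, reduced.msa, model,
        estimate_alpha=opts.estimate_alpha, tol=opts.fit_tol,
    )
    profile, background = build_profile(reduced.msa, fit.model.pi)
    truth_lineage = pkg.taxonomy[target_label] if pkg.taxonomy else ()

    records: list[EvaluationRecord] = []
    for frag_id, _, frag in fragments:
        res, trimmed, reason = _place_fragment(
            frag, fit, reduced, profile, background, opts, seed
        )
        if res is None:
            records.append(
                EvaluationRecord(
                    fragment_id=frag_id,
                    true_branch=true_branch,
                    observed_branch=None,
                    node_distance=None,
                    correct_at_2=False,
                    assigned_lineage=(),
                    deepest_correct_rank=0,
                    method=opts.method,
                    dropped=reason,
                )
            )
            continue
        obs = res.best.branch_id
        dist = (
            reduced.tree.node_distance(true_branch, obs)
            if true_branch is not None
            else None
        )
        assigned = (
            assign_taxonomy(reduced, res.best.edge_id)
            if reduced.taxonomy is not None
            else ()
        )
        records.append(
            EvaluationRecord(
                fragment_id=frag_id,
                true_branch=true_branch,
                observed_branch=obs,
                node_distance=dist,
                correct_at_2=dist is not None and dist <= 2,
                assigned_lineage=assigned,
                deepest_correct_rank=_lineage_agreement(assigned, truth_lineage),
                method=opts.method,
            )
        )
    return records


#: rank index (0-based into the 7-rank lineage) a record must agree through
_RANK_CHECKS = {"phylum": 2, "order": 4, "family": 5}


def aggregate_report(
    records: list[EvaluationRecord], weights: dict[str, float] | None = None
) -> dict:
    """Accuracy fractions plus per-branch placement counts.

    Placed fragments contribute their (optionally weighted) share to
    the exact (distance 0), within-two-nodes and per-rank agreement
    rates; dropped fragments are reported separately.
    """
    if not records:
        raise ValueError("no records to aggregate")
    placed = [r for r in records if r.observed_branch is not None]
    w = {r.fragment_id: (weights or {}).get(r.fragment_id, 1.0) for r in records}
    total = sum(w[r.fragment_id] for r in placed)
    counts: Counter = Counter()
    for r in placed:
        counts[r.observed_branch] += w[r.fragment_id]

    def frac(pred) -> float:
        if total == 0:
            return float("nan")
        return sum(w[r.fragment_id] for r in placed if pred(r)) / total

    report = {
        "n_fragments": len(records),
        "n_placed": len(placed),
        "n_dropped": len(records) - len(placed),
        "exact": frac(lambda r: r.node_distance == 0),
        "within_2_nodes": frac(lambda r: r.node_distance is not None and r.node_distance <= 2),
        "mean_node_distance": (
            float(np.mean([r.node_distance for r in placed if r.node_distance is not None]))
            if placed
            else float("nan")
        ),
        "per_branch_counts": dict(counts),
    }
    for rank, depth in _RANK_CHECKS.items():
        report[f"correct_{rank}"] = frac(lambda r, d=depth: r.deepest_correct_rank >= d)
    return report


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment_id": [r.fragment_id for r in records],
            "method": [r.method for r in records],
            "true_branch": [r.true_branch for r in records],
            "observed_branch": [r.observed_branch for r in records],
            "node_distance": [r.node_distance for r in records],
            "correct_at_2": [r.correct_at_2 for r in records],
            "deepest_correct_rank": [r.deepest_correct_rank for r in records],
            "assigned_lineage": [";".join(r.assigned_lineage) for r in records],
            "dropped": [r.dropped for r in records],
        }
    )
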