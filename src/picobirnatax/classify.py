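"""Consensus clade classification of candidate genera across a tree ensemble.

Candidate genus clades ("seeds") are identified on a reference tree as
well-supported, long-stem, sufficiently large clades — an explicit,
reproducible formalization of the visual identification of draft genera.
Each seed is then located in every tree of an ensemble inferred under
different outgroups and rooting schemes; tips that fall inside their seed's
well-supported representative clade in every tree are the "core" members
of that genus, and all others remain unclassified.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from picobirnatax.trees import Node, Tree

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CladeSeed:
    """A candidate genus: a label and its founding tip set."""

    genus_label: str
    member_tips: frozenset[str]
    origin: str = "detected"  # or "user-supplied"

    def __post_init__(self):
        if len(self.member_tips) == 0:
            raise ValueError(f"seed {self.genus_label!r} has no members")


@dataclass(frozen=True)
class MembershipEvidence:
    """Whether one tip sat inside its seed's supported clade in one tree."""

    tree_id: str
    genus_label: str
    tip_id: str
    in_supported_clade: bool
    support_at_clade: Optional[float]


@dataclass
class GenusAssignment:
    """Consensus tip-to-genus assignment with per-tip evidence."""

    assignments: dict[str, str]  # tip -> genus label or UNCLASSIFIED
    evidence: list[MembershipEvidence]

    def core_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genus in self.assignments.values():
            if genus != UNCLASSIFIED:
                counts[genus] = counts.get(genus, 0) + 1
        return counts

    def assignments_frame(self) -> pd.DataFrame:
        consistent: dict[str, int] = {}
        for ev in self.evidence:
            if ev.in_supported_clade:
                consistent[ev.tip_id] = consistent.get(ev.tip_id, 0) + 1
        rows = [
            {
                "tip_id": tip,
                "genus": genus,
                "n_trees_consistent": consistent.get(tip, 0),
            }
            for tip, genus in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows)

    def evidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tree_id": ev.tree_id,
                    "genus_label": ev.genus_label,
                    "tip_id": ev.tip_id,
                    "in_supported_clade": ev.in_supported_clade,
                    "support_at_clade": ev.support_at_clade,
                }
                for ev in self.evidence
            ]
        )


def _check_disjoint(seeds: Sequence[CladeSeed]) -> None:
    seen: dict[str, str] = {}
    for seed in seeds:
        for tip in seed.member_tips:
            if tip in seen:
                raise ValueError(
                    f"tip {tip!r} appears in seeds {seen[tip]!r} "
                    f"and {seed.genus_label!r}"
                )
            seen[tip] = seed.genus_label


def detect_seeds(
    reference_tree: Tree,
    min_support: float = 80.0,
    min_stem_factor: float = 2.0,
    min_seed_size: int = 5,
    label_prefix: str = "clade",
) -> list[CladeSeed]:
    """Detect candidate genus clades on a rooted reference tree.

    A clade qualifies if its MRCA support is at least ``min_support``, its
    stem branch is at least ``min_stem_factor`` times the median internal
    branch length, and it holds at least ``min_seed_size`` tips. Only
    maximal qualifying clades are kept (a seed cannot nest inside another).
    Seeds are labelled ``<prefix>_1`` ... in order of decreasing size, ties
    broken by smallest member label.
    """
    internal_lengths = [
        n.length
        for n in reference_tree.internal_nodes(include_root=False)
        if n.length is not None
    ]
    if not internal_lengths:
        warnings.warn("reference tree has no internal branch lengths")
        return []
    median_internal = statistics.median(internal_lengths)
    min_stem = min_stem_factor * median_internal

    qualifying: list[Node] = []
    for node in reference_tree.internal_nodes(include_root=False):
        if node.support is None or node.support < min_support:
            continue
        if node.length is None or node.length < min_stem:
            continue
        if sum(1 for _ in node.tips()) < min_seed_size:
            continue
        qualifying.append(node)

    # keep only maximal clades
    tipsets = [n.tip_set() for n in qualifying]
    maximal = [
        n
        for n, ts in zip(qualifying, tipsets)
        if not any(ts < other for other in tipsets)
    ]
    if not maximal:
        warnings.warn("no clade meets the seed criteria")
        return []
    maximal.sort(key=lambda n: (-sum(1 for _ in n.tips()), min(n.tip_set())))
    return [
        CladeSeed(f"{label_prefix}_{i + 1}", n.tip_set(), origin="detected")
        for i, n in enumerate(maximal)
    ]


def assess_membership(
    tree: Tree,
    seed: CladeSeed,
    min_support: float = 80.0,
    purity: float = 0.90,
    tree_id: str = "",
) -> list[MembershipEvidence]:
    """Locate the seed's representative clade in one tree and score members.

    Among internal nodes with support >= ``min_support`` whose tips are at
    least ``purity`` seed members, the representative is the one containing
    the most seed members (ties: higher purity, then fewer tips, then
    smallest tip label). Seed members inside it are marked consistent;
    members outside (or all members if no node qualifies) are not.
    """
    tree_tips = set(tree.tip_labels())
    present = seed.member_tips & tree_tips
    if not present:
        raise ValueError(
            f"seed {seed.genus_label!r} has no members in tree {tree_id!r}"
        )

    best: Optional[tuple] = None
    best_node: Optional[Node] = None
    for node in tree.internal_nodes(include_root=False):
        if node.support is None or node.support < min_support:
            continue
        clade = node.tip_set()
        n_members = len(clade & present)
        if n_members == 0:
            continue
        p = n_members / len(clade)
        if p < purity:
            continue
        key = (n_members, p, -len(clade))
        tiebreak = tuple(sorted(clade))
        if (
            best is None
            or key > best[0]
            or (key == best[0] and tiebreak < best[1])
        ):
            best = (key, tiebreak)
            best_node = node

    if best_node is None:
        inside: frozenset[str] = frozenset()
        support = None
    else:
        inside = best_node.tip_set()
        support = best_node.support

    return [
        MembershipEvidence(
            tree_id=tree_id,
            genus_label=seed.genus_label,
            tip_id=tip,
            in_supported_clade=tip in inside,
            support_at_clade=support if tip in inside else None,
        )
        for tip in sorted(present)
    ]


def classify_ensemble(
    trees: Sequence[Tree],
    seeds: Sequence[CladeSeed],
    min_support: float = 80.0,
    purity: float = 0.90,
    tree_ids: Optional[Sequence[str]] = None,
    allow_missing_tips: bool = False,
) -> GenusAssignment:
    """Retain per-genus core tips that are consistent in every ensemble tree.

    A tip is assigned to its seed's genus iff it sits inside that seed's
    supported representative clade in every tree (by default every tree
    must contain every seed member; ``allow_missing_tips`` relaxes this to
    consistency in every tree where the tip is present). The result is
    independent of tree order.
    """
    if not trees:
        raise ValueError("empty tree ensemble")
    _check_disjoint(seeds)
    if tree_ids is None:
        tree_ids = [f"tree_{i + 1}" for i in range(len(trees))]

    evidence: list[MembershipEvidence] = []
    consistent: dict[str, bool] = {
        tip: True for seed in seeds for tip in seed.member_tips
    }
    for tree, tid in zip(trees, tree_ids):
        tree_tips = set(tree.tip_labels())
        for seed in seeds:
            missing = seed.member_tips - tree_tips
            if missing and not allow_missing_tips:
                raise ValueError(
                    f"tree {tid!r} is missing seed members "
                    f"{sorted(missing)[:5]} of {seed.genus_label!r}; "
                    "use allow_missing_tips=True to permit this"
                )
            evs = assess_membership(
                tree, seed, min_support=min_support, purity=purity, tree_id=tid
            )
            evidence.extend(evs)
            for ev in evs:
                if not ev.in_supported_clade:
                    consistent[ev.tip_id] = False

    genus_of = {
        tip: seed.genus_label for seed in seeds for tip in seed.member_tips
    }
    assignments = {
        tip: (genus_of[tip] if ok else UNCLASSIFIED)
        for tip, ok in consistent.items()
    }
    return GenusAssignment(assignments=assignments, evidence=evidence)


def read_seeds_tsv(path) -> list[CladeSeed]:
    """Read user-supplied seeds (columns: genus_label, tip_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genus_label", "tip_id"} <= set(df.columns):
        raise ValueError("seeds TSV needs columns genus_label, tip_id")
    seeds = [
        CladeSeed(label, frozenset(group["tip_id"]), origin="user-supplied")
        for label, group in df.groupby("genus_label", sort=True)
    ]
    _check_disjoint(seeds)
    return seeds
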