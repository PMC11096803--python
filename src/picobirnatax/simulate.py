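"""Seeded synthetic-data generators with known ground truth.

Three generators cover the package's analyses end to end:

* :func:`simulate_cophylogeny` — a virus lineage descending a binary host
  tree under per-bifurcation probabilities of cross-species transmission
  (transfer), duplication and loss (otherwise it co-diverges). The
  generator is a generative mirror of the undated DTL model used by
  :mod:`picobirnatax.cophylogeny`, so event-likelihood recovery is
  well-posed.
* :func:`simulate_ensemble` — a tree ensemble with planted long-stem,
  well-supported clusters and a configurable set of migrant tips relocated
  into foreign clusters, for testing consensus classification.
* :func:`simulate_segments` — annotated genome segments whose 24-nt
  upstream windows carry RBS motifs planted at configured per-class
  frequencies (or exact per-class counts), on background sequence
  guaranteed free of accidental motifs.

All generators are reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from picobirnatax.classify import CladeSeed
from picobirnatax.cophylogeny import TipHostMap
from picobirnatax.rbs import (
    WINDOW,
    MOTIFS_4,
    MOTIFS_5,
    MOTIFS_6,
    ORF,
    AnnotatedSegment,
    classify_window,
)
from picobirnatax.trees import Node, Tree

#: Synthetic host cladogram over the animal host categories used for
#: virus-host congruence analysis (primates through invertebrates). It is a
#: hand-built stand-in following textbook vertebrate/invertebrate
#: relationships, not any published phylogeny, and contains no polytomies.
ANIMAL_HOST_CLADOGRAM = (
    "((Arthropod,Other_invertebrate),(Fish,((Reptile,Avian),"
    "(Tasmanian_devil,((Primate,(Rodent,Lagomorph)),"
    "(Bat,((Feline,Canine),(Equidae,(Suidae,(Dromedary,"
    "(Bovidae,Cervidae)))))))))));"
)


def yule_tree(
    n_tips: int, seed: int = 0, tip_prefix: str = "t", lengths: bool = True
) -> Tree:
    """Random binary tree grown by uniform tip splitting (Yule topology)."""
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    rng = random.Random(seed)
    root = Node(label=f"{tip_prefix}1")
    tips = [root]
    while len(tips) < n_tips:
        victim = tips.pop(rng.randrange(len(tips)))
        label = victim.label
        victim.label = None
        a = victim.add_child(Node(label=label))
        b = victim.add_child(Node(label=f"{tip_prefix}{len(tips) + 2}"))
        tips.extend([a, b])
    tree = Tree(root, rooted=True)
    if lengths:
        for node in tree.postorder():
            if node is not tree.root:
                node.length = round(rng.uniform(0.2, 1.5), 4)
    return tree


# ---------------------------------------------------------------------------
# Cophylogeny histories
# ---------------------------------------------------------------------------


@dataclass
class SimulatedHistory:
    """A planted virus-host history with exact realized event counts.

    ``event_counts`` refer to events surviving in the realized virus tree:
    every internal virus node is one cospeciation, transfer, or
    duplication (tagged on the node as ``.event``), and each drawn loss is
    one loss.
    """

    host_tree: Tree
    virus_tree: Tree
    tip_map: TipHostMap
    event_counts: dict[str, int]
    params: dict
    seed: int


class _AllLineagesLost(Exception):
    pass


def simulate_cophylogeny(
    host_tree: Tree,
    p_transfer: float = 0.0,
    p_duplication: float = 0.0,
    p_loss: float = 0.0,
    n_extant_target: Optional[int] = None,
    seed: int = 0,
    max_retries: int = 100,
) -> SimulatedHistory:
    """Drop a virus lineage down a binary host tree with planted events.

    At each host bifurcation the lineage co-diverges with probability
    ``1 - (p_transfer + p_duplication + p_loss)``; otherwise it transfers
    (one descendant jumps to a uniformly chosen non-ancestral host node
    while the donor descendant continues down one side of the
    bifurcation), duplicates (both descendants re-enter the same
    bifurcation), or dies. Because every non-duplication event makes
    progress toward the host tips, realized tree sizes stay close to the
    host size even at high transfer rates.
    Branching events whose one side is subsequently entirely lost collapse
    out of the realized tree and are not counted. Retries (bounded) if
    every lineage dies or fewer than ``n_extant_target`` virus tips remain.
    """
    ptot = p_transfer + p_duplication + p_loss
    if min(p_transfer, p_duplication, p_loss) < 0 or ptot > 1:
        raise ValueError("event probabilities must be >= 0 and sum to <= 1")
    for node in host_tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError("host tree must be binary")

    hnodes = list(host_tree.postorder())
    hindex = {id(n): i for i, n in enumerate(hnodes)}
    ancestors: dict[int, set[int]] = {}
    for i, h in enumerate(hnodes):
        anc = set()
        p = h.parent
        while p is not None:
            anc.add(hindex[id(p)])
            p = p.parent
        ancestors[i] = anc
    descendants: dict[int, set[int]] = {i: set() for i in range(len(hnodes))}
    for i, h in enumerate(hnodes):
        for ch in h.children:
            ci = hindex[id(ch)]
            descendants[i] |= descendants[ci] | {ci}
    non_ancestral = {
        i: [
            j
            for j in range(len(hnodes))
            if j != i and j not in ancestors[i] and j not in descendants[i]
        ]
        for i in range(len(hnodes))
    }

    last_err = None
    for attempt in range(max_retries):
        rng = random.Random(seed * 100003 + attempt)
        counts = {"cospeciation": 0, "transfer": 0, "duplication": 0, "loss": 0}
        tip_no = [0]
        tip_host: dict[str, str] = {}

        def gen(hi: int, depth: int = 0) -> Optional[Node]:
            if depth > 400:
                raise _AllLineagesLost("duplication cascade too deep")
            h = hnodes[hi]
            if h.is_tip:
                tip_no[0] += 1
                label = f"v{tip_no[0]:04d}"
                tip_host[label] = h.label
                return Node(label=label, length=1.0)
            r = rng.random()
            if r < p_loss:
                counts["loss"] += 1
                return None
            if r < p_loss + p_duplication:
                kind = "duplication"
                a = gen(hi, depth + 1)
                b = gen(hi, depth + 1)
            elif r < p_loss + p_duplication + p_transfer:
                kind = "transfer"
                # donor lineage continues down one side of the bifurcation;
                # recipient jumps to a uniformly chosen non-ancestral node
                stay_child = hindex[id(h.children[rng.randrange(2)])]
                a = gen(stay_child, depth + 1)
                target = non_ancestral[hi]
                if target:
                    b = gen(rng.choice(target), depth + 1)
                else:  # host root: nowhere to jump, treat as duplication
                    kind = "duplication"
                    b = gen(hi, depth + 1)
            else:
                kind = "cospeciation"
                a = gen(hindex[id(h.children[0])], depth + 1)
                b = gen(hindex[id(h.children[1])], depth + 1)
            if a is None and b is None:
                return None
            if a is None or b is None:
                return a if b is None else b
            node = Node(length=1.0)
            node.event = kind
            counts[kind] += 1
            node.add_child(a)
            node.add_child(b)
            return node

        try:
            root = gen(hindex[id(host_tree.root)])
        except _AllLineagesLost as err:
            last_err = err
            continue
        if root is None:
            last_err = _AllLineagesLost("all lineages lost before the tips")
            continue
        root.length = None
        virus = Tree(root, rooted=True)
        if n_extant_target is not None and virus.n_tips < n_extant_target:
            last_err = _AllLineagesLost(
                f"only {virus.n_tips} extant tips (target {n_extant_target})"
            )
            continue
        return SimulatedHistory(
            host_tree=host_tree,
            virus_tree=virus,
            tip_map=TipHostMap(tip_host),
            event_counts=counts,
            params={
                "p_transfer": p_transfer,
                "p_duplication": p_duplication,
                "p_loss": p_loss,
                "n_extant_target": n_extant_target,
            },
            seed=seed,
        )
    raise RuntimeError(
        f"simulation failed after {max_retries} attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# Planted cluster ensembles
# ---------------------------------------------------------------------------


@dataclass
class PlantedEnsemble:
    """A tree ensemble with planted clusters and known migrant tips."""

    trees: list[Tree]
    tree_ids: list[str]
    cluster_of: dict[str, str]  # tip -> planted cluster label
    migrants: list[str]
    seeds: list[CladeSeed] = field(default_factory=list)
    seed: int = 0
    #: migrant tip -> sorted tree indices where it was relocated
    moved_in: dict[str, list[int]] = field(default_factory=dict)


def _random_subtree(
    rng: random.Random,
    labels: Sequence[str],
    support_range: tuple[float, float],
    branch_range: tuple[float, float] = (0.05, 0.15),
) -> Node:
    nodes = [Node(label=lab, length=round(rng.uniform(*branch_range), 4))
             for lab in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        joint = Node(
            length=round(rng.uniform(*branch_range), 4),
            support=round(rng.uniform(*support_range), 1),
        )
        joint.add_child(a)
        joint.add_child(b)
        nodes.append(joint)
    return nodes[0]


def simulate_ensemble(
    n_clusters: int = 7,
    cluster_sizes: Optional[Sequence[int]] = None,
    n_trees: int = 10,
    n_migrants: int = 0,
    support_range: tuple[float, float] = (85.0, 100.0),
    seed: int = 0,
    stem_length: float = 1.0,
) -> PlantedEnsemble:
    """Generate a tree ensemble with planted long-stem clusters.

    Each tree re-draws within-cluster topology and supports, keeps every
    cluster monophyletic on a long stem with support in ``support_range``,
    and joins clusters on a weakly supported backbone (supports below 80,
    mirroring unstable deep relationships). Each of the ``n_migrants``
    randomly chosen tips is relocated into a foreign cluster in at least
    one tree (distinct foreign clusters per tree where possible).
    """
    if cluster_sizes is None:
        cluster_sizes = [12] * n_clusters
    if len(cluster_sizes) != n_clusters:
        raise ValueError("cluster_sizes length must equal n_clusters")
    if any(s < 2 for s in cluster_sizes):
        raise ValueError("cluster sizes must be >= 2")
    if n_migrants >= min(cluster_sizes):
        raise ValueError("n_migrants must be below the smallest cluster size")

    rng = random.Random(seed)
    cluster_labels = [f"cluster_{i + 1}" for i in range(n_clusters)]
    members = {
        lab: [f"c{i + 1}_t{j + 1}" for j in range(cluster_sizes[i])]
        for i, lab in enumerate(cluster_labels)
    }
    cluster_of = {
        tip: lab for lab, tips in members.items() for tip in tips
    }
    all_tips = sorted(cluster_of)
    migrants = sorted(rng.sample(all_tips, n_migrants))
    # each migrant is misplaced in a nonempty subset of trees
    moved_in: dict[str, set[int]] = {
        m: {rng.randrange(n_trees)} for m in migrants
    }
    for m in migrants:
        for t in range(n_trees):
            if rng.random() < 0.3:
                moved_in[m].add(t)

    trees: list[Tree] = []
    for t in range(n_trees):
        moved_here = [m for m in migrants if t in moved_in[m]]
        targets: dict[str, str] = {}
        pool = [c for c in cluster_labels]
        for m in moved_here:
            choices = [c for c in pool if c != cluster_of[m]]
            if not choices:
                choices = [c for c in cluster_labels if c != cluster_of[m]]
            tgt = rng.choice(choices)
            targets[m] = tgt
            if tgt in pool:
                pool.remove(tgt)

        clade_roots = []
        for lab in cluster_labels:
            present = [
                tip for tip in members[lab]
                if tip not in targets  # moved elsewhere this tree
            ]
            sub = _random_subtree(rng, present, support_range)
            sub.length = stem_length
            sub.support = round(rng.uniform(*support_range), 1)
            # graft incoming migrants as sister to a random member tip
            for m, tgt in targets.items():
                if tgt != lab:
                    continue
                victims = [n for n in sub.tips()]
                victim = victims[rng.randrange(len(victims))]
                holder = Node(
                    length=round(rng.uniform(0.05, 0.15), 4),
                    support=round(rng.uniform(*support_range), 1),
                )
                parent = victim.parent
                idx = parent.children.index(victim)
                parent.children[idx] = holder
                holder.parent = parent
                holder.add_child(victim)
                holder.add_child(
                    Node(label=m, length=round(rng.uniform(0.05, 0.15), 4))
                )
            clade_roots.append(sub)
        # weakly supported caterpillar backbone, random join order
        rng.shuffle(clade_roots)
        spine = clade_roots[0]
        for nxt in clade_roots[1:]:
            joint = Node(
                length=round(rng.uniform(0.05, 0.15), 4),
                support=round(rng.uniform(30.0, 75.0), 1),
            )
            joint.add_child(spine)
            joint.add_child(nxt)
            spine = joint
        spine.length = None
        spine.support = None
        trees.append(Tree(spine, rooted=True))

    seeds = [
        CladeSeed(lab, frozenset(members[lab]), origin="user-supplied")
        for lab in cluster_labels
    ]
    return PlantedEnsemble(
        trees=trees,
        tree_ids=[f"tree_{t + 1}" for t in range(n_trees)],
        cluster_of=cluster_of,
        migrants=migrants,
        seeds=seeds,
        seed=seed,
        moved_in={m: sorted(moved_in[m]) for m in migrants},
    )


# ---------------------------------------------------------------------------
# Planted RBS segments
# ---------------------------------------------------------------------------


@dataclass
class PlantedSegmentSet:
    """Annotated segments with known per-ORF planted motif classes."""

    segments: list[AnnotatedSegment]
    planted_class: dict[str, str]  # orf_id -> "6-mer"|"5-mer"|"4-mer"|"none"
    seed: int = 0


def _motif_free(rng: random.Random, length: int) -> str:
    """Random DNA with no RBS 4-mer (hence no 5/6-mer) anywhere."""
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(length))
        if not any(m in s for m in MOTIFS_4):
            return s


def _planted_window(rng: random.Random, cls: str, window: int) -> str:
    if cls == "none":
        return _motif_free(rng, window)
    motif = rng.choice(
        {"6-mer": MOTIFS_6, "5-mer": MOTIFS_5, "4-mer": MOTIFS_4}[cls]
    )
    k = len(motif)
    while True:
        bg = _motif_free(rng, window)
        off = rng.randrange(window - k + 1)
        win = bg[:off] + motif + bg[off + k :]
        if classify_window(win).motif_class == cls:
            return win


def _random_orf(rng: random.Random, n_codons: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice("ACGT") for _ in range(3))
            if codon not in stops:
                body.append(codon)
                break
    return "ATG" + "".join(body) + "TAA"


def simulate_segments(
    n_segments: int = 50,
    orfs_per_segment: int = 2,
    class_probabilities: Sequence[float] = (0.5, 0.2, 0.1, 0.2),
    utr_length: int = WINDOW,
    seed: int = 0,
    class_counts: Optional[Sequence[int]] = None,
    dataset_label: str = "synthetic",
    orf_codons: int = 60,
) -> PlantedSegmentSet:
    """Generate annotated segments with planted upstream RBS motifs.

    ``class_probabilities`` are (6-mer, 5-mer, 4-mer, none) draw
    probabilities per ORF; ``class_counts`` switches to deterministic
    composition mode with exactly those per-class ORF counts (shuffled
    across ORFs), in which case the total ORF count is spread as evenly as
    possible over ``n_segments``. The 24-nt window before every start
    codon is constructed on motif-free background so the planted class is
    exactly what the scanner reports.
    """
    if utr_length < WINDOW:
        raise ValueError(f"utr_length must be >= {WINDOW}")
    rng = random.Random(seed)
    classes = ("6-mer", "5-mer", "4-mer", "none")

    if class_counts is not None:
        if len(class_counts) != 4:
            raise ValueError("class_counts must have 4 entries")
        orf_classes = [
            cls for cls, n in zip(classes, class_counts) for _ in range(n)
        ]
        rng.shuffle(orf_classes)
        total = len(orf_classes)
        base, extra = divmod(total, n_segments)
        per_segment = [
            base + (1 if i < extra else 0) for i in range(n_segments)
        ]
        if base == 0:
            per_segment = [n for n in per_segment if n > 0]
    else:
        if abs(sum(class_probabilities) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        per_segment = [orfs_per_segment] * n_segments
        orf_classes = None

    segments: list[AnnotatedSegment] = []
    planted: dict[str, str] = {}
    orf_counter = 0
    for si, n_orfs in enumerate(per_segment):
        seq_parts: list[str] = []
        pos = 0
        orfs: list[ORF] = []
        lead = utr_length - WINDOW
        if lead:
            seq_parts.append("".join(rng.choice("ACGT") for _ in range(lead)))
            pos += lead
        for oi in range(n_orfs):
            if orf_classes is not None:
                cls = orf_classes[orf_counter]
            else:
                r = rng.random()
                acc = 0.0
                cls = classes[-1]
                for c, p in zip(classes, class_probabilities):
                    acc += p
                    if r < acc:
                        cls = c
                        break
            win = _planted_window(rng, cls, WINDOW)
            seq_parts.append(win)
            pos += WINDOW
            orf_seq = _random_orf(rng, orf_codons)
            orf_id = f"seg{si + 1:04d}_orf{oi + 1}"
            orfs.append(
                ORF(orf_id=orf_id, start=pos, end=pos + len(orf_seq), strand=1)
            )
            seq_parts.append(orf_seq)
            pos += len(orf_seq)
            planted[orf_id] = cls
            orf_counter += 1
        segments.append(
            AnnotatedSegment(
                segment_id=f"seg{si + 1:04d}",
                sequence="".join(seq_parts),
                orfs=orfs,
                dataset_label=dataset_label,
            )
        )
    return PlantedSegmentSet(segments=segments, planted_class=planted, seed=seed)
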