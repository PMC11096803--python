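"""Virus-host phylogenetic congruence: nPH85 distance and event-cost
parsimony reconciliation.

Two complementary measures of congruence between a virus phylogeny and a
host cladogram are provided:

* :func:`nph85` — the normalized Penny-Hendy (PH85) topological distance,
  i.e. the symmetric difference of non-trivial bipartition sets scaled to
  [0, 1]. 0 indicates complete co-divergence, 1 complete cross-species
  transmission (no shared splits). Because many virus tips usually map to
  one host tip, two explicit comparison modes are offered: expanding each
  host tip into a polytomy of its viruses (default), or repeatedly
  resampling one virus per host.

* :func:`reconcile_mpr` / :func:`event_likelihoods` — an undated
  duplication-transfer-loss (DTL) maximum-parsimony reconciliation of the
  virus tree into the host tree. Event costs default to 0 for
  co-divergence (cospeciation) and 1 each for cross-species transmission
  (transfer), duplication, and extinction (loss). The dynamic program
  returns the exact minimum cost and the exact number of maximum-parsimony
  reconciliations (MPRs, big-integer arithmetic); event likelihoods are
  the mean per-event-type fractions over reconciliations sampled uniformly
  from the MPR set.

Model notes: transfers may land on any host node not ancestrally comparable
with the donor position, and land directly (losses are charged only along
within-subtree descents). With a positive loss cost this yields the same
minimum cost as formulations that allow post-transfer losses, and it makes
the MPR count well defined.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from picobirnatax.trees import Bipartition, Node, Tree, bipartitions, restrict_to

_TOL = 1e-9


# ---------------------------------------------------------------------------
# Tip-to-host mapping
# ---------------------------------------------------------------------------


@dataclass
class TipHostMap:
    """Association of virus tips to host-cladogram tips and source categories.

    Many virus tips may map to one host tip. ``host_category`` optionally
    records the assumed host animal or environmental/microbial source
    category of each host tip (used to subset, e.g., animal-associated
    viruses).
    """

    virus_to_host: dict[str, str]
    host_category: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "TipHostMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = set(df.columns)
        vcol = "virus_tip" if "virus_tip" in cols else "tip_id"
        if vcol not in cols or "host_tip" not in cols:
            raise ValueError(
                "map TSV needs columns (virus_tip|tip_id, host_tip"
                "[, host_category])"
            )
        v2h = dict(zip(df[vcol], df["host_tip"]))
        cat: dict[str, str] = {}
        if "host_category" in cols:
            for _, row in df.iterrows():
                if isinstance(row["host_category"], str):
                    cat[row["host_tip"]] = row["host_category"]
        return cls(v2h, cat)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "virus_tip": v,
                "host_tip": h,
                "host_category": self.host_category.get(h, ""),
            }
            for v, h in sorted(self.virus_to_host.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def hosts_used(self) -> set[str]:
        return set(self.virus_to_host.values())

    def subset(self, virus_tips) -> "TipHostMap":
        keep = set(virus_tips)
        return TipHostMap(
            {v: h for v, h in self.virus_to_host.items() if v in keep},
            dict(self.host_category),
        )


@dataclass(frozen=True)
class EventCosts:
    """Parsimony costs; defaults are 0 for co-divergence, 1 otherwise."""

    cospeciation: float = 0.0
    transfer: float = 1.0
    duplication: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        for name in ("cospeciation", "transfer", "duplication", "loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be non-negative")


# ---------------------------------------------------------------------------
# Host-tree expansion and nPH85
# ---------------------------------------------------------------------------


def expand_host_tree(host: Tree, tip_map: TipHostMap) -> Tree:
    """Replace each host tip by (a polytomy of) its mapped virus tips.

    Host tips with no mapped virus are pruned; the result's tip set equals
    the mapped virus tip set.
    """
    host_tips = set(host.tip_labels())
    missing = {
        v: h for v, h in tip_map.virus_to_host.items() if h not in host_tips
    }
    if missing:
        raise KeyError(
            f"virus tips mapped to hosts absent from the cladogram: "
            f"{sorted(missing.items())}"
        )
    by_host: dict[str, list[str]] = {}
    for v, h in tip_map.virus_to_host.items():
        by_host.setdefault(h, []).append(v)

    tree = host.copy()
    for tip in tree.tips():
        viruses = sorted(by_host.get(tip.label, []))
        if not viruses:
            continue
        if len(viruses) == 1:
            tip.label = viruses[0]
        else:
            tip.label = None
            for v in viruses:
                tip.add_child(Node(label=v))
    mapped = set(tip_map.virus_to_host)
    if set(tree.tip_labels()) != mapped:
        tree = restrict_to(tree, mapped)
    return tree


@dataclass
class NPH85Result:
    """Normalized PH85 distance with shared-bipartition diagnostics."""

    distance: float
    mode: str
    n_virus_splits: int
    n_host_splits: int
    n_shared: int
    replicate_distances: Optional[list[float]] = None

    def to_dict(self) -> dict:
        out = {
            "nPH85": self.distance,
            "mode": self.mode,
            "n_virus_splits": self.n_virus_splits,
            "n_host_splits": self.n_host_splits,
            "n_shared_splits": self.n_shared,
        }
        if self.replicate_distances is not None:
            out["replicate_distances"] = self.replicate_distances
        return out


def _norm_split_distance(a: set[Bipartition], b: set[Bipartition]) -> float:
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return len(a ^ b) / denom


def nph85(
    virus_tree: Tree,
    host_cladogram: Tree,
    tip_map: TipHostMap,
    mode: str = "expanded-host-tree",
    resamples: int = 100,
    seed: int = 0,
) -> NPH85Result:
    """Normalized PH85 topological distance between virus and host trees.

    Both trees are treated as unrooted. In ``expanded-host-tree`` mode the
    host cladogram is expanded so each host tip becomes its mapped virus
    tips, and the distance is ``|Bv ^ Bh| / (|Bv| + |Bh|)`` over non-trivial
    bipartition sets. In ``resample-one-per-host`` mode, one virus tip per
    host is drawn uniformly ``resamples`` times; both trees are restricted
    to the draw and the mean normalized split distance is reported.
    """
    vtips = set(virus_tree.tip_labels())
    unmapped = vtips - set(tip_map.virus_to_host)
    if unmapped:
        raise KeyError(f"virus tips without host mapping: {sorted(unmapped)}")
    tip_map = tip_map.subset(vtips)
    if len(vtips) < 4:
        raise ValueError("nPH85 requires at least 4 virus tips")

    if mode == "expanded-host-tree":
        expanded = expand_host_tree(host_cladogram, tip_map)
        bv = bipartitions(virus_tree)
        bh = bipartitions(expanded)
        return NPH85Result(
            distance=_norm_split_distance(bv, bh),
            mode=mode,
            n_virus_splits=len(bv),
            n_host_splits=len(bh),
            n_shared=len(bv & bh),
        )
    if mode == "resample-one-per-host":
        rng = random.Random(seed)
        by_host: dict[str, list[str]] = {}
        for v, h in sorted(tip_map.virus_to_host.items()):
            by_host.setdefault(h, []).append(v)
        hosts = sorted(by_host)
        dists = []
        for _ in range(resamples):
            chosen = {h: rng.choice(by_host[h]) for h in hosts}
            draw = set(chosen.values())
            if len(draw) < 4:
                raise ValueError(
                    "fewer than 4 tips after one-per-host restriction"
                )
            v_sub = restrict_to(virus_tree, draw)
            h_sub = restrict_to(host_cladogram, set(chosen))
            for tip in h_sub.tips():
                tip.label = chosen[tip.label]
            dists.append(
                _norm_split_distance(bipartitions(v_sub), bipartitions(h_sub))
            )
        mean = sum(dists) / len(dists)
        return NPH85Result(
            distance=mean,
            mode=mode,
            n_virus_splits=-1,
            n_host_splits=-1,
            n_shared=-1,
            replicate_distances=dists,
        )
    raise ValueError(f"unknown nPH85 mode: {mode!r}")


# ---------------------------------------------------------------------------
# DTL reconciliation
# ---------------------------------------------------------------------------


def resolve_polytomies(tree: Tree, seed: int = 0) -> tuple[Tree, int]:
    """Binarize polytomies by seeded random caterpillar expansion.

    New internal nodes get zero-length, support-free branches. Returns the
    resolved copy and the number of polytomies resolved (for audit).
    """
    rng = random.Random(seed)
    tree = tree.copy()
    n_resolved = 0
    for node in list(tree.postorder()):
        if len(node.children) > 2:
            n_resolved += 1
        while len(node.children) > 2:
            kids = sorted(
                node.children, key=lambda c: min(c.tip_set())
            )
            rng.shuffle(kids)
            a, b = kids[0], kids[1]
            merged = Node(length=0.0)
            for k in (a, b):
                node.children.remove(k)
                merged.add_child(k)
            node.add_child(merged)
    return tree, n_resolved


class _DTLTables:
    """Dynamic-program tables over (virus node, host node) pairs."""

    __slots__ = ("c", "nc", "inn", "nin", "out", "nout")

    def __init__(self, np_: int, nh: int):
        self.c = [[math.inf] * nh for _ in range(np_)]
        self.nc = [[0] * nh for _ in range(np_)]
        self.inn = [[math.inf] * nh for _ in range(np_)]
        self.nin = [[0] * nh for _ in range(np_)]
        self.out = [[math.inf] * nh for _ in range(np_)]
        self.nout = [[0] * nh for _ in range(np_)]


@dataclass
class ReconciliationDP:
    """Result of the DTL dynamic program, ready for MPR sampling."""

    virus_tree: Tree
    host_tree: Tree  # binary; polytomies resolved if needed
    tip_map: TipHostMap
    costs: EventCosts
    min_cost: float
    mpr_count: int
    n_host_polytomies_resolved: int
    # internal state for sampling
    _vnodes: list[Node] = field(repr=False, default_factory=list)
    _hnodes: list[Node] = field(repr=False, default_factory=list)
    _vindex: dict = field(repr=False, default_factory=dict)
    _hindex: dict = field(repr=False, default_factory=dict)
    _tables: object = field(repr=False, default=None)
    _incomparable: list = field(repr=False, default_factory=list)


def reconcile_mpr(
    virus_tree: Tree,
    host_cladogram: Tree,
    tip_map: TipHostMap,
    costs: EventCosts = EventCosts(),
    host_resolution_seed: int = 0,
) -> ReconciliationDP:
    """Undated DTL maximum-parsimony reconciliation.

    Both trees must be rooted; the virus tree must be fully resolved (a
    polytomous virus tree is an error), while host polytomies are resolved
    deterministically from ``host_resolution_seed`` and reported. Returns
    the minimum total event cost and the exact MPR count.
    """
    for node in virus_tree.internal_nodes():
        if len(node.children) > 2:
            raise ValueError(
                "virus tree contains a polytomy at clade "
                f"{sorted(node.tip_set())[:4]}..."
            )
    unmapped = set(virus_tree.tip_labels()) - set(tip_map.virus_to_host)
    if unmapped:
        raise KeyError(f"unmapped virus tips: {sorted(unmapped)}")

    host_tree, n_resolved = resolve_polytomies(
        host_cladogram, seed=host_resolution_seed
    )
    hosts_in_tree = set(host_tree.tip_labels())
    bad = {
        v: h
        for v, h in tip_map.virus_to_host.items()
        if v in set(virus_tree.tip_labels()) and h not in hosts_in_tree
    }
    if bad:
        raise KeyError(f"virus tips mapped to unknown hosts: {sorted(bad.items())}")

    vnodes = list(virus_tree.postorder())
    hnodes = list(host_tree.postorder())
    vindex = {id(n): i for i, n in enumerate(vnodes)}
    hindex = {id(n): i for i, n in enumerate(hnodes)}
    np_, nh = len(vnodes), len(hnodes)

    # ancestor bitmasks for incomparability tests
    desc_mask = [0] * nh
    for i, h in enumerate(hnodes):
        m = 1 << i
        for ch in h.children:
            m |= desc_mask[hindex[id(ch)]]
        desc_mask[i] = m
    anc_mask = [0] * nh
    for i in reversed(range(nh)):  # preorder-ish: parents after children in postorder, so reverse
        h = hnodes[i]
        pm = anc_mask[hindex[id(h.parent)]] if h.parent is not None else 0
        anc_mask[i] = pm | (1 << (hindex[id(h.parent)]) if h.parent is not None else 0)
    incomparable: list[list[int]] = []
    for i in range(nh):
        comp = desc_mask[i] | anc_mask[i] | (1 << i)
        incomparable.append([j for j in range(nh) if not (comp >> j) & 1])

    T = _DTLTables(np_, nh)
    L = costs.loss
    tipmap_idx: dict[int, int] = {}
    hlabel_to_idx = {h.label: i for i, h in enumerate(hnodes) if h.is_tip}
    for i, v in enumerate(vnodes):
        if v.is_tip:
            tipmap_idx[i] = hlabel_to_idx[tip_map.virus_to_host[v.label]]

    def add_opt(best, count, cost, n):
        """Accumulate (min cost, count) over options."""
        if cost < best - _TOL:
            return cost, n
        if abs(cost - best) <= _TOL:
            return best, count + n
        return best, count

    for pi, p in enumerate(vnodes):
        if p.is_tip:
            hi = tipmap_idx[pi]
            T.c[pi][hi] = 0.0
            T.nc[pi][hi] = 1
        else:
            c1 = vindex[id(p.children[0])]
            c2 = vindex[id(p.children[1])]
            for hi, h in enumerate(hnodes):
                best, count = math.inf, 0
                if h.children:
                    hl = hindex[id(h.children[0])]
                    hr = hindex[id(h.children[1])]
                    for (x, hx, y, hy) in (
                        (c1, hl, c2, hr),
                        (c1, hr, c2, hl),
                    ):
                        cost = (
                            costs.cospeciation
                            + T.inn[x][hx]
                            + T.inn[y][hy]
                        )
                        if math.isfinite(cost):
                            best, count = add_opt(
                                best, count, cost, T.nin[x][hx] * T.nin[y][hy]
                            )
                cost = costs.duplication + T.inn[c1][hi] + T.inn[c2][hi]
                if math.isfinite(cost):
                    best, count = add_opt(
                        best, count, cost, T.nin[c1][hi] * T.nin[c2][hi]
                    )
                for stay, jump in ((c1, c2), (c2, c1)):
                    cost = costs.transfer + T.inn[stay][hi] + T.out[jump][hi]
                    if math.isfinite(cost):
                        best, count = add_opt(
                            best,
                            count,
                            cost,
                            T.nin[stay][hi] * T.nout[jump][hi],
                        )
                T.c[pi][hi] = best
                T.nc[pi][hi] = count
        # fill `in` over host postorder (children before parents)
        for hi, h in enumerate(hnodes):
            best, count = T.c[pi][hi], T.nc[pi][hi]
            for ch in h.children:
                ci = hindex[id(ch)]
                best, count = add_opt(
                    best, count, T.inn[pi][ci] + L, T.nin[pi][ci]
                )
            T.inn[pi][hi] = best
            T.nin[pi][hi] = count
        # fill `out` (best direct landing on an incomparable host node)
        for hi in range(nh):
            best, count = math.inf, 0
            for hj in incomparable[hi]:
                best, count = add_opt(best, count, T.c[pi][hj], T.nc[pi][hj])
            T.out[pi][hi] = best
            T.nout[pi][hi] = count

    ri = vindex[id(virus_tree.root)]
    best, count = math.inf, 0
    for hi in range(nh):
        best, count = add_opt(best, count, T.c[ri][hi], T.nc[ri][hi])

    return ReconciliationDP(
        virus_tree=virus_tree,
        host_tree=host_tree,
        tip_map=tip_map,
        costs=costs,
        min_cost=best,
        mpr_count=count,
        n_host_polytomies_resolved=n_resolved,
        _vnodes=vnodes,
        _hnodes=hnodes,
        _vindex=vindex,
        _hindex=hindex,
        _tables=T,
        _incomparable=incomparable,
    )


def _weighted_choice(rng: random.Random, options: list, weights: list[int]):
    """Choose an option with probability proportional to big-int weights."""
    total = sum(weights)
    r = rng.randrange(total)
    acc = 0
    for opt, w in zip(options, weights):
        acc += w
        if r < acc:
            return opt
    raise AssertionError("weighted choice fell through")  # pragma: no cover


_EVENTS = ("cospeciation", "transfer", "duplication", "loss")


def sample_reconciliation(
    dp: ReconciliationDP, rng: random.Random
) -> dict[str, int]:
    """Draw one MPR uniformly at random; returns its event counts."""
    T = dp._tables
    costs = dp.costs
    vindex, hindex = dp._vindex, dp._hindex
    vnodes, hnodes = dp._vnodes, dp._hnodes
    counts = dict.fromkeys(_EVENTS, 0)

    def sample_c(pi: int, hi: int) -> None:
        p = vnodes[pi]
        if p.is_tip:
            return
        h = hnodes[hi]
        c1 = vindex[id(p.children[0])]
        c2 = vindex[id(p.children[1])]
        target = T.c[pi][hi]
        opts, weights = [], []
        if h.children:
            hl = hindex[id(h.children[0])]
            hr = hindex[id(h.children[1])]
            for (x, hx, y, hy) in ((c1, hl, c2, hr), (c1, hr, c2, hl)):
                cost = costs.cospeciation + T.inn[x][hx] + T.inn[y][hy]
                if abs(cost - target) <= _TOL:
                    opts.append(("cosp", x, hx, y, hy))
                    weights.append(T.nin[x][hx] * T.nin[y][hy])
        cost = costs.duplication + T.inn[c1][hi] + T.inn[c2][hi]
        if abs(cost - target) <= _TOL:
            opts.append(("dup", c1, hi, c2, hi))
            weights.append(T.nin[c1][hi] * T.nin[c2][hi])
        for stay, jump in ((c1, c2), (c2, c1)):
            cost = costs.transfer + T.inn[stay][hi] + T.out[jump][hi]
            if abs(cost - target) <= _TOL:
                opts.append(("transfer", stay, hi, jump, None))
                weights.append(T.nin[stay][hi] * T.nout[jump][hi])
        kind, a, ha, b, hb = _weighted_choice(rng, opts, weights)
        if kind == "cosp":
            counts["cospeciation"] += 1
            sample_in(a, ha)
            sample_in(b, hb)
        elif kind == "dup":
            counts["duplication"] += 1
            sample_in(a, ha)
            sample_in(b, hb)
        else:
            counts["transfer"] += 1
            sample_in(a, ha)
            landings, lw = [], []
            for hj in dp._incomparable[hi]:
                if abs(T.c[b][hj] - T.out[b][hi]) <= _TOL:
                    landings.append(hj)
                    lw.append(T.nc[b][hj])
            hj = _weighted_choice(rng, landings, lw)
            sample_c(b, hj)

    def sample_in(pi: int, hi: int) -> None:
        while True:
            target = T.inn[pi][hi]
            opts, weights = [], []
            if abs(T.c[pi][hi] - target) <= _TOL:
                opts.append(("stay", hi))
                weights.append(T.nc[pi][hi])
            for ch in hnodes[hi].children:
                ci = hindex[id(ch)]
                if abs(T.inn[pi][ci] + costs.loss - target) <= _TOL:
                    opts.append(("desc", ci))
                    weights.append(T.nin[pi][ci])
            kind, nxt = _weighted_choice(rng, opts, weights)
            if kind == "stay":
                sample_c(pi, hi)
                return
            counts["loss"] += 1
            hi = nxt

    ri = vindex[id(dp.virus_tree.root)]
    roots, rw = [], []
    for hi in range(len(hnodes)):
        if abs(T.c[ri][hi] - dp.min_cost) <= _TOL:
            roots.append(hi)
            rw.append(T.nc[ri][hi])
    hi = _weighted_choice(rng, roots, rw)
    sample_c(ri, hi)
    return counts


@dataclass
class ReconciliationSummary:
    """Minimum cost, MPR count, and sampled event likelihoods.

    ``event_proportions`` is the mean, over sampled MPRs, of each event
    type's fraction of all events in the reconciliation (losses included in
    the denominator). "Cross-species transmission" is transfer and
    "extinction" is loss in standard DTL vocabulary; :meth:`to_dict` emits
    both labels.
    """

    min_total_cost: float
    mpr_count: int
    sampled_reconciliations: int
    event_proportions: dict[str, float]
    per_sample_counts: list[dict[str, int]]

    def to_dict(self) -> dict:
        p = self.event_proportions
        return {
            "min_total_cost": self.min_total_cost,
            "mpr_count": self.mpr_count,
            "sampled_reconciliations": self.sampled_reconciliations,
            "event_proportions": {
                "cospeciation": p["cospeciation"],
                "co_divergence": p["cospeciation"],
                "transfer": p["transfer"],
                "cross_species_transmission": p["transfer"],
                "duplication": p["duplication"],
                "loss": p["loss"],
                "extinction": p["loss"],
            },
        }


def event_likelihoods(
    dp: ReconciliationDP, n_samples: int = 100, seed: int = 0
) -> ReconciliationSummary:
    """Estimate event likelihoods over uniformly sampled MPRs.

    Each sample is an independent uniform draw from the MPR set (stochastic
    backtracking weighted by optimal-solution counts); proportions are the
    mean per-sample fraction of each event type among all events.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = random.Random(seed)
    samples = [sample_reconciliation(dp, rng) for _ in range(n_samples)]
    sums = dict.fromkeys(_EVENTS, 0.0)
    for counts in samples:
        total = sum(counts.values())
        if total == 0:
            continue
        for ev in _EVENTS:
            sums[ev] += counts[ev] / total
    denom = sum(1 for s in samples if sum(s.values()) > 0) or 1
    props = {ev: sums[ev] / denom for ev in _EVENTS}
    return ReconciliationSummary(
        min_total_cost=dp.min_cost,
        mpr_count=dp.mpr_count,
        sampled_reconciliations=n_samples,
        event_proportions=props,
        per_sample_counts=samples,
    )
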