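"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming / set-machinery
code paths: reconciliation is checked by exhaustive enumeration over all
placements and event labellings, and split distances against dendropy.
"""

from __future__ import annotations

from itertools import product

from picobirnatax.trees import Tree


def enumerate_reconciliations(virus_tree: Tree, host_tree: Tree,
                              v2h: dict[str, str], costs) -> tuple[float, int, list]:
    """Exhaustively enumerate every event-labelled reconciliation.

    Returns (min cost, number of optimal reconciliations, list of optimal
    per-event-count dicts). Host and virus trees must be binary and rooted.
    Transfers land directly on a host node incomparable with the donor;
    losses are charged per edge of within-subtree descent.
    """
    hnodes = list(host_tree.postorder())
    hidx = {id(n): i for i, n in enumerate(hnodes)}
    nh = len(hnodes)

    parent = [None] * nh
    for i, h in enumerate(hnodes):
        for ch in h.children:
            parent[hidx[id(ch)]] = i

    def ancestors(i):
        out = set()
        j = parent[i]
        while j is not None:
            out.add(j)
            j = parent[j]
        return out

    anc = [ancestors(i) for i in range(nh)]
    in_subtree = [[(i == j) or (j in anc[i]) for j in range(nh)]
                  for i in range(nh)]  # in_subtree[x][y]: x inside subtree of y

    def dist(top: int, low: int) -> int:
        d = 0
        j = low
        while j != top:
            j = parent[j]
            d += 1
        return d

    def incomparable(a: int, b: int) -> bool:
        return a != b and not in_subtree[a][b] and not in_subtree[b][a]

    vnodes = list(virus_tree.postorder())
    internal = [v for v in vnodes if not v.is_tip]
    hl_of = {i: hidx[id(hnodes[i].children[0])] for i in range(nh)
             if hnodes[i].children}
    hr_of = {i: hidx[id(hnodes[i].children[1])] for i in range(nh)
             if hnodes[i].children}
    htip = {h.label: i for i, h in enumerate(hnodes) if h.is_tip}

    best_cost = float("inf")
    best_count = 0
    best_profiles: list[dict] = []

    for assignment in product(range(nh), repeat=len(internal)):
        placed = {}
        for v in vnodes:
            if v.is_tip:
                placed[id(v)] = htip[v2h[v.label]]
        for v, h in zip(internal, assignment):
            placed[id(v)] = h

        total = 0.0
        count = 1
        profile_options = []  # per node: list of (extra cost over min, counts)
        node_opts_all = []
        feasible = True
        for v in internal:
            h = placed[id(v)]
            a = placed[id(v.children[0])]
            b = placed[id(v.children[1])]
            opts = []  # (cost, event, n_losses)
            if h in hl_of:
                hl, hr = hl_of[h], hr_of[h]
                if in_subtree[a][hl] and in_subtree[b][hr]:
                    opts.append((costs.cospeciation
                                 + costs.loss * (dist(hl, a) + dist(hr, b)),
                                 "cospeciation", dist(hl, a) + dist(hr, b)))
                if in_subtree[a][hr] and in_subtree[b][hl]:
                    opts.append((costs.cospeciation
                                 + costs.loss * (dist(hr, a) + dist(hl, b)),
                                 "cospeciation", dist(hr, a) + dist(hl, b)))
            if in_subtree[a][h] and in_subtree[b][h]:
                opts.append((costs.duplication
                             + costs.loss * (dist(h, a) + dist(h, b)),
                             "duplication", dist(h, a) + dist(h, b)))
            if in_subtree[a][h] and incomparable(b, h):
                opts.append((costs.transfer + costs.loss * dist(h, a),
                             "transfer", dist(h, a)))
            if in_subtree[b][h] and incomparable(a, h):
                opts.append((costs.transfer + costs.loss * dist(h, b),
                             "transfer", dist(h, b)))
            if not opts:
                feasible = False
                break
            node_min = min(c for c, _, _ in opts)
            winners = [(ev, nl) for c, ev, nl in opts
                       if abs(c - node_min) <= 1e-9]
            total += node_min
            count *= len(winners)
            node_opts_all.append(winners)
        if not feasible:
            continue
        if total < best_cost - 1e-9:
            best_cost = total
            best_count = count
            best_profiles = []
            record = True
        elif abs(total - best_cost) <= 1e-9:
            best_count += count
            record = True
        else:
            record = False
        if record:
            for combo in product(*node_opts_all):
                prof = {"cospeciation": 0, "transfer": 0,
                        "duplication": 0, "loss": 0}
                for ev, nl in combo:
                    prof[ev] += 1
                    prof["loss"] += nl
                best_profiles.append(prof)

    return best_cost, best_count, best_profiles


def dendropy_rf(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds symmetric difference via dendropy."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)
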