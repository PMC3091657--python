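"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive quantities the long way (exhaustive
enumeration, textbook recursions) and never call the engine code paths
they are used to check.
"""

import numpy as np

from phyloplace.alphabet import encode_sequence
from phyloplace.tree import parse_newick


def tipvec(s):
    v = np.zeros(20)
    if s < 0:
        v[:] = 1.0
    else:
        v[s] = 1.0
    return v


def brute_force_quartet_loglik(tree_newick, rows, model):
    """Exhaustive 20x20 internal-state enumeration for ((A,B),(C,D))."""
    t = parse_newick(tree_newick)
    lens = {n.label: n.length for n in t.edge_nodes if n.is_leaf}
    internal = [n.length for n in t.edge_nodes if not n.is_leaf]
    t_uv = sum(internal)  # merged root branch of the unrooted view
    enc = {k: encode_sequence(v) for k, v in rows.items()}
    n_sites = len(next(iter(rows.values())))
    total = 0.0
    for site in range(n_sites):
        site_l = 0.0
        for r in model.rates:
            P = lambda x: model.transition_matrix(x, r)
            Pa, Pb = P(lens["A"]), P(lens["B"])
            Pc, Pd = P(lens["C"]), P(lens["D"])
            Puv = P(t_uv)
            s = 0.0
            for u in range(20):
                pu = (Pa[u] @ tipvec(enc["A"][site])) * (Pb[u] @ tipvec(enc["B"][site]))
                for v in range(20):
                    pv = (Pc[v] @ tipvec(enc["C"][site])) * (
                        Pd[v] @ tipvec(enc["D"][site])
                    )
                    s += model.pi[u] * pu * Puv[u, v] * pv
            site_l += s / len(model.rates)
        total += np.log(site_l)
    return total


def fitch_insertion_oracle(tree, msa, query_states, branch):
    """Textbook Fitch on the rebuilt joined tree, rooted at the query."""
    branches = tree.placement_branches()
    adj = {}
    for b in branches:
        adj.setdefault(b.head.index, []).append(b.tail.index)
        adj.setdefault(b.tail.index, []).append(b.head.index)
    labels = {n.index: n.label for n in tree.nodes if n.is_leaf}

    def subtree(node, came_from):
        kids = [x for x in adj[node] if x != came_from]
        if not kids:
            return node
        return tuple(subtree(k, node) for k in kids)

    target = next(b for b in branches if b.branch_id == branch)
    down = subtree(target.head.index, target.tail.index)
    up = subtree(target.tail.index, target.head.index)
    score = 0

    def fitch(structure, site):
        nonlocal score
        if isinstance(structure, int):
            s = encode_sequence(msa[labels[structure]])[site]
            return set(range(20)) if s < 0 else {int(s)}
        sets = [fitch(child, site) for child in structure]
        acc = sets[0]
        for nxt in sets[1:]:
            inter = acc & nxt
            if inter:
                acc = inter
            else:
                acc = acc | nxt
                score += 1
        return acc

    for site in range(msa.n_cols):
        sd = fitch(down, site)
        su = fitch(up, site)
        inter = sd & su
        if inter:
            sx = inter
        else:
            sx = sd | su
            score += 1
        qs = query_states[site]
        qset = set(range(20)) if qs < 0 else {int(qs)}
        if not (sx & qset):
            score += 1
    return score
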