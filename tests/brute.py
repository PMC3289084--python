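"""Independent brute-force recomputations of every subgraph statistic.

These oracles deliberately use a different computational path from the
package: plain Python enumeration over itertools combinations and the
statistics module, with networkx only for connectivity checks.  They exist
so the vectorized feature code can be checked against direct definitions.
"""

from itertools import combinations
from statistics import median

from ppicomplex import ProteinNetwork
from ppicomplex.features import AMINO_ACIDS, POLAR_RESIDUES


def induced_edges(net: ProteinNetwork, members):
    mem = set(members)
    out = []
    for a, b, w in net.edges():
        if a in mem and b in mem:
            out.append((a, b, w))
    return out


def mean(xs):
    return sum(xs) / len(xs) if xs else 0.0


def pvar(xs):
    if not xs:
        return 0.0
    mu = mean(xs)
    return sum((x - mu) ** 2 for x in xs) / len(xs)


def density(net, members):
    k = len(members)
    if k < 2:
        return 0.0
    return 2 * len(induced_edges(net, members)) / (k * (k - 1))


def degrees(net, members):
    deg = {v: 0 for v in members}
    for a, b, _ in induced_edges(net, members):
        deg[a] += 1
        deg[b] += 1
    return deg


def degree_stats(net, members):
    d = list(degrees(net, members).values())
    return [mean(d), pvar(d), float(median(d)), max(d)]


def weight_stats(net, members):
    ws = [w for _, _, w in induced_edges(net, members) if w > 0]
    return [mean(ws), pvar(ws)]


def topological_change(net, members, cutoffs):
    ws = [w for _, _, w in induced_edges(net, members)]
    out = []
    for c_lo, c_hi in zip(cutoffs, cutoffs[1:]):
        e_lo = sum(1 for w in ws if w >= c_lo)
        e_hi = sum(1 for w in ws if w >= c_hi)
        out.append((e_lo - e_hi) / e_lo if e_lo else 0.0)
    return out


def _neighbors(net, members):
    mem = set(members)
    nbr = {v: set() for v in members}
    for a, b, _ in induced_edges(net, members):
        nbr[a].add(b)
        nbr[b].add(a)
    return nbr


def clustering_stats(net, members):
    nbr = _neighbors(net, members)
    cs = []
    for v in members:
        d = len(nbr[v])
        if d < 2:
            cs.append(0.0)
            continue
        tri = sum(1 for a, b in combinations(nbr[v], 2) if b in nbr[a])
        cs.append(tri / (d * (d - 1) / 2))
    return [mean(cs), pvar(cs), max(cs)]


def topological_coeff_stats(net, members):
    nbr = _neighbors(net, members)
    tcs = []
    for v in members:
        d = len(nbr[v])
        if d == 0:
            tcs.append(0.0)
            continue
        ratios = []
        for w in members:
            if w == v:
                continue
            shared = len(nbr[v] & nbr[w])
            if shared >= 1:
                j = shared + (1 if w in nbr[v] else 0)
                ratios.append(j / d)
        tcs.append(mean(ratios) if ratios else 0.0)
    return [mean(tcs), pvar(tcs), max(tcs)]


def length_stats(net, members):
    ls = [len(net.sequences.get(v, "")) for v in members]
    return [mean(ls), pvar(ls)]


def polarity(net, members):
    per_protein = []
    for v in members:
        seq = net.sequences.get(v, "")
        if not seq:
            per_protein.append([0.0] * 21)
            continue
        fracs = [seq.count(aa) / len(seq) for aa in AMINO_ACIDS]
        polar = sum(seq.count(aa) for aa in POLAR_RESIDUES) / len(seq)
        per_protein.append(fracs + [polar])
    return [mean([p[i] for p in per_protein]) for i in range(21)]


def full_vector(net, members, cutoffs):
    return (
        [density(net, members)]
        + degree_stats(net, members)
        + weight_stats(net, members)
        + topological_change(net, members, cutoffs)
        + clustering_stats(net, members)
        + topological_coeff_stats(net, members)
        + length_stats(net, members)
        + polarity(net, members)
    )
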