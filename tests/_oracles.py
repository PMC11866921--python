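"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity through exhaustive enumeration or a
closed form, deliberately sharing no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx

from tpscreen._elements import ISOTOPE_ABUNDANCE, MONOISOTOPIC_MASS


def isotope_pattern_multinomial(counts: dict[str, int],
                                max_offset: int = 2) -> list[float]:
    """Relative isotopologue abundance by nominal offset via explicit
    multinomial enumeration of isotope compositions per element."""

    def element_dist(elem: str, n: int) -> list[float]:
        probs = ISOTOPE_ABUNDANCE[elem]
        k = len(probs)
        dist = [0.0] * (max_offset + 1)
        for combo in itertools.product(range(n + 1), repeat=k):
            if sum(combo) != n:
                continue
            offset = sum(i * c for i, c in enumerate(combo))
            if offset > max_offset:
                continue
            coef = math.factorial(n)
            p = 1.0
            for c, prob in zip(combo, probs):
                coef //= math.factorial(c)
                p *= prob ** c
            dist[offset] += coef * p
        return dist

    total = [0.0] * (max_offset + 1)
    total[0] = 1.0
    for elem, n in counts.items():
        ed = element_dist(elem, n)
        new = [0.0] * (max_offset + 1)
        for i, a in enumerate(total):
            for j, b in enumerate(ed):
                if i + j <= max_offset:
                    new[i + j] += a * b
        total = new
    return [t / total[0] for t in total]


def mol_to_graph(mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), elem=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=bond.GetBondTypeAsDouble())
    return g


def mcs_size_bruteforce(mol_a, mol_b) -> int:
    """Maximum connected common subgraph (element- and bond-order-matched)
    by enumerating connected subgraphs of the smaller molecule and testing
    subgraph isomorphism into the other.  Exponential; only for molecules
    with <= ~12 heavy atoms."""
    ga, gb = mol_to_graph(mol_a), mol_to_graph(mol_b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga

    def connected_subsets(g: nx.Graph):
        nodes = list(g.nodes)
        found = set()
        for start in nodes:
            frontier = [frozenset([start])]
            while frontier:
                cur = frontier.pop()
                if cur in found:
                    continue
                found.add(cur)
                neighbors = {n for v in cur for n in g.neighbors(v)} - cur
                for n in neighbors:
                    frontier.append(cur | {n})
        return found

    node_match = nx.algorithms.isomorphism.categorical_node_match("elem", "")
    edge_match = nx.algorithms.isomorphism.numerical_edge_match("order", 1.0)
    best = 0
    for subset in sorted(connected_subsets(ga), key=len, reverse=True):
        if len(subset) <= best:
            continue
        sub = ga.subgraph(subset)
        gm = nx.algorithms.isomorphism.GraphMatcher(
            gb, sub, node_match=node_match, edge_match=edge_match)
        if gm.subgraph_is_monomorphic():
            best = len(subset)
    return best


def enumerate_formulas_nested(mz: float, tol_mda: float,
                              bounds: dict[str, int],
                              proton: float = 1.007276) -> set[str]:
    """Plain nested-loop enumeration over CHNOSF bounds with the same
    chemical filters expressed independently (RDBE and valence parity),
    returning Hill strings."""
    target = mz - proton
    tol = tol_mda / 1000.0
    out: set[str] = set()
    mC, mH, mN, mO, mS, mF = (MONOISOTOPIC_MASS[e]
                              for e in ("C", "H", "N", "O", "S", "F"))
    for c in range(bounds.get("C", 0) + 1):
        for h in range(bounds.get("H", 0) + 1):
            base_ch = c * mC + h * mH
            if base_ch > target + tol:
                break
            for n in range(bounds.get("N", 0) + 1):
                for o in range(bounds.get("O", 0) + 1):
                    for s in range(bounds.get("S", 0) + 1):
                        base = base_ch + n * mN + o * mO + s * mS
                        if base > target + tol:
                            break
                        for f in range(bounds.get("F", 0) + 1):
                            mass = base + f * mF
                            if mass > target + tol:
                                break
                            if abs(mass - target) > tol:
                                continue
                            if c + h + n + o + s + f == 0:
                                continue
                            if (h + n + f) % 2 != 0:
                                continue
                            if c - (h + f) / 2 + n / 2 + 1 < 0:
                                continue
                            out.add(hill(c, h, n, o, s, f))
    return out


def hill(c, h, n, o, s, f) -> str:
    parts = []
    counts = {"C": c, "H": h, "N": n, "O": o, "S": s, "F": f}
    if c:
        order = ["C"] + (["H"] if h else []) + sorted(
            e for e in counts if e not in "CH" and counts[e])
    else:
        order = sorted(e for e in counts if counts[e])
    for e in order:
        k = counts[e]
        parts.append(f"{e}{k if k > 1 else ''}")
    return "".join(parts)


def ols_normal_equations(x, y):
    """Slope/intercept/R² from the raw normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    syy = sum(v * v for v in y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_tot = syy - sy * sy / n
    ss_res = sum((b - slope * a - intercept) ** 2 for a, b in zip(x, y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def prune_decision_bruteforce(mix_intensity: float,
                              own_single: float,
                              other_singles: dict[str, float],
                              ratio: float, floor: float) -> bool:
    """Keep/remove decision of the single-parent rule, written directly
    from the rule statement: remove when the feature is present in any
    other parent's single run, unless the mixture intensity is at least
    `ratio` times that, or it is present in the linked parent's own run."""
    for _q, q_int in other_singles.items():
        present_in_other = q_int > floor
        if not present_in_other:
            continue
        if mix_intensity >= ratio * q_int:
            continue
        if own_single > floor:
            continue
        return False
    return True
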