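"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most naive method available
(double loops, memoized recursion, fine-grid quadrature) and stay
independent of the library code paths they check.
"""

from functools import lru_cache

import numpy as np

HB_ELEMENTS = {"N", "O"}
WATERS = {"HOH", "WAT", "H2O", "DOD"}


def brute_hbond_pairs(model, ligand_selector, max_d, min_d):
    """All qualifying ligand-protein/water N/O pairs as serial-number pairs."""
    chain, res_name, res_num = ligand_selector
    lig = [a for a in model.atoms
           if a.chain == chain and a.res_name == res_name and a.res_num == res_num]
    lig_ids = {id(a) for a in lig}
    pairs = set()
    for la in lig:
        if la.element.upper() not in HB_ELEMENTS:
            continue
        for pa in model.atoms:
            if id(pa) in lig_ids or pa.element.upper() not in HB_ELEMENTS:
                continue
            if pa.is_hetero and pa.res_name not in WATERS:
                continue
            d = np.linalg.norm(np.subtract(la.coords, pa.coords))
            if min_d <= d <= max_d:
                pairs.add(frozenset((la.serial, pa.serial)))
    return pairs


def brute_contacts(model, ligand_res_name, cutoff, bridge_cutoff):
    """Direct + bridged contact keys with per-chain distances."""
    out = {}  # (res_num, patom, latom) -> {chain: (dist, kind)}
    rank = {"direct": 0, "magnesium": 1, "water": 2}
    chains = sorted({a.chain for a in model.atoms if a.res_name == ligand_res_name})
    for ch in chains:
        lig = [a for a in model.atoms
               if a.chain == ch and a.res_name == ligand_res_name]
        prot = [a for a in model.atoms if a.chain == ch and not a.is_hetero]
        bridges = [a for a in model.atoms
                   if a.chain == ch and a.is_hetero
                   and (a.res_name in WATERS or a.element.upper() == "MG")
                   and a.res_name != ligand_res_name]
        for pa in prot:
            for la in lig:
                d = float(np.linalg.norm(np.subtract(pa.coords, la.coords)))
                if d <= cutoff:
                    key = (pa.res_num, pa.name, la.name)
                    entry = out.setdefault(key, {})
                    old = entry.get(ch)
                    if old is None or (0, d) < (rank[old[1]], old[0]):
                        entry[ch] = (d, "direct")
        for br in bridges:
            kind = "magnesium" if br.element.upper() == "MG" else "water"
            for la in lig:
                if np.linalg.norm(np.subtract(br.coords, la.coords)) > bridge_cutoff:
                    continue
                for pa in prot:
                    d = float(np.linalg.norm(np.subtract(pa.coords, br.coords)))
                    if d > bridge_cutoff:
                        continue
                    key = (pa.res_num, pa.name, la.name)
                    entry = out.setdefault(key, {})
                    old = entry.get(ch)
                    if old is None or (rank[kind], d) < (rank[old[1]], old[0]):
                        entry[ch] = (d, kind)
    return out


def brute_metal_shell(model, metal_element, cutoff):
    """serial -> set of (coordinating serial, rounded distance)."""
    out = {}
    for m in model.atoms:
        if m.element.upper() != metal_element.upper():
            continue
        shell = set()
        for a in model.atoms:
            if a is m or a.element.upper() not in HB_ELEMENTS:
                continue
            d = float(np.linalg.norm(np.subtract(a.coords, m.coords)))
            if d <= cutoff:
                shell.add((a.serial, round(d, 9)))
        out[m.serial] = shell
    return out


def nw_score_recursive(a, b, match, mismatch, gap):
    """Memoized top-down global-alignment score."""
    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = float("-inf")
        if i > 0 and j > 0:
            best = f(i - 1, j - 1) + (match if a[i - 1] == b[j - 1] else mismatch)
        if i > 0:
            best = max(best, f(i - 1, j) + gap)
        if j > 0:
            best = max(best, f(i, j - 1) + gap)
        return best
    return f(len(a), len(b))


def brute_identity(row_a, row_b):
    num = den = 0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        den += 1
        if x == y:
            num += 1
    return 100.0 * num / den


def random_rigid_motions(rng, n):
    """n random (rotation matrix, translation) pairs."""
    from scipy.spatial.transform import Rotation
    rots = Rotation.random(n, random_state=rng).as_matrix()
    trans = rng.normal(0, 5, size=(n, 3))
    return rots, trans
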