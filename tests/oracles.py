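"""Independent oracles used by the test suite.

These deliberately avoid the package's own mass tables and rank-based AUC:
masses are summed from atomic monoisotopic masses over explicit elemental
formulas, AUCs are counted over all (positive, negative) pairs, and peak
matching is done by exhaustive search over assignments.
"""

from __future__ import annotations

from itertools import permutations
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

ATOMIC = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196, "Na": 22.9897692809}
ELECTRON = 0.00054857990907

# free-monosaccharide residues (monosaccharide minus water) as element counts
RESIDUE_FORMULAS: Dict[str, Dict[str, int]] = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neu5ac": {"C": 11, "H": 17, "N": 1, "O": 8},
    # methylamidated sialic acid: -OH of the carboxyl replaced by -NHCH3
    "neu5ac_ma": {"C": 12, "H": 20, "N": 2, "O": 7},
    "water": {"H": 2, "O": 1},
}


def formula_mass(formula: Mapping[str, int]) -> float:
    return sum(ATOMIC[el] * n for el, n in formula.items())


def elemental_glycan_mass(hex: int, hexnac: int, neu5ac: int, dhex: int, methylamidated: bool) -> float:
    """Neutral monoisotopic mass by summing atomic masses of the full formula."""
    total: Dict[str, int] = {}

    def add(formula: Mapping[str, int], times: int = 1) -> None:
        for el, n in formula.items():
            total[el] = total.get(el, 0) + n * times

    add(RESIDUE_FORMULAS["hex"], hex)
    add(RESIDUE_FORMULAS["hexnac"], hexnac)
    add(RESIDUE_FORMULAS["dhex"], dhex)
    add(RESIDUE_FORMULAS["neu5ac_ma" if methylamidated else "neu5ac"], neu5ac)
    add(RESIDUE_FORMULAS["water"])
    return formula_mass(total)


def elemental_sodiated_mz(hex: int, hexnac: int, neu5ac: int, dhex: int, methylamidated: bool = True) -> float:
    return elemental_glycan_mass(hex, hexnac, neu5ac, dhex, methylamidated) + ATOMIC["Na"] - ELECTRON


def pairwise_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by exhaustive counting over (positive, negative) pairs; ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_force_match(
    peak_mzs: Sequence[float],
    glycan_mzs: Sequence[float],
    tolerance: float,
) -> Dict[int, int]:
    """Greedy globally-nearest assignment glycan -> peak, recomputed naively.

    Enumerates all candidate (glycan, peak) pairs within tolerance, then
    assigns in order of ascending |error| (ties toward the lower-m/z glycan),
    skipping any glycan or peak already used.
    """
    cands: list[Tuple[float, float, int, int]] = []
    for gi, g in enumerate(glycan_mzs):
        for pi, p in enumerate(peak_mzs):
            if abs(p - g) <= tolerance:
                cands.append((abs(p - g), g, gi, pi))
    assign: Dict[int, int] = {}
    used_peaks: set[int] = set()
    for err, g, gi, pi in sorted(cands):
        if gi in assign or pi in used_peaks:
            continue
        assign[gi] = pi
        used_peaks.add(pi)
    return assign


def kruskal_h_by_hand(groups: Sequence[Sequence[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H from first principles (mid-ranks)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    srt = pooled[order]
    while i < n:
        j = i
        while j < n and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g, float)
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / correction if correction > 0 else float("nan")
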