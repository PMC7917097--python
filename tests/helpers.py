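"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the Viterbi
oracle enumerates every state path, the transmission oracle enumerates
every meiosis outcome, and the Mendelian checker tests trio consistency
directly from dosages.
"""

from __future__ import annotations

import itertools

import numpy as np

from founderhap.datamodel import MISSING, Pedigree


def viterbi_bruteforce(h, p1, p2, mismatch=1.0, crossover=10.0) -> float:
    """Minimum penalty over all 2^m state paths (vectorized enumeration)."""
    h = np.asarray(h)
    p = np.stack([np.asarray(p1), np.asarray(p2)], axis=1)
    m = len(h)
    if m == 0:
        return 0.0
    if m > 16:
        raise ValueError("exhaustive enumeration limited to 16 markers")
    paths = ((np.arange(1 << m, dtype=np.uint32)[:, None] >> np.arange(m)[None, :]) & 1).astype(
        np.int8
    )  # (2^m, m)
    alle = p[np.arange(m)[None, :], paths]  # allele emitted by each path
    mism = (h[None, :] != MISSING) & (alle != MISSING) & (h[None, :] != alle)
    switches = np.abs(np.diff(paths, axis=1)).sum(axis=1)
    costs = mism.sum(axis=1) * mismatch + switches * crossover
    return float(costs.min())


def mendelian_consistent(child, mother, father) -> np.ndarray:
    """Per-marker trio consistency of dosages (missing entries pass)."""

    def amin(x):
        return np.where(x == 2, 1, 0)

    def amax(x):
        return np.where(x == 0, 0, 1)

    lo = np.where(mother == MISSING, 0, amin(mother)) + np.where(
        father == MISSING, 0, amin(father)
    )
    hi = np.where(mother == MISSING, 1, amax(mother)) + np.where(
        father == MISSING, 1, amax(father)
    )
    return (child == MISSING) | ((child >= lo) & (child <= hi))


def toy_pedigree_6_meioses() -> Pedigree:
    """Two founders, two F1s and one F2: six meioses in total."""
    ids = ["A", "B", "C", "D", "E"]
    mothers = [None, None, "A", "A", "C"]
    fathers = [None, None, "B", "B", "D"]
    return Pedigree(ids, mothers, fathers)


def enumerate_gene_drop(ped: Pedigree, subset, focal_label: int) -> np.ndarray:
    """Exact null distribution of the focal-label frequency by enumerating
    every transmission outcome (one bit per meiosis with a known parent)."""
    order = list(ped.topo_order)
    meioses = []  # (individual row, slot, parent row)
    for i in order:
        if ped.founder_mask[i]:
            continue
        for slot, p in ((0, ped.mother_idx[i]), (1, ped.father_idx[i])):
            if p >= 0:
                meioses.append((i, slot, p))
    raw0 = 2 * ped.n_founders + 1
    sub_rows = [ped.row(s) for s in subset]
    freqs = []
    for bits in itertools.product((0, 1), repeat=len(meioses)):
        labels = {}
        for i in order:
            if ped.founder_mask[i]:
                labels[i] = list(ped.founder_labels(ped.ids[i]))
            else:
                labels[i] = [raw0, raw0]
        for (i, slot, p), b in zip(meioses, bits):
            labels[i][slot] = labels[p][b]
        count = sum(labels[i].count(focal_label) for i in sub_rows)
        freqs.append(count / (2 * len(sub_rows)))
    return np.asarray(freqs)
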