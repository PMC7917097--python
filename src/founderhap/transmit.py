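"""Random transmission (gene-dropping) test of founder-haplotype propagation.

At a focal locus, each replicate drops labels through the pedigree in
topological order: every child draws one of each available parent's two
current labels with probability 1/2 (an unknown parent contributes an
untraceable raw code).  The focal label's frequency among the evaluation
subset's 2N allele slots is recorded per replicate; one-sided p-values
compare the observed frequency (from the actual assignment) against the
null distribution with the +1/(n+1) finite-sample correction.  The
expected initial frequency of any one founder haplotype is 1/(2F) —
1/14 ~ 0.07 for seven founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FounderAssignment, Pedigree


@dataclass
class TransmissionTestResult:
    locus: str
    focal_label: int
    observed_freq: float
    null_freqs: np.ndarray
    p_increase: float
    p_decrease: float
    initial_expected_freq: float


def gene_drop_labels(
    ped: Pedigree,
    locus_founder_labels: dict | None = None,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
    n_founders: int | None = None,
) -> np.ndarray:
    """Drop founder labels through the pedigree.

    Returns an (n_reps, N, 2) int16 array of labels.  Founders keep their
    fixed labels (overridable via ``locus_founder_labels``: founder id ->
    (label, label)); unknown parents contribute the raw code 2F+1.
    """
    rng = rng or np.random.default_rng()
    F = n_founders if n_founders is not None else ped.n_founders
    raw0 = 2 * F + 1
    n = ped.n_individuals
    labels = np.empty((n_reps, n, 2), dtype=np.int16)
    for i in ped.topo_order:
        ind = ped.ids[i]
        if ped.founder_mask[i]:
            if locus_founder_labels and ind in locus_founder_labels:
                l1, l2 = locus_founder_labels[ind]
            else:
                l1, l2 = ped.founder_labels(ind)
            labels[:, i, 0] = l1
            labels[:, i, 1] = l2
            continue
        for slot, pidx in ((0, ped.mother_idx[i]), (1, ped.father_idx[i])):
            if pidx < 0:
                labels[:, i, slot] = raw0
            else:
                pick = rng.integers(0, 2, size=n_reps)
                labels[:, i, slot] = labels[np.arange(n_reps), pidx, pick]
    return labels


def transmission_test(
    ped: Pedigree,
    fa: FounderAssignment,
    locus: str,
    focal_label: int,
    subset=None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> TransmissionTestResult:
    """Gene-dropping test of non-random transmission of ``focal_label``.

    ``subset`` defaults to all pedigree individuals; untraced slots count
    in the denominator of the observed frequency.
    """
    F = fa.n_founders
    if not 1 <= focal_label <= 2 * F:
        raise ValueError(f"focal label {focal_label} is not a founder haplotype (1..{2 * F})")
    j = fa.markers.index_of(locus)
    founder_labels_here = {
        fid: tuple(int(x) for x in fa.labels[fa.row(fid), j, :]) for fid in ped.founder_ids
    }
    if not any(focal_label in labs for labs in founder_labels_here.values()):
        raise ValueError(f"focal label {focal_label} absent from founders at locus {locus!r}")
    subset = list(subset) if subset is not None else list(ped.ids)
    if not subset:
        raise ValueError("evaluation subset must not be empty")
    fa_rows = np.array([fa.row(ind) for ind in subset])
    ped_rows = np.array([ped.row(ind) for ind in subset])
    observed = float(np.mean(fa.labels[fa_rows, j, :] == focal_label))

    rng = np.random.default_rng(seed)
    dropped = gene_drop_labels(ped, founder_labels_here, n_reps, rng, F)
    null_freqs = (dropped[:, ped_rows, :] == focal_label).mean(axis=(1, 2))
    p_inc = (int(np.sum(null_freqs >= observed)) + 1) / (n_reps + 1)
    p_dec = (int(np.sum(null_freqs <= observed)) + 1) / (n_reps + 1)
    return TransmissionTestResult(
        locus, focal_label, observed, null_freqs, p_inc, p_dec, 1.0 / (2 * F)
    )


def propagation_export(
    ped: Pedigree,
    fa: FounderAssignment,
    locus: str,
    focal_label: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carrier table for pedigree-viewer rendering of a focal haplotype.

    Returns (carriers, parent_summary): per-individual copy counts and
    untraced flags, plus per-parent progeny carrier percentages.
    """
    j = fa.markers.index_of(locus)
    rows = []
    for ind in ped.ids:
        if ind in fa._row:
            labs = fa.labels[fa.row(ind), j, :]
            copies = int(np.sum(labs == focal_label))
            untraced = bool(np.any(labs > 2 * fa.n_founders))
        else:
            copies, untraced = 0, True
        rows.append(
            (ind, ped.mother_of(ind) or "", ped.father_of(ind) or "", copies, copies > 0, untraced)
        )
    carriers = pd.DataFrame(
        rows, columns=["individual", "mother", "father", "copies", "carries_focal", "untraced"]
    )
    carried = dict(zip(carriers["individual"], carriers["carries_focal"]))
    summary_rows = []
    for parent in ped.ids:
        progeny = ped.children_of(parent)
        if not progeny:
            continue
        pct = 100.0 * np.mean([carried.get(c, False) for c in progeny])
        summary_rows.append((parent, len(progeny), pct))
    parent_summary = pd.DataFrame(
        summary_rows, columns=["parent", "n_progeny", "pct_progeny_carrying"]
    )
    return carriers, parent_summary
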