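"""Tracing founder haplotypes forward through a pedigree.

Three steps, run per individual in topological (parents-first) order:

1. **parental-phase assignment** — for each chromosome, each of the two
   phase slots of a child is paired with the parent (female or male) whose
   genotype it correlates with more strongly (product-moment correlation
   of the 0/1 phase vector against the 0/1/2 parental dosage);
2. **haplotype-block inference** — the child's slot assigned to a parent
   is explained as a mosaic of that parent's two phases by a
   minimum-penalty Viterbi path over states {phase 1, phase 2}: each
   allele mismatch on the path costs ``mismatch_penalty`` (default 1) and
   each state switch (a recombination) costs ``crossover_penalty``
   (default 10);
3. **founder labeling** — founder ``f`` carries fixed labels ``2f-1`` and
   ``2f``; a child's label at a marker is the parent's label on the phase
   chosen by the Viterbi path.  Wherever the parental side is unassigned,
   the parent is unknown, or the parent itself is untraced, the entry
   keeps the raw biallelic code ``2F+1``/``2F+2`` of its own allele (the
   classic 15/16 for seven founders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    FounderAssignment,
    Pedigree,
    PhasedGenotypes,
)

logger = logging.getLogger(__name__)

SIDES = ("maternal", "paternal")


@dataclass
class TraceConfig:
    mismatch_penalty: float = 1.0
    crossover_penalty: float = 10.0
    correlation_min_informative: int = 10

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0 or self.crossover_penalty < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class ParentalPhaseAssignment:
    """Per-chromosome slot -> parent mapping for one individual.

    ``slot_of[chrom]`` maps side ("maternal"/"paternal") to the child phase
    slot (0/1) inherited from that parent, or None when unassigned;
    ``scores[chrom]`` holds the two pairing scores (identity, swapped).
    """

    slot_of: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)


@dataclass
class BlockPath:
    """Viterbi state path for one (individual, parental side, chromosome)."""

    states: np.ndarray  # per marker, 0 = parent phase 1, 1 = parent phase 2
    penalty: float
    breakpoints: np.ndarray  # marker indices t where states[t] != states[t-1]


def viterbi_blocks(h, p1, p2, cfg: TraceConfig | None = None) -> BlockPath:
    """Minimum-penalty path explaining child haplotype ``h`` as a mosaic
    of parent phases ``p1``/``p2`` (one chromosome).

    Emission cost ``mismatch_penalty`` where the path allele differs from
    the child's (both non-missing; missing costs 0), transition cost
    ``crossover_penalty`` per state switch.  Ties prefer no state change,
    then phase 1; markers where ``p1 == p2`` never influence switching.
    """
    cfg = cfg or TraceConfig()
    h = np.asarray(h)
    p = np.stack([np.asarray(p1), np.asarray(p2)], axis=1)  # (m, 2)
    m = h.shape[0]
    if m == 0:
        return BlockPath(np.empty(0, dtype=np.uint8), 0.0, np.empty(0, dtype=np.int64))
    emit = np.where(
        (h[:, None] != MISSING) & (p != MISSING) & (h[:, None] != p),
        cfg.mismatch_penalty,
        0.0,
    )  # (m, 2)
    cost = emit[0].copy()
    back = np.zeros((m, 2), dtype=np.uint8)
    cp = cfg.crossover_penalty
    for t in range(1, m):
        for s in (0, 1):
            stay, switch = cost[s], cost[1 - s] + cp
            back[t, s] = s if stay <= switch else 1 - s
        new0 = cost[back[t, 0]] + (cp if back[t, 0] != 0 else 0.0) + emit[t, 0]
        new1 = cost[back[t, 1]] + (cp if back[t, 1] != 1 else 0.0) + emit[t, 1]
        cost[0], cost[1] = new0, new1
    states = np.empty(m, dtype=np.uint8)
    states[-1] = 0 if cost[0] <= cost[1] else 1
    for t in range(m - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    penalty = float(cost[states[-1]])
    breakpoints = np.flatnonzero(np.diff(states.astype(np.int8)) != 0) + 1
    return BlockPath(states, penalty, breakpoints)


def _phase_parent_correlation(h_slot, parent_dosage):
    """Pearson correlation of a child phase (0/1) with a parent dosage
    (0/1/2) over jointly non-missing markers; (corr, n_informative).

    When either vector is constant on the overlap (correlation undefined,
    e.g. a fully homozygous parent) the score degenerates to mean allele
    agreement mapped onto [-1, 1], which extends the correlation
    continuously and keeps the spec'd homozygous-parent case decidable.
    """
    ok = (h_slot != MISSING) & (parent_dosage != MISSING)
    n = int(ok.sum())
    if n < 2:
        return 0.0, 0
    x = h_slot[ok].astype(float)
    y = parent_dosage[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float(1.0 - 2.0 * np.mean(np.abs(x - y / 2.0))), n
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)), n


def assign_parental_phases(
    child: PhasedGenotypes,
    mother_dosage: np.ndarray | None,
    father_dosage: np.ndarray | None,
    cfg: TraceConfig | None = None,
    individual: str | None = None,
) -> ParentalPhaseAssignment:
    """Pair the two phase slots of a child with its parents, per chromosome.

    ``mother_dosage``/``father_dosage`` are full-length dosage vectors (or
    None when the parent is not genotyped).  With both parents available
    the slot->parent pairing maximizing the sum of its two correlations is
    chosen; exact ties, or fewer informative markers than
    ``correlation_min_informative``, leave the chromosome unassigned.
    """
    cfg = cfg or TraceConfig()
    row = child.row(individual) if individual is not None else 0
    alle = child.alleles[row]
    out = ParentalPhaseAssignment()
    for chrom in child.markers.chromosomes:
        sl = child.markers.chrom_slice(chrom)
        h0, h1 = alle[sl, 0], alle[sl, 1]
        mo = mother_dosage[sl] if mother_dosage is not None else None
        fa = father_dosage[sl] if father_dosage is not None else None
        slot = {"maternal": None, "paternal": None}
        score_id = score_sw = np.nan
        if mo is not None and fa is not None:
            c0m, n0m = _phase_parent_correlation(h0, mo)
            c0f, n0f = _phase_parent_correlation(h0, fa)
            c1m, n1m = _phase_parent_correlation(h1, mo)
            c1f, n1f = _phase_parent_correlation(h1, fa)
            score_id = c0m + c1f  # slot0 -> mother, slot1 -> father
            score_sw = c0f + c1m
            n_inf = min(max(n0m, n0f), max(n1m, n1f))
            if n_inf >= cfg.correlation_min_informative and score_id != score_sw:
                if score_id > score_sw:
                    slot = {"maternal": 0, "paternal": 1}
                else:
                    slot = {"maternal": 1, "paternal": 0}
        elif mo is not None or fa is not None:
            side = "maternal" if mo is not None else "paternal"
            pd_ = mo if mo is not None else fa
            c0, n0 = _phase_parent_correlation(h0, pd_)
            c1, n1 = _phase_parent_correlation(h1, pd_)
            score_id, score_sw = c0, c1
            if max(n0, n1) >= cfg.correlation_min_informative and c0 != c1:
                slot[side] = 0 if c0 > c1 else 1
        out.slot_of[chrom] = slot
        out.scores[chrom] = (score_id, score_sw)
    return out


@dataclass
class TraceResult:
    assignment: FounderAssignment
    phase_assignments: dict  # individual -> ParentalPhaseAssignment
    paths: dict  # (individual, side, chrom) -> BlockPath

    def blocks_table(self) -> pd.DataFrame:
        """BED-like half-open marker-index blocks, 0-based within chromosome."""
        rows = []
        fa = self.assignment
        for (ind, side, chrom), path in sorted(self.paths.items()):
            sl = fa.markers.chrom_slice(chrom)
            slot = self.phase_assignments[ind].slot_of[chrom][side]
            labels = fa.labels[fa.row(ind), sl, slot]
            states = path.states
            start = 0
            for t in range(1, len(states) + 1):
                if t == len(states) or states[t] != states[start] or labels[t] != labels[start]:
                    rows.append(
                        (ind, side, chrom, start, t, int(states[start]) + 1, int(labels[start]))
                    )
                    start = t
        return pd.DataFrame(
            rows,
            columns=[
                "individual",
                "parent_side",
                "chrom",
                "start_marker",
                "end_marker",
                "parent_phase_state",
                "founder_label",
            ],
        )


def assign_founder_labels(
    ped: Pedigree,
    phased: PhasedGenotypes,
    assignments: dict,
    paths: dict,
    n_founders: int | None = None,
) -> FounderAssignment:
    """Step 4: propagate founder labels down the pedigree.

    ``assignments``/``paths`` are the step-2/step-3 results keyed as in
    :class:`TraceResult`.  Individuals are processed in topological order;
    founders carry their fixed labels everywhere.
    """
    markers = phased.markers
    F = n_founders if n_founders is not None else ped.n_founders
    raw0, raw1 = 2 * F + 1, 2 * F + 2
    n, m = phased.n_individuals, markers.n_markers
    for ind in phased.individuals:
        if ind not in ped._row:
            raise ValueError(f"individual {ind!r} missing from pedigree")
    labels = np.empty((n, m, 2), dtype=np.int16)
    # default: raw biallelic code of the carried allele (missing -> allele-0 code)
    alle = phased.alleles
    labels[:] = np.where(alle == 1, raw1, raw0)

    row_of = {ind: phased.row(ind) for ind in phased.individuals}
    for i in ped.topo_order:
        ind = ped.ids[i]
        if ind not in row_of:
            continue
        r = row_of[ind]
        if ped.founder_mask[i]:
            l1, l2 = ped.founder_labels(ind)
            labels[r, :, 0] = l1
            labels[r, :, 1] = l2
            continue
        assignment = assignments.get(ind)
        if assignment is None:
            continue
        for side, parent in (("maternal", ped.mother_of(ind)), ("paternal", ped.father_of(ind))):
            if parent is None or parent not in row_of:
                continue
            pr = row_of[parent]
            for chrom in markers.chromosomes:
                slot = assignment.slot_of[chrom][side]
                path = paths.get((ind, side, chrom))
                if slot is None or path is None:
                    continue
                sl = markers.chrom_slice(chrom)
                plabels = labels[pr, sl, :]  # parent labels, (mc, 2)
                chosen = plabels[np.arange(sl.stop - sl.start), path.states]
                keep_raw = chosen > 2 * F  # parent untraced there -> child raw code
                child_raw = labels[r, sl, slot]
                labels[r, sl, slot] = np.where(keep_raw, child_raw, chosen)
    return FounderAssignment(list(phased.individuals), markers, labels, F)


def trace_founder_haplotypes(
    ped: Pedigree,
    phased: PhasedGenotypes,
    cfg: TraceConfig | None = None,
) -> TraceResult:
    """Steps 2-4 of the tracing pipeline on phased genotypes."""
    cfg = cfg or TraceConfig()
    markers = phased.markers
    dosage = phased.dosage()
    assignments: dict = {}
    paths: dict = {}
    row_of = {ind: phased.row(ind) for ind in phased.individuals}
    for i in ped.topo_order:
        ind = ped.ids[i]
        if ind not in row_of or ped.founder_mask[i]:
            continue
        mo, fa = ped.mother_of(ind), ped.father_of(ind)
        mo_d = dosage[row_of[mo]] if mo in row_of else None
        fa_d = dosage[row_of[fa]] if fa in row_of else None
        assignment = assign_parental_phases(phased, mo_d, fa_d, cfg, individual=ind)
        assignments[ind] = assignment
        for side, parent in (("maternal", mo), ("paternal", fa)):
            if parent not in row_of:
                continue
            pr = row_of[parent]
            for chrom in markers.chromosomes:
                slot = assignment.slot_of[chrom][side]
                if slot is None:
                    continue
                sl = markers.chrom_slice(chrom)
                h = phased.alleles[row_of[ind], sl, slot]
                p1 = phased.alleles[pr, sl, 0]
                p2 = phased.alleles[pr, sl, 1]
                paths[(ind, side, chrom)] = viterbi_blocks(h, p1, p2, cfg)
    fa_obj = assign_founder_labels(ped, phased, assignments, paths, ped.n_founders)
    return TraceResult(fa_obj, assignments, paths)


def coverage_stat(fa: FounderAssignment, subset) -> float:
    """Fraction of (individual, marker, slot) entries over ``subset`` whose
    label is a founder haplotype (1..2F)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must not be empty")
    rows = np.array([fa.row(ind) for ind in subset])
    return float(np.mean(fa.labels[rows] <= 2 * fa.n_founders))


def haplotyping_accuracy(fa: FounderAssignment, ref: FounderAssignment) -> float:
    """Fraction of reference founder-labeled entries that ``fa`` labels
    identically, after alignment.

    Two alignment freedoms are maximized per chromosome before counting:
    the label pair within each founder (a founder's two haplotypes have no
    canonical order, so the 2^F per-chromosome label-pair swaps are
    searched exhaustively) and, nested inside, each individual's phase
    slot orientation (mirroring ``phasing_accuracy``).
    """
    if fa.labels.shape != ref.labels.shape:
        raise ValueError("assignment and reference must have the same shape")
    if fa.n_founders != ref.n_founders:
        raise ValueError("assignment and reference must share the founder set")
    F = fa.n_founders
    if F > 12:
        raise NotImplementedError("exhaustive founder alignment limited to F <= 12")
    ref_rows = np.array([ref.row(ind) for ind in fa.individuals])
    E, R = fa.labels, ref.labels[ref_rows]
    swap_map = np.arange(2 * F + 3, dtype=np.int16)
    for f in range(1, F + 1):
        swap_map[2 * f - 1], swap_map[2 * f] = 2 * f, 2 * f - 1
    matched = compared = 0
    founder_of = np.zeros(2 * F + 3, dtype=np.int64)  # label -> founder index+1, 0 for raw
    for f in range(1, F + 1):
        founder_of[2 * f - 1] = founder_of[2 * f] = f
    for chrom in fa.markers.chromosomes:
        sl = fa.markers.chrom_slice(chrom)
        e, r = E[:, sl, :], R[:, sl, :]
        valid = r <= 2 * F
        compared += int(valid.sum())
        e_sw = swap_map[e]
        best = None
        # per-entry agreement split by the founder owning the estimated label
        for orient, ev in (("id", (e, e_sw)), ("sw", (e[:, :, ::-1], e_sw[:, :, ::-1]))):
            a = (ev[0] == r) & valid  # agree as-is
            b = (ev[1] == r) & valid  # agree after founder-pair swap
            fo = founder_of[ev[0]]
            n_ind = e.shape[0]
            A = np.zeros((n_ind, F + 1), dtype=np.int64)
            B = np.zeros((n_ind, F + 1), dtype=np.int64)
            for i in range(n_ind):
                A[i] = np.bincount(fo[i][a[i]], minlength=F + 1)
                B[i] = np.bincount(fo[i][b[i]], minlength=F + 1)
            if orient == "id":
                A_id, B_id = A[:, 1:], B[:, 1:]
            else:
                A_sw, B_sw = A[:, 1:], B[:, 1:]
        best = 0
        for combo in range(1 << F):
            bits = np.array([(combo >> f) & 1 for f in range(F)], dtype=bool)
            tot_id = np.where(bits, B_id, A_id).sum(axis=1)
            tot_sw = np.where(bits, B_sw, A_sw).sum(axis=1)
            total = int(np.maximum(tot_id, tot_sw).sum())
            if total > best:
                best = total
        matched += best
    if compared == 0:
        raise ValueError("reference carries no founder labels to compare")
    return matched / compared
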