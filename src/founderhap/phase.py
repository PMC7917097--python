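"""Pedigree-aware phasing and sporadic-missing imputation.

``mendelian_phase`` resolves each diploid genotype into two phase slots
(slot 0 = maternal, slot 1 = paternal wherever trio logic decides) using,
in order:

1. trio/duo logic — a heterozygous site is phased whenever one parent is
   homozygous (the transmitted allele is forced), iterated to a fixpoint;
2. progeny-backed logic — a parent's heterozygous site is phased from the
   alleles it demonstrably transmitted to its offspring (offspring
   homozygous, or offspring heterozygous with the other parent
   homozygous), with a greedy per-chromosome orientation scan that tracks
   which parental slot each offspring currently carries;
3. a window linkage heuristic — remaining heterozygous sites take the
   orientation that agrees with the more frequent two-locus haplotype
   (over the already-phased population) with the nearest phased
   heterozygous site within ``window`` markers; ties are deterministic
   (allele 0 into slot 0).

Sporadic missing genotypes are imputed from parental genotypes when
forced, otherwise set to the marker's major-allele homozygote; the imputed
mask is reported.  Mendelian-inconsistent child sites are set missing and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, Pedigree, PhasedGenotypes

logger = logging.getLogger(__name__)

# per-entry resolution source codes
SRC_NONE = 0
SRC_HOM = 1
SRC_TRIO = 2
SRC_LINKAGE = 3
SRC_RANDOM = 4


@dataclass
class PhasingResult:
    phased: PhasedGenotypes
    source: np.ndarray  # (n, m) uint8, SRC_* codes
    imputed: np.ndarray  # (n, m) bool
    n_mendelian_conflicts: int

    @property
    def resolved_fraction(self) -> float:
        """Fraction of entries resolved by genotype or pedigree evidence."""
        return float(np.mean((self.source == SRC_HOM) | (self.source == SRC_TRIO)))


def _parent_dosage(D: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Dosage rows of each individual's parent (MISSING where unknown)."""
    out = np.full_like(D, MISSING)
    has = rows >= 0
    out[has] = D[rows[has]]
    return out


def _mendelian_conflicts(D, M, F) -> np.ndarray:
    """True where a child dosage is impossible given parent dosages."""

    def amin(P):
        return np.where(P == 2, 1, 0)

    def amax(P):
        return np.where(P == 0, 0, 1)

    lo = np.where(M == MISSING, 0, amin(M)) + np.where(F == MISSING, 0, amin(F))
    hi = np.where(M == MISSING, 1, amax(M)) + np.where(F == MISSING, 1, amax(F))
    return (D != MISSING) & ((D < lo) | (D > hi))


def mendelian_phase(
    geno: GenotypeMatrix,
    ped: Pedigree,
    window: int = 50,
    max_iter: int = 10,
) -> PhasingResult:
    markers = geno.markers
    n, m = geno.dosage.shape
    D = geno.dosage.copy()
    A = np.full((n, m, 2), MISSING, dtype=np.int8)
    source = np.zeros((n, m), dtype=np.uint8)
    imputed = np.zeros((n, m), dtype=bool)

    # align pedigree parent links to genotype rows
    geno_row = {ind: i for i, ind in enumerate(geno.individuals)}
    mo_row = np.full(n, -1, dtype=np.int64)
    fa_row = np.full(n, -1, dtype=np.int64)
    for i, ind in enumerate(geno.individuals):
        if ind not in ped._row:
            raise ValueError(f"genotyped individual {ind!r} absent from pedigree")
        mo, fa = ped.mother_of(ind), ped.father_of(ind)
        if mo in geno_row:
            mo_row[i] = geno_row[mo]
        if fa in geno_row:
            fa_row[i] = geno_row[fa]

    M = _parent_dosage(D, mo_row)
    F = _parent_dosage(D, fa_row)
    conflicts = _mendelian_conflicts(D, M, F)
    n_conflicts = int(conflicts.sum())
    if n_conflicts:
        logger.warning("set %d Mendelian-inconsistent child genotype(s) missing", n_conflicts)
        D[conflicts] = MISSING

    # --- pass 1: trio/duo logic + forced imputation, iterated to fixpoint ---
    for _ in range(max_iter):
        changed = False
        M = _parent_dosage(D, mo_row)
        F = _parent_dosage(D, fa_row)

        hom = ((D == 0) | (D == 2)) & (A[:, :, 0] == MISSING)
        if hom.any():
            a = (D[hom] // 2).astype(np.int8)
            A[hom, 0] = a
            A[hom, 1] = a
            source[hom] = SRC_HOM
            changed = True

        het = (D == 1) & (A[:, :, 0] == MISSING)
        mat_forced = np.where(M == 0, 0, np.where(M == 2, 1, MISSING))
        pat_forced = np.where(F == 0, 0, np.where(F == 2, 1, MISSING))
        use_m = het & (mat_forced != MISSING)
        if use_m.any():
            a = mat_forced[use_m].astype(np.int8)
            A[use_m, 0] = a
            A[use_m, 1] = 1 - a
            source[use_m] = SRC_TRIO
            changed = True
        use_f = het & (mat_forced == MISSING) & (pat_forced != MISSING)
        if use_f.any():
            a = pat_forced[use_f].astype(np.int8)
            A[use_f, 1] = a
            A[use_f, 0] = 1 - a
            source[use_f] = SRC_TRIO
            changed = True

        # forced imputation: both parents homozygous
        forced = (D == MISSING) & np.isin(M, (0, 2)) & np.isin(F, (0, 2))
        if forced.any():
            am = (M[forced] // 2).astype(np.int8)
            af = (F[forced] // 2).astype(np.int8)
            D[forced] = am + af
            A[forced, 0] = am
            A[forced, 1] = af
            source[forced] = SRC_TRIO
            imputed[forced] = True
            changed = True

        if not changed:
            break

    # --- pass 2: progeny-backed phasing of parents (founders in particular) ---
    children_of: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for c in range(n):
        if mo_row[c] >= 0:
            children_of[mo_row[c]].append((c, fa_row[c]))
        if fa_row[c] >= 0:
            children_of[fa_row[c]].append((c, mo_row[c]))

    for p in (geno_row[ped.ids[i]] for i in ped.topo_order if ped.ids[i] in geno_row):
        kids = children_of[p]
        if not kids:
            continue
        unresolved = (D[p] == 1) & (A[p, :, 0] == MISSING)
        if not unresolved.any():
            continue
        _progeny_phase(p, kids, D, A, source, markers)

    # --- pass 3: window linkage heuristic for leftover het sites ---
    _linkage_phase(D, A, source, markers, window)

    # --- final imputation: leftover missing -> major-allele homozygote ---
    still = D == MISSING
    if still.any():
        with np.errstate(invalid="ignore"):
            alt = np.where(
                (D != MISSING).sum(axis=0) > 0,
                (D * (D != MISSING)).sum(axis=0) / np.maximum((D != MISSING).sum(axis=0), 1) / 2.0,
                0.0,
            )
        major = (alt > 0.5).astype(np.int8)  # ties -> REF
        rows, cols = np.nonzero(still)
        a = major[cols]
        D[rows, cols] = 2 * a
        A[rows, cols, 0] = a
        A[rows, cols, 1] = a
        source[rows, cols] = SRC_HOM
        imputed[rows, cols] = True

    phased = PhasedGenotypes(list(geno.individuals), markers, A)
    return PhasingResult(phased, source, imputed, n_conflicts)


def _transmitted_alleles(p: int, kids, D, j: int) -> list:
    """(child_row, transmitted allele from parent p at marker j), where forced."""
    out = []
    for c, q in kids:
        dc = D[c, j]
        if dc == 0:
            out.append((c, 0))
        elif dc == 2:
            out.append((c, 1))
        elif dc == 1 and q >= 0:
            dq = D[q, j]
            if dq == 0:
                out.append((c, 1))
            elif dq == 2:
                out.append((c, 0))
    return out


def _progeny_phase(p, kids, D, A, source, markers) -> None:
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        slot_of: dict[int, int] = {}  # child row -> parent slot currently carried
        for j in range(sl.start, sl.stop):
            if D[p, j] != 1:
                continue
            trans = _transmitted_alleles(p, kids, D, j)
            if A[p, j, 0] != MISSING:
                a0, a1 = int(A[p, j, 0]), int(A[p, j, 1])
            else:
                if not trans:
                    continue
                # orientation vote among offspring with a tracked slot
                n0 = n1 = 0  # votes for (0|1) vs (1|0)
                for c, t in trans:
                    s = slot_of.get(c)
                    if s is None:
                        continue
                    pred = s  # under orientation (0|1), slot s carries allele s
                    if t == pred:
                        n0 += 1
                    else:
                        n1 += 1
                a0, a1 = (0, 1) if n0 >= n1 else (1, 0)
                A[p, j, 0], A[p, j, 1] = a0, a1
                source[p, j] = SRC_TRIO
            if a0 == a1:
                continue
            for c, t in trans:
                s = slot_of.get(c)
                carried = a0 if s == 0 else a1
                if s is None:
                    slot_of[c] = 0 if t == a0 else 1
                elif t != carried:
                    slot_of[c] = 1 - s  # offspring recombination (or error)


def _linkage_phase(D, A, source, markers, window: int) -> None:
    n = D.shape[0]
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        for j in range(sl.start, sl.stop):
            rows = np.nonzero((D[:, j] == 1) & (A[:, j, 0] == MISSING))[0]
            if rows.size == 0:
                continue
            for i in rows:
                jn = _nearest_phased_het(A, D, i, j, sl, window)
                if jn < 0:
                    A[i, j, 0], A[i, j, 1] = 0, 1  # deterministic slot order
                    source[i, j] = SRC_RANDOM
                    continue
                x0 = int(A[i, jn, 0])
                # two-locus haplotype counts over phased entries
                ok = (A[:, jn, 0] != MISSING) & (A[:, j, 0] != MISSING)
                h_prev = A[ok][:, jn, :].ravel()
                h_here = A[ok][:, j, :].ravel()
                c0 = int(np.sum((h_prev == x0) & (h_here == 0)))
                c1 = int(np.sum((h_prev == x0) & (h_here == 1)))
                y0 = 0 if c0 >= c1 else 1
                A[i, j, 0], A[i, j, 1] = y0, 1 - y0
                source[i, j] = SRC_LINKAGE


def _nearest_phased_het(A, D, i, j, sl, window) -> int:
    for off in range(1, window + 1):
        for jn in (j - off, j + off):
            if sl.start <= jn < sl.stop and D[i, jn] == 1 and A[i, jn, 0] != MISSING:
                return jn
    return -1


def phasing_accuracy(est: PhasedGenotypes, ref: PhasedGenotypes) -> float:
    """Allele-wise phasing accuracy of ``est`` against reference phases.

    Per individual and chromosome the estimated phase pair is aligned to
    the reference by whichever of the two global slot orientations matches
    more alleles; accuracy is matched/compared alleles (both non-missing)
    aggregated over all individuals and chromosomes.  Invariant to a global
    slot swap of either argument.
    """
    if est.markers != ref.markers:
        raise ValueError("estimate and reference must share the same marker map")
    if set(est.individuals) != set(ref.individuals):
        raise ValueError("estimate and reference must cover the same individuals")
    ref_rows = np.array([ref.row(ind) for ind in est.individuals])
    E, R = est.alleles, ref.alleles[ref_rows]
    matched = compared = 0
    for chrom in est.markers.chromosomes:
        sl = est.markers.chrom_slice(chrom)
        e, r = E[:, sl, :], R[:, sl, :]
        ok_id = (e != MISSING) & (r != MISSING)
        ok_sw = (e != MISSING) & (r[:, :, ::-1] != MISSING)
        m_id = ((e == r) & ok_id).sum(axis=(1, 2))
        m_sw = ((e == r[:, :, ::-1]) & ok_sw).sum(axis=(1, 2))
        n_id = ok_id.sum(axis=(1, 2))
        n_sw = ok_sw.sum(axis=(1, 2))
        use_sw = m_sw > m_id
        matched += int(np.where(use_sw, m_sw, m_id).sum())
        compared += int(np.where(use_sw, n_sw, n_id).sum())
    if compared == 0:
        raise ValueError("no comparable alleles between estimate and reference")
    return matched / compared
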