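"""Forward simulation of pedigreed diploid genomes with founder-origin truth.

The generator emulates the structure of a clonally-propagated fruit-tree
breeding program: a handful of diploid founders, multi-generation crosses
among their descendants ("parental" material) and large full-sib F1
families ("breeding" material).  Meiosis follows the Haldane model: the
crossover count per chromosome is Poisson(length_cM / 100) and crossover
positions are uniform in map distance (no interference).  Genotyping error
is a symmetric per-allele flip; missingness masks dosage entries i.i.d.

Every simulated allele carries a truth label: founder ``f`` owns labels
``2f-1``/``2f``; haplotypes entering through an unknown parent are drawn
like founder haplotypes but keep the raw biallelic codes ``2F+1``/``2F+2``
(untraceable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    MISSING,
    FounderAssignment,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
)

Cross = tuple[str, str | None, str | None]  # (child, mother, father)


@dataclass
class TraitArch:
    """One simulated trait: QTL with per-founder-haplotype effects.

    ``qtl`` is a list of ``(marker_index, effects, dominant)`` where
    ``effects`` maps founder haplotype label 1..2F (1-based) to its effect;
    additive QTL contribute the sum of the two carried labels' effects,
    dominant QTL the maximum.  Untraceable labels contribute 0.
    """

    name: str
    qtl: list = field(default_factory=list)
    heritability: float = 0.6
    years: list = field(default_factory=lambda: [1])
    year_effect_sd: float = 0.0


@dataclass
class SimConfig:
    n_founders: int = 7
    chromosomes: list = field(default_factory=lambda: [(70, 80.0)] * 17)
    allele_freq_range: tuple = (0.1, 0.9)
    pedigree: list | None = None  # list of Cross; None -> apple_like_design
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    cM_per_Mb: float = 2.5
    traits: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.allele_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("allele_freq_range must be within [0, 1]")
        for n_mark, length in self.chromosomes:
            if n_mark < 1 or length < 0:
                raise ValueError("chromosomes need >=1 marker and length >= 0")
        for tr in self.traits:
            if not 0.0 < tr.heritability <= 1.0:
                raise ValueError(f"trait {tr.name!r}: heritability must be in (0, 1]")


@dataclass
class TruthSet:
    """Ground truth of a simulated population."""

    pedigree: Pedigree
    phased: PhasedGenotypes  # error-free true phases
    assignment: FounderAssignment  # true founder labels
    observed: GenotypeMatrix  # dosages after error + missingness
    crossovers: dict  # (child, side, chrom) -> cM positions (ndarray)
    breeding_values: dict = field(default_factory=dict)  # trait -> ndarray
    year_effects: dict = field(default_factory=dict)  # trait -> {year: shift}


def founder_names(n_founders: int) -> list:
    return [f"F{f}" for f in range(1, n_founders + 1)]


def three_generation_design(
    n_founders: int = 7,
    gen1_crosses: int = 7,
    gen1_size: int = 6,
    gen2_crosses: int = 8,
    gen2_size: int = 5,
) -> list:
    """Founders -> F1 crosses among founders -> crosses among the F1s.

    Deterministic round-robin mating; with the defaults this yields
    7 + 42 + 40 = 89 individuals and every founder has >= 12 children,
    enough for progeny-backed phasing.
    """
    fids = founder_names(n_founders)
    design: list[Cross] = [(f, None, None) for f in fids]
    gen1_parents: list[list[str]] = []
    for k in range(gen1_crosses):
        mother = fids[k % n_founders]
        father = fids[(k + 1) % n_founders]
        fam = [f"G1_{k + 1}_{j + 1}" for j in range(gen1_size)]
        design.extend((c, mother, father) for c in fam)
        gen1_parents.append(fam)
    for k in range(gen2_crosses):
        fam_a = gen1_parents[k % gen1_crosses]
        fam_b = gen1_parents[(k + 2) % gen1_crosses]
        mother = fam_a[k % gen1_size]
        father = fam_b[(k + 1) % gen1_size]
        design.extend(
            (f"G2_{k + 1}_{j + 1}", mother, father) for j in range(gen2_size)
        )
    return design


def breeding_design(
    n_founders: int = 7,
    n_families: int = 16,
    family_size: int = 25,
) -> list:
    """Three-generation parental base plus full-sib breeding families.

    The 16 families are crossed among 17 parental individuals (a chain of
    pairs), mirroring the cross-validation unit of a breeding program.
    """
    design = three_generation_design(n_founders)
    g1 = [c for c, _, _ in design if c.startswith("G1")]
    g2 = [c for c, _, _ in design if c.startswith("G2")]
    parents = (g2[::4] + g1[::5])[: n_families + 1]
    if len(parents) < n_families + 1:
        raise ValueError("parental base too small for the requested family count")
    for k in range(n_families):
        mo, fa = parents[k], parents[k + 1]
        design.extend((f"B{k + 1}_{j + 1}", mo, fa) for j in range(family_size))
    return design


def apple_like_design(n_founders: int = 7) -> list:
    """Pedigree mirroring the published cohort sizes.

    185 "parental" individuals (the founders plus two derived generations)
    and 659 F1s in 16 full-sib families crossed among 17 parental
    individuals: 844 in total.
    """
    fids = founder_names(n_founders)
    design: list[Cross] = [(f, None, None) for f in fids]

    # generation P1: 12 crosses among founders, 6 offspring each = 72
    p1: list[str] = []
    crosses = [(fids[i % n_founders], fids[(i + 1) % n_founders]) for i in range(7)]
    crosses += [(fids[i], fids[(i + 2) % n_founders]) for i in range(5)]
    for k, (mo, fa) in enumerate(crosses):
        for j in range(6):
            cid = f"P1_{k + 1}_{j + 1}"
            design.append((cid, mo, fa))
            p1.append(cid)

    # generation P2: 18 crosses among P1 individuals -> 106 offspring
    p2: list[str] = []
    sizes = [6] * 17 + [4]
    for k, sz in enumerate(sizes):
        mo = p1[(5 * k) % len(p1)]
        fa = p1[(5 * k + 7) % len(p1)]
        for j in range(sz):
            cid = f"P2_{k + 1}_{j + 1}"
            design.append((cid, mo, fa))
            p2.append(cid)
    assert len(design) == 185

    # breeding population: 16 full-sib families from 17 parental individuals
    parents17 = p2[::6][:9] + p1[::9][:8]
    assert len(set(parents17)) == 17
    fam_sizes = [42] * 3 + [41] * 13  # = 659
    for k, sz in enumerate(fam_sizes):
        mo, fa = parents17[k], parents17[k + 1]
        design.extend((f"B{k + 1}_{j + 1}", mo, fa) for j in range(sz))
    assert len(design) == 844
    return design


def breeding_family_of(design: list) -> dict:
    """Map breeding-population individual -> full-sib family id."""
    fam = {}
    for child, mo, fa in design:
        if child.startswith("B"):
            fam[child] = child.split("_")[0]
    return fam


def build_marker_map(cfg: SimConfig) -> MarkerMap:
    ids, chroms, bps, cms = [], [], [], []
    for c, (n_mark, length) in enumerate(cfg.chromosomes, start=1):
        if n_mark == 1:
            pos_cm = np.array([length / 2.0])
        else:
            pos_cm = np.linspace(0.0, length, n_mark)
        bp = np.round(pos_cm * 1e6 / cfg.cM_per_Mb).astype(np.int64) + 1
        # enforce strictly increasing bp
        for i in range(1, n_mark):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        ids.extend(f"S{c}_{i + 1}" for i in range(n_mark))
        chroms.extend([str(c)] * n_mark)
        bps.extend(bp.tolist())
        cms.extend(pos_cm.tolist())
    return MarkerMap(ids, chroms, bps, cms)


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw the founder haplotypes and per-marker allele frequencies.

    Returns ``(phased, label_map, freqs, markers)`` where ``label_map``
    maps founder id -> (label1, label2) and ``freqs`` are the per-marker
    allele-1 frequencies used for the draws.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    markers = build_marker_map(cfg)
    m = markers.n_markers
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    fids = founder_names(cfg.n_founders)
    alleles = (rng.random((cfg.n_founders, m, 2)) < freqs[None, :, None]).astype(np.int8)
    phased = PhasedGenotypes(fids, markers, alleles)
    label_map = {fid: (2 * f + 1, 2 * f + 2) for f, fid in enumerate(fids)}
    return phased, label_map, freqs, markers


def _meiosis(alleles, labels, markers: MarkerMap, rng):
    """One gamete from a parent: returns (gamete_alleles, gamete_labels, xovers)."""
    m = markers.n_markers
    gam_a = np.empty(m, dtype=np.int8)
    gam_l = np.empty(m, dtype=np.int16)
    xovers = {}
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        cm = markers.position_cM[sl]
        length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        n_x = rng.poisson(length / 100.0) if length > 0 else 0
        pos = np.sort(rng.uniform(cm[0], cm[0] + length, size=n_x)) if n_x else np.empty(0)
        start = int(rng.integers(2))
        state = (start + np.searchsorted(pos, cm, side="left")) % 2
        gam_a[sl] = alleles[sl, :][np.arange(len(cm)), state]
        gam_l[sl] = labels[sl, :][np.arange(len(cm)), state]
        xovers[chrom] = pos
    return gam_a, gam_l, xovers


def gene_drop_genomes(cfg: SimConfig, ped: Pedigree | None = None) -> TruthSet:
    """Drop founder genomes through the pedigree and record the truth."""
    rng = np.random.default_rng(cfg.seed)
    design = cfg.pedigree if cfg.pedigree is not None else apple_like_design(cfg.n_founders)
    if ped is None:
        ped = Pedigree(
            [c for c, _, _ in design],
            [m for _, m, _ in design],
            [f for _, _, f in design],
        )
    if ped.n_founders != cfg.n_founders:
        raise ValueError(
            f"pedigree has {ped.n_founders} designated founders, config says {cfg.n_founders}"
        )
    fphased, label_map, freqs, markers = simulate_founders(cfg, rng)
    n, m = ped.n_individuals, markers.n_markers
    raw0, raw1 = 2 * cfg.n_founders + 1, 2 * cfg.n_founders + 2

    alleles = np.empty((n, m, 2), dtype=np.int8)
    labels = np.empty((n, m, 2), dtype=np.int16)
    crossovers: dict = {}

    for i in ped.topo_order:
        ind = ped.ids[i]
        if ped.founder_mask[i]:
            # founders map positionally onto the simulated founder haplotypes
            f = ped.founder_index[ind]
            alleles[i] = fphased.alleles[f]
            labels[i, :, 0] = 2 * f + 1
            labels[i, :, 1] = 2 * f + 2
            continue
        for side, pidx in (("maternal", ped.mother_idx[i]), ("paternal", ped.father_idx[i])):
            slot = 0 if side == "maternal" else 1
            if pidx < 0:
                # unknown parent: novel external haplotype, untraceable labels
                hap = (rng.random(m) < freqs).astype(np.int8)
                alleles[i, :, slot] = hap
                labels[i, :, slot] = np.where(hap == 0, raw0, raw1)
                continue
            gam_a, gam_l, xov = _meiosis(alleles[pidx], labels[pidx], markers, rng)
            alleles[i, :, slot] = gam_a
            labels[i, :, slot] = gam_l
            for chrom, pos in xov.items():
                crossovers[(ind, side, chrom)] = pos

    phased = PhasedGenotypes(list(ped.ids), markers, alleles.copy())
    assignment = FounderAssignment(list(ped.ids), markers, labels, cfg.n_founders)

    obs_alleles = alleles.copy()
    if cfg.genotype_error_rate > 0:
        flip = rng.random(obs_alleles.shape) < cfg.genotype_error_rate
        obs_alleles[flip] = 1 - obs_alleles[flip]
    dosage = obs_alleles.sum(axis=2).astype(np.int8)
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = MISSING
    observed = GenotypeMatrix(list(ped.ids), markers, dosage)

    return TruthSet(ped, phased, assignment, observed, crossovers)


def genetic_values(trait: TraitArch, truth: TruthSet) -> np.ndarray:
    """True genetic value per pedigree individual for one trait."""
    n_f = truth.assignment.n_founders
    n = len(truth.pedigree.ids)
    g = np.zeros(n)
    for marker_idx, effects, dominant in trait.qtl:
        eff = np.zeros(2 * n_f + 3)
        eff[1 : 2 * n_f + 1] = np.asarray(effects, dtype=float)
        lab = truth.assignment.labels[:, marker_idx, :]  # (n, 2)
        vals = eff[lab]
        g += vals.max(axis=1) if dominant else vals.sum(axis=1)
    return g


def simulate_phenotypes(cfg: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None):
    """Multi-year phenotype records for every trait in the config."""
    import pandas as pd

    from .datamodel import PhenotypeTable

    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    rows = []
    for trait in cfg.traits:
        g = genetic_values(trait, truth)
        truth.breeding_values[trait.name] = g
        var_g = float(np.var(g))
        h2 = trait.heritability
        var_e = var_g * (1.0 - h2) / h2
        shifts = {y: rng.normal(0.0, trait.year_effect_sd) if trait.year_effect_sd > 0 else 0.0
                  for y in trait.years}
        truth.year_effects[trait.name] = shifts
        for y in trait.years:
            noise = rng.normal(0.0, np.sqrt(var_e), size=len(g)) if var_e > 0 else np.zeros(len(g))
            for i, ind in enumerate(truth.pedigree.ids):
                rows.append((ind, trait.name, y, g[i] + shifts[y] + noise[i]))
    return PhenotypeTable(pd.DataFrame(rows, columns=["individual", "trait", "year", "value"]))


def simulate_population(cfg: SimConfig):
    """Convenience driver: pedigree + genomes + phenotypes.

    Returns ``(truth, phenotypes)``; ``phenotypes`` is None when the config
    declares no traits.
    """
    truth = gene_drop_genomes(cfg)
    pheno = simulate_phenotypes(cfg, truth) if cfg.traits else None
    return truth, pheno
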