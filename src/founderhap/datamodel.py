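"""Core domain types for pedigreed SNP data and founder-haplotype labels.

Conventions used throughout the package:

* allele coding: REF -> 0, ALT -> 1; dosage is the ALT count in {0, 1, 2};
  ``MISSING`` (-1) marks missing alleles/dosages.
* marker order: within a chromosome markers are sorted by ascending
  base-pair position (1-based, VCF convention), ties broken by marker id.
* founder labels: founder ``f`` (1-based, in pedigree founder order) owns
  labels ``2f-1`` and ``2f`` for its two haplotypes.  Alleles that cannot be
  traced to a founder keep raw biallelic codes ``2F+1`` (allele 0) and
  ``2F+2`` (allele 1); for seven founders these are the classic 15/16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING: int = -1


class MarkerMap:
    """Ordered marker map: id, chromosome and 1-based bp position.

    Markers are sorted on construction by (chromosome, position_bp,
    marker_id); chromosomes keep their order of first appearance in the
    input, so a map built chromosome-by-chromosome round-trips unchanged.
    """

    def __init__(
        self,
        marker_id: Sequence[str],
        chromosome: Sequence,
        position_bp: Sequence[int],
        position_cM: Sequence[float] | None = None,
    ) -> None:
        marker_id = np.asarray(marker_id, dtype=object)
        chromosome = np.asarray(chromosome, dtype=object)
        position_bp = np.asarray(position_bp, dtype=np.int64)
        if not (len(marker_id) == len(chromosome) == len(position_bp)):
            raise ValueError("marker_id, chromosome and position_bp must have equal length")
        if len(np.unique(marker_id)) != len(marker_id):
            raise ValueError("marker ids must be unique")
        if np.any(position_bp < 0):
            raise ValueError("bp positions must be non-negative")
        if position_cM is not None:
            position_cM = np.asarray(position_cM, dtype=float)
            if len(position_cM) != len(marker_id):
                raise ValueError("position_cM length mismatch")
            if np.any(position_cM < 0):
                raise ValueError("cM positions must be non-negative")

        # chromosome order = first appearance in the input
        chrom_order: dict = {}
        for c in chromosome:
            if c not in chrom_order:
                chrom_order[c] = len(chrom_order)
        key = sorted(
            range(len(marker_id)),
            key=lambda i: (chrom_order[chromosome[i]], position_bp[i], str(marker_id[i])),
        )
        order = np.asarray(key, dtype=np.intp)
        self.marker_id = marker_id[order]
        self.chromosome = chromosome[order]
        self.position_bp = position_bp[order]
        self.position_cM = position_cM[order] if position_cM is not None else None
        self.chromosomes: list = list(chrom_order)
        self._index = {m: i for i, m in enumerate(self.marker_id)}
        self._slices = {}
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chromosome == c)
            self._slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def __len__(self) -> int:
        return self.n_markers

    def chrom_slice(self, chrom) -> slice:
        """Contiguous slice of marker indices belonging to ``chrom``."""
        return self._slices[chrom]

    def index_of(self, marker: str) -> int:
        return self._index[marker]

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker": self.marker_id,
            "chrom": self.chromosome,
            "pos_bp": self.position_bp,
        }
        if self.position_cM is not None:
            d["pos_cM"] = self.position_cM
        return pd.DataFrame(d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        same = (
            np.array_equal(self.marker_id, other.marker_id)
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position_bp, other.position_bp)
        )
        if not same:
            return False
        if (self.position_cM is None) != (other.position_cM is None):
            return False
        if self.position_cM is not None:
            return bool(np.allclose(self.position_cM, other.position_cM))
        return True


def _check_individuals(individuals: Sequence[str]) -> list:
    individuals = list(individuals)
    if len(set(individuals)) != len(individuals):
        raise ValueError("individual ids must be unique")
    return individuals


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (individuals x markers), values in {0,1,2,-1}."""

    individuals: list
    markers: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = _check_individuals(self.individuals)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), self.markers.n_markers):
            raise ValueError("dosage shape does not match individuals x markers")
        legal = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not legal.all():
            raise ValueError("dosage values must be in {0,1,2} or missing (-1)")
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, individual: str) -> int:
        return self._row[individual]

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.dosage == MISSING))


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes: individuals x markers x 2 phase slots."""

    individuals: list
    markers: MarkerMap
    alleles: np.ndarray
    phase_known: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individuals = _check_individuals(self.individuals)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.individuals), self.markers.n_markers, 2):
            raise ValueError("alleles shape does not match individuals x markers x 2")
        if not np.isin(self.alleles, (MISSING, 0, 1)).all():
            raise ValueError("alleles must be in {0,1} or missing (-1)")
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, individual: str) -> int:
        return self._row[individual]

    def dosage(self) -> np.ndarray:
        """ALT dosage; missing wherever either allele is missing."""
        a = self.alleles
        d = (a[:, :, 0] + a[:, :, 1]).astype(np.int8)
        d[(a[:, :, 0] == MISSING) | (a[:, :, 1] == MISSING)] = MISSING
        return d

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(list(self.individuals), self.markers, self.dosage())

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.alleles == MISSING))


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Pedigree DAG of individuals with mother/father links.

    ``mother_idx``/``father_idx`` hold row indices into ``ids`` (-1 for
    unknown).  ``founder_ids`` are the designated founders in their input
    order; founder ``f`` (1-based position in that order) owns haplotype
    labels ``2f-1`` and ``2f``.
    """

    def __init__(
        self,
        ids: Sequence[str],
        mothers: Sequence[str | None],
        fathers: Sequence[str | None],
        founders: Iterable[str] | None = None,
    ) -> None:
        self.ids = _check_individuals(ids)
        self._row = {ind: i for i, ind in enumerate(self.ids)}
        n = len(self.ids)

        def parent_index(parents):
            out = np.full(n, -1, dtype=np.int64)
            for i, p in enumerate(parents):
                if p is None or p == "" or p == "0":
                    continue
                if p not in self._row:
                    raise PedigreeError(
                        f"individual {self.ids[i]!r} references absent parent id {p!r}"
                    )
                out[i] = self._row[p]
            return out

        if not (len(mothers) == len(fathers) == n):
            raise PedigreeError("ids, mothers and fathers must have equal length")
        self.mother_idx = parent_index(mothers)
        self.father_idx = parent_index(fathers)

        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for p in (self.mother_idx[i], self.father_idx[i]):
                if p >= 0:
                    g.add_edge(int(p), i)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            names = [self.ids[u] for u, _ in cycle]
            raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(names)}")
        # deterministic topological order: by pedigree depth (founders and
        # other parentless individuals first), ties broken by input position
        depth = np.zeros(n, dtype=np.int64)
        for i in nx.topological_sort(g):
            parents = [p for p in (self.mother_idx[i], self.father_idx[i]) if p >= 0]
            depth[i] = 1 + max(depth[p] for p in parents) if parents else 0
        order = sorted(range(n), key=lambda i: (depth[i], i))
        self.topo_order = np.asarray(order, dtype=np.int64)

        parentless = {self.ids[i] for i in range(n) if self.mother_idx[i] < 0 and self.father_idx[i] < 0}
        if founders is None:
            founder_ids = [i for i in self.ids if i in parentless]
        else:
            founder_ids = list(founders)
            for fid in founder_ids:
                if fid not in self._row:
                    raise PedigreeError(f"designated founder {fid!r} not in pedigree")
                if fid not in parentless:
                    raise PedigreeError(f"designated founder {fid!r} has a known parent")
        self.founder_ids = founder_ids
        self.founder_index = {fid: f for f, fid in enumerate(founder_ids)}  # 0-based
        mask = np.zeros(n, dtype=bool)
        for fid in founder_ids:
            mask[self._row[fid]] = True
        self.founder_mask = mask

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def row(self, individual: str) -> int:
        return self._row[individual]

    def mother_of(self, individual: str) -> str | None:
        p = self.mother_idx[self._row[individual]]
        return self.ids[p] if p >= 0 else None

    def father_of(self, individual: str) -> str | None:
        p = self.father_idx[self._row[individual]]
        return self.ids[p] if p >= 0 else None

    def children_of(self, individual: str) -> list:
        i = self._row[individual]
        hit = (self.mother_idx == i) | (self.father_idx == i)
        return [self.ids[j] for j in np.flatnonzero(hit)]

    def founder_labels(self, founder_id: str) -> tuple[int, int]:
        """The two haplotype labels owned by a designated founder (1-based)."""
        f = self.founder_index[founder_id] + 1
        return 2 * f - 1, 2 * f


@dataclass
class FounderAssignment:
    """Founder-haplotype labels per individual x marker x phase slot.

    Legal labels are 1..2F (founder haplotypes) plus the raw biallelic
    fallback codes 2F+1 (allele 0) and 2F+2 (allele 1).
    """

    individuals: list
    markers: MarkerMap
    labels: np.ndarray
    n_founders: int

    def __post_init__(self) -> None:
        self.individuals = _check_individuals(self.individuals)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != (len(self.individuals), self.markers.n_markers, 2):
            raise ValueError("labels shape does not match individuals x markers x 2")
        hi = 2 * self.n_founders + 2
        if self.labels.min() < 1 or self.labels.max() > hi:
            raise ValueError(f"labels must lie in 1..{hi}")
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def raw_codes(self) -> tuple[int, int]:
        """Raw biallelic fallback codes (allele 0, allele 1); 15/16 for F=7."""
        return 2 * self.n_founders + 1, 2 * self.n_founders + 2

    def row(self, individual: str) -> int:
        return self._row[individual]

    def is_traced(self) -> np.ndarray:
        """Boolean mask of entries carrying a founder label (not raw codes)."""
        return self.labels <= 2 * self.n_founders


class PhenotypeTable:
    """Long-format phenotype records: (individual, trait, year, value)."""

    COLUMNS = ("individual", "trait", "year", "value")

    def __init__(self, records: pd.DataFrame) -> None:
        df = pd.DataFrame(records, columns=list(self.COLUMNS)).copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        if df.duplicated(subset=["individual", "trait", "year"]).any():
            raise ValueError("(individual, trait, year) keys must be unique")
        self.df = df.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique())

    def trait_records(self, trait: str) -> pd.DataFrame:
        sub = self.df[self.df["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} has no records")
        return sub.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)
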