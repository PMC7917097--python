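"""Design matrices, the genomic relationship matrix, and LD summaries.

SNP features are ALT-dosage columns (0/1/2); founder-haplotype features
are per-(marker, label) copy counts (0/1/2) whose columns sum to 2 per
individual and marker before MAF filtering.  The GRM is VanRaden method 1
computed from SNP dosages.  LD decay is summarized by pairwise r^2 against
bp distance with a Gaussian-kernel local-constant (Nadaraya-Watson)
smoother, plus the 95th percentile of r^2 over random unlinked
(inter-chromosome) marker pairs as a significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, FounderAssignment, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    individuals: list
    values: np.ndarray  # (n, p) float64
    meta: pd.DataFrame  # columns: marker, kind, label (label NaN for snp-dosage)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_keys(self) -> list:
        return [
            (m, k, None if pd.isna(l) else int(l))
            for m, k, l in zip(self.meta["marker"], self.meta["kind"], self.meta["label"])
        ]


def snp_design(geno: GenotypeMatrix, maf_min: float = 0.01) -> DesignMatrix:
    """SNP dosage design; columns with MAF strictly below ``maf_min`` are
    removed and missing dosages are column-mean imputed."""
    D = geno.dosage.astype(float)
    D[geno.dosage == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(D, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(D))
    D[idx] = col_mean[idx[1]]
    p_hat = col_mean / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("all SNP columns removed by the MAF filter")
    meta = pd.DataFrame(
        {
            "marker": geno.markers.marker_id[keep],
            "kind": "snp-dosage",
            "label": np.nan,
        }
    )
    return DesignMatrix(list(geno.individuals), D[:, keep], meta)


def haplotype_design(fa: FounderAssignment, maf_min: float = 0.0001) -> DesignMatrix:
    """Founder-haplotype design: per marker, one copy-count column per
    label observed there (founder labels and raw codes alike); columns
    with frequency strictly below ``maf_min`` are dropped."""
    n, m, _ = fa.labels.shape
    hi = 2 * fa.n_founders + 2
    cols, markers_out, labels_out = [], [], []
    for j in range(m):
        counts = np.bincount(fa.labels[:, j, :].ravel(), minlength=hi + 1)
        for lab in np.nonzero(counts)[0]:
            freq = counts[lab] / (2.0 * n)
            if freq < maf_min:
                continue
            col = (fa.labels[:, j, :] == lab).sum(axis=1).astype(float)
            cols.append(col)
            markers_out.append(fa.markers.marker_id[j])
            labels_out.append(int(lab))
    values = np.stack(cols, axis=1) if cols else np.empty((n, 0))
    meta = pd.DataFrame(
        {"marker": markers_out, "kind": "haplotype-count", "label": labels_out}
    )
    return DesignMatrix(list(fa.individuals), values, meta)


@dataclass
class GRM:
    individuals: list
    matrix: np.ndarray


def grm_vanraden(design: DesignMatrix) -> GRM:
    """VanRaden method-1 GRM from a SNP dosage design:
    ``G = WW' / (2 * sum p_k (1 - p_k))`` with ``W`` the 2p-centered dosages."""
    X = design.values
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("GRM needs at least 2 individuals and 1 marker")
    p_hat = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p_hat * (1.0 - p_hat)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = X - 2.0 * p_hat
    G = W @ W.T / denom
    G = (G + G.T) / 2.0
    return GRM(list(design.individuals), G)


@dataclass
class LDResult:
    pairs: pd.DataFrame  # marker_i, marker_j, chrom, dist_bp, r2
    mean_adjacent_r2: float
    mean_adjacent_dist_bp: float
    decay_grid: np.ndarray
    decay_r2: np.ndarray
    unlinked_threshold: float | None


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Xc.T @ Xc) / X.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = C / np.outer(sd, sd)
    return r**2


def ld_stats(
    geno: GenotypeMatrix,
    grid: np.ndarray | None = None,
    bandwidth: float = 250_000.0,
    n_unlinked_pairs: int = 100_000,
    max_pair_bp: int = 5_000_000,
    seed: int = 0,
) -> LDResult:
    """Pairwise r^2 within chromosomes (up to ``max_pair_bp`` apart), the
    kernel-smoothed decay curve, and the unlinked-pair 95th-percentile
    threshold (random inter-chromosome pairs, seeded)."""
    markers = geno.markers
    D = geno.dosage.astype(float)
    D[geno.dosage == MISSING] = np.nan
    col_mean = np.nanmean(D, axis=0)
    idx = np.where(np.isnan(D))
    D[idx] = col_mean[idx[1]]

    recs = []
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        pos = markers.position_bp[sl]
        R2 = _pairwise_r2(D[:, sl])
        iu, ju = np.triu_indices(sl.stop - sl.start, k=1)
        dist = pos[ju] - pos[iu]
        ok = dist <= max_pair_bp
        iu, ju, dist = iu[ok], ju[ok], dist[ok]
        r2 = R2[iu, ju]
        fin = np.isfinite(r2)
        recs.append(
            pd.DataFrame(
                {
                    "marker_i": markers.marker_id[sl][iu[fin]],
                    "marker_j": markers.marker_id[sl][ju[fin]],
                    "chrom": chrom,
                    "dist_bp": dist[fin],
                    "adjacent": (ju[fin] - iu[fin]) == 1,
                    "r2": r2[fin],
                }
            )
        )
    pairs = pd.concat(recs, ignore_index=True)
    adj = pairs[pairs["adjacent"]]
    mean_adj_r2 = float(adj["r2"].mean())
    mean_adj_dist = float(adj["dist_bp"].mean())

    if grid is None:
        grid = np.linspace(0.0, float(max_pair_bp), 51)
    x = pairs["dist_bp"].to_numpy(float)
    y = pairs["r2"].to_numpy(float)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2)
    with np.errstate(invalid="ignore"):
        decay = (w @ y) / w.sum(axis=1)

    threshold = None
    if len(markers.chromosomes) > 1:
        rng = np.random.default_rng(seed)
        chrom_of = markers.chromosome
        i = rng.integers(0, markers.n_markers, size=n_unlinked_pairs)
        j = rng.integers(0, markers.n_markers, size=n_unlinked_pairs)
        ok = chrom_of[i] != chrom_of[j]
        i, j = i[ok], j[ok]
        Xc = D - D.mean(axis=0)
        sd = Xc.std(axis=0)
        num = (Xc[:, i] * Xc[:, j]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / (sd[i] * sd[j])
        r2u = r[np.isfinite(r)] ** 2
        threshold = float(np.percentile(r2u, 95))
    else:
        logger.warning("single chromosome: unlinked-pair threshold unavailable")
    return LDResult(
        pairs.drop(columns="adjacent"),
        mean_adj_r2,
        mean_adj_dist,
        grid,
        decay,
        threshold,
    )
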