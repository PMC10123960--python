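"""Marker quality control: call-rate/MAF filters, mean imputation, LD pruning.

Filters mirror standard GBS panel curation: markers are dropped when the
call rate is below 90% or the minor allele frequency is below 5% (both
strict ``<`` comparisons), missing calls are mean-imputed, and near-duplicate
markers with pairwise r² above 0.99 are greedily pruned within chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class EmptyPanelError(ValueError):
    """All markers were removed by a filter."""


@dataclass
class QCReport:
    n_input: int
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_ld: int = 0
    n_retained: int = 0
    removed_ids: dict = field(default_factory=dict)
    zero_variance_ids: list = field(default_factory=list)

    def __post_init__(self):
        removed = (self.n_removed_callrate + self.n_removed_maf
                   + self.n_removed_ld)
        if self.n_input != self.n_retained + removed:
            raise ValueError("QC counts do not reconcile")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def filter_markers(G: GenotypeMatrix, min_call_rate: float = 0.90,
                   min_maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with call rate < ``min_call_rate``, then MAF < ``min_maf``.

    MAF is computed on the observed calls of call-rate survivors only; the
    boundaries are strict, so a marker with MAF exactly 0.05 is retained.
    """
    if G.n_markers == 0:
        raise EmptyPanelError("input panel has no markers")
    cr = G.call_rate()
    pass_cr = cr >= min_call_rate
    removed_cr = G.marker_ids[~pass_cr]

    maf = G.maf()
    pass_maf = pass_cr & (maf >= min_maf)
    removed_maf = G.marker_ids[pass_cr & (maf < min_maf)]

    out = G.subset_markers(pass_maf)
    report = QCReport(
        n_input=G.n_markers,
        n_removed_callrate=int((~pass_cr).sum()),
        n_removed_maf=len(removed_maf),
        n_retained=out.n_markers,
        removed_ids={"call_rate": list(removed_cr), "maf": list(removed_maf)},
    )
    if out.n_markers == 0:
        raise EmptyPanelError(
            f"all {G.n_markers} markers removed by call-rate/MAF filters")
    return out, report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean over observed lines."""
    d = G.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return G
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = list(G.marker_ids[fully_missing])
        raise ValueError(f"markers fully missing (should have failed "
                         f"call-rate filtering): {bad}")
    col_mean = np.nanmean(d, axis=0)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return GenotypeMatrix(dosages=d, chrom=G.chrom, pos_bp=G.pos_bp,
                          line_ids=G.line_ids, marker_ids=G.marker_ids)


def ld_prune(G: GenotypeMatrix, max_r2: float = 0.99
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy left-to-right LD pruning within chromosome.

    For each retained marker, any later marker on the same chromosome whose
    squared Pearson correlation of dosages with it exceeds ``max_r2`` is
    removed; the earlier-position marker always wins.  Zero-variance markers
    have undefined r² — they are never pruned by correlation but are flagged
    in the report.
    """
    if np.isnan(G.dosages).any():
        raise ValueError("ld_prune requires imputed (no-missing) dosages")
    d = G.dosages
    sd = d.std(axis=0)
    zero_var = sd == 0.0
    keep = np.ones(G.n_markers, dtype=bool)
    removed: list[str] = []
    # normalize once; correlations are then plain dot products / n
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d - d.mean(axis=0)) / sd
    n = d.shape[0]
    for c in pd.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == c)
        for a, j in enumerate(idx):
            if not keep[j] or zero_var[j]:
                continue
            later = idx[a + 1:]
            later = later[keep[later] & ~zero_var[later]]
            if later.size == 0:
                continue
            r = z[:, later].T @ z[:, j] / n
            prune = later[r ** 2 > max_r2]
            if prune.size:
                keep[prune] = False
                removed.extend(G.marker_ids[prune])
    out = G.subset_markers(keep)
    report = QCReport(
        n_input=G.n_markers,
        n_removed_ld=len(removed),
        n_retained=out.n_markers,
        removed_ids={"ld": removed},
        zero_variance_ids=list(G.marker_ids[zero_var]),
    )
    return out, report
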