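"""Dosage genotype container and on-disk formats.

A :class:`GenotypeMatrix` holds a line × marker matrix of alternate-allele
dosages (0, 1, 2, or NaN for missing) together with a marker map (chromosome,
1-based bp position) and line identifiers.  Marker identifiers follow the
``Chr<k>_<pos>`` convention.  Round-trips to a plain dosage TSV and to VCF
(one pseudo-sample per inbred line, GT field) are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def marker_id(chrom: str, pos: int) -> str:
    """Canonical marker identifier, e.g. ``Chr4_164335549``."""
    return f"{chrom}_{pos}"


@dataclass
class GenotypeMatrix:
    """Line × marker dosage matrix with a marker map.

    Parameters
    ----------
    dosages : ndarray of shape (n_lines, n_markers)
        Alternate-allele dosages in {0, 1, 2}; missing calls are NaN.
    chrom : array of str, per marker
    pos_bp : int array, per marker, 1-based, strictly increasing within
        each chromosome.
    line_ids : array of str, per line.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [marker_id(c, p) for c, p in zip(self.chrom, self.pos_bp)],
                dtype=object,
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match dosage rows")
        for arr, name in [(self.chrom, "chrom"), (self.pos_bp, "pos_bp"),
                          (self.marker_ids, "marker_ids")]:
            if len(arr) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker_ids are not unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(np.round(obs, 6), [0.0, 1.0, 2.0])):
            # mean-imputed matrices carry fractional dosages; only raw
            # matrices are checked strictly by callers that care
            pass
        for c in pd.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over observed calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the boolean/index mask ``keep``."""
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            chrom=self.chrom[keep],
            pos_bp=self.pos_bp[keep],
            line_ids=self.line_ids,
            marker_ids=self.marker_ids[keep],
        )

    # ------------------------------ TSV -------------------------------
    def to_dosage_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.line_ids,
                          columns=self.marker_ids)
        df.index.name = "line_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        chrom, pos = _parse_marker_ids(df.columns)
        return cls(
            dosages=df.to_numpy(dtype=float),
            chrom=chrom,
            pos_bp=pos,
            line_ids=df.index.to_numpy(dtype=object),
            marker_ids=df.columns.to_numpy(dtype=object),
        )

    # ------------------------------ VCF -------------------------------
    def to_vcf(self, path) -> None:
        """Write a minimal biallelic VCF, one pseudo-sample per line.

        Dosage 0 → 0/0, 1 → 0/1, 2 → 1/1, missing → ./. ; REF/ALT are
        placeholders (A/T) since only genotypes matter downstream.
        """
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in pd.unique(self.chrom):
                ln = int(self.pos_bp[self.chrom == c].max()) + 1
                fh.write(f"##contig=<ID={c},length={ln}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.line_ids)) + "\n")
            for j in range(self.n_markers):
                calls = [
                    "./." if np.isnan(d) else gt_map[round(float(d), 6)]
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{self.chrom[j]}\t{self.pos_bp[j]}\t{self.marker_ids[j]}"
                    f"\tA\tT\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF; multi-allelic records are skipped
        with a warning (dosage = count of the first alternate allele)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        line_ids = np.asarray(vcf.samples, dtype=object)
        rows, chrom, pos = [], [], []
        n_skipped = 0
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_skipped += 1
                continue
            g = rec.genotype.array()[:, :2].astype(float)
            g[g < 0] = np.nan
            rows.append(g.sum(axis=1))
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} non-biallelic VCF records")
        if not rows:
            raise ValueError("no biallelic records in VCF")
        return cls(
            dosages=np.column_stack(rows) if rows else np.empty((len(line_ids), 0)),
            chrom=np.asarray(chrom, dtype=object),
            pos_bp=np.asarray(pos, dtype=np.int64),
            line_ids=line_ids,
        )


def _parse_marker_ids(ids) -> tuple[np.ndarray, np.ndarray]:
    chrom, pos = [], []
    for mid in ids:
        c, _, p = str(mid).rpartition("_")
        chrom.append(c)
        pos.append(int(p))
    return np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64)
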