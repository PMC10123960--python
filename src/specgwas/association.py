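"""From posterior inclusion probabilities to GWA results.

Markers are selected by PIP threshold (0.10 for manually measured traits,
0.50 — more conservative — for the 281 hyperspectral phenotypes), candidate
genes are looked up in a ±50 kbp window around each selected SNP from a
local GFF3 annotation, and per-marker phenome profiles aggregate PIPs across
every phenotype and management for PheWAS-style display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MANUAL_PIP_THRESHOLD = 0.10
HYPERSPECTRAL_PIP_THRESHOLD = 0.50
PHENOTYPE_CLASSES = ("manual", "band", "index")
DEFAULT_FLANK_BP = 50_000

CLASS_THRESHOLDS = {
    "manual": MANUAL_PIP_THRESHOLD,
    "band": HYPERSPECTRAL_PIP_THRESHOLD,
    "index": HYPERSPECTRAL_PIP_THRESHOLD,
}


@dataclass
class MarkerHit:
    marker_id: str
    chrom: str
    pos_bp: int
    phenotype: str
    management: str
    pip: float
    threshold_used: float
    phenotype_class: str = "manual"

    def __post_init__(self):
        if self.pip < self.threshold_used:
            raise ValueError("hit PIP below its threshold")
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class {self.phenotype_class}")


@dataclass
class GeneWindow:
    marker_id: str
    window_start_bp: int
    window_end_bp: int
    gene_ids: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def select_markers(pips: pd.DataFrame | dict, threshold: float,
                   phenotype: str = "", management: str = "",
                   phenotype_class: str = "manual",
                   chrom=None, pos_bp=None) -> list[MarkerHit]:
    """Markers with PIP ≥ threshold, sorted by descending PIP then map order.

    ``pips`` is a mapping marker_id -> pip, or a DataFrame with columns
    marker_id, pip (and optionally chrom, pos_bp).  An empty result is valid
    (a trait may yield no hits in one management).
    """
    if isinstance(pips, dict):
        df = pd.DataFrame({"marker_id": list(pips), "pip": list(pips.values())})
    else:
        df = pips.copy()
    if chrom is not None:
        df["chrom"] = np.asarray(chrom)
    if pos_bp is not None:
        df["pos_bp"] = np.asarray(pos_bp)
    if "chrom" not in df:
        parsed = df["marker_id"].astype(str).str.rpartition("_")
        df["chrom"] = parsed[0]
        df["pos_bp"] = pd.to_numeric(parsed[2])
    if ((df["pip"] < 0) | (df["pip"] > 1)).any():
        raise ValueError("PIPs must lie in [0, 1]")
    sel = df[df["pip"] >= threshold].sort_values(
        ["pip", "chrom", "pos_bp"], ascending=[False, True, True])
    return [
        MarkerHit(marker_id=row.marker_id, chrom=row.chrom,
                  pos_bp=int(row.pos_bp), phenotype=phenotype,
                  management=management, pip=float(row.pip),
                  threshold_used=threshold, phenotype_class=phenotype_class)
        for row in sel.itertuples()
    ]


def read_gene_annotation(gff3_path) -> pd.DataFrame:
    """Gene features from a GFF3 file as (gene_id, chrom, start, end).

    Coordinates are 1-based inclusive as in GFF3.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", force=True,
                            keep_order=True)
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        rows.append({"gene_id": gid, "chrom": gene.seqid,
                     "start": gene.start, "end": gene.end})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def gene_window_lookup(hit: MarkerHit, annotation: pd.DataFrame,
                       flank_bp: int = DEFAULT_FLANK_BP) -> GeneWindow:
    """Genes whose span intersects [pos − flank, pos + flank] (closed
    intervals, same chromosome; window clipped at position 1)."""
    start = max(hit.pos_bp - flank_bp, 1)
    end = hit.pos_bp + flank_bp
    on_chrom = annotation[annotation["chrom"] == hit.chrom]
    if on_chrom.empty:
        log.warning("chromosome %s absent from annotation", hit.chrom)
        return GeneWindow(hit.marker_id, start, end, [])
    sel = on_chrom[(on_chrom["end"] >= start) & (on_chrom["start"] <= end)]
    return GeneWindow(hit.marker_id, start, end, list(sel["gene_id"]))


def aggregate_phewas(hits: list[MarkerHit], all_pips: pd.DataFrame,
                     class_thresholds: dict | None = None) -> pd.DataFrame:
    """Phenome profile of every marker appearing in ``hits``.

    ``all_pips`` is long format with columns marker_id, phenotype,
    phenotype_class, management, pip.  Returns that table restricted to hit
    markers with two additions per marker: ``n_phenotypes`` — the count of
    (phenotype, management) cells at or above the class threshold — and
    ``shared`` — True when the marker is selected in both the manual and a
    hyperspectral (band/index) class.
    """
    if not hits:
        raise ValueError("hits must be nonempty")
    if class_thresholds is None:
        class_thresholds = CLASS_THRESHOLDS
    need = {"marker_id", "phenotype", "phenotype_class", "management", "pip"}
    if not need <= set(all_pips.columns):
        raise ValueError(f"all_pips must have columns {sorted(need)}")
    markers = sorted({h.marker_id for h in hits})
    prof = all_pips[all_pips["marker_id"].isin(markers)].copy()
    thr = prof["phenotype_class"].map(class_thresholds)
    prof["selected"] = prof["pip"] >= thr
    counts = prof.groupby("marker_id")["selected"].sum().astype(int)
    by_class = (prof[prof["selected"]]
                .groupby("marker_id")["phenotype_class"]
                .agg(lambda s: set(s)))
    shared = {m: ("manual" in by_class.get(m, set())
                  and bool(by_class.get(m, set()) & {"band", "index"}))
              for m in markers}
    prof["n_phenotypes"] = prof["marker_id"].map(counts)
    prof["shared"] = prof["marker_id"].map(shared)
    return prof.reset_index(drop=True)


def hits_table(hits: list[MarkerHit], annotation: pd.DataFrame | None = None,
               maf: dict | None = None, flank_bp: int = DEFAULT_FLANK_BP
               ) -> pd.DataFrame:
    """Selected-marker table: one row per (management, marker), with the
    phenotype count, mean PIP over its selections, MAF, gene count and
    candidate gene ids in the flanked window."""
    rows = []
    key = lambda h: (h.management, h.marker_id)
    groups: dict[tuple, list[MarkerHit]] = {}
    for h in hits:
        groups.setdefault(key(h), []).append(h)
    for (mgmt, mid), hs in sorted(groups.items()):
        h0 = hs[0]
        row = {
            "management": mgmt,
            "chrom": h0.chrom,
            "marker_id": mid,
            "n_phenotypes": len(hs),
            "maf": maf.get(mid, np.nan) if maf else np.nan,
            "pip": float(np.mean([h.pip for h in hs])),
        }
        if annotation is not None:
            gw = gene_window_lookup(h0, annotation, flank_bp=flank_bp)
            row["n_genes"] = gw.n_genes
            row["candidate_genes"] = ";".join(map(str, gw.gene_ids))
        rows.append(row)
    return pd.DataFrame(rows)
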