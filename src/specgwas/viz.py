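"""Figures: Manhattan (PIP vs genome position), PheWAS profiles,
heritability and genomic-correlation spectra.

Static output is matplotlib (PNG); the PheWAS view is additionally written
as a self-contained HTML/SVG page with native hover tooltips identifying
each phenotype, standing in for an interactive multiphenotype browser.
Figures embed no timestamps, so regenerating from identical inputs is
byte-stable.
"""

from __future__ import annotations

import html as _html
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

CLASS_ORDER = ("band", "index", "manual")
CLASS_LABEL = {"band": "Bands", "index": "Index", "manual": "MM"}
CLASS_COLOR = {"band": "#1f77b4", "index": "#2ca02c", "manual": "#d62728"}


def _genome_coords(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Cumulative genome x-coordinate with per-chromosome offsets."""
    df = df.copy()
    offsets, ticks = {}, {}
    off = 0
    for c in sorted(df["chrom"].unique(),
                    key=lambda s: (len(str(s)), str(s))):
        span = df.loc[df["chrom"] == c, "pos_bp"].max()
        offsets[c] = off
        ticks[c] = off + span / 2
        off += span * 1.02
    df["x"] = df["pos_bp"] + df["chrom"].map(offsets)
    return df, ticks


def plot_manhattan(pips, threshold: float, path, title: str = "") -> Path:
    """PIP Manhattan plot; ``pips`` is a DataFrame (marker_id, chrom,
    pos_bp, pip) or a mapping management -> such DataFrame (aligned
    panels).  Markers at or above ``threshold`` are labeled."""
    panels = pips if isinstance(pips, dict) else {"": pips}
    fig, axes = plt.subplots(len(panels), 1, figsize=(9, 2.6 * len(panels)),
                             sharex=True, squeeze=False)
    for ax, (mgmt, df) in zip(axes[:, 0], panels.items()):
        df, ticks = _genome_coords(df)
        chroms = list(ticks)
        for i, c in enumerate(chroms):
            sub = df[df["chrom"] == c]
            ax.scatter(sub["x"], sub["pip"], s=6,
                       color="#444444" if i % 2 else "#999999")
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
        hits = df[df["pip"] >= threshold]
        for row in hits.itertuples():
            ax.annotate(row.marker_id, (row.x, row.pip), fontsize=6,
                        rotation=45, textcoords="offset points", xytext=(2, 2))
        ax.set_ylabel("PIP")
        ax.set_ylim(0, 1.05)
        label = f"{title} {mgmt}".strip()
        if label:
            ax.set_title(label, fontsize=9)
        ax.set_xticks(list(ticks.values()))
        ax.set_xticklabels(chroms, fontsize=7)
    axes[-1, 0].set_xlabel("genome position")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def _order_phenotypes(profile: pd.DataFrame) -> list[str]:
    order = []
    for cls in CLASS_ORDER:
        ph = profile.loc[profile["phenotype_class"] == cls, "phenotype"]
        order.extend(sorted(ph.unique()))
    return order


def plot_phewas(profile: pd.DataFrame, path, html_path=None) -> Path:
    """Phenome-wide association plot of the profiled markers.

    x-axis: phenotypes grouped Bands → Index → MM; y-axis: PIP; one panel
    per management; point shape per marker, color per phenotype class.
    With ``html_path``, also writes a self-contained SVG/HTML version whose
    points reveal the phenotype name on hover.
    """
    if profile.empty:
        raise ValueError("empty phenome profile")
    managements = sorted(profile["management"].unique())
    order = _order_phenotypes(profile)
    xpos = {p: i for i, p in enumerate(order)}
    markers = sorted(profile["marker_id"].unique())
    symbols = ["o", "s", "^", "v", "D", "P", "X", "*", "<", ">"]

    fig, axes = plt.subplots(len(managements), 1,
                             figsize=(10, 2.8 * len(managements)),
                             sharex=True, squeeze=False)
    for ax, mgmt in zip(axes[:, 0], managements):
        sub = profile[profile["management"] == mgmt]
        for mi, mid in enumerate(markers):
            s2 = sub[sub["marker_id"] == mid]
            ax.scatter([xpos[p] for p in s2["phenotype"]], s2["pip"],
                       s=14, marker=symbols[mi % len(symbols)],
                       c=[CLASS_COLOR[c] for c in s2["phenotype_class"]],
                       label=mid if mgmt == managements[0] else None,
                       alpha=0.8, linewidths=0)
        ax.set_ylabel("PIP")
        ax.set_ylim(-0.02, 1.05)
        ax.set_title(mgmt, fontsize=9)
        # class banding
        cls_of = profile.drop_duplicates("phenotype").set_index(
            "phenotype")["phenotype_class"]
        start = 0
        for cls in CLASS_ORDER:
            n = sum(1 for p in order if cls_of[p] == cls)
            if n:
                ax.axvspan(start - 0.5, start + n - 0.5, alpha=0.06,
                           color=CLASS_COLOR[cls])
                ax.text(start + n / 2, 1.0, CLASS_LABEL[cls], fontsize=7,
                        ha="center", color=CLASS_COLOR[cls])
                start += n
    axes[-1, 0].set_xlabel("phenotype (grouped by class)")
    axes[-1, 0].set_xticks([])
    fig.legend(loc="upper right", fontsize=6, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=130)
    plt.close(fig)

    if html_path is not None:
        _write_phewas_html(profile, order, xpos, managements, html_path)
    return path


def _write_phewas_html(profile, order, xpos, managements, html_path) -> None:
    w, h, pad = 960, 230, 40
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>"
             "<title>PheWAS</title></head><body>"
             "<h2>Phenome-wide association profiles</h2>"
             "<p>Hover a point to identify the phenotype.</p>"]
    nx = max(len(order), 1)
    for mgmt in managements:
        sub = profile[profile["management"] == mgmt]
        pts = []
        for row in sub.itertuples():
            x = pad + (w - 2 * pad) * xpos[row.phenotype] / nx
            y = h - pad - (h - 2 * pad) * row.pip
            tip = _html.escape(
                f"{row.marker_id} | {row.phenotype} ({row.phenotype_class})"
                f" | PIP={row.pip:.3f}")
            pts.append(
                f"<circle cx='{x:.1f}' cy='{y:.1f}' r='3' "
                f"fill='{CLASS_COLOR[row.phenotype_class]}' opacity='0.8'>"
                f"<title>{tip}</title></circle>")
        parts.append(
            f"<h3>{_html.escape(mgmt)}</h3>"
            f"<svg width='{w}' height='{h}' style='border:1px solid #ccc'>"
            f"<line x1='{pad}' y1='{h - pad}' x2='{w - pad}' y2='{h - pad}' "
            f"stroke='#333'/><line x1='{pad}' y1='{pad}' x2='{pad}' "
            f"y2='{h - pad}' stroke='#333'/>" + "".join(pts) + "</svg>")
    parts.append("</body></html>")
    Path(html_path).write_text("".join(parts))


def plot_heritability_spectrum(band_h2: pd.DataFrame,
                               index_h2: pd.DataFrame | None, path) -> Path:
    """h² vs wavelength per management, plus per-index bars when given.

    ``band_h2``: columns wavelength_nm, h2, management;
    ``index_h2``: columns index, h2, management.
    """
    ncols = 2 if index_h2 is not None and not index_h2.empty else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5.2 * ncols, 3.2),
                             squeeze=False)
    ax = axes[0, 0]
    for mgmt, sub in band_h2.groupby("management"):
        sub = sub.sort_values("wavelength_nm")
        ax.plot(sub["wavelength_nm"], sub["h2"], label=str(mgmt), lw=1.2)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("genomic heritability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if ncols == 2:
        ax2 = axes[0, 1]
        idx = sorted(index_h2["index"].unique())
        width = 0.38
        for k, (mgmt, sub) in enumerate(index_h2.groupby("management")):
            vals = sub.set_index("index")["h2"].reindex(idx)
            ax2.bar(np.arange(len(idx)) + k * width, vals, width,
                    label=str(mgmt))
        ax2.set_xticks(np.arange(len(idx)) + width / 2)
        ax2.set_xticklabels(idx, rotation=90, fontsize=6)
        ax2.set_ylabel("genomic heritability")
        ax2.set_ylim(0, 1)
        ax2.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def plot_correlation_spectrum(pairs_table: pd.DataFrame, path) -> Path:
    """Genomic correlation vs wavelength, one line per trait × management.

    Expects the long table from the bivariate pair runner with band
    phenotypes named ``R<nm>``; index phenotypes are drawn as points at the
    right margin.
    """
    df = pairs_table.copy()
    is_band = df["phenotype"].astype(str).str.fullmatch(r"R\d+(\.\d+)?")
    df["wavelength_nm"] = np.where(
        is_band, df["phenotype"].astype(str).str.lstrip("R"), np.nan)
    df["wavelength_nm"] = pd.to_numeric(df["wavelength_nm"], errors="coerce")
    fig, ax = plt.subplots(figsize=(7, 3.4))
    for (mgmt, trait), sub in df[is_band].groupby(["management", "trait"]):
        sub = sub.sort_values("wavelength_nm")
        ax.plot(sub["wavelength_nm"], sub["r_g_mean"], marker="o", ms=3,
                lw=1.0, label=f"{trait} {mgmt}")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("genomic correlation")
    ax.set_ylim(-1, 1)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
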