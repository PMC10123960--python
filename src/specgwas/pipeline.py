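"""End-to-end orchestration: simulate → qc → indices → gwas-uni → gwas-bi →
select → annotate → report.

Every stage is deterministic given the configuration (one seed, split per
stage), writes its artifacts under the run directory, and is listed in a
manifest with content hashes so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import synthetic, viz
from .bayes import (BayesCConfig, BivariateConfig, DesignSpec, fit_bayesc,
                    fit_pairs)
from .genotypes import GenotypeMatrix
from .qc import filter_markers, impute_missing, ld_prune
from .spectral import (SpectraTable, compute_indices, default_registry,
                       index_resolvable)
from .synthetic import SimConfig

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "indices", "gwas-uni", "gwas-bi", "select",
              "annotate", "report")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-pipeline run.

    The default scale is deliberately reduced relative to the real trial
    (300 lines, 1,000 markers, 20 analyzed bands, 5 indices, chains
    6,000/600/6) so a complete run finishes on one CPU in minutes while
    exercising every stage.
    """

    out_dir: str = "specgwas_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    genotype_tsv: str | None = None      # existing inputs; None -> simulate
    phenotype_csv: str | None = None
    spectra_csv: str | None = None
    gff3: str | None = None              # None -> synthetic annotation
    sim: dict = field(default_factory=lambda: dict(
        n_lines=300, n_markers=1000, n_bands=20,
        h2_target=(0.61, 0.60, 0.30), seed=0))
    chain: dict = field(default_factory=lambda: dict(
        n_iter=6000, burn_in=600, thin=6))
    n_index: int = 5                     # indices analyzed in gwas-uni
    n_bands_bivariate: int = 3           # bands per trait in gwas-bi
    n_index_bivariate: int = 1
    manual_threshold: float = assoc.MANUAL_PIP_THRESHOLD
    hyper_threshold: float = assoc.HYPERSPECTRAL_PIP_THRESHOLD
    flank_bp: int = assoc.DEFAULT_FLANK_BP
    log_level: str = "INFO"

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s}")
        for p in (self.genotype_tsv, self.phenotype_csv, self.spectra_csv,
                  self.gff3):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sim_cfg = SimConfig(**{**config.sim, "seed": config.sim.get("seed",
                                                                config.seed)})
    ch = config.chain

    G = truth = phenotypes = spectra = None
    G_qc = None
    index_table = None
    all_pips_rows = []
    h2_rows = []
    annotation = None
    hits: list[assoc.MarkerHit] = []

    def emit(path: Path):
        written.append(path)
        log.info("wrote %s", path)

    for stage in config.stages:
        log.info("stage %s (seed %d)", stage, config.seed)
        if stage == "simulate":
            G = synthetic.simulate_genotypes(sim_cfg)
            phenotypes, truth = synthetic.simulate_traits(G, sim_cfg)
            spectra = synthetic.simulate_spectra(G, truth, sim_cfg, phenotypes)
            G.to_dosage_tsv(out / "genotypes.tsv"); emit(out / "genotypes.tsv")
            phenotypes.to_csv(out / "phenotypes.csv", index=False)
            emit(out / "phenotypes.csv")
            spectra.to_csv(out / "spectra.csv"); emit(out / "spectra.csv")
            truth.to_json(out / "truth.json"); emit(out / "truth.json")

        elif stage == "qc":
            if G is None:
                G = GenotypeMatrix.from_dosage_tsv(
                    config.genotype_tsv or out / "genotypes.tsv")
            G_f, rep1 = filter_markers(G)
            G_f = impute_missing(G_f)
            G_qc, rep2 = ld_prune(G_f)
            G_qc.to_dosage_tsv(out / "genotypes_qc.tsv")
            emit(out / "genotypes_qc.tsv")
            rep1.to_json(out / "qc_filter.json"); emit(out / "qc_filter.json")
            rep2.to_json(out / "qc_ldprune.json"); emit(out / "qc_ldprune.json")

        elif stage == "indices":
            if spectra is None:
                spectra = SpectraTable.from_csv(
                    config.spectra_csv or out / "spectra.csv")
            registry = [d for d in default_registry()
                        if index_resolvable(d, spectra.wavelengths_nm)]
            registry = registry[: config.n_index]
            index_table = compute_indices(spectra, registry)
            index_table.to_csv(out / "indices.csv"); emit(out / "indices.csv")

        elif stage == "gwas-uni":
            phenotypes, spectra, G_qc = _require(config, out, phenotypes,
                                                 spectra, G_qc)
            if index_table is None and (out / "indices.csv").exists():
                index_table = pd.read_csv(out / "indices.csv",
                                          index_col="plot_id")
            h2_rows.clear()
            all_pips_rows.clear()
            for mgmt, sub in phenotypes.groupby("management"):
                design = DesignSpec.from_phenotypes(sub)
                X = _expand(G_qc, sub["line_id"])
                cols = _phenotype_columns(sub, spectra, index_table, sim_cfg)
                for name, (vec, cls) in cols.items():
                    cfg = BayesCConfig(seed=_stage_seed(config.seed, mgmt, name),
                                       **ch)
                    post = fit_bayesc(vec, design, X, cfg)
                    for mid, pip in zip(G_qc.marker_ids, post.pip):
                        all_pips_rows.append({
                            "marker_id": mid, "phenotype": name,
                            "phenotype_class": cls, "management": mgmt,
                            "pip": pip})
                    h2_rows.append({"management": mgmt, "phenotype": name,
                                    "phenotype_class": cls, "h2": post.h2,
                                    "h2_low": post.h2_ci[0],
                                    "h2_high": post.h2_ci[1]})
            pd.DataFrame(all_pips_rows).to_csv(out / "pips.tsv", sep="\t",
                                               index=False)
            emit(out / "pips.tsv")
            pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t",
                                         index=False)
            emit(out / "heritability.tsv")

        elif stage == "gwas-bi":
            phenotypes, spectra, G_qc = _require(config, out, phenotypes,
                                                 spectra, G_qc)
            if index_table is None and (out / "indices.csv").exists():
                index_table = pd.read_csv(out / "indices.csv",
                                          index_col="plot_id")
            tables = []
            for mgmt, sub in phenotypes.groupby("management"):
                design = DesignSpec.from_phenotypes(sub)
                X = _expand(G_qc, sub["line_id"])
                cols = _phenotype_columns(sub, spectra, index_table, sim_cfg)
                manual = [n for n, (_, c) in cols.items() if c == "manual"]
                bands = [n for n, (_, c) in cols.items() if c == "band"]
                idxs = [n for n, (_, c) in cols.items() if c == "index"]
                band_pick = bands[:: max(len(bands)
                                         // max(config.n_bands_bivariate, 1), 1)
                                  ][: config.n_bands_bivariate]
                pairs = [(t, p) for t in manual
                         for p in band_pick + idxs[: config.n_index_bivariate]]
                cfg = BivariateConfig(seed=_stage_seed(config.seed, mgmt, "bi"),
                                      **ch)
                tab = fit_pairs(pairs, {k: v for k, (v, _) in cols.items()},
                                design, X, cfg, management=mgmt)
                tables.append(tab)
            pd.concat(tables).to_csv(out / "genomic_correlations.tsv",
                                     sep="\t", index=False)
            emit(out / "genomic_correlations.tsv")

        elif stage == "select":
            pips = pd.read_csv(out / "pips.tsv", sep="\t")
            hits = []
            for (mgmt, name, cls), sub in pips.groupby(
                    ["management", "phenotype", "phenotype_class"]):
                thr = (config.manual_threshold if cls == "manual"
                       else config.hyper_threshold)
                hits.extend(assoc.select_markers(
                    sub[["marker_id", "pip"]], thr, phenotype=name,
                    management=mgmt, phenotype_class=cls))
            pd.DataFrame([h.__dict__ for h in hits]).to_csv(
                out / "hits.tsv", sep="\t", index=False)
            emit(out / "hits.tsv")

        elif stage == "annotate":
            if config.gff3 is not None:
                annotation = assoc.read_gene_annotation(config.gff3)
            else:
                if G_qc is None:
                    G_qc = GenotypeMatrix.from_dosage_tsv(out / "genotypes_qc.tsv")
                annotation = synthetic.simulate_gene_annotation(
                    G_qc, seed=config.seed)
                synthetic.write_gff3(annotation, out / "annotation.gff3")
                emit(out / "annotation.gff3")
            if not hits:
                hdf = pd.read_csv(out / "hits.tsv", sep="\t")
                hits = [assoc.MarkerHit(**{k: row[k] for k in (
                    "marker_id", "chrom", "pos_bp", "phenotype", "management",
                    "pip", "threshold_used", "phenotype_class")})
                    for _, row in hdf.iterrows()]
            maf = {}
            if G_qc is not None:
                maf = dict(zip(G_qc.marker_ids, G_qc.maf()))
            table = assoc.hits_table(hits, annotation, maf=maf,
                                     flank_bp=config.flank_bp)
            table.to_csv(out / "hits_annotated.tsv", sep="\t", index=False)
            emit(out / "hits_annotated.tsv")

        elif stage == "report":
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            h2 = pd.read_csv(out / "heritability.tsv", sep="\t")
            band_h2 = h2[h2["phenotype_class"] == "band"].copy()
            band_h2["wavelength_nm"] = pd.to_numeric(
                band_h2["phenotype"].str.lstrip("R"))
            index_h2 = h2[h2["phenotype_class"] == "index"].rename(
                columns={"phenotype": "index"})
            emit(viz.plot_heritability_spectrum(
                band_h2, index_h2, figdir / "heritability_spectrum.png"))
            corr_path = out / "genomic_correlations.tsv"
            if corr_path.exists():
                emit(viz.plot_correlation_spectrum(
                    pd.read_csv(corr_path, sep="\t"),
                    figdir / "correlation_spectrum.png"))
            pips = pd.read_csv(out / "pips.tsv", sep="\t")
            manual = pips[pips["phenotype_class"] == "manual"]
            for trait, sub in manual.groupby("phenotype"):
                panels = {}
                for mgmt, s2 in sub.groupby("management"):
                    s2 = s2.copy()
                    parsed = s2["marker_id"].str.rpartition("_")
                    s2["chrom"], s2["pos_bp"] = parsed[0], pd.to_numeric(parsed[2])
                    panels[mgmt] = s2
                emit(viz.plot_manhattan(panels, config.manual_threshold,
                                        figdir / f"manhattan_{trait}.png",
                                        title=trait))
            hdf = pd.read_csv(out / "hits.tsv", sep="\t")
            if not hdf.empty:
                top = [assoc.MarkerHit(**{k: row[k] for k in (
                    "marker_id", "chrom", "pos_bp", "phenotype", "management",
                    "pip", "threshold_used", "phenotype_class")})
                    for _, row in hdf.iterrows()]
                profile = assoc.aggregate_phewas(top, pips)
                emit(viz.plot_phewas(profile, figdir / "phewas.png",
                                     html_path=figdir / "phewas.html"))
                emit(figdir / "phewas.html")
                profile.to_csv(out / "phewas_profile.tsv", sep="\t",
                               index=False)
                emit(out / "phewas_profile.tsv")
        else:  # pragma: no cover
            raise AssertionError(stage)

    manifest = {
        "stages": list(config.stages),
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_seed(seed: int, mgmt: str, name: str) -> int:
    h = hashlib.sha256(f"{seed}|{mgmt}|{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def _expand(G: GenotypeMatrix, line_ids) -> np.ndarray:
    """Plot × marker dosage matrix: one row per plot, repeating its line."""
    index = {lid: i for i, lid in enumerate(G.line_ids)}
    rows = [index[lid] for lid in line_ids]
    return G.dosages[rows]


def _phenotype_columns(sub: pd.DataFrame, spectra, index_table,
                       sim_cfg: SimConfig) -> dict:
    """Plot-aligned phenotype vectors for one management: manual traits,
    band means and spectral indices, each tagged with its class."""
    cols: dict[str, tuple[np.ndarray, str]] = {}
    for t in sim_cfg.trait_names:
        cols[t] = (sub[t].to_numpy(float), "manual")
    if spectra is not None:
        pos = {pid: i for i, pid in enumerate(spectra.plot_ids)}
        rows = [pos[p] for p in sub["plot_id"]]
        for b, name in enumerate(spectra.band_names):
            cols[name] = (spectra.values[rows, b], "band")
    if index_table is not None:
        sel = index_table.loc[sub["plot_id"]]
        for name in index_table.columns:
            v = sel[name].to_numpy(float)
            if np.isnan(v).any() or v.std() == 0:
                continue
            cols[name] = (v, "index")
    return cols


def _require(config, out, phenotypes, spectra, G_qc):
    if phenotypes is None:
        phenotypes = pd.read_csv(config.phenotype_csv or out / "phenotypes.csv")
    if spectra is None:
        spectra = SpectraTable.from_csv(config.spectra_csv or out / "spectra.csv")
    if G_qc is None:
        G_qc = GenotypeMatrix.from_dosage_tsv(out / "genotypes_qc.tsv")
    return phenotypes, spectra, G_qc
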