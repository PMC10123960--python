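"""Synthetic genotypes, experimental designs, growth traits and spectra.

Emulates the statistical structure of a greenhouse PGPB trial on a maize
diversity panel: 360 inbred lines genotyped at ~13.8k SNPs, evaluated in two
replications (blocks nested in replication) under two managements (B+ with /
B− without growth-promoting bacteria), with a sparse marker architecture
(a marker is causal with probability 1 − π, π = 0.99 by default), plot-level
heritabilities in the 0.3–0.6 range, and 150-band leaf reflectance spectra
(386–1021 nm) genetically correlated with the growth traits.

Every quantity a downstream recovery test needs (causal sets, effect sizes,
realized heritabilities and genetic correlations, genetic values, band
loadings) is recorded in :class:`SimTruth`.

Randomness: a single ``seed`` in :class:`SimConfig`; each stage draws from
its own child stream — ``(seed, 0)`` genotypes, ``(seed, 1)`` traits and
design, ``(seed, 2)`` spectra — so stages are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .spectral import (SpectraTable, default_wavelength_grid, simulate_cube)  # noqa: F401

MANAGEMENTS = ("B-", "B+")


@dataclass
class SimConfig:
    """Study conditions for the simulated trial (defaults mirror the real one)."""

    n_lines: int = 360
    n_markers: int = 13826
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chrom: int = 10
    ld_block_size: int = 5
    ld_flip_rate: float = 0.10     # haplotype copy-with-mutation flip prob
    n_rep: int = 2
    n_block: int = 6               # blocks per replication
    pi_sparsity: float = 0.99
    h2_target: tuple[float, ...] = (0.61, 0.60, 0.30)
    trait_names: tuple[str, ...] = ("PH", "SD", "SDM")
    rg_target: np.ndarray | None = None     # default: 0.2 off-diagonal
    management_shift: float = 0.5           # B+ mean offset, residual-SD units
    causal_resample_frac: float = 0.5       # causal loci swapped for B+
    design_effect_sd: float = 0.3           # SD of rep and block effects
    n_bands: int = 150
    band_range_nm: tuple[float, float] = (386.0, 1021.0)
    band_h2_target: float = 0.45
    band_trait_rmax: float = 0.39           # peak |band-trait genetic corr|
    n_latent: int = 3                       # latent spectral genetic factors
    spectra_amplitude: float = 0.02         # reflectance units per genetic SD
    seed: int = 0

    def __post_init__(self):
        k = len(self.h2_target)
        if self.rg_target is None:
            self.rg_target = np.full((k, k), 0.2) + 0.8 * np.eye(k)
        self.rg_target = np.asarray(self.rg_target, dtype=float)
        self.validate()

    @property
    def n_traits(self) -> int:
        return len(self.h2_target)

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_lines", "n_markers", "n_chrom", "ld_block_size",
                     "n_rep", "n_block", "n_bands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.pi_sparsity <= 1.0:
            raise ValueError("pi_sparsity must be in [0, 1]")
        for h2 in self.h2_target:
            if not 0.0 <= h2 < 1.0:
                raise ValueError("h2_target entries must be in [0, 1); "
                                 "h2 = 1 implies zero residual variance")
        R = self.rg_target
        if R.shape != (self.n_traits, self.n_traits):
            raise ValueError("rg_target shape must be n_traits × n_traits")
        if not np.allclose(R, R.T):
            raise ValueError("rg_target must be symmetric")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("rg_target must be positive semidefinite")
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length must match h2_target")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage)))


@dataclass
class SimTruth:
    """Ground truth of a simulated trial, keyed by management."""

    marker_ids: np.ndarray
    trait_names: tuple[str, ...]
    causal_marker_ids: dict = field(default_factory=dict)   # mgmt -> list
    true_effects: dict = field(default_factory=dict)        # mgmt -> m × K
    true_h2: dict = field(default_factory=dict)             # mgmt -> K
    true_rg: dict = field(default_factory=dict)             # mgmt -> K × K
    true_genetic_values: dict = field(default_factory=dict) # mgmt -> n × K
    line_ids: np.ndarray | None = None
    band_loadings: np.ndarray | None = None                 # K × bands corr targets
    band_genetic_values: dict = field(default_factory=dict) # mgmt -> n × bands
    wavelengths_nm: np.ndarray | None = None

    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=enc)


# ----------------------------------------------------------------------
def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Dosage matrix with block-wise LD (haplotype copy-with-mutation).

    Markers are split into consecutive blocks of ``ld_block_size`` within
    chromosome; a block shares one base allele frequency drawn from
    ``maf_range``, and each haplotype allele copies its left neighbour with
    probability 1 − ``ld_flip_rate`` (else is redrawn), giving positive
    within-block r² and exact marginal frequencies.  Blocks are independent.
    """
    rng = config._rng(0)
    n, m = config.n_lines, config.n_markers
    per_chrom = np.full(config.n_chrom, m // config.n_chrom, dtype=int)
    per_chrom[: m % config.n_chrom] += 1

    chrom, pos = [], []
    for k, mk in enumerate(per_chrom, start=1):
        gaps = rng.integers(5_000, 300_000, size=mk)
        p = np.cumsum(gaps) + 1
        chrom.extend([f"Chr{k}"] * mk)
        pos.extend(p.tolist())

    dos = np.empty((n, m), dtype=float)
    j = 0
    bounds = np.cumsum(per_chrom)
    start = 0
    for end in bounds:
        while j < end:
            L = min(config.ld_block_size, end - j)
            p_b = rng.uniform(*config.maf_range)
            hap = np.empty((n, 2, L), dtype=np.int8)
            hap[:, :, 0] = rng.random((n, 2)) < p_b
            for l in range(1, L):
                redraw = rng.random((n, 2)) < config.ld_flip_rate
                fresh = rng.random((n, 2)) < p_b
                hap[:, :, l] = np.where(redraw, fresh, hap[:, :, l - 1])
            dos[:, j:j + L] = hap.sum(axis=1)
            j += L
        start = end

    return GenotypeMatrix(
        dosages=dos,
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=np.asarray(pos, dtype=np.int64),
        line_ids=np.array([f"L{i:04d}" for i in range(n)], dtype=object),
    )


# ----------------------------------------------------------------------
def _draw_effects(rng, mask: np.ndarray, R: np.ndarray) -> np.ndarray:
    """m × K effects: rows outside ``mask`` are exactly 0, causal rows are
    jointly Gaussian across traits with correlation ``R``."""
    m, K = mask.size, R.shape[0]
    E = np.zeros((m, K))
    nc = int(mask.sum())
    if nc:
        # eigh handles PSD (possibly singular) targets
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        E[mask] = rng.standard_normal((nc, K)) @ L.T
    return E


def simulate_traits(G: GenotypeMatrix, config: SimConfig
                    ) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level phenotypes for both managements, plus ground truth.

    Marker effects are spike-and-slab (zero with probability ``pi_sparsity``,
    else jointly Gaussian across traits with correlation ``rg_target``);
    genetic values are rescaled per trait so the realized plot-level
    heritability Var(g) / (Var(g) + Var(ε)/n_rep) equals ``h2_target``
    exactly (residual variance is 1).  Replication and block-in-replication
    effects are drawn once and added as fixed shifts.  Under B+ a fraction
    ``causal_resample_frac`` of causal loci is swapped for previously
    neutral loci with freshly drawn effects, so the two managements share
    genotypes but not their full architectures.
    """
    rng = config._rng(1)
    W = G.dosages
    if np.isnan(W).any():
        raise ValueError("simulate_traits requires complete dosages")
    n, m = W.shape
    K = config.n_traits
    R = config.rg_target

    causal = rng.random(m) < (1.0 - config.pi_sparsity)
    E_base = _draw_effects(rng, causal, R)

    effects, causal_sets = {}, {}
    effects["B-"] = E_base
    causal_sets["B-"] = causal
    cb = causal.copy()
    E_b = E_base.copy()
    idx_causal = np.flatnonzero(causal)
    n_swap = int(round(config.causal_resample_frac * idx_causal.size))
    if n_swap:
        drop = rng.choice(idx_causal, size=n_swap, replace=False)
        pool = np.flatnonzero(~causal)
        add = rng.choice(pool, size=min(n_swap, pool.size), replace=False)
        cb[drop] = False
        E_b[drop] = 0.0
        cb[add] = True
        new_mask = np.zeros(m, dtype=bool)
        new_mask[add] = True
        E_b += _draw_effects(rng, new_mask, R)
    effects["B+"] = E_b
    causal_sets["B+"] = cb

    truth = SimTruth(marker_ids=G.marker_ids, trait_names=config.trait_names,
                     line_ids=G.line_ids)
    rows = []
    for mi, mgmt in enumerate(MANAGEMENTS):
        E = effects[mgmt]
        g = np.zeros((n, K))
        for t in range(K):
            h2 = config.h2_target[t]
            g_raw = W @ E[:, t]
            g_raw = g_raw - g_raw.mean()
            v = g_raw.var()
            if h2 == 0.0 or v == 0.0:
                E[:, t] = 0.0
                continue
            vg_target = h2 / (1.0 - h2) / config.n_rep   # Var(ε) = 1
            s = np.sqrt(vg_target / v)
            E[:, t] *= s
            g[:, t] = g_raw * s
        vg = g.var(axis=0)
        truth.causal_marker_ids[mgmt] = list(G.marker_ids[np.abs(E).sum(axis=1) > 0])
        truth.true_effects[mgmt] = E
        truth.true_h2[mgmt] = vg / (vg + 1.0 / config.n_rep)
        with np.errstate(invalid="ignore"):
            rg = np.corrcoef(g, rowvar=False) if K > 1 else np.ones((1, 1))
        rg = np.atleast_2d(rg)
        np.fill_diagonal(rg, 1.0)
        truth.true_rg[mgmt] = rg
        truth.true_genetic_values[mgmt] = g

        rep_eff = rng.normal(0.0, config.design_effect_sd, size=config.n_rep)
        blk_eff = rng.normal(0.0, config.design_effect_sd,
                             size=(config.n_rep, config.n_block))
        shift = config.management_shift if mgmt == "B+" else 0.0
        for r in range(config.n_rep):
            order = rng.permutation(n)
            blocks = np.array_split(order, config.n_block)
            for b, members in enumerate(blocks):
                for i in members:
                    eps = rng.standard_normal(K)
                    y = shift + rep_eff[r] + blk_eff[r, b] + g[i] + eps
                    rows.append({
                        "plot_id": f"{mgmt}_R{r + 1}_{G.line_ids[i]}",
                        "line_id": G.line_ids[i],
                        "management": mgmt,
                        "replication": f"R{r + 1}",
                        "block": f"B{b + 1}",
                        **{config.trait_names[t]: y[t] for t in range(K)},
                    })

    phenotypes = pd.DataFrame(rows)
    return phenotypes, truth


# ----------------------------------------------------------------------
def simulate_gene_annotation(G: GenotypeMatrix, mean_gene_length: int = 3_000,
                             mean_gap: int = 30_000, seed: int = 0
                             ) -> pd.DataFrame:
    """Synthetic gene table covering the simulated chromosomes.

    Genes are tiled with exponential gaps and lengths so that a ±50 kbp
    window around a marker typically holds a handful of genes, as in a real
    annotation.  Purely synthetic plumbing for testing the window lookup.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in pd.unique(G.chrom):
        extent = int(G.pos_bp[G.chrom == c].max()) + mean_gap
        pos = 1
        i = 0
        while pos < extent:
            gap = int(rng.exponential(mean_gap)) + 200
            length = int(rng.exponential(mean_gene_length)) + 500
            start = pos + gap
            rows.append({"gene_id": f"{c}g{i:05d}", "chrom": c,
                         "start": start, "end": start + length})
            pos = start + length
            i += 1
    return pd.DataFrame(rows)


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write a gene table as a minimal GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples():
            fh.write(f"{row.chrom}\tsynthetic\tgene\t{row.start}\t{row.end}"
                     f"\t.\t+\t.\tID={row.gene_id}\n")


# ----------------------------------------------------------------------
def _baseline_reflectance(wl: np.ndarray) -> np.ndarray:
    """Template vegetation spectrum: dark visible with a green bump, red-edge
    rise near 715 nm, NIR plateau."""
    green = 0.04 * np.exp(-((wl - 550.0) / 40.0) ** 2)
    red_edge = 0.45 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    tail = -0.02 / (1.0 + np.exp(-(wl - 960.0) / 30.0))
    return 0.05 + green + red_edge + tail


def simulate_spectra(G: GenotypeMatrix, truth: SimTruth, config: SimConfig,
                     phenotypes: pd.DataFrame) -> SpectraTable:
    """Per-plot reflectance spectra genetically tied to the simulated traits.

    Each band's genetic value mixes (i) the manual traits' genetic values
    with smooth sign-changing loadings whose peak equals ``band_trait_rmax``
    (so band-vs-trait genetic correlations sweep through positive and
    negative values across the spectrum) and (ii) latent spectral genetic
    factors built from the same genotypes, scaled so band heritability is
    near ``band_h2_target``.  Plot noise is a smooth random curve plus white
    noise; reflectance = baseline + amplitude × signal, clipped to [0, 1].
    """
    rng = config._rng(2)
    wl = default_wavelength_grid(config.n_bands, config.band_range_nm)
    base = _baseline_reflectance(wl)
    W = G.dosages
    n, m = W.shape
    K = config.n_traits
    span = wl[-1] - wl[0]

    # latent spectral genetic factors: own sparse architectures, unit variance
    U = np.zeros((n, max(config.n_latent, 1)))
    for f in range(config.n_latent):
        mask = rng.random(m) < (1.0 - config.pi_sparsity)
        if not mask.any():
            mask[rng.integers(m)] = True
        u = W @ (mask * rng.standard_normal(m))
        sd = u.std()
        U[:, f] = (u - u.mean()) / sd if sd > 0 else 0.0

    # smooth latent loadings, normalized so the latent mix has unit variance
    centers = np.linspace(wl[0], wl[-1], max(config.n_latent, 1) + 2)[1:-1]
    M = np.exp(-((wl[None, :] - centers[:, None]) / (0.35 * span)) ** 2)
    norm = np.sqrt((M ** 2).sum(axis=0))
    M = M / norm

    # sign-changing manual-trait loadings (target correlations)
    freqs = 1.0 + 0.5 * np.arange(K)
    phases = 2.0 * np.pi * np.arange(K) / max(K, 1)
    rho = np.stack([
        config.band_trait_rmax * np.sin(2 * np.pi * freqs[t] * (wl - wl[0]) / span
                                        + phases[t])
        for t in range(K)
    ])  # K × bands
    truth.band_loadings = rho
    truth.wavelengths_nm = wl

    v_e = config.n_rep * (1.0 / config.band_h2_target - 1.0) \
        if config.band_h2_target > 0 else 1e6

    # smooth plot-noise basis, unit variance per band
    n_bumps = 8
    bc = np.linspace(wl[0], wl[-1], n_bumps)
    B = np.exp(-((wl[None, :] - bc[:, None]) / (0.12 * span)) ** 2)
    B = B / np.sqrt((B ** 2).sum(axis=0))

    values = np.empty((len(phenotypes), config.n_bands))
    line_index = {lid: i for i, lid in enumerate(G.line_ids)}
    for mgmt in MANAGEMENTS:
        g = truth.true_genetic_values[mgmt]
        sd = g.std(axis=0)
        gz = np.where(sd > 0, (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        gamma = np.sqrt(np.clip(1.0 - (rho ** 2).sum(axis=0), 0.05, None))
        Gband = gz @ rho + (U @ M) * gamma[None, :]       # n × bands
        truth.band_genetic_values[mgmt] = Gband

        sel = np.flatnonzero((phenotypes["management"] == mgmt).to_numpy())
        rows = [line_index[lid] for lid in phenotypes["line_id"].iloc[sel]]
        smooth = rng.standard_normal((sel.size, n_bumps)) @ B
        white = rng.standard_normal((sel.size, config.n_bands))
        noise = np.sqrt(v_e) * (np.sqrt(0.7) * smooth + np.sqrt(0.3) * white)
        values[sel] = base[None, :] + config.spectra_amplitude * (
            Gband[rows] + noise)

    np.clip(values, 0.0, 1.0, out=values)
    return SpectraTable(plot_ids=phenotypes["plot_id"].to_numpy(dtype=object),
                        values=values, wavelengths_nm=wl)
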