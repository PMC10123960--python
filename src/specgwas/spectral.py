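"""Hyperspectral cubes, per-plot band means, and named spectral indices.

A hyperspectral cube (rows × cols × bands) is reduced to a per-plot mean
reflectance spectrum by thresholding a reference band to mask out background
pixels.  Named vegetation/pigment indices (NDVI, EVI, CRI1–4, NPQI, ...) are
then evaluated from the per-plot band means; each index carries its
literature formula and citation, and the registry is data-driven (YAML
round-trip) so formula variants can be swapped without code changes.

Formulas are arithmetic expressions over ``R<nm>`` (reflectance at the band
nearest <nm> nanometres), ``D<nm>`` (first derivative of reflectance at the
band nearest <nm>, central finite difference on the camera grid), and
``dsum(lo, hi)`` (integral of the first derivative over [lo, hi] nm).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "HyperspectralCube", "SpectraTable", "IndexDefinition",
    "nearest_band", "mask_and_mean", "compute_indices",
    "default_registry", "load_registry", "save_registry",
    "default_wavelength_grid",
]


def default_wavelength_grid(n_bands: int = 150,
                            band_range_nm: tuple[float, float] = (386.0, 1021.0)
                            ) -> np.ndarray:
    """Uniform band-center grid emulating a 150-band VNIR camera."""
    return np.linspace(band_range_nm[0], band_range_nm[1], n_bands)


@dataclass
class HyperspectralCube:
    """Reflectance cube, axis order (row, col, band), values in [0, 1]."""

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube must be rows × cols × bands")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band count != wavelength count")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite reflectance in cube")


@dataclass
class SpectraTable:
    """Per-plot mean reflectance, one row per plot, values in [0, 1]."""

    plot_ids: np.ndarray
    values: np.ndarray          # plots × bands
    wavelengths_nm: np.ndarray

    def __post_init__(self):
        self.plot_ids = np.asarray(self.plot_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.shape != (self.plot_ids.size, self.wavelengths_nm.size):
            raise ValueError("spectra shape mismatch")

    @property
    def band_names(self) -> list[str]:
        return [f"R{w:.0f}" for w in self.wavelengths_nm]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.band_names)
        df.insert(0, "plot_id", self.plot_ids)
        # exact band centers in a header comment would not survive CSV;
        # they are recovered from the R<nm> names (integer-nm resolution)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        bands = [c for c in df.columns if re.fullmatch(r"R\d+(\.\d+)?", c)]
        wl = np.array([float(c[1:]) for c in bands])
        return cls(plot_ids=df["plot_id"].to_numpy(dtype=object),
                   values=df[bands].to_numpy(dtype=float),
                   wavelengths_nm=wl)


# ----------------------------------------------------------------------
def nearest_band(wavelengths_nm: np.ndarray, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties pick the lower band.

    Raises if the target lies outside the grid extended by one grid
    spacing on either side.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    delta = np.max(np.diff(wl)) if wl.size > 1 else np.inf
    if target_nm < wl[0] - delta or target_nm > wl[-1] + delta:
        raise ValueError(
            f"target {target_nm} nm outside camera range "
            f"[{wl[0]:.1f}, {wl[-1]:.1f}] ± {delta:.2f} nm")
    return int(np.argmin(np.abs(wl - target_nm)))


def resolvable(wavelengths_nm: np.ndarray, target_nm: float) -> bool:
    try:
        nearest_band(wavelengths_nm, target_nm)
        return True
    except ValueError:
        return False


def mask_and_mean(cube: HyperspectralCube, threshold: float,
                  threshold_band_nm: float) -> np.ndarray:
    """Per-band mean reflectance over foreground (above-threshold) pixels.

    The foreground is the set of pixels whose reflectance at the band
    nearest ``threshold_band_nm`` exceeds ``threshold`` — plant tissue is
    bright in the near infrared while the imaging background is dark.
    """
    b = nearest_band(cube.wavelengths_nm, threshold_band_nm)
    mask = cube.values[:, :, b] > threshold
    if not mask.any():
        raise ValueError(
            f"empty foreground: no pixel exceeds {threshold} at "
            f"{cube.wavelengths_nm[b]:.1f} nm")
    return cube.values[mask].mean(axis=0)


# ----------------------------------------------------------------------
@dataclass
class IndexDefinition:
    """A named spectral index: formula over R(λ) with its literature source."""

    name: str
    formula: str
    required_wavelengths_nm: list = field(default_factory=list)
    source: str = ""
    key: str = ""   # internal/column name; defaults to name

    def __post_init__(self):
        if not self.key:
            self.key = self.name
        referenced = {float(m) for m in
                      re.findall(r"[RD](\d+(?:\.\d+)?)", self.formula)}
        referenced |= {float(m) for pair in
                       re.findall(r"dsum\(\s*(\d+(?:\.\d+)?)\s*,\s*(\d+(?:\.\d+)?)\s*\)",
                                  self.formula)
                       for m in pair}
        declared = {float(w) for w in self.required_wavelengths_nm}
        if not referenced <= declared:
            raise ValueError(
                f"{self.name}: formula references wavelengths "
                f"{sorted(referenced - declared)} not declared")


_BUILTIN = [
    # (name, formula, wavelengths, source, key)
    ("NDVI", "(R800 - R680) / (R800 + R680)", [680, 800],
     "Rouse et al. 1974, NASA SP-351"),
    ("GNDVI", "(R800 - R550) / (R800 + R550)", [550, 800],
     "Gitelson et al. 1996, Remote Sens. Environ. 58"),
    ("RDVI", "(R800 - R670) / sqrt(R800 + R670)", [670, 800],
     "Roujean & Breon 1995, Remote Sens. Environ. 51"),
    ("EVI", "2.5 * (R800 - R670) / (R800 + 6*R670 - 7.5*R475 + 1)",
     [475, 670, 800], "Huete et al. 2002, Remote Sens. Environ. 83"),
    ("OSAVI", "1.16 * (R800 - R670) / (R800 + R670 + 0.16)", [670, 800],
     "Rondeaux et al. 1996, Remote Sens. Environ. 55"),
    ("NPQI", "(R415 - R435) / (R415 + R435)", [415, 435],
     "Barnes et al. 1992, Proc. 6th Symp. Physiol. Plant."),
    ("PRI", "(R531 - R570) / (R531 + R570)", [531, 570],
     "Gamon et al. 1992, Remote Sens. Environ. 41"),
    ("NDNI",
     "(log(1/R1510) - log(1/R1680)) / (log(1/R1510) + log(1/R1680))",
     [1510, 1680], "Serrano et al. 2002, Remote Sens. Environ. 81 "
     "(SWIR bands; unresolvable on a 386-1021 nm camera)"),
    ("Chlg", "R780 / R550 - 1", [550, 780],
     "Gitelson et al. 2003, J. Plant Physiol. 160 (green chlorophyll index)"),
    ("CRI1", "1/R510 - 1/R550", [510, 550],
     "Gitelson et al. 2002, Photochem. Photobiol. 75"),
    ("CRI2", "1/R510 - 1/R700", [510, 700],
     "Gitelson et al. 2002, Photochem. Photobiol. 75"),
    ("CRI3", "(1/R510 - 1/R550) * R770", [510, 550, 770],
     "Gitelson et al. 2002 variant scaled by NIR (hsdar CRI3)"),
    ("CRI4", "(1/R510 - 1/R700) * R770", [510, 700, 770],
     "Gitelson et al. 2002 variant scaled by NIR (hsdar CRI4)"),
    ("Datt6", "R860 / (R550 * R708)", [550, 708, 860],
     "Datt 1998, Remote Sens. Environ. 66"),
    ("GMI1", "R750 / R550", [550, 750],
     "Gitelson & Merzlyak 1997, Int. J. Remote Sens. 18"),
    ("GMI2", "R750 / R700", [700, 750],
     "Gitelson & Merzlyak 1997, Int. J. Remote Sens. 18"),
    ("PARS", "R746 / R513", [513, 746],
     "Chappelle et al. 1992, Remote Sens. Environ. 39"),
    ("RARSb", "R675 / (R650 * R700)", [650, 675, 700],
     "Chappelle et al. 1992, Remote Sens. Environ. 39 (chlorophyll b)"),
    ("SR3", "R750 / R550", [550, 750],
     "Gitelson & Merzlyak 1997 simple ratio (hsdar SR3)"),
    ("D2", "D705 / D722", [705, 722],
     "Zarco-Tejada et al. 2003, Remote Sens. Environ. 84 "
     "(first-derivative ratio)"),
    ("SD", "dsum(680, 780)", [680, 780],
     "Red-edge sum of first-derivative reflectance (Elvidge & Chen 1995 "
     "Sum_Dr family)", "SD_index"),
    ("SIPI", "(R800 - R445) / (R800 - R680)", [445, 680, 800],
     "Penuelas et al. 1995, Photosynthetica 31"),
    ("PSRI", "(R678 - R500) / R750", [500, 678, 750],
     "Merzlyak et al. 1999, Physiol. Plant. 106"),
    ("MCARI", "((R700 - R670) - 0.2*(R700 - R550)) * (R700 / R670)",
     [550, 670, 700], "Daughtry et al. 2000, Remote Sens. Environ. 74"),
    ("mND705", "(R750 - R705) / (R750 + R705 - 2*R445)", [445, 705, 750],
     "Sims & Gamon 2002, Remote Sens. Environ. 81"),
]


def default_registry() -> list[IndexDefinition]:
    """The built-in index registry (copies; safe to edit)."""
    out = []
    for entry in _BUILTIN:
        name, formula, wls, source = entry[:4]
        key = entry[4] if len(entry) > 4 else name
        out.append(IndexDefinition(name=name, formula=formula,
                                   required_wavelengths_nm=list(wls),
                                   source=source, key=key))
    return out


def save_registry(registry: list[IndexDefinition], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(d) for d in registry], fh, sort_keys=False)


def load_registry(path) -> list[IndexDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [IndexDefinition(**d) for d in raw]


# ----------------------------------------------------------------------
def _derivative(values: np.ndarray, wl: np.ndarray, band: int) -> np.ndarray:
    """dR/dλ at a band via central (one-sided at edges) finite difference."""
    lo = max(band - 1, 0)
    hi = min(band + 1, wl.size - 1)
    return (values[:, hi] - values[:, lo]) / (wl[hi] - wl[lo])


def index_resolvable(definition: IndexDefinition,
                     wavelengths_nm: np.ndarray) -> bool:
    """True when every wavelength the formula needs maps onto the grid."""
    return all(resolvable(wavelengths_nm, w)
               for w in definition.required_wavelengths_nm)


def compute_indices(spectra: SpectraTable,
                    registry: list[IndexDefinition] | None = None,
                    on_unresolvable: str = "nan") -> pd.DataFrame:
    """Evaluate index formulas per plot from band means.

    Indices whose required wavelengths fall outside the camera grid are
    filled with NaN (``on_unresolvable="nan"``, logged) or raise
    (``"error"``).  Division by zero or a log of a non-positive reflectance
    yields NaN for that plot and index, with a logged count.
    """
    if registry is None:
        registry = default_registry()
    wl = spectra.wavelengths_nm
    V = spectra.values
    n = V.shape[0]
    out = {}
    for d in registry:
        if not index_resolvable(d, wl):
            msg = (f"index {d.name} needs wavelengths outside the grid "
                   f"({d.required_wavelengths_nm}); filled with NaN")
            if on_unresolvable == "error":
                raise ValueError(msg)
            log.warning(msg)
            out[d.key] = np.full(n, np.nan)
            continue
        env: dict[str, object] = {
            "log": np.log, "sqrt": np.sqrt, "exp": np.exp,
            "dsum": _make_dsum(V, wl), "__builtins__": {},
        }
        for tok in set(re.findall(r"\b([RD]\d+(?:\.\d+)?)\b", d.formula)):
            b = nearest_band(wl, float(tok[1:]))
            env[tok.replace(".", "_")] = (V[:, b] if tok[0] == "R"
                                          else _derivative(V, wl, b))
        formula = re.sub(r"\b([RD]\d+)\.(\d+)\b", r"\1_\2", d.formula)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.asarray(eval(formula, env), dtype=float)  # noqa: S307
        vals = np.broadcast_to(vals, (n,)).copy()
        bad = ~np.isfinite(vals)
        if bad.any():
            log.warning("index %s: %d plots undefined (division by zero "
                        "or log of non-positive reflectance)", d.name,
                        int(bad.sum()))
            vals[bad] = np.nan
        out[d.key] = vals
    return pd.DataFrame(out, index=pd.Index(spectra.plot_ids, name="plot_id"))


def _make_dsum(V: np.ndarray, wl: np.ndarray):
    def dsum(lo: float, hi: float) -> np.ndarray:
        """Integral of dR/dλ over [lo, hi] nm (trapezoid on the grid)."""
        sel = np.flatnonzero((wl >= lo) & (wl <= hi))
        if sel.size < 2:
            raise ValueError(f"dsum({lo}, {hi}): fewer than 2 bands in range")
        deriv = np.column_stack([_derivative(V, wl, b) for b in sel])
        return np.trapezoid(deriv, wl[sel], axis=1)
    return dsum


def simulate_cube(reflectance: np.ndarray, shape: tuple[int, int],
                  wavelengths_nm: np.ndarray | None = None,
                  background_value: float = 0.0,
                  leaf_shape: tuple[int, int] | None = None,
                  noise_sd: float = 0.0, seed: int = 0) -> tuple[HyperspectralCube, np.ndarray]:
    """Toy cube: a rectangular "leaf" carrying ``reflectance`` (+ noise) on a
    constant background.  Returns the cube and the true leaf mask.

    The leaf is centered; its default size is half the cube in each
    dimension.  Raises if the leaf does not fit.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    if wavelengths_nm is None:
        wavelengths_nm = default_wavelength_grid(reflectance.size)
    rows, cols = shape
    if leaf_shape is None:
        leaf_shape = (max(rows // 2, 1), max(cols // 2, 1))
    lr, lc = leaf_shape
    if lr > rows or lc > cols:
        raise ValueError(f"leaf region {leaf_shape} larger than cube {shape}")
    rng = np.random.default_rng(seed)
    cube = np.full((rows, cols, reflectance.size), background_value, dtype=float)
    r0, c0 = (rows - lr) // 2, (cols - lc) // 2
    leaf = reflectance[None, None, :] + (
        rng.normal(0.0, noise_sd, size=(lr, lc, reflectance.size))
        if noise_sd > 0 else 0.0)
    cube[r0:r0 + lr, c0:c0 + lc, :] = leaf
    np.clip(cube, 0.0, 1.0, out=cube)
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r0 + lr, c0:c0 + lc] = True
    return HyperspectralCube(values=cube, wavelengths_nm=wavelengths_nm), mask
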