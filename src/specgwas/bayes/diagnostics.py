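"""MCMC chain diagnostics: effective sample size, Geweke z, trace plots."""

from __future__ import annotations

import numpy as np
import pandas as pd


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence estimator.

    Returns NaN for a degenerate (zero-variance) chain.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float("nan")
    if np.ptp(x) == 0.0:  # constant chain
        return float("nan")
    x = x - x.mean()
    # autocovariance by FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sums of adjacent pairs; truncate at first negative, enforce monotone
    tau = 0.0
    prev = np.inf
    for k in range(0, n - 1, 2):
        g = rho[k] + (rho[k + 1] if k + 1 < n else 0.0)
        if g < 0.0:
            break
        g = min(g, prev)
        prev = g
        tau += g
    tau = max(2.0 * tau - 1.0, 1.0 / n)
    return float(n / tau)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Means of the first ``first`` and last ``last`` fractions are compared
    with ESS-adjusted standard errors.  NaN for degenerate chains.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    ea, eb = effective_sample_size(a), effective_sample_size(b)
    if not (np.isfinite(ea) and np.isfinite(eb)):
        return float("nan")
    se = np.sqrt(a.var(ddof=1) / ea + b.var(ddof=1) / eb)
    if se == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / se)


def diagnostics(samples: dict[str, np.ndarray], outdir=None) -> pd.DataFrame:
    """Per-parameter ESS and Geweke z, with flags; optional trace plots.

    Chains with zero variance are flagged ``degenerate`` (no ESS number);
    |z| > 2 flags potential non-convergence.  With ``outdir`` set, a trace
    plot per parameter is written there.
    """
    rows = []
    for name, chain in samples.items():
        chain = np.asarray(chain, dtype=float)
        if chain.ndim != 1:
            continue
        if chain.size < 10:
            raise ValueError(f"{name}: need >= 10 retained draws")
        degenerate = np.ptp(chain) == 0.0
        e = float("nan") if degenerate else effective_sample_size(chain)
        z = float("nan") if degenerate else geweke_z(chain)
        rows.append({
            "parameter": name,
            "ess": e,
            "geweke_z": z,
            "degenerate": bool(degenerate),
            "flagged": bool(degenerate or (np.isfinite(z) and abs(z) > 2.0)),
        })
    report = pd.DataFrame(rows)
    if outdir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, chain in samples.items():
            chain = np.asarray(chain, dtype=float)
            if chain.ndim != 1:
                continue
            fig, ax = plt.subplots(figsize=(6, 2.2))
            ax.plot(chain, lw=0.6)
            ax.set_xlabel("retained draw")
            ax.set_ylabel(name)
            fig.tight_layout()
            safe = name.replace("/", "_").replace("[", "_").replace("]", "")
            fig.savefig(outdir / f"trace_{safe}.png", dpi=100)
            plt.close(fig)
        report.to_csv(outdir / "diagnostics.csv", index=False)
    return report
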