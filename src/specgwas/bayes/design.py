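"""Fixed-effect design: intercept + replication + block nested in replication.

Reference-level dummy coding: the first replication and the first block
within each replication are absorbed into the intercept, matching the usual
fixed-effect treatment of a randomized design with blocks nested in
replications.  The resulting matrix must be full rank; confounded columns
are named in the error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DesignSpec:
    """Plot-level design factors.

    replication, block : per-plot labels; block labels are interpreted
    within their replication (nesting), so the same block label may recur
    across replications.
    """

    replication: np.ndarray
    block: np.ndarray

    def __post_init__(self):
        self.replication = np.asarray(self.replication, dtype=object)
        self.block = np.asarray(self.block, dtype=object)
        if self.replication.shape != self.block.shape:
            raise ValueError("replication and block must have equal length")

    @property
    def n_plots(self) -> int:
        return self.replication.size

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        """Full-rank design matrix (intercept first) and column names."""
        cols: dict[str, np.ndarray] = {"mu": np.ones(self.n_plots)}
        reps = list(pd.unique(self.replication))
        for r in reps[1:]:
            cols[f"rep[{r}]"] = (self.replication == r).astype(float)
        for r in reps:
            in_r = self.replication == r
            blocks = list(pd.unique(self.block[in_r]))
            for b in blocks[1:]:
                cols[f"block[{r}.{b}]"] = (in_r & (self.block == b)).astype(float)
        names = list(cols)
        X = np.column_stack(list(cols.values()))
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns by greedy rank growth
            bad = []
            kept = np.empty((X.shape[0], 0))
            for i, nm in enumerate(names):
                cand = np.column_stack([kept, X[:, i]])
                if np.linalg.matrix_rank(cand) > kept.shape[1]:
                    kept = cand
                else:
                    bad.append(nm)
            raise ValueError(f"rank-deficient design; confounded columns: {bad}")
        return X, names

    @classmethod
    def from_phenotypes(cls, phenotypes: pd.DataFrame) -> "DesignSpec":
        return cls(replication=phenotypes["replication"].to_numpy(object),
                   block=phenotypes["block"].to_numpy(object))


def resolve_design(design, n: int) -> tuple[np.ndarray | None, list[str]]:
    """Normalize the ``design`` argument of the samplers.

    DesignSpec -> its matrix; ndarray -> used as-is; None -> intercept only;
    False -> no fixed effects at all (known-zero mean, used by oracle
    checks).
    """
    if design is None:
        return np.ones((n, 1)), ["mu"]
    if design is False:
        return None, []
    if isinstance(design, DesignSpec):
        X, names = design.matrix()
        if X.shape[0] != n:
            raise ValueError("design rows != phenotype length")
        return X, names
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("design matrix must be n_plots × p")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, [f"x{i}" for i in range(X.shape[1])]
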