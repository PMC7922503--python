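"""Mirror-tree co-evolution statistic for pairs of protein families.

Two protein families that co-evolve leave similar phylogenies; the
mirror-tree statistic quantifies this as the Pearson correlation
between their inter-protein distance matrices, restricted to organisms
shared by both families and compared entry-by-entry over the strict
lower triangle.  The p-value comes from the usual two-sided t-test on
C(n, 2) pairs; the C(n, 2) distance entries are not independent, so the
p-value is an optimistic screening value, not a calibrated error rate.

Inputs are square distance matrices (PHYLIP square format accepted);
homolog search, alignment and tree building are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats as st


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if n < 3:
            raise ValueError("distance matrix needs at least 3 labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    def reorder(self, labels: Sequence) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), d=self.d[np.ix_(idx, idx)])


class MirrorTreeResult(NamedTuple):
    r: float
    n: int
    p: float


def mirror_tree_r(d1: DistanceMatrix, d2: DistanceMatrix) -> MirrorTreeResult:
    """Correlation between two families' matched inter-protein distances."""
    s1, s2 = set(d1.labels), set(d2.labels)
    if s1 != s2:
        raise ValueError(
            f"label mismatch: only in first {sorted(s1 - s2)}, "
            f"only in second {sorted(s2 - s1)}"
        )
    n = len(d1.labels)
    if n < 4:
        raise ValueError(f"need at least 4 shared organisms, got {n}")
    d2 = d2.reorder(d1.labels)
    tri = np.tril_indices(n, k=-1)
    x, y = d1.d[tri], d2.d[tri]
    res = st.pearsonr(x, y)
    return MirrorTreeResult(r=float(res.statistic), n=n, p=float(res.pvalue))


def read_phylip_square(path) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix (count line, then label + row)."""
    tokens_by_line = [
        l.split() for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()
    ]
    if not tokens_by_line or len(tokens_by_line[0]) != 1:
        raise ValueError(f"{path}: first line must hold the taxon count")
    n = int(tokens_by_line[0][0])
    flat = [t for line in tokens_by_line[1:] for t in line]
    if len(flat) != n * (n + 1):
        raise ValueError(
            f"{path}: expected {n} rows of a label plus {n} distances"
        )
    labels, rows = [], []
    for i in range(n):
        chunk = flat[i * (n + 1):(i + 1) * (n + 1)]
        labels.append(chunk[0])
        rows.append([float(v) for v in chunk[1:]])
    return DistanceMatrix(labels=labels, d=np.array(rows))


def write_phylip_square(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
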