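"""Spearman co-occurrence edges with three-matrix validation.

A pair of GH families co-occurs when species that carry one tend to
carry the other.  Each unordered family pair gets a tie-corrected
Spearman rank correlation in each of the three species-level matrices
(aveF, minF, maxF); the pair is a *validated* edge only if rho > 0.45
with p < 0.001 in all three.  Requiring the correlation to survive both
extreme strain choices guards against edges created by the arbitrary
pick of one strain per species.  Edge strength classes follow the
aveF coefficient: strong (rho > 0.6), moderate-high (0.5 < rho <= 0.6),
moderate-low (0.45 < rho <= 0.5).

A second, species-level network links species whose GH-family profiles
correlate at rho > 0.8 (p < 0.001) on aveF alone.

P-values use the two-sided t approximation with n - 2 degrees of
freedom; no multiple-testing correction is applied by default, matching
the raw-threshold rule, but a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .ghf_io import CountMatrix

logger = logging.getLogger(__name__)

STRENGTH_LEVELS = ("strong", "moderate_high", "moderate_low", "none")


class ConstantInputError(ValueError):
    """A correlation was requested on a constant vector."""


@dataclass(frozen=True)
class EdgeRecord:
    """One family pair's correlations in the three matrices."""

    a: str
    b: str  # a < b lexicographically
    rho_ave: Optional[float]
    rho_min: Optional[float]
    rho_max: Optional[float]
    p_ave: Optional[float]
    p_min: Optional[float]
    p_max: Optional[float]
    validated: bool
    strength: str
    reason: Optional[str] = None  # why a pair could not be validated


@dataclass(frozen=True)
class SpeciesEdge:
    a: str
    b: str
    rho: float
    p: float

    @property
    def weight(self) -> float:
        return self.rho


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined on a constant vector")
    res = st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_strength(rho_ave: Optional[float]) -> str:
    if rho_ave is None:
        return "none"
    if rho_ave > 0.6:
        return "strong"
    if rho_ave > 0.5:
        return "moderate_high"
    if rho_ave > 0.45:
        return "moderate_low"
    return "none"


def _rank_corr_matrix(values: pd.DataFrame, axis: int = 0):
    """(rho, p) matrices of tie-corrected Spearman correlations.

    axis=0 correlates columns, axis=1 correlates rows.  Equivalent to
    mid-ranking each vector and taking Pearson correlations; p-values
    from the t approximation with n - 2 degrees of freedom.
    """
    data = values if axis == 0 else values.T
    n = data.shape[0]
    ranks = data.rank(axis=0, method="average").to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * st.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    labels = list(data.columns)
    return labels, rho, p


def _usable_columns(matrix: CountMatrix) -> list[str]:
    """Columns with non-zero variance; constant columns are skipped (logged)."""
    usable = []
    for c in matrix.columns:
        col = matrix.values[c].to_numpy()
        if (col == col[0]).all():
            logger.info(
                "skipping constant column %s in %s matrix", c, matrix.variant
            )
        else:
            usable.append(c)
    return usable


def pairwise_family_edges(
    ave: CountMatrix,
    minm: CountMatrix,
    maxm: CountMatrix,
    rho_cut: float = 0.45,
    alpha: float = 0.001,
) -> list[EdgeRecord]:
    """All unordered family pairs with the three-matrix validation flag.

    Pairs computable in only some matrices (a family constant in minF,
    say) are reported with ``validated=False`` and a reason code.
    """
    mats = {"ave": ave, "min": minm, "max": maxm}
    for name, m in mats.items():
        if m.row_keys != ave.row_keys:
            raise ValueError(f"row keys of {name} matrix differ from aveF")
        if m.columns != ave.columns:
            raise ValueError(f"columns of {name} matrix differ from aveF")
    if ave.values.shape[0] < 3:
        raise ValueError("need at least 3 species rows")

    usable = {name: set(_usable_columns(m)) for name, m in mats.items()}
    stats = {}
    for name, m in mats.items():
        cols = sorted(usable[name])
        if len(cols) >= 2:
            labels, rho, p = _rank_corr_matrix(m.values[cols], axis=0)
            idx = {c: i for i, c in enumerate(labels)}
            stats[name] = (idx, rho, p)
        else:
            stats[name] = ({}, None, None)

    edges = []
    columns = sorted(ave.columns)  # lexicographic so that a < b
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            vals = {}
            missing = []
            for name in ("ave", "min", "max"):
                if a in usable[name] and b in usable[name]:
                    idx, rho, p = stats[name]
                    vals[name] = (float(rho[idx[a], idx[b]]), float(p[idx[a], idx[b]]))
                else:
                    vals[name] = (None, None)
                    missing.append(name)
            rho_ave, p_ave = vals["ave"]
            rho_min, p_min = vals["min"]
            rho_max, p_max = vals["max"]
            if missing:
                validated = False
                reason = "constant_in_" + "+".join(missing)
            else:
                validated = (
                    min(rho_ave, rho_min, rho_max) > rho_cut
                    and max(p_ave, p_min, p_max) < alpha
                )
                reason = None
            edges.append(
                EdgeRecord(
                    a=a,
                    b=b,
                    rho_ave=rho_ave,
                    rho_min=rho_min,
                    rho_max=rho_max,
                    p_ave=p_ave,
                    p_min=p_min,
                    p_max=p_max,
                    validated=validated,
                    strength=classify_strength(rho_ave),
                    reason=reason,
                )
            )
    return edges


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional alternative to the raw threshold)."""
    return st.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def pair_fraction(n_pairs_hit: int, n_items: int) -> float:
    """Percentage of all unordered item pairs that were hit, to one decimal.

    E.g. 24 validated pairs among 154 families -> 100*24/C(154,2) = 0.2.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    total = comb(n_items, 2)
    if not 0 <= n_pairs_hit <= total:
        raise ValueError(f"n_pairs_hit must be in [0, {total}], got {n_pairs_hit}")
    return round(100.0 * n_pairs_hit / total, 1)


def pairwise_species_edges(
    ave: CountMatrix,
    rho_cut: float = 0.8,
    alpha: float = 0.001,
) -> list[SpeciesEdge]:
    """Edges between species with strongly correlated GH-family profiles.

    Computed on aveF only; species whose profile is constant (including
    all-zero profiles) are excluded and logged.
    """
    if ave.values.shape[1] < 3:
        raise ValueError("need at least 3 GHF columns")
    rows = []
    for key in ave.row_keys:
        prof = ave.values.loc[key].to_numpy()
        if (prof == prof[0]).all():
            logger.info("excluding species %r: constant GH profile", key)
        else:
            rows.append(key)
    if len(rows) < 2:
        return []
    labels, rho, p = _rank_corr_matrix(ave.values.loc[rows], axis=1)
    edges = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if rho[i, j] > rho_cut and p[i, j] < alpha:
                b = labels[j]
                x, y = (a, b) if a < b else (b, a)
                edges.append(SpeciesEdge(a=x, b=y, rho=float(rho[i, j]), p=float(p[i, j])))
    return edges


def edges_to_frame(edges: Sequence[EdgeRecord]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges])


def write_edges(edges: Sequence[EdgeRecord], path) -> None:
    df = edges_to_frame(edges)
    df.to_csv(path, sep="\t", index=False)


def read_edges(path) -> list[EdgeRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for k in ("rho_ave", "rho_min", "rho_max", "p_ave", "p_min", "p_max"):
            if pd.isna(d[k]):
                d[k] = None
        d["reason"] = None if pd.isna(d["reason"]) else d["reason"]
        d["validated"] = bool(d["validated"])
        out.append(EdgeRecord(**d))
    return out
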