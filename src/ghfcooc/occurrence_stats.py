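"""Per-family occurrence statistics and bacteria-vs-archaea comparison.

The occurrence frequency of a GH family in a domain is the number of
species with at least one gene of that family divided by the number of
species in the domain.  The average gene number divides the total genes
by the count of species that *possess* the family (never by all
species), so it is >= 1 whenever defined and is not deflated for rare
families.  Both are computed on the aveF matrix; robustness flags
("always at least 5 percentage points higher", "always one copy
larger") additionally require the condition to hold in minF and maxF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ghf_io import CountMatrix, DOMAINS


@dataclass
class FamilyStats:
    ghf: str
    domain: str  # bacteria | archaea | all
    n_species: int
    n_present: int
    frequency: float
    avg_genes: Optional[float]  # None when the family is absent everywhere


def family_stats(matrix: CountMatrix, domain: str = "all") -> list[FamilyStats]:
    """One :class:`FamilyStats` per GH family for the chosen domain subset."""
    if matrix.variant != "aveF":
        raise ValueError(
            f"occurrence statistics are defined on the aveF matrix, "
            f"got {matrix.variant!r}"
        )
    sub = matrix.subset_domain(domain)
    n_species = sub.values.shape[0]
    if n_species == 0:
        raise ValueError(f"no species in domain subset {domain!r}")
    out = []
    for ghf in sub.columns:
        col = sub.values[ghf]
        present = col > 0
        n_present = int(present.sum())
        avg = float(col[present].sum() / n_present) if n_present else None
        out.append(
            FamilyStats(
                ghf=ghf,
                domain=domain,
                n_species=n_species,
                n_present=n_present,
                frequency=n_present / n_species,
                avg_genes=avg,
            )
        )
    return out


def stats_frame(matrix: CountMatrix, domain: str = "all") -> pd.DataFrame:
    """:func:`family_stats` as a tidy DataFrame indexed by GHF."""
    rows = family_stats(matrix, domain)
    return pd.DataFrame(
        {
            "domain": [s.domain for s in rows],
            "n_species": [s.n_species for s in rows],
            "n_present": [s.n_present for s in rows],
            "frequency": [s.frequency for s in rows],
            "avg_genes": [s.avg_genes for s in rows],
        },
        index=[s.ghf for s in rows],
    )


def _per_domain(matrix: CountMatrix):
    """(freq, avg) Series pairs keyed by domain for one matrix.

    avg is NaN where the family is absent from the domain; the
    "one copy larger" comparison treats an absent family as 0 copies.
    """
    out = {}
    for dom in DOMAINS:
        sub = matrix.subset_domain(dom)
        n = sub.values.shape[0]
        present = sub.values > 0
        n_present = present.sum(axis=0)
        freq = n_present / n if n else n_present * np.nan
        totals = sub.values.where(present, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = totals / n_present
        out[dom] = (freq.astype(float), avg.astype(float))
    return out


def compare_domains(
    ave: CountMatrix, minm: CountMatrix, maxm: CountMatrix
) -> pd.DataFrame:
    """Per-family domain comparison report.

    Columns (values 'bacteria', 'archaea' or None):

    * ``higher_freq_domain`` — which domain has the higher aveF frequency
      (None on ties, including families absent from both).
    * ``exclusive_domain`` — present in exactly one domain (aveF).
    * ``freq_gap_ge_5pct_always`` — frequency at least 5 percentage
      points higher in that domain in aveF, minF and maxF alike.
    * ``avg_genes_one_copy_larger_always`` — average gene number at
      least one copy larger in that domain in all three matrices
      (absent families count as 0 copies).
    """
    mats = {"aveF": ave, "minF": minm, "maxF": maxm}
    cols = ave.columns
    for name, m in mats.items():
        if m.columns != cols:
            raise ValueError(f"matrix {name} columns differ from aveF columns")
    per = {name: _per_domain(m) for name, m in mats.items()}

    def directional(cond_b: pd.Series, cond_a: pd.Series) -> pd.Series:
        out = pd.Series([None] * len(cols), index=cols, dtype=object)
        out[cond_b] = "bacteria"
        out[cond_a] = "archaea"
        return out

    freq_b, _ = per["aveF"]["bacteria"]
    freq_a, _ = per["aveF"]["archaea"]
    higher = directional(freq_b > freq_a, freq_a > freq_b)

    present_b = freq_b > 0
    present_a = freq_a > 0
    exclusive = directional(present_b & ~present_a, present_a & ~present_b)

    gap_b = pd.Series(True, index=cols)
    gap_a = pd.Series(True, index=cols)
    copy_b = pd.Series(True, index=cols)
    copy_a = pd.Series(True, index=cols)
    for name in mats:
        fb, ab = per[name]["bacteria"]
        fa, aa = per[name]["archaea"]
        gap_b &= (fb - fa) >= 0.05
        gap_a &= (fa - fb) >= 0.05
        ab0 = ab.fillna(0.0)
        aa0 = aa.fillna(0.0)
        copy_b &= (ab0 - aa0) >= 1.0
        copy_a &= (aa0 - ab0) >= 1.0

    return pd.DataFrame(
        {
            "higher_freq_domain": higher,
            "exclusive_domain": exclusive,
            "freq_gap_ge_5pct_always": directional(gap_b, gap_a),
            "avg_genes_one_copy_larger_always": directional(copy_b, copy_a),
        },
        index=cols,
    )


def comparison_counts(report: pd.DataFrame) -> dict[str, int]:
    """Summary counts of families per comparison flag and direction."""
    out = {}
    for col in report.columns:
        for dom in DOMAINS:
            out[f"{col}:{dom}"] = int((report[col] == dom).sum())
    return out
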