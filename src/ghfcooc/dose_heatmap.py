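"""Species x functional-group gene-dose matrix (aveG) and its transform.

For every species, the aveF gene counts of each group's member families
are summed (families shared by two groups count toward both), yielding
the raw aveG matrix.  For heatmap display each number is square-rooted
(compressing the heavy right tail of gene doses) and each species row
is then z-scored with the population standard deviation, so that a
row's values express which groups are over- or under-represented in
that species relative to its own average.  Constant rows map to zeros.
A subset of rows (e.g. known cellulolytic species) can be cut out and
re-transformed on the subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .functional_groups import FunctionalGroup
from .ghf_io import CountMatrix

logger = logging.getLogger(__name__)

AXES = ("per_species_row", "per_group_column")


@dataclass
class GroupDoseMatrix:
    raw: pd.DataFrame  # species x groups, integer sums
    transformed: Optional[pd.DataFrame] = None
    axis: Optional[str] = None  # transform axis, once applied


def build_aveG(
    matrix: CountMatrix, groups: Sequence[FunctionalGroup]
) -> GroupDoseMatrix:
    """Sum member-family counts per group; columns ordered by group id."""
    if matrix.variant != "aveF":
        raise ValueError(
            f"gene doses are defined on the aveF matrix, got {matrix.variant!r}"
        )
    known = set(matrix.columns)
    data = {}
    for g in sorted(groups, key=lambda g: g.group_id):
        members = sorted(g.members & known)
        unknown = sorted(g.members - known)
        if unknown:
            logger.warning(
                "group %s references families absent from the matrix "
                "(treated as 0): %s", g.group_id, unknown
            )
        if members:
            data[g.group_id] = matrix.values[members].sum(axis=1)
        else:
            data[g.group_id] = pd.Series(0, index=matrix.values.index)
    raw = pd.DataFrame(data).astype("int64")
    return GroupDoseMatrix(raw=raw)


def _sqrt_zscore(frame: pd.DataFrame, axis: str) -> pd.DataFrame:
    root = np.sqrt(frame.to_numpy(dtype=float))
    ax = 1 if axis == "per_species_row" else 0
    mean = root.mean(axis=ax, keepdims=True)
    sd = root.std(axis=ax, keepdims=True)  # population SD (ddof=0)
    # exact max==min test: identical values can leave a ~1e-16 residual SD
    const = root.max(axis=ax, keepdims=True) == root.min(axis=ax, keepdims=True)
    sd = np.where(const, 1.0, sd)
    z = (root - mean) / sd
    z[np.broadcast_to(const, z.shape)] = 0.0  # constant vectors -> zeros
    return pd.DataFrame(z, index=frame.index, columns=frame.columns)


def transform_doses(
    dm: GroupDoseMatrix, axis: str = "per_species_row"
) -> GroupDoseMatrix:
    """Square root first, then z-score along the chosen axis."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    return GroupDoseMatrix(
        raw=dm.raw, transformed=_sqrt_zscore(dm.raw, axis), axis=axis
    )


def subset_species(dm: GroupDoseMatrix, species: Iterable[str]) -> GroupDoseMatrix:
    """Restrict to the listed species; re-transform on the subset.

    Unknown names are logged and skipped; it is an error if none match.
    """
    wanted = list(species)
    if not wanted:
        raise ValueError("empty species list")
    known = [s for s in wanted if s in dm.raw.index]
    unknown = [s for s in wanted if s not in dm.raw.index]
    if unknown:
        logger.warning("species absent from dose matrix, skipped: %s", unknown)
    if not known:
        raise ValueError("no listed species found in the dose matrix")
    sub = GroupDoseMatrix(raw=dm.raw.loc[known])
    if dm.axis is not None:
        sub = transform_doses(sub, axis=dm.axis)
    return sub


def read_species_list(path) -> list[str]:
    """One species name per line; '#' comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_doses(dm: GroupDoseMatrix, path) -> None:
    frame = dm.transformed if dm.transformed is not None else dm.raw
    with open(path, "w", encoding="utf-8") as fh:
        kind = "transformed" if dm.transformed is not None else "raw"
        fh.write(f"#aveG kind={kind} axis={dm.axis}\n")
        frame.to_csv(fh, sep="\t", index_label="species")


def plot_heatmap(dm: GroupDoseMatrix, path) -> None:
    """Thin optional rendering of the transformed matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = dm.transformed if dm.transformed is not None else dm.raw
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * frame.shape[1]), max(4, 0.02 * frame.shape[0]))
    )
    im = ax.imshow(frame.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(frame.shape[1]), frame.columns)
    ax.set_yticks([])
    ax.set_xlabel("functional group")
    ax.set_ylabel("species")
    fig.colorbar(im, ax=ax, label="z(sqrt gene dose)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
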