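"""Functional groups of GH families and type-X classification of microbes.

Twelve curated groups (A-L) partition the co-occurring GH families by
primary enzyme function: nine network modules, three of which are
subdivided by function into two groups each (lignocellulose A vs pectin
B; hexosaminidases G vs alpha-glycosidases H; fungal-cell-wall K vs
supplemental lignocellulose L).  GH55 and GH64 sit in both K and L;
GH144 (beta-1,2-glucanase) is deliberately ungrouped.  The curated
table ships with the package because the subdivision rests on
literature-curated enzyme functions, not on anything recomputable.

A species is a *type-X* microbe when it carries genes from at least two
families of group X ("partial" fit); "large" fit requires at least 75%
of the group's families and "perfect" fit all of them, so
perfect => large => partial.  For two-family groups the three levels
coincide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .ghf_io import CountMatrix
from .network_analysis import Partition

logger = logging.getLogger(__name__)


class FitLevel(IntEnum):
    none = 0
    partial = 1
    large = 2
    perfect = 3


@dataclass
class FunctionalGroup:
    group_id: str
    members: frozenset
    source_module: str
    function_note: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")


@dataclass
class TypeAssignment:
    species: str
    labels: dict  # group_id -> FitLevel


def _validate_groups(groups: Sequence[FunctionalGroup]) -> None:
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group_id in group table")
    membership: dict[str, int] = {}
    for g in groups:
        for ghf in g.members:
            membership[ghf] = membership.get(ghf, 0) + 1
    over = sorted(g for g, n in membership.items() if n > 2)
    if over:
        raise ValueError(f"GHFs assigned to more than 2 groups: {over}")


def load_group_table(path=None) -> list[FunctionalGroup]:
    """Load a group-definition TSV; defaults to the packaged curated table."""
    if path is None:
        source = resources.files("ghfcooc").joinpath("data/table1_groups.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    if header[:2] != ["group_id", "ghfs"]:
        raise ValueError("group table header must start with group_id, ghfs")
    groups = []
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        groups.append(
            FunctionalGroup(
                group_id=fields["group_id"],
                members=frozenset(g.strip() for g in fields["ghfs"].split(",")),
                source_module=fields.get("source_module", ""),
                function_note=fields.get("function_note", ""),
            )
        )
    _validate_groups(groups)
    return groups


def write_group_table(groups: Sequence[FunctionalGroup], path) -> None:
    from .ghf_io import ghf_sort_key

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tghfs\tsource_module\tfunction_note\n")
        for g in groups:
            members = ",".join(sorted(g.members, key=ghf_sort_key))
            fh.write(f"{g.group_id}\t{members}\t{g.source_module}\t{g.function_note}\n")


SplitMap = Mapping[Union[int, str], Union[str, Mapping[str, object]]]


def derive_groups(partition: Partition, split_map: SplitMap) -> list[FunctionalGroup]:
    """Turn network modules into functional groups, applying subdivisions.

    ``split_map`` assigns each module either a single group label, or a
    per-family mapping family -> label / list of labels (shared
    membership) / None (explicitly ungrouped).  Every module member must
    be covered by a subdivision.
    """
    modules = partition.modules()
    missing = set(modules) - set(split_map)
    if missing:
        raise ValueError(f"split_map does not cover modules: {sorted(missing)}")
    by_label: dict[str, set] = {}
    source: dict[str, str] = {}
    for mod, members in modules.items():
        rule = split_map[mod]
        if isinstance(rule, str):
            by_label.setdefault(rule, set()).update(members)
            source.setdefault(rule, f"M{mod}")
            continue
        uncovered = sorted(set(members) - set(rule))
        if uncovered:
            raise ValueError(
                f"subdivision of module {mod} omits members: {uncovered}"
            )
        for ghf in members:
            labels = rule[ghf]
            if labels is None:
                continue
            if isinstance(labels, str):
                labels = [labels]
            for label in labels:
                by_label.setdefault(label, set()).add(ghf)
                source.setdefault(label, f"M{mod}")
    groups = [
        FunctionalGroup(
            group_id=label,
            members=frozenset(members),
            source_module=source[label],
        )
        for label, members in sorted(by_label.items())
    ]
    _validate_groups(groups)
    return groups


def fit_level(n_present: int, group_size: int) -> FitLevel:
    """Fit of a species to one group from its count of present members."""
    if n_present >= group_size:
        return FitLevel.perfect
    if n_present >= max(2, math.ceil(0.75 * group_size)):
        return FitLevel.large
    if n_present >= 2:
        return FitLevel.partial
    return FitLevel.none


def assign_types(
    matrix: CountMatrix, groups: Sequence[FunctionalGroup]
) -> list[TypeAssignment]:
    """Per species, the fit level for every functional group (on aveF)."""
    if matrix.variant != "aveF":
        raise ValueError(
            f"type assignment is defined on the aveF matrix, got {matrix.variant!r}"
        )
    known = set(matrix.columns)
    out = []
    present_df = matrix.values > 0
    for key in matrix.row_keys:
        present = set(present_df.columns[present_df.loc[key]])
        labels = {}
        for g in groups:
            n = len(present & g.members & known)
            labels[g.group_id] = fit_level(n, len(g.members))
        out.append(TypeAssignment(species=key, labels=labels))
    return out


def assignments_to_frame(assignments: Sequence[TypeAssignment]) -> pd.DataFrame:
    group_ids = sorted({g for a in assignments for g in a.labels})
    return pd.DataFrame(
        [[a.labels[g].name for g in group_ids] for a in assignments],
        index=[a.species for a in assignments],
        columns=group_ids,
    )


def collection(
    assignments: Sequence[TypeAssignment],
    group_id: str,
    fit_min: FitLevel = FitLevel.partial,
) -> set:
    """Species whose fit to ``group_id`` is at least ``fit_min``."""
    out = set()
    for a in assignments:
        if group_id not in a.labels:
            raise ValueError(f"unknown group {group_id!r}")
        if a.labels[group_id] >= fit_min:
            out.add(a.species)
    return out


def phylum_prevalence(
    assignments: Sequence[TypeAssignment],
    taxonomy: Mapping[str, str],
    fit_min: FitLevel = FitLevel.partial,
) -> pd.DataFrame:
    """Per (group, phylum): species count at >= fit_min and the frequency
    relative to all species of that phylum.
    """
    missing = sorted({a.species for a in assignments} - set(taxonomy))
    if missing:
        raise ValueError(f"taxonomy missing for species: {missing}")
    totals: dict[str, int] = {}
    for a in assignments:
        ph = taxonomy[a.species]
        totals[ph] = totals.get(ph, 0) + 1
    group_ids = sorted({g for a in assignments for g in a.labels})
    rows = []
    for gid in group_ids:
        counts: dict[str, int] = {}
        for a in assignments:
            if a.labels[gid] >= fit_min:
                ph = taxonomy[a.species]
                counts[ph] = counts.get(ph, 0) + 1
        for ph in sorted(counts):
            rows.append(
                {
                    "group": gid,
                    "phylum": ph,
                    "count": counts[ph],
                    "frequency": counts[ph] / totals[ph],
                }
            )
    return pd.DataFrame(rows, columns=["group", "phylum", "count", "frequency"])


def collection_overlap(
    assignments: Sequence[TypeAssignment],
    group_x: str,
    group_y: str,
    fit_min: FitLevel = FitLevel.partial,
) -> tuple[float, bool]:
    """Coverage of collection Y by collection X: (|X & Y| / |Y|, Y <= X).

    An empty Y is covered vacuously (1.0, True).
    """
    x = collection(assignments, group_x, fit_min)
    y = collection(assignments, group_y, fit_min)
    if not y:
        return 1.0, True
    return len(x & y) / len(y), y <= x
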