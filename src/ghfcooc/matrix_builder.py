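"""Collapse strain-level GH profiles to one row per species.

Public genome collections often contain many sequenced strains for a few
well-studied species and a single strain for most others, which biases
any across-species statistic toward the popular species.  Three
de-biased species-level matrices are built:

* **aveF** — per species, the arithmetic mean gene count of each family
  over its strains, rounded half-away-from-zero to an integer.
* **minF** — per species, the full count vector of the single strain
  carrying the *fewest* distinct GH families.
* **maxF** — likewise for the strain carrying the *most* families.

When several strains tie on the number of families present, minF takes
the strain whose name sorts first alphabetically and maxF the one that
sorts last, which makes the selection deterministic and independent of
input order.  Strains without a species label are grouped by genus
instead.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ghf_io import CountMatrix, GenomeRecord, ghf_sort_key


def dedupe_key(record: GenomeRecord) -> tuple[str, str]:
    """Grouping key: the species, or the genus when no species is named."""
    if record.species:
        return ("species", record.species)
    if record.genus:
        return ("genus", record.genus)
    raise ValueError(
        f"strain {record.strain_name!r} has neither species nor genus"
    )


def _strain_sort_key(record: GenomeRecord) -> tuple[str, str]:
    # case-insensitive, locale-free collation of strain names
    return (record.strain_name.casefold(), record.strain_name)


def _group_records(
    records: Sequence[GenomeRecord],
) -> dict[tuple[str, str], list[GenomeRecord]]:
    if not records:
        raise ValueError("no records given")
    groups: dict[tuple[str, str], list[GenomeRecord]] = defaultdict(list)
    for r in records:
        groups[dedupe_key(r)].append(r)
    labels = [k[1] for k in groups]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(
            f"row key collision between species- and genus-level groups: {dup}"
        )
    return dict(groups)


def _group_taxonomy(key: tuple[str, str], members: list[GenomeRecord]) -> tuple[str, str]:
    domains = {r.domain for r in members}
    if len(domains) > 1:
        raise ValueError(
            f"group {key[1]!r} mixes domains {sorted(domains)}"
        )
    phyla = {r.phylum for r in members}
    if len(phyla) > 1:
        raise ValueError(
            f"group {key[1]!r} mixes phyla {sorted(phyla)}"
        )
    return next(iter(domains)), next(iter(phyla))


def _round_half_away(x: float) -> int:
    # counts are non-negative, so half-away-from-zero is floor(x + 0.5)
    return int(math.floor(x + 0.5))


def _assemble(
    variant: str,
    rows: dict[str, dict[str, int]],
    taxonomy: dict[str, tuple[str, str]],
    columns: list[str],
) -> CountMatrix:
    keys = sorted(rows, key=lambda k: (k.casefold(), k))
    values = pd.DataFrame(
        [[rows[k].get(c, 0) for c in columns] for k in keys],
        index=keys,
        columns=columns,
        dtype="int64",
    )
    tax = pd.DataFrame(
        {"domain": [taxonomy[k][0] for k in keys],
         "phylum": [taxonomy[k][1] for k in keys]},
        index=keys,
    )
    return CountMatrix(variant=variant, values=values, taxonomy=tax)


def _union_columns(records: Sequence[GenomeRecord]) -> list[str]:
    return sorted({g for r in records for g in r.counts}, key=ghf_sort_key)


def build_aveF(records: Sequence[GenomeRecord]) -> CountMatrix:
    """Average gene counts per species, rounded half-away-from-zero."""
    groups = _group_records(records)
    columns = _union_columns(records)
    rows, taxonomy = {}, {}
    for key, members in groups.items():
        taxonomy[key[1]] = _group_taxonomy(key, members)
        n = len(members)
        rows[key[1]] = {
            c: _round_half_away(sum(r.counts.get(c, 0) for r in members) / n)
            for c in columns
        }
    return _assemble("aveF", rows, taxonomy, columns)


def _build_extreme(records: Sequence[GenomeRecord], variant: str) -> CountMatrix:
    groups = _group_records(records)
    columns = _union_columns(records)
    rows, taxonomy = {}, {}
    for key, members in groups.items():
        taxonomy[key[1]] = _group_taxonomy(key, members)
        if variant == "minF":
            n_target = min(r.n_families_present() for r in members)
            tied = [r for r in members if r.n_families_present() == n_target]
            chosen = min(tied, key=_strain_sort_key)
        else:
            n_target = max(r.n_families_present() for r in members)
            tied = [r for r in members if r.n_families_present() == n_target]
            chosen = max(tied, key=_strain_sort_key)
        rows[key[1]] = {c: chosen.counts.get(c, 0) for c in columns}
    return _assemble(variant, rows, taxonomy, columns)


def build_minF(records: Sequence[GenomeRecord]) -> CountMatrix:
    """Per species, the count vector of the strain with fewest GH families."""
    return _build_extreme(records, "minF")


def build_maxF(records: Sequence[GenomeRecord]) -> CountMatrix:
    """Per species, the count vector of the strain with most GH families."""
    return _build_extreme(records, "maxF")


def build_all(records: Sequence[GenomeRecord]) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """Convenience: (aveF, minF, maxF) with identical rows and columns."""
    return build_aveF(records), build_minF(records), build_maxF(records)


def drop_all_zero_columns(matrix: CountMatrix) -> CountMatrix:
    """Optional post-step removing families absent from every row."""
    keep = matrix.values.columns[(matrix.values != 0).any(axis=0)]
    return CountMatrix(
        variant=matrix.variant,
        values=matrix.values[list(keep)],
        taxonomy=matrix.taxonomy,
    )
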