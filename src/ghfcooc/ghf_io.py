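"""Reading and writing genome GH-family profiles and count matrices.

The on-disk dialect is UTF-8 tab-separated text.  A genome-profile table
has five fixed metadata columns (strain_name, species, genus, domain,
phylum) followed by one column per glycoside hydrolase family ("GH13",
"GH5", ...), holding non-negative integer gene counts.  Lines starting
with ``#`` are comments.  An empty count cell is read as 0; anything
that is not a plain non-negative integer is an error — counts are never
silently coerced.

A count matrix file carries its construction variant (aveF, minF, maxF
or raw) in a ``#variant=...`` comment header so that downstream stages
can enforce which matrix they were given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

META_COLUMNS = ("strain_name", "species", "genus", "domain", "phylum")
DOMAINS = ("bacteria", "archaea")
VARIANTS = ("aveF", "minF", "maxF", "raw")

_INT_RE = re.compile(r"^\d+$")


class FormatError(ValueError):
    """Raised when an input file violates the TSV dialect."""


def ghf_sort_key(ghf: str) -> tuple:
    """Sort key ordering GH families by their family number (GH5 < GH13)."""
    if ghf.startswith("GH") and ghf[2:].isdigit():
        return (0, int(ghf[2:]), ghf)
    return (1, 0, ghf)


@dataclass
class GenomeRecord:
    """One sequenced strain: taxonomy labels plus gene counts per GH family."""

    strain_name: str
    species: str
    genus: str
    domain: str
    phylum: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.strain_name:
            raise ValueError("strain_name must be non-empty")
        if self.domain not in DOMAINS:
            raise ValueError(
                f"domain for strain {self.strain_name!r} must be one of "
                f"{DOMAINS}, got {self.domain!r}"
            )
        for ghf, n in self.counts.items():
            if isinstance(n, bool) or not isinstance(n, int):
                raise ValueError(
                    f"count for {ghf} in strain {self.strain_name!r} is not "
                    f"an integer: {n!r}"
                )
            if n < 0:
                raise ValueError(
                    f"count for {ghf} in strain {self.strain_name!r} is "
                    f"negative: {n}"
                )

    def n_families_present(self) -> int:
        """Number of distinct GH families with at least one gene."""
        return sum(1 for n in self.counts.values() if n >= 1)


@dataclass(eq=False)
class CountMatrix:
    """Species (or genus) x GH-family integer matrix with taxonomy labels.

    ``values`` is indexed by row key (species name, or genus name for
    strains lacking a species label); ``taxonomy`` shares the index and
    holds ``domain`` and ``phylum`` columns.
    """

    variant: str
    values: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown matrix variant {self.variant!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate row keys: {dups}")
        if list(self.taxonomy.index) != list(self.values.index):
            raise ValueError("taxonomy index does not match matrix rows")
        for col in ("domain", "phylum"):
            if col not in self.taxonomy.columns:
                raise ValueError(f"taxonomy missing column {col!r}")
        bad_domain = set(self.taxonomy["domain"]) - set(DOMAINS)
        if bad_domain:
            raise ValueError(f"unknown domain labels: {sorted(bad_domain)}")
        if self.values.size:
            if self.values.to_numpy().dtype.kind not in "iu":
                raise ValueError("matrix values must be integers")
            if (self.values.to_numpy() < 0).any():
                raise ValueError("matrix values must be non-negative")

    @property
    def row_keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.variant == other.variant
            and self.values.equals(other.values)
            and self.taxonomy.equals(other.taxonomy)
        )

    def subset_domain(self, domain: str) -> "CountMatrix":
        """Rows restricted to one domain ('bacteria'|'archaea') or 'all'."""
        if domain == "all":
            return self
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        mask = self.taxonomy["domain"] == domain
        return CountMatrix(
            variant=self.variant,
            values=self.values.loc[mask],
            taxonomy=self.taxonomy.loc[mask],
        )


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_count(cell: str, lineno: int, column: str, path) -> int:
    cell = cell.strip()
    if cell == "":
        return 0
    if not _INT_RE.match(cell):
        raise FormatError(
            f"{path}: line {lineno}, column {column!r}: count {cell!r} is "
            "not a non-negative integer"
        )
    return int(cell)


def read_genome_table(path) -> list[GenomeRecord]:
    """Parse a genome-profile TSV into one :class:`GenomeRecord` per row."""
    path = Path(path)
    rows = _data_lines(path)
    try:
        _, header_line = next(iter(rows))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    header = header_line.split("\t")
    if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
        raise FormatError(
            f"{path}: header must start with {list(META_COLUMNS)}, "
            f"got {header[:5]}"
        )
    ghf_columns = header[len(META_COLUMNS):]
    if len(set(ghf_columns)) != len(ghf_columns):
        raise FormatError(f"{path}: duplicated GHF columns in header")

    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        strain, species, genus, domain, phylum = fields[:5]
        if strain in seen:
            raise FormatError(f"{path}: duplicate strain_name {strain!r}")
        seen.add(strain)
        if domain not in DOMAINS:
            raise FormatError(
                f"{path}: line {lineno}: unknown domain {domain!r} for "
                f"strain {strain!r}"
            )
        counts = {
            ghf: _parse_count(cell, lineno, ghf, path)
            for ghf, cell in zip(ghf_columns, fields[5:])
        }
        records.append(
            GenomeRecord(
                strain_name=strain,
                species=species,
                genus=genus,
                domain=domain,
                phylum=phylum,
                counts=counts,
            )
        )
    return records


def write_genome_table(records: Iterable[GenomeRecord], path) -> None:
    """Write records as a genome-profile TSV.

    Columns are the union of all GH families seen in any record, sorted
    by family number; missing counts are written as 0.
    """
    records = list(records)
    if not records:
        raise ValueError("nothing to write: no records")
    ghfs = sorted({g for r in records for g in r.counts}, key=ghf_sort_key)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(list(META_COLUMNS) + ghfs) + "\n")
        for r in records:
            meta = [r.strain_name, r.species, r.genus, r.domain, r.phylum]
            counts = [str(r.counts.get(g, 0)) for g in ghfs]
            fh.write("\t".join(meta + counts) + "\n")


def write_matrix(matrix: CountMatrix, path) -> None:
    """Serialize a count matrix; the variant goes into a comment header."""
    matrix.validate()
    if matrix.values.shape[0] == 0:
        raise ValueError("nothing to write: matrix has no rows")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#variant={matrix.variant}\n")
        fh.write("\t".join(["row_key", "domain", "phylum"] + matrix.columns) + "\n")
        for key in matrix.row_keys:
            tax = matrix.taxonomy.loc[key]
            row = matrix.values.loc[key]
            fh.write(
                "\t".join(
                    [key, tax["domain"], tax["phylum"]]
                    + [str(int(v)) for v in row]
                )
                + "\n"
            )


def read_matrix(path) -> CountMatrix:
    """Inverse of :func:`write_matrix`; errors if the variant header is absent."""
    path = Path(path)
    variant = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#variant="):
                variant = line.split("=", 1)[1]
                break
            if line and not line.startswith("#"):
                break
    if variant is None:
        raise FormatError(f"{path}: missing '#variant=' header")

    rows = _data_lines(path)
    _, header_line = next(iter(rows))
    header = header_line.split("\t")
    if header[:3] != ["row_key", "domain", "phylum"]:
        raise FormatError(f"{path}: matrix header must start with row_key/domain/phylum")
    ghfs = header[3:]
    keys, doms, phyla, data = [], [], [], []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: line {lineno}: field count mismatch")
        keys.append(fields[0])
        doms.append(fields[1])
        phyla.append(fields[2])
        data.append([_parse_count(c, lineno, g, path) for g, c in zip(ghfs, fields[3:])])
    values = pd.DataFrame(data, index=keys, columns=ghfs, dtype="int64")
    taxonomy = pd.DataFrame({"domain": doms, "phylum": phyla}, index=keys)
    return CountMatrix(variant=variant, values=values, taxonomy=taxonomy)


def records_to_frame(records: Iterable[GenomeRecord]) -> pd.DataFrame:
    """Strain-level DataFrame (rows = strains) used by the matrix builders."""
    records = list(records)
    ghfs = sorted({g for r in records for g in r.counts}, key=ghf_sort_key)
    data = [[r.counts.get(g, 0) for g in ghfs] for r in records]
    return pd.DataFrame(
        data, index=[r.strain_name for r in records], columns=ghfs, dtype="int64"
    )
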