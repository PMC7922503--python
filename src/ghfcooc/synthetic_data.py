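"""Seeded synthetic prokaryotic communities with planted co-occurrence.

The generator emulates the statistical shape of a genome-annotation
snapshot — a few hundred species, each with one or more sequenced
strains, and an integer gene count per GH family — while planting a
known co-occurrence structure that downstream network inference should
recover:

* Families are split into *planted groups* plus a background pool.
* Each species independently *activates* each group with that group's
  activation probability; members of an activated group are present
  with high probability (``within_group_presence``), everything else
  appears at a small background rate (``p_background``).  This makes
  families of one group strongly rank-correlated across species while
  families of different groups stay independent.
* A present family's species-level gene count is 1 + Poisson(lambda-1),
  a zero-truncated-style law giving the zero-inflated, right-skewed
  counts seen in real genome profiles.
* Strains of a species perturb the species profile: each present
  family is dropped or duplicated with probability ``strain_noise``
  (half each way), so the aveF/minF/maxF builders have real work to do.
* Optionally each planted group prefers one phylum
  (``phylum_affinity`` multiplies its activation there), reproducing
  the module-phylum correspondence of species networks.

Everything is a deterministic function of the seed.  The latent draws
(which species activated which groups) are returned as a
:class:`PlantedTruth` so that recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cooccurrence import EdgeRecord
from .ghf_io import GenomeRecord
from .network_analysis import Partition

ARCHAEAL_PHYLA = (("Euryarchaeota", 0.6), ("Crenarchaeota", 0.4))
BACTERIAL_PHYLA = (
    ("Proteobacteria", 0.35),
    ("Firmicutes", 0.20),
    ("Actinobacteria", 0.15),
    ("Bacteroidetes", 0.15),
    ("Cyanobacteria", 0.06),
    ("Acidobacteria", 0.05),
    ("Planctomycetes", 0.04),
)


@dataclass(frozen=True)
class PlantedGroup:
    members: tuple
    activation: float
    preferred_phylum: Optional[str] = None


def default_groups_for(
    n_families: int, group_size: int = 6, activation: float = 0.5
) -> tuple:
    """Plant groups of ``group_size`` families over the first half of the
    family set, leaving the rest as background (the default 60-family
    layout gives 5 groups of 6 over GH1..GH30, background GH31..GH60)."""
    n_planted = n_families // 2
    groups = []
    start = 1
    while start + group_size - 1 <= n_planted:
        groups.append(
            PlantedGroup(
                members=tuple(f"GH{i}" for i in range(start, start + group_size)),
                activation=activation,
            )
        )
        start += group_size
    return tuple(groups)


def _default_groups() -> tuple:
    return default_groups_for(60)


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the defaults are the package's study conditions."""

    n_species: int = 500
    strains_per_species: tuple = (1, 3)  # inclusive range
    n_families: int = 60
    planted_groups: tuple = field(default_factory=_default_groups)
    p_background: float = 0.03
    within_group_presence: float = 0.95
    count_lambda: float = 2.0
    strain_noise: float = 0.05
    archaea_fraction: float = 0.06
    bacterial_phyla: tuple = BACTERIAL_PHYLA
    archaeal_phyla: tuple = ARCHAEAL_PHYLA
    phylum_affinity: float = 1.0  # >1 ties planted groups to preferred phyla
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        lo, hi = self.strains_per_species
        if not (1 <= lo <= hi):
            raise ValueError("strains_per_species must be a range with lo >= 1")
        for p in (self.p_background, self.within_group_presence,
                  self.strain_noise, self.archaea_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        fams = set(self.family_names())
        for g in self.planted_groups:
            if not 0.0 <= g.activation <= 1.0:
                raise ValueError(f"activation out of [0,1]: {g.activation}")
            if not set(g.members) <= fams:
                raise ValueError(
                    f"planted group members {sorted(set(g.members) - fams)} "
                    "outside the family set"
                )

    def family_names(self) -> list[str]:
        return [f"GH{i}" for i in range(1, self.n_families + 1)]


def null_params(**overrides) -> SimParams:
    """All families background: no planted structure at all."""
    return replace(SimParams(planted_groups=()), **overrides)


def with_phylum_affinity(params: SimParams, affinity: float = 3.0) -> SimParams:
    """Give each planted group a preferred bacterial phylum, cyclically."""
    phyla = [name for name, _ in params.bacterial_phyla]
    groups = tuple(
        replace(g, preferred_phylum=phyla[i % len(phyla)])
        for i, g in enumerate(params.planted_groups)
    )
    return replace(params, planted_groups=groups, phylum_affinity=affinity)


@dataclass
class PlantedTruth:
    """Latent generator state needed to score recovery."""

    active_groups: dict  # species row key -> frozenset of group indices
    membership: dict  # family -> planted group index
    expected_pairs: set  # sorted (a, b) tuples within co-activated groups


def _choose(rng: np.random.Generator, weighted: Sequence[tuple]) -> str:
    names = [n for n, _ in weighted]
    w = np.array([w for _, w in weighted], dtype=float)
    return names[rng.choice(len(names), p=w / w.sum())]


def generate_community(params: SimParams) -> tuple[list[GenomeRecord], PlantedTruth]:
    """Draw a strain-level community and its planted ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    families = params.family_names()
    fam_idx = {f: i for i, f in enumerate(families)}

    membership = {
        f: gi for gi, g in enumerate(params.planted_groups) for f in g.members
    }

    records: list[GenomeRecord] = []
    active_by_species: dict[str, frozenset] = {}
    activators: dict[int, int] = {gi: 0 for gi in range(len(params.planted_groups))}

    def draw_count() -> int:
        lam = max(params.count_lambda - 1.0, 0.0)
        return 1 + int(rng.poisson(lam))

    for i in range(params.n_species):
        genus = f"Genus{i % 40:02d}"
        species = f"{genus} sp{i:04d}"
        is_archaeon = rng.random() < params.archaea_fraction
        domain = "archaea" if is_archaeon else "bacteria"
        phylum = _choose(
            rng, params.archaeal_phyla if is_archaeon else params.bacterial_phyla
        )

        active = []
        for gi, g in enumerate(params.planted_groups):
            p = g.activation
            if (
                params.phylum_affinity != 1.0
                and g.preferred_phylum is not None
                and phylum == g.preferred_phylum
            ):
                p = min(1.0, p * params.phylum_affinity)
            if rng.random() < p:
                active.append(gi)
                activators[gi] += 1
        active_by_species[species] = frozenset(active)

        base = np.zeros(len(families), dtype=np.int64)
        active_members = {
            f for gi in active for f in params.planted_groups[gi].members
        }
        for f in families:
            if f in active_members:
                if rng.random() < params.within_group_presence:
                    base[fam_idx[f]] = draw_count()
            elif rng.random() < params.p_background:
                base[fam_idx[f]] = draw_count()

        n_strains = int(
            rng.integers(params.strains_per_species[0], params.strains_per_species[1] + 1)
        )
        for k in range(n_strains):
            counts = base.copy()
            if params.strain_noise > 0:
                for j in np.nonzero(base)[0]:
                    u = rng.random()
                    if u < params.strain_noise / 2:
                        counts[j] = 0  # dropout
                    elif u < params.strain_noise:
                        counts[j] += 1  # duplication
            records.append(
                GenomeRecord(
                    strain_name=f"{species} str{k:02d}",
                    species=species,
                    genus=genus,
                    domain=domain,
                    phylum=phylum,
                    counts={f: int(counts[fam_idx[f]]) for f in families},
                )
            )

    expected_pairs = set()
    for gi, g in enumerate(params.planted_groups):
        if activators[gi] >= 2:
            members = sorted(g.members)
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    expected_pairs.add((members[x], members[y]))

    truth = PlantedTruth(
        active_groups=active_by_species,
        membership=membership,
        expected_pairs=expected_pairs,
    )
    return records, truth


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    adjusted_rand: float
    n_predicted: int
    n_expected: int
    precision_defined: bool  # False when no pairs were predicted


def score_recovery(
    truth: PlantedTruth,
    edges: Sequence[EdgeRecord],
    partition: Optional[Partition] = None,
) -> RecoveryScore:
    """Set-overlap precision/recall of validated pairs, plus module ARI.

    The adjusted Rand index compares detected modules with planted group
    memberships, restricted to planted families that made it into the
    network; with no partition (or fewer than two such families) it is
    reported as 0.  An empty prediction has precision 1 by convention,
    flagged via ``precision_defined=False``.
    """
    predicted = {
        tuple(sorted((e.a, e.b))) for e in edges if e.validated
    }
    expected = set(truth.expected_pairs)
    hit = predicted & expected
    if predicted:
        precision, defined = len(hit) / len(predicted), True
    else:
        precision, defined = 1.0, False
    recall = len(hit) / len(expected) if expected else 1.0

    ari = 0.0
    if partition is not None:
        shared = sorted(set(truth.membership) & set(partition.assignment))
        if len(shared) >= 2:
            from sklearn.metrics import adjusted_rand_score

            ari = float(
                adjusted_rand_score(
                    [truth.membership[f] for f in shared],
                    [partition.assignment[f] for f in shared],
                )
            )
    return RecoveryScore(
        precision=precision,
        recall=recall,
        adjusted_rand=ari,
        n_predicted=len(predicted),
        n_expected=len(expected),
        precision_defined=defined,
    )
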