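"""Greedy centroid clustering and the hierarchical putative-taxon scaffold.

Clustering follows UCLUST semantics: sequences are processed longest first
(ties by id), each is assigned to the first existing centroid within the
level's divergence radius, otherwise it seeds a new cluster. The seven-level
scaffold clusters the species level over all sequences, then re-clusters the
centroids of each level at the next (wider) radius, so cluster membership
nests by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from taxoscaffold.align import AlignParams, global_align_identity
from taxoscaffold.seqio import RANKS, SeqRecord

#: Default per-level hypersphere radii, % divergence from the centroid.
#: The "kingdom" level of the hierarchy occupies the domain slot.
DEFAULT_RADII: dict[str, float] = {
    "species": 1.5,
    "genus": 2.5,
    "family": 3.5,
    "order": 4.5,
    "class": 6.0,
    "phylum": 11.0,
    "domain": 12.5,
}

#: Scaffold build order: deepest rank first.
LEVEL_ORDER: tuple[str, ...] = tuple(reversed(RANKS))


@dataclass(frozen=True)
class LevelConfig:
    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        vals = [self.radii[r] for r in LEVEL_ORDER]
        if sorted(set(vals)) != vals:
            raise ValueError("radii must be strictly increasing species -> kingdom")

    def identity_threshold(self, rank: str) -> float:
        return 100.0 - self.radii[rank]


def radius_to_ani(radius: float) -> float:
    """Worst-case member-to-member ANI of a cluster with the given radius.

    Two members may each sit the full radius from the centroid, so the
    cluster diameter is twice the radius and the implied ANI is
    ``100 - 2 * radius`` percent.
    """
    return 100.0 - 2.0 * radius


@dataclass(frozen=True)
class Cluster:
    level: str
    centroid_id: str
    member_ids: tuple[str, ...]  # includes the centroid

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")


def greedy_cluster(
    seqs: Sequence[SeqRecord],
    radius: float,
    params: AlignParams = AlignParams(),
    level: str = "",
    best_centroid: bool = False,
) -> list[Cluster]:
    """Length-sorted greedy centroid clustering at a divergence radius.

    ``best_centroid=True`` assigns each sequence to the qualifying centroid
    of highest identity instead of the first created one.
    """
    if not 0.0 < radius < 50.0:
        raise ValueError("radius must be in (0, 50) percent divergence")
    threshold = 100.0 - radius
    order = sorted(seqs, key=lambda r: (-r.length, r.id))
    centroids: list[SeqRecord] = []
    members: list[list[str]] = []
    for rec in order:
        chosen = None
        best_ident = -1.0
        for i, cen in enumerate(centroids):
            ident = global_align_identity(rec, cen, params).identity
            if ident >= threshold:
                if not best_centroid:
                    chosen = i
                    break
                if ident > best_ident:
                    best_ident, chosen = ident, i
        if chosen is None:
            centroids.append(rec)
            members.append([rec.id])
        else:
            members[chosen].append(rec.id)
    return [
        Cluster(level, cen.id, tuple(m)) for cen, m in zip(centroids, members)
    ]


@dataclass(frozen=True)
class TaxonScaffold:
    """Per-rank membership maps (id -> centroid id) plus centroid ids."""

    assignments: Mapping[str, Mapping[str, str]]
    centroids: Mapping[str, tuple[str, ...]]
    clusters: Mapping[str, tuple[Cluster, ...]]

    def centroid_of(self, seq_id: str, rank: str) -> str:
        return self.assignments[rank][seq_id]

    def ids(self) -> tuple[str, ...]:
        return tuple(self.assignments["species"].keys())

    def check_nesting(self) -> int:
        """Count nesting violations (should always be zero)."""
        violations = 0
        ids = list(self.ids())
        for shallow, deep in zip(LEVEL_ORDER[1:], LEVEL_ORDER[:-1]):
            deep_groups: dict[str, set[str]] = {}
            for i in ids:
                deep_groups.setdefault(self.assignments[deep][i], set()).add(
                    self.assignments[shallow][i]
                )
            violations += sum(len(v) - 1 for v in deep_groups.values())
        return violations


def build_scaffold(
    seqs: Sequence[SeqRecord],
    levels: LevelConfig = LevelConfig(),
    params: AlignParams = AlignParams(),
    best_centroid: bool = False,
) -> TaxonScaffold:
    """Hierarchical seven-level clustering.

    Species-level clustering runs over all sequences; every shallower level
    clusters the previous level's centroid sequences at its own radius.
    """
    by_id = {rec.id: rec for rec in seqs}
    assignments: dict[str, dict[str, str]] = {}
    centroid_ids: dict[str, tuple[str, ...]] = {}
    all_clusters: dict[str, tuple[Cluster, ...]] = {}

    pool = list(seqs)
    # id -> centroid at the previous (deeper) level; identity map to start
    chain = {rec.id: rec.id for rec in seqs}
    for rank in LEVEL_ORDER:
        clusters = greedy_cluster(
            pool, levels.radii[rank], params, level=rank, best_centroid=best_centroid
        )
        local = {m: c.centroid_id for c in clusters for m in c.member_ids}
        chain = {seq_id: local[prev] for seq_id, prev in chain.items()}
        assignments[rank] = dict(chain)
        centroid_ids[rank] = tuple(c.centroid_id for c in clusters)
        all_clusters[rank] = tuple(clusters)
        pool = [by_id[c.centroid_id] for c in clusters]
    return TaxonScaffold(assignments, centroid_ids, all_clusters)


def scaffold_to_tsv(scaffold: TaxonScaffold, path) -> None:
    """TSV: id then the centroid id at each of the seven levels."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(RANKS) + "\n")
        for seq_id in scaffold.ids():
            row = [scaffold.assignments[r][seq_id] for r in RANKS]
            fh.write(seq_id + "\t" + "\t".join(row) + "\n")


def clusters_to_uc(clusters: Sequence[Cluster], path) -> None:
    """Minimal UC-like export (S/H records with centroid column)."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(f"S\t{i}\t*\t*\t*\t*\t*\t*\t{c.centroid_id}\t*\n")
            for m in c.member_ids:
                if m != c.centroid_id:
                    fh.write(f"H\t{i}\t*\t*\t*\t*\t*\t*\t{m}\t{c.centroid_id}\n")
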