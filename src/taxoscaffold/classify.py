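"""Taxonomic annotation: threshold LCA, bootstrapped k-mers, single best hit.

All three classifiers emit an :class:`Assignment` whose lineage uses ``?``
for unresolved ranks. The LCA and best-hit outputs satisfy the prefix
property (nothing resolved below an unresolved rank); best-hit annotation
against a fully populated (KSGP+-style) database propagates putative
``cl_<rank>_<centroid>`` labels as-is.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from taxoscaffold.align import AlignParams, Hit, search_best_hits
from taxoscaffold.seqio import RANKS, Lineage, SeqRecord, UNRESOLVED, make_label

#: Minimum percent identity required to assign at each rank.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "species": 97.0,
    "genus": 95.0,
    "family": 93.0,
    "order": 91.0,
    "class": 88.0,
    "phylum": 78.0,
    "domain": 75.0,
}


@dataclass(frozen=True)
class RankThresholds:
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        vals = [self.thresholds[r] for r in RANKS]  # domain -> species
        if sorted(set(vals)) != vals:
            raise ValueError("thresholds must be strictly decreasing species -> domain")

    def __getitem__(self, rank: str) -> float:
        return self.thresholds[rank]


@dataclass(frozen=True)
class Assignment:
    query_id: str
    lineage: Lineage
    supports: Mapping[str, float]
    method: str  # "lca" | "boot" | "besthit"

    @property
    def depth(self) -> int:
        return self.lineage.depth


def lca_assign(
    hits: Sequence[Hit],
    ref_lineages: Mapping[str, Lineage],
    thresholds: RankThresholds = RankThresholds(),
    consensus_f: float = 0.9,
    query_id: str | None = None,
) -> Assignment:
    """Rank-thresholded lowest-common-ancestor assignment.

    Working down from domain, only hits whose identity reaches the rank's
    threshold and that carry a label there are eligible; a taxon is assigned
    when it accounts for at least ``consensus_f`` of eligible hits, else the
    rank (and everything deeper) stays ``?``.
    """
    qid = query_id if query_id is not None else (hits[0].query_id if hits else "")
    labels = list(Lineage.empty().ranks)
    supports: dict[str, float] = {}
    for i, rank in enumerate(RANKS):
        eligible = [
            h
            for h in hits
            if h.identity >= thresholds[rank] and ref_lineages[h.ref_id][rank].resolved
        ]
        if not eligible:
            break
        counts: dict[str, int] = {}
        for h in eligible:
            name = ref_lineages[h.ref_id][rank].name
            counts[name] = counts.get(name, 0) + 1
        winner = max(counts, key=lambda n: (counts[n], n))
        frac = counts[winner] / len(eligible)
        if frac < consensus_f:
            break
        labels[i] = make_label(winner, rank)
        supports[rank] = frac
    return Assignment(qid, Lineage(tuple(labels)), supports, "lca")


def _query_rng(query_id: str, seed: int) -> np.random.Generator:
    # one independent stream per query, order-independent across a run
    return np.random.default_rng([seed, zlib.crc32(query_id.encode())])


def _forward_kmers(seq: str, k: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w and w not in seen:
            seen.add(w)
            out.append(w)
    return out


def boot_assign(
    query: SeqRecord,
    refs: Sequence[SeqRecord],
    ref_lineages: Mapping[str, Lineage],
    k: int = 8,
    subsample: int = 32,
    n_boot: int = 100,
    cutoff: float = 0.8,
    seed: int = 0,
) -> Assignment:
    """Bootstrapped k-mer classification (SINTAX-style).

    Each bootstrap draws ``subsample`` of the query's distinct k-mers with
    replacement and votes for the reference sharing most of them (ties to
    the lexicographically smallest reference id). Per-rank support is the
    fraction of bootstraps agreeing on the modal taxon; ranks are assigned
    where support reaches ``cutoff``, truncated at the first failure.
    """
    empty = Assignment(query.id, Lineage.empty(), {}, "boot")
    if len(query.seq) < k:
        return empty
    qk = _forward_kmers(query.seq, k)
    if not qk:
        return empty

    ordered = sorted(refs, key=lambda r: r.id)
    ref_sets = [set(_forward_kmers(r.seq, k)) for r in ordered]
    membership = np.array(
        [[w in s for w in qk] for s in ref_sets], dtype=np.int32
    )  # refs x query k-mers

    rng = _query_rng(query.id, seed)
    votes: list[int] = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(qk), size=subsample)
        counts = membership[:, idx].sum(axis=1)
        votes.append(int(np.argmax(counts)))  # first max = smallest ref id

    labels = list(Lineage.empty().ranks)
    supports: dict[str, float] = {}
    truncated = False
    for i, rank in enumerate(RANKS):
        tally: dict[str, int] = {}
        for v in votes:
            name = ref_lineages[ordered[v].id][rank].name
            tally[name] = tally.get(name, 0) + 1
        winner = max(tally, key=lambda n: (tally[n], n))
        support = tally[winner] / n_boot
        supports[rank] = support
        if truncated or support < cutoff or winner == "?":
            truncated = True
            continue
        labels[i] = make_label(winner, rank)
    return Assignment(query.id, Lineage(tuple(labels)), supports, "boot")


def besthit_annotate(
    query: SeqRecord,
    db: Sequence[SeqRecord],
    db_lineages: Mapping[str, Lineage],
    params: AlignParams = AlignParams(),
    thresholds: RankThresholds = RankThresholds(),
) -> Assignment:
    """Copy the single best hit's lineage, masking ranks above the identity.

    The database must carry fully populated lineages (named or putative at
    all seven ranks): with mixed named/putative databases only single-best-
    hit annotation is sound, and partially resolved references would break
    that contract.
    """
    for rec in db:
        lin = db_lineages.get(rec.id)
        if lin is None or not lin.is_full:
            raise ValueError(
                f"reference {rec.id} lacks a fully populated lineage; "
                "best-hit annotation requires a KSGP+-style database "
                "(named or putative labels at all seven ranks)"
            )
    hits = search_best_hits(query, db, params, top_n=1)
    if not hits:
        return Assignment(query.id, Lineage.empty(), {}, "besthit")
    best = hits[0]
    labels = []
    supports: dict[str, float] = {}
    for rank, lbl in zip(RANKS, db_lineages[best.ref_id].ranks):
        if thresholds[rank] > best.identity:
            labels.append(UNRESOLVED)
        else:
            labels.append(lbl)
            supports[rank] = 1.0
    return Assignment(query.id, Lineage(tuple(labels)), supports, "besthit")
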