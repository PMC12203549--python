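"""Database-coverage diagnostics.

Best single match per query with the identity gate disabled (only a 25%
query-overlap floor), cumulative similarity curves by query rank and by
abundance, and paired two-database profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from taxoscaffold.align import AlignParams, search_best_hits
from taxoscaffold.seqio import SeqRecord


@dataclass(frozen=True)
class QueryCoverage:
    query_id: str
    similarity: float | None  # percent; None = no hit
    abundance: float
    ref_id: str | None


@dataclass(frozen=True)
class CoverageProfile:
    entries: tuple[QueryCoverage, ...]

    @property
    def pct_with_hit(self) -> float:
        if not self.entries:
            return 0.0
        hits = sum(1 for e in self.entries if e.similarity is not None)
        return 100.0 * hits / len(self.entries)

    @property
    def unique_refs(self) -> int:
        """References that are some query's best hit."""
        return len({e.ref_id for e in self.entries if e.ref_id is not None})


def coverage_profile(
    queries: Sequence[SeqRecord],
    db: Sequence[SeqRecord],
    params: AlignParams = AlignParams(),
) -> CoverageProfile:
    """Best-hit similarity per query with thresholds disabled."""
    relaxed = params.relaxed()
    entries = []
    for q in queries:
        hits = search_best_hits(q, db, relaxed, top_n=1)
        if hits:
            entries.append(QueryCoverage(q.id, hits[0].identity, q.abundance, hits[0].ref_id))
        else:
            entries.append(QueryCoverage(q.id, None, q.abundance, None))
    return CoverageProfile(tuple(entries))


def cumulative_curves(
    profile: CoverageProfile, drop_nohit: bool = False
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Similarity vs cumulative query fraction and cumulative abundance.

    Similarities are sorted descending; queries without a hit contribute
    similarity 0 (or are dropped with ``drop_nohit``). Both curves end at
    cumulative fraction 1.0 exactly.
    """
    entries = [
        e for e in profile.entries if not (drop_nohit and e.similarity is None)
    ]
    scored = sorted(
        ((e.similarity if e.similarity is not None else 0.0, e.abundance) for e in entries),
        key=lambda x: -x[0],
    )
    if not scored:
        return [], []
    n = len(scored)
    total_ab = sum(ab for _, ab in scored) or 1.0
    by_rank: list[tuple[float, float]] = []
    by_abundance: list[tuple[float, float]] = []
    cum_ab = 0.0
    for i, (sim, ab) in enumerate(scored, start=1):
        cum_ab += ab
        by_rank.append((sim, i / n))
        by_abundance.append((sim, cum_ab / total_ab))
    # guard against float drift at the endpoint
    by_abundance[-1] = (by_abundance[-1][0], 1.0)
    return by_rank, by_abundance


def paired_profile(
    queries: Sequence[SeqRecord],
    db_a: Sequence[SeqRecord],
    db_b: Sequence[SeqRecord],
    params: AlignParams = AlignParams(),
) -> list[tuple[str, float, float]]:
    """Per-query best-hit similarity in two databases (0 = no hit)."""
    prof_a = coverage_profile(queries, db_a, params)
    prof_b = coverage_profile(queries, db_b, params)
    out = []
    for ea, eb in zip(prof_a.entries, prof_b.entries):
        out.append(
            (ea.query_id, ea.similarity or 0.0, eb.similarity or 0.0)
        )
    return out


def profile_to_tsv(profile: CoverageProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsimilarity\tabundance\tref_id\n")
        for e in profile.entries:
            sim = f"{e.similarity:.4f}" if e.similarity is not None else "NA"
            fh.write(f"{e.query_id}\t{sim}\t{e.abundance}\t{e.ref_id or 'NA'}\n")


def pairs_to_tsv(pairs: Sequence[tuple[str, float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsimilarity_a\tsimilarity_b\n")
        for qid, sa, sb in pairs:
            fh.write(f"{qid}\t{sa:.4f}\t{sb:.4f}\n")
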