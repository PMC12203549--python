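"""Pairwise identity and best-hit search.

The alignment primitive is semi-global (free terminal gaps, affine internal
gaps) with BLAST-style identity: matching columns divided by alignment
columns between the first and last column in which both sequences have a
residue. Internal gap columns count against identity; ``N`` never counts as
a match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from taxoscaffold.seqio import SeqRecord

_PREFILTER_K = 8


@dataclass(frozen=True)
class AlignParams:
    """Scoring and search parameters (USEARCH-local style defaults)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open_internal: float = 10.0
    gap_extend_internal: float = 1.0
    min_identity: float = 0.75
    min_query_cov: float = 0.25
    maxaccepts: int | float = 100
    maxrejects: int | float = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be a fraction in [0, 1]")
        if not 0.0 <= self.min_query_cov <= 1.0:
            raise ValueError("min_query_cov must be a fraction in [0, 1]")

    def relaxed(self) -> "AlignParams":
        """Same scoring with identity/coverage gates effectively disabled."""
        return AlignParams(
            match=self.match,
            mismatch=self.mismatch,
            gap_open_internal=self.gap_open_internal,
            gap_extend_internal=self.gap_extend_internal,
            min_identity=0.0,
            min_query_cov=0.25,
            maxaccepts=math.inf,
            maxrejects=math.inf,
        )


@dataclass(frozen=True)
class Hit:
    """A query-to-reference match."""

    query_id: str
    ref_id: str
    identity: float  # percent, in [0, 100]
    query_cov: float  # fraction of query residues inside the aligned region
    aln_len: int  # alignment columns excluding terminal gaps

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity out of range")
        if not 0.0 < self.query_cov <= 1.0:
            raise ValueError("query coverage out of range")


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    alphabet = "ACGTN"
    m = np.full((5, 5), mismatch, dtype=float)
    for i in range(4):
        m[i, i] = match
    # N aligns at mismatch score against everything, including itself
    mat = substitution_matrices.Array(alphabet, dims=2, data=m)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_internal_gap_score = -gap_open
    aligner.extend_internal_gap_score = -gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def global_align_identity(
    a: str | SeqRecord,
    b: str | SeqRecord,
    params: AlignParams = AlignParams(),
) -> Hit:
    """Align query ``a`` against ``b`` semi-globally; return identity/coverage.

    Deterministic: the first optimal traceback reported by the Gotoh
    implementation is used.
    """
    query_id = a.id if isinstance(a, SeqRecord) else "query"
    ref_id = b.id if isinstance(b, SeqRecord) else "ref"
    qseq = a.seq if isinstance(a, SeqRecord) else a
    rseq = b.seq if isinstance(b, SeqRecord) else b
    if not qseq or not rseq:
        raise ValueError("cannot align empty sequences")

    aligner = _aligner(
        params.match, params.mismatch, params.gap_open_internal, params.gap_extend_internal
    )
    aln = aligner.align(qseq, rseq)[0]
    ga, gb = str(aln[0]), str(aln[1])

    # trim terminal-gap columns: keep [i0, i1] where both rows have residues
    i0, i1 = 0, len(ga) - 1
    while i0 <= i1 and (ga[i0] == "-" or gb[i0] == "-"):
        i0 += 1
    while i1 >= i0 and (ga[i1] == "-" or gb[i1] == "-"):
        i1 -= 1
    if i1 < i0:  # no overlapping residues at the optimum
        return Hit(query_id, ref_id, 0.0, 1.0 / len(qseq), 0)

    cols = i1 - i0 + 1
    matches = 0
    qres = 0
    for ca, cb in zip(ga[i0 : i1 + 1], gb[i0 : i1 + 1]):
        if ca != "-":
            qres += 1
        if ca == cb and ca != "-" and ca != "N":
            matches += 1
    identity = 100.0 * matches / cols
    query_cov = qres / len(qseq)
    return Hit(query_id, ref_id, identity, query_cov, cols)


@lru_cache(maxsize=8192)
def kmer_set(seq: str, k: int = _PREFILTER_K) -> frozenset[str]:
    """Distinct forward k-mers containing no N (prefilter ordering only)."""
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            out.add(w)
    return frozenset(out)


def search_best_hits(
    query: SeqRecord,
    db: Sequence[SeqRecord],
    params: AlignParams = AlignParams(),
    top_n: int = 1,
) -> list[Hit]:
    """Best database hits for a query under identity/coverage gates.

    Candidates are visited in descending shared-k-mer order (ties by ref id);
    scanning stops after ``maxaccepts`` accepted hits or ``maxrejects``
    consecutive rejections. Accepted hits are returned sorted by identity
    descending, then ref id ascending, truncated to ``top_n``. An empty list
    means "no database match".
    """
    if not db:
        raise ValueError("empty reference database")
    qkmers = kmer_set(query.seq)
    order = sorted(db, key=lambda r: (-len(qkmers & kmer_set(r.seq)), r.id))

    accepted: list[Hit] = []
    consecutive_rejects = 0
    for ref in order:
        hit = global_align_identity(query, ref, params)
        if hit.identity >= params.min_identity * 100.0 and hit.query_cov >= params.min_query_cov:
            accepted.append(hit)
            consecutive_rejects = 0
            if len(accepted) >= params.maxaccepts:
                break
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= params.maxrejects:
                break
    accepted.sort(key=lambda h: (-h.identity, h.ref_id))
    return accepted[:top_n]


def hits_to_tsv(hits: Sequence[Hit], path) -> None:
    """BLAST-tab-like export: qid, rid, identity, aln_len, qcov."""
    with open(path, "w") as fh:
        fh.write("query_id\tref_id\tidentity\taln_len\tquery_cov\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.ref_id}\t{h.identity:.4f}\t{h.aln_len}\t{h.query_cov:.4f}\n"
            )
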