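"""Reference-set screening: rank congruence, duplicates, chimeras.

The congruence screen is a leave-one-out nearest-centroid test on canonical
k-mer profiles: each sequence is compared against the mean profile of every
taxon at the tested rank, its own taxon's centroid being recomputed without
it. A sequence whose nearest centroid disagrees with its label is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from taxoscaffold.align import AlignParams
from taxoscaffold.seqio import Lineage, SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScreenReport:
    seq_id: str
    rank_tested: str
    labeled: str
    predicted: str
    score_margin: float
    verdict: str  # "keep" | "flag"

    def __post_init__(self) -> None:
        if self.verdict == "flag" and self.labeled == self.predicted:
            raise ValueError("flag verdict requires a label/prediction mismatch")
        if self.score_margin < 0:
            raise ValueError("score margin must be non-negative")


def kmer_profile(seq: str, k: int) -> dict[str, int]:
    """Counts of canonical (strand-collapsed) k-mers; N windows dropped."""
    if not 3 <= k <= 16:
        raise ValueError("k must be in [3, 16]")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = w.translate(_COMPLEMENT)[::-1]
        canon = min(w, rc)
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def _unit(profile: Mapping[str, int]) -> dict[str, float]:
    norm = math.sqrt(sum(v * v for v in profile.values()))
    return {key: v / norm for key, v in profile.items()}


def _dot(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    if len(b) < len(a):
        a, b = b, a
    return sum(v * b.get(key, 0.0) for key, v in a.items())


def _cosine(unit_profile: Mapping[str, float], centroid: Mapping[str, float]) -> float:
    cn = math.sqrt(sum(v * v for v in centroid.values()))
    if cn == 0.0:
        return 0.0
    return _dot(unit_profile, centroid) / cn


def screen_at_rank(
    records: Sequence[SeqRecord],
    labels: Mapping[str, str],
    rank: str,
    k: int = 8,
) -> list[ScreenReport]:
    """Leave-one-out nearest-centroid screen for one rank partition.

    Ties (zero margin) keep the original label; single-member taxa are kept
    with a warning since they cannot be screened leave-one-out.
    """
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(labels[rec.id], []).append(rec.id)
    if len(groups) < 2:
        logger.warning("rank %s: fewer than two taxa, nothing to screen", rank)
        return [
            ScreenReport(r.id, rank, labels[r.id], labels[r.id], 0.0, "keep")
            for r in records
        ]

    unit_profiles = {rec.id: _unit(kmer_profile(rec.seq, k)) for rec in records}
    sums: dict[str, dict[str, float]] = {}
    for rec in records:
        acc = sums.setdefault(labels[rec.id], {})
        for key, v in unit_profiles[rec.id].items():
            acc[key] = acc.get(key, 0.0) + v

    reports: list[ScreenReport] = []
    for rec in records:
        own = labels[rec.id]
        prof = unit_profiles[rec.id]
        if len(groups[own]) == 1:
            logger.warning(
                "rank %s: taxon %s has a single member (%s); kept unscreened",
                rank, own, rec.id,
            )
            reports.append(ScreenReport(rec.id, rank, own, own, 0.0, "keep"))
            continue
        sims: dict[str, float] = {}
        for taxon, acc in sums.items():
            if taxon == own:
                centroid = {key: v for key, v in acc.items()}
                for key, v in prof.items():  # exact leave-one-out
                    centroid[key] = centroid.get(key, 0.0) - v
            else:
                centroid = acc
            sims[taxon] = _cosine(prof, centroid)
        best_other, best_sim = max(
            ((t, s) for t, s in sims.items() if t != own), key=lambda ts: (ts[1], ts[0])
        )
        if best_sim > sims[own]:
            reports.append(
                ScreenReport(rec.id, rank, own, best_other, best_sim - sims[own], "flag")
            )
        else:  # ties favour the label: no flag without positive evidence
            reports.append(ScreenReport(rec.id, rank, own, own, 0.0, "keep"))
    return reports


def domain_screen(
    records: Sequence[SeqRecord],
    lineages: Mapping[str, Lineage],
    k: int = 8,
) -> list[ScreenReport]:
    """Screen domain labels by leave-one-out nearest centroid."""
    labels = {rec.id: lineages[rec.id]["domain"].name for rec in records}
    if len(set(labels.values())) < 2:
        raise ValueError("domain screening requires at least two domains")
    return screen_at_rank(records, labels, "domain", k=k)


def loot_screen(
    records: Sequence[SeqRecord],
    lineages: Mapping[str, Lineage],
    ranks: Sequence[str] = ("domain", "phylum", "class"),
    k: int = 8,
) -> tuple[list[ScreenReport], list[str]]:
    """Two-pass leave-one-out screen.

    Pass 1 screens the shallowest requested rank and removes flags; pass 2
    screens the survivors at every requested rank and removes flags. Returns
    all reports plus the surviving ids in input order.
    """
    for rec in records:
        for rank in ranks:
            if not lineages[rec.id][rank].resolved:
                raise ValueError(f"sequence {rec.id} unlabelled at rank {rank}")

    reports: list[ScreenReport] = []
    survivors = list(records)

    def run(pool: list[SeqRecord], rank: str) -> set[str]:
        labels = {rec.id: lineages[rec.id][rank].name for rec in pool}
        batch = screen_at_rank(pool, labels, rank, k=k)
        reports.extend(batch)
        return {r.seq_id for r in batch if r.verdict == "flag"}

    flagged = run(survivors, ranks[0])
    survivors = [r for r in survivors if r.id not in flagged]
    flagged = set()
    for rank in ranks:
        flagged |= run(survivors, rank)
    survivors = [r for r in survivors if r.id not in flagged]
    return reports, [r.id for r in survivors]


def dedupe(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Drop byte-identical residue duplicates, keeping first occurrence."""
    seen: set[str] = set()
    out: list[SeqRecord] = []
    for rec in records:
        if rec.seq in seen:
            continue
        seen.add(rec.seq)
        out.append(rec)
    if len(out) < len(records):
        logger.info("dedupe: removed %d duplicate sequences", len(records) - len(out))
    return out


@dataclass(frozen=True)
class ChimeraReport:
    query_id: str
    flagged: bool
    best_single_identity: float
    best_chimeric_identity: float
    parent_a: str | None
    parent_b: str | None
    breakpoint: int | None  # query coordinate


def _query_match_mask(query: SeqRecord, parent: SeqRecord, params: AlignParams) -> np.ndarray:
    """Boolean per-query-position array: residue aligns to an identical one."""
    from taxoscaffold.align import _aligner  # shared scoring machinery

    aligner = _aligner(
        params.match, params.mismatch, params.gap_open_internal, params.gap_extend_internal
    )
    aln = aligner.align(query.seq, parent.seq)[0]
    gq, gp = str(aln[0]), str(aln[1])
    mask = np.zeros(len(query.seq), dtype=bool)
    qi = 0
    for cq, cp in zip(gq, gp):
        if cq != "-":
            if cq == cp and cq != "N":
                mask[qi] = True
            qi += 1
    return mask


def chimera_screen(
    queries: Sequence[SeqRecord],
    parents: Sequence[SeqRecord],
    min_gain: float = 2.0,
    stride: int = 10,
    params: AlignParams = AlignParams(),
) -> list[ChimeraReport]:
    """Flag queries better explained by a two-parent model.

    For each breakpoint (scanned at ``stride`` nt along the query) the
    best prefix parent and best suffix parent are combined; the query is
    flagged when the combined identity beats the best single parent by at
    least ``min_gain`` percentage points. Symmetric in parent roles by
    construction (all ordered pairs are searched).
    """
    if not parents:
        raise ValueError("chimera screen requires at least one parent")
    reports: list[ChimeraReport] = []
    for query in queries:
        L = len(query.seq)
        masks = {p.id: _query_match_mask(query, p, params) for p in parents}
        totals = {pid: int(m.sum()) for pid, m in masks.items()}
        cums = {pid: np.concatenate(([0], np.cumsum(m))) for pid, m in masks.items()}
        best_single = max(totals.values()) / L * 100.0

        best_chim = -1.0
        best = (None, None, None)
        for b in range(stride, L, stride):
            pa, pre = max(
                ((pid, int(c[b])) for pid, c in cums.items()), key=lambda x: (x[1], x[0])
            )
            pb, suf = max(
                ((pid, totals[pid] - int(c[b])) for pid, c in cums.items()),
                key=lambda x: (x[1], x[0]),
            )
            ident = (pre + suf) / L * 100.0
            if ident > best_chim:
                best_chim = ident
                best = (pa, pb, b)
        flagged = best_chim >= best_single + min_gain
        reports.append(
            ChimeraReport(query.id, flagged, best_single, best_chim, *best)
        )
    return reports


def screen_reports_to_tsv(reports: Iterable[ScreenReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\trank_tested\tlabeled\tpredicted\tscore_margin\tverdict\n")
        for r in reports:
            fh.write(
                f"{r.seq_id}\t{r.rank_tested}\t{r.labeled}\t{r.predicted}\t"
                f"{r.score_margin:.6f}\t{r.verdict}\n"
            )
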