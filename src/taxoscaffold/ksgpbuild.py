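"""Reference-database construction pipeline.

``build_reference`` cleans a species-labelled core set (two-pass
leave-one-out screen, deduplication), concatenates outgroup references and
annotates an unlabelled long-read collection with two tiers (threshold LCA
and bootstrapped k-mers). ``ksgp_plus`` fuses LCA lineages with the
hierarchical cluster scaffold so every sequence carries a label at all
seven ranks; ``classify_reads`` runs relaxed best-hit classification for
short reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from taxoscaffold.align import AlignParams, search_best_hits
from taxoscaffold.classify import (
    Assignment,
    RankThresholds,
    besthit_annotate,
    boot_assign,
    lca_assign,
)
from taxoscaffold.cluster import TaxonScaffold
from taxoscaffold.hygiene import dedupe, loot_screen
from taxoscaffold.seqio import RANKS, Lineage, SeqRecord, putative_label


@dataclass(frozen=True)
class BuildConfig:
    min_length: int = 1200  # long-read length filter for the unlabelled set
    length_filter: bool = True
    loot_ranks: tuple[str, ...] = ("domain", "phylum", "class")
    screen_k: int = 8
    align: AlignParams = AlignParams()
    thresholds: RankThresholds = RankThresholds()
    consensus_f: float = 0.9
    boot_k: int = 8
    boot_subsample: int = 32
    n_boot: int = 100
    boot_cutoff: float = 0.8
    seed: int = 0


@dataclass
class BuildResult:
    reference_records: list[SeqRecord]  # cleaned core + outgroups ("GTDB+")
    reference_lineages: dict[str, Lineage]
    lca_assignments: dict[str, Assignment]  # tier 1, per unlabelled id
    boot_assignments: dict[str, Assignment]  # tier 2, per unlabelled id
    report: dict[str, int]  # stage counts


def build_reference(
    core_db: Sequence[SeqRecord],
    core_lineages: Mapping[str, Lineage],
    outgroup_dbs: Sequence[SeqRecord],
    outgroup_lineages: Mapping[str, Lineage],
    unlabelled: Sequence[SeqRecord],
    config: BuildConfig = BuildConfig(),
) -> BuildResult:
    """Clean, merge and annotate: the full database-construction pipeline."""
    for rec in core_db:
        if core_lineages[rec.id].depth < len(RANKS):
            raise ValueError(f"core sequence {rec.id} is not labelled to species")
    for rec in outgroup_dbs:
        if not outgroup_lineages[rec.id]["domain"].resolved:
            raise ValueError(f"outgroup sequence {rec.id} lacks a domain label")

    _, survivor_ids = loot_screen(
        core_db, core_lineages, ranks=config.loot_ranks, k=config.screen_k
    )
    survivor_set = set(survivor_ids)
    survivors = [r for r in core_db if r.id in survivor_set]
    n_flagged = len(core_db) - len(survivors)

    kept = dedupe(survivors)
    n_dup = len(survivors) - len(kept)

    reference = list(kept) + list(outgroup_dbs)
    lineages: dict[str, Lineage] = {
        **{r.id: core_lineages[r.id] for r in kept},
        **{r.id: outgroup_lineages[r.id] for r in outgroup_dbs},
    }

    candidates = [
        r
        for r in unlabelled
        if not config.length_filter or r.length >= config.min_length
    ]
    n_short = len(unlabelled) - len(candidates)

    lca_out: dict[str, Assignment] = {}
    boot_out: dict[str, Assignment] = {}
    for query in candidates:
        hits = search_best_hits(
            query, reference, config.align, top_n=int(config.align.maxaccepts)
        )
        lca_out[query.id] = lca_assign(
            hits,
            lineages,
            thresholds=config.thresholds,
            consensus_f=config.consensus_f,
            query_id=query.id,
        )
        boot_out[query.id] = boot_assign(
            query,
            reference,
            lineages,
            k=config.boot_k,
            subsample=config.boot_subsample,
            n_boot=config.n_boot,
            cutoff=config.boot_cutoff,
            seed=config.seed,
        )

    report = {
        "core_in": len(core_db),
        "core_flagged": n_flagged,
        "core_deduplicated": n_dup,
        "core_kept": len(kept),
        "outgroups": len(outgroup_dbs),
        "reference_total": len(reference),
        "unlabelled_in": len(unlabelled),
        "unlabelled_short": n_short,
        "unlabelled_annotated": len(candidates),
    }
    return BuildResult(reference, lineages, lca_out, boot_out, report)


def ksgp_plus(
    lca_annotated: Mapping[str, Lineage],
    scaffold: TaxonScaffold,
) -> dict[str, Lineage]:
    """Substitute putative cluster taxa for every unresolved rank.

    Each ``?`` becomes ``cl_<rank>_<centroid>`` from the scaffold, so the
    output lineages are fully populated; named ranks are left untouched.
    """
    out: dict[str, Lineage] = {}
    for seq_id, lineage in lca_annotated.items():
        labels = []
        for rank, lbl in zip(RANKS, lineage.ranks):
            if lbl.resolved:
                labels.append(lbl)
            else:
                try:
                    centroid = scaffold.centroid_of(seq_id, rank)
                except KeyError:
                    raise KeyError(
                        f"sequence {seq_id} missing from the {rank}-level scaffold"
                    ) from None
                labels.append(putative_label(rank, centroid))
        out[seq_id] = Lineage(tuple(labels))
    return out


def min_aligned_length(read_length: int, min_query_cov: float) -> int:
    """Smallest aligned length (bp) passing the coverage gate for a read."""
    return math.ceil(read_length * min_query_cov)


@dataclass(frozen=True)
class ReadSummary:
    by_domain: Mapping[str, int]
    by_phylum: Mapping[str, int]
    unassigned: int


def classify_reads(
    reads: Sequence[SeqRecord],
    db: Sequence[SeqRecord],
    db_lineages: Mapping[str, Lineage],
    min_identity: float = 0.75,
    min_query_cov: float = 0.3,
    params: AlignParams = AlignParams(),
    thresholds: RankThresholds = RankThresholds(),
) -> tuple[list[Assignment], ReadSummary]:
    """Best-hit classification of short reads under relaxed gates."""
    relaxed = AlignParams(
        match=params.match,
        mismatch=params.mismatch,
        gap_open_internal=params.gap_open_internal,
        gap_extend_internal=params.gap_extend_internal,
        min_identity=min_identity,
        min_query_cov=min_query_cov,
        maxaccepts=params.maxaccepts,
        maxrejects=params.maxrejects,
    )
    assignments = [
        besthit_annotate(read, db, db_lineages, relaxed, thresholds) for read in reads
    ]
    by_domain: dict[str, int] = {}
    by_phylum: dict[str, int] = {}
    unassigned = 0
    for a in assignments:
        dom = a.lineage["domain"]
        if not dom.resolved:
            unassigned += 1
            continue
        by_domain[dom.name] = by_domain.get(dom.name, 0) + 1
        phy = a.lineage["phylum"]
        if phy.resolved:
            by_phylum[phy.name] = by_phylum.get(phy.name, 0) + 1
    return assignments, ReadSummary(by_domain, by_phylum, unassigned)


def report_to_tsv(report: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for key, val in report.items():
            fh.write(f"{key}\t{val}\n")
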