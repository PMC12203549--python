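"""Seeded synthetic communities with known truth.

Generates labelled multi-rank reference sets with rank-calibrated
divergences, query OTUs at controlled distance from the references,
injected mislabels, duplicates and two-parent chimeras. Everything is
deterministic for a given seed; realized mutation counts are returned so
tests can check them against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from taxoscaffold.seqio import RANKS, Lineage, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T

#: Expected % substitutions separating sibling taxa at each rank, chosen to
#: straddle the default clustering radii (within-species divergence is 1%).
DEFAULT_RANK_DIVERGENCE: dict[str, float] = {
    "species": 4.0,
    "genus": 8.0,
    "family": 12.0,
    "order": 16.0,
    "class": 22.0,
    "phylum": 26.0,
    "domain": 30.0,
}

#: Taxa per parent at each rank for the default worked fixture
#: (1 lineage down to 3 genera x 5 species x 4 sequences).
DEFAULT_BRANCHING: dict[str, int] = {
    "domain": 1,
    "phylum": 1,
    "class": 1,
    "order": 1,
    "family": 1,
    "genus": 3,
    "species": 5,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    branching: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_BRANCHING))
    seqs_per_species: int = 4
    rank_divergence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_DIVERGENCE)
    )
    within_species_divergence: float = 0.5
    seq_length: int = 1400
    indel_rate: float = 0.0005
    abundance_p: float = 0.3  # geometric abundance parameter
    #: (weight, % divergence) mixture for query distance to the source ref
    query_divergence_mix: tuple[tuple[float, float], ...] = ((0.5, 0.0), (0.5, 5.0))

    def __post_init__(self) -> None:
        vals = [self.rank_divergence[r] for r in RANKS]  # domain -> species
        if sorted(set(vals), reverse=True) != vals:
            raise ValueError(
                "rank divergences must be strictly increasing species -> domain"
            )


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> tuple[str, int]:
    """Mutate per-site at ``divergence``% (uniform over the 3 alternatives).

    Indels occur per-site at ``indel_rate`` with geometric lengths (mean
    1.5); insertions and deletions are equally likely. Returns the mutated
    sequence and the realized substitution count.
    """
    if not 0.0 <= divergence <= 50.0:
        raise ValueError("divergence must be in [0, 50] percent")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.array([_BASE_INDEX.get(b, 0) for b in arr], dtype=np.int64)

    sub_mask = rng.random(len(arr)) < divergence / 100.0
    sub_mask &= np.isin(arr, _BASES)  # never substitute N
    n_subs = int(sub_mask.sum())
    if n_subs:
        shift = rng.integers(1, 4, size=n_subs)
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
        arr[sub_mask] = _BASES[codes[sub_mask]]

    if indel_rate > 0.0:
        events = np.flatnonzero(rng.random(len(arr)) < indel_rate)
        if events.size:
            out = []
            prev = 0
            for pos in events:
                length = int(rng.geometric(2.0 / 3.0))  # mean 1.5
                insert = rng.random() < 0.5
                out.append(arr[prev:pos])
                if insert:
                    out.append(rng.choice(_BASES, size=length))
                    prev = pos
                else:
                    prev = pos + length
            out.append(arr[prev:])
            arr = np.concatenate(out) if out else arr
    if arr.size == 0:  # pathological deletion of everything
        arr = rng.choice(_BASES, size=1)
    return arr.tobytes().decode(), n_subs


@dataclass(frozen=True)
class SimReference:
    records: tuple[SeqRecord, ...]
    lineages: Mapping[str, Lineage]  # truth: id -> full 7-rank lineage

    def taxa_at(self, rank: str) -> set[str]:
        return {lin[rank].name for lin in self.lineages.values()}


def simulate_reference(config: SimConfig = SimConfig()) -> SimReference:
    """Generate a labelled reference set by descending the rank tree.

    Sibling taxa at each rank are separated by the configured divergence
    (each child is mutated at half that distance from the parent sequence);
    leaf sequences within a species are separated by the within-species
    divergence. All domains descend from one random ancestor.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _random_seq(config.seq_length, rng)

    records: list[SeqRecord] = []
    lineages: dict[str, Lineage] = {}

    def descend(rank_idx: int, parent_seq: str, names: tuple[str, ...]) -> None:
        rank = RANKS[rank_idx]
        half = config.rank_divergence[rank] / 2.0
        for t in range(config.branching[rank]):
            child_seq, _ = mutate_sequence(
                parent_seq, half, config.indel_rate, rng=rng
            )
            label = f"{rank[0]}{t + 1:02d}"
            taxon = label if not names else f"{names[-1]}.{label}"
            child_names = names + (taxon,)
            if rank == "species":
                for j in range(config.seqs_per_species):
                    leaf, _ = mutate_sequence(
                        child_seq,
                        config.within_species_divergence / 2.0,
                        config.indel_rate,
                        rng=rng,
                    )
                    seq_id = f"{taxon}_seq{j + 1}"
                    records.append(SeqRecord(seq_id, leaf, source="sim"))
                    lineages[seq_id] = Lineage.from_names(child_names)
            else:
                descend(rank_idx + 1, child_seq, child_names)

    descend(0, ancestor, ())
    return SimReference(tuple(records), lineages)


def inject_mislabels(
    sim: SimReference,
    n: int,
    mode: str = "domain",
    seed: int = 0,
) -> tuple[dict[str, Lineage], list[str]]:
    """Relabel ``n`` random records with another taxon's lineage at ``mode``.

    The victim keeps its sequence but adopts a donor's labels from the
    target rank down to species, so deeper ranks stay internally
    consistent. Returns the modified lineage map and the injected ids.
    """
    if n >= len(sim.records):
        raise ValueError("cannot mislabel the entire database")
    rank_idx = RANKS.index(mode)
    by_taxon: dict[str, list[str]] = {}
    for seq_id, lin in sim.lineages.items():
        by_taxon.setdefault(lin[mode].name, []).append(seq_id)
    if len(by_taxon) < 2:
        raise ValueError(f"need at least two taxa at rank {mode} to mislabel")

    rng = np.random.default_rng(seed)
    victims = list(rng.choice([r.id for r in sim.records], size=n, replace=False))
    lineages = dict(sim.lineages)
    for victim in victims:
        own = lineages[victim][mode].name
        other_taxa = sorted(t for t in by_taxon if t != own)
        donor_taxon = other_taxa[int(rng.integers(0, len(other_taxa)))]
        members = by_taxon[donor_taxon]
        donor = members[int(rng.integers(0, len(members)))]
        donor_lin = sim.lineages[donor]
        lineages[victim] = Lineage(
            lineages[victim].ranks[:rank_idx] + donor_lin.ranks[rank_idx:]
        )
    return lineages, [str(v) for v in victims]


def make_chimera(
    parent_a: SeqRecord,
    parent_b: SeqRecord,
    breakpoint_fraction: float,
    chim_id: str = "chimera",
) -> tuple[SeqRecord, dict]:
    """Two-parent chimera: prefix of A joined to the homologous suffix of B.

    The suffix starts at the same fractional coordinate of B, which is
    homologous enough for substitution-dominated fixtures.
    """
    if not 0.0 < breakpoint_fraction < 1.0:
        raise ValueError("breakpoint fraction must be in (0, 1)")
    cut_a = int(len(parent_a.seq) * breakpoint_fraction)
    cut_b = int(len(parent_b.seq) * breakpoint_fraction)
    seq = parent_a.seq[:cut_a] + parent_b.seq[cut_b:]
    truth = {
        "parent_a": parent_a.id,
        "parent_b": parent_b.id,
        "breakpoint_fraction": breakpoint_fraction,
        "breakpoint": cut_a,
    }
    return SeqRecord(chim_id, seq, source="chimera"), truth


def simulate_queries(
    refs: Sequence[SeqRecord],
    n: int,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
) -> tuple[list[SeqRecord], list[dict]]:
    """Query OTUs at mixture-controlled divergence from random references.

    Abundances are geometric(``abundance_p``). Truth rows record the source
    reference, requested divergence and realized substitution count.
    """
    if not refs:
        raise ValueError("need at least one reference to simulate queries")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights = np.array([w for w, _ in config.query_divergence_mix], dtype=float)
    weights /= weights.sum()
    divs = [d for _, d in config.query_divergence_mix]

    queries: list[SeqRecord] = []
    truth: list[dict] = []
    for i in range(n):
        ref = refs[int(rng.integers(0, len(refs)))]
        div = divs[int(rng.choice(len(divs), p=weights))]
        seq, n_subs = mutate_sequence(ref.seq, div, config.indel_rate, rng=rng)
        abundance = float(rng.geometric(config.abundance_p))
        qid = f"otu{i + 1:04d}"
        queries.append(SeqRecord(qid, seq, source="query", abundance=abundance))
        truth.append(
            {
                "query_id": qid,
                "source_ref": ref.id,
                "divergence": div,
                "realized_subs": n_subs,
            }
        )
    return queries, truth


def queries_truth_to_tsv(truth: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsource_ref\tdivergence\trealized_subs\n")
        for row in truth:
            fh.write(
                f"{row['query_id']}\t{row['source_ref']}\t"
                f"{row['divergence']}\t{row['realized_subs']}\n"
            )
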