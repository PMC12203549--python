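import numpy as np
import pytest

from taxoscaffold.seqio import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutated_copy(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Exactly n_subs substitutions at distinct positions (test oracle helper)."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def make_records(seqs: dict[str, str], source: str = "test") -> list[SeqRecord]:
    return [SeqRecord(i, s, source=source) for i, s in seqs.items()]
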