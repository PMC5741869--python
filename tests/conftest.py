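import numpy as np
import pytest

from csmetapred.score_io import GoldAnnotation, ResidueKey
from csmetapred.ranking import RankedPrediction


def keys_for(n, aa="H", chain="A"):
    """n residue keys on one chain, resnum 1..n."""
    return [ResidueKey(chain=chain, resnum=i + 1, icode="", aa=aa) for i in range(n)]


def ranking_with_hits(n, hit_ranks, protein_id="P"):
    """A ranking of n residues whose catalytic residues sit at the given
    1-based ranks; returns (RankedPrediction, GoldAnnotation)."""
    keys = keys_for(n)
    entries = [(k, float(n - i), i + 1) for i, k in enumerate(keys)]
    gold = GoldAnnotation(
        protein_id=protein_id,
        catalytic=frozenset(keys[r - 1] for r in hit_ranks),
    )
    return RankedPrediction(protein_id=protein_id, entries=entries, subset="all"), gold


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
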