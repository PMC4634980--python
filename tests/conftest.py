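import numpy as np
import pytest

from sporeamp.gene_model import Feature, GeneModel, riaox_model
from sporeamp.mapping import AlignmentRecord


@pytest.fixture(scope="session")
def riaox():
    return riaox_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_reference():
    """A 400-nt random reference shared across alignment/caller tests."""
    r = np.random.default_rng(99)
    return "".join("ACGT"[i] for i in r.integers(0, 4, 400))


@pytest.fixture()
def toy_model():
    """Two exons around one intron; CDS = both exons ('ATGAAA' + 'TGA')."""
    return GeneModel(
        gene_id="toy",
        sequence="ATGAAAGTAGTGA",
        features=[Feature("exon", 1, 6), Feature("intron", 7, 10),
                  Feature("exon", 11, 13)],
        cds_intervals=[(1, 6), (11, 13)],
    )


def make_alignment(read_id, reference, ref_start, ops, seq=None, quality=35):
    """Hand-built mapped AlignmentRecord consistent with ``ops``.

    ``ops`` uses the internal run-length alphabet; when ``seq`` is omitted it
    is synthesised from the reference (mismatches/insertions need explicit
    ``seq``).
    """
    if seq is None:
        parts = []
        r = ref_start
        for op, n in ops:
            if op in ("=",):
                parts.append(reference[r - 1 : r - 1 + n])
                r += n
            elif op == "D":
                r += n
            else:
                raise ValueError("explicit seq needed for op " + op)
        seq = "".join(parts)
    read_len = sum(n for op, n in ops if op in ("=", "X", "I", "S"))
    assert read_len == len(seq), "ops inconsistent with seq"
    quals = [quality] * len(seq) if isinstance(quality, int) else list(quality)
    return AlignmentRecord(read_id, True, ref_start, list(ops), 1.0, 1.0,
                           seq, quals)
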