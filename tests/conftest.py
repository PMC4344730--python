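import numpy as np
import pytest

from helhunt.seqio import GenomicSequence


@pytest.fixture(scope="session", autouse=True)
def warm_numba():
    """Trigger the JIT compilations once so per-test timings are flat."""
    from helhunt.alignment import global_score
    from helhunt.homology_scan import ScoringScheme, local_align
    from helhunt.structure_annotate import AnnotationConfig, fold_hairpin

    global_score("ACGT", "ACG")
    local_align(GenomicSequence("q", "ACGTACGT"), GenomicSequence("s", "ACGTACGT"))
    fold_hairpin(GenomicSequence("w", "GGGGAAAACCCC"), AnnotationConfig(dg_ceiling=100.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20150227)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=n)])
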