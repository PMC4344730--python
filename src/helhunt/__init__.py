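"""helhunt: non-autonomous Helitron detection, structural annotation, and
horizontal-transposon-transfer screening.

The package finds copies of a conserved non-autonomous Helitron family in
DNA sequences by filtered local alignment, annotates their diagnostic
primary/secondary structure (5'-TC and 3'-CTRR termini, 3' hairpin, 5'-IR
and SIR inverted repeats, (CTGT)n microsatellite), and screens species
pairs for horizontal transfer by comparative divergence (element vs host
marker) and phylogenetic incongruence.  A synthetic-data module generates
genomes with planted elements under vertical and horizontal inheritance so
every stage is testable against exact ground truth.
"""

__version__ = "0.1.0"

from importlib import resources as _resources


def example_identity_matrices():
    """Bundled six-taxon lepidopteran example: Hel-2 element identity and
    RpS5 host-marker identity matrices (percent, 2 d.p.).

    Returns (te_matrix, host_matrix) as :class:`~helhunt.alignment.IdentityMatrix`.
    """
    from .alignment import IdentityMatrix

    base = _resources.files(__name__) / "data"
    te = IdentityMatrix.from_tsv(str(base / "lepidoptera_hel2_identity.tsv"))
    host = IdentityMatrix.from_tsv(str(base / "lepidoptera_rps5_identity.tsv"))
    return te, host
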