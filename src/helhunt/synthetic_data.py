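"""Synthetic genomes, element families, and host-marker genes with ground truth.

The generator renders a Hel-2-style non-autonomous element template (5'-TC /
3'-CTRR termini, 5'-IR, SIR, (CTGT)n microsatellite, GC-rich 3' hairpin),
plants copies into random background genomes between AT/TT dinucleotides
with no target-site duplication, and evolves element and host-marker
sequences along a species tree under the T92 substitution model — with
optional horizontal-transfer events that copy the donor lineage's element
into a recipient lineage at a stated age.  Every output carries exact
coordinate and event truth, and everything is reproducible from a single
seed (fanned out to per-operation streams via ``numpy.random.SeedSequence``
spawning in a fixed order).

Indels are not simulated: substitution-only evolution keeps homologous
columns exactly mapped, which is what coordinate-truth tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._dp import encode
from .phylo import PhyloModel, gamma_category_rates, transition_probability
from .seqio import GenomicSequence, Region, reverse_complement, write_fasta

__all__ = [
    "ElementTemplate",
    "RenderedElement",
    "PlantedTruth",
    "HTTEvent",
    "ScenarioSpec",
    "SimulatedDataset",
    "render_template",
    "random_genome",
    "plant_elements",
    "evolve",
    "simulate_scenario",
    "write_dataset",
    "star_tree",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ElementTemplate:
    """Feature layout for a rendered Hel-2-style element.

    Defaults describe a ~300 bp non-autonomous element with all diagnostic
    features; the rendered sequence annotates at tier ``full`` at zero
    divergence by construction.
    """

    length: int = 300
    terminus_5p: str = "TC"            # or "TCC"
    terminus_3p: str = "CTAG"          # any CTRR choice
    hairpin_arm: int = 8
    hairpin_loop: int = 4
    ir_arm: int = 10                   # 5'-IR arm length
    sir_arm: int = 12                  # SIR arm length
    microsat_unit: str = "CTGT"
    microsat_copies: int = 5
    gc_content: float = 0.4

    def __post_init__(self) -> None:
        if self.terminus_5p not in ("TC", "TCC"):
            raise ValueError("terminus_5p must be TC or TCC")
        import re

        if not re.fullmatch("CT[AG][AG]", self.terminus_3p):
            raise ValueError("terminus_3p must match CTRR (R = A/G)")


@dataclass(frozen=True)
class RenderedElement:
    sequence: GenomicSequence
    features: dict


@dataclass(frozen=True)
class PlantedTruth:
    genome_id: str
    element: Region                    # 1-based inclusive, final coordinates
    source_lineage: str
    divergence_applied: float
    insertion_site_dinucleotide: str   # AT or TT
    htt_event: bool = False


@dataclass(frozen=True)
class HTTEvent:
    """A horizontal transfer: the donor lineage's element state at ``age``
    time units before the present replaces the recipient's element lineage,
    then evolves in the recipient for the remaining ``age``."""

    donor: str
    recipient: str
    age: float


def star_tree(n: int = 6, branch_length: float = 0.1, prefix: str = "sp") -> str:
    """Newick for an n-tip star (hard polytomy) with equal tip branches —
    a rapid-radiation species history."""
    tips = ",".join(f"{prefix}{i + 1}:{branch_length:g}" for i in range(n))
    return f"({tips});"


@dataclass(frozen=True)
class ScenarioSpec:
    species_tree: str = star_tree()
    te_clock: float = 1.0
    host_clock: float = 1.0
    htt_events: tuple[HTTEvent, ...] = ()
    copies_per_genome: int = 3
    copy_divergence: float = 0.0
    genome_length: int = 4000
    background_gc: float = 0.4
    template: ElementTemplate = ElementTemplate()
    marker_length: int = 500
    model: PhyloModel = PhyloModel()
    seed: int = 0


@dataclass
class SimulatedDataset:
    spec: ScenarioSpec
    element_by_species: dict[str, GenomicSequence]
    marker_by_species: dict[str, GenomicSequence]
    genome_by_species: dict[str, GenomicSequence]
    truth: dict[str, list[PlantedTruth]]
    template_features: dict


# ---------------------------------------------------------------------------
# Template rendering
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def render_template(
    template: ElementTemplate | None = None, seed: int | np.random.Generator = 0
) -> RenderedElement:
    """Render the element template into a concrete sequence.

    Feature coordinates (1-based within the element) are returned alongside
    the sequence.  The layout anchors the termini at the ends, the 5'-IR and
    SIR arms and the microsatellite in the 5' half, and a GC-only stem-loop
    just upstream of the 3' terminus so its free energy is always reported.
    """
    t = template or ElementTemplate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = t.length
    ms_len = len(t.microsat_unit) * t.microsat_copies
    # 5'-side feature starts (0-based)
    p5_len = len(t.terminus_5p)
    ir_a = p5_len + 2
    ir_b = ir_a + t.ir_arm + 5
    sir_a = ir_b + t.ir_arm + 3
    ms = sir_a + t.sir_arm + 3
    # 3'-side features, anchored from the right
    t3 = L - len(t.terminus_3p)
    hp_right_end = t3 - 8                      # 0-based exclusive end of right arm
    hp_left = hp_right_end - (2 * t.hairpin_arm + t.hairpin_loop)
    sir_b = hp_left - t.sir_arm - 4
    if ms + ms_len + 2 > sir_b:
        raise ValueError("template features do not fit in the requested length")
    seq = list(_random_dna(rng, L, t.gc_content))

    def put(pos: int, s: str) -> None:
        seq[pos : pos + len(s)] = list(s)

    put(0, t.terminus_5p)
    ir_arm_seq = _random_dna(rng, t.ir_arm, 0.5)
    put(ir_a, ir_arm_seq)
    put(ir_b, reverse_complement(ir_arm_seq))
    sir_arm_seq = _random_dna(rng, t.sir_arm, 0.5)
    put(sir_a, sir_arm_seq)
    put(sir_b, reverse_complement(sir_arm_seq))
    put(ms, t.microsat_unit * t.microsat_copies)
    # guard bases so the microsatellite array is exactly the requested copies
    seq[ms - 1] = "A"
    seq[ms + ms_len] = "A"
    stem = "".join(np.array(list("GC"))[rng.integers(0, 2, size=t.hairpin_arm)])
    put(hp_left, stem)
    put(hp_left + t.hairpin_arm, _random_dna(rng, t.hairpin_loop, 0.0) or "A" * t.hairpin_loop)
    put(hp_left + t.hairpin_arm + t.hairpin_loop, reverse_complement(stem))
    put(t3, t.terminus_3p)
    residues = "".join(seq)
    gs = GenomicSequence("element_template", residues)
    features = {
        "terminus_5p": Region(gs.id, 1, p5_len),
        "five_prime_IR": (
            Region(gs.id, ir_a + 1, ir_a + t.ir_arm),
            Region(gs.id, ir_b + 1, ir_b + t.ir_arm),
        ),
        "SIR": (
            Region(gs.id, sir_a + 1, sir_a + t.sir_arm),
            Region(gs.id, sir_b + 1, sir_b + t.sir_arm),
        ),
        "microsatellite": Region(gs.id, ms + 1, ms + ms_len),
        "hairpin": (
            Region(gs.id, hp_left + 1, hp_left + t.hairpin_arm),
            Region(
                gs.id,
                hp_left + t.hairpin_arm + t.hairpin_loop + 1,
                hp_left + 2 * t.hairpin_arm + t.hairpin_loop,
            ),
        ),
        "terminus_3p": Region(gs.id, t3 + 1, L),
    }
    return RenderedElement(gs, features)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def random_genome(
    length: int, gc: float = 0.4, seed: int | np.random.Generator = 0, name: str = "genome"
) -> GenomicSequence:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GenomicSequence(name, _random_dna(rng, length, gc))


def plant_elements(
    host: GenomicSequence,
    element: GenomicSequence | Sequence[GenomicSequence],
    n: int | None = None,
    seed: int | np.random.Generator = 0,
    source_lineage: str = "",
    divergence_applied: float = 0.0,
    htt_event: bool = False,
) -> tuple[GenomicSequence, list[PlantedTruth]]:
    """Insert element copies between AT/TT dinucleotides of ``host``.

    ``element`` may be a single sequence (inserted ``n`` times) or a list of
    copies (one insertion each).  All insertion sites are chosen uniformly
    without replacement from the ORIGINAL host, so planted copies never nest
    inside one another.  Each element is placed between the two bases of its
    dinucleotide with no target-site duplication: flanks read
    ``...A | element | T...`` or ``...T | element | T...``.  Removing each
    planted element at its truth coordinates reconstructs the host exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(element, GenomicSequence):
        elements = [element] * (1 if n is None else n)
    else:
        elements = list(element)
        if n is not None and n != len(elements):
            raise ValueError("n does not match the number of element copies")
    n = len(elements)
    s = host.residues
    sites = [p for p in range(len(s) - 1) if s[p] in "AT" and s[p + 1] == "T"]
    if len(sites) < n:
        raise ValueError(f"host has only {len(sites)} eligible AT/TT sites, need {n}")
    chosen = sorted(rng.choice(len(sites), size=n, replace=False))
    chosen = [sites[i] for i in chosen]
    parts = []
    truth = []
    prev = 0
    offset = 0
    for p, elem in zip(chosen, elements):
        parts.append(s[prev : p + 1])
        parts.append(elem.residues)
        start = (p + 1) + offset + 1            # 1-based start in final coordinates
        truth.append(
            PlantedTruth(
                genome_id=host.id,
                element=Region(host.id, start, start + len(elem) - 1),
                source_lineage=source_lineage or elem.id,
                divergence_applied=divergence_applied,
                insertion_site_dinucleotide=s[p : p + 2],
                htt_event=htt_event,
            )
        )
        offset += len(elem)
        prev = p + 1
    parts.append(s[prev:])
    return GenomicSequence(host.id, "".join(parts), host.description), truth


# ---------------------------------------------------------------------------
# Substitution simulation
# ---------------------------------------------------------------------------

def evolve(
    seq: GenomicSequence,
    divergence: float,
    model: PhyloModel | None = None,
    seed: int | np.random.Generator = 0,
) -> GenomicSequence:
    """Evolve a sequence by ``divergence`` expected substitutions/site under
    the T92 process (discrete-gamma rate variation when configured).

    Ambiguity codes are carried through unchanged.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    model = model or PhyloModel()
    if divergence == 0:
        return GenomicSequence(seq.id, seq.residues, seq.description)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    enc = encode(seq.residues).astype(np.int64)
    out = enc.copy()
    rates = gamma_category_rates(model.gamma_shape, model.n_rate_categories)
    cats = rng.integers(0, len(rates), size=enc.shape[0])
    u = rng.random(enc.shape[0])
    for c, r in enumerate(rates):
        P = transition_probability(model, divergence, float(r))
        cum = np.cumsum(P, axis=1)
        for state in range(4):
            m = (enc == state) & (cats == c)
            if not m.any():
                continue
            out[m] = np.searchsorted(cum[state], u[m], side="right")
    out = np.minimum(out, 3)
    res = np.array(list(seq.residues))
    valid = enc < 4
    res[valid] = _BASES[out[valid]]
    return GenomicSequence(seq.id, "".join(res), seq.description)


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------

def _simulate_along_tree(
    tree: dendropy.Tree,
    root_seq: GenomicSequence,
    clock: float,
    model: PhyloModel,
    rng: np.random.Generator,
    snapshots: Optional[dict[tuple[str, float], GenomicSequence]] = None,
    snapshot_points: Optional[dict] = None,
) -> dict[str, GenomicSequence]:
    """Evolve ``root_seq`` down the tree; optionally record lineage states at
    (tip, depth) snapshot points lying on the root-to-tip path of ``tip``."""
    depths = {}
    states = {id(tree.seed_node): root_seq}
    tips: dict[str, GenomicSequence] = {}
    depths[id(tree.seed_node)] = 0.0
    # map tip label -> set of nodes on its root path (for snapshot routing)
    on_path: dict[str, set[int]] = {}
    if snapshot_points:
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if label in snapshot_points:
                path = set()
                node = leaf
                while node is not None:
                    path.add(id(node))
                    node = node.parent_node
                on_path[label] = path
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = (node.edge.length or 0.0)
        d0 = depths[id(node.parent_node)]
        depths[id(node)] = d0 + bl
        parent_state = states[id(node.parent_node)]
        # split the branch at any snapshot point that lies on it
        cuts = []
        if snapshot_points:
            for label, req_depths in snapshot_points.items():
                if id(node) in on_path.get(label, ()):
                    for rd in req_depths:
                        if d0 < rd <= d0 + bl + 1e-12:
                            cuts.append((rd, label))
        cuts.sort()
        cur = parent_state
        cur_d = d0
        for rd, label in cuts:
            cur = evolve(cur, (rd - cur_d) * clock, model, rng)
            snapshots[(label, rd)] = cur
            cur_d = rd
        cur = evolve(cur, (d0 + bl - cur_d) * clock, model, rng)
        states[id(node)] = cur
        if node.is_leaf():
            tips[node.taxon.label] = GenomicSequence(
                node.taxon.label, cur.residues
            )
    return tips


def simulate_scenario(spec: ScenarioSpec | None = None) -> SimulatedDataset:
    """Simulate element and host-marker families along a species tree.

    Element and marker sequences evolve at their respective clocks; each
    horizontal-transfer event replaces the recipient tip's element with the
    donor lineage's state at the event time, evolved independently for the
    event's age.  ``copies_per_genome`` copies of each species' element are
    then planted into a random background genome with coordinate truth.
    Fully reproducible from ``spec.seed``.
    """
    spec = spec or ScenarioSpec()
    ss = np.random.SeedSequence(spec.seed)
    (s_template, s_marker, s_te, s_host, s_events, s_genomes, s_copies) = ss.spawn(7)
    tree = dendropy.Tree.get(
        data=spec.species_tree, schema="newick", preserve_underscores=True
    )
    tip_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    depths = {}
    for node in tree.preorder_node_iter():
        depths[id(node)] = (
            0.0
            if node.parent_node is None
            else depths[id(node.parent_node)] + (node.edge.length or 0.0)
        )
    tip_depth = {lf.taxon.label: depths[id(lf)] for lf in tree.leaf_node_iter()}
    for ev in spec.htt_events:
        for who in (ev.donor, ev.recipient):
            if who not in tip_depth:
                raise ValueError(f"HTT event names unknown tip {who!r}")
        if ev.age < 0 or ev.age > tip_depth[ev.donor]:
            raise ValueError(f"HTT age {ev.age} outside the donor's root-to-tip depth")

    rendered = render_template(spec.template, np.random.default_rng(s_template))
    root_marker = random_genome(
        spec.marker_length, spec.background_gc, np.random.default_rng(s_marker), "marker_root"
    )

    snapshot_points: dict[str, list[float]] = {}
    for ev in spec.htt_events:
        snapshot_points.setdefault(ev.donor, []).append(tip_depth[ev.donor] - ev.age)
    snapshots: dict[tuple[str, float], GenomicSequence] = {}
    te_tips = _simulate_along_tree(
        tree, rendered.sequence, spec.te_clock, spec.model,
        np.random.default_rng(s_te), snapshots, snapshot_points,
    )
    marker_tips = _simulate_along_tree(
        tree, root_marker, spec.host_clock, spec.model, np.random.default_rng(s_host)
    )
    rng_events = np.random.default_rng(s_events)
    transferred = set()
    for ev in spec.htt_events:
        snap = snapshots[(ev.donor, tip_depth[ev.donor] - ev.age)]
        te_tips[ev.recipient] = GenomicSequence(
            ev.recipient,
            evolve(snap, ev.age * spec.te_clock, spec.model, rng_events).residues,
        )
        transferred.add(ev.recipient)

    rng_genomes = np.random.default_rng(s_genomes)
    rng_copies = np.random.default_rng(s_copies)
    genomes: dict[str, GenomicSequence] = {}
    truth: dict[str, list[PlantedTruth]] = {}
    for label in tip_labels:
        bg = random_genome(spec.genome_length, spec.background_gc, rng_genomes, label)
        copies = [
            evolve(te_tips[label], spec.copy_divergence, spec.model, rng_copies)
            for _ in range(spec.copies_per_genome)
        ]
        g, t = plant_elements(
            bg, copies, seed=rng_copies,
            source_lineage=label,
            divergence_applied=spec.copy_divergence,
            htt_event=label in transferred,
        )
        genomes[label] = g
        truth[label] = sorted(t, key=lambda x: x.element.start)
    return SimulatedDataset(
        spec=spec,
        element_by_species=te_tips,
        marker_by_species=marker_tips,
        genome_by_species=genomes,
        truth=truth,
        template_features=rendered.features,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Serialize a simulated dataset: FASTA sequences, BED truth, the true
    species tree (newick), and a TSV event log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.element_by_species.values(), outdir / "elements.fasta")
    write_fasta(ds.marker_by_species.values(), outdir / "markers.fasta")
    write_fasta(ds.genome_by_species.values(), outdir / "genomes.fasta")
    with open(outdir / "truth.bed", "w") as fh:
        fh.write('track name="planted_elements"\n')
        for recs in ds.truth.values():
            for r in recs:
                lo, hi = r.element.span
                fh.write(
                    f"{r.genome_id}\t{lo - 1}\t{hi}\t{r.source_lineage}"
                    f"\t0\t+\n"
                )
    with open(outdir / "species_tree.nwk", "w") as fh:
        fh.write(ds.spec.species_tree.strip() + "\n")
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("donor\trecipient\tage\n")
        for ev in ds.spec.htt_events:
            fh.write(f"{ev.donor}\t{ev.recipient}\t{ev.age:g}\n")
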