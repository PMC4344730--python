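"""End-to-end orchestration: scan -> annotate -> align -> htt -> phylo.

The pipeline is a thin, auditable driver over the library modules: every
stage reads/writes plain-text files under the run directory, a JSON manifest
records the effective configuration, seeds, per-stage counts, and SHA-256
checksums of all outputs, and a fixed seed reproduces byte-identical stage
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .alignment import identity_matrix, progressive_msa
from .homology_scan import ScoringScheme, filter_hits, local_align
from .htt_screen import screen
from .phylo import PhyloModel, bootstrap_consensus, tree_to_newick
from .seqio import GenomicSequence, Region, extract_region, read_fasta, write_annotations
from .structure_annotate import AnnotationConfig, annotate_element

logger = logging.getLogger("helhunt")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration for a pipeline run.

    Threshold defaults are the pipeline's documented operating point:
    identity >= 65%, E <= 1e-5, terminal anchor >= 50 bp, gamma shape 2.249,
    1000 bootstrap replicates with a 50% support floor.
    """

    elements_fasta: str = ""
    markers_fasta: str = ""
    genomes_fasta: str = ""
    query_fasta: str = ""
    outdir: str = "helhunt_run"
    stages: tuple[str, ...] = ("scan", "annotate", "align", "htt", "phylo")
    min_identity: float = 65.0
    max_evalue: float = 1e-5
    min_terminal: int = 50
    gamma: float = 2.249
    bootstrap: int = 1000
    support_floor: float = 50.0
    n_perm: int = 999
    identity_mode: str = "all_columns"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_hits_tsv(hits, path: Path) -> None:
    cols = [
        "query_id", "query_start", "query_end", "subject_id", "subject_start",
        "subject_end", "strand", "score", "identity_pct", "evalue", "coverage_class",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_span.seq_id}\t{h.query_span.start}\t{h.query_span.end}\t"
                f"{h.subject_span.seq_id}\t{h.subject_span.start}\t{h.subject_span.end}\t"
                f"{h.strand}\t{h.score:g}\t{h.identity_pct:.2f}\t{h.evalue:.3g}\t"
                f"{h.coverage_class}\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Any stage failure raises :class:`StageError` naming the stage.  Rerunning
    with an identical configuration reproduces identical outputs (manifest
    timestamps aside).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "helhunt",
        "version": __version__,
        "config": {**asdict(config), "stages": list(config.stages)},
        "stages": {},
        "checksums": {},
    }
    config.to_yaml(outdir / "effective_config.yaml")

    retained_by_subject: dict[str, list] = {}
    subjects: list[GenomicSequence] = []

    if "scan" in config.stages:
        stage = "scan"
        try:
            if not config.genomes_fasta:
                raise ValueError("scan requires genomes_fasta")
            subjects = read_fasta(config.genomes_fasta)
            if not subjects:
                raise ValueError("subject FASTA is empty")
            if config.query_fasta:
                query = read_fasta(config.query_fasta)[0]
            elif config.elements_fasta:
                query = read_fasta(config.elements_fasta)[0]
            else:
                raise ValueError("scan requires query_fasta or elements_fasta")
            all_hits = []
            for subj in subjects:
                hits = local_align(query, subj, ScoringScheme())
                kept = filter_hits(
                    hits, config.min_identity, config.max_evalue, config.min_terminal
                )
                retained_by_subject[subj.id] = kept
                all_hits.extend(kept)
            _write_hits_tsv(all_hits, outdir / "hits.tsv")
            manifest["stages"][stage] = {
                "subjects": len(subjects),
                "hits_retained": len(all_hits),
            }
            logger.info("scan: %d subjects, %d retained hits", len(subjects), len(all_hits))
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - stage-named propagation
            raise StageError(stage, str(e)) from e

    if "annotate" in config.stages:
        stage = "annotate"
        try:
            annotations = []
            tiers: dict[str, int] = {}
            by_id = {s.id: s for s in subjects}
            for subj_id, kept in retained_by_subject.items():
                subj = by_id[subj_id]
                for h in kept:
                    lo, hi = h.subject_span.span
                    elem = extract_region(subj, Region(subj.id, lo, hi))
                    left = subj.residues[max(0, lo - 11) : lo - 1]
                    right = subj.residues[hi : hi + 10]
                    anno = annotate_element(
                        elem, (left, right), element=Region(subj.id, lo, hi)
                    )
                    annotations.append(anno)
                    tiers[anno.tier] = tiers.get(anno.tier, 0) + 1
            write_annotations(annotations, outdir / "annotations.gff3", "GFF3")
            write_annotations(annotations, outdir / "annotations.bed", "BED")
            manifest["stages"][stage] = {"elements": len(annotations), "tiers": tiers}
            logger.info("annotate: %d elements by tier %s", len(annotations), tiers)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    te_matrix = host_matrix = None
    te_aln = None
    if "align" in config.stages or "htt" in config.stages or "phylo" in config.stages:
        stage = "align"
        try:
            if not config.elements_fasta:
                raise ValueError("align requires elements_fasta")
            te_seqs = read_fasta(config.elements_fasta)
            te_aln = progressive_msa(te_seqs)
            te_matrix = identity_matrix(te_aln, config.identity_mode)
            te_matrix.to_tsv(outdir / "te_identity.tsv")
            n_host = 0
            if config.markers_fasta:
                host_aln = progressive_msa(read_fasta(config.markers_fasta))
                host_matrix = identity_matrix(host_aln, config.identity_mode)
                host_matrix.to_tsv(outdir / "host_identity.tsv")
                n_host = len(host_aln.rows)
            manifest["stages"][stage] = {"te_rows": len(te_aln.rows), "host_rows": n_host}
            logger.info("align: %d TE rows, %d host rows", len(te_aln.rows), n_host)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    if "htt" in config.stages:
        stage = "htt"
        try:
            if host_matrix is None:
                raise ValueError("htt requires markers_fasta")
            cands = screen(te_matrix, host_matrix, n_perm=config.n_perm, seed=config.seed)
            with open(outdir / "htt_candidates.tsv", "w") as fh:
                fh.write("species_a\tspecies_b\tte_identity\thost_identity\tdelta"
                         "\tflagged\tp_value\tidentity_mode\n")
                for c in cands:
                    fh.write(
                        f"{c.species_pair[0]}\t{c.species_pair[1]}\t{c.te_identity:.2f}\t"
                        f"{c.host_identity:.2f}\t{c.delta:.2f}\t{int(c.flagged)}\t"
                        f"{c.p_value:.4g}\t{config.identity_mode}\n"
                    )
            n_flag = sum(c.flagged for c in cands)
            manifest["stages"][stage] = {"pairs": len(cands), "flagged": n_flag}
            logger.info("htt: %d pairs, %d flagged", len(cands), n_flag)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    if "phylo" in config.stages:
        stage = "phylo"
        try:
            model = PhyloModel(gamma_shape=config.gamma)
            cons = bootstrap_consensus(
                te_aln, model, n_reps=config.bootstrap,
                support_floor=config.support_floor, seed=config.seed,
            )
            (outdir / "te_consensus.nwk").write_text(tree_to_newick(cons) + "\n")
            manifest["stages"][stage] = {"bootstrap": config.bootstrap}
            logger.info("phylo: consensus from %d replicates", config.bootstrap)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
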