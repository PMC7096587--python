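"""Pipeline orchestration: phylogeny -> motifs -> pocket -> polymorphisms.

The final report intersects clade-conserved polymorphic alignment columns
with the structure's substrate-contact residues and with motif membership —
the summary that nominates candidate substrate-specificity residues.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .conservation import (
    PropertyTable,
    classify_columns,
    detect_group_polymorphisms,
    polymorphisms_to_tsv,
    reports_to_tsv,
)
from .motifs import architecture, read_meme_minimal
from .phylo import DeletionPolicy, bootstrap_support, distance_matrix, neighbor_joining
from .seqio import ProteinSequence, read_alignment
from .structure import (
    LigandSite,
    PocketConfig,
    map_columns_to_residues,
    project_motifs,
    read_pdb,
    select_contact_residues,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run; every resolved parameter
    is echoed into the run manifest."""

    alignment: str = ""
    groups: str = ""
    motifs: str = ""
    structure: str = ""
    reference_id: str = ""  # sequence mapped onto the structure
    chain: str = "A"
    clades: tuple[str, str] = ("monocot", "brassicales")
    substrate_het: str = "LIG"
    fe_het: str = "FE"
    og_het: str = "AKG"
    out_dir: str = "sdpscan_out"
    seed: int = 0
    # stage parameters (defaults mirror the module defaults)
    deletion_mode: str = "partial"
    coverage_cutoff: float = 0.95
    bootstrap: int = 0
    conservation_threshold: float = 0.8
    min_bits: float | None = None
    substrate_cutoff: float = 5.0
    fe_cutoff: float = 2.6
    og_cutoff: float = 3.5
    orientation: str = "centroid"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "clades" in data:
            data["clades"] = tuple(data["clades"])
        return cls(**data)

    def validate(self) -> None:
        for attr in ("alignment", "groups", "motifs", "structure"):
            p = getattr(self, attr)
            if not p:
                raise PipelineError(f"config: {attr} path not set")
            if not Path(p).exists():
                raise PipelineError(f"config: {attr} path does not exist: {p}")
        if not self.reference_id:
            raise PipelineError("config: reference_id not set")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write TSV/newick/JSON outputs plus a manifest.

    Returns the final report as a dict. Any stage failure raises with the
    stage name; outputs of earlier stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("phylo")
        family = read_alignment(config.alignment, config.groups)
        policy = DeletionPolicy(
            mode=config.deletion_mode, coverage_cutoff=config.coverage_cutoff
        )
        if config.bootstrap > 0:
            tree = bootstrap_support(
                family, policy, n_reps=config.bootstrap, seed=config.seed
            )
        else:
            tree = neighbor_joining(distance_matrix(family, policy))
        (out / "tree.nwk").write_text(tree.to_newick())
        report["stages"]["phylo"] = {"n_leaves": len(tree.leaf_labels())}
    except Exception as e:
        raise PipelineError(f"stage phylo failed: {e}") from e

    try:
        stage("motifscan")
        motif_models = read_meme_minimal(config.motifs)
        archs = {}
        for sid in family.ids:
            seq = ProteinSequence(id=sid, residues=family.ungapped(sid))
            archs[sid] = architecture(seq, motif_models, config.min_bits)
        hits_tsv = ["seq_id\tmotif_id\tstart\tend\tbits"]
        for a in archs.values():
            for h in a.hits:
                hits_tsv.append(
                    f"{h.seq_id}\t{h.motif_id}\t{h.start}\t{h.end}\t{h.score:.3f}"
                )
        (out / "motif_hits.tsv").write_text("\n".join(hits_tsv) + "\n")
        report["stages"]["motifscan"] = {
            "n_motifs": len(motif_models),
            "n_hits": sum(len(a.hits) for a in archs.values()),
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage motifscan failed: {e}") from e

    try:
        stage("pocket")
        model, hets = read_pdb(config.structure)
        site = LigandSite.from_het_groups(
            hets,
            substrate_het=config.substrate_het,
            fe_het=config.fe_het,
            og_het=config.og_het,
        )
        pocket_cfg = PocketConfig(
            substrate_cutoff=config.substrate_cutoff,
            fe_cutoff=config.fe_cutoff,
            og_cutoff=config.og_cutoff,
            orientation=config.orientation,
        )
        pocket = select_contact_residues(model, site, pocket_cfg, chain=config.chain)
        (out / "pocket.tsv").write_text(pocket.to_tsv())
        report["stages"]["pocket"] = pocket.counts()
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage pocket failed: {e}") from e

    try:
        stage("polymorph")
        tables = PropertyTable.load()
        a_ids = family.members_of_clade(config.clades[0])
        b_ids = family.members_of_clade(config.clades[1])
        records = detect_group_polymorphisms(
            family,
            a_ids,
            b_ids,
            threshold=config.conservation_threshold,
            tables=tables,
            group_a_label=config.clades[0],
            group_b_label=config.clades[1],
            reference_id=config.reference_id,
        )
        (out / "polymorphisms.tsv").write_text(polymorphisms_to_tsv(records))
        # with a single enzyme class the clades are the comparative unit
        class_family = family
        if len(family.classes()) < 2:
            from .seqio import AlignedFamily

            class_family = AlignedFamily(
                records=list(family.records),
                class_of={sid: family.clade_of[sid] for sid in family.ids},
                clade_of=dict(family.clade_of),
            )
        reports = classify_columns(
            class_family,
            threshold=config.conservation_threshold,
            clades=config.clades,
            tables=tables,
            reference_id=config.reference_id,
        )
        (out / "columns.tsv").write_text(reports_to_tsv(reports))
        report["stages"]["polymorph"] = {"n_polymorphic_columns": len(records)}
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage polymorph failed: {e}") from e

    try:
        stage("intersect")
        rmap = map_columns_to_residues(
            family, config.reference_id, model, config.chain
        )
        contact_keys = {
            e.residue.key for e in pocket.with_role("substrate_contact")
        }
        contact_cols = {
            rmap.res_to_col[k] for k in contact_keys if k in rmap.res_to_col
        }
        poly_cols = {r.column for r in records}
        poly_contact = sorted(poly_cols & contact_cols)

        ref_seq = ProteinSequence(
            id=config.reference_id, residues=family.ungapped(config.reference_id)
        )
        ref_arch = architecture(ref_seq, motif_models, config.min_bits)
        labels = project_motifs(ref_arch, rmap)
        contact_in_motifs = sorted(
            rmap.res_to_pos[k] for k in contact_keys if k in labels
        )
        summary = {
            "contact_residues": len(contact_keys),
            "cofactor_residues": len(pocket.with_role("cofactor_coordinating")),
            "flagged_residues": len(pocket.flagged),
            "clade_polymorphic_columns": len(poly_cols),
            "polymorphic_contact_columns": poly_contact,
            "n_polymorphic_contact": len(poly_contact),
            "contact_positions_in_motifs": contact_in_motifs,
            "n_contact_in_motifs": len(contact_in_motifs),
        }
        report["summary"] = summary
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage intersect failed: {e}") from e

    manifest = {
        "package": "sdpscan",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
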