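"""End-to-end orchestration: weights -> pattern selection -> alignment
cleaning -> affinity/topology analysis, with deterministic TSV reports.

Stages whose inputs are absent from the config are skipped and logged, so the
same entry point serves partial runs (e.g. pattern statistics without trees).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

import arcogkit
from arcogkit import alignment_filtering, clade_affinity, phyletic_patterns
from arcogkit.genome_weighting import GenomeWeightTable, distribute_weights
from arcogkit.tree_io import CladeMap, MembershipTable, read_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    clade_map: str
    species_tree: Optional[str] = None
    weights: Optional[str] = None  # precomputed weights TSV (else from tree)
    membership: Optional[str] = None
    tree_dir: Optional[str] = None
    alignment_dir: Optional[str] = None
    out_dir: str = "arcogkit_out"
    target: Optional[str] = None
    root_weight: Optional[float] = None  # None -> leaf count
    core_threshold: float = 0.75
    core_excluded_clades: list[str] = field(default_factory=list)
    candidate_threshold: float = 0.5
    candidate_min_clades: int = 4
    affinity_threshold: float = 0.75
    exclusivity_cutoff: float = 10.0
    exclusive_in_set: list[str] = field(default_factory=list)
    topology: Optional[dict] = None  # sister_set / group / threshold
    max_gap: float = 0.5
    min_hom: float = 0.1
    max_row_gap: float = 2.0 / 3.0
    requalify_threshold: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, (set, frozenset)) else v)
            for k, v in self.__dict__.items()
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_report(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# arcogkit {arcogkit.__version__} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all configured stages; returns {report name: path}."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    reports: dict[str, Path] = {}

    clades = CladeMap.from_tsv(config.clade_map)

    # ---- stage: genome weights -------------------------------------------
    if config.weights:
        weights = GenomeWeightTable.from_tsv(config.weights)
        logger.info("weights: loaded %d genomes from %s", len(weights), config.weights)
    elif config.species_tree:
        tree = read_tree(config.species_tree)
        weights = distribute_weights(tree, config.root_weight)
        logger.info(
            "weights: distributed root weight %.6g over %d leaves",
            weights.root_weight,
            len(weights),
        )
    else:
        raise ValueError("pipeline needs either 'weights' or 'species_tree'")
    path = out_dir / "weights.tsv"
    _write_report(
        pd.DataFrame(
            sorted(weights.weights.items()), columns=["genome_id", "weight"]
        ),
        path,
        chash,
    )
    reports["weights"] = path

    # ---- stage: phyletic patterns ----------------------------------------
    if config.membership:
        membership = MembershipTable.from_tsv(config.membership)
        matrix = phyletic_patterns.PhyleticMatrix.from_membership(membership)
        profile = phyletic_patterns.clade_representation(matrix, weights, clades)

        path = out_dir / "representation.tsv"
        _write_report(
            phyletic_patterns.representation_frame(profile), path, chash
        )
        reports["representation"] = path

        core = phyletic_patterns.select_core(
            profile,
            excluded_clades=set(config.core_excluded_clades),
            threshold=config.core_threshold,
        )
        path = out_dir / "core_arcogs.tsv"
        _write_report(
            pd.DataFrame(sorted(core), columns=["cluster_id"]), path, chash
        )
        reports["core_arcogs"] = path
        logger.info("patterns: %d core clusters", len(core))

        candidates = phyletic_patterns.select_tree_candidates(
            profile,
            min_clades=config.candidate_min_clades,
            threshold=config.candidate_threshold,
        )
        path = out_dir / "tree_candidates.tsv"
        _write_report(
            pd.DataFrame(sorted(candidates), columns=["cluster_id"]), path, chash
        )
        reports["tree_candidates"] = path

        if config.exclusive_in_set:
            hits = phyletic_patterns.exclusive_screen(
                matrix,
                clades,
                set(config.exclusive_in_set),
                cutoff=config.exclusivity_cutoff,
            )
            rows = [
                (
                    cluster,
                    r_e,
                    phyletic_patterns.contribution_units(
                        r_e, cutoff=config.exclusivity_cutoff
                    ),
                )
                for cluster, r_e in hits
            ]
            path = out_dir / "exclusive_genes.tsv"
            _write_report(
                pd.DataFrame(rows, columns=["cluster_id", "R_E", "units"]),
                path,
                chash,
            )
            reports["exclusive_genes"] = path
    else:
        logger.info("patterns: no membership table configured, stage skipped")

    # ---- stage: alignment cleaning ---------------------------------------
    if config.alignment_dir:
        aln_dir = Path(config.alignment_dir)
        cleaned_dir = out_dir / "cleaned_alignments"
        cleaned_dir.mkdir(exist_ok=True)
        rows = []
        for aln_path in sorted(aln_dir.glob("*.fasta")) + sorted(
            aln_dir.glob("*.fa")
        ):
            aln = alignment_filtering.Alignment.from_fasta(aln_path)
            try:
                filtered, stats = alignment_filtering.filter_sites(
                    aln, max_gap=config.max_gap, min_hom=config.min_hom
                )
                filtered = alignment_filtering.drop_fragmented(
                    filtered, max_row_gap=config.max_row_gap
                )
            except ValueError as exc:
                logger.warning("clean: %s dropped (%s)", aln_path.name, exc)
                rows.append((aln_path.stem, aln.n_cols, 0, 0, "dropped"))
                continue
            filtered, surviving = alignment_filtering.requalify_clades(
                filtered, clades, weights, threshold=config.requalify_threshold
            )
            if filtered.n_rows:
                filtered.to_fasta(cleaned_dir / aln_path.name)
            rows.append(
                (
                    aln_path.stem,
                    aln.n_cols,
                    filtered.n_cols if filtered.n_rows else 0,
                    len(surviving),
                    "ok" if filtered.n_rows else "no_rows",
                )
            )
        path = out_dir / "cleaning_report.tsv"
        _write_report(
            pd.DataFrame(
                rows,
                columns=[
                    "cluster_id",
                    "n_cols_in",
                    "n_cols_out",
                    "n_clades",
                    "status",
                ],
            ),
            path,
            chash,
        )
        reports["cleaning_report"] = path
    else:
        logger.info("clean: no alignment directory configured, stage skipped")

    # ---- stage: clade affinity -------------------------------------------
    if config.tree_dir and config.target:
        topo_cfg = None
        if config.topology:
            data = dict(config.topology)
            data.setdefault("target", config.target)
            data.setdefault("threshold", config.affinity_threshold)
            topo_cfg = clade_affinity.TopologyConfig.from_dict(data)
        results = []
        n_without_target = 0
        for tree_path in sorted(Path(config.tree_dir).glob("*.nwk")):
            tree = read_tree(tree_path)
            genomes = {
                label.split("|", 1)[0] for label in tree.leaf_labels()
            }
            if not any(clades.get(g) == config.target for g in genomes):
                n_without_target += 1
                continue
            results.append(
                clade_affinity.analyze_tree(
                    tree,
                    config.target,
                    weights,
                    clades,
                    config=topo_cfg,
                    threshold=config.affinity_threshold,
                    tree_id=tree_path.stem,
                )
            )
        logger.info(
            "affinity: %d trees analyzed, %d without target clade",
            len(results),
            n_without_target,
        )
        rows = [
            (
                r.tree_id,
                clade,
                r.W.get(clade, 0.0),
                r.R.get(clade, 0.0),
                r.n_nodes,
                r.topology_class or "",
            )
            for r in results
            for clade in sorted(r.R)
        ]
        path = out_dir / "affinity.tsv"
        _write_report(
            pd.DataFrame(
                rows,
                columns=["tree_id", "clade_id", "W", "R", "n_nodes", "class"],
            ),
            path,
            chash,
        )
        reports["affinity"] = path

        if results:
            summary = clade_affinity.aggregate(results)
            rows = [
                ("n_trees_with_target", "", summary.n_trees)
            ]
            for clade in sorted(summary.mean_affinity):
                rows.append(("mean_affinity", clade, summary.mean_affinity[clade]))
            for cls in sorted(summary.class_counts):
                rows.append(("class_count", cls, summary.class_counts[cls]))
            path = out_dir / "summary.tsv"
            _write_report(
                pd.DataFrame(rows, columns=["statistic", "key", "value"]),
                path,
                chash,
            )
            reports["summary"] = path
    else:
        logger.info("affinity: no tree directory / target configured, stage skipped")

    manifest = {
        "tool": "arcogkit",
        "version": arcogkit.__version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "reports": {name: str(p) for name, p in reports.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    reports["manifest"] = manifest_path
    return reports
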