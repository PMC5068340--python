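"""End-to-end orchestration: simulate → qc → assign → consensus → tree →
summarize → cost, with per-stage seeding and a machine-readable manifest.

One global seed fans out to per-stage seeds by fixed offsets, so each stage
is individually reproducible and a rerun with the same config produces
byte-identical outputs.  The manifest records versions, seeds, SHA-256
digests of every output file and per-stage record counts; the counts
satisfy the conservation law
``queries_in == pseudogene_flagged + categorised + unassigned``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, consensus, costing, matchdb, phylo, seqio_qc, survey, synthdata
from .taxonomy import Taxonomy

log = logging.getLogger("larvid")

_STAGE_SEED_OFFSETS = {"simulate": 101, "tree": 211}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: Path
    synth: Optional[synthdata.SynthConfig] = None
    # external inputs, used when synth is None
    queries_fasta: Optional[Path] = None
    db1_fasta: Optional[Path] = None
    db2_fasta: Optional[Path] = None
    taxonomy_tsv: Optional[Path] = None
    stations_tsv: Optional[Path] = None
    cost_yaml: Optional[Path] = None
    min_identity: float = 97.0
    min_coverage: float = 80.0
    check_reverse: bool = False
    bootstrap_reps: int = 100
    tree_queries_per_species: int = 2
    default_visual_minutes: float = 12.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        cfg = cls(
            **{
                k: (Path(v) if k.endswith(("dir", "_fasta", "_tsv", "_yaml")) and v else v)
                for k, v in raw.items()
            }
        )
        if synth is not None:
            cfg.synth = synthdata.SynthConfig(**synth)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 7_919 + _STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Optional[Path], what: str) -> Path:
    if path is None:
        raise PipelineError("inputs", f"no {what} given and no synthetic config set")
    if not Path(path).exists():
        raise PipelineError("inputs", f"{what} not found: {path}")
    return Path(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "larvid_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_SEED_OFFSETS},
        "counts": {},
        "outputs": {},
    }
    counts = manifest["counts"]

    # ---- inputs ---------------------------------------------------------
    truth = None
    if config.synth is not None:
        synth_cfg = config.synth.with_seed(config.stage_seed("simulate"))
        sim = synthdata.simulate(synth_cfg, outdir / "inputs")
        queries, db1, db2 = sim.queries, sim.db1, sim.db2
        taxonomy, stations, truth = sim.taxonomy, sim.stations, sim.truth
    else:
        queries = seqio_qc.read_fasta(_require(config.queries_fasta, "queries FASTA"), "query")
        db1 = seqio_qc.read_fasta(_require(config.db1_fasta, "db1 FASTA"), "reference")
        db2 = seqio_qc.read_fasta(_require(config.db2_fasta, "db2 FASTA"), "reference")
        taxonomy = Taxonomy.read_tsv(_require(config.taxonomy_tsv, "taxonomy TSV"))
        stations = (
            survey.read_stations(_require(config.stations_tsv, "stations TSV"))
            if config.stations_tsv
            else []
        )
    counts["queries_in"] = len(queries)
    counts["db1_references"] = len(db1)
    counts["db2_references"] = len(db2)
    log.info("inputs: %d queries, %d + %d references", len(queries), len(db1), len(db2))

    # ---- qc -------------------------------------------------------------
    qc_table, passing, flagged = seqio_qc.qc_report(queries, config.check_reverse)
    qc_table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    seqio_qc.write_fasta(flagged, outdir / "pseudogene_flagged.fasta")
    counts["pseudogene_flagged"] = len(flagged)
    counts["qc_passed"] = len(passing)
    log.info("qc: %d passed, %d flagged as putative pseudogenes", len(passing), len(flagged))

    # ---- assign ---------------------------------------------------------
    clf = consensus.DualDatabaseClassifier(
        min_identity=config.min_identity, min_coverage=config.min_coverage
    ).fit(db1, db2)
    a1, a2 = clf.predict_per_db(passing)
    matchdb.assignments_frame(a1 + a2).to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    # ---- consensus ------------------------------------------------------
    assignments = [consensus.reconcile(x, y) for x, y in zip(a1, a2)]
    consensus.consensus_frame(assignments).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    tly = consensus.tally(assignments)
    tly.to_frame().to_csv(outdir / "tally.tsv", sep="\t")
    counts["categorised"] = tly.n
    counts["unassigned"] = tly.unassigned
    if counts["qc_passed"] != tly.n + tly.unassigned:
        raise PipelineError("consensus", "record conservation violated")
    log.info(
        "consensus: %d categorised (%s species-final), %d unassigned",
        tly.n, int(tly.final_counts["species"]), tly.unassigned,
    )

    # ---- tree -----------------------------------------------------------
    if config.bootstrap_reps > 0:
        result = _tree_stage(config, passing, assignments, db1, db2, outdir)
        if result is not None:
            counts["tree_leaves"], manifest["monophyly_fraction"], manifest["bootstrap_skipped"] = result

    # ---- summarize ------------------------------------------------------
    if stations:
        query_stations = {q.id: q.station for q in queries if q.station}
        table = survey.species_station_table(assignments, query_stations, stations, taxonomy)
        table.to_csv(outdir / "species_station.tsv", sep="\t", index=False)
        survey.station_abundance(table, stations).to_csv(
            outdir / "abundance.tsv", sep="\t", index=False
        )
        counts["species_final_species"] = len(table)

    # ---- cost -----------------------------------------------------------
    spec = (
        costing.CostSpec.from_yaml(config.cost_yaml)
        if config.cost_yaml
        else costing.CostSpec(default_visual_minutes=config.default_visual_minutes)
    )
    species_counts: dict[str, int] = {}
    for a in assignments:
        if a.final_rank == "species":
            species_counts[a.final_taxon] = species_counts.get(a.final_taxon, 0) + 1
    if species_counts:
        reports = costing.compare_methods(species_counts, spec)
        pd.DataFrame([r.__dict__ for r in reports.values()]).to_csv(
            outdir / "cost_report.tsv", sep="\t", index=False
        )

    # ---- manifest -------------------------------------------------------
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    if truth is not None:
        manifest["recovery"] = _recovery(assignments, truth)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _tree_stage(config, passing, assignments, db1, db2, outdir):
    ref_by_species = {r.lineage.species: r for r in db1}
    for r in db2:
        ref_by_species.setdefault(r.lineage.species, r)
    by_query = {a.query_id: a for a in assignments}
    groups: dict[str, set[str]] = {}
    seqs, labels = [], []
    per_species: dict[str, int] = {}
    for q in passing:
        a = by_query.get(q.id)
        if a is None or a.final_rank != "species":
            continue
        sp = a.final_taxon
        if per_species.get(sp, 0) >= config.tree_queries_per_species:
            continue
        per_species[sp] = per_species.get(sp, 0) + 1
        seqs.append(q.sequence)
        labels.append(q.id)
        groups.setdefault(sp, set()).add(q.id)
    for sp in list(groups):
        ref = ref_by_species.get(sp)
        if ref is not None:
            seqs.append(ref.sequence)
            labels.append(sp)
            groups[sp].add(sp)
    if len(seqs) < 4 or len({len(s) for s in seqs}) != 1:
        log.warning("tree: skipped (<4 leaves or unequal lengths)")
        return None
    boot = phylo.bootstrap_support(
        seqs, labels, n_reps=config.bootstrap_reps, seed=config.stage_seed("tree")
    )
    if boot.skipped:
        log.warning("tree: %d bootstrap replicates skipped (saturation)", boot.skipped)
    phylo.write_newick(boot.tree, outdir / "tree.nwk")
    mono = phylo.monophyly_fraction(boot.tree, groups)
    log.info("tree: %d leaves, monophyly fraction %.3f", len(labels), mono)
    return len(labels), mono, boot.skipped


def _recovery(assignments, truth: synthdata.GroundTruth) -> dict:
    """Fraction of all queries finally assigned to their true species."""
    correct = sum(
        1
        for a in assignments
        if a.final_rank == "species"
        and a.query_id in truth.queries
        and truth.queries[a.query_id].species == a.final_taxon
    )
    total = len(truth.queries)
    return {
        "species_correct": correct,
        "n_queries": total,
        "fraction": correct / total if total else float("nan"),
    }
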