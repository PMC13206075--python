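"""Config-driven orchestration of the full target-discovery analysis.

Stages: simulate (optional) -> per-dataset differential expression ->
pre-ranked GSEA -> consensus pathways / core leading-edge genes ->
target intersection -> docking-affinity triage -> virtual perturbation ->
concordance validation -> report.  Every stage writes TSV/JSON outputs to
the run directory and the run manifest records their SHA-256 hashes, so a
rerun with the same config and seed is verifiably identical.

A single global seed is expanded into independent per-stage child seeds
through ``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``;
toggling one stage therefore never shifts the randomness of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import diffexpr as de
from .concordance import concordance_report
from .containers import CountMatrix, PerturbationProfile, ValidationError
from .datasets import teriflunomide_docking_table
from .enrichment import (GeneSetCollection, RankedGeneList, frame_to_results,
                         preranked_gsea, results_to_frame)
from .perturb import fit_reference_model
from .synthetic import (SimulationConfig, generate_counts, generate_gene_sets,
                        generate_perturbation_profiles)
from .targets import (filter_by_affinity, harmonize_symbols, intersect_targets,
                      read_docking_table, read_target_list)

logger = logging.getLogger(__name__)

# fixed stage order; spawn keys derive from this, not from which stages run
_STAGES = ("simulate", "de", "gsea", "consensus", "intersect", "affinity",
           "perturb", "validate")


@dataclass
class PipelineConfig:
    """All thresholds, paths and toggles of one pipeline run."""

    outdir: str = "dedtarget_run"
    seed: int = 0
    # input paths (ignored when simulate=True)
    counts_paths: list[tuple[str, str]] = field(default_factory=list)  # (counts, groups)
    gmt_path: str | None = None
    target_list_path: str | None = None
    docking_table_path: str | None = None
    profile_paths: list[tuple[str, str]] = field(default_factory=list)  # (path, label)
    # thresholds
    min_count: int = 10
    lfc: float = 1.0
    alpha: float = 0.05
    consensus_frac: float = 0.5
    core_freq: float = 0.5
    affinity: float = -6.5
    top_fraction: float = 0.2
    n_null: int = 100
    n_perm: int = 1000
    kd_primary_log2fc: float = -2.0
    # stage toggles
    simulate: bool = True
    run_perturbation: bool = True
    use_builtin_docking: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if not (0 < self.consensus_frac <= 1 and 0 < self.top_fraction <= 1):
            raise ValidationError("fractions must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))

    # ------------------------------------------------------------- YAML IO
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("counts_paths", "profile_paths"):
            if raw.get(key):
                raw[key] = [tuple(x) for x in raw[key]]
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {"config": dataclasses.asdict(config), "stages": {},
                     "log": []}
        self.outdir = Path(config.outdir)

    def record(self, stage: str, files: list[Path], t0: float) -> None:
        self.data["stages"][stage] = {
            f.name: _sha256(f) for f in files
        }
        self.data["log"].append({
            "stage": stage, "level": "info",
            "message": f"wrote {len(files)} file(s)",
            "wall_time_s": round(time.perf_counter() - t0, 3),
        })

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Fails loudly at the first broken stage (the exception names it); files
    written by earlier stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    config.to_yaml(outdir / "config.yaml")

    # ---------------------------------------------------------- simulate
    sim_cfg: SimulationConfig | None = None
    profiles: dict[str, PerturbationProfile] = {}
    truth = None
    if config.simulate:
        t0 = time.perf_counter()
        sim_cfg = SimulationConfig(**{"seed": config.stage_seed("simulate"),
                                      **config.simulation})
        datasets, truth = generate_counts(sim_cfg)
        collection = generate_gene_sets(sim_cfg)
        profiles = generate_perturbation_profiles(sim_cfg, truth)
        files = []
        for d in datasets:
            cpath = outdir / f"{d.name}_counts.tsv"
            gpath = outdir / f"{d.name}_groups.tsv"
            d.to_tsv(cpath, gpath)
            files += [cpath, gpath]
        gmt = outdir / "gene_sets.gmt"
        collection.write_gmt(gmt)
        for label, prof in profiles.items():
            ppath = outdir / f"profile_{label.replace(':', '_')}.tsv"
            prof.to_tsv(ppath)
            files.append(ppath)
        tpath = outdir / "ground_truth.json"
        truth.to_json(tpath)
        manifest.record("simulate", files + [gmt, tpath], t0)
    else:
        datasets = [
            CountMatrix.from_tsv(c, g, name=f"D{i + 1}")
            for i, (c, g) in enumerate(config.counts_paths)
        ]
        if config.gmt_path is None:
            raise ValidationError("gmt_path required when simulate=False")
        collection = GeneSetCollection.read_gmt(config.gmt_path)

    # ---------------------------------------------------------------- de
    t0 = time.perf_counter()
    de_tables: dict[str, pd.DataFrame] = {}
    files = []
    for d in datasets:
        filtered = de.filter_low_counts(d, config.min_count)
        table = de.differential_expression(filtered)
        de_tables[d.name] = table
        path = outdir / f"{d.name}_de.tsv"
        table.to_csv(path, sep="\t", index=False)
        files.append(path)
    manifest.record("de", files, t0)

    # -------------------------------------------------------------- gsea
    t0 = time.perf_counter()
    gsea_seed = config.stage_seed("gsea")
    enrich: dict[str, list] = {}
    files = []
    for i, (name, table) in enumerate(de_tables.items()):
        ranked = de.rank_genes(table)
        enrich[name] = preranked_gsea(ranked, collection, n_perm=config.n_perm,
                                      seed=gsea_seed + i)
        path = outdir / f"{name}_gsea.tsv"
        results_to_frame(enrich[name]).to_csv(path, sep="\t", index=False)
        files.append(path)
    manifest.record("gsea", files, t0)

    # ---------------------------------------------------------- consensus
    t0 = time.perf_counter()
    consensus = cons.consensus_pathways(enrich, alpha=config.alpha,
                                        min_frac=config.consensus_frac)
    cpath = outdir / "consensus_pathways.tsv"
    cons.consensus_to_frame(consensus).to_csv(cpath, sep="\t", index=False)
    files = [cpath]
    core: set[str] = set()
    if consensus:
        freq = cons.leading_edge_frequency(consensus, enrich)
        fpath = outdir / "core_genes.tsv"
        freq.to_csv(fpath, sep="\t", index=False)
        files.append(fpath)
        core = cons.core_leading_edge_genes(freq, config.core_freq)
    manifest.record("consensus", files, t0)

    # ---------------------------------------------------------- intersect
    t0 = time.perf_counter()
    if config.target_list_path:
        predicted_raw = read_target_list(config.target_list_path)
    elif sim_cfg is not None:
        decoys = sorted(
            g[3:] for g in profiles if g.startswith("KD:")
            and g[3:] not in sim_cfg.true_targets
        )[:10]
        predicted_raw = list(sim_cfg.true_targets) + decoys
    else:
        predicted_raw = []
    predicted, _ = harmonize_symbols(predicted_raw)
    core_harm, _ = harmonize_symbols(sorted(core))
    key_genes = intersect_targets(predicted, core_harm)
    ipath = outdir / "key_genes.tsv"
    pd.DataFrame({
        "gene": key_genes
    }).to_csv(ipath, sep="\t", index=False)
    meta = outdir / "target_counts.json"
    with open(meta, "w") as fh:
        json.dump({"predicted_raw": len(predicted_raw),
                   "predicted_harmonized": len(predicted),
                   "core_genes": len(core_harm),
                   "key_genes": len(key_genes)}, fh, indent=1)
    manifest.record("intersect", [ipath, meta], t0)

    # ----------------------------------------------------------- affinity
    t0 = time.perf_counter()
    if config.docking_table_path:
        docking = read_docking_table(config.docking_table_path)
    elif config.use_builtin_docking:
        docking = teriflunomide_docking_table()
    else:
        docking = None
    files = []
    if docking is not None:
        prioritized = filter_by_affinity(docking, config.affinity)
        apath = outdir / "prioritized_targets.tsv"
        prioritized.to_csv(apath, sep="\t", index=False)
        files.append(apath)
    manifest.record("affinity", files, t0)

    # -------------------------------------------- perturbation + validate
    if config.run_perturbation:
        t0 = time.perf_counter()
        model = fit_reference_model(datasets)
        mpath = outdir / "coexpression_model.tsv"
        model.to_tsv(mpath)
        manifest.record("perturb", [mpath], t0)

        t0 = time.perf_counter()
        drug = profiles.get("drug")
        if drug is None and config.profile_paths:
            from .perturb import load_profiles
            loaded = load_profiles(config.profile_paths, universe=model.genes)
            by_label = {p.label: p for p in loaded}
            drug = by_label.get("drug")
            profiles = by_label
        if drug is not None:
            candidates = [g for g in (key_genes or predicted)
                          if g in set(model.genes)]
            cand_profiles = {
                g: profiles[f"KD:{g}"] for g in candidates
                if f"KD:{g}" in profiles
            }
            # pathway-level enrichment of drug + candidate KD profiles
            enrichments = {"synthetic": {}}
            v_seed = config.stage_seed("validate")
            for j, (label, prof) in enumerate(
                    [("drug", drug)] +
                    [(f"KD:{g}", p) for g, p in sorted(cand_profiles.items())]):
                order = prof.log2fc.sort_values(ascending=False)
                order = order.iloc[np.lexsort(
                    (order.index.to_numpy(), -order.to_numpy()))]
                ranked = RankedGeneList(list(order.index), order.to_numpy())
                enrichments["synthetic"][label] = preranked_gsea(
                    ranked, collection, n_perm=config.n_perm, seed=v_seed + 1 + j)
            report = concordance_report(
                model, drug, candidates,
                eligible=set(model.genes),
                enrichments=enrichments,
                fraction=config.top_fraction, n_null=config.n_null,
                seed=v_seed, primary_log2fc=config.kd_primary_log2fc,
                alpha=config.alpha, profiles=cand_profiles,
            )
            rpath = outdir / "concordance.json"
            report.to_json(rpath)
            ppath = outdir / "candidate_pcc.tsv"
            report.candidate_pcc.rename_axis("gene").to_csv(ppath, sep="\t")
            npath = outdir / "null_pcc.tsv"
            report.null_pcc.rename_axis("gene").to_csv(npath, sep="\t")
            aupath = outdir / "auroc.tsv"
            report.auroc_table.to_csv(aupath, sep="\t", index=False)
            manifest.record("validate", [rpath, ppath, npath, aupath], t0)
        else:
            logger.info("validate: no drug profile available; skipped")

    path = manifest.write()
    logger.info("pipeline complete: %s", path)
    return manifest.data


def write_report(manifest: dict, outdir=None) -> Path:
    """Human-readable markdown summary of one run's outputs."""
    cfg = manifest["config"]
    outdir = Path(outdir or cfg["outdir"])
    lines = ["# Target-discovery run report", ""]
    lines.append("## Thresholds")
    for key in ("min_count", "lfc", "alpha", "consensus_frac", "core_freq",
                "affinity", "top_fraction", "n_null", "n_perm", "seed"):
        lines.append(f"- {key}: {cfg[key]}")
    lines.append("")

    def table_section(title, fname, max_rows=25):
        lines.append(f"## {title}")
        path = outdir / fname
        if fname not in manifest["stages"].get(_stage_of(fname), {}) \
                or not path.exists():
            lines.append("_not run_\n")
            return
        frame = pd.read_csv(path, sep="\t")
        if frame.empty:
            lines.append("_empty (zero rows)_\n")
            return
        lines.append(frame.head(max_rows).to_markdown(index=False))
        if len(frame) > max_rows:
            lines.append(f"\n({len(frame) - max_rows} more rows)")
        lines.append("")

    def _stage_of(fname):
        for stage, files in manifest["stages"].items():
            if fname in files:
                return stage
        return ""

    table_section("Consensus pathways", "consensus_pathways.tsv")
    table_section("Core leading-edge genes", "core_genes.tsv")
    table_section("Key genes (targets ∩ core)", "key_genes.tsv")
    table_section("Prioritized targets (affinity filter)",
                  "prioritized_targets.tsv")
    table_section("Candidate PCC vs drug", "candidate_pcc.tsv")
    table_section("Pathway AUROC", "auroc.tsv")

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
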