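"""End-to-end pipeline: normalize → DE → clustering → transitions → enrichment
→ cell abundance, driven by a single YAML-able config with one seed.

Every stage writes its artifact as TSV (or GMT/plain text) into the output
directory; the run manifest records the config echo, per-stage row counts and
a SHA-256 checksum of every file, so identical (config, seed) pairs can be
verified to reproduce bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import SignatureSet, estimate_abundance, zscore_abundance
from .clustering import (build_profiles, estimate_fuzzifier, fuzzy_cmeans,
                         select_cluster_number)
from .de import run_all_contrasts, select_dynamic_genes
from .enrichment import (GeneSetCollection, build_enrichment_map,
                         gsea_preranked, ora_hypergeometric, rank_genes)
from .expression import (ValidationError, filter_expressed, normalize,
                         read_counts, read_sample_table, tmm_factors)
from .io import read_gmt, read_signatures, write_rnk
from .simulate import SimulationConfig, simulate_counts, write_dataset
from .transitions import compute_transition_matrix, extract_transition_genes

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Inputs (file paths) XOR a simulate block, plus stage parameters."""

    outdir: str = "clustershift_run"
    seed: int = 0
    tissue: str | None = None
    inputs: dict | None = None          # counts, lengths, samples, gene_sets, signatures
    simulate: dict | None = None        # SimulationConfig fields
    pseudocount: float = 1.0
    p_threshold: float = 0.05
    fuzzifier: float | None = None
    clusters: int | None = None
    scan_range: tuple = (4, 27)
    theta: float = 0.1
    n_perm: int = 1000
    q_cut: float = 0.05
    sim_cut: float = 0.25
    min_transition_genes: int = 10

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValidationError("config must provide exactly one of inputs / simulate")
        if not 0 < self.p_threshold < 1 or not 0 < self.q_cut < 1:
            raise ValidationError("p_threshold and q_cut must lie in (0, 1)")
        if not 0 <= self.sim_cut <= 1:
            raise ValidationError("sim_cut must lie in [0, 1]")
        if self.theta < 0 or self.pseudocount <= 0:
            raise ValidationError("theta >= 0 and pseudocount > 0 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()},
                      "stages": {}, "files": {}}

    def emit(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    # stage 0: inputs
    if config.simulate is not None:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulate})
        cm, samples, gt = simulate_counts(sim)
        paths = write_dataset(out / "simulated", cm, samples, gt)
        for k, p in paths.items():
            emit(f"simulated/{k}", Path(p))
        gene_sets = GeneSetCollection(
            {k: v["genes"] for k, v in gt.planted_sets.items()},
            {"source": "simulated"})
        signatures = SignatureSet(getattr(gt, "signatures", {}), {"source": "simulated"})
    else:
        inp = config.inputs
        cm = read_counts(inp["counts"], inp.get("lengths"))
        samples = read_sample_table(inp["samples"])
        gene_sets = GeneSetCollection(read_gmt(inp["gene_sets"]),
                                      {"source": inp["gene_sets"]}) \
            if inp.get("gene_sets") else GeneSetCollection({}, {})
        signatures = SignatureSet(read_signatures(inp["signatures"]),
                                  {"source": inp["signatures"]}) \
            if inp.get("signatures") else SignatureSet({})
    if config.tissue is not None:
        samples = samples.subset(config.tissue)
        cm_cols = [s for s in cm.samples if s in set(samples.samples)]
        from .expression import CountMatrix
        cm = CountMatrix(cm.counts[cm_cols], cm.lengths)
    manifest["stages"]["input"] = {"genes": len(cm.genes), "samples": len(cm.samples)}

    # stage 1: normalization
    cm = filter_expressed(cm)
    factors = tmm_factors(cm)
    expr = normalize(cm, factors, config.pseudocount)
    expr.values.to_csv(out / "expression.tsv", sep="\t", float_format=FLOAT_FMT,
                       index_label="gene")
    emit("expression", out / "expression.tsv")
    manifest["stages"]["normalize"] = {
        "genes": len(expr.genes), "tmm_reference": factors.reference}

    # stage 2: differential expression
    de = run_all_contrasts(expr, samples)
    for name, df in de.items():
        p = out / f"de_{name}.tsv"
        df.to_csv(p, sep="\t", float_format=FLOAT_FMT, index_label="gene")
        emit(f"de/{name}", p)
    dynamic = select_dynamic_genes(de, config.p_threshold)
    (out / "dynamic_genes.txt").write_text("\n".join(dynamic) + "\n")
    emit("dynamic_genes", out / "dynamic_genes.txt")
    manifest["stages"]["differential_expression"] = {
        "contrasts": sorted(de), "dynamic_genes": len(dynamic)}
    if not dynamic:
        raise ValidationError("differential_expression: no dynamic genes selected")

    # stage 3: profiles + clustering
    profiles = build_profiles(expr, samples, dynamic)
    profiles.values.to_csv(out / "profiles.tsv", sep="\t", float_format=FLOAT_FMT)
    emit("profiles", out / "profiles.tsv")
    m = config.fuzzifier or estimate_fuzzifier(profiles)
    if config.clusters is not None:
        c = int(config.clusters)
    else:
        scan = select_cluster_number(profiles, m, tuple(config.scan_range),
                                     config.theta, seed=config.seed)
        scan.table.to_csv(out / "cluster_scan.tsv", sep="\t", index=False,
                          float_format=FLOAT_FMT)
        emit("cluster_scan", out / "cluster_scan.tsv")
        c = scan.chosen_c
    model = fuzzy_cmeans(profiles, c, m, seed=config.seed)
    model.centroids.to_csv(out / "centroids.tsv", sep="\t", float_format=FLOAT_FMT,
                           index_label="cluster")
    assign = pd.DataFrame({
        "cluster": model.assignments,
        "max_membership": model.memberships.max(axis=1),
    })
    assign.to_csv(out / "clusters.tsv", sep="\t", float_format=FLOAT_FMT)
    emit("centroids", out / "centroids.tsv")
    emit("clusters", out / "clusters.tsv")
    manifest["stages"]["clustering"] = {
        "rows": len(profiles.values), "c": c, "fuzzifier": m,
        "dropped_flat_genes": len(profiles.dropped)}

    # stage 4: transition matrix
    tm = compute_transition_matrix(model)
    tm.counts.to_csv(out / "transition_counts.tsv", sep="\t")
    tm.proportions.to_csv(out / "transition_proportions.tsv", sep="\t",
                          float_format=FLOAT_FMT)
    emit("transition_counts", out / "transition_counts.tsv")
    emit("transition_proportions", out / "transition_proportions.tsv")
    manifest["stages"]["transitions"] = {
        "genes": int(tm.counts.to_numpy().sum()), "empty_rows": tm.empty_rows}

    # stage 5: per-transition gene lists + ORA
    trans_dir = out / "transition_genes"
    trans_dir.mkdir(exist_ok=True)
    universe = list(profiles.genes)
    ora_runs = {}
    for i in tm.counts.index:
        for j in tm.counts.columns:
            if i == j or tm.counts.loc[i, j] < config.min_transition_genes:
                continue
            genes_ij = extract_transition_genes(model, i, j)
            p = trans_dir / f"C{i}_to_C{j}.txt"
            p.write_text("\n".join(genes_ij) + "\n")
            emit(f"transition_genes/C{i}_to_C{j}", p)
            if len(gene_sets):
                ora = ora_hypergeometric(genes_ij, gene_sets, universe)
                po = out / f"ora_C{i}_to_C{j}.tsv"
                ora.to_csv(po, sep="\t", float_format=FLOAT_FMT)
                emit(f"ora/C{i}_to_C{j}", po)
                ora_runs[f"C{i}>C{j}"] = int((ora["q"] < config.q_cut).sum())
    manifest["stages"]["transition_ora"] = ora_runs

    # stage 6: stage-wise GSEA on the four vs-baseline contrasts
    gsea_runs = {}
    if len(gene_sets):
        for name in ("3v0_control", "8v0_control", "3v0_inhibitor", "8v0_inhibitor"):
            if name not in de:
                continue
            ranked = rank_genes(de[name])
            write_rnk(ranked, out / f"ranked_{name}.rnk")
            emit(f"rnk/{name}", out / f"ranked_{name}.rnk")
            res = gsea_preranked(ranked, gene_sets, n_perm=config.n_perm,
                                 seed=config.seed)
            tbl = res.table.copy()
            tbl["leading_edge"] = tbl["leading_edge"].map(",".join)
            p = out / f"gsea_{name}.tsv"
            tbl.to_csv(p, sep="\t", float_format=FLOAT_FMT)
            emit(f"gsea/{name}", p)
            gsea_runs[name] = int((res.table["q"] < config.q_cut).sum())
            emap = build_enrichment_map(res.table, gene_sets, universe=ranked.index,
                                        q_cut=config.q_cut, sim_cut=config.sim_cut)
            nodes = pd.DataFrame(
                [{"set": n, **d} for n, d in emap.nodes(data=True)])
            edges = pd.DataFrame(
                [{"source": a, "target": b, **d} for a, b, d in emap.edges(data=True)])
            nodes.to_csv(out / f"emap_nodes_{name}.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
            edges.to_csv(out / f"emap_edges_{name}.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
            emit(f"emap_nodes/{name}", out / f"emap_nodes_{name}.tsv")
            emit(f"emap_edges/{name}", out / f"emap_edges_{name}.tsv")
    manifest["stages"]["gsea"] = gsea_runs

    # stage 7: cell abundance
    if signatures.signatures:
        ab = estimate_abundance(expr, signatures)
        abz = zscore_abundance(ab)
        ab.values.to_csv(out / "abundance_raw.tsv", sep="\t", float_format=FLOAT_FMT,
                         index_label="cell_type")
        abz.values.to_csv(out / "abundance_zscore.tsv", sep="\t",
                          float_format=FLOAT_FMT, index_label="cell_type")
        emit("abundance_raw", out / "abundance_raw.tsv")
        emit("abundance_zscore", out / "abundance_zscore.tsv")
        manifest["stages"]["abundance"] = {"cell_types": len(ab.values)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
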