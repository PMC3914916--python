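"""Stage-wise pipeline: simulate -> cluster -> translate -> community ->
nullmodel -> network, with every stage reading its inputs from and writing
its outputs to a results directory.

Each stage derives its own random substream from the single global seed, so
reruns with an identical configuration reproduce identical numeric outputs
and stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, io, motu as motu_mod, network, nullmodel, synthetic
from .config import PipelineConfig

__all__ = ["run_pipeline", "stage_names", "run_stage", "stage_seed"]

logger = logging.getLogger("nifhnet")

STAGES = ("simulate", "cluster", "translate", "community", "nullmodel", "network")


def stage_names() -> tuple[str, ...]:
    return STAGES


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed fanned out from the global seed."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _read_logs(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "logs.tsv", sep="\t", index_col=0)


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    seed = stage_seed(config.seed, "simulate")
    design = synthetic.StudyDesign(n_logs=config.n_logs, seed=seed)
    logs = synthetic.generate_logs(design)
    fungal, motus, truth = synthetic.generate_occurrences(
        logs,
        n_fungi=config.n_fungi,
        n_motus=config.n_motus,
        seed=seed + 1,
        species_effect=config.species_effect,
    )
    reads = synthetic.generate_amplicons(
        motus,
        divergence_within=config.divergence_within,
        seed=seed + 2,
        log_species=logs["species"].to_dict(),
    )
    logs.to_csv(outdir / "logs.tsv", sep="\t")
    io.write_matrix(fungal, outdir / "fungal.tsv", dialect="binary")
    io.write_matrix(motus, outdir / "motus_true.tsv", dialect="abundance")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    io.write_fasta(reads, outdir / "reads.fasta")
    logger.info("simulate: %d logs, %d reads", len(logs), len(reads))


def stage_cluster(config: PipelineConfig, outdir: Path) -> None:
    reads = io.read_fasta(outdir / "reads.fasta")
    trims = [motu_mod.trim_primers(r) for r in reads]
    kept = [t.record for t in trims if t.trimmed]
    n_flagged = len(trims) - len(kept)
    motus = motu_mod.cluster_greedy(kept, threshold=config.clustering_threshold)
    logs = _read_logs(outdir)
    table = pd.DataFrame(0, index=logs.index, columns=[m.id for m in motus])
    for m in motus:
        for log_id, count in m.abundance_by_log().items():
            table.loc[log_id, m.id] = count
    io.write_matrix(table, outdir / "motu_table.tsv", dialect="abundance")
    membership = pd.DataFrame(
        [
            {
                "read_id": rec.id,
                "motu": m.id,
                "representative": int(rec.id == m.representative.id),
            }
            for m in motus
            for rec in m.members
        ]
    )
    membership.to_csv(outdir / "membership.tsv", sep="\t", index=False)
    summary = motu_mod.motu_summaries(motus)
    (outdir / "motu_summary.json").write_text(json.dumps(summary, indent=1))
    logger.info(
        "cluster: %d reads trimmed (%d flagged), %d MOTUs, singleton fraction %.3f",
        len(kept), n_flagged, len(motus), summary["singleton_fraction"],
    )


def _rebuild_motus(outdir: Path) -> list[motu_mod.Motu]:
    reads = {r.id: r for r in io.read_fasta(outdir / "reads.fasta")}
    membership = pd.read_csv(outdir / "membership.tsv", sep="\t")
    motus: dict[str, motu_mod.Motu] = {}
    for _, row in membership.iterrows():
        rec = motu_mod.trim_primers(reads[row["read_id"]]).record
        m = motus.get(row["motu"])
        if m is None:
            m = motu_mod.Motu(id=row["motu"], representative=rec, members=[])
            motus[row["motu"]] = m
        m.members.append(rec)
        if row["representative"]:
            m.representative = rec
    return list(motus.values())


def stage_translate(config: PipelineConfig, outdir: Path) -> None:
    motus = _rebuild_motus(outdir)
    rows, fasta_lines = [], []
    for m in motus:
        frame = motu_mod.select_reading_frame(m.representative.sequence)
        if frame is None:
            rows.append({"motu": m.id, "frame": -1, "conserved_cysteines": False})
            continue
        cons = motu_mod.consensus_protein(m, frame)
        rows.append(
            {
                "motu": m.id,
                "frame": frame,
                "conserved_cysteines": cons.conserved_cysteines,
            }
        )
        fasta_lines.append(f">{m.id} frame={frame}\n{cons.sequence}\n")
    pd.DataFrame(rows).to_csv(outdir / "frames.tsv", sep="\t", index=False)
    (outdir / "consensus_proteins.faa").write_text("".join(fasta_lines))
    logger.info("translate: %d consensus proteins", len(fasta_lines))


def stage_community(config: PipelineConfig, outdir: Path) -> None:
    seed = stage_seed(config.seed, "community")
    logs = _read_logs(outdir)
    motus, _ = io.read_matrix(outdir / "motu_table.tsv")
    fungal, _ = io.read_matrix(outdir / "fungal.tsv")
    decay = community.kmeans_decay_classes(logs["remaining_mass"], k=config.kmeans_k)
    meta = logs.assign(decay_class=decay.classes)
    meta.to_csv(outdir / "log_metadata.tsv", sep="\t")

    nonzero = motus.index[motus.sum(axis=1) > 0]
    dist = community.bray_curtis(motus.loc[nonzero])
    perm = community.permanova(
        dist, meta.loc[nonzero], n_permutations=config.n_permutations, seed=seed
    )
    perm.table.to_csv(outdir / "permanova.tsv", sep="\t")

    tree = community.mrt(
        motus.loc[nonzero], meta.loc[nonzero, ["species", "management", "decay_class"]]
    )
    (outdir / "mrt.json").write_text(json.dumps(tree.to_dict(), indent=1))
    leaf_groups = pd.Series(
        {s: leaf.leaf_id for leaf in tree.leaves() for s in leaf.samples}
    ).loc[nonzero]
    if leaf_groups.nunique() > 1:
        pca = community.pca_group_means(motus.loc[nonzero], leaf_groups)
        pca["sample_scores"].to_csv(outdir / "pca_scores.tsv", sep="\t")

    richness = pd.DataFrame(
        {
            "sporocarp_richness": (fungal > 0).sum(axis=1),
            "nifh_richness": (motus > 0).sum(axis=1),
            "species": meta["species"],
            "n_per_density": meta["n_per_density"],
            "c_per_density": meta["c_per_density"],
            "decay_class": meta["decay_class"],
        }
    )
    models = community.richness_models(richness)
    models["anova"].to_csv(outdir / "richness_anova.tsv", sep="\t")
    (outdir / "richness_selected.json").write_text(
        json.dumps({"selected_predictors": models["selected_predictors"]}, indent=1)
    )
    logger.info(
        "community: residual df %d (perMANOVA), %d MRT leaves",
        perm.residual_df, len(tree.leaves()),
    )


def stage_nullmodel(config: PipelineConfig, outdir: Path) -> None:
    seed = stage_seed(config.seed, "nullmodel")
    motus, _ = io.read_matrix(outdir / "motu_table.tsv")
    fungal, _ = io.read_matrix(outdir / "fungal.tsv")

    full = nullmodel.binarize_and_filter(fungal, motus, apply_filter=False)
    ens_full = nullmodel.null_ensemble(
        full, n=config.ensemble_size, burn_in=config.burn_in,
        spacing=config.spacing, seed=seed,
    )
    obs_c = nullmodel.cscore(full)
    obs_pairs, obs_units = nullmodel.checkerboard_stats(full)
    stats = {
        "cscore_observed": obs_c,
        "cscore_expected": float(ens_full.cscores.mean()),
        "cscore_p": nullmodel.matrix_test(obs_c, ens_full.cscores),
        "checkerboard_pairs_observed": obs_pairs,
        "checkerboard_pairs_expected": float(ens_full.checkerboard_pairs.mean()),
        "checkerboard_pairs_p": nullmodel.matrix_test(
            obs_pairs, ens_full.checkerboard_pairs
        ),
        "checkerboard_units_observed": obs_units,
        "checkerboard_units_expected": float(ens_full.checkerboard_units.mean()),
        "swap_acceptance_rate": ens_full.acceptance_rate,
    }
    (outdir / "matrix_stats.json").write_text(json.dumps(stats, indent=1))
    logger.info(
        "nullmodel: C-score %.4f (expected %.4f), swap acceptance %.3f",
        obs_c, stats["cscore_expected"], ens_full.acceptance_rate,
    )

    filtered = nullmodel.binarize_and_filter(
        fungal, motus, min_occurrence=config.min_occurrence
    )
    binary = pd.DataFrame(filtered.data, index=filtered.taxa, columns=filtered.sites)
    io.write_matrix(binary, outdir / "binary_matrix.tsv", dialect="binary")
    ens = nullmodel.null_ensemble(
        filtered, n=config.ensemble_size, burn_in=config.burn_in,
        spacing=config.spacing, seed=seed + 1,
    )
    pairs = nullmodel.pairwise_z(filtered, ens, z_threshold=config.z_threshold)
    (outdir / "pairs.json").write_text(
        json.dumps(
            {
                "kingdoms": dict(zip(filtered.taxa, filtered.kingdoms)),
                "pairs": [dataclasses.asdict(p) for p in pairs],
            },
            indent=1,
        )
    )
    n_sig = sum(p.classification in ("co-occurrence", "avoidance") for p in pairs)
    logger.info("nullmodel: %d/%d pairs significant", n_sig, len(pairs))


def stage_network(config: PipelineConfig, outdir: Path) -> None:
    logs = _read_logs(outdir)
    payload = json.loads((outdir / "pairs.json").read_text())
    pairs = [nullmodel.PairScore(**p) for p in payload["pairs"]]
    binary, _ = io.read_matrix(outdir / "binary_matrix.tsv")

    graph = network.build_network(pairs)
    species_of = logs["species"]
    counts = {
        taxon: {
            sp: int(binary.loc[taxon][species_of == sp].astype(bool).sum())
            for sp in species_of.unique()
        }
        for taxon in binary.index
    }
    network.annotate_affiliations(
        graph, counts, threshold=config.affiliation_threshold
    )
    network.export_network(graph, outdir / "network.tsv", fmt="tsv")
    network.export_network(graph, outdir / "network.sif", fmt="sif")
    network.export_network(graph, outdir / "network.graphml", fmt="graphml")
    if graph.number_of_nodes():
        hubs, mean_degree = network.hubs_and_degree(
            graph, hub_threshold=config.hub_threshold
        )
    else:
        hubs, mean_degree = [], 0.0
    stats = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "mean_degree": mean_degree,
        "hubs": hubs,
        "subnetworks": network.subnetwork_summary(graph),
    }
    (outdir / "network_stats.json").write_text(json.dumps(stats, indent=1))
    logger.info(
        "network: %d nodes, %d edges, mean degree %.2f",
        stats["n_nodes"], stats["n_edges"], mean_degree,
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "translate": stage_translate,
    "community": stage_community,
    "nullmodel": stage_nullmodel,
    "network": stage_network,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> None:
    """Run a single named stage against an existing results directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[stage](config, outdir)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage in order, logging to ``run.log`` in the output dir.

    Writes the effective configuration (with resolved per-stage seeds) as
    ``effective_config.json``.  A failing stage raises after the failure is
    recorded in the log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        effective = dict(config.to_dict())
        effective["stage_seeds"] = {s: stage_seed(config.seed, s) for s in STAGES}
        (outdir / "effective_config.json").write_text(json.dumps(effective, indent=1))
        for stage in STAGES:
            logger.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](config, outdir)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
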