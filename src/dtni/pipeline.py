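"""End-to-end orchestration: groups x gene sets -> consensus networks,
role reports, perturbation calls, optional edge validation, cross-group
partition, and a hashed artifact manifest."""

from __future__ import annotations

import hashlib
import json
import os

from . import __version__
from .analysis import (annotate_and_export, cross_group_partition, max_response_table,
                       node_roles)
from .config import PipelineConfig
from .consensus import GroupSpec, intersect_networks, run_group_dtni
from .errors import ConfigError
from .expression import read_expression_long, subset_genes
from .exports import write_network_attributes, write_network_json, write_network_sif
from .genesets import read_gmt
from .refnet import classify_network, read_sif


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured workflow and write all artifacts.

    Returns the manifest mapping (also written to ``manifest.json``):
    relative artifact paths to content hashes, plus the parameters and
    seed of the run.
    """
    outdir = cfg.resolve(cfg.outdir)
    os.makedirs(outdir, exist_ok=True)
    artifacts: list[str] = []

    all_sets = {gs.name: gs for gs in read_gmt(cfg.resolve(cfg.gmt_path))}
    missing = [n for n in cfg.geneset_names if n not in all_sets]
    if missing:
        raise ConfigError(f"gene set(s) {missing} not present in {cfg.gmt_path}")
    reference = read_sif(cfg.resolve(cfg.reference_path)) if cfg.reference_path else None

    groups = {}
    for g in cfg.groups:
        data = {c["compound"]: read_expression_long(cfg.resolve(c["path"]))
                for c in g.compounds}
        groups[g.name] = GroupSpec(name=g.name,
                                   compounds=[c["compound"] for c in g.compounds],
                                   data=data)

    consensus_by_set: dict[str, dict] = {}
    for set_name in cfg.geneset_names:
        geneset = all_sets[set_name]
        consensus_by_set[set_name] = {}
        for group_name, group in groups.items():
            prefix = os.path.join(outdir, f"{group_name}__{set_name}")
            runset = run_group_dtni(group, geneset, cfg.params)
            for k, run in enumerate(runset.runs):
                tag = "pooled" if k == 0 else f"loo_{sorted(set(group.compounds) - set(run.included))[0]}"
                for writer, ext in ((write_network_sif, "sif"),
                                    (write_network_attributes, "edges.tsv"),
                                    (write_network_json, "json")):
                    p = f"{prefix}__run_{tag}.{ext}"
                    writer(run.network, p)
                    artifacts.append(p)
            consensus = intersect_networks(runset, cfg.require_sign_consistency)
            for writer, ext in ((write_network_sif, "sif"),
                                (write_network_attributes, "edges.tsv"),
                                (write_network_json, "json")):
                p = f"{prefix}__consensus.{ext}"
                writer(consensus, p)
                artifacts.append(p)
            roles = node_roles(consensus, geneset=None)
            roles_path = f"{prefix}__roles.json"
            with open(roles_path, "w", encoding="utf-8") as fh:
                json.dump({
                    "starting": sorted(roles.starting),
                    "targets": sorted(roles.targets),
                    "intermediate": sorted(roles.intermediate),
                    "isolated": sorted(roles.isolated),
                    "perturbation_calls": consensus.perturbation_calls,
                }, fh, indent=2)
            artifacts.append(roles_path)
            if reference is not None:
                summary = classify_network(consensus, reference)
                summary.write_tsv(f"{prefix}__validation.tsv")
                summary.write_json(f"{prefix}__validation.json")
                artifacts += [f"{prefix}__validation.tsv", f"{prefix}__validation.json"]
            consensus_by_set[set_name][group_name] = (consensus, group)

        nets = {g: c for g, (c, _) in consensus_by_set[set_name].items()}
        if len(nets) >= 2:
            partition = cross_group_partition(nets)
            part_path = os.path.join(outdir, f"{set_name}__cross_group.json")
            with open(part_path, "w", encoding="utf-8") as fh:
                json.dump({
                    "nodes": {n: sorted(g) for n, g in partition.node_groups.items()},
                    "edges": {f"{s}->{t}": sorted(g)
                              for (s, t), g in partition.edge_groups.items()},
                    "target_clusters": {"|".join(sorted(k)): sorted(v)
                                        for k, v in partition.target_clusters.items()},
                }, fh, indent=2)
            artifacts.append(part_path)
        summaries = {}
        for group_name, (consensus, group) in consensus_by_set[set_name].items():
            pooled = None
            for compound in group.compounds:
                sub, _ = subset_genes(group.data[compound], consensus.genes)
                pooled = sub if pooled is None else _concat(pooled, sub)
            summaries[group_name] = max_response_table(pooled)
        graphml = os.path.join(outdir, f"{set_name}__annotated.graphml")
        node_tsv = os.path.join(outdir, f"{set_name}__nodes.tsv")
        edge_tsv = os.path.join(outdir, f"{set_name}__edges.tsv")
        annotate_and_export(nets, summaries, graphml, node_tsv, edge_tsv)
        artifacts += [graphml, node_tsv, edge_tsv]

    manifest = {
        "version": __version__,
        "seed": cfg.params.seed,
        "alpha": cfg.params.alpha,
        "estimator": cfg.params.estimator,
        "artifacts": {os.path.relpath(p, outdir): _sha256(p) for p in sorted(artifacts)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _concat(a, b):
    from .consensus import pool_group

    return pool_group({"a": a, "b": b}, ("a", "b"))
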