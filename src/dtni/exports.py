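"""Writers for inferred and consensus networks: SIF, TSV attributes, JSON.

SIF uses the interaction tags ``activates`` / ``represses`` according to
the sign of the inferred coefficient.
"""

from __future__ import annotations

import json

import pandas as pd

from .consensus import ConsensusNetwork
from .inference import InferredNetwork


def _tag(sign: int) -> str:
    return "activates" if sign > 0 else "represses"


def write_network_sif(net: InferredNetwork | ConsensusNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\t{_tag(e.sign)}\t{e.target}\n")


def write_network_attributes(net: InferredNetwork | ConsensusNetwork, path) -> None:
    rows = []
    if isinstance(net, ConsensusNetwork):
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            rows.append({
                "source": e.source, "target": e.target, "sign": e.sign,
                "weight": e.weights[0],
                "p_value": max(e.pvalues),
                "weights_per_run": ";".join(f"{w:.6g}" for w in e.weights),
                "p_values_per_run": ";".join(f"{p:.6g}" for p in e.pvalues),
            })
        columns = ["source", "target", "sign", "weight", "p_value",
                   "weights_per_run", "p_values_per_run"]
    else:
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            rows.append({"source": e.source, "target": e.target, "sign": e.sign,
                         "weight": e.weight, "p_value": e.pvalue})
        columns = ["source", "target", "sign", "weight", "p_value"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_network_json(net: InferredNetwork | ConsensusNetwork, path) -> None:
    summary = net.summary()
    if isinstance(net, ConsensusNetwork):
        summary["perturbation_calls"] = net.perturbation_calls
    else:
        summary["perturbed_genes"] = [
            {"gene": g, "b": b, "p": p} for g, b, p in net.perturbed_genes
        ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
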