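"""Declarative pipeline configuration (YAML or TOML).

A configuration names the chemical groups (each compound with its
expression TSV), the gene sets to analyse (a GMT path plus selected set
names), the inference parameters, an optional reference SIF, and the
output directory::

    outdir: results
    genesets:
      gmt: pathways.gmt
      names: [NRF2, NFKB]
    reference: cpdb_modules.sif   # optional
    params:
      alpha: 0.05
      estimator: lasso_ols
      seed: 42
    groups:
      - name: DILI
        compounds:
          - {compound: diclofenac, path: expr_diclofenac.tsv}
          - {compound: nitrofurantoin, path: expr_nitrofurantoin.tsv}
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml

from .errors import ConfigError
from .inference import InferenceParams

_PARAM_FIELDS = ("alpha", "derivative_scheme", "estimator", "dose_encoding",
                 "permutation_count", "seed")


@dataclass
class GroupConfig:
    name: str
    compounds: list[dict]  # {compound: str, path: str}


@dataclass
class PipelineConfig:
    groups: list[GroupConfig]
    gmt_path: str
    geneset_names: list[str]
    params: InferenceParams
    outdir: str
    reference_path: str | None = None
    require_sign_consistency: bool = True
    base_dir: str = "."

    def resolve(self, path: str) -> str:
        return path if os.path.isabs(path) else os.path.join(self.base_dir, path)


def _load_mapping(path: str) -> dict:
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                return tomllib.load(fh)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return data


def load_config(path: str, seed_override: int | None = None,
                alpha_override: float | None = None,
                estimator_override: str | None = None) -> PipelineConfig:
    """Parse and validate a pipeline configuration file."""
    data = _load_mapping(path)
    base = os.path.dirname(os.path.abspath(path))
    for key in ("groups", "genesets", "outdir"):
        if key not in data:
            raise ConfigError(f"{path}: missing required key {key!r}")

    raw_params = dict(data.get("params") or {})
    unknown = set(raw_params) - set(_PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    if seed_override is not None:
        raw_params["seed"] = seed_override
    if alpha_override is not None:
        raw_params["alpha"] = alpha_override
    if estimator_override is not None:
        raw_params["estimator"] = estimator_override
    try:
        params = InferenceParams(**raw_params)
    except Exception as exc:
        raise ConfigError(f"{path}: invalid params: {exc}") from exc

    genesets = data["genesets"]
    if not isinstance(genesets, dict) or "gmt" not in genesets or "names" not in genesets:
        raise ConfigError(f"{path}: genesets must provide 'gmt' and 'names'")

    groups = []
    for g in data["groups"]:
        if "name" not in g or "compounds" not in g:
            raise ConfigError(f"{path}: each group needs 'name' and 'compounds'")
        comps = g["compounds"]
        if not isinstance(comps, list) or len(comps) < 2:
            raise ConfigError(f"{path}: group {g['name']!r} needs >= 2 compounds")
        for c in comps:
            if "compound" not in c or "path" not in c:
                raise ConfigError(
                    f"{path}: group {g['name']!r}: compounds need 'compound' and 'path'"
                )
        groups.append(GroupConfig(name=g["name"], compounds=comps))

    cfg = PipelineConfig(
        groups=groups,
        gmt_path=genesets["gmt"],
        geneset_names=list(genesets["names"]),
        params=params,
        outdir=data["outdir"],
        reference_path=data.get("reference"),
        require_sign_consistency=bool(data.get("require_sign_consistency", True)),
        base_dir=base,
    )
    for g in cfg.groups:
        for c in g.compounds:
            p = cfg.resolve(c["path"])
            if not os.path.exists(p):
                raise ConfigError(f"{path}: expression file not found: {p}")
    if not os.path.exists(cfg.resolve(cfg.gmt_path)):
        raise ConfigError(f"{path}: GMT file not found: {cfg.resolve(cfg.gmt_path)}")
    if cfg.reference_path and not os.path.exists(cfg.resolve(cfg.reference_path)):
        raise ConfigError(f"{path}: reference SIF not found: {cfg.resolve(cfg.reference_path)}")
    return cfg
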