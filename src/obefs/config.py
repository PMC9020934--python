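"""YAML run configuration for the CLI.

A run config has up to five sections::

    seed: 1
    dataset:            # either a CSV path or a synthetic spec
      path: table.csv          # with optional id_column/label_column/family_map
      # synthetic: {n_subjects_per_class: 20, n_informative: 10, ...}
    kpca: {enabled: false, kernel: rbf, components: null}
    selection:
      mode: obefs              # none | obefs
      pop_size: 25
      max_iters: 100
      size_penalty: 0.2
      r_threshold: 0.9
      lfcsa: {prb_a: 0.25}
      afa: {gamma: 1.0}
      fmboa: {peri: 1.2}
    classifier: {backend: default}
    output_dir: out/

Unknown keys raise a configuration error naming the offending key.  All
component seeds derive from the global ``seed`` (see :mod:`obefs._rng`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from . import metaheuristics as mh
from .datamodel import FeatureTable, SyntheticSpec, generate_synthetic, read_feature_table
from .ensemble import ObefsConfig
from .evaluation import PipelineConfig


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in section {name!r}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


@dataclasses.dataclass
class RunConfig:
    seed: int
    dataset: dict
    pipeline: PipelineConfig
    output_dir: Path
    raw: dict

    def load_table(self) -> FeatureTable:
        if "path" in self.dataset:
            return read_feature_table(
                self.dataset["path"],
                id_column=self.dataset.get("id_column", "id"),
                label_column=self.dataset.get("label_column", "class"),
                family_map=self.dataset.get("family_map"),
            )
        spec_kwargs = dict(self.dataset.get("synthetic", {}))
        spec_kwargs.setdefault("seed", self.seed)
        spec = _build(SyntheticSpec, spec_kwargs, "dataset.synthetic")
        table, _ = generate_synthetic(spec)
        return table

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _obefs_config(section: dict, seed: int) -> ObefsConfig:
    section = dict(section)
    section.pop("mode", None)
    sub = {}
    for name, cls in (("lfcsa", mh.LfcsaParams), ("afa", mh.AfaParams), ("fmboa", mh.FmboaParams)):
        if name in section:
            sub[name] = _build(cls, section.pop(name), f"selection.{name}")
    section.setdefault("seed", seed)
    cfg = _build(ObefsConfig, section, "selection")
    return dataclasses.replace(cfg, **sub)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path.name}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping in {path.name}")

    known_top = {"seed", "dataset", "kpca", "selection", "classifier", "output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} at config top level")
    seed = int(raw.get("seed", 0))
    dataset = raw.get("dataset", {"synthetic": {}})
    if "path" not in dataset and "synthetic" not in dataset:
        raise ConfigError("section 'dataset' needs either 'path' or 'synthetic'")

    kpca = dict(raw.get("kpca", {}))
    sel = dict(raw.get("selection", {}))
    clf = dict(raw.get("classifier", {}))
    mode = sel.get("mode", "obefs")
    if mode not in ("none", "obefs"):
        raise ConfigError(f"unknown key {mode!r} for selection.mode")

    pipeline = PipelineConfig(
        seed=seed,
        kpca_enabled=bool(kpca.get("enabled", False)),
        kpca_kernel=kpca.get("kernel", "rbf"),
        kpca_components=kpca.get("components"),
        selection=mode,
        select_once=bool(sel.get("select_once", False)),
        obefs=_obefs_config(
            {k: v for k, v in sel.items() if k not in ("select_once",)}, seed
        ),
        classifier_backend=clf.get("backend", "default"),
    )
    return RunConfig(
        seed=seed,
        dataset=dataset,
        pipeline=pipeline,
        output_dir=Path(raw.get("output_dir", ".")),
        raw=raw,
    )
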