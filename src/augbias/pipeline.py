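"""End-to-end study orchestration.

Three studies, each a pure function of a :class:`StudyConfig`:

``sweep``
    Train one encoder per (composition-in-sweep x seed), linear-probe it,
    assemble the per-class :class:`~augbias.biasstats.AccuracySurface`, and run
    the full bias-statistics chain (pairwise correlations, opposite-behavior
    flags, bias ratio, behavior labels, property association).

``style``
    Train one encoder per (transformation set x seed) on two-factor glyph
    images and report, per set: k-means assignments, silhouette, AMI against
    glyph labels and against style labels, probe accuracy, and the mean
    perceptual dissimilarity between that set's view pairs.

``phenotype``
    On centered-cell microscopy images, train the random-crop composition, the
    strong-rotation composition, and the dual-composition weighted objective;
    report condition AMI (k = 2) and phenotype clustering (k = n_phenotypes+1)
    per run, plus an optional progressive-integration ablation.

Every training is cached under the output directory keyed by a config hash,
so an interrupted study resumes where it stopped; a hash collision with
different config contents is an error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import biasstats
from .data import ImageDataset
from .evalrep import (
    RandomConvPerceptualBackend,
    RepresentationSet,
    adjusted_mutual_information,
    cluster_kmeans,
    linear_probe,
    perceptual_dissimilarity,
    silhouette,
)
from .nn import EncoderSpec
from .rng import child_rng, child_seed
from .ssrl import DualObjectiveConfig, SSRLConfig, embed_dataset, train_dual_objective, train_encoder
from .synthgen import CellImageConfig, gen_cell_images, gen_glyph_images, gen_property_classes
from .transforms import (
    SweepGrid,
    TransformComposition,
    TransformSpec,
    cell_center_set,
    cell_crop_set,
    cell_rotation_set,
    glyph_set1,
    glyph_set2,
    make_view_pair,
    sweep_compositions,
)

__all__ = [
    "StudyConfig",
    "make_dataset",
    "run_sweep_study",
    "run_style_study",
    "run_phenotype_study",
    "write_report",
    "default_sweep_config",
    "default_style_config",
    "default_phenotype_config",
]


@dataclass
class StudyConfig:
    study: str
    dataset: dict
    encoder: dict = field(default_factory=dict)
    ssrl: dict = field(default_factory=dict)
    compositions: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    out_dir: str | None = None

    def __post_init__(self):
        if self.study not in ("sweep", "style", "phenotype"):
            raise ValueError("study must be sweep, style or phenotype")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls(**yaml.safe_load(text))


# ---------------------------------------------------------------------------
# dataset dispatch
# ---------------------------------------------------------------------------

def make_dataset(spec: dict) -> ImageDataset:
    """Build a dataset from a generator descriptor or an image directory.

    ``{"generator": "cells" | "glyphs" | "properties", ...kwargs}`` or
    ``{"directory": path}``.
    """
    spec = dict(spec)
    if "directory" in spec:
        return ImageDataset.load_png_dir(spec["directory"])
    gen = spec.pop("generator")
    if gen == "cells":
        return gen_cell_images(CellImageConfig(**spec))
    if gen == "glyphs":
        return gen_glyph_images(**spec)
    if gen == "properties":
        return gen_property_classes(**spec)
    raise ValueError(f"unknown dataset source {gen!r}")


def _encoder_spec(cfg: StudyConfig) -> EncoderSpec:
    return EncoderSpec(**cfg.encoder) if cfg.encoder else EncoderSpec()


def _ssrl_config(cfg: StudyConfig, seed: int) -> SSRLConfig:
    kwargs = dict(cfg.ssrl)
    kwargs["seed"] = seed
    return SSRLConfig(**kwargs)


# ---------------------------------------------------------------------------
# caching
# ---------------------------------------------------------------------------

class _Cache:
    """Per-study JSON cache of expensive per-training results."""

    def __init__(self, cfg: StudyConfig):
        self.dir = None
        if cfg.out_dir:
            self.dir = os.path.join(cfg.out_dir, "cache", cfg.config_hash())
            os.makedirs(self.dir, exist_ok=True)
            marker = os.path.join(self.dir, "config.yaml")
            if os.path.exists(marker):
                if open(marker).read() != cfg.to_yaml():
                    raise RuntimeError(
                        "config-hash collision: cached config differs from current")
            else:
                with open(marker, "w") as fh:
                    fh.write(cfg.to_yaml())

    def get(self, key: str):
        if not self.dir:
            return None
        path = os.path.join(self.dir, key + ".json")
        if os.path.exists(path):
            with open(path) as fh:
                return json.load(fh)
        return None

    def put(self, key: str, value: dict):
        if self.dir:
            with open(os.path.join(self.dir, key + ".json"), "w") as fh:
                json.dump(value, fh)


# ---------------------------------------------------------------------------
# sweep study
# ---------------------------------------------------------------------------

def run_sweep_study(cfg: StudyConfig) -> dict:
    """Parameter sweep -> AccuracySurface -> full bias-statistics chain."""
    if cfg.study != "sweep":
        raise ValueError("config is not a sweep study")
    dataset = make_dataset(cfg.dataset)
    enc_spec = _encoder_spec(cfg)
    base = TransformComposition.from_dict(cfg.compositions["base"])
    grid = SweepGrid.from_dict(cfg.compositions["grid"])
    comps = sweep_compositions(base, grid)
    cache = _Cache(cfg)

    classes = np.unique(dataset.labels)
    acc = np.zeros((len(classes), len(comps), len(cfg.seeds)))
    for j, comp in enumerate(comps):
        for s, seed in enumerate(cfg.seeds):
            key = f"sweep_v{j}_s{seed}"
            hit = cache.get(key)
            if hit is None:
                ssrl_cfg = _ssrl_config(cfg, seed)
                enc, _ = train_encoder(dataset, enc_spec, ssrl_cfg, comp)
                reps = embed_dataset(enc, dataset)
                _, per_class = linear_probe(
                    reps, cfg.evaluation.get("probe_fraction", 0.8), seed=seed)
                hit = {str(c): per_class[int(c)] for c in classes}
                cache.put(key, hit)
            acc[:, j, s] = [hit[str(c)] for c in classes]

    values = [v if np.isscalar(v) else float(np.mean(v)) for v in grid.values]
    surface = biasstats.AccuracySurface(
        accuracies=acc,
        param_name=f"{base.specs[grid.spec_index].kind}.{grid.parameter}",
        param_values=values,
        class_names=[f"class_{c}" for c in classes],
        superclass_map=cfg.evaluation.get("superclass_map"),
    )
    artifacts: dict = {"surface": surface}
    if len(values) >= 3:
        artifacts["bias_report"] = biasstats.make_bias_report(surface)
        artifacts["behaviors"] = biasstats.classify_all_behaviors(surface)
    return artifacts


# ---------------------------------------------------------------------------
# style study
# ---------------------------------------------------------------------------

def run_style_study(cfg: StudyConfig) -> dict:
    """Two transformation sets on two-factor glyphs; per-set cluster reports."""
    if cfg.study != "style":
        raise ValueError("config is not a style study")
    dataset = make_dataset(cfg.dataset)
    if dataset.aux_labels is None:
        raise ValueError("style study requires aux_labels (style factor)")
    enc_spec = _encoder_spec(cfg)
    sets = {
        name: TransformComposition.from_dict(d)
        for name, d in cfg.compositions.items()
    }
    k = cfg.evaluation.get("k", len(np.unique(dataset.labels)))
    n_pairs = cfg.evaluation.get("perceptual_pairs", 200)
    backend = RandomConvPerceptualBackend(seed=0)
    cache = _Cache(cfg)

    rows = []
    for name, comp in sets.items():
        rng = child_rng(0, "perceptual", name)
        pairs = [make_view_pair(dataset.images[i], comp, comp, rng)
                 for i in range(min(n_pairs, len(dataset)))]
        lpips_like = perceptual_dissimilarity(pairs, backend)
        for seed in cfg.seeds:
            key = f"style_{name}_s{seed}"
            hit = cache.get(key)
            if hit is None:
                enc, _ = train_encoder(dataset, enc_spec, _ssrl_config(cfg, seed), comp)
                reps = embed_dataset(enc, dataset)
                asg = cluster_kmeans(reps, k, seed=0)
                top1, _ = linear_probe(reps, seed=0, max_iter=1000)
                hit = {
                    "ami_glyph": adjusted_mutual_information(asg, dataset.labels),
                    "ami_style": adjusted_mutual_information(asg, dataset.aux_labels),
                    "silhouette": silhouette(reps, asg),
                    "top1_glyph": top1,
                }
                cache.put(key, hit)
            rows.append({"set": name, "seed": seed, "perceptual": lpips_like, **hit})
    table = pd.DataFrame(rows)
    summary = table.groupby("set").median(numeric_only=True).drop(columns="seed")
    return {"table": table, "summary": summary}


# ---------------------------------------------------------------------------
# phenotype study
# ---------------------------------------------------------------------------

def _composition_steps(final: TransformComposition) -> list[TransformComposition]:
    """Prefixes of a composition, for the progressive-integration ablation."""
    steps = []
    for i in range(1, len(final.specs) + 1):
        steps.append(TransformComposition(
            specs=list(final.specs[:i]),
            name=f"{final.name}__step{i}_{final.specs[i - 1].kind}",
        ))
    return steps


def run_phenotype_study(cfg: StudyConfig, ablation: bool = False) -> dict:
    """Crop set vs rotation set vs dual objective on centered-cell images."""
    if cfg.study != "phenotype":
        raise ValueError("config is not a phenotype study")
    dataset = make_dataset(cfg.dataset)
    enc_spec = _encoder_spec(cfg)
    comp_crop = TransformComposition.from_dict(cfg.compositions["crop"])
    comp_rot = TransformComposition.from_dict(cfg.compositions["rotation"])
    comp_center = TransformComposition.from_dict(cfg.compositions["center"])
    weight_a = cfg.evaluation.get("dual_weight_a", 0.7)
    k_pheno = cfg.evaluation.get(
        "k_phenotype", int(dataset.aux_labels.max()) + 1 if dataset.aux_labels is not None else 4)
    cache = _Cache(cfg)

    def evaluate(reps: RepresentationSet) -> dict:
        asg2 = cluster_kmeans(reps, 2, seed=0)
        out = {"ami_condition": adjusted_mutual_information(asg2, dataset.labels)}
        if dataset.aux_labels is not None and k_pheno >= 2:
            asg_p = cluster_kmeans(reps, k_pheno, seed=0)
            out["ami_phenotype"] = adjusted_mutual_information(asg_p, dataset.aux_labels)
        return out

    rows = []
    for seed in cfg.seeds:
        ssrl_cfg = _ssrl_config(cfg, seed)
        for name, comp in [("crop", comp_crop), ("rotation", comp_rot),
                           ("center", comp_center)]:
            key = f"pheno_{name}_s{seed}"
            hit = cache.get(key)
            if hit is None:
                enc, _ = train_encoder(dataset, enc_spec, ssrl_cfg, comp)
                hit = evaluate(embed_dataset(enc, dataset))
                cache.put(key, hit)
            rows.append({"run": name, "seed": seed, **hit})
        key = f"pheno_dual_s{seed}"
        hit = cache.get(key)
        if hit is None:
            dual = DualObjectiveConfig(base=ssrl_cfg, comp_a=comp_center,
                                       comp_b=comp_crop, weight_a=weight_a,
                                       weight_b=1.0 - weight_a)
            enc, _ = train_dual_objective(dataset, enc_spec, dual)
            hit = evaluate(embed_dataset(enc, dataset))
            cache.put(key, hit)
        rows.append({"run": "dual", "seed": seed, **hit})
    table = pd.DataFrame(rows)
    artifacts = {"table": table,
                 "summary": table.groupby("run").median(numeric_only=True).drop(columns="seed")}

    if ablation:
        ab_rows = []
        for step in _composition_steps(comp_center):
            for seed in cfg.seeds:
                key = f"ablation_{step.name}_s{seed}"
                hit = cache.get(key)
                if hit is None:
                    dual = DualObjectiveConfig(base=_ssrl_config(cfg, seed),
                                               comp_a=step, comp_b=comp_crop,
                                               weight_a=weight_a,
                                               weight_b=1.0 - weight_a)
                    enc, _ = train_dual_objective(dataset, enc_spec, dual)
                    hit = evaluate(embed_dataset(enc, dataset))
                    cache.put(key, hit)
                ab_rows.append({"step": step.name, "seed": seed, **hit})
        artifacts["ablation"] = pd.DataFrame(ab_rows)
    return artifacts


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(artifacts: dict, cfg: StudyConfig, out_dir: str,
                 overwrite: bool = False) -> str:
    """Persist all study artifacts plus a JSON manifest; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.json")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    files: dict[str, str] = {}
    for name, art in artifacts.items():
        if isinstance(art, biasstats.AccuracySurface):
            path = os.path.join(out_dir, f"{name}.csv")
            art.to_csv(path)
            files[name] = path
        elif isinstance(art, biasstats.BiasReport):
            path = os.path.join(out_dir, f"{name}.json")
            with open(path, "w") as fh:
                fh.write(art.to_json())
            files[name] = path
        elif isinstance(art, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.csv")
            art.to_csv(path, index=isinstance(art.index, pd.MultiIndex) or art.index.name is not None)
            files[name] = path
        elif isinstance(art, list):  # behavior labels etc.
            path = os.path.join(out_dir, f"{name}.json")
            with open(path, "w") as fh:
                json.dump([dataclasses.asdict(x) for x in art], fh, indent=1)
            files[name] = path
        else:
            path = os.path.join(out_dir, f"{name}.json")
            with open(path, "w") as fh:
                json.dump(art, fh, indent=1, default=str)
            files[name] = path
    manifest = {
        "study": cfg.study,
        "config": yaml.safe_load(cfg.to_yaml()),
        "config_hash": cfg.config_hash(),
        "seeds": cfg.seeds,
        "files": files,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def validate_manifest(path: str) -> dict:
    """Check a report bundle: every listed table must exist."""
    with open(path) as fh:
        manifest = json.load(fh)
    for key in ("study", "config", "config_hash", "seeds", "files"):
        if key not in manifest:
            raise ValueError(f"manifest missing field {key!r}")
    for name, fpath in manifest["files"].items():
        if not os.path.exists(fpath):
            raise FileNotFoundError(f"bundle table {name!r} missing at {fpath}")
    return manifest


__all__.append("validate_manifest")


# ---------------------------------------------------------------------------
# frozen desk-scale study conditions
# ---------------------------------------------------------------------------

def default_sweep_config(out_dir: str | None = None, n_values: int = 3,
                         seeds: list[int] | None = None) -> StudyConfig:
    """A small trained sweep over center-crop fraction on cell images."""
    base = TransformComposition([
        TransformSpec("color_jitter", probability=0.8, amplitude=0.15),
        TransformSpec("hflip", probability=0.5),
        TransformSpec("center_crop_fraction", probability=1.0, amplitude=0.8),
    ], name="crop_sweep_base")
    grid = SweepGrid(spec_index=2, parameter="amplitude",
                     values=[float(v) for v in np.round(np.linspace(0.4, 0.9, n_values), 3)],
                     n_seeds=len(seeds or [1, 2]))
    return StudyConfig(
        study="sweep",
        dataset={"generator": "cells", "image_size": 32, "n_untreated": 150,
                 "n_treated": 150, "seed": 11},
        encoder={"embedding_dim": 16, "projector_dims": [64, 32]},
        ssrl={"method": "simclr", "epochs": 10, "batch_size": 100, "lr": 0.3},
        compositions={"base": base.to_dict(), "grid": grid.to_dict()},
        evaluation={"probe_fraction": 0.8},
        seeds=seeds or [1, 2],
        out_dir=out_dir,
    )


def default_style_config(out_dir: str | None = None,
                         seeds: list[int] | None = None) -> StudyConfig:
    """The glyph two-set study at its desk-scale conditions."""
    return StudyConfig(
        study="style",
        dataset={"generator": "glyphs", "n_per_class": 70, "n_classes": 6,
                 "style_levels": 2, "seed": 11, "template_set": "bars"},
        encoder={"embedding_dim": 6, "projector_dims": [64, 32]},
        ssrl={"method": "simclr", "epochs": 30, "batch_size": 100, "lr": 0.3},
        compositions={"set1": glyph_set1().to_dict(), "set2": glyph_set2().to_dict()},
        evaluation={"k": 6, "perceptual_pairs": 200},
        seeds=seeds or [1, 2, 3, 4, 5],
        out_dir=out_dir,
    )


def default_phenotype_config(out_dir: str | None = None,
                             seeds: list[int] | None = None) -> StudyConfig:
    """The microscopy crop/rotation/dual study at its desk-scale conditions."""
    return StudyConfig(
        study="phenotype",
        dataset={"generator": "cells", "image_size": 32, "n_untreated": 200,
                 "n_treated": 200, "seed": 11},
        encoder={"embedding_dim": 16, "projector_dims": [64, 32]},
        ssrl={"method": "simclr", "epochs": 25, "batch_size": 100, "lr": 0.3},
        compositions={"crop": cell_crop_set().to_dict(),
                      "rotation": cell_rotation_set().to_dict(),
                      "center": cell_center_set().to_dict()},
        evaluation={"dual_weight_a": 0.85, "k_phenotype": 4},
        seeds=seeds or [1, 2, 3, 4, 5],
        out_dir=out_dir,
    )
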