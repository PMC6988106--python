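"""End-to-end experiment orchestration on phantom corpora.

A run generates train/test phantoms, extracts the endocardial surface from
the *automatic* (perturbed) LA segmentation, projects ground-truth scar onto
it, trains T-NET and (for lambda > 0) N-NET on balanced node/edge samples,
classifies scars by exact graph-cuts on every test case, and scores the
result on surface nodes.  Classical baselines run from the *manual* LA
segmentation and are scored against the ground truth projected onto the
manual surface, mirroring how semi-automatic methods are initialized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .baselines import mgmm_fit, mgmm_gc, threshold_nsd, threshold_otsu, wall_from_la
from .graphcut import classify_scars
from .metrics import surface_metrics, voxel_dice
from .msp import MSPConfig, ShiftConfig
from .nets import (NetConfig, TrainConfig, make_edge_training_set,
                   make_training_set, train_n_net, train_t_net)
from .phantom import Confounder, PhantomConfig, PhantomTruth, make_phantom
from .surface import extract_surface, project_labels

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "PipelineResult", "run_pipeline",
           "run_parameter_study", "config_to_dict", "config_from_dict"]

BASELINE_METHODS = ("2sd", "otsu", "mgmm", "mgmm-gc")


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_train: int = 2
    n_test: int = 2
    msp: MSPConfig = field(default_factory=MSPConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    lam: float = 0.4
    depth_out_mm: float = 4.0
    depth_in_mm: float = 1.0
    wall_dilation_mm: float = 3.0
    densify: bool = True
    baselines: tuple[str, ...] = ()
    mgmm_k_scar: int = 2
    mgmm_k_normal: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.baselines) - set(BASELINE_METHODS)
        if unknown:
            raise ValueError(f"unknown baselines {sorted(unknown)}")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("need at least one training and one test case")


@dataclass
class PipelineResult:
    cases: pd.DataFrame     # one row per (case, method)
    summary: pd.DataFrame   # mean/SD per method
    t_losses: list[float]
    n_losses: list[float]
    config_hash: str

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.cases.to_csv(os.path.join(out_dir, "cases.csv"), index=False)
        self.summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)


# ---------------------------------------------------------------------------
# config (de)serialisation

def config_to_dict(cfg: ExperimentConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    ph = dict(d.pop("phantom", {}))
    if "confounders" in ph:
        confs = []
        for c in ph["confounders"]:
            if isinstance(c, dict):
                c = dict(c)
                if isinstance(c.get("direction"), list):
                    c["direction"] = tuple(c["direction"])
                c = Confounder(**c)
            confs.append(c)
        ph["confounders"] = confs
    for key in ("grid_shape", "spacing_mm", "intensity_means"):
        if key in ph and isinstance(ph[key], list):
            ph[key] = tuple(ph[key])
    msp = dict(d.pop("msp", {}))
    if "shift" in msp and isinstance(msp["shift"], dict):
        msp["shift"] = ShiftConfig(**msp["shift"])
    if "dims" in msp and isinstance(msp["dims"], list):
        msp["dims"] = tuple(msp["dims"])
    net = dict(d.pop("net", {}))
    if "channels" in net and isinstance(net["channels"], list):
        net["channels"] = tuple(net["channels"])
    if "baselines" in d and isinstance(d["baselines"], list):
        d["baselines"] = tuple(d["baselines"])
    return ExperimentConfig(phantom=PhantomConfig(**ph), msp=MSPConfig(**msp),
                            net=NetConfig(**net),
                            train=TrainConfig(**dict(d.pop("train", {}))), **d)


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline stages

def _case_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]  # keep below 2**31


def make_corpus(cfg: ExperimentConfig) -> tuple[list[PhantomTruth], list[PhantomTruth]]:
    """Generate disjoint train/test phantom sets from the experiment seed."""
    seeds = _case_seeds(cfg.seed, cfg.n_train + cfg.n_test)
    phantoms = [make_phantom(replace(cfg.phantom, seed=s)) for s in seeds]
    return phantoms[:cfg.n_train], phantoms[cfg.n_train:]


def _auto_surface(truth: PhantomTruth, cfg: ExperimentConfig):
    img = truth.image
    mesh = extract_surface(truth.la_seg_auto, img.spacing, img.origin,
                           densify=cfg.densify)
    gt = project_labels(truth.scar_seg, img.spacing, img.origin, mesh,
                        cfg.depth_out_mm, cfg.depth_in_mm)
    return mesh, gt


def _manual_surface(truth: PhantomTruth, cfg: ExperimentConfig):
    img = truth.image
    mesh = extract_surface(truth.la_seg, img.spacing, img.origin,
                           densify=cfg.densify)
    gt = project_labels(truth.scar_seg, img.spacing, img.origin, mesh,
                        cfg.depth_out_mm, cfg.depth_in_mm)
    return mesh, gt


def train_networks(train_set: list[PhantomTruth], cfg: ExperimentConfig):
    """Train T-NET (and N-NET when lambda > 0) on the training phantoms."""
    rng = np.random.default_rng(_case_seeds(cfg.seed + 1, 1)[0])
    t_cases, n_cases = [], []
    for k, truth in enumerate(train_set):
        mesh, gt = _auto_surface(truth, cfg)
        if gt.sum() == 0:
            raise ValueError(f"training case {k} has no scar labels on the surface")
        sample = make_training_set(mesh, gt, rng)
        nodes = sample.nodes
        t_cases.append((truth.image, mesh, nodes, gt[nodes]))
        if cfg.lam > 0:
            edges, d, m = make_edge_training_set(mesh, gt, nodes, rng)
            n_cases.append((truth.image, mesh, edges, d, m))
    t0 = time.perf_counter()
    t_net, t_losses = train_t_net(t_cases, cfg.msp, cfg.train, rng, cfg.net)
    log.info("T-NET trained in %.1f s (final loss %.4f)",
             time.perf_counter() - t0, t_losses[-1])
    n_net, n_losses = None, []
    if cfg.lam > 0:
        t0 = time.perf_counter()
        n_net, n_losses = train_n_net(n_cases, cfg.msp, cfg.train, rng, cfg.net)
        log.info("N-NET trained in %.1f s (final loss %.4f)",
                 time.perf_counter() - t0, n_losses[-1])
    return t_net, n_net, t_losses, n_losses


def _baseline_mask(method: str, truth: PhantomTruth, wall, cfg: ExperimentConfig):
    img = truth.image.data
    if method == "2sd":
        return threshold_nsd(img, wall, n_sd=2.0)
    if method == "otsu":
        return threshold_otsu(img, wall)
    model = mgmm_fit(img[wall], k_scar=cfg.mgmm_k_scar, k_normal=cfg.mgmm_k_normal,
                     seed=cfg.seed)
    if method == "mgmm":
        scar = np.zeros_like(wall)
        scar[wall] = model.scar_posterior(img[wall]) > 0.5
        return scar
    return mgmm_gc(img, wall, model, lam=0.5)


def evaluate_case(truth: PhantomTruth, t_net, n_net, cfg: ExperimentConfig,
                  case_id: str) -> list[dict]:
    """Score the learned pipeline (and any baselines) on one test phantom."""
    rows = []
    img = truth.image
    mesh_auto, gt_auto = _auto_surface(truth, cfg)
    pred = classify_scars(img, mesh_auto, t_net, n_net, cfg.lam, cfg.msp)
    rep = surface_metrics(pred, gt_auto)
    dice_la = voxel_dice(truth.la_seg, truth.la_seg_auto)
    rows.append({"case": case_id, "method": "learngc", "dice_la": dice_la,
                 **rep.as_dict()})
    if cfg.baselines:
        mesh_m, gt_m = _manual_surface(truth, cfg)
        wall = wall_from_la(truth.la_seg, cfg.wall_dilation_mm, img.spacing)
        for method in cfg.baselines:
            mask = _baseline_mask(method, truth, wall, cfg)
            labels = project_labels(mask, img.spacing, img.origin, mesh_m,
                                    cfg.depth_out_mm, cfg.depth_in_mm)
            rep = surface_metrics(labels, gt_m)
            rows.append({"case": case_id, "method": method, "dice_la": 1.0,
                         **rep.as_dict()})
    return rows


def run_pipeline(cfg: ExperimentConfig,
                 corpus: tuple[list[PhantomTruth], list[PhantomTruth]] | None = None
                 ) -> PipelineResult:
    """Full experiment: phantoms -> surfaces -> training -> cut -> metrics."""
    train_set, test_set = corpus if corpus is not None else make_corpus(cfg)
    t_net, n_net, t_losses, n_losses = train_networks(train_set, cfg)
    rows = []
    for k, truth in enumerate(test_set):
        rows.extend(evaluate_case(truth, t_net, n_net, cfg, case_id=f"test{k:02d}"))
    cases = pd.DataFrame(rows)
    summary = (cases.groupby("method")
               .agg(dice_scar_mean=("dice_scar", "mean"),
                    dice_scar_sd=("dice_scar", "std"),
                    gdice_mean=("gdice", "mean"),
                    accuracy_mean=("accuracy", "mean"),
                    n_cases=("case", "count"))
               .reset_index())
    result = PipelineResult(cases, summary, t_losses, n_losses, _config_hash(cfg))
    if cfg.out_dir:
        result.save(cfg.out_dir)
        with open(os.path.join(cfg.out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump({"config": config_to_dict(cfg),
                            "hash": result.config_hash, "seed": cfg.seed}, fh)
    return result


STUDY_AXES = ("patch_size", "lambda", "R", "N_s")


def _apply_axis(cfg: ExperimentConfig, axis: str, value) -> ExperimentConfig:
    cfg = config_from_dict(config_to_dict(cfg))  # deep copy
    if axis == "patch_size":
        cfg.msp.dims = tuple(value)
    elif axis == "lambda":
        cfg.lam = float(value)
    elif axis == "R":
        cfg.msp.shift.R = float(value)
    elif axis == "N_s":
        cfg.msp.n_scales = int(value)
    else:
        raise ValueError(f"unknown study axis {axis!r}; one of {STUDY_AXES}")
    return cfg


def run_parameter_study(cfg: ExperimentConfig, axis: str, values,
                        n_seeds: int = 1) -> pd.DataFrame:
    """Repeat the pipeline varying one axis; all runs share the phantom corpus.

    Returns one row per value with mean and SD of surface Dice(scar) across
    test cases and seeds.
    """
    values = list(values)
    if len(values) < 2:
        raise ValueError("a parameter study needs at least two values")
    rows = []
    for value in values:
        dices = []
        for s in range(n_seeds):
            run_cfg = _apply_axis(cfg, axis, value)
            run_cfg.seed = cfg.seed + s
            run_cfg.out_dir = None
            res = run_pipeline(run_cfg)
            sub = res.cases[res.cases.method == "learngc"]
            dices.extend(sub.dice_scar.tolist())
        rows.append({"axis": axis, "value": str(value),
                     "dice_scar_mean": float(np.mean(dices)),
                     "dice_scar_sd": float(np.std(dices, ddof=1)) if len(dices) > 1 else 0.0,
                     "n_runs": len(dices)})
    return pd.DataFrame(rows)
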