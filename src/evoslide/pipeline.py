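"""End-to-end orchestration of the slide-classification pipeline.

The demo pipeline runs entirely on synthetic slides: generate slides ->
tissue mask -> patch gating (tumor oracle = tumor-mask fraction) -> built-in
featurization -> evolutionary projection to 2-D -> per-slide spatial graphs
-> classifier head training -> slide-level evaluation.  Everything is
deterministic for a fixed global seed; each stage derives its own seed from
the global one via ``numpy.random.SeedSequence([global_seed, stage_index])``
so stages are independently reproducible.

Two surfaces are provided: an in-memory :func:`run_demo` returning all
intermediate products and results, and file-based stage functions (used by
the command-line interface) that exchange artifacts through an output
directory, each writing a manifest of its inputs, outputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .evolve import EAConfig, evolve, save_matrix, transform
from .features import ExtractorSpec, extract_features
from .graphs import (
    SlideGraph,
    assemble_slide,
    build_graph,
    infer_nmax,
    normalize_adjacency,
    save_graph,
)
from .heads import make_head
from .preprocess import (
    MaskFractionScorer,
    PatchRecord,
    export_annotated_thumbnail,
    score_patches,
    tile_positions,
    tissue_mask,
)
from .projections import pca_projection
from .silhouette import silhouette
from .synthetic import gen_dataset
from .training import TrainConfig, dice, graphs_to_arrays, metrics, train

__all__ = ["PipelineConfig", "run_demo", "stratified_split"]

logger = logging.getLogger(__name__)

_STAGE_INDEX = {
    "synth": 0, "split": 1, "preprocess": 2, "extract": 3,
    "optimize": 4, "graphs": 5, "train": 6, "evaluate": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed (documented derivation, below 2**31)."""
    ss = np.random.SeedSequence([global_seed, _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Resolved configuration of the demo pipeline.

    Defaults define the reference study conditions of the synthetic harness:
    24 slides split 16/4/4, 8x8 patch grids of 32 px, built-in 96-D
    features, evolutionary projection to 2-D with P=5, mu=0.8, rho=0.4,
    sigma=0.1 over 200 generations, 4-neighborhood graphs, and the 1-D CNN
    head trained with the balanced-batch protocol.
    """

    seed: int = 0
    n_slides: int = 24
    class_balance: float = 0.5
    n_val: int = 4
    n_test: int = 4
    grid_rows: int = 8
    grid_cols: int = 8
    patch_px: int = 32
    resize_to: int = 64
    ea_generations: int = 200
    ea_population: int = 5
    ea_mu: float = 0.8
    ea_rho: float = 0.4
    ea_sigma: float = 0.1
    d_out: int = 2
    radius_factor: float = 1.05
    head: str = "onedcnn"
    learning_rate: float = 0.001
    epochs: int = 400
    batch_size: int = 8
    patience: int = 20

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f for f in cls.__dataclass_fields__}
        for key in data:
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)


def stratified_split(
    labels: np.ndarray, n_val: int, n_test: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class proportional split into train / val / test index arrays."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    classes = np.unique(y)
    n = len(y)
    for c in classes:
        members = rng.permutation(np.flatnonzero(y == c))
        nv = int(round(n_val * len(members) / n))
        nt = int(round(n_test * len(members) / n))
        val_idx.extend(members[:nv])
        test_idx.extend(members[nv:nv + nt])
        train_idx.extend(members[nv + nt:])
    return (np.sort(train_idx).astype(int), np.sort(val_idx).astype(int),
            np.sort(test_idx).astype(int))


def _slide_products(slide, cfg: PipelineConfig):
    """Mask, gated records and per-patch features for one slide."""
    tmask = tissue_mask(slide.thumbnail)
    h, w = slide.thumbnail.shape
    boxes = tile_positions(w, h, cfg.patch_px, cfg.patch_px)
    records = [PatchRecord(slide_id=slide.slide_id, box=b) for b in boxes]
    scorer = MaskFractionScorer(slide.tumor_mask)
    scored = score_patches(records, tmask, scorer)
    retained = [r for r in scored if r.retained]
    patches = [
        slide.thumbnail[r.box[1]:r.box[3], r.box[0]:r.box[2]] for r in retained
    ]
    feats = None
    if patches:
        feats = extract_features(
            patches,
            ExtractorSpec(resize_to=cfg.resize_to),
            patch_ids=[r.box for r in retained],
        )
    return tmask, scored, retained, feats


def run_demo(cfg: PipelineConfig | None = None) -> dict:
    """Run the full demo pipeline in memory; returns results and artifacts."""
    if cfg is None:
        cfg = PipelineConfig()
    slides = gen_dataset(
        cfg.n_slides, cfg.class_balance, seed=stage_seed(cfg.seed, "synth"),
        grid_rows=cfg.grid_rows, grid_cols=cfg.grid_cols, patch_px=cfg.patch_px,
    )
    labels = np.array([s.label for s in slides])
    tr, va, te = stratified_split(
        labels, cfg.n_val, cfg.n_test, stage_seed(cfg.seed, "split")
    )

    per_slide = {}
    dice_scores = []
    for slide in slides:
        tmask, scored, retained, feats = _slide_products(slide, cfg)
        if feats is None:
            raise RuntimeError(f"slide {slide.slide_id}: no retained patches")
        per_slide[slide.slide_id] = (tmask, retained, feats)
        dice_scores.append(dice(tmask.mask, slide.tissue_mask))

    # Evolutionary projection fitted on training-split patches, labels taken
    # from the slide each patch belongs to.
    train_rows, train_labels = [], []
    for i in tr:
        sid = slides[i].slide_id
        feats = per_slide[sid][2]
        train_rows.append(feats.values)
        train_labels.extend([labels[i]] * feats.n_patches)
    X_train = np.vstack(train_rows)
    y_train = np.array(train_labels)
    ea_cfg = EAConfig(
        P=cfg.ea_population, G=cfg.ea_generations, mu=cfg.ea_mu,
        rho=cfg.ea_rho, sigma=cfg.ea_sigma,
        seed=stage_seed(cfg.seed, "optimize"),
    )
    W, trace = evolve(X_train, y_train, ea_cfg, d_out=cfg.d_out)
    ea_sil = silhouette(transform(X_train, W), y_train)
    pca_sil = silhouette(
        transform(X_train, pca_projection(X_train, cfg.d_out)), y_train
    )

    # Per-slide graphs with a shared N_max inferred from the training split.
    n_max = infer_nmax([len(per_slide[slides[i].slide_id][1]) for i in tr])
    radius = cfg.patch_px * cfg.radius_factor
    graphs = []
    for slide in slides:
        _, retained, feats = per_slide[slide.slide_id]
        projected = transform(feats.values, W)
        X, positions, mask = assemble_slide(retained, projected, n_max)
        A_small = build_graph(positions, radius)
        A = np.zeros((n_max, n_max), dtype=np.int8)
        k = positions.shape[0]
        A[:k, :k] = A_small
        A_hat = normalize_adjacency(A, mask)
        g = SlideGraph(
            X=X, A=A, A_hat=A_hat, node_mask=mask, n_real=int(mask.sum()),
            label=slide.label, slide_id=slide.slide_id, positions=positions,
        )
        g.validate()
        graphs.append(g)

    head = make_head(cfg.head, d_in=cfg.d_out, seed=stage_seed(cfg.seed, "train"))
    tc = TrainConfig(
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, patience=cfg.patience,
        seed=stage_seed(cfg.seed, "train"),
    )
    head, history = train(
        head, [graphs[i] for i in tr], [graphs[i] for i in va], tc
    )

    def _eval(idx):
        inputs, y = graphs_to_arrays([graphs[i] for i in idx], head.input_keys)
        probs = head.predict_proba(**inputs)
        return metrics(y, probs), probs, y

    train_metrics, _, _ = _eval(tr)
    test_metrics, test_probs, test_labels = _eval(te)

    return {
        "config": cfg,
        "slides": slides,
        "splits": {"train": tr, "val": va, "test": te},
        "graphs": graphs,
        "per_slide": per_slide,
        "W": W,
        "trace": trace,
        "ea_silhouette": ea_sil,
        "pca_silhouette": pca_sil,
        "head": head,
        "history": history,
        "train_metrics": train_metrics,
        "test_metrics": test_metrics,
        "test_probs": test_probs,
        "test_labels": test_labels,
        "mean_tissue_dice": float(np.mean(dice_scores)),
    }


# ---------------------------------------------------------------------------
# File-based stages (CLI surface).  Each stage writes artifacts plus a
# manifest under <out_root>/<stage>/ and fails with an actionable error when
# an upstream artifact is missing.
# ---------------------------------------------------------------------------

def _write_manifest(stage_dir: Path, stage: str, cfg: PipelineConfig,
                    inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "seed": stage_seed(cfg.seed, stage) if stage in _STAGE_INDEX else cfg.seed,
        "global_seed": cfg.seed,
        "config": asdict(cfg),
        "inputs": inputs,
        "outputs": outputs,
        "version": _pkg_version,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def stage_synth(cfg: PipelineConfig, root: Path) -> Path:
    import tifffile
    import imageio.v3 as iio

    out = root / "synth"
    out.mkdir(parents=True, exist_ok=True)
    slides = gen_dataset(
        cfg.n_slides, cfg.class_balance, seed=stage_seed(cfg.seed, "synth"),
        grid_rows=cfg.grid_rows, grid_cols=cfg.grid_cols, patch_px=cfg.patch_px,
    )
    labels = np.array([s.label for s in slides])
    tr, va, te = stratified_split(
        labels, cfg.n_val, cfg.n_test, stage_seed(cfg.seed, "split")
    )
    entries, outputs = [], []
    for s in slides:
        sdir = out / s.slide_id
        sdir.mkdir(exist_ok=True)
        tifffile.imwrite(sdir / "thumbnail.tif", s.thumbnail)
        iio.imwrite(sdir / "tissue_mask.png", (s.tissue_mask * 255).astype(np.uint8))
        iio.imwrite(sdir / "tumor_mask.png", (s.tumor_mask * 255).astype(np.uint8))
        entries.append({"slide_id": s.slide_id, "label": int(s.label)})
        outputs.append(str(sdir))
    with open(out / "dataset.json", "w") as fh:
        json.dump({
            "slides": entries,
            "splits": {"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()},
        }, fh, indent=2)
    _write_manifest(out, "synth", cfg, [], outputs)
    return out


def _load_dataset(root: Path) -> dict:
    path = _require(root / "synth" / "dataset.json", "synth")
    with open(path) as fh:
        return json.load(fh)


def _load_slide(root: Path, slide_id: str):
    import tifffile
    import imageio.v3 as iio

    sdir = _require(root / "synth" / slide_id, "synth")
    thumbnail = tifffile.imread(sdir / "thumbnail.tif")
    tumor = iio.imread(sdir / "tumor_mask.png") > 127
    tissue = iio.imread(sdir / "tissue_mask.png") > 127
    return thumbnail, tissue, tumor


def stage_preprocess(cfg: PipelineConfig, root: Path) -> Path:
    data = _load_dataset(root)
    out = root / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    all_records, outputs = {}, []
    for entry in data["slides"]:
        sid = entry["slide_id"]
        thumbnail, _, tumor = _load_slide(root, sid)
        tmask = tissue_mask(thumbnail)
        h, w = thumbnail.shape
        boxes = tile_positions(w, h, cfg.patch_px, cfg.patch_px)
        records = [PatchRecord(slide_id=sid, box=b) for b in boxes]
        scored = score_patches(records, tmask, MaskFractionScorer(tumor))
        all_records[sid] = [r.to_dict() for r in scored]
        retained = [r for r in scored if r.retained]
        png = out / f"{sid}_annotated.png"
        export_annotated_thumbnail(thumbnail, retained, png)
        outputs.append(str(png))
    with open(out / "patches.json", "w") as fh:
        json.dump(all_records, fh)
    _write_manifest(out, "preprocess", cfg, [str(root / "synth")], outputs)
    return out


def stage_extract(cfg: PipelineConfig, root: Path) -> Path:
    patches_path = _require(root / "preprocess" / "patches.json", "preprocess")
    with open(patches_path) as fh:
        all_records = json.load(fh)
    out = root / "extract"
    out.mkdir(parents=True, exist_ok=True)
    spec = ExtractorSpec(resize_to=cfg.resize_to)
    outputs = []
    for sid, recs in all_records.items():
        thumbnail, _, _ = _load_slide(root, sid)
        retained = [r for r in recs if r["retained"]]
        if not retained:
            continue
        imgs = [
            thumbnail[r["box"][1]:r["box"][3], r["box"][0]:r["box"][2]]
            for r in retained
        ]
        fm = extract_features(imgs, spec, patch_ids=[tuple(r["box"]) for r in retained])
        df = pd.DataFrame(fm.values)
        df.insert(0, "box", [json.dumps(list(b)) for b in fm.row_index])
        csv = out / f"{sid}.csv"
        df.to_csv(csv, index=False)
        with open(out / f"{sid}.json", "w") as fh:
            json.dump({"slide_id": sid, "d_in": fm.d_in,
                       "n_patches": fm.n_patches,
                       "extractor": {"kind": spec.kind, "resize_to": spec.resize_to}},
                      fh)
        outputs.append(str(csv))
    _write_manifest(out, "extract", cfg, [str(patches_path)], outputs)
    return out


def _load_features(root: Path, slide_id: str):
    csv = _require(root / "extract" / f"{slide_id}.csv", "extract")
    df = pd.read_csv(csv)
    boxes = [tuple(json.loads(b)) for b in df.pop("box")]
    return df.to_numpy(dtype=np.float64), boxes


def stage_optimize(cfg: PipelineConfig, root: Path) -> Path:
    data = _load_dataset(root)
    out = root / "optimize"
    out.mkdir(parents=True, exist_ok=True)
    rows, labels = [], []
    for i in data["splits"]["train"]:
        entry = data["slides"][i]
        X, _ = _load_features(root, entry["slide_id"])
        rows.append(X)
        labels.extend([entry["label"]] * X.shape[0])
    X_train, y_train = np.vstack(rows), np.array(labels)
    ea_cfg = EAConfig(
        P=cfg.ea_population, G=cfg.ea_generations, mu=cfg.ea_mu, rho=cfg.ea_rho,
        sigma=cfg.ea_sigma, seed=stage_seed(cfg.seed, "optimize"),
    )
    W, trace = evolve(X_train, y_train, ea_cfg, d_out=cfg.d_out)
    save_matrix(W, out / "matrix.txt")
    pd.DataFrame({
        "generation": range(len(trace.best)),
        "best": trace.best, "mean": trace.mean,
    }).to_csv(out / "trace.csv", index=False)
    _write_manifest(out, "optimize", cfg, [str(root / "extract")],
                    [str(out / "matrix.txt"), str(out / "trace.csv")])
    return out


def stage_graphs(cfg: PipelineConfig, root: Path) -> Path:
    from .evolve import load_matrix

    data = _load_dataset(root)
    W = load_matrix(_require(root / "optimize" / "matrix.txt", "optimize"))
    out = root / "graphs"
    out.mkdir(parents=True, exist_ok=True)
    counts = []
    for i in data["splits"]["train"]:
        X, _ = _load_features(root, data["slides"][i]["slide_id"])
        counts.append(X.shape[0])
    n_max = infer_nmax(counts)
    with open(out / "nmax.json", "w") as fh:
        json.dump({"N_max": n_max}, fh)
    radius = cfg.patch_px * cfg.radius_factor
    outputs = []
    for entry in data["slides"]:
        sid, label = entry["slide_id"], entry["label"]
        X_raw, boxes = _load_features(root, sid)
        records = [PatchRecord(slide_id=sid, box=b) for b in boxes]
        projected = transform(X_raw, W)
        X, positions, mask = assemble_slide(records, projected, n_max)
        A = np.zeros((n_max, n_max), dtype=np.int8)
        k = positions.shape[0]
        A[:k, :k] = build_graph(positions, radius)
        A_hat = normalize_adjacency(A, mask)
        g = SlideGraph(X=X, A=A, A_hat=A_hat, node_mask=mask,
                       n_real=int(mask.sum()), label=label, slide_id=sid,
                       positions=positions)
        path = out / str(label) / f"{sid}.evograph"
        save_graph(g, path)
        outputs.append(str(path))
    _write_manifest(out, "graphs", cfg, [str(root / "optimize")], outputs)
    return out


def _load_graphs(root: Path) -> tuple[list[SlideGraph], dict]:
    from .graphs import load_graph

    data = _load_dataset(root)
    gdir = _require(root / "graphs", "graphs")
    graphs = []
    for entry in data["slides"]:
        path = gdir / str(entry["label"]) / f"{entry['slide_id']}.evograph"
        graphs.append(load_graph(_require(path, "graphs")))
    return graphs, data


def stage_train(cfg: PipelineConfig, root: Path) -> Path:
    graphs, data = _load_graphs(root)
    out = root / "train"
    out.mkdir(parents=True, exist_ok=True)
    tr = data["splits"]["train"]
    va = data["splits"]["val"]
    head = make_head(cfg.head, d_in=cfg.d_out, seed=stage_seed(cfg.seed, "train"))
    tc = TrainConfig(learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                     batch_size=cfg.batch_size, patience=cfg.patience,
                     seed=stage_seed(cfg.seed, "train"))
    head, history = train(head, [graphs[i] for i in tr],
                          [graphs[i] for i in va], tc)
    state = {k: v.tolist() for k, v in head.state_dict().items()}
    with open(out / "model.json", "w") as fh:
        json.dump({"head": cfg.head, "d_in": cfg.d_out,
                   "N_max": graphs[0].X.shape[0], "state": state}, fh)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    _write_manifest(out, "train", cfg, [str(root / "graphs")],
                    [str(out / "model.json"), str(out / "history.csv")])
    return out


def _load_model(cfg: PipelineConfig, root: Path):
    path = _require(root / "train" / "model.json", "train")
    with open(path) as fh:
        doc = json.load(fh)
    head = make_head(doc["head"], d_in=doc["d_in"],
                     seed=stage_seed(cfg.seed, "train"))
    head.load_state_dict({k: np.array(v) for k, v in doc["state"].items()})
    return head


def stage_evaluate(cfg: PipelineConfig, root: Path) -> Path:
    graphs, data = _load_graphs(root)
    head = _load_model(cfg, root)
    out = root / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("train", "val", "test"):
        idx = data["splits"][name]
        inputs, y = graphs_to_arrays([graphs[i] for i in idx], head.input_keys)
        probs = head.predict_proba(**inputs)
        rep = metrics(y, probs)
        rows.append({"split": name, **rep.to_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.csv", index=False)
    _write_manifest(out, "evaluate", cfg, [str(root / "train")],
                    [str(out / "metrics.csv")])
    return out


def stage_predict(cfg: PipelineConfig, root: Path) -> Path:
    graphs, data = _load_graphs(root)
    head = _load_model(cfg, root)
    out = root / "predict"
    out.mkdir(parents=True, exist_ok=True)
    inputs, _ = graphs_to_arrays(graphs, head.input_keys)
    probs = head.predict_proba(**inputs)
    df = pd.DataFrame({
        "slide_id": [g.slide_id for g in graphs],
        "p_class0": probs[:, 0],
        "p_class1": probs[:, 1],
        "predicted": (probs[:, 1] > 0.5).astype(int),
    })
    df.to_csv(out / "predictions.csv", index=False)
    _write_manifest(out, "predict", cfg, [str(root / "train")],
                    [str(out / "predictions.csv")])
    return out


STAGES = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "extract": stage_extract,
    "optimize": stage_optimize,
    "graphs": stage_graphs,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "predict": stage_predict,
}


def run_stage(name: str, cfg: PipelineConfig, root: Path) -> Path:
    if name == "all":
        for stage in ("synth", "preprocess", "extract", "optimize",
                      "graphs", "train", "evaluate"):
            STAGES[stage](cfg, root)
        return root
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    return STAGES[name](cfg, root)
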