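"""End-to-end pipeline driver: synth -> stain -> segment -> classify -> map.

Stages run in dependency order and share outputs: the virtual-staining stage
feeds tiles to segmentation and classification, segmentation features feed
classification, and the classifier's out-of-fold probabilities are rendered
into the whole-slide cancer-probability map.  Every artifact lands under the
configured output directory and is listed in ``manifest.json`` together with
its stage and the config hash; stage failures abort with a stage-tagged error
while already-written artifacts are kept.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path

import numpy as np

from . import ecut, segmentation as seg_mod, stepff, genmetrics
from .config import RunConfig, config_hash, dump_config, stage_seed
from .synthetic import generate_dataset, write_dataset
from .tiling import (ImageTile, TileGrid, downsample_2x, invert_intensity,
                     stack_to_3ch, write_image)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(cfg, msg):
    if cfg.verbosity:
        print(f"[pahisto] {msg}", flush=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    dump_config(cfg, out / "config.yaml")
    manifest = {"config_hash": chash, "seed": cfg.seed, "artifacts": [],
                "timings_s": {}}

    def add(stage, path):
        manifest["artifacts"].append({"stage": stage,
                                      "path": str(Path(path).relative_to(out))})

    def flush():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def run_stage(name, fn):
        t0 = time.time()
        _log(cfg, f"stage {name} ...")
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage tag
            flush()
            traceback.print_exc()
            raise PipelineError(name, e) from e
        manifest["timings_s"][name] = round(time.time() - t0, 2)
        flush()

    state: dict = {}

    # ---- stage 1: synthetic data --------------------------------------------
    def synth():
        items = generate_dataset(cfg.scale.n_per_class, cfg.scene,
                                 cfg.scale.canvas_size,
                                 stage_seed(cfg.seed, "synth"))
        state["items"] = items
        mpath = write_dataset(items, out / "synth")
        add("synth", mpath)
        for i in range(len(items)):
            for mod in ("pah", "he", "mask"):
                add("synth", out / "synth" / f"{i:04d}_{mod}.png")

    run_stage("synth", synth)
    items = state["items"]
    src_tiles = [stack_to_3ch(invert_intensity(it.pah.pixels)) for it in items]
    he_tiles = [it.he.pixels for it in items]

    # ---- stage 2: virtual staining ------------------------------------------
    def stain():
        if not cfg.scale.include_vhe:
            state["vhe"] = None
            return
        tc = cfg.ecut_train
        tc.seed = stage_seed(cfg.seed, "stain")
        gen = ecut.ResnetGenerator(base_width=cfg.scale.gen_base_width,
                                   seed=tc.seed)
        disc = ecut.PatchDiscriminator(base_width=cfg.scale.gen_base_width,
                                       seed=tc.seed + 1)
        snap = out / "stain" / "snapshots"
        gen, disc, sampler, history = ecut.train_ecut(
            src_tiles, he_tiles, gen, disc, cfg.ecut_loss, tc,
            snapshot_dir=snap)
        hpath = out / "stain" / "history.json"
        hpath.parent.mkdir(parents=True, exist_ok=True)
        hpath.write_text(json.dumps(
            {k: v for k, v in history.items() if k != "snapshots"}, indent=2))
        add("stain", hpath)
        ckpt = out / "stain" / "generator.npz"
        ecut.save_checkpoint(ckpt, gen, disc, sampler,
                             extra_meta={"config_hash": chash})
        add("stain", ckpt)
        vhe = []
        for i, tile in enumerate(src_tiles):
            v = gen.translate(tile)
            vhe.append(v)
            write_image(out / "stain" / f"{i:04d}_vhe.png", v)
            add("stain", out / "stain" / f"{i:04d}_vhe.png")
        state["vhe"] = vhe

    run_stage("stain", stain)
    vhe_tiles = state["vhe"]

    # ---- stage 3: segmentation + features -----------------------------------
    def segment():
        useed = stage_seed(cfg.seed, "segment")
        ucfg = cfg.unet_train
        ucfg.seed = useed
        train_pairs = [(he, it.mask.pixels) for he, it in zip(he_tiles, items)]
        model = seg_mod.UNet(base_width=cfg.scale.unet_base_width,
                             in_ch=3, seed=useed)
        model, hist = seg_mod.train_unet(train_pairs, model, ucfg)
        state["unet"] = model
        seg_dir = out / "segment"
        seg_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        labels01 = [1 if it.label == "cancerous" else 0 for it in items]
        feats = {}
        for mod_name, tiles in (("pah", src_tiles), ("vhe", vhe_tiles)):
            if tiles is None:
                continue
            masks = [seg_mod.predict_mask(model, t) for t in tiles]
            table = seg_mod.feature_table(tiles, masks=masks, labels=labels01,
                                          modality=mod_name.upper())
            table.to_csv(seg_dir / f"features_{mod_name}.csv", index=False)
            add("segment", seg_dir / f"features_{mod_name}.csv")
            feats[mod_name] = table
        state["features"] = feats
        (seg_dir / "history.json").write_text(json.dumps(hist, indent=2))
        add("segment", seg_dir / "history.json")

    run_stage("segment", segment)

    # ---- stage 4: classification --------------------------------------------
    def classify():
        feats = state["features"]
        scfg = cfg.stepff_train
        scfg.seed = stage_seed(cfg.seed, "classify")
        mods = ["pah", "seg"] if vhe_tiles is None else ["pah", "vhe", "seg"]
        scfg.modalities = tuple(mods)
        sources = ["pah"] if vhe_tiles is None else ["pah", "vhe"]
        scfg.seg_dim = 3 * len(sources)
        records = []
        for i, it in enumerate(items):
            px = invert_intensity(it.pah.pixels)
            vh = vhe_tiles[i] if vhe_tiles is not None else None
            for _ in range(cfg.scale.stepff_downsample):
                px = downsample_2x(px)
                vh = downsample_2x(vh) if vh is not None else None
            row = {"pah": px, "label": 1 if it.label == "cancerous" else 0}
            if vh is not None:
                row["vhe"] = vh
            svec = []
            for srcname in sources:
                r = feats[srcname].iloc[i]
                h = float(it.scene.canvas_size[0])
                # undefined features (empty tiles) fall back to neutral values
                svec += [np.nan_to_num(r["cell_area"]), r["cell_count"],
                         r["mean_distance"] if np.isfinite(r["mean_distance"])
                         else h]
            row["seg"] = svec
            records.append(row)
        result = stepff.train_stepff(records, scfg)
        cls_dir = out / "classify"
        cls_dir.mkdir(parents=True, exist_ok=True)
        result["metrics"].to_csv(cls_dir / "cv_metrics.csv", index=False)
        add("classify", cls_dir / "cv_metrics.csv")
        (cls_dir / "mean_metrics.json").write_text(
            json.dumps(result["mean_metrics"], indent=2))
        add("classify", cls_dir / "mean_metrics.json")
        state["cls"] = result

    run_stage("classify", classify)

    # ---- stage 5: probability map + generation metrics ----------------------
    def metrics():
        result = state["cls"]
        probs = np.nan_to_num(result["oof_probs"], nan=0.5)
        # lay the tiles out in a row-major mosaic and render the slide map
        n = len(items)
        ts = cfg.scale.canvas_size[0]
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        tiles = [ImageTile(np.zeros((ts, ts), np.uint8),
                           origin=((i // ncol) * ts, (i % ncol) * ts),
                           modality="PROB")
                 for i in range(n)]
        grid = TileGrid(tiles, canvas_size=(nrow * ts, ncol * ts),
                        tile_size=ts, stride=ts)
        pmap = stepff.probability_map(probs, grid)
        met_dir = out / "metrics"
        met_dir.mkdir(parents=True, exist_ok=True)
        write_image(met_dir / "probability_map.png", pmap)
        add("metrics", met_dir / "probability_map.png")
        report = {"n_tiles": n,
                  "cv_accuracy": result["mean_metrics"]["accuracy"]}
        if vhe_tiles is not None:
            fs = stage_seed(cfg.seed, "metrics")
            f_real = genmetrics.extract_features(he_tiles, seed=fs)
            f_fake = genmetrics.extract_features(vhe_tiles, seed=fs)
            report["fid_vhe_vs_he"] = genmetrics.fid(f_real, f_fake)
            report["kid_vhe_vs_he"] = genmetrics.kid(
                f_real, f_fake, n_blocks=5,
                block_size=min(f_real.n, f_fake.n), seed=fs)
            report["extractor"] = f_real.extractor_id
        (met_dir / "generation_metrics.json").write_text(
            json.dumps(report, indent=2))
        add("metrics", met_dir / "generation_metrics.json")

    run_stage("metrics", metrics)
    flush()
    _log(cfg, f"done; manifest at {out / 'manifest.json'}")
    return manifest
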