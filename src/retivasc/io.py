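"""On-disk formats: scene rasters with JSON sidecars, tree JSON, cohort CSV."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import FundusScene, TreeParams, TreeSegment, VesselTree

__all__ = ["save_scene", "load_scene", "tree_to_json", "tree_from_json",
           "save_cohort", "load_cohort"]


def tree_to_json(tree: VesselTree) -> dict:
    from dataclasses import asdict
    return {
        "params": asdict(tree.params),
        "segments": [
            {
                "segment_id": s.segment_id,
                "points": np.asarray(s.points).tolist(),
                "width_um": s.width_um,
                "generation": s.generation,
                "label": s.label,
                "parent_id": s.parent_id,
                "path_id": s.path_id,
            }
            for s in tree.segments
        ],
    }


def tree_from_json(obj: dict) -> VesselTree:
    pdict = dict(obj["params"])
    if pdict.get("disc_center") is not None:
        pdict["disc_center"] = tuple(pdict["disc_center"])
    params = TreeParams(**pdict)
    segments = [
        TreeSegment(
            segment_id=s["segment_id"],
            points=np.asarray(s["points"], dtype=float),
            width_um=s["width_um"],
            generation=s["generation"],
            label=s["label"],
            parent_id=s["parent_id"],
            path_id=s.get("path_id", -1),
        )
        for s in obj["segments"]
    ]
    return VesselTree(segments, params)


def save_scene(scene: FundusScene, stem: Path) -> dict[str, Path]:
    """Write image PNG (8-bit), mask PNG, JSON sidecar and tree JSON.

    ``stem`` is the path prefix; files are ``<stem>.png``, ``<stem>_mask.png``,
    ``<stem>.json`` and ``<stem>_tree.json``.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img_path = stem.with_suffix(".png")
    mask_path = stem.parent / f"{stem.name}_mask.png"
    meta_path = stem.with_suffix(".json")
    tree_path = stem.parent / f"{stem.name}_tree.json"

    iio.imwrite(img_path, np.round(scene.image * 255).astype(np.uint8))
    iio.imwrite(mask_path, (scene.truth_mask.astype(np.uint8) * 255))
    meta = {
        "disc_center": list(scene.disc_center),
        "disc_radius": scene.disc_radius,
        "px_per_micron": scene.px_per_micron,
        "seed": scene.seed,
        "vessel_area_px": scene.vessel_area_px,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    tree_path.write_text(json.dumps(tree_to_json(scene.tree)))
    return {"image": img_path, "mask": mask_path, "meta": meta_path, "tree": tree_path}


def load_scene(stem: Path) -> FundusScene:
    stem = Path(stem)
    img = iio.imread(stem.with_suffix(".png")).astype(float) / 255.0
    mask = iio.imread(stem.parent / f"{stem.name}_mask.png") > 127
    meta = json.loads(stem.with_suffix(".json").read_text())
    tree = tree_from_json(json.loads((stem.parent / f"{stem.name}_tree.json").read_text()))
    return FundusScene(
        image=img,
        truth_mask=mask,
        disc_center=tuple(meta["disc_center"]),
        disc_radius=meta["disc_radius"],
        px_per_micron=meta["px_per_micron"],
        tree=tree,
        vessel_area_px=meta["vessel_area_px"],
        seed=meta["seed"],
    )


def save_cohort(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return path


def load_cohort(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)
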