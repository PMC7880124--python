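"""Orchestration: image -> metrics -> association as reproducible runs.

Thin functional layer over the library modules. A :class:`RunConfig` carries
every knob, round-trips losslessly through YAML, and each run writes the
resolved configuration next to its outputs. All randomness flows from the
single run seed: stage seeds are drawn from ``numpy.random.SeedSequence(seed)``
spawned in a fixed order (scenes first, then cohort), so reruns are
byte-identical.

Two reproduction paths exist: the *fast* path samples cohort metrics from
their configured distributions and runs only the statistical stage; the
*full* path renders scenes, segments them and measures the metrics from the
images (used for image-level validation on a few dozen scenes).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import caliber, geometry, io, segment, stats, synth

__all__ = ["RunConfig", "simulate", "compute_metrics", "associate", "reproduce",
           "stage_seeds", "scene_metrics"]

logger = logging.getLogger(__name__)

METRIC_CSV_COLUMNS = [
    "image_id", "df", "lac", "tort", "n_branches", "df_r2", "lac_r2",
    "crae_um", "crve_um", "n_art", "n_ven", "dice_vs_truth",
]


@dataclass
class RunConfig:
    seed: int = 0
    n_scenes: int = 10
    contrast: float = 0.55
    noise_sd: float = 0.05
    tree: synth.TreeParams = field(default_factory=synth.TreeParams)
    cohort: synth.CohortParams = field(default_factory=synth.CohortParams)
    line: segment.LineFilterConfig = field(default_factory=segment.LineFilterConfig)
    post: segment.PostprocessConfig = field(default_factory=segment.PostprocessConfig)
    geometry_zone: segment.ZoneSpec = field(default_factory=lambda: segment.GEOMETRY_ZONE)
    caliber_zone: segment.ZoneSpec = field(default_factory=lambda: segment.CALIBER_ZONE)
    min_branch_len: float = 10.0

    def to_yaml(self) -> str:
        return yaml.safe_dump(_listify(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        kw = dict(raw)
        kw["tree"] = _from_dict(synth.TreeParams, raw["tree"])
        kw["cohort"] = _from_dict(synth.CohortParams, raw["cohort"])
        kw["line"] = _from_dict(segment.LineFilterConfig, raw["line"])
        kw["post"] = _from_dict(segment.PostprocessConfig, raw["post"])
        kw["geometry_zone"] = _from_dict(segment.ZoneSpec, raw["geometry_zone"])
        kw["caliber_zone"] = _from_dict(segment.ZoneSpec, raw["caliber_zone"])
        return cls(**kw)


def _listify(obj):
    if isinstance(obj, (list, tuple)):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(x) for x in obj)
    return obj


def _from_dict(cls, d: dict):
    kw = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if cls is synth.CohortParams and f.name == "outcomes":
            v = tuple(
                (name, op if isinstance(op, synth.OutcomeParams)
                 else synth.OutcomeParams(**{k: _tupleize(x) for k, x in op.items()}))
                for name, op in v
            )
        elif cls is synth.TreeParams and f.name == "disc_center" and v is not None:
            v = tuple(v)
        else:
            v = _tupleize(v)
        kw[f.name] = v
    return cls(**kw)


def stage_seeds(seed: int, n_scenes: int) -> dict:
    """Deterministic per-stage seed derivation from the single run seed."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(n_scenes * 2 + 1) % (2**31 - 1)
    return {
        "trees": [int(s) for s in state[:n_scenes]],
        "renders": [int(s) for s in state[n_scenes:2 * n_scenes]],
        "cohort": int(state[-1]),
    }


def simulate(config: RunConfig, out_dir: Path) -> dict:
    """Write rendered scenes and a cohort CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, config.n_scenes)
    paths = {"scenes": [], "config": out_dir / "run_config.yaml"}
    for i in range(config.n_scenes):
        tree = synth.simulate_tree(dataclasses.replace(config.tree, seed=seeds["trees"][i]))
        scene = synth.render_scene(tree, contrast=config.contrast,
                                   noise_sd=config.noise_sd, seed=seeds["renders"][i])
        paths["scenes"].append(io.save_scene(scene, out_dir / f"scene_{i:03d}"))
    cohort = synth.simulate_cohort(dataclasses.replace(config.cohort, seed=seeds["cohort"]))
    paths["cohort"] = io.save_cohort(cohort, out_dir / "cohort.csv")
    paths["config"].write_text(config.to_yaml())
    return paths


def scene_metrics(scene: synth.FundusScene, config: RunConfig,
                  image_id: str = "scene") -> dict:
    """Segment one scene and measure geometry + caliber metrics."""
    mask = segment.segment(scene.image, config.line, config.post)
    zone_geom = segment.zone_mask(mask.shape, scene.disc_center,
                                  scene.disc_radius, config.geometry_zone)
    geom_mask = mask & zone_geom
    row: dict = {"image_id": image_id}
    truth = scene.truth_mask
    inter = np.logical_and(mask, truth).sum()
    row["dice_vs_truth"] = 2.0 * inter / (mask.sum() + truth.sum()) if truth.any() else np.nan
    try:
        summ = geometry.geometry_summary(geom_mask, min_branch_len=config.min_branch_len)
        row.update(df=summ.fractal_dimension, lac=summ.lacunarity, tort=summ.tortuosity,
                   n_branches=summ.n_branches, df_r2=summ.df_r2, lac_r2=summ.lac_r2)
    except ValueError as exc:
        logger.warning("%s: geometry failed (%s)", image_id, exc)
        row.update(df=np.nan, lac=np.nan, tort=np.nan, n_branches=0,
                   df_r2=np.nan, lac_r2=np.nan)
    labeler = caliber.TreeLabeler(scene.tree)
    widths = caliber.measure_widths(mask, scene.disc_center, scene.disc_radius,
                                    scene.px_per_micron, labeler,
                                    zone=config.caliber_zone)
    summary = caliber.caliber_summary(widths)
    row.update(crae_um=summary.crae_um, crve_um=summary.crve_um,
               n_art=summary.n_arterioles_used, n_ven=summary.n_venules_used)
    return row


def compute_metrics(image_dir: Path, config: RunConfig, out_csv: Path | None = None) -> pd.DataFrame:
    """Per-image metrics CSV for every saved scene in a directory."""
    image_dir = Path(image_dir)
    stems = sorted(p.with_suffix("") for p in image_dir.glob("scene_*.json")
                   if not p.stem.endswith("_tree"))
    rows = []
    if not stems:
        warnings.warn(f"no scenes found in {image_dir}; writing empty metrics table")
    for stem in stems:
        scene = io.load_scene(stem)
        rows.append(scene_metrics(scene, config, image_id=stem.name))
    out = pd.DataFrame(rows, columns=METRIC_CSV_COLUMNS)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_csv, index=False)
    return out


def associate(cohort: pd.DataFrame | Path, config: RunConfig,
              out_dir: Path | None = None) -> dict:
    """Average the cohort per child and run the full outcome x metric grid."""
    if not isinstance(cohort, pd.DataFrame):
        cohort = io.load_cohort(cohort)
    per_child = stats.average_metrics(cohort)
    effects = stats.run_analysis_matrix(per_child)
    report = stats.format_report(effects)
    out = {"per_child": per_child, "effects": effects, "report": report}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        effects.to_csv(out_dir / "effects.csv", index=False)
        (out_dir / "report.md").write_text(report)
        (out_dir / "run_config.yaml").write_text(config.to_yaml())
    return out


def reproduce(config: RunConfig, out_dir: Path | None = None,
              fast: bool = True) -> dict:
    """Full chain: simulate -> (segment/measure) -> associate -> compare.

    Fast path: cohort metrics sampled from their configured distributions.
    Full path additionally renders ``config.n_scenes`` scenes and measures
    image-level metrics. The result compares recovered per-IQR effects with
    the configured marginal truths.
    """
    seeds = stage_seeds(config.seed, config.n_scenes)
    cohort = synth.simulate_cohort(dataclasses.replace(config.cohort, seed=seeds["cohort"]))
    res = associate(cohort, config, out_dir=out_dir)
    res["cohort"] = cohort

    truths = _configured_truths(config.cohort)
    eff = res["effects"].set_index(["outcome", "metric"])
    rows = []
    for (outcome, metric), true_val in truths.items():
        if (outcome, metric) in eff.index:
            est = eff.loc[(outcome, metric), "beta_per_iqr"]
            rows.append({"outcome": outcome, "metric": metric,
                         "true_per_iqr": true_val, "recovered_per_iqr": est})
    res["recovery"] = pd.DataFrame(rows)

    if not fast:
        scene_rows = []
        for i in range(config.n_scenes):
            tree = synth.simulate_tree(dataclasses.replace(config.tree, seed=seeds["trees"][i]))
            scene = synth.render_scene(tree, contrast=config.contrast,
                                       noise_sd=config.noise_sd, seed=seeds["renders"][i])
            scene_rows.append(scene_metrics(scene, config, image_id=f"scene_{i:03d}"))
        res["image_metrics"] = pd.DataFrame(scene_rows, columns=METRIC_CSV_COLUMNS)
        if out_dir is not None:
            res["image_metrics"].to_csv(Path(out_dir) / "image_metrics.csv", index=False)
    if out_dir is not None:
        res["recovery"].to_csv(Path(out_dir) / "recovery.csv", index=False)
    return res


def _configured_truths(cp: synth.CohortParams) -> dict:
    truths = {}
    for name, base_mean, m_iqr, _cov in cp.sdq_effects:
        for j, met in enumerate(synth.METRICS):
            truths[(f"sdq_{name}", met)] = m_iqr[j]
    sdq_total = {}
    for name, _bm, m_iqr, _cov in cp.sdq_effects:
        for j, met in enumerate(synth.METRICS):
            sdq_total[met] = sdq_total.get(met, 0.0) + m_iqr[j]
    for met, v in sdq_total.items():
        truths[("sdq_total", met)] = v
    for name, op in cp.outcomes:
        for j, met in enumerate(synth.METRICS):
            truths[(name, met)] = op.metric_effects_per_iqr[j]
    return truths
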