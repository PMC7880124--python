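"""Synthetic ground truth: vascular trees, fundus-like scenes, cohort tables.

Two decoupled layers:

* **Image level** — :func:`simulate_tree` grows a rooted vascular network of
  major arterioles/venules radiating from the optic-disc margin, with sinuous
  centrelines (transverse sine perturbation), stochastic side branching and
  Murray-law-like width decay per branch generation. :func:`render_scene`
  rasterises the tree into a grayscale fundus-like image (radial illumination,
  dark anti-aliased vessels, Gaussian noise) plus a lossless binary truth
  mask. These emulate the 45-degree non-mydriatic fundus field the analysis
  pipeline expects, not photorealistic retinas.

* **Table level** — :func:`simulate_cohort` draws a cohort of children with
  repeated examinations: covariates, child-latent retinal metrics with
  configured between/within variance (targeting published test-retest
  reliability), per-eye measured metrics, SDQ behavioural scores (four
  problem subscales, integers 0-10, total = sum) and four cognitive test
  latencies with configured metric/covariate effect structure.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TreeParams",
    "TreeSegment",
    "VesselTree",
    "FundusScene",
    "OutcomeParams",
    "CohortParams",
    "simulate_tree",
    "render_scene",
    "simulate_cohort",
    "simulate_repeats",
    "METRICS",
    "SDQ_SUBSCALES",
    "marginal_to_structural",
]

METRICS = ("df", "lac", "tort", "crae", "crve")
SDQ_SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer")


# ---------------------------------------------------------------------------
# vascular trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeParams:
    """Knobs of the synthetic vascular network.

    Scale: with the default ``px_per_micron`` the 60 px disc radius maps to a
    900 um optic-disc radius, so a ~100 um major vessel renders ~6.7 px wide.
    ``sine_amplitude`` (px) controls curvature: 0 gives perfectly straight
    segments; the default is calibrated so the measured mean branch chord/arc
    tortuosity of rendered scenes sits at the published population mean.
    """

    seed: int = 0
    n_major_vessels: int = 12          # alternating arteriole / venule
    branching_prob: float = 0.004      # side-branch probability per px of arc
    taper_exponent: float = 3.0        # child width = parent * 2**(-1/exponent)
    sine_amplitude: float = 11.0       # px; calibrated, see docs/methods.md
    sine_period: float = 34.0          # px
    root_width_mean_art: float = 94.0  # um
    root_width_mean_ven: float = 105.0  # um
    root_width_sd_frac: float = 0.12
    image_size: int = 1024
    disc_center: tuple[float, float] | None = None  # default: image centre
    disc_radius: float = 60.0
    px_per_micron: float = 60.0 / 900.0
    max_generations: int = 3
    step_px: float = 2.0
    continuation_taper: float = 0.97   # trunk width decay at each bifurcation

    def __post_init__(self) -> None:
        if self.root_width_mean_art <= 0 or self.root_width_mean_ven <= 0:
            raise ValueError("root widths must be positive")
        if self.sine_amplitude < 0 or self.sine_period <= 0:
            raise ValueError("sine_amplitude >= 0 and sine_period > 0 required")
        cy, cx = self.center
        r = self.disc_radius
        if not (r < cy < self.image_size - r and r < cx < self.image_size - r):
            raise ValueError("optic disc must lie fully inside the image")
        # the geometry zone (out to 2 disc diameters from the margin = 5 r
        # from the centre) must fit inside the image
        if min(cy, cx, self.image_size - 1 - cy, self.image_size - 1 - cx) < 5 * r:
            raise ValueError("image too small to contain the 2-disc-diameter zone")

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        c = (self.image_size - 1) / 2.0
        return (c, c)


@dataclass
class TreeSegment:
    segment_id: int
    points: np.ndarray  # (n, 2) float, (row, col)
    width_um: float
    generation: int
    label: Literal["arteriole", "venule"]
    parent_id: int | None
    path_id: int = -1   # trunk-chain identity: continuations share their
                        # parent's path, side branches start a new one


@dataclass
class VesselTree:
    segments: list[TreeSegment]
    params: TreeParams

    def __post_init__(self) -> None:
        self.by_id = {s.segment_id: s for s in self.segments}

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_arc_length(self) -> float:
        return float(sum(
            np.linalg.norm(np.diff(s.points, axis=0), axis=1).sum() for s in self.segments
        ))


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def simulate_tree(params: TreeParams) -> VesselTree:
    """Grow a deterministic (seeded) vascular tree rooted at the disc margin.

    Major vessels emanate radially; centrelines follow a straight baseline
    plus a transverse sine offset ``A * (sin(2 pi s / P + phi) - sin(phi))``
    along the arc coordinate ``s`` (zero at the start so segments join their
    parent endpoint exactly). A branch event ends the current segment and
    spawns a continuation (same generation, mild width decay) and a rotated
    side branch one generation deeper with Murray-law width decay. No point
    enters the disc interior.
    """
    rng = np.random.default_rng(params.seed)
    cy, cx = params.center
    center = np.array([cy, cx])
    r = params.disc_radius
    size = params.image_size
    max_radial = min(size / 2.0 - 15.0, 7.8 * r)
    side_taper = 2.0 ** (-1.0 / params.taper_exponent)
    margin = 6.0

    segments: list[TreeSegment] = []
    next_id = [0]

    # stack of (start, direction, width_um, generation, label, parent, run)
    stack: list[tuple] = []
    for i in range(params.n_major_vessels - 1, -1, -1):
        theta = 2.0 * math.pi * i / params.n_major_vessels + rng.normal(0.0, 0.04)
        u = np.array([math.sin(theta), math.cos(theta)])
        u = _rotate(u, rng.normal(0.0, 0.06))
        label = "arteriole" if i % 2 == 0 else "venule"
        wmean = params.root_width_mean_art if label == "arteriole" else params.root_width_mean_ven
        width = max(wmean * (1.0 + params.root_width_sd_frac * rng.standard_normal()),
                    0.3 * wmean)
        start = center + (r + 2.0) * np.array([math.sin(theta), math.cos(theta)])
        run = max_radial - (r + 2.0)
        stack.append((start, u, width, 0, label, None, run, None))

    step = params.step_px
    while stack:
        start, u, width, gen, label, parent, run, path = stack.pop()
        phase = rng.uniform(0.0, 2.0 * math.pi)
        v = np.array([-u[1], u[0]])
        pts = [start.copy()]
        sin0 = math.sin(phase)
        branch_at = None
        s = step
        while s <= run:
            off = params.sine_amplitude * (math.sin(2.0 * math.pi * s / params.sine_period + phase) - sin0)
            p = start + s * u + off * v
            d = np.linalg.norm(p - center)
            if (p[0] < margin or p[0] > size - 1 - margin
                    or p[1] < margin or p[1] > size - 1 - margin
                    or d <= r + 1.0 or d >= max_radial):
                break
            pts.append(p)
            if (gen < params.max_generations and s > 30.0 and len(pts) > 3
                    and width * side_taper * params.px_per_micron >= 1.5
                    and rng.uniform() < params.branching_prob * step):
                branch_at = s
                break
            s += step
        if len(pts) < 2:
            continue
        seg_id = next_id[0]
        next_id[0] += 1
        if path is None:
            path = seg_id
        poly = np.asarray(pts)
        segments.append(TreeSegment(seg_id, poly, width, gen, label, parent, path))
        if branch_at is not None:
            tangent = poly[-1] - poly[-2]
            tangent = tangent / np.linalg.norm(tangent)
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            side_dir = _rotate(tangent, sign * math.radians(25.0 + rng.uniform(0.0, 15.0)))
            side_run = (run - branch_at) * rng.uniform(0.35, 0.7)
            cont_dir = _rotate(tangent, -sign * math.radians(rng.uniform(0.0, 8.0)))
            p_end = poly[-1]
            # continuation first so rng draw order stays stable
            stack.append((p_end, cont_dir, width * params.continuation_taper,
                          gen, label, seg_id, run - branch_at, path))
            stack.append((p_end, side_dir, width * side_taper,
                          gen + 1, label, seg_id, side_run, None))
    return VesselTree(segments, params)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class FundusScene:
    image: np.ndarray          # grayscale in [0, 1]
    truth_mask: np.ndarray     # bool, vessel pixels = True
    disc_center: tuple[float, float]
    disc_radius: float
    px_per_micron: float
    tree: VesselTree
    vessel_area_px: int        # rasteriser bookkeeping: truth_mask.sum()
    seed: int = 0


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] <= 0:
        return points[:1]
    si = np.arange(0.0, s[-1] + spacing / 2.0, spacing)
    return np.column_stack([np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])])


def render_scene(
    tree: VesselTree,
    contrast: float = 0.55,
    noise_sd: float = 0.05,
    seed: int = 0,
    background_level: float = 0.82,
    vignette: float = 0.25,
    disc_brightness: float = 0.08,
) -> FundusScene:
    """Rasterise a tree into a grayscale scene and its truth mask.

    Vessels are drawn as anti-aliased strokes of thickness equal to their
    width; the soft coverage map ``V`` in [0, 1] darkens the smooth radial
    background by ``contrast * V`` before Gaussian noise is added. The truth
    mask is the ``V >= 0.5`` level set, stored losslessly.
    """
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = tree.params
    size = p.image_size
    V = np.zeros((size, size), dtype=float)
    for seg in tree.segments:
        radius = max(seg.width_um * p.px_per_micron / 2.0, 0.6)
        samples = _resample(seg.points, 0.6)
        half = int(math.ceil(radius + 1.0))
        offs = np.arange(-half, half + 1)
        for q in samples:
            r0 = int(round(q[0]))
            c0 = int(round(q[1]))
            rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, size)
            clo, chi = max(c0 - half, 0), min(c0 + half + 1, size)
            if rlo >= rhi or clo >= chi:
                continue
            dr = (np.arange(rlo, rhi) - q[0])[:, None]
            dc = (np.arange(clo, chi) - q[1])[None, :]
            val = np.clip(radius + 0.5 - np.sqrt(dr * dr + dc * dc), 0.0, 1.0)
            np.maximum(V[rlo:rhi, clo:chi], val, out=V[rlo:rhi, clo:chi])

    truth = V >= 0.5
    cy, cx = p.center
    rr, cc = np.ogrid[:size, :size]
    d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    bg = background_level - vignette * (d / (size / 2.0)) ** 2
    img = bg * (1.0 - contrast * V)
    if disc_brightness > 0:
        disc_soft = np.clip((p.disc_radius - d) / 6.0 + 1.0, 0.0, 1.0)
        img = img + disc_brightness * disc_soft
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return FundusScene(
        image=img,
        truth_mask=truth,
        disc_center=p.center,
        disc_radius=p.disc_radius,
        px_per_micron=p.px_per_micron,
        tree=tree,
        vessel_area_px=int(truth.sum()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeParams:
    """One outcome's generative structure.

    ``metric_effects_per_iqr`` are the configured *single-exposure* (marginal)
    associations, in outcome units per interquartile range of each metric in
    :data:`METRICS` order. They are converted internally to joint structural
    coefficients so that a one-metric-at-a-time regression recovers exactly
    these marginals (see :func:`marginal_to_structural`).
    ``covariate_effects`` keys: ``boy`` (vs girl), ``age`` (per year),
    ``passive_smoking``, ``low_occupation``.
    """

    mean: float
    child_sd: float
    exam_sd: float
    metric_effects_per_iqr: tuple[float, float, float, float, float] = (0, 0, 0, 0, 0)
    covariate_effects: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.child_sd < 0 or self.exam_sd < 0:
            raise ValueError("outcome noise SDs must be >= 0")


def _sdq_default_effects() -> dict[str, dict]:
    """Configured marginal effect structure of the four SDQ problem subscales.

    Per-IQR geometry effects follow the published subscale decomposition
    (they sum to the overall-score effects 1.12 / -1.38 / -0.99 per IQR of
    fractal dimension / lacunarity / tortuosity); covariate effects on the
    total (+1.5 boys, -0.8 per year of age, +2.7 passive smoking, +2.2 low
    maternal occupation) are split equally across the subscales.
    """
    geometry = {
        "emotional": (0.06, -0.13, -0.10),
        "conduct": (0.34, -0.23, -0.38),
        "hyperactivity": (0.63, -0.88, -0.53),
        "peer": (0.09, -0.14, 0.02),
    }
    base_means = {"emotional": 1.6, "conduct": 1.2, "hyperactivity": 2.8, "peer": 1.0}
    cov = (("boy", 1.5 / 4), ("age", -0.8 / 4),
           ("passive_smoking", 2.7 / 4), ("low_occupation", 2.2 / 4))
    out = {}
    for name in SDQ_SUBSCALES:
        g = geometry[name]
        out[name] = {
            "base_mean": base_means[name],
            "metric_effects_per_iqr": (g[0], g[1], g[2], 0.0, 0.0),
            "covariate_effects": cov,
        }
    return out


def _default_outcomes() -> dict[str, OutcomeParams]:
    return {
        # mean reaction time, Stroop colour-word test (ms); geometry null
        "stroop_ms": OutcomeParams(1403.0, 250.0, 90.0,
                                   covariate_effects=(("age", -60.0), ("low_occupation", 180.1))),
        # Continuous Performance sustained-attention reaction time (ms)
        "cp_ms": OutcomeParams(598.0, 40.0, 25.0,
                               metric_effects_per_iqr=(11.0, -11.1, -13.4, 0.0, 0.0),
                               covariate_effects=(("age", -15.0),)),
        # Digit-Symbol substitution total latency (s)
        "digit_symbol_s": OutcomeParams(126.0, 21.0, 7.0,
                                        metric_effects_per_iqr=(2.63, 0.0, 0.0, 0.0, 0.0),
                                        covariate_effects=(("age", -5.0), ("low_occupation", 7.3))),
        # Pattern Comparison mean latency of correct items (s); geometry null
        "pattern_comparison_s": OutcomeParams(4.3, 0.85, 0.3,
                                              covariate_effects=(("age", -0.15), ("boy", 0.28))),
    }


@dataclass(frozen=True)
class CohortParams:
    """Stated world of the synthetic cohort (defaults follow the study
    population: n = 190 children, 48.2% girls, age 9.9 +/- 1.2 y, visit mix
    25/124/72 of 221 for 1/2/3 examinations, and the published metric means
    and SDs)."""

    seed: int = 0
    n_children: int = 190
    exam_count_probs: tuple[float, float, float] = (25 / 221, 124 / 221, 72 / 221)
    girl_frac: float = 0.482
    age_mean: float = 9.9
    age_sd: float = 1.2
    exam_interval_years: float = 49.0 / 365.25
    bmi_probs: tuple[float, float, float, float] = (0.084, 0.80, 0.09, 0.026)
    map_mean: float = 80.0
    map_sd: float = 6.5
    passive_smoking_frac: float = 0.084
    low_occupation_frac: float = 0.168
    # child-latent metric distributions (METRICS order: df, lac, tort, crae, crve)
    metric_means: tuple[float, ...] = (1.500, 0.495, 0.857, 163.8, 223.3)
    metric_sds: tuple[float, ...] = (0.034, 0.042, 0.012, 12.2, 16.5)
    df_lac_corr: float = -0.6
    # per-exam test-retest reliability targets; within-exam SD derives as
    # sd * sqrt((1 - icc) / icc)
    icc_targets: tuple[float, ...] = (0.80, 0.78, 0.74, 0.85, 0.88)
    # per-IQR scaling used to convert configured marginal effects to per-unit
    # (geometry IQRs as published; caliber IQRs from the normal 1.349 sd rule)
    metric_iqrs: tuple[float, ...] = (0.04, 0.06, 0.02, 1.349 * 12.2, 1.349 * 16.5)
    sdq_noise_sd: float = 1.6
    sdq_clip_max: int = 10      # per subscale; theoretical bound
    sdq_effects: tuple = tuple(sorted(
        (k, v["base_mean"], v["metric_effects_per_iqr"], v["covariate_effects"])
        for k, v in _sdq_default_effects().items()
    ))
    outcomes: tuple = tuple(sorted(_default_outcomes().items()))

    def __post_init__(self) -> None:
        for probs in (self.exam_count_probs, self.bmi_probs):
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError("categorical probabilities must sum to 1")
        if any(sd <= 0 for sd in self.metric_sds):
            raise ValueError("metric SDs must be positive")
        if any(not 0 < icc < 1 for icc in self.icc_targets):
            raise ValueError("ICC targets must lie in (0, 1)")
        if not -1 < self.df_lac_corr < 1:
            raise ValueError("df_lac_corr must lie in (-1, 1)")

    @property
    def metric_cov(self) -> np.ndarray:
        sds = np.asarray(self.metric_sds)
        cov = np.diag(sds ** 2)
        cov[0, 1] = cov[1, 0] = self.df_lac_corr * sds[0] * sds[1]
        return cov

    @property
    def within_exam_sds(self) -> np.ndarray:
        sds = np.asarray(self.metric_sds)
        icc = np.asarray(self.icc_targets)
        return sds * np.sqrt((1.0 - icc) / icc)


def marginal_to_structural(marginals_per_unit: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Joint coefficients whose implied single-exposure slopes equal ``m``.

    A one-exposure-at-a-time regression of ``y = x' beta + noise`` on metric
    ``j`` alone has slope ``m_j = (Sigma beta)_j / Sigma_jj``. Inverting,
    ``beta = Sigma^{-1} diag(Sigma) m``. With uncorrelated metrics this is
    the identity map.
    """
    m = np.asarray(marginals_per_unit, dtype=float)
    return np.linalg.solve(cov, np.diag(np.diag(cov)) @ m)


def _linear_predictor(
    marginals_per_iqr: np.ndarray,
    cov_effects: dict[str, float],
    params: CohortParams,
    latent_c: np.ndarray,
    covars: pd.DataFrame,
) -> np.ndarray:
    """Centered linear predictor (zero population mean by construction)."""
    m_unit = np.asarray(marginals_per_iqr) / np.asarray(params.metric_iqrs)
    beta = marginal_to_structural(m_unit, params.metric_cov)
    lp = latent_c @ beta
    e_boy = 1.0 - params.girl_frac
    centers = {"boy": e_boy, "age": params.age_mean,
               "passive_smoking": params.passive_smoking_frac,
               "low_occupation": params.low_occupation_frac}
    cols = {"boy": covars["boy"], "age": covars["age"],
            "passive_smoking": covars["passive_smoking"],
            "low_occupation": covars["low_occupation"]}
    for key, eff in cov_effects.items():
        lp = lp + eff * (cols[key].to_numpy(dtype=float) - centers[key])
    return lp


BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """One record per child x examination, with per-eye and eye-averaged
    retinal metrics, SDQ scores, cognitive latencies and covariates.

    Measured metrics are child latent value + examination noise, generated
    per eye with SD ``sqrt(2) * within_exam_sd`` so the two-eye average has
    the configured within-examination SD. Outcomes are generated from the
    child *latent* metrics (biology, not measurement), so downstream
    regressions on averaged measured metrics see realistic attenuation.
    """
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_children

    sex = np.where(rng.uniform(size=n) < params.girl_frac, "girl", "boy")
    age = rng.normal(params.age_mean, params.age_sd, n)
    bmi = rng.choice(BMI_CATEGORIES, size=n, p=params.bmi_probs)
    map_mmhg = rng.normal(params.map_mean, params.map_sd, n)
    smoke = (rng.uniform(size=n) < params.passive_smoking_frac).astype(int)
    lowocc = (rng.uniform(size=n) < params.low_occupation_frac).astype(int)
    n_exams = rng.choice([1, 2, 3], size=n, p=params.exam_count_probs)

    latent = rng.multivariate_normal(np.asarray(params.metric_means), params.metric_cov, size=n)
    latent_c = latent - np.asarray(params.metric_means)

    covars = pd.DataFrame({
        "boy": (sex == "boy").astype(int),
        "age": age,
        "passive_smoking": smoke,
        "low_occupation": lowocc,
    })

    # --- child-level outcomes -------------------------------------------
    sdq = {}
    for name, base_mean, m_iqr, cov_eff in params.sdq_effects:
        lp = _linear_predictor(np.asarray(m_iqr), dict(cov_eff), params, latent_c, covars)
        raw = base_mean + lp + rng.normal(0.0, params.sdq_noise_sd, n)
        sdq[name] = np.clip(np.rint(raw), 0, params.sdq_clip_max).astype(int)
    sdq_total = sum(sdq.values())

    cognitive_child = {}
    for name, op in params.outcomes:
        lp = _linear_predictor(np.asarray(op.metric_effects_per_iqr),
                               dict(op.covariate_effects), params, latent_c, covars)
        cognitive_child[name] = op.mean + lp + rng.normal(0.0, op.child_sd, n)

    # --- examination-level rows -----------------------------------------
    within = params.within_exam_sds
    eye_sd = within * math.sqrt(2.0)
    rows = []
    outcome_names = [name for name, _ in params.outcomes]
    outcome_by_name = dict(params.outcomes)
    for i in range(n):
        for e in range(int(n_exams[i])):
            rec = {
                "child_id": i,
                "exam": e + 1,
                "n_exams": int(n_exams[i]),
                "sex": sex[i],
                "age": age[i] + e * params.exam_interval_years,
                "bmi_category": bmi[i],
                "map_mmhg": map_mmhg[i],
                "passive_smoking": int(smoke[i]),
                "low_maternal_occupation": int(lowocc[i]),
            }
            for j, met in enumerate(METRICS):
                left = latent[i, j] + rng.normal(0.0, eye_sd[j])
                right = latent[i, j] + rng.normal(0.0, eye_sd[j])
                rec[f"{met}_left"] = left
                rec[f"{met}_right"] = right
                rec[met] = 0.5 * (left + right)
            for name in SDQ_SUBSCALES:
                rec[f"sdq_{name}"] = int(sdq[name][i])
            rec["sdq_total"] = int(sdq_total[i])
            for name in outcome_names:
                op = outcome_by_name[name]
                val = cognitive_child[name][i] + rng.normal(0.0, op.exam_sd)
                rec[name] = max(val, 0.01)  # latencies are strictly positive
            rows.append(rec)
    return pd.DataFrame(rows)


def simulate_repeats(
    child_values: np.ndarray,
    within_sd: float,
    n_exams: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-examination measurements around child latent values.

    Returns a long table (child_id, exam, value) with
    ``value = latent + Normal(0, within_sd^2)``.
    """
    if within_sd < 0:
        raise ValueError("within_sd must be >= 0")
    child_values = np.asarray(child_values, dtype=float)
    n_exams = np.asarray(n_exams, dtype=int)
    if len(child_values) != len(n_exams):
        raise ValueError("child_values and n_exams must align")
    rng = np.random.default_rng(seed)
    cid = np.repeat(np.arange(len(child_values)), n_exams)
    exam = np.concatenate([np.arange(1, k + 1) for k in n_exams]) if len(n_exams) else np.array([])
    vals = child_values[cid] + rng.normal(0.0, within_sd, size=len(cid))
    return pd.DataFrame({"child_id": cid, "exam": exam, "value": vals})


def default_repeat_study(
    params: CohortParams | None = None,
    metric: str = "df",
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated examinations of one metric under the default visit mix."""
    if params is None:
        params = CohortParams()
    j = METRICS.index(metric)
    rng = np.random.default_rng(seed)
    latents = rng.normal(params.metric_means[j], params.metric_sds[j], params.n_children)
    n_exams = rng.choice([1, 2, 3], size=params.n_children, p=params.exam_count_probs)
    # derive the repeat-noise seed from the same stream for full determinism
    sub_seed = int(rng.integers(0, 2**31 - 1))
    return simulate_repeats(latents, float(params.within_exam_sds[j]), n_exams, seed=sub_seed)
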