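"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end without any image download:

* :func:`simulate_mlm_dataset` draws from the two-level generative model
  (random plant intercepts, optional random slope on one covariate,
  Gaussian sampling noise) that the mixed-model engine fits, returning the
  latent truths alongside for parameter-recovery testing.  Defaults mirror
  the study design (12 plants x 3 root regions x 3 replicates) and the
  fitted percent-colonization fixed effects and variance components.

* :func:`simulate_instance_tables` emulates per-slide instance-segmentation
  output: correlated class counts via a Gaussian copula over Poisson
  margins (extraradical hyphae co-occur with arbuscules; vesicles and
  spores are positively correlated; vesicle/spore-rich slides carry smaller
  arbuscules), log-normal instance sizes, one root instance consuming the
  root pixel budget, and per-class confidence scores.  Region effects push
  arbuscule/extraradical-hypha counts and arbuscule size TOP > MID > BOT.

* :func:`simulate_mask_pairs` builds (truth, prediction) mask fixtures on a
  disjoint grid of geometric shapes with independent TP/FP/FN bookkeeping.

Every generator is a pure function of its parameters and seed.  The
instance-table defaults are order-of-magnitude choices that land total
percent colonization near the observed population mean; they are synthetic
conventions, not estimates of any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seg_eval import MaskInstance

__all__ = [
    "SimParams",
    "InstanceSimParams",
    "simulate_mlm_dataset",
    "simulate_instance_tables",
    "simulate_mask_pairs",
]

REGIONS = ("TOP", "MID", "BOT")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-level generative model.

    Fixed-effect defaults are the fitted percent-colonization model with a
    random slope on scaled arbuscule count: population intercept 0.3410
    (the MID-region mean), region offsets 0.0226 (TOP) and -0.0087 (BOT),
    and coefficients 0.0937 / 0.0304 on scaled arbuscule count / size.
    Variance defaults: between-plant intercept 0.0009, residual 0.0007;
    slope variance 0.0004 (a synthetic-only choice making VPC visibly
    increase with arbuscule count), zero intercept-slope covariance.
    """

    n_plants: int = 12
    n_replicates: int = 3
    regions: tuple[str, ...] = REGIONS
    beta0: float = 0.3410
    beta_region: tuple[float, float] = (0.0226, -0.0087)  # (TOP, BOT) vs MID
    betas: tuple[tuple[str, float], ...] = (
        ("arb_count_scaled", 0.0937),
        ("arb_size_scaled", 0.0304),
    )
    var_u0: float = 0.0009
    var_u1: float = 0.0004
    cov_u0u1: float = 0.0
    var_resid: float = 0.0007
    slope_covariate: str | None = "arb_count_scaled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 2 or self.n_replicates < 1:
            raise ValueError("need n_plants >= 2 and n_replicates >= 1")
        if min(self.var_u0, self.var_u1, self.var_resid) < 0:
            raise ValueError("variances must be non-negative")
        if self.cov_u0u1**2 > self.var_u0 * self.var_u1:
            raise ValueError("intercept-slope covariance violates positive-definiteness")
        if self.slope_covariate is not None and self.slope_covariate not in dict(self.betas):
            raise ValueError("slope covariate must be one of the fixed-effect covariates")


def simulate_mlm_dataset(p: SimParams) -> tuple[pd.DataFrame, dict]:
    """Draw one design table from the two-level model; return latent truths.

    The table has one row per (plant, region, replicate): grouping columns,
    iid standard-normal covariates, and the response ``y`` assembled as
    fixed effects + plant intercept (+ plant slope x covariate) + noise.
    Output is byte-identical for identical parameters and seed.
    """
    rng = np.random.default_rng(p.seed)
    n_obs = p.n_plants * len(p.regions) * p.n_replicates
    plants = [f"P{i:03d}" for i in range(1, p.n_plants + 1)]

    rows = {
        "plant": np.repeat(plants, len(p.regions) * p.n_replicates),
        "region": np.tile(np.repeat(p.regions, p.n_replicates), p.n_plants),
        "replicate": np.tile(np.arange(1, p.n_replicates + 1), p.n_plants * len(p.regions)),
    }
    df = pd.DataFrame(rows)
    df["slide_id"] = df["plant"] + "_" + df["region"] + "_r" + df["replicate"].astype(str)

    cov = np.array([[p.var_u0, p.cov_u0u1], [p.cov_u0u1, p.var_u1]])
    # cholesky-free draw that tolerates zero variances
    evals, evecs = np.linalg.eigh(cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    u = rng.standard_normal((p.n_plants, 2)) @ root.T
    u0, u1 = u[:, 0], u[:, 1]

    beta_top, beta_bot = p.beta_region
    eta = np.full(n_obs, p.beta0)
    eta += np.where(df["region"] == "TOP", beta_top, 0.0)
    eta += np.where(df["region"] == "BOT", beta_bot, 0.0)
    for name, beta in p.betas:
        df[name] = rng.standard_normal(n_obs)
        eta += beta * df[name].to_numpy()

    plant_idx = df["plant"].map({pl: i for i, pl in enumerate(plants)}).to_numpy()
    y = eta + u0[plant_idx]
    if p.slope_covariate is not None:
        y = y + u1[plant_idx] * df[p.slope_covariate].to_numpy()
    eps = rng.normal(0.0, math.sqrt(p.var_resid), n_obs) if p.var_resid > 0 else np.zeros(n_obs)
    df["y"] = y + eps

    truths = {
        "u0": pd.Series(u0, index=plants),
        "u1": pd.Series(u1, index=plants),
        "beta0": p.beta0,
        "beta_region": {"TOP": beta_top, "BOT": beta_bot},
        "betas": dict(p.betas),
        "var_u0": p.var_u0,
        "var_u1": p.var_u1 if p.slope_covariate is not None else 0.0,
        "cov_u0u1": p.cov_u0u1 if p.slope_covariate is not None else 0.0,
        "var_resid": p.var_resid,
    }
    return df, truths


# ---------------------------------------------------------------------------
# instance tables


@dataclass(frozen=True)
class InstanceSimParams:
    """Parameters of the per-slide instance generator.

    Mean counts and log-normal size medians are per-slide, per-class.
    ``correlations`` lists latent Gaussian-copula correlations between
    count dimensions (and the arbuscule-size factor, dimension ``arb_size``).
    Region multipliers implement the TOP > MID > BOT pattern on
    arbuscule/extraradical-hypha counts and arbuscule size.

    Three log-normal per-plant multipliers create the between-plant
    hierarchy the mixed models partition: an overall colonization
    multiplier on every AMF class count (``plant_colonization_sigma``), an
    allocation tilt that raises nutrient-exchange structures (arbuscules,
    extraradical hyphae) while lowering the others — giving PNE its
    plant-level variance (``plant_allocation_sigma``) — and an arbuscule
    size multiplier (``plant_size_sigma``).
    """

    mean_counts: tuple[tuple[str, float], ...] = (
        ("arb", 40.0),
        ("exH", 25.0),
        ("inH", 15.0),
        ("ves", 10.0),
        ("sp", 6.0),
    )
    size_medians: tuple[tuple[str, float], ...] = (
        ("arb", 3000.0),
        ("exH", 4000.0),
        ("inH", 2500.0),
        ("ves", 2000.0),
        ("sp", 1500.0),
    )
    size_sigma: float = 0.4
    root_pixel_budget: float = 7.0e5
    plant_colonization_sigma: float = 0.35
    plant_allocation_sigma: float = 0.25
    plant_size_sigma: float = 0.15
    correlations: tuple[tuple[str, str, float], ...] = (
        ("arb", "exH", 0.5),
        ("ves", "sp", 0.4),
        ("ves", "arb_size", -0.3),
        ("sp", "arb_size", -0.3),
    )
    region_count_factor: tuple[tuple[str, float], ...] = (("TOP", 1.3), ("MID", 1.0), ("BOT", 0.75))
    region_size_factor: tuple[tuple[str, float], ...] = (("TOP", 1.2), ("MID", 1.0), ("BOT", 0.85))
    confidence_beta: tuple[tuple[str, tuple[float, float]], ...] = (
        ("arb", (4.5, 2.2)),
        ("exH", (10.0, 2.0)),
        ("inH", (6.0, 2.5)),
        ("ves", (8.0, 2.0)),
        ("sp", (8.0, 2.0)),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for _, m in self.mean_counts):
            raise ValueError("mean counts must be non-negative")
        if any(not -1.0 < r < 1.0 for _, _, r in self.correlations):
            raise ValueError("correlation targets must lie in (-1, 1)")

    def latent_correlation(self) -> tuple[list[str], np.ndarray]:
        dims = [c for c, _ in self.mean_counts] + ["arb_size"]
        R = np.eye(len(dims))
        for a, b, r in self.correlations:
            i, j = dims.index(a), dims.index(b)
            R[i, j] = R[j, i] = r
        evals = np.linalg.eigvalsh(R)
        if evals.min() < 1e-9:
            clipped = np.clip(evals, 1e-6, None)
            raise ValueError(
                "correlation targets form an infeasible matrix "
                f"(min eigenvalue {evals.min():.3g}); nearest feasible spectrum {np.round(clipped, 4)}"
            )
        return dims, R


def simulate_instance_tables(p: InstanceSimParams, design: pd.DataFrame) -> pd.DataFrame:
    """Simulate an instance-record table for every slide in ``design``.

    ``design`` needs columns ``slide_id`` and ``region``.  Per slide, class
    counts come from a Gaussian copula over Poisson margins, instance sizes
    are log-normal (the arbuscule size median shifted by the latent size
    factor, giving the negative vesicle/spore-count vs arbuscule-size
    correlation), and one root instance consumes the root pixel budget.
    Root confidences are drawn in [0.75, 1] so root denominators always
    survive the 0.7 confidence filter.
    """
    for col in ("slide_id", "region"):
        if col not in design.columns:
            raise ValueError(f"design table lacks column {col!r}")
    dims, R = p.latent_correlation()
    chol = np.linalg.cholesky(R)
    rng = np.random.default_rng(p.seed)
    mean_counts = dict(p.mean_counts)
    size_medians = dict(p.size_medians)
    count_factor = dict(p.region_count_factor)
    size_factor = dict(p.region_size_factor)
    conf_beta = dict(p.confidence_beta)
    classes = [c for c, _ in p.mean_counts]

    plants = design["plant"] if "plant" in design.columns else design["slide_id"]
    plant_effects: dict = {}
    for pl in pd.unique(plants):
        plant_effects[pl] = {
            "colonization": rng.lognormal(0.0, p.plant_colonization_sigma),
            "allocation": rng.normal(0.0, p.plant_allocation_sigma),
            "arb_size": rng.lognormal(0.0, p.plant_size_sigma),
        }

    records: list[dict] = []
    for slide_id, region, plant in zip(design["slide_id"], design["region"], plants):
        eff = plant_effects[plant]
        z = chol @ rng.standard_normal(len(dims))
        uni = stats.norm.cdf(z)
        image_id = f"{slide_id}_im1"
        root_px = max(1.0, p.root_pixel_budget * rng.lognormal(0.0, 0.1))
        records.append(
            {
                "image_id": image_id,
                "slide_id": slide_id,
                "class_label": "root",
                "pixel_area": round(root_px),
                "confidence": 0.75 + 0.25 * rng.beta(5.0, 1.5),
            }
        )
        for k, cls in enumerate(classes):
            mu = mean_counts[cls] * eff["colonization"]
            mu *= math.exp(eff["allocation"] if cls in ("arb", "exH") else -eff["allocation"])
            if cls in ("arb", "exH"):
                mu *= count_factor.get(region, 1.0)
            if mu <= 0:
                continue
            n = int(stats.poisson.ppf(uni[k], mu))
            if n <= 0:
                continue
            med = size_medians[cls]
            if cls == "arb":
                med *= size_factor.get(region, 1.0) * eff["arb_size"]
                # latent size factor links arbuscule size to vesicle/spore counts
                med *= math.exp(0.3 * z[dims.index("arb_size")])
            sizes = np.maximum(1.0, rng.lognormal(math.log(med), p.size_sigma, n))
            a, b = conf_beta[cls]
            confs = rng.beta(a, b, n)
            for s, c in zip(sizes, confs):
                records.append(
                    {
                        "image_id": image_id,
                        "slide_id": slide_id,
                        "class_label": cls,
                        "pixel_area": round(float(s)),
                        "confidence": float(c),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# mask pairs


@dataclass
class MaskPairBookkeeping:
    """Per-prediction provenance: matched truth index (or None) and its IoU."""

    n_truths: int
    entries: list[tuple[int | None, float]] = field(default_factory=list)

    def expected_counts(self, iou_threshold: float) -> tuple[int, int, int]:
        """(TP, FP, FN) implied by construction at one IoU threshold.

        Valid because shapes occupy disjoint grid cells (at most one
        candidate truth per prediction), making greedy matching trivial.
        """
        tp = sum(1 for t, iou in self.entries if t is not None and iou >= iou_threshold)
        fp = len(self.entries) - tp
        fn = self.n_truths - tp
        return tp, fp, fn


def _cell_shape(rng: np.random.Generator, x0: int, y0: int, inner: int) -> frozenset:
    """A random rectangle, ellipse or thin filament inside one grid cell."""
    kind = rng.choice(["rect", "ellipse", "filament"])
    if kind == "rect":
        w, h = rng.integers(8, inner // 2, 2)
        ox, oy = rng.integers(0, inner - w), rng.integers(0, inner - h)
        xs, ys = np.meshgrid(np.arange(w), np.arange(h))
        pts = np.column_stack([xs.ravel() + x0 + ox, ys.ravel() + y0 + oy])
    elif kind == "ellipse":
        a, b = rng.integers(5, inner // 4, 2)
        cx, cy = rng.integers(a, inner - a), rng.integers(b, inner - b)
        xs, ys = np.meshgrid(np.arange(inner), np.arange(inner))
        mask = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
        pts = np.column_stack([xs[mask] + x0, ys[mask] + y0])
    else:  # thin diagonal filament, emulating a hypha fragment
        width = int(rng.integers(2, 4))
        t = np.arange(inner - 2)
        pts = []
        for off in range(width):
            pts.append(np.column_stack([t + x0 + 1, np.clip(t + off, 0, inner - 1) + y0]))
        pts = np.vstack(pts)
    return frozenset((int(x), int(y)) for x, y in np.asarray(pts, dtype=int))


def simulate_mask_pairs(
    n_cases: int,
    jitter: int = 2,
    drop_rate: float = 0.1,
    spurious_rate: float = 0.15,
    seed: int = 0,
    classes: Sequence[str] = ("arb", "exH", "ves", "sp"),
) -> tuple[list[MaskInstance], list[MaskInstance], list[MaskPairBookkeeping]]:
    """Generate (truth, prediction) mask lists with known matching bookkeeping.

    Each case is one image holding several shapes on a coarse grid whose
    cells are wide enough that a prediction jittered by up to ``jitter``
    pixels can only overlap its own truth.  Predictions are integer-jittered
    copies (dropped with ``drop_rate``); spurious predictions appear in
    otherwise-empty cells with ``spurious_rate``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cell = 48
    margin = max(2 * jitter + 1, 4)
    inner = cell - 2 * margin
    grid = 3  # 3x3 cells per image
    truths: list[MaskInstance] = []
    preds: list[MaskInstance] = []
    books: list[MaskPairBookkeeping] = []
    for case in range(n_cases):
        image_id = f"case{case:04d}"
        case_truths: list[MaskInstance] = []
        entries: list[tuple[int | None, float]] = []
        for cy in range(grid):
            for cx in range(grid):
                x0, y0 = cx * cell + margin, cy * cell + margin
                occupied = rng.random() < 0.7
                cls = str(rng.choice(classes))
                if occupied:
                    pixels = _cell_shape(rng, x0, y0, inner)
                    t = MaskInstance(image_id, cls, pixels, 1.0)
                    case_truths.append(t)
                    if rng.random() >= drop_rate:
                        dx, dy = rng.integers(-jitter, jitter + 1, 2)
                        moved = frozenset((x + int(dx), y + int(dy)) for x, y in pixels)
                        pr = MaskInstance(image_id, cls, moved, float(rng.uniform(0.5, 1.0)))
                        iou = len(pixels & moved) / len(pixels | moved)
                        preds.append(pr)
                        entries.append((len(case_truths) - 1, iou))
                elif rng.random() < spurious_rate:
                    pixels = _cell_shape(rng, x0, y0, inner)
                    preds.append(MaskInstance(image_id, cls, pixels, float(rng.uniform(0.5, 1.0))))
                    entries.append((None, 0.0))
        truths.extend(case_truths)
        books.append(MaskPairBookkeeping(n_truths=len(case_truths), entries=entries))
    return truths, preds, books
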