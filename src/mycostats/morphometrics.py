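"""Slide-level colonization statistics from instance-segmentation records.

Each segmented object in a root image is one record: class label, pixel
area, confidence score.  Per slide (the unit carrying the plant / root
region / replicate structure) three class-level statistics are derived for
each AM fungal structure class:

* count density  = instance count / root pixels   (count per root pixel)
* average size   = class pixels / instance count  (pixels per instance)
* percent colonization = class pixels / root pixels

plus their totals over the AMF classes and the proportion of
nutrient-exchange structures (PNE): (arbuscule + extraradical hypha counts)
divided by all AMF structure counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_geometry import CANONICAL_CLASSES

__all__ = [
    "AMF_CLASSES",
    "NUTRIENT_EXCHANGE_CLASSES",
    "InstanceRecord",
    "SlidePhenotypes",
    "aggregate_slide",
    "aggregate_slides",
    "proportion_nutrient_exchange",
    "pne_from_counts",
    "transform",
    "correlation_panel",
    "read_instance_table",
    "phenotype_frame",
]

#: The five AM fungal structure classes ("other" and "root" excluded).
AMF_CLASSES = ("arb", "exH", "inH", "ves", "sp")
#: Structures mediating nutrient exchange (PNE numerator).
NUTRIENT_EXCHANGE_CLASSES = ("arb", "exH")


@dataclass(frozen=True)
class InstanceRecord:
    """One segmented object in one image."""

    image_id: str
    slide_id: str
    class_label: str
    pixel_area: float
    confidence: float

    def __post_init__(self) -> None:
        if self.class_label not in CANONICAL_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.pixel_area < 1:
            raise ValueError("pixel_area must be >= 1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class SlidePhenotypes:
    """Class-level colonization statistics for one slide.

    ``avg_size`` entries are NaN for classes with zero surviving instances;
    ``pne`` is NaN when no AMF structure survives filtering.
    """

    slide_id: str
    root_pixels: float
    count: dict[str, int] = field(default_factory=dict)
    pixels: dict[str, float] = field(default_factory=dict)
    count_density: dict[str, float] = field(default_factory=dict)
    avg_size: dict[str, float] = field(default_factory=dict)
    pct_colonization: dict[str, float] = field(default_factory=dict)
    total_pct_colonization: float = 0.0
    total_count_density: float = 0.0
    pne: float = math.nan


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"slide_id", "class_label", "pixel_area", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"instance records lack columns: {sorted(missing)}")
    return df


def aggregate_slide(
    records: Sequence[InstanceRecord] | pd.DataFrame,
    conf_threshold: float = 0.7,
    amf_classes: Sequence[str] = AMF_CLASSES,
    pne_classes: Sequence[str] = NUTRIENT_EXCHANGE_CLASSES,
) -> SlidePhenotypes:
    """Aggregate one slide's instance records into colonization phenotypes.

    Records below ``conf_threshold`` are excluded before any statistic is
    computed.  The denominator for density and percent colonization sums all
    root-class pixels on the slide.  ``amf_classes`` controls which classes
    enter the totals and the PNE denominator ("other" never does).
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no instance records supplied")
    slide_ids = df["slide_id"].unique()
    if len(slide_ids) != 1:
        raise ValueError(f"records span multiple slides: {sorted(slide_ids)}")
    df = df[df["confidence"] >= conf_threshold]
    root_pixels = float(df.loc[df["class_label"] == "root", "pixel_area"].sum())
    if root_pixels <= 0:
        raise ValueError(f"slide {slide_ids[0]!r}: no root pixels after filtering; phenotypes undefined")

    pheno = SlidePhenotypes(slide_id=str(slide_ids[0]), root_pixels=root_pixels)
    grouped = df.groupby("class_label")["pixel_area"].agg(["count", "sum"])
    for cls in CANONICAL_CLASSES:
        n = int(grouped["count"].get(cls, 0))
        px = float(grouped["sum"].get(cls, 0.0))
        pheno.count[cls] = n
        pheno.pixels[cls] = px
        if cls == "root":
            continue
        pheno.count_density[cls] = n / root_pixels
        pheno.pct_colonization[cls] = px / root_pixels
        pheno.avg_size[cls] = px / n if n > 0 else math.nan
    pheno.total_count_density = sum(pheno.count_density[c] for c in amf_classes)
    pheno.total_pct_colonization = sum(pheno.pct_colonization[c] for c in amf_classes)
    pheno.pne = pne_from_counts(pheno.count, amf_classes=amf_classes, pne_classes=pne_classes)
    return pheno


def pne_from_counts(
    counts: dict[str, int],
    amf_classes: Sequence[str] = AMF_CLASSES,
    pne_classes: Sequence[str] = NUTRIENT_EXCHANGE_CLASSES,
) -> float:
    """PNE from raw class counts; NaN when no AMF structure is present."""
    total = sum(counts.get(c, 0) for c in amf_classes)
    if total == 0:
        warnings.warn("no AMF structures: PNE undefined", stacklevel=2)
        return math.nan
    return sum(counts.get(c, 0) for c in pne_classes) / total


def proportion_nutrient_exchange(pheno: SlidePhenotypes) -> float:
    """Proportion of nutrient-exchange structures among all AMF structures."""
    return pne_from_counts(pheno.count)


def aggregate_slides(
    records: pd.DataFrame,
    conf_threshold: float = 0.7,
    amf_classes: Sequence[str] = AMF_CLASSES,
) -> pd.DataFrame:
    """Per-slide phenotype table over many slides (one row per slide).

    Columns: ``count_<cls>``, ``size_<cls>``, ``density_<cls>``,
    ``pct_<cls>`` per AMF class, plus ``root_pixels``,
    ``total_pct_colonization``, ``total_count_density`` and ``pne``.
    """
    df = _records_frame(records)
    rows = []
    for slide_id, sub in df.groupby("slide_id", sort=True):
        p = aggregate_slide(sub, conf_threshold=conf_threshold, amf_classes=amf_classes)
        row: dict[str, float] = {"slide_id": slide_id, "root_pixels": p.root_pixels}
        for cls in AMF_CLASSES:
            row[f"count_{cls}"] = p.count[cls]
            row[f"size_{cls}"] = p.avg_size[cls]
            row[f"density_{cls}"] = p.count_density[cls]
            row[f"pct_{cls}"] = p.pct_colonization[cls]
        row["total_pct_colonization"] = p.total_pct_colonization
        row["total_count_density"] = p.total_count_density
        row["pne"] = p.pne
        rows.append(row)
    return pd.DataFrame(rows).set_index("slide_id")


phenotype_frame = aggregate_slides  # convenience alias


def transform(
    values, kind: Literal["logit", "arcsine_sqrt", "identity"] = "identity", eps: float = 0.0
) -> np.ndarray:
    """Vectorized response transformations for proportion phenotypes.

    ``logit(p) = ln((p + eps) / (1 - p + eps))``; ``arcsine_sqrt(p) =
    asin(sqrt(p))``.  ``eps`` defaults to 0: callers must pre-clip exact
    0/1 values rather than rely on silent smoothing.
    """
    x = np.asarray(values, dtype=float)
    if kind == "identity":
        return x.copy()
    bad = np.where((x < 0) | (x > 1))[0]
    if bad.size:
        raise ValueError(f"values outside [0, 1] at indices {bad.tolist()}")
    if kind == "logit":
        return np.log((x + eps) / (1.0 - x + eps))
    if kind == "arcsine_sqrt":
        return np.arcsin(np.sqrt(x))
    raise ValueError(f"unknown transform {kind!r}")


def _pairwise_corr(df_x: pd.DataFrame, df_y: pd.DataFrame, method: str):
    """Pairwise-complete correlation + p-value matrices between two frames."""
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = pd.DataFrame(index=df_x.columns, columns=df_y.columns, dtype=float)
    p = r.copy()
    for cx in df_x.columns:
        for cy in df_y.columns:
            pair = pd.concat([df_x[cx], df_y[cy]], axis=1).dropna()
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
                r.loc[cx, cy] = np.nan
                p.loc[cx, cy] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fn(a, b)
            r.loc[cx, cy] = res.statistic if hasattr(res, "statistic") else res[0]
            p.loc[cx, cy] = res.pvalue if hasattr(res, "pvalue") else res[1]
    return r, p


def correlation_panel(
    phenos: pd.DataFrame | Iterable[SlidePhenotypes],
    method: Literal["pearson", "spearman"] = "pearson",
    classes: Sequence[str] = AMF_CLASSES,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """The three structure-trait correlation panels with p-values.

    Returns ``{"count_count": (r, p), "size_size": (r, p),
    "count_size": (r, p)}``; in the mixed panel counts index the rows and
    sizes the columns.  Slides with undefined sizes are handled
    pairwise-complete; constant columns yield NaN entries.
    """
    if not isinstance(phenos, pd.DataFrame):
        phenos = aggregate_slides_from_objects(list(phenos))
    if len(phenos) < 3:
        raise ValueError("need at least 3 slides for correlations")
    counts = phenos[[f"count_{c}" for c in classes]]
    sizes = phenos[[f"size_{c}" for c in classes]]
    return {
        "count_count": _pairwise_corr(counts, counts, method),
        "size_size": _pairwise_corr(sizes, sizes, method),
        "count_size": _pairwise_corr(counts, sizes, method),
    }


def aggregate_slides_from_objects(phenos: Sequence[SlidePhenotypes]) -> pd.DataFrame:
    """Tabulate already-aggregated :class:`SlidePhenotypes` objects."""
    rows = []
    for p in phenos:
        row: dict[str, float] = {"slide_id": p.slide_id, "root_pixels": p.root_pixels}
        for cls in AMF_CLASSES:
            row[f"count_{cls}"] = p.count.get(cls, 0)
            row[f"size_{cls}"] = p.avg_size.get(cls, math.nan)
            row[f"density_{cls}"] = p.count_density.get(cls, math.nan)
            row[f"pct_{cls}"] = p.pct_colonization.get(cls, math.nan)
        row["total_pct_colonization"] = p.total_pct_colonization
        row["total_count_density"] = p.total_count_density
        row["pne"] = p.pne
        rows.append(row)
    return pd.DataFrame(rows).set_index("slide_id")


def read_instance_table(path: str | Path) -> pd.DataFrame:
    """Read an instance table from tab- or comma-delimited text."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df["class_label"] = df["class_label"].map(
        lambda v: v if v in CANONICAL_CLASSES else _normalize(v)
    )
    return df


def _normalize(v):
    from .annotation_geometry import normalize_class_label

    return normalize_class_label(v)
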