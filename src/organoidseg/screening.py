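"""Drug-screening quantification: from masks to per-organoid area tables.

Each connected foreground region of a segmentation mask is treated as one
organoid (touching organoids merge into one component — splitting adhering
organoids is deliberately out of scope).  Areas are reported in pixels and
in um^2, grouped by treatment arm and culture day, and summarised by
median and quartiles (linear-interpolation, "type 7") for violin-style
visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class OrganoidRecord:
    source_id: str
    organoid_id: int
    area_pixels: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    culture_day: int
    group_label: str


@dataclass
class GroupSummary:
    group_label: str
    culture_day: int
    n_organoids: int
    median_area: float
    q1_area: float
    q3_area: float
    total_area: float


# ---------------------------------------------------------------------------
# component labeling and measurement
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}

DEFAULT_MIN_SIZE = 30  # px; suppresses speckle at 256x256 tile scale


def label_components(mask: np.ndarray, connectivity: int = 8,
                     min_size: int = DEFAULT_MIN_SIZE) -> tuple[np.ndarray, int]:
    """Label maximal connected foreground regions; drop tiny ones.

    Returns (labeled map with consecutive positive labels, count).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return labeled, 0
    counts = np.bincount(labeled.ravel())
    keep = np.flatnonzero(counts >= max(min_size, 1))
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=labeled.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labeled], int(len(keep))


def measure_organoids(labeled: np.ndarray, meta: dict) -> list[OrganoidRecord]:
    """One record per label: exact pixel area, centroid, metadata copy."""
    for key in ("source_id", "culture_day", "group_label"):
        if key not in meta:
            raise KeyError(f"metadata for {meta.get('source_id', '?')!r} lacks {key!r}")
    px = float(meta.get("pixel_size_um", 1.0))
    if px <= 0:
        raise ValueError("pixel_size_um must be positive")
    n = int(labeled.max())
    records = []
    if n == 0:
        return records
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    cents = ndimage.center_of_mass(np.ones_like(labeled), labeled, index=range(1, n + 1))
    for i, (area, cent) in enumerate(zip(areas, cents), start=1):
        records.append(
            OrganoidRecord(
                source_id=str(meta["source_id"]),
                organoid_id=i,
                area_pixels=int(area),
                area_um2=float(area) * px * px,
                centroid=(float(cent[0]), float(cent[1])),
                culture_day=int(meta["culture_day"]),
                group_label=str(meta["group_label"]),
            )
        )
    return records


def quantify_masks(samples, connectivity: int = 8,
                   min_size: int = DEFAULT_MIN_SIZE) -> list[OrganoidRecord]:
    """Run labeling + measurement over (mask, meta) pairs or AnnotatedImages."""
    records = []
    for s in samples:
        mask, meta = (s.mask, s.meta) if hasattr(s, "mask") else s
        labeled, _ = label_components(mask, connectivity, min_size)
        records.extend(measure_organoids(labeled, meta))
    return records


# ---------------------------------------------------------------------------
# summaries and export
# ---------------------------------------------------------------------------


def records_frame(records: list[OrganoidRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    if not df.empty:
        df[["centroid_row", "centroid_col"]] = pd.DataFrame(
            df.pop("centroid").tolist(), index=df.index
        )
    return df


def summarize_groups(records: list[OrganoidRecord]) -> list[GroupSummary]:
    """Median/quartile area summaries per (group_label, culture_day).

    Quantiles use linear interpolation (numpy default, "type 7"); empty
    groups are omitted (they cannot arise from records, but a warning is
    kept for symmetry with file-driven pipelines).
    """
    if not records:
        warnings.warn("no organoid records to summarize")
        return []
    df = records_frame(records)
    out = []
    for (group, day), sub in df.groupby(["group_label", "culture_day"], sort=True):
        areas = sub["area_um2"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(areas, [0.25, 0.5, 0.75])
        out.append(
            GroupSummary(
                group_label=str(group), culture_day=int(day), n_organoids=len(areas),
                median_area=float(med), q1_area=float(q1), q3_area=float(q3),
                total_area=float(areas.sum()),
            )
        )
    return out


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


VIOLIN_COLUMNS = ["group_label", "culture_day", "source_id", "organoid_id", "area_um2"]


def export_violin_data(records: list[OrganoidRecord], path) -> None:
    """Long-format CSV with one row per organoid, ready for violin plots."""
    if not records:
        raise ValueError("no records to export")
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    df = records_frame(records)[VIOLIN_COLUMNS]
    df.to_csv(path, index=False)


def plot_violins(records: list[OrganoidRecord], path) -> None:
    """Convenience rendering of per-group/day area violins (not a contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_frame(records)
    days = sorted(df["culture_day"].unique())
    groups = sorted(df["group_label"].unique())
    fig, axes = plt.subplots(1, len(days), figsize=(3.2 * len(days), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, day in zip(axes, days):
        sub = df[df["culture_day"] == day]
        series = [sub[sub["group_label"] == g]["area_um2"].to_numpy() for g in groups]
        series = [s if len(s) else np.array([np.nan]) for s in series]
        ax.violinplot(series, showmedians=True)
        ax.set_xticks(range(1, len(groups) + 1), groups)
        ax.set_title(f"day {day}")
    axes[0].set_ylabel("organoid area (um$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
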