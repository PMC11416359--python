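"""Statistical comparison of paired US and histology measurements.

The analysis mirrors a standard modality-agreement workflow: a
Shapiro-Wilk normality gate selects Pearson (normal) or Spearman
(otherwise) correlation, agreement is summarized by Bland-Altman mean
difference and 95% limits of agreement (d +/- 1.96 SD), and everything
is reported per region (TT, caudal, deep, cranial, anterior, posterior)
and pooled. Differences are always taken as US - histology; the sign
convention is stated in every rendered output.

A sensitivity re-analysis excluding chosen specimens is built in
(specimens handled atypically — e.g. pinned out before fixation — can
dominate the pooled statistics).

Caveat, replicated deliberately: multiple slices per specimen are pooled
into one correlation without any clustering correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ALL_MEASURES, END_MEASURES, PER_SLICE_MEASURES, MeasurementRecord

__all__ = [
    "PairedMeasurements",
    "RegionStats",
    "AgreementReport",
    "pair_records",
    "concat_pairs",
    "correlation",
    "bland_altman",
    "estimate_shrinkage",
    "build_report",
    "sensitivity_exclude",
    "render_report",
]

REPORT_REGIONS = ("TT", "caudal", "deep", "cranial", "anterior", "posterior")
POOLED = "all"
_ALPHA = 0.05
_LOA_FACTOR = 1.96  # standard 95% limits of agreement


@dataclass
class PairedMeasurements:
    """Aligned (US, histology) value pairs with their labels.

    ``frame`` columns: specimen, slide (nullable), region, us_mm,
    histo_mm, source. Discordant detections — slides where only one
    modality shows tumor — are excluded from the pairs but counted.
    """

    frame: pd.DataFrame
    discordant: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"specimen", "slide", "region", "us_mm", "histo_mm"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"paired frame missing columns {sorted(missing)}")
        if self.frame[["us_mm", "histo_mm"]].isna().any().any():
            raise ValueError("pairs must be complete (no missing values)")
        bad = set(self.frame["region"]) - set(ALL_MEASURES)
        if bad:
            raise ValueError(f"unknown regions in pairs: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)

    def specimens(self) -> list[str]:
        return sorted(self.frame["specimen"].unique())

    def select(self, region: Optional[str] = None,
               exclude: Sequence[str] = ()) -> pd.DataFrame:
        df = self.frame
        if exclude:
            df = df[~df["specimen"].isin(set(exclude))]
        if region is not None and region != POOLED:
            df = df[df["region"] == region]
        return df

    def values(self, region: Optional[str] = None,
               exclude: Sequence[str] = ()) -> tuple[np.ndarray, np.ndarray]:
        df = self.select(region, exclude)
        return df["us_mm"].to_numpy(float), df["histo_mm"].to_numpy(float)


def pair_records(us: MeasurementRecord, histo: MeasurementRecord) -> PairedMeasurements:
    """Inner-join two modality records of the same specimen."""
    if us.specimen != histo.specimen:
        raise ValueError(
            f"cannot pair different specimens: {us.specimen!r} vs {histo.specimen!r}"
        )
    for rec in (us, histo):
        idx = rec.slide_indices()
        if len(idx) != len(set(idx)):
            raise ValueError(f"duplicate slide entries in {rec.modality} record")

    us_slices = {s.slide: s for s in us.slices}
    histo_slices = {s.slide: s for s in histo.slices}
    shared = sorted(set(us_slices) & set(histo_slices))
    discordant = [
        (us.specimen, k)
        for k in sorted(set(us_slices) ^ set(histo_slices))
    ]

    rows = []
    for k in shared:
        for region in PER_SLICE_MEASURES:
            a = getattr(us_slices[k], region)
            b = getattr(histo_slices[k], region)
            if a is not None and b is not None:
                rows.append((us.specimen, k, region, float(a), float(b)))
    for region in END_MEASURES:
        a = getattr(us, region)
        b = getattr(histo, region)
        if a is not None and b is not None and np.isfinite(a) and np.isfinite(b):
            rows.append((us.specimen, pd.NA, region, float(a), float(b)))

    frame = pd.DataFrame(
        rows, columns=["specimen", "slide", "region", "us_mm", "histo_mm"]
    )
    frame["source"] = us.modality
    return PairedMeasurements(frame=frame, discordant=discordant)


def concat_pairs(parts: Iterable[PairedMeasurements]) -> PairedMeasurements:
    parts = list(parts)
    if not parts:
        raise ValueError("no paired measurements to concatenate")
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    discordant = [d for p in parts for d in p.discordant]
    return PairedMeasurements(frame=frame, discordant=discordant)


# ---------------------------------------------------------------------------
# statistics


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 10)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    count = 0
    total = 0
    batch = []

    def flush(batch_list):
        nonlocal count, total
        if not batch_list:
            return
        arr = np.asarray(batch_list)
        arr = (arr - arr.mean(axis=1, keepdims=True))
        sd = arr.std(axis=1)
        rs = (arr @ rx) / (n * sd)
        count += int(np.sum(np.abs(rs) >= abs(r_obs) - 1e-12))
        total += len(arr)

    for perm in itertools.permutations(ry):
        batch.append(perm)
        if len(batch) >= 200_000:
            flush(batch)
            batch = []
    flush(batch)
    return count / total


def correlation(
    x,
    y,
    method: Optional[str] = None,
    alpha: float = _ALPHA,
    exact: bool = False,
) -> tuple[str, float, float]:
    """Correlation between two measurement vectors.

    ``method=None`` applies the normality gate: Shapiro-Wilk on both
    vectors at ``alpha``; Pearson if both pass, Spearman otherwise.
    Spearman handles ties by average ranks; its p-value uses the
    t-approximation, or an exact permutation test when ``exact`` and
    n <= 10.

    Returns (type, r, p); zero-variance input yields
    ("undefined", nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ("undefined", float("nan"), float("nan"))

    if method is None:
        p_x = stats.shapiro(x).pvalue
        p_y = stats.shapiro(y).pvalue
        method = "pearson" if (p_x > alpha and p_y > alpha) else "spearman"
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return ("pearson", float(res.statistic), float(res.pvalue))
    if method == "spearman":
        res = stats.spearmanr(x, y)
        r = float(res.statistic)
        p = float(res.pvalue)
        if exact and n <= 10:
            p = _spearman_exact_p(x, y, r)
        return ("spearman", r, p)
    raise ValueError(f"unknown correlation method {method!r}")


def bland_altman(x, y) -> tuple[float, float, tuple[float, float]]:
    """Bland-Altman summary of differences x - y (US - histology).

    Returns (mean difference, sample SD of differences, (lower, upper)
    95% limits of agreement = mean +/- 1.96 SD).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(x)}")
    diff = x - y
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return mean, sd, (mean - _LOA_FACTOR * sd, mean + _LOA_FACTOR * sd)


def estimate_shrinkage(pairs: PairedMeasurements,
                       exclude: Sequence[str] = ()) -> float:
    """Linear shrinkage estimate from the per-slice pairs.

    Fits (US - histology) = s * US through the origin over the per-slice
    measures (end margins are excluded: the histology side quantizes
    them to whole slices). Returns the slope s.
    """
    df = pairs.select(exclude=exclude)
    df = df[df["region"].isin(PER_SLICE_MEASURES)]
    if len(df) < 2:
        raise ValueError("not enough per-slice pairs to estimate shrinkage")
    u = df["us_mm"].to_numpy(float)
    h = df["histo_mm"].to_numpy(float)
    return float(np.sum(u * (u - h)) / np.sum(u * u))


# ---------------------------------------------------------------------------
# reports


@dataclass
class RegionStats:
    region: str
    n: int
    shapiro_p: Optional[float] = None
    corr_type: Optional[str] = None
    r: Optional[float] = None
    p: Optional[float] = None
    mean_diff: Optional[float] = None
    sd_diff: Optional[float] = None
    loa_lower: Optional[float] = None
    loa_upper: Optional[float] = None

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p is None or math.isnan(self.p) else self.p < _ALPHA


@dataclass
class AgreementReport:
    rows: dict[str, RegionStats]
    corr_method: str
    excluded: list[str] = field(default_factory=list)
    n_discordant: int = 0

    def __post_init__(self) -> None:
        for row in self.rows.values():
            if row.mean_diff is not None and row.loa_lower is not None:
                if not (row.loa_lower <= row.mean_diff <= row.loa_upper):
                    raise ValueError("limits of agreement must bracket the mean")

    @property
    def pooled(self) -> RegionStats:
        return self.rows[POOLED]


def build_report(
    pairs: PairedMeasurements,
    exclude: Sequence[str] = (),
    alpha: float = _ALPHA,
) -> AgreementReport:
    """Full per-region + pooled agreement report.

    The normality gate is applied once, to the pooled vectors, and the
    selected correlation type is used for every region.
    """
    exclude = list(exclude)
    present = set(pairs.frame["specimen"].unique())
    unknown = set(exclude) - present
    if unknown:
        raise ValueError(f"cannot exclude unknown specimens {sorted(unknown)}")
    pooled_us, pooled_histo = pairs.values(exclude=exclude)
    if len(pooled_us) == 0:
        raise ValueError("exclusion removed all paired measurements")

    if len(pooled_us) >= 3 and np.ptp(pooled_us) > 0 and np.ptp(pooled_histo) > 0:
        normal = (
            stats.shapiro(pooled_us).pvalue > alpha
            and stats.shapiro(pooled_histo).pvalue > alpha
        )
        method = "pearson" if normal else "spearman"
    else:
        method = "spearman"

    rows: dict[str, RegionStats] = {}
    for region in REPORT_REGIONS + (POOLED,):
        u, h = pairs.values(region=region, exclude=exclude)
        n = len(u)
        row = RegionStats(region=region, n=n)
        if n >= 3:
            diff = u - h
            if np.ptp(diff) > 0:
                row.shapiro_p = float(stats.shapiro(diff).pvalue)
            _, row.r, row.p = correlation(u, h, method=method)
        if n >= 2:
            row.mean_diff, row.sd_diff, (row.loa_lower, row.loa_upper) = bland_altman(
                u, h
            )
        rows[region] = row
    return AgreementReport(
        rows=rows,
        corr_method=method,
        excluded=exclude,
        n_discordant=pairs.n_discordant,
    )


def sensitivity_exclude(
    pairs: PairedMeasurements, specimen_ids: Sequence[str]
) -> AgreementReport:
    """Recompute the report with ``specimen_ids`` excluded."""
    return build_report(pairs, exclude=list(specimen_ids))


def _fmt(v, digits=3):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return f"{v:.{digits}f}"


def report_frame(report: AgreementReport) -> pd.DataFrame:
    rows = []
    for region in REPORT_REGIONS + (POOLED,):
        s = report.rows[region]
        rows.append(
            {
                "region": region,
                "n": s.n,
                "shapiro_p": s.shapiro_p,
                "corr_type": s.corr_type or report.corr_method,
                "r": s.r,
                "p": s.p,
                "mean_diff_mm": s.mean_diff,
                "sd_diff_mm": s.sd_diff,
                "loa_lower_mm": s.loa_lower,
                "loa_upper_mm": s.loa_upper,
                "significant": s.significant,
            }
        )
    return pd.DataFrame(rows)


def render_report(
    report: AgreementReport,
    pairs: PairedMeasurements,
    out_dir,
) -> list[Path]:
    """Write report.csv, report.md and one Bland-Altman plot per region.

    Significant correlations (p < 0.05) are bolded in the markdown
    table. Returns the list of written paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out_dir / "report.csv"
    report_frame(report).to_csv(csv_path, index=False)
    written.append(csv_path)

    lines = [
        "# Agreement between 3D ultrasound and histopathology",
        "",
        f"Differences are US - histology ({report.corr_method} correlation; "
        "limits of agreement = mean +/- 1.96 SD).",
        "",
    ]
    if report.excluded:
        lines.append(f"Excluded specimens: {', '.join(report.excluded)}.")
        lines.append("")
    if report.n_discordant:
        lines.append(
            f"Discordant tumor detections excluded from pairing: "
            f"{report.n_discordant} slide(s)."
        )
        lines.append("")
    lines.append("| region | n | r (p) | mean diff mm (95% LoA) |")
    lines.append("|---|---|---|---|")
    for region in REPORT_REGIONS + (POOLED,):
        s = report.rows[region]
        if s.r is not None and not math.isnan(s.r):
            r_cell = f"{_fmt(s.r)} (p = {_fmt(s.p)})"
            if s.significant:
                r_cell = f"**{r_cell}**"
        else:
            r_cell = ""
        if s.mean_diff is not None:
            ba_cell = (
                f"{_fmt(s.mean_diff, 2)} ({_fmt(s.loa_lower, 2)}; "
                f"{_fmt(s.loa_upper, 2)})"
            )
        else:
            ba_cell = ""
        lines.append(f"| {region} | {s.n} | {r_cell} | {ba_cell} |")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    written.append(md_path)

    for region in REPORT_REGIONS + (POOLED,):
        s = report.rows[region]
        fig, ax = plt.subplots(figsize=(5, 4))
        u, h = pairs.values(region=region, exclude=report.excluded)
        if len(u) >= 2 and s.mean_diff is not None:
            means = (u + h) / 2.0
            diffs = u - h
            ax.scatter(means, diffs, s=14, alpha=0.7)
            ax.axhline(s.mean_diff, color="tab:blue",
                       label=f"mean = {s.mean_diff:.2f} mm")
            ax.axhline(s.loa_lower, color="tab:red", linestyle="--",
                       label=f"LoA = ({s.loa_lower:.2f}; {s.loa_upper:.2f})")
            ax.axhline(s.loa_upper, color="tab:red", linestyle="--")
            ax.legend(fontsize=8)
        else:
            ax.text(0.5, 0.5, f"n = {len(u)}", ha="center", va="center",
                    transform=ax.transAxes)
        ax.set_xlabel("mean of US and histology (mm)")
        ax.set_ylabel("US - histology (mm)")
        ax.set_title(f"Bland-Altman: {region} (n = {s.n})")
        fig.tight_layout()
        png_path = out_dir / f"bland_altman_{region}.png"
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
        written.append(png_path)
    return written
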