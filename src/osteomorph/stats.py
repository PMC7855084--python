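"""Method-agreement statistics and the summary report tables.

Agreement between an estimator and its reference (ground truth, or the 3D
method) is quantified by Pearson's r squared, the mean difference, and
Bland-Altman 95% limits of agreement (mean difference +/- 1.96 SD of the
differences).  The sign convention throughout is ``estimate - reference``
(2D minus 3D / ground truth), so systematic 2D underestimation of the
longitudinal angle shows up as a negative bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "TestResult",
    "r_squared",
    "bland_altman",
    "t_tests",
    "plot_bland_altman",
    "orientation_agreement_report",
    "classification_accuracy_report",
    "lacunar_volume_report",
    "build_report",
]


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation between paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class AgreementReport:
    """Bland-Altman agreement between two paired series."""

    n: int
    mean_difference: float
    loa_low: float
    loa_high: float
    sd_difference: float
    means: np.ndarray
    differences: np.ndarray
    r_squared: Optional[float] = None


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Bland-Altman (Tukey mean-difference) agreement of ``x`` against ``y``.

    Differences are ``x - y`` (estimate minus reference); the 95% limits of
    agreement are ``mean +/- 1.96 SD`` with the sample (n-1) SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    mean = (x + y) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    r2 = None
    if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        r2 = r_squared(x, y)
    return AgreementReport(
        n=len(x),
        mean_difference=md,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        sd_difference=sd,
        means=mean,
        differences=diff,
        r_squared=r2,
    )


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    test_kind: str


def t_tests(
    a: Sequence[float],
    b: Union[Sequence[float], float],
    kind: str,
) -> TestResult:
    """Two-tailed Student's t-tests: paired, one-sample or two-sample.

    The two-sample form uses pooled variance (the classical equal-variance
    Student's test).  For ``one_sample``, ``b`` is the null mean.
    """
    a = np.asarray(a, dtype=float)
    if kind == "paired":
        b = np.asarray(b, dtype=float)
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs equal-length series, n >= 2")
        if np.std(a - b) == 0 and np.allclose(a, b):
            # identical series: zero difference with zero spread
            return TestResult(0.0, float(len(a) - 1), 1.0, kind)
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
    elif kind == "one_sample":
        if len(a) < 2:
            raise ValueError("one-sample test needs n >= 2")
        if np.std(a) == 0 and a[0] == float(b):
            return TestResult(0.0, float(len(a) - 1), 1.0, kind)
        res = sps.ttest_1samp(a, popmean=float(b))
        df = len(a) - 1
    elif kind == "two_sample":
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("two-sample test needs n >= 2 in both groups")
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
        test_kind=kind,
    )


def plot_bland_altman(report: AgreementReport, ax=None, title: str = ""):
    """Render a Bland-Altman plot (auxiliary; requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(report.means, report.differences, s=12, alpha=0.7)
    ax.axhline(report.mean_difference, color="k", lw=1)
    for loa in (report.loa_low, report.loa_high):
        ax.axhline(loa, color="k", lw=1, ls=":")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (estimate - reference)")
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _require(frames: Dict, what: str):
    if not frames:
        raise ValueError(f"no {what} cohort results supplied")


def orientation_agreement_report(cylinder_frames: Dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Orientation-agreement table: r2 and mean difference per angle,
    aspect ratio and method.

    ``cylinder_frames`` maps aspect ratio to a per-phantom frame with
    columns ``omega_true, theta_true, omega_2d, theta_2d, omega_3d,
    theta_3d``.  Canals with undefined ground-truth theta are excluded from
    the theta rows.
    """
    _require(cylinder_frames, "cylinder")
    rows = []
    for angle in ("omega", "theta"):
        for aspect in sorted(cylinder_frames):
            df = cylinder_frames[aspect]
            sub = df.dropna(subset=[f"{angle}_true", f"{angle}_2d", f"{angle}_3d"])
            truth = sub[f"{angle}_true"].to_numpy()
            row = {"angle": angle, "aspect_ratio": aspect, "n": len(sub)}
            for method in ("2d", "3d"):
                est = sub[f"{angle}_{method}"].to_numpy()
                row[f"r2_{method}"] = r_squared(truth, est)
                row[f"mean_diff_{method}"] = float((est - truth).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def classification_accuracy_report(cylinder_frames: Dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Classification-accuracy table per aspect ratio and category.

    Ground-truth categories come from the set angles; accuracy is reported
    for both the 3D skeleton and the 2D section estimates.
    """
    from .classify import classification_accuracy

    _require(cylinder_frames, "cylinder")
    rows = []
    for aspect in sorted(cylinder_frames):
        df = cylinder_frames[aspect]
        major = df[df["category_true"].isin(["longitudinal", "radial", "laminar"])]
        acc3 = classification_accuracy(major["category_3d"], major["category_true"])
        acc2 = classification_accuracy(major["category_2d"], major["category_true"])
        for (_, r3), (_, r2row) in zip(acc3.iterrows(), acc2.iterrows()):
            rows.append({
                "aspect_ratio": aspect,
                "category": r3["category"],
                "n_true": r3["n_true"],
                "n_correct_3d": r3["n_correct"],
                "pct_correct_3d": r3["pct_correct"],
                "n_correct_2d": r2row["n_correct"],
                "pct_correct_2d": r2row["pct_correct"],
            })
    return pd.DataFrame(rows)


def lacunar_volume_report(
    ellipsoid_frames: Dict[Tuple[str, float], pd.DataFrame],
) -> pd.DataFrame:
    """Lacunar-volume table: mean and SD per method, voxel size and
    alignment mode, for woven and parallel-fibred conditions.

    ``ellipsoid_frames`` maps ``(alignment_mode, voxel_size)`` to a
    per-phantom frame with columns ``vol_xy, vol_xyxz, vol_3d, fit_ok``.
    """
    _require(ellipsoid_frames, "ellipsoid")
    rows = []
    for (mode, voxel_size) in sorted(ellipsoid_frames):
        df = ellipsoid_frames[(mode, voxel_size)]
        for method, col in (("xy_plane", "vol_xy"),
                            ("xy_xz_plane", "vol_xyxz"),
                            ("ellipsoid_3d", "vol_3d")):
            v = df[col]
            if col == "vol_3d":
                v = v[df["fit_ok"]]
            v = v.dropna()
            rows.append({
                "alignment_mode": mode,
                "voxel_size_um": voxel_size,
                "method": method,
                "mean_volume_um3": float(v.mean()) if len(v) else np.nan,
                "sd_um3": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "n": int(len(v)),
                "n_failed": int((~df["fit_ok"]).sum()) if col == "vol_3d" else 0,
            })
    return pd.DataFrame(rows)


def build_report(
    cylinder_frames: Dict[float, pd.DataFrame],
    ellipsoid_frames: Dict[Tuple[str, float], pd.DataFrame],
) -> Dict[str, pd.DataFrame]:
    """Assemble all summary tables from per-phantom cohort frames."""
    return {
        "orientation_agreement": orientation_agreement_report(cylinder_frames),
        "classification_accuracy": classification_accuracy_report(cylinder_frames),
        "lacunar_volume": lacunar_volume_report(ellipsoid_frames),
    }
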