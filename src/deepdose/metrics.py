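"""Absorbed-dose integration, organ-dose aggregation and error statistics.

Turns a series of dose-rate frames into an absorbed-dose map (trapezoidal sum
over the imaging window plus an analytic exponential tail to infinity),
aggregates organ doses with reference-mass correction against the ORNL
stylized-phantom organ masses, and computes the voxel-level and organ-level
mean absolute percentage differences against a reference (always the direct
Monte-Carlo map), with paired t-tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import GA68_HALF_LIFE_MIN
from .volumes import DoseMap, Volume, check_same_grid

#: Voxels whose reference dose is below this fraction of the reference max
#: are excluded from percentage differences (the formula divides by the
#: reference and is unstable at near-zero dose).
DEFAULT_RELATIVE_FLOOR = 1e-3


def load_reference_masses() -> pd.DataFrame:
    """ORNL adult stylized-phantom organ masses packaged with deepdose."""
    with resources.files("deepdose.data").joinpath("ornl_organ_masses.csv").open() as f:
        return pd.read_csv(f, comment="#")


def load_published_organ_errors() -> pd.DataFrame:
    """Published per-organ dose-error comparator table (see data file header)."""
    with resources.files("deepdose.data").joinpath("published_organ_dose_errors.csv").open() as f:
        return pd.read_csv(f, comment="#")


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------


@dataclass
class TimeDoseRateSeries:
    times_min: tuple[float, ...]
    rate_maps: list[DoseMap]  # Gy/s
    decay_constant_per_min: float = np.log(2.0) / GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if len(t) != len(self.rate_maps) or len(t) < 2:
            raise ValueError("need >= 2 time points with one rate map each")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.decay_constant_per_min <= 0:
            raise ValueError("decay constant must be positive")
        check_same_grid(*self.rate_maps)
        self.times_min = tuple(float(x) for x in t)


def integrate_series(series: TimeDoseRateSeries, head: str = "hold") -> DoseMap:
    """Absorbed dose (Gy): trapezoid over the frames plus analytic tail.

    Per voxel: the rate is integrated by the trapezoidal rule from the first
    to the last frame time; before the first frame the rate is held constant
    at its first-frame value (``head="hold"``, default) or taken as zero
    (``head="zero"``); after the last frame the rate is assumed to decay
    exponentially with the series' decay constant, contributing
    ``R_last / λ`` analytically.
    """
    rates = np.stack([m.data for m in series.rate_maps])
    if np.any(rates < 0):
        raise ValueError("negative dose rates")
    t_s = np.asarray(series.times_min) * 60.0
    lam_s = series.decay_constant_per_min / 60.0
    dose = np.trapezoid(rates, t_s, axis=0)
    if head == "hold":
        dose = dose + rates[0] * t_s[0]
    elif head != "zero":
        raise ValueError(f"unknown head model {head!r}")
    dose = dose + rates[-1] / lam_s
    m0 = series.rate_maps[0]
    return DoseMap(dose, m0.voxel_size, "Gy",
                   {"stage": "integrate", "head": head,
                    "lambda_per_min": series.decay_constant_per_min})


# ---------------------------------------------------------------------------
# Organ doses
# ---------------------------------------------------------------------------


def organ_doses(
    dose: DoseMap,
    labels: Volume,
    density: Volume,
    organ_names: dict[int, str],
    reference_masses: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-organ mean absorbed dose with reference-mass correction.

    Organ mass is Σ density·voxel volume over the label; organ dose is the
    energy-weighted mean (Σ dose·voxel mass / Σ mass); the mass-corrected
    dose scales by (patient organ mass / reference organ mass).  That scaling
    direction is one documented reading of reference-mass correction and is
    swappable by post-processing the returned table.  Labels absent from the
    volume are flagged and excluded.
    """
    check_same_grid(dose, labels, density)
    if reference_masses is None:
        reference_masses = load_reference_masses()
    ref = dict(zip(reference_masses["organ"], reference_masses["reference_mass_g"]))
    vox_ml = dose.voxel_volume_ml
    rows = []
    for label, name in sorted(organ_names.items()):
        sel = labels.data == label
        n = int(sel.sum())
        if n == 0:
            rows.append({"organ": name, "label": label, "voxel_count": 0,
                         "present": False, "organ_mass_g": np.nan,
                         "reference_mass_g": ref.get(name, np.nan),
                         "mean_dose_gy": np.nan, "mass_corrected_dose_gy": np.nan})
            continue
        mass_vox = density.data[sel] * vox_ml  # g
        mass = float(mass_vox.sum())
        mean_dose = float((dose.data[sel] * mass_vox).sum() / mass)
        ref_mass = ref.get(name, np.nan)
        corrected = mean_dose * mass / ref_mass if np.isfinite(ref_mass) else mean_dose
        rows.append({"organ": name, "label": label, "voxel_count": n, "present": True,
                     "organ_mass_g": mass, "reference_mass_g": ref_mass,
                     "mean_dose_gy": mean_dose, "mass_corrected_dose_gy": corrected})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Percentage differences
# ---------------------------------------------------------------------------


def voxel_percent_diff(
    method: np.ndarray,
    reference: np.ndarray,
    mask: Optional[np.ndarray] = None,
    floor: float = DEFAULT_RELATIVE_FLOOR,
) -> tuple[float, float]:
    """Mean ± std of |method − reference| / reference × 100 over mask voxels.

    The reference is always the Monte-Carlo map; the metric is asymmetric by
    construction.  Voxels whose reference value is below ``floor`` × the
    reference maximum inside the mask are excluded.
    """
    method = np.asarray(method)
    reference = np.asarray(reference)
    if method.shape != reference.shape:
        raise ValueError("method and reference grids differ")
    sel = np.ones(reference.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not sel.any():
        raise ValueError("empty mask")
    sel = sel & (reference > floor * reference[sel].max())
    if not sel.any():
        raise ValueError("all voxels below the reference floor")
    pct = np.abs(method[sel] - reference[sel]) / reference[sel] * 100.0
    return float(pct.mean()), float(pct.std())


def organ_percent_diff(
    method_doses: pd.DataFrame | Sequence[pd.DataFrame],
    reference_doses: pd.DataFrame | Sequence[pd.DataFrame],
    dose_column: str = "mass_corrected_dose_gy",
    exclude_from_average: Optional[str] = None,
) -> pd.DataFrame:
    """Per-organ |method − reference| / reference × 100 averaged over subjects.

    Accepts a single table per method or a list (one per subject).  Returns a
    per-organ mean/std table plus two summary rows: the cross-organ average
    and, if ``exclude_from_average`` is given, the average excluding that
    organ (outlier organs with near-zero reference dose can dominate the
    plain average).
    """
    ms = [method_doses] if isinstance(method_doses, pd.DataFrame) else list(method_doses)
    rs = [reference_doses] if isinstance(reference_doses, pd.DataFrame) else list(reference_doses)
    if len(ms) != len(rs):
        raise ValueError("one reference table per method table required")
    per_subject = []
    for m, r in zip(ms, rs):
        mm = m.set_index("organ")[dose_column]
        rr = r.set_index("organ")[dose_column]
        if set(mm.index) != set(rr.index):
            raise ValueError("organ sets differ between method and reference tables")
        per_subject.append((np.abs(mm - rr) / rr * 100.0).rename(None))
    table = pd.concat(per_subject, axis=1)
    out = pd.DataFrame({"organ": table.index,
                        "mean_pct_diff": table.mean(axis=1).values,
                        "std_pct_diff": table.std(axis=1, ddof=1).values if len(ms) > 1
                        else np.zeros(len(table))})
    rows = [out]
    rows.append(pd.DataFrame({"organ": ["average"],
                              "mean_pct_diff": [out["mean_pct_diff"].mean()],
                              "std_pct_diff": [np.nan]}))
    if exclude_from_average is not None:
        keep = out["organ"] != exclude_from_average
        rows.append(pd.DataFrame({"organ": [f"average_excluding_{exclude_from_average}"],
                                  "mean_pct_diff": [out.loc[keep, "mean_pct_diff"].mean()],
                                  "std_pct_diff": [np.nan]}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    t: float
    p: float
    significant: bool
    alpha_adjusted: float
    n: int
    status: str = "ok"  # "ok" | "degenerate"


def paired_ttest_bonferroni(
    a: Sequence[float],
    b: Sequence[float],
    m_tests: int = 1,
    alpha: float = 0.05,
) -> PairedTestResult:
    """Two-sided paired t-test with Bonferroni-adjusted significance level.

    The null is rejected when p < alpha / m_tests.  Zero-variance differences
    give a "degenerate" status with no fabricated p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    diffs = a - b
    adj = alpha / m_tests
    if np.allclose(diffs, diffs[0]):
        return PairedTestResult(np.nan, np.nan, False, adj, len(a), status="degenerate")
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), bool(p < adj), adj, len(a))
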