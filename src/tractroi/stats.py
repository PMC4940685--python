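"""Reliability and comparison statistics for ROI FA measurements.

Implements the study's full statistical framework on a long-format
measurement table: per-section summaries (mean, SD, CV), pairwise method
contrasts with Tukey-Kramer adjustment, variance-components ANOVA with the
repeatability coefficient (1.96 * sqrt(2) * sigma_error) and Bland-Altman
limits of agreement (dbar +/- 1.96 * sqrt(2) * sigma_sum), start-point
correction, inter-scan variability, and the Jaccard overlap of voxel sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from tractroi.roi_methods import Roi

Z95_SQRT2 = 1.96 * np.sqrt(2.0)


from functools import lru_cache


@lru_cache(maxsize=256)
def _tukey_qcrit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


# ---------------------------------------------------------------------------
# section summaries
# ---------------------------------------------------------------------------

def section_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and CV of FA per method and section, over subjects.

    FA is first averaged within section and across sides (and slices) for
    each subject, then summarised across subjects.  CV = SD/mean in percent;
    a zero mean leaves CV as NaN with a warning.
    """
    per_subject = (
        table.dropna(subset=["fa"])
        .groupby(["method", "section", "subject"], as_index=False)["fa"]
        .mean()
    )
    counts = per_subject.groupby(["method", "section"])["subject"].nunique()
    if (counts < 2).any():
        raise ValueError("section summaries need >= 2 subjects per method/section")
    out = (
        per_subject.groupby(["method", "section"])["fa"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * out["sd"] / out["mean"]
    bad = out["mean"] == 0
    if bad.any():
        warnings.warn("CV undefined where the section mean FA is 0")
        cv[bad] = np.nan
    out["cv_percent"] = cv
    return out


# ---------------------------------------------------------------------------
# pairwise method comparison
# ---------------------------------------------------------------------------

@dataclass
class SectionComparison:
    method_a: str
    method_b: str
    section: int
    mean_difference: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    p_unadjusted: float
    n_subjects: int


def compare_methods(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise method contrasts per section, Tukey-Kramer adjusted.

    Slice-level FA is averaged across sides, then the five slices of a
    section, within subject; each method pair is contrasted by its paired
    per-subject differences.  On a balanced design this paired contrast is
    exactly the generalized-least-squares contrast under a
    compound-symmetric within-subject covariance over the slices, and each
    pair carries its own variance (the "paired t-test with unequal
    variances").  Adjustment uses the studentized range with k = number of
    methods (q = sqrt(2) |t|), which for k = 2 reduces to the unadjusted
    paired t-test.
    """
    methods = sorted(table["method"].unique())
    if len(methods) < 2:
        raise ValueError("compare_methods needs at least two methods")
    k = len(methods)
    rows = []
    for section, sub in table.groupby("section"):
        wide = (
            sub.dropna(subset=["fa"])
            .groupby(["subject", "method"])["fa"]
            .mean()
            .unstack("method")
            .dropna()
        )
        n = len(wide)
        if n < 3:
            raise ValueError(f"section {section}: fewer than 3 complete subjects")
        df = n - 1
        for i in range(k):
            for j in range(i + 1, k):
                a, b = methods[i], methods[j]
                d = wide[a] - wide[b]
                mean = float(d.mean())
                se = float(d.std(ddof=1) / np.sqrt(n))
                if se == 0:
                    t = 0.0 if mean == 0 else np.inf * np.sign(mean)
                else:
                    t = mean / se
                q = np.sqrt(2.0) * abs(t)
                p_adj = float(sps.studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
                p_un = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
                if abs(t) == 0.0:
                    p_adj, p_un = 1.0, 1.0
                qcrit = _tukey_qcrit(alpha, k, df)
                half = qcrit / np.sqrt(2.0) * se
                rows.append(
                    SectionComparison(
                        method_a=a, method_b=b, section=int(section),
                        mean_difference=mean, ci_low=mean - half,
                        ci_high=mean + half, p_adjusted=min(p_adj, 1.0),
                        p_unadjusted=min(p_un, 1.0), n_subjects=n,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Estimated variance components (FA^2) and derived reliability measures.

    ``sigma2_interactions`` holds the labelled interaction terms; negative
    method-of-moments estimates are truncated at 0 and listed in
    ``truncated``.  ``limits_of_agreement`` are symmetric about the mean
    difference ``mean_difference`` between the two factor levels.
    """

    factor: str
    sigma2_subject: float
    sigma2_factor: float
    sigma2_interactions: dict = field(default_factory=dict)
    sigma2_error: float = 0.0
    mean_difference: float = np.nan
    repeatability_coefficient: float = np.nan
    limits_of_agreement: tuple = (np.nan, np.nan)
    total_sigma2: float | None = None  # scan + error, inter-scan analyses only
    truncated: list = field(default_factory=list)
    include_main_effect: bool = False
    #: untruncated method-of-moments estimates (can be negative); these are the
    #: unbiased quantities, useful for Monte-Carlo averaging
    sigma2_raw: dict = field(default_factory=dict)


def _balanced_cube(df: pd.DataFrame, rows: str, cols: str, layers: str,
                   value: str = "fa") -> tuple[np.ndarray, list, list, list]:
    """Pivot to a (rows, cols, layers) array with exactly one value per cell.

    A NaN value (a missing slice in one rating) drops that row level
    (complete-case); a structurally absent cell is a design error and is
    rejected with the offending cell named.
    """
    dup = df.duplicated(subset=[rows, cols, layers])
    if dup.any():
        cell = df.loc[dup.idxmax(), [rows, cols, layers]].tolist()
        raise ValueError(f"more than one observation in cell {cell}")
    c_levels = sorted(df[cols].unique())
    l_levels = sorted(df[layers].unique())
    seen = df.groupby(rows)[cols].count()
    bad = seen[seen != len(c_levels) * len(l_levels)]
    if len(bad):
        raise ValueError(
            f"unbalanced design: {rows} {bad.index[0]!r} is missing a "
            f"({cols}, {layers}) cell"
        )
    piv = df.pivot_table(index=rows, columns=[cols, layers], values=value,
                         aggfunc="first", dropna=False)
    piv = piv.dropna()  # complete-case over the row factor (missing slices)
    r_levels = list(piv.index)
    if len(r_levels) < 2:
        raise ValueError("fewer than 2 complete levels of " + rows)
    cube = np.empty((len(r_levels), len(c_levels), len(l_levels)))
    for j, c in enumerate(c_levels):
        for m, lev in enumerate(l_levels):
            cube[:, j, m] = piv[(c, lev)].to_numpy()
    return cube, r_levels, c_levels, l_levels


def reliability_anova(
    table: pd.DataFrame,
    factor: str = "rater",
    include_main_effect: bool = False,
) -> VarianceComponents:
    """Variance components of one method at one coronal position.

    Expected-mean-squares (method-of-moments) ANOVA of FA on subject
    (random), ``factor`` (random: rater or repeat) and side (fixed), one
    observation per cell.  With a single observation per cell the three-way
    interaction is the error term.  Derived measures:

    * repeatability coefficient = 1.96 * sqrt(2) * sigma_error
    * limits of agreement = dbar +/- 1.96 * sqrt(2) * sigma_sum, where
      sigma_sum^2 sums the variance components of all interaction terms
      containing the factor plus the error (the factor main effect is added
      only when ``include_main_effect`` is set).
    """
    needed = {"subject", factor, "side", "fa"}
    if not needed.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    cube, subjects, f_levels, sides = _balanced_cube(table, "subject", factor, "side")
    if factor == "rater" and len(f_levels) != 2:
        raise ValueError("rater reliability needs exactly 2 raters")
    if len(f_levels) < 2 or len(sides) != 2:
        raise ValueError("need >= 2 factor levels and both sides")
    a, b, c = cube.shape
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_f = cube.mean(axis=(0, 2))
    m_d = cube.mean(axis=(0, 1))
    m_sf = cube.mean(axis=2)
    m_sd = cube.mean(axis=1)
    m_fd = cube.mean(axis=0)

    ms_s = b * c * np.sum((m_s - grand) ** 2) / (a - 1)
    ms_f = a * c * np.sum((m_f - grand) ** 2) / (b - 1)
    ms_sf = c * np.sum(
        (m_sf - m_s[:, None] - m_f[None, :] + grand) ** 2
    ) / ((a - 1) * (b - 1))
    ms_sd = b * np.sum(
        (m_sd - m_s[:, None] - m_d[None, :] + grand) ** 2
    ) / ((a - 1) * (c - 1))
    ms_fd = a * np.sum(
        (m_fd - m_f[:, None] - m_d[None, :] + grand) ** 2
    ) / ((b - 1) * (c - 1))
    resid = (
        cube
        - m_sf[:, :, None] - m_sd[:, None, :] - m_fd[None, :, :]
        + m_s[:, None, None] + m_f[None, :, None] + m_d[None, None, :]
        - grand
    )
    ms_err = np.sum(resid**2) / ((a - 1) * (b - 1) * (c - 1))

    raw = {
        "error": ms_err,
        "subject:" + factor: (ms_sf - ms_err) / c,
        "subject:side": (ms_sd - ms_err) / b,
        factor + ":side": (ms_fd - ms_err) / a,
        "subject": (ms_s - ms_sf - ms_sd + ms_err) / (b * c),
        factor: (ms_f - ms_sf - ms_fd + ms_err) / (a * c),
    }
    truncated = [k for k, v in raw.items() if v < 0]
    if truncated:
        warnings.warn(
            "negative variance-component estimates truncated to 0: "
            + ", ".join(truncated)
        )
    comp = {k: max(v, 0.0) for k, v in raw.items()}

    dbar = float(cube[:, 0, :].mean() - cube[:, 1, :].mean()) if b == 2 else np.nan
    sigma_err = np.sqrt(comp["error"])
    s2_sum = comp["subject:" + factor] + comp[factor + ":side"] + comp["error"]
    if include_main_effect:
        s2_sum += comp[factor]
    sigma_sum = np.sqrt(s2_sum)
    return VarianceComponents(
        factor=factor,
        sigma2_subject=comp["subject"],
        sigma2_factor=comp[factor],
        sigma2_interactions={
            "subject:" + factor: comp["subject:" + factor],
            "subject:side": comp["subject:side"],
            factor + ":side": comp[factor + ":side"],
        },
        sigma2_error=comp["error"],
        mean_difference=dbar,
        repeatability_coefficient=Z95_SQRT2 * sigma_err,
        limits_of_agreement=(
            dbar - Z95_SQRT2 * sigma_sum, dbar + Z95_SQRT2 * sigma_sum
        ),
        truncated=truncated,
        include_main_effect=include_main_effect,
        sigma2_raw=raw,
    )


def reliability_by_position(
    table: pd.DataFrame, factor: str = "rater", **kwargs
) -> pd.DataFrame:
    """``reliability_anova`` applied at each analysis position separately."""
    rows = []
    for pos, sub in table.groupby("position"):
        try:
            vc = reliability_anova(sub, factor=factor, **kwargs)
        except ValueError:
            continue
        rows.append(
            {
                "position": int(pos),
                "repeatability_coefficient": vc.repeatability_coefficient,
                "loa_low": vc.limits_of_agreement[0],
                "loa_high": vc.limits_of_agreement[1],
                "mean_difference": vc.mean_difference,
                "sigma2_error": vc.sigma2_error,
                "sigma2_subject": vc.sigma2_subject,
                "sigma2_factor": vc.sigma2_factor,
            }
        )
    return pd.DataFrame(rows)


def interscan_variability(table: pd.DataFrame) -> VarianceComponents:
    """Scan-to-scan variability of one repeatedly scanned subject.

    Two-way ANOVA per position-pooled input: scan (random) x side (fixed),
    one observation per cell; the interaction is the error.  The scan
    variance is summed with the error to form the total variance due to scan
    number (``total_sigma2``).
    """
    needed = {"scan", "side", "fa"}
    if not needed.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    cube, scans, sides, _ = _balanced_cube(
        table.assign(_one=0), "scan", "side", "_one"
    )
    y = cube[:, :, 0]  # (scan, side)
    b, c = y.shape
    if b < 2 or c != 2:
        raise ValueError("inter-scan analysis needs >= 2 scans and both sides")
    grand = y.mean()
    m_scan = y.mean(axis=1)
    m_side = y.mean(axis=0)
    ms_scan = c * np.sum((m_scan - grand) ** 2) / (b - 1)
    resid = y - m_scan[:, None] - m_side[None, :] + grand
    ms_err = np.sum(resid**2) / ((b - 1) * (c - 1))
    s2_err = ms_err
    s2_scan = max((ms_scan - ms_err) / c, 0.0)
    total = s2_scan + s2_err
    return VarianceComponents(
        factor="scan",
        sigma2_subject=np.nan,
        sigma2_factor=s2_scan,
        sigma2_interactions={},
        sigma2_error=s2_err,
        mean_difference=np.nan,
        repeatability_coefficient=Z95_SQRT2 * np.sqrt(s2_err),
        limits_of_agreement=(
            -Z95_SQRT2 * np.sqrt(total), Z95_SQRT2 * np.sqrt(total)
        ),
        total_sigma2=total,
        truncated=["scan"] if (ms_scan - ms_err) < 0 else [],
    )


# ---------------------------------------------------------------------------
# start-point correction and Jaccard overlap
# ---------------------------------------------------------------------------

def startpoint_correct(roi_a: Roi, roi_b: Roi) -> tuple[Roi, Roi]:
    """Re-index two ROIs of the same tract to a common anterior start.

    The new position 1 is the most anterior slice included in both ROIs;
    anterior slices present in only one ROI are dropped.  Only meaningful
    for repeated definitions on the same dataset.
    """
    if roi_a.side != roi_b.side:
        raise ValueError("start-point correction needs ROIs of the same side")
    lo = max(roi_a.start_slice, roi_b.start_slice)
    hi = min(roi_a.start_slice + roi_a.n_slices - 1,
             roi_b.start_slice + roi_b.n_slices - 1)
    if lo > hi:
        raise ValueError("the two ROIs share no coronal slice")

    def _trim(roi: Roi) -> Roi:
        off = lo - roi.start_slice
        return Roi(
            method=roi.method, side=roi.side, start_slice=lo,
            selections=list(roi.selections[off:]), rater_id=roi.rater_id,
            scan_id=roi.scan_id, repeat_id=roi.repeat_id,
        )

    return _trim(roi_a), _trim(roi_b)


def startpoint_correct_table(
    table: pd.DataFrame, factor: str = "rater", n_slices: int = 15,
    section_mm: int = 5,
) -> pd.DataFrame:
    """Re-position a measurement table at the common anterior slice.

    Within each group sharing all identity columns except ``factor``, the new
    position 1 is the most anterior absolute slice present at every factor
    level; rows anterior of it are dropped and positions/sections renumbered.
    Requires an absolute ``slice`` column.
    """
    if "slice" not in table.columns:
        raise ValueError("start-point correction needs the absolute 'slice' column")
    ids = [c for c in ("subject", "method", "side", "scan") if c in table.columns]
    out = []
    for _, grp in table.groupby(ids):
        start = grp.dropna(subset=["fa"]).groupby(factor)["slice"].min().max()
        g = grp[grp["slice"] >= start].copy()
        g["position"] = g["slice"] - start + 1
        g = g[g["position"] <= n_slices]
        g["section"] = 1 + (g["position"] - 1) // section_mm
        out.append(g)
    return pd.concat(out, ignore_index=True)


def jaccard(roi_a: Roi, roi_b: Roi) -> float:
    """Jaccard overlap |A n B| / |A u B| over the slices included in both ROIs.

    Returns NaN (with a warning) when the restricted union is empty.
    1 means complete agreement, 0 no overlap at all.
    """
    lo = max(roi_a.start_slice, roi_b.start_slice)
    hi = min(roi_a.start_slice + roi_a.n_slices - 1,
             roi_b.start_slice + roi_b.n_slices - 1)
    a = roi_a.voxel_set((lo, hi))
    b = roi_b.voxel_set((lo, hi))
    union = a | b
    if not union:
        warnings.warn("Jaccard undefined: the ROIs share no slices with voxels")
        return float("nan")
    return len(a & b) / len(union)


def normality_report(values) -> tuple[float, float]:
    """Advisory Shapiro-Wilk check (statistic, p-value)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    w, p = sps.shapiro(arr)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# synthetic measurement tables for estimator validation
# ---------------------------------------------------------------------------

def simulate_reliability_table(
    n_subjects: int,
    sigma2_subject: float,
    sigma2_factor: float,
    sigma2_error: float,
    factor: str = "rater",
    n_levels: int = 2,
    sigma2_interactions: dict | None = None,
    side_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced subject x factor x side table drawn from the ANOVA model."""
    inter = {"subject:factor": 0.0, "subject:side": 0.0, "factor:side": 0.0}
    inter.update(sigma2_interactions or {})
    rng = np.random.default_rng(seed)
    subj = rng.normal(0, np.sqrt(sigma2_subject), n_subjects)
    fac = rng.normal(0, np.sqrt(sigma2_factor), n_levels)
    sf = rng.normal(0, np.sqrt(inter["subject:factor"]), (n_subjects, n_levels))
    sd = rng.normal(0, np.sqrt(inter["subject:side"]), (n_subjects, 2))
    fd = rng.normal(0, np.sqrt(inter["factor:side"]), (n_levels, 2))
    rows = []
    for s in range(n_subjects):
        for f in range(n_levels):
            for d, side in enumerate(("left", "right")):
                y = (
                    subj[s] + fac[f] + sf[s, f] + sd[s, d] + fd[f, d]
                    + (side_effect if d == 1 else 0.0)
                    + rng.normal(0, np.sqrt(sigma2_error))
                )
                rows.append(
                    {"subject": s, factor: f, "side": side, "fa": y}
                )
    return pd.DataFrame(rows)


def simulate_method_table(
    n_subjects: int,
    method_means: dict,
    sigma_subject: float = 0.05,
    sigma_noise: float = 0.02,
    n_sections: int = 3,
    n_slices_per_section: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Slice-level table with known method offsets, for testing contrasts."""
    rng = np.random.default_rng(seed)
    subj = rng.normal(0, sigma_subject, n_subjects)
    rows = []
    for s in range(n_subjects):
        for method, mu in method_means.items():
            for sec in range(1, n_sections + 1):
                for sl in range(n_slices_per_section):
                    for side in ("left", "right"):
                        rows.append(
                            {
                                "subject": s,
                                "method": method,
                                "side": side,
                                "section": sec,
                                "position": (sec - 1) * n_slices_per_section + sl + 1,
                                "fa": mu + subj[s] + rng.normal(0, sigma_noise),
                            }
                        )
    return pd.DataFrame(rows)
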