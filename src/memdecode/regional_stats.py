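"""ROI-level decoding by decision evidence and its statistics.

For each ROI and evidence level the shared pipeline decodes a label set
(choice, memory status, action, image type, target side) under
leave-one-subject-out folds with ANOVA feature selection (k = 50) on the
training folds. A linear mixed-effects model with a random intercept per
subject tests the linear effect of evidence (coded -1/0/+1) on accuracy;
low-evidence analyses test choice decoding against chance and against
status decoding with paired t tests. Families of p-values are Bonferroni
corrected by the number of ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decode_core import CvScheme, LabeledPatterns, cross_validate
from .study_design import EVIDENCE_CODE

__all__ = [
    "regional_decode",
    "EvidenceSlopeResult",
    "evidence_slope_test",
    "low_evidence_tests",
    "bonferroni",
]


def regional_decode(
    patterns: LabeledPatterns,
    roi_voxels: np.ndarray,
    roi_name: str = "roi",
    label_set: str = "choice",
    evidence_levels: tuple[str, ...] = ("low", "middle", "high"),
    scheme: CvScheme | None = None,
    k_select: int = 50,
    C: float = 1.0,
) -> pd.DataFrame:
    """Decode within one ROI separately per evidence level.

    ``patterns`` must carry an ``evidence`` column in its metadata and
    feature columns spanning the full in-mask voxel axis (the ROI columns
    are selected here). Returns tidy rows (roi, subject, evidence,
    label_set, accuracy), one per left-out subject per level.
    """
    if patterns.meta is None or "evidence" not in patterns.meta.columns:
        raise ValueError("patterns.meta must contain an 'evidence' column")
    roi_voxels = np.asarray(roi_voxels, dtype=int)
    if roi_voxels.size == 0:
        raise ValueError("empty ROI")
    scheme = scheme or CvScheme("leave_one_subject_out")
    rows = []
    for level in evidence_levels:
        idx = np.where(patterns.meta["evidence"].to_numpy() == level)[0]
        if idx.size == 0:
            raise ValueError(f"no trials at evidence level {level!r}")
        sub = patterns.subset(idx)
        sub = LabeledPatterns(sub.X[:, roi_voxels], sub.y, sub.subject_ids, sub.meta)
        res = cross_validate(sub, scheme, k_select=k_select, C=C)
        for fid, acc in zip(res.fold_ids, res.fold_accuracies):
            rows.append(
                dict(roi=roi_name, subject=fid, evidence=level, label_set=label_set, accuracy=acc)
            )
    return pd.DataFrame(rows)


@dataclass
class EvidenceSlopeResult:
    slope: float
    stat: float
    p: float
    method: str  # "mixedlm" or "subject_slopes"


def evidence_slope_test(rows: pd.DataFrame) -> EvidenceSlopeResult:
    """Linear mixed model: accuracy ~ evidence code, random intercept/subject.

    Evidence is coded -1/0/+1 (low/middle/high); the fixed slope is tested
    with a Wald z. If the REML fit is singular or fails to converge, the
    test falls back to a one-sample t on subject-wise OLS slopes and says
    so in ``method``.
    """
    levels = rows["evidence"].unique()
    if len(levels) < 2:
        raise ValueError("need at least two evidence levels")
    if rows["subject"].nunique() < 3:
        raise ValueError("need at least three subjects")
    data = rows.copy()
    data["ev_code"] = data["evidence"].map(EVIDENCE_CODE)
    if data["ev_code"].isna().any():
        raise ValueError("unknown evidence level in rows")

    import statsmodels.formula.api as smf

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("accuracy ~ ev_code", data, groups=data["subject"]).fit(reml=True)
        slope = float(fit.params["ev_code"])
        se = float(fit.bse["ev_code"])
        if not np.isfinite(se) or se == 0:
            raise ValueError("singular mixed-model fit")
        z = slope / se
        return EvidenceSlopeResult(slope, z, float(2 * stats.norm.sf(abs(z))), "mixedlm")
    except (ValueError, np.linalg.LinAlgError):
        slopes = []
        for _, g in data.groupby("subject"):
            x = g["ev_code"].to_numpy()
            y = g["accuracy"].to_numpy()
            xc = x - x.mean()
            denom = (xc**2).sum()
            if denom == 0:
                continue
            slopes.append((xc * y).sum() / denom)
        t, p = stats.ttest_1samp(slopes, 0.0)
        return EvidenceSlopeResult(float(np.mean(slopes)), float(t), float(p), "subject_slopes")


def low_evidence_tests(
    choice_rows: pd.DataFrame, status_rows: pd.DataFrame, chance: float = 0.5
) -> dict[str, float]:
    """Low-evidence analyses: choice vs chance, and choice vs status.

    Both inputs are RegionalAccuracy-style rows restricted (or restrictable)
    to the low-evidence level; subjects must match. Returns the one-sample
    t of choice accuracy against chance and the paired t of choice minus
    status decoding.
    """
    c = choice_rows[choice_rows["evidence"] == "low"].sort_values("subject")
    s = status_rows[status_rows["evidence"] == "low"].sort_values("subject")
    if list(c["subject"]) != list(s["subject"]):
        raise ValueError("choice and status rows must cover the same subjects")
    t1, p1 = stats.ttest_1samp(c["accuracy"], chance)
    diff = c["accuracy"].to_numpy() - s["accuracy"].to_numpy()
    if np.allclose(diff, 0.0):
        t2, p2 = 0.0, 1.0
    else:
        t2, p2 = stats.ttest_rel(c["accuracy"].to_numpy(), s["accuracy"].to_numpy())
    return dict(
        t_vs_chance=float(t1), p_vs_chance=float(p1),
        t_choice_minus_status=float(t2), p_choice_minus_status=float(p2),
        mean_choice=float(c["accuracy"].mean()), mean_status=float(s["accuracy"].mean()),
    )


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    if m < 1:
        raise ValueError("m must be at least 1")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out
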