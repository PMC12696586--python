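"""Synthetic resting-state ROI functional-connectivity comparison.

Re-creates, on synthetic data, the group comparison of resting-state
functional connectivity across the six model ROIs (speech sound maps,
articulator maps, feedback control map).  Because the clinical series are
not publicly available, a generator emits multivariate-Gaussian BOLD-like
series (216 volumes, TR = 2.2 s) whose expected pairwise correlations match
printed group statistics, with per-subject heterogeneity tuned so the
between-subject spread of correlations matches the printed SDs.

The analysis pipeline mirrors the clinical one: per-subject Pearson
correlations per ROI pair, Fisher Z transform, per-pair Welch two-sample
t-tests, Benjamini-Hochberg FDR across the 15 pairs at q < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.correlation_tools import corr_clipped
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROI",
    "ROISet",
    "default_rois",
    "GroupTimeSeries",
    "FCResult",
    "generate_group",
    "fc_pipeline",
    "clinical_effects",
    "clinical_target_matrices",
    "subject_sd_r",
]

N_TIMEPOINTS = 216
TR_SECONDS = 2.2
SERIES_RADIUS_MM = 5.0
LESION_RADIUS_MM = 6.0


@dataclass(frozen=True)
class ROI:
    label: str
    mni: tuple[int, int, int]
    feedforward: bool
    feedback: bool


@dataclass(frozen=True)
class ROISet:
    rois: tuple[ROI, ...]
    radius_mm: float = SERIES_RADIUS_MM

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rois)

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.labels, 2))

    def index(self, label: str) -> int:
        return self.labels.index(label)


def default_rois() -> ROISet:
    """The six model ROIs with their MNI peak coordinates."""
    return ROISet(
        rois=(
            ROI("left_ssm_lateral", (-55, 9, 0), True, False),
            ROI("left_ssm_medial", (-34, 13, 4), True, False),
            ROI("left_articulator", (-58, 1, 23), True, False),
            ROI("feedback_control_map", (50, 8, 13), False, True),
            ROI("right_ssm", (39, 12, 0), True, False),
            ROI("right_articulator", (58, 1, 23), True, True),
        )
    )


@dataclass
class GroupTimeSeries:
    group: str
    data: np.ndarray  # (subjects, timepoints, rois)
    rois: ROISet
    tr: float = TR_SECONDS
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class FCResult:
    rois: ROISet
    subject_r: dict[str, np.ndarray]  # group -> (subjects, pairs)
    stats: pd.DataFrame  # pair, group means/SDs, t, p, p_fdr, significant
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.stats[self.stats["significant"]]
        return [(r["roi_a"], r["roi_b"]) for _, r in sig.iterrows()]


def subject_sd_r(r_mean: float, r_sd: float, n_timepoints: int = N_TIMEPOINTS) -> float:
    """Between-subject SD of the per-subject target correlation that
    reproduces an observed between-subject SD of r.

    The observed spread is heterogeneity plus the sampling noise of a
    Pearson r from a finite series (delta method, variance
    (1-r^2)^2/(T-3)); the latter is subtracted out.
    """
    sampling_var = (1.0 - r_mean**2) ** 2 / (n_timepoints - 3)
    return float(np.sqrt(max(r_sd**2 - sampling_var, 0.0)))


def _repair_psd(corr: np.ndarray) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() >= 1e-10:
        return corr
    repaired = corr_clipped(corr, threshold=1e-8)
    eigvals = np.linalg.eigvalsh(repaired)
    if eigvals.min() < -1e-8:
        raise ValueError("correlation matrix could not be repaired to PSD")
    return repaired


def generate_group(
    target_corr: np.ndarray,
    n_subjects: int,
    n_timepoints: int = N_TIMEPOINTS,
    seed: int | np.random.Generator | None = None,
    subject_sd: float | np.ndarray = 0.0,
    group: str = "group",
    rois: ROISet | None = None,
) -> GroupTimeSeries:
    """Synthetic group of ROI time series with target pairwise correlations.

    Each subject draws a personal correlation matrix — the target, perturbed
    per pair by N(0, subject_sd) on the correlation scale and repaired to a
    PSD matrix — and then a zero-mean multivariate Gaussian series with that
    correlation.  subject_sd may be a scalar or a symmetric per-pair matrix;
    zero gives a homogeneous group whose only r spread is sampling noise.
    """
    rois = rois or default_rois()
    k = len(rois.labels)
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.shape != (k, k):
        raise ValueError(f"target correlation matrix must be {k}x{k}")
    if not np.allclose(target_corr, target_corr.T) or not np.allclose(
        np.diag(target_corr), 1.0
    ):
        raise ValueError("target must be symmetric with unit diagonal")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    target_corr = _repair_psd(target_corr)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sd = np.asarray(subject_sd, dtype=float)
    if sd.ndim == 0:
        sd = np.full((k, k), float(sd))
    data = np.empty((n_subjects, n_timepoints, k))
    iu = np.triu_indices(k, 1)
    for i in range(n_subjects):
        subj_corr = target_corr.copy()
        noise = rng.normal(0.0, 1.0, size=len(iu[0])) * sd[iu]
        subj_corr[iu] = np.clip(subj_corr[iu] + noise, -0.97, 0.97)
        subj_corr.T[iu] = subj_corr[iu]
        np.fill_diagonal(subj_corr, 1.0)
        subj_corr = _repair_psd(subj_corr)
        chol = np.linalg.cholesky(subj_corr + 1e-10 * np.eye(k))
        data[i] = rng.standard_normal((n_timepoints, k)) @ chol.T
    return GroupTimeSeries(group=group, data=data, rois=rois,
                           seed=seed if isinstance(seed, int) else None)


def _subject_pair_r(g: GroupTimeSeries) -> np.ndarray:
    """(subjects, pairs) Pearson correlations, pairs in ROISet.pairs() order."""
    k = len(g.rois.labels)
    iu = np.triu_indices(k, 1)
    out = np.empty((g.n_subjects, len(iu[0])))
    for i in range(g.n_subjects):
        out[i] = np.corrcoef(g.data[i], rowvar=False)[iu]
    return out


def fc_pipeline(a: GroupTimeSeries, b: GroupTimeSeries, alpha: float = 0.05) -> FCResult:
    """Group FC comparison: Pearson r -> Fisher Z -> Welch t -> BH-FDR."""
    if a.rois.labels != b.rois.labels:
        raise ValueError("both groups must share the same ROI set")
    if a.n_timepoints < 3 or b.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints per series")
    pairs = a.rois.pairs()
    r_a, r_b = _subject_pair_r(a), _subject_pair_r(b)
    z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)
    rows = []
    for j, (x, y) in enumerate(pairs):
        t, p = stats.ttest_ind(z_a[:, j], z_b[:, j], equal_var=False)
        if np.isnan(t):  # zero variance in both groups, equal means
            t, p = 0.0, 1.0
        rows.append(
            {
                "roi_a": x,
                "roi_b": y,
                "r_mean_a": r_a[:, j].mean(),
                "r_sd_a": r_a[:, j].std(ddof=1),
                "r_mean_b": r_b[:, j].mean(),
                "r_sd_b": r_b[:, j].std(ddof=1),
                "t": float(t),
                "p": float(p),
            }
        )
    frame = pd.DataFrame(rows)
    reject, p_fdr, _, _ = multipletests(frame["p"], alpha=alpha, method="fdr_bh")
    frame["p_fdr"] = p_fdr
    frame["significant"] = reject
    return FCResult(
        rois=a.rois,
        subject_r={a.group: r_a, b.group: r_b},
        stats=frame,
        alpha=alpha,
    )


def clinical_effects() -> dict[tuple[str, str], dict[str, float]]:
    """Printed group statistics for the three affected ROI pairs.

    Means and between-subject SDs of r for the aphasia-only (a) and
    AOS-plus-aphasia (b) groups.
    """
    return {
        ("left_ssm_lateral", "right_articulator"): {
            "r_a": 0.25, "sd_a": 0.25, "r_b": 0.01, "sd_b": 0.19,
        },
        ("left_articulator", "right_articulator"): {
            "r_a": 0.42, "sd_a": 0.32, "r_b": 0.11, "sd_b": 0.22,
        },
        ("right_ssm", "left_articulator"): {
            "r_a": 0.12, "sd_a": 0.25, "r_b": -0.09, "sd_b": 0.15,
        },
    }


def clinical_target_matrices(
    background_sd: float = 0.25, n_timepoints: int = N_TIMEPOINTS
) -> dict[str, dict]:
    """Generator parameterizations emulating the two clinical groups.

    Returns, per group, the target correlation matrix, the per-pair
    between-subject SD matrix (correlation scale) and the group size
    (16 aphasia-only, 15 AOS-plus-aphasia).  Unreported pairs get zero
    target correlation and a nominal background heterogeneity.
    """
    rois = default_rois()
    k = len(rois.labels)
    out: dict[str, dict] = {}
    for group, n_subj, key_r, key_sd in (
        ("aphasia_only", 16, "r_a", "sd_a"),
        ("aos_plus_aphasia", 15, "r_b", "sd_b"),
    ):
        corr = np.eye(k)
        sd = np.full((k, k), subject_sd_r(0.0, background_sd, n_timepoints))
        np.fill_diagonal(sd, 0.0)
        for (x, y), eff in clinical_effects().items():
            i, j = rois.index(x), rois.index(y)
            corr[i, j] = corr[j, i] = eff[key_r]
            sd[i, j] = sd[j, i] = subject_sd_r(eff[key_r], eff[key_sd], n_timepoints)
        out[group] = {"corr": corr, "subject_sd": sd, "n_subjects": n_subj}
    return out
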