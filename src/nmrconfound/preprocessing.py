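"""Feature-processing chain from raw peak table to analysis-ready matrix.

Order of operations: presence filter -> probabilistic quotient
normalization (PQN) -> QC coefficient-of-variation filter -> k-nearest-
neighbor imputation -> generalized log (GLOG) transform; optionally the
normalization reference and GLOG parameter are re-derived after a robust
PCA outlier pass over the QC and HV groups, and the chain is reapplied.
Patient (STUDY) samples are never dropped by this stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import PeakTable

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "presence_filter",
    "pqn_normalize",
    "cv_filter",
    "knn_impute",
    "glog_fit",
    "glog_apply",
    "robust_outlier_pass",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Tuning knobs of the preprocessing chain.

    presence_threshold : keep a peak iff detected in at least this fraction
        of QC samples or of HV samples (default 0.80).
    cv_threshold : remove peaks whose QC coefficient of variation exceeds
        this (default 0.30).
    knn_k : neighbors for missing-value imputation (default 10).
    glog_lambda : positive scalar, or None to fit from QC replicates.
    outlier_pass : rerun reference/lambda fitting after dropping robust-PCA
        outliers from the QC and HV groups.
    pqn_reference_role : role of the normalization reference samples.
    pqn_reference_center : restrict the reference to one center (healthy
        volunteers from a single site); None uses all samples of the role.
    cv_before_pqn : alternative stage order (CV filter on raw intensities).
    """

    presence_threshold: float = 0.80
    cv_threshold: float = 0.30
    knn_k: int = 10
    glog_lambda: float | None = None
    outlier_pass: bool = True
    pqn_reference_role: str = "HV"
    pqn_reference_center: str | None = "GYDR"
    cv_before_pqn: bool = False
    exclude_peaks: tuple = ()

    def __post_init__(self):
        if not 0 < self.presence_threshold <= 1:
            raise ValueError("presence_threshold must be in (0, 1]")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class PreprocessReport:
    """What the chain removed, flagged and fitted."""

    removed_peaks: dict = field(default_factory=dict)  # step -> list of peaks
    outlier_samples: list = field(default_factory=list)
    glog_lambda: float | None = None
    dilution_factors: pd.Series | None = None
    stage_order: list = field(default_factory=list)

    def all_removed(self) -> list:
        return [p for peaks in self.removed_peaks.values() for p in peaks]


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def presence_filter(
    table: PeakTable, meta: pd.DataFrame, threshold: float = 0.80
) -> tuple[PeakTable, list]:
    """Keep a peak iff its detected fraction reaches ``threshold`` in the
    QC group OR in the HV group (the reference groups, measured under
    controlled conditions)."""
    qc_ids = meta.loc[meta["role"] == "QC", "sample_id"]
    hv_ids = meta.loc[meta["role"] == "HV", "sample_id"]
    if len(qc_ids) == 0 and len(hv_ids) == 0:
        raise ValueError("presence filter requires QC or HV samples")
    det = table.detected()
    keep = np.zeros(table.shape[1], dtype=bool)
    for ids in (qc_ids, hv_ids):
        ids = [s for s in ids if s in table.values.index]
        if ids:
            keep |= (det.loc[ids].mean(axis=0) >= threshold).to_numpy()
    removed = table.peak_ids[~keep].tolist()
    return table.subset(peaks=table.peak_ids[keep]), removed


def pqn_normalize(
    table: PeakTable, reference_samples: Sequence[str]
) -> tuple[PeakTable, pd.Series]:
    """Probabilistic quotient normalization against a reference spectrum.

    The reference spectrum is the per-peak median over the reference
    samples, ignoring non-detects.  Each sample is divided by the median of
    its detected-peak quotients against that reference, correcting
    sample-specific dilution.  Non-detects are preserved.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("PQN reference set is empty")
    ref = table.values.loc[reference_samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = ref.median(axis=0, skipna=True)
    usable = r.notna() & (r > 0)
    if not usable.any():
        raise ValueError("PQN reference spectrum has no positive peaks")
    quotients = table.values.loc[:, usable].div(r[usable], axis=1)
    factors = quotients.median(axis=1, skipna=True)
    bad = factors.isna() | (factors <= 0)
    if bad.any():
        raise ValueError(
            "sample(s) share no detected peaks with the PQN reference: "
            f"{factors.index[bad].tolist()}"
        )
    out = table.values.div(factors, axis=0)
    return PeakTable(out), factors.rename("dilution_factor")


def cv_filter(
    table: PeakTable, qc_samples: Sequence[str], threshold: float = 0.30
) -> tuple[PeakTable, dict]:
    """Remove peaks whose coefficient of variation (sd/mean over detected
    QC replicate values) exceeds ``threshold``.  Peaks with fewer than 3
    detected QC values are removed as having insufficient QC support."""
    qc_samples = list(qc_samples)
    if len(qc_samples) < 3:
        raise ValueError("CV filter requires at least 3 QC samples")
    qc = table.values.loc[qc_samples]
    removed: dict[str, list] = {"high_cv": [], "insufficient_qc_support": []}
    keep = []
    for peak in table.peak_ids:
        vals = qc[peak].dropna().to_numpy()
        if len(vals) < 3:
            removed["insufficient_qc_support"].append(peak)
            continue
        cv = vals.std(ddof=1) / vals.mean()
        if cv > threshold:
            removed["high_cv"].append(peak)
        else:
            keep.append(peak)
    return table.subset(peaks=keep), removed


def _knn_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise root-mean-square difference over mutually detected peaks.

    NaN where two samples share no detected peak.
    """
    n = values.shape[0]
    mask = ~np.isnan(values)
    filled = np.where(mask, values, 0.0)
    # squared diffs over shared peaks via expansion
    shared = mask.astype(float) @ mask.T.astype(float)
    g = filled @ filled.T
    sq = (filled**2 @ mask.T.astype(float)) + (mask.astype(float) @ (filled**2).T) - 2 * g
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / shared)
    d[shared == 0] = np.nan
    np.fill_diagonal(d, np.inf)
    return d


def knn_impute(table: PeakTable, k: int = 10) -> PeakTable:
    """Replace each non-detect by the weighted mean of the peak's values in
    the k nearest samples (by RMS distance over mutually detected peaks)
    among samples that detect the peak; weights are 1/distance, with equal
    weights on exact ties at zero distance."""
    values = table.values.to_numpy().copy()
    n = values.shape[0]
    if k >= n:
        warnings.warn(f"k={k} >= n_samples={n}; clipped to {n - 1}", stacklevel=2)
        k = n - 1
    col_det = ~np.isnan(values)
    if not col_det.any(axis=0).all():
        bad = table.peak_ids[~col_det.any(axis=0)].tolist()
        raise ValueError(f"peak(s) with no detected value: {bad}")
    dist = _knn_distances(values)
    out = values.copy()
    miss_i, miss_j = np.where(np.isnan(values))
    for i, j in zip(miss_i, miss_j):
        cand = np.where(col_det[:, j] & np.isfinite(dist[i]))[0]
        if len(cand) == 0:
            # fall back to the peak's detected mean
            out[i, j] = values[col_det[:, j], j].mean()
            continue
        order = cand[np.argsort(dist[i, cand], kind="stable")]
        nn = order[:k]
        d = dist[i, nn]
        if np.any(d == 0):
            out[i, j] = values[nn[d == 0], j].mean()
        else:
            w = 1.0 / d
            out[i, j] = float(np.dot(w, values[nn, j]) / w.sum())
    return PeakTable(pd.DataFrame(out, index=table.sample_ids, columns=table.peak_ids))


def glog_apply(table: PeakTable, lam: float) -> PeakTable:
    """Generalized log transform g(x) = ln(x + sqrt(x^2 + lambda)).

    Strictly increasing; reduces to ln(2x) for x >> sqrt(lambda) and
    stabilizes the variance of mixed additive/multiplicative noise.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x = table.values.to_numpy()
    if np.nanmin(x) < 0:
        raise ValueError("negative intensity passed to glog")
    g = np.log(x + np.sqrt(x**2 + lam))
    return PeakTable._unchecked(
        pd.DataFrame(g, index=table.sample_ids, columns=table.peak_ids)
    )


GLOG_GRID = np.logspace(-2, 8, 25)


def glog_objective(qc: np.ndarray, lam: float) -> float:
    """Variance heterogeneity of transformed QC replicates: the squared
    coefficient of variation of the per-peak replicate variances (small
    when the transform equalizes technical variance across the intensity
    range; normalizing by the mean variance keeps the criterion invariant
    to the overall shrinkage a large lambda applies)."""
    g = np.log(qc + np.sqrt(qc**2 + lam))
    per_peak_var = g.var(axis=0, ddof=1)
    m = per_peak_var.mean()
    if m <= 0:
        return np.inf
    return float(per_peak_var.var() / m**2)

def glog_fit(qc_table: PeakTable, grid: np.ndarray = GLOG_GRID) -> float:
    """Pick the GLOG lambda minimizing replicate-variance heterogeneity
    over a log-spaced grid of candidate values."""
    qc = qc_table.values.to_numpy()
    if qc.shape[0] < 3:
        raise ValueError("glog_fit requires >= 3 QC replicates")
    if np.isnan(qc).any():
        raise ValueError("glog_fit requires a complete (imputed) QC table")
    obj = np.array([glog_objective(qc, lam) for lam in grid])
    if np.ptp(obj) < 1e-15 * max(obj.max(), 1.0):
        warnings.warn(
            "QC variance already homogeneous; returning smallest grid lambda",
            stacklevel=2,
        )
        return float(grid[0])
    return float(grid[int(np.argmin(obj))])


def robust_outlier_pass(
    table: PeakTable,
    quantile: float = 0.975,
    max_components: int = 5,
    var_explained: float = 0.90,
) -> list:
    """Flag outlying samples of one group via PCA on robustly standardized
    data (median centering, MAD scaling).

    A sample is flagged when its score distance (Mahalanobis distance in
    the retained PC space) exceeds the chi-square quantile cutoff, or its
    orthogonal distance exceeds the Box-type normal-quantile cutoff on
    OD^(2/3).
    """
    X = table.values.to_numpy()
    if X.shape[0] < 10:
        raise ValueError("outlier pass requires >= 10 samples")
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
    med = np.median(X, axis=0)
    mad = stats.median_abs_deviation(X, axis=0, scale="normal")
    mad[mad == 0] = 1.0
    Z = (X - med) / mad
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    evar = (s**2) / (s**2).sum()
    ncomp = int(np.searchsorted(np.cumsum(evar), var_explained) + 1)
    ncomp = min(ncomp, max_components, rank)
    if ncomp < min(max_components, X.shape[1]):
        pass  # rank-reduced quietly; cutoffs adapt to ncomp
    T = U[:, :ncomp] * s[:ncomp]
    eig = (s[:ncomp] ** 2) / (X.shape[0] - 1)
    sd = np.sqrt(((T**2) / eig).sum(axis=1))
    sd_cut = np.sqrt(stats.chi2.ppf(quantile, ncomp))
    resid = Zc - T @ Vt[:ncomp]
    od = np.linalg.norm(resid, axis=1)
    flagged_od = np.zeros(len(od), dtype=bool)
    if od.max() > 1e-12:
        od23 = od ** (2 / 3)
        mu, sigma = np.median(od23), stats.median_abs_deviation(od23, scale="normal")
        if sigma > 0:
            od_cut = (mu + sigma * stats.norm.ppf(quantile)) ** (3 / 2)
            flagged_od = od > od_cut
    flagged = (sd > sd_cut) | flagged_od
    return table.sample_ids[flagged].tolist()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _pqn_reference_ids(meta: pd.DataFrame, config: PreprocessConfig, exclude=()):
    sel = meta["role"] == config.pqn_reference_role
    if config.pqn_reference_center is not None:
        centered = sel & (meta["center"] == config.pqn_reference_center)
        if centered.any():
            sel = centered
    ids = [s for s in meta.loc[sel, "sample_id"] if s not in set(exclude)]
    return ids


def _run_chain(
    table: PeakTable,
    meta: pd.DataFrame,
    config: PreprocessConfig,
    drop_samples: Iterable[str],
    report: PreprocessReport,
) -> PeakTable:
    drop_set = set(drop_samples)
    keep_ids = [s for s in table.sample_ids if s not in drop_set]
    work = table.subset(samples=keep_ids)
    meta = meta[meta["sample_id"].isin(keep_ids)]
    qc_ids = [s for s in meta.loc[meta["role"] == "QC", "sample_id"]]

    if config.exclude_peaks:
        dropped = [p for p in config.exclude_peaks if p in work.peak_ids]
        work = work.drop_peaks(dropped)
        report.removed_peaks["excluded_upfront"] = dropped
        report.stage_order.append("peak_exclusion")

    work, removed = presence_filter(work, meta, config.presence_threshold)
    report.removed_peaks["presence_filter"] = removed
    report.stage_order.append("presence_filter")

    if config.cv_before_pqn:
        work, removed_cv = cv_filter(work, qc_ids, config.cv_threshold)
        for reason, peaks in removed_cv.items():
            report.removed_peaks[f"cv_filter:{reason}"] = peaks
        report.stage_order.append("cv_filter")

    ref_ids = _pqn_reference_ids(meta, config, exclude=drop_set)
    work, factors = pqn_normalize(work, ref_ids)
    report.dilution_factors = factors
    report.stage_order.append("pqn")

    if not config.cv_before_pqn:
        work, removed_cv = cv_filter(work, qc_ids, config.cv_threshold)
        for reason, peaks in removed_cv.items():
            report.removed_peaks[f"cv_filter:{reason}"] = peaks
        report.stage_order.append("cv_filter")

    work = knn_impute(work, config.knn_k)
    report.stage_order.append("knn_impute")

    if config.glog_lambda is not None:
        lam = config.glog_lambda
    else:
        lam = glog_fit(work.subset(samples=[s for s in qc_ids if s in work.sample_ids]))
    report.glog_lambda = lam
    work = glog_apply(work, lam)
    report.stage_order.append("glog")
    return work


def preprocess_pipeline(
    table: PeakTable, meta: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[PeakTable, PreprocessReport]:
    """Run the full chain; if ``outlier_pass`` is set, flag robust-PCA
    outliers in the processed QC and HV groups, then recompute the PQN
    reference and GLOG lambda without them and reapply the chain.  STUDY
    samples are never dropped."""
    config = config or PreprocessConfig()
    report = PreprocessReport()
    processed = _run_chain(table, meta, config, drop_samples=(), report=report)
    if not config.outlier_pass:
        return processed, report

    outliers: list[str] = []
    for role in ("HV", "QC"):
        ids = [
            s
            for s in meta.loc[meta["role"] == role, "sample_id"]
            if s in processed.sample_ids
        ]
        if len(ids) >= 10:
            outliers += robust_outlier_pass(processed.subset(samples=ids))
    if not outliers:
        return processed, report
    report2 = PreprocessReport(outlier_samples=sorted(outliers))
    processed = _run_chain(table, meta, config, drop_samples=outliers, report=report2)
    report2.stage_order = report.stage_order + ["outlier_pass"] + report2.stage_order
    return processed, report2
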