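"""Confounder investigation and correction.

Three complementary strategies for a multicenter design in which center
cluster and sample storage age are entangled with disease group:

* Approach A — ANOVA-simultaneous component analysis (ASCA): decompose the
  data matrix into design-factor effect matrices and remove the cluster
  effect (and the cluster x disease interaction) before modelling.
* Approach B — build an inclusive confounder signature (PLS-DA on
  cluster / sample-age groupings, PCA contrast for the small flagged
  subgroup) and exclude those peaks up front.
* Approach C — exclude whole centers most affected by the confounder and
  model the retained, more homogeneous cohort; the excluded samples serve
  as an external test set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cohort import PeakTable
from .pls import PLSDA, SparsePLSDA, pca
from .preprocessing import PreprocessConfig, preprocess_pipeline
from .validation import (
    CVConfig,
    CV2Result,
    SplsdaSignature,
    cv2_evaluate,
    scenario_subset,
    signature_from_splsda,
    signature_from_vip,
)

__all__ = [
    "ASCA",
    "AscaDecomposition",
    "asca_decompose",
    "asca_correct",
    "confounder_design",
    "confounder_signature",
    "frpa1_pca_contrast",
    "approach_b_run",
    "approach_c_run",
    "compare_signatures",
    "assign_clusters_by_pc1",
]


# ---------------------------------------------------------------------------
# ASCA (Approach A)
# ---------------------------------------------------------------------------

@dataclass
class AscaDecomposition:
    """Additive decomposition of a centered data matrix into design-factor
    effect matrices, an optional interaction, and residuals.

    ``centered == sum(effects.values()) + residual`` holds exactly; every
    effect matrix has zero column means.
    """

    grand_mean: np.ndarray
    effects: dict  # effect name -> (n, p) matrix
    residual: np.ndarray
    ss: dict  # effect name -> sum of squares
    level_effects: dict  # effect name -> {level or (levelA, levelB): row}

    def reconstruct(self) -> np.ndarray:
        return sum(self.effects.values()) + self.residual

    def effect_rows(self, name: str, levels) -> np.ndarray:
        """Per-sample effect rows for new samples with the given factor
        levels (a vector for a main effect, a pair of vectors for an
        interaction).  Unseen levels contribute a zero row."""
        lut = self.level_effects[name]
        p = len(self.grand_mean)
        if "x" in name and name not in self.ss:  # defensive; not reached
            raise KeyError(name)
        if isinstance(levels, tuple) and len(levels) == 2 and not np.isscalar(levels[0]):
            keys = list(zip(np.asarray(levels[0]), np.asarray(levels[1])))
        else:
            keys = list(np.asarray(levels))
        return np.vstack([lut.get(k, np.zeros(p)) for k in keys])

    def summary(self) -> pd.DataFrame:
        total = sum(self.ss.values())
        rows = [
            {"effect": name, "ss": s, "fraction": s / total if total > 0 else np.nan}
            for name, s in self.ss.items()
        ]
        return pd.DataFrame(rows)


class ASCA:
    """ANOVA-simultaneous component analysis model.

    Parameters
    ----------
    X : (n, p) data matrix.
    factors : mapping name -> length-n categorical vector.
    with_interaction : include the pairwise interaction term (requires
        exactly two factors and a full crossing: every combination of
        observed levels must contain at least one sample).
    """

    def __init__(self, X, factors: dict, with_interaction: bool = False):
        self.X = np.asarray(X, dtype=float)
        if not factors:
            raise ValueError("need at least one design factor")
        self.factors = {k: np.asarray(v) for k, v in factors.items()}
        for name, v in self.factors.items():
            if len(v) != self.X.shape[0]:
                raise ValueError(f"factor {name!r} length mismatch")
        if with_interaction and len(self.factors) != 2:
            raise ValueError("interaction term requires exactly two factors")
        self.with_interaction = with_interaction

    def fit(self) -> AscaDecomposition:
        X = self.X
        grand = X.mean(axis=0)
        Xc = X - grand
        effects: dict[str, np.ndarray] = {}
        level_effects: dict[str, dict] = {}
        for name, fac in self.factors.items():
            eff = np.zeros_like(Xc)
            level_effects[name] = {}
            for lv in np.unique(fac):
                m = fac == lv
                row = Xc[m].mean(axis=0)
                eff[m] = row
                level_effects[name][lv] = row
            effects[name] = eff
        if self.with_interaction:
            (na, fa), (nb, fb) = self.factors.items()
            for la, lb in itertools.product(np.unique(fa), np.unique(fb)):
                if not np.any((fa == la) & (fb == lb)):
                    raise ValueError(
                        f"empty design cell ({na}={la!r}, {nb}={lb!r}); "
                        "interaction effects cannot be estimated"
                    )
            iname = f"{na}x{nb}"
            inter = np.zeros_like(Xc)
            level_effects[iname] = {}
            for la, lb in itertools.product(np.unique(fa), np.unique(fb)):
                m = (fa == la) & (fb == lb)
                row = (
                    Xc[m].mean(axis=0)
                    - level_effects[na][la]
                    - level_effects[nb][lb]
                )
                inter[m] = row
                level_effects[iname][(la, lb)] = row
            effects[iname] = inter
        residual = Xc - sum(effects.values())
        ss = {name: float((eff**2).sum()) for name, eff in effects.items()}
        ss["residual"] = float((residual**2).sum())
        return AscaDecomposition(grand, effects, residual, ss, level_effects)


def asca_decompose(X, factors: dict, with_interaction: bool = False) -> AscaDecomposition:
    """Functional wrapper around :class:`ASCA`."""
    return ASCA(X, factors, with_interaction).fit()


def asca_correct(X, decomposition: AscaDecomposition, remove, levels=None) -> np.ndarray:
    """Centered X with the named effect matrices subtracted.

    The default confounder correction removes the cluster main effect and
    the cluster x disease interaction while keeping the disease effect.

    With ``levels`` (mapping effect name -> level vector for the rows of
    ``X``, a pair of vectors for an interaction) the correction is applied
    out of sample: the level means estimated in the decomposition are
    subtracted from new data.  This is the protocol for judging whether a
    removed effect is still predictable — evaluating on the very samples
    the effect was estimated from constrains their corrected group means
    to zero and biases any cross-validated classifier below chance.
    """
    remove = list(remove)
    unknown = [r for r in remove if r not in decomposition.effects]
    if unknown:
        raise ValueError(f"unknown effect(s): {unknown}")
    if levels is None and set(remove) >= set(decomposition.effects):
        if np.allclose(decomposition.residual, 0):
            raise ValueError("removing all effects would leave nothing")
    X = np.asarray(X, dtype=float)
    if levels is None:
        Xc = X - X.mean(axis=0)
        for name in remove:
            Xc = Xc - decomposition.effects[name]
        return Xc
    Xc = X - decomposition.grand_mean
    for name in remove:
        if name not in levels:
            raise ValueError(f"levels for effect {name!r} not provided")
        Xc = Xc - decomposition.effect_rows(name, levels[name])
    return Xc


def assign_clusters_by_pc1(X, center_codes) -> pd.Series:
    """Assign center clusters by 2-means on the first-principal-component
    scores of center means (ties break to the lower center code).  Cluster
    1 is the cluster containing the lowest center code among its members.
    """
    center_codes = np.asarray(center_codes)
    scores, _, _ = pca(np.asarray(X, dtype=float), ncomp=1)
    s = scores[:, 0]
    centers = np.unique(center_codes)
    means = np.array([s[center_codes == c].mean() for c in centers])
    order = np.argsort(means, kind="stable")
    # 1-D 2-means == best split point of sorted means
    best_split, best_cost = 1, np.inf
    for split in range(1, len(centers)):
        left, right = means[order[:split]], means[order[split:]]
        cost = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, split
    group = {centers[i]: (1 if k < best_split else 2) for k, i in enumerate(order)}
    # canonical numbering: the group holding the lexicographically lowest code is 1
    lowest = min(centers)
    if group[lowest] == 2:
        group = {c: 3 - g for c, g in group.items()}
    return pd.Series({c: group[c] for c in centers}, name="cluster")


# ---------------------------------------------------------------------------
# confounder signatures (Approach B ingredients)
# ---------------------------------------------------------------------------

def confounder_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Binary confounder groupings per STUDY sample: center cluster,
    flagged-subgroup membership, and sample age dichotomized at the global
    median (computed over all STUDY samples)."""
    study = meta[meta["role"] == "STUDY"].copy()
    med = study["sample_age_days"].median()
    study["age_group"] = np.where(study["sample_age_days"] > med, "above", "below")
    if "frpa1_pht" not in study.columns:
        study["frpa1_pht"] = False
    return study[["sample_id", "cluster", "frpa1_pht", "age_group"]]


def confounder_signature(
    X,
    confounder_labels,
    cfg: CVConfig | None = None,
    feature_names=None,
    threshold: float = 1.0,
    min_accuracy: float = 60.0,
) -> pd.DataFrame:
    """Inclusive feature list related to a binary confounder grouping.

    Runs CV2 PLS-DA on the confounder labels and returns the features with
    median outer-loop VIP above ``threshold``, with the direction of the
    effect (sign of the group-2 minus group-1 mean difference, groups in
    sorted label order).

    VIPs are only interpreted when the model has predictive ability: if
    the mean CV2 balanced accuracy does not reach ``min_accuracy``
    percent, the grouping carries no demonstrable effect and an empty list
    is returned with a warning.  (Without this gate the VIP > 1 rule would
    flag roughly a third of all features even for a null grouping, since
    VIP^2 averages to 1 by construction.)"""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(confounder_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("confounder grouping must be binary")
    result = cv2_evaluate(X, labels, "plsda", cfg or CVConfig())
    if result.balanced_accuracy.mean() < min_accuracy:
        warnings.warn(
            "confounder grouping shows no predictive ability "
            f"(balanced accuracy {result.balanced_accuracy.mean():.1f} < "
            f"{min_accuracy}); returning an empty signature",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["feature", "direction", "median_vip"])
    idx = signature_from_vip(result, threshold)
    diff = X[labels == groups[1]].mean(axis=0) - X[labels == groups[0]].mean(axis=0)
    names = (
        np.asarray(feature_names)
        if feature_names is not None
        else np.arange(X.shape[1])
    )
    med = np.median(result.vips, axis=0)
    return pd.DataFrame(
        {
            "feature": names[idx],
            "direction": np.sign(diff[idx]).astype(int),
            "median_vip": med[idx],
        }
    )


def frpa1_pca_contrast(
    X, flag_group, cor_cutoff: float = 0.5, min_flag_corr: float = 0.3,
    feature_names=None,
) -> pd.DataFrame:
    """Small-subgroup contrast by PCA.

    Chooses the principal component whose scores correlate most with the
    flagged-subgroup indicator (point-biserial correlation) and returns
    the features whose correlation with that component exceeds
    ``cor_cutoff``, signed as up/down in the flagged group.  Used when the
    flagged group is too small for a supervised model.
    """
    X = np.asarray(X, dtype=float)
    flag = np.asarray(flag_group, dtype=bool)
    if flag.sum() < 3:
        raise ValueError("flagged group needs >= 3 samples")
    ncomp = min(10, X.shape[0] - 1, X.shape[1])
    scores, loadings, _ = pca(X, ncomp=ncomp)
    f = flag.astype(float)
    fc = f - f.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (scores * fc[:, None]).sum(axis=0) / (
            np.linalg.norm(scores - scores.mean(axis=0), axis=0) * np.linalg.norm(fc)
        )
    r = np.nan_to_num(r)
    best = int(np.argmax(np.abs(r)))
    names = (
        np.asarray(feature_names)
        if feature_names is not None
        else np.arange(X.shape[1])
    )
    if np.abs(r[best]) <= min_flag_corr:
        warnings.warn(
            "no principal component separates the flagged group "
            f"(max |r| = {np.abs(r[best]):.2f})",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["feature", "direction", "correlation"])
    t = scores[:, best]
    Xc = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc * (t - t.mean())[:, None]).sum(axis=0) / (
            np.linalg.norm(Xc, axis=0) * np.linalg.norm(t - t.mean())
        )
    corr = np.nan_to_num(corr)
    idx = np.flatnonzero(np.abs(corr) > cor_cutoff)
    sign_flag = np.sign(r[best])
    return pd.DataFrame(
        {
            "feature": names[idx],
            "direction": (np.sign(corr[idx]) * sign_flag).astype(int),
            "correlation": np.abs(corr[idx]),
        }
    )


# ---------------------------------------------------------------------------
# Approaches B and C
# ---------------------------------------------------------------------------

@dataclass
class ApproachResult:
    cv2: CV2Result
    signature: SplsdaSignature
    excluded_peaks: list = field(default_factory=list)
    external: dict | None = None
    retained_counts: pd.Series | None = None


def _study_matrix(processed: PeakTable, meta: pd.DataFrame, sample_ids):
    ids = [s for s in sample_ids if s in processed.sample_ids]
    return processed.values.loc[ids].to_numpy(), ids


def build_confounder_exclusion(
    processed: PeakTable, meta: pd.DataFrame, cfg: CVConfig | None = None
) -> list:
    """Union of the cluster, sample-age and flagged-subgroup feature lists.

    Cluster grouping omits the flagged subgroup (its chemistry is distinct
    from the rest of its cluster); sample age is split at the global
    median over all STUDY samples."""
    cfg = cfg or CVConfig()
    design = confounder_design(meta)
    design = design[design["sample_id"].isin(processed.sample_ids)]
    peaks = processed.peak_ids.to_numpy()
    excluded: set = set()

    cl = design[design["cluster"].isin([1, 2]) & ~design["frpa1_pht"]]
    X, _ = _study_matrix(processed, meta, cl["sample_id"])
    sig = confounder_signature(
        X, cl["cluster"].astype(int).to_numpy(), cfg, feature_names=peaks
    )
    excluded |= set(sig["feature"])

    X, ids = _study_matrix(processed, meta, design["sample_id"])
    age = design.set_index("sample_id").loc[ids, "age_group"].to_numpy()
    sig = confounder_signature(X, age, cfg, feature_names=peaks)
    excluded |= set(sig["feature"])

    cl1 = design[design["cluster"] == 1]
    if cl1["frpa1_pht"].sum() >= 3:
        X, ids = _study_matrix(processed, meta, cl1["sample_id"])
        flag = cl1.set_index("sample_id").loc[ids, "frpa1_pht"].to_numpy()
        sig = frpa1_pca_contrast(X, flag, feature_names=peaks)
        excluded |= set(sig["feature"])
    return sorted(excluded)


def approach_b_run(
    table: PeakTable,
    meta: pd.DataFrame,
    scenario: str,
    cfg: CVConfig | None = None,
    pre_config: PreprocessConfig | None = None,
    exclude_peaks=None,
) -> ApproachResult:
    """Confounder-peak exclusion: derive the inclusive confounder feature
    list (unless supplied), exclude those peaks at the start of
    preprocessing, and re-run CV2 and signature extraction on the reduced
    matrix."""
    from dataclasses import replace

    cfg = (cfg or CVConfig()).for_scenario(scenario)
    pre_config = pre_config or PreprocessConfig()
    if exclude_peaks is None:
        processed, _ = preprocess_pipeline(table, meta, pre_config)
        exclude_peaks = build_confounder_exclusion(processed, meta, cfg)
    exclude_peaks = list(exclude_peaks)
    reduced_cfg = replace(pre_config, exclude_peaks=tuple(exclude_peaks))
    processed, _ = preprocess_pipeline(table, meta, reduced_cfg)
    if processed.shape[1] == 0:
        raise ValueError("confounder exclusion removed every peak")
    ids_all, y_all = scenario_subset(meta, scenario)
    label_of = dict(zip(ids_all, y_all))
    X, ids = _study_matrix(processed, meta, ids_all)
    y = np.array([label_of[s] for s in ids])
    cv2 = cv2_evaluate(X, y, "splsda", cfg)
    signature = signature_from_splsda(
        X, y, cfg, feature_names=processed.peak_ids.to_numpy()
    )
    return ApproachResult(cv2=cv2, signature=signature, excluded_peaks=exclude_peaks)


def approach_c_run(
    table: PeakTable,
    meta: pd.DataFrame,
    keep_centers,
    scenario: str,
    cfg: CVConfig | None = None,
    pre_config: PreprocessConfig | None = None,
) -> ApproachResult:
    """Whole-center exclusion: CV2 on the retained centers only, plus an
    external prediction of the excluded patients using a model refit on
    all retained samples with the CV2-modal hyperparameters."""
    keep_centers = set(keep_centers)
    if not keep_centers:
        raise ValueError("keep_centers must be non-empty")
    cfg = (cfg or CVConfig()).for_scenario(scenario)
    pre_config = pre_config or PreprocessConfig()
    processed, _ = preprocess_pipeline(table, meta, pre_config)
    ids_all, y_all = scenario_subset(meta, scenario)
    label_of = dict(zip(ids_all, y_all))
    centers = meta.set_index("sample_id")["center"]
    retained = [s for s in ids_all if centers[s] in keep_centers and s in processed.sample_ids]
    excluded = [s for s in ids_all if centers[s] not in keep_centers and s in processed.sample_ids]
    y_ret = np.array([label_of[s] for s in retained])
    present = set(y_ret)
    expected = set(np.unique(y_all))
    if present != expected:
        raise ValueError(
            f"scenario {scenario}: class(es) {sorted(expected - present)} "
            "absent from the retained centers"
        )
    X_ret = processed.values.loc[retained].to_numpy()
    cv2 = cv2_evaluate(X_ret, y_ret, "splsda", cfg)
    signature = signature_from_splsda(
        X_ret, y_ret, cfg, feature_names=processed.peak_ids.to_numpy()
    )
    counts = pd.Series(y_ret).value_counts()

    external = None
    if excluded:
        a, keepx = cv2.modal_ncomp(), cv2.modal_keepx()
        res = SparsePLSDA(
            X_ret, y_ret, a, keep_x=keepx if keepx is not None else X_ret.shape[1]
        ).fit()
        X_ext = processed.values.loc[excluded].to_numpy()
        y_ext = np.array([label_of[s] for s in excluded])
        pred = res.predict(X_ext, a)
        acc = float((pred == y_ext).mean()) * 100
        external = {"accuracy": acc, "n": len(y_ext)}
        if len(expected) == 2 and cv2.positive is not None:
            pos = cv2.positive
            neg = [c for c in expected if c != pos][0]
            if (y_ext == pos).any():
                external["sensitivity"] = float(
                    (pred[y_ext == pos] == pos).mean()
                ) * 100
            if (y_ext == neg).any():
                external["specificity"] = float(
                    (pred[y_ext == neg] == neg).mean()
                ) * 100
    return ApproachResult(
        cv2=cv2,
        signature=signature,
        external=external,
        retained_counts=counts,
    )


def compare_signatures(
    signatures: dict, exclusion: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cross-approach signature comparison.

    ``signatures`` maps approach name -> Series of per-metabolite
    coefficients (0 or NaN = not selected).  Returns one row per
    metabolite with its selected-by set, per-approach signs, sign
    agreement among selecting approaches, and the confounder flag."""
    approaches = list(signatures)
    metabolites: list = []
    for s in signatures.values():
        metabolites += [m for m in s.index if m not in metabolites]
    confounded = set(exclusion["metabolite"]) if exclusion is not None else set()
    rows = []
    for m in metabolites:
        sel, signs = [], {}
        for a in approaches:
            v = signatures[a].get(m, np.nan)
            if pd.notna(v) and v != 0:
                sel.append(a)
                signs[a] = int(np.sign(v))
        rows.append(
            {
                "metabolite": m,
                "selected_by": tuple(sel),
                "n_selected": len(sel),
                **{f"sign_{a}": signs.get(a, 0) for a in approaches},
                "sign_agreement": len(set(signs.values())) <= 1,
                "confounder": m in confounded,
            }
        )
    return pd.DataFrame(rows)
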