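"""Double cross-validation (CV2) for (sparse) PLS-DA, repeat-level
confidence intervals, and signature extraction.

The outer loop estimates prediction performance on left-out folds; for
each outer training set an inner k-fold selects the hyperparameters (the
minimum number of components attaining the maximum inner accuracy, and the
keepX cap for the sparse variant).  The outer loop is repeated with
re-randomized folds; metrics are summarized as mean and 95% one-sample-t
confidence interval across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pls import PLSDA, SparsePLSDA

__all__ = [
    "CVConfig",
    "CV2Result",
    "stratified_kfold",
    "cv2_evaluate",
    "metrics_ci",
    "signature_from_vip",
    "signature_from_splsda",
    "SplsdaSignature",
    "scenario_subset",
    "SCENARIOS",
]

#: Scenario name -> class labels; "EHT" pools PA+PPGL+CS.
SCENARIOS = ("EHT-PHT", "PA-PHT", "CS-PHT", "PPGL-PHT", "ALL-ALL")

#: Fold-count overrides for high class imbalance.
IMBALANCE_OVERRIDES = {"CS-PHT": (7, 6), "high_imbalance": (6, 5)}


@dataclass
class CVConfig:
    """Fold counts, repeats and hyperparameter grids for CV2.

    Defaults follow the study protocol: 8 outer / 7 inner folds, one inner
    repeat, 50 outer repeats, at most 10 latent variables.  Scenarios with
    high class imbalance use reduced fold counts via
    ``imbalance_overrides``.
    """

    outer_k: int = 8
    inner_k: int = 7
    outer_repeats: int = 50
    inner_repeats: int = 1
    max_ncomp: int = 10
    keepx_grid: tuple = (1, 2, 5, 10, 15, 20, None)  # None = all features
    imbalance_overrides: dict = field(
        default_factory=lambda: dict(IMBALANCE_OVERRIDES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.outer_repeats < 1 or self.inner_repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.inner_k < 2 or self.outer_k < 2:
            raise ValueError("fold counts must be >= 2")

    def for_scenario(self, scenario: str) -> "CVConfig":
        if scenario in self.imbalance_overrides:
            ok, ik = self.imbalance_overrides[scenario]
            return replace(self, outer_k=ok, inner_k=ik)
        return self


def stratified_kfold(labels, k: int, rng) -> np.ndarray:
    """Class-stratified fold assignment (sizes differ by <= 1 per class).

    ``rng`` is a numpy Generator or a seed.  ``k`` above the smallest class
    count is reduced with a warning so every training split contains every
    class.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("stratified folds need >= 2 samples per class")
    if k > min_count:
        warnings.warn(
            f"k={k} exceeds smallest class count {min_count}; reduced", stacklevel=2
        )
        k = min_count
    folds = np.empty(len(labels), dtype=int)
    start = 0
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        # rotate the starting fold between classes to even out fold sizes
        folds[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)
    return folds


@dataclass
class CV2Result:
    """Per-outer-repeat confusion matrices, metrics, chosen
    hyperparameters, and outer-fold VIP distributions."""

    classes: np.ndarray
    confusion: np.ndarray  # (repeats, g, g): rows true, cols predicted
    balanced_accuracy: np.ndarray  # (repeats,), percent
    tp_rates: np.ndarray  # (repeats, g), percent
    chosen_ncomp: list  # per repeat: list per outer fold
    chosen_keepx: list
    vips: np.ndarray  # (repeats * outer folds, p)
    positive: object | None
    config: CVConfig

    @property
    def sensitivity(self) -> np.ndarray:
        """Percent TP rate of the positive (disease) class."""
        if self.positive is None:
            raise ValueError("sensitivity defined for binary scenarios only")
        k = int(np.where(self.classes == self.positive)[0][0])
        return self.tp_rates[:, k]

    @property
    def specificity(self) -> np.ndarray:
        if self.positive is None or len(self.classes) != 2:
            raise ValueError("specificity defined for binary scenarios only")
        k = int(np.where(self.classes != self.positive)[0][0])
        return self.tp_rates[:, k]

    def modal_ncomp(self) -> int:
        vals = [a for rep in self.chosen_ncomp for a in rep]
        uniq, counts = np.unique(vals, return_counts=True)
        return int(uniq[counts == counts.max()].min())

    def modal_keepx(self):
        vals = [k for rep in self.chosen_keepx for k in rep if k is not None]
        if not vals:
            return None
        uniq, counts = np.unique(vals, return_counts=True)
        return int(uniq[counts == counts.max()].min())

    def summary(self) -> pd.DataFrame:
        """Metric table (percent scale) with 95% CIs across repeats."""
        rows = [("balanced_accuracy", *metrics_ci(self.balanced_accuracy))]
        if self.positive is not None and len(self.classes) == 2:
            rows.append(("sensitivity", *metrics_ci(self.sensitivity)))
            rows.append(("specificity", *metrics_ci(self.specificity)))
        else:
            for k, c in enumerate(self.classes):
                rows.append((f"tp_rate_{c}", *metrics_ci(self.tp_rates[:, k])))
        return pd.DataFrame(rows, columns=["metric", "mean", "ci95_low", "ci95_high"])

    def render(self) -> str:
        """Metrics as 'mean (lo-hi)' rounded to integers, percent scale."""
        df = self.summary()
        return "\n".join(
            f"{r.metric}: {r.mean:.0f} ({r.ci95_low:.0f}-{r.ci95_high:.0f})"
            for r in df.itertuples()
        )


def metrics_ci(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean and 95% one-sample-t confidence interval across repeats."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 repeats for a confidence interval")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        return m, m, m
    half = stats.t.ppf(0.975, len(v) - 1) * sd / np.sqrt(len(v))
    return m, m - half, m + half


def _fit_family(X, y, ncomp, keepx):
    if keepx is None:
        return PLSDA(X, y, ncomp).fit()
    return SparsePLSDA(X, y, ncomp, keep_x=min(keepx, X.shape[1])).fit()


def _select_inner(X, y, cfg: CVConfig, sparse: bool, rng) -> tuple[int, object]:
    """Inner k-fold hyperparameter selection.

    Picks the (keepX, ncomp) cell with maximum overall inner accuracy;
    ties resolve to the minimum ncomp, then the smallest keepX.
    """
    classes, counts = np.unique(y, return_counts=True)
    p = X.shape[1]
    grid = sorted(
        {min(k, p) if k is not None else p for k in cfg.keepx_grid}
    ) if sparse else [None]
    max_a = min(cfg.max_ncomp, p)
    correct = np.zeros((len(grid), max_a))
    total = 0
    for _ in range(cfg.inner_repeats):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            folds = stratified_kfold(y, cfg.inner_k, rng)
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            a_cap = min(max_a, int(tr.sum()) - 1)
            for gi, keepx in enumerate(grid):
                res = _fit_family(X[tr], y[tr], a_cap, keepx)
                for a in range(1, a_cap + 1):
                    pred = res.predict(X[te], a)
                    correct[gi, a - 1] += (pred == y[te]).sum()
            total += int(te.sum())
    acc = correct / total
    best = acc.max()
    # minimum ncomp attaining the max, then smallest keepX
    cand = np.argwhere(acc >= best - 1e-12)
    a_best = cand[:, 1].min() + 1
    g_best = cand[cand[:, 1] == a_best - 1][:, 0].min()
    keepx = grid[g_best] if sparse else None
    return int(a_best), keepx


def cv2_evaluate(
    X,
    y,
    model_family: str = "plsda",
    cfg: CVConfig | None = None,
    positive=None,
) -> CV2Result:
    """Estimate classification performance by double cross-validation.

    For every outer repeat: split class-stratified outer folds; select
    hyperparameters by inner cross-validation within each outer training
    set; refit on the outer training set and predict the held-out fold by
    Mahalanobis distance in score space.  Returns per-repeat confusion
    matrices and metrics plus the VIP vectors of every refit outer model.

    ``positive`` names the disease class of a binary scenario (defaults to
    the non-PHT class when PHT is present).
    """
    cfg = cfg or CVConfig()
    if model_family not in ("plsda", "splsda"):
        raise ValueError("model_family must be 'plsda' or 'splsda'")
    sparse = model_family == "splsda"
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    g = len(classes)
    if g < 2:
        raise ValueError("CV2 needs >= 2 classes")
    if positive is None and g == 2 and "PHT" in classes:
        positive = classes[classes != "PHT"][0]
    cls_index = {c: k for k, c in enumerate(classes)}

    n, p = X.shape
    reps = cfg.outer_repeats
    confusion = np.zeros((reps, g, g), dtype=int)
    chosen_ncomp, chosen_keepx, vip_store = [], [], []
    for r in range(reps):
        rng = np.random.default_rng([cfg.seed, r])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            folds = stratified_kfold(y, cfg.outer_k, rng)
        rep_ncomp, rep_keepx = [], []
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            a, keepx = _select_inner(X[tr], y[tr], cfg, sparse, rng)
            res = _fit_family(X[tr], y[tr], a, keepx)
            pred = res.predict(X[te], a)
            for yt, yp in zip(y[te], pred):
                confusion[r, cls_index[yt], cls_index[yp]] += 1
            rep_ncomp.append(a)
            rep_keepx.append(keepx)
            vip_store.append(res.vip(a))
        chosen_ncomp.append(rep_ncomp)
        chosen_keepx.append(rep_keepx)

    with np.errstate(invalid="ignore"):
        tp = 100.0 * np.diagonal(confusion, axis1=1, axis2=2) / confusion.sum(axis=2)
    bal = tp.mean(axis=1)
    return CV2Result(
        classes=classes,
        confusion=confusion,
        balanced_accuracy=bal,
        tp_rates=tp,
        chosen_ncomp=chosen_ncomp,
        chosen_keepx=chosen_keepx,
        vips=np.vstack(vip_store),
        positive=positive,
        config=cfg,
    )


def signature_from_vip(
    result: CV2Result, threshold: float = 1.0, feature_names=None
) -> list:
    """Features whose median VIP across all outer-fold models strictly
    exceeds ``threshold``."""
    if result.vips.size == 0:
        raise ValueError("CV2 result carries no VIP vectors")
    med = np.median(result.vips, axis=0)
    idx = np.flatnonzero(med > threshold)
    if feature_names is None:
        return idx.tolist()
    feature_names = np.asarray(feature_names)
    return feature_names[idx].tolist()


@dataclass
class SplsdaSignature:
    """Signature model fit on the full sample set after repeated single CV."""

    feature_names: np.ndarray | None
    coef: np.ndarray  # per-feature contrast coefficient (binary) or (p, g)
    ncomp: int
    keep_x: object
    positive: object | None

    def nonzero(self) -> np.ndarray:
        c = self.coef if self.coef.ndim == 1 else np.abs(self.coef).sum(axis=1)
        return np.flatnonzero(c)

    def as_series(self):
        names = (
            self.feature_names
            if self.feature_names is not None
            else np.arange(len(self.coef))
        )
        if self.coef.ndim == 1:
            return pd.Series(self.coef, index=names, name="coefficient")
        return pd.DataFrame(self.coef, index=names)


def signature_from_splsda(
    X, y, cfg: CVConfig | None = None, feature_names=None, positive=None
) -> SplsdaSignature:
    """Extract the sparse-PLS-DA signature on the total sample set.

    Hyperparameters come from repeated single cross-validation over all
    samples (same repeat count and fold size as the CV2 inner loop): the
    modal ncomp (ties to the smaller) and the modal keepX across repeats.
    The final model is refit on all samples; the coefficient vector is the
    positive-minus-control class contrast for binary scenarios.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if positive is None and len(classes) == 2 and "PHT" in classes:
        positive = classes[classes != "PHT"][0]
    picks = []
    for r in range(cfg.outer_repeats):
        rng = np.random.default_rng([cfg.seed, 7919, r])
        picks.append(_select_inner(X, y, cfg, sparse=True, rng=rng))
    ncomps = np.array([a for a, _ in picks])
    keepxs = np.array([k for _, k in picks])
    uniq, counts = np.unique(ncomps, return_counts=True)
    ncomp = int(uniq[counts == counts.max()].min())
    uniq, counts = np.unique(keepxs, return_counts=True)
    keepx = int(uniq[counts == counts.max()].min())
    res = SparsePLSDA(X, y, ncomp, keep_x=keepx).fit()
    if len(classes) == 2 and positive is not None:
        negative = classes[classes != positive][0]
        coef = res.contrast_coef(positive, negative)
    else:
        coef = res.coefficients()
    return SplsdaSignature(
        feature_names=None if feature_names is None else np.asarray(feature_names),
        coef=coef,
        ncomp=ncomp,
        keep_x=keepx,
        positive=positive,
    )


def scenario_subset(meta: pd.DataFrame, scenario: str):
    """STUDY sample ids and class labels for a named comparison scenario.

    ``EHT-PHT`` pools PA/PPGL/CS into EHT; ``ALL-ALL`` keeps all four
    disease groups as separate classes.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    study = meta[meta["role"] == "STUDY"].copy()
    if scenario == "ALL-ALL":
        sel = study
        labels = sel["disease"]
    else:
        grp, ctrl = scenario.split("-")
        if grp == "EHT":
            sel = study[study["disease"].isin(("PA", "PPGL", "CS", ctrl))]
            labels = sel["disease"].where(sel["disease"] == ctrl, "EHT")
        else:
            sel = study[study["disease"].isin((grp, ctrl))]
            labels = sel["disease"]
    present = set(labels)
    expected = (
        {"PHT", "PA", "PPGL", "CS"} if scenario == "ALL-ALL" else set(scenario.split("-"))
    )
    missing = expected - present
    if missing:
        raise ValueError(f"scenario {scenario}: class(es) {sorted(missing)} absent")
    return sel["sample_id"].to_numpy(), labels.to_numpy()
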