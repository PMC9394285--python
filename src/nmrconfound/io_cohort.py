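"""Peak-table and cohort metadata I/O, validation and summary statistics.

A *peak table* is a samples x peaks matrix of nonnegative NMR peak
intensities in which a cell may be a *non-detect* (the peak fell below the
detection limit in that sample).  Non-detects are carried as NaN and are
semantically distinct from a measured zero.  Sample metadata records the
study design: role (STUDY patient, pooled-plasma QC replicate, or healthy
volunteer HV), disease group, center of origin, center cluster, sample age
in days (storage time before acquisition), analytical batch and run order,
patient sex and age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "PeakTable",
    "read_peak_table",
    "validate_meta",
    "cohort_summary",
    "count_after_center_filter",
    "apply_exclusion_arithmetic",
    "signature_confounder_overlap",
    "fisher_exact_rc",
    "load_table1_counts",
    "load_table3_signature",
    "load_table4_exclusion",
    "meta_from_center_counts",
    "ROLES",
    "DISEASES",
    "META_COLUMNS",
]

ROLES = ("STUDY", "QC", "HV")
DISEASES = ("PHT", "PA", "PPGL", "CS")
#: EHT is the pool of the three endocrine forms.
EHT_DISEASES = ("PA", "PPGL", "CS")

META_COLUMNS = [
    "sample_id",
    "role",
    "disease",
    "center",
    "cluster",
    "sample_age_days",
    "batch",
    "run_order",
    "sex",
    "patient_age",
]

#: Samples per batch beyond which QC replicates were seen to drift.
RUN_ORDER_LIMIT = 18


class PeakTable:
    """Samples x peaks intensity matrix with explicit non-detects.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns are peaks labelled by chemical shift as a
        3-decimal ppm string (e.g. ``"2.356"``).  NaN cells are non-detects.

    Raises
    ------
    ValueError
        On duplicate sample/peak identifiers, negative or non-finite
        intensities, or peak labels that do not parse as ppm in (-1, 11).
    """

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate peak id(s): {dup}")
        try:
            ppm = values.columns.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"peak labels must parse as ppm numbers: {exc}")
        if ((ppm <= -1) | (ppm >= 11)).any():
            bad = values.columns[(ppm <= -1) | (ppm >= 11)].tolist()
            raise ValueError(f"ppm labels outside (-1, 11): {bad}")
        arr = values.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            i, j = np.argwhere(~finite)[0]
            raise ValueError(
                f"non-finite intensity at sample {values.index[i]!r}, "
                f"peak {values.columns[j]!r}"
            )
        neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative intensity {arr[i, j]} at sample "
                f"{values.index[i]!r}, peak {values.columns[j]!r}"
            )
        values.index.name = None
        values.columns.name = None
        self.values = values.astype(float)

    @classmethod
    def _unchecked(cls, values: pd.DataFrame) -> "PeakTable":
        """Wrap already-validated (possibly transformed, e.g. log-scale)
        values without re-running the raw-intensity checks."""
        obj = object.__new__(cls)
        values = values.copy()
        values.index.name = None
        values.columns.name = None
        obj.values = values.astype(float)
        return obj

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def ppm(self) -> np.ndarray:
        return self.values.columns.astype(float).to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_nondetect(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (non-missing) cells."""
        return self.values.notna()

    def subset(self, samples=None, peaks=None) -> "PeakTable":
        df = self.values
        if samples is not None:
            df = df.loc[list(samples)]
        if peaks is not None:
            df = df.loc[:, list(peaks)]
        return PeakTable._unchecked(df)

    def drop_peaks(self, peaks: Iterable[str]) -> "PeakTable":
        drop = [p for p in peaks if p in self.values.columns]
        return PeakTable._unchecked(self.values.drop(columns=drop))

    def copy(self) -> "PeakTable":
        return PeakTable._unchecked(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return self.values.equals(other.values)

    def __repr__(self) -> str:
        n, p = self.shape
        return f"PeakTable({n} samples x {p} peaks, {self.n_nondetect()} non-detects)"

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, missing_token: str = "", sep: str = ",") -> None:
        """Write the table; non-detects become ``missing_token``."""
        self.values.to_csv(path, na_rep=missing_token, sep=sep, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, missing_token: str = "", sep: str = ",") -> "PeakTable":
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=[missing_token],
            keep_default_na=False,
        )
        return cls(df)


def read_peak_table(path, missing_token: str = "", sep: str = ",") -> PeakTable:
    """Read a delimited peak table (header of peak ids, one row per sample).

    ``missing_token`` cells become non-detects; a literal ``"0"`` is a
    measured zero, never a non-detect.
    """
    return PeakTable.from_csv(path, missing_token=missing_token, sep=sep)


def validate_meta(meta: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a sample metadata table against the design contract.

    STUDY samples must carry a disease group; QC/HV must not.  The
    (batch, run_order) pair is unique, and run orders past the drift limit
    only raise a warning.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s) in metadata: {dup}")
    bad_role = ~meta["role"].isin(ROLES)
    if bad_role.any():
        raise ValueError(f"unknown role(s): {meta.loc[bad_role, 'role'].unique().tolist()}")
    study = meta["role"] == "STUDY"
    if strict:
        if meta.loc[study, "disease"].isna().any():
            raise ValueError("STUDY sample(s) without a disease group")
        if meta.loc[~study, "disease"].notna().any():
            raise ValueError("QC/HV sample(s) carry a disease group")
        if meta.duplicated(subset=["batch", "run_order"]).any():
            raise ValueError("(batch, run_order) pairs are not unique")
    over = meta["run_order"] > RUN_ORDER_LIMIT
    if over.any():
        warnings.warn(
            f"{int(over.sum())} sample(s) recorded past run order "
            f"{RUN_ORDER_LIMIT}; QC replicates drift beyond this point",
            stacklevel=2,
        )
    return meta


# ---------------------------------------------------------------------------
# cohort summaries (the Table 1 / Table 5 analogues)
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = ("patient_age", "sample_age_days", "batch", "run_order")
CATEGORICAL_VARS = ("sex", "center")


def _fmt_range(x: np.ndarray) -> str:
    return f"[{x.min():g}-{x.max():g}]"


def fisher_exact_rc(
    table: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Fisher exact test for an r x c contingency table.

    2x2 tables use the exact two-sided test; larger tables use a
    Monte-Carlo estimate with fixed-margin table draws: the p-value is the
    (add-one smoothed) fraction of sampled tables whose fixed-margin
    probability does not exceed that of the observed table.
    """
    table = np.asarray(table, dtype=int)
    if min(table.shape) < 2:
        return 1.0  # margins determine the table completely
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])

    def logp(t):
        t = np.asarray(t)
        rows = t.sum(axis=-1)
        cols = t.sum(axis=-2)
        n = rows.sum(axis=-1)
        return (
            gammaln(rows + 1).sum(axis=-1)
            + gammaln(cols + 1).sum(axis=-1)
            - gammaln(n + 1)
            - gammaln(t + 1).sum(axis=(-2, -1))
        )

    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    lp_obs = logp(table)
    lp = logp(draws)
    hits = int((lp <= lp_obs + 1e-9).sum())
    return (hits + 1) / (n_draws + 1)


def cohort_summary(
    meta: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    continuous: Sequence[str] = CONTINUOUS_VARS,
    categorical: Sequence[str] = CATEGORICAL_VARS,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable group comparisons for STUDY samples.

    For each ``(group, control)`` contrast: continuous variables are
    summarised as mean [range] when Shapiro-Wilk at ``alpha`` passes in
    both groups (then a two-sided t-test), otherwise median [range] (then a
    two-sided Wilcoxon rank-sum); categorical variables get a Fisher exact
    test (Monte Carlo for tables larger than 2x2).  Groups with n < 3 get
    counts only, no statistics.

    ``group``/``control`` are disease labels; ``"EHT"`` pools PA+PPGL+CS.
    """
    study = meta[meta["role"] == "STUDY"]

    def members(label):
        if label == "EHT":
            return study[study["disease"].isin(EHT_DISEASES)]
        return study[study["disease"] == label]

    rows = []
    for group, control in contrasts:
        g, c = members(group), members(control)
        if len(c) == 0:
            raise ValueError(f"empty control group {control!r}")
        small = len(g) < 3 or len(c) < 3
        for var in continuous:
            gv = g[var].dropna().to_numpy(dtype=float)
            cv = c[var].dropna().to_numpy(dtype=float)
            row = {
                "variable": var,
                "group": group,
                "control": control,
                "n_group": len(gv),
                "n_control": len(cv),
            }
            if small or len(gv) < 3 or len(cv) < 3:
                rows.append(row)
                continue
            normal = (
                stats.shapiro(gv).pvalue > alpha and stats.shapiro(cv).pvalue > alpha
            )
            if normal:
                row["summary_group"] = f"{gv.mean():.4g} {_fmt_range(gv)}"
                row["summary_control"] = f"{cv.mean():.4g} {_fmt_range(cv)}"
                row["test"] = "t"
                row["p"] = float(stats.ttest_ind(gv, cv).pvalue)
            else:
                row["summary_group"] = f"{np.median(gv):.4g} {_fmt_range(gv)}"
                row["summary_control"] = f"{np.median(cv):.4g} {_fmt_range(cv)}"
                row["test"] = "wilcoxon"
                row["p"] = float(stats.mannwhitneyu(gv, cv, alternative="two-sided").pvalue)
            rows.append(row)
        for var in categorical:
            row = {
                "variable": var,
                "group": group,
                "control": control,
                "n_group": len(g),
                "n_control": len(c),
            }
            if small:
                rows.append(row)
                continue
            levels = sorted(set(g[var].dropna()) | set(c[var].dropna()))
            tab = np.array(
                [
                    [(g[var] == lv).sum() for lv in levels],
                    [(c[var] == lv).sum() for lv in levels],
                ]
            ).T  # levels x 2
            tab = tab[tab.sum(axis=1) > 0]
            row["test"] = "fisher"
            row["p"] = fisher_exact_rc(tab, seed=seed)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in-paper count checks
# ---------------------------------------------------------------------------

def count_after_center_filter(
    meta: pd.DataFrame,
    keep_centers: Iterable[str],
    drop_diseases: Iterable[str] = (),
) -> pd.Series:
    """Per-disease STUDY sample counts restricted to ``keep_centers``.

    Returns a Series with one entry per disease plus ``EHT`` (pooled
    PA+PPGL+CS) and ``total``.  ``drop_diseases`` removes whole disease
    groups from the retained cohort first — the whole-center-exclusion
    analyses drop CS because the retained centers contribute almost no CS
    samples.  An empty center intersection yields zero counts.
    """
    keep_centers = set(keep_centers)
    drop = set(drop_diseases)
    study = meta[(meta["role"] == "STUDY") & meta["center"].isin(keep_centers)]
    study = study[~study["disease"].isin(drop)]
    out = {d: int((study["disease"] == d).sum()) for d in DISEASES if d not in drop}
    out["EHT"] = sum(out.get(d, 0) for d in EHT_DISEASES)
    out["total"] = int(len(study))
    return pd.Series(out, dtype=int)


def apply_exclusion_arithmetic(initial_n: int, exclusion_counts: Iterable[int]) -> int:
    """Remaining cohort size after disjoint exclusions; errors if negative."""
    exclusions = list(exclusion_counts)
    if any(e < 0 for e in exclusions):
        raise ValueError("exclusion counts must be nonnegative")
    remaining = initial_n - sum(exclusions)
    if remaining < 0:
        raise ValueError(
            f"exclusions ({sum(exclusions)}) exceed initial cohort ({initial_n})"
        )
    return remaining


APPROACHES = ("Initial", "A", "B", "C")


def signature_confounder_overlap(
    signature: pd.DataFrame, exclusion: pd.DataFrame, approach: str
) -> tuple[int, int, list[str]]:
    """Overlap between an approach's signature and the confounder list.

    Returns ``(overlap, signature_size, overlapping_names)`` where the
    signature is the set of metabolites with a nonzero (and non-blank)
    coefficient under ``approach``.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    coef = pd.to_numeric(signature[approach], errors="coerce")
    selected = signature.loc[coef.fillna(0) != 0, "metabolite"].tolist()
    confounded = set(exclusion["metabolite"])
    overlap = [m for m in selected if m in confounded]
    return len(overlap), len(selected), overlap


# ---------------------------------------------------------------------------
# transcribed fixture tables
# ---------------------------------------------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("nmrconfound.tables").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def load_table1_counts() -> pd.DataFrame:
    """Center x disease STUDY sample counts of the full cohort."""
    df = _fixture("table1_counts.csv")
    return df.set_index("center")


def load_table3_signature() -> pd.DataFrame:
    """Per-metabolite sparse PLS-DA coefficients for the EHT-PHT scenario.

    Columns ``Initial``, ``A``, ``B``, ``C`` are the per-approach
    coefficients; blank Approach-B cells mark metabolites excluded from
    the Approach-B dataset.
    """
    df = _fixture("table3_signature.csv")
    df["excluded_under_B"] = df["B"].isna()
    for col in ("Initial", "A", "B", "C"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_table4_exclusion() -> pd.DataFrame:
    """Metabolites strongly related to a confounder, with reason tags.

    ``direction`` is the shift in the FRPA1-PHT / cluster-2 / high
    sample-age groups relative to the rest (up or down).
    """
    df = _fixture("table4_exclusion.csv")
    df["ppm_peaks"] = df["ppm_peaks"].astype(str).str.split(";")
    df["reasons"] = df["reasons"].astype(str).str.split(";")
    if not df["reasons"].map(len).ge(1).all() or not df["direction"].isin(["up", "down"]).all():
        raise ValueError("exclusion list entries need >=1 reason tag and a direction")
    return df


def meta_from_center_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand a center x disease count table into a minimal STUDY metadata
    table (one row per sample), for count checks that operate on metadata."""
    rows = []
    i = 0
    for center, row in counts.iterrows():
        for disease in DISEASES:
            for _ in range(int(row.get(disease, 0))):
                rows.append(
                    {
                        "sample_id": f"S{i:04d}",
                        "role": "STUDY",
                        "disease": disease,
                        "center": center,
                        "cluster": np.nan,
                        "sample_age_days": 0,
                        "batch": 1 + i // RUN_ORDER_LIMIT,
                        "run_order": 1 + i % RUN_ORDER_LIMIT,
                        "sex": np.nan,
                        "patient_age": np.nan,
                    }
                )
                i += 1
    return pd.DataFrame(rows, columns=META_COLUMNS)
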