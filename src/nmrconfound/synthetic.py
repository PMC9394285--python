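"""Synthetic multicenter plasma-NMR cohort generator.

Emulates the confounding structure of a retrospective multicenter study:
two clusters of centers whose samples differ systematically on a fixed
panel of preanalytically sensitive metabolites (pre-centrifugation /
pre-storage delay chemistry: lactate, ornithine, glutamate up; glucose,
glutamine, pyruvate down; ...), a storage-time (sample age) covariate
correlated with both center cluster and disease group, configurable
disease effects, batch and run-order nuisance, pooled QC replicates,
healthy-volunteer reference samples, and intensity-dependent non-detects.

All effects are additive on the log scale (multiplicative on intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_cohort import (
    DISEASES,
    META_COLUMNS,
    PeakTable,
    load_table1_counts,
    load_table4_exclusion,
)

__all__ = [
    "SimConfig",
    "table4_template",
    "template_peaks",
    "simulate_cohort",
    "default_paper_scenario",
    "PEAK_METABOLITE",
]

# ---------------------------------------------------------------------------
# peak namespace: ppm label -> metabolite
# ---------------------------------------------------------------------------

#: Default ~40-peak namespace: the signature-table peaks plus the remaining
#: confounder-panel peaks (ornithine, acetylcarnitine, second creatine /
#: glucose / glycerol signals) and a handful of uninformative unknowns.
PEAK_METABOLITE: dict[str, str] = {
    "1.457": "Alanine",
    "3.021": "Creatine",
    "3.917": "Creatine",
    "4.041": "Creatinine",
    "3.137": "Dimethyl sulfone",
    "2.695": "Dimethylamine",
    "2.910": "Dimethylglycine",
    "8.441": "Formate",
    "2.433": "Glutamine",
    "2.325": "Glutamate",
    "5.220": "Glucose",
    "5.227": "Glucose",
    "3.548": "Glycine",
    "3.555": "Glycerol",
    "3.567": "Glycerol",
    "4.108": "Lactate",
    "2.997": "Lysine",
    "2.122": "Methionine",
    "3.346": "Methanol",
    "3.041": "Ornithine",
    "3.057": "Ornithine",
    "1.996": "Proline",
    "2.356": "Pyruvate",
    "4.240": "Threonine",
    "7.168": "Tyrosine",
    "0.981": "Valine",
    "3.177": "Acetylcarnitine",
    "3.162": "Unknown 3.162",
    "3.262": "Unknown 3.262",
    "3.284": "Unknown 3.284",
    "3.612": "Unknown 3.612",
    "3.670": "Unknown 3.670",
    # uninformative filler peaks
    "1.045": "Unknown 1.045",
    "1.732": "Unknown 1.732",
    "2.567": "Unknown 2.567",
    "3.425": "Unknown 3.425",
    "3.785": "Unknown 3.785",
    "4.305": "Unknown 4.305",
    "6.512": "Unknown 6.512",
    "7.345": "Unknown 7.345",
}

#: Sub-panel shifted in the flagged (room-temperature pre-storage delay)
#: subgroup: amino-acid chemistry only, no glycolysis shift.
FRPA1_PHT_TEMPLATE: dict[str, int] = {
    "Glutamate": +1,
    "Glutamine": -1,
    "Methionine": -1,
}

_CLUSTER1_CENTERS = ("GYDR", "GYLU", "GYMU", "GYWU", "ITTU3", "NLNI", "PLWW")
_CLUSTER2_CENTERS = ("FRPA1", "FRPA2", "GBGL2", "IRGA", "ITPD", "ITPD3")


def table4_template() -> dict[str, int]:
    """Metabolite -> sign (+1 up, -1 down) of the confounder direction panel.

    The sign is the direction of the shift in cluster-2 / high-sample-age
    samples relative to the rest (lactate up, glucose down, ...); 14 entries.
    """
    excl = load_table4_exclusion()
    return {
        m: (+1 if d == "up" else -1)
        for m, d in zip(excl["metabolite"], excl["direction"])
    }


def template_peaks(
    peak_metabolite: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Per-peak sign map induced by the metabolite-level direction panel."""
    pm = PEAK_METABOLITE if peak_metabolite is None else peak_metabolite
    tpl = table4_template()
    return {peak: tpl[met] for peak, met in pm.items() if met in tpl}


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the cohort simulator.

    Parameters
    ----------
    n_per_cell : mapping (center, disease) -> count of STUDY samples.
    centers : mapping center -> cluster (1 or 2).
    baseline_log_mean, baseline_log_sd : per-peak log-intensity mean and
        biological (between-sample) SD; keys define the peak namespace.
    disease_effects : mapping disease -> (peak tuple, log-scale shift).
    cluster_effect_scale : multiplier (log-units) on the confounder-panel
        direction template, applied to cluster-2 samples.
    frpa1_pht_scale : log shift of the flagged-subgroup amino-acid panel.
    sample_age_ranges : (lo, hi) days, looked up by (center, disease),
        then ("cluster<k>", disease), then center, then disease, then
        ``"*"``.
    age_slope : log-intensity change per 1000 days of storage, applied to
        template peaks with the template sign.
    age_cluster_corr : >= 0; skews cluster-2 (and flagged) samples toward
        old sample ages, correlating age with cluster membership.
    batch_sd : SD of the per-batch scalar log offset.
    run_order_slope : log drift per run-order position.
    lod : absolute intensity below which a cell becomes a non-detect.
    n_qc, n_hv : pooled QC replicates and healthy-volunteer samples.
    qc_noise_sd : technical (replicate) log SD of QC samples.
    hv_center : center whose healthy volunteers anchor the reference.
    flagged_cell : (center, disease) subgroup carrying the flagged
        sub-template and forced to cluster 1.
    """

    n_per_cell: dict
    centers: dict
    baseline_log_mean: dict
    baseline_log_sd: dict
    disease_effects: dict = field(default_factory=dict)
    cluster_effect_scale: float = 0.0
    frpa1_pht_scale: float = 0.0
    sample_age_ranges: dict = field(default_factory=lambda: {"*": (30, 2000)})
    age_slope: float = 0.0
    age_cluster_corr: float = 0.0
    batch_sd: float = 0.05
    run_order_slope: float = 0.002
    lod: float = 0.0
    n_qc: int = 30
    n_hv: int = 30
    qc_noise_sd: float = 0.05
    hv_center: str = "GYDR"
    flagged_cell: tuple | None = None
    peak_metabolite: dict = field(default_factory=lambda: dict(PEAK_METABOLITE))
    batch_size: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.lod < 0:
            raise ValueError("lod must be >= 0")
        for name in ("batch_sd", "qc_noise_sd", "age_cluster_corr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        peaks = set(self.baseline_log_mean)
        if set(self.baseline_log_sd) != peaks:
            raise ValueError("baseline_log_mean and baseline_log_sd keys differ")
        for d, (pset, _) in self.disease_effects.items():
            if not set(pset) <= peaks:
                raise ValueError(f"disease_effects[{d!r}] peaks outside namespace")

    @property
    def peaks(self) -> list[str]:
        return sorted(self.baseline_log_mean, key=float)


def _age_range(cfg: SimConfig, center: str, disease) -> tuple[float, float]:
    cluster = cfg.centers.get(center)
    for key in (
        (center, disease),
        (f"cluster{cluster}", disease),
        center,
        disease,
        "*",
    ):
        if key in cfg.sample_age_ranges:
            return cfg.sample_age_ranges[key]
    raise KeyError(f"no sample-age range for center {center!r} / disease {disease!r}")


_SEX_P_FEMALE = {"PHT": 0.58, "PA": 0.45, "PPGL": 0.62, "CS": 0.91}
_PATIENT_AGE = {"PHT": (55, 12), "PA": (48, 12), "PPGL": (50, 13), "CS": (47, 13)}


def simulate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[PeakTable, pd.DataFrame]:
    """Draw a synthetic peak table + metadata under the configured design.

    Log intensity of STUDY sample i, peak j:

        baseline_j + disease effect + cluster effect + flagged-subgroup
        effect + age_slope * sign_j * age_i/1000 + batch offset +
        run_order_slope * run_order_i + N(0, baseline_log_sd_j)

    Intensities below ``lod`` become non-detects.  QC samples are replicate
    draws around the pooled baseline with technical noise only; HV samples
    are baseline draws assigned to ``hv_center``.
    """
    if sum(config.n_per_cell.values()) == 0:
        raise ValueError("n_per_cell must contain at least one sample")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    peaks = config.peaks
    p = len(peaks)
    base_mu = np.array([config.baseline_log_mean[j] for j in peaks])
    base_sd = np.array([config.baseline_log_sd[j] for j in peaks])
    tpl_sign = np.array(
        [template_peaks(config.peak_metabolite).get(j, 0) for j in peaks], dtype=float
    )
    flag_sign = np.array(
        [
            FRPA1_PHT_TEMPLATE.get(config.peak_metabolite.get(j, ""), 0)
            for j in peaks
        ],
        dtype=float,
    )

    rows: list[dict] = []
    log_mu: list[np.ndarray] = []
    noise_sd: list[np.ndarray] = []

    def draw_age(lo, hi, old_skew: bool) -> int:
        if config.age_cluster_corr > 0:
            a, b = (1 + config.age_cluster_corr, 1.0) if old_skew else (
                1.0,
                1 + config.age_cluster_corr,
            )
            u = rng.beta(a, b)
        else:
            u = rng.uniform()
        return int(round(lo + u * (hi - lo)))

    i = 0
    for (center, disease), n in sorted(config.n_per_cell.items()):
        cluster = config.centers[center]
        flagged_cell = config.flagged_cell == (center, disease)
        for _ in range(n):
            lo, hi = _age_range(config, center, disease)
            old = (cluster == 2) or flagged_cell
            age = draw_age(lo, hi, old)
            mu = base_mu.copy()
            if disease in config.disease_effects:
                pset, shift = config.disease_effects[disease]
                mu += np.isin(peaks, list(pset)) * shift
            if cluster == 2 and not flagged_cell:
                mu += config.cluster_effect_scale * tpl_sign
            if flagged_cell:
                mu += config.frpa1_pht_scale * flag_sign
            mu += config.age_slope * tpl_sign * age / 1000.0
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "role": "STUDY",
                    "disease": disease,
                    "center": center,
                    "cluster": 1 if flagged_cell else cluster,
                    "sample_age_days": age,
                    "sex": "F" if rng.uniform() < _SEX_P_FEMALE.get(disease, 0.5) else "M",
                    "patient_age": float(
                        np.round(rng.normal(*_PATIENT_AGE.get(disease, (50, 12))), 1)
                    ),
                    "frpa1_pht": flagged_cell,
                }
            )
            log_mu.append(mu)
            noise_sd.append(base_sd)
            i += 1

    for q in range(config.n_qc):
        rows.append(
            {
                "sample_id": f"QC{q:03d}",
                "role": "QC",
                "disease": np.nan,
                "center": "POOL",
                "cluster": np.nan,
                "sample_age_days": 0,
                "sex": np.nan,
                "patient_age": np.nan,
                "frpa1_pht": False,
            }
        )
        log_mu.append(base_mu)
        noise_sd.append(np.full(p, config.qc_noise_sd))

    hv_cluster = config.centers.get(config.hv_center, 1)
    for h in range(config.n_hv):
        lo, hi = _age_range(config, config.hv_center, None)
        rows.append(
            {
                "sample_id": f"HV{h:03d}",
                "role": "HV",
                "disease": np.nan,
                "center": config.hv_center,
                "cluster": hv_cluster,
                "sample_age_days": draw_age(lo, hi, hv_cluster == 2),
                "sex": np.nan,
                "patient_age": np.nan,
                "frpa1_pht": False,
            }
        )
        log_mu.append(base_mu)
        noise_sd.append(base_sd)

    meta = pd.DataFrame(rows)
    n_total = len(meta)

    # analytical nuisance: sequential batches in randomized sample order
    order = rng.permutation(n_total)
    batch = np.empty(n_total, dtype=int)
    run_order = np.empty(n_total, dtype=int)
    for pos, idx in enumerate(order):
        batch[idx] = 1 + pos // config.batch_size
        run_order[idx] = 1 + pos % config.batch_size
    meta["batch"] = batch
    meta["run_order"] = run_order
    n_batches = int(batch.max())
    batch_offsets = rng.normal(0.0, config.batch_sd, size=n_batches)

    mu_mat = np.vstack(log_mu)
    sd_mat = np.vstack(noise_sd)
    logx = (
        mu_mat
        + rng.normal(size=mu_mat.shape) * sd_mat
        + batch_offsets[batch - 1][:, None]
        + config.run_order_slope * run_order[:, None]
    )
    x = np.exp(logx)
    x[x < config.lod] = np.nan

    table = PeakTable(
        pd.DataFrame(x, index=meta["sample_id"].tolist(), columns=peaks)
    )
    meta = meta[META_COLUMNS + ["frpa1_pht"]]
    return table, meta


def default_paper_scenario(seed: int = 0, **overrides) -> SimConfig:
    """The default multicenter scenario: published center x disease layout,
    two-cluster center structure with the flagged FRPA1-PHT subgroup, and
    disease-specific sample-age ranges.

    Effect magnitudes for the confounders are not published; the defaults
    (cluster scale 0.5 log-units, age slope 0.08 per 1000 days) are chosen
    so the two clusters separate on the first principal component while
    technical variation stays an order of magnitude smaller.
    """
    counts = load_table1_counts()
    n_per_cell = {
        (center, d): int(counts.loc[center, d])
        for center in counts.index
        for d in DISEASES
        if counts.loc[center, d] > 0
    }
    centers = {c: 1 for c in _CLUSTER1_CENTERS}
    centers.update({c: 2 for c in _CLUSTER2_CENTERS})
    base_rng = np.random.default_rng(12345)  # fixed: part of the scenario
    peaks = sorted(PEAK_METABOLITE, key=float)
    baseline_log_mean = {
        j: float(np.round(base_rng.uniform(3.0, 6.0), 3)) for j in peaks
    }
    baseline_log_sd = {j: 0.4 for j in peaks}
    cfg = SimConfig(
        n_per_cell=n_per_cell,
        centers=centers,
        baseline_log_mean=baseline_log_mean,
        baseline_log_sd=baseline_log_sd,
        disease_effects={},
        cluster_effect_scale=0.5,
        frpa1_pht_scale=0.5,
        # storage-time ranges: the retained (cluster-1) cohort is much
        # younger and more age-homogeneous than the excluded centers,
        # whose control samples dominate the old end of the distribution
        sample_age_ranges={
            ("cluster1", "PHT"): (127, 1307),
            ("cluster1", "PA"): (83, 1598),
            ("cluster1", "PPGL"): (121, 2841),
            ("cluster1", "CS"): (19, 1186),
            ("cluster2", "PHT"): (1307, 6418),
            "PHT": (127, 6418),
            "PA": (52, 2280),
            "PPGL": (11, 3442),
            "CS": (19, 1186),
            "*": (30, 2000),
        },
        age_slope=0.08,
        age_cluster_corr=1.5,
        batch_sd=0.05,
        run_order_slope=0.002,
        lod=8.0,
        n_qc=133,
        n_hv=98,
        qc_noise_sd=0.05,
        hv_center="GYDR",
        flagged_cell=("FRPA1", "PHT"),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
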