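"""Synthetic two-group longitudinal study generator.

Emulates the data-generating structure that the downstream latent change
score models assume: per region of interest (ROI) a latent "gray-matter
structural integrity" factor measured by three imaging modalities (VBM
gray-matter probability, MT saturation, mean diffusivity), three occasions
linked by latent change factors, group-specific mean change (control-group
decline, exercise-group maintenance), individual differences in change,
and — in one designated ROI — coupling between change in integrity and
change in cardiovascular fitness (VO2peak).  Method variance shared within
a modality across occasions is realized as a participant-level random
intercept per modality, which is the minimal mechanism producing equal
within-modality cross-occasion residual covariances.  Dropout, sporadic
missingness and rare gross outliers are applied last, so the stored latent
draws remain the clean ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .studytable import (
    FITNESS_OCCASIONS,
    FITNESS_VARIABLE,
    GROUPS,
    MODALITIES,
    ROI_ROSTER,
    StudyTable,
    roi_variable,
)

COMPLIANCE_PROFILES = ("compliant", "low-minutes", "long-pause", "decreasing-watts")


@dataclass
class TrainingLog:
    """Weekly activity log: (week, minutes, mean watts) per training week."""

    participant: str
    weeks: list[int]
    minutes: list[float]
    watts: list[float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        arr = np.asarray(self.minutes + self.watts, dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("minutes and watts must be finite")


@dataclass
class SimConfig:
    """Population parameters of the synthetic study.

    Latent units are chosen so that the baseline integrity factor has unit
    variance; indicator residual SDs then set the standardized loadings.
    The defaults encode the study conditions the generator emulates:
    35 controls (ACG) and 40 exercisers (EG), three occasions, MD the
    strongest (negative) indicator, small control-group decline per
    three-month interval, near-zero exerciser change, and positive
    fitness–integrity change coupling in the exercise group localized to
    one ROI.  Fitness is in mL/kg/min.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"ACG": 35, "EG": 40}
    )
    occasions: int = 3
    rois: Sequence[str] = ("ACC_R", "JLC_L")
    # measurement model (per modality): loading, residual SD, method-effect SD
    loadings: Mapping[str, float] = field(
        default_factory=lambda: {"VBM": 1.0, "MT": 1.0, "MD": -1.0}
    )
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: {"VBM": 1.45, "MT": 1.85, "MD": 0.55}
    )
    method_sd: Mapping[str, float] = field(
        default_factory=lambda: {"VBM": 0.55, "MT": 0.55, "MD": 0.20}
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"VBM": 0.0, "MT": 0.0, "MD": 0.0}
    )
    # latent integrity trajectory
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    change_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ACG": (-0.15, -0.20), "EG": (0.02, 0.00)}
    )
    change_sds: tuple[float, float] = (0.30, 0.30)
    cov_baseline_d21: float = 0.0
    cov_baseline_d32: float = 0.0
    cov_d21_d32: float = 0.0
    # cardiovascular fitness (VO2peak, mL/kg/min; observed at occasions 1 and 3)
    fitness_baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ACG": (23.0, 5.5), "EG": (23.0, 5.5)}
    )
    fitness_change: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ACG": (0.8, 2.3), "EG": (2.9, 2.3)}
    )
    #: correlation between fitness change and integrity change (T1->T2),
    #: applied in the ROI named by ``coupled_roi`` only
    coupling: Mapping[str, float] = field(
        default_factory=lambda: {"ACG": 0.30, "EG": 0.70}
    )
    coupled_roi: str | None = "ACC_R"
    # demographics
    age_mean_sd: tuple[float, float] = (70.2, 3.6)
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"ACG": 0.40, "EG": 0.50}
    )
    education_mean_sd: tuple[float, float] = (13.3, 3.1)
    icv_mean_sd: tuple[float, float] = (1500.0, 140.0)
    #: added to VBM indicators per unit of (ICV - mean ICV); gives the
    #: ICV-adjustment operator something real to remove
    icv_slope_vbm: float = 0.002
    #: optional per-covariate regression of the latent trajectory on a
    #: standardized covariate: name -> (effect on eta1, on d21, on d32)
    covariate_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    # data hygiene nuisances
    dropout_prob: float = 0.05
    mcar_rate: float = 0.02
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in GROUPS}
        for name in ("residual_sd", "method_sd"):
            for m, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{m}] must be >= 0, got {v}")
        if any(sd < 0 for sd in self.change_sds) or self.baseline_sd < 0:
            raise ValueError("latent SDs must be >= 0")
        for g, c in self.coupling.items():
            if not -1.0 <= c <= 1.0:
                raise ValueError(f"coupling[{g}] must lie in [-1, 1], got {c}")
        if not 0.0 <= self.dropout_prob < 1.0 or not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("missingness rates must lie in [0, 1)")
        unknown = set(self.rois) - set(ROI_ROSTER)
        if unknown:
            raise ValueError(f"unknown ROIs {sorted(unknown)}")
        for g in GROUPS:
            self.latent_covariance(g)  # PSD check at construction

    # ------------------------------------------------------------------
    # implied population moments (used by the generator and by oracles)
    # ------------------------------------------------------------------
    def latent_covariance(self, group: str) -> np.ndarray:
        """5x5 covariance of (eta1, d21, d32, fit1, dfit) for the coupled ROI.

        For non-coupled ROIs the upper-left 3x3 block applies and the fitness
        block is independent.  Raises if any diagonal block is not positive
        semi-definite.
        """
        s_e, (s21, s32) = self.baseline_sd, self.change_sds
        sf = self.fitness_baseline[group][1]
        sdf = self.fitness_change[group][1]
        rho = self.coupling[group]
        cov = np.diag([s_e**2, s21**2, s32**2, sf**2, sdf**2]).astype(float)
        cov[0, 1] = cov[1, 0] = self.cov_baseline_d21
        cov[0, 2] = cov[2, 0] = self.cov_baseline_d32
        cov[1, 2] = cov[2, 1] = self.cov_d21_d32
        cov[1, 4] = cov[4, 1] = rho * s21 * sdf
        for block, idx in (("integrity", slice(0, 3)), ("joint", slice(0, 5))):
            w = np.linalg.eigvalsh(cov[idx, idx])
            if w.min() < -1e-10:
                raise ValueError(
                    f"latent covariance block '{block}' for group {group} is "
                    f"not positive semi-definite (min eigenvalue {w.min():.3g})"
                )
        return cov

    def indicator_covariance(self) -> np.ndarray:
        """Population covariance of the 9 ROI indicators (modality x occasion,
        ordered VBM@1..3, MT@1..3, MD@1..3) for a non-coupled ROI, pooling
        groups only through the shared variance components (change-mean
        differences do not enter the within-group covariance)."""
        s_e, (s21, s32) = self.baseline_sd, self.change_sds
        L = np.zeros((3, 3))  # cov of (eta1, eta2, eta3)
        c01, c02, c12 = self.cov_baseline_d21, self.cov_baseline_d32, self.cov_d21_d32
        v1 = s_e**2
        v2 = v1 + s21**2 + 2 * c01
        v3 = v2 + s32**2 + 2 * (c02 + c12)
        L[0, 0] = v1
        L[0, 1] = L[1, 0] = v1 + c01
        L[0, 2] = L[2, 0] = v1 + c01 + c02
        L[1, 1] = v2
        L[1, 2] = L[2, 1] = v1 + s21**2 + 2 * c01 + c02 + c12
        L[2, 2] = v3
        lam = np.repeat([self.loadings[m] for m in MODALITIES], 3)
        occ = np.tile([0, 1, 2], 3)
        mod = np.repeat(np.arange(3), 3)
        cov = np.outer(lam, lam) * L[np.ix_(occ, occ)]
        for i in range(9):
            for j in range(9):
                if mod[i] == mod[j]:
                    m = MODALITIES[mod[i]]
                    cov[i, j] += self.method_sd[m] ** 2
                    if i == j:
                        cov[i, j] += self.residual_sd[m] ** 2
        return cov

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("change_sds", "age_mean_sd", "education_mean_sd", "icv_mean_sd"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        for key in ("change_means", "fitness_baseline", "fitness_change"):
            if key in raw:
                raw[key] = {g: tuple(v) for g, v in raw[key].items()}
        if "rois" in raw:
            raw["rois"] = tuple(raw["rois"])
        if "covariate_effects" in raw:
            raw["covariate_effects"] = {
                k: tuple(v) for k, v in raw["covariate_effects"].items()
            }
        return cls(**raw)


# ----------------------------------------------------------------------
# study generation
# ----------------------------------------------------------------------
def generate_study(config: SimConfig) -> StudyTable:
    """Draw a full synthetic study table from ``config``.

    The returned table carries the clean latent draws in ``.latents``
    (columns ``"<ROI>.eta1"``, ``"<ROI>.d21"``, ``"<ROI>.d32"``, ``fit1``,
    ``dfit``) and a log of injected outliers and missingness in ``.meta``.
    Identical configs (same seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    ids, groups = [], []
    for g in GROUPS:
        n = config.n_per_group.get(g, 0)
        ids += [f"{g}{i + 1:03d}" for i in range(n)]
        groups += [g] * n
    n_total = len(ids)

    age = np.clip(rng.normal(*config.age_mean_sd, n_total), 63, 77).round(1)
    sex = np.where(
        rng.random(n_total) < [config.female_fraction[g] for g in groups], "F", "M"
    )
    edu = np.clip(rng.normal(*config.education_mean_sd, n_total), 7, 18).round(0)
    icv = rng.normal(*config.icv_mean_sd, n_total).round(1)
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "group": groups,
            "age": age,
            "sex": sex,
            "education_years": edu,
            "icv": icv,
        }
    )

    # covariate shifts of the latent trajectory (standardized covariates)
    shift = np.zeros((n_total, 3))
    std = {
        "age": (age - age.mean()) / (age.std() or 1.0),
        "sex": (sex == "F").astype(float) - (sex == "F").mean(),
        "education": (edu - edu.mean()) / (edu.std() or 1.0),
    }
    for cov_name, betas in config.covariate_effects.items():
        if cov_name not in std:
            raise ValueError(f"unknown covariate {cov_name!r}")
        shift += np.outer(std[cov_name], betas)

    group_idx = {g: np.array([i for i, gg in enumerate(groups) if gg == g]) for g in GROUPS}

    # fitness + per-ROI latent draws, jointly MVN within participant
    latents = pd.DataFrame(index=pd.Index(ids, name="participant_id"), dtype=float)
    latents["fit1"] = 0.0
    latents["dfit"] = 0.0
    fit_draw = np.zeros((n_total, 2))
    for g in GROUPS:
        idx = group_idx[g]
        if idx.size == 0:
            continue
        mean = [config.fitness_baseline[g][0], config.fitness_change[g][0]]
        cov = config.latent_covariance(g)[3:, 3:]
        fit_draw[idx] = _mvn(rng, mean, cov, idx.size)
    latents["fit1"] = fit_draw[:, 0]
    latents["dfit"] = fit_draw[:, 1]

    for roi in config.rois:
        draw = np.zeros((n_total, 3))
        coupled = roi == config.coupled_roi
        for g in GROUPS:
            idx = group_idx[g]
            if idx.size == 0:
                continue
            d21m, d32m = config.change_means[g]
            mean3 = np.array([config.baseline_mean, d21m, d32m])
            cov5 = config.latent_covariance(g)
            if coupled:
                # condition the integrity trio on the fitness pair already drawn
                c_aa = cov5[:3, :3]
                c_ab = cov5[:3, 3:]
                c_bb = cov5[3:, 3:]
                sol = np.linalg.solve(c_bb, c_ab.T).T
                resid_mean = (
                    mean3
                    + (fit_draw[idx] - [config.fitness_baseline[g][0], config.fitness_change[g][0]])
                    @ sol.T
                )
                resid_cov = c_aa - sol @ c_ab.T
                draw[idx] = resid_mean + _mvn(rng, np.zeros(3), resid_cov, idx.size)
            else:
                draw[idx] = _mvn(rng, mean3, cov5[:3, :3], idx.size)
        draw += shift
        latents[f"{roi}.eta1"] = draw[:, 0]
        latents[f"{roi}.d21"] = draw[:, 1]
        latents[f"{roi}.d32"] = draw[:, 2]

    # manifest indicators
    rows: list[tuple] = []
    icv_c = icv - icv.mean()
    for roi in config.rois:
        eta = np.column_stack(
            [
                latents[f"{roi}.eta1"],
                latents[f"{roi}.eta1"] + latents[f"{roi}.d21"],
                latents[f"{roi}.eta1"] + latents[f"{roi}.d21"] + latents[f"{roi}.d32"],
            ]
        )
        for m in MODALITIES:
            method = rng.normal(0.0, config.method_sd[m], n_total)
            for t in range(config.occasions):
                eps = rng.normal(0.0, config.residual_sd[m], n_total)
                val = (
                    config.intercepts[m]
                    + config.loadings[m] * eta[:, t]
                    + method
                    + eps
                )
                if m == "VBM":
                    val = val + config.icv_slope_vbm * icv_c
                var = roi_variable(roi, m)
                rows += [
                    (pid, g, var, t + 1, v)
                    for pid, g, v in zip(ids, groups, val)
                ]
    for k, t in enumerate(FITNESS_OCCASIONS):
        val = latents["fit1"].to_numpy() + (latents["dfit"].to_numpy() if k else 0.0)
        rows += [
            (pid, g, FITNESS_VARIABLE, t, v) for pid, g, v in zip(ids, groups, val)
        ]
    meas = pd.DataFrame(rows, columns=["participant_id", "group", "variable", "occasion", "value"])

    # outlier contamination (before missingness; on ROI indicators only)
    meta: dict = {"seed": config.seed, "outliers": [], "dropout": []}
    if config.outlier_rate > 0:
        roi_mask = meas["variable"] != FITNESS_VARIABLE
        candidates = meas.index[roi_mask]
        hit = candidates[rng.random(candidates.size) < config.outlier_rate]
        sds = meas.loc[roi_mask].groupby("variable")["value"].std()
        signs = rng.choice([-1.0, 1.0], size=hit.size)
        for i, s in zip(hit, signs):
            var = meas.at[i, "variable"]
            meas.at[i, "value"] += s * config.outlier_magnitude * sds[var]
            meta["outliers"].append(
                (meas.at[i, "participant_id"], var, int(meas.at[i, "occasion"]))
            )

    # missingness: monotone dropout (all variables from the dropout occasion
    # onward) then sporadic MCAR holes
    keep = np.ones(len(meas), dtype=bool)
    occ = meas["occasion"].to_numpy()
    pid_col = meas["participant_id"].to_numpy()
    for pid in ids:
        for t in range(2, config.occasions + 1):
            if rng.random() < config.dropout_prob:
                keep &= ~((pid_col == pid) & (occ >= t))
                meta["dropout"].append((pid, t))
                break
    if config.mcar_rate > 0:
        keep &= ~(rng.random(len(meas)) < config.mcar_rate)
    meas = meas.loc[keep]

    return StudyTable(meas, participants, latents.reset_index(), meta)


def _mvn(rng: np.random.Generator, mean, cov, n: int) -> np.ndarray:
    """MVN draw via eigendecomposition — tolerant of PSD-but-singular blocks."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((n, mean.size))
    return mean + z @ (v * np.sqrt(w)).T


# ----------------------------------------------------------------------
# training logs
# ----------------------------------------------------------------------
def generate_training_logs(
    config: SimConfig,
    profiles: Iterable[str],
    participant_ids: Sequence[str] | None = None,
) -> dict[str, TrainingLog]:
    """Emit one weekly training log per requested compliance profile.

    Profiles: ``compliant`` (>=90 min/week on average over 26 weeks, watts
    non-decreasing), ``low-minutes`` (average weekly minutes below 90),
    ``long-pause`` (a gap of more than 2 consecutive zero-activity weeks),
    ``decreasing-watts`` (negative wattage trend).  Keys of the returned
    mapping are participant ids (defaulting to the profile tokens).
    """
    profiles = list(profiles)
    unknown = set(profiles) - set(COMPLIANCE_PROFILES)
    if unknown:
        raise ValueError(
            f"unknown compliance profile(s) {sorted(unknown)}; "
            f"choose from {COMPLIANCE_PROFILES}"
        )
    if participant_ids is None:
        participant_ids = profiles
    if len(participant_ids) != len(profiles):
        raise ValueError("participant_ids must match profiles in length")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6C6F67]))
    logs: dict[str, TrainingLog] = {}
    n_weeks = 26
    for pid, profile in zip(participant_ids, profiles):
        weeks = list(range(1, n_weeks + 1))
        base_watts = float(rng.uniform(40, 100))
        watts = [round(base_watts + 1.5 * w + float(rng.uniform(0, 0.5)), 1) for w in weeks]
        minutes = [round(float(rng.uniform(110, 140)), 1) for _ in weeks]
        if profile == "low-minutes":
            minutes = [round(float(rng.uniform(40, 75)), 1) for _ in weeks]
        elif profile == "long-pause":
            start = int(rng.integers(5, n_weeks - 5))
            for w in range(start, start + 3):
                minutes[w - 1] = 0.0
                watts[w - 1] = 0.0
        elif profile == "decreasing-watts":
            watts = [round(base_watts + 40 - 2.0 * w + float(rng.uniform(0, 0.5)), 1) for w in weeks]
        logs[pid] = TrainingLog(pid, weeks, minutes, watts)
    return logs


def training_logs_to_frame(logs: Mapping[str, TrainingLog]) -> pd.DataFrame:
    rows = [
        (log.participant, w, m, p)
        for log in logs.values()
        for w, m, p in zip(log.weeks, log.minutes, log.watts)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "week", "minutes", "watts"])


def training_logs_from_frame(frame: pd.DataFrame) -> dict[str, TrainingLog]:
    logs = {}
    for pid, sub in frame.groupby("participant_id", sort=False):
        sub = sub.sort_values("week")
        logs[str(pid)] = TrainingLog(
            str(pid),
            sub["week"].astype(int).tolist(),
            sub["minutes"].astype(float).tolist(),
            sub["watts"].astype(float).tolist(),
        )
    return logs
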