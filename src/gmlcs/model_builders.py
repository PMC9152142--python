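"""Builders for the three latent change score model families.

All builders emit :class:`~gmlcs.sem_engine.ModelSpec` objects:

* a univariate two-occasion LCSM for cardiovascular fitness (a pseudo-latent
  difference factor between occasions 1 and 3; exactly identified per group);
* a multivariate three-occasion LCSM for one ROI's gray-matter structural
  integrity factor, measured at each occasion by VBM (reference indicator,
  loading fixed to 1), MT and MD, with within-modality cross-occasion
  residual covariances constrained equal (one parameter per modality) and
  indicator intercepts held equal across occasions so latent change means
  stay interpretable;
* the bivariate union of the two, adding the free covariances that carry the
  fitness-change / integrity-change coupling.

Label conventions: group-specific parameters carry a ``.<group>`` suffix;
merging labels (dropping the suffix) imposes cross-group equality.
Invariance levels: ``configural`` frees loadings and residual variances per
occasion (and per group), ``metric`` equates loadings across occasions and
groups, ``strict`` additionally equates residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .sem_engine import POOLED, ModelSpec
from .studytable import GROUPS, MODALITIES, ROI_ROSTER, StudyTable, roi_variable

INVARIANCE_LEVELS = ("configural", "metric", "strict")
COVARIATES = ("age", "sex", "education")
INTERVALS = ("21", "32")


@dataclass
class ROIModelConfig:
    """Configuration for one ROI's integrity model."""

    roi: str
    occasions: tuple[int, ...] = (1, 2, 3)
    modalities: tuple[str, ...] = MODALITIES
    groups: tuple[str, ...] = GROUPS
    invariance: str = "strict"
    #: intervals whose latent change mean is constrained equal across groups
    equal_change_means: tuple[str, ...] = ()
    #: intervals whose latent change variance (and its covariances) are fixed 0
    zero_change_variance: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.roi not in ROI_ROSTER:
            raise ValueError(f"ROI {self.roi!r} not in roster {ROI_ROSTER}")
        if self.invariance not in INVARIANCE_LEVELS:
            raise ValueError(f"invariance must be one of {INVARIANCE_LEVELS}")
        bad = set(self.equal_change_means + self.zero_change_variance) - set(INTERVALS)
        if bad:
            raise ValueError(f"unknown interval(s) {sorted(bad)}; intervals are {INTERVALS}")
        bad = set(self.covariates) - set(COVARIATES)
        if bad:
            raise ValueError(f"unknown covariate(s) {sorted(bad)}")


def _g(label: str, group: str) -> str:
    """Group-suffixed label (no suffix for a pooled single-group spec)."""
    return label if group == POOLED else f"{label}.{group}"


# ======================================================================
# univariate two-occasion LCSM
# ======================================================================
def build_univariate_lcsm(
    variable: str,
    occasions: tuple[int, int] = (1, 3),
    groups: tuple[str, ...] = GROUPS,
) -> ModelSpec:
    """Two-occasion difference model: x_last = x_first + delta.

    Free per group: mean and variance of the first occasion, mean and
    variance of the latent difference, and their covariance — five
    parameters against five observed moments, so the model is exactly
    identified (df = 0) and the latent change mean equals the occasion-mean
    difference.
    """
    t1, t2 = occasions
    x1, x2 = f"{variable}@{t1}", f"{variable}@{t2}"
    delta = f"d_{variable}"
    spec = ModelSpec(
        manifest=(x1, x2),
        latent=(delta,),
        groups=tuple(groups),
        name=f"lcsm_{variable}",
    )
    for g in spec.groups:
        spec.set_path(g, x1, x2, 1.0)
        spec.set_path(g, delta, x2, 1.0)
        spec.set_cov(g, x1, x1, _g(f"{variable}_base_var", g))
        spec.set_cov(g, delta, delta, _g(f"{variable}_d_var", g))
        spec.set_cov(g, x1, delta, _g(f"{variable}_base_d_cov", g))
        spec.set_cov(g, x2, x2, 0.0)
        spec.set_mean(g, x1, _g(f"{variable}_base_mean", g))
        spec.set_mean(g, delta, _g(f"{variable}_d_mean", g))
        spec.set_mean(g, x2, 0.0)
        # directional hypotheses: positive change in EG, negative in ACG
        if g == "EG":
            spec.signs[_g(f"{variable}_d_mean", g)] = 1
        elif g == "ACG":
            spec.signs[_g(f"{variable}_d_mean", g)] = -1
    return spec


# ======================================================================
# single-occasion factor model (group-invariance ladder)
# ======================================================================
def build_occasion_factor(
    roi: str,
    occasion: int = 1,
    groups: tuple[str, ...] = GROUPS,
    invariance: str = "configural",
    modalities: tuple[str, ...] = MODALITIES,
) -> ModelSpec:
    """One-factor model of a single occasion's three modality indicators.

    The group-invariance ladder runs on this model at occasion 1:
    configural (all measurement parameters group-specific) -> metric
    (loadings shared, freeing 2 parameters) -> strict (residual variances
    additionally shared, freeing 3 more).  The latent mean is fixed to 0,
    so group baseline differences live in the intercepts.
    """
    if invariance not in INVARIANCE_LEVELS:
        raise ValueError(f"invariance must be one of {INVARIANCE_LEVELS}")
    cols = tuple(f"{roi_variable(roi, m)}@{occasion}" for m in modalities)
    spec = ModelSpec(manifest=cols, latent=("GMSI",), groups=tuple(groups), name=f"{roi}_occ{occasion}_{invariance}")
    ref, *others = modalities
    for g in spec.groups:
        spec.set_path(g, "GMSI", cols[0], 1.0)
        for m, col in zip(modalities[1:], cols[1:]):
            lbl = f"lam_{m}" if invariance in ("metric", "strict") else _g(f"lam_{m}", g)
            spec.set_path(g, "GMSI", col, lbl)
            spec.signs.setdefault(lbl, -1 if m == "MD" else 1)
            spec.start.setdefault(lbl, -0.5 if m == "MD" else 0.5)
        spec.set_cov(g, "GMSI", "GMSI", _g("psi", g))
        for m, col in zip(modalities, cols):
            res = f"res_{m}" if invariance == "strict" else _g(f"res_{m}", g)
            spec.set_cov(g, col, col, res)
            spec.set_mean(g, col, _g(f"tau_{m}", g))
        spec.set_mean(g, "GMSI", 0.0)
    return spec


# ======================================================================
# multivariate three-occasion integrity LCSM
# ======================================================================
def build_integrity_lcsm(config: ROIModelConfig) -> ModelSpec:
    """Three-occasion latent change score model of one ROI's integrity factor.

    Latent structure: GMSI_2 = GMSI_1 + d21, GMSI_3 = GMSI_2 + d32 (unit
    paths); free latent parameters per group are the baseline variance, the
    change means and variances, and the three covariances among (GMSI_1,
    d21, d32).  The baseline latent mean is fixed to 0 (indicator intercepts
    carry the group baseline level).  Measurement structure per the module
    docstring; ``config.invariance`` sets how loadings and residual
    variances are shared across occasions and groups.
    """
    roi = config.roi
    occ = config.occasions
    if occ != (1, 2, 3):
        raise ValueError("the integrity LCSM requires occasions (1, 2, 3)")
    mods = config.modalities
    cols = {(m, t): f"{roi_variable(roi, m)}@{t}" for m in mods for t in occ}
    manifest = tuple(cols[(m, t)] for m in mods for t in occ)
    latent = ("GMSI1", "GMSI2", "GMSI3", "d21", "d32")
    spec = ModelSpec(
        manifest=manifest,
        latent=latent,
        groups=tuple(config.groups),
        name=f"{roi}_integrity_{config.invariance}",
    )
    level = config.invariance
    ref = mods[0]  # reference indicator: VBM, loading fixed to 1 at every occasion
    for g in spec.groups:
        # measurement model
        for t, eta in zip(occ, ("GMSI1", "GMSI2", "GMSI3")):
            spec.set_path(g, eta, cols[(ref, t)], 1.0)
            for m in mods[1:]:
                if level == "configural":
                    lbl = _g(f"lam_{m}_t{t}", g)
                else:
                    lbl = f"lam_{m}"
                spec.set_path(g, eta, cols[(m, t)], lbl)
                spec.signs.setdefault(lbl, -1 if m == "MD" else 1)
                spec.start.setdefault(lbl, -0.5 if m == "MD" else 0.5)
        for m in mods:
            for t in occ:
                if level == "strict":
                    res = f"res_{m}"
                else:
                    res = _g(f"res_{m}_t{t}", g)
                spec.set_cov(g, cols[(m, t)], cols[(m, t)], res)
            # within-modality cross-occasion residual covariances, equal
            # within each modality (method variance)
            meth = _g(f"meth_{m}", g)
            for i, t1 in enumerate(occ):
                for t2 in occ[i + 1 :]:
                    spec.set_cov(g, cols[(m, t1)], cols[(m, t2)], meth)
            # intercepts equal across occasions within indicator
            for t in occ:
                spec.set_mean(g, cols[(m, t)], _g(f"tau_{m}", g))
        # latent trajectory
        spec.set_path(g, "GMSI1", "GMSI2", 1.0)
        spec.set_path(g, "d21", "GMSI2", 1.0)
        spec.set_path(g, "GMSI2", "GMSI3", 1.0)
        spec.set_path(g, "d32", "GMSI3", 1.0)
        spec.set_cov(g, "GMSI1", "GMSI1", _g("psi1", g))
        spec.set_cov(g, "GMSI2", "GMSI2", 0.0)
        spec.set_cov(g, "GMSI3", "GMSI3", 0.0)
        spec.set_mean(g, "GMSI1", 0.0)
        spec.set_mean(g, "GMSI2", 0.0)
        spec.set_mean(g, "GMSI3", 0.0)
        for iv, d in (("21", "d21"), ("32", "d32")):
            if iv in config.zero_change_variance:
                spec.set_cov(g, d, d, 0.0)
                spec.set_cov(g, "GMSI1", d, 0.0)
            else:
                spec.set_cov(g, d, d, _g(f"vd{iv}", g))
                spec.set_cov(g, "GMSI1", d, _g(f"c_b{iv}", g))
            mean_lbl = (
                f"mu{iv}" if iv in config.equal_change_means else _g(f"mu{iv}", g)
            )
            spec.set_mean(g, d, mean_lbl)
            if g == "EG":
                spec.signs.setdefault(mean_lbl, 1)
            elif g == "ACG":
                spec.signs.setdefault(mean_lbl, -1)
        if "21" in config.zero_change_variance or "32" in config.zero_change_variance:
            spec.set_cov(g, "d21", "d32", 0.0)
        else:
            spec.set_cov(g, "d21", "d32", _g("c_2132", g))
        # start values that keep the first iterations well-conditioned
        spec.start.setdefault(_g("psi1", g), 0.5)
        for iv in INTERVALS:
            if iv not in config.zero_change_variance:
                spec.start.setdefault(_g(f"vd{iv}", g), 0.1)
    if config.covariates:
        spec = add_covariates(spec, config.covariates)
    return spec


# ======================================================================
# bivariate LCSM (integrity + fitness)
# ======================================================================
def build_bivariate_lcsm(config: ROIModelConfig, fitness_variable: str = "VO2peak") -> ModelSpec:
    """Union of the integrity LCSM and the fitness difference model, plus
    the six free covariances linking the two: (dFit, d21), (dFit, d32),
    (fit1, GMSI1), (fit1, d21), (fit1, d32), (dFit, GMSI1)."""
    base = build_integrity_lcsm(
        ROIModelConfig(
            roi=config.roi,
            occasions=config.occasions,
            modalities=config.modalities,
            groups=config.groups,
            invariance=config.invariance,
            equal_change_means=config.equal_change_means,
            zero_change_variance=config.zero_change_variance,
        )
    )
    f1, f3 = f"{fitness_variable}@1", f"{fitness_variable}@3"
    dfit = f"d_{fitness_variable}"
    spec = ModelSpec(
        manifest=base.manifest + (f1, f3),
        latent=base.latent + (dfit,),
        groups=base.groups,
        name=f"{config.roi}_bivariate_{config.invariance}",
    )
    for g in spec.groups:
        spec.A[g] = dict(base.A[g])
        spec.S[g] = dict(base.S[g])
        spec.M[g] = dict(base.M[g])
        spec.set_path(g, f1, f3, 1.0)
        spec.set_path(g, dfit, f3, 1.0)
        spec.set_cov(g, f1, f1, _g("fit_base_var", g))
        spec.set_cov(g, dfit, dfit, _g("fit_d_var", g))
        spec.set_cov(g, f1, dfit, _g("fit_base_d_cov", g))
        spec.set_cov(g, f3, f3, 0.0)
        spec.set_mean(g, f1, _g("fit_base_mean", g))
        spec.set_mean(g, dfit, _g("fit_d_mean", g))
        spec.set_mean(g, f3, 0.0)
        # change-change and cross-construct covariances
        for iv, d in (("21", "d21"), ("32", "d32")):
            if iv in config.zero_change_variance:
                spec.set_cov(g, dfit, d, 0.0)
                spec.set_cov(g, f1, d, 0.0)
            else:
                phi = _g(f"phi{iv}", g)
                spec.set_cov(g, dfit, d, phi)
                spec.signs.setdefault(phi, 1)
                spec.set_cov(g, f1, d, _g(f"c_f_d{iv}", g))
        spec.set_cov(g, f1, "GMSI1", _g("c_f_b", g))
        spec.set_cov(g, dfit, "GMSI1", _g("c_df_b", g))
    spec.start.update(base.start)
    spec.signs.update(base.signs)
    spec.bounds.update(base.bounds)
    if config.covariates:
        spec = add_covariates(spec, config.covariates)
    return spec


# ======================================================================
# covariates
# ======================================================================
def add_covariates(spec: ModelSpec, covariates: Sequence[str]) -> ModelSpec:
    """Add exogenous manifest covariates with free means, variances and
    pairwise covariances, plus directed paths to GMSI1, d21 and d32.

    Covariate columns follow the ``"<name>@1"`` convention (one value per
    participant, attached at occasion 1); FIML absorbs their missingness.
    """
    covariates = tuple(covariates)
    bad = set(covariates) - set(COVARIATES)
    if bad:
        raise ValueError(f"unknown covariate(s) {sorted(bad)}")
    cols = tuple(f"{c}@1" for c in covariates)
    clash = set(cols) & set(spec.manifest)
    if clash:
        raise ValueError(f"covariate column(s) {sorted(clash)} collide with indicators")
    targets = [v for v in ("GMSI1", "d21", "d32") if v in spec.latent]
    out = ModelSpec(
        manifest=spec.manifest + cols,
        latent=spec.latent,
        groups=spec.groups,
        name=spec.name + "_cov",
    )
    for g in out.groups:
        out.A[g] = dict(spec.A[g])
        out.S[g] = dict(spec.S[g])
        out.M[g] = dict(spec.M[g])
        for c, col in zip(covariates, cols):
            out.set_mean(g, col, _g(f"{c}_mean", g))
            out.set_cov(g, col, col, _g(f"{c}_var", g))
            for tgt in targets:
                out.set_path(g, col, tgt, _g(f"b_{c}_{tgt}", g))
        for i, (c1, col1) in enumerate(zip(covariates, cols)):
            for c2, col2 in list(zip(covariates, cols))[i + 1 :]:
                out.set_cov(g, col1, col2, _g(f"{c1}_{c2}_cov", g))
    out.start.update(spec.start)
    out.signs.update(spec.signs)
    out.bounds.update(spec.bounds)
    return out


def covariate_measurements(table: StudyTable, covariates: Sequence[str]) -> StudyTable:
    """Inject per-participant covariates as occasion-1 measurement rows so
    the SEM data pivot can see them (sex coded female = 1, male = 0)."""
    part = table.participants
    rows = []
    for c in covariates:
        if c == "age":
            vals = part["age"].astype(float)
        elif c == "sex":
            vals = (part["sex"] == "F").astype(float)
        elif c == "education":
            vals = part["education_years"].astype(float)
        else:
            raise ValueError(f"unknown covariate {c!r}")
        for pid, g, v in zip(part["participant_id"], part["group"], vals):
            rows.append((pid, g, c, 1, float(v)))
    extra = pd.DataFrame(rows, columns=["participant_id", "group", "variable", "occasion", "value"])
    meas = pd.concat([table.measurements, extra], ignore_index=True)
    return table.with_values(meas)
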