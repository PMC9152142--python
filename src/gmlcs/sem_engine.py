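"""A compact multigroup SEM kernel with full-information ML estimation.

Models are written in RAM form per group: a directed-path matrix ``A``, a
symmetric covariance matrix ``S``, a mean vector ``M`` and an implicit
filter selecting the manifest variables.  Entries are either fixed numbers
or string labels; sharing a label — within or across groups — imposes an
equality constraint.  Model-implied moments follow the usual RAM algebra

    Sigma = F (I - A)^-1 S (I - A)^-T F',      mu = F (I - A)^-1 M,

and the objective is the full-information -2 log-likelihood, each case
contributing a multivariate-normal term over its observed variables only
(cases are grouped by missingness pattern; the result is identical to
case-by-case evaluation).  Optimization is bounded quasi-Newton (L-BFGS-B)
with finite-difference gradients and optional jittered restarts; standard
errors come from the inverse of one-half the numerical Hessian of -2lnL.
Fit indices (chi-square vs. the saturated model, RMSEA with a noncentral
chi-square confidence interval, CFI against the independence model) and a
standardized solution are computed on request.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .studytable import StudyTable

LOG_2PI = math.log(2.0 * math.pi)
#: pooled-group pseudo group name: a spec with this single group is fitted
#: to all cases regardless of their group label
POOLED = "ALL"

Entry = float | str


# ======================================================================
# model specification
# ======================================================================
@dataclass
class ModelSpec:
    """RAM-parameterized multigroup model with labeled parameters.

    ``manifest`` names carry the data-column convention ``"<variable>@<occasion>"``
    so a :class:`StudyTable` can be pivoted automatically at fit time.
    """

    manifest: tuple[str, ...]
    latent: tuple[str, ...] = ()
    groups: tuple[str, ...] = (POOLED,)
    A: dict = field(default_factory=dict)  # group -> {(to, frm): Entry}
    S: dict = field(default_factory=dict)  # group -> {frozenset-like (i, j): Entry}
    M: dict = field(default_factory=dict)  # group -> {var: Entry}
    start: dict = field(default_factory=dict)  # label -> start value
    bounds: dict = field(default_factory=dict)  # label -> (lo, hi)
    signs: dict = field(default_factory=dict)  # label -> +1 | -1 (hypothesized sign)
    name: str = "model"

    def __post_init__(self) -> None:
        overlap = set(self.manifest) & set(self.latent)
        if overlap:
            raise ValueError(f"variables {sorted(overlap)} are both manifest and latent")
        for g in self.groups:
            self.A.setdefault(g, {})
            self.S.setdefault(g, {})
            self.M.setdefault(g, {})

    # -- construction helpers ------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        return self.manifest + self.latent

    def set_path(self, group: str, frm: str, to: str, entry: Entry) -> None:
        self._check(group, frm, to)
        self.A[group][(to, frm)] = entry

    def set_cov(self, group: str, a: str, b: str, entry: Entry) -> None:
        self._check(group, a, b)
        i, j = sorted((a, b), key=self.variables.index)
        self.S[group][(i, j)] = entry

    def set_mean(self, group: str, var: str, entry: Entry) -> None:
        self._check(group, var, var)
        self.M[group][var] = entry

    def _check(self, group: str, *vars_: str) -> None:
        if group not in self.groups:
            raise ValueError(f"unknown group {group!r}")
        for v in vars_:
            if v not in self.variables:
                raise ValueError(f"unknown variable {v!r}")

    # -- parameter bookkeeping -----------------------------------------
    def free_labels(self) -> list[str]:
        """Distinct parameter labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            for store in (self.A[g], self.S[g], self.M[g]):
                for entry in store.values():
                    if isinstance(entry, str):
                        seen.setdefault(entry, None)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    def moment_count(self) -> int:
        p = len(self.manifest)
        return len(self.groups) * (p + p * (p + 1) // 2)

    def df(self) -> int:
        return self.moment_count() - self.n_free

    def free_locations(self) -> set[tuple]:
        """(group, matrix, i, j) locations carrying a free parameter."""
        locs = set()
        for g in self.groups:
            for (i, j), e in self.A[g].items():
                if isinstance(e, str):
                    locs.add((g, "A", i, j))
            for (i, j), e in self.S[g].items():
                if isinstance(e, str):
                    locs.add((g, "S", i, j))
            for v, e in self.M[g].items():
                if isinstance(e, str):
                    locs.add((g, "M", v, v))
        return locs

    def nested_within(self, parent: "ModelSpec") -> bool:
        """Structural nesting check: every location free here is free in the
        parent, and this model has no more distinct parameters.  (Equality
        constraints merge labels, so label identity is not required.)"""
        return (
            self.groups == parent.groups
            and self.manifest == parent.manifest
            and self.free_locations() <= parent.free_locations()
            and self.n_free <= parent.n_free
        )

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    # -- constraint surgery (used by builders and tests) ---------------
    def fix_label(self, label: str, value: float) -> "ModelSpec":
        """Return a copy with every occurrence of ``label`` fixed to ``value``."""
        return self.replace_labels({label: value})

    def merge_labels(self, mapping: Mapping[str, str]) -> "ModelSpec":
        """Return a copy with labels renamed (sharing a target name imposes
        an equality constraint)."""
        return self.replace_labels(dict(mapping))

    def replace_labels(self, mapping: Mapping[str, Entry]) -> "ModelSpec":
        out = self.copy()
        for g in out.groups:
            for store in (out.A[g], out.S[g], out.M[g]):
                for key, entry in list(store.items()):
                    if isinstance(entry, str) and entry in mapping:
                        store[key] = mapping[entry]
        for d in (out.start, out.bounds, out.signs):
            for old, new in mapping.items():
                if old in d:
                    val = d.pop(old)
                    if isinstance(new, str):
                        d.setdefault(new, val)
        return out

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        def enc(store):
            return {" | ".join(k) if isinstance(k, tuple) else k: v for k, v in store.items()}

        doc = {
            "name": self.name,
            "manifest": list(self.manifest),
            "latent": list(self.latent),
            "groups": list(self.groups),
            "A": {g: enc(self.A[g]) for g in self.groups},
            "S": {g: enc(self.S[g]) for g in self.groups},
            "M": {g: dict(self.M[g]) for g in self.groups},
            "start": dict(self.start),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "signs": dict(self.signs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def dec(store):
            return {tuple(k.split(" | ")): v for k, v in store.items()}

        spec = cls(
            manifest=tuple(doc["manifest"]),
            latent=tuple(doc.get("latent", ())),
            groups=tuple(doc["groups"]),
            name=doc.get("name", "model"),
        )
        for g in spec.groups:
            spec.A[g] = dec(doc["A"].get(g, {}))
            spec.S[g] = dec(doc["S"].get(g, {}))
            spec.M[g] = dict(doc["M"].get(g, {}))
        spec.start = dict(doc.get("start", {}))
        spec.bounds = {k: tuple(v) for k, v in doc.get("bounds", {}).items()}
        spec.signs = dict(doc.get("signs", {}))
        return spec


# ======================================================================
# compiled problem
# ======================================================================
class _GroupStructure:
    """Scatter maps from the parameter vector into one group's A, S, M."""

    def __init__(self, spec: ModelSpec, group: str, label_index: Mapping[str, int]):
        v = spec.variables
        idx = {name: i for i, name in enumerate(v)}
        k = len(v)
        self.base_A = np.zeros((k, k))
        self.base_S = np.zeros((k, k))
        self.base_M = np.zeros(k)
        self.scatter_A: list[tuple[int, int, int]] = []
        self.scatter_S: list[tuple[int, int, int]] = []
        self.scatter_M: list[tuple[int, int]] = []
        for (to, frm), e in spec.A[group].items():
            i, j = idx[to], idx[frm]
            if isinstance(e, str):
                self.scatter_A.append((i, j, label_index[e]))
            else:
                self.base_A[i, j] = float(e)
        for (a, b), e in spec.S[group].items():
            i, j = idx[a], idx[b]
            if isinstance(e, str):
                self.scatter_S.append((i, j, label_index[e]))
            else:
                self.base_S[i, j] = self.base_S[j, i] = float(e)
        for var, e in spec.M[group].items():
            i = idx[var]
            if isinstance(e, str):
                self.scatter_M.append((i, label_index[e]))
            else:
                self.base_M[i] = float(e)
        self.manifest_idx = np.array([idx[m] for m in spec.manifest], dtype=int)
        self.k = k

    def moments(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(manifest mu, manifest Sigma, full mu, full Sigma) at ``theta``."""
        A = self.base_A.copy()
        S = self.base_S.copy()
        M = self.base_M.copy()
        for i, j, p in self.scatter_A:
            A[i, j] = theta[p]
        for i, j, p in self.scatter_S:
            S[i, j] = S[j, i] = theta[p]
        for i, p in self.scatter_M:
            M[i] = theta[p]
        I = np.eye(self.k)
        try:
            B = np.linalg.solve(I - A, I)
        except np.linalg.LinAlgError as exc:
            raise SingularPathsError(
                "I - A is singular: the directed paths form a cycle or an "
                "ill-posed structure"
            ) from exc
        full_sigma = B @ S @ B.T
        full_sigma = 0.5 * (full_sigma + full_sigma.T)
        full_mu = B @ M
        m = self.manifest_idx
        return full_mu[m], full_sigma[np.ix_(m, m)], full_mu, full_sigma


class SingularPathsError(np.linalg.LinAlgError):
    pass


def implied_moments(
    spec: ModelSpec, values: Mapping[str, float]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Model-implied manifest (mean vector, covariance matrix) per group."""
    labels = spec.free_labels()
    missing = set(labels) - set(values)
    if missing:
        raise ValueError(f"no value supplied for label(s) {sorted(missing)}")
    theta = np.array([values[l] for l in labels], dtype=float)
    out = {}
    for g in spec.groups:
        gs = _GroupStructure(spec, g, {l: i for i, l in enumerate(labels)})
        mu, sigma, _, _ = gs.moments(theta)
        out[g] = (mu, sigma)
    return out


class FimlProblem:
    """Model + data bound together for likelihood evaluation."""

    def __init__(self, spec: ModelSpec, data: Mapping[str, np.ndarray]):
        self.spec = spec
        self.labels = spec.free_labels()
        label_index = {l: i for i, l in enumerate(self.labels)}
        self.structures = {g: _GroupStructure(spec, g, label_index) for g in spec.groups}
        self.patterns: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self.n_cases = 0
        for g in spec.groups:
            x = np.asarray(data[g], dtype=float)
            if x.ndim != 2 or x.shape[1] != len(spec.manifest):
                raise ValueError(
                    f"group {g!r}: data must be n x {len(spec.manifest)}"
                )
            obs = ~np.isnan(x)
            keep = obs.any(axis=1)
            x, obs = x[keep], obs[keep]
            self.n_cases += len(x)
            pats: list[tuple[np.ndarray, np.ndarray]] = []
            if len(x):
                codes = np.ascontiguousarray(obs).view(
                    np.dtype((np.void, obs.shape[1]))
                ).ravel()
                for code in np.unique(codes):
                    rows = codes == code
                    mask = obs[np.argmax(rows)]
                    pats.append((mask, x[np.ix_(rows, mask)]))
            self.patterns[g] = pats

    def neg2ll(self, theta: np.ndarray) -> float:
        total = 0.0
        for g in self.spec.groups:
            try:
                mu, sigma, _, _ = self.structures[g].moments(theta)
            except SingularPathsError:
                return np.inf
            for mask, x in self.patterns[g]:
                mu_o = mu[mask]
                sig_o = sigma[np.ix_(mask, mask)]
                try:
                    chol = np.linalg.cholesky(sig_o)
                except np.linalg.LinAlgError:
                    return np.inf
                k = mask.sum()
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                resid = x - mu_o
                y = solve_triangular(chol, resid.T, lower=True, check_finite=False)
                quad = np.einsum("ij,ij->", y, y)
                total += x.shape[0] * (k * LOG_2PI + logdet) + quad
        return float(total)


def fiml_neg2ll(
    spec: ModelSpec,
    values: Mapping[str, float],
    data: "StudyTable | Mapping[str, np.ndarray]",
) -> float:
    """-2 log-likelihood of ``spec`` at ``values`` for the given data."""
    arrays = _extract_arrays(spec, data)
    labels = spec.free_labels()
    missing = set(labels) - set(values)
    if missing:
        raise ValueError(f"no value supplied for label(s) {sorted(missing)}")
    prob = FimlProblem(spec, arrays)
    return prob.neg2ll(np.array([values[l] for l in labels], dtype=float))


def _extract_arrays(
    spec: ModelSpec, data: "StudyTable | Mapping[str, np.ndarray] | pd.DataFrame"
) -> dict[str, np.ndarray]:
    """Pivot a StudyTable (or accept pre-built arrays) into per-group
    n x p arrays following the spec's manifest column convention."""
    if isinstance(data, StudyTable):
        vars_occ: dict[str, list[int]] = {}
        for col in spec.manifest:
            v, t = col.rsplit("@", 1)
            vars_occ.setdefault(v, []).append(int(t))
        wide = data.wide(list(vars_occ), {v: tuple(o) for v, o in vars_occ.items()})
        wide = wide[[*spec.manifest, "group"]]
        out = {}
        for g in spec.groups:
            sub = wide if g == POOLED else wide[wide["group"] == g]
            out[g] = sub[list(spec.manifest)].to_numpy(dtype=float)
        return out
    if isinstance(data, pd.DataFrame):
        if len(spec.groups) == 1:
            return {spec.groups[0]: data[list(spec.manifest)].to_numpy(dtype=float)}
        return {
            g: data.loc[data["group"] == g, list(spec.manifest)].to_numpy(dtype=float)
            for g in spec.groups
        }
    return {g: np.asarray(data[g], dtype=float) for g in spec.groups}


# ======================================================================
# fit result
# ======================================================================
@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float | None]
    neg2ll: float
    n_params: int
    n_obs: int
    converged: bool
    saturated_neg2ll: float | None = None
    chi_square: float | None = None
    df: int | None = None
    rmsea: float | None = None
    rmsea_ci: tuple[float, float] | None = None
    cfi: float | None = None
    standardized: dict[str, float] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)
    #: (labels, covariance matrix) of the free parameters, when available
    param_covariance: tuple[list[str], np.ndarray] | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label in self.spec.free_labels():
            rows.append(
                {
                    "label": label,
                    "estimate": self.estimates[label],
                    "se": self.se.get(label),
                    "standardized": self.standardized.get(label),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "neg2ll": self.neg2ll,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "chi_square": self.chi_square,
            "df": self.df,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci) if self.rmsea_ci else None,
            "cfi": self.cfi,
            "estimates": self.estimates,
            "se": self.se,
            "standardized": self.standardized,
            "diagnostics": self.diagnostics,
        }


# ======================================================================
# estimation
# ======================================================================
def _auto_start(prob: FimlProblem, spec: ModelSpec) -> np.ndarray:
    """Heuristic start values: observed means for manifest means, halved
    observed variances for variances, mild values elsewhere; overridden by
    any explicit entry in ``spec.start``."""
    theta = np.zeros(len(prob.labels))
    man_idx = {m: i for i, m in enumerate(spec.manifest)}
    # observed per-group moments over available values
    obs_mean: dict[str, np.ndarray] = {}
    obs_var: dict[str, np.ndarray] = {}
    for g in spec.groups:
        p = len(spec.manifest)
        sums = np.zeros(p)
        sq = np.zeros(p)
        cnt = np.zeros(p)
        for mask, x in prob.patterns[g]:
            sums[mask] += x.sum(axis=0)
            sq[mask] += (x**2).sum(axis=0)
            cnt[mask] += x.shape[0]
        cnt = np.maximum(cnt, 1)
        mu = sums / cnt
        obs_mean[g] = mu
        obs_var[g] = np.maximum(sq / cnt - mu**2, 1e-3)
    for pos, label in enumerate(prob.labels):
        if label in spec.start:
            theta[pos] = spec.start[label]
            continue
        guess = 0.1
        for g in spec.groups:
            st = prob.structures[g]
            for i, j, p_ in st.scatter_S:
                if p_ == pos:
                    if i == j and i < len(spec.manifest):
                        guess = 0.5 * obs_var[g][i]
                    elif i == j:
                        guess = 0.5
                    else:
                        guess = 0.0
            for i, p_ in st.scatter_M:
                if p_ == pos:
                    guess = obs_mean[g][i] if i < len(spec.manifest) else 0.0
            for i, j, p_ in st.scatter_A:
                if p_ == pos:
                    guess = 0.5 * spec.signs.get(label, 1)
        theta[pos] = guess
    return theta


def _default_bounds(prob: FimlProblem, spec: ModelSpec) -> list[tuple[float | None, float | None]]:
    """Variance parameters (labels on the S diagonal only) are bounded below
    at 1e-6; anything else is unbounded unless the spec says otherwise."""
    bounds: list[tuple[float | None, float | None]] = []
    diag_only: dict[str, bool] = {}
    for g in spec.groups:
        st = prob.structures[g]
        for i, j, p in st.scatter_S:
            lbl = prob.labels[p]
            diag_only[lbl] = diag_only.get(lbl, True) and i == j
        for i, j, p in st.scatter_A:
            diag_only[prob.labels[p]] = False
        for i, p in st.scatter_M:
            diag_only[prob.labels[p]] = False
    for label in prob.labels:
        if label in spec.bounds:
            bounds.append(tuple(spec.bounds[label]))
        elif diag_only.get(label, False):
            bounds.append((1e-6, None))
        else:
            bounds.append((None, None))
    return bounds


def fit(
    spec: ModelSpec,
    data: "StudyTable | Mapping[str, np.ndarray] | pd.DataFrame",
    start: Mapping[str, float] | None = None,
    restarts: int = 5,
    indices: bool = True,
    standard_errors: bool = True,
    seed: int = 0,
    ftol: float = 1e-10,
) -> FitResult:
    """Fit ``spec`` to ``data`` by FIML.

    ``restarts`` quasi-Newton runs are performed, the first from the (auto
    or supplied) start values and the rest from 10%-jittered copies; the
    best converged solution wins.  With ``indices=True`` the saturated and
    independence models are fitted internally to produce chi-square, RMSEA
    (with 95% CI) and CFI.  A non-converged fit is returned with
    ``converged=False`` and a diagnostic, never silently.
    """
    if spec.df() < 0:
        raise ValueError(
            f"model {spec.name!r} is not identified: df = {spec.df()} < 0"
        )
    arrays = _extract_arrays(spec, data)
    prob = FimlProblem(spec, arrays)
    theta0 = _auto_start(prob, spec)
    if start:
        for i, l in enumerate(prob.labels):
            if l in start:
                theta0[i] = start[l]
    bounds = _default_bounds(prob, spec)
    theta0 = _clip_to_bounds(theta0, bounds)

    rng = np.random.default_rng(seed)
    best = None
    diagnostics: list[str] = []

    def objective(theta: np.ndarray) -> float:
        # a large finite ceiling instead of +inf keeps the finite-difference
        # gradient defined when a step crosses into a non-PD region
        val = prob.neg2ll(theta)
        return val if np.isfinite(val) else 1e12

    for attempt in range(max(1, restarts)):
        t0 = theta0 if attempt == 0 else _clip_to_bounds(
            theta0 * (1.0 + 0.1 * rng.standard_normal(theta0.size))
            + 0.01 * rng.standard_normal(theta0.size),
            bounds,
        )
        if not np.isfinite(prob.neg2ll(t0)):
            continue
        with np.errstate(invalid="ignore", over="ignore"):
            res = optimize.minimize(
                objective,
                t0,
                method="L-BFGS-B",
                jac="3-point",
                bounds=bounds,
                options={"ftol": ftol, "gtol": 1e-8, "maxiter": 2000, "maxfun": 200000},
            )
        if best is None or (res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise RuntimeError(f"no finite start value found for model {spec.name!r}")
    converged = bool(best.success) and np.isfinite(best.fun) and best.fun < 1e11
    if not converged:
        diagnostics.append(f"optimizer did not converge: {best.message}")

    theta = best.x
    estimates = {l: float(v) for l, v in zip(prob.labels, theta)}
    se: dict[str, float | None] = {l: None for l in prob.labels}
    param_cov = None
    if standard_errors and prob.labels:
        cov = _parameter_covariance(prob, theta)
        if cov is None:
            diagnostics.append(
                "Hessian of -2lnL not positive definite; standard errors unavailable"
            )
        else:
            for i, l in enumerate(prob.labels):
                se[l] = float(np.sqrt(cov[i, i])) if cov[i, i] > 0 else None
            param_cov = (list(prob.labels), cov)

    result = FitResult(
        spec=spec,
        estimates=estimates,
        se=se,
        neg2ll=float(best.fun),
        n_params=len(prob.labels),
        n_obs=prob.n_cases,
        converged=converged,
        df=spec.df(),
        diagnostics=diagnostics,
    )
    result.param_covariance = param_cov

    if indices:
        _attach_fit_indices(result, prob, arrays)
    result.standardized = standardize_solution(result, spec)
    return result


def start_from(parent: FitResult, child: ModelSpec) -> dict[str, float]:
    """Warm-start values for ``child`` read off a fitted parent model.

    Each of the child's free entries takes the parent's estimate at the same
    (group, matrix, location); entries whose labels were merged by an
    equality constraint average the corresponding parent estimates.  Used to
    chain nested fits so a constrained model never starts worse than its
    parent's optimum projected onto the constraint.
    """
    pspec = parent.spec
    acc: dict[str, list[float]] = {}
    for g in child.groups:
        if g not in pspec.groups:
            continue
        for store_name in ("A", "S", "M"):
            child_store = getattr(child, store_name)[g]
            parent_store = getattr(pspec, store_name)[g]
            for key, entry in child_store.items():
                if not isinstance(entry, str):
                    continue
                pentry = parent_store.get(key)
                if isinstance(pentry, str) and pentry in parent.estimates:
                    acc.setdefault(entry, []).append(parent.estimates[pentry])
                elif isinstance(pentry, (int, float)):
                    acc.setdefault(entry, []).append(float(pentry))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _clip_to_bounds(theta: np.ndarray, bounds) -> np.ndarray:
    out = theta.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[i] = max(out[i], lo)
        if hi is not None:
            out[i] = min(out[i], hi)
    return out


def _parameter_covariance(prob: FimlProblem, theta: np.ndarray) -> np.ndarray | None:
    """cov(theta) = inverse of one-half the numerical Hessian of -2lnL."""
    h = _numerical_hessian(prob.neg2ll, theta)
    try:
        cov = np.linalg.inv(0.5 * h)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return cov


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = f(x)
    # diagonal terms
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        H[i, i] = (f(x + e) - 2 * f0 + f(x - e)) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# ======================================================================
# saturated / independence models and fit indices
# ======================================================================
def _saturated_neg2ll_group(x: np.ndarray) -> float:
    """Saturated-model FIML -2lnL for one group (free means, free covariances).

    Complete data has the closed form n (k ln 2pi + ln|S_ml| + k); under
    missingness the saturated model is optimized by the same quasi-Newton
    FIML machinery, with the covariance parameterized through its Cholesky
    factor for unconstrained positive definiteness.
    """
    obs = ~np.isnan(x)
    x = x[obs.any(axis=1)]
    obs = ~np.isnan(x)
    n, p = x.shape
    if obs.all():
        mu = x.mean(axis=0)
        s = (x - mu).T @ (x - mu) / n
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular saturated covariance")
        return float(n * (p * LOG_2PI + logdet + p))

    # start values from available-case moments
    mu0 = np.nanmean(x, axis=0)
    df_ = pd.DataFrame(x)
    s0 = df_.cov(ddof=0).to_numpy()
    s0 = np.where(np.isfinite(s0), s0, 0.0)
    w, v = np.linalg.eigh(0.5 * (s0 + s0.T))
    s0 = (v * np.clip(w, 1e-3, None)) @ v.T
    chol0 = np.linalg.cholesky(s0)
    tril = np.tril_indices(p)

    codes = np.ascontiguousarray(obs).view(np.dtype((np.void, obs.shape[1]))).ravel()
    pats = []
    for code in np.unique(codes):
        rows = codes == code
        mask = obs[np.argmax(rows)]
        pats.append((mask, x[np.ix_(rows, mask)]))

    def objective(theta: np.ndarray) -> float:
        mu = theta[:p]
        L = np.zeros((p, p))
        L[tril] = theta[p:]
        sigma = L @ L.T
        total = 0.0
        for mask, xx in pats:
            sig_o = sigma[np.ix_(mask, mask)]
            try:
                c = np.linalg.cholesky(sig_o)
            except np.linalg.LinAlgError:
                return 1e12
            k = mask.sum()
            resid = xx - mu[mask]
            y = np.linalg.solve(c, resid.T)
            total += xx.shape[0] * (k * LOG_2PI + 2 * np.log(np.diag(c)).sum()) + np.einsum(
                "ij,ij->", y, y
            )
        return float(total)

    theta0 = np.concatenate([mu0, chol0[tril]])
    with np.errstate(invalid="ignore", over="ignore"):
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            jac="3-point",
            options={"ftol": 1e-10, "maxiter": 5000, "maxfun": 500000},
        )
    return float(res.fun)


def _independence_neg2ll_group(x: np.ndarray) -> float:
    """Independence model (free means and variances, zero covariances):
    separable across variables, so each variable's ML solution is its
    observed-value mean and n-denominator variance."""
    total = 0.0
    for j in range(x.shape[1]):
        col = x[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        var = col.var()
        var = max(var, 1e-12)
        total += col.size * (LOG_2PI + math.log(var) + 1.0)
    return float(total)


def _attach_fit_indices(result: FitResult, prob: FimlProblem, arrays: Mapping[str, np.ndarray]) -> None:
    spec = result.spec
    p = len(spec.manifest)
    sat = sum(_saturated_neg2ll_group(arrays[g]) for g in spec.groups)
    indep = sum(_independence_neg2ll_group(arrays[g]) for g in spec.groups)
    chi2 = result.neg2ll - sat
    if chi2 < 0:
        if chi2 > -1e-6:
            result.diagnostics.append(f"chi-square {chi2:.2e} clipped to 0")
            chi2 = 0.0
        else:
            raise RuntimeError(
                f"model {spec.name!r}: -2lnL fell below the saturated model by "
                f"{-chi2:.4g}; saturated fit failed to converge or model fit is invalid"
            )
    base_chi2 = max(indep - sat, 0.0)
    base_df = len(spec.groups) * (p * (p + 1) // 2 - p)
    result.saturated_neg2ll = sat
    result.chi_square = float(chi2)
    if result.df and result.df >= 1:
        rmsea, ci, cfi = fit_indices(chi2, result.df, prob.n_cases, base_chi2, base_df)
        result.rmsea = rmsea
        result.rmsea_ci = ci
        result.cfi = cfi
    else:
        # exactly identified: fit is perfect by definition; RMSEA undefined
        result.rmsea = None
        result.rmsea_ci = None
        result.cfi = 1.0 if result.df == 0 else None


def fit_indices(
    chi_square: float,
    df: int,
    n_total: int,
    baseline_chi_square: float,
    baseline_df: int,
) -> tuple[float, tuple[float, float], float]:
    """RMSEA with 95% CI (noncentral chi-square inversion) and CFI.

    RMSEA = sqrt(max(0, chi2 - df) / (df (N - 1))); the CI bounds invert the
    noncentral chi-square CDF in the noncentrality parameter at coverage
    0.975 / 0.025.  CFI = 1 - max(0, chi2 - df) / max(chi2 - df,
    baseline_chi2 - baseline_df, 0), clipped into [0, 1].
    """
    if df < 1:
        raise ValueError("RMSEA requires df >= 1 (exactly identified models have perfect fit)")
    if baseline_df < 0:
        raise ValueError("baseline df must be non-negative")
    # NB: a mean-structured model (equal intercepts across occasions) can have
    # more df than the conventional independence baseline, whose means are
    # saturated; the CFI denominator's max(..., 0) keeps the index in range.
    nm1 = n_total - 1
    rmsea = math.sqrt(max(0.0, chi_square - df) / (df * nm1))

    def _invert(coverage: float) -> float:
        # find lambda with ncx2.cdf(chi2; df, lambda) = coverage
        f = lambda lam: stats.ncx2.cdf(chi_square, df, lam) - coverage
        if f(0.0) < 0:
            return 0.0
        hi = max(chi_square, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return hi
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))

    lam_l = _invert(0.975)
    lam_u = _invert(0.025)
    ci = (
        math.sqrt(max(lam_l, 0.0) / (df * nm1)),
        math.sqrt(max(lam_u, 0.0) / (df * nm1)),
    )
    num = max(0.0, chi_square - df)
    den = max(chi_square - df, baseline_chi_square - baseline_df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi = min(max(cfi, 0.0), 1.0)
    return rmsea, ci, cfi


# ======================================================================
# standardized solution
# ======================================================================
def standardize_solution(result: FitResult, spec: ModelSpec) -> dict[str, float]:
    """Standardize estimates by the model-implied variable SDs.

    Loadings / regressions: a_ij * sd(source) / sd(target); covariances:
    s_ij / (sd_i sd_j); variances: 1 by construction (reported as the raw
    estimate divided by the implied variance of the variable).  Values may
    exceed |1| when a latent covariance block is not positive definite —
    they are reported as-is with a diagnostic, never clipped.  Entries with
    zero implied variance are omitted.
    """
    labels = spec.free_labels()
    theta = np.array([result.estimates[l] for l in labels], dtype=float)
    label_index = {l: i for i, l in enumerate(labels)}
    acc: dict[str, list[float]] = {}
    for g in spec.groups:
        gs = _GroupStructure(spec, g, label_index)
        _, _, _, full_sigma = gs.moments(theta)
        sd = np.sqrt(np.clip(np.diag(full_sigma), 0.0, None))
        for i, j, p in gs.scatter_A:
            if sd[i] > 0 and sd[j] > 0:
                acc.setdefault(labels[p], []).append(theta[p] * sd[j] / sd[i])
        for i, j, p in gs.scatter_S:
            if i == j:
                if sd[i] > 0:
                    acc.setdefault(labels[p], []).append(theta[p] / sd[i] ** 2)
            elif sd[i] > 0 and sd[j] > 0:
                acc.setdefault(labels[p], []).append(theta[p] / (sd[i] * sd[j]))
    out: dict[str, float] = {}
    for label, vals in acc.items():
        out[label] = float(np.mean(vals))
        if abs(out[label]) > 1.0 + 1e-9 and spec_entry_is_cov(spec, label):
            result.diagnostics.append(
                f"standardized estimate of {label!r} = {out[label]:.3f} exceeds |1| "
                "(non-positive-definite latent block; reported unclipped)"
            )
    return out


def spec_entry_is_cov(spec: ModelSpec, label: str) -> bool:
    for g in spec.groups:
        for (i, j), e in spec.S[g].items():
            if e == label and i != j:
                return True
    return False
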