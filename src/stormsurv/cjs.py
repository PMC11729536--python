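"""Cormack-Jolly-Seber models with immediate trap-dependent resighting.

The likelihood is multinomial over the split-history m-array.  A release at
occasion *i* is an individual that was just detected there, so at occasion
*i+1* it is resighted with the "seen" probability; if missed at *i+1* it
drops into the "unseen" state for every later occasion until its next
detection (immediate, one-occasion trap-dependence):

    Pr(next at j | release at i)
        = prod_{k=i..j-1} phi_k
          * [ p_seen_{i+1}                                  if j = i+1
              (1-p_seen_{i+1}) prod_{k=i+2..j-1}(1-p_unseen_k) p_unseen_j
                                                            if j > i+1 ]

with the never-seen-again cell taking the complement.  Survival phi and both
resighting probabilities use logit links; survival may be constant, fully
time-dependent, or a logit-linear formula in per-winter covariates
(standardised upstream; interactions are products of standardised mains).

Model structures are written in a mini-language mirroring the field's tables,
e.g. ``phi(t) p(./t)`` or ``phi(PC1 + sSST) p(t + m)``; in ``p(a/b)`` the part
before the slash models individuals detected at the previous occasion and the
part after models those not detected, while ``p(t + m)`` shares time effects
between the groups with a single additive trap offset ``m`` on the logit
scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .encounters import MArray

__all__ = [
    "ModelStructure",
    "FitResult",
    "AnodevResult",
    "negloglik",
    "negloglik_grad",
    "fit",
    "qaicc",
    "survival_series",
    "rank_models",
    "anodev",
    "covariate_effect",
    "CandidateConfig",
    "resighting_candidates",
    "survival_candidates",
    "storm_candidates",
]

_EPS = 1e-12
_BOUNDARY_LOGIT = 15.0


def _invlogit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    # lower-clipped only: a logit beyond ~+37 genuinely saturates to 1.0 and
    # cells requiring its complement become structural zeros (infinite nll)
    return np.clip(out, 1e-300, None)


# ---------------------------------------------------------------------------
# model structures


_STRUCT_RE = re.compile(r"phi\((?P<phi>[^)]*)\)\s*p\((?P<p>[^)]*)\)")


@dataclass(frozen=True)
class ModelStructure:
    """Symbolic survival/resighting parameterisation.

    ``phi_spec``: ``"."`` (constant), ``"t"`` (one parameter per interval) or a
    formula such as ``"PC1 + sSST"`` / ``"PC1 * population"`` (``*`` or the
    times sign denote an interaction; mains are included automatically).

    ``p_spec``: ``"a/b"`` with each of a, b in {``.``, ``t``} for separate
    seen/unseen-group models, or ``"t + m"`` for shared time effects with one
    additive trap offset on the seen group's logit.
    """

    phi_spec: str
    p_spec: str

    @classmethod
    def parse(cls, label: str) -> "ModelStructure":
        m = _STRUCT_RE.search(label.replace("×", "*"))
        if not m:
            raise ValueError(f"cannot parse model label {label!r}")
        return cls(m.group("phi").strip(), m.group("p").strip().replace(" ", ""))

    @property
    def label(self) -> str:
        return f"phi({self.phi_spec}) p({self.p_spec})"

    # -- phi side -----------------------------------------------------------

    def phi_terms(self) -> list[str]:
        """Slope names for a formula phi (expanded mains + interactions)."""
        spec = self.phi_spec.replace("×", "*")
        if spec in (".", "t"):
            return []
        terms: list[str] = []
        inters: list[str] = []
        for raw in spec.split("+"):
            raw = raw.strip()
            if "*" in raw:
                a, b = (s.strip() for s in raw.split("*", 1))
                for name in (a, b):
                    if name not in terms:
                        terms.append(name)
                inters.append(f"{a}:{b}")
            elif raw and raw not in terms:
                terms.append(raw)
        return terms + inters

    @property
    def n_slopes(self) -> int:
        return len(self.phi_terms())

    def phi_design(self, T: int, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
        if self.phi_spec == ".":
            return np.ones((T, 1)), ["phi"]
        if self.phi_spec == "t":
            return np.eye(T), [f"phi_{t + 1}" for t in range(T)]
        if covariates is None:
            raise ValueError(f"phi formula {self.phi_spec!r} requires a covariate table")
        if len(covariates) != T:
            raise ValueError(
                f"covariate table has {len(covariates)} rows; need one per interval (T={T})"
            )
        cols = [np.ones(T)]
        names = ["(intercept)"]
        for term in self.phi_terms():
            if ":" in term:
                a, b = term.split(":", 1)
                x = covariates[a].to_numpy(float) * covariates[b].to_numpy(float)
            else:
                if term not in covariates.columns:
                    raise ValueError(f"covariate {term!r} not in table")
                x = covariates[term].to_numpy(float)
            if np.isnan(x).any():
                raise ValueError(f"covariate {term!r} has missing values over the intervals used")
            cols.append(x)
            names.append(term)
        return np.column_stack(cols), names

    # -- p side -------------------------------------------------------------

    def p_design(self, T: int) -> tuple[np.ndarray, list[str]]:
        """Design mapping p-parameters to stacked logits [eta_seen; eta_unseen]."""
        spec = self.p_spec.replace(" ", "")
        if spec == "t+m":
            # shared per-occasion effects, trap offset m added to the seen group
            D = np.zeros((2 * T, T + 1))
            D[:T, :T] = np.eye(T)
            D[T:, :T] = np.eye(T)
            D[:T, T] = 1.0
            names = [f"p_{t + 2}" for t in range(T)] + ["m"]
            return D, names
        if "/" not in spec:
            raise ValueError(f"cannot parse p spec {self.p_spec!r}")
        seen, unseen = spec.split("/", 1)
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for grp, sub in (("seen", seen), ("unseen", unseen)):
            if sub == ".":
                blocks.append(np.ones((T, 1)))
                names.append(f"p_{grp}")
            elif sub == "t":
                blocks.append(np.eye(T))
                names.extend(f"p_{grp}_{t + 2}" for t in range(T))
            else:
                raise ValueError(f"unknown p group spec {sub!r} in {self.p_spec!r}")
        k_seen = blocks[0].shape[1]
        k_unseen = blocks[1].shape[1]
        D = np.zeros((2 * T, k_seen + k_unseen))
        D[:T, :k_seen] = blocks[0]
        D[T:, k_seen:] = blocks[1]
        return D, names


@dataclass
class _Design:
    structure: ModelStructure
    T: int
    Xphi: np.ndarray
    Dp: np.ndarray
    phi_names: list[str]
    p_names: list[str]

    @property
    def k_phi(self) -> int:
        return self.Xphi.shape[1]

    @property
    def k(self) -> int:
        return self.Xphi.shape[1] + self.Dp.shape[1]

    @property
    def names(self) -> list[str]:
        return self.phi_names + self.p_names

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        beta = theta[: self.k_phi]
        gamma = theta[self.k_phi :]
        phi = _invlogit(self.Xphi @ beta)
        eta_p = self.Dp @ gamma
        return phi, _invlogit(eta_p[: self.T]), _invlogit(eta_p[self.T :])


def build_design(
    structure: ModelStructure, n_occasions: int, covariates: pd.DataFrame | None = None
) -> _Design:
    T = n_occasions - 1
    Xphi, phi_names = structure.phi_design(T, covariates)
    Dp, p_names = structure.p_design(T)
    return _Design(structure, T, Xphi, Dp, phi_names, p_names)


# ---------------------------------------------------------------------------
# likelihood


def _marray_cells(marray: MArray) -> tuple[np.ndarray, np.ndarray]:
    """(Mm, v): Mm[r, jm] = count released at occasion r+1 next seen at jm+2;
    v[r] = never seen again.  Shapes (T, T) and (T,)."""
    T = marray.n_occasions - 1
    Mm = marray.next_recapture[:T, 1:].astype(float)
    v = marray.never_again[:T].astype(float)
    return Mm, v


def _cell_logprobs(
    phi: np.ndarray, p_seen: np.ndarray, p_unseen: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log cell probabilities logP[r, jm] (jm >= r), cell probs, and chi."""
    T = phi.shape[0]
    lphi = np.log(phi)
    l1pu = np.log1p(-p_unseen)
    A = np.concatenate(([0.0], np.cumsum(lphi)))
    B = np.concatenate(([0.0], np.cumsum(l1pu)))
    r = np.arange(T)[:, None]
    jm = np.arange(T)[None, :]
    S = A[jm + 1] - A[r]  # survival product over intervals r..jm
    with np.errstate(divide="ignore"):  # saturated p -> structural zero cells
        later = (
            np.log1p(-p_seen)[:, None]
            + (B[jm] - B[np.minimum(r + 1, T)])
            + np.log(p_unseen)[None, :]
        )
        logP = np.where(jm == r, np.log(p_seen)[:, None], later) + S
    mask = jm >= r
    logP = np.where(mask, logP, -np.inf)
    P = np.exp(logP)
    chi = 1.0 - P.sum(axis=1)
    return logP, P, chi


def negloglik(
    marray: MArray,
    structure: ModelStructure,
    params: np.ndarray,
    covariates: pd.DataFrame | None = None,
    design: _Design | None = None,
) -> float:
    """Negative multinomial log-likelihood of the m-array (log-space cells)."""
    design = design or build_design(structure, marray.n_occasions, covariates)
    phi, ps, pu = design.unpack(np.asarray(params, float))
    Mm, v = _marray_cells(marray)
    logP, P, chi = _cell_logprobs(phi, ps, pu)
    with np.errstate(invalid="ignore"):
        cell_term = np.where(Mm > 0, Mm * logP, 0.0)
    if not np.isfinite(cell_term[Mm > 0]).all():
        return np.inf  # structural zero cell carries a positive count
    chi_safe = np.clip(chi, 1e-300, None)
    if ((chi <= 0) & (v > 0)).any():
        return np.inf
    return float(-(cell_term.sum() + np.sum(v * np.log(chi_safe))))


def negloglik_grad(
    marray: MArray,
    structure: ModelStructure,
    params: np.ndarray,
    covariates: pd.DataFrame | None = None,
    design: _Design | None = None,
) -> np.ndarray:
    """Analytic gradient of :func:`negloglik` (chain rule through logits)."""
    design = design or build_design(structure, marray.n_occasions, covariates)
    T = design.T
    phi, ps, pu = design.unpack(np.asarray(params, float))
    Mm, v = _marray_cells(marray)
    _, P, chi = _cell_logprobs(phi, ps, pu)
    chi_safe = np.clip(chi, 1e-300, None)
    w = Mm - (v / chi_safe)[:, None] * P  # d nll / d logP weights (negated below)

    # survival logits: lphi[u] appears in cells with r <= u <= jm
    cum_right = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]  # sum over jm >= u
    U = np.array([cum_right[: u + 1, u].sum() for u in range(T)])
    g_phi = -(1.0 - phi) * U

    # seen-group logits: row r only
    diag = np.diagonal(w).copy()
    row_later = w.sum(axis=1) - diag
    g_ps = -((1.0 - ps) * diag - ps * row_later)

    # unseen-group logits at occasion u+2: detection cell jm=u (rows r<u),
    # miss term for r < u and jm > u
    g_pu = np.zeros(T)
    for u in range(T):
        det = w[:u, u].sum()
        miss = w[:u, u + 1 :].sum()
        g_pu[u] = -((1.0 - pu[u]) * det - pu[u] * miss)

    grad_beta = design.Xphi.T @ g_phi
    grad_gamma = design.Dp.T @ np.concatenate([g_ps, g_pu])
    return np.concatenate([grad_beta, grad_gamma])


# ---------------------------------------------------------------------------
# fitting


def qaicc(minus2lnl: float, chat: float, k: int, ess: float) -> float:
    """Quasi-likelihood AICc: -2lnL/chat + 2K + 2K(K+1)/(ess - K - 1)."""
    if ess - k - 1 <= 0:
        return np.inf
    return minus2lnl / chat + 2 * k + 2 * k * (k + 1) / (ess - k - 1)


@dataclass
class FitResult:
    structure: ModelStructure
    estimates: np.ndarray
    vcov: np.ndarray
    minus2lnl: float
    k: int                       # usable parameter count (rank-adjusted)
    k_structural: int
    qaicc: float
    chat_used: float
    ess: float
    converged: bool
    boundary: np.ndarray         # per-parameter |logit| > 15 flags
    param_names: list[str]
    n_occasions: int
    n_intervals: int
    design: _Design = field(repr=False, default=None)
    grad_inf_norm: float = np.nan

    @property
    def label(self) -> str:
        return self.structure.label

    @property
    def n_slopes(self) -> int:
        return self.structure.n_slopes

    def phi_estimates(self) -> np.ndarray:
        phi, _, _ = self.design.unpack(self.estimates)
        return phi

    def p_estimates(self) -> tuple[np.ndarray, np.ndarray]:
        _, ps, pu = self.design.unpack(self.estimates)
        return ps, pu


_JITTER_SEEDS = (101, 202, 303, 404, 505)


def _hessian(fun_grad, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += step
        tm[j] -= step
        H[:, j] = (fun_grad(tp) - fun_grad(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def fit(
    marray: MArray,
    structure: ModelStructure | str,
    covariates: pd.DataFrame | None = None,
    chat: float = 1.0,
    ess: float | None = None,
    compute_vcov: bool = True,
    rank_tol: float = 1e-8,
) -> FitResult:
    """Maximise the trap-dependent CJS likelihood for one model structure.

    Optimisation starts from all logits at zero (deterministic) with a
    fixed-seed multi-start fallback; the covariance comes from the inverse
    observed curvature (scaled by ``chat``), and the usable parameter count K
    is the structural count minus the curvature rank deficiency (eigenvalues
    below ``rank_tol`` times the largest).  The effective sample size for
    QAICc defaults to the total number of (split-history) releases.
    """
    if isinstance(structure, str):
        structure = ModelStructure.parse(structure)
    design = build_design(structure, marray.n_occasions, covariates)
    ess = float(marray.total_releases if ess is None else ess)

    def f(theta: np.ndarray) -> float:
        return negloglik(marray, structure, theta, design=design)

    def g(theta: np.ndarray) -> np.ndarray:
        return negloglik_grad(marray, structure, theta, design=design)

    def solve(theta0: np.ndarray):
        return optimize.minimize(
            f, theta0, jac=g, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 5000},
        )

    res = solve(np.zeros(design.k))
    best = res
    ginf = float(np.max(np.abs(g(best.x))))
    if ginf >= 1e-5:
        for seed in _JITTER_SEEDS:
            rng = np.random.default_rng(seed)
            trial = solve(rng.normal(scale=0.5, size=design.k))
            t_ginf = float(np.max(np.abs(g(trial.x))))
            if trial.fun < best.fun - 1e-9 or (t_ginf < ginf and trial.fun < best.fun + 1e-6):
                best, ginf = trial, t_ginf
    theta = best.x
    m2ll = 2.0 * float(best.fun)
    converged = bool(ginf < 1e-5 and np.isfinite(m2ll))
    boundary = np.abs(theta) > _BOUNDARY_LOGIT

    k_struct = design.k
    if compute_vcov:
        H = _hessian(g, theta)
        eigvals, _ = np.linalg.eigh(H)
        max_eig = float(eigvals.max()) if eigvals.size else 0.0
        deficient = int(np.sum(eigvals < rank_tol * max(max_eig, 1.0)))
        k_use = k_struct - deficient
        vcov = np.linalg.pinv(H, rcond=rank_tol) * chat
    else:
        k_use = k_struct - int(boundary.sum())
        vcov = np.full((k_struct, k_struct), np.nan)

    return FitResult(
        structure=structure,
        estimates=theta,
        vcov=vcov,
        minus2lnl=m2ll,
        k=k_use,
        k_structural=k_struct,
        qaicc=qaicc(m2ll, chat, k_use, ess),
        chat_used=chat,
        ess=ess,
        converged=converged,
        boundary=boundary,
        param_names=design.names,
        n_occasions=marray.n_occasions,
        n_intervals=design.T,
        design=design,
        grad_inf_norm=ginf,
    )


# ---------------------------------------------------------------------------
# post-fit summaries


def survival_series(fit_result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-interval survival estimates with Wald CIs on the logit scale.

    Intervals whose logit is at a boundary or whose curvature is deficient
    (huge or undefined SE) are flagged; under fully time-dependent structures
    the final interval's survival is confounded with the final resighting
    probability and typically carries such a flag.
    """
    d = fit_result.design
    beta = fit_result.estimates[: d.k_phi]
    V = fit_result.vcov[: d.k_phi, : d.k_phi]
    eta = d.Xphi @ beta
    var_eta = np.einsum("ij,jk,ik->i", d.Xphi, V, d.Xphi)
    se_eta = np.sqrt(np.clip(var_eta, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2)
    lo = _invlogit(eta - z * se_eta)
    hi = _invlogit(eta + z * se_eta)
    flagged = (np.abs(eta) > _BOUNDARY_LOGIT) | (se_eta > 10.0) | ~np.isfinite(se_eta)
    return pd.DataFrame(
        {
            "interval": np.arange(1, d.T + 1),
            "phi": _invlogit(eta),
            "se_logit": se_eta,
            "lo": lo,
            "hi": hi,
            "flagged": flagged,
        }
    )


def rank_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """QAICc model table: sorted, with deltas, Akaike weights and likelihoods."""
    if not fits:
        raise ValueError("no fits to rank")
    chats = {round(f.chat_used, 12) for f in fits}
    if len(chats) != 1:
        raise ValueError(f"fits use different chat values: {sorted(chats)}")
    rows = [
        {"model": f.label, "qaicc": f.qaicc, "k": f.k,
         "minus2lnl": f.minus2lnl, "converged": f.converged}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(
        ["qaicc", "k", "model"], kind="mergesort"
    ).reset_index(drop=True)
    df["delta_qaicc"] = df["qaicc"] - df["qaicc"].iloc[0]
    df["model_likelihood"] = np.exp(-df["delta_qaicc"] / 2)
    df["weight"] = df["model_likelihood"] / df["model_likelihood"].sum()
    return df[["model", "qaicc", "delta_qaicc", "weight", "model_likelihood",
               "k", "minus2lnl", "converged"]]


@dataclass
class AnodevResult:
    r2: float
    f: float
    df1: int
    df2: int
    p: float


def anodev(
    fit_constant: FitResult,
    fit_covariate: FitResult,
    fit_time: FitResult,
    chat: float | None = None,
) -> AnodevResult:
    """Analysis of deviance: share of temporal deviance explained by covariates.

    With quasi-deviances D = -2lnL / chat, R2 = (D_cst - D_cov)/(D_cst - D_t)
    and F = [(D_cst - D_cov)/J] / [(D_cov - D_t)/(T - J - 1)] on (J, T-J-1) df.
    """
    chat = fit_covariate.chat_used if chat is None else chat
    d_cst = fit_constant.minus2lnl / chat
    d_cov = fit_covariate.minus2lnl / chat
    d_t = fit_time.minus2lnl / chat
    J = fit_covariate.n_slopes
    T = fit_covariate.n_intervals
    if J < 1:
        raise ValueError("covariate model has no slopes")
    if d_cst < d_t - 1e-9:
        raise ValueError("deviance ordering violated: constant model fits better than time model")
    df2 = T - J - 1
    if df2 <= 0:
        raise ValueError(f"non-positive denominator df (T={T}, J={J})")
    denom = d_cst - d_t
    r2 = (d_cst - d_cov) / denom if denom > 0 else 0.0
    resid = (d_cov - d_t) / df2
    f_stat = 0.0 if (d_cst - d_cov) <= 0 else ((d_cst - d_cov) / J) / max(resid, 1e-300)
    p = float(stats.f.sf(f_stat, J, df2))
    return AnodevResult(float(r2), float(f_stat), J, df2, p)


def covariate_effect(fit_result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Logit-scale slope estimates with Wald SEs and CIs (singular -> NaN SE)."""
    if fit_result.n_slopes == 0:
        raise ValueError("model has no covariate slopes")
    d = fit_result.design
    names = d.phi_names
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for idx in range(1, d.k_phi):  # skip intercept
        beta = fit_result.estimates[idx]
        var = fit_result.vcov[idx, idx]
        se = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else np.nan
        rows.append(
            {"term": names[idx], "beta": float(beta), "se": se,
             "lo": beta - z * se if np.isfinite(se) else np.nan,
             "hi": beta + z * se if np.isfinite(se) else np.nan}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate model sets


@dataclass
class CandidateConfig:
    """Which covariates a species' candidate model sets may draw on."""

    species: str
    environmental: tuple[str, ...] = ("sSST", "wSST", "lag_sSST", "lag_wSST", "naoi")
    include_population: bool = True
    include_oil: bool = True
    storm_variables: tuple[str, ...] = ()
    storminess: str | None = "PC1"

    def __post_init__(self) -> None:
        if self.species.lower() == "puffin" and self.include_population:
            raise ValueError(
                "population-count models are unsupported for puffins "
                "(counts do not span the study)"
            )


def _dedupe(items: list[ModelStructure]) -> list[ModelStructure]:
    seen: set[str] = set()
    out = []
    for s in items:
        if s.label not in seen:
            seen.add(s.label)
            out.append(s)
    return out


def resighting_candidates(phi_spec: str = "t") -> list[ModelStructure]:
    """Resighting structures screened under time-dependent survival."""
    return [ModelStructure(phi_spec, p) for p in ("./t", "t/.", "t+m", "./.")]


def survival_candidates(config: CandidateConfig, p_spec: str) -> list[ModelStructure]:
    """Environmental candidate set: singles, plus storminess +/x combinations."""
    pc1 = config.storminess
    phis: list[str] = [".", "t"]
    if pc1:
        phis.append(pc1)
    phis.extend(config.environmental)
    combos = [c for c in config.environmental if c.lower() != "naoi"]
    if config.include_population:
        phis.append("population")
        combos.append("population")
    if pc1:
        for x in combos:
            phis.append(f"{pc1} + {x}")
            phis.append(f"{pc1} * {x}")
    if config.include_oil:
        phis.append("oil")
    return _dedupe([ModelStructure(s, p_spec) for s in phis])


def storm_candidates(
    config: CandidateConfig,
    p_spec: str,
    best_storm: str | None = None,
    best_environmental: str | None = None,
) -> list[ModelStructure]:
    """Storm-characteristic set: each storm variable alone, plus the best
    storm variable combined with the best environmental covariate."""
    phis: list[str] = [".", "t"]
    phis.extend(config.storm_variables)
    if best_storm is not None and best_environmental is not None:
        phis.append(f"{best_storm} + {best_environmental}")
        phis.append(f"{best_storm} * {best_environmental}")
    return _dedupe([ModelStructure(s, p_spec) for s in phis])
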