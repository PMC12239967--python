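"""Ring-neighborhood composition modeling with a Poisson mixed count model.

For each focal cell type, the number of focal-type cells in each ring
neighborhood of each leukemia cell is modeled as

    log E[count] = log(total) + response x timepoint x ring (full factorial)
                   + u_FOV,   u_FOV ~ N(0, sigma^2)

where ``total`` is the number of typed cells in that ring (an offset: the
model describes the focal type's *share* of the neighborhood) and the FOV
random intercept absorbs field-to-field density variation.  Estimation is
maximum likelihood with a Laplace approximation of the marginal likelihood
(penalized IRLS for the joint mode, a 1-D profile over the variance
component — the nAGQ=1 scheme of standard mixed-model software).

Records sharing a FOV and a covariate cell are collapsed by summing counts
and totals before fitting; under the model this is an exact reduction
(sums of independent Poissons with a shared rate and random effect).

Contrasts of interest (per ring: responders post-ICI vs baseline,
nonresponders post-ICI vs baseline, responders vs nonresponders at
baseline) are Wald tests on linear combinations of the fixed effects, with
Bonferroni adjustment over the whole family of contrasts x fitted models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import gammaln
from scipy.stats import norm

from .io import TIMEPOINTS, CellRecord, cells_to_dataframe

logger = logging.getLogger("nichemap.glmm")

RING_COUNT_COLUMNS = [
    "leukemia_cell_id", "fov_id", "patient_id", "response", "timepoint",
    "ring_index", "focal_type", "count", "total",
]


def build_ring_counts(
    ring_assignment: pd.DataFrame,
    cells: Sequence[CellRecord] | pd.DataFrame,
    focal_types: Sequence[str] | None = None,
    exclude_types: Sequence[str] = ("RBC", "unassigned"),
) -> pd.DataFrame:
    """Per-leukemia-cell, per-ring, per-type counts with ring totals.

    ``ring_assignment`` comes from :func:`nichemap.geometry.assign_rings`.
    Ring totals count every typed neighbor except ``exclude_types`` (RBCs
    and untyped cells by default; leukemia neighbors are counted).  One
    record is emitted per (leukemia cell, ring with positive total, focal
    type), with zero counts kept — the model needs them.
    """
    meta = cells if isinstance(cells, pd.DataFrame) else cells_to_dataframe(cells)
    meta = meta.set_index("cell_id")
    ra = ring_assignment.copy()
    ra["neighbor_type"] = meta.loc[ra["other_cell_id"], "cell_type"].to_numpy()
    ra = ra[~ra["neighbor_type"].isin(exclude_types)]
    if focal_types is None:
        focal_types = sorted(set(ra["neighbor_type"]) - {"leukemia"})
    groups = ra.groupby(["leukemia_cell_id", "ring_index"])
    totals = groups.size().rename("total")
    type_counts = (
        ra.groupby(["leukemia_cell_id", "ring_index", "neighbor_type"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(focal_types), fill_value=0)
    )
    out = type_counts.join(totals).reset_index()
    out = out.melt(
        id_vars=["leukemia_cell_id", "ring_index", "total"],
        value_vars=list(focal_types),
        var_name="focal_type",
        value_name="count",
    )
    leuk_meta = meta.loc[out["leukemia_cell_id"], ["fov_id", "patient_id", "response", "timepoint"]]
    out = pd.concat([out.reset_index(drop=True), leuk_meta.reset_index(drop=True)], axis=1)
    out = out[out["total"] > 0]
    return out[RING_COUNT_COLUMNS].sort_values(
        ["focal_type", "leukemia_cell_id", "ring_index"]
    ).reset_index(drop=True)


class FactorialDesign:
    """Treatment-coded full-factorial design over response, timepoint, ring."""

    def __init__(self, responses: Sequence[str], timepoints: Sequence[str], rings: Sequence[int]):
        self.responses = list(responses)
        self.timepoints = list(timepoints)
        self.rings = list(rings)
        self._factors = [
            ("response", self.responses),
            ("timepoint", self.timepoints),
            ("ring", self.rings),
        ]
        self.terms = ["Intercept"]
        self._term_levels: list[tuple[tuple[str, object], ...]] = [()]
        for k in (1, 2, 3):
            for combo in itertools.combinations(self._factors, k):
                for levels in itertools.product(*[f[1][1:] for f in combo]):
                    key = tuple((f[0], lev) for f, lev in zip(combo, levels))
                    self._term_levels.append(key)
                    self.terms.append(":".join(f"{n}[{lev}]" for n, lev in key))

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "FactorialDesign":
        resp = [r for r in ("nonresponder", "responder") if r in set(records["response"])]
        tps = [t for t in TIMEPOINTS if t in set(records["timepoint"])]
        rings = sorted(set(records["ring_index"]))
        return cls(resp, tps, rings)

    def row(self, response: str, timepoint: str, ring: int) -> np.ndarray:
        values = {"response": response, "timepoint": timepoint, "ring": ring}
        for name, levels in self._factors:
            if values[name] not in levels:
                raise ValueError(f"level {values[name]!r} absent from factor {name}")
        out = np.empty(len(self.terms))
        for i, key in enumerate(self._term_levels):
            out[i] = float(all(values[name] == lev for name, lev in key))
        return out

    def matrix(self, records: pd.DataFrame) -> np.ndarray:
        rows = {
            key: self.row(*key)
            for key in set(zip(records["response"], records["timepoint"], records["ring_index"]))
        }
        return np.vstack([
            rows[key] for key in zip(records["response"], records["timepoint"], records["ring_index"])
        ])


@dataclass
class PoissonGLMMFit:
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray  # fixed-effect covariance (conditional on sigma)
    sigma2: float
    u: np.ndarray  # conditional modes of the random intercepts
    loglik: float
    converged: bool


def fit_poisson_glmm(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    groups: np.ndarray,
    log_sigma_bounds: tuple[float, float] = (-6.0, 2.0),
) -> PoissonGLMMFit:
    """Laplace-approximated ML for a Poisson GLMM with one random intercept.

    Inner loop: penalized IRLS for the joint (beta, u) mode at fixed sigma.
    Outer loop: bounded 1-D maximization of the Laplace marginal
    log-likelihood over log(sigma).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    codes, _ = pd.factorize(groups)
    n, p = X.shape
    G = int(codes.max()) + 1
    const = -gammaln(y + 1).sum()

    state = {"theta": None}

    def pirls(sigma2: float):
        theta = state["theta"]
        if theta is None:
            beta = np.zeros(p)
            beta[0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
            theta = np.concatenate([beta, np.zeros(G)])
        for _ in range(100):
            beta, u = theta[:p], theta[p:]
            eta = offset + X @ beta + u[codes]
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-12)
            XtW = X.T * w
            A11 = XtW @ X
            A12 = np.zeros((p, G))
            for j in range(p):
                A12[j] = np.bincount(codes, weights=w * X[:, j], minlength=G)
            d22 = np.bincount(codes, weights=w, minlength=G) + 1.0 / sigma2
            b1 = XtW @ z
            b2 = np.bincount(codes, weights=w * z, minlength=G)
            # solve the arrowhead system by eliminating the u block
            inv_d = 1.0 / d22
            S = A11 - (A12 * inv_d) @ A12.T
            rhs = b1 - A12 @ (inv_d * b2)
            try:
                beta_new = scipy.linalg.solve(S + 1e-10 * np.eye(p), rhs, assume_a="pos")
            except scipy.linalg.LinAlgError:
                return theta, False
            u_new = inv_d * (b2 - A12.T @ beta_new)
            theta_new = np.concatenate([beta_new, u_new])
            step = theta_new - theta
            if np.max(np.abs(step)) < 1e-9:
                theta = theta_new
                state["theta"] = theta
                return theta, True
            theta = theta_new
        state["theta"] = theta
        return theta, False

    def laplace_ll(sigma2: float) -> tuple[float, np.ndarray, bool]:
        theta, ok = pirls(sigma2)
        beta, u = theta[:p], theta[p:]
        eta = offset + X @ beta + u[codes]
        mu = np.exp(np.clip(eta, -30, 30))
        group_mu = np.bincount(codes, weights=mu, minlength=G)
        ll = (
            (y * eta - mu).sum() + const
            - (u**2).sum() / (2 * sigma2)
            - 0.5 * np.log1p(sigma2 * group_mu).sum()
        )
        return ll, theta, ok

    def neg_ll(log_sigma: float) -> float:
        return -laplace_ll(np.exp(2 * log_sigma))[0]

    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=log_sigma_bounds, method="bounded",
        options={"xatol": 1e-4},
    )
    sigma2 = float(np.exp(2 * res.x))
    ll, theta, ok = laplace_ll(sigma2)
    beta, u = theta[:p], theta[p:]

    # conditional fixed-effect covariance from the penalized information
    eta = offset + X @ beta + u[codes]
    w = np.exp(np.clip(eta, -30, 30))
    XtW = X.T * w
    A11 = XtW @ X
    A12 = np.zeros((p, G))
    for j in range(p):
        A12[j] = np.bincount(codes, weights=w * X[:, j], minlength=G)
    d22 = np.bincount(codes, weights=w, minlength=G) + 1.0 / sigma2
    S = A11 - (A12 / d22) @ A12.T
    vcov = scipy.linalg.inv(S + 1e-10 * np.eye(p))
    se = np.sqrt(np.diag(vcov))
    return PoissonGLMMFit(beta, se, vcov, sigma2, u, float(ll), bool(res.success and ok))


def fit_fixed_fov_glm(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-check fit: plain Poisson GLM with one fixed effect per FOV.

    FOVs are nested within (response, timepoint), so FOV dummies absorb
    those factors entirely — only within-FOV terms (the ring main effects
    and their interactions realized within a FOV) remain identifiable.
    Useful as an independent check on the mixed model's ring coefficients,
    not as a substitute for it.  Returns a term/estimate/se table.
    """
    import statsmodels.api as sm

    df = records[records["total"] > 0].copy()
    df = (
        df.groupby(["fov_id", "response", "timepoint", "ring_index"], as_index=False)
        .agg(count=("count", "sum"), total=("total", "sum"))
    )
    rings = sorted(df["ring_index"].unique())
    ring_dummies = pd.get_dummies(df["ring_index"], prefix="ring", dtype=float)[
        [f"ring_{r}" for r in rings[1:]]
    ]
    fov_dummies = pd.get_dummies(df["fov_id"], prefix="fov", dtype=float)
    X = pd.concat([ring_dummies, fov_dummies], axis=1)
    fit = sm.GLM(
        df["count"].to_numpy(), X.to_numpy(),
        family=sm.families.Poisson(),
        offset=np.log(df["total"].to_numpy(dtype=float)),
    ).fit()
    return pd.DataFrame({"term": X.columns, "estimate": fit.params, "se": fit.bse})


@dataclass
class NicheModelResult:
    focal_type: str
    design: FactorialDesign
    coefficients: pd.DataFrame  # term, estimate, se
    sigma2: float
    vcov: np.ndarray
    converged: bool
    n_obs: int
    contrasts: pd.DataFrame | None = field(default=None)


def fit_niche_model(records: pd.DataFrame, focal_type: str | None = None) -> NicheModelResult:
    """Fit the ring-composition model for one focal cell type."""
    df = records.copy()
    if focal_type is not None:
        df = df[df["focal_type"] == focal_type]
    else:
        types = set(df["focal_type"])
        if len(types) != 1:
            raise ValueError(f"records hold {len(types)} focal types; pass focal_type")
        focal_type = next(iter(types))
    df = df[df["total"] > 0]
    for factor in ("response", "timepoint", "ring_index"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has <2 levels in the data")
    # exact collapse: same FOV and covariate cell share rate and random effect
    df = (
        df.groupby(["fov_id", "response", "timepoint", "ring_index"], as_index=False)
        .agg(count=("count", "sum"), total=("total", "sum"))
    )
    design = FactorialDesign.from_records(df)
    X = design.matrix(df)
    fit = fit_poisson_glmm(
        X, df["count"].to_numpy(), np.log(df["total"].to_numpy(dtype=float)),
        df["fov_id"].to_numpy(),
    )
    coef = pd.DataFrame({"term": design.terms, "estimate": fit.beta, "se": fit.se})
    if not fit.converged:
        logger.warning("niche model for %r did not converge", focal_type)
    return NicheModelResult(
        focal_type=focal_type, design=design, coefficients=coef,
        sigma2=fit.sigma2, vcov=fit.vcov, converged=fit.converged, n_obs=len(df),
    )


def default_contrasts(design: FactorialDesign) -> list[tuple[str, tuple, tuple]]:
    """The built-in per-ring contrasts, for the levels the model has."""
    specs = []
    has_post = "post_ici" in design.timepoints and "baseline" in design.timepoints
    both_resp = {"responder", "nonresponder"} <= set(design.responses)
    for ring in design.rings:
        if has_post and "responder" in design.responses:
            specs.append((
                f"responder_post_vs_baseline_ring{ring}",
                ("responder", "post_ici", ring), ("responder", "baseline", ring),
            ))
        if has_post and "nonresponder" in design.responses:
            specs.append((
                f"nonresponder_post_vs_baseline_ring{ring}",
                ("nonresponder", "post_ici", ring), ("nonresponder", "baseline", ring),
            ))
        if both_resp and "baseline" in design.timepoints:
            specs.append((
                f"responder_vs_nonresponder_baseline_ring{ring}",
                ("responder", "baseline", ring), ("nonresponder", "baseline", ring),
            ))
    return specs


def niche_contrasts(
    results: Sequence[NicheModelResult],
    contrast_spec: str | list[tuple[str, tuple, tuple]] = "default",
) -> pd.DataFrame:
    """Wald contrasts with Bonferroni adjustment over models x contrasts.

    Each contrast is ``c = row(cell_a) - row(cell_b)``: the log rate ratio
    between two (response, timepoint, ring) conditions.  Raw p-values are
    two-sided Wald; the Bonferroni family is every contrast of every fitted
    model passed in.
    """
    rows = []
    for res in results:
        if not res.converged:
            logger.warning("skipping contrasts for non-converged model %r", res.focal_type)
            continue
        specs = default_contrasts(res.design) if contrast_spec == "default" else contrast_spec
        beta = res.coefficients["estimate"].to_numpy()
        for name, cond_a, cond_b in specs:
            c = res.design.row(*cond_a) - res.design.row(*cond_b)
            est = float(c @ beta)
            se = float(np.sqrt(c @ res.vcov @ c))
            z = est / se if se > 0 else np.inf
            p = 2 * norm.sf(abs(z))
            ci = (est - 1.96 * se, est + 1.96 * se)
            rows.append({
                "focal_type": res.focal_type, "contrast": name,
                "log_rr": est, "rr": float(np.exp(est)), "se": se,
                "ci_low": float(np.exp(ci[0])), "ci_high": float(np.exp(ci[1])),
                "p_raw": float(p),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out
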