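"""Functional readouts: competitive protease inhibition, affinity-column
retention, and NMR chemical-shift perturbation.

Protease inhibition is modelled as classical competitive inhibition of a
Michaelis-Menten enzyme: the apparent Michaelis constant scales as
``K_M(app) = K_M (1 + [I]/K_I)`` while ``V_max`` is unchanged.  The
inhibition constant is recovered two ways from an initial-rate table —
per-inhibitor-level Michaelis-Menten fits followed by a weighted linear
regression of ``K_M(app)`` on ``[I]``, and a global one-stage fit — and
both estimates are reported.

Binding affinity is read out from retention on an affinity column under
fast-equilibrium assumptions: the elution volume (in column volumes) is
``1 + [sites]/K_D``, so complete retention past a CV threshold bounds
``K_D`` from above.

Enzyme depletion is ignored throughout ([E] well below K_I); a
tight-binding correction is deliberately out of scope and a warning is
logged when inhibitor concentrations approach the enzyme concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

logger = logging.getLogger(__name__)

#: Substrate grid used for K_M / K_M(apparent) determination, uM.
SUBSTRATE_GRID_UM = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
#: Inhibitor levels for competitive-inhibition assays, nM.
INHIBITOR_GRID_NM = (0.0, 50.0, 100.0)
#: Default immobilised binding-site concentration, uM.
SITE_CONC_UM = 100.0
#: Column volumes after which complete retention is called.
CV_THRESHOLD = 20.0
#: Chemical-shift perturbation weights (1H, 15N).
W_H, W_N = 1.0, 0.2


# -- kinetics primitives ---------------------------------------------------


def mm_rate(S, V_max: float, K_M: float):
    """Michaelis-Menten initial rate ``v = V_max S / (K_M + S)``."""
    if K_M <= 0:
        raise DomainError("K_M must be positive")
    S = np.asarray(S, dtype=float)
    v = V_max * S / (K_M + S)
    return float(v) if v.shape == () else v


def km_apparent(K_M: float, I: float, K_I: float) -> float:
    """Apparent Michaelis constant under competitive inhibition.

    ``K_M(app) = K_M (1 + I/K_I)``; ``I`` and ``K_I`` share units (nM here).
    """
    if K_I <= 0:
        raise DomainError("K_I must be positive")
    if I < 0:
        raise DomainError("inhibitor concentration must be non-negative")
    return K_M * (1.0 + I / K_I)


# -- datasets --------------------------------------------------------------


@dataclass(frozen=True)
class InhibitionDataset:
    """Initial-rate table over a substrate x inhibitor grid.

    ``rates[i, s]`` is the rate at ``inhibitor_nM[i]``, ``substrate_uM[s]``.
    """

    substrate_uM: tuple[float, ...]
    inhibitor_nM: tuple[float, ...]
    rates: np.ndarray
    enzyme_nM: float = 1.0
    rate_units: str = "uM/min"

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (len(self.inhibitor_nM), len(self.substrate_uM)):
            raise DomainError("rate matrix shape must be (n_inhibitor, n_substrate)")
        if np.any(r < 0):
            raise DomainError("rates must be non-negative")
        object.__setattr__(self, "rates", r)
        if any(0 < i < 10 * self.enzyme_nM for i in self.inhibitor_nM):
            logger.warning(
                "inhibitor levels within 10x enzyme concentration: "
                "tight-binding effects ignored by this model"
            )


@dataclass(frozen=True)
class KiFit:
    """Competitive-inhibition fit: two-stage and global K_I estimates (nM)."""

    K_I: float
    K_I_stderr: float
    K_I_global: float
    K_I_global_stderr: float
    K_M: float
    V_max: float
    km_app_by_level: tuple[float, ...]
    no_inhibition: bool = False
    message: str = ""


def _fit_mm_level(S: np.ndarray, v: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Stage-1 Michaelis-Menten fit; returns (V_max, K_M_app, covariance)."""
    v_max0 = float(np.max(v)) * 1.2 + 1e-9
    km0 = float(np.median(S))
    try:
        popt, pcov = curve_fit(
            lambda s, vm, km: vm * s / (km + s),
            S, v, p0=[v_max0, km0],
            bounds=([1e-12, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
    return float(popt[0]), float(popt[1]), pcov


def fit_ki(dataset: InhibitionDataset) -> KiFit:
    """Estimate the competitive inhibition constant K_I from a rate table.

    Stage 1 fits ``(V_max, K_M(app))`` per inhibitor level; stage 2
    regresses ``K_M(app)`` on ``[I]`` (inverse-variance weights from the
    stage-1 standard errors when available) giving
    ``K_I = K_M(0) / slope``.  A global one-stage fit of
    ``v = V_max S / (K_M (1 + I/K_I) + S)`` is reported alongside.  A
    non-positive slope is reported as "no inhibition detected".
    """
    I = np.asarray(dataset.inhibitor_nM, dtype=float)
    S = np.asarray(dataset.substrate_uM, dtype=float)
    if len(I) < 2 or 0.0 not in I:
        raise DomainError("need at least two inhibitor levels including I = 0")
    if len(S) < 4:
        raise DomainError("need at least four substrate levels")

    km_apps, km_vars, vmaxes = [], [], []
    for k in range(len(I)):
        try:
            vm, km, pcov = _fit_mm_level(S, dataset.rates[k])
        except FitError as exc:
            raise FitError(f"inhibitor level {k} ([I]={I[k]} nM): {exc}") from exc
        km_apps.append(km)
        vmaxes.append(vm)
        var = pcov[1, 1] if np.all(np.isfinite(pcov)) else np.nan
        km_vars.append(var)
    km_apps = np.array(km_apps)
    km_vars = np.array(km_vars)

    # Stage 2: weighted linear regression K_M(app) = K_M + slope * I.
    if np.all(np.isfinite(km_vars)) and np.all(km_vars > 0):
        w = 1.0 / km_vars
    else:
        w = np.ones_like(km_apps)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(I), I])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * km_apps, rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])
    cov = np.linalg.inv(X.T @ W @ X)

    # slope <= 0, or a K_M(app) rise over the whole inhibitor range that is
    # negligible next to K_M itself, means no measurable inhibition
    if slope <= 0 or slope * float(np.max(I)) < 1e-6 * max(intercept, 1e-12):
        return KiFit(
            K_I=math.nan, K_I_stderr=math.nan,
            K_I_global=math.nan, K_I_global_stderr=math.nan,
            K_M=intercept, V_max=float(np.mean(vmaxes)),
            km_app_by_level=tuple(km_apps),
            no_inhibition=True,
            message="no inhibition detected (K_M(app) does not increase with [I])",
        )

    ki = intercept / slope
    # First-order error propagation for K_I = intercept/slope.
    var_i, var_s, cov_is = cov[0, 0], cov[1, 1], cov[0, 1]
    ki_var = ki**2 * (var_i / intercept**2 + var_s / slope**2 - 2 * cov_is / (intercept * slope))
    ki_stderr = math.sqrt(max(ki_var, 0.0))

    # Global one-stage fit.
    grid_I, grid_S = np.meshgrid(I, S, indexing="ij")
    flat_I, flat_S = grid_I.ravel(), grid_S.ravel()
    flat_v = dataset.rates.ravel()

    def global_model(x, vm, km, ki_):
        i_, s_ = x
        return vm * s_ / (km * (1.0 + i_ / ki_) + s_)

    try:
        popt, pcov = curve_fit(
            global_model, (flat_I, flat_S), flat_v,
            p0=[float(np.mean(vmaxes)), max(intercept, 1e-6), max(ki, 1e-6)],
            bounds=([1e-12, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        ki_g = float(popt[2])
        ki_g_err = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else math.nan
    except RuntimeError:
        ki_g, ki_g_err = math.nan, math.nan
        logger.warning("global K_I fit did not converge; two-stage estimate only")

    return KiFit(
        K_I=float(ki), K_I_stderr=float(ki_stderr),
        K_I_global=ki_g, K_I_global_stderr=ki_g_err,
        K_M=float(intercept), V_max=float(np.mean(vmaxes)),
        km_app_by_level=tuple(float(k) for k in km_apps),
    )


# -- retention assay -------------------------------------------------------


@dataclass(frozen=True)
class RetentionResult:
    elution_cv: float
    retained: bool
    kd_bound: str


def retention_classify(
    K_D_uM: float,
    site_conc_uM: float = SITE_CONC_UM,
    cv_threshold: float = CV_THRESHOLD,
) -> RetentionResult:
    """Affinity-column retention call under fast-equilibrium binding.

    ``elution_cv = 1 + [sites]/K_D``; the protein is called retained when
    the elution volume reaches ``cv_threshold`` column volumes.  A
    retained protein gets a conservative order-of-magnitude upper bound
    on K_D (with the default 100 uM sites and 20 CV threshold this reads
    "K_D <= 1 uM"); otherwise the model's point estimate is echoed.
    """
    if K_D_uM <= 0 or site_conc_uM <= 0 or cv_threshold <= 0:
        raise DomainError("K_D, site concentration and CV threshold must be positive")
    elution = 1.0 + site_conc_uM / K_D_uM
    retained = elution >= cv_threshold
    if retained:
        kd_at_threshold = site_conc_uM / (cv_threshold - 1.0)
        bound = 10.0 ** math.floor(math.log10(kd_at_threshold))
        text = f"K_D <= {bound:g} uM"
    else:
        text = f"K_D ~ {K_D_uM:g} uM (not retained)"
    return RetentionResult(elution_cv=float(elution), retained=bool(retained), kd_bound=text)


# -- chemical shift perturbation -------------------------------------------


def csp(dH: float, dN: float, w_h: float = W_H, w_n: float = W_N) -> float:
    """Combined 1H/15N chemical-shift perturbation in ppm.

    ``ddelta_total = sqrt((w_H ddelta_H)^2 + (w_N ddelta_N)^2)`` with the
    conventional weights w_H = 1 and w_N = 0.2.
    """
    return math.sqrt((w_h * dH) ** 2 + (w_n * dN) ** 2)


def csp_table(df):
    """Add a ``ddelta_total_ppm`` column to a (residue, dH_ppm, dN_ppm) frame."""
    out = df.copy()
    out["ddelta_total_ppm"] = [csp(h, n) for h, n in zip(df["dH_ppm"], df["dN_ppm"])]
    return out


# -- tabular IO ------------------------------------------------------------


def read_kinetics_csv(path, enzyme_nM: float = 1.0) -> InhibitionDataset:
    """Read a long-format (inhibitor_nM, substrate_uM, rate) CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    needed = {"inhibitor_nM", "substrate_uM", "rate"}
    if not needed.issubset(df.columns):
        raise DomainError(f"kinetics CSV must have columns {sorted(needed)}")
    I = sorted(df["inhibitor_nM"].unique())
    S = sorted(df["substrate_uM"].unique())
    rates = np.full((len(I), len(S)), np.nan)
    for _, row in df.iterrows():
        rates[I.index(row["inhibitor_nM"]), S.index(row["substrate_uM"])] = row["rate"]
    if np.any(~np.isfinite(rates)):
        raise DomainError("kinetics CSV does not cover the full inhibitor x substrate grid")
    return InhibitionDataset(
        substrate_uM=tuple(S), inhibitor_nM=tuple(I), rates=rates, enzyme_nM=enzyme_nM
    )


def write_kinetics_csv(path, dataset: InhibitionDataset) -> None:
    import pandas as pd

    rows = [
        {"inhibitor_nM": i, "substrate_uM": s, "rate": dataset.rates[a, b]}
        for a, i in enumerate(dataset.inhibitor_nM)
        for b, s in enumerate(dataset.substrate_uM)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
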