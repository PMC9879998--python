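"""Two-state stability, fold-switch linkage, and CD melting curves.

Each construct is treated as a two-state folder whose unfolding free
energy follows the Gibbs-Helmholtz relation

    dG_unf(T) = dHm (1 - T/Tm) - dCp [(Tm - T) + T ln(T/Tm)]

with ``Tm`` the melting midpoint, ``dHm`` the van 't Hoff enthalpy at
``Tm`` and ``dCp`` the heat-capacity change of unfolding.  The sign
convention throughout is that ``dG_folding = -dG_unf`` is *negative* for
a stable fold.

Because the short construct is exactly the embedded window of the long
one, the equilibria S-fold <-> U <-> G-fold are thermodynamically
linked: the free energy of switching from the long (S) fold to the
embedded (G) fold is approximated by the difference of the two folding
free energies, ``dG_switch = dG_short - dG_long``, and the three state
populations follow from the two Boltzmann factors.

Temperatures are accepted in degrees Celsius at every public interface
and converted internally to Kelvin; free energies are kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError, FitError

logger = logging.getLogger(__name__)

#: Gas constant, kcal / (mol K).
R_KCAL = 1.9872e-3
CELSIUS_OFFSET = 273.15
#: Default reference temperature for dG_folding, deg C.
T_REF_C = 25.0
#: Empirical heat-capacity change of unfolding per residue, kcal/(mol K).
DCP_PER_RESIDUE = 0.014


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


# -- domain types ----------------------------------------------------------


@dataclass(frozen=True)
class ThermoState:
    """Two-state stability parameters for one construct.

    ``tm_K`` in Kelvin (constructors accept Celsius via :meth:`from_celsius`),
    ``dHm`` kcal/mol (> 0 for cooperative unfolding), ``dCp`` kcal/(mol K).
    """

    name: str
    tm_K: float
    dHm: float
    dCp: float = 0.0
    t_ref_C: float = T_REF_C

    def __post_init__(self):
        if self.tm_K <= 0:
            raise DomainError("Tm must be positive (Kelvin)")
        if self.dHm <= 0:
            raise DomainError("dHm must be positive for cooperative unfolding")

    @classmethod
    def from_celsius(cls, name: str, tm_C: float, dHm: float, dCp: float = 0.0,
                     t_ref_C: float = T_REF_C) -> "ThermoState":
        return cls(name=name, tm_K=celsius_to_kelvin(tm_C), dHm=dHm, dCp=dCp, t_ref_C=t_ref_C)

    @property
    def tm_C(self) -> float:
        return self.tm_K - CELSIUS_OFFSET

    @property
    def dG_ref(self) -> float:
        """dG_folding at the reference temperature (negative = stable)."""
        return gibbs_helmholtz(celsius_to_kelvin(self.t_ref_C), self)


@dataclass(frozen=True)
class SwitchEquilibrium:
    """Three-state populations of long fold (S), embedded fold (G), unfolded (U)."""

    dG_long: float
    dG_switch: float
    T: float  # Kelvin
    f_S: float
    f_G: float
    f_U: float

    def __post_init__(self):
        total = self.f_S + self.f_G + self.f_U
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"populations sum to {total}, not 1")
        for f in (self.f_S, self.f_G, self.f_U):
            if not (0.0 <= f <= 1.0):
                raise DomainError("populations must lie in [0, 1]")


@dataclass(frozen=True)
class MeltingCurve:
    """Ellipticity-vs-temperature melt, mean residue ellipticity at 222 nm."""

    temperatures_C: np.ndarray
    ellipticity: np.ndarray
    baselines: dict | None = None

    def __post_init__(self):
        t = np.asarray(self.temperatures_C, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if t.shape != y.shape:
            raise DomainError("temperature and ellipticity grids differ in length")
        if np.any(np.diff(t) <= 0):
            raise DomainError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures_C", t)
        object.__setattr__(self, "ellipticity", y)


# -- core relations --------------------------------------------------------


def gibbs_helmholtz(T: float, state: ThermoState) -> float:
    """dG_folding(T) in kcal/mol (negative when the fold is stable).

    ``dG_unf(T) = dHm (1 - T/Tm) - dCp [(Tm - T) + T ln(T/Tm)]``; the
    returned value is ``-dG_unf``.  ``T`` in Kelvin.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (Kelvin)")
    dg_unf = state.dHm * (1.0 - T / state.tm_K) - state.dCp * (
        (state.tm_K - T) + T * np.log(T / state.tm_K)
    )
    return -dg_unf if dg_unf.shape else float(-dg_unf)


def switch_free_energy(dG_short: float, dG_long: float) -> float:
    """Fold-switch free energy ``dG_switch = dG_short - dG_long``.

    Positive means the long fold is favoured over the embedded fold.
    """
    if not (np.isfinite(dG_short) and np.isfinite(dG_long)):
        raise DomainError("folding free energies must be finite")
    return dG_short - dG_long


def three_state_populations(dG_long: float, dG_switch: float, T: float) -> SwitchEquilibrium:
    """Populations of the linked S (long fold) / G (embedded fold) / U equilibrium.

    ``K_S = exp(-dG_long / RT)``; ``K_G = exp(-(dG_long + dG_switch)/RT)``;
    ``f_U = 1/(1 + K_S + K_G)``.  Evaluated in log space so extreme
    stabilities cannot overflow.  ``T`` in Kelvin.
    """
    if T <= 0:
        raise DomainError("temperature must be positive (Kelvin)")
    rt = R_KCAL * T
    logits = np.array([0.0, -dG_long / rt, -(dG_long + dG_switch) / rt])
    log_z = logsumexp(logits)
    f_u, f_s, f_g = np.exp(logits - log_z)
    return SwitchEquilibrium(
        dG_long=dG_long, dG_switch=dG_switch, T=T, f_S=float(f_s), f_G=float(f_g), f_U=float(f_u)
    )


# -- melt simulation -------------------------------------------------------

#: Typical 222 nm baselines: (folded intercept, folded slope,
#: unfolded intercept, unfolded slope), deg cm^2 dmol^-1 vs deg C.
DEFAULT_BASELINES = (-12000.0, 20.0, -3000.0, 5.0)


def fraction_unfolded(state: ThermoState, t_C: np.ndarray) -> np.ndarray:
    """Two-state unfolded fraction over a Celsius grid (overflow-safe)."""
    t_K = np.asarray(t_C, dtype=float) + CELSIUS_OFFSET
    dg_unf = -gibbs_helmholtz(t_K, state)
    from scipy.special import expit

    return expit(-dg_unf / (R_KCAL * t_K))


def simulate_melt(
    state: ThermoState,
    baselines: tuple[float, float, float, float] = DEFAULT_BASELINES,
    t_grid_C: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> MeltingCurve:
    """Simulate a two-state CD melt with linear baselines and Gaussian noise.

    ``theta(T) = theta_N(T) (1 - f_U) + theta_U(T) f_U`` with
    ``f_U = K/(1+K)``, ``K = exp(-dG_unf/RT)``.  ``noise_sd = 0`` gives a
    deterministic curve; otherwise the seed fixes the noise draw.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if t_grid_C is None:
        t_grid_C = default_melt_grid()
    t = np.asarray(t_grid_C, dtype=float)
    n0, n1, u0, u1 = baselines
    fu = fraction_unfolded(state, t)
    theta = (n0 + n1 * t) * (1 - fu) + (u0 + u1 * t) * fu
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, size=theta.shape)
    return MeltingCurve(temperatures_C=t, ellipticity=theta)


def default_melt_grid() -> np.ndarray:
    """The standard scan grid: 20-100 deg C in 0.5 deg steps."""
    return np.arange(20.0, 100.0 + 1e-9, 0.5)


# -- melt fitting ----------------------------------------------------------


@dataclass
class MeltFit:
    """Result of a two-state Gibbs-Helmholtz melt fit."""

    state: ThermoState
    baselines: tuple[float, float, float, float]
    dG_ref: float
    stderr: dict
    sse: float
    dcp_policy: str
    warnings: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return any("degenerate" in w or "outside" in w for w in self.warnings)


def resolve_dcp_policy(policy: str | float, n_points_hint: int | None = None) -> tuple[float, str]:
    """Resolve a dCp policy to a numeric value and a record string.

    ``"per_residue:<n>"`` uses the empirical per-residue estimate times the
    chain length ``n``; a bare number (or numeric string) fixes dCp
    directly.
    """
    if isinstance(policy, str) and policy.startswith("per_residue:"):
        n = int(policy.split(":", 1)[1])
        return DCP_PER_RESIDUE * n, f"per_residue:{n} ({DCP_PER_RESIDUE} kcal/mol/K per residue)"
    value = float(policy)
    return value, f"fixed:{value}"


def fit_melt(
    curve: MeltingCurve,
    dcp_policy: str | float = 0.0,
    name: str = "fit",
    fixed_unfolded_baseline: tuple[float, float] | None = None,
) -> MeltFit:
    """Nonlinear least-squares fit of a two-state melt.

    Fits ``(Tm, dHm)`` plus linear folded/unfolded baselines with dCp
    fixed by ``dcp_policy``; optionally the unfolded baseline is borrowed
    from a reference construct (e.g. a destabilised variant measured to
    characterise the unfolded state) and held fixed.  Five Tm starting
    points spread across the grid are tried and the lowest-SSE solution
    returned, so the result is deterministic for a given curve and
    policy.  Degenerate inputs (no transition in the grid) yield a fit
    whose warnings mark it unusable rather than silently wrong numbers.
    """
    import lmfit

    t = curve.temperatures_C
    y = curve.ellipticity
    if len(t) < 20:
        raise DomainError("need at least 20 points spanning the transition")
    dcp, policy_record = resolve_dcp_policy(dcp_policy)
    span = float(t[-1] - t[0])

    def model(tc, tm_C, dHm, n0, n1, u0, u1):
        st = ThermoState("m", celsius_to_kelvin(tm_C), max(dHm, 1e-6), dcp)
        fu = fraction_unfolded(st, tc)
        return (n0 + n1 * tc) * (1 - fu) + (u0 + u1 * tc) * fu

    # Baseline initials from the grid ends.
    k = max(3, len(t) // 10)
    n1_0, n0_0 = np.polyfit(t[:k], y[:k], 1)
    u1_0, u0_0 = np.polyfit(t[-k:], y[-k:], 1)

    gmodel = lmfit.Model(model, independent_vars=["tc"])
    best = None
    for q in (0.1, 0.3, 0.5, 0.7, 0.9):
        params = gmodel.make_params(
            tm_C=float(t[0] + q * span),
            dHm=40.0,
            n0=float(n0_0), n1=float(n1_0), u0=float(u0_0), u1=float(u1_0),
        )
        params["dHm"].set(min=1.0, max=500.0)
        params["tm_C"].set(min=float(t[0] - span), max=float(t[-1] + span))
        if fixed_unfolded_baseline is not None:
            params["u0"].set(value=fixed_unfolded_baseline[0], vary=False)
            params["u1"].set(value=fixed_unfolded_baseline[1], vary=False)
        try:
            res = gmodel.fit(y, params, tc=t)
        except Exception:
            continue
        sse = float(np.sum(res.residual**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise FitError("melt fit failed to converge from all starting points")
    sse, res = best

    tm_C = float(res.params["tm_C"].value)
    dHm = float(res.params["dHm"].value)
    stderr = {
        p: (float(res.params[p].stderr) if res.params[p].stderr is not None else np.nan)
        for p in res.params
    }
    warns: list[str] = []
    tm_err = stderr.get("tm_C", np.nan)
    if not np.isfinite(tm_err) or tm_err > span:
        warns.append("degenerate fit: Tm uncertainty exceeds the temperature span")
    # A real transition must stand clear of the residual noise.
    n0v, n1v, u0v, u1v = (res.params[p].value for p in ("n0", "n1", "u0", "u1"))
    amplitude = abs((n0v + n1v * tm_C) - (u0v + u1v * tm_C))
    rms = np.sqrt(sse / len(t))
    if amplitude < 5.0 * rms:
        warns.append("degenerate fit: transition amplitude indistinguishable from noise")
    if not (t[0] <= tm_C <= t[-1]):
        warns.append("transition midpoint outside the measured grid; Tm poorly determined")
    for w in warns:
        logger.warning("%s: %s", name, w)

    state = ThermoState.from_celsius(name, tm_C, max(dHm, 1e-6), dcp)
    baselines = tuple(float(res.params[p].value) for p in ("n0", "n1", "u0", "u1"))
    return MeltFit(
        state=state,
        baselines=baselines,
        dG_ref=state.dG_ref,
        stderr=stderr,
        sse=sse,
        dcp_policy=policy_record,
        warnings=warns,
    )


# -- tabular IO ------------------------------------------------------------


def read_melting_curve(path) -> MeltingCurve:
    """Read a 2-column TSV/CSV melt (temperature_C, mean residue ellipticity)."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise DomainError("melting-curve file needs two columns with a header")
    return MeltingCurve(
        temperatures_C=df.iloc[:, 0].to_numpy(float),
        ellipticity=df.iloc[:, 1].to_numpy(float),
    )


def write_melting_curve(path, curve: MeltingCurve) -> None:
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(
        {"temperature_C": curve.temperatures_C, "mre_deg_cm2_dmol": curve.ellipticity}
    ).to_csv(path, sep=sep, index=False)
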