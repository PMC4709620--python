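"""One-compartment oral pharmacokinetics from plasma profiles.

The model is first-order absorption into and first-order elimination out
of a single compartment, whose concentration course is the Bateman
function Cp(t) = A*(exp(-Ke*t) - exp(-Ka*t)). Estimation follows the
classical graphical procedure:

1. **Terminal slope.** On semilog (base-10) axes the terminal phase is a
   straight line of slope -Ke/ln10; ordinary least squares of
   log10(Cp) on t over the terminal points gives Ke and the
   back-extrapolated intercept.
2. **Method of residuals (feathering).** The back-extrapolated terminal
   line minus the observed early concentrations decays as exp(-Ka*t);
   a second log-linear fit of those residuals gives Ka.
3. **Derived quantities.** t1/2 = ln2/Ke; the model peak is at
   tmax = ln(Ka/Ke)/(Ka - Ke); AUC0-t by the linear trapezoidal rule
   over quantifiable points; AUC0-inf = AUC0-t + Clast/Ke.

Concentrations below the LLOQ are excluded from every fit and from the
trapezoids; tlast is the last quantifiable time. When the residual rate
comes out below the terminal rate (flip-flop kinetics, which the curve
shape cannot resolve), the larger rate is reported as Ka and the result
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile",
    "TerminalFit",
    "PKResult",
    "PKConfig",
    "terminal_ke",
    "method_of_residuals",
    "half_life",
    "tmax_model",
    "auc_trapezoid",
    "auc_to_infinity",
    "analyze_profile",
    "PKError",
    "EligibilityError",
    "NoEliminationPhaseError",
    "ModelViolationError",
    "PKStageError",
    "LN10",
]

LN10 = float(np.log(10.0))  # the 2.303 of the decadic-slope relation


class PKError(ValueError):
    """Base class for pharmacokinetic estimation failures."""


class EligibilityError(PKError):
    """The profile has too few quantifiable points for the stage."""


class NoEliminationPhaseError(PKError):
    """Terminal fit slope is nonnegative; no elimination phase visible."""


class ModelViolationError(PKError):
    """A feathering residual is nonpositive; the model does not apply."""


class PKStageError(PKError):
    """Wraps a component failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject x analyte plasma series with LLOQ metadata.

    ``censored`` flags concentrations below the LLOQ; they stay in the
    record but are excluded from fits and trapezoids. ``truth`` may hold
    the generating parameters for recovery studies.
    """

    analyte_id: str
    subject_id: str
    dose_mg: float
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    censored: tuple[bool, ...] | None = None
    lloq: float = 0.0
    truth: object | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size or t.size == 0:
            raise ValueError("times and concentrations must match and be non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        cens = self.censored
        if cens is None:
            cens = tuple(bool(x) for x in (c < self.lloq))
        if len(cens) != t.size:
            raise ValueError("censored flags must match times")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))
        object.__setattr__(self, "censored", tuple(bool(x) for x in cens))

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, concentrations) of the uncensored points."""
        t = np.asarray(self.times)
        c = np.asarray(self.concentrations)
        mask = ~np.asarray(self.censored, dtype=bool)
        return t[mask], c[mask]


@dataclass(frozen=True)
class TerminalFit:
    """Log-linear terminal fit: log10(Cp) = intercept + slope*t."""

    ke: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    times: tuple[float, ...]

    def extrapolate(self, t) -> np.ndarray | float:
        """Back-extrapolated terminal line on the concentration scale."""
        return 10.0 ** (self.intercept + self.slope * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class PKConfig:
    """Estimation options.

    ``terminal_rule`` selects the terminal points: ``after_tmax`` (all
    quantifiable points strictly after the observed peak — the
    deterministic default) or ``best_r2`` (suffix of length >= 3 with
    the best adjusted r-squared, the usual lambda-z search).
    """

    terminal_rule: str = "after_tmax"
    min_terminal_points: int = 3
    terminal_times: tuple[float, ...] | None = None    # explicit override
    absorption_times: tuple[float, ...] | None = None  # explicit override


def _loglinear(t: np.ndarray, c: np.ndarray):
    fit = stats.linregress(t, np.log10(c))
    r2 = float(fit.rvalue**2) if t.size > 2 else 1.0
    return float(fit.slope), float(fit.intercept), r2


def _terminal_candidates(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    t, c = profile.quantifiable()
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size == 0:
        raise EligibilityError("profile has no quantifiable points")
    i_max = int(np.argmax(c))
    return t[i_max + 1 :], c[i_max + 1 :]


def terminal_ke(
    profile: ConcentrationTimeProfile,
    candidate_points: str | Sequence[float] = "after_tmax",
    min_points: int = 3,
) -> TerminalFit:
    """Elimination rate constant from the log-linear terminal phase.

    ``candidate_points`` is either a selection rule (``after_tmax`` or
    ``best_r2``) or an explicit sequence of sampling times to fit.
    Ke = -slope * ln10 where slope is the decadic log-linear slope.
    """
    if isinstance(candidate_points, str):
        t_cand, c_cand = _terminal_candidates(profile)
        if t_cand.size < min_points:
            raise EligibilityError(
                f"need >= {min_points} quantifiable points after the observed "
                f"peak; have {t_cand.size}"
            )
        if candidate_points == "after_tmax":
            t_fit, c_fit = t_cand, c_cand
        elif candidate_points == "best_r2":
            best = None
            for start in range(t_cand.size - min_points + 1):
                ts, cs = t_cand[start:], c_cand[start:]
                slope, intercept, r2 = _loglinear(ts, cs)
                n = ts.size
                adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
                if best is None or adj > best[0] + 1e-12:
                    best = (adj, ts, cs)
            _, t_fit, c_fit = best
        else:
            raise ValueError(f"unknown selection rule {candidate_points!r}")
    else:
        wanted = set(float(x) for x in candidate_points)
        t_all, c_all = profile.quantifiable()
        mask = np.array([x in wanted for x in t_all])
        t_fit, c_fit = t_all[mask], c_all[mask]
        if t_fit.size < min_points:
            raise EligibilityError(
                f"only {t_fit.size} of the requested terminal times are "
                f"quantifiable; need >= {min_points}"
            )
        if np.any(c_fit <= 0):
            raise EligibilityError("terminal points must have positive concentration")

    slope, intercept, r2 = _loglinear(t_fit, c_fit)
    if slope >= 0:
        raise NoEliminationPhaseError(
            "terminal log-linear slope is nonnegative; no elimination phase"
        )
    return TerminalFit(
        ke=-slope * LN10,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=int(t_fit.size),
        times=tuple(float(x) for x in t_fit),
    )


def method_of_residuals(
    profile: ConcentrationTimeProfile,
    terminal_fit: TerminalFit,
    absorption_times: Sequence[float] | None = None,
) -> float:
    """Absorption rate constant by feathering.

    Residuals r(t) = 10**(intercept + slope*t) - Cp(t) are formed at the
    absorption-phase points (by default every quantifiable point before
    the first terminal-fit time); their decadic log-linear slope gives
    Ka = -slope * ln10. Any nonpositive residual means the
    back-extrapolated line does not dominate the data there and the
    one-compartment model is violated.
    """
    t_all = np.asarray(profile.times)
    c_all = np.asarray(profile.concentrations)
    mask = ~np.asarray(profile.censored, dtype=bool)
    if absorption_times is None:
        first_terminal = min(terminal_fit.times)
        mask = mask & (t_all < first_terminal)
    else:
        wanted = set(float(x) for x in absorption_times)
        mask = mask & np.array([x in wanted for x in t_all])
    t_abs, c_abs = t_all[mask], c_all[mask]
    if t_abs.size < 2:
        raise EligibilityError(
            f"need >= 2 quantifiable absorption-phase points; have {t_abs.size}"
        )
    extrap = np.asarray(terminal_fit.extrapolate(t_abs))
    residuals = extrap - c_abs
    # a residual within float noise of zero means the curves have already
    # converged there; treat it as nonpositive
    bad_mask = residuals <= 1e-9 * extrap
    if np.any(bad_mask):
        bad = t_abs[bad_mask]
        raise ModelViolationError(
            f"nonpositive feathering residual at t = {bad.tolist()} h; "
            "no resolvable absorption phase"
        )
    slope, _, _ = _loglinear(t_abs, residuals)
    if slope >= 0:
        raise ModelViolationError("residuals do not decay; Ka not identifiable")
    return -slope * LN10


def half_life(ke: float) -> float:
    """Elimination half-life ln2/Ke in hours."""
    if ke <= 0:
        raise ValueError("Ke must be > 0")
    return float(np.log(2.0) / ke)


def tmax_model(ka: float, ke: float) -> float:
    """Model time of peak, ln(Ka/Ke)/(Ka - Ke).

    The degenerate case Ka == Ke (limit 1/Ke) is rejected rather than
    silently substituted.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("rate constants must be > 0")
    if ka == ke:
        raise ValueError("Ka == Ke: tmax limit is 1/Ke but the Bateman form is degenerate")
    return float(np.log(ka / ke) / (ka - ke))


def auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """AUC from the first to the last quantifiable time, linear trapezoids."""
    t, c = profile.quantifiable()
    if t.size < 2:
        raise EligibilityError("need >= 2 quantifiable points for a trapezoid")
    return float(np.trapezoid(c, t))


def auc_to_infinity(auc_0_t: float, c_last: float, ke: float) -> float:
    """Extrapolate to infinity: AUC0-t + Clast/Ke."""
    if ke <= 0:
        raise ValueError("Ke must be > 0")
    if c_last < 0:
        raise ValueError("c_last must be >= 0")
    return auc_0_t + c_last / ke


@dataclass(frozen=True)
class PKResult:
    """Estimated parameter set for one profile.

    Identities: t_half = ln2/Ke and, for Ka > Ke,
    tmax_model = ln(Ka/Ke)/(Ka - Ke) hold exactly by construction.
    """

    analyte_id: str
    subject_id: str
    ke: float
    t_half: float
    ka: float
    tmax_model: float
    cmax_model: float
    tmax_observed: float
    cmax_observed: float
    auc_0_t: float
    auc_0_inf: float
    n_terminal_points: int
    terminal_r_squared: float
    flip_flop_flag: bool = False

    def to_row(self) -> dict:
        """Report row in the conventional column order, 2-decimal display."""
        return {
            "analyte_id": self.analyte_id,
            "subject_id": self.subject_id,
            "Ke": round(self.ke, 2),
            "t_half": round(self.t_half, 2),
            "Tmax": round(self.tmax_observed, 2),
            "Cmax": round(self.cmax_observed, 2),
            "AUC_0_t": round(self.auc_0_t, 2),
            "AUC_0_inf": round(self.auc_0_inf, 2),
            "Ka": round(self.ka, 2),
            "flip_flop": self.flip_flop_flag,
        }


def analyze_profile(
    profile: ConcentrationTimeProfile, config: PKConfig | None = None
) -> PKResult:
    """Full estimation pipeline for one concentration-time profile.

    Orchestrates terminal fit -> feathering -> derived parameters ->
    trapezoidal AUC -> infinity extrapolation, and reports the observed
    Cmax/tmax straight from the quantifiable data. Component failures
    are re-raised as :class:`PKStageError` naming the stage.
    """
    config = config or PKConfig()
    t_q, c_q = profile.quantifiable()
    if t_q.size == 0:
        raise EligibilityError("profile is entirely below the LLOQ")

    i_obs = int(np.argmax(c_q))
    tmax_obs, cmax_obs = float(t_q[i_obs]), float(c_q[i_obs])

    try:
        term = terminal_ke(
            profile,
            config.terminal_times or config.terminal_rule,
            min_points=config.min_terminal_points,
        )
    except PKError as exc:
        raise PKStageError("terminal_ke", exc) from exc
    ke = term.ke

    try:
        ka = method_of_residuals(profile, term, config.absorption_times)
    except PKError as exc:
        raise PKStageError("method_of_residuals", exc) from exc

    flip_flop = ka < ke
    if flip_flop:
        # the curve cannot tell the rates apart; report the larger as Ka
        ka, ke = ke, ka

    t_mod = tmax_model(ka, ke)
    a_back = 10.0 ** term.intercept
    c_mod = float(a_back * (np.exp(-ke * t_mod) - np.exp(-ka * t_mod)))

    try:
        auc_t = auc_trapezoid(profile)
    except PKError as exc:
        raise PKStageError("auc_trapezoid", exc) from exc
    auc_inf = auc_to_infinity(auc_t, float(c_q[-1]), ke)

    return PKResult(
        analyte_id=profile.analyte_id,
        subject_id=profile.subject_id,
        ke=ke,
        t_half=half_life(ke),
        ka=ka,
        tmax_model=t_mod,
        cmax_model=c_mod,
        tmax_observed=tmax_obs,
        cmax_observed=cmax_obs,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        n_terminal_points=term.n_points,
        terminal_r_squared=term.r_squared,
        flip_flop_flag=flip_flop,
    )
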