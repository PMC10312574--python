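"""Binding isotherms and steric-trapping stability fits.

Three fluorescence binding models are implemented for titrations of
biotinylated membrane protein with monovalent streptavidin (mSA):

* ``single_site`` — tight-binding quadratic for the unhindered first
  binding of mSA to a single biotin tag (used to measure the intrinsic
  biotin affinity K_d,biotin of an mSA variant);
* ``competition`` — FRET-based competition between labeled and
  unlabeled mSA variants, used to chain stronger biotin affinities off
  a directly measurable weak one;
* ``steric_trap`` — the attenuated second binding of mSA to a doubly
  biotinylated protein, where binding requires spontaneous denaturation.
  Its apparent dissociation constant K_app = K_d,biotin·(1 + 1/K_D)
  couples the intrinsic biotin affinity to the denaturation equilibrium
  constant K_D, so the fitted K_D yields the thermodynamic stability
  ΔG°_N-D = −RT·ln(1/K_D).

Fits are done per replicate by multi-start nonlinear least squares and
averaged; see :func:`fit_isotherm`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .constants import R_KCAL, T_EXPERIMENT

__all__ = [
    "BindingParams",
    "IsothermDataset",
    "FitResult",
    "StabilityResult",
    "single_site_signal",
    "competition_signal",
    "steric_trap_signal",
    "apparent_kd",
    "fit_isotherm",
    "dg_from_KD",
    "KD_from_dg",
]

MODELS = ("single_site", "competition", "steric_trap")


@dataclass
class BindingParams:
    """Parameter bundle shared by the three binding models.

    All concentrations are molar. Not every model uses every field:
    ``single_site`` uses (P_T, K_d_biotin, A1, A2); ``competition`` adds
    C_T and the affinity ratio K_ratio = K_unlabel/K_label;
    ``steric_trap`` uses (K_d_biotin, K_D, F_o, F_inf).
    """

    P_T: float = 1e-6          # total protein, M
    C_T: float = 0.0           # total labeled-mSA (competition), M
    K_d_biotin: float = 52e-12  # unhindered biotin dissociation constant, M
    K_ratio: float = 1.0       # K_unlabel / K_label, dimensionless
    K_D: float = 1.0           # denaturation equilibrium constant [D]/[N]
    A1: float = 1.0            # signal amplitude
    A2: float = 0.0            # signal offset
    F_o: float = 0.0           # steric-trap signal at zero mSA
    F_inf: float = 1.0         # steric-trap signal at saturating mSA


@dataclass
class IsothermDataset:
    """Titration points (total mSA vs background-subtracted signal).

    ``data`` columns: ``conc_M`` (total titrant, molar), ``signal``
    (arbitrary units), ``replicate`` (integer id). Concentrations must
    be nonnegative and sorted within a replicate.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"conc_M", "signal", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"isotherm table missing columns: {sorted(missing)}")
        if (self.data["conc_M"] < 0).any():
            raise ValueError("titrant concentrations must be nonnegative")
        for rid, grp in self.data.groupby("replicate"):
            conc = grp["conc_M"].to_numpy()
            if np.any(np.diff(conc) < 0):
                raise ValueError(f"replicate {rid}: concentrations not sorted")

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique())

    def replicate_arrays(self, rid: int) -> tuple[np.ndarray, np.ndarray]:
        grp = self.data[self.data["replicate"] == rid]
        return grp["conc_M"].to_numpy(float), grp["signal"].to_numpy(float)


@dataclass
class FitResult:
    """Result of :func:`fit_isotherm`.

    ``estimates``/``stderr`` map parameter names to the across-replicate
    mean and its uncertainty (replicate SEM combined in quadrature with
    the propagated per-replicate fit covariance). ``per_replicate`` keeps
    the individual fits for inspection.
    """

    model_id: str
    estimates: dict
    stderr: dict
    residuals: np.ndarray
    converged: bool
    n_replicates: int
    per_replicate: list[dict] = field(default_factory=list)


@dataclass
class StabilityResult:
    """Fitted stability ΔG°_N-D with its error and tags."""

    dG: float                  # kcal/mol; negative = stable native state
    err: float                 # kcal/mol, ≥ 0
    subdomain: str = ""        # "N" | "C"
    environment: str = ""      # "micelle" | "bicelle"
    variant: str = "WT"

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError("stability error must be nonnegative")


def single_site_signal(params: BindingParams, mSA_total) -> np.ndarray | float:
    """Tight-binding single-site isotherm.

    F = A1·f_bound + A2, with f_bound the physically admissible root of
    the quadratic for a 1:1 complex at comparable protein and ligand
    concentrations:

        f_bound = [(P_T + L + K_d) − √((P_T + L + K_d)² − 4·P_T·L)] / (2·P_T)

    f_bound ∈ [0, 1]; monotone nondecreasing in the titrant when A1 > 0.
    """
    L = np.asarray(mSA_total, dtype=float)
    if params.P_T <= 0:
        raise ValueError("P_T must be positive")
    if params.K_d_biotin < 0:
        raise ValueError("K_d_biotin must be nonnegative")
    if np.any(L < 0):
        raise ValueError("titrant concentration must be nonnegative")
    b = params.P_T + L + params.K_d_biotin
    disc = np.maximum(b * b - 4.0 * params.P_T * L, 0.0)
    f_bound = (b - np.sqrt(disc)) / (2.0 * params.P_T)
    out = params.A1 * f_bound + params.A2
    return out.item() if np.isscalar(mSA_total) else out


def competition_signal(params: BindingParams, mSA_total) -> np.ndarray | float:
    """Competition isotherm between labeled and unlabeled mSA.

    With r = K_unlabel/K_label and b = P_T + [mSA] + r·(C_T − P_T):

        F = A1·[−b + √(b² + 4·P_T·[mSA]·r)] / (2·P_T·r) + A2

    The expression is evaluated verbatim (no algebraic rearrangement).
    """
    L = np.asarray(mSA_total, dtype=float)
    if params.P_T <= 0:
        raise ValueError("P_T must be positive")
    if params.K_ratio <= 0:
        raise ValueError("K_ratio must be positive")
    if np.any(L < 0):
        raise ValueError("titrant concentration must be nonnegative")
    r = params.K_ratio
    b = params.P_T + L + r * (params.C_T - params.P_T)
    root = np.sqrt(b * b + 4.0 * params.P_T * L * r)
    out = params.A1 * (-b + root) / (2.0 * params.P_T * r) + params.A2
    return out.item() if np.isscalar(mSA_total) else out


def apparent_kd(K_d_biotin: float, K_D: float) -> float:
    """Apparent dissociation constant of the attenuated second binding.

    K_app = K_d,biotin·(1 + 1/K_D): the smaller the denatured fraction
    (small K_D), the more the second binding is attenuated.
    """
    if K_d_biotin <= 0 or K_D <= 0:
        raise ValueError("K_d_biotin and K_D must be positive")
    return K_d_biotin * (1.0 + 1.0 / K_D)


def steric_trap_signal(params: BindingParams, mSA_total) -> np.ndarray | float:
    """Steric-trap (second binding phase) isotherm.

    F = (F_inf − F_o) / (1 + K_app/[mSA]) + F_o with
    K_app = K_d,biotin·(1 + 1/K_D). Half-signal at [mSA] = K_app.
    At [mSA] = 0 the limit F_o is returned.
    """
    L = np.asarray(mSA_total, dtype=float)
    K_app = apparent_kd(params.K_d_biotin, params.K_D)
    with np.errstate(divide="ignore"):
        frac = np.where(L > 0, 1.0 / (1.0 + K_app / np.where(L > 0, L, 1.0)), 0.0)
    out = (params.F_inf - params.F_o) * frac + params.F_o
    return out.item() if np.isscalar(mSA_total) else out


def dg_from_KD(K_D: float, T: float = T_EXPERIMENT) -> float:
    """Stability ΔG°_N-D = −R·T·ln(1/K_D), kcal/mol.

    K_D = [D]/[N]; K_D < 1 (mostly native) gives a negative, stabilizing
    ΔG. Strictly monotone increasing in K_D.
    """
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    return -R_KCAL * T * math.log(1.0 / K_D)


def KD_from_dg(dG: float, T: float = T_EXPERIMENT) -> float:
    """Inverse of :func:`dg_from_KD`: K_D = exp(ΔG/RT)."""
    return math.exp(dG / (R_KCAL * T))


# ---------------------------------------------------------------------------
# fitting

_FREE_PARAMS = {
    # model_id -> (free parameter names, required fixed names)
    "single_site": (("A1", "A2", "K_d_biotin"), ("P_T",)),
    "competition": (("A1", "A2", "K_ratio"), ("P_T", "C_T")),
    "steric_trap": (("F_o", "F_inf", "K_D"), ("K_d_biotin",)),
}

_MODEL_FUNCS = {
    "single_site": single_site_signal,
    "competition": competition_signal,
    "steric_trap": steric_trap_signal,
}

_LOG_PARAMS = {"K_d_biotin", "K_ratio", "K_D"}  # fitted on a log scale


def _model_curve(model_id: str, base: BindingParams, free_names: tuple[str, ...]):
    func = _MODEL_FUNCS[model_id]

    def curve(L, *theta):
        kwargs = {
            # clamp the log scale so optimizer excursions cannot overflow
            # (345 keeps the squared value inside float range)
            name: (math.exp(min(max(v, -345.0), 345.0))
                   if name in _LOG_PARAMS else v)
            for name, v in zip(free_names, theta)
        }
        return func(replace(base, **kwargs), L)

    return curve


def _initial_guesses(model_id: str, conc: np.ndarray, signal: np.ndarray,
                     init: dict) -> list[dict]:
    """Deterministic multi-start list; equilibrium constants on a log grid."""
    lo, hi = float(signal[0]), float(signal[-1])
    amp = hi - lo
    if amp == 0:
        amp = 1.0
    starts: list[dict] = []
    if model_id == "steric_trap":
        kd_grid = [init["K_D"]] if "K_D" in init else list(
            np.logspace(-10, 0, 11))
        for kd in kd_grid:
            starts.append({"F_o": init.get("F_o", lo),
                           "F_inf": init.get("F_inf", hi),
                           "K_D": kd})
    elif model_id == "single_site":
        kd_grid = [init["K_d_biotin"]] if "K_d_biotin" in init else list(
            np.logspace(-12, -5, 8))
        for kd in kd_grid:
            starts.append({"A1": init.get("A1", amp),
                           "A2": init.get("A2", lo),
                           "K_d_biotin": kd})
    else:  # competition
        ratio_grid = [init["K_ratio"]] if "K_ratio" in init else list(
            np.logspace(-3, 3, 7))
        for r in ratio_grid:
            starts.append({"A1": init.get("A1", amp),
                           "A2": init.get("A2", lo),
                           "K_ratio": r})
    return starts


def _fit_one_replicate(model_id: str, base: BindingParams,
                       conc: np.ndarray, signal: np.ndarray,
                       init: dict) -> dict:
    free_names, _ = _FREE_PARAMS[model_id]
    curve = _model_curve(model_id, base, free_names)
    best = None
    for start in _initial_guesses(model_id, conc, signal, init):
        p0 = [math.log(start[n]) if n in _LOG_PARAMS else start[n]
              for n in free_names]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(curve, conc, signal, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = signal - curve(conc, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best["ssr"]:
            best = {"popt": popt, "pcov": pcov, "ssr": ssr, "resid": resid}
    if best is None:
        raise RuntimeError(f"{model_id} fit failed to converge on any start")

    est, se = {}, {}
    diag = np.diag(best["pcov"])
    # exactly-identified / noise-free fits yield a singular covariance
    perr = np.where(np.isfinite(diag), np.sqrt(np.maximum(diag, 0.0)), 0.0)
    for i, name in enumerate(free_names):
        if name in _LOG_PARAMS:
            est[name] = math.exp(best["popt"][i])
            se[name] = est[name] * perr[i]      # delta method on log scale
        else:
            est[name] = float(best["popt"][i])
            se[name] = float(perr[i])
    return {"estimates": est, "stderr": se, "ssr": best["ssr"],
            "residuals": best["resid"]}


def fit_isotherm(data: IsothermDataset, model_id: str,
                 fixed: dict | None = None,
                 init: dict | None = None) -> FitResult:
    """Fit a binding isotherm per replicate and average.

    Parameters
    ----------
    data : IsothermDataset
        Titration points; each replicate needs ≥ 5 points and a
        non-flat signal.
    model_id : {"single_site", "competition", "steric_trap"}
    fixed : dict
        Model-required fixed parameters (e.g. ``K_d_biotin`` for
        ``steric_trap``, ``P_T`` for ``single_site``). Any
        :class:`BindingParams` field may be pinned here.
    init : dict
        Optional initial values; a parameter given here is still fitted
        but gets a single start instead of the multi-start grid.

    The reported estimate of each free parameter is the mean over
    replicates; its stderr combines the replicate SEM with the
    propagated per-replicate fit covariance in quadrature
    (√(SEM² + mean(SE_i²)/n)). For a single replicate the
    covariance-based error is reported directly.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODELS}")
    fixed = dict(fixed or {})
    init = dict(init or {})
    free_names, required = _FREE_PARAMS[model_id]
    missing = [name for name in required if name not in fixed]
    if missing:
        raise ValueError(f"model {model_id!r} requires fixed parameters {missing}")
    base = replace(BindingParams(), **fixed)

    rep_fits: list[dict] = []
    residual_chunks: list[np.ndarray] = []
    for rid in data.replicates:
        conc, signal = data.replicate_arrays(rid)
        if conc.size < 5:
            raise ValueError(f"replicate {rid}: need ≥ 5 points, got {conc.size}")
        if np.ptp(signal) == 0:
            raise ValueError(f"replicate {rid}: flat signal, nothing to fit")
        fit = _fit_one_replicate(model_id, base, conc, signal, init)
        fit["replicate"] = rid
        rep_fits.append(fit)
        residual_chunks.append(fit["residuals"])

    n = len(rep_fits)
    estimates, stderr = {}, {}
    for name in free_names:
        vals = np.array([f["estimates"][name] for f in rep_fits])
        ses = np.array([f["stderr"][name] for f in rep_fits])
        estimates[name] = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1) / math.sqrt(n))
            cov_term = float(np.mean(ses ** 2) / n)
            stderr[name] = math.sqrt(sem ** 2 + cov_term)
        else:
            stderr[name] = float(ses[0])

    return FitResult(model_id=model_id, estimates=estimates, stderr=stderr,
                     residuals=np.concatenate(residual_chunks),
                     converged=True, n_replicates=n, per_replicate=rep_fits)


def stability_from_fit(fit: FitResult, T: float = T_EXPERIMENT,
                       subdomain: str = "", environment: str = "",
                       variant: str = "WT") -> StabilityResult:
    """Convert a steric-trap fit into ΔG°_N-D with a propagated error.

    ΔG is computed per replicate from each fitted K_D and averaged;
    the error combines the replicate SEM with the delta-method
    propagation of the per-replicate K_D covariance errors.
    """
    if fit.model_id != "steric_trap":
        raise ValueError("stability requires a steric_trap fit")
    dgs = np.array([dg_from_KD(f["estimates"]["K_D"], T)
                    for f in fit.per_replicate])
    # d(ΔG)/dK_D = RT/K_D
    dg_ses = np.array([R_KCAL * T * f["stderr"]["K_D"] / f["estimates"]["K_D"]
                       for f in fit.per_replicate])
    n = len(dgs)
    if n >= 2:
        sem = float(dgs.std(ddof=1) / math.sqrt(n))
        err = math.sqrt(sem ** 2 + float(np.mean(dg_ses ** 2) / n))
    else:
        err = float(dg_ses[0])
    return StabilityResult(dG=float(dgs.mean()), err=err,
                           subdomain=subdomain, environment=environment,
                           variant=variant)
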