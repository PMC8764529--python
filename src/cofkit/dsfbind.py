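"""Two-state thermal unfolding with ligand linkage for nano-DSF data.

Model
-----
The protein unfolds in a two-state N <-> U equilibrium with van 't Hoff
free energy (heat capacity change optional, zero by default)::

    dG_u(T) = dH_u (1 - T/T_m) + dCp [(T - T_m) - T ln(T/T_m)]

A ligand L that binds only the folded state stabilises it through the
standard linkage term, giving the apparent unfolding free energy and the
unfolded fraction::

    dG_app(T) = dG_u(T) + R T ln(1 + [L]/K_D)
    f_u(T)    = 1 / (1 + exp(dG_app / (R T)))

When a fraction ``phi`` of the protein co-purifies with tightly bound
product (GPPG), the observable is the phi-weighted mixture of the
product-loaded subpopulation (stabilised by the stoichiometric GPPG pool,
``[GPPG] = phi * [P]``) and the remainder, which is titrated by the GTP
series.  The fluorescence signal is two linear baselines mixed by f_u.

Temperatures are Kelvin internally (Celsius accepted on CSV input),
concentrations molar, dH_u kJ/mol, R = 8.314 J/mol/K.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, SchemaError, ValidationError

__all__ = [
    "R_GAS",
    "MeltingCurve",
    "UnfoldingModel",
    "FitResult",
    "GridResult",
    "unfolded_fraction",
    "predict_signal",
    "read_melting_csv",
    "fit_melting",
    "kd_feasibility_grid",
]

R_GAS = 8.314  # J / (mol K)


@dataclass
class MeltingCurve:
    """Fluorescence vs temperature at one ligand concentration."""

    ligand_conc: float                # molar
    points: np.ndarray                # shape (n, 2): temperature_K, signal
    protein_conc: float = 1e-5        # molar

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("curve points must be (n, 2): T_K, signal")
        if len(self.points) < 10:
            raise ValidationError("a melting curve needs >= 10 points")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if self.ligand_conc < 0 or self.protein_conc <= 0:
            raise ValidationError("concentrations must be non-negative / positive")


@dataclass
class UnfoldingModel:
    """Thermodynamic + baseline parameters of the two-state linkage model."""

    t_m: float                        # K, apo midpoint
    delta_h_u: float                  # kJ/mol at T_m
    a_n: float = 1.0                  # native baseline intercept (signal)
    b_n: float = 0.0                  # native baseline slope (signal/K)
    a_u: float = 2.0                  # unfolded baseline intercept
    b_u: float = 0.0                  # unfolded baseline slope
    k_d_gtp: float = 1e-5             # molar
    k_d_gppg: float | None = None     # molar
    phi_gppg: float = 0.0             # fraction pre-loaded with product
    delta_cp: float = 0.0             # kJ/mol/K, opt-in

    def __post_init__(self):
        if self.t_m <= 0 or self.delta_h_u <= 0:
            raise ValidationError("T_m and dH_u must be positive")
        if self.k_d_gtp <= 0:
            raise ValidationError("K_D(GTP) must be positive")
        if not 0.0 <= self.phi_gppg <= 1.0:
            raise ValidationError("phi_gppg must lie in [0, 1]")
        if self.phi_gppg > 0 and (self.k_d_gppg is None or self.k_d_gppg <= 0):
            raise ValidationError("phi_gppg > 0 requires a positive K_D(GPPG)")


@dataclass
class FitResult:
    """Point estimates with linearized 95% confidence intervals."""

    params: dict[str, tuple[float, float, float]]   # name -> (est, lo, hi)
    rss: float
    converged: bool
    message: str = ""
    n_points: int = 0
    model: UnfoldingModel | None = None

    def estimate(self, name: str) -> float:
        return self.params[name][0]


@dataclass
class GridResult:
    """RSS surface over (phi, K_D GTP, K_D GPPG) with its feasible set."""

    phi_grid: np.ndarray
    kd_gtp_grid: np.ndarray
    kd_gppg_grid: np.ndarray
    rss: np.ndarray                   # shape (n_phi, n_gtp, n_gppg)
    feasible: np.ndarray              # bool, same shape
    threshold: float


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _delta_g_u(model: UnfoldingModel, T: np.ndarray) -> np.ndarray:
    """Unfolding free energy in J/mol (van 't Hoff, optional dCp)."""
    dg = model.delta_h_u * 1e3 * (1.0 - T / model.t_m)
    if model.delta_cp:
        dg = dg + model.delta_cp * 1e3 * ((T - model.t_m) - T * np.log(T / model.t_m))
    return dg


def _two_state(dg_app: np.ndarray, T: np.ndarray) -> np.ndarray:
    x = dg_app / (R_GAS * T)
    x = np.clip(x, -500, 500)
    return 1.0 / (1.0 + np.exp(x))


def unfolded_fraction(model: UnfoldingModel, T, ligand_conc: float,
                      protein_conc: float = 1e-5):
    """Unfolded fraction at temperature(s) ``T`` and GTP concentration ``L``.

    Ligand is assumed in large excess (free ~ total).  With
    ``phi_gppg > 0`` the result is the phi-weighted mixture of the
    GPPG-loaded and GTP-titrated subpopulations.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperatures must be positive Kelvin")
    if ligand_conc < 0:
        raise ValidationError("ligand concentration must be >= 0")
    dg_u = _delta_g_u(model, T)
    dg_gtp = dg_u + R_GAS * T * np.log1p(ligand_conc / model.k_d_gtp)
    f = _two_state(dg_gtp, T)
    if model.phi_gppg > 0:
        gppg = model.phi_gppg * protein_conc
        dg_gppg = dg_u + R_GAS * T * np.log1p(gppg / model.k_d_gppg)
        f = (1.0 - model.phi_gppg) * f + model.phi_gppg * _two_state(dg_gppg, T)
    return f if f.ndim else float(f)


def predict_signal(model: UnfoldingModel, T, ligand_conc: float,
                   protein_conc: float = 1e-5):
    """Fluorescence signal: two linear baselines mixed by f_u."""
    T = np.asarray(T, dtype=float)
    f = unfolded_fraction(model, T, ligand_conc, protein_conc)
    return (model.a_n + model.b_n * T) * (1.0 - f) + (model.a_u + model.b_u * T) * f


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

def read_melting_csv(source, protein_conc: float = 1e-5) -> list[MeltingCurve]:
    """Read long-format melting data: ligand_conc_M, temperature_C, signal."""
    df = pd.read_csv(source) if not isinstance(source, str) or "\n" not in source \
        else pd.read_csv(io.StringIO(source))
    required = ["ligand_conc_M", "temperature_C", "signal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    curves = []
    for conc, grp in df.groupby("ligand_conc_M", sort=True):
        grp = grp.sort_values("temperature_C", kind="mergesort")
        pts = np.column_stack([grp["temperature_C"].to_numpy(float) + 273.15,
                               grp["signal"].to_numpy(float)])
        curves.append(MeltingCurve(float(conc), pts, protein_conc))
    return curves


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _baseline_guess(curve: MeltingCurve) -> tuple[float, float, float, float]:
    """Linear fits to the first and last quarter of the curve."""
    T, S = curve.points[:, 0], curve.points[:, 1]
    k = max(3, len(T) // 4)
    bn, an = np.polyfit(T[:k], S[:k], 1)
    bu, au = np.polyfit(T[-k:], S[-k:], 1)
    return an, bn, au, bu


def _apparent_tm_guess(curve: MeltingCurve) -> float:
    """Temperature of steepest signal change (crude transition locator)."""
    T, S = curve.points[:, 0], curve.points[:, 1]
    w = max(3, len(S) // 20)
    kernel = np.ones(w) / w
    smooth = np.convolve(S, kernel, mode="same")
    grad = np.gradient(smooth, T)
    interior = slice(w, len(T) - w) if len(T) > 3 * w else slice(None)
    idx = np.argmax(np.abs(grad[interior]))
    return float(T[interior][idx])


def _check_transition(curve: MeltingCurve) -> None:
    """Reject curves indistinguishable from a straight line."""
    T, S = curve.points[:, 0], curve.points[:, 1]
    coeff = np.polyfit(T, S, 1)
    resid = S - np.polyval(coeff, T)
    amplitude = float(np.ptp(resid))
    noise = float(np.std(np.diff(S, 2))) / np.sqrt(6.0) if len(S) > 4 else 0.0
    if amplitude <= max(10.0 * noise, 1e-12):
        raise FitError("no unfolding transition detected (flat curve)")


def fit_melting(curves: list[MeltingCurve], fix_phi: float = 0.0,
                fix_k_d_gppg: float | None = None,
                fix_k_d_gtp: float | None = None,
                n_starts: int = 8, seed: int = 0) -> FitResult:
    """Global fit of shared (T_m, dH_u, K_D) plus per-curve baselines.

    Trust-region least squares with multistart initialization: T_m starts
    spread +/- 10 K around the apo transition estimate, K_D starts
    log-spaced.  With apo-only input the K_D is unidentifiable and the
    returned result is flagged accordingly.  95% CIs are linearized
    (Jacobian-based).
    """
    if not curves:
        raise ValidationError("no curves supplied")
    curves = sorted(curves, key=lambda c: c.ligand_conc)
    for c in curves:
        _check_transition(c)
    apo = curves[0]
    if apo.ligand_conc > 0:
        raise ValidationError("a ligand-free (apo) curve is required")
    has_titration = any(c.ligand_conc > 0 for c in curves)
    fit_kd = has_titration and fix_k_d_gtp is None

    tm0 = _apparent_tm_guess(apo)
    baselines0 = [np.array(_baseline_guess(c)) for c in curves]
    n_curves = len(curves)

    def unpack(theta):
        t_m = theta[0]
        dh = np.exp(theta[1])
        kd = np.exp(theta[2]) if fit_kd else (fix_k_d_gtp or 1e-5)
        bl = theta[3:].reshape(n_curves, 4)
        return t_m, dh, kd, bl

    def residuals(theta):
        t_m, dh, kd, bl = unpack(theta)
        try:
            res = []
            for c, (an, bn, au, bu) in zip(curves, bl):
                m = UnfoldingModel(t_m=t_m, delta_h_u=dh, a_n=an, b_n=bn,
                                   a_u=au, b_u=bu, k_d_gtp=kd,
                                   k_d_gppg=fix_k_d_gppg, phi_gppg=fix_phi)
                res.append(predict_signal(m, c.points[:, 0], c.ligand_conc,
                                          c.protein_conc) - c.points[:, 1])
            return np.concatenate(res)
        except ValidationError:
            return np.full(sum(len(c.points) for c in curves), 1e6)

    rng = np.random.default_rng(seed)
    tm_starts = tm0 + np.linspace(-10.0, 10.0, n_starts)
    kd_starts = np.logspace(-7, -3, n_starts)
    rng.shuffle(kd_starts)

    best = None
    for i in range(n_starts):
        theta0 = np.concatenate([
            [tm_starts[i], np.log(300.0), np.log(kd_starts[i])],
            np.concatenate(baselines0)])
        try:
            sol = least_squares(residuals, theta0, method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("optimizer failed from every start")

    t_m, dh, kd, bl = unpack(best.x)
    rss = float(2.0 * best.cost)
    n_pts = sum(len(c.points) for c in curves)
    n_par = len(best.x) if fit_kd else len(best.x) - 1

    # linearized covariance
    ci: dict[str, tuple[float, float, float]] = {}
    names = ["t_m", "log_dh", "log_kd"]
    try:
        J = best.jac
        dof = max(n_pts - n_par, 1)
        cov = np.linalg.pinv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        se = np.full(len(best.x), np.nan)
    ci["t_m"] = (t_m, t_m - 1.96 * se[0], t_m + 1.96 * se[0])
    ci["delta_h_u"] = (dh, dh * np.exp(-1.96 * se[1]), dh * np.exp(1.96 * se[1]))
    if fit_kd:
        ci["k_d_gtp"] = (kd, kd * np.exp(-1.96 * se[2]), kd * np.exp(1.96 * se[2]))
    else:
        ci["k_d_gtp"] = (kd, np.nan, np.nan)

    message = "" if has_titration else "K_D unidentifiable: apo-only data"
    model = UnfoldingModel(t_m=t_m, delta_h_u=dh,
                           a_n=bl[0][0], b_n=bl[0][1],
                           a_u=bl[0][2], b_u=bl[0][3],
                           k_d_gtp=kd, k_d_gppg=fix_k_d_gppg,
                           phi_gppg=fix_phi)
    return FitResult(params=ci, rss=rss, converged=bool(best.success),
                     message=message, n_points=n_pts, model=model)


def kd_feasibility_grid(curves: list[MeltingCurve],
                        phi_grid, kd_gtp_grid, kd_gppg_grid,
                        threshold: float = 0.05,
                        seed: int = 0) -> GridResult:
    """RSS surface over fixed (phi, K_D GTP, K_D GPPG) combinations.

    At each grid point the thermodynamic parameters and baselines are
    refit with both dissociation constants held fixed.  The feasible set
    collects points with ``RSS <= min(RSS) * (1 + threshold)``; the
    minimum itself is always feasible, so the set is never empty.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    kd_gtp_grid = np.asarray(kd_gtp_grid, dtype=float)
    kd_gppg_grid = np.asarray(kd_gppg_grid, dtype=float)
    if phi_grid.size == 0 or kd_gtp_grid.size == 0 or kd_gppg_grid.size == 0:
        raise ValidationError("all grids must be non-empty")
    rss = np.empty((phi_grid.size, kd_gtp_grid.size, kd_gppg_grid.size))
    for i, phi in enumerate(phi_grid):
        for j, kd_gtp in enumerate(kd_gtp_grid):
            for k, kd_gppg in enumerate(kd_gppg_grid):
                if phi == 0.0 and k > 0:
                    # K_D(GPPG) is absent from the model at phi = 0
                    rss[i, j, k] = rss[i, j, 0]
                    continue
                fit = fit_melting(curves, fix_phi=float(phi),
                                  fix_k_d_gppg=float(kd_gppg),
                                  fix_k_d_gtp=float(kd_gtp),
                                  n_starts=2, seed=seed)
                rss[i, j, k] = fit.rss
    feasible = rss <= rss.min() * (1.0 + threshold)
    return GridResult(phi_grid=phi_grid, kd_gtp_grid=kd_gtp_grid,
                      kd_gppg_grid=kd_gppg_grid, rss=rss,
                      feasible=feasible, threshold=threshold)
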