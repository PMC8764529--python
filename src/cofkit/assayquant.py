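"""Quantification chain for the combined CofC/D activity assay.

In the assay, competing phospho-acid substrates are turned into distinct
deazaflavin products whose accumulation is followed by LC-MS.  The chain
implemented here goes: extracted ion chromatogram (XIC) at a target m/z
-> trapezoidal peak area (AUC) with optional window-edge baseline
subtraction -> per-replicate normalization -> ordinary-least-squares
formation rate over the linear time range (0-20 min by default) -> relative
turnover per substrate as a percentage of the summed rates, with mean and
sample SD over biological replicates.

Normalization is applied with one denominator per replicate (the summed
AUC over the whole time course), so within-replicate time structure -- and
hence the fitted rates -- are rescaled uniformly and rate *ratios* are
normalization-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    FitError,
    IntegrationError,
    NormalizationError,
    SchemaError,
    SelectorError,
    UndefinedProfileError,
    ValidationError,
)

__all__ = [
    "CSV_COLUMNS",
    "SUBSTRATE_PRODUCT_MAP",
    "XICTrace",
    "ChromatogramRun",
    "ChromatogramSet",
    "TimeCourse",
    "RateFit",
    "SpecificityProfile",
    "read_chromatograms",
    "write_chromatograms",
    "extract_xic",
    "integrate_peak",
    "normalize_area",
    "fit_linear_rate",
    "specificity_profile",
    "quantify",
]

CSV_COLUMNS = ("replicate", "reaction_time_min", "species", "rt_min", "mz", "intensity")

#: which product species reports the turnover of which substrate
SUBSTRATE_PRODUCT_MAP = {
    "3-PG": "3PG-F420-0",
    "2-PL": "F420-0",
    "PEP": "DF420-0",
}


@dataclass
class XICTrace:
    """An extracted ion chromatogram: (rt, intensity) at a target m/z."""

    species: str
    mz_target: float
    mz_tol: float
    points: np.ndarray           # shape (n, 2): rt_min, intensity

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ChromatogramRun:
    """All traces recorded for one replicate at one reaction time."""

    replicate_id: str
    reaction_time_min: float
    traces: dict[str, pd.DataFrame]   # species -> columns rt_min, mz, intensity


@dataclass
class ChromatogramSet:
    """A collection of runs spanning replicates and reaction times."""

    runs: list[ChromatogramRun] = field(default_factory=list)

    def replicates(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.runs:
            seen.setdefault(r.replicate_id, None)
        return list(seen)

    def times(self) -> list[float]:
        return sorted({r.reaction_time_min for r in self.runs})

    def run(self, replicate_id: str, reaction_time_min: float) -> ChromatogramRun:
        for r in self.runs:
            if (r.replicate_id == replicate_id
                    and r.reaction_time_min == reaction_time_min):
                return r
        raise SelectorError(
            f"no run for replicate {replicate_id!r} at t={reaction_time_min}")


@dataclass
class TimeCourse:
    """(reaction time, normalized AUC) points for one species, one replicate."""

    species: str
    replicate_id: str
    points: np.ndarray           # shape (n, 2): time_min, normalized_auc


@dataclass
class RateFit:
    species: str
    slope: float                 # normalized AUC per min
    intercept: float
    r_squared: float
    window: tuple[float, float]
    n_points: int


@dataclass
class SpecificityProfile:
    """Relative turnover per substrate with replicate statistics."""

    substrates: list[str]
    mean_percent: dict[str, float]
    sd_percent: dict[str, float]
    per_replicate: dict[str, dict[str, float]]   # replicate -> substrate -> %
    n_replicates: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chromatograms(source) -> ChromatogramSet:
    """Load the long-format assay CSV (path, file object or text buffer).

    Required columns: replicate, reaction_time_min, species, rt_min, mz,
    intensity.  Traces are grouped per (replicate, reaction time, species)
    and sorted by retention time.
    """
    df = pd.read_csv(source)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if (df["intensity"] < 0).any():
        raise ValidationError("negative intensities in chromatogram data")
    runs = []
    for (rep, t), grp in df.groupby(["replicate", "reaction_time_min"], sort=True):
        traces = {}
        for sp, sub in grp.groupby("species", sort=True):
            traces[str(sp)] = (sub[["rt_min", "mz", "intensity"]]
                               .sort_values("rt_min", kind="mergesort")
                               .reset_index(drop=True))
        runs.append(ChromatogramRun(str(rep), float(t), traces))
    return ChromatogramSet(runs)


def write_chromatograms(cset: ChromatogramSet) -> str:
    """Serialize a chromatogram set back to the long CSV format."""
    frames = []
    for run in cset.runs:
        for sp, df in run.traces.items():
            f = df.copy()
            f.insert(0, "species", sp)
            f.insert(0, "reaction_time_min", run.reaction_time_min)
            f.insert(0, "replicate", run.replicate_id)
            frames.append(f)
    return pd.concat(frames, ignore_index=True).to_csv(index=False)


# ---------------------------------------------------------------------------
# XIC extraction and integration
# ---------------------------------------------------------------------------

def extract_xic(run: ChromatogramRun, species: str,
                mz_target: float, mz_tol: float) -> XICTrace:
    """Filter one species' trace to |mz - mz_target| <= mz_tol."""
    if species not in run.traces:
        raise SelectorError(f"species {species!r} absent from run "
                            f"{run.replicate_id!r} t={run.reaction_time_min}")
    df = run.traces[species]
    keep = (df["mz"] - mz_target).abs() <= mz_tol
    pts = df.loc[keep, ["rt_min", "intensity"]].to_numpy(dtype=float)
    if len(pts) == 0:
        warnings.warn(f"XIC for {species!r} at m/z {mz_target} +/- {mz_tol} "
                      "is empty", stacklevel=2)
    return XICTrace(species, mz_target, mz_tol, pts)


def integrate_peak(xic: XICTrace, rt_window: tuple[float, float],
                   subtract_baseline: bool = True) -> float:
    """Trapezoidal AUC of the XIC inside ``rt_window``.

    With ``subtract_baseline`` the straight line through the first and
    last in-window points is removed first, which cancels a constant or
    linearly drifting background.
    """
    lo, hi = rt_window
    pts = xic.points[(xic.points[:, 0] >= lo) & (xic.points[:, 0] <= hi)]
    if len(pts) < 2:
        raise IntegrationError(
            f"only {len(pts)} point(s) in rt window [{lo}, {hi}]")
    rt, inten = pts[:, 0], pts[:, 1]
    if subtract_baseline:
        base = np.interp(rt, [rt[0], rt[-1]], [inten[0], inten[-1]])
        inten = inten - base
    return float(np.trapezoid(inten, rt))


def normalize_area(raw_areas: dict[str, float], mode: str = "total",
                   reference: str | None = None) -> dict[str, float]:
    """Normalize a map of species AUCs.

    mode ``total`` divides by the summed area of all species present;
    mode ``reference`` divides by the named reference species' area
    (for example the FO core, supplied at fixed input in the assay).
    """
    if mode == "total":
        denom = float(sum(raw_areas.values()))
    elif mode == "reference":
        if reference is None or reference not in raw_areas:
            raise NormalizationError(f"reference species {reference!r} not in areas")
        denom = float(raw_areas[reference])
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise NormalizationError("normalization denominator is zero or negative")
    return {sp: a / denom for sp, a in raw_areas.items()}


# ---------------------------------------------------------------------------
# rate fitting and turnover profiles
# ---------------------------------------------------------------------------

def fit_linear_rate(tc: TimeCourse,
                    window: tuple[float, float] = (0.0, 20.0)) -> RateFit:
    """OLS slope of normalized AUC vs time, restricted to ``window``.

    Endpoints inclusive; points outside the linear range are excluded
    before fitting.
    """
    lo, hi = window
    pts = tc.points[(tc.points[:, 0] >= lo) & (tc.points[:, 0] <= hi)]
    t, y = pts[:, 0], pts[:, 1]
    if len(pts) < 2 or np.ptp(t) == 0:
        raise FitError(f"rate fit for {tc.species!r} needs >= 2 distinct "
                       f"time points in [{lo}, {hi}]")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return RateFit(species=tc.species, slope=float(res.slope),
                   intercept=float(res.intercept), r_squared=r2,
                   window=(lo, hi), n_points=len(pts))


def specificity_profile(replicate_rates: dict[str, dict[str, float]],
                        substrate_product_map: dict[str, str] | None = None,
                        ) -> SpecificityProfile:
    """Relative turnover percentages from per-replicate formation rates.

    ``replicate_rates`` maps replicate id -> substrate (or product
    species, resolved through ``substrate_product_map``) -> fitted slope.
    Negative slopes are clamped to zero with a warning; each replicate's
    percentages sum to 100.  Reported: arithmetic mean and sample SD
    (ddof=1; zero for a single replicate).
    """
    if not replicate_rates:
        raise UndefinedProfileError("no replicates supplied")
    inv = {}
    if substrate_product_map:
        inv = {prod: sub for sub, prod in substrate_product_map.items()}
    per_rep: dict[str, dict[str, float]] = {}
    substrates: list[str] = []
    for rep, rates in replicate_rates.items():
        named = {inv.get(k, k): v for k, v in rates.items()}
        clamped = {}
        for sub, k in named.items():
            if k < 0:
                warnings.warn(f"negative rate {k:.3g} for {sub!r} in replicate "
                              f"{rep!r} clamped to 0", stacklevel=2)
                k = 0.0
            clamped[sub] = k
        total = sum(clamped.values())
        if total <= 0:
            raise UndefinedProfileError(
                f"all formation rates are zero in replicate {rep!r}")
        per_rep[rep] = {sub: 100.0 * k / total for sub, k in clamped.items()}
        for sub in clamped:
            if sub not in substrates:
                substrates.append(sub)
    substrates.sort()
    mean = {}
    sd = {}
    for sub in substrates:
        vals = np.array([per_rep[rep].get(sub, 0.0) for rep in per_rep])
        mean[sub] = float(vals.mean())
        sd[sub] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return SpecificityProfile(substrates=substrates, mean_percent=mean,
                              sd_percent=sd, per_replicate=per_rep,
                              n_replicates=len(per_rep))


def quantify(cset: ChromatogramSet,
             species_params: dict[str, dict],
             substrate_product_map: dict[str, str] | None = None,
             window: tuple[float, float] = (0.0, 20.0),
             normalize: str = "total",
             reference: str | None = None,
             subtract_baseline: bool = True) -> SpecificityProfile:
    """Run the full XIC -> AUC -> rate -> relative-turnover pipeline.

    ``species_params`` maps each product species to a dict with keys
    ``mz_target``, ``mz_tol`` and ``rt_window``.  Normalization uses one
    denominator per replicate (summed AUC over the time course), so
    fitted-rate ratios are independent of the normalization mode.
    """
    if substrate_product_map is None:
        substrate_product_map = SUBSTRATE_PRODUCT_MAP
    species = sorted(species_params)
    # 1. areas per (replicate, time, species)
    areas: dict[str, dict[float, dict[str, float]]] = {}
    for run in cset.runs:
        rec = areas.setdefault(run.replicate_id, {}).setdefault(
            run.reaction_time_min, {})
        for sp in species:
            xic = extract_xic(run, sp, species_params[sp]["mz_target"],
                              species_params[sp]["mz_tol"])
            rec[sp] = integrate_peak(xic, species_params[sp]["rt_window"],
                                     subtract_baseline=subtract_baseline)
    # 2. one normalization constant per replicate
    replicate_rates: dict[str, dict[str, float]] = {}
    for rep, by_time in areas.items():
        totals = {sp: sum(by_time[t][sp] for t in by_time) for sp in species}
        norm_totals = normalize_area(totals, mode=normalize, reference=reference)
        factors = {sp: (norm_totals[sp] / totals[sp] if totals[sp] != 0 else 0.0)
                   for sp in species}
        # 3. time course and rate per species
        rates = {}
        for sp in species:
            pts = np.array(sorted((t, by_time[t][sp] * factors[sp])
                                  for t in by_time))
            tc = TimeCourse(species=sp, replicate_id=rep, points=pts)
            rates[sp] = fit_linear_rate(tc, window=window).slope
        replicate_rates[rep] = rates
    # 4. turnover profile
    return specificity_profile(replicate_rates, substrate_product_map)
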