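"""Dose-kinetics models and fitting for peptide radiation resistance.

Peptide SRM peak areas measured over a gamma-irradiation dose ladder are
modelled with two kinetic forms, both written as half-life (base-2)
parameterizations so t1 and t2 are literally the doses at which each
component halves:

* decay (non-oxidized peptide):    I(D) = A1·2^(−D/t1) + A2·2^(−D/t2) + C
* growth-and-decay (oxidized form): I(D) = A·(2^(−D/t2) − 2^(−D/t1)), t1 < t2

From a decay fit two resistance summaries follow: D50, the smallest dose at
which the curve falls to half its dose-0 value, and I_sat = 100·C/I0, the
plateau as a percentage of the initial intensity. Replicate reproducibility
is reported as a coefficient of variation (CV).

Fitting is constrained trust-region nonlinear least squares with a
deterministic grid of multi-starts spanning decades of (t1, t2); the label
swap t1 ↔ t2 is resolved after every start so t1 < t2 always holds.
Degenerate inputs yield flagged failure results rather than exceptions so a
pipeline over many series never halts on one bad series.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PAPER_DOSES = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0, 5000.0)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DoseSeries:
    """Intensity-vs-dose measurements for one fragment/transition/replicate."""

    fragment: str
    transition: str
    replicate: str
    doses: tuple
    intensities: tuple

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if d.shape != y.shape:
            raise ValueError("doses and intensities must have equal length")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be non-negative and strictly increasing")
        if d.size == 0 or d[0] != 0.0:
            raise ValueError("series must include dose 0")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "doses", tuple(float(x) for x in d))
        object.__setattr__(self, "intensities", tuple(float(x) for x in y))

    @property
    def n_obs(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class DecayFit:
    """Bi-exponential decay fit: amplitudes A1/A2, plateau C, half-doses t1<t2."""

    t1: float
    t2: float
    A1: float
    A2: float
    C: float
    rss: float = math.nan
    n_obs: int = 0
    success: bool = True
    message: str = ""

    @property
    def I0(self) -> float:
        return self.A1 + self.A2 + self.C

    def __call__(self, dose):
        return decay_model(dose, self.t1, self.t2, self.A1, self.A2, self.C)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["I0"] = self.I0
        d["D50"] = d50(self) if self.success else None
        d["Isat"] = i_sat(self) if self.success and self.I0 > 0 else None
        return d


@dataclass(frozen=True)
class FormDecayFit:
    """Growth-and-decay fit: formation half-dose t1, degradation half-dose t2."""

    t1: float
    t2: float
    A: float
    rss: float = math.nan
    n_obs: int = 0
    success: bool = True
    message: str = ""

    def __call__(self, dose):
        return form_decay_model(dose, self.t1, self.t2, self.A)

    @property
    def peak_dose(self) -> float:
        return peak_dose(self.t1, self.t2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_dose"] = self.peak_dose if self.success else None
        return d


def decay_model(dose, t1: float, t2: float, A1: float, A2: float, C: float):
    """I(D) = A1·2^(−D/t1) + A2·2^(−D/t2) + C."""
    D = np.asarray(dose, dtype=float)
    out = A1 * np.exp2(-D / t1) + A2 * np.exp2(-D / t2) + C
    return out if out.ndim else float(out)


def form_decay_model(dose, t1: float, t2: float, A: float):
    """I(D) = A·(2^(−D/t2) − 2^(−D/t1)); zero at D=0, rises then decays."""
    if t1 >= t2:
        raise ValueError("form-decay model requires t1 < t2 (unidentifiable otherwise)")
    D = np.asarray(dose, dtype=float)
    out = A * (np.exp2(-D / t2) - np.exp2(-D / t1))
    return out if out.ndim else float(out)


def peak_dose(t1: float, t2: float) -> float:
    """Dose of maximal oxidized-form intensity: ln(k1/k2)/(k1−k2), k=ln2/t."""
    k1, k2 = LN2 / t1, LN2 / t2
    return math.log(k1 / k2) / (k1 - k2)


def _start_grid(doses: np.ndarray, n_starts: int):
    """Deterministic (t1, t2) start pairs spanning decades of the dose range."""
    d_hi = float(doses.max())
    lo = max(doses[doses > 0].min() / 4.0, 1e-2) if np.any(doses > 0) else 1.0
    t1s = np.geomspace(lo, d_hi / 4.0, 5)
    t2s = np.geomspace(lo * 10.0, d_hi * 2.0, 4)
    pairs = [(a, b) for a, b in itertools.product(t1s, t2s) if a < b]
    return pairs[:n_starts]


def _residual_scale(y: np.ndarray, weighting: str) -> np.ndarray:
    """Residual denominators: SRM peak areas carry multiplicative noise, so
    ``relative`` (default) weights residuals by the observed intensity
    (floored at 0.1% of the maximum to keep near-zero tail points finite);
    ``absolute`` is plain unweighted least squares."""
    if weighting == "relative":
        return np.maximum(y, 1e-3 * y.max())
    if weighting == "absolute":
        return np.ones_like(y)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_decay(
    series: DoseSeries,
    n_starts: int = 20,
    seed: int = 0,
    weighting: str = "relative",
) -> DecayFit:
    """Fit the bi-exponential decay model by multi-start least squares.

    The starts are a fixed geometric grid, so the fit is a pure function of
    the data (``seed`` is accepted for interface symmetry with the synthetic
    generators and reserved for optional start jittering). Requires at least
    6 dose points including dose 0; degenerate input returns a flagged
    failure, never raises.
    """
    d = np.asarray(series.doses)
    y = np.asarray(series.intensities)
    fail = lambda msg: DecayFit(
        math.nan, math.nan, math.nan, math.nan, math.nan,
        rss=math.nan, n_obs=series.n_obs, success=False, message=msg,
    )
    if series.n_obs < 6:
        return fail("need >= 6 dose points")
    if not np.any(y > 0):
        return fail("all-zero intensities")

    i0 = max(y[0], y.max() * 1e-3)
    ymin = y.min()
    scale = _residual_scale(y, weighting)

    def residuals(x):
        a1, a2, c, lt1, lt2 = x
        return (decay_model(d, 10.0 ** lt1, 10.0 ** lt2, a1, a2, c) - y) / scale

    best = None
    for t1_0, t2_0 in _start_grid(d, n_starts):
        x0 = np.array([
            max((i0 - ymin) * 0.6, 1e-6 * i0),
            max((i0 - ymin) * 0.3, 1e-6 * i0),
            max(ymin, 1e-9 * i0),
            math.log10(t1_0),
            math.log10(t2_0),
        ])
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=([0.0, 0.0, 0.0, -3.0, -3.0], [np.inf, np.inf, np.inf, 7.0, 7.0]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x.copy())
    if best is None:
        return fail("no start converged")
    rss, x = best
    a1, a2, c, lt1, lt2 = x
    t1, t2 = 10.0 ** lt1, 10.0 ** lt2
    if t1 > t2:  # resolve label swap
        t1, t2 = t2, t1
        a1, a2 = a2, a1
    if t2 <= 1.001 * t1:
        # the two components collapsed onto one time constant, where the
        # amplitude split A1/A2 is unidentifiable: refit the nested
        # single-exponential model and report A2 = 0 (t2 then carries no
        # information and is set to the conventional 10·t1)
        def residuals1(x):
            a, cc, lt = x
            return (a * np.exp2(-d / 10.0 ** lt) + cc - y) / scale

        try:
            sol1 = least_squares(
                residuals1,
                np.array([a1 + a2, c, math.log10(t1)]),
                bounds=([0.0, 0.0, -3.0], [np.inf, np.inf, 7.0]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            sol1 = None
        if sol1 is not None and sol1.success:
            rss1 = float(2.0 * sol1.cost)
            ss = float(np.sum((y / scale) ** 2))
            if rss1 <= rss * (1.0 + 1e-6) + 1e-12 * max(ss, 1.0):
                a1, c, lt1 = sol1.x
                t1 = 10.0 ** lt1
                a2, t2, rss = 0.0, 10.0 * t1, rss1
    return DecayFit(t1=t1, t2=t2, A1=a1, A2=a2, C=c,
                    rss=rss, n_obs=series.n_obs, success=True)


def fit_form_decay(
    series: DoseSeries,
    n_starts: int = 20,
    seed: int = 0,
    weighting: str = "relative",
) -> FormDecayFit:
    """Fit the growth-and-decay model; conventions as in :func:`fit_decay`."""
    d = np.asarray(series.doses)
    y = np.asarray(series.intensities)
    fail = lambda msg: FormDecayFit(
        math.nan, math.nan, math.nan,
        rss=math.nan, n_obs=series.n_obs, success=False, message=msg,
    )
    if series.n_obs < 6:
        return fail("need >= 6 dose points")
    if not np.any(y > 0):
        return fail("all-zero intensities")

    ymax = y.max()
    scale = _residual_scale(y, weighting)

    def residuals(x):
        a, lt1, lt2 = x
        t1, t2 = 10.0 ** lt1, 10.0 ** lt2
        # allow the optimizer to wander across the t1==t2 ridge; the
        # antisymmetric form A·(2^(−D/t2) − 2^(−D/t1)) is evaluated directly
        return (a * (np.exp2(-d / t2) - np.exp2(-d / t1)) - y) / scale

    best = None
    for t1_0, t2_0 in _start_grid(d, n_starts):
        x0 = np.array([ymax * 2.5, math.log10(t1_0), math.log10(t2_0)])
        try:
            sol = least_squares(
                residuals, x0,
                bounds=([-np.inf, -3.0, -3.0], [np.inf, 7.0, 7.0]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x.copy())
    if best is None:
        return fail("no start converged")
    rss, x = best
    a, lt1, lt2 = x
    t1, t2 = 10.0 ** lt1, 10.0 ** lt2
    if t1 > t2:  # swapping t1,t2 negates the difference, so flip A too
        t1, t2 = t2, t1
        a = -a
    if not a > 0 or math.isclose(t1, t2, rel_tol=1e-6):
        return fail("degenerate fit (non-positive amplitude or t1 == t2)")
    return FormDecayFit(t1=t1, t2=t2, A=a, rss=rss, n_obs=series.n_obs, success=True)


def d50(fit: DecayFit, tol: float = 0.1) -> Optional[float]:
    """Smallest dose with I(D) = I0/2, by bisection on [0, 10·t2].

    Returns None (undefined) when the plateau C is at or above half the
    initial intensity, or for failed fits.
    """
    if not fit.success:
        return None
    i0 = fit.I0
    if i0 <= 0 or fit.C >= i0 / 2.0:
        return None
    half = i0 / 2.0
    lo, hi = 0.0, 10.0 * fit.t2
    if fit(hi) > half:  # not reached within the bracket
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fit(mid) > half:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def i_sat(fit: DecayFit) -> float:
    """Saturating intensity as percent of the fitted dose-0 intensity."""
    if fit.I0 == 0:
        raise ValueError("I0 is zero; I_sat undefined")
    return 100.0 * fit.C / fit.I0


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 × sample sd / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * v.std(ddof=1) / m


# ---------------------------------------------------------------------------
# panel-level fitting


def pool_series(group: Sequence[DoseSeries]) -> DoseSeries:
    """Sum intensities of several series over a shared dose ladder."""
    base = group[0]
    for s in group[1:]:
        if s.doses != base.doses:
            raise ValueError("pooled series must share the dose ladder")
    total = np.sum([s.intensities for s in group], axis=0)
    return DoseSeries(
        fragment=base.fragment, transition="pooled", replicate=base.replicate,
        doses=base.doses, intensities=tuple(total),
    )


def fit_fragment(
    group: Sequence[DoseSeries],
    model: str = "decay",
    mode: str = "per-transition",
    n_starts: int = 20,
    seed: int = 0,
    weighting: str = "relative",
) -> pd.DataFrame:
    """Fit every series of one fragment and summarize parameters with CVs.

    ``mode='per-transition'`` (default) fits each transition/replicate series
    separately then averages the parameters, reporting the CV across fits —
    the triplicate-CV convention of SRM assays. ``mode='pooled'`` sums the
    transitions per replicate before fitting.
    """
    fitter = fit_decay if model == "decay" else fit_form_decay
    if mode == "pooled":
        by_rep: dict = {}
        for s in group:
            by_rep.setdefault(s.replicate, []).append(s)
        series_list = [pool_series(v) for v in by_rep.values()]
    else:
        series_list = list(group)
    fits = [
        fitter(s, n_starts=n_starts, seed=seed, weighting=weighting)
        for s in series_list
    ]
    ok = [f for f in fits if f.success]
    rows = []
    params = ("t1", "t2") if model != "decay" else ("t1", "t2", "D50", "Isat")
    for p in params:
        if model == "decay":
            vals = {
                "t1": [f.t1 for f in ok],
                "t2": [f.t2 for f in ok],
                "D50": [d50(f) for f in ok],
                "Isat": [i_sat(f) for f in ok if f.I0 > 0],
            }[p]
            vals = [v for v in vals if v is not None]
        else:
            vals = [getattr(f, p) for f in ok]
        if not vals:
            rows.append(dict(parameter=p, mean=math.nan, cv_pct=math.nan, n=0))
            continue
        mean = float(np.mean(vals))
        cv = replicate_cv(vals) if len(vals) >= 2 and mean > 0 else math.nan
        rows.append(dict(parameter=p, mean=mean, cv_pct=cv, n=len(vals)))
    out = pd.DataFrame(rows)
    out.insert(0, "fragment", group[0].fragment)
    out.insert(1, "model", model)
    out["n_failed"] = len(fits) - len(ok)
    return out


# ---------------------------------------------------------------------------
# exchange formats


def read_dose_csv(path) -> list:
    """Read a dose-response CSV (fragment, transition, replicate, dose_gy, intensity)."""
    df = pd.read_csv(path)
    out = []
    for (frag, trans, rep), g in df.groupby(
        ["fragment", "transition", "replicate"], sort=True
    ):
        g = g.sort_values("dose_gy")
        out.append(
            DoseSeries(
                fragment=str(frag), transition=str(trans), replicate=str(rep),
                doses=tuple(g["dose_gy"]), intensities=tuple(g["intensity"]),
            )
        )
    return out


def write_dose_csv(series: Iterable[DoseSeries], path) -> None:
    recs = [
        dict(fragment=s.fragment, transition=s.transition, replicate=s.replicate,
             dose_gy=d, intensity=y)
        for s in series
        for d, y in zip(s.doses, s.intensities)
    ]
    pd.DataFrame(recs).to_csv(path, index=False)


def fits_to_json(fits: dict, path=None) -> str:
    """Serialize {name: DecayFit|FormDecayFit} to JSON (deterministic key order)."""
    payload = {k: f.to_dict() for k, f in sorted(fits.items())}
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
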