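"""Crop-statistics GPP conversion, harvest-index calibration and validation.

District crop production P_i (tonnes) is converted to a gross-productivity
estimate via the harvest index HI_i, respiration coefficient RC_i and
produce moisture content MC_i of each crop i:

    stat_GPP = 1.15 * sum_i  P_i[g] / HI_i * (1 + RC_i) * (1 - MC_i)

The 1.15 multiplier accounts for litterfall and energy-efficiency losses.
Calibration finds, per district/season/year, the bounded HI vector that
matches the satellite GPP total; validation applies a previous year's
coefficients to the next year's statistics without any optimisation.

One district yields one scalar matching equation, which cannot identify
several harvest indices independently. The default solver therefore moves
all free HIs together along their bound intervals, hi_i = lo_i + s*(up_i-lo_i)
with a single shared s in [0,1], and finds s by bisection (the objective is
strictly decreasing in s). A multivariate bounded minimiser started from the
bound midpoints is available as an alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

LITTER_FACTOR = 1.15
GRAMS_PER_TONNE = 1e6
#: bisection tolerance on the shared bound-interval position s
S_TOL = 1e-10


@dataclass(frozen=True)
class CropCoefficients:
    """Per-crop conversion coefficients and harvest-index bounds.

    ``fixed_hi`` pins the harvest index (e.g. sugarcane at 0.69) so the
    crop contributes to the conversion but is excluded from optimisation.
    """

    crop: str
    hi_lower: float
    hi_upper: float
    rc: float
    mc: float
    fixed_hi: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.hi_lower <= self.hi_upper < 1):
            raise ValueError(f"{self.crop}: need 0 < hi_lower <= hi_upper < 1")
        if not (0 <= self.mc < 1):
            raise ValueError(f"{self.crop}: need 0 <= mc < 1")
        if self.rc < 0:
            raise ValueError(f"{self.crop}: rc must be non-negative")
        if self.fixed_hi is not None and not (0 < self.fixed_hi < 1):
            raise ValueError(f"{self.crop}: fixed_hi must be in (0,1)")


@dataclass
class CalibrationResult:
    district_id: int
    season: str
    year: int
    hi: dict[str, float]
    residual_z: float  # gC, the |difference| objective at the solution
    at_bound: dict[str, bool] = field(default_factory=dict)
    objective_evals: int = 0


def production_to_gpp(records: pd.DataFrame, hi: dict[str, float],
                      coefficients: dict[str, CropCoefficients],
                      litter_factor: float = LITTER_FACTOR,
                      carbon_fraction: float = 1.0) -> float:
    """Statistics-derived GPP (gC) for one district's records.

    ``records`` needs columns ``crop`` and ``production_t``; every crop must
    have coefficients and a harvest index in (0, 1).
    """
    total = 0.0
    for row in records.itertuples():
        crop = row.crop
        if crop not in coefficients:
            raise KeyError(f"no coefficients for crop {crop!r}")
        c = coefficients[crop]
        h = hi[crop]
        if not (0 < h < 1):
            raise ValueError(f"harvest index for {crop!r} must be in (0,1)")
        total += row.production_t * GRAMS_PER_TONNE / h * (1 + c.rc) * (1 - c.mc)
    return litter_factor * total * carbon_fraction


def _hi_vector(coeffs: dict[str, CropCoefficients], free: list[str], s: float,
               ) -> dict[str, float]:
    hi = {c.crop: c.fixed_hi for c in coeffs.values() if c.fixed_hi is not None}
    for crop in free:
        c = coeffs[crop]
        hi[crop] = c.hi_lower + s * (c.hi_upper - c.hi_lower)
    return hi


def calibrate_hi(sat_gpp: float, records: pd.DataFrame,
                 coefficients: dict[str, CropCoefficients],
                 district_id: int = 0, season: str = "", year: int = 0,
                 backend: str = "shared_s",
                 litter_factor: float = LITTER_FACTOR,
                 carbon_fraction: float = 1.0) -> CalibrationResult:
    """Find the bounded harvest-index vector matching the satellite GPP.

    Minimises Z = |sat_gpp - stat_gpp(HI)| subject to the per-crop bounds;
    fixed-HI crops are held constant. Ties at exact bounds resolve to the
    bound. Raises on empty records or when every crop has a fixed HI.
    """
    if len(records) == 0:
        raise ValueError("no crop statistics records for this district")
    crops = list(records["crop"].unique())
    for crop in crops:
        if crop not in coefficients:
            raise KeyError(f"no coefficients for crop {crop!r}")
    free = [c for c in crops if coefficients[crop_key(coefficients, c)].fixed_hi is None]
    if not free:
        raise ValueError("calibration needs at least one crop with a free harvest index")

    evals = 0

    def stat_gpp(hi: dict[str, float]) -> float:
        nonlocal evals
        evals += 1
        return production_to_gpp(records, hi, coefficients, litter_factor,
                                 carbon_fraction)

    if backend == "shared_s":
        def f(s: float) -> float:
            return stat_gpp(_hi_vector(coefficients, free, s))

        # stat GPP is strictly decreasing in s (each HI grows with s)
        if sat_gpp >= f(0.0):
            s_hat, clipped = 0.0, True
        elif sat_gpp <= f(1.0):
            s_hat, clipped = 1.0, True
        else:
            lo, hi_s = 0.0, 1.0
            while hi_s - lo > S_TOL:
                mid = 0.5 * (lo + hi_s)
                if f(mid) > sat_gpp:
                    lo = mid
                else:
                    hi_s = mid
            s_hat, clipped = 0.5 * (lo + hi_s), False
            # secant polish inside the final bracket closes the residual
            # to machine precision on noiseless data
            a, b = lo, hi_s
            fa, fb = f(a) - sat_gpp, f(b) - sat_gpp
            for _ in range(3):
                if fb == fa:
                    break
                c = min(1.0, max(0.0, b - fb * (b - a) / (fb - fa)))
                fc = f(c) - sat_gpp
                a, fa, b, fb = b, fb, c, fc
                if fc == 0.0:
                    break
            if abs(fb) < abs(f(s_hat) - sat_gpp):
                s_hat = b
        hi_vec = _hi_vector(coefficients, free, s_hat)
        at_bound = {c: clipped for c in free}
    elif backend == "multivariate":
        lo = np.array([coefficients[c].hi_lower for c in free])
        up = np.array([coefficients[c].hi_upper for c in free])
        x0 = 0.5 * (lo + up)  # bound midpoints as the starting point

        def obj(x: np.ndarray) -> float:
            hi = _hi_vector(coefficients, free, 0.0)
            hi.update(dict(zip(free, x)))
            return (sat_gpp - stat_gpp(hi)) ** 2

        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, up)),
                                options={"ftol": 1e-18, "gtol": 1e-14})
        hi_vec = _hi_vector(coefficients, free, 0.0)
        hi_vec.update(dict(zip(free, res.x)))
        at_bound = {c: bool(np.isclose(h, coefficients[c].hi_lower)
                            or np.isclose(h, coefficients[c].hi_upper))
                    for c, h in zip(free, res.x)}
    else:
        raise ValueError(f"unknown backend {backend!r}")

    residual = abs(sat_gpp - stat_gpp(hi_vec))
    # the solution must never be worse than the midpoint start
    mid_obj = abs(sat_gpp - stat_gpp(_hi_vector(coefficients, free, 0.5)))
    if residual > mid_obj * (1 + 1e-9) + 1e-9:
        raise RuntimeError("calibration worsened the objective relative to the midpoint start")
    hi_out = {c: hi_vec[c] for c in crops}
    return CalibrationResult(district_id, season, year, hi_out, residual,
                             at_bound, evals)


def crop_key(coefficients: dict[str, CropCoefficients], crop: str) -> str:
    if crop not in coefficients:
        raise KeyError(f"no coefficients for crop {crop!r}")
    return crop


def calibrate_all(district_gpp: pd.DataFrame, stats: pd.DataFrame,
                  coefficients: dict[str, CropCoefficients],
                  retained_ids: set[int] | None = None,
                  backend: str = "shared_s") -> list[CalibrationResult]:
    """Calibrate every (retained) district independently."""
    results = []
    gpp_by_district = district_gpp.set_index("district_id")
    for did, recs in stats.groupby("district_id"):
        if retained_ids is not None and did not in retained_ids:
            continue
        row = gpp_by_district.loc[did]
        results.append(calibrate_hi(float(row["sat_gpp_total_gc"]), recs,
                                    coefficients, district_id=int(did),
                                    season=str(row.get("season", "")),
                                    year=int(row.get("year", 0)),
                                    backend=backend))
    return results


def validate_next_year(prev_results: list[CalibrationResult],
                       next_year_records: pd.DataFrame,
                       next_year_district_gpp: pd.DataFrame,
                       coefficients: dict[str, CropCoefficients],
                       litter_factor: float = LITTER_FACTOR,
                       carbon_fraction: float = 1.0
                       ) -> tuple[pd.DataFrame, list[int]]:
    """Apply previous-year harvest indices to next-year statistics.

    No optimisation is performed. Returns ``(pairs, skipped)`` where
    ``pairs`` has one (sat_gpp, stat_gpp) row per district and ``skipped``
    lists districts lacking previous-year coefficients.
    """
    prev_hi = {r.district_id: r.hi for r in prev_results}
    gpp_by_district = next_year_district_gpp.set_index("district_id")
    rows, skipped = [], []
    for did, recs in next_year_records.groupby("district_id"):
        if did not in prev_hi or did not in gpp_by_district.index:
            skipped.append(int(did))
            continue
        hi = dict(prev_hi[did])
        for crop in recs["crop"].unique():
            if crop not in hi:  # crop absent in the calibration year
                c = coefficients[crop_key(coefficients, crop)]
                hi[crop] = c.fixed_hi if c.fixed_hi is not None \
                    else 0.5 * (c.hi_lower + c.hi_upper)
        stat = production_to_gpp(recs, hi, coefficients, litter_factor,
                                 carbon_fraction)
        rows.append({"district_id": int(did),
                     "sat_gpp": float(gpp_by_district.loc[did, "sat_gpp_total_gc"]),
                     "stat_gpp": stat})
    return pd.DataFrame(rows), skipped


def compute_r2(pairs: pd.DataFrame) -> float:
    """Squared Pearson correlation of (sat_gpp, stat_gpp); NaN if degenerate."""
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    x = pairs["sat_gpp"].to_numpy(float)
    y = pairs["stat_gpp"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def compute_nrmse(pairs: pd.DataFrame) -> float:
    """RMSE of sat vs stat GPP as a percentage of the mean stat GPP."""
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    x = pairs["sat_gpp"].to_numpy(float)
    y = pairs["stat_gpp"].to_numpy(float)
    mean_y = np.mean(y)
    if mean_y == 0:
        raise ValueError("nRMSE undefined for zero-mean statistics GPP")
    return float(100.0 * np.sqrt(np.mean((x - y) ** 2)) / mean_y)
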