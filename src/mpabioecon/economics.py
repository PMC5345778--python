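"""Revenue, distance-corrected operating cost, discounting, and error stats.

Landed revenue is price x catch (CAD 1.24 per kg). Operating cost is anchored
to the mixed-fleet profitability ratio (~1.6 = landed value / operating cost)
for the Status-Quo baseline distance; the distance-variable share of cost
(fuel and labour) scales linearly with the catch-weighted mean fishing
distance relative to that baseline:

    C = (R / ratio) * [(1 - share) + share * d / d_baseline]

Net present value discounts annual net revenue with beta_t = (1 + SDR)^-t
over the evaluation horizon. Scenario NPVs are compared with paired error
statistics (MAE, RMSE, MAPE) against the Status-Quo reference.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import EconParams

__all__ = [
    "revenue",
    "operating_cost",
    "discount_factor",
    "npv",
    "error_stats",
]


def revenue(catch_t: float, price: float = 1.24) -> float:
    """Landed value, CAD, from catch in tonnes at ``price`` CAD/kg."""
    if catch_t < 0:
        raise ValueError("catch must be non-negative")
    return catch_t * 1000.0 * price


def operating_cost(
    revenue_cad: float,
    mean_distance: float | None,
    ep: EconParams,
) -> float:
    """Operating cost with the distance correction factor, CAD.

    At the baseline distance the cost is revenue / profitability_ratio; the
    distance-variable share of cost scales with distance relative to the
    baseline. A year without catch (missing distance) costs nothing.
    """
    if revenue_cad < 0:
        raise ValueError("revenue must be non-negative")
    if revenue_cad == 0 or mean_distance is None or not np.isfinite(mean_distance):
        return 0.0
    if ep.baseline_distance is None or ep.baseline_distance <= 0:
        raise ValueError("baseline_distance must be configured and positive")
    share = ep.distance_variable_share
    factor = (1.0 - share) + share * mean_distance / ep.baseline_distance
    return revenue_cad / ep.profitability_ratio * factor


def discount_factor(sdr: float, t) -> np.ndarray | float:
    """Discount factor beta_t = (1 + SDR)^-t."""
    if sdr <= -1:
        raise ValueError("sdr must exceed -1")
    t = np.asarray(t, dtype=float)
    out = (1.0 + sdr) ** -t
    return float(out) if out.ndim == 0 else out


def npv(net_revenues, sdr: float, t_start: int = 1) -> float:
    """NPV = sum_t (R_t - C_t) beta_t for t = t_start, t_start+1, ...

    ``net_revenues`` is the yearly net revenue series in evaluation order;
    the first element is discounted at ``t_start`` (default 1).
    """
    net = np.asarray(net_revenues, dtype=float)
    if net.size == 0:
        raise ValueError("net revenue series must be non-empty")
    t = np.arange(t_start, t_start + net.size)
    return float(np.sum(net * discount_factor(sdr, t)))


def error_stats(npv_ref, npv_alt) -> tuple[float, float, float | None]:
    """Paired (MAE, RMSE, MAPE%) of an alternative scenario vs the reference.

    Values are paired by replicate index. MAPE is undefined (returned as
    None, with a warning) if any reference value is zero.
    """
    ref = np.asarray(npv_ref, dtype=float)
    alt = np.asarray(npv_alt, dtype=float)
    if ref.shape != alt.shape or ref.ndim != 1 or ref.size == 0:
        raise ValueError("series must be non-empty, equal-length 1-D arrays")
    err = alt - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.any(ref == 0):
        warnings.warn("reference NPV contains zeros; MAPE is undefined")
        mape = None
    else:
        mape = float(100.0 * np.mean(np.abs(err) / np.abs(ref)))
    return mae, rmse, mape
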