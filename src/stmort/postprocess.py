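"""Posterior summaries: trend categories, exceedance bands, quartile maps.

The decision rule for excess mortality is based on the posterior
probability that the rate ratio exceeds 1, banded at the cut-offs
0.05 / 0.20 / 0.80 / 0.95:

* prob > 0.95          -> significant excess mortality;
* 0.80 < prob <= 0.95  -> area at risk;
* 0.20 <= prob <= 0.80 -> little evidence either way (similar to reference);
* 0.05 <= prob < 0.20  -> low-risk area;
* prob < 0.05          -> significantly lower than the reference rate.

Boundary conventions at the cut-offs are centralized here (prose
statements of such rules are typically ambiguous about strictness).

Trend classification uses the posterior distribution of each area's
average time-derivative of the log rate over the study window; with a
centered time scale this is beta1 + delta_m (the quadratic term averages
out).  An area is called increasing (decreasing) when the posterior
probability of a positive (negative) slope reaches ``prob_level``
(default 0.95), and non-significant otherwise.

Reporting-scale conversion lives only here: rates are mapped per 10,000
inhabitants, except the under-1 age group which is reported per 1,000.
Everything upstream is per-person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "EXCESS_BANDS", "reporting_scale",
    "municipality_trend_draws", "classify_trend", "trend_classification",
    "exceedance_probability", "classify_excess", "excess_classification",
    "quartile_bins", "QuartileResult", "rate_summary",
    "tabulate_trend", "excess_summary",
]

EXCESS_BANDS = ("significantly_low", "low_risk", "similar", "at_risk",
                "significant_excess")
TREND_CATEGORIES = ("decreasing", "non_significant", "increasing")


def reporting_scale(age_group: str) -> float:
    """Per-10,000 reporting scale; per-1,000 for the under-1 group."""
    return 1000.0 if age_group == "<1" else 10000.0


# ---------------------------------------------------------------------------
# Trend
# ---------------------------------------------------------------------------


def municipality_trend_draws(samples: PosteriorSamples, area: int) -> np.ndarray:
    """Posterior draws of one area's average log-rate slope (per t' unit).

    The average over the study years of d(eta)/dt' =
    sum_k k beta_k t'^(k-1) + delta_m.  On a symmetric centered grid the
    even-degree contributions vanish and this reduces to beta1 + delta_m.
    """
    C, D, K = samples.beta.shape
    ts = samples.tstar
    beta = samples.beta.reshape(C * D, K)
    deriv = np.zeros(C * D)
    for k in range(1, K):
        deriv += k * beta[:, k] * float(np.mean(ts ** (k - 1)))
    if samples.delta is not None:
        deriv = deriv + samples.delta.reshape(C * D, -1)[:, area]
    return deriv


def classify_trend(draws: np.ndarray, prob_level: float = 0.95) -> str:
    """increasing / decreasing when P(slope >< 0) reaches ``prob_level``."""
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    if p_pos >= prob_level:
        return "increasing"
    if p_neg >= prob_level:
        return "decreasing"
    return "non_significant"


def trend_classification(samples: PosteriorSamples,
                         prob_level: float = 0.95) -> pd.DataFrame:
    """Per-area trend category and posterior probability of a positive slope."""
    rows = []
    for m, aid in enumerate(samples.areas):
        draws = municipality_trend_draws(samples, m)
        rows.append({
            "area_id": aid,
            "prob_positive_slope": float(np.mean(draws > 0)),
            "median_slope": float(np.median(draws)),
            "category": classify_trend(draws, prob_level),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exceedance
# ---------------------------------------------------------------------------


def exceedance_probability(rr_draws: np.ndarray) -> float:
    """Fraction of rate-ratio draws strictly greater than 1."""
    rr = np.asarray(rr_draws)
    if rr.size == 0:
        raise ValueError("empty draw vector")
    return float(np.mean(rr > 1.0))


def classify_excess(prob: float) -> str:
    """Band a P(RR > 1) value at the 0.05/0.20/0.80/0.95 cut-offs."""
    if not (0.0 <= prob <= 1.0):
        raise ValueError(f"probability {prob} outside [0, 1]")
    if prob > 0.95:
        return "significant_excess"
    if prob > 0.80:
        return "at_risk"
    if prob >= 0.20:
        return "similar"
    if prob >= 0.05:
        return "low_risk"
    return "significantly_low"


def excess_classification(samples: PosteriorSamples, year: int) -> pd.DataFrame:
    """Per-area P(RR>1) and band for one year, from a rate-ratio fit."""
    if samples.spec.variant != "rate_ratio":
        raise ValueError("exceedance classification needs a rate_ratio fit")
    rr = np.exp(samples.eta_draws(year))     # (draws, areas)
    probs = (rr > 1.0).mean(axis=0)
    return pd.DataFrame({
        "area_id": list(samples.areas),
        "year": year,
        "prob_rr_gt_1": probs,
        "median_rr": np.median(rr, axis=0),
        "band": [classify_excess(float(p)) for p in probs],
    })


# ---------------------------------------------------------------------------
# Quartile maps and dispersion
# ---------------------------------------------------------------------------


@dataclass
class QuartileResult:
    bins: np.ndarray        # 1..4 per value
    quartiles: tuple        # (Q1, Q2, Q3)
    iqr: float
    degenerate: bool        # IQR == 0 (flat map)


def quartile_bins(values: np.ndarray) -> QuartileResult:
    """Quartile bin (1-4) per value plus the interquartile range.

    Quartiles use linear-interpolation quantiles.  Bins are the half-open
    intervals [Q_{k-1}, Q_k), with bin 4 closed above, so a constant
    vector lands entirely in bin 4 and is flagged degenerate.  Bins are
    invariant under strictly increasing affine rescaling.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile binning")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    bins = np.full(v.shape, 4, dtype=int)
    bins[v < q3] = 3
    bins[v < q2] = 2
    bins[v < q1] = 1
    iqr = float(q3 - q1)
    return QuartileResult(bins=bins, quartiles=(float(q1), float(q2), float(q3)),
                          iqr=iqr, degenerate=iqr == 0.0)


def rate_summary(samples: PosteriorSamples, year: int, age_group: str,
                 point: str = "median") -> pd.DataFrame:
    """Per-area smoothed specific rate on the reporting scale, with
    quartile bin and the stratum-level IQR.

    The point estimate is the posterior median by default (robust for
    skewed small-count posteriors); ``point="mean"`` is available.
    """
    if samples.spec.variant != "rate":
        raise ValueError("rate summaries need a rate-variant fit")
    scale = reporting_scale(age_group)
    rates = np.exp(samples.eta_draws(year)) * scale
    est = (np.median(rates, axis=0) if point == "median"
           else rates.mean(axis=0))
    qr = quartile_bins(est)
    return pd.DataFrame({
        "area_id": list(samples.areas),
        "year": year,
        "rate": est,
        "quartile_bin": qr.bins,
        "iqr": qr.iqr,
    })


# ---------------------------------------------------------------------------
# Tabulations
# ---------------------------------------------------------------------------


def tabulate_trend(classifications: dict[tuple[str, str], pd.DataFrame]
                   ) -> pd.DataFrame:
    """Counts and percentages of areas per trend category, per stratum.

    One row per stratum; counts sum to the number of areas, percentages to
    100 up to rounding.
    """
    rows = []
    for (gender, age), cls in classifications.items():
        n = len(cls)
        row = {"gender": gender, "age_group": age, "n_areas": n}
        for cat in TREND_CATEGORIES:
            cnt = int((cls["category"] == cat).sum())
            row[f"{cat}_n"] = cnt
            row[f"{cat}_pct"] = 100.0 * cnt / n
        rows.append(row)
    return pd.DataFrame(rows)


def _five_number(v: np.ndarray) -> dict[str, float]:
    q = np.percentile(v, [25, 50, 75])
    return {"min": float(np.min(v)), "q1": float(q[0]), "median": float(q[1]),
            "q3": float(q[2]), "max": float(np.max(v))}


def excess_summary(rate_summ: pd.DataFrame, excess_cls: pd.DataFrame,
                   reference_rate: float,
                   select_bands: tuple = ("significant_excess",)) -> dict:
    """Characterize the areas in the selected excess bands (one stratum/year).

    Returns n and percentage of areas selected, five-number summaries of
    their smoothed rate (reporting scale) and smoothed rate ratio, and the
    reference rate for context.  An empty selection yields n = 0 with no
    quantiles.
    """
    merged = rate_summ.merge(excess_cls, on=["area_id", "year"])
    sel = merged[merged["band"].isin(select_bands)]
    n_total = len(merged)
    out = {"n": int(len(sel)), "pct": 100.0 * len(sel) / n_total,
           "reference_rate": float(reference_rate)}
    if len(sel) == 0:
        return out
    out["rate"] = _five_number(sel["rate"].to_numpy())
    out["rate_ratio"] = _five_number(sel["median_rr"].to_numpy())
    return out
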