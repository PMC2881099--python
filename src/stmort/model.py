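"""Hierarchical Poisson models for small-area mortality rates and rate ratios.

Two model variants share one linear predictor on the log scale,

    eta_mt = beta0 + beta1*t' + beta2*t'^2 (+ ...) + S_m + H_m + delta_m*t'

with ``t'`` a centered/scaled year index, ``S`` a spatially structured
(intrinsic CAR) field, ``H`` an exchangeable heterogeneity field, and
``delta`` an area-specific differential time trend.  They differ only in
the Poisson offset:

* ``rate`` variant:        O_mt ~ Poisson(p_mt * exp(eta)) — exp(eta) is the
  area's specific mortality rate;
* ``rate_ratio`` variant:  O_mt ~ Poisson(p_mt * R_t * exp(eta)) — exp(eta)
  is the rate ratio against the reference (national) rate R_t.

Smoothing the rate ratio directly is not the same as dividing a smoothed
rate by the reference rate, which is why both variants exist.

Priors: flat intercept; vague normal on the remaining polynomial
coefficients (variance ``V_beta``); intrinsic CAR on ``S`` (and on ``delta``
by default); exchangeable normal on ``H``; gamma on every precision.
Everything here is a pure, sampler-agnostic specification; the sampler
lives in :mod:`stmort.mcmc`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import IO, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .spatial_graph import AdjacencyGraph, car_log_kernel

__all__ = [
    "AGE_GROUPS", "GENDERS", "StudyPanel", "StratumData",
    "ModelSpec", "ModelState", "NumericalError",
    "time_index", "tstar_grid", "linear_predictor", "eta_matrix",
    "cell_mean", "poisson_loglik", "log_prior", "log_posterior", "deviance",
]

AGE_GROUPS = ("<1", "1-14", "15-44", "45-64", "65-74", "75-84", "85+")
GENDERS = ("male", "female")

PANEL_COLUMNS = ["area_id", "year", "gender", "age_group",
                 "deaths", "population", "reference_rate"]


class NumericalError(FloatingPointError):
    """Raised when a posterior evaluation fails numerically (NaN/overflow),
    as opposed to a validly rejected state (-inf)."""


# ---------------------------------------------------------------------------
# Panel containers
# ---------------------------------------------------------------------------


@dataclass
class StratumData:
    """One stratum's panel, pivoted to (area x year) arrays.

    ``deaths`` holds 0 at missing cells; ``observed`` is False there.
    ``reference_rate`` is per-person per-year and constant across areas
    within a year.
    """

    gender: str
    age_group: str
    areas: tuple
    years: np.ndarray
    deaths: np.ndarray          # (M, T) int
    population: np.ndarray      # (M, T) int
    reference_rate: np.ndarray  # (T,) float
    observed: np.ndarray        # (M, T) bool

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def offset(self, variant: str) -> np.ndarray:
        """Poisson offset matrix: population, or population x reference rate."""
        p = self.population.astype(float)
        if variant == "rate":
            return p
        if variant == "rate_ratio":
            return p * self.reference_rate[None, :]
        raise ValueError(f"unknown variant {variant!r}")


class StudyPanel:
    """Long-format mortality panel: (area, year, stratum) cells.

    Wraps a tidy DataFrame with columns ``area_id, year, gender, age_group,
    deaths, population, reference_rate, missing``.  Missing deaths are the
    cells excluded from the likelihood (they are skipped, not imputed).
    Area order is significant: it must match the adjacency graph's node
    order.
    """

    def __init__(self, data: pd.DataFrame, areas: Sequence | None = None):
        df = data.copy()
        missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"panel missing columns: {missing_cols}")
        if "missing" not in df.columns:
            df["missing"] = df["deaths"].isna()
        else:
            df["missing"] = df["missing"].astype(bool) | df["deaths"].isna()
        df["deaths"] = df["deaths"].astype(float)
        neg = df.loc[~df["missing"], ["deaths", "population"]]
        if (neg["deaths"] < 0).any() or (df["population"] < 0).any():
            raise ValueError("negative death or population counts")
        self.data = df
        if areas is None:
            areas = list(dict.fromkeys(df["area_id"]))
        self.areas = tuple(areas)
        self.years = tuple(sorted(df["year"].unique()))
        self.strata = [tuple(s) for s in
                       df[["gender", "age_group"]].drop_duplicates().itertuples(index=False)]

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def copy(self) -> "StudyPanel":
        return StudyPanel(self.data.copy(), areas=self.areas)

    # -- CSV round-trip ----------------------------------------------------

    @classmethod
    def from_csv(cls, path_or_buf) -> "StudyPanel":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls(df)

    def to_csv(self, path_or_buf, header_comments: Sequence[str] = ()) -> None:
        """Write the panel; missing deaths become empty fields."""
        out = self.data.copy()
        out["deaths"] = out["deaths"].where(~out["missing"]).astype("Int64")
        out = out[PANEL_COLUMNS]

        def _write(f: IO[str]):
            for line in header_comments:
                f.write(f"# {line}\n")
            out.to_csv(f, index=False)

        if hasattr(path_or_buf, "write"):
            _write(path_or_buf)
        else:
            with open(path_or_buf, "w") as f:
                _write(f)

    # -- pivoting ----------------------------------------------------------

    def stratum_data(self, gender: str, age_group: str) -> StratumData:
        sub = self.data[(self.data["gender"] == gender)
                        & (self.data["age_group"] == age_group)]
        if sub.empty:
            raise KeyError(f"stratum ({gender}, {age_group}) not in panel")
        aidx = {a: i for i, a in enumerate(self.areas)}
        yidx = {y: j for j, y in enumerate(self.years)}
        M, T = len(self.areas), len(self.years)
        deaths = np.zeros((M, T), dtype=np.int64)
        pop = np.zeros((M, T), dtype=np.int64)
        R = np.full(T, np.nan)
        observed = np.zeros((M, T), dtype=bool)
        ii = sub["area_id"].map(aidx).to_numpy()
        jj = sub["year"].map(yidx).to_numpy()
        obs = ~sub["missing"].to_numpy()
        d = sub["deaths"].to_numpy()
        deaths[ii[obs], jj[obs]] = d[obs].astype(np.int64)
        pop[ii, jj] = sub["population"].to_numpy().astype(np.int64)
        observed[ii[obs], jj[obs]] = True
        rr = sub["reference_rate"].to_numpy(dtype=float)
        for j, r in zip(jj, rr):
            if np.isnan(R[j]):
                R[j] = r
            elif not np.isclose(R[j], r, rtol=1e-9, atol=0):
                raise ValueError(
                    f"reference rate varies across areas within year index {j}")
        if np.isnan(R).any():
            raise ValueError("missing reference rates for some years")
        if (R <= 0).any():
            raise ValueError("reference rates must be positive")
        return StratumData(gender=gender, age_group=age_group,
                           areas=self.areas, years=np.array(self.years),
                           deaths=deaths, population=pop, reference_rate=R,
                           observed=observed)

    def with_missing(self, missing: pd.Series) -> "StudyPanel":
        """Return a copy with an updated missingness column (index-aligned)."""
        df = self.data.copy()
        df["missing"] = missing.astype(bool)
        return StudyPanel(df, areas=self.areas)


# ---------------------------------------------------------------------------
# Model specification and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Parameterization of one model variant.

    Attributes
    ----------
    variant
        ``"rate"`` (offset = population) or ``"rate_ratio"``
        (offset = population x reference rate, i.e. expected deaths).
    time_degree
        Degree of the global polynomial time trend (default 2: quadratic
        captures most mortality trends; higher degrees are for DIC tests).
    time_center, time_scale
        Year transform ``t' = (year - center)/scale``.  ``None`` means
        resolve from the panel: center = mid-period, scale = half-range,
        so ``t'`` spans [-1, 1].
    include_spatial, include_differential
        Switch off S/H or delta for reduced models (e.g. oracle toys).
    delta_structure
        ``"car"`` (spatially structured differential trend, the default) or
        ``"iid"`` (exchangeable alternative).
    V_beta
        Prior variance of non-intercept coefficients (vague normal).  The
        intercept prior is improper flat.
    prior_tau_*
        Gamma (shape, rate) hyperpriors for the precisions.
    """

    variant: Literal["rate", "rate_ratio"] = "rate"
    time_degree: int = 2
    time_center: float | None = None
    time_scale: float | None = None
    include_spatial: bool = True
    include_differential: bool = True
    delta_structure: Literal["car", "iid"] = "car"
    V_beta: float = 1e5
    prior_tau_S: tuple[float, float] = (0.5, 0.0005)
    prior_tau_H: tuple[float, float] = (0.5, 0.0005)
    prior_tau_delta: tuple[float, float] = (0.5, 0.0005)

    def __post_init__(self):
        if self.time_degree < 0:
            raise ValueError("time_degree must be >= 0")
        if self.V_beta <= 0:
            raise ValueError("V_beta must be positive")
        for name in ("prior_tau_S", "prior_tau_H", "prior_tau_delta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must have positive shape and rate")
        if self.include_differential and self.time_degree < 1:
            raise ValueError("differential trend requires time_degree >= 1")

    def resolve_time(self, years: Sequence[int]) -> "ModelSpec":
        """Fill in the default time transform from the panel's year range."""
        years = np.asarray(years, dtype=float)
        center = self.time_center
        scale = self.time_scale
        if center is None:
            center = 0.5 * (years.min() + years.max())
        if scale is None:
            scale = 0.5 * (years.max() - years.min())
            if scale == 0:
                scale = 1.0  # single-year panel: t' = 0 everywhere
        if scale == 0:
            raise ValueError("time scale must be nonzero")
        return dataclasses.replace(self, time_center=center, time_scale=scale)

    @property
    def n_beta(self) -> int:
        return self.time_degree + 1


@dataclass
class ModelState:
    """A point in parameter space: coefficients, fields, precisions."""

    beta: np.ndarray
    S: np.ndarray | None = None
    H: np.ndarray | None = None
    delta: np.ndarray | None = None
    tau_S: float = 1.0
    tau_H: float = 1.0
    tau_delta: float = 1.0

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(),
            S=None if self.S is None else self.S.copy(),
            H=None if self.H is None else self.H.copy(),
            delta=None if self.delta is None else self.delta.copy(),
            tau_S=self.tau_S, tau_H=self.tau_H, tau_delta=self.tau_delta)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def time_index(year: float, spec: ModelSpec) -> float:
    """Transformed time t' = (year - center)/scale.

    The spec must have a resolved transform (see ``ModelSpec.resolve_time``).
    """
    if spec.time_center is None or spec.time_scale is None:
        raise ValueError("time transform unresolved; call spec.resolve_time(years)")
    if spec.time_scale == 0:
        raise ValueError("time scale must be nonzero")
    return (year - spec.time_center) / spec.time_scale


def tstar_grid(years: Sequence[int], spec: ModelSpec) -> np.ndarray:
    return np.array([time_index(y, spec) for y in np.asarray(years, dtype=float)])


def linear_predictor(state: ModelState, area: int, tstar: float,
                     spec: ModelSpec) -> float:
    """eta = sum_k beta_k t'^k + S_m + H_m + delta_m t' for one cell."""
    if len(state.beta) != spec.n_beta:
        raise ValueError("beta length inconsistent with time_degree")
    eta = float(np.polyval(state.beta[::-1], tstar))
    if state.S is not None:
        eta += state.S[area]
    if state.H is not None:
        eta += state.H[area]
    if state.delta is not None:
        eta += state.delta[area] * tstar
    return eta


def eta_matrix(state: ModelState, tstar: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Linear predictor for all areas x years at once."""
    if len(state.beta) != spec.n_beta:
        raise ValueError("beta length inconsistent with time_degree")
    tp = np.vstack([tstar ** k for k in range(spec.n_beta)])  # (K+1, T)
    eta = (state.beta @ tp)[None, :]
    M = None
    for f in (state.S, state.H, state.delta):
        if f is not None:
            M = len(f)
            break
    if M is None:
        return np.broadcast_to(eta, (1, len(tstar))).copy()
    eta = np.broadcast_to(eta, (M, len(tstar))).copy()
    if state.S is not None:
        eta += state.S[:, None]
    if state.H is not None:
        eta += state.H[:, None]
    if state.delta is not None:
        eta += state.delta[:, None] * tstar[None, :]
    return eta


def cell_mean(state: ModelState, cell: tuple[int, int], sdata: StratumData,
              spec: ModelSpec) -> float:
    """Poisson mean mu for one (area index, year index) cell.

    rate variant: mu = p * exp(eta); rate_ratio: mu = p * R * exp(eta).
    """
    m, t = cell
    if not sdata.observed[m, t]:
        raise ValueError(f"cell ({m},{t}) is missing; no model mean is defined")
    ts = time_index(float(sdata.years[t]), spec)
    eta = linear_predictor(state, m, ts, spec)
    off = float(sdata.offset(spec.variant)[m, t])
    return off * float(np.exp(eta))


def _masked_arrays(sdata: StratumData, spec: ModelSpec):
    """O and offset with zeros at missing cells, so masked sums are plain sums."""
    O = sdata.deaths.astype(float).copy()
    off = sdata.offset(spec.variant).copy()
    O[~sdata.observed] = 0.0
    off[~sdata.observed] = 0.0
    return O, off


def poisson_loglik(state: ModelState, sdata: StratumData, spec: ModelSpec) -> float:
    """Sum over non-missing cells of O log(mu) - mu, Stirling constant dropped.

    Returns -inf (a validly rejected state) when mu = 0 with O > 0 on an
    observed cell; raises :class:`NumericalError` on NaN/overflow.
    """
    spec = spec.resolve_time(sdata.years)
    ts = tstar_grid(sdata.years, spec)
    eta = eta_matrix(state, ts, spec)
    O, off = _masked_arrays(sdata, spec)
    if eta.shape[0] == 1 and O.shape[0] > 1:
        eta = np.broadcast_to(eta, O.shape)
    mu = off * np.exp(eta)
    obs = sdata.observed
    bad = obs & (mu == 0) & (sdata.deaths > 0)
    if bad.any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(O > 0, O * np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    val = float(term.sum() - mu.sum())
    if np.isnan(val):
        raise NumericalError("NaN in Poisson log likelihood")
    if np.isinf(mu.sum()):
        raise NumericalError("overflow in Poisson mean")
    return val


def _gamma_log_kernel(tau: float, a: float, b: float) -> float:
    if tau <= 0:
        return -np.inf
    return (a - 1.0) * np.log(tau) - b * tau


def log_prior(state: ModelState, graph: AdjacencyGraph, spec: ModelSpec) -> float:
    """All prior kernels: CAR(S), CAR-or-iid(delta), normal(H), normal(beta),
    gamma(precisions); flat intercept contributes nothing."""
    lp = 0.0
    if spec.include_spatial:
        lp += car_log_kernel(state.S, state.tau_S, graph)
        n = graph.n_areas
        lp += 0.5 * n * np.log(state.tau_H) - 0.5 * state.tau_H * float(state.H @ state.H)
        lp += _gamma_log_kernel(state.tau_S, *spec.prior_tau_S)
        lp += _gamma_log_kernel(state.tau_H, *spec.prior_tau_H)
    if spec.include_differential:
        if spec.delta_structure == "car":
            lp += car_log_kernel(state.delta, state.tau_delta, graph)
        else:
            n = graph.n_areas
            lp += (0.5 * n * np.log(state.tau_delta)
                   - 0.5 * state.tau_delta * float(state.delta @ state.delta))
        lp += _gamma_log_kernel(state.tau_delta, *spec.prior_tau_delta)
    if spec.n_beta > 1:
        lp += float(-(state.beta[1:] @ state.beta[1:]) / (2.0 * spec.V_beta))
    return lp


def log_posterior(state: ModelState, sdata: StratumData, graph: AdjacencyGraph,
                  spec: ModelSpec) -> float:
    """Unnormalized log posterior: Poisson likelihood + prior kernels."""
    ll = poisson_loglik(state, sdata, spec)
    if ll == -np.inf:
        return -np.inf
    return ll + log_prior(state, graph, spec)


def deviance(state: ModelState, sdata: StratumData, spec: ModelSpec) -> float:
    """D = -2 log L including the Stirling constant (for DIC)."""
    spec = spec.resolve_time(sdata.years)
    ts = tstar_grid(sdata.years, spec)
    eta = eta_matrix(state, ts, spec)
    O, off = _masked_arrays(sdata, spec)
    if eta.shape[0] == 1 and O.shape[0] > 1:
        eta = np.broadcast_to(eta, O.shape)
    mu = off * np.exp(eta)
    obs = sdata.observed
    with np.errstate(divide="ignore"):
        logmu = np.where(obs & (mu > 0), np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    ll = float((O * logmu).sum() - mu.sum() - gammaln(O[obs] + 1.0).sum())
    return -2.0 * ll
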