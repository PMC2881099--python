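"""Metropolis-within-Gibbs sampler, convergence diagnostics and DIC.

The sampler is a single-site random-walk Metropolis scheme with conjugate
Gibbs draws for the precisions, chosen over blocked or gradient-based
alternatives for transparency and testability.  One sweep updates, in a
fixed order: the polynomial coefficients, the structured field S, the
heterogeneity field H, the differential-trend field delta, the three
precisions, and finally re-centers the improper CAR fields (folding the
removed means into beta0/beta1 so the linear predictor is untouched).

Within S and delta the areas are partitioned into graph-coloring classes
(independent sets of the adjacency graph).  All areas of one class are
proposed and accepted/rejected simultaneously: given the rest of the
state, their full conditionals are mutually independent — the CAR prior
couples only neighbors and the likelihood only the area's own cells — so
the vectorized block is exactly a sequence of single-site Metropolis
updates.  H needs no coloring (no cross-area coupling at all).

Proposal scales adapt multiplicatively toward a 20-50% acceptance band
during burn-in only, and are frozen afterwards so the stationary law is
untouched.  Two (or more) chains start from overdispersed points and are
compared with the Brooks-Gelman corrected potential scale reduction
factor; model choice uses DIC = Dbar + pD with pD = Dbar - Dhat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from scipy.special import gammaln

from . import model as _model
from .model import ModelSpec, ModelState, StratumData
from .spatial_graph import AdjacencyGraph, car_pairwise_quadratic

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig", "PosteriorSamples", "GelmanRubinResult", "DICResult",
    "gibbs_update_precision", "mh_update_scalar", "center_constraints",
    "run_mcmc", "gelman_rubin", "convergence_report", "dic",
]


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults follow common small-area practice: 1000 burn-in iterations and
    10,000 retained updates on each of two chains.  ``chain_seeds`` may pin
    per-chain seeds explicitly (e.g. to demonstrate bitwise determinism);
    otherwise they derive from ``seed``.
    """

    n_chains: int = 2
    burn_in: int = 1000
    n_keep: int = 10000
    thin: int = 1
    seed: int = 0
    chain_seeds: Sequence[int] | None = None
    target_accept: tuple[float, float] = (0.2, 0.5)
    tune_interval: int = 50
    init_effect_sd: float = 0.1
    chain_dispersion: float = 0.2
    refresh_interval: int = 200   # exact eta/mu recomputation cadence

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in < 0 or self.n_keep < 1 or self.thin < 1:
            raise ValueError("invalid iteration counts")


@dataclass
class PosteriorSamples:
    """Multi-chain posterior draws plus per-iteration deviance.

    Arrays are shaped (chains, draws, ...).  Stored draws are on the
    identified, centered scale.  ``acceptance`` maps block names to
    post-burn-in acceptance rates.
    """

    beta: np.ndarray
    tau_S: np.ndarray | None
    tau_H: np.ndarray | None
    tau_delta: np.ndarray | None
    S: np.ndarray | None
    H: np.ndarray | None
    delta: np.ndarray | None
    deviance: np.ndarray
    spec: ModelSpec
    years: np.ndarray
    tstar: np.ndarray
    areas: tuple
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def scalar_addresses(self) -> list[str]:
        out = [f"beta{k}" for k in range(self.beta.shape[2])]
        for name in ("tau_S", "tau_H", "tau_delta"):
            if getattr(self, name) is not None:
                out.append(name)
        out.append("deviance")
        return out

    def extract(self, address: str) -> np.ndarray:
        """Draws for one parameter address, shaped (chains, draws).

        Addresses: ``beta0..betaK``, ``tau_S``, ``tau_H``, ``tau_delta``,
        ``deviance``, ``S[i]``, ``H[i]``, ``delta[i]``.
        """
        if address.startswith("beta"):
            k = int(address[4:])
            return self.beta[:, :, k]
        if address in ("tau_S", "tau_H", "tau_delta", "deviance"):
            arr = getattr(self, address)
            if arr is None:
                raise KeyError(f"{address} not sampled in this model")
            return arr
        if "[" in address and address.endswith("]"):
            name, idx = address[:-1].split("[")
            arr = getattr(self, name, None)
            if arr is None:
                raise KeyError(f"{name} not sampled in this model")
            return arr[:, :, int(idx)]
        raise KeyError(f"unknown parameter address {address!r}")

    def flat(self, address: str) -> np.ndarray:
        """All chains pooled into one draw vector."""
        return self.extract(address).reshape(-1)

    def mean_state(self) -> ModelState:
        """Posterior mean of every parameter (on the centered scale)."""
        def m(a):
            return None if a is None else a.mean(axis=(0, 1))
        return ModelState(
            beta=self.beta.mean(axis=(0, 1)),
            S=m(self.S), H=m(self.H), delta=m(self.delta),
            tau_S=float(self.tau_S.mean()) if self.tau_S is not None else 1.0,
            tau_H=float(self.tau_H.mean()) if self.tau_H is not None else 1.0,
            tau_delta=(float(self.tau_delta.mean())
                       if self.tau_delta is not None else 1.0))

    def eta_draws(self, year: int) -> np.ndarray:
        """Linear-predictor draws for one calendar year, (total draws, areas).

        exp of these is the specific rate (rate variant) or the rate ratio
        (rate_ratio variant).
        """
        t = float(_model.time_index(year, self.spec))
        C, D, K = self.beta.shape
        tp = np.array([t ** k for k in range(K)])
        eta = (self.beta.reshape(C * D, K) @ tp)[:, None]
        M = len(self.areas)
        eta = np.broadcast_to(eta, (C * D, M)).copy()
        if self.S is not None:
            eta += self.S.reshape(C * D, M)
        if self.H is not None:
            eta += self.H.reshape(C * D, M)
        if self.delta is not None:
            eta += self.delta.reshape(C * D, M) * t
        return eta

    def to_inference_data(self):
        """Export to an ArviZ InferenceData (self-describing container)."""
        import arviz as az
        posterior = {"beta": self.beta}
        for name in ("S", "H", "delta"):
            if getattr(self, name) is not None:
                posterior[name] = getattr(self, name)
        for name in ("tau_S", "tau_H", "tau_delta"):
            if getattr(self, name) is not None:
                posterior[name] = getattr(self, name)
        return az.from_dict(posterior=posterior,
                            sample_stats={"deviance": self.deviance})

    def save(self, path) -> None:
        arrays = {k: getattr(self, k) for k in
                  ("beta", "tau_S", "tau_H", "tau_delta", "S", "H", "delta",
                   "deviance") if getattr(self, k) is not None}
        arrays["years"] = self.years
        arrays["tstar"] = self.tstar
        np.savez_compressed(path, **arrays)


# ---------------------------------------------------------------------------
# Elementary updates (public, tested against closed forms)
# ---------------------------------------------------------------------------


def gibbs_update_precision(effects: np.ndarray, kind: str,
                           graph: AdjacencyGraph | None,
                           a: float, b: float,
                           rng: np.random.Generator) -> float:
    """Conjugate gamma draw for a field precision.

    car kind:  tau ~ Gamma(a + (n - c)/2, b + q/2) with q the pairwise CAR
    quadratic form; iid kind: tau ~ Gamma(a + n/2, b + sum(phi^2)/2).
    """
    if a <= 0 or b <= 0:
        raise ValueError("gamma prior parameters must be positive")
    phi = np.asarray(effects, dtype=float)
    if kind == "car":
        if graph is None:
            raise ValueError("car kind requires a graph")
        shape = a + 0.5 * (graph.n_areas - graph.n_components)
        rate = b + 0.5 * car_pairwise_quadratic(phi, graph)
    elif kind == "iid":
        shape = a + 0.5 * phi.size
        rate = b + 0.5 * float(phi @ phi)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(rng.gamma(shape, 1.0 / rate))


def mh_update_scalar(state: ModelState, which: str, sdata: StratumData,
                     graph: AdjacencyGraph, spec: ModelSpec,
                     proposal_scale: float, rng: np.random.Generator
                     ) -> tuple[ModelState, bool]:
    """One symmetric random-walk Metropolis update of a single parameter.

    ``which`` addresses a coefficient (``beta0``..) or one component of a
    field (``S[3]``, ``H[0]``, ``delta[7]``).  Acceptance probability is
    min(1, exp(delta log posterior)); a non-finite increment is rejected.
    This is the reference single-site kernel; :func:`run_mcmc` applies the
    same kernel vectorized over graph-coloring classes.
    """
    eps = float(rng.normal(0.0, proposal_scale))
    prop = state.copy()
    if which.startswith("beta"):
        prop.beta[int(which[4:])] += eps
    elif "[" in which:
        name, idx = which[:-1].split("[")
        getattr(prop, name)[int(idx)] += eps
    else:
        raise ValueError(f"cannot address {which!r} with a Metropolis step")
    with np.errstate(over="ignore"):
        try:
            d = (_model.log_posterior(prop, sdata, graph, spec)
                 - _model.log_posterior(state, sdata, graph, spec))
        except _model.NumericalError:
            logger.warning("non-finite posterior increment at %s; rejected", which)
            return state, False
    if not np.isfinite(d) and d != -np.inf:
        logger.warning("non-finite posterior increment at %s; rejected", which)
        return state, False
    if np.log(rng.uniform()) < d:
        return prop, True
    return state, False


def center_constraints(state: ModelState, graph: AdjacencyGraph) -> ModelState:
    """Enforce per-component sum-to-zero on the CAR fields.

    Per connected component the mean of S is subtracted (and of delta, when
    present); the global mean is folded into beta0 (respectively beta1), so
    for a connected graph the linear predictor is unchanged to rounding.
    For multi-component graphs the per-component means are still forced to
    zero and beta0 absorbs only their common (global) part — a constraint
    enforcement rather than an exact reparameterization.
    """
    out = state.copy()
    if out.S is not None:
        mean_all = float(out.S.mean())
        out.S = graph.center_by_component(out.S)
        out.beta[0] += mean_all
    if out.delta is not None:
        if len(out.beta) < 2:
            raise ValueError("delta requires a linear time coefficient to absorb")
        mean_all = float(out.delta.mean())
        out.delta = graph.center_by_component(out.delta)
        out.beta[1] += mean_all
    return out


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _Precomp:
    """Immutable per-fit arrays shared by all chains."""

    def __init__(self, sdata: StratumData, graph: AdjacencyGraph, spec: ModelSpec):
        spec = spec.resolve_time(sdata.years)
        self.spec = spec
        self.graph = graph
        self.sdata = sdata
        self.M = sdata.n_areas
        self.T = sdata.n_years
        if graph.n_areas != self.M:
            raise ValueError("graph size does not match panel areas")
        self.tstar = _model.tstar_grid(sdata.years, spec)
        K = spec.n_beta
        self.Tpow = np.vstack([self.tstar ** k for k in range(K)])

        obs = sdata.observed.copy()
        if not obs.any():
            raise ValueError("all cells missing; nothing to fit")
        O = sdata.deaths.astype(float).copy()
        off = sdata.offset(spec.variant).copy()
        zero_off = obs & (off == 0)
        if (zero_off & (O > 0)).any():
            raise ValueError(
                "observed cell with zero offset but positive deaths; "
                "run the cleaning rules first")
        if zero_off.any():
            warnings.warn("cells with zero population treated as missing")
            obs[zero_off] = False
        O[~obs] = 0.0
        off[~obs] = 0.0
        self.obs = obs
        self.O = O
        self.offset = off
        with np.errstate(divide="ignore"):
            logoff = np.where(obs & (off > 0), np.log(np.where(off > 0, off, 1.0)), 0.0)
        self.dev_const = float((O * logoff).sum() - gammaln(O[obs] + 1.0).sum())
        self.rowO = O.sum(axis=1)
        self.colO = O.sum(axis=0)
        self.SOt = self.Tpow @ self.colO          # (K,)
        self.rowOt = (O * self.tstar[None, :]).sum(axis=1)

        self.A = graph.adjacency_matrix()
        self.deg = graph.degree.astype(float)
        need_colors = spec.include_spatial or (
            spec.include_differential and spec.delta_structure == "car")
        if need_colors and graph.edges:
            G = nx.Graph()
            G.add_nodes_from(range(graph.n_areas))
            G.add_edges_from(graph.edges)
            coloring = nx.greedy_color(G, strategy="largest_first")
            ncol = max(coloring.values()) + 1
            self.colors = [np.array([i for i, c in coloring.items() if c == k],
                                    dtype=np.intp) for k in range(ncol)]
        else:
            self.colors = [np.arange(graph.n_areas, dtype=np.intp)]


class _ChainState:
    """Mutable chain state with maintained eta and mu matrices."""

    def __init__(self, pre: _Precomp, state: ModelState):
        self.pre = pre
        self.state = state
        self.refresh()

    def refresh(self):
        st, pre = self.state, self.pre
        eta = (st.beta @ pre.Tpow)[None, :]
        eta = np.broadcast_to(eta, (pre.M, pre.T)).copy()
        if st.S is not None:
            eta += st.S[:, None]
        if st.H is not None:
            eta += st.H[:, None]
        if st.delta is not None:
            eta += st.delta[:, None] * pre.tstar[None, :]
        self.eta = eta
        self.mu = pre.offset * np.exp(eta)

    def loglik(self) -> float:
        return float((self.pre.O * self.eta).sum() - self.mu.sum()
                     + self.pre.dev_const)

    def deviance(self) -> float:
        return -2.0 * self.loglik()


def _init_state(pre: _Precomp, spec: ModelSpec, config: MCMCConfig,
                chain: int, rng: np.random.Generator) -> ModelState:
    total_O = pre.O.sum()
    total_off = pre.offset.sum()
    b0 = float(np.log((total_O + 0.5) / total_off))
    sd = config.init_effect_sd
    for _attempt in range(5):
        beta = np.zeros(spec.n_beta)
        beta[0] = b0 + config.chain_dispersion * chain
        M = pre.M
        S = H = delta = None
        if spec.include_spatial:
            S = pre.graph.center_by_component(rng.normal(0.0, sd, size=M))
            H = rng.normal(0.0, sd, size=M)
        if spec.include_differential:
            delta = rng.normal(0.0, sd, size=M)
            if spec.delta_structure == "car":
                delta = pre.graph.center_by_component(delta)
        pm = lambda ab: ab[0] / ab[1]
        st = ModelState(beta=beta, S=S, H=H, delta=delta,
                        tau_S=pm(spec.prior_tau_S), tau_H=pm(spec.prior_tau_H),
                        tau_delta=pm(spec.prior_tau_delta))
        cs = _ChainState(pre, st)
        if np.isfinite(cs.loglik()):
            return st
        sd *= 0.5
    raise RuntimeError("could not find a finite starting point")


def _adapt(scale: np.ndarray, acc: np.ndarray, att: np.ndarray,
           lo: float, hi: float) -> None:
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(att > 0, acc / np.maximum(att, 1), 0.35)
    scale *= np.where(rate < lo, 0.7, np.where(rate > hi, 1.4, 1.0))
    np.clip(scale, 1e-4, 20.0, out=scale)
    acc[:] = 0
    att[:] = 0


def _run_chain(pre: _Precomp, config: MCMCConfig, chain: int, seed) -> dict:
    rng = np.random.default_rng(seed)
    spec = pre.spec
    K = spec.n_beta
    M, T = pre.M, pre.T
    st = _init_state(pre, spec, config, chain, rng)
    cs = _ChainState(pre, st)
    lo, hi = config.target_accept

    scale_beta = np.full(K, 0.02)
    scale_S = np.full(M, 0.5)
    scale_H = np.full(M, 0.5)
    scale_delta = np.full(M, 0.5)
    acc_beta = np.zeros(K); att_beta = np.zeros(K)
    acc_S = np.zeros(M); att_S = np.zeros(M)
    acc_H = np.zeros(M); att_H = np.zeros(M)
    acc_d = np.zeros(M); att_d = np.zeros(M)
    post_acc = {"beta": np.zeros(K), "beta_att": np.zeros(K),
                "S": np.zeros(M), "S_att": np.zeros(M),
                "H": np.zeros(M), "H_att": np.zeros(M),
                "delta": np.zeros(M), "delta_att": np.zeros(M)}
    n_rejected_nonfinite = 0

    n_total = config.burn_in + config.n_keep * config.thin
    out_beta = np.empty((config.n_keep, K))
    out_tauS = np.empty(config.n_keep) if spec.include_spatial else None
    out_tauH = np.empty(config.n_keep) if spec.include_spatial else None
    out_taud = np.empty(config.n_keep) if spec.include_differential else None
    out_S = np.empty((config.n_keep, M)) if spec.include_spatial else None
    out_H = np.empty((config.n_keep, M)) if spec.include_spatial else None
    out_d = np.empty((config.n_keep, M)) if spec.include_differential else None
    out_dev = np.empty(config.n_keep)

    aS, bS = spec.prior_tau_S
    aH, bH = spec.prior_tau_H
    ad, bd = spec.prior_tau_delta
    kept = 0

    def _split_moves():
        """Likelihood-invariant moves on the S/H decomposition.

        (a) Exact Gibbs interchange (S_m + c, H_m - c) per coloring class:
        the likelihood sees only S + H, so the split's full conditional is
        Gaussian, resolved by the priors alone.  (b) Global rescale
        H' = r H, S' = S + (1 - r) H (Jacobian r^M), a Metropolis move
        along the slow "funnel" direction of the variance decomposition
        that single-site moves cross only by long excursions.  Both leave
        eta and mu untouched.
        """
        for idx in pre.colors:
            AS = pre.A @ st.S
            prec = st.tau_S * pre.deg[idx] + st.tau_H
            mean = (st.tau_H * st.H[idx]
                    - st.tau_S * (pre.deg[idx] * st.S[idx] - AS[idx])) / prec
            c = mean + rng.normal(size=len(idx)) / np.sqrt(prec)
            st.S[idx] += c
            st.H[idx] -= c
        ei, ej = pre.graph.edge_arrays
        for sig in (0.1, 0.3, 0.6):
            r = float(np.exp(rng.normal(0.0, sig)))
            Sp = st.S + (1.0 - r) * st.H
            dq = float(((Sp[ei] - Sp[ej]) ** 2).sum()
                       - ((st.S[ei] - st.S[ej]) ** 2).sum())
            Hss = float(st.H @ st.H)
            d = (-0.5 * st.tau_S * dq
                 - 0.5 * st.tau_H * (r * r - 1.0) * Hss
                 + M * np.log(r))
            if np.isfinite(d) and np.log(rng.uniform()) < d:
                st.S = Sp
                st.H = r * st.H

    def _precision_gibbs():
        if spec.include_spatial:
            st.tau_S = gibbs_update_precision(st.S, "car", pre.graph, aS, bS, rng)
            st.tau_H = gibbs_update_precision(st.H, "iid", None, aH, bH, rng)
        if spec.include_differential:
            kind = "car" if spec.delta_structure == "car" else "iid"
            st.tau_delta = gibbs_update_precision(
                st.delta, kind, pre.graph if kind == "car" else None, ad, bd, rng)

    for it in range(n_total):
        tuning = it < config.burn_in

        # ---- polynomial coefficients (scalar MH, sufficient column sums)
        for k in range(K):
            eps = rng.normal(0.0, scale_beta[k])
            cmu = cs.mu.sum(axis=0)
            with np.errstate(over="ignore"):
                grow = np.expm1(eps * pre.Tpow[k])
                d = eps * pre.SOt[k] - float(cmu @ grow)
            if k >= 1:
                b = st.beta[k]
                d += -((b + eps) ** 2 - b ** 2) / (2.0 * spec.V_beta)
            att_beta[k] += 1
            if not tuning:
                post_acc["beta_att"][k] += 1
            if not np.isfinite(d):
                n_rejected_nonfinite += 1
            elif np.log(rng.uniform()) < d:
                st.beta[k] += eps
                cs.eta += eps * pre.Tpow[k][None, :]
                cs.mu *= np.exp(eps * pre.Tpow[k])[None, :]
                acc_beta[k] += 1
                if not tuning:
                    post_acc["beta"][k] += 1

        # ---- structured spatial field S (color-blocked single-site MH)
        if spec.include_spatial:
            for idx in pre.colors:
                eps = rng.normal(0.0, scale_S[idx])
                rowmu = cs.mu[idx].sum(axis=1)
                with np.errstate(over="ignore"):
                    dlik = eps * pre.rowO[idx] - np.expm1(eps) * rowmu
                AS = pre.A @ st.S
                dpri = -0.5 * st.tau_S * (pre.deg[idx] * eps ** 2
                                          + 2.0 * eps * (pre.deg[idx] * st.S[idx]
                                                         - AS[idx]))
                d = dlik + dpri
                finite = np.isfinite(d)
                n_rejected_nonfinite += int((~finite).sum())
                acc = finite & (np.log(rng.uniform(size=len(idx))) < d)
                att_S[idx] += 1
                acc_S[idx[acc]] += 1
                if not tuning:
                    post_acc["S_att"][idx] += 1
                    post_acc["S"][idx[acc]] += 1
                sel = idx[acc]
                if len(sel):
                    e = eps[acc]
                    st.S[sel] += e
                    cs.eta[sel] += e[:, None]
                    cs.mu[sel] *= np.exp(e)[:, None]

            # ---- heterogeneity field H (no coupling: one vectorized block)
            idx = np.arange(M)
            eps = rng.normal(0.0, scale_H)
            rowmu = cs.mu.sum(axis=1)
            with np.errstate(over="ignore"):
                dlik = eps * pre.rowO - np.expm1(eps) * rowmu
            dpri = -0.5 * st.tau_H * (2.0 * st.H * eps + eps ** 2)
            d = dlik + dpri
            finite = np.isfinite(d)
            n_rejected_nonfinite += int((~finite).sum())
            acc = finite & (np.log(rng.uniform(size=M)) < d)
            att_H += 1
            acc_H[acc] += 1
            if not tuning:
                post_acc["H_att"] += 1
                post_acc["H"][acc] += 1
            sel = idx[acc]
            if len(sel):
                e = eps[acc]
                st.H[sel] += e
                cs.eta[sel] += e[:, None]
                cs.mu[sel] *= np.exp(e)[:, None]

        # ---- differential trend delta
        if spec.include_differential:
            car_delta = spec.delta_structure == "car"
            blocks = pre.colors if car_delta else [np.arange(M, dtype=np.intp)]
            for idx in blocks:
                eps = rng.normal(0.0, scale_delta[idx])
                with np.errstate(over="ignore"):
                    E = np.expm1(np.outer(eps, pre.tstar))
                    dlik = eps * pre.rowOt[idx] - (cs.mu[idx] * E).sum(axis=1)
                if car_delta:
                    Ad = pre.A @ st.delta
                    dpri = -0.5 * st.tau_delta * (
                        pre.deg[idx] * eps ** 2
                        + 2.0 * eps * (pre.deg[idx] * st.delta[idx] - Ad[idx]))
                else:
                    dpri = -0.5 * st.tau_delta * (2.0 * st.delta[idx] * eps
                                                  + eps ** 2)
                d = dlik + dpri
                finite = np.isfinite(d)
                n_rejected_nonfinite += int((~finite).sum())
                acc = finite & (np.log(rng.uniform(size=len(idx))) < d)
                att_d[idx] += 1
                acc_d[idx[acc]] += 1
                if not tuning:
                    post_acc["delta_att"][idx] += 1
                    post_acc["delta"][idx[acc]] += 1
                sel = idx[acc]
                if len(sel):
                    e = eps[acc]
                    st.delta[sel] += e
                    cs.eta[sel] += np.outer(e, pre.tstar)
                    cs.mu[sel] *= np.exp(np.outer(e, pre.tstar))

        # ---- precisions (conjugate Gibbs), interleaved with the
        #      likelihood-invariant S/H decomposition moves: two rounds per
        #      sweep roughly double the effective sample size of the
        #      precision chains at negligible cost.
        _precision_gibbs()
        if spec.include_spatial:
            _split_moves()
            _precision_gibbs()
            _split_moves()
            _precision_gibbs()

        # ---- centering (fold means into beta0/beta1; eta untouched when
        #      the graph is connected, else recompute)
        multi = pre.graph.n_components > 1
        if spec.include_spatial:
            if multi:
                g = float(st.S.mean())
                st.S = pre.graph.center_by_component(st.S)
                st.beta[0] += g
            else:
                mS = float(st.S.mean())
                st.S -= mS
                st.beta[0] += mS
        if spec.include_differential and spec.delta_structure == "car":
            if multi:
                g = float(st.delta.mean())
                st.delta = pre.graph.center_by_component(st.delta)
                st.beta[1] += g
            else:
                md = float(st.delta.mean())
                st.delta -= md
                st.beta[1] += md
        if multi:
            cs.refresh()

        if tuning and (it + 1) % config.tune_interval == 0:
            _adapt(scale_beta, acc_beta, att_beta, lo, hi)
            _adapt(scale_S, acc_S, att_S, lo, hi)
            _adapt(scale_H, acc_H, att_H, lo, hi)
            _adapt(scale_delta, acc_d, att_d, lo, hi)

        if (it + 1) % config.refresh_interval == 0:
            cs.refresh()

        if not tuning and (it - config.burn_in) % config.thin == 0:
            out_beta[kept] = st.beta
            if spec.include_spatial:
                out_S[kept] = st.S
                out_H[kept] = st.H
                out_tauS[kept] = st.tau_S
                out_tauH[kept] = st.tau_H
            if spec.include_differential:
                out_d[kept] = st.delta
                out_taud[kept] = st.tau_delta
            out_dev[kept] = cs.deviance()
            kept += 1

    if n_rejected_nonfinite:
        logger.warning("%d proposals rejected for non-finite increments",
                       n_rejected_nonfinite)

    def rate(a, att):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(att > 0, a / np.maximum(att, 1), np.nan)

    return {
        "beta": out_beta, "S": out_S, "H": out_H, "delta": out_d,
        "tau_S": out_tauS, "tau_H": out_tauH, "tau_delta": out_taud,
        "deviance": out_dev,
        "acceptance": {
            "beta": rate(post_acc["beta"], post_acc["beta_att"]),
            "S": rate(post_acc["S"], post_acc["S_att"]),
            "H": rate(post_acc["H"], post_acc["H_att"]),
            "delta": rate(post_acc["delta"], post_acc["delta_att"]),
        },
    }


def run_mcmc(sdata: StratumData, graph: AdjacencyGraph, spec: ModelSpec,
             config: MCMCConfig) -> PosteriorSamples:
    """Fit one model variant to one stratum by Metropolis-within-Gibbs.

    Deterministic given the configured seeds.  Raises on an all-missing
    panel; an initialization failure after retries with shrinking
    dispersion is a hard error.
    """
    pre = _Precomp(sdata, graph, spec)
    spec = pre.spec
    if config.chain_seeds is not None:
        if len(config.chain_seeds) != config.n_chains:
            raise ValueError("chain_seeds length must equal n_chains")
        seeds = list(config.chain_seeds)
    else:
        seeds = [np.random.SeedSequence([config.seed, c])
                 for c in range(config.n_chains)]
    results = [_run_chain(pre, config, c, s) for c, s in enumerate(seeds)]

    def stack(name):
        if results[0][name] is None:
            return None
        return np.stack([r[name] for r in results])

    acceptance = {k: np.stack([r["acceptance"][k] for r in results])
                  for k in results[0]["acceptance"]}
    return PosteriorSamples(
        beta=stack("beta"), tau_S=stack("tau_S"), tau_H=stack("tau_H"),
        tau_delta=stack("tau_delta"), S=stack("S"), H=stack("H"),
        delta=stack("delta"), deviance=stack("deviance"),
        spec=spec, years=np.asarray(sdata.years), tstar=pre.tstar,
        areas=tuple(sdata.areas), acceptance=acceptance)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


@dataclass
class GelmanRubinResult:
    psrf: float             # uncorrected sqrt(Vhat/W)
    psrf_corrected: float   # with the df/(df-2) sampling-variability correction
    df: float


def _psrf(x: np.ndarray) -> GelmanRubinResult:
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 4:
        raise ValueError("chains too short")
    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = float(s2.mean())
    B = n * float(np.var(xbar, ddof=1))
    if W == 0.0:
        warnings.warn("within-chain variance is zero (constant chains); "
                      "PSRF reported as 1 by convention")
        return GelmanRubinResult(psrf=1.0, psrf_corrected=1.0, df=np.inf)
    Vhat = (n - 1) / n * W + (m + 1) / (m * n) * B
    ratio2 = Vhat / W

    # Gelman-Rubin (1992) moment-matched degrees of freedom of the t
    # approximation to the pooled posterior.
    mu = float(x.mean())
    var_s2 = float(np.var(s2, ddof=1))
    if m > 1:
        cov_s2_xb2 = float(np.cov(s2, xbar ** 2, ddof=1)[0, 1])
        cov_s2_xb = float(np.cov(s2, xbar, ddof=1)[0, 1])
    else:  # pragma: no cover
        cov_s2_xb2 = cov_s2_xb = 0.0
    var_V = (((n - 1) / n) ** 2 / m * var_s2
             + ((m + 1) / (m * n)) ** 2 * 2.0 / (m - 1) * B ** 2
             + 2.0 * (m + 1) * (n - 1) / (m * n ** 2)
             * (n / m) * (cov_s2_xb2 - 2.0 * mu * cov_s2_xb))
    df = 2.0 * Vhat ** 2 / var_V if var_V > 0 else np.inf
    corr = df / (df - 2.0) if df > 2.0 else np.nan
    psrf_c = float(np.sqrt(ratio2 * corr)) if np.isfinite(corr) else float(np.sqrt(ratio2))
    return GelmanRubinResult(psrf=float(np.sqrt(ratio2)), psrf_corrected=psrf_c,
                             df=float(df))


def gelman_rubin(samples: PosteriorSamples | np.ndarray,
                 address: str | None = None) -> GelmanRubinResult:
    """Brooks-Gelman corrected potential scale reduction factor.

    ``samples`` is either a PosteriorSamples (with a parameter ``address``)
    or a raw (chains, draws) array.  Constant chains report 1 with a
    warning.  Values near 1 indicate convergence; 1.1 is the conventional
    alarm threshold.
    """
    if isinstance(samples, PosteriorSamples):
        if address is None:
            raise ValueError("address required with PosteriorSamples input")
        x = samples.extract(address)
    else:
        x = np.asarray(samples)
    return _psrf(x)


def convergence_report(samples: PosteriorSamples,
                       addresses: Sequence[str] | None = None,
                       threshold: float = 1.1):
    """R-hat (corrected and raw) plus an ESS proxy per monitored parameter.

    Returns a DataFrame; any corrected R-hat above ``threshold`` is logged
    as a warning (never an error — an unconverged fit is a diagnosis, not
    a failure).
    """
    import pandas as pd
    import arviz as az
    if addresses is None:
        addresses = samples.scalar_addresses()
    rows = []
    for addr in addresses:
        x = samples.extract(addr)
        gr = _psrf(x)
        ess = float(az.ess(az.convert_to_dataset(x))["x"].values)
        rows.append({"parameter": addr, "rhat_corrected": gr.psrf_corrected,
                     "rhat": gr.psrf, "ess": ess})
        if gr.psrf_corrected > threshold:
            logger.warning("R-hat %.3f > %.2f for %s", gr.psrf_corrected,
                           threshold, addr)
    return pd.DataFrame(rows)


@dataclass
class DICResult:
    Dbar: float
    Dhat: float
    pD: float
    DIC: float


def dic(samples: PosteriorSamples, sdata: StratumData,
        spec: ModelSpec | None = None) -> DICResult:
    """Deviance information criterion from recorded per-iteration deviance.

    Dbar is the posterior mean deviance; Dhat the deviance at the posterior
    mean of all parameters (identified, centered scale); pD = Dbar - Dhat;
    DIC = Dbar + pD.
    """
    spec = samples.spec if spec is None else spec.resolve_time(sdata.years)
    Dbar = float(samples.deviance.mean())
    Dhat = float(_model.deviance(samples.mean_state(), sdata, spec))
    pD = Dbar - Dhat
    return DICResult(Dbar=Dbar, Dhat=Dhat, pD=pD, DIC=Dbar + pD)
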