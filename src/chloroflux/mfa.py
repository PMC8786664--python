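"""Desk-scale isotopically non-stationary metabolic flux analysis.

Estimates net fluxes (and optionally pool sizes and dilution fractions) of an
atom-transition network from transient mass-isotopomer measurements by
weighted least squares over the EMU forward model:

    SSR = sum over metabolites, times, mass channels of
          ((measured - predicted) / sd)^2

subject to steady-state mass balance.  The balance constraint is handled by
parameterizing fluxes through an orthonormal null-space basis of the
stoichiometric matrix (v = N @ theta), pools on a log scale, and dilutions on
[0, 1].  Non-negativity of fluxes is enforced softly through penalty
residuals, which keeps the problem smooth for the trust-region solver.

Measurement errors use the maximum replicate standard deviation over all mass
fractions of a metabolite at a time point, floored at ``min_sd`` (default
0.001).  Estimation restarts from ``restarts`` random initial parameter
vectors (default 50) and keeps the best sum of squared residuals.

Confidence intervals come in two flavours: fast linearized (Wald) intervals
from the Jacobian at the optimum, attached to every :class:`FitResult`, and
profile-likelihood intervals (:func:`confidence_intervals`) that re-optimize
all remaining parameters while stepping one flux or pool until the SSR rises
by the chi-square 95% increment for one parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.optimize import least_squares

from .emu import EMUSimulator, full_emu
from .network import AtomNetwork

__all__ = [
    "MeasuredMIDs",
    "FitResult",
    "FluxFitter",
    "fit",
    "chi2_verdict",
    "confidence_intervals",
]

_NEG_PENALTY = 1e4
_CHI2_1D_95 = float(stats.chi2.ppf(0.95, 1))


@dataclass
class MeasuredMIDs:
    """Measured MIDs with per-metabolite-and-time standard deviations.

    ``mids[met]`` is ``(T, n+1)``; ``sd[met]`` is ``(T,)`` (one error per
    metabolite and time point: the maximum over its mass channels).  ``mask``
    is a set of ``(metabolite, time)`` pairs excluded from fitting.
    """

    times: np.ndarray
    mids: dict
    sd: dict
    mask: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    @classmethod
    def from_table(cls, table: pd.DataFrame, min_sd: float = 0.001,
                   mask=None) -> "MeasuredMIDs":
        """Build from the tidy MID table format (replicates averaged;
        error = max over channels of the replicate s.d., floored)."""
        mcols = sorted((c for c in table.columns if c.startswith("m")
                        and c[1:].isdigit()), key=lambda c: int(c[1:]))
        times = np.array(sorted(table["time_s"].unique()))
        mids, sds = {}, {}
        for met, g in table.groupby("metabolite"):
            n = int(g["n_carbons"].iloc[0])
            cols = mcols[: n + 1]
            mean = g.groupby("time_s")[cols].mean().reindex(times)
            sd = g.groupby("time_s")[cols].std(ddof=1).reindex(times)
            mids[met] = mean.to_numpy()
            sds[met] = np.maximum(np.nan_to_num(sd.to_numpy()).max(axis=1),
                                  min_sd)
        return cls(times=times, mids=mids, sd=sds, mask=set(mask or ()))


@dataclass
class FitResult:
    """Best-fit parameters with goodness of fit and linearized 95% CI."""

    fluxes: dict
    pools: dict
    dilutions: dict
    ssr: float
    dof: int
    n_residuals: int
    n_params: int
    flux_ci: dict
    pool_ci: dict
    dilution_ci: dict
    n_restarts: int
    best_restart_seed: int
    theta: np.ndarray = field(repr=False, default=None)
    x_internal: np.ndarray = field(repr=False, default=None)
    nonidentifiable: list = field(default_factory=list)

    @property
    def chi2_accept(self) -> bool:
        return chi2_verdict(self) == "accept"


def chi2_verdict(fit: "FitResult", alpha: float = 0.05) -> str:
    """Two-sided chi-square goodness-of-fit verdict on the SSR.

    Accept iff SSR lies inside [chi2_{alpha/2, dof}, chi2_{1-alpha/2, dof}]
    (an SSR far below the lower bound indicates overfitting or overstated
    errors and is rejected too).
    """
    if fit.dof <= 0:
        raise ValueError("dof must be > 0")
    lo = stats.chi2.ppf(alpha / 2.0, fit.dof)
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, fit.dof)
    return "accept" if lo <= fit.ssr <= hi else "reject"


class FluxFitter:
    """Least-squares INST-MFA estimator over a fixed network structure."""

    def __init__(self, net: AtomNetwork, measured: MeasuredMIDs,
                 fit_pools: bool = True, fit_dilutions: bool = False,
                 min_sd: float = 0.001, dt: float = 0.1,
                 rate_measurements: dict | None = None,
                 pool_measurements: dict | None = None):
        self.net = net
        self.measured = measured
        # Absolute anchors {name: (value, sd)}.  Transient MIDs alone
        # determine fluxes only up to a common (v, P) scale when pools are
        # fitted; independently measured synthesis rates (starch, sucrose in
        # the study design) and measured pool sizes pin the scale and enter
        # the SSR as additional residuals.  Pools remain fitted parameters;
        # pool measurements act as lognormal error terms on them.
        self.rate_measurements = dict(rate_measurements or {})
        self.pool_measurements = dict(pool_measurements or {})
        self.fit_pools = fit_pools
        self.fit_dilutions = fit_dilutions
        self.dt = dt
        mets = sorted(measured.mids)
        unknown = [m for m in mets if m not in net.pools]
        if unknown:
            raise ValueError(f"measured metabolites not in network: {unknown}")
        self.measured_mets = mets
        self.sim = EMUSimulator(net, [full_emu(net, m) for m in mets])
        S, _, _ = net.stoichiometric_matrix()
        self.N = null_space(S)
        if self.N.shape[1] == 0:
            raise ValueError("network has no degrees of freedom in flux space")
        self.p_v = self.N.shape[1]
        self.pool_names = self.sim.met_names
        self.n_pools = len(self.pool_names) if fit_pools else 0
        self.n_dil = len(mets) if fit_dilutions else 0
        self.n_params = self.p_v + self.n_pools + self.n_dil
        self._v_ref = self.net.flux_vector()
        self._p_ref = np.array([net.pools[m] for m in self.pool_names])
        self.flux_scale = float(np.abs(self._v_ref).max())
        # fit times exclude t=0 (no information: everything unlabelled)
        self._tmask = measured.times > 0
        self._fit_times = measured.times[self._tmask]
        # residual bookkeeping
        self._blocks = []
        n_res = 0
        for m in mets:
            sl = self.sim.target_slice(m)
            y = measured.mids[m][self._tmask]
            w = 1.0 / np.maximum(measured.sd[m][self._tmask], min_sd)
            keep = np.array([(m, t) not in measured.mask
                             for t in self._fit_times])
            self._blocks.append((m, sl, y, w, keep))
            n_res += int(keep.sum()) * y.shape[1]
        rxn_order = {n: i for i, n in enumerate(self.sim.rxn_names)}
        self._rate_rows = [(rxn_order[r], val, sd)
                           for r, (val, sd) in self.rate_measurements.items()]
        n_res += len(self._rate_rows)
        pool_order = {m: i for i, m in enumerate(self.pool_names)}
        self._pool_rows = []
        if fit_pools:
            self._pool_rows = [(pool_order[m], np.log(val), sd / val)
                               for m, (val, sd) in self.pool_measurements.items()]
        n_res += len(self._pool_rows)
        self.n_residuals = n_res
        self.dof = n_res - self.n_params
        if self.dof <= 0:
            raise ValueError(
                f"{n_res} residuals for {self.n_params} parameters: dof <= 0")

    # -- parameter packing -------------------------------------------------

    def pack(self, fluxes: dict, pools: dict | None = None,
             dilutions: dict | None = None) -> np.ndarray:
        v = np.array([fluxes[n] for n in self.sim.rxn_names])
        theta = self.N.T @ v
        parts = [theta]
        if self.fit_pools:
            p = pools or self.net.pools
            parts.append(np.log([p[m] for m in self.pool_names]))
        if self.fit_dilutions:
            d = dilutions or {}
            parts.append(np.array([d.get(m, 0.0) for m in self.measured_mets]))
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray):
        theta = x[: self.p_v]
        fv = self.N @ theta
        i = self.p_v
        if self.fit_pools:
            pv = np.exp(x[i:i + self.n_pools])
            i += self.n_pools
        else:
            pv = self._p_ref
        dv = x[i:i + self.n_dil] if self.fit_dilutions else np.zeros(
            len(self.measured_mets))
        return fv, pv, dv

    def bounds(self):
        lo = [-np.inf] * self.p_v
        hi = [np.inf] * self.p_v
        if self.fit_pools:
            lo += list(np.log(self._p_ref) - np.log(1e3))
            hi += list(np.log(self._p_ref) + np.log(1e3))
        if self.fit_dilutions:
            lo += [0.0] * self.n_dil
            hi += [1.0] * self.n_dil
        return np.array(lo), np.array(hi)

    # -- residuals ---------------------------------------------------------

    def residuals(self, x: np.ndarray) -> np.ndarray:
        fv, pv, dv = self.unpack(x)
        # negative trial fluxes would make the labelling ODE explosive; the
        # forward model sees them clipped at zero while the penalty below
        # pushes the raw parameters back into the feasible cone
        states = self.sim.simulate_states(self._fit_times,
                                          np.clip(fv, 0.0, None), pv,
                                          dt=self.dt)
        parts = []
        for j, (m, sl, y, w, keep) in enumerate(self._blocks):
            pred = states[:, sl]
            if self.fit_dilutions:
                d = dv[j]
                pred = (1.0 - d) * pred
                pred = pred.copy()
                pred[:, 0] += d
            r = (pred - y) * w[:, None]
            parts.append(r[keep].ravel())
        if self._rate_rows:
            parts.append(np.array([(fv[j] - val) / sd
                                   for j, val, sd in self._rate_rows]))
        if self._pool_rows:
            parts.append(np.array([(np.log(pv[j]) - logval) / rel_sd
                                   for j, logval, rel_sd in self._pool_rows]))
        # soft non-negativity on net fluxes
        parts.append(_NEG_PENALTY * np.minimum(fv, 0.0) / self.flux_scale)
        return np.concatenate(parts)

    def ssr(self, x: np.ndarray) -> float:
        r = self.residuals(x)[: self.n_residuals]
        return float(r @ r)

    # -- optimization ------------------------------------------------------

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        # fluxes: random log-uniform within two decades of the network scale,
        # projected onto the balance null space
        v0 = self.flux_scale * 10.0 ** rng.uniform(-1.5, 0.5,
                                                   size=len(self.sim.rxn_names))
        parts = [self.N.T @ v0]
        if self.fit_pools:
            parts.append(np.log(self._p_ref) + rng.uniform(-1.5, 1.5,
                                                           self.n_pools))
        if self.fit_dilutions:
            parts.append(rng.uniform(0.0, 0.3, self.n_dil))
        return np.concatenate(parts)

    def optimize_from(self, x0: np.ndarray, max_nfev: int = 400):
        lo, hi = self.bounds()
        x0 = np.clip(x0, lo, hi)
        return least_squares(self.residuals, x0, bounds=(lo, hi),
                             method="trf", x_scale="jac", max_nfev=max_nfev)

    def fit(self, restarts: int = 50, seed: int = 0,
            max_nfev: int = 400) -> FitResult:
        """Multi-start weighted least squares; deterministic under ``seed``."""
        best = None
        best_seed = seed
        for i in range(restarts):
            rng = np.random.default_rng(seed + i)
            sol = self.optimize_from(self._random_start(rng),
                                     max_nfev=max_nfev)
            if best is None or sol.cost < best.cost:
                best = sol
                best_seed = seed + i
        return self._result(best, restarts, best_seed)

    def _result(self, sol, restarts: int, best_seed: int) -> FitResult:
        x = sol.x
        fv, pv, dv = self.unpack(x)
        ssr = self.ssr(x)
        # linearized covariance (data rows only)
        J = sol.jac[: self.n_residuals]
        JtJ = J.T @ J
        sv = np.linalg.svd(JtJ, compute_uv=False)
        flat = []
        if sv.size and sv[-1] < 1e-10 * sv[0]:
            _, _, vt = np.linalg.svd(JtJ)
            for k in range(len(sv)):
                if sv[k] < 1e-10 * sv[0]:
                    idx = int(np.argmax(np.abs(vt[k])))
                    flat.append(self._param_name(idx))
        cov = np.linalg.pinv(JtJ)
        z = stats.norm.ppf(0.975)
        # flux CIs through v = N theta
        cov_theta = cov[: self.p_v, : self.p_v]
        var_v = np.einsum("ij,jk,ik->i", self.N, cov_theta, self.N)
        se_v = np.sqrt(np.clip(var_v, 0.0, None))
        flux_ci = {n: (fv[i] - z * se_v[i], fv[i] + z * se_v[i])
                   for i, n in enumerate(self.sim.rxn_names)}
        pool_ci = {}
        if self.fit_pools:
            se_lp = np.sqrt(np.clip(np.diag(cov)[self.p_v:
                                                 self.p_v + self.n_pools],
                                    0.0, None))
            pool_ci = {m: (pv[i] * np.exp(-z * se_lp[i]),
                           pv[i] * np.exp(z * se_lp[i]))
                       for i, m in enumerate(self.pool_names)}
        dil_ci = {}
        if self.fit_dilutions:
            off = self.p_v + self.n_pools
            se_d = np.sqrt(np.clip(np.diag(cov)[off:off + self.n_dil],
                                   0.0, None))
            dil_ci = {m: (max(0.0, dv[i] - z * se_d[i]),
                          min(1.0, dv[i] + z * se_d[i]))
                      for i, m in enumerate(self.measured_mets)}
        return FitResult(
            fluxes=dict(zip(self.sim.rxn_names, fv)),
            pools=dict(zip(self.pool_names, pv)) if self.fit_pools
            else dict(self.net.pools),
            dilutions=dict(zip(self.measured_mets, dv))
            if self.fit_dilutions else {},
            ssr=ssr, dof=self.dof, n_residuals=self.n_residuals,
            n_params=self.n_params, flux_ci=flux_ci, pool_ci=pool_ci,
            dilution_ci=dil_ci, n_restarts=restarts,
            best_restart_seed=best_seed, theta=x[: self.p_v].copy(),
            x_internal=x.copy(), nonidentifiable=flat)

    def _param_name(self, idx: int) -> str:
        if idx < self.p_v:
            return f"flux_basis_{idx}"
        if idx < self.p_v + self.n_pools:
            return f"pool:{self.pool_names[idx - self.p_v]}"
        return f"dilution:{self.measured_mets[idx - self.p_v - self.n_pools]}"


def fit(net: AtomNetwork, measured: MeasuredMIDs, restarts: int = 50,
        seed: int = 0, min_sd: float = 0.001, fit_pools: bool = True,
        fit_dilutions: bool = False, dt: float = 0.1, max_nfev: int = 400,
        rate_measurements: dict | None = None,
        pool_measurements: dict | None = None) -> FitResult:
    """One-call INST-MFA: build a :class:`FluxFitter` and run it."""
    fitter = FluxFitter(net, measured, fit_pools=fit_pools,
                        fit_dilutions=fit_dilutions, min_sd=min_sd, dt=dt,
                        rate_measurements=rate_measurements,
                        pool_measurements=pool_measurements)
    return fitter.fit(restarts=restarts, seed=seed, max_nfev=max_nfev)


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_ssr_at_flux(fitter: FluxFitter, x_opt: np.ndarray,
                         rxn_index: int, target: float,
                         max_nfev: int = 200) -> float:
    """Minimum SSR with reaction ``rxn_index`` flux constrained to ``target``."""
    g = fitter.N[rxn_index]                      # v_j = g . theta
    gn2 = float(g @ g)
    if gn2 < 1e-14:
        return fitter.ssr(x_opt)                 # flux structurally fixed at 0
    Q = null_space(g[None, :])                   # (p_v, p_v-1)
    theta_part = g * (target / gn2)

    theta_opt = x_opt[: fitter.p_v]
    rest_opt = x_opt[fitter.p_v:]
    c0 = Q.T @ (theta_opt - theta_part)
    y0 = np.concatenate([c0, rest_opt])
    lo, hi = fitter.bounds()
    lo_y = np.concatenate([np.full(c0.size, -np.inf), lo[fitter.p_v:]])
    hi_y = np.concatenate([np.full(c0.size, np.inf), hi[fitter.p_v:]])

    def res(y):
        theta = theta_part + Q @ y[: c0.size]
        return fitter.residuals(np.concatenate([theta, y[c0.size:]]))

    if c0.size + rest_opt.size == 0:
        return fitter.ssr(np.concatenate([theta_part, rest_opt]))
    sol = least_squares(res, np.clip(y0, lo_y, hi_y), bounds=(lo_y, hi_y),
                        method="trf", x_scale="jac", max_nfev=max_nfev)
    theta = theta_part + Q @ sol.x[: c0.size]
    return fitter.ssr(np.concatenate([theta, sol.x[c0.size:]]))


def _profile_bound(fitter, x_opt, rxn_index, v_hat, ssr_min, direction,
                   scale, tol, hard_lo, hard_hi):
    """Walk outward until SSR crosses the threshold, then bisect."""
    thr = ssr_min + _CHI2_1D_95
    step = 0.25 * scale
    inside = v_hat
    for _ in range(25):
        cand = inside + direction * step
        if cand < hard_lo or cand > hard_hi:
            cand = hard_lo if direction < 0 else hard_hi
            if _profile_ssr_at_flux(fitter, x_opt, rxn_index, cand) <= thr:
                return cand, True               # unbounded within limits
            break
        if _profile_ssr_at_flux(fitter, x_opt, rxn_index, cand) > thr:
            break
        inside = cand
        step *= 2.0
    else:
        return inside, True
    outside = cand
    while abs(outside - inside) > tol * scale:
        mid = 0.5 * (inside + outside)
        if _profile_ssr_at_flux(fitter, x_opt, rxn_index, mid) <= thr:
            inside = mid
        else:
            outside = mid
    return 0.5 * (inside + outside), False


def confidence_intervals(fitter: FluxFitter, fit_result: FitResult,
                         reactions=None, tol: float = 1e-3) -> dict:
    """Profile-likelihood 95% CIs for reaction fluxes.

    For each requested reaction the flux is stepped away from its estimate
    while all other parameters are re-optimized, until the SSR exceeds
    SSR_min + chi2(0.95, 1); the crossing is located by bisection to ``tol``
    of the flux scale.  Returns ``{reaction: (lo, hi, unbounded_flag)}``;
    a profile that never crosses the threshold before the search limit is
    flagged unbounded.
    """
    names = fitter.sim.rxn_names
    reactions = list(reactions) if reactions is not None else names
    x_opt = fit_result.x_internal
    ssr_min = fit_result.ssr
    out = {}
    for rname in reactions:
        j = names.index(rname)
        v_hat = fit_result.fluxes[rname]
        scale = max(abs(v_hat), 0.1 * fitter.flux_scale)
        hard_lo, hard_hi = 0.0, v_hat + 50.0 * scale
        lo, un_lo = _profile_bound(fitter, x_opt, j, v_hat, ssr_min, -1.0,
                                   scale, tol, hard_lo, hard_hi)
        hi, un_hi = _profile_bound(fitter, x_opt, j, v_hat, ssr_min, +1.0,
                                   scale, tol, hard_lo, hard_hi)
        out[rname] = (lo, hi, bool(un_lo or un_hi))
    return out
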