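"""Synthetic ¹³C-labelling data generator.

Emulates the data structures the analysis pipeline consumes: noisy
mass-isotopomer tables from short (seconds) and long (minutes–hours) labelling
experiments, starch ¹²C/¹³C trajectories, and protein-bound amino-acid
enrichment lagging the free pool.  Label propagation through an atom-mapped
network is simulated at metabolic steady state (constant pools and fluxes;
only the isotopic state evolves) with a step change of the input enrichment at
t = 0; per-metabolite dilution mixes a permanently unlabelled subpool into the
measured MID, which caps the enrichment plateau below the medium enrichment,
as observed for real cells.

Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emu import EMUSimulator
from .isotopomer import IsotopomerSimulator
from .mids import IsotopeModel, correction_matrix
from .network import AtomNetwork, builtin_network

__all__ = [
    "SimOutput",
    "simulate_labeling",
    "add_noise",
    "simulate_starch",
    "simulate_protein_labeling",
    "mid_table",
    "synthetic_enrichment_families",
]


@dataclass
class SimOutput:
    """Simulated labelling data plus the generating truth for recovery tests."""

    times: np.ndarray
    mids: dict                      # metabolite -> (T, n+1) measured MIDs
    n_carbons: dict
    truth: dict = field(default_factory=dict)
    starch: pd.DataFrame | None = None
    protein: pd.DataFrame | None = None

    def enrichment(self, met: str) -> np.ndarray:
        mids = self.mids[met]
        n = self.n_carbons[met]
        return mids @ np.arange(n + 1) / n

    def enrichment_frame(self) -> pd.DataFrame:
        """Metabolite x time matrix of fractional enrichments."""
        return pd.DataFrame(
            {m: self.enrichment(m) for m in self.mids}, index=self.times
        ).T


def simulate_labeling(net: AtomNetwork, times, method: str = "emu",
                      rtol: float = 1e-8, atol: float = 1e-10) -> SimOutput:
    """Integrate the isotopomer/EMU balance ODEs of ``net`` at ``times`` (s).

    ``method`` selects the engine: "emu" (default) or "isotopomer" (exhaustive
    reference).  Both start fully unlabelled and apply the step input and the
    network's dilutions identically.
    """
    times = np.asarray(times, dtype=float)
    if method == "emu":
        mids = EMUSimulator(net).simulate(times, method="accurate",
                                          rtol=rtol, atol=atol)
    elif method == "isotopomer":
        mids = IsotopomerSimulator(net).simulate(times, rtol=rtol, atol=atol)
    else:
        raise ValueError(f"unknown method {method!r}")
    counts = net.carbon_counts
    truth = {
        "fluxes": dict(net.fluxes),
        "pools": dict(net.pools),
        "dilutions": dict(net.dilutions),
        "medium_enrichment": dict(net.inputs),
        "input_carbon_flux": net.total_input_carbon_flux(),
    }
    return SimOutput(times=times, mids={m: mids[m] for m in mids},
                     n_carbons={m: counts[m] for m in mids}, truth=truth)


def add_noise(sim: SimOutput, sd: float, seed: int) -> SimOutput:
    """Truncated-Gaussian measurement noise on MID fractions, renormalized.

    Deterministic under a fixed seed; sd = 0 returns an identical copy.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = {}
    for m, mids in sim.mids.items():
        x = mids + rng.normal(0.0, sd, size=mids.shape)
        x = np.clip(x, 0.0, None)
        rows = x.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        noisy[m] = x / rows
    return SimOutput(times=sim.times.copy(), mids=noisy,
                     n_carbons=dict(sim.n_carbons), truth=dict(sim.truth),
                     starch=sim.starch, protein=sim.protein)


def mid_table(sim: SimOutput, replicate: int = 1,
              natural_abundance: IsotopeModel | None = None) -> pd.DataFrame:
    """Emit the delimited MID table format consumed by the correction stage.

    Columns: metabolite, fragment_id, n_carbons, time_s, replicate, m0...mk.
    If ``natural_abundance`` is given the true MIDs are convolved forward with
    its correction matrix, producing raw (uncorrected) measurements.
    """
    kmax = max(sim.n_carbons.values())
    rows = []
    for m, mids in sim.mids.items():
        n = sim.n_carbons[m]
        conv = None
        if natural_abundance is not None:
            conv = correction_matrix(n, natural_abundance)
        for ti, t in enumerate(sim.times):
            frac = mids[ti]
            if conv is not None:
                frac = conv @ frac
            row = {"metabolite": m, "fragment_id": f"{m}_full", "n_carbons": n,
                   "time_s": float(t), "replicate": replicate}
            for i in range(kmax + 1):
                row[f"m{i}"] = frac[i] if i <= n else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_starch(content0: float, synth: float, degr: float, times,
                    precursor_enrichment=None) -> pd.DataFrame:
    """Starch ¹²C/¹³C trajectories under continuous turnover.

    Parameters
    ----------
    content0 : float
        Initial starch content in µmol C6 units g⁻¹ DW (all ¹²C at t = 0).
    synth, degr : float
        Synthesis and degradation rates in nmol C g⁻¹ DW s⁻¹.
    times : array
        Seconds.
    precursor_enrichment : callable or None
        ¹³C enrichment of the glucosyl precursor as a function of time;
        defaults to fully labelled (1.0).

    Returns a frame with columns time_s, c12_umolC, c13_umolC, total_umolC.
    ¹³C accumulates at ``synth * E_prec``; ¹²C is lost at ``degr`` times the
    unlabelled fraction of starch (plus gained from the unlabelled share of
    synthesis).  Signals depletion by truncating at zero.
    """
    if synth < 0 or degr < 0:
        raise ValueError("rates must be >= 0")
    times = np.asarray(times, dtype=float)
    eprec = precursor_enrichment or (lambda t: 1.0)
    c12 = content0 * 6.0          # µmol C
    c13 = 0.0
    s = synth * 1e-3              # nmol -> µmol C per s
    d = degr * 1e-3
    out = [(times[0], c12, c13)]
    for t0, t1 in zip(times[:-1], times[1:]):
        nsub = max(1, int(np.ceil((t1 - t0) / 60.0)))
        dt = (t1 - t0) / nsub
        t = t0
        for _ in range(nsub):
            tot = c12 + c13
            f13 = c13 / tot if tot > 0 else 0.0
            e = float(eprec(t))
            dc13 = s * e - d * f13
            dc12 = s * (1.0 - e) - d * (1.0 - f13)
            c12 = max(0.0, c12 + dc12 * dt)
            c13 = max(0.0, c13 + dc13 * dt)
            t += dt
        out.append((t1, c12, c13))
    df = pd.DataFrame(out, columns=["time_s", "c12_umolC", "c13_umolC"])
    df["total_umolC"] = df["c12_umolC"] + df["c13_umolC"]
    return df


def simulate_protein_labeling(psr: float, free_aa_enrichment, times) -> pd.DataFrame:
    """Protein-bound amino-acid enrichment lagging the free pool.

    dE_b/dt = k (E_free(t) − E_b) with k = psr/100 per hour (psr in % h⁻¹).
    ``times`` in hours.  Integrated with fine-step RK4.
    """
    if psr <= 0:
        raise ValueError("psr must be > 0")
    k = psr / 100.0
    times = np.asarray(times, dtype=float)
    eb = 0.0
    out = []
    tprev = None
    for t in times:
        if tprev is not None and t > tprev:
            nsub = max(10, int(np.ceil((t - tprev) / 0.01)))
            dt = (t - tprev) / nsub
            tt = tprev
            for _ in range(nsub):
                f = lambda y, tau: k * (float(free_aa_enrichment(tau)) - y)
                k1 = f(eb, tt)
                k2 = f(eb + 0.5 * dt * k1, tt + 0.5 * dt)
                k3 = f(eb + 0.5 * dt * k2, tt + 0.5 * dt)
                k4 = f(eb + dt * k3, tt + dt)
                eb += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                tt += dt
        out.append((t, float(free_aa_enrichment(t)), eb))
        tprev = t
    return pd.DataFrame(out, columns=["time_h", "free_enrichment",
                                      "bound_enrichment"])


# ---------------------------------------------------------------------------
# Shaped synthetic datasets for the clustering / kinetics analyses
# ---------------------------------------------------------------------------

#: (plateau enrichment, time constant in minutes) per curve family, emulating
#: the qualitative classes seen in long-time-course labelling of algal
#: metabolism: rapidly saturating CBC-adjacent pools, intermediate pools,
#: slowly labelling storage/amino-acid pools, and essentially unlabelled pools.
#: Family plateaus are spaced so that between-family differences exceed the
#: within-family spread several-fold (well-separated planted clusters).
FAMILY_SHAPES = {
    "fast": (0.60, 10.0),
    "medium": (0.42, 45.0),
    "slow": (0.25, 160.0),
    "flat": (0.03, 500.0),
}

LONG_TIMES_MIN = (15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 300.0)


def synthetic_enrichment_families(n_per_family: int, seed: int,
                                  times_min=LONG_TIMES_MIN,
                                  noise_sd: float = 0.01,
                                  families=None,
                                  rel_jitter: float = 0.01) -> pd.DataFrame:
    """Saturating enrichment curves in well-separated kinetic families.

    Returns a metabolite x time matrix (percent enrichment) whose index
    carries the generating family in the name (``fast_03`` etc.), for
    cluster-recovery tests.  Within a family, plateau and time constant are
    jittered by ``rel_jitter`` (relative s.d.).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_min, dtype=float)
    families = families or FAMILY_SHAPES
    rows = {}
    for fam, (plateau, tau) in families.items():
        for i in range(n_per_family):
            p = plateau * rng.normal(1.0, rel_jitter)
            tc = tau * rng.normal(1.0, 2 * rel_jitter)
            curve = p * (1.0 - np.exp(-t / tc))
            curve = np.clip(curve + rng.normal(0, noise_sd, t.size), 0, 1)
            rows[f"{fam}_{i:02d}"] = 100.0 * curve
    return pd.DataFrame(rows, index=t).T


def study_like_dataset(seed: int, noise_sd: float = 0.005,
                       preset: str = "cbc_toy",
                       times_s=(0.0, 5.0, 10.0, 20.0, 40.0),
                       dilutions: dict | None = None,
                       n_replicates: int = 3) -> tuple:
    """Full short-pulse synthetic experiment: network truth + noisy MID tables.

    Returns ``(net, sim, table)`` where ``table`` stacks ``n_replicates``
    independently noised replicate MID tables (with natural abundance folded
    in, as raw instruments would report).
    """
    net = builtin_network(preset, dilutions=dilutions)
    sim = simulate_labeling(net, list(times_s), method="emu")
    # natural abundance is convolved in BEFORE the measurement noise: the
    # instrument's noise acts on the observed (isotope-contaminated) channels
    model = IsotopeModel()
    conv = {m: mids @ correction_matrix(sim.n_carbons[m], model).T
            for m, mids in sim.mids.items()}
    sim_na = SimOutput(times=sim.times, mids=conv,
                       n_carbons=dict(sim.n_carbons), truth=dict(sim.truth))
    tables = []
    for rep in range(1, n_replicates + 1):
        noisy = add_noise(sim_na, noise_sd, seed + rep)
        tables.append(mid_table(noisy, replicate=rep))
    return net, sim, pd.concat(tables, ignore_index=True)
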