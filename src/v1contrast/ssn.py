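"""Four-population stabilized supralinear ring network (SSN).

One excitatory population (layer 2/3 pyramidal, "E") and three inhibitory
populations (PV, SST, VIP) live on a ring covering 180 degrees of direction
preference.  E units tile the ring at 1-degree spacing (plus a few extra
units at 0 degrees encoding the measured front-to-back over-representation);
all interneurons prefer 0 degrees.  Connection strength falls off as a
wrapped Gaussian of preferred-direction difference, narrow (sigma_e = 30
degrees) for E->E and E->VIP, broad (sigma_b = 100 degrees) for every other
projection.  Units are rate models with a rectified quadratic transfer
function ``r_ss(I) = k I^2`` for ``I > 0`` (k = 0.04), evolved by Euler
integration of ``tau r' = r_ss(I_sum) - r``.

External ("sensory") drive, a stand-in for stimulus contrast, reaches E
units through a 30-degree Gaussian kernel (slightly biased toward 0
degrees) and PV units untuned; SST and VIP receive none.  VIP's only
output is inhibition of SST, closing the disinhibitory loop
E -> VIP -| SST -| E whose gain and stability this module analyses.

Linear stability of the excitatory subnetwork is summarized by the E-E
element of the Fourier-domain linear-response matrix,
``J(x, n) = g(x) W G(n)``: ``EE_stability = J00 - 1 > 0`` diagnoses an
inhibitory-stabilized network (ISN) when the full network is stable.

The absolute coupling strengths are not constrained by anatomy here; the
shipped defaults are a documented calibration chosen so that the VIP->SST
weight of -0.6 sits at 0.99 of its critical (destabilizing) magnitude with
the PV share of inhibition onto E at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

POPS = ("e", "pv", "sst", "vip")

#: Projections present in the circuit (pre -> post).  VIP's only target is
#: SST; SST inhibits E, PV and VIP; PV inhibits E and itself.
PROJECTIONS = (
    ("e", "e"),
    ("e", "pv"),
    ("e", "sst"),
    ("e", "vip"),
    ("pv", "e"),
    ("pv", "pv"),
    ("sst", "e"),
    ("sst", "pv"),
    ("sst", "vip"),
    ("vip", "sst"),
)

#: Narrow-kernel projections (sigma_e); everything else uses sigma_b.
NARROW_PROJECTIONS = (("e", "e"), ("e", "vip"))


@dataclass(frozen=True)
class Couplings:
    """Total signed synaptic weight of each projection (pre -> post).

    Each value is the summed input a postsynaptic neuron receives from the
    presynaptic population when that population fires at rate 1 (the
    wrapped-Gaussian profile is normalized to unit sum), so the numbers are
    population-level coupling strengths independent of unit counts.
    The defaults are the shipped calibration (see module docstring).
    """

    e_e: float = 0.6
    e_pv: float = 0.65
    e_sst: float = 0.8
    e_vip: float = 0.293
    pv_e: float = -0.7
    pv_pv: float = -0.8
    sst_e: float = -0.7
    sst_pv: float = -0.2
    sst_vip: float = -0.6
    vip_sst: float = -0.6

    def __post_init__(self) -> None:
        for pre, post in PROJECTIONS:
            v = getattr(self, f"{pre}_{post}")
            if pre == "e" and v < 0:
                raise ValueError(f"excitatory coupling {pre}->{post} must be >= 0")
            if pre != "e" and v > 0:
                raise ValueError(f"inhibitory coupling {pre}->{post} must be <= 0")

    def get(self, pre: str, post: str) -> float:
        return getattr(self, f"{pre}_{post}", 0.0) if (pre, post) in PROJECTIONS else 0.0

    @property
    def pv_fraction(self) -> float:
        """PV share of inhibition onto E: W_PV / (W_PV + W_SST)."""
        total = abs(self.pv_e) + abs(self.sst_e)
        return abs(self.pv_e) / total if total else float("nan")

    def with_pv_fraction(self, rho: float) -> "Couplings":
        """Redistribute the total inhibition onto E between PV and SST."""
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"pv fraction must be in [0, 1], got {rho}")
        total = abs(self.pv_e) + abs(self.sst_e)
        return replace(self, pv_e=-rho * total, sst_e=-(1.0 - rho) * total)

    def ablate_vip_sst(self) -> "Couplings":
        return replace(self, vip_sst=0.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and dynamical parameters of the ring network."""

    n_e_ring: int = 180  # E units tiling the ring at uniform spacing
    n_e_extra: int = 4  # extra E units at 0 degrees (front-to-back bias)
    n_pv: int = 40
    n_sst: int = 15
    n_vip: int = 15
    period: float = 180.0  # degrees of direction covered by the ring
    sigma_e: float = 30.0  # narrow kernel width (degrees)
    sigma_b: float = 100.0  # broad kernel width (degrees)
    k: float = 0.04  # rate units per squared input
    dt: float = 0.1  # ms
    tau: dict = field(
        default_factory=lambda: {"e": 20.0, "pv": 10.0, "sst": 20.0, "vip": 20.0}
    )
    i_sp: dict = field(
        default_factory=lambda: {"e": 2.0, "pv": 2.0, "sst": 2.0, "vip": 10.0}
    )
    couplings: Couplings = field(default_factory=Couplings)
    input_bias: float = 0.05  # multiplicative drive bias toward 0 degrees
    pv_input_frac: float = 0.4  # untuned PV drive as a fraction of strength

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_b <= 0:
            raise ValueError("kernel widths must be positive")
        for name in ("n_e_ring", "n_pv", "n_sst", "n_vip"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_e_extra < 0:
            raise ValueError("n_e_extra must be >= 0")

    @property
    def n_e(self) -> int:
        return self.n_e_ring + self.n_e_extra


def wrapped_gaussian(delta: np.ndarray, sigma: float, period: float = 180.0) -> np.ndarray:
    """Peak-1 Gaussian of angular difference, wrapped on the ring."""
    d = np.asarray(delta, dtype=float) % period
    out = np.zeros_like(d)
    for m in range(-6, 7):
        out += np.exp(-((d + m * period) ** 2) / (2.0 * sigma**2))
    return out


def wrapped_gaussian_transform(
    n: int, sigma: float, period: float = 180.0, normalized: bool = True
) -> float:
    """Fourier coefficient of the wrapped Gaussian connectivity profile.

    By Poisson summation the coefficient at spatial frequency ``n`` is
    ``(sqrt(2 pi) sigma / L) exp(-2 (n pi sigma / L)^2)``; the normalized
    form divides by the n = 0 coefficient, matching connectivity rows that
    are normalized to unit sum.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    value = np.sqrt(2.0 * np.pi) * sigma / period * np.exp(
        -2.0 * (n * np.pi * sigma / period) ** 2
    )
    if normalized:
        value = value / (np.sqrt(2.0 * np.pi) * sigma / period)
    return float(value)


def transform_matrix(n: int, config: NetworkConfig) -> np.ndarray:
    """4x4 matrix of normalized kernel transforms per projection (post x pre)."""
    G = np.zeros((len(POPS), len(POPS)))
    for i, post in enumerate(POPS):
        for j, pre in enumerate(POPS):
            if (pre, post) not in PROJECTIONS:
                continue
            sigma = config.sigma_e if (pre, post) in NARROW_PROJECTIONS else config.sigma_b
            G[i, j] = wrapped_gaussian_transform(n, sigma, config.period)
    return G


class SSNetwork:
    """Constructed ring network: positions, population labels and weights."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        c = self.config
        spacing = c.period / c.n_e_ring
        positions = [np.arange(c.n_e_ring) * spacing, np.zeros(c.n_e_extra)]
        positions += [np.zeros(c.n_pv), np.zeros(c.n_sst), np.zeros(c.n_vip)]
        self.positions = np.concatenate(positions)
        self.pop_labels = np.array(
            ["e"] * c.n_e + ["pv"] * c.n_pv + ["sst"] * c.n_sst + ["vip"] * c.n_vip
        )
        self.slices = {}
        start = 0
        for pop, count in zip(POPS, (c.n_e, c.n_pv, c.n_sst, c.n_vip)):
            self.slices[pop] = slice(start, start + count)
            start += count
        self.n = start
        self.tau = np.concatenate(
            [np.full(self.slices[p].stop - self.slices[p].start, c.tau[p]) for p in POPS]
        )
        self.i_sp = np.concatenate(
            [np.full(self.slices[p].stop - self.slices[p].start, c.i_sp[p]) for p in POPS]
        )
        self.W = self._build_weights()

    def _build_weights(self) -> np.ndarray:
        c = self.config
        W = np.zeros((self.n, self.n))
        for pre, post in PROJECTIONS:
            J = c.couplings.get(pre, post)
            if J == 0.0:
                continue
            sigma = c.sigma_e if (pre, post) in NARROW_PROJECTIONS else c.sigma_b
            pre_sl, post_sl = self.slices[pre], self.slices[post]
            delta = self.positions[post_sl, None] - self.positions[None, pre_sl]
            kernel = wrapped_gaussian(delta, sigma, c.period)
            # Normalize each postsynaptic row so the summed weight equals J.
            W[post_sl, pre_sl] = J * kernel / kernel.sum(axis=1, keepdims=True)
        return W

    def rate_transfer(self, I: np.ndarray) -> np.ndarray:
        """Rectified quadratic steady-state transfer r_ss(I) = k I^2 (I > 0)."""
        I = np.asarray(I, dtype=float)
        return self.config.k * np.square(np.maximum(I, 0.0))

    def gain(self, I: np.ndarray) -> np.ndarray:
        """Postsynaptic gain dr_ss/dI = 2 k max(I, 0)."""
        return 2.0 * self.config.k * np.maximum(np.asarray(I, dtype=float), 0.0)

    def external_drive(self, strength: float, direction: float | None = 0.0) -> np.ndarray:
        """External input vector for a stimulus of the given drive strength.

        E units receive ``strength`` through the 30-degree kernel centered
        on the stimulus direction (given in 0-360 degree direction space and
        mapped onto the 180-degree ring), boosted by the 0-degree input
        bias; ``direction=None`` delivers spatially uniform drive to E
        (used for homogeneous-state analyses).  PV units receive an equal
        untuned share; SST and VIP receive nothing.
        """
        if strength < 0:
            raise ValueError("strength must be >= 0")
        c = self.config
        drive = np.zeros(self.n)
        e_sl = self.slices["e"]
        x = self.positions[e_sl]
        bias = 1.0 + c.input_bias * wrapped_gaussian(x, c.sigma_e, c.period)
        if direction is None:
            drive[e_sl] = strength * bias
        else:
            delta = x - (float(direction) % c.period)
            drive[e_sl] = strength * wrapped_gaussian(delta, c.sigma_e, c.period) * bias
        drive[self.slices["pv"]] = strength * c.pv_input_frac
        return drive

    def net_input(self, r: np.ndarray, drive: np.ndarray) -> np.ndarray:
        return self.i_sp + drive + self.W @ r

    def pop_mean(self, values: np.ndarray, pop: str) -> float:
        return float(values[self.slices[pop]].mean())

    def zero_units(self, pop: str) -> np.ndarray:
        """Indices of a population's units with preferred direction 0."""
        sl = self.slices[pop]
        idx = np.arange(sl.start, sl.stop)
        return idx[self.positions[sl] == 0.0]


def build_network(config: NetworkConfig | None = None) -> SSNetwork:
    return SSNetwork(config)


@dataclass
class NetworkState:
    """Outcome of evolving the network to (attempted) steady state."""

    r: np.ndarray
    i_sum: np.ndarray
    steady: bool
    diverged: bool
    t: float  # simulated ms
    drive: np.ndarray

    def pop_rates(self, net: SSNetwork) -> dict[str, float]:
        return {p: net.pop_mean(self.r, p) for p in POPS}


def steady_state(
    net: SSNetwork,
    drive: np.ndarray,
    r0: np.ndarray | None = None,
    t_max: float = 6000.0,
    tol: float = 1e-6,
    ceiling: float = 1e6,
    check_every: int = 50,
) -> NetworkState:
    """Euler-evolve the rate dynamics until steady or divergent.

    Steady means ``max |r_ss(I_sum) - r| < tol``; divergence (any rate
    above ``ceiling`` or non-finite) is flagged, not raised, so sweeps can
    treat instability as data.
    """
    c = net.config
    r = np.zeros(net.n) if r0 is None else np.array(r0, dtype=float)
    b = net.i_sp + drive
    step = c.dt / net.tau
    n_steps = int(round(t_max / c.dt))
    steady = False
    diverged = False
    t = 0.0
    # overflow during runaway activity is expected and handled as divergence
    with np.errstate(over="ignore", invalid="ignore"):
        I = b + net.W @ r
        for i in range(n_steps):
            delta = net.rate_transfer(I) - r
            r = r + step * delta
            t += c.dt
            I = b + net.W @ r
            if (i + 1) % check_every == 0 or i == n_steps - 1:
                if not np.all(np.isfinite(r)) or np.max(r) > ceiling:
                    diverged = True
                    r = np.where(np.isfinite(r), r, ceiling)
                    break
                if np.max(np.abs(net.rate_transfer(I) - r)) < tol:
                    steady = True
                    break
    return NetworkState(r=r, i_sum=I, steady=steady, diverged=diverged, t=t, drive=drive)


DEFAULT_STRENGTHS = np.arange(0.0, 101.0, 10.0)
DEFAULT_GAIN_STRENGTHS = np.arange(0.0, 101.0, 1.0)


def tuning_surface(
    net: SSNetwork,
    directions: Iterable[float] = tuple(np.arange(0.0, 360.0, 45.0)),
    strengths: Iterable[float] = tuple(DEFAULT_STRENGTHS),
    **steady_kwargs,
) -> pd.DataFrame:
    """Mean steady-state rate per population per (direction, strength).

    Within a direction the strength grid is solved with warm starts.
    Non-converged grid points are flagged via ``steady``.
    """
    rows = []
    for direction in directions:
        r0 = None
        for strength in strengths:
            state = steady_state(
                net, net.external_drive(strength, direction), r0=r0, **steady_kwargs
            )
            r0 = None if state.diverged else state.r
            for pop, rate in state.pop_rates(net).items():
                rows.append(
                    {
                        "direction": float(direction),
                        "strength": float(strength),
                        "pop": pop,
                        "mean_rate": rate,
                        "steady": state.steady,
                    }
                )
    return pd.DataFrame(rows)


def decompose_currents(net: SSNetwork, state: NetworkState) -> pd.DataFrame:
    """Input components onto each E unit, summing exactly to the net input.

    Columns: external drive, recurrent excitation, PV and SST inhibition,
    and the spontaneous input; ``external + e + pv + sst + spontaneous``
    equals ``i_sum`` to machine precision (VIP does not project to E).
    """
    e_sl = net.slices["e"]
    r = state.r
    comp = {"external": state.drive[e_sl], "spontaneous": net.i_sp[e_sl]}
    for pre in ("e", "pv", "sst"):
        comp[pre] = net.W[e_sl, net.slices[pre]] @ r[net.slices[pre]]
    df = pd.DataFrame(comp)
    df["i_sum"] = state.i_sum[e_sl]
    df["position"] = net.positions[e_sl]
    return df


@dataclass
class GainResult:
    """Pyramidal rate and finite-difference gain along a drive grid."""

    strengths: np.ndarray
    rate: np.ndarray  # mean rate of 0-degree E units
    gain: np.ndarray  # centered finite-difference slope
    steady: np.ndarray
    pop_rates: pd.DataFrame  # long format per population


def gain_curve(
    net: SSNetwork,
    strengths: Iterable[float] = tuple(DEFAULT_GAIN_STRENGTHS),
    direction: float | None = 0.0,
    **steady_kwargs,
) -> GainResult:
    """Pyramidal rate and gain (d rate / d drive) versus drive strength."""
    strengths = np.asarray(list(strengths), dtype=float)
    zero_e = net.zero_units("e")
    rates = np.full(strengths.size, np.nan)
    steady_flags = np.zeros(strengths.size, dtype=bool)
    rows = []
    r0 = None
    for i, s in enumerate(strengths):
        state = steady_state(net, net.external_drive(s, direction), r0=r0, **steady_kwargs)
        r0 = None if state.diverged else state.r
        steady_flags[i] = state.steady
        if state.steady:
            rates[i] = float(state.r[zero_e].mean())
        for pop, rate in state.pop_rates(net).items():
            rows.append(
                {
                    "strength": float(s),
                    "pop": pop,
                    "mean_rate": rate,
                    "rate_at_zero_deg": float(state.r[net.zero_units(pop)].mean()),
                    "steady": state.steady,
                }
            )
    gain = np.gradient(rates, strengths)
    return GainResult(strengths, rates, gain, steady_flags, pd.DataFrame(rows))


def delta_gain(
    config: NetworkConfig,
    strengths: Iterable[float] = tuple(DEFAULT_GAIN_STRENGTHS),
    direction: float | None = 0.0,
    **steady_kwargs,
) -> tuple[GainResult, GainResult, np.ndarray]:
    """Gain of the intact network minus the VIP->SST-ablated network."""
    intact = gain_curve(SSNetwork(config), strengths, direction, **steady_kwargs)
    ablated_cfg = replace(config, couplings=config.couplings.ablate_vip_sst())
    ablated = gain_curve(SSNetwork(ablated_cfg), strengths, direction, **steady_kwargs)
    return intact, ablated, intact.gain - ablated.gain


@dataclass
class StabilityResult:
    """Analytic E-E linear-stability summary at one steady state."""

    gains: dict  # postsynaptic gain per population at x = 0
    j00: float  # E-E element of J(x, n) = g W G(n)
    ee_stability: float  # j00 - 1
    regime: str  # "non_isn" | "isn" | "unstable"
    n: int


def ee_stability(net: SSNetwork, state: NetworkState, n: int = 0) -> StabilityResult:
    """E-E stability at spatial frequency ``n``, evaluated at 0 degrees.

    ``J00 = g_E(0) * W_EE * G_EE(n)`` with ``g = 2 k max(I, 0)`` the
    postsynaptic gain at the steady state.  ``J00 - 1 > 0`` with a stable
    full network marks the inhibitory-stabilized (ISN) regime; a
    non-converged state is classified unstable.
    """
    if state.diverged:
        gains = {p: float("nan") for p in POPS}
        return StabilityResult(gains, float("nan"), float("nan"), "unstable", n)
    if not state.steady:
        raise ValueError("state did not converge; re-run steady_state with larger t_max")
    g_all = net.gain(state.i_sum)
    gains = {p: float(g_all[net.zero_units(p)].mean()) for p in POPS}
    G = transform_matrix(n, net.config)
    j00 = gains["e"] * net.config.couplings.e_e * G[0, 0]
    ee = j00 - 1.0
    regime = "isn" if ee > 0 else "non_isn"
    return StabilityResult(gains, float(j00), float(ee), regime, n)


def stability_curve(
    net: SSNetwork,
    strengths: Iterable[float] = tuple(DEFAULT_STRENGTHS),
    direction: float | None = 0.0,
    n: int = 0,
    **steady_kwargs,
) -> pd.DataFrame:
    """EE stability and regime along a drive-strength grid (warm-started)."""
    rows = []
    r0 = None
    for s in strengths:
        state = steady_state(net, net.external_drive(s, direction), r0=r0, **steady_kwargs)
        r0 = None if state.diverged else state.r
        if state.diverged or not state.steady:
            rows.append(
                {
                    "strength": float(s),
                    "ee_stability": np.nan,
                    "regime": "unstable",
                    "e_rate": np.nan,
                }
            )
            continue
        res = ee_stability(net, state, n=n)
        rows.append(
            {
                "strength": float(s),
                "ee_stability": res.ee_stability,
                "regime": res.regime,
                "e_rate": net.pop_mean(state.r, "e"),
            }
        )
    return pd.DataFrame(rows)


def jacobian(net: SSNetwork, state: NetworkState) -> np.ndarray:
    """Analytic Jacobian of ``tau_j r_j'`` at a state: ``g_j W - I``."""
    g = net.gain(state.i_sum)
    return g[:, None] * net.W - np.eye(net.n)


def sweep_parameter(
    base_config: NetworkConfig,
    parameter: str,
    grid: Iterable[float],
    strengths: Iterable[float] = tuple(DEFAULT_STRENGTHS),
    direction: float | None = 0.0,
    **steady_kwargs,
) -> pd.DataFrame:
    """Sweep ``w_vip_sst`` or ``pv_fraction`` against drive strength.

    For each grid cell the long-format result records the regime, the E-E
    stability and population mean rates; instabilities are recorded, not
    raised.
    """
    if parameter not in ("w_vip_sst", "pv_fraction"):
        raise ValueError(f"unknown parameter {parameter!r}")
    rows = []
    for value in grid:
        if parameter == "w_vip_sst":
            coup = replace(base_config.couplings, vip_sst=float(value))
        else:
            coup = base_config.couplings.with_pv_fraction(float(value))
        net = SSNetwork(replace(base_config, couplings=coup))
        r0 = None
        for s in strengths:
            state = steady_state(net, net.external_drive(s, direction), r0=r0, **steady_kwargs)
            r0 = None if state.diverged else state.r
            if state.steady:
                res = ee_stability(net, state)
                regime, ee = res.regime, res.ee_stability
            else:
                regime, ee = "unstable", np.nan
            row = {
                "parameter": parameter,
                "value": float(value),
                "strength": float(s),
                "regime": regime,
                "ee_stability": ee,
            }
            for pop, rate in state.pop_rates(net).items():
                row[f"rate_{pop}"] = rate if state.steady else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def find_critical_vip_sst(
    base_config: NetworkConfig,
    strengths: Iterable[float] = tuple(DEFAULT_STRENGTHS),
    lo: float = 0.0,
    hi: float = 2.0,
    tol: float = 0.005,
    **steady_kwargs,
) -> float:
    """Largest stable |W_VIP->SST| (bisection on full-grid convergence).

    Returns the magnitude of the critical coupling: below it the network
    reaches a steady state at every strength on the grid, above it at least
    one grid point diverges or fails to settle.
    """
    strengths = list(strengths)

    def stable(magnitude: float) -> bool:
        coup = replace(base_config.couplings, vip_sst=-magnitude)
        net = SSNetwork(replace(base_config, couplings=coup))
        r0 = None
        for s in strengths:
            state = steady_state(net, net.external_drive(s, 0.0), r0=r0, **steady_kwargs)
            if not state.steady:
                return False
            r0 = state.r
        return True

    if not stable(lo):
        raise ValueError("network unstable even with the weakest VIP->SST coupling")
    if stable(hi):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
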