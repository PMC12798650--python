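"""Networks of four-population neural mass regions.

Each region of interest (ROI) lumps a cortical patch into four interacting
populations: pyramidal neurons (``p``), excitatory interneurons (``e``), and
inhibitory interneurons with slow (``s``) and fast (``f``) synaptic kinetics.
Every population converts its average membrane potential into an average
firing rate through a static sigmoid (threshold below, saturation above), and
every synapse is a critically damped second-order filter with impulse
response ``h(t) = G * omega * t * exp(-omega * t)``.

Long-range connections always originate from the pyramidal population of the
source ROI.  An *excitatory* connection targets the pyramidal population of
the receiving ROI; an *inhibitory* (disynaptic) connection targets its fast
inhibitory interneurons, producing net inhibition of the receiving pyramidal
cells.  Each connection has a strength ``W`` and a pure transmission delay
``D`` (10 ms by default).

Per-band parameter presets make an isolated ROI express a dominant intrinsic
rhythm in the theta (4-8 Hz), alpha (8-12 Hz), beta (13-30 Hz) or gamma
(30-50 Hz) band when driven by its default noisy input.  Integration is
Euler-Maruyama with white-noise increments scaled by ``sigma / sqrt(dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SigmoidParams",
    "SynapseKinetics",
    "InternalCoupling",
    "ROIParams",
    "Connection",
    "Network",
    "SimOutput",
    "SimulationDiverged",
    "sigmoid",
    "preset",
    "simulate",
    "simulate_trials",
    "postsynaptic_current_summary",
    "BANDS",
    "DEFAULT_DT",
    "DEFAULT_DELAY",
]

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Euler-Maruyama step (s).  The fastest synapse has omega ~ 300 /s, so
#: dt * omega = 0.03 << 1.
DEFAULT_DT = 1e-4

#: Long-range transmission delay (s).
DEFAULT_DELAY = 0.010


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidParams:
    """Static rate function ``z(v) = 2 e0 / (1 + exp(r (v0 - v)))``.

    e0 : half-maximum firing rate (s^-1); the output saturates at 2 e0.
    r  : slope at the center (mV^-1).
    v0 : center potential (mV).
    """

    e0: float = 2.5
    r: float = 0.56
    v0: float = 0.0

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.r <= 0:
            raise ValueError("sigmoid requires e0 > 0 and r > 0")


@dataclass(frozen=True)
class SynapseKinetics:
    """Second-order synapse: gain ``G`` (mV) and rate constant ``omega`` (s^-1).

    The impulse response ``G * omega * t * exp(-omega t)`` peaks at ``1/omega``.
    """

    G: float
    omega: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("synapse rate constant omega must be > 0")

    def impulse_response(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.G * self.omega * t * np.exp(-self.omega * t)


@dataclass(frozen=True)
class InternalCoupling:
    """Average numbers of synaptic contacts on the eight internal links.

    Attribute ``xy`` is the directed link x -> y (e.g. ``pe`` is
    pyramidal -> excitatory interneurons).
    """

    pe: float
    ep: float
    ps: float
    sp: float
    pf: float
    fp: float
    sf: float
    ff: float

    def __post_init__(self) -> None:
        for name in ("pe", "ep", "ps", "sp", "pf", "fp", "sf", "ff"):
            if getattr(self, name) < 0:
                raise ValueError(f"internal coupling {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pe, self.ep, self.ps, self.sp, self.pf, self.fp, self.sf, self.ff]
        )


@dataclass(frozen=True)
class ROIParams:
    """Full parameterization of one neural-mass region."""

    sigmoid: SigmoidParams
    kin_exc: SynapseKinetics
    kin_slow: SynapseKinetics
    kin_fast: SynapseKinetics
    C: InternalCoupling
    m_p: float = 400.0
    m_f: float = 0.0
    sigma_p: float = 0.0
    sigma_f: float = 0.0
    rhythm: str = "alpha"

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_f < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.rhythm not in BANDS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}; expected one of {sorted(BANDS)}")


@dataclass(frozen=True)
class Connection:
    """Directed long-range link between two ROIs.

    ``kind='excitatory'`` targets the pyramidal population of ``target``;
    ``kind='inhibitory'`` targets its fast inhibitory interneurons.
    """

    source: int
    target: int
    W: float
    kind: str = "excitatory"
    D: float = DEFAULT_DELAY

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("long-range connections must link distinct ROIs")
        if self.W < 0:
            raise ValueError("connection strength W must be >= 0")
        if self.D < 0:
            raise ValueError("delay D must be >= 0")
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown connection kind {self.kind!r}")


@dataclass(frozen=True)
class Network:
    """An ordered set of ROIs plus directed, weighted, delayed connections."""

    rois: tuple[ROIParams, ...]
    connections: tuple[Connection, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        object.__setattr__(self, "connections", tuple(self.connections))
        n = len(self.rois)
        seen = set()
        for c in self.connections:
            if not (0 <= c.source < n and 0 <= c.target < n):
                raise ValueError(f"connection {c} references an ROI outside 0..{n - 1}")
            key = (c.source, c.target, c.kind)
            if key in seen:
                raise ValueError(f"duplicate connection {key}")
            seen.add(key)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def weight_matrix(self, kind: str | None = None) -> np.ndarray:
        """True-connectivity matrix; entry [i, j] is W for the link j -> i."""
        W = np.zeros((self.n_rois, self.n_rois))
        for c in self.connections:
            if kind is None or c.kind == kind:
                W[c.target, c.source] += c.W
        return W


@dataclass
class SimOutput:
    """Simulated traces of one trial.

    vp       : (n_samples, n_rois) pyramidal membrane potential (mV) at the
               raw integration rate.
    psp      : per-connection long-range postsynaptic potential traces (mV),
               keyed by index into ``network.connections`` (empty unless
               requested).
    rates    : optional (n_samples, n_rois) pyramidal firing-rate traces.
    """

    vp: np.ndarray
    psp: dict[int, np.ndarray]
    dt_raw: float
    duration: float
    seed: int
    network: Network
    rates: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.vp.shape[0]

    @property
    def fs_raw(self) -> float:
        return 1.0 / self.dt_raw


class SimulationDiverged(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


# ---------------------------------------------------------------------------
# sigmoid and presets
# ---------------------------------------------------------------------------

def sigmoid(v, p: SigmoidParams):
    """Average firing rate (s^-1) of a population at membrane potential ``v`` (mV).

    Strictly increasing, bounded in (0, 2 e0); equals ``e0`` at ``v = v0``.
    """
    v = np.asarray(v, dtype=float)
    out = 2.0 * p.e0 / (1.0 + np.exp(p.r * (p.v0 - v)))
    return out if out.ndim else float(out)


# Per-band presets.  The structural template and internal coupling ratios
# follow the classic four-population (Wendling-family) cortical model
# (C = 135 with the usual fractions for the slow loop).  The resonance of
# the slow-inhibitory feedback loop sets the theta/alpha/beta frequency, so
# those presets rescale the glutamatergic and slow-GABAergic rate constants
# (gains rescaled with them, keeping G/omega and hence the operating point
# fixed).  The gamma preset instead strengthens the pyramidal <-> fast
# interneuron loop, whose phase crossover with omega_e ~ 110 and
# omega_f = 650 s^-1 lies in the 30-50 Hz band, and weakens the slow loop.
# Numeric values are calibration-verified: an isolated ROI driven by the
# default noisy input (m_p = 400, sigma = 10) shows a Welch-PSD peak of vp
# inside its nominal band.
_PRESETS: dict[str, ROIParams] = {}


def _register_presets() -> None:
    base_sig = SigmoidParams(e0=2.5, r=0.56, v0=6.0)
    noise = dict(sigma_p=10.0, sigma_f=10.0)
    slow_C = InternalCoupling(
        pe=135.0, ep=108.0, ps=33.75, sp=33.75, pf=40.5, fp=108.0, sf=13.5, ff=0.0
    )

    def kin(scale: float, G_slow: float = 22.0, G_fast: float = 20.0, om_fast: float = 500.0) -> dict:
        return dict(
            kin_exc=SynapseKinetics(3.25 * scale, 100.0 * scale),
            kin_slow=SynapseKinetics(G_slow * scale, 50.0 * scale),
            kin_fast=SynapseKinetics(G_fast, om_fast),
        )

    _PRESETS["theta"] = ROIParams(
        sigmoid=base_sig, C=slow_C, m_p=400.0, m_f=100.0, rhythm="theta", **kin(0.55), **noise
    )
    _PRESETS["alpha"] = ROIParams(
        sigmoid=base_sig, C=slow_C, m_p=400.0, m_f=100.0, rhythm="alpha", **kin(1.0), **noise
    )
    _PRESETS["beta"] = ROIParams(
        sigmoid=base_sig, C=slow_C, m_p=400.0, m_f=100.0, rhythm="beta", **kin(2.0), **noise
    )
    _PRESETS["gamma"] = ROIParams(
        sigmoid=base_sig,
        C=InternalCoupling(
            pe=135.0, ep=108.0, ps=33.75, sp=33.75, pf=140.0, fp=160.0, sf=13.5, ff=0.0
        ),
        m_p=400.0,
        rhythm="gamma",
        **kin(1.0, G_slow=15.0, G_fast=40.0, om_fast=650.0),
        **noise,
    )


_register_presets()


def preset(rhythm: str, **overrides) -> ROIParams:
    """Parameter preset whose isolated ROI expresses the requested rhythm.

    Parameters
    ----------
    rhythm : {'theta', 'alpha', 'beta', 'gamma'}
    **overrides : replace any ROIParams field (e.g. ``m_p=800``).
    """
    if rhythm not in _PRESETS:
        raise ValueError(f"unknown rhythm {rhythm!r}; expected one of {sorted(_PRESETS)}")
    p = _PRESETS[rhythm]
    return replace(p, **overrides) if overrides else p


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

# Eight second-order synaptic filters per ROI.  Row order:
#   0 exc->p (internal e->p + external input + long-range excitatory)
#   1 slow->p    2 fast->p    3 exc->e (p->e)    4 exc->s (p->s)
#   5 exc->f (p->f + external input + long-range inhibitory afferents)
#   6 slow->f    7 fast->f (self-loop)
_N_FILT = 8
_FILT_FAMILY = ("exc", "slow", "fast", "exc", "exc", "exc", "slow", "fast")

_NOISE_CHUNK = 20_000  # steps of pre-drawn noise per trial (memory/speed balance)


def _kin_arrays(net: Network) -> tuple[np.ndarray, np.ndarray]:
    R = net.n_rois
    G = np.empty((_N_FILT, R))
    OM = np.empty((_N_FILT, R))
    for r, roi in enumerate(net.rois):
        fam = {"exc": roi.kin_exc, "slow": roi.kin_slow, "fast": roi.kin_fast}
        for k, name in enumerate(_FILT_FAMILY):
            G[k, r] = fam[name].G
            OM[k, r] = fam[name].omega
    return G, OM


def simulate_trials(
    net: Network,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
    seeds: int | list[int] = 0,
    store_psp: bool = True,
    store_rates: bool = False,
    rate_transform: str = "sigmoid",
) -> list[SimOutput]:
    """Integrate ``net`` for one or more independently seeded trials.

    Trials share the deterministic dynamics and differ only in their noise
    streams; each trial's stream is generated from its own seed, so results
    are identical whether trials are run together or one at a time.

    ``rate_transform='identity'`` replaces the sigmoid by the identity map
    (a linearity test hook; not used in production runs).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _, OM = _kin_arrays(net)
    if dt * OM.max() >= 0.1:
        raise ValueError(
            f"dt={dt} too large for fastest synapse (dt*omega_max={dt * OM.max():.3f} >= 0.1)"
        )
    if rate_transform not in ("sigmoid", "identity"):
        raise ValueError("rate_transform must be 'sigmoid' or 'identity'")
    seed_list = [int(seeds)] if np.isscalar(seeds) else [int(s) for s in seeds]
    return _simulate_batch(
        net, float(duration), float(dt), seed_list, store_psp, store_rates, rate_transform
    )


def simulate(
    net: Network,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    store_psp: bool = True,
    store_rates: bool = False,
    rate_transform: str = "sigmoid",
) -> SimOutput:
    """Single-trial convenience wrapper around :func:`simulate_trials`."""
    return simulate_trials(
        net, duration, dt, seed, store_psp, store_rates, rate_transform
    )[0]


def _simulate_batch(
    net: Network,
    duration: float,
    dt: float,
    seeds: list[int],
    store_psp: bool,
    store_rates: bool,
    rate_transform: str,
) -> list[SimOutput]:
    R = net.n_rois
    B = len(seeds)
    n_samples = round(duration / dt)
    G, OM = _kin_arrays(net)
    GW = (G * OM)[:, None, :]  # (8, 1, R) broadcast over trials
    OM_b = OM[:, None, :]
    OM2 = OM_b**2

    e0 = np.array([roi.sigmoid.e0 for roi in net.rois])
    r_sl = np.array([roi.sigmoid.r for roi in net.rois])
    v0 = np.array([roi.sigmoid.v0 for roi in net.rois])
    C = np.stack([roi.C.as_array() for roi in net.rois], axis=1)  # (8, R)
    c_pe, c_ep, c_ps, c_sp, c_pf, c_fp, c_sf, c_ff = (C[k] for k in range(8))
    m_p = np.array([roi.m_p for roi in net.rois])
    m_f = np.array([roi.m_f for roi in net.rois])
    sig_p = np.array([roi.sigma_p for roi in net.rois]) / math.sqrt(dt)
    sig_f = np.array([roi.sigma_f for roi in net.rois]) / math.sqrt(dt)

    use_sigmoid = rate_transform == "sigmoid"

    def rate(v):
        if use_sigmoid:
            return 2.0 * e0 / (1.0 + np.exp(r_sl * (v0 - v)))
        return v.copy()

    # delay ring buffer for pyramidal rates, one slot per lag step
    conns = net.connections
    lags = [max(1, round(c.D / dt)) if c.D > 0 else 0 for c in conns]
    L = max(lags, default=0) + 1
    buf = np.zeros((L, B, R))
    buf[:] = rate(np.zeros((B, R)))  # history primed with the resting rate

    y = np.zeros((_N_FILT, B, R))
    dy = np.zeros((_N_FILT, B, R))
    drive = np.empty((_N_FILT, B, R))

    n_psp = len(conns) if store_psp else 0
    if n_psp:
        # separate per-connection second-order filter with the target ROI's
        # glutamatergic kinetics; by linearity its output equals the share of
        # the lumped afferent potential contributed by that connection
        psp_y = np.zeros((n_psp, B))
        psp_dy = np.zeros((n_psp, B))
        psp_G = np.array([net.rois[c.target].kin_exc.G for c in conns])
        psp_OM = np.array([net.rois[c.target].kin_exc.omega for c in conns])
        psp_out = np.empty((n_samples, n_psp, B))
    vp_out = np.empty((n_samples, B, R))
    rates_out = np.empty((n_samples, B, R)) if store_rates else None

    gens = [np.random.default_rng(s) for s in seeds]
    chunk = min(_NOISE_CHUNK, n_samples)
    eps = np.empty((chunk, 2, B, R))

    check_every = 2000
    for t in range(n_samples):
        k = t % chunk
        if k == 0:
            m = min(chunk, n_samples - t)
            for b, g in enumerate(gens):
                eps[:m, :, b, :] = g.standard_normal((m, 2, R))

        v_p = y[0] - y[1] - y[2]
        v_f = y[5] - y[6] - y[7]
        z_p = rate(v_p)
        z_e = rate(y[3])
        z_s = rate(y[4])
        z_f = rate(v_f)

        vp_out[t] = v_p
        if store_rates:
            rates_out[t] = z_p
        buf[t % L] = z_p

        drive[0] = c_ep * z_e + m_p + sig_p * eps[k, 0]
        drive[1] = c_sp * z_s
        drive[2] = c_fp * z_f
        drive[3] = c_pe * z_p
        drive[4] = c_ps * z_p
        drive[5] = c_pf * z_p + m_f + sig_f * eps[k, 1]
        drive[6] = c_sf * z_s
        drive[7] = c_ff * z_f

        for ci, c in enumerate(conns):
            inp = c.W * buf[(t - lags[ci]) % L][:, c.source]
            drive[0 if c.kind == "excitatory" else 5, :, c.target] += inp
            if n_psp:
                psp_out[t, ci] = psp_y[ci]
                acc = psp_G[ci] * psp_OM[ci] * inp - 2.0 * psp_OM[ci] * psp_dy[ci] - psp_OM[ci] ** 2 * psp_y[ci]
                psp_y[ci] += dt * psp_dy[ci]
                psp_dy[ci] += dt * acc

        # Euler-Maruyama step of y'' = G*omega*u - 2*omega*y' - omega^2*y
        acc = GW * drive
        acc -= 2.0 * OM_b * dy
        acc -= OM2 * y
        y += dt * dy
        dy += dt * acc

        if (t + 1) % check_every == 0 or t == n_samples - 1:
            bad = ~np.isfinite(v_p)
            if bad.any():
                b_ix, r_ix = np.argwhere(bad)[0]
                raise SimulationDiverged(
                    f"non-finite membrane potential in ROI {r_ix} "
                    f"(rhythm={net.rois[r_ix].rhythm}) at t={t * dt:.4f} s, "
                    f"trial seed {seeds[b_ix]}"
                )

    outputs = []
    for b, s in enumerate(seeds):
        psp = {ci: psp_out[:, ci, b].copy() for ci in range(n_psp)} if n_psp else {}
        outputs.append(
            SimOutput(
                vp=vp_out[:, b, :].copy(),
                psp=psp,
                dt_raw=dt,
                duration=duration,
                seed=s,
                network=net,
                rates=rates_out[:, b, :].copy() if store_rates else None,
                meta={"psp_summary": "std of long-range postsynaptic potential"},
            )
        )
    return outputs


def postsynaptic_current_summary(
    out: SimOutput, c: Connection, burn_in: float = 1.0
) -> float:
    """Scalar summary (mV) of the synaptic drive delivered by connection ``c``.

    The summary is the standard deviation over time of the long-range
    postsynaptic potential trace, after discarding ``burn_in`` seconds of
    initial transient.  Zero-strength connections yield exactly 0.
    """
    try:
        ci = out.network.connections.index(c)
    except ValueError:
        raise ValueError(f"connection {c} is not part of the simulated network") from None
    if ci not in out.psp:
        raise ValueError("postsynaptic traces were not stored for this simulation")
    trace = out.psp[ci]
    i0 = min(round(burn_in / out.dt_raw), len(trace) - 1)
    return float(np.std(trace[i0:]))
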