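"""Figure-level scenario runners.

Every runner generates its own ground-truth data with the neural-mass
simulator, pushes it through the preprocessing pipeline (burn-in removal,
50 Hz low-pass, decimation to 100 Hz, variance normalization) and estimates
directed Granger causality in both formulations, writing tidy result
tables.  Defaults reproduce the headline operating conditions: 10 s signals
at 100 Hz, AR order 15, 10 ms delay, 20 trials, alpha = 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import inference, spectra
from .neural_mass import Connection, Network, postsynaptic_current_summary, preset, simulate_trials
from .preprocess import preprocess_sim
from .var_granger import gc_matrix, select_order_aic

__all__ = [
    "ScenarioConfig",
    "two_roi_network",
    "common_input_network",
    "brain_network",
    "four_roi_variants",
    "run_two_roi_sweep",
    "run_input_sweep",
    "run_common_input",
    "run_network",
    "run_sensitivity",
    "normalize_connection_estimates",
    "significance_onset",
]

#: grid of connection strengths used in the published sweeps
DEFAULT_W_GRID = (0, 20, 40, 60, 80, 100, 120)


@dataclass(frozen=True)
class ScenarioConfig:
    """Fixed operating conditions shared by all scenarios."""

    duration: float = 10.0       # analysis length (s)
    burn_in: float = 1.0         # discarded initial transient (s)
    dt: float = 1e-4             # integration step (s)
    fs_out: float = 100.0        # analysis sampling rate (Hz)
    cutoff: float = 50.0         # low-pass cutoff (Hz)
    order: int = 15              # AR model order
    delay: float = 0.010         # long-range transmission delay (s)
    n_trials: int = 20
    alpha: float = 0.05
    base_seed: int = 0
    modes: tuple[str, ...] = ("unconditional", "conditional")
    corrections: tuple[str, ...] = inference.CORRECTIONS

    def trial_seeds(self) -> list[int]:
        return [self.base_seed + t for t in range(self.n_trials)]

    def provenance(self) -> dict:
        d = asdict(self)
        d["config_sha1"] = hashlib.sha1(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        d["seeds"] = self.trial_seeds()
        return d


# ---------------------------------------------------------------------------
# network templates
# ---------------------------------------------------------------------------

def two_roi_network(pair: tuple[str, str], W_fwd: float, W_rev: float,
                    kinds: tuple[str, str] = ("excitatory", "excitatory"),
                    delay: float = 0.010, overrides=(None, None)) -> Network:
    """Two reciprocally connected ROIs.

    Connection 0 is pair[0] -> pair[1] with weight ``W_fwd``; connection 1 is
    the reverse with ``W_rev``.
    """
    rois = tuple(
        preset(b, **(ov or {})) for b, ov in zip(pair, overrides)
    )
    return Network(
        rois=rois,
        connections=(
            Connection(0, 1, W_fwd, kinds[0], delay),
            Connection(1, 0, W_rev, kinds[1], delay),
        ),
    )


def common_input_network(W: float, delay: float = 0.010) -> Network:
    """An alpha ROI (0) driving unconnected theta (1) and beta (2) ROIs."""
    return Network(
        rois=(preset("alpha"), preset("theta"), preset("beta")),
        connections=(
            Connection(0, 1, W, "excitatory", delay),
            Connection(0, 2, W, "excitatory", delay),
        ),
    )


#: 7-ROI ordering: 0 theta-L, 1 beta-L, 2 gamma-L, 3 alpha (thalamic),
#: 4 theta-R, 5 beta-R, 6 gamma-R
BRAIN_ROIS = ("theta", "beta", "gamma", "alpha", "theta", "beta", "gamma")

_BRAIN_EXC_EDGES = (
    # thalamic alpha hub projects to every cortical region
    (3, 0), (3, 1), (3, 2), (3, 4), (3, 5), (3, 6),
    # intra-hemispheric chains: theta -> beta, beta <-> gamma
    (0, 1), (4, 5),
    (1, 2), (2, 1), (5, 6), (6, 5),
)
_BRAIN_INH_EDGES = ((0, 4), (4, 0), (1, 5), (5, 1), (2, 6), (6, 2))


def brain_network(inhibitory: bool = False, W_exc: float = 40.0,
                  W_inh: float = 40.0, delay: float = 0.010) -> Network:
    """Brain-inspired 7-ROI network (two theta, two beta, two gamma, one alpha).

    With ``inhibitory=True`` the three homologous left/right pairs are also
    linked by reciprocal inhibitory connections (six directed inhibitory
    edges).
    """
    conns = [Connection(s, t, W_exc, "excitatory", delay) for s, t in _BRAIN_EXC_EDGES]
    if inhibitory:
        conns += [Connection(s, t, W_inh, "inhibitory", delay) for s, t in _BRAIN_INH_EDGES]
    return Network(rois=tuple(preset(b) for b in BRAIN_ROIS), connections=tuple(conns))


#: Six 4-ROI mixed excitatory/inhibitory fixtures (ROIs: theta, alpha,
#: beta, gamma).  Edge lists are (source, target, W, kind); topologies are
#: documented design fixtures covering chains, rings, hubs and feedback
#: loops with both synapse kinds.
FOUR_ROI_BANDS = ("theta", "alpha", "beta", "gamma")
_FOUR_ROI_VARIANTS: dict[str, tuple] = {
    "chain_mixed": ((3, 0, 40, "excitatory"), (0, 1, 40, "excitatory"),
                    (1, 2, 40, "inhibitory"), (2, 3, 40, "inhibitory")),
    "ring_alternating": ((0, 1, 40, "excitatory"), (1, 2, 40, "inhibitory"),
                         (2, 3, 40, "excitatory"), (3, 0, 40, "inhibitory")),
    "hub_alpha": ((1, 0, 40, "excitatory"), (1, 2, 40, "excitatory"),
                  (1, 3, 40, "inhibitory"), (3, 1, 40, "inhibitory")),
    "feedback_pairs": ((3, 0, 40, "excitatory"), (0, 3, 40, "inhibitory"),
                       (1, 2, 40, "excitatory"), (2, 1, 40, "inhibitory")),
    "fan_in_beta": ((0, 2, 40, "excitatory"), (1, 2, 40, "inhibitory"),
                    (3, 2, 40, "excitatory"), (2, 0, 40, "inhibitory")),
    "two_loops": ((3, 1, 40, "excitatory"), (1, 3, 40, "excitatory"),
                  (0, 2, 40, "inhibitory"), (2, 0, 40, "inhibitory")),
}


def four_roi_variants() -> dict[str, Network]:
    rois = tuple(preset(b) for b in FOUR_ROI_BANDS)
    out = {}
    for name, edges in _FOUR_ROI_VARIANTS.items():
        conns = tuple(Connection(s, t, float(w), k) for s, t, w, k in edges)
        out[name] = Network(rois=rois, connections=conns)
    return out


# ---------------------------------------------------------------------------
# shared pipeline
# ---------------------------------------------------------------------------

def _trial_signals(net: Network, cfg: ScenarioConfig, store_psp: bool = False):
    outs = simulate_trials(
        net, duration=cfg.duration + cfg.burn_in, dt=cfg.dt,
        seeds=cfg.trial_seeds(), store_psp=store_psp,
    )
    tss = [
        preprocess_sim(o, burn_in=cfg.burn_in, cutoff=cfg.cutoff, fs_out=cfg.fs_out)
        for o in outs
    ]
    return outs, tss


def _attach_provenance(df: pd.DataFrame, cfg: ScenarioConfig, **extra) -> pd.DataFrame:
    df.attrs["provenance"] = {**cfg.provenance(), **extra}
    return df


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def run_two_roi_sweep(pair: tuple[str, str] = ("gamma", "theta"),
                      grid=DEFAULT_W_GRID[1:], fixed_W: float = 40.0,
                      kinds: tuple[str, str] = ("excitatory", "excitatory"),
                      cfg: ScenarioConfig = ScenarioConfig(),
                      collect_psds: bool = False):
    """Sweep the pair[0] -> pair[1] weight with the reverse weight fixed.

    Returns a tidy table with one row per (W, trial): GC in both directions
    and both formulations, per-pair p-values, and postsynaptic-potential
    summaries for both connections.  With ``collect_psds=True`` also returns
    a dict (W, roi_index) -> trial-averaged PSD.
    """
    rows = []
    psds: dict[tuple[float, int], spectra.PSD] = {}
    for W in grid:
        net = two_roi_network(pair, W_fwd=float(W), W_rev=float(fixed_W),
                              kinds=kinds, delay=cfg.delay)
        outs, tss = _trial_signals(net, cfg, store_psp=True)
        if collect_psds:
            for r in range(2):
                psds[(float(W), r)] = spectra.average_psds(
                    spectra.welch_psd(ts.data[:, r], ts.fs) for ts in tss
                )
        for trial, (out, ts) in enumerate(zip(outs, tss)):
            row = {"W": float(W), "trial": trial, "seed": out.seed,
                   "psp_fwd": postsynaptic_current_summary(out, net.connections[0]),
                   "psp_rev": postsynaptic_current_summary(out, net.connections[1])}
            for mode in cfg.modes:
                res = gc_matrix(ts, p=cfg.order, mode=mode, alpha=cfg.alpha)
                tag = mode[0]  # 'u' / 'c'
                row[f"gc_{tag}_fwd"] = res.gc[1, 0]
                row[f"gc_{tag}_rev"] = res.gc[0, 1]
                row[f"p_{tag}_fwd"] = res.pval[1, 0]
                row[f"p_{tag}_rev"] = res.pval[0, 1]
            rows.append(row)
    df = _attach_provenance(pd.DataFrame(rows), cfg, scenario="two_roi_sweep",
                            pair=pair, kinds=kinds, fixed_W=fixed_W)
    return (df, psds) if collect_psds else df


def run_input_sweep(pair: tuple[str, str] = ("theta", "gamma"),
                    W_both: float = 80.0,
                    grid=tuple(np.linspace(0.0, 3500.0, 14).round(1)),
                    cfg: ScenarioConfig = ScenarioConfig()) -> pd.DataFrame:
    """Sweep the mean input m_p of the second ROI (nonlinearity probe).

    The first ROI keeps its default operating point (m_p = 400); the swept
    region moves from silence (m_p = 0) through its dynamic range up to
    saturation, so GC from that region rises and then collapses.
    """
    rows = []
    for m_p in grid:
        net = two_roi_network(pair, W_fwd=float(W_both), W_rev=float(W_both),
                              delay=cfg.delay, overrides=(None, {"m_p": float(m_p)}))
        _, tss = _trial_signals(net, cfg)
        for trial, ts in enumerate(tss):
            row = {"m_p": float(m_p), "trial": trial}
            for mode in cfg.modes:
                res = gc_matrix(ts, p=cfg.order, mode=mode, alpha=cfg.alpha)
                tag = mode[0]
                # fwd = from the swept (second) region to the fixed one
                row[f"gc_{tag}_fwd"] = res.gc[0, 1]
                row[f"gc_{tag}_rev"] = res.gc[1, 0]
                row[f"p_{tag}_fwd"] = res.pval[0, 1]
            rows.append(row)
    return _attach_provenance(pd.DataFrame(rows), cfg, scenario="input_sweep",
                              pair=pair, W_both=W_both)


def run_common_input(grid=DEFAULT_W_GRID[1:], cfg: ScenarioConfig = ScenarioConfig()) -> pd.DataFrame:
    """Common-input scenario: alpha drives unconnected theta and beta ROIs.

    All six directed pairs are estimated per trial in both formulations;
    each row carries GC, p-value and the uncorrected significance flag for
    one (W, trial, mode, pair).
    """
    labels = ("alpha", "theta", "beta")
    rows = []
    for W in grid:
        net = common_input_network(float(W), delay=cfg.delay)
        _, tss = _trial_signals(net, cfg)
        for trial, ts in enumerate(tss):
            for mode in cfg.modes:
                res = gc_matrix(ts, p=cfg.order, mode=mode, alpha=cfg.alpha)
                for i in range(3):
                    for j in range(3):
                        if i == j:
                            continue
                        rows.append({
                            "W": float(W), "trial": trial, "mode": mode,
                            "source": labels[j], "target": labels[i],
                            "gc": res.gc[i, j], "pval": res.pval[i, j],
                            "significant": bool(res.pval[i, j] < cfg.alpha),
                        })
    return _attach_provenance(pd.DataFrame(rows), cfg, scenario="common_input")


def significance_onset(table: pd.DataFrame, source: str, target: str, mode: str,
                       rule: str = "group", alpha: float = 0.05,
                       null_bias: float | None = None,
                       min_frac: float = 0.5) -> float | None:
    """Smallest swept W at which the (source -> target) pair is significant.

    ``rule='group'``: one-sided one-sample t-test of the per-trial GC values
    against the small-sample null-bias level of the log-variance-ratio
    estimator (q added parameters over n_obs samples -> E[GC] ~ q/n_obs under
    the null); one call per grid value, pooling the trials.
    ``rule='majority'``: the uncorrected per-trial F test rejects in more
    than ``min_frac`` of trials.  Returns None if no grid value qualifies.
    """
    from scipy import stats

    if null_bias is None:
        prov = table.attrs.get("provenance", {})
        try:
            n_obs = prov["duration"] * prov["fs_out"] - prov["order"]
            null_bias = prov["order"] / n_obs
        except KeyError:
            raise ValueError("null_bias not given and not derivable from table provenance")
    sel = table[(table["source"] == source) & (table["target"] == target)
                & (table["mode"] == mode)]
    for W, grp in sel.groupby("W"):
        if rule == "group":
            p = stats.ttest_1samp(grp["gc"], null_bias, alternative="greater").pvalue
            hit = p < alpha
        elif rule == "majority":
            hit = grp["significant"].mean() > min_frac
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if hit:
            return float(W)
    return None


def run_network(net_id: str = "fig5_excitatory",
                cfg: ScenarioConfig = ScenarioConfig()):
    """Run one of the multi-ROI network scenarios.

    ``fig5_excitatory``: 7-ROI excitatory-only brain network.
    ``fig8_mixed``: the same network plus six interhemispheric inhibitory
    links.  ``fig7_variants``: the six 4-ROI mixed fixtures, returning per
    variant the normalized-share comparison of true weights vs GC estimates.

    Returns ``(aggregates, per_trial_results)`` keyed by mode (and variant
    for fig7).
    """
    if net_id in ("fig5_excitatory", "fig8_mixed"):
        net = brain_network(inhibitory=(net_id == "fig8_mixed"))
        _, tss = _trial_signals(net, cfg)
        results = {mode: [gc_matrix(ts, p=cfg.order, mode=mode, alpha=cfg.alpha,
                                    corrections=cfg.corrections) for ts in tss]
                   for mode in cfg.modes}
        aggregates = {mode: inference.aggregate_trials(res, alpha=cfg.alpha,
                                                       corrections=cfg.corrections)
                      for mode, res in results.items()}
        for agg in aggregates.values():
            agg.meta.update(net_id=net_id, network=net, **cfg.provenance())
        return aggregates, results
    if net_id == "fig7_variants":
        out = {}
        for name, net in four_roi_variants().items():
            _, tss = _trial_signals(net, cfg)
            res = {mode: [gc_matrix(ts, p=cfg.order, mode=mode, alpha=cfg.alpha)
                          for ts in tss] for mode in cfg.modes}
            agg = {mode: inference.aggregate_trials(r, alpha=cfg.alpha) for mode, r in res.items()}
            out[name] = {"network": net, "aggregates": agg,
                         "shares": _variant_shares(net, agg)}
        return out
    raise ValueError(f"unknown net_id {net_id!r}")


def normalize_connection_estimates(values) -> np.ndarray:
    """Normalize per-edge estimates so they sum to one across all edges."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("estimates must be nonnegative")
    tot = v.sum()
    if tot <= 0:
        raise ValueError("all-zero estimates cannot be normalized")
    return v / tot


def _variant_shares(net: Network, aggregates) -> pd.DataFrame:
    """Normalized per-edge shares: true weights vs mean GC estimates."""
    edges = [(c.source, c.target, c.kind) for c in net.connections]
    true_w = np.array([c.W for c in net.connections])
    data = {"true": normalize_connection_estimates(true_w)}
    for mode, agg in aggregates.items():
        est = np.array([max(agg.mean[t, s], 0.0) for s, t, _ in edges])
        data[mode] = normalize_connection_estimates(est)
    df = pd.DataFrame(data, index=[f"{s}->{t}({k})" for s, t, k in edges])
    df["kind"] = [k for _, _, k in edges]
    return df


def run_sensitivity(factors=("signal_length", "order", "delay", "fs"),
                    grids: dict | None = None,
                    pair: tuple[str, str] = ("gamma", "theta"),
                    cfg: ScenarioConfig = ScenarioConfig()) -> pd.DataFrame:
    """One-at-a-time sensitivity of GC to operating parameters.

    Uses the two-ROI reciprocal pair at W = 40 in both directions; every
    factor is swept with the others held at their defaults.
    """
    default_grids = {
        "signal_length": (2.0, 3.0, 5.0, 10.0),
        "order": (5, 8, 9, 15, 20),
        "delay": (0.005, 0.010, 0.020),
        "fs": (100.0, 200.0, 500.0, 1000.0),
    }
    grids = {**default_grids, **(grids or {})}
    rows = []
    for factor in factors:
        for level in grids[factor]:
            c = cfg
            order = cfg.order
            if factor == "signal_length":
                c = replace(cfg, duration=float(level))
            elif factor == "order":
                order = int(level)
            elif factor == "delay":
                c = replace(cfg, delay=float(level))
            elif factor == "fs":
                c = replace(cfg, fs_out=float(level))
            else:
                raise ValueError(f"unknown sensitivity factor {factor!r}")
            net = two_roi_network(pair, 40.0, 40.0, delay=c.delay)
            _, tss = _trial_signals(net, c)
            for trial, ts in enumerate(tss):
                row = {"factor": factor, "level": float(level), "trial": trial}
                for mode in c.modes:
                    res = gc_matrix(ts, p=order, mode=mode, alpha=c.alpha)
                    tag = mode[0]
                    row[f"gc_{tag}_fwd"] = res.gc[1, 0]
                    row[f"gc_{tag}_rev"] = res.gc[0, 1]
                rows.append(row)
    return _attach_provenance(pd.DataFrame(rows), cfg, scenario="sensitivity")


def select_orders_two_roi(pairs=None, p_max: int = 30, cfg: ScenarioConfig = ScenarioConfig()) -> pd.DataFrame:
    """Akaike-selected VAR orders for each two-ROI rhythm pair at W = 40.

    Returns one row per (pair, trial) with the selected order.
    """
    if pairs is None:
        bands = ("theta", "alpha", "beta", "gamma")
        pairs = [(a, b) for ai, a in enumerate(bands) for b in bands[ai + 1:]]
    rows = []
    for pair in pairs:
        net = two_roi_network(tuple(pair), 40.0, 40.0, delay=cfg.delay)
        _, tss = _trial_signals(net, cfg)
        for trial, ts in enumerate(tss):
            rows.append({"pair": f"{pair[0]}-{pair[1]}", "trial": trial,
                         "order": select_order_aic(ts, p_max=p_max)})
    return _attach_provenance(pd.DataFrame(rows), cfg, scenario="order_selection")
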