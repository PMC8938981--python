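"""Network simulation driver: flattens a :class:`~bgnet.network.Network`
into the arrays the numba kernel consumes and wraps the result as a
:class:`SpikeRaster`.

Integration uses a 0.1-ms step by default; conduction delays must be
integer multiples of the step (all table delays are). LIF membranes are
advanced with the midpoint Runge-Kutta scheme, AdEx membranes with
exponential-Euler substeps (their synaptic conductances make the membrane
stiff), and the linear alpha-synapse states with their exact exponential
propagator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from ._kernel import run_kernel
from .network import Network
from .params import AdExParams, ConfigurationError

DEFAULT_DT = 0.1  # ms

#: AdEx numerical spike-cutoff potential (mV)
V_PEAK = 0.0


class SimulationError(RuntimeError):
    pass


@dataclass
class SpikeRaster:
    """Timestamped spike events for one trial.

    ``times`` are in ms within (0, duration]; ``ids`` are global neuron
    ids; ``populations`` maps population name -> (first_id, size).
    """

    times: np.ndarray
    ids: np.ndarray
    duration: float
    populations: dict
    trial: int = 0
    condition: str = ""
    onset: Optional[float] = None

    def population_mask(self, name: str) -> np.ndarray:
        first, size = self.populations[name]
        return (self.ids >= first) & (self.ids < first + size)

    def population_events(self, name: str):
        m = self.population_mask(name)
        return self.times[m], self.ids[m]

    def population_rate(self, name: str, t_start: float = 0.0,
                        t_stop: Optional[float] = None) -> float:
        """Mean single-neuron firing rate (Hz) over [t_start, t_stop)."""
        if t_stop is None:
            t_stop = self.duration
        t, _ = self.population_events(name)
        n = self.populations[name][1]
        nsp = int(np.count_nonzero((t >= t_start) & (t < t_stop)))
        return nsp / n / ((t_stop - t_start) / 1000.0)

    def binned_population_counts(self, name: str, bin_ms: float,
                                 t_start: float = 0.0,
                                 t_stop: Optional[float] = None) -> np.ndarray:
        """Population spike counts in rectangular bins of ``bin_ms``."""
        if t_stop is None:
            t_stop = self.duration
        t, _ = self.population_events(name)
        t = t[(t >= t_start) & (t < t_stop)]
        n_bins = int(round((t_stop - t_start) / bin_ms))
        edges = t_start + np.arange(n_bins + 1) * bin_ms
        counts, _ = np.histogram(t, bins=edges)
        return counts

    def save(self, path) -> None:
        """Delimited event file with a populations manifest header."""
        path = Path(path)
        lines = [f"# trial={self.trial} condition={self.condition} "
                 f"duration={self.duration} onset={self.onset}"]
        for name, (first, size) in self.populations.items():
            lines.append(f"# population {name} {first} {size}")
        lines.append("neuron_id\ttime_ms")
        lines.extend(f"{i}\t{t:.1f}" for i, t in zip(self.ids, self.times))
        path.write_text("\n".join(lines) + "\n")


def _neuron_arrays(network: Network):
    n = network.n_neurons
    arr = {k: np.zeros(n) for k in
           ("C_m", "g_L", "E_L", "V_th", "V_reset", "E_ex", "E_in",
            "tau_ex", "tau_in", "I_e", "a", "b", "Delta_T", "tau_w",
            "V_peak")}
    is_adex = np.zeros(n, dtype=np.bool_)
    for name, pop in network.populations.items():
        p = network.bundle.neuron_params[name]
        s = pop.slice
        arr["C_m"][s] = p.C_m
        arr["g_L"][s] = p.g_L
        arr["E_L"][s] = p.E_L
        arr["V_th"][s] = p.V_th
        arr["V_reset"][s] = p.V_reset
        arr["E_ex"][s] = p.E_ex
        arr["E_in"][s] = p.E_in
        arr["tau_ex"][s] = p.tau_syn_ex
        arr["tau_in"][s] = p.tau_syn_in
        arr["I_e"][s] = p.I_e
        if isinstance(p, AdExParams):
            is_adex[s] = True
            arr["a"][s] = p.a
            arr["b"][s] = p.b
            arr["Delta_T"][s] = p.Delta_T
            arr["tau_w"][s] = p.tau_w
            arr["V_peak"][s] = p.V_peak if p.V_peak is not None else V_PEAK
        else:
            arr["Delta_T"][s] = 1.0
            arr["tau_w"][s] = 1.0
            arr["V_peak"][s] = p.V_th
    return arr, is_adex


def _edge_csr(network: Network, dt: float):
    """Out-edge CSR (sorted by source id) and the delay ring size."""
    n = network.n_neurons
    srcs, tgts, ws, ds = [], [], [], []
    for edges in network.projections.values():
        spec = edges.spec
        dsteps_f = spec.delay / dt
        dsteps = int(round(dsteps_f))
        if abs(dsteps_f - dsteps) > 1e-9:
            raise ConfigurationError(
                f"delay {spec.delay} ms of {spec.name} is not an integer "
                f"multiple of dt={dt} ms"
            )
        n_e = edges.sources.size
        srcs.append(edges.sources.ravel())
        tgts.append(np.repeat(edges.targets, edges.sources.shape[1]))
        ws.append(np.full(n_e, spec.weight))
        ds.append(np.full(n_e, dsteps, dtype=np.int64))
    if srcs:
        src = np.concatenate(srcs)
        order = np.argsort(src, kind="stable")
        src = src[order]
        tgt = np.concatenate(tgts)[order].astype(np.int64)
        w = np.concatenate(ws)[order]
        d = np.concatenate(ds)[order]
    else:
        src = np.zeros(0, dtype=np.int64)
        tgt = np.zeros(0, dtype=np.int64)
        w = np.zeros(0)
        d = np.zeros(0, dtype=np.int64)
    counts = np.bincount(src, minlength=n)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=out_ptr[1:])
    max_d = int(d.max()) if d.size else 1
    return out_ptr, tgt, w, d, max_d + 1


def run(
    network: Network,
    background,
    duration: float,
    seed: int,
    dt: float = DEFAULT_DT,
    stimulus=None,
    onset: Optional[float] = None,
    trial: int = 0,
    record_v: Optional[int] = None,
    spike_capacity: Optional[int] = None,
    V_init: Optional[np.ndarray] = None,
    w_init: Optional[np.ndarray] = None,
):
    """Simulate the network for ``duration`` ms and return a SpikeRaster.

    ``background`` is a :class:`bgnet.inputs.BackgroundDrive`;
    ``stimulus`` an optional :class:`bgnet.inputs.StimulusRealization`
    whose rate profile is placed at ``onset`` (ms). Identical arguments
    and seed give identical rasters.
    """
    n = network.n_neurons
    n_steps = int(round(duration / dt))
    arr, is_adex = _neuron_arrays(network)
    out_ptr, out_tgt, out_w, out_d, n_buf = _edge_csr(network, dt)

    # Input groups: per population, one group of non-stimulated and one of
    # stimulated members. Each group gets a per-neuron background rate and
    # weight; stimulated groups additionally carry the stimulus synaptic
    # weight and have their background scaled during the suppression phase.
    stim_lam = np.zeros(n_steps)
    bg_scale = np.ones(n_steps)
    stim_ids: dict = {}
    if stimulus is not None:
        if onset is None:
            raise ConfigurationError("stimulus requires an onset time")
        stim_lam, bg_scale = stimulus.per_step_arrays(onset, n_steps, dt)
        stim_ids = stimulus.subsets

    members_parts, g_ptr = [], [0]
    g_lam, g_w, g_is_stim, g_stim_w = [], [], [], []
    for name, pop in network.populations.items():
        if background is not None:
            rate, weight, n_src = background.for_population(name)
            lam = rate * n_src * dt / 1000.0
        else:
            lam, weight = 0.0, 0.0
        ids = pop.ids.astype(np.int64)
        sel = stim_ids.get(name)
        if sel is not None and sel.size:
            in_stim = np.zeros(pop.size, dtype=bool)
            in_stim[np.asarray(sel) - pop.first_id] = True
            parts = [(ids[~in_stim], False, 0.0),
                     (ids[in_stim], True,
                      float(stimulus.eff_weights[name]))]
        else:
            parts = [(ids, False, 0.0)]
        for mem, is_stim, sw in parts:
            if mem.size == 0:
                continue
            members_parts.append(mem)
            g_ptr.append(g_ptr[-1] + mem.size)
            g_lam.append(lam)
            g_w.append(weight)
            g_is_stim.append(is_stim)
            g_stim_w.append(sw)
    g_members = (np.concatenate(members_parts) if members_parts
                 else np.zeros(0, dtype=np.int64))
    g_ptr = np.asarray(g_ptr, dtype=np.int64)
    g_lam = np.asarray(g_lam)
    g_w = np.asarray(g_w)
    g_is_stim = np.asarray(g_is_stim, dtype=np.bool_)
    g_stim_w = np.asarray(g_stim_w)

    rng = np.random.default_rng(seed)
    v_lo = arr["E_L"]
    v_hi = arr["V_th"]
    # desynchronized start: V uniform in [E_L, V_th], adaptation at zero
    V0 = v_lo + (v_hi - v_lo) * rng.random(n)
    w0 = np.zeros(n)
    if V_init is not None:
        V0 = np.asarray(V_init, dtype=float).copy()
    if w_init is not None:
        w0 = np.asarray(w_init, dtype=float).copy()
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    ref_steps = int(round(2.0 / dt))
    cap = spike_capacity or max(100_000, int(n * duration / 1000.0 * 150))
    for _attempt in range(3):
        spike_ids = np.zeros(cap, dtype=np.int64)
        spike_steps = np.zeros(cap, dtype=np.int64)
        rec = record_v if record_v is not None else -1
        v_trace = np.zeros(n_steps if rec >= 0 else 1)
        n_rec, status = run_kernel(
            n_steps, dt, kernel_seed,
            arr["C_m"], arr["g_L"], arr["E_L"], arr["V_th"], arr["V_reset"],
            arr["E_ex"], arr["E_in"], arr["tau_ex"], arr["tau_in"],
            arr["I_e"], is_adex, arr["a"], arr["b"], arr["Delta_T"],
            arr["tau_w"], arr["V_peak"], ref_steps,
            out_ptr, out_tgt, out_w, out_d, n_buf,
            g_ptr, g_members, g_lam, g_w, g_is_stim, g_stim_w,
            stim_lam, bg_scale,
            V0, w0, spike_ids, spike_steps, rec, v_trace,
        )
        if status == 2:
            raise SimulationError(
                "membrane potential diverged (non-finite V); check weights"
            )
        if status == 0:
            break
        cap *= 4  # overflow: retry with a larger spike buffer
    else:
        raise SimulationError("spike buffer overflow after retries")

    times = (spike_steps[:n_rec] + 1) * dt
    raster = SpikeRaster(
        times=times, ids=spike_ids[:n_rec].astype(np.int32),
        duration=duration,
        populations={name: (p.first_id, p.size)
                     for name, p in network.populations.items()},
        trial=trial, condition=network.bundle.name, onset=onset,
    )
    if record_v is not None:
        raster.v_trace = v_trace  # type: ignore[attr-defined]
    return raster
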