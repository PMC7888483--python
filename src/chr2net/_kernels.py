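"""Compiled inner loops for the simulators.

One kernel advances a population of LIF neurons with embedded ChR2
channels and per-neuron Ornstein-Uhlenbeck input over a chunk of steps.
The same kernel serves both the single-neuron batch driver (neurons =
independent trials, no coupling) and the recurrent network driver
(neurons = E grid + I pool, CSR out-edge coupling), so the two paths are
numerically identical in the decoupled limit.

Noise is pre-drawn outside the kernel with a seeded numpy Generator;
chunking does not alter the stream, so results are independent of the
chunk size used.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_chunk", "spike_capacity"]


def spike_capacity(n_neurons: int, chunk_steps: int, ref_steps: int) -> int:
    """Upper bound on spikes a chunk can produce (refractoriness limits rate)."""
    per_neuron = chunk_steps // max(ref_steps, 1) + 2
    return n_neurons * per_neuron


@njit(cache=True)
def step_chunk(
    # mutable per-neuron state
    V, O, D, Iext, Isyn, ref_count,
    # per-neuron constants
    light_scale,  # spatial light factor in [0, 1]; 0 disables the channel
    n_g,          # N_ChR2 * g_ChR2, S; 0 for neurons without channels
    # per-step schedule and noise
    drive,        # eps * p(t_s) * phi(E_hat at t_s), 1/s, at unit light_scale
    z,            # (chunk_steps, n) standard normals
    # recurrent coupling, CSR over out-edges (row = presynaptic neuron)
    indptr, indices, weights,  # weights already J_ij / tau_syn, A
    syn_decay,    # exp(-dt / tau_syn)
    # scalars
    step0, dt,
    alpha_ou, ou_step_sd, I0,
    gd0, gd_slope, gd_vref, gr,
    e_chr2, gm, vrev, cm_inv, vth, vreset, ref_steps,
    # outputs
    spike_neuron, spike_step, sumO, v_out, record_v,
):
    """Advance all neurons by ``z.shape[0]`` explicit-Euler steps of size dt.

    Returns ``(n_spikes, n_clip)``: number of spikes written to the
    buffers and number of channel-simplex clippings.  Spike steps are
    absolute (``step0`` offset included) and refer to the post-step time,
    i.e. time = step * dt.
    """
    m = z.shape[0]
    n = V.shape[0]
    coupled = weights.size > 0
    ns = 0
    n_clip = 0
    for s in range(m):
        ns_step0 = ns
        a_s = drive[s]
        for i in range(n):
            # Ornstein-Uhlenbeck external input, exact discretization
            Iext[i] = I0 + (Iext[i] - I0) * alpha_ou + ou_step_sd * z[s, i]
            # ChR2 channel (skipped when the neuron has no light drive and
            # all channels are closed)
            if light_scale[i] > 0.0 or O[i] > 0.0:
                gd = gd0 * (1.0 - gd_slope * (V[i] - gd_vref))
                if gd < 0.0:
                    gd = 0.0
                a = a_s * light_scale[i]
                dO = (a * (1.0 - O[i] - D[i]) - gd * O[i]) * dt
                dD = (gd * O[i] - gr * D[i]) * dt
                O[i] += dO
                D[i] += dD
                if O[i] < 0.0 or D[i] < 0.0 or O[i] + D[i] > 1.0:
                    n_clip += 1
                    if O[i] < 0.0:
                        O[i] = 0.0
                    if D[i] < 0.0:
                        D[i] = 0.0
                    tot = O[i] + D[i]
                    if tot > 1.0:
                        O[i] /= tot
                        D[i] /= tot
            i_chr2 = -(V[i] - e_chr2) * n_g[i] * O[i]
            # leaky integrate-and-fire membrane
            if ref_count[i] > 0:
                V[i] = vreset
                ref_count[i] -= 1
            else:
                itot = Iext[i] + Isyn[i] + i_chr2
                V[i] += dt * cm_inv * (-gm * (V[i] - vrev) + itot)
                if V[i] >= vth:
                    V[i] = vreset
                    ref_count[i] = ref_steps
                    spike_neuron[ns] = i
                    spike_step[ns] = step0 + s + 1
                    ns += 1
            if record_v:
                v_out[s, i] = V[i]
            sumO[s] += O[i]
        # recurrent synapses: decay, then deposit this step's spikes
        if coupled:
            for i in range(n):
                Isyn[i] *= syn_decay
            for k in range(ns_step0, ns):
                j = spike_neuron[k]
                for e in range(indptr[j], indptr[j + 1]):
                    Isyn[indices[e]] += weights[e]
    return ns, n_clip
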