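"""Fixed-step integration kernel (numba).

One generic routine advances an arbitrary network of 3-variable nonspiking
neurons, graded instantaneous synapses, and second-order antagonistic
muscle-pair joints by one supervision interval.  The same kernel serves
the 216-neuron six-leg model, single-leg assemblies and the two-neuron
half-center circuits of the unit-level API; only the arrays differ.

State is mutated in place; all discrete logic (sensory gates, behavioral
modes, interleg rules) lives outside in the Python supervisor, which
rewrites the control-conductance vectors between calls.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def step_network(V, m, q,
                 nC, ngL, nEL, ngP, nEP, nthm, nsm, ntaum,
                 ngq, nEK, nthq, nsq, ntauq,
                 syn_pre, syn_post, syn_g, syn_E, syn_grp, grp_gain,
                 gexc, ginh, E_ex, E_inh, th_s, s_s,
                 theta, omega, jmn, jlim, jgain, jslow,
                 jdamp, jinert, th_a, s_a, a_floor,
                 dt, n_sub):
    """Advance the network by ``n_sub`` explicit-Euler substeps of ``dt``."""
    n = V.shape[0]
    nsyn = syn_pre.shape[0]
    nj = theta.shape[0]
    s = np.empty(n)
    gsyn_e = np.empty(n)
    gsyn_i = np.empty(n)
    for _ in range(n_sub):
        # graded synaptic transfer of presynaptic voltage
        for i in range(n):
            s[i] = 1.0 / (1.0 + np.exp(-(V[i] - th_s) / s_s))
            gsyn_e[i] = gexc[i]
            gsyn_i[i] = ginh[i]
        for k in range(nsyn):
            g = syn_g[k] * grp_gain[syn_grp[k]] * s[syn_pre[k]]
            if syn_E[k] > -40.0:
                gsyn_e[syn_post[k]] += g
            else:
                gsyn_i[syn_post[k]] += g
        # membrane update
        for i in range(n):
            v = V[i]
            I = (-ngL[i] * (v - nEL[i])
                 - ngP[i] * m[i] * (v - nEP[i])
                 - ngq[i] * q[i] * (v - nEK[i])
                 - gsyn_e[i] * (v - E_ex)
                 - gsyn_i[i] * (v - E_inh))
            V[i] = v + dt * I / nC[i]
            minf = 1.0 / (1.0 + np.exp(-(V[i] - nthm[i]) / nsm[i]))
            qinf = 1.0 / (1.0 + np.exp(-(V[i] - nthq[i]) / nsq[i]))
            m[i] += dt * (minf - m[i]) / ntaum[i]
            q[i] += dt * (qinf - q[i]) / ntauq[i]
            if m[i] < 0.0:
                m[i] = 0.0
            elif m[i] > 1.0:
                m[i] = 1.0
            if q[i] < 0.0:
                q[i] = 0.0
            elif q[i] > 1.0:
                q[i] = 1.0
        # joints: J th'' = sum_i gain_i a_i (lim_i - th) - c th'
        for j in range(nj):
            torque = 0.0
            for u in range(4):
                mn = jmn[j, u]
                if mn < 0:
                    continue
                if jslow[j, u]:
                    a = q[mn]          # slow muscle: calcium-like signal
                else:
                    a = 1.0 / (1.0 + np.exp(-(V[mn] - th_a) / s_a))
                a -= a_floor           # recruitment threshold: a resting
                if a <= 0.0:           # MN produces no force at all
                    continue
                torque += jgain[j, u] * a * (jlim[j, u] - theta[j])
            omega[j] += dt * (torque - jdamp[j] * omega[j]) / jinert[j]
            theta[j] += dt * omega[j]


@njit(cache=True)
def joint_trajectory(theta0, omega0, act, lims, gains, damp, inert, dt):
    """Integrate one joint under prescribed muscle activations.

    ``act`` is (n, 4) activation samples (one row per dt step); returns the
    (n, 2) trajectory of angle and angular velocity.
    """
    n = act.shape[0]
    out = np.empty((n, 2))
    th = theta0
    om = omega0
    for i in range(n):
        torque = 0.0
        for u in range(4):
            torque += gains[u] * act[i, u] * (lims[u] - th)
        om += dt * (torque - damp * om) / inert
        th += dt * om
        out[i, 0] = th
        out[i, 1] = om
    return out
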