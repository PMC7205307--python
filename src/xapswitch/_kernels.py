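"""Numba kernels for the discrete-molecule simulator.

The reaction network is encoded in a flat float64 parameter vector
``theta`` so that the propensity evaluation, the direct (Gillespie) solver
and the hybrid SSA/tau-leap solver can all be JIT-compiled.  Species order
is (M, P, X) = (mRNA, protein, intracellular xanthosine); reaction order:

    0 transcription        +M   a = A_TX * p_active(X / Omega)
    1 mRNA decay           -M   a = G_MP * M
    2 translation          +P   a = RHO_P * M
    3 protein decay        -P   a = G_P * P
    4 XapB import          +X   a = KBI_C * P
    5 XapB export          -X   a = KBE * (X/Om)/(KBE_K + X/Om) * P
    6 XapA degradation     -X   a = KAL * (X/Om)/(1 + X/Om) * P
    7 Nup influx           +X   a = ETA_IN
    8 Nup efflux           -X   a = ETA_X * X

Propensities are chosen so that S^T a(Omega * y) = Omega * rhs(y): the
macroscopic rate equations are recovered in the large-volume limit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# theta layout
A_TX, G_MP, RHO_P, G_P, KBI_C, KBE, KBE_K, KAL, ETA_IN, ETA_X = range(10)
OMEGA, KCHIA, KIA, EDX, ECOOP, XRR, N_IND, N_PROM, POLICY, CONST_PACT = range(10, 20)
BURST_M, BURST_P = 20, 21
THETA_LEN = 22

N_REACTIONS = 9
N_SPECIES = 3

#: stoichiometry matrix, reactions x species
STOICH = np.array([
    [1, 0, 0],
    [-1, 0, 0],
    [0, 1, 0],
    [0, -1, 0],
    [0, 0, 1],
    [0, 0, -1],
    [0, 0, -1],
    [0, 0, 1],
    [0, 0, -1],
], dtype=np.int64)


@njit(cache=True)
def p_active_kernel(x_conc, theta):
    """Promoter activity at xanthosine concentration ``x_conc`` (K_a units)."""
    if theta[CONST_PACT] >= 0.0:
        return theta[CONST_PACT]
    u = x_conc / theta[KCHIA]
    if theta[N_IND] > 1.5:
        act = (1.0 + u) ** 2
        inact = theta[EDX] * (1.0 + u / theta[KIA]) ** 2
    else:
        act = 1.0 + u
        inact = theta[EDX] * (1.0 + u / theta[KIA])
    r = theta[XRR] * act / (act + inact)
    if theta[N_PROM] < 1.5:
        return r / (1.0 + r)
    w = r * r * theta[ECOOP]
    num = 2.0 * r + w if theta[POLICY] > 0.5 else w
    return num / (1.0 + 2.0 * r + w)


@njit(cache=True)
def propensities_kernel(counts, theta, a):
    """Fill ``a`` (length 9) with propensities at integer ``counts``."""
    M = counts[0]
    P = counts[1]
    X = counts[2]
    om = theta[OMEGA]
    xc = X / om
    a[0] = theta[A_TX] * p_active_kernel(xc, theta)
    a[1] = theta[G_MP] * M
    a[2] = theta[RHO_P] * M
    a[3] = theta[G_P] * P
    a[4] = theta[KBI_C] * P
    a[5] = theta[KBE] * xc / (theta[KBE_K] + xc) * P if X > 0 else 0.0
    a[6] = theta[KAL] * xc / (1.0 + xc) * P if X > 0 else 0.0
    a[7] = theta[ETA_IN]
    a[8] = theta[ETA_X] * X
    return a


@njit(cache=True)
def _burst_size(mean):
    if mean <= 1.0:
        return 1
    return np.random.geometric(1.0 / mean)


@njit(cache=True)
def _apply_reaction(counts, r, theta):
    if r == 0:
        counts[0] += _burst_size(theta[BURST_M])
    elif r == 2:
        counts[1] += _burst_size(theta[BURST_P])
    else:
        for s in range(N_SPECIES):
            counts[s] += STOICH[r, s]


@njit(cache=True)
def simulate_direct_kernel(theta, counts0, t_end, seed, max_events,
                           sample_times, fp_species, fp_value):
    """Exact SSA.  Returns (samples, final, t_final, n_events, fp_time, status).

    status 0 = reached t_end, 1 = event budget exhausted.  ``fp_time`` is
    the first time counts[fp_species] >= fp_value, or -1 if never
    (fp_species < 0 disables first-passage tracking).
    """
    np.random.seed(seed)
    counts = counts0.copy()
    a = np.zeros(N_REACTIONS)
    nsamp = sample_times.shape[0]
    samples = np.zeros((nsamp, N_SPECIES), dtype=np.int64)
    s_idx = 0
    t = 0.0
    n_events = 0
    fp_time = -1.0
    if fp_species >= 0 and counts[fp_species] >= fp_value:
        fp_time = 0.0
    status = 0
    while t < t_end:
        propensities_kernel(counts, theta, a)
        atot = 0.0
        for r in range(N_REACTIONS):
            atot += a[r]
        if atot <= 0.0:
            break
        dt = -np.log(np.random.random()) / atot
        t_new = t + dt
        while s_idx < nsamp and sample_times[s_idx] < t_new:
            for s in range(N_SPECIES):
                samples[s_idx, s] = counts[s]
            s_idx += 1
        if t_new >= t_end:
            t = t_end
            break
        t = t_new
        u = np.random.random() * atot
        acc = 0.0
        r_sel = N_REACTIONS - 1
        for r in range(N_REACTIONS):
            acc += a[r]
            if u < acc:
                r_sel = r
                break
        _apply_reaction(counts, r_sel, theta)
        n_events += 1
        if fp_species >= 0 and fp_time < 0.0 and counts[fp_species] >= fp_value:
            fp_time = t
        if n_events >= max_events:
            status = 1
            break
    while s_idx < nsamp:
        for s in range(N_SPECIES):
            samples[s_idx, s] = counts[s]
        s_idx += 1
    return samples, counts, t, n_events, fp_time, status


@njit(cache=True)
def simulate_hybrid_kernel(theta, counts0, t_end, seed, max_steps,
                           sample_times, fp_species, fp_value,
                           eps, count_threshold, rate_threshold):
    """Partitioned SSA / tau-leap solver.

    Channels with propensity >= ``rate_threshold`` whose consumed species
    all exceed ``count_threshold`` are advanced by Poisson tau-leaps with
    the bounded-relative-change step (parameter ``eps``); the remaining
    channels fire as exact SSA events with propensities frozen over each
    leap.  The partition is re-evaluated every macro-step; leaps that
    would drive a count negative are halved and re-drawn.
    """
    np.random.seed(seed)
    counts = counts0.copy()
    a = np.zeros(N_REACTIONS)
    fast = np.zeros(N_REACTIONS, dtype=np.bool_)
    mu = np.zeros(N_SPECIES)
    sig2 = np.zeros(N_SPECIES)
    trial = np.zeros(N_SPECIES, dtype=np.int64)
    nsamp = sample_times.shape[0]
    samples = np.zeros((nsamp, N_SPECIES), dtype=np.int64)
    s_idx = 0
    t = 0.0
    n_steps = 0
    fp_time = -1.0
    if fp_species >= 0 and counts[fp_species] >= fp_value:
        fp_time = 0.0
    status = 0

    while t < t_end:
        n_steps += 1
        if n_steps >= max_steps:
            status = 1
            break
        propensities_kernel(counts, theta, a)
        atot = 0.0
        for r in range(N_REACTIONS):
            atot += a[r]
        if atot <= 0.0:
            break

        # partition
        n_fast = 0
        slow_sum = 0.0
        for r in range(N_REACTIONS):
            ok = a[r] >= rate_threshold
            if ok:
                for s in range(N_SPECIES):
                    if STOICH[r, s] < 0 and counts[s] < count_threshold:
                        ok = False
            fast[r] = ok
            if ok:
                n_fast += 1
            else:
                slow_sum += a[r]

        do_exact = n_fast == 0
        if not do_exact:
            # Cao's bounded relative-change leap over fast channels
            for s in range(N_SPECIES):
                mu[s] = 0.0
                sig2[s] = 0.0
            for r in range(N_REACTIONS):
                if fast[r]:
                    for s in range(N_SPECIES):
                        v = STOICH[r, s]
                        if v != 0:
                            mu[s] += v * a[r]
                            sig2[s] += v * v * a[r]
            tau1 = t_end - t
            for s in range(N_SPECIES):
                if sig2[s] > 0.0:
                    bnd = eps * counts[s]
                    if bnd < 1.0:
                        bnd = 1.0
                    if mu[s] != 0.0:
                        c1 = bnd / abs(mu[s])
                        if c1 < tau1:
                            tau1 = c1
                    c2 = bnd * bnd / sig2[s]
                    if c2 < tau1:
                        tau1 = c2
            if tau1 < 10.0 / atot:
                do_exact = True  # leap not worthwhile; fall back to SSA

        if do_exact:
            dt = -np.log(np.random.random()) / atot
            t_new = t + dt
            while s_idx < nsamp and sample_times[s_idx] < t_new:
                for s in range(N_SPECIES):
                    samples[s_idx, s] = counts[s]
                s_idx += 1
            if t_new >= t_end:
                t = t_end
                break
            t = t_new
            u = np.random.random() * atot
            acc = 0.0
            r_sel = N_REACTIONS - 1
            for r in range(N_REACTIONS):
                acc += a[r]
                if u < acc:
                    r_sel = r
                    break
            _apply_reaction(counts, r_sel, theta)
            if fp_species >= 0 and fp_time < 0.0 and counts[fp_species] >= fp_value:
                fp_time = t
            continue

        tau2 = t_end - t + 1.0
        if slow_sum > 0.0:
            tau2 = -np.log(np.random.random()) / slow_sum
        tau = tau1 if tau1 < tau2 else tau2
        if tau > t_end - t:
            tau = t_end - t
            if tau <= 0.0:
                break

        # leap, halving on negative excursions
        while True:
            for s in range(N_SPECIES):
                trial[s] = counts[s]
            for r in range(N_REACTIONS):
                if fast[r]:
                    k = np.random.poisson(a[r] * tau)
                    if k > 0:
                        if r == 0:
                            if theta[BURST_M] > 1.0:
                                tot = 0
                                for _ in range(k):
                                    tot += _burst_size(theta[BURST_M])
                                trial[0] += tot
                            else:
                                trial[0] += k
                        elif r == 2:
                            if theta[BURST_P] > 1.0:
                                tot = 0
                                for _ in range(k):
                                    tot += _burst_size(theta[BURST_P])
                                trial[1] += tot
                            else:
                                trial[1] += k
                        else:
                            for s in range(N_SPECIES):
                                if STOICH[r, s] != 0:
                                    trial[s] += STOICH[r, s] * k
            fire_slow = tau2 <= tau
            if fire_slow and slow_sum > 0.0:
                u = np.random.random() * slow_sum
                acc = 0.0
                r_sel = -1
                for r in range(N_REACTIONS):
                    if not fast[r]:
                        acc += a[r]
                        if u < acc:
                            r_sel = r
                            break
                if r_sel >= 0:
                    if r_sel == 0:
                        trial[0] += _burst_size(theta[BURST_M])
                    elif r_sel == 2:
                        trial[1] += _burst_size(theta[BURST_P])
                    else:
                        for s in range(N_SPECIES):
                            trial[s] += STOICH[r_sel, s]
            neg = False
            for s in range(N_SPECIES):
                if trial[s] < 0:
                    neg = True
            if not neg:
                break
            tau *= 0.5
            if tau <= 1e-300:
                status = 2  # tau underflow: thresholds unsuitable
                break
        if status == 2:
            break

        t_new = t + tau
        while s_idx < nsamp and sample_times[s_idx] < t_new:
            for s in range(N_SPECIES):
                samples[s_idx, s] = counts[s]
            s_idx += 1
        t = t_new
        for s in range(N_SPECIES):
            counts[s] = trial[s]
        if fp_species >= 0 and fp_time < 0.0 and counts[fp_species] >= fp_value:
            fp_time = t

    while s_idx < nsamp:
        for s in range(N_SPECIES):
            samples[s_idx, s] = counts[s]
        s_idx += 1
    return samples, counts, t, n_steps, fp_time, status
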