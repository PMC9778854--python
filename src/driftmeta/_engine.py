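"""Compiled forward-simulation kernel (numba).

One call simulates one population for a fixed number of generations and
returns class-wise diversity sums and polymorphism/fixation counts. The
kernel owns its RNG (numba's internal generator, seeded per call), so a
given (seed, config) pair is bit-reproducible.

Mutations are stored as rows of a fixed-capacity genotype matrix over the
2N haplotypes; the caller grows the capacity and retries on overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DFE_FIXED_ZERO = 0
DFE_GAMMA = 1
DFE_GAMMA_BENEFICIAL = 2


@njit(cache=True)
def run_kernel(
    seed,
    n_gen,
    N,
    L,
    mu,
    rec,
    sex_interval,
    f_nonsyn,
    h,
    dfe_kind,
    gamma_shape,
    gamma_scale,
    beneficial_fraction,
    beneficial_s,
    cap,
    sample_start=-1,
):
    """``sample_start`` >= 0 switches the diversity output from the
    endpoint value to the time-average over generations > sample_start
    (an ergodic-averaging variance reduction; the expectation is the
    same)."""
    np.random.seed(seed)
    n2 = 2 * N
    geno = np.zeros((cap, n2), dtype=np.uint8)
    buf = np.zeros((cap, n2), dtype=np.uint8)
    sites = np.zeros(cap, dtype=np.int64)
    nonsyn = np.zeros(cap, dtype=np.uint8)
    sel = np.zeros(cap)
    freq = np.zeros(cap, dtype=np.int64)
    logw = np.zeros(N)
    cumw = np.zeros(N)
    cols = np.zeros(n2, dtype=np.int64)
    M = 0
    D_n = 0
    D_s = 0
    overflow = False
    lam_mut = 2.0 * N * L * mu
    lam_rec = rec * max(L - 1, 0)
    avg_pi_n = 0.0
    avg_pi_s = 0.0
    n_samples = 0

    for gen in range(1, n_gen + 1):
        # ---- purge lost mutations, count fixations -----------------
        if M > 0:
            for m in range(M):
                c = 0
                for j in range(n2):
                    c += geno[m, j]
                freq[m] = c
            if sample_start >= 0 and gen > sample_start:
                for m in range(M):
                    c = freq[m]
                    if 0 < c < n2:
                        p = c / n2
                        het = 2.0 * p * (1.0 - p) * n2 / (n2 - 1.0)
                        if nonsyn[m] == 1:
                            avg_pi_n += het
                        else:
                            avg_pi_s += het
            k = 0
            for m in range(M):
                if freq[m] == n2:
                    if nonsyn[m] == 1:
                        D_n += 1
                    else:
                        D_s += 1
                elif freq[m] > 0:
                    if k != m:
                        geno[k, :] = geno[m, :]
                        sites[k] = sites[m]
                        nonsyn[k] = nonsyn[m]
                        sel[k] = sel[m]
                    k += 1
            M = k
        if sample_start >= 0 and gen > sample_start:
            n_samples += 1

        # ---- fitness-proportional parent sampling weights ----------
        selected = False
        for m in range(M):
            if sel[m] != 0.0:
                selected = True
                break
        if selected:
            for i in range(N):
                logw[i] = 0.0
            for m in range(M):
                if sel[m] == 0.0:
                    continue
                f_het = 1.0 + h * sel[m]
                f_hom = 1.0 + sel[m]
                lh = np.log(f_het) if f_het > 1e-300 else -690.0
                lo = np.log(f_hom) if f_hom > 1e-300 else -690.0
                for i in range(N):
                    d = geno[m, 2 * i] + geno[m, 2 * i + 1]
                    if d == 1:
                        logw[i] += lh
                    elif d == 2:
                        logw[i] += lo
            mx = logw[0]
            for i in range(1, N):
                if logw[i] > mx:
                    mx = logw[i]
            tot = 0.0
            for i in range(N):
                tot += np.exp(logw[i] - mx)
                cumw[i] = tot
            if tot <= 0.0:
                selected = False

        # ---- offspring generation ----------------------------------
        sexual = gen % sex_interval == 0
        if not sexual:
            for i in range(N):
                if selected:
                    u = np.random.random() * cumw[N - 1]
                    p = np.searchsorted(cumw, u)
                    if p >= N:
                        p = N - 1
                else:
                    p = np.random.randint(0, N)
                cols[2 * i] = 2 * p
                cols[2 * i + 1] = 2 * p + 1
            for m in range(M):
                for j in range(n2):
                    buf[m, j] = geno[m, cols[j]]
        else:
            for i in range(N):
                p1 = 0
                for k_par in range(2):
                    while True:
                        if selected:
                            u = np.random.random() * cumw[N - 1]
                            p = np.searchsorted(cumw, u)
                            if p >= N:
                                p = N - 1
                        else:
                            p = np.random.randint(0, N)
                        if k_par == 0:
                            p1 = p
                            break
                        if p != p1:
                            break
                    ncross = np.random.poisson(lam_rec)
                    start = np.random.randint(0, 2)
                    if ncross == 0:
                        src = 2 * p + start
                        for m in range(M):
                            buf[m, 2 * i + k_par] = geno[m, src]
                    else:
                        breaks = np.sort(
                            np.random.random(ncross) * (L - 1)
                        )
                        for m in range(M):
                            nb = np.searchsorted(breaks, float(sites[m]))
                            hap = (start + nb) % 2
                            buf[m, 2 * i + k_par] = geno[m, 2 * p + hap]
        tmp = geno
        geno = buf
        buf = tmp

        # ---- new mutations -----------------------------------------
        n_new = np.random.poisson(lam_mut)
        for _ in range(n_new):
            if M >= cap:
                overflow = True
                break
            geno[M, :] = 0
            geno[M, np.random.randint(0, n2)] = 1
            sites[M] = np.random.randint(0, L)
            if np.random.random() < f_nonsyn:
                nonsyn[M] = 1
                if dfe_kind == DFE_FIXED_ZERO:
                    sel[M] = 0.0
                elif (
                    dfe_kind == DFE_GAMMA_BENEFICIAL
                    and np.random.random() < beneficial_fraction
                ):
                    sel[M] = beneficial_s
                else:
                    sel[M] = -np.random.gamma(gamma_shape, gamma_scale)
            else:
                nonsyn[M] = 0
                sel[M] = 0.0
            M += 1
        if overflow:
            break

    # ---- final purge and summaries ---------------------------------
    pi_n_sum = 0.0
    pi_s_sum = 0.0
    n_seg_n = 0
    n_seg_s = 0
    for m in range(M):
        c = 0
        for j in range(n2):
            c += geno[m, j]
        if c == n2:
            if nonsyn[m] == 1:
                D_n += 1
            else:
                D_s += 1
        elif c > 0:
            p = c / n2
            het = 2.0 * p * (1.0 - p) * n2 / (n2 - 1.0)
            if nonsyn[m] == 1:
                pi_n_sum += het
                n_seg_n += 1
            else:
                pi_s_sum += het
                n_seg_s += 1
    if n_samples > 0:
        pi_n_sum = avg_pi_n / n_samples
        pi_s_sum = avg_pi_s / n_samples
    return pi_n_sum, pi_s_sum, n_seg_n, n_seg_s, D_n, D_s, overflow
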