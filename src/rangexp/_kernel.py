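"""Numba kernels for the structured-coalescent simulator.

Time runs backward from the present in units of 2*N_ref generations. The
demographic history is compiled (by :mod:`rangexp.simulate`) into piecewise
epochs: per epoch and deme a size curve nu(t) relative to N_ref (constant,
exponential or logistic), a constant backward migration-rate matrix, and
discrete events (founding divergences, admixture pulses) pinned to epoch
boundaries. Waiting times under time-varying coalescence rates are drawn by
thinning; the proposal window is shortened adaptively so the bound never
overshoots the true rate by more than ~2x.

Size-curve encodings (``size_p[e, d]``):
  form 0 (constant):     (nu, -, -)
  form 1 (exponential):  (nu_recent, lg, g) with lg = ln(nu_old/nu_recent) and
                         nu(t) = nu_recent * exp(lg * (t-te)/(te1-te));
                         g = |lg|/(te1-te) is the log-slope bound
  form 2 (logistic):     (K, x0, r): nu(t) = K*x0*e^(r*tau)/(1-x0+x0*e^(r*tau)),
                         tau = te1 - t (forward time from the epoch's old end)
"""

import numpy as np
from numba import njit

BIG_TIME = 1e30

EV_FOUNDING = 0
EV_PULSE = 1


@njit(cache=True, fastmath=True)
def _nu_eval(e, d, t, epoch_times, size_form, size_p):
    form = size_form[e, d]
    if form == 0:
        return size_p[e, d, 0]
    te = epoch_times[e]
    te1 = epoch_times[e + 1]
    if form == 1:
        nur = size_p[e, d, 0]
        lg = size_p[e, d, 1]
        return nur * np.exp(lg * (t - te) / (te1 - te))
    K = size_p[e, d, 0]
    x0 = size_p[e, d, 1]
    r = size_p[e, d, 2]
    ert = np.exp(r * (te1 - t))
    return K * x0 * ert / (1.0 - x0 + x0 * ert)


@njit(cache=True, fastmath=True)
def _log_slope(e, d, epoch_times, size_form, size_p):
    """Upper bound on |d ln nu / dt| within epoch e for deme d."""
    if size_form[e, d] == 0:
        return 0.0
    return size_p[e, d, 2]  # exponential: |lg|/duration; logistic: r


@njit(cache=True)
def _pick_in_deme(lin_deme, k, d, ordinal):
    """Index of the ordinal-th active lineage currently in deme d."""
    seen = 0
    for i in range(k):
        if lin_deme[i] == d:
            if seen == ordinal:
                return i
            seen += 1
    return -1


@njit(cache=True, fastmath=True)
def sim_genealogy(
    epoch_times,
    size_form,
    size_p,
    mig,
    mig_out,
    ev_bidx,
    ev_kind,
    ev_src,
    ev_dst,
    ev_frac,
    sample_demes,
    t_max,
    children,
    node_birth,
    node_death,
    lin_node,
    lin_deme,
    deme_count,
):
    """Simulate one genealogy; fills children/node_birth/node_death.

    Returns 1 on success, 0 if the sample failed to coalesce by t_max or the
    scenario leaves isolated lineages with no remaining events.
    """
    n = sample_demes.size
    n_demes = mig.shape[1]
    n_ev = ev_bidx.size
    for i in range(n):
        lin_node[i] = i
        lin_deme[i] = sample_demes[i]
        node_birth[i] = 0.0
        children[i, 0] = -1
        children[i, 1] = -1
    for d in range(n_demes):
        deme_count[d] = 0
    for i in range(n):
        deme_count[sample_demes[i]] += 1
    k = n
    next_node = n
    t = 0.0
    e = 0
    while k > 1:
        t_epoch_end = epoch_times[e + 1]
        # inner loop: proposals within the epoch
        need_bound = True
        t_seg_end = t_epoch_end
        R = 0.0
        while k > 1:
            if need_bound:
                # adaptive proposal window so size curves vary < ~2x inside it
                g_max = 0.0
                for d in range(n_demes):
                    if deme_count[d] > 1:
                        g = _log_slope(e, d, epoch_times, size_form, size_p)
                        if g > g_max:
                            g_max = g
                if g_max > 0.0:
                    t_seg_end = min(t_epoch_end, t + 0.6931471805599453 / g_max)
                else:
                    t_seg_end = t_epoch_end
                # bound on the total event rate over [t, t_seg_end)
                R = 0.0
                for d in range(n_demes):
                    kd = deme_count[d]
                    if kd > 0:
                        R += kd * mig_out[e, d]
                    if kd > 1:
                        nu_a = _nu_eval(e, d, t, epoch_times, size_form, size_p)
                        if t_seg_end < BIG_TIME * 0.5:
                            nu_b = _nu_eval(e, d, t_seg_end, epoch_times, size_form, size_p)
                        else:
                            nu_b = nu_a
                        nu_min = min(nu_a, nu_b)
                        R += 0.5 * kd * (kd - 1) / nu_min
                need_bound = False
            if R <= 0.0:
                if t_seg_end >= BIG_TIME * 0.5:
                    return 0  # isolated lineages, nothing can happen
                t = t_seg_end
            else:
                dt = -np.log(np.random.random()) / R
                if t + dt >= t_seg_end:
                    t = t_seg_end
                else:
                    t = t + dt
                    if t > t_max:
                        return 0
                    u = np.random.random() * R
                    acc = 0.0
                    done = False
                    for d in range(n_demes):
                        kd = deme_count[d]
                        if kd > 1:
                            nu = _nu_eval(e, d, t, epoch_times, size_form, size_p)
                            acc += 0.5 * kd * (kd - 1) / nu
                            if u < acc:
                                # coalescence in deme d
                                o1 = np.random.randint(0, kd)
                                o2 = np.random.randint(0, kd - 1)
                                ia = _pick_in_deme(lin_deme, k, d, o1)
                                if o2 >= o1:
                                    o2 += 1
                                ib = _pick_in_deme(lin_deme, k, d, o2)
                                children[next_node, 0] = lin_node[ia]
                                children[next_node, 1] = lin_node[ib]
                                node_birth[next_node] = t
                                node_death[lin_node[ia]] = t
                                node_death[lin_node[ib]] = t
                                lin_node[ia] = next_node
                                lin_node[ib] = lin_node[k - 1]
                                lin_deme[ib] = lin_deme[k - 1]
                                next_node += 1
                                k -= 1
                                deme_count[d] -= 1
                                done = True
                                break
                    if not done:
                        for d in range(n_demes):
                            kd = deme_count[d]
                            if kd == 0:
                                continue
                            for j in range(n_demes):
                                m = mig[e, d, j]
                                if m <= 0.0:
                                    continue
                                acc += kd * m
                                if u < acc:
                                    o = np.random.randint(0, kd)
                                    i = _pick_in_deme(lin_deme, k, d, o)
                                    lin_deme[i] = j
                                    deme_count[d] -= 1
                                    deme_count[j] += 1
                                    done = True
                                    break
                            if done:
                                break
                    if done:
                        need_bound = True  # lineage configuration changed
                    # else: thinning rejection; cached bound still valid
                    continue
            # reached t_seg_end
            if t >= t_epoch_end:
                break
            need_bound = True  # new proposal window within the epoch
        if k <= 1:
            break
        # cross into epoch e+1, applying any events pinned to its start
        e += 1
        for iv in range(n_ev):
            if ev_bidx[iv] == e:
                src = ev_src[iv]
                dst = ev_dst[iv]
                if ev_kind[iv] == EV_FOUNDING:
                    for i in range(k):
                        if lin_deme[i] == dst:
                            lin_deme[i] = src
                            deme_count[dst] -= 1
                            deme_count[src] += 1
                else:
                    frac = ev_frac[iv]
                    for i in range(k):
                        if lin_deme[i] == dst and np.random.random() < frac:
                            lin_deme[i] = src
                            deme_count[dst] -= 1
                            deme_count[src] += 1
    root = lin_node[0]
    node_death[root] = node_birth[root]  # root subtends no observable branch
    return 1


@njit(cache=True)
def seed_kernel(seed):
    """Seed numba's internal np.random state (separate from NumPy's global)."""
    np.random.seed(seed)


@njit(cache=True)
def _leaf_counts(children, leaf_pop, n, c0, c1):
    total = 2 * n - 1
    for v in range(n):
        if leaf_pop[v] == 0:
            c0[v] = 1
            c1[v] = 0
        else:
            c0[v] = 0
            c1[v] = 1
    for v in range(n, total):
        a = children[v, 0]
        b = children[v, 1]
        c0[v] = c0[a] + c0[b]
        c1[v] = c1[a] + c1[b]


@njit(cache=True)
def expected_sfs_kernel(
    epoch_times,
    size_form,
    size_p,
    mig,
    mig_out,
    ev_bidx,
    ev_kind,
    ev_src,
    ev_dst,
    ev_frac,
    sample_demes,
    leaf_pop,
    n0,
    n1,
    n_reps,
    seed,
    t_max,
):
    """Mean and mean-square per-genealogy branch-length spectra.

    Cell (i, j) of the returned mean holds the average total branch length (in
    2*N_ref generations) subtending exactly i sampled copies of population 0
    and j of population 1. Divide by 2 for the per-unit-theta expected SFS.
    """
    np.random.seed(seed)
    n = sample_demes.size
    total = 2 * n - 1
    children = np.empty((total, 2), dtype=np.int32)
    node_birth = np.empty(total, dtype=np.float64)
    node_death = np.empty(total, dtype=np.float64)
    lin_node = np.empty(n, dtype=np.int32)
    lin_deme = np.empty(n, dtype=np.int32)
    deme_count = np.empty(mig.shape[1], dtype=np.int64)
    c0 = np.empty(total, dtype=np.int64)
    c1 = np.empty(total, dtype=np.int64)
    mean = np.zeros((n0 + 1, n1 + 1))
    meansq = np.zeros((n0 + 1, n1 + 1))
    rep_sfs = np.zeros((n0 + 1, n1 + 1))
    fails = 0
    for _ in range(n_reps):
        ok = sim_genealogy(
            epoch_times, size_form, size_p, mig, mig_out,
            ev_bidx, ev_kind, ev_src, ev_dst, ev_frac,
            sample_demes, t_max,
            children, node_birth, node_death, lin_node, lin_deme, deme_count,
        )
        if ok == 0:
            fails += 1
            continue
        _leaf_counts(children, leaf_pop, n, c0, c1)
        rep_sfs[:] = 0.0
        for v in range(total):
            rep_sfs[c0[v], c1[v]] += node_death[v] - node_birth[v]
        mean += rep_sfs
        meansq += rep_sfs * rep_sfs
    n_ok = n_reps - fails
    if n_ok > 0:
        mean /= n_ok
        meansq /= n_ok
    return mean, meansq, fails
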