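"""Jit-compiled MCMC kernel for the BYM Poisson model.

Single long loop of Metropolis-within-Gibbs sweeps:

* each spatial effect u_i: random-walk Metropolis against its intrinsic-CAR
  full conditional (normal around the neighbour mean with precision
  tau_u * n_i) times the region's Poisson likelihood;
* per-component re-centring of u every sweep (the ICAR sum-to-zero
  constraint), with the removed overall mean folded into the intercept;
* each unstructured effect v_i: random-walk Metropolis, N(0, 1/tau_v) prior;
* intercept and each regression coefficient: random-walk Metropolis with
  diffuse normal priors;
* tau_u, tau_v: conjugate Gamma Gibbs draws.

Random-walk step sizes adapt only during burn-in (target acceptance
0.2-0.5) and are frozen afterwards, preserving detailed balance for the
retained draws. The kernel takes only flat arrays/scalars so numba can
compile it; the ergonomic wrapper lives in :mod:`carmap.car_model`.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def run_chain(
    O,            # (n,) observed counts, float64
    logE,         # (n,) log expected counts
    X,            # (n, p) design matrix (reference-cell dummies)
    col_indptr,   # CSC pointers of non-zero rows per design column
    col_rows,     # CSC row indices
    adj_indptr,   # CSR adjacency pointers
    adj_indices,  # CSR adjacency indices
    comp_id,      # (n,) connected-component label per region
    n_comp,       # number of components
    icar_rank,    # rank of D - W = n - n_comp
    island,       # (n,) bool: degree-0 regions (u pinned at 0)
    a_u, b_u,     # Gamma(shape, rate) hyperprior on tau_u
    a_v, b_v,     # Gamma(shape, rate) hyperprior on tau_v
    prec_beta,    # normal prior precision on coefficients
    prec_alpha,   # normal prior precision on the intercept
    n_burn, n_iter, thin, seed, adapt_every,
):
    np.random.seed(seed)
    n = O.shape[0]
    p = X.shape[1]

    u = np.zeros(n)
    v = np.zeros(n)
    beta = np.zeros(p)
    alpha = 0.0
    tau_u = 1.0
    tau_v = 1.0
    xb = np.zeros(n)

    s_u = np.full(n, 0.5)
    s_v = np.full(n, 0.5)
    s_beta = np.full(p, 0.3)
    s_alpha = 0.1
    acc_u = np.zeros(n)
    acc_v = np.zeros(n)
    acc_beta = np.zeros(p)
    acc_alpha = 0.0

    sum_O = O.sum()

    n_keep = n_iter // thin
    out_alpha = np.empty(n_keep)
    out_beta = np.empty((n_keep, p))
    out_u = np.empty((n_keep, n))
    out_v = np.empty((n_keep, n))
    out_tau_u = np.empty(n_keep)
    out_tau_v = np.empty(n_keep)

    keep = 0
    total = n_burn + n_iter
    for it in range(total):
        # --- structured effects u_i -------------------------------------
        for i in range(n):
            if island[i]:
                continue
            lo = adj_indptr[i]
            hi = adj_indptr[i + 1]
            di = hi - lo
            m = 0.0
            for k in range(lo, hi):
                m += u[adj_indices[k]]
            m /= di
            cur = u[i]
            prop = cur + s_u[i] * np.random.normal()
            base = alpha + xb[i] + v[i]
            eta0 = base + cur
            eta1 = base + prop
            ei = np.exp(logE[i])
            delta = (
                -0.5 * tau_u * di * ((prop - m) ** 2 - (cur - m) ** 2)
                + O[i] * (eta1 - eta0)
                - ei * (np.exp(eta1) - np.exp(eta0))
            )
            if delta > 0.0 or np.log(np.random.random()) < delta:
                u[i] = prop
                acc_u[i] += 1.0

        # --- sum-to-zero centring per component -------------------------
        shift_total = 0.0
        for c in range(n_comp):
            s = 0.0
            cnt = 0
            for i in range(n):
                if comp_id[i] == c:
                    s += u[i]
                    cnt += 1
            mbar = s / cnt
            for i in range(n):
                if comp_id[i] == c:
                    u[i] -= mbar
            shift_total += s
        alpha += shift_total / n

        # --- unstructured effects v_i -----------------------------------
        for i in range(n):
            cur = v[i]
            prop = cur + s_v[i] * np.random.normal()
            base = alpha + xb[i] + u[i]
            eta0 = base + cur
            eta1 = base + prop
            ei = np.exp(logE[i])
            delta = (
                -0.5 * tau_v * (prop * prop - cur * cur)
                + O[i] * (eta1 - eta0)
                - ei * (np.exp(eta1) - np.exp(eta0))
            )
            if delta > 0.0 or np.log(np.random.random()) < delta:
                v[i] = prop
                acc_v[i] += 1.0

        # --- intercept ----------------------------------------------------
        sum_mu = 0.0
        for i in range(n):
            sum_mu += np.exp(logE[i] + alpha + xb[i] + u[i] + v[i])
        eps = s_alpha * np.random.normal()
        prop = alpha + eps
        delta = (
            sum_O * eps
            - (np.exp(eps) - 1.0) * sum_mu
            - 0.5 * prec_alpha * (prop * prop - alpha * alpha)
        )
        if delta > 0.0 or np.log(np.random.random()) < delta:
            alpha = prop
            acc_alpha += 1.0

        # --- regression coefficients -------------------------------------
        for j in range(p):
            eps = s_beta[j] * np.random.normal()
            cur = beta[j]
            prop = cur + eps
            delta = -0.5 * prec_beta * (prop * prop - cur * cur)
            for k in range(col_indptr[j], col_indptr[j + 1]):
                i = col_rows[k]
                xij = X[i, j]
                mu_i = np.exp(logE[i] + alpha + xb[i] + u[i] + v[i])
                delta += O[i] * xij * eps - mu_i * (np.exp(xij * eps) - 1.0)
            if delta > 0.0 or np.log(np.random.random()) < delta:
                beta[j] = prop
                for k in range(col_indptr[j], col_indptr[j + 1]):
                    i = col_rows[k]
                    xb[i] += X[i, j] * eps
                acc_beta[j] += 1.0

        # --- precisions (conjugate Gibbs) ---------------------------------
        quad = 0.0
        for i in range(n):
            for k in range(adj_indptr[i], adj_indptr[i + 1]):
                d = u[i] - u[adj_indices[k]]
                quad += d * d
        quad *= 0.5  # each pair counted twice
        tau_u = np.random.gamma(a_u + 0.5 * icar_rank, 1.0 / (b_u + 0.5 * quad))
        ss_v = 0.0
        for i in range(n):
            ss_v += v[i] * v[i]
        tau_v = np.random.gamma(a_v + 0.5 * n, 1.0 / (b_v + 0.5 * ss_v))

        # --- step-size adaptation, burn-in only ---------------------------
        if it < n_burn and (it + 1) % adapt_every == 0:
            inv = 1.0 / adapt_every
            for i in range(n):
                r = acc_u[i] * inv
                if r < 0.2:
                    s_u[i] *= 0.8
                elif r > 0.5:
                    s_u[i] *= 1.25
                acc_u[i] = 0.0
                r = acc_v[i] * inv
                if r < 0.2:
                    s_v[i] *= 0.8
                elif r > 0.5:
                    s_v[i] *= 1.25
                acc_v[i] = 0.0
            for j in range(p):
                r = acc_beta[j] * inv
                if r < 0.2:
                    s_beta[j] *= 0.8
                elif r > 0.5:
                    s_beta[j] *= 1.25
                acc_beta[j] = 0.0
            r = acc_alpha * inv
            if r < 0.2:
                s_alpha *= 0.8
            elif r > 0.5:
                s_alpha *= 1.25
            acc_alpha = 0.0

        # --- storage -------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0 and keep < n_keep:
            out_alpha[keep] = alpha
            for j in range(p):
                out_beta[keep, j] = beta[j]
            for i in range(n):
                out_u[keep, i] = u[i]
                out_v[keep, i] = v[i]
            out_tau_u[keep] = tau_u
            out_tau_v[keep] = tau_v
            keep += 1

    return out_alpha, out_beta, out_u, out_v, out_tau_u, out_tau_v
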