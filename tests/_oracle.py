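"""Independent brute-force SECR likelihood for tiny instances.

Written with explicit Python loops and direct probability products —
no shared code with the vectorized likelihood it checks, beyond the
model definition itself.
"""
import math

import numpy as np


def per_occasion_p(d, lam0, sigma):
    lam = lam0 * math.exp(-(d**2) / (2.0 * sigma**2))
    return -math.expm1(-lam), lam


def _lambda0_ks(theta_l, names_l, det_type, gb, k, s, bk=0):
    lp = 0.0
    for j, nm in enumerate(names_l):
        if nm == "(Intercept)":
            lp += theta_l[j]
        elif nm.startswith("traptype["):
            lp += theta_l[j] * (det_type[k] == nm[9:-1])
        elif nm == "T":
            lp += theta_l[j] * s
        elif nm == "GB":
            lp += theta_l[j] * gb[k][s]
        elif nm == "bk":
            lp += theta_l[j] * bk
        else:
            raise ValueError(nm)
    return math.exp(lp)


def brute_negloglik(
    theta,
    omega,
    det_xy,
    det_type,
    usage,
    mask_xy,
    cell_area,
    names_d,
    names_l,
    names_s,
    mask_cov=None,
    gb=None,
    distribution="poisson",
):
    """Direct evaluation of the marginalized SECR likelihood.

    omega: (n, K, S) 0/1; theta ordered as density, lambda0, sigma
    coefficient blocks matching the given name lists.
    """
    n, K, S = omega.shape
    M = len(mask_xy)
    pD, pl = len(names_d), len(names_l)
    th_d = theta[:pD]
    th_l = theta[pD: pD + pl]
    th_s = theta[pD + pl:]
    mask_cov = mask_cov or {}
    gb = gb if gb is not None else [[0] * S for _ in range(K)]

    D = []
    for m in range(M):
        lp = 0.0
        for j, nm in enumerate(names_d):
            if nm == "(Intercept)":
                lp += th_d[j]
            elif nm.startswith("tenure["):
                lp += th_d[j] * (mask_cov["tenure"][m] == nm[7:-1])
            else:
                lp += th_d[j] * mask_cov[nm[2:] if nm.startswith("D.") else nm][m]
        D.append(math.exp(lp))

    def sigma_ks(k, s):
        lp = 0.0
        for j, nm in enumerate(names_s):
            if nm == "(Intercept)":
                lp += th_s[j]
            elif nm.startswith("traptype["):
                lp += th_s[j] * (det_type[k] == nm[9:-1])
            elif nm == "T":
                lp += th_s[j] * s
            elif nm == "GB":
                lp += th_s[j] * gb[k][s]
            else:
                raise ValueError(nm)
        return math.exp(lp)

    def dist(k, m):
        return math.hypot(
            det_xy[k][0] - mask_xy[m][0], det_xy[k][1] - mask_xy[m][1]
        )

    # probability a naive animal at m escapes detection entirely
    pdot = []
    for m in range(M):
        p_none = 1.0
        for k in range(K):
            for s in range(S):
                if usage[k][s]:
                    lam0 = _lambda0_ks(th_l, names_l, det_type, gb, k, s, bk=0)
                    p, _ = per_occasion_p(dist(k, m), lam0, sigma_ks(k, s))
                    p_none *= 1.0 - p
        pdot.append(1.0 - p_none)

    Lambda = sum(D[m] * cell_area for m in range(M))
    expected = sum(pdot[m] * D[m] * cell_area for m in range(M))

    sum_log_int = 0.0
    for i in range(n):
        # first detection occasion of i at each trap -> bk switches on after
        first = {}
        for k in range(K):
            for s in range(S):
                if omega[i][k][s]:
                    first.setdefault(k, s)
                    break
        integral = 0.0
        for m in range(M):
            pr = 1.0
            for k in range(K):
                for s in range(S):
                    if not usage[k][s]:
                        continue
                    bk = 1 if (k in first and s > first[k]) else 0
                    lam0 = _lambda0_ks(
                        th_l, names_l, det_type, gb, k, s, bk=bk
                    )
                    p, _ = per_occasion_p(dist(k, m), lam0, sigma_ks(k, s))
                    pr *= p if omega[i][k][s] else (1.0 - p)
            integral += pr * D[m] * cell_area
        sum_log_int += math.log(integral)

    if distribution == "poisson":
        return expected - sum_log_int + math.lgamma(n + 1)
    pbar = expected / Lambda
    ll = (
        math.lgamma(Lambda + 1)
        - math.lgamma(Lambda - n + 1)
        - math.lgamma(n + 1)
        + (Lambda - n) * math.log(1.0 - pbar)
        + sum_log_int
        - n * math.log(Lambda)
    )
    return -ll


def single_animal_history_prob(omega_i, x_m, det_xy, det_type, usage,
                               theta_l, names_l, theta_s, names_s, gb=None):
    """Pr(one animal's full history | activity center x_m), including
    the trap-specific behavioral step change."""
    K = len(det_xy)
    S = len(usage[0])
    gb = gb if gb is not None else [[0] * S for _ in range(K)]
    first = {}
    for k in range(K):
        for s in range(S):
            if omega_i[k][s]:
                first.setdefault(k, s)
                break
    pr = 1.0
    for k in range(K):
        d = math.hypot(det_xy[k][0] - x_m[0], det_xy[k][1] - x_m[1])
        for s in range(S):
            if not usage[k][s]:
                continue
            bk = 1 if (k in first and s > first[k]) else 0
            lam0 = _lambda0_ks(theta_l, names_l, det_type, gb, k, s, bk=bk)
            sig_lp = 0.0
            for j, nm in enumerate(names_s):
                if nm == "(Intercept)":
                    sig_lp += theta_s[j]
                elif nm.startswith("traptype["):
                    sig_lp += theta_s[j] * (det_type[k] == nm[9:-1])
                elif nm == "T":
                    sig_lp += theta_s[j] * s
                elif nm == "GB":
                    sig_lp += theta_s[j] * gb[k][s]
            p, _ = per_occasion_p(d, lam0, math.exp(sig_lp))
            pr *= p if omega_i[k][s] else (1.0 - p)
    return pr
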