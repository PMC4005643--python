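"""Numba kernel for the intermolecular duplex dynamic program.

The recursion runs over the query (miRNA, 5'->3') and the *reversed*
target window, so base pairs advance monotonically on both axes.  State
``H[i, k]`` is the best energy of a duplex whose 3'-most query pair is
(i, k), counting the opening terminal penalty, all stacks and loop terms;
the closing terminal penalty and duplex initiation are added when a cell
is read out.  Ties within ``EPS`` are broken toward more base pairs, then
fewer loops, matching the package's documented determinism rule.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EPS = 1e-9
BIG = 1e18


@njit(cache=False)
def fill(q, r, stack, pair_ok, bulge_init, internal_init, asym, asym_max,
         term_pen, max_bulge, max_internal):
    m = q.shape[0]
    n = r.shape[0]
    H = np.full((m, n), BIG)
    NP = np.zeros((m, n), np.int32)   # pairs in the best duplex ending here
    NL = np.zeros((m, n), np.int32)   # loops in the best duplex ending here
    Pi = np.full((m, n), -1, np.int32)
    Pk = np.full((m, n), -1, np.int32)
    gmax = max_internal if max_internal > max_bulge else max_bulge
    for i in range(m):
        qi = q[i]
        for k in range(n):
            rk = r[k]
            if pair_ok[qi, rk] == 0:
                continue
            # open a new duplex at this pair
            best = term_pen[qi, rk]
            bnp = 1
            bnl = 0
            bi = -1
            bk = -1
            ip0 = i - 1 - gmax
            if ip0 < 0:
                ip0 = 0
            kp0 = k - 1 - gmax
            if kp0 < 0:
                kp0 = 0
            for ip in range(ip0, i):
                gi = i - ip - 1
                for kp in range(kp0, k):
                    h = H[ip, kp]
                    if h >= BIG:
                        continue
                    gk = k - kp - 1
                    nl = 0
                    if gi == 0 and gk == 0:
                        c = stack[q[ip], qi, r[kp], rk]
                    elif gk == 0:
                        if gi > max_bulge:
                            continue
                        c = bulge_init[gi]
                        if gi == 1:
                            c += stack[q[ip], qi, r[kp], rk]
                        nl = 1
                    elif gi == 0:
                        if gk > max_bulge:
                            continue
                        c = bulge_init[gk]
                        if gk == 1:
                            c += stack[q[ip], qi, r[kp], rk]
                        nl = 1
                    else:
                        sz = gi + gk
                        if sz > max_internal:
                            continue
                        a = asym * abs(gi - gk)
                        if a > asym_max:
                            a = asym_max
                        c = internal_init[sz] + a
                        nl = 1
                    cand = h + c
                    cnp = NP[ip, kp] + 1
                    cnl = NL[ip, kp] + nl
                    if (cand < best - EPS
                            or (cand < best + EPS
                                and (cnp > bnp or (cnp == bnp and cnl < bnl)))):
                        best = cand
                        bnp = cnp
                        bnl = cnl
                        bi = ip
                        bk = kp
            H[i, k] = best
            NP[i, k] = bnp
            NL[i, k] = bnl
            Pi[i, k] = bi
            Pk[i, k] = bk
    return H, NP, NL, Pi, Pk
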