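"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic by a different route than the
implementation: the dip via linear-programming feasibility of the
unimodal band per modal split, BH by checking every reordering against
the step-up definition, ssGSEA by a literal walk down the ranked list.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x) -> float:
    """Dip by LP: minimal band half-width admitting a unimodal CDF.

    For every candidate modal split (between points and at a point, where
    the mode may carry an atom) solve ``min d`` subject to: a convex
    nondecreasing g on the left and a concave nondecreasing g on the
    right, each within the band ``[F_i - d, Fprev_i + d]`` at the unique
    sample points (the upper constraint is the CDF's left limit, the
    lower its value).  The dip is the minimum over splits.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    u, cnt = np.unique(x, return_counts=True)
    t_n = u.size
    if t_n == 1:
        return 0.0
    cum = np.cumsum(cnt)
    f_hi = cum / n
    f_lo = (cum - cnt) / n

    def solve(left_idx, right_idx, drop_lower_at=None, drop_upper_at=None):
        kl, kr = len(left_idx), len(right_idx)
        nv = kl + kr + 1  # g values + d
        a_ub, b_ub = [], []

        def box(idx, off, drop_lower, drop_upper):
            for j, i in enumerate(idx):
                if drop_upper != i:
                    row = [0.0] * nv
                    row[off + j], row[-1] = 1.0, -1.0
                    a_ub.append(row)
                    b_ub.append(f_lo[i])
                if drop_lower != i:
                    row = [0.0] * nv
                    row[off + j], row[-1] = -1.0, -1.0
                    a_ub.append(row)
                    b_ub.append(-f_hi[i])

        def shape(idx, off, convex):
            for j in range(1, len(idx) - 1):
                h0, h1, h2 = u[idx[j - 1]], u[idx[j]], u[idx[j + 1]]
                row = [0.0] * nv
                row[off + j - 1] = 1.0 / (h1 - h0)
                row[off + j] = -1.0 / (h1 - h0) - 1.0 / (h2 - h1)
                row[off + j + 1] = 1.0 / (h2 - h1)
                if convex:  # second difference >= 0
                    a_ub.append([-r for r in row])
                else:
                    a_ub.append(row)
                b_ub.append(0.0)

        def mono(idx, off):
            for j in range(len(idx) - 1):
                row = [0.0] * nv
                row[off + j], row[off + j + 1] = 1.0, -1.0
                a_ub.append(row)
                b_ub.append(0.0)

        box(left_idx, 0, drop_lower_at, None)
        box(right_idx, kl, None, drop_upper_at)
        shape(left_idx, 0, convex=True)
        shape(right_idx, kl, convex=False)
        mono(left_idx, 0)
        mono(right_idx, kl)
        c = [0.0] * nv
        c[-1] = 1.0
        bounds = [(0.0, 1.0)] * (kl + kr) + [(0.0, None)]
        res = linprog(c, A_ub=a_ub or None, b_ub=b_ub or None, bounds=bounds,
                      method="highs")
        return res.fun if res.status == 0 else np.inf

    best = np.inf
    for s in range(t_n + 1):  # mode strictly between u_s-1 and u_s
        best = min(best, solve(list(range(s)), list(range(s, t_n))))
    for t in range(t_n):  # mode at u_t, atom allowed
        best = min(
            best,
            solve(list(range(t + 1)), list(range(t, t_n)),
                  drop_lower_at=t, drop_upper_at=t),
        )
    return float(best)


def bh_bruteforce(pvals) -> np.ndarray:
    """Step-up BH from the definition: q_i = min over j with p_(j) >= p_i of
    min(1, m * p_(j) / j), evaluated by explicit search."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = np.empty(m)
    for i in range(m):
        q_ranked[i] = min(
            min(1.0, m * ranked[j] / (j + 1)) for j in range(i, m)
        )
    q = np.empty(m)
    q[order] = q_ranked
    return q


def ssgsea_bruteforce(values, set_genes, alpha) -> float:
    """Literal running-sum walk down the ranked gene list."""
    import pandas as pd

    v = pd.Series(values)
    order = np.argsort(-v.to_numpy(float), kind="stable")
    genes = v.index.to_numpy()[order]
    n = len(genes)
    in_set = np.array([g in set(set_genes) for g in genes])
    m = in_set.sum()
    weights = np.array([(n - i) ** alpha for i in range(n)], dtype=float)
    denom_in = float((weights * in_set).sum())
    total = 0.0
    p_in = p_out = 0.0
    for i in range(n):
        if in_set[i]:
            p_in += weights[i] / denom_in
        else:
            p_out += 1.0 / (n - m)
        total += p_in - p_out
    return total


def km_bruteforce(times, events):
    """Product-limit estimate computed subject by subject."""
    import pandas as pd

    df = pd.DataFrame({"t": times, "e": events}).sort_values("t", kind="stable")
    s = 1.0
    out = {}
    for t in sorted(df.loc[df.e == 1, "t"].unique()):
        r = int((df.t >= t).sum())
        d = int(((df.t == t) & (df.e == 1)).sum())
        s *= 1 - d / r
        out[t] = s
    return out
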