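"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (dict-based
state, explicit per-family branches, plain Python loops) and shares no code
with the package's likelihood path.
"""

import math

import numpy as np

CONTEXTS = ["GP", "LP", "GC", "LC"]


def naive_run(family, variant, params, trials):
    """Hand-written sequential pass over one subject's trial table.

    Returns (loglik, latents-list-of-dicts, Q_end, V_end) where Q_end maps
    symbol ids to end-of-learning values.
    """
    Q = {f"{c}_{r}": 0.0 for c in CONTEXTS for r in ("hi", "lo")}
    V = {c: 0.0 for c in CONTEXTS}
    last_seen = {f"{c}_{r}": 0.0 for c in CONTEXTS for r in ("hi", "lo")}
    beta = params["beta"]
    relative = family in ("REL", "RELASYM")
    asym = family in ("ASYM", "RELASYM")
    ll = 0.0
    latents = []

    def softmax_chosen(qc, qu):
        p = 1.0 / (1.0 + math.exp(-beta * (qc - qu)))
        return min(max(p, 1e-12), 1 - 1e-12)

    for row in trials[trials["phase"] == "learning"].itertuples():
        ctx = row.context
        chosen = f"{ctx}_hi" if row.correct == 1 else f"{ctx}_lo"
        unchosen = f"{ctx}_lo" if row.correct == 1 else f"{ctx}_hi"
        qc, qu, v = Q[chosen], Q[unchosen], V[ctx]
        p = softmax_chosen(qc, qu)
        ll += math.log(p)
        complete = row.information == "complete"
        rc = row.outcome_chosen
        ru = row.outcome_unchosen if complete else None

        center = v if relative else 0.0
        dc = rc - center - qc
        du = (ru - center - qu) if complete else float("nan")
        if relative:
            if complete:
                x = ru
            elif variant == "zero":
                x = 0.0
            elif variant == "Qu":
                x = qu
            elif variant == "last_outcome":
                x = last_seen[unchosen]
            else:  # weighted imaginary forgone outcome
                if v == 0:
                    img = 0.0
                else:
                    comp = 1.0 if math.isclose(abs(rc), 0.1) else 0.1
                    img = comp if v > 0 else -comp
                x = params["w"] * img
            dv = (rc + x) / 2.0 - v
        else:
            dv = float("nan")

        latents.append(
            dict(Qc=qc, Qu=qu, V=v, delta_c=dc, delta_u=du, delta_v=dv, choice_prob=p)
        )

        if asym:
            a_c = params["alpha_con"] if dc > 0 else params["alpha_dis"]
        else:
            a_c = params["alpha_c"]
        Q[chosen] = qc + a_c * dc
        if complete:
            if asym:
                a_u = params["alpha_con"] if du < 0 else params["alpha_dis"]
            else:
                a_u = params["alpha_u"]
            Q[unchosen] = qu + a_u * du
        if relative:
            V[ctx] = v + params["alpha_v"] * dv
        last_seen[chosen] = rc
        if complete:
            last_seen[unchosen] = ru

    for row in trials[trials["phase"] == "transfer"].itertuples():
        a, b = row.context.split("|")
        chosen = row.chosen
        unchosen = b if chosen == a else a
        p = softmax_chosen(Q[chosen], Q[unchosen])
        ll += math.log(p)
        latents.append(
            dict(
                Qc=Q[chosen], Qu=Q[unchosen],
                V=(V[a.split("_")[0]] + V[b.split("_")[0]]) / 2.0,
                delta_c=float("nan"), delta_u=float("nan"), delta_v=float("nan"),
                choice_prob=p,
            )
        )
    return ll, latents, dict(Q), dict(V)


def richardson_hessian(f, x, h0=1e-3):
    """Richardson-extrapolated central-difference Hessian."""

    def central(h):
        k = len(x)
        H = np.empty((k, k))
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            H[i, i] = (f(x + ei) - 2 * f(x) + f(x - ei)) / h**2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h * h)
        return H

    return (4.0 * central(h0 / 2.0) - central(h0)) / 3.0


def dirichlet_ep_oracle(alpha, n_samples, seed, chunk=1_000_000):
    """Monte-Carlo exceedance probabilities, sampled independently."""
    rng = np.random.default_rng(seed)
    k = len(alpha)
    counts = np.zeros(k)
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        for i in range(k):
            counts[i] += np.sum(winners == i)
        remaining -= m
    return counts / n_samples
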