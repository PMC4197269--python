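"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (loops, enumeration, textbook
formulas), deliberately avoiding the code paths and libraries the package
itself uses, so implementation and oracle can disagree.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- correlations
def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def average_ranks(v) -> np.ndarray:
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman(x, y) -> float:
    return pearson(average_ranks(x), average_ranks(y))


# ------------------------------------------------------------- matrix filtering
def brute_matrix_filter(calls_per_sample, min_coverage, autosomes_only, require_complete,
                        autosomes) -> set:
    """Retained-site set by direct scan over every site and sample."""
    sites = set()
    for calls in calls_per_sample.values():
        sites.update(c.site for c in calls)
    cov = {s: {} for s in calls_per_sample}
    for s, calls in calls_per_sample.items():
        for c in calls:
            cov[s][c.site] = cov[s].get(c.site, 0) + c.n_meth + c.n_unmeth
    kept = set()
    for site in sites:
        if autosomes_only and site.chrom not in autosomes:
            continue
        flags = [cov[s].get(site, 0) >= min_coverage for s in calls_per_sample]
        if (all(flags) if require_complete else any(flags)):
            kept.add(site)
    return kept


# ---------------------------------------------------------------- Ward linkage
def naive_ward(dist: np.ndarray):
    """O(n^3) Ward.D2 agglomeration by the Lance-Williams update.

    Returns (clades, heights): leaf-index frozensets of every merge and the
    merge heights, ties broken by the lexicographically smallest pair.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    clades, heights = [], []
    while len(clusters) > 1:
        (i, j), best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(math.sqrt(best))
        merged = clusters[i] | clusters[j]
        clades.append(merged)
        ni, nj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dij = d[(i, j)]
            d[tuple(sorted((next_id, k)))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        for k in list(d):
            if i in k or j in k:
                del d[k]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    return clades, heights


# ------------------------------------------------------------------ DMR caller
def brute_unique_dmrs(region_means, groups, control, subgroup, delta_sub, delta_oth,
                      min_cpgs, cpg_counts) -> dict:
    """region_id -> direction for every region passing the criterion, by loops."""
    sub = [s for s, g in groups.items() if g == subgroup and s != control]
    others = [s for s in region_means.columns
              if s != control and s not in sub and s in groups]
    out = {}
    for rid in region_means.index:
        row = region_means.loc[rid]
        ctl = row[control]
        if np.isnan(ctl):
            continue
        if cpg_counts.get(rid, min_cpgs) < min_cpgs:
            continue
        vals_sub = [row[s] for s in sub]
        vals_oth = [row[s] for s in others]
        if any(np.isnan(v) for v in vals_sub + vals_oth):
            continue
        deltas = [v - ctl for v in vals_sub]
        if any(abs(dd) < delta_sub for dd in deltas):
            continue
        if any(dd > 0 for dd in deltas) and any(dd < 0 for dd in deltas):
            continue
        if any(abs(v - ctl) >= delta_oth for v in vals_oth):
            continue
        out[rid] = "hypo" if np.mean(vals_sub) < ctl else "hyper"
    return out


# --------------------------------------------------------------- TSS windows
def brute_assign(regions, genes, upstream, downstream) -> set:
    """(region_id, gene_id) pairs by quadratic all-vs-all overlap scan."""
    pairs = set()
    for g in genes:
        if g.strand == "+":
            ws, we = g.tss - upstream, g.tss + downstream
        else:
            ws, we = g.tss - downstream, g.tss + upstream
        ws, we = max(ws, 0), max(we, 0)
        for r in regions:
            if r.chrom == g.chrom and max(r.start, ws) < min(r.end, we):
                pairs.add((r.region_id, g.gene_id))
    return pairs


# ---------------------------------------------------------- integration filter
def brute_integration(pairs, meth, expr, control, rho_max, fold_min, ratio_min, eps) -> set:
    kept = set()
    cases = [s for s in meth.columns if s != control]
    for rid, gid in pairs:
        m = meth.loc[rid]
        e = expr.loc[gid]
        if len(set(m)) == 1 or len(set(e)) == 1:
            continue
        rho = spearman(m.to_numpy(), e.to_numpy())
        folds = []
        for s in cases:
            a, b = m[s] + eps, m[control] + eps
            folds.append(max(a, b) / min(a, b))
        if rho <= rho_max and max(folds) >= fold_min and m.max() >= ratio_min:
            kept.add((rid, gid))
    return kept


# ------------------------------------------------------------------ statistics
def fisher_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # hypergeometric P(a = x)
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def brute_u_statistic(x, y) -> float:
    """U for x by pairwise comparison: sum of 1[x_i > y_j] + 0.5 ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def km_by_hand(times, events):
    """Product-limit estimate: list of (event time, survival after it)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_by_hand(t1, e1, t2, e2) -> float:
    """Chi-square statistic of the two-group log-rank test from first principles."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def cif_by_hand(times, rel, dth):
    """Aalen-Johansen cumulative incidence of relapse, death competing.

    Returns list of (event time, CIF after it)."""
    times = np.asarray(times, float)
    rel = np.asarray(rel, int)
    dth = np.asarray(dth, int)
    any_event = (rel == 1) | (dth == 1)
    s = 1.0  # overall event-free survival S(t-)
    cif = 0.0
    out = []
    for t in sorted(set(times[any_event])):
        n = int((times >= t).sum())
        d_rel = int(((times == t) & (rel == 1)).sum())
        d_all = int(((times == t) & any_event).sum())
        cif += s * d_rel / n
        s *= 1 - d_all / n
        if d_rel:
            out.append((t, cif))
    return out
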