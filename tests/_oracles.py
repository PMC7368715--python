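"""Independent naive-loop oracles for every algorithm under test.

These deliberately avoid the package's vectorized code paths: plain Python
loops, explicit formulas, scipy only for reference distributions.  They are
slow and only meant for tiny fixtures.
"""

import math

from scipy import stats


def sd(xs):
    """Sample standard deviation (n-1 denominator) by explicit loop."""
    n = len(xs)
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def mean(xs):
    return sum(xs) / len(xs)


def geomean(xs):
    return math.exp(sum(math.log(x) for x in xs) / len(xs))


# --- stability algorithms ---------------------------------------------------

def genorm_m(q):
    """Full-panel geNorm M per gene; q: dict gene -> list of quantities."""
    genes = list(q)
    out = {}
    for g in genes:
        vs = []
        for h in genes:
            if h == g:
                continue
            ratios = [math.log2(a / b) for a, b in zip(q[g], q[h])]
            vs.append(sd(ratios))
        out[g] = mean(vs)
    return out


def genorm_v(q, ranking):
    """Pairwise variations V_n between NF_n and NF_{n+1} given a ranking."""
    ordered = sorted(ranking, key=lambda g: ranking[g])
    n_samples = len(q[ordered[0]])
    out = {}
    for n in range(2, len(ordered)):
        nf_n = [geomean([q[g][j] for g in ordered[:n]]) for j in range(n_samples)]
        nf_n1 = [geomean([q[g][j] for g in ordered[: n + 1]]) for j in range(n_samples)]
        out[n] = sd([math.log2(a / b) for a, b in zip(nf_n, nf_n1)])
    return out


def delta_ct(ct):
    """Mean pairwise delta-Ct SD; ct: dict gene -> list of Ct."""
    genes = list(ct)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            sds.append(sd([a - b for a, b in zip(ct[g], ct[h])]))
        out[g] = mean(sds)
    return out


def bestkeeper_std(ct, center="arith"):
    """Mean absolute deviation of Ct about the central Ct per gene."""
    out = {}
    for g, xs in ct.items():
        c = mean(xs) if center == "arith" else geomean(xs)
        out[g] = mean([abs(x - c) for x in xs])
    return out


def bestkeeper_index(ct):
    genes = list(ct)
    n = len(ct[genes[0]])
    return [geomean([ct[g][j] for g in genes]) for j in range(n)]


def normfinder(y, groups=None):
    """Model-based stability on log quantities; y: dict gene -> list.

    groups: dict level -> list of sample indices (None = ungrouped, returns
    the bias-corrected model variance per gene).  Mirrors the published
    estimators: two-way residual variances with the k/(k-2) correction,
    gene-centred intergroup deviations, shrinkage, |d| + sqrt(var/n).
    """
    genes = list(y)
    k = len(genes)

    def block_s(idx):
        # two-way residual variance per gene over the sample subset idx
        sub = {g: [y[g][j] for j in idx] for g in genes}
        gmean = {g: mean(sub[g]) for g in genes}
        smean = [mean([sub[g][j] for g in genes]) for j in range(len(idx))]
        grand = mean([sub[g][j] for g in genes for j in range(len(idx))])
        s = {}
        for g in genes:
            rss = sum(
                (sub[g][j] - gmean[g] - smean[j] + grand) ** 2
                for j in range(len(idx))
            )
            s[g] = rss / (len(idx) - 1)
        return s

    def corrected(s):
        tot = sum(s.values())
        return {g: (k / (k - 2)) * (s[g] - tot / (k * (k - 1))) for g in genes}

    if groups is None:
        n = len(y[genes[0]])
        sig2 = corrected(block_s(list(range(n))))
        return {g: max(0.0, sig2[g]) for g in genes}

    levels = sorted(groups)
    grand_gene = {g: mean(y[g]) for g in genes}
    sig2 = {}
    d = {}
    for lv in levels:
        idx = groups[lv]
        c = corrected(block_s(idx))
        sig2[lv] = {g: max(0.0, c[g]) for g in genes}
        z = {g: mean([y[g][j] for j in idx]) - grand_gene[g] for g in genes}
        zbar = mean(list(z.values()))
        d[lv] = {g: z[g] - zbar for g in genes}
    samp_var = {lv: {g: sig2[lv][g] / len(groups[lv]) for g in genes} for lv in levels}
    d_all = [d[lv][g] for lv in levels for g in genes]
    d_mean = mean(d_all)
    var_d = mean([(x - d_mean) ** 2 for x in d_all])
    gamma2 = max(0.0, var_d - mean([samp_var[lv][g] for lv in levels for g in genes]))
    out = {}
    for g in genes:
        rhos = []
        for lv in levels:
            if gamma2 > 0:
                dt = d[lv][g] * gamma2 / (gamma2 + samp_var[lv][g])
            else:
                dt = 0.0
            rhos.append(abs(dt) + math.sqrt(samp_var[lv][g]))
        out[g] = mean(rhos)
    return out


# --- aggregation ------------------------------------------------------------

def comprfinder_fs(table):
    """table: dict algorithm -> dict gene -> value.  Returns gene -> FS."""
    algs = list(table)
    genes = list(table[algs[0]])
    std = {}
    for a in algs:
        vals = table[a]
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            std[a] = {g: 0.0 for g in genes}
        else:
            std[a] = {g: (vals[g] - lo) / (hi - lo) for g in genes}
    return {g: mean([std[a][g] for a in algs]) for g in genes}


def average_ranks(vals):
    """gene -> average rank (ties share the mean of their positions)."""
    genes = list(vals)
    out = {}
    for g in genes:
        below = sum(1 for h in genes if vals[h] < vals[g])
        equal = sum(1 for h in genes if vals[h] == vals[g])
        out[g] = below + (equal + 1) / 2.0
    return out


def reffinder(table):
    algs = list(table)
    ranks = {a: average_ranks(table[a]) for a in algs}
    genes = list(table[algs[0]])
    return {
        g: math.exp(mean([math.log(ranks[a][g]) for a in algs])) for g in genes
    }


# --- normalization / validation --------------------------------------------

def nf(cts):
    """Geometric-mean normalization factor from a list of Ct values."""
    return geomean(cts)


def rel_expr(ct_target, nf_value):
    return 2.0 ** (-(ct_target - nf_value))


def paired_t(a, b):
    """Textbook paired t-test: t on the differences, two-sided p."""
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    t = mean(diffs) / (sd(diffs) / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def pearson_r(x, y):
    mx, my = mean(x), mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
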