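"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: exhaustive enumeration instead of dynamic programming, textbook
sums-of-squares instead of a stats library, direct convolution loops
instead of ndimage. Oracles stay slow and obvious.
"""

import itertools

import numpy as np


def enumerate_brightest_path(image, max_step, penalty):
    """Exhaustive search over every admissible left-to-right path.

    Returns (rows, score) with the same tie-break as the package contract:
    among maximal paths, the one whose row sequence read from the last
    column backwards is lexicographically smallest.
    """
    img = np.asarray(image, dtype=float)
    n_r, n_c = img.shape
    steps = np.array(list(itertools.product(range(-max_step, max_step + 1), repeat=n_c - 1)),
                     dtype=int)
    if n_c == 1:
        steps = np.zeros((1, 0), dtype=int)
    offsets = np.concatenate(
        [np.zeros((len(steps), 1), dtype=int), np.cumsum(steps, axis=1)], axis=1
    )
    rows = np.arange(n_r)[:, None, None] + offsets[None]  # (R, S, C)
    valid = ((rows >= 0) & (rows < n_r)).all(axis=2)
    cols = np.arange(n_c)
    brightness = img[np.clip(rows, 0, n_r - 1), cols].sum(axis=2)
    pen = penalty * np.abs(steps).sum(axis=1)
    score = np.where(valid, brightness - pen[None, :], -np.inf)
    best = score.max()
    cand = np.argwhere(score == best)
    paths = [tuple(rows[r, s]) for r, s in cand]
    chosen = min(paths, key=lambda p: tuple(reversed(p)))
    return np.array(chosen), float(best)


def sobel_energy_by_hand(frame):
    """Mean gradient magnitude via explicit 3x3 convolution, reflect padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    f = np.asarray(frame, dtype=float)
    padded = np.pad(f, 1, mode="symmetric")  # matches ndimage 'reflect'
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            win = padded[i : i + 3, j : j + 3]
            # correlation (ndimage.sobel applies the kernel unmirrored)
            gx[i, j] = (win * kx[::-1, ::-1]).sum()
            gy[i, j] = (win * ky[::-1, ::-1]).sum()
    return float(np.hypot(gx, gy).mean())


def mixed_anova_by_hand(data, dv, within, between, subject):
    """Textbook SS decomposition of a balanced two-way mixed design.

    Returns a dict with F / df / p / partial eta-squared of the
    between x within interaction and the between main effect.
    """
    from scipy.stats import f as f_dist

    wide = data.pivot_table(index=[subject, between], columns=within, values=dv)
    groups = wide.index.get_level_values(1)
    y = wide.to_numpy()
    n_subj, k = y.shape
    levels = sorted(set(groups))
    g = len(levels)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    group_means = {a: y[groups == a].mean() for a in levels}
    n_per = {a: (groups == a).sum() for a in levels}
    ss_a = sum(n_per[a] * k * (group_means[a] - grand) ** 2 for a in levels)
    ss_subj_within = ss_between_subj - ss_a
    rep_means = y.mean(axis=0)
    ss_b = n_subj * ((rep_means - grand) ** 2).sum()
    ss_ab = 0.0
    for a in levels:
        cell = y[groups == a].mean(axis=0)
        ss_ab += n_per[a] * ((cell - group_means[a] - rep_means + grand) ** 2).sum()
    ss_err = ss_total - ss_a - ss_subj_within - ss_b - ss_ab
    df_a, df_sw = g - 1, n_subj - g
    df_b, df_ab = k - 1, (g - 1) * (k - 1)
    df_err = (k - 1) * (n_subj - g)
    f_ab = (ss_ab / df_ab) / (ss_err / df_err)
    f_a = (ss_a / df_a) / (ss_subj_within / df_sw)
    return {
        "F_interaction": f_ab,
        "df_interaction": (df_ab, df_err),
        "p_interaction": float(f_dist.sf(f_ab, df_ab, df_err)),
        "np2_interaction": ss_ab / (ss_ab + ss_err),
        "F_between": f_a,
        "p_between": float(f_dist.sf(f_a, df_a, df_sw)),
    }


def mauchly_by_hand(wide):
    """Mauchly's W via orthonormal contrasts of the sample covariance."""
    y = np.asarray(wide, dtype=float)
    n, k = y.shape
    s = np.cov(y, rowvar=False, ddof=1)
    # orthonormal contrast matrix (normalized Helmert, k-1 x k)
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    t = h @ s @ h.T
    eig = np.linalg.eigvalsh(t)
    w = np.prod(eig) / (eig.mean() ** (k - 1))
    d = k - 1
    f_corr = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(w)
    dof = k * (k - 1) // 2 - 1
    from scipy.stats import chi2 as chi2_dist

    return float(w), float(chi2), int(dof), float(chi2_dist.sf(chi2, dof))


def mann_whitney_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)

    def u_of(idx_a):
        sa = pooled[list(idx_a)]
        sb = np.delete(pooled, list(idx_a))
        u1 = sum((x > y) + 0.5 * (x == y) for x in sa for y in sb)
        return min(u1, len(sa) * len(sb) - u1)

    observed = u_of(range(n1))
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if u_of(idx) <= observed + 1e-12:
            count += 1
    return count / total


def paired_t_by_hand(a, b):
    """Closed-form paired t, two-sided p, Cohen's d."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * t_dist.sf(abs(t), n - 1)
    return float(t), float(p), float(d.mean() / sd)
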