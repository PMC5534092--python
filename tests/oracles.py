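"""Independent oracles used by the test suite.

Each function here deliberately avoids the code paths it is used to check:
swept areas are validated by pixel counting, ANOVA by the explicit
between/within mean-square ratio, Spearman by an explicit rank transform and
brute-force permutation enumeration.
"""

import itertools
import math

import numpy as np
import shapely


def raster_swept_area(contour_ed, contour_es, window, center, pixel=0.1):
    """Signed swept area inside an angular sector by pixel counting.

    Counts pixels inside the ED polygon minus pixels inside the ES polygon,
    restricted to the sector mask about `center`, times the pixel area.
    """
    pts = np.vstack([contour_ed.points, contour_es.points])
    x0, y0 = pts.min(axis=0) - 2 * pixel
    x1, y1 = pts.max(axis=0) + 2 * pixel
    xs = np.arange(x0, x1, pixel) + pixel / 2
    ys = np.arange(y0, y1, pixel) + pixel / 2
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    ang = np.mod(np.arctan2(gy - center[1], gx - center[0]), 2 * np.pi)
    in_sector = np.mod(ang - window.start, 2 * np.pi) < window.length
    gx, gy = gx[in_sector], gy[in_sector]
    poly_ed = shapely.Polygon(contour_ed.points)
    poly_es = shapely.Polygon(contour_es.points)
    n_ed = int(np.sum(shapely.contains_xy(poly_ed, gx, gy)))
    n_es = int(np.sum(shapely.contains_xy(poly_es, gx, gy)))
    return (n_ed - n_es) * pixel * pixel


def regular_ngon_area(n, radius):
    """Closed-form area of a regular n-gon inscribed in a circle."""
    return 0.5 * n * radius**2 * math.sin(2 * math.pi / n)


def hand_anova_f(groups):
    """One-way ANOVA F from explicit between/within mean squares."""
    k = len(groups)
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def rank_transform(values):
    """Average ranks computed by explicit sorting (handles ties)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def hand_spearman_rho(x, y):
    """Pearson correlation of explicitly computed average ranks."""
    rx, ry = rank_transform(x), rank_transform(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def brute_force_spearman_p(x, y):
    """Exact two-sided permutation p for Spearman rho by full enumeration."""
    rho_obs = abs(hand_spearman_rho(x, y))
    y = list(y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(hand_spearman_rho(x, perm)) >= rho_obs - 1e-12:
            count += 1
    return count / total
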