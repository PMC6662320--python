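"""Independent oracles used by the test suite.

Everything here is built directly on scipy.stats.truncnorm and plain
quadrature, deliberately avoiding the package's own truncated-normal module
and sampler, so that agreement between the two routes is informative.
"""

import numpy as np
from scipy import stats


def tn0_pdf(x, mean, sd):
    """Zero-truncated normal pdf via scipy (broadcasting over all args)."""
    a = (0.0 - np.asarray(mean)) / sd
    return stats.truncnorm.pdf(x, a, np.inf, loc=mean, scale=sd)


def tn0_logpdf(x, mean, sd):
    a = (0.0 - np.asarray(mean)) / sd
    return stats.truncnorm.logpdf(x, a, np.inf, loc=mean, scale=sd)


def _trap_w(grid):
    w = np.full(len(grid), grid[1] - grid[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def reduced_model_posterior_means(
    q,
    y,
    survey_cells,
    sigma_bounds,
    tau_upper,
    coef_sd,
    d1_grid=(-2.0, 2.0, 121),
    s_grid_n=61,
    t_grid=(0.015, None, 81),
    z_grid_n=401,
):
    """Posterior means of (delta1, sigma, tau, z) for the reduced model by
    dense-grid quadrature.

    Reduced model: theta = 0, delta2 = 1, independent U(0,1) prior on each
    latent z, delta1 ~ N(0, coef_sd), sigma ~ U(*sigma_bounds),
    tau ~ U(0, tau_upper).  Exploits the conditional independence of the
    latent cells given the scalars: for each (delta1, sigma, tau) grid point
    the per-cell evidence is a 1-D integral over z.

    Returns (means: dict, Ez: array, edge_masses: dict) — edge masses let the
    caller verify the grids contain the posterior.
    """
    q = np.asarray(q, dtype=float)
    y = np.asarray(y, dtype=float)
    d1g = np.linspace(*d1_grid)
    sg = np.linspace(sigma_bounds[0], sigma_bounds[1], s_grid_n)
    tg = np.linspace(t_grid[0], t_grid[1] or tau_upper, t_grid[2])
    zg = np.linspace(0.0, 1.0, z_grid_n)
    wz = _trap_w(zg)

    n_cells = len(q)
    # census factor A[d, t, c, z] and survey factor B[s, c, z]
    A = tn0_pdf(
        q[None, None, :, None],
        d1g[:, None, None, None] + zg[None, None, None, :],
        tg[None, :, None, None],
    )
    B = np.ones((len(sg), n_cells, len(zg)))
    for k, cell in enumerate(survey_cells):
        B[:, cell, :] = tn0_pdf(y[k], zg[None, :], sg[:, None])
    AW = A * wz
    f = np.einsum("dtcz,scz->dstc", AW, B)  # per-cell evidence
    g = np.einsum("dtcz,scz->dstc", AW * zg, B) / np.maximum(f, 1e-300)

    logpost = np.log(np.maximum(f, 1e-300)).sum(axis=3)
    logpost += (-0.5 * (d1g / coef_sd) ** 2)[:, None, None]
    logpost -= logpost.max()
    post = np.exp(logpost)
    post *= (
        _trap_w(d1g)[:, None, None]
        * _trap_w(sg)[None, :, None]
        * _trap_w(tg)[None, None, :]
    )
    post /= post.sum()

    means = {
        "delta1": float((post * d1g[:, None, None]).sum()),
        "sigma": float((post * sg[None, :, None]).sum()),
        "tau": float((post * tg[None, None, :]).sum()),
    }
    Ez = np.einsum("dst,dstc->c", post, g)
    edges = {
        "delta1": (post.sum(axis=(1, 2))[0], post.sum(axis=(1, 2))[-1]),
        "tau": (post.sum(axis=(0, 1))[0], post.sum(axis=(0, 1))[-1]),
    }
    return means, Ez, edges


def sort_quantiles(draws, probs):
    """Order-statistic quantiles by explicit sorting and interpolation."""
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = len(x)
    out = []
    for p in probs:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return np.array(out)
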