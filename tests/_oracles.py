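"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the mathematical definitions with
explicit loops, sharing no code with the package implementation.
"""

import numpy as np


def ncc_direct(pre, post, center, kernel, search):
    """Two-loop zero-normalized cross-correlation over integer lags."""
    ka, kl = kernel
    sa, sl = search
    r, c = center
    ha, hl = ka // 2, kl // 2
    out = np.zeros((2 * sa + 1, 2 * sl + 1))
    ker = pre[r - ha:r + ha + 1, c - hl:c + hl + 1]
    k0 = ker - ker.mean()
    kn = np.sqrt((k0 ** 2).sum())
    for i, da in enumerate(range(-sa, sa + 1)):
        for j, dl in enumerate(range(-sl, sl + 1)):
            win = post[r + da - ha:r + da + ha + 1, c + dl - hl:c + dl + hl + 1]
            w0 = win - win.mean()
            wn = np.sqrt((w0 ** 2).sum())
            if kn <= 1e-12 or wn <= 1e-12:
                out[i, j] = 0.0
            else:
                out[i, j] = (k0 * w0).sum() / (kn * wn)
    return out


def likelihood_direct(pdf, sigma, floor=1e-12):
    """L(u) = max over v in the 3-sigma box around u of pdf(v) * Gauss(v - u)."""
    na, nl = pdf.shape
    sa, sl = sigma
    out = np.full((na, nl), floor)
    for ua in range(na):
        for ul in range(nl):
            best = 0.0
            for va in range(na):
                for vl in range(nl):
                    da, dl = va - ua, vl - ul
                    if abs(da) > 3 * sa or abs(dl) > 3 * sl:
                        continue
                    g = np.exp(-(da ** 2 / (2 * sa ** 2) + dl ** 2 / (2 * sl ** 2)))
                    best = max(best, pdf[va, vl] * g)
            out[ua, ul] = max(best, floor)
    return out


def _spatial_neighbors(i, j, shape):
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ni, nj = i + di, j + dj
        if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
            yield ni, nj


def sbr_direct(pdfs, sigma, floor=1e-12, n_iterations=1):
    """Posterior ∝ prior x product of neighbor likelihoods, synchronous."""
    cur = np.array(pdfs, dtype=float)
    nr, nc = cur.shape[:2]
    for _ in range(n_iterations):
        new = np.empty_like(cur)
        for i in range(nr):
            for j in range(nc):
                post = cur[i, j].copy()
                for ni, nj in _spatial_neighbors(i, j, (nr, nc)):
                    post = post * likelihood_direct(cur[ni, nj], sigma, floor)
                new[i, j] = post / post.sum()
        cur = new
    return cur


def stbr1_direct(past, present, future, sigma_s, sigma_t, floor=1e-12):
    """One SBR pass per time, then temporal combination at the middle time."""
    s_past = sbr_direct(past, sigma_s, floor)
    s_pres = sbr_direct(present, sigma_s, floor)
    s_fut = sbr_direct(future, sigma_s, floor)
    nr, nc = s_pres.shape[:2]
    out = np.empty_like(s_pres)
    for i in range(nr):
        for j in range(nc):
            post = (s_pres[i, j]
                    * likelihood_direct(s_past[i, j], sigma_t, floor)
                    * likelihood_direct(s_fut[i, j], sigma_t, floor))
            out[i, j] = post / post.sum()
    return out


def stbr2_direct(past, present, future, sigma_s, sigma_t, floor=1e-12):
    """Prior x four spatial likelihoods x two temporal likelihoods."""
    present = np.asarray(present, dtype=float)
    nr, nc = present.shape[:2]
    out = np.empty_like(present)
    for i in range(nr):
        for j in range(nc):
            post = present[i, j].copy()
            for ni, nj in _spatial_neighbors(i, j, (nr, nc)):
                post = post * likelihood_direct(present[ni, nj], sigma_s, floor)
            post = post * likelihood_direct(past[i, j], sigma_t, floor)
            post = post * likelihood_direct(future[i, j], sigma_t, floor)
            out[i, j] = post / post.sum()
    return out


def median_direct(a, kernel):
    """Sort-based median filter with edge replication."""
    ka, kl = kernel
    h, w = a.shape
    pad = np.pad(a, ((ka // 2, ka // 2), (kl // 2, kl // 2)), mode="edge")
    out = np.empty_like(a)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(pad[i:i + ka, j:j + kl])
    return out


def ols_gradient_direct(points, disp, center_idx, half_box):
    """Normal-equations affine fit of displacement vs position."""
    p0 = points[center_idx]
    sel = (np.abs(points[:, 0] - p0[0]) <= half_box[0] + 1e-9) & \
          (np.abs(points[:, 1] - p0[1]) <= half_box[1] + 1e-9)
    X = np.column_stack([np.ones(sel.sum()), points[sel, 0] - p0[0],
                         points[sel, 1] - p0[1]])
    beta = np.linalg.inv(X.T @ X) @ X.T @ disp[sel]
    return beta[1:, :].T  # du_a/dx_b
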