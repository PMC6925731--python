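"""Independent naive reference implementations of the printed formulas.

Everything here is written as plain double loops / direct arithmetic, kept
deliberately independent of the package internals so it can serve as an
oracle for the vectorized implementations.
"""

import numpy as np


def naive_icov(I, h=1.0, w=1, longitudinal_axis="col"):
    """Instantaneous coefficient of variation, pixel by pixel."""
    I = np.asarray(I, dtype=float)
    rows, cols = I.shape
    q = np.zeros_like(I)
    for i in range(rows):
        for j in range(cols):
            iN, iS = max(i - 1, 0), min(i + 1, rows - 1)
            jW, jE = max(j - 1, 0), min(j + 1, cols - 1)
            dN = I[iN, j] - I[i, j]
            dS = I[iS, j] - I[i, j]
            dW = I[i, jW] - I[i, j]
            dE = I[i, jE] - I[i, j]
            if w == 2:
                if longitudinal_axis == "col":
                    dW, dE = 2 * dW, 2 * dE
                else:
                    dN, dS = 2 * dN, 2 * dS
            g2 = (dN**2 + dS**2 + dW**2 + dE**2) / (h * I[i, j]) ** 2
            lap = (dN + dS + dW + dE) / (h**2 * I[i, j])
            q2 = (0.5 * g2 - lap**2 / 16.0) / (1.0 + lap / 4.0) ** 2
            q[i, j] = np.sqrt(max(q2, 0.0))
    return q


def naive_diffusion_coeff(q, q0):
    c = 1.0 / (1.0 + (q**2 - q0**2) / (q0**2 * (1.0 + q0**2)))
    return min(max(c, 0.0), 1.0)


def naive_srad_step(I, q0, dt=0.1, h=1.0, w=1, longitudinal_axis="col"):
    """One explicit SRAD update with reflective borders, double loop."""
    I = np.asarray(I, dtype=float)
    rows, cols = I.shape
    q = naive_icov(I, h=h, w=w, longitudinal_axis=longitudinal_axis)
    c = np.empty_like(I)
    for i in range(rows):
        for j in range(cols):
            c[i, j] = naive_diffusion_coeff(q[i, j], q0)
    out = np.empty_like(I)
    for i in range(rows):
        for j in range(cols):
            iN, iS = max(i - 1, 0), min(i + 1, rows - 1)
            jW, jE = max(j - 1, 0), min(j + 1, cols - 1)
            dN = I[iN, j] - I[i, j]
            dS = I[iS, j] - I[i, j]
            dW = I[i, jW] - I[i, j]
            dE = I[i, jE] - I[i, j]
            if w == 2 and longitudinal_axis == "col":
                div = (2 * c[i, jE] * dE + 2 * c[i, j] * dW
                       + c[iS, j] * dS + c[i, j] * dN)
            elif w == 2:
                div = (c[i, jE] * dE + c[i, j] * dW
                       + 2 * c[iS, j] * dS + 2 * c[i, j] * dN)
            else:
                div = (c[i, jE] * dE + c[i, j] * dW
                       + c[iS, j] * dS + c[i, j] * dN)
            out[i, j] = I[i, j] + dt / 4.0 * div / h**2
    return out


def naive_ncc(R, F):
    R = np.asarray(R, dtype=float)
    F = np.asarray(F, dtype=float)
    rbar = R.mean()
    fbar = F.mean()
    num = 0.0
    dr2 = 0.0
    df2 = 0.0
    for m in range(R.shape[0]):
        for n in range(R.shape[1]):
            num += (R[m, n] - rbar) * (F[m, n] - fbar)
            dr2 += (R[m, n] - rbar) ** 2
            df2 += (F[m, n] - fbar) ** 2
    return num / np.sqrt(dr2 * df2)


def naive_nrmse(est, ref):
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    err = np.sqrt(np.mean((est - ref) ** 2))
    return err / (ref.max() - ref.min())


def naive_regression(x, y):
    """Closed-form normal equations + Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    return slope, intercept, r


def naive_bland_altman(a, b):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    mean = d.mean()
    sd = np.sqrt(((d - mean) ** 2).sum() / (len(d) - 1))
    return mean, sd, mean - 1.96 * sd, mean + 1.96 * sd


def count_local_maxima(x):
    """Strict interior local maxima of a 1D series."""
    x = np.asarray(x, dtype=float)
    n = 0
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] >= x[i + 1]:
            n += 1
    return n
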