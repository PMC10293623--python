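"""Spherical-spline interpolation of scalp potentials (Perrin et al.).

A bad electrode's potential is reconstructed from the good electrodes by a
smoothing spline on the unit sphere. The kernel is the Legendre series

    g(x) = (1 / 4*pi) * sum_{n=1}^{N} (2n + 1) / (n * (n + 1))^m * P_n(x)

with ``x`` the cosine of the angle between two electrode directions,
stiffness ``m`` and truncation order ``N``. Interpolation solves the usual
augmented linear system with a constant (mean-potential) term, so the weight
matrix depends only on electrode geometry.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

DEFAULT_ORDER_M = 4
DEFAULT_N_TERMS = 50
DEFAULT_LAMBDA = 1e-5


def g_kernel(cosang: np.ndarray, m: int = DEFAULT_ORDER_M, n_terms: int = DEFAULT_N_TERMS) -> np.ndarray:
    """Evaluate the spherical-spline kernel g(cos angle) elementwise."""
    cosang = np.clip(np.asarray(cosang, dtype=float), -1.0, 1.0)
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n * (n + 1)) ** m
    # P_n evaluated for all orders at once: shape (n_terms,) + cosang.shape
    pn = eval_legendre(n.reshape((-1,) + (1,) * cosang.ndim), cosang[None])
    return np.tensordot(coef, pn, axes=(0, 0)) / (4 * np.pi)


def interpolation_weights(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = DEFAULT_ORDER_M,
    n_terms: int = DEFAULT_N_TERMS,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Weight matrix W (n_bad, n_good) with  v_bad = W @ v_good.

    ``good_pos`` and ``bad_pos`` are unit vectors. The spline coefficients
    solve ``(G + lam*I) c + d*1 = v_good`` subject to ``sum(c) = 0``; the
    estimate at a bad site is ``d + g(bad, good) @ c``. Rows of W sum to 1,
    so constants are reproduced exactly.
    """
    good_pos = np.asarray(good_pos, dtype=float)
    bad_pos = np.atleast_2d(np.asarray(bad_pos, dtype=float))
    n_good = good_pos.shape[0]
    if n_good < 4:
        raise ValueError(
            f"spherical-spline interpolation needs >= 4 good electrodes, got {n_good}"
        )

    G = g_kernel(good_pos @ good_pos.T, m=m, n_terms=n_terms)
    G_reg = G + lam * np.eye(n_good)
    # Augmented system [[G+lam*I, 1], [1^T, 0]] [c; d] = [v; 0]
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G_reg
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    # Solve for the mapping of all canonical basis vectors at once:
    B = np.zeros((n_good + 1, n_good))
    B[:n_good, :] = np.eye(n_good)
    CD = np.linalg.solve(A, B)  # rows: c-coefficients per good channel, then d
    C, d = CD[:n_good], CD[n_good]

    Gb = g_kernel(bad_pos @ good_pos.T, m=m, n_terms=n_terms)
    return Gb @ C + d[None, :]
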