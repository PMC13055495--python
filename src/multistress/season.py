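"""Season-wide penalized additive model with plate random intercepts.

A simplified generalized additive mixed model: the parametric 2x2 factorial
terms (intercept, warming, pollution, interaction) are the contract; on top
of them sit one centered B-spline smooth of time per treatment combination
(ridge-penalized, penalty chosen by GCV) and optional ridge-penalized plate
random intercepts whose penalty is iterated from the implied variance
component.  No attempt is made to replicate mgcv's REML/edf machinery - the
smooths exist to absorb seasonal trend so that the factorial coefficients
are estimated against it, and are reported with approximate effective
degrees of freedom only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PenalizedAdditiveFit", "fit_penalized_additive"]

_GCV_GRID = 10.0 ** np.arange(-2.0, 8.0)

#: GCV effective-df inflation; values > 1 guard against the well-known
#: tendency of plain GCV to undersmooth
_GCV_GAMMA = 1.4


def _spline_basis(day: np.ndarray, df: int) -> np.ndarray:
    """Centered cubic B-spline basis of ``day`` with ~df effective columns."""
    u = np.unique(day)
    k = 3 if len(u) > 3 else len(u) - 1
    n_basis = df + 1
    n_internal = max(n_basis - k - 1, 0)
    if n_internal > 0:
        qs = np.linspace(0, 1, n_internal + 2)[1:-1]
        internal = np.quantile(u, qs)
    else:
        internal = np.array([])
    t = np.r_[[u[0]] * (k + 1), internal, [u[-1]] * (k + 1)]
    B = BSpline.design_matrix(day, t, k).toarray()
    return B - B.mean(axis=0)  # sum-to-zero: the constant lives in the intercept


def _working(y, eta, family, phi_nb):
    """IRLS working response and weights for the supported families."""
    if family == "gaussian":
        return y, np.ones_like(y)
    if family == "count_nb":
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + phi_nb * mu)
        return eta + (y - mu) / mu, w
    # binomial / quasi-binomial (binary occurrence and proportion cover)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    return eta + (y - mu) / w, w


@dataclass
class PenalizedAdditiveFit:
    beta: np.ndarray          # all coefficients (parametric first)
    se_parametric: np.ndarray  # Wald SEs of the 4 parametric terms
    edf_total: float
    scale: float
    smooths: Dict[str, Dict[str, np.ndarray]]
    phi_nb: float


def fit_penalized_additive(
    y: np.ndarray,
    Xp: np.ndarray,
    day: np.ndarray,
    cell_labels: np.ndarray,
    plate_codes: Optional[np.ndarray],
    family: str,
    smooth_df: int = 4,
    max_outer: int = 30,
) -> PenalizedAdditiveFit:
    """Fit parametric factorial terms + per-cell time smooths (+ plate effects).

    ``Xp`` is the (n, 4) parametric design; ``cell_labels`` assigns each row
    to one of the four treatment combinations; ``plate_codes`` (integer codes
    or None) switches the ridge-penalized plate random intercepts on/off.
    """
    n = len(y)
    B = _spline_basis(day, smooth_df)
    cells = sorted(set(cell_labels.tolist()))
    blocks = [Xp]
    block_slices = {}
    pos = Xp.shape[1]
    for c in cells:
        ind = (cell_labels == c).astype(float)[:, None]
        blocks.append(B * ind)
        block_slices[c] = slice(pos, pos + B.shape[1])
        pos += B.shape[1]
    n_smooth = pos - Xp.shape[1]
    if plate_codes is not None:
        n_plates = int(plate_codes.max()) + 1
        Z = np.zeros((n, n_plates))
        Z[np.arange(n), plate_codes] = 1.0
        blocks.append(Z)
        plate_slice = slice(pos, pos + n_plates)
        pos += n_plates
    else:
        plate_slice = None
    X = np.hstack(blocks)
    p_tot = X.shape[1]

    def penalty(lam_s: float, lam_p: float) -> np.ndarray:
        d = np.zeros(p_tot)
        d[Xp.shape[1]:Xp.shape[1] + n_smooth] = lam_s
        if plate_slice is not None:
            d[plate_slice] = lam_p
        return np.diag(d)

    def solve(lam_s, lam_p, phi_nb, beta0=None, n_irls=25):
        beta = np.zeros(p_tot) if beta0 is None else beta0.copy()
        if family == "count_nb" and beta0 is None:
            beta[0] = np.log(np.mean(y) + 0.1)
        elif family == "binomial" and beta0 is None:
            m = np.clip(np.mean(y), 0.02, 0.98)
            beta[0] = np.log(m / (1 - m))
        S = penalty(lam_s, lam_p)
        for _ in range(n_irls):
            eta = X @ beta
            z, w = _working(y, eta, family, phi_nb)
            XtW = X.T * w
            A = XtW @ X + S
            beta_new = np.linalg.solve(A, XtW @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-9:
                beta = beta_new
                break
            beta = beta_new
        eta = X @ beta
        z, w = _working(y, eta, family, phi_nb)
        XtW = X.T * w
        A = XtW @ X + S
        Ainv = np.linalg.inv(A)
        H = Ainv @ (XtW @ X)
        edf = float(np.trace(H))
        resid2 = float(np.sum(w * (z - eta) ** 2))
        return beta, Ainv, H, edf, resid2, w

    # NB dispersion: moment estimate from a Poisson-weight pilot fit
    phi_nb = 0.0
    if family == "count_nb":
        beta_pilot, *_ = solve(1.0, 1.0, 0.0)
        mu = np.exp(np.clip(X @ beta_pilot, -30, 30))
        num = float(np.sum((y - mu) ** 2 - mu))
        den = float(np.sum(mu ** 2))
        phi_nb = max(num / den, 1e-8) if den > 0 else 1e-8

    # smooth penalty by GCV (deviance proxy: weighted working residuals)
    lam_p = 1.0
    best = (np.inf, _GCV_GRID[0])
    for lam_s in _GCV_GRID:
        _, _, _, edf, resid2, _ = solve(lam_s, lam_p, phi_nb)
        gcv = n * resid2 / (n - _GCV_GAMMA * edf) ** 2
        if gcv < best[0]:
            best = (gcv, lam_s)
    lam_s = best[1]

    # plate variance component via Schall's update: sigma_b^2 = b'b / edf_b
    # with edf_b the effective df of the plate block (accounts for BLUP
    # shrinkage); lambda_p = scale / sigma_b^2
    if plate_slice is not None:
        for _ in range(6):
            beta, Ainv, H, edf, resid2, w = solve(lam_s, lam_p, phi_nb)
            scale = resid2 / max(n - edf, 1.0) if family == "gaussian" else 1.0
            b_pl = beta[plate_slice]
            edf_pl = float(np.trace(H[plate_slice, plate_slice]))
            var_b = float(np.sum(b_pl ** 2)) / max(edf_pl, 1e-6)
            lam_p_new = np.clip(scale / max(var_b, 1e-10), 1e-3, 1e8)
            if abs(np.log(lam_p_new / lam_p)) < 0.02:
                lam_p = lam_p_new
                break
            lam_p = lam_p_new

    beta, Ainv, H, edf, resid2, w = solve(lam_s, lam_p, phi_nb)
    scale = resid2 / max(n - edf, 1.0) if family == "gaussian" else 1.0
    cov = scale * Ainv
    se_par = np.sqrt(np.diag(cov)[: Xp.shape[1]])

    smooths: Dict[str, Dict[str, np.ndarray]] = {}
    order = np.argsort(day)
    udays, first = np.unique(day[order], return_index=True)
    for c in cells:
        sl = block_slices[c]
        fitted_all = B @ beta[sl]
        fitted = fitted_all[order][first]
        edf_c = float(np.trace(H[sl, sl]))
        smooths[c] = {
            "days": udays,
            "fitted": fitted,
            "edf": edf_c,
            "range": float(fitted.max() - fitted.min()),
        }

    return PenalizedAdditiveFit(
        beta=beta, se_parametric=se_par, edf_total=edf,
        scale=scale, smooths=smooths, phi_nb=phi_nb,
    )
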