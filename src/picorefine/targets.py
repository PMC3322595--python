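"""Experimental refinement targets and weighting.

Two experimental targets are available: a least-squares amplitude residual
and an amplitude maximum-likelihood target built on the Rice (acentric) /
folded-Gaussian (centric) distribution with per-resolution-bin error
parameters (alpha, beta).  alpha plays the role of the amplitude-scaling
coefficient D and beta is the complex-plane variance of the model error;
both are estimated by maximizing the likelihood of the cross-validation
(free) reflections and yield the per-reflection figure of merit m and D
used in map coefficients.

The weighted totals are

    T_xyz = wxc_scale * wxc * T_exp + wc * T_xyz_restraints
    T_adp = wxu_scale * wxu * T_exp + wu * T_adp_restraints

with wxc (wxu) estimated automatically as the ratio of restraint- to
experimental-gradient norms, so both terms pull with comparable strength.
"""

from __future__ import annotations

import dataclasses

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e, i1e

from .model_data import ReflectionSet, resolution_bins


# ---------------------------------------------------------------------------
# LS target
# ---------------------------------------------------------------------------

def ls_target(f_obs: np.ndarray, f_model_amp: np.ndarray,
              weights: np.ndarray | None = None,
              selection: np.ndarray | None = None,
              fit_scale: bool = True) -> tuple[float, np.ndarray]:
    """sum w (|Fo| - k |Fm|)^2 with LS scale k; gradient w.r.t. |Fm|.

    The returned gradient treats k as fixed at its optimum (the extra term
    from dk/d|Fm| vanishes at the LS optimum).
    """
    fo = np.asarray(f_obs, float)
    fm = np.asarray(f_model_amp, float)
    n = len(fo)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    sel = np.ones(n, bool) if selection is None else selection
    if fit_scale:
        denom = np.sum(w[sel] * fm[sel] ** 2)
        k = np.sum(w[sel] * fo[sel] * fm[sel]) / denom if denom > 0 else 1.0
    else:
        k = 1.0
    resid = np.where(sel, fo - k * fm, 0.0)
    value = float(np.sum(w * resid**2))
    grad = np.where(sel, -2.0 * w * k * resid, 0.0)
    return value, grad


# ---------------------------------------------------------------------------
# ML (Rice / folded Gaussian) target
# ---------------------------------------------------------------------------

def centric_flags(miller: np.ndarray, spacegroup_hm: str) -> np.ndarray:
    ops = gemmi.SpaceGroup(spacegroup_hm).operations()
    return np.array([ops.is_reflection_centric(list(h)) for h in
                     np.asarray(miller, int)])


def epsilon_factors(miller: np.ndarray, spacegroup_hm: str) -> np.ndarray:
    ops = gemmi.SpaceGroup(spacegroup_hm).operations()
    return np.array([ops.epsilon_factor(list(h)) for h in
                     np.asarray(miller, int)], float)


@dataclasses.dataclass
class ErrorModel:
    """Per-bin likelihood parameters and their per-reflection expansion."""
    bin_s2: np.ndarray      # bin centers, 1/d^2
    alpha: np.ndarray       # D-like scale per bin
    beta: np.ndarray        # variance-like per bin (> 0)

    def interpolate(self, s2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-reflection (alpha, beta), linear in 1/d^2."""
        if len(self.bin_s2) == 1:
            return (np.full(len(s2), self.alpha[0]),
                    np.full(len(s2), self.beta[0]))
        a = np.interp(s2, self.bin_s2, self.alpha)
        b = np.interp(s2, self.bin_s2, self.beta)
        return a, np.maximum(b, 1e-10)

    def m_and_d(self, f_obs: np.ndarray, f_model_amp: np.ndarray,
                s2: np.ndarray, centric: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Figure of merit m and amplitude coefficient D per reflection."""
        alpha, beta = self.interpolate(s2)
        # acentric argument 2 Fo D Fc / beta; centric Fo D Fc / beta
        xa = 2.0 * f_obs * alpha * f_model_amp / beta
        xc = f_obs * alpha * f_model_amp / beta
        m = np.where(centric, np.tanh(xc), _i1_over_i0(xa))
        return m, alpha


def _i1_over_i0(x: np.ndarray) -> np.ndarray:
    return i1e(x) / np.maximum(i0e(x), 1e-300)


def ml_residual(f_obs: np.ndarray, f_model_amp: np.ndarray,
                alpha: np.ndarray, beta: np.ndarray,
                centric: np.ndarray, epsilon: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-reflection -log likelihood and its derivative w.r.t. |F_model|.

    Acentric (Rice):
        -ln P = -ln(2 Fo/(eb)) + (Fo^2 + a^2 Fm^2)/(eb) - ln I0(2 Fo a Fm/(eb))
    Centric (folded Gaussian):
        -ln P = -ln((2/(pi eb))^1/2) + (Fo^2 + a^2 Fm^2)/(2 eb)
                - ln cosh(Fo a Fm/(eb))
    with eb = epsilon * beta.
    """
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    eb = epsilon * beta
    fo, fm = f_obs, f_model_amp
    a = alpha
    xa = 2.0 * fo * a * fm / eb
    xc = fo * a * fm / eb
    # log I0(x) = log(i0e(x)) + |x| ; log cosh stable via logaddexp
    log_i0 = np.log(np.maximum(i0e(xa), 1e-300)) + np.abs(xa)
    log_cosh = np.logaddexp(xc, -xc) - np.log(2.0)
    val_ac = (-np.log(np.maximum(2.0 * fo / eb, 1e-300))
              + (fo**2 + a**2 * fm**2) / eb - log_i0)
    val_c = (-0.5 * np.log(2.0 / (np.pi * eb))
             + (fo**2 + a**2 * fm**2) / (2.0 * eb) - log_cosh)
    g_ac = 2.0 * a**2 * fm / eb - (2.0 * fo * a / eb) * _i1_over_i0(xa)
    g_c = a**2 * fm / eb - (fo * a / eb) * np.tanh(xc)
    return (np.where(centric, val_c, val_ac),
            np.where(centric, g_c, g_ac))


def ml_target(f_obs: ReflectionSet, f_model_amp: np.ndarray,
              error: ErrorModel, spacegroup_hm: str = "P 1",
              selection: np.ndarray | None = None
              ) -> tuple[float, np.ndarray]:
    """Summed -log amplitude likelihood over the selection (default: work)."""
    sel = f_obs.work if selection is None else selection
    s2 = f_obs.s2
    alpha, beta = error.interpolate(s2)
    centric = centric_flags(f_obs.miller, spacegroup_hm)
    eps = epsilon_factors(f_obs.miller, spacegroup_hm)
    vals, grads = ml_residual(f_obs.data, f_model_amp, alpha, beta,
                              centric, eps)
    value = float(np.sum(vals[sel]))
    grad = np.where(sel, grads, 0.0)
    return value, grad


def estimate_error_model(f_obs: ReflectionSet, f_model_amp: np.ndarray,
                         spacegroup_hm: str = "P 1",
                         n_bins: int | None = None,
                         min_free: int = 25) -> ErrorModel:
    """Per-bin (alpha, beta) maximizing the free-set likelihood.

    Falls back to the work set when fewer than ``min_free`` free
    reflections exist.  Bins with fewer than 8 usable reflections are
    merged into their neighbours by construction of the equal-count
    binning.
    """
    sel = f_obs.free
    if sel.sum() < min_free:
        sel = f_obs.work
    d = f_obs.d_spacing
    s2 = f_obs.s2
    centric = centric_flags(f_obs.miller, spacegroup_hm)
    eps = epsilon_factors(f_obs.miller, spacegroup_hm)
    if n_bins is None:
        n_bins = int(np.clip(sel.sum() // 50, 1, 10))
    labels = resolution_bins(d, target_per_bin=max(len(d) // n_bins, 1),
                             min_per_bin=1)
    uniq = np.unique(labels)
    bin_s2, alphas, betas = [], [], []
    for b in uniq:
        m = (labels == b) & sel
        if m.sum() < 8:
            m = labels == b  # sparse free set in this bin: use everything
        fo, fm = f_obs.data[m], f_model_amp[m]
        cen, ep = centric[m], eps[m]

        def nll(p):
            a, log_b = p
            vals, _ = ml_residual(fo, fm, np.full_like(fo, a),
                                  np.full_like(fo, np.exp(log_b)), cen, ep)
            return np.sum(vals)

        corr = np.sum(fo * fm) / max(np.sum(fm**2), 1e-300)
        resid_var = max(np.mean((fo - corr * fm) ** 2), 1e-6)
        res = minimize(nll, x0=[corr, np.log(resid_var)],
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 400})
        a_hat, b_hat = res.x[0], float(np.exp(res.x[1]))
        bin_s2.append(np.mean(s2[labels == b]))
        alphas.append(max(a_hat, 0.0))
        betas.append(max(b_hat, 1e-10))
    order = np.argsort(bin_s2)
    return ErrorModel(np.array(bin_s2)[order], np.array(alphas)[order],
                      np.array(betas)[order])


def figures_of_merit(f_obs: ReflectionSet, f_model_amp: np.ndarray,
                     error: ErrorModel, spacegroup_hm: str = "P 1"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(m, D) per reflection for map coefficients."""
    centric = centric_flags(f_obs.miller, spacegroup_hm)
    eps = epsilon_factors(f_obs.miller, spacegroup_hm)
    alpha, beta = error.interpolate(f_obs.s2)
    eb = eps * beta
    xa = 2.0 * f_obs.data * alpha * f_model_amp / eb
    xc = f_obs.data * alpha * f_model_amp / eb
    m = np.where(centric, np.tanh(xc), _i1_over_i0(xa))
    return m, alpha


# ---------------------------------------------------------------------------
# Weighted total target
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TargetWeights:
    wx_scale: float = 1.0  # wxc_scale or wxu_scale
    wx: float = 1.0        # wxc or wxu (usually the automatic estimate)
    w_restraints: float = 1.0  # wc or wu

    def validate(self) -> None:
        if min(self.wx_scale, self.wx, self.w_restraints) < 0:
            raise ValueError("weights must be non-negative")


def assemble_total_target(exp_value: float, exp_grad: np.ndarray,
                          rest_value: float, rest_grad: np.ndarray,
                          weights: TargetWeights
                          ) -> tuple[float, np.ndarray]:
    """T = wx_scale * wx * T_exp + w_restraints * T_restraints."""
    weights.validate()
    wtot = weights.wx_scale * weights.wx
    value = wtot * exp_value + weights.w_restraints * rest_value
    grad = wtot * exp_grad + weights.w_restraints * rest_grad
    return float(value), grad


def estimate_weight_auto(grad_exp: np.ndarray, grad_restraints: np.ndarray,
                         fallback: float = 1.0) -> float:
    """wx = ||g_restraints|| / ||g_exp||, balancing the two pulls."""
    ge = np.linalg.norm(np.asarray(grad_exp).ravel())
    gr = np.linalg.norm(np.asarray(grad_restraints).ravel())
    if ge == 0.0:
        return fallback
    if gr == 0.0:
        return 1.0
    return float(gr / ge)
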