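"""Total model structure factor: scaling, bulk solvent, twinning, R factors.

The total structure factor is assembled as

    F_model(h) = k_overall * exp(-2 pi^2 s^t U_cryst s)
                 * [ F_calc(h) + k_sol exp(-B_sol s^2/4) F_mask(h) ]

with s the Cartesian reciprocal-lattice vector of h (|s| = 1/d), U_cryst a
symmetric overall anisotropic scale matrix in the Cartesian basis (A^2,
constrained by the crystal symmetry), and (k_sol, B_sol) the flat
bulk-solvent parameters.  Twinned data mix intensities of operator-related
reflections: |F_twin(h)|^2 = (1-a)|F(h)|^2 + a|F(Th)|^2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from .model_data import AtomicModel, ReflectionSet
from . import scatter


@dataclasses.dataclass
class ScaleModel:
    k_overall: float = 1.0
    k_sol: float = 0.0
    b_sol: float = 0.0
    u_cryst: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros((3, 3)))

    def validate(self) -> None:
        if self.k_overall <= 0:
            raise ValueError("k_overall must be positive")
        if self.k_sol < 0 or self.b_sol < 0:
            raise ValueError("k_sol and B_sol must be non-negative")
        if not np.allclose(self.u_cryst, self.u_cryst.T):
            raise ValueError("U_cryst must be symmetric")


@dataclasses.dataclass
class TwinState:
    operator: np.ndarray  # 3x3 integer matrix acting on Miller indices
    fraction: float = 0.0

    def __post_init__(self) -> None:
        self.operator = np.asarray(self.operator, int).reshape(3, 3)
        if not 0.0 <= self.fraction <= 0.5:
            raise ValueError("twin fraction must lie in [0, 0.5]")


def _svec_s2(miller: np.ndarray, cell) -> tuple[np.ndarray, np.ndarray]:
    fmat = np.array(cell.frac.mat.tolist())
    svec = miller @ fmat
    s2 = np.sum(svec * svec, axis=1)
    return svec, s2


def scale_factors(scales: ScaleModel, miller: np.ndarray, cell
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(overall anisotropic scale K(h), solvent scale k_sol exp(-B_sol s2/4))."""
    svec, s2 = _svec_s2(np.asarray(miller, int), cell)
    aniso = np.exp(-2.0 * np.pi**2 *
                   np.einsum("hi,ij,hj->h", svec, scales.u_cryst, svec))
    K = scales.k_overall * aniso
    ksol_h = scales.k_sol * np.exp(-scales.b_sol * s2 / 4.0)
    return K, ksol_h


def total_fmodel(f_calc: np.ndarray, f_mask: np.ndarray,
                 scales: ScaleModel, miller: np.ndarray, cell) -> np.ndarray:
    if len(f_calc) != len(miller) or len(f_mask) != len(miller):
        raise ValueError("F_calc/F_mask/Miller arrays are not aligned")
    K, ksol_h = scale_factors(scales, miller, cell)
    return K * (f_calc + ksol_h * f_mask)


def r_factor(f_obs: np.ndarray, f_model_amp: np.ndarray,
             selection: np.ndarray | None = None,
             fit_scale: bool = True) -> float:
    """R = sum | |Fo| - k |Fm| | / sum |Fo| with k the LS scale."""
    fo = np.asarray(f_obs, float)
    fm = np.asarray(f_model_amp, float)
    if selection is not None:
        fo, fm = fo[selection], fm[selection]
    if len(fo) == 0:
        raise ValueError("empty selection for R factor")
    if fit_scale:
        denom = np.sum(fm * fm)
        k = np.sum(fo * fm) / denom if denom > 0 else 0.0
    else:
        k = 1.0
    return float(np.sum(np.abs(fo - k * fm)) / np.sum(fo))


# ---------------------------------------------------------------------------
# Bulk-solvent and scale fitting
# ---------------------------------------------------------------------------

def _u_basis(spacegroup_hm: str) -> list[np.ndarray]:
    """Symmetric basis matrices for U_cryst allowed by the symmetry.

    Triclinic cells get all six components; orthorhombic (and higher
    orthogonal toy groups handled here) keep the diagonal only.
    """
    def e(i, j):
        m = np.zeros((3, 3))
        m[i, j] = m[j, i] = 1.0
        return m
    diag = [e(0, 0), e(1, 1), e(2, 2)]
    if spacegroup_hm.replace(" ", "") in ("P1",):
        return diag + [e(0, 1), e(0, 2), e(1, 2)]
    return diag


def fit_bulk_solvent_and_scales(
        f_obs: ReflectionSet, f_calc: np.ndarray, f_mask: np.ndarray,
        spacegroup_hm: str = "P 1",
        k_sol_grid: np.ndarray | None = None,
        b_sol_grid: np.ndarray | None = None) -> ScaleModel:
    """LS fit of (k_overall, k_sol, B_sol, U_cryst) to |F_obs|.

    Coarse grid over (k_sol, B_sol) with closed-form k_overall and a
    log-linear constrained U_cryst fit at each node, then bounded polish of
    (k_sol, B_sol).  Never worse than the zero-solvent baseline.
    """
    sel = f_obs.work
    if sel.sum() < 50:
        sel = ~f_obs.excluded
    fo = f_obs.data[sel]
    if np.all(fo == 0):
        raise ValueError("degenerate F_obs: all amplitudes zero")
    miller = f_obs.miller[sel]
    fc, fm = f_calc[sel], f_mask[sel]
    svec, s2 = _svec_s2(miller, f_obs.cell)
    basis = _u_basis(spacegroup_hm)
    bq = np.stack([np.einsum("hi,ij,hj->h", svec, B, svec) for B in basis],
                  axis=1)  # (n, n_basis)

    def eval_params(k_sol: float, b_sol: float,
                    ucoef: np.ndarray | None) -> tuple[float, float, np.ndarray]:
        amp = np.abs(fc + k_sol * np.exp(-b_sol * s2 / 4.0) * fm)
        if ucoef is None:
            ucoef = np.zeros(len(basis))
            good = (amp > 1e-6 * amp.max()) & (fo > 0)
            if good.sum() >= len(basis) + 1:
                # ln(fo/amp) ~ ln k - 2 pi^2 s^t U s  (log-linear LS)
                y = np.log(fo[good] / amp[good])
                A = np.column_stack([np.ones(good.sum()),
                                     -2 * np.pi**2 * bq[good]])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                ucoef = coef[1:]
        aniso = np.exp(-2 * np.pi**2 * (bq @ ucoef))
        fmamp = aniso * amp
        denom = np.sum(fmamp**2)
        k = np.sum(fo * fmamp) / denom if denom > 0 else 1.0
        r = np.sum(np.abs(fo - k * fmamp)) / np.sum(fo)
        return r, k, ucoef

    if k_sol_grid is None:
        k_sol_grid = np.arange(0.0, 0.601, 0.05)
    if b_sol_grid is None:
        b_sol_grid = np.arange(10.0, 80.1, 5.0)
    best = (np.inf, 0.0, 0.0, 1.0, np.zeros(len(basis)))
    r0, k0, u0 = eval_params(0.0, 0.0, None)
    best = (r0, 0.0, 0.0, k0, u0)
    if np.any(np.abs(fm) > 0):
        for ks in k_sol_grid:
            for bs in b_sol_grid:
                r, k, u = eval_params(ks, bs, None)
                if r < best[0] - 1e-12:
                    best = (r, ks, bs, k, u)
        if best[1] > 0:
            res = minimize(lambda p: eval_params(p[0], p[1], None)[0],
                           x0=[best[1], best[2]], method="L-BFGS-B",
                           bounds=[(0.0, 1.0), (1.0, 200.0)])
            r, k, u = eval_params(res.x[0], res.x[1], None)
            if r < best[0]:
                best = (r, res.x[0], res.x[1], k, u)
    _, ks, bs, k, ucoef = best
    u_cryst = sum(c * B for c, B in zip(ucoef, _u_basis(spacegroup_hm)))
    return ScaleModel(k_overall=float(k), k_sol=float(ks), b_sol=float(bs),
                      u_cryst=np.asarray(u_cryst, float))


def optimize_mask_params(f_obs: ReflectionSet, model: AtomicModel,
                         f_calc: np.ndarray,
                         trials: list[tuple[float, float]],
                         defaults: tuple[float, float] = (1.1, 0.9),
                         spacing: float = 0.6) -> tuple[float, float]:
    """Pick the (r_solvent, r_shrink) pair minimizing R_work after rescaling.

    Ties (to 1e-10 in R) are broken toward the pair closest to the
    conventional defaults.
    """
    if not trials:
        raise ValueError("at least one trial pair required")
    results = []
    for rs, rsh in trials:
        mask = scatter.build_solvent_mask(model, rs, rsh, spacing)
        fm = scatter.f_mask(mask, f_obs.miller)
        scales = fit_bulk_solvent_and_scales(f_obs, f_calc, fm,
                                             model.spacegroup.hm)
        amp = np.abs(total_fmodel(f_calc, fm, scales, f_obs.miller,
                                  f_obs.cell))
        r = r_factor(f_obs.data, amp, f_obs.work, fit_scale=False)
        results.append((r, (rs, rsh)))
    r_best = min(r for r, _ in results)
    tied = [p for r, p in results if r <= r_best + 1e-10]
    return min(tied, key=lambda p: (p[0] - defaults[0])**2 +
               (p[1] - defaults[1])**2)


# ---------------------------------------------------------------------------
# Twinning
# ---------------------------------------------------------------------------

def twin_fmodel(f_model: np.ndarray, twin: TwinState,
                miller: np.ndarray) -> np.ndarray:
    """Amplitudes of the twinned model: intensity mixing across the operator."""
    amp2 = np.abs(np.asarray(f_model)) ** 2
    lookup = {tuple(h): i for i, h in enumerate(np.asarray(miller, int))}
    mates = np.empty(len(miller), int)
    missing = []
    for i, h in enumerate(np.asarray(miller, int)):
        th = tuple(twin.operator @ h)
        j = lookup.get(th)
        if j is None:  # Friedel mate of the image may be the one stored
            j = lookup.get(tuple(-np.array(th)))
        if j is None:
            missing.append(th)
            j = i
        mates[i] = j
    if missing:
        raise ValueError(f"twin operator image outside the Miller set: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    a = twin.fraction
    return np.sqrt((1.0 - a) * amp2 + a * amp2[mates])


def estimate_twin_fraction(f_obs: ReflectionSet, f_model: np.ndarray,
                           twin_operator: np.ndarray,
                           step: float = 0.01) -> float:
    """Grid search for the twin fraction over [0, 0.5] minimizing R_work.

    Ties are broken toward the smaller fraction (the less drastic model).
    """
    grid = np.arange(0.0, 0.5 + step / 2, step)
    best_a, best_r = 0.0, np.inf
    for a in grid:
        amp = twin_fmodel(f_model, TwinState(twin_operator, a), f_obs.miller)
        r = r_factor(f_obs.data, amp, f_obs.work)
        if r < best_r - 1e-12:
            best_r, best_a = r, float(a)
    return round(best_a, 10)


# ---------------------------------------------------------------------------
# FModel container
# ---------------------------------------------------------------------------

class FModel:
    """Assembled total-structure-factor state for one model + data set."""

    def __init__(self, model: AtomicModel, f_obs: ReflectionSet,
                 mask_params: tuple[float, float] = (1.1, 0.9),
                 mask_spacing: float = 0.6,
                 use_solvent: bool = True,
                 twin: TwinState | None = None):
        self.model = model
        self.f_obs = f_obs
        self.mask_params = mask_params
        self.mask_spacing = mask_spacing
        self.use_solvent = use_solvent
        self.twin = twin
        self.scales = ScaleModel()
        self.f_calc = np.zeros(len(f_obs), complex)
        self.f_mask_arr = np.zeros(len(f_obs), complex)
        self.update_f_calc()
        self.update_mask()

    def update_f_calc(self) -> None:
        self.f_calc = scatter.f_calc_direct(self.model, self.f_obs.miller)

    def update_mask(self) -> None:
        if self.use_solvent and self.model.n_atoms:
            mask = scatter.build_solvent_mask(
                self.model, self.mask_params[0], self.mask_params[1],
                self.mask_spacing)
            self.f_mask_arr = scatter.f_mask(mask, self.f_obs.miller)
        else:
            self.f_mask_arr = np.zeros(len(self.f_obs), complex)

    def update_scales(self) -> None:
        self.scales = fit_bulk_solvent_and_scales(
            self.f_obs, self.f_calc, self.f_mask_arr,
            self.model.spacegroup.hm)

    @property
    def f_model(self) -> np.ndarray:
        return total_fmodel(self.f_calc, self.f_mask_arr, self.scales,
                            self.f_obs.miller, self.f_obs.cell)

    def f_model_at(self, miller: np.ndarray) -> np.ndarray:
        """Evaluate the total structure factor at arbitrary indices."""
        fc = scatter.f_calc_direct(self.model, miller)
        if self.use_solvent and self.model.n_atoms and \
                np.any(np.abs(self.f_mask_arr) > 0):
            mask = scatter.build_solvent_mask(
                self.model, self.mask_params[0], self.mask_params[1],
                self.mask_spacing)
            fm = scatter.f_mask(mask, miller)
        else:
            fm = np.zeros(len(miller), complex)
        return total_fmodel(fc, fm, self.scales, miller, self.f_obs.cell)

    @property
    def f_model_amp(self) -> np.ndarray:
        f = self.f_model
        if self.twin is not None and self.twin.fraction > 0:
            return twin_fmodel(f, self.twin, self.f_obs.miller)
        return np.abs(f)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.f_model)

    def r_work(self) -> float:
        return r_factor(self.f_obs.data, self.f_model_amp, self.f_obs.work,
                        fit_scale=False)

    def r_free(self) -> float:
        if not self.f_obs.free.any():
            return float("nan")
        return r_factor(self.f_obs.data, self.f_model_amp, self.f_obs.free,
                        fit_scale=False)
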