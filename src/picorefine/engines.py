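"""Parameter-class refinement engines and the macro-cycle driver.

Each engine optimizes one class of parameters (coordinates, ADPs,
occupancies, anomalous coefficients, rigid-body transforms) against the
weighted total target while leaving every other class untouched.  The
macro-cycle driver repeats, in order: scale/bulk-solvent refit, error-model
update, ordered-solvent update, coordinate refinement (real-space then
reciprocal-space when both are enabled), ADP refinement and occupancy
refinement, recording R factors and geometry statistics per cycle.
"""

from __future__ import annotations

import dataclasses
import warnings

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .model_data import AtomicModel, Atom, OccupancyGroup, B_TO_U
from .fmodel import FModel
from .restraints import (GeometryRestraintSet, SphereRestraintParams,
                         build_restraints, geometry_target,
                         sphere_adp_restraint, similarity_aniso_restraint)
from .targets import (ErrorModel, TargetWeights, assemble_total_target,
                      estimate_error_model, estimate_weight_auto, ls_target,
                      ml_target)
from . import maps, scatter


# ---------------------------------------------------------------------------
# Experimental target with structure-factor sensitivities
# ---------------------------------------------------------------------------

class XrayTarget:
    """LS or ML experimental target evaluated through an FModel.

    Produces the target value and the complex sensitivity S(h) such that
    dT = sum_h Re[S(h) dF_calc(h)], folding in the overall/solvent scales.
    """

    def __init__(self, fmodel: FModel, kind: str = "ml",
                 error: ErrorModel | None = None):
        if kind not in ("ls", "ml"):
            raise ValueError("target kind must be 'ls' or 'ml'")
        self.fmodel = fmodel
        self.kind = kind
        self.error = error

    def update_error_model(self) -> None:
        self.error = estimate_error_model(
            self.fmodel.f_obs, self.fmodel.f_model_amp,
            self.fmodel.model.spacegroup.hm)

    def value_and_sensitivity(self) -> tuple[float, np.ndarray]:
        fm = self.fmodel
        f_model = fm.f_model
        amp = np.abs(f_model)
        f_obs = fm.f_obs
        if self.kind == "ls":
            w = np.ones(len(f_obs))
            value, g_amp = ls_target(f_obs.data, amp, w, f_obs.work)
        else:
            if self.error is None:
                self.update_error_model()
            value, g_amp = ml_target(f_obs, amp, self.error,
                                     fm.model.spacegroup.hm)
        from .fmodel import scale_factors
        K, _ = scale_factors(fm.scales, f_obs.miller, f_obs.cell)
        safe = np.maximum(amp, 1e-30)
        S = g_amp * K * np.conj(f_model) / safe
        return value, S

    def value(self) -> float:
        return self.value_and_sensitivity()[0]


# ---------------------------------------------------------------------------
# Refinement state
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RefinementState:
    model: AtomicModel
    fmodel: FModel
    restraints: GeometryRestraintSet
    target_kind: str = "ml"
    error: ErrorModel | None = None
    history: list[dict] = dataclasses.field(default_factory=list)
    rng_seed: int = 0

    @classmethod
    def create(cls, model: AtomicModel, f_obs, target_kind: str = "ml",
               use_solvent: bool = True, twin=None,
               rng_seed: int = 0) -> "RefinementState":
        fm = FModel(model, f_obs, use_solvent=use_solvent, twin=twin)
        fm.update_scales()
        return cls(model=model, fmodel=fm,
                   restraints=build_restraints(model),
                   target_kind=target_kind, rng_seed=rng_seed)

    def xray_target(self) -> XrayTarget:
        t = XrayTarget(self.fmodel, self.target_kind, self.error)
        if self.target_kind == "ml" and self.error is None:
            t.update_error_model()
            self.error = t.error
        return t

    def geometry_stats(self) -> dict:
        _, _, stats = geometry_target(self.model, self.restraints)
        return stats

    def record(self, label: str) -> None:
        stats = self.geometry_stats()
        self.history.append({
            "step": label,
            "r_work": self.fmodel.r_work(),
            "r_free": self.fmodel.r_free(),
            "bond_rmsd": stats["bond_rmsd"],
            "angle_rmsd": stats["angle_rmsd"],
        })


# ---------------------------------------------------------------------------
# Coordinate refinement (reciprocal space, L-BFGS)
# ---------------------------------------------------------------------------

def refine_coordinates_lbfgs(state: RefinementState,
                             weights: TargetWeights | None = None,
                             selection: np.ndarray | None = None,
                             max_iter: int = 50) -> RefinementState:
    """Restrained individual-coordinate refinement by L-BFGS.

    All other parameter classes are held fixed; the weighted total target
    is non-increasing over accepted iterations (the result is reverted if
    the optimizer somehow ends higher than it started).
    """
    model = state.model
    fm = state.fmodel
    sel = np.ones(model.n_atoms, bool) if selection is None else selection
    idx = np.where(sel)[0]
    target = state.xray_target()
    x_start = model.coordinates()

    if weights is None:
        weights = auto_coordinate_weights(state)

    def func(x: np.ndarray) -> tuple[float, np.ndarray]:
        xyz = x_start.copy()
        xyz[idx] = x.reshape(-1, 3)
        model.set_coordinates(xyz)
        fm.update_f_calc()
        v_exp, S = target.value_and_sensitivity()
        g_exp_full = scatter.f_calc_param_grads(model, fm.f_obs.miller, S,
                                                "xyz")
        v_rest, g_rest_full, _ = geometry_target(model, state.restraints)
        v, g_full = assemble_total_target(v_exp, g_exp_full, v_rest,
                                          g_rest_full, weights)
        if not np.isfinite(v):
            raise FloatingPointError("non-finite refinement target; "
                                     "check scales and data")
        return v, g_full[idx].ravel()

    v0 = func(x_start[idx].ravel())[0]
    res = minimize(func, x_start[idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxls": 40})
    if res.fun > v0:  # line-search contract: never accept an increase
        model.set_coordinates(x_start)
    else:
        xyz = x_start.copy()
        xyz[idx] = res.x.reshape(-1, 3)
        model.set_coordinates(xyz)
    fm.update_f_calc()
    return state

def auto_coordinate_weights(state: RefinementState) -> TargetWeights:
    """wxc from the gradient-norm ratio at the current point.

    A model at (near-)ideal geometry has a vanishing restraint gradient,
    which would switch the experimental term off entirely; in that case
    the restraint-gradient norm is measured on a slightly shaken copy so
    the ratio reflects the restraint stiffness rather than the accident of
    starting on the ideal.
    """
    target = state.xray_target()
    _, S = target.value_and_sensitivity()
    g_exp = scatter.f_calc_param_grads(state.model, state.fmodel.f_obs.miller,
                                       S, "xyz")
    _, g_rest, _ = geometry_target(state.model, state.restraints)
    g_exp_norm = np.linalg.norm(g_exp)
    if np.linalg.norm(g_rest) < 1e-3 * g_exp_norm or \
            np.linalg.norm(g_rest) < 1e-9:
        from .fixtures import perturb_model
        probe = perturb_model(state.model, "shake", 0.05,
                              seed=state.rng_seed)
        _, g_rest, _ = geometry_target(probe, state.restraints)
    return TargetWeights(wx_scale=1.0,
                         wx=estimate_weight_auto(g_exp, g_rest),
                         w_restraints=1.0)


def optimize_weight_scan(state: RefinementState,
                         trial_scales: tuple[float, ...] = (
                             10.0, 5.0, 2.0, 1.0, 0.5, 0.25, 0.1),
                         geometry_limit: float = 0.015,
                         max_iter: int = 25) -> float:
    """Pick wxc_scale minimizing R_free subject to a bond-rmsd ceiling.

    Each trial runs a short refinement from the same starting model; ties
    in R_free (to 1e-10) break toward the smallest scale, and if no trial
    meets the geometry limit the one with the smallest bond rmsd wins.
    """
    base = auto_coordinate_weights(state)
    start_xyz = state.model.coordinates()
    results = []
    for ts in trial_scales:
        state.model.set_coordinates(start_xyz)
        state.fmodel.update_f_calc()
        w = TargetWeights(wx_scale=ts, wx=base.wx, w_restraints=1.0)
        refine_coordinates_lbfgs(state, weights=w, max_iter=max_iter)
        stats = state.geometry_stats()
        results.append((state.fmodel.r_free(), stats["bond_rmsd"], ts))
    state.model.set_coordinates(start_xyz)
    state.fmodel.update_f_calc()
    ok = [r for r in results if r[1] <= geometry_limit]
    if not ok:
        return min(results, key=lambda r: r[1])[2]
    best_rfree = min(r[0] for r in ok)
    return min(ts for rf, _, ts in ok if rf <= best_rfree + 1e-10)


# ---------------------------------------------------------------------------
# ADP refinement
# ---------------------------------------------------------------------------

def refine_adp(state: RefinementState, mode: str = "iso",
               sphere_params: SphereRestraintParams | None = None,
               weights: TargetWeights | None = None,
               max_iter: int = 40) -> RefinementState:
    """Restrained ADP refinement: isotropic B with sphere restraints or
    anisotropic U with bonded-pair similarity restraints.

    Anisotropic U eigenvalues are clamped non-negative on exit.
    """
    model = state.model
    fm = state.fmodel
    target = state.xray_target()
    if mode == "iso":
        # resolve the gauge between atomic B and the isotropic part of
        # U_cryst: move trace(U_cryst)/3 into the atomic Bs, keep the
        # anisotropic remainder, then refit scales
        tr = float(np.trace(fm.scales.u_cryst)) / 3.0
        b_shift = 8.0 * np.pi**2 * tr
        if abs(b_shift) > 1e-6 and all(a.b_iso + b_shift > 0.5
                                       for a in model.atoms):
            for a in model.atoms:
                a.b_iso += b_shift
            fm.scales.u_cryst = fm.scales.u_cryst - tr * np.eye(3)
            fm.update_f_calc()
            fm.update_scales()
        b0 = model.b_values()
        w = weights
        if w is None:  # fix the auto weight at the starting point
            _, S0 = target.value_and_sensitivity()
            g_exp0 = scatter.f_calc_param_grads(model, fm.f_obs.miller, S0,
                                                "b_iso")
            _, g_rest0 = sphere_adp_restraint(model, sphere_params)
            w = TargetWeights(wx=estimate_weight_auto(g_exp0,
                                                      g_rest0 * B_TO_U))

        def func(b: np.ndarray) -> tuple[float, np.ndarray]:
            for a, bi in zip(model.atoms, b):
                a.b_iso = float(bi)
            fm.update_f_calc()
            v_exp, S = target.value_and_sensitivity()
            g_exp = scatter.f_calc_param_grads(model, fm.f_obs.miller, S,
                                               "b_iso")
            v_rest, g_rest_u = sphere_adp_restraint(model, sphere_params)
            g_rest = g_rest_u * B_TO_U  # chain U -> B
            return assemble_total_target(v_exp, g_exp, v_rest, g_rest, w)

        res = minimize(func, b0, jac=True, method="L-BFGS-B",
                       bounds=[(0.5, 300.0)] * len(b0),
                       options={"maxiter": max_iter})
        final = res.x if res.fun <= func(b0)[0] else b0
        for a, bi in zip(model.atoms, final):
            a.b_iso = float(bi)
    elif mode == "aniso":
        for a in model.atoms:
            if a.u_aniso is None:
                a.u_aniso = a.u_iso * np.eye(3)
        pairs = [(i, j) for i, j, *_ in state.restraints.bonds]
        tri = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        u0 = np.array([[a.u_aniso[i, j] for i, j in tri]
                       for a in model.atoms]).ravel()

        def set_u(u: np.ndarray) -> None:
            for a, row in zip(model.atoms, u.reshape(-1, 6)):
                m = np.empty((3, 3))
                for (i, j), v in zip(tri, row):
                    m[i, j] = m[j, i] = v
                a.u_aniso = m

        w_fixed = [weights]

        def func(u: np.ndarray) -> tuple[float, np.ndarray]:
            set_u(u)
            fm.update_f_calc()
            v_exp, S = target.value_and_sensitivity()
            g_exp = scatter.f_calc_param_grads(model, fm.f_obs.miller, S,
                                               "u_aniso")
            v_rest, g_rest_t = similarity_aniso_restraint(model, pairs)
            g_rest = np.stack([
                [g[i, j] * (1.0 if i == j else 2.0) for i, j in tri]
                for g in g_rest_t])
            if w_fixed[0] is None:  # fix the auto weight at the start
                w_fixed[0] = TargetWeights(
                    wx=estimate_weight_auto(g_exp, g_rest))
            v, g = assemble_total_target(v_exp, g_exp.ravel(),
                                         v_rest, np.asarray(g_rest).ravel(),
                                         w_fixed[0])
            return v, g

        res = minimize(func, u0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter})
        set_u(res.x if res.fun <= func(u0)[0] else u0)
        for a in model.atoms:  # clamp to positive semidefinite
            w_eig, v_eig = np.linalg.eigh(a.u_aniso)
            a.u_aniso = (v_eig * np.maximum(w_eig, 0.0)) @ v_eig.T
    else:
        raise ValueError("mode must be 'iso' or 'aniso'")
    fm.update_f_calc()
    return state


# ---------------------------------------------------------------------------
# Occupancy refinement
# ---------------------------------------------------------------------------

def refine_occupancies(state: RefinementState,
                       groups: list[OccupancyGroup],
                       max_iter: int = 40) -> RefinementState:
    """Constrained occupancy refinement against T_exp alone.

    Sum-to-one groups are reparameterized so the constraint holds exactly
    (the last conformer carries 1 - sum of the others); bounded groups are
    clipped to their bounds.
    """
    if not groups:
        return state
    model, fm = state.model, state.fmodel
    target = state.xray_target()
    # parameter layout: for each group, k-1 free params (sum-to-one) or 1
    layout: list[tuple[OccupancyGroup, slice]] = []
    x0, bounds = [], []
    pos = 0
    for g in groups:
        if g.kind == "sum_to_one":
            occs = [model.atoms[s[0]].occ for s in g.selections]
            npar = len(g.selections) - 1
            x0.extend(occs[:-1])
            bounds.extend([(0.0, 1.0)] * npar)
        else:
            x0.append(model.atoms[g.selections[0][0]].occ)
            bounds.append(g.bounds)
            npar = 1
        layout.append((g, slice(pos, pos + npar)))
        pos += npar

    def apply(x: np.ndarray) -> None:
        for g, sl in layout:
            vals = x[sl]
            if g.kind == "sum_to_one":
                occs = list(vals) + [1.0 - float(np.sum(vals))]
                for s, q in zip(g.selections, occs):
                    for i in s:
                        model.atoms[i].occ = float(np.clip(q, 0.0, 1.0))
            else:
                q = float(np.clip(vals[0], *g.bounds))
                for s in g.selections:
                    for i in s:
                        model.atoms[i].occ = q

    def func(x: np.ndarray) -> tuple[float, np.ndarray]:
        apply(x)
        fm.update_f_calc()
        v, S = target.value_and_sensitivity()
        g_occ = scatter.f_calc_param_grads(model, fm.f_obs.miller, S, "occ")
        grad = np.zeros(len(x))
        for g, sl in layout:
            if g.kind == "sum_to_one":
                g_conf = [sum(g_occ[i] for i in s) for s in g.selections]
                grad[sl] = np.array(g_conf[:-1]) - g_conf[-1]
            else:
                grad[sl] = sum(sum(g_occ[i] for i in s)
                               for s in g.selections)
        return v, grad

    x0 = np.array(x0)
    res = minimize(func, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter})
    apply(res.x if res.fun <= func(x0)[0] else x0)
    fm.update_f_calc()
    return state


# ---------------------------------------------------------------------------
# f' / f'' refinement
# ---------------------------------------------------------------------------

def refine_fprime_fdoubleprime(state: RefinementState,
                               scatterer_classes: list[list[int]],
                               max_iter: int = 40,
                               min_signal: float = 0.0) -> RefinementState:
    """Refine one (f', f'') pair per scatterer class (startable from 0, 0).

    Requires Bijvoet mates in the data; when the mean absolute Bijvoet
    difference carries no significant signal a warning is issued and the
    values are left unchanged.
    """
    model, fm = state.model, state.fmodel
    f_obs = fm.f_obs
    lookup = f_obs.index_map()
    danom = []
    for i, h in enumerate(f_obs.miller):
        j = lookup.get(tuple(-h))
        if j is not None and j > i:
            danom.append(abs(f_obs.data[i] - f_obs.data[j]))
    if not danom or np.mean(danom) <= min_signal:
        warnings.warn("no anomalous difference signal; f'/f'' unchanged")
        return state
    target = state.xray_target()

    def apply(p: np.ndarray) -> None:
        for cls, (fp, fpp) in zip(scatterer_classes, p.reshape(-1, 2)):
            for i in cls:
                model.atoms[i].f_prime = float(fp)
                model.atoms[i].f_double_prime = float(fpp)

    def func(p: np.ndarray) -> tuple[float, np.ndarray]:
        apply(p)
        fm.update_f_calc()
        v, S = target.value_and_sensitivity()
        g = scatter.f_calc_param_grads(model, f_obs.miller, S, "anom")
        grad = np.array([[sum(g[i, 0] for i in cls),
                          sum(g[i, 1] for i in cls)]
                         for cls in scatterer_classes]).ravel()
        return v, grad

    p0 = np.array([[model.atoms[cls[0]].f_prime,
                    model.atoms[cls[0]].f_double_prime]
                   for cls in scatterer_classes]).ravel()
    bounds = [(-10.0, 10.0), (0.0, 10.0)] * len(scatterer_classes)
    res = minimize(func, p0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter})
    apply(res.x if res.fun <= func(p0)[0] else p0)
    fm.update_f_calc()
    return state


# ---------------------------------------------------------------------------
# Rigid-body refinement (multi-zone protocol)
# ---------------------------------------------------------------------------

def rigid_body_refine_mz(state: RefinementState,
                         groups: list[list[int]],
                         zone_start: int = 300,
                         max_iter_per_zone: int = 30) -> RefinementState:
    """Rigid-body refinement over a growing resolution ladder.

    Starts from the lowest-resolution few hundred reflections and doubles
    the reflection count zone by zone until the full set is used; each
    zone LS-refines a rotation + translation per group.
    """
    if not groups:
        raise ValueError("at least one rigid group required")
    for g in groups:
        if len(g) < 3:
            raise ValueError("rigid groups need at least 3 atoms")
    model, fm = state.model, state.fmodel
    f_obs = fm.f_obs
    order = np.argsort(-f_obs.d_spacing)  # lowest resolution first
    sizes = []
    n = zone_start
    while n < len(order):
        sizes.append(n)
        n *= 2
    sizes.append(len(order))
    x_ref = model.coordinates()
    centers = [x_ref[g].mean(axis=0) for g in groups]
    params = np.zeros(6 * len(groups))  # rotvec (rad) + translation per group

    def apply(p: np.ndarray) -> None:
        xyz = x_ref.copy()
        for gi, g in enumerate(groups):
            rv = p[6 * gi:6 * gi + 3]
            t = p[6 * gi + 3:6 * gi + 6]
            R = Rotation.from_rotvec(rv).as_matrix()
            xyz[g] = (x_ref[g] - centers[gi]) @ R.T + centers[gi] + t
        model.set_coordinates(xyz)

    for size in sizes:
        zone = np.zeros(len(f_obs), bool)
        zone[order[:size]] = True
        zone &= f_obs.work

        def func(p: np.ndarray) -> float:
            apply(p)
            fc = scatter.f_calc_direct(model, f_obs.miller[zone])
            from .fmodel import total_fmodel
            fmz = total_fmodel(fc, fm.f_mask_arr[zone], fm.scales,
                               f_obs.miller[zone], f_obs.cell)
            v, _ = ls_target(f_obs.data[zone], np.abs(fmz))
            return v

        bounds = ([(-0.25, 0.25)] * 3 + [(-3.0, 3.0)] * 3) * len(groups)
        res = minimize(func, params, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter_per_zone,
                                "eps": 1e-6, "finite_diff_rel_step": None})
        if res.fun <= func(params):
            params = res.x
    apply(params)
    fm.update_f_calc()
    return state


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def simulated_annealing(state: RefinementState,
                        t_start: float = 30.0, t_end: float = 1.0,
                        n_steps: int = 150, max_step: float = 0.12,
                        weights: TargetWeights | None = None,
                        selection: np.ndarray | None = None,
                        langevin_gamma: float = 0.2,
                        seed: int | None = None) -> RefinementState:
    """Cartesian molecular-dynamics annealing of the weighted total target.

    Velocity-Verlet integration with element masses, Maxwell-distributed
    initial velocities drawn from the seed and per-step velocity rescaling
    to a geometric cooling schedule.  Temperature is kinetic energy per
    degree of freedom in target units; with bond weights of order 1/0.02^2
    per A^2, kT ~ 30 sustains coordinate excursions of a few tenths of an
    angstrom.  The timestep is capped so no atom moves further than
    ``max_step`` per step.  A boolean ``selection`` restricts the mobile
    atoms (all others stay fixed), allowing hot annealing of a suspect
    fragment without melting the rest.  The final state is
    geometry-regularized and briefly minimized.
    """
    if t_start <= 0 or t_end <= 0:
        raise ValueError("temperatures must be positive")
    model, fm = state.model, state.fmodel
    rng = np.random.default_rng(state.rng_seed if seed is None else seed)
    target = state.xray_target()
    if weights is None:
        weights = auto_coordinate_weights(state)
    masses = np.array([gemmi.Element(a.element).weight
                       for a in model.atoms])[:, None]

    def grad(xyz: np.ndarray) -> tuple[float, np.ndarray]:
        model.set_coordinates(xyz)
        fm.update_f_calc()
        v_exp, S = target.value_and_sensitivity()
        g_exp = scatter.f_calc_param_grads(model, fm.f_obs.miller, S, "xyz")
        v_rest, g_rest, _ = geometry_target(model, state.restraints)
        return assemble_total_target(v_exp, g_exp, v_rest, g_rest, weights)

    x = model.coordinates()
    mobile = (np.ones(model.n_atoms, bool) if selection is None
              else np.asarray(selection, bool))
    n_dof = 3 * int(mobile.sum())
    if n_dof == 0:
        raise ValueError("empty annealing selection")
    vel = rng.normal(0.0, 1.0, x.shape) * np.sqrt(t_start / masses)
    vel[~mobile] = 0.0
    schedule = t_start * (t_end / t_start) ** (np.arange(n_steps) /
                                               max(n_steps - 1, 1))
    _, g = grad(x)
    g[~mobile] = 0.0
    for temp in schedule:
        # timestep capped so the fastest atom moves at most max_step
        vmax = np.abs(vel).max()
        amax = np.abs(g / masses).max()
        dt_eff = min(max_step / max(vmax, 1e-9),
                     np.sqrt(2.0 * max_step / max(amax, 1e-9)))
        vel -= 0.5 * dt_eff * g / masses
        vel[~mobile] = 0.0
        x = x + np.clip(dt_eff * vel, -max_step, max_step)
        _, g = grad(x)
        g[~mobile] = 0.0
        vel -= 0.5 * dt_eff * g / masses
        vel[~mobile] = 0.0
        # Langevin-style momentum randomization keeps the motion diffusive
        # (pure rescaling would leave a lone mobile atom ballistic), then
        # rescale to the schedule temperature
        vel = (1.0 - langevin_gamma) * vel + langevin_gamma * \
            rng.normal(0.0, 1.0, x.shape) * np.sqrt(temp / masses)
        vel[~mobile] = 0.0
        ke = 0.5 * np.sum(masses * vel**2)
        t_now = 2.0 * ke / n_dof
        if t_now > 0:
            vel *= np.sqrt(temp / t_now)
    model.set_coordinates(x)
    regularize_geometry(state)
    refine_coordinates_lbfgs(state, weights=weights, max_iter=30)
    return state


def regularize_geometry(state: RefinementState, max_iter: int = 60) -> None:
    """Minimize the geometry restraints alone."""
    model = state.model

    def func(x: np.ndarray) -> tuple[float, np.ndarray]:
        model.set_coordinates(x.reshape(-1, 3))
        v, g, _ = geometry_target(model, state.restraints)
        return v, g.ravel()

    res = minimize(func, model.coordinates().ravel(), jac=True,
                   method="L-BFGS-B", options={"maxiter": max_iter})
    model.set_coordinates(res.x.reshape(-1, 3))
    state.fmodel.update_f_calc()


# ---------------------------------------------------------------------------
# Real-space refinement
# ---------------------------------------------------------------------------

def real_space_refine(state: RefinementState,
                      rho: np.ndarray | None = None,
                      trial_weights: tuple[float, ...] = (8.0, 4.0, 2.0,
                                                          1.0, 0.5),
                      geometry_limit: float = 0.02,
                      r_increase_limit: float = 0.015,
                      local_search_radius: float = 1.2,
                      max_iter: int = 60) -> RefinementState:
    """Refine atoms into the current likelihood-weighted map.

    The 2mFo-DFc map is computed once; each residue first undergoes a
    rigid local translation grid search into density, then all coordinates
    are polished against  -w * sum occ * rho(x)  + T_geometry  for each
    trial weight.  The largest weight keeping the bond rmsd within
    ``geometry_limit`` wins (smallest-violation fallback).  If the
    reciprocal-space R_work rises by more than ``r_increase_limit`` the
    whole result is discarded.
    """
    model, fm = state.model, state.fmodel
    if rho is None:
        target = state.xray_target()
        req = maps.MapRequest(map_p=2.0, map_q=1.0, weighted=True)
        mc = maps.map_coefficients(fm.f_obs, fm, target.error, req,
                                   model.spacegroup.hm)
        rho = maps.synthesize_map(mc, spacing=0.4)
    r_before = fm.r_work()
    x_start = model.coordinates()
    occ = model.occupancies()
    cell = model.cell

    # per-residue rigid translation grid search into density
    def local_search(xyz: np.ndarray) -> np.ndarray:
        out = xyz.copy()
        step = 0.3
        k = int(np.ceil(local_search_radius / step))
        offsets = np.array([(i, j, l) for i in range(-k, k + 1)
                            for j in range(-k, k + 1)
                            for l in range(-k, k + 1)], float) * step
        offsets = offsets[np.linalg.norm(offsets, axis=1)
                          <= local_search_radius + 1e-9]
        residues = {}
        for i, a in enumerate(model.atoms):
            residues.setdefault((a.chain, a.resseq, a.altloc), []).append(i)
        for idxs in residues.values():
            base = out[idxs]
            scores = np.array([
                np.sum(occ[idxs] * maps.map_value_at(rho, cell, base + off))
                for off in offsets])
            out[idxs] = base + offsets[int(np.argmax(scores))]
        return out

    def polish(xyz0: np.ndarray, w: float) -> np.ndarray:
        def func(x: np.ndarray) -> tuple[float, np.ndarray]:
            xyz = x.reshape(-1, 3)
            model.set_coordinates(xyz)
            dens = maps.map_value_at(rho, cell, xyz)
            v_map = -w * float(np.sum(occ * dens))
            g_map = -w * occ[:, None] * maps.map_gradient_at(rho, cell, xyz)
            v_geo, g_geo, _ = geometry_target(model, state.restraints)
            return v_map + v_geo, (g_map + g_geo).ravel()

        res = minimize(func, xyz0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter})
        return res.x.reshape(-1, 3)

    searched = local_search(x_start)
    trials = []
    for w in sorted(trial_weights, reverse=True):
        xyz = polish(searched, w)
        model.set_coordinates(xyz)
        stats = state.geometry_stats()
        trials.append((w, xyz, stats["bond_rmsd"]))
    ok = [t for t in trials if t[2] <= geometry_limit]
    if ok:
        w, xyz, _ = max(ok, key=lambda t: t[0])
    else:
        w, xyz, _ = min(trials, key=lambda t: t[2])
    model.set_coordinates(xyz)
    fm.update_f_calc()
    if fm.r_work() > r_before + r_increase_limit:
        model.set_coordinates(x_start)  # discard
        fm.update_f_calc()
    return state


# ---------------------------------------------------------------------------
# Ordered-solvent (water) update
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WaterUpdateParams:
    b_max: float = 80.0
    occ_min: float = 0.1
    dist_min: float = 2.2
    dist_max: float = 3.6
    peak_cutoff: float = 3.0      # mFo-DFc sigma units for new waters
    peak_2fofc_min: float = 3.0   # 2mFo-DFc sigma required at a new peak
    map_value_min: float = 1.0    # 2mFo-DFc sigma at O center to survive
    map_cc_min: float = 0.0       # reserved; 0 disables the CC filter
    b_new: float | None = None    # None: model average B

    def __post_init__(self) -> None:
        if self.dist_min >= self.dist_max:
            raise ValueError("dist_min must be below dist_max")


def _min_image_dists(xyz_a: np.ndarray, xyz_b: np.ndarray, cell
                     ) -> np.ndarray:
    fmat = np.array(cell.frac.mat.tolist())
    orth = np.array(cell.orth.mat.tolist())
    fa = xyz_a @ fmat.T
    fb = xyz_b @ fmat.T
    d = fa[:, None, :] - fb[None, :, :]
    d -= np.round(d)
    return np.linalg.norm(d @ orth.T, axis=-1)


def update_waters(state: RefinementState,
                  params: WaterUpdateParams | None = None
                  ) -> RefinementState:
    """Remove implausible waters, add difference-map peaks, re-center.

    Removal: B, occupancy, distance-to-model and 2mFo-DFc map-value
    cutoffs.  Addition: mFo-DFc peaks above ``peak_cutoff`` sigma lying
    within [dist_min, dist_max] of a non-water atom become O atoms with B
    set to the model average.  Existing waters are re-centered onto the
    local 2mFo-DFc maximum.
    """
    params = params or WaterUpdateParams()
    model, fm = state.model, state.fmodel
    cell = model.cell
    target = state.xray_target()
    req_2 = maps.MapRequest(map_p=2.0, map_q=1.0, weighted=True)
    req_d = maps.MapRequest(map_p=1.0, map_q=1.0, weighted=True)
    rho2 = maps.synthesize_map(
        maps.map_coefficients(fm.f_obs, fm, target.error, req_2,
                              model.spacegroup.hm), spacing=0.4)
    rhod = maps.synthesize_map(
        maps.map_coefficients(fm.f_obs, fm, target.error, req_d,
                              model.spacegroup.hm), spacing=0.4)
    non_water = [a for a in model.atoms if not a.is_water]
    waters = [a for a in model.atoms if a.is_water]
    nw_xyz = np.array([a.xyz for a in non_water]).reshape(-1, 3)

    kept: list[Atom] = []
    for a in waters:
        if a.b_iso > params.b_max or a.occ < params.occ_min:
            continue
        others = [b for b in model.atoms if b is not a]
        d = _min_image_dists(a.xyz[None, :],
                             np.array([b.xyz for b in others]), cell)[0]
        if d.min() < params.dist_min:
            continue
        dn = _min_image_dists(a.xyz[None, :], nw_xyz, cell)[0] \
            if len(nw_xyz) else np.array([np.inf])
        wat_others = [b for b in waters if b is not a]
        if len(wat_others):
            dw = _min_image_dists(
                a.xyz[None, :], np.array([b.xyz for b in wat_others]),
                cell)[0]
            dn = np.concatenate([dn, dw])
        if dn.min() > params.dist_max:
            continue
        if maps.map_value_at(rho2, cell, a.xyz)[0] < params.map_value_min:
            continue
        kept.append(a)

    # re-center survivors onto the local 2mFo-DFc maximum
    for a in kept:
        a.xyz = _climb_to_peak(rho2, cell, a.xyz)

    # new waters from mFo-DFc peaks
    peaks = _find_peaks(rhod, cell, params.peak_cutoff)
    anchor_xyz = nw_xyz if len(nw_xyz) else np.zeros((0, 3))
    existing = np.array([a.xyz for a in (non_water + kept)]).reshape(-1, 3)
    b_new = params.b_new if params.b_new is not None else \
        float(np.mean([a.b_iso for a in model.atoms]))
    seq = max([a.resseq for a in waters], default=0)
    new_waters: list[Atom] = []
    for p in peaks:
        if len(existing):
            d = _min_image_dists(p[None, :], existing, cell)[0]
            if d.min() < params.dist_min or d.min() > params.dist_max:
                continue
        # a genuine solvent site also shows up in the 2mFo-DFc map;
        # series-termination ripples in the difference map do not
        if maps.map_value_at(rho2, cell, p[None, :])[0] < \
                params.peak_2fofc_min:
            continue
        seq += 1
        w = Atom("O", "O", "W", "HOH", seq, "", p, 1.0, b_new)
        new_waters.append(w)
        existing = np.concatenate([existing, p[None, :]])
    model.atoms = non_water + kept + new_waters
    state.restraints = build_restraints(model)
    fm.model = model
    fm.update_f_calc()
    fm.update_mask()
    fm.update_scales()
    return state


def _climb_to_peak(rho: np.ndarray, cell, xyz: np.ndarray,
                   max_shift: float = 0.6) -> np.ndarray:
    """Steepest-ascent re-centering onto the nearby density maximum."""
    x = xyz.copy()
    for _ in range(40):
        g = maps.map_gradient_at(rho, cell, x[None, :], delta=0.15)[0]
        norm = np.linalg.norm(g)
        if norm < 1e-4:
            break
        step = min(0.1, 0.05 * norm) * g / norm
        x_new = x + step
        if np.linalg.norm(x_new - xyz) > max_shift:
            break
        if maps.map_value_at(rho, cell, x_new[None, :])[0] <= \
                maps.map_value_at(rho, cell, x[None, :])[0]:
            break
        x = x_new
    return x


def _find_peaks(rho: np.ndarray, cell, cutoff: float) -> np.ndarray:
    """Grid local maxima above cutoff, as Cartesian positions."""
    from scipy.ndimage import maximum_filter
    local_max = maximum_filter(rho, size=3, mode="wrap") == rho
    sel = local_max & (rho >= cutoff)
    idx = np.argwhere(sel)
    if not len(idx):
        return np.zeros((0, 3))
    heights = rho[sel]
    order = np.argsort(-heights)
    frac = idx[order] / np.array(rho.shape)
    orth = np.array(cell.orth.mat.tolist())
    return frac @ orth.T


# ---------------------------------------------------------------------------
# Macro-cycle driver
# ---------------------------------------------------------------------------

DEFAULT_STRATEGY = ("scales", "waters", "xyz_real", "xyz_reciprocal", "adp",
                    "occupancy")


def run_macro_cycles(state: RefinementState, n_cycles: int,
                     strategy: tuple[str, ...] = DEFAULT_STRATEGY,
                     water_params: WaterUpdateParams | None = None,
                     occupancy_groups: list[OccupancyGroup] | None = None,
                     anneal_cycles: int = 0,
                     optimize_mask: bool = False) -> RefinementState:
    """The repeatable refinement block.

    Per cycle, in order: refit scales and bulk solvent (optionally mask
    parameters), update the likelihood error model, update ordered
    solvent, refine coordinates (real-space first when both spaces are
    enabled, optionally with simulated annealing in the early cycles),
    refine ADPs, refine occupancies.  R factors and geometry statistics
    are recorded after each cycle.
    """
    allowed = {"scales", "waters", "xyz_reciprocal", "xyz_real", "adp",
               "occupancy", "fprime"}
    if not strategy:
        raise ValueError("empty refinement strategy")
    unknown = set(strategy) - allowed
    if unknown:
        raise ValueError(f"unknown strategy flags: {sorted(unknown)}")
    fm = state.fmodel
    for cycle in range(n_cycles):
        if "scales" in strategy:
            fm.update_mask()
            fm.update_scales()
        if state.target_kind == "ml":
            state.error = estimate_error_model(
                fm.f_obs, fm.f_model_amp, state.model.spacegroup.hm)
        if "waters" in strategy:
            update_waters(state, water_params)
            if state.target_kind == "ml":
                state.error = estimate_error_model(
                    fm.f_obs, fm.f_model_amp, state.model.spacegroup.hm)
        if "xyz_real" in strategy:
            real_space_refine(state)
        if "xyz_reciprocal" in strategy:
            if cycle < anneal_cycles:
                simulated_annealing(state, seed=state.rng_seed + cycle)
            refine_coordinates_lbfgs(state)
        if "adp" in strategy:
            refine_adp(state, mode="iso")
        if "occupancy" in strategy:
            # automatic groups are rebuilt each cycle: the water update may
            # have changed atom indexing
            from .model_data import build_occupancy_groups
            groups = (occupancy_groups if occupancy_groups is not None
                      else build_occupancy_groups(state.model))
            if groups:
                refine_occupancies(state, groups)
        if "fprime" in strategy:
            classes: dict[str, list[int]] = {}
            for i, a in enumerate(state.model.atoms):
                if a.f_double_prime != 0.0 or a.f_prime != 0.0:
                    classes.setdefault(a.element, []).append(i)
            if classes:
                refine_fprime_fdoubleprime(state, list(classes.values()))
        if "scales" in strategy:
            fm.update_scales()
        state.record(f"cycle_{cycle + 1}")
    return state
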