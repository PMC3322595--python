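"""Synthetic toy crystals, simulated data and controlled perturbations.

Every stage of the refinement engine is exercised against structures and
reflection data made here: small P1 or P2(1)2(1)2(1) cells populated with
rigid residue templates (glycine-like chain units, a generic C-C-S ligand,
waters) placed self-avoidingly, with optional alternative conformations and
anomalous scatterers.  Observed amplitudes come from the full forward model
(atomic structure factors, flat bulk solvent, overall scales, optional twin
mixing) plus Gaussian noise, so the ground truth of every simulated
quantity is recorded and recoverable.
"""

from __future__ import annotations

import dataclasses

import gemmi
import numpy as np

from .model_data import Atom, AtomicModel, ReflectionSet, check_free_flags
from .fmodel import ScaleModel, TwinState, total_fmodel, twin_fmodel
from .restraints import load_geometry_dictionary
from . import scatter


@dataclasses.dataclass
class ToySpec:
    """Study conditions for one synthetic crystal.

    Defaults describe the standard toy: a ~20 A P1 cell, a handful of
    glycine-like residues plus waters, 1.6 A data with 5% fractional noise
    on F, a flat bulk solvent at (k_sol, B_sol) = (0.35, 45), no twinning
    and no anomalous signal.
    """
    cell: tuple[float, ...] = (18.0, 20.0, 22.0, 90.0, 90.0, 90.0)
    space_group: str = "P 1"
    n_residues: int = 4
    n_waters: int = 4
    n_ligands: int = 0
    altloc_residues: int = 0  # residues duplicated into A/B conformers
    altloc_occ: tuple[float, float] = (0.6, 0.4)
    b_range: tuple[float, float] = (10.0, 30.0)
    d_min: float = 1.6
    noise: float = 0.05  # fractional sigma on F
    k_sol: float = 0.35
    b_sol: float = 45.0
    k_overall: float = 1.0
    twin_operator: np.ndarray | None = None
    twin_fraction: float = 0.0
    anomalous: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict)  # element -> (f', f'')
    free_fraction: float = 0.05
    min_distance: float = 2.4  # between atoms of different residues
    seed: int = 0


def _place_atom(a: np.ndarray, b: np.ndarray, bond: float,
                angle_deg: float, direction_hint: np.ndarray) -> np.ndarray:
    """Position bonded to b at ``bond`` A with angle a-b-new = angle."""
    v = a - b
    v /= np.linalg.norm(v)
    perp = direction_hint - (direction_hint @ v) * v
    norm = np.linalg.norm(perp)
    if norm < 1e-8:
        perp = np.array([v[1], -v[0], 0.0]) if abs(v[2]) < 0.9 \
            else np.array([0.0, v[2], -v[1]])
        perp -= (perp @ v) * v
        norm = np.linalg.norm(perp)
    perp /= norm
    th = np.deg2rad(angle_deg)
    return b + bond * (np.cos(th) * v + np.sin(th) * perp)


def residue_template(resname: str) -> list[tuple[str, str, np.ndarray]]:
    """Ideal-geometry local coordinates for a toy residue type."""
    d = load_geometry_dictionary()["residues"][resname]
    if resname == "HOH":
        return [("O", "O", np.zeros(3))]
    bonds = {tuple(sorted((b[0], b[1]))): b[2] for b in d["bonds"]}
    if resname == "GLY":
        n = np.zeros(3)
        ca = np.array([bonds[("CA", "N")], 0.0, 0.0])
        c = _place_atom(n, ca, bonds[("C", "CA")], 110.4,
                        np.array([0.0, 1.0, 0.0]))
        o = _place_atom(ca, c, bonds[("C", "O")], 120.8,
                        np.array([0.0, -1.0, 0.3]))
        names = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
        return names
    if resname == "LIG":
        c1 = np.zeros(3)
        c2 = np.array([bonds[("C1", "C2")], 0.0, 0.0])
        s1 = _place_atom(c1, c2, bonds[("C2", "S1")], 112.0,
                         np.array([0.0, 1.0, 0.0]))
        return [("C1", "C", c1), ("C2", "C", c2), ("S1", "S", s1)]
    raise ValueError(f"no template for residue {resname!r}")


def _symmetry_images(xyz: np.ndarray, cell: gemmi.UnitCell,
                     sg: str) -> np.ndarray:
    fmat = np.array(cell.frac.mat.tolist())
    orth = np.array(cell.orth.mat.tolist())
    out = []
    for op in gemmi.SpaceGroup(sg).operations():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        xf = (xyz @ fmat.T) @ rot.T + tran
        out.append(xf)
    return np.concatenate(out, axis=0), orth


def _min_dist_ok(new_xyz: np.ndarray, placed_xyz: np.ndarray,
                 cell: gemmi.UnitCell, sg: str, dmin: float) -> bool:
    if len(placed_xyz) == 0:
        pool = new_xyz
        # still check self vs own symmetry mates (skip identity block)
    all_xyz = np.concatenate([placed_xyz, new_xyz]) if len(placed_xyz) \
        else new_xyz
    frac_all, orth = _symmetry_images(all_xyz, cell, sg)
    nf = np.array(cell.frac.mat.tolist())
    new_f = new_xyz @ nf.T
    n_total = len(all_xyz)
    n_new = len(new_xyz)
    for i, xf in enumerate(new_f):
        df = frac_all - xf
        df -= np.round(df)
        d2 = np.sum((df @ orth.T) ** 2, axis=1)
        # exclude the identity-image self entries of the new residue
        self_idx = n_total - n_new + i
        d2[self_idx] = np.inf
        for k in range(n_new):
            if k != i:
                # identity images of sibling atoms: bonded, allowed
                d2[n_total - n_new + k] = np.inf
        if d2.min() < dmin * dmin:
            return False
    return True


def make_toy_structure(spec: ToySpec) -> AtomicModel:
    """Self-avoiding placement of rigid residue templates in the cell."""
    cell = gemmi.UnitCell(*spec.cell)
    rng = np.random.default_rng(spec.seed)
    residues: list[tuple[str, int]] = (
        [("GLY", 0)] * spec.n_residues + [("LIG", 0)] * spec.n_ligands +
        [("HOH", 0)] * spec.n_waters)
    atoms: list[Atom] = []
    placed: list[np.ndarray] = []
    chain_for = {"GLY": "A", "LIG": "L", "HOH": "W"}
    counters = {"A": 0, "L": 0, "W": 0}
    n_non_water = spec.n_residues + spec.n_ligands
    max_attempts = 4000
    for r_idx, (resname, _) in enumerate(residues):
        template = residue_template(resname)
        local = np.array([t[2] for t in template])
        local = local - local.mean(axis=0)
        for attempt in range(max_attempts):
            from scipy.spatial.transform import Rotation
            R = Rotation.random(random_state=rng).as_matrix()
            if resname == "HOH" and placed and n_non_water > 0:
                # waters sit in the first hydration shell of the model
                anchors = np.concatenate(placed[:n_non_water])
                anchor = anchors[rng.integers(len(anchors))]
                direction = rng.normal(0, 1, 3)
                direction /= np.linalg.norm(direction)
                shift = anchor + rng.uniform(2.6, 3.3) * direction
            else:
                shift = np.array(cell.orth.mat.tolist()) @ \
                    rng.uniform(0, 1, 3)
            xyz = local @ R.T + shift
            prev = np.concatenate(placed) if placed else np.zeros((0, 3))
            if _min_dist_ok(xyz, prev, cell, spec.space_group,
                            spec.min_distance):
                break
        else:
            raise ValueError(
                f"cell too small: cannot place residue {r_idx + 1} "
                f"({resname}) without clashes")
        chain = chain_for[resname]
        counters[chain] += 1
        seq = counters[chain]
        make_altloc = (resname == "GLY" and
                       counters["A"] <= spec.altloc_residues)
        b_vals = rng.uniform(*spec.b_range, size=len(template))
        if make_altloc:
            # second conformer: small rigid shift of the whole residue
            offset = rng.normal(0, 1, 3)
            offset *= 0.6 / np.linalg.norm(offset)
            for (name, el, _), x, b in zip(template, xyz, b_vals):
                atoms.append(Atom(name, el, chain, resname, seq, "A",
                                  x, spec.altloc_occ[0], float(b)))
            for (name, el, _), x, b in zip(template, xyz, b_vals):
                atoms.append(Atom(name, el, chain, resname, seq, "B",
                                  x + offset, spec.altloc_occ[1], float(b)))
            placed.append(np.concatenate([xyz, xyz + offset]))
        else:
            for (name, el, _), x, b in zip(template, xyz, b_vals):
                atoms.append(Atom(name, el, chain, resname, seq, "",
                                  x, 1.0, float(b)))
            placed.append(xyz)
    model = AtomicModel(cell, spec.space_group, atoms)
    for el, (fp, fpp) in spec.anomalous.items():
        for a in model.atoms:
            if a.element == el:
                a.f_prime, a.f_double_prime = fp, fpp
    return model


def simulate_fobs(model: AtomicModel, spec: ToySpec) -> ReflectionSet:
    """Observed amplitudes from the full forward model, plus noise."""
    anomalous = bool(spec.anomalous)
    hkl = scatter.miller_set(model.cell, spec.d_min, anomalous=anomalous,
                             spacegroup=model.spacegroup.hm)
    f_calc = scatter.f_calc_direct(model, hkl)
    if spec.k_sol > 0:
        mask = scatter.build_solvent_mask(model)
        fmask = scatter.f_mask(mask, hkl)
    else:
        fmask = np.zeros(len(hkl), complex)
    scales = ScaleModel(k_overall=spec.k_overall, k_sol=spec.k_sol,
                        b_sol=spec.b_sol)
    f_model = total_fmodel(f_calc, fmask, scales, hkl, model.cell)
    if spec.twin_operator is not None and spec.twin_fraction > 0:
        amp = twin_fmodel(f_model,
                          TwinState(spec.twin_operator, spec.twin_fraction),
                          hkl)
    else:
        amp = np.abs(f_model)
    rng = np.random.default_rng(spec.seed + 1)
    sigma = np.maximum(spec.noise * amp, 1e-6 * max(amp.max(), 1.0))
    fobs = amp + rng.normal(0.0, 1.0, len(amp)) * (sigma if spec.noise > 0
                                                   else 0.0)
    fobs = np.abs(fobs)
    data = ReflectionSet(hkl, fobs, sigma, model.cell, "F")
    return check_free_flags(data, spec.free_fraction, seed=spec.seed + 2)


def rmsd_between(model_a: AtomicModel, model_b: AtomicModel,
                 allow_translation: bool = True) -> float:
    """Coordinate r.m.s.d. between two same-topology models.

    Amplitude-only refinement leaves the crystal origin floating in P1, so
    by default the comparison removes the best global translation first.
    """
    xa, xb = model_a.coordinates(), model_b.coordinates()
    if xa.shape != xb.shape:
        raise ValueError("models have different atom counts")
    d = xa - xb
    if allow_translation:
        d = d - d.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def perturb_model(model: AtomicModel, kind: str, magnitude: float = 0.0,
                  seed: int = 0,
                  selection: list[int] | None = None) -> AtomicModel:
    """Controlled corruption: shake | rotate_domain | reset_adp | strip_waters.

    ``shake`` draws Gaussian displacements and rescales them so the achieved
    r.m.s. displacement equals ``magnitude`` exactly.  ``rotate_domain``
    rotates the selection by ``magnitude`` degrees about a random axis
    through its centroid.  ``reset_adp`` sets every B to the model mean;
    ``strip_waters`` deletes waters.
    """
    out = model.copy()
    rng = np.random.default_rng(seed)
    if kind == "shake":
        if magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if magnitude > 0 and out.n_atoms:
            disp = rng.normal(0.0, 1.0, (out.n_atoms, 3))
            rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
            disp *= magnitude / rms
            out.set_coordinates(out.coordinates() + disp)
    elif kind == "rotate_domain":
        sel = selection if selection is not None else list(range(out.n_atoms))
        xyz = out.coordinates()
        center = xyz[sel].mean(axis=0)
        axis = rng.normal(0, 1, 3)
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec(np.deg2rad(magnitude) * axis).as_matrix()
        xyz[sel] = (xyz[sel] - center) @ R.T + center
        out.set_coordinates(xyz)
    elif kind == "reset_adp":
        mean_b = float(np.mean(out.b_values())) if out.n_atoms else 0.0
        for a in out.atoms:
            a.b_iso = mean_b
            a.u_aniso = None
    elif kind == "strip_waters":
        out.atoms = [a for a in out.atoms if not a.is_water]
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return out
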