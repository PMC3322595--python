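"""Restraints: geometry, isotropic sphere ADP, anisotropic similarity,
TLS-generated ADPs and NCS harmonic terms.

Geometry restraints are harmonic in bond lengths and angles plus a
quadratic short-range nonbonded repulsion; ideals and sigmas come from a
small shipped dictionary covering the toy residue types (water, a
glycine-like chain unit and a generic ligand).

Isotropic ADP smoothness uses the sphere restraint

    T = sum_i sum_{j in sphere(R, i)}  (U_i - U_j)^2
                                      / ( r_ij^p  ((U_i + U_j)/2)^q )

whose inner sum runs over the M atoms within radius R of atom i.  With
p = q = 0 and R near a bond length it reduces to the plain pairwise
similarity sum.  Defaults (R, p, q) = (5.0 A, 1.69, 1.03).

TLS rigid-group ADPs: U_TLS = T + A L A^t + A S + S^t A^t with A the
antisymmetric matrix of the atom offset from the group origin; the
trace(S) = 0 convention leaves 6 + 6 + 8 = 20 independent parameters.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json

import numpy as np
from scipy.spatial.transform import Rotation

from .model_data import AtomicModel

SPHERE_RADIUS_DEFAULT = 5.0
SPHERE_P_DEFAULT = 1.69
SPHERE_Q_DEFAULT = 1.03


def load_geometry_dictionary() -> dict:
    path = importlib.resources.files("picorefine.data") / "geometry.json"
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# Geometry restraints
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeometryRestraintSet:
    bonds: list[tuple[int, int, float, float]]  # i, j, ideal A, weight
    angles: list[tuple[int, int, int, float, float]]  # i,j,k, ideal rad, w
    nonbonded_min: float = 2.2
    nonbonded_weight: float = 25.0

    def bonded_pairs(self) -> set[tuple[int, int]]:
        out = set()
        for i, j, *_ in self.bonds:
            out.add((min(i, j), max(i, j)))
        for i, j, k, *_ in self.angles:  # 1-3 pairs excluded from repulsion
            out.add((min(i, k), max(i, k)))
        return out


def build_restraints(model: AtomicModel,
                     dictionary: dict | None = None) -> GeometryRestraintSet:
    """Instantiate dictionary restraints over a model, residue by residue.

    Atoms are matched by residue type and atom name within each conformer;
    altloc copies of a residue each get their own restraints.
    """
    d = dictionary or load_geometry_dictionary()
    res = d["residues"]
    nb = d["nonbonded"]
    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    index: dict[tuple, int] = {a.key(): i for i, a in enumerate(model.atoms)}
    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(model.atoms):
        by_res.setdefault((a.chain, a.resseq, a.altloc), {})[a.name] = i
    resnames = {(a.chain, a.resseq): a.resname for a in model.atoms}
    for (chain, seq, alt), names in by_res.items():
        rname = resnames[(chain, seq)]
        entry = res.get(rname)
        if entry is None:
            continue

        def find(name: str) -> int | None:
            i = names.get(name)
            if i is None and alt:  # blank-altloc atoms shared by conformers
                i = by_res.get((chain, seq, ""), {}).get(name)
            return i

        for n1, n2, ideal, sigma in entry["bonds"]:
            i, j = find(n1), find(n2)
            if i is None or j is None:
                raise ValueError(
                    f"restraint {rname} {n1}-{n2}: atom missing in "
                    f"{chain}{seq}{alt or ''}")
            bonds.append((i, j, float(ideal), 1.0 / float(sigma) ** 2))
        for n1, n2, n3, ideal, sigma in entry["angles"]:
            i, j, k = find(n1), find(n2), find(n3)
            if i is None or j is None or k is None:
                raise ValueError(
                    f"restraint {rname} angle {n1}-{n2}-{n3}: atom missing "
                    f"in {chain}{seq}{alt or ''}")
            srad = np.deg2rad(float(sigma))
            angles.append((i, j, k, np.deg2rad(float(ideal)),
                           1.0 / srad**2))
    # deduplicate shared-atom bonds coming from multiple conformers
    bonds = list({(min(i, j), max(i, j), d0, w): (i, j, d0, w)
                  for i, j, d0, w in bonds}.values())
    return GeometryRestraintSet(bonds, angles,
                                nonbonded_min=float(nb["min_distance"]),
                                nonbonded_weight=1.0 / float(nb["sigma"])**2)


def geometry_target(model: AtomicModel, restraints: GeometryRestraintSet
                    ) -> tuple[float, np.ndarray, dict]:
    """Harmonic geometry target, gradient (n_atoms, 3) and rmsd summary."""
    xyz = model.coordinates()
    n = len(xyz)
    grad = np.zeros((n, 3))
    value = 0.0
    bond_dev, angle_dev = [], []
    for i, j, ideal, w in restraints.bonds:
        d_vec = xyz[i] - xyz[j]
        d = np.linalg.norm(d_vec)
        delta = d - ideal
        bond_dev.append(delta)
        value += w * delta**2
        g = 2.0 * w * delta * d_vec / max(d, 1e-12)
        grad[i] += g
        grad[j] -= g
    for i, j, k, ideal, w in restraints.angles:
        v1, v2 = xyz[i] - xyz[j], xyz[k] - xyz[j]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        theta = np.arccos(c)
        delta = theta - ideal
        angle_dev.append(np.rad2deg(delta))
        value += w * delta**2
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        dth_dv1 = -(v2 / (n1 * n2) - c * v1 / n1**2) / s
        dth_dv2 = -(v1 / (n1 * n2) - c * v2 / n2**2) / s
        grad[i] += 2.0 * w * delta * dth_dv1
        grad[k] += 2.0 * w * delta * dth_dv2
        grad[j] -= 2.0 * w * delta * (dth_dv1 + dth_dv2)
    excluded = restraints.bonded_pairs()
    if n > 1 and restraints.nonbonded_weight > 0:
        dmin, wnb = restraints.nonbonded_min, restraints.nonbonded_weight
        alt = [a.altloc for a in model.atoms]
        from scipy.spatial.distance import pdist, squareform
        dm = squareform(pdist(xyz))
        ii, jj = np.where((dm < dmin) & (dm > 0))
        for i, j in zip(ii, jj):
            if i >= j or (i, j) in excluded:
                continue
            if alt[i] and alt[j] and alt[i] != alt[j]:
                continue  # different conformers never clash
            d = dm[i, j]
            delta = d - dmin
            value += wnb * delta**2
            g = 2.0 * wnb * delta * (xyz[i] - xyz[j]) / d
            grad[i] += g
            grad[j] -= g
    stats = {
        "bond_rmsd": float(np.sqrt(np.mean(np.square(bond_dev))))
        if bond_dev else 0.0,
        "angle_rmsd": float(np.sqrt(np.mean(np.square(angle_dev))))
        if angle_dev else 0.0,
    }
    return float(value), grad, stats


# ---------------------------------------------------------------------------
# ADP restraints
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SphereRestraintParams:
    radius: float = SPHERE_RADIUS_DEFAULT
    p: float = SPHERE_P_DEFAULT
    q: float = SPHERE_Q_DEFAULT


def sphere_adp_restraint(model: AtomicModel,
                         params: SphereRestraintParams | None = None
                         ) -> tuple[float, np.ndarray]:
    """Sphere ADP restraint on isotropic U_local; returns (value, dT/dU_i)."""
    params = params or SphereRestraintParams()
    if params.radius <= 0:
        raise ValueError("sphere radius must be positive")
    xyz = model.coordinates()
    u = np.array([a.u_iso for a in model.atoms])
    n = len(u)
    grad = np.zeros(n)
    value = 0.0
    if n < 2:
        return 0.0, grad
    from scipy.spatial.distance import pdist, squareform
    dm = squareform(pdist(xyz))
    eps = 1e-3
    for i in range(n):
        within = np.where((dm[i] > 0) & (dm[i] <= params.radius))[0]
        for j in within:
            r = dm[i, j]
            du = u[i] - u[j]
            mean_u = max((u[i] + u[j]) / 2.0, eps)
            denom = r**params.p * mean_u**params.q
            value += du**2 / denom
            g = 2.0 * du / denom
            gq = -params.q * du**2 / (denom * mean_u) / 2.0 \
                if mean_u > eps else 0.0
            grad[i] += g + gq
            grad[j] += -g + gq
    return float(value), grad


def similarity_aniso_restraint(model: AtomicModel,
                               pairs: list[tuple[int, int]],
                               weight: float = 1.0
                               ) -> tuple[float, np.ndarray]:
    """Squared Frobenius difference of U tensors over bonded pairs.

    Returns (value, gradient) with gradient shaped (n_atoms, 3, 3).
    """
    n = model.n_atoms
    grad = np.zeros((n, 3, 3))
    value = 0.0
    for i, j in pairs:
        ui, uj = model.atoms[i].u_aniso, model.atoms[j].u_aniso
        if ui is None or uj is None:
            continue
        d = ui - uj
        value += weight * float(np.sum(d * d))
        grad[i] += 2.0 * weight * d
        grad[j] -= 2.0 * weight * d
    return float(value), grad


# ---------------------------------------------------------------------------
# TLS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TLSGroup:
    selection: list[int]
    origin: np.ndarray
    T: np.ndarray  # 3x3 symmetric, A^2
    L: np.ndarray  # 3x3 symmetric, rad^2
    S: np.ndarray  # 3x3, trace-zero convention, A rad

    def n_independent_parameters(self) -> int:
        """Rank of the TLS parameterization under trace(S) = 0.

        6 (T) + 6 (L) + 9 (S) components minus the one trace constraint.
        Computed from the constraint rank rather than asserted.
        """
        n_raw = 6 + 6 + 9
        constraints = np.zeros((1, n_raw))
        constraints[0, 12] = constraints[0, 16] = constraints[0, 20] = 1.0
        # S is stored row-major in slots 12..20; S00, S11, S22 at 12, 16, 20
        return n_raw - np.linalg.matrix_rank(constraints)


def _antisym(r: np.ndarray) -> np.ndarray:
    x, y, z = r
    return np.array([[0.0, z, -y], [-z, 0.0, x], [y, -x, 0.0]])


def tls_u(group: TLSGroup, positions: np.ndarray) -> np.ndarray:
    """Per-atom anisotropic U from TLS: U = T + A L A^t + A S + S^t A^t."""
    out = np.empty((len(positions), 3, 3))
    for idx, pos in enumerate(np.asarray(positions, float)):
        A = _antisym(pos - group.origin)
        u = group.T + A @ group.L @ A.T + A @ group.S + group.S.T @ A.T
        out[idx] = 0.5 * (u + u.T)  # symmetric by construction; belt+braces
    return out


def apply_tls(model: AtomicModel, groups: list[TLSGroup]) -> None:
    """Write U_TLS + U_local(iso) into the atoms' anisotropic U."""
    for g in groups:
        pos = np.array([model.atoms[i].xyz for i in g.selection])
        u_tls = tls_u(g, pos)
        for k, i in enumerate(g.selection):
            a = model.atoms[i]
            a.u_aniso = u_tls[k] + a.u_iso * np.eye(3)


# ---------------------------------------------------------------------------
# NCS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NCSGroups:
    groups: list[list[list[int]]]  # group -> copy -> atom indices
    weight_coords: float = 100.0
    weight_adp: float = 10.0


def _superpose(mobile: np.ndarray, target: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """LS rotation + translation mapping mobile onto target."""
    cm, ct = mobile.mean(0), target.mean(0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    return R, ct - cm @ R.T


def ncs_restraint(model: AtomicModel, groups: NCSGroups,
                  mode: str = "coordinates") -> tuple[float, np.ndarray]:
    """Harmonic restraint of each NCS copy to the group average.

    Coordinates: each copy is LS-superposed onto the running average and
    penalized for residual deviations; the gradient is pulled back through
    the (fixed) superposition rotation.  ADP mode penalizes deviations of
    isotropic U_local from the copy average (TLS contributions excluded by
    construction: only U_local enters).
    """
    if mode not in ("coordinates", "adp"):
        raise ValueError("mode must be 'coordinates' or 'adp'")
    xyz = model.coordinates()
    n = model.n_atoms
    if mode == "adp":
        u = np.array([a.u_iso for a in model.atoms])
        value, grad = 0.0, np.zeros(n)
        for copies in groups.groups:
            _check_copies(copies)
            uc = np.array([u[c] for c in copies])
            mean = uc.mean(axis=0)
            dev = uc - mean
            value += groups.weight_adp * float(np.sum(dev**2))
            for ci, c in enumerate(copies):
                for k, i in enumerate(c):
                    grad[i] += 2.0 * groups.weight_adp * dev[ci, k]
        return value, grad
    value, grad = 0.0, np.zeros((n, 3))
    for copies in groups.groups:
        _check_copies(copies)
        coords = [xyz[c] for c in copies]
        fits = []
        ref = coords[0]
        for c in coords:
            R, t = _superpose(c, ref)
            fits.append((R, t, c @ R.T + t))
        avg = np.mean([f[2] for f in fits], axis=0)
        for (R, t, aligned), c in zip(fits, copies):
            dev = aligned - avg
            value += groups.weight_coords * float(np.sum(dev**2))
            g = 2.0 * groups.weight_coords * dev @ R
            for k, i in enumerate(c):
                grad[i] += g[k]
    return value, grad


def _check_copies(copies: list[list[int]]) -> None:
    sizes = {len(c) for c in copies}
    if len(sizes) != 1:
        raise ValueError("NCS copies have mismatched atom counts")
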