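"""Atomic structure factors and bulk-solvent mask structure factors.

Two routes to F_calc are provided: exact direct summation over atoms
(reference path, also carries anomalous scattering and analytic gradients)
and an FFT route that samples the atomic electron density on a grid.  The
flat bulk-solvent contribution comes from the FFT of a binary solvent mask
built from per-element van der Waals radii grown by r_solvent and shrunk
back by r_shrink.

X-ray form factors are the 4-Gaussian international-tables coefficients
(via gemmi): f0(s) = sum_i a_i exp(-b_i s^2/4) + c, with s = 1/d.
"""

from __future__ import annotations

import dataclasses

import gemmi
import numpy as np

from .model_data import AtomicModel

# Van der Waals radii (A) default to the gemmi element table; override here
# for elements where the mask literature uses different values.
VDW_OVERRIDES: dict[str, float] = {}


def vdw_radius(element: str) -> float:
    if element in VDW_OVERRIDES:
        return VDW_OVERRIDES[element]
    r = gemmi.Element(element).vdw_r
    if r <= 0:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    return float(r)


def form_factor_coeffs(element: str) -> tuple[np.ndarray, np.ndarray, float]:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element {element!r}")
    it92 = el.it92
    return np.array(it92.a), np.array(it92.b), float(it92.c)


def form_factor(element: str, s2: np.ndarray) -> np.ndarray:
    """f0 at |s|^2 = 1/d^2 (stol^2 = s^2/4)."""
    a, b, c = form_factor_coeffs(element)
    stol2 = np.asarray(s2, float)[..., None] / 4.0
    return np.sum(a * np.exp(-b * stol2), axis=-1) + c


def miller_set(cell: gemmi.UnitCell, d_min: float,
               anomalous: bool = False,
               spacegroup: str = "P 1") -> np.ndarray:
    """All Miller indices with d >= d_min (000 excluded).

    Without ``anomalous`` one Friedel hemisphere is kept (h > 0, or h = 0
    and k > 0, or h = k = 0 and l > 0); with it both mates are returned.
    Systematic absences of the space group are removed.
    """
    g = np.array(cell.frac.mat.tolist())
    gstar = g @ g.T
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    s2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl.astype(float))
    keep = (s2 > 0) & (s2 <= 1.0 / d_min**2)
    hkl = hkl[keep]
    if not anomalous:
        hemi = ((hkl[:, 0] > 0)
                | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
                | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)))
        hkl = hkl[hemi]
    ops = gemmi.SpaceGroup(spacegroup).operations()
    absent = np.array([ops.is_systematically_absent(list(h)) for h in hkl])
    hkl = hkl[~absent]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


# ---------------------------------------------------------------------------
# Direct summation
# ---------------------------------------------------------------------------

def _dw_factors(model: AtomicModel, miller: np.ndarray,
                s2: np.ndarray, svec: np.ndarray) -> np.ndarray:
    """Debye-Waller factor per (reflection, atom)."""
    n_h, n_a = len(miller), model.n_atoms
    dw = np.empty((n_h, n_a))
    b_iso = model.b_values()
    iso = np.exp(-np.outer(s2, b_iso) / 4.0)
    for j, a in enumerate(model.atoms):
        if a.u_aniso is None:
            dw[:, j] = iso[:, j]
        else:
            q = np.einsum("hi,ij,hj->h", svec, a.u_aniso, svec)
            dw[:, j] = np.exp(-2.0 * np.pi**2 * q)
    return dw


def f_calc_direct(model: AtomicModel, miller: np.ndarray) -> np.ndarray:
    """Exact structure factors F(h) by summation over atoms.

    F(h) = sum_atoms occ (f0 + f' + i f'') DW(h) exp(2 pi i h.x_frac),
    expanded over all symmetry operators (P1 expansion).  The anisotropic
    Debye-Waller term is exp(-2 pi^2 s^t U s) with s the Cartesian
    reciprocal vector and U in the Cartesian basis.
    """
    miller = np.asarray(miller, int).reshape(-1, 3)
    F = np.zeros(len(miller), complex)
    if model.n_atoms == 0:
        return F
    fmat = model.frac_mat
    gstar = fmat @ fmat.T
    s2 = np.einsum("ij,jk,ik->i", miller, gstar, miller.astype(float))
    svec = miller @ fmat  # Cartesian reciprocal vectors (A^-1)
    occ = model.occupancies()
    elements = [a.element for a in model.atoms]
    f0 = np.empty((len(miller), model.n_atoms))
    cache: dict[str, np.ndarray] = {}
    for j, el in enumerate(elements):
        if el not in cache:
            cache[el] = form_factor(el, s2)
        f0[:, j] = cache[el]
    fanom = np.array([a.f_prime + 1j * a.f_double_prime for a in model.atoms])
    scat = (f0 + fanom[None, :])
    ops = model.symmetry_ops()
    if len(ops) > 1 and any(a.u_aniso is not None for a in model.atoms):
        raise ValueError("anisotropic ADPs are supported in P1 only "
                         "(expand the model to P1 first)")
    dw = _dw_factors(model, miller, s2, svec)
    xfrac = model.coordinates() @ fmat.T
    for op in ops:
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        xs = xfrac @ rot.T + tran
        phase = np.exp(2j * np.pi * (miller @ xs.T))
        F += np.einsum("a,ha,ha,ha->h", occ + 0j, scat, dw, phase)
    return F


def f_calc_param_grads(model: AtomicModel, miller: np.ndarray,
                       sensitivity: np.ndarray, wrt: str) -> np.ndarray:
    """Chain-rule gradients of a scalar through F_calc.

    ``sensitivity`` is S(h) with dT = sum_h Re[S(h) dF_calc(h)].  Returns
    per-atom gradients: shape (n_atoms, 3) for 'xyz', (n_atoms,) for
    'b_iso' or 'occ', (n_atoms, 2) for 'anom' (f', f'' order), and
    (n_atoms, 6) for 'u_aniso' (U11, U22, U33, U12, U13, U23; atoms with
    isotropic ADPs get zeros).
    """
    miller = np.asarray(miller, int).reshape(-1, 3)
    S = np.asarray(sensitivity, complex)
    fmat = model.frac_mat
    gstar = fmat @ fmat.T
    s2 = np.einsum("ij,jk,ik->i", miller, gstar, miller.astype(float))
    svec = miller @ fmat
    occ = model.occupancies()
    f0 = np.empty((len(miller), model.n_atoms))
    cache: dict[str, np.ndarray] = {}
    for j, a in enumerate(model.atoms):
        if a.element not in cache:
            cache[a.element] = form_factor(a.element, s2)
        f0[:, j] = cache[a.element]
    fanom = np.array([a.f_prime + 1j * a.f_double_prime for a in model.atoms])
    scat = f0 + fanom[None, :]
    dw = _dw_factors(model, miller, s2, svec)
    xfrac = model.coordinates() @ fmat.T
    shapes = {"xyz": (model.n_atoms, 3), "b_iso": (model.n_atoms,),
              "occ": (model.n_atoms,), "anom": (model.n_atoms, 2),
              "u_aniso": (model.n_atoms, 6)}
    grad = np.zeros(shapes[wrt])
    iso_flags = np.array([a.u_aniso is None for a in model.atoms])
    for op in model.symmetry_ops():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        xs = xfrac @ rot.T + tran
        phase = np.exp(2j * np.pi * (miller @ xs.T))
        contrib = occ[None, :] * scat * dw * phase  # (n_h, n_atoms)
        if wrt == "xyz":
            # d(h . R F x)/dx = F^t R^t h ; gradient in Cartesian basis
            hvec = (miller @ rot) @ fmat  # (n_h, 3)
            core = np.real(S[:, None, None] * 2j * np.pi *
                           contrib[:, :, None] * hvec[:, None, :])
            grad += core.sum(axis=0)
        elif wrt == "b_iso":
            term = np.real(S[:, None] * contrib) * (-s2[:, None] / 4.0)
            grad += np.where(iso_flags[None, :], term, 0.0).sum(axis=0)
        elif wrt == "occ":
            grad += np.real(S[:, None] * scat * dw * phase).sum(axis=0)
        elif wrt == "anom":
            base = occ[None, :] * dw * phase
            grad[:, 0] += np.real(S[:, None] * base).sum(axis=0)
            grad[:, 1] += np.real(S[:, None] * 1j * base).sum(axis=0)
        elif wrt == "u_aniso":
            sv = miller @ rot @ fmat  # rotated reciprocal vector
            quad = np.stack([sv[:, 0]**2, sv[:, 1]**2, sv[:, 2]**2,
                             2 * sv[:, 0] * sv[:, 1],
                             2 * sv[:, 0] * sv[:, 2],
                             2 * sv[:, 1] * sv[:, 2]], axis=1)
            core = np.real(S[:, None] * contrib)[:, :, None] * \
                (-2 * np.pi**2) * quad[:, None, :]
            term = core.sum(axis=0)
            term[iso_flags] = 0.0
            grad += term
    return grad


# ---------------------------------------------------------------------------
# FFT route
# ---------------------------------------------------------------------------

def _grid_shape(cell: gemmi.UnitCell, spacing: float) -> tuple[int, int, int]:
    def even(n: int) -> int:
        return n + n % 2
    return tuple(max(8, even(int(np.ceil(ax / spacing))))
                 for ax in (cell.a, cell.b, cell.c))


def f_calc_fft(model: AtomicModel, d_min: float,
               grid_factor: float = 3.0,
               b_extra_min: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """F_calc on the full hemisphere to d_min by density sampling + FFT.

    Each 4-Gaussian form-factor term with the atomic B folded in becomes a
    real-space Gaussian; densities are accumulated on a grid of spacing
    <= d_min/grid_factor and Fourier transformed.  Atoms sharper than
    ``b_extra_min`` are smeared by an extra B that is divided out of the
    transform afterwards (artificial temperature-factor trick).  Anomalous
    scatterers are not supported on this route.

    Returns (miller, F) on the non-anomalous hemisphere.
    """
    if any(a.f_double_prime != 0.0 or a.f_prime != 0.0 for a in model.atoms):
        raise ValueError("FFT route does not carry anomalous scattering; "
                         "use f_calc_direct")
    cell = model.cell
    hkl = miller_set(cell, d_min, spacegroup=model.spacegroup.hm)
    if model.n_atoms == 0:
        return hkl, np.zeros(len(hkl), complex)
    spacing = d_min / grid_factor
    shape = _grid_shape(cell, spacing)
    b_min = min(a.b_iso if a.u_aniso is None
                else 8 * np.pi**2 * np.linalg.eigvalsh(a.u_aniso).min()
                for a in model.atoms)
    b_extra = max(0.0, b_extra_min - b_min)
    rho = np.zeros(shape)
    fmat = model.frac_mat
    n = np.array(shape)
    for op in model.symmetry_ops():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        for a in model.atoms:
            xf = (rot @ (fmat @ a.xyz) + tran) % 1.0
            _add_atom_density(rho, xf, a, b_extra, cell, n)
    Fgrid = np.fft.ifftn(rho) * np.prod(shape) * cell.volume / np.prod(shape)
    idx = tuple((hkl % n).T)
    F = Fgrid[idx[0], idx[1], idx[2]]
    g = fmat @ fmat.T
    s2 = np.einsum("ij,jk,ik->i", hkl, g, hkl.astype(float))
    F *= np.exp(b_extra * s2 / 4.0)  # undo the artificial smearing
    return hkl, F


def _add_atom_density(rho: np.ndarray, xf: np.ndarray, atom, b_extra: float,
                      cell: gemmi.UnitCell, n: np.ndarray) -> None:
    a_coef, b_coef, c_coef = form_factor_coeffs(atom.element)
    b_iso = atom.b_iso if atom.u_aniso is None else \
        8 * np.pi**2 * np.trace(atom.u_aniso) / 3.0
    b_tot = b_coef + b_iso + b_extra
    # constant term treated as a Gaussian with b = 0
    a_all = np.append(a_coef, c_coef)
    b_all = np.append(b_tot, b_iso + b_extra)
    # cutoff radius: beyond ~5 sigma of the widest Gaussian
    r_cut = 1.5 * np.sqrt(b_all.max())
    orth = np.array(cell.orth.mat.tolist())
    steps = np.ceil(r_cut * n / np.array([cell.a, cell.b, cell.c])).astype(int)
    base = np.floor(xf * n).astype(int)
    ranges = [np.arange(base[i] - steps[i], base[i] + steps[i] + 1)
              for i in range(3)]
    gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
    gf = np.stack([gi, gj, gk], axis=-1) / n
    d = (gf - xf) @ orth.T
    r2 = np.sum(d * d, axis=-1)
    dens = np.zeros(r2.shape)
    for aa, bb in zip(a_all, b_all):
        dens += aa * (4.0 * np.pi / bb) ** 1.5 * np.exp(-4 * np.pi**2 * r2 / bb)
    dens *= atom.occ
    np.add.at(rho, (gi % n[0], gj % n[1], gk % n[2]), dens)


# ---------------------------------------------------------------------------
# Solvent mask
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SolventMask:
    grid: np.ndarray  # 1 = solvent, 0 = protein
    cell: gemmi.UnitCell
    r_solvent: float
    r_shrink: float

    @property
    def solvent_fraction(self) -> float:
        return float(self.grid.mean())


def build_solvent_mask(model: AtomicModel, r_solvent: float = 1.1,
                       r_shrink: float = 0.9,
                       spacing: float = 0.6) -> SolventMask:
    """Binary solvent mask: zero within vdW + r_solvent of any atom, then
    solvent re-grown by r_shrink (shrinking the protein region).

    Periodic images and symmetry mates are honored.  Distances use the
    minimum-image convention, adequate for the near-orthogonal toy cells
    this engine targets.
    """
    cell = model.cell
    shape = _grid_shape(cell, spacing)
    n = np.array(shape)
    mask = np.ones(shape, dtype=bool)
    fmat = model.frac_mat
    orth = np.array(cell.orth.mat.tolist())
    fi, fj, fk = np.meshgrid(*(np.arange(s) / s for s in shape), indexing="ij")
    gf = np.stack([fi.ravel(), fj.ravel(), fk.ravel()], axis=1)
    sites: list[tuple[np.ndarray, float]] = []
    for op in model.symmetry_ops():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        for a in model.atoms:
            xf = (rot @ (fmat @ a.xyz) + tran) % 1.0
            sites.append((xf, vdw_radius(a.element) + r_solvent))
    for xf, r in sites:
        df = gf - xf
        df -= np.round(df)
        d2 = np.sum((df @ orth.T) ** 2, axis=1)
        mask.ravel()[d2 <= r * r] = False
    if r_shrink > 0 and model.n_atoms:
        mask = _dilate_periodic(mask, r_shrink, cell, shape)
    return SolventMask(mask.astype(np.int8), cell, r_solvent, r_shrink)


def _dilate_periodic(solvent: np.ndarray, radius: float,
                     cell: gemmi.UnitCell, shape: tuple[int, int, int]
                     ) -> np.ndarray:
    """Grow the solvent (True) region by ``radius`` with periodic wrap,
    via FFT convolution with a spherical kernel."""
    n = np.array(shape)
    orth = np.array(cell.orth.mat.tolist())
    axes = [np.minimum(np.arange(s), s - np.arange(s)) / s for s in shape]
    fi, fj, fk = np.meshgrid(*axes, indexing="ij")
    # minimum-image distance from the origin for each grid offset
    off = np.stack([fi, fj, fk], axis=-1)
    d2 = np.sum((off @ orth.T) ** 2, axis=-1)
    kernel = (d2 <= radius * radius).astype(float)
    conv = np.fft.ifftn(np.fft.fftn(solvent.astype(float)) *
                        np.fft.fftn(kernel)).real
    return conv > 0.5


def f_mask(mask: SolventMask, miller: np.ndarray) -> np.ndarray:
    """Structure factors of the binary mask at the requested indices."""
    miller = np.asarray(miller, int).reshape(-1, 3)
    shape = mask.grid.shape
    Fgrid = np.fft.ifftn(mask.grid.astype(float)) * mask.cell.volume
    n = np.array(shape)
    idx = (miller % n).T
    return Fgrid[idx[0], idx[1], idx[2]]
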