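"""Atomic models and reflection data.

The model is a flat list of :class:`Atom` records plus a unit cell and a
space group; a chain/residue/conformer hierarchy view is derived on demand
from chain id, residue number and altloc identifier.  Coordinates are kept
in Cartesian angstroms; fractionalization uses the standard orthogonalization
convention with *a* along *x* (the matrix comes from the unit cell).

Reflection data are Miller-indexed amplitudes or intensities with sigmas and
cross-validation (free) flags.  Intensities can be converted to amplitudes
with a Bayesian truncated-Gaussian x Wilson-prior posterior (French-Wilson),
and improbably large amplitudes can be flagged as outliers from the tail
probability of the per-bin Wilson distribution.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

B_TO_U = 1.0 / (8.0 * np.pi**2)  # B = 8 pi^2 U_iso


class UnsupportedInputError(ValueError):
    """Raised for inputs outside the supported PDB/reflection subset."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    chain: str
    resname: str
    resseq: int
    altloc: str  # '' for no alternative location
    xyz: np.ndarray  # Cartesian, angstrom
    occ: float = 1.0
    b_iso: float = 20.0
    u_aniso: np.ndarray | None = None  # 3x3 symmetric, Cartesian basis, A^2
    f_prime: float = 0.0
    f_double_prime: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)

    @property
    def is_water(self) -> bool:
        return self.resname in ("HOH", "WAT", "DOD")

    @property
    def u_iso(self) -> float:
        return self.b_iso * B_TO_U

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.chain, self.resname,
                    self.resseq, self.altloc, self.xyz.copy(), self.occ,
                    self.b_iso,
                    None if self.u_aniso is None else self.u_aniso.copy(),
                    self.f_prime, self.f_double_prime)

    def key(self) -> tuple:
        return (self.chain, self.resseq, self.altloc, self.name)


class AtomicModel:
    """A crystal: unit cell, space group and an ordered atom list."""

    def __init__(self, cell: gemmi.UnitCell, spacegroup: str,
                 atoms: Sequence[Atom]):
        if cell.volume <= 0:
            raise ValueError("unit cell volume must be positive")
        self.cell = cell
        self.spacegroup = gemmi.SpaceGroup(spacegroup)
        self.atoms = list(atoms)

    # -- geometry ---------------------------------------------------------
    @property
    def frac_mat(self) -> np.ndarray:
        """Fractionalization matrix F with x_frac = F @ x_cart."""
        return np.array(self.cell.frac.mat.tolist())

    @property
    def orth_mat(self) -> np.ndarray:
        return np.array(self.cell.orth.mat.tolist())

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms])

    def set_coordinates(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float).reshape(len(self.atoms), 3)
        for a, x in zip(self.atoms, xyz):
            a.xyz = x.copy()

    def b_values(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms])

    def occupancies(self) -> np.ndarray:
        return np.array([a.occ for a in self.atoms])

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.cell, self.spacegroup.hm,
                           [a.copy() for a in self.atoms])

    def symmetry_ops(self) -> list[gemmi.Op]:
        return list(self.spacegroup.operations())

    # -- hierarchy --------------------------------------------------------
    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain, resseq), in model order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.resseq), []).append(a)
        return out

    def conformers(self, chain: str, resseq: int) -> dict[str, list[Atom]]:
        """Conformers of one residue: altloc -> atoms.

        Blank-altloc atoms are shared: they appear in every conformer.  A
        residue with no altloc atoms yields a single '' conformer.
        """
        atoms = self.residues()[(chain, resseq)]
        alts = sorted({a.altloc for a in atoms if a.altloc})
        if not alts:
            return {"": list(atoms)}
        shared = [a for a in atoms if not a.altloc]
        return {alt: shared + [a for a in atoms if a.altloc == alt]
                for alt in alts}

    def validate(self) -> None:
        for a in self.atoms:
            if not (0.0 <= a.occ <= 1.0):
                raise ValueError(f"occupancy out of [0,1] for {a.key()}")
            if a.b_iso < 0:
                raise ValueError(f"negative B for {a.key()}")
            if a.u_aniso is not None and not np.allclose(
                    a.u_aniso, a.u_aniso.T):
                raise ValueError(f"non-symmetric U for {a.key()}")


# ---------------------------------------------------------------------------
# PDB reading/writing (via gemmi)
# ---------------------------------------------------------------------------

def parse_pdb(text: str) -> AtomicModel:
    """Parse a single-MODEL PDB string into an :class:`AtomicModel`.

    Raises :class:`UnsupportedInputError` for multi-MODEL ensembles or for
    files without a CRYST1 record.
    """
    n_models = sum(1 for ln in text.splitlines() if ln.startswith("MODEL "))
    if n_models > 1:
        raise UnsupportedInputError(
            "only PDB files containing a single model are supported "
            f"(found {n_models} MODEL records)")
    if not any(ln.startswith("CRYST1") for ln in text.splitlines()):
        raise UnsupportedInputError("missing CRYST1 record")
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    cell = st.cell
    sg = st.spacegroup_hm or "P 1"
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                u = None
                if at.aniso.nonzero():
                    u = np.array(at.aniso.as_mat33().tolist())
                alt = at.altloc
                if alt in ("\x00", " ", ""):
                    alt = ""
                atoms.append(Atom(
                    name=at.name, element=at.element.name,
                    chain=chain.name, resname=res.name,
                    resseq=res.seqid.num, altloc=alt,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occ=at.occ, b_iso=at.b_iso, u_aniso=u))
    return AtomicModel(cell, sg, atoms)


def write_pdb(model: AtomicModel, stats: dict | None = None) -> str:
    """Render a model as PDB text with an optional REMARK 3 style header."""
    buf = io.StringIO()
    if stats:
        buf.write("REMARK   3 REFINEMENT.\n")
        if "r_work" in stats:
            buf.write(f"REMARK   3   R VALUE (WORKING SET) : {stats['r_work']:.4f}\n")
        if "r_free" in stats:
            buf.write(f"REMARK   3   FREE R VALUE          : {stats['r_free']:.4f}\n")
        if "bond_rmsd" in stats:
            buf.write(f"REMARK   3   BOND LENGTHS (A) RMSD  : {stats['bond_rmsd']:.4f}\n")
        if "angle_rmsd" in stats:
            buf.write(f"REMARK   3   BOND ANGLES (DEG) RMSD : {stats['angle_rmsd']:.4f}\n")
    c = model.cell
    buf.write(f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
              f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} "
              f"{model.spacegroup.hm:<11s}\n")
    for i, a in enumerate(model.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        rec = "HETATM" if a.is_water else "ATOM  "
        buf.write(f"{rec}{i:5d} {name:<4s}{a.altloc or ' '}{a.resname:>3s} "
                  f"{a.chain[:1]}{a.resseq:4d}    "
                  f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                  f"{a.occ:6.2f}{a.b_iso:6.2f}          {a.element:>2s}\n")
        if a.u_aniso is not None:
            u = np.rint(a.u_aniso * 1e4).astype(int)
            buf.write(f"ANISOU{i:5d} {name:<4s}{a.altloc or ' '}{a.resname:>3s} "
                      f"{a.chain[:1]}{a.resseq:4d}  "
                      f"{u[0, 0]:7d}{u[1, 1]:7d}{u[2, 2]:7d}"
                      f"{u[0, 1]:7d}{u[0, 2]:7d}{u[1, 2]:7d}"
                      f"      {a.element:>2s}\n")
    buf.write("END\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Occupancy constraint groups
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OccupancyGroup:
    selections: list[list[int]]  # atom-index lists; one per constrained unit
    kind: str  # 'sum_to_one' | 'bounded'
    bounds: tuple[float, float] = (0.0, 1.0)


def build_occupancy_groups(model: AtomicModel,
                           user_selections: Iterable[list[int]] | None = None
                           ) -> list[OccupancyGroup]:
    """Automatic occupancy constraints from altloc identifiers.

    Each residue carrying alternative conformations yields one sum-to-one
    group (one occupancy per conformer, occupancies summing to 1).  Atoms
    with partial occupancy and no altloc each become a bounded
    single-parameter group on [0, 1].
    """
    groups: list[OccupancyGroup] = []
    claimed: set[int] = set()
    index = {id(a): i for i, a in enumerate(model.atoms)}
    for (chain, resseq), atoms in model.residues().items():
        alts = sorted({a.altloc for a in atoms if a.altloc})
        if not alts:
            continue
        sels = []
        for alt in alts:
            sel = sorted(index[id(a)] for a in atoms if a.altloc == alt)
            sels.append(sel)
            claimed.update(sel)
        groups.append(OccupancyGroup(sels, "sum_to_one"))
    for i, a in enumerate(model.atoms):
        if i in claimed or a.altloc:
            continue
        if 0.0 < a.occ < 1.0:
            groups.append(OccupancyGroup([[i]], "bounded", (0.0, 1.0)))
            claimed.add(i)
    if user_selections is not None:
        for sel in user_selections:
            sel = sorted(sel)
            if claimed & set(sel):
                raise ValueError(
                    "user occupancy selection overlaps an automatic group")
            groups.append(OccupancyGroup([sel], "bounded", (0.0, 1.0)))
            claimed.update(sel)
    return groups


# ---------------------------------------------------------------------------
# Reflection data
# ---------------------------------------------------------------------------

class ReflectionSet:
    """Miller-indexed data (F or I) with sigmas, free flags, d-spacings."""

    def __init__(self, miller: np.ndarray, data: np.ndarray,
                 sigma: np.ndarray, cell: gemmi.UnitCell,
                 kind: str = "F", is_free: np.ndarray | None = None,
                 excluded: np.ndarray | None = None):
        self.miller = np.asarray(miller, dtype=int).reshape(-1, 3)
        n = len(self.miller)
        self.data = np.asarray(data, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        if kind not in ("F", "I"):
            raise ValueError("kind must be 'F' or 'I'")
        self.kind = kind
        self.cell = cell
        self.is_free = (np.zeros(n, bool) if is_free is None
                        else np.asarray(is_free, bool))
        self.excluded = (np.zeros(n, bool) if excluded is None
                         else np.asarray(excluded, bool))
        if len({tuple(h) for h in self.miller}) != n:
            raise ValueError("duplicate Miller indices")
        if np.any(self.sigma < 0):
            raise ValueError("negative sigma")

    def __len__(self) -> int:
        return len(self.miller)

    @property
    def d_spacing(self) -> np.ndarray:
        g = np.array(self.cell.frac.mat.tolist())
        gstar = g @ g.T  # reciprocal metric tensor
        s2 = np.einsum("ij,jk,ik->i", self.miller, gstar,
                       self.miller.astype(float))
        return 1.0 / np.sqrt(s2)

    @property
    def s2(self) -> np.ndarray:
        """|s|^2 = 1/d^2 per reflection."""
        return 1.0 / self.d_spacing**2

    @property
    def work(self) -> np.ndarray:
        return ~self.is_free & ~self.excluded

    @property
    def free(self) -> np.ndarray:
        return self.is_free & ~self.excluded

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.miller.copy(), self.data.copy(),
                             self.sigma.copy(), self.cell, self.kind,
                             self.is_free.copy(), self.excluded.copy())

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(self.miller)}

    # -- CSV dialect: h,k,l,F,SIGF,FREE (or I,SIGI); FREE 1 = free --------
    def to_csv(self) -> str:
        lab = ("F", "SIGF") if self.kind == "F" else ("I", "SIGI")
        df = pd.DataFrame({
            "h": self.miller[:, 0], "k": self.miller[:, 1],
            "l": self.miller[:, 2], lab[0]: self.data,
            lab[1]: self.sigma, "FREE": self.is_free.astype(int)})
        return df.to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str, cell: gemmi.UnitCell) -> "ReflectionSet":
        df = pd.read_csv(io.StringIO(text))
        if "F" in df.columns:
            kind, lab = "F", ("F", "SIGF")
        elif "I" in df.columns:
            kind, lab = "I", ("I", "SIGI")
        else:
            raise UnsupportedInputError("reflection CSV needs an F or I column")
        free = (df["FREE"].to_numpy().astype(bool)
                if "FREE" in df.columns else None)
        return cls(df[["h", "k", "l"]].to_numpy(), df[lab[0]].to_numpy(),
                   df[lab[1]].to_numpy(), cell, kind, free)


def resolution_bins(d: np.ndarray, target_per_bin: int = 150,
                    min_per_bin: int = 20) -> np.ndarray:
    """Equal-count bin assignment over 1/d^2, returned as int labels."""
    n = len(d)
    n_bins = max(1, min(n // max(min_per_bin, 1), n // target_per_bin or 1))
    n_bins = max(1, min(n_bins, n // min_per_bin if n >= min_per_bin else 1))
    order = np.argsort(1.0 / d**2)
    labels = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        labels[chunk] = b
    return labels


def french_wilson(data: ReflectionSet, target_per_bin: int = 150) -> ReflectionSet:
    """Convert intensities to posterior-mean amplitudes (French-Wilson).

    The posterior over the true amplitude F given a measured intensity I
    with Gaussian error sigma is p(F) ~ exp(-(I - F^2)^2 / 2 sigma^2) x
    prior, with the acentric Wilson prior p0(F) ~ F exp(-F^2 / S) whose
    mean-square amplitude S is estimated per resolution bin from
    <max(I, 0)>.  Mean and standard deviation are evaluated by quadrature.
    """
    if data.kind != "I":
        return data.copy()
    I, sig = data.data, np.maximum(data.sigma, 1e-30)
    labels = resolution_bins(data.d_spacing, target_per_bin)
    S = np.empty(len(I))
    global_S = max(np.mean(np.maximum(I, 0.0)), 1e-12)
    for b in np.unique(labels):
        m = labels == b
        sb = np.mean(np.maximum(I[m], 0.0))
        S[m] = sb if sb > 0 else global_S  # all-negative bin: fall back
    F = np.empty(len(I))
    sF = np.empty(len(I))
    for i in range(len(I)):
        F[i], sF[i] = _fw_posterior(I[i], sig[i], S[i])
    return ReflectionSet(data.miller, F, sF, data.cell, "F",
                         data.is_free, data.excluded)


def _fw_posterior(I: float, sig: float, S: float) -> tuple[float, float]:
    if I / sig > 30.0:  # high-signal limit: F ~ sqrt(I), delta method
        F = np.sqrt(I)
        return F, sig / (2.0 * F)
    hi = np.sqrt(max(I + 10.0 * sig, 0.0) + 10.0 * S)
    f = np.linspace(0.0, hi, 2001)[1:]
    logw = -((I - f**2)**2) / (2.0 * sig**2) - f**2 / S + np.log(f)
    w = np.exp(logw - logw.max())
    z = np.trapezoid(w, f)
    mean = np.trapezoid(w * f, f) / z
    var = np.trapezoid(w * f**2, f) / z - mean**2
    return mean, np.sqrt(max(var, 0.0))


def detect_outliers(data: ReflectionSet, threshold: float = 1e-6,
                    target_per_bin: int = 150) -> ReflectionSet:
    """Flag amplitudes with tiny Wilson-tail probability as excluded.

    Under the acentric Wilson distribution the tail probability of an
    amplitude F in a bin with mean-square amplitude S is exp(-F^2 / S).
    Reflections with tail probability below ``threshold`` are marked
    excluded (kept in the set, ignored by work/free selections).
    """
    out = data.copy()
    if threshold <= 0:
        return out
    F = data.data if data.kind == "F" else np.sqrt(np.maximum(data.data, 0))
    labels = resolution_bins(data.d_spacing, target_per_bin)
    flagged = np.zeros(len(data), bool)
    for b in np.unique(labels):
        m = labels == b
        S = np.mean(F[m] ** 2)
        if S <= 0:
            continue
        tail = np.exp(-F[m]**2 / S)
        sub = flagged[m]
        sub[tail < threshold] = True
        flagged[m] = sub
    out.excluded = out.excluded | flagged
    return out


def check_free_flags(data: ReflectionSet, fraction: float = 0.05,
                     seed: int = 0) -> ReflectionSet:
    """Validate existing free flags or generate them at ``fraction``."""
    out = data.copy()
    if out.is_free.any():
        frac = out.is_free.mean()
        if frac > 0.5:
            raise ValueError(f"free fraction {frac:.2f} exceeds 0.5")
        return out
    if not 0.0 < fraction <= 0.5:
        raise ValueError("free fraction must lie in (0, 0.5]")
    n = len(out)
    n_free = max(1, int(round(n * fraction)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_free, replace=False)
    out.is_free[:] = False
    out.is_free[idx] = True
    return out
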