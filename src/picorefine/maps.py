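"""Map coefficients and real-space synthesis.

Weighted maps use coefficients (p m |Fo| - q D |Fm|) exp(i phi_model) with
the likelihood figure of merit m and amplitude coefficient D interpolated
per reflection from the binned error model; unweighted maps drop m and D.
Missing observations inside the data sphere can be filled (by default with
D |F_model|) to reduce series-termination distortions; filled reflections
are flagged so both the filled and unfilled variants can be produced.

The anomalous difference map divides Bijvoet amplitude differences by 2i,
i.e. amplitude (F+ - F-)/2 carried on phase phi_model - 90 degrees.
"""

from __future__ import annotations

import dataclasses

import gemmi
import numpy as np

from .model_data import ReflectionSet, resolution_bins
from .targets import ErrorModel, figures_of_merit
from . import scatter

FILL_MODES = ("dfmodel", "bin_mean_fobs", "fmodel", "random_around_mean",
              "none")


@dataclasses.dataclass
class MapRequest:
    map_p: float = 2.0
    map_q: float = 1.0
    weighted: bool = True
    fill_mode: str = "none"
    fill_seed: int = 0

    def __post_init__(self) -> None:
        if self.fill_mode not in FILL_MODES:
            raise ValueError(f"fill_mode must be one of {FILL_MODES}")


@dataclasses.dataclass
class MapCoefficients:
    miller: np.ndarray
    coeffs: np.ndarray  # complex
    filled: np.ndarray  # True where the amplitude was filled, not observed
    cell: gemmi.UnitCell


def map_coefficients(f_obs: ReflectionSet, fmodel,
                     error: ErrorModel | None,
                     request: MapRequest,
                     spacegroup_hm: str = "P 1") -> MapCoefficients:
    """p.mFo - q.DFm (weighted) or p.Fo - q.Fm (unweighted) coefficients.

    ``fmodel`` may be an :class:`~picorefine.fmodel.FModel` (required when
    the request asks for filling) or a plain complex F_model array aligned
    with ``f_obs``.
    """
    f_model = fmodel.f_model if hasattr(fmodel, "f_model") else fmodel
    amp_model = np.abs(f_model)
    phases = np.angle(f_model)
    if request.weighted:
        if error is None:
            raise ValueError("weighted maps require an error model")
        m, D = figures_of_merit(f_obs, amp_model, error, spacegroup_hm)
    else:
        m = np.ones(len(f_obs))
        D = np.ones(len(f_obs))
    amp = request.map_p * m * f_obs.data - request.map_q * D * amp_model
    use = ~f_obs.excluded
    coeffs = np.where(use, amp * np.exp(1j * phases), 0.0)
    out = MapCoefficients(f_obs.miller.copy(), coeffs,
                          np.zeros(len(f_obs), bool), f_obs.cell)
    if request.fill_mode != "none":
        if not hasattr(fmodel, "f_model_at"):
            raise ValueError("filling requires an FModel instance")
        out = fill_missing(out, f_obs, fmodel, error, request,
                           spacegroup_hm)
    return out


def fill_missing(coeffs: MapCoefficients, f_obs: ReflectionSet,
                 fmodel, error: ErrorModel | None,
                 request: MapRequest,
                 spacegroup_hm: str = "P 1") -> MapCoefficients:
    """Augment coefficients at unobserved Miller indices inside the sphere.

    ``fmodel`` is an :class:`~picorefine.fmodel.FModel`, used to compute
    phases (and model amplitudes) at the missing indices.  The fill
    amplitude per mode: D|F_model| (default), the resolution-bin average
    of observed |F_obs|, plain |F_model|, or Gaussian draws around the bin
    average with a stated seed.  Observed reflections are never altered;
    filled ones are flagged.  Excluded (outlier) reflections count as
    missing.
    """
    d_min = float(f_obs.d_spacing.min())
    full = scatter.miller_set(f_obs.cell, d_min * (1 - 1e-9),
                              spacegroup=spacegroup_hm)
    have = f_obs.index_map()
    missing = np.array([h for h in full if tuple(h) not in have],
                       dtype=int).reshape(-1, 3)
    excl = f_obs.miller[f_obs.excluded]
    fill_hkl = np.concatenate([missing, excl]) if len(excl) \
        else missing
    if len(fill_hkl) == 0:
        return coeffs
    fmiss = fmodel.f_model_at(fill_hkl)
    amp_model = np.abs(fmiss)
    g = np.array(f_obs.cell.frac.mat.tolist())
    gstar = g @ g.T
    s2_miss = np.einsum("ij,jk,ik->i", fill_hkl, gstar,
                        fill_hkl.astype(float))
    if request.weighted and error is not None:
        D_miss, _ = error.interpolate(s2_miss)
    else:
        D_miss = np.ones(len(fill_hkl))
    # bin statistics of the observed amplitudes, interpolated in 1/d^2
    labels = resolution_bins(f_obs.d_spacing, target_per_bin=75,
                             min_per_bin=10)
    s2_obs = f_obs.s2
    centers, means, stds = [], [], []
    for b in np.unique(labels):
        msel = (labels == b) & ~f_obs.excluded
        if not msel.any():
            continue
        centers.append(s2_obs[msel].mean())
        means.append(f_obs.data[msel].mean())
        stds.append(f_obs.data[msel].std())
    order = np.argsort(centers)
    centers = np.array(centers)[order]
    mean_i = np.interp(s2_miss, centers, np.array(means)[order])
    std_i = np.interp(s2_miss, centers, np.array(stds)[order])
    rng = np.random.default_rng(request.fill_seed)
    if request.fill_mode == "dfmodel":
        fill_amp = D_miss * amp_model
    elif request.fill_mode == "fmodel":
        fill_amp = amp_model
    elif request.fill_mode == "bin_mean_fobs":
        fill_amp = mean_i
    elif request.fill_mode == "random_around_mean":
        fill_amp = np.abs(rng.normal(mean_i, np.maximum(std_i, 1e-12)))
    else:
        return coeffs
    # the filled coefficient carries the substitute amplitude directly
    # (the expected value of the weighted coefficient for an unobserved
    # acentric reflection is D|F_model|)
    new_coeffs = fill_amp * np.exp(1j * np.angle(fmiss))
    out_miller = np.concatenate([coeffs.miller, fill_hkl])
    out_vals = np.concatenate([coeffs.coeffs, new_coeffs])
    out_flags = np.concatenate([coeffs.filled,
                                np.ones(len(fill_hkl), bool)])
    # drop the zeroed excluded entries duplicated in the original block
    if len(excl):
        excl_set = {tuple(h) for h in excl}
        keep = np.ones(len(out_miller), bool)
        for i, h in enumerate(coeffs.miller):
            if tuple(h) in excl_set:
                keep[i] = False
        out_miller, out_vals, out_flags = (out_miller[keep],
                                           out_vals[keep], out_flags[keep])
    return MapCoefficients(out_miller, out_vals, out_flags, coeffs.cell)


def anomalous_difference_map(f_obs: ReflectionSet, f_model: np.ndarray
                             ) -> tuple[MapCoefficients, int]:
    """Bijvoet-difference coefficients {[Fo(+) - Fo(-)]/2i} exp(i phi_model).

    The division by 2i puts amplitude (F+ - F-)/2 on phase
    phi_model - 90 degrees.  Reflections without a measured Friedel mate
    are dropped; the count of dropped pairs is returned.
    """
    lookup = f_obs.index_map()
    phases = np.angle(f_model)
    seen: set[tuple] = set()
    miller, coeffs = [], []
    dropped = 0
    for i, h in enumerate(f_obs.miller):
        th = tuple(h)
        if th in seen:
            continue
        mate = lookup.get(tuple(-h))
        if mate is None:
            dropped += 1
            continue
        seen.add(th)
        seen.add(tuple(-h))
        danom = f_obs.data[i] - f_obs.data[mate]
        coeffs.append((danom / 2.0) * np.exp(1j * (phases[i] - np.pi / 2)))
        miller.append(h)
    miller = np.array(miller, int).reshape(-1, 3)
    return MapCoefficients(miller, np.array(coeffs, complex),
                           np.zeros(len(miller), bool), f_obs.cell), dropped


def synthesize_map(coeffs: MapCoefficients, spacing: float = 0.5,
                   sigma_scale: bool = True,
                   hermitian: bool = True) -> np.ndarray:
    """Real-space grid from map coefficients by inverse FFT.

    The hemisphere is Friedel-completed with conjugate mates; a coefficient
    set that is non-Hermitian (e.g. anomalous-difference coefficients,
    which are anti-Hermitian) is synthesized from its Hermitian projection
    when ``hermitian`` is requested, as is conventional for displaying such
    maps; pass hermitian=False to raise instead.  Values are scaled to
    rms = 1 (sigma scaling) unless disabled.
    """
    cell = coeffs.cell
    shape = scatter._grid_shape(cell, spacing)
    n = np.array(shape)
    grid = np.zeros(shape, complex)
    lookup: dict[tuple, complex] = {}
    for h, c in zip(coeffs.miller, coeffs.coeffs):
        lookup[tuple(h)] = c
    for h, c in list(lookup.items()):
        mh = tuple(-np.array(h))
        if mh not in lookup:
            lookup[mh] = np.conj(c)
    for h, c in lookup.items():
        mh = tuple(-np.array(h))
        if not np.isclose(lookup[mh], np.conj(c), atol=1e-8 * (1 + abs(c))):
            if not hermitian:
                raise ValueError("non-Hermitian coefficient set")
            # Hermitian projection: average with the conjugate mate
            avg = 0.5 * (c + np.conj(lookup[mh]))
            lookup[h], lookup[mh] = avg, np.conj(avg)
    for h, c in lookup.items():
        idx = tuple(np.array(h) % n)
        grid[idx] = c
    rho = np.fft.fftn(grid).real / cell.volume
    if sigma_scale:
        rms = np.sqrt(np.mean(rho**2))
        if rms > 0:
            rho = rho / rms
    return rho


def map_value_at(rho: np.ndarray, cell: gemmi.UnitCell,
                 xyz: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the grid at Cartesian positions."""
    fmat = np.array(cell.frac.mat.tolist())
    xf = (np.atleast_2d(xyz) @ fmat.T) % 1.0
    n = np.array(rho.shape)
    g = xf * n
    i0 = np.floor(g).astype(int)
    t = g - i0
    out = np.zeros(len(xf))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = ((t[:, 0] if di else 1 - t[:, 0]) *
                     (t[:, 1] if dj else 1 - t[:, 1]) *
                     (t[:, 2] if dk else 1 - t[:, 2]))
                idx = ((i0 + [di, dj, dk]) % n)
                out += w * rho[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def map_gradient_at(rho: np.ndarray, cell: gemmi.UnitCell,
                    xyz: np.ndarray, delta: float = 0.25) -> np.ndarray:
    """Central-difference Cartesian gradient of the interpolated map."""
    xyz = np.atleast_2d(xyz)
    g = np.zeros_like(xyz)
    for ax in range(3):
        step = np.zeros(3)
        step[ax] = delta
        g[:, ax] = (map_value_at(rho, cell, xyz + step)
                    - map_value_at(rho, cell, xyz - step)) / (2 * delta)
    return g


def b_sharpen(coeffs: MapCoefficients, b_sharp: float | None = None
              ) -> MapCoefficients:
    """Apply exp(+B s^2/4) sharpening; B fitted from the Wilson falloff
    of mean amplitude vs resolution when not given."""
    g = np.array(coeffs.cell.frac.mat.tolist())
    gstar = g @ g.T
    s2 = np.einsum("ij,jk,ik->i", coeffs.miller, gstar,
                   coeffs.miller.astype(float))
    amp = np.abs(coeffs.coeffs)
    if b_sharp is None:
        good = amp > 0
        if good.sum() < 10:
            b_sharp = 0.0
        else:
            A = np.column_stack([np.ones(good.sum()), -s2[good] / 4.0])
            coef, *_ = np.linalg.lstsq(A, np.log(amp[good]), rcond=None)
            b_sharp = max(coef[1], 0.0)
    out = coeffs.coeffs * np.exp(b_sharp * s2 / 4.0)
    return MapCoefficients(coeffs.miller.copy(), out, coeffs.filled.copy(),
                           coeffs.cell)
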