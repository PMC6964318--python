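"""Six-point chemical-shift water-fat separation.

The signal model per voxel is

    s(t) = (W + F * sum_m a_m exp(i 2π f_m t)) * exp(i 2π ψ t) * exp(-t/T2*)

with complex water/fat amplitudes W, F, off-resonance ψ (Hz), a mono-
exponential T2*, and the known multi-peak fat spectrum (f_m, a_m).

Fitting uses variable projection: for candidate (ψ, R2* = 1/T2*), the
amplitudes enter linearly through the 2-column design matrix

    A(ψ, R2*) = [e(t), c(t) e(t)],   e(t) = exp((i 2π ψ - R2*) t),
    c(t) = sum_m a_m exp(i 2π f_m t)

and are solved in closed form; the nonlinear search runs only over
(ψ, R2*).  Because ψ and the water-fat assignment are ambiguous (the
residual is near-periodic in ψ), the field map is first estimated at low
resolution by an exhaustive 1-D grid search and propagated by a region
growing scheme that prefers the candidate minimum closest to the ψ of
already-solved neighbours — spatial smoothness resolves the swap
ambiguity.  The smooth low-resolution ψ is then upsampled and refined
jointly with R2* by damped Gauss-Newton at full resolution.

The fat fraction is computed from the magnitude amplitudes:
``FF = |F| / (|F| + |W|)``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AcquisitionParams, EchoSeries, QuantitativeMaps

__all__ = [
    "model_signal", "fit_voxel", "estimate_fieldmap", "reconstruct_maps",
    "FieldmapResult",
]

_R2S_MIN = 0.5    # 1/s  (T2* <= 2000 ms)
_R2S_MAX = 2000.0  # 1/s  (T2* >= 0.5 ms)


def _fat_modulation(te: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
    offsets = np.array([f for f, _ in acq.fat_peaks])
    amps = np.array([a for _, a in acq.fat_peaks])
    return (amps[None, :] * np.exp(2j * np.pi * offsets[None, :] * te[:, None])).sum(axis=1)


def model_signal(water: complex, fat: complex, fieldmap: float, t2star: float,
                 acq: AcquisitionParams, te: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the signal model at the acquisition's echo times.

    ``t2star`` is in ms; pass ``np.inf`` for no decay.
    """
    if t2star <= 0:
        raise ValueError("t2star must be positive")
    te = acq.te if te is None else np.asarray(te, dtype=float)
    c = _fat_modulation(te, acq)
    decay = np.exp(-te / (t2star * 1e-3)) if np.isfinite(t2star) else 1.0
    return (water + fat * c) * np.exp(2j * np.pi * fieldmap * te) * decay


def _varpro(signal: np.ndarray, te: np.ndarray, psi: np.ndarray, r2s: np.ndarray,
            fat_mod: np.ndarray):
    """Closed-form linear subproblem of the variable projection.

    ``signal``: (..., E) complex; ``psi``, ``r2s``: broadcastable to (...,).
    Returns (w, f, residual) with residual of shape (..., E); where the
    2x2 normal system is singular, amplitudes are zero and the residual is
    the signal itself (flagged by the caller).
    """
    psi = np.asarray(psi, dtype=float)[..., None]
    r2s = np.asarray(r2s, dtype=float)[..., None]
    e = np.exp((2j * np.pi * psi - r2s) * te)  # (..., E)
    a1 = e
    a2 = fat_mod * e
    # normal equations of the 2-column complex least squares
    g11 = (np.conj(a1) * a1).sum(-1).real
    g12 = (np.conj(a1) * a2).sum(-1)
    g22 = (np.conj(a2) * a2).sum(-1).real
    b1 = (np.conj(a1) * signal).sum(-1)
    b2 = (np.conj(a2) * signal).sum(-1)
    det = g11 * g22 - (g12 * np.conj(g12)).real
    ok = det > 1e-12 * np.maximum(g11 * g22, 1e-300)
    det_safe = np.where(ok, det, 1.0)
    w = (g22 * b1 - g12 * b2) / det_safe
    f = (g11 * b2 - np.conj(g12) * b1) / det_safe
    w = np.where(ok, w, 0.0)
    f = np.where(ok, f, 0.0)
    resid = signal - (w[..., None] * a1 + f[..., None] * a2)
    return w, f, resid, ok


def _gauss_newton(signal: np.ndarray, te: np.ndarray, psi0: np.ndarray,
                  r2s0: np.ndarray, fat_mod: np.ndarray, n_iter: int = 40,
                  tol: float = 1e-12):
    """Damped Gauss-Newton over (ψ, R2*), vectorized across voxels.

    Finite-difference Jacobian of the projected residual; Levenberg damping
    adapted per voxel.  Returns (psi, r2s, w, f, cost, ok).
    """
    psi = np.asarray(psi0, dtype=float).copy()
    r2s = np.clip(np.asarray(r2s0, dtype=float), _R2S_MIN, _R2S_MAX).copy()
    lam = np.full(psi.shape, 1e-3)

    def cost_of(p, r):
        _, _, resid, ok = _varpro(signal, te, p, r, fat_mod)
        return (np.abs(resid) ** 2).sum(-1), ok

    cost, ok = cost_of(psi, r2s)
    h_psi, h_r2s = 1e-2, 1e-2  # Hz and 1/s finite-difference steps
    for _ in range(n_iter):
        _, _, r0, _ = _varpro(signal, te, psi, r2s, fat_mod)
        _, _, r1, _ = _varpro(signal, te, psi + h_psi, r2s, fat_mod)
        _, _, r2, _ = _varpro(signal, te, psi, r2s + h_r2s, fat_mod)
        j1 = (r1 - r0) / h_psi
        j2 = (r2 - r0) / h_r2s
        # real normal equations of the complex residual
        a11 = (np.conj(j1) * j1).sum(-1).real + lam
        a12 = (np.conj(j1) * j2).sum(-1).real
        a22 = (np.conj(j2) * j2).sum(-1).real + lam
        b1 = -(np.conj(j1) * r0).sum(-1).real
        b2 = -(np.conj(j2) * r0).sum(-1).real
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) > 1e-300, det, 1.0)
        dpsi = (a22 * b1 - a12 * b2) / det
        dr2s = (a11 * b2 - a12 * b1) / det
        psi_t = psi + dpsi
        r2s_t = np.clip(r2s + dr2s, _R2S_MIN, _R2S_MAX)
        cost_t, _ = cost_of(psi_t, r2s_t)
        better = cost_t <= cost
        psi = np.where(better, psi_t, psi)
        r2s = np.where(better, r2s_t, r2s)
        improved = cost - np.where(better, cost_t, cost)
        cost = np.where(better, cost_t, cost)
        lam = np.where(better, np.maximum(lam * 0.3, 1e-8), lam * 4.0)
        if np.all(improved <= tol * np.maximum(cost, 1e-300)):
            break
    w, f, resid, lin_ok = _varpro(signal, te, psi, r2s, fat_mod)
    cost = (np.abs(resid) ** 2).sum(-1)
    return psi, r2s, w, f, cost, ok & lin_ok


def fit_voxel(signal: np.ndarray, te: np.ndarray, psi_init: float,
              acq: AcquisitionParams, r2s_init: float = 50.0):
    """Fit one voxel's (water, fat, fieldmap, T2*) from its echo signal.

    Nonlinear least squares over (ψ, R2*) with the water/fat amplitudes
    solved linearly at each candidate (variable projection); converges to
    the solution in ``psi_init``'s basin.  Returns
    ``(water, fat, fieldmap_hz, t2star_ms, residual_norm, fit_ok)`` with
    magnitude amplitudes.
    """
    signal = np.asarray(signal, dtype=complex)
    te = np.asarray(te, dtype=float)
    if len(te) < 4:
        raise ValueError("at least 4 echoes required to fit 4 parameters")
    if np.all(np.abs(signal) == 0):
        return 0.0, 0.0, float(psi_init), np.nan, 0.0, False
    fat_mod = _fat_modulation(te, acq)
    psi, r2s, w, f, cost, ok = _gauss_newton(
        signal[None, :], te, np.array([psi_init]), np.array([r2s_init]), fat_mod)
    t2s_ms = 1000.0 / r2s[0]
    return (float(np.abs(w[0])), float(np.abs(f[0])), float(psi[0]),
            float(t2s_ms), float(np.sqrt(cost[0])), bool(ok[0]))


@dataclass
class FieldmapResult:
    """Low-resolution field map plus its upsampled full-resolution version."""

    psi_lowres: np.ndarray  # Hz, on the downsampled grid
    psi_init: np.ndarray  # Hz, upsampled to the full grid
    foreground_lowres: np.ndarray  # bool
    grid_step: float  # Hz


def _block_reduce_mean(data: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Mean over non-overlapping blocks (trailing partial blocks dropped)."""
    fx, fy, fz = factors
    nx, ny, nz = (data.shape[i] // f for i, f in enumerate(factors))
    d = data[: nx * fx, : ny * fy, : nz * fz]
    d = d.reshape(nx, fx, ny, fy, nz, fz, *data.shape[3:])
    return d.mean(axis=(1, 3, 5))


def _local_minima_1d(res: np.ndarray) -> list[np.ndarray]:
    """Indices of local minima along the last axis, per leading index."""
    interior = (res[..., 1:-1] <= res[..., :-2]) & (res[..., 1:-1] <= res[..., 2:])
    out = []
    flat = interior.reshape(-1, interior.shape[-1])
    res_flat = res.reshape(-1, res.shape[-1])
    for i in range(flat.shape[0]):
        idx = np.flatnonzero(flat[i]) + 1
        if idx.size == 0:
            idx = np.array([int(np.argmin(res_flat[i]))])
        out.append(idx)
    return out


def estimate_fieldmap(echoes: EchoSeries, downsample_factor: int = 2,
                      grid_step: float = 2.0, magnitude_floor: float = 0.05,
                      ) -> FieldmapResult:
    """Estimate the off-resonance map ψ by grid search plus region growing.

    A low-resolution reconstruction first evaluates, per voxel, the
    variable-projection residual on a 1-D ψ grid spanning the ambiguity
    period ±1/(2 ΔTE).  A region growing scheme then extrapolates the
    spatially smooth branch: starting from the strongest-signal voxel's
    global minimum, voxels are visited in decreasing magnitude order and
    each adopts its candidate local minimum closest to the median ψ of its
    already-solved 6-neighbours.  The result is upsampled as the
    initialization for the full-resolution fit.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    te = echoes.te
    dte = float(np.median(np.diff(te)))
    half_period = 1.0 / (2.0 * dte)
    factors = (downsample_factor, downsample_factor, 1)
    low = _block_reduce_mean(echoes.data, factors)
    mag = np.abs(low).mean(axis=-1)
    if mag.max() <= 0:
        raise ValueError("empty foreground: all voxel magnitudes are zero")
    foreground = mag > magnitude_floor * mag.max()
    if not foreground.any():
        raise ValueError("empty foreground: all magnitudes below the noise floor")

    psi_grid = np.arange(-half_period, half_period + grid_step / 2, grid_step)
    fat_mod = _fat_modulation(te, echoes.acq)
    fg_idx = np.argwhere(foreground)
    sig_fg = low[foreground]  # (N, E)

    # residual over the ψ grid, minimized over a coarse R2* set
    r2s_set = np.array([20.0, 50.0, 100.0])
    res = np.full((sig_fg.shape[0], psi_grid.size), np.inf)
    for r2s in r2s_set:
        for k, psi in enumerate(psi_grid):
            _, _, resid, _ = _varpro(sig_fg, te, np.full(sig_fg.shape[0], psi),
                                     np.full(sig_fg.shape[0], r2s), fat_mod)
            r = (np.abs(resid) ** 2).sum(-1)
            res[:, k] = np.minimum(res[:, k], r)

    minima = _local_minima_1d(res)
    lin = {tuple(v): i for i, v in enumerate(fg_idx)}
    psi_low = np.zeros(low.shape[:3])
    solved = np.zeros(low.shape[:3], dtype=bool)
    mag_fg = mag[foreground]

    seed_i = int(np.argmax(mag_fg))
    seed_vox = tuple(fg_idx[seed_i])
    psi_low[seed_vox] = psi_grid[int(np.argmin(res[seed_i]))]
    solved[seed_vox] = True

    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape3 = low.shape[:3]

    def push_neighbours(heap, vox, visited):
        for d in nbrs:
            n = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
            if all(0 <= n[i] < shape3[i] for i in range(3)) and n in lin and n not in visited:
                visited.add(n)
                heapq.heappush(heap, (-mag[n], n))

    heap: list = []
    visited = {seed_vox}
    push_neighbours(heap, seed_vox, visited)
    while heap:
        _, vox = heapq.heappop(heap)
        ref = [psi_low[(vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])]
               for d in nbrs
               if all(0 <= vox[i] + d[i] < shape3[i] for i in range(3))
               and solved[(vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])]]
        ref_psi = float(np.median(ref)) if ref else 0.0
        cand = psi_grid[minima[lin[vox]]]
        psi_low[vox] = cand[int(np.argmin(np.abs(cand - ref_psi)))]
        solved[vox] = True
        push_neighbours(heap, vox, visited)

    # fill background with the nearest solved ψ so upsampling stays smooth
    if not solved.all():
        _, inds = ndimage.distance_transform_edt(~solved, return_indices=True)
        psi_low = psi_low[tuple(inds)]

    zoom = [s / l for s, l in zip(echoes.shape, psi_low.shape)]
    psi_init = ndimage.zoom(psi_low, zoom, order=1, mode="nearest")
    # zoom can be off by one voxel on odd shapes; pad/crop defensively
    pads = [(0, max(0, s - p)) for s, p in zip(echoes.shape, psi_init.shape)]
    psi_init = np.pad(psi_init, pads, mode="edge")[
        : echoes.shape[0], : echoes.shape[1], : echoes.shape[2]]
    return FieldmapResult(psi_lowres=psi_low, psi_init=psi_init,
                          foreground_lowres=foreground, grid_step=grid_step)


def reconstruct_maps(echoes: EchoSeries, downsample_factor: int = 2,
                     r2s_init: float = 60.0, magnitude_floor: float = 0.02,
                     ) -> QuantitativeMaps:
    """Full water-fat reconstruction of an echo series.

    Runs :func:`estimate_fieldmap`, then the variable-projection
    Gauss-Newton fit at every voxel, and assembles quantitative maps.
    The fat fraction is ``|F| / (|F| + |W|)``; voxels with vanishing total
    signal or a singular linear subproblem are flagged ``fit_ok = False``
    and carry ``ff = nan``.
    """
    fm = estimate_fieldmap(echoes, downsample_factor=downsample_factor)
    te = echoes.te
    fat_mod = _fat_modulation(te, echoes.acq)
    shape = echoes.shape
    sig = echoes.data.reshape(-1, len(te))
    psi0 = fm.psi_init.reshape(-1)
    mag = np.abs(sig).mean(axis=-1)
    nz = mag > magnitude_floor * max(mag.max(), 1e-300)

    psi = psi0.copy()
    r2s = np.full(sig.shape[0], r2s_init)
    w = np.zeros(sig.shape[0], dtype=complex)
    f = np.zeros(sig.shape[0], dtype=complex)
    ok = np.zeros(sig.shape[0], dtype=bool)
    if nz.any():
        p, r, wv, fv, _, okv = _gauss_newton(sig[nz], te, psi0[nz],
                                             np.full(int(nz.sum()), r2s_init), fat_mod)
        psi[nz], r2s[nz], w[nz], f[nz], ok[nz] = p, r, wv, fv, okv

    water = np.abs(w)
    fat = np.abs(f)
    total = water + fat
    ff = np.full(sig.shape[0], np.nan)
    pos = total > 0
    ff[pos] = fat[pos] / total[pos]
    fit_ok = ok & nz & pos
    t2star = np.full(sig.shape[0], np.nan)
    t2star[fit_ok] = 1000.0 / r2s[fit_ok]

    return QuantitativeMaps(
        water=water.reshape(shape), fat=fat.reshape(shape),
        ff=ff.reshape(shape), t2star=t2star.reshape(shape),
        fieldmap=psi.reshape(shape), fit_ok=fit_ok.reshape(shape),
        affine=echoes.affine.copy(),
    )
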