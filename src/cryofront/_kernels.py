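"""Numba-compiled inner loops of the explicit stepper.

The update rule is the five-point explicit stencil in cylindrical (z, r)
coordinates with per-direction effective diffusivities: pairwise
harmonic-mean conductivity (series thermal resistors over the two half
cells) divided by the volumetric heat capacity of the receiving node, with
half-shifted radius weights r_plus/r_j and r_minus/r_j on the radial fluxes.

Thermophysical input comes as per-material lookup tables sampled on a
uniform temperature grid (built in :mod:`cryofront.solver` from the analytic
property models): ``k_tab[m, i]`` is point-sampled conductivity and
``c_tab[m, i]`` the bin-averaged volumetric heat capacity rho*Cp_eff, so the
latent heat contained in any traversed temperature interval is conserved to
interpolation accuracy.  Material id 0 (ghost/void) has k = 0, which blocks
flux through the harmonic mean, and a dummy capacity of 1 to keep the
branchless loop division-safe.

Per step: conductivities are refreshed from the current field, pairwise edge
conductances are formed once per edge, then a Jacobi sweep writes the new
field into a second buffer -- the same refresh / synchronize / update
ordering a parallel implementation needs.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_SIG_EPS = 1e-30  # keeps 0/0 harmonic means at exactly 0 for ghost pairs


@nb.njit(cache=True, fastmath=True)
def refresh_conductivity(T, mat, k_tab, t0, inv_dT, K):
    nz2, nr2 = T.shape
    hi = k_tab.shape[1] - 1.000001
    for i in range(nz2):
        for j in range(nr2):
            m = mat[i, j]
            x = (T[i, j] - t0) * inv_dT
            x = min(max(x, 0.0), hi)
            it = int(x)
            f = x - it
            k = k_tab[m, it] + f * (k_tab[m, it + 1] - k_tab[m, it])
            K[i, j] = k if m > 0 else 0.0


@nb.njit(cache=True, fastmath=True)
def _edge_conductances(K, HV, HH):
    # HV[i, j]: vertical edge between rows i and i+1; HH[i, j]: radial edge
    # between columns j and j+1
    nz2, nr2 = K.shape
    for i in range(nz2 - 1):
        for j in range(nr2):
            a = K[i, j]
            b = K[i + 1, j]
            HV[i, j] = 2.0 * a * b / (a + b + _SIG_EPS)
    for i in range(nz2):
        for j in range(nr2 - 1):
            a = K[i, j]
            b = K[i, j + 1]
            HH[i, j] = 2.0 * a * b / (a + b + _SIG_EPS)


@nb.njit(cache=True, fastmath=True)
def _sweep(A, B, HV, HH, mat, upd, c_tab, t0, inv_dT,
           wr, wl, dt, inv_dz2, mu, md, ml, mr, use_m, top_active):
    nz2, nr2 = A.shape
    hi = c_tab.shape[1] - 1.000001
    if top_active:
        # surface-film row i = 0: no neighbor above, upward conductance 0
        for j in range(1, nr2 - 1):
            Tij = A[0, j]
            m = mat[0, j]
            x = (Tij - t0) * inv_dT
            x = min(max(x, 0.0), hi)
            it = int(x)
            f = x - it
            c = c_tab[m, it] + f * (c_tab[m, it + 1] - c_tab[m, it])
            hd = HV[0, j]
            hr = HH[0, j]
            hl = HH[0, j - 1]
            if use_m:
                hd *= md[0, j]
                hr *= mr[0, j]
                hl *= ml[0, j]
            flux = hd * (A[1, j] - Tij) * inv_dz2 \
                + hr * wr[j] * (A[0, j + 1] - Tij) \
                + hl * wl[j] * (A[0, j - 1] - Tij)
            B[0, j] = Tij + upd[0, j] * dt * flux / c
    for i in range(1, nz2 - 1):
        for j in range(1, nr2 - 1):
            Tij = A[i, j]
            m = mat[i, j]
            x = (Tij - t0) * inv_dT
            x = min(max(x, 0.0), hi)
            it = int(x)
            f = x - it
            c = c_tab[m, it] + f * (c_tab[m, it + 1] - c_tab[m, it])
            hu = HV[i - 1, j]
            hd = HV[i, j]
            hr = HH[i, j]
            hl = HH[i, j - 1]
            if use_m:
                hu *= mu[i, j]
                hd *= md[i, j]
                hr *= mr[i, j]
                hl *= ml[i, j]
            flux = (hu * (A[i - 1, j] - Tij) + hd * (A[i + 1, j] - Tij)) * inv_dz2 \
                + hr * wr[j] * (A[i, j + 1] - Tij) \
                + hl * wl[j] * (A[i, j - 1] - Tij)
            B[i, j] = Tij + upd[i, j] * dt * flux / c


@nb.njit(cache=True, fastmath=True)
def run_chunk(T, Tbuf, K, HV, HH, mat, upd, k_tab, c_tab, t0, inv_dT,
              wr, wl, dt, inv_dz2,
              mu, md, ml, mr, nsteps, top_active):
    """Advance ``nsteps`` explicit steps; the result is left in ``T``.

    ``Tbuf`` must enter as an exact copy of ``T`` (boundary entries are never
    rewritten).  ``wr[j]`` = r_plus/(r_j dr^2) and ``wl[j]`` = r_minus/(r_j
    dr^2) are the precomputed radial stencil weights.  ``top_active`` enables
    the surface-film row i = 0, which has no neighbor above and therefore a
    zero upward flux.  The directional flux-mask multiplies are skipped when
    every mask entry is 1.
    """
    nz2, nr2 = T.shape
    use_m = False
    for i in range(nz2):
        for j in range(nr2):
            if mu[i, j] != 1.0 or md[i, j] != 1.0 \
                    or ml[i, j] != 1.0 or mr[i, j] != 1.0:
                use_m = True
    A = T
    B = Tbuf
    for _ in range(nsteps):
        refresh_conductivity(A, mat, k_tab, t0, inv_dT, K)
        _edge_conductances(K, HV, HH)
        _sweep(A, B, HV, HH, mat, upd, c_tab, t0, inv_dT,
               wr, wl, dt, inv_dz2, mu, md, ml, mr, use_m, top_active)
        A, B = B, A
    if nsteps % 2 == 1:
        T[:, :] = A
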