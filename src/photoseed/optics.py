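"""CW light transport in the diffusion approximation.

In strongly scattering tissue the fluence rate of a narrow CW beam entering
at a surface point is modelled by the point-source diffusion kernel

    phi(r_vec) = P0 * exp(-mu_eff * (r_vec . n_hat)) / (4 * pi * D * r)

with ``r_vec`` measured from the entry point, ``r = |r_vec|``, ``n_hat`` the
beam direction, and ``D``/``mu_eff`` the diffusion coefficient and effective
attenuation of the medium.  The volumetric heat source available to the
bioheat equation is ``q = mu_a * phi`` (W m^-3).

Heterogeneity is handled locally by default: each voxel is attenuated with
its *own* material's ``mu_eff`` and ``D``.  An optional depth-integrated
mode accumulates the optical depth ``integral mu_eff dz`` along an
axis-aligned beam instead, which is the physically truer reading for a
layered medium.

Non-diffusive inclusions (the photoseeds, with mu_s' = 0, or water) are not
media the diffusion approximation can propagate light through: their own
mu_eff/D would either annihilate or blow up the kernel.  They are instead
treated as absorbers embedded in the *host* tissue's light field: their
voxels evaluate the kernel with the host material's mu_eff and D, while
keeping their own mu_a for the heat source mu_a * phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import LaserBeam, TissuePhantom

__all__ = ["FluenceField", "absorbance_to_mua", "fluence", "heat_source"]


def absorbance_to_mua(a810: float, path_length: float) -> float:
    """Convert a decadic absorbance to an absorption coefficient (1/m).

    ``mu_a = ln(10) * A / l ~= 2.303 * A / l`` for a sample of thickness
    ``l`` (m).  Used to turn the nanocomposite's measured NIR absorbance
    (e.g. A810 = 1.54 across a 30 um film) into the bulk ``mu_a`` of the
    photoseed material.
    """
    if path_length <= 0:
        raise ValueError("path length must be positive")
    if a810 < 0:
        raise ValueError("absorbance must be non-negative")
    return 2.303 * a810 / path_length


@dataclass
class FluenceField:
    """Fluence rate (W m^-2) per voxel, tied to the beam that produced it."""

    values: np.ndarray
    beam: LaserBeam

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("fluence must be finite and non-negative")


def fluence(
    phantom: TissuePhantom,
    beam: LaserBeam,
    *,
    depth_integrated: bool = False,
    host_label: int | None = None,
) -> FluenceField:
    """Evaluate the diffusion point-source kernel on every voxel center.

    The kernel's 1/r singularity at the entry point is regularized by
    clamping ``r`` to half the smallest voxel spacing, which affects at most
    the entry voxel itself.

    Voxels of non-diffusive materials (mu_s' = 0) evaluate the kernel with
    the host medium's ``mu_eff``/``D``; the host defaults to the phantom's
    most abundant diffusive material and can be forced with ``host_label``.
    If the phantom has no diffusive material at all (the clear-water bench
    model), the diffusion kernel does not apply and the fluence is zero --
    such runs deposit absorbed power directly (see ``runs.run_validation``).

    With ``depth_integrated=True`` (axis-aligned beams only) the exponent is
    the cumulative optical depth along the beam path rather than the local
    ``mu_eff * depth``.
    """
    x, y, z = phantom.voxel_centers()
    e = np.asarray(beam.entry_point, dtype=float)
    n_hat = beam.n_hat

    dx = x[:, None, None] - e[0]
    dy = y[None, :, None] - e[1]
    dz = z[None, None, :] - e[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    r = np.maximum(r, 0.5 * min(phantom.spacing))
    depth = dx * n_hat[0] + dy * n_hat[1] + dz * n_hat[2]

    mu_eff, d_coef, diffusive = _kernel_coefficients(phantom, host_label)

    if depth_integrated:
        tau = _cumulative_optical_depth(phantom, beam, mu_eff)
    else:
        tau = mu_eff * depth

    with np.errstate(over="ignore"):
        phi = beam.p0 * np.exp(-tau) / (4.0 * np.pi * d_coef * r)
    if not diffusive:
        phi[:] = 0.0
    return FluenceField(values=phi, beam=beam)


def _kernel_coefficients(phantom: TissuePhantom, host_label: int | None):
    """Per-voxel mu_eff and D, substituting the host medium's values inside
    non-diffusive inclusions.  Returns (mu_eff, D, any_diffusive_material)."""
    diffusive = {
        lbl: m for lbl, m in phantom.materials.items() if m.optical.mu_s_prime > 0
    }
    if not diffusive:
        return np.zeros(phantom.shape), np.full(phantom.shape, np.inf), False

    if host_label is None:
        counts = {
            lbl: int(np.count_nonzero(phantom.labels == lbl)) for lbl in diffusive
        }
        host_label = max(counts, key=counts.get)  # type: ignore[arg-type]
    elif host_label not in diffusive:
        raise ValueError(f"host label {host_label} is not a diffusive material")
    host = phantom.materials[host_label].optical

    mu_eff = np.empty(phantom.shape)
    d_coef = np.empty(phantom.shape)
    for lbl, mat in phantom.materials.items():
        sel = phantom.labels == lbl
        opt = mat.optical if lbl in diffusive else host
        mu_eff[sel] = opt.mu_eff
        d_coef[sel] = opt.diffusion_coefficient
    return mu_eff, d_coef, True


def _cumulative_optical_depth(
    phantom: TissuePhantom, beam: LaserBeam, mu_eff: np.ndarray
) -> np.ndarray:
    n_hat = beam.n_hat
    axis = int(np.argmax(np.abs(n_hat)))
    if not np.isclose(np.abs(n_hat[axis]), 1.0):
        raise NotImplementedError(
            "depth-integrated attenuation requires an axis-aligned beam"
        )
    h = phantom.spacing[axis]
    sign = int(np.sign(n_hat[axis]))
    m = mu_eff if sign > 0 else np.flip(mu_eff, axis=axis)
    # midpoint rule: half a voxel of self-attenuation plus full upstream voxels
    tau = np.cumsum(m, axis=axis) * h - 0.5 * m * h
    return tau if sign > 0 else np.flip(tau, axis=axis)


def heat_source(fl: FluenceField, phantom: TissuePhantom) -> np.ndarray:
    """Volumetric photothermal source ``q = mu_a * phi`` (W m^-3) per voxel."""
    if fl.values.shape != phantom.shape:
        raise ValueError(
            f"fluence grid {fl.values.shape} does not match phantom {phantom.shape}"
        )
    return phantom.mu_a_field() * fl.values
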