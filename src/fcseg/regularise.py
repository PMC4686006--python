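"""Mean curvature flow regularisation of a binary mask boundary.

The mask is embedded as a signed distance function (positive inside) and the
level set is evolved with normal speed equal to curvature,
``phi_t = kappa * |grad phi|``, using an explicit scheme with central
differences — the parabolic term needs no upwinding.  The distance function
is rebuilt periodically to keep ``|grad phi|`` close to 1.  Under this flow
corners round off, the perimeter never increases, and a circle of radius r
shrinks to radius ``sqrt(r^2 - 2*tau)`` after time tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MCFParams", "mcf_smooth"]


@dataclass(frozen=True)
class MCFParams:
    """Explicit mean-curvature-flow settings.

    ``time_step`` must respect the 2D explicit CFL bound (<= 0.25);
    ``n_iter`` steps are taken, with the signed distance rebuilt every
    ``reinit_every`` steps.  Total smoothing "time" is n_iter * time_step in
    px^2 units.
    """

    time_step: float = 0.2
    n_iter: int = 25
    reinit_every: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.time_step <= 0.25:
            raise ValueError(f"time_step must be in (0, 0.25], got {self.time_step}")
        if self.n_iter < 0:
            raise ValueError(f"n_iter must be >= 0, got {self.n_iter}")
        if self.reinit_every < 1:
            raise ValueError("reinit_every must be >= 1")


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _reinitialise(phi: np.ndarray, n_steps: int = 20, dtau: float = 0.3) -> np.ndarray:
    """Restore |grad phi| ~ 1 without moving the zero level.

    Sussman-style PDE reinitialisation ``phi_tau = S(phi0) (1 - |grad phi|)``
    with a Godunov upwind gradient and a smoothed sign function.  Rebuilding
    the distance function from the binary mask instead would snap the
    interface back to pixel centres and erase sub-pixel motion, stalling
    slow flows entirely.
    """
    phi0 = phi
    sign = phi0 / np.sqrt(phi0**2 + 1.0)
    for _ in range(n_steps):
        dr_f = np.diff(phi, axis=0, append=phi[-1:, :])
        dr_b = np.diff(phi, axis=0, prepend=phi[:1, :])
        dc_f = np.diff(phi, axis=1, append=phi[:, -1:])
        dc_b = np.diff(phi, axis=1, prepend=phi[:, :1])
        # Godunov scheme: pick the upwind one-sided differences
        grad_pos = np.sqrt(
            np.maximum(np.maximum(dr_b, 0) ** 2, np.minimum(dr_f, 0) ** 2)
            + np.maximum(np.maximum(dc_b, 0) ** 2, np.minimum(dc_f, 0) ** 2)
        )
        grad_neg = np.sqrt(
            np.maximum(np.minimum(dr_b, 0) ** 2, np.maximum(dr_f, 0) ** 2)
            + np.maximum(np.minimum(dc_b, 0) ** 2, np.maximum(dc_f, 0) ** 2)
        )
        grad = np.where(sign > 0, grad_pos, grad_neg)
        phi = phi + dtau * sign * (1.0 - grad)
    return phi


def _curvature_speed(phi: np.ndarray) -> np.ndarray:
    """kappa * |grad phi| with central differences, curvature clipped for
    stability at thin structures."""
    phi_r, phi_c = np.gradient(phi)
    phi_rr = np.gradient(phi_r, axis=0)
    phi_cc = np.gradient(phi_c, axis=1)
    phi_rc = np.gradient(phi_r, axis=1)
    grad2 = phi_r**2 + phi_c**2
    denom = np.power(grad2, 1.5) + 1e-12
    kappa = (phi_rr * phi_c**2 - 2 * phi_r * phi_c * phi_rc + phi_cc * phi_r**2) / denom
    kappa = np.clip(kappa, -1.0, 1.0)
    return kappa * np.sqrt(grad2)


def mcf_smooth(mask: np.ndarray, params: MCFParams | None = None) -> np.ndarray:
    """Smooth the boundary of `mask` by mean curvature flow.

    Returns the zero-superlevel set after ``params.n_iter`` explicit steps.
    Raises if the object disappears under the flow (reporting the step at
    which it vanished): small objects collapse in finite time, so overly
    long flows on thin structures are a user error, not a silent no-op.
    """
    if params is None:
        params = MCFParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if params.n_iter == 0:
        return mask.copy()

    phi = _signed_distance(mask)
    for step in range(1, params.n_iter + 1):
        phi = phi + params.time_step * _curvature_speed(phi)
        if step % params.reinit_every == 0 and step < params.n_iter:
            if not (phi > 0).any():
                raise ValueError(f"mask vanished under curvature flow at step {step}")
            phi = _reinitialise(phi)

    out = phi > 0
    if not out.any():
        raise ValueError(f"mask vanished under curvature flow at step {params.n_iter}")
    return out
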