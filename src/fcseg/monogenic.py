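"""Monogenic signal: local amplitude, phase and orientation of a 2D image.

The monogenic signal generalises the 1D analytic signal to images via the
Riesz transform.  An isotropic, DC-free bandpass filter selects a scale; the
two Riesz components form the odd (quadrature) counterpart of the even
bandpass response.  Local phase encodes structure (edges, ridges) and is
invariant to image contrast, which is what makes it attractive for B-mode
ultrasound where absolute intensities are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandpassSpec",
    "MonogenicResponse",
    "PhaseMaps",
    "make_bandpass",
    "riesz_responses",
    "monogenic_signal",
    "phase_maps",
]

#: amplitude below this is treated as zero when deriving phase/orientation
_ZERO_AMPLITUDE = 1e-12


@dataclass(frozen=True)
class BandpassSpec:
    """Isotropic radial bandpass filter selection.

    Parameters
    ----------
    sigma
        Scale of the Gaussian-derivative profile ``B(u) = |u| exp(-|u|^2 sigma^2)``
        with the radial frequency ``|u|`` in cycles/pixel on ``[-0.5, 0.5]``.
        Larger sigma selects lower frequencies (coarser structures); the peak
        of the continuous profile sits at ``|u| = 1/(sigma*sqrt(2))``.
    kind
        Bandpass family; only ``"gaussian_derivative"`` is implemented.
    """

    sigma: float
    kind: str = "gaussian_derivative"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.kind != "gaussian_derivative":
            raise ValueError(f"unknown bandpass kind {self.kind!r}")


@dataclass
class MonogenicResponse:
    """Even bandpass response and the two odd Riesz responses at one scale."""

    even: np.ndarray
    odd1: np.ndarray
    odd2: np.ndarray
    scale: BandpassSpec

    def __post_init__(self) -> None:
        if not (self.even.shape == self.odd1.shape == self.odd2.shape):
            raise ValueError("even/odd1/odd2 must share one shape")

    @property
    def odd_norm(self) -> np.ndarray:
        """Pointwise magnitude of the odd (Riesz) vector."""
        return np.hypot(self.odd1, self.odd2)


@dataclass
class PhaseMaps:
    """Local amplitude, phase and orientation maps.

    ``phase`` follows the folded convention: values in ``[0, pi]`` with 0 at a
    strong positive even response (bright ridge) and pi at a strong negative
    one (dark ridge); pure odd structure (step edge crest) sits at pi/2.
    ``orientation`` is the angle of the odd vector, meaningful modulo pi.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    orientation: np.ndarray


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (u, v, |u|) grids in cycles/pixel; u varies along columns."""
    rows, cols = shape
    v = np.fft.fftfreq(rows)[:, None]  # row frequency
    u = np.fft.fftfreq(cols)[None, :]  # column frequency
    radius = np.hypot(u, v)
    return u, v, radius


def make_bandpass(
    shape: tuple[int, int],
    spec: BandpassSpec,
    *,
    normalise: bool = True,
) -> np.ndarray:
    """Frequency response of the radial Gaussian-derivative bandpass.

    ``B(u, v) = |u| exp(-|u|^2 sigma^2)`` on the discrete FFT grid of `shape`,
    with ``|u|`` the radial frequency in cycles/pixel.  The DC bin is exactly
    zero, so filtered images lose their mean (contrast-offset invariance).

    With ``normalise=True`` (default) the response is rescaled to unit peak
    gain on the given grid, so response magnitudes are commensurate with the
    image contrast regardless of scale; the analytic peak location
    ``1/(sigma*sqrt(2))`` is unaffected.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must have positive extents, got {shape}")
    if not spec.sigma > 0:
        raise ValueError(f"sigma must be > 0, got {spec.sigma}")
    _, _, radius = _freq_grids(shape)
    response = radius * np.exp(-(radius**2) * spec.sigma**2)
    if normalise:
        peak = response.max()
        if peak > 0:
            response = response / peak
    return response


def riesz_responses(even: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the two Riesz transforms to a (bandpassed) real image.

    The frequency-domain transfer functions are ``H1 = u/|u|`` and
    ``H2 = v/|u|`` (zero at DC), applied in quadrature so that the outputs
    are real: a pure cosine along the column axis maps to its sine in odd1.
    ``H1^2 + H2^2 = 1`` away from DC, so the odd pair carries exactly the
    energy of the even response per frequency.
    """
    even = np.asarray(even, dtype=float)
    u, v, radius = _freq_grids(even.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        h1 = np.where(radius > 0, u / radius, 0.0)
        h2 = np.where(radius > 0, v / radius, 0.0)
    spectrum = np.fft.fft2(even)
    odd1 = np.real(np.fft.ifft2(spectrum * (-1j) * h1))
    odd2 = np.real(np.fft.ifft2(spectrum * (-1j) * h2))
    return odd1, odd2


def monogenic_signal(
    image: np.ndarray,
    spec: BandpassSpec,
    *,
    padding: str = "mirror",
) -> MonogenicResponse:
    """Compute the monogenic signal of `image` at one scale.

    The image is mirror-padded by half its size on each side before the
    frequency-domain filtering and cropped afterwards, which suppresses FFT
    wrap-around artefacts at the image border.  ``padding="wrap"`` skips the
    padding (plain periodic filtering).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    rows, cols = image.shape
    if padding == "mirror":
        pr, pc = rows // 2, cols // 2
        work = np.pad(image, ((pr, pr), (pc, pc)), mode="symmetric")
    elif padding == "wrap":
        pr = pc = 0
        work = image
    else:
        raise ValueError(f"unknown padding {padding!r}")

    bandpass = make_bandpass(work.shape, spec)
    even = np.real(np.fft.ifft2(np.fft.fft2(work) * bandpass))
    odd1, odd2 = riesz_responses(even)

    sl = (slice(pr, pr + rows), slice(pc, pc + cols))
    return MonogenicResponse(even=even[sl], odd1=odd1[sl], odd2=odd2[sl], scale=spec)


def phase_maps(resp: MonogenicResponse, *, convention: str = "folded") -> PhaseMaps:
    """Derive amplitude, local phase and local orientation from a response.

    Amplitude is ``sqrt(even^2 + odd1^2 + odd2^2)``.  Under the default
    ``"folded"`` convention phase is ``atan2(|odd|, even)`` in ``[0, pi]``;
    under ``"raw"`` it is ``arctan(even/|odd|)`` in ``(-pi/2, pi/2)``.
    Orientation is ``atan2(odd2, odd1)``, meaningful modulo pi.  Pixels with
    (numerically) zero amplitude get phase pi/2 and orientation 0.
    """
    even = resp.even
    odd_norm = resp.odd_norm
    amplitude = np.sqrt(even**2 + odd_norm**2)

    degenerate = amplitude < _ZERO_AMPLITUDE
    if convention == "folded":
        phase = np.arctan2(odd_norm, even)
    elif convention == "raw":
        with np.errstate(invalid="ignore", divide="ignore"):
            phase = np.arctan(even / odd_norm)
        phase = np.where(odd_norm == 0, np.pi / 2 * np.sign(even), phase)
    else:
        raise ValueError(f"unknown phase convention {convention!r}")
    phase = np.where(degenerate, np.pi / 2, phase)

    orientation = np.arctan2(resp.odd2, resp.odd1)
    orientation = np.where(degenerate, 0.0, orientation)
    return PhaseMaps(amplitude=amplitude, phase=phase, orientation=orientation)
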