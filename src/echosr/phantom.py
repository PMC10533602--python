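"""Synthetic speckle phantoms: B-mode-like images and videos.

Real B-mode texture is dominated by speckle — the interference pattern of
many sub-resolution scatterers.  The generator emulates it at the image
grid level: a complex circular-Gaussian scatterer field (the fully
developed speckle limit of many scatterers per cell), amplitude-scaled by
a per-region echogenicity map with smooth elliptical inclusions, is
convolved with a separable point-spread function (lateral Gaussian; axial
Gaussian modulated by a carrier mimicking the pulse oscillation).  The
envelope (modulus) is then log-compressed over a fixed dynamic range and
normalised to [0, 1], with an optional mean-brightness shift.

The envelope of the uniform field is pointwise Rayleigh-distributed, the
standard fully-developed-speckle statistic.  A lateral PSF width of a
pixel or more gives speckle a lateral correlation length above one line
spacing — the regime where interpolating decimated beamlines is
meaningful, mirroring lateral resolution being lower than axial in real
scanners.

Videos keep the scatterer field frozen and translate the inclusions, so a
feature moves across frames while the speckle texture stays coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import convolve1d

from .image import USImage

__all__ = ["Inclusion", "PhantomSpec", "envelope_field", "generate_phantom",
           "generate_dataset", "generate_video"]


@dataclass(frozen=True)
class Inclusion:
    """Elliptical region with its own echogenicity.

    ``centre`` and ``axes`` are in pixels, (lateral, depth) order;
    ``echogenicity`` multiplies the background scattering amplitude
    (> 1 bright, < 1 dark).
    """

    centre: Tuple[float, float]
    axes: Tuple[float, float]
    echogenicity: float = 2.0


@dataclass(frozen=True)
class SpecularInterface:
    """Bright curved band mimicking a coherent tissue interface.

    Specular reflectors (fascia, organ capsules, vessel walls) return a
    coherent echo that stays axially sharp — it is set by the pulse, not
    by the diffuse-scattering beam profile — so the band is added to the
    complex field *after* the PSF convolution of the diffuse speckle.
    The band sits at depth ``depth_centre`` and undulates across lines as
    a sine with ``depth_excursion`` amplitude and ``lateral_wavelength``
    period; ``amplitude`` is relative to the background scattering level
    and ``axial_sigma`` is the (pulse-limited) band half-width in pixels.
    Where the sloped band crosses a fixed depth, intensity varies sharply
    from line to line — the structure lateral interpolation blurs most.
    """

    depth_centre: float
    amplitude: float = 4.0
    axial_sigma: float = 1.0
    lateral_wavelength: float = 48.0
    depth_excursion: float = 4.0
    lateral_phase: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic B-mode image."""

    L: int = 64
    D: int = 64
    scatterer_density: float = 1.0  # expected scatterers per pixel (amplitude variance)
    psf_lateral_sigma: float = 4.0  # pixels; wide beam: lateral res << axial res
    psf_axial_sigma: float = 0.8  # pixels
    axial_carrier_period: float = 4.0  # pixels
    inclusions: Tuple[Inclusion, ...] = ()
    interfaces: Tuple[SpecularInterface, ...] = ()
    log_compression_db: float = 50.0
    brightness_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 16 or self.D < 16:
            raise ValueError(f"dimensions must be >= 16, got {self.L} x {self.D}")
        if self.scatterer_density <= 0:
            raise ValueError("scatterer_density must be positive")
        if self.log_compression_db <= 0:
            raise ValueError("dynamic range must be positive")
        for inc in self.inclusions:
            cl, cd = inc.centre
            al, ad = inc.axes
            if not (0 <= cl - al and cl + al <= self.L and 0 <= cd - ad and cd + ad <= self.D):
                raise ValueError(f"inclusion {inc} extends outside the {self.L} x {self.D} image")
        for itf in self.interfaces:
            span = itf.depth_excursion
            if not 0 <= itf.depth_centre - span <= itf.depth_centre + span <= self.D:
                raise ValueError(f"interface {itf} extends outside depth range 0..{self.D}")


def _echogenicity_map(spec: PhantomSpec, shift: Tuple[float, float] = (0.0, 0.0)
                      ) -> np.ndarray:
    """Background-1 map with tapered elliptical inclusions, optionally shifted."""
    ll, dd = np.meshgrid(np.arange(spec.L), np.arange(spec.D), indexing="ij")
    emap = np.ones((spec.L, spec.D))
    taper = 1.0  # 1-pixel smooth edge, mimicking acoustic interface blur
    for inc in spec.inclusions:
        cl = inc.centre[0] + shift[0]
        cd = inc.centre[1] + shift[1]
        r = np.sqrt(((ll - cl) / inc.axes[0]) ** 2 + ((dd - cd) / inc.axes[1]) ** 2)
        # normalised radial distance -> weight 1 inside, 0 outside, smooth edge
        edge_px = (r - 1.0) * min(inc.axes)  # approx. distance to boundary in px
        w = np.clip(0.5 - edge_px / taper, 0.0, 1.0)
        emap = emap * (1.0 - w) + inc.echogenicity * w
    return emap


def _psf_kernels(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    def gauss(sigma: float) -> np.ndarray:
        half = max(1, int(np.ceil(3.0 * sigma)))
        t = np.arange(-half, half + 1)
        k = np.exp(-0.5 * (t / sigma) ** 2)
        return k / k.sum()

    lat = gauss(spec.psf_lateral_sigma)
    ax = gauss(spec.psf_axial_sigma)
    half = (ax.size - 1) // 2
    t = np.arange(-half, half + 1)
    ax = ax * np.cos(2.0 * np.pi * t / spec.axial_carrier_period)
    return lat, ax


def envelope_field(spec: PhantomSpec, shift: Tuple[float, float] = (0.0, 0.0),
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Pre-compression envelope: |PSF * (echogenicity x complex Gaussian)|.

    Exposed separately so speckle statistics (pointwise Rayleigh for a
    uniform spec) can be checked before log compression.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    amp = np.sqrt(spec.scatterer_density / 2.0)
    fld = amp * (rng.standard_normal((spec.L, spec.D))
                 + 1j * rng.standard_normal((spec.L, spec.D)))
    fld *= _echogenicity_map(spec, shift)
    lat, ax = _psf_kernels(spec)
    for kern, axis in ((lat, 0), (ax, 1)):
        fld = (convolve1d(fld.real, kern, axis=axis, mode="reflect")
               + 1j * convolve1d(fld.imag, kern, axis=axis, mode="reflect"))
    # specular interfaces are coherent reflectors: axially sharp, added
    # after the diffuse-scattering PSF (their width is pulse-limited)
    if spec.interfaces:
        ll = np.arange(spec.L)[:, None]
        dd = np.arange(spec.D)[None, :]
        for itf in spec.interfaces:
            d0 = (itf.depth_centre + shift[1]
                  + itf.depth_excursion * np.sin(
                      2.0 * np.pi * (ll - shift[0]) / itf.lateral_wavelength
                      + itf.lateral_phase))
            band = np.exp(-0.5 * ((dd - d0) / itf.axial_sigma) ** 2)
            carrier = np.exp(2j * np.pi * (dd - d0) / spec.axial_carrier_period)
            fld = fld + itf.amplitude * np.sqrt(spec.scatterer_density) * band * carrier
    return np.abs(fld)


def _compress(env: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Log compression: map [max/10^(dB/20), max] -> [0, 1], clip below."""
    emax = env.max()
    db = spec.log_compression_db
    with np.errstate(divide="ignore"):
        img = (20.0 * np.log10(env / emax) + db) / db
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> USImage:
    """Generate one synthetic B-mode image; deterministic per spec.seed."""
    env = envelope_field(spec)
    img = _compress(env, spec)
    img = np.clip(img + spec.brightness_offset, 0.0, 1.0)
    return USImage(pixels=img, value_range=(0.0, 1.0), district_tag="synthetic")


def _default_spec_sampler(rng: np.random.Generator, base: PhantomSpec) -> PhantomSpec:
    """Randomise anatomy (inclusions + interfaces) and brightness."""
    n_inc = int(rng.integers(1, 4))
    incs = []
    for _ in range(n_inc):
        al = rng.uniform(0.08, 0.2) * base.L
        ad = rng.uniform(0.08, 0.2) * base.D
        cl = rng.uniform(al, base.L - al)
        cd = rng.uniform(ad, base.D - ad)
        ech = rng.uniform(0.2, 3.0)
        incs.append(Inclusion(centre=(cl, cd), axes=(al, ad), echogenicity=ech))
    n_itf = int(rng.integers(1, 3))
    itfs = []
    for _ in range(n_itf):
        exc = rng.uniform(0.04, 0.1) * base.D
        itfs.append(SpecularInterface(
            depth_centre=rng.uniform(0.15 * base.D + exc, 0.85 * base.D - exc),
            amplitude=rng.uniform(2.0, 5.0),
            axial_sigma=rng.uniform(0.8, 1.5),
            lateral_wavelength=rng.uniform(0.5, 2.0) * base.L,
            depth_excursion=exc,
            lateral_phase=rng.uniform(0.0, 2.0 * np.pi),
        ))
    offset = rng.uniform(-0.08, 0.08)
    return replace(base, inclusions=tuple(incs), interfaces=tuple(itfs),
                   brightness_offset=offset)


def generate_dataset(
    n: int,
    spec_sampler: Callable[[np.random.Generator, PhantomSpec], PhantomSpec] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> List[USImage]:
    """Generate ``n`` phantoms with randomised anatomy and brightness.

    Each image draws its geometry and its scatterer noise from a disjoint
    child seed of ``seed``, so image i is unchanged by anything about
    image j (seed isolation) and splits taken from one call are disjoint
    by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    if spec_sampler is None:
        spec_sampler = _default_spec_sampler
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for child in children:
        sub = np.random.default_rng(child)
        img_seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        spec = replace(spec_sampler(sub, base_spec), seed=img_seed)
        out.append(generate_phantom(spec))
    return out


def generate_video(
    spec: PhantomSpec,
    T: int,
    motion: Tuple[float, float] | Sequence[Tuple[float, float]],
) -> List[USImage]:
    """Generate ``T`` frames with fixed speckle and moving inclusions.

    ``motion`` is a constant per-frame displacement (lateral, depth) in
    pixels, or a length-T sequence of cumulative displacements (frame 0's
    entry is usually (0, 0)).  Raises if the motion pushes an inclusion
    out of frame.  ``T == 1`` degenerates to ``generate_phantom``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if T == 1:
        return [generate_phantom(spec)]
    motion = np.asarray(motion, dtype=float)
    if motion.ndim == 1:
        motion = np.outer(np.arange(T), motion)
    if motion.shape != (T, 2):
        raise ValueError(f"motion must be (2,) or (T, 2), got {motion.shape}")

    for t in range(T):
        for inc in spec.inclusions:
            cl = inc.centre[0] + motion[t, 0]
            cd = inc.centre[1] + motion[t, 1]
            if not (inc.axes[0] <= cl <= spec.L - inc.axes[0]
                    and inc.axes[1] <= cd <= spec.D - inc.axes[1]):
                raise ValueError(f"motion pushes inclusion out of frame at t={t}")

    frames = []
    for t in range(T):
        rng = np.random.default_rng(spec.seed)  # same noise draw every frame
        env = envelope_field(spec, shift=tuple(motion[t]), rng=rng)
        img = np.clip(_compress(env, spec) + spec.brightness_offset, 0.0, 1.0)
        frames.append(USImage(pixels=img, value_range=(0.0, 1.0),
                              district_tag="synthetic-video"))
    return frames
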