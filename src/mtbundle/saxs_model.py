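"""Small-angle X-ray scattering model for bundles of parallel hollow filaments.

A microtubule is modelled as a long hollow cylinder; a bundle is a small set of
parallel rods whose centres sit on a 2D cross-sectional lattice (hexagonal with
centre-to-centre spacing ``L_h``, or rectangular with constants ``L_a <= L_b``).
For rods much longer than 1/q the orientationally averaged intensity factorises
into the long-rod factor 1/q times the in-plane (cross-sectional) average

    I(q) = scale * exp(-q^2 sigma_d^2) / q * < | sum_j F_j(q, psi) e^{i q r_j . u(psi)} |^2 >_psi

where ``F_j`` is the annular cross-section amplitude, ``r_j`` the rod centre,
``u(psi)`` the in-plane unit vector and ``sigma_d`` a Debye-Waller lattice
disorder parameter.  For identical circular rods the azimuthal average has the
closed form ``|F(q)|^2 * sum_jk J0(q d_jk)`` which is used as a fast path.

Units: lengths nm, q in nm^-1 (A^-1 input can be converted with
:func:`a_inv_to_nm_inv`).  A Bragg peak at q corresponds to d = 2*pi/q.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0, j1

#: Instrument q window of the measurements this model emulates (nm^-1).
Q_RANGE_NM = (0.075, 2.185)

#: Silver behenate d(001) spacing used for detector calibration (nm).
AGBH_D_NM = 5.8376


def q_to_d(q: float) -> float:
    """Real-space spacing d = 2*pi/q (inverse units of q)."""
    return 2.0 * np.pi / q


def d_to_q(d: float) -> float:
    """Scattering vector q = 2*pi/d."""
    return 2.0 * np.pi / d


def a_inv_to_nm_inv(q_angstrom_inv):
    """Convert q from A^-1 to nm^-1 (multiply by 10)."""
    return 10.0 * np.asarray(q_angstrom_inv)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSection:
    """Annular (hollow) rod cross-section, circular or elliptical.

    Elliptical convention: ``a`` is the semi-axis along the lattice y
    direction (the ``L_b`` axis for rectangular packing), ``b`` the semi-axis
    along x (the ``L_a`` axis); deformed microtubules in tight rectangular
    packing have their major axis along the larger lattice constant.
    ``contrast`` is the wall scattering density relative to solvent.
    """

    shape: str = "circular"
    r_out: float | None = 12.5
    r_in: float | None = 8.4
    a_out: float | None = None
    b_out: float | None = None
    a_in: float | None = None
    b_in: float | None = None
    contrast: float = 1.0

    def __post_init__(self):
        if self.shape not in ("circular", "elliptical"):
            raise ValueError(f"unknown cross-section shape {self.shape!r}")
        if self.shape == "circular":
            if self.r_out is None or self.r_in is None:
                raise ValueError("circular cross-section requires r_out and r_in")
            if not (0.0 <= self.r_in < self.r_out):
                raise ValueError("need 0 <= r_in < r_out")
        else:
            for name in ("a_out", "b_out", "a_in", "b_in"):
                v = getattr(self, name)
                if v is None or v < 0:
                    raise ValueError(f"elliptical cross-section requires {name} >= 0")
            if not (self.a_in < self.a_out and self.b_in < self.b_out):
                raise ValueError("inner ellipse must lie strictly inside outer")
        if self.wall_area() <= 0:
            raise ValueError("degenerate cross-section: zero wall area")

    def semi_axes(self):
        """Return (x_out, y_out, x_in, y_in) semi-axes in lattice coordinates."""
        if self.shape == "circular":
            return self.r_out, self.r_out, self.r_in, self.r_in
        return self.b_out, self.a_out, self.b_in, self.a_in

    def wall_area(self) -> float:
        xo, yo, xi, yi = self.semi_axes()
        return math.pi * (xo * yo - xi * yi)

    @classmethod
    def microtubule(cls, contrast: float = 1.0) -> "CrossSection":
        """Default undeformed microtubule: r_out 12.5 nm, r_in 8.4 nm."""
        return cls(shape="circular", r_out=12.5, r_in=8.4, contrast=contrast)

    @classmethod
    def deformed_microtubule(cls, L_a: float = 20.2, L_b: float = 27.2,
                             contrast: float = 1.0) -> "CrossSection":
        """Elliptical cross-section for rods touching along both axes of a
        rectangular lattice: outer semi-axes (L_b/2 along y, L_a/2 along x);
        inner ellipse similar to the outer, scaled so the wall area equals
        that of the undeformed circular microtubule.  Lattices too tight to
        hold that wall area degrade gracefully to a filled ellipse (the wall
        thins to fill the whole cross-section), keeping the model defined
        everywhere a fitter may evaluate it."""
        ref = cls.microtubule()
        a_out, b_out = L_b / 2.0, L_a / 2.0
        inner_prod = max(a_out * b_out - (ref.r_out ** 2 - ref.r_in ** 2), 0.0)
        t = math.sqrt(inner_prod / (a_out * b_out))
        return cls(shape="elliptical", r_out=None, r_in=None,
                   a_out=a_out, b_out=b_out, a_in=t * a_out, b_in=t * b_out,
                   contrast=contrast)


@dataclass(frozen=True)
class BundleLatticeModel:
    """Cross-sectional packing model of a filament bundle.

    lattice "none" is a single free rod; "hexagonal" places ``n_rods`` on a
    triangular lattice (centre + shells) at spacing ``L_h``; "rectangular"
    places them on an ``L_a x L_b`` grid (convention L_a <= L_b).
    ``disorder_sigma`` (nm) enters as a Debye-Waller factor exp(-q^2 sigma^2).
    ``mixture_weight`` is the hexagonal-phase fraction when two phases coexist.
    """

    lattice: str = "hexagonal"
    L_h: float = 45.8
    L_a: float = 20.2
    L_b: float = 27.2
    n_rods: int = 7
    disorder_sigma: float = 1.0
    cross_section: CrossSection = field(default_factory=CrossSection.microtubule)
    mixture_weight: float = 1.0

    def __post_init__(self):
        if self.lattice not in ("none", "hexagonal", "rectangular"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.n_rods < 1:
            raise ValueError("n_rods >= 1 required")
        if self.lattice == "none" and self.n_rods != 1:
            raise ValueError("lattice 'none' implies a single rod")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight in [0, 1]")
        if self.disorder_sigma < 0:
            raise ValueError("disorder_sigma >= 0")
        if self.lattice == "rectangular" and not (0 < self.L_a <= self.L_b):
            raise ValueError("rectangular convention requires 0 < L_a <= L_b")


@dataclass
class ScatteringCurve:
    """1D scattering curve I(q) with optional per-point uncertainty."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be >= 0")
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma/q shape mismatch")
        if self.q.shape != self.I.shape:
            raise ValueError("q/I shape mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


@dataclass
class DetectorGeometry:
    """Flat 2D detector geometry for radial averaging."""

    wavelength_nm: float = 0.154
    distance_m: float = 3.4
    pixel_mm: float = 0.075
    center_px: tuple[float, float] = (0.0, 0.0)  # (row, col)
    mask: np.ndarray | None = None               # nonzero = excluded
    calibrant_d_nm: float = AGBH_D_NM

    def __post_init__(self):
        if min(self.wavelength_nm, self.distance_m, self.pixel_mm) <= 0:
            raise ValueError("wavelength, distance and pixel size must be > 0")

    def q_of_radius_px(self, r_px):
        """q (nm^-1) at radial distance r (pixels) from the beam centre."""
        theta = np.arctan(np.asarray(r_px) * self.pixel_mm * 1e-3 / self.distance_m)
        return (4.0 * np.pi / self.wavelength_nm) * np.sin(theta / 2.0)

    def radius_px_of_q(self, q):
        """Inverse of :meth:`q_of_radius_px`."""
        theta = 2.0 * np.arcsin(np.asarray(q) * self.wavelength_nm / (4.0 * np.pi))
        return np.tan(theta) * self.distance_m / (self.pixel_mm * 1e-3)

    def calibrant_q(self) -> float:
        """Expected ring position of the calibration standard, q = 2*pi/d."""
        return d_to_q(self.calibrant_d_nm)


# --------------------------------------------------------------------------
# form factor
# --------------------------------------------------------------------------

def _disk_amp(u):
    """2 J1(u)/u with the u -> 0 limit of 1."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-8
    safe = np.where(small, 1.0, u)
    return np.where(small, 1.0 - u * u / 8.0, 2.0 * j1(safe) / safe)


def cross_section_amplitude(cs: CrossSection, q, psi=0.0):
    """In-plane scattering amplitude of an annular cross-section.

    Normalised to 1 at q = 0.  ``psi`` is the in-plane azimuth of the
    scattering vector; the circular case is psi-independent.  Broadcasts
    over ``q`` and ``psi``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q >= 0 required")
    psi = np.asarray(psi, dtype=float)
    xo, yo, xi, yi = cs.semi_axes()
    c2, s2 = np.cos(psi) ** 2, np.sin(psi) ** 2
    r_out = np.sqrt(xo * xo * c2 + yo * yo * s2)
    r_in = np.sqrt(xi * xi * c2 + yi * yi * s2)
    s_out = math.pi * xo * yo
    s_in = math.pi * xi * yi
    amp = (s_out * _disk_amp(q * r_out) - s_in * _disk_amp(q * r_in)) / (s_out - s_in)
    return amp


# --------------------------------------------------------------------------
# lattices
# --------------------------------------------------------------------------

def _rect_grid_shape(n: int) -> tuple[int, int]:
    """Most-square factorisation (na, nb) of n with na <= nb, na along L_a."""
    na = 1
    for d in range(1, int(math.isqrt(n)) + 1):
        if n % d == 0:
            na = d
    return na, n // na


def lattice_positions(model: BundleLatticeModel) -> np.ndarray:
    """Rod centre coordinates (n_rods, 2) in nm for the model's lattice."""
    n = model.n_rods
    if model.lattice == "none":
        return np.zeros((1, 2))
    if model.lattice == "hexagonal":
        L = model.L_h
        a1 = np.array([L, 0.0])
        a2 = np.array([L / 2.0, L * math.sqrt(3) / 2.0])
        m = int(math.ceil(math.sqrt(n))) + 2
        pts = []
        for i in range(-m, m + 1):
            for jj in range(-m, m + 1):
                p = i * a1 + jj * a2
                pts.append((round(float(np.hypot(*p)), 9),
                            round(float(np.arctan2(p[1], p[0])), 9), p))
        pts.sort(key=lambda t: (t[0], t[1]))
        return np.array([p for _, _, p in pts[:n]])
    # rectangular grid, centred
    na, nb = _rect_grid_shape(n)
    xs = (np.arange(na) - (na - 1) / 2.0) * model.L_a
    ys = (np.arange(nb) - (nb - 1) / 2.0) * model.L_b
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


# --------------------------------------------------------------------------
# forward intensity
# --------------------------------------------------------------------------

def structure_average(model: BundleLatticeModel, q, n_psi: int = 720,
                      force_general: bool = False) -> np.ndarray:
    """Azimuthal average < |sum_j F_j e^{i q r_j . u}|^2 >_psi on grid ``q``.

    Uses the closed-form Bessel sum for circular cross-sections and uniform
    azimuthal quadrature (equivalent to trapezoid for the pi-periodic
    integrand) otherwise.
    """
    q = np.asarray(q, dtype=float)
    pos = lattice_positions(model)
    cs = model.cross_section
    if cs.shape == "circular" and not force_general:
        f2 = cross_section_amplitude(cs, q) ** 2
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        dist, counts = np.unique(np.round(d.ravel(), 9), return_counts=True)
        s = np.zeros_like(q)
        for dk, ck in zip(dist, counts):
            s += ck * (np.ones_like(q) if dk == 0 else j0(q * dk))
        return f2 * s
    psi = np.linspace(0.0, np.pi, n_psi, endpoint=False)
    f = cross_section_amplitude(cs, q[:, None], psi[None, :])      # (nq, npsi)
    proj = pos[:, 0][None, :] * np.cos(psi)[:, None] \
        + pos[:, 1][None, :] * np.sin(psi)[:, None]                # (npsi, nrod)
    phase = np.exp(1j * q[:, None, None] * proj[None, :, :])       # (nq, npsi, nrod)
    amp = f * phase.sum(axis=2)
    return np.mean(np.abs(amp) ** 2, axis=1)


def bundle_intensity(model: BundleLatticeModel, q_grid, scale: float = 1.0,
                     n_psi: int = 720, force_general: bool = False,
                     label: str = "") -> ScatteringCurve:
    """Orientationally averaged bundle intensity on ``q_grid`` (nm^-1).

    I(q) = scale * w^2 * exp(-q^2 sigma_d^2)/q * structure_average(q) with
    w = contrast * wall area.  q = 0 entries are excluded with a warning
    (the long-rod 1/q factor diverges there).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        warnings.warn("q <= 0 excluded from the grid (1/q long-rod factor)")
        q = q[q > 0]
    s = structure_average(model, q, n_psi=n_psi, force_general=force_general)
    w = model.cross_section.contrast * model.cross_section.wall_area()
    dw = np.exp(-(q * model.disorder_sigma) ** 2)
    return ScatteringCurve(q=q, I=scale * w * w * dw / q * s, label=label)


def mix_phases(curve_hex: ScatteringCurve, curve_rect: ScatteringCurve,
               w: float) -> ScatteringCurve:
    """Incoherent two-phase mixture I = w*I_hex + (1-w)*I_rect."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w in [0, 1]")
    if curve_hex.q.shape != curve_rect.q.shape or \
            not np.allclose(curve_hex.q, curve_rect.q):
        raise ValueError("phase curves must share one q grid")
    I = w * curve_hex.I + (1.0 - w) * curve_rect.I
    sigma = None
    if curve_hex.sigma is not None and curve_rect.sigma is not None:
        sigma = np.sqrt((w * curve_hex.sigma) ** 2
                        + ((1.0 - w) * curve_rect.sigma) ** 2)
    return ScatteringCurve(q=curve_hex.q.copy(), I=I, sigma=sigma,
                           label=f"mix(w={w:g})")


def subtract_background(sample: ScatteringCurve, background: ScatteringCurve,
                        scale: float = 1.0) -> ScatteringCurve:
    """I_sample - scale * I_background with linear interpolation of the
    background onto the sample grid and quadrature error propagation.
    Negative results are retained."""
    if sample.q[0] < background.q[0] - 1e-12 or sample.q[-1] > background.q[-1] + 1e-12:
        raise ValueError("sample q range extends beyond background support")
    bg_I = np.interp(sample.q, background.q, background.I)
    I = sample.I - scale * bg_I
    sigma = None
    if sample.sigma is not None or background.sigma is not None:
        ss = sample.sigma if sample.sigma is not None else np.zeros_like(sample.q)
        if background.sigma is not None:
            sb = np.interp(sample.q, background.q, background.sigma)
        else:
            sb = np.zeros_like(sample.q)
        sigma = np.sqrt(ss ** 2 + (scale * sb) ** 2)
    return ScatteringCurve(q=sample.q.copy(), I=I, sigma=sigma,
                           label=f"{sample.label}-bg")


def radial_average(image: np.ndarray, geom: DetectorGeometry, n_bins: int,
                   q_range: tuple[float, float] = Q_RANGE_NM) -> ScatteringCurve:
    """Azimuthally average a detector frame into ``n_bins`` equal-width q bins.

    Masked pixels (nonzero in ``geom.mask``) are excluded; empty bins are NaN.
    Per-bin sigma is the standard error sd/sqrt(n).
    """
    image = np.asarray(image, dtype=float)
    if geom.mask is not None and geom.mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    rows, cols = np.indices(image.shape)
    r = np.hypot(rows - geom.center_px[0], cols - geom.center_px[1])
    qpix = geom.q_of_radius_px(r)
    keep = np.ones(image.shape, dtype=bool)
    if geom.mask is not None:
        keep &= geom.mask == 0
    lo, hi = q_range
    keep &= (qpix >= lo) & (qpix < hi)
    idx = np.floor((qpix[keep] - lo) / (hi - lo) * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    vals = image[keep]
    n = np.bincount(idx, minlength=n_bins).astype(float)
    tot = np.bincount(idx, weights=vals, minlength=n_bins)
    tot2 = np.bincount(idx, weights=vals ** 2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = tot / n
        var = np.maximum(tot2 / n - mean ** 2, 0.0)
        sem = np.sqrt(var / np.maximum(n - 1, 1))
    mean[n == 0] = np.nan
    sem[n == 0] = 0.0
    centers = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    curve = ScatteringCurve(q=centers, I=mean, sigma=sem, label="radial_average")
    curve.counts = n  # per-bin pixel counts, 0 flags an empty bin
    return curve
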