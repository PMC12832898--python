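"""Real even-order spherical-harmonic basis for antipodally symmetric fODFs.

A fiber orientation distribution function (fODF) is a non-negative, antipodally
symmetric function on the unit sphere, so only even-order harmonics carry
signal.  At maximum order ``lmax`` the representation has
``(lmax + 1)(lmax + 2) / 2`` real coefficients — 45 at the standard lmax=8.

Convention (pinned; matches MRtrix-style fODF files): orthonormal real
symmetric basis with flat index ``j(l, m) = l(l+1)/2 + m`` over even ``l``,
``m in [-l, l]``; ``m < 0`` maps to ``sqrt(2) * Im(Y_l^|m|)``, ``m = 0`` to
``Y_l^0`` and ``m > 0`` to ``sqrt(2) * Re(Y_l^m)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y


# --------------------------------------------------------------------------- #
# basis bookkeeping
# --------------------------------------------------------------------------- #

def count_coefficients(lmax: int) -> int:
    """Number of real even-order SH coefficients up to ``lmax``.

    Counts the (l, m) pairs with even ``l <= lmax`` and ``|m| <= l``:
    ``(lmax + 1)(lmax + 2) / 2``.  lmax=8 gives the 45 coefficients used per
    voxel throughout the pipeline.
    """
    if not isinstance(lmax, (int, np.integer)):
        raise ValueError(f"lmax must be an integer, got {lmax!r}")
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def sh_index(l: int, m: int) -> int:
    """Flat index j(l, m) = l(l+1)/2 + m for even ``l``, ``m in [-l, l]``."""
    if l < 0 or l % 2 != 0 or abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m})")
    return l * (l + 1) // 2 + m


def sh_degrees(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in flat-index order."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


@dataclass(frozen=True)
class SHBasisSpec:
    """Real even-order orthonormal SH basis up to ``lmax``."""

    lmax: int = 8

    def __post_init__(self) -> None:
        count_coefficients(self.lmax)  # validates

    @property
    def n_coeffs(self) -> int:
        return count_coefficients(self.lmax)

    @property
    def degrees(self) -> list[tuple[int, int]]:
        return sh_degrees(self.lmax)


# --------------------------------------------------------------------------- #
# sphere grids
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SphereGrid:
    """Unit directions on the sphere, optionally with quadrature weights.

    Antipodally non-duplicated hemisphere sampling is allowed because even-order
    SH functions are symmetric.  ``weights`` integrate symmetric functions over
    the full sphere (they sum to 4*pi).
    """

    directions: np.ndarray  # (N, 3)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] == 0:
            raise ValueError("directions must be a non-empty (N, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("directions must be unit vectors (tol 1e-10)")
        object.__setattr__(self, "directions", d)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (d.shape[0],):
                raise ValueError("weights must be a length-N vector")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.directions.shape[0]

    @staticmethod
    def fibonacci_hemisphere(n: int = 724) -> "SphereGrid":
        """Deterministic Fibonacci spiral on the upper hemisphere (z >= 0).

        Equal weights 4*pi/N: each point stands for an antipodal pair of a
        2N-point full-sphere spiral.  Good for least-squares projection and
        peak search; not an exact quadrature.
        """
        i = np.arange(n)
        # z spaced uniformly in (0, 1]; golden-angle azimuth
        z = (i + 0.5) / n
        phi = np.pi * (1.0 + np.sqrt(5.0)) * i
        r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = np.full(n, 4.0 * np.pi / n)
        return SphereGrid(dirs, w)

    @staticmethod
    def gauss_legendre(n_theta: int = 50, n_phi: int = 100) -> "SphereGrid":
        """Gauss-Legendre x uniform-azimuth product grid with exact weights.

        Integrates spherical polynomials of degree <= 2*n_theta - 1 in the
        polar part exactly and trigonometric polynomials of azimuthal order
        < n_phi exactly, so the SH Gram matrix is identity to machine
        precision whenever n_theta >= lmax + 1 and n_phi >= 2*lmax + 1.
        """
        x, wx = np.polynomial.legendre.leggauss(n_theta)  # nodes in cos(theta)
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        ct, ph = np.meshgrid(x, phi, indexing="ij")
        st = np.sqrt(1.0 - ct**2)
        dirs = np.stack(
            [st * np.cos(ph), st * np.sin(ph), ct], axis=-1
        ).reshape(-1, 3)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = (np.repeat(wx, n_phi) * (2.0 * np.pi / n_phi))
        return SphereGrid(dirs, w)


# --------------------------------------------------------------------------- #
# basis evaluation / projection
# --------------------------------------------------------------------------- #

def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def sh_basis_matrix(grid: SphereGrid, spec: SHBasisSpec) -> np.ndarray:
    """Basis matrix B with B[i, j] = Y_j(direction_i), shape (N, n_coeffs).

    Even orders only, so rows for a direction and its antipode coincide.
    """
    theta, phi = _to_angles(grid.directions)
    cols = []
    for l, m in spec.degrees:
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * y.real)
        else:
            cols.append(np.sqrt(2.0) * y.imag)
    return np.stack(cols, axis=1)


def project_to_sh(
    samples: np.ndarray, spec: SHBasisSpec, grid: SphereGrid
) -> np.ndarray:
    """Least-squares SH coefficients of function samples on ``grid``.

    Weighted least squares when the grid carries quadrature weights; exact
    (to round-off) for band-limited inputs whenever the basis matrix has full
    column rank.  ``samples`` may be (N,) or (N, K) for K functions at once.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] != len(grid):
        raise ValueError("samples must have one value per grid direction")
    if len(grid) < spec.n_coeffs:
        raise ValueError(
            f"need at least {spec.n_coeffs} directions, got {len(grid)}"
        )
    B = sh_basis_matrix(grid, spec)
    if grid.weights is not None:
        sw = np.sqrt(grid.weights)
        B = B * sw[:, None]
        samples = samples * (sw if samples.ndim == 1 else sw[:, None])
    coeffs, _, rank, _ = np.linalg.lstsq(B, samples, rcond=None)
    if rank < spec.n_coeffs:
        raise np.linalg.LinAlgError(
            f"basis matrix is rank deficient (rank {rank} < {spec.n_coeffs})"
        )
    return coeffs


def evaluate_sh(
    coeffs: np.ndarray, directions: np.ndarray, spec: SHBasisSpec
) -> np.ndarray:
    """Evaluate an SH coefficient vector at unit ``directions``.

    Adjoint of projection: linear in ``coeffs`` and antipodally symmetric.
    ``coeffs`` may be (n_coeffs,) or (..., n_coeffs) batched.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != spec.n_coeffs:
        raise ValueError(
            f"expected {spec.n_coeffs} coefficients, got {coeffs.shape[-1]}"
        )
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    B = sh_basis_matrix(SphereGrid(d / np.linalg.norm(d, axis=1, keepdims=True)), spec)
    return coeffs @ B.T


# --------------------------------------------------------------------------- #
# peak extraction
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PeakSet:
    """Up to K fODF peak directions with non-negative amplitudes.

    Unit vectors sorted by descending amplitude; antipodal duplicates are
    collapsed (a peak and its negation are the same fiber orientation).
    """

    directions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )  # (K, 3)
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        a = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if d.shape[0] != a.shape[0]:
            raise ValueError("directions and amplitudes must pair up")
        if a.size and (np.any(a < 0) or np.any(np.diff(a) > 1e-12)):
            raise ValueError("amplitudes must be non-negative and non-increasing")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return self.amplitudes.size


_PEAK_GRID: dict[int, SphereGrid] = {}


def _peak_grid(n: int = 724) -> SphereGrid:
    if n not in _PEAK_GRID:
        _PEAK_GRID[n] = SphereGrid.fibonacci_hemisphere(n)
    return _PEAK_GRID[n]


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _refine_peak(
    coeffs: np.ndarray, spec: SHBasisSpec, u: np.ndarray, n_steps: int = 10
) -> tuple[np.ndarray, float]:
    """Projected gradient ascent on the sphere from a grid maximum.

    Finite-difference tangent gradient with a small backtracking line search;
    the fODF is a degree-lmax polynomial, so a few steps suffice to undo the
    ~5 degree quantization of the search grid.
    """
    eps = 1e-4
    step = 0.05  # radians
    val = float(evaluate_sh(coeffs, u[None, :], spec)[0])
    for _ in range(n_steps):
        e1, e2 = _tangent_basis(u)
        probe = np.stack([u + eps * e1, u - eps * e1, u + eps * e2, u - eps * e2])
        probe /= np.linalg.norm(probe, axis=1, keepdims=True)
        f = evaluate_sh(coeffs, probe, spec)
        g = ((f[0] - f[1]) * e1 + (f[2] - f[3]) * e2) / (2 * eps)
        gn = np.linalg.norm(g)
        if gn < 1e-12:
            break
        improved = False
        while step > 1e-5:
            cand = u + step * g / gn
            cand /= np.linalg.norm(cand)
            fv = float(evaluate_sh(coeffs, cand[None, :], spec)[0])
            if fv > val:
                u, val, improved = cand, fv, True
                break
            step *= 0.5
        if not improved:
            break
    return u, val


def extract_peaks(
    coeffs: np.ndarray,
    spec: SHBasisSpec,
    grid: SphereGrid | None = None,
    max_peaks: int = 3,
    rel_threshold: float = 0.1,
    min_separation_deg: float = 10.0,
) -> PeakSet:
    """Dominant fODF orientations from an SH coefficient vector.

    Local maxima over a hemisphere grid, refined by projected gradient
    ascent, merged when closer than ``min_separation_deg`` (antipodal pairs
    collapsed), thresholded at ``rel_threshold`` times the global maximum,
    and truncated to the ``max_peaks`` strongest.  An fODF with no positive
    values yields an empty :class:`PeakSet`.
    """
    if not 0.0 <= rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in [0, 1)")
    if grid is None:
        grid = _peak_grid()
    dirs = grid.directions
    vals = evaluate_sh(coeffs, dirs, spec)
    if np.all(vals <= 0):
        return PeakSet()
    # a (near-)constant fODF has no local structure, hence no peaks
    if vals.max() - vals.min() <= 1e-8 * max(abs(vals.max()), 1.0):
        return PeakSet()

    # local maxima: strictly the best within an angular neighbourhood
    dots = np.abs(dirs @ dirs.T)
    neighborhood = dots >= np.cos(np.deg2rad(12.0))
    is_max = np.array(
        [vals[i] >= vals[neighborhood[i]].max() for i in range(len(dirs))]
    )
    cand_idx = np.where(is_max & (vals > 0))[0]
    cand_idx = cand_idx[np.argsort(vals[cand_idx])[::-1]][: 4 * max_peaks]

    refined: list[tuple[np.ndarray, float]] = []
    for i in cand_idx:
        u, v = _refine_peak(coeffs, spec, dirs[i].copy())
        if v <= 0:
            continue
        dup = any(
            abs(float(u @ ru)) >= np.cos(np.deg2rad(min_separation_deg))
            for ru, _ in refined
        )
        if not dup:
            refined.append((u, v))

    if not refined:
        return PeakSet()
    refined.sort(key=lambda t: -t[1])
    vmax = refined[0][1]
    kept = [(u, v) for u, v in refined if v >= rel_threshold * vmax][:max_peaks]
    return PeakSet(
        np.stack([u for u, _ in kept]), np.array([v for _, v in kept])
    )


def fodf_to_peak_image(volume: np.ndarray, spec: SHBasisSpec, K: int = 3,
                       rel_threshold: float = 0.1) -> np.ndarray:
    """Convert a 4D SH fODF volume into a peak-vector image (X, Y, Z, 3K).

    The representation peak-based segmenters consume: per voxel the K
    strongest peak directions scaled by amplitude, zero-padded, channel
    layout (x1, y1, z1, x2, ...).  K=3 gives the standard 9-channel input.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] != spec.n_coeffs:
        raise ValueError(
            f"expected (X, Y, Z, {spec.n_coeffs}) volume, got {vol.shape}"
        )
    out = np.zeros(vol.shape[:3] + (3 * K,), dtype=np.float32)
    grid = _peak_grid()
    # voxels with identical coefficients (e.g. background) share peaks
    flat = vol.reshape(-1, spec.n_coeffs)
    cache: dict[bytes, np.ndarray] = {}
    out_flat = out.reshape(-1, 3 * K)
    for i, c in enumerate(flat):
        key = c.tobytes()
        if key not in cache:
            ps = extract_peaks(c, spec, grid, max_peaks=K,
                               rel_threshold=rel_threshold)
            vec = np.zeros(3 * K, dtype=np.float32)
            for k in range(len(ps)):
                vec[3 * k: 3 * k + 3] = ps.amplitudes[k] * ps.directions[k]
            cache[key] = vec
        out_flat[i] = cache[key]
    return out
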