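"""Seeded synthetic fODF phantoms with crossing-fiber and bottleneck geometry.

The generator reproduces, at desk scale, the two ambiguity structures that make
voxel-wise tract segmentation hard: crossing fibers (two differently oriented
tracts sharing a voxel) and bottlenecks (distinct tracts merging along one
shared orientation for a corridor before diverging, so local orientation alone
cannot assign the voxel).  Tracts are tubes around polylines; each contributes
an axially symmetric Watson-kernel fODF lobe along the local tube direction,
and overlapping tracts mix lobes by volume fraction on top of an isotropic
background.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import hyp1f1

from sphtract.sh import (
    SHBasisSpec,
    SphereGrid,
    project_to_sh,
)


@dataclass(frozen=True)
class FiberLobe:
    """One axially symmetric fiber population inside a voxel."""

    direction: np.ndarray  # unit 3-vector
    kappa: float  # Watson concentration, > 0
    volume_fraction: float = 1.0  # in (0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("lobe direction must be a unit vector")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in (0, 1]")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class TractGeometry:
    """A tract realized as a tube of given radius around a 3D polyline."""

    name: str
    path: np.ndarray  # (P, 3) voxel coordinates
    radius: float
    lobe_kappa: float = 20.0

    def __post_init__(self) -> None:
        p = np.asarray(self.path, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("path must be an (P>=2, 3) array of points")
        if self.radius < 1:
            raise ValueError("radius must be >= 1 voxel")
        if self.lobe_kappa <= 0:
            raise ValueError("lobe_kappa must be positive")
        object.__setattr__(self, "path", p)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic fODF dataset.

    ``volume_side`` must be at least 16 and, for downstream 2D segmentation,
    divisible by 2**(depth-1) of the network.  ``noise_sigma`` is the standard
    deviation of i.i.d. Gaussian noise added to every SH coefficient;
    ``background_iso_amplitude`` is the constant fODF value of the isotropic
    background present in every voxel.
    """

    volume_side: int = 48
    tracts: tuple[TractGeometry, ...] = ()
    scenario: str = "crossing"
    noise_sigma: float = 0.0
    background_iso_amplitude: float = 0.02
    lmax: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_side < 16:
            raise ValueError("volume_side must be >= 16")
        if self.scenario not in ("crossing", "bottleneck", "single"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background_iso_amplitude < 0:
            raise ValueError("background_iso_amplitude must be >= 0")
        object.__setattr__(self, "tracts", tuple(self.tracts))
        for t in self.tracts:
            if np.any(t.path < 0) or np.any(t.path > self.volume_side - 1):
                raise ValueError(
                    f"tract {t.name!r} path leaves the volume"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tracts"] = [
            {
                "name": t.name,
                "path": np.asarray(t.path).tolist(),
                "radius": t.radius,
                "lobe_kappa": t.lobe_kappa,
            }
            for t in self.tracts
        ]
        return d

    @staticmethod
    def from_dict(d: dict) -> "PhantomSpec":
        tracts = tuple(
            TractGeometry(
                name=t["name"],
                path=np.asarray(t["path"], dtype=float),
                radius=t["radius"],
                lobe_kappa=t.get("lobe_kappa", 20.0),
            )
            for t in d.get("tracts", [])
        )
        return PhantomSpec(
            volume_side=d.get("volume_side", 48),
            tracts=tracts,
            scenario=d.get("scenario", "crossing"),
            noise_sigma=d.get("noise_sigma", 0.0),
            background_iso_amplitude=d.get("background_iso_amplitude", 0.02),
            lmax=d.get("lmax", 8),
            seed=d.get("seed", 0),
        )


@dataclass
class PhantomDataset:
    """Generated fODF volume plus one binary mask per tract."""

    fodf: np.ndarray  # (S, S, S, n_coeffs) float32
    masks: dict[str, np.ndarray]  # name -> (S, S, S) uint8
    spec: PhantomSpec

    @property
    def overlap(self) -> np.ndarray:
        """Voxels covered by two or more tracts (allowed, and flagged here)."""
        stack = np.stack(list(self.masks.values()), axis=0)
        return (stack.sum(axis=0) >= 2).astype(np.uint8)


# --------------------------------------------------------------------------- #
# single-fiber kernel
# --------------------------------------------------------------------------- #

_LOBE_GRID: SphereGrid | None = None


def _lobe_grid() -> SphereGrid:
    global _LOBE_GRID
    if _LOBE_GRID is None:
        _LOBE_GRID = SphereGrid.fibonacci_hemisphere(724)
    return _LOBE_GRID


def watson_pdf(directions: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Watson density C(kappa) * exp(kappa * (u . mu)^2) on the sphere.

    Antipodally and axially symmetric; normalizes to 1 over the full sphere
    with C(kappa) = 1 / (4 pi M(1/2, 3/2, kappa)), M the confluent
    hypergeometric function.
    """
    c = 1.0 / (4.0 * np.pi * hyp1f1(0.5, 1.5, kappa))
    dots = np.asarray(directions, dtype=float) @ np.asarray(mu, dtype=float)
    return c * np.exp(kappa * dots**2)


def make_single_fiber_lobe(
    direction: np.ndarray, kappa: float, spec: SHBasisSpec
) -> np.ndarray:
    """SH coefficients of a normalized Watson lobe along ``direction``.

    The kernel is sampled on a Fibonacci hemisphere and least-squares
    projected onto the even-order basis, so arbitrary orientations need no
    rotation machinery.  At kappa ~ 20 and lmax = 8 the truncated lobe keeps a
    well-defined peak at +/- direction.
    """
    mu = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(mu)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    grid = _lobe_grid()
    samples = watson_pdf(grid.directions, mu / n, kappa)
    return project_to_sh(samples, spec, grid)


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #

def _segment_distances(points: np.ndarray, path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each point to a polyline and the index of its nearest segment."""
    best = np.full(points.shape[0], np.inf)
    seg_idx = np.zeros(points.shape[0], dtype=int)
    for k in range(path.shape[0] - 1):
        a, b = path[k], path[k + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab)
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < best
        best[closer] = d[closer]
        seg_idx[closer] = k
    return best, seg_idx


def _segment_directions(path: np.ndarray) -> np.ndarray:
    seg = np.diff(path, axis=0)
    norms = np.linalg.norm(seg, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("polyline has a zero-length segment")
    return seg / norms


def default_tracts(scenario: str, S: int, radius: float = 3.0,
                   kappa: float = 20.0) -> tuple[TractGeometry, ...]:
    """Canonical tract geometries for the three built-in scenarios.

    crossing    two orthogonal straight tubes through the volume centre.
    bottleneck  two U-shaped tubes whose middle segments coincide along a
                central corridor (shared orientation, distinct ends).
    single      one straight tube.
    """
    c = (S - 1) / 2.0
    lo, hi = 1.0, float(S - 2)
    if scenario == "crossing":
        return (
            TractGeometry("tract_x", np.array([[lo, c, c], [hi, c, c]]), radius, kappa),
            TractGeometry("tract_y", np.array([[c, lo, c], [c, hi, c]]), radius, kappa),
        )
    if scenario == "bottleneck":
        x0, x1 = S / 3.0, 2.0 * S / 3.0
        corridor_a = np.array([[x0, hi, c], [x0, c, c], [x1, c, c], [x1, hi, c]])
        corridor_b = np.array([[x0, lo, c], [x0, c, c], [x1, c, c], [x1, lo, c]])
        return (
            TractGeometry("tract_a", corridor_a, radius, kappa),
            TractGeometry("tract_b", corridor_b, radius, kappa),
        )
    if scenario == "single":
        return (
            TractGeometry("tract_x", np.array([[lo, c, c], [hi, c, c]]), radius, kappa),
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def bottleneck_corridor_mask(dataset: "PhantomDataset") -> np.ndarray:
    """Voxels where every tract of a bottleneck phantom overlaps away from
    the crossing points — i.e. the shared corridor interior."""
    return dataset.overlap.astype(bool)


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #

def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate the fODF volume and per-tract masks described by ``spec``.

    Per voxel the fODF is the volume-fraction-weighted sum of the Watson
    lobes of all covering tracts (equal fractions when several tracts share
    the voxel) plus the isotropic background; each tract's local lobe
    direction is that of its nearest polyline segment.  In a bottleneck
    corridor both tracts therefore contribute lobes along the corridor axis:
    indistinguishable orientation, distinct masks outside.  Gaussian noise of
    ``spec.noise_sigma`` is then added channel-wise with the spec seed, so
    identical specs give bit-identical outputs.
    """
    tracts = spec.tracts or default_tracts(spec.scenario, spec.volume_side)
    # re-validate paths if defaults were substituted
    for t in tracts:
        if np.any(t.path < 0) or np.any(t.path > spec.volume_side - 1):
            raise ValueError(f"tract {t.name!r} path leaves the volume")

    S = spec.volume_side
    sh_spec = SHBasisSpec(spec.lmax)
    n_coeffs = sh_spec.n_coeffs
    ax = np.arange(S, dtype=float)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)

    masks: dict[str, np.ndarray] = {}
    voxel_dirs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in tracts:
        dist, seg_idx = _segment_distances(pts, t.path)
        inside = dist <= t.radius
        masks[t.name] = inside.reshape(S, S, S).astype(np.uint8)
        voxel_dirs[t.name] = (inside, seg_idx)

    fodf = np.zeros((S * S * S, n_coeffs), dtype=np.float64)
    # isotropic background everywhere: constant value b has only the j=0
    # coefficient, equal to 2 b sqrt(pi)
    fodf[:, 0] = 2.0 * spec.background_iso_amplitude * np.sqrt(np.pi)

    cover = np.zeros(S * S * S, dtype=int)
    for t in tracts:
        cover += voxel_dirs[t.name][0]
    frac = np.zeros(S * S * S)
    frac[cover > 0] = 1.0 / cover[cover > 0]

    lobe_cache: dict[tuple, np.ndarray] = {}
    for t in tracts:
        inside, seg_idx = voxel_dirs[t.name]
        seg_dirs = _segment_directions(t.path)
        for k in range(seg_dirs.shape[0]):
            sel = inside & (seg_idx == k)
            if not np.any(sel):
                continue
            d = seg_dirs[k]
            if d[2] < 0 or (d[2] == 0 and (d[1] < 0 or (d[1] == 0 and d[0] < 0))):
                d = -d  # canonical hemisphere: lobes are antipodally symmetric
            key = (round(d[0], 9), round(d[1], 9), round(d[2], 9), t.lobe_kappa)
            if key not in lobe_cache:
                lobe_cache[key] = make_single_fiber_lobe(d, t.lobe_kappa, sh_spec)
            fodf[sel] += frac[sel, None] * lobe_cache[key][None, :]

    fodf = fodf.reshape(S, S, S, n_coeffs).astype(np.float32)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        fodf = fodf + rng.normal(
            0.0, spec.noise_sigma, size=fodf.shape
        ).astype(np.float32)
    return PhantomDataset(fodf=fodf, masks=masks, spec=spec)


def add_noise(volume: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise to every SH coefficient.

    ``sigma = 0`` returns an identical copy; fixed seeds reproduce exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    vol = np.asarray(volume)
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    return (vol + rng.normal(0.0, sigma, size=vol.shape)).astype(vol.dtype, copy=False)
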